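"""Global/regional consistency measures and condition contrasts.

Two scalar summaries per subject and scan condition feed the group
statistics:

* **global consistency** — sum the study-specific ROI SI maps node-wise,
  then take the whole-brain mean; a single number per subject/condition
  describing how consistent the subject's whole community structure is
  with the rest of the cohort.
* **regional consistency** — the mean of a *min-max scaled* SI map over
  one ROI's nodes.  Scaling is done jointly across all of a
  subject/condition's ROI maps so that regional contrasts are not driven
  by the global shift in consistency between conditions.

Condition differences are estimated with :class:`ConditionContrastModel`,
a repeated-measures linear model: each complete subject contributes one
outcome per condition, covariates (age, sex, race) enter a shared design
matrix, and the residual covariance across conditions is left
unstructured.  With complete data this multivariate least-squares fit is
the maximum-likelihood repeated-measures solution.  The results object
reports covariate-adjusted (least-squares) means per condition and all
pairwise differences β with Bonferroni-adjusted confidence intervals and
p-values.  A seeded within-subject permutation test is provided for
two-condition contrasts of regional consistency.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .si import ROISet, SIMap

__all__ = [
    "DegenerateScaleError",
    "global_consistency",
    "minmax_scale",
    "regional_consistency",
    "pairwise_difference",
    "ConditionContrastModel",
    "ConditionContrastResults",
    "PairwiseContrast",
    "PermutationResult",
    "permutation_test",
]


class DegenerateScaleError(ValueError):
    """All pooled SI values are identical; min-max scaling is undefined."""


def global_consistency(maps: Sequence[SIMap] | Mapping[int, SIMap]) -> float:
    """Whole-brain mean of the node-wise sum of per-ROI SI maps."""
    if isinstance(maps, Mapping):
        maps = [maps[k] for k in sorted(maps)]
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one SI map")
    n = maps[0].n_nodes
    if any(m.n_nodes != n for m in maps):
        raise ValueError("all SI maps must share the node universe")
    total = np.sum([m.values for m in maps], axis=0)
    return float(total.mean())


def minmax_scale(maps: Mapping[int, SIMap]) -> dict[int, SIMap]:
    """Min-max normalize one subject/condition's SI maps jointly.

    The minimum and maximum are taken over the pooled values of *all*
    the maps, so the transform is a single affine map applied to every
    ROI map of that subject/condition and preserves their ordering.
    """
    if not maps:
        raise ValueError("need at least one SI map")
    pooled_min = min(float(m.values.min()) for m in maps.values())
    pooled_max = max(float(m.values.max()) for m in maps.values())
    if pooled_max == pooled_min:
        raise DegenerateScaleError(
            "all SI values identical; min-max normalization undefined"
        )
    span = pooled_max - pooled_min
    return {
        rid: SIMap((m.values - pooled_min) / span, roi_id=m.roi_id, level=m.level)
        for rid, m in maps.items()
    }


def regional_consistency(scaled_map: SIMap, roi: ROISet) -> float:
    """Mean scaled SI over the ROI's nodes."""
    if roi.nodes.max() >= scaled_map.n_nodes:
        raise ValueError("ROI references nodes outside the map's universe")
    return float(scaled_map.values[roi.nodes].mean())


# ---------------------------------------------------------------------------
# repeated-measures condition contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseContrast:
    """One pairwise difference of least-squares means."""

    cond_a: str
    cond_b: str
    beta: float
    ci_low: float
    ci_high: float
    p_adjusted: float
    p_unadjusted: float
    se: float
    df: float


def pairwise_difference(ls_means: Mapping[str, float], cond_a: str, cond_b: str) -> float:
    """β for ``cond_a`` vs ``cond_b``: first-listed minus second."""
    return float(ls_means[cond_a]) - float(ls_means[cond_b])


class ConditionContrastModel:
    """Repeated-measures linear model for condition contrasts.

    Parameters
    ----------
    endog
        Subjects x conditions outcome matrix (complete cases only).
    exog
        Subjects x covariates matrix, or None for an intercept-only
        model.  A constant column is always added internally.
    conditions
        Condition names, in the order of ``endog``'s columns.

    Notes
    -----
    Coefficients are estimated by least squares per condition column
    with a shared design matrix; the residual covariance across
    conditions is unstructured.  Wald contrasts on differences of
    least-squares means use the t distribution with n - p degrees of
    freedom.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray | None,
        conditions: Sequence[str],
        covariate_names: Sequence[str] = (),
        n_dropped: int = 0,
    ):
        y = np.asarray(endog, dtype=np.float64)
        if y.ndim != 2:
            raise ValueError("endog must be subjects x conditions")
        n, k = y.shape
        if k != len(conditions):
            raise ValueError("endog column count must match len(conditions)")
        if exog is None:
            x = np.ones((n, 1))
        else:
            exog = np.asarray(exog, dtype=np.float64)
            if exog.shape[0] != n:
                raise ValueError("exog rows must match endog rows")
            x = np.column_stack([np.ones(n), exog])
        if n < max(3, x.shape[1] + 1):
            raise ValueError(
                f"need at least {max(3, x.shape[1] + 1)} complete subjects, got {n}"
            )
        self.endog = y
        self.exog = x
        self.conditions = tuple(conditions)
        self.covariate_names = tuple(covariate_names)
        self.n_dropped = int(n_dropped)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        value_col: str = "value",
        condition_col: str = "condition",
        subject_col: str = "subject_id",
        covariates: Sequence[str] = ("age", "sex", "race"),
        conditions: Sequence[str] | None = None,
    ) -> "ConditionContrastModel":
        """Build from a long table (one row per subject x condition).

        Subjects missing any condition (or any covariate) are dropped;
        the count of dropped subjects is kept on the model.
        """
        df = data.copy()
        if conditions is None:
            conditions = tuple(pd.unique(df[condition_col]))
        wide = df.pivot_table(
            index=subject_col, columns=condition_col, values=value_col, aggfunc="first"
        ).reindex(columns=list(conditions))
        cov = None
        if covariates:
            cov = (
                df.drop_duplicates(subject_col)
                .set_index(subject_col)[list(covariates)]
                .reindex(wide.index)
            )
            complete = wide.notna().all(axis=1) & cov.notna().all(axis=1)
        else:
            complete = wide.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        wide = wide.loc[complete]
        exog = cov.loc[complete].to_numpy(dtype=np.float64) if cov is not None else None
        return cls(
            wide.to_numpy(dtype=np.float64),
            exog,
            conditions=tuple(conditions),
            covariate_names=tuple(covariates),
            n_dropped=n_dropped,
        )

    def fit(self, alpha: float = 0.05, bonferroni: int | None = None) -> "ConditionContrastResults":
        """Estimate least-squares means and all pairwise contrasts.

        ``bonferroni`` defaults to the number of pairwise comparisons
        (3 for three conditions); confidence intervals and p-values are
        adjusted by that factor.
        """
        x, y = self.exog, self.endog
        n = x.shape[0]
        k = y.shape[1]
        m = bonferroni if bonferroni is not None else k * (k - 1) // 2
        # pseudo-inverse tolerates constant covariates (e.g. a minority
        # indicator that happens to be all-zero in a small cohort)
        xtx_inv = np.linalg.pinv(x.T @ x)
        coefs = xtx_inv @ x.T @ y  # p x k
        resid = y - x @ coefs
        rank = int(np.linalg.matrix_rank(x))
        df_resid = n - rank
        if df_resid < 1:
            raise ValueError("not enough subjects for the covariate design")
        sigma = resid.T @ resid / df_resid  # unstructured k x k
        xbar = x.mean(axis=0)
        ls_means = {c: float(xbar @ coefs[:, j]) for j, c in enumerate(self.conditions)}
        leverage = float(xbar @ xtx_inv @ xbar)
        tcrit = sps.t.ppf(1.0 - alpha / (2.0 * m), df_resid)
        pairwise: dict[tuple[str, str], PairwiseContrast] = {}
        for i, j in itertools.combinations(range(k), 2):
            ca, cb = self.conditions[i], self.conditions[j]
            beta = ls_means[ca] - ls_means[cb]
            var = leverage * (sigma[i, i] + sigma[j, j] - 2.0 * sigma[i, j])
            se = float(np.sqrt(max(var, 0.0)))
            tval = beta / se if se > 0 else np.inf * np.sign(beta or 1.0)
            p_un = float(2.0 * sps.t.sf(abs(tval), df_resid))
            pairwise[(ca, cb)] = PairwiseContrast(
                cond_a=ca,
                cond_b=cb,
                beta=beta,
                ci_low=beta - tcrit * se,
                ci_high=beta + tcrit * se,
                p_adjusted=min(1.0, m * p_un),
                p_unadjusted=p_un,
                se=se,
                df=float(df_resid),
            )
        return ConditionContrastResults(
            model=self,
            params=coefs,
            resid_cov=sigma,
            ls_means=ls_means,
            pairwise=pairwise,
            alpha=alpha,
            bonferroni=m,
        )


@dataclass
class ConditionContrastResults:
    """Least-squares means, pairwise βs, and their uncertainty."""

    model: ConditionContrastModel
    params: np.ndarray
    resid_cov: np.ndarray
    ls_means: dict[str, float]
    pairwise: dict[tuple[str, str], PairwiseContrast]
    alpha: float
    bonferroni: int

    @property
    def nobs(self) -> int:
        return self.model.endog.shape[0]

    def beta(self, cond_a: str, cond_b: str) -> float:
        """β(cond_a, cond_b) = ls_means[cond_a] - ls_means[cond_b]."""
        return pairwise_difference(self.ls_means, cond_a, cond_b)

    def contrast(self, cond_a: str, cond_b: str) -> PairwiseContrast:
        """Pairwise contrast in either orientation (sign flips)."""
        if (cond_a, cond_b) in self.pairwise:
            return self.pairwise[(cond_a, cond_b)]
        c = self.pairwise[(cond_b, cond_a)]
        return PairwiseContrast(
            cond_a=cond_a,
            cond_b=cond_b,
            beta=-c.beta,
            ci_low=-c.ci_high,
            ci_high=-c.ci_low,
            p_adjusted=c.p_adjusted,
            p_unadjusted=c.p_unadjusted,
            se=c.se,
            df=c.df,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": f"{c.cond_a} vs. {c.cond_b}",
                "beta": c.beta,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_adjusted": c.p_adjusted,
            }
            for c in self.pairwise.values()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report: LS means, then pairwise contrasts."""
        lines = [
            "Repeated-measures condition contrasts",
            f"  subjects: {self.nobs} (dropped incomplete: {self.model.n_dropped})",
            f"  covariates: {', '.join(self.model.covariate_names) or 'none'}",
            f"  Bonferroni factor: {self.bonferroni}   alpha: {self.alpha}",
            "",
            "  Least-squares means",
        ]
        for c, v in self.ls_means.items():
            lines.append(f"    {c:<10s} {v: .4f}")
        lines += ["", f"  {'Comparison':<18s}{'beta':>9s}{'95% CI':>22s}{'p (adj.)':>10s}"]
        for c in self.pairwise.values():
            ci = f"[{c.ci_low: .4f}, {c.ci_high: .4f}]"
            lines.append(
                f"  {c.cond_a + ' vs. ' + c.cond_b:<18s}{c.beta: 9.4f}{ci:>22s}"
                f"{c.p_adjusted:10.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Two-sided within-subject permutation test result."""

    observed: float
    p_value: float
    n_perm: int
    null: np.ndarray


def permutation_test(
    maps_a: Mapping[object, SIMap],
    maps_b: Mapping[object, SIMap],
    roi: ROISet,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Within-subject label-swap test for a two-condition regional contrast.

    The observed statistic is the difference in group-mean regional
    consistency between conditions a and b.  Under the null the two
    condition labels are exchangeable within each subject, so each
    permutation independently swaps a/b per subject.  The two-sided
    p-value is (1 + #{|null| >= |observed|}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if set(maps_a) != set(maps_b):
        raise ValueError("the two conditions must cover the same subjects")
    subjects = sorted(maps_a, key=repr)
    ra = np.array([regional_consistency(maps_a[s], roi) for s in subjects])
    rb = np.array([regional_consistency(maps_b[s], roi) for s in subjects])
    diff = ra - rb
    observed = float(diff.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(int(n_perm), diff.size))
    null = (signs * diff).mean(axis=1)
    p = float((1 + np.sum(np.abs(null) >= abs(observed))) / (1 + n_perm))
    return PermutationResult(observed=observed, p_value=p, n_perm=int(n_perm), null=null)
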