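"""Synthetic multi-subject, multi-condition cohorts with planted communities.

The study data this package targets — BOLD time series from an older-adult
cohort scanned at rest and during two graded motor-imagery tasks — are not
publicly deposited, so every downstream stage is exercised on synthetic
cohorts instead.  Each subject/condition gets a node time-series matrix
drawn from a latent-factor block model: nodes in the same community share
a latent Gaussian factor, an optional global factor is shared by all
nodes, and independent Gaussian noise is added per node.  Factor loadings
are solved so the expected within-community Pearson correlation equals
``within_r`` and the between-community correlation equals ``between_r``.

Condition-dependent loss of cross-subject spatial consistency — the
phenomenon the Scaled Inclusivity analysis measures — is planted by
*jitter*: before signals are synthesized, a per-condition fraction of
nodes is reassigned to a uniformly random other community, independently
per subject.  Higher jitter means subjects agree less about where each
community lives, which lowers group SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Partition

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "template_partition",
    "generate_block_timeseries",
    "generate_cohort",
    "generate_vas_responses",
    "generate_covariates",
]


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``conditions`` maps each condition name to its jitter fraction, the
    share of nodes whose community membership is scrambled per subject.
    Defaults emulate the target study's design at desk scale: three
    conditions (Rest, then an easy and a hard imagery task) with
    consistency degrading as task load increases.
    """

    n_subjects: int = 20
    n_nodes: int = 200
    community_sizes: tuple[int, ...] = (50, 50, 50, 50)
    conditions: tuple[tuple[str, float], ...] = (
        ("Rest", 0.0),
        ("Easy", 0.2),
        ("Hard", 0.4),
    )
    within_r: float = 0.6
    between_r: float = 0.0
    n_timepoints: int = 300
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(sz < 1 for sz in self.community_sizes):
            raise ValueError("every community must be non-empty")
        if sum(self.community_sizes) != self.n_nodes:
            raise ValueError(
                f"community sizes sum to {sum(self.community_sizes)}, "
                f"expected n_nodes={self.n_nodes}"
            )
        if not 0 <= self.within_r < 1:
            raise ValueError("within_r must lie in [0, 1)")
        # within_r = 0 (pure noise) is allowed; otherwise between_r < within_r
        if self.within_r == 0:
            if self.between_r != 0:
                raise ValueError("between_r must be 0 when within_r is 0")
        elif not 0 <= self.between_r < self.within_r:
            raise ValueError("between_r must lie in [0, within_r)")
        for name, j in self.conditions:
            if not 0 <= j <= 1:
                raise ValueError(f"jitter for condition {name!r} must be in [0, 1]")
        if self.n_timepoints < 30:
            raise ValueError("n_timepoints must be >= 30")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.conditions)

    @property
    def n_communities(self) -> int:
        return len(self.community_sizes)


@dataclass
class GroundTruth:
    """Planted partitions and the nodes jittered away from the template."""

    template: Partition
    planted: dict[tuple[int, str], Partition] = field(default_factory=dict)
    jittered_nodes: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)


@dataclass
class Cohort:
    """Generated time series keyed by (subject index, condition name)."""

    spec: CohortSpec
    timeseries: dict[tuple[int, str], np.ndarray]
    ground_truth: GroundTruth

    def subjects(self) -> range:
        return range(self.spec.n_subjects)


def template_partition(community_sizes: tuple[int, ...] | list[int]) -> Partition:
    """Contiguous block partition: the cohort's shared community template."""
    return Partition(np.repeat(np.arange(len(community_sizes)), community_sizes))


def _loadings(spec: CohortSpec) -> tuple[float, float]:
    """Community and global factor loadings hitting the target correlations.

    With node signal x = lg*g + lc*f_c + noise_sd*eps, the within- and
    between-community correlations are (lg^2 + lc^2)/v and lg^2/v where
    v = lg^2 + lc^2 + noise_sd^2.  Solving gives v = noise_sd^2/(1 - within_r).
    """
    v = spec.noise_sd**2 / (1.0 - spec.within_r)
    lam_g = float(np.sqrt(spec.between_r * v))
    lam_c = float(np.sqrt((spec.within_r - spec.between_r) * v))
    return lam_c, lam_g


def generate_block_timeseries(
    spec: CohortSpec,
    partition: Partition | np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One nodes x timepoints matrix from the latent-factor block model.

    With the default ``rng=None`` the spec's own seed is used, so the
    same spec always yields bit-identical output.
    """
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if labels.size == 0:
        raise ValueError("partition is empty")
    if np.any(np.bincount(labels) == 0):
        raise ValueError("empty community in partition")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lam_c, lam_g = _loadings(spec)
    n_comm = int(labels.max()) + 1
    t = spec.n_timepoints
    factors = rng.standard_normal((n_comm, t))
    global_factor = rng.standard_normal(t)
    noise = rng.standard_normal((labels.size, t))
    return lam_c * factors[labels] + lam_g * global_factor + spec.noise_sd * noise


def _jitter_labels(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Reassign a fraction of nodes to a uniformly random other community."""
    n = labels.size
    n_move = int(round(fraction * n))
    if n_move == 0:
        return labels.copy(), np.empty(0, dtype=np.int64)
    n_comm = int(labels.max()) + 1
    if n_comm < 2:
        raise ValueError("jitter requires at least two communities")
    moved = np.sort(rng.choice(n, size=n_move, replace=False))
    out = labels.copy()
    # shift by 1..n_comm-1 modulo n_comm: uniform over the *other* communities
    shift = rng.integers(1, n_comm, size=n_move)
    out[moved] = (out[moved] + shift) % n_comm
    return out, moved.astype(np.int64)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full synthetic cohort: time series plus planted ground truth.

    Per subject and condition the template partition is jittered by that
    condition's fraction, the signal is synthesized from the *jittered*
    membership (so the graph itself reflects the perturbation), and both
    the planted partition and the moved nodes are recorded.
    """
    template = template_partition(spec.community_sizes)
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects * len(spec.conditions))
    gt = GroundTruth(template=template)
    data: dict[tuple[int, str], np.ndarray] = {}
    idx = 0
    for subj in range(spec.n_subjects):
        for cond, jitter in spec.conditions:
            rng = np.random.default_rng(children[idx])
            idx += 1
            labels, moved = _jitter_labels(template.labels, jitter, rng)
            # keep empty communities out of the signal model: jitter can in
            # principle empty a block at extreme fractions on tiny cohorts
            if np.any(np.bincount(labels, minlength=spec.n_communities) == 0):
                labels[moved[0]] = int(
                    np.argmin(np.bincount(labels, minlength=spec.n_communities))
                )
            key = (subj, cond)
            gt.planted[key] = Partition(labels, canonicalize=False)
            gt.jittered_nodes[key] = moved
            data[key] = generate_block_timeseries(spec, labels, rng)
    return Cohort(spec=spec, timeseries=data, ground_truth=gt)


def generate_vas_responses(
    n_subjects: int,
    location_shift: float = 0.0,
    seed: int = 0,
    question: str | None = None,
) -> pd.DataFrame:
    """Synthetic 0-100 visual-analog-scale scores for an easy and a hard task.

    ``location_shift`` is the expected easy-minus-hard difference; 0
    gives symmetric responses.  Scores are integers clipped to [0, 100].
    Many subjects report identical scores for both tasks, mimicking the
    heaped, coarse use of VAS sliders seen in practice.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    base = rng.normal(65.0, 15.0, size=n_subjects)
    same = rng.random(n_subjects) < 0.5  # heaping: identical easy/hard reports
    diff = rng.normal(location_shift, 12.0, size=n_subjects)
    easy = base + np.where(same & (location_shift == 0), 0.0, diff / 2.0)
    hard = base - np.where(same & (location_shift == 0), 0.0, diff / 2.0)
    out = pd.DataFrame(
        {
            "subject_id": np.arange(n_subjects),
            "easy_score": np.clip(np.rint(easy), 0, 100).astype(int),
            "hard_score": np.clip(np.rint(hard), 0, 100).astype(int),
        }
    )
    if question is not None:
        out.insert(1, "question", question)
    return out


def generate_covariates(n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic demographics shaped like an older-adult mobility cohort.

    Age ~ N(76, 4.3) years, 55% female, 8% African American — the
    covariates adjusted for in the condition contrasts.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": np.arange(n_subjects),
            "age": np.round(rng.normal(76.1, 4.3, size=n_subjects), 1),
            "sex": (rng.random(n_subjects) < 0.554).astype(int),
            "race": (rng.random(n_subjects) < 0.083).astype(int),
        }
    )
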