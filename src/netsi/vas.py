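"""Classification of easy-vs-hard visual-analog-scale (VAS) responses.

After each task run subjects rate themselves 0-100 on several questions.
For a given question, each subject's hard-task score is subtracted from
the easy-task score and the cohort is split into negative (easy < hard),
zero (exact tie of the integer scores), and positive (easy > hard)
groups.  Percentages use the number of responders to that question —
subjects missing either score are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VASClassification", "classify_differences"]

GROUPS = ("negative", "zero", "positive")


@dataclass(frozen=True)
class VASClassification:
    """Counts and percentages of easy-minus-hard difference signs."""

    question: str | None
    counts: dict[str, int]
    percentages: dict[str, float]
    n_responders: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        """One row shaped like a published contingency table."""
        row = {"question": self.question or "all"}
        for g, col in zip(GROUPS, ("easy<hard", "easy=hard", "easy>hard")):
            row[col] = f"{self.counts[g]} ({self.percentages[g]:.1f})"
        return pd.DataFrame([row])


def classify_differences(
    table: pd.DataFrame, question: str | None = None
) -> VASClassification:
    """Group subjects by the sign of easy_score - hard_score.

    ``table`` needs columns ``easy_score`` and ``hard_score`` (and
    ``question`` when a question filter is given).  Percentages are
    count / responders x 100, reported to one decimal.
    """
    df = table
    if question is not None:
        df = df[df["question"] == question]
    if df.empty:
        raise ValueError(f"no VAS rows{f' for question {question!r}' if question else ''}")
    easy = pd.to_numeric(df["easy_score"], errors="coerce")
    hard = pd.to_numeric(df["hard_score"], errors="coerce")
    ok = easy.notna() & hard.notna()
    n_excluded = int((~ok).sum())
    diff = easy[ok].to_numpy() - hard[ok].to_numpy()
    n = diff.size
    if n == 0:
        raise ValueError("no subject has both scores for this question")
    counts = {
        "negative": int(np.sum(diff < 0)),
        "zero": int(np.sum(diff == 0)),
        "positive": int(np.sum(diff > 0)),
    }
    percentages = {g: round(100.0 * c / n, 1) for g, c in counts.items()}
    return VASClassification(
        question=question,
        counts=counts,
        percentages=percentages,
        n_responders=n,
        n_excluded=n_excluded,
    )
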