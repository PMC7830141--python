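"""Scaled Inclusivity: cross-subject consistency of community structure.

Scaled Inclusivity (SI) quantifies how consistently a reference
community — typically an a-priori subnetwork ROI such as the default
mode network — is reproduced in each subject's data-driven partition.
For a reference node set R and a candidate community C the statistic is

    SI(R, C) = |R ∩ C|**2 / (|R| * |C|)

which lies in [0, 1], equals 1 iff R == C, and penalizes both
fragmentation (C missing parts of R) and dilation (C spilling beyond R).

A subject's SI *map* seeds the statistic with the ROI but scores every
node in the brain: node v receives SI(R, C(v)) where C(v) is the
community containing v in that subject's partition.  Nodes whose
community is disjoint from the ROI score 0; nodes outside the ROI can
score above 0 whenever their community overlaps it, which is what lets
the method detect consistent structure the original ROI missed.  The
group map is the node-wise mean of the subject maps, so perfect spatial
alignment across every subject yields exactly 1 on the community's
nodes.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .community import Partition

__all__ = ["ROISet", "SIMap", "pairwise_si", "subject_si_map", "group_si_map"]


@dataclass(frozen=True)
class ROISet:
    """A reference region of interest: an identifier and its node set."""

    roi_id: int
    nodes: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        nodes = np.unique(np.asarray(self.nodes, dtype=np.int64))
        if nodes.size == 0:
            raise ValueError(f"ROI {self.roi_id} is empty")
        if nodes.min() < 0:
            raise ValueError(f"ROI {self.roi_id} has negative node indices")
        object.__setattr__(self, "nodes", nodes)

    @property
    def size(self) -> int:
        return int(self.nodes.size)


@dataclass
class SIMap:
    """Node-wise Scaled Inclusivity values seeded from one ROI."""

    values: np.ndarray
    roi_id: int
    level: str = "subject"  # "subject" or "group"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("SI map must be a 1-D node vector")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("SI values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return int(self.values.size)

    def mean(self) -> float:
        """Whole-map mean; the per-subject-per-ROI scalar summary."""
        return float(self.values.mean())


def pairwise_si(ref: Iterable[int], cand: Iterable[int]) -> float:
    """SI between a reference node set and a candidate community."""
    ref = frozenset(int(v) for v in ref)
    cand = frozenset(int(v) for v in cand)
    if not ref or not cand:
        raise ValueError("SI is undefined for an empty node set")
    inter = len(ref & cand)
    return inter * inter / (len(ref) * len(cand))


def subject_si_map(roi: ROISet, partition: Partition) -> SIMap:
    """Whole-brain SI map of one subject's partition seeded by ``roi``.

    Every node in community C receives SI(roi, C); the map therefore has
    one distinct value per community.
    """
    n = partition.n_nodes
    if roi.nodes.max() >= n:
        raise ValueError(
            f"ROI {roi.roi_id} references node {int(roi.nodes.max())} but the "
            f"partition covers only {n} nodes"
        )
    labels = partition.labels
    n_comm = partition.n_communities
    comm_size = np.bincount(labels, minlength=n_comm)
    overlap = np.bincount(labels[roi.nodes], minlength=n_comm)
    si_per_comm = overlap.astype(np.float64) ** 2 / (roi.size * comm_size)
    return SIMap(si_per_comm[labels], roi_id=roi.roi_id, level="subject")


def group_si_map(roi: ROISet, partitions: Sequence[Partition]) -> SIMap:
    """Node-wise mean of per-subject SI maps across a cohort.

    A node scores 1 iff every subject's community containing it equals
    the ROI exactly (perfect spatial alignment).
    """
    partitions = list(partitions)
    if not partitions:
        raise ValueError("need at least one subject partition")
    n = partitions[0].n_nodes
    acc = np.zeros(n, dtype=np.float64)
    for part in partitions:
        if part.n_nodes != n:
            raise ValueError("all partitions must share the node universe")
        acc += subject_si_map(roi, part).values
    return SIMap(acc / len(partitions), roi_id=roi.roi_id, level="group")
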