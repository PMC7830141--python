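"""Study-specific ROI refinement by pooled-SI argmax assignment.

Reference subnetwork ROIs are typically drawn from a different (often
younger) population than the cohort under study.  To de-bias them, the
group SI map of every reference ROI is pooled over all subjects and all
scan conditions, and each node is then reassigned to whichever ROI shows
the highest pooled SI there.  The result tiles the node universe exactly
once.  An ROI that collects scanner-artifact regions can be flagged as
excluded so downstream statistics skip it.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .community import Partition
from .si import ROISet, SIMap, group_si_map

__all__ = [
    "ROIAtlas",
    "AllROIsExcludedError",
    "pooled_si_maps",
    "assign_by_argmax",
    "exclude_rois",
    "rois_from_labels",
]


class AllROIsExcludedError(ValueError):
    """Every ROI in the atlas is excluded; nothing left to analyze."""


@dataclass
class ROIAtlas:
    """Node -> ROI assignment with optional excluded (artifact) ROIs."""

    assignment: np.ndarray
    source_roi_ids: tuple[int, ...]
    excluded_roi_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        self.source_roi_ids = tuple(int(r) for r in self.source_roi_ids)
        self.excluded_roi_ids = frozenset(int(r) for r in self.excluded_roi_ids)
        extra = set(np.unique(self.assignment)) - set(self.source_roi_ids)
        if extra:
            raise ValueError(f"assignment uses unknown ROI ids {sorted(extra)}")

    @property
    def n_nodes(self) -> int:
        return int(self.assignment.size)

    def roi(self, roi_id: int) -> ROISet:
        nodes = np.flatnonzero(self.assignment == roi_id)
        return ROISet(roi_id=roi_id, nodes=nodes)

    def present_roi_ids(self) -> tuple[int, ...]:
        """ROI ids that received at least one node."""
        present = set(np.unique(self.assignment).tolist())
        return tuple(r for r in self.source_roi_ids if r in present)

    def analyzable_rois(self) -> list[ROISet]:
        """Non-excluded, non-empty ROIs, in ascending id order."""
        ids = [r for r in self.present_roi_ids() if r not in self.excluded_roi_ids]
        if not ids:
            raise AllROIsExcludedError("no analyzable ROIs remain in the atlas")
        return [self.roi(r) for r in ids]

    def node_counts(self) -> dict[int, int]:
        counts = dict(zip(*np.unique(self.assignment, return_counts=True)))
        return {int(r): int(counts.get(r, 0)) for r in self.source_roi_ids}


def rois_from_labels(labels: np.ndarray | Partition) -> list[ROISet]:
    """One ROISet per distinct label in a node -> roi_id map."""
    if isinstance(labels, Partition):
        labels = labels.labels
    labels = np.asarray(labels, dtype=np.int64)
    return [
        ROISet(roi_id=int(r), nodes=np.flatnonzero(labels == r))
        for r in np.unique(labels)
    ]


def pooled_si_maps(
    rois: Sequence[ROISet], partitions: Sequence[Partition]
) -> dict[int, SIMap]:
    """Group SI map per ROI, pooled over every subject-condition partition.

    Pooling is a flat mean: each partition (one subject in one scan
    condition) contributes equally.
    """
    partitions = list(partitions)
    if not partitions:
        raise ValueError("need at least one partition to pool over")
    n = partitions[0].n_nodes
    if any(p.n_nodes != n for p in partitions):
        raise ValueError("all partitions must share the node universe")
    return {roi.roi_id: group_si_map(roi, partitions) for roi in rois}


def assign_by_argmax(maps: dict[int, SIMap]) -> ROIAtlas:
    """Assign every node to the ROI whose pooled SI is highest there.

    Ties — including nodes where every map is zero — go to the lowest
    roi_id, so the assignment is deterministic.
    """
    if not maps:
        raise ValueError("need at least one SI map")
    roi_ids = sorted(maps)
    stack = np.stack([maps[r].values for r in roi_ids])
    if stack.ndim != 2 or len({m.n_nodes for m in maps.values()}) != 1:
        raise ValueError("all SI maps must share the node universe")
    winners = np.argmax(stack, axis=0)  # first max -> lowest roi_id on ties
    assignment = np.asarray(roi_ids, dtype=np.int64)[winners]
    return ROIAtlas(assignment=assignment, source_roi_ids=tuple(roi_ids))


def exclude_rois(atlas: ROIAtlas, roi_ids: Sequence[int]) -> ROIAtlas:
    """Flag ROIs (e.g. the MRI-artifact region) as excluded downstream."""
    roi_ids = [int(r) for r in roi_ids]
    unknown = set(roi_ids) - set(atlas.source_roi_ids)
    if unknown:
        raise ValueError(f"cannot exclude unknown ROI ids {sorted(unknown)}")
    return ROIAtlas(
        assignment=atlas.assignment.copy(),
        source_roi_ids=atlas.source_roi_ids,
        excluded_roi_ids=atlas.excluded_roi_ids | set(roi_ids),
    )
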