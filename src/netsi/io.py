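"""On-disk formats: delimited-text adapters and an optional NIfTI bridge.

Everything the pipeline reads or writes is plain text.  Node indices are
0-based everywhere except edge lists, which follow the 1-based (i < j)
convention usual for exchanged edge files.  Malformed lines are reported
with their 1-based line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .community import Partition
from .network import AdjacencyMatrix

__all__ = [
    "FormatError",
    "write_timeseries",
    "read_timeseries",
    "write_edgelist",
    "read_edgelist",
    "write_partition",
    "read_partition",
    "write_roi_map",
    "read_roi_map",
    "write_si_map",
    "read_si_map",
    "timeseries_from_nifti",
    "si_map_to_nifti",
]


class FormatError(ValueError):
    """A file failed to parse; carries the offending line number."""

    def __init__(self, path: Path | str, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


# ---------------------------------------------------------------------------
# time series (nodes x timepoints)
# ---------------------------------------------------------------------------


def write_timeseries(ts: np.ndarray, path: Path | str) -> None:
    """Nodes x timepoints TSV with a header row of timepoint indices."""
    ts = np.asarray(ts)
    df = pd.DataFrame(ts, columns=[str(t) for t in range(ts.shape[1])])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries(path: Path | str) -> np.ndarray:
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, ValueError) as err:
        raise FormatError(path, 0, f"unparseable time-series TSV: {err}") from err
    arr = df.to_numpy(dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(path, 1, "expected a non-empty nodes x timepoints table")
    return arr


# ---------------------------------------------------------------------------
# two-column integer tables (edge lists, partitions, ROI maps)
# ---------------------------------------------------------------------------


def _read_two_int_columns(path: Path | str, header: tuple[str, str]) -> list[tuple[int, int]]:
    rows: list[tuple[int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if line_no == 1 and parts[0] == header[0]:
                continue
            if len(parts) != 2:
                raise FormatError(path, line_no, f"expected 2 columns, got {len(parts)}")
            try:
                rows.append((int(parts[0]), int(parts[1])))
            except ValueError as err:
                raise FormatError(path, line_no, f"non-integer field: {err}") from err
    if not rows:
        raise FormatError(path, 1, "empty table")
    return rows


def write_edgelist(adj: AdjacencyMatrix, path: Path | str) -> None:
    """Edges as 1-based (node_i, node_j) pairs with i < j."""
    iu, ju = np.triu_indices(adj.n, k=1)
    mask = adj.a[iu, ju].astype(bool)
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\n")
        for i, j in zip(iu[mask] + 1, ju[mask] + 1):
            fh.write(f"{i}\t{j}\n")


def read_edgelist(path: Path | str, n_nodes: int, requested_s: float | None = None) -> AdjacencyMatrix:
    rows = _read_two_int_columns(path, ("node_i", "node_j"))
    a = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
    for line_no, (i, j) in enumerate(rows, start=2):
        if not (1 <= i <= n_nodes and 1 <= j <= n_nodes):
            raise FormatError(path, line_no, f"node index out of range: ({i}, {j})")
        if i == j:
            raise FormatError(path, line_no, f"self-loop at node {i}")
        a[i - 1, j - 1] = a[j - 1, i - 1] = 1
    return AdjacencyMatrix(a, requested_s=requested_s)


def _write_label_map(labels: np.ndarray, path: Path | str, value_name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"node_id\t{value_name}\n")
        for node, lab in enumerate(np.asarray(labels)):
            fh.write(f"{node}\t{int(lab)}\n")


def _read_label_map(path: Path | str, value_name: str) -> np.ndarray:
    rows = _read_two_int_columns(path, ("node_id", value_name))
    nodes = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    n = nodes.max() + 1
    if sorted(nodes.tolist()) != list(range(n)):
        raise FormatError(path, 1, "node ids must cover 0..n-1 exactly once")
    out = np.empty(n, dtype=np.int64)
    out[nodes] = vals
    return out


def write_partition(partition: Partition, path: Path | str) -> None:
    _write_label_map(partition.labels, path, "community_id")


def read_partition(path: Path | str) -> Partition:
    return Partition(_read_label_map(path, "community_id"))


def write_roi_map(labels: np.ndarray, path: Path | str) -> None:
    _write_label_map(labels, path, "roi_id")


def read_roi_map(path: Path | str) -> np.ndarray:
    return _read_label_map(path, "roi_id")


# ---------------------------------------------------------------------------
# SI maps
# ---------------------------------------------------------------------------


def write_si_map(values: np.ndarray, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tvalue\n")
        for node, v in enumerate(np.asarray(values, dtype=np.float64)):
            fh.write(f"{node}\t{v:.12g}\n")


def read_si_map(path: Path | str) -> np.ndarray:
    vals: list[float] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (line_no == 1 and line.startswith("node_id")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(path, line_no, f"expected 2 columns, got {len(parts)}")
            try:
                node, v = int(parts[0]), float(parts[1])
            except ValueError as err:
                raise FormatError(path, line_no, str(err)) from err
            if node != len(vals):
                raise FormatError(path, line_no, f"node ids must be consecutive, got {node}")
            vals.append(v)
    if not vals:
        raise FormatError(path, 1, "empty SI map")
    return np.asarray(vals)


# ---------------------------------------------------------------------------
# NIfTI adapter (optional; requires nibabel)
# ---------------------------------------------------------------------------


def timeseries_from_nifti(bold_path: Path | str, mask_path: Path | str):
    """Extract a nodes x timepoints matrix from a 4D volume and a mask.

    Nodes are the non-zero mask voxels in C order; the returned index
    array maps node -> flat voxel index so maps can be written back
    losslessly with :func:`si_map_to_nifti`.
    """
    import nibabel as nib

    bold = nib.load(str(bold_path))
    mask = nib.load(str(mask_path))
    mdata = np.asarray(mask.dataobj) > 0
    data = np.asarray(bold.dataobj)
    if data.ndim != 4:
        raise ValueError("BOLD image must be 4-D")
    if mdata.shape != data.shape[:3]:
        raise ValueError("mask and BOLD spatial shapes differ")
    flat_idx = np.flatnonzero(mdata.reshape(-1))
    ts = data.reshape(-1, data.shape[3])[flat_idx].astype(np.float64)
    return ts, flat_idx


def si_map_to_nifti(values: np.ndarray, flat_idx: np.ndarray, mask_path: Path | str, out_path: Path | str) -> None:
    """Write a node-wise map back into the mask's voxel grid."""
    import nibabel as nib

    mask = nib.load(str(mask_path))
    shape = mask.shape[:3]
    vol = np.zeros(int(np.prod(shape)), dtype=np.float64)
    vol[np.asarray(flat_idx)] = np.asarray(values, dtype=np.float64)
    img = nib.Nifti1Image(vol.reshape(shape), mask.affine)
    nib.save(img, str(out_path))
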