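"""Segmentation quality metrics: DICE overlap and average Hausdorff distance.

DICE measures volume overlap and is insensitive to boundary errors; the
average Hausdorff distance (AVHD) between extracted tissue boundaries (the
WM-GM and GM-CSF interfaces) is the boundary-sensitive metric the
refinement aims to improve.  AVHD here is the maximum of the two directed
average nearest-neighbor distances, with both directed values reported so
either convention can be audited.  Distances are in voxel-index units by
default; a flag switches to mm via the voxel size.
"""

from __future__ import annotations

import dataclasses
import csv
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import CSF, GM, WM, LabelVolume

__all__ = ["BoundarySet", "SegMetrics", "dice", "extract_boundary",
           "average_hausdorff", "evaluate_report", "write_report"]


@dataclasses.dataclass
class BoundarySet:
    """Voxel coordinates of one tissue interface layer."""

    voxels: np.ndarray          # (m, 3) integer coordinates
    grid_shape: tuple[int, int, int]
    interface_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        if self.voxels.size and (
            np.any(self.voxels < 0)
            or np.any(self.voxels >= np.asarray(self.grid_shape))
        ):
            raise ValueError("boundary coordinates outside the source grid")

    def __len__(self) -> int:
        return self.voxels.shape[0]


@dataclasses.dataclass
class SegMetrics:
    dice: float | None
    avhd: float | None
    directed_ab: float | None = None
    directed_ba: float | None = None
    interface_name: str = ""


def _require_same_grid(a: LabelVolume, b: LabelVolume) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")


def dice(a: LabelVolume, b: LabelVolume, label: int) -> float:
    """2 |A n B| / (|A| + |B|) over voxels carrying ``label`` (1 if both empty)."""
    _require_same_grid(a, b)
    am, bm = a.labels == label, b.labels == label
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom


def extract_boundary(seg: LabelVolume, class_a: int, class_b: int,
                     name: str | None = None) -> BoundarySet:
    """Voxels of class_a with at least one face neighbor (6-connectivity)
    of class_b — the thinnest well-defined interface layer."""
    for lab in (class_a, class_b):
        if lab not in seg.vocabulary:
            raise ValueError(f"label {lab} not in vocabulary {sorted(seg.vocabulary)}")
    am = seg.labels == class_a
    bm = seg.labels == class_b
    near_b = np.zeros_like(bm)
    for ax in range(3):
        for shift in (1, -1):
            near_b |= np.roll(bm, shift, axis=ax) & _valid_roll(bm.shape, ax, shift)
    coords = np.argwhere(am & near_b)
    if name is None:
        name = f"{seg.vocabulary[class_a]}-{seg.vocabulary[class_b]}"
    return BoundarySet(coords, seg.shape, interface_name=name)


def _valid_roll(shape, ax: int, shift: int) -> np.ndarray:
    """Mask that cancels np.roll wrap-around along one axis."""
    valid = np.ones(shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[ax] = slice(0, 1) if shift == 1 else slice(-1, None)
    valid[tuple(sl)] = False
    return valid


def average_hausdorff(a: BoundarySet, b: BoundarySet,
                      voxel_size: np.ndarray | None = None) -> SegMetrics:
    """Max of the two directed average nearest-neighbor distances.

    directed(A->B) is the mean over a in A of the minimum Euclidean distance
    to B, computed with a Euclidean distance transform on the voxel grid.
    With ``voxel_size`` the distances are physical (mm); default is
    voxel-index units.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("average Hausdorff distance is undefined for empty boundary sets")
    if a.grid_shape != b.grid_shape:
        raise ValueError("boundary sets live on different grids")
    sampling = None if voxel_size is None else tuple(np.asarray(voxel_size, float))

    def directed(src: BoundarySet, dst: BoundarySet) -> float:
        occ = np.ones(dst.grid_shape, dtype=bool)
        occ[tuple(dst.voxels.T)] = False
        dt = ndimage.distance_transform_edt(occ, sampling=sampling)
        return float(dt[tuple(src.voxels.T)].mean())

    d_ab, d_ba = directed(a, b), directed(b, a)
    return SegMetrics(dice=None, avhd=max(d_ab, d_ba),
                      directed_ab=d_ab, directed_ba=d_ba,
                      interface_name=a.interface_name or b.interface_name)


def evaluate_report(seg: LabelVolume, truth: LabelVolume,
                    in_mm: bool = False) -> dict[str, SegMetrics]:
    """GM DICE plus AVHD on the WM-GM and GM-CSF interfaces."""
    _require_same_grid(seg, truth)
    vs = seg.voxel_size if in_mm else None
    out: dict[str, SegMetrics] = {
        "GM": SegMetrics(dice=dice(seg, truth, GM), avhd=None, interface_name="GM")
    }
    for name, (ca, cb) in (("WM-GM", (GM, WM)), ("GM-CSF", (GM, CSF))):
        bs = extract_boundary(seg, ca, cb, name=name)
        bt = extract_boundary(truth, ca, cb, name=name)
        m = average_hausdorff(bs, bt, voxel_size=vs)
        m.interface_name = name
        out[name] = m
    return out


def write_report(report: dict[str, SegMetrics], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["interface", "dice", "avhd", "directed_ab", "directed_ba"])
        for name, m in report.items():
            w.writerow([name,
                        "" if m.dice is None else f"{m.dice:.6f}",
                        "" if m.avhd is None else f"{m.avhd:.6f}",
                        "" if m.directed_ab is None else f"{m.directed_ab:.6f}",
                        "" if m.directed_ba is None else f"{m.directed_ba:.6f}"])
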