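"""2D histograms with an invertible voxel-to-bin map.

The histogram over two aligned feature volumes (intensity x gradient
magnitude, or ilr1 x ilr2) is the canvas on which transfer functions are
defined: a transfer function is just a boolean mask over the bins, and the
stored voxel->bin map carries any bin selection back to voxel space.
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from io import BytesIO
from pathlib import Path
from typing import Optional

import numpy as np

from .volume_io import LabelVolume, ScalarVolume

__all__ = ["Histogram2D", "build_histogram", "bins_to_voxels",
           "save_histogram", "load_histogram"]

#: voxel_bin value for voxels outside the mask or the clip range
OUT_OF_RANGE = -1


@dataclasses.dataclass
class Histogram2D:
    """Bin counts over two feature axes plus the voxel->bin index map.

    ``voxel_bin`` has the source grid shape plus a trailing axis of length 2
    holding (bin_x, bin_y), with OUT_OF_RANGE marking voxels that were out of
    mask or outside the clipped axis range.
    """

    edges_x: np.ndarray
    edges_y: np.ndarray
    counts: np.ndarray
    voxel_bin: np.ndarray
    axes_names: tuple[str, str] = ("x", "y")
    voxel_size: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = None

    @property
    def nbins(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxel_bin.shape[:3]  # type: ignore[return-value]

    def centers_x(self) -> np.ndarray:
        return 0.5 * (self.edges_x[:-1] + self.edges_x[1:])

    def centers_y(self) -> np.ndarray:
        return 0.5 * (self.edges_y[:-1] + self.edges_y[1:])


def _digitize(values: np.ndarray, lo: float, hi: float, nbins: int) -> np.ndarray:
    """Equal-width bin index in [0, nbins); OUT_OF_RANGE outside [lo, hi]."""
    if hi <= lo:
        # Degenerate axis (constant feature): everything lands in bin 0.
        return np.where(values == lo, 0, OUT_OF_RANGE)
    idx = np.floor((values - lo) / (hi - lo) * nbins).astype(np.int64)
    idx[values == hi] = nbins - 1  # right edge inclusive
    idx[(values < lo) | (values > hi)] = OUT_OF_RANGE
    return idx


def build_histogram(ax: ScalarVolume, ay: ScalarVolume, mask: LabelVolume,
                    nbins: int = 100,
                    clip_percentiles=((0.0, 100.0), (0.0, 99.9)),
                    axes_names: tuple[str, str] = ("x", "y")) -> Histogram2D:
    """Bin two aligned volumes over the masked voxels.

    Axis ranges are the masked percentile intervals given by
    ``clip_percentiles`` (one (low, high) pair applied to both axes, or one
    pair per axis; the default clips the top 0.1% of the y axis, where
    vessel gradients would otherwise stretch the range).  Bins are
    equal-width on the clipped range; voxels outside it map to the
    out-of-range sentinel.
    """
    if ax.shape != ay.shape or ax.shape != mask.shape:
        raise ValueError(f"grids differ: {ax.shape}, {ay.shape}, {mask.shape}")
    if nbins < 2:
        raise ValueError(f"nbins must be >= 2, got {nbins}")
    cp = np.asarray(clip_percentiles, dtype=np.float64)
    if cp.shape == (2,):
        cp = np.stack([cp, cp])
    if cp.shape != (2, 2) or np.any(cp < 0) or np.any(cp > 100) or np.any(cp[:, 0] >= cp[:, 1]):
        raise ValueError(f"bad clip_percentiles {clip_percentiles}")
    inside = mask.labels != 0
    if not inside.any():
        raise ValueError("empty mask")

    shape = ax.shape
    voxel_bin = np.full(shape + (2,), OUT_OF_RANGE, dtype=np.int64)
    idx = []
    edges = []
    for axis_i, vol in enumerate((ax, ay)):
        vals = vol.values[inside]
        lo, hi = np.percentile(vals, cp[axis_i])
        edges.append(np.linspace(lo, hi, nbins + 1))
        full = np.full(shape, OUT_OF_RANGE, dtype=np.int64)
        full[inside] = _digitize(vals, float(lo), float(hi), nbins)
        idx.append(full)
    ok = inside & (idx[0] >= 0) & (idx[1] >= 0)
    voxel_bin[ok, 0] = idx[0][ok]
    voxel_bin[ok, 1] = idx[1][ok]
    flat = idx[0][ok] * nbins + idx[1][ok]
    counts = np.bincount(flat, minlength=nbins * nbins).reshape(nbins, nbins)
    return Histogram2D(edges_x=edges[0], edges_y=edges[1], counts=counts,
                       voxel_bin=voxel_bin, axes_names=tuple(axes_names),
                       voxel_size=ax.voxel_size.copy(), affine=ax.affine.copy())


def bins_to_voxels(h: Histogram2D, bin_mask: np.ndarray) -> LabelVolume:
    """Binary label volume of the voxels whose bin is selected.

    Out-of-range voxels are never selected; selecting the complement of a
    bin mask yields exactly the complement of the in-range voxel set.
    """
    bin_mask = np.asarray(bin_mask, dtype=bool)
    if bin_mask.shape != h.counts.shape:
        raise ValueError(f"bin_mask shape {bin_mask.shape} != counts shape {h.counts.shape}")
    bx = h.voxel_bin[..., 0]
    by = h.voxel_bin[..., 1]
    in_range = bx >= 0
    sel = np.zeros(h.grid_shape, dtype=np.int32)
    sel[in_range] = bin_mask[bx[in_range], by[in_range]].astype(np.int32)
    return LabelVolume(sel, {0: "background", 1: "selected"},
                       h.voxel_size, h.affine, name="selection")


# -- deterministic .npz-style persistence ------------------------------------
# numpy's savez stamps entries with the current time; the CLI contract is
# bit-identical re-runs, so entries are written with a fixed zip date.

def _write_deterministic_npz(path: Path, arrays: dict[str, np.ndarray]) -> None:
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(arrays):
            buf = BytesIO()
            np.save(buf, arrays[name], allow_pickle=False)
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def save_histogram(h: Histogram2D, path: str | Path) -> None:
    """Persist a histogram (np.load-compatible zip of arrays)."""
    meta = json.dumps({"axes_names": list(h.axes_names)}).encode()
    arrays = {
        "edges_x": h.edges_x, "edges_y": h.edges_y, "counts": h.counts,
        "voxel_bin": h.voxel_bin, "voxel_size": h.voxel_size, "affine": h.affine,
        "meta": np.frombuffer(meta, dtype=np.uint8),
    }
    _write_deterministic_npz(Path(path), arrays)


def load_histogram(path: str | Path) -> Histogram2D:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return Histogram2D(
            edges_x=z["edges_x"], edges_y=z["edges_y"], counts=z["counts"],
            voxel_bin=z["voxel_bin"], axes_names=tuple(meta["axes_names"]),
            voxel_size=z["voxel_size"], affine=z["affine"],
        )
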