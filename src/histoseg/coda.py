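"""Compositional data analysis (CoDa) on the simplex and the ilr map.

A voxel measured in D contrasts is treated as a composition: only the
relative sizes of its parts matter, so a multiplicative field common to all
contrasts (the RF-coil bias) cancels under closure.  This module implements
the Aitchison geometry of the simplex — closure, perturbation (the simplex
addition), powering (the simplex scalar multiplication), the Aitchison
distance, sample center and total variance — plus centering/standardization
and the isometric log-ratio (ilr) transform that maps 3-part compositions
to 2 real coordinates through an orthonormal Helmert sub-matrix:

    ilr(b) = ln(b) . H,   H = [[ 1/sqrt2, 1/sqrt6],
                               [-1/sqrt2, 1/sqrt6],
                               [ 0,      -2/sqrt6]].

The ilr map is an isometry: Euclidean distance between ilr images equals
the Aitchison distance between the compositions.  The two ilr coordinates
are the axes of the multi-modal 2D histogram.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np

from .volume_io import LabelVolume, MultiContrastStack, ScalarVolume

__all__ = [
    "HELMERT_3x2",
    "CompositionMatrix",
    "CodaCenterScale",
    "IlrPair",
    "closure",
    "perturb",
    "power_op",
    "aitchison_distance",
    "sample_center",
    "total_variance",
    "center_standardize",
    "ilr_transform",
    "coda_pipeline",
]

_SQ2, _SQ6 = np.sqrt(2.0), np.sqrt(6.0)
#: Orthonormal, zero-column-sum Helmert sub-matrix (3 parts -> 2 ilr axes).
HELMERT_3x2 = np.array([
    [1.0 / _SQ2, 1.0 / _SQ6],
    [-1.0 / _SQ2, 1.0 / _SQ6],
    [0.0, -2.0 / _SQ6],
])


def _as_rows(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x[None, :] if x.ndim == 1 else x


@dataclasses.dataclass
class CompositionMatrix:
    """n voxels x D strictly positive parts, each row summing to k."""

    parts: np.ndarray
    k: float = 1.0
    voxel_index: Optional[np.ndarray] = None  # flat indices into grid_shape
    grid_shape: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        self.parts = _as_rows(self.parts)
        if np.any(self.parts <= 0):
            bad = np.argwhere(self.parts <= 0)[0]
            raise ValueError(f"non-positive part at row {bad[0]}, column {bad[1]}")
        sums = self.parts.sum(axis=1)
        if not np.allclose(sums, self.k, rtol=0, atol=1e-9 * self.k):
            raise ValueError("rows do not sum to the closure constant k")

    @property
    def n(self) -> int:
        return self.parts.shape[0]

    @property
    def D(self) -> int:
        return self.parts.shape[1]


@dataclasses.dataclass
class CodaCenterScale:
    """Geometric-mean center and total variance of a composition sample."""

    center: np.ndarray
    totvar: float


@dataclasses.dataclass
class IlrPair:
    """The two ilr coordinate volumes (0 outside the analysis mask)."""

    ilr1: ScalarVolume
    ilr2: ScalarVolume
    mask: Optional[LabelVolume] = None


def closure(rows: np.ndarray, k: float = 1.0,
            voxel_index: Optional[np.ndarray] = None,
            grid_shape: Optional[tuple[int, int, int]] = None) -> CompositionMatrix:
    """Project positive rows onto the simplex: row * k / sum(row).

    Scale invariant: a common positive multiplier per row cancels exactly.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    rows = _as_rows(rows)
    if np.any(rows <= 0) or not np.all(np.isfinite(rows)):
        bad = np.argwhere(~(rows > 0) | ~np.isfinite(rows))[0]
        raise ValueError(
            f"closure requires strictly positive finite parts; offending row "
            f"{bad[0]}, column {bad[1]} (value {rows[bad[0], bad[1]]})"
        )
    parts = k * rows / rows.sum(axis=1, keepdims=True)
    return CompositionMatrix(parts, k=k, voxel_index=voxel_index, grid_shape=grid_shape)


def _comp(x) -> np.ndarray:
    if isinstance(x, CompositionMatrix):
        return x.parts
    return _as_rows(x)


def perturb(x, y, k: float = 1.0) -> np.ndarray:
    """Simplex addition: closure of the componentwise product.

    The uniform composition is the neutral element; the closure of the
    reciprocals is the inverse.
    """
    xa, ya = _comp(x), _comp(y)
    if xa.shape[1] != ya.shape[1]:
        raise ValueError(f"part counts differ: {xa.shape[1]} vs {ya.shape[1]}")
    out = closure(xa * ya, k=k).parts
    return out[0] if out.shape[0] == 1 else out


def power_op(x, p: float, k: float = 1.0) -> np.ndarray:
    """Simplex scalar multiplication: closure of componentwise p-th powers."""
    xa = _comp(x)
    out = closure(xa ** p if p != 0 else np.ones_like(xa), k=k).parts
    return out[0] if out.shape[0] == 1 else out


def aitchison_distance(x, y) -> np.ndarray | float:
    """Aitchison distance sqrt((1/2D) sum_jk (ln(xj/xk) - ln(yj/yk))^2)."""
    xa, ya = _comp(x), _comp(y)
    if xa.shape[1] != ya.shape[1]:
        raise ValueError(f"part counts differ: {xa.shape[1]} vs {ya.shape[1]}")
    if np.any(xa <= 0) or np.any(ya <= 0):
        raise ValueError("compositions must have strictly positive parts")
    lx, ly = np.log(xa), np.log(ya)
    # log-ratio differences via clr: ln(xj/xk) - ln(yj/yk) = (cj - ck) with
    # c = ln x - ln y; the double sum equals 2D * ||c - mean(c)||^2.
    c = lx - ly
    c = c - c.mean(axis=1, keepdims=True)
    d = np.sqrt((c * c).sum(axis=1))
    return float(d[0]) if d.shape[0] == 1 else d


def sample_center(B: CompositionMatrix) -> np.ndarray:
    """Closure of the per-part geometric means over all rows."""
    g = np.exp(np.log(B.parts).mean(axis=0))
    return closure(g, k=B.k).parts[0]


def total_variance(B: CompositionMatrix) -> float:
    """Mean squared Aitchison distance of the rows to the sample center."""
    c = sample_center(B)
    d = aitchison_distance(B.parts, np.broadcast_to(c, B.parts.shape))
    d = np.atleast_1d(d)
    return float(np.mean(d * d))


def center_standardize(B: CompositionMatrix) -> tuple[CompositionMatrix, CodaCenterScale]:
    """Center to the uniform composition, then scale to total variance 1.

    Each row is perturbed with the inverse of the sample center and the whole
    matrix is powered by totvar^(-1/2).  Applying the function twice is the
    identity (up to rounding) — the output is already centered with unit
    total variance.
    """
    if B.n < 2:
        raise ValueError("need at least 2 rows to standardize")
    cen = sample_center(B)
    tv = total_variance(B)
    if tv <= 1e-15 or not np.isfinite(tv):
        raise ValueError("degenerate data: total variance is zero")
    inv_cen = closure(1.0 / cen, k=B.k).parts[0]
    centered = closure(B.parts * inv_cen, k=B.k).parts
    standardized = closure(centered ** (tv ** -0.5), k=B.k)
    standardized = dataclasses.replace(
        standardized, voxel_index=B.voxel_index, grid_shape=B.grid_shape
    )
    return standardized, CodaCenterScale(center=cen, totvar=tv)


def ilr_transform(B: CompositionMatrix, H: np.ndarray = HELMERT_3x2) -> np.ndarray:
    """Rowwise isometric log-ratio coordinates ln(parts) . H (n x 2).

    Because H is orthonormal with zero column sums, the Euclidean distance
    between two rows' ilr coordinates equals their Aitchison distance.
    """
    if B.D != 3:
        raise ValueError(f"ilr transform is implemented for D = 3 parts, got D = {B.D}")
    H = np.asarray(H, dtype=np.float64)
    if H.shape != (3, 2):
        raise ValueError(f"Helmert sub-matrix must be 3x2, got {H.shape}")
    return np.log(B.parts) @ H


def _floor_nonpositive(rows: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace non-positive parts with 1e-6 x the voxel's own maximum part.

    A per-voxel relative floor keeps the repaired composition equivariant
    under any common multiplicative field (the bias-cancellation guarantee);
    a voxel with no positive part becomes uniform.
    """
    rows = rows.copy()
    bad = rows <= 0
    nbad = int(bad.any(axis=1).sum())
    if nbad:
        vmax = rows.max(axis=1, keepdims=True)
        repaired = np.where(bad, 1e-6 * np.maximum(vmax, 0), rows)
        allbad = (vmax <= 0).ravel()
        repaired[allbad] = 1.0
        rows = repaired
    return rows, nbad


def coda_pipeline(stack: MultiContrastStack, mask: LabelVolume, k: float = 1.0,
                  normalize_medians: bool = False) -> IlrPair:
    """Closure -> center/standardize -> ilr on the masked voxels of a stack.

    Out-of-mask voxels carry 0 in both ilr volumes; the mask is returned
    alongside so downstream histograms are built over masked voxels only.
    With ``normalize_medians`` each contrast is first divided by its masked
    median, an optional pre-step for inputs with very different dynamic
    ranges.
    """
    if stack.D != 3:
        raise ValueError(f"the CoDa pipeline needs exactly 3 contrasts, got {stack.D}")
    if stack.shape != mask.shape:
        raise ValueError(f"mask grid {mask.shape} differs from stack grid {stack.shape}")
    inside = mask.labels.ravel() != 0
    if not inside.any():
        raise ValueError("empty mask")
    M = stack.as_matrix()[inside]
    if normalize_medians:
        med = np.median(M, axis=0)
        if np.any(med <= 0):
            raise ValueError("median normalization requires positive masked medians")
        M = M / med
    M, nfloored = _floor_nonpositive(M)
    if nfloored:
        warnings.warn(f"floored non-positive parts in {nfloored} masked voxels",
                      stacklevel=2)
    B = closure(M, k=k, voxel_index=np.flatnonzero(inside), grid_shape=stack.shape)
    Bt, _ = center_standardize(B)
    coords = ilr_transform(Bt)
    vols = []
    for j in range(2):
        flat = np.zeros(int(np.prod(stack.shape)))
        flat[inside] = coords[:, j]
        vols.append(stack.contrasts[0].like(flat.reshape(stack.shape), name=f"ilr{j + 1}"))
    return IlrPair(ilr1=vols[0], ilr2=vols[1], mask=mask)
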