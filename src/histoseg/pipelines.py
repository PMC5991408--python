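"""End-to-end refinement pipelines composing the package's stages.

Two routes turn raw contrasts into a refined GM segmentation:

* GraMag: a single intensity volume (typically a T1w/PDw ratio image) is
  optionally denoised, its Scharr gradient magnitude computed, and the
  intensity x gradient-magnitude histogram is clustered by recursive
  normalized cuts; low-gradient clusters above the CSF intensity gap are
  kept as brain.
* CoDa: three co-registered contrasts are mapped to two ilr coordinates
  (closure -> centering/standardization -> ilr), histogrammed, clustered
  the same way, and clusters near the tissue axis are kept.

Both return the refined segmentation together with the intermediate
objects, so scripts and tests can audit every stage.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import coda, gradmag, histogram2d, transfer, volume_io

__all__ = ["PipelineResult", "gramag_refine", "coda_refine"]


@dataclasses.dataclass
class PipelineResult:
    refined: volume_io.LabelVolume
    tf: transfer.TransferFunction
    tree: transfer.NcutTree
    histogram: histogram2d.Histogram2D


def _masked_smooth(vol: volume_io.ScalarVolume, mask: volume_io.LabelVolume,
                   iterations: int) -> volume_io.ScalarVolume:
    """Mask, then diffuse with a conductance set from the masked robust range.

    Out-of-mask voxels carry arbitrary values (air, noise-dominated ratios),
    so both the diffusion and its conductance threshold must see only brain
    intensities.
    """
    masked = volume_io.apply_mask(vol, mask)
    if iterations == 0:
        return masked
    inside = mask.labels != 0
    p1, p99 = np.percentile(masked.values[inside], [1, 99])
    conductance = 0.2 * float(p99 - p1) or 1.0
    return volume_io.anisotropic_smooth(masked, iterations, conductance)


def gramag_refine(intensity: volume_io.ScalarVolume,
                  init_seg: volume_io.LabelVolume,
                  mask: volume_io.LabelVolume,
                  smooth_iterations: int = 5,
                  nbins: int = 100,
                  max_depth: int = 8,
                  gm_quantile: float = 0.9) -> PipelineResult:
    """Refine GM with the uni-modal intensity x gradient-magnitude route."""
    vol = _masked_smooth(intensity, mask, smooth_iterations)
    grad = gradmag.magnitude(gradmag.scharr_partials(vol))
    h = histogram2d.build_histogram(
        vol, grad, mask, nbins=nbins,
        clip_percentiles=((0.0, 100.0), (0.0, 99.9)),
        axes_names=("intensity", "gradient_magnitude"),
    )
    graph = transfer.build_bin_graph(h)
    tree = transfer.normalized_cut_tree(graph, max_depth=max_depth)
    tf = transfer.auto_brain_select(tree, h, gm_quantile=gm_quantile, y_rule="low")
    refined = transfer.refine_segmentation(init_seg, tf, h)
    return PipelineResult(refined=refined, tf=tf, tree=tree, histogram=h)


def coda_refine(stack: volume_io.MultiContrastStack,
                init_seg: volume_io.LabelVolume,
                mask: volume_io.LabelVolume,
                smooth_iterations: int = 5,
                nbins: int = 100,
                max_depth: int = 8,
                gm_quantile: float = 0.95) -> PipelineResult:
    """Refine GM with the multi-modal compositional (ilr histogram) route."""
    smoothed = volume_io.MultiContrastStack(
        [_masked_smooth(c, mask, smooth_iterations) for c in stack.contrasts]
    )
    pair = coda.coda_pipeline(smoothed, mask)
    h = histogram2d.build_histogram(
        pair.ilr1, pair.ilr2, mask, nbins=nbins,
        clip_percentiles=((0.5, 99.5), (0.5, 99.5)),
        axes_names=("ilr1", "ilr2"),
    )
    graph = transfer.build_bin_graph(h)
    tree = transfer.normalized_cut_tree(graph, max_depth=max_depth)
    tf = transfer.auto_brain_select(tree, h, gm_quantile=gm_quantile, y_rule="central")
    refined = transfer.refine_segmentation(init_seg, tf, h)
    return PipelineResult(refined=refined, tf=tf, tree=tree, histogram=h)
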