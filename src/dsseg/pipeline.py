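"""Benchmark presets and one-call segmentation for the synthetic sweeps.

The synthetic benchmark uses the light de-noising chain (Gaussian sigma 0.5,
window 5, median window 3, no deconvolution, no diffusion) and unit mask
weights with a derivative scale of 1.1 px.  Real confocal stacks typically
add nonlinear diffusion (kappa = 10, n = 4); see :class:`DenoiseParams`.
"""

from __future__ import annotations

import numpy as np

from .baselines import LoGParams, log_detect, watershed_intensity_split
from .core import (
    MaskParams,
    SegmentationResult,
    SegmentedObject,
    ds_segment,
    label_mask_from_objects,
)
from .postprocess import postprocess_all
from .preprocess import DenoiseParams, denoise
from .stacks import ImageStack

__all__ = [
    "BENCHMARK_DENOISE",
    "BENCHMARK_MASK",
    "segment",
    "detect_centroids",
    "METHODS",
]

#: de-noising used for the synthetic benchmark (no diffusion)
BENCHMARK_DENOISE = DenoiseParams(
    gauss_sigma=0.5, gauss_window=5, median_window=3, diff_iterations=0
)
#: mask weights for the synthetic benchmark
BENCHMARK_MASK = MaskParams(alpha=1, beta=1, epsilon=1, gamma=1, delta=1, sigma_g=1.1)

#: method names accepted by the sweep drivers
METHODS = ("ds", "ds+kmeans", "ds+gmm", "ds+watershed", "log")


def segment(
    stack: ImageStack,
    method: str = "ds+gmm",
    denoise_params: DenoiseParams | None = None,
    mask_params: MaskParams | None = None,
    n_weight: float = 0.0,
    seed: int = 0,
    connectivity: int = 6,
) -> SegmentationResult:
    """Run DS segmentation plus the requested post-processing variant.

    The watershed baseline is applied to *every* object (not only those above
    the fused-object-volume threshold): its characteristic over-segmentation
    of single nuclei is the phenomenon the comparison is about, and gating it
    by volume would hide it.
    """
    if method not in ("ds", "ds+kmeans", "ds+gmm", "ds+watershed"):
        raise ValueError(f"unknown segmentation method {method!r}")
    denoise_params = denoise_params or BENCHMARK_DENOISE
    mask_params = mask_params or BENCHMARK_MASK
    result = ds_segment(stack, denoise_params, mask_params, connectivity=connectivity)
    if method == "ds":
        return result
    if method == "ds+watershed":
        den = denoise(stack.astype_float(), denoise_params)
        children: list[SegmentedObject] = []
        for obj in result.objects:
            sr = watershed_intensity_split(obj, den.voxels, result.spacing)
            children.extend(sr.children)
        relabeled = [
            SegmentedObject(i, o.voxels, o.spacing) for i, o in enumerate(children, start=1)
        ]
        params = dict(result.params)
        params["postprocess"] = {"method": "watershed-intensity", "gated": False}
        return SegmentationResult(
            objects=relabeled,
            label_mask=label_mask_from_objects(relabeled, stack.voxels.shape),
            spacing=result.spacing,
            params=params,
        )
    result, _ = postprocess_all(result, n_weight, method=method.split("+")[1], seed=seed)
    return result


def detect_centroids(
    stack: ImageStack,
    method: str = "ds+gmm",
    log_params: LoGParams | None = None,
    **kwargs,
) -> np.ndarray:
    """Centroids (x, y, z) in um from any benchmark method, LoG included.

    The LoG detector runs on the de-noised (not masked) stack: it is used as
    a standalone detector, not as a post-processing step.
    """
    if method == "log":
        den = denoise(stack.astype_float(), kwargs.get("denoise_params") or BENCHMARK_DENOISE)
        return log_detect(den, log_params)
    return segment(stack, method, **kwargs).centroids_um
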