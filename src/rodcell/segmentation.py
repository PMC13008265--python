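"""Cell and nucleus segmentation from image stacks.

The pipeline is deliberately classical: project the stack, Gaussian-smooth,
global-threshold (Otsu by default), clean up with binary morphology, label
connected components, and filter by size / border contact / solidity.  The
solidity filter stands in for the manual removal of unresolved cell clumps:
a clump of rods is strongly non-convex while a single rod is nearly convex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as sk_seg


@dataclass
class LabeledMask:
    """Integer-labeled 2D mask with physical pixel size and provenance.

    Labels are positive consecutive integers (0 = background); provenance
    records every parameter that produced the mask, so identical image +
    provenance reproduces the mask.
    """

    labels: np.ndarray
    pixel_size: float
    channel: str = "cell"
    provenance: dict = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def areas_um2(self) -> dict[int, float]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        a = self.pixel_size**2
        return {int(i): float(c) * a for i, c in zip(ids, counts)}


def project(stack: np.ndarray, mode: str = "sum", plane: int | None = None) -> np.ndarray:
    """Project a (z, y, x) stack to 2D.

    ``sum`` adds all planes, ``max`` takes the plane-wise maximum, and
    ``single_plane`` returns one plane (the middle one by default, matching
    how single z-sections are displayed).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < 1:
        raise ValueError("stack must contain at least one plane")
    if mode == "sum":
        return stack.sum(axis=0)
    if mode == "max":
        return stack.max(axis=0)
    if mode == "single_plane":
        idx = stack.shape[0] // 2 if plane is None else plane
        if not 0 <= idx < stack.shape[0]:
            raise IndexError(f"plane {idx} out of range for {stack.shape[0]} planes")
        return stack[idx]
    raise ValueError(f"unknown projection mode {mode!r}")


def _binarize(image: np.ndarray, sigma_px: float, threshold) -> tuple[np.ndarray, float]:
    """Smooth, threshold, and orient polarity so the minority class (the
    cells, which occupy < 50% of a field) is foreground."""
    smooth = ndimage.gaussian_filter(image, sigma_px) if sigma_px > 0 else image
    if threshold == "otsu":
        if np.ptp(smooth) == 0:  # constant image: nothing to segment
            return np.zeros(image.shape, dtype=bool), float(smooth.flat[0])
        thr = float(filters.threshold_otsu(smooth))
    else:
        thr = float(threshold)
    fg = smooth > thr
    if fg.mean() > 0.5:
        fg = ~fg
    return fg, thr


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Make labels consecutive 1..n, preserving order."""
    return measure.label(labels > 0, connectivity=2).astype(np.int32)


def _filter_components(
    labels: np.ndarray,
    pixel_size: float,
    min_area: float,
    max_area: float,
    exclude_edges: bool,
    min_solidity: float | None,
) -> np.ndarray:
    """Apply the area window, border-contact and solidity filters."""
    if exclude_edges:
        labels = sk_seg.clear_border(labels)
    out = labels.copy()
    px_area = pixel_size**2
    for rp in measure.regionprops(labels):
        area_um2 = rp.area * px_area
        drop = not (min_area <= area_um2 <= max_area)
        if not drop and min_solidity is not None and rp.solidity < min_solidity:
            drop = True
        if drop:
            out[labels == rp.label] = 0
    return _relabel(out)


def segment_cells(
    image: np.ndarray,
    pixel_size: float,
    *,
    sigma: float = 0.1,
    threshold: str | float = "otsu",
    open_radius: int = 2,
    close_radius: int = 2,
    min_area: float = 10.0,
    max_area: float = 200.0,
    exclude_edges: bool = True,
    min_solidity: float | None = 0.8,
) -> LabeledMask:
    """Segment rod cells from a 2D brightfield image.

    ``sigma`` is the Gaussian smoothing scale in µm; ``min_area``/``max_area``
    bound the accepted footprint in µm²; the solidity floor rejects
    non-convex blobs (fused or clumped cells).  An empty result is returned
    as an empty mask with a warning, not an exception.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    fg, thr = _binarize(image, sigma / pixel_size, threshold)
    if open_radius > 0:
        fg = morphology.opening(fg, morphology.disk(open_radius))
    if close_radius > 0:
        fg = morphology.closing(fg, morphology.disk(close_radius))
    labels = measure.label(fg, connectivity=2).astype(np.int32)
    labels = _filter_components(
        labels, pixel_size, min_area, max_area, exclude_edges, min_solidity
    )
    if labels.max() == 0:
        warnings.warn("cell segmentation produced an empty mask", stacklevel=2)
    prov = dict(
        channel="cell", sigma_um=sigma, threshold=thr, threshold_method=str(threshold),
        open_radius_px=open_radius, close_radius_px=close_radius,
        min_area_um2=min_area, max_area_um2=max_area,
        exclude_edges=exclude_edges, min_solidity=min_solidity,
        pixel_size=pixel_size,
    )
    return LabeledMask(labels=labels, pixel_size=pixel_size, channel="cell", provenance=prov)


def segment_nuclei(
    image: np.ndarray,
    pixel_size: float,
    *,
    sigma: float = 0.1,
    threshold: str | float = "otsu",
    min_area: float = 0.5,
    max_area: float = 12.0,
    exclude_edges: bool = True,
) -> LabeledMask:
    """Segment nuclei from a sum-projected nuclear-marker image.

    No opening/closing is applied (nuclei are compact blobs); the area
    window removes abnormally small or large objects, which also guards
    against uneven marker illumination across the field.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    fg, thr = _binarize(image, sigma / pixel_size, threshold)
    labels = measure.label(fg, connectivity=2).astype(np.int32)
    labels = _filter_components(
        labels, pixel_size, min_area, max_area, exclude_edges, min_solidity=None
    )
    if labels.max() == 0:
        warnings.warn("nucleus segmentation produced an empty mask", stacklevel=2)
    prov = dict(
        channel="nucleus", sigma_um=sigma, threshold=thr,
        threshold_method=str(threshold), min_area_um2=min_area,
        max_area_um2=max_area, exclude_edges=exclude_edges, pixel_size=pixel_size,
    )
    return LabeledMask(labels=labels, pixel_size=pixel_size, channel="nucleus", provenance=prov)


def iou_per_truth_label(pred: np.ndarray, truth: np.ndarray) -> dict[int, float]:
    """Best IoU of each ground-truth label against any predicted label."""
    out: dict[int, float] = {}
    for t in np.unique(truth[truth > 0]):
        tmask = truth == t
        cand = np.unique(pred[tmask])
        cand = cand[cand > 0]
        best = 0.0
        for p in cand:
            pmask = pred == p
            inter = np.logical_and(tmask, pmask).sum()
            union = np.logical_or(tmask, pmask).sum()
            best = max(best, inter / union)
        out[int(t)] = best
    return out
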