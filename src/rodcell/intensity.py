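"""Fluorescence quantification in nucleus, cytoplasm and whole cell.

Sum-projected z-stacks are measured inside the cell and nucleus masks:
per cell, the mean intensity of the whole footprint, of the nuclear pixels,
and of the cytoplasm (cell minus nucleus).  A linear regression of nuclear
mean against cell volume quantifies size-dependent nuclear accumulation of
a protein (e.g. the phosphatase Cdc25, whose nuclear concentration scales
with cell volume in wild-type cells).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from skimage import measure

from .segmentation import LabeledMask, project


def modal_background(image: np.ndarray, mask: np.ndarray, bins: int = 256) -> float:
    """Modal intensity of non-cell pixels (histogram peak)."""
    bg = image[mask == 0]
    if bg.size == 0:
        return 0.0
    hist, edges = np.histogram(bg, bins=bins)
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2)


def measure_intensity(
    stack: np.ndarray,
    cell_mask: LabeledMask,
    nuclei_mask: LabeledMask,
    background: str | float = "modal",
) -> pd.DataFrame:
    """Per-cell region means from a sum projection.

    ``background`` is 'modal' (mode of non-cell pixels), 'none', or a fixed
    value subtracted before measuring.  Nuclei are attached to cells by
    centroid containment; a cell without a nucleus gets NaN nuclear and
    cytoplasmic means and is flagged.
    """
    img = project(stack, "sum")
    if img.shape != cell_mask.labels.shape or img.shape != nuclei_mask.labels.shape:
        raise ValueError("stack frame and mask shapes differ")

    if background == "modal":
        bg = modal_background(img, cell_mask.labels)
    elif background == "none":
        bg = 0.0
    else:
        bg = float(background)
    img = img - bg

    cells = cell_mask.labels
    nuc_of_cell: dict[int, np.ndarray] = {}
    for rp in measure.regionprops(nuclei_mask.labels):
        cy, cx = rp.centroid
        owner = int(cells[int(round(cy)), int(round(cx))])
        if owner > 0:
            m = nuclei_mask.labels == rp.label
            nuc_of_cell[owner] = m | nuc_of_cell.get(owner, np.zeros_like(m))

    px_area = cell_mask.pixel_size**2
    rows = []
    for lbl in np.unique(cells[cells > 0]):
        cm = cells == lbl
        nm = nuc_of_cell.get(int(lbl))
        whole = float(img[cm].mean())
        if nm is None or not (cm & nm).any():
            rows.append(dict(
                cell_id=int(lbl), mean_nuclear=np.nan, mean_cytoplasmic=np.nan,
                mean_whole_cell=whole, nuclear_area_um2=0.0,
                cell_area_um2=float(cm.sum() * px_area), background=bg,
                flagged="no_nucleus",
            ))
            continue
        nmask = cm & nm
        cyto = cm & ~nm
        rows.append(dict(
            cell_id=int(lbl),
            mean_nuclear=float(img[nmask].mean()),
            mean_cytoplasmic=float(img[cyto].mean()) if cyto.any() else np.nan,
            mean_whole_cell=whole,
            nuclear_area_um2=float(nmask.sum() * px_area),
            cell_area_um2=float(cm.sum() * px_area),
            background=bg,
            flagged=None,
        ))
    return pd.DataFrame(rows)


def scaling_regression(volumes, nuclear_means) -> dict:
    """OLS of nuclear mean intensity on cell volume.

    Returns slope, intercept, R², and the slope's 95% confidence interval;
    a slope CI excluding zero indicates size-dependent nuclear accumulation,
    while a CI covering zero is consistent with constitutive expression.
    """
    v = np.asarray(list(volumes), dtype=float)
    y = np.asarray(list(nuclear_means), dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 points for a regression")
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(v) == 0:
        raise ValueError("zero variance in volumes")
    res = sm.OLS(y, sm.add_constant(v)).fit()
    lo, hi = res.conf_int(alpha=0.05)[1]
    return dict(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        slope_ci=(float(lo), float(hi)),
        n=len(v),
    )
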