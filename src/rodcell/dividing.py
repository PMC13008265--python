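"""Dividing-cell identification: cells that contain exactly two nuclei.

In fission yeast a cell between anaphase and separation holds two nuclei;
the measurement population for division size is exactly these binucleates.
Nuclei are first eroded (to detach them from cell borders), then each
nucleus is assigned to the cell whose footprint contains its centroid, and
cells with a nucleus count of two are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .segmentation import LabeledMask


@dataclass
class DividingCellSet:
    """Nucleus counts per cell and the retained (binucleate) labels."""

    cell_mask: LabeledMask
    eroded_nuclei: np.ndarray
    nuclei_per_cell: dict[int, int]
    retained_labels: set[int]
    unassigned_nuclei: list[int] = field(default_factory=list)
    straddling_nuclei: list[int] = field(default_factory=list)


def assign_nuclei(
    cell_mask: LabeledMask, nuclei_mask: LabeledMask, erode_radius: int = 2
) -> DividingCellSet:
    """Count nuclei per cell by centroid containment after erosion.

    Each eroded nucleus is assigned to the cell label under its centroid;
    centroids over background are reported as unassigned, and nuclei whose
    pixels span more than one cell are flagged (the centroid still decides).
    Cells with exactly two assigned nuclei form ``retained_labels``.
    """
    if cell_mask.labels.shape != nuclei_mask.labels.shape:
        raise ValueError(
            f"mask shapes differ: {cell_mask.labels.shape} vs {nuclei_mask.labels.shape}"
        )
    if not np.isclose(cell_mask.pixel_size, nuclei_mask.pixel_size):
        raise ValueError("masks have different pixel sizes")

    nuc = nuclei_mask.labels.copy()
    if erode_radius > 0:
        # per-label erosion via binary erosion of the union; labels can't
        # merge because erosion only removes pixels
        eroded_fg = morphology.erosion(nuc > 0, morphology.disk(erode_radius))
        nuc[~eroded_fg] = 0

    counts: dict[int, int] = {i: 0 for i in range(1, cell_mask.n_labels + 1)}
    unassigned: list[int] = []
    straddling: list[int] = []
    cells = cell_mask.labels
    for rp in measure.regionprops(nuc):
        cy, cx = rp.centroid
        owner = int(cells[int(round(cy)), int(round(cx))])
        touched = np.unique(cells[nuc == rp.label])
        touched = set(int(t) for t in touched if t > 0)
        if len(touched) > 1:
            straddling.append(rp.label)
            warnings.warn(
                f"nucleus {rp.label} straddles cells {sorted(touched)}; "
                f"centroid assigns it to cell {owner}",
                stacklevel=2,
            )
        if owner == 0:
            unassigned.append(rp.label)
        else:
            counts[owner] = counts.get(owner, 0) + 1

    retained = {lbl for lbl, c in counts.items() if c == 2}
    return DividingCellSet(
        cell_mask=cell_mask,
        eroded_nuclei=nuc,
        nuclei_per_cell=counts,
        retained_labels=retained,
        unassigned_nuclei=unassigned,
        straddling_nuclei=straddling,
    )


def dividing_cell_masks(dset: DividingCellSet, remove_nuclei: bool = True) -> LabeledMask:
    """Mask of retained (binucleate) cells, keeping their original labels.

    With ``remove_nuclei`` the (eroded) nuclear pixels are cut out of each
    retained cell, mirroring masks processed to excise nuclei — geometry
    code must fill holes before measuring such masks.
    """
    src = dset.cell_mask.labels
    out = np.where(np.isin(src, list(dset.retained_labels)), src, 0).astype(np.int32)
    if remove_nuclei:
        out[dset.eroded_nuclei > 0] = 0
    prov = dict(dset.cell_mask.provenance)
    prov.update(stage="dividing_cells", remove_nuclei=remove_nuclei,
                retained_labels=sorted(dset.retained_labels))
    return LabeledMask(
        labels=out, pixel_size=dset.cell_mask.pixel_size,
        channel="cell", provenance=prov,
    )


def detection_metrics(
    retained_labels: set[int],
    pred_to_truth: dict[int, int],
    truth_binucleate: set[int],
    all_truth: set[int],
) -> tuple[float, float]:
    """Precision and recall of binucleate detection given a predicted-label →
    truth-id correspondence."""
    pred_pos = {pred_to_truth[p] for p in retained_labels if p in pred_to_truth}
    tp = len(pred_pos & truth_binucleate)
    fp = len(pred_pos - truth_binucleate)
    fn = len(truth_binucleate - pred_pos)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall


def match_labels_to_truth(pred: np.ndarray, truth: np.ndarray) -> dict[int, int]:
    """Map each predicted label to the truth label it overlaps most."""
    out: dict[int, int] = {}
    for p in np.unique(pred[pred > 0]):
        vals, counts = np.unique(truth[pred == p], return_counts=True)
        nz = vals > 0
        if nz.any():
            out[int(p)] = int(vals[nz][np.argmax(counts[nz])])
    return out
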