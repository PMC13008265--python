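"""Shared synthetic scenes (session-scoped: rendering is the slow part)."""

import numpy as np
import pytest

from rodcell import (
    generate_scene,
    project,
    render_brightfield,
    render_nuclear,
    segment_cells,
    segment_nuclei,
    truth_label_mask,
)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, blur-free field of 8 cells, half of them binucleate."""
    return generate_scene(
        8, seed=3, binucleate_fraction=0.5, noise_sd=0.0, blur_sigma=0.0,
        image_shape=(512, 512), pixel_size=0.1, z_planes=3,
    )


@pytest.fixture(scope="session")
def clean_render(clean_scene):
    bf = render_brightfield(clean_scene)
    nuc = render_nuclear(clean_scene)
    return bf, nuc


@pytest.fixture(scope="session")
def clean_masks(clean_scene, clean_render):
    bf, nuc = clean_render
    px = clean_scene.pixel_size
    cell_mask = segment_cells(project(bf, "single_plane"), px)
    nuclei_mask = segment_nuclei(project(nuc, "sum"), px)
    return cell_mask, nuclei_mask


@pytest.fixture(scope="session")
def clean_truth(clean_scene):
    return truth_label_mask(clean_scene)


def rectangle_coords(n_long=140, n_short=40, pixel_size=0.1, angle=0.0):
    """Pixel-center coordinates (µm) of a digital rectangle, optionally rotated."""
    ys, xs = np.mgrid[0:n_short, 0:n_long]
    pts = np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5]) * pixel_size
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        pts = pts @ rot.T
    return pts
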