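"""Synthetic micrograph, growth-curve and septation-count generators.

Fission yeast cells are modelled as capsules (spherocylinders): a cylinder
of radius R capped by two hemispheres, total tip-to-tip length L >= 2R.
Every generator is a pure function of its parameters and a seed, and every
rendered artifact carries its ground truth, so downstream segmentation and
geometry code can be tested for exact recovery without any real image data.

Conventions: physical units are µm (lengths), µm² (areas), minutes (time);
images are (z, y, x) float arrays; masks are 2D integer label arrays where
0 is background and cell ids start at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    """Ground truth for one capsule-shaped cell.

    ``center`` is the capsule midpoint in µm (x, y); ``orientation`` is the
    long-axis angle in [0, π); ``length`` is tip-to-tip, so the cylindrical
    body has length ``length - 2 * radius``.  Nuclei sit on the symmetry
    axis: one at the midpoint, or two placed symmetrically about it.
    """

    id: int
    center: tuple[float, float]
    orientation: float
    radius: float
    length: float
    n_nuclei: int = 1
    has_septum: bool = False
    nucleus_radius: float = 0.9

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"cell {self.id}: radius must be > 0")
        if self.length < 2 * self.radius:
            raise ValueError(
                f"cell {self.id}: length {self.length} < 2*radius "
                f"{2 * self.radius} (capsule degenerates below a sphere)"
            )
        if self.n_nuclei not in (1, 2):
            raise ValueError(f"cell {self.id}: n_nuclei must be 1 or 2")
        if not 0 <= self.orientation < math.pi:
            raise ValueError(f"cell {self.id}: orientation outside [0, π)")

    @property
    def direction(self) -> tuple[float, float]:
        return (math.cos(self.orientation), math.sin(self.orientation))

    def nuclei_centers(self) -> list[tuple[float, float]]:
        """Nucleus centers in µm, on the axis, symmetric for binucleates."""
        cx, cy = self.center
        dx, dy = self.direction
        if self.n_nuclei == 1:
            return [(cx, cy)]
        # post-anaphase nuclei: symmetric about midcell, kept inside the tips
        off = min(self.length / 4, self.length / 2 - self.radius)
        off = max(off, self.nucleus_radius)
        return [(cx - off * dx, cy - off * dy), (cx + off * dx, cy + off * dy)]

    def footprint_area(self) -> float:
        """Analytic 2D footprint area in µm²: rectangle + full disc."""
        r, ln = self.radius, self.length
        return 2 * r * (ln - 2 * r) + math.pi * r * r


@dataclass
class SyntheticScene:
    """A field of non-overlapping capsule cells plus rendering parameters."""

    cells: list[CellSpec]
    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1083
    z_planes: int = 27
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    contrast: float = 1.0
    background: float = 0.1
    seed: int = 0

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                dict(
                    id=c.id,
                    center_x_um=c.center[0],
                    center_y_um=c.center[1],
                    orientation_rad=c.orientation,
                    radius_um=c.radius,
                    length_um=c.length,
                    n_nuclei=c.n_nuclei,
                    has_septum=c.has_septum,
                    nucleus_radius_um=c.nucleus_radius,
                )
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GrowthTruth:
    """Parameters of a logistic OD(t) growth curve.

    ``k`` is the exponential rate constant (min⁻¹); the implied doubling
    time is ln(2)/k.  Defaults mirror a plate-reader run: initial OD 0.05,
    readings every 2 min over 33 h, four replicate wells.
    """

    k: float = math.log(2) / 136.0
    od0: float = 0.05
    od_max: float = 1.5
    noise_sd: float = 0.0
    interval: float = 2.0
    duration: float = 1980.0
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if not self.od0 < self.od_max:
            raise ValueError("od0 must be < od_max")

    @property
    def doubling_time(self) -> float:
        return math.log(2) / self.k


def logistic_od(t: np.ndarray, k: float, od0: float, od_max: float) -> np.ndarray:
    """Logistic growth OD(t) = od_max·od0·e^{kt} / (od_max + od0(e^{kt}−1))."""
    e = np.exp(k * np.asarray(t, dtype=float))
    return od_max * od0 * e / (od_max + od0 * (e - 1.0))


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _segment_endpoints(cell: CellSpec) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints (µm) of the capsule's axis segment (cylinder part)."""
    c = np.array(cell.center)
    d = np.array(cell.direction)
    half = cell.length / 2 - cell.radius
    return c - half * d, c + half * d


def _capsules_overlap(a: CellSpec, b: CellSpec, margin: float) -> bool:
    """True if two capsule footprints (dilated by margin) intersect."""
    p1, p2 = _segment_endpoints(a)
    q1, q2 = _segment_endpoints(b)
    return _segment_distance(p1, p2, q1, q2) < a.radius + b.radius + margin


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 2D segments."""
    def point_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
        return float(np.linalg.norm(p - (a + t * ab)))

    if _segments_intersect(p1, p2, q1, q2):
        return 0.0
    return min(
        point_seg(p1, q1, q2), point_seg(p2, q1, q2),
        point_seg(q1, p1, p2), point_seg(q2, p1, p2),
    )


def _segments_intersect(p1, p2, q1, q2) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    return o1 != o2 and o3 != o4


def generate_scene(
    n_cells: int,
    seed: int = 0,
    *,
    radius_range: tuple[float, float] = (1.8, 2.2),
    length_range: tuple[float, float] = (10.0, 16.0),
    binucleate_fraction: float = 1.0,
    septum_fraction: float = 0.0,
    nucleus_radius: float = 0.9,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.1083,
    z_planes: int = 27,
    noise_sd: float = 0.0,
    blur_sigma: float = 0.0,
    contrast: float = 1.0,
    background: float = 0.1,
    separation: float = 0.5,
    max_tries: int = 200,
) -> SyntheticScene:
    """Place ``n_cells`` non-overlapping capsules fully inside the frame.

    Radii and lengths are drawn uniformly from the given ranges (pass equal
    bounds for a fixed value); each cell is binucleate with probability
    ``binucleate_fraction`` and septated with probability ``septum_fraction``.
    Placement uses rejection sampling with ``max_tries`` attempts per cell;
    a too-crowded field raises with the achieved density.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    fw, fh = nx * pixel_size, ny * pixel_size

    cells: list[CellSpec] = []
    for i in range(n_cells):
        placed = False
        for _ in range(max_tries):
            r = rng.uniform(*radius_range)
            ln = rng.uniform(*length_range)
            if ln < 2 * r:
                ln = 2 * r
            theta = rng.uniform(0, math.pi)
            # keep the whole capsule (plus margin) inside the frame
            half_x = abs(math.cos(theta)) * ln / 2 + r
            half_y = abs(math.sin(theta)) * ln / 2 + r
            pad = separation
            if 2 * (half_x + pad) > fw or 2 * (half_y + pad) > fh:
                continue
            cx = rng.uniform(half_x + pad, fw - half_x - pad)
            cy = rng.uniform(half_y + pad, fh - half_y - pad)
            cand = CellSpec(
                id=i + 1,
                center=(cx, cy),
                orientation=theta,
                radius=r,
                length=ln,
                n_nuclei=2 if rng.random() < binucleate_fraction else 1,
                has_septum=bool(rng.random() < septum_fraction),
                nucleus_radius=nucleus_radius,
            )
            if all(not _capsules_overlap(cand, c, separation) for c in cells):
                cells.append(cand)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n_cells} after {max_tries} "
                f"tries; achieved density {len(cells)} cells in "
                f"{fw:.0f}x{fh:.0f} µm — reduce n_cells or enlarge the frame"
            )

    return SyntheticScene(
        cells=cells,
        image_shape=image_shape,
        pixel_size=pixel_size,
        z_planes=z_planes,
        noise_sd=noise_sd,
        blur_sigma=blur_sigma,
        contrast=contrast,
        background=background,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _pixel_grid_um(scene: SyntheticScene) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of pixel centers, µm."""
    ny, nx = scene.image_shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    return (xs + 0.5) * scene.pixel_size, (ys + 0.5) * scene.pixel_size


def cell_footprint(cell: CellSpec, scene: SyntheticScene) -> np.ndarray:
    """Boolean ground-truth footprint: pixels whose center is within
    ``radius`` of the capsule's axis segment."""
    gx, gy = _pixel_grid_um(scene)
    p1, p2 = _segment_endpoints(cell)
    ab = p2 - p1
    denom = float(ab @ ab)
    px, py = gx - p1[0], gy - p1[1]
    if denom == 0:  # spherical cell
        d2 = px**2 + py**2
    else:
        t = np.clip((px * ab[0] + py * ab[1]) / denom, 0.0, 1.0)
        d2 = (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2
    return d2 <= cell.radius**2


def truth_label_mask(scene: SyntheticScene) -> np.ndarray:
    """Ground-truth label image (cell ids; later cells never overwrite
    earlier ones — placement guarantees disjoint footprints anyway)."""
    labels = np.zeros(scene.image_shape, dtype=np.int32)
    for cell in scene.cells:
        fp = cell_footprint(cell, scene)
        labels[(labels == 0) & fp] = cell.id
    return labels


def truth_nuclei_mask(scene: SyntheticScene) -> np.ndarray:
    """Ground-truth nucleus label image (sequential ids across the scene)."""
    gx, gy = _pixel_grid_um(scene)
    labels = np.zeros(scene.image_shape, dtype=np.int32)
    nid = 0
    for cell in scene.cells:
        for cx, cy in cell.nuclei_centers():
            nid += 1
            disc = (gx - cx) ** 2 + (gy - cy) ** 2 <= cell.nucleus_radius**2
            labels[(labels == 0) & disc] = nid
    return labels


def _stack_from_plane(
    plane: np.ndarray, scene: SyntheticScene, rng: np.random.Generator,
    defocus_step: float = 0.15,
) -> np.ndarray:
    """Replicate the in-focus plane across z with increasing defocus blur
    away from the middle plane, then add per-plane Gaussian noise."""
    z = scene.z_planes
    mid = z // 2
    px = scene.pixel_size
    stack = np.empty((z, *plane.shape), dtype=float)
    for i in range(z):
        extra = abs(i - mid) * defocus_step  # µm of extra blur off-focus
        sigma_um = scene.blur_sigma + extra
        if sigma_um > 0:
            stack[i] = ndimage.gaussian_filter(plane, sigma_um / px)
        else:
            stack[i] = plane
    if scene.noise_sd > 0:
        stack += rng.normal(0.0, scene.noise_sd, size=stack.shape)
    return stack


def render_brightfield(scene: SyntheticScene, noise_seed: int | None = None) -> np.ndarray:
    """Render the cell-outline channel as a (z, y, x) stack.

    Cell interiors sit at ``background + contrast``; a septum, when present,
    is drawn as a 1-px line across midcell at ``background + 0.75*contrast``
    (visible but still on the foreground side of the midpoint threshold, so
    thresholding a noise-free render recovers the truth mask exactly).
    """
    plane = np.full(scene.image_shape, scene.background, dtype=float)
    hi = scene.background + scene.contrast
    for cell in scene.cells:
        plane[cell_footprint(cell, scene)] = hi
    for cell in scene.cells:
        if cell.has_septum:
            sept = _septum_pixels(cell, scene)
            plane[sept] = scene.background + 0.75 * scene.contrast
    rng = np.random.default_rng(scene.seed if noise_seed is None else noise_seed)
    return _stack_from_plane(plane, scene, rng)


def _septum_pixels(cell: CellSpec, scene: SyntheticScene) -> np.ndarray:
    """Pixels of a thin line through midcell, perpendicular to the axis."""
    gx, gy = _pixel_grid_um(scene)
    dx, dy = cell.direction
    u = (gx - cell.center[0]) * dx + (gy - cell.center[1]) * dy
    fp = cell_footprint(cell, scene)
    return fp & (np.abs(u) <= scene.pixel_size / 2)


def render_nuclear(
    scene: SyntheticScene, peak: float = 1.0, noise_seed: int | None = None
) -> np.ndarray:
    """Render the nuclear-marker channel: isotropic Gaussian blobs (sd =
    nucleus_radius/2) at each nucleus center on a zero background."""
    gx, gy = _pixel_grid_um(scene)
    plane = np.zeros(scene.image_shape, dtype=float)
    for cell in scene.cells:
        sd = cell.nucleus_radius / 2.0
        for cx, cy in cell.nuclei_centers():
            plane += peak * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sd**2))
    rng = np.random.default_rng(scene.seed if noise_seed is None else noise_seed)
    return _stack_from_plane(plane, scene, rng)


# ---------------------------------------------------------------------------
# growth curves and septation tables
# ---------------------------------------------------------------------------

def generate_growth_curves(truth: GrowthTruth, seed: int = 0) -> pd.DataFrame:
    """Simulate replicate OD600 time series; columns time_min, replicate, od."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, truth.duration + truth.interval / 2, truth.interval)
    clean = logistic_od(t, truth.k, truth.od0, truth.od_max)
    frames = []
    for rep in range(1, truth.n_replicates + 1):
        od = clean + rng.normal(0.0, truth.noise_sd, size=t.shape)
        frames.append(pd.DataFrame({"time_min": t, "replicate": rep, "od": od}))
    return pd.concat(frames, ignore_index=True)


def generate_septation_table(
    p_septated: dict[str, float] | dict[tuple[str, str], float],
    n: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial septation counts per group.

    Keys are genotype names or (genotype, condition) pairs; each group gets
    ``n`` cells split into septated/unseptated by a binomial draw.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for key, p in p_septated.items():
        if not 0 <= p <= 1:
            raise ValueError(f"p_septated[{key!r}] = {p} outside [0, 1]")
        geno, cond = key if isinstance(key, tuple) else (key, "control")
        s = int(rng.binomial(n, p))
        rows.append(dict(genotype=geno, condition=cond, septated=s, unseptated=n - s))
    return pd.DataFrame(rows)


def scene_params_dict(scene: SyntheticScene) -> dict:
    """Serializable record of a scene's rendering parameters (not cells)."""
    d = asdict(scene)
    d.pop("cells")
    return d
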