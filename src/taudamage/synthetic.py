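"""Synthetic ground-truthed data emulating the study's statistical structure.

The original 76 brain-slice photographs are not publicly deposited, so this
module generates (1) binary slice masks with a known number of damaged
regions and an exact damaged-pixel count, matching the per-stage region
counts and area fractions reported in the source histology captions;
(2) noisy damage trajectories drawn from the exponential ISV laws; and
(3) per-position head-impact exposure tables.  Every generator is seeded
and bitwise reproducible.

The masks emulate only the quantities the downstream pipeline measures —
region count, total damaged area, separation — not brain anatomy, sulci
geometry, or staining texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .histology import DamageObservation, SliceImage
from .isv import evaluate_trajectory
from .params import ISVParams, StrainSchedule

__all__ = [
    "SliceSpec",
    "SliceGroundTruth",
    "InfeasiblePackingError",
    "generate_slice_mask",
    "generate_trajectory",
    "generate_exposure_table",
    "stage_fixture_spec",
    "example_g_level_proportions",
    "STAGE_REGION_COUNTS",
    "STAGE_AREA_FRACTIONS",
    "STAGE_MEAN_AGES",
    "STAGE_AGE_SCATTER",
]

#: Per-stage damaged-region counts and area fractions from the published
#: staged slice examples (stage 1 through 4).
STAGE_REGION_COUNTS = {1: 2, 2: 6, 3: 8, 4: 23}
STAGE_AREA_FRACTIONS = {1: 0.0003, 2: 0.0059, 3: 0.0287, 4: 0.2085}
#: Mean age at death (years) and reported scatter per stage.
STAGE_MEAN_AGES = {1: 28.3, 2: 44.3, 3: 56.0, 4: 77.4}
STAGE_AGE_SCATTER = {1: 13.0, 2: 16.0, 3: 14.0, 4: 12.0}


class InfeasiblePackingError(RuntimeError):
    """Requested regions cannot be placed without overlap at the required separation."""


@dataclass
class SliceSpec:
    """Recipe for one synthetic slice mask.

    ``target_area_fraction`` is realized exactly in pixels: the damaged
    pixel count is round(fraction * H * W), apportioned over regions.
    ``min_separation`` (cm) is the minimum edge-to-edge clearance between
    regions; regions never touch regardless (a two-pixel floor applies so
    components stay distinct under 8-connectivity).
    """

    image_height_px: int
    image_width_px: int
    pixel_scale: float  # cm per pixel
    n_regions: int
    target_area_fraction: float
    region_shape: str = "disk"
    min_separation: float = 0.0  # cm
    size_distribution: str = "equal"  # or "lognormal"
    lognormal_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be > 0")
        if self.n_regions < 0:
            raise ValueError("n_regions must be >= 0")
        if not 0 <= self.target_area_fraction < 1:
            raise ValueError("target_area_fraction must be in [0, 1)")
        if self.region_shape not in ("disk", "square"):
            raise ValueError("region_shape must be 'disk' or 'square'")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.size_distribution not in ("equal", "lognormal"):
            raise ValueError("size_distribution must be 'equal' or 'lognormal'")
        n_px = self.image_height_px * self.image_width_px
        total = round(self.target_area_fraction * n_px)
        if self.n_regions == 0 and total > 0:
            raise ValueError("target_area_fraction > 0 requires n_regions > 0")
        if self.n_regions > 0 and total < self.n_regions:
            raise InfeasiblePackingError(
                f"{self.n_regions} regions need at least {self.n_regions} damaged pixels; "
                f"target fraction yields only {total}")


@dataclass
class SliceGroundTruth:
    """Exact truth for a generated mask (counts, areas, centroids)."""

    mask: np.ndarray
    n_regions: int
    total_damaged_area_cm2: float
    area_fraction: float  # damaged pixels / total pixels, exact
    centroids: np.ndarray = field(repr=False)  # (n, 2) in cm, columns (x, y)
    pairwise_min_nnd: float = math.nan  # cm, NaN when < 2 regions


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights`` (exact sum)."""
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _region_offsets(k: int, shape: str) -> np.ndarray:
    """Offsets of the k pixels nearest the origin (Euclidean for disk,
    Chebyshev for square); ties broken lexicographically so the blob is
    deterministic.  Returns (k, 2) array of (dy, dx)."""
    r = int(math.ceil(math.sqrt(k))) + 1
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    dy, dx = dy.ravel(), dx.ravel()
    dist = dy**2 + dx**2 if shape == "disk" else np.maximum(np.abs(dy), np.abs(dx))
    order = np.lexsort((dx, dy, dist))
    return np.column_stack((dy[order[:k]], dx[order[:k]]))


def _blob_radius(k: int, shape: str) -> float:
    if shape == "disk":
        return math.sqrt(k / math.pi) + 1.0
    return math.sqrt(k) / 2.0 + 1.0


def generate_slice_mask(spec: SliceSpec) -> tuple[SliceImage, SliceGroundTruth]:
    """Generate a slice image and its exact ground truth.

    The returned mask has exactly ``spec.n_regions`` connected components
    (8-connectivity) and exactly round(target_area_fraction * H * W) damaged
    pixels, so the measured area fraction matches the target to within one
    pixel-area.  The image is 8-bit grayscale with damage dark (intensity 0)
    on a bright (255) background, ready for the thresholding stage.

    Placement is rejection sampling of region centers subject to the
    separation constraint; an :class:`InfeasiblePackingError` is raised when
    the regions cannot be placed, never a silently truncated mask.
    """
    H, W = spec.image_height_px, spec.image_width_px
    total_px = round(spec.target_area_fraction * H * W)
    rng = np.random.default_rng(spec.seed)

    if spec.n_regions == 0 or total_px == 0:
        mask = np.zeros((H, W), bool)
        gt = SliceGroundTruth(mask=mask, n_regions=0, total_damaged_area_cm2=0.0,
                              area_fraction=0.0, centroids=np.empty((0, 2)))
        img = SliceImage(np.full((H, W), 255, np.uint8), spec.pixel_scale)
        return img, gt

    if spec.size_distribution == "equal":
        weights = np.ones(spec.n_regions)
    else:
        weights = rng.lognormal(mean=0.0, sigma=spec.lognormal_sigma, size=spec.n_regions)
    sizes = _largest_remainder(weights, total_px)
    if (sizes < 1).any():  # lognormal tail can starve a region
        sizes = np.maximum(sizes, 1)
        sizes = _largest_remainder(sizes.astype(float), total_px)
    radii = np.array([_blob_radius(int(k), spec.region_shape) for k in sizes])
    sep_px = max(spec.min_separation / spec.pixel_scale, 2.0)

    for _ in range(25):  # whole-configuration retries
        centers = _place_centers(rng, H, W, radii, sep_px)
        if centers is None:
            continue
        mask = np.zeros((H, W), bool)
        for (cy, cx), k in zip(centers, sizes):
            off = _region_offsets(int(k), spec.region_shape)
            mask[off[:, 0] + cy, off[:, 1] + cx] = True
        if measure.label(mask, connectivity=2).max() == spec.n_regions \
                and int(mask.sum()) == total_px:
            break
    else:
        raise InfeasiblePackingError(
            f"could not place {spec.n_regions} regions totalling {total_px} px "
            f"in a {H}x{W} image at separation {sep_px:.1f} px")

    lab = measure.label(mask, connectivity=2)
    cents = []
    for i in range(1, spec.n_regions + 1):
        ys, xs = np.nonzero(lab == i)
        cents.append((xs.mean() * spec.pixel_scale, ys.mean() * spec.pixel_scale))
    centroids = np.array(cents)
    if spec.n_regions >= 2:
        dist, _ = cKDTree(centroids).query(centroids, k=2)
        min_nnd = float(dist[:, 1].min())
    else:
        min_nnd = math.nan

    gt = SliceGroundTruth(
        mask=mask,
        n_regions=spec.n_regions,
        total_damaged_area_cm2=total_px * spec.pixel_scale**2,
        area_fraction=total_px / (H * W),
        centroids=centroids,
        pairwise_min_nnd=min_nnd,
    )
    img = SliceImage(np.where(mask, 0, 255).astype(np.uint8), spec.pixel_scale)
    return img, gt


def _place_centers(rng, H, W, radii, sep_px, max_attempts: int = 20000):
    """Sequential rejection sampling of centers; None when a region fails."""
    centers: list[tuple[int, int]] = []
    for i, r in enumerate(radii):
        m = int(math.ceil(r)) + 1
        if H - 2 * m <= 0 or W - 2 * m <= 0:
            return None
        for _ in range(max_attempts):
            cy = int(rng.integers(m, H - m))
            cx = int(rng.integers(m, W - m))
            ok = all(math.hypot(cy - py, cx - px) >= r + radii[j] + sep_px
                     for j, (py, px) in enumerate(centers))
            if ok:
                centers.append((cy, cx))
                break
        else:
            return None
    return centers


def stage_fixture_spec(stage: int, seed: int = 42) -> SliceSpec:
    """Spec for the packaged per-stage fixture mask.

    A 200x200 px canvas at 0.1 cm/px (a 20x20 cm slice) makes every
    published stage area fraction an exact pixel multiple (e.g. 20.85% of
    40,000 px is exactly 8,340 px), so quantification recovers the printed
    percentage exactly.  Region count and area fraction are seed-invariant;
    only the placement varies with the seed.
    """
    if stage not in STAGE_REGION_COUNTS:
        raise ValueError("stage must be 1..4")
    return SliceSpec(
        image_height_px=200, image_width_px=200, pixel_scale=0.1,
        n_regions=STAGE_REGION_COUNTS[stage],
        target_area_fraction=STAGE_AREA_FRACTIONS[stage],
        region_shape="disk", min_separation=0.2, seed=seed,
    )


def generate_trajectory(params: ISVParams, times, noise_cv: float = 0.0,
                        seed: int = 0, schedule: StrainSchedule | None = None,
                        nominal_slice_area_cm2: float = 400.0
                        ) -> list[DamageObservation]:
    """Draw damage observations from the ISV laws at the given times.

    With ``noise_cv`` = 0 the observations lie exactly on the laws.
    Otherwise each measured quantity is perturbed by independent
    multiplicative lognormal noise with unit mean and coefficient of
    variation ``noise_cv`` (damage quantities are positive, so the error
    model is multiplicative).  ``nominal_slice_area_cm2`` only sets the
    integer region count bookkeeping field; the measured series are
    area-independent.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    times = np.asarray(times, dtype=float)
    traj = evaluate_trajectory(times, params, schedule)
    eta, v, nnd, phi = traj.eta, traj.v, traj.nnd, traj.phi
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        def jitter(x):
            return x * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=x.shape))
        eta, v, nnd, phi = jitter(eta), jitter(v), jitter(nnd), jitter(phi)
    return [
        DamageObservation(
            slice_id=f"synthetic_{i:03d}",
            n_regions=int(round(e * nominal_slice_area_cm2)),
            nucleation_density=float(e),
            damaged_area=float(a),
            nnd=float(d),
            damage_fraction=float(100.0 * p),
            time=float(t),
        )
        for i, (t, e, a, d, p) in enumerate(zip(times, eta, v, nnd, phi))
    ]


def generate_exposure_table(position: str, annual_impacts: int,
                            bin_proportions, years_per_stage, seed: int = 0):
    """Build an :class:`~taudamage.fatigue.ExposureProfile`.

    ``bin_proportions`` is a sequence of (g_level, fraction) pairs summing
    to 1 (within 1e-9); counts are apportioned by largest remainder so the
    per-bin annual counts sum exactly to ``annual_impacts``.  The seed is
    accepted for interface uniformity; the construction is deterministic.
    """
    from .fatigue import ExposureProfile

    return ExposureProfile.from_proportions(position, annual_impacts,
                                            bin_proportions, years_per_stage)


def example_g_level_proportions() -> list[tuple[float, float]]:
    """Illustrative synthetic G-level impact distribution for a lineman.

    The accelerometer study the exposure construction draws on does not
    print its per-G-level proportions, so this fixture is synthetic: a
    decaying distribution over 20-140 G bins typical of published helmet
    telemetry summaries.  Use measured proportions for any real analysis.
    """
    g = [20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 140.0]
    w = np.array([0.45, 0.25, 0.14, 0.08, 0.05, 0.02, 0.01])
    return list(zip(g, (w / w.sum()).tolist()))
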