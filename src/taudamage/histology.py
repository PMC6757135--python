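"""Quantification of damaged regions in stained brain-slice images.

A slice image is thresholded into a binary damage mask (damaged tissue
appears as dark p-tau accumulations on a brighter background), connected
components are labeled and measured, and three summary quantities are
computed per slice:

* nucleation density — number of damaged regions per cm^2 of slice,
* damage fraction    — 100 * A_damage / A_total, in percent,
* mean nearest-neighbor distance (NND) between region centroids, in cm.

Pixel coordinates use pixel centers, x right / y down, 0-based; physical
areas are pixel counts times ``pixel_scale**2``.  The total slice area
defaults to the full image frame; pass ``tissue_mask`` to restrict it when
the slice does not fill the frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import io as skio
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "SliceImage",
    "DamageMask",
    "ThresholdConfig",
    "RegionSet",
    "DamageObservation",
    "threshold_slice",
    "label_regions",
    "nucleation_density",
    "damage_fraction",
    "nearest_neighbor_distances",
    "quantify_slice",
    "write_observations_csv",
]


@dataclass
class SliceImage:
    """A grayscale slice picture with its physical scale.

    ``pixels`` is a 2-D intensity array; ``pixel_scale`` is cm per pixel.
    """

    pixels: np.ndarray
    pixel_scale: float
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("SliceImage requires a nonempty 2-D array")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be > 0")

    @classmethod
    def from_file(cls, path, pixel_scale: float, slice_id: str = "") -> "SliceImage":
        """Read an 8/16-bit grayscale PNG or TIFF."""
        px = skio.imread(path)
        if px.ndim == 3:  # collapse identical channels (greyscale saved as RGB)
            px = px[..., 0]
        return cls(px, pixel_scale, slice_id or str(path))


@dataclass
class DamageMask:
    """Binary damage mask (True = damaged) sharing the source image geometry."""

    mask: np.ndarray
    pixel_scale: float
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    def save(self, path) -> None:
        """Write as 8-bit PNG/TIFF, 0 = background, 255 = damage."""
        skio.imsave(path, (self.mask.astype(np.uint8) * 255), check_contrast=False)

    @classmethod
    def from_file(cls, path, pixel_scale: float, slice_id: str = "") -> "DamageMask":
        px = skio.imread(path)
        if px.ndim == 3:
            px = px[..., 0]
        return cls(px > 0, pixel_scale, slice_id or str(path))


@dataclass
class ThresholdConfig:
    """Global-threshold settings.

    method ``fixed`` uses ``fixed_value``; ``otsu`` picks the threshold from
    the intensity histogram.  ``dark_damage`` states the polarity: damaged
    tissue darker (True, the stained-slice convention) or brighter than
    background.
    """

    method: str = "otsu"
    fixed_value: float | None = None
    dark_damage: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "otsu"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "fixed" and self.fixed_value is None:
            raise ValueError("fixed method requires fixed_value")


@dataclass
class RegionSet:
    """Labeled damaged regions with physical measurements.

    ``regions`` is a DataFrame with columns label, area_cm2, centroid_x_cm,
    centroid_y_cm; ``total_slice_area_cm2`` is A_total and
    ``damaged_area_cm2`` is A_damage (the sum of region areas).
    """

    regions: pd.DataFrame
    total_slice_area_cm2: float
    damaged_area_cm2: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.total_slice_area_cm2 > 0:
            raise ValueError("total_slice_area_cm2 must be > 0")
        self.damaged_area_cm2 = float(self.regions["area_cm2"].sum()) if len(self.regions) else 0.0

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of region centroids in cm, columns (x, y)."""
        return self.regions[["centroid_x_cm", "centroid_y_cm"]].to_numpy()


@dataclass
class DamageObservation:
    """One slice's worth of damage measurements.

    ``time`` (approximate age at death, years) is unset at quantification
    and assigned later during data conditioning.  ``nnd`` is NaN when the
    slice has fewer than two regions (NND undefined, not zero).
    """

    slice_id: str
    n_regions: int
    nucleation_density: float  # regions per cm^2
    damaged_area: float        # cm^2
    nnd: float                 # cm, NaN when undefined
    damage_fraction: float     # percent
    time: float = math.nan


def threshold_slice(image: SliceImage, config: ThresholdConfig) -> DamageMask:
    """Apply a global threshold to a slice image.

    With ``dark_damage`` the damaged set is pixels at or below the
    threshold (the dark-object convention of ImageJ-style global
    thresholding, and the choice that makes Otsu work on already-binary
    images, where the computed threshold equals the dark value); bright
    damage takes pixels strictly above.  The fixed method is idempotent on
    an already-binary {0, 255} image thresholded at the midpoint.  A
    constant-intensity image
    yields an all-background mask (Otsu has nothing to separate; a fixed
    threshold classifies everything one way, and a constant field carries no
    damage evidence either way).
    """
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if lo == hi:
        return DamageMask(np.zeros(px.shape, bool), image.pixel_scale, image.slice_id)
    if config.method == "fixed":
        thr = float(config.fixed_value)
        if not (lo <= thr <= hi):
            raise ValueError(f"fixed threshold {thr} outside intensity range [{lo}, {hi}]")
    else:
        thr = float(threshold_otsu(px))
    mask = px <= thr if config.dark_damage else px > thr
    return DamageMask(mask, image.pixel_scale, image.slice_id)


def label_regions(mask: DamageMask, connectivity: int = 8) -> RegionSet:
    """Label connected damaged regions and measure them in cm.

    ``connectivity`` is 4 (edge neighbors) or 8 (edges + diagonals, the
    particle-analysis default).  Areas are pixel counts * pixel_scale^2;
    A_total is the full frame H*W*pixel_scale^2.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    scale = mask.pixel_scale
    lab = measure.label(mask.mask, connectivity=1 if connectivity == 4 else 2)
    rows = []
    for rp in measure.regionprops(lab):
        cy, cx = rp.centroid  # (row, col) -> y, x
        rows.append((rp.label, rp.area * scale**2, cx * scale, cy * scale))
    regions = pd.DataFrame(rows, columns=["label", "area_cm2", "centroid_x_cm", "centroid_y_cm"])
    a_total = mask.mask.shape[0] * mask.mask.shape[1] * scale**2
    return RegionSet(regions=regions, total_slice_area_cm2=a_total)


def nucleation_density(regions: RegionSet) -> float:
    """Nucleation = number of damaged regions / A_total, per cm^2."""
    return len(regions) / regions.total_slice_area_cm2


def damage_fraction(regions: RegionSet) -> float:
    """Damage (%) = 100 * A_damage / A_total."""
    return 100.0 * regions.damaged_area_cm2 / regions.total_slice_area_cm2


def nearest_neighbor_distances(regions: RegionSet, metric: str = "centroid"
                               ) -> tuple[np.ndarray, float]:
    """Per-region nearest-neighbor distance and the slice mean, in cm.

    For each region, the distance to its nearest other region.  ``centroid``
    (default) measures centroid to centroid, as the standard particle NND
    plugins do; ``edge`` measures minimum boundary-pixel separation.

    Raises ``ValueError`` when fewer than two regions exist: the NND is
    undefined there, never zero.
    """
    n = len(regions)
    if n < 2:
        raise ValueError(f"NND undefined for {n} region(s); need at least 2")
    if metric == "centroid":
        pts = regions.centroids
        dist, _ = cKDTree(pts).query(pts, k=2)
        nnds = dist[:, 1]
    elif metric == "edge":
        raise NotImplementedError(
            "edge-to-edge NND requires the labeled mask; use nearest_neighbor_distances_edge")
    else:
        raise ValueError(f"unknown NND metric {metric!r}")
    return nnds, float(nnds.mean())


def nearest_neighbor_distances_edge(mask: DamageMask, connectivity: int = 8
                                    ) -> tuple[np.ndarray, float]:
    """Edge-to-edge NND variant: minimum boundary-to-boundary distance per region."""
    lab = measure.label(mask.mask, connectivity=1 if connectivity == 4 else 2)
    n = lab.max()
    if n < 2:
        raise ValueError(f"NND undefined for {n} region(s); need at least 2")
    scale = mask.pixel_scale
    coords = [np.argwhere(lab == i) * scale for i in range(1, n + 1)]
    trees = [cKDTree(c[:, ::-1]) for c in coords]  # (x, y) order, irrelevant for distances
    nnds = np.empty(n)
    for i in range(n):
        best = math.inf
        for j in range(n):
            if i == j:
                continue
            d = trees[j].query(coords[i][:, ::-1], k=1)[0].min()
            best = min(best, d)
        nnds[i] = best
    return nnds, float(nnds.mean())


def quantify_slice(image: SliceImage, config: ThresholdConfig | None = None,
                   connectivity: int = 8) -> DamageObservation:
    """Full per-slice pipeline: threshold, label, and summarize.

    Composes the thresholding, region labeling, nucleation density, damage
    fraction and NND stages into one observation.  The time field is left
    NaN; it is filled during data conditioning.  An empty (undamaged) slice
    yields zeros with NaN NND.
    """
    config = config or ThresholdConfig()
    mask = threshold_slice(image, config)
    regions = label_regions(mask, connectivity=connectivity)
    n = len(regions)
    if n >= 2:
        _, mean_nnd = nearest_neighbor_distances(regions)
    else:
        mean_nnd = math.nan
    return DamageObservation(
        slice_id=image.slice_id,
        n_regions=n,
        nucleation_density=nucleation_density(regions),
        damaged_area=regions.damaged_area_cm2,
        nnd=mean_nnd,
        damage_fraction=damage_fraction(regions),
    )


def observations_to_frame(observations: list[DamageObservation],
                          area_units: str = "cm2") -> pd.DataFrame:
    """Tabulate observations; ``area_units`` cm2 (default) or mm2."""
    if area_units not in ("cm2", "mm2"):
        raise ValueError("area_units must be 'cm2' or 'mm2'")
    k = 100.0 if area_units == "mm2" else 1.0  # 1 cm^2 = 100 mm^2
    return pd.DataFrame({
        "slice_id": [o.slice_id for o in observations],
        "time_years": [o.time for o in observations],
        "n_regions": [o.n_regions for o in observations],
        "nucleation_per_cm2": [o.nucleation_density for o in observations],
        f"damaged_area_{area_units}": [o.damaged_area * k for o in observations],
        "mean_nnd_cm": [o.nnd for o in observations],
        "damage_pct": [o.damage_fraction for o in observations],
    })


def write_observations_csv(observations: list[DamageObservation], path,
                           area_units: str = "cm2") -> None:
    observations_to_frame(observations, area_units).to_csv(path, index=False)
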