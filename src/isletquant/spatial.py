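"""Mantle/core stratification, vessel proximity, glucose-penetration
profiles and HSV classification maps.

The embryonic islet is a compact, near-spherical cluster; the mantle is
its outer single-cell layer.  The surface is estimated from the detected
centroids themselves (least-squares sphere through the convex-hull
vertices, radius corrected for the sample maximum and inflated by one
mean cell radius), so stratification needs no extra imaging channel and
is invariant under rigid motion of the islet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull

from .io import ROISet
from .synth import PenetrationField

__all__ = ["CompartmentCall", "classify_mantle_core", "vessel_proximity",
           "penetration_profile", "hsv_render"]

MANTLE = "mantle"
CORE = "core"


@dataclass
class CompartmentCall:
    cell_id: int
    compartment: str                 # mantle / core
    surface_distance: float          # μm
    vessel_distance: float = np.inf  # μm
    vessel_proximal: bool = False


def _sphere_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere through ``points`` (center, radius)."""
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def _enclosing_ball_center(points: np.ndarray) -> np.ndarray:
    """Centre of the (approximate) minimum enclosing ball of ``points``."""
    from scipy.optimize import minimize
    res = minimize(lambda x: np.linalg.norm(points - x, axis=1).max(),
                   points.mean(axis=0), method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 3000})
    return res.x


def _surface_radius(dist: np.ndarray, r_mean: float, k: int = 3) -> float:
    """Surface radius from the top-``k`` centroid distances.

    Each of the k largest order statistics of a uniform-ball sample gives
    an unbiased estimate of the ball radius after the correction
    ``d_(n-j) × ((n+1)/(n-j))^(1/3)``; averaging them is less sensitive to
    centroid noise than the sample maximum alone.  One mean cell radius is
    added to go from outermost centroid to islet surface.
    """
    n = len(dist)
    ds = np.sort(dist)[::-1]
    k = min(k, n)
    ests = [ds[j] * ((n + 1) / (n - j)) ** (1.0 / 3.0) for j in range(k)]
    return float(np.mean(ests)) + r_mean


def classify_mantle_core(rois: ROISet,
                         voxel_size: tuple[float, float, float]
                         = (1.0, 1.0, 1.0),
                         mantle_depth: Optional[float] = None,
                         cell_radius: Optional[float] = None
                         ) -> list[CompartmentCall]:
    """Label each cell mantle or core from centroid geometry alone.

    The islet centre is estimated twice — a least-squares sphere through
    the convex-hull vertices, iteratively refined on the putative mantle
    shell, and the minimum-enclosing-ball centre — and the two estimates
    averaged (their errors are only partly correlated).  The surface
    radius is the corrected maximum centroid distance plus one mean cell
    radius.  A cell is mantle when its centroid lies within
    ``mantle_depth`` (default one mean cell diameter) of that surface; a
    single-cell islet is mantle.

    ``cell_radius`` (μm) overrides the per-ROI equivalent radii, which
    are inflated by the PSF when the ROIs come from blob detection.
    """
    if len(rois) == 0:
        raise ValueError("need at least one ROI")
    d = np.asarray(voxel_size)
    cents = rois.centroids() * d
    ids = rois.ids
    r_mean = float(cell_radius) if cell_radius is not None \
        else float((rois.radii() * d[2]).mean())
    if mantle_depth is None:
        mantle_depth = 2.0 * r_mean
    n = len(cents)
    if n < 5:
        # too few points for a hull/sphere fit: all cells are surface cells
        return [CompartmentCall(int(i), MANTLE, r_mean) for i in ids]

    hull = ConvexHull(cents)
    center, _ = _sphere_fit(cents[hull.vertices])
    for _ in range(3):      # damped refinement on the putative mantle shell
        dist = np.linalg.norm(cents - center, axis=1)
        mantle = (_surface_radius(dist, r_mean) - dist) <= mantle_depth
        if mantle.sum() < 5:
            break
        refined, _ = _sphere_fit(cents[mantle])
        center = 0.5 * center + 0.5 * refined
    center = 0.5 * center + 0.5 * _enclosing_ball_center(cents)

    dist = np.linalg.norm(cents - center, axis=1)
    surface_r = _surface_radius(dist, r_mean)
    calls = []
    for i, dd in zip(ids, dist):
        sd = max(0.0, surface_r - float(dd))
        comp = MANTLE if sd <= mantle_depth else CORE
        calls.append(CompartmentCall(int(i), comp, sd))
    return calls


def _point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray
                        ) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
    return float(np.linalg.norm(p - (a + t * ab)))


def vessel_proximity(rois: ROISet, vessels: Sequence[np.ndarray],
                     threshold: float = 7.0,
                     voxel_size: tuple[float, float, float]
                     = (1.0, 1.0, 1.0)) -> list[CompartmentCall]:
    """Min centroid→vessel-segment distance and a proximity flag per cell.

    ``threshold`` defaults to one cell diameter (7 μm).  With no vessels
    every distance is +inf and no cell is proximal.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = np.asarray(voxel_size)
    cents = rois.centroids() * d
    calls = []
    for i, p in zip(rois.ids, cents):
        dist = np.inf
        for line in vessels:
            line = np.asarray(line, float)
            if len(line) == 1:
                dist = min(dist, float(np.linalg.norm(p - line[0])))
            for a, b in zip(line[:-1], line[1:]):
                dist = min(dist, _point_segment_dist(p, a, b))
        calls.append(CompartmentCall(
            int(i), "", surface_distance=np.nan, vessel_distance=dist,
            vessel_proximal=bool(dist <= threshold)))
    return calls


def penetration_profile(field: PenetrationField,
                        compartments: Sequence[CompartmentCall],
                        half_level: float = 0.5
                        ) -> tuple[np.ndarray, np.ndarray, Optional[float]]:
    """Core/mantle mean-concentration ratio over time.

    Returns ``(times, ratio, t_half)`` where ``t_half`` is the first time
    the ratio reaches ``half_level`` (None if never).  Raises if the
    compartment calls do not cover all sampled cells or there are no core
    cells (undefined ratio).
    """
    comp_by_id = {c.cell_id: c.compartment for c in compartments}
    try:
        comp = np.array([comp_by_id[int(i)] for i in field.cell_ids])
    except KeyError as e:
        raise ValueError(f"compartment call missing for cell {e}") from None
    core = comp == CORE
    mantle = comp == MANTLE
    if not core.any():
        raise ValueError("no core cells: core/mantle ratio undefined")
    if not mantle.any():
        raise ValueError("no mantle cells: core/mantle ratio undefined")
    core_mean = field.concentrations[:, core].mean(axis=1)
    mantle_mean = field.concentrations[:, mantle].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mantle_mean > 0, core_mean / mantle_mean, 0.0)
    above = np.flatnonzero(ratio >= half_level)
    t_half = float(field.times[above[0]]) if above.size else None
    return field.times, ratio, t_half


_HUES = (0.0, 120.0, 240.0)


def hsv_render(volume: np.ndarray, labels_by_class: Sequence[Sequence[int]],
               rois: ROISet, z_scale: float = 1.0) -> np.ndarray:
    """Colour-code a grayscale frame by cell class in HSV space.

    Saturation is 1 inside classified cells and 0 elsewhere; value is the
    normalised gray level everywhere; hue is 0°, 120° or 240° by class
    (e.g. responsive → 0 = red, nonresponsive → 120/240).  Returns an
    RGB float volume in [0, 1] with shape ``volume.shape + (3,)``.
    """
    if len(labels_by_class) > 3:
        raise ValueError("at most 3 classes supported (hues 0/120/240)")
    from skimage.color import hsv2rgb

    vol = np.asarray(volume, float)
    vmax = vol.max()
    value = vol / vmax if vmax > 0 else vol
    label_vol = rois.labels if rois.labels is not None else None
    if label_vol is None:
        from .io import rois_to_labels
        label_vol = rois_to_labels(rois, vol.shape, z_scale).labels

    hue = np.zeros_like(vol)
    sat = np.zeros_like(vol)
    for cls_idx, ids in enumerate(labels_by_class):
        for i in ids:
            m = label_vol == i
            hue[m] = _HUES[cls_idx] / 360.0
            sat[m] = 1.0
    hsv = np.stack([hue, sat, value], axis=-1)
    return hsv2rgb(hsv, channel_axis=-1)
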