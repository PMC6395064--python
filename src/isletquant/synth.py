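"""Ground-truthed synthetic islet generator.

Forward model for the in vivo imaging arm of the study: sphere-packed
β-cell geometries with a mantle/core partition, ingrowing vessel trees,
glucose-evoked calcium transients, a light-sheet-style volumetric renderer
(anisotropic Gaussian PSF, frame-averaged Poisson shot noise, Gaussian read
noise, optional bleaching), a reaction–diffusion glucose-penetration model,
and truncated-normal insulin-secretion / ensemble-calcium draws for the
cultured mouse-islet arm.

Every stochastic operation takes an explicit integer seed and is bit-
reproducible.  Ground truth (cell positions, compartments, responsive
flags, amplitudes, onsets) is carried alongside every simulated object so
the analysis pipeline can be validated end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .io import CalciumRecording, ROI, ROISet
from .presets import StagePreset

__all__ = [
    "IsletGeometry", "CellTraceSet", "ImagingParams", "PenetrationField",
    "generate_geometry", "generate_vessels", "simulate_transients",
    "render_recording", "render_marker_channel", "geometry_rois",
    "simulate_glucose_penetration", "simulate_secretion",
    "simulate_ensemble_recording", "write_ground_truth", "read_ground_truth",
]

MANTLE = "mantle"
CORE = "core"

# default classification floor mirrored by the generator: a ground-truth
# responsive cell carries a supra-threshold amplitude by definition
AMPLITUDE_FLOOR = 0.20


# --------------------------------------------------------------------------
# domain types

@dataclass
class IsletGeometry:
    """Ground-truth cell geometry of one islet.

    Coordinates are μm, ordered (z, y, x), with the islet centroid at the
    origin.  ``compartment`` holds the ground-truth mantle/core label
    (centroid within one mean cell diameter of the islet surface → mantle).
    """

    cell_ids: np.ndarray            # (n,)
    centroids: np.ndarray           # (n, 3) μm, zyx
    radii: np.ndarray               # (n,) μm
    compartment: np.ndarray         # (n,) str, "mantle"/"core"
    marker2: np.ndarray             # (n,) bool, mosaic second channel
    islet_radius: float             # μm
    islet_centroid: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    vessels: list[np.ndarray] = field(default_factory=list)  # (k_i, 3) μm

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))


@dataclass
class CellTraceSet:
    """Per-cell fluorescence time courses plus their ground truth."""

    cell_ids: np.ndarray
    F: np.ndarray                   # (n, T) intensity, a.u.
    times: np.ndarray               # (T,) s
    stim_time: float                # s
    F0: np.ndarray                  # (n,) baseline intensity
    responsive: np.ndarray          # (n,) bool
    onset_time: np.ndarray          # (n,) s, nan for nonresponsive
    amplitude: np.ndarray           # (n,) Max ΔF/F0, 0 for nonresponsive
    sync_group: np.ndarray          # (n,) int, -1 = ungrouped

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ImagingParams:
    """Acquisition model: optics, sampling and noise.

    ``voxel_size`` is μm (z, y, x).  Each saved frame is the average of
    ``exposures_per_frame`` independent exposures, matching plane-by-plane
    frame-averaged acquisition.  ``photon_scale`` converts intensity units
    to expected photons per exposure; ``math.inf`` disables shot noise.
    ``n_planes=None`` sizes the z-stack to the islet automatically.
    """

    voxel_size: tuple[float, float, float] = (3.5, 0.8, 0.8)
    n_planes: Optional[int] = None
    frame_interval: float = 1.0         # s
    exposures_per_frame: int = 5
    psf_sigma: tuple[float, float, float] = (1.8, 0.6, 0.6)  # μm, zyx
    photon_scale: float = 2.0           # photons per intensity unit
    read_noise_sd: float = 2.0          # intensity units, per exposure
    bleach_rate: float = 0.0            # 1/s
    background: float = 2.0             # intensity units
    lateral_margin: float = 4.0         # μm padding around the islet

    def __post_init__(self) -> None:
        if self.n_planes is not None and self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.psf_sigma[0] < self.psf_sigma[1]:
            raise ValueError("axial PSF sigma must be >= lateral sigma")
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be positive")
        if self.exposures_per_frame < 1:
            raise ValueError("exposures_per_frame must be >= 1")


@dataclass
class PenetrationField:
    """Concentration at each cell centroid over time (mM)."""

    times: np.ndarray               # (T,) s
    concentrations: np.ndarray      # (T, n_cells) mM
    cell_ids: np.ndarray


# --------------------------------------------------------------------------
# geometry

def _islet_radius(n: int, cell_radius: float, fill: float) -> float:
    # islet sized so that β-cells occupy `fill` of its volume
    return cell_radius * (n / fill) ** (1.0 / 3.0)


def generate_geometry(preset: StagePreset, seed: int) -> IsletGeometry:
    """Pack non-overlapping β-cell spheres into a spherical islet.

    The cell count is drawn from N(n_cells_mean, n_cells_sd), rounded and
    floored at 1.  Cells whose centroid lies within one mean cell diameter
    of the islet surface are ground-truth mantle, the rest core; a
    single-cell islet is mantle by definition.  The mosaic second marker is
    drawn per cell from ``coexpression_frac``.
    """
    if not preset.has_geometry:
        raise ValueError(f"preset {preset.name!r} has no geometry parameters")
    rng = np.random.default_rng(seed)
    sd = preset.n_cells_sd or 0.0
    n = max(1, int(round(rng.normal(preset.n_cells_mean, sd))))
    r = preset.cell_radius
    R = _islet_radius(n, r, preset.beta_fill_frac)

    max_c = R - r                       # centroids keep cells inside the islet
    min_gap = lambda: 2.0 * r - 0.1 * r  # ≤10% overlap of the smaller radius
    centroids = np.empty((n, 3))
    placed = 0
    attempts = 0
    max_attempts = 2000 * n
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"sphere packing failed: {n} cells of radius {r} μm do not "
                f"fit an islet of radius {R:.1f} μm "
                f"(fill fraction {preset.beta_fill_frac})")
        attempts += 1
        p = rng.uniform(-max_c, max_c, 3)
        if np.dot(p, p) > max_c ** 2:
            continue
        if placed and np.min(
                np.linalg.norm(centroids[:placed] - p, axis=1)) < min_gap():
            continue
        centroids[placed] = p
        placed += 1

    dist = np.linalg.norm(centroids, axis=1)
    compartment = np.where(dist >= R - 2.0 * r, MANTLE, CORE).astype(object)
    if n == 1:
        compartment[:] = MANTLE
    frac2 = preset.coexpression_frac
    marker2 = (rng.random(n) < frac2) if frac2 is not None \
        else np.zeros(n, bool)
    return IsletGeometry(
        cell_ids=np.arange(1, n + 1),
        centroids=centroids,
        radii=np.full(n, float(r)),
        compartment=np.asarray(compartment, dtype=object),
        marker2=marker2,
        islet_radius=float(R),
    )


def generate_vessels(geometry: IsletGeometry, penetration: float,
                     seed: int, n_vessels: int = 3,
                     step: float = 2.0) -> IsletGeometry:
    """Populate ``geometry.vessels`` with inward-growing polylines.

    Vessels start outside the islet and advance toward the centre with
    small lateral jitter; the deepest vessel terminates exactly at depth
    ``penetration × islet_radius`` below the surface, the others at
    shallower random depths.  ``penetration=0`` leaves surface contacts
    only.
    """
    if not (0.0 <= penetration <= 1.0):
        raise ValueError("penetration must be in [0, 1]")
    rng = np.random.default_rng(seed)
    R = geometry.islet_radius
    target_r = R * (1.0 - penetration)
    vessels: list[np.ndarray] = []
    for k in range(n_vessels):
        # deepest vessel hits the target depth exactly; others are shallower
        end_r = target_r if k == 0 else rng.uniform(target_r, R)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start = direction * (R * 1.3)
        pts = [start]
        pos = start.copy()
        while np.linalg.norm(pos) > max(end_r, step * 0.5):
            inward = -pos / np.linalg.norm(pos)
            jitter = rng.normal(scale=0.3, size=3)
            d = inward + jitter - np.dot(jitter, inward) * inward * 0.0
            d /= np.linalg.norm(d)
            pos = pos + d * step
            pts.append(pos.copy())
        # land exactly on the target radius
        if np.linalg.norm(pos) > 1e-9:
            pts[-1] = pos / np.linalg.norm(pos) * end_r
        vessels.append(np.array(pts))
    geometry.vessels = vessels
    return geometry


# --------------------------------------------------------------------------
# calcium transients

def _matched_truncnorm_mu(target_mean: float, sd: float,
                          floor: float) -> float:
    """Underlying normal mean whose ``floor``-truncated mean equals target."""
    if sd == 0:
        return target_mean

    def trunc_mean(mu: float) -> float:
        a = (floor - mu) / sd
        return float(truncnorm.mean(a, np.inf, loc=mu, scale=sd))

    lo, hi = target_mean - 6 * sd, target_mean + sd
    return brentq(lambda m: trunc_mean(m) - target_mean, lo, hi, xtol=1e-10)


def _draw_amplitude(rng: np.random.Generator, mean: float, sd: float,
                    floor: float = AMPLITUDE_FLOOR) -> float:
    """Draw Max ΔF/F0 from a normal truncated at the responsiveness floor.

    The underlying mean is moment-matched so the truncated distribution has
    mean ``mean`` (for mean > floor); a responsive cell is by definition
    supra-threshold.
    """
    if sd == 0:
        return float(mean)
    mu = _matched_truncnorm_mu(mean, sd, floor)
    while True:                      # rejection keeps the rng stream simple
        a = rng.normal(mu, sd)
        if a >= floor:
            return float(a)


def _transient_shape(t: np.ndarray, onset: float, tau_rise: float,
                     tau_decay: float) -> np.ndarray:
    """Rise/decay double exponential, normalised to a sampled max of 1."""
    u = t - onset
    s = np.where(u > 0,
                 (1.0 - np.exp(-np.clip(u, 0, None) / tau_rise))
                 * np.exp(-np.clip(u, 0, None) / tau_decay), 0.0)
    m = s.max()
    return s / m if m > 1e-12 else s


def _responsive_fraction(preset: StagePreset, comp: str,
                         n_comp: int) -> float:
    frac = getattr(preset, f"frac_responsive_{comp}")
    target = getattr(preset, f"target_responsive_{comp}")
    if target is not None:
        return min(1.0, target / n_comp) if n_comp else 0.0
    return frac if frac is not None else 0.0


def simulate_transients(geometry: IsletGeometry, preset: StagePreset,
                        duration: float, stim_time: float, seed: int,
                        frame_interval: float = 1.0,
                        f0_mean: float = 150.0,
                        f0_sd: float = 15.0) -> CellTraceSet:
    """Noise-free per-cell fluorescence traces with ground truth.

    Responsive cells are drawn per compartment (from preset fractions or
    expected counts); each gets F(t) = F0·(1 + A·s(t)) with a double-
    exponential transient starting at ``stim_time`` plus a cell- or
    group-level delay.  Neighbouring responsive cells join a shared onset
    group with probability ``sync_group_prob``.  Nonresponsive cells stay
    flat at F0.
    """
    if not stim_time < duration:
        raise ValueError("stim_time must be < duration")
    rng = np.random.default_rng(seed)
    n = geometry.n_cells
    times = np.arange(0.0, duration, frame_interval)

    responsive = np.zeros(n, bool)
    for comp in (MANTLE, CORE):
        idx = np.flatnonzero(geometry.compartment == comp)
        frac = _responsive_fraction(preset, comp, len(idx))
        responsive[idx] = rng.random(len(idx)) < frac

    # synchronized onset groups among responsive neighbours (union-find)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    neighbor_dist = 2.0 * geometry.mean_radius * 1.5
    resp_idx = np.flatnonzero(responsive)
    for a_pos in range(len(resp_idx)):
        for b_pos in range(a_pos + 1, len(resp_idx)):
            i, j = resp_idx[a_pos], resp_idx[b_pos]
            d = np.linalg.norm(geometry.centroids[i] - geometry.centroids[j])
            if d <= neighbor_dist and rng.random() < preset.sync_group_prob:
                parent[find(i)] = find(j)

    max_delay = max(0.0, duration - stim_time - preset.tau_rise)
    group_delay: dict[int, float] = {}
    amplitude = np.zeros(n)
    onset = np.full(n, np.nan)
    F = np.empty((n, len(times)))
    F0 = np.maximum(rng.normal(f0_mean, f0_sd, n), 0.2 * f0_mean)
    sync_group = np.full(n, -1)

    for i in range(n):
        if not responsive[i]:
            F[i] = F0[i]
            continue
        root = find(i)
        if root not in group_delay:
            d = rng.normal(preset.onset_delay_mean, preset.onset_delay_sd)
            group_delay[root] = float(np.clip(d, 0.0, max_delay))
        sync_group[i] = root
        comp = geometry.compartment[i]
        amp = _draw_amplitude(
            rng,
            getattr(preset, f"amp_mean_{comp}"),
            getattr(preset, f"amp_sd_{comp}") or 0.0)
        onset[i] = stim_time + group_delay[root]
        s = _transient_shape(times, onset[i], preset.tau_rise,
                             preset.tau_decay)
        if s.max() < 1e-12:          # transient entirely outside the record
            responsive[i] = False
            F[i] = F0[i]
            onset[i] = np.nan
            sync_group[i] = -1
            continue
        amplitude[i] = amp
        F[i] = F0[i] * (1.0 + amp * s)

    return CellTraceSet(
        cell_ids=geometry.cell_ids.copy(), F=F, times=times,
        stim_time=float(stim_time), F0=F0, responsive=responsive,
        onset_time=onset, amplitude=amplitude, sync_group=sync_group)


# --------------------------------------------------------------------------
# volumetric rendering

def _grid_for(geometry: IsletGeometry, params: ImagingParams
              ) -> tuple[tuple[int, int, int], np.ndarray]:
    """Voxel-grid shape and physical origin (μm, zyx) enclosing the islet."""
    dz, dy, dx = params.voxel_size
    extent = 2.0 * (geometry.islet_radius + params.lateral_margin)
    nz = params.n_planes if params.n_planes is not None \
        else int(math.ceil(extent / dz))
    ny = int(math.ceil(extent / dy))
    nx = int(math.ceil(extent / dx))
    shape = (nz, ny, nx)
    span = np.array([nz * dz, ny * dy, nx * dx])
    origin = -span / 2.0            # islet centroid sits at the grid centre
    reach = np.linalg.norm(geometry.centroids, axis=1) + geometry.radii \
        if geometry.n_cells else np.array([0.0])
    if reach.max() > min(span) / 2.0:
        raise ValueError(
            f"islet (extent {2 * reach.max():.1f} μm) overflows the field of "
            f"view ({span} μm); increase n_planes or the margin")
    return shape, origin


def _cell_voxel_indices(geometry: IsletGeometry, shape, origin, voxel_size
                        ) -> list[np.ndarray]:
    """Flat voxel indices covered by each cell sphere (physical space)."""
    d = np.asarray(voxel_size)
    idx_lists = []
    grid_shape = np.array(shape)
    for c, r in zip(geometry.centroids, geometry.radii):
        lo = np.maximum(((c - r - origin) / d - 0.5).astype(int), 0)
        hi = np.minimum(((c + r - origin) / d + 1.5).astype(int), grid_shape)
        zz, yy, xx = np.meshgrid(
            *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        pos = (np.stack([zz, yy, xx], -1) + 0.5) * d + origin
        inside = np.sum((pos - c) ** 2, -1) <= r * r
        flat = (zz * shape[1] * shape[2] + yy * shape[2] + xx)[inside]
        idx_lists.append(flat.ravel())
    return idx_lists


def geometry_rois(geometry: IsletGeometry, params: ImagingParams) -> ROISet:
    """Ground-truth ROIs in the voxel frame of :func:`render_recording`."""
    shape, origin = _grid_for(geometry, params)
    d = np.asarray(params.voxel_size)
    rois = []
    for i, (c, r) in enumerate(zip(geometry.centroids, geometry.radii)):
        vox = (c - origin) / d - 0.5
        rois.append(ROI(int(geometry.cell_ids[i]), tuple(vox),
                        float(r / d[2])))
    return ROISet(rois=rois)


def _acquire(clean: np.ndarray, params: ImagingParams,
             rng: np.random.Generator) -> np.ndarray:
    """Frame-averaged Poisson shot noise plus Gaussian read noise.

    The average of E i.i.d. Poisson(λ) draws equals Poisson(E·λ)/E in
    distribution, so frame averaging is sampled with a single draw; the
    averaged read noise is N(0, σ/√E).
    """
    e = params.exposures_per_frame
    if math.isinf(params.photon_scale):
        out = clean.copy()
    else:
        lam = clean * (params.photon_scale * e)
        out = rng.poisson(lam) / (e * params.photon_scale)
    if params.read_noise_sd > 0:
        out = out + rng.normal(0.0, params.read_noise_sd / math.sqrt(e),
                               clean.shape)
    return np.maximum(out, 0.0)


def render_recording(geometry: IsletGeometry, traces: CellTraceSet,
                     params: ImagingParams, seed: int) -> CalciumRecording:
    """Rasterise cell spheres at their trace intensities into a noisy
    volumetric time-lapse.

    Per frame: paint spheres, convolve with the anisotropic Gaussian PSF,
    apply exponential bleaching, then average ``exposures_per_frame``
    Poisson draws and add read noise.
    """
    rng = np.random.default_rng(seed)
    shape, origin = _grid_for(geometry, params)
    idx_lists = _cell_voxel_indices(geometry, shape, origin,
                                    params.voxel_size)
    T = len(traces.times)
    sigma_vox = tuple(s / d for s, d in zip(params.psf_sigma,
                                            params.voxel_size))
    clean = np.empty((T,) + shape, dtype=np.float64)
    flat = np.empty(int(np.prod(shape)))
    for t in range(T):
        flat[:] = params.background
        for i, idx in enumerate(idx_lists):
            flat[idx] = traces.F[i, t]
        clean[t] = flat.reshape(shape)
    if max(sigma_vox) > 1e-9:
        clean = ndimage.gaussian_filter(clean, (0.0,) + sigma_vox)
    if params.bleach_rate > 0:
        decay = np.exp(-params.bleach_rate * traces.times)
        clean = params.background + (clean - params.background) \
            * decay[:, None, None, None]
    voxels = _acquire(clean, params, rng)
    return CalciumRecording(
        voxels=voxels, voxel_size=params.voxel_size,
        frame_interval=traces.frame_interval, stim_time=traces.stim_time,
        n_planes=shape[0])


def render_marker_channel(geometry: IsletGeometry, params: ImagingParams,
                          seed: int, intensity: float = 120.0) -> np.ndarray:
    """Static second-channel volume: marker2-positive cells are bright."""
    rng = np.random.default_rng(seed)
    shape, origin = _grid_for(geometry, params)
    idx_lists = _cell_voxel_indices(geometry, shape, origin,
                                    params.voxel_size)
    flat = np.full(int(np.prod(shape)), params.background)
    for i, idx in enumerate(idx_lists):
        if geometry.marker2[i]:
            flat[idx] = intensity
    frame = flat.reshape(shape)
    sigma_vox = tuple(s / d for s, d in zip(params.psf_sigma,
                                            params.voxel_size))
    if max(sigma_vox) > 1e-9:
        frame = ndimage.gaussian_filter(frame, sigma_vox)
    return _acquire(frame, params, rng)


# --------------------------------------------------------------------------
# glucose penetration (reaction–diffusion)

def simulate_glucose_penetration(
        geometry: IsletGeometry, dose: float, diffusivity: float,
        vessel_source: bool, duration: float, dt: float,
        grid_h: float = 2.0, uptake_vmax: float = 0.0,
        uptake_km: float = 5.0, save_every: int = 10) -> PenetrationField:
    """Explicit finite-difference diffusion of glucose into the islet.

    The islet surface is held at ``dose`` (bath concentration); with
    ``vessel_source`` the vessel polylines are clamped to ``dose`` as well.
    A Michaelis–Menten sink (``uptake_vmax``, ``uptake_km``) models
    saturable cellular uptake, which makes *relative* penetration dose-
    dependent.  Returns concentration sampled at each cell centroid.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    h = grid_h
    if diffusivity > 0:
        dt_max = h * h / (6.0 * diffusivity)
        if dt > dt_max:
            raise ValueError(
                f"unstable dt={dt}; explicit scheme needs dt <= "
                f"h^2/(6D) = {dt_max:.4g} s")
    R = geometry.islet_radius
    half = R + 2 * h
    n_side = int(math.ceil(2 * half / h))
    ax = (np.arange(n_side) + 0.5) * h - half
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = zz ** 2 + yy ** 2 + xx ** 2 <= R * R

    fixed = ~inside                          # bath voxels clamped to dose
    if vessel_source and geometry.vessels:
        for line in geometry.vessels:
            # densify each segment so the clamp is contiguous on the grid
            for a, b in zip(line[:-1], line[1:]):
                npts = max(2, int(np.linalg.norm(b - a) / (h / 2)) + 1)
                pts = a + (b - a) * np.linspace(0, 1, npts)[:, None]
                ijk = np.clip(((pts + half) / h - 0.5).round().astype(int),
                              0, n_side - 1)
                fixed[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True

    C = np.zeros_like(zz)
    C[fixed] = dose
    n_steps = int(round(duration / dt))
    cells_ijk = np.clip(((geometry.centroids + half) / h - 0.5)
                        .round().astype(int), 0, n_side - 1)
    times, samples = [], []
    lap = np.empty_like(C)
    for step in range(n_steps + 1):
        if step % save_every == 0 or step == n_steps:
            times.append(step * dt)
            samples.append(C[cells_ijk[:, 0], cells_ijk[:, 1],
                             cells_ijk[:, 2]].copy())
        if step == n_steps:
            break
        if diffusivity > 0:
            lap[:] = -6.0 * C
            lap[:-1] += C[1:]
            lap[1:] += C[:-1]
            lap[:, :-1] += C[:, 1:]
            lap[:, 1:] += C[:, :-1]
            lap[:, :, :-1] += C[:, :, 1:]
            lap[:, :, 1:] += C[:, :, :-1]
            C = C + dt * diffusivity * lap / (h * h)
        if uptake_vmax > 0:
            C = C - dt * uptake_vmax * C / (uptake_km + C) * inside
        np.clip(C, 0.0, None, out=C)
        C[fixed] = dose
    return PenetrationField(
        times=np.array(times), concentrations=np.array(samples),
        cell_ids=geometry.cell_ids.copy())


# --------------------------------------------------------------------------
# secretion and ensemble calcium (cultured mouse-islet arm)

def _trunc_draw(rng: np.random.Generator, mean: float, sd: float,
                lo: float = 0.0) -> float:
    if sd == 0:
        return float(max(mean, lo))
    while True:
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)


def simulate_secretion(preset: StagePreset, n_batches: int, seed: int):
    """Draw per-batch low/high-glucose insulin secretion (ng/ml).

    Presets specified via GSI draw high and the per-batch stimulation index
    from their published distributions and derive low = high / GSI, so both
    printed statistics are reproduced in expectation.
    """
    from .secretion import SecretionRecord
    if not preset.has_secretion:
        raise ValueError(
            f"preset {preset.name!r} has no secretion parameters")
    rng = np.random.default_rng(seed)
    records = []
    for b in range(n_batches):
        high = _trunc_draw(rng, preset.secretion_high_mean,
                           preset.secretion_high_sd or 0.0)
        if preset.gsi_mean is not None:
            g = _trunc_draw(rng, preset.gsi_mean, preset.gsi_sd or 0.0,
                            lo=1e-6)
            low = high / g
        else:
            low = _trunc_draw(rng, preset.secretion_low_mean,
                              preset.secretion_low_sd or 0.0)
        records.append(SecretionRecord(
            batch_id=b + 1, condition=preset.name,
            low_secretion=low, high_secretion=high))
    return records


DEFAULT_PROTOCOL = ((0.5, 300.0), (2.8, 600.0), (16.7, 600.0))


def simulate_ensemble_recording(
        preset: StagePreset, seed: int,
        protocol: Sequence[tuple[float, float]] = DEFAULT_PROTOCOL,
        frame_interval: float = 1.0, baseline: float = 100.0,
        noise_sd: float = 0.3, tau_rise: float = 20.0,
        tau_decay: float = 240.0) -> CalciumRecording:
    """Whole-islet recording under the sequential glucose protocol.

    Phase maxima (percent of the first-phase baseline) are drawn from the
    preset's ensemble-calcium distributions; phases below baseline render
    as flat (abolished transients).  The output is a minimal uniform
    volume suitable for :func:`isletquant.secretion.ensemble_calcium`.
    """
    if preset.ca_high_pct_mean is None:
        raise ValueError(f"preset {preset.name!r} has no ensemble-calcium "
                         "parameters")
    if len(protocol) != 3:
        raise ValueError("protocol must have three phases (rest, low, high)")
    rng = np.random.default_rng(seed)
    durations = [p[1] for p in protocol]
    total = sum(durations)
    times = np.arange(0.0, total, frame_interval)
    trace = np.full_like(times, baseline)
    starts = np.cumsum([0.0] + durations[:-1])
    targets = [None, (preset.ca_low_pct_mean, preset.ca_low_pct_sd or 0.0),
               (preset.ca_high_pct_mean, preset.ca_high_pct_sd or 0.0)]
    for phase_i, (start, tgt) in enumerate(zip(starts, targets)):
        if tgt is None:
            continue
        pct = _trunc_draw(rng, tgt[0], tgt[1])
        amp = max(0.0, pct / 100.0 - 1.0)
        s = _transient_shape(times, start + 20.0, tau_rise, tau_decay)
        # confine each phase's transient to its own phase window
        phase_end = start + durations[phase_i]
        s = np.where((times >= start) & (times < phase_end), s, 0.0)
        m = s.max()
        if m > 1e-12:
            trace = trace + baseline * amp * s / m
    trace = trace + rng.normal(0.0, noise_sd, trace.shape)
    vox = np.maximum(trace, 0.0)[:, None, None, None] * np.ones((1, 2, 4, 4))
    return CalciumRecording(
        voxels=vox, voxel_size=(10.0, 5.0, 5.0),
        frame_interval=frame_interval, stim_time=float(starts[1]),
        n_planes=2)


# --------------------------------------------------------------------------
# ground-truth sidecar

def write_ground_truth(geometry: IsletGeometry, traces: Optional[CellTraceSet],
                       path: str | Path) -> Path:
    """Structured-text (JSON) ground-truth sidecar."""
    cells = []
    for i in range(geometry.n_cells):
        entry = {
            "id": int(geometry.cell_ids[i]),
            "centroid_um_zyx": [float(v) for v in geometry.centroids[i]],
            "radius_um": float(geometry.radii[i]),
            "compartment": str(geometry.compartment[i]),
            "marker2": bool(geometry.marker2[i]),
        }
        if traces is not None:
            entry.update({
                "responsive": bool(traces.responsive[i]),
                "amplitude": float(traces.amplitude[i]),
                "onset_s": None if np.isnan(traces.onset_time[i])
                else float(traces.onset_time[i]),
            })
        cells.append(entry)
    doc = {
        "islet_radius_um": geometry.islet_radius,
        "islet_centroid_um_zyx": [float(v) for v in geometry.islet_centroid],
        "cells": cells,
        "vessels_um_zyx": [[list(map(float, p)) for p in line]
                           for line in geometry.vessels],
        "coordinate_convention": "um, origin at islet centroid, axes (z,y,x)",
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def read_ground_truth(path: str | Path) -> IsletGeometry:
    doc = json.loads(Path(path).read_text())
    cells = doc["cells"]
    return IsletGeometry(
        cell_ids=np.array([c["id"] for c in cells]),
        centroids=np.array([c["centroid_um_zyx"] for c in cells])
        .reshape(-1, 3),
        radii=np.array([c["radius_um"] for c in cells]),
        compartment=np.array([c["compartment"] for c in cells],
                             dtype=object),
        marker2=np.array([c["marker2"] for c in cells], bool),
        islet_radius=float(doc["islet_radius_um"]),
        islet_centroid=np.array(doc["islet_centroid_um_zyx"]),
        vessels=[np.array(v) for v in doc["vessels_um_zyx"]],
    )
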