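"""Generator: geometry packing, vessels, transients, rendering, secretion."""

import numpy as np
import pytest

from isletquant import (ImagingParams, StagePreset, generate_geometry,
                        generate_vessels, get_preset, render_recording,
                        simulate_secretion, simulate_transients)
from isletquant.synth import IsletGeometry, _transient_shape


def _shell_geometry(outer_r=15.0, inner_r=4.0, n_outer=12, n_inner=4,
                    cell_r=3.5):
    """Two concentric shells of cells (constructed, not sampled)."""
    rng = np.random.default_rng(0)
    pts = []
    for r, n in [(outer_r, n_outer), (inner_r, n_inner)]:
        for _ in range(n):
            u = rng.normal(size=3)
            pts.append(u / np.linalg.norm(u) * r)
    pts = np.array(pts)
    n = len(pts)
    return IsletGeometry(
        cell_ids=np.arange(1, n + 1), centroids=pts,
        radii=np.full(n, cell_r),
        compartment=np.array(["mantle"] * n_outer + ["core"] * n_inner,
                             dtype=object),
        marker2=np.zeros(n, bool), islet_radius=outer_r + cell_r)


# ---------------------------------------------------------------- geometry

def test_cell_count_distribution_matches_preset():
    """Across many seeds the drawn count recovers the preset mean."""
    p = get_preset("wt_48hpf")
    counts = [generate_geometry(p, s).n_cells for s in range(500)]
    sem = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - 21.88) < 2 * sem + 1e-9


def test_single_cell_islet_is_mantle():
    p = StagePreset(name="one", n_cells_mean=1, n_cells_sd=0)
    g = generate_geometry(p, 0)
    assert g.n_cells == 1
    assert g.compartment[0] == "mantle"
    assert np.linalg.norm(g.centroids[0]) <= g.islet_radius


def test_concentric_shells_partition():
    g = _shell_geometry()
    r = np.linalg.norm(g.centroids, axis=1)
    mantle = r >= g.islet_radius - 2 * 3.5
    assert (g.compartment[mantle] == "mantle").all()
    assert (g.compartment[~mantle] == "core").all()


def test_geometry_deterministic_and_nonoverlapping(small_preset):
    g1 = generate_geometry(small_preset, 42)
    g2 = generate_geometry(small_preset, 42)
    assert np.array_equal(g1.centroids, g2.centroids)
    d = np.linalg.norm(g1.centroids[:, None] - g1.centroids[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    # overlap depth at most 10% of the smaller radius
    assert d.min() >= 2 * 3.5 - 0.1 * 3.5 - 1e-9


def test_infeasible_packing_raises():
    p = StagePreset(name="dense", n_cells_mean=200, n_cells_sd=0,
                    beta_fill_frac=1.0)
    with pytest.raises(RuntimeError, match="packing"):
        generate_geometry(p, 0)


# ----------------------------------------------------------------- vessels

def test_vessel_penetration_boundaries(small_preset):
    g = generate_geometry(small_preset, 1)
    R = g.islet_radius
    g0 = generate_vessels(g, 0.0, 2)
    for line in g0.vessels:
        assert np.linalg.norm(line, axis=1).min() >= R * (1 - 1e-6)
    g1 = generate_vessels(g, 1.0, 2)
    deepest = min(np.linalg.norm(v, axis=1).min() for v in g1.vessels)
    assert deepest <= 3.5  # within one cell radius of the centre


def test_vessel_depth_monotone_in_penetration(small_preset):
    g = generate_geometry(small_preset, 1)

    def mean_cell_vessel_dist(pen):
        gv = generate_vessels(g, pen, seed=7)
        dists = []
        for c in gv.centroids:
            dists.append(min(np.linalg.norm(line - c, axis=1).min()
                             for line in gv.vessels))
        return np.mean(dists)

    assert mean_cell_vessel_dist(0.8) < mean_cell_vessel_dist(0.3)


# -------------------------------------------------------------- transients

def test_no_responsive_fraction_gives_flat_traces(small_preset):
    p = StagePreset(name="flat", n_cells_mean=8, n_cells_sd=0,
                    frac_responsive_mantle=0.0, frac_responsive_core=0.0,
                    amp_mean_mantle=1.0, amp_sd_mantle=0.1,
                    amp_mean_core=1.0, amp_sd_core=0.1)
    g = generate_geometry(p, 3)
    t = simulate_transients(g, p, 120.0, 20.0, 5)
    assert not t.responsive.any()
    assert np.allclose(t.F, t.F0[:, None])
    assert (t.amplitude == 0).all()


def test_point_mass_amplitude_reproduced_exactly():
    """A zero-variance amplitude distribution peaks at exactly 145.6%."""
    p = StagePreset(name="pm", n_cells_mean=8, n_cells_sd=0,
                    frac_responsive_mantle=1.0, frac_responsive_core=1.0,
                    amp_mean_mantle=1.456, amp_sd_mantle=0.0,
                    amp_mean_core=1.456, amp_sd_core=0.0)
    g = generate_geometry(p, 3)
    t = simulate_transients(g, p, 220.0, 30.0, 5)
    assert t.responsive.all()
    max_dff = (t.F / t.F0[:, None] - 1.0).max(axis=1)
    assert np.allclose(max_dff, 1.456, atol=1e-9)


def test_amplitude_fidelity_invariant(small_preset):
    """Noise-free sampled max of (F−F0)/F0 equals the drawn amplitude."""
    for seed in (0, 1, 2):
        g = generate_geometry(small_preset, seed)
        t = simulate_transients(g, small_preset, 120.0, 20.0, seed + 10)
        max_dff = (t.F / t.F0[:, None] - 1.0).max(axis=1)
        resp = t.responsive
        assert np.allclose(max_dff[resp], t.amplitude[resp], atol=1e-9)
        assert np.allclose(max_dff[~resp], 0.0, atol=1e-12)


def test_full_synchrony_gives_correlated_neighbors():
    p = StagePreset(name="sync", n_cells_mean=10, n_cells_sd=0,
                    frac_responsive_mantle=1.0, frac_responsive_core=1.0,
                    amp_mean_mantle=1.0, amp_sd_mantle=0.1,
                    amp_mean_core=1.0, amp_sd_core=0.1,
                    sync_group_prob=1.0)
    g = generate_geometry(p, 3)
    t = simulate_transients(g, p, 220.0, 30.0, 5)
    d = np.linalg.norm(g.centroids[:, None] - g.centroids[None], axis=-1)
    neighbor = d <= 1.5 * 2 * 3.5
    for i in range(g.n_cells):
        for j in range(i + 1, g.n_cells):
            if neighbor[i, j] and t.responsive[i] and t.responsive[j]:
                r = np.corrcoef(t.F[i], t.F[j])[0, 1]
                assert r > 0.99


def test_transient_shape_peaks_at_one():
    t = np.arange(0, 300.0)
    s = _transient_shape(t, 40.0, 8.0, 30.0)
    assert s.max() == pytest.approx(1.0)
    assert (s[t <= 40.0] == 0).all()


# --------------------------------------------------------------- rendering

def test_noiseless_rendering_preserves_intensities(small_preset,
                                                   noise_free_params):
    g = generate_geometry(small_preset, 1)
    t = simulate_transients(g, small_preset, 40.0, 20.0, 2)
    rec = render_recording(g, t, noise_free_params, 3)
    # voxel at each cell centre carries the exact trace intensity
    from isletquant.synth import _grid_for
    shape, origin = _grid_for(g, noise_free_params)
    d = np.asarray(noise_free_params.voxel_size)
    for i, c in enumerate(g.centroids):
        vox = np.round((c - origin) / d - 0.5).astype(int)
        np.testing.assert_allclose(rec.voxels[:, vox[0], vox[1], vox[2]],
                                   t.F[i], rtol=1e-9)


def test_frame_averaging_reduces_shot_noise_variance(small_preset):
    """Averaging five exposures cuts the single-exposure variance ~5×."""
    g = generate_geometry(small_preset, 1)
    t = simulate_transients(g, small_preset, 150.0, 140.0, 2)
    var = {}
    for e in (1, 5):
        params = ImagingParams(exposures_per_frame=e, read_noise_sd=0.0,
                               psf_sigma=(1e-12, 1e-12, 1e-12))
        rec = render_recording(g, t, params, 3)
        var[e] = rec.voxels[:, 0, 0, 0].var()   # background corner voxel
    assert var[5] == pytest.approx(var[1] / 5.0, rel=0.35)


def test_bleaching_gives_nonincreasing_intensity(small_preset):
    p = StagePreset(name="nb", n_cells_mean=6, n_cells_sd=0,
                    frac_responsive_mantle=0.0, frac_responsive_core=0.0,
                    amp_mean_mantle=1.0, amp_sd_mantle=0.0,
                    amp_mean_core=1.0, amp_sd_core=0.0)
    g = generate_geometry(p, 1)
    t = simulate_transients(g, p, 120.0, 110.0, 2)
    params = ImagingParams(bleach_rate=0.01)
    rec = render_recording(g, t, params, 3)
    mean_t = rec.voxels.reshape(rec.n_frames, -1).mean(axis=1)
    slope = np.polyfit(np.arange(rec.n_frames), mean_t, 1)[0]
    assert slope < 0


def test_rendering_deterministic(small_preset, fast_params):
    g = generate_geometry(small_preset, 1)
    t = simulate_transients(g, small_preset, 40.0, 20.0, 2)
    r1 = render_recording(g, t, fast_params, 9)
    r2 = render_recording(g, t, fast_params, 9)
    assert np.array_equal(r1.voxels, r2.voxels)


def test_field_of_view_overflow_raises(small_preset):
    g = generate_geometry(small_preset, 1)
    t = simulate_transients(g, small_preset, 40.0, 20.0, 2)
    params = ImagingParams(n_planes=2)
    with pytest.raises(ValueError, match="overflow"):
        render_recording(g, t, params, 3)


# --------------------------------------------------------------- secretion

def test_secretion_point_mass_gsi():
    p = StagePreset(name="s", secretion_low_mean=1.0, secretion_low_sd=0.0,
                    secretion_high_mean=5.0, secretion_high_sd=0.0)
    recs = simulate_secretion(p, 10, 1)
    assert all(r.gsi == pytest.approx(5.0) for r in recs)


def test_secretion_draws_nonnegative():
    p = StagePreset(name="n", secretion_low_mean=0.1, secretion_low_sd=2.0,
                    secretion_high_mean=0.5, secretion_high_sd=3.0)
    recs = simulate_secretion(p, 300, 7)
    assert all(r.low_secretion >= 0 and r.high_secretion >= 0 for r in recs)


def test_secretion_requires_parameters(small_preset):
    with pytest.raises(ValueError):
        simulate_secretion(small_preset, 5, 1)
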