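"""End-to-end convenience: simulate → render → detect → extract →
classify → stratify, returning tidy per-cell calls.

This is the recovery loop used to validate the whole pipeline: islets are
generated from a stage preset with known ground truth, imaged through the
forward model, and re-quantified blind; the recovered per-islet statistics
should match the preset's population parameters within sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import CalciumRecording, ROISet
from .presets import StagePreset
from .segment import DetectionResult, MatchResult, detect_cells, match_rois
from .spatial import classify_mantle_core, vessel_proximity
from .synth import (CellTraceSet, ImagingParams, IsletGeometry, _grid_for,
                    generate_geometry, generate_vessels, geometry_rois,
                    render_recording, simulate_transients)
from .traces import classify_responsive, dff, extract_traces

__all__ = ["IsletAnalysis", "islet_seeds", "simulate_islet",
           "analyze_recording", "run_islet", "run_condition"]

DEFAULT_DURATION = 220.0     # s: 30 s baseline + the 180 s response window
DEFAULT_STIM = 30.0          # s
EXPECTED_DIAMETER = 7.0      # μm, β-cell diameter


@dataclass
class IsletAnalysis:
    islet_id: int
    geometry: IsletGeometry
    truth: CellTraceSet
    recording: CalciumRecording
    detection: DetectionResult
    calls: pd.DataFrame          # per detected cell
    match: MatchResult           # detected ↔ ground truth


def islet_seeds(base_seed: int, islet_index: int, n: int = 3) -> list[int]:
    """Independent per-stage integer seeds for one islet replicate."""
    ss = np.random.SeedSequence([int(base_seed), int(islet_index)])
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def simulate_islet(preset: StagePreset, seed: int,
                   params: Optional[ImagingParams] = None,
                   duration: float = DEFAULT_DURATION,
                   stim_time: float = DEFAULT_STIM,
                   ) -> tuple[IsletGeometry, CellTraceSet, CalciumRecording]:
    """Generate one ground-truthed islet and its rendered recording."""
    params = params or ImagingParams()
    g_seed, t_seed, r_seed = islet_seeds(seed, 0)
    geometry = generate_geometry(preset, g_seed)
    if preset.vessel_penetration is not None:
        geometry = generate_vessels(geometry, preset.vessel_penetration,
                                    g_seed + 1)
    truth = simulate_transients(geometry, preset, duration, stim_time,
                                t_seed, frame_interval=params.frame_interval)
    recording = render_recording(geometry, truth, params, r_seed)
    return geometry, truth, recording


def analyze_recording(recording: CalciumRecording,
                      rois: Optional[ROISet] = None,
                      expected_diameter: float = EXPECTED_DIAMETER,
                      dff_mode: str = "first_frame",
                      extraction_shrink: float = 0.8
                      ) -> tuple[DetectionResult, pd.DataFrame]:
    """Detect cells (unless ROIs are given), extract ΔF/F0, call
    responsiveness and stratify mantle/core.

    ``extraction_shrink`` shrinks each ROI radius for trace extraction to
    limit rim/background dilution and neighbour bleed-through.
    """
    if rois is None:
        detection = detect_cells(recording, expected_diameter)
    else:
        detection = DetectionResult(rois, np.zeros(len(rois)))
    roiset = detection.rois
    d = recording.voxel_size
    # fixed-size extraction spheres centred on the detections
    r_extract = extraction_shrink * (expected_diameter / 2.0) / d[2]
    from .io import ROI
    ext = ROISet(rois=[ROI(r.id, r.centroid, r_extract)
                       for r in roiset.rois]) \
        if roiset.rois is not None else roiset
    trs = extract_traces(recording, ext)
    comp = {c.cell_id: c for c in classify_mantle_core(
        roiset, d, cell_radius=expected_diameter / 2.0)}
    rows = []
    for tr in trs:
        call = classify_responsive(dff(tr, dff_mode, recording.stim_time),
                                   recording.stim_time)
        rows.append({
            "cell_id": call.cell_id,
            "compartment": comp[call.cell_id].compartment,
            "surface_distance": comp[call.cell_id].surface_distance,
            "max_dff": call.max_dff,
            "responsive": call.responsive,
            "time_to_peak": call.time_to_peak,
            "baseline_sd": call.baseline_sd,
        })
    return detection, pd.DataFrame(rows)


def run_islet(preset: StagePreset, seed: int, islet_id: int = 1,
              params: Optional[ImagingParams] = None,
              duration: float = DEFAULT_DURATION,
              stim_time: float = DEFAULT_STIM,
              use_truth_rois: bool = False) -> IsletAnalysis:
    """Simulate one islet and quantify it blind; attach ground truth."""
    params = params or ImagingParams()
    geometry, truth, recording = simulate_islet(
        preset, seed, params, duration, stim_time)
    truth_rois = geometry_rois(geometry, params)
    detection, calls = analyze_recording(
        recording, rois=truth_rois if use_truth_rois else None)
    calls.insert(0, "islet_id", islet_id)
    calls["condition"] = preset.name

    # vessel proximity of the detected cells, in the physical frame
    if geometry.vessels:
        _, origin = _grid_for(geometry, params)
        dvox = np.asarray(params.voxel_size)
        cents_um = detection.rois.centroids() * dvox + origin + 0.5 * dvox
        shifted = ROISet(rois=[
            type(r)(r.id, tuple(c), r.radius)
            for r, c in zip(detection.rois.rois, cents_um)])
        prox = {c.cell_id: c.vessel_proximal
                for c in vessel_proximity(shifted, geometry.vessels)}
        calls["vessel_proximal"] = calls.cell_id.map(prox)
    else:
        calls["vessel_proximal"] = False

    match = match_rois(detection.rois, truth_rois,
                       max_dist=EXPECTED_DIAMETER / 2.0,
                       scale=params.voxel_size)
    return IsletAnalysis(islet_id=islet_id, geometry=geometry, truth=truth,
                         recording=recording, detection=detection,
                         calls=calls, match=match)


def run_condition(preset: StagePreset, n_islets: int, base_seed: int = 1,
                  params: Optional[ImagingParams] = None,
                  **kwargs) -> pd.DataFrame:
    """Run the full pipeline over replicate islets; concatenated calls.

    Replicate ``k`` uses the deterministic seed stream
    ``SeedSequence([base_seed, k])``.
    """
    frames = []
    for k in range(1, n_islets + 1):
        res = run_islet(preset, seed=islet_seeds(base_seed, k, 1)[0],
                        islet_id=k, params=params, **kwargs)
        frames.append(res.calls)
    return pd.concat(frames, ignore_index=True)
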