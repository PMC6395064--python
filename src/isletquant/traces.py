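"""Per-cell trace extraction, ΔF/F0, responsiveness calls and synchrony.

ΔF/F0 follows the field convention: ΔF = F(t) − F0 with F0 the intensity
at the first time point (``first_frame`` mode).  A ``prestim_mean`` mode is
provided because a single-frame F0 is sensitive to noise.  The functional
readout per cell is Max ΔF/F0 over the post-stimulus window; a cell is
glucose-responsive when that maximum clears both an absolute floor and a
multiple of its baseline noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import CalciumRecording, ROISet, rois_to_labels

__all__ = ["Trace", "ResponseCall", "SynchronyGraph", "extract_traces",
           "dff", "classify_responsive", "synchrony"]

#: default responsiveness criterion: Max ΔF/F0 ≥ max(ABS_FLOOR, K_SIGMA·σ)
ABS_FLOOR = 0.20
K_SIGMA = 5.0
WINDOW_S = 180.0          # response expected within 3 min of stimulation


@dataclass
class Trace:
    cell_id: int
    F: np.ndarray                   # intensity per frame, a.u.
    frame_interval: float = 1.0     # s
    F0: Optional[float] = None
    dff: Optional[np.ndarray] = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.F)) * self.frame_interval


@dataclass
class ResponseCall:
    cell_id: int
    max_dff: float                  # dimensionless (1.50 = 150%)
    time_to_peak: float             # s after stimulus
    responsive: bool
    baseline_sd: float
    compartment: str = ""
    vessel_proximal: Optional[bool] = None


@dataclass
class SynchronyGraph:
    nodes: list[int]
    edges: list[tuple[int, int, float, float]]   # (i, j, r, lag_s)
    groups: list[set[int]]                       # synchronized components


def extract_traces(recording: CalciumRecording, rois: ROISet
                   ) -> list[Trace]:
    """Mean-intensity trace over each ROI's voxels, per frame."""
    dz, dy, dx = recording.voxel_size
    shape = recording.voxels.shape[1:]
    labels = rois.labels if rois.labels is not None else \
        rois_to_labels(rois, shape, z_scale=dz / dx).labels
    if labels.shape != shape:
        raise ValueError("ROI space does not match recording volume")
    vox = recording.voxels.reshape(recording.n_frames, -1)
    flat = labels.ravel()
    traces = []
    for i in rois.ids:
        idx = np.flatnonzero(flat == i)
        if idx.size == 0:
            raise ValueError(f"ROI {i} covers zero voxels")
        traces.append(Trace(cell_id=int(i), F=vox[:, idx].mean(axis=1),
                            frame_interval=recording.frame_interval))
    return traces


def dff(trace: Trace, mode: str = "first_frame",
        stim_time: Optional[float] = None) -> Trace:
    """Populate ΔF/F0 = (F − F0)/F0.

    ``first_frame`` (the field default) takes F0 = F[0]; ``prestim_mean``
    averages all frames before ``stim_time``.
    """
    if mode == "first_frame":
        f0 = float(trace.F[0])
    elif mode == "prestim_mean":
        if stim_time is None:
            raise ValueError("prestim_mean mode needs stim_time")
        n_pre = int(np.floor(stim_time / trace.frame_interval))
        if n_pre < 1:
            raise ValueError("no pre-stimulus frames for prestim_mean F0")
        f0 = float(trace.F[:n_pre].mean())
    else:
        raise ValueError(f"unknown dff mode {mode!r}")
    if f0 <= 0:
        raise ValueError(f"non-positive F0 ({f0}) for cell {trace.cell_id}")
    trace.F0 = f0
    trace.dff = (trace.F - f0) / f0
    return trace


def classify_responsive(trace: Trace, stim_time: float,
                        window: float = WINDOW_S,
                        abs_floor: float = ABS_FLOOR,
                        k_sigma: float = K_SIGMA) -> ResponseCall:
    """Call a cell glucose-responsive from its post-stimulus Max ΔF/F0.

    ``responsive ⇔ max_dff ≥ max(abs_floor, k_sigma × baseline_sd)`` with
    baseline_sd the SD of ΔF/F0 before the stimulus.  The threshold is
    inclusive; the peak time is the first frame attaining the maximum.
    """
    if trace.dff is None:
        raise ValueError("trace has no dff; call dff() first")
    t = trace.times
    post = (t >= stim_time) & (t <= stim_time + window)
    if not post.any():
        raise ValueError("no post-stimulus frames inside the window")
    pre = t < stim_time
    baseline_sd = float(trace.dff[pre].std()) if pre.sum() >= 2 else 0.0
    seg = trace.dff[post]
    k = int(np.argmax(seg))                 # first frame achieving the max
    max_dff = float(seg[k])
    t_peak = float(t[post][k] - stim_time)
    thr = max(abs_floor, k_sigma * baseline_sd)
    return ResponseCall(
        cell_id=trace.cell_id, max_dff=max_dff, time_to_peak=t_peak,
        responsive=bool(max_dff >= thr), baseline_sd=baseline_sd)


def synchrony(traces: list[Trace], rois: ROISet, stim_time: float,
              neighbor_dist: Optional[float] = None,
              r_min: float = 0.7, max_lag_frames: int = 2,
              voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
              ) -> SynchronyGraph:
    """Pairwise synchrony of neighbouring cells' post-stimulus ΔF/F0.

    Neighbours are centroid pairs within ``neighbor_dist`` (default 1.5×
    the mean cell diameter); an edge is synchronized when the Pearson r of
    the post-stimulus ΔF/F0 is ≥ ``r_min`` and the peak-time lag is within
    ``max_lag_frames``.  Groups are connected components of synchronized
    edges.
    """
    if len(traces) < 2:
        raise ValueError("need at least two traces")
    d = np.asarray(voxel_size)
    cents = rois.centroids() * d
    radii = rois.radii() * d[2]
    if neighbor_dist is None:
        neighbor_dist = 1.5 * 2.0 * float(radii.mean())
    id_to_pos = {i: k for k, i in enumerate(rois.ids)}
    fi = traces[0].frame_interval
    post = traces[0].times >= stim_time

    nodes = [t.cell_id for t in traces]
    edges = []
    adj: dict[int, set[int]] = {i: set() for i in nodes}
    for a in range(len(traces)):
        for b in range(a + 1, len(traces)):
            ta, tb = traces[a], traces[b]
            ca = cents[id_to_pos[ta.cell_id]]
            cb = cents[id_to_pos[tb.cell_id]]
            if np.linalg.norm(ca - cb) > neighbor_dist:
                continue
            xa, xb = ta.dff[post], tb.dff[post]
            if xa.std() == 0 or xb.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(xa, xb)[0, 1])
            lag = (int(np.argmax(xa)) - int(np.argmax(xb))) * fi
            edges.append((ta.cell_id, tb.cell_id, r, lag))
            if r >= r_min and abs(lag) <= max_lag_frames * fi:
                adj[ta.cell_id].add(tb.cell_id)
                adj[tb.cell_id].add(ta.cell_id)

    groups, seen = [], set()
    for start in nodes:
        if start in seen or not adj[start]:
            continue
        comp, stack = set(), [start]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        groups.append(comp)
    return SynchronyGraph(nodes=nodes, edges=edges, groups=groups)
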