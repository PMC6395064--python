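"""β-cell detection in the time-averaged basal volume.

The calcium indicator is bright at resting calcium, so every β-cell is
visible before stimulation; detection therefore runs on the average of the
pre-stimulus frames.  Cells are found by multi-scale Laplacian-of-Gaussian
filtering with per-axis sigmas (anisotropy-corrected for the coarse z
sampling), touching cells are split by marker-based watershed, and
centroids are refined by intensity weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .io import CalciumRecording, ROI, ROISet

__all__ = ["DetectionResult", "MatchResult", "detect_cells", "match_rois",
           "colocalize"]


@dataclass
class DetectionResult:
    rois: ROISet
    scores: np.ndarray          # per-ROI LoG response (dimensionless)

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.rois):
            raise ValueError("scores must match rois")


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]        # (detected id, truth id)
    unmatched_detected: list[int]
    unmatched_truth: list[int]
    distances: np.ndarray               # μm (or voxels), per pair

    @property
    def precision(self) -> float:
        n_det = len(self.pairs) + len(self.unmatched_detected)
        return len(self.pairs) / n_det if n_det else 0.0

    @property
    def recall(self) -> float:
        n_truth = len(self.pairs) + len(self.unmatched_truth)
        return len(self.pairs) / n_truth if n_truth else 0.0


def _log_response(volume: np.ndarray, sigma_vox: tuple[float, ...]
                  ) -> np.ndarray:
    # scale-normalised negative LoG: bright blobs give positive peaks
    s2 = float(np.mean([s * s for s in sigma_vox]))
    return -s2 * ndimage.gaussian_laplace(volume, sigma_vox)


def detect_cells(recording: CalciumRecording, expected_diameter: float,
                 scale_factors: tuple[float, ...] = (0.8, 1.0, 1.25),
                 min_separation_factor: float = 0.7,
                 threshold_rel: float = 0.25) -> DetectionResult:
    """Detect cell-sized blobs in the pre-stimulus average volume.

    Detection is invariant to global intensity scaling: the volume is
    normalised to its mean before filtering, and all thresholds are
    relative.  Returns centroid+radius ROIs in voxel coordinates, with
    centroids refined by intensity-weighted averaging over the watershed
    region and radii from the equivalent-sphere volume.
    """
    stim_frame = recording.stim_frame
    if stim_frame < 1:
        raise ValueError("recording has no pre-stimulus frames")
    basal = recording.voxels[:stim_frame].mean(axis=0)
    mean = basal.mean()
    if mean <= 0:
        raise ValueError("empty volume")
    vol = basal / mean

    d = np.asarray(recording.voxel_size, float)     # (dz, dy, dx) μm
    r_um = expected_diameter / 2.0
    responses = []
    for f in scale_factors:
        sigma_um = f * r_um / np.sqrt(3.0)
        sigma_vox = tuple(sigma_um / d)
        responses.append(_log_response(vol, sigma_vox))
    response = np.max(responses, axis=0)

    # minimum peak separation, anisotropy-aware (ellipsoidal footprint)
    sep_um = min_separation_factor * expected_diameter
    foot_r = np.maximum((sep_um / 2.0) / d, 1).astype(int)
    zz, yy, xx = np.indices(2 * foot_r + 1) - foot_r[:, None, None, None]
    footprint = ((zz / max(foot_r[0], 1e-9)) ** 2
                 + (yy / foot_r[1]) ** 2
                 + (xx / foot_r[2]) ** 2) <= 1.0

    peaks = peak_local_max(
        response, footprint=footprint,
        threshold_abs=threshold_rel * response.max(),
        exclude_border=False)
    if len(peaks) == 0:
        return DetectionResult(ROISet(rois=[]), np.zeros(0))
    # deterministic order: by response desc, then linear index asc
    lin = np.ravel_multi_index(peaks.T, response.shape)
    resp_at = response[tuple(peaks.T)]
    order = np.lexsort((lin, -resp_at))
    peaks = peaks[order]
    lin = lin[order]

    # watershed assignment of foreground voxels to markers
    smooth = ndimage.gaussian_filter(vol, tuple((r_um / 2.0) / d))
    mask = smooth > threshold_otsu(smooth)
    markers = np.zeros(vol.shape, int)
    for k, p in enumerate(peaks, start=1):
        markers[tuple(p)] = k
    labels = watershed(-smooth, markers, mask=mask)

    voxel_volume = float(np.prod(d))
    rois, scores = [], []
    for k, p in enumerate(peaks, start=1):
        region = labels == k
        n_vox = int(region.sum())
        if n_vox == 0:
            continue
        w = np.clip(vol[region] - vol[~mask].mean() if (~mask).any()
                    else vol[region], 1e-9, None)
        coords = np.argwhere(region)
        centroid = (coords * w[:, None]).sum(0) / w.sum()
        r_eq_um = (3.0 * n_vox * voxel_volume / (4.0 * np.pi)) ** (1 / 3)
        rois.append(ROI(len(rois) + 1, tuple(centroid),
                        float(r_eq_um / d[2])))
        scores.append(response[tuple(p)])
    return DetectionResult(ROISet(rois=rois), np.array(scores))


def match_rois(detected: ROISet, truth: ROISet, max_dist: float,
               scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
               ) -> MatchResult:
    """Optimal one-to-one centroid assignment within ``max_dist``.

    Pairs minimise the total distance (Hungarian algorithm); ``scale``
    converts per-axis voxel coordinates to a common metric (e.g. μm).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    det_c = detected.centroids() * np.asarray(scale)
    tru_c = truth.centroids() * np.asarray(scale)
    det_ids, tru_ids = detected.ids, truth.ids
    if len(det_c) == 0 or len(tru_c) == 0:
        return MatchResult([], list(det_ids), list(tru_ids), np.zeros(0))
    dist = np.linalg.norm(det_c[:, None] - tru_c[None], axis=-1)
    big = max_dist * 1e6
    cost = np.where(dist <= max_dist, dist, big)
    ri, ci = linear_sum_assignment(cost)
    pairs, dists = [], []
    matched_d, matched_t = set(), set()
    for i, j in zip(ri, ci):
        if dist[i, j] <= max_dist:
            pairs.append((det_ids[i], tru_ids[j]))
            dists.append(dist[i, j])
            matched_d.add(det_ids[i])
            matched_t.add(tru_ids[j])
    return MatchResult(
        pairs=pairs,
        unmatched_detected=[i for i in det_ids if i not in matched_d],
        unmatched_truth=[j for j in tru_ids if j not in matched_t],
        distances=np.array(dists))


def colocalize(primary_rois: ROISet, second_channel: np.ndarray,
               k: float = 3.0, z_scale: float = 1.0) -> float:
    """Fraction of primary ROIs positive in the second channel.

    An ROI co-expresses when its mean second-channel intensity exceeds the
    background mean + ``k``·SD, background being all voxels outside every
    ROI.  ``z_scale`` is the z/x voxel-size ratio used when rasterising
    centroid ROIs.
    """
    if len(primary_rois) == 0:
        raise ValueError("no primary ROIs")
    vol = np.asarray(second_channel, float)
    if primary_rois.labels is not None:
        labels = primary_rois.labels
    else:
        from .io import rois_to_labels
        labels = rois_to_labels(primary_rois, vol.shape, z_scale).labels
    if labels.shape != vol.shape:
        raise ValueError("channel volume shape does not match ROI space")
    bg = vol[labels == 0]
    thresh = bg.mean() + k * bg.std()
    ids = primary_rois.ids
    positive = 0
    for i in ids:
        m = labels == i
        if m.any() and vol[m].mean() > thresh:
            positive += 1
    return positive / len(ids)
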