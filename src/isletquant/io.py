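"""On-disk artifacts: TIFF recordings with metadata sidecars, ROI sets,
and per-cell response-call CSV tables.

Conventions (also written into every sidecar):

* voxel indices are 0-based; arrays are ordered T×Z×Y×X;
* physical coordinates are μm with the origin at the volume corner, ordered
  (z, y, x) to match the array axes;
* TIFF pages are T-major (all Z planes of frame 0, then frame 1, …),
  16-bit unsigned;
* data files are byte-for-byte deterministic: no timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger("isletquant")

CALLS_HEADER = ["id", "compartment", "max_dff", "responsive",
                "time_to_peak", "vessel_proximal"]

COORD_NOTE = ("voxel indices 0-based; physical coordinates um, origin at "
              "volume corner, axis order (z, y, x); TIFF pages T-major then Z")


# --------------------------------------------------------------------------
# domain types

@dataclass
class CalciumRecording:
    """A voxel time-series (T×Z×Y×X) plus acquisition metadata."""

    voxels: np.ndarray                  # T×Z×Y×X, intensity (a.u.)
    voxel_size: tuple[float, float, float]   # μm, (z, y, x)
    frame_interval: float               # s
    stim_time: float                    # s, glucose onset
    n_planes: int

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be T x Z x Y x X")
        if self.voxels.shape[0] < 2:
            raise ValueError("recording needs T >= 2 frames")
        if self.voxels.shape[1] != self.n_planes:
            raise ValueError(
                f"n_planes={self.n_planes} but volume has "
                f"{self.voxels.shape[1]} planes")
        dur = self.voxels.shape[0] * self.frame_interval
        if not (0.0 <= self.stim_time < dur):
            raise ValueError(f"stim_time {self.stim_time} outside [0, {dur})")
        if np.any(self.voxels < 0):
            raise ValueError("negative intensities")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def stim_frame(self) -> int:
        return int(np.ceil(self.stim_time / self.frame_interval))


@dataclass
class ROI:
    id: int
    centroid: tuple[float, float, float]   # voxel coordinates, (z, y, x)
    radius: float                          # voxels (lateral scale)


@dataclass
class ROISet:
    """Either a centroid+radius list or a dense integer label volume."""

    rois: Optional[list[ROI]] = None
    labels: Optional[np.ndarray] = None     # Z×Y×X, 0 = background

    def __post_init__(self) -> None:
        if (self.rois is None) == (self.labels is None):
            raise ValueError("provide exactly one of rois / labels")
        if self.rois is not None:
            ids = [r.id for r in self.rois]
            if len(ids) != len(set(ids)):
                raise ValueError("duplicate ROI ids")
        else:
            self.labels = np.asarray(self.labels)
            if self.labels.ndim != 3 or np.any(self.labels < 0):
                raise ValueError("labels must be a non-negative Z x Y x X volume")

    def __len__(self) -> int:
        if self.rois is not None:
            return len(self.rois)
        return int(len(np.unique(self.labels[self.labels > 0])))

    @property
    def ids(self) -> list[int]:
        if self.rois is not None:
            return [r.id for r in self.rois]
        return [int(v) for v in np.unique(self.labels[self.labels > 0])]

    def centroids(self) -> np.ndarray:
        """N×3 centroid array in voxel coordinates (z, y, x)."""
        if self.rois is not None:
            return np.array([r.centroid for r in self.rois], float).reshape(-1, 3)
        from scipy import ndimage
        ids = self.ids
        if not ids:
            return np.empty((0, 3))
        return np.array(ndimage.center_of_mass(
            self.labels > 0, self.labels, ids), float)

    def radii(self) -> np.ndarray:
        if self.rois is not None:
            return np.array([r.radius for r in self.rois], float)
        counts = np.array([(self.labels == i).sum() for i in self.ids], float)
        return np.cbrt(3.0 * counts / (4.0 * np.pi))


# --------------------------------------------------------------------------
# recordings

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: CalciumRecording, path: str | Path) -> Path:
    """Write a multi-page TIFF (T-major then Z, uint16) plus JSON sidecar."""
    path = Path(path)
    vox = rec.voxels
    if vox.max() > 65535:
        log.warning("intensity %.0f exceeds 16-bit range; saturating", vox.max())
    pages = np.clip(np.round(vox), 0, 65535).astype(np.uint16)
    t, z, y, x = pages.shape
    tifffile.imwrite(path, pages.reshape(t * z, y, x))
    meta = {
        "voxel_size_um_zyx": list(rec.voxel_size),
        "frame_interval_s": rec.frame_interval,
        "stim_time_s": rec.stim_time,
        "n_planes": rec.n_planes,
        "n_frames": t,
        "coordinate_convention": COORD_NOTE,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_recording(path: str | Path) -> CalciumRecording:
    """Read a TIFF + sidecar pair, validating page count against metadata."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_planes = int(meta["n_planes"])
    if pages.shape[0] % n_planes:
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages, not a multiple of "
            f"n_planes={n_planes}")
    t = pages.shape[0] // n_planes
    if "n_frames" in meta and int(meta["n_frames"]) != t:
        raise ValueError(
            f"sidecar n_frames={meta['n_frames']} but TIFF implies T={t}")
    return CalciumRecording(
        voxels=pages.reshape(t, n_planes, *pages.shape[1:]).astype(float),
        voxel_size=tuple(meta["voxel_size_um_zyx"]),
        frame_interval=float(meta["frame_interval_s"]),
        stim_time=float(meta["stim_time_s"]),
        n_planes=n_planes,
    )


# --------------------------------------------------------------------------
# ROI sets

def write_roiset(roiset: ROISet, path: str | Path) -> Path:
    """Write an ROI set as structured text.

    Centroid dialect: TSV with header ``id z y x radius`` (voxel units).
    Label dialect: one header line ``labels <Z> <Y> <X>`` followed by the
    flattened volume as whitespace-separated integers.
    """
    path = Path(path)
    if roiset.rois is not None:
        lines = ["id\tz\ty\tx\tradius"]
        for r in roiset.rois:
            cz, cy, cx = r.centroid
            lines.append(f"{r.id}\t{cz:.6g}\t{cy:.6g}\t{cx:.6g}\t{r.radius:.6g}")
        path.write_text("\n".join(lines) + "\n")
    else:
        lab = roiset.labels
        header = f"labels {lab.shape[0]} {lab.shape[1]} {lab.shape[2]}"
        body = " ".join(map(str, lab.ravel().tolist()))
        path.write_text(header + "\n" + body + "\n")
    return path


def read_roiset(path: str | Path) -> ROISet:
    path = Path(path)
    text = path.read_text()
    first = text.split("\n", 1)[0]
    if first.startswith("labels"):
        header, body = text.split("\n", 1)
        _, z, y, x = header.split()
        lab = np.array(body.split(), dtype=int).reshape(int(z), int(y), int(x))
        return ROISet(labels=lab)
    rois: list[ROI] = []
    for line in text.strip().splitlines()[1:]:
        i, cz, cy, cx, r = line.split("\t")
        rois.append(ROI(int(i), (float(cz), float(cy), float(cx)), float(r)))
    return ROISet(rois=rois)


def rois_to_labels(roiset: ROISet, shape: tuple[int, int, int],
                   z_scale: float = 1.0) -> ROISet:
    """Rasterize centroid+radius ROIs into a label volume.

    ``z_scale`` is the z/x voxel-size ratio so spheres stay spherical in
    physical space; later ids win ties (ids are unique so overlap is rare).
    """
    if roiset.rois is None:
        return roiset
    lab = np.zeros(shape, dtype=int)
    zz, yy, xx = np.indices(shape)
    for r in roiset.rois:
        cz, cy, cx = r.centroid
        d2 = ((zz - cz) * z_scale) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        lab[d2 <= r.radius ** 2] = r.id
    return ROISet(labels=lab)


def labels_to_rois(roiset: ROISet) -> ROISet:
    """Centroids-of-mass + equivalent-sphere radii from a label volume."""
    if roiset.labels is None:
        return roiset
    cents = roiset.centroids()
    radii = roiset.radii()
    rois = [ROI(int(i), tuple(c), float(r))
            for i, c, r in zip(roiset.ids, cents, radii)]
    return ROISet(rois=rois)


# --------------------------------------------------------------------------
# response-call tables

def write_calls(calls: Sequence, path: str | Path) -> Path:
    """Write per-cell response calls as CSV with a fixed header."""
    rows = []
    for c in calls:
        rows.append({
            "id": c.cell_id,
            "compartment": getattr(c, "compartment", ""),
            "max_dff": getattr(c, "max_dff", np.nan),
            "responsive": bool(getattr(c, "responsive", False)),
            "time_to_peak": getattr(c, "time_to_peak", np.nan),
            "vessel_proximal": getattr(c, "vessel_proximal", ""),
        })
    df = pd.DataFrame(rows, columns=CALLS_HEADER)
    df.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != CALLS_HEADER:
        raise ValueError(f"unexpected calls header {list(df.columns)}")
    return df
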