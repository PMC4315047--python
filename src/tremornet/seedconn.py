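"""Seed-based functional connectivity with spherical ROIs.

A seed is a 6-mm-radius sphere (configurable) around a peak coordinate
in mm space; its mean time series is correlated with every other in-mask
voxel and the map is variance-stabilised with Fisher's r-to-z transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preproc import BoldRun

logger = logging.getLogger(__name__)

__all__ = [
    "SphereRoi",
    "FcMap",
    "make_sphere_roi",
    "extract_roi_timeseries",
    "seed_fc_map",
    "roi_overlap",
    "drop_overlapping_rois",
]

R_CLIP = 1.0 - 1e-7  # |r| ceiling applied before arctanh so z stays finite


@dataclass
class SphereRoi:
    """Sphere ROI: all in-mask voxels whose centres lie within
    ``radius_mm`` of ``center_mm`` (centre-to-centre Euclidean distance)."""

    center_mm: np.ndarray
    radius_mm: float
    voxel_set: np.ndarray  # (k, 3) int voxel indices
    name: str = ""

    def __post_init__(self) -> None:
        self.voxel_set = np.atleast_2d(np.asarray(self.voxel_set, dtype=int))
        if self.voxel_set.size == 0:
            raise ValueError(f"ROI {self.name or self.center_mm} has no member voxels")

    @property
    def n_voxels(self) -> int:
        return self.voxel_set.shape[0]


@dataclass
class FcMap:
    """Seed-to-voxel Fisher-z connectivity map (finite everywhere)."""

    z_values: np.ndarray
    seed: SphereRoi
    mask: np.ndarray
    n_flagged: int = 0  # constant voxels whose z was set to 0

    def masked_values(self) -> np.ndarray:
        return self.z_values[self.mask]


def make_sphere_roi(
    center_mm,
    radius_mm: float,
    mask: np.ndarray,
    affine: np.ndarray,
    name: str = "",
) -> SphereRoi:
    """Build a sphere ROI on the grid defined by ``affine``.

    Raises if the sphere intersects no in-mask voxel.
    """
    center_mm = np.asarray(center_mm, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    affine = np.asarray(affine, dtype=float)
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    ijk = np.argwhere(mask)
    centers = ijk @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(centers - center_mm, axis=1)
    inside = dist <= radius_mm + 1e-9
    if not inside.any():
        raise ValueError(f"sphere at {center_mm.tolist()} mm (r={radius_mm}) contains no in-mask voxel")
    return SphereRoi(center_mm=center_mm, radius_mm=radius_mm, voxel_set=ijk[inside], name=name)


def extract_roi_timeseries(run: BoldRun, roi: SphereRoi) -> np.ndarray:
    """Unweighted mean series over the ROI's member voxels."""
    i, j, k = roi.voxel_set.T
    shape = run.data.shape[:3]
    if (i >= shape[0]).any() or (j >= shape[1]).any() or (k >= shape[2]).any():
        raise ValueError("ROI voxels outside the run grid")
    return run.data[i, j, k].mean(axis=0)


def seed_fc_map(run: BoldRun, roi: SphereRoi, mask: np.ndarray | None = None) -> FcMap:
    """Correlate the ROI mean series with every in-mask voxel and apply
    Fisher's r-to-z (r clipped to +/-(1 - 1e-7) first).

    Constant voxel series get z = 0 and are counted in ``n_flagged``.
    """
    mask = np.asarray(run.mask if mask is None else mask, dtype=bool)
    seed_ts = extract_roi_timeseries(run, roi)
    if seed_ts.std() == 0:
        raise ValueError("ROI mean series is constant")
    series = run.data[mask]
    x = series - series.mean(axis=1, keepdims=True)
    s = seed_ts - seed_ts.mean()
    norms = np.linalg.norm(x, axis=1)
    flagged = norms == 0
    norms[flagged] = 1.0
    r = (x @ s) / (norms * np.linalg.norm(s))
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    z[flagged] = 0.0
    if flagged.any():
        logger.warning("seed_fc_map: %d constant voxel(s) flagged, z set to 0", int(flagged.sum()))
    out = np.zeros(mask.shape)
    out[mask] = z
    return FcMap(z_values=out, seed=roi, mask=mask, n_flagged=int(flagged.sum()))


def roi_overlap(a: SphereRoi, b: SphereRoi) -> int:
    """Number of voxels shared by two ROIs."""
    sa = {tuple(v) for v in a.voxel_set}
    return sum(tuple(v) in sa for v in b.voxel_set)


def drop_overlapping_rois(rois: list[SphereRoi]) -> list[SphereRoi]:
    """Greedy spatial-overlap exclusion: walk the list in order and drop
    any ROI sharing at least one voxel with an earlier kept ROI."""
    kept: list[SphereRoi] = []
    for roi in rois:
        if any(roi_overlap(prev, roi) > 0 for prev in kept):
            logger.info("dropping ROI %s: overlaps an earlier seed", roi.name or roi.center_mm)
            continue
        kept.append(roi)
    return kept
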