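"""Voxel-wise weighted degree centrality (WDC).

For grey-matter voxel i the centrality is the sum of its Pearson
correlations with every other grey-matter voxel,

    S_i = sum_{j != i} r_ij,

restricted to positive correlations surviving a Bonferroni-corrected
significance floor; sub-threshold and negative correlations contribute 0.
The self term (r_ii = 1) is excluded.  The correlation matrix is never
materialised in full: rows are processed in blocks so memory stays
bounded on large masks.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preproc import BoldRun

logger = logging.getLogger(__name__)

__all__ = ["CentralityMap", "bonferroni_r_threshold", "wdc_from_series", "compute_wdc_map"]


@dataclass
class CentralityMap:
    """Per-voxel weighted degree centrality.

    ``values`` is a 3D map, defined (and non-negative) inside ``mask``,
    zero outside.  ``r_threshold`` and ``n_voxels`` record the
    significance floor and the N used.
    """

    values: np.ndarray
    mask: np.ndarray
    r_threshold: float
    n_voxels: int

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def bonferroni_r_threshold(alpha: float, n_tests: int, n_timepoints: int) -> float:
    """Minimal |r| whose two-sided Pearson p-value (t transform,
    df = n_timepoints - 2) is <= alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if n_timepoints <= 3:
        raise ValueError("need more than 3 time points")
    df = n_timepoints - 2
    p_corr = alpha / n_tests
    if p_corr <= 0 or p_corr / 2 < np.finfo(float).tiny:
        warnings.warn("corrected alpha underflows; returning correlation floor 1.0")
        return 1.0
    t_crit = stats.t.ppf(1.0 - p_corr / 2.0, df)
    if not np.isfinite(t_crit):
        warnings.warn("corrected alpha underflows; returning correlation floor 1.0")
        return 1.0
    return float(t_crit / math.sqrt(df + t_crit**2))


def wdc_from_series(
    series: np.ndarray,
    alpha: float = 0.05,
    n_tests: int | None = None,
    bonferroni_scope: str = "per_voxel",
    block_size: int = 1024,
) -> tuple[np.ndarray, float]:
    """WDC for a (n_voxels, t) series matrix.

    Parameters
    ----------
    bonferroni_scope : {"per_voxel", "pairwise"}
        Denominator of the Bonferroni correction when ``n_tests`` is not
        given: N - 1 tests per seed voxel (default, matching the per-row
        framing of the centrality sum) or the N(N-1)/2 pairwise total.

    Returns
    -------
    values : (n_voxels,) centrality sums
    r_threshold : the correlation floor applied
    """
    z = np.asarray(series, dtype=float)
    if z.ndim != 2:
        raise ValueError("series must be 2D (voxels x time)")
    n, t = z.shape
    if n < 2:
        raise ValueError("need at least 2 voxels")
    if n_tests is None:
        if bonferroni_scope == "per_voxel":
            n_tests = n - 1
        elif bonferroni_scope == "pairwise":
            n_tests = n * (n - 1) // 2
        else:
            raise ValueError(f"unknown bonferroni_scope {bonferroni_scope!r}")
    r_thr = bonferroni_r_threshold(alpha, n_tests, t)

    z = z - z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    if (norms == 0).any():
        raise ValueError("constant voxel series present; remove them from the mask first")
    z /= norms[:, None]

    values = np.empty(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r_block = z[start:stop] @ z.T  # (b, n)
        np.clip(r_block, -1.0, 1.0, out=r_block)
        r_block[r_block < r_thr] = 0.0
        # exclude the self correlation
        idx = np.arange(start, stop)
        r_block[np.arange(stop - start), idx] = 0.0
        values[start:stop] = r_block.sum(axis=1)
    return values, r_thr


def compute_wdc_map(
    run: BoldRun,
    gm_mask: np.ndarray | None = None,
    alpha: float = 0.05,
    bonferroni_scope: str = "per_voxel",
    block_size: int = 1024,
) -> CentralityMap:
    """Whole-mask WDC map for one preprocessed run.

    Constant voxels are dropped from the mask with a warning; an empty
    mask is an error.  The returned log-worthy quantities (r_threshold,
    n_voxels) are recorded on the map.
    """
    mask = np.asarray(run.mask if gm_mask is None else gm_mask, dtype=bool)
    if mask.shape != run.data.shape[:3]:
        raise ValueError("gm mask shape does not match run grid")
    if not mask.any():
        raise ValueError("empty grey-matter mask")
    series = run.data[mask]
    const = series.std(axis=1) == 0
    if const.any():
        warnings.warn(f"removing {int(const.sum())} constant voxel(s) from the mask")
        flat_idx = np.flatnonzero(mask.ravel())[const]
        mask = mask.copy()
        mask.ravel()[flat_idx] = False
        series = series[~const]
        if series.shape[0] < 2:
            raise ValueError("fewer than 2 non-constant voxels in mask")
    values, r_thr = wdc_from_series(
        series, alpha=alpha, bonferroni_scope=bonferroni_scope, block_size=block_size
    )
    out = np.zeros(mask.shape)
    out[mask] = values
    n = int(mask.sum())
    logger.info("WDC: N=%d voxels, r threshold=%.4f (alpha=%g, scope=%s)", n, r_thr, alpha, bonferroni_scope)
    return CentralityMap(values=out, mask=mask, r_threshold=r_thr, n_voxels=n)
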