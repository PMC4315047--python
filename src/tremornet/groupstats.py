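"""Group-difference inference, brain-behaviour correlation, and ROC
discrimination.

Voxel maps are compared between groups with a per-voxel GLM (group +
nuisance covariates such as gender, age, motion summaries, and optional
voxel-wise grey-matter volume), corrected by a Monte-Carlo
cluster-extent procedure.  Scalar network metrics are compared with
covariate-aware (Freedman-Lane) permutation tests, corrected across the
sparsity grid by Benjamini-Hochberg FDR.  Brain-behaviour coupling uses
partial Spearman correlation, and discriminative power is summarised by
an ROC threshold sweep with Mann-Whitney AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GlmDesign",
    "StatMap",
    "RocResult",
    "glm_contrast_map",
    "cluster_extent_correct",
    "permutation_test_metric",
    "fdr_across_sparsities",
    "partial_spearman",
    "roc_analysis",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)  # 26-neighbour cluster connectivity


@dataclass
class GlmDesign:
    """Design for a two-group comparison with nuisance covariates.

    ``group`` is a binary indicator (1 = patient-analog).  ``covariates``
    maps names to per-subject columns; ``voxel_covariates`` optionally
    adds per-subject, per-voxel columns (e.g. grey-matter volume) entered
    voxel by voxel.
    """

    group: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_covariates: np.ndarray | None = None  # (n_subjects, n_voxels)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float)
        levels = np.unique(self.group)
        if levels.size != 2:
            raise ValueError("group indicator must have exactly two levels")
        n = self.group.size
        for name, col in self.covariates.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (n,):
                raise ValueError(f"covariate {name!r} has shape {col.shape}, expected ({n},)")
            self.covariates[name] = col

    def matrix(self) -> np.ndarray:
        """Intercept + group + covariate columns; group is column 1."""
        cols = [np.ones_like(self.group), self.group]
        cols.extend(self.covariates.values())
        return np.column_stack(cols)


@dataclass
class StatMap:
    """Per-voxel group-contrast t map with correction bookkeeping."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    mask: np.ndarray
    height_p: float | None = None
    clusters: np.ndarray | None = None  # labelled components after height threshold
    cluster_sizes: np.ndarray | None = None
    extent_cutoff: int | None = None
    surviving_mask: np.ndarray | None = None


@dataclass
class RocResult:
    """Threshold sweep of a diagnostic score (patients = positive class,
    classified positive when score >= threshold)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_threshold: float
    best_sensitivity: float
    best_specificity: float
    auc_ci: tuple[float, float] | None = None

    @property
    def youden(self) -> float:
        return self.best_sensitivity + self.best_specificity - 1.0


def _t_stats(X: np.ndarray, Y: np.ndarray, coef: int = 1) -> tuple[np.ndarray, np.ndarray, int]:
    """t statistic and two-sided p for one coefficient of Y = X b + e,
    fitted column-wise over Y's second axis."""
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("non-positive residual degrees of freedom")
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef, coef], 1e-300))
    t = beta[coef] / se
    p_two = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p_two, df


def glm_contrast_map(maps: np.ndarray, design: GlmDesign, mask: np.ndarray | None = None) -> StatMap:
    """Per-voxel GLM of map value on group + covariates.

    ``maps`` is (n_subjects, x, y, z) or (n_subjects, n_voxels).  With a
    3D layout a ``mask`` selects analysed voxels.  Requires at least 3
    subjects per group.  A covariate collinear with group triggers a
    warning with a variance-inflation diagnostic.
    """
    maps = np.asarray(maps, dtype=float)
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    Y = maps[:, mask]  # (n_subjects, V)
    g = design.group
    counts = [int((g == v).sum()) for v in np.unique(g)]
    if min(counts) < 3:
        raise ValueError(f"need >= 3 subjects per group; got {counts}")
    X = design.matrix()

    # collinearity diagnostic: VIF of the group column against the rest
    others = np.delete(X, 1, axis=1)
    resid_g = X[:, 1] - others @ np.linalg.lstsq(others, X[:, 1], rcond=None)[0]
    r2 = 1.0 - (resid_g**2).sum() / ((X[:, 1] - X[:, 1].mean()) ** 2).sum()
    if r2 > 1.0 - 1e-10:
        warnings.warn("group indicator is collinear with the covariates (VIF -> inf)")
    elif r2 > 0.99:
        warnings.warn(f"near-collinear design: group VIF = {1.0 / (1.0 - r2):.1f}")

    if design.voxel_covariates is not None:
        VC = np.asarray(design.voxel_covariates, dtype=float)
        if VC.ndim > 2:
            VC = VC[:, mask]
        t = np.empty(Y.shape[1])
        p = np.empty(Y.shape[1])
        df = 0
        for v in range(Y.shape[1]):
            Xv = np.column_stack([X, VC[:, v]])
            tv, pv, df = _t_stats(Xv, Y[:, v : v + 1])
            t[v], p[v] = tv[0], pv[0]
    else:
        t, p, df = _t_stats(X, Y)

    t_map = np.zeros(mask.shape)
    p_map = np.ones(mask.shape)
    t_map[mask], p_map[mask] = t, p
    return StatMap(t_values=t_map, p_values=p_map, df=df, mask=mask)


def _max_cluster_size(binary: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_extent_correct(
    stat: StatMap,
    n_sims: int = 1000,
    alpha_fwe: float = 0.05,
    height_p: float = 0.01,
    smooth_sigma_vox: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> StatMap:
    """Monte-Carlo cluster-extent correction of a t map.

    Suprathreshold voxels (two-sided height ``height_p``) are grouped
    into 26-connected clusters.  ``n_sims`` null Gaussian maps are
    simulated on the mask (optionally smoothed with a Gaussian kernel of
    ``smooth_sigma_vox`` voxels, matching residual smoothness, then
    re-standardised); the (1 - alpha_fwe) quantile of their max cluster
    size is the extent cutoff.  Clusters at or above the cutoff survive.
    """
    if n_sims < 100:
        warnings.warn(f"n_sims={n_sims} gives an unstable extent quantile; use >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = stat.mask
    if mask.ndim != 3:
        raise ValueError("cluster correction needs a 3D mask")
    t_height = stats.t.ppf(1.0 - height_p / 2.0, stat.df)
    supra = (np.abs(stat.t_values) > t_height) & mask
    labels, n_clusters = ndimage.label(supra, structure=_STRUCT26)
    sizes = np.bincount(labels.ravel())[1:] if n_clusters else np.array([], dtype=int)

    z_height = stats.norm.ppf(1.0 - height_p / 2.0)
    null_max = np.empty(n_sims, dtype=int)
    for i in range(n_sims):
        z = rng.standard_normal(mask.shape)
        if smooth_sigma_vox > 0:
            z = ndimage.gaussian_filter(z, smooth_sigma_vox)
            z = z / z[mask].std()
        null_max[i] = _max_cluster_size((np.abs(z) > z_height) & mask)
    cutoff = int(np.quantile(null_max, 1.0 - alpha_fwe, method="higher")) + 1

    surviving = np.zeros_like(mask)
    for c in range(1, n_clusters + 1):
        if sizes[c - 1] >= cutoff:
            surviving |= labels == c
    logger.info(
        "cluster correction: height p=%g (t=%.3f), extent cutoff=%d voxels, %d/%d clusters survive",
        height_p, t_height, cutoff, int(np.unique(labels[surviving]).size), n_clusters,
    )
    return StatMap(
        t_values=stat.t_values,
        p_values=stat.p_values,
        df=stat.df,
        mask=mask,
        height_p=height_p,
        clusters=labels,
        cluster_sizes=sizes,
        extent_cutoff=cutoff,
        surviving_mask=surviving,
    )


def permutation_test_metric(
    values_a: np.ndarray,
    values_b: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for a group difference in a scalar
    metric, covariate-adjusted by the Freedman-Lane scheme.

    The metric is residualised on intercept + covariates; the statistic
    is the difference of group means of the residuals; group labels of
    the residuals are permuted.  p = (1 + #{|perm| >= |obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    y = np.concatenate([a, b])
    if np.ptp(y) == 0:
        warnings.warn("constant metric; permutation p-value is 1")
        return 1.0
    g = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    Z = np.ones((y.size, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != y.size:
            cov = cov.T
        Z = np.column_stack([Z, cov])
    resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]

    def stat(e: np.ndarray) -> float:
        return e[g == 1].mean() - e[g == 0].mean()

    obs = stat(resid)
    perms = rng.permuted(np.tile(resid, (n_perm, 1)), axis=1)
    w = np.where(g == 1, 1.0 / (g == 1).sum(), -1.0 / (g == 0).sum())
    null = perms @ w
    return float((1 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (n_perm + 1))


def fdr_across_sparsities(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over the sparsity grid; returns the
    boolean rejection set."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Spearman correlation: rank-transform x, y (and the
    covariates), residualise both on the covariates, and Pearson-correlate
    the residuals.  p from the t approximation with df = n - k - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    k = 0
    Z = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        k = cov.shape[1]
        Z = np.column_stack([Z, np.apply_along_axis(stats.rankdata, 0, cov)])
    if n < k + 3:
        raise ValueError(f"need n >= {k + 3} observations for {k} covariates")
    for v in (x, y):
        if np.unique(v).size <= n // 2:
            warnings.warn("more than 50% ties; rank correlation may be unstable")
            break
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ex = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ey = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    if denom == 0:
        return 0.0, 1.0
    rho = float(np.clip(ex @ ey / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), df))


def roc_analysis(
    scores_patients: np.ndarray,
    scores_controls: np.ndarray,
    n_boot: int = 0,
    seed: int | np.random.Generator | None = None,
) -> RocResult:
    """ROC threshold sweep with Mann-Whitney AUC.

    Every distinct score (plus a +inf sentinel) is a candidate
    threshold; a subject is classified as patient when score >= threshold.
    AUC = P(patient score > control score) + 0.5 P(tie).  The reported
    operating point maximises the Youden index (sensitivity +
    specificity - 1).  ``n_boot`` > 0 adds a percentile-bootstrap 95% CI
    for the AUC.
    """
    p = np.asarray(scores_patients, dtype=float)
    c = np.asarray(scores_controls, dtype=float)
    if p.size == 0 or c.size == 0:
        raise ValueError("need at least one score per group")
    thresholds = np.concatenate([np.unique(np.concatenate([p, c])), [np.inf]])
    sens = np.array([(p >= t).mean() for t in thresholds])
    spec = np.array([(c < t).mean() for t in thresholds])
    gt = (p[:, None] > c[None, :]).sum()
    eq = (p[:, None] == c[None, :]).sum()
    auc = float((gt + 0.5 * eq) / (p.size * c.size))
    best = int(np.argmax(sens + spec))
    ci = None
    if n_boot > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            pb = rng.choice(p, size=p.size, replace=True)
            cb = rng.choice(c, size=c.size, replace=True)
            gtb = (pb[:, None] > cb[None, :]).sum()
            eqb = (pb[:, None] == cb[None, :]).sum()
            boots[i] = (gtb + 0.5 * eqb) / (p.size * c.size)
        ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_threshold=float(thresholds[best]),
        best_sensitivity=float(sens[best]),
        best_specificity=float(spec[best]),
        auc_ci=ci,
    )
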