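"""End-to-end scaled-down analysis on a synthetic cohort.

One call simulates a two-group cohort, then runs the full chain:
temporal preprocessing -> voxel-wise weighted degree centrality with
group GLM and Monte-Carlo cluster correction -> seed-based Fisher-z
connectivity from the surviving peaks -> ROI-network efficiency sweep
with degree-preserving null normalisation -> permutation tests with FDR
across sparsities -> brain-behaviour partial Spearman -> ROC
discrimination.  Every stage writes its declared on-disk format under
the output directory, plus a run log with all thresholds and seeds.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .centrality import compute_wdc_map
from .groupstats import (
    GlmDesign,
    cluster_extent_correct,
    fdr_across_sparsities,
    glm_contrast_map,
    partial_spearman,
    permutation_test_metric,
    roc_analysis,
)
from .netgraph import default_sparsity_grid, efficiency_curve, roi_correlation_matrix, sparsity_threshold
from .preproc import preprocess_run
from .seedconn import drop_overlapping_rois, make_sphere_roi, extract_roi_timeseries, seed_fc_map
from .synthcohort import SyntheticConfig, generate_clinical, generate_cohort, generate_motion_traces

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _wm_csf_masks(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Carve two small corner blocks out of the grid to serve as WM and
    CSF compartments; the remainder is the grey-matter mask."""
    wm = np.zeros(shape, dtype=bool)
    csf = np.zeros(shape, dtype=bool)
    wm[:2, :2, :2] = True
    csf[-2:, -2:, -2:] = True
    gm = ~(wm | csf)
    return gm, wm, csf


def run_pipeline(
    out_dir,
    seed: int = 0,
    config: SyntheticConfig | None = None,
    n_seeds_max: int = 7,
    seed_radius_mm: float = 6.0,
    n_null: int = 100,
    n_perm: int = 10000,
    n_cluster_sims: int = 500,
    height_p: float = 0.01,
    alpha_fwe: float = 0.05,
    fdr_q: float = 0.05,
    write_bold: bool = True,
) -> dict:
    """Run the full synthetic-cohort analysis; returns a summary dict
    (also written as ``summary.json``)."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config if config is not None else SyntheticConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100,)))

    log_lines = [f"seed={seed}", f"config_seed={cfg.seed}", f"grid={cfg.grid_shape}", f"n_volumes={cfg.n_volumes}"]

    # --- simulate ---------------------------------------------------------
    runs, truth = generate_cohort(cfg)
    motions = generate_motion_traces(cfg)
    clinical = generate_clinical(truth)
    gm, wm, csf = _wm_csf_masks(cfg.grid_shape)
    gm &= truth.mask
    tio.save_truth(truth, out / "truth.json")
    tio.save_table(clinical, out / "clinical.tsv")
    tio.save_map(gm.astype(float), cfg.affine, out / "gm_mask.nii.gz")
    if write_bold:
        for sid, run, mot in zip(truth.subject_ids, runs, motions):
            tio.save_bold(run, out / f"bold_{sid}.nii.gz")
            tio.save_motion(mot, out / f"rp_{sid}.txt")

    # --- preprocess -------------------------------------------------------
    low, high = cfg.band
    clean, msum = [], []
    for run, mot in zip(runs, motions):
        r, s = preprocess_run(run, mot, wm_mask=wm, csf_mask=csf, low=low, high=high)
        clean.append(r)
        msum.append(s.as_array())
    msum = np.asarray(msum)
    log_lines.append(f"preproc: drop=5 band={low}-{high}Hz nuisance=friston24+wm+csf")

    # --- voxel-wise centrality + group GLM --------------------------------
    wdc_maps = np.stack([compute_wdc_map(r, gm_mask=gm, alpha=0.05).values for r in clean])
    tio.save_map(wdc_maps.mean(axis=0), cfg.affine, out / "wdc_mean.nii.gz")
    covs = {
        "age": clinical["age"].to_numpy(dtype=float),
        "gender": (clinical["gender"] == "M").to_numpy(dtype=float),
        "max_disp": msum[:, 0],
        "rms_disp": msum[:, 1],
        "mean_fd": msum[:, 2],
    }
    design = GlmDesign(group=truth.group_labels.astype(float), covariates=covs)
    stat = glm_contrast_map(wdc_maps, design, mask=gm)
    corrected = cluster_extent_correct(
        stat, n_sims=n_cluster_sims, alpha_fwe=alpha_fwe, height_p=height_p, seed=rng
    )
    tio.save_map(corrected.t_values, cfg.affine, out / "wdc_group_t.nii.gz")
    tio.save_map(
        (corrected.surviving_mask if corrected.surviving_mask is not None else np.zeros_like(gm)).astype(float),
        cfg.affine,
        out / "wdc_group_surviving.nii.gz",
    )
    log_lines.append(
        f"glm: df={stat.df} height_p={height_p} extent_cutoff={corrected.extent_cutoff} "
        f"cluster_sims={n_cluster_sims} alpha_fwe={alpha_fwe}"
    )

    # --- seeds from surviving peaks (fallback: strongest |t| voxels) ------
    abs_t = np.where(
        corrected.surviving_mask if corrected.surviving_mask is not None and corrected.surviving_mask.any() else gm,
        np.abs(corrected.t_values),
        -np.inf,
    )
    peak_order = np.argsort(abs_t, axis=None)[::-1]
    peak_centers = []
    for flat in peak_order[: n_seeds_max * 20]:
        ijk = np.unravel_index(flat, gm.shape)
        mm = (cfg.affine @ np.array([*ijk, 1.0]))[:3]
        if all(np.linalg.norm(mm - np.asarray(p)) > 2 * seed_radius_mm for p in peak_centers):
            peak_centers.append(mm)
        if len(peak_centers) >= n_seeds_max:
            break
    seed_rois = [
        make_sphere_roi(c, seed_radius_mm, gm, cfg.affine, name=f"peak{i}")
        for i, c in enumerate(peak_centers)
    ]
    seed_rois = drop_overlapping_rois(seed_rois)
    tio.save_seed_list(
        pd.DataFrame(
            [(r.name, *r.center_mm, r.radius_mm) for r in seed_rois],
            columns=["name", "x_mm", "y_mm", "z_mm", "radius_mm"],
        ),
        out / "seeds.tsv",
    )
    # seed FC z-maps (group means written to disk)
    for roi in seed_rois[:2]:
        zs = np.stack([seed_fc_map(r, roi, gm).z_values for r in clean])
        tio.save_map(zs.mean(axis=0), cfg.affine, out / f"fcz_mean_{roi.name}.nii.gz")
    log_lines.append(f"seeds: {len(seed_rois)} non-overlapping spheres r={seed_radius_mm}mm")

    # --- ROI network efficiency sweep -------------------------------------
    centroids = truth.region_centroids_mm()
    net_rois = drop_overlapping_rois(
        [
            make_sphere_roi(c, seed_radius_mm, gm, cfg.affine, name=f"region{k}")
            for k, c in enumerate(centroids)
        ]
    )
    labels = [r.name for r in net_rois]
    sparsities = default_sparsity_grid()
    curves = []
    per_sparsity_eg = np.zeros((len(clean), sparsities.size))
    per_sparsity_el = np.zeros((len(clean), sparsities.size))
    for i, r in enumerate(clean):
        series = np.vstack([extract_roi_timeseries(r, roi) for roi in net_rois])
        net = roi_correlation_matrix(series, labels=labels)
        if i == 0:
            tio.save_matrix(net, out / "roi_corr_subj0.tsv")
            tio.save_edge_list(sparsity_threshold(net, 0.3), out / "roi_edges_s0.30_subj0.tsv", labels)
        curve = efficiency_curve(net, sparsities, n_null=n_null, seed=rng)
        curves.append(curve)
        per_sparsity_eg[i] = curve.e_glob
        per_sparsity_el[i] = curve.e_loc
    auc_glob = np.array([c.auc_glob for c in curves])
    auc_loc = np.array([c.auc_loc for c in curves])
    sw_frac = float(np.mean([bool(c.small_world) for c in curves]))
    curve_df = pd.DataFrame(
        {
            "sparsity": sparsities,
            "e_glob_control": per_sparsity_eg[truth.group_labels == 0].mean(axis=0),
            "e_glob_patient": per_sparsity_eg[truth.group_labels == 1].mean(axis=0),
            "e_loc_control": per_sparsity_el[truth.group_labels == 0].mean(axis=0),
            "e_loc_patient": per_sparsity_el[truth.group_labels == 1].mean(axis=0),
        }
    )
    tio.save_table(curve_df, out / "efficiency_curves.tsv")
    log_lines.append(f"network: {len(net_rois)} ROIs, sparsities 0.08-0.60 step 0.02, nulls={n_null}")

    # --- permutation statistics + FDR across sparsities -------------------
    is_pat = truth.group_labels == 1
    cov_mat = np.column_stack(list(covs.values()))
    cov_ordered = np.vstack([cov_mat[~is_pat], cov_mat[is_pat]])
    p_auc_glob = permutation_test_metric(
        auc_glob[~is_pat], auc_glob[is_pat], cov_ordered, n_perm=n_perm, seed=rng
    )
    p_auc_loc = permutation_test_metric(
        auc_loc[~is_pat], auc_loc[is_pat], cov_ordered, n_perm=n_perm, seed=rng
    )
    p_per_sparsity = np.array(
        [
            permutation_test_metric(
                per_sparsity_eg[~is_pat, k],
                per_sparsity_eg[is_pat, k],
                cov_ordered,
                n_perm=max(1000, n_perm // 10),
                seed=rng,
            )
            for k in range(sparsities.size)
        ]
    )
    rejected = fdr_across_sparsities(p_per_sparsity, q=fdr_q)
    tio.save_table(
        pd.DataFrame({"sparsity": sparsities, "p_e_glob": p_per_sparsity, "fdr_rejected": rejected}),
        out / "efficiency_pvalues.tsv",
    )

    # --- brain-behaviour correlation --------------------------------------
    tremor = clinical.loc[is_pat, "tremor"].to_numpy(dtype=float)
    n_pat = int(is_pat.sum())
    cov_pat = cov_mat[is_pat]
    if n_pat < cov_pat.shape[1] + 3:  # tiny cohorts: keep as many covariates as df allows
        cov_pat = cov_pat[:, : max(0, n_pat - 3)]
    rho, p_rho = partial_spearman(
        auc_glob[is_pat], tremor, cov_pat if cov_pat.shape[1] else None
    )

    # --- ROC ---------------------------------------------------------------
    roc = roc_analysis(auc_glob[is_pat], auc_glob[~is_pat], n_boot=2000, seed=rng)
    tio.save_table(
        pd.DataFrame(
            {"threshold": roc.thresholds, "sensitivity": roc.sensitivity, "specificity": roc.specificity}
        ),
        out / "roc.tsv",
    )

    summary = {
        "seed": seed,
        "n_subjects": cfg.n_subjects,
        "n_gm_voxels": int(gm.sum()),
        "n_seeds": len(seed_rois),
        "n_rois": len(net_rois),
        "wdc_r_threshold": float(compute_wdc_map(clean[0], gm_mask=gm).r_threshold),
        "extent_cutoff": corrected.extent_cutoff,
        "n_surviving_voxels": int(corrected.surviving_mask.sum()) if corrected.surviving_mask is not None else 0,
        "auc_glob_mean_control": float(auc_glob[~is_pat].mean()),
        "auc_glob_mean_patient": float(auc_glob[is_pat].mean()),
        "auc_loc_mean_control": float(auc_loc[~is_pat].mean()),
        "auc_loc_mean_patient": float(auc_loc[is_pat].mean()),
        "p_auc_glob": p_auc_glob,
        "p_auc_loc": p_auc_loc,
        "n_sparsities_fdr_significant": int(rejected.sum()),
        "small_world_fraction": sw_frac,
        "partial_spearman_tremor_rho": rho,
        "partial_spearman_tremor_p": p_rho,
        "roc_auc": roc.auc,
        "roc_auc_ci": list(roc.auc_ci) if roc.auc_ci else None,
        "roc_sensitivity_pct": round(100 * roc.best_sensitivity, 1),
        "roc_specificity_pct": round(100 * roc.best_specificity, 1),
        "runtime_s": round(time.time() - t0, 1),
    }
    log_lines.append(f"n_perm={n_perm} fdr_q={fdr_q} runtime_s={summary['runtime_s']}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("pipeline finished in %.1fs", summary["runtime_s"])
    return summary
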