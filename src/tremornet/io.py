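"""Readers and writers for the pipeline's on-disk formats.

NIfTI images go through nibabel; motion traces are 6-column
whitespace-delimited text (SPM ``rp_*.txt`` dialect: 3 translations in
mm, 3 rotations in radians); tables (clinical, matrices, curves, seeds,
ROC) are tab-delimited text with headers; ground truth is a JSON
sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .netgraph import RoiNetwork, WeightedGraph
from .preproc import BoldRun
from .synthcohort import ScoreCoupling, SyntheticConfig, SyntheticTruth

__all__ = [
    "save_bold",
    "load_bold",
    "save_map",
    "load_map",
    "save_motion",
    "load_motion",
    "save_table",
    "load_table",
    "save_seed_list",
    "load_seed_list",
    "save_matrix",
    "load_matrix",
    "save_edge_list",
    "save_truth",
    "load_truth",
]


def save_bold(run: BoldRun, path) -> None:
    nib.save(nib.Nifti1Image(run.data.astype(np.float32), run.affine), str(path))


def load_bold(path, mask: np.ndarray | None = None, tr: float | None = None) -> BoldRun:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldRun(data=data, mask=mask, tr=tr, affine=np.asarray(img.affine))


def save_map(values: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D map (or boolean mask) as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def load_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def save_motion(motion6: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(motion6, dtype=float), fmt="%.8f")


def load_motion(path) -> np.ndarray:
    m = np.loadtxt(str(path), ndmin=2)
    if m.shape[1] != 6:
        raise ValueError(f"motion file {path} has {m.shape[1]} columns, expected 6")
    return m


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False, na_rep="NA")


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", na_values=["NA", "-"])


def save_seed_list(seeds: pd.DataFrame, path) -> None:
    """Seed table with columns name, x_mm, y_mm, z_mm, radius_mm."""
    save_table(seeds[["name", "x_mm", "y_mm", "z_mm", "radius_mm"]], path)


def load_seed_list(path) -> pd.DataFrame:
    df = load_table(path)
    required = {"name", "x_mm", "y_mm", "z_mm", "radius_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"seed list must have columns {sorted(required)}")
    return df


def save_matrix(net: RoiNetwork | np.ndarray, path, labels: list[str] | None = None) -> None:
    if isinstance(net, RoiNetwork):
        mat, labels = net.corr, net.labels
    else:
        mat = np.asarray(net)
        labels = labels or [f"roi{i}" for i in range(mat.shape[0])]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(str(path), sep="\t")


def load_matrix(path) -> RoiNetwork:
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    return RoiNetwork(corr=df.to_numpy(dtype=float), labels=list(df.columns))


def save_edge_list(graph: WeightedGraph, path, labels: list[str] | None = None) -> None:
    rows = []
    for i, j, w in graph.edge_list():
        a = labels[i] if labels else str(i)
        b = labels[j] if labels else str(j)
        rows.append((a, b, w))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(str(path), sep="\t", index=False)


def save_truth(truth: SyntheticTruth, path) -> None:
    cfg = truth.config
    payload = {
        "config": {
            "n_group_a": cfg.n_group_a,
            "n_group_b": cfg.n_group_b,
            "grid_shape": list(cfg.grid_shape),
            "voxel_size": cfg.voxel_size,
            "n_volumes": cfg.n_volumes,
            "tr": cfg.tr,
            "band": list(cfg.band),
            "n_regions": cfg.n_regions,
            "hub_voxels": [list(v) for v in cfg.hub_voxels],
            "base_cov": cfg.base_cov.tolist(),
            "effect_delta": cfg.effect_delta.tolist(),
            "noise_sd": cfg.noise_sd,
            "hub_noise_sd": cfg.hub_noise_sd,
            "latent_sd": cfg.latent_sd,
            "score_coupling": {k: asdict(v) for k, v in cfg.score_coupling.items()},
            "seed": cfg.seed,
        },
        "group_labels": truth.group_labels.tolist(),
        "true_scores_latent": truth.true_scores_latent.tolist(),
        "subject_ids": truth.subject_ids,
        "region_labels_flat": truth.region_labels.ravel().tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    c = payload["config"]
    couplings = {k: ScoreCoupling(**v) for k, v in c["score_coupling"].items()}
    cfg = SyntheticConfig(
        n_group_a=c["n_group_a"],
        n_group_b=c["n_group_b"],
        grid_shape=tuple(c["grid_shape"]),
        voxel_size=c["voxel_size"],
        n_volumes=c["n_volumes"],
        tr=c["tr"],
        band=tuple(c["band"]),
        n_regions=c["n_regions"],
        hub_voxels=tuple(tuple(v) for v in c["hub_voxels"]),
        base_cov=np.asarray(c["base_cov"]),
        effect_delta=np.asarray(c["effect_delta"]),
        noise_sd=c["noise_sd"],
        hub_noise_sd=c["hub_noise_sd"],
        latent_sd=c["latent_sd"],
        score_coupling=couplings,
        seed=c["seed"],
    )
    shape = tuple(c["grid_shape"])
    return SyntheticTruth(
        config=cfg,
        region_labels=np.asarray(payload["region_labels_flat"], dtype=int).reshape(shape),
        group_labels=np.asarray(payload["group_labels"], dtype=int),
        true_scores_latent=np.asarray(payload["true_scores_latent"], dtype=float),
        mask=np.ones(shape, dtype=bool),
        subject_ids=list(payload["subject_ids"]),
    )
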