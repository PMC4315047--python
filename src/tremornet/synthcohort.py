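"""Synthetic two-group resting-state BOLD cohorts with known ground truth.

Emulates the data regime of a small case-control tremor study: 180
volumes at TR = 2 s, 16 patient-analog subjects vs 20 control-analog
subjects, band-limited (0.01-0.1 Hz) signals with region-structured
covariance, planted hub voxels, bounded head-motion traces, and clinical
scores coupled to each patient's connectivity strength.

Generative model
----------------
Each subject s carries a latent connectivity strength c_s (0 for the
control group, Normal(1, latent_sd) truncated at 0 for the patient
group).  Region signals are drawn from a multivariate normal with
covariance ``base_cov + c_s * effect_delta`` and broadcast to member
voxels; independent voxel noise is added.  Both the region latents and
the voxel noise are shaped by the same ideal band-pass filter used in
preprocessing (and rescaled to preserve their variance), so generated
series are band-limited and realised region correlations stay at their
nominal values.  Hub voxels carry the standardised mean of all region
latents with reduced noise, which makes them the strongest correlation
aggregators on the grid.  Clinical scores are affine functions of c_s
plus noise, clipped to plausible ranges; controls get missing disease
scores.

All randomness flows from a single integer seed through a documented
``numpy.random.SeedSequence`` splitting scheme, so identical configs
give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preproc import BoldRun, bandpass_variance_fraction, ideal_bandpass

__all__ = [
    "ScoreCoupling",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_score_couplings",
    "slope_for_correlation",
    "generate_truth",
    "generate_cohort",
    "generate_clinical",
    "generate_motion_traces",
]

# stream ids for the seed-splitting scheme (SeedSequence(seed, spawn_key))
_STREAM_LATENTS = 0
_STREAM_NOISE = 1
_STREAM_MOTION = 2
_STREAM_CLINICAL = 3
_STREAM_DEMOGRAPHICS = 4


@dataclass(frozen=True)
class ScoreCoupling:
    """Affine map from the latent connectivity strength to one clinical score:
    score = baseline + slope * latent + Normal(0, noise_sd), clipped to
    [lo, hi]."""

    slope: float
    noise_sd: float
    baseline: float = 0.0
    lo: float = -math.inf
    hi: float = math.inf


def default_score_couplings() -> dict[str, ScoreCoupling]:
    """Disease scores with ranges matching a typical tremor-dominant
    Parkinson cohort (duration in years; tremor item 1-4; Hoehn-Yahr 1-3;
    UPDRS 4-49; MMSE essentially at ceiling and uncoupled)."""
    return {
        "duration": ScoreCoupling(slope=2.0, noise_sd=1.2, baseline=0.5, lo=0.42, hi=6.0),
        "tremor": ScoreCoupling(slope=1.5, noise_sd=0.6, baseline=0.5, lo=1.0, hi=4.0),
        "hy": ScoreCoupling(slope=1.5, noise_sd=0.7, baseline=0.75, lo=1.0, hi=3.0),
        "updrs": ScoreCoupling(slope=20.0, noise_sd=10.0, baseline=7.0, lo=4.0, hi=49.0),
        "mmse": ScoreCoupling(slope=0.0, noise_sd=0.05, baseline=29.8, lo=29.0, hi=30.0),
    }


def slope_for_correlation(rho: float, latent_sd: float, noise_sd: float) -> float:
    """Slope giving Pearson correlation ``rho`` between score and latent
    for the affine score model (noise_sd > 0, 0 < rho < 1)."""
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    return rho * noise_sd / (latent_sd * math.sqrt(1.0 - rho * rho))


def _default_base_cov(n_regions: int, r: float = 0.3) -> np.ndarray:
    cov = np.full((n_regions, n_regions), r)
    np.fill_diagonal(cov, 1.0)
    return cov


def _default_effect_delta(n_regions: int, d: float = 0.15) -> np.ndarray:
    delta = np.full((n_regions, n_regions), d)
    np.fill_diagonal(delta, 0.0)
    return delta


@dataclass
class SyntheticConfig:
    """Cohort-level generation parameters.

    Defaults emulate the target data regime: 20 controls vs 16 patients,
    180 volumes at TR = 2 s, 0.01-0.1 Hz band, a 12x12x12 grid of 3-mm
    voxels split into 8 regions with within-cohort correlation 0.3, a
    +0.15 correlation increment in the patient group, and one hub voxel
    at the grid centre.
    """

    n_group_a: int = 20  # control-analog
    n_group_b: int = 16  # patient-analog (receives effect_delta)
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size: float = 3.0
    n_volumes: int = 180
    tr: float = 2.0
    band: tuple[float, float] = (0.01, 0.1)
    n_regions: int = 8
    hub_voxels: tuple[tuple[int, int, int], ...] | None = None  # None -> grid centre
    base_cov: np.ndarray | None = None
    effect_delta: np.ndarray | None = None
    noise_sd: float = 1.0
    hub_noise_sd: float = 0.3
    latent_sd: float = 0.2
    score_coupling: dict[str, ScoreCoupling] = field(default_factory=default_score_couplings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        low, high = self.band
        if not (0 <= low < high < 1.0 / (2.0 * self.tr) + 1e-12):
            raise ValueError(f"band {self.band} must satisfy low < high <= Nyquist = {1/(2*self.tr)} Hz")
        if self.base_cov is None:
            self.base_cov = _default_base_cov(self.n_regions)
        self.base_cov = np.asarray(self.base_cov, dtype=float)
        if self.effect_delta is None:
            self.effect_delta = _default_effect_delta(self.base_cov.shape[0])
        self.effect_delta = np.asarray(self.effect_delta, dtype=float)
        self.n_regions = self.base_cov.shape[0]
        if self.base_cov.shape != self.effect_delta.shape:
            raise ValueError("base_cov and effect_delta shapes differ")
        if not np.allclose(self.base_cov, self.base_cov.T):
            raise ValueError("base_cov must be symmetric")
        if np.linalg.eigvalsh(self.base_cov).min() < -1e-10:
            raise ValueError("base_cov must be positive semi-definite")
        if self.hub_voxels is None:
            self.hub_voxels = (tuple(s // 2 for s in self.grid_shape),)
        for v in self.hub_voxels:
            if not all(0 <= v[i] < self.grid_shape[i] for i in range(3)):
                raise ValueError(f"hub voxel {v} outside grid {self.grid_shape}")

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


@dataclass
class SyntheticTruth:
    """Ground truth a simulated cohort was generated from."""

    config: SyntheticConfig
    region_labels: np.ndarray  # (x, y, z) int region id
    group_labels: np.ndarray  # (n_subjects,) 0 = group A (control), 1 = group B (patient)
    true_scores_latent: np.ndarray  # (n_subjects,) connectivity strength c_s
    mask: np.ndarray  # analysis mask, all True by default
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_a = int((self.group_labels == 0).sum())
        n_b = int((self.group_labels == 1).sum())
        if (n_a, n_b) != (self.config.n_group_a, self.config.n_group_b):
            raise ValueError("group_labels do not partition subjects into the configured sizes")
        for v in self.config.hub_voxels:
            if not self.mask[v]:
                raise ValueError(f"hub voxel {v} outside mask")
        if not self.subject_ids:
            self.subject_ids = [
                f"{'ctrl' if g == 0 else 'pat'}{i:03d}" for i, g in enumerate(self.group_labels)
            ]

    def subject_covariance(self, subject: int) -> np.ndarray:
        """Region covariance matrix used for one subject."""
        c = self.true_scores_latent[subject]
        return self.config.base_cov + c * self.config.effect_delta

    def region_centroids_mm(self) -> np.ndarray:
        """(n_regions, 3) mean voxel-centre coordinate per region, in mm."""
        cfg = self.config
        out = np.zeros((cfg.n_regions, 3))
        ijk = np.indices(cfg.grid_shape).reshape(3, -1).T
        labels = self.region_labels.ravel()
        for k in range(cfg.n_regions):
            centre_vox = ijk[labels == k].mean(axis=0)
            out[k] = (cfg.affine @ np.append(centre_vox, 1.0))[:3]
        return out


def _block_factors(n: int) -> tuple[int, int, int]:
    """Factor n into three near-equal integers a*b*c = n (a <= b <= c)."""
    a = max(d for d in range(1, int(round(n ** (1 / 3))) + 1) if n % d == 0)
    rem = n // a
    b = max(d for d in range(1, int(math.isqrt(rem)) + 1) if rem % d == 0)
    return a, b, rem // b


def _region_labels(grid_shape: tuple[int, int, int], n_regions: int) -> np.ndarray:
    """Partition the grid into n_regions contiguous rectangular blocks of
    near-equal size (axis splits as cubic as the factorisation allows),
    keeping region centroids well separated for ROI placement."""
    n_vox = int(np.prod(grid_shape))
    if n_regions > n_vox:
        raise ValueError("more regions than voxels")
    facs = sorted(_block_factors(n_regions))
    # give the most splits to the longest axes
    axis_order = np.argsort(grid_shape)
    splits = [1, 1, 1]
    for ax, f in zip(axis_order, facs):
        splits[ax] = f
    bins = []
    for ax in range(3):
        edges = np.linspace(0, grid_shape[ax], splits[ax] + 1).round().astype(int)
        bins.append(np.digitize(np.arange(grid_shape[ax]), edges[1:-1], right=False))
    bx, by, bz = np.meshgrid(bins[0], bins[1], bins[2], indexing="ij")
    return (bx * splits[1] + by) * splits[2] + bz


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Draw the per-subject latent strengths and fixed cohort structure.

    Cheap (no BOLD data); ``generate_cohort`` builds on it.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_STREAM_LATENTS,)))
    group_labels = np.concatenate(
        [np.zeros(config.n_group_a, dtype=int), np.ones(config.n_group_b, dtype=int)]
    )
    latent = np.zeros(config.n_subjects)
    n_b = config.n_group_b
    draws = np.abs(rng.normal(1.0, config.latent_sd, size=n_b))  # truncated at 0
    latent[group_labels == 1] = draws
    # every subject covariance must remain PSD
    for i in range(config.n_subjects):
        sigma = config.base_cov + latent[i] * config.effect_delta
        if np.linalg.eigvalsh(sigma).min() < -1e-10:
            raise ValueError(
                f"base_cov + {latent[i]:.3f} * effect_delta is not positive semi-definite "
                f"(min eigenvalue {np.linalg.eigvalsh(sigma).min():.3g}); reduce effect_delta"
            )
    return SyntheticTruth(
        config=config,
        region_labels=_region_labels(config.grid_shape, config.n_regions),
        group_labels=group_labels,
        true_scores_latent=latent,
        mask=np.ones(config.grid_shape, dtype=bool),
    )


def _shaped_noise(rng: np.random.Generator, shape: tuple, tr: float, band: tuple, scale: float) -> np.ndarray:
    """Band-limited unit-variance-preserving Gaussian noise (time on last axis)."""
    x = rng.standard_normal(shape)
    frac = bandpass_variance_fraction(shape[-1], tr, *band)
    return ideal_bandpass(x, tr, *band, axis=-1) * (scale / math.sqrt(frac))


def generate_cohort(config: SyntheticConfig, truth: SyntheticTruth | None = None):
    """Generate the full cohort of 4D BOLD runs.

    Returns
    -------
    runs : list of BoldRun
    truth : SyntheticTruth
    """
    if truth is None:
        truth = generate_truth(config)
    cfg = config
    t = cfg.n_volumes
    lat_seq = np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM_LATENTS, 1))
    noise_seq = np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM_NOISE,))
    lat_children = lat_seq.spawn(cfg.n_subjects)
    noise_children = noise_seq.spawn(cfg.n_subjects)

    labels_flat = truth.region_labels.ravel()
    n_vox = labels_flat.size
    hub_flat = [np.ravel_multi_index(v, cfg.grid_shape) for v in cfg.hub_voxels]
    frac = bandpass_variance_fraction(t, cfg.tr, *cfg.band)

    runs: list[BoldRun] = []
    for s in range(cfg.n_subjects):
        rng_l = np.random.default_rng(lat_children[s])
        rng_n = np.random.default_rng(noise_children[s])
        sigma = truth.subject_covariance(s)
        chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(cfg.n_regions))
        latents = chol @ rng_l.standard_normal((cfg.n_regions, t))
        latents = ideal_bandpass(latents, cfg.tr, *cfg.band, axis=-1) / math.sqrt(frac)

        data = latents[labels_flat] + _shaped_noise(rng_n, (n_vox, t), cfg.tr, cfg.band, cfg.noise_sd)

        if hub_flat:
            hub_mean = latents.mean(axis=0)
            var_mean = float(np.ones(cfg.n_regions) @ sigma @ np.ones(cfg.n_regions)) / cfg.n_regions**2
            hub_signal = hub_mean / math.sqrt(max(var_mean, 1e-12))
            hub_noise = _shaped_noise(
                rng_n, (len(hub_flat), t), cfg.tr, cfg.band, cfg.hub_noise_sd
            )
            data[hub_flat] = hub_signal + hub_noise

        runs.append(
            BoldRun(
                data=data.reshape(*cfg.grid_shape, t),
                mask=truth.mask.copy(),
                tr=cfg.tr,
                affine=cfg.affine,
            )
        )
    return runs, truth


def generate_motion_traces(
    config: SyntheticConfig,
    step_sd_mm: float = 0.02,
    step_sd_rad: float = 2e-4,
    bound_mm: float = 1.0,
    bound_rad: float = 0.01,
) -> list[np.ndarray]:
    """Bounded random-walk motion traces, one (n_volumes, 6) array per subject.

    Columns follow the SPM ``rp_*.txt`` dialect: 3 translations in mm,
    then 3 rotations in radians.  Walks reflect at +/- the bounds, which
    default to well inside the conventional 3 mm / 3 degree exclusion
    limits.  step sds of 0 give all-zero traces.
    """
    seq = np.random.SeedSequence(config.seed, spawn_key=(_STREAM_MOTION,))
    traces = []
    for child in seq.spawn(config.n_subjects):
        rng = np.random.default_rng(child)
        steps = rng.standard_normal((config.n_volumes, 6))
        steps[:, :3] *= step_sd_mm
        steps[:, 3:] *= step_sd_rad
        steps[0] = 0.0
        walk = np.cumsum(steps, axis=0)
        bounds = np.array([bound_mm] * 3 + [bound_rad] * 3)
        # reflect into [-b, b]
        walk = np.abs((walk + bounds) % (4 * bounds) - 2 * bounds) - bounds
        traces.append(walk)
    return traces


_DISEASE_SCORES = ("duration", "tremor", "hy", "updrs", "mmse")


def generate_clinical(
    truth: SyntheticTruth,
    couplings: dict[str, ScoreCoupling] | None = None,
) -> pd.DataFrame:
    """Build the clinical table from the latent connectivity strengths.

    Each coupled score is ``baseline + slope * latent + noise`` clipped to
    its plausible range; control subjects carry missing (NaN) disease
    scores.  Demographics (age, gender) are drawn group-matched.
    """
    cfg = truth.config
    couplings = couplings if couplings is not None else cfg.score_coupling
    for name in _DISEASE_SCORES:
        if name not in couplings:
            raise KeyError(f"missing coupling specification for score {name!r}")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM_CLINICAL,)))
    rng_demo = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM_DEMOGRAPHICS,)))

    n = cfg.n_subjects
    is_pat = truth.group_labels == 1
    table: dict[str, np.ndarray] = {
        "subject": np.array(truth.subject_ids, dtype=object),
        "group": np.where(is_pat, "patient", "control"),
        "age": np.clip(rng_demo.normal(60.0, 10.0, size=n).round(1), 37.0, 81.0),
        "gender": rng_demo.choice(["M", "F"], size=n, p=[0.55, 0.45]),
    }
    for name, spec in couplings.items():
        vals = spec.baseline + spec.slope * truth.true_scores_latent + rng.normal(0, spec.noise_sd, n)
        vals = np.clip(vals, spec.lo, spec.hi)
        vals[~is_pat] = np.nan  # controls: missing disease scores
        table[name] = vals
    return pd.DataFrame(table)
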