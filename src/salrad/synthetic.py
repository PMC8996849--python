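"""Synthetic phantoms and simulated multi-center cohorts.

The phantom generator builds paired PET/CT volumes containing an ellipsoid
tumor with an offset, higher-contrast sub-lesion (a distinct habitat) on a
noisy background — the minimal structure the saliency pipeline is meant to
expose. The cohort generator produces feature tables with additive and
multiplicative batch effects, protected covariate effects, planted
prognostic features driving Weibull survival times under independent
uniform censoring, and an HPV label from a logistic model. All outputs are
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .volume_io import Modality, TumorMask, VolumeImage

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "simulate_cohort",
    "linear_predictor_sd_for_cindex",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of a two-habitat tumor phantom.

    Intensity levels are SUV-like for PET and HU-like for CT; the
    sub-lesion multiplies the lesion level by ``sublesion_contrast`` on
    both modalities. Defaults give a 64 x 64 x 16 grid at 1 mm with a
    contrast-2 sub-lesion and mild Gaussian noise (5% of the PET lesion
    level), emulating a smoothed FDG-avid tumor with a hypermetabolic
    habitat.
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_center: tuple[float, float, float] = (32.0, 32.0, 8.0)
    lesion_radii: tuple[float, float, float] = (14.0, 11.0, 6.0)
    sublesion_offset: tuple[float, float, float] = (5.0, 3.0, 1.0)
    sublesion_radii: tuple[float, float, float] = (5.0, 4.0, 3.0)
    sublesion_contrast: float = 2.0
    pet_background: float = 1.0
    pet_lesion: float = 4.0
    pet_noise_sd: float = 0.2
    ct_background: float = 20.0
    ct_lesion: float = 50.0
    ct_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.lesion_radii + self.sublesion_radii):
            raise ValueError("radii must be positive")
        c = np.asarray(self.lesion_center)
        r = np.asarray(self.lesion_radii)
        if np.any(c - r < 0) or np.any(c + r > np.asarray(self.shape)):
            raise ValueError("lesion extends outside the grid")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec | None = None, seed: int = 0
                 ) -> tuple[VolumeImage, VolumeImage, TumorMask, TumorMask]:
    """Build paired PET/CT phantom volumes.

    Returns (pet, ct, tumor_mask, sublesion_mask); the sub-lesion mask is
    the planted habitat ground truth (clipped to the lesion).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    lesion = _ellipsoid(spec.shape, spec.lesion_center, spec.lesion_radii)
    sub_center = tuple(c + o for c, o in zip(spec.lesion_center, spec.sublesion_offset))
    sub = _ellipsoid(spec.shape, sub_center, spec.sublesion_radii) & lesion
    if not sub.any():
        raise ValueError("sub-lesion fell entirely outside the lesion")

    def build(background, level, noise_sd):
        vol = np.full(spec.shape, float(background))
        vol[lesion] = level
        vol[sub] = level * spec.sublesion_contrast
        if noise_sd > 0:
            vol = vol + rng.normal(0.0, noise_sd, size=spec.shape)
        return vol

    pet = VolumeImage(np.maximum(build(spec.pet_background, spec.pet_lesion,
                                       spec.pet_noise_sd), 0.0),
                      spec.spacing, Modality.PET)
    ct = VolumeImage(build(spec.ct_background, spec.ct_lesion, spec.ct_noise_sd),
                     spec.spacing, Modality.CT)
    return pet, ct, TumorMask(lesion, spec.spacing), TumorMask(sub, spec.spacing,
                                                               label="sublesion")


# ------------------------------------------------------------------ cohorts

def linear_predictor_sd_for_cindex(c_target: float) -> float:
    """Standard deviation of a normal linear predictor giving a population
    concordance of ``c_target`` under proportional hazards.

    For two patients with hazards exp(eta_i), exp(eta_j), the higher-risk
    one fails first with probability 1/(1 + exp(-|eta_i - eta_j|)); with
    eta ~ N(0, sd^2) the population C-index is
    E[sigmoid(|D|)], D ~ N(0, 2 sd^2). Solved by bisection.
    """
    if not 0.5 < c_target < 1.0:
        raise ValueError("target concordance must lie in (0.5, 1)")

    def c_of(sd: float) -> float:
        scale = np.sqrt(2.0) * sd
        f = lambda d: (1.0 / (1.0 + np.exp(-d))) * 2.0 * stats.norm.pdf(d, scale=scale)
        val, _ = integrate.quad(f, 0, np.inf)
        return val

    return float(optimize.brentq(lambda s: c_of(s) - c_target, 1e-6, 50.0))


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a multi-center radiomics feature table.

    Features: x_ij = mu_j + (covariate effects)_ij + gamma_b(i) +
    delta_b(i) * eps_ij with eps ~ N(0, 1). Survival: Weibull times with
    rate proportional to exp(eta_i), eta_i the batch-free prognostic
    signal over ``n_prognostic`` features; four endpoints (recurrence,
    metastasis, death; DFS = first of the three) under shared independent
    uniform censoring to the target rate. HPV ~ Bernoulli(sigmoid(
    intercept + x . beta_hpv)) on batch-free features.
    """

    n_patients: int = 500
    n_features: int = 100
    n_prognostic: int = 3
    target_cindex: float = 0.75
    batch_labels: tuple[str, ...] = ("all",)
    batch_shift: tuple[float, ...] = (0.0,)
    batch_scale: tuple[float, ...] = (1.0,)
    covariate_beta_age: float = 0.0  # effect of standardized age on every feature
    weibull_shape: float = 1.2
    weibull_scale: float = 60.0  # months
    censoring_rate: float = 0.3
    n_hpv_informative: int = 2
    hpv_beta: float = 1.5
    hpv_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.batch_labels) == len(self.batch_shift) == len(self.batch_scale)):
            raise ValueError("batch label/shift/scale lengths differ")
        if any(d <= 0 for d in self.batch_scale):
            raise ValueError("batch scale factors must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must lie in [0, 1)")
        if self.n_prognostic > self.n_features or self.n_hpv_informative > self.n_features:
            raise ValueError("planted features exceed feature count")


def simulate_cohort(spec: CohortSpec | None = None):
    """Generate one simulated cohort.

    Returns a dict with:
      features      patients x features DataFrame (batch effects applied)
      features_true batch-free features (generative ground truth)
      survival      per-endpoint `{ep}_time` / `{ep}_event` columns (months)
      hpv           0/1 Series
      metadata      center/manufacturer/voxel-size/age columns
      truth         planted feature names, eta, coefficient vectors
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_patients, spec.n_features
    idx = pd.Index([f"P{i:04d}" for i in range(n)], name="patient")
    feat_names = [f"f{j:03d}" for j in range(p)]

    mu = rng.normal(0.0, 1.0, size=p)
    eps = rng.normal(0.0, 1.0, size=(n, p))
    age_z = rng.normal(0.0, 1.0, size=n)
    x_true = mu[None, :] + spec.covariate_beta_age * age_z[:, None] + eps

    batch_idx = rng.integers(0, len(spec.batch_labels), size=n)
    shift = np.asarray(spec.batch_shift)[batch_idx]
    scale = np.asarray(spec.batch_scale)[batch_idx]
    x_obs = mu[None, :] + spec.covariate_beta_age * age_z[:, None] \
        + shift[:, None] + scale[:, None] * eps

    # prognostic signal on the batch-free features, scaled to the target C
    prog = rng.choice(p, size=spec.n_prognostic, replace=False)
    if spec.n_prognostic:
        # signal rides on the per-patient noise component, so it is batch-free
        raw_beta = rng.uniform(0.5, 1.0, size=spec.n_prognostic)
        sd_target = linear_predictor_sd_for_cindex(spec.target_cindex)
        beta = raw_beta * sd_target / np.sqrt((raw_beta ** 2).sum())
        eta = eps[:, prog] @ beta
    else:
        beta = np.zeros(0)
        eta = np.zeros(n)

    # Weibull PH times per endpoint component: S(t) = exp(-(t/scale)^shape * e^eta)
    def draw_times(mult: float) -> np.ndarray:
        u = rng.uniform(size=n)
        return spec.weibull_scale * (-np.log(u) / (mult * np.exp(eta))) ** (1.0 / spec.weibull_shape)

    components = {"recurrence": draw_times(1.0), "metastasis": draw_times(0.8),
                  "death": draw_times(0.6)}
    dfs_raw = np.minimum.reduce(list(components.values()))

    if spec.censoring_rate > 0:
        # independent Uniform(0, cmax) censoring; cmax calibrated by bisection
        # so the realized DFS censoring fraction matches the target
        draws = np.random.default_rng(spec.seed + 1).uniform(size=n)
        lo, hi = 1e-3, float(dfs_raw.max() * 50)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac_censored = (draws * mid < dfs_raw).mean()
            if frac_censored > spec.censoring_rate:
                lo = mid  # censor times too short; lengthen them
            else:
                hi = mid
        censor = draws * 0.5 * (lo + hi)
    else:
        censor = np.full(n, np.inf)

    survival = pd.DataFrame(index=idx)
    comp_map = {"rfs": components["recurrence"], "mfs": components["metastasis"],
                "os": components["death"], "dfs": dfs_raw}
    for ep, raw in comp_map.items():
        survival[f"{ep}_time"] = np.minimum(raw, censor)
        survival[f"{ep}_event"] = (raw <= censor).astype(int)
    # guard against zero-duration records
    for ep in comp_map:
        survival[f"{ep}_time"] = np.maximum(survival[f"{ep}_time"], 1e-6)

    hpv_feats = rng.choice(np.setdiff1d(np.arange(p), prog),
                           size=spec.n_hpv_informative, replace=False)
    beta_hpv = np.full(spec.n_hpv_informative, spec.hpv_beta)
    logit = spec.hpv_intercept + eps[:, hpv_feats] @ beta_hpv
    hpv = pd.Series((rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))).astype(int),
                    index=idx, name="hpv")

    manufacturers = ("GE", "Philips", "Siemens", "CPS")
    metadata = pd.DataFrame({
        "center": [spec.batch_labels[b] for b in batch_idx],
        "manufacturer": [manufacturers[b % len(manufacturers)] for b in batch_idx],
        "inplane_mm": rng.choice([2.5, 3.3, 4.0, 5.0], size=n),
        "slice_mm": rng.choice([1.5, 2.0, 2.5, 3.0, 3.2, 4.0], size=n),
        "age": 60.0 + 10.0 * age_z,
        "sex": rng.choice(["M", "F"], size=n, p=[0.8, 0.2]),
    }, index=idx)

    return {
        "features": pd.DataFrame(x_obs, index=idx, columns=feat_names),
        "features_true": pd.DataFrame(x_true, index=idx, columns=feat_names),
        "survival": survival,
        "hpv": hpv,
        "metadata": metadata,
        "truth": {
            "prognostic_features": [feat_names[j] for j in prog],
            "hpv_features": [feat_names[j] for j in hpv_feats],
            "beta_surv": beta,
            "beta_hpv": beta_hpv,
            "eta": pd.Series(eta, index=idx, name="eta"),
            "batch": pd.Series([spec.batch_labels[b] for b in batch_idx],
                               index=idx, name="batch"),
        },
    }
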