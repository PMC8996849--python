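"""End-to-end workflow: phantom cohort -> saliency-derived image types ->
feature tables -> reproducibility screening -> ComBat harmonization ->
outcome model construction -> evaluation, with a deterministic manifest.

Every stage is seeded from the run configuration, so rerunning an identical
configuration reproduces every artifact hash. Artifacts are written under
the run directory as CSV/JSON; the manifest records parameters, seeds,
per-stage artifact hashes and the fitted scores.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import FeatureConfig, extract_features, feature_names
from .harmonize import STRATEGIES, harmonize
from .modeling import ENDPOINTS, FittedScore, stepwise_outcome_model, univariate_screen
from .reproducibility import fused_reproducible, icc_per_feature
from .saliency import (SaliencyParams, compute_saliency_volume, derive_products,
                       fuse_images, normalize_volume)
from .survival import c_index
from .synthetic import PhantomSpec, make_phantom
from .volume_io import Modality, TumorMask, VolumeImage, crop_to_bbox, truncate_ct

IMAGE_TYPES = ("Origin", "SalMap", "highSal", "lowSal", "SalxImg", "FusedImg")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one phantom-cohort pipeline run."""

    seed: int = 0
    n_patients: int = 16
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        shape=(48, 48, 12), lesion_center=(24.0, 24.0, 6.0),
        lesion_radii=(10.0, 8.0, 4.0), sublesion_offset=(3.5, 2.5, 0.5),
        sublesion_radii=(4.0, 3.5, 2.0)))
    saliency: SaliencyParams = field(default_factory=SaliencyParams)
    n_bins: int = 64
    icc_cutoff: float = 0.8
    rho_max: float = 0.8
    top_n: int = 20
    harmonization: str = "none"
    image_types: tuple[str, ...] = IMAGE_TYPES
    train_frac: float = 0.6
    val_frac: float = 0.2
    weibull_shape: float = 1.2
    weibull_scale: float = 60.0
    censoring_rate: float = 0.3
    risk_coef: float = 1.5  # log-hazard per SD of sub-lesion volume fraction

    def __post_init__(self) -> None:
        if self.harmonization not in STRATEGIES:
            raise ValueError(f"unknown harmonization strategy {self.harmonization!r}")
        unknown = set(self.image_types) - set(IMAGE_TYPES)
        if unknown:
            raise ValueError(f"unknown image types: {sorted(unknown)}")
        if not 0 < self.train_frac < 1 or not 0 <= self.val_frac < 1:
            raise ValueError("invalid split fractions")
        if self.train_frac + self.val_frac >= 1:
            raise ValueError("train + validation fractions must leave a test split")


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.round(12).to_csv().encode()).hexdigest()[:16]


def _hash_arr(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(np.round(arr, 12)).tobytes()).hexdigest()[:16]


def _patient_phantom(config: RunConfig, i: int):
    """Per-patient phantom with jittered geometry and contrast."""
    rng = np.random.default_rng(config.seed * 100_003 + i)
    base = config.phantom
    jit = lambda vals, lo, hi: tuple(float(v * rng.uniform(lo, hi)) for v in vals)
    spec = replace(
        base,
        lesion_radii=jit(base.lesion_radii, 0.85, 1.1),
        sublesion_radii=jit(base.sublesion_radii, 0.8, 1.15),
        sublesion_offset=jit(base.sublesion_offset, 0.7, 1.2),
        sublesion_contrast=float(base.sublesion_contrast * rng.uniform(0.85, 1.2)),
    )
    return make_phantom(spec, seed=int(rng.integers(0, 2**31 - 1))), spec


def _jitter_mask(mask: TumorMask, seed: int) -> TumorMask:
    """Simulated re-segmentation: one-voxel boundary erosion/dilation patches."""
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    m = mask.voxels.copy()
    grown = ndimage.binary_dilation(m)
    shrunk = ndimage.binary_erosion(m)
    boundary_out = grown & ~m
    boundary_in = m & ~shrunk
    m[boundary_out] = rng.uniform(size=boundary_out.sum()) < 0.3
    keep_in = rng.uniform(size=boundary_in.sum()) >= 0.2
    inner = np.zeros_like(m)
    inner[boundary_in] = ~keep_in
    m &= ~inner
    if not m.any():
        m = mask.voxels.copy()
    return TumorMask(m, mask.spacing, label=mask.label)


def _image_type_rois(pet, ct, mask, params):
    """All (image_type, modality, image, roi_mask, usable) tuples for one patient."""
    pet_c, mask_c = crop_to_bbox(pet, mask)
    ct_c, _ = crop_to_bbox(ct, mask)
    ct_c = truncate_ct(ct_c)
    sal_pet = compute_saliency_volume(pet_c, mask_c, params)
    sal_ct = compute_saliency_volume(ct_c, mask_c, params)
    prod_pet = derive_products(pet_c, sal_pet, mask_c, params)
    prod_ct = derive_products(ct_c, sal_ct, mask_c, params)
    fused = fuse_images(prod_pet, prod_ct)

    out = []
    for modality, img_c, sal, prod in (("pet", pet_c, sal_pet, prod_pet),
                                       ("ct", ct_c, sal_ct, prod_ct)):
        sal_img = VolumeImage(sal.values, img_c.spacing, Modality.DERIVED)
        out.append(("Origin", modality, img_c, mask_c, True))
        out.append(("SalMap", modality, sal_img, mask_c, True))
        out.append(("highSal", modality, img_c, prod.high_mask, prod.high_usable))
        out.append(("lowSal", modality, img_c, prod.low_mask, prod.low_usable))
        out.append(("SalxImg", modality, prod.sal_x_img, mask_c, True))
    out.append(("FusedImg", "fused", fused, mask_c, True))
    return out, sal_pet, sal_ct, mask_c


def _extract_tables(config: RunConfig, masks_fn, label: str):
    """Feature tables per image type for one segmentation variant.

    ``masks_fn(i, mask)`` maps the true mask to the variant used.
    Returns dict image_type -> DataFrame (columns prefixed by modality).
    """
    fc = FeatureConfig(n_bins=config.n_bins)
    rows: dict[str, dict[str, dict[str, float]]] = {t: {} for t in config.image_types}
    sal_stats = {}
    for i in range(config.n_patients):
        (pet, ct, mask, sub), spec = _patient_phantom(config, i)
        mask_v = masks_fn(i, mask)
        rois, sal_pet, sal_ct, mask_c = _image_type_rois(pet, ct, mask_v, config.saliency)
        pid = f"P{i:04d}"
        feats: dict[str, dict[str, float]] = {t: {} for t in config.image_types}
        for image_type, modality, img, roi_mask, usable in rois:
            if image_type not in config.image_types:
                continue
            if roi_mask is None or not usable:
                named = {f"{modality}.{k}": np.nan for k in feature_names(fc)}
            else:
                vec = extract_features(img, roi_mask, fc)
                named = {f"{modality}.{k}": v for k, v in vec.as_dict().items()}
            feats[image_type].update(named)
        for t in config.image_types:
            rows[t][pid] = feats[t]
        sal_stats[pid] = {
            "sublesion_volume_fraction": sub.n_voxels / mask.n_voxels,
            "sublesion_contrast": spec.sublesion_contrast,
        }
    tables = {t: pd.DataFrame(rows[t]).T.sort_index(axis=1) for t in config.image_types}
    for t in tables:
        tables[t].index.name = "patient"
    return tables, pd.DataFrame(sal_stats).T


def _simulate_outcomes(config: RunConfig, phantom_stats: pd.DataFrame):
    """Weibull outcomes driven by the planted sub-lesion volume fraction."""
    rng = np.random.default_rng(config.seed + 77)
    vf = phantom_stats["sublesion_volume_fraction"].to_numpy()
    eta = config.risk_coef * (vf - vf.mean()) / max(vf.std(), 1e-12)
    n = len(vf)

    def draw(mult):
        u = rng.uniform(size=n)
        return config.weibull_scale * (-np.log(u) / (mult * np.exp(eta))) ** (1 / config.weibull_shape)

    comp = {"rfs": draw(1.0), "mfs": draw(0.8), "os": draw(0.6)}
    comp["dfs"] = np.minimum.reduce(list(comp.values()))
    censor = rng.uniform(0, np.percentile(comp["dfs"], 90) * (1 / max(config.censoring_rate, 0.05)),
                         size=n) if config.censoring_rate > 0 else np.full(n, np.inf)
    surv = pd.DataFrame(index=phantom_stats.index)
    for ep in ENDPOINTS:
        surv[f"{ep}_time"] = np.maximum(np.minimum(comp[ep], censor), 1e-6)
        surv[f"{ep}_event"] = (comp[ep] <= censor).astype(int)
    return surv, pd.Series(eta, index=phantom_stats.index, name="eta")


def _synthetic_metadata(config: RunConfig, index: pd.Index) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed + 13)
    centers = ["C1", "C2", "C3"]
    return pd.DataFrame({
        "center": [centers[i % 3] for i in range(len(index))],
        "manufacturer": rng.choice(["GE", "Philips", "Siemens"], size=len(index)),
        "inplane_mm": rng.choice([2.5, 3.3, 4.0, 5.0], size=len(index)),
        "slice_mm": rng.choice([1.5, 2.0, 2.5, 3.0], size=len(index)),
        "age": rng.normal(60, 10, size=len(index)),
    }, index=index)


def _screen_columns(tables_by_variant: dict[str, dict[str, pd.DataFrame]],
                    image_type: str, cutoff: float) -> list[str]:
    """Columns of one image-type table passing inter+intra ICC screening."""
    variants = list(tables_by_variant)
    ref = tables_by_variant[variants[0]][image_type]
    usable = [c for c in ref.columns
              if all(np.isfinite(tables_by_variant[v][image_type][c]).all()
                     and np.ptp(tables_by_variant[v][image_type][c].to_numpy()) > 0
                     for v in variants)]
    if not usable:
        return []
    inter = {v: tables_by_variant[v][image_type][usable] for v in ("obs1", "obs2")}
    intra = {v: tables_by_variant[v][image_type][usable] for v in ("obs1", "obs1rep")}
    icc_inter = icc_per_feature(inter, model="random")
    icc_intra = icc_per_feature(intra, model="mixed")
    return [c for c in usable if icc_inter[c] > cutoff and icc_intra[c] > cutoff]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow and return the manifest (also written to
    ``out_dir/manifest.json``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": _config_dict(config),
                      "stages": {}, "models": {}}

    # stage 1-3: phantoms, saliency, features, for three segmentation variants
    variants = {
        "obs1": lambda i, m: m,
        "obs1rep": lambda i, m: _jitter_mask(m, config.seed * 7919 + 2 * i),
        "obs2": lambda i, m: _jitter_mask(m, config.seed * 104729 + 2 * i + 1),
    }
    tables_by_variant: dict[str, dict[str, pd.DataFrame]] = {}
    phantom_stats = None
    for vname, fn in variants.items():
        tables, stats = _extract_tables(config, fn, vname)
        tables_by_variant[vname] = tables
        if vname == "obs1":
            phantom_stats = stats
    manifest["stages"]["features"] = {
        t: _hash_df(tables_by_variant["obs1"][t]) for t in config.image_types}

    # stage 4: reproducibility screening
    screened: dict[str, list[str]] = {}
    for t in config.image_types:
        if t == "FusedImg":
            continue
        screened[t] = _screen_columns(tables_by_variant, t, config.icc_cutoff)
    if "FusedImg" in config.image_types:
        # a fused feature needs reproducibility on both source modalities;
        # judged on the original-image tables when available
        ref_types = ["Origin"] if "Origin" in screened else list(screened)
        pet_ok = {c.split(".", 1)[1] for t in ref_types for c in screened[t]
                  if c.startswith("pet.")}
        ct_ok = {c.split(".", 1)[1] for t in ref_types for c in screened[t]
                 if c.startswith("ct.")}
        fused_cols = [c for c in tables_by_variant["obs1"]["FusedImg"].columns
                      if np.isfinite(tables_by_variant["obs1"]["FusedImg"][c]).all()]
        base = fused_reproducible(pet_ok, ct_ok,
                                  [c.split(".", 1)[1] for c in fused_cols])
        screened["FusedImg"] = [f"fused.{b}" for b in base
                                if f"fused.{b}" in fused_cols]
    manifest["stages"]["screening"] = {t: len(v) for t, v in screened.items()}

    # outcomes + metadata
    surv, eta = _simulate_outcomes(config, phantom_stats)
    metadata = _synthetic_metadata(config, surv.index)
    surv.to_csv(out_dir / "outcomes.csv")
    metadata.to_csv(out_dir / "metadata.csv")
    manifest["stages"]["outcomes"] = _hash_df(surv)

    # split
    rng = np.random.default_rng(config.seed + 99)
    idx = surv.index.to_numpy()
    events = surv["dfs_event"].to_numpy()
    train_idx, val_idx, test_idx = _stratified_split(idx, events, config, rng)
    manifest["stages"]["split"] = {"train": list(map(str, train_idx)),
                                   "val": list(map(str, val_idx)),
                                   "test": list(map(str, test_idx))}

    # stage 5-7 per image type: harmonize, train, evaluate
    for t in config.image_types:
        cols = screened.get(t, [])
        table = tables_by_variant["obs1"][t]
        if len(cols) < 2:
            manifest["models"][t] = {"status": "skipped",
                                     "reason": f"{len(cols)} screened features"}
            continue
        feats = table[cols]
        if config.harmonization != "none":
            feats = harmonize(feats, metadata, config.harmonization,
                              covariate_cols=["age"])
        feats.to_csv(out_dir / f"features_{t}.csv")
        try:
            selected, _ = univariate_screen(feats.loc[train_idx], surv.loc[train_idx],
                                            rho_max=config.rho_max, top_n=config.top_n)
            score = stepwise_outcome_model(selected, feats.loc[train_idx],
                                           surv.loc[train_idx], feats.loc[val_idx],
                                           surv.loc[val_idx])
        except Exception as exc:
            manifest["models"][t] = {"status": "failed", "reason": str(exc)}
            continue
        test_scores = score.predict(feats.loc[test_idx]).to_numpy()
        test_c = {}
        for ep in ENDPOINTS:
            tt = surv.loc[test_idx, f"{ep}_time"].to_numpy()
            ee = surv.loc[test_idx, f"{ep}_event"].to_numpy()
            c = c_index(tt, ee, test_scores)
            test_c[ep] = None if not np.isfinite(c) else round(float(c), 6)
        model_rec = {"status": "fitted", "score": score.to_dict(),
                     "diagnostics": score.diagnostics, "test_c_index": test_c,
                     "features_hash": _hash_df(feats)}
        (out_dir / f"model_{t}.json").write_text(json.dumps(model_rec, indent=2,
                                                            sort_keys=True))
        manifest["models"][t] = model_rec

    manifest_json = json.dumps(manifest, indent=2, sort_keys=True, default=str)
    (out_dir / "manifest.json").write_text(manifest_json)
    manifest["manifest_hash"] = hashlib.sha256(manifest_json.encode()).hexdigest()
    return manifest


def _stratified_split(idx, events, config: RunConfig, rng):
    """Stratified random split by DFS event status."""
    train, val, test = [], [], []
    for stratum in (0, 1):
        members = idx[events == stratum]
        perm = members[rng.permutation(len(members))]
        n_tr = int(round(config.train_frac * len(perm)))
        n_va = int(round(config.val_frac * len(perm)))
        train.extend(perm[:n_tr])
        val.extend(perm[n_tr:n_tr + n_va])
        test.extend(perm[n_tr + n_va:])
    return (np.array(sorted(train)), np.array(sorted(val)), np.array(sorted(test)))


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=lambda o: str(o)))
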