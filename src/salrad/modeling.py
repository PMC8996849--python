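"""Model construction for outcome and HPV-status prediction.

The outcome arm ranks features by their mean univariate C-index across the
four endpoints (RFS, MFS, OS, DFS), prunes redundant features, and grows a
multivariate Cox model for the primary endpoint DFS by stepwise addition of
the top-20 candidates (19 nested models, k = 2..20). The winner maximizes
the mean of eight C-indices: the four training endpoints plus the four
validation endpoints. Its coefficient-weighted feature sum is the outcome
radiomics score (Rad_Ocm), dichotomized at the training-cohort median.

The HPV arm ranks features by univariate AUC, prunes redundancy, fits
logistic models on the top k = 2..20 features, and selects by the summed
ranks of descending AUC and ascending BIC; the linear predictor is Rad_HPV.
Integration refits a bivariate Cox model on (Rad_Ocm, Rad_HPV) for DFS,
yielding Rad_Ocm_HPV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .reproducibility import prune_redundant
from .survival import CoxConvergenceError, c_index, cox_fit

__all__ = [
    "ENDPOINTS",
    "FittedScore",
    "univariate_screen",
    "stepwise_outcome_model",
    "hpv_model",
    "integrate_scores",
    "auc_mann_whitney",
]

ENDPOINTS = ("rfs", "mfs", "os", "dfs")
PRIMARY_ENDPOINT = "dfs"
TOP_N = 20
MIN_MINORITY = 5


@dataclass(frozen=True)
class FittedScore:
    """A linear radiomics score: named features, coefficients, training median."""

    kind: str  # Rad_Ocm | Rad_HPV | Rad_Ocm_HPV
    features: tuple[str, ...]
    coef: np.ndarray
    train_median: float
    intercept: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coef", np.asarray(self.coef, dtype=np.float64))
        if len(self.features) != self.coef.size:
            raise ValueError("features/coefficients length mismatch")

    def predict(self, table: pd.DataFrame) -> pd.Series:
        X = table[list(self.features)].to_numpy(dtype=np.float64)
        return pd.Series(self.intercept + X @ self.coef, index=table.index,
                         name=self.kind)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "features": list(self.features),
                "coef": self.coef.tolist(), "train_median": self.train_median,
                "intercept": self.intercept}


def _endpoint_arrays(survival: pd.DataFrame, endpoint: str, index=None):
    sub = survival if index is None else survival.loc[index]
    t = sub[f"{endpoint}_time"].to_numpy(dtype=np.float64)
    e = sub[f"{endpoint}_event"].to_numpy(dtype=np.float64)
    ok = np.isfinite(t) & np.isfinite(e)  # endpoint-wise missing-data drop
    return t[ok], e[ok], ok


def _feature_c_index(x: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    """C-index of a feature's univariate-Cox linear predictor (sign-resolved)."""
    if np.ptp(x) == 0:
        return 0.5
    try:
        beta = cox_fit(x[:, None], t, e).coef[0]
    except CoxConvergenceError:
        beta = 1.0  # fall back to the raw feature orientation
    return c_index(t, e, beta * x)


def univariate_screen(table: pd.DataFrame, survival: pd.DataFrame,
                      rho_max: float = 0.8, top_n: int = TOP_N) -> tuple[list[str], pd.DataFrame]:
    """Rank features by mean univariate C-index over the four endpoints,
    then keep the top ``top_n`` non-redundant ones (greedy Spearman prune).

    Returns (selected feature names in rank order, per-feature C-index table).
    """
    rows = {}
    for feat in table.columns:
        x_full = table[feat].to_numpy(dtype=np.float64)
        cs = {}
        for ep in ENDPOINTS:
            t, e, ok = _endpoint_arrays(survival, ep, table.index)
            cs[ep] = _feature_c_index(x_full[ok], t, e)
        cs["mean"] = float(np.mean([cs[ep] for ep in ENDPOINTS]))
        rows[feat] = cs
    report = pd.DataFrame(rows).T.sort_values("mean", ascending=False)
    ranking = report.index.tolist()
    selected = prune_redundant(table, ranking, rho_max=rho_max, top_n=top_n)
    return selected, report


def stepwise_outcome_model(selected: list[str], train_table: pd.DataFrame,
                           train_survival: pd.DataFrame,
                           val_table: pd.DataFrame,
                           val_survival: pd.DataFrame) -> FittedScore:
    """Grow the DFS Cox model by stepwise addition of the screened features.

    Model k uses the first k features (k = 2..len(selected), 19 models for
    a top-20 screen), fit on the training cohort for DFS only. Each model
    is scored by the mean of eight C-indices — all four endpoints on
    training and all four on validation — and the best mean wins. Failed
    fits are skipped with a warning.
    """
    if len(selected) < 2:
        raise ValueError("need at least two screened features")
    t_tr, e_tr, ok_tr = _endpoint_arrays(train_survival, PRIMARY_ENDPOINT,
                                         train_table.index)
    candidates = []
    for k in range(2, len(selected) + 1):
        feats = selected[:k]
        X_tr = train_table[feats].to_numpy(dtype=np.float64)
        try:
            fit = cox_fit(X_tr[ok_tr], t_tr, e_tr)
        except CoxConvergenceError as exc:
            warnings.warn(f"stepwise model k={k} skipped: {exc}")
            continue
        score_tr = train_table[feats].to_numpy(np.float64) @ fit.coef
        score_va = val_table[feats].to_numpy(np.float64) @ fit.coef
        cs = []
        for ep in ENDPOINTS:
            t, e, ok = _endpoint_arrays(train_survival, ep, train_table.index)
            cs.append(c_index(t, e, score_tr[ok]))
            t, e, ok = _endpoint_arrays(val_survival, ep, val_table.index)
            cs.append(c_index(t, e, score_va[ok]))
        candidates.append({"k": k, "features": feats, "coef": fit.coef,
                           "mean_c": float(np.nanmean(cs)), "c_indices": cs})
    if not candidates:
        raise CoxConvergenceError("every stepwise model failed to fit")
    best = max(candidates, key=lambda c: c["mean_c"])
    score_train = train_table[best["features"]].to_numpy(np.float64) @ best["coef"]
    return FittedScore(
        kind="Rad_Ocm", features=tuple(best["features"]), coef=best["coef"],
        train_median=float(np.median(score_train)),
        diagnostics={"n_models_evaluated": len(candidates),
                     "n_models_planned": len(selected) - 1,
                     "selected_k": best["k"], "mean_c": best["mean_c"]},
    )


def auc_mann_whitney(labels: np.ndarray, score: np.ndarray) -> float:
    """AUC by exhaustive positive/negative pair counting (ties credit 1/2)."""
    labels = np.asarray(labels)
    score = np.asarray(score, dtype=np.float64)
    pos = score[labels == 1]
    neg = score[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def hpv_model(table: pd.DataFrame, labels: pd.Series,
              rho_max: float = 0.8, top_n: int = TOP_N) -> FittedScore:
    """AUC-ranked, rank-sum-selected logistic model for HPV status.

    Features are sorted by univariate AUC (descending), pruned for
    redundancy, and the top k = 2..top_n feed nested logistic fits. The
    winner minimizes rank(descending AUC) + rank(ascending BIC), with
    BIC = -2 loglik + p ln n. The linear predictor defines Rad_HPV.
    """
    y = labels.loc[table.index].to_numpy(dtype=np.float64)
    n_min = int(min((y == 1).sum(), (y == 0).sum()))
    if n_min < MIN_MINORITY:
        raise ValueError(f"minority class has {n_min} cases (< {MIN_MINORITY})")

    aucs = {f: roc_auc_score(y, table[f].to_numpy(np.float64))
            if np.ptp(table[f].to_numpy()) > 0 else 0.5
            for f in table.columns}
    ranking = sorted(aucs, key=lambda f: -aucs[f])
    selected = prune_redundant(table, ranking, rho_max=rho_max, top_n=top_n)
    if len(selected) < 2:
        raise ValueError("fewer than two non-redundant candidate features")

    models = []
    for k in range(2, len(selected) + 1):
        feats = selected[:k]
        X = sm.add_constant(table[feats].to_numpy(np.float64))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite coefficients")
        except Exception as exc:  # separation, singular design, ...
            warnings.warn(f"HPV model k={k} skipped: {exc}")
            continue
        lin = X @ res.params
        auc = roc_auc_score(y, lin)
        bic = -2.0 * res.llf + len(res.params) * np.log(len(y))
        models.append({"k": k, "features": feats, "params": res.params,
                       "auc": float(auc), "bic": float(bic)})
    if not models:
        raise RuntimeError("every HPV logistic model failed to fit")

    auc_rank = np.argsort(np.argsort([-m["auc"] for m in models]))
    bic_rank = np.argsort(np.argsort([m["bic"] for m in models]))
    rank_sum = auc_rank + bic_rank
    best = models[int(np.argmin(rank_sum))]

    coef = best["params"][1:]
    intercept = float(best["params"][0])
    lin_train = intercept + table[best["features"]].to_numpy(np.float64) @ coef
    return FittedScore(
        kind="Rad_HPV", features=tuple(best["features"]), coef=coef,
        train_median=float(np.median(lin_train)), intercept=intercept,
        diagnostics={"n_models_evaluated": len(models), "selected_k": best["k"],
                     "auc": best["auc"], "bic": best["bic"]},
    )


def integrate_scores(rad_ocm: FittedScore, rad_hpv: FittedScore,
                     train_table: pd.DataFrame,
                     train_survival: pd.DataFrame) -> FittedScore:
    """Combine outcome and HPV scores by refitting a bivariate DFS Cox model.

    Near-collinear scores (|Pearson rho| > 0.99) or a degenerate fit fall
    back to Rad_Ocm with a warning.
    """
    s_ocm = rad_ocm.predict(train_table).to_numpy()
    s_hpv = rad_hpv.predict(train_table).to_numpy()
    rho = np.corrcoef(s_ocm, s_hpv)[0, 1] if np.ptp(s_hpv) > 0 else 1.0
    t, e, ok = _endpoint_arrays(train_survival, PRIMARY_ENDPOINT, train_table.index)

    def _fallback(reason: str) -> FittedScore:
        warnings.warn(f"score integration fell back to Rad_Ocm: {reason}")
        return FittedScore(kind="Rad_Ocm_HPV", features=rad_ocm.features,
                           coef=rad_ocm.coef, train_median=rad_ocm.train_median,
                           intercept=rad_ocm.intercept,
                           diagnostics={"fallback": reason})

    if not np.isfinite(rho) or abs(rho) > 0.99:
        return _fallback(f"collinear scores (rho={rho:.3f})")
    try:
        fit = cox_fit(np.column_stack([s_ocm, s_hpv])[ok], t, e)
    except CoxConvergenceError as exc:
        return _fallback(str(exc))
    w_ocm, w_hpv = fit.coef
    if w_ocm == 0 and w_hpv == 0:
        return _fallback("zero-coefficient degenerate fit")
    # expand to the underlying feature space: w_ocm * Rad_Ocm + w_hpv * Rad_HPV
    feats = list(dict.fromkeys(list(rad_ocm.features) + list(rad_hpv.features)))
    coef = np.zeros(len(feats))
    for f, c in zip(rad_ocm.features, rad_ocm.coef):
        coef[feats.index(f)] += w_ocm * c
    for f, c in zip(rad_hpv.features, rad_hpv.coef):
        coef[feats.index(f)] += w_hpv * c
    intercept = w_hpv * rad_hpv.intercept + w_ocm * rad_ocm.intercept
    combined_train = intercept + train_table[feats].to_numpy(np.float64) @ coef
    return FittedScore(kind="Rad_Ocm_HPV", features=tuple(feats), coef=coef,
                       train_median=float(np.median(combined_train)),
                       intercept=intercept,
                       diagnostics={"w_ocm": float(w_ocm), "w_hpv": float(w_hpv),
                                    "rho": float(rho)})
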