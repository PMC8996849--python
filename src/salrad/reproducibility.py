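"""Feature reproducibility screening and redundancy pruning.

Segmentation variability is assessed with absolute-agreement, single-rater
intraclass correlation coefficients from a two-way ANOVA (rows = subjects,
columns = raters/repeats). Features must exceed the ICC cutoff for both
inter- and intra-observer variation to survive screening; features of the
fused PET-CT image are kept only when reproducible on both modalities.
Redundancy is removed by a greedy walk down a performance ranking, dropping
any feature whose absolute Spearman correlation with an already-kept
feature exceeds the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IccResult",
    "icc_absolute_agreement",
    "icc_per_feature",
    "screen_reproducible",
    "prune_redundant",
]

ICC_CUTOFF = 0.8
RHO_MAX = 0.8


@dataclass(frozen=True)
class IccResult:
    feature: str
    icc_inter: float
    icc_intra: float

    def reproducible(self, cutoff: float = ICC_CUTOFF) -> bool:
        return self.icc_inter > cutoff and self.icc_intra > cutoff


def icc_absolute_agreement(ratings: np.ndarray, model: str = "random") -> float:
    """Single-rater, absolute-agreement ICC from two-way ANOVA mean squares.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)), where MSR,
    MSC, MSE are the row (subject), column (rater) and error mean squares.
    The two-way random-effects (ICC(2,1) / ICC(A,1)) and two-way
    mixed-effects single-measurement absolute-agreement forms share this
    equation, so ``model`` only documents intent.
    """
    if model not in ("random", "mixed"):
        raise ValueError(f"unknown ICC model {model!r}")
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be complete and finite")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)


def icc_per_feature(replicates: dict[str, pd.DataFrame], model: str = "random") -> pd.Series:
    """ICC per feature across segmentation replicates.

    ``replicates`` maps a replicate label (rater or repeat) to a feature
    table (subjects x features) with identical index and columns.
    """
    labels = list(replicates)
    if len(labels) < 2:
        raise ValueError("need at least two segmentation replicates")
    first = replicates[labels[0]]
    out = {}
    for feat in first.columns:
        mat = np.column_stack([replicates[lab][feat].to_numpy(dtype=float)
                               for lab in labels])
        out[feat] = icc_absolute_agreement(mat, model=model)
    return pd.Series(out, name=f"icc_{model}")


def screen_reproducible(inter_replicates: dict[str, pd.DataFrame],
                        intra_replicates: dict[str, pd.DataFrame],
                        cutoff: float = ICC_CUTOFF) -> list[IccResult]:
    """Inter- and intra-observer ICC per feature; keep those above cutoff on both."""
    icc_inter = icc_per_feature(inter_replicates, model="random")
    icc_intra = icc_per_feature(intra_replicates, model="mixed")
    return [IccResult(f, float(icc_inter[f]), float(icc_intra[f]))
            for f in icc_inter.index]


def reproducible_names(results: list[IccResult], cutoff: float = ICC_CUTOFF) -> list[str]:
    return [r.feature for r in results if r.reproducible(cutoff)]


def fused_reproducible(pet_reproducible: set[str], ct_reproducible: set[str],
                       fused_features: list[str]) -> list[str]:
    """Fused-image features are retained only when the same feature was
    reproducible on both the PET and the CT image."""
    keep = pet_reproducible & ct_reproducible
    return [f for f in fused_features if f in keep]


def prune_redundant(table: pd.DataFrame, ranking: list[str],
                    rho_max: float = RHO_MAX, top_n: int | None = None) -> list[str]:
    """Greedy non-redundant selection in ranking order.

    Walks down ``ranking``; a feature is kept iff its absolute Spearman
    correlation with every already-kept feature is <= ``rho_max``. Stops
    after ``top_n`` survivors when given.
    """
    missing = [f for f in ranking if f not in table.columns]
    if missing:
        raise ValueError(f"ranking names absent from table: {missing[:5]}")
    kept: list[str] = []
    for feat in ranking:
        col = table[feat].to_numpy(dtype=float)
        if np.ptp(col) == 0:  # constant feature carries no signal
            continue
        redundant = False
        for k in kept:
            rho = stats.spearmanr(col, table[k].to_numpy(dtype=float)).statistic
            if np.isnan(rho) or abs(rho) > rho_max:
                redundant = True
                break
        if not redundant:
            kept.append(feat)
            if top_n is not None and len(kept) >= top_n:
                break
    return kept
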