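"""Survival-analysis machinery: Harrell's C, Cox partial likelihood with
Efron tie correction, Kaplan–Meier / log-rank risk-group reporting,
percentile-bootstrap confidence intervals, and the saliency-peak
localization statistic.

The Cox fitter is a plain Newton maximizer of the Efron-corrected log
partial likelihood with step halving; lifelines is used for Kaplan–Meier
curves and the log-rank test and serves as an independent cross-check of
the fitter in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .saliency import SaliencyMap
from .volume_io import TumorMask

__all__ = [
    "c_index",
    "c_index_bruteforce",
    "CoxFit",
    "CoxConvergenceError",
    "cox_fit",
    "KmLogrankResult",
    "km_logrank",
    "bootstrap_ci",
    "saliency_peak_distance",
]


def _validate_surv(time, event, score=None):
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.float64)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1D arrays of equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise ValueError("event flags must be 0/1")
    if score is not None:
        score = np.asarray(score, dtype=np.float64)
        if score.shape != time.shape:
            raise ValueError("score must align with time")
        return time, event, score
    return time, event


def c_index(time, event, score) -> float:
    """Harrell's concordance index; higher score = higher risk.

    Permissible pairs: (i, j) with time_i < time_j and event_i = 1, or tied
    times where exactly one has an event. Concordant when the earlier
    failure has the higher score; score ties credit 1/2. Returns NaN when
    no pair is permissible.
    """
    time, event, score = _validate_surv(time, event, score)
    # pair (i,j) permissible with i the known-earlier failure
    ti = time[:, None]
    tj = time[None, :]
    ei = event[:, None]
    ej = event[None, :]
    perm = (ei == 1) & ((ti < tj) | ((ti == tj) & (ej == 0)))
    if not perm.any():
        return float("nan")
    si = score[:, None]
    sj = score[None, :]
    conc = (perm & (si > sj)).sum()
    tied = (perm & (si == sj)).sum()
    return float((conc + 0.5 * tied) / perm.sum())


def c_index_bruteforce(time, event, score) -> float:
    """Explicit pair-loop reference implementation of :func:`c_index`."""
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    score = np.asarray(score, float)
    n = len(time)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if event[i] != 1:
                continue
            if not (time[i] < time[j] or (time[i] == time[j] and event[j] == 0)):
                continue
            den += 1
            if score[i] > score[j]:
                num += 1
            elif score[i] == score[j]:
                num += 0.5
    return float("nan") if den == 0 else num / den


class CoxConvergenceError(RuntimeError):
    """Newton iterations failed (separation, collinearity, or divergence)."""


@dataclass(frozen=True)
class CoxFit:
    coef: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    loglik_path: tuple[float, ...]

    def linear_predictor(self, X) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.coef


def cox_loglik(beta, X, time, event):
    """Efron-corrected Cox log partial likelihood, gradient, Hessian."""
    n, p = X.shape
    eta = X @ beta
    # cap to avoid overflow during aggressive Newton trials
    w = np.exp(np.clip(eta, -500, 500))
    order = np.argsort(-time, kind="stable")  # decreasing time
    Xo, to, eo, wo = X[order], time[order], event[order], w[order]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    csum_w = 0.0
    csum_xw = np.zeros(p)
    csum_xxw = np.zeros((p, p))

    i = 0
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        # accumulate the full risk set for this time (all with t >= t_i)
        for k in range(i, j):
            xw = Xo[k] * wo[k]
            csum_w += wo[k]
            csum_xw += xw
            csum_xxw += np.outer(Xo[k], xw)
        dead = [k for k in range(i, j) if eo[k] == 1]
        m = len(dead)
        if m:
            d_w = sum(wo[k] for k in dead)
            d_xw = np.zeros(p)
            d_xxw = np.zeros((p, p))
            for k in dead:
                d_xw += Xo[k] * wo[k]
                d_xxw += np.outer(Xo[k], Xo[k] * wo[k])
                ll += float(np.clip(Xo[k] @ beta, -500, 500))
                grad += Xo[k]
            for l in range(m):
                f = l / m
                rw = csum_w - f * d_w
                rxw = csum_xw - f * d_xw
                rxxw = csum_xxw - f * d_xxw
                ll -= np.log(rw)
                mu = rxw / rw
                grad -= mu
                hess -= rxxw / rw - np.outer(mu, mu)
        i = j
    return ll, grad, hess


def cox_fit(X, time, event, tol: float = 1e-8, max_iter: int = 60) -> CoxFit:
    """Maximize the Efron partial likelihood by damped Newton iterations.

    Converges when the gradient max-norm drops below ``tol``. Covariates
    are standardized internally for numerical stability; coefficients are
    returned on the original scale. The log-likelihood path is monotone
    non-decreasing (step halving enforces ascent).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(time)) > 1:
        X = X.T
    time, event = _validate_surv(time, event)
    if X.shape[0] != len(time):
        raise ValueError("X rows must match number of patients")
    if event.sum() < 1:
        raise CoxConvergenceError("no events in the data")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise CoxConvergenceError("constant covariate column")
    mu = X.mean(axis=0)
    Xs = (X - mu) / sd

    p = Xs.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = cox_loglik(beta, Xs, time, event)
    ll_null = ll
    path = [ll]
    def _finish(it: int) -> CoxFit:
        # a converged but enormous standardized effect signals separation /
        # monotone likelihood: no useful finite MLE
        if np.max(np.abs(beta)) > 10:
            raise CoxConvergenceError(
                f"separation suspected (standardized |beta| = "
                f"{np.max(np.abs(beta)):.1f})")
        return CoxFit(beta / sd, float(ll), float(ll_null), it, tuple(path))

    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            return _finish(it - 1)
        try:
            step = np.linalg.solve(-hess + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular Hessian at iter {it}: {exc}") from exc
        if np.max(np.abs(step)) > 50:
            raise CoxConvergenceError(
                f"diverging step (|step|={np.max(np.abs(step)):.1f}); "
                "likely separation or monotone likelihood")
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = cox_loglik(cand, Xs, time, event)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise CoxConvergenceError("step halving failed to improve likelihood")
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        path.append(ll)
    if np.max(np.abs(grad)) < 1e-5:  # accept near-converged flat likelihoods
        return _finish(max_iter)
    raise CoxConvergenceError(
        f"no convergence in {max_iter} iterations (|grad|={np.max(np.abs(grad)):.2g})")


@dataclass(frozen=True)
class KmLogrankResult:
    chi_square: float
    p_value: float
    hazard_ratio: float
    high_curve: object  # fitted KaplanMeierFitter, high-risk group
    low_curve: object
    n_high: int
    n_low: int


def km_logrank(score, cut: float, time, event) -> KmLogrankResult:
    """Split at the training-cohort median score, compare the two groups.

    ``cut`` must come from the training cohort. Returns the two-group
    log-rank statistic and the hazard ratio of high vs. low risk from a
    univariate Cox fit on the group indicator.
    """
    time, event, score = _validate_surv(time, event, score)
    high = score > cut
    if high.all() or not high.any():
        raise ValueError("median cut leaves one risk group empty")
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    km_hi = KaplanMeierFitter().fit(time[high], event[high], label="high risk")
    km_lo = KaplanMeierFitter().fit(time[~high], event[~high], label="low risk")
    try:
        hr = float(np.exp(cox_fit(high.astype(float)[:, None], time, event).coef[0]))
    except CoxConvergenceError:
        hr = float("nan")
    return KmLogrankResult(float(res.test_statistic), float(res.p_value), hr,
                           km_hi, km_lo, int(high.sum()), int((~high).sum()))


def bootstrap_ci(metric_fn, data: dict[str, np.ndarray], rng, B: int = 100,
                 max_retries: int = 10):
    """Percentile bootstrap over patients.

    ``metric_fn`` maps a dict of aligned arrays to a scalar; ``data`` holds
    the per-patient arrays. Replicates on which the metric is undefined
    (NaN or an exception) are redrawn up to ``max_retries`` times.
    Returns (point_estimate, (lo95, hi95)).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(rng)
    keys = list(data)
    n = len(data[keys[0]])
    point = float(metric_fn(data))
    vals = []
    for _ in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            sample = {k: np.asarray(v)[idx] for k, v in data.items()}
            try:
                v = float(metric_fn(sample))
            except Exception:
                v = float("nan")
            if np.isfinite(v):
                vals.append(v)
                break
        else:
            raise RuntimeError("bootstrap metric undefined after retries")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return point, (float(lo), float(hi))


def saliency_peak_distance(sal: SaliencyMap | np.ndarray, mask: TumorMask) -> float:
    """Normalized distance from the highest-saliency voxel to the tumor centroid.

    0 means the peak sits at the mask centroid, 1 at the farthest mask
    voxel; distances in physical mm. Only in-mask voxels compete for the
    peak. A single-voxel mask returns 0.
    """
    values = sal.values if isinstance(sal, SaliencyMap) else np.asarray(sal)
    if values.shape != mask.shape:
        raise ValueError("saliency map and mask must be congruent")
    sp = np.asarray(mask.spacing)
    coords = np.argwhere(mask.voxels)
    if len(coords) == 1:
        return 0.0
    phys = coords * sp
    centroid = phys.mean(axis=0)
    radii = np.linalg.norm(phys - centroid, axis=1)
    r_max = radii.max()
    if r_max == 0:
        return 0.0
    in_mask_vals = values[mask.voxels]
    peak = phys[np.argmax(in_mask_vals)]
    return float(np.linalg.norm(peak - centroid) / r_max)
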