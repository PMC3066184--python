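"""Step 2 — copy-number class detection at each candidate locus.

Each locus is summarized to one median log2 ratio per sample. A constrained
one-dimensional mixture is then fitted by EM for 1..6 components: variances
are tied across components except for 2- and 3-component models (where the
deletion class legitimately has a different spread), the model with the
lowest BIC wins, a Student-t mixture (df = 4) replaces a non-converged
winner, and class-interval overlaps trigger component reduction. Rare copy
number classes that EM cannot resolve (a handful of carriers) are rescued by
a recursive Grubbs outlier scan which promotes outliers to singleton classes.

The EM implementation is deliberately deterministic: components are
initialized by quantile slicing of the sorted values, which also makes every
fit exactly shift-equivariant.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core_io import (
    CandidateLocus,
    CNClassModel,
    IgC2NError,
    IntensityMatrix,
    OneCNDifference,
    SummarySignal,
    logger,
)

__all__ = [
    "summarize_locus",
    "fit_mixture",
    "select_model",
    "grubbs_rescue",
    "grubbs_critical_value",
    "merge_close_classes",
    "one_cn_differences",
    "CNClassDetector",
]

_VAR_FLOOR = 1e-6
_T_DF = 4.0
_MAX_ITER = 1000
_TOL = 1e-6


def summarize_locus(matrix: IntensityMatrix, locus: CandidateLocus) -> SummarySignal:
    """Per-sample median over the markers covered by the locus."""
    if locus.n_markers == 0:
        raise IgC2NError("locus covers no markers")
    sub = matrix.values[:, locus.marker_indices]
    return SummarySignal(locus, np.median(sub, axis=1))


# ---------------------------------------------------------------------------
# 1-D EM for Gaussian / t mixtures
# ---------------------------------------------------------------------------


def _quantile_init(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic shift-equivariant init: slice sorted values into k blocks."""
    xs = np.sort(x)
    blocks = np.array_split(xs, k)
    mu = np.array([b.mean() for b in blocks])
    # nudge exact ties apart so components can separate
    for i in range(1, k):
        if mu[i] <= mu[i - 1]:
            mu[i] = mu[i - 1] + 1e-8
    var = np.full(k, max(np.var(xs) / max(k * k, 1), _VAR_FLOOR))
    w = np.array([max(len(b), 1) for b in blocks], dtype=float)
    return mu, var, w / w.sum()


import math

_LOG_2PI = np.log(2.0 * np.pi)
# t(df) normalizing constant: lgamma((df+1)/2) - lgamma(df/2) - 0.5*log(df*pi)
_T_NORM = (
    math.lgamma((_T_DF + 1) / 2)
    - math.lgamma(_T_DF / 2)
    - 0.5 * math.log(_T_DF * math.pi)
)


def _log_density(x, mu, var, family):
    z2 = (x[:, None] - mu[None, :]) ** 2 / var[None, :]
    if family == "gaussian":
        return -0.5 * (z2 + _LOG_2PI + np.log(var)[None, :])
    return _T_NORM - 0.5 * np.log(var)[None, :] - ((_T_DF + 1) / 2) * np.log1p(z2 / _T_DF)


def fit_mixture(
    values: np.ndarray,
    n_comp: int,
    variance_mode: str = "tied",
    family: str = "gaussian",
    seed: int | None = None,
) -> CNClassModel:
    """EM fit of a 1-D mixture with ``n_comp`` components.

    ``variance_mode="tied"`` shares a single variance across components;
    ``"free"`` estimates one per component. ``family="t"`` fits a Student-t
    mixture with 4 degrees of freedom (longer tails) via the usual latent
    scale-weight EM. BIC = -2 logL + k log n with k = n_comp means +
    (n_comp - 1) weights + 1 (tied) or n_comp (free) variances.

    The fit is deterministic (quantile-slice initialization); ``seed`` is
    accepted for interface stability but unused.
    """
    x = np.asarray(values, dtype=np.float64)
    if not np.isfinite(x).all():
        raise IgC2NError("mixture input must be finite")
    n = x.size
    if n < n_comp:
        raise IgC2NError(f"{n} values cannot support {n_comp} components")
    if np.unique(x).size < n_comp:
        raise IgC2NError(
            f"{np.unique(x).size} distinct values cannot support {n_comp} components"
        )
    if variance_mode not in ("tied", "free"):
        raise IgC2NError(f"unknown variance_mode {variance_mode!r}")
    if family not in ("gaussian", "t"):
        raise IgC2NError(f"unknown family {family!r}")

    mu, var, w = _quantile_init(x, n_comp)
    loglik_old = -np.inf
    converged = False
    for _ in range(_MAX_ITER):
        logd = _log_density(x, mu, var, family) + np.log(w)[None, :]
        norm = np.logaddexp.reduce(logd, axis=1)
        loglik = float(norm.sum())
        r = np.exp(logd - norm[:, None])  # responsibilities, rows sum to 1

        if family == "t":
            z2 = (x[:, None] - mu[None, :]) ** 2 / var[None, :]
            u = (_T_DF + 1.0) / (_T_DF + z2)  # latent scale weights
        else:
            u = np.ones_like(r)

        rw = r.sum(axis=0)
        ru = (r * u).sum(axis=0)
        w = np.maximum(rw, 1e-12) / n
        w = w / w.sum()
        mu = (r * u * x[:, None]).sum(axis=0) / np.maximum(ru, 1e-12)
        sq = (r * u * (x[:, None] - mu[None, :]) ** 2).sum(axis=0)
        if variance_mode == "tied":
            var = np.full(n_comp, max(sq.sum() / max(rw.sum(), 1e-12), _VAR_FLOOR))
        else:
            var = np.maximum(sq / np.maximum(rw, 1e-12), _VAR_FLOOR)

        if abs(loglik - loglik_old) < _TOL * max(abs(loglik_old), 1.0):
            converged = True
            break
        loglik_old = loglik

    logd = _log_density(x, mu, var, family) + np.log(w)[None, :]
    norm = np.logaddexp.reduce(logd, axis=1)
    loglik = float(norm.sum())
    labels = np.argmax(logd, axis=1)

    k_params = n_comp + (n_comp - 1) + (1 if variance_mode == "tied" else n_comp)
    bic = -2.0 * loglik + k_params * np.log(n)

    return _build_model(x, labels, mu, var, w, family, bic, converged)


def _build_model(
    x: np.ndarray,
    labels: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    w: np.ndarray,
    family: str,
    bic: float,
    converged: bool,
) -> CNClassModel:
    """Compact empty classes, order by center, set centers to member medians."""
    occupied = np.unique(labels)
    centers, variances, weights = [], [], []
    new_labels = np.full_like(labels, -1)
    for new_k, old_k in enumerate(occupied):
        member = labels == old_k
        centers.append(float(np.median(x[member])))
        variances.append(float(var[old_k]))
        weights.append(float(member.mean()))
        new_labels[member] = new_k
    order = np.argsort(centers)
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    centers = np.asarray(centers)[order]
    # merge classes whose member medians coincide (ill-separated components)
    if len(centers) > 1 and not (np.diff(centers) > 0).all():
        keep = np.concatenate([[True], np.diff(centers) > 0])
        remap = np.cumsum(keep) - 1
        new_labels = remap[rank[new_labels]]
        merged = np.unique(new_labels)
        centers = np.array([np.median(x[new_labels == k]) for k in merged])
        variances = np.array(
            [np.asarray(variances)[order][keep][k] for k in merged], dtype=float
        )
        weights = np.array([np.mean(new_labels == k) for k in merged])
    else:
        new_labels = rank[new_labels]
        variances = np.asarray(variances)[order]
        weights = np.asarray(weights)[order]
    weights = weights / weights.sum()
    return CNClassModel(
        centers=centers,
        variances=variances,
        weights=weights,
        labels=new_labels,
        family=family,
        n_comp=len(centers),
        bic=bic,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Model selection with fallback rules
# ---------------------------------------------------------------------------


def _class_intervals_overlap(x: np.ndarray, model: CNClassModel) -> bool:
    """Do the member [min, max] intervals of consecutive classes overlap?"""
    if model.n_comp < 2:
        return False
    bounds = [
        (x[model.labels == k].min(), x[model.labels == k].max())
        for k in range(model.n_comp)
    ]
    return any(bounds[k + 1][0] <= bounds[k][1] for k in range(model.n_comp - 1))


def _split_nonoverlapping(x: np.ndarray, model: CNClassModel) -> CNClassModel:
    """Force non-overlapping classes by cutting at midpoints between centers."""
    cuts = (model.centers[:-1] + model.centers[1:]) / 2.0
    labels = np.digitize(x, cuts)
    return _build_model(
        x,
        labels,
        model.centers,
        model.variances,
        model.weights,
        model.family,
        model.bic,
        model.converged,
    )


def fit_mixture_candidates(
    values: np.ndarray, max_comp: int = 6, seed: int | None = None
) -> list[CNClassModel]:
    """Fit the candidate models for n_comp = 1..max_comp with the tying rules.

    Variances are tied for every component count except 2 and 3, where free
    per-component variances accommodate the wider deletion class; a
    non-converging free fit at 2 or 3 is refit with tied variances.
    """
    x = np.asarray(values, dtype=np.float64)
    fits: list[CNClassModel] = []
    kmax = min(max_comp, np.unique(x).size)
    for k in range(1, kmax + 1):
        mode = "free" if k in (2, 3) else "tied"
        fit = fit_mixture(x, k, variance_mode=mode, family="gaussian", seed=seed)
        if mode == "free" and not fit.converged:
            fit = fit_mixture(x, k, variance_mode="tied", family="gaussian", seed=seed)
        fits.append(fit)
    return fits


def select_model(values: np.ndarray, seed: int | None = None) -> CNClassModel:
    """BIC-select among the 1..6 component candidate fits, with fallbacks.

    The minimum-BIC fit wins; if it failed to converge it is refit as a
    t mixture (longer tails); overlapping class intervals reduce the component
    count by one, and a persisting overlap is resolved by splitting at the
    midpoints between class centers into non-overlapping classes.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise IgC2NError("need at least 2 values to model a locus")
    if np.unique(x).size < 2:
        logger.warning("locus has a single distinct value; trivial 1-class model")
        return fit_mixture(x, 1, variance_mode="tied", seed=seed)

    fits = fit_mixture_candidates(x, seed=seed)
    best = min(fits, key=lambda f: f.bic)
    if not best.converged:
        mode = "free" if best.n_comp in (2, 3) else "tied"
        tfit = fit_mixture(x, best.n_comp, variance_mode=mode, family="t", seed=seed)
        tfit.bic = best.bic  # selection already happened on the Gaussian scale
        best = tfit

    while _class_intervals_overlap(x, best) and best.n_comp > 1:
        k = best.n_comp - 1
        mode = "free" if k in (2, 3) else "tied"
        reduced = fit_mixture(x, k, variance_mode=mode, family="gaussian", seed=seed)
        if not reduced.converged or _class_intervals_overlap(x, reduced):
            best = _split_nonoverlapping(x, reduced if reduced.n_comp > 1 else best)
            break
        best = reduced
    return best


# ---------------------------------------------------------------------------
# Grubbs rescue of rare classes
# ---------------------------------------------------------------------------


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t quantile at level alpha."""
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_rescue(
    values: np.ndarray, model: CNClassModel, alpha: float = 0.05
) -> CNClassModel:
    """Recursive single-outlier rescue of rare copy-number classes.

    Works on the pooled residual view (value minus the centre of its class):
    the most extreme residual is tested with the two-sided Grubbs statistic;
    a rejected sample is promoted to a new singleton class and the scan
    recurses on the remainder until no rejection, or fewer than 3 samples
    remain in the pool. The multiset of values is conserved.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size != model.labels.size:
        raise IgC2NError("model was not fitted on these values")
    if x.size < 3:
        logger.info("Grubbs rescue skipped: n < 3")
        return model

    labels = model.labels.copy()
    centers = model.centers.copy()
    active = np.ones(x.size, dtype=bool)
    promoted: list[int] = []
    while active.sum() >= 3:
        resid = x[active] - centers[labels[active]]
        mean, sd = resid.mean(), resid.std(ddof=1)
        if sd <= 0:
            break
        g = np.abs(resid - mean) / sd
        i_local = int(np.argmax(g))
        if g[i_local] <= grubbs_critical_value(int(active.sum()), alpha):
            break
        idx = np.flatnonzero(active)[i_local]
        promoted.append(int(idx))
        active[idx] = False

    if not promoted:
        return model

    new_labels = labels.copy()
    next_label = model.n_comp
    for idx in promoted:
        new_labels[idx] = next_label
        next_label += 1
    var = np.concatenate([model.variances, np.full(len(promoted), _VAR_FLOOR)])
    w = np.bincount(new_labels, minlength=next_label) / x.size
    mu = np.array(
        [np.median(x[new_labels == k]) if (new_labels == k).any() else np.nan
         for k in range(next_label)]
    )
    logger.info("Grubbs rescue promoted %d sample(s) to singleton classes",
                len(promoted))
    return _build_model(x, new_labels, mu, var, w, model.family, model.bic,
                        model.converged)


def merge_close_classes(
    values: np.ndarray, model: CNClassModel, min_gap: float = 0.25
) -> CNClassModel:
    """Merge adjacent classes whose center gap is below ``min_gap``.

    The smallest genuine 1-CN transition on the log2 scale is the 3-4 gap,
    log2(4/3) ~ 0.415; class gaps well below it cannot represent a copy
    transition and arise from EM over-splitting or from Grubbs singletons
    carved out of the same rare class. Merging is applied greedily to the
    smallest gap first until all gaps are >= ``min_gap``.
    """
    x = np.asarray(values, dtype=np.float64)
    labels = model.labels.copy()
    while True:
        centers = np.array(
            [np.median(x[labels == k]) for k in range(labels.max() + 1)]
        )
        if len(centers) < 2:
            break
        gaps = np.diff(centers)
        i = int(np.argmin(gaps))
        if gaps[i] >= min_gap:
            break
        labels[labels == i + 1] = i
        labels[labels > i + 1] -= 1
    if labels.max() + 1 == model.n_comp:
        return model
    k = labels.max() + 1
    var = np.array(
        [max(np.var(x[labels == j]), _VAR_FLOOR) for j in range(k)]
    )
    mu = np.array([np.median(x[labels == j]) for j in range(k)])
    w = np.bincount(labels, minlength=k) / x.size
    logger.info("merged %d class(es) with sub-transition gaps", model.n_comp - k)
    return _build_model(x, labels, mu, var, w, model.family, model.bic,
                        model.converged)


def one_cn_differences(
    model: CNClassModel, locus_id: str = ""
) -> OneCNDifference:
    """Consecutive-class centre gaps (per-class medians), the 1-CN differences.

    A 1-class model yields empty diffs; such loci are non-polymorphic and are
    dropped downstream.
    """
    if model.n_comp < 2:
        return OneCNDifference(locus_id, np.empty(0))
    return OneCNDifference(locus_id, np.diff(model.centers))


class CNClassDetector(BaseEstimator):
    """Per-locus copy-number class detector (scikit-learn estimator interface).

    Fits the BIC-selected constrained mixture to a per-sample summary-signal
    vector, applies the Grubbs rare-class rescue, then merges class gaps too
    small to be a real copy transition (``merge_min_gap``, default 0.25, set
    below the smallest modeled transition gap log2(4/3) ~ 0.415).

    Attributes
    ----------
    model_ : CNClassModel
    diffs_ : OneCNDifference
    labels_ : ndarray, per-sample class index
    """

    def __init__(
        self,
        grubbs_alpha: float = 0.05,
        merge_min_gap: float = 0.25,
        random_state: int | None = None,
    ):
        self.grubbs_alpha = grubbs_alpha
        self.merge_min_gap = merge_min_gap
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "CNClassDetector":
        x = np.asarray(X, dtype=np.float64).ravel()
        model = select_model(x, seed=self.random_state)
        model = grubbs_rescue(x, model, alpha=self.grubbs_alpha)
        if self.merge_min_gap > 0:
            model = merge_close_classes(x, model, min_gap=self.merge_min_gap)
        self.model_ = model
        self.diffs_ = one_cn_differences(model)
        self.labels_ = model.labels
        return self

    def predict(self, X=None) -> np.ndarray:
        return self.labels_
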