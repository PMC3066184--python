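"""Step 3 — reference-model bias estimation and integer copy-number calls.

Normalizing array intensities against a reference set removes marker-specific
hybridization but shifts every log2 ratio by the (log) average copy number of
the reference at that locus: when the reference contains carriers, the whole
locus is displaced and relative CN classes no longer sit at their theoretical
log2 positions. This module converts the relative classes of Step 2 into
integer genotypes by combining three pieces of evidence:

* the *expected direction of bias* — a dominant extreme class whose median is
  within a window of 0 is hypothesized to be CN 2 (frequent deletions push the
  reference down and hence the data up, and vice versa for gains);
* the magnitudes of the 1-CN class differences, classified against a
  four-component mixture of the 0-1, 1-2, 2-3 and 3-4 transition gaps
  (theoretical log2 spacings 2.0, 1.0, log2(3/2), log2(4/3));
* a Hardy–Weinberg *zero-presence* check: the observed CN 0 count is compared
  with the expected homozygous-deletion proportion p^2 by an exact binomial
  test before a CN 0 labelling is accepted.

Precedence when the three disagree: anchor > difference assignment >
zero-test veto.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core_io import (
    CandidateLocus,
    CNClassModel,
    GenotypedLocus,
    IgC2NError,
    OneCNDifference,
    logger,
)
from .genotyping import fit_mixture

__all__ = [
    "THEORETICAL_DIFF_CENTERS",
    "DiffMixture",
    "AssignmentMatrix",
    "fit_diff_mixture",
    "expected_bias_direction",
    "zero_presence_test",
    "assign_genotypes",
    "UnresolvedLocus",
]

# No-noise log2 gaps of the 0-1, 1-2, 2-3 and 3-4 copy transitions. The 0-1
# gap assumes the CN0 signal floors at ~1/4 copy of background (see simulator).
THEORETICAL_DIFF_CENTERS = np.array([2.0, 1.0, np.log2(3 / 2), np.log2(4 / 3)])
TRANSITION_LABELS = ("0-1", "1-2", "2-3", "3-4")


@dataclass
class DiffMixture:
    """Four-component mixture over 1-CN difference magnitudes.

    Component order is fixed to the transition labels 0-1, 1-2, 2-3, 3-4, so
    centers are strictly decreasing on the log2 scale.
    """

    centers: np.ndarray  # length 4, decreasing
    variances: np.ndarray
    weights: np.ndarray
    fallback: bool = False  # True when fixed theoretical centers were used

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.centers) != 4:
            raise IgC2NError("diff mixture must have exactly 4 components")
        if not (np.diff(self.centers) < 0).all():
            raise IgC2NError("diff mixture centers must be strictly decreasing")

    def membership(self, diffs: np.ndarray) -> np.ndarray:
        """Row-normalized membership probabilities, shape (len(diffs), 4)."""
        d = np.asarray(diffs, dtype=np.float64)
        dens = self.weights[None, :] * stats.norm.pdf(
            d[:, None], self.centers[None, :], np.sqrt(self.variances)[None, :]
        )
        dens = np.maximum(dens, 1e-300)
        return dens / dens.sum(axis=1, keepdims=True)


@dataclass
class AssignmentMatrix:
    """(k-1) x 4 membership probabilities of each observed diff per transition."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise IgC2NError("assignment matrix must be (k-1) x 4")
        if self.probs.shape[0] > 4:
            raise IgC2NError("more than 4 class gaps cannot be assigned")


@dataclass
class UnresolvedLocus:
    """A locus whose transition assignment could not be made consistent."""

    locus_id: str
    reason: str


def fit_diff_mixture(
    all_diffs: np.ndarray,
    min_pooled: int = 20,
    fallback_variance: float = 0.01,
    seed: int | None = None,
) -> DiffMixture:
    """Fit the 4-component transition-gap mixture to pooled 1-CN differences.

    EM is initialized at the theoretical log2 transition gaps; with fewer than
    ``min_pooled`` observed differences (or a fit that loses the label
    ordering) the fixed theoretical centers are used instead, with the
    configured variance.
    """
    d = np.asarray(all_diffs, dtype=np.float64)
    fallback = DiffMixture(
        THEORETICAL_DIFF_CENTERS.copy(),
        np.full(4, fallback_variance),
        np.full(4, 0.25),
        fallback=True,
    )
    if d.size < min_pooled:
        logger.warning(
            "only %d pooled 1-CN differences (< %d); using theoretical centers",
            d.size,
            min_pooled,
        )
        return fallback

    # Each component IS one copy transition: its center may drift with
    # platform compression but must not migrate onto a neighbouring
    # transition, so means are clipped to the theoretical gap +/- 0.08
    # (under half the smallest inter-transition spacing, 0.585 - 0.415).
    # A variance floor keeps components from collapsing to delta spikes.
    center_slack = 0.08
    var_floor = 1e-3
    mu = THEORETICAL_DIFF_CENTERS.copy()
    var = np.full(4, fallback_variance)
    w = np.full(4, 0.25)
    for _ in range(500):
        dens = w[None, :] * stats.norm.pdf(d[:, None], mu[None, :], np.sqrt(var)[None, :])
        dens = np.maximum(dens, 1e-300)
        r = dens / dens.sum(axis=1, keepdims=True)
        rw = r.sum(axis=0)
        new_w = rw / d.size
        # keep starved components anchored at their theoretical gap
        starved = rw < 0.5
        new_mu = np.where(
            starved, THEORETICAL_DIFF_CENTERS, (r * d[:, None]).sum(axis=0) / np.maximum(rw, 1e-12)
        )
        new_mu = np.clip(
            new_mu,
            THEORETICAL_DIFF_CENTERS - center_slack,
            THEORETICAL_DIFF_CENTERS + center_slack,
        )
        new_var = np.where(
            starved,
            fallback_variance,
            np.maximum((r * (d[:, None] - new_mu[None, :]) ** 2).sum(axis=0)
                       / np.maximum(rw, 1e-12), var_floor),
        )
        if np.allclose(new_mu, mu, atol=1e-8) and np.allclose(new_var, var, atol=1e-10):
            mu, var, w = new_mu, new_var, np.maximum(new_w, 1e-6)
            break
        mu, var, w = new_mu, new_var, np.maximum(new_w, 1e-6)
    w = w / w.sum()
    if not (np.diff(mu) < 0).all():
        logger.warning("diff-mixture fit lost label order; using theoretical centers")
        return fallback
    return DiffMixture(mu, var, w)


def expected_bias_direction(
    model: CNClassModel, window: float = 0.25
) -> int | None:
    """Anchor heuristic: which class, if any, is hypothesized to be CN 2.

    Returns the index of the major (most frequent) class iff it is an extreme
    class (first or last in center order) and its median is within ``window``
    of 0 — the situation produced by frequent one-sided polymorphisms biasing
    the reference. Otherwise None.
    """
    major = int(np.argmax(model.weights))
    if major not in (0, model.n_comp - 1):
        return None
    if abs(model.centers[major]) > window:
        return None
    return major


def zero_presence_test(
    class_counts: np.ndarray, candidate_zero: int = 0
) -> tuple[float, bool]:
    """Exact two-sided binomial test of the CN 0 count against HW p^2.

    ``class_counts`` are ordered counts for CN 0, 1, 2 (further classes are
    ignored for the allele count). The deletion-allele frequency is
    p = (2 n0 + n1) / (2 n_total); support means p-value >= 0.05.
    """
    counts = np.asarray(class_counts, dtype=np.int64)
    n_total = int(counts.sum())
    if n_total == 0:
        raise IgC2NError("zero-presence test needs at least one sample")
    n0 = int(counts[candidate_zero])
    n1 = int(counts[candidate_zero + 1]) if candidate_zero + 1 < len(counts) else 0
    p_allele = (2.0 * n0 + n1) / (2.0 * n_total)
    if p_allele == 0.0:
        return 1.0, True
    res = stats.binomtest(n0, n_total, p_allele**2, alternative="two-sided")
    pval = float(res.pvalue)
    return pval, pval >= 0.05


def _greedy_assign(probs: np.ndarray) -> np.ndarray:
    """Greedy global-max assignment with column removal.

    Ties break by probability, then smaller row index, then smaller column
    index (argmax on the flattened matrix scans in that order).
    """
    p = probs.copy()
    n_rows = p.shape[0]
    cols = np.full(n_rows, -1, dtype=np.int64)
    for _ in range(n_rows):
        flat = int(np.argmax(p))
        r, c = divmod(flat, 4)
        cols[r] = c
        p[r, :] = -np.inf
        p[:, c] = -np.inf
    return cols


def assign_genotypes(
    model: CNClassModel,
    diffs: OneCNDifference,
    diff_mix: DiffMixture,
    anchor: int | None = None,
    locus: CandidateLocus | None = None,
    major_freq_threshold: float = 0.05,
    zero_alpha: float = 0.05,
) -> GenotypedLocus | UnresolvedLocus:
    """Turn relative CN classes into integer genotypes and estimate the bias.

    The (k-1) x 4 membership matrix of the observed gaps is resolved by greedy
    global-max selection with column removal; consecutive classes force the
    transition labels to be consecutive, which pins the integer CN of every
    class up to feasibility. An anchor class (expected-direction-of-bias
    heuristic) overrides the offset so that class is CN 2; absent an anchor, a
    rejected zero-presence test vetoes a CN 0 labelling by shifting the ladder
    up one copy when feasible.

    The bias estimate is the median of the centering class minus the
    theoretical log2 ratio of its assigned copy number, log2(cn / 2).
    """
    k = model.n_comp
    locus_id = diffs.locus_id or (locus.name() if locus is not None else "")
    if k < 2:
        return UnresolvedLocus(locus_id, "single CN class (non-polymorphic)")
    if k - 1 > 4:
        return UnresolvedLocus(locus_id, f"{k} classes exceed the 0-4 CN ladder")

    probs = diff_mix.membership(diffs.diffs)
    AssignmentMatrix(probs)  # validates shape
    cols = _greedy_assign(probs)

    # Consecutive classes need consecutive transition columns: cols[i] == o + i.
    offsets = cols - np.arange(k - 1)
    if np.unique(offsets).size == 1:
        offset = int(offsets[0])
    else:
        # keep the highest-probability row, force the rest to adjacent columns
        row_p = probs[np.arange(k - 1), cols]
        best_row = int(np.argmax(row_p))
        offset = int(cols[best_row] - best_row)
        logger.info(
            "locus %s: inconsistent transition labels %s resolved around row %d",
            locus_id, cols.tolist(), best_row,
        )
    if offset < 0 or offset + (k - 1) > 4:
        return UnresolvedLocus(
            locus_id, f"transition labels imply CN outside 0..4 (offset {offset})"
        )

    counts = model.class_counts()
    n_total = counts.sum()

    if anchor is not None:
        anchored = 2 - anchor  # class i -> CN anchored + i
        if anchored >= 0 and anchored + (k - 1) <= 4:
            offset = anchored
    cn_per_class = offset + np.arange(k)

    # zero-presence veto (only when the anchor did not fix the ladder)
    if anchor is None and cn_per_class[0] == 0 and k >= 2:
        _, supported = zero_presence_test(counts, candidate_zero=0)
        if not supported and offset + 1 + (k - 1) <= 4:
            logger.info("locus %s: CN 0 labelling vetoed by HW zero-presence test",
                        locus_id)
            offset += 1
            cn_per_class = offset + np.arange(k)

    cn_calls = cn_per_class[model.labels]

    # centering class: CN 2 if frequent enough, else most frequent, else
    # second most frequent when the most frequent is CN 0
    freq = counts / n_total
    center_class: int | None = None
    if 2 in cn_per_class:
        c2 = int(np.flatnonzero(cn_per_class == 2)[0])
        if freq[c2] > major_freq_threshold:
            center_class = c2
    if center_class is None:
        by_freq = np.argsort(-freq, kind="stable")
        center_class = int(by_freq[0])
        if cn_per_class[center_class] == 0 and len(by_freq) > 1:
            center_class = int(by_freq[1])
    cn_c = cn_per_class[center_class]
    expected = np.log2(cn_c / 2.0) if cn_c > 0 else np.log2(0.25 / 2.0)
    bias = float(model.centers[center_class] - expected)

    major = int(np.argmax(freq))
    incidence = float(1.0 - freq[major])
    maf = min(incidence, 0.5)
    if incidence > 0.05:
        present = freq > 0
        has_del = bool((cn_per_class[present] < 2).any())
        has_gain = bool((cn_per_class[present] > 2).any())
        if has_del and has_gain:
            ptype = "del-gain"
        elif has_gain:
            ptype = "gain"
        else:
            ptype = "del"
    else:
        ptype = "low-frequency"

    return GenotypedLocus(
        locus=locus
        if locus is not None
        else CandidateLocus("NA", 1, 1, np.array([0]), 1.0),
        cn_calls=cn_calls,
        bias_estimate=bias,
        maf=maf,
        polymorphism_type=ptype,
    )


class ReferenceBiasGenotyper(BaseEstimator):
    """Cohort-level genotyper: pools 1-CN differences, fits the transition
    mixture, and assigns integer genotypes to every locus model.

    Parameters
    ----------
    anchor_window : float, default 0.25
        Half-width of the near-zero window for the CN 2 anchor heuristic.
    min_pooled_diffs : int, default 20
        Below this pooled-difference count the transition mixture falls back
        to the theoretical log2 gaps.

    Attributes
    ----------
    diff_mixture_ : DiffMixture
    genotyped_loci_ : list of GenotypedLocus
    unresolved_ : list of UnresolvedLocus
    """

    def __init__(
        self,
        anchor_window: float = 0.25,
        min_pooled_diffs: int = 20,
        fallback_variance: float = 0.01,
        major_freq_threshold: float = 0.05,
        random_state: int | None = None,
    ):
        self.anchor_window = anchor_window
        self.min_pooled_diffs = min_pooled_diffs
        self.fallback_variance = fallback_variance
        self.major_freq_threshold = major_freq_threshold
        self.random_state = random_state

    def fit(
        self,
        models: list[CNClassModel],
        loci: list[CandidateLocus] | None = None,
    ) -> "ReferenceBiasGenotyper":
        loci = loci if loci is not None else [None] * len(models)
        from .genotyping import one_cn_differences

        all_diffs = [
            one_cn_differences(m, locus.name() if locus is not None else f"locus{i}")
            for i, (m, locus) in enumerate(zip(models, loci))
        ]
        pooled = np.concatenate([d.diffs for d in all_diffs]) if all_diffs else np.empty(0)
        self.diff_mixture_ = fit_diff_mixture(
            pooled,
            min_pooled=self.min_pooled_diffs,
            fallback_variance=self.fallback_variance,
            seed=self.random_state,
        )
        self.genotyped_loci_ = []
        self.unresolved_ = []
        for model, d, locus in zip(models, all_diffs, loci):
            anchor = expected_bias_direction(model, window=self.anchor_window)
            out = assign_genotypes(
                model,
                d,
                self.diff_mixture_,
                anchor=anchor,
                locus=locus,
                major_freq_threshold=self.major_freq_threshold,
            )
            if isinstance(out, UnresolvedLocus):
                self.unresolved_.append(out)
            else:
                self.genotyped_loci_.append(out)
        return self
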