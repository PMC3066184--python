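"""Step 1 — detection of candidate CNV loci.

A cross-sample score counts, for every marker, how many individuals have a
log2 ratio beyond a dichotomization threshold ``t``. Genome-wide significance
of the score is assessed either against a Binomial(N, p0) null — p0 being the
genome-wide average score per sample — or against a permutation null in which
each sample's dichotomized marker vector is permuted across markers. Marker
p-values are converted to Benjamini–Hochberg q-values, and maximal runs of
consecutive sub-threshold markers become candidate loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core_io import CandidateLocus, IgC2NError, IntensityMatrix, MarkerMap, logger

__all__ = [
    "ScoreVector",
    "SignificanceResult",
    "dichotomize",
    "score_vector",
    "estimate_p0",
    "binomial_pvalues",
    "permutation_pvalues",
    "bh_qvalues",
    "call_candidate_loci",
    "CNVDetector",
]


@dataclass
class ScoreVector:
    """Per-marker count of individuals beyond the threshold."""

    S: np.ndarray  # int, length M, 0 <= S_j <= N
    t: float
    N: int

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.int64)
        if self.S.size and (self.S.min() < 0 or self.S.max() > self.N):
            raise IgC2NError("scores must lie in [0, N]")


@dataclass
class SignificanceResult:
    """Per-marker p- and q-values with the null used to produce them."""

    p: np.ndarray
    q: np.ndarray | None
    method: str  # "binomial" | "permutation"
    p0: float | None = None
    n_perm: int | None = None


def dichotomize(
    matrix: IntensityMatrix, t: float, mode: str = "two_sided"
) -> np.ndarray:
    """Binary N x M indicator of log2 ratios beyond ``t`` (strict inequality)."""
    if t <= 0:
        raise IgC2NError(f"dichotomization threshold must be positive, got {t}")
    v = matrix.values
    if mode == "two_sided":
        b = np.abs(v) > t
    elif mode == "gain_only":
        b = v > t
    elif mode == "loss_only":
        b = v < -t
    else:
        raise IgC2NError(f"unknown dichotomization mode {mode!r}")
    return b.astype(np.int8)


def score_vector(binary: np.ndarray, t: float = np.nan) -> ScoreVector:
    """Column sums of the dichotomized matrix."""
    binary = np.asarray(binary)
    if not np.isin(binary, (0, 1)).all():
        raise IgC2NError("score_vector input must be binary")
    return ScoreVector(binary.sum(axis=0, dtype=np.int64), t, binary.shape[0])


def estimate_p0(S: ScoreVector) -> float:
    """Null per-marker event probability: the average score per sample.

    p0 = sum_j S_j / (M * N) = mean(S) / N, averaged across all markers.
    """
    if S.S.size < 1 or S.N < 1:
        raise IgC2NError("need at least one marker and one sample")
    return float(S.S.sum()) / (S.S.size * S.N)


def binomial_pvalues(S: ScoreVector, p0: float) -> SignificanceResult:
    """Upper-tail binomial p-values: p_j = P(X >= S_j), X ~ Binomial(N, p0)."""
    if not 0.0 <= p0 <= 1.0:
        raise IgC2NError(f"p0 must be in [0, 1], got {p0}")
    # sf(k-1) = P(X >= k); S_j = 0 gives exactly 1.
    p = stats.binom.sf(S.S - 1, S.N, p0)
    return SignificanceResult(p=np.asarray(p, dtype=np.float64), q=None,
                              method="binomial", p0=p0)


def permutation_pvalues(
    matrix: IntensityMatrix,
    t: float,
    n_perm: int,
    seed: int | None = 0,
    mode: str = "two_sided",
) -> SignificanceResult:
    """Permutation p-values from a genome-wide pooled null score distribution.

    For each replicate every sample's dichotomized marker vector is permuted
    independently across markers; all permuted column scores (all markers, all
    replicates) are pooled into one null distribution. An add-one correction
    keeps p strictly positive: p_j = (1 + #{null >= S_j}) / (1 + #null).
    """
    if n_perm < 1:
        raise IgC2NError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    binary = dichotomize(matrix, t, mode=mode)
    S = binary.sum(axis=0, dtype=np.int64)
    n_samples, n_markers = binary.shape

    null_counts = np.zeros(n_samples + 1, dtype=np.int64)  # histogram of null S
    for _ in range(n_perm):
        permuted = rng.permuted(binary, axis=1)
        null_s = permuted.sum(axis=0, dtype=np.int64)
        null_counts += np.bincount(null_s, minlength=n_samples + 1)

    # tail[k] = #{null >= k}
    tail = np.concatenate([np.cumsum(null_counts[::-1])[::-1], [0]])
    total = null_counts.sum()
    p = (1.0 + tail[S]) / (1.0 + total)
    return SignificanceResult(p=p, q=None, method="permutation", n_perm=n_perm)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, capped at 1, in input order."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise IgC2NError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_candidate_loci(
    q: np.ndarray,
    mmap: MarkerMap,
    q_threshold: float = 0.10,
    breakpoints: str = "marker",
    exclude_xy: bool = True,
) -> list[CandidateLocus]:
    """Merge maximal runs of FDR-significant markers into candidate loci.

    Runs never cross a chromosome boundary; single-marker runs are allowed (no
    restriction on the number of covering markers or on locus size). In
    ``midpoint`` mode breakpoints are extended halfway to the neighbouring
    non-significant markers, truncated at chromosome ends.
    """
    if not 0.0 < q_threshold < 1.0:
        raise IgC2NError(f"q_threshold must be in (0, 1), got {q_threshold}")
    if breakpoints not in ("marker", "midpoint"):
        raise IgC2NError(f"unknown breakpoint mode {breakpoints!r}")
    q = np.asarray(q, dtype=np.float64)
    if q.size != len(mmap):
        raise IgC2NError("q-vector not aligned to marker map")

    sig = q <= q_threshold
    if exclude_xy:
        sig = sig & ~mmap.is_sex_chromosome

    loci: list[CandidateLocus] = []
    chroms = mmap.chromosome.astype(str)
    pos = mmap.position
    j = 0
    M = len(mmap)
    while j < M:
        if not sig[j]:
            j += 1
            continue
        k = j
        while k + 1 < M and sig[k + 1] and chroms[k + 1] == chroms[j]:
            k += 1
        start, end = int(pos[j]), int(pos[k])
        if breakpoints == "midpoint":
            if j > 0 and chroms[j - 1] == chroms[j]:
                start = int(np.floor((pos[j - 1] + pos[j]) / 2))
            if k + 1 < M and chroms[k + 1] == chroms[k]:
                end = int(np.ceil((pos[k] + pos[k + 1]) / 2))
        loci.append(
            CandidateLocus(
                chromosome=chroms[j],
                start=start,
                end=end,
                marker_indices=np.arange(j, k + 1),
                q_min=float(q[j : k + 1].min()),
            )
        )
        j = k + 1
    logger.info(
        "candidate loci: %d significant markers -> %d loci", int(sig.sum()), len(loci)
    )
    return loci


class CNVDetector(BaseEstimator):
    """Cross-sample CNV locus detector (scikit-learn estimator interface).

    Parameters
    ----------
    marker_map : MarkerMap
        Coordinate authority for the columns of the fitted matrix.
    t : float, default 0.3
        Dichotomization threshold on the log2-ratio scale. The default sits
        halfway between the diploid baseline (0) and a single-copy gain
        (log2(3/2) ~ 0.585); raise it on noisy, unsegmented data.
    mode : {"two_sided", "gain_only", "loss_only"}
    test : {"binomial", "permutation"}
        The binomial null is cheap and suits large marker panels; the
        permutation null is exact under exchangeability but costs
        ``n_perm`` passes over the matrix.
    n_perm : int, default 1000
    q_threshold : float, default 0.10
        BH FDR threshold for calling significant markers.
    breakpoints : {"marker", "midpoint"}
    exclude_xy : bool, default True
    random_state : int, default 0

    Attributes
    ----------
    scores_ : ScoreVector
    p0_ : float (binomial test only)
    pvalues_, qvalues_ : ndarray of shape (n_markers,)
    loci_ : list of CandidateLocus
    """

    def __init__(
        self,
        marker_map: MarkerMap,
        t: float = 0.3,
        mode: str = "two_sided",
        test: str = "binomial",
        n_perm: int = 1000,
        q_threshold: float = 0.10,
        breakpoints: str = "marker",
        exclude_xy: bool = True,
        random_state: int = 0,
    ):
        self.marker_map = marker_map
        self.t = t
        self.mode = mode
        self.test = test
        self.n_perm = n_perm
        self.q_threshold = q_threshold
        self.breakpoints = breakpoints
        self.exclude_xy = exclude_xy
        self.random_state = random_state

    def fit(self, X: IntensityMatrix | np.ndarray, y=None) -> "CNVDetector":
        matrix = (
            X
            if isinstance(X, IntensityMatrix)
            else IntensityMatrix([f"S{i}" for i in range(len(X))], np.asarray(X))
        )
        if matrix.n_markers != len(self.marker_map):
            raise IgC2NError("matrix columns do not match the marker map")
        binary = dichotomize(matrix, self.t, mode=self.mode)
        self.scores_ = score_vector(binary, t=self.t)
        if self.test == "binomial":
            self.p0_ = estimate_p0(self.scores_)
            res = binomial_pvalues(self.scores_, self.p0_)
        elif self.test == "permutation":
            res = permutation_pvalues(
                matrix, self.t, self.n_perm, seed=self.random_state, mode=self.mode
            )
        else:
            raise IgC2NError(f"unknown test {self.test!r}")
        self.pvalues_ = res.p
        self.qvalues_ = bh_qvalues(res.p)
        self.loci_ = call_candidate_loci(
            self.qvalues_,
            self.marker_map,
            q_threshold=self.q_threshold,
            breakpoints=self.breakpoints,
            exclude_xy=self.exclude_xy,
        )
        return self

    def significance_table(self):
        """TSV-ready per-marker table (marker_id, S, p, q)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "marker_id": self.marker_map.marker_id,
                "S": self.scores_.S,
                "p": self.pvalues_,
                "q": self.qvalues_,
            }
        )
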