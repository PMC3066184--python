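"""End-to-end pipeline: detection -> CN class fitting -> bias-corrected calls."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .bias_correction import ReferenceBiasGenotyper, UnresolvedLocus
from .core_io import (
    CandidateLocus,
    GenotypedLocus,
    IntensityMatrix,
    MarkerMap,
    logger,
)
from .detection import CNVDetector
from .genotyping import CNClassDetector, summarize_locus


class CNVGenotyper(BaseEstimator):
    """Genotype a list of candidate loci on a cohort matrix.

    For every locus: summarize to a per-sample median, fit the BIC-selected
    constrained mixture with Grubbs rescue, drop loci left with a single CN
    class (non-polymorphic), pool the 1-CN class differences across the run,
    and assign bias-corrected integer genotypes.

    Attributes
    ----------
    models_ : list of CNClassModel, for retained (polymorphic) loci
    genotyped_loci_ : list of GenotypedLocus
    unresolved_ : list of UnresolvedLocus
    n_dropped_monomorphic_ : int
    """

    def __init__(
        self,
        grubbs_alpha: float = 0.05,
        anchor_window: float = 0.25,
        min_pooled_diffs: int = 20,
        random_state: int | None = None,
    ):
        self.grubbs_alpha = grubbs_alpha
        self.anchor_window = anchor_window
        self.min_pooled_diffs = min_pooled_diffs
        self.random_state = random_state

    def fit(
        self, X: IntensityMatrix, loci: list[CandidateLocus]
    ) -> "CNVGenotyper":
        models, kept = [], []
        n_mono = 0
        for locus in loci:
            signal = summarize_locus(X, locus)
            det = CNClassDetector(
                grubbs_alpha=self.grubbs_alpha, random_state=self.random_state
            ).fit(signal.values)
            if det.model_.n_comp < 2:
                n_mono += 1
                continue
            models.append(det.model_)
            kept.append(locus)
        logger.info(
            "genotyping: %d candidate loci, %d polymorphic retained, %d dropped",
            len(loci), len(kept), n_mono,
        )
        corrector = ReferenceBiasGenotyper(
            anchor_window=self.anchor_window,
            min_pooled_diffs=self.min_pooled_diffs,
            random_state=self.random_state,
        ).fit(models, kept)
        self.models_ = models
        self.kept_loci_ = kept
        self.diff_mixture_ = corrector.diff_mixture_
        self.genotyped_loci_ = corrector.genotyped_loci_
        self.unresolved_ = corrector.unresolved_
        self.n_dropped_monomorphic_ = n_mono
        return self


class IgC2NPipeline(BaseEstimator):
    """Full three-step pipeline on one cohort matrix.

    ``fit`` runs detection, per-locus CN class fitting and bias correction;
    fitted attributes expose each stage's output.
    """

    def __init__(
        self,
        marker_map: MarkerMap,
        t: float = 0.3,
        test: str = "binomial",
        q_threshold: float = 0.10,
        breakpoints: str = "marker",
        exclude_xy: bool = True,
        grubbs_alpha: float = 0.05,
        anchor_window: float = 0.25,
        random_state: int = 0,
    ):
        self.marker_map = marker_map
        self.t = t
        self.test = test
        self.q_threshold = q_threshold
        self.breakpoints = breakpoints
        self.exclude_xy = exclude_xy
        self.grubbs_alpha = grubbs_alpha
        self.anchor_window = anchor_window
        self.random_state = random_state

    def fit(self, X: IntensityMatrix, y=None) -> "IgC2NPipeline":
        self.detector_ = CNVDetector(
            self.marker_map,
            t=self.t,
            test=self.test,
            q_threshold=self.q_threshold,
            breakpoints=self.breakpoints,
            exclude_xy=self.exclude_xy,
            random_state=self.random_state,
        ).fit(X)
        self.genotyper_ = CNVGenotyper(
            grubbs_alpha=self.grubbs_alpha,
            anchor_window=self.anchor_window,
            random_state=self.random_state,
        ).fit(X, self.detector_.loci_)
        self.loci_ = self.detector_.loci_
        self.genotyped_loci_ = self.genotyper_.genotyped_loci_
        return self

    def cn_matrix(self) -> np.ndarray:
        """Samples x genotyped-loci integer copy-number matrix."""
        return np.column_stack([g.cn_calls for g in self.genotyped_loci_])
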