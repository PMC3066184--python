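"""Scoring detections and genotypes: power, FPR, overlap rules, trios,
cross-platform validation, and the simulation power/FPR study harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CandidateLocus, IgC2NError, TrioTable, logger
from .detection import CNVDetector
from .simulator import SimConfig, TrueCNV, make_marker_map, make_truth_layout, simulate_dataset

__all__ = [
    "overlaps_1bp",
    "dataset_fpr",
    "empirical_power",
    "cnv_equal",
    "trio_discordance",
    "cross_platform_validate",
    "PowerStudyResult",
    "run_power_study",
]


def overlaps_1bp(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """1-bp overlap of two 1-based inclusive intervals on the same chromosome."""
    return max(a[0], b[0]) <= min(a[1], b[1])


def dataset_fpr(detected: list, truth: list) -> float:
    """Fraction of detected loci with no 1-bp overlap to any truth CNV."""
    if not detected:
        logger.warning("no detections; FPR reported as 0")
        return 0.0
    truth_iv = [(t.chromosome, t.start, t.end) for t in truth]
    n_false = 0
    for d in detected:
        hit = any(
            d.chromosome == c and overlaps_1bp((d.start, d.end), (s, e))
            for c, s, e in truth_iv
        )
        n_false += not hit
    return n_false / len(detected)


def empirical_power(
    detections_per_dataset: list[list], truth: list
) -> np.ndarray:
    """Per-CNV fraction of datasets in which the CNV is detected (1-bp rule)."""
    if not detections_per_dataset:
        raise IgC2NError("need at least one dataset")
    hits = np.zeros(len(truth))
    for detected in detections_per_dataset:
        for i, t in enumerate(truth):
            if any(
                d.chromosome == t.chromosome
                and overlaps_1bp((d.start, d.end), (t.start, t.end))
                for d in detected
            ):
                hits[i] += 1
    return hits / len(detections_per_dataset)


def cnv_equal(
    target: tuple[int, int], reference: tuple[int, int], frac: float = 0.5
) -> bool:
    """Equality rule: the target covers >= ``frac`` of the reference's bases."""
    if not 0.0 < frac <= 1.0:
        raise IgC2NError(f"frac must be in (0, 1], got {frac}")
    overlap = min(target[1], reference[1]) - max(target[0], reference[0]) + 1
    ref_len = reference[1] - reference[0] + 1
    return overlap > 0 and overlap / ref_len >= frac


def trio_discordance(
    cn_matrix: pd.DataFrame,
    trios: TrioTable,
    polymorphism: str = "non_major",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mendelian discordance of CN calls in mother-father-child trios.

    A trio is discordant at a CNV when the child carries a polymorphism that
    neither parent carries. Polymorphism means a CN different from the locus
    major class (``polymorphism="non_major"``, default) or CN != 2
    (``polymorphism="non_diploid"``).

    Returns (per-CNV table, per-trio table); each reports the discordant
    count over informative trios (child polymorphic) and over all scored
    trios, since either denominator is defensible.
    """
    if polymorphism not in ("non_major", "non_diploid"):
        raise IgC2NError(f"unknown polymorphism rule {polymorphism!r}")
    usable = []
    for child, mother, father in trios.rows:
        if all(s in cn_matrix.index for s in (child, mother, father)):
            usable.append((child, mother, father))
        else:
            logger.warning("trio (%s, %s, %s) skipped: sample missing",
                           child, mother, father)

    per_cnv_rows = []
    child_poly = {c: 0 for c, _, _ in usable}
    child_disc = {c: 0 for c, _, _ in usable}
    for locus in cn_matrix.columns:
        calls = cn_matrix[locus]
        if polymorphism == "non_major":
            major = calls.mode().iloc[0]
        else:
            major = 2
        informative = discordant = 0
        for child, mother, father in usable:
            if calls[child] == major:
                continue
            informative += 1
            child_poly[child] += 1
            if calls[mother] == major and calls[father] == major:
                discordant += 1
                child_disc[child] += 1
        per_cnv_rows.append(
            {
                "locus": locus,
                "informative_trios": informative,
                "discordant_trios": discordant,
                "rate_informative": discordant / informative if informative else np.nan,
                "rate_all_trios": discordant / len(usable) if usable else np.nan,
            }
        )
    per_trio_rows = [
        {
            "child_id": c,
            "informative_cnvs": child_poly[c],
            "discordant_cnvs": child_disc[c],
            "fraction_discordant": child_disc[c] / child_poly[c]
            if child_poly[c]
            else np.nan,
        }
        for c, _, _ in usable
    ]
    return pd.DataFrame(per_cnv_rows), pd.DataFrame(per_trio_rows)


def _iqr_outlier_sign(values: np.ndarray) -> np.ndarray:
    """+1 / -1 / 0 per sample: outside 1.5 x IQR above / below / neither."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    out = np.zeros(len(values), dtype=np.int64)
    out[values > q3 + 1.5 * iqr] = 1
    out[values < q1 - 1.5 * iqr] = -1
    return out


def cross_platform_validate(
    discovery_summary: np.ndarray,
    companion_signal: np.ndarray,
    discovery_calls: np.ndarray | None = None,
) -> tuple[str, float]:
    """Validate a locus against companion-platform markers at the same position.

    ``companion_signal`` is (n_samples,) or (n_samples, n_companion_markers).
    The locus is ``validated`` when the best Pearson correlation with the
    discovery summary signal is >= 0.5; for 0.3 <= r < 0.5 the companion's
    1.5-IQR outliers are classified as gains/losses by sign and compared with
    the discovery side (``discovery_calls`` integer CN if given, else the
    discovery signal's own IQR outliers) — concordance upgrades the locus to
    ``borderline_validated``. Anything else is ``not_validated``.
    """
    x = np.asarray(discovery_summary, dtype=np.float64)
    comp = np.atleast_2d(np.asarray(companion_signal, dtype=np.float64))
    if comp.shape[0] != x.size:
        comp = comp.T
    if comp.shape[0] != x.size or x.size < 3:
        raise IgC2NError("need >= 3 shared samples with matching shapes")
    if np.std(x) == 0:
        logger.warning("discovery signal has zero variance; not validated")
        return "not_validated", np.nan

    best_r, best_j = -np.inf, 0
    for j in range(comp.shape[1]):
        if np.std(comp[:, j]) == 0:
            continue
        r = float(stats.pearsonr(x, comp[:, j])[0])
        if r > best_r:
            best_r, best_j = r, j
    if not np.isfinite(best_r):
        return "not_validated", np.nan
    if best_r >= 0.5:
        return "validated", best_r
    if best_r < 0.3:
        return "not_validated", best_r

    comp_sign = _iqr_outlier_sign(comp[:, best_j])
    if discovery_calls is not None:
        calls = np.asarray(discovery_calls)
        disc_gain = bool((calls > 2).any())
        disc_loss = bool((calls < 2).any())
    else:
        disc_sign = _iqr_outlier_sign(x)
        disc_gain = bool((disc_sign > 0).any())
        disc_loss = bool((disc_sign < 0).any())
    comp_gain = bool((comp_sign > 0).any())
    comp_loss = bool((comp_sign < 0).any())
    concordant = (comp_gain and disc_gain) or (comp_loss and disc_loss)
    return ("borderline_validated" if concordant else "not_validated"), best_r


# ---------------------------------------------------------------------------
# Simulation power / FPR study
# ---------------------------------------------------------------------------


@dataclass
class PowerStudyResult:
    """Per-CNV power plus per-dataset FPRs for one study configuration."""

    truth: list  # fixed layout, TrueCNV entries (no genotypes)
    power: np.ndarray  # per-CNV empirical power
    fprs: np.ndarray  # per-dataset FPR
    n_datasets: int
    config: SimConfig

    def power_table(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c.chromosome,
                "start": c.start,
                "end": c.end,
                "size_class": c.size_class,
                "size_bp": c.size_bp,
                "n_markers": c.n_markers,
                "type": c.cnv_type,
                "frequency": c.frequency,
                "power": p,
            }
            for c, p in zip(self.truth, self.power)
        ]
        return pd.DataFrame(rows)

    def category_power(self) -> pd.DataFrame:
        """Average power per (size_class, frequency) grid cell."""
        df = self.power_table()
        return (
            df.groupby(["size_class", "frequency"], sort=False)["power"]
            .mean()
            .reset_index()
        )

    def class_power(
        self, frequency: float, min_markers: int = 10, min_size_bp: int = 100_000
    ) -> float:
        """Average power over CNVs of one frequency with >= min_markers
        covering markers or size >= min_size_bp."""
        df = self.power_table()
        sel = df[
            (df["frequency"] == frequency)
            & ((df["n_markers"] >= min_markers) | (df["size_bp"] >= min_size_bp))
        ]
        return float(sel["power"].mean())


def detection_threshold_for(noise_sd: float) -> float:
    """Operating point for unsegmented simulated data: t = 3 x noise SD.

    Placing the dichotomization threshold three noise standard deviations
    from the diploid baseline keeps the genome-wide null exceedance rate at
    2 Phi(-3) ~ 0.3%, so the cross-sample score is driven by carriers rather
    than marker noise. (On segmented real data the default t = 0.3 plays the
    same role because segmentation has already removed most marker noise.)
    """
    return 3.0 * noise_sd


def run_power_study(
    config: SimConfig,
    n_datasets: int,
    seed: int,
    t: float | None = None,
    q_threshold: float = 0.10,
    test: str = "binomial",
) -> PowerStudyResult:
    """Simulate ``n_datasets`` datasets on one fixed layout and score detection.

    The marker map and CNV placements are drawn once from ``seed``; each
    dataset re-draws genotypes and noise. Detection runs with the binomial
    score test and BH q <= ``q_threshold``; ``t`` defaults to the 3-sigma
    operating point for the configured noise.
    """
    t = detection_threshold_for(config.noise_sd) if t is None else t
    layout_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    mmap = make_marker_map(config.n_markers, config.median_gap_bp, seed=layout_rng)
    layout = make_truth_layout(mmap, config, layout_rng)

    detections: list[list[CandidateLocus]] = []
    fprs = []
    for d in range(n_datasets):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1 + d]))
        matrix, _, truth = simulate_dataset(config, mmap=mmap, truth_layout=layout, rng=rng)
        det = CNVDetector(
            mmap, t=t, test=test, q_threshold=q_threshold, random_state=seed
        ).fit(matrix)
        detections.append(det.loci_)
        fprs.append(dataset_fpr(det.loci_, truth))
    power = empirical_power(detections, layout)
    return PowerStudyResult(
        truth=layout,
        power=power,
        fprs=np.asarray(fprs),
        n_datasets=n_datasets,
        config=config,
    )
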