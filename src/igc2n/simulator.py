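"""Synthetic multi-sample array datasets with a mechanistic signal model.

The generator reproduces the physics of a two-channel-free SNP array
experiment: the raw intensity of sample i at marker j is

    I_ij = h_j * c_ij * exp(eps_ij)

with h_j a marker-specific hybridization efficiency (log-normal across
markers), c_ij the true copy number of the genomic segment, and eps Gaussian
noise. The observed log2 ratio normalizes against the average intensity of a
reference set R:

    IR_ij = log2(I_ij) - log2(mean_{r in R} I_rj)

so the marker effect h_j cancels, while a reference set containing carriers
mechanically displaces the whole locus — the reference-model bias the
inference pipeline must undo.

CNVs are laid out on a 5-size x 3-frequency x 3-type grid (two replicates of
each cell, 90 CNVs per dataset); per-sample genotypes are drawn per locus from
Hardy–Weinberg proportions of a deletion and/or duplication allele. Copy
number 0 signal floors at 0.25 copies of background, which puts the no-noise
0-1 transition gap at exactly 2.0 on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import IgC2NError, IntensityMatrix, MarkerMap, logger

__all__ = [
    "SIZE_CLASSES",
    "DEFAULT_FREQUENCIES",
    "CNV_TYPES",
    "SimConfig",
    "TrueCNV",
    "TruthSet",
    "make_marker_map",
    "make_truth_layout",
    "simulate_genotypes",
    "simulate_dataset",
    "truth_to_bed",
]

# size-class realizations in bp (the grid names classes, not exact draws)
SIZE_CLASSES: dict[str, tuple[int, int]] = {
    "very_small": (100, 500),
    "small": (800, 1200),
    "medium": (4500, 5500),
    "large": (50_000, 100_000),
    "very_large": (200_000, 300_000),
}
DEFAULT_FREQUENCIES = (0.01, 0.05, 0.15)
CNV_TYPES = ("del", "gain", "del_gain")
CN0_FLOOR = 0.25  # residual background signal of a homozygous deletion, in copies


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_samples: int = 200
    n_markers: int = 30_000
    median_gap_bp: float = 700.0
    frequencies: tuple = DEFAULT_FREQUENCIES
    size_classes: tuple = tuple(SIZE_CLASSES)
    types: tuple = CNV_TYPES
    replicates_per_cell: int = 2  # 5 x 3 x 3 x 2 = 90 CNVs
    noise_sd: float = 0.2  # log2 units
    hyb_log2_sd: float = 0.5
    reference_size: int | str = "all"
    reference_bias_injection: float | dict | None = None  # extra per-locus shift
    seed: int = 17

    @property
    def n_cnvs(self) -> int:
        return (
            len(self.size_classes)
            * len(self.frequencies)
            * len(self.types)
            * self.replicates_per_cell
        )


@dataclass
class TrueCNV:
    """One entry of the truth set."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    cnv_type: str
    frequency: float
    size_class: str
    marker_indices: np.ndarray
    true_cn: np.ndarray | None = None  # per-sample, filled by simulate_genotypes

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)


TruthSet = list  # list[TrueCNV]


def make_marker_map(
    n_markers: int,
    median_gap_bp: float = 700.0,
    fixed_gap_bp: float | None = None,
    seed: int | np.random.Generator | None = 0,
    chromosome: str = "1",
) -> MarkerMap:
    """Emulated marker map: exponential inter-marker gaps on one chromosome.

    The exponential law reproduces the clustered-with-deserts spacing of a
    genotyping array (heavy right tail); ``fixed_gap_bp`` gives a regular
    grid instead.
    """
    if n_markers < 1:
        raise IgC2NError("n_markers must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fixed_gap_bp is not None:
        pos = (np.arange(1, n_markers + 1) * fixed_gap_bp).astype(np.int64)
    else:
        mean_gap = median_gap_bp / np.log(2.0)
        gaps = np.maximum(rng.exponential(mean_gap, size=n_markers), 1.0)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = np.unique(pos)
        while len(pos) < n_markers:  # deduplication shortfall, rare
            extra = np.maximum(rng.exponential(mean_gap, size=n_markers), 1.0)
            pos = np.unique(np.concatenate([pos, pos[-1] + np.cumsum(extra)]))
        pos = pos[:n_markers]
    ids = np.array([f"mk{j:06d}" for j in range(len(pos))], dtype=object)
    chrom = np.full(len(pos), chromosome, dtype=object)
    return MarkerMap(ids, chrom, pos)


def make_truth_layout(
    mmap: MarkerMap, config: SimConfig, rng: np.random.Generator
) -> TruthSet:
    """Place the CNV grid on the map without overlapping marker runs.

    Large variants are placed first; each placed interval is padded by one
    flanking marker on either side so no two CNVs share a marker run.
    """
    span = int(mmap.position[-1])
    pos = mmap.position
    cells = [
        (size, freq, cnv_type)
        for size in config.size_classes
        for freq in config.frequencies
        for cnv_type in config.types
        for _ in range(config.replicates_per_cell)
    ]
    # big first: easier packing
    cells.sort(key=lambda c: -SIZE_CLASSES[c[0]][1])
    occupied: list[tuple[int, int]] = []
    truth: TruthSet = []
    for size_class, freq, cnv_type in cells:
        lo, hi = SIZE_CLASSES[size_class]
        placed = False
        for _ in range(10_000):
            size = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(1, max(span - size, 2)))
            end = start + size - 1
            j0, j1 = np.searchsorted(pos, [start, end + 1])
            # pad to flanking markers so marker runs stay disjoint
            pad_lo = int(pos[j0 - 1]) if j0 > 0 else 1
            pad_hi = int(pos[j1]) if j1 < len(pos) else span
            if any(not (pad_hi < s or pad_lo > e) for s, e in occupied):
                continue
            occupied.append((pad_lo, pad_hi))
            truth.append(
                TrueCNV(
                    chromosome=str(mmap.chromosome[0]),
                    start=start,
                    end=end,
                    cnv_type=cnv_type,
                    frequency=freq,
                    size_class=size_class,
                    marker_indices=np.arange(j0, j1),
                )
            )
            placed = True
            break
        if not placed:
            raise IgC2NError(
                f"cannot place a {size_class} CNV without overlap; map too small"
            )
    truth.sort(key=lambda c: c.start)
    return truth


def _allele_rates(cnv_type: str, freq: float) -> tuple[float, float]:
    """Deletion/duplication allele frequencies giving carrier incidence freq."""
    if cnv_type == "del":
        return 1.0 - np.sqrt(1.0 - freq), 0.0
    if cnv_type == "gain":
        return 0.0, 1.0 - np.sqrt(1.0 - freq)
    if cnv_type == "del_gain":
        q = (1.0 - np.sqrt(1.0 - freq)) / 2.0
        return q, q
    raise IgC2NError(f"unknown CNV type {cnv_type!r}")


def simulate_genotypes(
    truth: TruthSet, n_samples: int, rng: np.random.Generator
) -> None:
    """Draw per-sample integer copy numbers for each truth CNV (in place).

    Two alleles per sample; each allele is independently a deletion with
    probability q_del or a duplication with q_dup, under Hardy–Weinberg.
    CN = 2 - #del + #dup, clipped to [0, 4].
    """
    for cnv in truth:
        q_del, q_dup = _allele_rates(cnv.cnv_type, cnv.frequency)
        u = rng.random((n_samples, 2))
        n_del = (u < q_del).sum(axis=1)
        n_dup = ((u >= q_del) & (u < q_del + q_dup)).sum(axis=1)
        cnv.true_cn = np.clip(2 - n_del + n_dup, 0, 4).astype(np.int64)


def simulate_dataset(
    config: SimConfig,
    mmap: MarkerMap | None = None,
    truth_layout: TruthSet | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[IntensityMatrix, MarkerMap, TruthSet]:
    """Generate one dataset: log2-ratio matrix, marker map and truth set.

    A fixed ``mmap``/``truth_layout`` pair can be supplied so that repeated
    datasets share coordinates (the power study re-simulates genotypes and
    noise on a fixed layout); genotype and noise draws come from ``rng`` or,
    when omitted, from ``config.seed``. Matrices are emitted unsegmented.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if mmap is None:
        mmap = make_marker_map(config.n_markers, config.median_gap_bp, seed=rng)
    if truth_layout is None:
        truth_layout = make_truth_layout(mmap, config, rng)
    truth = [
        TrueCNV(c.chromosome, c.start, c.end, c.cnv_type, c.frequency,
                c.size_class, c.marker_indices)
        for c in truth_layout
    ]
    simulate_genotypes(truth, config.n_samples, rng)

    n, m = config.n_samples, len(mmap)
    copies = np.full((n, m), 2.0)
    for cnv in truth:
        if cnv.n_markers:
            copies[:, cnv.marker_indices] = np.maximum(
                cnv.true_cn, CN0_FLOOR
            )[:, None]

    log2_h = rng.normal(10.0, config.hyb_log2_sd, size=m)  # cancels in the ratio
    eps = rng.normal(0.0, config.noise_sd * np.log(2.0), size=(n, m))
    log2_I = log2_h[None, :] + np.log2(copies) + eps / np.log(2.0)

    if config.reference_size == "all":
        ref_rows = np.arange(n)
    else:
        k = int(config.reference_size)
        if not 1 <= k <= n:
            raise IgC2NError("reference_size must be in [1, n_samples] or 'all'")
        ref_rows = rng.choice(n, size=k, replace=False)
    # log2 of the arithmetic mean intensity of the reference set
    ref = np.log2(np.mean(np.exp2(log2_I[ref_rows]), axis=0))
    ir = log2_I - ref[None, :]

    if config.reference_bias_injection is not None:
        inj = config.reference_bias_injection
        for i, cnv in enumerate(truth):
            shift = inj.get(i, 0.0) if isinstance(inj, dict) else float(inj)
            if shift and cnv.n_markers:
                ir[:, cnv.marker_indices] += shift

    matrix = IntensityMatrix(
        [f"S{i:04d}" for i in range(n)], ir, is_segmented=False
    )
    logger.info("simulated %d samples x %d markers with %d CNVs", n, m, len(truth))
    return matrix, mmap, truth


def truth_to_bed(truth: TruthSet, path) -> None:
    """Write the truth set as BED (0-based half-open) with grid annotations."""
    import pandas as pd

    rows = [
        {
            "chrom": c.chromosome,
            "start": c.start - 1,
            "end": c.end,
            "type": c.cnv_type,
            "frequency": c.frequency,
            "size_class": c.size_class,
        }
        for c in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
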