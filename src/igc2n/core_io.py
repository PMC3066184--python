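"""Domain types, readers/writers and configuration.

All genomic coordinates held in memory are 1-based inclusive (the convention of
the marker positions on the array annotation); conversion to 0-based half-open
happens exactly once, at the BED boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("igc2n")

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY", "x", "y"}


class IgC2NError(Exception):
    """Base error for this package."""


class ParseError(IgC2NError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered genomic positions of the coverage markers.

    Coordinate authority for every locus call: marker index ``j`` everywhere in
    the package refers to a column of this map.
    """

    marker_id: np.ndarray  # dtype object/str, unique
    chromosome: np.ndarray  # dtype object/str
    position: np.ndarray  # int64, 1-based

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        if len({*self.marker_id}) != len(self.marker_id):
            dup = pd.Series(self.marker_id)
            dup = sorted(dup[dup.duplicated()].unique())
            raise ParseError(f"duplicate marker_id(s): {dup}")
        order = np.lexsort((self.position, self.chromosome.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            logger.warning("marker map not sorted by (chrom, pos); re-sorting")
            self.marker_id = self.marker_id[order]
            self.chromosome = self.chromosome[order]
            self.position = self.position[order]

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def is_sex_chromosome(self) -> np.ndarray:
        """Boolean mask over markers flagging X/Y, for exclusion in detection."""
        return np.isin(self.chromosome.astype(str), list(SEX_CHROMOSOMES))

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosome:
            seen.setdefault(str(c))
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_id, "chrom": self.chromosome, "pos": self.position}
        )


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a tab-delimited marker map with header ``marker_id  chrom  pos``.

    Rows are re-sorted by (chromosome, position) if needed; duplicated
    positions are retained (and logged), duplicated marker ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    missing = {"marker_id", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    try:
        pos = pd.to_numeric(df["pos"], errors="raise")
        if (pos != pos.astype(np.int64)).any():
            raise ValueError
    except (ValueError, TypeError):
        bad = df.index[pd.to_numeric(df["pos"], errors="coerce").isna()].tolist()
        line = (bad[0] + 2) if bad else "?"
        raise ParseError(f"{path}: non-integer position (data line {line})") from None
    n_dup = df.duplicated(subset=["chrom", "pos"]).sum()
    if n_dup:
        logger.warning("%s: %d duplicated positions retained", path, n_dup)
    return MarkerMap(
        df["marker_id"].to_numpy(dtype=object),
        df["chrom"].to_numpy(dtype=object),
        pos.to_numpy(dtype=np.int64),
    )


def write_marker_map(mmap: MarkerMap, path: str | Path) -> None:
    mmap.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------


@dataclass
class IntensityMatrix:
    """Samples x markers log2 intensity ratios ``IR_ij``.

    The single input to detection and genotyping. Missing values are rejected,
    not imputed — imputation belongs upstream.
    """

    sample_ids: list[str]
    values: np.ndarray  # shape (N, M), float64, finite
    is_segmented: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise IgC2NError("intensity values must be a 2-D samples x markers array")
        if len(self.sample_ids) != self.values.shape[0]:
            raise IgC2NError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[0]} rows"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise IgC2NError(
                f"non-finite intensity for sample {self.sample_ids[i]!r}, column {j}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


def read_intensity_matrix(path: str | Path, mmap: MarkerMap) -> IntensityMatrix:
    """Read a samples x markers TSV whose header matches the marker map.

    First column holds sample ids; remaining columns must be exactly the
    marker ids of ``mmap`` in map order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    file_markers = [str(c) for c in df.columns]
    map_markers = [str(m) for m in mmap.marker_id]
    if file_markers != map_markers:
        extra = set(file_markers) - set(map_markers)
        absent = set(map_markers) - set(file_markers)
        raise ParseError(
            f"{path}: marker columns do not match the map "
            f"(missing={sorted(absent)[:5]}, unexpected={sorted(extra)[:5]})"
        )
    values = df.to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: NaN entry for sample {df.index[i]!r}, marker {file_markers[j]!r}"
        )
    return IntensityMatrix([str(s) for s in df.index], values)


def write_intensity_matrix(
    matrix: IntensityMatrix, mmap: MarkerMap, path: str | Path
) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=mmap.marker_id)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")  # lossless float round-trip


# ---------------------------------------------------------------------------
# Loci and per-locus models
# ---------------------------------------------------------------------------


@dataclass
class CandidateLocus:
    """A maximal run of FDR-significant markers with breakpoints [start, end]."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    marker_indices: np.ndarray  # contiguous indices into the MarkerMap
    q_min: float = 1.0

    def __post_init__(self) -> None:
        self.marker_indices = np.asarray(self.marker_indices, dtype=np.int64)
        if self.start > self.end:
            raise IgC2NError(f"locus start {self.start} > end {self.end}")
        d = np.diff(self.marker_indices)
        if d.size and not (d == 1).all():
            raise IgC2NError("locus marker indices must be contiguous")

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    def name(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


@dataclass
class SummarySignal:
    """Per-sample median log2 ratio over the markers of one locus."""

    locus: CandidateLocus
    values: np.ndarray  # length N, finite

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise IgC2NError("summary signal contains non-finite values")


@dataclass
class CNClassModel:
    """Fitted mixture for one locus.

    ``centers`` are per-class medians of member values (not EM means), in
    strictly increasing order; ``labels`` maps each sample to a class index.
    """

    centers: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    labels: np.ndarray  # int, per sample
    family: str  # "gaussian" | "t"
    n_comp: int
    bic: float
    converged: bool

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.n_comp != len(self.centers):
            raise IgC2NError("n_comp does not match number of centers")
        if self.n_comp > 1 and not (np.diff(self.centers) > 0).all():
            raise IgC2NError("class centers must be strictly increasing")
        if abs(self.weights.sum() - 1.0) > 1e-8 or (self.weights < 0).any():
            raise IgC2NError("weights must be nonnegative and sum to 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_comp):
            raise IgC2NError("labels out of range")

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_comp)


@dataclass
class OneCNDifference:
    """Gaps between the medians of consecutive CN classes at one locus."""

    locus_id: str
    diffs: np.ndarray  # length n_comp - 1, strictly positive

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=np.float64)
        if self.diffs.size and not (self.diffs > 0).all():
            raise IgC2NError("1-CN class differences must be strictly positive")


@dataclass
class GenotypedLocus:
    """Integer copy-number genotypes for one locus after bias correction."""

    locus: CandidateLocus
    cn_calls: np.ndarray  # int >= 0, per sample
    bias_estimate: float  # log2-ratio units
    maf: float
    polymorphism_type: str  # del | gain | del-gain | low-frequency

    def __post_init__(self) -> None:
        self.cn_calls = np.asarray(self.cn_calls, dtype=np.int64)
        if (self.cn_calls < 0).any():
            raise IgC2NError("copy-number calls must be >= 0")
        if not (0.0 <= self.maf <= 0.5):
            raise IgC2NError(f"MAF {self.maf} outside [0, 0.5]")


@dataclass
class TrioTable:
    """Rows of (child_id, mother_id, father_id)."""

    rows: list[tuple[str, str, str]]

    def validate(self, sample_ids: Iterable[str]) -> None:
        known = set(sample_ids)
        for child, mother, father in self.rows:
            for sid in (child, mother, father):
                if sid not in known:
                    raise IgC2NError(f"trio sample {sid!r} absent from genotyped set")


def read_trio_table(path: str | Path) -> TrioTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"child_id", "mother_id", "father_id"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: trio table needs columns {sorted(need)}")
    return TrioTable(
        [tuple(r) for r in df[["child_id", "mother_id", "father_id"]].itertuples(index=False)]
    )


# ---------------------------------------------------------------------------
# Genotype output (BED + CN matrix)
# ---------------------------------------------------------------------------

BED_HEADER = ["chrom", "start", "end", "id", "type", "maf", "bias"]


def write_genotyped_loci(
    loci: Sequence[GenotypedLocus],
    sample_ids: Sequence[str],
    bed_path: str | Path,
    matrix_path: str | Path,
) -> None:
    """Write a BED-style locus file and a samples x loci integer CN matrix.

    BED uses the 0-based half-open convention: internal 1-based inclusive
    [start, end] becomes (start - 1, end).
    """
    rows = []
    for g in loci:
        rows.append(
            {
                "chrom": g.locus.chromosome,
                "start": g.locus.start - 1,
                "end": g.locus.end,
                "id": g.locus.name(),
                "type": g.polymorphism_type,
                "maf": round(g.maf, 6),
                "bias": round(g.bias_estimate, 6),
            }
        )
    pd.DataFrame(rows, columns=BED_HEADER).to_csv(bed_path, sep="\t", index=False)

    cn = pd.DataFrame(
        {g.locus.name(): g.cn_calls for g in loci},
        index=list(sample_ids),
    )
    cn.index.name = "sample_id"
    cn.to_csv(matrix_path, sep="\t")


def read_cn_matrix(path: str | Path) -> pd.DataFrame:
    """Read back a samples x loci integer CN matrix written by this package."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(np.int64)


def read_locus_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-style locus table back to 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t")
    df["start"] = df["start"].astype(np.int64) + 1  # back to 1-based inclusive
    df["end"] = df["end"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "detect": {
        "t": 0.3,
        "mode": "two_sided",
        "test": "binomial",
        "n_perm": 1000,
        "q_threshold": 0.10,
        "breakpoints": "marker",
        "exclude_xy": True,
        "seed": 13,
    },
    "genotype": {
        "grubbs_alpha": 0.05,
        "min_class_polymorphic": 2,
        "seed": 13,
    },
    "bias": {
        "anchor_window": 0.25,
        "zero_test_alpha": 0.05,
        "min_pooled_diffs": 20,
        "fallback_variance": 0.01,
        "major_freq_threshold": 0.05,
    },
    "simulate": {
        "n_samples": 200,
        "n_markers": 30000,
        "median_gap_bp": 700,
        "noise_sd": 0.2,
        "hyb_log2_sd": 0.5,
        "reference_size": "all",
        "seed": 17,
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML config (one section per pipeline step) over the defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


def median_filter_smooth(matrix: IntensityMatrix, width: int = 5) -> IntensityMatrix:
    """Optional odd-width running-median smoother (a non-CBS stand-in).

    Provided for raw matrices only; proper segmentation belongs upstream.
    """
    if width < 1 or width % 2 == 0:
        raise IgC2NError("smoother width must be odd and positive")
    from scipy.ndimage import median_filter

    smoothed = median_filter(matrix.values, size=(1, width), mode="nearest")
    return IntensityMatrix(matrix.sample_ids, smoothed, is_segmented=True)
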