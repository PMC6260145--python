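"""Coverage-based quantitation of I-exon and constant-gene transcription.

Expression of an unannotated interval is measured as RPKM computed from the
area under the per-base coverage track (AUC): ``reads = AUC / read_length``
and ``RPKM = reads * 1e9 / (region_length * library_reads)``. Zero-RPKM cells
are treated as a distinct "absent" class: they are masked, never
log-transformed or pseudocounted, and are excluded from per-sample averages
and from the per-region moments used for Z-standardization.

A sample's overall sterile-transcription level is the mean log2 RPKM across
its non-zero I-exons; samples are classified against the compendium-derived
cutoff of 2.65 log2 RPKM into high (> cutoff), low (0 < mean <= cutoff) and
none (all I-exons at zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_map import GenomicInterval, RegionCatalog

logger = logging.getLogger(__name__)

#: Compendium mean of per-sample average log2 RPKM; the high/low cutoff.
DEFAULT_LOG2_CUTOFF = 2.65


class QuantError(ValueError):
    """Invalid quantitation input."""


@dataclass(frozen=True)
class QuantConfig:
    read_length: int = 100
    log2_cutoff: float = DEFAULT_LOG2_CUTOFF
    # zeros are masked, never log-transformed; the only supported policy
    pseudocount_policy: str = "exclude-zeros"

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise QuantError("read_length must be >= 1")
        if self.pseudocount_policy != "exclude-zeros":
            raise QuantError("only the 'exclude-zeros' policy is supported")


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Per-base depth over a contiguous genomic window, 1-based inclusive."""

    def __init__(self, chrom: str, start: int, depth: np.ndarray):
        depth = np.asarray(depth, dtype=float)
        if depth.ndim != 1:
            raise QuantError("depth must be a 1-D vector")
        if np.any(depth < 0):
            raise QuantError("coverage depth must be non-negative")
        self.chrom = chrom
        self.start = int(start)
        self.depth = depth

    @property
    def end(self) -> int:
        return self.start + len(self.depth) - 1

    @property
    def total_auc(self) -> float:
        return float(self.depth.sum())

    def region_depth(self, region: GenomicInterval) -> np.ndarray:
        if region.chrom != self.chrom or region.start < self.start or region.end > self.end:
            raise QuantError(
                f"region {region.name!r} ({region.chrom}:{region.start}-{region.end}) "
                f"outside track bounds {self.chrom}:{self.start}-{self.end}"
            )
        offset = region.start - self.start
        return self.depth[offset : offset + region.length]

    @classmethod
    def from_bedgraph(cls, path: str) -> "CoverageTrack":
        """Load a 4-column bedGraph (0-based half-open intervals)."""
        rows = []
        chrom = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise QuantError(f"{path}:{lineno}: expected 4 bedGraph fields")
                if chrom is None:
                    chrom = parts[0]
                elif parts[0] != chrom:
                    raise QuantError(f"{path}:{lineno}: multi-chromosome bedGraph unsupported")
                rows.append((int(parts[1]), int(parts[2]), float(parts[3])))
        if not rows:
            raise QuantError(f"{path}: empty bedGraph")
        rows.sort()
        span_start = rows[0][0]
        span_end = max(e for _, e, _ in rows)
        depth = np.zeros(span_end - span_start, dtype=float)
        for s, e, v in rows:
            depth[s - span_start : e - span_start] += v
        return cls(chrom, span_start + 1, depth)

    @classmethod
    def from_bigwig(cls, path: str, chrom: str,
                    start: int | None = None, end: int | None = None) -> "CoverageTrack":
        """Load per-base depth for one chromosome window from a BigWig file."""
        import pyBigWig

        bw = pyBigWig.open(path)
        try:
            chrom_len = bw.chroms(chrom)
            if chrom_len is None:
                raise QuantError(f"{path}: chromosome {chrom!r} not present")
            s0 = 0 if start is None else start - 1
            e0 = chrom_len if end is None else end
            values = np.nan_to_num(
                np.asarray(bw.values(chrom, s0, e0), dtype=float), nan=0.0
            )
        finally:
            bw.close()
        return cls(chrom, s0 + 1, values)


def region_auc(track: CoverageTrack, region: GenomicInterval) -> float:
    """Area under coverage: the sum of per-base depth over the interval."""
    return float(track.region_depth(region).sum())


def rpkm(auc: float, region_length_bp: int, library_reads: float,
         config: QuantConfig = QuantConfig()) -> float:
    """RPKM from coverage AUC. ``reads = auc / read_length``."""
    if region_length_bp < 1:
        raise QuantError("region length must be >= 1 bp")
    if library_reads <= 0:
        raise QuantError("library_reads must be positive")
    reads = auc / config.read_length
    return reads * 1e9 / (region_length_bp * library_reads)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Samples x regions RPKM matrix with an explicit zero/absent mask.

    ``values`` holds RPKM (always >= 0); ``zero_mask`` flags RPKM = 0 cells.
    ``log2()`` yields log2 RPKM with masked cells as NaN.
    """

    def __init__(self, values: pd.DataFrame):
        values = values.astype(float)
        if (values.to_numpy() < 0).any():
            raise QuantError("RPKM values must be non-negative")
        self.values = values

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def zero_mask(self) -> pd.DataFrame:
        return self.values == 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log2(self) -> pd.DataFrame:
        """log2 RPKM with absent (RPKM = 0) cells as NaN."""
        with np.errstate(divide="ignore"):
            out = np.log2(self.values.where(self.values > 0))
        return out

    def to_tsv(self, path: str, log2: bool = False) -> None:
        df = self.log2() if log2 else self.values
        df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.fillna(0.0))


def quantify_tracks(
    tracks: Mapping[str, CoverageTrack],
    catalog: RegionCatalog,
    library_reads: Mapping[str, float] | None = None,
    config: QuantConfig = QuantConfig(),
    kinds: Sequence[str] = ("I_exon",),
) -> ExpressionMatrix:
    """Quantify every catalog region of the given kinds in every track.

    ``library_reads`` gives per-sample mapped-read totals; when a sample is
    absent it is derived from the track as ``total_auc / read_length``.
    """
    regions = [iv for iv in catalog if iv.kind in kinds]
    if not regions:
        raise QuantError(f"catalog has no regions of kinds {kinds}")
    data = {}
    for sample, track in tracks.items():
        if library_reads is not None and sample in library_reads:
            lib = float(library_reads[sample])
        else:
            lib = track.total_auc / config.read_length
        if lib <= 0:
            # an all-empty track has no mapped reads; every region is absent
            data[sample] = [0.0] * len(regions)
            continue
        data[sample] = [
            rpkm(region_auc(track, iv), iv.length, lib, config) for iv in regions
        ]
    df = pd.DataFrame.from_dict(
        data, orient="index", columns=[iv.name for iv in regions]
    )
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# Per-sample classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleClassification:
    sample_id: str
    mean_log2_rpkm: float | None  # None when every region is absent
    label: str  # high | low | none


def sample_mean_log2(rpkm_row: np.ndarray, mask: np.ndarray | None = None) -> float | None:
    """Mean log2 RPKM over non-zero regions; None when all are zero."""
    row = np.asarray(rpkm_row, dtype=float)
    if mask is None:
        mask = row == 0
    mask = np.asarray(mask, dtype=bool)
    if row.shape != mask.shape:
        raise QuantError("row and mask length mismatch")
    keep = ~mask
    if not keep.any():
        return None
    return float(np.mean(np.log2(row[keep])))


def classify_samples(
    matrix: ExpressionMatrix, config: QuantConfig = QuantConfig()
) -> tuple[list[SampleClassification], dict]:
    """Label every sample high / low / none against the log2-RPKM cutoff.

    A mean exactly at the cutoff is "low": high is strictly above.
    Returns the classifications and the partition summary (counts and
    percentages to one decimal).
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise QuantError("empty expression matrix")
    records = []
    for sample_id, row in matrix.values.iterrows():
        mean = sample_mean_log2(row.to_numpy())
        if mean is None:
            label = "none"
        elif mean > config.log2_cutoff:
            label = "high"
        else:
            label = "low"
        records.append(SampleClassification(str(sample_id), mean, label))
    n_high = sum(r.label == "high" for r in records)
    n_low = sum(r.label == "low" for r in records)
    n_none = sum(r.label == "none" for r in records)
    return records, partition_summary(n_high, n_low, n_none)


def partition_summary(n_high: int, n_low: int, n_none: int) -> dict:
    """Bookkeeping of the high/low/none partition, percentages to 1 decimal."""
    total = n_high + n_low + n_none
    if total == 0:
        raise QuantError("empty partition")
    pct = lambda n: round(100.0 * n / total, 1)
    return {
        "n_total": total,
        "n_high": n_high,
        "n_low": n_low,
        "n_none": n_none,
        "n_nonzero": n_high + n_low,
        "pct_high": pct(n_high),
        "pct_low": pct(n_low),
        "pct_none": pct(n_none),
        "pct_nonzero": pct(n_high + n_low),
    }


# ---------------------------------------------------------------------------
# Z-standardization
# ---------------------------------------------------------------------------

def zscore_by_region(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each region (column) of a log2 matrix to Z-scores.

    Moments use only unmasked (non-NaN) entries with sample SD (n - 1).
    Zero-variance columns map to Z = 0; columns with fewer than two observed
    values are left fully masked with a warning. Masked cells stay NaN.
    """
    Z = pd.DataFrame(
        np.nan, index=log2_matrix.index, columns=log2_matrix.columns
    )
    for col in log2_matrix.columns:
        x = log2_matrix[col]
        observed = x.notna()
        n_obs = int(observed.sum())
        if n_obs < 2:
            logger.warning(
                "region %r has %d observed value(s); Z-scores left masked",
                col, n_obs,
            )
            continue
        sd = x.std(ddof=1)
        if sd == 0:
            Z.loc[observed, col] = 0.0
        else:
            Z.loc[observed, col] = (x[observed] - x.mean()) / sd
    return Z


def classification_to_frame(records: Sequence[SampleClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "mean_log2_rpkm": [
                np.nan if r.mean_log2_rpkm is None else r.mean_log2_rpkm
                for r in records
            ],
            "label": [r.label for r in records],
        }
    )
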