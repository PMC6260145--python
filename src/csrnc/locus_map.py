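"""Switch-region mapping and the IGH region catalog.

Class-switch recombination is targeted to repetitive, AGCT-rich switch (S)
regions upstream of each immunoglobulin heavy-chain constant gene. Because
neither the sterile I-exon transcripts nor the S regions are annotated in
GRCh38, S regions are located by scanning the locus sequence for the density
of the AGCT motif in fixed-width bins and flagging bins whose count stands
out from the locus background.

Coordinates are 1-based and inclusive throughout (``length = end - start + 1``);
BED input/output converts to the 0-based half-open convention at the boundary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

REGION_KINDS = ("I_exon", "S_region", "C_gene")

#: hg38 span of the human IGH locus scanned for switch regions.
IGH_LOCUS_CHROM = "chr14"
IGH_LOCUS_START = 105_583_700
IGH_LOCUS_END = 105_863_000

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class CatalogError(ValueError):
    """Invalid region catalog or BED input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A named genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str = ""
    kind: str = "S_region"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CatalogError("chrom must be non-empty")
        if self.start > self.end:
            raise CatalogError(
                f"interval {self.name!r}: start {self.start} > end {self.end}"
            )
        if self.kind not in REGION_KINDS:
            raise CatalogError(f"unknown region kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class RegionCatalog:
    """The I-exon / S-region / C-gene interval catalog for one genome build."""

    intervals: tuple[GenomicInterval, ...]
    genome_build: str = "GRCh38.p10"

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        for kind in REGION_KINDS:
            names = [iv.name for iv in self.intervals if iv.kind == kind]
            if len(names) != len(set(names)):
                raise CatalogError(f"duplicate names within kind {kind!r}")
        i_exons = sorted(self.of_kind("I_exon"), key=lambda iv: iv.start)
        for a, b in zip(i_exons, i_exons[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise CatalogError(f"I-exons {a.name!r} and {b.name!r} overlap")

    def of_kind(self, kind: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.kind == kind]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def get(self, name: str) -> GenomicInterval:
        for iv in self.intervals:
            if iv.name == name:
                return iv
        raise KeyError(name)


def default_catalog() -> RegionCatalog:
    """The packaged GRCh38.p10 IGH catalog: 10 I-exons, 8 S regions, 9 C genes."""
    ref = importlib.resources.files("csrnc.data").joinpath("igh_catalog.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_catalog_tsv(str(path))


def read_catalog_tsv(path: str) -> RegionCatalog:
    """Read a catalog TSV with columns name, chrom, start, end, kind."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"name", "chrom", "start", "end", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog TSV missing columns: {sorted(missing)}")
    intervals = [
        GenomicInterval(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            name=row.name_, kind=row.kind,
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    return RegionCatalog(tuple(intervals))


def write_catalog_tsv(catalog: RegionCatalog, path: str) -> None:
    df = pd.DataFrame(
        {
            "name": [iv.name for iv in catalog],
            "chrom": [iv.chrom for iv in catalog],
            "start": [iv.start for iv in catalog],
            "end": [iv.end for iv in catalog],
            "kind": [iv.kind for iv in catalog],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def catalog_lengths(catalog: RegionCatalog) -> pd.DataFrame:
    """Per-interval lengths in bp (``end - start + 1``)."""
    return pd.DataFrame(
        {
            "name": [iv.name for iv in catalog],
            "kind": [iv.kind for iv in catalog],
            "length": [iv.length for iv in catalog],
        }
    )


# ---------------------------------------------------------------------------
# Motif-density scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifScanConfig:
    """Parameters of the binned motif-density scan.

    The default motif AGCT is the canonical AID hotspot core; it is its own
    reverse complement, so a single-strand scan is complete. Non-palindromic
    motifs are scanned on both strands and the counts summed.
    """

    motif: str = "AGCT"
    bin_size: int = 500
    span: GenomicInterval = field(
        default_factory=lambda: GenomicInterval(
            IGH_LOCUS_CHROM, IGH_LOCUS_START, IGH_LOCUS_END
        )
    )
    call_threshold_sd: float = 2.0

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if self.bin_size < len(self.motif):
            raise ValueError("bin_size must be at least the motif length")


@dataclass(frozen=True)
class BinProfile:
    """Motif counts per fixed-width bin; the last bin may be short."""

    bin_starts: np.ndarray  # 1-based genomic start of each bin
    counts: np.ndarray
    bin_size: int
    span: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.bin_starts) != len(self.counts):
            raise ValueError("bin_starts and counts length mismatch")

    def __len__(self) -> int:
        return len(self.counts)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _motif_start_positions(seq: np.ndarray, motif: str) -> np.ndarray:
    """0-based start positions of every (possibly overlapping) occurrence."""
    m = len(motif)
    if len(seq) < m:
        return np.empty(0, dtype=np.intp)
    hits = np.ones(len(seq) - m + 1, dtype=bool)
    for offset, base in enumerate(motif.encode()):
        hits &= seq[offset : len(seq) - m + 1 + offset] == base
    return np.flatnonzero(hits)


def scan_motif_density(sequence: str, config: MotifScanConfig) -> BinProfile:
    """Count motif occurrences per bin, assigning each hit to the bin
    containing its start position.

    The scan is case-insensitive; IUPAC ambiguity codes never match the motif.
    The sequence is laid out along ``config.span`` starting at ``span.start``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    motif = config.motif.upper()
    positions = _motif_start_positions(seq, motif)
    if motif != reverse_complement(motif):
        rc_positions = _motif_start_positions(seq, reverse_complement(motif))
        positions = np.concatenate([positions, rc_positions])
    n_bins = -(-len(sequence) // config.bin_size)  # ceil division
    counts = np.bincount(positions // config.bin_size, minlength=n_bins)
    bin_starts = config.span.start + config.bin_size * np.arange(n_bins)
    return BinProfile(
        bin_starts=bin_starts.astype(np.int64),
        counts=counts.astype(np.int64),
        bin_size=config.bin_size,
        span=config.span,
    )


def call_switch_regions(
    profile: BinProfile, config: MotifScanConfig
) -> list[GenomicInterval]:
    """Flag bins whose motif count exceeds mean + ``call_threshold_sd`` SD of
    the profile and merge adjacent flagged bins into S-region intervals.

    An all-zero (or otherwise flat) profile yields no calls. Returned
    intervals are disjoint, sorted by start, and clipped to the scanned span.
    """
    counts = np.asarray(profile.counts, dtype=float)
    if counts.size == 0:
        return []
    threshold = counts.mean() + config.call_threshold_sd * counts.std(ddof=1)
    flagged = counts > threshold
    intervals: list[GenomicInterval] = []
    i = 0
    n = 0
    while i < len(flagged):
        if flagged[i]:
            j = i
            while j + 1 < len(flagged) and flagged[j + 1]:
                j += 1
            start = int(profile.bin_starts[i])
            end = min(
                int(profile.bin_starts[j]) + profile.bin_size - 1,
                profile.span.end,
            )
            n += 1
            intervals.append(
                GenomicInterval(
                    profile.span.chrom, start, end,
                    name=f"S_call_{n}", kind="S_region",
                )
            )
            i = j + 1
        else:
            i += 1
    return intervals


# ---------------------------------------------------------------------------
# BED conversion (0-based half-open at the boundary)
# ---------------------------------------------------------------------------

def to_bed(catalog_or_intervals: RegionCatalog | Iterable[GenomicInterval]) -> str:
    """Render intervals as BED6 text (0-based half-open starts)."""
    lines = []
    for iv in catalog_or_intervals:
        lines.append(
            f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t0\t+\t{iv.kind}"
        )
    return "\n".join(lines) + "\n"


def from_bed(text: str, genome_build: str = "GRCh38.p10") -> RegionCatalog:
    """Parse BED records back into a catalog; inverse of :func:`to_bed`."""
    intervals = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise CatalogError(f"BED line {lineno}: expected >= 3 fields")
        try:
            bed_start, bed_end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise CatalogError(f"BED line {lineno}: non-integer coordinate") from exc
        if bed_start >= bed_end:
            raise CatalogError(
                f"BED line {lineno}: start {bed_start} >= end {bed_end}"
            )
        name = parts[3] if len(parts) > 3 else f"region_{lineno}"
        kind = parts[6] if len(parts) > 6 else "S_region"
        intervals.append(
            GenomicInterval(parts[0], bed_start + 1, bed_end, name=name, kind=kind)
        )
    return RegionCatalog(tuple(intervals), genome_build=genome_build)


def write_bed(catalog: RegionCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(to_bed(catalog))


def read_bed(path: str) -> RegionCatalog:
    with open(path) as fh:
        return from_bed(fh.read())
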