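"""Genomic interval data model and algebra.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``. The *center* of an interval, ``floor((start + end) / 2)``,
is the reference point for every site-centered analysis in the package
(metaplots, GC* profiles, motif densities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "AnnotationSet",
    "BedParseError",
    "ConfigurationError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "find_overlaps",
    "overlap_length",
    "subtract_overlapping",
    "annotate_feature_context",
    "window_counts",
]


class BedParseError(ValueError):
    """Raised for malformed BED input; message names the offending line."""


class ConfigurationError(ValueError):
    """Raised when a required annotation category or parameter is missing."""


@dataclass(frozen=True)
class GenomicInterval:
    """A scored, optionally stranded genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; <= 0 means no overlap."""
    if a.chrom != b.chrom:
        return 0
    return min(a.end, b.end) - max(a.start, b.start)


def _sort_key(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end, iv.name or "")


@dataclass
class PeakSet:
    """A coordinate-sorted collection of intervals with assay metadata.

    ``strain`` is one of B6 / RJ2 / other, ``target`` the ChIP target
    (PRDM9, DMC1, H3K4me3, H3K36me3, other) and ``genotype`` WT / Prdm9KO /
    Spo11KO / other. Intervals are sorted on construction.
    """

    label: str = ""
    strain: str = "other"
    target: str = "other"
    genotype: str = "WT"
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=_sort_key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def with_intervals(self, intervals: Iterable[GenomicInterval]) -> "PeakSet":
        """A copy of this set's metadata around a different interval list."""
        return PeakSet(
            label=self.label,
            strain=self.strain,
            target=self.target,
            genotype=self.genotype,
            intervals=list(intervals),
        )

    def scores(self) -> np.ndarray:
        return np.array(
            [np.nan if iv.score is None else iv.score for iv in self.intervals]
        )

    def centers(self) -> list[tuple[str, int]]:
        return [(iv.chrom, iv.center) for iv in self.intervals]


@dataclass
class AnnotationSet:
    """Genomic feature annotations used for peak context labelling."""

    promoters: list[GenomicInterval] = field(default_factory=list)
    genes: list[GenomicInterval] = field(default_factory=list)
    cpg_islands: list[GenomicInterval] = field(default_factory=list)
    ctcf_motifs: list[GenomicInterval] = field(default_factory=list)
    tss: list[tuple[str, int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    label: str = "",
    strain: str = "other",
    target: str = "other",
    genotype: str = "WT",
) -> PeakSet:
    """Read a 3-6 column BED file into a :class:`PeakSet`.

    Column 5 (when present) is mapped to the interval score, column 4 to the
    name and column 6 to the strand. Lines starting with ``#``, ``track`` or
    ``browser`` are skipped. Malformed lines raise :class:`BedParseError`
    naming the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: fewer than 3 columns at line {lineno}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: non-integer coordinates at line {lineno}"
                ) from exc
            if end <= start:
                raise BedParseError(f"{path}: end <= start at line {lineno}")
            if start < 0:
                raise BedParseError(f"{path}: negative start at line {lineno}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}: non-numeric score at line {lineno}"
                    ) from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
            )
    return PeakSet(
        label=label, strain=strain, target=target, genotype=genotype, intervals=intervals
    )


def _format_score(score: float) -> str:
    # repr preserves the float exactly for round-tripping
    return repr(score) if score != int(score) else str(int(score))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a :class:`PeakSet` as BED, using only the columns it populates.

    Round-trip contract: ``read_bed(write_bed(P)) == P`` for coordinates,
    names and scores (given the same metadata arguments).
    """
    any_name = any(iv.name is not None for iv in peaks)
    any_score = any(iv.score is not None for iv in peaks)
    any_strand = any(iv.strand != "." for iv in peaks)
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if any_name or any_score or any_strand:
                cols.append(iv.name if iv.name is not None else ".")
            if any_score or any_strand:
                cols.append(_format_score(iv.score) if iv.score is not None else ".")
            if any_strand:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}: expected 2 columns at line {lineno}")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _build_trees(peaks: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(peaks):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def find_overlaps(
    set_a: PeakSet | Sequence[GenomicInterval],
    set_b: PeakSet | Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[list[GenomicInterval]]:
    """For each interval of A, the sorted list of B intervals overlapping it.

    Overlap requires >= ``min_overlap`` shared bp on the same chromosome
    (half-open arithmetic: adjacent intervals never overlap). The returned
    list is parallel to ``set_a``'s (sorted) intervals.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    a_ivs = list(set_a)
    b_ivs = list(set_b)
    trees = _build_trees(b_ivs)
    out: list[list[GenomicInterval]] = []
    for a in a_ivs:
        tree = trees.get(a.chrom)
        hits: list[GenomicInterval] = []
        if tree is not None:
            for node in tree.overlap(a.start, a.end):
                b = b_ivs[node.data]
                if overlap_length(a, b) >= min_overlap:
                    hits.append(b)
        hits.sort(key=_sort_key)
        out.append(hits)
    return out


def subtract_overlapping(
    set_a: PeakSet,
    set_b: PeakSet | Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> PeakSet:
    """Intervals of A with no overlap (>= min_overlap bp) in B."""
    hits = find_overlaps(set_a, set_b, min_overlap=min_overlap)
    kept = [iv for iv, h in zip(set_a, hits) if not h]
    return set_a.with_intervals(kept)


def annotate_feature_context(
    peaks: PeakSet,
    ann: AnnotationSet,
) -> list[dict]:
    """Label each peak promoter / genic / intergenic, plus CpG-island overlap.

    Label precedence is promoter > genic > intergenic, so each peak gets
    exactly one label; ``cpg_overlap`` is recorded independently.
    """
    for attr in ("promoters", "genes", "cpg_islands"):
        if getattr(ann, attr) is None:
            raise ConfigurationError(f"annotation category {attr!r} is missing")
    prom_hits = find_overlaps(peaks, ann.promoters)
    gene_hits = find_overlaps(peaks, ann.genes)
    cpg_hits = find_overlaps(peaks, ann.cpg_islands)
    records = []
    for iv, in_prom, in_gene, in_cpg in zip(peaks, prom_hits, gene_hits, cpg_hits):
        if in_prom:
            feature = "promoter"
        elif in_gene:
            feature = "genic"
        else:
            feature = "intergenic"
        records.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": iv.name,
                "feature": feature,
                "cpg_overlap": bool(in_cpg),
            }
        )
    return records


def window_counts(
    sites: PeakSet | Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int,
) -> dict[str, np.ndarray]:
    """Site counts in non-overlapping windows, per chromosome.

    A site is assigned to the window containing its center, so total counts
    are conserved. Sites on chromosomes absent from ``chrom_sizes`` raise an
    error listing the chromosome.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    counts = {
        chrom: np.zeros(max(1, -(-size // window)), dtype=int)
        for chrom, size in chrom_sizes.items()
    }
    for iv in sites:
        if iv.chrom not in counts:
            raise KeyError(
                f"site on chromosome {iv.chrom!r} absent from chrom_sizes"
            )
        counts[iv.chrom][min(iv.center // window, len(counts[iv.chrom]) - 1)] += 1
    return counts
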