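"""Coverage tracks and site-centered aggregate enrichment profiles.

Normalization follows ChIP-seq metaplot convention: per-bp counts are
converted to RPKM (reads per kb per million mapped reads) using each
track's library size, then combined with the matched input either by
subtraction (``input_subtract``) or by a pseudovalue-stabilized ratio
(``input_ratio``). Both modes are explicit parameters, never defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, PeakSet, subtract_overlapping

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack", "EnrichmentProfile", "CorrelationResult",
    "rpkm", "aggregate_profile", "filter_intergenic", "correlate_strengths",
]


@dataclass
class CoverageTrack:
    """Per-bp counts per chromosome with the library size used to
    normalize them. Tracks may be windowed extracts, so the library size
    is not required to equal the stored total."""

    data: dict[str, np.ndarray]
    library_size: float

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    def pooled_with(self, other: "CoverageTrack") -> "CoverageTrack":
        """Replicate pooling: sum counts and library sizes."""
        if set(self.data) != set(other.data):
            raise ValueError("tracks cover different chromosomes")
        return CoverageTrack(
            data={c: self.data[c] + other.data[c] for c in self.data},
            library_size=self.library_size + other.library_size,
        )

    def mean_rpkm(self) -> float:
        """Genome-wide mean per-bp RPKM of the stored counts."""
        total = sum(float(a.sum()) for a in self.data.values())
        bp = sum(a.size for a in self.data.values())
        return rpkm(total, bp, self.library_size)

    def to_bedgraph(self, path: str | Path) -> None:
        """Run-length encoded 4-column bedGraph (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom in self.data:
                arr = np.asarray(self.data[chrom])
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [arr.size]])
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        chrom_sizes: Mapping[str, int],
        library_size: float | None = None,
    ) -> "CoverageTrack":
        data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}: expected 4 columns at line {lineno}")
                chrom, start, end, value = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                )
                if chrom not in data:
                    raise KeyError(f"{path}: unknown chromosome {chrom!r} at line {lineno}")
                data[chrom][start:end] = value
        if library_size is None:
            library_size = sum(float(a.sum()) for a in data.values())
        return cls(data=data, library_size=library_size)


def rpkm(count: float, window_bp: float, library_size: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / ((window_bp / 1000.0) * (library_size / 1e6))


@dataclass
class EnrichmentProfile:
    """Mean input-normalized enrichment per offset around site centers."""

    offsets: np.ndarray
    values: np.ndarray
    n_sites: int
    mode: str

    def max_offset(self) -> int:
        return int(self.offsets[int(np.argmax(self.values))])


def _site_windows(
    sites: PeakSet, track: CoverageTrack, extent: int
) -> tuple[np.ndarray, list[GenomicInterval]]:
    """Stack per-site count windows (n_sites, 2*extent + 1); skips
    out-of-bounds sites with a warning."""
    rows = []
    used = []
    for iv in sites:
        arr = track.data.get(iv.chrom)
        if arr is None:
            logger.warning("site on %s not covered by track; skipped", iv.chrom)
            continue
        c = iv.center
        lo, hi = c - extent, c + extent + 1
        if lo < 0 or hi > arr.size:
            logger.warning(
                "site %s:%d-%d window exceeds chromosome bounds; skipped",
                iv.chrom, iv.start, iv.end,
            )
            continue
        rows.append(np.asarray(arr[lo:hi], dtype=float))
        used.append(iv)
    if not rows:
        raise ValueError("zero usable sites after bounds filtering")
    return np.vstack(rows), used


def aggregate_profile(
    sites: PeakSet,
    chip: CoverageTrack,
    input_track: CoverageTrack,
    extent: int,
    mode: str,
    pseudovalue: float | None = None,
    smoothing_bin: int = 1,
) -> EnrichmentProfile:
    """Site-centered aggregate profile, library-size and input normalized.

    At every offset in [-extent, extent], per-bp chip and input counts are
    converted to RPKM; ``input_subtract`` takes their difference,
    ``input_ratio`` the ratio stabilized with ``pseudovalue`` (default: the
    input track's genome-wide mean RPKM). Values are averaged over sites;
    ``smoothing_bin`` > 1 averages consecutive offsets for plotting.
    """
    if mode not in ("input_subtract", "input_ratio"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    chip_win, used = _site_windows(sites, chip, extent)
    input_win, _ = _site_windows(sites.with_intervals(used), input_track, extent)
    chip_rpkm = chip_win * (1e9 / chip.library_size)  # per-bp windows: w = 1 bp
    input_rpkm = input_win * (1e9 / input_track.library_size)
    if mode == "input_subtract":
        per_site = chip_rpkm - input_rpkm
    else:
        eps = pseudovalue if pseudovalue is not None else input_track.mean_rpkm()
        if eps <= 0:
            raise ValueError("pseudovalue must be positive for ratio mode")
        per_site = (chip_rpkm + eps) / (input_rpkm + eps)
    values = per_site.mean(axis=0)
    offsets = np.arange(-extent, extent + 1)
    if smoothing_bin > 1:
        n = (values.size // smoothing_bin) * smoothing_bin
        values = values[:n].reshape(-1, smoothing_bin).mean(axis=1)
        offsets = offsets[:n].reshape(-1, smoothing_bin).mean(axis=1)
    return EnrichmentProfile(
        offsets=offsets, values=values, n_sites=len(used), mode=mode
    )


def filter_intergenic(
    peaks: PeakSet, genes: PeakSet | Sequence[GenomicInterval]
) -> PeakSet:
    """Peaks with zero overlap with any gene interval (idempotent).

    Used for H3K36me3 metaplots, where transcription-coupled signal on
    gene bodies would otherwise dominate the hotspot signal.
    """
    return subtract_overlapping(peaks, genes)


@dataclass
class CorrelationResult:
    pearson: float
    spearman: float
    n: int


def correlate_strengths(
    peaks: PeakSet,
    mark_track: CoverageTrack,
    input_track: CoverageTrack,
    window: int | None = None,
) -> CorrelationResult:
    """Correlation between peak strength and a mark's enrichment per peak.

    Enrichment is the input-subtracted RPKM over the peak interval itself,
    or over center +- ``window`` when given. Requires >= 3 scored peaks
    and non-degenerate variance in both variables.
    """
    scores = []
    enrich = []
    for iv in peaks:
        if iv.score is None:
            raise ValueError("all peaks must be scored")
        arr = mark_track.data.get(iv.chrom)
        inp = input_track.data.get(iv.chrom)
        if arr is None or inp is None:
            continue
        if window is None:
            lo, hi = iv.start, iv.end
        else:
            lo, hi = iv.center - window, iv.center + window + 1
        lo = max(0, lo)
        hi = min(arr.size, hi)
        if hi <= lo:
            continue
        span = hi - lo
        e = rpkm(float(arr[lo:hi].sum()), span, mark_track.library_size) - rpkm(
            float(inp[lo:hi].sum()), span, input_track.library_size
        )
        scores.append(iv.score)
        enrich.append(e)
    if len(scores) < 3:
        raise ValueError("need >= 3 peaks for a correlation")
    scores_arr = np.array(scores)
    enrich_arr = np.array(enrich)
    if np.ptp(scores_arr) == 0 or np.ptp(enrich_arr) == 0:
        raise ValueError(
            "zero variance in peak scores or enrichments; correlation undefined"
        )
    pear = stats.pearsonr(scores_arr, enrich_arr).statistic
    spear = stats.spearmanr(scores_arr, enrich_arr).statistic
    return CorrelationResult(float(pear), float(spear), len(scores))
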