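"""Chromosome-window density correlations and feature-overlap summaries.

Site classes that co-vary along chromosomes (e.g. hotspot sites and
DSB-independent sites) produce correlated per-window counts; promoter-like
classes track CpG-island density instead. Correlations are computed
genome-wide over pooled non-overlapping windows (Pearson by default,
Spearman reported alongside); they are descriptive, with no significance
test under spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    AnnotationSet,
    GenomicInterval,
    PeakSet,
    annotate_feature_context,
    window_counts,
)
from .classify import ClassifiedPeak

__all__ = [
    "DensityCorrelationResult",
    "site_density_correlation",
    "cpg_density_correlation",
    "feature_overlap_percentages",
]


@dataclass
class DensityCorrelationResult:
    window: int
    pearson_r: float
    spearman_r: float
    n_windows: int


def _concat_counts(
    counts: Mapping[str, np.ndarray], chrom_order: Sequence[str]
) -> np.ndarray:
    return np.concatenate([counts[c] for c in chrom_order])


def _correlate(
    vec_a: np.ndarray, vec_b: np.ndarray, window: int
) -> DensityCorrelationResult:
    if vec_a.size < 3:
        raise ValueError("fewer than 3 windows; choose a smaller window size")
    if np.ptp(vec_a) == 0 or np.ptp(vec_b) == 0:
        raise ValueError("zero variance in window counts; correlation undefined")
    pear = stats.pearsonr(vec_a, vec_b).statistic
    spear = stats.spearmanr(vec_a, vec_b).statistic
    return DensityCorrelationResult(
        window=window,
        pearson_r=float(pear),
        spearman_r=float(spear),
        n_windows=int(vec_a.size),
    )


def site_density_correlation(
    sites_a: PeakSet | Sequence[GenomicInterval],
    sites_b: PeakSet | Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int,
) -> DensityCorrelationResult:
    """Correlation of two site sets' per-window counts genome-wide.

    Windows are non-overlapping; the trailing partial window of each
    chromosome is included.
    """
    order = list(chrom_sizes)
    vec_a = _concat_counts(window_counts(sites_a, chrom_sizes, window), order)
    vec_b = _concat_counts(window_counts(sites_b, chrom_sizes, window), order)
    return _correlate(vec_a, vec_b, window)


def cpg_density_correlation(
    sites: PeakSet | Sequence[GenomicInterval],
    cpg_islands: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int = 1_000_000,
) -> DensityCorrelationResult:
    """Correlation between site counts and CpG-island counts per window."""
    order = list(chrom_sizes)
    vec_a = _concat_counts(window_counts(sites, chrom_sizes, window), order)
    vec_b = _concat_counts(window_counts(cpg_islands, chrom_sizes, window), order)
    return _correlate(vec_a, vec_b, window)


def feature_overlap_percentages(
    classified: Sequence[ClassifiedPeak],
    ann: AnnotationSet,
    aggregate: bool = True,
) -> pd.DataFrame:
    """Per-class percentages of peaks in promoter/genic/intergenic context
    and overlapping CpG islands.

    The three context labels are exclusive (precedence promoter > genic >
    intergenic) so their percentages sum to 100 per class; the CpG column
    is independent. Empty classes report NaN.
    """
    if not classified:
        raise ValueError("no classified peaks")
    labels = (
        ("1", "2A", "2B")
        if aggregate
        else tuple(sorted({c.class_label for c in classified}))
    )
    peaks = PeakSet(intervals=[c.interval for c in classified])
    # annotate in sorted order, then map back to peaks by coordinates
    records = annotate_feature_context(peaks, ann)
    by_coord = {
        (r["chrom"], r["start"], r["end"], r["name"]): r for r in records
    }
    rows = []
    for label in labels:
        members = [
            c for c in classified
            if (c.aggregate_label if aggregate else c.class_label) == label
        ]
        if not members:
            rows.append(
                {"class": label, "n": 0, "promoter": np.nan, "genic": np.nan,
                 "intergenic": np.nan, "cpg": np.nan}
            )
            continue
        feats = [
            by_coord[
                (c.interval.chrom, c.interval.start, c.interval.end, c.interval.name)
            ]
            for c in members
        ]
        n = len(members)
        rows.append(
            {
                "class": label,
                "n": n,
                "promoter": 100.0 * sum(f["feature"] == "promoter" for f in feats) / n,
                "genic": 100.0 * sum(f["feature"] == "genic" for f in feats) / n,
                "intergenic": 100.0
                * sum(f["feature"] == "intergenic" for f in feats) / n,
                "cpg": 100.0 * sum(f["cpg_overlap"] for f in feats) / n,
            }
        )
    return pd.DataFrame(rows)
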