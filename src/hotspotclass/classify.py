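"""Multi-evidence classification of PRDM9 binding sites.

PRDM9 peaks are first partitioned against the Prdm9-KO control (nonspecific
signal) and the other strain (shared peaks), then classified from two
evidence axes:

* DMC1 overlap -- marks active DSB formation at the site;
* H3K4me3 status -- ``strain_specific`` (PRDM9-catalyzed), ``shared``
  (present in both strains, i.e. promoter-like) or ``none``.

The six-cell decision table::

            H3K4me3:  strain_specific   shared   none
    DMC1 +            1a                1b       1c
    DMC1 -            1d                2A       2B

Class 1 (1a-1d) are recombination-active, motif-bound hotspot sites;
class 2A are DSB-negative promoter-overlapping sites; class 2B carry
neither mark. The module also provides strength binning, overlap fractions
per strength bin (Spo11-dependence analysis) and the class-distribution
goodness-of-fit chi-square comparing two genotypes' class proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, PeakSet, find_overlaps

CLASS_LABELS = ("1a", "1b", "1c", "1d", "2A", "2B")
AGGREGATE_LABELS = ("1", "2A", "2B")

__all__ = [
    "CLASS_LABELS", "AGGREGATE_LABELS",
    "ClassifiedPeak", "ClassTable", "StatTestResult", "PartitionResult",
    "partition_by_strain", "classify_peak", "classify_all",
    "bin_by_strength", "overlap_fraction_by_bin",
    "class_distribution_gof_chisq",
]


@dataclass(frozen=True)
class ClassifiedPeak:
    """A PRDM9 peak with its evidence flags and class label."""

    interval: GenomicInterval
    strain: str
    dmc1_overlap: bool
    h3k4me3_status: str  # none | strain_specific | shared
    class_label: str

    @property
    def aggregate_label(self) -> str:
        return "1" if self.class_label.startswith("1") else self.class_label


@dataclass
class ClassTable:
    """Per-class peak counts with class 1 aggregated over subclasses."""

    counts: dict[str, int] = field(
        default_factory=lambda: {label: 0 for label in CLASS_LABELS}
    )

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "ClassTable":
        table = cls()
        for label in labels:
            if label not in table.counts:
                raise ValueError(f"unknown class label {label!r}")
            table.counts[label] += 1
        return table

    @property
    def class1(self) -> int:
        return sum(self.counts[l] for l in ("1a", "1b", "1c", "1d"))

    @property
    def class2a(self) -> int:
        return self.counts["2A"]

    @property
    def class2b(self) -> int:
        return self.counts["2B"]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def aggregated(self) -> tuple[int, int, int]:
        """Counts aggregated to (class 1, class 2A, class 2B)."""
        return (self.class1, self.class2a, self.class2b)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": l, "count": self.counts[l]} for l in CLASS_LABELS]
        rows += [
            {"class": "1 (all)", "count": self.class1},
            {"class": "total", "count": self.total},
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StatTestResult:
    """A test statistic with degrees of freedom and p-value."""

    statistic: float
    df: float
    p_value: float


@dataclass
class PartitionResult:
    """Outcome of the strain/KO partition of two strains' PRDM9 peaks."""

    specific_a: PeakSet
    specific_b: PeakSet
    common_a: PeakSet
    common_b: PeakSet
    removed_a: PeakSet
    removed_b: PeakSet

    @property
    def common(self) -> PeakSet:
        """Shared peaks of both strains pooled into one set."""
        merged = list(self.common_a) + list(self.common_b)
        return self.common_a.with_intervals(merged)


def partition_by_strain(
    prdm9_a: PeakSet,
    prdm9_b: PeakSet,
    prdm9_ko: PeakSet,
    min_overlap: int = 1,
) -> PartitionResult:
    """Split each strain's peaks into KO-removed, shared and specific.

    ``removed_X`` are peaks overlapping the Prdm9-KO set (nonspecific
    signal). Among the remainder, peaks of A overlapping the remainder of B
    (and their partners) form the shared pool; what is left is strain
    specific. Per strain, specific + common + removed equals the input.
    """
    ko_a = find_overlaps(prdm9_a, prdm9_ko, min_overlap=min_overlap)
    ko_b = find_overlaps(prdm9_b, prdm9_ko, min_overlap=min_overlap)
    removed_a = [iv for iv, h in zip(prdm9_a, ko_a) if h]
    kept_a = [iv for iv, h in zip(prdm9_a, ko_a) if not h]
    removed_b = [iv for iv, h in zip(prdm9_b, ko_b) if h]
    kept_b = [iv for iv, h in zip(prdm9_b, ko_b) if not h]

    cross = find_overlaps(kept_a, kept_b, min_overlap=min_overlap)
    common_a = [iv for iv, h in zip(kept_a, cross) if h]
    specific_a = [iv for iv, h in zip(kept_a, cross) if not h]
    # partners found from B's side (the overlap relation is symmetric)
    cross_b = find_overlaps(kept_b, kept_a, min_overlap=min_overlap)
    common_b = [iv for iv, h in zip(kept_b, cross_b) if h]
    specific_b = [iv for iv, h in zip(kept_b, cross_b) if not h]

    return PartitionResult(
        specific_a=prdm9_a.with_intervals(specific_a),
        specific_b=prdm9_b.with_intervals(specific_b),
        common_a=prdm9_a.with_intervals(common_a),
        common_b=prdm9_b.with_intervals(common_b),
        removed_a=prdm9_a.with_intervals(removed_a),
        removed_b=prdm9_b.with_intervals(removed_b),
    )


def classify_peak(
    dmc1_overlap: bool,
    h3k4_this_strain: bool,
    h3k4_other_strain: bool,
) -> str:
    """Class label from the three boolean evidence flags (decision table)."""
    if not h3k4_this_strain:
        status = "none"
    elif h3k4_other_strain:
        status = "shared"
    else:
        status = "strain_specific"
    if dmc1_overlap:
        return {"strain_specific": "1a", "shared": "1b", "none": "1c"}[status]
    return {"strain_specific": "1d", "shared": "2A", "none": "2B"}[status]


def _h3k4_status(h3k4_this: bool, h3k4_other: bool) -> str:
    if not h3k4_this:
        return "none"
    return "shared" if h3k4_other else "strain_specific"


def classify_all(
    prdm9: PeakSet,
    dmc1: PeakSet,
    h3k4_this: PeakSet,
    h3k4_other: PeakSet,
    min_overlap: int = 1,
    shared_only: bool = False,
) -> tuple[list[ClassifiedPeak], ClassTable]:
    """Classify every peak of ``prdm9`` from binary overlap evidence.

    ``shared_only`` implements the rule for peaks common to both strains,
    where no strain-specific H3K4me3 call is possible: any overlapping
    H3K4me3 is treated as shared.
    """
    dmc1_hits = find_overlaps(prdm9, dmc1, min_overlap=min_overlap)
    this_hits = find_overlaps(prdm9, h3k4_this, min_overlap=min_overlap)
    other_hits = find_overlaps(prdm9, h3k4_other, min_overlap=min_overlap)
    classified = []
    for iv, d, t, o in zip(prdm9, dmc1_hits, this_hits, other_hits):
        has_d, has_t, has_o = bool(d), bool(t), bool(o)
        if shared_only:
            has_o = has_t
        label = classify_peak(has_d, has_t, has_o)
        classified.append(
            ClassifiedPeak(
                interval=iv,
                strain=prdm9.strain,
                dmc1_overlap=has_d,
                h3k4me3_status=_h3k4_status(has_t, has_o),
                class_label=label,
            )
        )
    table = ClassTable.from_labels([c.class_label for c in classified])
    return classified, table


def bin_by_strength(peaks: PeakSet, n_bins: int) -> list[PeakSet]:
    """Equal-count quantile bins by score, ordered weakest to strongest.

    Ties are broken by coordinate order; bin sizes differ by at most one.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > len(peaks):
        raise ValueError(f"n_bins={n_bins} exceeds peak count {len(peaks)}")
    if any(iv.score is None for iv in peaks):
        raise ValueError("all peaks must be scored for strength binning")
    ordered = sorted(peaks, key=lambda iv: (iv.score, iv.chrom, iv.start, iv.end))
    bounds = np.linspace(0, len(ordered), n_bins + 1).round().astype(int)
    return [
        peaks.with_intervals(ordered[bounds[i] : bounds[i + 1]])
        for i in range(n_bins)
    ]


def overlap_fraction_by_bin(
    bins: Sequence[PeakSet],
    other: PeakSet,
    min_overlap: int = 1,
) -> np.ndarray:
    """Fraction of peaks per strength bin overlapping ``other``."""
    fractions = []
    for b in bins:
        if len(b) == 0:
            raise ValueError("empty strength bin")
        hits = find_overlaps(b, other, min_overlap=min_overlap)
        fractions.append(sum(bool(h) for h in hits) / len(b))
    return np.array(fractions)


def class_distribution_gof_chisq(
    observed: tuple[int, int, int] | ClassTable,
    reference: tuple[int, int, int] | ClassTable,
    method: str = "gof",
) -> StatTestResult:
    """Chi-square comparison of (class 1, 2A, 2B) counts between genotypes.

    The default is a one-sample Pearson goodness-of-fit of the observed
    counts against the reference proportions: ``expected_i =
    observed_total * reference_i / reference_total``, df = 2. The printed
    statistics of the study match this form. ``method='contingency'``
    instead runs a 2x3 contingency chi-square (without continuity
    correction) as a sensitivity variant.
    """
    obs = np.asarray(
        observed.aggregated() if isinstance(observed, ClassTable) else observed,
        dtype=float,
    )
    ref = np.asarray(
        reference.aggregated() if isinstance(reference, ClassTable) else reference,
        dtype=float,
    )
    if obs.shape != (3,) or ref.shape != (3,):
        raise ValueError("observed and reference must be (class1, 2A, 2B) triples")
    if obs.sum() <= 0:
        raise ValueError("observed total must be positive")
    if method == "gof":
        if np.any(ref <= 0):
            raise ValueError("reference counts must all be positive")
        expected = obs.sum() * ref / ref.sum()
        stat, p = stats.chisquare(obs, f_exp=expected)
        return StatTestResult(float(stat), 2, float(p))
    if method == "contingency":
        stat, p, df, _ = stats.chi2_contingency(np.vstack([obs, ref]), correction=False)
        return StatTestResult(float(stat), int(df), float(p))
    raise ValueError(f"unknown method {method!r}")
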