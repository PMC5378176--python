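"""Peak partitioning, the six-class decision table and the class-
distribution chi-square."""

import numpy as np
import pytest

from hotspotclass.classify import (
    ClassTable,
    bin_by_strength,
    class_distribution_gof_chisq,
    classify_all,
    classify_peak,
    overlap_fraction_by_bin,
    partition_by_strain,
)
from hotspotclass.intervals import GenomicInterval, PeakSet


def peakset(coords, scores=None, **meta):
    ivs = [
        GenomicInterval("chr1", s, e,
                        score=None if scores is None else scores[i])
        for i, (s, e) in enumerate(coords)
    ]
    return PeakSet(intervals=ivs, **meta)


class TestDecisionTable:
    @pytest.mark.parametrize(
        "dmc1,h4_this,h4_other,expected",
        [
            (True, True, False, "1a"),
            (True, True, True, "1b"),
            (True, False, False, "1c"),
            (True, False, True, "1c"),  # other-strain mark alone is no mark
            (False, True, False, "1d"),
            (False, True, True, "2A"),
            (False, False, False, "2B"),
            (False, False, True, "2B"),
        ],
    )
    def test_all_cells(self, dmc1, h4_this, h4_other, expected):
        assert classify_peak(dmc1, h4_this, h4_other) == expected


class TestPartition:
    def test_set_arithmetic_example(self):
        # 10 peaks in A: 1 overlaps KO, 2 of the rest overlap B
        a = peakset([(i * 1000, i * 1000 + 100) for i in range(10)])
        ko = peakset([(0, 150)])
        b = peakset([(1000, 1080), (2020, 2120), (50_000, 50_100)])
        part = partition_by_strain(a, b, ko)
        assert len(part.removed_a) == 1
        assert len(part.common_a) == 2
        assert len(part.specific_a) == 7

    def test_empty_ko_and_b_is_identity(self):
        a = peakset([(0, 100), (500, 600)])
        part = partition_by_strain(a, PeakSet(), PeakSet())
        assert part.specific_a == a
        assert len(part.common_a) == len(part.removed_a) == 0

    def test_conservation_per_strain(self, default_sim):
        ps = default_sim.peaksets
        part = partition_by_strain(
            ps["PRDM9_B6"], ps["PRDM9_RJ2"], ps["PRDM9_Prdm9KO"]
        )
        for total, p in (
            (ps["PRDM9_B6"], (part.specific_a, part.common_a, part.removed_a)),
            (ps["PRDM9_RJ2"], (part.specific_b, part.common_b, part.removed_b)),
        ):
            assert sum(len(x) for x in p) == len(total)

    def test_published_b6_bookkeeping_identity(self, rng):
        """3041 B6 peaks decompose as 2601 specific + 213 shared + 227
        KO-removed; a synthetic set built with those counts partitions
        back into exactly those numbers."""
        n_specific, n_common, n_removed = 2601, 213, 227
        step = 500
        coords, b_coords, ko_coords = [], [], []
        pos = 0
        for _ in range(n_specific):
            coords.append((pos, pos + 100)); pos += step
        for _ in range(n_common):
            coords.append((pos, pos + 100))
            b_coords.append((pos + 50, pos + 150))
            pos += step
        for _ in range(n_removed):
            coords.append((pos, pos + 100))
            ko_coords.append((pos + 50, pos + 150))
            pos += step
        part = partition_by_strain(
            peakset(coords), peakset(b_coords), peakset(ko_coords)
        )
        assert (
            len(part.specific_a), len(part.common_a), len(part.removed_a)
        ) == (n_specific, n_common, n_removed)
        assert len(part.specific_a) + len(part.common_a) + len(part.removed_a) == 3041


class TestClassifyAll:
    def test_truth_recovery_on_default_synthetic(self, default_sim):
        ps = default_sim.peaksets
        truth = default_sim.truth
        for strain, other in (("B6", "RJ2"), ("RJ2", "B6")):
            part = partition_by_strain(
                ps[f"PRDM9_{strain}"] if strain == "B6" else ps["PRDM9_B6"],
                ps["PRDM9_RJ2"], ps["PRDM9_Prdm9KO"],
            )
            specific = part.specific_a if strain == "B6" else part.specific_b
            classified, table = classify_all(
                specific, ps[f"DMC1_{strain}"],
                ps[f"H3K4me3_{strain}"], ps[f"H3K4me3_{other}"],
            )
            expected = truth[truth["strain"] == strain]
            by_center = {
                (r.chrom, r.center): getattr(r, "_asdict", lambda: r)
                for r in expected.itertuples()
            }
            lookup = expected.set_index(["chrom", "center"])["class"]
            assert len(classified) == len(expected)
            for c in classified:
                key = (c.interval.chrom, c.interval.center)
                assert c.aggregate_label == lookup.loc[key]
            assert table.aggregated() == (50, 20, 30)

    def test_no_evidence_means_all_2b(self):
        prdm9 = peakset([(0, 100), (1000, 1100)])
        classified, table = classify_all(prdm9, PeakSet(), PeakSet(), PeakSet())
        assert all(c.class_label == "2B" for c in classified)
        assert table.aggregated() == (0, 0, 2)

    def test_classification_is_pure(self, default_sim):
        ps = default_sim.peaksets
        args = (ps["PRDM9_B6"], ps["DMC1_B6"],
                ps["H3K4me3_B6"], ps["H3K4me3_RJ2"])
        first = classify_all(*args)
        second = classify_all(*args)
        assert [c.class_label for c in first[0]] == [c.class_label for c in second[0]]
        assert first[1].counts == second[1].counts

    def test_shared_only_mode_never_calls_strain_specific(self, default_sim):
        ps = default_sim.peaksets
        classified, _ = classify_all(
            ps["PRDM9_B6"], ps["DMC1_B6"],
            ps["H3K4me3_B6"], PeakSet(), shared_only=True,
        )
        assert all(c.h3k4me3_status != "strain_specific" for c in classified)


class TestStrengthBins:
    def test_equal_bins(self):
        peaks = peakset([(i * 10, i * 10 + 5) for i in range(100)],
                        scores=list(np.arange(100.0)))
        bins = bin_by_strength(peaks, 10)
        assert [len(b) for b in bins] == [10] * 10
        means = [np.mean([iv.score for iv in b]) for b in bins]
        assert means == sorted(means)

    def test_tied_scores_fall_back_to_coordinates(self):
        peaks = peakset([(i * 10, i * 10 + 5) for i in range(100)],
                        scores=[1.0] * 100)
        bins = bin_by_strength(peaks, 10)
        assert [len(b) for b in bins] == [10] * 10
        starts = [iv.start for b in bins for iv in b]
        assert starts == sorted(starts)

    def test_uneven_split_differs_by_at_most_one(self):
        peaks = peakset([(i * 10, i * 10 + 5) for i in range(101)],
                        scores=list(np.arange(101.0)))
        sizes = sorted(len(b) for b in bin_by_strength(peaks, 10))
        assert sum(sizes) == 101
        assert max(sizes) - min(sizes) <= 1

    def test_missing_scores_rejected(self):
        peaks = peakset([(0, 10), (20, 30)])
        with pytest.raises(ValueError, match="scored"):
            bin_by_strength(peaks, 2)

    def test_overlap_fractions_trivial_cases(self):
        peaks = peakset([(i * 100, i * 100 + 50) for i in range(20)],
                        scores=list(np.arange(20.0)))
        bins = bin_by_strength(peaks, 4)
        assert overlap_fraction_by_bin(bins, peaks).tolist() == [1.0] * 4
        far = peakset([(10_000_000, 10_000_100)])
        assert overlap_fraction_by_bin(bins, far).tolist() == [0.0] * 4

    def test_strength_dependent_overlap_is_monotone_step(self):
        # only the strongest half of peaks has a partner
        peaks = peakset([(i * 100, i * 100 + 50) for i in range(40)],
                        scores=list(np.arange(40.0)))
        strong = peakset([
            (iv.start, iv.end) for iv in peaks if iv.score >= 20
        ])
        bins = bin_by_strength(peaks, 4)
        assert overlap_fraction_by_bin(bins, strong).tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_weighted_mean_equals_overall_fraction(self, default_sim):
        ps = default_sim.peaksets
        peaks = ps["PRDM9_B6"]
        bins = bin_by_strength(peaks, 5)
        fr = overlap_fraction_by_bin(bins, ps["PRDM9_B6_Spo11KO"])
        weights = np.array([len(b) for b in bins])
        from hotspotclass.intervals import find_overlaps

        overall = sum(
            bool(h) for h in find_overlaps(peaks, ps["PRDM9_B6_Spo11KO"])
        ) / len(peaks)
        assert np.isclose(np.average(fr, weights=weights), overall)


def reference_pearson_gof(obs, ref):
    obs = np.asarray(obs, float)
    ref = np.asarray(ref, float)
    exp = obs.sum() * ref / ref.sum()
    return float(((obs - exp) ** 2 / exp).sum())


class TestClassChiSquare:
    def test_spo11ko_vs_b6_statistic(self):
        res = class_distribution_gof_chisq((1010, 1, 59), (1896, 459, 246))
        assert res.statistic == pytest.approx(272.26, abs=0.01)
        assert res.df == 2
        assert res.p_value < 1e-6

    def test_spo11ko_vs_strongest_b6_statistic(self):
        res = class_distribution_gof_chisq((1010, 1, 59), (861, 198, 11))
        assert res.statistic == pytest.approx(431.24, abs=0.01)
        assert res.df == 2

    def test_proportional_counts_give_zero(self):
        res = class_distribution_gof_chisq((100, 40, 20), (500, 200, 100))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_reference_count_rejected(self):
        with pytest.raises(ValueError):
            class_distribution_gof_chisq((10, 5, 1), (10, 0, 5))

    def test_matches_independent_formula_on_random_triples(self, rng):
        for _ in range(50):
            obs = tuple(int(x) for x in rng.integers(1, 2000, 3))
            ref = tuple(int(x) for x in rng.integers(1, 2000, 3))
            res = class_distribution_gof_chisq(obs, ref)
            assert res.statistic == pytest.approx(
                reference_pearson_gof(obs, ref), abs=1e-9
            )

    def test_contingency_variant_differs(self):
        gof = class_distribution_gof_chisq((1010, 1, 59), (1896, 459, 246))
        cont = class_distribution_gof_chisq(
            (1010, 1, 59), (1896, 459, 246), method="contingency"
        )
        assert cont.statistic != pytest.approx(gof.statistic, abs=1.0)

    def test_class_table_inputs_accepted(self):
        t1 = ClassTable.from_labels(["1a"] * 3 + ["2A"] * 2 + ["2B"])
        t2 = ClassTable.from_labels(["1b"] * 6 + ["2A"] * 4 + ["2B"] * 2)
        res = class_distribution_gof_chisq(t1, t2)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
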