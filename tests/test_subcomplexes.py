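"""Subcomplex classification, co-occupancy, state enrichment, expression."""

import numpy as np
import pandas as pd
import pytest

from bafmap.intervals import GenomicInterval, Peak, PeakSet, StateSegmentation
from bafmap.subcomplexes import (
    CLASS_LABELS,
    assign_peaks_to_genes,
    class_label,
    classify_subcomplexes,
    cooccupancy_fractions,
    expression_by_occupancy,
    state_enrichment,
)
from bafmap.simulate import SimulationConfig, simulate_peaksets

from conftest import make_peaks


@pytest.mark.parametrize(
    "triple,expected",
    [
        ((True, True, True), "BAF+PBAF+ncBAF"),
        ((True, True, False), "BAF+PBAF"),
        ((True, False, True), "BAF+ncBAF"),
        ((False, True, True), "PBAF+ncBAF"),
        ((True, False, False), "BAF_only"),
        ((False, True, False), "PBAF_only"),
        ((False, False, True), "ncBAF_only"),
        ((False, False, False), "BRG1_unassigned"),
    ],
)
def test_class_label_is_pure_function_of_triple(triple, expected):
    assert class_label(*triple) == expected


class TestClassify:
    def test_definitional_single_site_calls(self):
        brg1 = make_peaks("BRG1", [("chr1", 100, 700, "s1"), ("chr1", 2000, 2600, "s2")])
        dpf2 = make_peaks("DPF2", [("chr1", 150, 750)])
        pbrm1 = make_peaks("PBRM1", [("chr1", 2100, 2700), ("chr1", 9000, 9600)])
        brd9 = make_peaks("BRD9", [("chr1", 2050, 2650)])
        calls = classify_subcomplexes(brg1, dpf2, pbrm1, brd9)
        assert calls.table.loc["s1", "class_label"] == "BAF_only"
        assert calls.table.loc["s2", "class_label"] == "PBAF+ncBAF"
        assert calls.pbrm1_without_brg1 is not None
        assert [p.start for p in calls.pbrm1_without_brg1] == [9000]

    def test_empty_brg1_warns_and_returns_empty(self):
        empty = PeakSet("BRG1", [])
        other = make_peaks("DPF2", [("chr1", 0, 10)])
        with pytest.warns(UserWarning, match="empty BRG1"):
            calls = classify_subcomplexes(empty, other, other, other)
        assert len(calls) == 0

    def test_class_counts_partition_brg1_set(self):
        cfg = SimulationConfig(seed=7, n_sites=1500)
        ps, _ = simulate_peaksets(cfg)
        calls = classify_subcomplexes(ps["BRG1"], ps["DPF2"], ps["PBRM1"], ps["BRD9"])
        assert int(calls.class_counts().sum()) == len(ps["BRG1"])

    def test_invariant_under_input_record_order(self):
        cfg = SimulationConfig(seed=11, n_sites=300)
        ps, _ = simulate_peaksets(cfg)
        shuffled = {
            f: PeakSet(s.factor, list(reversed(s.peaks))) for f, s in ps.items()
        }
        a = classify_subcomplexes(ps["BRG1"], ps["DPF2"], ps["PBRM1"], ps["BRD9"])
        b = classify_subcomplexes(
            shuffled["BRG1"], shuffled["DPF2"], shuffled["PBRM1"], shuffled["BRD9"]
        )
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_recovers_planted_class_proportions(self):
        cfg = SimulationConfig(seed=5, n_sites=1000)
        ps, _ = simulate_peaksets(cfg)
        calls = classify_subcomplexes(ps["BRG1"], ps["DPF2"], ps["PBRM1"], ps["BRD9"])
        counts = calls.class_counts()
        for label, p in zip(CLASS_LABELS, cfg.class_probs):
            se = np.sqrt(p * (1 - p) / cfg.n_sites)
            assert abs(counts[label] / cfg.n_sites - p) <= 3 * se


class TestCooccupancy:
    def _calls(self, seed=3, n_sites=400):
        cfg = SimulationConfig(seed=seed, n_sites=n_sites)
        ps, _ = simulate_peaksets(cfg)
        return ps, classify_subcomplexes(ps["BRG1"], ps["DPF2"], ps["PBRM1"], ps["BRD9"])

    def test_no_crtf_peaks_gives_zero_fractions(self):
        ps, calls = self._calls()
        tab = cooccupancy_fractions(calls, [PeakSet("P3F", [])])
        nonempty = tab.class_sizes[tab.class_sizes > 0].index
        assert (tab.fractions.loc[nonempty, "P3F"] == 0).all()

    def test_crtf_identical_to_class_sites_gives_fraction_one(self):
        ps, calls = self._calls()
        members = calls.class_members("BAF_only")
        crtf = PeakSet("P3F", [Peak(p.interval, f"c{i}") for i, p in enumerate(members)])
        tab = cooccupancy_fractions(calls, [crtf])
        assert tab.fractions.loc["BAF_only", "P3F"] == 1.0

    def test_empty_class_is_nan_not_zero(self):
        brg1 = make_peaks("BRG1", [("chr1", 0, 100, "s")])
        nothing = PeakSet("X", [])
        calls = classify_subcomplexes(brg1, nothing, nothing, nothing)
        tab = cooccupancy_fractions(calls, [PeakSet("P3F", [])])
        assert np.isnan(tab.fractions.loc["BAF_only", "P3F"])
        assert tab.fractions.loc["BRG1_unassigned", "P3F"] == 0.0

    def test_fractions_monotone_under_min_bp_relaxation(self):
        ps, calls = self._calls(seed=9)
        loose = cooccupancy_fractions(calls, [ps["MYCN"]], min_bp=1)
        strict = cooccupancy_fractions(calls, [ps["MYCN"]], min_bp=200)
        nonempty = loose.class_sizes[loose.class_sizes > 0].index
        assert (
            loose.fractions.loc[nonempty, "MYCN"]
            >= strict.fractions.loc[nonempty, "MYCN"]
        ).all()

    def test_recovers_planted_bernoulli_rates(self):
        cfg = SimulationConfig(seed=21, n_sites=2000)
        ps, _ = simulate_peaksets(cfg)
        calls = classify_subcomplexes(ps["BRG1"], ps["DPF2"], ps["PBRM1"], ps["BRD9"])
        tab = cooccupancy_fractions(calls, [ps["P3F"]])
        for label in ("BAF_only", "PBAF_only"):
            p = cfg.crtf_probs[label][0]
            n = int(tab.class_sizes[label])
            se = np.sqrt(p * (1 - p) / n)
            assert abs(float(tab.fractions.loc[label, "P3F"]) - p) <= 3 * se


class TestStateEnrichment:
    def test_single_state_covering_genome_has_zero_enrichment(self):
        seg = StateSegmentation(
            [(GenomicInterval("chr1", 0, 100_000), "all")], {"chr1": 100_000}
        )
        peaks = make_peaks("F", [("chr1", i * 1000, i * 1000 + 100) for i in range(20)])
        enr = state_enrichment(peaks, seg)
        assert enr["all"] == 0.0

    def test_concentration_in_small_state_matches_closed_form(self):
        # all peaks in a state covering 10% of the genome -> log2(10)
        seg = StateSegmentation(
            [
                (GenomicInterval("chr1", 0, 100_000), "hot"),
                (GenomicInterval("chr1", 100_000, 1_000_000), "cold"),
            ],
            {"chr1": 1_000_000},
        )
        peaks = make_peaks("F", [("chr1", i * 1000, i * 1000 + 50) for i in range(50)])
        enr = state_enrichment(peaks, seg)
        assert enr["hot"] == pytest.approx(np.log2(10), abs=1e-12)
        assert enr["cold"] == -np.inf

    def test_uniform_peaks_have_vanishing_enrichment(self):
        rng = np.random.default_rng(17)
        L = 1_000_000
        seg = StateSegmentation(
            [
                (GenomicInterval("chr1", 0, 300_000), "a"),
                (GenomicInterval("chr1", 300_000, 650_000), "b"),
                (GenomicInterval("chr1", 650_000, 1_000_000), "c"),
            ],
            {"chr1": L},
        )
        starts = rng.integers(0, L - 10, size=50_000)
        peaks = PeakSet(
            "F",
            [
                Peak(GenomicInterval("chr1", int(s), int(s) + 10), f"p{i}")
                for i, s in enumerate(sorted(set(starts.tolist())))
            ],
        )
        enr = state_enrichment(peaks, seg)
        assert (enr.abs() < 0.2).all()

    def test_enlarging_state_share_decreases_enrichment(self):
        peaks = make_peaks("F", [("chr1", 1000 * i, 1000 * i + 100) for i in range(10)])
        def enr_for(width):
            seg = StateSegmentation(
                [
                    (GenomicInterval("chr1", 0, width), "s"),
                    (GenomicInterval("chr1", width, 1_000_000), "rest"),
                ],
                {"chr1": 1_000_000},
            )
            return state_enrichment(peaks, seg)["s"]
        assert enr_for(200_000) < enr_for(20_000)

    def test_gap_midpoints_counted_in_none_state(self):
        seg = StateSegmentation(
            [(GenomicInterval("chr1", 0, 1000), "s")], {"chr1": 10_000}
        )
        peaks = make_peaks("F", [("chr1", 5000, 5100)])
        enr = state_enrichment(peaks, seg)
        assert enr["none"] == pytest.approx(np.log2(1 / 0.9), abs=1e-12)


class TestGeneAssignment:
    TSS = {
        "GENEA": GenomicInterval("chr1", 100_000, 100_001),
        "GENEB": GenomicInterval("chr1", 500_000, 500_001),
    }

    def test_peak_midpoint_exactly_at_tss_is_assigned(self):
        peaks = make_peaks("F", [("chr1", 99_950, 100_050)])
        out = assign_peaks_to_genes(peaks, self.TSS, window_bp=50_000)
        assert [a.gene for a in out] == ["GENEA"]

    def test_midpoint_one_bp_beyond_window_is_not_assigned(self):
        w = 50_000
        mid = 100_000 + w + 1
        peaks = make_peaks("F", [("chr1", mid - 50, mid + 50)])
        out = assign_peaks_to_genes(peaks, self.TSS, window_bp=w)
        assert out == []
        edge = make_peaks("F", [("chr1", mid - 51, mid + 49)])  # midpoint at +w
        assert [a.gene for a in assign_peaks_to_genes(edge, self.TSS, window_bp=w)] == ["GENEA"]

    def test_noiseless_planted_binding_recovered_exactly(self, rng):
        tss = {
            f"G{i:03d}": GenomicInterval("chr1", 10_000 + 200_000 * i, 10_001 + 200_000 * i)
            for i in range(100)
        }
        bound = sorted(rng.choice(100, size=40, replace=False).tolist())
        peaks = make_peaks(
            "F",
            [("chr1", 10_000 + 200_000 * i - 50, 10_000 + 200_000 * i + 50) for i in bound],
        )
        out = assign_peaks_to_genes(peaks, tss, window_bp=50_000)
        assert sorted(a.gene for a in out) == [f"G{i:03d}" for i in bound]


class TestExpressionByOccupancy:
    def test_all_zero_log2fc_gives_zero_median_and_degenerate_ci(self):
        deg = pd.Series(0.0, index=[f"g{i}" for i in range(30)])
        res = expression_by_occupancy(deg, {"grp": list(deg.index)}, seed=0)
        row = res.loc["grp"]
        assert row["median_log2fc"] == 0 and row["ci_low"] == 0 and row["ci_high"] == 0

    def test_median_of_three(self):
        deg = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        res = expression_by_occupancy(deg, {"g": ["a", "b", "c"]}, seed=0)
        assert res.loc["g", "median_log2fc"] == 2.0

    def test_empty_group_reported_with_n_zero(self):
        deg = pd.Series({"a": 1.0})
        res = expression_by_occupancy(deg, {"none": ["zzz"]}, seed=0)
        assert res.loc["none", "n"] == 0 and np.isnan(res.loc["none", "median_log2fc"])

    def test_planted_group_shift_recovered_across_seeds(self):
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            rng = np.random.default_rng(900 + s)
            deg = pd.Series(
                np.concatenate([rng.normal(0.8, 1.0, 500), rng.normal(0.0, 1.0, 500)]),
                index=[f"g{i}" for i in range(1000)],
            )
            groups = {
                "shifted": [f"g{i}" for i in range(500)],
                "null": [f"g{i}" for i in range(500, 1000)],
            }
            res = expression_by_occupancy(deg, groups, n_boot=10, seed=s)
            diff = res.loc["shifted", "median_log2fc"] - res.loc["null", "median_log2fc"]
            hits += 0.6 <= diff <= 1.0
        assert hits >= 95
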