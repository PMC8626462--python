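"""Spike-in normalization, quartile stratification, differential occupancy."""

import numpy as np
import pandas as pd
import pytest

from bafmap.chiprx import (
    SpikeInCounts,
    invasion_analysis,
    quartile_stratify,
    read_spikein_counts,
    rpmpr_normalize,
    rrpm_normalize,
    signal_delta_track,
    write_spikein_counts,
)
from bafmap.simulate import SimulationConfig, simulate_chiprx


def lib(counts, spike=1_000_000, human=None, cond="c"):
    s = pd.Series(counts)
    return SpikeInCounts("L", cond, s, human or int(s.sum() * 2 + 10), spike)


class TestSpikeInCounts:
    def test_counts_exceeding_human_total_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SpikeInCounts("L", "c", pd.Series({"p": 100}), 50, 1000)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SpikeInCounts("L", "c", pd.Series({"p": -1}), 50, 1000)

    def test_tsv_roundtrip(self, tmp_path):
        a = lib({"p1": 5, "p2": 9}, spike=123_456)
        path = tmp_path / "lib.tsv"
        write_spikein_counts(a, path)
        b = read_spikein_counts(path)
        pd.testing.assert_series_equal(a.counts, b.counts)
        assert b.spike_mapped_total == 123_456


class TestRRPM:
    def test_million_spike_reads_is_identity_scale(self):
        sig = rrpm_normalize(lib({"p": 137}, spike=1_000_000))
        assert sig["p"] == 137.0

    def test_direct_evaluation(self):
        assert rrpm_normalize(lib({"p": 100}, spike=500_000))["p"] == 200.0

    def test_doubling_spike_total_halves_signal_exactly(self, rng):
        counts = {f"p{i}": int(v) for i, v in enumerate(rng.integers(0, 5000, 200))}
        s1 = rrpm_normalize(lib(counts, spike=250_000))
        s2 = rrpm_normalize(lib(counts, spike=500_000))
        assert (s2 * 2 == s1).all()

    def test_zero_spike_reads_is_hard_error(self):
        with pytest.raises(ValueError, match="spike"):
            rrpm_normalize(lib({"p": 1}, spike=0))


class TestRPMPR:
    def test_single_peak_gets_the_full_million(self):
        assert rpmpr_normalize(lib({"p": 42}), ["p"])["p"] == 1e6

    def test_direct_proportion(self):
        sig = rpmpr_normalize(lib({"a": 300, "b": 700}), ["a", "b"])
        assert sig["a"] == 3e5 and sig["b"] == 7e5

    def test_sums_to_one_million(self, rng):
        counts = {f"p{i}": int(v) + 1 for i, v in enumerate(rng.integers(0, 999, 300))}
        assert rpmpr_normalize(lib(counts), list(counts)).sum() == pytest.approx(1e6, rel=1e-12)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="no reads"):
            rpmpr_normalize(lib({"a": 0, "b": 0}), ["a", "b"])

    def test_missing_union_peaks_count_zero(self):
        sig = rpmpr_normalize(lib({"a": 10}), ["a", "ghost"])
        assert sig["ghost"] == 0.0


class TestQuartileStratify:
    def test_eight_peaks_split_two_per_bin(self):
        anchor = pd.Series({f"p{i}": float(i) for i in range(8)})
        q = quartile_stratify(anchor, anchor)
        assert q["n"].tolist() == [2, 2, 2, 2]

    def test_remainder_goes_to_lower_quartiles(self):
        anchor = pd.Series({f"p{i}": float(i) for i in range(10)})
        q = quartile_stratify(anchor, anchor)
        assert q["n"].tolist() == [3, 3, 2, 2]

    def test_fewer_than_eight_anchors_rejected(self):
        anchor = pd.Series({f"p{i}": 1.0 for i in range(7)})
        with pytest.raises(ValueError, match=">=8"):
            quartile_stratify(anchor, anchor)

    def test_self_coupling_gives_strictly_increasing_medians(self, rng):
        anchor = pd.Series(rng.lognormal(3, 1, 100), index=[f"p{i}" for i in range(100)])
        q = quartile_stratify(anchor, anchor)
        med = q["median_partner"].to_numpy()
        assert (np.diff(med) > 0).all()

    def test_absent_partner_peaks_counted_as_zero(self):
        anchor = pd.Series({f"p{i}": float(i + 1) for i in range(8)})
        partner = pd.Series({"p7": 5.0})
        q = quartile_stratify(anchor, partner)
        assert q.loc["Q1", "median_partner"] == 0.0
        assert q.loc["Q4", "median_partner"] == 2.5  # {0, 5}


class TestInvasion:
    def test_identical_libraries_give_null_result(self):
        a = lib({"s1": 10, "s2": 20})
        b = lib({"s1": 10, "s2": 20})
        res = invasion_analysis(["s1", "s2"], a, b)
        assert (res.deltas == 0).all()
        assert res.fraction_increased == 0.0  # strictly greater than
        assert res.p_value == 1.0

    def test_direct_delta_evaluation(self):
        # RRPM 10 -> 20 with pseudocount 0.5
        a = lib({"s": 10}, spike=1_000_000)
        b = lib({"s": 20}, spike=1_000_000)
        res = invasion_analysis(["s"], a, b, pseudocount=0.5)
        assert res.deltas["s"] == pytest.approx(np.log2(20.5 / 10.5), abs=1e-12)

    def test_antisymmetric_under_condition_swap(self, rng):
        names = [f"s{i}" for i in range(50)]
        a = lib(dict(zip(names, rng.integers(0, 500, 50).tolist())))
        b = lib(dict(zip(names, rng.integers(0, 500, 50).tolist())))
        fwd = invasion_analysis(names, a, b)
        rev = invasion_analysis(names, b, a)
        assert np.max(np.abs(fwd.deltas.to_numpy() + rev.deltas.to_numpy())) == 0.0

    def test_missing_site_error_names_the_site(self):
        a = lib({"s1": 1})
        b = lib({"s1": 1})
        with pytest.raises(KeyError, match="ghost"):
            invasion_analysis(["s1", "ghost"], a, b)

    def test_planted_shift_recovered(self):
        cfg = SimulationConfig(seed=42, n_sites=8, depth=100.0)
        sites = [f"s{i}" for i in range(1000)]
        libs, _ = simulate_chiprx(cfg, sites, {"ctrl": 0.0, "trt": 1.0})
        res = invasion_analysis(sites, libs["ctrl"], libs["trt"])
        assert 0.85 <= res.median_delta <= 1.15
        assert res.p_value < 1e-6

    def test_null_fraction_of_large_deltas_is_small(self):
        # no condition effect, every site at depth >= 100: |delta| > 3*MAD rare
        frac = []
        for rep in range(20):
            cfg = SimulationConfig(
                seed=500 + rep, n_sites=8, depth=100.0, weight_sigma=0.0
            )
            sites = [f"s{i}" for i in range(400)]
            libs, _ = simulate_chiprx(cfg, sites, {"a": 0.0, "b": 0.0})
            d = invasion_analysis(sites, libs["a"], libs["b"]).deltas.to_numpy()
            mad = 1.4826 * np.median(np.abs(d - np.median(d)))
            frac.append(np.mean(np.abs(d) > 3 * mad))
        assert np.mean(frac) <= 0.01


class TestDeltaTrack:
    def test_knockout_direction_is_strongly_negative(self):
        a = lib({"s": 200}, spike=1_000_000)
        b = lib({"s": 0}, spike=1_000_000)
        track = signal_delta_track(a, b, ["s"], pseudocount=0.5)
        assert track.loc["s", "log2_delta"] == pytest.approx(np.log2(0.5 / 200.5))

    def test_identical_libraries_give_zero_deltas(self):
        a = lib({"s1": 3, "s2": 7})
        track = signal_delta_track(a, a, ["s1", "s2"])
        assert (track["log2_delta"] == 0).all()

    def test_planted_ninety_percent_loss_recovered(self):
        cfg = SimulationConfig(seed=77, n_sites=8, depth=200.0)
        sites = [f"s{i}" for i in range(500)]
        libs, _ = simulate_chiprx(cfg, sites, {"ctrl": 0.0, "kd": np.log2(0.1)})
        track = signal_delta_track(libs["ctrl"], libs["kd"], sites)
        assert abs(track["log2_delta"].median() - np.log2(0.1)) <= 0.2
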