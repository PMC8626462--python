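"""BioID filtering, robust normalization, moderated testing, pseudo FC."""

import numpy as np
import pandas as pd
import pytest

from bafmap.proteomics import (
    IntensityMatrix,
    bioid_enrichment,
    filter_matrix,
    fit_variance_prior,
    group_compare,
    pseudo_fold_change,
    read_intensity_matrix,
    robust_z_normalize,
)
from bafmap.simulate import ProteomicsConfig, SimulationConfig, simulate_proteomics

SAMPLES = ["b1", "b2", "b3", "b4", "c1", "c2", "c3", "c4"]
GROUPS = pd.Series(["bait"] * 4 + ["control"] * 4, index=SAMPLES)


class TestFilter:
    def _m(self):
        vals = {
            "single_pep": [20.0] * 8,
            "too_missing": [20.0, np.nan, np.nan, np.nan, np.nan, np.nan, 20.0, 20.0],
            "good": [20.0] * 8,
        }
        df = pd.DataFrame(vals, index=SAMPLES).T
        return IntensityMatrix(
            np.power(2.0, df),
            pd.Series({"single_pep": 1, "too_missing": 3, "good": 2}),
            GROUPS,
        )

    def test_peptide_and_missingness_rules(self):
        kept = filter_matrix(self._m())
        assert list(kept.intensities.index) == ["good"]

    def test_filter_is_idempotent(self):
        once = filter_matrix(self._m())
        twice = filter_matrix(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)


class TestRobustZ:
    def test_location_shift_of_one_sample_is_removed(self, rng):
        # a per-sample location shift must not survive normalization: the
        # shifted matrix equals the original up to one global additive
        # constant (the data-driven grand location moves slightly), so all
        # contrasts between entries are restored exactly
        base = rng.normal(20, 2, size=(50, 8))
        m1 = IntensityMatrix(
            pd.DataFrame(np.power(2.0, base), columns=SAMPLES),
            pd.Series(2, index=range(50)),
            GROUPS,
        )
        shifted = base.copy()
        shifted[:, 0] += 3.0
        m2 = IntensityMatrix(
            pd.DataFrame(np.power(2.0, shifted), columns=SAMPLES),
            pd.Series(2, index=range(50)),
            GROUPS,
        )
        a = robust_z_normalize(m1).intensities.to_numpy()
        b = robust_z_normalize(m2).intensities.to_numpy()
        diff = b - a
        assert np.allclose(diff, diff.ravel()[0])
        assert abs(diff.ravel()[0]) < 0.5  # far smaller than the +3 shift

    def test_matches_hand_computed_transform(self):
        # two samples with known medians/MADs
        x = pd.DataFrame(
            {"s1": [10.0, 12.0, 14.0, 16.0, 18.0], "s2": [20.0, 21.0, 22.0, 23.0, 24.0]}
        )
        m = IntensityMatrix(
            np.power(2.0, x),
            pd.Series(2, index=x.index),
            pd.Series({"s1": "bait", "s2": "control"}),
        )
        norm = robust_z_normalize(m).intensities
        allv = x.to_numpy().ravel()
        gmed = np.median(allv)
        centered = np.concatenate(
            [x[c].to_numpy() - np.median(x[c]) for c in x.columns]
        )
        gmad = 1.4826 * np.median(np.abs(centered))
        s1 = x["s1"]
        expected = gmed + (s1 - np.median(s1)) / (1.4826 * np.median(np.abs(s1 - np.median(s1)))) * gmad
        assert np.allclose(norm["s1"], expected)

    def test_zero_mad_sample_is_error(self):
        x = pd.DataFrame({"s1": [10.0, 10.0, 10.0, 12.0], "s2": [10.0, 11.0, 12.0, 13.0]})
        m = IntensityMatrix(
            np.power(2.0, x), pd.Series(2, index=x.index),
            pd.Series({"s1": "bait", "s2": "control"}),
        )
        with pytest.raises(ValueError, match="s1"):
            robust_z_normalize(m)


class TestGroupCompare:
    def _norm(self, log2_df, n_pep=2):
        m = IntensityMatrix.__new__(IntensityMatrix)
        m.intensities = log2_df
        m.n_peptides = pd.Series(n_pep, index=log2_df.index)
        m.groups = GROUPS
        return m

    def test_identical_groups_give_zero_fold_change(self, rng):
        vals = rng.normal(20, 1, size=(30, 4))
        df = pd.DataFrame(np.hstack([vals, vals]), columns=SAMPLES)
        res = group_compare(self._norm(df), "bait", "control")
        assert np.allclose(res["log2fc"], 0.0)

    def test_constant_offset_recovered_exactly(self, rng):
        ctrl = rng.normal(20, 1, size=(30, 4))
        df = pd.DataFrame(np.hstack([ctrl + 3.0, ctrl]), columns=SAMPLES)
        res = group_compare(self._norm(df), "bait", "control")
        assert np.allclose(res["log2fc"], 3.0)

    def test_monotone_in_bait_values(self, rng):
        base = rng.normal(20, 1, size=(20, 8))
        df = pd.DataFrame(base, columns=SAMPLES)
        res1 = group_compare(self._norm(df), "bait", "control")
        df2 = df.copy()
        df2[["b1", "b2", "b3", "b4"]] += 0.5
        res2 = group_compare(self._norm(df2), "bait", "control")
        assert (res2["log2fc"] > res1["log2fc"]).all()

    def test_variance_prior_recovers_known_scale(self, rng):
        # pooled variances from a common sigma^2 -> s0^2 near sigma^2, large df0
        s2 = rng.chisquare(6, size=2000) / 6 * 0.25
        df0, s0_2 = fit_variance_prior(s2, np.full(2000, 6.0))
        assert s0_2 == pytest.approx(0.25, rel=0.15)
        assert df0 > 20

    def test_hit_flag_reproduces_volcano_quadrant(self, rng):
        ctrl = rng.normal(20, 0.3, size=(40, 4))
        bait = ctrl.copy()
        bait[:10] += 4.0  # clear hits
        df = pd.DataFrame(np.hstack([bait, ctrl]), columns=SAMPLES)
        res = group_compare(self._norm(df), "bait", "control")
        expected = (res["log2fc"] > 2.5) & (res["p_value"] < 0.05)
        assert res["hit"].equals(expected)
        assert res["hit"].iloc[:10].all()


class TestPseudoFoldChange:
    def _norm(self, df):
        m = IntensityMatrix.__new__(IntensityMatrix)
        m.intensities = df
        m.n_peptides = pd.Series(2, index=df.index)
        m.groups = GROUPS
        return m

    def test_all_missing_control_gives_positive_flagged_fc(self):
        rows = {f"p{i}": [15.0 + i] * 8 for i in range(10)}
        df = pd.DataFrame(rows, index=SAMPLES).T
        df.loc["p9", ["c1", "c2", "c3", "c4"]] = np.nan
        df.loc["p9", ["b1", "b2", "b3", "b4"]] = 25.0
        pseudo = pseudo_fold_change(self._norm(df), "bait", "control")
        assert list(pseudo.index) == ["p9"]
        assert pseudo["p9"] > 0

    def test_ten_percent_smallest_rule_direct(self):
        # control column observed log2 values {10,12,...,28}: floor = mean({10}) = 10
        vals = {f"p{i}": [20.0, 20, 20, 20, np.nan, np.nan, np.nan, np.nan] for i in range(1)}
        df = pd.DataFrame(vals, index=SAMPLES).T
        extra = pd.DataFrame(
            {f"q{i}": [np.nan] * 4 + [float(10 + 2 * i)] + [np.nan] * 3 for i in range(10)},
            index=SAMPLES,
        ).T
        # q-proteins populate control with 10,12,...,28 in c1 only
        full = pd.concat([df, extra])
        pseudo = pseudo_fold_change(self._norm(full), "bait", "control")
        assert pseudo["p0"] == pytest.approx(20.0 - 10.0)

    def test_raising_bait_by_one_raises_fc_by_one(self):
        df = pd.DataFrame(
            {"p0": [20.0, 20, 20, 20, np.nan, np.nan, np.nan, np.nan],
             "floor": [np.nan, np.nan, np.nan, np.nan, 10.0, 10, 10, 10]},
            index=SAMPLES,
        ).T
        a = pseudo_fold_change(self._norm(df), "bait", "control")["p0"]
        df2 = df.copy()
        df2.loc["p0", ["b1", "b2", "b3", "b4"]] += 1.0
        b = pseudo_fold_change(self._norm(df2), "bait", "control")["p0"]
        assert b - a == pytest.approx(1.0)

    def test_both_groups_missing_dropped_with_warning(self):
        df = pd.DataFrame(
            {"gone": [np.nan] * 8, "floor": [10.0] * 8}, index=SAMPLES
        ).T
        with pytest.warns(UserWarning, match="both conditions"):
            pseudo = pseudo_fold_change(self._norm(df), "bait", "control")
        assert "gone" not in pseudo.index


class TestEndToEnd:
    def test_forced_missing_controls_take_pseudo_route(self):
        cfg = SimulationConfig(seed=31)
        cfg.proteomics = ProteomicsConfig(n_hits=10, n_forced_missing_control=2)
        m, truth = simulate_proteomics(cfg)
        res = bioid_enrichment(m, "bait", "control")
        forced = truth.index[truth["forced_missing_control"]]
        for p in forced:
            assert bool(res.loc[p, "pseudo_fc_flag"])
            assert np.isfinite(res.loc[p, "log2fc"])
            assert res.loc[p, "log2fc"] > 0

    def test_tsv_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=13)
        cfg.proteomics = ProteomicsConfig(n_proteins=30)
        m, _ = simulate_proteomics(cfg)
        ip, gp = tmp_path / "i.tsv", tmp_path / "g.tsv"
        out = m.intensities.copy()
        out.insert(0, "n_peptides", m.n_peptides)
        out.index.name = "protein"
        out.to_csv(ip, sep="\t")
        m.groups.rename("condition").to_frame().rename_axis("sample").to_csv(gp, sep="\t")
        back = read_intensity_matrix(ip, gp)
        pd.testing.assert_frame_equal(back.intensities, m.intensities)
        assert back.groups.equals(m.groups)
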