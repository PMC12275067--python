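"""Retention indexing, quantification, rOAV and the marker screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voctrace import chemometrics, gcms, synthetic
from voctrace.containers import VocTable
from voctrace.gcms import AlkaneLadder, InternalStandard

LADDER = AlkaneLadder(np.arange(7, 41), np.linspace(2.0, 40.0, 34))


class TestRetentionIndex:
    def test_hand_evaluations_on_stated_bracket(self):
        ladder = AlkaneLadder([11, 12], [10.0, 12.0])
        assert gcms.retention_index(11.0, ladder) == pytest.approx(1150.0)
        assert gcms.retention_index(10.5, ladder) == pytest.approx(1125.0)

    def test_exact_alkane_hit_returns_hundred_z(self):
        ladder = AlkaneLadder([9, 10], [5.0, 6.0])
        assert gcms.retention_index(5.0, ladder) == 900.0
        assert gcms.retention_index(6.0, ladder) == 1000.0

    def test_out_of_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gcms.retention_index(1.0, LADDER)
        with pytest.raises(ValueError, match="outside"):
            gcms.retention_index(41.0, LADDER)

    @given(st.floats(min_value=2.0, max_value=40.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_retention_time(self, rt):
        eps = 1e-6
        if rt + eps <= 40.0:
            assert gcms.retention_index(rt + eps, LADDER) > gcms.retention_index(rt, LADDER)

    def test_continuous_across_brackets(self):
        ladder = AlkaneLadder([9, 10, 11], [5.0, 6.0, 8.0])
        below = gcms.retention_index(6.0 - 1e-9, ladder)
        above = gcms.retention_index(6.0 + 1e-9, ladder)
        assert abs(below - 1000.0) < 1e-4 and abs(above - 1000.0) < 1e-4

    def test_reference_match_window(self):
        assert gcms.ri_match(1161, 1161)
        assert gcms.ri_match(1191, 1161)
        assert not gcms.ri_match(1192, 1161)
        assert not gcms.ri_match(900, 1161)


class TestQuantify:
    def build(self, areas, istd_area=100.0):
        rows = []
        for sid, area in areas.items():
            rows.append(
                {
                    "sample_id": sid,
                    "origin": "origin_A",
                    "compound_id": "X",
                    "cas": "-",
                    "rt_min": 5.0,
                    "peak_area": area,
                    "threshold": 1.0,
                }
            )
        return VocTable(pd.DataFrame(rows))

    def test_worked_protocol_value(self):
        """20 uL of 10 ug/mL standard in 0.5 g with unit area ratio -> 0.4 ug/g."""
        voc = self.build({"s1": 100.0})
        istd = InternalStandard(v_s=20, c_s=10, mass_g=0.5, i_s=100.0)
        out = gcms.quantify(voc, istd)
        assert out.data["conc"].iloc[0] == pytest.approx(0.4)

    def test_zero_area_gives_zero_conc(self):
        out = gcms.quantify(self.build({"s1": 0.0}), InternalStandard())
        assert out.data["conc"].iloc[0] == 0.0

    def test_mass_scaling_law(self):
        voc = self.build({"s1": 50.0})
        c1 = gcms.quantify(voc, InternalStandard(mass_g=0.5)).data["conc"].iloc[0]
        c2 = gcms.quantify(voc, InternalStandard(mass_g=1.0)).data["conc"].iloc[0]
        assert c1 == pytest.approx(2 * c2)

    def test_zero_internal_standard_area_reported(self):
        with pytest.raises(ZeroDivisionError, match="s1"):
            gcms.quantify(self.build({"s1": 1.0}), InternalStandard(i_s=0.0))


class TestRoav:
    def test_definition_and_boundary(self):
        assert gcms.roav(2.0, 1.0) == 2.0
        assert gcms.roav(1.5, 1.5) == 1.0

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_homogeneity_in_concentration(self, k):
        assert gcms.roav(k * 0.3, 0.1) == pytest.approx(k * gcms.roav(0.3, 0.1))

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            gcms.roav(1.0, 0.0)

    def test_within_compound_ratios_track_concentration_ratios(self):
        """Published furanone rOAVs 1.63/0.83/1.32 and concentrations
        0.65/0.33/0.53 agree ratio-wise to two decimals."""
        roavs = np.array([1.63, 0.83, 1.32])
        concs = np.array([0.65, 0.33, 0.53])
        assert abs(roavs[0] / roavs[1] - concs[0] / concs[1]) < 0.01
        assert abs(roavs[0] / roavs[2] - concs[0] / concs[2]) < 0.01
        mine = gcms.roav(concs, 1.77e-7)
        assert mine[0] / mine[1] == pytest.approx(concs[0] / concs[1])

    def test_contribution_categories(self):
        assert gcms.classify_contribution(0.5) == "none"
        assert gcms.classify_contribution(1.63) == "contributor"
        assert gcms.classify_contribution(107.1) == "key_contributor"
        assert gcms.classify_contribution(1.0) == "contributor"
        assert gcms.classify_contribution(100.0) == "key_contributor"


class TestWelchAnova:
    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 12), (0.5, 2, 9), (1, 0.5, 15))]
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [12, 9, 15]),
            }
        )
        expected = pingouin.welch_anova(data=df, dv="y", between="g")["p_unc"].iloc[0]
        assert gcms.welch_anova_p(groups) == pytest.approx(expected, rel=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            gcms.welch_anova_p([np.array([1.0]), np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            gcms.welch_anova_p([np.ones(5), np.ones(5)])


class TestScreenMarkers:
    def test_exact_recovery_of_planted_markers(self, conc_table):
        """Planted 8-marker / 40-null table: the screen flags exactly the
        planted compounds (default cohort, 20/15/15 samples)."""
        X = conc_table.pivot("conc")
        y = conc_table.origins.loc[X.index].to_numpy()
        model, _ = chemometrics.oplsda(X, y, scale="uv")
        vip = chemometrics.vip(model)
        result = gcms.screen_markers(conc_table, vip)
        assert sorted(result.flagged) == [f"M{i + 1:02d}" for i in range(8)]

    def test_and_semantics_of_the_three_criteria(self):
        cfg = synthetic.SyntheticConfig(
            n_per_class=6, wavenumber_grid=synthetic.default_grid(16.0), seed=1
        )
        voc = synthetic.make_voc_table(cfg)
        voc.data["conc"] = voc.data["true_conc"]
        # force one marker odor-inactive: huge threshold -> rOAV < 1
        voc.data.loc[voc.data["compound_id"] == "M01", "threshold"] = 1e9
        vip = pd.Series(2.0, index=voc.compounds)  # all pass the VIP gate
        result = gcms.screen_markers(voc, vip)
        row = result.table.set_index("compound_id").loc["M01"]
        assert row["pass_vip"] and row["pass_p"] and not row["pass_roav"]
        assert not row["flagged"]

    def test_no_class_effect_and_no_variance_flags_nothing(self):
        cfg = synthetic.SyntheticConfig(
            n_per_class=5,
            n_markers=0,
            conc_cv=0.0,
            wavenumber_grid=synthetic.default_grid(16.0),
        )
        voc = synthetic.make_voc_table(cfg)
        voc.data["conc"] = voc.data["true_conc"]
        vip = pd.Series(2.0, index=voc.compounds)
        with pytest.warns(UserWarning, match="excluded"):
            result = gcms.screen_markers(voc, vip)
        assert result.flagged == []

    def test_flagged_sorted_by_vip(self, conc_table):
        X = conc_table.pivot("conc")
        y = conc_table.origins.loc[X.index].to_numpy()
        model, _ = chemometrics.oplsda(X, y, scale="uv")
        vip = chemometrics.vip(model)
        result = gcms.screen_markers(conc_table, vip)
        vips = [vip[c] for c in result.flagged]
        assert vips == sorted(vips, reverse=True)
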