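import numpy as np
import pandas as pd
import pytest

from humdea import (
    FactorDef,
    FactorPanel,
    exclude_heterogeneous_dmus,
    generate_schema,
    modification_catalog,
    reciprocal_bad_output,
    screen_correlations,
    spec_errors,
    validate_spec,
)


def bad_output_panel(values_by_period):
    periods = list(values_by_period)
    dmus = [f"D{i+1}" for i in range(len(next(iter(values_by_period.values()))))]
    rows = []
    for t, deaths in values_by_period.items():
        for i, d in enumerate(dmus):
            rows.append((d, t, 1.0 + i, float(deaths[i]), 5.0))
    frame = pd.DataFrame(rows, columns=["dmu", "period", "I1", "O1", "O2"]).set_index(["dmu", "period"])
    factors = [FactorDef("I1", "input"), FactorDef("O1", "output", "bad"), FactorDef("O2", "output")]
    return FactorPanel(dmus, periods, factors, frame)


class TestReciprocalBadOutput:
    def test_printed_formula(self):
        panel = bad_output_panel({"t1": [10, 4, 7]})
        out, log = reciprocal_bad_output(panel, "O1")
        assert [out.value(d, "t1", "O1") for d in out.dmu_ids] == [0.0, 6.0, 3.0]
        assert log.per_period["t1"][0] == 10.0
        assert out.factor("O1").desirability == "good"

    def test_max_dmu_maps_to_zero_each_period(self):
        panel = bad_output_panel({"t1": [3, 9, 1], "t2": [8, 2, 5]})
        out, _ = reciprocal_bad_output(panel, "O1")
        col = out.values["O1"].unstack("period")
        assert (col.min(axis=0) == 0.0).all()
        assert (col == 0.0).sum().sum() == 2  # exactly one zero per period, no ties

    def test_all_equal_degenerates_to_zero(self):
        panel = bad_output_panel({"t1": [4, 4, 4]})
        out, _ = reciprocal_bad_output(panel, "O1")
        assert (out.values["O1"] == 0.0).all()

    def test_good_factor_is_misuse(self):
        panel = bad_output_panel({"t1": [1, 2, 3]})
        with pytest.raises(ValueError, match="bad-desirability"):
            reciprocal_bad_output(panel, "O2")

    def test_double_transform_restores_up_to_period_min(self):
        # max-minus-value applied twice gives the original shifted down by the
        # period minimum: levels are anchored at the per-period extremes, but
        # all pairwise gaps between DMUs are restored exactly
        panel = bad_output_panel({"t1": [10, 4, 7], "t2": [2, 8, 5]})
        once, _ = reciprocal_bad_output(panel, "O1")
        relabel = once.with_values(
            once.values, [FactorDef("I1", "input"), FactorDef("O1", "output", "bad"), FactorDef("O2", "output")]
        )
        twice, _ = reciprocal_bad_output(relabel, "O1")
        orig = panel.values["O1"].unstack("period")
        back = twice.values["O1"].unstack("period")
        assert np.allclose(back, orig - orig.min(axis=0), atol=1e-12)

    def test_period_local(self):
        a = bad_output_panel({"t1": [10, 4, 7], "t2": [1, 2, 3]})
        b = bad_output_panel({"t1": [10, 4, 7], "t2": [30, 20, 10]})
        ta, _ = reciprocal_bad_output(a, "O1")
        tb, _ = reciprocal_bad_output(b, "O1")
        assert np.allclose(
            ta.values["O1"].xs("t1", level="period"), tb.values["O1"].xs("t1", level="period")
        )


class TestScreenCorrelations:
    def test_duplicated_factor_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 5, 12)
        frame = pd.DataFrame(
            {"I1": x, "O1": x, "O2": rng.uniform(1, 5, 12)},
            index=pd.MultiIndex.from_product([[f"D{i}" for i in range(4)], list("abc")], names=["dmu", "period"]),
        )
        panel = FactorPanel(
            [f"D{i}" for i in range(4)], list("abc"),
            [FactorDef("I1", "input"), FactorDef("O1", "output"), FactorDef("O2", "output")],
            frame,
        )
        rep = screen_correlations(panel, threshold=0.8)
        assert ("I1", "O1") in rep.flagged
        assert rep.matrix.loc["I1", "O1"] == pytest.approx(1.0)

    def test_independent_factor_unflagged(self):
        rng = np.random.default_rng(42)
        n = 400
        idx = pd.MultiIndex.from_product([[f"D{i}" for i in range(n)], ["t"]], names=["dmu", "period"])
        frame = pd.DataFrame({"I1": rng.uniform(1, 5, n), "O1": rng.uniform(1, 5, n)}, index=idx)
        panel = FactorPanel([f"D{i}" for i in range(n)], ["t"], [FactorDef("I1", "input"), FactorDef("O1", "output")], frame)
        rep = screen_correlations(panel, threshold=0.8)
        assert rep.flagged == ()
        assert abs(rep.max_abs) < 0.15

    def test_orthogonal_contrasts_zero(self):
        idx = pd.MultiIndex.from_product([[f"D{i}" for i in range(4)], ["t"]], names=["dmu", "period"])
        frame = pd.DataFrame({"I1": [1.0, 2.0, 1.0, 2.0], "O1": [1.0, 1.0, 2.0, 2.0]}, index=idx)
        panel = FactorPanel([f"D{i}" for i in range(4)], ["t"], [FactorDef("I1", "input"), FactorDef("O1", "output")], frame)
        assert screen_correlations(panel).matrix.loc["I1", "O1"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_factor_degenerate_not_failed(self):
        idx = pd.MultiIndex.from_product([[f"D{i}" for i in range(5)], ["t"]], names=["dmu", "period"])
        frame = pd.DataFrame({"I1": np.full(5, 2.0), "O1": np.arange(1.0, 6.0)}, index=idx)
        panel = FactorPanel([f"D{i}" for i in range(5)], ["t"], [FactorDef("I1", "input"), FactorDef("O1", "output")], frame)
        rep = screen_correlations(panel)
        assert "I1" in rep.degenerate


class TestExclusion:
    def funder_panel(self, inputs):
        dmus = [f"N{i+1}" for i in range(len(inputs))]
        idx = pd.MultiIndex.from_product([dmus, ["t1"]], names=["dmu", "period"])
        frame = pd.DataFrame({"I1": np.asarray(inputs, dtype=float), "O1": np.ones(len(inputs))}, index=idx)
        return FactorPanel(dmus, ["t1"], [FactorDef("I1", "input"), FactorDef("O1", "output")], frame)

    def test_reported_funding_ratio(self):
        # one funder invests 9,895,337 USD against a 153,272 USD minimum
        panel = self.funder_panel([9_895_337, 153_272, 200_000])
        kept, rep = exclude_heterogeneous_dmus(panel, "I1", ratio_threshold=10)
        assert rep.excluded == ("N1",)
        assert rep.ratios.loc["N1", "t1"] == pytest.approx(64.56, abs=0.005)
        assert kept.dmu_ids == ("N2", "N3")

    def test_equal_inputs_nothing_excluded(self):
        panel = self.funder_panel([5, 5, 5])
        kept, rep = exclude_heterogeneous_dmus(panel, "I1", ratio_threshold=1.5)
        assert rep.excluded == () and kept.dmu_ids == panel.dmu_ids

    def test_infinite_threshold_is_identity(self):
        panel = self.funder_panel([1, 50, 2000])
        kept, rep = exclude_heterogeneous_dmus(panel, "I1", ratio_threshold=np.inf)
        assert kept == panel and rep.excluded == ()

    def test_monotone_in_threshold(self):
        panel = self.funder_panel([1, 12, 80, 300])
        _, loose = exclude_heterogeneous_dmus(panel, "I1", ratio_threshold=100)
        _, tight = exclude_heterogeneous_dmus(panel, "I1", ratio_threshold=10)
        assert set(loose.excluded) <= set(tight.excluded)

    def test_emptying_panel_is_error(self):
        panel = self.funder_panel([1, 100])
        with pytest.raises(ValueError, match="every DMU"):
            exclude_heterogeneous_dmus(panel, "I1", ratio_threshold=0.5)


class TestModificationCatalog:
    def test_national_catalog(self):
        specs = modification_catalog("national")
        assert [s.label for s in specs] == ["I", "II", "III", "IV", "V", "VI"]
        assert set(specs[0].active_factors) == {"I1", "I2", "I3", "O1", "O2", "O3", "O4", "O5"}
        assert set(specs[1].active_factors) == {"I2", "I3", "O3", "O4", "O5"}
        assert set(specs[2].active_factors) == {"I1", "I2", "I3", "O1", "O2", "O3"}
        assert [s.weight_restrictions.get("O3") for s in specs] == [None, None, None, 0.05, 0.10, 0.15]

    def test_ngo_catalog(self):
        specs = modification_catalog("ngo")
        assert [s.label for s in specs] == ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
        viii = specs[7]
        assert viii.rts == "vrs" and viii.orientation == "output"
        assert set(viii.active_factors) == {"I1", "O1", "O2"}
        assert sum(s.orientation == "input" for s in specs) == 4
        assert sum(s.rts == "crs" for s in specs) == 4

    def test_unknown_schema(self):
        with pytest.raises(ValueError):
            modification_catalog("municipal")

    @pytest.mark.parametrize("schema", ["national", "ngo"])
    def test_catalog_validates_on_schema_panel(self, schema):
        data = generate_schema(schema, seed=1, n_dmu=10 if schema == "national" else None,
                               n_periods=3 if schema == "national" else None)
        for spec in modification_catalog(schema):
            assert spec_errors(validate_spec(spec, data.panel)) == []
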