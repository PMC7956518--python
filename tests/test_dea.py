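import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from humdea import ModelSpec, efficiency_table, solve_multiplier, solve_radial

from conftest import make_panel, random_panel


class TestRadialOracle:
    def test_crs_output_matches_productivity_ratio(self, abc_panel, crs_output):
        # closed form: CRS score = (y/x) / max_j (y_j/x_j)
        expected = {"A": 0.5, "B": 1.0, "C": 0.5}
        for d, s in expected.items():
            rec = solve_radial(abc_panel, "t1", d, crs_output)
            assert rec.ok and rec.farrell_score == pytest.approx(s, abs=1e-9)

    def test_vrs_output_all_efficient(self, abc_panel, vrs_output):
        # A by minimal input, B on the CRS ray, C because no convex combination
        # with x <= 8 exceeds y = 8
        for d in "ABC":
            rec = solve_radial(abc_panel, "t1", d, vrs_output)
            assert rec.farrell_score == pytest.approx(1.0, abs=1e-9)

    def test_single_dmu_scores_one(self):
        panel = make_panel([[5.0]], [[3.0]], dmus=["only"])
        for ori in ("input", "output"):
            for rts in ("crs", "vrs"):
                rec = solve_radial(panel, "t1", "only", ModelSpec("s", ori, rts))
                assert rec.farrell_score == pytest.approx(1.0, abs=1e-9)

    def test_vrs_lambdas_sum_to_one(self, abc_panel, vrs_output):
        rec = solve_radial(abc_panel, "t1", "A", vrs_output)
        assert sum(rec.lambdas.values()) == pytest.approx(1.0, abs=1e-6)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_single_ratio_oracle_random(seed):
    """1-input/1-output CRS equals the productivity-ratio closed form."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 8))
    x = rng.uniform(0.5, 20, n)
    y = rng.uniform(0.5, 20, n)
    panel = make_panel(x[:, None], y[:, None])
    ratios = y / x
    spec = ModelSpec("ccr", "output", "crs")
    for i, d in enumerate(panel.dmu_ids):
        rec = solve_radial(panel, "t1", d, spec)
        assert rec.farrell_score == pytest.approx(ratios[i] / ratios.max(), abs=1e-8)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(0, 10_000))
def test_units_invariance(seed):
    """Rescaling any factor column leaves every score unchanged (to 1e-9)."""
    rng = np.random.default_rng(seed)
    panel = random_panel(seed, n=6, m=2, r=2)
    scale = rng.uniform(0.01, 100.0, 4)
    scaled_vals = panel.values * scale
    scaled = panel.with_values(scaled_vals)
    for ori in ("input", "output"):
        spec = ModelSpec("s", ori, "vrs")
        for d in panel.dmu_ids:
            s1 = solve_radial(panel, "t1", d, spec).farrell_score
            s2 = solve_radial(scaled, "t1", d, spec).farrell_score
            assert s1 == pytest.approx(s2, abs=1e-9)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(0, 10_000))
def test_crs_nested_below_vrs(seed):
    """The conic (CRS) frontier dominates the convex (VRS) one cellwise."""
    panel = random_panel(seed, n=7, m=2, r=2)
    for d in panel.dmu_ids:
        crs = solve_radial(panel, "t1", d, ModelSpec("c", "output", "crs")).farrell_score
        vrs = solve_radial(panel, "t1", d, ModelSpec("v", "output", "vrs")).farrell_score
        assert crs <= vrs + 1e-9


@settings(deadline=None, max_examples=10, derandomize=True)
@given(st.integers(0, 10_000))
def test_duality_envelopment_vs_multiplier(seed):
    """Without weight restrictions both LP forms agree within 1e-7."""
    panel = random_panel(seed, n=6, m=2, r=2)
    for ori in ("input", "output"):
        for rts in ("crs", "vrs"):
            spec = ModelSpec("s", ori, rts)
            for d in panel.dmu_ids:
                s1 = solve_radial(panel, "t1", d, spec).farrell_score
                s2 = solve_multiplier(panel, "t1", d, spec).farrell_score
                assert s1 == pytest.approx(s2, abs=1e-7)


class TestFrontierStability:
    def test_duplicate_dmu_changes_no_score(self, abc_panel, crs_output):
        base = {d: solve_radial(abc_panel, "t1", d, crs_output).farrell_score for d in "ABC"}
        dup = make_panel([[2], [4], [8], [4]], [[2], [8], [8], [8]], dmus=["A", "B", "C", "B2"])
        for d in "ABC":
            assert solve_radial(dup, "t1", d, crs_output).farrell_score == pytest.approx(base[d], abs=1e-9)

    def test_dominated_dmu_changes_no_other_score(self, abc_panel, vrs_output):
        base = {d: solve_radial(abc_panel, "t1", d, vrs_output).farrell_score for d in "ABC"}
        ext = make_panel([[2], [4], [8], [5]], [[2], [8], [8], [7]], dmus=["A", "B", "C", "W"])
        for d in "ABC":
            assert solve_radial(ext, "t1", d, vrs_output).farrell_score == pytest.approx(base[d], abs=1e-9)


class TestWeightRestrictions:
    def test_zero_share_equals_unrestricted(self, seed=4):
        panel = random_panel(seed, n=6, m=2, r=2)
        free = ModelSpec("f", "output", "vrs")
        zero = ModelSpec("z", "output", "vrs", (), {"O1": 0.0})
        for d in panel.dmu_ids:
            assert solve_multiplier(panel, "t1", d, zero).farrell_score == pytest.approx(
                solve_multiplier(panel, "t1", d, free).farrell_score, abs=1e-8
            )

    def test_monotone_in_share(self):
        panel = random_panel(11, n=6, m=2, r=3)
        prev = None
        for s in (0.0, 0.05, 0.15, 0.35, 0.6):
            spec = ModelSpec("w", "output", "vrs", (), {"O2": s})
            score = solve_multiplier(panel, "t1", "D1", spec).farrell_score
            if prev is not None:
                assert score <= prev + 1e-9
            prev = score

    def test_restriction_bites_single_strength_dmu(self):
        # D1's only strength is O1; forcing weight onto O2 must strictly cut it
        panel = make_panel(
            [[1.0], [1.0], [1.0]],
            [[10.0, 1.0], [1.0, 10.0], [5.0, 5.0]],
        )
        free = solve_multiplier(panel, "t1", "D1", ModelSpec("f", "output", "crs")).farrell_score
        tied = solve_multiplier(
            panel, "t1", "D1", ModelSpec("t", "output", "crs", (), {"O2": 0.5})
        ).farrell_score
        assert free == pytest.approx(1.0, abs=1e-8)
        assert tied < free - 1e-6


class TestEfficiencyTable:
    def test_identical_dmus_all_one(self):
        X = {t: np.full((4, 1), 3.0) for t in ("t1", "t2")}
        Y = {t: np.full((4, 1), 5.0) for t in ("t1", "t2")}
        panel = make_panel(X, Y)
        tab = efficiency_table(panel, ModelSpec("m", "output", "vrs"))
        assert np.allclose(tab.scores().to_numpy(), 1.0, atol=1e-9)
        assert np.allclose(tab.summary()["sd"].to_numpy(), 0.0, atol=1e-12)

    def test_summary_recomputable_from_records(self):
        panel = random_panel(3, n=5, m=1, r=2, periods=3)
        tab = efficiency_table(panel, ModelSpec("m", "output", "crs"))
        sc = tab.scores()
        summ = tab.summary()
        assert np.allclose(summ["mean"], sc.mean(axis=1))
        assert np.allclose(summ["median"], sc.median(axis=1))
        assert np.allclose(summ["min"], sc.min(axis=1))
        assert np.allclose(summ["sd"], sc.std(axis=1, ddof=1))
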