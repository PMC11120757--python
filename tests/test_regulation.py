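"""Signed ratio, Welch test, gene-specific cut-off, WIR and distance measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import genefabric as gf
from genefabric.regulation import DOWN, NOT_REGULATED, UP


class TestExpressionRatio:
    @pytest.mark.parametrize("a,b,expected", [(1.0, 1.0, 1.0), (2.0, 1.0, 2.0), (0.5, 1.0, -2.0)])
    def test_examples(self, a, b, expected):
        assert gf.expression_ratio(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.001, 1e4), b=st.floats(0.001, 1e4))
    def test_signed_convention(self, a, b):
        x = gf.expression_ratio(a, b)
        assert abs(x) >= 1.0
        if a != b:
            assert gf.expression_ratio(b, a) == pytest.approx(-x, rel=1e-9)

    def test_positive_required(self):
        with pytest.raises(ValueError):
            gf.expression_ratio(-1.0, 2.0)


class TestRegulationPvalue:
    def test_identical_groups(self):
        assert gf.regulation_pvalue([1.0, 1, 1, 1], [1.0, 1, 1, 1]) == 1.0
        v = [1.0, 2.0, 3.0, 4.0]
        assert gf.regulation_pvalue(v, v) > 0.99

    def test_degenerate_unequal_means(self):
        assert gf.regulation_pvalue([1.0, 1, 1, 1], [2.0, 2, 2, 2]) == 0.0

    def test_clear_separation(self):
        p = gf.regulation_pvalue([1.0, 1, 1, 1], [10.0, 10.1, 9.9, 10.0])
        assert p < 0.001

    def test_matches_scipy_welch(self, rng):
        a = rng.normal(5, 1, size=(50, 4))
        b = rng.normal(5, 2, size=(50, 4))
        ours = gf.regulation_pvalue(a, b)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_type_one_error_calibration(self):
        """Null genes are flagged at p < 0.05 about 5% of the time."""
        rng = np.random.default_rng(606)
        a = rng.lognormal(0, 0.1, size=(4000, 4))
        b = rng.lognormal(0, 0.1, size=(4000, 4))
        p = gf.regulation_pvalue(a, b)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.015)

    def test_minimum_replicas(self):
        with pytest.raises(ValueError):
            gf.regulation_pvalue([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCut:
    def test_limit_and_formula(self):
        assert gf.compute_cut(0.0, 0.0) == 1.0
        assert gf.compute_cut(50.0, 50.0) == pytest.approx(1 + np.sqrt(0.5))

    def test_negative_rev_rejected(self):
        with pytest.raises(ValueError):
            gf.compute_cut(-1.0, 10.0)

    def test_flexible_cutoff_stricter_than_fixed_for_noisy_genes(self):
        """For very variable unregulated genes the adaptive cut-off calls
        fewer false positives than a fixed 1.5x rule."""
        design = gf.SyntheticDesign(n_genes=3000, conditions=("N", "T"), cv=0.40, seed=313)
        esets, _ = gf.generate_expression_set(design)
        rev_n = gf.compute_rev(esets["N"].data)
        rev_t = gf.compute_rev(esets["T"].data)
        x = gf.expression_ratio(gf.compute_ave(esets["T"].data), gf.compute_ave(esets["N"].data))
        p = gf.regulation_pvalue(esets["T"].data, esets["N"].data)
        cut = gf.compute_cut(rev_n, rev_t)
        adaptive = (gf.classify_regulation(x, p, cut) != NOT_REGULATED).mean()
        fixed = ((np.abs(x) > 1.5) & (p < 0.05)).mean()
        assert adaptive <= fixed


class TestClassify:
    def test_below_cut_never_regulated(self):
        assert gf.classify_regulation(1.2, 0.0001, 1.5) == NOT_REGULATED

    def test_up_call(self):
        assert gf.classify_regulation(3.0, 0.01, 1.4) == UP

    def test_down_requires_beyond_negative_cut(self):
        assert gf.classify_regulation(-3.0, 0.01, 1.4) == DOWN
        assert gf.classify_regulation(-1.3, 0.01, 1.4) == NOT_REGULATED
        assert gf.classify_regulation(-3.0, 0.2, 1.4) == NOT_REGULATED

    def test_planted_fold_two_recall(self):
        """Moderate-noise fold-2 regulation is recalled above 90%."""
        regulated = {f"g{i + 1}": (2.0 if i % 2 == 0 else -2.0) for i in range(100)}
        design = gf.SyntheticDesign(
            n_genes=2000, conditions=("N", "T"), cv=0.10, seed=99, regulated=regulated
        )
        esets, truth = gf.generate_expression_set(design)
        x = gf.expression_ratio(gf.compute_ave(esets["T"].data), gf.compute_ave(esets["N"].data))
        p = gf.regulation_pvalue(esets["T"].data, esets["N"].data)
        cut = gf.compute_cut(gf.compute_rev(esets["N"].data), gf.compute_rev(esets["T"].data))
        status = gf.classify_regulation(x, p, cut)
        planted = list(regulated)
        want = np.where(truth.fold["T"].loc[planted] > 0, UP, DOWN)
        assert (status.loc[planted].to_numpy() == want).mean() > 0.9


class TestWir:
    def test_unit_ratio_gives_zero(self):
        assert gf.compute_wir(10.0, 1.0, 0.5) == 0.0

    def test_antisymmetry_in_sign(self):
        assert gf.compute_wir(10.0, 2.0, 0.0) == 10.0
        assert gf.compute_wir(10.0, -2.0, 0.0) == -10.0

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            gf.compute_wir(10.0, 0.5, 0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        ave=st.floats(0.01, 100),
        x=st.floats(1.0, 100),
        p=st.floats(0, 0.99),
        dx=st.floats(0.1, 10),
        dp=st.floats(0.001, 0.5),
    )
    def test_monotonicity(self, ave, x, p, dx, dp):
        base = gf.compute_wir(ave, x, p)
        assert gf.compute_wir(ave, x + dx, p) >= base
        assert gf.compute_wir(ave * 2, x, p) >= base
        if p + dp < 1:
            assert gf.compute_wir(ave, x, p + dp) <= base


class TestDeltas:
    def test_identity_and_antisymmetry(self):
        a = pd.Series([1.0, 2.0], index=["g1", "g2"])
        b = pd.Series([3.0, 1.0], index=["g1", "g2"])
        assert (gf.delta_rec(a, a) == 0).all()
        pd.testing.assert_series_equal(
            gf.delta_rec(a, b), -gf.delta_rec(b, a), check_names=False
        )

    def test_universe_mismatch_rejected(self):
        a = pd.Series([1.0], index=["g1"])
        b = pd.Series([1.0], index=["g2"])
        with pytest.raises(ValueError, match="universes differ"):
            gf.delta_coord(a, b)


class TestTranscriptomicDistance:
    def test_origin_and_pythagoras(self):
        assert gf.transcriptomic_distance(0.0, 0.0, 0.0) == 0.0
        assert gf.transcriptomic_distance(3.0, 4.0, 0.0) == 5.0

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(*[st.floats(-100, 100) for _ in range(6)]))
    def test_metric_properties(self, vals):
        w1, r1, c1, w2, r2, c2 = vals
        d1 = gf.transcriptomic_distance(w1, r1, c1)
        d2 = gf.transcriptomic_distance(w2, r2, c2)
        dsum = gf.transcriptomic_distance(w1 + w2, r1 + r2, c1 + c2)
        assert d1 >= 0
        assert dsum <= d1 + d2 + 1e-9
        if (w1, r1, c1) != (0.0, 0.0, 0.0):
            assert d1 > 0


def _study_tables(design):
    esets, truth = gf.generate_expression_set(design)
    chars = {c: gf.condition_characteristics(e) for c, e in esets.items()}
    return esets, chars, truth


@pytest.fixture(scope="module")
def study():
    design = gf.SyntheticDesign(
        n_genes=250, conditions=("N", "T"), cv=0.10, seed=4242, regulated={"g9": 4.0}
    )
    return _study_tables(design)


class TestRegulationTable:

    def test_schema_and_invariants(self, study):
        esets, chars, _ = study
        table = gf.regulation_table(esets["T"], esets["N"], chars["T"], chars["N"])
        assert list(table.columns) == ["x", "p", "CUT", "status", "WIR", "dREC", "dCOORD", "TD"]
        assert (table["x"].abs() >= 1).all()
        assert (table["CUT"] > 1).all()
        up = table[table["status"] == UP]
        assert ((up["x"] > up["CUT"]) & (up["p"] < 0.05)).all()
        ok = table.dropna()
        np.testing.assert_allclose(
            ok["TD"], np.sqrt(ok["WIR"] ** 2 + ok["dREC"] ** 2 + ok["dCOORD"] ** 2)
        )

    def test_swapping_conditions_negates_signed_measures(self, study):
        esets, chars, _ = study
        fwd = gf.regulation_table(esets["T"], esets["N"], chars["T"], chars["N"])
        rev = gf.regulation_table(esets["N"], esets["T"], chars["N"], chars["T"])
        moving = fwd["x"].abs() > 1
        np.testing.assert_allclose(rev.loc[moving, "x"], -fwd.loc[moving, "x"], rtol=1e-9)
        np.testing.assert_allclose(rev["dREC"], -fwd["dREC"], rtol=1e-9)
        np.testing.assert_allclose(rev["dCOORD"], -fwd["dCOORD"], rtol=1e-9)
        assert (rev["WIR"] * fwd["WIR"] <= 1e-12).all()  # opposite regulation direction

    def test_gene_universe_mismatch_rejected(self, study):
        esets, chars, _ = study
        trimmed = esets["T"].restrict(esets["T"].genes[:-1])
        with pytest.raises(ValueError, match="different genes"):
            gf.regulation_table(trimmed, esets["N"], chars["T"], chars["N"])

    def test_planting_regulation_increases_distance_of_planted_genes(self):
        """With identical noise (same seed), planting fold changes strictly
        raises the planted genes' WIR magnitude and hence their mean TD;
        REV/REC/COORD are scale-invariant so the other components match."""
        planted = {f"g{i + 1}": (10.0 if i % 2 == 0 else -10.0) for i in range(40)}
        null_design = gf.SyntheticDesign(n_genes=250, conditions=("N", "T"), cv=0.10, seed=555)
        reg_design = gf.SyntheticDesign(
            n_genes=250, conditions=("N", "T"), cv=0.10, seed=555, regulated=planted
        )
        means = {}
        for name, design in (("null", null_design), ("regulated", reg_design)):
            esets, chars, _ = _study_tables(design)
            table = gf.regulation_table(esets["T"], esets["N"], chars["T"], chars["N"])
            means[name] = table.loc[list(planted), "TD"].mean()
        assert means["regulated"] > means["null"]
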