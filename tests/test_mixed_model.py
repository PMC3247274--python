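import numpy as np
import pandas as pd
import pytest

from hapwin.io import PedigreeTable
from hapwin.mixed_model import (PedigreeREML, build_design,
                                build_numerator_matrix, heritability,
                                reml_fit, rss_r2, substitution_tests)
from oracles import reml_loglik_direct


def _ped(rows):
    return PedigreeTable(pd.DataFrame(rows, columns=["individual", "sire",
                                                     "dam", "breed"]))


class TestNumeratorMatrix:
    def test_unrelated_founders_identity(self):
        ped = _ped([(f"F{i}", "", "", "X") for i in range(4)])
        rm = build_numerator_matrix(ped)
        np.testing.assert_allclose(rm.a, np.eye(4))

    def test_textbook_relationships(self):
        ped = _ped([("S", "0", "0", "X"), ("D", "0", "0", "X"),
                    ("C1", "S", "D", "X"), ("C2", "S", "D", "X")])
        rm = build_numerator_matrix(ped)
        i = {ind: k for k, ind in enumerate(rm.ids)}
        assert rm.a[i["S"], i["C1"]] == pytest.approx(0.5)  # parent-offspring
        assert rm.a[i["C1"], i["C2"]] == pytest.approx(0.5)  # full sibs
        assert rm.a[i["C1"], i["C1"]] == pytest.approx(1.0)  # non-inbred

    def test_inbred_pedigree_matches_hand_recursion(self):
        """Six-animal pedigree with a full-sib mating (animal 5) and a
        parent-offspring backcross (animal 6); expected entries were worked
        out by hand with the tabular rules."""
        ped = _ped([("1", "", "", "X"), ("2", "", "", "X"),
                    ("3", "1", "2", "X"), ("4", "1", "2", "X"),
                    ("5", "3", "4", "X"), ("6", "1", "5", "X")])
        rm = build_numerator_matrix(ped)
        i = {ind: k for k, ind in enumerate(rm.ids)}
        expected = {
            ("3", "4"): 0.5, ("3", "5"): 0.75, ("5", "5"): 1.25,
            ("1", "5"): 0.5, ("1", "6"): 0.75, ("2", "6"): 0.25,
            ("3", "6"): 0.625, ("5", "6"): 0.875, ("6", "6"): 1.25,
        }
        for (a, b), v in expected.items():
            assert rm.a[i[a], i[b]] == pytest.approx(v), (a, b)

    def test_generation_cap_truncates_old_ancestors(self):
        chain = [("G0", "", "", "X")]
        for g in range(1, 8):
            chain.append((f"G{g}", f"G{g-1}", "", "X"))
        rm_all = build_numerator_matrix(_ped(chain), max_generations=100)
        rm_cut = build_numerator_matrix(_ped(chain), max_generations=5)
        assert len(rm_cut.ids) == 5
        assert "G0" not in rm_cut.ids and "G7" in rm_cut.ids
        assert len(rm_all.ids) == 8

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            _ped([("A", "B", "", "X"), ("B", "A", "", "X")])


def _toy_data(n=120, h2=0.4, seed=0, n_sires=12):
    """Half-sib families with known variance components, founders included
    in the pedigree but unphenotyped."""
    rng = np.random.default_rng(seed)
    rows = []
    s_a, s_e = h2, 1 - h2
    recs = []
    for s in range(n_sires):
        sire = f"S{s}"
        rows.append((sire, "", "", "X"))
        u_s = rng.normal(0, np.sqrt(s_a))
        for k in range(n // n_sires):
            ind = f"I{s}_{k}"
            rows.append((ind, sire, "", "X"))
            u = u_s / 2 + rng.normal(0, np.sqrt(0.75 * s_a))
            y = 3.0 + u + rng.normal(0, np.sqrt(s_e))
            recs.append((ind, y))
    ped = _ped(rows)
    phen = pd.DataFrame(recs, columns=["individual", "trait"])
    phen["breed"] = "X"
    phen["herd"] = "H1"
    phen["sex"] = "M"
    phen["day"] = "D1"
    phen["age"] = 100.0
    return ped, phen


class TestPedigreeREML:
    def test_lambda_zero_reduces_to_ols(self):
        ped, phen = _toy_data(n=60, seed=1)
        amat = build_numerator_matrix(ped)
        rng = np.random.default_rng(2)
        phen["age"] = rng.uniform(0, 1, len(phen))
        fit = reml_fit(phen, amat, fixed=(), covariates=("age",),
                       lambda_value=0.0)
        X = np.column_stack([np.ones(len(phen)), phen["age"]])
        beta_ols, *_ = np.linalg.lstsq(X, phen["trait"], rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-10)
        resid = phen["trait"] - X @ beta_ols
        assert fit.rss == pytest.approx(float(resid @ resid))
        assert fit.sigma2_a == 0.0 and fit.h2 == 0.0

    def test_lambda_matches_grid_search_oracle(self):
        """On a 10-animal toy instance the profiled lambda-hat agrees with a
        fine grid search of an independently coded restricted likelihood."""
        ped = _ped([("S1", "", "", "X"), ("S2", "", "", "X")]
                   + [(f"I{k}", "S1" if k < 5 else "S2", "", "X")
                      for k in range(10)])
        amat = build_numerator_matrix(ped)
        rng = np.random.default_rng(4)
        ids = [f"I{k}" for k in range(10)]
        sub = amat.submatrix(ids)
        L = np.linalg.cholesky(sub.a + 1e-10 * np.eye(10))
        y = 1.0 + L @ rng.normal(0, 1.2, 10) + rng.normal(0, 1, 10)
        phen = pd.DataFrame({"individual": ids, "trait": y, "breed": "X",
                             "herd": "H", "sex": "M", "day": "D",
                             "age": 0.0})
        fit = reml_fit(phen, amat, fixed=(), covariates=())
        X = np.ones((10, 1))
        grid = np.arange(0.0, 30.0, 1e-3)
        lls = [reml_loglik_direct(l, y, X, sub.a) for l in grid]
        lam_grid = grid[int(np.argmax(lls))]
        # refine around the coarse winner to the 1e-4 resolution
        fine = np.arange(max(lam_grid - 2e-3, 0.0), lam_grid + 2e-3, 1e-4)
        lam_fine = fine[int(np.argmax([reml_loglik_direct(l, y, X, sub.a)
                                       for l in fine]))]
        assert fit.lambda_ == pytest.approx(lam_fine, abs=1e-4 * (1 + lam_fine))

    def test_balanced_half_sib_matches_anova_oracle(self):
        """Animal-model REML agrees with the closed-form sire-variance ANOVA
        estimator on a balanced 100x10 half-sib design."""
        ped, phen = _toy_data(n=1000, h2=0.4, seed=3, n_sires=100)
        amat = build_numerator_matrix(ped)
        fit = reml_fit(phen, amat, fixed=(), covariates=())
        y = phen["trait"].to_numpy().reshape(100, 10)
        ms_between = 10 * y.mean(axis=1).var(ddof=1)
        ms_within = y.var(axis=1, ddof=1).mean()
        sigma2_s = (ms_between - ms_within) / 10
        h2_anova = 4 * sigma2_s / (sigma2_s + ms_within)
        assert fit.h2 == pytest.approx(h2_anova, abs=0.08)
        assert abs(fit.h2 - 0.4) < 2.5 * fit.h2_se

    def test_aliased_fixed_level_dropped_and_reported(self):
        ped, phen = _toy_data(n=60, seed=5)
        phen["herd"] = np.where(phen.index < 30, "H1", "H2")
        phen["day"] = np.where(phen.index < 30, "D1", "D2")  # aliased w/ herd
        amat = build_numerator_matrix(ped)
        fit = reml_fit(phen, amat, fixed=("herd", "day"), covariates=())
        assert fit.dropped == ("day[D2]",)
        assert fit.rank == 2

    def test_haplotype_columns_n_minus_one_estimable(self):
        """All 8 dosage columns sum to 2 per row, so with an intercept
        exactly n-1 partial substitution effects are estimable and the
        preferred (most frequent) column is the dropped reference."""
        ped, phen = _toy_data(n=80, seed=6)
        rng = np.random.default_rng(6)
        draws = rng.choice(8, size=(len(phen), 2),
                           p=[0.3, 0.2, 0.15, 0.1, 0.1, 0.06, 0.05, 0.04])
        dos = np.zeros((len(phen), 8))
        for r, (i, j) in enumerate(draws):
            dos[r, i] += 1
            dos[r, j] += 1
        labels = [f"h{i}" for i in range(8)]
        markers = pd.DataFrame(dos, index=phen["individual"], columns=labels)
        amat = build_numerator_matrix(ped)
        fit = reml_fit(phen, amat, fixed=(), covariates=(), markers=markers,
                       drop_preference=labels[:1])
        assert fit.dropped == ("h0",)
        tests = substitution_tests(fit, labels)
        assert int(tests["estimable"].sum()) == 7

    def test_missing_marker_dosage_rejected(self):
        ped, phen = _toy_data(n=20, seed=7)
        markers = pd.DataFrame({"m": np.r_[np.nan, np.ones(len(phen) - 1)]},
                               index=phen["individual"])
        with pytest.raises(ValueError, match="impute upstream"):
            reml_fit(phen, build_numerator_matrix(ped), fixed=(),
                     covariates=(), markers=markers)


@pytest.fixture(scope="module")
def marker_fit():
    ped, phen = _toy_data(n=200, seed=8, n_sires=20)
    rng = np.random.default_rng(8)
    markers = pd.DataFrame({"m": rng.integers(0, 3, len(phen)).astype(float)},
                           index=phen["individual"])
    amat = build_numerator_matrix(ped)
    return reml_fit(phen, amat, fixed=(), covariates=(), markers=markers)


class TestSubstitutionTests:

    def test_t_is_b_over_se(self, marker_fit):
        tab = substitution_tests(marker_fit, ["m"]).iloc[0]
        assert tab["t"] == pytest.approx(tab["b"] / tab["se"])

    def test_reported_effect_arithmetic(self, marker_fit):
        """b = 0.179, se = 0.040 at large residual df gives t about 4.48 and
        a two-sided p of order 1e-5 (the printed benchmark association)."""
        from scipy import stats

        t = 0.179 / 0.040
        assert t == pytest.approx(4.475, abs=0.01)
        p = 2 * stats.t.sf(t, 850)
        assert 1e-6 < p < 1e-4

    def test_zero_effect_p_one(self):
        from hapwin.mixed_model import ModelFit

        fit = ModelFit(names=["(Intercept)", "m"], beta=np.array([1.0, 0.0]),
                       se=np.array([0.1, 0.1]), sigma2_a=0.1, sigma2_e=0.9,
                       h2=0.1, h2_se=0.05, h2_se_approx=False, rss=10.0,
                       loglik_restricted=0.0, n_used=50, rank=2, dropped=(),
                       individuals=tuple(str(i) for i in range(50)),
                       lambda_=0.1)
        tab = substitution_tests(fit, ["m"])
        assert tab["p"].iloc[0] == pytest.approx(1.0)
        assert tab["t"].iloc[0] == 0.0


class TestRssR2:
    def test_identity_and_arithmetic(self):
        ped, phen = _toy_data(n=40, seed=9)
        amat = build_numerator_matrix(ped)
        fit = reml_fit(phen, amat, fixed=(), covariates=())
        assert rss_r2(fit, fit) == 0.0
        without = dataclass_replace(fit, rss=100.0)
        with_ = dataclass_replace(fit, rss=98.0)
        assert rss_r2(with_, without) == pytest.approx(0.02)

    def test_mismatched_samples_rejected(self):
        ped, phen = _toy_data(n=40, seed=10)
        amat = build_numerator_matrix(ped)
        fit_a = reml_fit(phen, amat, fixed=(), covariates=())
        fit_b = reml_fit(phen.iloc[:-1], amat, fixed=(), covariates=())
        with pytest.raises(ValueError, match="identical"):
            rss_r2(fit_a, fit_b)

    def test_null_marker_r2_near_zero(self):
        ped, phen = _toy_data(n=400, seed=11, n_sires=40)
        rng = np.random.default_rng(11)
        markers = pd.DataFrame({"null": rng.integers(0, 3, len(phen)).astype(float)},
                               index=phen["individual"])
        amat = build_numerator_matrix(ped)
        base = reml_fit(phen, amat, fixed=(), covariates=())
        fit = reml_fit(phen, amat, fixed=(), covariates=(), markers=markers)
        assert abs(rss_r2(fit, base)) < 0.02

    def test_invariant_to_factor_coding(self):
        """R^2 must not depend on treatment vs sum contrasts of the fixed
        factors."""
        ped, phen = _toy_data(n=120, seed=12)
        rng = np.random.default_rng(12)
        phen["herd"] = rng.choice(["H1", "H2", "H3"], len(phen))
        markers = pd.DataFrame({"m": rng.integers(0, 3, len(phen)).astype(float)},
                               index=phen["individual"])
        amat = build_numerator_matrix(ped)
        r2 = {}
        for coding in ("treatment", "sum"):
            base = reml_fit(phen, amat, fixed=("herd",), covariates=(),
                            coding=coding)
            fit = reml_fit(phen, amat, fixed=("herd",), covariates=(),
                           markers=markers, coding=coding)
            r2[coding] = rss_r2(fit, base)
        assert r2["treatment"] == pytest.approx(r2["sum"], abs=1e-9)


def dataclass_replace(fit, **kw):
    import dataclasses

    return dataclasses.replace(fit, **kw)


class TestHeritability:
    def test_equal_components_give_half(self):
        ped, phen = _toy_data(n=60, seed=13)
        amat = build_numerator_matrix(ped)
        fit = reml_fit(phen, amat, fixed=(), covariates=(), lambda_value=1.0)
        h2, se = heritability(fit)
        assert h2 == pytest.approx(0.5)
        assert fit.sigma2_a == pytest.approx(fit.sigma2_e)

    def test_boundary_zero_flagged(self):
        ped, phen = _toy_data(n=60, seed=14)
        amat = build_numerator_matrix(ped)
        fit = reml_fit(phen, amat, fixed=(), covariates=(), lambda_value=0.0)
        assert fit.h2 == 0.0
        assert fit.h2_se_approx
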