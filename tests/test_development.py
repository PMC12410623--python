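"""FP transforms, logistic fitting, FP1 selection and backward elimination."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import endopredict as ep
from endopredict.cards import BinaryTerm, ContinuousTerm
from endopredict.development import backward_eliminate, select_fp1
from endopredict.transforms import FPTransform, positivity_shift_scale


class TestApplyFP:
    @pytest.mark.parametrize(
        "x,t,expected",
        [
            # published baseline-score transform: ((9+1)/10)^-1 - 1.10
            (9.0, FPTransform(shift=1, scale=10, power=-1, center=1.10), -0.10),
            # age centered at its development-sample mean maps the mean to 0
            (33.77, FPTransform(center=33.77), 0.0),
            (9.0, FPTransform(shift=1, scale=10, power=0), 0.0),  # log of unity
            (9.0, FPTransform(shift=1, scale=10, power=-2, center=2.77), 1.0 - 2.77),
            (49.0, FPTransform(shift=1, scale=100, power=3, center=0.0), 0.125),
        ],
    )
    def test_printed_transform_arithmetic(self, x, t, expected):
        assert ep.apply_fp(x, t) == pytest.approx(expected, abs=1e-12)

    def test_non_positive_argument_is_an_error(self):
        with pytest.raises(ValueError, match="positive"):
            ep.apply_fp(-1.0, FPTransform(power=0.5))

    def test_monotone_for_fixed_power(self):
        xs = np.linspace(0.0, 10.0, 50)
        for p in ep.FP1_POWERS:
            t = FPTransform(shift=1, scale=10, power=p)
            vals = ep.apply_fp(xs, t)
            diffs = np.diff(vals)
            assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_positivity_convention_matches_published_layout(self):
        # 0-10 scores with zeros present -> (x+1)/10; strictly positive ages -> untouched order 10
        shift, scale = positivity_shift_scale(np.array([0.0, 3.0, 10.0]))
        assert (shift, scale) == (1.0, 10.0)
        shift, scale = positivity_shift_scale(np.array([16.0, 40.0, 65.0]))
        assert (shift, scale) == (0.0, 10.0)


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # events 30/100 exposed vs 10/100 unexposed -> OR (30*90)/(70*10)
        df = pd.DataFrame({"exposed": np.r_[np.ones(100), np.zeros(100)]})
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        m = ep.fit_logistic([BinaryTerm("exposed", 0.0)], df, y)
        assert np.exp(m.coef[0]) == pytest.approx(30 * 90 / (70 * 10), rel=1e-6)
        assert m.coef[0] == pytest.approx(np.log(3.857142857), rel=1e-6)

    def test_intercept_only_recovers_logit_of_event_fraction(self):
        y = np.r_[np.ones(568), np.zeros(432)]
        df = pd.DataFrame(index=range(1000))
        m = ep.fit_logistic([], df, y)
        assert m.intercept == pytest.approx(logit(0.568), abs=1e-8)

    def test_matches_statsmodels_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(400, 3))
        lp = 0.4 + X @ np.array([0.8, -0.5, 0.0])
        y = (rng.random(400) < expit(lp)).astype(float)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        terms = [BinaryTerm("a", 0.0), BinaryTerm("b", 0.0), BinaryTerm("c", 0.0)]
        mine = ep.fit_logistic(terms, df, y)
        ora = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(np.r_[mine.intercept, mine.coef], ora.params, atol=1e-6)
        np.testing.assert_allclose(np.r_[mine.intercept_se, mine.se], ora.bse, atol=1e-6)

    def test_perfect_separation_raises(self):
        df = pd.DataFrame({"x": np.r_[np.ones(50), np.zeros(50)]})
        y = df["x"].to_numpy()
        with pytest.raises(ep.SeparationError):
            ep.fit_logistic([BinaryTerm("x", 0.0)], df, y)

    def test_collinearity_names_aliased_columns(self, rng):
        n = 200
        a = rng.normal(size=n)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        y = (rng.random(n) < expit(a)).astype(float)
        terms = [BinaryTerm("a", 0.0), BinaryTerm("b", 0.0)]
        with pytest.raises(ep.CollinearityError, match="b"):
            ep.fit_logistic(terms, df, y)

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 0.0]})
        with pytest.raises(ValueError, match="single class"):
            ep.fit_logistic([BinaryTerm("x", 0.0)], df, np.ones(3))


class TestSelectFP1:
    def _simulate(self, rng, power, n=5000, beta=3.0):
        x = rng.uniform(1.0, 9.0, size=n)
        z = (x + 1) / 10
        fx = np.log(z) if power == 0 else z**power
        fx = (fx - fx.mean()) / fx.std()
        y = (rng.random(n) < expit(fx * beta * -np.sign(power or 1))).astype(float)
        return x, y

    def test_recovers_inverse_square_law(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x, y = self._simulate(rng, -2.0)
            t = select_fp1(x, y)
            assert t is not None
            hits += t.power in (-2.0, -1.0)
        assert hits >= 3  # strongly non-linear powers chosen in the majority of seeds

    def test_linear_law_keeps_linear(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 5000
            x = rng.uniform(1.0, 9.0, size=n)
            y = (rng.random(n) < expit((x - 5.0) * 0.4)).astype(float)
            t = select_fp1(x, y)
            assert t is not None
            hits += t.power == 1.0
        assert hits >= 3

    def test_independent_predictor_mostly_excluded(self):
        excluded = 0
        runs = 40
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(1.0, 9.0, size=400)
            y = (rng.random(400) < 0.5).astype(float)
            excluded += select_fp1(x, y) is None
        # exclusion happens in about 1 - alpha of runs; allow broad slack at 40 runs
        assert excluded / runs > 0.6

    def test_linear_choice_centers_at_mean(self, rng):
        x = rng.uniform(20.0, 50.0, size=3000)
        y = (rng.random(3000) < expit((x - 35) * 0.1)).astype(float)
        t = select_fp1(x, y)
        if t.power == 1.0:
            assert t.center == pytest.approx(x.mean())

    def test_too_few_distinct_values_is_an_error(self):
        with pytest.raises(ValueError, match="distinct"):
            select_fp1(np.array([1.0, 1.0, 2.0, 2.0]), np.array([0, 1, 0, 1.0]))


class TestBackwardElimination:
    def test_mandatory_term_survives_even_when_null(self, rng):
        n = 3000
        df = pd.DataFrame(
            {
                "baseline_score": rng.uniform(1, 10, n),
                "signal": (rng.random(n) < 0.5).astype(float),
            }
        )
        y = (rng.random(n) < expit(1.2 * df["signal"] - 0.3)).astype(float)
        terms = [
            ContinuousTerm("baseline_score", FPTransform(center=5.5), 0.0),
            BinaryTerm("signal", 0.0),
        ]
        m = backward_eliminate(terms, df, y, mandatory=("baseline_score",), alpha=0.157)
        assert "baseline_score" in [t.name for t in m.terms]
        assert "signal" in [t.name for t in m.terms]

    def test_single_strong_predictor_kept_without_removals(self, rng):
        n = 2000
        df = pd.DataFrame({"x": (rng.random(n) < 0.4).astype(float)})
        y = (rng.random(n) < expit(1.5 * df["x"] - 0.5)).astype(float)
        trace = []
        m = backward_eliminate([BinaryTerm("x", 0.0)], df, y, mandatory=(), trace=trace)
        assert [t.name for t in m.terms] == ["x"] and trace == []

    def test_pure_noise_mostly_eliminated_and_llf_monotone(self, rng):
        n = 1500
        df = pd.DataFrame({f"n{i}": (rng.random(n) < 0.5).astype(float) for i in range(6)})
        y = (rng.random(n) < 0.5).astype(float)
        terms = [BinaryTerm(c, 0.0) for c in df.columns]
        trace = []
        m = backward_eliminate(terms, df, y, mandatory=(), trace=trace)
        assert len(m.terms) <= 2  # a few noise terms may survive at alpha=0.157
        assert len(trace) == 6 - len(m.terms)

    def test_centering_leaves_slopes_unchanged(self, rng):
        # re-centering a transform changes the intercept only
        n = 2500
        x = rng.uniform(1, 9, n)
        y = (rng.random(n) < expit(0.3 * (x - 5))).astype(float)
        df = pd.DataFrame({"x": x})
        m1 = ep.fit_logistic([ContinuousTerm("x", FPTransform(center=0.0), 0.0)], df, y)
        m2 = ep.fit_logistic([ContinuousTerm("x", FPTransform(center=5.0), 0.0)], df, y)
        assert m1.coef[0] == pytest.approx(m2.coef[0], abs=1e-7)
        assert m1.intercept == pytest.approx(m2.intercept - 5.0 * m2.coef[0], abs=1e-6)


class TestDevelopPipeline:
    def test_develop_returns_mandatory_baseline_and_logs(self, small_cohort):
        spec = ep.DevelopmentSpec(candidates=("strong_painkillers", "ovarian_usl_endo", "age"))
        log = {}
        m = ep.develop(small_cohort, spec, log=log)
        assert "baseline_score" in [t.name for t in m.terms]
        assert set(log) >= {"missingness", "complete_case", "dichotomization", "elimination"}
        assert m.n == log["dichotomization"]["defined"]
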