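"""Bootstrap internal validation, uniform shrinkage and external validation."""


import numpy as np
import pytest

import endopredict as ep

CANDIDATES = ("strong_painkillers", "conceiving", "ovarian_usl_endo", "age", "smoking")


@pytest.fixture(scope="module")
def dev_spec():
    return ep.DevelopmentSpec(candidates=CANDIDATES)


@pytest.fixture(scope="module")
def cohort(dyspareunia_card):
    return ep.generate(ep.GeneratorSpec(n=1500, seed=31, truth=dyspareunia_card))


# reuse the session card fixture at module scope
@pytest.fixture(scope="module")
def dyspareunia_card():
    return ep.load_shipped_card("dyspareunia_external")


class TestBootstrapValidate:
    def test_seeded_runs_are_bit_reproducible(self, cohort, dev_spec):
        a = ep.bootstrap_validate(cohort, dev_spec, ep.ValidationSpec(B=8, seed=2))
        b = ep.bootstrap_validate(cohort, dev_spec, ep.ValidationSpec(B=8, seed=2))
        assert a.to_dict() == b.to_dict()
        assert a.card.content_hash() == b.card.content_hash()

    def test_optimism_nonnegative_and_slope_below_one(self, cohort, dev_spec):
        res = ep.bootstrap_validate(cohort, dev_spec, ep.ValidationSpec(B=30, seed=7))
        assert res.optimism["c_statistic"] >= 0
        assert res.adjusted["calibration_slope"] < 1.0
        assert res.shrinkage == res.adjusted["calibration_slope"]
        assert res.B_effective == 30

    def test_identity_resample_gives_zero_optimism(self, cohort, dev_spec, monkeypatch):
        # degenerate bootstrap: when the resample is forced to equal the
        # original sample, apparent and test performance coincide exactly
        class IdentityRng:
            def integers(self, lo, hi=None, size=None):
                return np.arange(size)

        monkeypatch.setattr(np.random, "default_rng", lambda seed=None: IdentityRng())
        res = ep.bootstrap_validate(cohort, dev_spec, ep.ValidationSpec(B=1, seed=0))
        for v in res.optimism.values():
            assert v == pytest.approx(0.0, abs=1e-9)
        assert res.adjusted["c_statistic"] == pytest.approx(res.apparent.c_statistic)
        assert res.shrinkage == pytest.approx(1.0, abs=1e-9)

    def test_fast_mode_skips_reselection(self, cohort, dev_spec):
        res = ep.bootstrap_validate(
            cohort, dev_spec, ep.ValidationSpec(B=10, seed=7, replay_selection=False)
        )
        assert res.B_effective == 10
        assert 0.5 < res.adjusted["calibration_slope"] <= 1.05

    def test_shrunken_card_records_provenance(self, cohort, dev_spec):
        res = ep.bootstrap_validate(cohort, dev_spec, ep.ValidationSpec(B=5, seed=3))
        card = res.card
        assert card.shrinkage == pytest.approx(res.shrinkage)
        assert card.n == res.model.n and card.events == res.model.events
        assert "optimism_adjusted" in card.performance


class TestApplyShrinkage:
    def _simple_model(self, cohort):
        spec = ep.DevelopmentSpec(candidates=("ovarian_usl_endo", "age"), select_transforms=False)
        return ep.develop(cohort, spec)

    def _prepared(self, cohort):
        cc, _ = ep.complete_case(cohort, list(cohort.codebook.predictors))
        y, _ = ep.outcome_indicator(cc)
        keep = y.notna()
        tab = ep.CohortTable(cc.df[keep].reset_index(drop=True), cc.codebook)
        return tab, y[keep].to_numpy(dtype=float)

    def test_identity_shrinkage_preserves_model(self, cohort):
        m = self._simple_model(cohort)
        tab, y = self._prepared(cohort)
        card = ep.apply_shrinkage(m, 1.0, tab, y=y)
        np.testing.assert_allclose(
            np.concatenate([t.coefs for t in card.terms]), m.coef, atol=1e-12
        )
        assert card.intercept == pytest.approx(m.intercept, abs=1e-5)

    def test_shrunken_model_slope_is_inverse_of_s(self, cohort):
        # on its own development data, a model shrunk by S has calibration slope 1/S
        m = self._simple_model(cohort)
        tab, y = self._prepared(cohort)
        card = ep.apply_shrinkage(m, 0.9, tab, y=y)
        lp = card.linear_predictor(tab.df)
        assert ep.calibration_slope(lp, y) == pytest.approx(1 / 0.9, abs=0.02)

    def test_c_statistic_invariant_under_shrinkage(self, cohort):
        m = self._simple_model(cohort)
        tab, y = self._prepared(cohort)
        lp0 = m.linear_predictor(tab.df)
        for S in (0.5, 0.8, 1.0):
            card = ep.apply_shrinkage(m, S, tab, y=y)
            assert ep.c_statistic(card.linear_predictor(tab.df), y) == pytest.approx(
                ep.c_statistic(lp0, y), abs=1e-12
            )

    def test_mean_prediction_matches_event_fraction(self, cohort):
        m = self._simple_model(cohort)
        tab, y = self._prepared(cohort)
        card = ep.apply_shrinkage(m, 0.85, tab, y=y)
        assert card.predict(tab.df).mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_out_of_range_s_warns(self, cohort):
        m = self._simple_model(cohort)
        tab, y = self._prepared(cohort)
        with pytest.warns(UserWarning, match="shrinkage"):
            ep.apply_shrinkage(m, 1.2, tab, y=y)


class TestValidateExternal:
    def test_self_simulation_is_well_calibrated(self, dyspareunia_card):
        tab = ep.generate(ep.GeneratorSpec(n=50_000, seed=8, truth=dyspareunia_card))
        rep = ep.validate_external(dyspareunia_card, tab)
        assert rep.calibration_slope == pytest.approx(1.0, abs=0.05)
        assert rep.citl == pytest.approx(0.0, abs=0.05)

    def test_card_is_never_mutated(self, dyspareunia_card):
        before = dyspareunia_card.content_hash()
        tab = ep.generate(ep.GeneratorSpec(n=2000, seed=8, truth=dyspareunia_card))
        ep.validate_external(dyspareunia_card, tab)
        assert dyspareunia_card.content_hash() == before

    def test_shuffled_outcomes_give_chance_discrimination(self, dyspareunia_card, rng):
        tab = ep.generate(ep.GeneratorSpec(n=8000, seed=8, truth=dyspareunia_card))
        df = tab.df.copy()
        perm = rng.permutation(len(df))
        df["followup_score"] = df["followup_score"].to_numpy()[perm]
        df["baseline_score"] = df["baseline_score"].to_numpy()[perm]
        shuffled = ep.CohortTable(df, tab.codebook)
        rep = ep.validate_external(dyspareunia_card, shuffled)
        assert rep.c_statistic == pytest.approx(0.5, abs=0.03)

    def test_missing_predictor_column_is_an_error(self, dyspareunia_card):
        tab = ep.generate(ep.GeneratorSpec(n=200, seed=8, truth=dyspareunia_card))
        df = tab.df.drop(columns=["smoking"])
        cb_preds = {k: v for k, v in tab.codebook.predictors.items() if k != "smoking"}
        import dataclasses

        cb = dataclasses.replace(tab.codebook, predictors=cb_preds)
        with pytest.raises(KeyError, match="smoking"):
            ep.validate_external(dyspareunia_card, ep.CohortTable(df, cb))

    def test_unseen_categorical_level_is_an_error(self, dyspareunia_card):
        tab = ep.generate(ep.GeneratorSpec(n=200, seed=8, truth=dyspareunia_card))
        df = tab.df.copy()
        df.loc[0, "smoking"] = "vaper"
        import dataclasses

        preds = dict(tab.codebook.predictors)
        preds["smoking"] = dataclasses.replace(
            preds["smoking"], levels=(*preds["smoking"].levels, "vaper")
        )
        cb = dataclasses.replace(tab.codebook, predictors=preds)
        with pytest.raises(ValueError, match="unseen"):
            ep.validate_external(dyspareunia_card, ep.CohortTable(df, cb))
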