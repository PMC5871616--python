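import math

import numpy as np
import pytest

from caretactics._glmm import GLMMResult
from caretactics.demographic_rates import (
    ModelFit,
    bootstrap_rates,
    fit_recruitment,
    fit_survival,
    lrt_compare,
    protection_effect,
)
from caretactics.records_io import BearYear, T15, T25
from caretactics.reference import SURVIVAL_MODEL


def _record(**kw):
    base = dict(
        bear_id="F1",
        year=2000,
        age=5,
        tactic=T15,
        status="solitary",
        survived=True,
        cause_of_death="none",
        available_for_hunting=True,
        recruits=0,
    )
    base.update(kw)
    return BearYear(**base)


def _model_fit(names, beta, cov, loglik=0.0, family="binomial", n_obs=100, sigma=0.0):
    res = GLMMResult(
        family=family,
        names=list(names),
        beta=np.asarray(beta, dtype=float),
        sigma=sigma,
        alpha=0.5 if family == "negative_binomial" else None,
        loglik=loglik,
        cov_beta=np.asarray(cov, dtype=float),
        se_beta=np.sqrt(np.clip(np.diag(cov), 0, None)),
        n_obs=n_obs,
        n_groups=10,
        converged=True,
    )
    return ModelFit(
        formula="~", family=family, link="logit" if family == "binomial" else "log",
        random_terms=[], result=res, n_obs=n_obs,
    )


def _table1_fits(scale=0.0):
    """Survival/recruitment ModelFits pinned at the published coefficients,
    with covariance ``scale`` times a unit-ish diagonal."""
    names = ["intercept", "tactic_T25", "age_2", "age_3", "age_4-8", "age_9+"]
    beta = [SURVIVAL_MODEL[k] for k in ("intercept", "tactic_T25", "age_2", "age_3", "age_4-8", "age_9+")]
    fs = _model_fit(names, beta, scale * np.eye(6))
    fr = _model_fit(["intercept", "tactic_T25"], [-0.923, -0.425], scale * np.eye(2),
                    family="negative_binomial")
    return fs, fr


class TestFitSurvival:
    def test_all_survived_flags_separation(self):
        recs = [_record(bear_id=f"F{i}", year=2000 + i % 4, age=1 + i % 9) for i in range(40)]
        fit = fit_survival(recs)
        assert "separation" in fit.flags

    def test_empty_cells_flagged_but_fit_proceeds(self, small_population):
        _, bear_years, _ = small_population
        recs = [r for r in bear_years if not (r.tactic == T25 and r.age_class == "9+")]
        fit = fit_survival(recs, interaction="never")
        assert "empty_cell:T25x9+" in fit.flags
        assert np.all(np.isfinite(fit.coef_vector()))

    def test_recovers_generating_coefficients(self, small_population):
        """The default-population tactic and prime-age contrasts land near the
        log-odds implied by the configured class survival rates."""
        _, bear_years, _ = small_population
        fit = fit_survival(bear_years, interaction="never")
        coefs = fit.coefficients
        # implied contrasts from the configured rates (T15 reference)
        lo = lambda p: math.log(p / (1 - p))
        implied_48 = lo(0.973) - lo(0.809)
        est = coefs["age_4-8"]
        assert est["ci_low"] - 0.5 < implied_48 < est["ci_high"] + 0.5
        assert coefs["tactic_T25"]["estimate"] > 0

    def test_no_tactic_records_is_error(self):
        with pytest.raises(ValueError, match="known tactic"):
            fit_survival([_record(tactic="unknown")])


class TestFitRecruitment:
    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="recruits"):
            fit_recruitment([_record(age=3, recruits=None)])

    def test_all_zero_recruits_flagged(self):
        recs = [_record(bear_id=f"F{i}", age=6, recruits=0) for i in range(30)]
        fit = fit_recruitment(recs)
        assert any(f.startswith("non_estimable") for f in fit.flags)


class TestLRT:
    def test_identical_models_give_zero_statistic(self):
        f = _model_fit(["intercept", "x"], [0.1, 0.2], np.eye(2), loglik=-50.0)
        out = lrt_compare(f, f)
        assert out["statistic"] == 0.0 and out["p"] == 1.0 and out["df"] == 0

    def test_statistic_equals_deviance_difference(self):
        """On a fixed 50-row fixture the LRT statistic equals the brute-force
        GLM deviance difference."""
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        x = rng.normal(size=50)
        y = (rng.random(50) < 1 / (1 + np.exp(-(0.4 + 0.9 * x)))).astype(float)
        Xf = np.column_stack([np.ones(50), x])
        full = sm.GLM(y, Xf, family=sm.families.Binomial()).fit()
        red = sm.GLM(y, Xf[:, :1], family=sm.families.Binomial()).fit()
        mf = _model_fit(["intercept", "x"], full.params, np.eye(2), loglik=float(full.llf), n_obs=50)
        mr = _model_fit(["intercept"], red.params[:1], np.eye(1), loglik=float(red.llf), n_obs=50)
        out = lrt_compare(mf, mr)
        assert out["statistic"] == pytest.approx(float(red.deviance - full.deviance), abs=1e-8)
        assert out["df"] == 1

    def test_non_nested_models_rejected(self):
        a = _model_fit(["intercept", "x"], [0, 0], np.eye(2))
        b = _model_fit(["intercept", "z"], [0, 0], np.eye(2))
        with pytest.raises(ValueError, match="nested"):
            lrt_compare(a, b)


class TestBootstrapRates:
    def test_zero_uncertainty_collapses_to_closed_form(self):
        fs, fr = _table1_fits(scale=0.0)
        table = bootstrap_rates(fs, fr, n_bootstrap=100, seed=1)
        inv = lambda x: 1 / (1 + math.exp(-x))
        assert table.survival[T15]["1"]["mean"] == pytest.approx(inv(1.430), abs=1e-12)
        assert table.survival[T25]["1"]["mean"] == pytest.approx(inv(1.430 + 0.761), abs=1e-12)
        assert table.survival[T25]["1"]["mean"] == pytest.approx(0.899, abs=5e-4)
        for tac in (T15, T25):
            for cls, cell in table.survival[tac].items():
                assert cell["ci_low"] == pytest.approx(cell["mean"])
                assert cell["ci_high"] == pytest.approx(cell["mean"])
        # recruitment back-transforms of the published coefficients
        assert table.recruitment[T15]["5-9"]["mean"] == pytest.approx(math.exp(-0.923), rel=1e-9)
        assert table.recruitment[T25]["10+"]["mean"] == pytest.approx(math.exp(-1.348), rel=1e-9)
        assert table.recruitment[T15]["5-9"] == table.recruitment[T15]["10+"]

    def test_ci_width_shrinks_with_coefficient_uncertainty(self):
        widths = []
        for scale in (0.04, 0.01, 0.0025):
            fs, fr = _table1_fits(scale=scale)
            table = bootstrap_rates(fs, fr, n_bootstrap=2000, seed=3)
            cell = table.survival[T15]["1"]
            widths.append(cell["ci_high"] - cell["ci_low"])
        assert widths[0] > widths[1] > widths[2]

    def test_draws_are_deterministic_given_seed(self):
        fs, fr = _table1_fits(scale=0.01)
        a = bootstrap_rates(fs, fr, n_bootstrap=500, seed=7)
        b = bootstrap_rates(fs, fr, n_bootstrap=500, seed=7)
        for t in (T15, T25):
            assert np.array_equal(a.draws_by_tactic[t], b.draws_by_tactic[t])


class TestProtectionEffect:
    @staticmethod
    def _published_counts_fixture():
        recs = []
        for i in range(407):
            died = i < 55
            recs.append(
                _record(bear_id=f"S{i}", year=1993 + i % 20, age=4 + i % 12,
                        status="solitary", survived=not died,
                        cause_of_death="hunting" if died else "none",
                        available_for_hunting=True, recruits=None)
            )
        for i in range(207):
            died = i < 9
            recs.append(
                _record(bear_id=f"G{i}", year=1993 + i % 20, age=4 + i % 12,
                        status="with_offspring", survived=not died,
                        cause_of_death="hunting" if died else "none",
                        available_for_hunting=False, recruits=None)
            )
        return recs

    def test_reproduces_published_hunting_mortality(self):
        res = protection_effect(self._published_counts_fixture())
        sol = res.rates["solitary"]["hunting_mortality"]
        fam = res.rates["family_group"]["hunting_mortality"]
        assert round(sol["rate"], 2) == 0.14
        assert round(fam["rate"], 2) == 0.04
        assert (round(sol["ci_low"], 2), round(sol["ci_high"], 2)) == (0.10, 0.17)
        assert (round(fam["ci_low"], 2), round(fam["ci_high"], 2)) == (0.02, 0.07)
        assert res.hunting_odds_ratio == pytest.approx(3.44, abs=0.01)
        assert res.status_odds_ratio < 1.0

    def test_hunting_rate_never_exceeds_total_rate(self):
        res = protection_effect(self._published_counts_fixture())
        for block in res.rates.values():
            assert block["hunting_mortality"]["rate"] <= block["mortality"]["rate"]

    def test_zero_deaths_flags_non_estimable(self):
        recs = [_record(bear_id=f"A{i}", age=5, status="solitary", recruits=None) for i in range(20)]
        recs += [_record(bear_id=f"B{i}", age=5, status="with_offspring",
                         available_for_hunting=False, recruits=None) for i in range(20)]
        res = protection_effect(recs)
        assert math.isnan(res.status_odds_ratio)
        assert "non-estimable" in res.note
        assert res.rates["solitary"]["mortality"]["rate"] == 0

    def test_single_status_returns_rates_only(self):
        recs = [_record(bear_id=f"A{i}", age=5, status="solitary",
                        survived=i > 2, cause_of_death="hunting" if i <= 2 else "none",
                        recruits=None) for i in range(30)]
        res = protection_effect(recs)
        assert "single status" in res.note
        assert "solitary" in res.rates and "family_group" not in res.rates
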