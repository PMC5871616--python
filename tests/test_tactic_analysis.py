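import math
import random

import numpy as np
import pytest

from caretactics.records_io import BearYear, Litter, T15, T25
from caretactics.synthetic_population import SimulationConfig, simulate
from caretactics.tactic_analysis import (
    assign_tactics,
    consistency_summary,
    primiparity_effect,
    repeatability,
    weaning_trend,
)


def _litter(mother, birth, care, lid=None, primiparous=None):
    wean = None if care == "lost" else birth + (1 if care == 1.5 else 2)
    return Litter(
        litter_id=lid or f"L{mother}-{birth}",
        mother_id=mother,
        birth_year=birth,
        weaning_year=wean,
        care_duration=care,
        litter_size=2,
        mother_primiparous=primiparous,
    )


def _glmm_litters(seed, n_females=40, sigma=1.2733, slope=0.0, intercept=-0.5,
                  litters_per_female=(2, 3, 4), years=range(1993, 2016)):
    """Litters generated straight from the latent-intercept logistic model."""
    rng = np.random.default_rng(seed)
    litters = []
    base_year = min(years)
    for i in range(n_females):
        u = rng.normal(0, sigma)
        n = int(rng.choice(litters_per_female))
        for j, year in enumerate(sorted(rng.choice(list(years), size=n, replace=False))):
            eta = intercept + slope * (year - base_year) + u
            care = 2.5 if rng.random() < 1 / (1 + math.exp(-eta)) else 1.5
            litters.append(_litter(f"F{i}", int(year), care, lid=f"L{i}-{j}"))
    return litters


class TestAssignTactics:
    def test_mean_at_least_two_is_long_tactic(self):
        litters = [_litter("F1", 2000, 1.5), _litter("F1", 2003, 2.5), _litter("F1", 2007, 2.5)]
        (a,) = assign_tactics(litters)
        assert a.tactic == T25
        assert a.mean_care_duration == pytest.approx((1.5 + 2.5 + 2.5) / 3)
        assert not a.consistent

    def test_exact_mean_two_classified_long(self):
        litters = [_litter("F1", 2000, 1.5), _litter("F1", 2003, 2.5)]
        (a,) = assign_tactics(litters)
        assert a.mean_care_duration == 2.0 and a.tactic == T25

    def test_consistent_short_tactic_female(self):
        litters = [_litter("F1", 2000, 1.5), _litter("F1", 2002, 1.5)]
        (a,) = assign_tactics(litters)
        assert a.tactic == T15 and a.consistent

    def test_order_independent_and_idempotent(self):
        litters = _glmm_litters(seed=3)
        ref = assign_tactics(litters)
        shuffled = litters[:]
        random.Random(0).shuffle(shuffled)
        assert assign_tactics(shuffled) == ref
        assert assign_tactics(litters) == ref

    def test_lost_only_female_excluded_with_warning(self):
        litters = [_litter("F1", 2000, 1.5), _litter("F2", 2001, "lost")]
        with pytest.warns(UserWarning, match="no weaned litter"):
            out = assign_tactics(litters)
        assert [a.bear_id for a in out] == ["F1"]

    def test_simulator_consistent_females_all_flagged_consistent(self):
        cfg = SimulationConfig(n_initial_females=100, n_years=14, seed=6, tactic_consistency=1.0)
        _, litters = simulate(cfg)
        multi = [a for a in assign_tactics(litters) if a.n_litters >= 2]
        assert multi and all(a.consistent for a in multi)


class TestWeaningTrend:
    def test_single_year_flagged_non_estimable(self):
        litters = [_litter("F1", 2000, 1.5), _litter("F2", 2000, 2.5)]
        res = weaning_trend(litters)
        assert not res.estimable

    def test_all_one_tactic_flagged_separation(self):
        litters = [_litter(f"F{i}", 1995 + i, 1.5) for i in range(10)]
        res = weaning_trend(litters)
        assert not res.estimable and "separation" in res.note

    def test_year_shift_leaves_odds_ratio_unchanged(self):
        litters = _glmm_litters(seed=8, slope=math.log(1.17))
        res = weaning_trend(litters)
        shifted = [
            Litter(l.litter_id, l.mother_id, l.birth_year + 7, l.weaning_year + 7,
                   l.care_duration, l.litter_size, l.mother_primiparous)
            for l in litters
        ]
        res2 = weaning_trend(shifted)
        assert res.annual_odds_ratio == pytest.approx(res2.annual_odds_ratio, rel=1e-6)

    def test_confidence_interval_brackets_estimate(self):
        res = weaning_trend(_glmm_litters(seed=12, slope=math.log(1.17)))
        assert res.estimable
        assert res.ci_low < res.annual_odds_ratio < res.ci_high


class TestRepeatability:
    def test_requires_five_repeat_females(self):
        litters = [_litter("F1", 2000, 1.5), _litter("F1", 2002, 1.5)]
        with pytest.raises(ValueError, match=">= 5 females"):
            repeatability(litters)

    def test_iid_litters_have_near_zero_repeatability(self):
        litters = _glmm_litters(seed=21, sigma=0.0)
        res = repeatability(litters, n_bootstrap=100, seed=1)
        assert res.r_original < 0.05
        assert res.r_latent < 0.05

    def test_perfectly_consistent_females_approach_upper_bound(self):
        litters = []
        for i in range(12):
            care = 2.5 if i % 2 else 1.5
            litters += [_litter(f"F{i}", 1995 + j * 3, care, lid=f"L{i}-{j}") for j in range(3)]
        res = repeatability(litters, n_bootstrap=50, seed=1)
        assert res.r_latent > 0.85
        assert 0.0 <= res.r_original <= 1.0

    def test_label_swap_invariance(self):
        litters = _glmm_litters(seed=30)
        swapped = [
            Litter(l.litter_id, l.mother_id, l.birth_year,
                   l.birth_year + (2 if l.care_duration == 1.5 else 1),
                   2.5 if l.care_duration == 1.5 else 1.5,
                   l.litter_size, l.mother_primiparous)
            for l in litters
        ]
        a = repeatability(litters, n_bootstrap=0, seed=1)
        b = repeatability(swapped, n_bootstrap=0, seed=1)
        assert a.r_original == pytest.approx(b.r_original, abs=1e-4)
        assert a.r_latent == pytest.approx(b.r_latent, abs=1e-4)

    def test_bootstrap_interval_contains_point_estimate(self):
        litters = _glmm_litters(seed=14)
        res = repeatability(litters, n_bootstrap=200, seed=2)
        assert res.ci_low <= res.r_original + 0.1
        assert res.ci_high >= res.r_original - 0.1
        assert 0 <= res.ci_low <= res.ci_high <= 1


class TestPrimiparity:
    def test_full_separation_flagged(self):
        litters = [_litter(f"F{i}", 1995 + i, 1.5, primiparous=True) for i in range(6)]
        litters += [_litter(f"G{i}", 1995 + i, 2.5, primiparous=False) for i in range(6)]
        res = primiparity_effect(litters)
        assert not res.estimable

    def test_no_effect_ci_covers_one(self):
        rng = np.random.default_rng(40)
        litters = []
        for i in range(60):
            for j in range(2):
                care = 2.5 if rng.random() < 0.35 else 1.5
                litters.append(
                    _litter(f"F{i}", 1994 + 2 * j + int(rng.integers(0, 12)), care,
                            lid=f"L{i}-{j}", primiparous=j == 0)
                )
        res = primiparity_effect(litters)
        assert res.estimable
        assert res.ci_low < 1.0 < res.ci_high

    def test_unknown_parity_removed(self):
        litters = _glmm_litters(seed=2)
        litters = [
            Litter(l.litter_id, l.mother_id, l.birth_year, l.weaning_year, l.care_duration,
                   l.litter_size, None if i % 3 == 0 else i % 2 == 0)
            for i, l in enumerate(litters)
        ]
        res = primiparity_effect(litters)
        assert res.n_litters == sum(l.mother_primiparous is not None for l in litters)


class TestConsistencySummary:
    @staticmethod
    def _bear_years_for(ages_by_id):
        out = []
        for bid, ages in ages_by_id.items():
            for k, age in enumerate(ages):
                out.append(
                    BearYear(bid, 2000 + k, age, T15, "solitary", True, "none", True, None)
                )
        return out

    def test_five_of_eight_is_62_5_percent(self):
        litters = []
        for i in range(8):
            care2 = 1.5 if i < 5 else 2.5  # 5 consistent, 3 flexible
            litters += [_litter(f"F{i}", 2000, 1.5), _litter(f"F{i}", 2004, care2)]
        assignments = assign_tactics(litters)
        out = consistency_summary(assignments, [])
        assert out["pct_consistent"] == pytest.approx(62.5)

    def test_t_statistic_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(13)
        cons_ages = rng.integers(6, 16, 10)
        flex_ages = rng.integers(6, 16, 10)
        litters = []
        ages = {}
        for i, age in enumerate(cons_ages):
            litters += [_litter(f"C{i}", 2000, 1.5), _litter(f"C{i}", 2004, 1.5)]
            ages[f"C{i}"] = [int(age)]
        for i, age in enumerate(flex_ages):
            litters += [_litter(f"X{i}", 2000, 1.5), _litter(f"X{i}", 2004, 2.5)]
            ages[f"X{i}"] = [int(age)]
        out = consistency_summary(assign_tactics(litters), self._bear_years_for(ages))
        x, ycomp = cons_ages.astype(float), flex_ages.astype(float)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(ycomp) - 1) * ycomp.var(ddof=1)) / (
            len(x) + len(ycomp) - 2
        )
        t_manual = (x.mean() - ycomp.mean()) / math.sqrt(sp2 * (1 / len(x) + 1 / len(ycomp)))
        assert out["t"] == pytest.approx(t_manual, abs=1e-10)
        assert out["df"] == 18

    def test_equal_means_give_zero_t(self):
        litters = []
        ages = {}
        for i in range(6):
            litters += [_litter(f"C{i}", 2000, 1.5), _litter(f"C{i}", 2004, 1.5)]
            litters += [_litter(f"X{i}", 2000, 1.5), _litter(f"X{i}", 2004, 2.5)]
            ages[f"C{i}"] = [8 + i]
            ages[f"X{i}"] = [8 + i]
        out = consistency_summary(assign_tactics(litters), self._bear_years_for(ages))
        assert out["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_empty_group_skips_t_test(self):
        litters = [_litter("F1", 2000, 1.5), _litter("F1", 2004, 1.5),
                   _litter("F2", 2000, 1.5), _litter("F2", 2004, 1.5)]
        out = consistency_summary(assign_tactics(litters), [])
        assert math.isnan(out["t"]) and "skipped" in out["note"]
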