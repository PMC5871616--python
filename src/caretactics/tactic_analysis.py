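"""Classification and analysis of maternal-care tactics.

Females are classified by the average duration of maternal care over their
weaned litters: an average >= 2 years is the 2.5-year tactic, < 2 years the
1.5-year tactic; single-litter females are classified by that litter, and
litters lost before weaning are excluded throughout.

Inference on the binary litter outcome (1 = 2.5 years of care) uses
logistic mixed models with a female random intercept: the temporal trend
(`weaning_trend`, exponentiated year coefficient = annual odds ratio), the
effect of parity (`primiparity_effect`), and a GLMM-based repeatability
(`repeatability`) with a female-level bootstrap for confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._glmm import fit_glmm
from .records_io import BearYear, Litter, T15, T25, LOST

__all__ = [
    "TacticAssignment",
    "TrendResult",
    "RepeatabilityResult",
    "PrimiparityResult",
    "assign_tactics",
    "weaning_trend",
    "repeatability",
    "primiparity_effect",
    "consistency_summary",
]


@dataclass(frozen=True)
class TacticAssignment:
    bear_id: str
    mean_care_duration: float
    tactic: str
    n_litters: int
    consistent: bool


@dataclass(frozen=True)
class TrendResult:
    annual_odds_ratio: float
    ci_low: float
    ci_high: float
    n_litters: int
    n_females: int
    estimable: bool = True
    note: str = ""


@dataclass(frozen=True)
class RepeatabilityResult:
    r_original: float
    r_latent: float
    sigma2_individual: float
    sigma2_residual: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    boundary: bool = False


@dataclass(frozen=True)
class PrimiparityResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_litters: int
    estimable: bool = True
    note: str = ""


def _weaned(litters: list[Litter]) -> list[Litter]:
    return [l for l in litters if l.care_duration != LOST]


def assign_tactics(litters: list[Litter]) -> list[TacticAssignment]:
    """One assignment per female with >= 1 weaned litter.

    The mean care duration decides the tactic (>= 2 years -> 2.5-year
    tactic); ``consistent`` records whether every weaned litter had the same
    duration. Females with only lost litters are excluded with a warning.
    """
    by_female: dict[str, list[float]] = defaultdict(list)
    excluded = set()
    for lit in litters:
        if lit.care_duration == LOST:
            excluded.add(lit.mother_id)
            continue
        by_female[lit.mother_id].append(float(lit.care_duration))
    dropped = excluded - set(by_female)
    if dropped:
        warnings.warn(
            f"{len(dropped)} female(s) with no weaned litter excluded from tactic assignment"
        )
    out = []
    for bear_id in sorted(by_female):
        durations = by_female[bear_id]
        mean = sum(durations) / len(durations)
        out.append(
            TacticAssignment(
                bear_id=bear_id,
                mean_care_duration=mean,
                tactic=T25 if mean >= 2.0 else T15,
                n_litters=len(durations),
                consistent=len(set(durations)) == 1,
            )
        )
    return out


def _binary_response(litters: list[Litter]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    weaned = _weaned(litters)
    y = np.array([1.0 if l.care_duration == 2.5 else 0.0 for l in weaned])
    years = np.array([float(l.weaning_year) for l in weaned])
    mothers = np.array([l.mother_id for l in weaned])
    return y, years, mothers


def weaning_trend(litters: list[Litter]) -> TrendResult:
    """Annual odds ratio of a litter being weaned after 2.5 years of care.

    Logistic mixed model of the litter outcome on (centered) weaning year
    with a female random intercept; returns the exponentiated year
    coefficient with its Wald 95% CI. Complete separation or a single
    observed year yields a flagged non-estimable result.
    """
    y, years, mothers = _binary_response(litters)
    n_females = len(set(mothers))
    base = TrendResult(math.nan, math.nan, math.nan, len(y), n_females, estimable=False)
    if len(y) == 0 or len(set(years)) < 2:
        return TrendResult(**{**base.__dict__, "note": "fewer than two distinct years"})
    if y.min() == y.max():
        return TrendResult(**{**base.__dict__, "note": "complete separation: all litters one tactic"})
    X = np.column_stack([np.ones_like(years), years - years.mean()])
    fit = fit_glmm(y, X, mothers, family="binomial", names=["intercept", "year"])
    row = fit.coef_table()["year"]
    if "separation" in fit.flags:
        return TrendResult(**{**base.__dict__, "note": "separation flagged by fit"})
    return TrendResult(
        annual_odds_ratio=math.exp(row["estimate"]),
        ci_low=math.exp(row["ci_low"]),
        ci_high=math.exp(row["ci_high"]),
        n_litters=len(y),
        n_females=n_females,
    )


def _repeatability_point(y: np.ndarray, mothers: np.ndarray) -> tuple[float, float, float, bool]:
    """(r_original, r_latent, sigma2_ind, boundary) from an intercept-only
    logistic GLMM.

    Latent-scale repeatability uses the logit-link distribution-specific
    residual pi^2/3: r_latent = s2 / (s2 + s2_resid + pi^2/3), with the
    multiplicative-overdispersion residual s2_resid fixed at 0 for strictly
    binary data. The original-scale value back-transforms the latent
    variance with the first-order link correction: with p = invlogit(beta0)
    and m = dp/deta = p(1-p),

        r_original = s2 m^2 / (s2 m^2 + p(1-p)),

    i.e. the among-female variance mapped through the link slope against the
    Bernoulli residual variance.
    """
    X = np.ones((len(y), 1))
    fit = fit_glmm(y, X, mothers, family="binomial", names=["intercept"])
    s2 = fit.sigma2
    boundary = "boundary" in fit.flags
    p = 1.0 / (1.0 + math.exp(-float(fit.beta[0])))
    m = p * (1 - p)
    r_latent = s2 / (s2 + math.pi**2 / 3)
    r_original = s2 * m**2 / (s2 * m**2 + m) if m > 0 else 0.0
    return min(max(r_original, 0.0), 1.0), min(max(r_latent, 0.0), 1.0), s2, boundary


def repeatability(
    litters: list[Litter], n_bootstrap: int = 1000, seed: int = 0
) -> RepeatabilityResult:
    """GLMM-based repeatability of the binary care-duration outcome.

    Uses only females with >= 2 weaned litters. The 95% CI is a percentile
    bootstrap over females (resample females with replacement, keep all
    their litters), seeded and of ``n_bootstrap`` iterations; the reported
    interval is for the original-scale repeatability.
    """
    y, _, mothers = _binary_response(litters)
    counts = defaultdict(int)
    for m in mothers:
        counts[m] += 1
    keep = np.array([counts[m] >= 2 for m in mothers])
    y, mothers = y[keep], mothers[keep]
    females = sorted(set(mothers))
    if len(females) < 5:
        raise ValueError(
            f"repeatability needs >= 5 females with >= 2 care periods, got {len(females)}"
        )
    r_orig, r_latent, s2, boundary = _repeatability_point(y, mothers)

    rng = np.random.default_rng(seed)
    groups = {f: np.flatnonzero(mothers == f) for f in females}
    boots = []
    for _ in range(n_bootstrap):
        chosen = rng.choice(females, size=len(females), replace=True)
        idx = np.concatenate([groups[f] for f in chosen])
        new_ids = np.repeat(np.arange(len(chosen)), [len(groups[f]) for f in chosen])
        yb = y[idx]
        if yb.min() == yb.max():
            boots.append(0.0)  # degenerate resample: no variance to attribute
            continue
        rb, _, _, _ = _repeatability_point(yb, new_ids)
        boots.append(rb)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = math.nan
    return RepeatabilityResult(
        r_original=r_orig,
        r_latent=r_latent,
        sigma2_individual=s2,
        sigma2_residual=0.0,
        ci_low=float(lo),
        ci_high=float(hi),
        n_bootstrap=n_bootstrap,
        boundary=boundary,
    )


def primiparity_effect(litters: list[Litter]) -> PrimiparityResult:
    """Odds ratio for primiparous (vs multiparous) mothers using the
    2.5-year tactic; litters with unknown parity are removed."""
    weaned = [l for l in _weaned(litters) if l.mother_primiparous is not None]
    if not weaned:
        return PrimiparityResult(math.nan, math.nan, math.nan, 0, False, "no litters with known parity")
    y = np.array([1.0 if l.care_duration == 2.5 else 0.0 for l in weaned])
    primi = np.array([1.0 if l.mother_primiparous else 0.0 for l in weaned])
    mothers = np.array([l.mother_id for l in weaned])
    base = PrimiparityResult(math.nan, math.nan, math.nan, len(y), estimable=False)
    # quasi-complete separation: an empty cell in the 2x2 tactic x parity table
    cells = {(int(a), int(b)) for a, b in zip(primi, y)}
    if len({int(v) for v in y}) < 2 or len({int(v) for v in primi}) < 2:
        return PrimiparityResult(**{**base.__dict__, "note": "degenerate design: single level"})
    if len(cells) < 4:
        return PrimiparityResult(**{**base.__dict__, "note": "separation: empty tactic x parity cell"})
    X = np.column_stack([np.ones_like(y), primi])
    fit = fit_glmm(y, X, mothers, family="binomial", names=["intercept", "primiparous"])
    if "separation" in fit.flags:
        return PrimiparityResult(**{**base.__dict__, "note": "separation flagged by fit"})
    row = fit.coef_table()["primiparous"]
    return PrimiparityResult(
        odds_ratio=math.exp(row["estimate"]),
        ci_low=math.exp(row["ci_low"]),
        ci_high=math.exp(row["ci_high"]),
        n_litters=len(y),
    )


def consistency_summary(
    assignments: list[TacticAssignment], bear_years: list[BearYear]
) -> dict:
    """Share of consistent females and the age comparison between consistent
    and flexible females.

    ``pct_consistent`` is the percentage of multi-litter females whose weaned
    litters all shared one duration; ``pct_consistent_all`` uses all assigned
    females as the denominator (single-litter females counted consistent).
    The age comparison is a two-sample Student's t-test (pooled variance) of
    each female's mean observed age, consistent vs flexible multi-litter
    females.
    """
    multi = [a for a in assignments if a.n_litters >= 2]
    n_consistent = sum(a.consistent for a in multi)
    out = {
        "n_females": len(assignments),
        "n_multi_litter": len(multi),
        "pct_consistent": 100.0 * n_consistent / len(multi) if multi else math.nan,
        "pct_consistent_all": (
            100.0 * (n_consistent + sum(a.n_litters == 1 for a in assignments)) / len(assignments)
            if assignments
            else math.nan
        ),
    }
    ages: dict[str, list[int]] = defaultdict(list)
    for rec in bear_years:
        ages[rec.bear_id].append(rec.age)
    cons = [np.mean(ages[a.bear_id]) for a in multi if a.consistent and ages[a.bear_id]]
    flex = [np.mean(ages[a.bear_id]) for a in multi if not a.consistent and ages[a.bear_id]]
    if not cons or not flex:
        out.update(t=math.nan, df=math.nan, p=math.nan, note="one group empty; t-test skipped")
        return out
    t, p = stats.ttest_ind(cons, flex, equal_var=True)
    out.update(
        t=float(t),
        df=len(cons) + len(flex) - 2,
        p=float(p),
        mean_age_consistent=float(np.mean(cons)),
        mean_age_flexible=float(np.mean(flex)),
    )
    return out
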