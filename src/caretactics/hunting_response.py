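"""Hunting-pressure index and the tactic-specific response of survival and
population growth to hunting.

The annual hunting-pressure index ``h`` is the number of marked bears shot
in a year divided by the number of marked bears legally available for
hunting that year; family-group members (not available) and bears dead
before the season never enter the denominator. Years with no available
bears have an undefined (missing) index, not 0.

Each tactic x age-class survival probability is regressed on ``h``
(logistic regression, annual ``h`` shared by every individual in that
year); estimation uncertainty is represented by parametric draws from the
asymptotic distribution of the (intercept, slope) pair. Feeding the
predicted survival probabilities over a pressure grid into the
tactic-specific Leslie matrices — recruitment held fixed, since only the
survival components respond to hunting — yields a distribution of the
asymptotic growth rate lambda at each pressure for each tactic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .matrix_demography import build_matrix
from .records_io import BearYear, T15, T25, AGE_CLASSES

__all__ = [
    "PressureSeries",
    "PressureModelSet",
    "pressure_index",
    "fit_pressure_models",
    "lambda_vs_pressure",
    "default_pressure_grid",
]

_SEPARATION_BOUND = 30.0


@dataclass(frozen=True)
class PressureSeries:
    """year -> index value, with numerator/denominator counts retained."""

    years: list[int]
    shot: dict[int, int]
    available: dict[int, int]

    def value(self, year: int) -> float | None:
        n = self.available.get(year, 0)
        if n == 0:
            return None
        return self.shot[year] / n

    def as_dict(self) -> dict[int, float | None]:
        return {y: self.value(y) for y in self.years}

    def observed_range(self) -> tuple[float, float]:
        vals = [v for v in self.as_dict().values() if v is not None]
        if not vals:
            raise ValueError("no year has a defined pressure index")
        return min(vals), max(vals)


@dataclass
class PressureModelSet:
    """Per (tactic, age class): logistic fit of survival on pressure with
    uncertainty draws; cells that could not be estimated carry a flag."""

    cells: dict = field(default_factory=dict)  # (tactic, cls) -> dict
    n_draws: int = 0

    def cell(self, tactic: str, age_class: str) -> dict:
        return self.cells[(tactic, age_class)]

    def estimable(self, tactic: str) -> bool:
        return all(
            not self.cells.get((tactic, c), {"flag": "missing"}).get("flag")
            for c in AGE_CLASSES
        )


def pressure_index(bear_years: list[BearYear]) -> PressureSeries:
    """Annual hunting-pressure index from marked-bear records."""
    years = sorted({r.year for r in bear_years})
    shot = {y: 0 for y in years}
    available = {y: 0 for y in years}
    for r in bear_years:
        if not r.available_for_hunting:
            continue
        available[r.year] += 1
        if r.cause_of_death == "hunting":
            shot[r.year] += 1
    return PressureSeries(years=years, shot=shot, available=available)


def fit_pressure_models(
    bear_years: list[BearYear],
    pressure: PressureSeries,
    n_draws: int = 1000,
    seed: int = 0,
) -> PressureModelSet:
    """Logistic survival-on-pressure models for every tactic x age class.

    Cells with a constant pressure covariate or complete separation are
    flagged and excluded downstream (with a warning at lambda prediction).
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    h_by_year = {y: v for y, v in pressure.as_dict().items() if v is not None}
    out = PressureModelSet(n_draws=n_draws)
    for tactic in (T15, T25):
        for cls in AGE_CLASSES:
            recs = [
                r
                for r in bear_years
                if r.tactic == tactic and r.age_class == cls and r.year in h_by_year
            ]
            cell: dict = {"tactic": tactic, "age_class": cls, "n_obs": len(recs), "flag": ""}
            if not recs:
                cell["flag"] = "no_observations"
                out.cells[(tactic, cls)] = cell
                continue
            y = np.array([1.0 if r.survived else 0.0 for r in recs])
            h = np.array([h_by_year[r.year] for r in recs])
            if len(set(np.round(h, 12))) < 2:
                cell["flag"] = "constant_pressure"
                out.cells[(tactic, cls)] = cell
                continue
            X = sm.add_constant(h)
            if y.min() == y.max():
                # no deaths (or no survivors) in the cell: slope inestimable,
                # intercept pinned at the boundary
                cell["flag"] = "separation"
                out.cells[(tactic, cls)] = cell
                continue
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            params = np.asarray(fit.params, dtype=float)
            if np.any(np.abs(params) > _SEPARATION_BOUND) or not np.all(np.isfinite(params)):
                cell["flag"] = "separation"
                out.cells[(tactic, cls)] = cell
                continue
            cov = np.asarray(fit.cov_params(), dtype=float)
            draws = rng.multivariate_normal(params, cov, size=n_draws, method="eigh")
            cell.update(
                intercept=float(params[0]),
                slope=float(params[1]),
                cov=cov,
                draws=draws,
            )
            out.cells[(tactic, cls)] = cell
    return out


def default_pressure_grid(
    pressure: PressureSeries | None = None, n_points: int = 12
) -> np.ndarray:
    """12 evenly spaced pressures over the observed range (0-0.33 fallback)."""
    if pressure is None:
        lo, hi = 0.0, 0.33
    else:
        lo, hi = pressure.observed_range()
    return np.linspace(lo, hi, n_points)


def lambda_vs_pressure(
    models: PressureModelSet,
    recruitment_by: dict[str, float],
    pressures=None,
    seed: int = 0,
) -> dict:
    """Distribution of lambda per tactic over a hunting-pressure grid.

    For each coefficient draw and grid pressure, the five predicted survival
    probabilities enter the tactic's Leslie matrix with the tactic's (fixed)
    recruitment; lambda is the dominant eigenvalue. Returns, per tactic, the
    grid, the (n_pressures, n_draws) array of lambda values, and the 2.5 /
    25 / 50 / 75 / 97.5 percent quantiles per pressure. Tactics with any
    non-estimable survival cell are skipped with a note; matrix-invalid
    draws (survival outside [0, 1] after back-transform cannot occur; only
    non-finite draws can) are dropped and counted.
    """
    if pressures is None:
        pressures = default_pressure_grid()
    pressures = np.asarray(pressures, dtype=float)
    out: dict = {"pressures": pressures, "tactics": {}, "skipped": {}}
    for tactic in (T15, T25):
        if tactic not in recruitment_by:
            continue
        if not models.estimable(tactic):
            bad = [
                c
                for c in AGE_CLASSES
                if models.cells.get((tactic, c), {}).get("flag")
            ]
            out["skipped"][tactic] = f"non-estimable cells: {bad}"
            continue
        cell_draws = [models.cell(tactic, c)["draws"] for c in AGE_CLASSES]
        n_draws = min(len(d) for d in cell_draws)
        lam = np.full((len(pressures), n_draws), np.nan)
        R = float(recruitment_by[tactic])
        dropped = 0
        for ip, p in enumerate(pressures):
            # survival per class and draw: invlogit(a + b * p)
            S = np.column_stack(
                [1.0 / (1.0 + np.exp(-(d[:n_draws, 0] + d[:n_draws, 1] * p))) for d in cell_draws]
            )
            for k in range(n_draws):
                s1, s2, s3, s48, s9 = S[k]
                if not np.all(np.isfinite(S[k])):
                    dropped += 1
                    continue
                m = build_matrix(s1, s2, s3, s48, s9, R, tactic=tactic)
                vals = np.linalg.eigvals(m.entries)
                lam[ip, k] = float(np.max(np.abs(vals)))
        qs = np.nanpercentile(lam, [2.5, 25, 50, 75, 97.5], axis=1)
        out["tactics"][tactic] = {
            "lambda_draws": lam,
            "quantiles": {
                "2.5": qs[0],
                "25": qs[1],
                "50": qs[2],
                "75": qs[3],
                "97.5": qs[4],
            },
            "dropped": dropped,
        }
    return out
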