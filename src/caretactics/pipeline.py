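"""End-to-end pipeline: simulate -> classify tactics -> rates -> matrix
demography -> hunting curves, with a single reproducibility manifest.

Every stochastic stage has an explicit seed; re-running the same
configuration reproduces byte-identical JSON outputs (no timestamps, sorted
keys, seeded generators). The manifest records package and library
versions, per-stage seeds, output paths and SHA-256 checksums.
"""

from __future__ import annotations

import csv
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import demographic_rates as dr
from . import hunting_response as hr
from . import matrix_demography as md
from . import synthetic_population as sp
from . import tactic_analysis as ta
from .records_io import (
    T15,
    T25,
    AGE_CLASSES,
    read_bear_years,
    read_litters,
    write_bear_years,
    write_litters,
)

__all__ = ["PipelineConfig", "run", "report"]

STAGES = ("simulate", "tactics", "rates", "demography", "hunting")


@dataclass
class PipelineConfig:
    out_dir: str = "caretactics_out"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    seeds: dict = field(default_factory=lambda: {"simulate": 1, "tactics": 2, "rates": 3, "hunting": 4})
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    tactics: dict = field(default_factory=lambda: {"n_bootstrap": 1000})
    rates: dict = field(default_factory=lambda: {"n_bootstrap": 10000})
    hunting: dict = field(default_factory=lambda: {"n_draws": 1000, "grid_points": 12})
    bear_years_path: str | None = None  # inputs when the simulate stage is off
    litters_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown pipeline config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        for s in cfg.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        return cfg


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj):  # NaN -> null for valid JSON
        return None
    return obj


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_to_jsonable(payload), indent=1, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(f"[caretactics] {msg}", file=sys.stderr)


def _modelfit_summary(fit: dr.ModelFit) -> dict:
    return {
        "formula": fit.formula,
        "family": fit.family,
        "link": fit.link,
        "random_terms": fit.random_terms,
        "n_obs": fit.n_obs,
        "loglik": fit.loglik,
        "sigma": fit.result.sigma,
        "alpha": fit.result.alpha,
        "coefficients": fit.coefficients,
        "flags": fit.flags,
    }


def run(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "caretactics",
        "version": __version__,
        "versions": {"numpy": np.__version__},
        "seeds": dict(config.seeds),
        "stages": [],
        "outputs": {},
    }

    bear_years = litters = None
    rate_table = None
    fits = {}

    def record_stage(name, paths):
        entry = {"stage": name, "outputs": {}}
        for label, p in paths.items():
            entry["outputs"][label] = {"path": str(p), "sha256": _sha256(Path(p))}
            manifest["outputs"][label] = str(p)
        manifest["stages"].append(entry)

    if config.stages.get("simulate", True):
        _log("stage simulate")
        sim_cfg = sp.SimulationConfig(**config.simulate, seed=config.seeds.get("simulate", 1))
        bear_years, litters = sp.simulate(sim_cfg)
        by_path = out / "bear_years.csv"
        li_path = out / "litters.csv"
        truth_path = out / "truth.json"
        write_bear_years(bear_years, by_path)
        write_litters(litters, li_path)
        _write_json(truth_path, sp.truth_record(sim_cfg))
        record_stage("simulate", {"bear_years": by_path, "litters": li_path, "truth": truth_path})
    else:
        if config.bear_years_path:
            bear_years = read_bear_years(config.bear_years_path)
        if config.litters_path:
            litters = read_litters(config.litters_path)

    if config.stages.get("tactics", True):
        if litters is None or bear_years is None:
            raise RuntimeError("tactics stage requires litters and bear-year records")
        _log("stage tactics")
        assignments = ta.assign_tactics(litters)
        trend = ta.weaning_trend(litters)
        rep = ta.repeatability(
            litters,
            n_bootstrap=config.tactics.get("n_bootstrap", 1000),
            seed=config.seeds.get("tactics", 2),
        )
        payload = {
            "assignments": [a.__dict__ for a in assignments],
            "trend": trend.__dict__,
            "repeatability": rep.__dict__,
            "primiparity": ta.primiparity_effect(litters).__dict__,
            "consistency": ta.consistency_summary(assignments, bear_years),
        }
        p = out / "tactics.json"
        _write_json(p, payload)
        record_stage("tactics", {"tactics": p})

    if config.stages.get("rates", True):
        if bear_years is None:
            raise RuntimeError("rates stage requires bear-year records")
        _log("stage rates")
        fits["survival"] = dr.fit_survival(bear_years)
        fits["recruitment"] = dr.fit_recruitment(bear_years)
        rate_table = dr.bootstrap_rates(
            fits["survival"],
            fits["recruitment"],
            n_bootstrap=config.rates.get("n_bootstrap", 10000),
            seed=config.seeds.get("rates", 3),
        )
        payload = {
            "models": {k: _modelfit_summary(f) for k, f in fits.items()},
            "survival": rate_table.survival,
            "recruitment": rate_table.recruitment,
            "point": rate_table.point,
            "n_bootstrap": rate_table.n_bootstrap,
        }
        p = out / "rates.json"
        _write_json(p, payload)
        draws_path = out / "rate_draws.csv"
        with open(draws_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["tactic", "S1", "S2", "S3", "S4-8", "S9+", "R5-9", "R10+"])
            for tactic, draws in rate_table.draws_by_tactic.items():
                for row in draws:
                    writer.writerow([tactic] + [f"{v:.10g}" for v in row])
        record_stage("rates", {"rates": p, "rate_draws": draws_path})

    if config.stages.get("demography", True):
        if rate_table is None:
            raise RuntimeError("demography stage requires the rates stage")
        _log("stage demography")
        payload: dict = {"tactics": {}}
        for tactic in (T15, T25):
            s = rate_table.survival[tactic]
            r = rate_table.recruitment[tactic]
            matrix = md.build_matrix(
                s["1"]["mean"], s["2"]["mean"], s["3"]["mean"], s["4-8"]["mean"], s["9+"]["mean"],
                r["5-9"]["mean"], r["10+"]["mean"], tactic=tactic,
            )
            summary = md.summarize(matrix)
            payload["tactics"][tactic] = {
                "matrix": matrix.entries,
                "lambda": summary.lambda_,
                "R0": summary.R0,
                "T": summary.T,
                "stable_age": summary.w,
                "adult_fraction": summary.adult_fraction,
            }
        boot = md.bootstrap_demography(rate_table.draws_by_tactic)
        for tactic in (T15, T25):
            payload["tactics"][tactic]["ci"] = boot[tactic]["summaries"]
        payload["p_T_T25_exceeds_T15"] = boot["p_T_second_exceeds_first"]
        payload["n_draws"] = boot["n_draws"]
        p = out / "demography.json"
        _write_json(p, payload)
        record_stage("demography", {"demography": p})

    if config.stages.get("hunting", True):
        if bear_years is None or rate_table is None:
            raise RuntimeError("hunting stage requires bear-year records and rates")
        _log("stage hunting")
        index = hr.pressure_index(bear_years)
        models = hr.fit_pressure_models(
            bear_years,
            index,
            n_draws=config.hunting.get("n_draws", 1000),
            seed=config.seeds.get("hunting", 4),
        )
        grid = hr.default_pressure_grid(index, config.hunting.get("grid_points", 12))
        recruitment = {t: rate_table.point["recruitment"][t] for t in (T15, T25)}
        curves = hr.lambda_vs_pressure(models, recruitment, pressures=grid)
        payload = {
            "pressure_index": {
                str(y): {
                    "h": index.value(y),
                    "shot": index.shot[y],
                    "available": index.available[y],
                }
                for y in index.years
            },
            "cells": {
                f"{t}:{c}": {
                    k: v
                    for k, v in models.cells[(t, c)].items()
                    if k in ("tactic", "age_class", "n_obs", "flag", "intercept", "slope")
                }
                for t in (T15, T25)
                for c in AGE_CLASSES
            },
            "grid": grid,
            "lambda_quantiles": {
                t: curves["tactics"][t]["quantiles"] for t in curves["tactics"]
            },
            "skipped": curves["skipped"],
        }
        p = out / "curves.json"
        _write_json(p, payload)
        record_stage("hunting", {"curves": p})

    manifest_path = out / "manifest.json"
    _write_json(manifest_path, manifest)
    _log(f"wrote manifest with {len(manifest['stages'])} stage(s)")
    return manifest


def report(manifest: dict) -> str:
    """Human-readable markdown summary assembled from stage outputs.

    Values are read from the stage JSON files verbatim (no re-computation);
    missing stages are noted, not fatal.
    """
    if not manifest.get("stages"):
        return "# caretactics report\n\nno stages run\n"
    lines = ["# caretactics report", ""]
    outputs = manifest.get("outputs", {})

    def load(label):
        path = outputs.get(label)
        if path and Path(path).exists():
            return json.loads(Path(path).read_text())
        return None

    tactics = load("tactics")
    if tactics:
        tr = tactics["trend"]
        rep = tactics["repeatability"]
        lines += [
            "## Maternal-care tactics",
            f"- litters: {tr['n_litters']} from {tr['n_females']} females",
            f"- annual odds ratio of 2.5-year care: {tr['annual_odds_ratio']:.3f} "
            f"[{tr['ci_low']:.3f}, {tr['ci_high']:.3f}]" if tr["estimable"]
            else "- trend non-estimable",
            f"- repeatability (original scale): {rep['r_original']:.3f} "
            f"[{rep['ci_low']:.3f}, {rep['ci_high']:.3f}]",
            f"- consistent females: {tactics['consistency']['pct_consistent']:.1f}%"
            if tactics["consistency"]["pct_consistent"] is not None
            else "- consistent females: n/a",
            "",
        ]

    rates = load("rates")
    if rates:
        lines += ["## Demographic rates (bootstrap means, 95% CI)", ""]
        lines.append("| rate | 1.5-year tactic | 2.5-year tactic |")
        lines.append("|---|---|---|")
        for cls in AGE_CLASSES:
            row = [f"S_{cls}"]
            for t in (T15, T25):
                c = rates["survival"][t][cls]
                row.append(f"{c['mean']:.3f} [{c['ci_low']:.3f}, {c['ci_high']:.3f}]")
            lines.append("| " + " | ".join(row) + " |")
        row = ["R"]
        for t in (T15, T25):
            c = rates["recruitment"][t]["5-9"]
            row.append(f"{c['mean']:.3f} [{c['ci_low']:.3f}, {c['ci_high']:.3f}]")
        lines.append("| " + " | ".join(row) + " |")
        lines.append("")

    demo = load("demography")
    if demo:
        lines += ["## Tactic demography", ""]
        lines.append("| metric | 1.5-year tactic | 2.5-year tactic |")
        lines.append("|---|---|---|")
        for key, label in [
            ("lambda", "lambda"),
            ("R0", "R0"),
            ("T", "generation time (y)"),
            ("adult_fraction", "stable-age adult fraction"),
        ]:
            row = [label]
            for t in (T15, T25):
                block = demo["tactics"][t]
                ci = block["ci"][key if key != "lambda" else "lambda"]
                row.append(f"{block[key]:.3f} [{ci['ci_low']:.3f}, {ci['ci_high']:.3f}]")
            lines.append("| " + " | ".join(row) + " |")
        lines.append("")
        lines.append(
            f"P(generation time 2.5-tactic > 1.5-tactic) = {demo['p_T_T25_exceeds_T15']:.3f}"
        )
        lines.append("")

    curves = load("curves")
    if curves:
        lines += ["## Lambda vs hunting pressure (median per grid point)", ""]
        grid = curves["grid"]
        for t, q in curves["lambda_quantiles"].items():
            med = ", ".join(f"{v:.3f}" for v in q["50"])
            lines.append(f"- {t} at h = {', '.join(f'{g:.2f}' for g in grid)}:")
            lines.append(f"  lambda_50 = {med}")
        lines.append("")

    missing = [s for s in STAGES if s not in {e["stage"] for e in manifest["stages"]}]
    if missing:
        lines.append(f"_stages not run: {', '.join(missing)}_")
    return "\n".join(lines) + "\n"
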