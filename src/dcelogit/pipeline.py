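"""Configuration-driven pipeline: simulate -> fit -> WTP -> scenarios.

A YAML config declares the data source (files or a simulation block), an
ordered list of model specifications, the WTP conversion rate, and the
scenario block.  ``run_pipeline`` executes the stages in order, writes
machine-readable JSON results plus a run manifest, and is idempotent for
a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .choice_data import AttributeSchema, read_dataset, summarize, write_dataset
from .estimation import (
    FitResult,
    ModelSpec,
    fit_mixed,
    fit_mnl,
    pct_correct,
    significance_stars,
    std_errors,
)
from .scenarios import default_scenarios, build_scenario, scenario_table, simulate_scenario
from .synthetic_data import (
    default_preferences,
    default_schema,
    generate_design,
    generate_respondents,
    simulate_choices,
)
from .wtp import DEFAULT_RATE, extract_wtp_space, wtp_ratio, wtp_table

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    raw: dict
    path: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        cfg = cls(raw=yaml.safe_load(path.read_text()), path=path)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        raw = self.raw
        if "data" in raw and "simulate" in raw:
            raise ConfigError("config declares both 'data' and 'simulate'")
        if "data" not in raw and "simulate" not in raw:
            raise ConfigError("config needs a 'data' or 'simulate' block")
        if "data" in raw:
            for key in ("choices", "respondents"):
                p = raw["data"].get(key)
                if not p or not Path(p).exists():
                    raise ConfigError(f"data file for {key!r} missing: {p}")
        if raw.get("schema") and not Path(raw["schema"]).exists():
            raise ConfigError(f"schema file missing: {raw['schema']}")
        if not raw.get("models"):
            raise ConfigError("config needs a non-empty 'models' list")


def _model_spec(block: dict, seed: int) -> ModelSpec:
    return ModelSpec(
        family=block.get("family", "rpl"),
        correlated=bool(block.get("correlated", False)),
        sdc=tuple(block.get("sdc", ())),
        random_set=tuple(block["random_set"]) if block.get("random_set") else None,
        n_draws=int(block.get("n_draws", 500)),
        seed=int(block.get("seed", seed)),
        gamma_mode=block.get("gamma_mode", "free"),
        gamma_fixed=float(block.get("gamma_fixed", 0.0)),
        maxiter=int(block.get("maxiter", 1000)),
    )


def fit_to_dict(fit: FitResult) -> dict:
    """JSON-serialisable view of a FitResult."""
    p = fit.params
    out = {
        "family": fit.spec.family,
        "correlated": fit.spec.correlated,
        "sdc": list(fit.spec.sdc),
        "n_draws": fit.spec.n_draws,
        "seed": fit.spec.seed,
        "columns": list(fit.column_names),
        "beta": np.asarray(p.beta).tolist(),
        "asc": p.asc,
        "delta": None if p.delta is None else np.asarray(p.delta).tolist(),
        "chol": None if p.chol is None else np.asarray(p.chol).tolist(),
        "implied_sd": None if p.chol is None else p.implied_sd().tolist(),
        "tau": p.tau,
        "gamma": p.gamma,
        "bc": p.bc,
        "sample_mean_sigma": fit.sample_mean_sigma,
        "loglik": fit.loglik,
        "k_params": fit.k_params,
        "aic": fit.aic,
        "n_obs": fit.n_obs,
        "n_respondents": fit.n_respondents,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "message": fit.message,
        "notes": list(fit.notes),
    }
    if fit.se is not None:
        out["se"] = {k: np.asarray(v).tolist() for k, v in fit.se.items()}
        out["pvalues"] = {k: np.asarray(v).tolist() for k, v in fit.pvalues.items()}
    return out


def coefficient_table(fit: FitResult) -> str:
    """Human-readable coefficient table (coefficient, SE, SD, SE of SD,
    significance stars; legend *** p<0.01, ** p<0.05, * p<0.1)."""
    names = list(fit.column_names)
    if fit.spec.family == "gmxl_wtp":
        names = [n for n in names if n != fit.spec.price_column]
    sds = fit.params.implied_sd()
    lines = [
        f"model: {fit.spec.family}{' (correlated)' if fit.spec.correlated else ''}",
        f"{'parameter':<30}{'coef':>10}{'SE':>9}{'StdD':>9}{'SE':>9}  sig",
    ]

    def fmt(x):
        return "" if x is None else f"{x:.3f}"

    se = fit.se or {}
    pv = fit.pvalues or {}
    # "sd" standard errors align with the random-coefficient set
    sd_pos = (
        [] if fit.params.chol is None else list(np.flatnonzero(np.any(fit.params.chol != 0, axis=1)))
    )
    for pos, name in enumerate(names):
        k = fit.column_names.index(name)
        coef = fit.params.beta[k]
        s = se["beta"][pos] if "beta" in se else None
        p = pv["beta"][pos] if "beta" in pv else None
        sd = None if sds is None else sds[k]
        sd_se = None
        if "sd" in se and k in sd_pos:
            sd_se = se["sd"][sd_pos.index(k)]
        star = "" if p is None else significance_stars(float(p))
        lines.append(
            f"{name:<30}{coef:>10.3f}{fmt(s):>9}{fmt(sd):>9}{fmt(sd_se):>9}  {star}"
        )
    asc_se = se.get("asc", [None])[0] if "asc" in se else None
    asc_p = pv.get("asc", [None])[0] if "asc" in pv else None
    star = "" if asc_p is None else significance_stars(float(asc_p))
    lines.append(f"{'opt-out ASC':<30}{fit.params.asc:>10.3f}{fmt(asc_se):>9}{'':>9}{'':>9}  {star}")
    if fit.params.tau is not None:
        lines.append(f"{'tau (scale dispersion)':<30}{fit.params.tau:>10.3f}")
        lines.append(f"{'gamma (weighting)':<30}{fit.params.gamma:>10.4f}")
        lines.append(f"{'sample mean sigma':<30}{fit.sample_mean_sigma:>10.3f}")
    if fit.params.bc is not None:
        lines.append(f"{'price (pref-space form)':<30}{-fit.params.bc:>10.4f}")
        lines.append(f"{'price in WTP-space':<30}{1.0:>10.0f}")
    lines.append(
        f"LL = {fit.loglik:.1f}   K = {fit.k_params}   AIC = {fit.aic:.1f}   "
        f"N = {fit.n_respondents} respondents / {fit.n_obs} observations"
    )
    lines.append("***p < 0.01; **p < 0.05; *p < 0.1")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Execute all configured stages and write results + manifest."""
    config.validate()
    raw = config.raw
    seed = int(raw.get("seed", 0))
    out_dir = Path(output_dir or raw.get("output_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "stages": [],
        "config": raw,
    }
    bundle = {}

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append({"name": name, "t": round(time.time() - t0, 2)})

    try:
        schema = (
            AttributeSchema.from_yaml(raw["schema"]) if raw.get("schema") else default_schema()
        )
        if "data" in raw:
            stage("load")
            dataset = read_dataset(raw["data"]["choices"], raw["data"]["respondents"], schema)
        else:
            stage("simulate")
            sim = raw["simulate"] or {}
            rng = np.random.default_rng(seed)
            s_design, s_resp, s_choice = (int(s) for s in rng.integers(2**31, size=3))
            design = generate_design(
                schema,
                n_tasks=int(sim.get("n_tasks", 12)),
                n_alts=int(sim.get("n_alts", 2)),
                seed=s_design,
            )
            respondents = generate_respondents(int(sim.get("n_respondents", 537)), seed=s_resp)
            prefs = default_preferences(schema)
            dataset = simulate_choices(
                design, respondents, prefs, family=sim.get("family", "gmxl"), seed=s_choice
            )
            if sim.get("write_csv", False):
                write_dataset(dataset, out_dir / "choices.csv", out_dir / "respondents.csv")
        bundle["summary"] = summarize(dataset)

        fits = {}
        for block in raw["models"]:
            name = block.get("name", block.get("family", "model"))
            stage(f"fit:{name}")
            spec = _model_spec(block, seed)
            fit = fit_mnl(dataset, spec=spec) if spec.family == "mnl" else fit_mixed(dataset, spec)
            if block.get("std_errors", True):
                fit = std_errors(fit, dataset)
            if block.get("pct_correct", True):
                bundle.setdefault("pct_correct", {})[name] = pct_correct(fit, dataset)
            fits[name] = fit
            (out_dir / f"fit_{name}.json").write_text(json.dumps(fit_to_dict(fit), indent=1))
        bundle["fits"] = fits

        wtp_block = raw.get("wtp")
        if wtp_block:
            stage("wtp")
            rate = float(wtp_block.get("rate", DEFAULT_RATE))
            source = wtp_block.get("from") or list(fits)[-1]
            fit = fits[source]
            if fit.spec.family == "gmxl_wtp":
                estimates = extract_wtp_space(fit, rate=rate)
            else:
                estimates = [
                    wtp_ratio(fit, c, seed=seed, rate=rate)
                    for c in fit.column_names
                    if c != fit.spec.price_column
                ]
            bundle["wtp"] = estimates
            (out_dir / "wtp.json").write_text(
                json.dumps([asdict(e) for e in estimates], indent=1)
            )

        sc_block = raw.get("scenarios")
        if sc_block:
            stage("scenarios")
            source = raw.get("scenario_model") or list(fits)[0]
            fit = fits[source]
            if sc_block == "default":
                scen = default_scenarios(schema)
            else:
                scen = [
                    build_scenario(s["base"], s.get("changes", {}), s["label"], schema)
                    for s in sc_block
                ]
            n_draws = int(raw.get("scenario_draws", 2000))
            results = [
                simulate_scenario(
                    fit, s, dataset.respondents, schema, n_draws=n_draws, seed=seed
                )
                for s in scen
            ]
            bundle["scenarios"] = results
            (out_dir / "scenarios.json").write_text(
                json.dumps([asdict(r) for r in results], indent=1)
            )

        report = render_tables(bundle)
        (out_dir / "report.txt").write_text(report)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed at stage {manifest['stages'][-1]['name'] if manifest['stages'] else 'init'}: {exc}"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    bundle["manifest"] = manifest
    return bundle


def render_tables(bundle: dict) -> str:
    """Formatted report: coefficient tables, WTP table, scenario table."""
    parts = []
    if "summary" in bundle:
        parts.append("panel: " + json.dumps(bundle["summary"]))
    for name, fit in bundle.get("fits", {}).items():
        parts.append(f"== {name} ==\n{coefficient_table(fit)}")
    if bundle.get("wtp"):
        parts.append(wtp_table(bundle["wtp"]))
    if bundle.get("scenarios"):
        parts.append(scenario_table(bundle["scenarios"]))
    return "\n\n".join(parts)
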