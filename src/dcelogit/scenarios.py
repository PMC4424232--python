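"""Service-package scenario simulation.

A scenario compares a *simulated* package configuration against a *base*
configuration.  For each respondent and each fresh draw from the fitted
coefficient (and scale) distribution, both packages' systematic utilities
are computed — including SDC interactions — and the binary-logit share
Pr(sim) = e^{U_sim} / (e^{U_sim} + e^{U_base}) recorded.  The headline
statistic is 100 x (mean Pr(sim) - 0.5): positive values mean more
respondents prefer the simulated package than the base, around the 50%
indifference point.  Averaging is unconditional (population draws, not
individual-posterior coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .choice_data import AttributeSchema, SchemaError, sdc_dummies
from .estimation import FitResult, simulate_beta_i, _Layout, build_panel  # noqa: F401


@dataclass(frozen=True)
class Scenario:
    """A base-vs-simulated package comparison.

    Both configurations must assign a level to every attribute of the
    schema (price included).
    """

    label: str
    base: dict
    simulated: dict

    def validate_against(self, schema: AttributeSchema) -> None:
        for tag, cfg in (("base", self.base), ("simulated", self.simulated)):
            for a in schema.attributes:
                if a.name not in cfg:
                    raise SchemaError(f"scenario {self.label!r}: {tag} misses {a.name!r}")
            schema.code_profile(cfg)


@dataclass(frozen=True)
class ScenarioResult:
    """Choice-probability outcome of one scenario."""

    label: str
    mean_prob: float  # mean Pr(simulated)
    delta_pp: float  # 100 * (mean_prob - 0.5)
    subgroup_delta_pp: dict = field(default_factory=dict)
    mc_se: float = 0.0
    n_draws: int = 0
    seed: int = 0


def build_scenario(base: dict, changes: dict, label: str, schema: AttributeSchema | None = None) -> Scenario:
    """Simulated configuration = base overridden by ``changes``."""
    sim = dict(base)
    sim.update(changes)
    sc = Scenario(label=label, base=dict(base), simulated=sim)
    if schema is not None:
        sc.validate_against(schema)
    return sc


def choice_prob(u_sim, u_base):
    """Binary logit share Pr(sim) = e^{u_sim} / (e^{u_sim} + e^{u_base})."""
    u_sim = np.asarray(u_sim, dtype=float)
    u_base = np.asarray(u_base, dtype=float)
    if not (np.all(np.isfinite(u_sim)) and np.all(np.isfinite(u_base))):
        raise ValueError("utilities must be finite")
    d = u_sim - u_base
    out = np.empty_like(d)
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    out[~pos] = np.exp(d[~pos]) / (1.0 + np.exp(d[~pos]))
    return out if out.ndim else float(out)


_SUBGROUPS = {
    "female": ("female", 1.0),
    "male": ("female", 0.0),
    "age_15_19": ("older", 0.0),
    "age_20_24": ("older", 1.0),
    "in_relationship": ("in_relationship", 1.0),
    "single": ("in_relationship", 0.0),
}


def simulate_scenario(
    fit: FitResult,
    scenario: Scenario,
    respondents: pd.DataFrame,
    schema: AttributeSchema,
    n_draws: int = 2000,
    seed: int = 0,
    subgroups: tuple = tuple(_SUBGROUPS),
) -> ScenarioResult:
    """Mean probability of choosing the simulated package over the base.

    Fresh seeded draws from the fitted mixing/scale distribution are taken
    per respondent (coefficients include delta z_i shifts); subgroup
    results restrict the respondent set.  The Monte-Carlo standard error
    of the mean probability is estimated across draws.
    """
    if fit.spec.family == "gmxl_wtp":
        raise ValueError("scenario simulation uses a preference-space fit")
    scenario.validate_against(schema)
    dum = sdc_dummies(respondents)
    for g in subgroups:
        if g not in _SUBGROUPS:
            raise ValueError(f"unknown subgroup {g!r}")
        col, val = _SUBGROUPS[g]
        if not (dum[col] == val).any():
            raise ValueError(f"subgroup {g!r} matches zero respondents")

    x_base = schema.code_profile(scenario.base)
    x_sim = schema.code_profile(scenario.simulated)

    I = len(respondents)
    p = fit.params
    Z = (
        dum[list(fit.spec.sdc)].to_numpy(dtype=float)
        if fit.spec.sdc
        else np.zeros((I, 0))
    )
    rng = np.random.default_rng(seed)
    K = len(p.beta)

    draws = SimpleNamespace(
        v=rng.standard_normal((I, n_draws, K)),
        w=rng.standard_normal((I, n_draws)),
        n_resp=I,
        n_draws=n_draws,
        n_dims=K,
    )
    beta_i, *_ = simulate_beta_i(p, draws, Z, fit.spec.family)
    u_base = beta_i @ x_base  # (I, R)
    u_sim = beta_i @ x_sim
    pr = choice_prob(u_sim, u_base)  # (I, R)

    mean_prob = float(pr.mean())
    draw_means = pr.mean(axis=0)
    mc_se = float(draw_means.std(ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else 0.0
    sub = {}
    for g in subgroups:
        col, val = _SUBGROUPS[g]
        mask = (dum[col] == val).to_numpy()
        sub[g] = float(100.0 * (pr[mask].mean() - 0.5))
    return ScenarioResult(
        label=scenario.label,
        mean_prob=mean_prob,
        delta_pp=float(100.0 * (mean_prob - 0.5)),
        subgroup_delta_pp=sub,
        mc_se=mc_se,
        n_draws=n_draws,
        seed=seed,
    )


def default_scenarios(schema: AttributeSchema) -> list[Scenario]:
    """The sixteen service-package scenarios used in the outreach study:
    three price increases, five single-attribute changes, and eight
    multi-attribute packages."""
    full = {
        "provider_age": ">30",
        "provider_gender": "female",
        "confidentiality": "confidential",
        "hiv_services": "hct_art",
        "youth_component": "sports",
        "price": 0,
    }
    plain = dict(full, youth_component="none")  # confidential, HCT+ART, no youth add-on
    uncertain = dict(plain, confidentiality="uncertain")
    hct_only = dict(plain, hiv_services="hct_only")
    uncertain_hct = dict(uncertain, hiv_services="hct_only")

    mk = build_scenario
    return [
        mk(full, {"price": 50}, "1: price free -> 50MK", schema),
        mk(dict(full, price=50), {"price": 150}, "2: price 50 -> 150MK", schema),
        mk(dict(full, price=150), {"price": 500}, "3: price 150 -> 500MK", schema),
        mk(plain, {"youth_component": "sports"}, "4: add sports", schema),
        mk(plain, {"youth_component": "health_talk"}, "5: add health talk", schema),
        mk(uncertain, {"confidentiality": "confidential"}, "6: add confidentiality", schema),
        mk(hct_only, {"hiv_services": "hct_art"}, "7: add HIV services", schema),
        mk(plain, {"provider_age": "<30"}, "8: younger provider", schema),
        mk(
            uncertain,
            {"youth_component": "sports", "confidentiality": "confidential"},
            "9: add sports and confidentiality",
            schema,
        ),
        mk(
            uncertain,
            {"youth_component": "health_talk", "confidentiality": "confidential"},
            "10: add health talk and confidentiality",
            schema,
        ),
        mk(
            uncertain_hct,
            {"confidentiality": "confidential", "hiv_services": "hct_art"},
            "11: add confidentiality and HIV services",
            schema,
        ),
        mk(
            uncertain_hct,
            {
                "youth_component": "sports",
                "confidentiality": "confidential",
                "hiv_services": "hct_art",
            },
            "12: add sports, confidentiality and HIV services",
            schema,
        ),
        mk(
            uncertain_hct,
            {
                "youth_component": "health_talk",
                "confidentiality": "confidential",
                "hiv_services": "hct_art",
            },
            "13: add health talk, confidentiality and HIV services",
            schema,
        ),
        mk(
            uncertain,
            {
                "price": 50,
                "youth_component": "sports",
                "confidentiality": "confidential",
            },
            "14: free -> 50MK with sports and confidentiality",
            schema,
        ),
        mk(
            uncertain_hct,
            {
                "price": 50,
                "hiv_services": "hct_art",
                "confidentiality": "confidential",
            },
            "15: free -> 50MK with HIV services and confidentiality",
            schema,
        ),
        mk(
            uncertain_hct,
            {
                "price": 50,
                "youth_component": "sports",
                "hiv_services": "hct_art",
                "confidentiality": "confidential",
            },
            "16: free -> 50MK with confidentiality, sports and HIV services",
            schema,
        ),
    ]


def scenario_table(results: list[ScenarioResult], subgroups: tuple = tuple(_SUBGROUPS)) -> str:
    """Text table of scenario deltas (percentage points vs indifference),
    full sample and by subgroup."""
    head = f"{'scenario':<55}{'full':>7}" + "".join(f"{g:>16}" for g in subgroups)
    lines = [head]
    for r in results:
        row = f"{r.label:<55}{r.delta_pp:>7.1f}"
        for g in subgroups:
            row += f"{r.subgroup_delta_pp.get(g, float('nan')):>16.1f}"
        lines.append(row)
    return "\n".join(lines)
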