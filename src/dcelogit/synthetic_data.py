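"""Synthetic DCE data: designs, respondent populations, and simulated choices.

The default configuration emulates the study conditions of the Malawi
youth family-planning/HIV outreach DCE: 537 respondents each answering 12
choice tasks with two generic service alternatives plus an opt-out, the
six-attribute design (provider age, provider gender, confidentiality, HIV
service package, youth-friendly component, price in Malawi Kwacha), and
respondent socio-demographic margins matching the study sample.  Choices
are generated from a known MNL / RPL / GMXL random-utility process with
IID standard Gumbel errors, so every downstream stage can be tested
against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice_data import (
    Attribute,
    AttributeSchema,
    ChoiceDataset,
    DataValidationError,
    SchemaError,
    sdc_dummies,
)

#: Study-sample socio-demographic margins (shares of the non-base category).
DEFAULT_MARGINS = {"female": 0.498, "age_15_19": 0.607, "in_relationship": 0.643}


def default_schema() -> AttributeSchema:
    """The six-attribute outreach-service schema (8 coded design columns)."""
    return AttributeSchema(
        (
            Attribute("provider_age", "categorical", ("<30", ">30"), base_level="<30"),
            Attribute("provider_gender", "categorical", ("male", "female"), base_level="male"),
            Attribute(
                "confidentiality",
                "categorical",
                ("uncertain", "confidential"),
                base_level="uncertain",
            ),
            Attribute("hiv_services", "categorical", ("hct_only", "hct_art"), base_level="hct_only"),
            Attribute(
                "youth_component",
                "categorical",
                ("sports", "music_drama", "health_talk", "none"),
                base_level="none",
            ),
            Attribute("price", "numeric", (0, 50, 150, 500)),
        )
    )


@dataclass(frozen=True)
class TruePreferences:
    """Known data-generating parameters for the simulator.

    ``beta`` are mean utility coefficients per coded design column,
    ``chol`` the lower-triangular spread factor (Gamma) of the random
    coefficients, ``delta`` interaction coefficients per (column, SDC
    dummy), ``asc`` the opt-out alternative-specific constant, and
    ``tau``/``gamma`` the GMXL scale-dispersion and weighting parameters.
    """

    beta: np.ndarray
    chol: np.ndarray | None = None
    delta: np.ndarray | None = None
    asc: float = 0.0
    tau: float = 0.0
    gamma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.chol is not None:
            chol = np.asarray(self.chol, dtype=float)
            if chol.ndim == 1:
                chol = np.diag(chol)
            if not np.allclose(chol, np.tril(chol)):
                raise ValueError("chol must be lower triangular")
            if np.any(np.diag(chol) < 0):
                raise ValueError("chol needs a non-negative diagonal")
            object.__setattr__(self, "chol", chol)
        if self.delta is not None:
            object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")

    def validate_against(self, schema: AttributeSchema) -> None:
        K = schema.n_columns
        if self.beta.shape != (K,):
            raise ValueError(f"beta has length {len(self.beta)}, schema has {K} coded columns")
        if self.chol is not None and self.chol.shape != (K, K):
            raise ValueError("chol must be K x K")
        if self.delta is not None and self.delta.shape[0] != K:
            raise ValueError("delta must have one row per coded column")


def default_preferences(schema: AttributeSchema | None = None) -> TruePreferences:
    """Realistic GMXL truth anchored to the magnitudes estimated in the
    Malawi outreach study (preference-space GMXL with correlated normals
    approximated by a diagonal spread, full SDC interaction block)."""
    schema = schema or default_schema()
    beta = np.array([-0.228, 0.146, 2.609, 0.611, 0.952, -0.282, 0.395, -0.006])
    sd = np.array([0.198, 0.034, 2.042, 0.844, 0.655, 0.711, 0.622, 0.008])
    delta = np.array(
        [
            [0.088, -0.095, -0.070],
            [-0.098, -0.011, 0.060],
            [-0.476, -0.317, 0.850],
            [0.160, -0.285, 0.416],
            [-0.424, 0.282, -0.092],
            [0.146, -0.278, 0.212],
            [-0.220, -0.164, -0.110],
            [-0.001, 0.001, 0.002],
        ]
    )
    prefs = TruePreferences(
        beta=beta, chol=np.diag(sd), delta=delta, asc=-2.529, tau=0.997, gamma=0.0
    )
    prefs.validate_against(schema)
    return prefs


@dataclass(frozen=True)
class ChoiceDesign:
    """A fixed experimental design: ``tasks[t][j]`` is the profile (level
    map) of service alternative j in task t.  The opt-out is implicit."""

    schema: AttributeSchema
    tasks: tuple

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_alts(self) -> int:
        return len(self.tasks[0])

    def coded(self) -> np.ndarray:
        """Coded design array of shape (n_tasks, n_alts, n_columns)."""
        return np.array(
            [[self.schema.code_profile(p) for p in task] for task in self.tasks]
        )


def generate_design(
    schema: AttributeSchema | None = None,
    n_tasks: int = 12,
    n_alts: int = 2,
    seed: int = 0,
) -> ChoiceDesign:
    """Seeded level-balanced random design.

    Levels are allocated as evenly as possible over the n_tasks x n_alts
    profile slots (per-level frequencies differ by at most 1), then
    shuffled; a repair pass removes within-task duplicate profiles by
    balance-preserving swaps across tasks.  This is a randomizer, not a
    D-optimal search — D-efficiency evaluation lives in
    :mod:`dcelogit.design_efficiency`.
    """
    schema = schema or default_schema()
    if len(schema.attributes) < 2:
        raise SchemaError("design generation needs a schema with >= 2 attributes")
    if n_tasks < 1 or n_alts < 2:
        raise ValueError("need n_tasks >= 1 and n_alts >= 2")
    rng = np.random.default_rng(seed)
    n_slots = n_tasks * n_alts
    grid = {}
    for a in schema.attributes:
        reps = -(-n_slots // len(a.levels))  # ceil
        pool = np.array((list(a.levels) * reps)[:n_slots], dtype=object)
        rng.shuffle(pool)
        grid[a.name] = pool.reshape(n_tasks, n_alts)

    def profile(t, j):
        return {name: grid[name][t, j] for name in grid}

    # repair: swap one attribute value with another task until no task
    # contains two identical profiles (swaps preserve level balance)
    attr_names = [a.name for a in schema.attributes]
    for _ in range(1000):
        dup = None
        for t in range(n_tasks):
            profs = [tuple(profile(t, j).items()) for j in range(n_alts)]
            if len(set(profs)) < n_alts:
                dup = t
                break
        if dup is None:
            break
        name = attr_names[int(rng.integers(len(attr_names)))]
        t2 = int(rng.integers(n_tasks))
        j2 = int(rng.integers(n_alts))
        grid[name][dup, -1], grid[name][t2, j2] = grid[name][t2, j2], grid[name][dup, -1]
    else:  # pragma: no cover - astronomically unlikely for real schemas
        raise RuntimeError("could not remove duplicate profiles")

    tasks = tuple(
        tuple(profile(t, j) for j in range(n_alts)) for t in range(n_tasks)
    )
    return ChoiceDesign(schema=schema, tasks=tasks)


def generate_respondents(
    n: int, margins: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a respondent table with independent SDC margins.

    ``margins`` gives the probabilities of female, age 15-19, and being in
    a relationship; defaults match the study sample (49.8% / 60.7% / 64.3%).
    """
    m = dict(DEFAULT_MARGINS)
    if margins:
        m.update(margins)
    for key, p in m.items():
        if not 0.0 <= float(p) <= 1.0:
            raise ValueError(f"margin {key}={p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    female = rng.random(n) < m["female"]
    younger = rng.random(n) < m["age_15_19"]
    rel = rng.random(n) < m["in_relationship"]
    return pd.DataFrame(
        {
            "respondent_id": np.arange(1, n + 1),
            "gender": np.where(female, "female", "male"),
            "age_group": np.where(younger, "15-19", "20-24"),
            "relationship": np.where(rel, "in_relationship", "single"),
        }
    )


def draw_individual_coefficients(
    prefs: TruePreferences,
    z: np.ndarray,
    family: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one coefficient vector per respondent under the given family.

    MNL holds coefficients at the mean; RPL draws beta_i = beta + delta z_i
    + Gamma v_i; GMXL scales by sigma_i = exp(-tau^2/2 + tau w_i) with the
    gamma-weighted mixing of residual heterogeneity.
    """
    I = z.shape[0]
    K = len(prefs.beta)
    dz = z @ prefs.delta.T if prefs.delta is not None else 0.0
    if family == "mnl":
        return np.broadcast_to(prefs.beta, (I, K)).copy()
    v = rng.standard_normal((I, K))
    gv = v @ prefs.chol.T if prefs.chol is not None else np.zeros((I, K))
    if family == "rpl":
        return prefs.beta + dz + gv
    if family == "gmxl":
        w = rng.standard_normal(I)
        sigma = np.exp(-prefs.tau**2 / 2 + prefs.tau * w)[:, None]
        mix = prefs.gamma + sigma * (1 - prefs.gamma)
        return sigma * (prefs.beta + dz) + mix * gv
    raise ValueError(f"unknown family {family!r}")


def simulate_choices(
    design: ChoiceDesign,
    respondents: pd.DataFrame,
    prefs: TruePreferences,
    family: str = "rpl",
    seed: int = 0,
) -> ChoiceDataset:
    """Simulate stated choices under a known random-utility process.

    Each respondent's coefficient vector is drawn once and held fixed over
    their tasks (panel structure); independent standard Gumbel errors are
    added per alternative; the opt-out's systematic utility is the ASC.
    Separate seeded substreams drive coefficient and error draws.
    """
    prefs.validate_against(design.schema)
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_beta, rng_eps = (np.random.default_rng(s) for s in ss)

    I = len(respondents)
    T, J = design.n_tasks, design.n_alts
    z = np.nan_to_num(sdc_dummies(respondents).to_numpy(dtype=float))
    beta_i = draw_individual_coefficients(prefs, z, family, rng_beta)

    X = design.coded()  # (T, J, K)
    V = np.einsum("tjk,ik->itj", X, beta_i)
    V_full = np.concatenate([V, np.full((I, T, 1), prefs.asc)], axis=2)
    U = V_full + rng_eps.gumbel(size=(I, T, J + 1))
    chosen = U.argmax(axis=2)  # (I, T)

    # assemble the long-format table
    names = [a.name for a in design.schema]
    n_rows = I * T * (J + 1)
    rid = np.repeat(respondents["respondent_id"].to_numpy(), T * (J + 1))
    tid = np.tile(np.repeat(np.arange(1, T + 1), J + 1), I)
    aid = np.tile(np.arange(1, J + 2), I * T)
    optout = aid == J + 1
    chosen_flag = chosen[:, :, None] == (np.arange(J + 1))[None, None, :]
    obs = pd.DataFrame({"respondent_id": rid, "task_id": tid, "alt_id": aid})
    for name in names:
        vals = np.empty((T, J + 1), dtype=object)
        vals[:, J] = ""
        for t in range(T):
            for j in range(J):
                vals[t, j] = design.tasks[t][j][name]
        obs[name] = np.tile(vals.reshape(-1), I)
    obs["chosen"] = chosen_flag.reshape(-1)
    obs["optout"] = np.tile(optout[: T * (J + 1)], I)

    coded = np.zeros((n_rows, design.schema.n_columns))
    X_opt = np.concatenate([X, np.zeros((T, 1, X.shape[2]))], axis=1)  # (T, J+1, K)
    coded[:] = np.tile(X_opt.reshape(T * (J + 1), -1), (I, 1))
    return ChoiceDataset(
        schema=design.schema, obs=obs, respondents=respondents, coded=coded
    )


def simulate_default_panel(
    n_respondents: int = 537,
    n_tasks: int = 12,
    family: str = "gmxl",
    prefs: TruePreferences | None = None,
    seed: int = 0,
) -> ChoiceDataset:
    """The full synthetic default: 537 respondents x 12 tasks x (2 services
    + opt-out) under the study-anchored preference process."""
    schema = default_schema()
    prefs = prefs or default_preferences(schema)
    s_design, s_resp, s_choice = np.random.default_rng(seed).integers(2**31, size=3)
    design = generate_design(schema, n_tasks=n_tasks, seed=int(s_design))
    respondents = generate_respondents(n_respondents, seed=int(s_resp))
    return simulate_choices(design, respondents, prefs, family=family, seed=int(s_choice))
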