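"""Long-format stated-choice data: attribute schema, coding, validation, I/O.

The canonical representation is *long format*: one row per respondent x
choice task x alternative.  Categorical service attributes are effects
coded (base level -> -1), price enters as its raw monetary value, and
respondent socio-demographic characteristics (SDCs) are dummy coded.
Opt-out alternatives carry an all-zero attribute vector plus a flag; their
systematic utility is an alternative-specific constant handled by the
estimation layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: SDC dummy names with base categories male / 15-19 / single (coded 0).
SDC_DUMMIES = ("female", "older", "in_relationship")

_SDC_LEVELS = {
    "gender": ("male", "female"),
    "age_group": ("15-19", "20-24"),
    "relationship": ("single", "in_relationship"),
}


class SchemaError(ValueError):
    """Raised for ill-formed attribute schemas or unknown levels."""


class DataValidationError(ValueError):
    """Raised when a choice dataset violates a structural invariant."""


def _norm(label: str) -> str:
    """Normalise a level label: trim, lower-case, unify dash characters."""
    return str(label).strip().lower().replace("–", "-").replace("—", "-")


@dataclass(frozen=True)
class Attribute:
    """One attribute of the choice design.

    Categorical attributes with L levels map to L-1 effects-coded columns
    relative to ``base_level``; numeric attributes (price) map to a single
    column holding the raw value.
    """

    name: str
    kind: str  # "categorical" | "numeric"
    levels: tuple
    base_level: str | None = None

    def __post_init__(self):
        if self.kind not in ("categorical", "numeric"):
            raise SchemaError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise SchemaError(f"attribute {self.name!r}: needs >= 2 levels")
            if self.base_level is None:
                raise SchemaError(f"attribute {self.name!r}: categorical needs a base level")
            if self._match(self.base_level) is None:
                raise SchemaError(
                    f"attribute {self.name!r}: base level {self.base_level!r} not in levels"
                )
        else:
            if any(float(v) < 0 for v in self.levels):
                raise SchemaError(f"attribute {self.name!r}: negative numeric level")

    def _match(self, level) -> int | None:
        """Index of ``level`` in the level list (case/whitespace-insensitive)."""
        if self.kind == "numeric":
            try:
                v = float(level)
            except (TypeError, ValueError):
                return None
            for i, lv in enumerate(self.levels):
                if float(lv) == v:
                    return i
            return None
        target = _norm(level)
        for i, lv in enumerate(self.levels):
            if _norm(lv) == target:
                return i
        return None

    @property
    def n_columns(self) -> int:
        return len(self.levels) - 1 if self.kind == "categorical" else 1

    @property
    def column_names(self) -> list[str]:
        if self.kind == "numeric":
            return [self.name]
        non_base = [lv for lv in self.levels if _norm(lv) != _norm(self.base_level)]
        if len(non_base) == 1:
            return [self.name]
        return [f"{self.name}:{lv}" for lv in non_base]

    @property
    def non_base_levels(self) -> list:
        return [lv for lv in self.levels if _norm(lv) != _norm(self.base_level)]


def effects_code(level, attribute: Attribute) -> np.ndarray:
    """Effects-code one level of a categorical attribute.

    The base level maps to -1 in every column; non-base level m maps to 1
    in column m and 0 elsewhere.  Two-level attributes reduce to a single
    +-1 column.
    """
    if attribute.kind != "categorical":
        raise SchemaError(f"effects_code applies to categorical attributes, not {attribute.name!r}")
    idx = attribute._match(level)
    if idx is None:
        raise SchemaError(f"attribute {attribute.name!r}: unknown level {level!r}")
    cols = attribute.n_columns
    if _norm(attribute.levels[idx]) == _norm(attribute.base_level):
        return -np.ones(cols)
    out = np.zeros(cols)
    pos = attribute.non_base_levels
    out[pos.index(attribute.levels[idx])] = 1.0
    return out


def code_price(level) -> float:
    """Price is coded as its raw value in Malawi Kwacha (no rescaling)."""
    v = float(level)
    if v < 0:
        raise SchemaError(f"negative price {level!r}")
    return v


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered attribute list defining the coded design matrix."""

    attributes: tuple[Attribute, ...]

    def __post_init__(self):
        if len({a.name for a in self.attributes}) != len(self.attributes):
            raise SchemaError("duplicate attribute names")

    def __iter__(self):
        return iter(self.attributes)

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def n_columns(self) -> int:
        return sum(a.n_columns for a in self.attributes)

    @property
    def column_names(self) -> list[str]:
        out: list[str] = []
        for a in self.attributes:
            out.extend(a.column_names)
        return out

    def code_profile(self, profile: Mapping) -> np.ndarray:
        """Code a {attribute name: level} mapping into the design vector."""
        parts = []
        for a in self.attributes:
            if a.name not in profile:
                raise SchemaError(f"profile missing attribute {a.name!r}")
            if a.kind == "categorical":
                parts.append(effects_code(profile[a.name], a))
            else:
                parts.append(np.array([code_price(profile[a.name])]))
        return np.concatenate(parts)

    def decode_vector(self, vector: Sequence[float]) -> dict:
        """Invert :meth:`code_profile` (exact match required)."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_columns,):
            raise SchemaError(f"expected a vector of length {self.n_columns}")
        out, i = {}, 0
        for a in self.attributes:
            chunk = vector[i : i + a.n_columns]
            i += a.n_columns
            if a.kind == "numeric":
                out[a.name] = float(chunk[0])
                continue
            for lv in a.levels:
                if np.array_equal(effects_code(lv, a), chunk):
                    out[a.name] = lv
                    break
            else:
                raise SchemaError(f"attribute {a.name!r}: cannot decode {chunk!r}")
        return out

    def to_yaml(self, path) -> None:
        doc = {
            "attributes": [
                {
                    "name": a.name,
                    "kind": a.kind,
                    "levels": list(a.levels),
                    **({"base_level": a.base_level} if a.base_level else {}),
                }
                for a in self.attributes
            ]
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AttributeSchema":
        doc = yaml.safe_load(Path(path).read_text())
        attrs = tuple(
            Attribute(
                name=d["name"],
                kind=d["kind"],
                levels=tuple(d["levels"]),
                base_level=d.get("base_level"),
            )
            for d in doc["attributes"]
        )
        return cls(attrs)


def sdc_dummies(respondents: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code respondent SDCs (base categories male, 15-19, single -> 0).

    Returns a DataFrame indexed by respondent_id with columns
    ``female``, ``older``, ``in_relationship``; missing SDC values become NaN.
    """
    req = ["respondent_id", "gender", "age_group", "relationship"]
    missing = [c for c in req if c not in respondents.columns]
    if missing:
        raise DataValidationError(f"respondent table missing columns {missing}")

    def dummy(col, nonbase):
        vals = respondents[col].map(lambda v: _norm(v) if pd.notna(v) else None)
        known = set(map(_norm, _SDC_LEVELS[col]))
        bad = sorted(set(v for v in vals.dropna()) - known)
        if bad:
            raise DataValidationError(f"unknown {col} values {bad}")
        return vals.map(lambda v: np.nan if v is None else float(v == _norm(nonbase)))

    out = pd.DataFrame(
        {
            "female": dummy("gender", "female"),
            "older": dummy("age_group", "20-24"),
            "in_relationship": dummy("relationship", "in_relationship"),
        }
    )
    out.index = pd.Index(respondents["respondent_id"], name="respondent_id")
    return out


@dataclass
class ChoiceDataset:
    """Long-format panel of coded choice observations.

    ``obs`` has one row per (respondent, task, alternative) with raw level
    columns plus ``chosen`` and ``optout`` flags; ``coded`` is the aligned
    effects/numeric design matrix (all-zero rows for the opt-out).
    Interaction columns, when built, live in ``interactions`` and are kept
    separate from the design columns.
    """

    schema: AttributeSchema
    obs: pd.DataFrame
    respondents: pd.DataFrame
    coded: np.ndarray = field(default=None, repr=False)
    interactions: np.ndarray | None = field(default=None, repr=False)
    interaction_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.obs = self.obs.reset_index(drop=True)
        if self.coded is None:
            self.coded = self._code_rows()
        self.validate()

    # -- construction helpers -------------------------------------------------

    def _code_rows(self) -> np.ndarray:
        K = self.schema.n_columns
        coded = np.zeros((len(self.obs), K))
        service = ~self.obs["optout"].astype(bool).to_numpy()
        names = [a.name for a in self.schema]
        missing = [n for n in names if n not in self.obs.columns]
        if missing:
            raise DataValidationError(f"choice table missing attribute columns {missing}")
        for i in np.flatnonzero(service):
            row = self.obs.iloc[i]
            try:
                coded[i] = self.schema.code_profile({n: row[n] for n in names})
            except SchemaError as exc:
                raise DataValidationError(f"row {i}: {exc}") from exc
        return coded

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        obs = self.obs
        for col in ("respondent_id", "task_id", "alt_id", "chosen", "optout"):
            if col not in obs.columns:
                raise DataValidationError(f"choice table missing column {col!r}")
        grp = obs.groupby(["respondent_id", "task_id"], sort=False)
        n_chosen = grp["chosen"].sum()
        bad = n_chosen[n_chosen != 1]
        if len(bad):
            raise DataValidationError(
                f"each task needs exactly one chosen alternative; offending tasks: "
                f"{list(bad.index[:5])}"
            )
        sizes = grp.size()
        if sizes.nunique() > 1:
            raise DataValidationError(
                f"ragged tasks: alternative counts {sorted(sizes.unique())}; "
                f"first offending task {sizes.index[sizes != sizes.iloc[0]][0]}"
            )
        optout_rows = obs["optout"].astype(bool).to_numpy()
        if np.any(self.coded[optout_rows] != 0):
            raise DataValidationError("opt-out rows must carry an all-zero attribute vector")
        ids_obs = set(obs["respondent_id"])
        ids_resp = set(self.respondents["respondent_id"])
        if not ids_obs <= ids_resp:
            raise DataValidationError(
                f"respondents missing from respondent table: {sorted(ids_obs - ids_resp)[:5]}"
            )

    # -- basic accessors ------------------------------------------------------

    @property
    def respondent_ids(self) -> list:
        return list(pd.unique(self.obs["respondent_id"]))

    @property
    def n_respondents(self) -> int:
        return self.obs["respondent_id"].nunique()

    @property
    def n_tasks(self) -> int:
        """Task-level observation count (respondent-task pairs)."""
        return self.obs.groupby(["respondent_id", "task_id"], sort=False).ngroups

    @property
    def n_alternatives(self) -> int:
        return int(self.obs.groupby(["respondent_id", "task_id"], sort=False).size().iloc[0])

    def design_matrix(self) -> np.ndarray:
        """Design columns plus, when built, interaction columns."""
        if self.interactions is None:
            return self.coded
        return np.hstack([self.coded, self.interactions])

    def equals(self, other: "ChoiceDataset") -> bool:
        a = self.obs[["respondent_id", "task_id", "alt_id", "chosen", "optout"]]
        b = other.obs[["respondent_id", "task_id", "alt_id", "chosen", "optout"]]
        return (
            a.reset_index(drop=True).equals(b.reset_index(drop=True))
            and np.allclose(self.coded, other.coded)
            and self.respondents.reset_index(drop=True).equals(
                other.respondents.reset_index(drop=True)
            )
        )


def build_interactions(
    dataset: ChoiceDataset, sdc_vars: Sequence[str] = SDC_DUMMIES
) -> ChoiceDataset:
    """Append design-column x SDC-dummy product columns.

    With the default 8 design columns and 3 SDC dummies this yields 24
    interaction columns.  Respondents with a missing value on any SDC in the
    active set are dropped with a logged count.
    """
    unknown = [v for v in sdc_vars if v not in SDC_DUMMIES]
    if unknown:
        raise DataValidationError(f"unknown SDC dummies {unknown}; available: {SDC_DUMMIES}")
    dum = sdc_dummies(dataset.respondents)[list(sdc_vars)]
    incomplete = dum.index[dum.isna().any(axis=1)]
    obs, coded, respondents = dataset.obs, dataset.coded, dataset.respondents
    if len(incomplete):
        logger.warning(
            "dropping %d respondent(s) with missing SDC values: %s",
            len(incomplete),
            list(incomplete[:10]),
        )
        keep = ~obs["respondent_id"].isin(incomplete).to_numpy()
        obs = obs[keep].reset_index(drop=True)
        coded = coded[keep]
        respondents = respondents[~respondents["respondent_id"].isin(incomplete)].reset_index(
            drop=True
        )
        dum = dum.drop(index=incomplete)
    z = dum.loc[obs["respondent_id"]].to_numpy()  # (rows, M)
    inter = coded[:, :, None] * z[:, None, :]  # (rows, K, M)
    names = [
        f"{col}:{sdc}" for col in dataset.schema.column_names for sdc in sdc_vars
    ]
    return ChoiceDataset(
        schema=dataset.schema,
        obs=obs,
        respondents=respondents,
        coded=coded,
        interactions=inter.reshape(len(obs), -1),
        interaction_names=names,
    )


def summarize(dataset: ChoiceDataset) -> dict:
    """Panel geometry summary (task-level observation count as reported
    in model-fit tables: respondents x tasks for a complete panel)."""
    return {
        "n_respondents": dataset.n_respondents,
        "n_task_observations": dataset.n_tasks,
        "n_rows": len(dataset.obs),
        "n_alternatives": dataset.n_alternatives,
        "n_design_columns": dataset.schema.n_columns,
        "n_interaction_columns": len(dataset.interaction_names),
    }


# -- delimited-text I/O -------------------------------------------------------


def write_dataset(dataset: ChoiceDataset, choice_path, respondent_path) -> None:
    """Write the CSV pair (choice rows + respondent table)."""
    cols = ["respondent_id", "task_id", "alt_id"] + [a.name for a in dataset.schema] + [
        "chosen",
        "optout",
    ]
    out = dataset.obs.copy()
    out["chosen"] = out["chosen"].astype(int)
    out["optout"] = out["optout"].astype(int)
    out[cols].to_csv(choice_path, index=False)
    dataset.respondents.to_csv(respondent_path, index=False)


def read_dataset(choice_path, respondent_path, schema: AttributeSchema) -> ChoiceDataset:
    """Read and validate the CSV pair written by :func:`write_dataset`."""
    obs = pd.read_csv(choice_path)
    respondents = pd.read_csv(respondent_path)
    for col in ("chosen", "optout"):
        if col in obs.columns:
            obs[col] = obs[col].astype(bool)
    return ChoiceDataset(schema=schema, obs=obs, respondents=respondents)
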