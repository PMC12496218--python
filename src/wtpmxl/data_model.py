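"""Domain types and I/O for discrete-choice-experiment panels.

The study design this package targets is a stated-preference survey on
landscape rewilding: each respondent faces a sequence of choice cards, each
offering two rewilding *program* alternatives and a no-program *status quo*
(SQ).  Programs are described by six attributes — four landscape gradients
(forest, river, agriculture, connectivity), the presence of large carnivores,
and the presence of large herbivores — plus an annual tax (EUR/year).

Attribute coding conventions
----------------------------
* Landscape gradients have ordered levels coded ``1..4`` and enter the
  utility as ``log(code)``, so the SQ (lowest level, code 1) contributes 0
  and successive improvements carry diminishing marginal utility.
* Large carnivores: ``none -> 0``, ``just lynx -> 1``, ``just wolf -> 1``
  (the two single-species levels are pooled), ``both -> 2``; the coefficient
  is per pooled level.
* Large herbivores: ``none -> 0``, ``elk -> 1``, ``bison -> 2``,
  ``both -> 3``; linear in the code.
* Cost is continuous EUR/year and passes through unchanged; the SQ costs 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "DesignSpec",
    "ChoiceDataset",
    "CovariateMatrix",
    "PartyMeta",
    "SchemaError",
    "default_design",
    "encode_attributes",
    "read_choice_table",
    "write_choice_table",
    "read_covariate_table",
    "write_covariate_table",
    "clean_respondents",
]

#: canonical choice-table column order for the default rewilding design
CHOICE_COLUMNS = [
    "respondent_id", "task", "alt", "is_sq",
    "forest", "river", "agriculture", "connectivity",
    "carnivores", "herbivores", "cost_eur", "chosen",
]


def choice_columns(design: "DesignSpec") -> list[str]:
    """Column order of the long-format choice table for a given design."""
    return (["respondent_id", "task", "alt", "is_sq"]
            + [a.name for a in design.attributes if a.kind != "cost"]
            + ["cost_eur", "chosen"])

#: respondent-covariate columns (plus the categorical voting / region labels)
COVARIATE_COLUMNS = [
    "respondent_id", "log_distance", "age", "male", "city_size",
    "income", "education", "voting", "region",
]


class SchemaError(ValueError):
    """Raised when an input table violates the declared design contract."""


@dataclass(frozen=True)
class AttributeSpec:
    """One choice attribute: its kind, its ordered levels, and their codes.

    ``kind`` is one of ``log_level`` (enters utility as log(code), codes
    start at 1), ``linear_count`` (enters as the code itself, nonnegative
    integers), ``dummy`` (0/1) or ``cost`` (continuous EUR, no level codes).
    """

    name: str
    kind: str
    level_labels: tuple[str, ...] = ()
    level_codes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {"log_level", "linear_count", "dummy", "cost"}:
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "cost":
            if self.level_codes:
                raise ValueError("a cost attribute is continuous and has no level codes")
            return
        if len(self.level_labels) != len(self.level_codes):
            raise ValueError(f"{self.name}: labels and codes differ in length")
        codes = np.asarray(self.level_codes, dtype=float)
        if np.any(np.diff(codes) < 0):
            raise ValueError(f"{self.name}: level codes must be nondecreasing")
        if self.kind == "log_level" and codes[0] != 1:
            raise ValueError(f"{self.name}: log-level codes must start at 1")
        if self.kind == "linear_count" and (np.any(codes < 0) or np.any(codes != np.round(codes))):
            raise ValueError(f"{self.name}: linear counts must be nonnegative integers")

    def encode(self, label: str) -> float:
        """Map a raw level label to its model encoding."""
        try:
            code = self.level_codes[self.level_labels.index(str(label))]
        except ValueError:
            raise SchemaError(
                f"unknown level {label!r} for attribute {self.name!r}"
            ) from None
        return float(np.log(code)) if self.kind == "log_level" else float(code)


@dataclass(frozen=True)
class DesignSpec:
    """The experimental design: attributes, tasks per respondent, alternatives."""

    attributes: tuple[AttributeSpec, ...]
    n_tasks_per_respondent: int = 12
    n_program_alternatives: int = 2
    has_status_quo: bool = True
    cost_levels: tuple[float, ...] = (10.0, 25.0, 50.0, 100.0, 200.0)

    def __post_init__(self) -> None:
        if self.n_tasks_per_respondent < 1:
            raise ValueError("need at least one task per respondent")
        n_cost = sum(a.kind == "cost" for a in self.attributes)
        if n_cost != 1:
            raise ValueError(f"exactly one cost attribute required, got {n_cost}")

    @property
    def non_cost_attributes(self) -> tuple[AttributeSpec, ...]:
        return tuple(a for a in self.attributes if a.kind != "cost")

    @property
    def cost_attribute(self) -> AttributeSpec:
        return next(a for a in self.attributes if a.kind == "cost")

    @property
    def n_alternatives(self) -> int:
        return self.n_program_alternatives + int(self.has_status_quo)

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.non_cost_attributes]

    def sq_encoding(self) -> dict[str, float]:
        """Encoded attribute values carried by the status-quo alternative."""
        out: dict[str, float] = {}
        for a in self.non_cost_attributes:
            out[a.name] = 0.0  # log(1) = 0 for log_level; count 0 otherwise
        return out


def default_design(
    n_tasks: int = 12,
    cost_levels: Sequence[float] = (10.0, 25.0, 50.0, 100.0, 200.0),
) -> DesignSpec:
    """The rewilding design: four 4-level landscape gradients (log-coded),
    pooled carnivore presence (0/1/1/2), herbivore presence (0/1/2/3), and an
    annual tax, with two programs plus the status quo per card."""
    landscape = lambda name: AttributeSpec(
        name, "log_level",
        ("level 1", "level 2", "level 3", "level 4"), (1, 2, 3, 4),
    )
    attrs = (
        landscape("forest"),
        landscape("river"),
        landscape("agriculture"),
        landscape("connectivity"),
        AttributeSpec("carnivores", "linear_count",
                      ("none", "just lynx", "just wolf", "both"), (0, 1, 1, 2)),
        AttributeSpec("herbivores", "linear_count",
                      ("none", "elk", "bison", "both"), (0, 1, 2, 3)),
        AttributeSpec("cost_eur", "cost"),
    )
    return DesignSpec(attributes=attrs, n_tasks_per_respondent=n_tasks,
                      cost_levels=tuple(float(c) for c in cost_levels))


@dataclass
class ChoiceDataset:
    """Long-format choice panel: one row per (respondent, task, alternative).

    ``table`` holds encoded attribute values (log-transformed for log-level
    attributes), the SQ dummy, cost in EUR and the 0/1 chosen flag.  The
    status quo, when present, is always alternative 0.
    """

    table: pd.DataFrame
    design: DesignSpec

    def __post_init__(self) -> None:
        missing = [c for c in choice_columns(self.design)
                   if c not in self.table.columns]
        if missing:
            raise SchemaError(f"choice table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    # -- validation ---------------------------------------------------------

    def validate(self, require_chosen: bool = True) -> None:
        t = self.table
        dup = t.duplicated(["respondent_id", "task", "alt"])
        if dup.any():
            row = t.loc[dup.idxmax()]
            raise SchemaError(
                f"duplicate (respondent, task, alt) key "
                f"({row.respondent_id}, {row.task}, {row.alt})"
            )
        counts = t.groupby("respondent_id")["task"].nunique()
        expect = self.design.n_tasks_per_respondent
        bad = counts[counts != expect]
        if len(bad):
            raise SchemaError(
                f"respondent {bad.index[0]} has {bad.iloc[0]} tasks, expected {expect}"
            )
        if require_chosen:
            per_task = t.groupby(["respondent_id", "task"])["chosen"].sum()
            off = per_task[per_task != 1]
            if len(off):
                rid, task = off.index[0]
                raise SchemaError(
                    f"task {task} of respondent {rid} has {off.iloc[0]} chosen "
                    "alternatives (exactly 1 required)"
                )

    # -- accessors ----------------------------------------------------------

    @property
    def respondent_ids(self) -> np.ndarray:
        return self.table["respondent_id"].unique()

    @property
    def n_respondents(self) -> int:
        return self.table["respondent_id"].nunique()

    def to_arrays(self) -> "ChoiceArrays":
        """Rectangular numpy views used by the likelihood code."""
        return ChoiceArrays.from_dataset(self)

    def subset(self, respondent_ids: Sequence) -> "ChoiceDataset":
        keep = self.table["respondent_id"].isin(respondent_ids)
        return ChoiceDataset(self.table.loc[keep].copy(), self.design)


@dataclass
class ChoiceArrays:
    """Dense (N, T, A) tensors backing the likelihood: attribute matrix X
    of shape (N, T, A, K) in the order [SQ dummy, *design attributes*],
    cost (N, T, A), and chosen alternative index (N, T)."""

    x: np.ndarray
    cost: np.ndarray
    chosen: np.ndarray
    respondent_ids: np.ndarray
    coef_names: list[str]

    @classmethod
    def from_dataset(cls, ds: ChoiceDataset) -> "ChoiceArrays":
        t = ds.table.sort_values(["respondent_id", "task", "alt"], kind="stable")
        ids = t["respondent_id"].unique()
        n, T = len(ids), ds.design.n_tasks_per_respondent
        A = ds.design.n_alternatives
        if len(t) != n * T * A:
            raise SchemaError(
                f"expected {n * T * A} rows for a rectangular panel, got {len(t)}"
            )
        names = ds.design.attribute_names
        k = 1 + len(names)
        x = np.empty((n, T, A, k))
        x[..., 0] = t["is_sq"].to_numpy(float).reshape(n, T, A)
        for j, name in enumerate(names, start=1):
            x[..., j] = t[name].to_numpy(float).reshape(n, T, A)
        cost = t["cost_eur"].to_numpy(float).reshape(n, T, A)
        ch = t["chosen"].to_numpy(float).reshape(n, T, A)
        chosen = ch.argmax(axis=2)
        return cls(x=x, cost=cost, chosen=chosen, respondent_ids=ids,
                   coef_names=["asc_sq"] + names)


@dataclass
class CovariateMatrix:
    """Respondent-level covariates with declared categorical baselines.

    ``table`` is keyed by ``respondent_id`` and carries the continuous /
    ordinal columns plus the raw ``voting`` and ``region`` labels; encoding
    into a shift-parameterized design matrix (baseline level omitted) is done
    by :meth:`encode`.
    """

    table: pd.DataFrame
    baseline_party: str | None = None
    baseline_region: str | None = None
    party_levels: tuple[str, ...] | None = None
    region_levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"covariate table missing columns: {missing}")
        if self.table["respondent_id"].duplicated().any():
            raise SchemaError("duplicate respondent_id in covariate table")
        self.table = self.table.reset_index(drop=True)
        if self.baseline_party is None:
            self.baseline_party = self.table["voting"].mode().iloc[0]
        if self.baseline_region is None:
            self.baseline_region = self.table["region"].mode().iloc[0]
        if self.party_levels is None:
            self.party_levels = tuple(sorted(self.table["voting"].unique()))
        if self.region_levels is None:
            self.region_levels = tuple(sorted(self.table["region"].unique()))

    @property
    def respondent_ids(self) -> np.ndarray:
        return self.table["respondent_id"].to_numpy()

    def check_matches(self, ds: ChoiceDataset) -> None:
        want = set(ds.respondent_ids)
        have = set(self.respondent_ids)
        if want != have:
            raise SchemaError(
                f"covariates and choice data disagree on respondents "
                f"({len(want - have)} missing, {len(have - want)} extra)"
            )

    def encode(
        self, columns: Sequence[str] | None = None
    ) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
        """Build the design matrix X_n.

        Returns ``(X, names, groups)`` where categorical columns (``voting``,
        ``region``) are one-hot encoded with the declared baseline level
        omitted, and ``groups`` maps each requested covariate to its column
        indices in X (categoricals span several).
        """
        if columns is None:
            columns = ["log_distance", "age", "male", "city_size",
                       "income", "education", "voting", "region"]
        t = self.table.sort_values("respondent_id", kind="stable")
        blocks: list[np.ndarray] = []
        names: list[str] = []
        groups: dict[str, list[int]] = {}
        for col in columns:
            start = len(names)
            if col == "voting":
                levels = [p for p in sorted(self.party_levels)
                          if p != self.baseline_party]
                for p in levels:
                    blocks.append((t["voting"] == p).to_numpy(float))
                    names.append(f"voting[{p}]")
            elif col == "region":
                levels = [r for r in sorted(self.region_levels)
                          if r != self.baseline_region]
                for r in levels:
                    blocks.append((t["region"] == r).to_numpy(float))
                    names.append(f"region[{r}]")
            else:
                if col not in t.columns:
                    raise SchemaError(f"unknown covariate column {col!r}")
                blocks.append(t[col].to_numpy(float))
                names.append(col)
            groups[col] = list(range(start, len(names)))
        x = np.column_stack(blocks) if blocks else np.empty((len(t), 0))
        return x, names, groups


@dataclass(frozen=True)
class PartyMeta:
    """Political-party metadata: two-axis map coordinates and sample share."""

    party: str
    country: str
    econ_lr: float        # economic left-right axis
    eu_position: float    # against-vs-favor EU integration axis
    share: float

    @staticmethod
    def validate_shares(parties: Sequence["PartyMeta"]) -> None:
        by_country: dict[str, float] = {}
        for p in parties:
            by_country[p.country] = by_country.get(p.country, 0.0) + p.share
        for country, s in by_country.items():
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"party shares for {country} sum to {s}, not 1")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def encode_attributes(raw_levels: pd.DataFrame, design: DesignSpec) -> ChoiceDataset:
    """Encode a raw long-format table of level *labels* into model space.

    ``raw_levels`` must carry the key columns (respondent_id, task, alt,
    is_sq, chosen), one label column per non-cost attribute, and the numeric
    cost column.  Log-level attributes become ``log(code)``, count attributes
    become their code, cost passes through in EUR.
    """
    required = ["respondent_id", "task", "alt", "is_sq", "chosen"]
    missing = [c for c in required if c not in raw_levels.columns]
    if missing:
        raise SchemaError(f"raw table missing columns: {missing}")
    if raw_levels["chosen"].isna().any():
        raise SchemaError("missing chosen flag")
    out = raw_levels[required].copy()
    for a in design.non_cost_attributes:
        if a.name not in raw_levels.columns:
            raise SchemaError(f"raw table missing attribute column {a.name!r}")
        out[a.name] = [a.encode(v) for v in raw_levels[a.name]]
    cost_col = design.cost_attribute.name
    if cost_col not in raw_levels.columns:
        raise SchemaError(f"raw table missing cost column {cost_col!r}")
    cost = pd.to_numeric(raw_levels[cost_col], errors="raise")
    out["cost_eur"] = cost.astype(float)
    ds = ChoiceDataset(out[choice_columns(design)], design)
    ds.validate()
    return ds


def write_choice_table(ds: ChoiceDataset, path: str | Path) -> None:
    ds.table[choice_columns(ds.design)].to_csv(path, index=False)


def read_choice_table(
    path: str | Path,
    design: DesignSpec,
    covariate_path: str | Path | None = None,
) -> ChoiceDataset | tuple[ChoiceDataset, CovariateMatrix]:
    """Read an encoded choice CSV (and optionally its covariate CSV),
    validating the panel invariants of both."""
    t = pd.read_csv(path)
    ds = ChoiceDataset(t, design)
    ds.validate()
    if covariate_path is None:
        return ds
    cov = read_covariate_table(covariate_path)
    cov.check_matches(ds)
    return ds, cov


def write_covariate_table(cov: CovariateMatrix, path: str | Path) -> None:
    cov.table[COVARIATE_COLUMNS].to_csv(path, index=False)


def read_covariate_table(
    path: str | Path,
    baseline_party: str | None = None,
    baseline_region: str | None = None,
) -> CovariateMatrix:
    return CovariateMatrix(pd.read_csv(path), baseline_party, baseline_region)


def clean_respondents(
    dataset: ChoiceDataset,
    durations: Mapping,
    qc_flags: Mapping,
    protest_flags: Mapping | None = None,
) -> tuple[ChoiceDataset, pd.DataFrame]:
    """Drop speeders, quality-control failures, and protest responders.

    A *speeder* completed the survey in under half the median completion
    time.  ``qc_flags`` maps respondent id to True when the respondent
    *passed* quality control; ``protest_flags`` (optional) maps to True for
    identified protest responses.  Returns the retained dataset and a
    removal log with one row per dropped respondent and the reasons.
    """
    ids = list(dataset.respondent_ids)
    for rid in ids:
        if rid not in durations:
            raise SchemaError(f"no duration recorded for respondent {rid}")
        if rid not in qc_flags:
            raise SchemaError(f"no QC flag recorded for respondent {rid}")
    dur = np.asarray([float(durations[r]) for r in ids])
    median = float(np.median(dur))
    records = []
    kept = []
    for rid, d in zip(ids, dur):
        reasons = []
        if d < 0.5 * median:
            reasons.append("speeder")
        if not qc_flags[rid]:
            reasons.append("qc_fail")
        if protest_flags is not None and protest_flags.get(rid, False):
            reasons.append("protest")
        if reasons:
            records.append({"respondent_id": rid, "duration_s": d,
                            "reasons": "+".join(reasons)})
        else:
            kept.append(rid)
    if not kept:
        raise SchemaError("no respondents remain after cleaning")
    log = pd.DataFrame(records, columns=["respondent_id", "duration_s", "reasons"])
    return dataset.subset(kept), log
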