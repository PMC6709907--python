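"""Tidy measurement tables and study designs.

The single input currency of the pipeline is a :class:`MeasurementTable`: a
tidy table of either positive continuous responses (bone or expression-zone
lengths, qPCR relative quantities) or labelled/total cell counts (BrdU), with
categorical grouping columns (genotype, litter, animal, batch, region,
treatment, stage).  A :class:`StudyDesign` states which noise family to use,
which factors are effects of interest, and which factors enter as group
intercepts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FACTOR_COLUMNS",
    "MeasurementTable",
    "StudyDesign",
    "ValidationReport",
    "load_measurements",
    "save_measurements",
    "validate_against_design",
    "SchemaError",
    "RecordError",
]

#: Categorical columns a table may carry, in canonical order.
FACTOR_COLUMNS = ("genotype", "litter", "animal", "batch", "region", "treatment", "stage")

#: Factors with a conventional reference level: forced to be the reference
#: (first) level whenever present, so effect signs read mutant-vs-control and
#: treated-vs-vehicle.
PREFERRED_REFERENCE = {"genotype": "control", "treatment": "vehicle"}

GENOTYPE_LEVELS = ("control", "het", "hom")
TREATMENT_LEVELS = ("vehicle", "purmorphamine")


class SchemaError(ValueError):
    """A required column is missing or the file does not match the schema."""


class RecordError(ValueError):
    """A row violates a record invariant; the message names the row."""


def _ordered_levels(column: str, values) -> list:
    """Factor levels in first-appearance order, preferred reference first."""
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    pref = PREFERRED_REFERENCE.get(column)
    if pref is not None and pref in seen:
        seen.remove(pref)
        seen.insert(0, pref)
    return seen


@dataclass
class StudyDesign:
    """Which GLM to fit: noise family, effects of interest, group intercepts.

    Parameters
    ----------
    family : {"lognormal", "binomial_logit"}
        ``lognormal`` for positive continuous responses (log link, normal
        noise); ``binomial_logit`` for labelled/total counts (logit link,
        binomial noise).
    effect_terms : list of str
        Factor names whose coefficients are effects of interest
        (e.g. ``["genotype"]`` or ``["genotype", "treatment"]``).
    interaction : bool
        Include the pairwise interaction of the first two effect terms.
    group_intercept_factors : list of str
        Factors modelled as per-level intercepts (any subset of
        ``{"batch", "litter", "animal"}`` present in the table).
    """

    family: str
    effect_terms: list[str] = field(default_factory=lambda: ["genotype"])
    interaction: bool = False
    group_intercept_factors: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.family not in ("lognormal", "binomial_logit"):
            raise SchemaError(f"unknown family {self.family!r}")
        if not self.effect_terms:
            raise SchemaError("effect_terms must be non-empty")
        if self.interaction and len(self.effect_terms) < 2:
            raise SchemaError("interaction=True requires at least two effect terms")

    @property
    def response_kind(self) -> str:
        return "continuous" if self.family == "lognormal" else "count"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "effect_terms": list(self.effect_terms),
            "interaction": self.interaction,
            "group_intercept_factors": list(self.group_intercept_factors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        return cls(
            family=d["family"],
            effect_terms=list(d.get("effect_terms", ["genotype"])),
            interaction=bool(d.get("interaction", False)),
            group_intercept_factors=list(d.get("group_intercept_factors", [])),
        )


class MeasurementTable:
    """A validated tidy table of homogeneous measurement records.

    Continuous tables carry a positive ``value`` column; count tables carry
    non-negative ``labelled`` and positive ``total`` columns with
    ``labelled <= total``.  Every record carries a genotype and at least one
    grouping factor.  Factor levels are registered in first-appearance order
    (reference level forced to ``control``/``vehicle`` where present).
    """

    def __init__(self, df: pd.DataFrame, kind: str, metadata: dict | None = None):
        if kind not in ("continuous", "count"):
            raise SchemaError(f"unknown response kind {kind!r}")
        self.kind = kind
        self.metadata = dict(metadata or {})
        df = df.reset_index(drop=True)
        self._check_records(df)
        self.df = df
        self.factor_levels: dict[str, list] = {
            c: _ordered_levels(c, df[c].tolist())
            for c in FACTOR_COLUMNS
            if c in df.columns and df[c].notna().any()
        }
        self._check_consistency()

    # ------------------------------------------------------------------ #
    def _check_records(self, df: pd.DataFrame) -> None:
        if "genotype" not in df.columns:
            raise SchemaError("missing required column 'genotype'")
        grouping = [c for c in ("litter", "animal", "batch") if c in df.columns]
        if not grouping:
            raise SchemaError("table needs at least one grouping column (litter, animal or batch)")
        if self.kind == "continuous":
            if "value" not in df.columns:
                raise SchemaError("missing required column 'value'")
            bad = df.index[~(pd.to_numeric(df["value"], errors="coerce") > 0)]
            if len(bad):
                raise RecordError(f"row {bad[0] + 1}: continuous value must be > 0")
            for col in ("labelled", "total"):
                if col in df.columns and df[col].notna().any():
                    raise RecordError(f"continuous table must not carry '{col}'")
        else:
            for col in ("labelled", "total"):
                if col not in df.columns:
                    raise SchemaError(f"missing required column '{col}'")
            if "value" in df.columns and df["value"].notna().any():
                raise RecordError("count table must not carry 'value'")
            lab = pd.to_numeric(df["labelled"], errors="coerce")
            tot = pd.to_numeric(df["total"], errors="coerce")
            bad = df.index[~((lab >= 0) & (tot >= 1) & (lab <= tot))]
            if len(bad):
                i = bad[0]
                raise RecordError(
                    f"row {i + 1}: need 0 <= labelled <= total and total >= 1 "
                    f"(labelled={df['labelled'][i]}, total={df['total'][i]})"
                )

    def _check_consistency(self) -> None:
        # an animal id may not appear in two litters
        if "animal" in self.df.columns and "litter" in self.df.columns:
            per_animal = self.df.groupby("animal", sort=False)["litter"].nunique()
            bad = per_animal[per_animal > 1]
            if len(bad):
                raise RecordError(f"animal {bad.index[0]!r} appears in more than one litter")

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def response(self) -> np.ndarray:
        """Response values: the value column, or the labelled counts."""
        if self.kind == "continuous":
            return self.df["value"].to_numpy(dtype=float)
        return self.df["labelled"].to_numpy(dtype=int)

    def totals(self) -> np.ndarray:
        if self.kind != "count":
            raise SchemaError("totals only defined for count tables")
        return self.df["total"].to_numpy(dtype=int)

    def codes(self, factor: str) -> np.ndarray:
        """Integer level codes for a factor, in registered level order."""
        levels = self.factor_levels[factor]
        index = {lvl: i for i, lvl in enumerate(levels)}
        return np.array([index[v] for v in self.df[factor]], dtype=int)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MeasurementTable)
            and self.kind == other.kind
            and self.df.equals(other.df)
            and self.factor_levels == other.factor_levels
        )


# ---------------------------------------------------------------------- #
def load_measurements(path, design: StudyDesign | None = None, kind: str | None = None) -> MeasurementTable:
    """Read a comma-separated measurement file into a validated table.

    The response kind is taken from ``design`` (or ``kind``) when given,
    otherwise inferred from the columns present.  Empty strings are treated
    as missing optional fields.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": np.nan}).infer_objects(copy=False)
    df = df.dropna(axis=1, how="all")
    if kind is None:
        kind = design.response_kind if design is not None else (
            "continuous" if "value" in df.columns else "count"
        )
    for col in ("value",):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    for col in ("labelled", "total"):
        if col in df.columns:
            vals = pd.to_numeric(df[col])
            df[col] = vals.astype("int64") if vals.notna().all() else vals.astype("Int64")
    if kind == "continuous" and "value" not in df.columns:
        if {"labelled", "total"} <= set(df.columns):
            raise SchemaError("file has count columns but a continuous table was requested")
        raise SchemaError("missing required column 'value'")
    table = MeasurementTable(df, kind=kind)
    if design is not None:
        report = validate_against_design(table, design)
        if not report.ok:
            raise SchemaError("table does not satisfy the design:\n" + report.text())
    return table


def save_measurements(table: MeasurementTable, path) -> None:
    """Write a table back to comma-separated text (round-trips exactly)."""
    df = table.df.copy()
    for col in ("labelled", "total"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------- #
@dataclass
class ValidationReport:
    """All violations of a design against a table; empty means valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def text(self) -> str:
        if self.ok:
            return "valid: no violations"
        return "\n".join(f"- {v}" for v in self.violations)

    def to_json(self) -> str:
        return json.dumps({"ok": self.ok, "violations": self.violations}, indent=2)


def validate_against_design(table: MeasurementTable, design: StudyDesign) -> ValidationReport:
    """Check a table against a design, reporting every violation.

    Validation is total: it never raises, it reports.
    """
    v: list[str] = []
    if design.response_kind != table.kind:
        v.append(
            f"family {design.family!r} expects {design.response_kind} records, "
            f"table holds {table.kind} records"
        )
    for term in design.effect_terms:
        if term not in table.factor_levels:
            v.append(f"effect term {term!r} not present in the table")
        elif len(table.factor_levels[term]) < 2:
            v.append(f"effect term {term!r} has one level ({table.factor_levels[term][0]!r})")
    for g in design.group_intercept_factors:
        if g not in ("batch", "litter", "animal"):
            v.append(f"group intercept factor {g!r} not one of batch/litter/animal")
        elif g not in table.factor_levels:
            v.append(f"group intercept factor {g!r} not present in the table")
    if "genotype" in table.factor_levels:
        unknown = [lvl for lvl in table.factor_levels["genotype"] if lvl not in GENOTYPE_LEVELS]
        if unknown:
            v.append(f"unknown genotype level(s) {unknown!r}")
    if "treatment" in table.factor_levels:
        unknown = [lvl for lvl in table.factor_levels["treatment"] if lvl not in TREATMENT_LEVELS]
        if unknown:
            v.append(f"unknown treatment level(s) {unknown!r}")
    if design.interaction and len(design.effect_terms) >= 2:
        a, b = design.effect_terms[0], design.effect_terms[1]
        if a in table.factor_levels and b in table.factor_levels:
            cells = table.df.groupby([a, b], sort=False).size()
            expect = len(table.factor_levels[a]) * len(table.factor_levels[b])
            if len(cells) < expect:
                v.append(f"interaction {a}×{b}: {expect - len(cells)} empty cell(s)")
    return ValidationReport(v)
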