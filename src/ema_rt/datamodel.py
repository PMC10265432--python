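"""Domain types, the long-table CSV format, and shared validation.

All timed responses — EMA survey items, Symbol Search trials, and Go–No Go
trials — live in one tidy long table with a ``measure`` column.  Occasion
identity is the pair ``(person_id, occasion_id)``; clock time is stored as a
date-free decimal hour because the diurnal model only uses time of day.

The canonical in-memory carrier is a :class:`pandas.DataFrame` with the
column contract in :data:`RT_COLUMNS`.  :class:`RTRecord` is the row-level
view used for small data and validation messages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Measure",
    "ResponseType",
    "RTRecord",
    "CatalogItem",
    "ItemCatalog",
    "PersonCovariates",
    "SchemaError",
    "RowValidationError",
    "RT_COLUMNS",
    "COVARIATE_COLUMNS",
    "ITEM_SETS",
    "read_long_table",
    "write_long_table",
    "validate_rt_frame",
    "records_from_frame",
    "frame_from_records",
]

#: Exact header of the long RT table.  Column order is part of the contract.
RT_COLUMNS = [
    "person_id",
    "occasion_id",
    "timestamp_hour",
    "measure",
    "item_id",
    "rt_seconds",
    "correct",
    "is_target",
    "response_value",
    "valid",
]

#: Exact header of the person-covariate table.
COVARIATE_COLUMNS = ["person_id", "age", "phq8"]


class Measure(str, enum.Enum):
    """Which timed instrument produced a record."""

    EMA = "EMA"
    SYMBOL_SEARCH = "SYMBOL_SEARCH"
    GO_NO_GO = "GO_NO_GO"


class ResponseType(str, enum.Enum):
    """Response-option type of an EMA item."""

    slider = "slider"
    multiple_choice = "multiple_choice"
    checkbox = "checkbox"


class SchemaError(ValueError):
    """A file header does not match the published column contract."""


class RowValidationError(ValueError):
    """One or more rows violate record invariants.

    Attributes
    ----------
    lines : list of int
        1-based file line numbers of the offending rows (header is line 1).
    """

    def __init__(self, message: str, lines: list[int]):
        super().__init__(message)
        self.lines = lines


@dataclass(frozen=True)
class RTRecord:
    """A single timed response.

    ``correct`` is present iff the measure is a cognitive task;
    ``is_target`` is present iff the measure is GO_NO_GO.
    """

    person_id: str
    occasion_id: str
    timestamp_hour: float
    measure: Measure
    item_id: str
    rt_seconds: float
    correct: bool | None = None
    is_target: bool | None = None
    response_value: float | None = None
    valid: bool = True

    def __post_init__(self):
        if not self.rt_seconds > 0:
            raise ValueError(f"rt_seconds must be > 0, got {self.rt_seconds}")
        if not (0.0 <= self.timestamp_hour < 24.0):
            raise ValueError(
                f"timestamp_hour must be in [0, 24), got {self.timestamp_hour}"
            )
        measure = Measure(self.measure)
        if (self.correct is None) != (measure is Measure.EMA):
            raise ValueError(
                f"correct must be present iff measure != EMA ({measure.value})"
            )
        if (self.is_target is None) == (measure is Measure.GO_NO_GO):
            raise ValueError(
                f"is_target must be present iff measure == GO_NO_GO ({measure.value})"
            )


@dataclass(frozen=True)
class PersonCovariates:
    """Baseline person-level covariates (one row per person)."""

    person_id: str
    age: float
    phq8: int

    def __post_init__(self):
        if not (0 <= self.phq8 <= 24):
            raise ValueError(f"phq8 must be in [0, 24], got {self.phq8}")


@dataclass(frozen=True)
class CatalogItem:
    response_type: ResponseType
    content_domain: str
    n_options: int


@dataclass(frozen=True)
class ItemCatalog:
    """Mapping of EMA item ids to response-type / content metadata."""

    items: Mapping[str, CatalogItem]

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.items

    def item_ids(self) -> list[str]:
        return list(self.items)

    def counts_by_type(self) -> dict[ResponseType, int]:
        counts = {rt: 0 for rt in ResponseType}
        for item in self.items.values():
            counts[item.response_type] += 1
        return counts

    def item_set(self, name: str) -> list[str]:
        """Resolve a named item-set selector to a list of item ids.

        Selectors are the study's groupings (``slider16``, ``pa4``, ``na4``,
        ``activity3``, ``stress3``, ``mc3``, ``check3``, ``all22``) plus any
        single item id.
        """
        if name in self.items:
            return [name]
        try:
            spec = ITEM_SETS[name]
        except KeyError:
            raise KeyError(
                f"unknown item set {name!r}; known: {sorted(ITEM_SETS)} "
                "or a single item id"
            ) from None
        ids = [
            iid
            for iid, item in self.items.items()
            if spec(item)
        ]
        if not ids:
            raise KeyError(f"item set {name!r} is empty in this catalog")
        return ids

    @staticmethod
    def default() -> "ItemCatalog":
        """The 22-item catalog used throughout: 16 slider + 3 MC + 3 checkbox."""
        return ItemCatalog(items=dict(_DEFAULT_ITEMS))


def _slider(domain: str) -> CatalogItem:
    return CatalogItem(ResponseType.slider, domain, 101)


_DEFAULT_ITEMS: list[tuple[str, CatalogItem]] = [
    # positive affect (4 sliders)
    ("pa_content", _slider("positive_affect")),
    ("pa_happy", _slider("positive_affect")),
    ("pa_excited", _slider("positive_affect")),
    ("pa_enthusiastic", _slider("positive_affect")),
    # negative affect (4 sliders)
    ("na_disappointed", _slider("negative_affect")),
    ("na_sad", _slider("negative_affect")),
    ("na_upset", _slider("negative_affect")),
    ("na_anxious", _slider("negative_affect")),
    # activity engagement (3 sliders)
    ("act_ability", _slider("activity_engagement")),
    ("act_satisfaction", _slider("activity_engagement")),
    ("act_importance", _slider("activity_engagement")),
    # stress (3 sliders)
    ("stress_level", _slider("stress")),
    ("stress_diabetes", _slider("stress")),
    ("stress_tense", _slider("stress")),
    # fatigue + pain sliders
    ("fatigue", _slider("fatigue")),
    ("pain", _slider("pain")),
    # multiple choice
    ("activity_done", CatalogItem(ResponseType.multiple_choice, "activity_done", 10)),
    ("activity_where", CatalogItem(ResponseType.multiple_choice, "location", 5)),
    ("subjective_glucose", CatalogItem(ResponseType.multiple_choice, "subjective_glucose", 5)),
    # checkbox
    ("with_whom", CatalogItem(ResponseType.checkbox, "with_whom", 8)),
    ("diabetes_intrusive", CatalogItem(ResponseType.checkbox, "diabetes_intrusiveness", 4)),
    ("eat_drink", CatalogItem(ResponseType.checkbox, "eat_drink", 3)),
]

#: Named item-set selectors -> predicate over CatalogItem.
ITEM_SETS = {
    "slider16": lambda it: it.response_type is ResponseType.slider,
    "pa4": lambda it: it.content_domain == "positive_affect",
    "na4": lambda it: it.content_domain == "negative_affect",
    "activity3": lambda it: it.content_domain == "activity_engagement"
    and it.response_type is ResponseType.slider,
    "stress3": lambda it: it.content_domain == "stress",
    "mc3": lambda it: it.response_type is ResponseType.multiple_choice,
    "check3": lambda it: it.response_type is ResponseType.checkbox,
    "all22": lambda it: True,
}


# ---------------------------------------------------------------------------
# Frame <-> record conversion


def frame_from_records(records: Iterable[RTRecord]) -> pd.DataFrame:
    """Build a typed long-table frame from RTRecord instances."""
    rows = list(records)
    df = pd.DataFrame(
        {
            "person_id": [r.person_id for r in rows],
            "occasion_id": [r.occasion_id for r in rows],
            "timestamp_hour": np.array([r.timestamp_hour for r in rows], dtype=float),
            "measure": [Measure(r.measure).value for r in rows],
            "item_id": [r.item_id for r in rows],
            "rt_seconds": np.array([r.rt_seconds for r in rows], dtype=float),
            "correct": pd.array([r.correct for r in rows], dtype="boolean"),
            "is_target": pd.array([r.is_target for r in rows], dtype="boolean"),
            "response_value": np.array(
                [np.nan if r.response_value is None else r.response_value for r in rows],
                dtype=float,
            ),
            "valid": np.array([r.valid for r in rows], dtype=bool),
        },
        columns=RT_COLUMNS,
    )
    return df


def records_from_frame(df: pd.DataFrame) -> list[RTRecord]:
    """Materialize a validated frame as a list of RTRecord."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RTRecord(
                person_id=str(row.person_id),
                occasion_id=str(row.occasion_id),
                timestamp_hour=float(row.timestamp_hour),
                measure=Measure(row.measure),
                item_id=str(row.item_id),
                rt_seconds=float(row.rt_seconds),
                correct=None if pd.isna(row.correct) else bool(row.correct),
                is_target=None if pd.isna(row.is_target) else bool(row.is_target),
                response_value=None
                if pd.isna(row.response_value)
                else float(row.response_value),
                valid=bool(row.valid),
            )
        )
    return out


def validate_rt_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Check record invariants on a long-table frame.

    Returns the frame unchanged on success; raises :class:`RowValidationError`
    listing offending 1-based file line numbers (assuming a header line) on
    failure.
    """
    measures = set(df["measure"].unique())
    unknown = measures - {m.value for m in Measure}
    if unknown:
        raise RowValidationError(
            f"unknown measure values: {sorted(unknown)}",
            _lines(df, ~df["measure"].isin([m.value for m in Measure])),
        )
    bad = pd.Series(False, index=df.index)
    rt = df["rt_seconds"]
    bad |= ~(rt > 0) | rt.isna()
    hour = df["timestamp_hour"]
    bad |= ~((hour >= 0) & (hour < 24))
    is_ema = df["measure"] == Measure.EMA.value
    is_gng = df["measure"] == Measure.GO_NO_GO.value
    bad |= is_ema & df["correct"].notna()
    bad |= ~is_ema & df["correct"].isna()
    bad |= is_gng & df["is_target"].isna()
    bad |= ~is_gng & df["is_target"].notna()
    if bad.any():
        lines = _lines(df, bad)
        raise RowValidationError(
            f"{int(bad.sum())} row(s) violate record invariants "
            f"(file lines {lines[:20]}{'...' if len(lines) > 20 else ''})",
            lines,
        )
    return df


def _lines(df: pd.DataFrame, mask: pd.Series) -> list[int]:
    # +2: 1-based and one header line
    return [int(i) + 2 for i in np.flatnonzero(np.asarray(mask))]


# ---------------------------------------------------------------------------
# I/O

_BOOL_IN = {"true": True, "false": False, "": None}


def read_long_table(path: str | Path, schema: str = "rt") -> pd.DataFrame:
    """Read and validate a long table.

    Parameters
    ----------
    path:
        CSV file with the exact header for the requested schema.
    schema:
        ``"rt"`` for the timed-response table, ``"covariates"`` for the
        person-covariate table.

    Returns
    -------
    A validated, typed DataFrame (row order preserved).
    """
    path = Path(path)
    if schema == "covariates":
        return _read_covariates(path)
    if schema != "rt":
        raise ValueError(f"unknown schema {schema!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    if list(raw.columns) != RT_COLUMNS:
        raise SchemaError(
            f"header of {path} must be exactly {RT_COLUMNS}, got {list(raw.columns)}"
        )
    df = pd.DataFrame(index=raw.index)
    df["person_id"] = raw["person_id"]
    df["occasion_id"] = raw["occasion_id"]
    df["timestamp_hour"] = pd.to_numeric(raw["timestamp_hour"], errors="coerce")
    df["measure"] = raw["measure"]
    df["item_id"] = raw["item_id"]
    df["rt_seconds"] = pd.to_numeric(raw["rt_seconds"], errors="coerce")
    for col in ("correct", "is_target"):
        vals = raw[col].str.lower()
        ok = vals.isin(_BOOL_IN)
        if not ok.all():
            raise RowValidationError(
                f"unparseable boolean in column {col!r}", _lines(raw, ~ok)
            )
        df[col] = pd.array([_BOOL_IN[v] for v in vals], dtype="boolean")
    df["response_value"] = pd.to_numeric(
        raw["response_value"].mask(raw["response_value"] == "", np.nan),
        errors="coerce",
    )
    vv = raw["valid"].str.lower()
    ok = vv.isin(("true", "false"))
    if not ok.all():
        raise RowValidationError("unparseable boolean in column 'valid'", _lines(raw, ~ok))
    df["valid"] = vv == "true"
    unparseable = df["timestamp_hour"].isna() | df["rt_seconds"].isna()
    if unparseable.any():
        raise RowValidationError(
            "unparseable numeric value(s) in timestamp_hour/rt_seconds",
            _lines(raw, unparseable),
        )
    return validate_rt_frame(df)


def _read_covariates(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COVARIATE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    df = pd.DataFrame(
        {
            "person_id": raw["person_id"],
            "age": pd.to_numeric(raw["age"], errors="coerce"),
            "phq8": pd.to_numeric(raw["phq8"], errors="coerce"),
        }
    )
    bad = df["age"].isna() | df["phq8"].isna() | ~df["phq8"].between(0, 24)
    if bad.any():
        raise RowValidationError("invalid covariate row(s)", _lines(raw, bad))
    if df["person_id"].duplicated().any():
        dup = df["person_id"][df["person_id"].duplicated()].iloc[0]
        raise RowValidationError(
            f"duplicate person_id {dup!r}", _lines(raw, df["person_id"].duplicated())
        )
    df["phq8"] = df["phq8"].astype(int)
    return df


def write_long_table(
    data: pd.DataFrame | Iterable[RTRecord], path: str | Path, schema: str = "rt"
) -> Path:
    """Write a long table with deterministic column order.

    Optional booleans are written as ``true``/``false`` and missing optional
    values as empty cells.  ``read_long_table(write_long_table(x)) == x``.
    """
    path = Path(path)
    if schema == "covariates":
        df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(data)
        df.to_csv(path, index=False, columns=COVARIATE_COLUMNS)
        return path
    if not isinstance(data, pd.DataFrame):
        data = frame_from_records(data)
    out = data.copy()
    for col in ("correct", "is_target"):
        out[col] = (
            out[col]
            .map({True: "true", False: "false"})
            .astype(object)
            .where(out[col].notna(), "")
        )
    out["valid"] = out["valid"].map({True: "true", False: "false"})
    out.to_csv(path, index=False, columns=RT_COLUMNS, na_rep="")
    return path
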