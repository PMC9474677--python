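"""Core domain types for quasi-identifier generalization.

A quasi-identifier (QI) set is a minimal set of attributes that, joined with
external data, can re-identify individuals.  Anonymization replaces QI values
with *generalizations* — intervals for arithmetic/date attributes, value sets
for categorical attributes — so that every record becomes indistinguishable
from at least ``k - 1`` others (k-anonymity).  The maximal groups of records
sharing one generalized QI tuple are the *equivalence classes*.

This module holds the shared vocabulary of the pipeline: attribute schemas
with global domain bounds, datasets, generalized values, equivalence classes,
and the reconstruction of equivalence classes from a recoded table.

Conventions
-----------
* Dates are encoded as integer days since 1970-01-01 for every arithmetic
  operation and rendered back to ISO-8601 for output.
* A null categorical value (a missing address) is a category of its own,
  written ``"∅"`` and sorted after every real value.
* Generalized values have a canonical string token (interval endpoints joined
  by ``"/"``, sorted value sets joined by ``"|"`` inside braces) so that
  grouping by generalized tuples is deterministic across runs.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NULL_CATEGORY",
    "AttributeSpec",
    "QISchema",
    "Dataset",
    "GeneralizedValue",
    "EquivalenceClass",
    "AnonymizedDataset",
    "date_to_days",
    "days_to_date",
    "infer_schema",
    "group_equivalence_classes",
    "parse_token",
]

#: Sentinel category used for null values of categorical attributes.
NULL_CATEGORY = "∅"

_EPOCH = _dt.date(1970, 1, 1).toordinal()

VALID_KINDS = ("arithmetic", "categorical", "date")


def date_to_days(d) -> int:
    """Encode a date (datetime.date or ISO-8601 string) as days since 1970-01-01."""
    if isinstance(d, str):
        d = _dt.date.fromisoformat(d)
    elif isinstance(d, _dt.datetime):
        d = d.date()
    return d.toordinal() - _EPOCH


def days_to_date(days: int) -> _dt.date:
    """Decode an integer day offset back to a date."""
    return _dt.date.fromordinal(int(days) + _EPOCH)


def _is_null(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


@dataclass(frozen=True)
class AttributeSpec:
    """One QI attribute with its kind and global domain summary.

    For arithmetic and date attributes ``lower``/``upper`` are the global
    domain bounds L_i and U_i (dates as integer days); for categorical
    attributes ``cardinality`` is the global distinct-value count N_i.
    """

    name: str
    kind: str
    lower: float | None = None
    upper: float | None = None
    cardinality: int | None = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "categorical":
            if self.cardinality is None or self.cardinality < 1:
                raise ValueError(f"{self.name}: categorical spec needs cardinality >= 1")
            if self.lower is not None or self.upper is not None:
                raise ValueError(f"{self.name}: categorical spec must not carry bounds")
        else:
            if self.lower is None or self.upper is None:
                raise ValueError(f"{self.name}: {self.kind} spec needs lower/upper bounds")
            if self.upper < self.lower:
                raise ValueError(f"{self.name}: upper < lower")
            if self.cardinality is not None:
                raise ValueError(f"{self.name}: {self.kind} spec must not carry cardinality")

    @property
    def is_numeric(self) -> bool:
        return self.kind in ("arithmetic", "date")

    @property
    def width(self) -> float:
        """Global domain width U_i - L_i (numeric kinds only)."""
        return float(self.upper) - float(self.lower)


@dataclass(frozen=True)
class QISchema:
    """Ordered quasi-identifier set; the order fixes dimension indexing."""

    attributes: tuple[AttributeSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "attributes", tuple(self.attributes))
        names = [a.name for a in self.attributes]
        if len(names) == 0:
            raise ValueError("QI schema needs at least one attribute")
        if len(set(names)) != len(names):
            raise ValueError("QI attribute names must be unique")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def __len__(self) -> int:
        return len(self.attributes)

    def __getitem__(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)


class Dataset:
    """A table ``T`` of records, each a mapping attribute-name -> value.

    Internally backed by a :class:`pandas.DataFrame`; ``records`` gives the
    list-of-mappings view.  ``meta`` carries generator ground truth (e.g. the
    true null-address tally) when the table is synthetic.
    """

    def __init__(self, records, label: str = "T", meta: dict | None = None):
        if isinstance(records, pd.DataFrame):
            self.df = records.reset_index(drop=True)
        else:
            self.df = pd.DataFrame(list(records))
        self.label = label
        self.meta = dict(meta or {})

    @property
    def size(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[dict]:
        recs = self.df.to_dict(orient="records")
        for r in recs:
            for k, v in r.items():
                if isinstance(v, float) and np.isnan(v):
                    r[k] = None
        return recs

    def column(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise KeyError(f"attribute {name!r} not present in dataset {self.label!r}")
        return self.df[name]

    @staticmethod
    def concat(datasets: Sequence["Dataset"], label: str | None = None) -> "Dataset":
        lab = label or "+".join(d.label for d in datasets)
        df = pd.concat([d.df for d in datasets], ignore_index=True)
        return Dataset(df, label=lab)


def _fmt_number(x: float) -> str:
    """Canonical token for a numeric endpoint (integers render without '.0')."""
    f = float(x)
    if f.is_integer():
        return str(int(f))
    return repr(f)


@dataclass(frozen=True)
class GeneralizedValue:
    """A per-class generalization of one attribute.

    Numeric kinds carry a closed interval [L_ij, U_ij] (``lower``/``upper``,
    dates as integer days, ``None`` when every member value is null);
    categorical kinds carry the sorted tuple of member values with class
    cardinality N_ij = ``len(values)``.  ``covers_null`` marks numeric
    generalizations of classes containing null-valued members, which are
    emitted as the attribute's full-domain interval.
    """

    kind: str
    lower: float | None = None
    upper: float | None = None
    values: tuple | None = None
    covers_null: bool = False

    @property
    def cardinality(self) -> int:
        return len(self.values)

    def contains(self, value) -> bool:
        """Whether a raw value falls inside this generalization (nulls trivially do)."""
        if _is_null(value):
            return True
        if self.kind == "categorical":
            return value in self.values
        if self.lower is None:
            return False
        return self.lower <= float(value) <= self.upper

    def token(self, spec: AttributeSpec | None = None) -> str:
        """Canonical string form; the unit of grouping and of recoded output.

        Numeric generalizations that cover nulls render as the attribute's
        full global domain so every member of a class emits one identical
        token (``spec`` supplies the global bounds; without it the class
        bounds are used).
        """
        if self.kind == "categorical":
            if len(self.values) == 1:
                return str(self.values[0])
            return "{" + "|".join(str(v) for v in self.values) + "}"
        lo, hi = self.lower, self.upper
        if self.covers_null or lo is None:
            if spec is not None:
                lo, hi = spec.lower, spec.upper
            elif lo is None:
                return "*"
        if self.kind == "date":
            a, b = days_to_date(lo).isoformat(), days_to_date(hi).isoformat()
        else:
            a, b = _fmt_number(lo), _fmt_number(hi)
        return a if a == b else f"{a}/{b}"

    @staticmethod
    def point(value, kind: str) -> "GeneralizedValue":
        """Degenerate generalization of a single raw value."""
        if kind == "categorical":
            v = NULL_CATEGORY if _is_null(value) else value
            return GeneralizedValue(kind=kind, values=(v,))
        if _is_null(value):
            return GeneralizedValue(kind=kind, covers_null=True)
        x = float(date_to_days(value)) if kind == "date" and not isinstance(value, (int, float)) else float(value)
        return GeneralizedValue(kind=kind, lower=x, upper=x)


@dataclass
class EquivalenceClass:
    """One equivalence class: a generalization per QI attribute plus members."""

    generalization: dict[str, GeneralizedValue]
    members: np.ndarray

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=np.int64)

    @property
    def size(self) -> int:
        return len(self.members)

    def tuple_token(self, schema: QISchema) -> tuple[str, ...]:
        return tuple(self.generalization[a.name].token(a) for a in schema.attributes)


class AnonymizedDataset:
    """The recoded table ``T*``: source table, equivalence classes and k."""

    def __init__(self, source: Dataset, classes: list[EquivalenceClass], k: int,
                 schema: QISchema, diagnostics: dict | None = None):
        self.source = source
        self.classes = classes
        self.k = int(k)
        self.schema = schema
        self.diagnostics = dict(diagnostics or {})
        self._check_partition()

    def _check_partition(self):
        n = self.source.size
        counts = np.zeros(n, dtype=np.int64)
        for eq in self.classes:
            counts[eq.members] += 1
        if not np.all(counts == 1):
            raise ValueError("equivalence classes do not partition the record set")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def min_class_size(self) -> int:
        return min(eq.size for eq in self.classes) if self.classes else 0

    def class_index(self) -> np.ndarray:
        """Record index -> equivalence-class index."""
        idx = np.empty(self.source.size, dtype=np.int64)
        for c, eq in enumerate(self.classes):
            idx[eq.members] = c
        return idx

    def recoded_frame(self) -> pd.DataFrame:
        """Source table with QI columns replaced by canonical generalization tokens."""
        df = self.source.df.copy()
        cidx = self.class_index()
        for spec in self.schema.attributes:
            tokens = np.array([eq.generalization[spec.name].token(spec) for eq in self.classes],
                              dtype=object)
            df[spec.name] = tokens[cidx]
        return df

    @property
    def recoded_records(self) -> list[dict]:
        return self.recoded_frame().to_dict(orient="records")

    @staticmethod
    def concat(parts: Sequence["AnonymizedDataset"], label: str | None = None,
               schema: QISchema | None = None) -> "AnonymizedDataset":
        """Concatenate disjoint anonymized tables without merging classes.

        The parts keep their own class structure (offset member indices); the
        result's k is the smallest part k.  A schema over the union may be
        supplied (e.g. re-inferred global bounds); per-class generalizations
        are untouched.
        """
        if not parts:
            raise ValueError("nothing to concatenate")
        source = Dataset.concat([p.source for p in parts], label=label)
        classes: list[EquivalenceClass] = []
        offset = 0
        for p in parts:
            for eq in p.classes:
                classes.append(EquivalenceClass(dict(eq.generalization), eq.members + offset))
            offset += p.source.size
        k = min(p.k for p in parts)
        sch = schema or parts[0].schema
        diag = {"concatenated_from": [p.source.label for p in parts]}
        return AnonymizedDataset(source, classes, k, sch, diagnostics=diag)


def infer_schema(dataset: Dataset, qi_names: Sequence[str],
                 kinds: Mapping[str, str]) -> QISchema:
    """Compute the QI schema with global domain summaries from a table.

    Bounds are min/max over non-null values (dates encoded as integer days);
    categorical cardinality counts distinct non-null values, plus one null
    category when nulls occur.  Raises on unknown attributes or attributes
    with zero non-null values.
    """
    specs = []
    for name in qi_names:
        col = dataset.column(name)
        kind = kinds.get(name)
        if kind not in VALID_KINDS:
            raise ValueError(f"attribute {name!r}: missing or invalid kind {kind!r}")
        nonnull = col.dropna()
        if len(nonnull) == 0:
            raise ValueError(f"attribute {name!r} has zero non-null values")
        if kind == "categorical":
            card = nonnull.nunique() + (1 if col.isna().any() else 0)
            specs.append(AttributeSpec(name=name, kind=kind, cardinality=int(card)))
        else:
            vals = nonnull.map(date_to_days) if kind == "date" else nonnull.astype(float)
            specs.append(AttributeSpec(name=name, kind=kind,
                                       lower=float(vals.min()), upper=float(vals.max())))
    return QISchema(tuple(specs))


def parse_token(token: str, kind: str) -> GeneralizedValue:
    """Rebuild a GeneralizedValue from its canonical string token.

    Inverse of :meth:`GeneralizedValue.token` for stored recoded documents:
    ``"a/b"`` intervals (dates or numbers), single values, and
    ``"{a|b|c}"`` value sets.
    """
    if kind == "categorical":
        if token.startswith("{") and token.endswith("}"):
            return GeneralizedValue(kind=kind, values=tuple(token[1:-1].split("|")))
        return GeneralizedValue(kind=kind, values=(token,))
    if kind == "date":
        parts = token.split("/")
        lo = float(date_to_days(parts[0]))
        hi = float(date_to_days(parts[-1]))
        return GeneralizedValue(kind=kind, lower=lo, upper=hi)
    parts = token.split("/")
    return GeneralizedValue(kind=kind, lower=float(parts[0]), upper=float(parts[-1]))


def _record_token(value, spec: AttributeSpec) -> str:
    if isinstance(value, GeneralizedValue):
        return value.token(spec)
    return GeneralizedValue.point(value, spec.kind).token(spec)


def group_equivalence_classes(recoded_records, qi_schema: QISchema) -> list[EquivalenceClass]:
    """Reconstruct equivalence classes by grouping records on generalized QI tuples.

    ``recoded_records`` may hold :class:`GeneralizedValue` instances, canonical
    token strings, or raw values (treated as degenerate point generalizations).
    Records with identical canonical tuples share one class; class sizes sum to
    the record count.  The class generalization is taken from the shared
    :class:`GeneralizedValue` where available, otherwise rebuilt as a point/token
    generalization.
    """
    if isinstance(recoded_records, Dataset):
        recoded_records = recoded_records.records
    records = list(recoded_records)
    groups: dict[tuple, list[int]] = {}
    first_rec: dict[tuple, dict] = {}
    for j, rec in enumerate(records):
        key_parts = []
        for spec in qi_schema.attributes:
            if spec.name not in rec:
                raise KeyError(f"record {j} missing QI attribute {spec.name!r}")
            v = rec[spec.name]
            key_parts.append(v.token(spec) if isinstance(v, GeneralizedValue)
                             else str(v) if isinstance(v, str)
                             else _record_token(v, spec))
        key = tuple(key_parts)
        groups.setdefault(key, []).append(j)
        first_rec.setdefault(key, rec)
    classes = []
    for key in sorted(groups):
        rec = first_rec[key]
        gen = {}
        for spec in qi_schema.attributes:
            v = rec[spec.name]
            if isinstance(v, GeneralizedValue):
                gen[spec.name] = v
            elif isinstance(v, str) and spec.kind != "categorical":
                # token string from a recoded store: keep it as an opaque
                # categorical-style singleton; grouping only needs equality
                gen[spec.name] = GeneralizedValue(kind="categorical", values=(v,))
            else:
                gen[spec.name] = GeneralizedValue.point(v, spec.kind)
        classes.append(EquivalenceClass(gen, np.array(groups[key], dtype=np.int64)))
    return classes
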