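"""Information-loss metrics for k-anonymized tables: GIL, DM and C_AVG.

For an anonymized table T* with original table T, QI attributes i = 1..n and
records j = 1..|T|:

* **Generalized information loss**::

      GIL(T*) = 1/(|T| n) * sum_i sum_j  (U_ij - L_ij)/(U_i - L_i)   (arithmetic/date)
                                         (N_ij - 1)/(N_i - 1)        (categorical)

  where U_i/L_i and N_i are the attribute's global bounds / cardinality and
  U_ij/L_ij, N_ij those of record j's equivalence class.  GIL is the
  fraction of the domain consumed by generalization, 0 (no loss) to 1
  (everything generalized to the full domain).

* **Discernibility metric**::

      DM(T*) = sum over classes EQ with |EQ| >= k  of |EQ|^2

  each record is penalized by the size of its class.  The ``|EQ| >= k``
  guard is kept verbatim even though Mondrian output always satisfies it, so
  foreign anonymized tables can be scored.

* **Average equivalence class size**::

      C_AVG(T*) = |T| / (|EQs| * k)

  how far class sizes sit above the ideal of exactly k records each.

Degenerate domains (U_i = L_i, or N_i = 1) contribute 0: the attribute
carries no identifying information and the penalty ratio is 0/0.  A record
whose own value is null on a numeric attribute contributes a full-domain
term (ratio 1) — its class interval is computed from non-null members only.

``sweep`` runs anonymization + scoring across a list of k values and
assembles the per-(dataset, k) report with mean / sample-standard-deviation
summary rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnonymizedDataset, Dataset, QISchema
from .mondrian import AnonymizationParams, anonymize

__all__ = ["gil", "dm", "c_avg", "sweep", "mean_std", "SummaryStat", "MetricReport"]


@dataclass(frozen=True)
class SummaryStat:
    """Mean and sample standard deviation (divisor n-1) of a metric column.

    ``degenerate`` flags a single-observation column, where the sample
    standard deviation is undefined and reported as 0.
    """

    mean: float
    std: float
    degenerate: bool = False


def mean_std(values) -> SummaryStat:
    """Mean / sample std (ddof=1) used for every summary row in a report."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    if arr.size == 1:
        return SummaryStat(float(arr[0]), 0.0, degenerate=True)
    return SummaryStat(float(arr.mean()), float(arr.std(ddof=1)))


def _class_terms(anon: AnonymizedDataset, qi: QISchema):
    """Per-class, per-attribute penalty pieces for GIL.

    For each class and attribute returns the per-record penalty for non-null
    members and the null-member count (null members score the full domain,
    ratio 1).  Categorical attributes have no null members: the null category
    is a value of its own.
    """
    n_attrs = len(qi)
    sizes = np.array([eq.size for eq in anon.classes], dtype=np.int64)
    nonnull_term = np.zeros((len(anon.classes), n_attrs))
    null_count = np.zeros((len(anon.classes), n_attrs), dtype=np.int64)
    for a, spec in enumerate(qi.attributes):
        if spec.kind == "categorical":
            denom = spec.cardinality - 1
            for c, eq in enumerate(anon.classes):
                g = eq.generalization[spec.name]
                nonnull_term[c, a] = 0.0 if denom == 0 else (g.cardinality - 1) / denom
        else:
            width = spec.width
            col = anon.source.column(spec.name)
            isnull = col.isna() | col.map(lambda v: v is None)
            nulls = isnull.to_numpy()
            for c, eq in enumerate(anon.classes):
                g = eq.generalization[spec.name]
                nnull = int(nulls[eq.members].sum())
                null_count[c, a] = nnull
                if width == 0 or g.lower is None:
                    nonnull_term[c, a] = 0.0
                else:
                    nonnull_term[c, a] = (g.upper - g.lower) / width
            if width == 0:
                null_count[:, a] = 0  # degenerate domain contributes nothing
    return sizes, nonnull_term, null_count


def gil(anon: AnonymizedDataset, qi: QISchema | None = None,
        method: str = "per_record") -> float:
    """Generalized information loss in [0, 1].

    ``method="per_record"`` evaluates the literal double sum over records;
    ``method="per_class"`` aggregates per class as
    |EQ| * (class penalty) — the two agree to floating-point accuracy and
    the second is the fast path.
    """
    qi = qi or anon.schema
    sizes, nonnull_term, null_count = _class_terms(anon, qi)
    if method == "per_class":
        total = float(((sizes[:, None] - null_count) * nonnull_term).sum()
                      + null_count.sum())
    elif method == "per_record":
        cidx = anon.class_index()
        total = 0.0
        for a in range(len(qi)):
            # record j's term: its class's non-null ratio, or 1 if j is null
            term = nonnull_term[cidx, a].copy()
            if null_count[:, a].any():
                col = anon.source.column(qi.attributes[a].name)
                nulls = (col.isna() | col.map(lambda v: v is None)).to_numpy()
                term[nulls] = 1.0
            total += float(term.sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    return total / (anon.source.size * len(qi))


def dm(anon: AnonymizedDataset, k: int | None = None) -> float:
    """Discernibility metric: sum of squared class sizes over classes >= k."""
    k = anon.k if k is None else k
    return float(sum(eq.size ** 2 for eq in anon.classes if eq.size >= k))


def c_avg(anon: AnonymizedDataset, k: int | None = None) -> float:
    """Average equivalence class size relative to the ideal size k."""
    k = anon.k if k is None else k
    if anon.n_classes == 0:
        raise ValueError("no equivalence classes")
    return anon.source.size / (anon.n_classes * k)


class MetricReport:
    """Per-(dataset, k) metric rows plus mean/sample-std summaries.

    ``frame`` has columns ``dataset, k, gil, dm, c_avg, n_classes``; the
    summary methods reduce each metric column per dataset and over all
    cells (grand summary).
    """

    COLUMNS = ["dataset", "k", "gil", "dm", "c_avg", "n_classes"]
    METRICS = ["gil", "dm", "c_avg"]

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)[self.COLUMNS]

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "MetricReport":
        return cls(pd.DataFrame(rows))

    @classmethod
    def combine(cls, reports) -> "MetricReport":
        return cls(pd.concat([r.frame for r in reports], ignore_index=True))

    def dataset_summary(self, dataset: str, metric: str) -> SummaryStat:
        col = self.frame.loc[self.frame["dataset"] == dataset, metric]
        return mean_std(col)

    def grand_summary(self, metric: str) -> SummaryStat:
        return mean_std(self.frame[metric])

    def summary_frame(self) -> pd.DataFrame:
        """Avg and Std rows per dataset, plus a grand row over all cells."""
        rows = []
        for ds in self.frame["dataset"].unique():
            for stat_name in ("Avg", "Std"):
                row = {"dataset": ds, "stat": stat_name}
                for m in self.METRICS:
                    s = self.dataset_summary(ds, m)
                    row[m] = s.mean if stat_name == "Avg" else s.std
                    row["degenerate"] = s.degenerate
                rows.append(row)
        for stat_name in ("Avg", "Std"):
            row = {"dataset": "ALL", "stat": stat_name}
            for m in self.METRICS:
                s = self.grand_summary(m)
                row[m] = s.mean if stat_name == "Avg" else s.std
                row["degenerate"] = s.degenerate
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path=None):
        return self.frame.to_csv(path, index=False)

    def to_text(self) -> str:
        """Formatted report: one block per metric, datasets as columns,
        k values as rows, with Avg/Std footer rows."""
        datasets = list(dict.fromkeys(self.frame["dataset"]))
        ks = sorted(self.frame["k"].unique())
        out = []
        for m in self.METRICS:
            out.append(m.upper())
            header = ["k"] + datasets
            lines = [header]
            for k in ks:
                row = [str(k)]
                for ds in datasets:
                    sel = self.frame[(self.frame["dataset"] == ds) & (self.frame["k"] == k)]
                    row.append("" if sel.empty else f"{sel[m].iloc[0]:.6g}")
                lines.append(row)
            for stat_name in ("Avg", "Std"):
                row = [stat_name]
                for ds in datasets:
                    s = self.dataset_summary(ds, m)
                    row.append(f"{(s.mean if stat_name == 'Avg' else s.std):.6g}")
                lines.append(row)
            widths = [max(len(r[c]) for r in lines) for c in range(len(header))]
            for r in lines:
                out.append("  ".join(x.rjust(w) for x, w in zip(r, widths)))
            out.append("")
        return "\n".join(out)


def sweep(dataset: Dataset, ks, qi: QISchema, label: str | None = None,
          return_anonymized: bool = False):
    """Anonymize and score one table for every k in an ascending list.

    Returns a :class:`MetricReport` (and, optionally, the per-k
    :class:`AnonymizedDataset` objects).  Raises when the list is not sorted
    ascending or any k exceeds |T|.
    """
    ks = list(ks)
    if ks != sorted(ks):
        raise ValueError("k values must be sorted ascending")
    if ks and ks[-1] > dataset.size:
        raise ValueError("k exceeds |T|")
    lab = label or dataset.label
    rows = []
    anons = {}
    for k in ks:
        anon = anonymize(dataset, AnonymizationParams(k=k, qi=qi))
        rows.append({"dataset": lab, "k": k,
                     "gil": gil(anon, qi, method="per_class"),
                     "dm": dm(anon), "c_avg": c_avg(anon),
                     "n_classes": anon.n_classes})
        anons[k] = anon
    report = MetricReport.from_rows(rows)
    if return_anonymized:
        return report, anons
    return report


def score_documents(source_docs, anonymized_docs, qi_names=None, k: int = 2):
    """Score a stored anonymized NDJSON table against its source documents.

    Reconstructs the equivalence classes by grouping the anonymized
    documents on their generalized QI tokens, parses the tokens back into
    generalizations, and evaluates GIL/DM/C_AVG with global bounds inferred
    from the source store.  Documents must be positionally aligned.
    """
    from .core import EquivalenceClass, GeneralizedValue, infer_schema, parse_token
    from .fhir import docs_to_dataset
    from .model import DEFAULT_QI_KINDS, DEFAULT_QI_NAMES
    from .validation import _qi_value

    qi_names = list(qi_names or [n for n in DEFAULT_QI_NAMES])
    if len(source_docs) != len(anonymized_docs):
        raise ValueError("source and anonymized stores differ in length")
    source = docs_to_dataset(source_docs, label="store")
    schema = infer_schema(source, qi_names, DEFAULT_QI_KINDS)
    groups: dict[tuple, list[int]] = {}
    for j, doc in enumerate(anonymized_docs):
        key = tuple(str(_qi_value(doc, n)) for n in qi_names)
        groups.setdefault(key, []).append(j)
    classes = []
    for key in sorted(groups):
        gen = {}
        for name, tok in zip(qi_names, key):
            spec = schema[name]
            g = parse_token(tok, spec.kind)
            if spec.is_numeric and g.lower == spec.lower and g.upper == spec.upper:
                g = GeneralizedValue(kind=spec.kind, lower=g.lower,
                                     upper=g.upper, covers_null=True)
            gen[name] = g
        classes.append(EquivalenceClass(gen, np.array(groups[key], dtype=np.int64)))
    anon = AnonymizedDataset(source, classes, k, schema)
    return {"gil": gil(anon, schema, method="per_record"), "dm": dm(anon),
            "c_avg": c_avg(anon), "n_classes": anon.n_classes,
            "min_class_size": anon.min_class_size}
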