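"""Model-style front end: a Mondrian anonymizer fitted to a patient table.

Usage mirrors the fit/results idiom of statistical modelling packages::

    model = MondrianKAnonymizer.from_fhir_documents(docs)
    res = model.fit(k=5)
    print(res.summary())
    res5, res10 = model.fit(5), model.fit(10)

    sweep = model.fit_sweep([5, 10, 15, 20])
    print(sweep.summary())

The model object holds the data and the quasi-identifier schema (global
domain bounds, inferred from the data unless supplied); ``fit`` runs the
partitioning for one k and returns an :class:`AnonymizationResult` carrying
the equivalence classes, the information-loss metrics, diagnostics, and a
``summary()`` table; ``fit_sweep`` runs a whole k grid and returns the
combined report.
"""

from __future__ import annotations

import pandas as pd

from .core import AnonymizedDataset, Dataset, QISchema, infer_schema
from .metrics import MetricReport, c_avg, dm, gil, sweep as _sweep
from .mondrian import AnonymizationParams, anonymize
from .validation import validate_k_anonymity

__all__ = ["MondrianKAnonymizer", "AnonymizationResult", "SweepResult",
           "DEFAULT_QI_KINDS"]

#: QI attribute kinds of the standard FHIR Patient projection.
DEFAULT_QI_KINDS = {
    "birthDate": "date",
    "address": "categorical",
    "ord_latitude": "arithmetic",
    "ord_longitude": "arithmetic",
}

DEFAULT_QI_NAMES = tuple(DEFAULT_QI_KINDS)


class MondrianKAnonymizer:
    """Mondrian k-anonymization model over a fixed table and QI schema."""

    def __init__(self, data, qi=None, kinds=None, label: str | None = None):
        if isinstance(data, pd.DataFrame):
            data = Dataset(data, label=label or "T")
        if label:
            data.label = label
        self.data: Dataset = data
        if isinstance(qi, QISchema):
            self.schema = qi
        else:
            names = list(qi) if qi is not None else [
                n for n in DEFAULT_QI_NAMES if n in data.df.columns]
            if not names:
                raise ValueError("no QI attributes given and none of the "
                                 "standard names found in the data")
            kindmap = dict(DEFAULT_QI_KINDS)
            kindmap.update(kinds or {})
            self.schema = infer_schema(data, names, kindmap)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, qi, kinds=None,
                       label: str | None = None) -> "MondrianKAnonymizer":
        return cls(df, qi=qi, kinds=kinds, label=label)

    @classmethod
    def from_fhir_documents(cls, docs, label: str = "store") -> "MondrianKAnonymizer":
        from .fhir import docs_to_dataset
        return cls(docs_to_dataset(docs, label=label))

    @property
    def qi_names(self) -> list[str]:
        return self.schema.names

    def fit(self, k: int) -> "AnonymizationResult":
        anon = anonymize(self.data, AnonymizationParams(k=k, qi=self.schema))
        return AnonymizationResult(self, anon)

    def fit_sweep(self, ks) -> "SweepResult":
        report, anons = _sweep(self.data, ks, self.schema, return_anonymized=True)
        results = {k: AnonymizationResult(self, a) for k, a in anons.items()}
        return SweepResult(self, report, results)


class AnonymizationResult:
    """One fitted anonymization: classes, metrics and diagnostics."""

    def __init__(self, model: MondrianKAnonymizer, anonymized: AnonymizedDataset):
        self.model = model
        self.anonymized = anonymized
        self._gil = None

    @property
    def k(self) -> int:
        return self.anonymized.k

    @property
    def equivalence_classes(self):
        return self.anonymized.classes

    @property
    def n_classes(self) -> int:
        return self.anonymized.n_classes

    @property
    def min_class_size(self) -> int:
        return self.anonymized.min_class_size

    @property
    def max_depth(self) -> int:
        return self.anonymized.diagnostics.get("max_depth")

    @property
    def gil(self) -> float:
        if self._gil is None:
            self._gil = gil(self.anonymized, method="per_class")
        return self._gil

    @property
    def dm(self) -> float:
        return dm(self.anonymized)

    @property
    def c_avg(self) -> float:
        return c_avg(self.anonymized)

    def recoded_frame(self) -> pd.DataFrame:
        return self.anonymized.recoded_frame()

    def validate(self):
        """Independent k-anonymity check by re-grouping the recoded table."""
        return validate_k_anonymity(self.recoded_frame()[self.model.qi_names],
                                    self.model.qi_names, self.k,
                                    with_quality=False)

    def summary(self) -> str:
        a = self.anonymized
        sizes = [eq.size for eq in a.classes]
        lines = [
            "Mondrian k-anonymization results",
            "=" * 48,
            f"dataset           {a.source.label}",
            f"records |T|       {a.source.size}",
            f"QI attributes     {', '.join(self.model.qi_names)}",
            f"k                 {self.k}",
            "-" * 48,
            f"equivalence classes |EQs|   {a.n_classes}",
            f"class size min/max          {min(sizes)}/{max(sizes)}",
            f"partition tree depth        {self.max_depth}",
            "-" * 48,
            f"GIL    (information loss)   {self.gil:.6f}",
            f"DM     (discernibility)     {self.dm:.0f}",
            f"C_AVG  (avg class / k)      {self.c_avg:.4f}",
            "=" * 48,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<AnonymizationResult k={self.k} |T|={self.anonymized.source.size} "
                f"|EQs|={self.n_classes} GIL={self.gil:.4g}>")


class SweepResult:
    """Anonymization results across a k grid plus the metric report."""

    def __init__(self, model: MondrianKAnonymizer, report: MetricReport,
                 results: dict[int, AnonymizationResult]):
        self.model = model
        self.report = report
        self.results = results

    @property
    def ks(self) -> list[int]:
        return sorted(self.results)

    def __getitem__(self, k: int) -> AnonymizationResult:
        return self.results[k]

    def summary(self) -> str:
        head = (f"Mondrian k-anonymization sweep — dataset "
                f"{self.model.data.label} (|T|={self.model.data.size})\n")
        return head + self.report.to_text()
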