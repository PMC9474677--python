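"""End-to-end experiment runner: generate -> harmonize -> anonymize -> score.

Emulates the multi-registry design: several independently seeded cohorts
(labelled e.g. S1, S2, S3) each go through the full pipeline for every k in
a grid, and their union is evaluated either by concatenating the per-cohort
anonymized outputs (``mode="concat"``, which preserves each cohort's class
structure, so DM is exactly additive) or by anonymizing the pooled table as
one (``mode="union"``).  Every artifact is written with a manifest recording
seeds, parameters and row counts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import CohortConfig, build_gazetteer, cohort_to_csv, generate_cohort
from .core import AnonymizedDataset, Dataset, infer_schema
from .fhir import anonymize_docs, docs_to_dataset, harmonize_cohort, write_ndjson
from .metrics import MetricReport, c_avg, dm, gil
from .model import DEFAULT_QI_KINDS, DEFAULT_QI_NAMES
from .mondrian import AnonymizationParams, anonymize
from .validation import validate_k_anonymity

__all__ = ["RunConfig", "ExperimentResult", "run_experiment"]


@dataclass(frozen=True)
class RunConfig:
    """One experiment: cohorts per label, a k grid and the union mode."""

    cohorts: dict[str, CohortConfig]
    ks: tuple[int, ...] = (5, 10, 15, 20)
    qi_names: tuple[str, ...] = DEFAULT_QI_NAMES
    mode: str = "concat"
    union_label: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.cohorts:
            raise ValueError("no cohorts configured")
        if not self.ks:
            raise ValueError("empty k list")
        if self.mode not in ("concat", "union"):
            raise ValueError("mode must be 'concat' or 'union'")

    @classmethod
    def standard(cls, sizes: dict[str, int], seed: int = 0, ks=(5, 10, 15, 20),
                 mode: str = "concat", **cohort_kwargs) -> "RunConfig":
        """Cohort per label with per-label seeds derived from ``seed``."""
        cohorts = {
            label: CohortConfig(n=n, seed=(seed * 1000 + i + 1) % (2**31), **cohort_kwargs)
            for i, (label, n) in enumerate(sorted(sizes.items()))
        }
        return cls(cohorts=cohorts, ks=tuple(ks), mode=mode, seed=seed)


@dataclass
class ExperimentResult:
    metrics: MetricReport
    validations: dict = field(default_factory=dict)   # (label, k) -> ValidationReport
    manifest: dict = field(default_factory=dict)

    @property
    def all_valid(self) -> bool:
        return all(v.k_anonymous for v in self.validations.values())


def _score_row(label: str, k: int, anon: AnonymizedDataset, schema) -> dict:
    return {"dataset": label, "k": k, "gil": gil(anon, schema, method="per_class"),
            "dm": dm(anon), "c_avg": c_avg(anon), "n_classes": anon.n_classes}


def run_experiment(config: RunConfig, out_dir=None, progress=None) -> ExperimentResult:
    """Run the full pipeline for every (cohort, k) cell plus the union.

    Returns the combined metric report, a validation report per cell, and a
    manifest; when ``out_dir`` is given, cohort CSVs, gazetteer CSVs,
    harmonized and anonymized NDJSON stores, the metric CSV/table and the
    manifest are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log = progress or (lambda msg: None)
    manifest = {
        "config": {
            "cohorts": {lab: dataclasses.asdict(c) for lab, c in config.cohorts.items()},
            "ks": list(config.ks), "qi_names": list(config.qi_names),
            "mode": config.mode, "seed": config.seed,
        },
        "artifacts": [],
        "timings_s": {},
    }

    def _write(name, writer):
        if out is None:
            return
        path = out / name
        writer(path)
        manifest["artifacts"].append(name)

    rows = []
    validations = {}
    per_label_anons: dict[str, dict[int, AnonymizedDataset]] = {}
    datasets: dict[str, Dataset] = {}
    docs_by_label = {}

    for label, cconf in config.cohorts.items():
        t0 = time.perf_counter()
        cohort = generate_cohort(cconf)
        cohort.label = label
        gaz = cohort.meta["gazetteer"]
        docs = harmonize_cohort(cohort, gaz)
        store = docs_to_dataset(docs, label=label)
        schema = infer_schema(store, config.qi_names, DEFAULT_QI_KINDS)
        datasets[label] = store
        docs_by_label[label] = docs
        _write(f"{label}_cohort.csv", lambda p, c=cohort: cohort_to_csv(c, p))
        _write(f"{label}_gazetteer.csv", lambda p, g=gaz: g.to_csv(p))
        _write(f"{label}_patients.ndjson", lambda p, d=docs: write_ndjson(d, p))
        per_label_anons[label] = {}
        for k in config.ks:
            anon = anonymize(store, AnonymizationParams(k=k, qi=schema))
            per_label_anons[label][k] = anon
            rows.append(_score_row(label, k, anon, schema))
            adocs = anonymize_docs(docs, anon)
            validations[(label, k)] = validate_k_anonymity(
                adocs, config.qi_names, k, with_quality=False)
            _write(f"{label}_anonymized_k{k}.ndjson",
                   lambda p, d=adocs: write_ndjson(d, p))
            log(f"{label} k={k}: |EQs|={anon.n_classes}")
        manifest["timings_s"][label] = round(time.perf_counter() - t0, 3)

    if len(config.cohorts) > 1:
        union_label = config.union_label or "".join(
            lab.lstrip("S") if lab.startswith("S") else lab for lab in config.cohorts)
        union_label = ("S" + union_label) if all(
            lab.startswith("S") for lab in config.cohorts) else union_label
        t0 = time.perf_counter()
        union_store = Dataset.concat(list(datasets.values()), label=union_label)
        union_schema = infer_schema(union_store, config.qi_names, DEFAULT_QI_KINDS)
        union_docs = [d for lab in config.cohorts for d in docs_by_label[lab]]
        for k in config.ks:
            if config.mode == "concat":
                anon = AnonymizedDataset.concat(
                    [per_label_anons[lab][k] for lab in config.cohorts],
                    label=union_label, schema=union_schema)
            else:
                anon = anonymize(union_store, AnonymizationParams(k=k, qi=union_schema))
            rows.append(_score_row(union_label, k, anon, union_schema))
            adocs = anonymize_docs(union_docs, anon)
            validations[(union_label, k)] = validate_k_anonymity(
                adocs, config.qi_names, k, with_quality=False)
            _write(f"{union_label}_anonymized_k{k}.ndjson",
                   lambda p, d=adocs: write_ndjson(d, p))
            log(f"{union_label} k={k} ({config.mode}): |EQs|={anon.n_classes}")
        manifest["timings_s"][union_label] = round(time.perf_counter() - t0, 3)

    report = MetricReport.from_rows(rows)
    _write("metrics.csv", lambda p: report.to_csv(p))
    _write("metrics_table.txt", lambda p: p.write_text(report.to_text(), encoding="utf-8"))
    _write("validation.json", lambda p: p.write_text(json.dumps(
        {f"{lab}:k={k}": json.loads(v.to_json()) for (lab, k), v in validations.items()},
        ensure_ascii=False, indent=2), encoding="utf-8"))
    if out is not None:
        (out / "manifest.json").write_text(
            json.dumps(manifest, ensure_ascii=False, indent=2), encoding="utf-8")
    return ExperimentResult(metrics=report, validations=validations, manifest=manifest)
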