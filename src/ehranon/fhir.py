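"""HL7 FHIR R4 Patient harmonization, NDJSON storage and incremental extraction.

Relational patient rows are mapped field-by-field onto FHIR R4 ``Patient``
resources serialized as JSON, one document per line (NDJSON), which serves as
the inter-stage format of the pipeline.  Two extra numeric fields,
``ord_latitude`` and ``ord_longitude``, carry the geocoded address
coordinates as top-level siblings of the standard Patient fields so they can
take part in anonymization alongside ``birthDate`` and ``address``.

Incremental extraction follows a watermark scheme: the primary key of the
last extracted record is stored per source table and version, and a later
run extracts only rows with a larger key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .core import Dataset
from .cohort import Gazetteer, geocode

__all__ = ["FhirPatient", "ExtractionWatermark", "harmonize_patient",
           "harmonize_cohort", "incremental_extract", "write_ndjson",
           "read_ndjson", "docs_to_dataset", "anonymize_docs",
           "MARITAL_STATUS_CODES"]

#: HL7 v3 MaritalStatus code map used for the maritalStatus codeable concept.
MARITAL_STATUS_CODES = {
    "single": ("S", "Never Married"),
    "married": ("M", "Married"),
    "divorced": ("D", "Divorced"),
    "widowed": ("W", "Widowed"),
}

_MARITAL_SYSTEM = "http://terminology.hl7.org/CodeSystem/v3-MaritalStatus"


class _Coding(BaseModel):
    model_config = ConfigDict(extra="forbid")
    system: str
    code: str
    display: str


class _CodeableConcept(BaseModel):
    model_config = ConfigDict(extra="forbid")
    coding: list[_Coding]
    text: str


class _Address(BaseModel):
    model_config = ConfigDict(extra="forbid")
    text: str


class FhirPatient(BaseModel):
    """Schema of the FHIR R4 Patient fields this pipeline emits.

    Covers the subset of the R4 Patient resource actually populated
    (resourceType, id, gender, birthDate, address, maritalStatus) plus the
    two coordinate extension fields; ``birthDate`` must be ISO-8601 and
    ``gender`` a valid administrative-gender code.
    """

    model_config = ConfigDict(extra="forbid")

    resourceType: Literal["Patient"]
    id: str
    gender: Literal["male", "female", "other", "unknown"]
    birthDate: str
    maritalStatus: _CodeableConcept
    address: Optional[list[_Address]] = None
    ord_latitude: Optional[float] = None
    ord_longitude: Optional[float] = None

    @field_validator("birthDate")
    @classmethod
    def _iso_date(cls, v: str) -> str:
        import datetime as _dt
        _dt.date.fromisoformat(v)
        return v


def harmonize_patient(row, gazetteer: Gazetteer) -> dict:
    """Map one patient row to a FHIR Patient JSON document.

    ``row`` is a mapping with keys ``patient_id, gender, birth_date,
    marital_status, address``.  A null address yields a document without the
    ``address`` and ``ord_*`` fields; otherwise the address text is geocoded
    through the gazetteer.  Key order is fixed for diff-able NDJSON output.
    """
    status = row["marital_status"]
    if status not in MARITAL_STATUS_CODES:
        raise ValueError(f"unmappable marital status {status!r}")
    code, display = MARITAL_STATUS_CODES[status]
    bd = row["birth_date"]
    birth_date = bd if isinstance(bd, str) else bd.isoformat()
    doc = {
        "resourceType": "Patient",
        "id": str(int(row["patient_id"])),
        "gender": str(row["gender"]),
        "birthDate": birth_date,
        "maritalStatus": {
            "coding": [{"system": _MARITAL_SYSTEM, "code": code, "display": display}],
            "text": status,
        },
    }
    address = row.get("address")
    if address is not None and not (isinstance(address, float) and np.isnan(address)):
        lat, lon = geocode(address, gazetteer)
        doc["address"] = [{"text": str(address)}]
        doc["ord_latitude"] = lat
        doc["ord_longitude"] = lon
    FhirPatient.model_validate(doc)
    return doc


def harmonize_cohort(dataset: Dataset, gazetteer: Gazetteer | None = None) -> list[dict]:
    """Harmonize a whole cohort; raises if two rows share a patient_id."""
    gaz = gazetteer or dataset.meta.get("gazetteer")
    if gaz is None:
        raise ValueError("no gazetteer supplied and none attached to the dataset")
    ids = dataset.df["patient_id"]
    if ids.duplicated().any():
        raise ValueError("duplicate patient_id values in source table")
    return [harmonize_patient(rec, gaz) for rec in dataset.records]


@dataclass
class ExtractionWatermark:
    """Per-table last-extracted primary key with a version counter."""

    last_key: dict[str, int] = field(default_factory=dict)
    version: int = 0

    def get(self, table: str) -> int:
        return self.last_key.get(table, 0)

    def to_json(self) -> str:
        return json.dumps({"last_key": self.last_key, "version": self.version})

    @classmethod
    def from_json(cls, text: str) -> "ExtractionWatermark":
        d = json.loads(text)
        return cls(last_key={k: int(v) for k, v in d["last_key"].items()},
                   version=int(d["version"]))


def incremental_extract(rows, watermark: ExtractionWatermark,
                        table: str = "CARE_PERSON"):
    """Extract only rows with primary key above the stored watermark.

    Returns ``(new_rows, updated_watermark)``; the input watermark is not
    mutated.  Keys must be positive and unique; the updated watermark stores
    the maximum key seen (unchanged when the batch is empty) and bumps the
    version counter.
    """
    if isinstance(rows, Dataset):
        df = rows.df
    elif isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    if len(df) and "patient_id" not in df.columns:
        raise KeyError("rows lack a patient_id primary key")
    keys = df["patient_id"] if len(df) else pd.Series([], dtype=np.int64)
    if len(keys) and (keys <= 0).any():
        raise ValueError("primary keys must be positive")
    if keys.duplicated().any():
        raise ValueError("duplicate primary keys in extraction batch")
    last = watermark.get(table)
    new = df[keys > last].sort_values("patient_id").reset_index(drop=True) if len(df) else df
    new_last = int(new["patient_id"].max()) if len(new) else last
    updated = ExtractionWatermark(last_key={**watermark.last_key, table: new_last},
                                  version=watermark.version + 1)
    return new, updated


def write_ndjson(docs: Iterable[dict], path) -> None:
    """One JSON document per line, UTF-8, insertion key order preserved."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc, ensure_ascii=False) + "\n")


def read_ndjson(path) -> list[dict]:
    docs = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(json.loads(line))
    return docs


def docs_to_dataset(docs: list[dict], label: str = "store") -> Dataset:
    """Project FHIR Patient documents onto the flat QI table used downstream.

    Columns: ``id``, ``birthDate`` (ISO string), ``address`` (text or None),
    ``ord_latitude``, ``ord_longitude`` (floats or None), plus ``gender`` and
    ``maritalStatus`` text for profiling.
    """
    rows = []
    for doc in docs:
        addr = doc.get("address")
        rows.append({
            "id": doc.get("id"),
            "birthDate": doc.get("birthDate"),
            "address": addr[0]["text"] if addr else None,
            "ord_latitude": doc.get("ord_latitude"),
            "ord_longitude": doc.get("ord_longitude"),
            "gender": doc.get("gender"),
            "maritalStatus": (doc.get("maritalStatus") or {}).get("text"),
        })
    return Dataset(pd.DataFrame(rows), label=label)


def anonymize_docs(docs: list[dict], anon) -> list[dict]:
    """Replace the QI fields of stored FHIR documents with class tokens.

    ``docs`` must be in the same order as ``anon.source`` rows.  The
    generalized birthDate becomes an ISO interval string, the address text
    becomes the class's value set, and the coordinates become interval
    strings; every member of a class emits the identical generalized tuple.
    """
    if len(docs) != anon.source.size:
        raise ValueError("document count does not match the anonymized table")
    schema = anon.schema
    cidx = anon.class_index()
    tokens = {}
    for spec in schema.attributes:
        tokens[spec.name] = [eq.generalization[spec.name].token(spec)
                             for eq in anon.classes]
    out = []
    for j, doc in enumerate(docs):
        new = dict(doc)
        c = int(cidx[j])
        for spec in schema.attributes:
            tok = tokens[spec.name][c]
            if spec.name == "address":
                new["address"] = [{"text": tok}]
            else:
                new[spec.name] = tok
        out.append(new)
    return out
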