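"""Post-load checks: k-anonymity validation and data-quality profiling.

The k-anonymity validator is deliberately independent of the anonymizer: it
reads the stored (recoded) documents back, groups them by their generalized
QI values — reconstructing the equivalence classes exactly as an attacker
querying the repository would see them — and checks that no class holds
fewer than k documents.

The quality profile reports exact duplicate documents (full-document
equality, storage-assigned identifiers excluded) and per-field null counts;
null addresses are an expected feature of the source data and are profiled,
not rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from .core import Dataset

__all__ = ["ValidationReport", "validate_k_anonymity", "data_quality_profile"]

#: Marker used when grouping documents whose address field is absent.
_ABSENT = "∅"


@dataclass
class ValidationReport:
    """Outcome of the repository checks for one (store, k) pair."""

    k: int
    n_documents: int
    n_classes: int
    min_class_size: int
    violating_classes: int
    k_anonymous: bool
    duplicate_count: int = 0
    null_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        assert self.k_anonymous == (self.min_class_size >= self.k
                                    and self.violating_classes == 0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), ensure_ascii=False, indent=2)

    def __str__(self) -> str:
        verdict = "PASS" if self.k_anonymous else "FAIL"
        lines = [
            f"k-anonymity check (k={self.k}): {verdict}",
            f"  documents            {self.n_documents}",
            f"  equivalence classes  {self.n_classes}",
            f"  min class size       {self.min_class_size}",
            f"  violating classes    {self.violating_classes}",
            f"  duplicate documents  {self.duplicate_count}",
        ]
        for name, cnt in self.null_counts.items():
            lines.append(f"  nulls in {name:<12} {cnt}")
        return "\n".join(lines)


def _load_docs(store) -> list[dict]:
    if isinstance(store, (str,)) or hasattr(store, "__fspath__"):
        from .fhir import read_ndjson
        return read_ndjson(store)
    if isinstance(store, Dataset):
        return store.records
    if isinstance(store, pd.DataFrame):
        return store.to_dict(orient="records")
    return list(store)


def _qi_value(doc: dict, name: str):
    """Extract one QI field from a stored document, FHIR layout aware."""
    if name == "address" and isinstance(doc.get("address"), list):
        addr = doc["address"]
        return addr[0].get("text") if addr else _ABSENT
    if name not in doc:
        if name == "address":
            return _ABSENT
        raise KeyError(f"document missing QI field {name!r}")
    return doc[name]


def validate_k_anonymity(store, qi_names, k: int,
                         with_quality: bool = True) -> ValidationReport:
    """Group stored documents by generalized QI tuple and check class sizes.

    ``store`` may be an NDJSON path, a list of documents, a DataFrame or a
    :class:`~ehranon.core.Dataset`.  A class violates k-anonymity when it
    holds fewer than k documents; the check passes iff no class does.
    """
    docs = _load_docs(store)
    if not docs:
        raise ValueError("empty store")
    keys = [tuple(str(_qi_value(doc, name)) for name in qi_names) for doc in docs]
    sizes = pd.Series(keys).value_counts()
    min_size = int(sizes.min())
    violating = int((sizes < k).sum())
    dup_count, null_counts = (0, {})
    if with_quality:
        dup_count, null_counts = data_quality_profile(docs)
    return ValidationReport(
        k=int(k), n_documents=len(docs), n_classes=int(len(sizes)),
        min_class_size=min_size, violating_classes=violating,
        k_anonymous=(min_size >= k and violating == 0),
        duplicate_count=dup_count, null_counts=null_counts)


def data_quality_profile(store, fields=None, ignore_keys=("_id",)):
    """Duplicate count and per-field null counts for a document store.

    Duplicates are detected on full-document equality after dropping
    storage-assigned identifier keys (the repository's ``_id``; the FHIR
    resource ``id`` derives from the source primary key and is content);
    the count is the number of documents
    over and above the first occurrence of each distinct content.  Null
    counts cover ``fields`` (default: every key seen), counting explicit
    nulls and absent keys alike.
    """
    docs = _load_docs(store)
    seen: dict[str, int] = {}
    for doc in docs:
        content = {k: v for k, v in doc.items() if k not in ignore_keys}
        key = json.dumps(content, sort_keys=True, ensure_ascii=False, default=str)
        seen[key] = seen.get(key, 0) + 1
    dup_count = sum(c - 1 for c in seen.values())
    if fields is None:
        fields = sorted({k for doc in docs for k in doc} - set(ignore_keys))
    null_counts = {}
    for name in fields:
        null_counts[name] = sum(
            1 for doc in docs
            if name not in doc or doc[name] is None
            or (isinstance(doc[name], float) and doc[name] != doc[name]))
    return dup_count, null_counts
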