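"""Seeded synthetic patient tables emulating a hospital patient registry.

The generator produces CARE_PERSON-style rows — an integer primary key,
gender, date of birth, marital status and a free-text postal address — with
the data-quality features that dominate anonymization behaviour in real
patient registries:

* **Municipality-level addresses.** The address field holds a street + city
  string drawn from a small Zipf-weighted universe (most patients live in the
  catchment area's main city), so address equivalence groups are large.
* **Null addresses.** A configurable fraction of rows has no address at all;
  these are kept (not rejected) and flow through the pipeline as the null
  category.
* **Registry sentinel dates of birth.** A fraction of patients carries the
  registry's placeholder DOB (January 1 of the configured range start — the
  classic "unknown DOB" convention), and a further fraction is heaped on
  January 1 of their birth year (month/day unknown).  Together with the
  coarse addresses this yields many records that are exactly
  indistinguishable on the quasi-identifiers, i.e. large equivalence classes
  whose sizes do not depend on k.

A deterministic :class:`Gazetteer` maps every address the generator can emit
to latitude/longitude decimal degrees (one fixed coordinate pair per
address), standing in for an online geocoding service.  Coordinates live on
a plausible urban grid (lat 37.9–38.1 N, lon 23.6–23.9 E).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Dataset, date_to_days, days_to_date

__all__ = ["CohortConfig", "Gazetteer", "PatientRow", "build_gazetteer",
           "generate_cohort", "geocode", "cohort_to_csv", "cohort_from_csv"]

_CITIES = [
    ("Athens", 37.984, 23.728),
    ("Piraeus", 37.942, 23.646),
    ("Peristeri", 38.013, 23.692),
    ("Kallithea", 37.955, 23.702),
    ("Glyfada", 37.912, 23.755),
    ("Marousi", 38.056, 23.808),
    ("Kifisia", 38.074, 23.811),
    ("Elliniko", 37.911, 23.747),
]

_STREETS = [
    "Ermou", "Stadiou", "Akadimias", "Panepistimiou", "Patision", "Kifisias",
    "Vouliagmenis", "Syngrou", "Alexandras", "Mesogeion", "Athinas", "Pireos",
    "Solonos", "Skoufa", "Voukourestiou", "Mitropoleos", "Aiolou", "Agiou Konstantinou",
    "Tritis Septemvriou", "Acharnon", "Liosion", "Lenorman", "Thiseos", "Dimokratias",
]

_CSV_COLUMNS = ["patient_id", "gender", "birth_date", "marital_status", "address"]


@dataclass(frozen=True)
class PatientRow:
    """One synthetic source record, pre-harmonization."""

    patient_id: int
    gender: str
    birth_date: _dt.date
    marital_status: str
    address: str | None


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters; the defaults define the study conditions.

    ``n_addresses`` distinct street+city strings are drawn once per seed and
    assigned to patients with Zipf weights (exponent ``address_zipf``).
    ``sentinel_dob_fraction`` of patients get the registry placeholder DOB
    (Jan 1 of ``birth_year_range[0]``); ``dob_jan1_fraction`` get Jan 1 of a
    uniform birth year; the rest get a uniform day in the range.
    ``cluster_spread`` is the per-address coordinate jitter (decimal degrees,
    s.d.) around the address's city center.
    """

    n: int
    seed: int = 0
    n_addresses: int = 12
    null_address_fraction: float = 0.10
    birth_year_range: tuple[int, int] = (1920, 2005)
    cluster_spread: float = 0.02
    address_zipf: float = 0.9
    sentinel_dob_fraction: float = 0.05
    dob_jan1_fraction: float = 0.80

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_addresses < 1:
            raise ValueError("n_addresses must be >= 1")
        for name in ("null_address_fraction", "sentinel_dob_fraction", "dob_jan1_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.birth_year_range
        if hi < lo:
            raise ValueError("invalid birth_year_range")


class Gazetteer:
    """Deterministic total map address-string -> (latitude, longitude)."""

    def __init__(self, mapping: dict[str, tuple[float, float]]):
        self.mapping = dict(mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, address: str) -> bool:
        return address in self.mapping

    def lookup(self, address: str) -> tuple[float, float]:
        if address not in self.mapping:
            raise KeyError(f"address not in gazetteer: {address!r}")
        return self.mapping[address]

    def to_csv(self, path):
        df = pd.DataFrame(
            [(a, lat, lon) for a, (lat, lon) in sorted(self.mapping.items())],
            columns=["address", "latitude", "longitude"],
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Gazetteer":
        df = pd.read_csv(path)
        return cls({r.address: (float(r.latitude), float(r.longitude))
                    for r in df.itertuples(index=False)})


def geocode(address: str | None, gazetteer: Gazetteer):
    """Look an address up; null address propagates to null coordinates."""
    if address is None or (isinstance(address, float) and np.isnan(address)):
        return (None, None)
    return gazetteer.lookup(address)


def _address_universe(config: CohortConfig):
    """Draw the address strings and their coordinates for a config's seed."""
    rng = np.random.default_rng([config.seed, 7919])  # gazetteer sub-stream
    addresses: list[str] = []
    coords: dict[str, tuple[float, float]] = {}
    seen = set()
    while len(addresses) < config.n_addresses:
        city, clat, clon = _CITIES[int(rng.integers(len(_CITIES)))]
        street = _STREETS[int(rng.integers(len(_STREETS)))]
        number = int(rng.integers(1, 200))
        addr = f"{street} {number}, {city}"
        if addr in seen:
            continue
        seen.add(addr)
        lat = round(clat + float(rng.normal(0.0, config.cluster_spread)), 5)
        lon = round(clon + float(rng.normal(0.0, config.cluster_spread)), 5)
        addresses.append(addr)
        coords[addr] = (lat, lon)
    return addresses, coords


def build_gazetteer(config: CohortConfig) -> Gazetteer:
    """The gazetteer covering every address ``generate_cohort(config)`` can emit."""
    _, coords = _address_universe(config)
    return Gazetteer(coords)


def generate_cohort(config: CohortConfig) -> Dataset:
    """Generate a seeded synthetic patient table.

    Returns a :class:`Dataset` with columns
    ``patient_id, gender, birth_date, marital_status, address`` and ground
    truth tallies (null-address count, sentinel-DOB count) plus the gazetteer
    in ``meta``.  The same config (seed included) reproduces the table
    byte-for-byte.
    """
    rng = np.random.default_rng([config.seed, 104729])  # row sub-stream
    n = config.n
    addresses, coords = _address_universe(config)

    ranks = np.arange(1, config.n_addresses + 1, dtype=float)
    weights = ranks ** (-config.address_zipf)
    weights /= weights.sum()
    addr_idx = rng.choice(config.n_addresses, size=n, p=weights)
    null_mask = rng.random(n) < config.null_address_fraction
    address_col = np.array([addresses[i] for i in addr_idx], dtype=object)
    address_col[null_mask] = None

    y0, y1 = config.birth_year_range
    d0 = date_to_days(_dt.date(y0, 1, 1))
    d1 = date_to_days(_dt.date(y1, 12, 31))
    days = rng.integers(d0, d1 + 1, size=n)
    u = rng.random(n)
    sentinel = u < config.sentinel_dob_fraction
    jan1 = (~sentinel) & (u < config.sentinel_dob_fraction + config.dob_jan1_fraction)
    days[sentinel] = d0
    if jan1.any():
        years = rng.integers(y0, y1 + 1, size=int(jan1.sum()))
        days[jan1] = np.array([date_to_days(_dt.date(int(y), 1, 1)) for y in years])
    birth_dates = [days_to_date(d) for d in days]

    gender = rng.choice(["male", "female", "other", "unknown"], size=n,
                        p=[0.49, 0.49, 0.01, 0.01])
    marital = rng.choice(["single", "married", "divorced", "widowed"], size=n,
                         p=[0.35, 0.45, 0.10, 0.10])

    df = pd.DataFrame({
        "patient_id": np.arange(1, n + 1, dtype=np.int64),
        "gender": gender,
        "birth_date": birth_dates,
        "marital_status": marital,
        "address": address_col,
    })
    meta = {
        "config": dataclasses.asdict(config),
        "null_address_count": int(null_mask.sum()),
        "sentinel_dob_count": int(sentinel.sum()),
        "gazetteer": Gazetteer(coords),
    }
    return Dataset(df, label=f"cohort-seed{config.seed}", meta=meta)


def cohort_to_csv(dataset: Dataset, path=None) -> str | None:
    """Write a cohort as CSV (null address -> empty field); returns text if no path."""
    df = dataset.df.copy()
    df["birth_date"] = df["birth_date"].map(lambda d: d.isoformat())
    if path is None:
        buf = io.StringIO()
        df.to_csv(buf, index=False, columns=_CSV_COLUMNS)
        return buf.getvalue()
    df.to_csv(path, index=False, columns=_CSV_COLUMNS)
    return None


def cohort_from_csv(path, label: str = "cohort") -> Dataset:
    df = pd.read_csv(path, dtype={"address": object})
    df["birth_date"] = df["birth_date"].map(_dt.date.fromisoformat)
    df["address"] = df["address"].where(df["address"].notna(), None)
    return Dataset(df, label=label)


def cohort_to_ndjson(dataset: Dataset, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in dataset.records:
            rec = dict(rec)
            rec["birth_date"] = rec["birth_date"].isoformat()
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
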