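"""Greedy multidimensional k-anonymization (Mondrian).

The algorithm recursively partitions the quasi-identifier space into
axis-aligned regions, kd-tree style: at each step it picks the attribute
with the widest normalized observed range, cuts the region at the lower
median of that attribute's values, and recurses while both sides keep at
least ``k`` records.  Each final region becomes one equivalence class, and a
recoding pass replaces member QI values with the region's summary statistics
(min/max interval for arithmetic and date attributes, the sorted set of
member values for categoricals).

The procedure is strict multidimensional recoding: regions are axis-aligned
boxes, no record is relocated, and no record is suppressed — unsplittable
regions simply become (possibly large) classes.  Everything is deterministic
for a fixed input and parameter set.

Rules fixing the behaviour where the greedy scheme leaves freedom:

* dimension choice: widest normalized range (observed width / global width
  for numeric attributes, observed distinct count / global cardinality for
  categoricals), ties broken by lowest attribute index;
* median: lower median; records equal to the median value all go left;
* categorical values are ordered lexicographically with the null category
  sorted last, and the cut is at the median distinct value;
* records with a null numeric value are excluded from widths and medians and
  fall on the right side of any cut on that attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (NULL_CATEGORY, AnonymizedDataset, AttributeSpec, Dataset,
                   EquivalenceClass, GeneralizedValue, QISchema, date_to_days)

__all__ = ["AnonymizationParams", "Partition", "anonymize",
           "choose_dimension", "split_partition", "recode", "encode_dataset"]


@dataclass(frozen=True)
class AnonymizationParams:
    """Mondrian parameters: minimum class size, QI schema and rule identifiers."""

    k: int
    qi: QISchema
    dimension_rule: str = "widest_normalized"
    tie_break: str = "lowest_index"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.dimension_rule != "widest_normalized" or self.tie_break != "lowest_index":
            raise ValueError("unknown dimension-selection or tie-break rule")


class _Encoded:
    """Numeric view of a dataset's QI columns.

    Numeric/date attributes become float arrays (NaN for null, dates as
    integer days); categorical attributes become integer codes into a
    lexicographically sorted value list with the null category last.
    """

    def __init__(self, dataset: Dataset, qi: QISchema):
        self.qi = qi
        self.arrays: list[np.ndarray] = []
        self.cat_values: list[list | None] = []
        for spec in qi.attributes:
            col = dataset.column(spec.name)
            if spec.kind == "categorical":
                vals = col.map(lambda v: NULL_CATEGORY if v is None or
                               (isinstance(v, float) and np.isnan(v)) else str(v))
                uniq = sorted(set(vals) - {NULL_CATEGORY})
                if (vals == NULL_CATEGORY).any():
                    uniq.append(NULL_CATEGORY)
                code = {v: i for i, v in enumerate(uniq)}
                self.arrays.append(vals.map(code).to_numpy(dtype=np.int64))
                self.cat_values.append(uniq)
            else:
                if spec.kind == "date":
                    enc = col.map(lambda v: np.nan if v is None else float(date_to_days(v)))
                else:
                    enc = col.astype(float)
                self.arrays.append(enc.to_numpy(dtype=np.float64))
                self.cat_values.append(None)


@dataclass
class Partition:
    """A working region: member record indices within an encoded dataset."""

    enc: _Encoded
    idx: np.ndarray
    depth: int = 0
    _cached_cut: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        return len(self.idx)

    def normalized_width(self, dim: int) -> float:
        """Observed range of this region on one attribute, scaled to the domain."""
        spec = self.enc.qi.attributes[dim]
        vals = self.enc.arrays[dim][self.idx]
        if spec.kind == "categorical":
            return len(np.unique(vals)) / float(spec.cardinality)
        finite = vals[~np.isnan(vals)]
        if len(finite) == 0 or spec.width == 0:
            return 0.0
        return float(finite.max() - finite.min()) / spec.width

    def observed_bounds(self, dim: int):
        spec = self.enc.qi.attributes[dim]
        vals = self.enc.arrays[dim][self.idx]
        if spec.kind == "categorical":
            return [self.enc.cat_values[dim][c] for c in np.unique(vals)]
        finite = vals[~np.isnan(vals)]
        if len(finite) == 0:
            return (None, None)
        return (float(finite.min()), float(finite.max()))


def split_partition(partition: Partition, dim: int, k: int):
    """Cut a region at the lower median of attribute ``dim``.

    Numeric/date: records with value <= lower median go left, nulls and the
    rest go right.  Categorical: distinct values are ordered (null category
    last) and the cut is after the median distinct value.  Returns
    ``(left, right)`` or ``None`` when either side would drop below ``k``
    (the cut is not *allowable*) or the attribute cannot separate the region.
    """
    spec = partition.enc.qi.attributes[dim]
    vals = partition.enc.arrays[dim][partition.idx]
    if spec.kind == "categorical":
        distinct = np.unique(vals)
        if len(distinct) < 2:
            return None
        median = distinct[(len(distinct) - 1) // 2]
        left_mask = vals <= median
    else:
        finite = np.sort(vals[~np.isnan(vals)])
        if len(finite) == 0:
            return None
        median = finite[(len(finite) - 1) // 2]
        left_mask = vals <= median  # NaN compares False -> right side
    n_left = int(left_mask.sum())
    if n_left < k or partition.size - n_left < k:
        return None
    left = Partition(partition.enc, partition.idx[left_mask], partition.depth + 1)
    right = Partition(partition.enc, partition.idx[~left_mask], partition.depth + 1)
    return left, right


def choose_dimension(partition: Partition, qi: QISchema | None = None, k: int = 2):
    """Pick the allowable dimension with the widest normalized range.

    Candidates are ranked by normalized width (descending), ties broken by
    lowest attribute index; a dimension qualifies only if the median cut on
    it is allowable for ``k``.  Returns the attribute index, or ``None`` when
    no dimension admits an allowable cut.  The winning cut is cached on the
    partition so the caller does not recompute it.
    """
    enc = partition.enc
    n_dims = len(enc.qi.attributes)
    widths = [partition.normalized_width(d) for d in range(n_dims)]
    order = sorted(range(n_dims), key=lambda d: (-widths[d], d))
    for d in order:
        if widths[d] <= 0.0:
            continue
        cut = split_partition(partition, d, k)
        if cut is not None:
            partition._cached_cut = (d, cut)
            return d
    return None


def recode(partition: Partition, qi: QISchema | None = None) -> EquivalenceClass:
    """Summarize a final region into an equivalence class.

    Arithmetic/date attributes generalize to the [min, max] interval over
    non-null member values (``covers_null`` set when null members exist, in
    which case the emitted token widens to the full domain); categoricals
    generalize to the sorted set of member values.
    """
    if partition.size == 0:
        raise ValueError("cannot recode an empty partition")
    enc = partition.enc
    gen: dict[str, GeneralizedValue] = {}
    for d, spec in enumerate(enc.qi.attributes):
        vals = enc.arrays[d][partition.idx]
        if spec.kind == "categorical":
            values = tuple(enc.cat_values[d][c] for c in np.unique(vals))
            gen[spec.name] = GeneralizedValue(kind=spec.kind, values=values)
        else:
            nan = np.isnan(vals)
            finite = vals[~nan]
            if len(finite) == 0:
                gen[spec.name] = GeneralizedValue(kind=spec.kind, covers_null=True)
            else:
                gen[spec.name] = GeneralizedValue(
                    kind=spec.kind, lower=float(finite.min()),
                    upper=float(finite.max()), covers_null=bool(nan.any()))
    return EquivalenceClass(gen, partition.idx)


def anonymize(dataset: Dataset, params: AnonymizationParams) -> AnonymizedDataset:
    """k-anonymize a table by recursive median partitioning plus recoding.

    Every output class has at least ``params.k`` members, the classes
    partition the record set, and the result is deterministic for a fixed
    input and parameter set.  ``diagnostics`` reports the maximum recursion
    depth reached (the kd-tree construction is logarithmic in |T|) and the
    class count.
    """
    if len(params.qi) == 0:
        raise ValueError("empty QI set")
    if dataset.size < params.k:
        raise ValueError(f"|T| = {dataset.size} < k = {params.k}")
    enc = _Encoded(dataset, params.qi)
    root = Partition(enc, np.arange(dataset.size, dtype=np.int64), depth=0)
    leaves: list[Partition] = []
    stack = [root]
    max_depth = 0
    while stack:
        part = stack.pop()
        max_depth = max(max_depth, part.depth)
        if choose_dimension(part, k=params.k) is None:
            leaves.append(part)
            continue
        _, (left, right) = part._cached_cut
        part._cached_cut = None
        stack.append(left)
        stack.append(right)
    classes = [recode(p) for p in leaves]
    diag = {"max_depth": max_depth, "n_classes": len(classes)}
    return AnonymizedDataset(dataset, classes, params.k, params.qi, diagnostics=diag)
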