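import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ehranon.core import (NULL_CATEGORY, AttributeSpec, Dataset, GeneralizedValue,
                          QISchema, date_to_days, days_to_date,
                          group_equivalence_classes, infer_schema, parse_token)


def test_date_encoding_roundtrip():
    assert date_to_days(dt.date(1970, 1, 1)) == 0
    assert date_to_days("1970-01-02") == 1
    for iso in ["1920-02-29", "1999-12-31", "2005-06-15"]:
        assert days_to_date(date_to_days(iso)).isoformat() == iso


class TestAttributeSpec:
    def test_kind_field_consistency_enforced(self):
        with pytest.raises(ValueError):
            AttributeSpec("a", "arithmetic", lower=5, upper=1)
        with pytest.raises(ValueError):
            AttributeSpec("a", "categorical", cardinality=0)
        with pytest.raises(ValueError):
            AttributeSpec("a", "categorical", cardinality=3, lower=0, upper=1)
        with pytest.raises(ValueError):
            AttributeSpec("a", "arithmetic", lower=0, upper=1, cardinality=2)

    def test_schema_rejects_duplicates_and_empty(self):
        a = AttributeSpec("a", "arithmetic", lower=0, upper=1)
        with pytest.raises(ValueError):
            QISchema((a, a))
        with pytest.raises(ValueError):
            QISchema(())


class TestInferSchema:
    def test_arithmetic_bounds_are_min_max(self):
        ds = Dataset(pd.DataFrame({"x": [1, 2, 3]}))
        spec = infer_schema(ds, ["x"], {"x": "arithmetic"})["x"]
        assert (spec.lower, spec.upper) == (1, 3)

    def test_categorical_cardinality_distinct(self):
        ds = Dataset(pd.DataFrame({"c": ["A", "B", "B"]}))
        assert infer_schema(ds, ["c"], {"c": "categorical"})["c"].cardinality == 2

    def test_null_is_its_own_category(self):
        # oracle: brute-force distinct count including a null sentinel
        vals = ["A", None, "B"]
        expected = len({v if v is not None else NULL_CATEGORY for v in vals})
        ds = Dataset(pd.DataFrame({"c": vals}))
        assert infer_schema(ds, ["c"], {"c": "categorical"})["c"].cardinality == expected == 3

    def test_date_bounds_in_days(self):
        ds = Dataset(pd.DataFrame({"d": ["1970-01-01", "1970-01-11"]}))
        spec = infer_schema(ds, ["d"], {"d": "date"})["d"]
        assert (spec.lower, spec.upper) == (0, 10)

    def test_errors(self):
        ds = Dataset(pd.DataFrame({"x": [None, None]}))
        with pytest.raises(ValueError):
            infer_schema(ds, ["x"], {"x": "arithmetic"})
        with pytest.raises(KeyError):
            infer_schema(ds, ["missing"], {"missing": "arithmetic"})


class TestGeneralizedValue:
    def test_tokens_are_canonical(self):
        g = GeneralizedValue("arithmetic", lower=1.0, upper=3.5)
        assert g.token() == "1/3.5"
        assert GeneralizedValue("arithmetic", lower=2.0, upper=2.0).token() == "2"
        assert GeneralizedValue("categorical", values=("A",)).token() == "A"
        assert GeneralizedValue("categorical", values=("A", "B")).token() == "{A|B}"
        d = GeneralizedValue("date", lower=0.0, upper=10.0)
        assert d.token() == "1970-01-01/1970-01-11"

    def test_null_covering_interval_widens_to_domain(self):
        spec = AttributeSpec("x", "arithmetic", lower=0, upper=10)
        g = GeneralizedValue("arithmetic", lower=3.0, upper=4.0, covers_null=True)
        assert g.token(spec) == "0/10"

    def test_parse_token_inverts_token(self):
        spec = AttributeSpec("x", "arithmetic", lower=-10, upper=10)
        for g in [GeneralizedValue("arithmetic", lower=-5.25, upper=-3.0),
                  GeneralizedValue("arithmetic", lower=7.0, upper=7.0)]:
            back = parse_token(g.token(spec), "arithmetic")
            assert (back.lower, back.upper) == (g.lower, g.upper)
        back = parse_token("1970-01-01/1970-01-11", "date")
        assert (back.lower, back.upper) == (0, 10)
        assert parse_token("{A|B}", "categorical").values == ("A", "B")

    def test_containment(self):
        g = GeneralizedValue("arithmetic", lower=1.0, upper=3.0)
        assert g.contains(2) and not g.contains(4)
        assert g.contains(None)  # nulls contained trivially
        assert GeneralizedValue("categorical", values=("A", "B")).contains("A")


class TestGrouping:
    schema = QISchema((AttributeSpec("x", "arithmetic", lower=0, upper=100),))

    def test_single_group(self):
        g = GeneralizedValue("arithmetic", lower=0.0, upper=9.0)
        recs = [{"x": g}] * 10
        classes = group_equivalence_classes(recs, self.schema)
        assert len(classes) == 1 and classes[0].size == 10

    def test_identity_grouping_on_raw_tuples(self):
        recs = [{"x": v} for v in [1, 2, 3, 4]]
        classes = group_equivalence_classes(recs, self.schema)
        assert [c.size for c in classes] == [1, 1, 1, 1]

    def test_missing_attribute_raises(self):
        with pytest.raises(KeyError):
            group_equivalence_classes([{"y": 1}], self.schema)

    def test_anonymized_cohort_matches_hash_grouping_oracle(self, result_1k_k5, model_1k):
        """Grouping the recoded table reproduces the anonymizer's classes."""
        anon = result_1k_k5.anonymized
        frame = anon.recoded_frame()[model_1k.qi_names]
        classes = group_equivalence_classes(frame.to_dict(orient="records"),
                                            anon.schema)
        # oracle: independent hash-grouping of the serialized QI tuples
        oracle = {}
        for j, rec in enumerate(frame.itertuples(index=False)):
            oracle.setdefault(tuple(map(str, rec)), []).append(j)
        assert sum(c.size for c in classes) == anon.source.size == 1000
        assert min(c.size for c in classes) >= 5
        assert sorted(c.size for c in classes) == sorted(map(len, oracle.values()))
        got = {frozenset(c.members.tolist()) for c in classes}
        assert got == {frozenset(m) for m in oracle.values()}

    def test_grouping_is_idempotent(self, result_1k_k5, model_1k):
        frame = result_1k_k5.recoded_frame()[model_1k.qi_names]
        recs = frame.to_dict(orient="records")
        once = group_equivalence_classes(recs, result_1k_k5.anonymized.schema)
        again = group_equivalence_classes(recs, result_1k_k5.anonymized.schema)
        assert [c.size for c in once] == [c.size for c in again]
        assert all((a.members == b.members).all() for a, b in zip(once, again))


def test_concat_offsets_members_and_preserves_classes(result_1k_k5):
    from ehranon.core import AnonymizedDataset
    both = AnonymizedDataset.concat([result_1k_k5.anonymized, result_1k_k5.anonymized],
                                    label="2x")
    assert both.source.size == 2000
    assert both.n_classes == 2 * result_1k_k5.n_classes
    idx = np.concatenate([c.members for c in both.classes])
    assert sorted(idx.tolist()) == list(range(2000))
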