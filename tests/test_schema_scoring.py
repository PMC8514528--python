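"""Schema handling, keyed scoring, filtering and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from traitspace.schema import Instrument, Item, QuestionnaireSchema, SchemaError, hsps_variant_schemas
from traitspace.scoring import (
    ResponseMatrix,
    ScoringError,
    apply_key,
    exclude_subjects,
    load_responses,
    score_traits,
    zscore_columns,
)


class TestSchema:
    def test_duplicate_item_ids_rejected(self):
        with pytest.raises(SchemaError, match="duplicate"):
            QuestionnaireSchema(
                (
                    Instrument("a", "a", (Item("q1"),), scale=(1, 5)),
                    Instrument("b", "b", (Item("q1"),), scale=(1, 5)),
                )
            )

    def test_degenerate_scale_rejected(self):
        with pytest.raises(SchemaError, match="scale"):
            Instrument("a", "a", (Item("q1"),), scale=(5, 5))

    def test_yaml_roundtrip(self, small_schema, tmp_path):
        path = tmp_path / "schema.yaml"
        small_schema.to_yaml(path)
        back = QuestionnaireSchema.from_yaml(path)
        assert back == small_schema

    def test_without_items_drops_and_validates(self, small_schema):
        variant = small_schema.without_items(["sens_q3", "sens_q4"])
        assert "sens_q3" not in variant.item_ids
        assert len(variant.instrument_for_trait("sens").items) == 3
        with pytest.raises(SchemaError):
            small_schema.without_items(["nope"])

    def test_hsps_variants_have_published_sizes(self):
        variants = hsps_variant_schemas()
        assert len(variants["hsps27"].items) == 27
        assert len(variants["hsps25"].items) == 25
        assert len(variants["hsps16"].items) == 16
        by_sub = {s: len(variants["hsps27"].subdomain_items(s)) for s in ("AES", "EOE", "LST")}
        assert by_sub == {"AES": 7, "EOE": 12, "LST": 6}
        # the modified scale drops the aesthetic-sensitivity positive part
        for q in (2, 10, 15, 22, 5, 8):
            assert f"HSPS_q{q:02d}" not in variants["hsps16"].item_ids


class TestApplyKey:
    def test_reverse_keying(self, small_schema, small_raw):
        rm = apply_key(small_raw, small_schema)
        # sens_q2 on 1-7: v -> 8 - v
        assert rm.values["sens_q2"].tolist() == [6, 6, 5, 2, 1]
        # aq_q2 on 1-4: v -> 5 - v
        assert rm.values["aq_q2"].tolist() == [1, 2, 3, 4, 1]

    def test_graded_autism_scoring_keeps_1_to_4(self, small_schema, small_raw):
        rm = apply_key(small_raw, small_schema)
        assert rm.values["aq_q1"].tolist() == [1, 2, 3, 4, 1]

    def test_binary_mode_collapses_to_01(self, small_schema, small_raw):
        rm = apply_key(small_raw, small_schema, binary_mode=True)
        assert set(rm.values["aq_q1"].unique()) <= {0, 1}
        assert rm.values["aq_q1"].tolist() == [0, 0, 1, 1, 0]
        # non-binary instruments are untouched
        assert rm.values["sens_q1"].tolist() == [1, 2, 3, 4, 5]

    def test_out_of_range_names_subject_item_value(self, small_schema, small_raw):
        bad = small_raw.copy()
        bad.loc["S3", "sens_q1"] = 9
        with pytest.raises(ScoringError, match=r"9.*S3.*sens_q1"):
            apply_key(bad, small_schema)

    def test_unknown_item_rejected(self, small_schema, small_raw):
        bad = small_raw.copy()
        bad["mystery"] = 1
        with pytest.raises(ScoringError, match="unknown item"):
            apply_key(bad, small_schema)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=7), min_size=3, max_size=12))
    def test_keying_is_an_involution(self, vals):
        schema = QuestionnaireSchema(
            (Instrument("t", "t", (Item("t_q1", reverse=True),), scale=(1, 7)),)
        )
        raw = pd.DataFrame({"t_q1": vals})
        once = apply_key(raw, schema).values
        twice = apply_key(once, schema).values
        assert twice["t_q1"].tolist() == vals


class TestExcludeSubjects:
    def _rm(self, flags, reasons=None):
        n = len(flags)
        values = pd.DataFrame({"q1": range(1, n + 1)}, index=[f"S{i}" for i in range(n)])
        meta = pd.DataFrame(
            {
                "age": 30,
                "sex": "female",
                "excluded": flags,
                "exclusion_reason": reasons or [None] * n,
            },
            index=values.index,
        )
        return ResponseMatrix(values, meta)

    def test_flagged_subjects_dropped(self):
        rm = self._rm([False] * 8 + [True] * 2, [None] * 8 + ["mental", "brain"])
        out = exclude_subjects(rm)
        assert len(out.subjects) == 8

    def test_no_flags_is_identity(self):
        rm = self._rm([False] * 4)
        out = exclude_subjects(rm)
        assert out.values.equals(rm.values)

    def test_all_flagged_errors(self):
        rm = self._rm([True] * 3, ["mental"] * 3)
        with pytest.raises(ScoringError, match="every subject"):
            exclude_subjects(rm)

    def test_policy_restricts_to_reasons(self):
        rm = self._rm([True, True, False], ["mental", "physio", None])
        out = exclude_subjects(rm, policy={"mental"})
        assert len(out.subjects) == 2


class TestZScore:
    def test_simple_column(self):
        rm = pd.DataFrame({"q": [1, 2, 3]})
        z = zscore_columns(rm)
        assert np.allclose(z.values["q"], [-1, 0, 1])

    def test_constant_column_names_item(self):
        rm = pd.DataFrame({"good": [1, 2, 3], "flat": [5, 5, 5]})
        with pytest.raises(ScoringError, match="flat"):
            zscore_columns(rm)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_columns_standardized(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.integers(1, 8, size=(40, 4)).astype(float))
        df.iloc[0] += 0.5  # guard against constant columns
        z = zscore_columns(df).values
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-10


class TestScoreTraits:
    def test_sum_and_subdomain_hand_totals(self, small_schema, small_raw):
        rm = apply_key(small_raw, small_schema)
        table = score_traits(rm, small_schema)
        v = rm.values
        expect = v[["sens_q1", "sens_q2", "sens_q3", "sens_q4", "sens_q5"]].sum(axis=1)
        assert table.traits["sens"].equals(expect)
        # subdomain totals cover exactly their own items (hand sums)
        assert table.subdomains["sens:A"].equals(v["sens_q3"] + v["sens_q4"])
        assert table.subdomains["sens:B"].equals(v["sens_q5"])

    def test_mean_scoring_at_scale_max(self):
        schema = QuestionnaireSchema(
            (
                Instrument(
                    "h", "h", tuple(Item(f"h_q{i}") for i in range(27)), scale=(1, 7), scoring="mean"
                ),
            )
        )
        raw = pd.DataFrame({f"h_q{i}": [7, 7] for i in range(27)})
        rm = apply_key(raw, schema)
        assert (score_traits(rm, schema).traits["h"] == 7).all()

    def test_missing_item_errors(self, small_schema, small_raw):
        rm = apply_key(small_raw.drop(columns=["sens_q5"]), small_schema)
        with pytest.raises(ScoringError, match="missing"):
            score_traits(rm, small_schema)


class TestLoader:
    def test_roundtrip_and_missing_policy(self, small_schema, small_raw, tmp_path):
        rm = apply_key(small_raw, small_schema)
        path = tmp_path / "resp.csv"
        rm.to_csv(path)
        back = load_responses(path)
        assert back.values.astype(int).equals(rm.values.astype(int))
        # poke a hole and check both policies
        df = pd.read_csv(path)
        df["sens_q1"] = df["sens_q1"].astype(float)
        df.loc[2, "sens_q1"] = np.nan
        path2 = tmp_path / "holes.csv"
        df.to_csv(path2, index=False)
        with pytest.raises(ScoringError, match="missing"):
            load_responses(path2)
        dropped = load_responses(path2, missing="drop")
        assert len(dropped.subjects) == 4
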