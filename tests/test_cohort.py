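"""Cohort model: codebook derivations, CSV loading, matching, splitting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskpatterns.cohort import (
    Codebook,
    Dataset,
    Derivation,
    IntegrityError,
    Item,
    LevelError,
    Pattern,
    SchemaError,
    SizeError,
    VariableDef,
    load_dataset,
    match,
    split_three,
)
from riskpatterns.synthetic import default_codebook


@pytest.fixture
def tiny_codebook() -> Codebook:
    return Codebook(
        variables=(
            VariableDef("age", ("<35", ">=35"), Derivation((35,))),
            VariableDef("parity", ("<5", ">=5"), Derivation((5,))),
            VariableDef("anc", ("0", "1-3", ">=4"), Derivation((1, 4))),
        )
    )


def write_csv(path, rows, header="record_id,stratum,age,parity,anc,death"):
    path.write_text("\n".join([header, *rows]) + ("\n" if rows else "\n"))


class TestLoadDataset:
    def test_derives_clinical_levels(self, tmp_path, tiny_codebook):
        """age 36 -> >=35, parity 2 -> <5, anc 2 -> 1-3; outcome parsed."""
        p = tmp_path / "c.csv"
        write_csv(p, ["a,s1,36,2,2,1", "b,s1,20,6,0,0", "c,s2,35,5,4,0"])
        ds = load_dataset(p, tiny_codebook)
        assert ds.n == 3 and ds.n_deaths == 1
        r = ds.record(0)
        assert r.attributes == {"age": ">=35", "parity": "<5", "anc": "1-3"}
        assert r.death is True
        # boundary values land on the closed side of the cut
        assert ds.record(2).attributes == {"age": ">=35", "parity": ">=5", "anc": ">=4"}

    def test_header_only_gives_empty_dataset(self, tmp_path, tiny_codebook):
        p = tmp_path / "c.csv"
        write_csv(p, [])
        ds = load_dataset(p, tiny_codebook)
        assert ds.n == 0 and ds.n_deaths == 0

    def test_anc_boundary_value_4_is_ge4(self, tmp_path, tiny_codebook):
        p = tmp_path / "c.csv"
        write_csv(p, ["a,s1,20,1,4,0"])
        assert load_dataset(p, tiny_codebook).record(0).attributes["anc"] == ">=4"

    def test_missing_column_is_schema_error(self, tmp_path, tiny_codebook):
        p = tmp_path / "c.csv"
        p.write_text("record_id,stratum,age,parity,death\na,s,20,1,0\n")
        with pytest.raises(SchemaError, match="anc"):
            load_dataset(p, tiny_codebook)

    def test_bad_level_names_row_and_variable(self, tmp_path, tiny_codebook):
        p = tmp_path / "c.csv"
        write_csv(p, ["a,s1,20,1,2,0", "b,s1,xx,1,2,0"])
        with pytest.raises(LevelError, match=r"row 2.*age"):
            load_dataset(p, tiny_codebook)

    def test_duplicate_record_id_is_integrity_error(self, tmp_path, tiny_codebook):
        p = tmp_path / "c.csv"
        write_csv(p, ["a,s1,20,1,2,0", "a,s1,21,1,2,0"])
        with pytest.raises(IntegrityError):
            load_dataset(p, tiny_codebook)

    def test_missing_value_rejected_unless_allowed(self, tmp_path):
        cb_strict = Codebook(variables=(VariableDef("x", ("no", "yes")),))
        cb_lax = Codebook(
            variables=(VariableDef("x", ("no", "yes"), allow_missing=True),)
        )
        p = tmp_path / "c.csv"
        p.write_text("record_id,stratum,x,death\na,s,,0\n")
        with pytest.raises(LevelError, match="missing"):
            load_dataset(p, cb_strict)
        ds = load_dataset(p, cb_lax)
        assert ds.record(0).attributes["x"] == "missing"
        # the missing level is not minable
        assert Item("x", "missing") not in cb_lax.items()

    def test_exclusion_filter(self, tmp_path, tiny_codebook):
        p = tmp_path / "c.csv"
        p.write_text(
            "record_id,stratum,age,parity,anc,death,died_before,transferred\n"
            "a,s,20,1,2,0,0,0\n"
            "b,s,20,1,2,1,1,0\n"
            "c,s,20,1,2,0,0,1\n"
        )
        ds = load_dataset(
            p, tiny_codebook, exclusion_columns=["died_before", "transferred"]
        )
        assert ds.n == 1 and ds.record(0).record_id == "a"
        # no exclusion by default
        assert load_dataset(p, tiny_codebook).n == 3

    def test_round_trip(self, tmp_path, f1):
        p = tmp_path / "rt.csv"
        f1.to_csv(p)
        back = load_dataset(p, f1.codebook)
        pd.testing.assert_frame_equal(back.frame, f1.frame)


class TestMatch:
    def test_empty_pattern_matches_everything(self, f1):
        for rec in f1.records():
            assert match(Pattern(), rec)

    def test_conjunction_semantics(self, f1):
        rec1 = f1.record(0)  # X=1, Y=1
        rec2 = f1.record(1)  # X=1, Y=0
        assert match(Pattern.of(("X", "1")), rec1)
        assert not match(Pattern.of(("X", "0")), rec1)
        assert match(Pattern.of(("X", "1"), ("Y", "1")), rec1)
        assert not match(Pattern.of(("X", "1"), ("Y", "1")), rec2)

    def test_unknown_variable_rejected(self, f1):
        with pytest.raises(LevelError):
            match(Pattern.of(("Z", "1")), f1.record(0), f1.codebook)

    def test_pattern_rejects_repeated_variable(self):
        with pytest.raises(ValueError):
            Pattern.of(("X", "0"), ("X", "1"))


class TestSplitThree:
    def test_printed_cohort_sizes(self):
        """Splitting 89,518 deliveries yields 29,840/29,839/29,839."""
        frame = pd.DataFrame(
            {
                "record_id": np.arange(89518).astype(str),
                "stratum": "s",
                "X": "0",
                "Y": "0",
                "death": False,
            }
        )
        cb = Codebook(
            variables=(VariableDef("X", ("0", "1")), VariableDef("Y", ("0", "1")))
        )
        parts = split_three(Dataset(frame, cb), seed=0)
        assert tuple(p.n for p in parts) == (29840, 29839, 29839)

    @pytest.mark.parametrize("n,expected", [(9, (3, 3, 3)), (10, (4, 3, 3)), (11, (4, 4, 3))])
    def test_remainder_goes_to_earlier_parts(self, n, expected):
        cb = Codebook(variables=(VariableDef("X", ("0", "1")), VariableDef("Y", ("0", "1"))))
        frame = pd.DataFrame(
            {"record_id": [str(i) for i in range(n)], "stratum": "s",
             "X": "0", "Y": "0", "death": False}
        )
        parts = split_three(Dataset(frame, cb), seed=1)
        assert tuple(p.n for p in parts) == expected

    def test_too_small_raises(self, f1):
        with pytest.raises(SizeError):
            split_three(f1.subset(np.array([0, 1])), seed=0)

    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(3, 60), seed=st.integers(0, 2**31 - 1))
    def test_partition_property(self, n, seed):
        """Parts are disjoint, exhaustive, and size-balanced (max-min <= 1)."""
        cb = Codebook(variables=(VariableDef("X", ("0", "1")), VariableDef("Y", ("0", "1"))))
        frame = pd.DataFrame(
            {"record_id": [str(i) for i in range(n)], "stratum": "s",
             "X": "0", "Y": "0", "death": False}
        )
        parts = split_three(Dataset(frame, cb), seed=seed)
        ids = [set(p.frame["record_id"]) for p in parts]
        assert ids[0] | ids[1] | ids[2] == set(frame["record_id"])
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])
        sizes = [p.n for p in parts]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_and_seed_sensitive(self, f1):
        big = Dataset(
            pd.concat([f1.frame.assign(record_id=f1.frame.record_id + f"_{k}")
                       for k in range(5)], ignore_index=True),
            f1.codebook,
        )
        a1 = split_three(big, seed=42)
        a2 = split_three(big, seed=42)
        b = split_three(big, seed=43)
        for x, y in zip(a1, a2):
            pd.testing.assert_frame_equal(x.frame, y.frame)
        assert any(
            not x.frame.equals(y.frame) for x, y in zip(a1, b)
        ), "different seeds should give different partitions at N=50"


def test_default_codebook_is_well_formed():
    cb = default_codebook()
    assert len(cb.variables) >= 20
    assert cb.outcome == "death"
    # every derived variable maps each raw value to exactly one level
    age = cb["age"]
    assert age.derive.level_index(34.9) == 0 and age.derive.level_index(35) == 1
    universe = cb.items()
    assert len(universe) == len(set(universe))
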