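"""Examination building: grouping, CT merging, oracle equivalence, RIS checks."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers
from popdose import MergeRule, build_examinations, verification_table, verify_against_ris
from popdose import vocab
from popdose.data import load_verification_reference
from popdose.errors import AmbiguousMergeError, MappingError

CODE_MAP = {
    "C1": (vocab.CT, "chest"),
    "C2": (vocab.CT, "abdomen"),
    "C3": (vocab.CT, "pelvis"),
    "C4": (vocab.CT, "head"),
    "C5": (vocab.CT, vocab.CHEST_ABDOMEN),
    "R1": (vocab.RADIOGRAPHY, vocab.UNSPECIFIED_REGION),
}
RULES = (MergeRule(frozenset({"chest", "abdomen"}), vocab.CHEST_ABDOMEN),)


def _invoices(rows):
    return pd.DataFrame(rows, columns=["patient_id", "facility_id", "date",
                                       "billing_code"])


def test_chest_plus_abdomen_same_session_merges_to_combined():
    inv = _invoices([(1, "F0", "2018-03-01", "C1"), (1, "F0", "2018-03-01", "C2")])
    exams = build_examinations(inv, CODE_MAP, RULES)
    assert len(exams) == 1
    row = exams.iloc[0]
    assert row.region == vocab.CHEST_ABDOMEN
    assert row.n_source_codes == 2


def test_duplicate_codes_collapse_to_one_examination():
    inv = _invoices([(1, "F0", "2018-03-01", "C4"), (1, "F0", "2018-03-01", "C4")])
    exams = build_examinations(inv, CODE_MAP, RULES)
    assert len(exams) == 1
    assert exams.iloc[0].n_source_codes == 2


def test_separate_days_stay_separate():
    inv = _invoices([(1, "F0", "2018-03-01", "C1"), (1, "F0", "2018-03-02", "C2")])
    exams = build_examinations(inv, CODE_MAP, RULES)
    assert len(exams) == 2
    assert set(exams.region) == {"chest", "abdomen"}


def test_greedy_merge_leaves_unmatched_region_alone():
    inv = _invoices(
        [(1, "F0", "2018-03-01", c) for c in ("C1", "C2", "C3")]
    )
    exams = build_examinations(inv, CODE_MAP, RULES)
    assert sorted(exams.region) == [vocab.CHEST_ABDOMEN, "pelvis"]


def test_existing_combined_exam_absorbed_by_merge():
    inv = _invoices(
        [(1, "F0", "2018-03-01", c) for c in ("C1", "C2", "C5")]
    )
    exams = build_examinations(inv, CODE_MAP, RULES)
    assert len(exams) == 1
    assert exams.iloc[0].n_source_codes == 3


def test_merge_only_applies_within_ct():
    code_map = {**CODE_MAP, "X1": (vocab.RADIOGRAPHY, "chest"),
                "X2": (vocab.RADIOGRAPHY, "abdomen")}
    inv = _invoices([(1, "F0", "2018-03-01", "X1"), (1, "F0", "2018-03-01", "X2")])
    exams = build_examinations(inv, code_map, RULES)
    assert len(exams) == 2


def test_unmapped_code_strict_raises_listing_codes():
    inv = _invoices([(1, "F0", "2018-03-01", "ZZZ")])
    with pytest.raises(MappingError, match="ZZZ"):
        build_examinations(inv, CODE_MAP, RULES)


def test_unmapped_code_lenient_drops_with_warning():
    inv = _invoices([(1, "F0", "2018-03-01", "ZZZ"), (1, "F0", "2018-03-01", "C4")])
    with pytest.warns(UserWarning, match="ZZZ"):
        exams = build_examinations(inv, CODE_MAP, RULES, strict=False)
    assert len(exams) == 1


def test_overlapping_applicable_rules_raise():
    rules = (
        MergeRule(frozenset({"chest", "abdomen"}), vocab.CHEST_ABDOMEN),
        MergeRule(frozenset({"abdomen", "pelvis"}), "spine"),
    )
    inv = _invoices([(1, "F0", "2018-03-01", c) for c in ("C1", "C2", "C3")])
    with pytest.raises(AmbiguousMergeError):
        build_examinations(inv, CODE_MAP, rules)


def test_idempotence_on_rebuilt_examinations():
    inv = _invoices(
        [
            (1, "F0", "2018-03-01", "C1"),
            (1, "F0", "2018-03-01", "C2"),
            (2, "F1", "2018-05-07", "R1"),
        ]
    )
    exams = build_examinations(inv, CODE_MAP, RULES)
    # re-express each examination as a single synthetic code and rebuild
    remap = {f"K{i}": (r.modality, r.region) for i, r in enumerate(exams.itertuples())}
    again = pd.DataFrame(
        {
            "patient_id": exams.patient_id,
            "facility_id": exams.facility_id,
            "date": exams.date,
            "billing_code": [f"K{i}" for i in range(len(exams))],
        }
    )
    rebuilt = build_examinations(again, remap, RULES)
    pd.testing.assert_frame_equal(
        rebuilt[["patient_id", "facility_id", "date", "modality", "region"]],
        exams[["patient_id", "facility_id", "date", "modality", "region"]],
    )
    assert (rebuilt.n_source_codes == 1).all()


_invoice_strategy = st.lists(
    st.tuples(
        st.integers(1, 2),
        st.sampled_from(["FA", "FB"]),
        st.sampled_from(["2018-01-01", "2018-01-02"]),
        st.sampled_from(sorted(CODE_MAP)),
    ),
    max_size=20,
)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(_invoice_strategy)
def test_matches_exhaustive_grouping_oracle(rows):
    inv = _invoices(rows)
    exams = build_examinations(inv, CODE_MAP, RULES)
    expected = helpers.oracle_build_examinations(
        [dict(zip(["patient_id", "facility_id", "date", "billing_code"], r))
         for r in rows],
        CODE_MAP,
        RULES,
    )
    assert helpers.exams_as_tuples(exams) == expected


@settings(max_examples=100, derandomize=True, deadline=None)
@given(_invoice_strategy)
def test_source_code_conservation_and_merge_monotonicity(rows):
    inv = _invoices(rows)
    merged = build_examinations(inv, CODE_MAP, RULES)
    unmerged = build_examinations(inv, CODE_MAP, merge_rules=())
    assert merged.n_source_codes.sum() == len(rows)
    assert unmerged.n_source_codes.sum() == len(rows)
    assert len(merged) <= len(unmerged)


def test_verification_reproduces_published_differences():
    ref = load_verification_reference()
    table = verification_table(
        dict(zip(ref.modality, ref.billing_frequency_per_1000)),
        dict(zip(ref.modality, ref.ris_frequency_per_1000)),
    )
    diff = dict(zip(table.modality, table.difference_pct))
    assert diff[vocab.TOTAL] == 7.73
    assert diff[vocab.RADIOGRAPHY] == 4.10
    assert diff[vocab.CT] == 19.26
    assert diff[vocab.DIAGNOSTIC_MAMMOGRAPHY] == 9.48
    total = table[table.modality == vocab.TOTAL].iloc[0]
    assert total.invoice_frequency == pytest.approx(595.1)
    assert total.ris_frequency == pytest.approx(549.1)


def test_verification_identical_inputs_all_zero():
    t = verification_table({"CT": 10.0, "X": 5.0}, {"CT": 10.0, "X": 5.0})
    assert (t.difference_pct == 0).all()


def test_verification_zero_invoice_side_is_nan_not_crash():
    t = verification_table({"CT": 0.0}, {"CT": 4.0})
    assert np.isnan(t.loc[t.modality == "CT", "difference_pct"]).all()


def test_verify_against_ris_counts(default_bundle):
    from popdose import build_examinations as build

    exams = build(default_bundle.invoices, default_bundle.code_map)
    table = verify_against_ris(exams, default_bundle.ris)
    # symmetric deletions/duplications: total difference stays near zero
    total = table.loc[table.modality == vocab.TOTAL, "difference_pct"].iloc[0]
    assert abs(total) < 1.0
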