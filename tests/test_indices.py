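"""Mapping code sets to the CCI, FCI, chapter and Haagsma measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbidx import (
    ComorbidityMapper,
    categorize,
    compute_profile,
    map_cci,
    map_chapters,
    map_fci,
    map_haagsma,
    select_comorbidity_codes,
)
from comorbidx.indices import profiles_from_tables, slugify


def flags_on(flags: dict) -> set:
    return {k for k, v in flags.items() if v}


def test_map_counts(condition_maps):
    assert len(condition_maps["CCI"]) == 19
    assert len(condition_maps["FCI"]) == 18
    assert len(condition_maps["HAAGSMA"]) == 7  # six specific + Other
    assert all(c.ranges for m in condition_maps.values() for c in m)


def test_cci_weights_are_charlson(condition_maps):
    weights = {c.condition: c.weight for c in condition_maps["CCI"]}
    assert set(weights.values()) == {1, 2, 3, 6}
    assert weights["Moderate or severe liver disease"] == 3
    assert weights["Metastatic solid tumour"] == weights["AIDS"] == 6


class TestCCI:
    def test_empty(self, condition_maps):
        flags, score = map_cci([], condition_maps["CCI"])
        assert not any(flags.values()) and score == 0

    def test_diabetes_end_organ(self, condition_maps):
        flags, score = map_cci(["E102"], condition_maps["CCI"])
        assert flags_on(flags) == {"Diabetes with end-organ damage"}
        assert score == 2

    def test_leukaemia_plus_aids(self, condition_maps):
        flags, score = map_cci(["C910", "B20"], condition_maps["CCI"])
        assert flags_on(flags) == {"Leukaemia", "AIDS"}
        assert score == 2 + 6

    def test_bare_diabetes_code_is_plain_diabetes(self, condition_maps):
        flags, score = map_cci(["E11"], condition_maps["CCI"])
        assert "Diabetes" in flags_on(flags)

    def test_chf_on_i501(self, condition_maps):
        flags, _ = map_cci(["I501"], condition_maps["CCI"])
        assert "Congestive heart failure" in flags_on(flags)

    def test_f10_counts_as_dementia_as_printed(self, condition_maps):
        flags, _ = map_cci(["F101"], condition_maps["CCI"])
        assert "Dementia" in flags_on(flags)


class TestFCI:
    def test_asthma(self, condition_maps):
        flags, score = map_fci(["J459"], condition_maps["FCI"])
        assert flags_on(flags) == {"Asthma"} and score == 1

    def test_two_conditions(self, condition_maps):
        flags, score = map_fci(["E660", "M810"], condition_maps["FCI"])
        assert flags_on(flags) == {"Obesity", "Osteoporosis"} and score == 2

    def test_duplicates_within_condition(self, condition_maps):
        flags, score = map_fci(["J450", "J451"], condition_maps["FCI"])
        assert score == 1


class TestChapters:
    def test_two_chapters(self):
        flags, count = map_chapters(["F320", "I10"])
        assert flags_on(flags) == {"V", "IX"} and count == 2

    def test_empty(self):
        assert map_chapters([]) == ({ch: False for ch in map_chapters([])[0]}, 0)

    def test_same_chapter_once(self):
        _, count = map_chapters(["I10", "I500"])
        assert count == 1

    def test_unfiltered_code_is_internal_error(self):
        with pytest.raises(RuntimeError):
            map_chapters(["R509"])


class TestHaagsma:
    def test_diabetes(self, condition_maps):
        flags, other, count = map_haagsma(["E109"], condition_maps["HAAGSMA"])
        assert flags_on(flags) == {"Diabetes"} and not other and count == 1

    def test_other_only(self, condition_maps):
        flags, other, count = map_haagsma(["L200"], condition_maps["HAAGSMA"])
        assert not any(flags.values()) and other and count == 0

    def test_ra_not_other(self, condition_maps):
        flags, other, count = map_haagsma(["M050"], condition_maps["HAAGSMA"])
        assert flags_on(flags) == {"Rheumatoid arthritis"} and not other and count == 1

    def test_count_includes_other_option(self, condition_maps):
        _, other, count = map_haagsma(
            ["L200", "E109"], condition_maps["HAAGSMA"], count_includes_other=True
        )
        assert other and count == 2


@pytest.mark.parametrize("score,cat", [(0, "0"), (1, "1"), (2, "2+"), (7, "2+")])
def test_categorize(score, cat):
    assert categorize(score) == cat


def test_categorize_negative_errors():
    with pytest.raises(ValueError):
        categorize(-1)


def test_m480_overlap(condition_maps):
    """M48.0 sits in several printed rows and must flag all of them."""
    prof = compute_profile(["M480"], condition_maps)
    assert prof.fci_flags["Arthritis"]
    assert prof.haagsma_flags["Osteoarthritis"]
    assert prof.haagsma_flags["Backache"]
    assert prof.chapter_flags["XIII"]


def test_i252_heart_attack_not_chf(condition_maps):
    prof = compute_profile(["I252"], condition_maps)
    assert prof.fci_flags["Heart attack"]
    assert not prof.fci_flags["CHF or heart disease"]
    assert prof.cci_flags["Myocardial infarction"]


_POOL = [
    "E102", "E119", "J459", "J440", "I500", "I219", "M050", "M480", "M800",
    "F320", "F100", "G200", "H540", "K250", "C910", "B20", "N180", "L200",
    "T910", "D480", "K704", "I739",
]


@settings(max_examples=100, deadline=None)
@given(st.sets(st.sampled_from(_POOL), max_size=6), st.sampled_from(_POOL))
def test_adding_codes_never_decreases_scores(codes, extra):
    from comorbidx import load_condition_maps

    maps = load_condition_maps()
    before = compute_profile(codes, maps)
    after = compute_profile(codes | {extra}, maps)
    assert after.cci_weight >= before.cci_weight
    assert after.fci_score >= before.fci_score
    assert after.chapter_count >= before.chapter_count
    assert after.haagsma_count >= before.haagsma_count


def test_flagged_codes_are_chapter_flagged(condition_maps, rng):
    """The chapter measure subsumes every condition-specific panel."""
    for _ in range(200):
        codes = list(rng.choice(_POOL, size=rng.integers(1, 5), replace=False))
        prof = compute_profile(codes, condition_maps)
        any_specific = (
            any(prof.cci_flags.values())
            or any(prof.fci_flags.values())
            or any(prof.haagsma_flags.values())
        )
        if any_specific:
            assert prof.chapter_count >= 1


def test_mapper_matches_scalar_path(small_cohort):
    """Vectorised transform equals the per-patient scalar pipeline."""
    mapper = ComorbidityMapper().fit()
    prof = mapper.transform(small_cohort.diagnoses)
    dx = small_cohort.diagnoses
    rng = np.random.default_rng(5)
    for pid in rng.choice(prof.index.to_numpy(), size=50, replace=False):
        rows = dx[dx["patient_id"] == pid]
        codes = select_comorbidity_codes(
            list(zip(rows["prefix"], rows["icd10_code"])), blocklist=mapper.blocklist_
        )
        scalar = compute_profile(codes, mapper.maps_)
        row = prof.loc[pid]
        assert row["cci_weight"] == scalar.cci_weight
        assert row["fci_score"] == scalar.fci_score
        assert row["chapter_count"] == scalar.chapter_count
        assert row["haagsma_count"] == scalar.haagsma_count
        for cond, v in scalar.fci_flags.items():
            assert bool(row[f"fci_{slugify(cond)}"]) == v
        for cond, v in scalar.cci_flags.items():
            assert bool(row[f"cci_{slugify(cond)}"]) == v
        assert row["cci_category"] == scalar.categories["cci_category"]


def test_profiles_reindex_zero_fills():
    patients = pd.DataFrame({"patient_id": [1, 2, 3]})
    dx = pd.DataFrame(
        {"patient_id": [1], "prefix": ["A"], "icd10_code": ["E11.9"]}
    )
    prof = profiles_from_tables(patients, dx)
    assert len(prof) == 3
    assert prof.loc[2, "chapter_count"] == 0
    assert prof.loc[2, "cci_category"] == "0"
    assert prof.loc[1, "fci_diabetes"] == 1


def test_mapper_sklearn_clone():
    from sklearn.base import clone

    m = ComorbidityMapper(haagsma_count_includes_other=True)
    m2 = clone(m)
    assert m2.get_params()["haagsma_count_includes_other"] is True
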