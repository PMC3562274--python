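"""Mapping comorbidity code sets to the four comorbidity measures.

Four measures are supported, all computed from the post-selection code
set of one admission:

* **CCI** — 19 Charlson conditions, each carrying a weight of 1, 2, 3
  or 6; the score is the sum of weights over conditions present (0 if
  none).
* **FCI** — 18 Functional Comorbidity Index conditions, unweighted;
  the score is the number of conditions present (0-18).
* **CHAPTERS** — indicator per ICD-10 chapter among I-XVII and XIX,
  plus the number of distinct chapters represented.
* **HAAGSMA** — the six frequent chronic conditions (chronic
  non-specific lung disease, heart disease, diabetes, backache,
  osteoarthritis, rheumatoid arthritis) plus an "other" indicator; the
  count covers the six specific conditions only (configurable).

All measures are presence-based: duplicate codes never double-count,
but one code may flag several conditions (e.g. M48.0 is both
osteoarthritis and backache under the Haagsma panel).  Scores are
additionally categorised as 0 / 1 / 2+ for use as model covariates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .codes import (
    CodeError,
    CodeRange,
    COMORBIDITY_CHAPTERS,
    assign_chapter,
    canonicalize_code,
    in_range,
    load_blocklist,
)

__all__ = [
    "ConditionMap",
    "ComorbidityProfile",
    "load_condition_maps",
    "map_cci",
    "map_fci",
    "map_chapters",
    "map_haagsma",
    "categorize",
    "compute_profile",
    "ComorbidityMapper",
    "CATEGORY_LEVELS",
]

CATEGORY_LEVELS = ("0", "1", "2+")

MEASURES = ("CCI", "FCI", "HAAGSMA")

#: expected condition counts per measure (sanity-checked at load)
_N_CONDITIONS = {"CCI": 19, "FCI": 18, "HAAGSMA": 7}  # HAAGSMA: 6 + Other

_HAAGSMA_OTHER = "Other disease or injury"


@dataclass(frozen=True)
class ConditionMap:
    """One condition of one measure: its code ranges and (CCI) weight."""

    measure: str
    condition: str
    ranges: tuple[CodeRange, ...]
    weight: int = 0

    def hit(self, codes: Iterable[str]) -> bool:
        return any(in_range(c, r) for c in codes for r in self.ranges)


def slugify(label: str) -> str:
    """Condition label -> column-safe snake_case slug."""
    s = re.sub(r"[^0-9a-zA-Z]+", "_", label.strip().lower()).strip("_")
    return s


def load_condition_maps(path=None) -> dict[str, list[ConditionMap]]:
    """Load the packaged (or user-supplied) condition map table.

    Returns measure -> ordered list of :class:`ConditionMap`.
    """
    src = path if path is not None else resources.files("comorbidx.data").joinpath(
        "condition_maps.csv"
    )
    df = pd.read_csv(src, dtype=str, comment="#")
    out: dict[str, list[ConditionMap]] = {m: [] for m in MEASURES}
    for _, row in df.iterrows():
        ranges = [CodeRange.parse(s) for s in str(row["spans"]).split(";") if s]
        if isinstance(row.get("exact_spans"), str) and row["exact_spans"].strip():
            ranges += [
                CodeRange.parse(s, exact=True)
                for s in row["exact_spans"].split(";")
                if s
            ]
        out[row["measure"]].append(
            ConditionMap(
                measure=row["measure"],
                condition=row["condition"],
                ranges=tuple(ranges),
                weight=int(row["weight"]),
            )
        )
    for m, n in _N_CONDITIONS.items():
        if len(out[m]) != n:
            raise CodeError(f"condition map for {m} has {len(out[m])} rows, expected {n}")
    return out


def categorize(score: int) -> str:
    """Categorise a non-negative burden score as "0", "1" or "2+"."""
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    return "0" if score == 0 else ("1" if score == 1 else "2+")


def _flags(codes: Sequence[str], conditions: Sequence[ConditionMap]) -> dict[str, bool]:
    return {c.condition: c.hit(codes) for c in conditions}


def map_cci(
    codes: Iterable[str], conditions: Sequence[ConditionMap]
) -> tuple[dict[str, bool], int]:
    """Charlson flags and weighted score for a filtered code set."""
    codes = [canonicalize_code(c) for c in codes]
    flags = _flags(codes, conditions)
    score = sum(c.weight for c in conditions if flags[c.condition])
    return flags, score


def map_fci(
    codes: Iterable[str], conditions: Sequence[ConditionMap]
) -> tuple[dict[str, bool], int]:
    """FCI flags and unweighted score (0-18)."""
    codes = [canonicalize_code(c) for c in codes]
    flags = _flags(codes, conditions)
    return flags, sum(flags.values())


def map_chapters(codes: Iterable[str]) -> tuple[dict[str, bool], int]:
    """Chapter indicators over I-XVII and XIX, plus the distinct count.

    Codes must already be comorbidity-filtered; a code landing in
    chapter XVIII or XX-XXII indicates a filtering bug upstream.
    """
    flags = {ch: False for ch in COMORBIDITY_CHAPTERS}
    for c in codes:
        chap = assign_chapter(c)
        if chap not in flags:
            raise RuntimeError(
                f"code {c} in chapter {chap} reached chapter mapping; "
                "comorbidity filtering should have removed it"
            )
        flags[chap] = True
    return flags, sum(flags.values())


def map_haagsma(
    codes: Iterable[str],
    conditions: Sequence[ConditionMap],
    count_includes_other: bool = False,
) -> tuple[dict[str, bool], bool, int]:
    """Haagsma six-condition flags, the "other" flag, and the count.

    By default the count covers the six specific conditions only; set
    ``count_includes_other`` to include the "other" indicator.
    """
    codes = [canonicalize_code(c) for c in codes]
    specific = [c for c in conditions if c.condition != _HAAGSMA_OTHER]
    other_map = next(c for c in conditions if c.condition == _HAAGSMA_OTHER)
    flags = _flags(codes, specific)
    other = other_map.hit(codes)
    count = sum(flags.values()) + (int(other) if count_includes_other else 0)
    return flags, other, count


@dataclass
class ComorbidityProfile:
    """Per-patient condition flags, scores and 0/1/2+ categories."""

    cci_flags: dict[str, bool]
    cci_weight: int
    fci_flags: dict[str, bool]
    fci_score: int
    chapter_flags: dict[str, bool]
    chapter_count: int
    haagsma_flags: dict[str, bool]
    haagsma_other: bool
    haagsma_count: int

    @property
    def categories(self) -> dict[str, str]:
        return {
            "cci_category": categorize(self.cci_weight),
            "fci_category": categorize(self.fci_score),
            "chapter_category": categorize(self.chapter_count),
            "haagsma_category": categorize(self.haagsma_count),
        }


def compute_profile(
    codes: Iterable[str],
    maps: Mapping[str, Sequence[ConditionMap]] | None = None,
    haagsma_count_includes_other: bool = False,
) -> ComorbidityProfile:
    """Map one filtered code set to all four measures."""
    if maps is None:
        maps = load_condition_maps()
    codes = [canonicalize_code(c) for c in codes]
    cci_flags, cci_weight = map_cci(codes, maps["CCI"])
    fci_flags, fci_score = map_fci(codes, maps["FCI"])
    ch_flags, ch_count = map_chapters(codes)
    h_flags, h_other, h_count = map_haagsma(
        codes, maps["HAAGSMA"], count_includes_other=haagsma_count_includes_other
    )
    return ComorbidityProfile(
        cci_flags=cci_flags,
        cci_weight=cci_weight,
        fci_flags=fci_flags,
        fci_score=fci_score,
        chapter_flags=ch_flags,
        chapter_count=ch_count,
        haagsma_flags=h_flags,
        haagsma_other=h_other,
        haagsma_count=h_count,
    )


class ComorbidityMapper(BaseEstimator, TransformerMixin):
    """Transform prefixed admission diagnosis lists into profile features.

    Input to :meth:`transform` is a long DataFrame of diagnosis rows
    with columns ``patient_id``, ``prefix`` (P/A/C) and ``icd10_code``
    (dotted or dotless).  Output is a wide DataFrame indexed by
    ``patient_id`` with one column per condition flag (0/1), the four
    burden scores, and the 0/1/2+ categories.  Patients whose codes
    are all filtered out get an all-zero row; patients absent from the
    input are absent from the output (reindex downstream).

    Parameters
    ----------
    map_path, blocklist_path : optional paths overriding packaged data.
    haagsma_count_includes_other : bool, default False
        Whether the Haagsma burden count includes the "other" flag.
    """

    def __init__(
        self,
        map_path=None,
        blocklist_path=None,
        haagsma_count_includes_other: bool = False,
    ):
        self.map_path = map_path
        self.blocklist_path = blocklist_path
        self.haagsma_count_includes_other = haagsma_count_includes_other

    # -- sklearn plumbing -------------------------------------------------
    def fit(self, X=None, y=None) -> "ComorbidityMapper":
        self.maps_ = load_condition_maps(self.map_path)
        self.blocklist_ = load_blocklist(self.blocklist_path)
        cols: list[str] = []
        cols += [f"cci_{slugify(c.condition)}" for c in self.maps_["CCI"]]
        cols += ["cci_weight", "cci_category"]
        cols += [f"fci_{slugify(c.condition)}" for c in self.maps_["FCI"]]
        cols += ["fci_score", "fci_category"]
        cols += [f"chapter_{ch.lower()}" for ch in COMORBIDITY_CHAPTERS]
        cols += ["chapter_count", "chapter_category"]
        cols += [
            f"haagsma_{slugify(c.condition)}"
            for c in self.maps_["HAAGSMA"]
            if c.condition != _HAAGSMA_OTHER
        ]
        cols += ["haagsma_other", "haagsma_count", "haagsma_category"]
        self.feature_names_out_ = cols
        return self

    def _check_fitted(self):
        if not hasattr(self, "maps_"):
            self.fit()

    def get_feature_names_out(self, input_features=None):
        self._check_fitted()
        return np.asarray(self.feature_names_out_, dtype=object)

    # -- core -------------------------------------------------------------
    def _code_incidence(self, unique_codes: Sequence[str]) -> pd.DataFrame:
        """Condition-hit incidence matrix over unique canonical codes."""
        rows = {}
        for code in unique_codes:
            rec: dict[str, bool] = {}
            for c in self.maps_["CCI"]:
                rec[f"cci_{slugify(c.condition)}"] = c.hit([code])
            for c in self.maps_["FCI"]:
                rec[f"fci_{slugify(c.condition)}"] = c.hit([code])
            chap = assign_chapter(code)
            for ch in COMORBIDITY_CHAPTERS:
                rec[f"chapter_{ch.lower()}"] = chap == ch
            for c in self.maps_["HAAGSMA"]:
                if c.condition != _HAAGSMA_OTHER:
                    rec[f"haagsma_{slugify(c.condition)}"] = c.hit([code])
            other_map = next(
                c for c in self.maps_["HAAGSMA"] if c.condition == _HAAGSMA_OTHER
            )
            rec["haagsma_other"] = other_map.hit([code])
            rows[code] = rec
        return pd.DataFrame.from_dict(rows, orient="index").astype(bool)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Map diagnosis rows to per-patient comorbidity profiles."""
        self._check_fitted()
        req = {"patient_id", "prefix", "icd10_code"}
        missing = req - set(X.columns)
        if missing:
            raise ValueError(f"diagnosis table missing columns: {sorted(missing)}")
        df = X[["patient_id", "prefix", "icd10_code"]].copy()
        canon_map = {u: canonicalize_code(u) for u in df["icd10_code"].unique()}
        df["code"] = df["icd10_code"].map(canon_map)

        # per-unique-code selection attributes (rules i-v act row-wise)
        uniq = pd.unique(df["code"])
        chap = {u: assign_chapter(u) for u in uniq}
        blocked = {u: any(in_range(u, r) for r in self.blocklist_) for u in uniq}
        code_chap = df["code"].map(chap)
        keep = (
            (df["prefix"] != "C")
            & ~((df["prefix"] == "P") & (code_chap == "XIX"))
            & (code_chap != "XVIII")
            & ~code_chap.isin(["XX", "XXI", "XXII"])
            & ~df["code"].map(blocked)
        )
        kept = df.loc[keep, ["patient_id", "code"]].drop_duplicates()

        all_patients = pd.Index(pd.unique(df["patient_id"]), name="patient_id")
        flag_cols = [
            c
            for c in self.feature_names_out_
            if c
            not in (
                "cci_weight", "cci_category", "fci_score", "fci_category",
                "chapter_count", "chapter_category", "haagsma_count",
                "haagsma_category",
            )
        ]
        if len(kept):
            inc = self._code_incidence(list(pd.unique(kept["code"])))
            hit = inc.loc[kept["code"].to_numpy()].set_axis(
                kept["patient_id"].to_numpy(), axis=0
            )
            flags = hit.groupby(level=0).any().reindex(all_patients, fill_value=False)
        else:
            flags = pd.DataFrame(False, index=all_patients, columns=flag_cols)
        flags = flags.reindex(columns=flag_cols, fill_value=False)

        out = flags.astype(int)
        weights = {
            f"cci_{slugify(c.condition)}": c.weight for c in self.maps_["CCI"]
        }
        cci_cols = list(weights)
        out["cci_weight"] = sum(
            out[col] * w for col, w in weights.items()
        ) if cci_cols else 0
        fci_cols = [f"fci_{slugify(c.condition)}" for c in self.maps_["FCI"]]
        out["fci_score"] = out[fci_cols].sum(axis=1)
        ch_cols = [f"chapter_{ch.lower()}" for ch in COMORBIDITY_CHAPTERS]
        out["chapter_count"] = out[ch_cols].sum(axis=1)
        h_cols = [
            f"haagsma_{slugify(c.condition)}"
            for c in self.maps_["HAAGSMA"]
            if c.condition != _HAAGSMA_OTHER
        ]
        out["haagsma_count"] = out[h_cols].sum(axis=1)
        if self.haagsma_count_includes_other:
            out["haagsma_count"] += out["haagsma_other"]
        for score, cat in [
            ("cci_weight", "cci_category"),
            ("fci_score", "fci_category"),
            ("chapter_count", "chapter_category"),
            ("haagsma_count", "haagsma_category"),
        ]:
            out[cat] = out[score].map(categorize)
        out.index.name = "patient_id"
        return out[self.feature_names_out_]


def profiles_from_tables(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    mapper: ComorbidityMapper | None = None,
) -> pd.DataFrame:
    """Profiles for every patient in ``patients`` (zero-filled if no codes)."""
    if mapper is None:
        mapper = ComorbidityMapper().fit()
    mapper._check_fitted()
    prof = mapper.transform(diagnoses)
    prof = prof.reindex(pd.Index(patients["patient_id"], name="patient_id"))
    score_cols = ["cci_weight", "fci_score", "chapter_count", "haagsma_count"]
    cat_cols = ["cci_category", "fci_category", "chapter_category", "haagsma_category"]
    flag_cols = [c for c in prof.columns if c not in score_cols + cat_cols]
    prof[flag_cols] = prof[flag_cols].fillna(0).astype(int)
    prof[score_cols] = prof[score_cols].fillna(0).astype(int)
    for c in cat_cols:
        prof[c] = prof[c].fillna("0")
    return prof
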