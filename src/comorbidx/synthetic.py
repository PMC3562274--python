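"""Synthetic orthopaedic trauma registry generator.

The real cohort this package's analysis was designed around (a state
orthopaedic trauma registry) is not publicly deposited, so this module
generates registry-shaped cohorts with the same statistical structure:

* marginal distributions of age group (8 levels), gender, injury
  mechanism (8 levels) and orthopaedic injury group (10 levels) default
  to the published followed-up cohort margins;
* ~46 comorbid conditions sampled marginally independently, each with a
  default prevalence matching the published condition table and a pool
  of ICD-10-AM codes from which one code is drawn uniformly and
  attached with prefix ``A``.  Pools are pairwise disjoint so the
  configured marginal prevalences stay identifiable after mapping.
  Optional age multipliers (default on) make older patients carry more
  comorbidity while preserving the marginal prevalence;
* injury principal diagnoses (prefix ``P``, Chapter XIX) per injury
  group, concurrent non-orthopaedic injury codes (prefix ``P``) for the
  indicator flags, occasional prefix-``C`` complication noise, and a
  small rate of erroneously coded acute complications (prefix ``A``,
  codes on the default blocklist);
* 12-month GOS-E drawn from a logistic outcome model on age, injury
  group, the non-orthopaedic flags and the 0/1/2+ comorbidity burden
  (ICD-chapter count category), with the intercept calibrated so the
  recovered (GOS-E 7-8) fraction hits a target of 0.42.  Non-recovered
  mass is spread uniformly over GOS-E 2-6, recovered over 7-8;
* per-stratum loss to follow-up (higher for younger, male and motor
  vehicle strata) removing GOS-E from "lost" records, defaulting to an
  overall loss around 12.6%.

Everything is driven by a :class:`SyntheticConfig` and a single seed;
identical seed and config give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .codes import assign_chapter

__all__ = [
    "AGE_GROUPS",
    "GENDERS",
    "MECHANISMS",
    "INJURY_GROUPS",
    "GeneratorCondition",
    "SyntheticConfig",
    "Cohort",
    "generate_registry",
    "apply_loss_to_followup",
]

AGE_GROUPS = ("15-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85+")
GENDERS = ("male", "female")
MECHANISMS = (
    "low_fall", "motor_vehicle", "high_fall", "motorcycle",
    "pedestrian", "pedal_cyclist", "collision", "other",
)
INJURY_GROUPS = (
    "isolated_lower_extremity_fracture",
    "isolated_upper_extremity_fracture",
    "spinal_fractures_only",
    "multiple_lower_extremity_fractures",
    "upper_and_lower_extremity_fractures",
    "soft_tissue_injury",
    "spine_and_lower_extremity_fractures",
    "multiple_upper_extremity_fractures",
    "spine_and_upper_extremity_fractures",
    "spine_upper_and_lower_extremity_fractures",
)

# cohort margins: counts from the published followed-up column
_AGE_COUNTS = (1704, 1672, 1694, 1655, 1577, 1480, 2071, 1666)
_INJURY_COUNTS = (5271, 2809, 1741, 972, 620, 540, 465, 440, 431, 230)
_MECH_COUNTS = (5390, 1869, 1816, 1349, 579, 616, 505, 1395)
_N_FOLLOWED = 13519


def _probs(counts) -> tuple[float, ...]:
    t = float(sum(counts))
    return tuple(c / t for c in counts)


#: principal injury diagnosis codes (prefix P, Chapter XIX) per injury group
INJURY_PRINCIPAL_CODES: dict[str, tuple[str, ...]] = {
    "isolated_lower_extremity_fracture": ("S720",),
    "isolated_upper_extremity_fracture": ("S525",),
    "spinal_fractures_only": ("S320",),
    "multiple_lower_extremity_fractures": ("S721", "S821"),
    "upper_and_lower_extremity_fractures": ("S525", "S821"),
    "soft_tissue_injury": ("S835",),
    "spine_and_lower_extremity_fractures": ("S320", "S720"),
    "multiple_upper_extremity_fractures": ("S422", "S525"),
    "spine_and_upper_extremity_fractures": ("S320", "S422"),
    "spine_upper_and_lower_extremity_fractures": ("S320", "S525", "S720"),
}

#: concurrent non-orthopaedic injuries per indicator flag (prefix P)
FLAG_CODES = {
    "head_injury": "S065",
    "rib_fractures": "S224",
    "organ_injury": "S360",
    "burns": "T300",
}

#: prefix-C in-hospital complication noise codes
COMPLICATION_CODES = ("J960", "T813", "N390", "I802")


@dataclass(frozen=True)
class GeneratorCondition:
    """One sampled comorbid condition: disjoint code pool + prevalence."""

    name: str
    codes: tuple[str, ...]
    prevalence: float
    comorbidity: bool = True  # False: blocklisted noise, excluded from burden


# Default condition list.  Prevalences mirror the published condition
# table (fractions of 13,519); pools are pairwise disjoint.
DEFAULT_CONDITIONS: tuple[GeneratorCondition, ...] = (
    GeneratorCondition("rheumatoid_arthritis", ("M050", "M059", "M060", "M069", "M080"), 0.0015),
    GeneratorCondition("osteoarthritis", ("M150", "M159", "M160", "M170", "M179", "M190", "M199", "M470", "M479"), 0.010),
    GeneratorCondition("backache", ("M480", "M510", "M511", "M543", "M544", "M545", "M549"), 0.004),
    GeneratorCondition("osteoporosis", ("M800", "M805", "M809", "M810", "M819"), 0.022),
    GeneratorCondition("degenerative_disc", ("M500", "M501", "M509"), 0.002),
    GeneratorCondition("musculoskeletal_other", ("M209", "M255", "M400", "M430", "M625", "M790"), 0.025),
    GeneratorCondition("asthma", ("J450", "J451", "J459"), 0.002),
    GeneratorCondition("copd", ("J430", "J439", "J440", "J441", "J449"), 0.017),
    GeneratorCondition("respiratory_other", ("J301", "J320", "J342", "J380", "J390"), 0.010),
    GeneratorCondition("angina", ("I200", "I208", "I209"), 0.002),
    GeneratorCondition("heart_disease", ("I10", "I110", "I350", "I420", "I480", "I489", "I500", "I501", "I509"), 0.050),
    GeneratorCondition("myocardial_infarction", ("I210", "I219", "I220", "I252"), 0.007),
    GeneratorCondition("stroke", ("I600", "I610", "I630", "I639", "I64"), 0.004),
    GeneratorCondition("pvd", ("I702", "I739"), 0.004),
    GeneratorCondition("circulatory_other", ("I830", "I870", "I951"), 0.030),
    GeneratorCondition("hemiplegia", ("G810", "G811", "G819"), 0.008),
    GeneratorCondition("neurological", ("G20", "G250", "G400", "G409", "G439", "G629"), 0.038),
    GeneratorCondition("diabetes", ("E109", "E119", "E139", "E149", "E102", "E103", "E104", "E112", "E113", "E114", "E105", "E115"), 0.060),
    GeneratorCondition("obesity", ("E660", "E668", "E669"), 0.010),
    GeneratorCondition("thyroid_metabolic", ("E039", "E041", "E780", "E785", "E835"), 0.010),
    GeneratorCondition("dementia", ("F000", "F001", "F010", "F03"), 0.025),
    GeneratorCondition("alcohol_disorder", ("F100", "F101", "F102", "F105"), 0.108),
    GeneratorCondition("depression", ("F320", "F329", "F331"), 0.002),
    GeneratorCondition("anxiety", ("F400", "F410", "F411", "F419"), 0.006),
    GeneratorCondition("mental_other", ("F200", "F250", "F600", "F609"), 0.004),
    GeneratorCondition("visual_impairment", ("H530", "H533", "H540", "H544"), 0.008),
    GeneratorCondition("eye_other", ("H250", "H269", "H400", "H409"), 0.012),
    GeneratorCondition("hearing_impairment", ("H900", "H903", "H910", "H919"), 0.007),
    GeneratorCondition("ear_other", ("H600", "H612", "H810", "H819"), 0.003),
    GeneratorCondition("upper_gi", ("K210", "K219", "K250", "K259", "K270", "K295"), 0.005),
    GeneratorCondition("digestive_other", ("K500", "K519", "K573", "K590", "K599"), 0.014),
    GeneratorCondition("liver_mild", ("K700", "K703", "K730", "K740", "K746"), 0.007),
    GeneratorCondition("liver_severe", ("K704", "K720", "K721", "K729", "K766"), 0.002),
    GeneratorCondition("renal_disease", ("N180", "N183", "N185", "N189", "N19"), 0.035),
    GeneratorCondition("gu_other", ("N300", "N320", "N390", "N40"), 0.008),
    GeneratorCondition("metastatic_cancer", ("C780", "C782", "C790", "C795", "C798"), 0.008),
    GeneratorCondition("any_tumour", ("D120", "D250", "D350", "D480", "D489"), 0.005),
    GeneratorCondition("leukaemia", ("C910", "C911", "C950"), 0.001),
    GeneratorCondition("lymphoma", ("C820", "C829", "C851"), 0.0005),
    GeneratorCondition("aids", ("B20", "B21", "B24"), 0.0012),
    GeneratorCondition("infection", ("A049", "A090", "A410", "A419", "B962", "B978"), 0.030),
    GeneratorCondition("blood_disease", ("D509", "D630", "D640", "D649", "D689"), 0.050),
    GeneratorCondition("pregnancy", ("O200", "O269"), 0.0002),
    GeneratorCondition("perinatal", ("P961",), 0.0001),
    GeneratorCondition("congenital", ("Q210", "Q613", "Q790"), 0.004),
    GeneratorCondition("skin_disease", ("L089", "L209", "L400", "L989"), 0.025),
    GeneratorCondition("old_injury", ("T910", "T930", "T981"), 0.006),
    # erroneously coded acute complications (on the default blocklist;
    # filtered out upstream of every comorbidity measure)
    GeneratorCondition("erroneous_complication", ("D62", "N179", "J189"), 0.020, comorbidity=False),
)

# age multipliers on condition prevalence (older -> more comorbidity),
# normalised below so the marginal prevalence is preserved
_RAW_AGE_MULTIPLIERS = (0.30, 0.40, 0.55, 0.75, 1.00, 1.30, 1.70, 2.00)


def _normalised_age_multipliers(age_probs) -> tuple[float, ...]:
    w = float(np.dot(age_probs, _RAW_AGE_MULTIPLIERS))
    return tuple(m / w for m in _RAW_AGE_MULTIPLIERS)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic registry.

    Defaults emulate the published cohort: its marginal age, mechanism
    and injury-group distributions, condition prevalences, a 42%
    recovered fraction, and ~12.6% loss to follow-up concentrated in
    younger, male, motor-vehicle strata.
    """

    n: int = _N_FOLLOWED
    seed: int = 0
    age_probs: tuple[float, ...] = _probs(_AGE_COUNTS)
    gender_probs: tuple[float, ...] = (0.545, 0.455)
    mechanism_probs: tuple[float, ...] = _probs(_MECH_COUNTS)
    injury_probs: tuple[float, ...] = _probs(_INJURY_COUNTS)
    flag_probs: dict = field(
        default_factory=lambda: {
            "head_injury": 0.05,
            "rib_fractures": 0.04,
            "organ_injury": 0.03,
            "burns": 0.005,
        }
    )
    conditions: tuple[GeneratorCondition, ...] = DEFAULT_CONDITIONS
    age_dependent_comorbidity: bool = True
    complication_rate: float = 0.05
    # outcome model (log-odds, relative to the first level of each block)
    age_effects: tuple[float, ...] = (0.0, -0.15, -0.30, -0.50, -0.70, -0.90, -1.30, -1.90)
    injury_effects: tuple[float, ...] = (0.0, 0.50, 0.30, -0.40, -0.50, 0.60, -0.50, -0.10, -0.10, -0.80)
    flag_effects: dict = field(
        default_factory=lambda: {
            "head_injury": -0.70,
            "rib_fractures": -0.30,
            "organ_injury": -0.30,
            "burns": -0.60,
        }
    )
    # effect of the 0/1/2+ chapter-count burden category (levels 1 and 2+)
    comorbidity_effects: tuple[float, float] = (-0.45, -0.90)
    target_recovered: float = 0.42
    # loss to follow-up
    age_loss_probs: tuple[float, ...] = (0.177, 0.198, 0.154, 0.120, 0.114, 0.098, 0.089, 0.067)
    gender_loss_multipliers: tuple[float, float] = (1.12, 0.86)
    mechanism_loss_multiplier: dict = field(
        default_factory=lambda: {"motor_vehicle": 1.30}
    )
    mechanism_loss_base: float = 0.95

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name, probs, k in (
            ("age_probs", self.age_probs, len(AGE_GROUPS)),
            ("gender_probs", self.gender_probs, 2),
            ("mechanism_probs", self.mechanism_probs, len(MECHANISMS)),
            ("injury_probs", self.injury_probs, len(INJURY_GROUPS)),
        ):
            probs = np.asarray(probs, dtype=float)
            if len(probs) != k:
                raise ValueError(f"{name} must have {k} entries")
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"{name} entries must be in [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {probs.sum()!r})")
        for c in self.conditions:
            if not 0.0 <= c.prevalence <= 1.0:
                raise ValueError(f"prevalence of {c.name} outside [0, 1]")
            if not c.codes:
                raise ValueError(f"condition {c.name} has an empty code pool")
        if not 0.0 < self.target_recovered < 1.0:
            raise ValueError("target_recovered must be in (0, 1)")
        for p in self.age_loss_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("loss probabilities must be in [0, 1]")


class Cohort(NamedTuple):
    """A generated registry extract: covariates + long diagnosis table."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame


def _condition_chapters(conditions) -> dict[str, set[str]]:
    return {
        c.name: {assign_chapter(code) for code in c.codes} for c in conditions
    }


def generate_registry(config: SyntheticConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate ``config.n`` synthetic patient records.

    Returns a :class:`Cohort` of two DataFrames: ``patients`` (one row
    per patient: demographics, injury fields, flags, ``gose``) and
    ``diagnoses`` (long: patient_id, seq, prefix, icd10_code).
    Deterministic for a fixed config and seed (``seed`` overrides
    ``config.seed``).
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    age_idx = rng.choice(len(AGE_GROUPS), size=n, p=np.asarray(config.age_probs))
    gender_idx = rng.choice(2, size=n, p=np.asarray(config.gender_probs))
    mech_idx = rng.choice(len(MECHANISMS), size=n, p=np.asarray(config.mechanism_probs))
    inj_idx = rng.choice(len(INJURY_GROUPS), size=n, p=np.asarray(config.injury_probs))
    flags = {
        name: (rng.random(n) < p).astype(int)
        for name, p in config.flag_probs.items()
    }

    # conditions: marginally independent Bernoulli draws; optional age
    # multipliers tilt prevalence toward older patients without moving
    # the marginal (multipliers are normalised against age_probs)
    if config.age_dependent_comorbidity:
        mult = np.asarray(_normalised_age_multipliers(config.age_probs))[age_idx]
    else:
        mult = np.ones(n)
    cond_codes: dict[str, np.ndarray] = {}
    cond_has: dict[str, np.ndarray] = {}
    for c in config.conditions:
        has = rng.random(n) < np.clip(c.prevalence * mult, 0.0, 1.0)
        cond_has[c.name] = has
        cond_codes[c.name] = rng.choice(len(c.codes), size=n)

    # comorbidity burden = number of distinct ICD chapters represented
    # by the drawn comorbidity codes (the generating model's covariate)
    chap_ids = sorted({ch for s in _condition_chapters(config.conditions).values() for ch in s})
    chap_pos = {ch: i for i, ch in enumerate(chap_ids)}
    chap_hit = np.zeros((n, len(chap_ids)), dtype=bool)
    for c in config.conditions:
        if not c.comorbidity:
            continue
        code_chaps = [assign_chapter(code) for code in c.codes]
        for j, ch in enumerate(code_chaps):
            sel = cond_has[c.name] & (cond_codes[c.name] == j)
            chap_hit[sel, chap_pos[ch]] = True
    burden = np.minimum(chap_hit.sum(axis=1), 2)  # 0 / 1 / 2+

    lp = (
        np.asarray(config.age_effects)[age_idx]
        + np.asarray(config.injury_effects)[inj_idx]
        + sum(
            config.flag_effects.get(name, 0.0) * arr
            for name, arr in flags.items()
        )
        + np.asarray((0.0,) + tuple(config.comorbidity_effects))[burden]
    )

    # calibrate the intercept so the expected recovered fraction hits target
    def gap(c):
        return expit(lp + c).mean() - config.target_recovered

    intercept = brentq(gap, -20.0, 20.0)
    p_rec = expit(lp + intercept)
    recovered = rng.random(n) < p_rec
    gose = np.where(recovered, rng.integers(7, 9, size=n), rng.integers(2, 7, size=n))

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age_group": np.asarray(AGE_GROUPS)[age_idx],
            "gender": np.asarray(GENDERS)[gender_idx],
            "mechanism": np.asarray(MECHANISMS)[mech_idx],
            "injury_group": np.asarray(INJURY_GROUPS)[inj_idx],
            **flags,
            "gose": pd.array(gose, dtype="Int64"),
        }
    )

    # long diagnosis table: injury P codes, flag P codes, condition A
    # codes, prefix-C complication noise
    pid, prefix, code = [], [], []
    inj_names = np.asarray(INJURY_GROUPS)[inj_idx]
    for g, codes in INJURY_PRINCIPAL_CODES.items():
        sel = np.flatnonzero(inj_names == g)
        for cd in codes:
            pid.append(sel + 1)
            prefix.append(np.repeat("P", len(sel)))
            code.append(np.repeat(cd, len(sel)))
    for name, arr in flags.items():
        sel = np.flatnonzero(arr == 1)
        pid.append(sel + 1)
        prefix.append(np.repeat("P", len(sel)))
        code.append(np.repeat(FLAG_CODES[name], len(sel)))
    for c in config.conditions:
        sel = np.flatnonzero(cond_has[c.name])
        pid.append(sel + 1)
        prefix.append(np.repeat("A", len(sel)))
        code.append(np.asarray(c.codes, dtype=object)[cond_codes[c.name][sel]])
    compl = rng.random(n) < config.complication_rate
    sel = np.flatnonzero(compl)
    pid.append(sel + 1)
    prefix.append(np.repeat("C", len(sel)))
    code.append(
        np.asarray(COMPLICATION_CODES, dtype=object)[
            rng.choice(len(COMPLICATION_CODES), size=len(sel))
        ]
    )

    diagnoses = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid),
            "prefix": np.concatenate(prefix),
            "icd10_code": np.concatenate(code),
        }
    ).sort_values(["patient_id", "prefix"], kind="stable", ignore_index=True)
    diagnoses["seq"] = diagnoses.groupby("patient_id").cumcount() + 1
    diagnoses = diagnoses[["patient_id", "seq", "prefix", "icd10_code"]]
    return Cohort(patients, diagnoses)


def apply_loss_to_followup(
    cohort: Cohort, config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[Cohort, Cohort]:
    """Partition a cohort into followed-up and lost-to-follow-up parts.

    Loss probability per record is the age-group base probability times
    gender and mechanism multipliers; lost records have GOS-E removed.
    Returns ``(followed, lost)``; their patients partition the input.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 0x10F)
    pat = cohort.patients
    age_pos = {g: i for i, g in enumerate(AGE_GROUPS)}
    base = np.asarray(config.age_loss_probs)[pat["age_group"].map(age_pos).to_numpy()]
    gmult = np.where(
        pat["gender"].to_numpy() == "male",
        config.gender_loss_multipliers[0],
        config.gender_loss_multipliers[1],
    )
    mmult = pat["mechanism"].map(
        lambda m: config.mechanism_loss_multiplier.get(m, config.mechanism_loss_base)
    ).to_numpy()
    p_loss = np.clip(base * gmult * mmult, 0.0, 1.0)
    lost_mask = rng.random(len(pat)) < p_loss

    lost_pat = pat.loc[lost_mask].copy()
    lost_pat["gose"] = pd.array([pd.NA] * len(lost_pat), dtype="Int64")
    fu_pat = pat.loc[~lost_mask].copy()
    fu_ids = set(fu_pat["patient_id"])
    dx = cohort.diagnoses
    fu_dx = dx[dx["patient_id"].isin(fu_ids)].reset_index(drop=True)
    lost_dx = dx[~dx["patient_id"].isin(fu_ids)].reset_index(drop=True)
    return (
        Cohort(fu_pat.reset_index(drop=True), fu_dx),
        Cohort(lost_pat.reset_index(drop=True), lost_dx),
    )
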