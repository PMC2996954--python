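"""Synthetic cohort, QMPSF peak-table, CN-matrix and expression generators.

Emulates the data a candidate-locus CNV association study consumes: a
population cohort with a biallelic-dosage CNV locus (low 1X / high 2X
classes), multiplex-PCR peak heights against an X-linked reference
(Factor VIII: one copy in males, two in females) and a copy-number-invariant
autosomal reference (CN2-2), a probe-level copy-number matrix with an
embedded copy-number-variable region, and qPCR Ct tables where transcript
abundance tracks gene dosage.

Trait distributions default to the published non-diabetic group summaries
(mean +/- SD per sex and copy-number class); traits are drawn independently
per (sex, genotype) cell, since only marginal summaries are available.
HOMA-IR is derived from fasting insulin and glucose rather than drawn, so
the standard identity insulin*glucose/405 holds for every subject.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnvr import CNMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "MatchingParams",
    "CNMatrixParams",
    "ExpressionParams",
    "CaseParams",
    "SubjectRecord",
    "ExpressionRecord",
    "ExpressionData",
    "MatchedSet",
    "ConfigurationError",
    "DataError",
    "MatchingError",
    "ASSOCIATION_TRAITS",
    "AGE", "BMI", "GLUCOSE_0HR", "GLUCOSE_2HR", "INSULIN_0HR", "HOMA_IR",
    "AMPLICONS", "AMPLICON_COPIES",
    "simulate_cohort",
    "simulate_cases",
    "simulate_control_pool",
    "simulate_peak_table",
    "assign_diabetes",
    "match_nested_case_control",
    "simulate_cn_matrix",
    "simulate_expression",
    "cohort_to_frame",
    "default_trait_params",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class DataError(ValueError):
    """Input data violate a precondition."""


class MatchingError(ValueError):
    """Case-control matching cannot proceed."""


# ---------------------------------------------------------------------------
# Trait parameter table: (men low-CN mean, sd, men high-CN mean, sd,
#                          women low-CN mean, sd, women high-CN mean, sd)
# Published group summaries for the non-diabetic cohort (574 men, 493 women).
# ---------------------------------------------------------------------------

AGE = "Age (year)"
BMI = "Body mass index (BMI) (kg/m^2)"
GLUCOSE_0HR = "Glucose_0hr (mg/dL)"
GLUCOSE_1HR = "Glucose_1hr (mg/dL)"
GLUCOSE_2HR = "Glucose_2hr (mg/dL)"
INSULIN_0HR = "Insulin_0hr (μIU/ml)"
HOMA_IR = "HOMA-IR"

_TABLE: dict[str, tuple[float, ...]] = {
    AGE: (49.1, 8.4, 50.7, 8.6, 52.9, 9.0, 52.5, 8.6),
    "Height (cm)": (167.2, 5.7, 167.6, 6.1, 153.9, 5.9, 153.7, 5.6),
    "Weight (kg)": (67.1, 9.4, 66.6, 9.4, 57.3, 8.6, 57.6, 7.7),
    "Pulse (counts)": (61.0, 6.5, 61.4, 7.2, 64.2, 7.1, 63.8, 6.8),
    "Systolic blood pressure (mmHg)": (114.0, 14.7, 114.6, 13.9, 115.5, 17.6, 115.8, 15.7),
    "Diastolic blood pressure (mmHg)": (75.1, 11.2, 74.5, 10.6, 72.7, 11.1, 73.4, 10.0),
    "Distal radius Z": (0.16, 1.23, 0.48, 1.35, 0.91, 1.48, 1.08, 1.53),
    "Midshaft tibia Z": (0.47, 1.06, 0.68, 1.18, -0.36, 1.30, -0.39, 1.31),
    "Waist circumference (cm)": (82.2, 7.3, 81.4, 7.1, 81.0, 9.3, 81.7, 9.2),
    "Hip circumferences (cm)": (93.9, 5.6, 92.2, 6.2, 91.9, 6.3, 91.7, 6.0),
    "Waist-to-hip ratio (WHR)": (0.88, 0.06, 0.88, 0.06, 0.88, 0.08, 0.89, 0.08),
    "Body fat (%)": (20.5, 4.9, 19.4, 4.5, 29.6, 5.8, 30.3, 4.8),
    "Visceral fat (%)": (0.89, 0.04, 0.88, 0.04, 0.89, 0.05, 0.89, 0.05),
    "Obesity degree (%)": (112.2, 12.7, 110.2, 12.5, 119.9, 17.2, 120.8, 15.1),
    BMI: (23.9, 2.7, 23.6, 2.7, 24.2, 3.3, 24.4, 2.9),
    "Total cholesterol (mg/dL)": (199.1, 36.7, 181.7, 32.8, 188.0, 34.3, 180.9, 31.0),
    "HDL-cholesterol (mg/dL)": (45.6, 8.5, 44.4, 9.5, 47.7, 9.9, 45.1, 9.5),
    "Triglyceride (mg/dL)": (146.9, 86.1, 151.4, 82.5, 122.0, 68.7, 137.1, 73.2),
    "C-reactive protein (mg/dL)": (0.19, 0.31, 0.20, 0.21, 0.15, 0.24, 0.21, 0.52),
    "WBC (10^3/μL)": (6.6, 1.7, 6.4, 1.7, 5.8, 1.5, 5.6, 1.4),
    "RBC (10^6/μL)": (4.8, 0.4, 4.7, 0.4, 4.1, 0.3, 4.1, 0.3),
    "Hemoglobin (g/dL)": (14.7, 1.0, 14.6, 1.1, 12.5, 1.3, 12.4, 1.1),
    "Hemocritat": (44.4, 3.2, 44.1, 3.4, 37.9, 3.4, 37.7, 3.5),
    "HbA1C (%)": (5.5, 0.3, 5.5, 0.3, 5.5, 0.3, 5.4, 0.3),
    INSULIN_0HR: (6.5, 4.7, 6.2, 2.6, 7.6, 5.1, 7.8, 3.5),
    "Insulin_1hr (μIU/ml)": (32.0, 27.2, 34.5, 33.2, 29.5, 26.9, 37.2, 34.1),
    "Insulin_2hr (μIU/ml)": (18.9, 18.2, 18.9, 19.1, 22.1, 19.8, 29.1, 24.0),
    GLUCOSE_0HR: (84.0, 7.5, 80.3, 6.5, 80.7, 6.7, 77.9, 5.2),
    GLUCOSE_1HR: (127.4, 34.9, 128.3, 36.8, 121.7, 34.9, 121.1, 31.4),
    GLUCOSE_2HR: (94.9, 21.4, 91.1, 20.6, 103.0, 18.9, 101.3, 18.9),
    HOMA_IR: (1.41, 1.09, 1.39, 0.59, 1.70, 1.15, 1.8, 0.8),
}

#: The association traits (everything in the table except the age and BMI
#: covariates); there are 29 of them.
ASSOCIATION_TRAITS: tuple[str, ...] = tuple(t for t in _TABLE if t not in (AGE, BMI))

SEXES = ("male", "female")
GENOTYPES = ("1X", "2X")

#: QMPSF amplicons, per-copy fluorescence efficiency constants (arbitrary
#: units) and amplicon sizes in bp.  E2 is the target locus; Factor VIII is
#: X-linked (sex-dependent copy count); CN2-2 is autosomal invariant.
AMPLICONS = ("E2", "FVIII", "CN2-2")
AMPLICON_EFFICIENCY = {"E2": 1200.0, "FVIII": 1000.0, "CN2-2": 800.0}
AMPLICON_SIZE_BP = {"E2": 242, "FVIII": 199, "CN2-2": 160}


def AMPLICON_COPIES(amplicon: str, sex: str, genotype: str) -> int:
    """True template copy count for an amplicon given sex and E2 genotype."""
    if amplicon == "E2":
        return 1 if genotype == "1X" else 2
    if amplicon == "FVIII":
        return 1 if sex == "male" else 2
    if amplicon == "CN2-2":
        return 2
    raise ConfigurationError(f"unknown amplicon {amplicon!r}")


def default_trait_params() -> dict[str, dict[tuple[str, str], tuple[float, float]]]:
    """Trait -> {(sex, genotype): (mean, sd)} mapping with published defaults."""
    params: dict[str, dict[tuple[str, str], tuple[float, float]]] = {}
    for trait, row in _TABLE.items():
        params[trait] = {
            ("male", "1X"): (row[0], row[1]),
            ("male", "2X"): (row[2], row[3]),
            ("female", "1X"): (row[4], row[5]),
            ("female", "2X"): (row[6], row[7]),
        }
    return params


def null_trait_params() -> dict[str, dict[tuple[str, str], tuple[float, float]]]:
    """Defaults with every genotype effect removed (low-CN cell copied to
    high-CN), for type-I-error simulations."""
    params = default_trait_params()
    for cells in params.values():
        for sex in SEXES:
            cells[(sex, "2X")] = cells[(sex, "1X")]
    return params


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchingParams:
    """Nested case-control matching tolerances (1:2 on sex, age, BMI)."""
    ratio: int = 2
    age_tol: float = 1.0       # years
    bmi_tol: float = 0.1       # kg/m^2


@dataclass(frozen=True)
class CNMatrixParams:
    """Probe-level CN matrix with one embedded copy-number-variable region.

    cnvr_start/cnvr_end are 1-based probe indices, inclusive.  state_freqs
    are the frequencies of integer copy states 1, 2 and 3 inside the CNVR.
    """
    n_probes: int = 200
    n_subjects: int = 90
    cnvr_start: int = 40
    cnvr_end: int = 60
    background_sd: float = 0.10
    cnvr_sd: float = 0.10
    state_freqs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    chrom: str = "chr1"
    first_position: int = 65_400_001
    probe_spacing: int = 5_000


@dataclass(frozen=True)
class ExpressionParams:
    """Dosage-dependent expression model on the log2 scale.

    log2(expr) = intercept + slope * relative_cn + N(0, residual_sd), with a
    negative slope for LEPR and a positive one for LEPROT.  Defaults give
    squared correlations of roughly 0.4 and 0.15 at n=32 with the default
    relative-CN spread, the magnitudes reported for the LCL panel.
    """
    slope_lepr: float = -1.0
    slope_leprot: float = 0.5
    intercept_lepr: float = 0.0
    intercept_leprot: float = 0.0
    residual_sd: float = 0.30
    n_experiments: int = 3
    n_replicates: int = 3
    gapdh_ct_mean: float = 20.0
    gapdh_ct_sd: float = 0.5
    replicate_ct_sd: float = 0.05
    cn_measure_sd: float = 0.05


@dataclass(frozen=True)
class CaseParams:
    """Generation of the case-control arms of the nested study.

    The case low-CN fraction defaults to the published 86/135 = 0.637;
    OGTT glucose is drawn in the diabetic range so WHO classification
    (fasting >= 126 or 2-h >= 200 mg/dL) labels essentially every case.
    ``n_control_pool`` is the number of additional non-diabetic source-cohort
    members available only as matching controls: a nested design draws
    controls from the whole source cohort, and a pool of this size makes
    1:2 matching at the tight BMI tolerance feasible for nearly every case
    (mirroring 137 matched cases of which ~135 are analyzable).
    """
    n_cases: int = 137
    low_cn_fraction: float = 0.637
    glucose_0hr: tuple[float, float] = (155.0, 25.0)
    glucose_2hr: tuple[float, float] = (230.0, 45.0)
    n_control_pool: int = 8000


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_men: int = 574
    n_women: int = 493
    low_cn_fraction: float = 0.5
    #: per-amplicon multiplicative log-normal noise CV; the default
    #: 0.073/sqrt(2) makes the per-reaction CN2-2/FVIII ratio CV ~ 7.3%.
    peak_noise_cv: float = 0.073 / math.sqrt(2.0)
    n_rounds: int = 3
    n_duplicates: int = 2
    trait_params: Mapping[str, Mapping[tuple[str, str], tuple[float, float]]] = field(
        default_factory=default_trait_params)
    fasting_glucose_threshold: float = 126.0  # mg/dL, WHO OGTT
    glucose_2hr_threshold: float = 200.0      # mg/dL, WHO OGTT
    matching: MatchingParams = field(default_factory=MatchingParams)
    cn_matrix: CNMatrixParams = field(default_factory=CNMatrixParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    cases: CaseParams = field(default_factory=CaseParams)

    def validate(self) -> None:
        if self.n_men <= 0 or self.n_women <= 0:
            raise ConfigurationError("subject counts must be positive")
        if not 0.0 <= self.low_cn_fraction <= 1.0:
            raise ConfigurationError("low_cn_fraction must be in [0, 1]")
        if self.peak_noise_cv < 0:
            raise ConfigurationError("peak_noise_cv must be >= 0")
        if self.n_rounds <= 0 or self.n_duplicates <= 0:
            raise ConfigurationError("replicate counts must be positive")
        for trait, cells in self.trait_params.items():
            for sex in SEXES:
                for gt in GENOTYPES:
                    if (sex, gt) not in cells:
                        raise ConfigurationError(
                            f"trait_params[{trait!r}] missing cell ({sex}, {gt})")
                    mean, sd = cells[(sex, gt)]
                    if sd < 0:
                        raise ConfigurationError(
                            f"trait_params[{trait!r}] cell ({sex}, {gt}): sd < 0")
        cm = self.cn_matrix
        if not (1 <= cm.cnvr_start <= cm.cnvr_end <= cm.n_probes):
            raise ConfigurationError(
                "cn_matrix requires 1 <= cnvr_start <= cnvr_end <= n_probes")
        if cm.background_sd < 0 or cm.cnvr_sd < 0:
            raise ConfigurationError("cn_matrix sd values must be >= 0")
        if abs(sum(cm.state_freqs) - 1.0) > 1e-9 or min(cm.state_freqs) < 0:
            raise ConfigurationError("state_freqs must be a probability vector")
        if self.matching.ratio <= 0:
            raise ConfigurationError("matching ratio must be positive")
        if not 0.0 <= self.cases.low_cn_fraction <= 1.0:
            raise ConfigurationError("case low_cn_fraction must be in [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Subject records
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One cohort member.  ``true_genotype`` is simulation truth at the E2
    locus, hidden from the calling stage.  ``arm`` records which study arm
    a subject belongs to: the association cohort, the case series, or the
    extra source-cohort members available only as matching controls."""
    id: str
    sex: str
    age: float
    bmi: float
    diabetes: str                       # "T2DM" | "non-T2DM"
    traits: dict[str, float]            # the 29 association traits
    true_genotype: str                  # "1X" | "2X"
    arm: str = "association"            # "association" | "case" | "control_pool"


def cohort_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subjects, one row each; trait columns keep their labels."""
    rows = []
    for s in subjects:
        row = {"id": s.id, "sex": s.sex, "age": s.age, "bmi": s.bmi,
               "diabetes": s.diabetes, "true_genotype": s.true_genotype,
               "arm": s.arm}
        row.update(s.traits)
        rows.append(row)
    return pd.DataFrame(rows)


# Independent salts so each generated artefact has its own stream while the
# whole simulation stays a pure function of config.seed.
(_SALT_COHORT, _SALT_PEAKS, _SALT_MATRIX, _SALT_EXPR, _SALT_CASES,
 _SALT_POOL) = range(1, 7)


def _draw_subjects(config: SimulationConfig, rng: np.random.Generator,
                   n_by_sex: Mapping[str, int], low_fraction: float,
                   id_prefix: str, arm: str = "association",
                   glucose_override: Mapping[str, tuple[float, float]] | None = None,
                   ) -> list[SubjectRecord]:
    subjects: list[SubjectRecord] = []
    counter = 1
    for sex in SEXES:
        n = n_by_sex[sex]
        if n == 0:
            continue
        n_low = int(round(n * low_fraction))
        genotypes = np.array(["1X"] * n_low + ["2X"] * (n - n_low))
        rng.shuffle(genotypes)
        low_mask = genotypes == "1X"
        draws: dict[str, np.ndarray] = {}
        for trait, cells in config.trait_params.items():
            if trait == HOMA_IR:
                continue  # derived below
            if glucose_override and trait in glucose_override:
                mean, sd = glucose_override[trait]
                draws[trait] = rng.normal(mean, sd, size=n)
                continue
            m_lo, s_lo = cells[(sex, "1X")]
            m_hi, s_hi = cells[(sex, "2X")]
            mu = np.where(low_mask, m_lo, m_hi)
            sd = np.where(low_mask, s_lo, s_hi)
            draws[trait] = rng.normal(mu, sd)
        draws[HOMA_IR] = draws[INSULIN_0HR] * draws[GLUCOSE_0HR] / 405.0
        for i in range(n):
            traits = {t: float(draws[t][i]) for t in ASSOCIATION_TRAITS}
            subjects.append(SubjectRecord(
                id=f"{id_prefix}{counter:05d}",
                sex=sex,
                age=float(draws[AGE][i]),
                bmi=float(draws[BMI][i]),
                diabetes="non-T2DM",
                traits=traits,
                true_genotype=str(genotypes[i]),
                arm=arm,
            ))
            counter += 1
    return subjects


def simulate_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Generate the non-diabetic cohort.

    Per sex stratum, exactly round(n * low_cn_fraction) subjects carry the
    low-CN (1X) genotype, in shuffled positions; every trait is drawn from
    the (sex, genotype) normal cell of ``trait_params``.  Deterministic
    given the config seed.
    """
    config.validate()
    rng = np.random.default_rng([_SALT_COHORT, config.seed])
    return _draw_subjects(
        config, rng,
        {"male": config.n_men, "female": config.n_women},
        config.low_cn_fraction, id_prefix="S")


def simulate_cases(config: SimulationConfig) -> list[SubjectRecord]:
    """Generate the T2DM case arm for the nested case-control study.

    Cases share the cohort's age/BMI distributions (keeping matching on
    age +/- tol and BMI +/- tol feasible) but draw OGTT glucose from the
    diabetic-range distributions and carry the low-CN genotype at the
    case-specific fraction.
    """
    config.validate()
    rng = np.random.default_rng([_SALT_CASES, config.seed])
    n = config.cases.n_cases
    n_men = int(round(n * config.n_men / (config.n_men + config.n_women)))
    subjects = _draw_subjects(
        config, rng, {"male": n_men, "female": n - n_men},
        config.cases.low_cn_fraction, id_prefix="D", arm="case",
        glucose_override={GLUCOSE_0HR: config.cases.glucose_0hr,
                          GLUCOSE_2HR: config.cases.glucose_2hr})
    return assign_diabetes(subjects, config)


def simulate_control_pool(config: SimulationConfig) -> list[SubjectRecord]:
    """Generate the extra source-cohort members serving only as matching
    controls: same trait model as the association cohort, ``arm`` set to
    "control_pool", sex split proportional to the cohort's."""
    config.validate()
    n = config.cases.n_control_pool
    if n == 0:
        return []
    rng = np.random.default_rng([_SALT_POOL, config.seed])
    n_men = int(round(n * config.n_men / (config.n_men + config.n_women)))
    pool = _draw_subjects(
        config, rng, {"male": n_men, "female": n - n_men},
        config.low_cn_fraction, id_prefix="C", arm="control_pool")
    return assign_diabetes(pool, config)


def assign_diabetes(subjects: Sequence[SubjectRecord],
                    config: SimulationConfig) -> list[SubjectRecord]:
    """Label T2DM by the WHO OGTT rule: fasting glucose >= 126 mg/dL or
    2-hour glucose >= 200 mg/dL (thresholds configurable, >= convention)."""
    out = []
    for s in subjects:
        if GLUCOSE_0HR not in s.traits or GLUCOSE_2HR not in s.traits:
            raise DataError(f"subject {s.id}: missing OGTT glucose traits")
        t2dm = (s.traits[GLUCOSE_0HR] >= config.fasting_glucose_threshold
                or s.traits[GLUCOSE_2HR] >= config.glucose_2hr_threshold)
        s.diabetes = "T2DM" if t2dm else "non-T2DM"
        out.append(s)
    return out


def simulate_peak_table(subjects: Sequence[SubjectRecord],
                        config: SimulationConfig) -> pd.DataFrame:
    """QMPSF peak heights: n_rounds x n_duplicates reactions per subject,
    each with the three amplicons.

    Expected height = per-amplicon efficiency constant x true copy count,
    with multiplicative log-normal noise of CV ``peak_noise_cv`` drawn
    independently per reaction per amplicon (unit mean).
    """
    config.validate()
    rng = np.random.default_rng([_SALT_PEAKS, config.seed])
    cv = config.peak_noise_cv
    sigma = math.sqrt(math.log1p(cv * cv))
    rows: dict[str, list] = {k: [] for k in
                             ("subject_id", "round", "duplicate", "amplicon",
                              "size_bp", "peak_height")}
    n_reactions = config.n_rounds * config.n_duplicates
    for s in subjects:
        for amp in AMPLICONS:
            expected = AMPLICON_EFFICIENCY[amp] * AMPLICON_COPIES(amp, s.sex, s.true_genotype)
            if sigma > 0:
                noise = rng.lognormal(-0.5 * sigma * sigma, sigma, size=n_reactions)
            else:
                noise = np.ones(n_reactions)
            k = 0
            for rnd in range(1, config.n_rounds + 1):
                for dup in range(1, config.n_duplicates + 1):
                    rows["subject_id"].append(s.id)
                    rows["round"].append(rnd)
                    rows["duplicate"].append(dup)
                    rows["amplicon"].append(amp)
                    rows["size_bp"].append(AMPLICON_SIZE_BP[amp])
                    rows["peak_height"].append(expected * noise[k])
                    k += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nested case-control matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedSet:
    cases: list[SubjectRecord]
    controls: list[SubjectRecord]
    pairs: dict[str, list[str]]     # case id -> matched control ids
    dropped: list[str]              # case ids with no eligible control


def match_nested_case_control(cases: Sequence[SubjectRecord],
                              controls: Sequence[SubjectRecord],
                              matching: MatchingParams | None = None) -> MatchedSet:
    """Greedy 1:ratio matching on sex, age and BMI, without replacement.

    Cases are processed in ascending id order; for each, up to ``ratio``
    controls of identical sex with |delta age| <= age_tol and
    |delta BMI| <= bmi_tol are taken, nearest BMI first, ties broken by
    ascending control id.  Cases with no eligible control are dropped.
    """
    matching = matching or MatchingParams()
    if not controls:
        raise MatchingError("empty control pool")
    case_ids = {c.id for c in cases}
    if case_ids & {c.id for c in controls}:
        raise MatchingError("cases and controls overlap")
    pool: dict[str, SubjectRecord] = {c.id: c for c in controls}
    kept: list[SubjectRecord] = []
    matched: list[SubjectRecord] = []
    pairs: dict[str, list[str]] = {}
    dropped: list[str] = []
    for case in sorted(cases, key=lambda s: s.id):
        eligible = [c for c in pool.values()
                    if c.sex == case.sex
                    and abs(c.age - case.age) <= matching.age_tol
                    and abs(c.bmi - case.bmi) <= matching.bmi_tol]
        if not eligible:
            dropped.append(case.id)
            logger.warning("case %s dropped: no eligible control", case.id)
            continue
        eligible.sort(key=lambda c: (abs(c.bmi - case.bmi), c.id))
        chosen = eligible[:matching.ratio]
        for c in chosen:
            del pool[c.id]
        kept.append(case)
        matched.extend(chosen)
        pairs[case.id] = [c.id for c in chosen]
    logger.info("matched %d/%d cases to %d controls (%d dropped)",
                len(kept), len(cases), len(matched), len(dropped))
    return MatchedSet(cases=kept, controls=matched, pairs=pairs, dropped=dropped)


# ---------------------------------------------------------------------------
# Probe-level CN matrix
# ---------------------------------------------------------------------------

def simulate_cn_matrix(config: SimulationConfig) -> CNMatrix:
    """Probe x subject copy-number matrix with one embedded CNVR.

    Background probes are Normal(2, background_sd).  Probes inside the CNVR
    carry a per-subject integer copy state (1, 2 or 3 at ``state_freqs``)
    plus Normal(0, cnvr_sd) noise; the state is constant across a subject's
    CNVR probes, as for a contiguous deletion/duplication.
    """
    config.validate()
    cm = config.cn_matrix
    rng = np.random.default_rng([_SALT_MATRIX, config.seed])
    values = rng.normal(2.0, cm.background_sd, size=(cm.n_probes, cm.n_subjects))
    states = rng.choice([1, 2, 3], size=cm.n_subjects, p=list(cm.state_freqs))
    lo, hi = cm.cnvr_start - 1, cm.cnvr_end  # to 0-based half-open
    values[lo:hi, :] = (states[None, :]
                        + rng.normal(0.0, cm.cnvr_sd, size=(hi - lo, cm.n_subjects)))
    positions = cm.first_position + cm.probe_spacing * np.arange(cm.n_probes)
    probes = pd.DataFrame({
        "chrom": cm.chrom,
        "position": positions,
        "probe_id": [f"P{i + 1:05d}" for i in range(cm.n_probes)],
    })
    subjects = [f"S{i + 1:05d}" for i in range(cm.n_subjects)]
    return CNMatrix(probes=probes, subjects=subjects, values=values)


# ---------------------------------------------------------------------------
# Dosage-dependent expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionRecord:
    """Raw qPCR threshold cycles for one cell line and one gene:
    ``ct`` has shape (n_experiments, n_replicates)."""
    line_id: str
    gene: str
    ct: np.ndarray


@dataclass
class ExpressionData:
    records: list[ExpressionRecord]
    relative_cn: pd.Series  # measured relative E2 content per line


def simulate_expression(subjects: Sequence[SubjectRecord],
                        config: SimulationConfig) -> ExpressionData:
    """Triplicate Ct tables for LEPR, LEPROT and GAPDH across cell lines.

    Per line, log2 relative expression of each target is
    intercept + slope * relative_cn + N(0, residual_sd); the target Ct is
    placed below/above the line's GAPDH Ct accordingly (perfect doubling per
    cycle), with small per-well replicate jitter.
    """
    config.validate()
    ex = config.expression
    rng = np.random.default_rng([_SALT_EXPR, config.seed])
    records: list[ExpressionRecord] = []
    rel_cns: dict[str, float] = {}
    gene_models = {
        "LEPR": (ex.intercept_lepr, ex.slope_lepr),
        "LEPROT": (ex.intercept_leprot, ex.slope_leprot),
    }
    shape = (ex.n_experiments, ex.n_replicates)
    for s in subjects:
        copies = AMPLICON_COPIES("E2", s.sex, s.true_genotype)
        rel_cn = max(0.05, copies / 2.0 + rng.normal(0.0, ex.cn_measure_sd))
        rel_cns[s.id] = rel_cn
        gapdh_base = rng.normal(ex.gapdh_ct_mean, ex.gapdh_ct_sd)
        records.append(ExpressionRecord(
            line_id=s.id, gene="GAPDH",
            ct=gapdh_base + rng.normal(0.0, ex.replicate_ct_sd, size=shape)))
        for gene, (intercept, slope) in gene_models.items():
            log2_expr = intercept + slope * rel_cn + rng.normal(0.0, ex.residual_sd)
            # expr = 2^-(Ct_target - Ct_ref)  =>  Ct_target = Ct_ref - log2(expr)
            target_base = gapdh_base - log2_expr
            records.append(ExpressionRecord(
                line_id=s.id, gene=gene,
                ct=target_base + rng.normal(0.0, ex.replicate_ct_sd, size=shape)))
    return ExpressionData(records=records,
                          relative_cn=pd.Series(rel_cns, name="relative_cn"))


def expression_to_frame(data: ExpressionData) -> pd.DataFrame:
    """Long-format Ct table: line_id, gene, experiment, replicate, ct."""
    rows = []
    for rec in data.records:
        for e in range(rec.ct.shape[0]):
            for r in range(rec.ct.shape[1]):
                rows.append((rec.line_id, rec.gene, e + 1, r + 1, rec.ct[e, r]))
    return pd.DataFrame(rows, columns=["line_id", "gene", "experiment",
                                       "replicate", "ct"])
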