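"""Generator: cohort structure, trait moments, peaks, matching, matrix, Ct."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from cnvassoc import synthcohort as sc
from cnvassoc.expression import relative_expression_table
from cnvassoc.synthcohort import (GLUCOSE_0HR, GLUCOSE_2HR, HOMA_IR,
                                  INSULIN_0HR, MatchingParams,
                                  SimulationConfig, SubjectRecord)
from conftest import zero_noise_params


def test_cohort_counts_and_determinism():
    cfg = SimulationConfig(seed=1, n_men=574, n_women=493)
    cohort = sc.simulate_cohort(cfg)
    assert len(cohort) == 1067
    assert sum(s.sex == "male" for s in cohort) == 574
    again = sc.simulate_cohort(cfg)
    assert sc.cohort_to_frame(cohort).equals(sc.cohort_to_frame(again))
    other = sc.simulate_cohort(cfg.with_seed(2))
    assert not sc.cohort_to_frame(cohort).equals(sc.cohort_to_frame(other))


def test_genotype_counts_are_stratified_fixed_fractions():
    cfg = SimulationConfig(seed=3, n_men=574, n_women=493)
    cohort = sc.simulate_cohort(cfg)
    men_low = sum(s.true_genotype == "1X" for s in cohort if s.sex == "male")
    women_low = sum(s.true_genotype == "1X" for s in cohort if s.sex == "female")
    assert men_low == 287
    assert women_low == round(493 * 0.5)


def test_zero_variance_limit_reproduces_group_means():
    cfg = SimulationConfig(seed=5, n_men=20, n_women=20,
                           trait_params=zero_noise_params())
    cohort = sc.simulate_cohort(cfg)
    for s in cohort:
        if s.sex == "male" and s.true_genotype == "1X":
            assert s.traits[GLUCOSE_0HR] == pytest.approx(84.0)
        if s.sex == "female" and s.true_genotype == "2X":
            assert s.traits[GLUCOSE_0HR] == pytest.approx(77.9)


def test_trait_moments_match_parameters_at_large_n():
    cfg = SimulationConfig(seed=9, n_men=1200, n_women=1200)
    frame = sc.cohort_to_frame(sc.simulate_cohort(cfg))
    checked = ["Total cholesterol (mg/dL)", GLUCOSE_0HR, "Hip circumferences (cm)"]
    for trait in checked:
        for sex in ("male", "female"):
            for gt in ("1X", "2X"):
                cell = frame[(frame.sex == sex) & (frame.true_genotype == gt)]
                mean, sd = cfg.trait_params[trait][(sex, gt)]
                tol = 3.0 * sd / math.sqrt(len(cell))
                assert abs(cell[trait].mean() - mean) < tol


def test_homa_ir_identity_holds_for_every_subject(small_config):
    for s in sc.simulate_cohort(small_config):
        expected = s.traits[INSULIN_0HR] * s.traits[GLUCOSE_0HR] / 405.0
        assert s.traits[HOMA_IR] == pytest.approx(expected)


def test_missing_trait_cell_raises():
    params = sc.default_trait_params()
    del params[GLUCOSE_0HR][("male", "1X")]
    with pytest.raises(sc.ConfigurationError):
        SimulationConfig(trait_params=params).validate()


# --- peak table ---------------------------------------------------------------

def test_peak_table_replicate_structure(small_config):
    cohort = sc.simulate_cohort(small_config)
    peaks = sc.simulate_peak_table(cohort, small_config)
    per_subject = peaks.groupby("subject_id").size()
    assert (per_subject == 3 * 2 * 3).all()  # rounds x duplicates x amplicons
    one = peaks[peaks.subject_id == cohort[0].id]
    assert set(map(tuple, one[["round", "duplicate"]].drop_duplicates().values)) \
        == {(r, d) for r in (1, 2, 3) for d in (1, 2)}


def test_noiseless_peaks_encode_dosage():
    cfg = SimulationConfig(seed=2, n_men=4, n_women=4, peak_noise_cv=0.0)
    cohort = sc.simulate_cohort(cfg)
    peaks = sc.simulate_peak_table(cohort, cfg)
    male_1x = next(s for s in cohort
                   if s.sex == "male" and s.true_genotype == "1X")
    sub = peaks[peaks.subject_id == male_1x.id].groupby("amplicon")[
        "peak_height"].first()
    # copy counts 1 (E2), 1 (FVIII), 2 (CN2-2), scaled by efficiency constants
    assert sub["E2"] / sc.AMPLICON_EFFICIENCY["E2"] == pytest.approx(1.0)
    assert sub["FVIII"] / sc.AMPLICON_EFFICIENCY["FVIII"] == pytest.approx(1.0)
    assert sub["CN2-2"] / sc.AMPLICON_EFFICIENCY["CN2-2"] == pytest.approx(2.0)


def test_reference_ratio_cv_near_calibration():
    cfg = SimulationConfig(seed=13, n_men=500, n_women=500)
    cohort = sc.simulate_cohort(cfg)
    peaks = sc.simulate_peak_table(cohort, cfg)
    females = {s.id for s in cohort if s.sex == "female"}
    wide = peaks.pivot_table(index=["subject_id", "round", "duplicate"],
                             columns="amplicon", values="peak_height")
    wide = wide[wide.index.get_level_values(0).isin(females)]
    ratio = wide["CN2-2"] / wide["FVIII"]
    cv = ratio.std(ddof=1) / ratio.mean()
    assert abs(cv - 0.073) < 0.02


# --- diabetes classification ---------------------------------------------------

@pytest.mark.parametrize("fasting,two_hr,expected", [
    (130.0, 90.0, "T2DM"),       # fasting above threshold
    (84.0, 94.9, "non-T2DM"),    # typical non-diabetic values
    (126.0, 90.0, "T2DM"),       # boundary: >= convention
    (100.0, 200.0, "T2DM"),      # 2-hour criterion alone
])
def test_who_ogtt_classification(small_config, fasting, two_hr, expected):
    subject = SubjectRecord(id="X1", sex="male", age=50.0, bmi=24.0,
                            diabetes="non-T2DM",
                            traits={GLUCOSE_0HR: fasting, GLUCOSE_2HR: two_hr},
                            true_genotype="1X")
    out, = sc.assign_diabetes([subject], small_config)
    assert out.diabetes == expected


def test_assign_diabetes_requires_glucose(small_config):
    subject = SubjectRecord(id="X1", sex="male", age=50.0, bmi=24.0,
                            diabetes="non-T2DM", traits={}, true_genotype="1X")
    with pytest.raises(sc.DataError):
        sc.assign_diabetes([subject], small_config)


# --- matching -------------------------------------------------------------------

def _subject(id, sex="male", age=50.0, bmi=24.0, diabetes="non-T2DM"):
    return SubjectRecord(id=id, sex=sex, age=age, bmi=bmi, diabetes=diabetes,
                         traits={}, true_genotype="1X")


def test_matching_takes_two_nearest_bmi_controls():
    cases = [_subject("D1", bmi=24.0), _subject("D2", bmi=24.05)]
    controls = [_subject(f"C{i}", bmi=b) for i, b in
                enumerate([24.01, 23.96, 24.09, 24.02, 23.92], start=1)]
    matched = sc.match_nested_case_control(cases, controls)
    assert len(matched.cases) == 2
    assert len(matched.controls) == 4
    for case in matched.cases:
        for cid in matched.pairs[case.id]:
            ctrl = next(c for c in matched.controls if c.id == cid)
            assert ctrl.sex == case.sex
            assert abs(ctrl.age - case.age) <= 1.0
            assert abs(ctrl.bmi - case.bmi) <= 0.1 + 1e-12


def test_matching_drops_infeasible_case_and_breaks_ties_by_id():
    cases = [_subject("D1", age=80.0), _subject("D2")]
    controls = [_subject(f"C{i}") for i in (3, 1, 2)]  # identical to D2
    matched = sc.match_nested_case_control(cases, controls)
    assert matched.dropped == ["D1"]
    assert matched.pairs["D2"] == ["C1", "C2"]  # ascending-id tie-break


def test_matching_without_replacement_random_property():
    rng = np.random.default_rng(42)
    cases = [_subject(f"D{i:03d}", sex=rng.choice(["male", "female"]),
                      age=float(rng.normal(55, 5)), bmi=float(rng.normal(25, 2)),
                      diabetes="T2DM") for i in range(20)]
    controls = [_subject(f"C{i:04d}", sex=rng.choice(["male", "female"]),
                         age=float(rng.normal(55, 5)), bmi=float(rng.normal(25, 2)))
                for i in range(800)]
    matched = sc.match_nested_case_control(cases, controls)
    used = [cid for ids in matched.pairs.values() for cid in ids]
    assert len(used) == len(set(used))            # without replacement
    by_id = {c.id: c for c in controls}
    for case in matched.cases:
        assert 1 <= len(matched.pairs[case.id]) <= 2
        for cid in matched.pairs[case.id]:
            ctrl = by_id[cid]
            assert ctrl.sex == case.sex
            assert abs(ctrl.age - case.age) <= 1.0
            assert abs(ctrl.bmi - case.bmi) <= 0.1 + 1e-12


def test_matching_empty_pool_raises():
    with pytest.raises(sc.MatchingError):
        sc.match_nested_case_control([_subject("D1")], [])


# --- CN matrix ------------------------------------------------------------------

def test_cn_matrix_dispersion_inside_and_outside_cnvr():
    cfg = SimulationConfig(
        seed=21,
        cn_matrix=sc.CNMatrixParams(n_probes=100, n_subjects=400,
                                    cnvr_start=40, cnvr_end=60,
                                    background_sd=0.05, cnvr_sd=0.05))
    matrix = sc.simulate_cn_matrix(cfg)
    stds = matrix.values.std(axis=1, ddof=1)
    inside = stds[39:60]
    outside = np.concatenate([stds[:39], stds[60:]])
    # population SD of uniform {1,2,3} is sqrt(2/3) ~ 0.816
    assert np.all(np.abs(inside - math.sqrt(2 / 3)) < 0.1)
    assert np.all(outside < 0.07)


def test_cn_matrix_no_signal_when_all_states_diploid():
    cfg = SimulationConfig(
        seed=22,
        cn_matrix=sc.CNMatrixParams(n_probes=60, n_subjects=50,
                                    cnvr_start=10, cnvr_end=20,
                                    background_sd=0.05, cnvr_sd=0.05,
                                    state_freqs=(0.0, 1.0, 0.0)))
    matrix = sc.simulate_cn_matrix(cfg)
    assert np.all(matrix.values.std(axis=1, ddof=1) < 0.25)


def test_cn_matrix_determinism_and_bounds_check():
    cfg = SimulationConfig(seed=23)
    a = sc.simulate_cn_matrix(cfg)
    b = sc.simulate_cn_matrix(cfg)
    assert np.array_equal(a.values, b.values)
    bad = dataclasses.replace(cfg, cn_matrix=sc.CNMatrixParams(
        n_probes=50, cnvr_start=40, cnvr_end=60))
    with pytest.raises(sc.ConfigurationError):
        sc.simulate_cn_matrix(bad)


# --- expression -----------------------------------------------------------------

def test_noiseless_expression_is_exactly_linear_in_cn():
    cfg = SimulationConfig(
        seed=31, n_men=16, n_women=16,
        expression=sc.ExpressionParams(residual_sd=0.0, replicate_ct_sd=0.0,
                                       cn_measure_sd=0.1))
    cohort = sc.simulate_cohort(cfg)
    data = sc.simulate_expression(cohort, cfg)
    ct = sc.expression_to_frame(data)
    log2_levels = relative_expression_table(ct, log2=True)
    aligned = log2_levels.join(data.relative_cn)
    r_lepr = np.corrcoef(aligned["relative_cn"], aligned["LEPR"])[0, 1]
    r_leprot = np.corrcoef(aligned["relative_cn"], aligned["LEPROT"])[0, 1]
    assert r_lepr == pytest.approx(-1.0, abs=1e-9)
    assert r_leprot == pytest.approx(1.0, abs=1e-9)


def test_expression_record_shapes(small_config):
    cohort = sc.simulate_cohort(small_config)[:5]
    data = sc.simulate_expression(cohort, small_config)
    assert len(data.records) == 5 * 3  # LEPR, LEPROT, GAPDH per line
    assert all(rec.ct.shape == (3, 3) for rec in data.records)
    assert set(data.relative_cn.index) == {s.id for s in cohort}
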