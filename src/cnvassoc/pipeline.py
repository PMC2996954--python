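"""End-to-end pipeline: simulate -> call -> scan -> assoc -> casecontrol -> expr.

Every stage reads and writes the TSV interchange formats from ``cnvassoc.io``
so stages can also be run individually from files.  Outputs carry provenance
headers (seed, config hash, stage name); the log records subject counts
entering and leaving each stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, cnvr, expression, io, qmpsf, synthcohort
from .synthcohort import SimulationConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

STAGES = ("simulate", "call", "scan", "assoc", "casecontrol", "expr")


@dataclass
class PipelineConfig:
    out_dir: Path = Path("cnvassoc_out")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reference_amplicon: str = "FVIII"     # or "CN2-2"
    cnv_cutoff: float = 0.25
    min_probes: int = 3
    merge_gap: int = 0
    smoothing_window: int = 5
    m_traits: int = assoc.N_ASSOCIATION_TRAITS
    n_expression_lines: int = 32
    skip: tuple[str, ...] = ()
    log_level: str = "INFO"

    def validate(self) -> None:
        self.simulation.validate()
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise synthcohort.ConfigurationError(
                f"unknown stages in skip: {sorted(unknown)}")
        if self.reference_amplicon not in ("FVIII", "CN2-2"):
            raise synthcohort.ConfigurationError(
                "reference_amplicon must be FVIII or CN2-2")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML or JSON document.

    Top-level keys mirror PipelineConfig fields; the ``simulation`` mapping
    mirrors SimulationConfig (nested mappings for matching, cn_matrix,
    expression and cases).
    """
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    doc = doc or {}
    sim_doc = doc.pop("simulation", {})
    nested = {
        "matching": synthcohort.MatchingParams,
        "cn_matrix": synthcohort.CNMatrixParams,
        "expression": synthcohort.ExpressionParams,
        "cases": synthcohort.CaseParams,
    }
    sim_kwargs = {}
    for key, value in sim_doc.items():
        if key in nested:
            sim_kwargs[key] = nested[key](**value)
        elif key == "trait_params":
            sim_kwargs[key] = {
                trait: {tuple(cell.split("/")): tuple(ms)
                        for cell, ms in cells.items()}
                for trait, cells in value.items()}
        else:
            sim_kwargs[key] = value
    if "out_dir" in doc:
        doc["out_dir"] = Path(doc["out_dir"])
    if "skip" in doc:
        doc["skip"] = tuple(doc["skip"])
    return PipelineConfig(simulation=SimulationConfig(**sim_kwargs), **doc)


def _meta(config: PipelineConfig, stage: str) -> dict:
    return {"stage": stage,
            "seed": config.simulation.seed,
            "config_hash": io.config_hash(config)}


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the pipeline stages in order; returns output paths by name.

    Stages named in ``config.skip`` are omitted (downstream stages that can
    run from already-written files still do when those files exist).
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    outputs: dict[str, Path] = {}

    def active(stage: str) -> bool:
        return stage not in config.skip

    # --- simulate -----------------------------------------------------------
    if active("simulate"):
        cohort = synthcohort.simulate_cohort(sim)
        cohort = synthcohort.assign_diabetes(cohort, sim)
        cases = synthcohort.simulate_cases(sim)
        pool = synthcohort.simulate_control_pool(sim)
        everyone = cohort + cases + pool
        logger.info("simulate: %d cohort + %d case + %d control-pool subjects",
                    len(cohort), len(cases), len(pool))
        peaks = synthcohort.simulate_peak_table(everyone, sim)
        matrix = synthcohort.simulate_cn_matrix(sim)
        expr_subjects = cohort[:config.n_expression_lines]
        expr_data = synthcohort.simulate_expression(expr_subjects, sim)
        meta = _meta(config, "simulate")
        outputs["cohort"] = io.write_cohort(everyone, out / "cohort.tsv", meta)
        outputs["peaks"] = io.write_peaks(peaks, out / "peaks.tsv", meta)
        outputs["cn_matrix"], outputs["probes"] = io.write_cn_matrix(
            matrix, out / "cn_matrix.tsv", out / "probes.tsv", meta)
        outputs["ct"] = io.write_ct_table(
            synthcohort.expression_to_frame(expr_data), out / "ct.tsv", meta)
        io.write_table(expr_data.relative_cn.rename_axis("line_id").reset_index(),
                       out / "expression_cn.tsv", meta)
        outputs["expression_cn"] = out / "expression_cn.tsv"

    # --- call ----------------------------------------------------------------
    if active("call"):
        peaks = io.read_peaks(out / "peaks.tsv")
        cohort_df = io.read_cohort(out / "cohort.tsv")
        logger.info("call: %d subjects enter", cohort_df["id"].nunique())
        rel_cn = qmpsf.relative_copy_number(
            peaks, target="E2", reference=config.reference_amplicon)
        sex_map = dict(zip(cohort_df["id"], cohort_df["sex"]))
        qc = qmpsf.reference_cross_check(peaks, recorded_sex=sex_map)
        reference = set(cohort_df.loc[(cohort_df["diabetes"] == "non-T2DM")
                                      & (cohort_df["arm"] == "association"), "id"])
        calls, cutoffs = qmpsf.dichotomize_by_median(rel_cn, sex_map, reference)
        meta = _meta(config, "call")
        meta["cutoffs"] = json.dumps(cutoffs)
        meta["sex_concordance"] = qc.concordance
        meta["reference_cv"] = json.dumps(qc.cv_by_sex)
        outputs["calls"] = io.write_calls(calls, out / "calls.tsv", meta)
        logger.info("call: %d calls, cutoffs %s, sex concordance %s",
                    len(calls), cutoffs, qc.concordance)

    # --- scan ----------------------------------------------------------------
    if active("scan"):
        matrix = io.read_cn_matrix(out / "cn_matrix.tsv", out / "probes.tsv")
        stds = cnvr.per_probe_dispersion(matrix)
        regions = cnvr.call_cnv_regions(stds, matrix.probes,
                                        cutoff=config.cnv_cutoff,
                                        min_probes=config.min_probes,
                                        merge_gap=config.merge_gap)
        states = np.column_stack([
            cnvr.smooth_individual_states(matrix.values[:, j],
                                          config.smoothing_window)
            for j in range(len(matrix.subjects))])
        meta = _meta(config, "scan")
        outputs["regions"] = io.write_regions(regions, out / "regions.tsv", meta)
        state_df = pd.DataFrame(states, columns=matrix.subjects)
        state_df.insert(0, "probe_id", matrix.probes["probe_id"].to_numpy())
        outputs["states"] = io.write_table(state_df, out / "states.tsv", meta)
        logger.info("scan: %d regions called", len(regions))

    # --- assoc ---------------------------------------------------------------
    if active("assoc"):
        cohort_df = io.read_cohort(out / "cohort.tsv")
        calls_df = io.read_calls(out / "calls.tsv")
        nondiabetic = cohort_df[(cohort_df["diabetes"] == "non-T2DM")
                                & (cohort_df["arm"] == "association")]
        calls_map = dict(zip(calls_df["subject_id"], calls_df["cn_class"]))
        logger.info("assoc: %d non-diabetic subjects enter", len(nondiabetic))
        frames = []
        for sex in ("male", "female"):
            rows = assoc.association_table(nondiabetic, calls_map, sex,
                                           m=config.m_traits)
            frame = assoc.association_frame(rows)
            frame.insert(0, "sex", sex)
            frames.append(frame)
        meta = _meta(config, "assoc")
        outputs["associations"] = io.write_table(
            pd.concat(frames, ignore_index=True), out / "associations.tsv", meta)

    # --- casecontrol ----------------------------------------------------------
    if active("casecontrol"):
        cohort_df = io.read_cohort(out / "cohort.tsv")
        calls_df = io.read_calls(out / "calls.tsv")
        calls_map = dict(zip(calls_df["subject_id"], calls_df["cn_class"]))
        records = {
            row.id: synthcohort.SubjectRecord(
                id=row.id, sex=row.sex, age=row.age, bmi=row.bmi,
                diabetes=row.diabetes, traits={}, true_genotype=row.true_genotype,
                arm=row.arm)
            for row in cohort_df.itertuples()}
        cases = [r for r in records.values() if r.diabetes == "T2DM"]
        controls = [r for r in records.values()
                    if r.diabetes == "non-T2DM" and r.arm != "case"]
        matched = synthcohort.match_nested_case_control(cases, controls,
                                                        sim.matching)
        logger.info("casecontrol: %d/%d cases kept, %d controls",
                    len(matched.cases), len(cases), len(matched.controls))
        subset = cohort_df[cohort_df["id"].isin(
            {s.id for s in matched.cases} | {s.id for s in matched.controls})]
        result = assoc.case_control_analysis(subset, calls_map)
        meta = _meta(config, "casecontrol")
        outputs["casecontrol"] = io.write_table(
            pd.DataFrame([dataclasses.asdict(result)]),
            out / "casecontrol.tsv", meta)

    # --- expr ------------------------------------------------------------------
    if active("expr"):
        ct = io.read_ct_table(out / "ct.tsv")
        cn = io.read_table(out / "expression_cn.tsv",
                           required=["line_id", "relative_cn"],
                           numeric=["relative_cn"]).set_index("line_id")["relative_cn"]
        levels = expression.relative_expression_table(ct)
        rows = []
        for gene in levels.columns:
            corr = expression.dosage_correlation(cn, levels[gene], gene)
            rows.append(dataclasses.asdict(corr))
        meta = _meta(config, "expr")
        outputs["expression"] = io.write_table(
            pd.DataFrame(rows), out / "expression_correlation.tsv", meta)

    return outputs
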