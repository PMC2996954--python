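"""TSV readers and writers for every pipeline table.

All tables are tab-separated with a fixed header row, preceded by '#'
provenance comment lines (key: value) carrying at least the seed and a
configuration hash.  Region and probe-annotation files are BED-like TSV with
1-based inclusive coordinates (the convention is restated in each file's
header comments).  Readers validate required columns and numeric cells and
raise ParseError naming the file, column and first offending line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cnvr import CNMatrix, CNVRegion
from .qmpsf import CopyNumberCall
from .synthcohort import (ASSOCIATION_TRAITS, SubjectRecord, cohort_to_frame)

__all__ = [
    "ParseError",
    "config_hash",
    "write_table", "read_table",
    "write_cohort", "read_cohort",
    "write_peaks", "read_peaks",
    "write_cn_matrix", "read_cn_matrix",
    "write_calls", "read_calls",
    "write_regions",
    "write_ct_table", "read_ct_table",
]

PEAK_COLUMNS = ["subject_id", "round", "duplicate", "amplicon", "size_bp",
                "peak_height"]
CALL_COLUMNS = ["subject_id", "relative_cn", "cn_class", "stratum", "cutoff"]
CT_COLUMNS = ["line_id", "gene", "experiment", "replicate", "ct"]
COHORT_META = ["id", "sex", "age", "bmi", "diabetes", "true_genotype", "arm"]


class ParseError(ValueError):
    """Malformed input table; message names file, column and line."""


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config) -> str:
    """Stable short hash of a configuration object for provenance headers."""
    payload = json.dumps(_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                meta: Mapping[str, object] | None = None) -> Path:
    """Write a TSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path, required: Sequence[str],
               numeric: Sequence[str] = ()) -> pd.DataFrame:
    """Read a provenance-headed TSV, checking columns and numeric cells."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based + header row
            raise ParseError(
                f"{path}: non-numeric cell in column {col!r} near line {line}")
        df[col] = coerced
    return df


# --- cohort -----------------------------------------------------------------

def write_cohort(subjects: Sequence[SubjectRecord], path, meta=None) -> Path:
    return write_table(cohort_to_frame(subjects), path, meta)


def read_cohort(path) -> pd.DataFrame:
    traits = [t for t in ASSOCIATION_TRAITS]
    df = read_table(path, required=COHORT_META + traits,
                    numeric=["age", "bmi"] + traits)
    return df


# --- peaks ------------------------------------------------------------------

def write_peaks(peaks: pd.DataFrame, path, meta=None) -> Path:
    return write_table(peaks[PEAK_COLUMNS], path, meta)


def read_peaks(path) -> pd.DataFrame:
    return read_table(path, required=PEAK_COLUMNS,
                      numeric=["round", "duplicate", "size_bp", "peak_height"])


# --- CN matrix + probe annotation -------------------------------------------

def write_cn_matrix(matrix: CNMatrix, matrix_path, probes_path,
                    meta=None) -> tuple[Path, Path]:
    wide = pd.DataFrame(matrix.values, columns=matrix.subjects)
    wide.insert(0, "probe_id", matrix.probes["probe_id"].to_numpy())
    meta = dict(meta or {})
    meta.setdefault("coordinates", "1-based inclusive")
    probe_bed = matrix.probes.rename(columns={"position": "start"})
    probe_bed = probe_bed[["chrom", "start"]].assign(
        end=probe_bed["start"], probe_id=matrix.probes["probe_id"])
    return (write_table(wide, matrix_path, meta),
            write_table(probe_bed, probes_path, meta))


def read_cn_matrix(matrix_path, probes_path) -> CNMatrix:
    probes = read_table(probes_path, required=["chrom", "start", "end", "probe_id"],
                        numeric=["start", "end"])
    wide = read_table(matrix_path, required=["probe_id"])
    if not (wide["probe_id"].to_numpy() == probes["probe_id"].to_numpy()).all():
        raise ParseError(f"{matrix_path}: probe order disagrees with {probes_path}")
    subjects = [c for c in wide.columns if c != "probe_id"]
    values = wide[subjects].to_numpy(dtype=float)
    annot = pd.DataFrame({"chrom": probes["chrom"],
                          "position": probes["start"].astype(int),
                          "probe_id": probes["probe_id"]})
    return CNMatrix(probes=annot, subjects=subjects, values=values)


# --- calls ------------------------------------------------------------------

def write_calls(calls: Sequence[CopyNumberCall], path, meta=None) -> Path:
    df = pd.DataFrame([c.__dict__ for c in calls])[CALL_COLUMNS]
    return write_table(df, path, meta)


def read_calls(path) -> pd.DataFrame:
    return read_table(path, required=CALL_COLUMNS,
                      numeric=["relative_cn", "cutoff"])


# --- CNV regions ------------------------------------------------------------

def write_regions(regions: Sequence[CNVRegion], path, meta=None) -> Path:
    meta = dict(meta or {})
    meta.setdefault("coordinates", "1-based inclusive")
    df = pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "probe_count": r.probe_count, "mean_std": r.mean_probe_std,
        "max_std": r.max_probe_std,
    } for r in regions])
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "probe_count",
                                   "mean_std", "max_std"])
    return write_table(df, path, meta)


# --- Ct tables --------------------------------------------------------------

def write_ct_table(ct: pd.DataFrame, path, meta=None) -> Path:
    return write_table(ct[CT_COLUMNS], path, meta)


def read_ct_table(path) -> pd.DataFrame:
    return read_table(path, required=CT_COLUMNS,
                      numeric=["experiment", "replicate", "ct"])
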