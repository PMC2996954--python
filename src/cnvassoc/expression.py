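"""qPCR relative expression and gene dosage-expression correlation.

Relative expression is computed by the comparative-Ct method with perfect
doubling per cycle: per experiment, delta Ct = mean Ct(target) - mean
Ct(reference housekeeping gene), level = 2^(-delta Ct), averaged across
experiments.  The dosage-expression relationship is an ordinary
least-squares fit of expression level on relative DNA copy number, reported
as R^2 with a two-sided slope t-test on n - 2 degrees of freedom and the
slope sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DosageCorrelation",
    "ExpressionError",
    "relative_expression",
    "relative_expression_table",
    "dosage_correlation",
]


class ExpressionError(ValueError):
    """Expression quantities cannot be computed."""


@dataclass
class DosageCorrelation:
    gene: str
    n: int
    r_squared: float
    p: float
    slope_sign: int   # -1, 0 or +1


def relative_expression(target_ct: np.ndarray, reference_ct: np.ndarray) -> float:
    """Relative expression of one gene in one line from raw Ct arrays.

    Arrays have shape (n_experiments, n_replicates); replicates are averaged
    within each experiment, the per-experiment levels 2^(-delta Ct) are then
    averaged.  Log-scale averaging across replicates within an experiment
    matches the comparative-Ct convention.
    """
    t = np.asarray(target_ct, dtype=float)
    r = np.asarray(reference_ct, dtype=float)
    if t.ndim == 1:
        t = t[None, :]
    if r.ndim == 1:
        r = r[None, :]
    if t.shape[0] != r.shape[0]:
        raise ExpressionError("target and reference experiment counts differ")
    if not (np.isfinite(t).all() and np.isfinite(r).all()):
        raise ExpressionError("non-finite Ct value")
    delta_ct = t.mean(axis=1) - r.mean(axis=1)
    return float(np.mean(2.0 ** (-delta_ct)))


def relative_expression_table(ct_table: pd.DataFrame,
                              reference_gene: str = "GAPDH",
                              log2: bool = False) -> pd.DataFrame:
    """Per-line relative expression of every non-reference gene.

    ``ct_table`` is long-format with columns line_id, gene, experiment,
    replicate, ct.  Returns a line_id x gene DataFrame of expression levels
    relative to ``reference_gene`` (or their log2 with ``log2=True``).
    """
    required = {"line_id", "gene", "experiment", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ExpressionError(f"Ct table missing columns: {sorted(missing)}")
    means = (ct_table.groupby(["line_id", "gene", "experiment"])["ct"]
             .mean().unstack("gene"))
    if reference_gene not in means.columns:
        raise ExpressionError(f"reference gene {reference_gene!r} absent")
    if means[reference_gene].isna().any():
        bad = means.index[means[reference_gene].isna()][:3].tolist()
        raise ExpressionError(f"missing reference Ct for experiments: {bad}")
    targets = [g for g in means.columns if g != reference_gene]
    levels = {}
    for gene in targets:
        delta = means[gene] - means[reference_gene]
        per_exp = 2.0 ** (-delta)
        levels[gene] = per_exp.groupby(level="line_id").mean()
    out = pd.DataFrame(levels)
    return np.log2(out) if log2 else out


def dosage_correlation(relative_cn: pd.Series, expression: pd.Series,
                       gene: str) -> DosageCorrelation:
    """Least-squares dosage-expression fit for one gene.

    Pairs the two series on their index (cell-line id), fits expression on
    relative copy number, and reports R^2, the two-sided slope p on n - 2 df
    and the slope sign.
    """
    paired = pd.concat({"cn": relative_cn, "expr": expression},
                       axis=1, join="inner").dropna()
    n = len(paired)
    if n < 3:
        raise ExpressionError("need at least 3 paired observations")
    if paired["cn"].nunique() == 1:
        raise ExpressionError("zero variance in copy number")
    fit = stats.linregress(paired["cn"], paired["expr"])
    return DosageCorrelation(
        gene=gene,
        n=n,
        r_squared=float(fit.rvalue ** 2),
        p=float(fit.pvalue),
        slope_sign=int(np.sign(fit.slope)),
    )
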