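"""Copy-number calling from QMPSF peak-height tables.

Relative copy number of a target amplicon is the mean over replicate
reactions of the per-reaction peak-height ratio target/reference, where the
reference is either the X-linked Factor VIII amplicon (one copy in males,
two in females) or the autosomal invariant CN2-2 amplicon.  Because the
Factor VIII reference is X-linked, male and female relative copy numbers sit
on different scales, so calling is strictly sex-stratified: within each sex
the median relative CN of the non-diabetic reference subjects is the cutoff,
and a subject is called low (1X) iff strictly below it.

The dual references also provide a QC cross-check: the per-subject
FVIII/CN2-2 ratio separates the cohort into two clusters (one vs two X
chromosomes) whose assignment must match recorded sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CopyNumberCall",
    "ReferenceQC",
    "CallingError",
    "relative_copy_number",
    "reference_cross_check",
    "dichotomize_by_median",
]


class CallingError(ValueError):
    """Copy-number calling cannot proceed."""


@dataclass
class CopyNumberCall:
    subject_id: str
    relative_cn: float
    cn_class: str      # "1X" (low) | "2X" (high)
    stratum: str       # "male" | "female"
    cutoff: float      # the stratum median used


@dataclass
class ReferenceQC:
    """Dual-reference quality control.

    ratio: per-subject mean FVIII/CN2-2 peak ratio.
    inferred_sex: per-subject sex from the two-cluster split of ``ratio``
        (lower cluster = one X copy = male), or None if degenerate.
    concordance: fraction of subjects whose inferred sex matches the
        recorded sex (None when either is unavailable).
    cv_by_sex: per-sex coefficient of variation of the per-reaction
        CN2-2/FVIII ratio (the invariant-reference calibration statistic).
    degenerate: True when the ratio distribution shows no usable
        two-cluster separation.
    """
    ratio: pd.Series
    inferred_sex: pd.Series | None
    concordance: float | None
    cv_by_sex: dict[str, float]
    degenerate: bool


def _reaction_ratios(peaks: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    """Per-reaction target/reference peak-height ratio.

    Reactions with zero reference height are flagged (logged) and excluded.
    """
    required = {"subject_id", "round", "duplicate", "amplicon", "peak_height"}
    missing = required - set(peaks.columns)
    if missing:
        raise CallingError(f"peak table missing columns: {sorted(missing)}")
    wide = peaks.pivot_table(index=["subject_id", "round", "duplicate"],
                             columns="amplicon", values="peak_height",
                             aggfunc="first")
    for amp in (target, reference):
        if amp not in wide.columns:
            raise CallingError(f"amplicon {amp!r} absent from peak table")
    sub = wide[[target, reference]].dropna()
    bad = sub[reference] == 0
    if bad.any():
        for key in sub.index[bad]:
            logger.warning("reaction %s: zero %s peak, excluded", key, reference)
        sub = sub[~bad]
    return pd.DataFrame({"ratio": sub[target] / sub[reference]})


def relative_copy_number(peaks: pd.DataFrame, target: str = "E2",
                         reference: str = "FVIII") -> pd.Series:
    """Per-subject relative copy number: mean of per-reaction
    target/reference peak ratios over all usable replicate reactions."""
    ratios = _reaction_ratios(peaks, target, reference)
    per_subject = ratios.groupby(level="subject_id")["ratio"].mean()
    all_subjects = peaks["subject_id"].unique()
    lost = set(all_subjects) - set(per_subject.index)
    if lost:
        raise CallingError(
            f"subjects with zero usable reactions: {sorted(lost)[:5]}")
    per_subject.name = "relative_cn"
    return per_subject


def _two_cluster_split(values: np.ndarray) -> tuple[int, float, float, float]:
    """Exhaustive 1-D two-class split minimizing within-cluster variance.

    Returns (split index k into the sorted array, threshold, lower-cluster
    mean, upper-cluster mean): elements [0, k) form the lower cluster.
    """
    x = np.sort(values)
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    best_k, best_ssw = 1, np.inf
    for k in range(1, n):
        s1, q1 = csum[k - 1], csq[k - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        ssw = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
        if ssw < best_ssw:
            best_ssw, best_k = ssw, k
    threshold = 0.5 * (x[best_k - 1] + x[best_k])
    mean_lo = csum[best_k - 1] / best_k
    mean_hi = (csum[-1] - csum[best_k - 1]) / (n - best_k)
    return best_k, threshold, mean_lo, mean_hi


def reference_cross_check(peaks: pd.DataFrame,
                          recorded_sex: Mapping[str, str] | None = None) -> ReferenceQC:
    """Infer sex from the FVIII/CN2-2 ratio and report dual-reference QC.

    The per-subject ratio is split into two clusters by the exhaustive 1-D
    two-class split minimizing within-cluster variance; the lower cluster is
    inferred male (one X copy), the upper female.  If the cluster separation
    is below twice the pooled within-cluster SD the distribution is declared
    degenerate and no sex is assigned.
    """
    ratio = relative_copy_number(peaks, target="FVIII", reference="CN2-2")
    values = ratio.to_numpy()
    n = len(values)
    degenerate = False
    inferred: pd.Series | None = None
    if n < 2 or np.ptp(values) == 0:
        degenerate = True
    else:
        k, threshold, mean_lo, mean_hi = _two_cluster_split(values)
        x = np.sort(values)
        ssw = (np.sum((x[:k] - mean_lo) ** 2) + np.sum((x[k:] - mean_hi) ** 2))
        pooled_sd = np.sqrt(ssw / max(n - 2, 1))
        if (mean_hi - mean_lo) < 2.0 * pooled_sd:
            degenerate = True
        else:
            inferred = pd.Series(
                np.where(values > threshold, "female", "male"),
                index=ratio.index, name="inferred_sex")
    if degenerate:
        logger.warning("FVIII/CN2-2 ratio distribution degenerate; "
                       "no sex assignment")

    concordance: float | None = None
    sex_for_cv: pd.Series | None = inferred
    if recorded_sex is not None:
        recorded = pd.Series(dict(recorded_sex)).reindex(ratio.index)
        if inferred is not None:
            concordance = float((inferred == recorded).mean())
        sex_for_cv = recorded if inferred is None else inferred

    cv_by_sex: dict[str, float] = {}
    if sex_for_cv is not None:
        inverse = _reaction_ratios(peaks, target="CN2-2", reference="FVIII")
        per_reaction = inverse["ratio"]
        sexes = per_reaction.index.get_level_values("subject_id").map(sex_for_cv)
        for sex in ("male", "female"):
            vals = per_reaction[np.asarray(sexes == sex)]
            if len(vals) >= 2 and vals.mean() != 0:
                cv_by_sex[sex] = float(vals.std(ddof=1) / vals.mean())
    return ReferenceQC(ratio=ratio, inferred_sex=inferred,
                       concordance=concordance, cv_by_sex=cv_by_sex,
                       degenerate=degenerate)


def dichotomize_by_median(cn: Mapping[str, float] | pd.Series,
                          strata: Mapping[str, str],
                          reference_subjects: Iterable[str],
                          ) -> tuple[list[CopyNumberCall], dict[str, float]]:
    """Sex-stratified median dichotomization.

    The cutoff per sex is the median relative CN over ``reference_subjects``
    (the non-diabetic set) in that stratum; every subject — reference or
    not — is called low (1X) iff its relative CN is strictly below the
    stratum cutoff, else high (2X).  The same cutoffs therefore carry over
    to diabetic subjects.  Returns the calls and the per-stratum cutoffs.
    """
    cn = pd.Series(dict(cn)) if not isinstance(cn, pd.Series) else cn
    reference_subjects = set(reference_subjects)
    strata = dict(strata)
    missing = [s for s in cn.index if s not in strata]
    if missing:
        raise CallingError(f"subjects without stratum: {missing[:5]}")
    cutoffs: dict[str, float] = {}
    sexes = pd.Series({s: strata[s] for s in cn.index})
    for sex in sorted(set(sexes)):
        ref_vals = cn[[s for s in cn.index
                       if sexes[s] == sex and s in reference_subjects]]
        if len(ref_vals) == 0:
            raise CallingError(f"no reference subjects in stratum {sex!r}")
        cutoffs[sex] = float(np.median(ref_vals))
        if ref_vals.nunique() == 1:
            logger.warning("stratum %s: all reference values equal; "
                           "every subject will be called high", sex)
    calls = [CopyNumberCall(
        subject_id=s,
        relative_cn=float(cn[s]),
        cn_class="1X" if cn[s] < cutoffs[sexes[s]] else "2X",
        stratum=sexes[s],
        cutoff=cutoffs[sexes[s]],
    ) for s in cn.index]
    return calls, cutoffs
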