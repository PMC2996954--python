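"""Association statistics for dichotomized copy-number classes.

Implements the study's statistical layer: pooled-variance Student's t per
trait between the low (1X) and high (2X) copy-number groups, covariate-
adjusted linear association (OLS of trait on group indicator + age + BMI
within one sex stratum), Bonferroni correction over the m = 29 association
traits, and the nested case-control layer — closed-form odds ratio with the
Woolf confidence interval and Pearson chi-square, plus a maximum-likelihood
logistic fit by iteratively reweighted least squares (IRLS) for the
covariate-controlled odds ratio.

m = 29 counts every tabulated trait except the two covariates (age and BMI).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .qmpsf import CopyNumberCall
from .synthcohort import ASSOCIATION_TRAITS

logger = logging.getLogger(__name__)

__all__ = [
    "TraitAssociation",
    "CaseControlResult",
    "StatError",
    "SeparationError",
    "two_sample_t",
    "adjusted_association",
    "bonferroni_correct",
    "odds_ratio_2x2",
    "logistic_irls",
    "association_table",
    "case_control_analysis",
    "N_ASSOCIATION_TRAITS",
]

#: Number of association traits entering the Bonferroni correction.
N_ASSOCIATION_TRAITS = len(ASSOCIATION_TRAITS)   # 29


class StatError(ValueError):
    """A statistic cannot be computed from the given input."""


class SeparationError(StatError):
    """Complete or quasi-complete separation in a logistic fit."""


@dataclass
class TraitAssociation:
    trait: str
    mean_low: float
    sd_low: float
    n_low: int
    mean_high: float
    sd_high: float
    n_high: int
    p_raw: float
    p_adjusted: float
    p_corrected: float
    significant: bool


@dataclass
class CaseControlResult:
    """2x2 analysis of case/control vs low/high copy-number class.

    a = case-low, b = case-high, c = control-low, d = control-high.
    Logistic fields hold the low-CN coefficient from the covariate-
    controlled IRLS fit when one was run, else None.
    """
    a: int
    b: int
    c: int
    d: int
    or_point: float
    ci_low: float
    ci_high: float
    chi2_p: float
    haldane: bool = False
    logit_beta: float | None = None
    logit_se: float | None = None
    logit_p: float | None = None

    @property
    def case_low_fraction(self) -> float:
        return self.a / (self.a + self.b)


# ---------------------------------------------------------------------------
# Group comparison and adjusted association
# ---------------------------------------------------------------------------

def _summary(x) -> tuple[float, float, int]:
    """Accept raw samples or a (mean, sd, n) summary triple."""
    if isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0]):
        mean, sd, n = x
        return float(mean), float(sd), int(n)
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise StatError("samples must be one-dimensional")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def two_sample_t(x, y) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student's t-test.

    Each argument is either a 1-D sample array or a (mean, sd, n) summary.
    Returns (t, degrees of freedom, p).
    """
    m1, s1, n1 = _summary(x)
    m2, s2, n2 = _summary(y)
    if n1 < 2 or n2 < 2:
        raise StatError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    if sp2 <= 0:
        raise StatError("zero pooled variance")
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def adjusted_association(trait_values, cn_group, covariates: pd.DataFrame) -> float:
    """Covariate-adjusted p-value for the copy-number group effect.

    OLS of trait on {group indicator, covariates} (intercept added); returns
    the two-sided p of the group coefficient.  Intended for one sex stratum
    at a time with age and BMI as the covariates.
    """
    y = np.asarray(trait_values, dtype=float)
    g = np.asarray(cn_group, dtype=float)
    X = pd.DataFrame({"cn_group": g})
    for col in covariates.columns:
        X[col] = np.asarray(covariates[col], dtype=float)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise StatError("collinear design matrix")
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues["cn_group"])


def bonferroni_correct(p: float, m: int = N_ASSOCIATION_TRAITS) -> float:
    """Bonferroni family-wise correction: min(1, m * p)."""
    if not 0.0 < p <= 1.0:
        raise StatError("p must be in (0, 1]")
    if m < 1:
        raise StatError("m must be >= 1")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# 2x2 case-control analysis
# ---------------------------------------------------------------------------

def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> CaseControlResult:
    """Closed-form 2x2 analysis: OR = ad/bc, Woolf 95% CI, Pearson chi-square.

    The Woolf interval is exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
    The chi-square test uses df = 1 with no continuity correction.  A zero
    cell triggers the Haldane-Anscombe correction (+0.5 to every cell) for
    the OR and CI, flagged in the result; the chi-square p is computed from
    the original counts.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise StatError("counts must be nonnegative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise StatError("a row or column of the 2x2 table is entirely zero")
    haldane = bool(np.any(counts == 0))
    w = counts + 0.5 if haldane else counts
    if haldane:
        logger.warning("zero cell in 2x2 table; Haldane-Anscombe +0.5 applied")
    log_or = math.log(w[0] * w[3] / (w[1] * w[2]))
    se = math.sqrt((1.0 / w).sum())
    chi2, chi2_p, _, _ = stats.chi2_contingency(
        [[a, b], [c, d]], correction=False)
    return CaseControlResult(
        a=int(a), b=int(b), c=int(c), d=int(d),
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - 1.959963984540054 * se),
        ci_high=math.exp(log_or + 1.959963984540054 * se),
        chi2_p=float(chi2_p),
        haldane=haldane,
    )


def logistic_irls(outcome, design, add_intercept: bool = True,
                  max_iter: int = 50, tol: float = 1e-8,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic regression by IRLS.

    Returns (beta, se, wald_p) per coefficient, intercept first when
    ``add_intercept``.  Convergence at max |delta beta| < tol within
    ``max_iter`` iterations; any |beta| exceeding 15 on the way is treated
    as complete or quasi-complete separation.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise StatError("outcome must be binary 0/1")
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatError("collinear design matrix")
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtWX = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(XtWX, X.T @ (y - mu))
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + delta
        if np.max(np.abs(beta)) > 15.0:
            raise SeparationError("diverging coefficients (|beta| > 15)")
        if np.max(np.abs(delta)) < tol:
            break
    else:
        logger.warning("IRLS did not converge in %d iterations", max_iter)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    wald_p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return beta, se, wald_p


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def _calls_to_series(calls) -> pd.Series:
    if isinstance(calls, pd.Series):
        return calls
    if isinstance(calls, Mapping):
        return pd.Series(dict(calls))
    return pd.Series({c.subject_id: c.cn_class for c in calls})


def association_table(cohort: pd.DataFrame, calls, sex: str,
                      m: int = N_ASSOCIATION_TRAITS,
                      max_missing: float = 0.2) -> list[TraitAssociation]:
    """Per-trait association table for one sex stratum.

    ``cohort`` needs columns id, sex, age, bmi and the association traits;
    ``calls`` maps subject id to cn class ("1X"/"2X") — a mapping, Series or
    list of CopyNumberCall.  Each trait gets the pooled t-test, the
    age+BMI-adjusted OLS p, and the Bonferroni-corrected p over ``m`` traits;
    ``significant`` flags corrected p < 0.05.  Traits missing for more than
    ``max_missing`` of subjects are skipped with a warning.
    """
    cls = _calls_to_series(calls)
    sub = cohort[cohort["sex"] == sex].copy()
    if sub.empty:
        raise StatError(f"no subjects in stratum {sex!r}")
    sub["cn_class"] = sub["id"].map(cls)
    if sub["cn_class"].isna().any():
        raise StatError("calls do not cover the cohort")
    results: list[TraitAssociation] = []
    for trait in ASSOCIATION_TRAITS:
        if trait not in sub.columns:
            logger.warning("trait %r absent; skipped", trait)
            continue
        vals = sub[[trait, "cn_class", "age", "bmi"]]
        complete = vals.dropna()
        if len(complete) < (1.0 - max_missing) * len(sub):
            logger.warning("trait %r missing for > %.0f%% of subjects; skipped",
                           trait, 100 * max_missing)
            continue
        low = complete.loc[complete["cn_class"] == "1X", trait].to_numpy()
        high = complete.loc[complete["cn_class"] == "2X", trait].to_numpy()
        _, _, p_raw = two_sample_t(low, high)
        p_adj = adjusted_association(
            complete[trait],
            (complete["cn_class"] == "1X").astype(float),
            complete[["age", "bmi"]])
        p_cor = bonferroni_correct(p_adj, m)
        results.append(TraitAssociation(
            trait=trait,
            mean_low=float(low.mean()), sd_low=float(low.std(ddof=1)),
            n_low=len(low),
            mean_high=float(high.mean()), sd_high=float(high.std(ddof=1)),
            n_high=len(high),
            p_raw=p_raw, p_adjusted=p_adj, p_corrected=p_cor,
            significant=p_cor < 0.05,
        ))
    return results


def case_control_analysis(subjects: pd.DataFrame, calls) -> CaseControlResult:
    """Nested case-control analysis of T2DM vs copy-number class.

    ``subjects`` needs columns id, sex, age, bmi and diabetes ("T2DM" /
    "non-T2DM").  Fills the closed-form 2x2 result (OR, Woolf CI,
    chi-square p) and the low-CN coefficient of the IRLS logistic fit
    controlling for age, sex and BMI.
    """
    cls = _calls_to_series(calls)
    df = subjects.copy()
    df["cn_class"] = df["id"].map(cls)
    if df["cn_class"].isna().any():
        raise StatError("calls do not cover the case-control set")
    case = df["diabetes"] == "T2DM"
    low = df["cn_class"] == "1X"
    a = int((case & low).sum())
    b = int((case & ~low).sum())
    c = int((~case & low).sum())
    d = int((~case & ~low).sum())
    result = odds_ratio_2x2(a, b, c, d)
    design = np.column_stack([
        low.astype(float),
        df["age"].to_numpy(dtype=float),
        (df["sex"] == "female").astype(float),
        df["bmi"].to_numpy(dtype=float),
    ])
    try:
        beta, se, p = logistic_irls(case.astype(float), design)
        result.logit_beta, result.logit_se, result.logit_p = (
            float(beta[1]), float(se[1]), float(p[1]))
    except SeparationError:
        logger.warning("logistic fit separated; reporting closed form only")
    return result


def association_frame(rows: Sequence[TraitAssociation]) -> pd.DataFrame:
    """Tabular view of an association table."""
    return pd.DataFrame([r.__dict__ for r in rows])
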