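"""Descriptive and multivariate screening of a groundwater survey.

Per-parameter moments (bias-corrected skewness and excess kurtosis, the
SPSS convention), coefficient-of-variation classes (low <= 15% <
intermediate < 35% <= high), Kolmogorov–Smirnov normality with the
Lilliefors correction for estimated parameters, a Pearson correlation
matrix with two-tailed significance stars and verbal strength labels, and
comparison of parameter means against PNSDW 2017 / WHO drinking-water
guideline values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .data import GUIDELINES, SampleSet

VARIABILITY_CLASSES = ("low", "intermediate", "high")
CORRELATION_CLASSES = ("negligible", "weak", "moderate", "strong", "very_strong")


def classify_variability(cv_percent: float) -> str:
    """CV% class: <=15 low, (15, 35) intermediate, >=35 high."""
    if cv_percent < 0:
        raise ValueError("CV% cannot be negative")
    if cv_percent <= 15.0:
        return "low"
    if cv_percent < 35.0:
        return "intermediate"
    return "high"


def classify_correlation(r: float) -> str:
    """Verbal strength of |r| on the standard bins.

    Printed bin edges leave gaps (0.39–0.40, 0.69–0.70, 0.89–0.90); values
    in a gap go to the stronger bin, and each bin's lower edge is inclusive.
    The sign is reported separately.
    """
    a = abs(r)
    if a > 1:
        raise ValueError("|r| cannot exceed 1")
    if a < 0.10:
        return "negligible"
    if a <= 0.39:
        return "weak"
    if a <= 0.69:
        return "moderate"
    if a <= 0.89:
        return "strong"
    return "very_strong"


@dataclass
class DescriptiveRow:
    parameter: str
    n: int
    mean: float
    sd: float
    skewness: float
    kurtosis: float  # excess, bias-corrected
    cv_percent: float
    variability: str
    ks_d: float
    ks_p: float
    normal_at_05: bool


def descriptive_stats(s: SampleSet, parameter: str,
                      ks_variant: str = "lilliefors") -> DescriptiveRow:
    """Moments, CV% and normality verdict for one parameter.

    Skewness is the adjusted Fisher–Pearson g1*sqrt(n(n-1))/(n-2) and
    kurtosis the bias-corrected excess kurtosis — the formulas SPSS prints.
    A zero-variance sample gets NaN moments (undefined-marker); n < 4
    raises because the corrected kurtosis needs four points.
    """
    x = s.values(parameter)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 4:
        raise ValueError("descriptive statistics need at least 4 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        skew = kurt = ks_d = ks_p = np.nan
        normal = False
    else:
        skew = float(sps.skew(x, bias=False))
        kurt = float(sps.kurtosis(x, fisher=True, bias=False))
        ks_d, ks_p, normal = ks_normality(x, variant=ks_variant)
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    return DescriptiveRow(
        parameter=parameter, n=n, mean=mean, sd=sd, skewness=skew,
        kurtosis=kurt, cv_percent=cv,
        variability=classify_variability(cv) if np.isfinite(cv) else "undefined",
        ks_d=ks_d, ks_p=ks_p, normal_at_05=bool(normal),
    )


def ks_normality(x, variant: str = "lilliefors") -> tuple[float, float, bool]:
    """One-sample K-S normality test with sample-estimated mean/sd.

    ``variant="lilliefors"`` (default) corrects the null distribution for
    the estimated parameters — the SPSS "Kolmogorov-Smirnov with Lilliefors
    significance"; ``variant="ks"`` is the naive test with the estimates
    plugged in as if known.  Returns (D, p, normal_at_alpha_05).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 5:
        raise ValueError("K-S normality needs at least 5 values")
    if np.std(x) == 0:
        raise ValueError("K-S normality undefined for constant input")
    if variant == "lilliefors":
        d, p = _lilliefors(x, dist="norm")
    elif variant == "ks":
        d, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(d), float(p), bool(p >= 0.05)


@dataclass
class CorrelationReport:
    parameters: list
    r: pd.DataFrame
    p: pd.DataFrame
    labels: pd.DataFrame
    stars: pd.DataFrame


def correlation_matrix(s: SampleSet, parameters) -> CorrelationReport:
    """Pairwise-complete Pearson matrix with p-values, labels and stars.

    Two-tailed p from t = r sqrt((n-2)/(1-r^2)); stars "**" at 0.01, "*"
    at 0.05.  Zero-variance columns yield NaN entries with a warning.
    """
    parameters = list(parameters)
    k = len(parameters)
    R = np.eye(k)
    P = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = s.values(parameters[i])
            xj = s.values(parameters[j])
            okv = np.isfinite(xi) & np.isfinite(xj)
            n = int(okv.sum())
            if n < 3:
                R[i, j] = R[j, i] = P[i, j] = P[j, i] = np.nan
                continue
            a, b = xi[okv], xj[okv]
            if np.std(a) == 0 or np.std(b) == 0:
                warnings.warn(
                    f"zero-variance column in pair "
                    f"({parameters[i]}, {parameters[j]}); undefined r"
                )
                R[i, j] = R[j, i] = P[i, j] = P[j, i] = np.nan
                continue
            r, p = sps.pearsonr(a, b)
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    labels = np.empty((k, k), dtype=object)
    starm = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            r = R[i, j]
            labels[i, j] = classify_correlation(r) if np.isfinite(r) else "undefined"
            p = P[i, j]
            starm[i, j] = ("**" if p < 0.01 else "*" if p < 0.05 else "") \
                if (i != j and np.isfinite(p)) else ""
    idx = parameters
    return CorrelationReport(
        parameters=parameters,
        r=pd.DataFrame(R, index=idx, columns=idx),
        p=pd.DataFrame(P, index=idx, columns=idx),
        labels=pd.DataFrame(labels, index=idx, columns=idx),
        stars=pd.DataFrame(starm, index=idx, columns=idx),
    )


@dataclass
class GuidelineFlag:
    parameter: str
    mean: float
    pnsdw_limit: object
    who_limit: object
    exceeds_pnsdw: bool | None
    exceeds_who: bool | None
    n_above_pnsdw: int | None
    n_above_who: int | None


def _against_limit(values, mean, limit):
    """(mean exceeds?, station count outside) for a ceiling or a range."""
    if limit is None:
        return None, None
    if isinstance(limit, tuple):
        lo, hi = limit
        return not (lo <= mean <= hi), int(np.sum((values < lo) | (values > hi)))
    return mean > limit, int(np.sum(values > limit))


def guideline_flags(s: SampleSet, guidelines=None) -> list[GuidelineFlag]:
    """Compare per-parameter means (and stations) against guideline limits.

    Parameters without a guideline entry are skipped with a warning; pH is
    judged by range membership, everything else by a ceiling.
    """
    guidelines = GUIDELINES if guidelines is None else guidelines
    out = []
    for p in s.parameters:
        if p not in guidelines:
            warnings.warn(f"no guideline for {p!r}; skipped")
            continue
        vals = s.values(p)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        mean = float(vals.mean())
        lim = guidelines[p]
        exc_p, n_p = _against_limit(vals, mean, lim.pnsdw)
        exc_w, n_w = _against_limit(vals, mean, lim.who)
        out.append(GuidelineFlag(p, mean, lim.pnsdw, lim.who,
                                 exc_p, exc_w, n_p, n_w))
    return out
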