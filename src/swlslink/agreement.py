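"""Agreement battery comparing directly derived and prorated SWLS scores.

Implements the statistics used to validate a score link in a
method-comparison design: paired difference summaries, Bland-Altman 95%
limits of agreement (mean difference ± 1.96 × SD of the differences),
Pearson correlation, single-measure intraclass correlations from the
two-way crossed ANOVA without replication, proportions of respondents
under absolute-difference thresholds, and concordance of interpretive
category assignments.

Two ICC variants are computed throughout, because the conventional labels
are ambiguous: the *consistency* form ICC(C,1) ignores a systematic offset
between the two scores, while the *absolute-agreement* form ICC(A,1)
penalizes it.  Confidence intervals use exact F-distribution bounds for the
consistency form and the McGraw-Wong Satterthwaite approximation for the
absolute-agreement form.  Estimates are interpreted on the customary
reliability bands: poor (< 0.5), moderate (0.5-0.75), good (0.75-0.9),
excellent (> 0.9).

Differences are defined as ``direct − prorated`` throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import CATEGORIES, SCALE_MAX, SCALE_MIN, Category, classify

__all__ = [
    "PairedScores",
    "DifferenceStats",
    "LimitsOfAgreement",
    "CorrelationResult",
    "AnovaMeanSquares",
    "ICCResult",
    "ConcordanceResult",
    "AgreementReport",
    "difference_stats",
    "limits_of_agreement",
    "pearson_r",
    "anova_two_way",
    "icc",
    "icc_both",
    "interpret_icc",
    "threshold_proportions",
    "category_concordance",
    "agreement_report",
]

LOA_MULTIPLIER = 1.96
DEFAULT_THRESHOLDS = (2, 3, 4)


@dataclass(frozen=True)
class PairedScores:
    """Index-aligned direct (5-item) and prorated scores for n respondents."""

    direct: np.ndarray
    prorated: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.direct, dtype=float)
        p = np.asarray(self.prorated, dtype=float)
        if d.shape != p.shape or d.ndim != 1:
            raise ValueError("direct and prorated must be equal-length 1-d vectors")
        if d.size < 2:
            raise ValueError("need at least 2 paired scores")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(p))):
            raise ValueError("missing or non-finite entries are not allowed")
        for name, v in (("direct", d), ("prorated", p)):
            if v.min() < SCALE_MIN or v.max() > SCALE_MAX:
                raise ValueError(f"{name} scores must lie within [{SCALE_MIN}, {SCALE_MAX}]")
        object.__setattr__(self, "direct", d)
        object.__setattr__(self, "prorated", p)

    @property
    def n(self) -> int:
        return self.direct.size

    @property
    def differences(self) -> np.ndarray:
        """Per-respondent direct − prorated."""
        return self.direct - self.prorated


@dataclass(frozen=True)
class DifferenceStats:
    mean_diff: float
    sd_diff: float
    mean_abs_diff: float
    sd_abs_diff: float
    n: int


@dataclass(frozen=True)
class LimitsOfAgreement:
    lower: float
    upper: float
    mean_diff: float
    sd_diff: float


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r plus the qualitative 'very high' flag (r > 0.9)."""

    r: float
    very_high: bool
    defined: bool


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Mean squares of the two-way crossed layout without replication."""

    msr: float  # between subjects (rows), df n-1
    msc: float  # between measures (columns), df k-1
    mse: float  # residual, df (n-1)(k-1)
    n: int
    k: int


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    variant: str  # "ICC(C,1)" or "ICC(A,1)"
    ci95: tuple[float, float]
    interpretation: str | None


@dataclass(frozen=True)
class ConcordanceResult:
    prop_same: float
    prop_lower: float
    prop_higher: float
    max_abs_shift: int
    crosstab: pd.DataFrame = field(repr=False)
    n: int = 0


def difference_stats(p: PairedScores) -> DifferenceStats:
    """Mean/SD of direct − prorated and of |direct − prorated| (n−1 SDs)."""
    d = p.differences
    a = np.abs(d)
    return DifferenceStats(
        mean_diff=float(d.mean()),
        sd_diff=float(d.std(ddof=1)),
        mean_abs_diff=float(a.mean()),
        sd_abs_diff=float(a.std(ddof=1)),
        n=p.n,
    )


def limits_of_agreement(d: DifferenceStats) -> LimitsOfAgreement:
    """Bland-Altman 95% limits: mean difference ± 1.96 × SD of differences."""
    half = LOA_MULTIPLIER * d.sd_diff
    return LimitsOfAgreement(
        lower=d.mean_diff - half,
        upper=d.mean_diff + half,
        mean_diff=d.mean_diff,
        sd_diff=d.sd_diff,
    )


def pearson_r(p: PairedScores) -> CorrelationResult:
    """Product-moment correlation between the two scores.

    A constant vector leaves the correlation undefined; it is reported as
    such (NaN, ``defined=False``), never as 0.
    """
    if p.n < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(p.direct) == 0 or np.ptp(p.prorated) == 0:
        return CorrelationResult(r=float("nan"), very_high=False, defined=False)
    r = float(stats.pearsonr(p.direct, p.prorated).statistic)
    return CorrelationResult(r=r, very_high=r > 0.9, defined=True)


def _as_matrix(p) -> np.ndarray:
    """n×k data matrix from PairedScores or any (n, k≥2) array-like."""
    if isinstance(p, PairedScores):
        return np.column_stack([p.direct, p.prorated])
    x = np.asarray(p, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite entries are not allowed")
    return x


def anova_two_way(p) -> AnovaMeanSquares:
    """Two-way crossed ANOVA (subjects × measures, no replication).

    Decomposes total SS into between-subject, between-measure and residual
    components; the three sums of squares add to the total exactly.
    Accepts :class:`PairedScores` or a plain n×k matrix (subjects in rows).
    """
    x = _as_matrix(p)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    return AnovaMeanSquares(
        msr=ss_rows / (n - 1),
        msc=ss_cols / (k - 1),
        mse=max(ss_err, 0.0) / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def interpret_icc(estimate: float) -> str | None:
    """Qualitative reliability band for an ICC point estimate."""
    if not np.isfinite(estimate):
        return None
    if estimate < 0.5:
        return "poor"
    if estimate <= 0.75:
        return "moderate"
    if estimate <= 0.9:
        return "good"
    return "excellent"


def _icc_consistency_ci(ms: AnovaMeanSquares, alpha: float) -> tuple[float, float]:
    # exact F bounds (Shrout-Fleiss) for the consistency single-measure form
    n, k = ms.n, ms.k
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ms.mse == 0:
        return (1.0, 1.0)
    f_obs = ms.msr / ms.mse
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    return ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))


def _icc_agreement_ci(ms: AnovaMeanSquares, est: float, alpha: float) -> tuple[float, float]:
    # McGraw-Wong Satterthwaite-df approximation for the agreement form
    n, k = ms.n, ms.k
    if est >= 1.0 or (ms.msc == 0 and ms.mse == 0):
        return (1.0, 1.0) if est == 1.0 else (float("nan"), float("nan"))
    a = k * est / (n * (1 - est))
    b = 1 + k * est * (n - 1) / (n * (1 - est))
    num = (a * ms.msc + b * ms.mse) ** 2
    den = (a * ms.msc) ** 2 / (k - 1) + (b * ms.mse) ** 2 / ((n - 1) * (k - 1))
    if den == 0:
        return (float("nan"), float("nan"))
    v = num / den
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (ms.msr - f1 * ms.mse) / (
        f1 * (k * ms.msc + (k * n - k - n) * ms.mse) + n * ms.msr
    )
    upper = n * (f2 * ms.msr - ms.mse) / (
        k * ms.msc + (k * n - k - n) * ms.mse + n * f2 * ms.msr
    )
    return (lower, upper)


def icc(p, variant: str = "agreement", alpha: float = 0.05) -> ICCResult:
    """Single-measure intraclass correlation between the paired scores.

    variant "consistency" → ICC(C,1) = (MSR − MSE) / (MSR + (k−1) MSE);
    variant "agreement"   → ICC(A,1) = (MSR − MSE) /
                            (MSR + (k−1) MSE + (k/n)(MSC − MSE)).

    When every mean square vanishes (all entries equal) the coefficient is
    undefined and reported as NaN.
    """
    ms = anova_two_way(p)
    n, k = ms.n, ms.k
    if variant == "consistency":
        denom = ms.msr + (k - 1) * ms.mse
        label = "ICC(C,1)"
    elif variant == "agreement":
        denom = ms.msr + (k - 1) * ms.mse + (k / n) * (ms.msc - ms.mse)
        label = "ICC(A,1)"
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        return ICCResult(float("nan"), label, (float("nan"), float("nan")), None)
    est = (ms.msr - ms.mse) / denom
    if variant == "consistency":
        ci = _icc_consistency_ci(ms, alpha)
    else:
        ci = _icc_agreement_ci(ms, est, alpha)
    return ICCResult(float(est), label, (float(ci[0]), float(ci[1])), interpret_icc(est))


def icc_both(p: PairedScores, alpha: float = 0.05) -> dict[str, ICCResult]:
    """Both single-measure variants, keyed 'consistency' / 'agreement'."""
    return {v: icc(p, v, alpha) for v in ("consistency", "agreement")}


def threshold_proportions(
    diffs: Iterable[float], thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> dict[float, float]:
    """Fraction of respondents with |difference| strictly below each threshold."""
    d = np.abs(np.asarray(list(diffs), dtype=float))
    if d.size == 0:
        raise ValueError("empty difference vector")
    return {float(t): float(np.mean(d < t)) for t in thresholds}


def _ranks(cats: Sequence) -> np.ndarray:
    out = []
    for c in cats:
        if isinstance(c, Category):
            out.append(c.ordinal_rank)
        else:
            out.append(int(c))
    arr = np.asarray(out)
    if arr.size and (arr.min() < 1 or arr.max() > len(CATEGORIES)):
        raise ValueError("category ranks must lie in 1..6")
    return arr


def category_concordance(direct_cats: Sequence, prorated_cats: Sequence) -> ConcordanceResult:
    """Cross-classification of category assignments under the two scores.

    Accepts ``Category`` objects or integer ordinal ranks (1-6).  'Lower' /
    'higher' are by the prorated category's rank relative to the direct one.
    """
    d = _ranks(direct_cats)
    q = _ranks(prorated_cats)
    if d.size != q.size:
        raise ValueError("category vectors must be equal length")
    if d.size == 0:
        raise ValueError("empty category vectors")
    shift = q - d
    labels = [c.label for c in CATEGORIES]
    tab = np.zeros((len(CATEGORIES), len(CATEGORIES)), dtype=int)
    np.add.at(tab, (d - 1, q - 1), 1)
    crosstab = pd.DataFrame(tab, index=pd.Index(labels, name="direct"),
                            columns=pd.Index(labels, name="prorated"))
    return ConcordanceResult(
        prop_same=float(np.mean(shift == 0)),
        prop_lower=float(np.mean(shift < 0)),
        prop_higher=float(np.mean(shift > 0)),
        max_abs_shift=int(np.max(np.abs(shift))),
        crosstab=crosstab,
        n=int(d.size),
    )


@dataclass(frozen=True)
class AgreementReport:
    """One Table-style summary row for a sample or subgroup."""

    label: str
    n: int
    sum4_mean: float
    sum4_sd: float
    direct_mean: float
    direct_sd: float
    prorated_mean: float
    prorated_sd: float
    diff: DifferenceStats
    loa: LimitsOfAgreement
    correlation: CorrelationResult
    icc_consistency: ICCResult
    icc_agreement: ICCResult
    thresholds: dict[float, float]
    concordance: ConcordanceResult

    @property
    def icc_headline(self) -> ICCResult:
        """Absolute-agreement variant, the report's headline coefficient."""
        return self.icc_agreement

    def to_dict(self) -> dict:
        """JSON-serializable nested dict of every field."""
        def _f(x):
            return None if (isinstance(x, float) and math.isnan(x)) else x

        return {
            "label": self.label,
            "n": self.n,
            "sum4": {"mean": self.sum4_mean, "sd": self.sum4_sd},
            "direct": {"mean": self.direct_mean, "sd": self.direct_sd},
            "prorated": {"mean": self.prorated_mean, "sd": self.prorated_sd},
            "difference": {
                "mean": self.diff.mean_diff,
                "sd": self.diff.sd_diff,
                "mean_abs": self.diff.mean_abs_diff,
                "sd_abs": self.diff.sd_abs_diff,
            },
            "limits_of_agreement": {"lower": self.loa.lower, "upper": self.loa.upper},
            "pearson_r": _f(self.correlation.r),
            "pearson_very_high": self.correlation.very_high,
            "icc": {
                "headline_variant": "ICC(A,1)",
                "consistency": {
                    "estimate": _f(self.icc_consistency.estimate),
                    "ci95": [_f(v) for v in self.icc_consistency.ci95],
                    "interpretation": self.icc_consistency.interpretation,
                },
                "agreement": {
                    "estimate": _f(self.icc_agreement.estimate),
                    "ci95": [_f(v) for v in self.icc_agreement.ci95],
                    "interpretation": self.icc_agreement.interpretation,
                },
            },
            "threshold_proportions": {str(t): v for t, v in self.thresholds.items()},
            "concordance": {
                "prop_same": self.concordance.prop_same,
                "prop_lower": self.concordance.prop_lower,
                "prop_higher": self.concordance.prop_higher,
                "max_abs_shift": self.concordance.max_abs_shift,
                "crosstab": self.concordance.crosstab.values.tolist(),
            },
        }

    def to_row(self) -> dict:
        """Flat one-row summary mirroring the published table's columns.

        Scores are shown to 1 decimal, correlations and ICCs to 2; rounding
        here is display-only and never feeds back into computation.
        """
        ia = self.icc_agreement
        return {
            "label": self.label,
            "n": self.n,
            "sum4_mean": round(self.sum4_mean, 1),
            "sum4_sd": round(self.sum4_sd, 1),
            "direct_mean": round(self.direct_mean, 1),
            "direct_sd": round(self.direct_sd, 1),
            "prorated_mean": round(self.prorated_mean, 1),
            "prorated_sd": round(self.prorated_sd, 1),
            "diff_mean": round(self.diff.mean_diff, 2),
            "diff_sd": round(self.diff.sd_diff, 2),
            "abs_diff_mean": round(self.diff.mean_abs_diff, 2),
            "abs_diff_sd": round(self.diff.sd_abs_diff, 2),
            "pearson_r": round(self.correlation.r, 2) if self.correlation.defined else "",
            "icc_a1": round(ia.estimate, 2) if np.isfinite(ia.estimate) else "",
            "icc_a1_ci95": (
                f"{ia.ci95[0]:.2f}-{ia.ci95[1]:.2f}" if np.isfinite(ia.estimate) else ""
            ),
            "loa_lower": round(self.loa.lower, 1),
            "loa_upper": round(self.loa.upper, 1),
        }


def agreement_report(
    direct: Iterable[float],
    prorated: Iterable[float],
    label: str = "overall",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
) -> AgreementReport:
    """Run the full validation battery on one sample and bundle the results."""
    p = PairedScores(np.asarray(list(direct)), np.asarray(list(prorated)))
    d = difference_stats(p)
    both = icc_both(p, alpha)
    d_cats = [classify(s) for s in p.direct]
    q_cats = [classify(s) for s in p.prorated]
    return AgreementReport(
        label=label,
        n=p.n,
        sum4_mean=float(np.mean(p.prorated / 1.25)),
        sum4_sd=float(np.std(p.prorated / 1.25, ddof=1)),
        direct_mean=float(p.direct.mean()),
        direct_sd=float(p.direct.std(ddof=1)),
        prorated_mean=float(p.prorated.mean()),
        prorated_sd=float(p.prorated.std(ddof=1)),
        diff=d,
        loa=limits_of_agreement(d),
        correlation=pearson_r(p),
        icc_consistency=both["consistency"],
        icc_agreement=both["agreement"],
        thresholds=threshold_proportions(p.differences, thresholds),
        concordance=category_concordance(d_cats, q_cats),
    )
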