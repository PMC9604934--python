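"""Inter-rater and between-method agreement statistics.

Implements the staged concordance workflow used to compare inclination
measurement methods:

1. Pearson correlation gate (``r > 0.7``);
2. Bland-Altman bias and 95% limits of agreement against fixed clinical
   thresholds (|bias| <= 3 deg and limit half-width <= 5 deg => concordant,
   Lin's coefficient not computed);
3. otherwise Lin's concordance correlation coefficient, decomposed into a
   lack-of-precision (LoP) and lack-of-accuracy (LoA) percentage that sum
   to 100%.

Lin's estimator uses population (1/n) moments; it factors exactly as
``ccc = r * c_b`` with ``c_b = 2 s_a s_b / (s_a^2 + s_b^2 + (mean_a -
mean_b)^2)`` in (0, 1].  Total discordance splits as
``1 - ccc = (1 - r) + r (1 - c_b)``: the first term is scatter (precision),
the second systematic shift (accuracy); LoP/LoA are those terms as
percentages of ``1 - ccc``.

Rater reliability uses ICC(2,1): two-way random effects, absolute
agreement, single rater, with the F-based 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "AgreementReport",
    "PowerParams",
    "OutlierSummary",
    "icc_absolute_agreement",
    "bland_altman",
    "lin_ccc",
    "concordance_workflow",
    "min_sample_size",
    "discrepancy_outliers",
]

VERDICTS = (
    "concordant",
    "discordant-precision-dominant",
    "discordant-accuracy-dominant",
    "correlation-failed",
)


@dataclass
class AgreementReport:
    """Outcome of the staged between-method concordance workflow.

    Fields below the stage at which the workflow stopped are ``None``:
    a failed correlation gate leaves the Bland-Altman and Lin fields empty;
    a concordant Bland-Altman stage leaves the Lin fields empty.
    """

    r: float
    verdict: str
    bias_deg: Optional[float] = None
    loa_low_deg: Optional[float] = None
    loa_high_deg: Optional[float] = None
    ccc: Optional[float] = None
    c_b: Optional[float] = None
    lop_pct: Optional[float] = None
    loa_pct: Optional[float] = None

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise DegenerateDataError(f"unknown verdict {self.verdict!r}")


@dataclass
class PowerParams:
    """Two-sample power-analysis parameters (difference of means)."""

    delta: float = 5.0
    sd: float = 10.0
    alpha: float = 0.05
    beta: float = 0.20

    def __post_init__(self):
        if self.delta <= 0 or self.sd <= 0:
            raise DegenerateDataError("delta and sd must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise DegenerateDataError("alpha and beta must lie in (0, 1)")


def _paired(a, b, min_n: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise DegenerateDataError(f"samples must have equal length ({len(a)} vs {len(b)})")
    if len(a) < min_n:
        raise DegenerateDataError(f"need at least {min_n} pairs, got {len(a)}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DegenerateDataError("samples contain non-finite values")
    return a, b


def icc_absolute_agreement(values) -> Tuple[float, float, float]:
    """ICC(2,1) with its F-based 95% confidence interval.

    ``values`` is a (cases x raters) matrix with no missing cells.  Returns
    ``(icc, ci_low, ci_high)``.  Raises :class:`DegenerateDataError` when
    the between-case variance is zero (the coefficient is undefined, not
    zero).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DegenerateDataError(f"need a (>=2 cases, >=2 raters) matrix, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise DegenerateDataError("ICC input contains missing or non-finite cells")
    n, k = x.shape
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    grand = row_means.mean()
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    sse = float((resid**2).sum())
    sst = ssr + ssc + sse
    if ssr <= 1e-12 * max(sst, 1e-12):
        raise DegenerateDataError(
            "ICC undefined: zero between-case variance (all cases identical)"
        )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse == 0.0 and msc == 0.0:
        return 1.0, 1.0, 1.0
    # F-based CI (two-way random, absolute agreement, single rater)
    if icc >= 1.0:
        return float(icc), 1.0, 1.0
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else np.inf
    f_l = stats.f.ppf(0.975, n - 1, v)
    f_u = stats.f.ppf(0.975, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), float(lower), float(upper)


def bland_altman(a, b) -> Tuple[float, float, float]:
    """Mean difference and 95% limits of agreement of ``a - b``.

    Limits are ``bias +/- 1.96 * SD`` with the sample (n-1) standard
    deviation of the differences.
    """
    a, b = _paired(a, b)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def lin_ccc(a, b) -> Tuple[float, float, float, float]:
    """Lin's concordance coefficient and its precision/accuracy split.

    Returns ``(ccc, c_b, lop_pct, loa_pct)``.  ``lop_pct + loa_pct`` is
    100 by construction whenever ``ccc < 1``; a perfectly concordant pair
    reports both percentages as 0.
    """
    a, b = _paired(a, b)
    sa2 = float(a.var())  # population (1/n) moments, per Lin's estimator
    sb2 = float(b.var())
    if sa2 == 0.0 or sb2 == 0.0:
        raise DegenerateDataError("lin_ccc: constant sample, correlation undefined")
    dmean = float(a.mean() - b.mean())
    c_b = 2.0 * math.sqrt(sa2) * math.sqrt(sb2) / (sa2 + sb2 + dmean**2)
    r = float(np.corrcoef(a, b)[0, 1])
    ccc = r * c_b
    discord = 1.0 - ccc
    if discord < 1e-15:
        return ccc, c_b, 0.0, 0.0
    lop = 100.0 * (1.0 - r) / discord
    loa = 100.0 * r * (1.0 - c_b) / discord
    return ccc, c_b, lop, loa


def concordance_workflow(
    a,
    b,
    r_gate: float = 0.7,
    bias_threshold: float = 3.0,
    ci_threshold: float = 5.0,
) -> AgreementReport:
    """Staged method-comparison decision.

    (1) Pearson r; stop as ``correlation-failed`` unless ``r > r_gate``.
    (2) Bland-Altman; if ``|bias| <= bias_threshold`` and the limit
    half-width (1.96 SD) ``<= ci_threshold`` the pair is ``concordant`` and
    Lin's coefficient is deliberately not computed.
    (3) Otherwise Lin's decomposition assigns the discordance to precision
    (LoP > 50%) or accuracy.
    """
    a, b = _paired(a, b)
    if a.std() == 0.0 or b.std() == 0.0:
        raise DegenerateDataError("concordance_workflow: constant sample")
    r = float(np.corrcoef(a, b)[0, 1])
    if not r > r_gate:
        return AgreementReport(r=r, verdict="correlation-failed")
    bias, lo, hi = bland_altman(a, b)
    half_width = (hi - lo) / 2.0
    if abs(bias) <= bias_threshold and half_width <= ci_threshold:
        return AgreementReport(
            r=r, verdict="concordant", bias_deg=bias, loa_low_deg=lo, loa_high_deg=hi
        )
    ccc, c_b, lop, loa = lin_ccc(a, b)
    verdict = (
        "discordant-precision-dominant" if lop > 50.0 else "discordant-accuracy-dominant"
    )
    return AgreementReport(
        r=r,
        verdict=verdict,
        bias_deg=bias,
        loa_low_deg=lo,
        loa_high_deg=hi,
        ccc=ccc,
        c_b=c_b,
        lop_pct=lop,
        loa_pct=loa,
    )


def min_sample_size(p: PowerParams) -> int:
    """Minimum per-group n for a two-sample comparison of means.

    Normal-approximation formula
    ``n = ceil(2 (z_{1-alpha/2} + z_{1-beta})^2 (sd / delta)^2)``.
    """
    z = stats.norm.ppf(1.0 - p.alpha / 2.0) + stats.norm.ppf(1.0 - p.beta)
    return int(math.ceil(2.0 * z**2 * (p.sd / p.delta) ** 2))


@dataclass
class OutlierSummary:
    """Per-case lone-outlier flags and pairwise disagreement rates."""

    counts: Dict[str, int]
    flags: np.ndarray  # (n_cases, 3) bool, columns ordered as `methods`
    methods: Tuple[str, str, str]
    pairwise_rates_pct: Dict[str, float]
    max_pairwise_diff: np.ndarray  # (n_cases,)


def discrepancy_outliers(
    y,
    gt,
    bflf,
    outlier_threshold: float = 5.0,
    agree_threshold: float = 5.0,
) -> OutlierSummary:
    """Identify, per case, the method that disagrees with the other two.

    Method ``m`` is the lone outlier of a case iff it differs by at least
    ``outlier_threshold`` from *both* other methods while those two agree
    (differ by less than ``agree_threshold``).  Also reports, per method
    pair, the percentage of cases differing by >= ``outlier_threshold``,
    and each case's maximum pairwise difference.
    """
    y = np.asarray(y, dtype=float).ravel()
    gt = np.asarray(gt, dtype=float).ravel()
    bflf = np.asarray(bflf, dtype=float).ravel()
    if not (len(y) == len(gt) == len(bflf)):
        raise DegenerateDataError("per-method value vectors must have equal length")
    methods = ("y_axis", "gt_line", "bflf")
    vals = np.column_stack([y, gt, bflf])
    n = len(y)
    flags = np.zeros((n, 3), dtype=bool)
    for m in range(3):
        o1, o2 = [j for j in range(3) if j != m]
        d1 = np.abs(vals[:, m] - vals[:, o1])
        d2 = np.abs(vals[:, m] - vals[:, o2])
        dother = np.abs(vals[:, o1] - vals[:, o2])
        flags[:, m] = (d1 >= outlier_threshold) & (d2 >= outlier_threshold) & (
            dother < agree_threshold
        )
    counts = {methods[m]: int(flags[:, m].sum()) for m in range(3)}
    pair_rates = {}
    maxdiff = np.zeros(n)
    for i, j in ((0, 1), (0, 2), (1, 2)):
        d = np.abs(vals[:, i] - vals[:, j])
        pair_rates[f"{methods[i]}_vs_{methods[j]}"] = 100.0 * float(
            (d >= outlier_threshold).mean()
        )
        maxdiff = np.maximum(maxdiff, d)
    return OutlierSummary(
        counts=counts,
        flags=flags,
        methods=methods,
        pairwise_rates_pct=pair_rates,
        max_pairwise_diff=maxdiff,
    )
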