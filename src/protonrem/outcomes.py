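"""Cardiac-risk modelling and the study's paired nonparametric statistics.

The lifetime risk of acute coronary events (ACE) after mediastinal
radiotherapy is modelled in the Darby linear relative-risk form: the excess
event rate grows linearly with mean heart dose (MHD),

    NTCP(MHD) = baseline * (1 + c * MHD),

where ``baseline`` is the individual's lifetime baseline risk (%) given age,
sex and cardiac risk factors (supplied, not derived — patients younger than
40 are evaluated with the baseline of a 40-year-old, per the model's
validation domain), and ``c`` is the relative excess risk per Gy(RBE)
(default 0.074/Gy from the underlying cohort model; population-calibrated
values can be configured).  Model-based selection (MBS) grants proton
treatment when the photon-minus-proton risk difference reaches 2 percentage
points.

The statistics follow the study design: paired Wilcoxon signed-rank tests
across setup-uncertainty settings, Bonferroni-corrected over the three
pairwise comparisons, and median (range) reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ACEModelParams",
    "ace_ntcp",
    "delta_ntcp",
    "mbs_gate",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "BonferroniThreshold",
    "bonferroni_threshold",
    "MedianRange",
    "summarize_median_range",
    "PairedComparison",
    "paired_comparisons",
]

MBS_DELTA_NTCP_THRESHOLD = 2.0  # percentage points


@dataclass
class ACEModelParams:
    """Inputs of the linear ACE lifetime-risk model.

    ``baseline_lifetime_risk`` already encodes age (floored at 40 years),
    sex and risk factors; ``excess_rate_per_gy`` is the relative risk
    increase per Gy(RBE) of mean heart dose.
    """

    baseline_lifetime_risk: float           # %
    excess_rate_per_gy: float = 0.074       # relative increase / Gy(RBE)
    age_floor_years: int = 40

    def __post_init__(self):
        if self.baseline_lifetime_risk < 0:
            raise ValueError("baseline risk must be non-negative")
        if self.excess_rate_per_gy < 0:
            raise ValueError("excess rate must be non-negative")


def ace_ntcp(mhd: float, params: ACEModelParams) -> float:
    """Lifetime ACE risk (%) at a given mean heart dose in Gy(RBE)."""
    if mhd < 0:
        raise ValueError("mean heart dose must be non-negative")
    return params.baseline_lifetime_risk * (1.0 + params.excess_rate_per_gy * mhd)


def delta_ntcp(photon_mhd: float, proton_mhd: float, params: ACEModelParams) -> float:
    """Excess risk (%) of the photon plan over the proton plan."""
    return ace_ntcp(photon_mhd, params) - ace_ntcp(proton_mhd, params)


def mbs_gate(delta: float, threshold: float = MBS_DELTA_NTCP_THRESHOLD) -> bool:
    """Model-based selection: the risk difference must be at least 2 %."""
    return bool(delta >= threshold)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass
class WilcoxonResult:
    statistic: float        # W+ (sum of positive ranks)
    p_value: float          # two-sided
    n_used: int             # non-zero differences
    exact: bool

    def __float__(self):
        return self.p_value


def _exact_signed_rank_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided exact p over all 2^n sign assignments via subset-sum DP.

    ``ranks2`` are doubled ranks (integers even under ties with average
    ranks), ``w2`` the doubled observed W+.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[:-r].copy() if r > 0 else counts
    denom = counts.sum()
    cdf = counts[: w2 + 1].sum() / denom
    sf = counts[w2:].sum() / denom
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired data.

    Zero differences are dropped; ties get average ranks.  The p-value is
    exact (full enumeration of the sign-assignment distribution) for up to
    ``exact_max_n`` non-zero differences, and a tie-corrected normal
    approximation with continuity correction beyond that.
    """
    x = np.asarray(x, dtype=np.float64)
    d = x - np.asarray(y, dtype=np.float64) if y is not None else x
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    if n < 5:
        warnings.warn(
            f"only {n} non-zero differences; the exact p-value is returned but "
            "has very coarse resolution", stacklevel=2,
        )
    ranks = stats.rankdata(np.abs(d))
    wpos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2.0 * ranks).astype(np.int64)
        w2 = int(np.round(2.0 * wpos))
        p = _exact_signed_rank_p(ranks2, w2)
        return WilcoxonResult(wpos, p, n, True)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (abs(wpos - mu) - 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return WilcoxonResult(wpos, p, n, False)


# ---------------------------------------------------------------------------
# multiplicity and reporting


@dataclass
class BonferroniThreshold:
    alpha: float            # unrounded corrected threshold
    displayed: float        # rounded to 3 decimals for reporting

    def __float__(self):
        return self.alpha


def bonferroni_threshold(alpha: float, m: int) -> BonferroniThreshold:
    """Family-wise alpha divided by the number of comparisons
    (0.05 over 3 comparisons displays as 0.017)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    corrected = alpha / m
    return BonferroniThreshold(corrected, round(corrected, 3))


@dataclass
class MedianRange:
    median: float
    min: float
    max: float
    formatted: str

    def __str__(self):
        return self.formatted


def summarize_median_range(values, decimals: int = 1) -> MedianRange:
    """Median with range, formatted ``median (min–max)`` to one decimal by
    default (even n: mean of the middle two)."""
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    med, lo, hi = float(np.median(v)), float(v.min()), float(v.max())
    fmt = f"{{:.{decimals}f}}"
    formatted = f"{fmt.format(med)} ({fmt.format(lo)}–{fmt.format(hi)})"
    return MedianRange(med, lo, hi, formatted)


@dataclass
class PairedComparison:
    metric: str
    setting_a: str
    setting_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    p_value: float
    significant: bool


def paired_comparisons(
    metric: str,
    values_by_setting: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> tuple[list[PairedComparison], BonferroniThreshold]:
    """All pairwise Wilcoxon tests across settings with Bonferroni control."""
    names = list(values_by_setting)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    thr = bonferroni_threshold(alpha, max(len(pairs), 1))
    out = []
    for a, b in pairs:
        va = np.asarray(values_by_setting[a], dtype=np.float64)
        vb = np.asarray(values_by_setting[b], dtype=np.float64)
        if va.shape != vb.shape:
            raise ValueError("paired settings must have equal-length samples")
        res = wilcoxon_signed_rank(va, vb)
        out.append(
            PairedComparison(metric, a, b, va, vb, res.p_value, res.p_value < thr.alpha)
        )
    return out, thr
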