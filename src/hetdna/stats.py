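"""Statistical layer: tract-length medians, contingency tests, distribution
comparisons, and Luria-Delbrück fluctuation-rate estimation.

The crossover rate estimator is the Lea-Coulson method of the median: the
expected number of recombination events per culture ``m`` solves

    r_median / m - ln(m) = 1.24

for the observed median mutant count ``r_median``; the rate per cell per
generation is ``m / N`` with ``N`` the mean number of viable cells per
culture.  The 95% CI is computed on ln(m) with the Stewart-type standard
error ``sigma = 1.225 * m**-0.315 / sqrt(C)`` over ``C`` cultures, then
exponentiated back to the rate scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .substrate import MarkerMap, Side
from .tracts import SegmentedEvent, hetdna_length, total_hetdna_length

LEA_COULSON_CONST = 1.24


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# medians


@dataclass
class MedianSummary:
    median_upstream: float | None
    median_downstream: float | None
    median_total: float | None
    side_sum: float | None  # sum of the two per-side medians
    n_upstream: int
    n_downstream: int
    n_total: int


def _has_hetdna(event: SegmentedEvent) -> bool:
    return any("H" in call.genotype for call in (event.trunc, event.full))


def median_summary(
    events: list[SegmentedEvent],
    anchors: list[float],
    marker_map: MarkerMap,
) -> MedianSummary:
    """Per-side and total hetDNA-length medians over events containing
    hetDNA (even-count medians are the mean of the central pair)."""
    ups, dns, totals = [], [], []
    kept = [(e, a) for e, a in zip(events, anchors) if _has_hetdna(e)]
    if not kept:
        raise StatsError("no events with hetDNA")
    for event, anchor in kept:
        up = hetdna_length(event, Side.UPSTREAM, anchor, marker_map)
        dn = hetdna_length(event, Side.DOWNSTREAM, anchor, marker_map)
        if up > 0:
            ups.append(up)
        if dn > 0:
            dns.append(dn)
        if up > 0 or dn > 0:
            totals.append(total_hetdna_length(event, anchor, marker_map))
    med = lambda x: float(np.median(x)) if x else None
    mu, md = med(ups), med(dns)
    return MedianSummary(
        median_upstream=mu,
        median_downstream=md,
        median_total=med(totals),
        side_sum=(mu + md) if mu is not None and md is not None else None,
        n_upstream=len(ups),
        n_downstream=len(dns),
        n_total=len(totals),
    )


# ---------------------------------------------------------------------------
# classical tests (scipy-backed behind this module's surface)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (sum of
    hypergeometric probabilities no larger than the observed table's)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any() or not np.allclose(arr, arr.round()):
        raise StatsError("need a 2x2 table of non-negative integers")
    return float(sps.fisher_exact(arr.astype(int), alternative="two-sided")[1])


def chisq_gof(observed, expected_proportions, yates: bool = False) -> tuple[float, float]:
    """Pearson goodness-of-fit statistic and upper-tail p with k-1 df."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    props = props / props.sum()
    exp = props * obs.sum()
    if (exp <= 0).any():
        raise StatsError("all expected counts must be positive")
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / exp).sum())
    p = float(sps.chi2.sf(stat, df=len(obs) - 1))
    return stat, p


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p.

    Exact distribution when the smaller sample has <= 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Lea-Coulson method of the median


@dataclass
class RateEstimate:
    rate: float | None  # events per cell per generation
    m_hat: float | None  # events per culture
    ci95: tuple[float, float] | None
    n_cultures: int
    median_count: float
    flagged: bool = False
    rate_upper_bound: float | None = None


def _solve_lea_coulson(r_median: float) -> float:
    """Unique positive root of r/m - ln(m) = 1.24 (bracketed bisection)."""
    f = lambda m: r_median / m - math.log(m) - LEA_COULSON_CONST
    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise StatsError("failed to bracket Lea-Coulson root")
    return float(optimize.brentq(f, lo, hi, rtol=1e-9))


def lea_coulson_rate(
    mutant_counts, n_total_cells: float
) -> RateEstimate:
    """Method-of-the-median rate estimate with a 95% CI.

    With an all-zero count vector there is no point estimate; the standard
    95% upper bound from the zero-culture likelihood, m <= -ln(0.05)/C, is
    returned flagged instead.
    """
    counts = [int(c) for c in mutant_counts]
    if len(counts) < 2:
        raise StatsError("need at least 2 cultures")
    if any(c < 0 for c in counts):
        raise StatsError("negative mutant count")
    if n_total_cells <= 0:
        raise StatsError("n_total_cells must be positive")
    r_med = float(np.median(counts))
    if r_med < 1:
        m_bound = -math.log(0.05) / len(counts)
        return RateEstimate(
            rate=None,
            m_hat=None,
            ci95=None,
            n_cultures=len(counts),
            median_count=r_med,
            flagged=True,
            rate_upper_bound=m_bound / n_total_cells,
        )
    m_hat = _solve_lea_coulson(r_med)
    sigma = 1.225 * m_hat ** (-0.315) / math.sqrt(len(counts))
    lo = math.exp(math.log(m_hat) - 1.96 * sigma)
    hi = math.exp(math.log(m_hat) + 1.96 * sigma)
    return RateEstimate(
        rate=m_hat / n_total_cells,
        m_hat=m_hat,
        ci95=(lo / n_total_cells, hi / n_total_cells),
        n_cultures=len(counts),
        median_count=r_med,
    )
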