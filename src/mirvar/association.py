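"""Statistical analyses of target-allele frequencies.

Two analyses are provided on top of the pair/frequency machinery:

* a **latitude model** — ordinary least squares regression of the
  target-allele frequency on the absolute latitude of each sampled
  population's collection centroid, with recently migrated populations
  excluded; and
* a **paired frequency-shift test** — a two-sided Wilcoxon signed-rank
  test between two aligned frequency vectors (canonically European minus
  African target-allele frequencies over a shared site list), reported
  with the Hodges-Lehmann pseudomedian of the paired differences and a
  distribution-inversion 95% confidence interval.

The Hodges-Lehmann estimate is the median of the Walsh averages
(d_i + d_j)/2 over i <= j of the paired differences; its confidence
interval takes order statistics of the sorted Walsh averages at the
signed-rank critical value (exact null for n <= 25 without ties, normal
approximation with continuity correction otherwise).  Zero differences
are dropped before ranking, following Wilcoxon's original policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDesignError, InvalidInputError, UndefinedTestError

logger = logging.getLogger(__name__)

#: populations excluded from geographic analyses because the sampled
#: individuals are recent migrants whose location is uninformative
DEFAULT_EXCLUDED_POPULATIONS = frozenset(
    {"CHD", "CEU", "ASW", "ACB", "GIH", "STU", "ITU"}
)

#: sample size above which (or in the presence of ties) the signed-rank
#: null switches from exact enumeration to the normal approximation
EXACT_SIGNED_RANK_LIMIT = 25


@dataclass(frozen=True)
class PopulationGeoRecord:
    """A sampled population's collection geography.

    Multiple collection points are summarised by their plate carree
    centroid (arithmetic mean of latitudes and of longitudes); the
    effective latitude is the absolute value of the centroid latitude.
    """

    population: str
    points: tuple[tuple[float, float], ...]
    excluded: bool = False

    def __post_init__(self):
        for lat, _lon in self.points:
            if abs(lat) > 90:
                raise InvalidInputError(
                    f"{self.population}: latitude {lat} outside [-90, 90]"
                )

    @property
    def effective_latitude(self) -> float:
        return centroid_latitude(self.points)


def centroid_latitude(points: Sequence[tuple[float, float]]) -> float:
    """Absolute latitude of the plate carree centroid of collection points.

    The centroid is the arithmetic mean of the raw signed coordinates;
    the absolute value is taken afterwards.  Antipodal or hemisphere-
    symmetric point sets therefore cancel — a documented limitation of
    the flat centroid.
    """
    if len(points) == 0:
        raise InvalidInputError("need at least one collection point")
    return abs(float(np.mean([lat for lat, _ in points])))


@dataclass(frozen=True)
class LatitudeModelFit:
    slope: float
    intercept: float
    r2: float
    r2_adjusted: float
    p_value: float
    n: int


def fit_latitude_model(
    records: Sequence[tuple[float, float]],
) -> LatitudeModelFit:
    """OLS of target-allele frequency on absolute latitude.

    ``records`` are (effective latitude, frequency) for the populations
    retained after the migration exclusion.  Returns the fitted slope and
    intercept, plain and adjusted R^2, and the two-sided p-value of the
    slope t-test.  Requires >= 3 populations and a non-constant latitude.
    """
    if len(records) < 3:
        raise InvalidInputError("need >= 3 populations for a defined p-value")
    lat = np.asarray([r[0] for r in records], dtype=float)
    freq = np.asarray([r[1] for r in records], dtype=float)
    if np.ptp(lat) == 0.0:
        raise DegenerateDesignError("all latitudes identical; slope unidentifiable")
    model = sm.OLS(freq, sm.add_constant(lat)).fit()
    r2, r2_adj = float(model.rsquared), float(model.rsquared_adj)
    if np.ptp(freq) == 0.0:  # constant response: define R^2 = 0, not NaN
        r2 = r2_adj = 0.0
    return LatitudeModelFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=r2,
        r2_adjusted=r2_adj,
        p_value=float(model.pvalues[1]),
        n=len(records),
    )


@dataclass(frozen=True)
class ShiftTestResult:
    n_pairs: int
    p_value: float
    shift_median: float
    ci95: tuple[float, float]
    n_zero_dropped: int = 0
    exact: bool = False


def _walsh_averages(d: np.ndarray) -> np.ndarray:
    """All (d_i + d_j)/2 with i <= j, sorted ascending."""
    i, j = np.triu_indices(d.size)
    return np.sort((d[i] + d[j]) / 2.0)


def _signrank_cdf_exact(n: int) -> np.ndarray:
    """Null CDF of the signed-rank statistic W+ for sample size n.

    Counts sign assignments by dynamic programming over rank sums; the
    returned array has length n(n+1)/2 + 1, entry w = P(W+ <= w).
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        counts[rank:] += counts[: m + 1 - rank].copy()
    return np.cumsum(counts) / 2.0**n


def _signrank_critical_value(n: int, alpha: float, exact: bool) -> int:
    """Largest c with P(W+ <= c) <= alpha/2 under the null (or -1 if none)."""
    if exact:
        cdf = _signrank_cdf_exact(n)
        ok = np.nonzero(cdf <= alpha / 2.0)[0]
        return int(ok[-1]) if ok.size else -1
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    c = int(np.floor(mean + stats.norm.ppf(alpha / 2.0) * sd - 0.5))
    return max(c, -1)


def paired_shift_test(
    freqs_a: Sequence[float],
    freqs_b: Sequence[float],
    confidence: float = 0.95,
    exact_limit: int = EXACT_SIGNED_RANK_LIMIT,
) -> ShiftTestResult:
    """Wilcoxon signed-rank test and Hodges-Lehmann shift for paired data.

    Tests whether the differences b - a are symmetric about zero
    (two-sided).  Zero differences are dropped before ranking and their
    count reported.  The shift estimate is the HL pseudomedian of the
    non-zero differences; its confidence interval inverts the signed-rank
    distribution over the Walsh averages.

    Raises
    ------
    UndefinedTestError
        If no pairs remain after zero removal.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("paired vectors must have equal length")
    d = b - a
    nonzero = d != 0.0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    if d.size == 0:
        raise UndefinedTestError("all paired differences are zero; test undefined")
    if n_zero:
        logger.info("dropped %d zero differences before ranking", n_zero)

    n = d.size
    has_ties = np.unique(np.abs(d)).size < n
    exact = n <= exact_limit and not has_ties
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=not exact,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )

    walsh = _walsh_averages(d)
    hl = float(np.median(walsh))
    c = _signrank_critical_value(n, 1.0 - confidence, exact)
    m = walsh.size
    if c < 0 or c > (m - 1) // 2:
        lo, hi = walsh[0], walsh[-1]  # degenerate: whole Walsh range
    else:
        # order statistics A_(c+1) and A_(m-c), 1-based
        lo, hi = walsh[c], walsh[m - 1 - c]
    return ShiftTestResult(
        n_pairs=n,
        p_value=float(res.pvalue),
        shift_median=hl,
        ci95=(float(lo), float(hi)),
        n_zero_dropped=n_zero,
        exact=exact,
    )


@dataclass(frozen=True)
class FstDistributionReport:
    n_total: int
    threshold: float
    n_at_or_above: int
    fraction: float
    histogram_counts: tuple[int, ...] = field(default=())
    histogram_edges: tuple[float, ...] = field(default=())


def fst_distribution_report(
    fst_values: Sequence[float], threshold: float, bins: int = 20
) -> FstDistributionReport:
    """Summarise an Fst distribution against an inclusive threshold.

    Values are clamped into [0, 1] (negative finite-sample estimates map
    to 0); the count uses ``value >= threshold``.  Histogram data over
    [0, 1] is included for plotting.
    """
    v = np.asarray(fst_values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("empty Fst vector")
    v = np.clip(v, 0.0, 1.0)
    n_hit = int((v >= threshold).sum())
    counts, edges = np.histogram(v, bins=bins, range=(0.0, 1.0))
    return FstDistributionReport(
        n_total=int(v.size),
        threshold=threshold,
        n_at_or_above=n_hit,
        fraction=n_hit / v.size,
        histogram_counts=tuple(int(c) for c in counts),
        histogram_edges=tuple(float(e) for e in edges),
    )
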