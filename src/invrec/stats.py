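"""Recombination statistics: map lengths, exact intervals and tests.

Everything here is deliberately small and exact-method based, matching
how sparse recombination-event counts are analyzed in practice: genetic
map lengths as recombinant fractions with Clopper–Pearson exact binomial
confidence intervals, two-sided Fisher exact tests on 2x2 contingency
tables (point-probability definition), Spearman rank correlation of
window frequencies against distance from an inversion breakpoint,
two-sample Kolmogorov–Smirnov comparison of event position
distributions, window binning with per-window exact CIs, and the
closed-form prediction of how many gene-conversion tracts a given
marker density can detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "MapEstimate",
    "WindowedFrequency",
    "SpearmanResult",
    "PowerResult",
    "map_length_cM",
    "clopper_pearson",
    "fisher_exact_two_sided",
    "spearman_distance_corr",
    "ks_two_sample",
    "bin_and_normalize",
    "detection_probability",
    "simulated_detection_probability",
    "expected_ncogc_recovery",
    "format_p",
]


@dataclass(frozen=True)
class MapEstimate:
    """A genetic map length: 1 cM = 1% recombinant offspring."""

    name: str
    n_recomb: int
    n_total: int
    cM: float
    ci_lo_cM: float
    ci_hi_cM: float

    def __str__(self) -> str:
        return (
            f"{self.name or 'interval'}: {self.n_recomb}/{self.n_total} = "
            f"{self.cM:.2f} cM (95% CI {self.ci_lo_cM:.2f}-{self.ci_hi_cM:.2f})"
        )


@dataclass(frozen=True)
class WindowedFrequency:
    """One non-overlapping window of the event-frequency map."""

    start: int  # 0-based half-open [start, end)
    end: int
    count: int
    frequency: float  # count / total events in the analysis set
    ci_lo: float
    ci_hi: float
    distance_to_breakpoint: float  # window midpoint to breakpoint (bp)


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p: float

    @property
    def undefined(self) -> bool:
        return math.isnan(self.r)


@dataclass(frozen=True)
class PowerResult:
    """NCOGC detection power under a marker-density model.

    ``p_detect`` is the probability that a single conversion tract
    covers at least one diagnostic marker; ``expected_recovered`` is
    ``n_offspring * tracts_per_meiosis * p_detect``.
    """

    tracts_per_meiosis: float
    tract_mean: float
    marker_spacing: float
    n_offspring: int
    p_detect: float
    expected_recovered: float


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for k/n.

    Obtained by inverting the binomial tail probabilities via beta
    quantiles; the lower bound is 0 when k = 0 and the upper bound 1
    when k = n.
    """
    if n <= 0 or not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n and n > 0")
    if not (0 < conf < 1):
        raise ValueError("conf must be in (0, 1)")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


def map_length_cM(n_recomb: int, n_total: int, name: str = "", conf: float = 0.95) -> MapEstimate:
    """Map length in centiMorgans with an exact binomial CI."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_recomb <= n_total):
        raise ValueError("need 0 <= n_recomb <= n_total")
    lo, hi = clopper_pearson(n_recomb, n_total, conf)
    return MapEstimate(
        name=name,
        n_recomb=int(n_recomb),
        n_total=int(n_total),
        cM=100.0 * n_recomb / n_total,
        ci_lo_cM=100.0 * lo,
        ci_hi_cM=100.0 * hi,
    )


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table ((a, b), (c, d)).

    Point-probability definition: the sum of hypergeometric
    probabilities of all tables with the same margins whose probability
    does not exceed that of the observed table.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def spearman_distance_corr(windows, breakpoint: int | None = None) -> SpearmanResult:
    """Spearman rank correlation of window frequency vs breakpoint distance.

    ``windows`` is a list of :class:`WindowedFrequency` (their stored
    distances are used unless ``breakpoint`` is given, in which case
    distances are recomputed from window midpoints).  Ties get average
    ranks; the p-value uses the two-sided t approximation on n-2 df.  A
    constant vector has undefined correlation, returned as NaN.
    """
    if len(windows) < 4:
        raise ValueError("need at least 4 windows")
    freq = np.array([w.frequency for w in windows], dtype=float)
    if breakpoint is None:
        dist = np.array([w.distance_to_breakpoint for w in windows], dtype=float)
    else:
        dist = np.array([abs((w.start + w.end) / 2.0 - breakpoint) for w in windows])
    if np.all(freq == freq[0]) or np.all(dist == dist[0]):
        return SpearmanResult(float("nan"), float("nan"))
    r, p = sps.spearmanr(dist, freq)
    return SpearmanResult(float(r), float(p))


def ks_two_sample(sample1, sample2) -> tuple[float, float]:
    """Two-sample KS test (asymptotic p) on event position samples."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return (float(res.statistic), float(min(res.pvalue, 1.0)))


def bin_and_normalize(
    events,
    analysis_interval: tuple[int, int],
    window: int = 150_000,
    breakpoint: int | None = None,
    conf: float = 0.95,
) -> list[WindowedFrequency]:
    """Bin events into non-overlapping windows and normalize by the total.

    Windows are anchored at the analysis-interval start (the last window
    may be partial).  Each event is assigned by the midpoint of its
    flanking-marker uncertainty interval, half-open on the right.
    Frequencies are counts divided by the total number of events in the
    analysis set — the sample-size normalization used when only a subset
    of all recombinants is sequenced — with a per-window Clopper–Pearson
    CI on count/total.  With zero events all frequencies are NaN.
    """
    start, end = analysis_interval
    if not (0 <= start < end):
        raise ValueError("bad analysis interval")
    if window <= 0:
        raise ValueError("window must be positive")
    mids = np.array(
        [e.midpoint for e in events if not getattr(e, "excluded", False)], dtype=float
    )
    mids = mids[(mids >= start) & (mids < end)]
    total = len(mids)
    starts = np.arange(start, end, window, dtype=np.int64)
    out = []
    for a in starts:
        b = min(int(a) + window, end)
        count = int(((mids >= a) & (mids < a + window)).sum())
        if total > 0:
            freq = count / total
            lo, hi = clopper_pearson(count, total, conf)
        else:
            freq = lo = hi = float("nan")
        mid = (int(a) + b) / 2.0
        d = abs(mid - breakpoint) if breakpoint is not None else float("nan")
        out.append(WindowedFrequency(int(a), b, count, freq, lo, hi, d))
    return out


def detection_probability(tract_mean: float, marker_spacing: float, tract_model: str = "fixed") -> float:
    """P(a conversion tract covers >= 1 marker) under Poisson markers.

    ``fixed``: all tracts have length L = tract_mean, so
    P = 1 - exp(-L/d̄).  ``geometric``: tract length is geometric with
    mean L (the simulator's tract model); averaging the fixed-length
    expression over the geometric law gives
    P = 1 - p e^{-s} / (1 - (1-p) e^{-s}) with p = 1/L, s = 1/d̄.
    """
    if tract_mean <= 0 or marker_spacing <= 0:
        raise ValueError("tract_mean and marker_spacing must be positive")
    s = 1.0 / marker_spacing
    if tract_model == "fixed":
        return 1.0 - math.exp(-tract_mean * s)
    if tract_model == "geometric":
        p = 1.0 / tract_mean
        es = math.exp(-s)
        return 1.0 - (p * es) / (1.0 - (1.0 - p) * es)
    raise ValueError("tract_model must be 'fixed' or 'geometric'")


def simulated_detection_probability(
    tract_mean: float,
    marker_spacing: float,
    n_sim: int = 100_000,
    seed=None,
    tract_model: str = "fixed",
) -> tuple[float, float]:
    """Monte-Carlo estimate (and its SE) of the tract detection probability.

    Draws tract lengths from the stated model and marker counts within
    each tract from a Poisson process at rate 1/spacing; a tract is
    detected when it contains at least one marker.
    """
    rng = np.random.default_rng(seed)
    if tract_model == "fixed":
        lengths = np.full(n_sim, float(tract_mean))
    elif tract_model == "geometric":
        lengths = rng.geometric(1.0 / tract_mean, size=n_sim).astype(float)
    else:
        raise ValueError("tract_model must be 'fixed' or 'geometric'")
    hits = rng.poisson(lengths / marker_spacing) > 0
    p = float(hits.mean())
    se = math.sqrt(max(p * (1 - p), 1e-12) / n_sim)
    return (p, se)


def expected_ncogc_recovery(
    tracts_per_meiosis: float,
    tract_mean: float,
    marker_spacing: float,
    n_offspring: int,
    tract_model: str = "fixed",
) -> PowerResult:
    """Predicted NCOGC yield from sequencing ``n_offspring`` offspring.

    E[recovered] = n * lambda * P_detect, with lambda the expected
    conversion tracts per meiosis on the chromosome and P_detect from
    :func:`detection_probability`.
    """
    if tracts_per_meiosis <= 0 or n_offspring <= 0:
        raise ValueError("tracts_per_meiosis and n_offspring must be positive")
    p = detection_probability(tract_mean, marker_spacing, tract_model)
    return PowerResult(
        tracts_per_meiosis=float(tracts_per_meiosis),
        tract_mean=float(tract_mean),
        marker_spacing=float(marker_spacing),
        n_offspring=int(n_offspring),
        p_detect=p,
        expected_recovered=n_offspring * tracts_per_meiosis * p,
    )


def format_p(p: float) -> str:
    """Report a p-value to 2 significant figures, flooring at 1e-4."""
    if math.isnan(p):
        return "NA"
    if p < 1e-4:
        return "< 0.0001"
    return f"{p:.2g}"
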