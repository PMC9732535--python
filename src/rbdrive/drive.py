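"""Hypothesis tests for meiotic drive (transmission ratio distortion).

Goodness-of-fit of observed offspring Rb-count distributions to the
segregation null, one-sample binomial proportion tests, transmission
proportion estimation with Wilson intervals, a maternal-vs-paternal
two-proportion comparison, and a variance-ratio dispersion test that
separates shape distortion from a mean shift.

All Monte-Carlo p-values use the add-one estimator (1 + b) / (1 + B), so a
resampled p is never exactly zero, and are bit-reproducible for a fixed
seed (NumPy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .segregation import (
    CountDistribution,
    SegregationModel,
    fraction_of_max,
    transmission_pmf,
)

__all__ = [
    "GofResult",
    "ProportionResult",
    "gof_test",
    "proportion_test",
    "estimate_transmission",
    "compare_transmission",
    "dispersion_test",
]


@dataclass
class GofResult:
    """Goodness-of-fit test output."""

    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    method: str  # "asymptotic" | "monte_carlo"
    n_resamples: int | None = None
    seed: int | None = None
    pooled_bins: str = "none"


@dataclass
class ProportionResult:
    """Binomial proportion test / estimate output.

    ``estimate`` is the point estimate of the proportion under test;
    ``conf_int`` is the two-sided 95% Wilson score interval.  ``note``
    records modelling assumptions (e.g. independence of trivalent
    segregations across littermates for aggregated estimates).
    """

    estimate: float
    z: float | None
    p_value: float
    method: str  # "normal_approx" | "exact_binomial" | "two_proportion_z"
    alternative: str  # "greater" | "less" | "two_sided"
    conf_int: tuple[float, float]
    note: str = ""


def _pool_boundaries(expected: np.ndarray, threshold: float) -> tuple[int, int]:
    """Tail-pooling boundaries: bins 0..lo merge, bins hi-1..end merge.

    Bins are accumulated inward from each tail until the pooled expectation
    reaches the threshold; the interior is left untouched.
    """
    nbins = len(expected)
    lo = 0
    while lo < nbins - 1 and expected[: lo + 1].sum() < threshold:
        lo += 1
    hi = nbins
    while hi - 1 > lo + 1 and expected[hi - 1 :].sum() < threshold:
        hi -= 1
    return lo, hi


def _pool(arr: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Apply tail pooling along the last axis of a 1-D or 2-D count array."""
    a = np.atleast_2d(arr)
    out = np.concatenate(
        [a[:, : lo + 1].sum(axis=1, keepdims=True),
         a[:, lo + 1 : hi - 1],
         a[:, hi - 1 :].sum(axis=1, keepdims=True)],
        axis=1,
    )
    return out[0] if arr.ndim == 1 else out


def _chi2_stat(observed: np.ndarray, expected: np.ndarray) -> float:
    return float(((observed - expected) ** 2 / expected).sum())


def gof_test(
    observed: CountDistribution,
    model: SegregationModel,
    method: str = "asymptotic",
    pool_below: float | None = None,
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> GofResult:
    """Chi-square goodness of fit of offspring counts to a segregation model.

    Parameters
    ----------
    method:
        ``"asymptotic"`` uses the chi-square reference distribution with
        ``df = bins - 1``.  With small expected tail counts the chi-square
        approximation is anti-conservative; ``"monte_carlo"`` instead draws
        ``n_resamples`` multinomial(N, pmf) datasets and reports the add-one
        resampling p-value, which is exact up to Monte-Carlo error and is
        the defensible default when any expected count is below 5.
    pool_below:
        If given, adjacent tail bins are merged until every pooled tail bin
        has expected count at or above this threshold, before computing the
        statistic and df.

    Raises
    ------
    ValueError
        If under the asymptotic method without pooling some expected count
        is zero while the corresponding observed count is positive (the
        statistic would be infinite).
    """
    if observed.n < 1:
        raise ValueError("goodness-of-fit requires at least one offspring")
    if model.n_trivalents != observed.n_trivalents:
        raise ValueError("model and observed distribution disagree on n_trivalents")
    pmf = transmission_pmf(model)
    n_total = observed.n
    expected_full = n_total * pmf
    obs = observed.counts.astype(float)

    if pool_below is not None:
        lo, hi = _pool_boundaries(expected_full, pool_below)
        obs_used = _pool(obs, lo, hi)
        exp_used = _pool(expected_full, lo, hi)
        pooled_desc = (
            f"k<={lo} pooled, k>={hi - 1} pooled"
            if (lo > 0 or hi < len(expected_full)) else "none"
        )
    else:
        obs_used, exp_used, pooled_desc = obs, expected_full, "none"

    zero_exp = exp_used <= 0
    if zero_exp.any() and (obs_used[zero_exp] > 0).any():
        raise ValueError(
            "expected count is zero in a bin with observed offspring; "
            "the chi-square statistic is infinite (pool bins or use monte_carlo)"
        )
    keep = ~zero_exp
    statistic = _chi2_stat(obs_used[keep], exp_used[keep])
    df = int(keep.sum()) - 1

    if method == "asymptotic":
        p_value = float(stats.chi2.sf(statistic, df))
        return GofResult(statistic, df, p_value, expected_full, "asymptotic",
                         pooled_bins=pooled_desc)
    if method == "monte_carlo":
        if n_resamples < 1000:
            raise ValueError("monte_carlo requires n_resamples >= 1000")
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(n_total, pmf, size=n_resamples).astype(float)
        if pool_below is not None:
            sims_used = _pool(sims, lo, hi)
        else:
            sims_used = sims
        sim_stats = ((sims_used[:, keep] - exp_used[keep]) ** 2 / exp_used[keep]).sum(axis=1)
        exceed = int((sim_stats >= statistic).sum())
        p_value = (1 + exceed) / (1 + n_resamples)
        return GofResult(statistic, df, p_value, expected_full, "monte_carlo",
                         n_resamples=n_resamples, seed=seed, pooled_bins=pooled_desc)
    raise ValueError(f"unknown method {method!r}")


def proportion_test(
    successes: int,
    trials: int,
    p0: float = 0.5,
    alternative: str = "greater",
    method: str = "normal_approx",
) -> ProportionResult:
    """One-sample binomial proportion test.

    The normal approximation uses the null standard error
    ``sqrt(p0 (1 - p0) / trials)`` with no continuity correction; the
    two-sided p is twice the smaller one-sided p.  ``exact_binomial`` uses
    binomial tail sums.  The attached 95% confidence interval is the Wilson
    score interval in both cases.
    """
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in 0..trials")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be strictly inside (0, 1)")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    p_hat = successes / trials
    ci = proportion_confint(successes, trials, alpha=0.05, method="wilson")

    if method == "normal_approx":
        se0 = np.sqrt(p0 * (1.0 - p0) / trials)
        z = (p_hat - p0) / se0
        if alternative == "greater":
            p_value = float(stats.norm.sf(z))
        elif alternative == "less":
            p_value = float(stats.norm.cdf(z))
        else:
            p_value = float(2.0 * stats.norm.sf(abs(z)))
        return ProportionResult(p_hat, float(z), p_value, "normal_approx",
                                alternative, (float(ci[0]), float(ci[1])))
    if method == "exact_binomial":
        alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[alternative]
        p_value = float(stats.binomtest(successes, trials, p0, alternative=alt).pvalue)
        return ProportionResult(p_hat, None, p_value, "exact_binomial",
                                alternative, (float(ci[0]), float(ci[1])))
    raise ValueError(f"unknown method {method!r}")


def estimate_transmission(dist: CountDistribution) -> ProportionResult:
    """Estimate the per-trivalent transmission proportion from offspring counts.

    Treats each of the ``n * N`` trivalent segregations behind the cohort as
    an independent Bernoulli trial: the estimate is
    ``sum(k * counts[k]) / (n * N)`` with a Wilson 95% interval, tested
    two-sided against the Mendelian 0.5.  Independence across trivalents
    and across littermates is an assumption, not a finding; the result
    carries a note saying so.
    """
    if dist.n < 1:
        raise ValueError("estimate_transmission requires at least one offspring")
    k = np.arange(dist.n_trivalents + 1)
    successes = int((k * dist.counts).sum())
    trials = dist.n_trivalents * dist.n
    res = proportion_test(successes, trials, 0.5, "two_sided", "normal_approx")
    res.note = (
        "assumes independent segregation across trivalents and littermates; "
        f"aggregated {successes}/{trials} trivalent transmissions"
    )
    return res


def compare_transmission(
    dist_a: CountDistribution, dist_b: CountDistribution
) -> ProportionResult:
    """Two-proportion pooled z-test of transmission between two cohorts.

    Aggregates each cohort to trivalent-level successes (``sum k*counts``
    out of ``n * N`` trials), forms the pooled estimate and tests the
    difference two-sided.  ``z`` is signed as cohort a minus cohort b;
    ``estimate`` is the pooled proportion.  The Wilson interval reported is
    for the pooled proportion.
    """
    for d in (dist_a, dist_b):
        if d.n < 1:
            raise ValueError("compare_transmission requires non-empty cohorts")
    ka = np.arange(dist_a.n_trivalents + 1)
    kb = np.arange(dist_b.n_trivalents + 1)
    sa, na = int((ka * dist_a.counts).sum()), dist_a.n_trivalents * dist_a.n
    sb, nb = int((kb * dist_b.counts).sum()), dist_b.n_trivalents * dist_b.n
    p_a, p_b = sa / na, sb / nb
    pooled = (sa + sb) / (na + nb)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / na + 1.0 / nb))
    if se == 0:
        z = 0.0
    else:
        z = (p_a - p_b) / se
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    ci = proportion_confint(sa + sb, na + nb, alpha=0.05, method="wilson")
    return ProportionResult(
        pooled, float(z), p_value, "two_proportion_z", "two_sided",
        (float(ci[0]), float(ci[1])),
        note=(
            f"cohort a: {sa}/{na} ({p_a:.4f}); cohort b: {sb}/{nb} ({p_b:.4f}); "
            "assumes independent trivalent segregations"
        ),
    )


def dispersion_test(
    dist: CountDistribution,
    model: SegregationModel | None = None,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> GofResult:
    """Variance-ratio test of over/under-dispersion relative to the binomial.

    The statistic is the sample variance of the inherited Rb count divided
    by the binomial variance ``n * p_hat * (1 - p_hat)`` at the fitted mean
    fraction ``p_hat``.  A ratio above 1 means the offspring distribution is
    wider than any binomial with the same mean — shape distortion that a
    mean-shift alone cannot produce.  The two-sided p-value comes from
    Monte-Carlo resampling of Binomial(n, p_hat) cohorts of the same size,
    refitting ``p_hat`` in each resample.
    """
    if dist.n < 2:
        raise ValueError("dispersion test requires at least two offspring")
    n_triv = dist.n_trivalents
    k = np.arange(n_triv + 1)
    values = np.repeat(k, dist.counts)
    if np.ptp(values) == 0:
        raise ValueError(
            "all offspring share the same Rb count; the sample variance is "
            "degenerate and the dispersion ratio is undefined"
        )
    p_hat = fraction_of_max(dist)
    var_obs = float(np.var(values, ddof=1))
    var_binom = n_triv * p_hat * (1.0 - p_hat)
    statistic = var_obs / var_binom

    rng = np.random.default_rng(seed)
    sims = rng.binomial(n_triv, p_hat, size=(n_resamples, dist.n))
    sim_mean = sims.mean(axis=1)
    sim_phat = sim_mean / n_triv
    sim_var = sims.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim_stat = sim_var / (n_triv * sim_phat * (1.0 - sim_phat))
    sim_stat = sim_stat[np.isfinite(sim_stat)]
    b = len(sim_stat)
    p_hi = (1 + int((sim_stat >= statistic).sum())) / (1 + b)
    p_lo = (1 + int((sim_stat <= statistic).sum())) / (1 + b)
    p_value = min(1.0, 2.0 * min(p_hi, p_lo))
    expected = dist.n * transmission_pmf(
        model if model is not None else SegregationModel.homogeneous(n_triv, p_hat)
    )
    return GofResult(statistic, dist.n - 1, p_value, expected, "monte_carlo",
                     n_resamples=n_resamples, seed=seed,
                     pooled_bins="variance-ratio statistic")
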