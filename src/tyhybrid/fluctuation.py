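"""Luria-Delbruck fluctuation analysis of retrotransposition rates.

A fluctuation assay grows many parallel cultures from small inocula and
selects for cells in which the event of interest (here, mobilization of a
marked Ty1 element restoring *HIS3*) has occurred. Because an event early in
the growth of a culture leaves many descendant mutants while a late event
leaves few, mutant counts across cultures follow the heavy-tailed
Luria-Delbruck distribution rather than a Poisson. The Lea-Coulson
formulation of that distribution gives a likelihood for the expected number
of events per culture, ``m``; dividing the maximum-likelihood ``m`` by the
final number of cells per culture ``N_t`` yields the per-cell,
per-generation event rate ``mu = m / N_t``.

The module exposes both a functional surface (:func:`lea_coulson_pmf`,
:func:`ld_mle`, :func:`ld_confint`, ...) and a model-fitting surface
(:class:`LuriaDelbruckModel` whose :meth:`~LuriaDelbruckModel.fit` returns a
:class:`LuriaDelbruckResults` with estimates, confidence intervals and a
``summary()`` table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "lea_coulson_pmf",
    "ld_log_likelihood",
    "ld_mle",
    "ld_confint",
    "zero_adjust",
    "final_population_size",
    "transposition_rate",
    "DilutionRecord",
    "FluctuationExperiment",
    "RateEstimate",
    "LuriaDelbruckModel",
    "LuriaDelbruckResults",
]

#: counts at or above this are treated as right-censored in the likelihood;
#: a jackpot's exact size carries almost no information about m beyond
#: "large", so this keeps the O(n^2) recursion short without biasing the MLE
_DEFAULT_COUNT_CAP = 512


def lea_coulson_pmf(m: float, n_max: int) -> np.ndarray:
    """Probabilities of observing 0..n_max mutants under the Lea-Coulson model.

    The distribution is compound Poisson: a Poisson(m) number of mutant
    clones whose sizes follow the Luria-Delbruck clone law
    ``q_k = 1/(k(k+1))``. Its probabilities obey the Ma-Sandri-Sarkar
    (Panjer) recursion

    .. math::

        p_0 = e^{-m}, \\qquad
        p_n = \\frac{m}{n} \\sum_{i=0}^{n-1} \\frac{p_i}{n-i+1}

    Parameters
    ----------
    m : float
        Expected number of mutation events per culture, ``m >= 0``.
    n_max : int
        Largest mutant count for which a probability is returned.

    Returns
    -------
    numpy.ndarray
        Array of length ``n_max + 1`` with ``p_0 ... p_{n_max}``.
    """
    if m < 0:
        raise ValueError(f"m must be non-negative, got {m}")
    if n_max < 0:
        raise ValueError(f"n_max must be non-negative, got {n_max}")
    p = np.zeros(n_max + 1)
    p[0] = math.exp(-m)
    if n_max == 0:
        return p
    # Panjer weights j*q_j = 1/(j+1) for clone sizes j = n - i >= 1
    j = np.arange(1, n_max + 1, dtype=float)
    wr = (1.0 / (j + 1.0))[::-1].copy()  # reversed, contiguous for the dots
    for n in range(1, n_max + 1):
        # sum_{i=0}^{n-1} p_i / (n - i + 1)
        p[n] = (m / n) * np.dot(p[:n], wr[n_max - n :])
    return p


def ld_log_likelihood(
    m: float, counts: Sequence[int], count_cap: int = _DEFAULT_COUNT_CAP
) -> float:
    """Lea-Coulson log-likelihood of ``m`` given per-culture mutant counts.

    Counts at or above ``count_cap`` contribute the folded tail probability
    ``P(X >= count_cap)`` instead of a point probability, so a handful of
    jackpot cultures cannot force an O(n^2) recursion over huge counts.
    """
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("mutant counts must be non-negative")
    if m == 0:
        return 0.0 if np.all(counts == 0) else -np.inf
    capped = np.minimum(counts, count_cap)
    n_max = int(capped.max(initial=0))
    p = lea_coulson_pmf(m, n_max)
    ll = 0.0
    tail_needed = np.any(counts >= count_cap)
    tail = max(1.0 - p.sum(), 0.0) if tail_needed else 0.0
    for c, craw in zip(capped, counts):
        prob = tail + p[c] if (craw >= count_cap) else p[c]
        if prob <= 0.0:
            return -np.inf
        ll += math.log(prob)
    return ll


def ld_mle(
    counts: Sequence[int],
    count_cap: int = _DEFAULT_COUNT_CAP,
    rtol: float = 1e-8,
) -> float:
    """Maximum-likelihood estimate of ``m`` from per-culture mutant counts.

    The likelihood is unimodal in ``m``; a coarse logarithmic grid scan
    brackets the maximum (robust to the -inf plateaus at extreme ``m``
    where every observed count has underflowed probability), then bounded
    scalar minimization refines it to a relative tolerance of ``rtol``.
    All-zero counts sit on the boundary and return exactly 0.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty experiment: no mutant counts")
    if np.any(counts < 0):
        raise ValueError("mutant counts must be non-negative")
    if np.all(counts == 0):
        return 0.0
    hi = max(50.0, 4.0 * float(counts.mean()))
    grid = np.exp(np.linspace(math.log(1e-4), math.log(hi), 80))
    ll = np.array([ld_log_likelihood(m, counts, count_cap) for m in grid])
    if not np.any(np.isfinite(ll)):  # pragma: no cover - defensive
        raise RuntimeError("likelihood not finite anywhere on the bracket")
    i = int(np.argmax(ll))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        # clamp -inf (zero-probability m) to a huge finite penalty so the
        # bounded Brent iteration stays numerically well-defined
        lambda x: min(-ld_log_likelihood(x, counts, count_cap), 1e300),
        bounds=(a, b),
        method="bounded",
        options={"xatol": rtol * max(grid[i], 1.0)},
    )
    if not res.success:  # pragma: no cover - bounded Brent converges here
        raise RuntimeError(f"MLE search failed to converge: {res}")
    best = float(res.x)
    if ld_log_likelihood(best, counts, count_cap) < ll[i]:
        best = float(grid[i])  # pragma: no cover - defensive
    return best


def ld_confint(
    counts: Sequence[int],
    level: float = 0.95,
    count_cap: int = _DEFAULT_COUNT_CAP,
    rtol: float = 1e-6,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for ``m``.

    The interval is the set of ``m`` whose log-likelihood lies within
    ``chi2(1).ppf(level) / 2`` (1.9207 at 95%) of the maximum; endpoints are
    located by root bracketing and bisection. A lower endpoint that would
    fall below zero is clipped to 0 (one-sided boundary case, e.g. all-zero
    counts).
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty experiment: no mutant counts")
    crit = stats.chi2.ppf(level, df=1) / 2.0
    m_hat = ld_mle(counts, count_cap=count_cap)
    n = counts.size
    if m_hat == 0.0:
        # loglik(m) = -n * m, maximum 0 at the boundary
        return 0.0, crit / n

    ll_max = ld_log_likelihood(m_hat, counts, count_cap)
    target = ll_max - crit

    def f(x: float) -> float:
        # clamp -inf to a large finite value for the root bracketing
        return max(ld_log_likelihood(x, counts, count_cap) - target, -1e300)

    # lower endpoint: the log-likelihood of any positive count diverges to
    # -inf as m -> 0+, so the root is bracketed in (tiny, m_hat); if the
    # likelihood never drops below the target the endpoint clips at 0
    tiny = m_hat * 1e-10
    if f(tiny) >= 0:
        lower = 0.0
    else:
        lower = optimize.brentq(
            f, tiny, m_hat, rtol=max(rtol, 4 * np.finfo(float).eps)
        )

    # upper endpoint: expand bracket geometrically
    hi = m_hat * 2.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - pathological flat likelihood
            raise RuntimeError("upper confidence endpoint not bracketed")
    upper = optimize.brentq(
        f, m_hat, hi, rtol=max(rtol, 4 * np.finfo(float).eps)
    )
    return float(lower), float(upper)


def zero_adjust(counts: Sequence[int]) -> tuple[np.ndarray, bool]:
    """Inflate an all-zero experiment to a single mutant.

    When no culture yields any mutant the MLE of ``m`` is 0 and carries no
    upper-bound information on the rate; setting exactly one culture's count
    to 1 converts the estimate into an explicit upper bound, flagged via the
    returned boolean.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty experiment: no mutant counts")
    if np.all(counts == 0):
        adjusted = counts.copy()
        adjusted[0] = 1
        return adjusted, True
    return counts.copy(), False


@dataclass(frozen=True)
class DilutionRecord:
    """One dilution-plating observation used to estimate N_t.

    ``plated_fraction`` is the fraction of the (pooled) culture volume that
    ended up on the plate; ``pool_size`` the number of cultures pooled before
    dilution, so the resulting estimate is cells per single culture.
    """

    n_colonies: int
    dilution_factor: float
    plated_fraction: float
    pool_size: int = 1

    def cells_per_culture(self) -> float:
        if self.plated_fraction <= 0:
            raise ValueError("plated fraction must be positive")
        if self.pool_size < 1:
            raise ValueError("pool size must be >= 1")
        return (
            self.n_colonies * self.dilution_factor / self.plated_fraction
        ) / self.pool_size


def final_population_size(records: Sequence[DilutionRecord]) -> float:
    """Mean final population size (cells per culture) over dilution records."""
    if len(records) == 0:
        raise ValueError("at least one dilution record is required")
    return float(np.mean([r.cells_per_culture() for r in records]))


@dataclass
class FluctuationExperiment:
    """Parallel-culture mutant counts plus final-population-size evidence."""

    mutant_counts: np.ndarray
    final_population_size: float | None = None
    dilution_records: list[DilutionRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.mutant_counts = np.asarray(self.mutant_counts, dtype=int)
        if self.mutant_counts.size == 0:
            raise ValueError("empty experiment: no mutant counts")
        if self.final_population_size is None:
            if not self.dilution_records:
                raise ValueError(
                    "need final_population_size or dilution_records"
                )
            self.final_population_size = final_population_size(
                self.dilution_records
            )

    @property
    def n_cultures(self) -> int:
        return int(self.mutant_counts.size)


@dataclass(frozen=True)
class RateEstimate:
    """Per-cell per-generation rate estimate with 95% CI in both m and rate units."""

    m_hat: float
    ci_low: float
    ci_high: float
    rate: float
    rate_ci: tuple[float, float]
    is_upper_bound: bool
    n_cultures: int
    final_population_size: float
    label: str = ""


def transposition_rate(
    experiment: FluctuationExperiment, level: float = 0.95
) -> RateEstimate:
    """Estimate the per-cell per-generation event rate for one experiment.

    Runs zero-count adjustment, the Lea-Coulson MLE and the profile-likelihood
    interval, then scales by the final population size: ``rate = m_hat / N_t``.
    """
    n_t = experiment.final_population_size
    if n_t is None or n_t <= 0:
        raise ValueError("final population size must be positive")
    counts, adjusted = zero_adjust(experiment.mutant_counts)
    m_hat = ld_mle(counts)
    lo, hi = ld_confint(counts, level=level)
    return RateEstimate(
        m_hat=m_hat,
        ci_low=lo,
        ci_high=hi,
        rate=m_hat / n_t,
        rate_ci=(lo / n_t, hi / n_t),
        is_upper_bound=adjusted,
        n_cultures=experiment.n_cultures,
        final_population_size=n_t,
        label=experiment.label,
    )


class LuriaDelbruckModel:
    """Lea-Coulson likelihood model for one fluctuation experiment.

    Parameters
    ----------
    mutant_counts : array-like of int
        Mutant colony counts, one per parallel culture.
    final_population_size : float, optional
        Cells per culture at plating; may instead be derived from
        ``dilution_records``.
    dilution_records : sequence of DilutionRecord, optional
    label : str
        Free-text identifier (strain background, tester variant, ...).

    Examples
    --------
    >>> res = LuriaDelbruckModel([0, 1, 0, 3, 0, 0, 12, 1],
    ...                          final_population_size=1e6).fit()
    >>> 0 < res.m_hat < 5
    True
    """

    def __init__(
        self,
        mutant_counts: Sequence[int],
        final_population_size: float | None = None,
        dilution_records: Sequence[DilutionRecord] | None = None,
        label: str = "",
    ) -> None:
        self.experiment = FluctuationExperiment(
            mutant_counts=np.asarray(mutant_counts, dtype=int),
            final_population_size=final_population_size,
            dilution_records=list(dilution_records or []),
            label=label,
        )

    @classmethod
    def from_dataframe(
        cls,
        df,
        counts_col: str = "mutant_count",
        final_population_size: float | None = None,
        label: str = "",
    ) -> "LuriaDelbruckModel":
        """Build a model from a tidy per-culture table."""
        return cls(
            df[counts_col].to_numpy(),
            final_population_size=final_population_size,
            label=label,
        )

    def loglike(self, m: float) -> float:
        counts, _ = zero_adjust(self.experiment.mutant_counts)
        return ld_log_likelihood(m, counts)

    def fit(self, level: float = 0.95, adjust_zero: bool = True):
        """Fit the model; returns a :class:`LuriaDelbruckResults`."""
        exp = self.experiment
        counts = exp.mutant_counts
        if adjust_zero:
            counts, adjusted = zero_adjust(counts)
        else:
            adjusted = False
        m_hat = ld_mle(counts)
        lo, hi = ld_confint(counts, level=level)
        n_t = exp.final_population_size
        estimate = RateEstimate(
            m_hat=m_hat,
            ci_low=lo,
            ci_high=hi,
            rate=m_hat / n_t,
            rate_ci=(lo / n_t, hi / n_t),
            is_upper_bound=adjusted,
            n_cultures=exp.n_cultures,
            final_population_size=n_t,
            label=exp.label,
        )
        return LuriaDelbruckResults(self, estimate, level)


class LuriaDelbruckResults:
    """Fitted fluctuation-assay results.

    Attributes
    ----------
    m_hat : float
        MLE of the expected number of events per culture.
    rate : float
        Per-cell per-generation rate, ``m_hat / N_t``.
    is_upper_bound : bool
        True when the all-zero adjustment was applied.
    """

    def __init__(
        self,
        model: LuriaDelbruckModel,
        estimate: RateEstimate,
        level: float,
    ) -> None:
        self.model = model
        self.estimate = estimate
        self.level = level

    # -- statsmodels-style accessors -------------------------------------
    @property
    def m_hat(self) -> float:
        return self.estimate.m_hat

    @property
    def rate(self) -> float:
        return self.estimate.rate

    @property
    def is_upper_bound(self) -> bool:
        return self.estimate.is_upper_bound

    @property
    def nobs(self) -> int:
        return self.estimate.n_cultures

    def conf_int(self, units: str = "m") -> tuple[float, float]:
        """CI endpoints in ``m`` units or ``rate`` units."""
        if units == "m":
            return (self.estimate.ci_low, self.estimate.ci_high)
        if units == "rate":
            return self.estimate.rate_ci
        raise ValueError(f"unknown units {units!r}")

    def summary(self) -> str:
        e = self.estimate
        pct = int(round(self.level * 100))
        lines = [
            "Luria-Delbruck fluctuation assay (Lea-Coulson MLE)",
            "=" * 52,
            f"label:                 {e.label or '-'}",
            f"cultures:              {e.n_cultures}",
            f"final pop. size N_t:   {e.final_population_size:.4g}",
            f"m_hat (events/culture): {e.m_hat:.4g}",
            f"{pct}% CI for m:         [{e.ci_low:.4g}, {e.ci_high:.4g}]",
            f"rate (per cell-gen):   {e.rate:.4g}",
            f"{pct}% CI for rate:      [{e.rate_ci[0]:.4g}, {e.rate_ci[1]:.4g}]",
            f"upper bound only:      {e.is_upper_bound}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<LuriaDelbruckResults m_hat={self.m_hat:.4g} "
            f"rate={self.rate:.4g}>"
        )
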