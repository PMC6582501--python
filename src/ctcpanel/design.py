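"""Exact operating characteristics of a single-stage binomial decision rule.

A capture method is declared promising when at least ``k`` of ``n``
patients are CTC-positive at a per-sample count cutoff.  With a per-sample
positivity probability ``p`` the number of positives is Binomial(n, p), so
the rule's power (at the promising rate ``p_alt``) and one-sided type I
error (at the discouraging rate ``p_null``) are exact upper-tail binomial
probabilities.  Tails are computed by direct summation of exact terms
accumulated in log space — no normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp


def binomial_tail(n: int, p: float, k: int) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p).

    Summation of exact binomial terms in log space; no approximation.
    ``k <= 0`` returns 1.0 (certain event).
    """
    if n < 0 or int(n) != n:
        raise ValueError("n must be a nonnegative integer")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if int(k) != k:
        raise ValueError("k must be an integer")
    if k > n:
        raise ValueError("k must not exceed n")
    n, k = int(n), int(k)
    if k <= 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * np.log(p)
        + (n - i) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass(frozen=True)
class DesignRule:
    """Single-stage rule: promising if >= ``min_positive_samples`` of
    ``n_samples`` patients have >= ``per_sample_cutoff`` CTCs per draw.

    ``p_null`` is the discouraging per-sample positivity rate (null
    hypothesis), ``p_alt`` the promising rate (alternative).  Defaults are
    the study's sizing: 20 patients, >=2 CTCs per 7.5 mL, at least 2
    positive samples, 1% discouraging vs 20% promising rate.
    """

    n_samples: int = 20
    per_sample_cutoff: int = 2
    min_positive_samples: int = 2
    p_null: float = 0.01
    p_alt: float = 0.20

    def __post_init__(self) -> None:
        if not 0 <= self.min_positive_samples <= self.n_samples:
            raise ValueError("need 0 <= min_positive_samples <= n_samples")
        if not (0.0 <= self.p_null <= self.p_alt <= 1.0):
            raise ValueError("need 0 <= p_null <= p_alt <= 1")
        if self.per_sample_cutoff < 1:
            raise ValueError("per_sample_cutoff must be >= 1")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Power and one-sided type I error of a :class:`DesignRule`."""

    power: float
    type_i_error: float

    @property
    def power_pct(self) -> float:
        """Power as a whole percent (study reporting convention)."""
        return round(100.0 * self.power)

    @property
    def type_i_error_pct(self) -> float:
        """Type I error as a percent with one decimal."""
        return round(100.0 * self.type_i_error, 1)

    def to_dict(self) -> dict:
        return {"power": self.power, "type_i_error": self.type_i_error}


def operating_characteristics(rule: DesignRule) -> OperatingCharacteristics:
    """Exact power and type I error of ``rule``."""
    power = binomial_tail(rule.n_samples, rule.p_alt, rule.min_positive_samples)
    alpha = binomial_tail(rule.n_samples, rule.p_null, rule.min_positive_samples)
    return OperatingCharacteristics(power=power, type_i_error=alpha)


def minimal_success_threshold(n: int, p_null: float, alpha: float) -> int:
    """Smallest k with P(X >= k | n, p_null) <= alpha.

    Returns ``n + 1`` when no threshold keeps the type I error at or below
    ``alpha`` (the design is infeasible at that size).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    for k in range(n + 1):
        if binomial_tail(n, p_null, k) <= alpha:
            return k
    return n + 1


def monte_carlo_characteristics(
    rule: DesignRule, n_draws: int = 10**6, seed: int = 0
) -> dict:
    """Monte-Carlo estimate of the rule's operating characteristics.

    Draws ``n_draws`` binomial trial outcomes under each hypothesis and
    reports the hit frequencies with their binomial standard errors.
    Intended as a simulation cross-check of the exact tails.
    """
    rng = np.random.default_rng(seed)
    k = rule.min_positive_samples
    out = {}
    for name, p in (("power", rule.p_alt), ("type_i_error", rule.p_null)):
        hits = rng.binomial(rule.n_samples, p, size=n_draws) >= k
        est = float(hits.mean())
        out[name] = est
        out[name + "_se"] = float(np.sqrt(max(est * (1 - est), 1e-12) / n_draws))
    return out
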