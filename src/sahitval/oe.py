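"""Observed-vs-expected event-count benchmarking.

Given per-patient predicted risks p_1..p_n from a transported model, the
number of deaths the model *expects* in a cohort of this size is a random
variable X = sum of independent Bernoulli(p_i) — a Poisson-binomial
distribution with mean sum(p_i) and variance sum(p_i (1 - p_i)).

Two routes to that distribution are provided and cross-checked:

* :func:`simulate_event_counts` — Monte Carlo, B replicates of the cohort
  (the convention in observed-vs-expected benchmarking studies, default
  B = 10,000), seeded and reproducible.
* :func:`exact_poisson_binomial_pmf` — the exact pmf by dynamic-programming
  convolution, O(n^2). The exact result is authoritative; Monte Carlo is
  retained for the density-plot output and fidelity to common practice.

:func:`oe_assess` then flags whether the observed death count falls outside
the central (equal-tailed) 95% interval of the predicted distribution and
reports the exceedance probability P(X >= observed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

__all__ = [
    "OEError",
    "OEConfig",
    "OEResult",
    "simulate_event_counts",
    "exact_poisson_binomial_pmf",
    "event_count_interval",
    "interval_from_pmf",
    "interval_from_samples",
    "oe_assess",
]

RNG_ALGORITHM = "numpy PCG64 (np.random.default_rng)"


class OEError(Exception):
    """Invalid input to the observed-vs-expected benchmark."""


@dataclass
class OEConfig:
    """Monte Carlo settings: B replicates, central interval level, seed."""

    n_sims: int = 10_000
    level: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.n_sims < 1:
            raise OEError(f"n_sims={self.n_sims} must be >= 1")
        if not 0 < self.level < 1:
            raise OEError(f"level={self.level} outside (0, 1)")


def _check_probs(probabilities) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise OEError("probabilities must be a non-empty 1-d array")
    if np.any(p <= 0) or np.any(p >= 1):
        raise OEError("probabilities must lie strictly inside (0, 1)")
    return p


def simulate_event_counts(probabilities, config: OEConfig) -> np.ndarray:
    """B Monte Carlo replicates of the cohort's event count.

    Replicate k = sum_i Bernoulli(p_i); reproducible given ``config.seed``.
    Work is chunked so B x n never materialises more than ~2e7 draws at once.
    """
    p = _check_probs(probabilities)
    config.validate()
    rng = np.random.default_rng(config.seed)
    B, n = config.n_sims, p.size
    out = np.empty(B, dtype=np.int64)
    chunk = max(1, int(2e7) // n)
    done = 0
    while done < B:
        b = min(chunk, B - done)
        u = rng.random((b, n))
        out[done : done + b] = (u < p).sum(axis=1)
        done += b
    return out


def exact_poisson_binomial_pmf(probabilities) -> np.ndarray:
    """Exact pmf of sum(Bernoulli(p_i)) over {0..n} by iterative convolution.

    ``pmf[k] = P(exactly k events)``; sums to 1, mean sum(p_i), variance
    sum(p_i (1 - p_i)).
    """
    p = _check_probs(probabilities)
    n = p.size
    if n > 100_000:
        raise OEError(f"n={n} too large for the O(n^2) exact computation")
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        # after i+1 patients only entries 0..i+1 are non-zero
        hi = i + 1
        pmf[1 : hi + 1] = pmf[1 : hi + 1] * (1 - pi) + pmf[0:hi] * pi
        pmf[0] *= 1 - pi
    return pmf


def interval_from_pmf(pmf: np.ndarray, level: float) -> Tuple[int, int]:
    """Central (equal-tailed) interval on the discrete support {0..n}:
    low = smallest k with CDF(k) >= (1-level)/2, high = smallest k with
    CDF(k) >= 1-(1-level)/2."""
    cdf = np.cumsum(pmf)
    alpha = (1 - level) / 2
    low = int(np.searchsorted(cdf, alpha))
    high = int(np.searchsorted(cdf, 1 - alpha))
    return low, min(high, pmf.size - 1)


def interval_from_samples(samples: np.ndarray, level: float) -> Tuple[int, int]:
    """Same rule applied to the empirical CDF of Monte Carlo samples."""
    samples = np.asarray(samples)
    n_max = int(samples.max())
    counts = np.bincount(samples, minlength=n_max + 1)
    return interval_from_pmf(counts / samples.size, level)


def hdi_from_pmf(pmf: np.ndarray, level: float) -> Tuple[int, int]:
    """Highest-density interval (smallest contiguous set of support points
    with mass >= level); alternative to the default equal-tailed interval."""
    best = (0, pmf.size - 1)
    cdf = np.concatenate([[0.0], np.cumsum(pmf)])
    best_width = pmf.size
    for lo in range(pmf.size):
        hi = int(np.searchsorted(cdf[lo + 1 :], cdf[lo] + level)) + lo
        if hi >= pmf.size:
            continue
        if hi - lo < best_width:
            best_width = hi - lo
            best = (lo, hi)
    return best


def event_count_interval(distribution, level: float) -> Tuple[int, int]:
    """Dispatch on distribution type: integer samples -> empirical CDF;
    float pmf (sums to ~1) -> exact CDF."""
    arr = np.asarray(distribution)
    if not 0 < level < 1:
        raise OEError(f"level={level} outside (0, 1)")
    if np.issubdtype(arr.dtype, np.integer):
        return interval_from_samples(arr, level)
    if abs(float(arr.sum()) - 1.0) < 1e-6 and np.all(arr >= 0):
        return interval_from_pmf(arr, level)
    raise OEError("distribution is neither integer samples nor a normalised pmf")


@dataclass
class OEResult:
    """Observed event count against the model-predicted count distribution."""

    observed: int
    expected_mean: float
    interval_low: int
    interval_high: int
    level: float
    outside_interval: bool
    exceedance_prob: float  # P(X >= observed) under the exact pmf
    method: str = "exact"
    n_sims: int = 0
    seed: int = 0
    pmf: Optional[np.ndarray] = None
    samples: Optional[np.ndarray] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "observed": self.observed,
                "expected_mean": self.expected_mean,
                "interval": [self.interval_low, self.interval_high],
                "level": self.level,
                "outside_interval": self.outside_interval,
                "exceedance_prob": self.exceedance_prob,
                "method": self.method,
                "n_sims": self.n_sims,
                "seed": self.seed,
                "rng": RNG_ALGORITHM,
            },
            indent=2,
        )


def oe_assess(observed: int, probabilities, config: Optional[OEConfig] = None) -> OEResult:
    """Full observed-vs-expected assessment of a cohort's event count.

    Computes both the Monte Carlo samples (for plotting, at ``config.n_sims``)
    and the exact Poisson-binomial pmf; the interval and exceedance
    probability reported come from the exact pmf.
    """
    p = _check_probs(probabilities)
    config = config or OEConfig()
    config.validate()
    n = p.size
    observed = int(observed)
    if not 0 <= observed <= n:
        raise OEError(f"observed={observed} outside 0..{n}")
    pmf = exact_poisson_binomial_pmf(p)
    samples = simulate_event_counts(p, config)
    low, high = interval_from_pmf(pmf, config.level)
    return OEResult(
        observed=observed,
        expected_mean=float(p.sum()),
        interval_low=low,
        interval_high=high,
        level=config.level,
        outside_interval=not (low <= observed <= high),
        exceedance_prob=float(pmf[observed:].sum()),
        method="exact",
        n_sims=config.n_sims,
        seed=config.seed,
        pmf=pmf,
        samples=samples,
    )
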