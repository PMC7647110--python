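"""Closed-form probability results for sequential basis building.

When samples are drawn from a finite set of multiplicity vectors
M = a_1 x a_2 x ... x a_n (each genome j takes copy numbers from a finite
set a_j), the chance that a fresh random sample escapes the span of the
samples already found is bounded below:

* with s values per genome and p independent samples already found, the
  fraction of M outside any codimension-p plane is at least 1 - s^-p;
* with a non-uniform measure, the mass outside any hyperplane is at least
  lambda / (1 + lambda), where lambda is the minimal tail-to-mode
  probability ratio over genomes; for integer-rounded Normal(m, sigma_j)
  copy numbers lambda = exp(-1 / (2 sigma_0^2)) with sigma_0 = min sigma_j.

From the per-draw success probability p the expected number of samples to
collect all n basis vectors is n/p (a negative-binomial waiting time),
and observing m consecutive dependent samples certifies completion with
probability 1 - (1-p)^m (1 - 2^-m in the uniform two-value case).

The module also carries exhaustive and Monte-Carlo oracles that verify
these statements on small instances with exact rational arithmetic.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .exactrank import integer_rank, points_in_span

__all__ = [
    "independence_probability_bound",
    "lambda_from_probs",
    "measure_bound",
    "lambda_normal",
    "expected_sample_count",
    "termination_confidence",
    "rounded_normal_mean_abs_deviation",
    "negative_binomial_mean_check",
    "enumerate_fraction_outside",
    "enumerate_measure_outside",
]


def independence_probability_bound(s: int, p: int) -> float:
    """Lower bound 1 - s^-p on the fraction of M outside a codimension-p plane."""
    if s < 2:
        raise ValueError(f"need at least two values per genome, got s={s}")
    if p < 1:
        raise ValueError(f"codimension must be >= 1, got p={p}")
    return 1.0 - float(s) ** (-p)


def _validate_prob_rows(probs: Sequence[Sequence[float]]) -> list[np.ndarray]:
    rows = [np.asarray(r, dtype=float) for r in probs]
    for r in rows:
        if r.size < 2:
            raise ValueError("each probability row needs at least two values")
        if np.any(r < 0) or not math.isclose(r.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("probability rows must be nonnegative and sum to 1")
        if np.any(np.diff(r) > 1e-12):
            raise ValueError("probability rows must be sorted non-increasing")
    return rows


def lambda_from_probs(probs: Sequence[Sequence[float]]) -> float:
    """lambda = min_i (sum_{j>=2} p(a_ij)) / p(a_i1) over the genome rows.

    Rows must be sorted non-increasing (mode first) and sum to one.
    """
    rows = _validate_prob_rows(probs)
    return min(float(r[1:].sum() / r[0]) for r in rows)


def measure_bound(lam: float) -> float:
    """Lower bound lambda/(1+lambda) on the measure outside a hyperplane."""
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    return 1.0 - 1.0 / (1.0 + lam)


def lambda_normal(sigma0: float) -> float:
    """lambda for integer-rounded normal multiplicities: exp(-1/(2 sigma_0^2)).

    sigma_0 is the smallest per-genome standard deviation; the bound
    approaches 1 as the scatter grows (0.995 already at sigma_0 = 10).
    """
    if sigma0 <= 0:
        raise ValueError(f"sigma0 must be positive, got {sigma0}")
    return math.exp(-1.0 / (2.0 * sigma0**2))


def expected_sample_count(n: int, p: float) -> float:
    """Mean number of samples to find all n basis vectors at per-draw success p."""
    if n < 1:
        raise ValueError(f"need n >= 1 basis vectors, got {n}")
    if not 0 < p <= 1:
        raise ValueError(f"success probability must lie in (0, 1], got {p}")
    return n / p


def termination_confidence(m_consecutive: int, p_independent: float = 0.5) -> float:
    """P(all basis vectors found) after m consecutive dependent samples.

    1 - (1 - p)^m; with the uniform two-value probability p = 0.5 this is
    the familiar 1 - 2^-m (93.75% at m = 4).
    """
    if m_consecutive < 1:
        raise ValueError(f"need m >= 1 consecutive dependent samples, got {m_consecutive}")
    if not 0 < p_independent <= 1:
        raise ValueError(f"p_independent must lie in (0, 1], got {p_independent}")
    return 1.0 - (1.0 - p_independent) ** m_consecutive


def rounded_normal_mean_abs_deviation(sigma: float, tol: float = 1e-12) -> float:
    """E|round(X) - m| for X ~ Normal(m, sigma), m integer.

    The rounded deviation takes integer values d with probability
    Phi((d+0.5)/sigma) - Phi((d-0.5)/sigma) (twice, for +-d), so the
    expectation is the series sum_{d>=1} 2 d [Phi((d+0.5)/sigma) -
    Phi((d-0.5)/sigma)], truncated once terms drop below `tol`.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma}")
    if sigma == 0:
        return 0.0
    total, d = 0.0, 1
    while True:
        term = 2.0 * d * (norm.cdf((d + 0.5) / sigma) - norm.cdf((d - 0.5) / sigma))
        total += term
        if term < tol and d > sigma:
            return total
        d += 1


def negative_binomial_mean_check(
    n: int, p: float, trials: int, rng: np.random.Generator | int | None = None
) -> float:
    """Monte-Carlo mean number of draws until n successes at success prob p.

    Simulates the waiting time directly (sum of n geometric draws) as an
    independent check of the closed form n/p.
    """
    if trials < 1:
        raise ValueError("need at least one trial")
    if n < 1 or not 0 < p <= 1:
        raise ValueError("need n >= 1 and p in (0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    draws = rng.geometric(p, size=(trials, n)).sum(axis=1)
    return float(draws.mean())


def _enumerate_points(value_sets: Sequence[Sequence[int]]) -> np.ndarray:
    sizes = [len(vs) for vs in value_sets]
    total = math.prod(sizes)
    n = len(value_sets)
    if n > 16 or total > 10**6:
        raise ValueError(
            f"instance too large for exhaustive enumeration (n={n}, |M|={total})"
        )
    return np.asarray(list(itertools.product(*value_sets)), dtype=np.int64)


def enumerate_fraction_outside(
    value_sets: Sequence[Sequence[int]],
    hyperplane_spanning_vectors: Sequence[Sequence[int]],
) -> float:
    """Exact fraction of M = a_1 x ... x a_n outside the span of given vectors.

    Enumerates every multiplicity vector and tests span membership by
    exact rational rank; the spanning vectors must be linearly
    independent.
    """
    span = [list(map(int, v)) for v in hyperplane_spanning_vectors]
    if integer_rank(span) != len(span):
        raise ValueError("spanning vectors must be linearly independent")
    points = _enumerate_points(value_sets)
    inside = points_in_span(points, span)
    return float(1.0 - inside.mean())


def enumerate_measure_outside(
    value_sets: Sequence[Sequence[int]],
    probs: Sequence[Sequence[float]],
    hyperplane_spanning_vectors: Sequence[Sequence[int]],
) -> float:
    """Exact probability mass of M outside the span, under a product measure."""
    span = [list(map(int, v)) for v in hyperplane_spanning_vectors]
    if integer_rank(span) != len(span):
        raise ValueError("spanning vectors must be linearly independent")
    rows = [np.asarray(r, dtype=float) for r in probs]
    if len(rows) != len(value_sets) or any(
        len(r) != len(vs) for r, vs in zip(rows, value_sets)
    ):
        raise ValueError("need one probability per value-set element")
    points = _enumerate_points(value_sets)
    inside = points_in_span(points, span)
    weights = np.asarray(
        [math.prod(float(r[j]) for r, j in zip(rows, combo))
         for combo in itertools.product(*(range(len(vs)) for vs in value_sets))]
    )
    return float(weights[~inside].sum() / weights.sum())
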