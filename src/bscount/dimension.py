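"""Estimating the number of distinct genomes from a set of sample spectra.

Every sample spectrum is (up to sequencing error) a nonnegative integer
combination of the spectra of the genomes present, so with error-free
data the number of distinct genomes equals the linear rank of the
samples-by-words matrix.  That rank is found incrementally: each new
sample either extends the current basis or is declared dependent, and
after ``stop_m`` consecutive dependent samples the search stops — at that
point all basis vectors have been found with probability at least
1 - (1 - p)^stop_m, p being the per-draw chance of an independent sample
(at least 0.5 for two-valued multiplicities).

With sequencing errors the sample matrix is numerically full rank and the
genome count instead appears as the intrinsic dimension of a noisy
low-rank cloud.  The rows are centered and projected onto leading
principal components; f(n) is the summed Euclidean distance of all rows
to the span of the first n components.  The *marker pattern* is read from
the normalized derivatives

    f'~(n)  = (f(n)  - f(n+1))  / f(n)
    f''~(n) = (f'~(n) - f'~(n+1)) / f'~(n)

whose peak marks the last component still carrying genome signal.
Because centering removes one dimension, a peak at n corresponds to n + 1
genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .simulate import SampleSet
from .spectra import BarcodeSpectrum
from .theory import termination_confidence

__all__ = [
    "BasisState",
    "MarkerCurves",
    "DimensionEstimate",
    "NoMarkerPattern",
    "incremental_rank",
    "sequential_basis",
    "pca_residual_curve",
    "detect_marker_pattern",
    "estimate_genome_count",
]

#: relative residual below which a row counts as linearly dependent
DEFAULT_TOLERANCE = 1e-8
#: normalized first derivative below this is numerical zero (masked in d2)
D1_FLOOR = 1e-12
#: f(n)/f-scale below this means the data are exactly low rank
EXACT_RESIDUAL_FLOOR = 1e-9


class NoMarkerPattern(RuntimeError):
    """Raised when the residual curves show no usable peak."""


@dataclass
class BasisState:
    """Running state of the sequential basis search."""

    basis_rows: list[np.ndarray] = field(default_factory=list)
    consecutive_dependent: int = 0
    stop_m: int = 4
    tolerance: float = DEFAULT_TOLERANCE
    samples_consumed: int = 0
    _ortho: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def size(self) -> int:
        return len(self.basis_rows)

    def offer(self, row: np.ndarray) -> bool:
        """Test one sample row; keep it if independent.  Returns True if kept."""
        self.samples_consumed += 1
        row = np.asarray(row, dtype=float)
        residual = _residual(row, self._ortho)
        norm = np.linalg.norm(row)
        res_norm = np.linalg.norm(residual)
        if norm == 0 or res_norm < self.tolerance * norm:
            self.consecutive_dependent += 1
            return False
        self.basis_rows.append(row)
        self._ortho.append(residual / res_norm)
        self.consecutive_dependent = 0
        return True

    @property
    def terminated(self) -> bool:
        return self.consecutive_dependent >= self.stop_m


def _residual(row: np.ndarray, ortho: list[np.ndarray]) -> np.ndarray:
    """Component of `row` orthogonal to the unit rows in `ortho`.

    Two rounds of Gram-Schmidt ("twice is enough") keep the basis
    numerically orthonormal even for nearly dependent inputs.
    """
    r = row.astype(float, copy=True)
    for _ in range(2):
        for q in ortho:
            r -= (q @ r) * q
    return r


@dataclass
class MarkerCurves:
    """PCA residual curve f(n) and its normalized derivatives.

    ``f[i]`` is f(n) at n = i + 1; ``d1`` and ``d2`` are one and two
    entries shorter.  ``f0`` is the total distance with zero components
    (the scale of the data), kept for exact-rank detection.
    """

    f: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    n_max: int
    f0: float

    @property
    def n(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)


@dataclass
class DimensionEstimate:
    """Result of a genome-count estimation."""

    genome_count: int
    method: str
    peak_index: int | None = None
    curves: MarkerCurves | None = None
    confidence_note: str = ""
    ambiguous: bool = False
    terminated: bool = True
    notes: list[str] = field(default_factory=list)


def _as_matrix(samples) -> np.ndarray:
    if isinstance(samples, SampleSet):
        return np.asarray(samples.matrix, dtype=float)
    return np.asarray(samples, dtype=float)


def incremental_rank(samples, tolerance: float = DEFAULT_TOLERANCE) -> int:
    """Rank of the sample rows by sequential dependence testing.

    A row is dependent when its residual after projection onto the
    current basis is below ``tolerance`` times its own norm.  On integer
    count matrices this agrees with exact rational rank.
    """
    matrix = _as_matrix(samples)
    if matrix.size == 0:
        return 0
    state = BasisState(stop_m=matrix.shape[0] + 1, tolerance=tolerance)
    for row in matrix:
        state.offer(row)
    return state.size


def sequential_basis(
    sample_stream: Iterable[BarcodeSpectrum | np.ndarray],
    stop_m: int = 4,
    tolerance: float = DEFAULT_TOLERANCE,
    max_samples: int | None = None,
) -> tuple[BasisState, DimensionEstimate]:
    """Consume samples one at a time until `stop_m` consecutive are dependent.

    This is the error-free counting procedure: the basis size at
    termination is the genome-count estimate, and the confidence note
    carries the termination probability 1 - 2^-stop_m (uniform case).
    If the stream runs dry first, the estimate is returned flagged as
    non-terminated.
    """
    if stop_m < 1:
        raise ValueError("stop_m must be >= 1")
    state = BasisState(stop_m=stop_m, tolerance=tolerance)
    for item in sample_stream:
        row = item.counts if isinstance(item, BarcodeSpectrum) else np.asarray(item)
        state.offer(row)
        if state.terminated:
            break
        if max_samples is not None and state.samples_consumed >= max_samples:
            break
    confidence = termination_confidence(stop_m, 0.5)
    estimate = DimensionEstimate(
        genome_count=state.size,
        method="exact_rank",
        confidence_note=(
            f"P(all basis samples found) >= {confidence:.4f} after "
            f"{stop_m} consecutive dependent samples (two-valued multiplicities)"
        ),
        terminated=state.terminated,
    )
    if not state.terminated:
        estimate.notes.append("stream exhausted before termination rule fired")
    return state, estimate


def pca_residual_curve(samples) -> MarkerCurves:
    """Residual curve f(n) of centered rows against leading PCA subspaces.

    f(n) is the sum over rows of the Euclidean distance (not squared)
    between the centered row and the span of the first n principal
    components; the normalized first and second derivatives are returned
    alongside.  n runs from 1 to min(n_samples - 1, 4^k) - 1.
    """
    matrix = _as_matrix(samples)
    n_rows, n_cols = matrix.shape
    if n_rows < 3:
        raise ValueError(f"need at least 3 samples for a residual curve, got {n_rows}")
    centered = matrix - matrix.mean(axis=0)
    # distances to PC subspaces come from the row coordinates U*S alone
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords_sq = (u * s) ** 2  # rows x components
    n_max = min(n_rows - 1, n_cols) - 1
    if n_max < 1:
        raise ValueError("sample set too small for any principal subspace")
    # tail_sq[:, j] = squared distance using the first j+1 components
    tail_sq = coords_sq[:, ::-1].cumsum(axis=1)[:, ::-1]
    r = coords_sq.shape[1]
    f = np.empty(n_max)
    f0 = float(np.sqrt(tail_sq[:, 0]).sum())
    for n in range(1, n_max + 1):
        if n < r:
            f[n - 1] = np.sqrt(np.maximum(tail_sq[:, n], 0.0)).sum()
        else:
            f[n - 1] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = np.where(f[:-1] > 0, (f[:-1] - f[1:]) / f[:-1], 0.0)
        d2 = np.where(d1[:-1] > 0, (d1[:-1] - d1[1:]) / d1[:-1], np.nan)
    return MarkerCurves(f=f, d1=d1, d2=d2, n_max=n_max, f0=f0)


def detect_marker_pattern(
    curves: MarkerCurves, d1_floor: float = D1_FLOOR, prefer_peak: bool = False
) -> DimensionEstimate:
    """Read the genome count off the residual curves.

    If f(n) actually reaches (numerical) zero the data are exactly low
    rank: the first such n plus one is the count.  Otherwise the count is
    argmax of the normalized second derivative plus one (centering
    removed one dimension); positions where the first derivative
    underflows are masked, adjacent ties are resolved to the lower n and
    flagged ambiguous.

    ``prefer_peak`` handles stacks that mix noisy samples with exactly
    low-rank rows (clean virtual samples): the residual then reaches zero
    at the *stacked* rank, which overcounts, so the d2 peak before the
    zero tail takes precedence when one exists.
    """
    if curves.n_max < 3:
        raise ValueError("curves too short for marker detection (need n_max >= 3)")
    scale = max(curves.f0, 1.0)
    zero = np.flatnonzero(curves.f <= EXACT_RESIDUAL_FLOOR * scale)
    if zero.size and not prefer_peak:
        # exactly low-rank data: the residual vanishes once n reaches the
        # rank of the centered rows, which (for more samples than rank)
        # equals the number of genomes
        n0 = int(zero[0]) + 1  # n at which the residual vanishes
        return DimensionEstimate(
            genome_count=n0,
            method="pca_marker",
            peak_index=n0,
            curves=curves,
            notes=["residual reached zero: exact low-rank data"],
        )
    valid = np.isfinite(curves.d2) & (curves.d1[:-1] >= d1_floor)
    if zero.size:
        # restrict to strictly before the zero tail, where d1/d2 are sound
        valid &= np.arange(curves.d2.size) < max(int(zero[0]) - 2, 0)
        if not valid.any():
            n0 = int(zero[0]) + 1
            return DimensionEstimate(
                genome_count=n0,
                method="pca_marker",
                peak_index=n0,
                curves=curves,
                notes=["residual reached zero and no earlier peak: exact low-rank data"],
            )
    if not valid.any() or np.nanmax(curves.d2[valid]) <= 1e-9:
        raise NoMarkerPattern(
            "no marker pattern: the residual curve has no usable peak in d2"
        )
    d2 = np.where(valid, curves.d2, -np.inf)
    best = float(d2.max())
    # relative ties go to the lowest n and are reported as +-1 ambiguous
    tied = np.flatnonzero(d2 >= best - 1e-12 * max(abs(best), 1.0))
    peak = int(tied[0]) + 1  # positions are 1-based in n
    return DimensionEstimate(
        genome_count=peak + 1,
        method="pca_marker",
        peak_index=peak,
        curves=curves,
        ambiguous=bool(tied.size > 1),
        confidence_note="estimate carries a +-1 band (centering ambiguity)",
    )


def estimate_genome_count(
    samples,
    method: str = "auto",
    tolerance: float = DEFAULT_TOLERANCE,
    min_samples: int = 5,
    prefer_peak: bool = False,
) -> DimensionEstimate:
    """Estimate the number of distinct genomes behind a sample set.

    ``auto`` uses the exact rank when the rows are numerically low rank
    (error-free data) and falls back to the PCA marker pattern otherwise;
    ``rank`` and ``pca`` force the respective path.
    """
    matrix = _as_matrix(samples)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("need a nonempty 2-D sample matrix")
    n_rows = matrix.shape[0]
    if n_rows == 1:
        warnings.warn("single sample: genome count estimate degenerates to 1")
        return DimensionEstimate(
            genome_count=1, method="exact_rank", notes=["degenerate: single sample"]
        )
    if method not in ("auto", "rank", "pca"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("auto", "rank"):
        rank = incremental_rank(matrix, tolerance)
        if method == "rank" or rank < n_rows:
            return DimensionEstimate(
                genome_count=rank,
                method="exact_rank",
                notes=[] if rank < n_rows else ["forced rank path on full-rank data"],
            )
    if n_rows < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples for marker-pattern detection, got {n_rows}"
        )
    curves = pca_residual_curve(matrix)
    return detect_marker_pattern(curves, prefer_peak=prefer_peak)
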