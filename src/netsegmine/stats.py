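"""Stratified association testing for binary pattern encodings.

This module houses the statistical core of the miner: construction of one
2x2 contingency table per covariate class, the 1-df Cochran-Mantel-Haenszel
(CMH) test of association across the strata, the *minimum attainable*
p-value of a pattern given only its phenotype-free margins, the prunability
criterion that licenses discarding whole branches of the pattern search
space, and candidate threshold grids for the testability procedure.

Conventions
-----------
* The CMH statistic is computed without continuity correction,

      T = (sum_k a_k - sum_k x_k n1_k / n_k)^2
          / sum_k x_k (n_k - x_k) n1_k (n_k - n1_k) / (n_k^2 (n_k - 1)),

  and referred to the upper tail of a chi-squared distribution with one
  degree of freedom.  Strata in which the pattern or the phenotype is
  constant (``x_k`` in {0, n_k}, ``n1_k`` in {0, n_k}) or with ``n_k = 1``
  carry no information and contribute zero to both sums; if every stratum is
  degenerate the p-value is 1.
* Because the statistic is a one-degree-of-freedom quadratic in the single
  free total ``sum_k a_k``, its maximum over all feasible cell counts is
  attained when every ``a_k`` sits jointly at its upper or jointly at its
  lower feasibility bound.  ``min_pvalue`` therefore evaluates only these
  two corner configurations; the test suite checks the result against
  exhaustive minimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "Margins",
    "StratifiedTable",
    "ClassPartition",
    "build_tables",
    "cmh_pvalue",
    "min_pvalue",
    "is_prunable",
    "threshold_grid",
    "exact_threshold_grid",
]


def _chi2_sf(t):
    """Upper tail of chi-squared with 1 df: P(X > t) = erfc(sqrt(t/2))."""
    return special.erfc(np.sqrt(0.5 * np.asarray(t, dtype=np.float64)))


def _as_count_array(v) -> np.ndarray:
    a = np.atleast_1d(np.asarray(v, dtype=np.int64))
    if a.ndim != 1:
        raise ValueError("per-class counts must be one-dimensional")
    return a


@dataclass(frozen=True)
class Margins:
    """Phenotype-free margins of a stratified collection of 2x2 tables.

    Per covariate class ``k``: ``x[k]`` samples carry the pattern, ``n1[k]``
    are cases, out of ``n[k]`` samples.  The cell count ``a_k`` (pattern
    carriers among cases) is deliberately absent: every quantity derived
    from :class:`Margins` alone is independent of the phenotype assignment.
    """

    x: np.ndarray
    n1: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        x, n1, n = map(_as_count_array, (self.x, self.n1, self.n))
        if not (len(x) == len(n1) == len(n)) or len(n) < 1:
            raise ValueError("margin arrays must share a common length K >= 1")
        if np.any(n < 1):
            raise ValueError("every covariate class must be non-empty")
        if np.any((x < 0) | (x > n)) or np.any((n1 < 0) | (n1 > n)):
            raise ValueError("margins must satisfy 0 <= x_k, n1_k <= n_k")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "n1", n1)
        object.__setattr__(self, "n", n)

    @property
    def n_classes(self) -> int:
        return len(self.n)


@dataclass(frozen=True)
class StratifiedTable:
    """One 2x2 contingency table per covariate class.

    ``a[k]`` counts samples with pattern and phenotype 1, ``x[k]`` samples
    with the pattern, ``n1[k]`` cases and ``n[k]`` the class size.
    """

    a: np.ndarray
    x: np.ndarray
    n1: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        a, x, n1, n = map(_as_count_array, (self.a, self.x, self.n1, self.n))
        Margins(x, n1, n)  # reuse the margin validity checks
        lo = np.maximum(0, x - (n - n1))
        hi = np.minimum(x, n1)
        if np.any((a < lo) | (a > hi)):
            raise ValueError("cell counts a_k violate the feasibility bounds")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "n1", n1)
        object.__setattr__(self, "n", n)

    @property
    def margins(self) -> Margins:
        return Margins(self.x, self.n1, self.n)


class ClassPartition:
    """Precomputed covariate-class bookkeeping for fast stratified counting.

    Labels must be integers ``1..K`` with every class non-empty.  When the
    phenotype ``y`` is supplied, the per-class case counts ``n1`` are cached
    so that per-pattern work reduces to a single weighted bincount.
    """

    def __init__(self, c, y=None):
        c = np.asarray(c, dtype=np.int64)
        if c.ndim != 1 or len(c) == 0:
            raise ValueError("covariate vector must be a non-empty 1-d array")
        if c.min() < 1:
            raise ValueError("covariate labels must lie in {1..K}")
        self.code = c - 1
        self.K = int(c.max())
        self.n = np.bincount(self.code, minlength=self.K).astype(np.int64)
        if np.any(self.n == 0):
            raise ValueError("every covariate class in {1..K} must be non-empty")
        self.n_f = self.n.astype(np.float64)
        self.indices = [np.flatnonzero(self.code == k) for k in range(self.K)]
        if y is not None:
            y = np.asarray(y, dtype=np.float64)
            self.n1 = np.bincount(self.code, weights=y, minlength=self.K).astype(np.int64)
            self.n1_f = self.n1.astype(np.float64)
        else:
            self.n1 = None
            self.n1_f = None

    def supports(self, bits) -> np.ndarray:
        """Per-class count of ones of a binary encoding."""
        return np.bincount(self.code, weights=bits, minlength=self.K).astype(np.int64)


def build_tables(bits, y, c) -> StratifiedTable:
    """Count the stratified 2x2 tables of a binary encoding against ``y``.

    ``a_k = #{j : bits_j = 1 and y_j = 1 and c_j = k}`` with the margins
    filled from the same pass.
    """
    bits = np.asarray(bits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    part = ClassPartition(c, y)
    if len(bits) != len(y) or len(y) != len(part.code):
        raise ValueError("bits, y and c must have equal length")
    a = np.bincount(part.code, weights=bits * y, minlength=part.K).astype(np.int64)
    x = part.supports(bits)
    return StratifiedTable(a, x, part.n1, part.n)


# ---------------------------------------------------------------------------
# CMH p-value and minimum attainable p-value
# ---------------------------------------------------------------------------

def _cmh_pvalue_kernel(a, x, n1, n):
    """Vectorised CMH p-value; all inputs broadcast over a trailing class axis."""
    a, x, n1, n = np.broadcast_arrays(
        np.asarray(a, dtype=np.float64),
        np.asarray(x, dtype=np.float64),
        np.asarray(n1, dtype=np.float64),
        np.asarray(n, dtype=np.float64),
    )
    valid = (n > 1) & (x > 0) & (x < n) & (n1 > 0) & (n1 < n)
    mu = np.where(valid, x * n1 / np.where(n > 0, n, 1.0), 0.0)
    var = np.where(
        valid,
        x * (n - x) * n1 * (n - n1) / (n * n * np.maximum(n - 1.0, 1.0)),
        0.0,
    )
    num = np.where(valid, a - mu, 0.0).sum(axis=-1)
    den = var.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num * num / np.where(den > 0, den, 1.0), 0.0)
    p = _chi2_sf(t)
    return np.where(den > 0, p, 1.0)


def _min_pvalue_kernel(x, n1, n):
    """Vectorised minimum attainable CMH p-value from margins alone.

    Evaluates the two corner configurations (all ``a_k`` at their joint upper
    bound and all at their joint lower bound) and keeps the smaller p-value.
    """
    x, n1, n = np.broadcast_arrays(
        np.asarray(x, dtype=np.float64),
        np.asarray(n1, dtype=np.float64),
        np.asarray(n, dtype=np.float64),
    )
    valid = (n > 1) & (x > 0) & (x < n) & (n1 > 0) & (n1 < n)
    mu = np.where(valid, x * n1 / np.where(n > 0, n, 1.0), 0.0)
    var = np.where(
        valid,
        x * (n - x) * n1 * (n - n1) / (n * n * np.maximum(n - 1.0, 1.0)),
        0.0,
    )
    a_hi = np.minimum(x, n1)
    a_lo = np.maximum(0.0, x - (n - n1))
    s_hi = np.where(valid, a_hi - mu, 0.0).sum(axis=-1)
    s_lo = np.where(valid, a_lo - mu, 0.0).sum(axis=-1)
    den = var.sum(axis=-1)
    t = np.maximum(s_hi * s_hi, s_lo * s_lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, t / np.where(den > 0, den, 1.0), 0.0)
    p = _chi2_sf(t)
    return np.where(den > 0, p, 1.0)


def cmh_pvalue(table: StratifiedTable) -> float:
    """CMH p-value of a stratified table collection; degenerate tables give 1."""
    return float(_cmh_pvalue_kernel(table.a, table.x, table.n1, table.n))


def min_pvalue(margins: Margins) -> float:
    """Smallest p-value any phenotype assignment could produce on ``margins``."""
    return float(_min_pvalue_kernel(margins.x, margins.n1, margins.n))


class _MinPvalueCalculator:
    """Minimum attainable p-value with per-dataset constants precomputed.

    ``n1`` and ``n`` are fixed for a whole mining run; only the pattern
    support ``x`` varies.  The corner numerators need no stratum masking:
    for every degenerate stratum the forced cell count equals its null
    expectation, so its contribution vanishes identically, and the variance
    factor ``x (n - x)`` is itself zero at ``x`` in ``{0, n}``.
    """

    def __init__(self, n1, n):
        n1 = np.asarray(n1, dtype=np.float64)
        n = np.asarray(n, dtype=np.float64)
        self.n1 = n1
        self.n = n
        self.rate = np.where(n > 0, n1 / np.where(n > 0, n, 1.0), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            vcoef = n1 * (n - n1) / (n * n * (n - 1.0))
        self.vcoef = np.where(n > 1, vcoef, 0.0)

    def pmin(self, X) -> np.ndarray:
        """Minimum attainable p-value for supports ``X`` (last axis = class)."""
        X = np.asarray(X, dtype=np.float64)
        mu = X * self.rate
        den = (X * (self.n - X) * self.vcoef).sum(axis=-1)
        s_hi = (np.minimum(X, self.n1) - mu).sum(axis=-1)
        s_lo = (np.maximum(0.0, X - (self.n - self.n1)) - mu).sum(axis=-1)
        t = np.maximum(s_hi * s_hi, s_lo * s_lo)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(den > 0, t / np.where(den > 0, den, 1.0), 0.0)
        return np.where(den > 0, _chi2_sf(t), 1.0)


# ---------------------------------------------------------------------------
# Prunability
# ---------------------------------------------------------------------------

def _box_min_pvalue(calc: _MinPvalueCalculator, x, n,
                    stop_below: float | None = None,
                    chunk: int = 262_144) -> float:
    """Exact minimum of the attainable p-value over the reachable margin box.

    The box is ``{x' : x_k <= x'_k <= n_k}`` -- every margin vector a
    super-pattern of the current pattern can realise (supports only grow
    under the OR encoding).  Enumerates the box in chunks; if ``stop_below``
    is given, returns early once a value <= ``stop_below`` is found.
    """
    ranges = [np.arange(xi, ni + 1, dtype=np.int64) for xi, ni in zip(x, n)]
    sizes = [len(r) for r in ranges]
    total = int(np.prod(sizes))
    best = 1.0
    # enumerate lexicographically in chunks without materialising the full grid
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        cols = []
        rem = idx
        for size, r in zip(reversed(sizes), reversed(ranges)):
            cols.append(r[rem % size])
            rem = rem // size
        X = np.stack(cols[::-1], axis=1).astype(np.float64)
        best = min(best, float(calc.pmin(X).min()))
        if stop_below is not None and best <= stop_below:
            return best
    return best


def _is_prunable_kernel(calc: _MinPvalueCalculator, x, n1, n,
                        delta: float) -> bool:
    x = np.asarray(x, dtype=np.int64)
    n1 = np.asarray(n1, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    # Cheap witnesses: margin vectors inside the box at which the attainable
    # p-value tends to be smallest (per-class optima of the two corner
    # statistics, clipped into the box) plus the box corners themselves.
    # Any witness at or below delta proves the pattern is not prunable.
    witnesses = np.stack((np.clip(n1, x, n), np.clip(n - n1, x, n), x, n))
    if calc.pmin(witnesses).min() <= delta:
        return False
    # No witness fired: fall back to the exact enumeration of the box.
    return _box_min_pvalue(calc, x, n, stop_below=delta) > delta


def is_prunable(margins: Margins, delta: float) -> bool:
    """True iff *every* margin vector reachable by extending the pattern has
    a minimum attainable p-value above ``delta``.

    Reachable means ``x_k <= x'_k <= n_k`` componentwise, the consequence of
    the OR encoding: extending a segment can only add carriers.  A prunable
    pattern and all of its super-patterns are untestable at ``delta`` and --
    because the mining threshold only ever decreases -- remain untestable,
    so the entire search subtree can be discarded.
    """
    if not (0.0 < delta <= 1.0):
        raise ValueError("delta must lie in (0, 1]")
    calc = _MinPvalueCalculator(margins.n1, margins.n)
    return _is_prunable_kernel(calc, margins.x, margins.n1, margins.n, delta)


# ---------------------------------------------------------------------------
# Candidate threshold grids
# ---------------------------------------------------------------------------

def threshold_grid(floor: float = 1e-30, ratio: float = 0.5) -> np.ndarray:
    """Geometric grid of candidate testability thresholds.

    Returns ``[1, ratio, ratio^2, ...]`` continued one step past the first
    value at or below ``floor``.  Any strictly decreasing grid preserves
    FWER control; a finer grid is merely less conservative.
    """
    if not (0.0 < floor < 1.0):
        raise ValueError("floor must lie in (0, 1)")
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie in (0, 1)")
    n_steps = math.ceil(math.log(floor) / math.log(ratio)) + 1
    return np.concatenate(([1.0], ratio ** np.arange(1, n_steps + 1)))


def exact_threshold_grid(n: int, n1: int) -> np.ndarray:
    """Achievable-value grid for a single covariate class (K = 1).

    The minimum attainable p-value takes at most ``n + 1`` distinct values
    (one per support ``x``); lowering the threshold along exactly these
    values is the least conservative admissible schedule.
    """
    xs = np.arange(0, n + 1, dtype=np.float64)[:, None]
    ps = _min_pvalue_kernel(xs, np.float64(n1), np.float64(n))
    vals = np.unique(ps)[::-1]
    if vals[0] != 1.0:
        vals = np.concatenate(([1.0], vals))
    return vals
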