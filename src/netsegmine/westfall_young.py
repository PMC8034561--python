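"""Westfall-Young light permutation estimation of the familywise error rate.

Instead of bounding the FWER by ``delta_hat * |T|``, the permutation route
estimates it directly: the phenotype is permuted ``n_p`` times up front, and
for every processed pattern the CMH p-value under each permuted phenotype is
folded into a running vector ``p_min_vec`` of per-permutation smallest
p-values.  The empirical FWER at a threshold ``delta`` is then simply the
fraction of permutations whose smallest p-value is at or below ``delta``.

Untestable patterns can be skipped entirely: the minimum attainable p-value
depends only on phenotype-free margins, so it is identical under every
permutation that preserves those margins, and any permutation p-value of an
untestable pattern exceeds the current threshold by construction.  Under the
default within-class permutation scheme the per-class case counts -- and
hence the minimum p-values -- are exactly preserved; the global scheme
(permuting across covariate classes) is available but breaks that exact
invariance and is offered for sensitivity analysis only.
"""

from __future__ import annotations

import numpy as np

from .stats import ClassPartition, _chi2_sf, _cmh_pvalue_kernel
from .tarone import TaroneState

__all__ = [
    "PermutationState",
    "init_permutations",
    "fwer_estimate",
    "wy_threshold",
    "process_pattern_wy",
]


class PermutationState:
    """Permuted phenotypes and the running per-permutation minimum p-values."""

    def __init__(self, y, c, n_p: int, seed: int, scheme: str = "within-class"):
        if n_p < 1:
            raise ValueError("n_p must be >= 1")
        if scheme not in ("within-class", "global"):
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        y = np.asarray(y, dtype=np.int8)
        self.n_p = int(n_p)
        self.seed = int(seed)
        self.scheme = scheme
        self.partition = ClassPartition(c, y)
        rng = np.random.default_rng(seed)
        Y = np.tile(y, (n_p, 1))
        if scheme == "global":
            Y = rng.permuted(Y, axis=1)
        else:
            for idx in self.partition.indices:
                Y[:, idx] = rng.permuted(Y[:, idx], axis=1)
        self.Y = Y
        self._Y_f = np.ascontiguousarray(Y, dtype=np.float64)
        # Per-class permuted-label blocks (contiguous for fast matmuls) and
        # per-permutation case counts; constant per class under within-class.
        self._Y_by_class = [
            np.ascontiguousarray(Y[:, idx], dtype=np.float64)
            for idx in self.partition.indices
        ]
        self.n1_per_perm = np.stack(
            [blk.sum(axis=1) for blk in self._Y_by_class], axis=1
        )
        self.p_min_vec = np.ones(n_p, dtype=np.float64)

    def pattern_pvalues(self, bits) -> np.ndarray:
        """CMH p-value of one encoding against every permuted phenotype."""
        bits = np.asarray(bits, dtype=np.float64)
        if self.scheme == "within-class":
            return self._pattern_pvalues_fixed_margins(bits)
        K = self.partition.K
        A = np.empty((self.n_p, K))
        x = np.empty(K)
        for k, idx in enumerate(self.partition.indices):
            bk = bits[idx]
            x[k] = bk.sum()
            A[:, k] = self._Y_by_class[k] @ bk
        return _cmh_pvalue_kernel(
            A, x[None, :], self.n1_per_perm, self.partition.n_f[None, :]
        )

    def _pattern_pvalues_fixed_margins(self, bits) -> np.ndarray:
        # With per-class case counts preserved, only the stratum totals
        # sum_k a_k vary across permutations; degenerate strata contribute
        # their forced cell count, which equals its null expectation, so the
        # numerator needs no stratum mask and one matmul yields all totals.
        part = self.partition
        x = np.bincount(part.code, weights=bits, minlength=part.K)
        n, n1 = part.n_f, part.n1_f
        valid = (n > 1) & (x > 0) & (x < n) & (n1 > 0) & (n1 < n)
        den = float(
            (x * (n - x) * n1 * (n - n1) / (n * n * np.maximum(n - 1.0, 1.0)))[valid].sum()
        )
        if den <= 0:
            return np.ones(self.n_p)
        num = self._Y_f @ bits - float((x * n1 / n).sum())
        return _chi2_sf(num * num / den)

    def update(self, bits) -> np.ndarray:
        """Fold one pattern's permutation p-values into ``p_min_vec``.

        The elementwise-min merge is associative and commutative, so
        patterns (and permutations) may be processed in any order or
        concurrently without changing the result.
        """
        p = self.pattern_pvalues(bits)
        np.minimum(self.p_min_vec, p, out=self.p_min_vec)
        return p


def init_permutations(y, c, n_p: int, seed: int,
                      scheme: str = "within-class") -> PermutationState:
    """Generate ``n_p`` permuted phenotypes, reproducible from ``seed``."""
    return PermutationState(y, c, n_p, seed, scheme)


def fwer_estimate(p_min_vec, delta: float) -> float:
    """Empirical FWER: fraction of permutations with smallest p-value <= delta."""
    p_min_vec = np.asarray(p_min_vec)
    return float(np.mean(p_min_vec <= delta))


def wy_threshold(p_min_vec, alpha: float) -> float:
    """Largest threshold among the observed minima (or 0) whose empirical
    FWER stays at or below ``alpha``.

    With ``n_p`` permutations this is the lower alpha-quantile of
    ``p_min_vec``: without ties, the ``floor(alpha * n_p)``-th order
    statistic; the explicit search below also handles ties correctly.
    Entries are assumed strictly positive, as p-values are.
    """
    p_min_vec = np.sort(np.asarray(p_min_vec, dtype=np.float64))
    n_p = len(p_min_vec)
    budget = alpha * n_p
    candidates = np.unique(p_min_vec)
    counts = np.searchsorted(p_min_vec, candidates, side="right")
    feasible = candidates[counts <= budget]
    return float(feasible[-1]) if len(feasible) else 0.0


def process_pattern_wy(perm: PermutationState, state: TaroneState,
                       bits) -> np.ndarray:
    """Fold one testable pattern into the permutation state, then lower the
    threshold while the empirical FWER exceeds the target."""
    p = perm.update(bits)
    while fwer_estimate(perm.p_min_vec, state.delta_hat) > state.alpha:
        state.lower_once()
    return p
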