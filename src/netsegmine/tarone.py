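"""Testability-based familywise error control.

Maintains the running state of the testability procedure: the current
per-hypothesis threshold ``delta_hat``, the set ``T`` of patterns currently
testable at that threshold, and the running FWER bound
``alpha_hat = delta_hat * |T|``.  Whenever ``alpha_hat`` reaches the target
``alpha``, ``delta_hat`` is lowered along a precomputed strictly decreasing
grid and patterns whose minimum attainable p-value now exceeds the threshold
are evicted.  Because ``delta_hat`` only ever decreases, an evicted pattern
can never become testable again, which is what guarantees the error control.

The phenotype is touched only at the very end: ``filter_significant``
computes the actual CMH p-values of the surviving testable patterns and
keeps those at or below the corrected threshold ``delta* = alpha / |T|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ThresholdFloorError
from .segments import Segment
from .stats import ClassPartition, _cmh_pvalue_kernel

logger = logging.getLogger("netsegmine")

__all__ = ["TestablePattern", "TaroneState", "filter_significant"]


@dataclass
class TestablePattern:
    """A testable segment interaction retained in T.

    Stores everything needed to evict, re-test and report the pattern
    without re-enumeration: its identity, encoding bits, per-class supports
    and minimum attainable p-value.  Memory is O(n) bits per pattern.
    """

    __test__ = False  # not a test class despite the Test* name

    seg1: Segment
    seg2: Segment
    p_min: float
    bits: np.ndarray
    x: np.ndarray  # per-class support of the encoding
    cols1: np.ndarray | None = None  # absolute variant columns of seg1
    cols2: np.ndarray | None = None  # absolute variant columns of seg2

    @property
    def key(self) -> tuple:
        return (
            self.seg1.gene_id, self.seg2.gene_id,
            self.seg1.start, self.seg1.length,
            self.seg2.start, self.seg2.length,
        )


class TaroneState:
    """Threshold, testable set and FWER bookkeeping of one mining run."""

    def __init__(self, alpha: float, grid: np.ndarray,
                 evicted_sink: list | None = None):
        grid = np.asarray(grid, dtype=np.float64)
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if len(grid) < 2 or grid[0] != 1.0 or np.any(np.diff(grid) >= 0):
            raise ValueError("grid must start at 1 and be strictly decreasing")
        self.alpha = alpha
        self.grid = grid
        self._next = 1
        self.delta_hat = float(grid[0])
        self.testable: list[TestablePattern] = []
        self.trajectory: list[tuple[int, float]] = [(0, self.delta_hat)]
        self._n_registered = 0
        # optional: evicted patterns are handed to the caller instead of
        # being dropped (used by the engine's exact threshold refinement)
        self.evicted_sink = evicted_sink

    # -- state -------------------------------------------------------------

    @property
    def n_testable(self) -> int:
        return len(self.testable)

    @property
    def correction_factor(self) -> int:
        """The testability correction factor |T| (Bonferroni would use m >= |T|)."""
        return len(self.testable)

    @property
    def alpha_hat(self) -> float:
        return self.delta_hat * len(self.testable)

    @property
    def delta_prev(self) -> float:
        """The grid value preceding the current threshold (1 at the start)."""
        return float(self.grid[self._next - 2]) if self._next >= 2 else 1.0

    # -- transitions -------------------------------------------------------

    def admit(self, pattern: TestablePattern) -> None:
        """Append a pattern to T; requires testability at the current threshold."""
        if pattern.p_min > self.delta_hat:
            raise ValueError(
                f"pattern with p_min={pattern.p_min:.3g} is untestable at "
                f"delta_hat={self.delta_hat:.3g}"
            )
        self.testable.append(pattern)
        self._n_registered += 1

    def lower_once(self) -> None:
        """Move to the next grid value and evict newly untestable patterns."""
        if self._next >= len(self.grid):
            raise ThresholdFloorError(float(self.grid[-1]))
        self.delta_hat = float(self.grid[self._next])
        self._next += 1
        kept = [t for t in self.testable if t.p_min <= self.delta_hat]
        if self.evicted_sink is not None:
            self.evicted_sink.extend(
                t for t in self.testable if t.p_min > self.delta_hat
            )
        self.testable = kept
        self.trajectory.append((self._n_registered, self.delta_hat))

    def process_step(self) -> None:
        """Lower ``delta_hat`` until ``delta_hat * |T| < alpha``."""
        while self.delta_hat * len(self.testable) >= self.alpha:
            self.lower_once()

    def register_testable(self, pattern: TestablePattern) -> None:
        """Admit a testable pattern and restore the FWER bound."""
        self.admit(pattern)
        self.process_step()

    def final_threshold(self) -> float:
        """Corrected per-hypothesis threshold ``delta* = alpha / |T|``."""
        if not self.testable:
            logger.warning("zero testable patterns; reporting delta* = alpha")
            return self.alpha
        return self.alpha / len(self.testable)


def refine_threshold(
    patterns: list[TestablePattern],
    alpha: float,
    delta_hat: float,
    delta_prev: float,
) -> tuple[float, list[TestablePattern]]:
    """Exact testability threshold over the recorded minimum p-values.

    The geometric grid can overshoot: the step below the last violated grid
    value may land beneath the best admissible threshold, silently dropping
    patterns that a finer grid would keep (in the worst case losing hits a
    plain Bonferroni correction would have found).  Given every pattern with
    minimum p-value at or below ``delta_prev`` (the grid value preceding the
    final ``delta_hat`` -- the engine records these with a one-step cushion),
    this computes the largest threshold ``d`` among the observed minimum
    p-values with ``d * |{p_min <= d}| < alpha``, i.e. the result of
    retrospectively lowering along the finest possible grid.  The bound
    ``d * |T(d)| < alpha`` still holds, so error control is unchanged, and
    ``d >= alpha / m`` for any total hypothesis count ``m >= |T(d)|``, which
    restores dominance over Bonferroni.

    Returns the refined threshold and the testable set at that threshold.
    """
    pool = [p for p in patterns if p.p_min <= delta_prev]
    delta_ref = delta_hat
    if pool:
        pmins = np.sort(np.array([p.p_min for p in pool]))
        cands = np.unique(pmins)
        counts = np.searchsorted(pmins, cands, side="right")
        feasible = cands[cands * counts < alpha]
        if len(feasible):
            delta_ref = max(delta_ref, float(feasible[-1]))
    return delta_ref, [p for p in pool if p.p_min <= delta_ref]


def filter_significant(
    testable: list[TestablePattern],
    y,
    partition: ClassPartition,
    delta_star: float,
) -> list[tuple[TestablePattern, float]]:
    """Test every surviving testable pattern against the true phenotype.

    Returns patterns with CMH p-value <= ``delta_star``, sorted by p-value
    ascending with lexicographic ``(gene1, gene2, s1, l1, s2, l2)``
    tie-breaking.
    """
    if not testable:
        return []
    y = np.asarray(y, dtype=np.float64)
    B = np.stack([t.bits for t in testable]).astype(np.float64)  # M x n
    K = partition.K
    A = np.empty((len(testable), K))
    for k, idx in enumerate(partition.indices):
        A[:, k] = B[:, idx] @ y[idx]
    X = np.stack([t.x for t in testable]).astype(np.float64)
    p = _cmh_pvalue_kernel(A, X, partition.n1_f[None, :], partition.n_f[None, :])
    hits = [
        (t, float(pv)) for t, pv in zip(testable, p) if pv <= delta_star
    ]
    hits.sort(key=lambda tp: (tp[1],) + tp[0].key)
    return hits
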