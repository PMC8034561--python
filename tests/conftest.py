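"""Shared fixtures and brute-force oracles used across the suite."""

import itertools

import numpy as np
import pytest
from scipy.stats import chi2

import netsegmine as nm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately simple, loop-based; never the fast path)
# ---------------------------------------------------------------------------

def cmh_pvalue_reference(a, x, n1, n):
    """Textbook CMH 1-df p-value, no continuity correction, plain loops."""
    num = den = 0.0
    for ai, xi, n1i, ni in zip(
        np.atleast_1d(a), np.atleast_1d(x), np.atleast_1d(n1), np.atleast_1d(n)
    ):
        if ni > 1 and 0 < xi < ni and 0 < n1i < ni:
            num += ai - xi * n1i / ni
            den += xi * (ni - xi) * n1i * (ni - n1i) / (ni ** 2 * (ni - 1))
    if den <= 0:
        return 1.0
    return float(chi2.sf(num * num / den, 1))


def min_pvalue_exhaustive(x, n1, n):
    """Exhaustive minimisation over every feasible cell-count vector."""
    x, n1, n = (list(np.atleast_1d(v)) for v in (x, n1, n))
    lo = [max(0, xi - (ni - n1i)) for xi, n1i, ni in zip(x, n1, n)]
    hi = [min(xi, n1i) for xi, n1i in zip(x, n1)]
    return min(
        cmh_pvalue_reference(list(a), x, n1, n)
        for a in itertools.product(*[range(l, h + 1) for l, h in zip(lo, hi)])
    )


def is_prunable_box_enumeration(x, n1, n, delta):
    """Prunability by brute force over the whole reachable margin box."""
    x, n1, n = (list(np.atleast_1d(v)) for v in (x, n1, n))
    for xp in itertools.product(*[range(xi, ni + 1) for xi, ni in zip(x, n)]):
        if min_pvalue_exhaustive(list(xp), n1, n) <= delta:
            return False
    return True


def closed_segments_bruteforce(cols):
    """All (s, l) whose OR encoding differs from both length-(l-1) subs."""
    n, m = cols.shape
    enc = {}
    for s in range(1, m + 1):
        for l in range(1, m - s + 2):
            enc[(s, l)] = cols[:, s - 1:s + l - 1].max(axis=1)
    out = []
    for (s, l), e in enc.items():
        if l == 1 or (
            not np.array_equal(e, enc[(s, l - 1)])
            and not np.array_equal(e, enc[(s + 1, l - 1)])
        ):
            out.append((s, l))
    return sorted(out)


def random_margins(rng, K, n_max=30):
    n = rng.integers(2, n_max + 1, size=K)
    n1 = np.array([rng.integers(0, ni + 1) for ni in n])
    x = np.array([rng.integers(0, ni + 1) for ni in n])
    return x, n1, n


def snp_pair_reference(sim, alpha=0.05):
    """Straightforward single-variant-pair miner: loops, reference CMH and
    exhaustive minimum p-values, closed-form threshold schedule.

    Returns (delta_hat, n_testable, delta_star, sorted significant keys).
    """
    ds = sim.dataset
    gmap = nm.build_gene_snp_map(
        sim.annotations, ds.variant_chroms, ds.variant_pos, 0
    )
    K = ds.n_classes
    n_k = [int(np.sum(ds.c == k)) for k in range(1, K + 1)]
    n1_k = [int(np.sum(ds.y[ds.c == k])) for k in range(1, K + 1)]
    cand = []
    for g1, g2 in sorted(sim.network.edges):
        if g1 not in gmap or g2 not in gmap:
            continue
        for i1, col1 in enumerate(gmap[g1], start=1):
            for i2, col2 in enumerate(gmap[g2], start=1):
                w = ds.D[:, col1] | ds.D[:, col2]
                x = [int(np.sum(w[ds.c == k])) for k in range(1, K + 1)]
                a = [
                    int(np.sum(w[(ds.c == k) & (ds.y == 1)]))
                    for k in range(1, K + 1)
                ]
                pmin = min_pvalue_exhaustive(x, n1_k, n_k)
                p = cmh_pvalue_reference(a, x, n1_k, n_k)
                cand.append(((g1, g2, i1, 1, i2, 1), pmin, p))
    p_mins = np.array([c[1] for c in cand])
    grid = nm.threshold_grid()
    for i, d in enumerate(grid):
        if d * np.sum(p_mins <= d) < alpha:
            delta_grid = d
            delta_prev = grid[i - 1] if i else 1.0
            break
    # exact threshold: largest observed minimum p-value within one grid step
    # whose testable count still satisfies the familywise bound
    delta_hat = delta_grid
    for v in sorted(set(p_mins[p_mins <= delta_prev])):
        if v * np.sum(p_mins <= v) < alpha:
            delta_hat = max(delta_hat, v)
    n_testable = int(np.sum(p_mins <= delta_hat))
    delta_star = alpha / n_testable if n_testable else alpha
    significant = sorted(
        key for key, pmin, p in cand if pmin <= delta_hat and p <= delta_star
    )
    return delta_hat, n_testable, delta_star, significant


@pytest.fixture
def small_sim():
    """A small planted-signal dataset shared by engine tests."""
    design = nm.SimulationDesign(
        n_samples=60, n_genes=8, n_edges=10, variants_per_gene=4,
        maf=0.25, k_classes=2, p_s=0.9,
    )
    return nm.generate_dataset(design, seed=11)
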