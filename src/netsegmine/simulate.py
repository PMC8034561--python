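"""Synthetic data with a planted segment interaction, and power/FWER studies.

The generator emulates the simulation design of the method's evaluation: a
random network over a modest number of genes, i.i.d. Bernoulli background
variants, and exactly one *truly associated* segment interaction planted on
a randomly chosen edge.  The phenotype follows the interaction's combined
heterogeneity encoding ``w`` with tunable strength ``p_s``:

    P(y = 1 | w = 1) = p_s,     P(y = 1 | w = 0) = 1 - p_s,

so ``p_s = 0.5`` is the exact null (phenotype independent of genotype) and
``p_s = 1`` a deterministic phenotype-pattern link.  Background variants are
i.i.d. (no linkage disequilibrium) by default; an optional first-order
Markov mode introduces within-gene correlation for robustness experiments.
Covariate classes are balanced and shuffled at random, so they are
independent of both genotype and phenotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import GeneAnnotation, GenotypeDataset, Network
from .mining import MiningConfig, run

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "SimulatedData",
    "generate_dataset",
    "run_power_experiment",
]

GENE_SPACING = 10_000
VARIANT_SPACING = 100


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulated dataset.

    Defaults reconstruct the published evaluation conditions where stated
    (75 genes, 100 edges, association strength in [0.5, 1]); the remaining
    values (sample size, variants per gene, background allele frequency,
    covariate classes, planted segment lengths) are this package's declared
    reconstruction, documented in the methods note.
    """

    n_samples: int = 200
    n_genes: int = 75
    n_edges: int = 100
    variants_per_gene: int = 5
    maf: float = 0.2
    k_classes: int = 2
    p_s: float = 0.5
    planted_lengths: tuple[int, int] = (2, 2)
    markov_rho: float = 0.0  # within-gene carry-over probability (0 = iid)
    seed: int = 0

    def __post_init__(self):
        if not (0.5 <= self.p_s <= 1.0):
            raise ValueError("p_s must lie in [0.5, 1]")
        if self.n_edges > self.n_genes * (self.n_genes - 1) // 2:
            raise ValueError("n_edges exceeds the number of gene pairs")
        if any(l < 1 or l > self.variants_per_gene for l in self.planted_lengths):
            raise ValueError("planted segment lengths must fit inside a gene")
        if not (0.0 < self.maf < 1.0):
            raise ValueError("maf must lie in (0, 1)")
        if self.k_classes < 1 or self.k_classes > self.n_samples:
            raise ValueError("k_classes must lie in [1, n_samples]")
        if not (0.0 <= self.markov_rho < 1.0):
            raise ValueError("markov_rho must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """The planted interaction: genes, within-gene segments, columns, encoding."""

    gene1: str
    gene2: str
    seg1: tuple[int, int]  # (start, length), 1-based within the gene
    seg2: tuple[int, int]
    cols1: np.ndarray      # absolute column indices
    cols2: np.ndarray
    pos_range1: tuple[int, int]
    pos_range2: tuple[int, int]
    bits: np.ndarray       # combined heterogeneity encoding w


@dataclass
class SimulatedData:
    dataset: GenotypeDataset
    annotations: list[GeneAnnotation]
    network: Network
    ground_truth: GroundTruth


def _gene_id(i: int) -> str:
    return f"g{i:04d}"


def generate_dataset(design: SimulationDesign,
                     seed: int | None = None) -> SimulatedData:
    """Draw one dataset from the design; reproducible from the seed."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n, v = design.n_samples, design.variants_per_gene
    d = design.n_genes * v

    # background genotypes
    if design.markov_rho == 0.0:
        D = (rng.random((n, d)) < design.maf).astype(np.uint8)
    else:
        D = np.empty((n, d), dtype=np.uint8)
        for g in range(design.n_genes):
            block = slice(g * v, (g + 1) * v)
            cols = np.empty((n, v), dtype=np.uint8)
            cols[:, 0] = rng.random(n) < design.maf
            for j in range(1, v):
                carry = rng.random(n) < design.markov_rho
                fresh = (rng.random(n) < design.maf).astype(np.uint8)
                cols[:, j] = np.where(carry, cols[:, j - 1], fresh)
            D[:, block] = cols
    # annotation: disjoint gene intervals on one chromosome
    annotations = []
    chroms = np.empty(d, dtype=object)
    pos = np.empty(d, dtype=np.int64)
    for g in range(design.n_genes):
        start = 1 + g * GENE_SPACING
        p = start + VARIANT_SPACING * np.arange(v)
        annotations.append(GeneAnnotation(_gene_id(g), "1", start, int(p[-1])))
        chroms[g * v:(g + 1) * v] = "1"
        pos[g * v:(g + 1) * v] = p

    # random network of n_edges distinct gene pairs
    all_pairs = list(itertools.combinations(range(design.n_genes), 2))
    chosen = rng.choice(len(all_pairs), size=design.n_edges, replace=False)
    edges = frozenset(
        (_gene_id(all_pairs[i][0]), _gene_id(all_pairs[i][1])) for i in chosen
    )
    network = Network(frozenset(_gene_id(g) for g in range(design.n_genes)), edges)

    # plant the truly associated interaction on a random edge
    planted_pair = all_pairs[chosen[rng.integers(len(chosen))]]
    segs, cols, pranges = [], [], []
    for gene_idx, length in zip(planted_pair, design.planted_lengths):
        s = int(rng.integers(1, v - length + 2))
        c = np.arange(gene_idx * v + s - 1, gene_idx * v + s - 1 + length)
        segs.append((s, length))
        cols.append(c)
        pranges.append((int(pos[c[0]]), int(pos[c[-1]])))
    w = D[:, np.concatenate(cols)].max(axis=1).astype(np.uint8)

    # phenotype follows w with strength p_s; redraw if degenerate
    while True:
        u = rng.random(n)
        y = np.where(w == 1, u < design.p_s, u < 1.0 - design.p_s).astype(np.uint8)
        if y.min() != y.max():
            break

    # balanced, shuffled covariate classes
    c = np.resize(np.arange(1, design.k_classes + 1), n)
    rng.shuffle(c)

    dataset = GenotypeDataset(
        D=D, y=y, c=c,
        sample_ids=[f"s{i:05d}" for i in range(n)],
        variant_ids=[f"v{j:05d}" for j in range(d)],
        variant_chroms=chroms,
        variant_pos=pos,
    )
    truth = GroundTruth(
        gene1=_gene_id(planted_pair[0]), gene2=_gene_id(planted_pair[1]),
        seg1=segs[0], seg2=segs[1],
        cols1=cols[0], cols2=cols[1],
        pos_range1=pranges[0], pos_range2=pranges[1],
        bits=w,
    )
    return SimulatedData(dataset, annotations, network, truth)


def _ranges_overlap(range_str: str, truth_range: tuple[int, int]) -> bool:
    lo, hi = (int(t) for t in range_str.split("-"))
    return lo <= truth_range[1] and truth_range[0] <= hi


def _classify_hits(significant: pd.DataFrame, truth: GroundTruth,
                   null_run: bool) -> tuple[bool, bool]:
    """(true detection present, false positive present) for one replicate.

    A detection is true when the reported gene pair equals the planted edge
    and each reported segment's position range intersects the planted
    segment of its gene.  On a null dataset every report is false.
    """
    if significant.empty:
        return False, False
    if null_run:
        return False, True
    any_true = any_false = False
    for _, row in significant.iterrows():
        pair = {row.gene1: row.pos_range1, row.gene2: row.pos_range2}
        if set(pair) == {truth.gene1, truth.gene2} and \
                _ranges_overlap(pair[truth.gene1], truth.pos_range1) and \
                _ranges_overlap(pair[truth.gene2], truth.pos_range2):
            any_true = True
        else:
            any_false = True
    return any_true, any_false


def run_power_experiment(
    design: SimulationDesign,
    p_s_values,
    n_replicates: int,
    config: MiningConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate power and empirical FWER on a grid of association strengths.

    Power is the fraction of replicates in which any reported interaction
    overlaps the planted one; the empirical FWER is the fraction of
    replicates reporting at least one non-overlapping interaction (at the
    null strength 0.5, any report at all).  Per-replicate seeds derive
    deterministically from the master seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    config = config or MiningConfig()
    rows = []
    for i, p_s in enumerate(p_s_values):
        children = np.random.SeedSequence(entropy=seed, spawn_key=(i,)).spawn(n_replicates)
        hits = np.zeros(n_replicates, dtype=bool)
        false = np.zeros(n_replicates, dtype=bool)
        for r, child in enumerate(children):
            rep_seed = int(child.generate_state(1, np.uint32)[0] % (2 ** 31))
            sim = generate_dataset(replace(design, p_s=float(p_s)), seed=rep_seed)
            cfg = replace(config, seed=rep_seed)
            result = run(sim.dataset, sim.annotations, sim.network, cfg)
            hits[r], false[r] = _classify_hits(
                result.significant, sim.ground_truth, null_run=(p_s == 0.5)
            )
        rows.append({
            "p_s": float(p_s),
            "power": float(hits.mean()),
            "fwer": float(false.mean()),
            "n_replicates": n_replicates,
        })
    return pd.DataFrame(rows)
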