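"""The mining engine: network-guided enumeration, testing and reporting.

For every network edge whose two genes both carry mapped variants, the
engine enumerates the closed segments of each gene, walks the Cartesian
product of segment pairs in sub-pattern-first order, computes each
interaction's heterogeneity encoding and minimum attainable p-value, feeds
testable interactions into the FWER machinery (testability counting or
Westfall-Young permutations) and discards provably untestable subtrees.
The observed phenotype enters only after all edges are processed, when the
surviving testable patterns are tested at the corrected threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import NoMinableEdgesError
from .io import GeneAnnotation, GenotypeDataset, Network, build_gene_snp_map
from .segments import PruneSet, enumerate_closed_segments, enumerate_interactions
from .stats import ClassPartition, _MinPvalueCalculator, _is_prunable_kernel, threshold_grid
from .tarone import TaroneState, TestablePattern, filter_significant, refine_threshold
from .westfall_young import PermutationState, process_pattern_wy, wy_threshold

logger = logging.getLogger("netsegmine")

__all__ = ["MiningConfig", "MiningResult", "run"]

RESULT_COLUMNS = [
    "gene1", "gene2", "chrom1", "s1", "l1", "pos_range1",
    "chrom2", "s2", "l2", "pos_range2",
    "p_value", "p_min", "support", "shared_variants",
    "delta_star", "n_testable",
]


@dataclass(frozen=True)
class MiningConfig:
    """Run parameters of the miner.

    ``alpha`` is the target familywise error rate; ``mode`` selects the
    correction route (``tarone`` counts testable patterns, ``wy`` estimates
    the FWER from phenotype permutations).  ``max_len`` caps the per-segment
    length (1 reduces the search to single-variant pairs); ``None`` means
    unlimited.  ``window_bp`` extends gene intervals symmetrically when
    mapping variants.  ``n_perm``/``perm_scheme`` configure the permutation
    route; ``grid_ratio``/``grid_floor`` the candidate threshold grid.
    ``prune`` can disable subtree pruning for auditing (results must not
    change, only work done).
    """

    alpha: float = 0.05
    mode: str = "tarone"
    max_len: int | None = None
    window_bp: int = 0
    n_perm: int = 1000
    perm_scheme: str = "within-class"
    seed: int = 0
    grid_ratio: float = 0.5
    grid_floor: float = 1e-30
    prune: bool = True
    exclude_shared_variants: bool = False

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("tarone", "wy"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_len is not None and self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.mode == "wy" and self.alpha * self.n_perm < 10:
            logger.warning(
                "alpha * n_perm = %.1f < 10: the permutation FWER estimate "
                "is coarse; consider more permutations",
                self.alpha * self.n_perm,
            )


@dataclass
class MiningResult:
    """Everything a run produces: hits, thresholds, counters and provenance."""

    significant: pd.DataFrame
    threshold: float          # delta* (tarone) or delta_WY (wy)
    delta_hat: float          # final testability threshold
    n_testable: int
    n_enumerated: int         # interactions actually materialised
    n_pruned: int             # interactions skipped inside pruned subtrees
    n_prune_roots: int
    n_hypotheses: int         # closed interactions in the full search space
    n_edges_mined: int
    n_edges_skipped: int
    trajectory: list[tuple[int, float]]
    config: MiningConfig
    edge_counters: pd.DataFrame
    p_min_vec: np.ndarray | None = None

    @property
    def bonferroni_threshold(self) -> float:
        return self.config.alpha / max(self.n_hypotheses, 1)

    def summary(self) -> dict:
        return {
            "mode": self.config.mode,
            "alpha": self.config.alpha,
            "seed": self.config.seed,
            "threshold": self.threshold,
            "delta_hat_final": self.delta_hat,
            "n_testable": self.n_testable,
            "n_significant": int(len(self.significant)),
            "n_hypotheses": self.n_hypotheses,
            "n_enumerated": self.n_enumerated,
            "n_pruned": self.n_pruned,
            "n_prune_roots": self.n_prune_roots,
            "n_edges_mined": self.n_edges_mined,
            "n_edges_skipped": self.n_edges_skipped,
            "bonferroni_threshold": self.bonferroni_threshold,
            "delta_trajectory": [
                {"after_registered": k, "delta_hat": d} for k, d in self.trajectory
            ],
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.significant.to_csv(outdir / "results.tsv", sep="\t", index=False)
        with (outdir / "summary.json").open("w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _closed_segments_for_edge(gene_id, cols, dataset, partition, cache,
                              exclude=None):
    """Closed segments of one gene, optionally with shared columns removed."""
    if exclude:
        keep = np.array([c for c in cols if c not in exclude], dtype=np.int64)
        if len(keep) == 0:
            return None, keep
        return (
            enumerate_closed_segments(gene_id, dataset.D[:, keep], partition),
            keep,
        )
    if gene_id not in cache:
        cache[gene_id] = enumerate_closed_segments(
            gene_id, dataset.D[:, cols], partition
        )
    return cache[gene_id], cols


def run(
    dataset: GenotypeDataset,
    annotations: Sequence[GeneAnnotation],
    network: Network,
    config: MiningConfig | None = None,
) -> MiningResult:
    """Mine all network edges and return the significant segment interactions.

    Edges are processed in sorted gene-pair order; the final testable set and
    the significant set are invariant to that order in ``tarone`` mode (the
    threshold trajectory is a function of the multiset of minimum p-values).
    """
    config = config or MiningConfig()
    partition = ClassPartition(dataset.c, dataset.y)
    gmap = build_gene_snp_map(
        annotations, dataset.variant_chroms, dataset.variant_pos, config.window_bp
    )
    edges = sorted(network.edges)
    minable = [(g1, g2) for g1, g2 in edges if g1 in gmap and g2 in gmap]
    n_skipped = len(edges) - len(minable)
    if n_skipped:
        logger.info("skipping %d edge(s) with an unrepresentable gene", n_skipped)
    if not minable:
        raise NoMinableEdgesError("no network edge connects two variant-bearing genes")

    grid = threshold_grid(config.grid_floor, config.grid_ratio)
    # In testability-counting mode the engine keeps a one-grid-step cushion
    # of near-testable patterns so the final threshold can be refined to the
    # exact optimum over the observed minimum p-values (see refine_threshold).
    evicted: list[TestablePattern] = []
    cushion: list[TestablePattern] = []
    state = TaroneState(
        config.alpha, grid,
        evicted_sink=evicted if config.mode == "tarone" else None,
    )
    perm = None
    if config.mode == "wy":
        perm = PermutationState(
            dataset.y, dataset.c, config.n_perm, config.seed, config.perm_scheme
        )

    calc = _MinPvalueCalculator(partition.n1_f, partition.n_f)
    seg_cache: dict[str, list] = {}
    n_hypotheses = 0
    n_enumerated = 0
    n_prune_roots = 0
    edge_rows = []

    for g1, g2 in minable:
        cols1, cols2 = gmap[g1], gmap[g2]
        shared = set(cols1) & set(cols2)
        exclude = shared if (config.exclude_shared_variants and shared) else None
        segs1, used1 = _closed_segments_for_edge(
            g1, cols1, dataset, partition, seg_cache, exclude
        )
        segs2, used2 = _closed_segments_for_edge(
            g2, cols2, dataset, partition, seg_cache, exclude
        )
        if segs1 is None or segs2 is None:
            n_skipped += 1
            continue

        def n_eligible(segs):
            if config.max_len is None:
                return len(segs)
            return sum(1 for s, _ in segs if s.length <= config.max_len)

        m_edge = n_eligible(segs1) * n_eligible(segs2)
        n_hypotheses += m_edge

        pruned = PruneSet() if config.prune else None
        edge_enum = edge_testable = 0
        for seg1, enc1, seg2, enc2 in enumerate_interactions(
            segs1, segs2, config.max_len, skip=pruned
        ):
            edge_enum += 1
            w = np.maximum(enc1.bits, enc2.bits)
            x = partition.supports(w)
            p_min = float(calc.pmin(x))
            record = p_min <= (
                state.delta_prev if config.mode == "tarone" else state.delta_hat
            )
            if record:
                pattern = TestablePattern(
                    seg1, seg2, p_min, w, x,
                    cols1=used1[seg1.start - 1:seg1.end],
                    cols2=used2[seg2.start - 1:seg2.end],
                )
                if config.mode == "tarone":
                    if p_min <= state.delta_hat:
                        state.register_testable(pattern)
                        edge_testable += 1
                    else:
                        cushion.append(pattern)
                else:
                    state.admit(pattern)
                    process_pattern_wy(perm, state, w)
                    edge_testable += 1
            prune_delta = (
                state.delta_prev if config.mode == "tarone" else state.delta_hat
            )
            if pruned is not None and _is_prunable_kernel(
                calc, x, partition.n1, partition.n, prune_delta
            ):
                pruned.add(seg1, seg2)
                n_prune_roots += 1

        n_enumerated += edge_enum
        edge_rows.append({
            "gene1": g1, "gene2": g2,
            "n_hypotheses": m_edge,
            "n_enumerated": edge_enum,
            "n_pruned": pruned.n_skipped if pruned is not None else 0,
            "n_testable": edge_testable,
            "shared_variants": len(shared),
        })

    if config.mode == "tarone":
        delta_final, testable_final = refine_threshold(
            state.testable + cushion + evicted,
            config.alpha, state.delta_hat, state.delta_prev,
        )
        if testable_final:
            delta_star = config.alpha / len(testable_final)
        else:
            logger.warning("zero testable patterns; reporting delta* = alpha")
            delta_star = config.alpha
        p_min_vec = None
    else:
        delta_final = state.delta_hat
        testable_final = state.testable
        delta_star = wy_threshold(perm.p_min_vec, config.alpha)
        p_min_vec = perm.p_min_vec.copy()

    hits = filter_significant(testable_final, dataset.y, partition, delta_star)
    rows = []
    for pattern, p_value in hits:
        row = {}
        for tag, seg, cols in (
            ("1", pattern.seg1, pattern.cols1),
            ("2", pattern.seg2, pattern.cols2),
        ):
            first, last = cols[0], cols[-1]
            row[f"gene{tag}"] = seg.gene_id
            row[f"chrom{tag}"] = dataset.variant_chroms[first]
            row[f"s{tag}"] = seg.start
            row[f"l{tag}"] = seg.length
            row[f"pos_range{tag}"] = (
                f"{dataset.variant_pos[first]}-{dataset.variant_pos[last]}"
            )
        c1, c2 = set(pattern.cols1), set(pattern.cols2)
        row.update({
            "p_value": p_value,
            "p_min": pattern.p_min,
            "support": int(pattern.x.sum()),
            "shared_variants": bool(c1 & c2),
            "delta_star": delta_star,
            "n_testable": len(testable_final),
        })
        rows.append(row)
    significant = pd.DataFrame(rows, columns=RESULT_COLUMNS)

    n_pruned_total = int(sum(r["n_pruned"] for r in edge_rows))
    return MiningResult(
        significant=significant,
        threshold=delta_star,
        delta_hat=delta_final,
        n_testable=len(testable_final),
        n_enumerated=n_enumerated,
        n_pruned=n_pruned_total,
        n_prune_roots=n_prune_roots,
        n_hypotheses=n_hypotheses,
        n_edges_mined=len(edge_rows),
        n_edges_skipped=n_skipped,
        trajectory=state.trajectory,
        config=config,
        edge_counters=pd.DataFrame(edge_rows),
        p_min_vec=p_min_vec,
    )
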