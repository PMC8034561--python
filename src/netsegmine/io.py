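"""Reading and writing of genotypes, phenotypes, annotations and networks.

File dialects
-------------
* genotype ``tsv-matrix``: header line ``#id <variant_id...>``, then one line
  per sample ``<sample_id> <0/1...>``, whitespace-separated.  A companion
  positions file maps ``variant_id chrom pos`` (1-based positions).
* ``plink-raw``: a PLINK ``.raw`` additive file; dosages 0/1/2 are collapsed
  to a dominant 0/1 coding (1 and 2 become 1).
* phenotype / covariates: one label per sample, whitespace-separated, in the
  same order as the genotype rows.  Covariate labels may be arbitrary
  strings and are relabelled to contiguous ``1..K`` in order of first
  appearance; a missing covariate file yields the single-class vector
  (the stratified test then reduces to a plain 1-df chi-squared test).
* annotation: 4/5-column TSV ``gene_id chrom start end [strand]`` with
  1-based, fully inclusive coordinates, or GFF3 restricted to ``gene``
  features (read through :mod:`gffutils`).
* network: two whitespace-separated gene ids per line.  Self-edges are
  dropped with a warning and duplicate (including reversed) edges are
  collapsed.

Strand is informational only: window flanks extend in both directions
regardless of orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegeneratePhenotypeError, NoMinableEdgesError, ParseError

logger = logging.getLogger("netsegmine")

__all__ = [
    "GenotypeMatrix",
    "GenotypeDataset",
    "GeneAnnotation",
    "GeneSnpMap",
    "Network",
    "read_genotypes",
    "write_genotypes",
    "read_positions",
    "write_positions",
    "read_phenotype_covariates",
    "write_phenotype",
    "write_covariates",
    "read_annotation",
    "write_annotation",
    "read_network",
    "write_network",
    "build_gene_snp_map",
    "build_dataset",
]


@dataclass
class GenotypeMatrix:
    """A binary sample x variant matrix with row/column identifiers."""

    sample_ids: list[str]
    variant_ids: list[str]
    D: np.ndarray  # n x d, uint8 in {0, 1}

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=np.uint8)
        if self.D.ndim != 2:
            raise ValueError("genotype matrix must be two-dimensional")
        if self.D.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("matrix shape inconsistent with id lists")
        if self.D.size and self.D.max() > 1:
            raise ValueError("genotype matrix entries must be 0 or 1")


@dataclass
class GenotypeDataset:
    """Binary genotypes with phenotype, covariates and variant coordinates.

    Columns are ordered by (chromosome, position); ``c`` holds contiguous
    covariate class labels ``1..K`` with every class non-empty.
    """

    D: np.ndarray
    y: np.ndarray
    c: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    variant_chroms: np.ndarray
    variant_pos: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=np.uint8)
        self.y = np.asarray(self.y, dtype=np.uint8)
        self.c = np.asarray(self.c, dtype=np.int64)
        self.variant_chroms = np.asarray(self.variant_chroms, dtype=object)
        self.variant_pos = np.asarray(self.variant_pos, dtype=np.int64)
        n, d = self.D.shape
        if self.D.size and self.D.max() > 1:
            raise ValueError("genotype entries must be 0 or 1")
        if len(self.y) != n or len(self.c) != n or len(self.sample_ids) != n:
            raise ValueError("per-sample arrays must have length n")
        if len(self.variant_ids) != d or len(self.variant_chroms) != d \
                or len(self.variant_pos) != d:
            raise ValueError("per-variant arrays must have length d")
        if self.y.min() == self.y.max():
            raise DegeneratePhenotypeError("degenerate phenotype: y is constant")
        k = int(self.c.max())
        counts = np.bincount(self.c, minlength=k + 1)[1:]
        if self.c.min() < 1 or np.any(counts == 0):
            raise ValueError("covariate classes must be contiguous 1..K, all non-empty")
        for chrom in dict.fromkeys(self.variant_chroms):
            pos = self.variant_pos[self.variant_chroms == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"variant positions not sorted within chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return self.D.shape[0]

    @property
    def n_variants(self) -> int:
        return self.D.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.c.max())


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval; 1-based, fully inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class GeneSnpMap:
    """gene_id -> ascending column indices of the gene's mapped variants."""

    columns: dict[str, np.ndarray]
    unrepresentable: tuple[str, ...] = ()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.columns

    def __getitem__(self, gene_id: str) -> np.ndarray:
        return self.columns[gene_id]


@dataclass(frozen=True)
class Network:
    """An undirected gene-gene interaction network without self or duplicate edges."""

    nodes: frozenset
    edges: frozenset  # of 2-tuples (sorted gene_id pairs)

    def __post_init__(self):
        for g1, g2 in self.edges:
            if g1 == g2:
                raise ValueError("self-edges are not allowed")
            if g1 not in self.nodes or g2 not in self.nodes:
                raise ValueError("edge endpoint missing from node set")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format_name: str = "tsv-matrix") -> GenotypeMatrix:
    if format_name == "tsv-matrix":
        return _read_tsv_matrix(path)
    if format_name == "plink-raw":
        return _read_plink_raw(path)
    raise ValueError(f"unknown genotype format {format_name!r}")


def _read_tsv_matrix(path) -> GenotypeMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if not header or header[0] != "#id":
            raise ParseError(f"{path}: expected header starting with '#id'")
        variant_ids = header[1:]
        d = len(variant_ids)
        sample_ids, rows = [], []
        for i, line in enumerate(fh, start=2):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != d + 1:
                raise ParseError(
                    f"{path}: row {i} has {len(tokens) - 1} entries, expected {d}"
                )
            sample_ids.append(tokens[0])
            row = np.empty(d, dtype=np.uint8)
            for j, tok in enumerate(tokens[1:]):
                if tok == "0":
                    row[j] = 0
                elif tok == "1":
                    row[j] = 1
                else:
                    raise ValueError(
                        f"{path}: entry {tok!r} at row {i} (sample "
                        f"{tokens[0]!r}), column {j + 1} (variant "
                        f"{variant_ids[j]!r}) is not 0/1"
                    )
            rows.append(row)
    D = np.vstack(rows) if rows else np.empty((0, d), dtype=np.uint8)
    return GenotypeMatrix(sample_ids, variant_ids, D)


def _read_plink_raw(path) -> GenotypeMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: PLINK .raw header lacks columns {missing}")
    snp_cols = [c for c in df.columns if c not in meta_cols]
    geno = df[snp_cols].to_numpy()
    if np.isnan(geno.astype(float)).any():
        raise ValueError(f"{path}: missing genotype calls are not supported")
    geno = geno.astype(np.int64)
    if geno.size and (geno.min() < 0 or geno.max() > 2):
        raise ValueError(f"{path}: additive dosages must be 0, 1 or 2")
    D = (geno > 0).astype(np.uint8)  # dominant binarization
    variant_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    return GenotypeMatrix(df["IID"].astype(str).tolist(), variant_ids, D)


def write_genotypes(path, matrix: GenotypeMatrix) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#id " + " ".join(matrix.variant_ids) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.D):
            fh.write(sid + " " + " ".join(str(int(v)) for v in row) + "\n")


def read_positions(path) -> dict[str, tuple[str, int]]:
    """Companion positions file: ``variant_id chrom pos`` per line."""
    path = Path(path)
    out: dict[str, tuple[str, int]] = {}
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 3:
                raise ParseError(f"{path}: row {i} must have 3 columns")
            try:
                out[tokens[0]] = (tokens[1], int(tokens[2]))
            except ValueError as exc:
                raise ParseError(f"{path}: row {i}: bad position {tokens[2]!r}") from exc
    return out


def write_positions(path, variant_ids, chroms, positions) -> None:
    with Path(path).open("w") as fh:
        for vid, chrom, pos in zip(variant_ids, chroms, positions):
            fh.write(f"{vid} {chrom} {int(pos)}\n")


# ---------------------------------------------------------------------------
# phenotype / covariates
# ---------------------------------------------------------------------------

def _read_tokens(path) -> list[str]:
    return Path(path).read_text().split()


def read_phenotype_covariates(path_y, path_c=None,
                              n_expected: int | None = None):
    """Read the binary phenotype and the (optional) covariate labels.

    Returns ``(y, c)`` with ``y`` a 0/1 vector and ``c`` relabelled to
    contiguous ``1..K`` in order of first appearance; with no covariate file
    ``c`` is all ones (K = 1).
    """
    tokens = _read_tokens(path_y)
    if any(t not in ("0", "1") for t in tokens):
        bad = next(t for t in tokens if t not in ("0", "1"))
        raise ValueError(f"{path_y}: phenotype label {bad!r} is not 0/1")
    y = np.array([int(t) for t in tokens], dtype=np.uint8)
    if n_expected is not None and len(y) != n_expected:
        raise ValueError(
            f"{path_y}: {len(y)} phenotype labels, expected {n_expected}"
        )
    if len(y) == 0 or y.min() == y.max():
        raise DegeneratePhenotypeError("degenerate phenotype: y is constant")
    if path_c is None:
        return y, np.ones(len(y), dtype=np.int64)
    labels = _read_tokens(path_c)
    if len(labels) != len(y):
        raise ValueError(
            f"{path_c}: {len(labels)} covariate labels, expected {len(y)}"
        )
    mapping: dict[str, int] = {}
    c = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        c[i] = mapping.setdefault(lab, len(mapping) + 1)
    return y, c


def write_phenotype(path, y) -> None:
    Path(path).write_text("\n".join(str(int(v)) for v in y) + "\n")


def write_covariates(path, c) -> None:
    Path(path).write_text("\n".join(str(int(v)) for v in c) + "\n")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path, format_name: str = "auto") -> list[GeneAnnotation]:
    path = Path(path)
    if format_name == "auto":
        if path.suffix.lower() in (".gff", ".gff3"):
            format_name = "gff3"
        else:
            with path.open() as fh:
                first = fh.readline()
            format_name = "gff3" if first.startswith("##gff") else "tsv"
    if format_name == "gff3":
        genes = _read_gff3_genes(path)
    elif format_name == "tsv":
        genes = _read_annotation_tsv(path)
    else:
        raise ValueError(f"unknown annotation format {format_name!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ParseError(f"{path}: duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _read_annotation_tsv(path) -> list[GeneAnnotation]:
    genes = []
    with Path(path).open() as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) not in (4, 5):
                raise ParseError(f"{path}: row {i} must have 4 or 5 columns")
            try:
                start, end = int(tokens[2]), int(tokens[3])
            except ValueError as exc:
                raise ParseError(f"{path}: row {i}: bad coordinates") from exc
            strand = tokens[4] if len(tokens) == 5 else None
            genes.append(GeneAnnotation(tokens[0], tokens[1], start, end, strand))
    return genes


def _read_gff3_genes(path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.id
        if gid.startswith("gene:"):
            gid = gid[len("gene:"):]
        strand = feat.strand if feat.strand in ("+", "-") else None
        genes.append(GeneAnnotation(gid, feat.seqid, feat.start, feat.end, strand))
    return genes


def write_annotation(path, annotations: Iterable[GeneAnnotation]) -> None:
    with Path(path).open("w") as fh:
        for g in annotations:
            strand = f" {g.strand}" if g.strand else ""
            fh.write(f"{g.gene_id} {g.chrom} {g.start} {g.end}{strand}\n")


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def read_network(path, gene_universe: Iterable[str] | None = None) -> Network:
    """Read a 2-column edge list, dropping self-edges and duplicates.

    Edges whose endpoints are absent from ``gene_universe`` (when given) are
    retained in the network but logged; the mining engine skips them.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    n_self = n_dup = 0
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 2:
                raise ParseError(f"{path}: row {i} must have 2 columns")
            g1, g2 = tokens
            if g1 == g2:
                n_self += 1
                logger.warning("%s: row %d: dropping self-edge %s-%s", path, i, g1, g2)
                continue
            edge = (g1, g2) if g1 <= g2 else (g2, g1)
            if edge in edges:
                n_dup += 1
                continue
            edges.add(edge)
            nodes.update(edge)
    if n_dup:
        logger.info("%s: collapsed %d duplicate edge(s)", path, n_dup)
    if not edges:
        raise NoMinableEdgesError(f"{path}: no minable edges after filtering")
    if gene_universe is not None:
        universe = set(gene_universe)
        for g1, g2 in sorted(edges):
            if g1 not in universe or g2 not in universe:
                logger.info(
                    "edge %s-%s references a gene without mapped variants; "
                    "it will be skipped by mining", g1, g2,
                )
    return Network(frozenset(nodes), frozenset(edges))


def write_network(path, network: Network) -> None:
    with Path(path).open("w") as fh:
        for g1, g2 in sorted(network.edges):
            fh.write(f"{g1} {g2}\n")


# ---------------------------------------------------------------------------
# gene -> variant mapping and dataset assembly
# ---------------------------------------------------------------------------

def build_gene_snp_map(
    annotations: Sequence[GeneAnnotation],
    variant_chroms: Sequence[str],
    variant_pos: Sequence[int],
    window_bp: int = 0,
) -> GeneSnpMap:
    """Map every gene to the columns of variants inside its flanked interval.

    A variant at position ``p`` on the gene's chromosome maps to the gene
    iff ``start - window_bp <= p <= end + window_bp`` (1-based, inclusive on
    both ends).  A variant may map to several genes.  Genes without any
    mapped variant are recorded as unrepresentable, not errors.  The result
    is independent of the order of ``annotations``.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    chroms = np.asarray(variant_chroms, dtype=object)
    pos = np.asarray(variant_pos, dtype=np.int64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        order = np.argsort(p, kind="stable")
        by_chrom[chrom] = (p[order], idx[order])
    columns: dict[str, np.ndarray] = {}
    unrepresentable: list[str] = []
    for gene in annotations:
        hit = by_chrom.get(gene.chrom)
        if hit is None:
            unrepresentable.append(gene.gene_id)
            continue
        p_sorted, idx_sorted = hit
        lo = gene.start - window_bp
        hi = gene.end + window_bp
        left = np.searchsorted(p_sorted, lo, side="left")
        right = np.searchsorted(p_sorted, hi, side="right")
        cols = idx_sorted[left:right]
        if len(cols) == 0:
            unrepresentable.append(gene.gene_id)
        else:
            columns[gene.gene_id] = cols
    return GeneSnpMap(columns, tuple(sorted(unrepresentable)))


def build_dataset(
    matrix: GenotypeMatrix,
    positions: dict[str, tuple[str, int]],
    y,
    c=None,
) -> GenotypeDataset:
    """Assemble a validated dataset, sorting columns by (chromosome, position)."""
    missing = [v for v in matrix.variant_ids if v not in positions]
    if missing:
        raise ValueError(f"positions missing for variants {missing[:5]!r}...")
    chroms = np.array([positions[v][0] for v in matrix.variant_ids], dtype=object)
    pos = np.array([positions[v][1] for v in matrix.variant_ids], dtype=np.int64)
    order = np.lexsort((pos, chroms.astype(str)))
    y = np.asarray(y)
    if c is None:
        c = np.ones(len(y), dtype=np.int64)
    return GenotypeDataset(
        D=matrix.D[:, order],
        y=y,
        c=np.asarray(c),
        sample_ids=list(matrix.sample_ids),
        variant_ids=[matrix.variant_ids[j] for j in order],
        variant_chroms=chroms[order],
        variant_pos=pos[order],
    )
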