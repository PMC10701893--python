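"""Genome characteristics, gene-loss mapping, and phylogenetic correlation.

Covers per-genome size/GC/gene-presence summaries, Dollo-parsimony mapping
of gene losses onto a rooted species tree, and correlation of tip traits
with and without phylogenetic correction (GLS under a Brownian-motion
covariance with Pagel's lambda).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats

from .core_io import CANONICAL_GENES, ContigRecord, GeneAnnotation

__all__ = [
    "GenomeSummary",
    "LossMap",
    "PglsResult",
    "summarize_genome",
    "presence_proportions",
    "dollo_losses",
    "corr_plain",
    "corr_pgls",
    "brownian_covariance",
]


@dataclass(frozen=True)
class GenomeSummary:
    species: str
    size_bp: int
    gc_fraction: float
    presence: Mapping[str, bool]
    n_contigs: int
    intron_count: int
    fragmented: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in [0, 1]")


def _gc_counts(seq: str) -> tuple[int, int]:
    gc = sum(seq.count(b) for b in "GC")
    total = sum(seq.count(b) for b in "ACGT")
    return gc, total


def summarize_genome(
    contigs: Sequence[ContigRecord],
    annotations: Sequence[GeneAnnotation],
    species: str = "",
) -> GenomeSummary:
    """Summarize one mitochondrial genome.

    GC is computed as (G+C)/(A+C+G+T) with N excluded from the denominator;
    intron_count excludes single-bp frameshift spans; assemblies left in
    more than one contig are flagged fragmented.
    """
    if not contigs:
        raise ValueError("at least one contig required")
    if any(len(c.sequence) == 0 for c in contigs):
        raise ValueError("empty contig sequence")
    gc = total = 0
    for c in contigs:
        g, t = _gc_counts(c.sequence)
        gc += g
        total += t
    presence = {gene: False for gene in CANONICAL_GENES}
    introns = 0
    for ann in annotations:
        if ann.is_canonical and ann.gene in presence:
            presence[ann.gene] = True
        introns += sum(1 for flag in ann.single_bp_flags if not flag)
    return GenomeSummary(
        species=species,
        size_bp=sum(c.length_bp for c in contigs),
        gc_fraction=gc / total if total else 0.0,
        presence=presence,
        n_contigs=len(contigs),
        intron_count=introns,
        fragmented=len(contigs) > 1,
    )


def presence_proportions(
    summaries: Sequence[GenomeSummary], gene_set: Sequence[str]
) -> dict[str, float]:
    """Per-species proportion of ``gene_set`` present."""
    unknown = set(gene_set) - set(CANONICAL_GENES)
    if unknown:
        raise ValueError(f"genes outside canonical vocabulary: {sorted(unknown)}")
    return {
        s.species: sum(s.presence.get(g, False) for g in gene_set) / len(gene_set)
        for s in summaries
    }


# ---------------------------------------------------------------------------
# Dollo-parsimony loss mapping


@dataclass(frozen=True)
class LossMap:
    """Minimal loss placement under Dollo parsimony.

    Each loss edge is identified by the set of tip labels in the clade below
    it.  Under a single ancestral gain with irreversible losses, the unique
    minimum places one loss on each maximal edge whose whole clade lacks the
    trait; no loss edge is ancestral to another.
    """

    trait: str
    loss_edges: frozenset[frozenset[str]]
    n_losses: int


def dollo_losses(
    tree: dendropy.Tree,
    tip_presence: Mapping[str, bool],
    trait: str = "",
) -> LossMap:
    """Map trait losses on a rooted tree under Dollo parsimony."""
    if not tree.is_rooted:
        raise ValueError("tree must be rooted; root it explicitly first")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(tip_presence)
    if missing:
        raise ValueError(f"tips without presence labels: {sorted(missing)}")

    absent: dict[int, bool] = {}
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            absent[id(node)] = not tip_presence[label]
            below[id(node)] = frozenset({label})
        else:
            kids = node.child_nodes()
            absent[id(node)] = all(absent[id(k)] for k in kids)
            below[id(node)] = frozenset().union(*(below[id(k)] for k in kids))

    # losses live on edges: an edge is a loss iff its clade is all-absent and
    # it is maximal (no ancestral *edge* is all-absent; the root has no edge,
    # so a fully absent tree maps to losses on the root's child edges)
    losses: set[frozenset[str]] = set()
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if absent[id(node)] and (parent is root or not absent[id(parent)]):
            losses.add(below[id(node)])
    return LossMap(trait=trait, loss_edges=frozenset(losses), n_losses=len(losses))


# ---------------------------------------------------------------------------
# Correlation, plain and phylogenetically corrected


def corr_plain(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def brownian_covariance(
    tree: dendropy.Tree, taxa: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion tip covariance: shared root-to-MRCA path lengths."""
    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    labels: list[str] = []
    index: dict[str, int] = {}
    for leaf in tree.leaf_node_iter():
        index[leaf.taxon.label] = len(labels)
        labels.append(leaf.taxon.label)
    n = len(labels)
    C = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[id(node)] = (depth[id(parent)] + edge) if parent is not None else 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            below[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            kids = node.child_nodes()
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in below[id(kids[a])]:
                        for j in below[id(kids[b])]:
                            C[i, j] = C[j, i] = depth[id(node)]
            below[id(node)] = [i for k in kids for i in below[id(k)]]
    if taxa is not None:
        order = [index[t] for t in taxa]
        C = C[np.ix_(order, order)]
        labels = list(taxa)
    return C, labels


@dataclass(frozen=True)
class PglsResult:
    r: float
    p: float
    lam: float
    slope: float
    intercept: float
    slope_se: float


def _pagel_v(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _whiten(L: np.ndarray, M: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    return solve_triangular(L, M, lower=True)


def _gls(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """Return (beta, RSS, logdetV, Lw) for the GLS fit y = X beta."""
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        d = np.diag(V)
        dupes = [
            (i, j)
            for i in range(len(d))
            for j in range(i + 1, len(d))
            if math.isclose(V[i, j], d[i], rel_tol=1e-12)
            and math.isclose(d[i], d[j], rel_tol=1e-12)
        ]
        raise ValueError(
            "singular phylogenetic covariance; duplicated zero-length tips "
            f"(index pairs {dupes})"
        ) from exc
    Xw = _whiten(L, X)
    yw = _whiten(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, logdet, (Xw, yw)


def _neg_profile_loglik(lam, C, X, y):
    n = len(y)
    V = _pagel_v(C, float(lam))
    try:
        _, rss, logdet, _ = _gls(X, y, V)
    except ValueError:
        return np.inf
    sigma2 = rss / n
    if sigma2 <= 0:
        return np.inf
    return 0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def corr_pgls(
    x: Mapping[str, float] | Sequence[float],
    y: Mapping[str, float] | Sequence[float],
    tree: dendropy.Tree,
    lambda_mode: str = "ml",
    lambda_fixed: float | None = None,
) -> PglsResult:
    """Phylogenetically corrected correlation via GLS regression.

    Fits ``y = a + b*x`` by generalized least squares with residual
    covariance V(lambda): the Brownian tip covariance of the tree with
    off-diagonal entries multiplied by Pagel's lambda.  With
    ``lambda_mode='ml'``, lambda is profiled by a grid over [0, 1] refined
    by bounded golden-section search.  The reported r is
    sign(b) * sqrt(R2_GLS); p comes from the t statistic of b on n-2 df.
    """
    C, labels = brownian_covariance(tree)
    if isinstance(x, Mapping):
        xv = np.array([x[t] for t in labels], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
    if isinstance(y, Mapping):
        yv = np.array([y[t] for t in labels], dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    n = len(xv)
    if n < 4 or len(yv) != n or C.shape[0] != n:
        raise ValueError("need matched traits on at least 4 tips")

    X = np.column_stack([np.ones(n), xv])

    if lambda_mode == "fixed":
        if lambda_fixed is None or not (0.0 <= lambda_fixed <= 1.0):
            raise ValueError("lambda_fixed must be supplied in [0, 1]")
        lam = float(lambda_fixed)
    elif lambda_mode == "ml":
        grid = np.linspace(0.0, 1.0, 21)
        vals = [_neg_profile_loglik(g, C, X, yv) for g in grid]
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                _neg_profile_loglik, bounds=(lo, hi), args=(C, X, yv),
                method="bounded", options={"xatol": 1e-6},
            )
            lam = float(res.x)
            if _neg_profile_loglik(grid[k], C, X, yv) < res.fun:
                lam = float(grid[k])
        else:
            lam = float(grid[k])
    else:
        raise ValueError("lambda_mode must be 'ml' or 'fixed'")

    V = _pagel_v(C, lam)
    beta, rss, _, (Xw, yw) = _gls(X, yv, V)
    # intercept-only fit in the same metric for R^2
    ones_w = Xw[:, [0]]
    b0, *_ = np.linalg.lstsq(ones_w, yw, rcond=None)
    tss = float(np.sum((yw - ones_w @ b0) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    slope = float(beta[1])
    sigma2 = rss / (n - 2)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = math.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0))
    if se > 0:
        tstat = slope / se
        p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    else:
        p = 0.0 if slope != 0 else 1.0
    r = math.copysign(math.sqrt(r2), slope if slope != 0 else 1.0)
    return PglsResult(
        r=float(r), p=float(p), lam=lam,
        slope=slope, intercept=float(beta[0]), slope_se=se,
    )
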