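"""Intron similarity networks, sharing categories, and Louvain clusters.

Mitochondrial introns are compared all-versus-all; a hit is kept when its
bit score reaches at least half the query's self-alignment bit score at
e-value below 1e-10.  Retained edges define sharing categories (unique,
shared within a group, shared within and between groups, solely between
groups) and are clustered with the Louvain method.

A built-in Smith-Waterman local aligner (match +1, mismatch -3, gap open
-5, extend -2; first gap residue costs the open penalty) provides a
deterministic backend for tests and small inputs; real datasets normally
supply an external all-versus-all tabular hit file instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import HitRecord, ParseError

__all__ = [
    "IntronRecord",
    "IntronEdge",
    "IntronCluster",
    "normalized_hits",
    "classify_introns",
    "classify_intron",
    "louvain_clusters",
    "cluster_spans",
    "builtin_intron_aligner",
    "builtin_all_vs_all",
    "self_bit_score",
    "read_intron_table",
    "write_intron_table",
]

NORM_SCORE_THRESHOLD = 0.5
EVALUE_THRESHOLD = 1e-10

CATEGORIES = ("unique", "within_group", "within_and_between", "between_only")


@dataclass(frozen=True)
class IntronRecord:
    intron_id: str
    species: str
    group: str
    order: str
    host_gene: str
    ordinal: int
    sequence: str = ""
    intron_type: str = "unknown"  # I | II | unknown
    orf_motif: str = "unknown"  # LAGLIDADG | GIY-YIG | none | unknown

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ValueError("intron ordinal must be >= 1")


@dataclass(frozen=True)
class IntronEdge:
    """An undirected similarity edge between two distinct introns."""

    a: str
    b: str
    norm_score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self edges are excluded")
        if not (0.0 < self.norm_score <= 1.0):
            raise ValueError("norm_score must lie in (0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


def normalized_hits(
    hits: Sequence[HitRecord],
    self_scores: Mapping[str, float],
    edge_rule: str = "union",
    denominator: str = "query",
) -> list[IntronEdge]:
    """Turn raw pairwise hits into retained similarity edges.

    Each hit is normalized by the query's self-alignment bit score (or by
    the larger of the two self scores with ``denominator='max_self'``) and
    passes when the normalized score is at least 0.5 (inclusive) with
    e-value below 1e-10.  With ``edge_rule='union'`` an undirected edge
    exists when at least one direction passes; ``'both'`` requires both.
    """
    if edge_rule not in {"union", "both"}:
        raise ValueError("edge_rule must be 'union' or 'both'")
    if denominator not in {"query", "max_self"}:
        raise ValueError("denominator must be 'query' or 'max_self'")
    passing: dict[tuple[str, str], dict[tuple[str, str], tuple[float, float]]] = {}
    directions: dict[tuple[str, str], set[tuple[str, str]]] = {}
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        for name in (h.query_id, h.subject_id):
            if name not in self_scores:
                raise ValueError(f"missing self score for intron {name!r}")
        if denominator == "query":
            denom = self_scores[h.query_id]
        else:
            denom = max(self_scores[h.query_id], self_scores[h.subject_id])
        norm = min(h.bit_score / denom, 1.0)
        if norm >= NORM_SCORE_THRESHOLD and h.evalue < EVALUE_THRESHOLD:
            key = tuple(sorted((h.query_id, h.subject_id)))
            directions.setdefault(key, set()).add((h.query_id, h.subject_id))
            prev = best.get(key)
            if prev is None or norm > prev[0]:
                best[key] = (norm, h.evalue)
            elif norm == prev[0]:
                best[key] = (norm, min(h.evalue, prev[1]))
    edges = []
    for key, (norm, evalue) in sorted(best.items()):
        if edge_rule == "both" and len(directions[key]) < 2:
            continue
        edges.append(IntronEdge(a=key[0], b=key[1], norm_score=norm, evalue=evalue))
    return edges


# ---------------------------------------------------------------------------
# Sharing categories


def _adjacency(edges: Iterable[IntronEdge]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for e in edges:
        adj.setdefault(e.a, set()).add(e.b)
        adj.setdefault(e.b, set()).add(e.a)
    return adj


def classify_intron(
    intron: IntronRecord,
    edges: Sequence[IntronEdge],
    introns: Mapping[str, IntronRecord],
) -> str:
    """Sharing category of one intron given the retained edge set.

    Only partners in a *different species* count towards sharing
    (same-species paralogous hits stay in the graph for clustering but do
    not define a category).
    """
    adj = _adjacency(edges)
    partners = []
    for other_id in adj.get(intron.intron_id, ()):
        if other_id not in introns:
            raise ValueError(f"edge partner {other_id!r} has no metadata record")
        other = introns[other_id]
        if other.species != intron.species:
            partners.append(other)
    if not partners:
        return "unique"
    same = [p for p in partners if p.group == intron.group]
    if len(same) == len(partners):
        return "within_group"
    if not same:
        return "between_only"
    return "within_and_between"


def classify_introns(
    introns: Sequence[IntronRecord], edges: Sequence[IntronEdge]
) -> dict[str, str]:
    """Category for every intron; invariant to edge direction and order."""
    by_id = {i.intron_id: i for i in introns}
    return {
        i.intron_id: classify_intron(i, edges, by_id) for i in introns
    }


# ---------------------------------------------------------------------------
# Louvain clustering


@dataclass(frozen=True)
class IntronCluster:
    cluster_id: int
    members: frozenset[str]


def louvain_clusters(
    edges: Sequence[IntronEdge],
    introns: Sequence[IntronRecord],
    seed: int = 0,
) -> list[IntronCluster]:
    """Louvain communities on the similarity graph (weights = norm scores).

    Isolated introns form singleton clusters.  Nodes are inserted in sorted
    order and the optimizer is seeded, so the partition is reproducible for
    a given (graph, seed).  Clusters are numbered by their smallest member.
    """
    graph = nx.Graph()
    for intron_id in sorted(i.intron_id for i in introns):
        graph.add_node(intron_id)
    for e in sorted(edges, key=lambda e: e.key):
        graph.add_edge(e.a, e.b, weight=e.norm_score)
    communities = nx.community.louvain_communities(
        graph, weight="weight", seed=seed
    )
    ordered = sorted(communities, key=lambda c: min(c))
    return [
        IntronCluster(cluster_id=k, members=frozenset(c))
        for k, c in enumerate(ordered)
    ]


def cluster_spans(
    clusters: Sequence[IntronCluster],
    introns: Sequence[IntronRecord],
) -> pd.DataFrame:
    """Per-cluster span report over groups, orders, host genes and types.

    ``same_type`` reports whether all members of known type share one
    variety (group I or II) — an observation column, not an assertion.
    """
    by_id = {i.intron_id: i for i in introns}
    rows = []
    for cluster in clusters:
        members = [by_id[m] for m in sorted(cluster.members)]
        groups = {m.group for m in members}
        orders = {m.order for m in members}
        genes = {m.host_gene for m in members}
        types = sorted({m.intron_type for m in members})
        motifs = sorted({m.orf_motif for m in members})
        known_types = {m.intron_type for m in members if m.intron_type != "unknown"}
        rows.append(
            dict(
                cluster_id=cluster.cluster_id,
                n_members=len(members),
                n_groups=len(groups),
                n_orders=len(orders),
                n_host_genes=len(genes),
                types=",".join(types),
                motifs=",".join(motifs),
                multi_group=len(groups) >= 2,
                multi_order=len(orders) >= 2,
                multi_gene=len(genes) >= 2,
                same_type=len(known_types) <= 1,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_members", "n_groups", "n_orders", "n_host_genes",
            "types", "motifs", "multi_group", "multi_order", "multi_gene",
            "same_type",
        ],
    )


# ---------------------------------------------------------------------------
# Built-in local aligner

MATCH = 1
MISMATCH = -3
GAP_OPEN = 5  # penalty of the first gapped residue
GAP_EXTEND = 2

# Karlin-Altschul parameters for the ungapped +1/-3 scoring system
# (the standard blastn constants for these scores).
KA_LAMBDA = 1.374
KA_K = 0.711


def _sw_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), -10**9, dtype=np.int64)
    F = np.full((m + 1, n + 1), -10**9, dtype=np.int64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr, ptrE, ptrF


try:  # numba acceleration; pure-Python kernel otherwise
    from numba import njit

    _sw_kernel_fast = njit(cache=False)(_sw_kernel)
except Exception:  # pragma: no cover
    _sw_kernel_fast = _sw_kernel


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def smith_waterman(a: str, b: str) -> tuple[int, dict]:
    """Optimal local alignment score and alignment statistics."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    best, bi, bj, ptr, ptrE, ptrF = _sw_kernel_fast(
        _encode(a), _encode(b), MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
    )
    # traceback
    i, j = bi, bj
    matches = mismatches = gap_opens = aln_len = 0
    state = 0  # 0=H, 1=E, 2=F
    au, bu = a.upper(), b.upper()
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                aln_len += 1
                if au[i - 1] == bu[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            came_from_h = ptrE[i, j] == 1
            aln_len += 1
            j -= 1
            if came_from_h:
                gap_opens += 1
                state = 0
        else:
            came_from_h = ptrF[i, j] == 1
            aln_len += 1
            i -= 1
            if came_from_h:
                gap_opens += 1
                state = 0
    stats = dict(
        qstart=i + 1, qend=bi, sstart=j + 1, send=bj,
        matches=matches, mismatches=mismatches,
        gap_opens=gap_opens, aln_length=aln_len,
    )
    return int(best), stats


def _bit_score(raw: int) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)


def self_bit_score(seq: str) -> float:
    """Maximum possible bit score: the self-to-self alignment."""
    return _bit_score(len(seq) * MATCH)


def builtin_intron_aligner(a: str, b: str, query_id: str = "query",
                           subject_id: str = "subject") -> HitRecord:
    """Align two sequences with the built-in Smith-Waterman backend.

    Bit score follows Karlin-Altschul, B = (lambda*S - ln K) / ln 2, with
    the ungapped-approximation constants for the +1/-3 scoring system; the
    e-value is m*n*2^-B.
    """
    raw, stats = smith_waterman(a, b)
    bits = _bit_score(raw)
    evalue = len(a) * len(b) * 2.0 ** (-bits)
    identity = (
        100.0 * stats["matches"] / stats["aln_length"]
        if stats["aln_length"] else 0.0
    )
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=identity,
        aln_length=stats["aln_length"],
        mismatches=stats["mismatches"],
        gap_opens=stats["gap_opens"],
        qstart=stats["qstart"],
        qend=stats["qend"],
        sstart=stats["sstart"],
        send=stats["send"],
        evalue=evalue,
        bit_score=bits,
    )


def builtin_all_vs_all(
    seqs: Mapping[str, str]
) -> tuple[list[HitRecord], dict[str, float]]:
    """All-versus-all hits plus self scores using the built-in aligner.

    Scores are symmetric, so each unordered pair is aligned once and both
    directions are emitted.
    """
    names = sorted(seqs)
    self_scores = {name: self_bit_score(seqs[name]) for name in names}
    hits: list[HitRecord] = []
    for idx, qa in enumerate(names):
        for sb in names[idx + 1 :]:
            hit = builtin_intron_aligner(
                seqs[qa], seqs[sb], query_id=qa, subject_id=sb
            )
            hits.append(hit)
            hits.append(
                HitRecord(
                    query_id=sb, subject_id=qa,
                    pct_identity=hit.pct_identity,
                    aln_length=hit.aln_length,
                    mismatches=hit.mismatches, gap_opens=hit.gap_opens,
                    qstart=hit.sstart, qend=hit.send,
                    sstart=hit.qstart, send=hit.qend,
                    evalue=hit.evalue, bit_score=hit.bit_score,
                )
            )
    return hits, self_scores


# ---------------------------------------------------------------------------
# Metadata tables

_INTRON_COLUMNS = [
    "intron_id", "species", "group", "order", "host_gene",
    "ordinal", "intron_type", "orf_motif",
]


def read_intron_table(
    path: str | Path, sequences: Mapping[str, str] | None = None
) -> list[IntronRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_INTRON_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            IntronRecord(
                intron_id=row.intron_id,
                species=row.species,
                group=row.group,
                order=row.order,
                host_gene=row.host_gene,
                ordinal=int(row.ordinal),
                sequence=(sequences or {}).get(row.intron_id, ""),
                intron_type=row.intron_type,
                orf_motif=row.orf_motif,
            )
        )
    return records


def write_intron_table(introns: Sequence[IntronRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {c: getattr(i, c) for c in _INTRON_COLUMNS}
            for i in introns
        ],
        columns=_INTRON_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
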