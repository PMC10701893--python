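"""Branch-wise dN/dS estimation by counting.

Ancestral sequences are reconstructed with nucleotide Fitch parsimony, and
each branch's parent/child codon pair is scored with the Nei-Gojobori (1986)
counting method: synonymous/non-synonymous site counting by the
one-third-per-position convention, equal-weight averaging over substitution
pathways (paths through stop codons excluded), and Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p).  Group-level omega is the mean over branches
with sufficient synonymous signal (dS > 0.01, strict).

This is a deliberate counting-based engine: it is self-contained and
testable by parameter recovery, and it will not numerically match
likelihood-based branch models on real data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core_io import GeneticCode

__all__ = [
    "NG86Result",
    "BranchOmega",
    "GroupGeneOmega",
    "ng86_pairwise",
    "fitch_ancestors",
    "fitch_score",
    "branch_omegas",
    "aggregate_omega",
    "omega_variance_report",
    "codon_index",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def codon_index(codon: str) -> int:
    """Encode an ACGT codon as an integer in 0..63 (A=0, C=1, G=2, T=3)."""
    return (
        16 * _BASE_INDEX[codon[0]]
        + 4 * _BASE_INDEX[codon[1]]
        + _BASE_INDEX[codon[2]]
    )


def _index_codon(i: int) -> str:
    return _BASES[(i >> 4) & 3] + _BASES[(i >> 2) & 3] + _BASES[i & 3]


class _NGTables:
    """Precomputed NG86 site counts and pathway-averaged difference counts."""

    def __init__(self, code: GeneticCode) -> None:
        aa = np.empty(64, dtype="<U1")
        for i in range(64):
            aa[i] = code.codon_to_aa[_index_codon(i)]
        self.aa = aa
        self.is_stop = aa == "*"

        syn_sites = np.full(64, np.nan)
        for i in range(64):
            if self.is_stop[i]:
                continue
            syn = 0.0
            for pos in range(3):
                for j in self._neighbours(i, pos):
                    if not self.is_stop[j] and aa[j] == aa[i]:
                        syn += 1.0
            syn_sites[i] = syn / 3.0
        self.syn_sites = syn_sites
        self.nonsyn_sites = 3.0 - syn_sites

        sd = np.full((64, 64), np.nan)
        nd = np.full((64, 64), np.nan)
        for i in range(64):
            if self.is_stop[i]:
                continue
            for j in range(64):
                if self.is_stop[j]:
                    continue
                s, n = self._pathway_average(i, j)
                sd[i, j], nd[i, j] = s, n
        self.sd = sd
        self.nd = nd

    @staticmethod
    def _neighbours(i: int, pos: int) -> list[int]:
        shift = (2 - pos) * 2
        current = (i >> shift) & 3
        return [i ^ ((current ^ b) << shift) for b in range(4) if b != current]

    def _pathway_average(self, i: int, j: int) -> tuple[float, float]:
        diff = [pos for pos in range(3) if ((i >> ((2 - pos) * 2)) & 3)
                != ((j >> ((2 - pos) * 2)) & 3)]
        if not diff:
            return 0.0, 0.0
        totals = []
        for order in itertools.permutations(diff):
            cur = i
            syn = non = 0
            blocked = False
            for pos in order:
                shift = (2 - pos) * 2
                target = (j >> shift) & 3
                nxt = cur & ~(3 << shift) | (target << shift)
                if self.is_stop[nxt]:
                    blocked = True
                    break
                if self.aa[nxt] == self.aa[cur]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            if not blocked:
                totals.append((syn, non))
        if not totals:
            return math.nan, math.nan  # all pathways pass through a stop
        s = sum(t[0] for t in totals) / len(totals)
        n = sum(t[1] for t in totals) / len(totals)
        return s, n


_TABLE_CACHE: dict[int, _NGTables] = {}


def _tables(code: GeneticCode) -> _NGTables:
    key = id(code.codon_to_aa) if code.table_id == 0 else code.table_id
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _NGTables(code)
    return _TABLE_CACHE[key]


@dataclass(frozen=True)
class NG86Result:
    dn: float
    ds: float
    omega: float | None
    n_codons_used: int
    saturated: bool = False

    def __iter__(self):
        return iter((self.dn, self.ds, self.omega))


def _encode_codon_array(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (codon indices, validity mask); codons with non-ACGT are invalid."""
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    bases = lut[raw].reshape(-1, 3)
    valid = (bases < 4).all(axis=1)
    bases = np.where(bases < 4, bases, 0)
    idx = (16 * bases[:, 0] + 4 * bases[:, 1] + bases[:, 2]).astype(np.int64)
    return idx, valid


def _jc_correct(p: float) -> float:
    # beyond the JC ceiling the distance is undefined; report +inf and let
    # callers treat the estimate as saturated
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pairwise(
    codons_a: str, codons_b: str, code: GeneticCode
) -> NG86Result:
    """Nei-Gojobori dN/dS between two in-frame coding sequences.

    Codon pairs containing gaps, N, or stop codons are skipped, as are the
    (rare) pairs whose every substitution pathway crosses a stop.  When the
    proportion of differences reaches the Jukes-Cantor ceiling p >= 3/4 the
    corresponding distance is undefined and the result carries
    ``saturated=True``.
    """
    if len(codons_a) != len(codons_b):
        raise ValueError("sequences must have equal length")
    if len(codons_a) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    t = _tables(code)
    ia, va = _encode_codon_array(codons_a)
    ib, vb = _encode_codon_array(codons_b)
    use = va & vb & ~t.is_stop[ia] & ~t.is_stop[ib]
    sd_pair = t.sd[ia, ib]
    use &= ~np.isnan(sd_pair)
    n_used = int(use.sum())
    if n_used == 0:
        return NG86Result(0.0, 0.0, None, 0)
    S = float(((t.syn_sites[ia] + t.syn_sites[ib]) / 2.0)[use].sum())
    N = 3.0 * n_used - S
    sd = float(sd_pair[use].sum())
    nd = float(t.nd[ia, ib][use].sum())
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ds = _jc_correct(ps)
    dn = _jc_correct(pn)
    saturated = math.isinf(ds) or math.isinf(dn)
    omega = None
    if ds > 0 and not math.isinf(dn):
        omega = dn / ds  # dn/inf -> 0.0 in the synonymous-saturated limit
    return NG86Result(dn=dn, ds=ds, omega=omega,
                      n_codons_used=n_used, saturated=saturated)


# ---------------------------------------------------------------------------
# Fitch parsimony ancestral reconstruction

_FITCH_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK_BASE = {1: "A", 2: "C", 4: "G", 8: "T"}


def _seq_to_masks(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, 15, dtype=np.uint8)  # ambiguity/gap: uninformative
    for b, m in _FITCH_MASK.items():
        lut[ord(b)] = m
    return lut[raw]


def _label_nodes(tree: dendropy.Tree) -> None:
    used = {n.label for n in tree.preorder_node_iter() if n.label}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            while f"node{counter}" in used:
                counter += 1
            node.label = f"node{counter}"
            used.add(node.label)


def _fitch_pass(
    tree: dendropy.Tree, alignment: Mapping[str, str]
) -> tuple[dict[int, np.ndarray], int]:
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment sequences must have equal length")
    masks: dict[int, np.ndarray] = {}
    score = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in alignment:
                raise ValueError(f"tip {label!r} missing from alignment")
            masks[id(node)] = _seq_to_masks(alignment[label])
        else:
            kids = node.child_nodes()
            acc = masks[id(kids[0])]
            for k in kids[1:]:
                inter = acc & masks[id(k)]
                union = acc | masks[id(k)]
                empty = inter == 0
                score += int(empty.sum())
                acc = np.where(empty, union, inter)
            masks[id(node)] = acc
    return masks, score


def _lowest_bit(m: np.ndarray) -> np.ndarray:
    return m & (-m.astype(np.int16)).astype(np.uint8)


def fitch_score(tree: dendropy.Tree, alignment: Mapping[str, str]) -> int:
    """Total parsimony score (minimum implied changes) over all sites."""
    _, score = _fitch_pass(tree, alignment)
    return score


def fitch_ancestors(
    tree: dendropy.Tree, alignment: Mapping[str, str]
) -> dict[str, str]:
    """Per-site nucleotide Fitch reconstruction at internal nodes.

    Top-down resolution takes the parent's state when it lies in the node's
    candidate set and otherwise the alphabetically smallest candidate; the
    root always takes its smallest candidate.  Internal nodes without labels
    are assigned stable ``nodeN`` labels in preorder.  Ambiguous tip symbols
    (N, gaps) are uninformative in the up-pass.
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted")
    _label_nodes(tree)
    masks, _ = _fitch_pass(tree, alignment)
    states: dict[int, np.ndarray] = {}
    out: dict[str, str] = {}
    decode = np.empty(16, dtype="<U1")
    decode[:] = "N"
    for m, b in _MASK_BASE.items():
        decode[m] = b
    for node in tree.preorder_node_iter():
        mask = masks[id(node)]
        parent = node.parent_node
        if parent is None:
            chosen = _lowest_bit(mask)
        else:
            pstate = states[id(parent)]
            in_set = (mask & pstate) != 0
            chosen = np.where(in_set, pstate, _lowest_bit(mask))
        states[id(node)] = chosen
        if not node.is_leaf():
            out[node.label] = "".join(decode[chosen])
    return out


# ---------------------------------------------------------------------------
# Branch-wise omega


@dataclass(frozen=True)
class BranchOmega:
    """dN, dS, and omega along one tree edge.

    ``retained`` marks branches with sufficient synonymous substitutions
    (dS > 0.01, strict) for use in group means.
    """

    branch_id: str
    dn: float
    ds: float
    omega: float | None
    retained: bool


@dataclass(frozen=True)
class GroupGeneOmega:
    group: str
    gene: str
    omega_mean: float | None
    n_branches_used: int


DS_RETENTION_THRESHOLD = 0.01


def branch_omegas(
    tree: dendropy.Tree,
    codon_alignment: Mapping[str, str],
    code: GeneticCode,
) -> list[BranchOmega]:
    """Estimate omega on every branch of a rooted tree.

    Internal sequences come from nucleotide Fitch reconstruction; each
    parent/child pair is scored with :func:`ng86_pairwise`.  Reconstructed
    codons that are stops under ``code`` are skipped for that branch.
    """
    ancestors = fitch_ancestors(tree, codon_alignment)
    seqs: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            seqs[id(node)] = codon_alignment[node.taxon.label]
        else:
            seqs[id(node)] = ancestors[node.label]
    results = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        child_label = node.taxon.label if node.is_leaf() else node.label
        branch_id = f"{parent.label}->{child_label}"
        res = ng86_pairwise(seqs[id(parent)], seqs[id(node)], code)
        retained = (not res.saturated) and res.ds > DS_RETENTION_THRESHOLD
        results.append(
            BranchOmega(
                branch_id=branch_id, dn=res.dn, ds=res.ds,
                omega=res.omega, retained=retained,
            )
        )
    return results


def aggregate_omega(
    branches: Iterable[BranchOmega], group: str = "", gene: str = ""
) -> GroupGeneOmega:
    """Mean omega over retained branches (dS > 0.01)."""
    used = [
        b for b in branches
        if b.retained and b.omega is not None and math.isfinite(b.omega)
    ]
    assert all(b.ds > DS_RETENTION_THRESHOLD for b in used)
    if not used:
        return GroupGeneOmega(group=group, gene=gene,
                              omega_mean=None, n_branches_used=0)
    mean = sum(b.omega for b in used) / len(used)
    return GroupGeneOmega(group=group, gene=gene,
                          omega_mean=mean, n_branches_used=len(used))


def omega_variance_report(
    table: pd.DataFrame,
) -> tuple[float, float]:
    """Variance decomposition of group x gene omega estimates.

    Returns ``(across_groups, across_genes)``: the mean over genes of the
    unbiased variance of omega across groups, and the mean over groups of
    the variance across genes.  A component is NaN when no gene (resp.
    group) has at least two values.
    """
    required = {"group", "gene", "omega"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    clean = table.dropna(subset=["omega"])

    def _mean_var(by: str) -> float:
        variances = [
            float(np.var(sub["omega"], ddof=1))
            for _, sub in clean.groupby(by)
            if len(sub) >= 2
        ]
        return float(np.mean(variances)) if variances else math.nan

    return _mean_var("gene"), _mean_var("group")
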