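import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import balanced_tree, make_tree
from mitomine import selection
from mitomine.core_io import GeneticCode
from mitomine.selection import (
    BranchOmega,
    aggregate_omega,
    branch_omegas,
    fitch_ancestors,
    fitch_score,
    ng86_pairwise,
    omega_variance_report,
)

# ---------------------------------------------------------------------------
# Independent NG86 oracle: naive pathway enumeration, written from scratch.

BASES = "ACGT"


def _oracle_sites(codon, table):
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if table[alt] != "*" and table[alt] == table[codon]:
                syn += 1.0
    return syn / 3.0


def _oracle_path_counts(a, b, table):
    diff = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if table[nxt] == "*":
                ok = False
                break
            if table[nxt] == table[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def _oracle_ng86(seq_a, seq_b, code):
    table = dict(code.codon_to_aa)
    S = sd = nd = 0.0
    n_codons = 0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        if table[ca] == "*" or table[cb] == "*":
            continue
        counts = _oracle_path_counts(ca, cb, table)
        if counts is None:
            continue
        n_codons += 1
        S += (_oracle_sites(ca, table) + _oracle_sites(cb, table)) / 2.0
        sd += counts[0]
        nd += counts[1]
    N = 3.0 * n_codons - S

    def jc(p):
        return math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    ps = sd / S if S else 0.0
    pn = nd / N if N else 0.0
    return jc(pn), jc(ps)


class TestNG86:
    def test_identical_sequences(self, code4):
        res = ng86_pairwise("ATGAAA", "ATGAAA", code4)
        assert (res.dn, res.ds, res.omega) == (0.0, 0.0, None)

    def test_single_synonymous_difference(self, code4):
        # Phe -> Phe third-position change: purely synonymous
        res = ng86_pairwise("TTT", "TTC", code4)
        assert res.dn == 0.0
        assert res.ds > 0
        assert res.omega == 0.0

    def test_matches_pathway_enumeration_oracle(self, code4, code3):
        rng = np.random.default_rng(11)
        sense4 = [c for c in map("".join, itertools.product(BASES, repeat=3))
                  if code4.codon_to_aa[c] != "*"]
        for code in (code4, code3):
            for _ in range(100):
                n = int(rng.integers(2, 30))
                a = "".join(rng.choice(sense4, size=n))
                b_codons = []
                for ca in (a[i : i + 3] for i in range(0, len(a), 3)):
                    cb = list(ca)
                    for pos in rng.choice(3, size=int(rng.integers(0, 3)),
                                          replace=False):
                        cb[pos] = str(rng.choice(list(BASES)))
                    b_codons.append("".join(cb))
                b = "".join(b_codons)
                res = ng86_pairwise(a, b, code)
                dn_o, ds_o = _oracle_ng86(a, b, code)
                assert res.dn == pytest.approx(dn_o, abs=1e-9)
                assert res.ds == pytest.approx(ds_o, abs=1e-9)

    def test_symmetry(self, code4):
        rng = np.random.default_rng(3)
        sense = [c for c in map("".join, itertools.product(BASES, repeat=3))
                 if code4.codon_to_aa[c] != "*"]
        for _ in range(25):
            a = "".join(rng.choice(sense, size=20))
            b = "".join(rng.choice(sense, size=20))
            r1 = ng86_pairwise(a, b, code4)
            r2 = ng86_pairwise(b, a, code4)
            assert r1.dn == pytest.approx(r2.dn, abs=1e-12)
            assert r1.ds == pytest.approx(r2.ds, abs=1e-12)

    def test_gap_and_n_codons_skipped(self, code4):
        res = ng86_pairwise("TTT---AAA", "TTCNNNAAA", code4)
        assert res.n_codons_used == 2

    def test_length_mismatch_rejected(self, code4):
        with pytest.raises(ValueError):
            ng86_pairwise("ATG", "ATGATG", code4)


# ---------------------------------------------------------------------------
# Fitch: exhaustive assignment oracle on small trees


def _oracle_fitch_min(tree, alignment):
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    tips = {n.taxon.label: n for n in tree.leaf_node_iter()}
    length = len(next(iter(alignment.values())))
    total = 0
    for site in range(length):
        best = None
        for assignment in itertools.product(BASES, repeat=len(internals)):
            state = {id(n): a for n, a in zip(internals, assignment)}
            for label, node in tips.items():
                state[id(node)] = alignment[label][site]
            changes = 0
            for node in tree.preorder_node_iter():
                if node.parent_node is not None:
                    changes += state[id(node)] != state[id(node.parent_node)]
            best = changes if best is None else min(best, changes)
        total += best
    return total


def _changes_implied(tree, alignment, code=None):
    anc = fitch_ancestors(tree, alignment)
    seq = {}
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.is_leaf() else node.label
        seq[id(node)] = alignment.get(label, anc.get(label))
    changes = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        a, b = seq[id(node)], seq[id(node.parent_node)]
        changes += sum(x != y for x, y in zip(a, b))
    return changes


class TestFitch:
    def test_constant_site_constant_ancestors(self):
        tree = make_tree("((a:1,b:1):1,(c:1,d:1):1);")
        anc = fitch_ancestors(tree, {t: "AAA" for t in "abcd"})
        assert set(anc.values()) == {"AAA"}

    def test_two_tip_tie_break_is_smallest_base(self):
        tree = make_tree("(a:1,b:1);")
        anc = fitch_ancestors(tree, {"a": "T", "b": "G"})
        # candidates {G, T}: root takes the alphabetically smallest
        assert list(anc.values()) == ["G"]

    def test_matches_exhaustive_minimum_on_small_trees(self):
        rng = np.random.default_rng(5)
        newicks = [
            "((a:1,b:1):1,(c:1,(d:1,e:1):1):1);",
            "(((a:1,b:1):1,c:1):1,(d:1,(e:1,f:1):1):1);",
            "((a:1,(b:1,c:1):1):1,d:1);",
        ]
        for nwk in newicks:
            tree = make_tree(nwk)
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            for _ in range(8):
                aln = {
                    t: "".join(rng.choice(list(BASES), size=4)) for t in tips
                }
                expected = _oracle_fitch_min(tree, aln)
                assert fitch_score(tree, aln) == expected
                # the resolved reconstruction achieves the minimum
                assert _changes_implied(tree, aln) == expected

    def test_missing_tip_is_an_error(self):
        tree = make_tree("(a:1,b:1);")
        with pytest.raises(ValueError, match="missing"):
            fitch_ancestors(tree, {"a": "A"})


# ---------------------------------------------------------------------------
# Branch omegas and aggregation


class TestAggregate:
    def test_ds_filter_mean(self):
        branches = [
            BranchOmega("b1", dn=0.05, ds=0.5, omega=0.1, retained=True),
            BranchOmega("b2", dn=0.004, ds=0.02, omega=0.2, retained=True),
            BranchOmega("b3", dn=0.0015, ds=0.005, omega=0.3, retained=False),
        ]
        agg = aggregate_omega(branches)
        assert agg.omega_mean == pytest.approx(0.15)
        assert agg.n_branches_used == 2

    def test_no_retained_branches_reported_explicitly(self):
        branches = [BranchOmega("b", 0.0, 0.001, 0.0, retained=False)]
        agg = aggregate_omega(branches)
        assert agg.omega_mean is None and agg.n_branches_used == 0

    def test_branch_at_exact_threshold_excluded(self):
        branches = [
            BranchOmega("b", 0.002, 0.01, 0.2,
                        retained=0.01 > selection.DS_RETENTION_THRESHOLD)
        ]
        assert aggregate_omega(branches).omega_mean is None

    def test_branch_omegas_on_simulated_alignment(self, code4):
        from mitomine.synthetic_data import simulate_codon_evolution

        tree = balanced_tree(8, 0.2)
        aln = simulate_codon_evolution(
            tree, omega=0.1, n_codons=2000, code=code4, seed=2
        )
        branches = branch_omegas(tree, aln.sequences, code4)
        assert len(branches) == 14  # 2n-2 edges on a rooted binary tree
        agg = aggregate_omega(branches)
        assert agg.omega_mean == pytest.approx(0.1, abs=0.07)


class TestVarianceReport:
    def test_constant_table(self):
        table = pd.DataFrame(
            [(g, gene, 0.05) for g in "AB" for gene in ("COX1", "COB")],
            columns=["group", "gene", "omega"],
        )
        assert omega_variance_report(table) == (0.0, 0.0)

    def test_hand_computed(self):
        table = pd.DataFrame(
            [
                ("G1", "COX1", 0.1), ("G2", "COX1", 0.3),
                ("G1", "COB", 0.2), ("G2", "COB", 0.2),
            ],
            columns=["group", "gene", "omega"],
        )
        across_groups, across_genes = omega_variance_report(table)
        assert across_groups == pytest.approx((0.02 + 0.0) / 2)
        assert across_genes == pytest.approx((0.005 + 0.005) / 2)

    def test_single_group_gives_second_scalar_only(self):
        table = pd.DataFrame(
            [("G1", "COX1", 0.1), ("G1", "COB", 0.3)],
            columns=["group", "gene", "omega"],
        )
        across_groups, across_genes = omega_variance_report(table)
        assert math.isnan(across_groups)
        assert across_genes == pytest.approx(0.02)
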