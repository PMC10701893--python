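"""Alignment concatenation, occupancy filtering, codon threading, and
tree comparison."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .core_io import GeneticCode, translate

__all__ = [
    "MultipleAlignment",
    "concatenate",
    "occupancy_filter",
    "thread_codons",
    "normalized_rf",
]

GAP = "-"


@dataclass(frozen=True)
class MultipleAlignment:
    """An aligned set of sequences over a common column space."""

    sequences: Mapping[str, str]
    alphabet: str = "dna"  # "dna" | "protein"
    partitions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must all have equal length")
        if self.alphabet not in {"dna", "protein"}:
            raise ValueError("alphabet must be 'dna' or 'protein'")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)


def concatenate(alignments: Sequence[MultipleAlignment]) -> MultipleAlignment:
    """Concatenate partitions over the union of taxa.

    Taxa missing from a partition are filled with gaps; partition boundaries
    (name, start, end columns, 0-based half-open) are recorded.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    alphabets = {a.alphabet for a in alignments}
    if len(alphabets) > 1:
        raise ValueError("cannot concatenate mixed alphabets")
    taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    bounds: list[tuple[str, int, int]] = []
    offset = 0
    for k, aln in enumerate(alignments):
        n = aln.n_columns
        for t in taxa:
            parts[t].append(aln.sequences.get(t, GAP * n))
        bounds.append((f"part{k}", offset, offset + n))
        offset += n
    return MultipleAlignment(
        sequences={t: "".join(parts[t]) for t in taxa},
        alphabet=alignments[0].alphabet,
        partitions=tuple(bounds),
    )


def occupancy_filter(
    aln: MultipleAlignment, min_nongap: float = 0.95
) -> MultipleAlignment:
    """Keep columns whose non-gap fraction is at least ``min_nongap``.

    The boundary is inclusive: a column at exactly the threshold is kept.
    """
    if not (0.0 < min_nongap <= 1.0):
        raise ValueError("min_nongap must lie in (0, 1]")
    if not aln.sequences:
        return aln
    matrix = np.array(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in aln.sequences.values()]
    )
    nongap = (matrix != ord(GAP)).mean(axis=0)
    keep = np.nonzero(nongap >= min_nongap)[0]
    return MultipleAlignment(
        sequences={
            t: "".join(s[i] for i in keep) for t, s in aln.sequences.items()
        },
        alphabet=aln.alphabet,
    )


def thread_codons(
    protein_aln: MultipleAlignment,
    cds: Mapping[str, str],
    code: GeneticCode,
) -> MultipleAlignment:
    """Back-thread unaligned CDS onto a protein alignment.

    Each amino-acid column becomes a codon column; protein gaps become
    ``---``.  Every CDS must translate exactly to its ungapped protein
    sequence under ``code``.
    """
    if protein_aln.alphabet != "protein":
        raise ValueError("protein alignment required")
    out: dict[str, str] = {}
    for taxon, prot in protein_aln.sequences.items():
        if taxon not in cds:
            raise ValueError(f"no CDS supplied for taxon {taxon!r}")
        dna = cds[taxon].upper()
        translated = translate(dna, code)
        # trailing stop on the CDS is tolerated
        if translated.endswith("*"):
            translated = translated[:-1]
            dna = dna[: 3 * len(translated)]
        ungapped = prot.replace(GAP, "")
        if translated != ungapped:
            mismatch = next(
                (i for i, (a, b) in enumerate(zip(translated, ungapped)) if a != b),
                min(len(translated), len(ungapped)),
            )
            raise ValueError(
                f"CDS of {taxon!r} does not translate to its protein row "
                f"(first mismatch at residue {mismatch})"
            )
        codons = []
        k = 0
        for aa in prot:
            if aa == GAP:
                codons.append("---")
            else:
                codons.append(dna[3 * k : 3 * k + 3])
                k += 1
        out[taxon] = "".join(codons)
    return MultipleAlignment(sequences=out, alphabet="dna")


def normalized_rf(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> float:
    """Normalized Robinson-Foulds distance on the shared taxon set.

    Trees are pruned to their common taxa and compared unrooted; the
    bipartition symmetric difference is divided by its maximum 2(n-3).
    """
    taxa_a = {leaf.taxon.label for leaf in tree_a.leaf_node_iter()}
    taxa_b = {leaf.taxon.label for leaf in tree_b.leaf_node_iter()}
    shared = taxa_a & taxa_b
    if len(shared) < 4:
        raise ValueError("need at least 4 shared taxa")
    namespace = dendropy.TaxonNamespace(sorted(shared))

    def _prepare(tree: dendropy.Tree) -> dendropy.Tree:
        clone = dendropy.Tree.get(
            data=tree.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=namespace,
            rooting="force-unrooted",
            preserve_underscores=True,
        )
        clone.retain_taxa_with_labels(sorted(shared))
        clone.encode_bipartitions()
        return clone

    a = _prepare(tree_a)
    b = _prepare(tree_b)
    n = len(shared)
    rf = treecompare.symmetric_difference(a, b)
    return rf / (2.0 * (n - 3))
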