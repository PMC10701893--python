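"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its parameters and a seed, and each
emits a machine-readable truth object so downstream calls can be checked
exactly.  The generators emulate the *structure* of real inputs — AT-rich
high-coverage mitochondrial contigs among nuclear contigs, planted NUMT
fragments, codon alignments evolved under a known omega, intron families
with planted horizontal transfers — not realistic error or indel processes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .core_io import (
    CANONICAL_GENES,
    COMPLEX_I_GENES,
    CORE_GENES,
    ContigRecord,
    GeneAnnotation,
    GeneticCode,
    HitRecord,
    write_fasta,
    write_gff_annotations,
    write_hit_table,
)
from .genome_stats import brownian_covariance
from .intron_hgt import IntronRecord
from .phylo import MultipleAlignment
from .selection import codon_index

__all__ = [
    "PlantedAssemblyTruth",
    "SyntheticAssembly",
    "PlantedIntronTruth",
    "toy_reference_cds",
    "make_assembly",
    "simulate_codon_evolution",
    "make_intron_set",
    "make_presence_matrix",
    "random_loss_edges",
    "make_trait_pair",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


# ---------------------------------------------------------------------------
# Toy reference gene set

# Deterministic CDS lengths (bp, incl. stop) roughly matching the real genes.
_TOY_GENE_LENGTHS = {
    "COX1": 1536, "COX2": 750, "COX3": 810, "COB": 1155,
    "ATP6": 780, "ATP8": 147, "ATP9": 225,
    "NAD1": 954, "NAD2": 1482, "NAD3": 360, "NAD4": 1485,
    "NAD4L": 297, "NAD5": 1998, "NAD6": 540, "RPS3": 1200,
}
_TOY_SEED = 20230353  # fixed: the toy reference set is a constant of the package

# Codons avoided inside toy CDS: stops under tables 1/3/4 (TAA, TAG, TGA).
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


def toy_reference_cds() -> dict[str, str]:
    """The bundled toy reference CDS set (deterministic).

    One stop-free, ATG-initiated CDS per canonical gene, AT-biased codon
    choice, terminated with TAA.  Used as the planted gene content of
    synthetic assemblies and as the reference query set for hit tables.
    """
    rng = np.random.default_rng(_TOY_SEED)
    weights = np.array(
        [math.exp(-1.2 * (c.count("G") + c.count("C"))) for c in _SAFE_CODONS]
    )
    weights /= weights.sum()
    out = {}
    for gene, length in _TOY_GENE_LENGTHS.items():
        n_codons = length // 3 - 2
        body = "".join(rng.choice(_SAFE_CODONS, size=n_codons, p=weights))
        out[gene] = "ATG" + body + "TAA"
    return out


# ---------------------------------------------------------------------------
# Synthetic assemblies


@dataclass(frozen=True)
class PlantedAssemblyTruth:
    mito_contig_ids: frozenset[str]
    numt_contig_ids: frozenset[str]
    nuclear_contig_ids: frozenset[str]
    mito_coverage_multiplier: float
    junction_spanning_read_count: Mapping[str, int]

    def __post_init__(self) -> None:
        sets = [self.mito_contig_ids, self.numt_contig_ids,
                self.nuclear_contig_ids]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("contig id classes must be disjoint")
        if self.mito_coverage_multiplier <= 1:
            raise ValueError("coverage multiplier must exceed 1")

    def to_json(self) -> str:
        return json.dumps(
            dict(
                mito_contig_ids=sorted(self.mito_contig_ids),
                numt_contig_ids=sorted(self.numt_contig_ids),
                nuclear_contig_ids=sorted(self.nuclear_contig_ids),
                mito_coverage_multiplier=self.mito_coverage_multiplier,
                junction_spanning_read_count=dict(
                    self.junction_spanning_read_count
                ),
            ),
            indent=1,
        )


@dataclass(frozen=True)
class SyntheticAssembly:
    contigs: tuple[ContigRecord, ...]
    annotations: tuple[GeneAnnotation, ...]
    cds_hits: tuple[HitRecord, ...]
    genome_hits: tuple[HitRecord, ...]
    reads: tuple[str, ...]
    reference_cds: Mapping[str, str]
    truth: PlantedAssemblyTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            {c.contig_id: c.sequence for c in self.contigs},
            outdir / "assembly.fasta",
        )
        with open(outdir / "coverage.tsv", "w") as fh:
            fh.write("contig_id\tcoverage\n")
            for c in self.contigs:
                fh.write(f"{c.contig_id}\t{c.coverage}\n")
        write_gff_annotations(self.annotations, outdir / "annotations.gff3")
        write_hit_table(self.cds_hits, outdir / "cds_hits.tsv")
        write_hit_table(self.genome_hits, outdir / "genome_hits.tsv")
        write_fasta(
            {f"read{i}": r for i, r in enumerate(self.reads)},
            outdir / "reads.fasta",
        )
        write_fasta(dict(self.reference_cds), outdir / "reference_cds.fasta")
        (outdir / "truth.json").write_text(self.truth.to_json())


def _perfect_hit(query: str, subject: str, length: int, qcov: float,
                 scov: float) -> HitRecord:
    return HitRecord(
        query_id=query, subject_id=subject, pct_identity=100.0,
        aln_length=length, mismatches=0, gap_opens=0,
        qstart=1, qend=length, sstart=1, send=length,
        evalue=1e-180, bit_score=2.0 * length,
        query_cov=min(qcov, 1.0), subject_cov=min(scov, 1.0),
    )


def make_assembly(
    n_nuclear: int = 8,
    mito_size_bp: int = 40_000,
    n_numts: int = 2,
    gc_mito: float = 0.20,
    coverage_multiplier: float = 20.0,
    seed: int = 0,
    include_complex_i: bool = True,
    include_rps3: bool = True,
    gc_nuclear: float = 0.40,
    nuclear_size_bp: int = 30_000,
    numt_size_bp: int = 25_000,
    read_length: int = 150,
    n_junction_reads: int = 10,
    n_background_reads: int = 40,
) -> SyntheticAssembly:
    """Generate an assembly with one circular mito contig, nuclear contigs,
    and planted NUMT fragments.

    The mito contig carries the toy reference genes (7 core genes, plus
    Complex I genes and RPS3 unless disabled) evenly spaced on an AT-rich
    backbone; its coverage is ``coverage_multiplier`` times the nuclear
    mean.  Each NUMT contig embeds a mitochondrial fragment carrying
    exactly one full gene, so NUMTs always fall below one gene per 20 kb.
    Error-free fixed-length reads are emitted for the mito contig,
    including ``n_junction_reads`` spanning the circular junction.
    """
    if mito_size_bp < 10_000:
        raise ValueError("mito_size_bp must be at least 10,000")
    if not (0.0 < gc_mito < 1.0):
        raise ValueError("gc_mito must lie in (0, 1)")
    if coverage_multiplier <= 1:
        raise ValueError("coverage_multiplier must exceed 1")
    rng = np.random.default_rng(seed)
    reference = toy_reference_cds()
    genes = list(CORE_GENES)
    if include_complex_i:
        genes += list(COMPLEX_I_GENES)
    if include_rps3:
        genes.append("RPS3")
    total_gene_bp = sum(len(reference[g]) for g in genes)
    if total_gene_bp + 60 * len(genes) > mito_size_bp:
        raise ValueError(
            f"mito_size_bp={mito_size_bp} too small for {len(genes)} planted "
            f"genes ({total_gene_bp} bp of CDS)"
        )

    # --- mito contig
    mito_id = "mito_1"
    backbone = list(_random_seq(rng, mito_size_bp, gc_mito))
    spacing = (mito_size_bp - total_gene_bp) // (len(genes) + 1)
    annotations: list[GeneAnnotation] = []
    pos = spacing
    for gene in genes:
        cds = reference[gene]
        backbone[pos : pos + len(cds)] = list(cds)
        annotations.append(
            GeneAnnotation(
                contig_id=mito_id, gene=gene, strand="+",
                start=pos, end=pos + len(cds),
            )
        )
        pos += len(cds) + spacing
    mito_seq = "".join(backbone)

    # --- nuclear contigs
    nuclear_ids = []
    contig_seqs: dict[str, str] = {mito_id: mito_seq}
    for i in range(n_nuclear):
        cid = f"nuc_{i + 1}"
        nuclear_ids.append(cid)
        size = int(rng.integers(nuclear_size_bp // 2, nuclear_size_bp + 1))
        contig_seqs[cid] = _random_seq(rng, size, gc_nuclear)

    # --- NUMT contigs: one full gene + gene-free mito backbone filler
    numt_ids = []
    spacer = mito_seq[: spacing]  # gene-free by construction
    for i in range(n_numts):
        cid = f"numt_{i + 1}"
        numt_ids.append(cid)
        gene = genes[i % len(genes)]
        cds = reference[gene]
        frag_target = int(0.30 * numt_size_bp)
        filler_n = max(frag_target - len(cds), 0)
        filler = (spacer * (filler_n // len(spacer) + 1))[:filler_n]
        fragment = cds + filler
        left = (numt_size_bp - len(fragment)) // 2
        right = numt_size_bp - len(fragment) - left
        seq = (
            _random_seq(rng, left, gc_nuclear)
            + fragment
            + _random_seq(rng, right, gc_nuclear)
        )
        contig_seqs[cid] = seq
        annotations.append(
            GeneAnnotation(
                contig_id=cid, gene=gene, strand="+",
                start=left, end=left + len(cds),
            )
        )

    # --- coverages
    nuclear_cov = {
        cid: max(1.0, float(rng.normal(30.0, 2.0)))
        for cid in nuclear_ids + numt_ids
    }
    nuclear_mean = (
        float(np.mean(list(nuclear_cov.values()))) if nuclear_cov else 30.0
    )
    coverages = dict(nuclear_cov)
    coverages[mito_id] = coverage_multiplier * nuclear_mean

    contigs = tuple(
        ContigRecord(
            contig_id=cid, sequence=contig_seqs[cid],
            coverage=coverages[cid], assembly_id=f"synthetic_seed{seed}",
        )
        for cid in [mito_id] + numt_ids + nuclear_ids
    )

    # --- hit tables (emulating the two homology searches)
    cds_hits = []
    for ann in annotations:
        contig_len = len(contig_seqs[ann.contig_id])
        length = ann.end - ann.start
        cds_hits.append(
            _perfect_hit(
                query=f"ref_{ann.gene}", subject=ann.contig_id,
                length=length, qcov=1.0, scov=length / contig_len,
            )
        )
    genome_hits = [
        _perfect_hit(
            query=mito_id, subject="ref_mtdna",
            length=mito_size_bp, qcov=1.0, scov=1.0,
        )
    ]
    for cid in numt_ids:
        frag_len = int(0.30 * numt_size_bp)
        genome_hits.append(
            _perfect_hit(
                query=cid, subject="ref_mtdna", length=frag_len,
                qcov=frag_len / len(contig_seqs[cid]), scov=frag_len / mito_size_bp,
            )
        )

    # --- reads (error-free substrings of the mito contig)
    reads = []
    n_junction = 0
    for _ in range(n_junction_reads):
        k = int(rng.integers(1, read_length))
        reads.append(mito_seq[-(read_length - k):] + mito_seq[:k])
        n_junction += 1
    for _ in range(n_background_reads):
        start = int(rng.integers(0, mito_size_bp - read_length))
        reads.append(mito_seq[start : start + read_length])

    truth = PlantedAssemblyTruth(
        mito_contig_ids=frozenset({mito_id}),
        numt_contig_ids=frozenset(numt_ids),
        nuclear_contig_ids=frozenset(nuclear_ids),
        mito_coverage_multiplier=coverage_multiplier,
        junction_spanning_read_count={mito_id: n_junction},
    )
    return SyntheticAssembly(
        contigs=contigs,
        annotations=tuple(annotations),
        cds_hits=tuple(cds_hits),
        genome_hits=tuple(genome_hits),
        reads=tuple(reads),
        reference_cds=reference,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Codon-model simulation


def _transition(i: int, j: int) -> bool:
    return {i, j} in ({0, 2}, {1, 3})  # A<->G, C<->T


def _codon_rate_matrix(
    code: GeneticCode, omega: float, kappa: float
) -> tuple[np.ndarray, list[int]]:
    """GY-style rate matrix over sense codons, equal codon frequencies,
    scaled to one expected substitution per codon per unit branch length."""
    sense = [i for i in range(64) if not _is_stop_index(code, i)]
    idx = {c: k for k, c in enumerate(sense)}
    n = len(sense)
    Q = np.zeros((n, n))
    for a_pos, ci in enumerate(sense):
        for pos in range(3):
            shift = (2 - pos) * 2
            cur = (ci >> shift) & 3
            for b in range(4):
                if b == cur:
                    continue
                cj = ci & ~(3 << shift) | (b << shift)
                if cj not in idx:
                    continue  # change to a stop codon is forbidden
                rate = kappa if _transition(cur, b) else 1.0
                if _aa(code, ci) != _aa(code, cj):
                    rate *= omega
                Q[a_pos, idx[cj]] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.mean(np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / mean_rate, sense


def _aa(code: GeneticCode, i: int) -> str:
    from .selection import _index_codon

    return code.codon_to_aa[_index_codon(i)]


def _is_stop_index(code: GeneticCode, i: int) -> bool:
    return _aa(code, i) == "*"


def simulate_codon_evolution(
    tree: dendropy.Tree,
    omega: float,
    kappa: float = 1.0,
    n_codons: int = 1000,
    code: GeneticCode | None = None,
    seed: int = 0,
) -> MultipleAlignment:
    """Evolve a codon alignment on a tree under a GY-style model.

    Branch lengths are in expected substitutions per codon.  Substitution
    rates are proportional to kappa for transitions and multiplied by omega
    for non-synonymous changes; changes into stop codons have rate zero and
    codon frequencies are equal.  The root sequence is uniform over sense
    codons, so no simulated sequence contains an internal stop.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if code is None:
        code = GeneticCode.from_ncbi(4)
    edges = [e.length or 0.0 for e in tree.preorder_edge_iter()]
    if sum(edges) <= 0:
        raise ValueError("tree has zero total branch length")
    rng = np.random.default_rng(seed)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if n_codons == 0:
        return MultipleAlignment(sequences={t: "" for t in taxa}, alphabet="dna")
    Q, sense = _codon_rate_matrix(code, omega, kappa)
    n_states = len(sense)
    pcache: dict[float, np.ndarray] = {}

    def _pmatrix(t: float) -> np.ndarray:
        if t not in pcache:
            P = expm(Q * t)
            P = np.clip(P, 0.0, None)
            pcache[t] = np.cumsum(P / P.sum(axis=1, keepdims=True), axis=1)
        return pcache[t]

    states: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            states[id(node)] = rng.integers(0, n_states, size=n_codons)
        else:
            t = node.edge.length or 0.0
            parent_states = states[id(parent)]
            if t == 0:
                states[id(node)] = parent_states.copy()
            else:
                cum = _pmatrix(t)[parent_states]  # (n_codons, n_states)
                u = rng.random((n_codons, 1))
                states[id(node)] = (u > cum).sum(axis=1)

    from .selection import _index_codon

    codon_strings = np.array([_index_codon(i) for i in sense])
    sequences = {}
    for node in tree.leaf_node_iter():
        seq = "".join(codon_strings[states[id(node)]])
        sequences[node.taxon.label] = seq
    return MultipleAlignment(sequences=sequences, alphabet="dna")


# ---------------------------------------------------------------------------
# Intron sets with planted transfers


@dataclass(frozen=True)
class PlantedIntronTruth:
    family_id: Mapping[str, str]
    planted_hgt_pairs: tuple[tuple[str, str, str], ...]
    expected_category: Mapping[str, str]

    def to_json(self) -> str:
        return json.dumps(
            dict(
                family_id=dict(self.family_id),
                planted_hgt_pairs=[list(p) for p in self.planted_hgt_pairs],
                expected_category=dict(self.expected_category),
            ),
            indent=1,
        )


_HGT_SCOPES = ("within_group", "between_group", "between_order")


def _mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < p
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in np.nonzero(hit)[0]:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def make_intron_set(
    n_groups: int = 2,
    species_per_group: int = 3,
    introns_per_species: int = 2,
    hgt_events: Sequence[str | tuple] = (),
    divergence: float = 0.02,
    intron_length: int = 200,
    groups_per_order: int = 2,
    seed: int = 0,
) -> tuple[list[IntronRecord], PlantedIntronTruth]:
    """Generate intron records with known family structure and planted HGTs.

    Within each group, every species' first intron descends from a common
    group-ancestral sequence (a vertically inherited family); remaining
    introns are independent random sequences (unique).  Each HGT event
    copies the donor family ancestor into a recipient species chosen by
    scope: ``within_group``, ``between_group`` (same order), or
    ``between_order``.  Each copy mutates each site with probability
    ``divergence``.

    Events may be scope strings or ``(scope, donor_group, recipient_group)``
    tuples; naming an unknown group is an error.  Expected categories are
    derived from family membership (sharing requires a different species).
    """
    if not (0.0 <= divergence <= 0.5):
        raise ValueError("divergence must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    groups = [f"G{i + 1}" for i in range(n_groups)]
    order_of = {
        g: f"O{i // groups_per_order + 1}" for i, g in enumerate(groups)
    }
    species_of = {
        g: [f"{g}_sp{j + 1}" for j in range(species_per_group)] for g in groups
    }
    group_of_species = {
        sp: g for g, sps in species_of.items() for sp in sps
    }

    records: list[IntronRecord] = []
    family_id: dict[str, str] = {}
    ancestors: dict[str, str] = {}
    next_ordinal: dict[str, int] = {}

    def _add(species: str, seq: str, family: str, host: str,
             itype: str, motif: str) -> str:
        ordinal = next_ordinal.get(species, 0) + 1
        next_ordinal[species] = ordinal
        iid = f"{species}.{host}.i{ordinal}"
        g = group_of_species[species]
        records.append(
            IntronRecord(
                intron_id=iid, species=species, group=g,
                order=order_of[g], host_gene=host, ordinal=ordinal,
                sequence=seq, intron_type=itype, orf_motif=motif,
            )
        )
        family_id[iid] = family
        return iid

    # vertically inherited family per group (first intron of each species)
    for g in groups:
        ancestor = "".join(rng.choice(list("ACGT"), size=intron_length))
        ancestors[g] = ancestor
        for sp in species_of[g]:
            _add(sp, _mutate(rng, ancestor, divergence), f"fam_{g}",
                 "COX1", "I", "LAGLIDADG")
    # unique introns
    for g in groups:
        for sp in species_of[g]:
            for _ in range(introns_per_species - 1):
                seq = "".join(rng.choice(list("ACGT"), size=intron_length))
                iid = _add(sp, seq, "", "COB", "II", "none")
                family_id[iid] = f"singleton_{iid}"

    # planted transfers
    planted: list[tuple[str, str, str]] = []
    for event in hgt_events:
        if isinstance(event, str):
            scope, donor_g, recip_g = event, None, None
        else:
            scope = event[0]
            donor_g = event[1] if len(event) > 1 else None
            recip_g = event[2] if len(event) > 2 else None
        if scope not in _HGT_SCOPES:
            raise ValueError(f"unknown HGT scope {scope!r}")
        for name in (donor_g, recip_g):
            if name is not None and name not in order_of:
                raise ValueError(f"HGT event names unknown group {name!r}")
        donor_g = donor_g or groups[0]
        if recip_g is None:
            if scope == "within_group":
                recip_g = donor_g
            elif scope == "between_group":
                candidates = [
                    g for g in groups
                    if g != donor_g and order_of[g] == order_of[donor_g]
                ]
                if not candidates:
                    raise ValueError("no second group in the donor's order")
                recip_g = candidates[0]
            else:
                candidates = [
                    g for g in groups if order_of[g] != order_of[donor_g]
                ]
                if not candidates:
                    raise ValueError("no group outside the donor's order")
                recip_g = candidates[0]
        donor_sp = species_of[donor_g][0]
        recip_choices = [s for s in species_of[recip_g] if s != donor_sp]
        if not recip_choices:
            raise ValueError("HGT event requires two distinct species")
        recip_sp = recip_choices[-1]
        seq = _mutate(rng, ancestors[donor_g], divergence / 2.0)
        donor_iid = f"{donor_sp}.COX1.i1"
        recip_iid = _add(recip_sp, seq, f"fam_{donor_g}",
                         "COX1", "I", "LAGLIDADG")
        planted.append((donor_iid, recip_iid, scope))

    # expected categories from family composition
    members: dict[str, list[IntronRecord]] = {}
    by_id = {r.intron_id: r for r in records}
    for iid, fam in family_id.items():
        members.setdefault(fam, []).append(by_id[iid])
    expected: dict[str, str] = {}
    for rec in records:
        fam = family_id[rec.intron_id]
        partners = [
            m for m in members[fam]
            if m.species != rec.species
        ]
        if not partners:
            expected[rec.intron_id] = "unique"
        else:
            same = [p for p in partners if p.group == rec.group]
            if len(same) == len(partners):
                expected[rec.intron_id] = "within_group"
            elif not same:
                expected[rec.intron_id] = "between_only"
            else:
                expected[rec.intron_id] = "within_and_between"

    truth = PlantedIntronTruth(
        family_id=family_id,
        planted_hgt_pairs=tuple(planted),
        expected_category=expected,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Presence matrices and trait pairs


def _clades(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset({node.taxon.label})
        else:
            below[id(node)] = frozenset().union(
                *(below[id(k)] for k in node.child_nodes())
            )
    return below


def make_presence_matrix(
    tree: dendropy.Tree,
    planted_loss_edges: Sequence[frozenset[str]],
    trait: str = "complex_i",
    seed: int = 0,
) -> dict[str, bool]:
    """Tip presence vector with losses planted on the given edges.

    Edges are identified by their clade tip sets; they must be actual
    clades and non-nested (nested losses would make the Dollo ground truth
    ambiguous).  Tips below any planted edge are absent; all others present.
    """
    clades = set(_clades(tree).values())
    losses = [frozenset(e) for e in planted_loss_edges]
    for e in losses:
        if e not in clades:
            raise ValueError(f"planted edge {sorted(e)} is not a clade")
    for a in losses:
        for b in losses:
            if a is not b and a <= b:
                raise ValueError("planted loss edges must be non-nested")
    absent = frozenset().union(*losses) if losses else frozenset()
    return {
        leaf.taxon.label: leaf.taxon.label not in absent
        for leaf in tree.leaf_node_iter()
    }


def random_loss_edges(
    tree: dendropy.Tree, n_losses: int, seed: int = 0
) -> list[frozenset[str]]:
    """Pick random planted loss edges that are mutually exclusive and
    remain the unique Dollo minimum (no parent clade becomes fully absent)."""
    rng = np.random.default_rng(seed)
    below = _clades(tree)
    all_tips = below[id(tree.seed_node)]
    candidates = [
        below[id(node)]
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]
    parents = [
        below[id(node.parent_node)]
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]
    order = rng.permutation(len(candidates))
    chosen: list[frozenset[str]] = []
    union: frozenset[str] = frozenset()
    for k in order:
        clade = candidates[k]
        if clade & union:
            continue
        tentative = union | clade
        if tentative == all_tips:
            continue
        # accepting must not complete any chosen clade's parent
        ok = True
        for c, p in zip(candidates, parents):
            if (c in chosen or c == clade) and p <= tentative:
                ok = False
                break
        if not ok:
            continue
        chosen.append(clade)
        union = tentative
        if len(chosen) == n_losses:
            break
    return chosen


def random_binary_tree(
    n_tips: int,
    seed: int = 0,
    min_bl: float = 0.1,
    max_bl: float = 1.0,
    prefix: str = "t",
) -> dendropy.Tree:
    """A random rooted binary tree with branch lengths bounded away from 0.

    Built by sequential random coalescence of the tip lineages; the bounded
    branch lengths keep the Brownian covariance well conditioned, which the
    GLS machinery (and any honest use of it) requires.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"{prefix}{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        bl_a, bl_b = rng.uniform(min_bl, max_bl, size=2)
        merged = f"({a}:{bl_a:.6f},{b}:{bl_b:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return dendropy.Tree.get(
        data=nodes[0] + ";", schema="newick",
        rooting="force-rooted", preserve_underscores=True,
    )


def make_trait_pair(
    tree: dendropy.Tree,
    rho: float,
    lam: float = 1.0,
    seed: int = 0,
    sigma: float = 1.0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Two tip traits from a bivariate Brownian process on the tree.

    The phylogenetic covariance has off-diagonals scaled by ``lam``
    (Pagel's lambda); the cross-trait correlation is ``rho``.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [-1, 1]")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    C, labels = brownian_covariance(tree)
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    rng = np.random.default_rng(seed)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "phylogenetic covariance is singular (zero-length splits?)"
        ) from exc
    z1 = rng.standard_normal(len(labels))
    z2 = rng.standard_normal(len(labels))
    x = sigma * (L @ z1)
    y = sigma * (L @ (rho * z1 + math.sqrt(max(1 - rho * rho, 0.0)) * z2))
    return (
        dict(zip(labels, x.tolist())),
        dict(zip(labels, y.tolist())),
    )
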