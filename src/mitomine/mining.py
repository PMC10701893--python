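"""Mitochondrial contig identification and assembly selection.

Putative mitochondrial contigs are called from two homology searches — one
with reference mitochondrial CDS as queries against the assembly, one with
assembly contigs as queries against complete reference mtDNAs — then passed
through a NUMT gene-density filter and a size cap.  Competing assemblies of
the same genome are scored on completeness, contiguity, and circularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CANONICAL_GENES,
    COMPLEX_I_GENES,
    CORE_GENES,
    ContigRecord,
    GeneAnnotation,
    HitRecord,
)

__all__ = [
    "MiningParams",
    "MitoCallResult",
    "AssemblyScores",
    "identify_mito_contigs",
    "coverage_length_profile",
    "score_assembly",
    "select_best",
]


@dataclass(frozen=True)
class MiningParams:
    """Thresholds for the contig-calling rules.

    Rule A retains contigs with at least ``min_cds_hits`` reference-CDS hits
    of query coverage strictly above ``min_cds_query_cov`` at e-value below
    ``max_evalue``.  Rule B retains contigs with at least one hit to a
    complete reference mtDNA covering at least ``min_contig_cov_by_ref`` of
    the contig.  NUMTs are then removed by requiring at least one annotated
    mitochondrial gene per 20 kb (inclusive boundary), and contigs longer
    than ``max_contig_bp`` are removed last.
    """

    min_cds_hits: int = 10
    min_cds_query_cov: float = 0.70
    max_evalue: float = 0.001
    min_contig_cov_by_ref: float = 0.25
    min_gene_per_bp: float = 1.0 / 20_000.0
    max_contig_bp: int = 300_000
    count_raw_hits: bool = False  # literal reading: count HSPs, not distinct CDS

    def __post_init__(self) -> None:
        for name in ("min_cds_hits", "min_cds_query_cov", "max_evalue",
                     "min_contig_cov_by_ref", "min_gene_per_bp",
                     "max_contig_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MitoCallResult:
    """The status of one contig plus the evidence behind it."""

    contig_id: str
    status: str  # putative_mito | rejected_no_evidence | rejected_numt | rejected_size
    n_qualifying_cds_hits: int
    best_ref_cov: float
    n_canonical_genes: int
    gene_density: float
    length_bp: int

    @property
    def is_mito(self) -> bool:
        return self.status == "putative_mito"


def identify_mito_contigs(
    contigs: Sequence[ContigRecord],
    cds_hits: Sequence[HitRecord],
    genome_hits: Sequence[HitRecord],
    annotations: Sequence[GeneAnnotation],
    params: MiningParams | None = None,
) -> list[MitoCallResult]:
    """Call putative mitochondrial contigs.

    ``cds_hits`` must have reference CDS as queries and contigs as subjects;
    ``genome_hits`` must have contigs as queries and complete reference
    mtDNAs as subjects.  Each contig receives exactly one status, with
    filters applied in order: homology evidence, NUMT gene density, size.
    """
    params = params or MiningParams()
    known = {c.contig_id for c in contigs}
    for h in cds_hits:
        if h.subject_id not in known:
            raise ValueError(f"CDS hit references unknown contig {h.subject_id!r}")
    for h in genome_hits:
        if h.query_id not in known:
            raise ValueError(f"genome hit references unknown contig {h.query_id!r}")

    # Rule A evidence: qualifying reference-CDS hits per contig.
    qualifying: dict[str, list[HitRecord]] = {c.contig_id: [] for c in contigs}
    for h in cds_hits:
        if (
            h.query_cov is not None
            and h.query_cov > params.min_cds_query_cov
            and h.evalue < params.max_evalue
        ):
            qualifying[h.subject_id].append(h)

    def _count_rule_a(hits: list[HitRecord]) -> int:
        if params.count_raw_hits:
            return len(hits)
        # one hit per reference CDS, best e-value kept
        return len({h.query_id for h in hits})

    # Rule B evidence: best contig coverage by a reference mtDNA.
    best_ref_cov: dict[str, float] = {c.contig_id: 0.0 for c in contigs}
    for h in genome_hits:
        if h.evalue < params.max_evalue and h.query_cov is not None:
            best_ref_cov[h.query_id] = max(best_ref_cov[h.query_id], h.query_cov)

    # gene density counts annotations (a full mtDNA duplicate inside a large
    # nuclear contig may carry repeated copies), not distinct symbols
    genes_per_contig: dict[str, int] = {c.contig_id: 0 for c in contigs}
    for ann in annotations:
        if ann.is_canonical and ann.gene in CANONICAL_GENES:
            genes_per_contig[ann.contig_id] = (
                genes_per_contig.get(ann.contig_id, 0) + 1
            )

    results = []
    for contig in contigs:
        cid = contig.contig_id
        n_a = _count_rule_a(qualifying[cid])
        cov_b = best_ref_cov[cid]
        n_genes = genes_per_contig[cid]
        density = n_genes / contig.length_bp
        evidence = (
            n_a >= params.min_cds_hits
            or cov_b >= params.min_contig_cov_by_ref
        )
        if not evidence:
            status = "rejected_no_evidence"
        elif density < params.min_gene_per_bp:
            status = "rejected_numt"
        elif contig.length_bp > params.max_contig_bp:
            status = "rejected_size"
        else:
            status = "putative_mito"
        results.append(
            MitoCallResult(
                contig_id=cid,
                status=status,
                n_qualifying_cds_hits=n_a,
                best_ref_cov=cov_b,
                n_canonical_genes=n_genes,
                gene_density=density,
                length_bp=contig.length_bp,
            )
        )
    return results


def coverage_length_profile(
    contigs: Sequence[ContigRecord],
    calls: Sequence[MitoCallResult],
) -> pd.DataFrame:
    """Coverage/length table for diagnostic plotting.

    One row per contig with log10 columns; no filtering is applied — the
    joint coverage/length profile is diagnostic but has no strict cutoffs.
    """
    flagged = {r.contig_id: r.is_mito for r in calls}
    rows = [
        dict(
            contig_id=c.contig_id,
            length_bp=c.length_bp,
            coverage=c.coverage,
            log10_length=math.log10(c.length_bp) if c.length_bp else np.nan,
            log10_coverage=math.log10(c.coverage) if c.coverage > 0 else np.nan,
            flagged=flagged.get(c.contig_id, False),
        )
        for c in contigs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id", "length_bp", "coverage",
            "log10_length", "log10_coverage", "flagged",
        ],
    )


@dataclass(frozen=True)
class AssemblyScores:
    """Assembly quality: completeness %, contiguity %, junction-read count.

    ``circularity`` is ``None`` when no reads were provided (unknown, not 0).
    """

    completeness: float
    contiguity: float
    circularity: int | None
    per_contig_gene_fraction: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError("completeness must lie in [0, 100]")
        if not (0.0 <= self.contiguity <= 100.0):
            raise ValueError("contiguity must lie in [0, 100]")
        if self.circularity is not None and self.circularity < 0:
            raise ValueError("circularity must be >= 0")


def _junction_read_count(sequence: str, reads: Iterable[str]) -> int:
    """Count reads spanning the circular junction of ``sequence``.

    The contig is rotated by floor(L/2) so the original endpoint junction
    becomes internal; a read counts if an exact placement in the rotated
    contig strictly straddles that point.
    """
    n = len(sequence)
    half = n // 2
    rotated = sequence[half:] + sequence[:half]
    junction = n - half  # index of original position 0 in the rotated contig
    count = 0
    for read in reads:
        start = rotated.find(read)
        while start != -1:
            if start < junction < start + len(read):
                count += 1
                break
            start = rotated.find(read, start + 1)
    return count


def score_assembly(
    contigs: Sequence[ContigRecord],
    annotations: Sequence[GeneAnnotation],
    reads: Sequence[str] | None = None,
) -> AssemblyScores:
    """Score one candidate assembly.

    Completeness is the percentage of expected genes present, where the
    seven Complex I genes are dropped from the expected set when none is
    present and RPS3 is dropped when absent (their absence is a biological
    state, not an assembly defect).  Contiguity is the largest fraction of
    the found genes recovered on a single contig.  Circularity is the count
    of reads spanning the endpoint junction after rotating each contig by
    half its length, summed over contigs.
    """
    if not contigs:
        raise ValueError("candidate assembly must contain at least one contig")
    found: set[str] = set()
    per_contig: dict[str, set[str]] = {c.contig_id: set() for c in contigs}
    for ann in annotations:
        if ann.is_canonical and ann.gene in CANONICAL_GENES:
            found.add(ann.gene)
            per_contig.setdefault(ann.contig_id, set()).add(ann.gene)

    expected = set(CORE_GENES)
    if any(g in found for g in COMPLEX_I_GENES):
        expected.update(COMPLEX_I_GENES)
    if "RPS3" in found:
        expected.add("RPS3")
    completeness = 100.0 * len(found & expected) / len(expected)

    if found:
        best = max(len(genes) for genes in per_contig.values())
        contiguity = 100.0 * best / len(found)
    else:
        contiguity = 0.0
    fractions = {
        cid: (len(genes) / len(found) if found else 0.0)
        for cid, genes in per_contig.items()
    }

    circularity: int | None = None
    if reads is not None:
        circularity = sum(
            _junction_read_count(c.sequence, reads) for c in contigs
        )
    return AssemblyScores(
        completeness=completeness,
        contiguity=contiguity,
        circularity=circularity,
        per_contig_gene_fraction=fractions,
    )


#: Stable provenance order used as the final tie-break: mitochondria-targeted
#: reassemblies are preferred over contigs extracted from the nuclear assembly.
PROVENANCE_ORDER = ("reassembly", "nuclear_extraction")


def select_best(
    candidates: Sequence[tuple[AssemblyScores, str]],
) -> list[tuple[AssemblyScores, str]]:
    """Rank candidate assemblies.

    Completeness is prioritized; contiguity then circularity break ties;
    the documented provenance order makes the ranking fully deterministic.
    """
    if not candidates:
        raise ValueError("no candidate assemblies supplied")

    def _key(item: tuple[AssemblyScores, str]):
        scores, tag = item
        circ = -1 if scores.circularity is None else scores.circularity
        prov = (
            PROVENANCE_ORDER.index(tag) if tag in PROVENANCE_ORDER else
            len(PROVENANCE_ORDER)
        )
        return (-scores.completeness, -scores.contiguity, -circ, prov, tag)

    return sorted(candidates, key=_key)
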