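"""Readers, writers, genetic codes, and the shared gene vocabulary.

Internal coordinates are 0-based half-open throughout the package; GFF3 files
use the standard 1-based inclusive convention and are converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CORE_GENES",
    "COMPLEX_I_GENES",
    "CANONICAL_GENES",
    "GeneticCode",
    "ContigRecord",
    "HitRecord",
    "GeneAnnotation",
    "ParseError",
    "canonical_gene_name",
    "translate",
    "read_hit_table",
    "write_hit_table",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_gff_annotations",
    "write_gff_annotations",
    "read_coverage_table",
    "contigs_from_files",
]

#: The seven protein-coding genes present in every genome surveyed
#: (Complex III/IV subunits and ATP synthase subunits).
CORE_GENES = ("COX1", "COX2", "COX3", "COB", "ATP6", "ATP8", "ATP9")

#: Mitochondrially encoded NADH dehydrogenase (Complex I) subunits,
#: lost repeatedly across the subphylum.
COMPLEX_I_GENES = ("NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6")

CANONICAL_GENES = CORE_GENES + COMPLEX_I_GENES + ("RPS3",)

# Synonym table for gene-symbol normalisation.  This is a maintained config,
# extended as new annotation dialects are encountered.
_GENE_SYNONYMS: dict[str, str] = {
    "COB": "COB",
    "CYTB": "COB",
    "COX1": "COX1",
    "CO1": "COX1",
    "COI": "COX1",
    "COX2": "COX2",
    "CO2": "COX2",
    "COII": "COX2",
    "COX3": "COX3",
    "CO3": "COX3",
    "COIII": "COX3",
    "ATP6": "ATP6",
    "ATPASE6": "ATP6",
    "ATP8": "ATP8",
    "ATPASE8": "ATP8",
    "ATP9": "ATP9",
    "ATPASE9": "ATP9",
    "OLI1": "ATP9",
    "VAR1": "RPS3",
    "RPS3": "RPS3",
}
# NAD <-> ND prefixes, with and without the L suffix (NAD4L).
for _i in ("1", "2", "3", "4", "4L", "5", "6"):
    _GENE_SYNONYMS[f"NAD{_i}"] = f"NAD{_i}"
    _GENE_SYNONYMS[f"ND{_i}"] = f"NAD{_i}"
    _GENE_SYNONYMS[f"NADH{_i}"] = f"NAD{_i}"


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def canonical_gene_name(name: str) -> tuple[str, bool]:
    """Map an annotation label to the canonical vocabulary.

    Returns ``(symbol, is_canonical)``; unmapped symbols are returned
    uppercased with ``is_canonical=False``.
    """
    key = name.strip().upper().replace("-", "").replace("_", "")
    if key in _GENE_SYNONYMS:
        return _GENE_SYNONYMS[key], True
    return name.strip().upper(), False


# ---------------------------------------------------------------------------
# Genetic codes


_BASES = "ACGT"
_ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    Stops are mapped to ``'*'``.  Tables shipped: 1 (standard), 3 (yeast
    mitochondrial: AUA->Met, CUN->Thr, UGA->Trp) and 4 (mold/protozoan
    mitochondrial: UGA->Trp only).  Use :meth:`custom` for variants such as
    the CUN-only reassignment, for which no NCBI table exists.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(_ALL_CODONS):
            raise ValueError("codon_to_aa must map exactly the 64 DNA codons")

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            start_codons=frozenset(table.start_codons),
        )

    @classmethod
    def custom(
        cls,
        codon_to_aa: Mapping[str, str],
        start_codons: Iterable[str] = ("ATG",),
        table_id: int = 0,
    ) -> "GeneticCode":
        return cls(table_id=table_id, codon_to_aa=dict(codon_to_aa),
                   start_codons=frozenset(start_codons))

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"


def translate(seq: str, code: GeneticCode) -> str:
    """Translate a coding sequence codon by codon.

    Internal stops are rendered ``'*'``; codons containing N (or any
    non-ACGT base) become ``'X'``; the gap codon ``'---'`` becomes ``'-'``.

    Raises
    ------
    ValueError
        If the sequence length is not a multiple of 3.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(
            f"sequence length {len(seq)} is not divisible by 3"
        )
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon == "---":
            out.append("-")
        elif codon in code.codon_to_aa:
            out.append(code.codon_to_aa[codon])
        else:
            out.append("X")
    return "".join(out)


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class ContigRecord:
    """A contig with its sequence and mean read depth."""

    contig_id: str
    sequence: str
    coverage: float
    assembly_id: str = ""

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError(f"{self.contig_id}: coverage must be >= 0")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One pairwise homology hit (BLAST outfmt-6 column set).

    ``query_cov``/``subject_cov`` are fractions in [0, 1]; they require the
    companion sequence lengths and are ``None`` when those were not supplied.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bit_score: float
    query_cov: float | None = None
    subject_cov: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        for cov, name in ((self.query_cov, "query_cov"),
                          (self.subject_cov, "subject_cov")):
            if cov is not None and not (0.0 <= cov <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {cov}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene call on a contig; coordinates 0-based half-open.

    ``introns`` are spans nested inside the gene span.  Single-bp spans mark
    +1 frameshift positions encoded GenBank-style as 1-bp introns; they are
    flagged so intron analyses can exclude them.
    """

    contig_id: str
    gene: str
    strand: str
    start: int
    end: int
    introns: tuple[tuple[int, int], ...] = ()
    single_bp_flags: tuple[bool, ...] = ()
    is_canonical: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParseError(f"unknown strand symbol {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene}: start must be < end")
        for s, e in self.introns:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"{self.gene}: intron span ({s}, {e}) not nested in gene"
                )
        if self.single_bp_flags and len(self.single_bp_flags) != len(self.introns):
            raise ValueError("one single-bp flag per intron span required")
        if not self.single_bp_flags:
            object.__setattr__(
                self,
                "single_bp_flags",
                tuple(e - s == 1 for s, e in self.introns),
            )


# ---------------------------------------------------------------------------
# Hit tables (BLAST outfmt 6 dialect)

_OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_hit_table(
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
    subject_lengths: Mapping[str, int] | None = None,
) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table.

    Column order: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Coverages are computed as
    ``aln_length / length`` (capped at 1) when the companion length tables
    are given, else left ``None``.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 columns, "
                    f"got {len(fields)}"
                )
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            rec = attach_coverages(rec, query_lengths, subject_lengths)
            hits.append(rec)
    return hits


def attach_coverages(
    hit: HitRecord,
    query_lengths: Mapping[str, int] | None,
    subject_lengths: Mapping[str, int] | None,
) -> HitRecord:
    qcov = hit.query_cov
    scov = hit.subject_cov
    if query_lengths is not None and hit.query_id in query_lengths:
        qcov = min(1.0, hit.aln_length / query_lengths[hit.query_id])
    if subject_lengths is not None and hit.subject_id in subject_lengths:
        scov = min(1.0, hit.aln_length / subject_lengths[hit.subject_id])
    return replace(hit, query_cov=qcov, subject_cov=scov)


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.pct_identity, h.aln_length,
                        h.mismatches, h.gap_opens, h.qstart, h.qend,
                        h.sstart, h.send, h.evalue, h.bit_score,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA / newick


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an insertion-ordered ``{id: sequence}`` map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_newick(path: str | Path, rooted: bool = True) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick",
        rooting="force-rooted" if rooted else "force-unrooted",
        preserve_underscores=True,
    )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


# ---------------------------------------------------------------------------
# GFF3 annotations

# The subset used here: 9-column lines; `gene` features carrying
# ID=...;gene=SYMBOL attributes and `intron` features carrying
# Parent=<gene ID>[;single_bp=true].


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene/intron features from a GFF3 file.

    1-based inclusive file coordinates are converted to 0-based half-open.
    Gene symbols are uppercased and mapped through the synonym table;
    unmapped symbols are retained verbatim with a warning.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            seqid, _source, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype not in {"gene", "intron"}:
                continue
            if strand not in {"+", "-"}:
                raise ParseError(
                    f"{path}: line {lineno}: unknown strand symbol {strand!r}"
                )
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            attributes = _parse_attributes(attrs)
            if ftype == "gene":
                name = attributes.get("gene", attributes.get("Name", ""))
                gid = attributes.get("ID", f"{seqid}:{start0}-{end0}")
                symbol, canonical = canonical_gene_name(name)
                if not canonical:
                    warnings.warn(
                        f"{path}: line {lineno}: gene symbol {name!r} not in "
                        f"canonical vocabulary; retained as {symbol!r}",
                        stacklevel=2,
                    )
                genes[gid] = dict(
                    contig_id=seqid, gene=symbol, strand=strand,
                    start=start0, end=end0, introns=[], flags=[],
                    is_canonical=canonical,
                )
                order.append(gid)
            else:
                parent = attributes.get("Parent")
                if parent not in genes:
                    raise ParseError(
                        f"{path}: line {lineno}: intron with unknown Parent "
                        f"{parent!r} (gene features must precede their introns)"
                    )
                single = attributes.get("single_bp", "").lower() == "true"
                genes[parent]["introns"].append((start0, end0))
                genes[parent]["flags"].append(single or end0 - start0 == 1)
    return [
        GeneAnnotation(
            contig_id=g["contig_id"], gene=g["gene"], strand=g["strand"],
            start=g["start"], end=g["end"], introns=tuple(g["introns"]),
            single_bp_flags=tuple(g["flags"]), is_canonical=g["is_canonical"],
        )
        for g in (genes[gid] for gid in order)
    ]


def write_gff_annotations(
    annotations: Sequence[GeneAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ann in enumerate(annotations):
            gid = f"gene{i}"
            fh.write(
                "\t".join(
                    (
                        ann.contig_id, "mitomine", "gene",
                        str(ann.start + 1), str(ann.end), ".", ann.strand, ".",
                        f"ID={gid};gene={ann.gene}",
                    )
                )
                + "\n"
            )
            for (s, e), single in zip(ann.introns, ann.single_bp_flags):
                extra = ";single_bp=true" if single else ""
                fh.write(
                    "\t".join(
                        (
                            ann.contig_id, "mitomine", "intron",
                            str(s + 1), str(e), ".", ann.strand, ".",
                            f"Parent={gid}{extra}",
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Coverage metadata


def read_coverage_table(path: str | Path) -> dict[str, float]:
    """Read a two-column ``contig_id<TAB>coverage`` table."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected contig_id<TAB>coverage"
                )
            if lineno == 1 and fields[0].lower() in {"contig_id", "contig"}:
                continue
            out[fields[0]] = float(fields[1])
    return out


def contigs_from_files(
    fasta_path: str | Path,
    coverage_path: str | Path | None = None,
    assembly_id: str = "",
) -> list[ContigRecord]:
    """Assemble ContigRecords from a FASTA plus optional coverage TSV."""
    seqs = read_fasta(fasta_path)
    coverage = read_coverage_table(coverage_path) if coverage_path else {}
    return [
        ContigRecord(
            contig_id=name,
            sequence=seq,
            coverage=coverage.get(name, 0.0),
            assembly_id=assembly_id,
        )
        for name, seq in seqs.items()
    ]
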