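import itertools

import numpy as np
import pytest

from mitomine.core_io import ContigRecord, GeneAnnotation, HitRecord
from mitomine.mining import (
    AssemblyScores,
    MiningParams,
    coverage_length_profile,
    identify_mito_contigs,
    score_assembly,
    select_best,
)
from mitomine.synthetic_data import make_assembly


def _contig(cid="ctg", length=50_000, coverage=100.0):
    return ContigRecord(contig_id=cid, sequence="A" * length, coverage=coverage)


def _cds_hit(contig, cds="cds1", qcov=0.9, evalue=1e-30):
    return HitRecord(
        query_id=cds, subject_id=contig, pct_identity=99.0, aln_length=500,
        mismatches=0, gap_opens=0, qstart=1, qend=500, sstart=1, send=500,
        evalue=evalue, bit_score=900.0, query_cov=qcov,
    )


def _genome_hit(contig, qcov=0.5, evalue=1e-50):
    return HitRecord(
        query_id=contig, subject_id="ref_mt", pct_identity=95.0,
        aln_length=10_000, mismatches=0, gap_opens=0, qstart=1, qend=10_000,
        sstart=1, send=10_000, evalue=evalue, bit_score=15_000.0,
        query_cov=qcov,
    )


_GENE_CYCLE = ["COX1", "COX2", "COX3", "COB", "ATP6", "ATP8", "ATP9",
               "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6",
               "RPS3"]


def _genes(contig, n, length=1000, spacing=2000):
    return [
        GeneAnnotation(
            contig_id=contig, gene=_GENE_CYCLE[i % len(_GENE_CYCLE)],
            strand="+",
            start=i * (length + spacing), end=i * (length + spacing) + length,
        )
        for i in range(n)
    ]


def _call(contigs, cds_hits=(), genome_hits=(), annotations=(), **params):
    calls = identify_mito_contigs(
        contigs, list(cds_hits), list(genome_hits), list(annotations),
        MiningParams(**params) if params else None,
    )
    return {c.contig_id: c for c in calls}


class TestIdentifyRules:
    def test_rule_a_multi_gene_support(self):
        contig = _contig(length=50_000)
        hits = [_cds_hit("ctg", cds=f"cds{i}") for i in range(10)]
        res = _call([contig], cds_hits=hits, annotations=_genes("ctg", 3))
        assert res["ctg"].status == "putative_mito"

    def test_numt_density_boundary_inclusive(self):
        contig = _contig(length=40_000)
        hits = [_cds_hit("ctg", cds=f"cds{i}") for i in range(10)]
        one = _call([contig], cds_hits=hits, annotations=_genes("ctg", 1))
        assert one["ctg"].status == "rejected_numt"  # 1/40kb < 1/20kb
        two = _call([contig], cds_hits=hits, annotations=_genes("ctg", 2))
        assert two["ctg"].status == "putative_mito"  # exactly 1/20kb kept

    def test_oversized_contig_rejected_last(self):
        # 20 gene copies on 350 kb: density passes, size cap rejects
        contig = _contig(length=350_000)
        res = _call(
            [contig], genome_hits=[_genome_hit("ctg", qcov=0.5)],
            annotations=_genes("ctg", 20, spacing=15_000),
        )
        assert res["ctg"].status == "rejected_size"

    def test_no_evidence(self):
        res = _call([_contig()])
        assert res["ctg"].status == "rejected_no_evidence"

    def test_unknown_contig_in_hits_rejected(self):
        with pytest.raises(ValueError, match="unknown contig"):
            _call([_contig()], cds_hits=[_cds_hit("nope")])

    def test_duplicate_hsps_do_not_fake_multi_gene_support(self):
        # ten HSPs from one reference CDS count once by default
        contig = _contig()
        hits = [_cds_hit("ctg", cds="cds1") for _ in range(10)]
        res = _call([contig], cds_hits=hits, annotations=_genes("ctg", 3))
        assert res["ctg"].status == "rejected_no_evidence"
        literal = _call(
            [contig], cds_hits=hits, annotations=_genes("ctg", 3),
            count_raw_hits=True,
        )
        assert literal["ctg"].status == "putative_mito"


class TestThresholdBoundaries:
    """Each threshold flips classification exactly at its documented side."""

    def test_hit_count_at_least_10(self):
        contig = _contig()
        anns = _genes("ctg", 3)
        nine = [_cds_hit("ctg", cds=f"c{i}") for i in range(9)]
        ten = nine + [_cds_hit("ctg", cds="c9")]
        assert _call([contig], cds_hits=nine,
                     annotations=anns)["ctg"].status == "rejected_no_evidence"
        assert _call([contig], cds_hits=ten,
                     annotations=anns)["ctg"].status == "putative_mito"

    def test_query_coverage_strictly_above_70(self):
        contig = _contig()
        anns = _genes("ctg", 3)
        at = [_cds_hit("ctg", cds=f"c{i}", qcov=0.70) for i in range(10)]
        above = [_cds_hit("ctg", cds=f"c{i}", qcov=0.70 + 1e-9)
                 for i in range(10)]
        assert _call([contig], cds_hits=at,
                     annotations=anns)["ctg"].status == "rejected_no_evidence"
        assert _call([contig], cds_hits=above,
                     annotations=anns)["ctg"].status == "putative_mito"

    def test_evalue_strictly_below_0001(self):
        contig = _contig()
        anns = _genes("ctg", 3)
        at = [_cds_hit("ctg", cds=f"c{i}", evalue=0.001) for i in range(10)]
        below = [_cds_hit("ctg", cds=f"c{i}", evalue=0.000999)
                 for i in range(10)]
        assert _call([contig], cds_hits=at,
                     annotations=anns)["ctg"].status == "rejected_no_evidence"
        assert _call([contig], cds_hits=below,
                     annotations=anns)["ctg"].status == "putative_mito"

    def test_contig_coverage_at_least_25(self):
        contig = _contig()
        anns = _genes("ctg", 3)
        at = _call([contig], genome_hits=[_genome_hit("ctg", qcov=0.25)],
                   annotations=anns)
        under = _call([contig], genome_hits=[_genome_hit("ctg", qcov=0.2499)],
                      annotations=anns)
        assert at["ctg"].status == "putative_mito"
        assert under["ctg"].status == "rejected_no_evidence"

    def test_size_cap_at_300kb_inclusive(self):
        anns = _genes("ctg", 20, spacing=13_000)
        hit = [_genome_hit("ctg", qcov=0.9)]
        at = _call([_contig(length=300_000)], genome_hits=hit, annotations=anns)
        over = _call([_contig(length=300_001)], genome_hits=hit,
                     annotations=anns)
        assert at["ctg"].status == "putative_mito"
        assert over["ctg"].status == "rejected_size"


class TestMonotonicity:
    def test_relaxing_thresholds_never_removes_calls(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            n_hits = int(rng.integers(0, 15))
            contig = _contig(length=int(rng.integers(20_000, 120_000)))
            hits = [
                _cds_hit("ctg", cds=f"c{i}",
                         qcov=float(rng.uniform(0.5, 1.0)),
                         evalue=float(10.0 ** rng.uniform(-50, -1)))
                for i in range(n_hits)
            ]
            ghits = [_genome_hit("ctg", qcov=float(rng.uniform(0, 1)))]
            anns = _genes("ctg", int(rng.integers(0, 8)))
            strict = _call([contig], hits, ghits, anns)
            relaxed = _call(
                [contig], hits, ghits, anns,
                min_cds_hits=5, min_cds_query_cov=0.5, max_evalue=0.01,
                min_contig_cov_by_ref=0.1, min_gene_per_bp=1 / 40_000,
                max_contig_bp=600_000,
            )
            if strict["ctg"].status == "putative_mito":
                assert relaxed["ctg"].status == "putative_mito"


class TestProfile:
    def test_empty_assembly(self):
        assert coverage_length_profile([], []).empty

    def test_row_per_contig_and_flags(self):
        asm = make_assembly(seed=3, coverage_multiplier=20.0)
        calls = identify_mito_contigs(
            asm.contigs, asm.cds_hits, asm.genome_hits, asm.annotations
        )
        profile = coverage_length_profile(asm.contigs, calls)
        assert len(profile) == len(asm.contigs)
        flagged = profile[profile.flagged].coverage.median()
        unflagged = profile[~profile.flagged].coverage.median()
        assert flagged / unflagged >= 10


class TestScoreAssembly:
    def test_complex_i_excluded_when_fully_absent(self):
        contigs = [_contig("c1", 20_000)]
        anns = _genes("c1", 7)  # the 7 core genes only
        scores = score_assembly(contigs, anns)
        assert scores.completeness == 100.0

    def test_partial_core_with_complex_i_present(self):
        contigs = [_contig("c1", 30_000)]
        anns = [a for a in _genes("c1", 10) if a.gene != "COX1"]
        # 6/7 core + 3 Complex I genes found; expected set = 14 genes
        scores = score_assembly(contigs, anns)
        assert scores.completeness == pytest.approx(100 * 9 / 14)

    def test_contiguity_max_single_contig_fraction(self):
        contigs = [_contig("c1", 20_000), _contig("c2", 20_000)]
        anns = _genes("c1", 5) + [
            GeneAnnotation(contig_id="c2", gene="ATP9", strand="+",
                           start=0, end=225)
        ]
        scores = score_assembly(contigs, anns)
        assert scores.contiguity == pytest.approx(100 * 5 / 6)

    def test_circularity_counts_planted_junction_reads(self):
        asm = make_assembly(seed=4, n_junction_reads=10)
        mito = [c for c in asm.contigs if c.contig_id == "mito_1"]
        anns = [a for a in asm.annotations if a.contig_id == "mito_1"]
        scores = score_assembly(mito, anns, asm.reads)
        assert scores.circularity == 10

    def test_linear_contig_has_zero_junction_reads(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        contig = ContigRecord(contig_id="lin", sequence=seq, coverage=10.0)
        reads = [seq[100:250], seq[5000:5150]]
        anns = _genes("lin", 7, length=100, spacing=1000)
        scores = score_assembly([contig], anns, reads)
        assert scores.circularity == 0

    def test_no_reads_means_missing_not_zero(self):
        scores = score_assembly([_contig("c1")], _genes("c1", 7))
        assert scores.circularity is None

    def test_empty_candidate_is_error(self):
        with pytest.raises(ValueError):
            score_assembly([], [])


class TestSelectBest:
    def test_single_candidate(self):
        cand = (AssemblyScores(90.0, 50.0, 0), "reassembly")
        assert select_best([cand]) == [cand]

    def test_completeness_dominates(self):
        a = (AssemblyScores(100.0, 10.0, 0), "nuclear_extraction")
        b = (AssemblyScores(90.0, 100.0, 99), "reassembly")
        assert select_best([b, a])[0] == a

    def test_tie_breaks_in_order(self):
        a = (AssemblyScores(90.0, 80.0, 5), "nuclear_extraction")
        b = (AssemblyScores(90.0, 80.0, 0), "reassembly")
        assert select_best([b, a])[0] == a
        c = (AssemblyScores(90.0, 80.0, 5), "reassembly")
        assert select_best([a, c])[0] == c  # provenance breaks the last tie

    def test_total_order_under_permutation(self):
        cands = [
            (AssemblyScores(90.0, 80.0, 5), "reassembly"),
            (AssemblyScores(90.0, 80.0, 5), "nuclear_extraction"),
            (AssemblyScores(100.0, 0.0, None), "nuclear_extraction"),
            (AssemblyScores(90.0, 90.0, 0), "reassembly"),
        ]
        expected = select_best(cands)
        for perm in itertools.permutations(cands):
            assert select_best(list(perm)) == expected

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            select_best([])
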