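# Methods

This note describes the models and procedures implemented in `mitomine`,
the assumptions behind them, the parameter defaults and why they were
chosen, and what the synthetic-data generators do and do not emulate.

## Mitochondrial contig identification

Putative mitochondrial contigs are called from two homology searches whose
tabular results are *inputs* to the package (the package does not run
BLAST):

* **Rule A** — reference mitochondrial CDS as queries against the assembly.
  A contig is supported when at least `min_cds_hits = 10` reference CDS
  have a hit with query coverage strictly above `min_cds_query_cov = 0.70`
  and e-value below `max_evalue = 0.001`. By default hits are de-duplicated
  per reference CDS (best e-value kept) so that ten HSPs from a single gene
  cannot satisfy the rule alone; `count_raw_hits=True` restores the literal
  per-HSP count.
* **Rule B** — assembly contigs as queries against complete reference
  mtDNAs. A contig is supported when at least one hit covers at least
  `min_contig_cov_by_ref = 0.25` of the contig (inclusive) at the same
  e-value cutoff.

Supported contigs then pass a **NUMT filter**: contigs carrying fewer than
one annotated mitochondrial gene per 20 kb are rejected as likely nuclear
copies of mitochondrial DNA. The density counts canonical gene
*annotations* rather than distinct symbols, because a complete mtDNA
duplicate inside a large nuclear contig legitimately carries repeated
copies; the boundary is inclusive (exactly 1/20,000 keeps the contig).
Finally contigs longer than 300 kb are removed (300,000 bp itself is
kept). Each contig receives exactly one status, with the filters applied
in that order: homology evidence, gene density, size.

Coverage/length profiles are reported for diagnostics only; the joint
profile of mitochondrial contigs (elevated coverage, 10–100 kb) is not
sharp enough for strict cutoffs and none are applied there.

### Assembly scoring and selection

Competing assemblies of the same genome are scored on:

* **completeness** — percentage of expected genes present, where the seven
  Complex I genes (*NAD1–NAD6*, *NAD4L*) are dropped from the expected set
  when none of them is present, and *RPS3* is dropped when absent. Their
  absence is a repeatedly evolved biological state, not an assembly defect,
  so a Complex-I-free genome with all seven core genes scores 100%.
* **contiguity** — the largest fraction of the found genes recovered on a
  single contig (the per-contig vector is also reported).
* **circularity** — the number of reads whose exact placement crosses the
  original endpoint junction after rotating each contig by `floor(L/2)`.
  The rotation offset and exact-substring placement are this package's
  testable contract; real data would supply mapped coordinates instead.
  When no reads are given, circularity is reported as missing, never 0.

Ranking prioritizes completeness, then contiguity, then circularity, with
a documented provenance order (reassembly before nuclear extraction) as
the final tie-break so selection is a total order.

## Genome summaries and Dollo loss mapping

GC content is (G+C)/(A+C+G+T) with undefined bases excluded from the
denominator — an N carries no compositional signal. Genome size is the sum
over retained contigs, with a `fragmented` flag when more than one contig
remains. Intron counts exclude single-bp spans, which encode +1
programmed-frameshift positions rather than real introns.

Gene losses are mapped under Dollo parsimony: a single ancestral gain with
irreversible losses. The unique minimum places one loss on each maximal
edge whose entire clade lacks the gene. Losses live on edges; if every tip
is absent the root itself has no edge, so the losses map to the root's
child edges (this matches the exhaustive edge-subset minimum, which the
tests verify on small trees).

## Phylogenetically corrected correlation

`corr_pgls` fits `y = a + b·x` by generalized least squares with residual
covariance `V(λ)`: the Brownian-motion tip covariance of the tree (shared
root-to-MRCA path lengths) with off-diagonal entries multiplied by Pagel's
λ. λ is estimated by maximizing the profile likelihood on a 21-point grid
over [0, 1] refined by bounded golden-section search (`xatol = 1e-6`);
λ may also be fixed. The reported correlation is `sign(b)·sqrt(R²_GLS)`
with R² computed against the GLS intercept-only fit in the same whitened
metric, and the p-value comes from the t statistic of `b` on n−2 degrees
of freedom. The "r" of a GLS fit is not uniquely defined; the slope-based
definition is primary here and the slope, its standard error, and λ are
all reported.

A numerically singular covariance (duplicated zero-length tips) is an
error naming the offending tips, not a silent pseudo-inverse: inference on
such trees is meaningless and the trait simulator refuses them for the
same reason.

## Branch-wise dN/dS by counting

ω is estimated per branch with a deliberately self-contained counting
engine rather than a maximum-likelihood codon model:

1. **Ancestral reconstruction** — per-site nucleotide Fitch parsimony.
   The top-down pass resolves ambiguity by preferring the parent's state
   when it is in the node's candidate set and otherwise the alphabetically
   smallest candidate; the root takes its smallest candidate. This makes
   reconstruction deterministic and the implied change count equal to the
   parsimony score (verified against exhaustive assignment on small trees).
2. **Pairwise counting** — Nei–Gojobori (1986) on each parent/child pair:
   synonymous sites by the 1/3-per-position convention (changes into stop
   codons count as non-synonymous sites), observed differences averaged
   with equal weights over substitution pathways, pathways through stop
   codons excluded, and Jukes–Cantor correction
   `d = −(3/4)·ln(1 − (4/3)p)`. Codon pairs containing gaps, ambiguous
   bases, or reconstructed stop codons are skipped for that branch, as are
   the rare pairs whose every pathway crosses a stop. A proportion at or
   beyond the correction ceiling (p ≥ 3/4) yields an infinite distance
   flagged `saturated`; ω = dN/dS is then 0 in the synonymous-saturated
   limit and undefined when dN saturates.
3. **Aggregation** — the group/gene ω is the arithmetic mean over branches
   with sufficient synonymous signal, dS > 0.01 strictly; saturated
   branches are never used. Taxa missing a gene are dropped for that gene
   and the number of branches actually used is reported.

Counting estimators are biased relative to ML branch models when the
substitution process is transition-biased, because the equal-rate site
counting misattributes the transition excess; published ω values from ML
software are therefore comparable in pattern but not numerically. The
recovery tests characterize the engine under its own model assumptions
(κ = 1); the simulator's κ is exposed for studying that bias directly.

## Codon simulator

`simulate_codon_evolution` uses a GY-style continuous-time model on the
sense codons of the chosen genetic code: rate ∝ κ for transitions, × ω for
non-synonymous changes, zero into stop codons, equal codon frequencies,
scaled so branch lengths are expected substitutions per codon. Transition
probabilities come from the matrix exponential, cached per branch length.
Defaults: κ = 1 (see above), uniform root sequence. The simulator is a
test harness: it makes no claim about realistic codon frequencies, rate
heterogeneity, or indels.

## Intron similarity network

All-versus-all intron hits are normalized by the *query's* self-alignment
bit score — the maximum possible score for that intron — and an edge is
retained when the normalized score is at least 0.5 (inclusive) with
e-value below 1e-10. An undirected edge exists when at least one direction
passes (`edge_rule="both"` and `denominator="max_self"` give the stricter
readings; the choice is not settled by the underlying method description,
so both are exposed).

Sharing categories are defined over cross-*species* partners only: unique
(no partner), within group, within-and-between, or between groups only.
Same-species paralogous hits stay in the graph for clustering but do not
create sharing. Clusters are Louvain communities with edge weights equal
to the normalized scores; nodes are inserted in sorted order and the
optimizer is seeded, so a given (graph, seed) is reproducible — but
Louvain partitions are not canonical, and cluster identity at partition
granularity should not be treated as a stable quantity. Per-cluster span
reports flag clusters spanning multiple groups, orders, or host genes, and
report intron types and ORF motifs as observation columns (whether shared
introns are of one variety is a finding, not an assertion).

The built-in aligner is Smith–Waterman with match +1, mismatch −3, gap
open −5 and extension −2 (the first gapped residue costs the open
penalty), bit scores via Karlin–Altschul `B = (λS − ln K)/ln 2` with the
standard ungapped constants for this scoring system (λ = 1.374,
K = 0.711), and `E = m·n·2^(−B)`. It exists so the network stage is fully
testable without external software; real datasets should supply an
external all-versus-all tabular file.

## Alignment utilities

Concatenation fills missing taxa with gaps and records partition
boundaries. The occupancy filter keeps columns whose non-gap fraction is
at least the threshold (inclusive at the default 95%). Codon threading
maps each amino-acid column to its codon, turning protein gaps into `---`,
and refuses any CDS that does not translate exactly to its protein row
(trailing stop tolerated). The normalized Robinson–Foulds distance prunes
both trees to their shared taxa, compares them unrooted, and divides the
bipartition symmetric difference by its maximum 2(n−3); "matched subtrees"
is read as shared-taxon pruning.

## Synthetic data: what it does and does not show

Every generator is a pure function of (parameters, seed) and emits a
machine-readable truth object.

* **Assemblies** — one circular mitochondrial contig carrying a
  deterministic toy reference gene set (7 core genes plus Complex I genes
  and *RPS3* by default) evenly spaced on an AT-rich backbone (default GC
  0.20 against nuclear 0.40), nuclear contigs, and NUMT contigs embedding
  a mitochondrial fragment with exactly one full gene (so NUMTs always
  fall below the 1/20 kb density by construction). Mito coverage is a
  multiplier (default 20×) over the nuclear mean of ~30×. Hit tables are
  emitted analytically from the planted geometry (coverage fractions and
  near-zero e-values), emulating what the homology searches would return
  for exact copies. Reads are error-free fixed-length substrings,
  including a stated number spanning the circular junction; read placement
  is exact substring matching. None of this emulates sequencing error,
  repeats, heteroplasmy, or mis-assembly — passing tests show the
  *decision rules* are implemented correctly, not that the thresholds are
  optimal for real data.
* **Codon alignments** — see the simulator above; recovery within the
  stated tolerances shows the counting engine tracks the generating ω, not
  that it matches ML estimates on real alignments.
* **Intron sets** — one vertically inherited family per group (each
  species' first intron descends from a group ancestor) plus independent
  random introns, with HGT events copying a donor family ancestor into
  another species, group, or order. Defaults: intron length 200 bp,
  per-copy divergence 0.02. These defaults are chosen from the detection
  geometry of the 50% self-score threshold: the conservative threshold
  only ever detects strongly conserved sharing, so planted families
  emulate detectably shared introns (expected pairwise normalized score
  ≈ 0.84, comfortably above 0.5), while independent random sequences of
  this length sit far below it. Real intron families that have decayed
  near the detection boundary are *not* emulated; the generators measure
  classification logic, not sensitivity.
* **Presence matrices and trait pairs** — losses planted on non-nested
  clades chosen so the planted set remains the unique Dollo minimum;
  bivariate Brownian traits with cross-correlation ρ and Pagel λ applied
  to the covariance. `random_binary_tree` bounds branch lengths away from
  zero (default 0.1–1.0) to keep the Brownian covariance well conditioned;
  degenerate trees are a numerical error, not a silent warning.

## Problem sizes used in the checked results

The packaged checks run at desk scale: 200 planted assemblies for mining
precision/recall, 200 random ≤10-tip instances plus 64-tip planted cases
for Dollo, 100 random codon pairs for the NG86 oracle, 20 replicates of
16-tip/5000-codon alignments per ω level, 1000 Brownian replicates on a
32-tip tree for PGLS calibration, 500 seeded intron sets, and brute-force
RF/occupancy oracles on 8-taxon and 20-row instances. The acceptance
script reruns the same pipeline at moderately smaller replicate counts and
reports the measured quantities.

## Known limitations

* The ω engine is a counting method; it underestimates ω under strong
  transition bias and does not model rate variation or branch-specific
  codon frequencies.
* Dollo mapping assumes presence calls are correct; annotation failure is
  indistinguishable from loss.
* The λ grid search assumes a unimodal profile likelihood on [0, 1], which
  can fail on pathological trees.
* The built-in aligner's e-values use ungapped Karlin–Altschul constants
  as an approximation for its gapped scoring; they are suitable for
  thresholding at 1e-10, not for edge-wise significance claims.
* Translation-table inference, de novo annotation, and tree inference are
  out of scope; annotations, hit tables, alignments, and trees are inputs.
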