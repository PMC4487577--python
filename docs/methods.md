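# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical conventions and the open design choices behind
divergene. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Expression and differential calling

Expression is quantified as RPKM = 10⁹·C/(N·L). A variant of this
formula circulates with the constant written as 10⁶/(L·10³); it differs
from the standard definition by a constant factor only, which cancels
in every fold change, so `rpkm(..., literal=True)` reproduces that form
while the default keeps the standard scale.

With a single treated and a single control library there are no
biological replicates, so the test is the classic two-library
proportion comparison: a Pearson chi-square statistic (1 df, no Yates
correction) on {gene count, library remainder} × {condition}, p-value
from the χ² survival function. A gene absent from both libraries is
assigned p = 1 (it carries no information; any other convention would
manufacture significance from nothing). Multiplicity is controlled by
Benjamini–Hochberg step-up over all tested genes (via statsmodels);
the procedure is configurable because single-pair RNA-seq pipelines of
that era reported only "FDR" without naming the estimator. The DEG rule
is fold change > 2 or < 0.5 **and** FDR < 10⁻². Fold changes use a
pseudo-count of 1 on zero counts — only for the fold, never for the
test — to keep folds finite without reordering genes.

Limitations: a chi-square on library proportions treats biological
variability as zero; with real replicated data a negative-binomial
model (DESeq2/edgeR) is the appropriate tool. This module implements
the two-library design it is specified for, nothing more.

The 2^−ΔΔCt helper computes ΔCt = Ct_target − Ct_reference per
replicate, ΔΔCt against the calibrator sample's mean ΔCt, and
propagates the replicate SD to the fold scale by the delta method
(sd_fold = fold · ln2 · sd(ΔCt)).

## Enrichment

The upper-tail hypergeometric probability is evaluated through
`scipy.stats.hypergeom.sf(m−1, N, M, n)`, which computes
P(X ≥ m) = 1 − Σᵢ₌₀^{m−1} C(M,i)C(N−M,n−i)/C(N,n) in log space and does
not underflow at tail probabilities around 10⁻⁷; the test suite checks
it against an exact rational-arithmetic oracle for N ≤ 200.
Bonferroni multiplies by the number of terms tested — every term with
M > 0 in the supplied annotation, not a fixed constant, because the
tested-term count belongs to the annotation set, not to the method.
(For reference, a published KEGG analysis this module mirrors implies
T ≈ 201 from the ratio of its corrected to raw p-values.) Terms are
treated as flat classes; GO-graph propagation is out of scope.

## Homology

Families are connected components (networkx) over best-hit edges: per
query the smallest e-value under the 10⁻¹⁰ cutoff, ties broken by
higher bitscore then lexicographic subject id so results are
order-independent. Single linkage is the default because a "family"
should contain all sequences chained through best hits, including
multiple paralogs per genotype; `reciprocal_only=True` restricts
ortholog edges to mutual best hits for conservative pairing. Sequence
ids must be namespaced per genotype (enforced), since the Venn
bookkeeping is meaningless under id collisions.

The similarity search itself is external by design: the module consumes
the ubiquitous 12-column tabular format. Two built-in producers exist —
a wrapper that shells out to `makeblastdb`/`blastn` (used by the
pipeline and the recovery tests) and an exact Smith–Waterman aligner
(match 1, mismatch −1, gap −2) whose O(nm) cost restricts it to
desk-scale inputs; its surrogate e-value m·n·2^(−score) only ranks hits
on toy data.

The longest-ORF utility scans all six frames for ATG-to-stop spans
(standard code, stop required, length counted with the stop codon),
ties broken toward the forward strand then the smallest forward-strand
start; coordinates are 1-based inclusive on the forward strand.

## SSR mining

A tract is a maximal run of a primitive (non-self-periodic) 1–6 nt
motif: the maximal region where s[k] = s[k+u], reported from its
leftmost base with ⌊span/u⌋ full copies. Partial trailing copies are
not counted (so `end − start + 1 = unit × repeats` always holds), which
means coordinates on the reverse complement can shift by up to u−1 —
the strand-consistency test asserts identical canonical motifs, units
and repeat counts, and mirrored positions within that phase tolerance.
Overlapping tracts of different unit lengths are resolved longest-first
(ties: smaller start, then smaller unit). Default minimum repeats are
mono ≥ 8, di ≥ 6, tri/tetra/penta/hexa ≥ 4 — looser than the common
MISA defaults (10/6/5), deliberately, because marker panels in this
domain include loci such as (T)8 and (TGT)4; the thresholds are
arguments everywhere and the tests pass them explicitly. Only perfect
repeats are detected: polymorphism calling needs unambiguous tract
lengths, which compound/interrupted SSRs do not give.

Cross-genotype matching groups each ortholog pair's loci by canonical
motif — the lexicographic minimum over all rotations of the motif and
its reverse complement — and pairs them in rank order along the
sequences. A match must also agree over the inner 50 nt of both flanks
at ≥ 80% identity (edlib edit distance over the common length, so
flanks truncated at sequence ends are not penalized). This anchor check
is this module's operationalization of the "manual check" such studies
describe; both parameters are configurable. Matched loci with different
tract lengths are polymorphic; divergence > 2 nt sets
`passes_primer_rule`, the threshold used to shortlist loci for primer
design. Primer-region export emits template + 1-based target span and
flags (rather than emits) loci whose shorter flank is under 50 nt.

## SNP filtering

Depth and score thresholds are strict inequalities (> 10, > 30).
The spacing rule is evaluated on the depth/score-passing candidates:
any candidate whose nearest candidate neighbour on the same reference
is closer than 5 bp is dropped, and both members of a too-close pair
go, because dense SNP clusters in assembled transcripts usually flag
misassembly or collapsed paralogs rather than real variation. An
interval of exactly 5 bp is kept ("no less than"). The filter is
idempotent and is tested against an exhaustive all-pairs oracle.
SNP calling itself is out of scope; the module consumes call-record
tables (and the filter is agnostic to whether "score" is a consensus or
variant quality).

## Diversity and trees

GD and PIC use plug-in frequencies with no small-sample correction:
recomputation from printed major-allele frequencies of reference marker
tables matches the published GD/PIC at 2 d.p. for biallelic rows
without any correction, so none is applied. Bulked multi-plant samples
are scored as single diploid calls, mirroring gel-band scoring.

The default accession distance is the shared-allele distance
D(a,b) = 1 − (1/L)Σ s_l, s_l ∈ {0, ½, 1}, over loci typed in both
accessions (a pair with zero co-typed loci is an error, not a zero).
The distance actually used by legacy GUI packages for such trees is
rarely reported, so the measure is configuration, not a claim.

UPGMA is implemented directly because the required determinism —
joining the lexicographically smallest pair under distance ties — is
not expressible through `scipy.cluster.hierarchy.linkage`; scipy's
average linkage instead serves as the independent reference on tie-free
random matrices (n ≤ 6) in the tests. Node heights are half the join
distance, leaves sit at height 0, so trees are ultrametric by
construction; Newick export (dendropy-compatible) writes bootstrap
supports as internal labels. Bootstrap resamples marker columns with
replacement; the support of each internal clade of the full-data tree
is the percentage of replicates containing that clade. B defaults to
200 in the pipeline (1000 via CLI), a balance between support
resolution (±~2%) and runtime.

## The synthetic-data generator

`synthio` emulates the study design the pipeline targets: two genotype
unigene sets derived family-by-family from common base sequences, with

* SNPs planted per base at `snp_rate` (default 0.01), transitions with
  probability r/(r+1) for `tstv_ratio` r (default 1.5, the ratio
  implied by published transition/transversion class counts in this
  domain), at a minimum spacing of `snp_min_spacing` (default 6 bp) so
  the 5-bp interval filter retains every planted SNP and expected
  survivor counts are exact;
* SSRs planted in `ssr_plant_rate` of the >1 kb families (default
  0.15), polymorphic across genotypes with probability `ssr_poly_rate`
  (default 0.32), motifs drawn from the mono- to tetra-nucleotide
  classes typical of plant EST-SSR panels; boundary bases are fixed so
  the planted tract is exactly what the detector must report;
* paralogs as within-genotype copies mutated at 5% per base
  (within-family identity ≈ 95%, far above the between-family
  background ≈ 25% of random sequence);
* DE genes (default 20 at fold 4; tests use fold 8) over log-normal
  baseline weights, counts multinomial per 10⁶-read library;
* annotation maps whose planted enriched terms preferentially receive
  DE genes;
* SNP call records for every planted SNP (all passing depth/score) plus
  a 10% admixture of decoy records that must fail the quality filters;
* diploid genotype matrices under Hardy–Weinberg, optionally split into
  groups with group-private allele-size ranges to plant unambiguous
  population structure, with missing calls at 0.31%;
* qPCR Ct tables with known fold changes.

Incidental tandem repeats in the random background (including any
created by planted substitutions) are scrubbed below the detection
thresholds by deterministic point edits away from planted loci, so the
planted SSR set is exactly the detectable set and recovery can be
asserted as an equality, not a bound. Scrubbing may occasionally
rewrite a planted SNP base; SNP recovery is therefore defined over the
emitted call records, which is also what the filter consumes.

Each generator stage owns an RNG stream derived from
(stage-tag, master seed), so adding a stage never changes earlier
outputs, and a fixed seed reproduces byte-identical files.

Scales are deliberately modest — hundreds of families of 0.3–2 kb,
10⁶-read libraries, tens of accessions — the package's chosen study
size for fast, fully-exercised runs. What the generator does **not**
model: read-level data (FASTQ, assembly, sequencing error), ambiguity
codes beyond an optional N-injection flag, indels between orthologs,
interrupted/compound SSRs, linkage between markers, and biological
count overdispersion. Passing recovery tests therefore demonstrate the
correctness of the detectors, filters and statistics under their stated
assumptions — not robustness to assembly artifacts or replicate-level
biological noise.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| e-value cutoff | 1e-10 | best-hit edge threshold |
| DE fold / FDR | 2 / 1e-2 | DEG call rule |
| SSR min repeats | 8/6/4/4/4/4 | per unit length 1–6 |
| SSR min sequence length | 1000 nt | detection eligibility |
| flank length / anchor | 300 nt / 50 nt @ 80% | primer flanks, match check |
| primer rule | divergence > 2 nt | shortlist threshold |
| SNP depth / score / spacing | >10 / >30 / ≥5 bp | call filters |
| bootstrap B | 200 (pipeline), 1000 (CLI) | support replicates |

## Known limitations

Single-pair DE testing ignores biological variance; enrichment treats
annotation terms as flat sets; ortholog assignment is best-hit based,
not tree-aware; the SSR detector reports perfect repeats only; the
UPGMA tree inherits all the usual caveats of ultrametric clustering on
marker distances (it is a phenogram, not a phylogeny); and bootstrap
supports quantify marker resampling stability, not clade credibility.
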