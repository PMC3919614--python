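# Methods

## Data model and assumptions

The pipeline consumes per-site allele counts, not alignments. One counts-TSV
per cross holds, for every variant site, reference and alternative read
counts plus a read-strand breakdown (`plus_count`/`minus_count`). Counts are
assumed to be base-quality filtered (Phred ≥ 13; offset 33 for mpileup-style
text) and each counted read has weight 1 — if an upstream aligner distributed
multi-mapping reads, that weighting must be resolved before counting. SNP
positions are 1-based points (ids like `chr12_110872195`); all interval
logic (gene models, extensions in BED) is 0-based half-open internally, with
extension spans reported 1-based inclusive in the TSV output.

The design is exactly two crosses with swapped parents and a single
"alternative strain" assumed to carry the non-reference allele. This
assumption is empirically strong but not perfect in real inter-subspecific
crosses (~95–99% of informative SNPs in a JF1-versus-reference design); the
`alt_strain_concordance` statistic quantifies it per run, and a sites-only
VCF of known strain variants can pre-restrict which positions are tested.

## Decision rule

Candidates: AF ≥ `min_af` (0.80) and coverage ≥ `min_cov` (10) in at least
one cross. All comparisons are inclusive, matching the printed thresholds.
The coverage gate applies to the discovering cross only — the confirming
cross may be arbitrarily shallow, but a site with *zero* confirming reads is
flagged `unconfirmed_low_coverage` and can never be TRUE, because both the
Fisher test and the reciprocal-AF rule need two-cross information. Sites
with AF ≥ 0.80 in both crosses (each with coverage > 0) are removed as
strain-homozygous variants with reason code `strain_variant`.

Testing: a two-sided Fisher exact test (minimum-likelihood definition, as in
`scipy.stats.fisher_exact`) on ((alt, ref) discovering, (alt, ref)
confirming). Two-sidedness is the conservative choice; directionality is
supplied by the reciprocal-AF gate, not the test. The odds ratio is the
sample estimate a·d/(b·c), reported as +inf (or 0) when a zero cell makes it
degenerate, alongside a Haldane–Anscombe (+0.5) corrected column; odds
ratios are reported, never filtered on. Benjamini–Hochberg adjustment runs
over the pooled candidate family by default (`fdr_family="per_cross"` is
available). TRUE iff FDR ≤ 0.05 and confirming AF ≤ 0.20.

Origin: the discovering cross is the one where the expressed allele is the
alternative; if the alternative strain is the mother there, the call is
MATERNAL, else PATERNAL. Swapping the two cross labels provably flips every
origin and nothing else (tested end-to-end).

Tri-allelic sites: the mpileup converter keeps the most frequent
non-reference base as the alternative (ties broken alphabetically) and
tallies other bases in `other_count`; they never enter AF denominators.

## Aggregation and bookkeeping

A transcript call requires ≥ 1 TRUE SNP within the transcript span
(point-in-interval; `exonic_only` restricts to exon blocks). "Average reads"
is the mean over TRUE SNPs of the per-SNP coverage averaged across the two
crosses, rounded half-up to an integer — the combination across crosses is
not uniquely fixed by the reported tables, so a per-cross breakdown is
emitted alongside. Consensus origin is by unanimity; mixed-origin
transcripts are CONFLICT, excluded from imprinted-gene reporting but kept in
diagnostics. The representative SNP is the TRUE SNP with the highest
combined coverage.

Catalogue bookkeeping takes a TSV of known imprinted transcripts with
`category` (ok / small_rna / not_genuine / duplicate), `expressed` and
`has_snp` columns, and enforces two identities: evaluable = catalogue −
exclusions, and found + no-call + not-confirmed = evaluable. Both are
asserted at run time, not assumed. The bundled catalogue fixture is a
synthetic stand-in (real names only for the 32 confirmed genes) reproducing
the published category tallies.

## Extension detection

Intergenic TRUE SNPs are grouped by (chromosome, origin, majority read
strand) and clustered by single linkage with inter-SNP gap ≤ `max_gap`
(default 10 kb). Two refinements beyond plain gap clustering:

- clusters never extend across an annotated same-strand transcript lying
  between consecutive SNPs — an extension should not read through another
  gene (this is what keeps three adjacent same-strand extensions in one
  imprinted domain separate);
- a cluster becomes an extension only if the nearest annotated transcript
  upstream in transcription direction, within `max_reach` (default 100 kb)
  of the cluster's 5′-most SNP, has an imprinted transcript call of the same
  origin and strand. Any imprinted call is parent-eligible, so extensions
  can chain within read-through domains.

The defaults were chosen once to reconnect known extension geometries (the
longest published gap between a parent 3′ end and its extension is ~15 kb)
while `max_reach` bounds runaway assignment; both are CLI-exposed. The
reported span is the SNP span (min to max position): SNP positions are the
only desk-scale evidence, and whether published spans mark SNP or read
coverage extent is not stated. Orphan and undersized clusters are emitted as
diagnostics (`unassigned_cluster`, `too_few_snps`), never silently dropped.

## Vetting heuristics

Three artifact signatures flag a novel prediction as suspect: TRUE fraction
below 0.5 among informative SNPs ("in minority" read literally); informative
SNP density above 10/kb (a genuine inter-subspecific transcript rarely
exceeds ~1 SNP/150 bp, while pseudogene read misassignment produced ~27/kb
in the motivating case); and > 50% of informative SNPs with AF ≥ 0.8 in both
crosses (shared paralog variants). All three cutoffs are declared heuristics
— the source observations were qualitative — and are configurable. Detection
of mitochondrial-paralog (NUMT) artifacts is supported only via a
user-supplied BED of paralog intervals; inferring such regions from sequence
is out of scope, as is any DNA-level genotype verification.

## Synthetic data generator

The generator emulates the sampling structure of allele-specific RNA-seq in
a reciprocal cross: per gene, SNPs by a Poisson process (default 2/kb over
2 kb genes, floor of 3 SNPs for imprinted genes), per-SNP coverage from a
negative binomial (mean 30, dispersion 10; RNA-seq coverage is
overdispersed, and dispersion → inf recovers Poisson; `coverage_fixed`
gives exact coverage for degenerate tests), and alternative-read counts
Binomial(coverage, f) with f = 1−ε / ε / 0.5 / θ / 1−ε for the
maternal / paternal(silenced side) / biallelic / leaky / strain-variant
states, with the maternal strain carrying the alternative allele in cross A
and the paternal strain in cross B. A single global error rate ε = 0.01
absorbs sequencing error and cross-mapping. The leaky state models a
paternally expressed gene with maternal leak θ ∈ [0.21, 0.25], which places
its best AF at 1−θ ≤ 0.79 — just under the 0.80 discovery gate in the
noise-free limit. Pseudogene decoys are 1.1 kb, 27 SNPs/kb, mostly
shared-alt with two uniparental SNPs. Default gene fractions are 20
maternal, 20 paternal and 5 leaky per 500 genes. Seeding uses one root seed
with per-gene substreams (`default_rng([seed, gene_index])`), so adding
genes never perturbs existing genes' draws and identical (config, seed)
yield byte-identical files.

What the generator does *not* model: read-level artifacts (no FASTQ, no
aligner bias, no fragment-length structure), positional coverage
autocorrelation along a transcript, per-site error variation, and replicate
structure (the motivating design has one library per cross). Passing the
recovery suite therefore demonstrates the decision logic and its
calibration under the stated sampling model, not robustness to alignment
artifacts — which is exactly what the vetting module and its decoy states
are for, and why real-data confirmation (e.g. allelotyping) remains the
decisive check for novel calls.

Evaluation counts exact confusion matrices. Positives are SNPs of genuinely
imprinted loci; leaky, biallelic, strain-variant and decoy sites are all
negatives (a leaky gene called FALSE is a correct rejection). Per-SNP
specificity is computed over *tested* candidates only, which are enriched
for borderline negatives — it is deliberately pessimistic and should not be
read as genome-wide specificity. Gene-level sensitivity asks for ≥ 1 TRUE
SNP per imprinted gene; origin accuracy is scored among detected genes.

## Numerical choices

- Reported fractions and percentages round half-up (`80.3%`, AF to two
  decimals); banker's rounding is never used for display.
- Fisher two-sided enumeration includes tables whose point probability is
  within a 1e-7 relative tolerance of the observed one (ties at machine
  epsilon), matching the scipy convention; the test suite verifies exhaustive
  agreement with a from-scratch hypergeometric enumeration for all tables
  with total ≤ 25 and BH agreement with a naive quadratic step-up on random
  vectors up to n = 1000.
- Degenerate inputs fail loudly: zero-coverage allele fractions, all-zero
  Fisher tables, zero-read libraries and empty concordance groups raise
  typed errors rather than returning NaN.
- The worked-example fixtures treat the published representative rows as the
  already-discovered candidate set and apply the decision stage directly;
  one representative site has discovering-cross coverage 9 because published
  per-base "total coverage" counts full pileup depth rather than ref+alt
  reads, so re-imposing the discovery gate on representative rows would be
  anachronistic. Count quadruples that could not be recovered digit-exactly
  from the flattened source tables are reconstructed to reproduce the
  printed AF columns and flagged `counts_reconstructed=yes` in the fixture.

## Problem sizes in the test suite

The default test run keeps simulations at desk scale as a package choice:
recovery uses 500-gene genomes over 20 seeds (~2,000 SNPs each), unit suites
use 30–80-gene genomes, and the Fisher cross-check enumerates all ~2.4×10⁴
small tables. The acceptance script re-runs the 20-seed recovery suite at
the default 500-gene configuration.

## Known limitations

- No beta-binomial overdispersion or replicate-aware hierarchical testing;
  with one library per cross the Fisher test treats reads as independent.
- No genotype-likelihood model, no indels, no phasing, no isoform-level
  inference, no expression quantification.
- Extension calls are SNP-cluster evidence, not transcript-boundary
  inference; deciding whether an extension is an independent transcription
  unit requires wet-lab evidence by design.
- The candidate rule cannot distinguish strong allelic bias from genuine
  monoallelic expression near the AF = 0.8 boundary; leaky genes are
  reported FALSE, not as a separate class.
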