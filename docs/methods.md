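# Methods

This note documents the models, parameters, and numerical choices behind
`chaintrace`, and what its synthetic validation does and does not show
about real data.

## The tracing problem and its ladder of resolution

Community profiling (16S genus or exact-sequence OTU tables) can show that
the *same label* occurs in cow feces (CF), litter (LIT), raw milk (MIL),
and fresh cheese (PC), but not that the same organism travelled the chain.
The package therefore stacks methods of increasing resolution: prevalence
based sharing (taxon level), marker-primer PCR (strain level, high
sensitivity, limited specificity when the amplified region is conserved),
strict 100%/100% read mapping (higher specificity, lower sensitivity at
low abundance), SNP allele-frequency profiles (population-level identity),
and fragment ANI on isolate genomes (the final arbiter: 100% = isogenic).
Each stage is an independent module with the thresholds exposed.

## Core sharing

* **Presence** is prevalence strictly greater than `prevalence_threshold`
  (default 0.70) within one (site, matrix) group; "detected" means
  abundance > 0. With 10 samples per group, 8 positives are needed — 7/10
  is exactly 0.70 and fails. A `detection` mode (present iff seen in any
  sample) is provided because sharing narratives sometimes mix the two
  readings; both are reported rather than guessed between.
* **Site qualification**: a taxon qualifies at a site when present in
  ≥ `min_matrices_for_core` (default 3) of the matrices sampled there. No
  matrix is mandatory — this is the only reading consistent with the
  packaged core-table fixture, where a taxon with no cheese entry at one
  site still counts among the four-site core.
* Sharing counts are reported per site and as cross-site means;
  intersections are anti-monotone in the matrix combination by
  construction, and raising the prevalence threshold can only remove
  presences. Taxon sets are emitted in lexicographic order for
  deterministic output.

## Synthetic data

The generator emulates the study design the analyses assume: `n_sites`
production sites × 4 matrices × `n_samples_per_matrix` (default 10)
replicate samples.

* Per-sample compositions are Dirichlet draws centred on per-matrix mean
  abundances with a single concentration parameter (`overdispersion`,
  default 50 — sample-to-sample standard deviation ≈ 0.04 for a
  0.9-mean taxon, a realistic spread for a starter-dominated cheese
  community; no published per-sample dispersion exists, so this is a free
  parameter of the simulator). Unassigned mass (1 − Σ means) is an
  implicit "other" component that never appears in the table.
* Planted taxa are structural: their carry-over abundance (which must
  exceed the detection floor) is set exactly in every sample of their
  planted groups, background rescaled to the remaining mass — so planted
  prevalence is exactly 1.0 and recovery tests have exact truth.
* Zeros are structural too: abundances strictly below `detection_floor`
  (default 1e-4) are recorded as 0. Prevalence logic sees controllable
  absence rather than sampled dropouts.
* Strain variants carry exactly `n_snps` substitutions at distinct
  positions (the truth set is recorded); reads are drawn uniformly over
  positions and strands with independent per-base substitution errors.
  There are no indels, chimeras, copy-number effects, or quality-dependent
  errors — the mappers and pileup are ungapped, so the simulator matches
  the engines by design. Consequently, passing tests demonstrate the
  *logic* of the tracing rules, not robustness to indel-rich or
  amplification-biased real sequencing.
* Everything flows from explicit integer seeds; a fixed seed gives
  byte-identical tables, genomes, and reads.

## Primer design and in-silico PCR

Design is a deterministic left-to-right scan over forward-primer starts,
primer lengths (18–25 nt), and product lengths (100–600 bp), returning the
first pair where each primer occurs exactly once in the marker and neither
primer nor its reverse complement occurs as an exact substring of any
background sequence. Specificity-by-exact-absence is a conservative,
desk-scale screen: a primer rejected here might still be usable in
practice, but an accepted one cannot have a perfect background site.
Melting temperature uses the Wallace rule 2(A+T) + 4(G+C) with a 50–65 °C
window — crude but deterministic, and adequate for screening synthetic
markers; it is not a thermodynamic prediction. In-silico PCR requires both
primer sites verbatim (single mismatch ⇒ no amplicon) on either strand
within the maximum product length.

## Mapping engines

* **Strict engine** (presence calls): a read hits wherever it or its
  reverse complement is an exact, full-length substring of a contig. The
  implementation seeds with the read's leading k-mer (k = min(31, read
  length)) and verifies the full read, which is provably equivalent to
  naive substring search (an exact match implies an exact leading k-mer);
  the equivalence is also property-tested against the naive oracle. Reads
  containing N never match, preserving the exactness of the 100% rule.
  Presence = (hits ≥ `min_reads_for_presence`, default 1) and (breadth ≥
  `min_breadth_for_presence`, default 0.5) — the evidence behind a
  "detected" call is not standardized anywhere, so both knobs are exposed
  with conservative defaults.
* **Tolerant engine** (SNP profiling): best unique ungapped full-length
  placement with ≤ ⌊`max_mismatch_frac` × read length⌋ substitutions
  (default 0.05); ties leave the read unmapped — determinism is preferred
  over randomized placement (which remains possible upstream by seeding).
  Candidates come from pigeonhole seeding: with m mismatches allowed, one
  of m+1 equal chunks must be exact, so seeding each chunk's leading
  k-mer (k ≤ 13) finds every qualifying placement; short reads fall back
  to a full scan. Setting the strict mapper's `identity_cutoff` below 1.0
  routes it to this engine; `coverage_cutoff` below 1.0 is rejected,
  because partial-length alignment has no defined semantics in a
  full-length ungapped model.

## SNP profiles and the same-strain decision

Pileups tally every aligned base; conservation (Σ counts = Σ aligned
non-N bases) is asserted in tests. A profile keeps positions with
coverage ≥ `min_cov` (default 5) and records the variant allele frequency
1 − ref/coverage and the major-allele frequency.

`profile_distance` is the mean |Δ VAF| over all jointly covered positions
— a genuine pseudometric (restricting the mean to variant positions
breaks the triangle inequality, because the averaging set then depends on
the pair). The price of averaging over the whole covered length is
dilution: 50 fixed differences on 100 kb contribute only 5e-4 to the mean.
The same-strain verdict therefore rests on three criteria:

1. distance ≤ `max_distance` (default 0.01),
2. homogeneity of both samples ≥ `min_homogeneity` (default 0.95), where
   homogeneity is the fraction of profiled positions with major-allele
   frequency ≥ 0.9 — "absence of high-frequency SNPs", and
3. fewer than `max_discordant` (default 10) jointly covered positions
   with |Δ VAF| ≥ 0.5 — positions where one sample is near-fixed for an
   allele the other lacks, the signature of "markedly different" profiles.

With error-free planted data the separation is exact: two read sets of
one strain give 0 discordant positions, a 50-SNP sibling gives ~50. Fewer
than `min_joint` (default 50) jointly covered positions yields
"insufficient-overlap" instead of a verdict. All thresholds are
calibration parameters validated on synthetic truth; no published numeric
thresholds exist for this decision. A caveat worth keeping in mind: the
verdict compares the *dominant mapped populations* on the chosen
reference — in mixed communities it speaks about whatever maps, not about
everything present.

## ANI

The fragment convention: the query is cut into consecutive 1020 bp
fragments (trailing fragment kept if ≥ 100 bp); each fragment is placed
at its best ungapped position in the subject via k-mer seeding (k = 16,
seeds every 64 bp, candidate cap 200) on both strands; fragments with
identity ≥ 0.30 over ≥ 0.70 of their length are retained; one direction's
value is the mean identity of retained fragments, and the reported ANI is
the mean of both directions, in percent. Identical genomes give exactly
100.0 (every fragment identity is exactly 1.0; the mean is exact in
floating point). There is no gapped extension, so ANI between genomes
with substantial indel divergence will under-retain fragments rather than
mis-score them; with no retained fragments in either direction the
computation refuses ("no ANI support") instead of reporting a number.

## Expression screen

RPKM follows the standard formula exactly; the screen passes genes whose
condition/control RPKM ratio is strictly greater than `fold` (default 3).
A gene silent in the control but expressed in the condition is flagged
infinitely up-regulated and passes; silent-in-both genes are excluded.
Library sizes (totalNumReads) can be carried as explicit columns of the
count table — the whole library, which a gene subset does not sum to —
falling back to column sums only when absent. Replicate handling defaults
to screening per-condition mean RPKMs; per-replicate screening is a
caller-side loop over the same function.

## Pipeline and determinism

`run_pipeline` executes diversity → core tracing → strain tracing → SNP →
ANI → expression from one YAML config in which every threshold above is a
named key and every stochastic stage has an explicit seed (a missing seed
is a validation error). All reports are TSV; a JSON manifest records
inputs, parameters, seeds, and a SHA-256 checksum per output, and a rerun
with the same config is byte-identical. The demo chain (two sites, 10
samples per matrix, two planted strains on unrelated 10 kb genomes, 1500
reads per group ≈ 15× coverage) is sized to run the full pipeline in a
few seconds while keeping every stage's evidence (coverage ≥ `min_cov`,
breadth ≫ 0.5) comfortably above its thresholds.

## Problem sizes used in validation

Tests and the acceptance suite use deliberately modest sizes chosen so
each check's statistical resolution still exceeds the effect it measures:
planted-plan recovery on 50 random 2-site plans with 3 kb genomes; mapper
and pileup oracle equivalence on 200 randomized instances (0.5–3 kb
references); allele-frequency recovery at ~50× over 100 planted SNPs on a
10 kb reference (binomial 3σ ≈ 0.065 per position, aggregate 3σ ≈ 0.002);
strain-identity separation at ~20× on 20 kb references; ANI checks on
40–200 kb genomes and a ~1 Mb genome in the acceptance script. Scaling
any of these up changes runtimes, not conclusions — the statistics above
say which effects are resolvable at which depth.

## Known limitations

* Ungapped everything: no indels, structural variants, or phasing.
* Taxonomy, OTU picking, and assembly are inputs, not computations.
* Primer specificity is exact-substring screening against a user-supplied
  background, not a database-scale alignment search.
* The Wallace Tm rule ignores nearest-neighbour thermodynamics and salt.
* The same-strain thresholds are synthetic-truth calibrations; applying
  them to real mixed communities warrants the mixed-population caveat
  above.
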