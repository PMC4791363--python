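# Methods

`streampop` re-implements, as a tested library, the desk half of a
hot-spring "streamer"-community metagenome study: recovering population
genomes from assembled contigs and characterizing them. This note
records the models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## Synthetic communities (`streampop.synth`)

The generator exists so that every analysis stage can be exercised
against planted truth without any sequence download.

**Genome model.** Bases are drawn i.i.d. with per-position G+C
probability `gc_target` (G and C equiprobable, likewise A and T).
An optional canonical-k-mer bias layer rejection-samples 100-bp chunks:
a candidate chunk is accepted with probability proportional to the mean
bias weight of its k-mers (best-of-5 kept otherwise). This is the
simplest model that makes composition-based binning both separable and
controllable; it produces no repeats, no skew between leading/lagging
strands, no coding structure. Realized G+C converges to the target at
the binomial rate (sd ≈ 0.0016 at 100 kb); bias weights that are not
G+C-balanced pull the realized G+C off target, so tests that need both
use G+C-balanced word sets.

**Divergence.** `diverge_pair` plants i.i.d. substitutions at rate
1 − identity, each to one of the three other bases uniformly; no indels.
This keeps the planted identity analytic (binomial), which is what makes
the ±1-point ANI recovery claims meaningful. Real conspecific genome
pairs also differ by indels, rearrangement, and gene content — none of
which this models, so passing recovery tests demonstrate the metric
implementations, not robustness to structural variation.

**Contigs and reads.** `fragment_and_cover` places one contig per
equal-length genome block (disjoint by construction) and draws coverage
from a normal around the requested mean — default dispersion 15% of the
mean, exposed as a parameter since realistic dispersion varies with
assembler and depth. Defaults in tests use coverages in the 2–3.5×
range and contigs > 3 kbp, the regime this kind of Sanger-era assembly
produces. Reads are drawn with probability ∝ abundance × genome length,
uniform start, uniform strand, normal length (default mean 820 bp,
sd 120 bp — Sanger-like), substitution-only errors capped at 30%.
No chimeras, no quality values, no length–quality correlation.

**Marker truth.** When catalogs are supplied, a genome retains a
uniformly random subset of exactly `round(f·n)` markers per catalog
rather than i.i.d. Bernoulli(f) keeps. With Bernoulli keeps, the
21-marker catalog alone would give the three-catalog completeness mean
a sampling sd of ≈ 4.3 points, swamping the estimator error the
planted-deletion test is meant to measure; exact-count sampling makes
the planted truth equal the requested fraction up to rounding.

**Surveys.** `simulate_survey` draws site temperature and pH uniformly
over the survey ranges (70–90 °C, pH 7–9 by default) and fills each
site's 16S pool with one variant per phylotype: identity 0.99 to the
reference inside the phylotype's niche window, 0.90 outside (both
configurable). Occupancy is therefore exactly recoverable whenever the
inside/outside identities straddle the calling threshold by a clear gap;
real surveys have primer bias, chimeras, and a continuum of relatives
that this construction deliberately omits.

**Determinism.** Every generator takes a seed and is byte-reproducible.
`stage_rng(master_seed, stage_name)` derives independent per-stage
streams (CRC32 of the stage name mixed into a `SeedSequence`), so adding
a stage never perturbs another stage's draws.

## Composition binning (`streampop.binning`)

Contigs strictly longer than `min_len` (default 3000 bp — the
conventional floor below which tetranucleotide vectors get noisy) are
summarized by canonical k-mer frequencies (k = 4 by default; reverse
complements pooled because contig strand is arbitrary; windows with
ambiguous bases skipped) and projected with PCA. Clustering runs in the
concatenated space of standardized principal coordinates ⊕ G+C ⊕ log10
coverage, with seeded k-means (`n_init=10`).

**Orphan rule.** A contig farther than
`orphan_slack × quantile(within-cluster distances, orphan_quantile)`
from every cluster centre is left unassigned. With the raw 97.5th
percentile as cutoff, 2.5% of a perfectly clean cluster is expelled by
construction, which contradicts the desired behavior that a single
homogeneous population yields one bin with no orphans; the default
slack of 1.5 keeps clean-cluster tails assigned while still expelling
genuinely foreign contigs (in the two-population outlier test a contig
at G+C 0.72 among 0.44/0.29 populations is orphaned).

Manual curation of these plots (and homology screening of bins) is out
of scope; the truth tables serve that role in tests, and an external
annotation table can serve it on real data.

## Read recruitment (`streampop.recruit`)

Each read is aligned in both orientations against every bin's
references; the best hit assigns the read when identity is strictly
> `min_identity` (default 0.90 — the strict reading of a ">90% nt ID"
rule) and at least `min_read_cov` = 50% of the read aligns (a guard
against short spurious seeds; chosen, not prescribed). Equal best
scores in two bins orphan the read: deterministic and conservative,
matching the "Unassigned" semantics of abundance tables. Abundance is
the simple percentage of reads per bin, orphans included, summing
to 100.

## Completeness (`streampop.completeness`)

Completeness is the fraction of a marker catalog with at least one
annotated gene — partial genes count, since a partial single-copy gene
still evidences presence — averaged without weights over three
catalogs (21 tRNA synthetases, 40 universal prokaryotic markers, 178
bacterial housekeeping genes). Marker detection is consumed from
annotation tables, not computed by homology search: gene prediction and
annotation pipelines are upstream of this package. The bundled catalog
TSVs are editable placeholders (the 21 aaRS symbols are standard; the
40- and 178-entry lists carry generic labels) because the published
lists live in external references; on real data, supply catalogs whose
vocabulary matches the annotations. No contamination or duplication
estimate is attempted.

## Identity metrics (`streampop.identity`)

**Aligner.** `local_align` computes an optimal local alignment under a
configurable scoring scheme (nucleotide default +1/−1 with linear −2
gaps; protein default BLOSUM62 with −11/−1 affine gaps). Pairs up to
4×10⁶ DP cells get exact DP (Biopython's C engine); larger pairs are
seeded: exact k-mer hits (k = 15 nt / 5 aa; words occurring > 50 times
in the subject are skipped as repeats) vote for a diagonal band, and
exact DP runs in a ±100-column window around the best band. Identity is
matches / alignment columns (gaps included). The seeded path returns
identical scores to full DP whenever the true alignment lies within the
window — guaranteed for the substitution-only divergence the generator
plants, and property-tested against a brute-force Smith–Waterman.
Ties among co-optimal alignments are resolved deterministically by the
DP engine's fixed traceback order.

**AAI.** Bidirectional best hits between proteomes (candidates
shortlisted by shared 4-mer counts, a BLAST-style word prescreen; ties
broken by lexicographic subject id), retained when identity ≥ 30%, the
alignment covers ≥ 70% of the subject protein, and spans ≥ 100 aligned
residues. AAI is reported as mean ± sd percent identity over retained
pairs. "Similarity" in the 30% filter is implemented as percent
identity — the only reproducible reading. One-way vs bidirectional
best hits is genuinely underdetermined in the field's usage;
bidirectional is adopted as the stricter convention.

**ANI.** The query genome is cut into 1000-bp windows every 200 bp;
each is seed-aligned to the subject; fragments are retained when the
alignment spans ≥ 700 columns, identity ≥ 70%, and ≥ 70% of the
fragment aligns; ANI is mean ± sd of retained fragment identities, and
the result is undefined (None, not an error) below 50 retained
fragments. These are the established fragment-ANI defaults; every
parameter is a keyword argument. Because local alignment trims
mismatch-dense ends, ANI is biased slightly upward at low identity
(≈ +0.3 points at 80%), still inside the ±1-point recovery band.

**16S identity.** Percent identity of the best local alignment
(computed as 100·matches/columns in exact arithmetic, so a 30/1000
variant scores exactly 97.0). Sequences under 200 bases warn but
compute.

## Marker phylogeny (`streampop.phylo`)

Full partitioned maximum-likelihood estimation is external-tool work
and deliberately out of scope; the implementable content is curation,
concatenation, weighting, distances, NJ, support, and CSI scanning.

- **Curation**: a reference genome is retained iff it carries ≥ 16 of
  the 18 marker genes, or is whitelisted.
- **Concatenation**: genes in lexicographic order (determinism); taxa
  missing a gene are gap-filled across that partition; informative
  positions are columns with ≥ 2 distinct non-gap states.
- **Column weights**: (fraction non-gap) × (modal-residue frequency
  among non-gap). This is a deliberate, documented stand-in for
  external alignment-confidence tools, not a reproduction of any of
  them: it down-weights gappy and ambiguously aligned columns with the
  same intent.
- **Distances**: weighted p-distance over mutually non-gap columns,
  corrected for multiple hits by the Poisson-over-s-states formula
  d = −((s−1)/s)·ln(1 − s·p/(s−1)) with s = 20 for proteins; s = 4
  gives the Jukes–Cantor form used for 16S data. Saturated pairs
  (p ≥ (s−1)/s) cap at a configurable maximum (default 10
  substitutions/site).
- **NJ**: textbook agglomeration, ties in Q broken by the
  lexicographically smallest pair of subtree labels, negative branch
  lengths clamped to 0. Correct on additive matrices by construction;
  verified exhaustively against a four-point-condition oracle.
- **Bootstrap**: columns resampled with replacement within each gene
  partition (weights travel with columns); support is the percentage of
  replicates whose NJ tree contains each original bipartition.
- **CSI scan**: flank motifs located in the degapped row; the indel
  call is the residue count strictly between the flanks minus the
  signature's reference span; missing flank → not-found, duplicated
  flank → error (the signature is ambiguous). Signature files are
  user-supplied; none are bundled, since published signature alignments
  are not reproducible from first principles.

## Functional profiles (`streampop.profiles`)

COG matrices are binary over the union of observed COGs (using the full
COG universe would only append all-zero columns, which change Euclidean
distances not at all). For binary rows the Euclidean distance equals
√Hamming. NMDS minimizes Kruskal stress-1 with primary treatment of
ties, by SMACOF with isotonic regression, from 20 seeded random starts
plus one classical-scaling start; stress-1 of each converged
configuration is recomputed independently of the optimizer and the best
is returned. On distances exactly realizable in the target dimension
the classical start already has stress ≈ 0; on a regular 3-simplex
forced into the plane, stress is strictly positive (≈ 0.13). Pathway
completeness is a set fraction; the bundled pathway TSVs (cobalamin
synthesis with 30 genes, glycolysis, TCA, biotin) are editable
resources keyed by gene symbol.

## Ecological distribution (`streampop.survey`)

Occurrence is called strictly: positive iff best pool identity > the
threshold (97% default), so a site at exactly 97.0% is negative.
Temperature or pH ranges in site metadata collapse to their arithmetic
means. The Kruskal–Wallis test uses mid-ranks with the standard tie
correction and a χ²(k−1) p-value; an exact permutation p over all
distinct group assignments is available for total n ≤ 10 (it matches
the exact two-sided rank-sum p for two groups). At n = 5 + 5 the χ²
approximation can miss the exact p by ~0.08 in the mid-range — the
exact option exists for precisely that regime. Pearson correlation uses
the t-transform p-value with n − 2 df.

## Problem sizes

The recovery checks run at sizes chosen to make their tolerances
meaningful on a single CPU: binning at 100 contigs per population from
450-kb genomes; abundance at 10⁴ error-free 820-bp reads over four
200-kb genomes (binomial sd of the largest class ≈ 0.5 points, against
a ±2-point band); ANI on 10⁶-bp pairs (≈ 5000 fragments, fragment-mean
sd ≪ 1 point); AAI on 120 × ~300-aa proteomes; the aligner oracle on
500 pairs of ≤ 200 symbols; NJ on 100 random 4/5-taxon additive
matrices; the Kruskal–Wallis null calibration on 10⁴ replicates of
3 × 15 normals.

## Known limitations

- The genome model has no repeats, codon structure, or GC skew, so
  binning separability is cleaner than on real assemblies.
- Divergence is substitution-only; ANI/AAI behavior under indels and
  rearrangement is untested by design.
- The NJ/bootstrap machinery is a distance-based stand-in; it does not
  reproduce likelihood-based topologies or their support values.
- Placeholder marker catalogs and pathway lists must be replaced with
  study-specific vocabularies for real annotations.
- AAI/ANI are symmetric only to within ~0.5 points (fragmenting and
  best-hit direction are asymmetric by construction).
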