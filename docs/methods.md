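# Methods

This note documents the models, parameter choices and numerical
conventions behind `lncpig`, and what the synthetic-data experiments do
and do not demonstrate.

## Coordinates and sequences

All genomic intervals are 0-based half-open in memory; GTF I/O converts
to and from the 1-based inclusive convention exactly at the file
boundary, and the conversion is an involution.  Transcript sequences are
stored sense-strand (as a stranded RNA-seq assembly provides them);
reverse complementing is always explicit.  `N` bases are carried through
and handled per operation: excluded from GC denominators and Fickett
composition counts, never paired in folding or hybridization, never
counted as alignment matches.

## Identification cascade

Four successive filters, in fixed order, each producing a report with
per-transcript removal reasons so that every input transcript is
accounted for exactly once:

1. class-code exclusion, default `{=, e, p, c}` (annotated or
   near-annotated transcripts); unknown codes are retained;
2. structure: exon count ≥ 2 and length ≥ 200 bp, both boundaries
   inclusive ("shorter than 200 bp" removes 199 and keeps 200);
3. expression: ≥ 10 reads in ≥ 5 samples.  The literature states this
   rule both at identification and at DE filtering; we apply it at both
   stages with the same configurable thresholds;
4. known-database matching (below) splitting survivors into known and
   putative novel lncRNAs.

### Known-lncRNA matching

An in-package seed-and-extend aligner keeps verdicts reproducible
without external binaries.  Shared 11-mers between query (both strands)
and subject define a diagonal band (pad 48); a banded Smith–Waterman
with affine gaps (match +1, mismatch −2, gap open −3, gap extend −1,
open charged on the first gap column) is run inside the band.  Identity
is matches over alignment columns; coverage is the aligned query span
over query length — coverage is defined on the candidate because the
question asked is whether the *candidate* is a known lncRNA.  The
E-value uses the Karlin–Altschul form E = K·m·n·e^(−λS) with fixed
K = 0.1, λ = 1.0; this is a thresholding approximation, not a BLAST
statistic.  A candidate is *known* iff identity ≥ 0.90, coverage ≥ 0.90
and E ≤ 1e−6 for at least one subject.  (The e-value threshold printed
in parts of the source literature as 1 × 10⁶ is vacuous; the stringent
reading 1 × 10⁻⁶ is implemented.)  The aligner is verified against
Biopython's full local aligner under the same scoring.

## Coding potential

Three channels, unanimity required for a noncoding call:

* **CPAT-like** — logistic regression on ORF length, ORF coverage,
  Fickett TESTCODE score and in-frame hexamer usage bias.  The decision
  cutoff is chosen by 10-fold stratified cross-validation: in each fold
  the held-out scores are the candidate cutoffs, the winner maximizes
  Youden's J (ties to the smallest cutoff), and the final cutoff is the
  fold mean.  Stratified folds are used because plain random folds of
  small toy sets routinely produce single-class held-out parts on which
  sensitivity or specificity is undefined.  Note a subtlety: with ties
  resolved downward each fold's winner is the held-out noncoding
  maximum, so the fold-mean cutoff generally sits slightly below the
  global noncoding maximum; the J = 1 guarantee on separable data is a
  per-fold property (and a global one when folds = 1).  A published
  species-specific cutoff (e.g. 0.36 for cattle) can be supplied as an
  override; the trained cutoff is data-dependent by nature.
* **CPC2-like** — logistic regression on Fickett score, ORF length,
  coverage and integrity; fixed cutoff 0.5 (strict `<`).
* **PLEK-like** — regularized linear (logistic) model on the normalized
  1–5-mer spectrum (1,364 features, each k-block summing to 1); the
  signed decision score replaces the original SVM while preserving the
  sign convention (score < 0 ⇒ noncoding).  The heavier ridge (l2 = 1)
  on this channel reflects its dimensionality.

ORF scanning covers the three forward frames only (stranded assembly):
an ORF runs ATG → first in-frame stop (stop included); an ATG without a
downstream in-frame stop scores to the last complete codon with
integrity −1; ties go to the leftmost start.  The Fickett statistic uses
the published position-asymmetry and composition lookup tables and
weights; scores are case- and U/T-insensitive.  Hexamer bias is the mean
natural-log likelihood ratio of in-frame hexamers (frame of the longest
ORF, step 3) between coding and noncoding training tables, with
pseudo-frequency 1e−8 for unseen hexamers.

Logistic channels are fit by ridge IRLS on standardized features with
the penalty scaled per observation (objective: mean log-loss +
l2·‖w‖²), which makes the fit invariant to duplicating every row; the
intercept is unpenalized.  The fit is deterministic.

## Sequence characterization

FPKM = count / (length/1000) / (library_size/10⁶), computed from the
count matrix and per-sample library sizes; a pseudocount of 1e−3 is used
for log₁₀ display only.

Folding uses a Nussinov-style dynamic program over nested structures
with integer pair energies (G:C −3, A:U −2, G:U −1), minimum hairpin
loop 3, optimality ordered lexicographically on (energy, number of
pairs) so equal-energy structures with fewer pairs win; the traceback is
deterministic (right end unpaired preferred, then leftmost partner).
This ignores stacking and loop entropies, so ME/MEN values sit on a
different absolute scale from nearest-neighbor folding programs; the
class *orderings* of MEN, which is what the comparisons use, are
preserved.  Folding is cubic in length, so transcripts longer than
`max_fold_len` (default 250 nt) are characterized by their central
window, and MEN is normalized by the folded length.  The DP is verified
against exhaustive structure enumeration for sequences ≤ 20 nt.

Group comparisons use the Wilcoxon rank-sum test: exact permutation p
(mid-ranks, enumeration over all assignments of the observed data) for
n ≤ 12, otherwise the normal approximation with tie and continuity
corrections.  Class summaries report mean ± SE (SE = SD/√n) with a
compact letter display; classes share a letter when every pairwise p in
the group exceeds the threshold (default 0.01; the 0.05 variant used in
running text is a config option).

## Differential expression

A compact NB workflow for the 5-vs-6 design: median-of-ratios size
factors (rescaled to geometric mean 1; an all-positive reference feature
is required, with a clear error otherwise); method-of-moments dispersion
on normalized counts with group means removed, floored at 1e−8, and by
default shrunk 50/50 toward a fitted a/μ + b trend; closed-form group
means of normalized counts; Wald statistic on log₂(μ_pig/μ_unpig) with
the delta-method variance (1/n_g²)Σ_j(1/(s_j μ_g) + α) per group,
referred to the standard normal.  The normal reference (rather than a
t) was chosen by simulation: with the trend-shrunk dispersion at n = 11
it gives 0.05–0.06 empirical type-I error at nominal 0.05 across seeds
and a uniform null p distribution, whereas a t(9) reference is
conservative (≈ 0.025).  An all-zero group receives the pseudo-mean 0.5
normalized counts (bounded fold changes, configurable); features with
both groups all-zero get log₂FC 0 and p 1.  BH adjustment implements the
step-up formula directly and is cross-checked against statsmodels.

Call regimes: strict (padj ≤ 0.05 ∧ |log₂FC| ≥ 1.5) for lncRNAs,
relaxed (p ≤ 0.01 ∧ |log₂FC| ≥ 1) for target-candidate coding genes —
the asymmetry deliberately widens the pool of candidate targets.

## Target prediction

*Cis*: candidate genes lie within a ±300 kb window (inclusive) of the DE
lncRNA locus, distance being the minimal endpoint gap between spans on
the same chromosome (0 for overlap), strand ignored.

*Trans*: an ungapped antiparallel hybridization scan over all offsets of
the two sequences.  Per offset, pair energies (same integer scale as
folding) are summed over maximal runs of ≥ `min_run` consecutive
Watson–Crick/G:U pairs; shorter runs count as noise and contribute 0.
ndG = dG_min / min(len_lnc, len_mRNA) ≤ 0; the shorter-sequence
denominator is our choice where the literature leaves the normalization
unstated.  Defaults: `min_run` = 20 and threshold ndG ≤ −0.05, in the
package's energy units.  Calibration rationale: with uniform-ish base
composition the per-position pairing probability is 6/16, so short
complementary runs are everywhere — at `min_run` 4 the random
background dominates dG_min and genuine 20-nt antisense segments are
inseparable from shuffled controls; at `min_run` 20 (the canonical
antisense-oligomer scale) a random run is rare enough (~10⁻³–10⁻² per
pair, measured on shuffled sequences) that the statistic is essentially
zero for non-complementary pairs, while any ≥ 20-nt perfect duplex is
always counted.  The widely quoted tool-specific threshold −0.08 is not
transferable to this energy scale; both knobs are exposed in config, and
`min_run` = 1 disables the run filter.

Both modes gate links on co-expression: |Pearson r| ≥ 0.60 with
two-sided t-based p ≤ 0.05, computed on log₁₀(FPKM + 1e−3).  The
magnitude gate reflects that negative correlations are reported and
interpreted (e.g. destabilizing interactions).  Zero-variance profiles
are flagged undefined and never pass.

## Enrichment and qPCR

Enrichment is the one-sided (over-representation) hypergeometric upper
tail per gene set — identical to Fisher's exact test on the 2×2 table —
with BH across sets; sets are intersected with the universe first and
empty intersections skipped.  The universe defaults to the genes that
entered DE testing, a defensible default where the literature is silent;
a two-sided variant is available by flag.

qPCR: technical duplicates are averaged per sample; ΔCt = Ct_target −
Ct_housekeeping; ΔΔCt = mean ΔCt(pigmented) − mean ΔCt(unpigmented);
log₂FC = −ΔΔCt identically, with the reported range from ΔΔCt ± SE.
Group comparison uses Welch's t-test (unequal variances, since group
sizes are 5 and 6).  The concordance report joins RNA-seq and qPCR
log₂FC per validated gene and flags sign agreement.

## Synthetic data

The generator emulates the structure of the study's data at desk scale,
and its defaults are the package's study conditions:

* **Design** — 5 pigmented vs 6 unpigmented samples.
* **Transcripts** — coding: lognormal length (mean 900 nt, σ 0.30),
  built as 5′UTR + ORF + 3′UTR with ORF fraction ≈ 0.55; ORF codons are
  drawn from a fixed synthetic codon-usage table shipped with the
  package (GC-tilted, lognormal weight spread), which gives the hexamer
  and k-mer channels real signal; exon counts Poisson(12.3).
  Noncoding: lognormal length (mean 450 nt, σ 0.35), GC 0.469 vs coding
  ≈ 0.52, stop codons seeded every ~24 nt to suppress ORFs, exon counts
  Poisson(3.8) with a floor of 1.  One synthetic chromosome per 50
  loci, intergenic gaps log-uniform 1–500 kb so the ±300 kb window is
  exercised on both sides.  A configurable fraction (15%) of noncoding
  transcripts gets a lightly mutated copy (3% substitutions) in the
  synthetic known-lncRNA database.
* **Counts** — NB with Var = μ + αμ², α = 0.1; base means lognormal
  with class centers 150 (coding) vs 30 (noncoding), reproducing the
  class expression ordering; planted DE features (half coding, half
  noncoding) receive |log₂FC| ~ U[1.5, 4] split symmetrically between
  groups and a detectable base mean.
* **Cis/trans planting** — pairs are planted only on structurally
  well-formed lncRNAs (≥ 2 exons, ≥ 200 nt), since the cascade excludes
  anything else by design; cis genes are relocated to ≤ 300 kb of the
  lncRNA (decoys just beyond the window), trans lncRNAs receive a
  spliced 20-nt reverse complement of their target mRNA; both members
  of a pair share a per-sample lognormal latent factor (σ 0.5, redraw
  dispersion 0.02) so their expression correlates (r ≈ 0.9 at n = 11).
* **qPCR** — housekeeping Ct ~ N(20, 0.3), ΔCt = gene baseline −
  planted log₂FC (pigmented only) + N(0, 0.25), duplicates with 20% of
  the biological noise.

What passing the synthetic experiments shows: the pipeline's
bookkeeping, thresholds, estimators and gates behave as specified, and
planted signal at realistic magnitudes is recovered with the stated
sensitivity while planted negatives are rejected.  What it does not
show: performance on real assemblies (misassembly, fragmented
transcripts, strand errors, splice-graph complexity, GC-coverage bias
and batch effects are not simulated), absolute agreement with external
tools (CPC2/CPAT/PLEK scores, nearest-neighbor folding energies, BLAST
statistics), or the study's dataset-specific counts, which depend on
the real data and database versions.

## Problem sizes

Default synthetic studies use 300 transcripts (150 + 150) with 60
planted DE features, 6 cis and 6 trans pairs; classifier evaluation uses
300 + 300 training and 500 + 500 evaluation transcripts; DE calibration
uses 2,000 features per regime; recovery experiments use 10 pairs each.
These sizes keep a full verification run within a minute or two on one
CPU while leaving the measured proportions stable across seeds.

## Known limitations

* The Wald test's normal reference is calibrated for the 5-vs-6 design
  with the default dispersion pipeline; markedly different designs may
  need the (config-exposed) shrinkage off-switch rechecked.
* The folding window truncation makes ME incomparable across transcripts
  of very different lengths except through MEN.
* The ndG scale is internal; only orderings and the calibrated gate are
  meaningful, not absolute energies.
* The enrichment stage tests user-supplied gene sets; it ships no
  curated database content.
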