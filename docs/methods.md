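# Methods

`wingnet` re-implements, as a tested and fully specified pipeline, the
integrative transcriptome analysis used to compare wet-season (WS) and
dry-season (DS) butterfly wing forms across four developmental timepoints
(Wr60, PP50, P15, P50): per-stage differential expression of genes and
miRNAs, junction-based differential splicing, miRNA candidate filtering, a
three-method miRNA target consensus, and assembly of a DEG–DEmiR regulatory
network through negative-correlation and opposite-fold-change filters.
Because the real sequencing dataset is not required, every stage is
exercised on synthetic data with planted ground truth; this note records
the models, parameter choices, and their limitations.

## Synthetic data generator

The generator emulates the study design: 2 forms × 4 stages × 4 replicates
(32 libraries), with one library (`DS_rep2_P15`) excluded by default to
mirror the removal of an outlier replicate from all analysis.

**Counts.** Gene and miRNA counts are negative binomial with variance
μ + αμ², dispersions α drawn log-uniform on [0.01, 0.5] and baseline means
log-uniform on [20, 2000] (genes) and [50, 5000] (miRNAs) — overdispersion
and abundance ranges typical of bulk RNA-seq/sRNA-seq. Per sample the mean
is baseline × 2^(±lfc/2 by form at the sample's stage) × a log-uniform
library factor on [0.75, 1.35]. Differential expression is planted per
stage in 10% of genes and 15% of miRNAs with |log2FC| drawn from
{1, 1.5, 2}; these fractions yield DEG/DEmiR set sizes proportionally
comparable to the emulated study.

**Regulation.** 150 miRNA→gene pairs (distinct genes; a miRNA may regulate
several genes) are planted two ways at once. First, the gene's 3′UTR
carries an embedded perfect-complement site — the reverse complement of
mature positions 2..end followed by an A, i.e. a canonical 8mer extended by
full 3′ pairing — so that all three target predictors can, in principle,
detect it. Second, the gene's NB mean is multiplied by 2^(−βz), where z is
the sample's standardized miRNA deviation from baseline (log2 normalized
counts) and β = 2 by default, creating genuine negative cross-correlation
on top of the planted opposite fold changes. Each regulated miRNA receives
planted DE at a random nonempty stage subset (each stage w.p. 0.5) with a
consistent sign, and its target genes receive the opposite sign at the same
stages — persistent form bias across development, matching the observation
that some miRNAs are stage-specific and others are DE across stages. UTRs
are random DNA of length uniform on [300, 600] nt, a realistic range for
insect 3′UTRs.

**Splicing.** 300 events (SE/A5SS/A3SS/MXE/RI) carry form-specific true PSI
values; 20% get a planted form shift of 0.2–0.6. Per sample, the total
junction read count is Poisson (default depth 200) and the inclusion count
is Binomial(total, q) with q = ψ·lI / (ψ·lI + (1−ψ)·lS), the planted PSI
pushed through the effective-length weighting, so the length-corrected PSI
estimator is unbiased for ψ.

**What the generator does not emulate:** GC/length biases, correlated
dispersion structure, isoform-level expression, genomic clustering of
miRNAs, real 3′UTR base composition, or batch effects. Passing tests
therefore demonstrate the correctness and calibration of the pipeline's
logic, not its performance on real libraries.

## Differential expression

Counts are normalized by median-of-ratios size factors (reference features
are those positive in every sample; no pseudo-reference fallback). Per
stage, each feature gets a Wald test of log2FC = log2(WS mean / DS mean) on
normalized counts: the NB variance uses a per-feature method-of-moments
dispersion (within-group pooled), shrunk toward a fitted mean–dispersion
trend a₀ + a₁/μ. The shrink is one-sided: estimates below the trend are
raised to it and estimates above it take the 50/50 average — the standard
guard against luck-driven small replicate variances at n = 4, which would
otherwise make the test anticonservative. The standard error follows by the
delta method, p-values are two-sided normal, and Benjamini–Hochberg
adjustment is applied within stage and feature kind. The fold change is
computed as a difference of logs so that swapping form labels negates it
exactly; an empty group mean is floored at 0.5 normalized counts. No
shrinkage is applied to the fold change itself, so planted effects are
recovered without attenuation beyond sampling noise.

## Differential splicing

PSI per sample is (I/lI) / (I/lI + S/lS); samples with I + S = 0 are
missing for that event. The census filter requires combined junction
support ΣI + ΣS ≥ 20 (an `each` mode requiring both ΣI ≥ 20 and ΣS ≥ 20 is
available) and strict mean PSI inside (0.1, 0.9). For the WS-vs-DS test the
PSI band is not applied — an isoform may exist in only one form — and the
test is Welch's t on arcsine-square-root transformed per-sample PSI, a
variance-stabilizing replacement for the original caller's hierarchical
likelihood model that is fully specifiable and matches a closed-form oracle.
When both groups have zero variance, p = 1 for equal means and otherwise an
exact two-proportion (Fisher) comparison on pooled counts. FDR is BH over
all tested events within a stage, pooled across event types. A gene is a
DSG if ≥ 1 event reaches FDR < 0.05; with several, the event with maximum
|ΔPSI| represents the gene (ties: smaller p, then lexicographic event id).
ΔPSI is reported as mean PSI(DS) − mean PSI(WS).

## Target prediction

Three self-contained predictors, in the spirit of the canonical tool
families, all reading the miRNA 5′→3′ against the UTR 5′→3′ with
anti-parallel complementarity:

1. **Seed classes.** 8mer (WC match to positions 2–8 plus A opposite
   position 1), 7mer-m8, 7mer-A1 and 6mer; the most specific class wins per
   core position.
2. **Duplex alignment.** Local anti-parallel alignment (Gotoh) scored
   match +5, G:U wobble +1, mismatch −3, gap open −9 / extend −4 (a gap of
   length L costs 9 + 4(L−1)); substitution scores are doubled at miRNA
   positions 2–8. A fully complementary 22-mer scores 145.
3. **Accessibility-corrected energy.** ΔΔG = ΔGduplex − ΔGopen.
   ΔGduplex sums nearest-neighbor stack energies over the maximal
   contiguous helix containing the seed (WC stacks −1.0/−2.2/−3.4 kcal/mol
   by pair strength, any wobble −0.5) plus the standard intermolecular
   helix-initiation penalty of +4.1 kcal/mol, clamped at 0 — without
   initiation, a bare 7mer seed helix (~−13 kcal/mol) would pass any
   sensible ΔΔG cut and the filter would not discriminate. ΔGopen is the
   cost of forcing the site single-stranded under a simplified
   pair-stacking secondary-structure model (Nussinov-style minimization,
   minimum hairpin loop 3, only stacked adjacent pairs carry energy),
   evaluated on the site ± 17 nt window; it is nonnegative by construction.

Duplex and energy evaluation are anchored at seed-complementary 6mer cores,
the same pre-filter the alignment-based tools apply; a pair with no
qualifying seed can therefore never reach consensus, which also keeps the
scan over all DEG × DEmiR pairs tractable. A pair is a consensus target
when each method reports ≥ 1 qualifying site (pair-level agreement;
defaults: class ≥ 7mer, duplex ≥ 80, ΔΔG ≤ −10 kcal/mol). Site coordinates
are 0-based half-open internally and 1-based inclusive in files.

## Network assembly

Consensus pairs are filtered for Pearson r < 0 with two-sided P < 0.05
(t reference with n − 2 df) between log2(normalized count + 1) expression
of gene and miRNA across all analyzed samples, pooling stages and forms;
correlation P-values are deliberately left uncorrected across pairs,
reproducing the raw 0.05 cut of the emulated analysis. An edge is emitted
when ≥ 1 stage has both members significant (padj < 0.05) with opposite
log2FC signs; the DEG definition for the network uses padj only (no fold
change cut), with the log2FC > 1 variant available in configuration.
Recovery against planted truth reports precision, recall (denominator:
planted pairs whose members are each DE-called at ≥ 1 stage) and F1, with
precision 1 by convention (flagged) for an empty prediction.

A known property of this cascade, visible in the recovery metrics at the
default scale: chance consensus pairs — a 7mer seed plus a lucky alignment
extension in several hundred nt of UTR — are not rare across tens of
thousands of scanned DEG × DEmiR pairs, and unrelated DE features share
form-by-stage expression structure, so the correlation filter passes them
at well above the nominal rate. End-to-end recall of planted pairs is
essentially complete, while precision is limited by these chance passes;
shortening UTRs or tightening the thresholds raises precision
proportionally. The miRNA-column permutation control (shuffling miRNA
expression across samples) collapses the edge count by an order of
magnitude, confirming that retained edges depend on genuine cross-feature
correlation.

## miRNA census

Candidates are accepted when the discovery score exceeds 3 (strict) and the
hairpin-randomization p-value is below 0.05 (the significance threshold is
configurable; 0.05 is the conventional reading of "significant").
Conservation against a reference mature set is operationalized as an
ungapped alignment of ≥ 18 nt at ≥ 90% identity — reproducible without an
external search engine; redundancy collapsing with the same similarity rule
is offered as an optional pre-step. The 5′ nucleotide profile summarizes
the uridine bias expected of genuine miRNA sets.

## Numerical and design notes

* All randomness flows from named `numpy` Generators seeded from the run
  seed; identical (config, seed) gives byte-identical outputs, and output
  file names embed a hash of the configuration.
* BH adjustment and the Pearson/Welch statistics are authored in-package
  (they are part of the specified surface) and are tested for 1e-10/1e-12
  agreement against statsmodels/scipy references.
* The junction-support reading "a sum of 20 counts for both inclusion and
  skipping junctions" is ambiguous; the combined ΣI + ΣS ≥ 20 reading is
  the default (keeping one-form-exclusive events testable), with `each` as
  an option.
* Degenerate inputs: zero-variance correlation pairs are dropped with a
  logged reason; events with < 2 supported replicates per form are skipped;
  features absent from a matrix are dropped with a warning.
* Problem sizes used by the test-suite simulations (2,000 features for
  calibration, 50-seed replications for sensitivity, the full default
  configuration for end-to-end recovery) were chosen to make Monte-Carlo
  bands tight at interactive runtimes.

## Limitations

Alignment, quantification and hairpin discovery are out of scope — the
pipeline starts from count matrices, junction tables, and candidate
records. The energy model is deliberately minimal (no loop entropies, no
dangling ends, no full Turner parameter set), the target predictors ignore
conservation and 3′-supplementary pairing bonuses, and the DE test omits
outlier refitting and covariates beyond the two-group contrast.
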