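# Methods

`hkscan` analyzes Sort-seq (FACS-seq) deep-mutational-scanning
experiments that probe the partner specificity of a bacterial histidine
kinase. A saturation library of single substitutions in the kinase's
DHp domain is expressed in GFP reporter strains that read out
phosphotransfer to the cognate response regulator (OmpR) or to two
noncognate regulators (RstA, CpxR), with and without the activating
signal. Cells are sorted into bins gated on log10(GFP), each bin is
deep sequenced, and per-variant fluorescence peaks are inferred from
the bin-count profiles. Downstream, the package quantifies cross-talk
gains, classifies variants at fold-change thresholds, and asks whether
cross-talk-inducing residues are depleted among orthologs from species
that carry the paralogous signaling systems.

## Library model

The mutagenesis design replaces one codon at a time with NNS
(N = A/C/G/T, S = C/G): 32 codons covering all 20 amino acids plus the
amber stop TAG. Over a 60-residue domain this defines 19 × 60 = 1,140
amino-acid substitutions. Residues are numbered in full-protein
coordinates (230–289 for the EnvZ DHp), so variant labels such as
`A255R` match the conventional notation.

Variant calling from domain-spanning reads is codon-wise against the
reference coding sequence: reads with length mismatches or ambiguous
bases are rejected (the library is built by codon replacement, so
indels are artifacts); zero mismatching codons — or one synonymous
change — is wild type; one non-synonymous codon is that variant; a
stop codon is tallied under a separate `nonsense` key and excluded from
the 1,140-variant analysis; two or more mismatching codons are
rejected. The rejection policy is this package's choice; sequencing
errors and library escape are not modeled further.

## Synthetic experiment

The generator assigns every variant a class and exact true peak values
(log10 GFP) per reporter and condition:

| class | effect (defaults) |
|---|---|
| neutral | identical to wild type everywhere |
| loss_of_function | cognate +signal output × 0.02 (~50-fold loss) |
| constitutive | cognate −signal state raised 14-fold (to the induced level) |
| crosstalk_gain_R1 / R2 / both | noncognate +signal peak raised by the cross-talk fold (default 30) |

Wild type induces the cognate reporter ~14-fold
(μ_off = 2.20, μ_on = 2.20 + log10 14) and leaves the noncognate
reporters at baseline (2.00). The default class mix mirrors the
composition observed in the real library: 1.8% / 18.1% / 2.5% of
substitutions gaining ≥5-fold cross-talk toward CpxR only / RstA only /
both, 19% losing cognate output beyond 5-fold, 10% constitutive, the
remainder neutral. Effects are applied exactly (no per-variant jitter),
so planted values double as test oracles.

The sort itself draws, per (reporter, condition, replicate):

* one additive log10 shift ~ Normal(0, σ_rep) shared by every variant —
  day-to-day cytometer drift. σ_rep defaults to 0.02: because the shift
  is common to a replicate, its mean over 3 replicates (sd σ_rep/√3 ≈
  0.012) is an irreducible floor on per-variant peak error, and the
  default keeps that floor well under the 0.05 log10 recovery tolerance
  the recovery analyses use;
* uniform-abundance multinomial cell counts over the 1,141 library keys
  (variants + wild type), 2 × 10⁶ cells by default — no abundance or
  fitness model, so deconvolution behavior is isolated;
* per-cell log10 fluorescence ~ Normal(true_mu + shift, σ_cell), with
  σ_cell = 0.4 by default (log-normal cell autofluorescence/expression
  noise; gates are defined on the log10 axis, which is also why the
  downstream fit is Gaussian in log10 units);
* 8 gates evenly spaced between the pooled population's 0.1th and
  99.9th log10-fluorescence percentiles, the outermost bins half-open.
  The wide percentile span emulates a sorter whose detector voltage is
  adjusted until the whole population is on scale. This matters:
  gating at the 1st–99th percentiles leaves ~26% of the cells of a rare
  30-fold-gain subpopulation beyond the top gate, and the density fit
  then overestimates those peaks by ~0.5 log10 (measured in this
  package: full-library recovery within 0.05 log10 rises from 92.6% to
  99.9% when the span is widened);
* per bin, a multinomial read draw over the bin's cell composition,
  10⁶ reads per bin by default (the experiment collected 1–2 million
  reads per bin; recovery analyses here run at 10⁵ to stay fast, which
  is already read-depth-saturated for a 1,140-variant library).

Not modeled: sequencing error, PCR bias, sorting impurity/doublets,
fitness differences during post-sort outgrowth. Passing recovery tests
therefore demonstrates the estimator's statistical behavior under the
stated noise model, not robustness to these artifacts.

## Deconvolution

For variant v in bin b,

    freq(v, b) = reads(v, b) / reads_total(b) × cells_sorted(b) / cells_total,

i.e. the read fraction rescaled by the bin's share of sorted cells;
summed over variants it reproduces each bin's cell fraction exactly,
and summed over bins it estimates the variant's library abundance.
Frequencies are averaged across replicates (mean and sample SD per
bin; a single replicate gets an SD floor of 10⁻⁶ and a QC flag).

Each averaged profile is fit with A·exp(−(x−μ)²/(2σ²)) by weighted
nonlinear least squares (`scipy.optimize.curve_fit`), weights
1/max(SD, 10⁻⁶), at bin centers (midpoints of gate edges; the
half-open outer bins use their inner edge ± half the adjacent bin
width). Initialization is deterministic — μ₀ the frequency-weighted
mean of centers, σ₀ the weighted SD floored at half a bin width, A₀
the profile maximum — with bounds μ within the gate span ± 1 log10
unit, σ ∈ [0.05, 5], and tolerances 10⁻⁸. Fits with fewer than four
nonzero bins, or optimizer failures, return `converged = False` with a
QC flag rather than raising; variants whose mean read total across
bins falls below 20 are flagged `low_coverage` and excluded from
classification. Fitting the Gaussian *density* at bin centers (rather
than bin-integrated masses) is the standard Sort-seq convention and is
accurate while bin widths are comparable to σ and peaks sit inside the
gated span — the regime the gate policy above maintains.

Fold induction compares the +signal and −signal peaks. Two modes ship:
`linear` (default), the linear-units fluorescence ratio
10^(μ_on − μ_off); and `literal`, the raw ratio μ_on/μ_off of the two
log10-scale means. The literal ratio of logarithms is dimensionally
odd but is retained because both conventions appear in the field; the
mode is recorded in the output metadata.

## Cross-talk scoring

All comparisons are against the wild-type row of the same run:
Δ = μ_variant − μ_WT (log10, +signal). Cross-talk toward a noncognate
regulator X is normalized by the cognate response:

    score(X) = Δ_X − max(0, Δ_OmpR)        ("clip", default)
    score(X) = Δ_X − Δ_OmpR                ("raw")

Clipping subtracts only cognate *increases*, the stated purpose of the
normalization being to remove nonspecific gains in expression or
overall kinase activity; subtracting cognate losses would manufacture
spurious cross-talk for damaged kinases. Both modes are config-exposed
because the published arithmetic is not fully specified.

Classification is inclusive (score ≥ log10 t) at thresholds 3, 5 and
10-fold, which makes the calls monotone in the threshold by
construction. Overlap counts (X-only, Y-only, both) partition the
called sets. "Reduced fold induction" is the strict comparison
FI(variant) < FI(WT) with no margin (config-exposed); note that under
the synthetic model roughly half of the exactly-neutral variants fall
on either side of wild type's own noisy estimate, so this summary is
informative only when real effects dominate. Position profiles export
a 20 × L matrix (amino acids in fixed alphabetical order) with
wild-type cells at zero and per-position residues rank-ordered for
logo rendering, ties broken alphabetically.

## Ortholog-constraint statistics

Reference residue positions are mapped to alignment columns by walking
the reference row and skipping its gaps; insertion columns carry no
reference position and are ignored. A substitution's ortholog count is
the number of non-reference rows (optionally filtered to species
carrying both paralogous systems) with exactly the mutant residue at
the mapped column; gaps never count.

The constraint analysis compares the count distributions of
cross-talk-inducing vs non-inducing substitutions with a two-sided
two-sample Kolmogorov–Smirnov test (exact null for min(n, m) ≤ 25,
asymptotic otherwise) and compares complete absence (count = 0) with a
two-sided Fisher's exact test on the 2 × 2 of
(cross-talk, non-cross-talk) × (present, absent) — an odds ratio below
1 means cross-talk residues are more often absent. The Fisher
two-sided p sums hypergeometric probabilities no larger than the
observed table's (the probability-mass rule); the reported odds ratio
is the unconditional sample OR (ad)/(bc), flagged when infinite or
undefined. The enrichment statistic contrasting species groups is

    enrichment = count_without − count_with × (n_without / n_with),

zero under exactly proportional per-species rates. The
corresponding-residue test pools, over the CpxR- and RstA-directed
comparisons, a 2 × 2 of (mutant equals the other kinase's residue at
the aligned position) × (variant cross-talks at the 5-fold threshold)
and applies Fisher's test; the pairing of the two equal-length domains
is gapless by default, with an explicit correspondence accepted.

### Synthetic alignments and calibration

The alignment generator draws, per column, a baseline residue
distribution Dirichlet(α = 5) over the 20 amino acids (an optional
`conservation` weight can be mixed onto the reference residue; the
default is 0). In species flagged as carrying both systems, the
frequencies of designated cross-talk residues are multiplied by the
depletion factor and the column renormalized; species lacking a system
sample the baseline (relaxed selection), which also makes the planted
enrichment positive. Species rows are independent draws — no
phylogeny — and duplication flags are Bernoulli, more probable where
the systems are missing.

The dispersed, unconserved default baseline is a deliberate trade: the
KS test assumes continuous data, and substitution counts are integers,
so the null calibration of the constraint test (depletion = 1 →
uniform p-values) holds only when the count support is wide relative
to the sample sizes. With conserved/sparse baselines the counts tie
heavily at 0–2 and the test turns conservative; with the default
baseline and 10,000 species the null p-values pass a Kolmogorov
uniformity check comfortably, and at 1,000 species a planted depletion
of 0.2 is rejected at α = 0.01 in every calibration seed. Real
alignments are more conserved (and their many absent residues are what
the presence/absence Fisher test feeds on); the calibration results
therefore validate the machinery, not the discreteness regime of real
data, and analyses of sparse baselines should expect conservative KS
p-values.

Because the bundled reference sequences are deterministic synthetic
stand-ins (the deposited domain sequences are not shipped), every
position-level conclusion drawn from the defaults is about the
machinery, not about EnvZ itself; externally supplied FASTA regions
and alignments drop in through the documented readers.

## Problem sizes used by the test suite and acceptance script

Full-library analyses run at 1,140 variants, 8 bins, 3 replicates,
10⁵ reads per bin and 2 × 10⁶ cells; multi-seed recovery properties
use a 114-variant sub-domain at 10⁴ reads per bin over 20 seeds; the
null calibration uses 200 alignment seeds at 10,000 species and the
power study 100 seeds at 1,000 species. These sizes reproduce the
saturated-read-depth regime of the experiment while keeping a full run
in minutes.

## Known limitations

* No modeling of sequencing error, PCR amplification bias, sorting
  impurities, or growth-rate selection during outgrowth.
* The Gaussian density-at-center fit is biased for peaks pinned at the
  outermost half-open bins; such fits carry QC flags rather than being
  corrected.
* KS p-values on heavily tied counts are conservative (see above).
* The corresponding-residue test's gapless domain pairing assumes the
  two DHp domains align end to end; supply an explicit correspondence
  when they do not.
* The duplication-association analysis uses the per-species flags as
  given; no phylogenetic correction for shared ancestry is attempted.
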