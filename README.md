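# hkscan

Analysis of Sort-seq (FACS-seq) deep mutational scans of histidine-kinase
partner specificity: from binned read counts to per-variant fluorescence
peaks, cross-talk classification, and ortholog-based constraint
statistics — with a synthetic-data generator that emulates the whole
experiment so the pipeline runs and is testable without any downloads.

## The problem

Bacterial two-component systems pair a histidine kinase (HK) with its
cognate response regulator (RR). Specificity lives largely in the HK's
DHp domain; a single substitution there can redirect phosphotransfer to
a noncognate RR ("cross-talk"). A Sort-seq experiment measures this at
scale: a complete single-substitution library over the 60-residue DHp
domain (19 × 60 = 1,140 variants, built with NNS codons) is expressed in
GFP reporter strains reading out the cognate regulator (OmpR) and two
noncognate regulators (RstA, CpxR), grown ± signal, sorted into 8 bins
gated evenly on log₁₀(GFP), and each bin is deep sequenced.

`hkscan` implements the analysis:

1. **Deconvolution.** For variant *v* in bin *b*,
   `freq(v,b) = reads(v,b)/reads_total(b) × cells_sorted(b)/cells_total`;
   replicate-averaged profiles are fit with a Gaussian
   A·exp(−(x−μ)²/2σ²) in log₁₀(GFP) by weighted least squares, giving
   each variant's peak μ per reporter and condition, and fold induction
   10^(μ_on − μ_off).
2. **Cross-talk scoring.** Δ = μ_variant − μ_WT (+signal); the score
   toward a noncognate regulator X is Δ_X − max(0, Δ_OmpR), i.e.
   normalized by nonspecific cognate gains; variants are classified at
   inclusive 3/5/10-fold thresholds and summarized as overlap sets,
   heatmap matrices and ranked logo profiles.
3. **Evolutionary constraint.** Substitution counts at the equivalent
   aligned positions of HK orthologs are compared between
   cross-talk-inducing and non-inducing residues (two-sample KS test;
   Fisher's exact test on complete absence), plus the species-scaled
   enrichment statistic
   `count_without − count_with × n_without/n_with` and the
   corresponding-residue association test.
4. **Synthetic data.** A seeded generator plants ground-truth variant
   classes and effect sizes, simulates log-normal cell fluorescence,
   percentile-gated sorting and multinomial sequencing, and builds
   ortholog alignments with configurable depletion of cross-talk
   residues — every downstream stage has a parameter-recovery oracle.

Bundled reference sequences are deterministic synthetic stand-ins;
real regions, count tables, deposited per-variant mean tables and
alignments drop in through the documented FASTA/TSV/CSV readers.

## Worked example

```python
from hkscan import simulate as sim, deconvolve as dec, scoring

region = sim.default_reference_region()            # 60-aa DHp stand-in, 230-289
truth = sim.generate_ground_truth(region, seed=1)  # classes + true peaks
table = sim.simulate_sort_experiment(truth, sim.SortConfig(reads_per_bin=100_000, seed=1))
measurements = dec.deconvolve(table)               # per-variant Gaussian fits

wt = measurements.query("variant == 'WT' and reporter == 'OmpR'").iloc[0]
print(f"wild-type OmpR peak (+signal): {wt.mu_on:.3f} log10 GFP, "
      f"fold induction {wt.fold_induction:.1f}")

scores = {r: scoring.crosstalk_scores(measurements, r) for r in ("CpxR", "RstA")}
calls = {r: scoring.classify_crosstalk(s)[5.0] for r, s in scores.items()}
only_c, only_r, both = scoring.classify_and_overlap(calls["CpxR"], calls["RstA"])
print(f"5-fold cross-talk: {only_c} CpxR-only, {only_r} RstA-only, {both} both")
```

prints

```
wild-type OmpR peak (+signal): 3.345 log10 GFP, fold induction 13.6
5-fold cross-talk: 21 CpxR-only, 206 RstA-only, 28 both
```

The wild-type kinase induces its cognate reporter ~14-fold; the
deconvolved peak recovers the planted 13.6-fold within fit noise. The
overlap triple recovers the planted class mix exactly: of 1,140
substitutions, 21 gain ≥5-fold activity toward CpxR only, 206 toward
RstA only and 28 toward both — single substitutions readily create
cross-talk, the signature of marginal specificity.

## Command line

```sh
hkscan run --config config.yaml          # simulate -> deconvolve -> score ->
                                         # classify -> evo-stats -> summary.json
hkscan simulate   --config config.yaml   # or run the stages individually:
hkscan deconvolve --counts out/counts.tsv --bins out/bins.tsv
hkscan score      --measurements out/measurements.tsv --norm-mode clip
hkscan classify   --calls out/crosstalk_calls.tsv --threshold 5
hkscan evostats   --alignment aln.fasta --species species.tsv \
                  --calls out/crosstalk_calls.tsv
```

All tables are `#`-headed TSV carrying the tool version, seed and
config hash; the YAML config is schema-checked before any stage runs.

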