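# imseg

Detection and characterization of **intermediate DNA methylation (IM)
regions** from paired MeDIP-seq / MRE-seq read-count tracks.

Most CpGs in a differentiated cell population are either fully methylated or
fully unmethylated. A minority of loci — imprinting control regions, many
enhancers and exons — sit stably in between, at ~50–60% methylation. Two
complementary enrichment assays expose such loci: MeDIP-seq reads come from
methylated DNA, MRE-seq reads from unmethylated restriction sites, so a
genuine IM region shows *simultaneous* signal in both. `imseg` is for
epigenomics analysts who have per-CpG count tracks from both assays and want
calibrated IM region calls plus the standard follow-up analyses: a
multi-sample reference list, allele-specific vs allele-independent
classification at heterozygous SNPs, and chromatin/expression comparisons of
IM against fully methylated/unmethylated regions.

## The segmentation model

Each CpG *i* with normalized read densities (mᵢ, rᵢ) contributes a signed
score increment

    δᵢ = +w·min(mᵢ, rᵢ)   if mᵢ > 0 and rᵢ > 0      (assays overlap)
         −w·max(mᵢ, rᵢ)   if exactly one is > 0     (one-sided signal)
          0               otherwise

penalized by λ·(posᵢ − posᵢ₋₁) for the distance to the previous CpG
(defaults w = 1, λ = 0.01/bp). IM calls are the disjoint **maximal scoring
subsequences** of the penalized sequence (Ruzzo–Tompa): inside a maximal
segment the cumulative score peaks at the last CpG, so every call ends at
its highest-scoring position and its score is the running maximum. Before
scoring, MeDIP totals are library-size normalized to 50 M reads and MRE
totals to 35 M.

Score and length cutoffs are not fixed a priori: the paired (m, r) count
tuples are randomly reassigned to the observed CpG positions, detection is
re-run on each shuffled track, and the least stringent cutoff pair whose
estimated false-positive rate (shuffled passing calls / observed passing
calls) drops below 1% is selected. Per-sample calls merged within 100 bp
across samples, supported by ≥ 2 samples and ≥ 100 bp long form the
reference IM set.

At a heterozygous SNP inside an IM region, the 2×2 assay × allele table
separates allele-specific methylation (ASM: ≥ 75% of MeDIP reads on one
allele, ≥ 75% of MRE reads on the other, two-sided Fisher exact P < 0.01)
from allele-independent methylation (AIM: both assays ≤ 70% major-allele
fraction, P > 0.01).

## Worked example

The built-in generator plants a ground-truth methylome — 50 IM regions
(Poisson rates 4/4 per assay) among 50 methylated (8/0.1) and 50
unmethylated (0.1/8) regions in a bimodal background — then the pipeline
calibrates itself against shuffles and is scored against the truth:

```python
from imseg import DetectionParams, apply_filters, calibrate_cutoffs, detect_im
from imseg.simulate import (default_benchmark_config, evaluate_recovery,
                            simulate_counts, simulate_genome)

config = default_benchmark_config(seed=1)          # 50 IM + 50 M + 50 U regions
truth = simulate_genome(config)
track = simulate_counts(truth, config)
params = DetectionParams(medip_target=track.medip.sum(),   # counts already on
                         mre_target=track.mre.sum())       # the normalized scale

calib = calibrate_cutoffs(track, params, n_shuffles=100, seed=1)
print(f"calibrated cutoffs: score >= {calib.chosen_min_score}, "
      f"length >= {calib.chosen_min_length} bp (est. FPR {calib.fpr_estimate:.2%})")

calls = apply_filters(detect_im(track, params),
                      min_score=calib.chosen_min_score,
                      min_length=calib.chosen_min_length,
                      enforce_length=True)
result = evaluate_recovery(calls, truth)
print(f"{len(calls)} IM calls: precision {result.precision:.2f}, "
      f"recall {result.recall:.2f}, median boundary error "
      f"{result.median_boundary_error:.0f} bp")
```

prints

```
calibrated cutoffs: score >= 9.5, length >= 200 bp (est. FPR 0.85%)
48 IM calls: precision 0.98, recall 0.94, median boundary error 0 bp
```

The calibration lands close to the score cutoff of 8.0 used on real data,
the estimated false-positive rate is under 1%, and 94% of the planted IM
regions are recovered with essentially exact boundaries.

The same steps are available from the shell:

```sh
imseg simulate --seed 1 --out-prefix sim/
imseg calibrate --counts sim/track.tsv --shuffles 100 --seed 1 \
    --no-normalize --out sim/calib.json
imseg detect --counts sim/track.tsv --no-normalize --min-score 9.5 \
    --min-length 200 --enforce-length --out sim/calls.bed
```

Other subcommands: `reference` (multi-sample reference set), `allelic`
(ASM/AIM SNP and region calls), `profile` (binned signal around regions),
`exonexp` (relative exon expression), `enrich` (CpG-level overlap
enrichment), `distmat` (Jaccard/Canberra sample distances). Every run
writes a `*.manifest.json` with the resolved parameters and seed.

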