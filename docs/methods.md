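# Methods

## Scope and data model

`imseg` operates downstream of alignment: its inputs are per-CpG read
densities from MeDIP-seq (methylated DNA immunoprecipitation) and MRE-seq
(methylation-sensitive restriction enzyme digestion), already deduplicated
and mapping-quality filtered, as a 4-column `chrom pos medip mre` TSV.
Coordinates are 0-based half-open throughout; a CpG position is the cytosine
of the CG dinucleotide on the forward strand, with counts strand-collapsed.
The package does no BAM parsing, alignment, bisulfite processing or genotype
calling.

## Library-size normalization

Per sample, MeDIP densities are rescaled so the assay total equals 50 M
reads and MRE densities so their total equals 35 M (both configurable in
`DetectionParams`). Normalized densities stay real-valued — re-rounding
would distort low counts, and nothing downstream requires integers. The
asymmetric targets reflect the typical sequencing depth ratio of the two
assays and put the per-CpG scores of differently sequenced samples on a
common scale, which is what makes a single score cutoff transferable across
samples.

## The segmentation score

There is no canonical likelihood for "both assays fire here", so the score
is a designed statistic with two requirements: it must grow with co-occurring
signal and stay on the read-density scale so cutoffs are interpretable.

* Reward `+w·min(mᵢ, rᵢ)` when both assays are positive: overlapping
  evidence is only as strong as the weaker assay, and a CpG with counts
  (50, 1) should not look like strong IM evidence.
* Penalty `−w·max(mᵢ, rᵢ)` when exactly one assay is positive: a strong
  one-sided signal is strong evidence for a fully methylated or fully
  unmethylated state.
* Zero when both are silent: absence of reads is not evidence either way;
  such CpGs only cost the distance penalty.
* Distance penalty `λ·gap` between consecutive CpGs keeps segments from
  leaking across CpG deserts. The default λ = 0.01/bp makes the 100 bp
  merge scale (below) cost one score unit, so spatial coherence is priced
  in the same units as one read of evidence.

`w` defaults to 1.0 and is exposed; both constants live in
`DetectionParams`.

## Maximal scoring segments

IM calls are the disjoint maximal scoring subsequences of the penalized
increment sequence `xᵢ = δᵢ − gapᵢ`, computed per chromosome with the
Ruzzo–Tompa linear-time list algorithm. This is deliberately not the naive
"reset the running sum at zero" sweep: the naive sweep drops internal
segments in nested configurations (after a strong start, a later positive
run can be absorbed into a candidate whose peak it never beats, e.g.
`[5, −4, 3, −4, 5]`, where the middle `[3]` is a maximal segment in its own
right). The test suite checks equivalence against an exhaustive
extract-the-maximum-interval-and-recurse oracle on random sequences.

Two structural properties of maximal segments match the intended call
semantics: the cumulative score attains its maximum at the segment's last
element (otherwise a prefix would score higher), so each call ends at its
highest-scoring CpG (`end = peak + 1` half-open) and its reported score is
the running maximum; and all proper suffixes have positive sum, so a call
never starts on non-positive evidence. The first CpG of a segment still
pays its entry gap penalty, making the score independent of how the
surrounding background is laid out.

## Cutoff calibration against paired shuffles

The null model preserves everything about a track except spatial
arrangement: the paired `(medip, mre)` tuples are permuted over the observed
CpG positions, keeping the pairing (a CpG with overlapping signal keeps its
overlap — what the shuffle destroys is the *clustering* of such CpGs).
Detection runs on the observed track and on each of `n_shuffles` permuted
tracks (1,000 by default; 100 in the desk-scale benchmark, which is already
stable to ±0.2 percentage points across seeds). For each cutoff pair on a
grid (min score 1–20 in 0.5 steps × min length {0, 100, 200} bp) the
estimated false-positive rate is

    FPR = mean over shuffles of passing shuffled calls / passing observed calls

and the least stringent pair with FPR below the 1% target is chosen,
ordering the grid by score first. If no grid point qualifies — observed
indistinguishable from shuffled — the most stringent point is returned with
a `degenerate` flag rather than an arbitrary pass. Null score and length
distributions, shuffle count and seed are recorded in the result.

On the planted benchmark the calibration selects a score cutoff of
8.5–9.5 depending on seed, bracketing the cutoff of 8.0 established on real
data by the same procedure.

## Reference set assembly

Per-sample calls are pooled, transitively merged when gaps are ≤ 100 bp,
and kept when supported by ≥ 2 distinct samples and ≥ 100 bp long — the
length filter is applied here, at the reference stage, not to raw
per-sample calls. Support counts *cluster membership*, not pairwise overlap
(the weaker and simpler of the two readings; with a 100 bp merge radius the
difference is marginal). Regions that already carry a support count
contribute it unchanged, which makes re-assembly idempotent — a property
the tests enforce.

## ASM / AIM classification

All rules operate on the 2×2 assay × allele table at a SNP.

* **Heterozygosity**: ≥ 9 reads in each assay, ≤ 100 MRE reads (PCR-bias
  guard), and each allele reaching ≥ 30% of MeDIP reads *or* of MRE reads.
  The per-allele-across-assays reading is essential: at a true ASM locus
  each assay is nearly allele-pure, so requiring both alleles at 30% within
  one assay would veto exactly the SNPs the ASM test exists for.
* **ASM**: MeDIP major-allele fraction ≥ 75%, MRE fraction of the
  *opposite* allele ≥ 75% (the "variant allele" requirement is read as: the
  MRE majority must be the allele the MeDIP assay disfavours), and
  two-sided Fisher exact P < 0.01 on the cross-assay table. The cross-assay
  table is used (rather than one test per assay against an unknown
  expectation) because allele segregation *between* assays is the ASM
  phenomenon itself.
* **AIM**: both assays' major fractions ≤ 70% (exact 50/50 ties count as
  0.5) and Fisher P > 0.01.

The 70%/75% gap plus the opposing P-value cutoffs make the two statuses
mutually exclusive; SNPs in the gap are `het_unclassified`. Fisher's exact
P is the tie-inclusive two-sided hypergeometric sum (computed via scipy and
verified against exact rational enumeration over all tables with margins
≤ 15). A region is ASM when it contains ≥ 2 ASM SNPs and no AIM SNP
(symmetrically for AIM); regions with both kinds are flagged
`ambiguous_ignored`. dbSNP membership filtering is the caller's
responsibility — any SNP table is accepted.

## State comparison utilities

* A region is *unmethylated* in a sample when ≥ 75% of its CpGs each carry
  ≥ 4 MRE reads and zero MeDIP reads; *methylated* under the mirror rule.
  The 75% rule is per-CpG — the only reading under which "75% of CpGs" is
  well-defined — and the two per-CpG conditions are mutually exclusive, so
  no region can satisfy both.
* Signal profiles: RPKM (reads × 10⁹ / (length × library size)) in 100 bp
  bins tiling ±5 kb around each region centre, reads assigned by midpoint
  (avoids double counting); per-bin mean ± SEM replaces presentation-layer
  curve smoothing, which is rendering rather than inference.
* Associations: transcripts by TSS-to-nearest-edge distance ≤ 10 kb, exons
  by interval gap ≤ 1 kb (edge distance, 0 when overlapping; region
  midpoints would misrank long regions).
* Relative exon expression is the plain ratio R_e / R_t of exon to parent
  transcript RPKM; transcripts with R_t = 0 are excluded. A log or
  otherwise normalized variant would not change the rank-based group
  comparisons used downstream.
* Group comparisons use the two-sided Wilcoxon rank-sum test — exact for
  combined n ≤ 20 without ties, normal approximation with tie correction
  otherwise.
* Sample distances: Jaccard on binary IM presence/absence, Canberra on read
  counts, with average-linkage clustering; CpG-level overlap enrichment of
  two region sets is scored against a null that relocates one set's regions
  (lengths preserved) uniformly within each chromosome's CpG span, with a
  +1-corrected permutation P and a companion χ² on the 2×2 coverage table.

## The synthetic-data generator

`imseg.simulate` is the test substrate: it plants a known methylome and the
pipeline is scored against it.

* **Layout**: regions are laid left-to-right, each a run of CpGs with
  geometric inter-CpG gaps (mean 40 bp inside regions vs 120 bp in the
  background — region CpGs are clustered, as in real CpG-dense IM loci).
  The benchmark plan is 50 IM + 50 M + 50 U regions of 10 CpGs each in
  seeded random order (~350 bp per region, the scale of typical IM
  regions), ≈ 4,500 CpGs in total.
* **Counts**: independent Poisson per CpG and assay with state means IM
  (4, 4), methylated (8, 0.1), unmethylated (0.1, 8). Counts are generated
  directly on the normalized read-density scale, so detection uses
  normalization targets equal to the track totals (identity rescaling).
* **Background**: bimodal, mirroring a real methylome — each background CpG
  is fully methylated with probability 0.70, fully unmethylated with 0.25,
  otherwise silent at rate (0.1, 0.1). A silent-only background is
  unrealistic and materially easier *and* harder in the wrong ways:
  adjacent IM regions bridge through it (no negative evidence between
  them), while the shuffle null loses the strong one-sided counts that
  dominate real tracks.
* **Allelic tables**: per planted IM region, SNPs draw binomial
  allele counts — ASM scheme: MeDIP favours one allele at purity 0.95 and
  MRE the other (purity < 1 exercises the 75% threshold realistically;
  which allele is methylated is random, exercising label symmetry); AIM
  scheme: both assays at 0.5.
* **Expression tables**: one transcript (TSS within 5 kb upstream) and one
  overlapping exon per planted region; transcript RPKM log-normal with
  log-means ln 30 / ln 10 / ln 3 for U/IM/M and σ = 0.8; exon inclusion
  Beta(9,1) / Beta(6,4) / Beta(3,7) for M/IM/U, so inclusion is ordered
  opposite to expression.
* **Recovery scoring**: a call matches a planted IM region at ≥ 50%
  reciprocal overlap (standard in differentially-methylated-region
  benchmarking), matched one-to-one greedily by overlap; boundary error per
  pair is the mean of start and end offsets, reported as the median over
  pairs.

All generator draws derive from a single seed through named independent
streams (genome, counts, allelic, expression), so every artefact is
bit-reproducible and the streams can be varied independently.

**What passing these tests shows — and does not.** The generator emulates
clustered CpGs, state-dependent paired counts, bimodal background, allelic
segregation and state-ordered expression. It does not model fragment-level
read structure, GC or fragment-size bias, enzyme-site availability for MRE,
overdispersion (Poisson, not negative binomial — an extension hook exists),
copy-number variation, or correlated noise between assays. Recovery of
planted regions therefore validates the algorithmic machinery and its
calibration logic, not performance on any particular real library.

## Numerical choices and degenerate inputs

* Segment closure uses `running score ≤ 0`; per-chromosome processing means
  no segment spans a chromosome boundary.
* Zero-total assays cannot be normalized (error); unnormalized tracks fed
  to the scorer warn rather than fail, since raw-scale scoring is legitimate
  when targets are set to the totals.
* Calibration with zero observed calls is an error (the FPR ratio is
  undefined); a pure-noise track yields the `degenerate` flag.
* Regions without CpGs get state `neither` with a warning; allelic
  correlation with < 3 shared SNPs is an error and zero-variance input
  returns NaN with a warning rather than an arbitrary sign.
* Fisher's exact test on an all-zero table is an error; degenerate margins
  give P = 1.
* Benchmark problem sizes (≈ 4,500-CpG tracks, 100 shuffles, 500 SNPs per
  allelic scheme, 300 genes per expression group) keep the full suite and
  the acceptance script fast while leaving all statistical margins wide.

## Known limitations

* The reward/penalty constants (w, λ) are design choices, not fitted
  quantities; cutoff calibration absorbs moderate changes to them, but
  scores from different (w, λ) settings are not comparable.
* The cross-assay Fisher table is one of several defensible test choices at
  ASM loci; per-assay binomial tests against an external allele-frequency
  expectation would require genotype likelihoods this package does not
  model.
* Reference-set support counts cluster membership, not reciprocal overlap;
  heavily chained merges can accumulate support from samples whose calls do
  not mutually overlap.
* The overlap-enrichment null relocates regions independently and uniformly,
  ignoring chromatin domain structure; against strongly clustered region
  sets the null is conservative about long-range structure.
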