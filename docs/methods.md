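# Methods

## Data model and coordinates

Genotypes are a dense individuals × markers byte matrix with four codes
(HOM_A, HET, HOM_B, MISSING); ~80 × 60,000 cells fit in ~5 MB. Allele
letters map to codes per marker in alphabetical order. The HOM_A/HOM_B
distinction is an I/O convention only: MAF, the HWE test and ROH calling are
all symmetric under swapping the homozygote labels (asserted by label-swap
tests). PED text format does not record an allele that was never observed,
so a marker seen only as one homozygote re-reads as HOM_A; round-tripping is
exact for any matrix read from disk and for matrices where both alleles are
observed.

All internal coordinates are 1-based inclusive base pairs, matching the way
ROH and island intervals are conventionally printed; BED export converts to
0-based half-open (`start−1`, `end`). Marker maps are strictly sorted by
(chromosome, position) and duplicate positions are rejected, which is what
lets every windowed computation treat chromosomes as contiguous slices.

## Quality control

Samples with call rate below the threshold (default 0.95) are removed first,
on the full marker set; SNP call rates are then computed on the surviving
samples and SNPs below their threshold (default 0.95) are removed.
Comparisons are strict (`<`), so a call rate of exactly 0.95 is kept. The
order is configurable (`QCParams.samples_first`). Rationale for
sample-first: a dropped sample never lowers the call rate of the SNPs it was
missing at, so removing bad samples first rescues SNPs rather than the
reverse. (Note the unconditional form of that monotonicity is false —
dropping a sample *called* at SNP j moves j's rate from c/n to
(c−1)/(n−1).) QC is applied to each group independently in the two-group
pipeline; there is no cross-group step before island intersection.

## MAF and the exact Hardy–Weinberg test

MAF is min(p, 1−p) with p estimated from non-missing genotype counts;
"polymorphic" means MAF > 0 within the group under analysis. The spectrum
report bins polymorphic markers into (0, 0.1], …, (0.4, 0.5] by default
(configurable), with MAF = 0 as its own class.

The HWE test is the exact conditional test: given n individuals and the
observed allele counts, the heterozygote count n_AB has probability
proportional to `n! / (n_AA! n_AB! n_BB!) · 2^n_AB`; the two-sided p-value
sums the probabilities of all admissible heterozygote counts no more
probable than the observed one (computed in log space via log-gamma,
normalised, with an lru-cache on (n, allele count)). Homozygote excess is
declared when observed heterozygotes < 2pqn — the classical expectation; the
conditional-mean alternative differs by O(1/2n) and would change no
reported percentage at study scale. Default alpha is 0.05 with no
multiple-testing correction, since the summary reports raw percentages of
markers out of equilibrium. The exact test is conservative: its null
rejection rate at n = 70 is ~0.03 at alpha = 0.05 (measured by the
acceptance script), which is expected behaviour for exact conditional tests
at moderate n, not an error.

## ROH calling

The caller reproduces PLINK `--homozyg` semantics. Only windows fully
contained in a chromosome are counted; a SNP's hit fraction is the share of
qualifying windows among the windows containing it, so SNPs near chromosome
ends see fewer windows. A SNP whose own call is heterozygous is never inside
an ROH regardless of its hit fraction; missing SNPs may be interior but are
trimmed from run boundaries (also after gap-splitting). Candidate runs are
split at adjacent-SNP gaps > 1 Mb and kept when they hold ≥ 50 SNPs, span
≥ 1 Mb and average ≤ 50 kb per SNP. Window geometry (50 SNPs, ≤ 1
heterozygote, ≤ 1 missing, ≥ 50 SNPs per run) is the published protocol for
this class of study; the remaining four filters are PLINK 1.9 defaults and
all are exposed on `ROHParams`. The phrase "at least 50 SNPs per window" in
such protocols is read as the minimum SNP count per ROH (`--homozyg-snp`);
the alternative reading is reachable through `window_snps`.

Segment length is `end_bp − start_bp + 1` (1 bp longer than PLINK's
`end − start`; immaterial at Mb scale). Length classes are left-closed
([0,2), [2,4), [4,8), [8,16), [16,∞) Mb), so a 4.0 Mb segment falls in the
4–8 Mb class. Class coverage is 100 · (summed class length / n
individuals) / L, so class coverages and counts sum to the totals row
exactly.

Correctness is established against a brute-force oracle — explicit
enumeration of every window, plain-Python run chaining — on 200 random
fixtures with randomised parameters (plus 25 more inside the unit suite);
the two implementations agree exactly on all of them.

One behavioural consequence of window attenuation: at the boundary of a true
homozygous block, edge SNPs are covered by progressively fewer qualifying
windows, so called runs typically start 1–2 SNPs inside the true block.
Recovery tests therefore check coverage of block interiors, not exact edges.

## Incidence, cores and islands

The incidence track counts, per SNP, the individuals whose ROH cover it
(overlapping segments of one individual count once) and standardizes
genome-wide within the group — one threshold per group, as a single
Manhattan-plot line. The island threshold is the empirical
(1 − top_fraction) quantile (linear interpolation, `numpy.quantile`) of the
z scores, default top 1%; qualifying SNPs must *strictly* exceed it, so ties
at the threshold are excluded. Core ROH are maximal runs of consecutive SNPs
carried by ≥ 2 individuals (the minimum-carrier parameter is exposed; the
≥k-carrier-run rule is a documented approximation to consensus-ROH
machinery). Islands are maximal runs of ≥ 3 consecutive SNPs that are both
above threshold and inside a core, never spanning chromosome boundaries,
with bounds at the first/last SNP positions. Cross-group conserved islands
are pairwise same-chromosome intersections with ≥ 1 bp overlap.

A geometric constraint worth knowing: if hotspot SNPs make up ≥ 1% of the
genome's markers, the top-1% quantile lands *inside* the hotspot plateau and
the strict inequality suppresses the islands. This is inherent to the
top-percentile rule, not an implementation artifact; the simulated island
fixtures keep planted SNPs below 1% of the map for this reason.

## Two-group comparison

Group means of ROH count and F_ROH are compared with a pooled-variance
Student t test (df = n_A + n_B − 2) by default — the convention implied when
two-group studies of this design report df = n_A + n_B − 2 — with Welch as
an option. Two zero-variance groups with equal means return t = 0, p = 1.
The relative change of mean F_ROH is 100 · (mean_A − mean_B)/mean_A,
reported to the nearest integer percent; F_ROH and coverages are reported to
2 decimals. Each group is treated as one sample (no within-group generation
structure). Reports are deterministic: identical inputs and config yield
byte-identical TSVs.

## Synthetic data

The gene-dropping simulator draws founder haplotypes SNP-independently from
per-SNP frequencies (uniform on [0.05, 0.5] by default), then drops them
through an arbitrary pedigree with Poisson crossover counts per chromosome
(default 1 Morgan), uniform crossover positions and no interference.
Identity-by-descent is tracked by founder-haplotype labels, so every truly
autozygous interval is recorded as a truth segment before noise; identical
founder haplotypes share one label (a fully homozygous founder is itself
autozygous and transmits that state). Noise is injected after truth
recording: heterozygote errors at 0.2% per SNP *inside* IBD segments — the
error mode the caller's one-heterozygote allowance exists to absorb — and
1% missingness overall. Defaults mirror a 60k porcine array: 18 autosomes ×
125.88 Mb × 3420 SNPs (2265.77 Mb, ~37 kb spacing).

The planted-segment generator writes shared homozygous intervals into an
i.i.d. background (default 35% heterozygosity) for a chosen carrier
fraction; it gives exact ground truth for island-recovery tests.

What the simulations do **not** emulate: linkage disequilibrium beyond what
pedigree transmission induces, ascertainment bias of array SNPs, allele
frequencies structured along the genome, genotyping error outside IBD
segments, and selection. Passing recovery tests therefore demonstrates that
the detection chain is correct under its stated model, not that real data
will show the same recall.

## Validation problem sizes

Chosen as the package's own desk-scale validation design:

* caller/oracle equivalence: 200 random single-chromosome fixtures of 30–300
  SNPs with randomised window/filter parameters;
* pedigree F_ROH recovery: 20 seeds × 8 full-sib lines × 2 offspring on 20
  chromosomes × 1 Morgan × 100 Mb × 2500 SNPs; the grand mean of called
  F_ROH must sit within ±0.05 of the pedigree expectation 0.25 (measured
  ≈ 0.24: window attenuation and sub-threshold short IBD bias the call
  slightly downward, as expected for 50-SNP/1 Mb filters);
* island recovery: 20 seeds × two 50-individual groups on 6 chromosomes ×
  2500 SNPs, 70-SNP hotspots (~2.8 Mb) at carrier fraction 0.8; shared-island
  recall ≥ 0.95 with zero islands on the three uniform-background
  chromosomes (measured: recall 1.0, specificity clean);
* HWE exactness: implementation p-values agree with an exact-rational
  enumeration for every polymorphic genotype triple with n ≤ 30, and the
  null rejection rate at n = 70 over 10,000 simulated markers stays below
  alpha + 3·SE.

## Known limitations

* Binary PLINK (BED/BIM/FAM) and VCF input are not supported; convert to
  text PED/MAP first.
* The consensus "core ROH" rule is the ≥k-carrier-run approximation; tools
  that pool segments differently may shift core boundaries by a few SNPs.
* The top-percentile island rule is scale-sensitive (see the ≥1% plateau
  note above); with very few segregating hotspots the empirical quantile is
  grainy on small maps.
* Sex chromosomes are excluded by design; ploidy-aware calling is out of
  scope.
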