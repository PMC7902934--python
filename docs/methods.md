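# Methods

This note records the models and estimators carpiscan implements, the
design choices made where several defensible options existed, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducing its output.

## Data model and coordinates

All coordinates are 0-based half-open internally; conversion to the 1-based
inclusive convention happens only when reading or writing VCF/GFF (BED is
already half-open). Windows are `[k·step, k·step + size)` clipped at the
contig end; a window is emitted iff its start lies inside the contig, and
final partial windows are kept (their true length is used wherever a length
denominator is needed). Genotypes are diploid allele-index pairs; a call is
either fully present or fully missing (half-calls are demoted to missing on
input). Contig identifiers are opaque strings.

## Variant filtering

Hard filters follow the standard GATK recommendations for callsets without
a recalibration truth set. A SNP is removed if ANY clause fires:
QD < 2.0, FS > 60.0, ReadPosRankSum < −8.0, MQ < 40.0, MQRankSum < −12.5,
SOR > 3; indels use QD < 2.0, ReadPosRankSum < −20.0, FS > 200.0. All
inequalities are strict, so boundary values pass. A missing annotation
means the clause is not applicable and cannot fire — GATK omits the
rank-sum annotations at sites without heterozygous carriers, and treating
absence as failure would silently discard most homozygous sites.

Site-level filtering removes sites with QUAL < 50, with pooled site depth
(the DP field) above 3× or below ⅓× the mean site depth, and with more
than two alleles observed across samples. The depth clause needs depth
information and raises rather than silently skipping. The pooled-depth
reading was chosen over a per-sample one because DP is the annotation a
joint-called VCF actually carries; the per-sample variant can be supplied
through the `site_depth` argument.

SNPs at or within 5 bp of an indel are removed, with distance measured
between POS anchors (not the indel span): the anchor is the only
unambiguous coordinate for an indel and the convention is configurable
through the `radius` argument.

Relatedness pruning uses the PLINK allele-sharing IBS, (IBS2 + IBS1/2) per
mutually called site, and greedily removes one member of each pair above
0.9: the member of the worst pair with the higher mean IBS (ties broken
toward the lexicographically later id). Greedy one-per-pair removal mirrors
the usual practice of dropping a single member of each duplicate pair.

## Diversity

Per-site pairwise diversity is the unbiased 2j(n−j)/(n(n−1)) for j derived
copies among n called alleles; the windowed statistic divides the sum over
SNPs by the full window length in bp, assuming non-variant positions are
callable (the VCFtools `--window-pi` convention). A per-variant-site mode
exists behind the `per_site` flag.

Tajima's D uses the full 1989 normalisation; its constants are derived in
`tajima_constants` and cross-checked in the tests against an independent
derivation (a₁ = 11/6, e₁ = 0.005510, e₂ = 0.002690 at n = 4). D is
undefined (NaN, never 0) without segregating sites. With missing data a
window's haploid size n is the modal per-site called-allele count and sites
below 80% of it are dropped; each retained site contributes its own
per-site pairwise value to the numerator. This keeps the constants
consistent with a single n while discarding only heavily missing sites;
both thresholds are arguments.

Individual heterozygosity is the observed fraction of heterozygous calls.
This is a deliberate simplification: no sequencing-error model is fitted
(as a maximum-likelihood estimator such as mlRho would), so on real
low-coverage data the estimate is biased upward by genotype error. On
synthetic genotypes the two coincide; the tests validate the binomial
sampling behaviour only.

Folded site-frequency spectra use a fixed haploid size (twice the
population's sample count) and exclude sites with missing calls in the
population; the joint 2D spectrum folds on the total minor allele. A
hypergeometric down-projection was considered and not implemented — the
synthetic data is complete-call, and projection would be untested code.

## Divergence

Per-site variance components follow Weir & Cockerham (1984): a (among
populations), b (among individuals within populations), c (within
individuals), computed from diploid counts, allele frequencies and observed
heterozygote frequencies. The windowed statistic is the weighted
(ratio-of-sums) estimator Σa / Σ(a+b+c), which is the standard choice for
scans; negative values are reported as computed. Monomorphic or
single-population sites contribute nothing. Outlier calling standardises
window values and flags upper-tail P < α (divergence scans seek high
values); the α of 0.05 follows the screening threshold used in practice,
with 0.01 for the stricter outlier maps.

## Introgression

The four-taxon test uses population derived-allele frequencies:
ABBA = (1−p₁)p₂p₃(1−p₄), BABA = p₁(1−p₂)p₃(1−p₄), and
D = Σ(ABBA−BABA)/Σ(ABBA+BABA). Polarisation takes the (possibly pooled)
outgroup's major allele as ancestral and by default excludes sites where
the outgroup is polymorphic or missing (`max_outgroup_freq` relaxes this).

f_d replaces the donor by whichever of P2/P3 has the higher derived
frequency at each site, in both numerator positions of the denominator:
f_d = Σ(ABBA−BABA) / Σ(ABBA_D−BABA_D). Windows with D < 0 report f_d as
missing — the estimator only measures an ABBA excess — while genome-wide
summaries keep the signed value so a no-introgression genome shows a value
near zero rather than a censored one.

Significance comes from a delete-one block jackknife over contiguous
blocks of approximately equal informative mass (default 50 blocks):
SE² = (m−1)/m · Σ(t_i − t̄)², Z = D/SE, two-sided normal p. Blocks with no
informative sites are dropped; identical leave-one-out values are flagged
degenerate rather than yielding an infinite Z.

## Haplotype selection (EHH / iHH / XP-EHH)

Genetic positions default to the 1 Mb = 1 cM physical proxy used when no
recombination map exists. EHH is the unconditional sample homozygosity used
by the cross-population statistic: at extension x it is the probability
that two random haplotypes are identical over all SNPs strictly between the
core and x inclusive, so EHH(0) = 1 by the empty-interval convention
(allele-partitioned EHH, as in iHS, is not what XP-EHH integrates). Curves
truncate when EHH drops below 0.05, at gaps above 200 kb, or at the contig
end; the first sub-threshold point is included in the trapezoidal integral.
iHH sums both directions. XP-EHH is computed as ln iHH_obs − ln iHH_ref —
a log difference rather than a log of the ratio, so swapping panels flips
the sign bit-exactly. Positive scores mean longer haplotypes (a selection
signal) in the observed panel.

Panels must be fully phased with no missing calls; construction raises
otherwise. A minor-allele-frequency cutoff (`min_maf`, computed over all
samples so both panels keep one site grid) is available and recommended at
0.05, the usual default of EHH tools: very rare variants carry almost no
haplotype-homozygosity information but each singleton column splits one
haplotype off its class, eroding precisely the long shared haplotypes the
statistic looks for.

Window aggregation standardises the per-SNP scores genome-wide, averages
them per window, and flags two-sided outliers at α per tail (positive tail:
observed population; negative: reference). No allele-frequency binning is
applied in the normalisation — the statistic is cross-population.

## Copy-number differentiation

Integer copy numbers are median-ratio calls:
CN = round(ploidy · depth / median window depth of the sample), with an
optional GC correction that first divides by the median depth of windows in
the same 1%-GC bin. This transparent per-window estimator deliberately
replaces segmentation-based CNV calling (breakpoint search, ploidy
optimisation, smoothing): for window-level differentiation scans the
segmentation machinery adds parameters without changing the per-window
quantity being compared. Gene values are means over the windows a gene
overlaps.

V_ST = (V_T − V_S)/V_T with V_T the pooled copy-number variance and V_S the
size-weighted mean within-population variance, all with denominator N, and
is reported unclamped. Significance: population labels are permuted per
gene (sizes preserved, independent permutations per gene, vectorised over
permutations), the threshold is the 99th percentile of the 1,000 permuted
values, and a gene is significant iff its observed V_ST strictly exceeds
the threshold. The "99% of 1,000 repeats" reading is the per-gene
percentile (the convention of the CNV-differentiation literature this
follows); a global-max mode would be stricter and is not the default.
Mapping a fixed V_ST cutoff to a p-value (e.g. 0.42 ⇔ P < 0.005) is
data-dependent and therefore never hard-coded.

Gene-level gain/loss classification: on rounded gene CN, duplicated iff
CN ≥ ploidy+1, absent iff CN = 0, reported as per-population means.

## Population structure

Distances are allele-sharing distances 1 − IBS computed from genotypes
directly rather than from a consensus-sequence alignment — equivalent in
spirit for biallelic SNPs and far cheaper. Neighbor joining follows
Saitou–Nei with the Q-matrix; ties break toward the lowest index pair, and
a negative branch is clamped to zero with the excess moved to its sister so
the pair sum is preserved. The output is an unrooted (trifurcating-root)
newick tree plus its non-trivial bipartitions. Bootstrap support resamples
SNP columns with replacement and reports the recovery percentage of each
full-data bipartition. PCA operates on mean-imputed dosages, column-centred
and by default scaled by √(p(1−p)) (the smartPCA convention); monomorphic
sites drop out.

## Synthetic data

The generator defines the conditions under which every claim in the test
suite is evaluated; all generators are bit-reproducible under a seed and
emit a truth record sufficient to recompute the expected statistics.

**Anchors.** Generation time 15 y and mutation rate 3.75×10⁻⁸ /site/y give
μ = 5.625×10⁻⁷ per generation; a divergence time of 1.20 My is 80,000
generations; per-site diversity near 0.0057 implies N_e ≈ 2,500 diploids.
`carpinus_preset()` records these natural-scale values, and `rescaled()`
shrinks any configuration by λ (sizes and times divided; μ, r, m, s
multiplied) preserving 4Nμ, 4Nr, 4Nm and T/N.

**Balding–Nichols genotypes** draw ancestral frequencies uniform on
(maf_floor, 1−maf_floor), population frequencies Beta(p(1−F)/F,
(1−p)(1−F)/F) and genotypes Binomial(2, p_i). F is the expected
Weir–Cockerham F_ST, making this the parameter-recovery fixture for the
divergence module.

**Wright–Fisher engines.** Two engines share one demographic model
(population splits from a common ancestral lineage, per-generation
migration as a fraction of parents drawn from a donor, a one-generation
admixture pulse, genic selection 1+s per derived copy at one site):

- The *count engine* iterates exact per-site binomial sampling of allele
  counts with symmetric recurrent mutation. It is exact for unlinked sites
  and fast for 10⁴–10⁵ of them; sites that are uniformly lost or fixed in a
  population and its donors are advanced through an equivalent pooled
  binomial (the sum and uniform allocation of i.i.d. binomials), which is
  what makes genome-sized site counts affordable. Sampling at the end
  draws gene copies without replacement per site and scatters them over
  haploid slots — valid only because sites are unlinked, which is why this
  engine never feeds haplotype statistics.
- The *haplotype engine* evolves full haplotype matrices with
  Poisson-crossover meiosis (a compiled kernel, with a pure-numpy
  reference path) and per-base mutation. Its burn-in runs in two phases:
  allele frequencies are burned in at the count level for the full 10·N_anc
  generations, haplotypes are then assigned at linkage equilibrium, and a
  linked phase (default min(2N, …), shorter in the sweep preset) builds the
  LD structure — pairwise LD at distance d equilibrates within roughly
  1/(2rd) generations, so haplotype statistics at the distances
  recombination can reach are at stationarity at a fraction of the cost.

**Sweeps** are hard by construction: the site is cleared of standing
variation and re-seeded with a single copy, and the run is retried from the
pre-sweep state until the final frequency lands in a configured band.
Without the clearing step, conditioning on a high end frequency strongly
enriches for soft sweeps from standing variation, which carry almost no
haplotype signature. Two further desk-scale constraints shaped
`sweep_preset`: the mutation rate must stay low enough that hitchhiking
mutations do not fragment the founder haplotype within the sweep's
footprint, and the population size must be large enough (N = 200) that the
reference population's own recent coancestry does not mimic sweep-length
haplotypes.

**Quartet preset** (`quartet_preset`): four populations of 50 diploids on
the ladder ((P1,P2),P3),O with splits at 0.2, 1.0 and 3.0 coalescent units
and sample sizes (9, 13, 31, 2) mirroring the study design. Per-site θ is
compressed to 0.08 so 50,000 candidate sites carry the informative-site
mass of a genome-scale SNP set — at the study's per-site diversity a
50,000-site panel would resolve f_d to only ±0.02, the scale of the effect
being tested. The admixture pulse arrives two generations before sampling
so the admixed fraction is measured before drift erodes it.

**Neutral preset**: one population of 50 diploids, θ = 0.006 per site
(matching the focal species' diversity scale), 100,000 candidate sites on a
100-bp grid tiling 200 windows of 50 kb.

**CNV depths**: genes tiled on one contig; per sample the true gene CN is
the population mean plus rounded Normal(0, 0.7) noise floored at zero
(inter-individual CN variability is what makes the permutation null
effectively continuous — with near-constant integer CN the per-gene
permutation distribution collapses onto a handful of values and percentile
thresholds misbehave); the per-base CN is the gene CN inside genes and the
ploidy elsewhere, windows carry their per-base mean, and depth is Poisson
over reads (read length 100 bp), which sets the realistic noise floor.

**What the generators do not emulate**: sequencing and alignment error,
genotype-calling bias and allele-balance artefacts, linked selection
outside the single planted sweep, GC and mappability structure in read
depth, gene conversion, and any spatial population structure. Passing
tests therefore demonstrate the correctness and calibration of the
estimators under their model assumptions, not robustness to the artefacts
of real resequencing data.

## Problem sizes

The heavy validation experiments run at: 50,000 sites × 40 diploids for
F_ST recovery; 100 replicates of the 50,000-site quartet for the D/f_d null;
200 windows × ~500 sites for the neutral calibration; 500 + 200 genes ×
1,000 permutations for V_ST; and 50 replicates of a 1-Mb sweep contig plus
a 3-Mb neutral contig at N = 200 for XP-EHH power. These sizes keep each
claim statistically sharp (binomial confidence bounds well inside the
tolerances) at desk scale.

## Known limitations

- The count engine's recurrent-mutation model slightly distorts the site
  frequency spectrum at high per-site θ (multiple hits); the quartet preset
  accepts this for frequency-difference statistics, the neutral preset
  keeps θ low where spectrum shape matters.
- Heterozygosity is uncorrected for genotype error (see above).
- The overlap test reads "Yates' correcting t-test" as the Yates
  continuity-corrected chi-square — no t-statistic applies to a 2×2 table.
- Window flags carry raw z-based p-values; no multiple-testing correction
  is applied (an optional Benjamini–Hochberg column is a one-liner with
  `scipy.stats.false_discovery_control` on any track's `p` column).
- f_d systematically underestimates the admixture fraction when the donor
  substitution's maximum inflates the denominator (visible at f = 0.1 in
  the recovery experiments, which still lands within ±0.05 absolute).
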