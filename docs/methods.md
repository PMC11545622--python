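# Methods

## The problem

Island colonisation subjects a population to a bottleneck and a new
selective regime. Contrasting an insular population against its
mainland counterpart genome-wide asks three questions of each region:
is it unusually differentiated (F<sub>ST</sub>), does differentiation
come with a loss of absolute diversity (the recurrent-selection
signature: F<sub>ST</sub> peaks over d<sub>xy</sub> and π valleys), and
does haplotype or relatedness structure point at a recent sweep or a
segregating inversion? `islescan` implements this scan stack for small
panels (≈9–12 diploids per population, ~18× short-read depth) and pairs
it with a generator that plants each signature so recovery is testable.

## Site filtering

Variant records: indels and multi-allelic sites are dropped; individual
genotypes are masked to missing when depth lies outside [10, 40] or
GQ < 30; records are then dropped when the minor allele count (on the
masked record) is below 2 or more than 25% of genotypes are missing.
Invariant records carry no allele-count rule. Filters are applied
per-genotype first and per-record second, matching the semantics of the
standard VCF filtering tools these rules come from.

A deliberate choice: the depth mask and the missingness cap are applied
to invariant sites as well, although convention only demands the GQ
mask there. π and d<sub>xy</sub> denominators count genotyped sites of
both classes, so masking them identically keeps the denominators
comparable and avoids inflating them with effectively unsequenced
sites. Records whose DP/GQ fields are absent are treated as passing —
missing metadata is not evidence of bad data.

## Windowed estimators

Windows tile each chromosome from position 1 (default 10 kb,
non-overlapping; the terminal window may be short). Undefined values
propagate as NaN, never as 0; a window is undefined exactly when its
denominator is empty (π, d<sub>xy</sub>) or S = 0 / n < 4 (Tajima's D).

- **π, d<sub>xy</sub>** — ratio of sums of per-site difference and
  comparison counts over *all* genotyped sites; this is the
  invariant-site-aware estimator, robust to missing data because each
  site contributes exactly the pairs actually genotyped.
- **F<sub>ST</sub>** — Weir & Cockerham (1984) variance components
  a, b, c per biallelic variant site (two populations, diploid, unequal
  and per-site sample sizes), window value Σa / Σ(a+b+c). The window
  ratio-of-sums, not the mean of per-site ratios, is the standard
  windowing. Hudson's estimator (Bhatia et al. 2013 form) is available
  behind the same interface (`fst_estimator="hudson"`); the default is
  `wc84`.
- **Tajima's D** — computed from S (segregating sites with ≥2 called
  genotypes) and summed per-site heterozygosity. With missing data the
  allele count varies by site; the a₁…e₂ constants are evaluated once
  per window at the rounded harmonic mean of per-site allele counts,
  which keeps the statistic well defined without imputing genotypes.

## Sweep scan (XP-EHH)

EHH at marker *x* is the fraction of haplotype pairs identical at every
marker from the core through *x* (the core's own alleles included),
computed over *all* haplotypes of a population — the site variant used
by cross-population scans, which compare populations rather than
alleles at the core. EHH at the core is 1 by convention; the curve is
truncated when it falls below 0.05 (points below the threshold are
excluded, so a panel already diverse at the first flanking marker
integrates to 0, and a panel of identical haplotypes integrates to its
physical span). iES is the two-sided trapezoidal integral over bp.

XP-EHH = ln(iES<sub>island</sub>/iES<sub>mainland</sub>) per core SNP;
cores with either integral zero are dropped; scores are standardized
over all scanned cores genome-wide (no frequency binning) and converted
to two-sided normal p-values; −log10 p ≥ 3 is called significant.
Fewer than 50 scannable cores is refused — there is no usable null.
Significant cores within 100 kb (configurable) of a window with zero
mean depth are flagged as likely artifacts: peaks hugging unsequenced
spans are a known failure mode of haplotype scans near centromeric or
repeat-rich sequence.

Phasing is not implemented; panels come from the simulation truth or a
pre-phased VCF. Sites with any unphased or missing call are excluded
from the panels rather than imputed.

## Outlier calling and landscape classification

Each landscape statistic is Z-scored over its defined windows and
converted to a normal p-value — upper tail for F<sub>ST</sub>, lower
tail for d<sub>xy</sub> and π, two-sided for Tajima's D (all
configurable; the choice of tails is a design decision, since the
convention only prescribes "Z-scores, then p-values"). Rejection is
Benjamini–Hochberg at FDR 0.05. Merged F<sub>ST</sub>-high regions are
called `recurrent_selection` when at least 50% of their windows are
simultaneously d<sub>xy</sub>-low and π-low (either population)
outliers. The 50% co-occurrence fraction operationalises a visual
"coincidence" criterion; it is exposed in the config. Negative
Tajima's D is recorded as corroborating evidence but not required — it
is too population-specific to gate on.

## Inversion detection

Local PCA per non-overlapping 1000-SNP window (all samples pooled,
per-SNP mean-centred, missing set to the SNP mean; terminal windows
under half size dropped). Windows are compared by the Frobenius
distance between their scale-normalised rank-2 covariance
approximations λ₁u₁u₁ᵀ + λ₂u₂u₂ᵀ: raw PC score vectors are sign- and
rotation-unstable, the rank-2 approximation is not, so this is the
well-defined reading of "distance between the first two PCs". Classical
(Torgerson) MDS embeds the distance matrix into 40 axes; per axis,
windows beyond 4 SD from the mean are outliers; runs of outlier windows
(gaps ≤ 3 bridged) on one chromosome form candidates, with boundaries
at the first and last outlier window. A permutation test (1000
reassignments of windows to chromosomes preserving per-chromosome
totals) reports whether an axis's outliers concentrate on particular
chromosomes; it is reported per (axis, chromosome) but does not gate
validation by default (`require_permutation` enables gating), since the
validation checks are the decisive evidence.

Validation per candidate: (1) PCA of region genotypes, k-means (k = 3)
on PC1 with deterministic initial centres at the minimum, midpoint and
maximum of the score range — the three clusters are the two homokaryotypes
and the heterokaryotypes; (2) mean per-individual heterozygosity must
be strictly highest in the middle cluster (heterokaryotypes are
heterozygous at every orientation-diagnostic site); (3) mean composite
r² (pairwise-complete genotype correlation squared, evenly subsampled
to ≤200 SNPs) must reach 0.3. "High LD" is qualitative in the source
procedure; 0.3 is the package's default and is config-exposed. Status
is `putative_inversion` iff all three hold — the method flags
recombination anomalies and cannot by itself distinguish an inversion
from other causes of suppressed recombination.

## The synthetic generator

What it emulates: two diploid populations diverged from a common
ancestor, with the island bottleneck expressed as a larger drift
parameter. Ancestral allele frequencies follow a density ∝ 1/x
truncated to [1/2N, 1−1/2N] (N = 50 by default), the discrete-neutral
spectrum's continuous analogue; population frequencies follow
Balding–Nichols Beta distributions with parameters (p, F). Haplotypes
are independent Bernoulli draws given the population frequency,
genotypes are haplotype sums, invariant sites are interleaved at their
own density, depth is Poisson (mean 18) with zero-coverage gaps forcing
missing genotypes, and genotypes are additionally missing at a small
rate (2%). Parametric generation was chosen over coalescent machinery
because it has closed-form expectations — the genome-wide
Weir–Cockerham F<sub>ST</sub> of a two-population draw is ≈ F, which the
tests exploit directly — and runs at desk scale. Defaults: 12 + 12
diploids, F<sub>island</sub> = 0.3, F<sub>mainland</sub> = 0.05
(island π < mainland π, genome-wide F<sub>ST</sub> ≈ 0.18), variant
density 0.01/bp, invariant density 0.02/bp.

Planted features:

- **sweep(s)** — a fraction *s* of island haplotypes in the region is
  replaced by copies of one founder haplotype; the mainland is
  untouched. s = 1 zeroes island π over the region; s = 0.9 leaves the
  island polymorphic but with a long near-fixed haplotype, the XP-EHH
  power case.
- **inversion(q, d)** — two orientation pools fixed for opposite
  alleles at a fraction *d* of region SNPs; karyotypes AA/AB/BB drawn
  at frequency *q*; both of an individual's region haplotypes drawn
  whole from its karyotype's pools (no recombination between pools).
  Each pool holds 2 founder haplotypes by default: orientations descend
  from single inversion events, so near-clonal orientation classes —
  and hence region-wide elevated LD, not just LD among the
  *d*-divergent sites — are the realistic structure. Planting at q = 0
  is a strict no-op. Per-sample karyotypes go into the truth ledger.
- **recurrent(r, k_div)** — region variant density thinned by keeping
  every r-th SNP (removing polymorphism in both populations, the
  ancestral-selection component) plus k_div sites redrawn near-fixed
  for alternate alleles (island 0.97 / mainland 0.03, the
  post-divergence component). r = 1, k_div = 0 is a no-op; k_div alone
  is the F<sub>ST</sub>-peak-without-valley negative control.

What the generator does **not** model: linkage between neutral sites
(background LD is zero outside planted regions), recombination maps,
mutation-rate calibration, gene conversion, linked selection, or
window-wise phasing artifacts. Passing tests therefore demonstrate that
each detector recovers its target signature and stays quiet on this
clean null — not that power and false-positive rates transfer to real
genomes, where background LD and demography inflate both.

## Numerical choices and degenerate inputs

- Missing data sentinel −1 throughout; undefined statistics are NaN and
  are excluded from (not coerced into) downstream Z-scores and FDR.
- Z-scoring a constant or nearly-empty vector raises a degenerate-input
  error rather than emitting infinities.
- K-means on PC1 with fixed centres is deterministic; the permutation
  test and the generator consume explicit seeds (per-chromosome
  substreams spawned from the master seed), making the whole pipeline
  byte-reproducible for a fixed config. Output files carry the config
  hash and seed in a header comment and contain no timestamps.
- MDS axes with non-positive eigenvalues are zeroed; 4-SD outlier
  flagging guards zero-spread axes.
- TSV floats are printed with 17 significant digits so write/read round
  trips are exact.

## Problem sizes in the bundled study and checks

The worked example and the acceptance computations run on 1.5–3-Mb
chromosomes with ~15 variants/kb post-filter, 100-SNP local-PCA
windows, 20 seeded replicates for sweep recovery, 20 null runs for
inversion specificity, and 10 replicates for the recurrent-selection
classifier; these sizes give stable rates while keeping a full run in
minutes on one CPU. The estimator layer itself is size-agnostic.
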