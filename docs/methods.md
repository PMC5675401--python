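# Methods

## Coordinate model

A locus is a single uppercase DNA string with a 1-based array coordinate and
a designated TSS position. All reported coordinates are TSS-relative and
skip zero: the TSS maps to +1 and the base immediately upstream to −1, the
convention used in locus studies whose figures and tables print "+1" at the
bent arrow. Internally every computation uses array coordinates; the
conversion is a bijection applied only at I/O boundaries. Feature intervals
(BED 0-based half-open on input) are stored inclusive TSS-relative.

## Cytosine context classification

On the top strand a cytosine at position i is CG if base i+1 is G, CHG if
i+1 ∈ {A,C,T} and i+2 is G, and CHH if both i+1 and i+2 are in {A,C,T}. The
bottom strand applies the same rules to the reverse complement, i.e. reading
at decreasing array positions from a reference G. Any required base that is
N or beyond the sequence end yields UNKNOWN, and UNKNOWN sites are excluded
from every downstream tally — exclusion is the conservative choice when the
window is uninformative.

## Bisulfite clone model and estimator

Clones are gap-free, amplicon-length Sanger reads of one bisulfite-converted
strand; only the read strand is analyzed per amplicon, as nested-PCR
amplicon sequencing reads a single bisulfite strand. Clones are stored in
read-strand orientation so the readout rule is uniform: C → methylated,
T → unmethylated, anything else → ambiguous (excluded from numerator and
denominator; a clone whose ambiguity rate exceeds 10% of sites is flagged in
the profile but kept). The per-context percent pools all clones of one plant:
100 · m/(m+u). Sub-region tallies assign each site by membership of its
TSS-relative position in the named interval, so partitioning an amplicon
into sub-regions and recombining reproduces the whole-region counts exactly.

Genotypes are compared at the plant level: the replicate percents are the
observations of a two-sided, equal-variance Student's t-test (significance
P ≤ 0.05, mean ± SE reported; SE = sd/√n over plants). The classical
equal-variance form is used rather than Welch because two replicates per
group make Welch degrees of freedom degenerate. With a single plant in
either group the comparison is reported without t/P and flagged. When both
groups are constant and equal the test is reported as t = 0, P = 1 (scipy
returns NaN for zero pooled variance). Per-site fractions for plotting are
clone-pooled across replicates by default (replicate-averaged values can be
derived from the per-replicate profiles), since pooling is the natural
reading of per-site plots averaged over plants.

The simulator draws methylation i.i.d. per site per clone from the planted
per-(feature, context, genotype) probability — the smallest annotated
feature containing the site that has an entry in the truth table, else the
background entry. Unmethylated cytosines convert to T with probability
`conversion_rate` (default 0.99, a typical kit efficiency); methylated
cytosines never convert. Incomplete conversion therefore biases estimates
upward by exactly (1 − p)(1 − c), which the tests verify against the closed
form. Substitution errors (default 10⁻³) hit non-site bases only, producing
ambiguous calls downstream without perturbing the methylation signal; no
along-molecule correlation is modeled because clone data give no basis for
choosing one.

## Small-RNA pipeline

Trimming takes the read prefix before the leftmost exact occurrence of the
adapter's first k = 8 bases and keeps inserts of 18–30 nt; rejection reasons
(no adapter, length) are tallied so that raw = no-adapter + length-rejected
+ structural + non-structural holds exactly for every library. A read is
structural when it occurs verbatim in any structural reference record or its
reverse complement. Alignment to the locus is exact-match string search on
both strands; a multicopy gene is represented by a single copy, so multi-hit
reads count at every hit by default (an optional once-per-read mode divides
by the hit count).

The normalization denominator is locus-matched non-structural reads. In the
synthetic setting every non-structural, non-noise read derives from the
locus, so "genome-matched" and "locus-matched" coincide; with real data the
denominator would be genome-matched reads, which is out of scope here. RPM
is 10⁶/denominator; 22-nt anchoring further multiplies each library's factor
by (reference 22-nt RPM)/(library 22-nt RPM), equalizing 22-nt totals across
libraries. The anchor is a single scalar per library, so within-library
ratios between size classes are unchanged, and anchoring-before or -after
per-million scaling are algebraically identical (both reduce to
10⁶ · ref22/(ref_denom · lib22)); the read pool for the 22-nt tally
(locus-matched, non-structural, or all trimmed) is a parameter, default
locus-matched. The reference library defaults to the first library given
(a wild-type library by convention), and is a parameter because pooled-mean
anchoring is an equally defensible choice.

Binning uses a half-open 50-bp grid laid out in TSS-label space: edges are
labels ≡ anchor (mod width) under plain integer arithmetic. Because labels
skip 0, the bin straddling the TSS contains 49 real positions; edge values
are boundaries (an edge of 0 is the TSS boundary itself). The default
anchor is the label of array position 1, tiling the locus from its first
base; a nonzero anchor reproduces printed grids whose upstream and
downstream row boundaries share a residue mod 50 (e.g. rows starting at
−1726 and 5024, both ≡ 24). A hit joins the bin containing its biological
5′ end (left end on '+', right end on '−'), counted once per hit.

Lost-region calling flags bins with wild-type abundance ≥ `min_wt` (default
5, in the chosen normalized unit) and mutant/wild-type ratio ≤ `max_ratio`
(default 0.2; mutant 0 always passes), merges adjacent flagged bins into
maximal regions, sums abundances over the region and attaches overlapping
feature names. The defaults reproduce the qualitative pattern of published
locus tables, whose printed wild-type rows are ≥ 5 RPM with mutant values
≤ 20% of wild type; both are exposed on the CLI since no published cutoff
exists.

The simulator draws source reads uniformly within each planted interval,
with length from a per-source size mix, strand from a strand mix, and
per-genotype abundance weights; structural fragments come from a synthetic
tRNA/rRNA/sn/snoRNA reference; an unmatchable noise fraction and an
adapter-free junk fraction complete the library. Default fractions
(structural 0.15, noise 0.05, no-adapter 0.02) are typical of small-RNA
libraries after quality filtering. Reads are emitted as insert + 3′ adapter
truncated to 36 nt. The generator does not model sequencing errors within
inserts, PCR duplicates, or bisulfite strand pairing; consequently pipeline
tests demonstrate bookkeeping and recovery properties, not robustness to
base-call noise.

## qPCR and ChIP-qPCR

Technical replicates are averaged on the Ct scale before any Δ computation
(standard Livak practice). ΔCt = Ct(target) − Ct(control) per biological
replicate; ΔΔCt is taken against the calibrator's replicate-mean ΔCt, making
the calibrator's point estimate exactly 1; per-replicate 2^−ΔΔCt values give
mean ± SE on the linear scale, matching how such figures report three plants
with SE bars. No efficiency correction (Pfaffl) is applied. Percent-of-input
adjusts the input Ct by log2(1/f) for input fraction f (default 0.01, always
user-supplied for real data since dilutions vary by protocol), then
100 · 2^(adjusted − Ct_IP). Fold enrichment is a ratio of percents with
optional no-antibody subtraction floored at 0. The Ct simulator plants
relative-expression effects as ΔCt offsets (−log2 effect) with Gaussian
noise (sd 0.2 cycles, a typical SYBR instrument spread) at 3 biological × 3
technical replicates.

## Problem sizes and numerical choices

Test and validation runs use a 12 kb locus, 500–700 bp amplicons, 20–30
clones per plant, and small-RNA libraries of 10⁵–2×10⁵ reads — the scale of
the clone-based and single-locus sequencing studies this package targets,
which keeps any property check under a few seconds per seeded run.
Stochastic recovery properties are asserted over repeated seeded runs with
an explicit allowance (e.g. 18/20, 19/20, 8/10) because single-draw
assertions on quantities with percent-level sampling error are
uninformative; tolerance bands come from binomial standard deviations at the
realized call counts, never from observed values. Normalization identities
(RPM totals, 22-nt equalization) are asserted to 10⁻⁶ absolute and 10⁻⁹
relative respectively; the t statistic is checked against an independently
coded pooled-variance formula to 10⁻⁹. Degenerate inputs have defined
behavior throughout: empty regions enumerate no sites, contexts with zero
informative calls report missing (not 0%), single-replicate comparisons
carry no test statistic, and zero denominators raise errors naming the
offending library or sample.

## Known limitations

One locus at a time; no genome-wide alignment, no mismatch-tolerant
alignment, no multiple-sequence alignment of clones (clones are gap-free by
contract), no methylation segmentation, no amplification-efficiency
correction, and no plotting beyond per-position bedGraph export. The
synthetic generator's realism limits are listed above; passing recovery
tests demonstrate estimator correctness under the stated generative model,
not performance on real sequencing artifacts.
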