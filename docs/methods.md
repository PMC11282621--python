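# Methods

## The question and the model

Livestock range expansions that proceed overland tend to happen as a chain
of founder events: each newly established population carries a sample of
its source's allele copies.  Under pure drift, one foundation by `Nb`
diploids multiplies expected heterozygosity by `1 − 1/(2·Nb)`, so a
population `s` steps along the route has

    E[He_s] = E[2·p0·(1 − p0)] · (1 − 1/(2·Nb))^s .

A detectable consequence is a *cline*: per-breed diversity (Ho, He) falls,
and differentiation from near-origin populations (Fst) rises, with
geographic distance from the origin.  Maritime, leap-frog or heavily
admixed dispersal erases the gradient.  The package quantifies the cline
as a Pearson correlation between a per-breed statistic and the geodesic
distance from the breed's sampling site to a fixed origin — by default
Ganj Dareh (34.27° N, 47.47° E), a Neolithic site in the Zagros Mountains
with early evidence of goat management.

## Estimators

- **Ho**: per locus, the fraction of non-missing genotypes that are
  heterozygous; unweighted mean over loci with at least one call.
- **He**: Nei's unbiased gene diversity per locus, `2n/(2n−1) · 2p(1−p)`
  with `n` the locus's genotyped individuals and `p` its sample allele
  frequency; unweighted mean over usable loci.  The small-sample factor
  makes the per-locus value an unbiased estimate of `2p(1−p)` in the
  population, which is what the drift law predicts.
- **Fis** is reported as the aggregate `1 − (mean Ho)/(mean He)`; a
  locus-weighted variant (`1 − Σho_l/Σhe_l`) is available behind a flag.
  The two differ in the third decimal on real data because the aggregate
  form weights loci equally while the weighted form emphasises diverse
  loci.
- **Fst**: Weir & Cockerham's (1984) θ for two populations, variance
  components `a` (between populations), `b` (between individuals within
  populations) and `c` (within individuals) computed per locus from
  sample sizes, allele frequencies and observed heterozygote proportions,
  then combined across loci as `Σa / Σ(a+b+c)`.  Loci monomorphic across
  the pooled pair are excluded; mildly negative estimates are expected for
  undifferentiated pairs.  Which Fst variant the original software stack
  used is not documented at formula level, so numerical identity with
  other tools is not claimed; the packaged per-breed tables carry the
  published values.
- All statistics use locus-wise non-missing counts; nothing is imputed,
  and every statistic is invariant to which of the two alleles is counted
  (property-tested).

## Distances and the cline regression

Distances use Vincenty's inverse method on the WGS84 ellipsoid
(a = 6378137 m, f = 1/298.257223563), iterated to 1e−12 rad or 200
iterations; near-antipodal non-convergence raises rather than silently
falling back.  The implementation agrees with the independent `geosphere`
R implementation to below 1e−6 km (tested).

Recomputing the published distance column from the published coordinates
leaves deviations of up to ~0.6 km.  The published coordinates are printed
to two decimals (~1 km resolution), so the published distances were
evidently computed from unrounded coordinates; sub-kilometre agreement is
the attainable bound, and the tests assert it at 0.6 km.  Correlations are
therefore computed against the *published* distance column, which the
package treats as data.

The association is the Pearson product-moment correlation; its p-value
uses the exact two-sided t transform with n−2 degrees of freedom
(appropriate at the continental sample sizes of 22–43 breeds, and
calibrated against a 1000-permutation null in the tests).  Rows missing
either the statistic or the distance are dropped pairwise and counted.
OLS slope and intercept are reported for plotting.

### Breed subsets

Named presets encode the standard analyses.  Africa always excludes the
three commercial South African breeds (Boer, Savanna, Kalahari Red),
whose partly Asian ancestry makes them unrepresentative of indigenous
dispersal; the African insular breeds are the two Malagasy populations
and the Canary-Islands Palmera.  For Europe, `europe_no_british_irish`
removes only the Old English and Old Irish goats.  An extended
`europe_no_all_islands` preset additionally removes the breeds sampled on
Mediterranean islands (Corsica, Sardinia, Mallorca and the Sicilian
breeds Girgentana, Rossa Mediterranea and Argentata, plus the Maltese);
the island status of these goats sampled within Italian regions is partly
a judgement call, the published no-island European analysis is not fully
reconstructible from the published table (its printed p-values imply a
smaller breed count than removing only the British–Irish pair), and this
preset is provided as documented best effort rather than asserted to
reproduce the published no-island numbers.

## Quality control

Filter order is fixed and reported per criterion, because survivor counts
depend on it: individuals with missing rate > 0.1 first, then SNPs that
are unmapped, then SNP missing rate > 0.05, then MAF < 0.05, then
Hardy–Weinberg exact p ≤ 0.001.  MAF and HWE are computed over all
retained individuals pooled (matching a per-continent merged analysis);
per-breed testing is available by running per-breed matrices.  Pooling
across differentiated breeds deflates heterozygosity (Wahlund effect), so
the pooled HWE filter is conservative; this mirrors the source pipeline.

The HWE test is the conditional exact test: given the observed allele
counts, the probability of `h` heterozygotes is proportional to
`n!·2^h / (n_AA!·h!·n_BB!)` over counts of matching parity, and the
two-sided p sums all outcomes no more probable than the observed one (no
mid-p).  It is verified exhaustively against an exact-rational enumeration
for every genotype table with n ≤ 30, and against a formula-free
allele-permutation oracle at tiny n.

Per-breed subsampling to a target range (default 15–50) picks the subset
minimizing the Frobenius distance between the subsample's and the full
breed's genotype covariance on the breed's top 10 principal axes, by
greedy swap refinement from a seeded random start.  The tool the original
study used for this is published without formulas, so this procedure is
the package's own explicit, reproducible stand-in; equivalence is not
claimed, only the same stated goal (variance-structure preservation).

## PCA

SNPs are centred by mean call and scaled by `sqrt(2p(1−p))`; missing
calls become the mean (zero after centring).  Scores come from the SVD of
the normalized matrix, components ordered by eigenvalue, sign fixed by
forcing each component's largest-magnitude SNP loading positive.  Breed
centroids are unweighted means of member scores on PC1/PC2.

## IDW surfaces

Grid cells take `Σ w_i v_i / Σ w_i` with `w_i = d_i^(−power)`,
`power = 2` by default, all points contributing (no search radius), and
`d_i` the great-circle distance (mean-radius sphere) between cell centre
and sampling site — great-circle rather than planar degrees because at
continental extents a degree of longitude shrinks with latitude.  A cell
centre within 1e−9° of a sampling site takes that site's value exactly.
Surfaces are classed into ten equal-width intervals, half-open with the
global maximum in the top class.  The GIS software used for the published
maps does not document its projection/neighbourhood settings, so
figure-level numeric reproduction is out of scope; the tests assert
structural features instead (Malagasy cells in the lowest He classes,
mostly negative Fis across Europe).

## The simulator

`simulate_dispersal` draws origin allele frequencies i.i.d. from
Uniform(0.05, 0.95) (the ascertainment-like band typical of array SNPs),
then applies `founder_steps(k)` successive binomial resamplings of
`2·Nb` allele copies for population `k`, and samples individuals as
Binomial(2, p) per locus — Hardy–Weinberg within populations — with
i.i.d. missingness (default 1%).  Defaults are 12 populations with
0..11 founder steps, `Nb = 25` (2% heterozygosity loss per step,
totalling ~20% across the route — the scale of continental Ho/He spans in
the real tables), 30 sampled individuals (the real median is ~24), and
2000 loci (enough that per-breed He has a standard error well below the
per-step signal while keeping 100 replicates under a minute).
Sampling sites are placed every 4° along a fixed compass bearing from the
origin, and distances flow through the same Vincenty code as real
coordinates.  A `migration_rate` flag mixes each population's frequencies
with its route neighbours (one round), reproducing the cline-erasing
effect of gene flow; it defaults to 0.

What the simulator does *not* model: linkage disequilibrium and
recombination, selection (including trypanosomiasis-related pressure),
ascertainment bias beyond the uniform band, overlapping source
populations, and real geography.  Passing the recovery test therefore
shows the pipeline detects a drift-generated cline of realistic magnitude
under HWE sampling — not that array data from field breeds satisfy those
assumptions.

## Validation summary

The tests (i) reproduce the published continental Pearson correlations to
±0.01 and the continental Ho/He/Fis means to printed-rounding accuracy
from the packaged tables; (ii) verify every estimator against an
independent oracle (exact-rational HWE enumeration, long-hand
variance-component Fst, allele-pair-enumeration He, dense-eigendecomposition
PCA, `geosphere` distances); (iii) recover r < −0.8 for He-vs-distance in
≥95 of 100 seeded simulator replicates and match the closed-form He decay
within Monte-Carlo error; and (iv) property-test the conventions (IDW
convexity/exact hits/order invariance, allele-swap invariance, filter
idempotence, PED/MAP round-trips, t-based p calibration against a
permutation null).  Known irreducible gaps against the published tables —
sub-kilometre distance deviations from coordinate rounding, and the
not-fully-reconstructible European no-island breed set — are documented
above and asserted at their attainable bounds in the main suite.

## Numerical details

- Missing genotype code −1; all statistics mask it locus-wise.
- HWE log-probabilities compared with 1e−10 slack to absorb rounding in
  the ≤-ordering.
- θ combined across loci by summed components (not averaged ratios);
  pairs with fewer than two polymorphic loci raise.
- Equal-interval classing: `floor((v − min)/width) + 1`, clipped to k.
- Monomorphic sites read from PED get allele_a = "0" (unknown) so that
  allele_a ≠ allele_b always holds; dosage then counts the sole observed
  allele.
- All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; no global state.
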