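# Methods

`sympop` analyses diploid microsatellite genotypes from host-associated
populations diverging in sympatry while still exchanging migrants. Its core
question: how strong must divergent selection be, locus by locus, to hold an
observed allele-frequency difference in place against gene flow? Around that
core it implements the standard descriptive layers such a survey needs —
within-population diversity, pairwise differentiation, population networks,
geographic clines, and genotypic hybrid detection.

## The migration–selection balance model

Consider two populations of equal size exchanging migrants at a symmetric
gross rate *m* (the fraction of each population that is immigrant each
generation, before any selection against immigrants). Microsatellite loci are
multi-allelic, so each locus is first collapsed to two allele classes per
sympatric pair: an allele joins the "ancestral" class iff its frequency in
the ancestral population strictly exceeds its frequency in the derived
population (ties, including shared absence, go to the ancestral class —
they contribute equally to both class frequencies, so the frequency
difference Δ is unaffected). This yields class frequencies *a₁* (ancestral
population) ≥ *a₂* (derived population).

With viability selection on the locally favored class — genotype fitnesses
(1, 1−*h·s*, 1−*s*) for the favored homozygote, heterozygote, and disfavored
homozygote, with dominance *h* = ½ by default — one generation of selection
changes the favored-class frequency *p* by

  Δp_sel = ½ · p·q·s / (1 − q·s),   q = 1 − p  (h = ½).

One generation of migration moves the resident frequency by
Δp_mig = −m·(p_resident − p_immigrant). The **required selection
coefficient** is the *s* that makes selection exactly compensate migration at
equilibrium. Two formulations are provided, because the life-cycle bookkeeping
admits both:

* **compensatory** (default): solve Δp_sel(p_observed, s) = m·(p − p_imm) at
  the observed frequency; closed form s = Δ / (q·(½p + Δ)) for h = ½.
* **sequential**: apply migration first (p* = (1−m)p + m·p_imm), then solve
  for the selection step that returns p* to p. This is the literal
  one-generation fixed-point condition under a migration → selection life
  cycle, and it inverts the deterministic two-island recursion exactly
  (verified to 1e−6 in tests across s ∈ [0.05, 0.5], m ∈ {0.01, 0.03, 0.05}).

The two conventions differ only at second order in m; both are solved for
each pair and direction. For general *h* the closed form is replaced by
bisection on the full diploid update. Solutions with s > 1 mean the observed
difference cannot be maintained at equilibrium under the assumed *m*; they
are reported as s = 1 with a capped flag, and summaries (mean/min/max per
direction) are computed over the capped values. A 0.001 floor is applied only
in reporting tables; raw values are retained.

Each pair yields two coefficient sets: selection against ancestral-favored
alleles in the derived population, and the reverse. Asymmetry between
directions is tested with a paired t-test across loci and a variance-ratio
F-test (derived-direction variance in the numerator, two-sided p, df =
L−1, L−1 for L loci).

Interpretation caveats are inherited from the model's assumptions: evolution
at equilibrium, direct selection on each locus independently, symmetric
migration, and composite two-class frequencies. The estimates describe the
magnitude of selection *required*, not a measured selection regime; linked
and genome-wide selection are absorbed into the per-locus values.

Migration rates are always inputs, never estimated. The packaged default
profile (0.05 mayhaw/green hawthorn, 0.045 apple/downy hawthorn, 0.04
blueberry hawthorn/mayhaw, 0.03 flowering dogwood fly, 0.02 blueberry fly,
0.01 snowberry fly) reflects published mark–recapture and hybridization-rate
estimates for the study system; the silky-dogwood pair, which lacks a field
estimate, uses 0.01 in the synthetic fixture.

## Two-island simulator (the solver's oracle and test bed)

The deterministic recursion iterates migration and antagonistic selection
(deme 1 favors the tracked class, deme 2 the complement, same s) to a fixed
point (default tolerance 1e−12, both life-cycle orders supported via a flag,
migration-first default). A returned fixed point changes by less than the
tolerance under one further generation. The finite-N version adds
multinomial Wright–Fisher drift over alleles (selection acting on class
marginal fitnesses), stepwise mutation (±1 repeat = ±2 bp by default, mutants
inherit the parental selection class), and without-replacement diploid
sampling of individuals from the final generation's gene copies.

Default study conditions for parameter recovery: 19 unlinked loci, N_e = 10⁴
per deme, m = 0.03, s ~ U(0.05, 0.3), 300 generations from a near-symmetric
start (equilibration takes ≤ 200 generations in the deterministic limit over
this grid), n = 50 sampled per deme. Under these conditions the mean
recovered s per locus over 50 replicates stays within ±8% of truth (the
acceptance script recomputes this; the tolerance asserted is ±20%).

## Diversity

Rarefied allelic richness α_g is the exact hypergeometric expectation of the
number of distinct alleles among g gene copies drawn without replacement:
α_g = Σ_i [1 − C(N−N_i, g)/C(N, g)]. This equals exhaustive subset
enumeration to floating-point precision (asserted for all N ≤ 12).
Standardization uses g up to the smallest gene-copy count among the
populations being compared. Curves are summarized by a least-squares
Michaelis–Menten fit α(g) = A·g/(B+g) with A constrained ≥ α_gmax. The MM
asymptote is a deliberate simplification: on unsaturated curves (all alleles
already observed at modest N) it overshoots the true allele count by up to
~30%, so fitted asymptotes are comparative indices, not census estimates.
Richness is compared across groups by one-way ANOVA on per-population mean
asymptotes with Tukey-HSD letter groups; single-population groups are
excluded from the test.

Private alleles of a focal taxon are fragment-length variants absent from
every reference-taxon population and present in ≥ 2 focal populations
(singletons and single-site variants are thereby excluded; for
single-population taxa the criterion drops to 1). The reported frequency is
gene-copy weighted across all focal individuals.

## Differentiation and trees

Jost's D per locus for a population pair uses bias-corrected heterozygosities
with the harmonic-mean sample size ñ:
H_S = (2ñ/(2ñ−1))(1 − mean_i Σ_a p²_ia), H_T = 1 − Σ_a p̄²_a + H_S/(4ñ), and
D = (H_T − H_S)/(1 − H_S) · 2. D is chosen over F_ST-family measures because
the loci are highly polymorphic within populations, which compresses
heterozygosity-partition statistics toward zero. Slightly negative estimates
are clamped to 0 (flagged); monomorphic loci are D = 0 by convention.
Distribution comparisons between pairs use a Welch t-test on per-locus D.

Nei's (1972) standard distance sums genetic identity jointly over loci
(D = −ln I, I = Σ x·y / √(Σx² Σy²) with sums over all loci and alleles), and
population networks are neighbor-joining trees on that matrix (scikit-bio's
Saitou–Nei implementation; negative branch lengths clamped to zero;
tie-breaking is the implementation's first-minimum rule, so trees are
deterministic). Clade confidence is the percentage of locus-bootstrap
replicates (resampling loci with replacement, default 10,000) whose NJ tree
contains each bipartition of the point-estimate tree. These networks
describe current allele-frequency dissimilarity; under on-going gene flow
they are not rootable as historical phylogenies.

## Clinal mosaic analysis

Allelic variation at each locus in the ancestral populations is collapsed by
PCA on the centered population × allele frequency matrix (unweighted
population mean, no scaling — populations, not individuals, are the
observational unit). PC1 sign is fixed so score correlates non-negatively
with latitude. A locus is "major clinal" when |Pearson r(PC1, latitude)| ≥
0.8 with p ≤ 0.05 (both configurable; the thresholds quantify "strongly
correlated" and, at 14 ancestral populations, keep the null false-positive
rate per locus well below 1%).

Derived-taxon populations are projected onto each ancestral axis; alleles
unseen in the ancestral populations get zero loading and are logged (they
carry no positional information in the ancestral space, which also means
taxa rich in private alleles are pulled toward the centroid — their calls
should be read with that in mind). The taxon's mean score receives a 95%
percentile-bootstrap CI over populations (≥ 3), a normal-approximation CI
for 2, or a degenerate flagged interval for 1 (no statistical classification
possible for single-population taxa). The ancestral reference band is the
95% mean-prediction interval of a linear regression of ancestral score on
latitude, evaluated over the derived taxon's latitude range. Classification:
CI entirely above the band = northern-like, entirely below = southern-like,
otherwise mid-latitude. Note the classification is relative to the
ancestral expectation *at the derived taxon's own latitudes*: a taxon with
mid-cline allele frequencies living at northern latitudes is
"southern-like" relative to its local ancestral neighbors.

## Hybrid classification

Individuals of a natal population are scored against five gamete-origin
models: pure natal, pure migrant, F1, backcross-to-natal, and
backcross-to-other (ancestry two generations back only; no F2 class).
Per-locus genotype probabilities multiply gamete frequencies from the
appropriate pools (the backcross mixture gamete is ½ natal + ½ other), with
a factor 2 for heterozygotes from exchangeable sources. Natal frequencies
are leave-one-out; unseen alleles are floored at 1/(2N+1). The prior places
1 − μ on pure natal and splits the migration prior μ across non-natal
classes proportional to the number of ancestor configurations at each
pedigree depth (migrant 1, F1 2, each backcross class 4). This makes
non-natal posteriors monotone in μ and leaves the posterior exactly at the
prior when the parental pools are identical. When mean Jost's D between the
pools falls below 0.05 the output carries a warning: at that divergence the
posteriors are prior-dominated and genotypic hybrid detection is not well
supported. This classifier conditions on two predefined parental pools; it
is a transparent simplification of model-based clustering with prior
population information, not a replacement for it.

## Synthetic whole-radiation fixture

`make_radiation_fixture` emulates the study's sampling frame: 33 populations
from 6 taxa at the frame's printed latitudes and sample sizes (26–105
individuals; the single silky-dogwood population has n = 34), 19 loci, 7 of
them clinal in the ancestral hawthorn taxon (northern-allele frequency
linear in latitude from ~0.08 south to ~0.92 north, plus a 6% shared minor
allele). Non-clinal loci carry a shared 4-allele profile with taxon-level
(host-level within hawthorn) frequency shifts that grow along the divergence
continuum (0 for downy hawthorn through 0.42 for the snowberry and
silky-dogwood flies). Private alleles are injected at the frequencies the
study reports per taxon and locus (5 loci for the blueberry fly, 9 for the
snowberry fly, 14 for the silky-dogwood fly, including two fixed), using
odd-offset labels unreachable by stepwise mutation so injections are
unambiguous. Derived taxa are placed on the ancestral clines per a
locus-by-locus north/south/mid mosaic design. Genotypes are multinomial
draws under Hardy–Weinberg within populations; the same seed yields a
byte-identical dataset.

What the fixture does *not* emulate: linkage and inversion structure among
loci, isolation-by-distance within taxa beyond the designed clines,
null alleles and genotyping error, and within-population departures from
Hardy–Weinberg. Passing tests on the fixture therefore demonstrate the
correctness and calibration of the estimators under the model's own
assumptions, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

- All randomness flows from explicit integer seeds; no global RNG state.
- The deterministic recursion converges when max |Δp| < tol (default 1e−12);
  exceeding the generation cap raises an error carrying the last state.
- Solver degeneracies: equal frequencies or m = 0 give s = 0; a resident
  frequency of exactly 0/1 with a positive difference cannot respond to
  selection and is returned capped and flagged degenerate.
- Zero-gene-copy (population, locus) entries are flagged undefined, never
  silently reported as frequency 0.
- Monomorphic loci are excluded (and logged) from F_IS; F_IS uses the
  small-sample-corrected expected heterozygosity (2n/(2n−1)) and a
  percentile bootstrap over loci (10,000 replicates by default) for the
  across-loci CI — at 19 loci this CI runs slightly below nominal coverage
  (~88–97% across fixture populations), adequate for its purpose of
  flagging systematic inbreeding.
- ANOVA with zero within-group variance returns F = 0 (equal means) or
  F = ∞ (unequal), rather than NaN.
- Flat rarefaction curves pin the asymptote at observed richness with a
  warning; NJ rejects NaN or asymmetric matrices.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the solver grid at 4×10×10
(m × p_favored × p_immigrant), deterministic recovery at 19 loci × 3
migration rates, Wright–Fisher recovery at 50 replicates of the default
study conditions, rarefaction enumeration for all N ≤ 12, the null
calibration of the D-distribution comparison at 1000 replicates, NJ recovery
at 200 random additive trees of 4–8 taxa, the clinal mosaic at 100 replicate
datasets of 14 ancestral populations, and hybrid calibration at ~500
simulated individuals. Locus bootstraps in pipeline runs default to a few
hundred replicates in tests (10,000 remains the library default for
analyses).
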