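# Methods

This note documents the models behind each analysis module, the synthetic
data they are validated on, the numerical choices, and what the passing
tests do and do not establish.

## Four-taxon site patterns and the D-statistic

For taxa (P1, P2; P3, O) with per-site derived-allele frequencies, each site
contributes frequency weights ABBA = (1−p1)p2·p3(1−p4) and
BABA = p1(1−p2)p3(1−p4); D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA). Frequency
weighting (rather than sampling a single read or haplotype per taxon) makes
the estimator deterministic given the panel; per-individual tests are run by
passing one individual's genotypes as P2 frequencies (0, 0.5, 1).

The standard error is a delete-one-block jackknife over contiguous blocks,
weighted by block denominators following Busing et al. (1999): blocks carry
unequal information and the weighted pseudovalue variance accounts for it.
Blocks with zero ABBA+BABA are excluded from resampling; at least two
informative blocks are required. Z = D/SE, with |Z| > 3 the conventional
significance threshold.

The synthetic generator draws each site independently: with probability `f`
the genealogy is introgressed (ABBA w.p. `beta`, BABA w.p. `eps`), otherwise
the species genealogy applies (ABBA and BABA each w.p. `eps`); BBAA occurs
w.p. `p_bbaa` regardless. This yields the closed form
E[D] = f(β−ε)/(2ε + f(β−ε)) and an exactly symmetric null at f = 0. It is
*not* a coalescent model: `eps` compresses all incomplete lineage sorting
into one symmetric probability, sites are unlinked (blocks are informative
only as resampling units), and frequencies are fixed 0/1. Calibration and
recovery results therefore validate the estimator's arithmetic and the
jackknife's coverage, not robustness to linkage or demography.

## Supervised admixture

Genotypes g_j ∈ {0,1,2} of one individual are modelled as Binomial(2, m_j)
with m_j = q·a_j + (1−q)·b_j, where a and b are parental population allele
frequencies clamped to [1e−6, 1−1e−6]; the log-likelihood is maximised over
q ∈ [0,1] by bounded scalar optimisation (xatol 1e−8). Identifiability
requires a_j ≠ b_j somewhere. The F1 generator uses a Balding–Nichols
construction (ancestral frequency uniform on (0.05, 0.95), parental
frequencies Beta-distributed with drift parameter 0.2, an F_ST-like
divergence typical of well-separated congeners) and samples one allele from
each parent; the true F1 genotype law is Bernoulli(a)+Bernoulli(b), which
shares its mean with the binomial model, so q̂ concentrates at 0.5 even
under this mild misspecification.

## Fourfold-degenerate sites and T92 distances

Masking: every window of two adjacent codons (overlapping, stepping one
codon; a flag selects non-overlapping stepping) is checked on the unmasked
input; windows with more than one position at which the species do not all
carry one identical defined base have both codons replaced by N for all
species. This is the strictest reading of "two neighbouring codons
containing more than one non-identical base" and is idempotent. Ambiguity
codes and gaps are treated as missing. Filtering removes whole codons
containing any missing base (keeping the frame and codon context valid),
drops genes under 100 surviving columns, and concatenates.

Fourfold-degenerate families are derived programmatically from the genetic
code (standard code: CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN); a third
position is kept only when the codon is fourfold degenerate in *every*
species. θ is computed per pair from the two compared sequences' retained
sites, not averaged across the whole alignment. Saturated pairs (log
argument ≤ 0) and degenerate composition (θ ∈ {0,1}) raise named errors.
An all-third-position mode is available as the robustness check variant.

The codon simulator evolves only fourfold third positions, under the T92
rate matrix (stationary frequencies (1−θ)/2, θ/2, θ/2, (1−θ)/2 for A,C,G,T;
transitions κ = 2 times faster; matrix scaled to one expected substitution
per unit distance) with the second sequence evolved from the first over the
full pairwise distance (valid by reversibility). Estimator consistency is
checked at 5·10⁴ codons, |d̂ − 0.10| < 0.005 (the Monte-Carlo standard
deviation at that size is ≈ 0.0017). The closed-form spot check at
P = 0.1, Q = 0.05, θ = 0.5 equals 0.1701812, verified against the
independent implementation in R's `ape` (`dist.dna`, model "T92").

## Dental statistics

The top-cusp angle is measured at the tallest cusp tip (ties broken to the
most anterior); rays go to the most anterior and most posterior cusp tips
when tips exist on that side of the apex, otherwise to the crown-base
endpoint on that side — the operative extension of the published one/two-cusp
rule. The angle is invariant to translation, uniform scaling and
mirror-reflection of the tooth.

Disparity is the unweighted mean over positions P1–P5 of |Δ cusp count|,
reported for species means and species modes (mode ties broken to the
smaller count and flagged). An ordinal grade→cusp recoding table mechanism
supports hominin premolar/molar scoring conventions (grades 1–2 → one cusp,
grade 5 → four cusps; intermediate grades interpolate linearly).

The intermediacy bracket forms all n_a·n_b cross-species pairwise mean
angles per position; the bracket is the equal-tailed central 80% interval
(empirical quantiles, linear interpolation, verified against a brute-force
sort-and-count oracle); the hybrid's quantile is the fraction of pairwise
means ≤ its value, with one- and two-tailed extremity measures both
reported. Bands are per-position, matching per-tooth comparison plots.

The tooth-sample generator draws angles from truncated normals on (0, 180)
(per-position species means: ringed-type 115–120°, grey-type 40–85°,
σ = 9°) and cusp counts from per-position categorical distributions chosen
so the two species' disparity is ≈ 1.8 cusps/tooth, the scale separating
highly disparate dentitions from near-monotypic ones; 65 specimens per
species mirrors a realistic museum sample. The hybrid measurement is the
per-position midpoint of species means plus 1.5° noise, the order of the
repeat-measurement error of manual angle tabulation.

## Reduced enamel-knot tooth simulator

The full 3D epithelium–mesenchyme tooth-development model (20+ parameters)
is deliberately *not* re-implemented. The surrogate is one-dimensional and
deterministic: a growing interval with a primary knot at the origin; each of
n_iter = 1000 iterations the anterior end extends by g·Abi and the
posterior by g·(1−Abi) with g = g0·Egr; total inhibition
h(x) = Σ_k exp(−|x−x_k|/(λ0·Inh)) is evaluated on a fixed global grid
(spacing δ, grid points at absolute multiples of δ so refining δ only
inserts points); a knot nucleates at the minimising grid point when
h < θ_nuc (ties to the most anterior). A knot nucleated at step t ends at
height (1 + (n_iter−t)/n_iter)·h0·Egr, so early cusps are taller; crown-base
endpoints sit at the final domain edges at height zero, and cusp count and
top-cusp angle are read off with the dental module.

Constants are package calibration, not measured biology: g0 = 8·10⁻⁴,
λ0 = 0.25, δ = 0.01, θ_nuc = 0.35, L0 = 0.3, h0 = 0.5. They were set once so
that the packaged species rows reproduce the qualitative contrast between
the two dentitions — ringed-type (Inh 1.0, Egr 1.0, Abi 0.5, ΔEgr
+0.05/tooth) gives rows of 3–4 subequal cusps with top-cusp angles near
116°, grey-type (Inh 2.2, Egr 1.6, Abi 0.35, ΔEgr +0.05, ΔInh −0.2/tooth)
gives anterior teeth with 1–2 cusps dominated by a central fang (≈75°) and a
posterior cusp-number gradient. All claims made of the surrogate are ordinal
(cusp count non-increasing in Inh; the all-average hybrid intermediate
between the parents in count and angle at every position; grid-resolution
stability of cusp counts), never numerical agreement with any 3D model
output. Lateral biases exist as inert fields for interface parity.

Hybridization protocol: per parameter, average, 10% shift towards either
parent, or direct inheritance. The "10% towards a parent" rule is the
midpoint moved one tenth of the half-range — algebraically identical to a
0.55/0.45 weighted mean, so only one implementation exists. All modes are
affine, so combining a row's base and per-tooth deltas separately equals
combining per-tooth parameters. The combination grid enumerates all 27
assignments of {average, take_a, take_b} to (Inh, Egr, Abi) plus the two
whole-genotype 10%-shift rows. Compared simulations must share n_iter
(enforced with an error).

## Geometric morphometrics

Symmetrization reflects the configuration, swaps paired landmark labels,
superimposes the relabelled reflection on the original (translation +
proper rotation, no scaling) and averages; it is idempotent and, for
configurations already in their symmetry frame, agrees with the direct
projection onto the symmetric subspace to second order in the asymmetry.

GPA centres each configuration, scales to unit centroid size, and
iteratively rotates to the running consensus (proper rotations only —
crania are chiral) until the consensus moves < 1e−10 (max 100 iterations).
The output is put in a canonical frame (principal axes of the consensus,
signs fixed by the largest-magnitude projection, right-handed), which makes
aligned coordinates invariant — not merely equivariant — to arbitrary input
similarity transforms. Rank-deficient (collinear) configurations raise an
error naming the specimen. Shape coordinates are used directly for PCA
(no tangent-space projection, matching common MorphoJ-style practice);
PCA is the SVD of the centred specimen × 3k matrix with numerically null
components dropped.

The permutation test statistic is the Euclidean (Procrustes) distance
between group mean aligned shape vectors; labels are permuted n_perm times
(default 10,000) and p = (#{≥ observed} + 1)/(n_perm + 1), so p is never
exactly zero and "p < 1/n_perm" corresponds to zero exceedances.

Quadratic allometry regresses each aligned coordinate on (1, s, s²) by
least squares, s the centroid size (optionally standardised; default off),
with a rank check and a predicted trajectory over the observed size range.
Note the intercept at the mean size is *not* the group mean shape unless
the squared-size column is also centred; the identity that holds, and is
tested, is that fitted values average to the mean shape.

The landmark generator builds a fixed bilaterally symmetric 46-landmark
template (20 mirrored pairs + 6 midline points, unit centroid size,
deterministic and independent of the sampling seed), adds a species
displacement field of Procrustes magnitude 0.05, shared linear (0.03) and
quadratic (0.012) allometric fields in standardised size, isotropic noise
(SD 0.005 per coordinate), scales to centroid sizes drawn per age class
(newborn 1.0–1.3, juvenile 1.4–1.9, adult 2.0–2.6), and samples 11
specimens per species × age group, mirroring the size of real newborn
cranial series. With zero species offset the two species are exactly
exchangeable *within* an age class, so type-I calibration and the power
check compare the newborn groups — the same comparison one would make on
real cross-sectional growth series, where pooling age classes makes naive
label permutation conservative (the balanced design is atypical among
random relabelings when allometry dominates). Calibration uses 199
permutations per replicate, which makes the nominal 5% level exact under
exchangeability with the +1-corrected p-value.

What morphometric tests do not show: the generator's noise is isotropic and
landmark-independent, unlike digitising error on real crania, and the
species difference is a single displacement field rather than a
covariance-structured contrast; power at the packaged offset therefore
calibrates the machinery, not any real effect size.

## Pipeline

Stages run in a fixed order (simulate → seqdist → introgression → admixture
→ dental → toothdev → morpho) with explicit file handoffs only. Per-stage
random substreams are derived from the global seed by hashing the stage
name, so enabling or disabling one stage does not perturb another's output,
and reports are byte-identical across runs (no timestamps are embedded).
Unknown configuration keys fail validation before any stage runs. The JSON
report is validated against a packaged structural schema.

## Problem sizes

Statistical checks use: D-statistic null calibration at 10⁵ sites × 100
blocks × 100 replicates and recovery at 2·10⁵ sites; T92 recovery at 5·10⁴
codons; admixture at 10⁴ sites × 50 replicates; morphometric type-I at 400
replicates × 199 permutations and power at 60 replicates × 999
permutations. These sizes put Monte-Carlo error well inside each check's
tolerance while keeping the whole suite fast on a single CPU.

## Known limitations

- No coalescent, linkage or demographic realism in the site-pattern
  generator; the D-statistic's robustness claims are not re-derived here.
- The admixture estimator is supervised (two fixed sources); it does not
  re-implement unsupervised genotype-likelihood clustering.
- The tooth surrogate's parameter values are not transferable to any 3D
  tooth-development model; only ordinal behaviour is meaningful.
- The masking filter, applied to genuinely divergent sequence, removes some
  true variation (visible as a small downward distance bias in pipeline
  demos); on real data it targets alignment error, which the simulator does
  not emulate.
- Digitising-error assessment is represented only as replicate-measurement
  variance in input tables, not as an algorithm.
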