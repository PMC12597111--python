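# Methods

This note documents the statistical models implemented in `famclust`, the
conventions and numerical choices behind them, what the synthetic-data
generator emulates, and the limits of what the test suite can demonstrate.

## Pedigree model and informativeness

A genealogy is a directed acyclic graph of parent links over individuals
carrying sex, birth year, birth place and affection status.  Validation
enforces referential integrity, parent sexes, strict birth-year ordering
(child after both parents) and acyclicity.

*Generation depth* counts complete ancestral generations: depth 0 when any
parent is unrecorded, otherwise 1 + min(depth(father), depth(mother)).  The
min rule means a lineage known through only one parent does not count —
the conservative reading, since nothing is known about half the ancestry at
that level.  "Three or more generations of genealogy", the filter defining
the analyzable (informative) case set, counts the individual's own
generation by default (self + parents + grandparents ⇒ depth ≥ 2); the
alternative reading (three *ancestral* generations) is selectable via
`count_self=False`.

## Kinship and genetic distance

The Malécot coefficient of kinship is computed exactly by the standard
recursion φ(i,i) = (1 + φ(f_i, m_i))/2 and, for i ≠ j with i not an
ancestor of j, φ(i,j) = (φ(f_i, j) + φ(m_i, j))/2, recursing on the member
of the pair with the larger generation index (missing parents contribute
0).  Inbreeding loops are handled exactly; whether the source data's own
kinship software does the same is unknowable from published tables, so the
exact computation is the conservative superset.  The batch route is the
tabular (additive relationship matrix) method in topological order, exactly
equivalent; the two routes are cross-checked in tests, and both are checked
against an independent Monte-Carlo gene-dropping oracle (two unique alleles
per founder, one random allele transmitted per parent per drop; the
per-drop estimate averages the four allele pairings analytically, which is
unbiased with variance no larger than a Bernoulli draw, so binomial
3σ bounds are conservative).

*Genetic distance* is the minimum number of meioses connecting two
individuals through a common ancestor, computed from per-individual
ancestor-depth maps (so only valid ascend-then-descend paths are
considered, never paths through spouses or shared descendants).  Unrelated
pairs get an explicit infinite distance, never a sentinel integer.

## GIF and dGIF

GIF(C) = S × mean over unordered pairs {i,j} ⊆ C of φ(i,j), with scale
S = 10⁵ exposed as a parameter (`GIF_SCALE`) so raw mean kinship is
recoverable.  Contributions partition the GIF sum by each contributing
pair's genetic distance; pairs with φ = 0 (equivalently, infinite distance)
contribute to no bin, so the decomposition is conserved exactly — the suite
asserts agreement to 1e-9 relative tolerance.

dGIF zeroes pairs at distance < 3 by default (parent–offspring, sibling,
grandparent–grandchild), a cutoff chosen to match the purpose of the
statistic — aggregation beyond close relatives — and left configurable
because no canonical value exists.  Excluded pairs keep their slot in the
denominator, so dGIF ≤ GIF always and the two share a scale; this is a
convention, the alternative (renormalising over distant pairs only) would
change magnitudes but not the empirical test.

Controls are matched per case on sex, birth year within ±5 years, birth
place (binarized in-/out-of-state) and informativeness (the same ≥3
generation filter applied to cases, on by default because cases are drawn
from that subset), sampled uniformly without replacement within a set and
with replacement across sets; cases are never eligible.  A case with an
empty matching stratum raises an error naming the case and stratum rather
than silently relaxing the match.  The empirical one-sided p uses the
add-one rule (1 + b)/(1 + n), so p is never 0 and p = 1/(n+1) is the floor.
Each control set consumes its own derived random stream from the top-level
seed, so results are independent of evaluation order.

## Cohort rates and familial relative risks

Cohorts are sex × 5-year birth interval × in-/out-of-state birth-place
strata; bins are anchored at years divisible by 5 (anchor configurable).
The cohort rate is cases over *all* individuals in the stratum — cases are
not removed from denominators, and other cases are not excluded from
relative sets: the simple convention, applied consistently.

Relatives are enumerated by explicit kin-class construction — degree 1:
parents, offspring, full siblings; degree 2: grandparents, grandchildren,
avuncular kin, half-siblings; degree 3: first cousins,
great-grandparents/-grandchildren, half- and grand-avuncular kin — with an
individual related through several paths assigned to the closest degree, so
the three sets are disjoint.  Observed and expected counts use the union of
the cases' relative sets (each person once, "without duplication"); a case
appearing in another case's relative set counts as observed.  RR =
observed/expected; significance is the one-tailed Poisson tail
P(X ≥ obs | mean = expected).

Confidence intervals invert the small-sample Poisson test of H0: RR = r.
The default inverts the central mid-P test (each tail halves the
probability of the observed count) by Brent root-finding to 1e-6; the exact
central (Garwood) interval, available as `method="central"` and as
`garwood_ci`, brackets it from outside, and tests assert the mid-P interval
is never wider.  Mid-P trades strict conservatism for near-nominal average
coverage; empirical coverage at the 95% level stays above 95% on the grid
the suite checks, comfortably above the 93% floor asserted.

## Founder pedigrees and the high-risk scan

"Pedigree" is operationalised as a genealogy founder (no recorded parents)
plus all its descendants; pedigrees may overlap, and a founder couple
yields duplicate descendant sets, which reports collapse to the
earlier-born founder.  A founder is not a member of its own descendant set;
consequently a case cluster connected *only* through an affected founder
can escape the scan — a desk-scale corner case documented in the tests.
Expected counts sum cohort rates over all descendants; the test is the same
one-tailed Poisson tail as above (single source of truth, asserted), and a
pedigree is called high risk when p < α (default 0.05) and it has ≥2
observed cases.  No multiplicity adjustment is applied, deliberately: the
scan prioritises sensitivity, and the discreteness of small counts already
makes the per-pedigree type-I error conservative.

Non-overlapping clusters are the connected components of the graph joining
case pairs with positive kinship, computed by union–find over shared
ancestor sets.

## Synthetic genealogies

The simulator emulates the structure such analyses need, at desk scale:

- `SimParams` defaults: 110 initial founders, 5 non-overlapping
  generations, Poisson(2.6) offspring per couple, 35% immigrant-spouse
  rate, first births in the 1830s, ~28-year generation gap, natives born
  in-state with probability 0.85, immigrants always out-of-state.  This
  yields ≈2,000–2,400 individuals of whom roughly half are informative —
  the population scale used for null calibration, with a 0.8% phenotype
  rate giving ~8 informative cases per replicate.
- Couples form within a generation (sibling and parent–offspring unions
  excluded); natives without an eligible partner marry immigrants, so
  pairing never fails.  Child birth years are the parental mean plus the
  generation gap plus Gaussian noise, clamped ≥16 years after the younger
  parent so validation always passes.
- All randomness flows from named seeds; genealogy structure and phenotype
  assignment use separate streams, so phenotypes can be redrawn without
  perturbing the pedigree.

The null phenotype model affects each individual independently with its
(scalar or cohort) rate — the exchangeability that makes the GIF test's
empirical p approximately uniform, verified by the calibration test
(rejection rate at α = 0.05 within [0.02, 0.09] over 200 replicates).

The clustered model seeds a dominant-style risk allele in a fraction of
founders, transmits it to each child with probability 0.5 per carrier
parent, and multiplies carrier risk by an internal risk ratio λ (clipped so
carrier risk ≤ 1).  `familial_multiplier` is defined as the *degree-1
relative risk the model injects*, not λ itself, because the two differ
strongly: in the closed-form approximation RR₁ = [w(1 + τ(λ−1)) +
(1−w)(1 + q(λ−1))]/[1 + (λ−1)q] with carrier frequency q, case-carrier
probability w = λq/(1+(λ−1)q) and relative-carrier-sharing τ ≈ 0.5, RR₁ is
bounded far below λ.  At desk scale two further finite-population effects
compress measured RRs below even that closed form: relatives are counted
once however many cases they flank (union counting), and a clustered
family's own cases inflate its cohorts' rates, raising expected counts.
`calibrate_clustered_model` therefore resolves λ empirically — mean
degree-1 RR measured on a shared set of pilot genealogies at a geometric
grid of λ, monotone inversion, then secant refinement — and the suite
verifies out-of-sample recovery: mean RR over 200 fresh replicates within
15% of the injected target.

The clustered *study condition* (`CLUSTERED_SIM_PARAMS`,
`clustered_study_model`) uses larger genealogies (400 initial founders,
≈7,000–8,000 individuals), baseline risk 0.002 and carrier founder fraction
0.008.  The rarer baseline is deliberate: a degree-1 RR of ~13 is
inexpressible at a 0.8% baseline because carrier risk saturates at 1
(λ ≤ 125) while union counting and cohort self-inflation compress the
measured ratio — the empirical ceiling there is about 6–7.  A rare overall
prevalence with a higher share in the diagnosed subset also mirrors how
rare tumours appear in registry-linked genealogies.  The larger genealogy
keeps 30+ cases per replicate and stops single families from dominating
cohort rates.

What the generator does **not** emulate: overlapping generations,
mortality and censoring, ascertainment (all cases are observed),
record-linkage error, assortative or geographically structured mating, and
realistic demographic history.  Passing tests therefore demonstrate the
*statistical machinery* — calibration of the empirical null, power against
a heritable alternative, parameter recovery, interval coverage — not
robustness to the messiness of real registry data.

## Numerical conventions and degenerate inputs

- Empirical p-values use add-one smoothing; Poisson tails use the exact
  survival function; observed = 0 gives p = 1.
- RR with expected = 0 is undefined: reported as NaN and flagged rather
  than dropped; a pedigree with observed > 0 but expected = 0 reports the
  smallest positive float with a warning.
- Mid-P interval bounds are bisected to 1e-6; the observed-count-level
  interval is cached, so repeated calls at the same observed count (as in
  coverage simulations) cost one root-find.
- GIF requires ≥2 individuals; dGIF requires cutoff ≥ 1; zero control sets
  is an error.
- Kinship caches (pair memo, tabular matrix, ancestor maps) live on the
  genealogy object and survive phenotype reassignment, which touches only
  affection flags.

## Problem sizes used by the test suite

Unit tests run on hand-built pedigrees of 3–35 individuals.  The
calibration, power and recovery checks use 200 replicates at the scales
above (≈2,000-person genealogies with 200 matched control sets for the
null; ≈8,000-person genealogies for the clustered condition, with GIF
power measured on a 60-replicate subset), and the kinship oracle check uses
25 randomized pedigrees of ≤30 members at 10⁵ gene drops — sizes chosen so
the whole suite completes in well under half an hour on a single core
while keeping Monte-Carlo error far below the asserted tolerances.
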