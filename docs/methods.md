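# Methods

## Forward simulation of TIP fate under episodic drought

### Model

A single biallelic locus in a population of diploid *A. thaliana*-like
plants. Genotypes are wild-type homozygote (+/+), heterozygote (+/o) and
insertion homozygote (o/o). The insertion allele is fully recessive
(dominance h = 0): fitness is 1 for +/+ and +/o, and `1 + s⁺` (drought
generations) or `1 + s⁻` (all other generations) for o/o. The population
starts at carrying capacity K with exactly one heterozygous carrier, so
the initial allele frequency is 1/(2K).

Reproduction into each generation:

1. mean parental fitness `w̄` is computed over the current population;
2. **hard selection** sets the next population size
   `N' = min(K, round(K·w̄))`; `N' = 0` is recorded as population
   extinction (an absorbing state, counted as non-persistence);
3. each of the N' offspring draws parent 1 with probability proportional
   to fitness; with probability equal to the selfing rate the offspring
   selfs (parent 2 = parent 1), otherwise parent 2 is drawn independently
   with replacement (self-pairing by chance is allowed and negligible at
   K = 100);
4. each parent transmits one Mendelian allele.

Because offspring are i.i.d. given the parental state, steps 3–4 reduce
to one multinomial draw over the three offspring genotypes, with
probabilities mixing a selfing term (Mendelian segregation within one
fitness-weighted parent) and an outcrossing term (random union of two
fitness-weighted gametes). This is both the simulator's sampling step
and the transition kernel of the exact chain below.

Defaults: K = 100, selfing rate 0.99, G = 50 generations, 1000
replicates per scenario. The scenario sweep crosses
s⁺ ∈ {0.5, 1, 2, 5}, s⁻ ∈ {−0.1, −0.2, −0.5, −0.9}, 1–4 drought events
of 2–4 generations each (192 combinations).

### Drought schedules

"Regular intervals" is realised as: event e (1-based) starts at
generation `round(e·G/(n_events+1))`, leaving head and tail room and
spacing events symmetrically; an explicit schedule can be passed instead
wherever a schedule is accepted. Drought fitness applies to reproduction
*into* a scheduled generation. Schedules whose blocks would overlap
(possible only for short horizons) are rejected.

### Numerical and design choices

- Hard selection uses `K·w̄`, not `N·w̄`: the simplest monotone rule
  consistent with a carrying-capacity cap and a size that is "a function
  of mean fitness". With this rule the size update of a monomorphic
  population is deterministic, which the engine exploits.
- Once the insertion allele is lost or fixed its frequency cannot change
  (no mutation), so replicates stop early; a fixed population may still
  go deterministically extinct under strongly negative s⁻, which is
  checked without further random draws. This makes neutral long-horizon
  runs (G = 500) cheap.
- Persistence means final frequency strictly > 0; fixation means
  frequency exactly 1 in a surviving population; extinction is recorded
  separately and reported with frequency 0.
- RNG: every replicate gets its own child stream spawned from one root
  `SeedSequence`, so grid summaries are bit-identical under a fixed seed
  and independent of execution order.

### Exact-chain oracle

For K ≤ 6 the full state space (all genotype-count compositions of sizes
0..K) is enumerated and the generation update applied as a transition
matrix, using the identical offspring distribution. This provides exact
end-of-run state distributions against which the Monte-Carlo engine is
validated (total-variation distance < 0.01 at 10⁵ replicates), plus a
hand-enumerable special case (K = 2, full selfing, neutral, one
generation) frozen independently in the tests.

### Problem sizes

The packaged checks use 5×10⁴ replicates for the neutral martingale,
2×10⁴ replicates at K = 20, G = 500 for the 1/(2K) fixation law,
10⁵ replicates per setting for the oracle comparison and 10⁴ replicates
per cell for monotonicity, which gives Monte-Carlo errors comfortably
below the tested tolerances. Monotonicity is asserted as "no significant
decrease" (3σ on the difference of two binomial proportions), since
neighbouring cells with weak selection differ by less than pure sampling
noise.

## Phenotyping

Label images carry class codes 0 background / 1 vital / 2 necrotic /
3 scale label. Counting is an exact histogram; unknown codes are
rejected. Calibration multiplies counts by nominal-label-area /
measured-label-pixels, making areas invariant to zoom; the nominal area
defaults to 1 ("label units") since no physical label size is available.
Percent vitality is vital/(vital+necrotic) — background is excluded
because it dominates pot images — and a line is tolerant when its mean
across replicates strictly exceeds 50% (ties are non-tolerant). Images
with no plant tissue yield NaN with a warning and are excluded listwise
from summaries.

Pot weights measured on days adjacent to photo days are piecewise
linearly interpolated (linearly extrapolated from the two nearest points
at the ends, with a warning beyond one inter-measurement interval);
water content is weight − dry weight.

The water-use model is OLS `water_loss ~ C(line) * vital_pixels` with
treatment coding; per-term significance uses Type-II (marginal) F tests,
a choice the analysis itself leaves open — Type-II is invariant to
factor-level ordering and appropriate without a significant interaction.
The reduced model `water_loss ~ vital_pixels` summarises the shared
water-use-per-size law when line and interaction terms are not
significant.

## Insertion catalogue and validation genetics

Coordinates are 1-based inclusive as printed; abbreviated span ends are
expanded by prefix substitution, and re-rendered with at-least-two-digit
suffixes, which round-trips the shipped table cell-for-cell. The
candidate rule is exactly context = Exon ∧ zygosity = homozygous.
Band-pattern genotype calls assume the limited-elongation PCR design in
which a homozygous ~5 kb insertion suppresses the flanking product; the
caller is total over all four patterns ("failed" is a value, not an
error). F2 survival expectations assume a single-locus recessive
loss-of-function model: 1/4 for an outcross to wild type (selfed o/+
F1), 1 for the allelic cross combining two null alleles, 0 for wild-type
crosses.

## Copy number

Amplification efficiency is fixed at 2 (perfect doubling); no standard
curve is modelled. Replicate SDs of target and reference are combined in
quadrature through both Ct differences; the fold-scale SD uses the delta
method (`sd_fold = ln2 · fold · sd_ΔΔCt`). The wild-type baseline of 8
ONSEN copies is implied by the published 8-fold ≈ 64-copy conversion
rather than stated directly; it is exposed as a parameter everywhere.

## Aridity association

- **maf filter**: frequencies over non-missing alleles, strict > 0.3.
- **Kinship**: KING-robust,
  `k = (N_het,het − 2·N_opposing_hom) / (N_het,i + N_het,j)` over
  pairwise-shared non-missing sites; duplicates give exactly 0.5 when at
  least one heterozygous site exists; pairs with no heterozygous sites
  are undefined (NaN) and ignored by pruning. Pruning is greedy: while
  any pair has k ≥ 0.5, drop the ecotype in the most such pairs (ties:
  lexicographically smallest id) — one representative survives per
  duplicate cluster.
- **LMM**: maximum likelihood (not REML), profiling the variance ratio
  λ = σ²_g/σ²_e on [e⁻²⁵, e¹⁰] by bounded 1-D minimisation with the
  boundary λ = 0 checked explicitly; at each λ the group-block covariance
  is inverted in closed form (Sherman–Morrison per group), giving O(n)
  GLS updates. The SNP test is a Wald z-test. ML was chosen over REML as
  the simplest estimator for a single variance component at n ≈ 600 with
  2 fixed effects; the fit is cross-checked against an independent
  general-purpose mixed-model implementation in the tests.
- **Variance explained** is defined (the source analysis does not define
  it) as the fixed-effect share of total modelled variance:
  `VE = 100·β̂²·Var(g) / (β̂²·Var(g) + σ̂²_g + σ̂²_e)`, with Var(g) the
  sample variance (ddof = 1) of the dosage.
- **LD** is the squared Pearson correlation of dosage vectors over
  pairwise-complete ecotypes (composite LD), invariant to allele
  relabelling.
- The aridity response is labelled "summer mean" without committing to a
  month window; window handling is the caller's concern.

## Synthetic data

Generators emulate the structure of the study's raw inputs, not their
appearance:

- **Disc images**: uniform discs of known radius plus a rectangular
  scale label, placed by seeded rejection sampling; truth records exact
  painted pixels per disc. Class-flip noise (default experiments use 2%)
  emulates classifier confusion at boundaries. Real segmentations have
  irregular leaf shapes, shadows and spatially correlated errors; these
  are not modelled, so passing tests validate the counting/calibration
  arithmetic, not segmentation quality.
- **Weights / water-loss tables**: daily loss `a + b·size + ε` with
  optional per-line intercept/slope deviations. Defaults (150 pots, 5
  lines, a = 20 g, b = 0.004 g per vital pixel, σ = 2 g, sizes
  2000–20000 px) give the regression a signal-to-noise ratio at which
  the slope is estimated precisely but line effects of realistic size
  are detectable — comparable to the published experiment's clear size
  effect. Real evaporation is nonlinear in time and weather-driven; the
  linear generator matches the model being tested, so recovery tests
  demonstrate estimator correctness only.
- **TIP tables**: contexts drawn with an exon bias (default 0.6,
  matching the observed 6/10 exonic fraction), zygosity Bernoulli
  (default 0.6 homozygous vs the observed 6/10).
- **Panels**: 596 ecotypes in 9 admixture groups (the scale of the
  kinship-pruned accession set), 11 SNPs (the number found in *RPI2*)
  with allele frequencies in [0.3, 0.5], group SD 0.45 and residual SD 1
  — group effects explain ~17% of trait variance, a moderate degree of
  structure. The causal effect β is solved from the target variance
  explained (default 4.3%) using the realised dosage variance. Dosages
  are Hardy–Weinberg draws and SNPs are independent, so LD between
  panel SNPs is near zero by construction — unlike the real gene-local
  panel, where SNPs are strongly linked; LD estimation is therefore
  tested for calibration (independence → r² ≈ 0) and invariances, not
  for realistic haplotype structure. Duplicate clusters clone ecotypes
  whose genotypes contain at least one heterozygous site so the KING
  coefficient of a clone pair is exactly 0.5.
- **qPCR plates**: Ct_target = base − log2(fold) + noise, three
  technical replicates, control sample always present.

Every generator requires a seed and returns truth as a separate record;
tests and the acceptance script never re-derive truth from the generated
data.

## Known limitations

- Single locus, no mutation, recombination, migration or multiple
  insertions; the simulator addresses the fate of one TIP, not genome
  dynamics.
- The hard-selection size rule `K·w̄` is one of several readings of
  "size as a function of mean fitness"; results for strongly deleterious
  regimes (s⁻ = −0.9) depend quantitatively, though not qualitatively,
  on that choice.
- The LMM profiles a single variance component; it does not extend to
  crossed random effects or a full genomic relationship matrix.
- Image analysis consumes label maps; no classifier is trained or
  evaluated here.
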