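# Methods

## Photothermal time

Daily photothermal units are λᵢ(μ_Li − μ_b) for days whose daylight mean
temperature μ_Li strictly exceeds the base temperature μ_b (default
3 °C, the optimized base for the developmental rate of Arabidopsis
Col-0); λᵢ is the photoperiod as a fraction of 24 h.  Days at or below
the base contribute exactly zero — they are excluded, not clipped into
negative contributions.  Units are °C·daylight-days.

Intervals are half-open [start, end): the germination day counts toward
the vegetative period and the flowering-initiation day does not.  This
convention is a deliberate choice — the summation's endpoints are
genuinely ambiguous as usually written — because it is the only one
under which vegetative PTU (g→fi) plus flowering PTU (fi→ft) equals the
total g→ft PTU exactly.  A closed-interval switch is exposed in
`PTUConfig` for sensitivity checks.

Sub-daily logger records are averaged, unweighted, over the half-open
daylight window [sunrise, sunset).  A day with no daylight reading is
reported as a gap and its temperature left missing; gaps inside an
accumulation interval are a hard error.  No interpolation happens
silently.

## The SIg synchronization index

SIg = log₂(Var(germination cohort means) / Var(event cohort means)).
Both variances are sample variances (n−1) over the same cohort set in
the same order; the estimator choice cancels in the ratio, which is why
the implementation insists on matched cohort sets.  Classification is by
sign; |SIg| > 4 (a 16-fold variance change) is additionally flagged
"strong" as a reporting band.  Zero event variance yields +∞ with an
exactness flag rather than a capped value — capping would silently
reorder results.  Zero germination variance (no stagger to compare
against) makes the index undefined.

A cohort contributes to an event only if at least half its plants
(configurable) have the event recorded, so one surviving plant cannot
impersonate a cohort mean.

## The sequential-seeding generator

The generator encodes the hypothesis the synchrony analysis is built to
detect, as a mechanism:

* **Germination** is exactly the cohort's seeding offset (cohorts every
  7 days, 5 cohorts, 8 replicates, two regimes whose daylight means
  differ by a constant 3 °C).
* **Flowering initiation** occurs on the first day accumulated PTU from
  germination reaches a threshold (default 300 °C·daylight-days, giving
  first-cohort vegetative periods of ~6 weeks); **bolting** fires at a
  fixed PTU lead (default 30) before that threshold.
* **Termination and senescence** follow a seasonal cue shared by all
  cohorts of a regime: a fixed calendar day (default 150), with
  termination preceding senescence by 14 days.
* The environment is a cooling season: daylight mean temperature
  declining linearly at 0.12 °C/day from 18 °C with a 4 °C floor, and a
  smooth annual photoperiod sinusoid around 12 h.  The decline rate was
  chosen so that the cohort-to-cohort lengthening of the vegetative
  period amplifies flowering-initiation variance by roughly 2–5× the
  germination-stagger variance — the magnitude band reported for this
  design — rather than leaving it marginal.
* **Event noise** is independent Gaussian day-jitter (default sd 1 day;
  the within-cohort spread of event dates is not published for this
  design, so it is a free parameter).  Jitter is redrawn until the event
  ordering g ≤ bolting ≤ fi ≤ ft ≤ senescence holds (after 100 redraws a
  cumulative-max fallback forces monotonicity; at realistic noise levels
  this path is unreachable).  Events are rounded to whole days.

What the generator does *not* emulate: within-greenhouse spatial
structure, mortality, vernalization requirements, hormonal signalling
between plants, or any feedback of plant state on the environment.
Passing tests therefore show that the analysis recovers the designed
mechanism from data shaped like the study's — not that the mechanism is
true of real plants.

## The RIL generator

Each line's genome is a two-state Markov chain per chromosome: a fair
coin at the first marker, then allele switches between adjacent markers
with the Haldane recombination fraction r = (1 − e^(−2d/100))/2 for
their distance d.  Map distances are consumed as given: a published RIL
map already embeds the map expansion of the selfing generations, so no
additional correction is applied (and none is applied later by the scan,
keeping generator and analysis consistent).  The default map is
paper-scale: 5 chromosomes, 144 markers, lengths 120/75/95/80/120 cM,
marker spacing jittered uniformly with a 0.5 cM minimum.

Phenotypes: replicate value = grand mean + Σ aⱼsⱼ + Σ e·s_a s_b +
N(0, σ), with s = ±1 allele coding at the marker nearest each configured
QTL (effects act *at markers*; placing effects between markers would
require sampling latent genotypes and buys no generality for the tests
this package runs).  Line values are means of 8 replicates, so a lone
QTL's variance share among line means is a²/(a² + σ²/8);
`additive_effect_for_share` inverts this.  At n = 105 lines the realized
share of a single draw can deviate by several points from the target —
that is sampling, not miscalibration; the share converges at n = 500.

## QTL scan

Genotype probabilities come from a forward–backward pass over markers
plus pseudomarkers spaced ≤ 2 cM, with Haldane transitions and an
emission that assigns 1 − ε to the observed allele (ε = 0 by default, so
probabilities collapse at typed markers).  A line untyped on an entire
chromosome gets a uniform 0.5 posterior there and is flagged.

The scan is Haley–Knott regression: phenotype on E[dosage] = P(B) at
each grid position, LOD = (n/2)·log₁₀(RSS_reduced/RSS_full).  With no
covariates this is computed through the correlation identity
LOD = −(n/2)·log₁₀(1 − r²), which vectorizes over positions and over
permutation replicates; monomorphic positions get LOD 0.  Interval
mapping by EM is out of scope — Haley–Knott is the implemented method.

Composite interval mapping adds covariate markers chosen by forward
stepwise regression on typed-marker dosages (default up to 3, entry
gated by a partial F-test at 0.05, ties broken by genome order) and
drops any covariate within ±window (default 2 cM) of the tested
position.  With zero covariates CIM reduces exactly to the plain scan.

Permutation thresholds shuffle phenotype labels only (the RIL design has
no family structure to stratify on) and take the (1−α) empirical
quantile of genome-wide maxima; α = 0.05 and 0.63 mark significant and
suggestive peaks.  The reference analysis uses 10 000 permutations;
routine runs and the test suite use 1 000, which is ample for these two
quantiles.

Credible intervals take 10^LOD as the likelihood over the chromosome's
grid with a uniform positional prior, and grow the interval from the
peak (leftmost on ties) toward the side with more posterior mass until
it holds 95 %.  Grid points carry equal prior weight; the grid is
near-uniform by construction, so no spacing correction is applied.  This
interval type is known to undercover somewhat in single-QTL simulations;
the package's recovery test budgets for that (≥ 88 % nominal-95 %
coverage).

Multiple-QTL models regress on all peak dosages plus requested
interaction products; per-term R² is the drop-one share
100·(RSS_without − RSS_full)/TSS.  Peak pairs with |corr| > 0.99 are
rejected as collinear, naming the pair.  The two-locus scan compares
full (additive + product) and additive models against the null on a
coarsened grid (default 10 cM; same-chromosome pairs closer than twice
the step are skipped to avoid collinearity), so LOD_int =
LOD_full − LOD_add ≥ 0 up to numerical tolerance.

## Numerical and interface conventions

* All dates are integer day offsets from a run-level reference date;
  ISO-8601 appears only at the I/O boundary and the conversion is
  logged.
* Delimiter detection accepts comma and tab only.
* Output files never overwrite without an explicit force flag.
* Every randomized operation takes an explicit seed; identical
  (config, seed) reproduce outputs bit for bit.
* LOD maxima tie-break to the lowest cM position, deterministically.

## Problem sizes used in the test suite

The behavioural checks run at sizes chosen to make their statistics
stable while keeping the suite quick: 200 simulated SSE datasets for the
sign-pattern check; 500 null RIL datasets × 1 000 permutations for
type-I calibration; 200 replicates at n = 500 lines for R² recovery and
interval coverage; 20 random datasets for the least-squares oracle
comparison.

## Known limitations

* Phenotype effects are placed at markers, not between them.
* The Bayes interval uses grid-point mass, not length-weighted density.
* No X-chromosome handling, multi-parent designs, or missing-phenotype
  imputation; lines without a phenotype are dropped.
* The SSE generator's senescence rule is a calendar cue; a true
  environmental trigger (e.g. a temperature threshold) would differ
  between regimes in richer ways than a per-regime date can express.
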