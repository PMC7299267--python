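# phenoqtl

Tools for asking two linked questions about the timing of reproduction in
monocarpic plants such as *Arabidopsis thaliana*:

1. **Is a phenological event synchronized across plants of different ages?**
   In a sequential-seeding experiment (SSE), cohorts are sown at fixed
   intervals so germination is staggered by design.  The package computes
   the synchronization index

   SIg = log₂ ( Var(germination cohort means) / Var(event cohort means) ),

   where SIg > 0 means the event's spread across cohorts shrank relative
   to the germination stagger (synchrony: +1 = halved variance, +2 =
   quartered) and SIg < 0 means it grew (desynchrony: −1 = doubled, −2 =
   quadrupled).  Alongside it, the package accumulates **photothermal
   units** (PTU = Σᵢ λᵢ(μ_Li − μ_b), with λᵢ the daylight fraction of the
   day, μ_Li the daylight mean temperature and base temperature μ_b = 3 °C)
   over the vegetative (germination → flowering initiation) and flowering
   (initiation → termination) periods, to test whether plants flower at a
   constant accumulated PTU rather than a constant age.

2. **Which loci control those timing traits?**  A from-scratch QTL genome
   scan for two-allele recombinant inbred line (RIL) populations:
   Haldane map function, hidden-Markov genotype probabilities at 2-cM
   pseudomarkers, Haley–Knott regression LOD profiles (simple and
   composite interval mapping), genome-wide permutation thresholds at
   α = 0.05 (significant) and α = 0.63 (suggestive), 95 % Bayes credible
   intervals (posterior ∝ 10^LOD), multiple-QTL variance decomposition,
   and a two-locus additive/epistasis scan.

A synthetic-data module generates SSE cohort phenology (5 cohorts ×
7-day offsets × 8 replicates × 2 temperature regimes ~3 °C apart) and
RIL populations (105 lines × 144 markers on 5 chromosomes by default)
with known ground truth, so the whole pipeline is testable end to end.

## Worked example

Simulate an SSE and compute the synchrony table:

```
$ phenoqtl simulate-sse --seed 42 --outdir demo
wrote 80 plant records to demo
$ phenoqtl sig --phenology demo/phenology.csv --out demo/sig.csv
wrote 8 SIg rows to demo/sig.csv
```

The first rows of `demo/sig.csv` (colder regime):

| event           | var_germ | var_event | SIg   | classification |
|-----------------|----------|-----------|-------|----------------|
| bolting         | 122.5    | 326.7     | −1.42 | desynchronized |
| flowering_init  | 122.5    | 437.0     | −1.83 | desynchronized |
| flowering_term  | 122.5    | 0.211     | +9.18 | synchronized   |
| senescence      | 122.5    | 0.039     | +11.6 | synchronized   |

Flowering initiation is desynchronized (cohort variance ~3.6× the
germination stagger: later-sown cohorts meet a cooling season and need
more days to reach the same PTU threshold), while termination and
senescence are almost perfectly synchronized — the event variance
collapses because all cohorts respond to the same seasonal cue.

Simulate a RIL trait with one QTL at 40 cM on chromosome 1 explaining
25 % of the line-mean variance, then scan:

```
$ phenoqtl simulate-ril --seed 42 --qtl 1:40:0.25 --outdir demo
wrote 105 lines x 144 markers to demo
$ phenoqtl scan --genotypes demo/genotypes.csv --phenotypes demo/phenotypes.csv \
    --n-perm 1000 --seed 42 --outdir demo
max LOD 9.85; thresholds alpha=0.05: 2.38, alpha=0.63: 1.08; 1 peak(s)
```

`demo/peaks.csv` reports the peak on chromosome 1 at 32.97 cM
(LOD 9.85, significant, nearest marker m1_06, 95 % credible interval
[31.0, 38.5] cM, R² = 35.1 %) — the planted locus recovered within the
localization noise expected at n = 105 lines.

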