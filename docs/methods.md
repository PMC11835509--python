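# Methods

This note records the model underlying `tetracross`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data
can and cannot say about real breeding programs.

## Program structure

A scenario simulates `n_cycles` recurrent breeding cycles after a common
randomised burn-in (cycle 0). Each cycle:

1. enumerates the legal candidate crosses — at cycle 1 the half-diallel of
   the 100-parent pool minus the 300 burn-in crosses; from cycle 2 on only
   old × new crosses plus the half-diallel of the 20 newest parents
   (1790 candidates before exclusions). No cross is ever planned twice and
   self-crosses are excluded throughout;
2. scores the candidates with the configured criterion and plans the top
   300 (ties broken by candidate order);
3. simulates the same number of seedlings per planned cross
   (`n_sl // n_plan`, remainder dropped; desk default 3000/300 = 10);
4. runs the testing ladder SL → SH → A → B → C → D with stage proportions
   p1..p5 and selects exactly `n_d` = 60 D clones;
5. records metrics on the D population and refreshes the pool: the top 20
   D clones by their 4-location phenotype enter; 20 parents unused in the
   cycle's plan leave (the removal pool widens to parents used once, then
   twice, when fewer than 20 are unused; a remaining shortfall removes all
   available and is logged).

Seeds are hierarchical (`SeedSequence(master, spawn_key=...)`): founder
generation, per-run trait architecture, burn-in and each cycle draw from
independent streams. The burn-in stream does not depend on the criterion,
so different criteria share identical starting states within a run and can
be compared pairwise.

## Meiosis

Random bivalent pairing (3 equiprobable partitions of the four homologs),
one recombinant chromatid per bivalent, crossovers as a Poisson process on
the genetic map (count ~ Poisson(map span), positions uniform; Haldane, no
interference), no double reduction and no preferential pairing. This makes
single-locus gamete dosages follow the classical tetrasomic hypergeometric
law (duplex → 1/6 : 2/3 : 1/6), which the tests exploit as an analytic
oracle. An obligate crossover is *not* enforced. Gametes restricted to a
marker subset are generated directly on that subset; this is exact because
the chromatid's strand at a marker depends only on the crossover count
before it. The assembly kernel is compiled (numba); all randomness is
drawn from the numpy generator beforehand, so results are bit-reproducible
per stream.

Double reduction is a real tetrasomic phenomenon that we deliberately set
to zero; rankings of crosses whose merit rests on rare recessive
configurations could shift slightly under nonzero double reduction.

## Trait model

Genetic values follow the five-class tetraploid dosage table: breeding
value = dosage · a, genetic value adds one dominance deviation d = δ · a
for the three heterozygous classes (the three class deviations d1, d2, d3
are kept as separate fields but share this value by default — the simplest
construction consistent with a single QTL-level degree of dominance).
Additive effects are Gamma(2, 0.2) draws (mean 0.4); the favorable allele
is assigned to reference/alternate uniformly at random per QTL so effect
direction is not aligned with founder allele frequency. The four dominance
regimes scale one common δ ~ N(1, 1) draw by 0/1/2/3, so architectures are
identical across regimes up to that scaling for a fixed seed.

QTL markers stay in the heterozygosity panel (there is no evidence they
should be excluded); `TraitArchitecture.qtl_idx` makes exclusion trivial
for users who want it.

The auxiliary trait (the early-stage selection target) is purely additive
on the same QTLs: its effects are a mixture
`b(θ) = cos θ · s_t/σ_x + sin θ · s_e/σ_y` of the target trait's signed
effects and an independent same-distribution draw, with θ calibrated by
root-bracketing so that the realised founder-level correlation between the
two traits' TGVs hits the requested r (default 0.15) within ±0.03. Under
strong dominance the additive score can even anti-correlate with the
target TGV, so the attainable range of r shrinks; calibration fails loudly
with the attainable range when the request is outside it.

## Phenotypes and the GS proxy

Target-trait phenotype noise at stage j is (σ²G×L + σ²trial)/L_j with
L_B = 1, L_C = 2, L_D = 4. The D-stage count of four locations is pinned
by the entry-mean heritability 0.73 that follows from the 1 : 1 : 0.5
variance-component ratio; B and C counts are package defaults chosen to
increase monotonically along the ladder. σ²trial is frozen at the burn-in
seedling calibration; σ²G and σ²G×L are re-anchored at the seedling stage
of every cycle. The auxiliary trait uses a single frozen error variance
derived from its heritability (0.6).

Genomic selection is represented by a noise proxy rather than a trained
marker model: estimated values are true values plus
N(0, (1/(n′−2)) · ((1−PA²)/PA²) · Σ(x_i − x̄)²) over the genotyped set, so
the realised accuracy converges to PA (default 0.5). Proxy noise is
redrawn at every invocation; there is no persistent clone-level GS error
(the alternative would correlate estimates across cycles, which the
program's bookkeeping does not need).

Parental phenotypes used by the MPV criterion are D-equivalent 4-location
phenotypes refreshed in the cycle they are evaluated. Because
H²_D = 0.73 > PA² = 0.25, MPV ranks mid-parents better than the
proxy-based parent criteria — the intended behaviour of the design.

## Selection strategies

Three presets ship; their stage proportions are package defaults (the
exact proportions of the program they emulate are not public), all landing
3000 seedlings on 60 D clones:

| preset | p1 (SL) | p2 (SH) | p3 (A) | p4 (B) | p5 (C) | GS |
| --- | --- | --- | --- | --- | --- | --- |
| standard-ps | 0.20 | 0.40 | 0.50 | 0.70 | 0.71 | — |
| optimal-ps | 0.50 | 0.50 | 0.53 | 0.30 | 0.50 | — |
| optimal-gs | 0.50 | 0.20 | 0.50 | 0.60 | 0.67 | SH, A (α = 0.4, 1.0) |

The standard scheme culls hard in the early stages, which select only on
the weakly correlated auxiliary trait; the optimised phenotypic scheme
moves intensity onto the target-trait B/C stages; the genomic scheme
applies a two-step filter at SH and A — keep the top α_k by auxiliary
phenotype, genotype them, then meet the stage proportion by ranking the
genotyped subset on estimated genetic values. Fractional selections round
up; the final C → D event selects exactly `n_d`.

## Cross scoring

One shared in-silico progeny sample per candidate cross serves the progeny
mean, σ_G and He (three independent samples would triple the meiosis cost
for no benefit at the reported precision). μ uses proxy values (EBV for
MEBV-O, EGV for MEGV-O/EUC/EUCD); σ_G is the standard deviation of the
progenies' *true* genetic values — the proxy's noise variance is the same
for every cross in a cycle, so adding it mostly blurs rankings
(`sigma_from_proxy=True` restores it). The selection intensity inside
EUC/EUCD is the constant i(0.1) = 1.755 from the assumed per-cross
selected proportion, not a ladder quantity. The in-silico sample size is
configurable (50–1000, library default 200); progeny-mean accuracy is
known to be insensitive to it, which is why the desk-scale suites use 50.
`he_panel` optionally subsamples the marker panel (evenly spaced) for the
per-cross He; per-cross He is nearly a function of the parents' pooled
allele frequencies, so a few hundred markers rank crosses identically in
practice (the test suite checks r > 0.99 against pooled-parent He).

## Metrics

All per-cycle metrics are assessed on the 60 D clones: gain = mean TGV
minus the frozen founder mean; genetic variance = sample variance of TGV;
He over the full panel; fixed/lost = QTLs where every D clone carries 4/0
favorable alleles. Fixed-in-D counts can fluctuate (the D population is a
fresh sample each cycle); fixation in the candidate-parent pool is the
absorbing notion and is what the invariant tests check. Conversion
efficiency is the two-point slope of run-averaged gain change against
run-averaged genetic-SD loss between the first and last cycle; a per-cycle
regression is emitted as a diagnostic. Progeny-mean accuracy is the
Pearson correlation between the criterion's predicted μ and the realised
mean TGV of each planned cross's seedlings (at the burn-in cycle the
random plan is scored post hoc with the configured criterion).

## Synthetic founders

Per-marker allele frequencies are uniform on [maf_min, 1 − maf_min]
(default floor 0.05), haplotypes sampled independently, then 10
generations of random mating (via the package's own meiosis) build
map-consistent linkage disequilibrium. Markers whose realised minor allele
frequency falls below the floor are dropped from a simulated surplus, or
resampled in place when the surplus is exhausted (resampled columns carry
no burn-in LD). The genetic map is linear, 1 Morgan per chromosome by
default; marker positions are uniform on a 70-Mb chromosome. The default
panel is 12 × 200 = 2400 markers.

What this emulates: a diverse, highly heterozygous tetraploid panel with
realistic tetrasomic segregation and distance-decaying LD. What it does
not: empirical LD structure, allele-frequency spectra shaped by selection
history, variable recombination (Marey-map) landscapes, or genotyping
error. Absolute gain and He values therefore depend on panel density and
map length, and only *relative* comparisons between strategies/criteria at
matched conditions transfer to real programs.

## Problem sizes in the shipped suites

The directional test suites run the full founder panel (80 clones,
12 × 200 markers) with 200 QTLs, 10 cycles, 10 replicate runs, 50
in-silico progenies per candidate cross and a 240-marker He panel for the
diversity-weighted criterion; the acceptance script uses the same
dimensions with 8 cycles and 4 runs. These sizes keep a full suite in the
minutes range on one CPU while leaving the tested orderings (GS vs. PS
strategies, MEGV-O vs. MEBV-O under dominance, EUCD vs. UC on final He)
stable across seeds. Trajectory *magnitudes* at this scale are smaller
than at the full program scale (2000 QTLs, ~50k markers, 30 cycles, 30
runs) — scale up the config to approach those conditions.

## Known limitations

* No double reduction, quadrivalents, preferential pairing or sex-specific
  maps; no interference (pure Haldane).
* No epistasis; dominance is a single shared deviation per QTL across the
  three heterozygous classes.
* The GS proxy has no training-population genetics: accuracy is an input,
  not an emergent property, and does not decay between model updates.
* Optimal cross-selection (portfolio optimisation over the whole crossing
  plan) is out of scope; criteria rank crosses independently.
* Economic budget optimisation of stage proportions is out of scope; the
  strategy presets are fixed ladders.
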