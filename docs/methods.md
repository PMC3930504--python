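# Methods

## The question the package answers

A locus shows extreme allele-frequency differentiation between an African
and a European population sample (per-site FST near 1) but unremarkable
values of the classical neutrality statistics in both populations. Two
hypotheses are compared: (i) neutral evolution under a calibrated human
demographic history, and (ii) directional selection on the derived allele in
the African population, with the proviso that a recombination hotspot beside
the selected site has decoupled the flanking variation and eroded the
haplotype-structure and site-frequency-spectrum footprints of the sweep.
The comparison is made by simulating both scenarios, locating the observed
statistic values within the simulated null distributions, and forming
composite empirical likelihood ratios.

## Demographic model

The two-population history follows the published calibrated ("best-fit")
coalescent model of human African/European demography, reduced to the two
sampled demes, with three modifications used for this analysis:

* all migration rates are zero;
* the post-split African and European bottlenecks are both moved to 3,300
  generations before present (so that even the slowest sweep modelled fits
  inside a constant-size epoch);
* the sweep ends 350 generations before present, which retains the terminal
  population expansions.

Defaults (diploid N, generations before present):

| parameter | value | meaning |
| --- | --- | --- |
| N present (both demes) | 100,000 | post-agricultural expansion |
| African N | 24,000 | from 200 gen BP back; the sweep epoch |
| European N | 7,700 | from 350 gen BP back |
| bottlenecks | F=0.008 (AFR), 0.02 (EUR) at 3,300 gen | instantaneous, inbreeding prob. F |
| out-of-Africa bottleneck | F=0.085 at 3,499 gen | European lineage |
| split | 3,500 gen | Europeans merge into the African lineage |
| ancestral N | 24,000 → 12,500 at 17,000 gen | African/ancestral sizes |
| mutation rate | 1.5×10⁻⁸ /bp/gen | the calibrated model's default |

cosi-style bottlenecks of inbreeding probability F are encoded as
coalescent instantaneous bottlenecks of strength −2N·ln(1−F).

## Sweep model and trajectories

Selection is additive (genic) on a single derived allele in the African
deme: cosi-convention coefficient *s* with genotype fitnesses 1, 1+s, 1+2s.
The sweep starts from one copy (p₀ = 1/(2N), N = 24,000) and is conditioned
to reach frequency 0.98 at 350 generations before present.

`sweep_trajectory` offers two modes. The **deterministic** mode integrates
the logistic genic path, giving duration
T = (1/s)·ln(p_f(1−p₀)/(p₀(1−p_f))) — 2,934 / 1,467 / 489 generations for
s = 0.005 / 0.01 / 0.03, matching the published durations to 0.2% for the
two weaker coefficients and 7% for s = 0.03 (whose published duration
departs from exact 1/s scaling; the closed form documented here is the
package's reference). The **stochastic** mode draws a conditioned
Wright–Fisher diffusion bridge backward from 0.98 with the
fixation-conditioned drift s·x(1−x)/(1−e^(−2Nsx)) and per-generation
variance x(1−x)/(2N); conditioned paths run somewhat faster than the
logistic (mean ≈ 2,100 generations at s = 0.005).

The coalescent engine uses msprime's structured sweep model, which draws
its own stochastic conditioned trajectory. msprime parameterizes the
heterozygote as 1 + s/2 — half the cosi scale — so the engine passes 2s.
Because the sweep model only supports a single deme and migration is zero
throughout, the genealogy decomposes exactly: African lineages (standard
coalescent for 350 generations, then the sweep phase, then standard) and
European lineages (neutral) are simulated separately back to the split
time, the partial tree sequences are unioned, and remaining lineages
coalesce in the ancestral population (merged via a mass migration at the
split; the event is offset half a generation past the resume time because
an event at exactly the resume time does not fire). Rarely the stochastic
sweep phase outlasts the 3,300-generation epoch boundary; such replicates
fail cleanly and are redrawn with a fresh counter-derived seed (redraw
counts are recorded; at s = 0.005 roughly 1–3% of replicates redraw).

msprime does not place the beneficial mutation itself. Because a hard sweep
from one copy forces the derived class to coalesce into a single lineage by
the sweep origin, the marginal tree at the selected position contains a
clade holding (nearly) a 0.98 fraction of the African sample and no
European chromosome. The engine injects the derived allele on the clade
with zero European descendants whose African frequency is closest to the
final frequency (mean injected frequency 0.980, range ≈ 0.95–1.0 across
replicates; European frequency exactly 0).

## Recombination landscapes

Piecewise-constant maps over the 100 kb region:

* **constant** — 8.17×10⁻⁹ /bp/gen, the mean rate of the studied window;
* **hotspot** — background 1×10⁻⁸ with a 3,500 bp interval at 7×10⁻⁸
  (≈7 cM/Mb, 7-fold background) starting one bp right of the selected site
  (midpoint, 50 kb), i.e. immediately adjacent without covering it;
* **from_file** — two-column (position_bp, rate_cM/Mb) HapMap-style text,
  1 cM/Mb = 10⁻⁸ /bp/gen.

The hotspot's map length (2.45×10⁻⁴ crossovers/gen) times a weak sweep's
duration is of order one, so an appreciable fraction of swept lineages
recombine across it — the mechanism that erodes linked signatures.

## Synthetic panels and what they do and do not emulate

`simulate_panel` returns a polarized two-population panel (176 African +
194 European chromosomes over 100 kb; binary mutation model, so 0 is
ancestral at every site). `thin_singletons` then removes
round(0.48·K) of the K pooled-singleton sites uniformly at random
(round-half-away-from-zero), emulating the under-calling of singletons in
low-coverage sequence data. The generator reproduces the study conditions —
sample sizes, region length, demography, sweep endpoint, landscape — but
not sequencing artefacts beyond the singleton deficit (no genotyping error,
no missing data, no phasing switch errors, free recombination-map
uncertainty). Passing tests therefore validate the method under the modeled
conditions, not the full error structure of real resequencing panels.

## Statistics

All sample sizes are chromosome counts; panels are haploid rows.

* π = Σ 2p(1−p)·n/(n−1); θ_W = S/a_n; θ_H = Σ 2S_i·i²/(n(n−1)).
* Tajima's D with the 1989 constants; undefined (NaN) when S = 0.
* Fu & Li's D in the outgroup form (η_e = derived singletons), 1993
  constants.
* Fay & Wu's H is the unstandardized π − θ_H (the normalized variant
  postdates the convention adopted here); both it and Fu & Li's D refuse
  unpolarized input, and sites with unknown ancestral state are masked for
  them rather than dropped from the panel.
* FST is the haploid Weir–Cockerham ANOVA on chromosome counts —
  (MSP−MSG)/(MSP+(n_c−1)MSG) — reported as computed (negative values are
  not clamped, preserving the null-distribution shape). Hudson's
  1−H_w/H_b (unbiased within-heterozygosity) is carried as an independent
  cross-estimator; the two agree to 10⁻⁶ at equal sample sizes.
* EHH from a core site counts identical haplotype pairs over the sites
  strictly beyond the core, so EHH(0) = 1 by construction and the curve is
  non-increasing. XP-EHH integrates each population's EHH over physical
  distance in both directions, truncated one site past where the *pooled*
  two-population EHH first drops below 0.05 (or at the region edge), and
  reports ln(iHH_A/iHH_B); a standardized variant subtracts the mean and
  divides by the SD of a supplied neutral reference ensemble. Genetic-map
  distance integration is deliberately not the default (reproducible
  without a map).
* Sliding windows are half-open [start, start+width), width 30 kb, starts
  at multiples of the 3 kb offset, last start the largest with
  start+width ≤ region length (24 windows on 100 kb). SFS statistics are
  computed from the sites inside each window; per-site statistics (FST,
  ΔDAF, XP-EHH) are summarized by the window maximum. Windows with no
  usable site carry NaN, and NaNs never enter window summaries.

## Per-replicate summaries

Scenario ensembles store one summary per statistic per replicate, extracted
around the selected site (10 kb window):

* Tajima's D, Fu & Li's D, Fay & Wu's H — computed in the African sample
  from in-window sites;
* FST, ΔDAF — the value at the selected site, falling back to the window
  maximum when the site is absent (neutral replicates);
* XP-EHH — the mean of per-site scores across the window, the same
  10 kb averaging applied to observed data, evaluated on at most 16 evenly
  spaced in-window sites (subsampling keeps ensembles tractable; the mean
  over a site subset is an unbiased estimate of the window mean). The
  window mean, not the at-site score, is the summary because a one-sided
  flanking hotspot rescales both populations' EHH integrals almost
  proportionally at the selected site itself, leaving the at-site log-ratio
  blind to the hotspot; the windowed average sees the decoupling of sites
  across the hotspot.

## Empirical inference

For an observed value x and an R-replicate ensemble, F = #(ensemble ≤ x)/R
(ties count as ≤) and p = 2·min(F, 1−F); a value at the median scores
exactly 1 with no special-casing. Probabilities are floored at 1/R so an
observation outside the simulated range yields a small finite probability
rather than zero (products would otherwise vanish); floored statistics are
flagged in the evaluation metadata. Combinations must include at least one
statistic from each signature class (differentiation / haplotype / SFS),
FST and ΔDAF never co-occur, and the default table holds the three minimal
FST-based combinations plus the all-statistics set {FST, XP-EHH, Tajima's
D, Fu & Li's D, Fay & Wu's H} (ΔDAF excluded by default, available by
flag). Likelihood ratios divide a sweep scenario's composite by the
neutral composite computed under the same recombination landscape. An
undefined observed statistic invalidates only the combinations containing
it.

## Seeds and reproducibility

Every randomized operation takes an explicit seed. Ensembles derive
per-replicate seeds from a master seed through a counter-based SeedSequence
scheme keyed on (scenario index, replicate index, attempt), so runs are
bit-reproducible, independent of execution order, and a failed replicate's
redraw does not shift any other replicate's seed.

## Problem sizes used by the test suite

The simulation-backed tests run the study conditions at test scale chosen
to make the targeted effects statistically decisive: 200 replicates per
scenario for the recombination-landscape contrasts, 100 replicates per
scenario for the likelihood-ratio grid, and 20 pseudo-observed repetitions
— about a thousand coalescent simulations in total for the suite.

## Known limitations

* The sweep engine's trajectory is stochastic (msprime); effective sweep
  durations average ~30% shorter than the deterministic logistic, so
  linked-signal erosion is, if anything, slightly understated relative to a
  deterministic-trajectory engine at equal s.
* Hard sweeps from a single new mutation only; no soft/recurrent sweeps,
  background selection or gene conversion.
* Exactly two sampled populations; additional panels enter only through
  published frequency tables.
* The redraw policy conditions weak-sweep ensembles on the trajectory
  fitting inside the constant-size epoch (a 1–3% selection effect at
  s = 0.005).
* The binomial detection bound assumes Hardy–Weinberg sampling of
  chromosomes within populations.
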