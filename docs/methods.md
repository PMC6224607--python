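# Methods

This document describes the mathematical models implemented in `epiclone`,
the numerical methods used to solve them, the default parameter values and
why they were chosen, and the limitations of each component.

## 1. Single-progenitor clone model (`epiclone.sp_model`)

### Model

The interfollicular epidermis is maintained by a single population of
progenitor cells (P) dividing at rate λ (per week). Each division yields
one of three outcomes:

- PP (two progenitors), probability `r + Δ/2`;
- DD (two post-mitotic differentiated basal cells), probability `r − Δ/2`;
- PD (asymmetric), probability `1 − 2r`.

Differentiated basal cells (D) stratify into the suprabasal compartment (S)
at rate Γ, and suprabasal cells are shed at rate μ. The fate imbalance
Δ = P(PP) − P(DD) is the central quantity: Δ = 0 gives homeostasis (the
progenitor count is then a martingale), while Δ > 0 gives exponential
progenitor growth E[n_p](t) = e^{λΔt}. Validity requires |Δ| ≤ 2r so that
all three fate probabilities stay in [0, 1].

A clone is the set of descendants of a single labelled cell, scored by its
basal (P + D) and suprabasal (S) cell counts.

### Numerical routes

Three mutually cross-checking solution routes are implemented:

1. **Truncated master equation.** The (n_p, n_d) state space is truncated
   at total basal size `n_max`, with a single lumped boundary class that
   absorbs over-truncation probability so mass is conserved exactly. The
   generator is assembled sparse and propagated with
   `scipy.sparse.linalg.expm_multiply`. Boundary mass above a tolerance
   triggers a `RuntimeWarning` rather than silent truncation error.
2. **Probability generating function (PGF).** The basal-size PGF obeys a
   scalar Riccati-type backward ODE, solved on the unit circle and
   inverted with an FFT. The FFT length grows until the upper-quarter tail
   mass is negligible, preventing aliasing. This route has no truncation
   and is the production path for likelihoods.
3. **Gillespie simulation.** An exact stochastic simulation kernel
   (numba-compiled) samples clone paths; it is the only route that also
   yields full path statistics.

Closed-form oracles used in tests: the critical birth–death extinction
probability rλt/(1 + rλt) in the Γ → ∞, Δ = 0 limit; the exact 3×3 linear
moment system for (E[n_p], E[n_d], E[n_s]) solved by matrix exponential.

### Defaults

`r = 0.25`, `λ = 1.2 /week`, `Δ = 0`, `Γ = 1.2 /week`, `μ = 0.6 /week`.
These are typical of published single-progenitor fits to mouse epidermis:
division roughly weekly, a quarter of divisions symmetric, stratification
on the division timescale, and suprabasal transit slower than
stratification. The wild-type default Δ = 0 encodes homeostasis; a mutant
imbalance of Δ = 0.25 (with unchanged r, λ) reproduces the several-fold
clone-size advantage of p53-mutant clones by 12 weeks.

### Limitations

- Cells are well mixed within a clone; no spatial structure or
  neighbour-dependent fate.
- Rates are constant in time (no circadian/age modulation).
- The suprabasal compartment is a single pool; no distinction between
  spinous/granular/cornified layers.

## 2. Mean-field tissue model (`epiclone.tissue`)

The tissue module integrates the deterministic mean-field ODEs of the same
compartments (per unit area of basal layer):

```
dP/dt = λ Δ P
dD/dt = λ (1 − Δ) P − Γ D
dS/dt = Γ D − μ S
```

optionally with a crowding feedback that attenuates division as basal
density rises. A thickness proxy is computed from compartment sizes.

Five candidate perturbations of the wild-type parameters are screened
against three qualitative signatures (basal density rise ≥ 2-fold,
suprabasal growing faster than basal, thickness increase):
`symmetric_proportion_change` (r → 0.5), `stratification_decrease`
(Γ × 0.2), `shedding_decrease` (μ × 0.1), `fate_imbalance` (Δ = 0.2), and
`imbalance_plus_shedding` (Δ = 0.2 and μ × 0.1). Only the last satisfies
all three signatures: imbalance alone expands the basal layer but sheds
the excess, and shedding reduction alone thickens the suprabasal layer
without a basal rise. The 10-fold shedding reduction is a deliberately
substantial perturbation — the screen asks which *class* of mechanism can
reproduce the pattern, not for a fitted magnitude.

Limitations: mean-field only (no clone-level fluctuations), signatures are
threshold-based qualitative checks, and the feedback form is
phenomenological.

## 3. H2BGFP label dilution (`epiclone.h2b`)

After doxycycline withdrawal, histone-bound GFP halves at each division,
so a cell that has divided k times has log2 intensity `i0 − k`. With
divisions at rate λ, k ~ Poisson(λt) at chase time t; measured log2
intensity adds Gaussian noise (SD `noise_sd`). The likelihood is a
Poisson–Normal mixture, maximised with L-BFGS-B (vectorised over cells
using `gammaln`). A two-rate variant mixes fast and slow populations and
is compared by likelihood ratio/AIC. Label-retaining fractions equal the
Poisson CDF at the retention threshold, which the tests verify.

Defaults: `λ = 1.2 /week` (matching the SP division rate), chase times
(0, 1, 2, 4) weeks, 2000 cells, `i0 = 10` log2 units, `noise_sd = 0.35`
(flow-cytometry-scale spread). Limitations: no intensity floor or
autofluorescence model; division count independent across cells (no clone
correlation); Poisson division model (exponential waiting times), with a
deterministic "discrete" model available for checks.

## 4. Clonal competition (`epiclone.competition`)

A Moran process on a fixed population of `N` basal cells: at each event a
divider is chosen with probability proportional to `count × (1 + Δ_clone)`
and a uniformly chosen cell is removed, so N is conserved exactly. The
transgenic lineage is induced at frequency `f0`; background mutations
arise at rate ν per division with fitness effects drawn from a DFE
(point mass at 0 with probability 0.9, else exponential advantage with
mean 0.2); a fraction of cells start as standing mutant clones (modelling
prior mutagen exposure). The clone registry records the full parent–child
forest, enabling Muller plots and lineage aggregation.

Exact oracles: the mean-field of this update rule is
`df/dt = λ δ f (1 − f) / (1 + δ f)` (reducing to the replicator equation
for weak selection), and two-clone fixation probabilities are computed by
a direct absorbing-chain linear solve, both verified by simulation.

Defaults: `N = 2000`, `f0 = 0.01`, `δ0 = 0.2`, `ν = 0.005` per division,
DFE mean 0.2, 10% standing mutant fraction, 52 weeks. The DFE mean of 0.2
puts typical background mutants on the same fitness scale as the
transgenic lineage, which is what makes the rise-then-fall of the induced
lineage the typical outcome rather than a rarity. Limitations: fixed N
(no tissue growth), well-mixed population (no spatial clone geometry),
fitness acts only through division propensity.

## 5. Clone-size inference (`epiclone.inference`)

The likelihood of an observed clone with basal size b at time t is the
PGF-route pmf conditioned on detectability,
`P(b | basal ≥ detection_min)`. Log-likelihoods are summed over clones;
impossible observations yield −∞ rather than an error during optimisation.
Two numerical safeguards:

- **Tail censoring.** FFT-inverted pmf entries below
  `pmf.size × 1e-15` are numerical noise; observed sizes beyond the last
  reliable index are scored through a single censored tail bin using the
  survival probability, never through noise-level point masses.
- **Parameter lattice and pmf cache.** The optimiser works on a parameter
  lattice (step 1e-4, far below statistical resolution) and pmf lengths
  are rounded to powers of two, so multi-start Nelder–Mead and bootstrap
  refits hit a memo cache instead of re-solving the ODE.

Δ is bounded to [0, 2r] by default (one-sided alternative with the
balanced model on the boundary); bootstrap percentile intervals quantify
uncertainty, and `compare_models` reports the likelihood-ratio statistic
and AIC-preferred model between Δ = 0 and Δ free.

Limitations: fixed parameters (r, λ) must be known or fitted jointly —
with a single timepoint Δ and λ are confounded (a warning is raised);
the bootstrap resamples clones, assuming independence between clones.

## 6. Variant filtering (`epiclone.variants`)

Candidate variants from deep targeted sequencing are filtered in a fixed
order:

1. **Paired-sharing removal** — a site seen in biopsies from both exposure
   arms of one mouse is germline/systematic and removed everywhere in that
   mouse.
2. **Benjamini–Hochberg step-up** on caller p-values, one family per mouse
   (formed *after* shared removal so artifacts do not consume FDR budget),
   keeping q < 0.1. The BH step-up is hand-rolled — the grouped ordered
   q-value is the quantity under test — and cross-checked against
   statsmodels to 1e-12. P-values must be finite and in (0, 1].
3. **Strand filter** — at least one forward and one reverse supporting
   read.

Summaries: mutation burden per biopsy and per mm² (default area 16 mm²),
and a six-class pyrimidine-collapsed substitution spectrum with the C>T
fraction as a UV-signature readout.

Limitations: no trinucleotide context in the spectrum; the sharing filter
uses exact site identity (no fuzzy matching of neighbouring indels); FDR
control assumes valid, roughly independent p-values from the caller.

## 7. Synthetic data (`epiclone.synthetic`)

`StudyDesign` encodes a two-genotype, four-timepoint lineage-tracing
study (wild type Δ = 0, mutant Δ = 0.25; default clone counts per
timepoint at the scale of a real study), an H2BGFP dilution arm, and a
paired-biopsy variant-calling arm with planted ground truth. Planted
variant classes are separated by construction: true somatic variants have
p ∈ [1e-12, 1e-6] and both-strand support; weak artifacts have
p ∈ [0.3, 1]; single-strand artifacts have zero reads on one strand;
shared artifacts are planted in both exposure arms of a mouse. The
margins guarantee that the filter pipeline's survivor set equals the
planted truth set exactly, making end-to-end recovery a sharp test rather
than a statistical one. True variants are drawn C>T-biased (75%) to give
a UV-like spectrum.

All generators are pure functions of (design, seed) via
`numpy.random.default_rng`, and each clone table carries the generating
parameters in its truth dictionary.

## 8. Command-line interface (`epiclone.cli`)

Every subcommand is a pure function of (inputs, flags, seed): rerunning
with identical arguments produces byte-identical outputs, and a
provenance sidecar (package version, subcommand, all option values; no
timestamp, so reruns compare equal) is written next to each output.
A flat key-value `--config` file supplies defaults that explicit flags
override; `show-config` prints every default. Validation errors exit with
status 1 and a one-line diagnostic; unknown subcommands exit 2.
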