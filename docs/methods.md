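# Methods

`erkpop` simulates how a cell population whose members each respond in
an *analog* (graded) fashion to growth-factor stimulation can nevertheless
display a *digital* (bimodal) distribution of active ERK. The ingredients
are (i) a deterministic three-tier MAPK/ERK cascade with tunable feedback,
(ii) a dose-dependent, pulse-shaped RasGTP input, (iii) gamma-distributed
cell-to-cell variability in protein totals and peak RasGTP, and (iv) a
nonparametric test for bimodality. A latin-hypercube screen asks which
feedback topology reproduces the experimentally observed population
signatures across wide parameter ranges.

## Cascade model

Three phosphorylation tiers (Raf → MEK → ERK, written MAP3K → MAP2K →
MAPK), eight species, ten Michaelis–Menten reactions with shared
saturable denominators (substrate competition within a tier, plus the
competitive terms MAP2K/Ki1 and MAPK/Ki2 on the phosphatase steps). The
input RasGTP drives the first activation step; the output is doubly
phosphorylated ERK (ppERK). Active ERK feeds back on the first step
through a Hill-type gain

    g = (1 + Fa·(ppERK/Ka)²) / (1 + (ppERK/Ka)²),

so `Fa = 5` is positive feedback (PF, bistable/hysteretic), `Fa = 1`
no feedback (US, ultrasensitive), `Fa = 0.5` negative feedback (NF,
analog with an activation threshold). Each tier conserves its total
protein; conservation is asserted along every trajectory (1e-6
relative), never substituted.

**Units.** Concentrations are nM. The catalytic constants and Vmax's
carry units of 1/s and nM/s: at those rates the cascade relaxes within
tens of seconds, so on the minutes timescale of the RasGTP input the
output tracks the input quasi-statically. This pseudo-steady-state
operation is essential to the modelled phenomenology — responses are
already present at 2–5 min and shut off by 10–30 min as the input
decays — and is why time courses are insensitive to the exact
integration tolerances. Time grids are in minutes (the input's natural
unit); the ODE right-hand side applies the 60 s/min factor.

**Numerics.** LSODA (stiff-capable) with rtol 1e-8, atol 1e-10 nM; the
hot path uses a numba-compiled right-hand side with the closed-form
input evaluated in-line. Steady states integrate in growing chunks from
the given initial state and finish with a Newton polish, accepting only
‖rhs‖∞ < 1e-9 nM/min; non-convergence raises (a candidate oscillatory
regime is reported, not masked). Dose–response sweeps warm-start each
RasGTP level from the previous converged state (continuation), in both
directions — this is what exposes the PF hysteresis loop and its absence
under US/NF.

**Protein totals.** The mean totals are MAP3K 40 nM, MAP2K 450 nM,
MAPK 500 nM (configurable everywhere). The Raf tier's phosphatase
capacity (Vmax2 = 5 nM/s) is the bottleneck for both the activation
threshold and the off-kinetics; 40 nM of Raf puts the steady-state
activation threshold at ~15–25 nM RasGTP — above the input tails, so
responses terminate by 30 min, and inside the sampled peak range, so
intermediate doses split the population. ERK at 500 nM keeps the
on-state (300–500 nM ppERK) above both classification cutoffs. These
were chosen once against the qualitative experimental signatures and
then frozen.

## RasGTP input

RasGTP(t) = Io + K1(1−e^(−t/τ1)) + K2(1−e^(−t/τ2)), with one negative
amplitude so the curve rises to a peak and relaxes to Io+K1+K2. Four
weighted residuals pin the waveform landmarks — asymptote = Iss, zero
slope at τmax, value 1.01·Iss at τss, value Imax at τmax — with weights
(1, 100, 1, 1); two hard inequalities enforce a genuine maximum at τmax
and decay at τinfl. Because the amplitudes enter linearly, the fit
profiles them out over a log grid of (τ1, τ2) before an SLSQP polish
under the constraints; amplitude bounds scale with Imax so the problem
is exactly homogeneous in the magnitude landmarks.

Two consequences of that structure are worth knowing:

* **Per-cell fits are exact rescalings.** A cell's sampled peak scales
  (Io, Imax, Iss) jointly, so its optimal fit is the dose's reference
  fit with K1, K2 multiplied by the peak ratio — an identity, not a
  cache approximation. Populations therefore pay one fit per dose.
* **The landmark system is over-determined.** No rising-then-decaying
  double exponential can satisfy all four landmarks exactly (with the
  magnitude landmarks exact, the slope at τmax is forced well below
  zero). With the dominant zero-slope weight the compromise preserves
  the peak time and, at high doses, the peak magnitude (within 1%),
  while the achieved asymptote settles near 12% of the peak rather than
  the prescribed 15%, and low-dose peaks undershoot. The fit report
  carries all residuals and constraint slacks; infeasible fits raise
  rather than return.

The six-dose schedule maps EGF (0.01, 0.1, 0.5, 1, 5, 10 nM) to mean
peak RasGTP linearly spaced 10→200 nM, peak times 7→2 min (high doses
peak earlier), Io = 0, τss = 10 min, Iss = 15%·Imax, τinfl = (τmax+τss)/2.

## Cell-to-cell variability

Protein totals and per-dose peak RasGTP are drawn independently from
gamma distributions with a common shape k = 5.4 (the value measured for
total ERK; CV ≈ 43%) and scale set per quantity so the mean hits its
target. Gamma MLE (scipy, location fixed at zero) is scale-equivariant
and rejects degenerate samples. Every cell owns a spawned RNG
substream, so populations are reproducible regardless of execution
order; sampling more cells extends, never reshuffles, a smaller draw.

## Population responses

Per (cell, dose): one input trajectory (the dose's fit rescaled to the
cell's peak), one cascade integration, ppERK recorded at 2, 5, 10 and
30 min. Measurement noise — Normal(10, 10) nM, independent per
(cell, dose, time) — is added before classification, because that is
what a cytometer sees; a noiseless partition is available by simply not
adding noise. Negative noisy values are retained (compensated
fluorescence dips below zero). ERK-on means "strictly above the
cutoff" (100 nM for the figure-level analyses, 200 nM in the screen),
and an ERK-on population only exists when it has strictly more than 10
cells; smaller ones are *undefined*, not zero. Failed per-cell
integrations are flagged and logged, never dropped silently.

## Bimodality

Hartigan's dip — the smallest sup-distance between the empirical CDF
and any unimodal CDF — computed by the greatest-convex-minorant /
least-concave-majorant iteration (numba-compiled; ≥ 1/(2n), attaining
it for equally spaced data). Validated in the test suite against a
brute-force oracle that bisects the band half-width and checks
feasibility of a piecewise-linear unimodal CDF by linear programming.
The dip is location–scale invariant but *not* invariant under nonlinear
monotone maps (unimodality is a shape property in x), which the oracle
confirms. p-values are Monte-Carlo under the canonical uniform null
(default 2000 replicates) with an add-one correction; null tables are
cached per (n, n_boot, seed). Unimodality is rejected when p < α
(strict), α = 0.05.

## Sensitivity screen

Latin-hypercube sampling (scipy's stratified sampler) of the 23 kinetic
constants, uniform in log10 over ±1 decade around nominal (decades
treated symmetrically; a linear-uniform switch exists). Fa is never
varied — it is the topology. Each set × topology runs a full noisy
population and is scored by:

* **analogicity** — max−min of the ERK-on mean across qualifying doses,
  summed over the 2- and 5-min time points (a time point with fewer
  than two qualifying doses contributes 0);
* **transience** — mean ERK-on level at 2 and 5 min minus that at 10 and
  30 min, summed over doses whose ERK-on population exists at all four
  times (negative ⇒ sustained);
* **bimodal fraction** — rejected-unimodality share of the dose×time
  combinations (combos with < 4 usable cells leave both numerator and
  denominator).

Sets with zero analogicity or zero bimodality carry discard flags. The
screen checkpoints after every parameter set and resumes from the
checkpoint byte-identically. At nominal parameters NF scores positive
analogicity, positive transience and a nonzero bimodal fraction, while
PF fails transience (sustained signaling) — the discriminating
signature. Desk scale (25 sets × 100 cells × 3 topologies, dip with 500
bootstrap replicates) runs in a few minutes; the full 500 × 500 screen
is the same code with larger numbers.

## Synthetic cytometry

Event tables emulate the statistical structure of per-cell
phospho-flow data: total ERK drawn in arbitrary fluorescence units from
gamma(k = 5.4, θ = 2.7e5 AFU) and converted to the cell's ERK pool for
simulation; ppERK mapped back as scale·ppERK·lognormal(cv) +
Normal(background). The calibration (3000 AFU/nM, background
2e4 ± 6e3 AFU, cv 0.2) is an explicit synthetic convention — the real
AFU↔nM correspondence is unidentifiable from population data — so
analyses that matter are cutoff- and normalization-based. The analyzer
(dip test, on-fraction/on-mean, divide-by-total normalization rescaled
to mean 1) runs identically on exported real cytometry CSVs with the
documented header; binary FCS parsing is out of scope.

## Stochastic cross-checks

The two-state gene-expression model (gene on/off, transcription,
translation, first-order decays; rates per minute) is simulated exactly
with the Gillespie algorithm (numba core). Checks: stationary protein
mean against the closed form f·k_tx·k_tl/(γm·γp); mRNA mean and Fano
factor against the two-state formulas; exponential inter-event times on
a constant-propensity sub-model; and a small goodness screen fitting
gamma laws to stationary counts (KS distance < 0.1 counts as
well-described; bursty regimes pass, which is the empirical basis for
the gamma heterogeneity model). The cascade itself, run as a jump
process with Michaelis–Menten propensities at ≥1000 copies per tier,
reproduces the ODE steady state within 5% per species (threshold
configurable) — intrinsic reaction noise is negligible at these
abundances, which justifies confining stochasticity to protein totals.

## Problem sizes used by the shipped tests and scripts

Populations of 300 cells (trend tests), 1000 cells × 20 seeds
(bimodality headline), 26 × 3 × 100 cells (screen); SSA checks with 200
runs (gene model) and one 30-min cascade run at 25 copies/nM. These
sizes give comfortable margins for every assertion while keeping a full
run on one CPU in the tens of minutes.

## Known limitations

* The published mean protein totals and the 6400-condition
  gene-expression grid were not recoverable from the source text; the
  defaults above are this package's own documented choices.
* The input fit inherits the landmark system's inconsistency (asymptote
  ≈ 12% of peak instead of the prescribed 15%; low-dose peaks
  undershoot their nominal means). All downstream results use these
  fitted curves as-is.
* Proteins are sampled independently (no co-expression correlation),
  totals are constant over the 30-min window, and the synthetic
  cytometry model omits scatter gating, compensation artefacts and
  isotype controls — passing tests say nothing about those aspects of
  real data.
* Basal RasGTP is 0 by construction (Io = 0), so basal ppERK is exactly
  zero rather than the small nonzero level real cells show.
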