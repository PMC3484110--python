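# erkpop

Single-cell simulations of the MAPK/ERK cascade that explain a puzzle of
growth-factor signaling: individual cells respond to EGF in an **analog**
(graded) way, yet flow cytometry of the population shows **digital**
(bimodal) distributions of active, doubly phosphorylated ERK (ppERK).
`erkpop` shows how the combination of (a) a negative-feedback cascade
with a ppERK activation threshold and (b) gamma-distributed cell-to-cell
variability in protein expression and RasGTP levels produces exactly
that population behavior — no single-cell switch required.

The package is aimed at systems biologists who want to reproduce,
perturb or extend this analysis: it is a tested library plus a small
CLI, not a figure archive.

## The model in brief

Three phosphorylation tiers (Raf → MEK → ERK; species MAP3K, MAP2K,
MAPK with p-/pp- forms) driven by RasGTP, with Michaelis–Menten kinetics
and a Hill-type feedback of ppERK onto the first activation step,

&nbsp;&nbsp;&nbsp;&nbsp;g = (1 + F_a·(ppERK/K_a)²) / (1 + (ppERK/K_a)²),

so F_a = 5, 1, 0.5 give the positive-feedback (PF, bistable),
ultrasensitive (US) and negative-feedback (NF, analog + threshold)
topologies. The RasGTP input is a fitted double exponential
I(t) = I_o + K₁(1−e^(−t/τ₁)) + K₂(1−e^(−t/τ₂)) whose peak magnitude and
timing follow a six-dose EGF schedule (peaks 10→200 nM, peak times
7→2 min). Cell-to-cell variability: protein totals and per-dose peak
RasGTP are gamma-distributed with shape k = 5.4 (CV ≈ 43%). Bimodality
is tested with Hartigan's dip statistic against a Monte-Carlo uniform
null. A latin-hypercube screen (±1 decade around each of the 23 kinetic
constants) scores each topology by analogicity, transience and bimodal
fraction of the ERK-on population. Details: `docs/methods.md`.

## Worked example

Simulate 1000 negative-feedback cells at 1 nM EGF (dose 4 of the
schedule), add cytometry-like Normal(10, 10) nM noise, and examine the
population at the four experimental times:

```python
import numpy as np
from erkpop import population as pop, bimodality as bi

resp  = pop.simulate_population("NF", n_cells=1000, seed=1, dose_indices=(4,))
noisy = pop.add_measurement_noise(resp, seed=1)

for k, t in enumerate(noisy.times):
    x = noisy.ppERK[:, 0, k]
    part = pop.partition_on_off(x, cutoff=100.0)
    res  = bi.classify_unimodal(x, n_boot=2000, seed=1)
    print(f"t={t:>4} min  on-fraction={part.on_fraction:.2f}  "
          f"on-mean={np.mean(part.on_values):6.0f} nM  "
          f"dip={res.dip:.4f}  p={res.p_value:.4f}  unimodal={res.unimodal}")
```

prints

```
t= 2.0 min  on-fraction=0.73  on-mean=   430 nM  dip=0.0172  p=0.0390  unimodal=False
t= 5.0 min  on-fraction=0.77  on-mean=   458 nM  dip=0.0294  p=0.0005  unimodal=False
t=10.0 min  on-fraction=0.67  on-mean=   435 nM  dip=0.0129  p=0.3403  unimodal=True
t=30.0 min  on-fraction=0.01  on-mean=   144 nM  dip=0.0065  p=0.9995  unimodal=True
```

Read: at 2–5 min the population has split into ERK-off cells (near 0 nM,
noise only) and ERK-on cells (mean ≈ 430–460 nM) — the dip test rejects
unimodality even though every simulated cell is an analog responder. By
30 min the RasGTP input has decayed below the activation threshold and
the response has shut off almost everywhere. The same pipeline is
available from the shell:

```bash
erkpop simulate-population --topology NF --cells 1000 --seed 1 -o nf.csv
erkpop diptest nf.csv --column ppERK_nM --boot 2000 --seed 7
erkpop sensitivity-screen --sets 25 --cells 100 --seed 11 --out screen/
erkpop generate-fcpa --topology NF --events 10000 --seed 0 -o events.csv
erkpop analyze-fcpa events.csv -o report.csv
```

## Layout

| module | contents |
| --- | --- |
| `erkpop.cascade` | kinetic constants, rate laws, ODE integration, steady states, continuation sweeps |
| `erkpop.ras_input` | double-exponential input, constrained landmark fitting, dose schedule |
| `erkpop.heterogeneity` | gamma sampling/MLE, per-cell RNG substreams, population draws |
| `erkpop.population` | dose × time population simulation, noise, ERK-on/off partitioning, steady sweeps |
| `erkpop.bimodality` | Hartigan dip statistic, Monte-Carlo p-values, unimodality calls |
| `erkpop.sensitivity` | latin-hypercube screen, analogicity / transience / bimodal fraction |
| `erkpop.expression_noise` | Gillespie gene-expression model, gamma goodness screen, cascade SSA check |
| `erkpop.cytometry` | synthetic flow-cytometry event tables and their re-analysis |
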