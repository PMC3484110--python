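"""Parameter-sensitivity screen over the cascade's kinetic constants.

Latin-hypercube samples of the 23 kinetic constants (the feedback
strength Fa is excluded — it defines the topology), each spanning one
order of magnitude either side of its nominal value.  For every
parameter set and each feedback topology (NF, US, PF) a heterogeneous
population is simulated over the dose x time grid and scored on three
experimentally motivated features of the ERK-on population (cells with
ppERK over 200 nM; a population only counts when it has more than 10
cells):

* analogicity — max-minus-min of the ERK-on mean across doses, summed
  over the 2- and 5-minute time points (late times carry no dose
  information experimentally and are left out);
* transience — early (2, 5 min) minus late (10, 30 min) ERK-on means,
  summed over the doses whose ERK-on population exists at all four
  times; negative values mean sustained signaling;
* bimodal fraction — the fraction of dose/time combinations whose
  ppERK distribution rejects unimodality (dip test).

Sets with zero analogicity or zero bimodality are flagged for discard
as inconsistent with the experimental data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.stats import qmc

from . import bimodality, population
from .cascade import KineticParameters, PARAM_NAMES, ProteinTotals
from .heterogeneity import DEFAULT_SHAPE
from .ras_input import DoseSchedule, build_dose_schedule

__all__ = [
    "LHSConfig",
    "SensitivityMetrics",
    "lhs_sample",
    "analogicity",
    "transience",
    "bimodal_fraction",
    "run_screen",
]

log = logging.getLogger(__name__)

ANALOGICITY_TIMES = (2.0, 5.0)
LATE_TIMES = (10.0, 30.0)


@dataclass(frozen=True)
class LHSConfig:
    """Screen configuration.

    ``n_sets`` latin-hypercube parameter sets (plus the nominal set as
    set 0 when ``include_nominal``), ``range_decades`` on either side of
    nominal, ``cells_per_set`` cells per population.  ``log_uniform``
    samples uniformly in log10 (decades treated symmetrically); switch
    off for linear-uniform sampling on [p/10, 10p].
    """

    n_sets: int = 500
    cells_per_set: int = 500
    range_decades: float = 1.0
    nominal: KineticParameters = field(default_factory=KineticParameters)
    topologies: tuple = ("NF", "US", "PF")
    seed: int = 0
    log_uniform: bool = True
    include_nominal: bool = True
    cutoff: float = 200.0
    min_cells: int = 10
    alpha: float = 0.05
    n_boot: int = 500
    mean_totals: ProteinTotals = field(default_factory=ProteinTotals)
    k_shape: float = DEFAULT_SHAPE

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.range_decades <= 0:
            raise ValueError("range_decades must be > 0")


@dataclass(frozen=True)
class SensitivityMetrics:
    """Scores for one topology x parameter set."""

    analogicity: float
    transience: float
    bimodal_fraction: float
    discard_zero_analogicity: bool
    discard_zero_bimodality: bool
    n_combos_tested: int

    @property
    def retained(self) -> bool:
        return not (self.discard_zero_analogicity or self.discard_zero_bimodality)


def lhs_sample(config: LHSConfig) -> list[KineticParameters]:
    """Latin-hypercube parameter sets (Fa untouched, never varied).

    One sample per equal-probability stratum and dimension; values lie
    in [p/10^r, p*10^r] around each nominal value p.
    """
    sampler = qmc.LatinHypercube(d=len(PARAM_NAMES), seed=config.seed)
    u = sampler.random(n=config.n_sets)
    nom = config.nominal.screening_vector()
    r = config.range_decades
    if config.log_uniform:
        vals = nom * 10.0 ** ((2 * u - 1) * r)
    else:
        lo = nom / 10.0**r
        hi = nom * 10.0**r
        vals = lo + u * (hi - lo)
    return [KineticParameters.from_screening_vector(v, Fa=config.nominal.Fa) for v in vals]


def _on_matrix(resp: population.PopulationResponse, cutoff: float, min_cells: int):
    means, counts = population.erk_on_mean_matrix(resp, cutoff=cutoff, min_cells=min_cells)
    return means, counts


def _time_index(resp, t):
    try:
        return resp.times.index(t)
    except ValueError:
        raise ValueError(f"response lacks the {t}-min time point")


def analogicity(resp: population.PopulationResponse, cutoff: float = 200.0,
                min_cells: int = 10):
    """Dose discrimination of the ERK-on mean at early times.

    Per time point (2 and 5 min): max minus min of the ERK-on means over
    qualifying doses (> min_cells on-cells); fewer than two qualifying
    doses contribute 0.  Returns (total, per-time dict).
    """
    means, _ = _on_matrix(resp, cutoff, min_cells)
    per_time = {}
    for t in ANALOGICITY_TIMES:
        col = means[:, _time_index(resp, t)]
        ok = col[~np.isnan(col)]
        per_time[t] = float(ok.max() - ok.min()) if len(ok) >= 2 else 0.0
    return sum(per_time.values()), per_time


def transience(resp: population.PopulationResponse, cutoff: float = 200.0,
               min_cells: int = 10):
    """Early-minus-late ERK-on mean, summed over qualifying doses.

    A dose qualifies only if its ERK-on population exists (> min_cells)
    at every time point; its contribution is mean(on-mean at 2, 5 min)
    minus mean(on-mean at 10, 30 min).  May be negative for sustained
    responses.  Returns (total, per-dose array with NaN for
    non-qualifying doses).
    """
    means, _ = _on_matrix(resp, cutoff, min_cells)
    i_early = [_time_index(resp, t) for t in ANALOGICITY_TIMES]
    i_late = [_time_index(resp, t) for t in LATE_TIMES]
    per_dose = np.full(means.shape[0], np.nan)
    for d in range(means.shape[0]):
        if np.any(np.isnan(means[d])):
            continue
        per_dose[d] = means[d, i_early].mean() - means[d, i_late].mean()
    total = float(np.nansum(per_dose)) if np.any(~np.isnan(per_dose)) else 0.0
    return total, per_dose


def bimodal_fraction(resp: population.PopulationResponse, alpha: float = 0.05,
                     n_boot: int = 500, seed: int = 0):
    """Fraction of (dose, time) distributions rejecting unimodality.

    Combinations with fewer than 4 usable cells are excluded from both
    numerator and denominator (and logged).  Returns (fraction, p-value
    matrix with NaN for excluded combos).
    """
    n_d, n_t = resp.ppERK.shape[1:]
    pvals = np.full((n_d, n_t), np.nan)
    n_reject = 0
    n_tested = 0
    for d in range(n_d):
        for t in range(n_t):
            x = resp.ppERK[:, d, t]
            x = x[~np.isnan(x)]
            if len(x) < 4:
                log.info("dose %d time %s excluded (<4 cells)", d, resp.times[t])
                continue
            res = bimodality.classify_unimodal(x, alpha=alpha, n_boot=n_boot, seed=seed)
            pvals[d, t] = res.p_value
            n_tested += 1
            if not res.unimodal:
                n_reject += 1
    frac = n_reject / n_tested if n_tested else 0.0
    return float(frac), pvals


def _score_one(resp, config: LHSConfig, seed: int) -> SensitivityMetrics:
    ana, _ = analogicity(resp, cutoff=config.cutoff, min_cells=config.min_cells)
    tra, _ = transience(resp, cutoff=config.cutoff, min_cells=config.min_cells)
    bim, pmat = bimodal_fraction(resp, alpha=config.alpha, n_boot=config.n_boot, seed=seed)
    n_tested = int(np.count_nonzero(~np.isnan(pmat)))
    return SensitivityMetrics(
        analogicity=ana, transience=tra, bimodal_fraction=bim,
        discard_zero_analogicity=(ana == 0.0),
        discard_zero_bimodality=(bim == 0.0),
        n_combos_tested=n_tested,
    )


def run_screen(config: LHSConfig, schedule: DoseSchedule | None = None,
               checkpoint_path=None, progress: bool = False):
    """The full screen: populations + metrics per (set, topology).

    Deterministic given the master seed; per-set seeds are spawned so a
    resumed run reproduces the interrupted one exactly.  With
    ``checkpoint_path`` the result table is re-written as CSV after
    every parameter set and, when the file already exists, finished sets
    are loaded instead of recomputed.  Per-set failures are recorded
    (NaN metrics) and the screen continues.  Returns a DataFrame with
    one row per set x topology.
    """
    import pandas as pd

    schedule = schedule or build_dose_schedule()
    sets: list[tuple[int, KineticParameters]] = []
    if config.include_nominal:
        sets.append((0, config.nominal))
    sets.extend((i + 1, p) for i, p in enumerate(lhs_sample(config)))

    done = None
    if checkpoint_path is not None:
        import os

        if os.path.exists(checkpoint_path):
            done = pd.read_csv(checkpoint_path)
    rows = []
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(0x5C,))
    set_seeds = ss.spawn(len(sets))
    for (set_id, params), sseed in zip(sets, set_seeds):
        if done is not None and (done.set_id == set_id).any():
            rows.extend(done[done.set_id == set_id].to_dict("records"))
            continue
        pop_seed, dip_seed = [int(s.generate_state(1)[0]) & 0x7FFFFFFF for s in sseed.spawn(2)]
        for topo in config.topologies:
            row = {"set_id": set_id, "topology": topo, "is_nominal": set_id == 0}
            try:
                resp = population.simulate_population(
                    topo, config.cells_per_set, mean_totals=config.mean_totals,
                    schedule=schedule, k_shape=config.k_shape, seed=pop_seed,
                    params=params)
                resp = population.add_measurement_noise(resp, seed=pop_seed)
                m = _score_one(resp, config, dip_seed)
                row.update(analogicity=m.analogicity, transience=m.transience,
                           bimodal_fraction=m.bimodal_fraction,
                           discard_zero_analogicity=m.discard_zero_analogicity,
                           discard_zero_bimodality=m.discard_zero_bimodality,
                           retained=m.retained, n_combos_tested=m.n_combos_tested,
                           error="")
            except Exception as exc:  # per-set failures never kill the screen
                log.warning("set %d topology %s failed: %s", set_id, topo, exc)
                row.update(analogicity=np.nan, transience=np.nan,
                           bimodal_fraction=np.nan, discard_zero_analogicity=True,
                           discard_zero_bimodality=True, retained=False,
                           n_combos_tested=0, error=str(exc))
            rows.append(row)
        if checkpoint_path is not None:
            pd.DataFrame(rows).to_csv(checkpoint_path, index=False)
        if progress:
            print(f"screen: finished set {set_id}/{len(sets) - 1}")
    return pd.DataFrame(rows)


def summarize_screen(table) -> dict:
    """Per-topology retention and signature summary of a screen table."""
    out = {}
    for topo, grp in table.groupby("topology"):
        ok = grp.dropna(subset=["analogicity"])
        retained = ok[ok.retained]
        out[topo] = {
            "n_sets": int(len(grp)),
            "n_retained": int(len(retained)),
            "retained_fraction": float(len(retained) / len(ok)) if len(ok) else 0.0,
            "median_analogicity": float(ok.analogicity.median()) if len(ok) else float("nan"),
            "median_transience": float(ok.transience.median()) if len(ok) else float("nan"),
            "median_bimodal_fraction": float(ok.bimodal_fraction.median()) if len(ok) else float("nan"),
            "positive_transience_fraction": float((ok.transience > 0).mean()) if len(ok) else float("nan"),
        }
    return out
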