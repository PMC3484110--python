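"""Population-level ppERK responses.

The pipeline the rest of the package feeds: draw a heterogeneous
population (gamma-distributed Raf/MEK/ERK totals and per-dose peak
RasGTP), give every cell its own fitted RasGTP input whose peak is the
cell's sampled realization, integrate the cascade per cell, and record
ppERK on the experimental dose x time grid (6 EGF doses, 2/5/10/30 min).
Downstream ops add cytometry-like measurement noise, split cells into
ERK-on/ERK-off at a ppERK cutoff, tabulate ERK-on population means
(undefined unless more than ``min_cells`` cells are on), and run the
steady-state population sweeps that exhibit hysteresis (PF) or its
absence (US/NF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from . import heterogeneity
from .cascade import (CascadeState, IntegrationError, KineticParameters,
                      ProteinTotals, TOPOLOGY_FA, simulate_timecourse,
                      sweep_steady_states, SteadyStateError)
from .ras_input import DoseSchedule, build_dose_schedule, fit_for_dose

__all__ = [
    "PopulationResponse",
    "NoiseModel",
    "PartitionResult",
    "EXPERIMENT_TIMES_MIN",
    "simulate_population",
    "add_measurement_noise",
    "partition_on_off",
    "erk_on_mean_matrix",
    "population_steady_sweep",
    "normalize_by_total",
]

log = logging.getLogger(__name__)

#: the flow-cytometry sampling times (min after EGF)
EXPERIMENT_TIMES_MIN = (2.0, 5.0, 10.0, 30.0)


@dataclass
class PopulationResponse:
    """Per-cell ppERK (nM) on a (cell, dose, time) grid.

    ``ppERK[i, j, k]`` is cell i at dose index j (0-based into
    ``schedule``) and time ``times[k]``.  ``failed`` flags cells whose
    input fit or integration failed (their entries are NaN); they are
    reported, never silently dropped.
    """

    topology: str
    ppERK: np.ndarray                  # (n_cells, n_doses, n_times)
    times: tuple
    schedule: DoseSchedule
    mean_totals: ProteinTotals
    k_shape: float
    seed: int
    noisy: bool = False
    noise: "NoiseModel | None" = None
    cell_totals: np.ndarray | None = None     # (n_cells, 3)
    peak_ras: np.ndarray | None = None        # (n_cells, n_doses)
    failed: np.ndarray | None = None          # (n_cells, n_doses) bool

    @property
    def n_cells(self) -> int:
        return self.ppERK.shape[0]

    @property
    def n_doses(self) -> int:
        return self.ppERK.shape[1]

    def to_frame(self):
        """Tidy DataFrame: cell_id, dose_nM, time_min, ppERK_nM, failed."""
        import pandas as pd

        n_c, n_d, n_t = self.ppERK.shape
        cell, dose, tim = np.meshgrid(np.arange(n_c), np.arange(n_d),
                                      np.arange(n_t), indexing="ij")
        failed = (self.failed if self.failed is not None
                  else np.zeros((n_c, n_d), bool))
        return pd.DataFrame({
            "cell_id": cell.ravel(),
            "dose_nM": np.asarray(self.schedule.egf_doses_nM)[dose.ravel()],
            "time_min": np.asarray(self.times)[tim.ravel()],
            "ppERK_nM": self.ppERK.ravel(),
            "failed": failed[cell.ravel(), dose.ravel()],
        })


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise (nM); cytometry background."""

    mean: float = 10.0
    sd: float = 10.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class PartitionResult:
    """Exhaustive, exclusive ERK-on / ERK-off split at a ppERK cutoff."""

    on_values: np.ndarray
    off_values: np.ndarray
    cutoff: float

    @property
    def n_on(self) -> int:
        return len(self.on_values)

    @property
    def n_off(self) -> int:
        return len(self.off_values)

    @property
    def on_fraction(self) -> float:
        return self.n_on / (self.n_on + self.n_off)


def simulate_population(
    topology: str,
    n_cells: int,
    mean_totals: ProteinTotals | None = None,
    schedule: DoseSchedule | None = None,
    k_shape: float = heterogeneity.DEFAULT_SHAPE,
    seed: int = 0,
    times=EXPERIMENT_TIMES_MIN,
    dose_indices=None,
    params: KineticParameters | None = None,
) -> PopulationResponse:
    """Simulate a heterogeneous population over the dose x time grid.

    Each cell draws its own protein totals once and an independent peak
    RasGTP per dose; its input curve is the dose's fitted waveform
    rescaled to the sampled peak (an exact identity of the fitting
    system), and a single input trajectory per (cell, dose) is sampled
    at all requested times.  ``dose_indices`` (1-based) restricts the
    schedule; ``params`` overrides the nominal kinetic constants (its Fa
    is replaced by the topology's).

    Reproducible given ``seed``; per-cell RNG substreams make the result
    independent of execution order.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    topology = topology.upper()
    if topology not in TOPOLOGY_FA:
        raise ValueError(f"unknown topology {topology!r}")
    mean_totals = mean_totals or ProteinTotals()
    schedule = schedule or build_dose_schedule()
    if dose_indices is None:
        dose_indices = tuple(range(1, schedule.n_doses + 1))
    base = KineticParameters() if params is None else params
    kin = _dc_replace(base, Fa=TOPOLOGY_FA[topology])
    times = tuple(float(t) for t in times)
    t_grid = np.concatenate([[0.0], times])

    n_d = len(dose_indices)
    pp = np.full((n_cells, n_d, len(times)), np.nan)
    totals_arr = np.empty((n_cells, 3))
    peaks = np.empty((n_cells, n_d))
    failed = np.zeros((n_cells, n_d), bool)
    base_fits = {d: fit_for_dose(schedule, d) for d in dose_indices}

    for i, rng in enumerate(heterogeneity.cell_rngs(seed, n_cells)):
        t3 = rng.gamma(k_shape, mean_totals.MAP3K_total / k_shape)
        t2 = rng.gamma(k_shape, mean_totals.MAP2K_total / k_shape)
        tk = rng.gamma(k_shape, mean_totals.MAPK_total / k_shape)
        totals = ProteinTotals(t3, t2, tk)
        totals_arr[i] = totals.as_array()
        for j, d in enumerate(dose_indices):
            mean_imax = schedule.mean_Imax_nM[d - 1]
            peak = rng.gamma(k_shape, mean_imax / k_shape)
            peaks[i, j] = peak
            try:
                ras = base_fits[d].scaled(peak / mean_imax)
                traj = simulate_timecourse(totals, kin, ras, t_grid)
                pp[i, j] = traj.ppMAPK[1:]
            except (IntegrationError, ValueError) as exc:
                failed[i, j] = True
                log.warning("cell %d dose %d failed: %s", i, d, exc)
    return PopulationResponse(
        topology=topology, ppERK=pp, times=times, schedule=schedule,
        mean_totals=mean_totals, k_shape=k_shape, seed=seed,
        cell_totals=totals_arr, peak_ras=peaks, failed=failed,
    )


def add_measurement_noise(resp: PopulationResponse, noise: NoiseModel | None = None,
                          seed: int = 0) -> PopulationResponse:
    """Add independent Normal(mean, sd) noise per (cell, dose, time).

    Models cytometry background/stain noise: negative noisy values are
    retained (compensated fluorescence can dip below zero).  Applying
    noise twice is refused.
    """
    if resp.noisy:
        raise ValueError("response already carries measurement noise")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0x6E,)))
    noisy = resp.ppERK + rng.normal(noise.mean, noise.sd, size=resp.ppERK.shape)
    return _dc_replace(resp, ppERK=noisy, noisy=True, noise=noise)


def partition_on_off(values, cutoff: float = 100.0) -> PartitionResult:
    """Split values into ERK-on (strictly above cutoff) and ERK-off.

    A value exactly at the cutoff is OFF ("over the cutoff" is strict).
    NaN entries (failed cells) are excluded from both classes.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    v = np.asarray(values, float).ravel()
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no values to partition")
    on = v[v > cutoff]
    off = v[v <= cutoff]
    return PartitionResult(on_values=on, off_values=off, cutoff=cutoff)


def erk_on_mean_matrix(resp: PopulationResponse, cutoff: float = 100.0,
                       min_cells: int = 10):
    """ERK-on population means by (dose, time).

    Entries whose ERK-on population does not exceed ``min_cells`` cells
    (strictly) are NaN — undefined, not zero.  Returns (means, counts),
    both (n_doses, n_times).
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    pp = resp.ppERK
    on = pp > cutoff
    counts = on.sum(axis=0)
    sums = np.where(on, pp, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > min_cells, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def population_steady_sweep(
    topology: str,
    n_cells: int = 1000,
    ras_grid=None,
    mean_totals: ProteinTotals | None = None,
    k_shape: float = heterogeneity.DEFAULT_SHAPE,
    seed: int = 0,
    params: KineticParameters | None = None,
):
    """Per-cell steady-state dose-response curves, up- and down-sweep.

    Every cell (its own gamma-drawn totals) is continued along the
    RasGTP grid from 0 upward and then back down, warm-starting each
    step — the protocol that exposes hysteresis.  Returns a dict with
    the grid, per-cell up/down ppERK matrices, population mean and
    5th/95th percentile bands, and a non-convergence flag per cell.
    """
    if ras_grid is None:
        ras_grid = np.arange(0.0, 101.0, 1.0)
    ras_grid = np.asarray(ras_grid, float)
    mean_totals = mean_totals or ProteinTotals()
    base = KineticParameters() if params is None else params
    kin = _dc_replace(base, Fa=TOPOLOGY_FA[topology.upper()])

    up = np.full((n_cells, len(ras_grid)), np.nan)
    down = np.full((n_cells, len(ras_grid)), np.nan)
    bad = np.zeros(n_cells, bool)
    for i, rng in enumerate(heterogeneity.cell_rngs(seed, n_cells)):
        t3 = rng.gamma(k_shape, mean_totals.MAP3K_total / k_shape)
        t2 = rng.gamma(k_shape, mean_totals.MAP2K_total / k_shape)
        tk = rng.gamma(k_shape, mean_totals.MAPK_total / k_shape)
        totals = ProteinTotals(t3, t2, tk)
        try:
            states_up = sweep_steady_states(ras_grid, totals, kin)
            up[i] = states_up[:, 7]
            top = CascadeState.from_array(states_up[-1])
            states_down = sweep_steady_states(ras_grid[::-1], totals, kin, initial=top)
            down[i] = states_down[::-1, 7]
        except SteadyStateError as exc:
            bad[i] = True
            log.warning("cell %d sweep failed: %s", i, exc)
    res = {"ras_grid": ras_grid, "up": up, "down": down, "failed": bad}
    for name, mat in (("up", up), ("down", down)):
        res[f"{name}_mean"] = np.nanmean(mat, axis=0)
        res[f"{name}_p5"] = np.nanpercentile(mat, 5, axis=0)
        res[f"{name}_p95"] = np.nanpercentile(mat, 95, axis=0)
    return res


def run_experiment_config(path_or_mapping):
    """Run a population experiment described by a YAML mapping.

    Keys: ``topology`` (NF/US/PF), ``n_cells``, ``seed``, optional
    ``k_shape``, ``times``, ``dose_indices``, ``noise`` ({mean, sd} or
    false), ``mean_totals`` ({MAP3K_total, MAP2K_total, MAPK_total}).
    Returns the (possibly noisy) :class:`PopulationResponse`.
    """
    import yaml

    if isinstance(path_or_mapping, dict):
        cfg = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "topology" not in cfg:
        raise ValueError("experiment config must be a mapping with a 'topology' key")
    totals = (ProteinTotals(**cfg["mean_totals"]) if "mean_totals" in cfg
              else ProteinTotals())
    resp = simulate_population(
        cfg["topology"], int(cfg.get("n_cells", 1000)), mean_totals=totals,
        k_shape=float(cfg.get("k_shape", heterogeneity.DEFAULT_SHAPE)),
        seed=int(cfg.get("seed", 0)),
        times=tuple(cfg.get("times", EXPERIMENT_TIMES_MIN)),
        dose_indices=cfg.get("dose_indices"))
    noise_cfg = cfg.get("noise", {})
    if noise_cfg is not False and noise_cfg is not None:
        noise = NoiseModel(**noise_cfg) if noise_cfg else NoiseModel()
        resp = add_measurement_noise(resp, noise, seed=int(cfg.get("seed", 0)))
    return resp


def normalize_by_total(ppERK_values, totalERK_values) -> np.ndarray:
    """Per-cell ratio ppERK / total ERK, rescaled to population mean 1.

    This is the normalization that collapses expression-driven
    variability: if ppERK is exactly proportional to total ERK the
    output is identically 1.
    """
    pp = np.asarray(ppERK_values, float)
    tot = np.asarray(totalERK_values, float)
    if pp.shape != tot.shape:
        raise ValueError("ppERK and total ERK arrays must have the same shape")
    if np.any(tot <= 0):
        raise ValueError("total ERK values must be strictly positive")
    ratio = pp / tot
    m = ratio.mean()
    if m == 0:
        raise ValueError("cannot normalize an all-zero signal")
    return ratio / m
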