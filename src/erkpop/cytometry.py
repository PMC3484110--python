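"""Synthetic flow-cytometry event tables.

Turns model populations into event tables with the statistical structure
of a flow-cytometry phosphorylation assay: per-event total-ERK and
ppERK intensities in arbitrary fluorescence units (AFU).  Total ERK is
drawn directly in AFU from the measured gamma law (default shape 5.4,
scale 2.7e5 AFU) and mapped to nM through a linear calibration for the
simulation; ppERK readout is the simulated concentration scaled back to
AFU with multiplicative lognormal stain noise plus additive Gaussian
background.  The calibration is a synthetic convention — the real
AFU <-> nM correspondence is not identifiable from population data.

The analysis entry point runs the same per-condition report (dip test,
on-fraction/on-mean, total-normalized distributions) on any CSV with
the documented schema, so exported real cytometry tables can be
re-analyzed identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bimodality, population
from .cascade import ProteinTotals
from .heterogeneity import DEFAULT_SHAPE, GammaSpec
from .ras_input import DoseSchedule, build_dose_schedule

__all__ = [
    "CalibrationModel",
    "EVENT_COLUMNS",
    "DEFAULT_TOTAL_ERK_AFU",
    "generate_fcpa_dataset",
    "read_event_table",
    "write_event_table",
    "analyze_event_table",
]

EVENT_COLUMNS = ("event_id", "dose_nM", "time_min", "ppERK_AFU", "totalERK_AFU")

#: gamma law of the total-ERK fluorescence marginal (shape, scale in AFU)
DEFAULT_TOTAL_ERK_AFU = GammaSpec(k=DEFAULT_SHAPE, theta=2.7e5)


@dataclass(frozen=True)
class CalibrationModel:
    """Synthetic AFU <-> nM mapping and measurement noise.

    ``scale`` AFU per nM; lognormal multiplicative stain noise with
    coefficient of variation ``measurement_cv``; additive Gaussian
    background (AFU).
    """

    scale: float = 3000.0
    background_mean: float = 2.0e4
    background_sd: float = 6.0e3
    measurement_cv: float = 0.2

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.measurement_cv < 0 or self.background_sd < 0:
            raise ValueError("measurement_cv and background_sd must be >= 0")

    def afu_to_nM(self, afu):
        return np.asarray(afu, float) / self.scale

    def nM_to_afu(self, nm):
        return np.asarray(nm, float) * self.scale


def generate_fcpa_dataset(
    topology: str = "NF",
    calibration: CalibrationModel | None = None,
    n_events: int = 10_000,
    schedule: DoseSchedule | None = None,
    times=population.EXPERIMENT_TIMES_MIN,
    seed: int = 0,
    total_erk_afu: GammaSpec = DEFAULT_TOTAL_ERK_AFU,
    k_shape: float = DEFAULT_SHAPE,
    mean_totals: ProteinTotals | None = None,
    dose_indices=None,
) -> pd.DataFrame:
    """Simulate an event table (``n_events`` cells per condition).

    Every event is one simulated cell: its total-ERK fluorescence is a
    gamma draw in AFU, converted through the calibration to the cell's
    ERK pool (nM) for the cascade simulation (the population mean pool
    is ``mean_totals.MAPK_total``, so the calibration scale used for the
    conversion is total-ERK-mean-AFU / MAPK_total); Raf/MEK totals and
    per-dose peak RasGTP are gamma draws as in
    :func:`erkpop.population.simulate_population`.  ppERK_AFU = scale *
    ppERK_nM * lognormal(cv) + Normal(background).  Within ERK-on
    events, ppERK and total ERK are positively correlated because the
    on-level scales with the cell's ERK pool.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    calibration = calibration or CalibrationModel()
    schedule = schedule or build_dose_schedule()
    mean_totals = mean_totals or ProteinTotals()

    # per-cell ERK pool implied by its total-ERK fluorescence
    erk_scale = total_erk_afu.mean / mean_totals.MAPK_total  # AFU per nM of ERK pool

    resp = population.simulate_population(
        topology, n_events, mean_totals=mean_totals, schedule=schedule,
        k_shape=k_shape, seed=seed, times=times, dose_indices=dose_indices)
    # replace the MAPK totals' nM draws with the AFU gamma law via the fixed
    # conversion: identical distribution family, exact AFU marginal
    total_afu = resp.cell_totals[:, 2] * erk_scale

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xFC,)))
    frames = []
    n_c, n_d, n_t = resp.ppERK.shape
    doses = [schedule.egf_doses_nM[d - 1] for d in
             (dose_indices or range(1, schedule.n_doses + 1))]
    for j, dose in enumerate(doses):
        for k, t in enumerate(resp.times):
            pp_nm = resp.ppERK[:, j, k]
            stain = (rng.lognormal(mean=-0.5 * np.log1p(calibration.measurement_cv**2),
                                   sigma=np.sqrt(np.log1p(calibration.measurement_cv**2)),
                                   size=n_c)
                     if calibration.measurement_cv > 0 else np.ones(n_c))
            background = rng.normal(calibration.background_mean,
                                    calibration.background_sd, size=n_c)
            pp_afu = calibration.scale * pp_nm * stain + background
            frames.append(pd.DataFrame({
                "event_id": np.arange(n_c),
                "dose_nM": dose,
                "time_min": float(t),
                "ppERK_AFU": pp_afu,
                "totalERK_AFU": total_afu,
            }))
    return pd.concat(frames, ignore_index=True)


def write_event_table(table: pd.DataFrame, path) -> None:
    """Write an event table as CSV with the documented schema."""
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    table.loc[:, EVENT_COLUMNS].to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    """Read an event-table CSV, validating schema and numeric content."""
    df = pd.read_csv(path)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty file")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("dose_nM", "time_min", "ppERK_AFU", "totalERK_AFU"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy()))
            raise ValueError(f"{path}: non-numeric or missing value in column "
                             f"{col!r} at data row {row}")
        df[col] = pd.to_numeric(df[col])
    return df


def analyze_event_table(table: pd.DataFrame, cutoff_AFU: float = 3.2e5,
                        alpha: float = 0.05, n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Per-condition report: dip test, ERK-on stats, normalized spread.

    For each (dose, time) condition: the dip-test p-value of the
    ppERK_AFU distribution, the ERK-on fraction/mean at the AFU cutoff,
    and the coefficient of variation of the total-normalized ppERK
    distribution (each event's ppERK divided by its total ERK, rescaled
    to mean 1).  Conditions with fewer than 4 events are skipped with a
    warning row.
    """
    rows = []
    for (dose, t), grp in table.groupby(["dose_nM", "time_min"], sort=True):
        row = {"dose_nM": dose, "time_min": t, "n_events": len(grp)}
        if len(grp) < 4:
            row.update(skipped=True)
            rows.append(row)
            continue
        x = grp["ppERK_AFU"].to_numpy(float)
        res = bimodality.classify_unimodal(x, alpha=alpha, n_boot=n_boot, seed=seed)
        part = population.partition_on_off(x, cutoff=cutoff_AFU)
        norm = population.normalize_by_total(x - x.min() + 1e-9,
                                             grp["totalERK_AFU"].to_numpy(float))
        row.update(skipped=False, dip=res.dip, p_value=res.p_value,
                   unimodal=res.unimodal, on_fraction=part.on_fraction,
                   on_mean_AFU=float(part.on_values.mean()) if part.n_on else np.nan,
                   normalized_cv=float(np.std(norm) / np.mean(norm)))
        rows.append(row)
    return pd.DataFrame(rows)
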