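"""Gamma-distributed cell-to-cell variability.

Stationary protein abundances across a clonal population are well
described by a gamma law ``f(N) = N^(k-1) exp(-N/theta) / (theta^k
Gamma(k))`` whose shape ``k`` reflects burst frequency and scale
``theta`` burst size.  The package uses one shape (default ``k = 5.4``,
the value measured for total ERK by flow cytometry) for total Raf, MEK,
ERK and for the peak RasGTP a cell reaches, adjusting ``theta`` per
quantity so the mean hits its target (mean = k*theta).

Per-cell reproducibility: each cell gets its own RNG substream spawned
from the master seed, so draws are identical regardless of execution
order or parallel scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cascade import ProteinTotals

__all__ = [
    "GammaSpec",
    "CellDraw",
    "DEFAULT_SHAPE",
    "sample_gamma",
    "fit_gamma_mle",
    "draw_population",
    "cell_rngs",
]

#: shape parameter measured for total ERK, shared by all sampled quantities
DEFAULT_SHAPE = 5.4


@dataclass(frozen=True)
class GammaSpec:
    """Gamma distribution by shape ``k`` and scale ``theta`` (nM or AU)."""

    k: float
    theta: float

    def __post_init__(self):
        if not (self.k > 0 and self.theta > 0):
            raise ValueError(f"need k > 0 and theta > 0, got k={self.k}, theta={self.theta}")

    @property
    def mean(self) -> float:
        return self.k * self.theta

    @property
    def cv(self) -> float:
        """Coefficient of variation, 1/sqrt(k)."""
        return 1.0 / np.sqrt(self.k)

    @classmethod
    def from_mean(cls, mean: float, k: float = DEFAULT_SHAPE) -> "GammaSpec":
        return cls(k=k, theta=mean / k)

    def pdf(self, x):
        return stats.gamma.pdf(x, a=self.k, scale=self.theta)

    def logpdf(self, x):
        return stats.gamma.logpdf(x, a=self.k, scale=self.theta)


@dataclass(frozen=True)
class CellDraw:
    """One simulated cell: its protein totals and its peak RasGTP (nM)."""

    cell_id: int
    totals: ProteinTotals
    peak_ras: float


def sample_gamma(spec: GammaSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` gamma variates; ``seed`` may be an int, SeedSequence or
    Generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.gamma(shape=spec.k, scale=spec.theta, size=n)


def fit_gamma_mle(samples) -> tuple[GammaSpec, float]:
    """Maximum-likelihood gamma fit; returns (spec, log-likelihood).

    The fit is scale-equivariant: scaling the data by c scales theta by c
    and leaves k unchanged.  Degenerate (near-constant) samples have no
    finite MLE (k diverges) and raise instead of returning a spec.
    """
    x = np.asarray(samples, float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("need a 1-d array of at least 10 samples")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("samples must be finite and strictly positive; "
                         "shift or filter explicitly before fitting")
    cv2 = np.var(x) / np.mean(x) ** 2
    if cv2 < 1e-12:
        raise ValueError("samples are (near-)constant: gamma shape diverges, no MLE")
    k, loc, theta = stats.gamma.fit(x, floc=0)
    spec = GammaSpec(k=float(k), theta=float(theta))
    loglik = float(np.sum(stats.gamma.logpdf(x, a=k, scale=theta)))
    return spec, loglik


def cell_rngs(seed, n_cells: int) -> list[np.random.Generator]:
    """Independent, order-insensitive per-cell RNG substreams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_cells)]


def draw_population(
    n_cells: int,
    mean_totals: ProteinTotals,
    dose_mean_Imax: float,
    k_shape: float = DEFAULT_SHAPE,
    seed=0,
) -> list[CellDraw]:
    """Sample a population's protein totals and peak RasGTP.

    Each quantity is drawn independently with shape ``k_shape`` and
    ``theta = mean / k_shape``.  With a fixed seed the draws are
    reproducible cell by cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    draws = []
    for i, rng in enumerate(cell_rngs(seed, n_cells)):
        t3 = rng.gamma(k_shape, mean_totals.MAP3K_total / k_shape)
        t2 = rng.gamma(k_shape, mean_totals.MAP2K_total / k_shape)
        tk = rng.gamma(k_shape, mean_totals.MAPK_total / k_shape)
        ras = rng.gamma(k_shape, dose_mean_Imax / k_shape)
        draws.append(CellDraw(cell_id=i, totals=ProteinTotals(t3, t2, tk), peak_ras=float(ras)))
    return draws


def draws_to_frame(draws: list[CellDraw]):
    """CellDraw table as a DataFrame (cell_id, totals, peak_ras)."""
    import pandas as pd

    return pd.DataFrame({
        "cell_id": [d.cell_id for d in draws],
        "MAP3K_total": [d.totals.MAP3K_total for d in draws],
        "MAP2K_total": [d.totals.MAP2K_total for d in draws],
        "MAPK_total": [d.totals.MAPK_total for d in draws],
        "peak_ras": [d.peak_ras for d in draws],
    })
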