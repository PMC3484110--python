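"""Hartigan's dip test of unimodality.

The dip of an empirical distribution function F_n is the smallest sup
distance between F_n and any unimodal CDF,

    dip(F_n) = min_{G unimodal} sup_x |F_n(x) - G(x)|.

It is computed by the classic iterative construction: on a shrinking
candidate modal interval, build the greatest convex minorant (GCM) of
F_n on the left part and the least concave majorant (LCM) on the right,
find the largest gap between the two hulls, and accumulate the maximal
deviations of F_n from the hulls outside the new modal interval; the dip
is half the final gap (in units of 1/n it is at least 1/(2n), attained
by perfectly equally spaced data).  The statistic is rank-based, hence
invariant under strictly increasing transformations.

Significance is assessed against the canonical uniform null: the
p-value is the Monte-Carlo fraction of uniform(0,1) samples of the same
size whose dip is at least the observed one, with an add-one correction
so p is never exactly 0.  Null dip samples are cached per (n, n_boot,
seed), which makes repeated tests at the same sample size cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["DipResult", "dip_statistic", "dip_pvalue", "classify_unimodal"]


@dataclass(frozen=True)
class DipResult:
    dip: float
    p_value: float | None
    n: int
    n_boot: int | None
    seed: int | None
    alpha: float = 0.05

    @property
    def unimodal(self) -> bool | None:
        """Unimodality retained unless p < alpha (strictly)."""
        return None if self.p_value is None else not (self.p_value < self.alpha)


@njit(cache=True)
def _dip_counts(x):  # pragma: no cover - exercised via dip_statistic
    """Dip of sorted data ``x`` in count units; dip = result / (2n).

    Works with the empirical CDF in counts: the convex minorant is the
    lower hull of (x_i, i) and the concave majorant the upper hull of
    (x_i, i+1), 0-based, so a perfect fit still leaves a gap of one unit
    (the jump of F_n at each data point).
    """
    n = x.shape[0]
    low = 0
    high = n - 1
    D = 1.0
    mn = np.empty(n, np.int64)
    mj = np.empty(n, np.int64)
    gcm = np.empty(n, np.int64)
    lcm = np.empty(n, np.int64)
    while True:
        # greatest convex minorant touch points on [low, high]
        mn[low] = low
        for i in range(low + 1, high + 1):
            mn[i] = i - 1
            while True:
                mnj = mn[i]
                if mnj == low:
                    break
                mnmnj = mn[mnj]
                # drop mnj when slope(mnj -> i) < slope(mnmnj -> mnj)
                if (i - mnj) * (x[mnj] - x[mnmnj]) < (mnj - mnmnj) * (x[i] - x[mnj]):
                    mn[i] = mnmnj
                else:
                    break
        kg = 0
        idx = high
        while True:
            gcm[kg] = idx
            kg += 1
            if idx == low:
                break
            idx = mn[idx]
        # reverse into increasing order
        for a in range(kg // 2):
            tmp = gcm[a]
            gcm[a] = gcm[kg - 1 - a]
            gcm[kg - 1 - a] = tmp

        # least concave majorant touch points on [low, high]
        mj[high] = high
        for i in range(high - 1, low - 1, -1):
            mj[i] = i + 1
            while True:
                mjk = mj[i]
                if mjk == high:
                    break
                mjmjk = mj[mjk]
                # drop mjk when slope(i -> mjk) < slope(mjk -> mjmjk)
                if (mjk - i) * (x[mjmjk] - x[mjk]) < (mjmjk - mjk) * (x[mjk] - x[i]):
                    mj[i] = mjmjk
                else:
                    break
        kl = 0
        idx = low
        while True:
            lcm[kl] = idx
            kl += 1
            if idx == high:
                break
            idx = mj[idx]

        # largest gap between the hulls; remember the modal interval
        d = 0.0
        new_lo = low
        new_hi = high
        ia = 1 if kg > 1 else 0
        for t in range(kl):
            j = lcm[t]
            while ia < kg - 1 and gcm[ia] < j:
                ia += 1
            a = gcm[ia - 1] if ia > 0 else gcm[0]
            b = gcm[ia]
            if b > a and x[b] > x[a]:
                interp = a + (x[j] - x[a]) * (b - a) / (x[b] - x[a])
            else:
                interp = float(j)
            gap = (j + 1.0) - interp
            if gap > d:
                d = gap
                new_lo = a
                new_hi = j
        ib = 1 if kl > 1 else 0
        for t in range(kg):
            i = gcm[t]
            while ib < kl - 1 and lcm[ib] < i:
                ib += 1
            c = lcm[ib - 1] if ib > 0 else lcm[0]
            e = lcm[ib]
            if e > c and x[e] > x[c]:
                interp = (c + 1.0) + (x[i] - x[c]) * (e - c) / (x[e] - x[c])
            else:
                interp = float(i + 1)
            gap = interp - i
            if gap > d:
                d = gap
                new_lo = i
                new_hi = e

        if d <= D:
            return D
        # deviations of F_n from the hulls outside the new modal interval
        dl = 0.0
        ia = 1 if kg > 1 else 0
        for i in range(low, new_lo + 1):
            while ia < kg - 1 and gcm[ia] < i:
                ia += 1
            a = gcm[ia - 1] if ia > 0 else gcm[0]
            b = gcm[ia]
            if b > a and x[b] > x[a]:
                interp = a + (x[i] - x[a]) * (b - a) / (x[b] - x[a])
            else:
                interp = float(i)
            dev = (i + 1.0) - interp
            if dev > dl:
                dl = dev
        du = 0.0
        ib = 1 if kl > 1 else 0
        for i in range(new_hi, high + 1):
            while ib < kl - 1 and lcm[ib] < i:
                ib += 1
            c = lcm[ib - 1] if ib > 0 else lcm[0]
            e = lcm[ib]
            if e > c and x[e] > x[c]:
                interp = (c + 1.0) + (x[i] - x[c]) * (e - c) / (x[e] - x[c])
            else:
                interp = float(i + 1)
            dev = interp - i
            if dev > du:
                du = dev
        if dl > D:
            D = dl
        if du > D:
            D = du
        if new_lo == low and new_hi == high:
            return D
        low = new_lo
        high = new_hi


@njit(cache=True)
def _dips_of_rows(mat):  # pragma: no cover
    out = np.empty(mat.shape[0])
    for r in range(mat.shape[0]):
        out[r] = _dip_counts(mat[r])
    return out


def dip_statistic(samples) -> float:
    """The dip statistic of a 1-d sample (n >= 4, finite values)."""
    x = np.asarray(samples, float)
    if x.ndim != 1:
        raise ValueError("samples must be 1-dimensional")
    if len(x) < 4:
        raise ValueError(f"dip test needs n >= 4, got n={len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    x = np.sort(x)
    return float(_dip_counts(x)) / (2.0 * len(x))


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    key = (n, n_boot, seed)
    hit = _NULL_CACHE.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng(seed)
    u = np.sort(rng.random((n_boot, n)), axis=1)
    dips = _dips_of_rows(u) / (2.0 * n)
    if len(_NULL_CACHE) > 32:
        _NULL_CACHE.clear()
    _NULL_CACHE[key] = dips
    return dips


def dip_pvalue(dip: float, n: int, n_boot: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo p-value of a dip under the uniform(0,1) null.

    p = (#{null dips >= dip} + 1) / (n_boot + 1).
    """
    if n_boot < 500:
        raise ValueError("n_boot must be >= 500 for a stable p-value")
    null = _null_dips(int(n), int(n_boot), int(seed))
    b = int(np.count_nonzero(null >= dip - 1e-15))
    return (b + 1.0) / (n_boot + 1.0)


def classify_unimodal(samples, alpha: float = 0.05, n_boot: int = 2000, seed: int = 0) -> DipResult:
    """Dip test with rejection when p < alpha (strict); p == alpha keeps
    the unimodal call."""
    x = np.asarray(samples, float)
    d = dip_statistic(x)
    p = dip_pvalue(d, len(x), n_boot=n_boot, seed=seed)
    return DipResult(dip=d, p_value=p, n=len(x), n_boot=n_boot, seed=seed, alpha=alpha)
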