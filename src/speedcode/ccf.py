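"""Cross-correlation between binned firing rate and running speed.

The CCF is the Pearson correlation r(tau) between the firing-rate
series at time t and the speed series at time t + tau, evaluated on a
lag grid (default [-10, 10] s in 0.1 s steps, 201 lags).  Positive
lags mean firing leads speed.  The observed CCF uses truncated
(non-circular) overlap; the significance null is built from circular
shifts of the speed series only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import SpeedTrace, SpikeTrain


@dataclass
class CcfResult:
    lags: np.ndarray
    r: np.ndarray                 # NaN where undefined (zero variance)
    r_max: float
    lag_star: float
    plateau: tuple[float, float]
    fwhm: float
    p_perm: float | None = None
    null_rmax: np.ndarray | None = None

    @property
    def significant(self) -> bool | None:
        """95th-percentile rule on the permutation null."""
        if self.null_rmax is None:
            return None
        return bool(abs(self.r_max) > np.percentile(self.null_rmax, 95))


def bin_rate_and_speed(
    spikes: SpikeTrain,
    speed: SpeedTrace,
    bin_width: float = 0.1,
    lag_max: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin a session into paired (firing rate, |speed|) series.

    Firing = spike count per bin / bin width (spikes/s); speed = mean
    |speed| per bin (cm/s).  Raises if the session is shorter than
    twice the CCF lag range.
    """
    duration = speed.duration
    if duration < 2 * lag_max:
        raise ValueError(
            f"session duration {duration:.1f} s shorter than 2 * lag_max"
        )
    n_bins = int(np.floor(duration / bin_width))
    edges = speed.t0 + np.arange(n_bins + 1) * bin_width
    counts = np.histogram(spikes.spike_times, bins=edges)[0]
    firing = counts / bin_width
    idx = np.minimum(
        ((speed.times - speed.t0) / bin_width).astype(int), n_bins - 1
    )
    sums = np.bincount(idx, weights=np.abs(speed.samples), minlength=n_bins)
    nper = np.bincount(idx, minlength=n_bins)
    mean_speed = sums / np.maximum(nper, 1)
    return firing, mean_speed


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def cross_correlation(
    firing: np.ndarray,
    speed: np.ndarray,
    lag_max: float = 10.0,
    bin_width: float = 0.1,
    plateau_tol: float = 1e-3,
) -> CcfResult:
    """Compute r(tau) on the lag grid and its peak statistics.

    r(tau) is the Pearson correlation of firing(t) with speed(t + tau)
    over the truncated overlap; the grid has 2 * lag_max / bin + 1
    points.  Lags with a zero-variance segment are recorded as NaN.
    """
    firing = np.asarray(firing, dtype=float)
    speed = np.asarray(speed, dtype=float)
    n = firing.size
    m = int(round(lag_max / bin_width))
    if n <= 2 * m:
        raise ValueError("series too short for the requested lag range")
    lags_bins = np.arange(-m, m + 1)
    r = np.empty(lags_bins.size)
    for i, k in enumerate(lags_bins):
        if k >= 0:
            r[i] = _pearson(firing[: n - k], speed[k:])
        else:
            r[i] = _pearson(firing[-k:], speed[: n + k])
    lags = lags_bins * bin_width
    r_max, lag_star, plateau, fwhm = peak_stats(lags, r, plateau_tol)
    return CcfResult(lags=lags, r=r, r_max=r_max, lag_star=lag_star,
                     plateau=plateau, fwhm=fwhm)


def peak_stats(
    lags: np.ndarray,
    r: np.ndarray,
    plateau_tol: float = 1e-3,
) -> tuple[float, float, tuple[float, float], float]:
    """Peak statistics of a CCF curve.

    r_max is the maximum defined r; the plateau is the contiguous lag
    run containing the argmax where r >= r_max - plateau_tol;
    lag_star is the plateau midpoint.  The FWHM is the width of the
    contiguous region around the peak with r >= (r_max + r_floor)/2,
    where r_floor is the minimum observed r on the grid.
    """
    r = np.asarray(r, dtype=float)
    if np.all(np.isnan(r)):
        raise ValueError("CCF curve has no defined values")
    i_max = int(np.nanargmax(r))
    r_max = float(r[i_max])

    ok = ~np.isnan(r)
    at_peak = ok & (r >= r_max - plateau_tol)
    lo = i_max
    while lo > 0 and at_peak[lo - 1]:
        lo -= 1
    hi = i_max
    while hi < r.size - 1 and at_peak[hi + 1]:
        hi += 1
    plateau = (float(lags[lo]), float(lags[hi]))
    lag_star = 0.5 * (plateau[0] + plateau[1])

    r_floor = float(np.nanmin(r))
    half = 0.5 * (r_max + r_floor)
    above = ok & (r >= half)
    lo = i_max
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_max
    while hi < r.size - 1 and above[hi + 1]:
        hi += 1
    fwhm = float(lags[hi] - lags[lo])
    return r_max, lag_star, plateau, fwhm


def _rmax_rows(firing: np.ndarray, speed_rows: np.ndarray, m: int) -> np.ndarray:
    """max_tau |r(tau)| for each row of `speed_rows`, vectorized.

    Used by the permutation null, where many circularly shifted speed
    series must be correlated against one firing series.
    """
    n = firing.size
    best = np.zeros(speed_rows.shape[0])
    for k in range(-m, m + 1):
        if k >= 0:
            x, Y = firing[: n - k], speed_rows[:, k:]
        else:
            x, Y = firing[-k:], speed_rows[:, : n + k]
        xc = x - x.mean()
        sx = x.std()
        mu = Y.mean(axis=1)
        sy = Y.std(axis=1)
        cov = (Y @ xc) / x.size - mu * xc.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            rk = np.abs(cov / (sx * sy))
        rk = np.nan_to_num(rk)
        np.maximum(best, rk, out=best)
    return best


def permutation_test(
    firing: np.ndarray,
    speed: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    lag_max: float = 10.0,
    bin_width: float = 0.1,
    observed_rmax: float | None = None,
) -> tuple[float, np.ndarray]:
    """Circular-shift permutation null for the CCF peak.

    Each permutation circularly shifts the speed series by a uniform
    random offset of at least lag_max (so no shift recreates
    near-alignment), recomputes |r_max| over the full lag grid, and
    the add-one p-value is (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    firing = np.asarray(firing, dtype=float)
    speed = np.asarray(speed, dtype=float)
    n = speed.size
    m = int(round(lag_max / bin_width))
    if n <= 2 * m + 1:
        raise ValueError("series shorter than the minimum circular shift")
    rng = np.random.default_rng(seed)
    if observed_rmax is None:
        observed_rmax = abs(
            cross_correlation(firing, speed, lag_max, bin_width).r_max
        )
    else:
        observed_rmax = abs(observed_rmax)
    shifts = rng.integers(m, n - m, size=n_perm)
    rows = np.empty((n_perm, n))
    for i, s in enumerate(shifts):
        rows[i] = np.roll(speed, s)
    null = _rmax_rows(firing, rows, m)
    p = (1.0 + np.sum(null >= observed_rmax)) / (1.0 + n_perm)
    return float(p), null


def ccf_analysis(
    spikes: SpikeTrain,
    speed: SpeedTrace,
    bin_width: float = 0.1,
    lag_max: float = 10.0,
    n_perm: int = 1000,
    seed: int = 0,
    plateau_tol: float = 1e-3,
) -> CcfResult:
    """Full CCF analysis of one neuron: curve, peak stats, permutation p."""
    firing, v = bin_rate_and_speed(spikes, speed, bin_width, lag_max)
    result = cross_correlation(firing, v, lag_max, bin_width, plateau_tol)
    p, null = permutation_test(
        firing, v, n_perm=n_perm, seed=seed, lag_max=lag_max,
        bin_width=bin_width, observed_rmax=result.r_max,
    )
    result.p_perm = p
    result.null_rmax = null
    return result
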