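"""Single-phase-association encoding fits and population summaries.

The encoding model relates running speed v to firing rate f through
the saturating exponential

    v = v_m * (1 - exp(-(f - f0) / tau))

where f0 is the initial firing rate, v_m the asymptotic maximum speed,
and tau the firing effect constant: the rise in firing above f0 needed
to reach 63.2% of v_m.  Fits are nonlinear least squares with bounded
parameters and jittered multi-start; a linear fit is reported
alongside for model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit


def single_phase(f: np.ndarray, f0: float, v_m: float, tau: float) -> np.ndarray:
    """Forward model v = v_m * (1 - exp(-(f - f0) / tau))."""
    return v_m * -np.expm1(-(np.asarray(f, dtype=float) - f0) / tau)


@dataclass
class EncodingFit:
    model: str                     # "single_phase" | "linear"
    f0: float = np.nan
    v_m: float = np.nan
    tau: float = np.nan
    slope: float = np.nan          # linear only
    intercept: float = np.nan      # linear only
    r_squared: float = np.nan
    fit_p: float = np.nan          # regression F-test vs constant model
    n_points: int = 0
    converged: bool = False
    f0_negative: bool = False

    def predict(self, f: np.ndarray) -> np.ndarray:
        if self.model == "single_phase":
            return single_phase(f, self.f0, self.v_m, self.tau)
        return self.intercept + self.slope * np.asarray(f, dtype=float)


@dataclass
class NormalizedFit:
    group: str
    group_mean_vm: float
    neuron_ids: list[str]
    tau_refit: np.ndarray
    y_scale: np.ndarray
    x_shift: np.ndarray
    tau_mean: float = np.nan
    tau_sd: float = np.nan


def _goodness(v: np.ndarray, pred: np.ndarray, k_params: int) -> tuple[float, float]:
    """R^2 and the F-test p-value of the regression against a constant."""
    n = v.size
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    df1, df2 = k_params - 1, n - k_params
    if df2 <= 0 or ss_res <= 0 or ss_tot <= ss_res:
        p = 0.0 if ss_res == 0 else np.nan
    else:
        F = ((ss_tot - ss_res) / df1) / (ss_res / df2)
        p = float(stats.f.sf(F, df1, df2))
    return r2, p


def align_by_lag(
    firing: np.ndarray,
    speed: np.ndarray,
    lag_star: float,
    bin_width: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair firing(t) with speed(t + lag_star) over the overlap.

    Undoes the firing-leads-speed delay before fitting: positive
    lag_star pairs each firing sample with the speed it predicts.
    """
    firing = np.asarray(firing, dtype=float)
    speed = np.asarray(speed, dtype=float)
    n = firing.size
    k = int(round(lag_star / bin_width))
    if abs(k) >= n:
        raise ValueError("lag exceeds series length")
    if k >= 0:
        return firing[: n - k], speed[k:]
    return firing[-k:], speed[: n + k]


def fit_single_phase(
    f: np.ndarray,
    v: np.ndarray,
    f0_floor: float = -5.0,
    n_starts: int = 5,
    seed: int = 0,
) -> EncodingFit:
    """Nonlinear least squares fit of the single-phase association model.

    Requires >= 5 distinct firing-rate values and non-negative speeds.
    Bounds: v_m in (0, 10 * max v], tau > 0, f0 >= `f0_floor` (a small
    negative floor absorbs noise; a negative estimate is flagged).  On
    failure of the default start, up to `n_starts` jittered restarts
    are tried; the best converged solution wins.
    """
    f = np.asarray(f, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.unique(f).size < 5:
        raise ValueError("need >= 5 distinct firing-rate values")
    if np.any(v < 0):
        raise ValueError("speeds must be non-negative")

    vmax = float(v.max())
    if vmax == 0:
        raise ValueError("all speeds are zero")
    fspan = float(f.max() - f.min())
    bounds = ([f0_floor, 1e-9, 1e-9], [float(f.max()), 10.0 * vmax, np.inf])
    base_p0 = np.array([float(f.min()), 1.05 * vmax, max(fspan / 2.0, 1e-3)])

    rng = np.random.default_rng(seed)
    best, best_sse = None, np.inf
    for attempt in range(n_starts + 1):
        if attempt == 0:
            p0 = base_p0
        else:
            jitter = rng.uniform(0.5, 1.5, size=3)
            p0 = base_p0 * jitter
            p0[0] = float(f.min()) * jitter[0] if f.min() != 0 else rng.uniform(0, 1)
        p0 = np.clip(p0, np.asarray(bounds[0]) + 1e-8, np.asarray(bounds[1]) - 1e-8)
        try:
            popt, _ = curve_fit(
                single_phase, f, v, p0=p0, bounds=bounds, maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((v - single_phase(f, *popt)) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
        if attempt == 0 and best is not None:
            break

    if best is None:
        return EncodingFit(model="single_phase", n_points=f.size, converged=False)
    f0, v_m, tau = (float(x) for x in best)
    r2, p = _goodness(v, single_phase(f, f0, v_m, tau), k_params=3)
    return EncodingFit(
        model="single_phase", f0=f0, v_m=v_m, tau=tau, r_squared=r2,
        fit_p=p, n_points=int(f.size), converged=True, f0_negative=f0 < 0,
    )


def inverse_single_phase(v: np.ndarray, f0: float, v_m: float, tau: float) -> np.ndarray:
    """Inverse model f = f0 - tau * ln(1 - v / v_m) (v clipped below v_m)."""
    v = np.clip(np.asarray(v, dtype=float), 0.0, 0.995 * v_m)
    return f0 - tau * np.log1p(-v / v_m)


def fit_single_phase_inverse(
    v: np.ndarray,
    f: np.ndarray,
    f0_floor: float = -5.0,
    seed: int = 0,
) -> EncodingFit:
    """Estimate (f0, v_m, tau) by regressing firing rate on speed.

    Fits f = f0 - tau * ln(1 - v / v_m): the statistically sound
    direction when speed is measured almost noise-free while binned
    firing rates carry Poisson counting noise — regressing speed on
    noisy firing (errors in the predictor) inflates tau and v_m.
    The returned parameters describe the same curve as
    :func:`fit_single_phase`; r_squared/fit_p refer to the firing-rate
    regression actually performed.
    """
    v = np.asarray(v, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.unique(np.round(v, 9)).size < 5:
        raise ValueError("need >= 5 distinct speed values")
    vmax = float(v.max())
    if vmax <= 0:
        raise ValueError("all speeds are zero")
    bounds = ([f0_floor, 1.001 * vmax, 1e-9], [float(f.max()), 20.0 * vmax, np.inf])
    base_p0 = np.array([float(f.min()), 1.05 * vmax, max(float(np.ptp(f)) / 2.0, 1e-3)])
    rng = np.random.default_rng(seed)
    for attempt in range(6):
        p0 = base_p0 if attempt == 0 else base_p0 * rng.uniform(0.5, 1.5, size=3)
        p0 = np.clip(p0, np.asarray(bounds[0]) + 1e-9, np.asarray(bounds[1]) - 1e-9)
        try:
            popt, _ = curve_fit(
                inverse_single_phase, v, f, p0=p0, bounds=bounds, maxfev=20000
            )
            break
        except (RuntimeError, ValueError):
            popt = None
    if popt is None:
        return EncodingFit(model="single_phase", n_points=f.size, converged=False)
    f0, v_m, tau = (float(x) for x in popt)
    r2, p = _goodness(f, inverse_single_phase(v, f0, v_m, tau), k_params=3)
    return EncodingFit(
        model="single_phase", f0=f0, v_m=v_m, tau=tau, r_squared=r2,
        fit_p=p, n_points=int(f.size), converged=True, f0_negative=f0 < 0,
    )


def fit_linear(f: np.ndarray, v: np.ndarray) -> EncodingFit:
    """Ordinary least squares line v = a + b f with R^2 and F-test p."""
    f = np.asarray(f, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.ptp(f) == 0:
        raise ValueError("zero variance in firing rate")
    res = stats.linregress(f, v)
    pred = res.intercept + res.slope * f
    r2, p = _goodness(v, pred, k_params=2)
    return EncodingFit(
        model="linear", slope=float(res.slope), intercept=float(res.intercept),
        r_squared=r2, fit_p=p, n_points=int(f.size), converged=True,
    )


def _aicc(v: np.ndarray, pred: np.ndarray, k: int) -> float:
    """Small-sample-corrected AIC from the Gaussian log-likelihood."""
    n = v.size
    sse = float(np.sum((v - pred) ** 2))
    if sse <= 0 or n <= k + 1:
        return -np.inf if sse <= 0 else np.inf
    aic = n * np.log(sse / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def fit_linear_and_compare(
    f: np.ndarray,
    v: np.ndarray,
    nonlinear: EncodingFit,
) -> dict:
    """Fit the linear model on the same pairs and compare to the
    saturating fit: delta R^2 (nonlinear minus linear), per-model
    F-test p-values, and AICc for both.

    The nonlinear R^2 is recomputed here in the speed direction from
    the fitted curve, so the comparison stays consistent even when the
    parameters were estimated by the inverse (firing-on-speed)
    regression."""
    linear = fit_linear(f, v)
    r2_nl, _ = _goodness(np.asarray(v, dtype=float),
                         nonlinear.predict(f), k_params=3)
    out = {
        "linear": linear,
        "delta_r_squared": float(r2_nl - linear.r_squared),
        "aicc_nonlinear": _aicc(v, nonlinear.predict(f), k=3),
        "aicc_linear": _aicc(v, linear.predict(f), k=2),
    }
    out["preferred"] = (
        "single_phase" if out["aicc_nonlinear"] < out["aicc_linear"] else "linear"
    )
    return out


def peak_to_peak_fit(
    peak_rates: np.ndarray,
    peak_speeds: np.ndarray,
    seed: int = 0,
) -> tuple[EncodingFit, dict]:
    """Population-level fit across neurons' (peak firing, peak speed).

    Tests whether the same saturating law that holds within neurons
    also holds across the population's peak operating points.
    """
    fit = fit_single_phase(peak_rates, peak_speeds, seed=seed)
    comparison = fit_linear_and_compare(
        np.asarray(peak_rates, dtype=float), np.asarray(peak_speeds, dtype=float), fit
    )
    return fit, comparison


def normalize_population(
    fits: list[EncodingFit],
    pairs: list[tuple[np.ndarray, np.ndarray]],
    neuron_ids: list[str] | None = None,
    group: str = "",
) -> NormalizedFit:
    """Standardize a group of encoding curves and refit tau.

    Per neuron: subtract the minimum firing rate and minimum speed,
    rescale speed by (group mean fitted v_m / neuron fitted v_m), then
    refit tau alone with f0 fixed at 0 and v_m fixed at the group
    mean.  Collapsing f0 and v_m isolates the firing effect constant
    for within-group comparison.
    """
    if neuron_ids is None:
        neuron_ids = [f"n{i}" for i in range(len(fits))]
    keep = [
        i for i, ft in enumerate(fits)
        if ft.converged and ft.model == "single_phase" and ft.v_m > 0
    ]
    if not keep:
        raise ValueError("no converged single-phase fits in group")
    mean_vm = float(np.mean([fits[i].v_m for i in keep]))

    ids, taus, scales, shifts = [], [], [], []
    for i in keep:
        f, v = (np.asarray(a, dtype=float) for a in pairs[i])
        x_shift = float(f.min())
        v_shift = float(v.min())
        y_scale = mean_vm / fits[i].v_m
        fn = f - x_shift
        vn = (v - v_shift) * y_scale

        def model(x, tau):
            return single_phase(x, 0.0, mean_vm, tau)

        tau0 = max(fits[i].tau, 1e-3)
        popt, _ = curve_fit(
            model, fn, vn, p0=[tau0], bounds=(1e-9, np.inf), maxfev=20000
        )
        ids.append(neuron_ids[i])
        taus.append(float(popt[0]))
        scales.append(y_scale)
        shifts.append(x_shift)

    taus = np.asarray(taus)
    return NormalizedFit(
        group=group, group_mean_vm=mean_vm, neuron_ids=ids,
        tau_refit=taus, y_scale=np.asarray(scales), x_shift=np.asarray(shifts),
        tau_mean=float(taus.mean()),
        tau_sd=float(taus.std(ddof=1)) if taus.size > 1 else 0.0,
    )


def parameter_relations(fits: list[EncodingFit]) -> dict:
    """Across-neuron parameter relations: OLS of v_m on tau plus
    Pearson correlations of f0 with tau and with v_m."""
    good = [ft for ft in fits if ft.converged and ft.model == "single_phase"]
    if len(good) < 5:
        raise ValueError("need >= 5 converged fits")
    tau = np.array([ft.tau for ft in good])
    vm = np.array([ft.v_m for ft in good])
    f0 = np.array([ft.f0 for ft in good])
    if np.ptp(tau) == 0:
        raise ValueError("constant predictor tau")
    res = stats.linregress(tau, vm)
    out = {
        "n": len(good),
        "vm_on_tau": {
            "slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "p": float(res.pvalue),
            "r_squared": float(res.rvalue**2),
        },
    }
    for name, arr in (("f0_vs_tau", tau), ("f0_vs_vm", vm)):
        if np.ptp(f0) == 0 or np.ptp(arr) == 0:
            out[name] = {"r": np.nan, "p": np.nan}
        else:
            r, p = stats.pearsonr(f0, arr)
            out[name] = {"r": float(r), "p": float(p)}
    return out
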