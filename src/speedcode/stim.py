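"""Optogenetic stimulation dose-response analysis.

Per-trial peak-speed extraction and behaviour labelling (running,
backing away, rebound, stopping), block averaging over repeated
trials, fitting of the running-stimulation function

    v_peak = v_m * (1 - exp(-(F - f0_stim) / tau_s))

with stimulation frequency F as abscissa, linear frequency-to-firing
conversion across neuron classes, and latency-vs-frequency curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import EncodingFit, fit_single_phase
from .session import SpeedTrace, StimulusEvent


@dataclass
class StimFit:
    behaviour: str
    v_m: float
    tau_s: float
    f0_stim: float
    r_squared: float
    fit_p: float
    converged: bool = True

    def predict(self, frequency: np.ndarray) -> np.ndarray:
        f = np.asarray(frequency, dtype=float)
        return self.v_m * -np.expm1(-(f - self.f0_stim) / self.tau_s)


def extract_peak_speed(
    speed: SpeedTrace,
    stim: StimulusEvent,
    threshold: float = 0.5,
    rebound_window: float = 10.0,
) -> dict:
    """Peak speed, behaviour label and latency for one opto trial.

    During stimulation: max |speed|; its sign labels the behaviour
    (running vs backing away); |speed| < threshold throughout means
    stopping.  If the trial is quiet during stimulation but crosses
    threshold within `rebound_window` s after offset, it is rebound
    and latency is measured from the offset; otherwise latency is the
    first threshold crossing after onset.
    """
    t = speed.times
    if stim.offset + rebound_window > t[-1] + 0.5 / speed.sampling_rate:
        raise ValueError("analysis window extends past the speed trace")
    during = (t >= stim.onset) & (t < stim.offset)
    post = (t >= stim.offset) & (t < stim.offset + rebound_window)
    v_dur = speed.samples[during]
    v_post = speed.samples[post]

    if np.any(np.abs(v_dur) > threshold):
        i = int(np.argmax(np.abs(v_dur)))
        peak = float(v_dur[i])
        behaviour = "running" if peak >= 0 else "backing_away"
        cross = np.flatnonzero(np.abs(v_dur) > threshold)
        latency = float(t[during][cross[0]] - stim.onset)
        return {"peak_speed": peak, "behaviour": behaviour, "latency": latency}
    if np.any(np.abs(v_post) > threshold):
        i = int(np.argmax(np.abs(v_post)))
        cross = np.flatnonzero(np.abs(v_post) > threshold)
        return {
            "peak_speed": float(v_post[i]),
            "behaviour": "rebound",
            "latency": float(t[post][cross[0]] - stim.offset),
        }
    return {"peak_speed": 0.0, "behaviour": "stopping", "latency": None}


def block_average(table: pd.DataFrame, block_size: int = 10) -> pd.DataFrame:
    """Block means of |peak speed| per stimulation frequency.

    Trials at each frequency are grouped into consecutive blocks of
    `block_size`; partial trailing blocks are kept and flagged.
    Stopping trials contribute their zero peak to the mean.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if table.empty:
        raise ValueError("empty trial table")
    rows = []
    for freq, grp in table.groupby("frequency_hz", sort=True):
        mags = np.abs(grp.sort_values("trial_index")["peak_speed_cm_s"].to_numpy())
        for b in range(0, mags.size, block_size):
            chunk = mags[b : b + block_size]
            rows.append(
                {
                    "frequency_hz": float(freq),
                    "block": b // block_size,
                    "mean_peak_speed_cm_s": float(chunk.mean()),
                    "n_trials": int(chunk.size),
                    "partial": chunk.size < block_size,
                }
            )
    return pd.DataFrame(rows)


def fit_stimulation_curve(
    frequencies: np.ndarray,
    speeds: np.ndarray,
    behaviour: str = "running",
    seed: int = 0,
) -> StimFit:
    """Fit the running-stimulation function to (frequency, speed) points.

    The frequency offset f0_stim is bounded to [0, min frequency]:
    evoked speed is zero below the lowest tested frequency, not at a
    fitted negative rate.  Speeds are magnitudes.
    """
    from scipy.optimize import curve_fit

    from .encoding import _goodness, single_phase

    frequencies = np.asarray(frequencies, dtype=float)
    speeds = np.abs(np.asarray(speeds, dtype=float))
    if np.unique(frequencies).size < 5:
        raise ValueError("need >= 5 distinct frequencies")
    fmin = float(frequencies.min())
    bounds = ([0.0, 1e-9, 1e-9], [fmin, 10.0 * float(speeds.max()), np.inf])
    p0 = [fmin / 2.0, 1.05 * float(speeds.max()), float(np.ptp(frequencies)) / 2.0]
    try:
        popt, _ = curve_fit(
            single_phase, frequencies, speeds, p0=p0, bounds=bounds, maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        r2, p = _goodness(speeds, single_phase(frequencies, *popt), k_params=3)
        fit = EncodingFit(
            model="single_phase", f0=float(popt[0]), v_m=float(popt[1]),
            tau=float(popt[2]), r_squared=r2, fit_p=p,
            n_points=int(frequencies.size), converged=True,
        )
    except RuntimeError:
        fit = fit_single_phase(frequencies, speeds, f0_floor=0.0, seed=seed)
    return StimFit(
        behaviour=behaviour, v_m=fit.v_m, tau_s=fit.tau, f0_stim=fit.f0,
        r_squared=fit.r_squared, fit_p=fit.fit_p, converged=fit.converged,
    )


def fit_trial_table(
    table: pd.DataFrame,
    block_size: int = 10,
    behaviour: str | None = None,
    seed: int = 0,
) -> StimFit:
    """Block-average a trial table and fit the dose-response curve."""
    blocks = block_average(table, block_size)
    if behaviour is None:
        modes = table.loc[table["behaviour"] != "stopping", "behaviour"]
        behaviour = modes.mode().iat[0] if not modes.empty else "stopping"
    return fit_stimulation_curve(
        blocks["frequency_hz"].to_numpy(),
        blocks["mean_peak_speed_cm_s"].to_numpy(),
        behaviour=behaviour,
        seed=seed,
    )


def freq_to_rate_conversion(
    frequencies: np.ndarray,
    evoked_rates: dict[str, np.ndarray],
) -> dict:
    """Linear frequency -> firing-rate conversion per neuron class.

    Fits an OLS line of evoked rate (spikes/s) on stimulation
    frequency (Hz) for each class and reports the ratio of the first
    class's slope to each other (e.g. direct vs trans-synaptic drive).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.size < 3:
        raise ValueError("need >= 3 frequencies")
    slopes = {}
    for cls, rates in evoked_rates.items():
        rates = np.asarray(rates, dtype=float)
        if rates.size != frequencies.size:
            raise ValueError(f"class {cls!r}: rate/frequency length mismatch")
        res = stats.linregress(frequencies, rates)
        slopes[cls] = {
            "slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2), "p": float(res.pvalue),
        }
    classes = list(evoked_rates)
    ratios = {}
    if len(classes) >= 2:
        ref = slopes[classes[0]]["slope"]
        for cls in classes[1:]:
            s = slopes[cls]["slope"]
            ratios[f"{classes[0]}:{cls}"] = float(ref / s) if s != 0 else np.inf
    return {"slopes": slopes, "ratios": ratios}


def latency_curves(table: pd.DataFrame, stim_fit: StimFit) -> pd.DataFrame:
    """Mean latency per frequency, plus the model-converted speed axis.

    The second abscissa converts each stimulation frequency into the
    speed the fitted dose-response curve predicts, letting latency be
    read against evoked speed.  A Spearman correlation of latency with
    frequency is attached as a monotonicity diagnostic
    (`df.attrs['spearman_rho']`).
    """
    with_lat = table.dropna(subset=["latency_s"])
    if with_lat["frequency_hz"].nunique() < 3:
        raise ValueError("latencies defined for fewer than 3 frequencies")
    grp = with_lat.groupby("frequency_hz")["latency_s"].agg(["mean", "std", "count"])
    out = grp.reset_index().rename(
        columns={"mean": "latency_mean_s", "std": "latency_sd_s", "count": "n"}
    )
    out["converted_speed_cm_s"] = stim_fit.predict(out["frequency_hz"].to_numpy())
    if with_lat["latency_s"].nunique() > 1:
        rho, p = stats.spearmanr(with_lat["frequency_hz"], with_lat["latency_s"])
    else:
        rho, p = 0.0, 1.0  # flat latency curve
    out.attrs["spearman_rho"] = float(rho)
    out.attrs["spearman_p"] = float(p)
    return out
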