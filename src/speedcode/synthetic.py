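"""Synthetic session generator with known ground truth.

Emulates head-fixed turntable recordings: spontaneous running bouts
gated at a 0.5 cm/s threshold, brief sensory stimuli (sound / light /
air puff, 1 s), spike trains whose instantaneous rate follows the
inverse single-phase-association model with a firing-leads-speed lag,
and optogenetic trial tables (stimulation frequency vs evoked peak
speed).  Every generator is a pure function of its seed, and returns
the ground-truth labels/parameters needed to evaluate the pipeline.

The forward encoding model maps firing rate f to speed v as

    v = v_m * (1 - exp(-(f - f0) / tau))

so the generator drives each running-related neuron with its inverse,

    rate(t) = f0 - tau * ln(1 - |v(t + lag)| / v_m),

with |v| clipped to 0.99 * v_m where the log would diverge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import Session, SpeedTrace, SpikeTrain, StimulusEvent, StimulusSchedule

OPTO_FREQUENCIES = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)


@dataclass
class EncodingParams:
    """Ground-truth encoding parameters for one running-related neuron.

    f0 : baseline firing rate (spikes/s); tau_f : firing effect
    constant (spikes/s); v_m : asymptotic maximum speed (cm/s);
    lag : time by which firing leads speed (s).
    """

    f0: float = 2.0
    tau_f: float = 20.0
    v_m: float = 25.0
    lag: float = 2.0
    rate_noise_sd: float = 0.0
    speed_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.v_m <= 0 or self.tau_f <= 0:
            raise ValueError("v_m and tau_f must be positive")
        if self.f0 < 0 or self.lag < 0:
            raise ValueError("f0 and lag must be non-negative")


@dataclass
class PopulationSpec:
    """Distributional description of a simulated neural population.

    Defaults emulate temporal association cortex (TeA) running-related
    neurons: firing leads speed by 2.064 +/- 0.273 s, bout peak speeds
    16-28 cm/s.  For the periaqueductal-grey-like population use
    :meth:`dpag` (lag 0.903 +/- 0.228 s, slower bouts, hence smaller
    v_m and a firing effect constant about half the cortical one).

    Each neuron's v_m (asymptotic maximum speed of its saturation
    curve) is anchored just above the session's fastest bout: the
    fastest observed speed falls at a saturation fraction drawn from
    [saturation_lo, saturation_hi] of v_m, mirroring how a fitted
    asymptote sits slightly beyond the data.  tau then follows the
    empirical linear relation v_m = vm_slope * tau + vm_intercept
    with residual SD tau_residual_sd.
    """

    group: str = "TeA"
    n_neurons: int = 30
    fractions: tuple[float, float, float] = (1.0, 0.0, 0.0)  # (R, sensory, unrelated)
    bout_peak_lo: float = 16.0
    bout_peak_hi: float = 28.0
    saturation_lo: float = 0.78
    saturation_hi: float = 0.95
    vm_slope: float = 1.43
    vm_intercept: float = 7.37
    tau_residual_sd: float = 1.5
    f0_mean: float = 2.0
    f0_sd: float = 1.0
    lag_mean: float = 2.064
    lag_sd: float = 0.273
    baseline_rate: float = 5.0
    sensory_bump_scale: float = 3.0
    speed_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        fr = self.fractions
        if any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("class fractions must lie in [0,1] and sum to 1")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not 0 < self.saturation_lo < self.saturation_hi < 1:
            raise ValueError("saturation fractions must satisfy 0 < lo < hi < 1")

    @classmethod
    def tea(cls, **kw) -> "PopulationSpec":
        return cls(group="TeA", **kw)

    @classmethod
    def dpag(cls, **kw) -> "PopulationSpec":
        kw.setdefault("bout_peak_lo", 10.0)
        kw.setdefault("bout_peak_hi", 18.0)
        kw.setdefault("lag_mean", 0.903)
        kw.setdefault("lag_sd", 0.228)
        return cls(group="dPAG", **kw)


@dataclass
class BoutSchedule:
    """Planned running bouts: (onset s, duration s, peak speed cm/s)."""

    bouts: list[tuple[float, float, float]] = field(default_factory=list)
    min_gap: float = 0.5

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for onset, dur, peak in sorted(self.bouts):
            if dur <= 0:
                raise ValueError("bout duration must be positive")
            if onset < prev_end + self.min_gap:
                raise ValueError("bouts overlap or violate the minimum gap")
            prev_end = onset + dur
        self.bouts = sorted(self.bouts)


@dataclass
class StimResponseParams:
    """Forward dose-response model for optogenetic stimulation.

    Peak evoked speed at stimulation frequency F is
    v_m * (1 - exp(-(F - f0_stim) / tau_s)), floored at zero, plus
    trial noise.  `behaviour` selects the sign/window convention:
    running (positive, during stimulation), backing_away (negative,
    during stimulation), rebound (positive, after offset).
    """

    tau_s: float = 14.32
    v_m: float = 22.81
    f0_stim: float = 0.0
    trial_noise_sd: float = 2.0
    behaviour: str = "running"
    # latency model: latency(F) = lat_floor + lat_amp * exp(-F / lat_k)
    lat_floor: float = 0.3
    lat_amp: float = 2.0
    lat_k: float = 10.0
    lat_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.tau_s <= 0 or self.v_m <= 0:
            raise ValueError("tau_s and v_m must be positive")
        if self.behaviour not in ("running", "backing_away", "rebound"):
            raise ValueError(f"unknown behaviour {self.behaviour!r}")

    def mean_peak_speed(self, frequency: np.ndarray) -> np.ndarray:
        f = np.asarray(frequency, dtype=float)
        return self.v_m * -np.expm1(-(f - self.f0_stim) / self.tau_s)

    def mean_latency(self, frequency: np.ndarray) -> np.ndarray:
        f = np.asarray(frequency, dtype=float)
        return self.lat_floor + self.lat_amp * np.exp(-f / self.lat_k)


# ---------------------------------------------------------------------------
# Speed and rate construction


def generate_bouts_and_speed(
    schedule: BoutSchedule,
    sampling_rate: float = 100.0,
    speed_noise_sd: float = 0.05,
    seed: int = 0,
    duration: float | None = None,
    ramp: float = 1.0,
) -> SpeedTrace:
    """Build a signed speed trace from a bout schedule.

    Each bout is a trapezoid: linear `ramp`-second rise to its peak
    speed, plateau, linear fall.  Elsewhere the trace is zero plus
    Gaussian sensor noise.
    """
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = (max((o + d for o, d, _ in schedule.bouts), default=0.0) + 10.0)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    v = np.zeros(n)
    for onset, dur, peak in schedule.bouts:
        r = min(ramp, dur / 2.0)
        up = np.clip((t - onset) / r, 0.0, 1.0)
        down = np.clip((onset + dur - t) / r, 0.0, 1.0)
        shape = np.minimum(up, down)
        v = np.maximum(v, peak * shape)
    if speed_noise_sd > 0:
        v = v + rng.normal(0.0, speed_noise_sd, size=n)
    return SpeedTrace(sampling_rate=sampling_rate, samples=v)


def rate_from_speed(speed: SpeedTrace, params: EncodingParams) -> np.ndarray:
    """Instantaneous firing rate implied by the inverse encoding model.

    rate(t) = f0 - tau_f * ln(1 - |v(t + lag)| / v_m) with |v| clipped
    to 0.99 * v_m; the rate equals f0 wherever speed is zero and grows
    monotonically with |speed|.  Returns spikes/s on the speed grid.
    """
    t = speed.times
    v = np.abs(speed.speed_at(t + params.lag))
    v = np.clip(v, 0.0, 0.99 * params.v_m)
    return params.f0 - params.tau_f * np.log1p(-v / params.v_m)


def sample_inhomogeneous_poisson(
    rate: np.ndarray,
    sampling_rate: float,
    seed: int = 0,
    t0: float = 0.0,
) -> np.ndarray:
    """Draw spike times from an inhomogeneous Poisson process by thinning.

    Candidates come from a homogeneous process at max(rate); each is
    kept with probability rate(t)/max(rate).  Returns sorted times in
    [t0, t0 + len(rate)/sampling_rate].
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    duration = rate.size / sampling_rate
    rmax = float(rate.max(initial=0.0))
    if rmax == 0.0 or duration == 0.0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n_cand = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    grid = t0 + np.arange(rate.size) / sampling_rate
    local = np.interp(t0 + cand, grid, rate)
    keep = rng.uniform(0.0, rmax, size=n_cand) < local
    times = t0 + cand[keep]
    # strict ordering required downstream; perturb exact ties
    times = np.unique(times)
    return times


# ---------------------------------------------------------------------------
# Full-session generators


def _default_layout(
    rng: np.random.Generator,
    n_slots: int = 24,
    slot: float = 25.0,
    peak_lo: float = 16.0,
    peak_hi: float = 28.0,
    n_stimuli_per_modality: int = 5,
) -> tuple[BoutSchedule, StimulusSchedule, float]:
    """One bout per slot plus sensory stimuli early in a subset of slots.

    Bout peak speeds are drawn uniformly in [peak_lo, peak_hi] cm/s.
    Stimuli sit >= 6 s before the slot's bout onset and well after the
    previous bout's offset, so stimulus trials are running-free and
    every bout is spontaneous under the default 3 s labelling window.
    """
    bouts = []
    for k in range(n_slots):
        onset = k * slot + rng.uniform(8.0, 13.0)
        dur = rng.uniform(4.0, 9.0)
        peak = rng.uniform(peak_lo, peak_hi)
        bouts.append((onset, dur, peak))
    duration = n_slots * slot
    modalities = ("sound", "light", "air_puff")
    slots = rng.permutation(n_slots)[: n_stimuli_per_modality * len(modalities)]
    events = []
    for i, k in enumerate(sorted(slots)):
        events.append(
            StimulusEvent(modality=modalities[i % 3], onset=k * slot + 1.0, duration=1.0)
        )
    return BoutSchedule(bouts=bouts), StimulusSchedule(events=events), duration


def _sensory_rate(
    baseline: float,
    bump: float,
    stimuli: StimulusSchedule,
    times: np.ndarray,
) -> np.ndarray:
    """Constant baseline plus a rectangular bump during each sensory
    stimulus followed by a 200 ms exponential decay tail."""
    rate = np.full(times.size, baseline)
    for ev in stimuli:
        if ev.modality == "opto":
            continue
        during = (times >= ev.onset) & (times < ev.offset)
        rate[during] += bump
        after = times >= ev.offset
        rate[after] += bump * np.exp(-(times[after] - ev.offset) / 0.2)
    return rate


def make_r_neuron_session(
    params: EncodingParams | None = None,
    seed: int = 0,
    duration_slots: int = 24,
    sampling_rate: float = 100.0,
) -> tuple[Session, EncodingParams]:
    """A single running-related neuron under the default study
    conditions: ~24 spontaneous bouts over 600 s, bout peaks spanning
    60-95% of the neuron's v_m, spikes by Poisson thinning."""
    params = params or EncodingParams()
    rng = np.random.default_rng(seed)
    schedule, stimuli, duration = _default_layout(
        rng, n_slots=duration_slots,
        peak_lo=0.60 * params.v_m, peak_hi=0.95 * params.v_m,
    )
    speed = generate_bouts_and_speed(
        schedule,
        sampling_rate=sampling_rate,
        speed_noise_sd=params.speed_noise_sd,
        seed=int(rng.integers(2**31)),
        duration=duration,
    )
    rate = rate_from_speed(speed, params)
    if params.rate_noise_sd > 0:
        rate = np.maximum(rate + rng.normal(0, params.rate_noise_sd, rate.size), 0.0)
    spikes = sample_inhomogeneous_poisson(
        rate, sampling_rate, seed=int(rng.integers(2**31))
    )
    train = SpikeTrain("r0", spikes, session_duration=duration, region="TeA")
    return Session(spike_trains=[train], speed=speed, stimuli=stimuli), params


def generate_population_session(
    spec: PopulationSpec,
    seed: int = 0,
    schedule: BoutSchedule | None = None,
    stimuli: StimulusSchedule | None = None,
    sampling_rate: float = 100.0,
    duration: float | None = None,
) -> tuple[Session, pd.DataFrame]:
    """Simulate a mixed population sharing one speed trace.

    Running-related neurons encode speed through the inverse model;
    sensory neurons carry stimulus-locked rate bumps and no speed
    coupling; unrelated neurons fire at a constant rate.  Returns the
    session and a ground-truth table (neuron_id, class, f0, tau_f,
    v_m, lag).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_neurons
    counts = np.floor(np.asarray(spec.fractions) * n).astype(int)
    while counts.sum() < n:  # distribute rounding remainder
        counts[int(np.argmax(np.asarray(spec.fractions) * n - counts))] += 1
    classes = ["R"] * counts[0] + ["sensory"] * counts[1] + ["unrelated"] * counts[2]

    if schedule is None or stimuli is None:
        sched, stims, dur = _default_layout(
            rng, peak_lo=spec.bout_peak_lo, peak_hi=spec.bout_peak_hi
        )
        schedule = schedule or sched
        stimuli = stimuli or stims
        duration = duration or dur
    if duration is None:
        duration = max((o + d for o, d, _ in schedule.bouts), default=0.0) + 10.0
    max_peak = max((p for _, _, p in schedule.bouts), default=spec.bout_peak_hi)

    # v_m anchored just above the fastest bout; tau from the v_m line
    params: list[EncodingParams | None] = []
    for cls in classes:
        if cls != "R":
            params.append(None)
            continue
        sat = float(rng.uniform(spec.saturation_lo, spec.saturation_hi))
        vm = max_peak / sat
        tau = max(
            (vm - spec.vm_intercept) / spec.vm_slope
            + float(rng.normal(0, spec.tau_residual_sd)),
            3.0,
        )
        f0 = max(float(rng.normal(spec.f0_mean, spec.f0_sd)), 0.0)
        lag = max(float(rng.normal(spec.lag_mean, spec.lag_sd)), 0.0)
        params.append(
            EncodingParams(
                f0=f0, tau_f=tau, v_m=vm, lag=lag, speed_noise_sd=spec.speed_noise_sd
            )
        )

    speed = generate_bouts_and_speed(
        schedule,
        sampling_rate=sampling_rate,
        speed_noise_sd=spec.speed_noise_sd,
        seed=int(rng.integers(2**31)),
        duration=duration,
    )

    trains, truth_rows = [], []
    for i, (cls, p) in enumerate(zip(classes, params)):
        nid = f"n{i:03d}"
        if cls == "R":
            rate = rate_from_speed(speed, p)
            row = dict(f0=p.f0, tau_f=p.tau_f, v_m=p.v_m, lag=p.lag)
        elif cls == "sensory":
            base = max(float(rng.normal(spec.baseline_rate, 1.0)), 1.0)
            bump = spec.sensory_bump_scale * np.sqrt(base)
            rate = _sensory_rate(base, bump, stimuli, speed.times)
            row = dict(f0=base, tau_f=np.nan, v_m=np.nan, lag=np.nan)
        else:
            base = max(float(rng.normal(spec.baseline_rate, 1.0)), 1.0)
            rate = np.full(speed.samples.size, base)
            row = dict(f0=base, tau_f=np.nan, v_m=np.nan, lag=np.nan)
        spikes = sample_inhomogeneous_poisson(
            rate, sampling_rate, seed=int(rng.integers(2**31))
        )
        trains.append(
            SpikeTrain(nid, spikes, session_duration=duration,
                       region=spec.group if spec.group in ("TeA", "dPAG") else "other")
        )
        truth_rows.append({"neuron_id": nid, "class": cls, **row})

    session = Session(
        spike_trains=trains, speed=speed, stimuli=stimuli,
        metadata={"group": spec.group, "seed": seed},
    )
    return session, pd.DataFrame(truth_rows)


def generate_optostim_trials(
    params: StimResponseParams,
    frequencies: tuple[float, ...] = OPTO_FREQUENCIES,
    n_trials_per_freq: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an optogenetic frequency-series experiment.

    Returns a trial table with columns (frequency_hz, trial_index,
    peak_speed_cm_s, behaviour, latency_s).  Peak speed follows the
    forward dose-response curve plus Gaussian trial noise, floored at
    zero magnitude; backing-away rows are stored with negative sign.
    Latency decreases with frequency per the latency model.
    """
    if n_trials_per_freq < 1:
        raise ValueError("n_trials_per_freq must be >= 1")
    freqs = np.asarray(frequencies, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for f in freqs:
        mu = float(params.mean_peak_speed(f))
        lat_mu = float(params.mean_latency(f))
        for k in range(n_trials_per_freq):
            peak = max(mu + float(rng.normal(0, params.trial_noise_sd)), 0.0)
            lat = max(lat_mu + float(rng.normal(0, params.lat_noise_sd)), 0.0)
            behaviour = params.behaviour if peak > 0 else "stopping"
            signed = -peak if params.behaviour == "backing_away" else peak
            rows.append(
                {
                    "frequency_hz": f,
                    "trial_index": k,
                    "peak_speed_cm_s": signed,
                    "behaviour": behaviour,
                    "latency_s": lat if peak > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
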