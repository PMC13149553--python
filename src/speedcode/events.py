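"""Event detection and peri-event preprocessing.

Running-bout detection on the speed trace, trial labelling
(spontaneous vs stimulus-evoked runs; no-run stimulus trials),
peri-event time histograms (PETH), Gaussian spike-density functions,
detection of the pre-onset "firing-running" window, and population
heatmap construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .session import SpeedTrace, SpikeTrain, StimulusSchedule


@dataclass
class RunningEvents:
    """Detected running bouts: onsets/offsets in session time."""

    onsets: np.ndarray
    offsets: np.ndarray
    peak_speeds: np.ndarray
    provenance: list[str] = field(default_factory=list)  # spontaneous | stimulus_evoked

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.peak_speeds = np.asarray(self.peak_speeds, dtype=float)
        if np.any(self.offsets <= self.onsets):
            raise ValueError("event offsets must exceed onsets")
        if np.any(self.onsets[1:] < self.offsets[:-1]):
            raise ValueError("events must not overlap")

    def __len__(self) -> int:
        return int(self.onsets.size)

    def spontaneous_onsets(self) -> np.ndarray:
        if not self.provenance:
            return self.onsets
        mask = np.array([p == "spontaneous" for p in self.provenance])
        return self.onsets[mask]


@dataclass
class Peth:
    """Trial-aligned binned spike counts.

    `counts[i, j]` is the spike count of trial i in bin j; the mean
    firing rate per bin is sum over trials / (n_trials * bin_width).
    Bins are half-open [edge, edge + dt): a spike exactly at the
    alignment event falls in the first post-event bin.
    """

    bin_edges: np.ndarray  # len = n_bins + 1, relative to the event
    counts: np.ndarray     # trials x bins
    alignment: str = "running_onset"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.bin_edges.size - 1:
            raise ValueError("counts must be trials x (len(bin_edges) - 1)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return int(self.counts.shape[0])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_rate(self) -> np.ndarray:
        """Mean firing rate per bin (spikes/s): counts / (N * dt)."""
        return self.counts.sum(axis=0) / (self.n_trials * self.bin_width)


@dataclass
class FiringWindow:
    """Pre-onset interval of significantly elevated firing.

    `start` <= 0 is relative to running onset; `end` is 0 (the onset).
    A neuron that never crosses Baseline + 2*SD has no window
    (start is None).
    """

    start: float | None
    end: float
    baseline_mean: float
    baseline_sd: float
    degenerate_baseline: bool = False

    @property
    def found(self) -> bool:
        return self.start is not None

    @property
    def time_difference(self) -> float | None:
        """Lead time of firing before running onset (positive, s)."""
        return None if self.start is None else -self.start


@dataclass
class SpikeDensity:
    grid: np.ndarray
    density: np.ndarray
    sigma: float


# ---------------------------------------------------------------------------


def detect_running_events(
    speed: SpeedTrace,
    threshold: float = 0.5,
    min_gap: float = 0.5,
    min_duration: float = 0.5,
) -> RunningEvents:
    """Detect running bouts by threshold crossing on |speed|.

    A bout starts at the first sample whose |speed| exceeds
    `threshold` and ends at the first subsequent sample where |speed|
    stays below threshold for at least `min_gap` seconds (shorter
    sub-threshold dips are bridged).  Bouts shorter than
    `min_duration` are dropped.
    """
    v = np.abs(speed.samples)
    above = v > threshold
    if not above.any():
        return RunningEvents(np.empty(0), np.empty(0), np.empty(0), [])
    fs = speed.sampling_rate
    gap_n = max(int(round(min_gap * fs)), 1)

    # raw above-threshold segments
    starts = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    stops = np.flatnonzero(~above & np.r_[False, above[:-1]])  # first idx below
    if stops.size < starts.size:
        stops = np.r_[stops, above.size]

    # merge segments separated by sub-min_gap dips
    merged = []
    for s0, s1 in zip(starts, stops):
        if merged and s0 - merged[-1][1] < gap_n:
            merged[-1][1] = s1
        else:
            merged.append([s0, s1])

    onsets, offsets, peaks = [], [], []
    for s0, s1 in merged:
        if (s1 - s0) / fs < min_duration:
            continue
        onsets.append(speed.t0 + s0 / fs)
        offsets.append(speed.t0 + s1 / fs)
        peaks.append(float(v[s0:s1].max()))
    return RunningEvents(np.array(onsets), np.array(offsets), np.array(peaks), [])


def label_trials(
    events: RunningEvents,
    stimuli: StimulusSchedule,
    speed: SpeedTrace,
    sensory_running_window: float,
    threshold: float = 0.5,
) -> tuple[RunningEvents, list[dict]]:
    """Label running events and stimulus trials.

    A running onset is *spontaneous* iff no stimulus onset occurred
    within `sensory_running_window` seconds before it; otherwise it is
    stimulus-evoked.  A stimulus trial is *no-run* iff |speed| stays
    below `threshold` throughout the post-onset window.  Returns the
    events with provenance filled plus per-stimulus trial dicts.
    """
    if sensory_running_window <= 0:
        raise ValueError("sensory_running_window must be positive")
    stim_onsets = np.array([e.onset for e in stimuli])
    provenance = []
    for onset in events.onsets:
        evoked = stim_onsets.size and np.any(
            (stim_onsets <= onset) & (stim_onsets > onset - sensory_running_window)
        )
        provenance.append("stimulus_evoked" if evoked else "spontaneous")
    labelled = RunningEvents(
        events.onsets, events.offsets, events.peak_speeds, provenance
    )

    trials = []
    t, v = speed.times, np.abs(speed.samples)
    for ev in stimuli:
        window = (t >= ev.onset) & (t < ev.onset + sensory_running_window)
        no_run = bool(np.all(v[window] < threshold)) if window.any() else False
        trials.append(
            {"modality": ev.modality, "onset": ev.onset, "duration": ev.duration,
             "no_run": no_run}
        )
    return labelled, trials


def compute_peth(
    spikes: SpikeTrain,
    event_times: np.ndarray,
    window: tuple[float, float] = (-10.0, 10.0),
    bin_width: float = 0.010,
    alignment: str = "running_onset",
) -> Peth:
    """Bin spikes around each event into a trials x bins count matrix.

    `window` = (pre, post) in event-relative seconds (pre typically
    negative).  Bins are half-open [edge, edge + dt).
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no alignment events")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pre, post = window
    n_bins = int(round((post - pre) / bin_width))
    edges = pre + np.arange(n_bins + 1) * bin_width
    counts = np.empty((event_times.size, n_bins), dtype=int)
    for i, t0 in enumerate(event_times):
        rel = spikes.spike_times - t0
        counts[i] = np.histogram(rel, bins=edges)[0]
        # np.histogram closes the last bin on the right; enforce half-open
        if counts[i, -1] and np.any(rel == edges[-1]):
            counts[i, -1] -= int(np.sum(rel == edges[-1]))
    return Peth(bin_edges=edges, counts=counts, alignment=alignment)


def spike_density(
    spikes: SpikeTrain,
    sigma: float = 0.010,
    grid: np.ndarray | None = None,
    grid_step: float = 0.001,
) -> SpikeDensity:
    """Gaussian-kernel spike density function: sum of N(t - t_k; sigma).

    Integrates to the spike count (boundary truncation excepted).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if grid is None:
        grid = np.arange(0.0, spikes.session_duration + grid_step, grid_step)
    grid = np.asarray(grid, dtype=float)
    density = np.zeros(grid.size)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for t_k in spikes.spike_times:
        # Gaussian support truncated at 6 sigma for speed
        lo = np.searchsorted(grid, t_k - 6 * sigma)
        hi = np.searchsorted(grid, t_k + 6 * sigma)
        d = grid[lo:hi] - t_k
        density[lo:hi] += norm * np.exp(-0.5 * (d / sigma) ** 2)
    return SpikeDensity(grid=grid, density=density, sigma=sigma)


def detect_firing_window(
    peth: Peth,
    baseline_period: tuple[float, float] = (-10.0, -5.0),
    sustained: bool = True,
    smooth_sigma: float = 0.1,
) -> FiringWindow:
    """Find the pre-onset window where the PETH exceeds Baseline + 2*SD.

    The trial-mean rate is first smoothed with a Gaussian kernel of
    `smooth_sigma` seconds (0 disables smoothing): at 10 ms bins the
    raw per-bin rate is dominated by Poisson counting noise, and a
    threshold-crossing rule on it would fragment any sustained run.
    Baseline mean and SD are computed over the smoothed bins inside
    `baseline_period`.  With `sustained=True` (default) the window
    starts at the first bin of the final crossing run that persists
    until onset; with `sustained=False` it starts at the first
    crossing bin anywhere in the pre-onset span.
    """
    from scipy.ndimage import gaussian_filter1d

    centers = peth.bin_centers
    rate = peth.mean_rate
    if smooth_sigma > 0:
        rate = gaussian_filter1d(rate, smooth_sigma / peth.bin_width, mode="nearest")
    lo, hi = baseline_period
    base = rate[(centers >= lo) & (centers < hi)]
    if base.size == 0:
        raise ValueError("baseline_period contains no bins")
    mean, sd = float(base.mean()), float(base.std(ddof=0))
    degenerate = sd == 0.0
    threshold = mean + 2.0 * sd

    pre = (centers >= hi) & (centers < 0.0)
    idx = np.flatnonzero(pre)
    if idx.size == 0:
        return FiringWindow(None, 0.0, mean, sd, degenerate)
    crossing = rate[idx] > threshold
    if not crossing.any():
        return FiringWindow(None, 0.0, mean, sd, degenerate)
    if sustained:
        # last run of consecutive crossings must reach the onset bin
        if not crossing[-1]:
            return FiringWindow(None, 0.0, mean, sd, degenerate)
        below = np.flatnonzero(~crossing)
        first = below[-1] + 1 if below.size else 0
    else:
        first = int(np.flatnonzero(crossing)[0])
    start = float(peth.bin_edges[idx[first]])
    return FiringWindow(start, 0.0, mean, sd, degenerate)


def time_difference_stats(windows: list[FiringWindow]) -> dict:
    """Summarise firing-onset lead times and fit a Gaussian to their
    histogram by least squares (as for onset-lead distributions).

    Returns mean/SD of the lead times, the histogram, and (when at
    least 3 distinct values exist) the fitted Gaussian (mu, sigma,
    amplitude) with its R^2.
    """
    diffs = np.array([w.time_difference for w in windows if w.found])
    out: dict = {"n": int(diffs.size), "differences": diffs}
    if diffs.size == 0:
        return out
    out["mean"] = float(diffs.mean())
    out["sd"] = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    n_bins = max(int(np.ceil(np.sqrt(diffs.size))), 5)
    hist, edges = np.histogram(diffs, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out["hist"], out["bin_centers"] = hist, centers
    if diffs.size < 3 or np.unique(diffs).size < 3:
        return out

    def gauss(x, a, mu, s):
        return a * np.exp(-0.5 * ((x - mu) / s) ** 2)

    span = float(edges[-1] - edges[0])
    try:
        p0 = (float(hist.max()), float(out["mean"]), max(float(out["sd"]), 1e-3))
        bounds = ([0.0, edges[0] - span, 1e-6], [np.inf, edges[-1] + span, 10 * span])
        popt, _ = curve_fit(gauss, centers, hist, p0=p0, bounds=bounds, maxfev=10000)
        resid = hist - gauss(centers, *popt)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((hist - hist.mean()) ** 2))
        out["gauss_fit"] = {
            "amplitude": float(popt[0]),
            "mu": float(popt[1]),
            "sigma": float(abs(popt[2])),
            "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        }
    except RuntimeError:
        out["gauss_fit"] = None
    return out


def build_heatmap(
    spikes_list: list[SpikeTrain],
    events_list: list[RunningEvents],
    bin_width: float = 0.1,
    window: tuple[float, float] = (-10.0, 10.0),
    min_pre_quiet: float = 10.0,
    min_peak: float = 0.5,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Population heatmap of min-max-scaled trial-averaged rates.

    For each neuron, spontaneous running events qualify only if no
    other event onset fell within `min_pre_quiet` seconds before the
    onset and the bout's peak speed reached `min_peak`.  Rate per bin
    is count / (N * dt); each surviving row is min-max scaled to
    [0, 1] (constant rows map to 0).  Returns (matrix, kept neuron
    ids, bin centers); neurons with zero qualifying events are
    omitted.
    """
    rows, kept = [], []
    centers = None
    for spikes, events in zip(spikes_list, events_list):
        onsets = events.spontaneous_onsets()
        qualifying = []
        for i, onset in enumerate(onsets):
            prior = onsets[(onsets < onset) & (onsets >= onset - min_pre_quiet)]
            peak = events.peak_speeds[np.searchsorted(events.onsets, onset)] \
                if events.peak_speeds.size else 0.0
            if prior.size == 0 and peak >= min_peak:
                qualifying.append(onset)
        if not qualifying:
            continue
        peth = compute_peth(spikes, np.array(qualifying), window, bin_width)
        rate = peth.mean_rate
        rng_ = rate.max() - rate.min()
        scaled = (rate - rate.min()) / rng_ if rng_ > 0 else np.zeros_like(rate)
        rows.append(scaled)
        kept.append(spikes.neuron_id)
        centers = peth.bin_centers
    matrix = np.vstack(rows) if rows else np.empty((0, 0))
    return matrix, kept, centers if centers is not None else np.empty(0)
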