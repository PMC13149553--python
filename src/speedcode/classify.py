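"""Running-related (R-) neuron classification.

Two-stage criterion: a neuron is first tested for sensory
responsiveness (per-modality Wilcoxon signed-rank on no-run trials,
post-stimulus [0, 1] s vs 1 s pre-stimulus baseline, one-sided
increase); neurons responding to no stimulus are then tested for
running-related activity (pre-running firing vs stationary baseline,
one-sided Wilcoxon).  R-neuron = running-related and not sensory
responsive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .events import (
    FiringWindow,
    RunningEvents,
    compute_peth,
    detect_firing_window,
    detect_running_events,
    label_trials,
)
from .session import Session, SpikeTrain

SENSORY_MODALITIES = ("sound", "light", "air_puff")


@dataclass
class NeuronLabel:
    neuron_id: str
    sensory_p: dict = field(default_factory=dict)       # modality -> p (or None)
    sensory_flags: dict = field(default_factory=dict)   # modality -> bool
    sensory_responsive: bool = False
    running_related: bool = False
    running_p: float | None = None
    is_R_neuron: bool = False
    firing_window: FiringWindow | None = None
    indeterminate: str | None = None                    # reason, if any

    def __post_init__(self) -> None:
        if self.is_R_neuron and (self.sensory_responsive or not self.running_related):
            raise ValueError("is_R_neuron requires running-related and non-sensory")


def _count_in_window(spikes: SpikeTrain, t0: float, lo: float, hi: float) -> float:
    """Firing rate (spikes/s) of one trial window [t0+lo, t0+hi)."""
    t = spikes.spike_times
    n = np.sum((t >= t0 + lo) & (t < t0 + hi))
    return float(n) / (hi - lo)


def _wilcoxon_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided signed-rank p for median(x - y) > 0; 1.0 if all ties."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(x, y, alternative="greater", zero_method="wilcox").pvalue)


def sensory_response_test(
    post_rates: np.ndarray,
    baseline_rates: np.ndarray,
    alpha: float = 0.05,
    min_trials: int = 5,
) -> tuple[bool, float | None]:
    """Test for a firing increase after stimulus onset.

    `post_rates` and `baseline_rates` are paired per-trial firing
    rates over [0, 1] s post-stimulus and the 1 s pre-stimulus
    baseline, restricted to no-run trials.  Returns (flag, p); with
    fewer than `min_trials` pairs the result is indeterminate (None).
    """
    post_rates = np.asarray(post_rates, dtype=float)
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    if post_rates.size != baseline_rates.size:
        raise ValueError("post and baseline must be paired")
    if post_rates.size < min_trials:
        return False, None
    p = _wilcoxon_greater(post_rates, baseline_rates)
    return p < alpha, p


def running_related_test(
    pre_running_rates: np.ndarray,
    baseline_rates: np.ndarray,
    alpha: float = 0.05,
    min_trials: int = 5,
) -> tuple[bool, float | None]:
    """Test whether pre-running firing exceeds the stationary baseline.

    Paired per-trial rates; one-sided Wilcoxon signed-rank at `alpha`.
    Fewer than `min_trials` spontaneous runs -> indeterminate (None).
    """
    pre_running_rates = np.asarray(pre_running_rates, dtype=float)
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    if pre_running_rates.size != baseline_rates.size:
        raise ValueError("samples must be paired per trial")
    if pre_running_rates.size < min_trials:
        return False, None
    p = _wilcoxon_greater(pre_running_rates, baseline_rates)
    return p < alpha, p


def classify_neuron(
    session: Session,
    neuron_id: str,
    config: AnalysisConfig | None = None,
    events: RunningEvents | None = None,
    stimulus_trials: list[dict] | None = None,
    default_window: tuple[float, float] = (-3.0, 0.0),
) -> NeuronLabel:
    """Apply the two-stage classification to one neuron.

    Stage 1: per-modality sensory tests on no-run trials.  Stage 2
    (only for non-sensory neurons): pre-running vs stationary-baseline
    test over spontaneous runs; the pre-running sample is taken over
    the neuron's own firing-running window when one is detected, else
    over `default_window`.  The detected firing window is attached.
    """
    config = config or AnalysisConfig()
    spikes = session.neuron(neuron_id)

    if events is None or stimulus_trials is None:
        raw = detect_running_events(
            session.speed, config.run_threshold, config.min_gap, config.min_duration
        )
        events, stimulus_trials = label_trials(
            raw, session.stimuli, session.speed,
            config.sensory_running_window, config.run_threshold,
        )

    label = NeuronLabel(neuron_id=neuron_id)

    # ---- stage 1: sensory responsiveness on no-run trials
    for modality in SENSORY_MODALITIES:
        onsets = [
            tr["onset"] for tr in stimulus_trials
            if tr["modality"] == modality and tr["no_run"]
        ]
        post = np.array([_count_in_window(spikes, t, 0.0, 1.0) for t in onsets])
        base = np.array([_count_in_window(spikes, t, -1.0, 0.0) for t in onsets])
        flag, p = sensory_response_test(post, base, config.alpha, config.min_trials)
        label.sensory_flags[modality] = flag
        label.sensory_p[modality] = p
    label.sensory_responsive = any(label.sensory_flags.values())
    if label.sensory_responsive:
        return label

    # ---- stage 2: running-related activity on spontaneous runs
    onsets = events.spontaneous_onsets()
    if onsets.size < config.min_trials:
        label.indeterminate = "insufficient spontaneous running events"
        return label

    peth = compute_peth(
        spikes, onsets, window=(config.baseline_period[0], 1.0),
        bin_width=config.psth_bin,
    )
    window = detect_firing_window(
        peth, config.baseline_period, config.firing_window_sustained,
        smooth_sigma=config.window_smooth_sigma,
    )
    label.firing_window = window
    pre_lo, pre_hi = (window.start, 0.0) if window.found else default_window
    base_lo, base_hi = config.baseline_period
    pre = np.array([_count_in_window(spikes, t, pre_lo, pre_hi) for t in onsets])
    base = np.array([_count_in_window(spikes, t, base_lo, base_hi) for t in onsets])
    flag, p = running_related_test(pre, base, config.alpha, config.min_trials)
    label.running_related = flag
    label.running_p = p
    label.is_R_neuron = flag and not label.sensory_responsive
    return label
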