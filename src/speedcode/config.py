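"""Analysis configuration: the fixed constants of the pipeline.

Every analysis stage reads its tunables from :class:`AnalysisConfig`
so that a session can be re-analysed reproducibly from a single
structured-text (YAML) document plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Constants governing event detection, binning, CCF and fitting.

    Parameters
    ----------
    run_threshold : float
        Speed threshold (cm/s) defining running onset; a bout begins at
        the first sample whose |speed| exceeds this value.
    psth_bin : float
        Bin width (s) for stimulus/running-onset aligned histograms.
    heatmap_bin : float
        Bin width (s) for population heatmap rate maps.
    sdf_sigma : float
        Gaussian kernel sigma (s) for spike-density functions.
    ccf_lag_max : float
        Half-range (s) of the cross-correlation lag grid [-lag_max, lag_max].
    ccf_bin : float
        Bin width (s) used when binning rate and speed for the CCF.
    n_permutations : int
        Number of circular shifts in the permutation null.
    alpha : float
        Significance level for the classification tests.
    sensory_running_window : float
        Window (s) used to label trials: a running onset is spontaneous
        iff no stimulus onset fell within this window before it, and a
        stimulus trial is "no-run" iff speed stays below threshold for
        this long after onset.
    min_gap : float
        Sub-threshold gap (s) below which two bouts are merged.
    min_duration : float
        Bouts shorter than this (s) are discarded.
    baseline_period : tuple
        Interval (s, relative to running onset) used as the stationary
        baseline of the peri-event histogram.
    firing_window_sustained : bool
        If True the Baseline + 2*SD crossing must be sustained until
        onset; if False a single crossing bin starts the window.
    window_smooth_sigma : float
        Gaussian smoothing (s) applied to the PETH mean rate before
        the threshold-crossing scan (0 disables).
    resample_rate : float
        Common grid (Hz) that speed traces are linearly resampled to.
    min_trials : int
        Minimum paired trials required by each Wilcoxon test.
    plateau_tol : float
        Tolerance (r units) defining the CCF peak plateau.
    rng_seed : int
        Seed for every stochastic step (permutations, simulation).
    """

    run_threshold: float = 0.5
    psth_bin: float = 0.010
    heatmap_bin: float = 0.1
    sdf_sigma: float = 0.010
    ccf_lag_max: float = 10.0
    ccf_bin: float = 0.1
    n_permutations: int = 1000
    alpha: float = 0.05
    sensory_running_window: float = 3.0
    min_gap: float = 0.5
    min_duration: float = 0.5
    baseline_period: tuple[float, float] = (-10.0, -5.0)
    firing_window_sustained: bool = True
    window_smooth_sigma: float = 0.1
    resample_rate: float = 100.0
    min_trials: int = 5
    plateau_tol: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "run_threshold", "psth_bin", "heatmap_bin", "sdf_sigma",
            "ccf_lag_max", "ccf_bin", "sensory_running_window",
            "min_gap", "min_duration", "resample_rate",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if isinstance(self.baseline_period, list):
            self.baseline_period = tuple(self.baseline_period)
        lo, hi = self.baseline_period
        if not lo < hi <= 0:
            raise ValueError("baseline_period must satisfy lo < hi <= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config, filling unset fields with defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["baseline_period"] = list(self.baseline_period)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["baseline_period"] = list(self.baseline_period)
        return data
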