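"""Core data model for recording sessions plus text readers/writers.

A session bundles spike trains (loose-patch single-unit recordings),
a signed speed trace (positive = forward running, negative = backing
away) and a stimulus schedule.  All on-disk formats are plain TSV/JSON
so that sessions round-trip losslessly through text.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import AnalysisConfig

MODALITIES = ("sound", "light", "air_puff", "opto")
REGIONS = ("TeA", "dPAG", "SC", "other")


@dataclass
class SpikeTrain:
    """Sorted spike times for one neuron over one session.

    Times are session-relative seconds; they must be strictly
    increasing, finite and lie in [0, session_duration].
    """

    neuron_id: str
    spike_times: np.ndarray
    session_duration: float
    region: str = "other"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        t = self.spike_times
        if t.size:
            if not np.all(np.isfinite(t)):
                raise ValueError(f"neuron {self.neuron_id}: non-finite spike time")
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"neuron {self.neuron_id}: spike times not strictly increasing"
                )
            if t[0] < 0 or t[-1] > self.session_duration:
                raise ValueError(
                    f"neuron {self.neuron_id}: spike times outside "
                    f"[0, {self.session_duration}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.session_duration


@dataclass
class SpeedTrace:
    """Uniformly sampled signed locomotion speed (cm/s)."""

    sampling_rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("speed trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def resample(self, rate: float) -> "SpeedTrace":
        """Linear resampling onto a uniform grid at `rate` Hz."""
        if abs(rate - self.sampling_rate) <= 1e-6 * rate:
            return self
        new_t = np.arange(self.t0, self.t0 + self.duration, 1.0 / rate)
        new_s = np.interp(new_t, self.times, self.samples)
        return SpeedTrace(sampling_rate=rate, samples=new_s, t0=self.t0)

    def speed_at(self, t: np.ndarray) -> np.ndarray:
        """Signed speed linearly interpolated at arbitrary times."""
        return np.interp(t, self.times, self.samples)


@dataclass
class StimulusEvent:
    modality: str
    onset: float
    duration: float
    opto_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        has_freq = self.opto_frequency is not None
        if (self.modality == "opto") != has_freq:
            raise ValueError("opto_frequency present iff modality == 'opto'")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class StimulusSchedule:
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_modality(self, modality: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.modality == modality]


@dataclass
class Session:
    """One recording session: spike trains + speed + stimuli."""

    spike_trains: list[SpikeTrain]
    speed: SpeedTrace
    stimuli: StimulusSchedule = field(default_factory=StimulusSchedule)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dur = self.speed.t0 + self.speed.duration
        for st in self.spike_trains:
            # spike-train durations must be consistent with the trace
            if abs(st.session_duration - dur) > 1.0 / self.speed.sampling_rate + 1e-9:
                raise ValueError(
                    f"neuron {st.neuron_id}: session_duration {st.session_duration} "
                    f"inconsistent with speed trace span {dur}"
                )

    @property
    def duration(self) -> float:
        return self.speed.t0 + self.speed.duration

    @property
    def neuron_ids(self) -> list[str]:
        return [st.neuron_id for st in self.spike_trains]

    def neuron(self, neuron_id: str) -> SpikeTrain:
        for st in self.spike_trains:
            if st.neuron_id == neuron_id:
                return st
        raise KeyError(neuron_id)


# ---------------------------------------------------------------------------
# TSV readers / writers


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ValueError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _parse_float(value: str, path: Path, row: int, col: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(
            f"{path}: line {row + 2}: column {col!r} not numeric: {value!r}"
        ) from None


def read_session(
    spike_path: str | Path,
    speed_path: str | Path,
    stimulus_path: str | Path | None = None,
    config: AnalysisConfig | None = None,
    neuron_ids: list[str] | None = None,
    regions: dict[str, str] | None = None,
) -> Session:
    """Read a session from its three TSV files and validate it.

    Spike file columns: neuron_id, spike_time_s.  Speed file: time_s,
    speed_cm_s (uniform timestamps).  Stimulus file: modality, onset_s,
    duration_s, opto_freq_hz (empty allowed for non-opto rows).

    `neuron_ids` may list neurons that must appear even with zero
    spikes.  The speed trace is resampled to ``config.resample_rate``.
    """
    config = config or AnalysisConfig()
    spike_path, speed_path = Path(spike_path), Path(speed_path)

    speed_df = _read_tsv(speed_path, ["time_s", "speed_cm_s"])
    t = np.array(
        [_parse_float(v, speed_path, i, "time_s") for i, v in enumerate(speed_df["time_s"])]
    )
    s = np.array(
        [_parse_float(v, speed_path, i, "speed_cm_s") for i, v in enumerate(speed_df["speed_cm_s"])]
    )
    if t.size < 2:
        raise ValueError(f"{speed_path}: need at least 2 speed samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6 + 1e-4 * dt[0]):
        raise ValueError(f"{speed_path}: non-uniform speed timestamps")
    trace = SpeedTrace(sampling_rate=1.0 / dt[0], samples=s, t0=float(t[0]))
    trace = trace.resample(config.resample_rate)
    duration = trace.t0 + trace.duration

    spikes_df = _read_tsv(spike_path, ["neuron_id", "spike_time_s"])
    by_neuron: dict[str, list[float]] = {}
    for nid in neuron_ids or []:
        by_neuron[nid] = []
    for i, (nid, st) in enumerate(zip(spikes_df["neuron_id"], spikes_df["spike_time_s"])):
        by_neuron.setdefault(nid, []).append(_parse_float(st, spike_path, i, "spike_time_s"))
    regions = regions or {}
    trains = []
    for nid, times in by_neuron.items():
        arr = np.asarray(times, dtype=float)
        if arr.size and np.any(np.diff(arr) <= 0):
            raise ValueError(
                f"{spike_path}: neuron {nid}: spike times not strictly increasing"
            )
        trains.append(
            SpikeTrain(
                neuron_id=nid,
                spike_times=arr,
                session_duration=duration,
                region=regions.get(nid, "other"),
            )
        )

    schedule = StimulusSchedule()
    if stimulus_path is not None:
        stimulus_path = Path(stimulus_path)
        stim_df = _read_tsv(stimulus_path, ["modality", "onset_s", "duration_s", "opto_freq_hz"])
        events = []
        for i, row in stim_df.iterrows():
            freq = row["opto_freq_hz"].strip()
            events.append(
                StimulusEvent(
                    modality=row["modality"],
                    onset=_parse_float(row["onset_s"], stimulus_path, i, "onset_s"),
                    duration=_parse_float(row["duration_s"], stimulus_path, i, "duration_s"),
                    opto_frequency=(
                        _parse_float(freq, stimulus_path, i, "opto_freq_hz") if freq else None
                    ),
                )
            )
        schedule = StimulusSchedule(events=events)

    return Session(spike_trains=trains, speed=trace, stimuli=schedule)


def write_session(session: Session, directory: str | Path, prefix: str = "session") -> dict[str, Path]:
    """Write a session as the three TSVs; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "spikes": directory / f"{prefix}_spikes.tsv",
        "speed": directory / f"{prefix}_speed.tsv",
        "stimuli": directory / f"{prefix}_stimuli.tsv",
    }
    rows = [
        {"neuron_id": st.neuron_id, "spike_time_s": f"{t:.6f}"}
        for st in session.spike_trains
        for t in st.spike_times
    ]
    pd.DataFrame(rows, columns=["neuron_id", "spike_time_s"]).to_csv(
        paths["spikes"], sep="\t", index=False
    )
    pd.DataFrame(
        {
            "time_s": [f"{t:.6f}" for t in session.speed.times],
            "speed_cm_s": [f"{v:.6f}" for v in session.speed.samples],
        }
    ).to_csv(paths["speed"], sep="\t", index=False)
    stim_rows = [
        {
            "modality": e.modality,
            "onset_s": f"{e.onset:.6f}",
            "duration_s": f"{e.duration:.6f}",
            "opto_freq_hz": "" if e.opto_frequency is None else f"{e.opto_frequency:g}",
        }
        for e in session.stimuli
    ]
    pd.DataFrame(stim_rows, columns=["modality", "onset_s", "duration_s", "opto_freq_hz"]).to_csv(
        paths["stimuli"], sep="\t", index=False
    )
    return paths


# ---------------------------------------------------------------------------
# Results serialization (JSON with numpy coercion)


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__type__": type(obj).__name__, **_jsonify(dataclasses.asdict(obj))}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_results(
    results: Any,
    path: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write any pipeline output as structured JSON text.

    The file embeds a snapshot of the analysis configuration and the
    seed so the run is reconstructible from the artifact alone.
    """
    payload = {
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "results": _jsonify(results),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_results(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
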