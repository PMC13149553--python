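"""End-to-end per-session analysis driver.

Runs event detection and trial labelling once per session, then for
each neuron: two-stage classification, CCF with permutation test, and
(for R-neurons) the lag-aligned single-phase encoding fit with its
linear comparison.  The result is a plain dict per neuron, suitable
for JSON serialization via :func:`speedcode.session.write_results`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ccf import bin_rate_and_speed, ccf_analysis
from .classify import classify_neuron
from .config import AnalysisConfig
from .encoding import align_by_lag, fit_linear_and_compare, fit_single_phase_inverse
from .events import detect_running_events, label_trials
from .session import Session


def run_pipeline(session: Session, config: AnalysisConfig | None = None) -> dict:
    """Analyse every neuron of a session; pure function of
    (session, config) including the config seed."""
    config = config or AnalysisConfig()
    raw = detect_running_events(
        session.speed, config.run_threshold, config.min_gap, config.min_duration
    )
    events, stim_trials = label_trials(
        raw, session.stimuli, session.speed,
        config.sensory_running_window, config.run_threshold,
    )
    n_spont = int(events.spontaneous_onsets().size)

    neurons: dict[str, dict] = {}
    for i, train in enumerate(session.spike_trains):
        nid = train.neuron_id
        report: dict = {"neuron_id": nid, "region": train.region,
                        "n_spikes": train.n_spikes}
        if n_spont == 0:
            report["status"] = "insufficient running events"
            neurons[nid] = report
            continue
        try:
            label = classify_neuron(
                session, nid, config, events=events, stimulus_trials=stim_trials
            )
            report["label"] = _label_dict(label)

            ccf = ccf_analysis(
                train, session.speed,
                bin_width=config.ccf_bin, lag_max=config.ccf_lag_max,
                n_perm=config.n_permutations,
                seed=config.rng_seed + 7919 * i,
                plateau_tol=config.plateau_tol,
            )
            report["ccf"] = {
                "r_max": ccf.r_max, "lag_star": ccf.lag_star,
                "plateau": list(ccf.plateau), "fwhm": ccf.fwhm,
                "p_perm": ccf.p_perm, "significant": ccf.significant,
            }

            if label.is_R_neuron:
                firing, speed = bin_rate_and_speed(
                    train, session.speed, config.ccf_bin, config.ccf_lag_max
                )
                f, v = align_by_lag(firing, speed, ccf.lag_star, config.ccf_bin)
                # inverse regression: speed is (nearly) noise-free,
                # binned firing rates carry the counting noise
                fit = fit_single_phase_inverse(v, f, seed=config.rng_seed)
                comparison = fit_linear_and_compare(f, v, fit)
                report["encoding_fit"] = dataclasses.asdict(fit)
                report["linear_fit"] = dataclasses.asdict(comparison["linear"])
                report["delta_r_squared"] = comparison["delta_r_squared"]
            report["status"] = "ok"
        except Exception as exc:
            raise RuntimeError(f"neuron {nid}: {exc}") from exc
        neurons[nid] = report

    return {
        "n_neurons": len(session.spike_trains),
        "n_running_events": len(events),
        "n_spontaneous_runs": n_spont,
        "n_stimulus_trials": len(stim_trials),
        "neurons": neurons,
    }


def _label_dict(label) -> dict:
    d = {
        "sensory_responsive": label.sensory_responsive,
        "sensory_flags": dict(label.sensory_flags),
        "sensory_p": dict(label.sensory_p),
        "running_related": label.running_related,
        "running_p": label.running_p,
        "is_R_neuron": label.is_R_neuron,
        "indeterminate": label.indeterminate,
    }
    w = label.firing_window
    if w is not None:
        d["firing_window"] = {
            "start": w.start, "end": w.end,
            "baseline_mean": w.baseline_mean, "baseline_sd": w.baseline_sd,
        }
    return d


def classification_performance(report: dict, truth) -> dict:
    """Confusion counts for R-neuron detection against ground truth.

    `truth` is the generator's label table (neuron_id, class).
    """
    tp = fp = tn = fn = 0
    for _, row in truth.iterrows():
        rep = report["neurons"].get(row["neuron_id"])
        if rep is None:
            raise KeyError(f"neuron {row['neuron_id']} missing from report")
        pred = bool(rep.get("label", {}).get("is_R_neuron", False))
        actual = row["class"] == "R"
        if actual and pred:
            tp += 1
        elif actual:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": sens, "specificity": spec}
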