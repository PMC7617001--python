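"""File formats: waveform CSV, TOML configuration, bank and session files.

Waveforms are stored as two-column CSV ``(time_us, value)`` with a one-line
header naming the kind and units; the values are printed with full float64
precision so a write/read cycle is bit-exact.  Device and modulation
parameters live in a TOML file with ``[magstim]`` and ``[ptms]`` sections;
neuron banks in a TOML file with one ``[[neuron]]`` table per entry.
Sessions are a pair of CSVs: one row per trial plus a long-format trace
table, both read back with pandas.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .neurons import NeuronBank, NeuronModel, ThresholdComparison
from .study import EMGTrace, TrialRecord
from .waveforms import DeviceConfig, PWMConfig, SampledWaveform

__all__ = [
    "waveform_to_csv",
    "waveform_from_csv",
    "load_device_configs",
    "save_device_configs",
    "bank_to_toml",
    "bank_from_toml",
    "session_to_csv",
    "session_from_csv",
    "threshold_comparison_to_json",
]

_UNITS = {"voltage": "V", "current": "A", "didt": "A_per_us"}


def waveform_to_csv(wave: SampledWaveform, path: str | Path) -> None:
    """Write a waveform as ``time_us,<kind>_<units>`` CSV (bit-exact)."""
    header = f"time_us,{wave.kind}_{_UNITS[wave.kind]}"
    data = np.column_stack([wave.times(), wave.samples])
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header=header, comments="")


def waveform_from_csv(path: str | Path, label: str | None = None) -> SampledWaveform:
    """Read a waveform written by :func:`waveform_to_csv`."""
    with open(path) as fh:
        header = fh.readline().strip()
    kind = header.split(",")[1].split("_")[0]
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, samples = data[:, 0], data[:, 1]
    return SampledWaveform(
        dt=float(t[1]),
        samples=samples,
        kind=kind,
        label=label if label is not None else Path(path).stem,
    )


def load_device_configs(path: str | Path) -> tuple[DeviceConfig, PWMConfig]:
    """Read ``[magstim]`` and ``[ptms]`` sections of a TOML config file."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return DeviceConfig(**doc.get("magstim", {})), PWMConfig(**doc.get("ptms", {}))


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(v)


def save_device_configs(
    device: DeviceConfig, pwm: PWMConfig, path: str | Path
) -> None:
    """Write the device/modulation configuration as TOML.

    Units: capacitance µF, inductance µH, resistances Ω, voltages V,
    switching_frequency kHz, pulse_duration µs.
    """
    lines = ["[magstim]"]
    lines += [f"{k} = {_toml_value(v)}" for k, v in asdict(device).items()]
    lines += ["", "[ptms]"]
    lines += [
        f"{k} = {_toml_value(v)}"
        for k, v in asdict(pwm).items()
        if v is not None
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def bank_to_toml(bank: NeuronBank, path: str | Path) -> None:
    """Serialize a neuron bank as TOML with one ``[[neuron]]`` table each."""
    lines = [f"seed = {bank.seed}", ""]
    for n in bank.neurons:
        lines += [
            "[[neuron]]",
            f'layer = "{n.layer}"',
            f"clone_id = {n.clone_id}",
            f"membrane_time_constant = {n.membrane_time_constant!r}",
            f"polarity_gain = [{n.polarity_gain[0]!r}, {n.polarity_gain[1]!r}]",
            f"base_threshold = {n.base_threshold!r}",
            "",
        ]
    Path(path).write_text("\n".join(lines))


def bank_from_toml(path: str | Path) -> NeuronBank:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    neurons = [
        NeuronModel(
            layer=e["layer"],
            clone_id=e["clone_id"],
            membrane_time_constant=e["membrane_time_constant"],
            polarity_gain=tuple(e["polarity_gain"]),
            base_threshold=e["base_threshold"],
        )
        for e in doc["neuron"]
    ]
    return NeuronBank(neurons=neurons, seed=doc.get("seed", 0))


def session_to_csv(
    trials: list[TrialRecord], trials_path: str | Path, traces_path: str | Path
) -> None:
    """Write one session: a trial table and a long-format trace table."""
    rows = [
        {
            "trial_id": k,
            "participant": t.participant,
            "device": t.device,
            "intensity": t.intensity,
            "interval": t.interval,
        }
        for k, t in enumerate(trials)
    ]
    pd.DataFrame(rows).to_csv(trials_path, index=False)
    frames = []
    for k, t in enumerate(trials):
        fs = t.trace.sampling_rate
        time_ms = (np.arange(t.trace.samples.size) - t.trace.stimulus_index) / fs * 1e3
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": k,
                    "time_ms": time_ms,
                    "amplitude_uv": t.trace.samples,
                    "sampling_rate": fs,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(traces_path, index=False,
                                                float_format="%.17g")


def session_from_csv(
    trials_path: str | Path, traces_path: str | Path
) -> list[TrialRecord]:
    """Read a session written by :func:`session_to_csv`."""
    meta = pd.read_csv(trials_path)
    traces = pd.read_csv(traces_path, float_precision="round_trip")
    out: list[TrialRecord] = []
    for _, row in meta.iterrows():
        g = traces[traces["trial_id"] == row["trial_id"]]
        fs = float(g["sampling_rate"].iloc[0])
        stim = int(np.sum(g["time_ms"].to_numpy() < 0))
        trace = EMGTrace(
            sampling_rate=fs,
            samples=g["amplitude_uv"].to_numpy(),
            stimulus_index=stim,
        )
        out.append(
            TrialRecord(
                participant=int(row["participant"]),
                device=str(row["device"]),
                intensity=float(row["intensity"]),
                trace=trace,
                interval=float(row["interval"]),
            )
        )
    return out


def threshold_comparison_to_json(tc: ThresholdComparison, path: str | Path) -> None:
    """Write per-neuron thresholds and the comparison summary as JSON."""
    doc = {
        "neurons": [
            {
                "id": uid,
                "threshold_magstim_A_per_us": float(tm),
                "threshold_ptms_A_per_us": float(tp),
                "percent_difference": float(pd_),
            }
            for uid, tm, tp, pd_ in zip(
                tc.neuron_ids, tc.thresholds_magstim, tc.thresholds_ptms,
                tc.percent_difference,
            )
        ],
        "layer_median_percent_difference": tc.layer_median_difference,
        "regression": {
            "slope": tc.slope,
            "intercept": tc.intercept,
            "r_squared": tc.r_squared,
        },
        "n_excluded": tc.n_excluded,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
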