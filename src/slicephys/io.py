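"""Plain-text file dialects: documented CSV data files with JSON sidecars.

Recordings: CSV with a time column (s) and one voltage column (mV) per
channel (ch01..chNN), plus a JSON sidecar carrying sampling rate, the
channel->region map, the design labels and the seed. Destaining traces: CSV
with time plus one column per bouton, JSON sidecar with stimulus onsets and
the background value. Spike events and kinetics tables are flat CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fm_kinetics import DestainTrace
from .recording import RawRecording
from .signal_processing import SpikeEvent, events_to_frame

__all__ = [
    "write_recording",
    "read_recording",
    "write_spikes",
    "read_spikes",
    "write_destain_traces",
    "read_destain_traces",
    "write_ground_truth",
]


def write_recording(recording: RawRecording, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    t = np.arange(recording.n_samples) / recording.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for i, name in enumerate(recording.channel_names):
        df[name] = recording.samples[i]
    df.to_csv(csv_path, index=False, float_format="%.6g")
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate,
        "regions": {name: r for name, r in zip(recording.channel_names,
                                               recording.regions)},
        "genotype": recording.genotype,
        "animal_id": recording.animal_id,
        "slice_id": recording.slice_id,
        "condition": recording.condition,
        "n_traces": recording.n_traces,
        "trace_duration_s": recording.trace_duration,
        "filtered": recording.filtered,
        "seed": recording.meta.get("seed"),
    }
    meta_path = csv_path.with_suffix(".json")
    meta_path.write_text(json.dumps(sidecar, indent=1))
    return meta_path


def read_recording(csv_path: str | Path,
                   meta_path: str | Path | None = None) -> RawRecording:
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(csv_path)
    channels = [c for c in df.columns if c != "time_s"]
    samples = df[channels].to_numpy(dtype=np.float32).T
    regions = [meta["regions"][c] for c in channels]
    return RawRecording(
        samples=samples,
        sampling_rate=float(meta["sampling_rate_hz"]),
        regions=regions,
        genotype=meta.get("genotype", "wt"),
        animal_id=meta.get("animal_id", "a0"),
        slice_id=meta.get("slice_id", "a0s0"),
        condition=meta.get("condition", "normal"),
        n_traces=int(meta.get("n_traces", 600)),
        trace_duration=float(meta.get("trace_duration_s", 1.0)),
        filtered=bool(meta.get("filtered", False)),
        meta={"seed": meta.get("seed")},
    )


def write_spikes(events: Sequence[SpikeEvent], path: str | Path) -> Path:
    path = Path(path)
    events_to_frame(events).to_csv(path, index=False)
    return path


def read_spikes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_destain_traces(traces: Sequence[DestainTrace], csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    if not traces:
        raise ValueError("no traces to write")
    df = pd.DataFrame({"time_s": traces[0].time})
    for tr in traces:
        df[tr.bouton_id] = tr.fluorescence
    df.to_csv(csv_path, index=False, float_format="%.6g")
    sidecar = {
        "stimulus_onsets_s": list(traces[0].stimulus_onsets),
        "background": {tr.bouton_id: tr.background for tr in traces},
        "group": {tr.bouton_id: tr.group for tr in traces},
    }
    meta_path = csv_path.with_suffix(".json")
    meta_path.write_text(json.dumps(sidecar, indent=1))
    return meta_path


def read_destain_traces(csv_path: str | Path,
                        meta_path: str | Path | None = None) -> list[DestainTrace]:
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(csv_path)
    t = df["time_s"].to_numpy()
    out = []
    for col in df.columns:
        if col == "time_s":
            continue
        out.append(
            DestainTrace(
                bouton_id=col,
                time=t.copy(),
                fluorescence=df[col].to_numpy(),
                background=float(meta["background"][col]),
                stimulus_onsets=list(meta["stimulus_onsets_s"]),
                group=meta.get("group", {}).get(col, "wt"),
            )
        )
    return out


def write_ground_truth(truth, path: str | Path) -> Path:
    """Serialize a GroundTruth (or RecordingTruth) to JSON."""
    path = Path(path)

    def _rt(rt) -> dict:
        return {
            "recording_id": rt.recording_id,
            "genotype": rt.genotype,
            "animal_id": rt.animal_id,
            "slice_id": rt.slice_id,
            "condition": rt.condition,
            "rate_multiplier": rt.rate_multiplier,
            "expected_counts": [float(c) for c in rt.expected_counts],
            "spike_times": [list(map(float, t)) for t in rt.spike_times],
        }

    if hasattr(truth, "recordings"):
        payload = {rid: _rt(rt) for rid, rt in truth.recordings.items()}
    else:
        payload = {truth.recording_id: _rt(truth)}
    path.write_text(json.dumps(payload))
    return path
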