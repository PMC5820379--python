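"""Per-channel network-activity variables and their aggregates.

Five variables are computed per channel and condition: amplitude (+),
amplitude (-), inter-spike interval, frequency, and *active frequency* — the
spike count divided by the duration of the traces in which the channel was
active rather than the duration of the whole recording. The recording's
native segmentation into one-second traces defines "activity": a trace is
active when it contains at least one event, so

    frequency        = N / (n_traces * trace_duration)
    active_frequency = N / (active_traces * trace_duration)

and active_frequency >= frequency always, with equality exactly when every
trace is active. Inter-spike intervals are computed between consecutive
events within the same trace only (traces are separate acquisitions).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_processing import SpikeEvent

__all__ = [
    "ChannelStats",
    "channel_statistics",
    "stats_from_times",
    "cohort_statistics",
    "region_aggregate",
    "condition_delta",
    "STAT_VARIABLES",
]

STAT_VARIABLES = (
    "frequency",
    "mean_isi",
    "active_frequency",
    "mean_amp_pos",
    "mean_amp_neg",
)


@dataclass
class ChannelStats:
    channel: int
    region: str
    condition: str
    n_spikes: int
    frequency: float
    mean_isi: float | None
    active_traces: int
    active_frequency: float | None
    mean_amp_pos: float | None
    mean_amp_neg: float | None

    def as_row(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        for k, v in d.items():
            if v is None:
                d[k] = np.nan
        return d


def stats_from_times(
    times: np.ndarray,
    n_traces: int,
    trace_duration: float,
    channel: int = 0,
    region: str = "other",
    condition: str = "normal",
    amp_pos: np.ndarray | None = None,
    amp_neg: np.ndarray | None = None,
) -> ChannelStats:
    """Compute the five variables from raw spike times for one channel.

    ``amp_pos`` / ``amp_neg`` are optional per-event amplitude arrays (NaN for
    events lacking that polarity); amplitude means are taken over the events
    possessing each polarity.
    """
    times = np.sort(np.asarray(times, dtype=float))
    total = n_traces * trace_duration
    if times.size and (times[0] < 0 or times[-1] >= total):
        raise ValueError("spike times must lie within the recording")
    n = times.size
    freq = n / total
    tracks = np.floor(times / trace_duration).astype(int)
    active = int(np.unique(tracks).size)
    if n == 0:
        af = None
    else:
        af = n / (active * trace_duration)
    if n >= 2:
        same = np.diff(tracks) == 0
        isis = np.diff(times)[same]
        mean_isi = float(isis.mean()) if isis.size else None
    else:
        mean_isi = None
    map_ = None
    man = None
    if amp_pos is not None:
        a = np.asarray(amp_pos, dtype=float)
        a = a[np.isfinite(a)]
        map_ = float(a.mean()) if a.size else None
    if amp_neg is not None:
        a = np.asarray(amp_neg, dtype=float)
        a = a[np.isfinite(a)]
        man = float(a.mean()) if a.size else None
    return ChannelStats(
        channel=channel,
        region=region,
        condition=condition,
        n_spikes=n,
        frequency=freq,
        mean_isi=mean_isi,
        active_traces=active,
        active_frequency=af,
        mean_amp_pos=map_,
        mean_amp_neg=man,
    )


def channel_statistics(
    events: Sequence[SpikeEvent],
    n_traces: int,
    trace_duration: float,
    condition: str = "normal",
) -> ChannelStats:
    """Five-variable summary for the events of a single channel/condition."""
    channels = {e.channel for e in events}
    if len(channels) > 1:
        raise ValueError(f"events from mixed channels: {sorted(channels)}")
    ch = channels.pop() if channels else 0
    region = events[0].region if events else "other"
    times = np.array([e.time for e in events])
    ap = np.array([np.nan if e.amp_pos is None else e.amp_pos for e in events])
    an = np.array([np.nan if e.amp_neg is None else e.amp_neg for e in events])
    return stats_from_times(
        times, n_traces, trace_duration, ch, region, condition, ap, an
    )


def cohort_statistics(
    events: Sequence[SpikeEvent],
    n_channels: int,
    regions: Sequence[str],
    n_traces: int,
    trace_duration: float,
    condition: str = "normal",
) -> pd.DataFrame:
    """Per-channel stats for every channel (zero-spike channels included)."""
    by_ch: dict[int, list[SpikeEvent]] = {c: [] for c in range(n_channels)}
    for e in events:
        by_ch[e.channel].append(e)
    rows = []
    for ch in range(n_channels):
        st = channel_statistics(by_ch[ch], n_traces, trace_duration, condition)
        st.channel = ch
        st.region = regions[ch]
        rows.append(st.as_row())
    return pd.DataFrame(rows)


def region_aggregate(
    stats: pd.DataFrame, regions: Mapping[int, str] | None = None
) -> pd.DataFrame:
    """Pooled per-region summaries plus a "total" pool of all channels.

    The "total" row pools every channel; it is not the mean of region means.
    Channels with an absent (NaN) value are excluded from that variable's
    summary, with the contributing count reported.
    """
    df = stats.copy()
    if regions is not None:
        unmapped = set(df["channel"]) - set(regions)
        if unmapped:
            raise ValueError(f"channels without a region: {sorted(unmapped)}")
        df["region"] = df["channel"].map(regions)
    if df["region"].isna().any():
        raise ValueError("every channel must be mapped to a region")
    rows = []
    groups = [(r, sub) for r, sub in df.groupby("region")] + [("total", df)]
    for region, sub in groups:
        row = {"region": region, "n_channels": len(sub)}
        for var in STAT_VARIABLES:
            vals = sub[var].dropna()
            row[f"{var}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{var}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{var}_n"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def condition_delta(
    stats_normal: pd.DataFrame, stats_highk: pd.DataFrame
) -> pd.DataFrame:
    """Per-channel (high K+) - (normal) differences for every variable.

    A delta is absent (NaN) whenever either side is absent; such entries are
    marked in the companion ``*_missing`` flag column.
    """
    a = stats_normal.set_index("channel")
    b = stats_highk.set_index("channel")
    if set(a.index) != set(b.index):
        raise ValueError("channel sets differ between conditions")
    b = b.loc[a.index]
    out = pd.DataFrame({"channel": a.index, "region": a["region"].values})
    for var in STAT_VARIABLES:
        delta = b[var].values - a[var].values
        out[f"delta_{var}"] = delta
        out[f"delta_{var}_missing"] = ~np.isfinite(delta)
    return out.reset_index(drop=True)
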