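"""Raw multi-channel recording container.

A :class:`RawRecording` holds one continuous multi-electrode-array (MEA)
acquisition for a single (animal, slice, condition) cell of the study design.
The acquisition is conceptually segmented into consecutive fixed-length traces
(600 one-second traces at the defaults); the samples themselves are stored as
one continuous ``channels x time`` matrix and the trace grid is derived from
``n_traces`` / ``trace_duration``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

REGION_LABELS = ("DG", "CA3", "CA1", "other")
CONDITIONS = ("normal", "highk")


@dataclass
class RawRecording:
    """One MEA acquisition (one animal/slice/condition).

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Extracellular voltage in mV. Stored as float32 by convention to keep
        full-length (600 s, 20 kHz, 64-channel) recordings tractable.
    sampling_rate : float
        Samples per second. Must exceed 2 kHz so the 1 kHz high-pass cutoff
        stays below Nyquist.
    regions : sequence of str
        Per-channel region label, one of ``DG``, ``CA3``, ``CA1``, ``other``.
    """

    samples: np.ndarray
    sampling_rate: float
    regions: Sequence[str]
    genotype: str = "wt"
    animal_id: str = "a0"
    slice_id: str = "a0s0"
    condition: str = "normal"
    n_traces: int = 600
    trace_duration: float = 1.0
    filtered: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if self.sampling_rate <= 2000:
            raise ValueError(
                "sampling_rate must exceed 2000 Hz (high-pass cutoff below Nyquist)"
            )
        if len(self.regions) != self.n_channels:
            raise ValueError(
                f"regions has {len(self.regions)} entries for "
                f"{self.n_channels} channels"
            )
        bad = set(self.regions) - set(REGION_LABELS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def channel_names(self) -> list[str]:
        return [f"ch{i + 1:02d}" for i in range(self.n_channels)]

    def trace_boundaries(self) -> list[tuple[float, float]]:
        """(start_s, end_s) of each nominal trace, clipped to the recording."""
        out = []
        for i in range(self.n_traces):
            s = i * self.trace_duration
            e = min((i + 1) * self.trace_duration, self.duration)
            if s >= self.duration:
                break
            out.append((s, e))
        return out

    def region_map(self) -> Mapping[int, str]:
        return {i: r for i, r in enumerate(self.regions)}

    def mark_filtered(self) -> "RawRecording":
        return replace(self, filtered=True)


def default_region_layout(n_channels: int = 64) -> list[str]:
    """Region assignment for an 8x8 array straddling the trisynaptic circuit.

    Channels are assigned in blocks along the array: the first 20 to the
    dentate gyrus, the next 22 to CA3 and the final 22 to CA1, mimicking a
    slice positioned so all three sub-regions are sampled.
    """
    if n_channels < 3:
        raise ValueError("need at least 3 channels for a 3-region layout")
    n_dg = round(n_channels * 20 / 64) or 1
    n_ca3 = round(n_channels * 22 / 64) or 1
    n_ca1 = n_channels - n_dg - n_ca3
    return ["DG"] * n_dg + ["CA3"] * n_ca3 + ["CA1"] * n_ca1
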