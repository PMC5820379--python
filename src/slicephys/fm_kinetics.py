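"""FM1-43 destaining kinetics.

Styryl-dye destaining reports synaptic vesicle fusion: after loading, each
depolarizing stimulus round releases dye and the per-bouton fluorescence
decays. The analysis chain is

    background correction -> pre-stimulus normalization -> single-exponential
    fit of the first release round -> group-level comparison of the release
    rate k and recycling-pool size.

The release rate is the exponential rate constant k (s^-1) of
F(t) = plateau + A exp(-k (t - t0)) fitted from the first release stimulus;
t_half = ln2 / k is reported as a model-free companion, and the recycling
pool is the total normalized fluorescence released (1 - plateau).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .population_stats import ks_two_sample

__all__ = [
    "DestainTrace",
    "BoutonKinetics",
    "background_correct",
    "normalize_trace",
    "estimate_release_rate",
    "fit_cohort",
    "compare_groups",
    "GroupComparison",
]

log = logging.getLogger(__name__)

K_BOUNDS = (1e-4, 10.0)  # s^-1 box limits for the rate fit
MIN_RELEASE_AMPLITUDE = 0.02  # normalized units; below this there is no decay


@dataclass
class DestainTrace:
    """Per-bouton fluorescence time series with stimulus metadata."""

    bouton_id: str
    time: np.ndarray  # s, strictly increasing
    fluorescence: np.ndarray  # a.u.
    background: float  # a.u., post-experiment value for this region
    stimulus_onsets: Sequence[float]  # s, release rounds (loading excluded)
    group: str = "wt"
    background_corrected: bool = False
    normalized: bool = False
    flagged: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.background is None or not np.isfinite(self.background):
            raise ValueError("background must be a finite value")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if not self.stimulus_onsets:
            raise ValueError("at least one release stimulus is required")
        if int(np.sum(self.time < self.stimulus_onsets[0])) < 10:
            raise ValueError("need >= 10 pre-stimulus frames")

    def pre_stimulus_mask(self) -> np.ndarray:
        return self.time < self.stimulus_onsets[0]


def background_correct(trace: DestainTrace) -> DestainTrace:
    """Subtract the post-experiment background fluorescence, elementwise.

    Negative excursions are permitted (noise); the trace is flagged when the
    mean corrected pre-stimulus signal is non-positive.
    """
    f = trace.fluorescence - trace.background
    flagged = float(f[trace.pre_stimulus_mask()].mean()) <= 0
    return replace(
        trace,
        fluorescence=f,
        background=0.0,
        background_corrected=True,
        flagged=trace.flagged or flagged,
    )


def normalize_trace(trace: DestainTrace) -> DestainTrace:
    """Scale so the mean pre-stimulus level is exactly 1.

    Requires a background-corrected trace. Boutons whose pre-stimulus mean is
    non-positive cannot be normalized and raise; callers batch-processing a
    cohort should exclude them (see :func:`fit_cohort`).
    """
    if not trace.background_corrected:
        raise ValueError("normalize_trace requires a background-corrected trace")
    pre = float(trace.fluorescence[trace.pre_stimulus_mask()].mean())
    if pre <= 0:
        raise ValueError(
            f"bouton {trace.bouton_id}: non-positive pre-stimulus mean; excluded"
        )
    return replace(trace, fluorescence=trace.fluorescence / pre, normalized=True)


@dataclass
class BoutonKinetics:
    bouton_id: str
    group: str
    k: float  # s^-1
    t_half: float  # s
    pool: float  # normalized fluorescence released
    fit_rss: float
    fit_ok: bool


def estimate_release_rate(trace: DestainTrace) -> BoutonKinetics:
    """Fit F(t) = plateau + A exp(-k (t - t0)) from the first release round.

    Only the first of the release rounds is fitted (later rounds are kept for
    QC); the fit window runs from the first stimulus to the second (or the
    end of the trace). Initial values: plateau from the last window value, A
    from 1 - plateau, k from a log-linear regression on the first third of
    the window. ``fit_ok`` is False when the residual sum of squares exceeds
    a noise-scaled bound, when k sits at its box limits, or when there is no
    measurable decay.
    """
    if not trace.normalized:
        raise ValueError("estimate_release_rate requires a normalized trace")
    t0 = float(trace.stimulus_onsets[0])
    t_end = (
        float(trace.stimulus_onsets[1])
        if len(trace.stimulus_onsets) > 1
        else float(trace.time[-1]) + 1.0
    )
    m = (trace.time >= t0) & (trace.time < t_end)
    if int(m.sum()) < 20:
        raise ValueError("need >= 20 post-stimulus frames in the first round")
    t = trace.time[m] - t0
    f = trace.fluorescence[m]

    plateau0 = float(f[-1])
    a0 = max(1e-3, 1.0 - plateau0)
    third = max(3, f.size // 3)
    resid0 = np.clip(f[:third] - plateau0, 1e-6, None)
    slope, _ = np.polyfit(t[:third], np.log(resid0), 1)
    k0 = float(np.clip(-slope, K_BOUNDS[0] * 2, K_BOUNDS[1] / 2))

    def resid(p):
        plateau, a, k = p
        return plateau + a * np.exp(-k * t) - f

    sol = least_squares(
        resid,
        x0=[plateau0, a0, k0],
        bounds=([-0.5, 0.0, K_BOUNDS[0]], [1.5, 2.0, K_BOUNDS[1]]),
        method="trf",
    )
    plateau, a, k = sol.x
    rss = float(np.sum(sol.fun**2))
    pool = float(1.0 - plateau)

    pre = trace.fluorescence[trace.pre_stimulus_mask()]
    noise = float(np.std(pre))
    rss_bound = f.size * (4.0 * max(noise, 1e-4)) ** 2
    at_bounds = k <= K_BOUNDS[0] * 1.01 or k >= K_BOUNDS[1] * 0.99
    fit_ok = (rss <= rss_bound) and not at_bounds and a >= MIN_RELEASE_AMPLITUDE
    return BoutonKinetics(
        bouton_id=trace.bouton_id,
        group=trace.group,
        k=float(k),
        t_half=math.log(2) / float(k),
        pool=float(np.clip(pool, 0.0, 1.2)),
        fit_rss=rss,
        fit_ok=bool(fit_ok),
    )


def fit_cohort(traces: Sequence[DestainTrace]) -> pd.DataFrame:
    """Background-correct, normalize and fit every bouton; returns a table.

    Boutons that cannot be normalized are excluded with a log entry.
    """
    rows = []
    for tr in traces:
        try:
            norm = normalize_trace(background_correct(tr))
        except ValueError as e:
            log.warning("excluding bouton: %s", e)
            continue
        kin = estimate_release_rate(norm)
        rows.append(
            {
                "bouton_id": kin.bouton_id,
                "group": kin.group,
                "k": kin.k,
                "t_half": kin.t_half,
                "pool": kin.pool,
                "rss": kin.fit_rss,
                "fit_ok": kin.fit_ok,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    variable: str
    grid: np.ndarray
    cdfs: dict[str, np.ndarray]
    medians: dict[str, float]
    pairwise: pd.DataFrame  # group_a, group_b, D, p, p_holm
    excluded: list[str]


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_groups(
    kinetics: pd.DataFrame | Sequence[BoutonKinetics],
    variable: str = "k",
    min_group_size: int = 10,
    grid_points: int = 256,
) -> GroupComparison:
    """Empirical CDFs per group and Holm-adjusted pairwise KS tests.

    Only boutons with ``fit_ok`` are used; groups below ``min_group_size``
    are excluded with a warning.
    """
    if variable not in ("k", "pool"):
        raise ValueError("variable must be 'k' or 'pool'")
    if not isinstance(kinetics, pd.DataFrame):
        kinetics = pd.DataFrame([vars(k) for k in kinetics])
    ok = kinetics[kinetics["fit_ok"]]
    samples: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for g, sub in ok.groupby("group"):
        vals = sub[variable].to_numpy()
        if vals.size < min_group_size:
            excluded.append(str(g))
            warnings.warn(
                f"group {g!r} has only {vals.size} usable boutons; excluded",
                stacklevel=2,
            )
        else:
            samples[str(g)] = vals
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with enough usable boutons")
    allv = np.concatenate(list(samples.values()))
    grid = np.linspace(allv.min(), allv.max(), grid_points)
    cdfs = {
        g: np.searchsorted(np.sort(v), grid, side="right") / v.size
        for g, v in samples.items()
    }
    medians = {g: float(np.median(v)) for g, v in samples.items()}
    names = sorted(samples)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            r = ks_two_sample(samples[ga], samples[gb])
            rows.append(
                {"group_a": ga, "group_b": gb, "D": r.statistic, "p": r.pvalue}
            )
    pw = pd.DataFrame(rows)
    pw["p_holm"] = _holm(pw["p"].to_numpy())
    return GroupComparison(
        variable=variable,
        grid=grid,
        cdfs=cdfs,
        medians=medians,
        pairwise=pw,
        excluded=excluded,
    )
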