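"""End-to-end orchestration: simulate -> detect -> stats -> models -> report.

The in-memory entry point is :func:`run_cohort_analysis`, which streams the
simulated cohort one recording at a time (full-length rendered recordings are
large), extracts spikes, accumulates the per-channel variables, per-1-s-bin
count matrices and late-window activity, and then fits the inferential layer:
nested mixed-effects contrasts per variable, the genotype x condition
interaction for the high-K challenge, and per-region Poisson spline rate
curves with genotype difference intervals.

:func:`run_pipeline` wraps this with file outputs and a provenance manifest
(parameter values, seed, output checksums), so a rerun with the same config
and seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .evoked_io import build_io_curve
from .fm_kinetics import compare_groups, fit_cohort
from .network_metrics import (
    STAT_VARIABLES,
    cohort_statistics,
    condition_delta,
    region_aggregate,
)
from .population_stats import (
    MixedModelResult,
    boxcox_transform,
    fit_nested_model,
    fit_rate_curves,
    rate_difference_intervals,
)
from .signal_processing import FilterSpec, extract_spikes
from .synthetic_data import (
    DestainSimConfig,
    EvokedParams,
    SimConfig,
    iter_cohort,
    simulate_destain_cohort,
    simulate_evoked_sweep,
)

__all__ = [
    "RunConfig",
    "CohortResults",
    "run_cohort_analysis",
    "fit_variable_models",
    "run_pipeline",
    "make_report",
]

STAGES = ("simulate", "detect", "stats", "models", "ratecurves", "evoked", "fm",
          "report")


# --------------------------------------------------------------------------
# in-memory cohort analysis
# --------------------------------------------------------------------------

@dataclass
class CohortResults:
    stats: pd.DataFrame  # per channel x condition, five variables + design
    deltas: pd.DataFrame  # per-channel high-K minus normal
    late_stats: pd.DataFrame  # per-channel late-window frequency (high K)
    counts: dict  # (genotype, region|"total") -> (rows, n_bins) count matrix
    models: dict[str, MixedModelResult] = field(default_factory=dict)
    interaction_models: dict[str, MixedModelResult] = field(default_factory=dict)
    late_model: MixedModelResult | None = None
    curves: dict = field(default_factory=dict)
    intervals: dict = field(default_factory=dict)


def _maybe_boxcox(values: np.ndarray) -> tuple[np.ndarray, float | None]:
    """Variance-stabilize when a normality screen fails; records lambda."""
    from scipy import stats as _st

    vals = np.asarray(values, dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < 8:
        return vals, None
    sub = vals[ok]
    if sub.size > 4000:
        sub = sub[:: sub.size // 4000 + 1]
    if np.ptp(sub) == 0 or _st.shapiro(sub).pvalue >= 0.05:
        return vals, None
    res = boxcox_transform(vals[ok])
    out = np.full_like(vals, np.nan)
    out[ok] = res.values
    return out, res.lam


def run_cohort_analysis(
    config: SimConfig,
    filter_spec: FilterSpec | None = None,
    pos_thr: float = 0.021,
    neg_thr: float = -0.021,
    late_window: tuple[float, float] = (300.0, 600.0),
    fit_models: bool = True,
    fit_curves: bool = True,
    curve_knots: int = 20,
) -> CohortResults:
    """Simulate, detect and analyze the whole cohort (streaming)."""
    spec = filter_spec or FilterSpec()
    stat_frames, late_rows = [], []
    counts: dict = {}
    for rec, _truth in iter_cohort(config, render=True):
        events = extract_spikes(rec, spec, pos_thr=pos_thr, neg_thr=neg_thr)
        df = cohort_statistics(
            events, rec.n_channels, rec.regions, rec.n_traces,
            rec.trace_duration, rec.condition,
        )
        df["genotype"] = rec.genotype
        df["animal_id"] = rec.animal_id
        df["slice_id"] = rec.slice_id
        stat_frames.append(df)
        if rec.condition == "highk":
            ch_arr = np.array([e.channel for e in events], dtype=np.int64)
            ti_arr = np.array([e.trace_index for e in events], dtype=np.int64)
            t_arr = np.array([e.time for e in events])
            ok = (ti_arr >= 0) & (ti_arr < rec.n_traces)
            mat = np.bincount(
                ch_arr[ok] * rec.n_traces + ti_arr[ok],
                minlength=rec.n_channels * rec.n_traces,
            ).reshape(rec.n_channels, rec.n_traces)
            for key_region in {"total", *rec.regions}:
                if key_region == "total":
                    sub = mat
                else:
                    rows = [i for i, r in enumerate(rec.regions) if r == key_region]
                    sub = mat[rows]
                counts.setdefault((rec.genotype, key_region), []).append(sub)
            w0, w1 = late_window
            span = max(1e-9, w1 - w0)
            late_mask = (t_arr >= w0) & (t_arr < w1)
            n_late = np.bincount(ch_arr[late_mask], minlength=rec.n_channels)
            for ch in range(rec.n_channels):
                late_rows.append(
                    {
                        "genotype": rec.genotype,
                        "animal_id": rec.animal_id,
                        "slice_id": rec.slice_id,
                        "channel": ch,
                        "region": rec.regions[ch],
                        "late_frequency": n_late[ch] / span,
                    }
                )
    stats = pd.concat(stat_frames, ignore_index=True)
    counts = {k: np.vstack(v) for k, v in counts.items()}
    late_stats = pd.DataFrame(late_rows)

    deltas = []
    key = ["genotype", "animal_id", "slice_id"]
    for ids, sub in stats.groupby(key):
        a = sub[sub["condition"] == "normal"]
        b = sub[sub["condition"] == "highk"]
        if len(a) and len(b):
            d = condition_delta(a, b)
            for c, v in zip(key, ids):
                d[c] = v
            deltas.append(d)
    deltas = pd.concat(deltas, ignore_index=True) if deltas else pd.DataFrame()

    results = CohortResults(
        stats=stats, deltas=deltas, late_stats=late_stats, counts=counts
    )
    if fit_models:
        results.models = fit_variable_models(
            stats[stats["condition"] == "normal"], formula="value ~ genotype"
        )
        results.interaction_models = fit_variable_models(
            stats, formula="value ~ genotype * condition"
        )
        if len(late_stats):
            ca1 = _set_references(
                late_stats[late_stats["region"] == "CA1"].copy()
            )
            ca1["value"], _ = _maybe_boxcox(ca1["late_frequency"].to_numpy())
            if ca1["genotype"].nunique() >= 2:
                try:
                    results.late_model = fit_nested_model(ca1, "value ~ genotype")
                except (ValueError, np.linalg.LinAlgError):
                    results.late_model = None
    if fit_curves:
        genos = sorted({g for g, _ in counts})
        regions = sorted({r for _, r in counts})
        for region in regions:
            present = {g: counts[(g, region)] for g in genos if (g, region) in counts}
            curves = fit_rate_curves(
                present,
                trace_duration=config.trace_duration,
                n_knots=curve_knots,
                breakpoints=[config.highk_onset],
            )
            results.curves[region] = curves
            if len(curves) == 2:
                a, b = [curves[g] for g in sorted(curves)]
                results.intervals[region] = rate_difference_intervals(b, a)
    return results


def _set_references(df: pd.DataFrame) -> pd.DataFrame:
    """Order factors so wt / normal are the treatment-coding baselines."""
    for col, ref in (("genotype", "wt"), ("condition", "normal")):
        if col in df.columns:
            levels = list(pd.unique(df[col]))
            if ref in levels:
                levels = [ref] + [l for l in levels if l != ref]
            df[col] = pd.Categorical(df[col], categories=levels)
    return df


def fit_variable_models(
    stats: pd.DataFrame, formula: str = "value ~ genotype"
) -> dict[str, MixedModelResult]:
    """One nested mixed model per network variable, Box-Cox'ed when needed."""
    out: dict[str, MixedModelResult] = {}
    for var in STAT_VARIABLES:
        df = stats.dropna(subset=[var]).copy()
        if df.empty or df["genotype"].nunique() < 2:
            continue
        df = _set_references(df)
        vals, lam = _maybe_boxcox(df[var].to_numpy())
        df["value"] = vals
        try:
            res = fit_nested_model(df, formula)
        except (ValueError, np.linalg.LinAlgError):
            # degenerate response (e.g. all-zero counts) leaves the
            # contrast not estimable; the report marks it as such
            continue
        res.table.attrs["boxcox_lambda"] = lam
        out[var] = res
    return out


# --------------------------------------------------------------------------
# file-based pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline run configuration; defaults follow the recording protocol
    (thresholds +/-0.021 mV, 1000 Hz 2-pole high-pass, 1 ms spike length,
    600 x 1 s traces, high-K onset 20 s, currents 0-100 uA)."""

    stages: Sequence[str] = STAGES
    sim: Mapping = field(default_factory=dict)  # SimConfig overrides
    destain: Mapping = field(default_factory=dict)  # DestainSimConfig overrides
    evoked: Mapping = field(default_factory=dict)  # EvokedParams overrides
    pos_thr: float = 0.021
    neg_thr: float = -0.021
    cutoff_hz: float = 1000.0
    dc_window_ms: float = 10.0
    dead_time_ms: float = 1.0
    currents_ua: Sequence[float] = tuple(range(0, 101, 10))
    curve_knots: int = 20
    seed: int = 0
    out_dir: str = "slicephys-run"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        need = {
            "detect": "simulate",
            "stats": "detect",
            "models": "stats",
            "ratecurves": "stats",
            "report": "models",
        }
        for stage, dep in need.items():
            if stage in self.stages and dep not in self.stages:
                raise ValueError(f"stage {stage!r} requires stage {dep!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **dict(self.sim))

    def destain_config(self) -> DestainSimConfig:
        return DestainSimConfig(seed=self.seed, **dict(self.destain))

    def evoked_params(self) -> EvokedParams:
        return EvokedParams(**dict(self.evoked))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _to_jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_curves(curves: dict, intervals: dict, out: Path) -> list[Path]:
    rows = []
    for region, group_curves in curves.items():
        for g, c in group_curves.items():
            for i in range(c.times.size):
                rows.append(
                    {
                        "region": region,
                        "group": g,
                        "t_s": c.times[i],
                        "log_rate": c.log_rate[i],
                        "lo": c.lo[i],
                        "hi": c.hi[i],
                    }
                )
    p1 = out / "ratecurves.tsv"
    pd.DataFrame(rows).to_csv(p1, sep="\t", index=False, float_format="%.6g")
    rows = []
    for region, rd in intervals.items():
        for s, e in rd.intervals:
            rows.append({"region": region, "start_s": s, "end_s": e})
    p2 = out / "intervals.tsv"
    pd.DataFrame(rows, columns=["region", "start_s", "end_s"]).to_csv(
        p2, sep="\t", index=False, float_format="%.6g"
    )
    return [p1, p2]


def _models_table(models: dict[str, MixedModelResult], kind: str) -> pd.DataFrame:
    frames = []
    for var, res in models.items():
        t = res.table.copy()
        t.insert(0, "variable", var)
        t.insert(0, "model", kind)
        t["boxcox_lambda"] = t.attrs.get("boxcox_lambda")
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["model", "variable", "effect", "estimate", "se", "df",
                     "ci_lo", "ci_hi", "p", "boxcox_lambda"]
        )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write a provenance manifest.

    Returns the manifest dict. Identical config + seed reproduce identical
    outputs (checksums included in the manifest for re-validation).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    failed_stage = None
    try:
        if {"detect", "stats", "models", "ratecurves"} & set(config.stages):
            failed_stage = "detect"
            res = run_cohort_analysis(
                config.sim_config(),
                FilterSpec(cutoff=config.cutoff_hz, dc_window_ms=config.dc_window_ms),
                pos_thr=config.pos_thr,
                neg_thr=config.neg_thr,
                fit_models="models" in config.stages,
                fit_curves="ratecurves" in config.stages,
                curve_knots=config.curve_knots,
            )
            failed_stage = "stats"
            p = out / "channel_stats.csv"
            res.stats.to_csv(p, index=False, float_format="%.6g")
            written.append(p)
            p = out / "region_summary.tsv"
            region_aggregate(res.stats).to_csv(p, sep="\t", index=False,
                                               float_format="%.6g")
            written.append(p)
            p = out / "condition_deltas.csv"
            res.deltas.to_csv(p, index=False, float_format="%.6g")
            written.append(p)
            if "models" in config.stages:
                failed_stage = "models"
                table = pd.concat(
                    [
                        _models_table(res.models, "genotype"),
                        _models_table(res.interaction_models,
                                      "genotype_x_condition"),
                        _models_table(
                            {"late_ca1_frequency": res.late_model}
                            if res.late_model
                            else {},
                            "late_ca1",
                        ),
                    ],
                    ignore_index=True,
                )
                p = out / "models.tsv"
                table.to_csv(p, sep="\t", index=False, float_format="%.6g")
                written.append(p)
            if "ratecurves" in config.stages:
                failed_stage = "ratecurves"
                written.extend(_write_curves(res.curves, res.intervals, out))
        if "evoked" in config.stages:
            failed_stage = "evoked"
            params = config.evoked_params()
            rng = np.random.default_rng(config.seed % (2**31))
            sweeps = [
                simulate_evoked_sweep(c, params, rng)[0] for c in config.currents_ua
            ]
            curve = build_io_curve(sweeps)
            p = out / "io_curve.tsv"
            curve.as_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
            written.append(p)
        if "fm" in config.stages:
            failed_stage = "fm"
            traces, _truth = simulate_destain_cohort(config.destain_config())
            kin = fit_cohort(traces)
            p = out / "fm_kinetics.csv"
            kin.to_csv(p, index=False, float_format="%.6g")
            written.append(p)
            rows = []
            for var in ("k", "pool"):
                cmpres = compare_groups(kin, var)
                t = cmpres.pairwise.copy()
                t.insert(0, "variable", var)
                for g, m in cmpres.medians.items():
                    t[f"median_{g}"] = m
                rows.append(t)
            p = out / "fm_comparison.tsv"
            pd.concat(rows, ignore_index=True).to_csv(
                p, sep="\t", index=False, float_format="%.6g"
            )
            written.append(p)
        if "report" in config.stages:
            failed_stage = "report"
            written.extend(make_report(out))
        failed_stage = None
    except Exception as e:
        raise RuntimeError(f"pipeline stage {failed_stage!r} failed: {e}") from e
    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "parameters": _to_jsonable(config),
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_report(run_dir: str | Path) -> list[Path]:
    """Summary tables from pipeline outputs: per-variable effect estimates
    with 95% CIs, condition deltas, significant time intervals and FM CDF
    medians. Missing inputs are enumerated; non-estimable contrasts are
    marked rather than dropped."""
    run_dir = Path(run_dir)
    missing = [
        n
        for n in ("channel_stats.csv", "models.tsv")
        if not (run_dir / n).exists()
    ]
    if missing:
        raise FileNotFoundError(f"report inputs missing: {missing}")
    stats = pd.read_csv(run_dir / "channel_stats.csv")
    models = pd.read_csv(run_dir / "models.tsv", sep="\t")
    rows = []
    for var in STAT_VARIABLES:
        sub = models[
            (models["variable"] == var)
            & models["effect"].astype(str).str.contains("genotype", regex=False)
        ]
        if sub.empty:
            rows.append(
                {"variable": var, "estimate": np.nan, "ci_lo": np.nan,
                 "ci_hi": np.nan, "p": np.nan, "status": "not-estimable"}
            )
        else:
            r = sub.iloc[0]
            rows.append(
                {"variable": var, "estimate": r["estimate"], "ci_lo": r["ci_lo"],
                 "ci_hi": r["ci_hi"], "p": r["p"], "status": "ok"}
            )
    report = pd.DataFrame(rows)
    report["n_channels"] = stats.groupby("condition")["channel"].count().max()
    report["zero_count_channels"] = int((stats["n_spikes"] == 0).sum())
    p1 = run_dir / "report_effects.tsv"
    report.to_csv(p1, sep="\t", index=False, float_format="%.6g")
    out = [p1]
    ivp = run_dir / "intervals.tsv"
    if ivp.exists():
        out.append(ivp)
    return out
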