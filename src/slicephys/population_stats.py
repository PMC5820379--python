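"""Inferential layer for the nested recording design.

Contains four pieces of machinery:

* Box-Cox variance stabilization with profile-likelihood selection of the
  exponent over a grid.
* Nested linear mixed-effects contrasts (random intercepts for animal and for
  slice-within-animal, residual at channel level) fitted by REML, with Wald
  95% confidence intervals using containment degrees of freedom: each fixed
  effect is tested at the grouping level it varies over, so a genotype
  contrast is judged against the number of animals, not the number of
  channels.
* Penalized cubic B-spline Poisson smoothing of spike rates over time
  (log link), with GCV-selected penalty, overdispersion-inflated pointwise
  95% bands, and significant-difference intervals between group curves.
* The two-sample Kolmogorov-Smirnov statistic with its asymptotic p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate as _interp
from scipy import linalg as _la
from scipy import special as _spec
from scipy import stats as _st

__all__ = [
    "BoxCoxResult",
    "boxcox_transform",
    "MixedModelResult",
    "fit_nested_model",
    "RateCurve",
    "fit_rate_curves",
    "RateDifference",
    "rate_difference_intervals",
    "KSResult",
    "ks_two_sample",
]


# --------------------------------------------------------------------------
# Box-Cox
# --------------------------------------------------------------------------

@dataclass
class BoxCoxResult:
    values: np.ndarray
    lam: float
    shift: float


def boxcox_transform(
    values: Sequence[float], lam: float | None = None
) -> BoxCoxResult:
    """Box-Cox power transform y -> (y^lam - 1)/lam (log y at lam = 0).

    If the data contain non-positive values they are shifted by eps - min
    first. When ``lam`` is None the exponent maximizing the profile
    log-likelihood is selected over the grid [-2, 2] in steps of 0.01.
    """
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    shift = 0.0
    mn = y.min()
    if mn <= 0:
        shift = 1e-6 - mn
    y = y + shift
    if np.any(y <= 0):
        raise ValueError("values must be positive after shifting")
    if lam is None:
        grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 10)
        ll = np.array([_st.boxcox_llf(l, y) for l in grid])
        lam = float(grid[np.argmax(ll)])
    out = _spec.boxcox(y, lam)
    return BoxCoxResult(values=out, lam=float(lam), shift=shift)


# --------------------------------------------------------------------------
# nested linear mixed model
# --------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """Fixed-effect table plus variance components.

    ``table`` columns: effect, estimate, se, df, ci_lo, ci_hi, p.
    """

    table: pd.DataFrame
    sigma_animal: float
    sigma_slice: float
    sigma_resid: float
    formula: str
    transform: BoxCoxResult | None = None
    converged: bool = True

    def effect(self, name_contains: str) -> pd.Series:
        """First fixed-effect row whose name contains the given substring."""
        m = self.table[self.table["effect"].str.contains(name_contains, regex=False)]
        if m.empty:
            raise KeyError(f"no fixed effect matching {name_contains!r}")
        return m.iloc[0]


REQUIRED_COLUMNS = ("value", "animal_id", "slice_id")


def _validate_nested(data: pd.DataFrame) -> None:
    for c in REQUIRED_COLUMNS:
        if c not in data.columns:
            raise ValueError(f"missing column {c!r}")
    # slice ids must not recur across animals
    owners = data.groupby("slice_id", observed=True)["animal_id"].nunique()
    if (owners > 1).any():
        raise ValueError("slice_id must be unique within animal")
    if "genotype" in data.columns:
        per = data.groupby("genotype", observed=True).agg(
            animals=("animal_id", "nunique"), slices=("slice_id", "nunique")
        )
        if (per["animals"] < 2).any():
            raise ValueError(
                "singular design: need at least 2 animals per genotype"
            )
        if (per["slices"] < 2).any():
            raise ValueError("singular design: a genotype has a single slice")


def _containment_dfs(
    exog: np.ndarray, names: list[str], animal: pd.Series, slice_: pd.Series
) -> np.ndarray:
    """Degrees of freedom per fixed-effect column, by containment.

    A column constant within every animal is tested against the animal count;
    one constant within every slice against the slice count; anything else at
    the observation (channel) level.
    """
    n = exog.shape[0]
    p = exog.shape[1]
    acodes = pd.Categorical(animal).codes
    scodes = pd.Categorical(slice_).codes

    def _constant_within(col: np.ndarray, codes: np.ndarray) -> bool:
        df = pd.DataFrame({"g": codes, "v": col})
        return bool((df.groupby("g")["v"].nunique() == 1).all())

    level = np.empty(p, dtype=int)  # 0 animal, 1 slice, 2 obs
    for j in range(p):
        if _constant_within(exog[:, j], acodes):
            level[j] = 0
        elif _constant_within(exog[:, j], scodes):
            level[j] = 1
        else:
            level[j] = 2
    n_animal = len(np.unique(acodes))
    n_slice = len(np.unique(scodes))
    q0 = int((level == 0).sum())
    q1 = int((level <= 1).sum())
    dfs = {0: max(1, n_animal - q0), 1: max(1, n_slice - q1), 2: max(1, n - p)}
    return np.array([dfs[l] for l in level], dtype=float)


def fit_nested_model(
    data: pd.DataFrame,
    formula: str = "value ~ genotype * condition",
    reml: bool = True,
) -> MixedModelResult:
    """Nested linear mixed model for per-channel observations.

    Random intercepts for animal and slice-within-animal; the residual acts
    at the channel level. ``data`` must carry value, animal_id, slice_id and
    the fixed-effect factors named in the formula. The response should
    already be variance-stabilized (see :func:`boxcox_transform`).
    """
    import statsmodels.formula.api as smf

    data = data.copy()
    _validate_nested(data)
    data = data.dropna(subset=["value"])
    # label slices within each animal so the variance-component design stays
    # low-dimensional (slice-in-animal nesting)
    data["_slice_within"] = (
        data.groupby("animal_id")["slice_id"]
        .transform(lambda s: pd.Categorical(s).codes)
        .astype(str)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula,
            data,
            groups=data["animal_id"],
            re_formula="1",
            vc_formula={"slice": "0 + C(_slice_within)"},
        )
        try:
            res = model.fit(reml=reml, method=["lbfgs"])
        except Exception:
            res = None
        if res is None or not getattr(res, "converged", False):
            # L-BFGS stalls near variance-component boundaries; Powell is
            # slower but reliable there
            res = model.fit(reml=reml, method=["powell"], maxiter=2000)
    k = model.k_fe
    names = list(res.model.exog_names[:k])
    est = np.asarray(res.fe_params)[:k]
    se = np.asarray(res.bse.iloc[:k] if hasattr(res.bse, "iloc") else res.bse[:k])
    dfs = _containment_dfs(
        res.model.exog[:, :k], names, data["animal_id"], data["slice_id"]
    )
    tcrit = _st.t.ppf(0.975, dfs)
    tstat = est / se
    pvals = 2 * _st.t.sf(np.abs(tstat), dfs)
    table = pd.DataFrame(
        {
            "effect": names,
            "estimate": est,
            "se": se,
            "df": dfs,
            "ci_lo": est - tcrit * se,
            "ci_hi": est + tcrit * se,
            "p": pvals,
        }
    )
    sigma_animal = float(np.sqrt(max(0.0, np.asarray(res.cov_re)[0, 0])))
    vc = np.asarray(res.vcomp)
    sigma_slice = float(np.sqrt(max(0.0, vc[0]))) if vc.size else 0.0
    return MixedModelResult(
        table=table,
        sigma_animal=sigma_animal,
        sigma_slice=sigma_slice,
        sigma_resid=float(np.sqrt(res.scale)),
        formula=formula,
        converged=bool(getattr(res, "converged", True)),
    )


# --------------------------------------------------------------------------
# penalized Poisson spline rate curves
# --------------------------------------------------------------------------

@dataclass
class RateCurve:
    """Smoothed log firing rate (per channel-second) over time for one group."""

    group: str
    times: np.ndarray  # bin centers, s
    log_rate: np.ndarray
    se: np.ndarray
    lo: np.ndarray = field(init=False)
    hi: np.ndarray = field(init=False)
    lam: float = np.nan
    edf: float = np.nan
    dispersion: float = 1.0
    n_channels: int = 1
    flat_floor: bool = False

    def __post_init__(self) -> None:
        z = _st.norm.ppf(0.975)
        self.lo = self.log_rate - z * self.se
        self.hi = self.log_rate + z * self.se


def _bspline_basis(
    x: np.ndarray, n_knots: int, lo: float, hi: float, degree: int = 3
) -> np.ndarray:
    """Cubic B-spline design matrix with uniform interior knots."""
    interior = np.linspace(lo, hi, n_knots + 2)[1:-1]
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    xc = np.clip(x, lo, hi)
    return _interp.BSpline.design_matrix(xc, t, degree).toarray()


def _fit_pspline_poisson(
    y: np.ndarray, B: np.ndarray, offset: float, lam: float, max_iter: int = 50
) -> tuple[np.ndarray, float, np.ndarray]:
    """Penalized IRLS; returns (coef, edf, cov) for one penalty weight.

    First-difference coefficient penalty: its null space is the constant
    log-rate, so at infinite penalty the fit collapses to the homogeneous-
    Poisson mean rate — the natural reference for spike-rate smoothing. The
    returned covariance is the Bayesian posterior covariance of the
    penalized estimator (the convention of GAM software), which is wider
    than the frequentist sandwich and better calibrated for band coverage.
    """
    m = B.shape[1]
    D = np.diff(np.eye(m), n=1, axis=0)
    P = D.T @ D
    eta = np.log(np.clip(y, 0.5, None))  # includes offset implicitly
    coef = _la.lstsq(B.T @ B + 1e-6 * np.eye(m), B.T @ (eta - offset))[0]
    for _ in range(max_iter):
        eta = B @ coef + offset
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu
        z = (eta - offset) + (y - mu) / np.clip(mu, 1e-10, None)
        BW = B * w[:, None]
        A = B.T @ BW + lam * P
        new = _la.solve(A, BW.T @ z, assume_a="pos")
        if np.max(np.abs(new - coef)) < 1e-9:
            coef = new
            break
        coef = new
    eta = B @ coef + offset
    mu = np.exp(np.clip(eta, -30, 30))
    BW = B * mu[:, None]
    A = B.T @ BW + lam * P
    Ainv = _la.inv(A)
    edf = float(np.trace(Ainv @ (B.T @ BW)))
    return coef, edf, Ainv


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2 * np.sum(term - (y - mu)))


def fit_rate_curves(
    counts: Mapping[str, np.ndarray],
    trace_duration: float = 1.0,
    n_knots: int = 20,
    breakpoints: Sequence[float] | None = None,
    lam_grid: Sequence[float] | None = None,
    gcv_gamma: float = 2.0,
) -> dict[str, RateCurve]:
    """Per-group penalized cubic B-spline fit of log spike rate vs. time.

    Parameters
    ----------
    counts : mapping group -> (n_channels, n_bins) integer array
        Spike counts per channel per time bin (1-s bins at the defaults).
    breakpoints : optional times (s) at which the smooth is allowed to
        restart: the curve is fitted independently on each segment between
        breakpoints (with knot budget proportional to segment length), so a
        known intervention such as the perfusion switch can produce an
        abrupt rate change without smoothing leakage into the baseline.
    gcv_gamma : inflation factor on effective degrees of freedom in the GCV
        score; values above 1 counteract the undersmoothing plain GCV is
        prone to, which matters on short pre-intervention segments.

    The penalty weight is chosen per segment by (gamma-inflated) generalized
    cross-validation over a fixed log-spaced grid, and pointwise 95% bands
    are inflated by a Pearson overdispersion factor estimated at channel
    level (channels differ through random effects the smooth itself does not
    model).
    """
    if lam_grid is None:
        lam_grid = np.logspace(-4, 6, 21)
    out: dict[str, RateCurve] = {}
    for group, mat in counts.items():
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        if np.any(mat < 0) or not np.allclose(mat, np.round(mat)):
            raise ValueError("counts must be non-negative integers")
        n_ch, n_bins = mat.shape
        t = (np.arange(n_bins) + 0.5) * trace_duration
        y = mat.sum(axis=0)
        if y.sum() == 0:
            floor = math.log(1.0 / (n_ch * n_bins * trace_duration))
            out[group] = RateCurve(
                group=group,
                times=t,
                log_rate=np.full(n_bins, floor),
                se=np.full(n_bins, np.inf),
                n_channels=n_ch,
                flat_floor=True,
            )
            continue
        offset = math.log(n_ch * trace_duration)
        total = n_bins * trace_duration
        edges = [0.0]
        for b in sorted(breakpoints or []):
            if 0.0 < b < total:
                edges.append(float(b))
        edges.append(total)
        eta = np.empty(n_bins)
        var_eta = np.empty(n_bins)
        edf = 0.0
        lam = np.nan
        longest = -1.0
        for lo_e, hi_e in zip(edges, edges[1:]):
            m = (t >= lo_e) & (t < hi_e) if hi_e < total else (t >= lo_e)
            ys = y[m]
            if ys.sum() == 0:
                # no spikes in this segment: floor rate, uninformative band
                eta[m] = offset + math.log(
                    0.5 / max(1, ys.size)
                )
                var_eta[m] = np.inf
                continue
            nk = max(4, int(round(n_knots * (hi_e - lo_e) / total)))
            B = _bspline_basis(t[m], nk, lo_e, hi_e)
            best = None
            for lam_c in lam_grid:
                coef, edf_c, cov = _fit_pspline_poisson(ys, B, offset, lam_c)
                mu_c = np.exp(B @ coef + offset)
                dev = _poisson_deviance(ys, mu_c)
                # gamma-inflated GCV guards against the undersmoothing GCV is
                # prone to on short segments
                gcv = ys.size * dev / max(1e-6, (ys.size - gcv_gamma * edf_c)) ** 2
                if best is None or gcv < best[0]:
                    best = (gcv, lam_c, coef, edf_c, cov)
            _, lam_c, coef, edf_c, cov = best
            eta[m] = B @ coef + offset
            var_eta[m] = np.einsum("ij,jk,ik->i", B, cov, B)
            edf += edf_c
            if hi_e - lo_e > longest:
                longest = hi_e - lo_e
                lam = float(lam_c)
        mu = np.exp(eta)
        # channel-level Pearson dispersion: each channel's bin count has mean
        # mu_t / n_ch under homogeneity; random effects inflate this.
        mch = mu / n_ch
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.nansum((mat - mch[None, :]) ** 2 / np.clip(mch, 1e-10, None))
        dof = max(1.0, n_ch * n_bins - edf)
        phi = max(1.0, chi2 / dof)
        # log_rate is per channel-second: eta minus the count offset
        out[group] = RateCurve(
            group=group,
            times=t,
            log_rate=eta - math.log(n_ch * trace_duration),
            se=np.sqrt(phi * np.clip(var_eta, 0, None)),
            lam=float(lam),
            edf=edf,
            dispersion=phi,
            n_channels=n_ch,
        )
    return out


@dataclass
class RateDifference:
    times: np.ndarray
    diff: np.ndarray  # log-rate(a) - log-rate(b)
    lo: np.ndarray
    hi: np.ndarray
    intervals: list[tuple[float, float]]


def rate_difference_intervals(
    curve_a: RateCurve,
    curve_b: RateCurve,
    alpha: float = 0.05,
    simultaneous: bool = True,
) -> RateDifference:
    """Difference of two group log-rate curves with significance intervals.

    The band uses the summed pointwise variances; significant intervals are
    the maximal runs of time bins whose band excludes zero. By default the
    critical value is Sidak-adjusted for the effective number of independent
    comparisons along the grid (the summed effective degrees of freedom of
    the two smooths), so the chance of flagging any interval under a true
    null difference is held near ``alpha`` across the whole recording; set
    ``simultaneous=False`` for plain pointwise bands.
    """
    if curve_a.times.shape != curve_b.times.shape or not np.allclose(
        curve_a.times, curve_b.times
    ):
        raise ValueError("curves are not on a common time grid")
    diff = curve_a.log_rate - curve_b.log_rate
    se = np.sqrt(curve_a.se**2 + curve_b.se**2)
    if simultaneous:
        m_eff = max(
            1.0,
            (0.0 if np.isnan(curve_a.edf) else curve_a.edf)
            + (0.0 if np.isnan(curve_b.edf) else curve_b.edf),
        )
        alpha_eff = 1.0 - (1.0 - alpha) ** (1.0 / m_eff)
    else:
        alpha_eff = alpha
    z = _st.norm.ppf(1 - alpha_eff / 2)
    lo, hi = diff - z * se, diff + z * se
    sig = (lo > 0) | (hi < 0)
    intervals: list[tuple[float, float]] = []
    t = curve_a.times
    half = float(np.median(np.diff(t)) / 2) if t.size > 1 else 0.5
    i = 0
    while i < sig.size:
        if sig[i]:
            j = i
            while j + 1 < sig.size and sig[j + 1]:
                j += 1
            intervals.append((float(t[i] - half), float(t[j] + half)))
            i = j + 1
        else:
            i += 1
    return RateDifference(times=t, diff=diff, lo=lo, hi=hi, intervals=intervals)


# --------------------------------------------------------------------------
# Kolmogorov-Smirnov
# --------------------------------------------------------------------------

@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float]) -> KSResult:
    """Two-sample KS test: D = sup_x |F_a(x) - F_b(x)|.

    The p-value comes from the asymptotic Kolmogorov distribution evaluated
    at sqrt(n_eff) * D with n_eff = n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(fa - fb)))
    ne = a.size * b.size / (a.size + b.size)
    p = float(np.clip(_spec.kolmogorov(math.sqrt(ne) * d), 0.0, 1.0))
    return KSResult(statistic=d, pvalue=p, n_a=int(a.size), n_b=int(b.size))
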