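"""Cline-shape model selection: null, linear, sigmoid (tanh) and step.

Expression of each transcript is min-max rescaled to [0, 1] and latitude
is expressed in degrees relative to the southernmost site.  Four mean
functions are fitted by Gaussian maximum likelihood with profiled
residual variance:

    null      x_l = x_s
    linear    x_l = x_s + b * l
    sigmoid   x_l = x_s + (d / 2) * (1 + tanh(kappa * (l - c)))
    step      x_l = x_s + d * 1{l >= l_c}

where x_s is the southern-end expression, b the linear coefficient per
degree, d the expression difference between the cline extremes, c the
cline centre and l_c the step position.  The maximum slope of the
sigmoid at its centre is s = d * kappa / 2.  Parameter counts include
the residual sigma (2 / 3 / 5 / 4), AIC = 2k - 2 logL, and the model
with the smallest AIC is selected, ties broken toward fewer parameters.

A steep sigmoid is observationally a step with six sites; the AIC
penalty (5 vs 4 parameters) then favours the step model, which is the
intended behaviour when the transition is too sharp to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

MODEL_ORDER = ("null", "linear", "step", "sigmoid")  # fewer parameters first
N_PARAMS = {"null": 2, "linear": 3, "step": 4, "sigmoid": 5}

SIGMA_FLOOR = 1e-6
KAPPA_BOUNDS = (1e-2, 50.0)  # steepness per degree latitude
XS_BOUNDS = (-3.0, 3.0)
D_BOUNDS = (-3.0, 3.0)
AIC_TIE_TOL = 1e-6


@dataclass
class RescaledProfile:
    transcript_id: str
    x: np.ndarray  # rescaled expression per sample, in [0, 1]
    l: np.ndarray  # latitude relative to the southernmost site, >= 0
    constant: bool = False


@dataclass
class ModelFit:
    model: str
    params: dict
    logL: float
    sigma: float
    k: int

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.logL


@dataclass
class ClineFit:
    transcript_id: str
    fits: dict
    selected_model: str = ""
    delta_aic: float = np.nan  # margin to the runner-up

    @property
    def selected(self) -> ModelFit:
        return self.fits[self.selected_model]


def rescale(values: np.ndarray, latitudes: np.ndarray, transcript_id: str = "") -> RescaledProfile:
    """Min-max rescale expression to [0, 1]; latitude relative to the south.

    x_k = (r_k - min r) / (max r - min r).  A constant transcript cannot
    be rescaled and is flagged; it is assigned the null model directly.
    """
    r = np.asarray(values, float)
    lat = np.asarray(latitudes, float)
    if r.size < 2:
        raise ValueError("need at least 2 samples")
    if r.shape != lat.shape:
        raise ValueError(f"length mismatch: {r.shape} vs {lat.shape}")
    lo, hi = r.min(), r.max()
    l = lat - lat.min()
    if hi == lo:
        return RescaledProfile(transcript_id, np.zeros_like(r), l, constant=True)
    return RescaledProfile(transcript_id, (r - lo) / (hi - lo), l)


def gaussian_loglik(residuals: np.ndarray, sigma_floor: float = SIGMA_FLOOR) -> tuple[float, float]:
    """Profiled Gaussian log-likelihood: sigma^2 = RSS / n, floored.

    The floor keeps perfect (zero-residual) fits at a finite likelihood;
    below the floor the exact Gaussian log-likelihood at sigma = floor is
    returned.
    """
    res = np.asarray(residuals, float)
    n = res.size
    rss = float(res @ res)
    s2 = max(rss / n, sigma_floor**2)
    logl = -(n / 2.0) * np.log(2.0 * np.pi * s2) - rss / (2.0 * s2)
    return logl, float(np.sqrt(s2))


def _finish(model: str, params: dict, residuals: np.ndarray, sigma_floor: float) -> ModelFit:
    logl, sigma = gaussian_loglik(residuals, sigma_floor)
    return ModelFit(model, params, logl, sigma, N_PARAMS[model])


def fit_null(profile: RescaledProfile, sigma_floor: float = SIGMA_FLOOR) -> ModelFit:
    xs = float(profile.x.mean())
    return _finish("null", {"x_s": xs}, profile.x - xs, sigma_floor)


def fit_linear(profile: RescaledProfile, sigma_floor: float = SIGMA_FLOOR) -> ModelFit:
    l, x = profile.l, profile.x
    b, xs = np.polyfit(l, x, 1)
    return _finish(
        "linear", {"x_s": float(xs), "b": float(b)}, x - (xs + b * l), sigma_floor
    )


def fit_step(profile: RescaledProfile, sigma_floor: float = SIGMA_FLOOR) -> ModelFit:
    """Step position profiled exactly over between-site midpoints.

    With P discrete sites l_c is identified only to an interval; the
    midpoint between consecutive distinct latitudes is the canonical
    representative, and x_s / d are group means per candidate.
    """
    l, x = profile.l, profile.x
    sites = np.unique(l)
    if sites.size < 2:
        raise ValueError("step model needs at least 2 distinct latitudes")
    best = None
    for lc in (sites[:-1] + sites[1:]) / 2.0:
        south = l < lc
        m0, m1 = x[south].mean(), x[~south].mean()
        resid = x - np.where(south, m0, m1)
        rss = resid @ resid
        if best is None or rss < best[0]:
            best = (rss, lc, m0, m1, resid)
    _, lc, m0, m1, resid = best
    params = {"x_s": float(m0), "d": float(m1 - m0), "l_c": float(lc)}
    return _finish("step", params, resid, sigma_floor)


def _sigmoid_mean(l: np.ndarray, xs: float, d: float, kappa: float, c: float) -> np.ndarray:
    return xs + (d / 2.0) * (1.0 + np.tanh(kappa * (l - c)))


def _sigmoid_grid(l: np.ndarray, grid_c: int, grid_k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute the (kappa, c) start grid and its h = (1+tanh)/2 matrix."""
    l_max = float(l.max())
    cs = np.linspace(0.0, l_max, grid_c)
    ks = np.geomspace(KAPPA_BOUNDS[0], KAPPA_BOUNDS[1], grid_k)
    kk, cc = np.meshgrid(ks, cs, indexing="ij")
    kk, cc = kk.ravel(), cc.ravel()
    h = (1.0 + np.tanh(kk[:, None] * (l[None, :] - cc[:, None]))) / 2.0
    return kk, cc, h


def fit_sigmoid(
    profile: RescaledProfile,
    sigma_floor: float = SIGMA_FLOOR,
    grid_c: int = 25,
    grid_k: int = 25,
    _grid: tuple | None = None,
) -> ModelFit | None:
    """Bounded nonlinear least squares with a multi-start (kappa, c) grid.

    For fixed (kappa, c) the mean is linear in (x_s, d), so every grid
    point is scored in closed form; the best start is refined with
    trust-region least squares.  Returns None when no start converges.
    """
    l, x = profile.l, profile.x
    if np.unique(l).size < 4:
        raise ValueError("sigmoid model needs at least 4 distinct latitudes")
    kk, cc, h = _sigmoid_grid(l, grid_c, grid_k) if _grid is None else _grid

    n = x.size
    hbar = h.mean(axis=1)
    xbar = x.mean()
    var_h = (h**2).mean(axis=1) - hbar**2
    cov_hx = h @ x / n - hbar * xbar
    with np.errstate(invalid="ignore", divide="ignore"):
        d_hat = np.where(var_h > 1e-12, cov_hx / np.maximum(var_h, 1e-12), 0.0)
    # clip into the parameter box before scoring so every grid candidate is
    # a feasible start whose RSS matches its parameters
    d_hat = np.clip(d_hat, *D_BOUNDS)
    xs_hat = np.clip(xbar - d_hat * hbar, *XS_BOUNDS)
    resid = x[None, :] - (xs_hat[:, None] + d_hat[:, None] * h)
    rss = (resid**2).sum(axis=1)
    best = int(np.argmin(rss))

    lo = np.array([XS_BOUNDS[0], D_BOUNDS[0], KAPPA_BOUNDS[0], 0.0])
    hi = np.array([XS_BOUNDS[1], D_BOUNDS[1], KAPPA_BOUNDS[1], float(l.max())])
    p0 = np.array([xs_hat[best], d_hat[best], kk[best], cc[best]])

    def resid_fn(p):
        return x - _sigmoid_mean(l, *p)

    best_rss = rss[best]
    best_p = p0
    try:
        sol = least_squares(resid_fn, p0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        if sol.success and 2.0 * sol.cost <= best_rss:
            best_rss = 2.0 * sol.cost
            best_p = sol.x
    except Exception:
        if not np.isfinite(best_rss):
            return None
    xs, d, kappa, c = (float(v) for v in best_p)
    params = {"x_s": xs, "d": d, "kappa": kappa, "c": c, "s": d * kappa / 2.0}
    return _finish("sigmoid", params, x - _sigmoid_mean(l, xs, d, kappa, c), sigma_floor)


def select_shape(fits: dict) -> tuple[str, float]:
    """Pick the minimum-AIC model; near-ties go to fewer parameters.

    Returns the selected model name and its AIC margin to the runner-up.
    """
    if "null" not in fits or "linear" not in fits:
        raise ValueError("null and linear fits are required")
    avail = [m for m in MODEL_ORDER if m in fits and fits[m] is not None]
    aics = {m: fits[m].aic for m in avail}
    best_aic = min(aics.values())
    winner = next(m for m in avail if aics[m] - best_aic < AIC_TIE_TOL)
    others = [aics[m] for m in avail if m != winner]
    delta = min(others) - aics[winner] if others else np.nan
    return winner, float(delta)


def fit_transcript(
    values: np.ndarray,
    latitudes: np.ndarray,
    transcript_id: str = "",
    sigma_floor: float = SIGMA_FLOOR,
    grid_c: int = 25,
    grid_k: int = 25,
    _grid: tuple | None = None,
) -> ClineFit:
    """Rescale one transcript and select its cline shape by AIC."""
    profile = rescale(values, latitudes, transcript_id)
    if profile.constant:
        fit = ModelFit("null", {"x_s": float(np.asarray(values, float)[0])}, np.nan, np.nan, 2)
        return ClineFit(transcript_id, {"null": fit}, "null", np.nan)
    fits = {
        "null": fit_null(profile, sigma_floor),
        "linear": fit_linear(profile, sigma_floor),
    }
    if np.unique(profile.l).size >= 2:
        fits["step"] = fit_step(profile, sigma_floor)
    if np.unique(profile.l).size >= 4:
        sig = fit_sigmoid(profile, sigma_floor, grid_c, grid_k, _grid)
        if sig is not None:
            fits["sigmoid"] = sig
    selected, delta = select_shape(fits)
    return ClineFit(transcript_id, fits, selected, delta)


def fit_all(
    values: pd.DataFrame,
    latitudes: np.ndarray,
    transcript_ids: list[str] | None = None,
    sigma_floor: float = SIGMA_FLOOR,
    grid_c: int = 25,
    grid_k: int = 25,
) -> pd.DataFrame:
    """Shape selection for every row of ``values`` (optionally a subset).

    Returns a tidy table with the selected model, its AIC margin, the
    per-model AICs and the selected model's parameters.
    """
    lat = np.asarray(latitudes, float)
    if transcript_ids is not None:
        values = values.loc[[t for t in transcript_ids if t in values.index]]
    l_rel = lat - lat.min()
    grid = _sigmoid_grid(l_rel, grid_c, grid_k) if np.unique(lat).size >= 4 else None

    rows = []
    for tid, row in zip(values.index, values.to_numpy(float)):
        cf = fit_transcript(row, lat, tid, sigma_floor, grid_c, grid_k, _grid=grid)
        rec = {
            "transcript_id": tid,
            "selected_model": cf.selected_model,
            "delta_aic": cf.delta_aic,
        }
        for m in MODEL_ORDER:
            rec[f"aic_{m}"] = cf.fits[m].aic if m in cf.fits else np.nan
        for key, val in cf.selected.params.items():
            rec[key] = val
        rows.append(rec)
    return pd.DataFrame(rows)
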