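"""Tracer-kinetic model-based deconvolution for first-pass perfusion.

The tissue response is modelled as a linear time-invariant system: the
myocardial concentration curve is the arterial input function (AIF) convolved
with a model impulse response function (IRF),

    C_t(t) = [C_a(. - delay) * IRF](t).

Three IRFs are supported:

* Tofts:           IRF(t) = K_trans * exp(-(K_trans/Ve) * t)
* modified Tofts:  IRF(t) = K_trans * exp(-(K_trans/Ve) * t) + Vp * delta(t)
* Fermi:           IRF(t) = F / (exp(k * (t - MTT)) + 1)

K_trans (min^-1) and F (mL/min/g) set the amplitude of the IRF and are the
quantities reported as myocardial blood flow (MBF).  Time is carried in
seconds throughout, but the Tofts-family exponent and all convolution
integrals are evaluated with t in minutes so that the per-minute rate
constants keep their conventional units; the Fermi shape parameters k (s^-1)
and MTT (s) act on t in seconds.

Fitting is bounded trust-region nonlinear least squares on the continuous
parameters, combined with an exhaustive grid search over the bolus-arrival
delay (one candidate per frame interval by default); the lowest residual sum
of squares wins, ties broken by the smaller delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .types import AifCurve, DynamicSeries, ParametricMap, TissueCurve

__all__ = [
    "MODELS",
    "TISSUE_DENSITY_G_PER_ML",
    "KineticParams",
    "KineticFit",
    "FitOptions",
    "irf",
    "forward_model",
    "fit_curve",
    "fit_map",
    "compute_mpr",
]

MODELS = ("tofts", "modified_tofts", "fermi")

#: Myocardial tissue density used to convert K_trans (min^-1, per mL tissue)
#: to a mass-normalised flow in mL/min/g.
TISSUE_DENSITY_G_PER_ML = 1.05

_SECONDS_PER_MINUTE = 60.0


@dataclass
class KineticParams:
    """Parameters of one kinetic model.

    Tofts family: ``ktrans`` (min^-1), ``ve`` (fraction), and for the
    modified model ``vp`` (fraction).  Fermi: ``f`` (mL/min/g), ``k`` (s^-1),
    ``mtt`` (s).  ``delay`` (s) is the bolus-arrival offset, common to all.
    """

    model: str
    ktrans: float | None = None
    ve: float | None = None
    vp: float | None = None
    f: float | None = None
    k: float | None = None
    mtt: float | None = None
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.model in ("tofts", "modified_tofts"):
            if self.ktrans is None or self.ve is None:
                raise ValueError(f"{self.model} requires ktrans and ve")
            if self.ktrans < 0:
                raise ValueError("ktrans must be >= 0")
            if not 0.0 < self.ve <= 1.0:
                raise ValueError("ve must lie in (0, 1]")
            if self.model == "modified_tofts":
                if self.vp is None:
                    raise ValueError("modified_tofts requires vp")
                if not 0.0 <= self.vp < 1.0:
                    raise ValueError("vp must lie in [0, 1)")
                if self.vp + self.ve > 1.0 + 1e-12:
                    raise ValueError("vp + ve must not exceed 1")
        else:  # fermi
            if self.f is None or self.k is None or self.mtt is None:
                raise ValueError("fermi requires f, k and mtt")
            if self.f < 0 or self.k < 0 or self.mtt < 0:
                raise ValueError("fermi parameters must be >= 0")

    @property
    def mbf(self) -> float:
        """Flow metric reported as MBF, in mL/min/g.

        For the Tofts family this is K_trans divided by the tissue density;
        for the Fermi model it is the amplitude F itself (not IRF(0), which
        differs by the factor 1/(1 + exp(-k*MTT))).
        """
        if self.model == "fermi":
            return float(self.f)
        return float(self.ktrans) / TISSUE_DENSITY_G_PER_ML


@dataclass
class KineticFit:
    """Result of fitting one tissue curve."""

    params: KineticParams
    mbf: float
    rss: float
    r2: float
    n_iter: int
    converged: bool


@dataclass
class FitOptions:
    """Fitting controls shared by :func:`fit_curve` and :func:`fit_map`.

    ``delay_grid``: candidate bolus-arrival delays in seconds; ``None`` means
    0 to ``delay_max`` in frame-interval steps.  ``fit_window``: upper time
    bound (s) of the samples entering the fit — ``None`` uses the whole
    acquisition (a first-pass-only analysis truncates here).  ``multistart``
    adds two perturbed restarts of the amplitude parameter and keeps the best.
    """

    delay_grid: Sequence[float] | None = None
    delay_max: float = 10.0
    fit_window: float | None = None
    multistart: bool = False
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    init: dict[str, float] = field(default_factory=dict)
    max_nfev: int | None = None


_DEFAULT_BOUNDS = {
    "ktrans": (0.0, 20.0),  # min^-1
    "ve": (1e-3, 1.0),
    "vp": (0.0, 0.5),
    "f": (0.0, 20.0),  # mL/min/g
    "k": (1e-4, 10.0),  # s^-1
    "mtt": (0.0, 30.0),  # s
}

_DEFAULT_INIT = {
    "ktrans": 1.0,
    "ve": 0.2,
    "vp": 0.05,
    "f": 1.0,
    "k": 0.3,
    "mtt": 5.0,
}

_PARAM_NAMES = {
    "tofts": ("ktrans", "ve"),
    "modified_tofts": ("ktrans", "ve", "vp"),
    "fermi": ("f", "k", "mtt"),
}


def irf(model: str, params: KineticParams, t: np.ndarray) -> np.ndarray:
    """Sample the impulse response function on a time grid ``t`` (seconds).

    Values carry per-minute units (min^-1 for the Tofts family, mL/min/g for
    Fermi), so time integrals of the IRF must be taken with t in minutes.
    The modified-Tofts Dirac term is *not* represented here; it is handled
    analytically inside :func:`forward_model`.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    t = np.asarray(t, dtype=float)
    if model in ("tofts", "modified_tofts"):
        kep_per_min = params.ktrans / params.ve
        return params.ktrans * np.exp(-kep_per_min * (t / _SECONDS_PER_MINUTE))
    # Fermi: shape parameters act on seconds; clip the exponent for stability
    z = np.clip(params.k * (t - params.mtt), -700.0, 700.0)
    return params.f / (np.exp(z) + 1.0)


def _shift(curve: np.ndarray, times: np.ndarray, delay: float) -> np.ndarray:
    """Delay a sampled curve by linear interpolation; pre-bolus samples take
    the curve's initial (baseline) value."""
    if delay == 0.0:
        return curve
    return np.interp(times - delay, times, curve, left=curve[0])


def _conv_trapz(ca: np.ndarray, h: np.ndarray, dt_min: float) -> np.ndarray:
    """Causal trapezoidal convolution of two same-grid curves.

    Equivalent to trapezoid-rule evaluation of ``int_0^t ca(t-s) h(s) ds``
    with the time step expressed in minutes.
    """
    n = ca.size
    full = np.convolve(ca, h)[:n]
    # trapezoid endpoint correction: half-weight the s=0 and s=t samples
    return dt_min * (full - 0.5 * (ca[0] * h[:n] + h[0] * ca[:n]))


def _input_curve(aif: AifCurve | np.ndarray, model: str) -> np.ndarray:
    """Tofts-family models are plasma-referenced; Fermi uses whole blood."""
    if isinstance(aif, AifCurve):
        return aif.plasma if model in ("tofts", "modified_tofts") else aif.blood
    return np.asarray(aif, dtype=float)


def forward_model(
    aif: AifCurve,
    params: KineticParams,
    times: np.ndarray | None = None,
) -> TissueCurve:
    """Generate the tissue curve predicted by a kinetic model.

    The AIF must be uniformly sampled.  The modified-Tofts Dirac term
    contributes ``Vp * C_a(t - delay)`` added analytically, never as a
    discretised spike, so the result is grid-independent at first order.
    """
    if isinstance(aif, AifCurve):
        t = aif.times
        dt = aif.dt
    else:
        if times is None:
            raise ValueError("times required when aif is a bare array")
        t = np.asarray(times, dtype=float)
        d = np.diff(t)
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("AIF must be uniformly sampled; resample first")
        dt = float(d[0])
    ca = _input_curve(aif, params.model)
    ca_d = _shift(ca, t, params.delay)
    h = irf(params.model, params, t - t[0])
    ct = _conv_trapz(ca_d, h, dt / _SECONDS_PER_MINUTE)
    if params.model == "modified_tofts":
        ct = ct + params.vp * ca_d
    return TissueCurve(times=t, conc=ct)


def _predict(model: str, theta: np.ndarray, ca_d: np.ndarray, t0: np.ndarray, dt_min: float) -> np.ndarray:
    """Fast path of :func:`forward_model` used inside the optimiser."""
    if model == "tofts":
        ktrans, ve = theta
        h = ktrans * np.exp(-(ktrans / ve) * (t0 / _SECONDS_PER_MINUTE))
        return _conv_trapz(ca_d, h, dt_min)
    if model == "modified_tofts":
        ktrans, ve, vp = theta
        h = ktrans * np.exp(-(ktrans / ve) * (t0 / _SECONDS_PER_MINUTE))
        return _conv_trapz(ca_d, h, dt_min) + vp * ca_d
    f, k, mtt = theta
    z = np.clip(k * (t0 - mtt), -700.0, 700.0)
    h = f / (np.exp(z) + 1.0)
    return _conv_trapz(ca_d, h, dt_min)


def _make_params(model: str, theta: np.ndarray, delay: float) -> KineticParams:
    names = _PARAM_NAMES[model]
    kw = dict(zip(names, (float(v) for v in theta)))
    if model == "modified_tofts" and kw["vp"] + kw["ve"] > 1.0:
        kw["ve"] = min(kw["ve"], 1.0 - kw["vp"])  # numeric guard at the bound
    return KineticParams(model=model, delay=float(delay), **kw)


def fit_curve(
    tissue: TissueCurve,
    aif: AifCurve,
    model: str,
    options: FitOptions | None = None,
) -> KineticFit:
    """Fit one tissue curve by constrained least squares + delay grid search.

    Returns a :class:`KineticFit`; an identically-flat curve short-circuits to
    ``mbf = 0`` with ``converged = False``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    opts = options or FitOptions()
    t = tissue.times
    if not np.array_equal(t, aif.times):
        raise ValueError("tissue and AIF must share the same time grid")
    if t.size < 10:
        raise ValueError("need at least 10 frames to fit")
    dt = aif.dt
    y = tissue.conc
    keep = slice(None) if opts.fit_window is None else t <= opts.fit_window

    if np.ptp(y) == 0.0:
        zero = _make_params(model, np.zeros(len(_PARAM_NAMES[model])) + 1e-3, 0.0)
        if model in ("tofts", "modified_tofts"):
            zero = replace(zero, ktrans=0.0, ve=1e-3, vp=0.0 if model == "modified_tofts" else None)
        else:
            zero = replace(zero, f=0.0)
        return KineticFit(params=zero, mbf=0.0, rss=float(np.sum((y - y.mean()) ** 2)),
                          r2=0.0, n_iter=0, converged=False)

    names = _PARAM_NAMES[model]
    vp_pinned = model == "modified_tofts" and opts.bounds.get("vp", (None, 1))[1] == 0.0
    fit_model = "tofts" if vp_pinned else model
    fit_names = _PARAM_NAMES[fit_model]
    lb = np.array([opts.bounds.get(n, _DEFAULT_BOUNDS[n])[0] for n in fit_names])
    ub = np.array([opts.bounds.get(n, _DEFAULT_BOUNDS[n])[1] for n in fit_names])
    x0 = np.clip(np.array([opts.init.get(n, _DEFAULT_INIT[n]) for n in fit_names]), lb, ub)

    if opts.delay_grid is not None:
        delays = np.asarray(list(opts.delay_grid), dtype=float)
    else:
        delays = np.arange(0.0, opts.delay_max + 0.5 * dt, dt)

    ca = _input_curve(aif, model)
    t0 = t - t[0]
    dt_min = dt / _SECONDS_PER_MINUTE
    yk = y[keep]

    starts = [x0]
    if opts.multistart:
        for scale in (0.25, 4.0):
            s = x0.copy()
            s[0] = np.clip(x0[0] * scale, lb[0], ub[0])
            starts.append(s)

    best = None
    for delay in delays:
        ca_d = _shift(ca, t, delay)

        def resid(theta, _ca=ca_d):
            return _predict(fit_model, theta, _ca, t0, dt_min)[keep] - yk

        for s in starts:
            sol = least_squares(resid, s, bounds=(lb, ub), method="trf",
                                max_nfev=opts.max_nfev)
            rss = float(np.sum(sol.fun**2))
            # ties broken by lowest rss, then lowest delay (grid is ascending)
            if best is None or rss < best[0] - 1e-15 * max(1.0, best[0]):
                best = (rss, delay, sol)

    rss, delay, sol = best
    theta = sol.x
    if vp_pinned:
        theta = np.array([theta[0], theta[1], 0.0])
    params = _make_params(model, theta, delay)
    ss_tot = float(np.sum((yk - yk.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 0.0
    return KineticFit(params=params, mbf=params.mbf, rss=rss, r2=r2,
                      n_iter=int(sol.nfev), converged=bool(sol.success))


def fit_map(
    series: DynamicSeries,
    aif: AifCurve,
    model: str,
    mask: np.ndarray,
    options: FitOptions | None = None,
) -> ParametricMap:
    """Fit every masked pixel of a concentration-domain series.

    Non-convergent pixels are set to NaN (missing, not zero) and counted in
    ``meta['n_failed']``; identically-flat pixels report 0 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        mask = mask[:, :, np.newaxis]
    if mask.shape != series.data.shape[:3]:
        raise ValueError("mask shape must match the series grid")
    if not mask.any():
        raise ValueError("empty myocardial mask")
    values = np.full(mask.shape, np.nan)
    quality = np.full(mask.shape, np.nan)
    n_failed = 0
    idx = np.argwhere(mask)
    for i, j, s in idx:
        curve = TissueCurve(times=series.frame_times, conc=series.data[i, j, s, :])
        fit = fit_curve(curve, aif, model, options)
        flat = np.ptp(curve.conc) == 0.0
        if fit.converged or flat:
            values[i, j, s] = fit.mbf
            quality[i, j, s] = fit.r2
        else:
            n_failed += 1
    return ParametricMap(values=values, mask=mask, quality=quality,
                         spacing=series.spacing,
                         meta={"model": model, "n_pixels": int(idx.shape[0]),
                               "n_failed": n_failed})


def compute_mpr(
    stress: ParametricMap,
    rest: ParametricMap,
    rest_floor: float = 0.1,
) -> ParametricMap:
    """Pixel-wise myocardial perfusion reserve = stress MBF / rest MBF.

    Rest pixels at or below ``rest_floor`` (mL/min/g) are excluded from the
    MPR mask and counted in ``meta['n_below_floor']``.  Segment-level MPR is
    computed separately as the ratio of segment means (see segmentation
    module); on heterogeneous tissue the two differ.
    """
    if stress.values.shape != rest.values.shape:
        raise ValueError("stress and rest maps must share a grid")
    joint = stress.mask & rest.mask
    if not joint.any():
        raise ValueError("stress and rest masks are disjoint")
    ok = joint & np.isfinite(stress.values) & np.isfinite(rest.values)
    above = ok & (rest.values > rest_floor)
    values = np.full(stress.values.shape, np.nan)
    values[above] = stress.values[above] / rest.values[above]
    return ParametricMap(values=values, mask=above, spacing=stress.spacing,
                         meta={"rest_floor": rest_floor,
                               "n_below_floor": int(np.count_nonzero(ok & ~above))})
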