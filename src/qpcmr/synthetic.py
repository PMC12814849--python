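"""Synthetic perfusion inputs: AIFs, tissue curves, phantoms, paired cohorts.

Everything the pipeline consumes can be generated here with known ground
truth: a gamma-variate first-pass arterial input function with a delayed
recirculation copy, tissue curves produced by the kinetic forward models,
multi-slice annular ("ring") phantoms with per-AHA-segment true MBF, and
statistically simulated paired two-modality cohorts with configurable
inter-modality bias and noise.

Defaults emulate a 60 s one-frame-per-heartbeat first-pass acquisition with
a ~5 mM blood-pool peak, stress flows of ~3 mL/min/g against ~1 mL/min/g at
rest, and a paired cohort whose latent flows follow the reference-modality
stress/rest distributions with a 0.31 mL/min/g test-modality bias and a
0.70 mL/min/g paired-difference SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

from . import kinetics
from .kinetics import KineticParams, TISSUE_DENSITY_G_PER_ML
from .segmentation import SEGMENT_BASE, SEGMENTS_PER_LEVEL, SLICE_LEVELS, aha16_label
from .types import AifCurve, DynamicSeries, ParametricMap, TissueCurve

__all__ = [
    "AifModelParams",
    "PhantomSpec",
    "CohortSpec",
    "PhantomResult",
    "gamma_variate_aif",
    "simulate_tissue_curve",
    "uniform_sector_truth",
    "make_phantom",
    "simulate_paired_cohort",
]

#: Floor applied to simulated cohort MBF values (physiological positivity).
MBF_TRUNCATION_FLOOR = 0.05


@dataclass
class AifModelParams:
    """Gamma-variate first-pass bolus with a delayed, scaled recirculation.

    c(t) = baseline + A ((t-t0)/beta)^alpha exp(-(t-t0)/beta)
                    + recirc_fraction * [same, shifted by recirc_delay]

    ``amplitude`` sets the concentration scale (mM); the curve peaks at
    t0 + alpha*beta.  Defaults give a ~5 mM whole-blood peak near t = 11 s.
    """

    amplitude: float = 6.0
    t0: float = 5.0
    alpha: float = 2.5
    beta: float = 2.5
    recirc_fraction: float = 0.15
    recirc_delay: float = 20.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if not 0.0 <= self.recirc_fraction < 1.0:
            raise ValueError("recirc_fraction must lie in [0, 1)")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    @property
    def first_pass_area(self) -> float:
        """Analytic time-integral (mM*s) of the first pass above baseline."""
        return self.amplitude * self.beta * gamma_fn(self.alpha + 1.0)


def _gamma_variate(t: np.ndarray, a: float, t0: float, alpha: float, beta: float) -> np.ndarray:
    tau = np.maximum(t - t0, 0.0) / beta
    with np.errstate(invalid="ignore"):
        out = a * tau**alpha * np.exp(-tau)
    return np.where(t > t0, out, 0.0)


def gamma_variate_aif(
    params: AifModelParams,
    frame_times,
    hematocrit: float | None = 0.42,
) -> AifCurve:
    """Sample the bolus model on a time grid; returns whole-blood and
    hematocrit-corrected plasma curves."""
    t = np.asarray(frame_times, dtype=float)
    first = _gamma_variate(t, params.amplitude, params.t0, params.alpha, params.beta)
    recirc = params.recirc_fraction * _gamma_variate(
        t, params.amplitude, params.t0 + params.recirc_delay, params.alpha, params.beta
    )
    blood = params.baseline + first + recirc
    return AifCurve(times=t, blood=blood, hematocrit=hematocrit)


def simulate_tissue_curve(
    aif: AifCurve,
    model: str,
    params: KineticParams,
    delay: float | None = None,
) -> TissueCurve:
    """Tissue curve for one kinetic parameter set (thin wrapper around the
    kinetics forward model; bitwise-identical to it on the same grid)."""
    if model != params.model:
        params = replace(params, model=model)
    if delay is not None:
        params = replace(params, delay=delay)
    return kinetics.forward_model(aif, params)


def _params_for_mbf(model: str, mbf: float, ve: float = 0.3, vp: float = 0.05,
                    k: float = 0.35, mtt: float = 6.0, delay: float = 0.0) -> KineticParams:
    """Kinetic parameters whose reported MBF equals ``mbf`` exactly."""
    if model == "fermi":
        return KineticParams(model=model, f=mbf, k=k, mtt=mtt, delay=delay)
    kw = dict(ktrans=mbf * TISSUE_DENSITY_G_PER_ML, ve=ve, delay=delay)
    if model == "modified_tofts":
        kw["vp"] = vp
    return KineticParams(model=model, **kw)


def uniform_sector_truth(
    model: str,
    stress_mbf: float = 3.0,
    rest_mbf: float = 1.0,
    delay: float = 0.0,
    abnormal_segments: Mapping[int, float] | None = None,
    **model_kwargs,
) -> dict[str, dict[int, KineticParams]]:
    """Per-state, per-AHA-segment true parameters for :class:`PhantomSpec`.

    All 16 segments share ``stress_mbf``/``rest_mbf`` unless overridden in
    ``abnormal_segments`` (segment id -> stress MBF), which emulates a
    hypoperfused coronary territory.
    """
    truth: dict[str, dict[int, KineticParams]] = {"stress": {}, "rest": {}}
    for seg in range(1, 17):
        s_mbf = (abnormal_segments or {}).get(seg, stress_mbf)
        truth["stress"][seg] = _params_for_mbf(model, s_mbf, delay=delay, **model_kwargs)
        truth["rest"][seg] = _params_for_mbf(model, rest_mbf, delay=delay, **model_kwargs)
    return truth


@dataclass
class PhantomSpec:
    """Geometry, truth and noise of an annular myocardial phantom.

    The myocardium is a ring (endo/epi radii in mm) around a circular
    blood pool carrying the AIF; slices are labelled basal/mid/apical in
    order.  ``sector_truth`` maps state -> AHA segment id -> KineticParams;
    ``noise_sd`` is additive i.i.d. Gaussian noise in the concentration
    domain (mM).
    """

    grid: tuple[int, int] = (48, 48)
    spacing: tuple[float, float] = (1.5, 1.5)
    n_slices: int = 3
    endo_radius: float = 8.0
    epi_radius: float = 16.0
    blood_pool_radius: float = 6.0
    rv_insertion_angle: float = 0.0
    sector_truth: dict[str, dict[int, KineticParams]] = field(default_factory=dict)
    aif: AifModelParams = field(default_factory=AifModelParams)
    hematocrit: float = 0.42
    frame_times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 60.0, 1.0))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.endo_radius < self.epi_radius:
            raise ValueError("require epi_radius > endo_radius > 0")
        t = np.asarray(self.frame_times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("frame_times must be strictly increasing")
        self.frame_times = t
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_slices < 1 or self.n_slices > 3:
            raise ValueError("n_slices must be 1-3 (basal, mid, apical)")


@dataclass
class PhantomResult:
    stress: DynamicSeries
    rest: DynamicSeries
    truth_stress: ParametricMap
    truth_rest: ParametricMap
    labels: np.ndarray
    mask: np.ndarray
    aif: AifCurve
    blood_center: tuple[float, float]
    slice_levels: list[str]


def _annulus(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    ny, nx = spec.grid
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot((yy - cy) * spec.spacing[0], (xx - cx) * spec.spacing[1])
    myo = (rr >= spec.endo_radius) & (rr <= spec.epi_radius)
    blood = rr <= spec.blood_pool_radius
    return myo, blood, (cy, cx)


def make_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build stress and rest concentration-domain dynamic series.

    Every myocardial pixel's time course is its AHA sector's forward-model
    curve plus i.i.d. Gaussian noise; blood-pool pixels carry the (noisy)
    blood AIF; ground-truth per-pixel MBF maps and the segment label map are
    returned alongside.  Reproducible under a fixed seed.
    """
    if not spec.sector_truth:
        raise ValueError("sector_truth must be provided (see uniform_sector_truth)")
    for state in ("stress", "rest"):
        if state not in spec.sector_truth:
            raise ValueError(f"sector_truth missing state {state!r}")
    myo2d, blood2d, center = _annulus(spec)
    levels = list(SLICE_LEVELS[: spec.n_slices])
    aif = gamma_variate_aif(spec.aif, spec.frame_times, spec.hematocrit)
    rng = np.random.default_rng(spec.seed)

    ny, nx = spec.grid
    nt = spec.frame_times.size
    labels3d = np.zeros((ny, nx, spec.n_slices), dtype=int)
    mask3d = np.zeros((ny, nx, spec.n_slices), dtype=bool)
    series = {s: np.zeros((ny, nx, spec.n_slices, nt)) for s in ("stress", "rest")}
    truth = {s: np.full((ny, nx, spec.n_slices), np.nan) for s in ("stress", "rest")}

    for isl, level in enumerate(levels):
        lab = aha16_label(myo2d, spec.rv_insertion_angle, level, center=center)
        labels3d[:, :, isl] = lab
        mask3d[:, :, isl] = myo2d
        needed = set(range(SEGMENT_BASE[level],
                           SEGMENT_BASE[level] + SEGMENTS_PER_LEVEL[level]))
        for state in ("stress", "rest"):
            have = set(spec.sector_truth[state])
            if not needed <= have:
                raise ValueError(
                    f"sector_truth[{state!r}] missing segments {sorted(needed - have)}"
                )
            for seg in needed:
                params = spec.sector_truth[state][seg]
                curve = kinetics.forward_model(aif, params).conc
                sel = lab == seg
                series[state][sel, isl, :] = curve
                truth[state][sel, isl] = params.mbf
            series[state][blood2d, isl, :] = aif.blood

    for state in ("stress", "rest"):
        if spec.noise_sd > 0:
            series[state] = series[state] + rng.normal(
                0.0, spec.noise_sd, size=series[state].shape
            )

    meta = {"domain": "concentration", "seed": spec.seed}
    return PhantomResult(
        stress=DynamicSeries(series["stress"], spec.frame_times, spec.spacing,
                             {**meta, "state": "stress"}),
        rest=DynamicSeries(series["rest"], spec.frame_times, spec.spacing,
                           {**meta, "state": "rest"}),
        truth_stress=ParametricMap(truth["stress"], mask3d, spacing=spec.spacing),
        truth_rest=ParametricMap(truth["rest"], mask3d, spacing=spec.spacing),
        labels=labels3d,
        mask=mask3d,
        aif=aif,
        blood_center=center,
        slice_levels=levels,
    )


@dataclass
class CohortSpec:
    """Statistical stand-in for a paired two-modality perfusion study.

    Per subject a latent true stress and rest MBF are drawn from normals
    (truncated at 0.05 mL/min/g); the test arm (CMR) observes truth +
    ``cmr_bias`` + Gaussian noise, the reference arm (PET) truth + noise.
    Defaults: latent stress 2.83 +/- 0.73 and rest 1.46 +/- 0.45 mL/min/g
    (reference-modality participant-level distributions), bias 0.31 and
    per-arm noise 0.495 so the paired-difference SD is ~0.70 mL/min/g.
    """

    n_subjects: int = 39
    stress_mean: float = 2.83
    stress_sd: float = 0.73
    rest_mean: float = 1.46
    rest_sd: float = 0.45
    cmr_bias: float = 0.31
    cmr_noise_sd: float = 0.495
    pet_noise_sd: float = 0.495
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        for name in ("stress_sd", "rest_sd", "cmr_noise_sd", "pet_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _trunc(v: np.ndarray) -> np.ndarray:
    return np.maximum(v, MBF_TRUNCATION_FLOOR)


def simulate_paired_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a paired cohort; returns one row per subject with columns
    ``pet_stress, cmr_stress, pet_rest, cmr_rest, pet_mpr, cmr_mpr`` plus the
    latent truths (``true_stress, true_rest``)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    true_s = _trunc(rng.normal(spec.stress_mean, spec.stress_sd, n))
    true_r = _trunc(rng.normal(spec.rest_mean, spec.rest_sd, n))
    pet_s = _trunc(true_s + rng.normal(0.0, spec.pet_noise_sd, n))
    pet_r = _trunc(true_r + rng.normal(0.0, spec.pet_noise_sd, n))
    cmr_s = _trunc(true_s + spec.cmr_bias + rng.normal(0.0, spec.cmr_noise_sd, n))
    cmr_r = _trunc(true_r + spec.cmr_bias + rng.normal(0.0, spec.cmr_noise_sd, n))
    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "true_stress": true_s, "true_rest": true_r,
        "pet_stress": pet_s, "cmr_stress": cmr_s,
        "pet_rest": pet_r, "cmr_rest": cmr_r,
        "pet_mpr": pet_s / pet_r, "cmr_mpr": cmr_s / cmr_r,
    })
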