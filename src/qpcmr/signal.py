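"""Saturation-recovery signal <-> gadolinium concentration conversion.

A dual-sequence first-pass acquisition interleaves low-resolution images with
a short saturation delay (TD ~ 25 ms, keeping the blood-pool signal in the
quasi-linear regime for the AIF) and high-resolution images with a longer
delay (TD ~ 110 ms) for tissue.  Under an ideal saturation-recovery spoiled
gradient echo model, the signal normalised by its pre-contrast baseline is

    S(C) = (1 - exp(-TD * (R10 + r1 * C))) / (1 - exp(-TD * R10)),

with R10 = 1/T10 the pre-contrast relaxation rate and r1 the contrast-agent
relaxivity.  S(0) = 1, S is strictly increasing in C and saturates toward
1 / (1 - exp(-TD * R10)); inversion is closed-form logarithmic.  Readout
trains and flip-angle effects are deliberately ignored (see package docs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AifCurve, DynamicSeries

__all__ = [
    "SequenceParams",
    "AifRoi",
    "sr_signal",
    "inverse_sr_signal",
    "concentration_from_signal",
    "pd_normalize",
    "extract_aif",
]


@dataclass
class SequenceParams:
    """Acquisition constants of one image stream.

    ``saturation_delay`` in seconds (0.025 low-res / 0.110 high-res by
    convention); ``relaxivity_r1`` in L mmol^-1 s^-1 (default 3.5, typical of
    Gd-DOTA at 3 T); ``baseline_T1`` in seconds; ``baseline_frames`` counts
    the pre-contrast frames averaged into the normalisation baseline.
    """

    saturation_delay: float
    relaxivity_r1: float = 3.5
    baseline_T1: float = 1.2
    baseline_frames: int = 3

    def __post_init__(self) -> None:
        if self.saturation_delay <= 0:
            raise ValueError("saturation_delay must be > 0")
        if self.relaxivity_r1 <= 0:
            raise ValueError("relaxivity_r1 must be > 0")
        if self.baseline_T1 <= 0:
            raise ValueError("baseline_T1 must be > 0")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")

    @property
    def ceiling(self) -> float:
        """Saturation ceiling of the baseline-normalised signal."""
        return 1.0 / -np.expm1(-self.saturation_delay / self.baseline_T1)


def sr_signal(conc, seq: SequenceParams) -> np.ndarray:
    """Forward saturation-recovery model: concentration (mM) -> normalised SI."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    td = seq.saturation_delay
    r10 = 1.0 / seq.baseline_T1
    return -np.expm1(-td * (r10 + seq.relaxivity_r1 * c)) / -np.expm1(-td * r10)


def inverse_sr_signal(signal, seq: SequenceParams) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`sr_signal`; returns ``(conc, invertible)``.

    Samples at or above the saturation ceiling cannot be inverted and are
    returned as NaN with ``invertible = False``; negative concentrations
    (signal below baseline, e.g. noise) are clipped to 0 by the caller.
    """
    s = np.asarray(signal, dtype=float)
    td = seq.saturation_delay
    r10 = 1.0 / seq.baseline_T1
    arg = 1.0 + s * np.expm1(-td * r10)  # = exp(-td*(r10 + r1*c))
    # arg collapses to ~0 at the ceiling; the epsilon absorbs fp round-off
    invertible = np.isfinite(s) & (arg > 1e-12)
    conc = np.full(s.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc_ok = (-np.log(arg, where=invertible, out=np.full(s.shape, np.nan)) / td - r10) / seq.relaxivity_r1
    conc[invertible] = conc_ok[invertible]
    return conc, invertible


def concentration_from_signal(
    series: DynamicSeries, seq: SequenceParams
) -> tuple[DynamicSeries, dict]:
    """Convert a signal-intensity series to gadolinium concentration.

    Each pixel is normalised by the mean of its first ``baseline_frames``
    pre-contrast frames and pushed through the closed-form inversion of the
    saturation-recovery model.  Negative concentrations are clipped to zero
    (count reported); pixels with non-positive baseline or any sample at the
    saturation ceiling are flagged invalid and excluded from ``info['valid']``.
    """
    nb = seq.baseline_frames
    if series.n_frames <= nb:
        raise ValueError("series shorter than the baseline window")
    baseline = series.data[..., :nb].mean(axis=-1)
    valid = baseline > 0
    norm = np.full(series.data.shape, np.nan)
    norm[valid] = series.data[valid] / baseline[valid][..., np.newaxis]
    conc, invertible = inverse_sr_signal(norm, seq)
    noninvertible_px = valid & ~invertible.all(axis=-1)
    valid = valid & invertible.all(axis=-1)
    # clip negatives (noise below baseline); ignore fp round-off in the count
    n_clipped = int(np.count_nonzero(conc[valid] < -1e-9))
    conc = np.where(conc < 0, 0.0, conc)
    conc[~valid] = np.nan
    out = DynamicSeries(
        data=conc, frame_times=series.frame_times, spacing=series.spacing,
        meta={**series.meta, "domain": "concentration"},
    )
    info = {
        "valid": valid,
        "n_invalid_baseline": int(np.count_nonzero(baseline <= 0)),
        "n_noninvertible": int(np.count_nonzero(noninvertible_px)),
        "n_clipped": n_clipped,
    }
    return out, info


def pd_normalize(series: DynamicSeries, pd_map: np.ndarray, eps: float = 1e-9) -> DynamicSeries:
    """Divide out coil-sensitivity shading using a proton-density map.

    ``pd_map`` must match the spatial grid; pixels with ``pd <= eps`` become
    NaN (excluded from any downstream mask).
    """
    pd = np.asarray(pd_map, dtype=float)
    if pd.ndim == 2:
        pd = pd[:, :, np.newaxis]
    if pd.shape != series.data.shape[:3]:
        raise ValueError("pd_map grid does not match the series")
    if not np.any(pd > eps):
        raise ValueError("proton-density map is entirely non-positive")
    ok = pd > eps
    data = np.full(series.data.shape, np.nan)
    data[ok] = series.data[ok] / pd[ok][..., np.newaxis]
    return DynamicSeries(data=data, frame_times=series.frame_times,
                         spacing=series.spacing,
                         meta={**series.meta, "pd_normalized": True})


@dataclass
class AifRoi:
    """Circular blood-pool ROI: ``center`` = (row, col) in pixels, ``diameter``
    in mm (10 mm by convention), placed on one slice."""

    center: tuple[float, float]
    diameter: float = 10.0
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be > 0")


def roi_mask(roi: AifRoi, shape: tuple[int, int], spacing: tuple[float, float]) -> np.ndarray:
    """Boolean in-disk mask: a pixel is included if its center lies within
    diameter/2 of the ROI center (distances in mm)."""
    ny, nx = shape
    cy, cx = roi.center
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = ((yy - cy) * spacing[0]) ** 2 + ((xx - cx) * spacing[1]) ** 2
    return d2 <= (roi.diameter / 2.0) ** 2


def extract_aif(
    series: DynamicSeries, roi: AifRoi, hematocrit: float
) -> AifCurve:
    """Average a concentration-domain series over the blood-pool ROI.

    Returns the whole-blood curve and its plasma correction
    ``blood / (1 - hematocrit)`` (Tofts-family models are plasma-referenced;
    the Fermi model consumes the blood curve).
    """
    if not 0.0 < hematocrit < 1.0:
        raise ValueError("hematocrit must lie in (0, 1)")
    ny, nx = series.data.shape[:2]
    cy, cx = roi.center
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError("AIF ROI center lies outside the image")
    if not 0 <= roi.slice_index < series.n_slices:
        raise ValueError("AIF ROI slice index out of range")
    mask = roi_mask(roi, (ny, nx), series.spacing)
    if not mask.any():
        # degenerate ROI smaller than one pixel pitch: take the nearest pixel
        mask[int(round(cy)), int(round(cx))] = True
    blood = series.data[:, :, roi.slice_index, :][mask].mean(axis=0)
    return AifCurve(times=series.frame_times, blood=blood, hematocrit=hematocrit)
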