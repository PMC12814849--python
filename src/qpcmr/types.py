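"""Shared in-memory containers for the perfusion pipeline.

Array convention: dynamic image data is indexed ``(row, col, slice, time)``;
times are in seconds, in-plane pixel spacing in millimetres, gadolinium
concentration in mM, and myocardial blood flow (MBF) in mL/min/g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "DynamicSeries",
    "AifCurve",
    "TissueCurve",
    "ParametricMap",
]


def _as_times(frame_times) -> np.ndarray:
    t = np.asarray(frame_times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("frame_times must be a 1-D array with >= 2 entries")
    if not np.all(np.diff(t) > 0):
        raise ValueError("frame_times must be strictly increasing")
    return t


@dataclass
class DynamicSeries:
    """A registered, time-resolved short-axis image stack.

    ``data`` has shape ``(ny, nx, n_slices, n_frames)``; a 3-D array is
    promoted to a single-slice stack.  ``spacing`` is the in-plane pixel
    spacing ``(dy, dx)`` in mm.
    """

    data: np.ndarray
    frame_times: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[:, :, np.newaxis, :]
        if self.data.ndim != 4:
            raise ValueError("data must be (ny, nx, n_slices, n_frames)")
        self.frame_times = _as_times(self.frame_times)
        if self.data.shape[-1] != self.frame_times.size:
            raise ValueError(
                f"data has {self.data.shape[-1]} frames but "
                f"{self.frame_times.size} frame times were given"
            )
        if min(self.spacing) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def dt(self) -> float:
        """Frame interval in seconds; raises if sampling is non-uniform."""
        d = np.diff(self.frame_times)
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frame times are not uniformly spaced")
        return float(d[0])


@dataclass
class AifCurve:
    """Arterial input function sampled on the acquisition time grid.

    ``blood`` is whole-blood gadolinium concentration (mM); ``plasma`` is the
    hematocrit-corrected plasma concentration ``blood / (1 - hct)`` used by
    plasma-referenced (Tofts-family) models.
    """

    times: np.ndarray
    blood: np.ndarray
    plasma: np.ndarray | None = None
    hematocrit: float | None = None

    def __post_init__(self) -> None:
        self.times = _as_times(self.times)
        self.blood = np.asarray(self.blood, dtype=float)
        if self.blood.shape != self.times.shape:
            raise ValueError("blood curve and times must have the same length")
        if not np.all(np.isfinite(self.blood)):
            raise ValueError("AIF contains non-finite values")
        if self.plasma is None:
            if self.hematocrit is not None:
                if not 0.0 < self.hematocrit < 1.0:
                    raise ValueError("hematocrit must lie in (0, 1)")
                self.plasma = self.blood / (1.0 - self.hematocrit)
            else:
                self.plasma = self.blood.copy()
        else:
            self.plasma = np.asarray(self.plasma, dtype=float)

    @property
    def dt(self) -> float:
        d = np.diff(self.times)
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("AIF is not uniformly sampled")
        return float(d[0])


@dataclass
class TissueCurve:
    """Myocardial gadolinium-concentration curve (mM) on a time grid."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_times(self.times)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.shape != self.times.shape:
            raise ValueError("conc and times must have the same length")


@dataclass
class ParametricMap:
    """Pixel-wise MBF (mL/min/g) or MPR (ratio) over a myocardial mask.

    ``values`` is NaN outside ``mask`` and for pixels whose fit failed;
    ``quality`` carries the per-pixel coefficient of determination.
    """

    values: np.ndarray
    mask: np.ndarray
    quality: np.ndarray | None = None
    spacing: tuple[float, float] = (1.0, 1.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim == 2:
            self.values = self.values[:, :, np.newaxis]
            self.mask = self.mask[:, :, np.newaxis]
            if self.quality is not None:
                self.quality = np.asarray(self.quality, dtype=float)[:, :, np.newaxis]
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape != self.values.shape:
                raise ValueError("quality and values shapes differ")

    @property
    def masked_values(self) -> np.ndarray:
        """Finite values on the mask, flattened."""
        v = self.values[self.mask]
        return v[np.isfinite(v)]
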