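"""AHA 16-segment analysis of short-axis perfusion maps.

The standard American Heart Association model partitions the left-ventricular
myocardium into 6 basal, 6 mid-cavity and 4 apical segments by equal angular
sectors measured from the anterior right-ventricular insertion point.
Segments group into the three standard coronary territories:

    LAD = {1, 2, 7, 8, 13, 14}   RCA = {3, 4, 9, 10, 15}   LCX = {5, 6, 11, 12, 16}

Angles are measured counterclockwise from the RV-insertion ray, viewing the
short axis in standard orientation, so segment numbering runs anterior ->
anteroseptal -> inferoseptal -> inferior -> inferolateral -> anterolateral.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .types import ParametricMap

__all__ = [
    "SLICE_LEVELS",
    "SEGMENTS_PER_LEVEL",
    "SEGMENT_BASE",
    "TERRITORIES",
    "aha16_label",
    "aggregate",
    "segment_thickness",
    "apply_exclusions",
]

SLICE_LEVELS = ("basal", "mid", "apical")
SEGMENTS_PER_LEVEL = {"basal": 6, "mid": 6, "apical": 4}
SEGMENT_BASE = {"basal": 1, "mid": 7, "apical": 13}

TERRITORIES = {
    "LAD": frozenset({1, 2, 7, 8, 13, 14}),
    "RCA": frozenset({3, 4, 9, 10, 15}),
    "LCX": frozenset({5, 6, 11, 12, 16}),
}
_SEGMENT_TO_TERRITORY = {s: t for t, segs in TERRITORIES.items() for s in segs}


def territory_of(segment_id: int) -> str:
    """Coronary territory (LAD/RCA/LCX) of an AHA segment id (1-16)."""
    return _SEGMENT_TO_TERRITORY[int(segment_id)]


def aha16_label(
    mask: np.ndarray,
    rv_insertion_angle: float,
    slice_level: str,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Label an annular 2-D myocardial mask with AHA segment ids.

    ``rv_insertion_angle`` is the angle (degrees, counterclockwise from the
    +x image axis) of the anterior RV insertion ray; segments are equal
    angular sectors counterclockwise from that ray.  ``center`` defaults to
    the mask centroid.  Returns an int array, 0 outside the mask.
    """
    if slice_level not in SLICE_LEVELS:
        raise ValueError(f"slice_level must be one of {SLICE_LEVELS}")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("aha16_label expects a single 2-D slice mask")
    if not mask.any():
        raise ValueError("empty myocardial mask")
    n_seg = SEGMENTS_PER_LEVEL[slice_level]
    base = SEGMENT_BASE[slice_level]
    if center is None:
        yy, xx = np.nonzero(mask)
        center = (yy.mean(), xx.mean())
    cy, cx = center
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    # image rows grow downward; use -dy so angles are CCW in standard view
    theta = np.degrees(np.arctan2(-(yy - cy), xx - cx))
    rel = np.mod(theta - rv_insertion_angle, 360.0)
    sector = np.floor(rel / (360.0 / n_seg)).astype(int)
    sector = np.clip(sector, 0, n_seg - 1)  # guard rel == 360 after fp round
    labels = np.where(mask, base + sector, 0)
    return labels


def aggregate(
    pmap: ParametricMap,
    labels: np.ndarray,
    subject: str = "subject",
    state: str = "stress",
    participant_from: str = "pixels",
) -> pd.DataFrame:
    """Aggregate a parametric map to segment / vessel / participant rows.

    ``labels`` carries AHA ids per pixel (0 = background), shaped like the
    map (2-D or 3-D).  Segment value = mean over its pixels; vessel value =
    mean over all pixels of the territory's segments; participant value =
    mean over all labelled pixels (``participant_from='segments'`` switches
    to the unweighted mean of segment means).  Segments present in the label
    map but with no finite map values are emitted with ``n_pixels = 0`` and
    NaN, flagged for exclusion accounting downstream.
    """
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[:, :, np.newaxis]
    if labels.shape != pmap.values.shape:
        raise ValueError("labels grid does not match the map")
    vals = pmap.values
    finite = np.isfinite(vals) & pmap.mask & (labels > 0)

    rows = []
    for seg in sorted(set(labels[labels > 0].ravel().tolist())):
        sel = finite & (labels == seg)
        n = int(np.count_nonzero(sel))
        level = "basal" if seg <= 6 else ("mid" if seg <= 12 else "apical")
        rows.append({
            "subject": subject, "state": state, "level": level,
            "segment": int(seg), "territory": territory_of(seg),
            "value": float(vals[sel].mean()) if n else np.nan,
            "n_pixels": n,
            "unit_level": "segment",
        })
    seg_df = pd.DataFrame(rows)

    vessel_rows = []
    for terr, segs in TERRITORIES.items():
        sel = finite & np.isin(labels, list(segs))
        n = int(np.count_nonzero(sel))
        if n == 0 and not np.isin(labels, list(segs)).any():
            continue
        vessel_rows.append({
            "subject": subject, "state": state, "level": "all",
            "segment": None, "territory": terr,
            "value": float(vals[sel].mean()) if n else np.nan,
            "n_pixels": n, "unit_level": "vessel",
        })

    if participant_from == "pixels":
        part_val = float(vals[finite].mean()) if finite.any() else np.nan
        part_n = int(np.count_nonzero(finite))
    elif participant_from == "segments":
        seg_means = seg_df.loc[seg_df.n_pixels > 0, "value"]
        part_val = float(seg_means.mean()) if len(seg_means) else np.nan
        part_n = int(seg_df.n_pixels.sum())
    else:
        raise ValueError("participant_from must be 'pixels' or 'segments'")
    part_row = [{
        "subject": subject, "state": state, "level": "all", "segment": None,
        "territory": "global", "value": part_val, "n_pixels": part_n,
        "unit_level": "participant",
    }]
    return pd.concat([seg_df, pd.DataFrame(vessel_rows), pd.DataFrame(part_row)],
                     ignore_index=True)


def segment_thickness(
    mask: np.ndarray,
    labels: np.ndarray,
    spacing: tuple[float, float],
    center: tuple[float, float] | None = None,
) -> dict[int, float]:
    """Per-segment myocardial thickness (mm) as the radial extent of the
    masked annulus within each segment's sector, plus one pixel pitch so a
    single-pixel-thick wall reports one pixel of thickness.  An externally
    measured per-segment thickness table should override this estimate when
    available."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels)
    if center is None:
        yy, xx = np.nonzero(mask)
        center = (yy.mean(), xx.mean())
    cy, cx = center
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    rr = np.hypot((yy - cy) * spacing[0], (xx - cx) * spacing[1])
    pitch = float(np.mean(spacing))
    out: dict[int, float] = {}
    for seg in sorted(set(labels[labels > 0].ravel().tolist())):
        sel = mask & (labels == seg)
        if not sel.any():
            out[int(seg)] = 0.0
            continue
        out[int(seg)] = float(rr[sel].max() - rr[sel].min() + pitch)
    return out


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 1 decimal, matching clinical reporting."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def apply_exclusions(
    table: pd.DataFrame,
    registration_flags=None,
    thickness=None,
    min_thickness: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Apply the segment-exclusion rules and account for them.

    Segment rows flagged for poor registration, or whose myocardial thickness
    is below ``min_thickness`` mm (infarct thinning), are marked excluded.  A
    doubly-flagged segment counts once, with reason precedence
    ``poor_registration`` over ``thin_myocardium``.

    ``registration_flags``: boolean per-row array/Series, or a set of
    ``(subject, state, segment)`` keys, or a set of segment ids.
    ``thickness``: per-row array/Series of mm, or a ``{segment: mm}`` dict.
    Returns ``(table_with_flags, summary)``; the summary reports counts and
    percentages (half-up, 1 decimal) per reason and in total.
    """
    table = table.copy()
    n = len(table)
    poor = np.zeros(n, dtype=bool)
    if registration_flags is not None:
        if isinstance(registration_flags, (set, frozenset)):
            for i, row in enumerate(table.itertuples(index=False)):
                key3 = (row.subject, row.state, row.segment)
                poor[i] = key3 in registration_flags or row.segment in registration_flags
        else:
            poor = np.asarray(registration_flags, dtype=bool)
            if poor.shape != (n,):
                raise ValueError("registration_flags length must match table")
    thin = np.zeros(n, dtype=bool)
    if thickness is not None:
        if isinstance(thickness, dict):
            th = np.array([thickness.get(row.segment, np.inf)
                           for row in table.itertuples(index=False)], dtype=float)
        else:
            th = np.asarray(thickness, dtype=float)
            if th.shape != (n,):
                raise ValueError("thickness length must match table")
        thin = th < min_thickness

    reason = np.where(poor, "poor_registration",
                      np.where(thin, "thin_myocardium", "none"))
    table["excluded"] = poor | thin
    table["exclusion_reason"] = reason

    n_poor = int(np.count_nonzero(reason == "poor_registration"))
    n_thin = int(np.count_nonzero(reason == "thin_myocardium"))
    n_excl = n_poor + n_thin
    summary = {
        "n_segments": n,
        "n_excluded": n_excl,
        "pct_excluded": _pct(n_excl, n),
        "n_poor_registration": n_poor,
        "pct_poor_registration": _pct(n_poor, n),
        "n_thin_myocardium": n_thin,
        "pct_thin_myocardium": _pct(n_thin, n),
    }
    return table, summary
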