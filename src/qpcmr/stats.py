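"""Modality-agreement statistics for paired perfusion measurements.

Covers the comparison of a test modality (quantitative perfusion CMR) against
a reference (15O-water PET): Pearson correlation with ordinary least-squares
regression, Bland-Altman bias and limits of agreement, two-way random-effects
absolute-agreement single-measures intraclass correlation ICC(A,1) with an
F-based confidence interval, paired two-one-sided-tests (TOST) equivalence,
ROC analysis against reference-defined abnormality, the DeLong test for
correlated AUCs, and ICC-based sample-size planning.

Conventions: pairs are (x = reference, y = test); differences are d = y - x;
segment- and vessel-level rows are treated as independent observations (the
subject id, when present, is annotation only — no mixed-effects correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EquivalenceMargins",
    "AbnormalityThresholds",
    "pearson_regression",
    "bland_altman",
    "icc_agreement",
    "tost_equivalence",
    "classify_abnormal",
    "roc_auc",
    "delong_test",
    "icc_sample_size",
]


@dataclass(frozen=True)
class EquivalenceMargins:
    """TOST equivalence margins, from 15O-water PET interstudy variability:
    MBF/MPR at the participant level, stress MBF and MPR at the vessel and
    segment levels (mL/min/g for MBF, unitless for MPR)."""

    mbf_participant: float = 0.90
    mpr_participant: float = 0.98
    stress_mbf_vessel_segment: float = 1.43
    mpr_vessel_segment: float = 2.80

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"margin {name} must be > 0")


@dataclass(frozen=True)
class AbnormalityThresholds:
    """Reference-PET abnormality cut-offs: abnormal iff stress MBF <= 2.3
    mL/min/g, or MPR <= 2.5 (both inclusive)."""

    stress_mbf_le: float = 2.3
    mpr_le: float = 2.5

    def __post_init__(self) -> None:
        if self.stress_mbf_le <= 0 or self.mpr_le <= 0:
            raise ValueError("thresholds must be > 0")


def _paired_xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        x = pairs["x"].to_numpy(dtype=float)
        y = pairs["y"].to_numpy(dtype=float)
    else:
        x, y = pairs
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired data must be two equal-length 1-D arrays")
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.all():
        raise ValueError("paired data must be finite")
    return x, y


def pearson_regression(pairs) -> dict:
    """Pearson r with two-sided p (t transform) plus OLS y-on-x regression."""
    x, y = _paired_xy(pairs)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("reference values have zero variance")
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    return {"r": float(r), "p": float(p),
            "slope": float(reg.slope), "intercept": float(reg.intercept),
            "n": int(x.size)}


def bland_altman(pairs, loa_factor: float = 1.96) -> dict:
    """Bland-Altman agreement: bias = mean(y - x), sample SD of the
    differences, and limits of agreement bias +/- 1.96 SD."""
    x, y = _paired_xy(pairs)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "sd": sd,
            "loa_low": bias - loa_factor * sd,
            "loa_high": bias + loa_factor * sd,
            "n": int(x.size)}


def _icc_interpretation(icc: float) -> str:
    # boundary convention: 0.50 -> moderate, 0.75 -> moderate, 0.90 -> good
    if icc < 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def icc_agreement(pairs, conf: float = 0.95) -> dict:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares (subjects x methods) with
    the McGraw & Wong F-based confidence interval (Satterthwaite df for the
    column/error mixture).  Interpretation bands: < 0.50 poor, 0.50-0.75
    moderate, 0.75-0.90 good, > 0.90 excellent (upper boundaries inclusive
    on the lower band).
    """
    x, y = _paired_xy(pairs)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 pairs for the ICC")
    data = np.column_stack([x, y])
    k = data.shape[1]
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    degenerate = np.ptp(row_means) == 0.0  # zero between-subject variance
    if degenerate or denom <= 0:
        icc = 0.0
    else:
        icc = float((msr - mse) / denom)

    alpha = 1.0 - conf
    if mse == 0 and msc == 0:
        lo, hi = (1.0, 1.0) if icc == 1.0 else (icc, icc)
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isfinite(a):
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else (n - 1) * (k - 1)
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            mix = k * msc + (k * n - k - n) * mse
            lo = n * (msr - f_l * mse) / (f_l * mix + n * msr)
            hi = n * (f_u * msr - mse) / (mix + n * f_u * msr)
        else:
            lo, hi = 1.0, 1.0
    icc = min(icc, 1.0)
    return {"icc": icc, "ci_low": float(lo), "ci_high": float(hi),
            "interpretation": _icc_interpretation(icc),
            "degenerate": bool(degenerate), "n": int(n),
            "msr": float(msr), "msc": float(msc), "mse": float(mse)}


def tost_equivalence(pairs, margin: float, alpha: float = 0.05) -> dict:
    """Paired two-one-sided-tests equivalence.

    Tests H0_lower: mean(d) <= -margin and H0_upper: mean(d) >= +margin on
    the paired differences d = y - x with df = n - 1; the reported p is the
    greater of the two one-sided p-values and equivalence is declared when
    it falls below ``alpha``.  Zero-variance differences short-circuit:
    equivalent iff |mean d| < margin, p reported as 0.0 with a flag.
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    x, y = _paired_xy(pairs)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = y - x
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        eq = abs(mean_d) < margin
        return {"p": 0.0 if eq else 1.0, "t_lower": np.inf, "t_upper": -np.inf,
                "equivalent": bool(eq), "mean_diff": mean_d, "sd_diff": 0.0,
                "degenerate_variance": True, "n": int(n)}
    se = sd / math.sqrt(n)
    t_lower = (mean_d + margin) / se   # H0: mean <= -margin, reject for large t
    t_upper = (mean_d - margin) / se   # H0: mean >= +margin, reject for small t
    p_lower = float(sps.t.sf(t_lower, df=n - 1))
    p_upper = float(sps.t.cdf(t_upper, df=n - 1))
    p = max(p_lower, p_upper)
    return {"p": p, "t_lower": float(t_lower), "t_upper": float(t_upper),
            "p_lower": p_lower, "p_upper": p_upper,
            "equivalent": bool(p < alpha), "mean_diff": mean_d, "sd_diff": sd,
            "degenerate_variance": False, "n": int(n)}


def classify_abnormal(values, threshold: float) -> np.ndarray:
    """Abnormal iff value <= threshold (boundary inclusive), elementwise."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return v <= threshold


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U; ties get half credit."""
    pos = scores[labels]
    neg = scores[~labels]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    n1, n0 = pos.size, neg.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores, labels, direction: str = "greater") -> dict:
    """ROC AUC for detecting the positive (abnormal) class.

    ``direction='greater'`` scores higher values as more abnormal;
    ``direction='less'`` (the perfusion convention: low flow is abnormal)
    scores lower values as more abnormal.  The orientation is explicit —
    an AUC below 0.5 is returned as-is, never silently flipped.  Also
    returns the ROC curve points (FPR, TPR) at every threshold.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if s.shape != lab.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    z = -s if direction == "less" else s
    auc = _auc_mann_whitney(z, lab)
    order = np.argsort(-z, kind="mergesort")
    zl = lab[order]
    tps = np.cumsum(zl)
    fps = np.cumsum(~zl)
    # collapse tied thresholds
    zs = z[order]
    last = np.r_[np.nonzero(np.diff(zs))[0], zs.size - 1]
    tpr = np.r_[0.0, tps[last] / lab.sum()]
    fpr = np.r_[0.0, fps[last] / (~lab).sum()]
    return {"auc": auc, "fpr": fpr, "tpr": tpr,
            "n_pos": int(lab.sum()), "n_neg": int((~lab).sum())}


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    # V10_i = P(neg < pos_i) + 0.5 P(neg == pos_i), and symmetrically for V01
    v10 = np.array([(np.count_nonzero(neg < p) + 0.5 * np.count_nonzero(neg == p))
                    for p in pos]) / neg.size
    v01 = np.array([(np.count_nonzero(pos > q) + 0.5 * np.count_nonzero(pos == q))
                    for q in neg]) / pos.size
    return v10, v01, float(v10.mean())


def delong_test(scores_a, scores_b, labels, direction: str = "greater") -> dict:
    """DeLong comparison of two correlated AUCs measured on the same cases.

    Uses placement values to estimate the covariance of the paired AUC
    estimates and a two-sided normal p for the difference.  A zero-variance
    difference (e.g. identical or rank-equivalent score sets) returns p = 1
    with a degeneracy flag.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if not (sa.shape == sb.shape == lab.shape) or sa.ndim != 1:
        raise ValueError("score sets and labels must be equal-length 1-D arrays")
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present")
    if direction == "less":
        sa, sb = -sa, -sb
    elif direction != "greater":
        raise ValueError("direction must be 'greater' or 'less'")
    v10a, v01a, auc_a = _placements(sa, lab)
    v10b, v01b, auc_b = _placements(sb, lab)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0 or np.isclose(var_diff, 0.0, atol=1e-18):
        return {"auc_a": auc_a, "auc_b": auc_b, "diff": diff, "z": 0.0,
                "p": 1.0, "degenerate": True}
    z = diff / math.sqrt(var_diff)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "diff": diff, "z": float(z),
            "p": p, "var_diff": float(var_diff), "degenerate": False}


def icc_sample_size(
    icc_null: float,
    icc_alt: float,
    alpha: float = 0.05,
    power: float = 0.80,
    raters: int = 2,
    two_sided: bool = True,
) -> int:
    """Subjects needed to reject ICC = icc_null when the true ICC is icc_alt.

    Walter, Eliasziw & Donner (1998) approximation based on Fisher's
    variance-stabilising transform of the ICC with k raters:

        n = 1 + 2 k (z_a + z_b)^2 / ((k - 1) (ln C0)^2),
        C0 = (1 + k theta0) / (1 + k theta1),  theta = rho / (1 - rho),

    ceiling-rounded.  ``alpha`` is split two-sided by default.
    """
    if not 0.0 <= icc_null < icc_alt < 1.0:
        raise ValueError("require 0 <= icc_null < icc_alt < 1")
    if raters < 2:
        raise ValueError("raters must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    k = raters
    za = sps.norm.ppf(1 - alpha / 2) if two_sided else sps.norm.ppf(1 - alpha)
    zb = sps.norm.ppf(power)
    theta0 = icc_null / (1 - icc_null)
    theta1 = icc_alt / (1 - icc_alt)
    c0 = (1 + k * theta0) / (1 + k * theta1)
    n = 1 + 2 * k * (za + zb) ** 2 / ((k - 1) * math.log(c0) ** 2)
    return int(math.ceil(n))
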