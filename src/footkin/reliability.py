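"""Coefficient of multiple correlation (CMC) for gait waveform repeatability.

The within-day CMC of Kadaba and colleagues compares the dispersion of
repeated trial curves about their pointwise mean with the dispersion
about the grand mean:

    R = sqrt( 1 - [ sum_jt (Y_jt - Ybar_t)^2 / (T (M - 1)) ]
                / [ sum_jt (Y_jt - Ybar)^2   / (M T - 1)   ] )

with M trials, T time points, Ybar_t the time-point mean and Ybar the
grand mean.  R approaches 1 when trials repeat the same waveform; for
flat (constant) ensembles the denominator vanishes and R is undefined,
and a noisy ensemble of a near-flat waveform can push the radicand
negative -- both cases are reported as ``defined=False`` rather than
clamped, so degenerate outcomes stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CMCResult", "cmc", "classify_reliability", "reliability_report"]


@dataclass(frozen=True)
class CMCResult:
    R: float
    defined: bool


def cmc(curves: np.ndarray) -> CMCResult:
    """Within-day CMC of an (M trials x T time points) curve ensemble."""
    Y = np.asarray(curves, dtype=float)
    if Y.ndim != 2:
        raise ValueError("ensemble must be a 2-D (trials x time) array")
    M, T = Y.shape
    if M < 2 or T < 2:
        raise ValueError("CMC needs at least 2 trials and 2 time points")
    if not np.isfinite(Y).all():
        raise ValueError("ensemble contains gaps / non-finite values")
    within = np.sum((Y - Y.mean(axis=0, keepdims=True)) ** 2) / (T * (M - 1))
    total = np.sum((Y - Y.mean()) ** 2) / (M * T - 1)
    # a flat ensemble has zero curve-to-curve information; guard with a
    # relative tolerance so rounding in the grand mean cannot fake variance
    scale = max(float(np.abs(Y).max()), 1.0)
    if total <= (1e-9 * scale) ** 2:
        return CMCResult(R=np.nan, defined=False)
    radicand = 1.0 - within / total
    if radicand < 0:
        return CMCResult(R=np.nan, defined=False)
    return CMCResult(R=float(np.sqrt(radicand)), defined=True)


def classify_reliability(result: CMCResult | float) -> str:
    """Label a CMC: strong (R >= 0.7), moderate (0.3 <= R < 0.7), poor.

    The 0.7 boundary is classified as strong.  Undefined CMCs label as
    'undefined'.
    """
    if isinstance(result, CMCResult):
        if not result.defined:
            return "undefined"
        R = result.R
    else:
        R = float(result)
        if not np.isfinite(R):
            return "undefined"
    if R >= 0.7:
        return "strong"
    if R >= 0.3:
        return "moderate"
    return "poor"


def reliability_report(ensembles: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Tabulate per-measure CMCs across subjects.

    ``ensembles`` maps measure name -> subject id -> (M x T) curve array.
    Returns one row per measure with the across-subject mean R, its SD
    (NaN for a single subject), and the reliability label of the mean.
    Subjects whose ensemble is undefined are dropped from the average.
    """
    rows = []
    for measure, subjects in ensembles.items():
        rs = []
        for curves in subjects.values():
            res = cmc(np.asarray(curves))
            if res.defined:
                rs.append(res.R)
        if rs:
            mean_r = float(np.mean(rs))
            sd = float(np.std(rs, ddof=1)) if len(rs) > 1 else np.nan
            label = classify_reliability(mean_r)
        else:
            mean_r, sd, label = np.nan, np.nan, "undefined"
        rows.append({"measure": measure, "n_subjects": len(rs), "R": mean_r,
                     "SD": sd, "label": label})
    return pd.DataFrame(rows)
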