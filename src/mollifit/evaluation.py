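"""ROI statistics and method-agreement analysis.

Mirrors the usual relaxometry evaluation workflow: mean T1 within a drawn
region of interest (invalid pixels excluded, never zero-filled), and
Bland-Altman agreement between paired measurements — mean difference and
95% limits of agreement at mean +/- 1.96 times the sample (n-1) standard
deviation of the differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import ParameterMap

__all__ = ["AgreementStats", "roi_mean", "bland_altman", "agreement_report"]


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary: mean difference and symmetric 95% limits."""

    mean_diff: float
    loa_low: float
    loa_high: float
    n: int


def roi_mean(map_: ParameterMap, mask: np.ndarray) -> float:
    """Arithmetic mean T1 (ms) over pixels that are both valid and in ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != map_.shape:
        raise ValueError(f"mask shape {mask.shape} does not match map {map_.shape}")
    sel = mask & map_.valid
    if not sel.any():
        raise ValueError("ROI contains no valid pixels")
    return float(map_.t1[sel].mean())


def bland_altman(x, y) -> AgreementStats:
    """Agreement between paired measurements ``x`` and ``y``.

    Differences are ``d_i = x_i - y_i``; limits are
    ``mean(d) +/- 1.96 * sd(d)`` with the sample (ddof=1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean_diff = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return AgreementStats(
        mean_diff=mean_diff,
        loa_low=mean_diff - half,
        loa_high=mean_diff + half,
        n=int(x.size),
    )


def agreement_report(per_subject: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Tidy per-subject ROI means (columns: subject, t1_a, t1_b, diff)."""
    rows = [
        {"subject": k, "t1_a": a, "t1_b": b, "diff": a - b}
        for k, (a, b) in per_subject.items()
    ]
    return pd.DataFrame(rows)
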