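"""Extracellular volume fraction (ECV) mapping.

ECV is computed pixel-wise from co-registered pre- and post-contrast T1 maps:

    ECV = (1 - Hct) * (1/T1_post - 1/T1_pre) / (1/T1b_post - 1/T1b_pre)

i.e. the tissue relaxation-rate change normalized by the blood-pool change
and scaled by the plasma fraction (1 - hematocrit).  Blood values are
scalars, typically ROI means over a blood-pool mask.  Pixels invalid in
either input map, or whose ECV falls outside a plausibility band, are
invalid in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import ParameterMap

__all__ = ["ECVInputs", "compute_ecv_map", "blood_t1_from_mask"]


@dataclass(frozen=True)
class ECVInputs:
    """Inputs for ECV mapping: the two T1 maps, blood T1 values and hematocrit."""

    pre_map: ParameterMap
    post_map: ParameterMap
    blood_t1_pre: float
    blood_t1_post: float
    hct: float

    def __post_init__(self):
        if self.pre_map.shape != self.post_map.shape:
            raise ValueError(
                f"grid mismatch: pre {self.pre_map.shape} vs post {self.post_map.shape}"
            )
        if self.blood_t1_pre <= 0 or self.blood_t1_post <= 0:
            raise ValueError("blood T1 values must be positive")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hct}")


def compute_ecv_map(
    inputs: ECVInputs, plausibility_band: tuple[float, float] = (0.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise ECV grid and validity mask.

    Per pixel valid in both maps,
    ``ECV = (1 - hct) * (1/t1_post - 1/t1_pre) / (1/blood_t1_post - 1/blood_t1_pre)``.
    ECV values outside ``plausibility_band`` are flagged invalid.
    """
    blood_dr1 = 1.0 / inputs.blood_t1_post - 1.0 / inputs.blood_t1_pre
    if blood_dr1 == 0.0:
        raise ValueError("blood delta-R1 is zero; pre and post blood T1 coincide")
    valid = inputs.pre_map.valid & inputs.post_map.valid
    ecv = np.full(inputs.pre_map.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        dr1 = 1.0 / inputs.post_map.t1 - 1.0 / inputs.pre_map.t1
        ecv[valid] = (1.0 - inputs.hct) * dr1[valid] / blood_dr1
    lo, hi = plausibility_band
    plausible = valid & (ecv >= lo) & (ecv <= hi)
    ecv[~plausible] = np.nan
    return ecv, plausible


def blood_t1_from_mask(t1_map: ParameterMap, mask: np.ndarray) -> float:
    """Blood-pool scalar T1: mean over valid pixels of ``mask``."""
    from .evaluation import roi_mean

    return roi_mean(t1_map, mask)
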