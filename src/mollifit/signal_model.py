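"""Inversion-recovery signal model, least-squares objective and Look-Locker correction.

The MOLLI readout observes the longitudinal magnetization at a set of
inversion times ``TI_1 < ... < TI_N``.  At one pixel the magnitude (or
signed) signal is modeled by the three-parameter relaxation curve

    S(t) = a * (1 - exp(-b * t)) + c

where ``a`` is the recovery amplitude, ``c`` the signal at t = 0 (negative
right after a good inversion) and ``b`` the apparent relaxation rate:
``T1* = 1/b`` is the *apparent* T1 shortened by the repeated readouts.  The
true T1 is recovered by the Look-Locker correction

    T1 = T1* * (a / (a + c) - 1)

which reduces to ``T1 = T1*`` for an ideal inversion (``a = -2c``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RelaxationParams",
    "TISeries",
    "DegenerateFitError",
    "relaxation_signal",
    "residual_cost",
    "look_locker_correct",
    "zero_crossing_time",
    "DEGENERACY_FLOOR",
]

#: relative floor under which |a + c| is treated as exactly zero
DEGENERACY_FLOOR = 1e-6

# exp argument clamp: keeps the model finite even when an optimizer wanders
# into large-negative b territory mid-iteration
_EXP_CLIP = 700.0


class DegenerateFitError(ValueError):
    """Raised when a + c is (numerically) zero and T1 is undefined."""


@dataclass(frozen=True)
class RelaxationParams:
    """The model triple (a, b, c).

    Parameters
    ----------
    a : float
        Recovery amplitude (signal units).
    b : float
        Apparent relaxation rate (1/ms); a valid fit has ``b > 0``.
    c : float
        Signal offset at t = 0 (signal units).
    """

    a: float
    b: float
    c: float

    @property
    def t1_star(self) -> float:
        """Apparent T1 in ms, ``1/b``."""
        return 1.0 / self.b

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)


@dataclass(frozen=True)
class TISeries:
    """One pixel's samples: inversion times (ms, strictly ascending) and signals.

    ``is_magnitude`` marks magnitude-scale data whose polarity must be
    restored before fitting; magnitude signals are non-negative.
    """

    tis: np.ndarray
    signals: np.ndarray
    is_magnitude: bool = True

    def __post_init__(self) -> None:
        tis = np.asarray(self.tis, dtype=float)
        signals = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "tis", tis)
        object.__setattr__(self, "signals", signals)
        if tis.ndim != 1 or signals.ndim != 1:
            raise ValueError("tis and signals must be 1-D")
        if tis.shape != signals.shape:
            raise ValueError(
                f"length mismatch: {tis.size} inversion times, {signals.size} signals"
            )
        if tis.size < 4:
            raise ValueError("need at least 4 samples to fit 3 parameters")
        if not np.all(np.diff(tis) > 0):
            raise ValueError("inversion times must be strictly ascending")
        if self.is_magnitude and np.any(signals < 0):
            raise ValueError("magnitude data cannot contain negative signals")

    def __len__(self) -> int:
        return int(self.tis.size)


def relaxation_signal(params: RelaxationParams, t):
    """Evaluate ``a * (1 - exp(-b t)) + c`` at time(s) ``t`` (ms)."""
    t = np.asarray(t, dtype=float)
    out = params.a * (1.0 - np.exp(np.clip(-params.b * t, -_EXP_CLIP, _EXP_CLIP))) + params.c
    return out if out.ndim else float(out)


def residual_cost(params: RelaxationParams, series: TISeries, signs=None) -> float:
    """Sum-of-squares objective on the sign-restored samples.

    ``signs`` is a +/-1 vector applied to the stored signals before comparing
    with the model (all +1 for already-signed data).
    """
    if signs is None:
        signs = np.ones(len(series))
    signs = np.asarray(signs, dtype=float)
    if signs.shape != series.signals.shape:
        raise ValueError(
            f"signs length {signs.size} does not match series length {len(series)}"
        )
    r = signs * series.signals - relaxation_signal(params, series.tis)
    return float(np.dot(r, r))


def look_locker_correct(params: RelaxationParams, floor: float = DEGENERACY_FLOOR) -> float:
    """Look-Locker corrected T1 in ms: ``(1/b) * (a/(a+c) - 1)``.

    Raises
    ------
    DegenerateFitError
        If ``|a + c| < floor * max(|a|, 1)`` — the recovery plateau is at the
        noise floor and the correction factor diverges.
    ValueError
        If ``b <= 0`` (no apparent relaxation).
    """
    if params.b <= 0:
        raise ValueError(f"apparent rate b must be positive, got {params.b}")
    denom = params.a + params.c
    if abs(denom) < floor * max(abs(params.a), 1.0):
        raise DegenerateFitError(
            f"a + c = {denom:g} is below the degeneracy floor; T1 undefined"
        )
    return (1.0 / params.b) * (params.a / denom - 1.0)


def zero_crossing_time(params: RelaxationParams) -> float:
    """Time (ms) at which the signed relaxation curve crosses zero.

    Solves ``a (1 - exp(-b t)) + c = 0``; defined for ``a > 0``, ``b > 0`` and
    ``-a < c < 0`` (the usual inversion-recovery geometry).  Used by the
    phantom to derive the ground-truth polarity flip count.
    """
    if params.a <= 0 or params.b <= 0:
        raise ValueError("zero crossing requires a > 0 and b > 0")
    ratio = (params.a + params.c) / params.a
    if ratio <= 0 or ratio >= 1:
        raise ValueError("curve does not cross zero at positive time")
    return -np.log(ratio) / params.b
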