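"""Per-pixel T1 parameter estimation.

Two estimation paths for the three-parameter inversion-recovery model:

* **LM** — iterative Levenberg–Marquardt minimization of the sum-of-squares
  objective from a fixed initial point, repeated once per polarity candidate
  on magnitude data (the polarity of the earliest-TI samples is incrementally
  flipped and the flip count with the smallest residual wins).

* **RD** (reduced-dimension NLS) — for a fixed rate ``b`` the model is linear
  in ``(a, c)``, so the inner problem has a closed-form ordinary-least-squares
  solution and the fit collapses to a one-dimensional search over ``b``.  The
  search is a dense log-spaced grid over apparent T1 followed by bounded
  scalar refinement on the bracketing interval.  Polarity on magnitude data is
  restored by trying a small set of flip-count candidates around the
  minimum-magnitude sample: the sample nearest the zero crossing is the
  natural pivot, but noise can push the true crossing past it, so three
  candidates ``{m, m+1, m+2}`` are tried (two reproduces the classic RD
  behavior and is known to mis-fit when neighboring TIs nearly coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .signal_model import (
    DegenerateFitError,
    RelaxationParams,
    TISeries,
    look_locker_correct,
)

__all__ = [
    "FitResult",
    "LMConfig",
    "RDSearch",
    "CollinearDesignError",
    "sign_vector",
    "restore_polarity_candidates",
    "reduced_cost",
    "fit_rd",
    "fit_lm",
    "LM_INIT_PRE",
    "LM_INIT_POST",
]

#: empirically chosen LM starting points for pre- and post-contrast data
LM_INIT_PRE = RelaxationParams(a=350.0, b=0.001, c=-150.0)
LM_INIT_POST = RelaxationParams(a=350.0, b=0.005, c=-150.0)

# relative tie tolerance: candidates whose costs agree to this level are
# considered tied and the smaller flip count wins (deterministic output)
_TIE_RTOL = 1e-12

_EXP_CLIP = 700.0


class CollinearDesignError(ValueError):
    """The regressors 1 - exp(-b TI_i) are numerically identical for this b."""


@dataclass(frozen=True)
class FitResult:
    """Outcome of a per-pixel fit.

    Attributes
    ----------
    params : RelaxationParams
        Estimated (a, b, c).
    rss : float
        Residual sum of squares at the optimum, on the winning sign vector.
    flip_count : int
        Number of earliest-TI samples whose polarity was negated (0 for
        signed input).
    t1_star_ms : float
        Apparent T1, ``1/b`` (NaN if not converged).
    t1_ms : float
        Look-Locker corrected T1 (NaN if not converged).
    converged : bool
        True iff the optimizer succeeded, ``b > 0`` and the corrected T1 is
        finite and positive.
    method : str
        ``"LM"`` or ``"RD"``.
    """

    params: RelaxationParams
    rss: float
    flip_count: int
    t1_star_ms: float
    t1_ms: float
    converged: bool
    method: str


@dataclass(frozen=True)
class LMConfig:
    """Levenberg–Marquardt settings: initial point, iteration cap, stop tolerance."""

    init: RelaxationParams = LM_INIT_PRE
    max_iter: int = 200
    ftol: float = 1e-8


@dataclass(frozen=True)
class RDSearch:
    """1-D search configuration for the reduced-dimension fitter.

    ``t1_star_bounds`` bound the apparent T1 (ms) spanned by the log-spaced
    ``n_grid``-point b grid; ``rel_tol`` is the relative tolerance on b of the
    bounded refinement; ``n_candidates`` controls polarity restoration
    (``exhaustive=True`` sweeps every flip count 0..N instead).
    """

    t1_star_bounds: tuple[float, float] = (1.0, 5000.0)
    n_grid: int = 500
    rel_tol: float = 1e-6
    n_candidates: int = 3
    exhaustive: bool = False


def sign_vector(flip_count: int, n: int) -> np.ndarray:
    """Sign vector with the first ``flip_count`` entries -1, the rest +1."""
    if not 0 <= flip_count <= n:
        raise ValueError(f"flip_count {flip_count} out of range [0, {n}]")
    signs = np.ones(n)
    signs[:flip_count] = -1.0
    return signs


def restore_polarity_candidates(series: TISeries, n_candidates: int = 3) -> list[int]:
    """Flip-count candidates for magnitude polarity restoration.

    Let ``m`` be the (TI-ascending, 0-based) index of the minimum-magnitude
    sample, ties broken toward the smaller index.  With no noise the zero
    crossing lies next to TI_m, so the flip count is ``m`` or ``m+1`` — the
    classic two-candidate rule.  Noise near-ties can shift the observed
    minimum one sample past the crossing, in which case the correct flip
    count is ``m - 1``; candidates therefore expand symmetrically around the
    classic pair (``m``, ``m+1``, then ``m-1``, ``m+2``, ...), clipped to
    ``[0, N]`` and deduplicated.  The default three candidates give
    ``{m-1, m, m+1}``.
    """
    if not series.is_magnitude:
        raise ValueError("polarity restoration applies to magnitude data only")
    n = len(series)
    if not 1 <= n_candidates <= n:
        raise ValueError(f"n_candidates must be in [1, {n}]")
    m = int(np.argmin(series.signals))
    offsets = [0, 1]
    k = 1
    while len(offsets) < n_candidates:
        offsets.append(-k)
        if len(offsets) < n_candidates:
            offsets.append(k + 1)
        k += 1
    cands = {min(max(m + off, 0), n) for off in offsets[:n_candidates]}
    return sorted(cands)


def _design_sums(x: np.ndarray, y: np.ndarray):
    """Closed-form OLS of y ~ a*x + c. Returns (a, c, rss)."""
    n = x.size
    sx = x.sum()
    sy = y.sum()
    sxx = float(np.dot(x, x))
    sxy = float(np.dot(x, y))
    denom = n * sxx - sx * sx
    # denom == n * sum((x - mean x)^2); vanishes iff all x identical
    if denom <= 1e-12 * max(n * sxx, 1.0):
        raise CollinearDesignError("regressors 1 - exp(-b TI) are collinear")
    a = (n * sxy - sx * sy) / denom
    c = (sy - a * sx) / n
    r = y - a * x - c
    return a, c, float(np.dot(r, r))


def reduced_cost(b: float, series: TISeries, signs) -> tuple[float, float, float]:
    """Inner closed-form solve of the reduced-dimension objective at fixed b.

    Returns ``(cost, a_opt, c_opt)`` where ``(a_opt, c_opt)`` is the exact OLS
    solution of the (linear in a, c) model against the sign-restored samples
    and ``cost`` is the sum-of-squares objective at ``(a_opt, b, c_opt)``.

    Raises
    ------
    CollinearDesignError
        If the regressor values ``1 - exp(-b TI_i)`` are all identical within
        numerical tolerance (b too large or non-positive for these TIs).
    """
    signs = np.asarray(signs, dtype=float)
    if signs.shape != series.signals.shape:
        raise ValueError("signs length does not match series")
    x = 1.0 - np.exp(np.clip(-b * series.tis, -_EXP_CLIP, _EXP_CLIP))
    y = signs * series.signals
    a, c, rss = _design_sums(x, y)
    return rss, a, c


def _grid_costs(bs: np.ndarray, tis: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized reduced cost over a vector of rates ``bs`` (NaN where collinear)."""
    x = 1.0 - np.exp(np.clip(-np.outer(bs, tis), -_EXP_CLIP, _EXP_CLIP))  # (B, N)
    n = tis.size
    sx = x.sum(axis=1)
    sxx = np.einsum("ij,ij->i", x, x)
    sxy = x @ y
    sy = y.sum()
    syy = float(np.dot(y, y))
    denom = n * sxx - sx * sx
    bad = denom <= 1e-12 * np.maximum(n * sxx, 1.0)
    denom_safe = np.where(bad, 1.0, denom)
    a = (n * sxy - sx * sy) / denom_safe
    c = (sy - a * sx) / n
    cost = syy - 2.0 * a * sxy - 2.0 * c * sy + a * a * sxx + 2.0 * a * c * sx + n * c * c
    cost = np.maximum(cost, 0.0)
    cost[bad] = np.nan
    return cost


def _result_from(params, rss, flip_count, method, ok) -> FitResult:
    t1_star = np.nan
    t1 = np.nan
    converged = False
    if ok and np.isfinite(rss) and params.b > 0:
        t1_star = params.t1_star
        try:
            t1 = look_locker_correct(params)
        except (DegenerateFitError, ValueError):
            t1 = np.nan
        converged = bool(np.isfinite(t1) and t1 > 0)
        if not converged:
            t1_star = params.t1_star if params.b > 0 else np.nan
    return FitResult(
        params=params,
        rss=float(rss),
        flip_count=int(flip_count),
        t1_star_ms=float(t1_star),
        t1_ms=float(t1),
        converged=converged,
        method=method,
    )


def _better(cost: float, best: float | None) -> bool:
    """Strict improvement beyond the tie tolerance (smaller flip count wins ties)."""
    if not np.isfinite(cost):
        return False
    if best is None or not np.isfinite(best):
        return True
    if cost >= best:
        return False
    return (best - cost) > _TIE_RTOL * max(abs(best), abs(cost))


def fit_rd(series: TISeries, search: RDSearch | None = None) -> FitResult:
    """Reduced-dimension NLS fit (initialization-free).

    For each polarity candidate the reduced objective is minimized over b by
    a dense log-spaced grid spanning ``search.t1_star_bounds`` followed by
    bounded scalar minimization on the grid interval bracketing the best
    point; (a, c) come from the closed-form inner solve and T1 from the
    Look-Locker correction.  The candidate with globally minimal cost wins;
    ties go to the smaller flip count.
    """
    if search is None:
        search = RDSearch()
    tis = series.tis
    n = len(series)
    lo, hi = search.t1_star_bounds
    bs = 1.0 / np.geomspace(hi, lo, search.n_grid)  # ascending b

    if not series.is_magnitude:
        candidates = [0]
    elif search.exhaustive:
        candidates = list(range(n + 1))
    else:
        candidates = restore_polarity_candidates(series, search.n_candidates)

    best = None
    best_cost = None
    for fc in candidates:  # ascending: smaller flip count wins ties
        signs = sign_vector(fc, n)
        y = signs * series.signals
        costs = _grid_costs(bs, tis, y)
        if np.all(np.isnan(costs)):
            continue
        i = int(np.nanargmin(costs))
        b_lo = bs[max(i - 1, 0)]
        b_hi = bs[min(i + 1, bs.size - 1)]
        if b_hi > b_lo:
            res = minimize_scalar(
                lambda b: _grid_costs(np.array([b]), tis, y)[0],
                bounds=(b_lo, b_hi),
                method="bounded",
                options={"xatol": search.rel_tol * bs[i]},
            )
            b_opt = float(res.x)
        else:
            b_opt = float(bs[i])
        try:
            cost, a_opt, c_opt = reduced_cost(b_opt, series, signs)
        except CollinearDesignError:
            continue
        # keep the grid point if refinement somehow regressed
        if np.isfinite(costs[i]) and costs[i] < cost:
            b_opt = float(bs[i])
            cost, a_opt, c_opt = reduced_cost(b_opt, series, signs)
        if _better(cost, best_cost):
            best_cost = cost
            best = (RelaxationParams(a_opt, b_opt, c_opt), cost, fc)

    if best is None:
        return FitResult(
            params=RelaxationParams(np.nan, np.nan, np.nan),
            rss=np.nan,
            flip_count=0,
            t1_star_ms=np.nan,
            t1_ms=np.nan,
            converged=False,
            method="RD",
        )
    params, cost, fc = best
    return _result_from(params, cost, fc, "RD", ok=True)


def _lm_once(series: TISeries, signs: np.ndarray, config: LMConfig):
    """One LM minimization of the objective on sign-restored samples."""
    tis = series.tis
    y = signs * series.signals

    def resid(p):
        a, b, c = p
        return y - (a * (1.0 - np.exp(np.clip(-b * tis, -_EXP_CLIP, _EXP_CLIP))) + c)

    def jac(p):
        a, b, c = p
        e = np.exp(np.clip(-b * tis, -_EXP_CLIP, _EXP_CLIP))
        return np.column_stack([-(1.0 - e), -a * tis * e, -np.ones_like(tis)])

    try:
        res = least_squares(
            resid,
            config.init.as_array(),
            jac=jac,
            method="lm",
            ftol=config.ftol,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=config.max_iter,
        )
    except Exception:
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    rss = float(np.dot(res.fun, res.fun))
    if not np.isfinite(rss):
        return None
    return RelaxationParams(*map(float, res.x)), rss, bool(res.success)


def fit_lm(
    series: TISeries,
    config: LMConfig | None = None,
    flip_policy: str = "full_sweep",
) -> FitResult:
    """Levenberg–Marquardt fit from a fixed initial point.

    On magnitude data the polarity of the earliest-TI samples is flipped
    incrementally: with ``flip_policy="full_sweep"`` one minimization is run
    per flip count in ``0..N`` and the smallest residual wins; with
    ``"candidates"`` only the three flip counts around the minimum-magnitude
    sample are tried.  Signed data is fit once with all-positive signs.
    """
    if config is None:
        config = LMConfig()
    n = len(series)
    if series.is_magnitude:
        if flip_policy == "full_sweep":
            candidates = list(range(n + 1))
        elif flip_policy == "candidates":
            candidates = restore_polarity_candidates(series)
        elif flip_policy == "none":
            candidates = [0]
        else:
            raise ValueError(f"unknown flip_policy {flip_policy!r}")
    else:
        candidates = [0]

    best = None
    best_cost = None
    for fc in candidates:
        out = _lm_once(series, sign_vector(fc, n), config)
        if out is None:
            continue
        params, rss, success = out
        if not success:
            continue
        if _better(rss, best_cost):
            best_cost = rss
            best = (params, rss, fc)

    if best is None:
        return FitResult(
            params=RelaxationParams(np.nan, np.nan, np.nan),
            rss=np.nan,
            flip_count=0,
            t1_star_ms=np.nan,
            t1_ms=np.nan,
            converged=False,
            method="LM",
        )
    params, rss, fc = best
    return _result_from(params, rss, fc, "LM", ok=True)
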