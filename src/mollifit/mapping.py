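"""Pixel-wise T1 map assembly.

Fits every above-threshold pixel of a TI image stack with the chosen method
and assembles the results into a :class:`ParameterMap` with an explicit
validity mask: pixels that are masked out, fail to converge, yield a
non-positive or degenerate T1, or exceed the optional clamp limit are marked
invalid (never silently clipped) so that downstream ROI statistics and ECV
maps exclude them.  Parallel execution uses static row chunking; the output
is bit-identical for any worker count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .fitting import FitResult, LMConfig, RDSearch, fit_lm, fit_rd, sign_vector
from .signal_model import TISeries, relaxation_signal

__all__ = ["TIImageStack", "ParameterMap", "PixelReport", "compute_t1_map", "fit_pixel_report"]


@dataclass(frozen=True)
class TIImageStack:
    """A rows x cols x N image volume with its inversion times.

    ``tis`` are in ms, one per slice, strictly ascending (sorted with the
    slices on construction if needed); ``protocol`` tags the MOLLI scheme.
    """

    voxels: np.ndarray
    tis: np.ndarray
    protocol: str = "custom"
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    is_magnitude: bool = True

    def __post_init__(self):
        voxels = np.asarray(self.voxels, dtype=float)
        tis = np.asarray(self.tis, dtype=float)
        if voxels.ndim != 3:
            raise ValueError("voxels must be rows x cols x N")
        if tis.ndim != 1 or tis.size != voxels.shape[2]:
            raise ValueError(
                f"{tis.size} inversion times for {voxels.shape[2]} image slices"
            )
        if np.any(tis <= 0):
            raise ValueError("inversion times must be positive")
        order = np.argsort(tis, kind="stable")
        tis = tis[order]
        voxels = voxels[:, :, order]
        if np.any(np.diff(tis) <= 0):
            raise ValueError("inversion times must be distinct")
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "tis", tis)

    @property
    def shape(self) -> tuple[int, int]:
        return self.voxels.shape[:2]

    @property
    def n_ti(self) -> int:
        return int(self.tis.size)

    def series_at(self, row: int, col: int) -> TISeries:
        """The (TI, signal) series of one pixel (0-based row-major indexing)."""
        return TISeries(self.tis, self.voxels[row, col, :], self.is_magnitude)


@dataclass(frozen=True)
class ParameterMap:
    """Per-pixel T1 (ms), residual and validity, with fit provenance.

    ``t1`` is NaN wherever invalid; ``valid`` is False for masked-out pixels,
    failed fits, non-positive T1 and clamp violations.
    """

    t1: np.ndarray
    rss: np.ndarray
    valid: np.ndarray
    method: str
    threshold: float = 0.0
    clamp_limit: float | None = None
    tis: np.ndarray | None = None
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.t1.shape


@dataclass(frozen=True)
class PixelReport:
    """One pixel's fit plus dense model-curve samples for plotting."""

    row: int
    col: int
    fit: FitResult
    tis: np.ndarray
    signals: np.ndarray
    restored_signals: np.ndarray
    curve_t: np.ndarray
    curve_s: np.ndarray

    @property
    def valid(self) -> bool:
        return self.fit.converged


def _fit_one(method, tis, sig, is_magnitude, lm_config, lm_flip_policy, rd_search):
    series = TISeries(tis, sig, is_magnitude)
    if method == "RD":
        return fit_rd(series, rd_search)
    return fit_lm(series, lm_config, lm_flip_policy)


def _fit_rows(rows, stack_voxels, tis, is_magnitude, fit_mask, method,
              lm_config, lm_flip_policy, rd_search):
    out = []
    for r in rows:
        row_res: list[FitResult | None] = []
        for cidx in range(stack_voxels.shape[1]):
            if not fit_mask[r, cidx]:
                row_res.append(None)
                continue
            row_res.append(
                _fit_one(method, tis, stack_voxels[r, cidx, :], is_magnitude,
                         lm_config, lm_flip_policy, rd_search)
            )
        out.append((r, row_res))
    return out


def compute_t1_map(
    stack: TIImageStack,
    method: str = "RD",
    threshold: float = 0.0,
    workers: int = 1,
    clamp_limit: float | None = None,
    lm_config: LMConfig | None = None,
    lm_flip_policy: str = "candidates",
    rd_search: RDSearch | None = None,
) -> ParameterMap:
    """Pixel-by-pixel T1 map.

    Every pixel whose maximum signal across TIs strictly exceeds ``threshold``
    is fitted with ``method`` (``"RD"`` or ``"LM"``); others are invalid.  If
    ``clamp_limit`` is set, valid fits with T1 above it are marked invalid.
    ``workers > 1`` distributes static row chunks across processes; results
    are bit-identical for any worker count.

    At map scale the LM path defaults to the three-candidate polarity rule
    (``lm_flip_policy="candidates"``); pass ``"full_sweep"`` for the
    exhaustive flip sweep used by :func:`mollifit.fitting.fit_lm` on single
    series.
    """
    method = method.upper()
    if method not in ("RD", "LM"):
        raise ValueError(f"unknown method {method!r}; expected 'RD' or 'LM'")
    rows, cols = stack.shape
    if rows == 0 or cols == 0 or stack.n_ti == 0:
        raise ValueError("empty image stack")

    fit_mask = np.max(stack.voxels, axis=2) > threshold

    t1 = np.full((rows, cols), np.nan)
    rss = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)

    args = (stack.voxels, stack.tis, stack.is_magnitude, fit_mask, method,
            lm_config, lm_flip_policy, rd_search)
    if workers <= 1:
        chunks = [_fit_rows(range(rows), *args)]
    else:
        row_blocks = np.array_split(np.arange(rows), min(workers, rows))
        chunks = Parallel(n_jobs=workers)(
            delayed(_fit_rows)(list(block), *args) for block in row_blocks if block.size
        )

    for chunk in chunks:
        for r, row_res in chunk:
            for cidx, res in enumerate(row_res):
                if res is None:
                    continue
                rss[r, cidx] = res.rss
                if res.converged:
                    t1[r, cidx] = res.t1_ms
                    valid[r, cidx] = True

    if clamp_limit is not None:
        over = valid & (t1 > clamp_limit)
        valid[over] = False
        t1[over] = np.nan
    t1[~valid] = np.nan

    return ParameterMap(
        t1=t1,
        rss=rss,
        valid=valid,
        method=method,
        threshold=threshold,
        clamp_limit=clamp_limit,
        tis=stack.tis.copy(),
        pixel_spacing=stack.pixel_spacing,
    )


def fit_pixel_report(
    stack: TIImageStack,
    row: int,
    col: int,
    method: str = "RD",
    n_curve: int = 256,
    **fit_kw,
) -> PixelReport:
    """Fit one pixel and return the result with dense curve samples over [0, max TI]."""
    rows, cols = stack.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise IndexError(f"pixel ({row}, {col}) out of bounds for {rows}x{cols} map")
    method = method.upper()
    series = stack.series_at(row, col)
    if method == "RD":
        fit = fit_rd(series, fit_kw.get("rd_search"))
    elif method == "LM":
        fit = fit_lm(series, fit_kw.get("lm_config"),
                     fit_kw.get("lm_flip_policy", "full_sweep"))
    else:
        raise ValueError(f"unknown method {method!r}")
    curve_t = np.linspace(0.0, float(stack.tis[-1]), n_curve)
    curve_s = relaxation_signal(fit.params, curve_t)
    restored = sign_vector(fit.flip_count, len(series)) * series.signals
    return PixelReport(
        row=row,
        col=col,
        fit=fit,
        tis=series.tis,
        signals=series.signals,
        restored_signals=restored,
        curve_t=curve_t,
        curve_s=np.asarray(curve_s),
    )
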