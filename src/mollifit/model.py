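"""Model/Results interface for single-series inversion-recovery T1 fitting.

:class:`InversionRecoveryT1` wraps one pixel's (TI, signal) samples the way a
regression model wraps (endog, exog): construct from arrays or a DataFrame,
call :meth:`~InversionRecoveryT1.fit` with the estimation method, and receive
a :class:`T1FitResults` carrying the parameter estimates, their standard
errors (Gauss-Newton covariance at the optimum), the corrected T1 and a
``summary()`` table.  ``simulate`` generates noisy replicates from fitted or
supplied parameters; ``plot`` renders data and fitted curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import FitResult, fit_lm, fit_rd, sign_vector
from .signal_model import RelaxationParams, TISeries, relaxation_signal

__all__ = ["InversionRecoveryT1", "T1FitResults"]

_EXP_CLIP = 700.0


class InversionRecoveryT1:
    """Three-parameter inversion-recovery relaxation model for one series.

    Parameters
    ----------
    signals : array-like
        Observed signal at each inversion time (magnitude scale unless
        ``is_magnitude=False``).
    tis : array-like
        Inversion times in ms, strictly ascending.
    is_magnitude : bool
        Whether polarity must be restored before fitting.

    Examples
    --------
    >>> model = InversionRecoveryT1(signals, tis)
    >>> res = model.fit(method="rd")
    >>> res.t1, res.bse
    """

    def __init__(self, signals, tis, is_magnitude: bool = True):
        self.series = TISeries(np.asarray(tis, float), np.asarray(signals, float),
                               is_magnitude)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        ti_col: str = "ti",
        signal_col: str = "signal",
        is_magnitude: bool = True,
    ) -> "InversionRecoveryT1":
        """Build from a tidy DataFrame with TI and signal columns."""
        df = data.sort_values(ti_col)
        return cls(df[signal_col].to_numpy(), df[ti_col].to_numpy(), is_magnitude)

    @property
    def nobs(self) -> int:
        return len(self.series)

    def fit(self, method: str = "rd", **kwargs) -> "T1FitResults":
        """Estimate (a, b, c) and the Look-Locker corrected T1.

        ``method="rd"`` runs the reduced-dimension NLS (initialization-free;
        keyword ``search=RDSearch(...)``); ``method="lm"`` runs
        Levenberg-Marquardt from a fixed start (keywords
        ``config=LMConfig(...)``, ``flip_policy``).
        """
        m = method.lower()
        if m == "rd":
            raw = fit_rd(self.series, kwargs.get("search"))
        elif m == "lm":
            raw = fit_lm(self.series, kwargs.get("config"),
                         kwargs.get("flip_policy", "full_sweep"))
        else:
            raise ValueError(f"unknown method {method!r}; expected 'rd' or 'lm'")
        return T1FitResults(self, raw)

    def predict(self, params, t=None):
        """Model curve at times ``t`` (defaults to the observed TIs)."""
        if not isinstance(params, RelaxationParams):
            params = RelaxationParams(*params)
        if t is None:
            t = self.series.tis
        return relaxation_signal(params, t)

    def simulate(self, params, noise_sigma: float = 0.0, seed: int | None = None):
        """Draw one noisy replicate of the series from ``params``.

        Rician noise (two-channel Gaussian, magnitude) when the model holds
        magnitude data, plain Gaussian otherwise.
        """
        if not isinstance(params, RelaxationParams):
            params = RelaxationParams(*params)
        clean = relaxation_signal(params, self.series.tis)
        rng = np.random.default_rng(seed)
        if noise_sigma <= 0:
            noisy = np.abs(clean) if self.series.is_magnitude else np.asarray(clean)
        elif self.series.is_magnitude:
            noisy = np.hypot(clean + rng.normal(0, noise_sigma, clean.shape),
                             rng.normal(0, noise_sigma, clean.shape))
        else:
            noisy = clean + rng.normal(0, noise_sigma, clean.shape)
        return noisy


class T1FitResults:
    """Estimates, uncertainties and diagnostics of one inversion-recovery fit.

    Attributes
    ----------
    params : ndarray
        Point estimates ``[a, b, c]``.
    bse : ndarray
        Standard errors from the Gauss-Newton covariance
        ``s2 * (J'J)^{-1}`` with ``s2 = rss / (N - 3)``.
    t1 : float
        Look-Locker corrected T1 (ms); ``t1_se`` its delta-method error.
    t1_star : float
        Apparent T1, ``1/b`` (ms).
    """

    def __init__(self, model: InversionRecoveryT1, raw: FitResult):
        self.model = model
        self._raw = raw
        self.params = raw.params.as_array()
        self.rss = raw.rss
        self.flip_count = raw.flip_count
        self.converged = raw.converged
        self.method = raw.method
        self.t1 = raw.t1_ms
        self.t1_star = raw.t1_star_ms
        self.nobs = model.nobs
        self.df_resid = self.nobs - 3
        self._cov = self._compute_cov()

    # -- uncertainty -------------------------------------------------------
    def _jacobian(self) -> np.ndarray:
        a, b, _ = self.params
        t = self.model.series.tis
        e = np.exp(np.clip(-b * t, -_EXP_CLIP, _EXP_CLIP))
        return np.column_stack([1.0 - e, a * t * e, np.ones_like(t)])

    def _compute_cov(self):
        if not self.converged or self.df_resid <= 0:
            return np.full((3, 3), np.nan)
        J = self._jacobian()
        s2 = self.rss / self.df_resid
        try:
            return s2 * np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            return np.full((3, 3), np.nan)

    def cov_params(self) -> np.ndarray:
        """Gauss-Newton covariance of (a, b, c)."""
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self._cov))

    @property
    def t1_se(self) -> float:
        """Delta-method standard error of the corrected T1."""
        if not self.converged:
            return float("nan")
        a, b, c = self.params
        s = a + c
        g = np.array([c / (b * s * s), -self.t1 / b, -a / (b * s * s)])
        var = float(g @ self._cov @ g)
        return float(np.sqrt(var)) if var >= 0 else float("nan")

    # -- diagnostics -------------------------------------------------------
    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self.model.predict(self._raw.params))

    @property
    def resid(self) -> np.ndarray:
        restored = sign_vector(self.flip_count, self.nobs) * self.model.series.signals
        return restored - self.fittedvalues

    def predict(self, t=None):
        return self.model.predict(self._raw.params, t)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        names = ["a", "b", "c"]
        units = ["signal", "1/ms", "signal"]
        bse = self.bse
        lines = [
            "Inversion-Recovery T1 Fit Results",
            "=" * 46,
            f"Method:            {self.method}",
            f"No. observations:  {self.nobs}",
            f"Converged:         {self.converged}",
            f"Flip count:        {self.flip_count}",
            f"RSS:               {self.rss:.6g}",
            "-" * 46,
            f"{'param':>6} {'estimate':>14} {'std err':>12} {'unit':>8}",
        ]
        for name, est, se, unit in zip(names, self.params, bse, units):
            lines.append(f"{name:>6} {est:>14.6g} {se:>12.4g} {unit:>8}")
        lines += [
            "-" * 46,
            f"T1* (apparent):    {self.t1_star:.2f} ms",
            f"T1  (corrected):   {self.t1:.2f} ms  (se {self.t1_se:.3g})",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data (polarity-restored) and fitted curve."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.linspace(0, float(self.model.series.tis[-1]), 256)
        restored = sign_vector(self.flip_count, self.nobs) * self.model.series.signals
        ax.plot(self.model.series.tis, restored, "ko", label="samples (restored)")
        ax.plot(t, self.predict(t), "b-", label=f"{self.method} fit")
        ax.axhline(0, color="0.7", lw=0.5)
        ax.set_xlabel("inversion time (ms)")
        ax.set_ylabel("signal")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        return (f"<T1FitResults method={self.method} t1={self.t1:.2f} ms "
                f"converged={self.converged}>")
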