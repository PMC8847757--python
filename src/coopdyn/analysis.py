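"""Observable aggregation, time-lagged cross-correlation, and spectra.

The paper-style workflow: run many replicates, average their series
pointwise (:func:`aggregate_replicates`), discard the transient half of each
run (:func:`stable_window`), then quantify environment–population synchrony
with :func:`tlcc` and population-size variability with :func:`spectrum` —
the one-sided FFT amplitude spectrum of the population size standardized by
its mean, ``z_t = (N_t - mean(N)) / mean(N)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ShapeMismatchError, UndefinedStatisticError

__all__ = [
    "AggregateSeries",
    "LagCorrelation",
    "Spectrum",
    "aggregate_replicates",
    "stable_window",
    "tlcc",
    "spectrum",
    "mean_spectrum",
]


@dataclass
class AggregateSeries:
    """Pointwise mean and sample standard deviation across replicates."""

    mean: pd.DataFrame
    sd: Optional[pd.DataFrame]
    n_replicates: int


@dataclass
class LagCorrelation:
    """Pearson correlation of ``x_t`` with ``y_{t+k}`` per integer lag ``k``.

    ``r`` is NaN at lags where a window has zero variance (undefined
    correlation — flagged, never silently 0).
    """

    lags: np.ndarray
    r: np.ndarray

    def max_abs(self) -> float:
        """Largest |r| over defined lags."""
        if np.all(np.isnan(self.r)):
            raise UndefinedStatisticError("correlation undefined at every lag")
        return float(np.nanmax(np.abs(self.r)))

    def peak_lag(self) -> int:
        """Lag of the largest |r| (ties broken toward the smallest lag)."""
        if np.all(np.isnan(self.r)):
            raise UndefinedStatisticError("correlation undefined at every lag")
        a = np.abs(self.r)
        a = np.where(np.isnan(a), -np.inf, a)
        return int(self.lags[int(np.argmax(a))])


@dataclass
class Spectrum:
    """One-sided amplitude spectrum of a mean-standardized series.

    ``amplitude[k]`` is scaled so that a pure sinusoid of relative
    amplitude ``a`` shows a peak of height ``a`` at its frequency.
    """

    freqs: np.ndarray
    amplitude: np.ndarray

    def peak(self) -> tuple[float, float]:
        """(frequency, amplitude) of the largest non-DC component."""
        k = 1 + int(np.argmax(self.amplitude[1:]))
        return float(self.freqs[k]), float(self.amplitude[k])

    def total_power(self) -> float:
        """Power implied by the amplitudes (equals the variance of the
        standardized series, by Parseval)."""
        n_half = len(self.amplitude)
        power = self.amplitude[0] ** 2
        # interior bins carry a factor 2 in the one-sided fold; the final
        # bin is the unpaired Nyquist bin only for even-length input, which
        # is what the scaling in `spectrum` encodes.
        power += np.sum((self.amplitude[1:] ** 2) / self._fold[1:])
        return float(power)

    # fold factor per bin, set by `spectrum`; 2 for paired bins, 1 for DC
    # and (even n) Nyquist.
    _fold: np.ndarray = None  # type: ignore[assignment]


def _numeric_columns(frame: pd.DataFrame) -> list:
    return [c for c in frame.columns if np.issubdtype(frame[c].dtype, np.number)]


def aggregate_replicates(frames: Sequence[pd.DataFrame]) -> AggregateSeries:
    """Pointwise mean and sample sd (ddof=1) of replicate series.

    All series must share length and columns; the sd is ``None`` for a
    single replicate.
    """
    if len(frames) == 0:
        raise ValueError("need at least one replicate series")
    first = frames[0]
    cols = _numeric_columns(first)
    n = len(first)
    for f in frames[1:]:
        if len(f) != n:
            raise ShapeMismatchError(
                f"replicate series lengths differ: {len(f)} vs {n}"
            )
    stack = np.stack([f[cols].to_numpy(dtype=float) for f in frames])
    mean = pd.DataFrame(stack.mean(axis=0), columns=cols)
    if len(frames) >= 2:
        sd = pd.DataFrame(stack.std(axis=0, ddof=1), columns=cols)
    else:
        sd = None
    return AggregateSeries(mean=mean, sd=sd, n_replicates=len(frames))


def stable_window(series, fraction: float = 0.5):
    """Drop the transient: the first ``ceil(fraction * length)`` entries.

    Works on DataFrames, Series and arrays; ``fraction`` 0 is the identity.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n = len(series)
    start = math.ceil(fraction * n)
    if start >= n:
        raise ValueError("stable window is empty")
    if isinstance(series, (pd.DataFrame, pd.Series)):
        return series.iloc[start:]
    return np.asarray(series)[start:]


def tlcc(x, y, max_lag: int) -> LagCorrelation:
    """Time-lagged cross-correlation of two equal-length series.

    For each lag ``k`` in ``[-max_lag, max_lag]``, the Pearson correlation
    of ``x_t`` with ``y_{t+k}`` over the overlapping window; each window is
    standardized by its own mean and sd (that is Pearson on the overlap),
    so amplitude drift does not masquerade as synchrony.  Windows with zero
    variance yield NaN.  Antisymmetry holds: ``r_xy(k) = r_yx(-k)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeMismatchError("x and y must be equal-length 1-D series")
    n = len(x)
    if max_lag < 0 or n <= 2 * max_lag:
        raise ValueError("need series length > 2 * max_lag >= 0")
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(lags.shape, np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        if a.std() == 0.0 or b.std() == 0.0:
            continue
        r[i] = np.corrcoef(a, b)[0, 1]
    return LagCorrelation(lags=lags, r=r)


def spectrum(series) -> Spectrum:
    """One-sided FFT amplitude spectrum of the mean-standardized series.

    The input (typically a stable-window population-size series) is
    transformed to ``z_t = (x_t - mean(x)) / mean(x)``; the returned
    amplitudes satisfy Parseval's identity against the variance of ``z``
    (see :meth:`Spectrum.total_power`).  A zero-mean series (an extinct
    window) has no defined standardization and raises.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("need a 1-D series of length >= 8")
    mu = x.mean()
    if mu == 0.0:
        raise UndefinedStatisticError(
            "mean-standardization undefined for a zero-mean series"
        )
    z = (x - mu) / mu
    n = len(z)
    Z = np.fft.rfft(z)
    amp = np.abs(Z) / n
    fold = np.full(amp.shape, 2.0)
    fold[0] = 1.0
    if n % 2 == 0:
        fold[-1] = 1.0
    amp = amp * fold
    spec = Spectrum(freqs=np.fft.rfftfreq(n), amplitude=amp)
    spec._fold = fold
    return spec


def mean_spectrum(series_list: Sequence, fraction: float = 0.5
                  ) -> tuple[Spectrum, int]:
    """Replicate-averaged spectrum of population-size series.

    Each series is cut to its stable window; windows that touch zero
    (extinct replicates, whose standardization is undefined) are excluded.
    Returns the pointwise-mean spectrum over the included replicates and
    the number excluded.
    """
    windows = [np.asarray(stable_window(s, fraction), dtype=float)
               for s in series_list]
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ShapeMismatchError("replicate windows must share one length")
    included = [w for w in windows if w.min() > 0]
    n_excluded = len(windows) - len(included)
    if not included:
        raise UndefinedStatisticError(
            "every replicate is extinct on the stable window"
        )
    specs = [spectrum(w) for w in included]
    amp = np.mean([s.amplitude for s in specs], axis=0)
    out = Spectrum(freqs=specs[0].freqs, amplitude=amp)
    out._fold = specs[0]._fold
    return out, n_excluded
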