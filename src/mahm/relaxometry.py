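"""Conventional ADC and T2 mapping from a hybrid stack.

The hybrid acquisition contains an ordinary diffusion decay at every TE
(S_b = S_SE exp(-b D), fit across b-values) and an ordinary T2 decay at
every b-value (S_TE = S0 exp(-TE/T2), fit across TEs).  In multi-compartment
tissue the mono-exponential fits are TE- and b-dependent: long TEs weight
the long-T2 (typically high-diffusivity, luminal) water, raising the fitted
ADC, while strong diffusion weighting suppresses fast-diffusing long-T2
water, lowering the fitted T2.  Mapping these fits per TE / per b exposes
that coupling.

Default fitting is unweighted least squares on the log signal (deterministic,
no initialization); a nonlinear option refines by least squares on the
exponential model starting from the log-linear estimate.  No Rician noise
floor correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from mahm.grid import HybridStack

__all__ = ["MonoExpFit", "fit_adc", "fit_t2", "parametric_maps", "ParametricMaps"]


@dataclass(frozen=True)
class MonoExpFit:
    """Result of a mono-exponential decay fit.

    ``amplitude`` is the extrapolated zero-attenuation signal (S_SE or S0);
    ``rate_param`` is D in mm^2/s for diffusion fits or T2 in ms for
    relaxation fits.  ``flagged`` marks non-physical results (D <= 0,
    T2 <= 0 or infinite) that should be excluded from quantitative maps.
    """

    amplitude: float
    rate_param: float
    rss: float
    n_points: int
    flagged: bool = False


def _loglinear(x: np.ndarray, signals: np.ndarray, weights: Optional[np.ndarray]):
    """Weighted LS line through (x, ln S); returns (slope, intercept)."""
    y = np.log(signals)
    w = weights if weights is not None else np.ones_like(y)
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx if sxx > 0 else 0.0
    return slope, ym - slope * xm


def _fit_decay(
    signals, x, method: str, weighted: bool
) -> tuple[float, float, float, int]:
    """Shared mono-exponential machinery; returns (amplitude, decay_rate,
    rss, n) where the model is S = amplitude * exp(-decay_rate * x)."""
    signals = np.asarray(signals, dtype=float)
    x = np.asarray(x, dtype=float)
    if signals.shape != x.shape:
        raise ValueError(f"got {signals.shape} signals for {x.shape} x-values")
    pos = signals > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 positive signals to fit a decay")
    s, xv = signals[pos], x[pos]
    weights = s**2 if weighted else None
    slope, intercept = _loglinear(xv, s, weights)
    amp, rate = float(np.exp(intercept)), float(-slope)
    if method == "nonlinear":
        try:
            popt, _ = curve_fit(
                lambda t, a, r: a * np.exp(-r * t), xv, s, p0=[amp, rate],
                maxfev=2000,
            )
            amp, rate = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass  # keep the log-linear estimate
    elif method != "log-linear":
        raise ValueError(f"unknown method {method!r}")
    rss = float(np.sum((s - amp * np.exp(-rate * xv)) ** 2))
    return amp, rate, rss, int(pos.sum())


def fit_adc(
    signals, bvalues, method: str = "log-linear", weighted: bool = False
) -> MonoExpFit:
    """Fit S_b = S_SE exp(-b D) across b-values at one TE.

    D is reported in mm^2/s when b is in s/mm^2.  A fit with D <= 0
    (non-decaying signal) is returned flagged rather than rejected.
    """
    amp, d, rss, n = _fit_decay(signals, bvalues, method, weighted)
    return MonoExpFit(amp, d, rss, n, flagged=d <= 0)


def fit_t2(
    signals, tes, method: str = "log-linear", weighted: bool = False
) -> MonoExpFit:
    """Fit S_TE = S0 exp(-TE/T2) across TEs at one b-value.

    The fitted decay rate is 1/T2; a non-decaying or growing signal gives a
    non-positive rate and is reported as T2 = inf (constant) or negative,
    flagged either way.
    """
    amp, rate, rss, n = _fit_decay(signals, tes, method, weighted)
    if rate > 0:
        return MonoExpFit(amp, 1.0 / rate, rss, n, flagged=False)
    t2 = np.inf if rate == 0 else 1.0 / rate
    return MonoExpFit(amp, float(t2), rss, n, flagged=True)


@dataclass
class ParametricMaps:
    """Per-TE ADC maps and per-b T2 maps over a volume.

    ``adc`` has shape ``spatial + (M,)`` (mm^2/s, one map per TE), ``t2``
    shape ``spatial + (N,)`` (ms, one map per b-value).  Invalid or flagged
    pixels hold NaN.
    """

    adc: np.ndarray
    t2: np.ndarray
    adc_amplitude: np.ndarray
    t2_amplitude: np.ndarray
    valid: np.ndarray
    tes: tuple[float, ...]
    bvalues: tuple[float, ...]


def _batch_loglinear(y: np.ndarray, x: np.ndarray):
    """Vectorized unweighted LS line fit of y[..., :] on x; returns
    (slope, intercept) arrays over the leading axes."""
    xm = x.mean()
    ym = y.mean(axis=-1)
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym[..., None]), axis=-1) / sxx
    return slope, ym - slope * xm


def parametric_maps(
    stack: HybridStack,
    mask: Optional[np.ndarray] = None,
    *,
    rel_floor: float = 1e-6,
) -> ParametricMaps:
    """Log-linear ADC and T2 maps for every TE / b-value of a stack.

    Pixels with any non-positive signal are floored (rel_floor x median
    positive signal) before the log; pixels with no positive signal are
    invalid.  Non-physical fits (D <= 0, T2 <= 0) map to NaN.
    """
    signal = stack.signal
    X, Y, Z, M, N = signal.shape
    if mask is None:
        mask = np.any(signal > 0, axis=(3, 4))
    mask = np.asarray(mask, dtype=bool)

    pos = signal[signal > 0]
    floor = rel_floor * (np.median(pos) if pos.size else 1.0)
    lnS_safe = np.maximum(signal, floor)

    bvals = np.asarray(stack.grid.bvalues, dtype=float)
    tes = np.asarray(stack.grid.tes, dtype=float)

    # ADC at each TE: fit ln S over b (last axis already b)
    y_adc = np.log(lnS_safe)  # (X,Y,Z,M,N)
    slope_b, icpt_b = _batch_loglinear(y_adc, bvals)
    adc = -slope_b  # (X,Y,Z,M)
    adc_amp = np.exp(icpt_b)

    # T2 at each b: fit ln S over TE
    y_t2 = np.moveaxis(y_adc, 3, 4)  # (X,Y,Z,N,M)
    slope_t, icpt_t = _batch_loglinear(y_t2, tes)
    with np.errstate(divide="ignore"):
        t2 = np.where(slope_t < 0, -1.0 / slope_t, np.nan)
    t2_amp = np.exp(icpt_t)

    adc = np.where(adc > 0, adc, np.nan)
    invalid = ~(mask & np.any(signal > 0, axis=(3, 4)))
    adc[invalid] = np.nan
    t2[invalid] = np.nan
    adc_amp[invalid] = np.nan
    t2_amp[invalid] = np.nan

    return ParametricMaps(
        adc=adc,
        t2=t2,
        adc_amplitude=adc_amp,
        t2_amplitude=t2_amp,
        valid=~invalid,
        tes=stack.grid.tes,
        bvalues=stack.grid.bvalues,
    )
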