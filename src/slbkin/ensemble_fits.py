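"""Ensemble biochemical assay fits.

Two workhorse forms cover the bulk assays around the single-molecule work:

* hyperbolic saturation, v = A * c / (K + c) — stimulated GTPase turnover
  (A = kcat in 1/min, K = Km in µM) and co-translational translocation
  (A = Vmax in %, K = K1/2 in µM);
* single exponentials — stopped-flow time courses of the early-to-closed
  rearrangement, rising offset + amplitude*(1 - exp(-rate*t)) or the
  decaying counterpart, autodetected from the trend of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = ["SaturationFitResult", "ExpFitResult", "fit_saturation", "fit_single_exp"]


@dataclass
class SaturationFitResult:
    vmax_like: float
    half_sat: float
    se: tuple[float, float]
    rss: float
    kind: str
    wide_error: bool = False


def fit_saturation(conc, response, kind: str = "gtpase") -> SaturationFitResult:
    """Nonlinear least squares of v = A*c/(K + c).

    Initial guesses: A0 = max(response), K0 = concentration at half-max.
    Data confined to the linear regime (c << K) identify only A/K; such
    non-saturating fits are returned with ``wide_error=True``.
    """
    c = np.asarray(conc, dtype=float)
    v = np.asarray(response, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if len(c) < 4:
        raise ValueError("need at least 4 concentration points")

    vmax0 = float(np.max(v))
    half = vmax0 / 2.0
    k0 = float(c[np.argmin(np.abs(v - half))])
    params = lmfit.Parameters()
    params.add("A", value=max(vmax0, 1e-12), min=0.0)
    params.add("K", value=max(k0, 1e-9), min=1e-12)

    def residual(p):
        return p["A"].value * c / (p["K"].value + c) - v

    res = lmfit.minimize(residual, params, method="leastsq")
    A, K = res.params["A"], res.params["K"]
    se = (
        float(A.stderr) if A.stderr is not None else float("nan"),
        float(K.stderr) if K.stderr is not None else float("nan"),
    )
    rss = float(np.sum(res.residual**2))
    # non-saturating data: half-saturation beyond the sampled range, or the
    # plateau essentially unconstrained
    wide = bool(
        K.value > float(np.max(c))
        or (np.isfinite(se[1]) and se[1] > K.value)
        or not np.isfinite(se[1])
    )
    return SaturationFitResult(
        vmax_like=float(A.value), half_sat=float(K.value), se=se, rss=rss,
        kind=kind, wide_error=wide,
    )


@dataclass
class ExpFitResult:
    rate: float
    amplitude: float
    offset: float
    rising: bool
    non_monotone_flag: bool = False


def fit_single_exp(times, signal) -> ExpFitResult:
    """Fit offset + amplitude*(1 - exp(-rate*t)) (rising) or
    offset + amplitude*exp(-rate*t) (decaying), autodetected by trend sign."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    rising = bool(y[-1] >= y[0])
    span = float(np.max(y) - np.min(y))
    # flag clearly non-monotone traces (overshoot beyond plausible noise)
    head, tail = y[: max(len(y) // 5, 2)], y[-max(len(y) // 5, 2):]
    inner = y[1:-1]
    overshoot = float(
        max(np.max(inner) - max(head.mean(), tail.mean()),
            min(head.mean(), tail.mean()) - np.min(inner), 0.0)
    )
    non_monotone = span > 0 and overshoot > 0.2 * span

    t_span = float(t[-1] - t[0]) or 1.0
    params = lmfit.Parameters()
    params.add("rate", value=3.0 / t_span, min=1e-9)
    params.add("amp", value=span if rising else span)
    params.add("offset", value=float(y[0]) if rising else float(np.min(y)))

    def residual(p):
        r, a, o = p["rate"].value, p["amp"].value, p["offset"].value
        model = o + a * (1.0 - np.exp(-r * t)) if rising else o + a * np.exp(-r * t)
        return model - y

    res = lmfit.minimize(residual, params, method="leastsq")
    return ExpFitResult(
        rate=float(res.params["rate"].value),
        amplitude=float(res.params["amp"].value),
        offset=float(res.params["offset"].value),
        rising=rising,
        non_monotone_flag=non_monotone,
    )
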