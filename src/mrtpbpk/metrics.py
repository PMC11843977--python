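"""Non-compartmental exposure metrics: AUC, ABC and %PE.

AUC is the linear trapezoidal area from the first to the last observed time
point, with no terminal extrapolation.  The antibody biodistribution
coefficient (ABC) is the tissue-to-plasma AUC ratio expressed as a
percentage; the source literature prints the defining equation with a factor
of 10, but every reported value (e.g. epididymis 2253/87505 -> 2.57%) is
consistent with x100, which is what is implemented here.  The percentage
prediction error is %PE = 100*(AUC_pred/AUC_obs - 1), positive when the
model overpredicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PKCurve", "auc_linear_trapezoid", "auc_log_trapezoid",
           "abc_percent", "percent_prediction_error",
           "absolute_percent_prediction_error"]


@dataclass(frozen=True)
class PKCurve:
    """A concentration-time profile for one tissue."""

    times: np.ndarray
    concentrations: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.shape != t.shape or len(t) < 2:
            raise ValueError("need matched 1-D arrays with >= 2 points")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(c)):
            raise ValueError("times and concentrations must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")


def auc_linear_trapezoid(curve: PKCurve) -> float:
    """Linear-trapezoid AUC over the observed window, h*nmol/L."""
    return float(np.trapezoid(curve.concentrations, curve.times))


def auc_log_trapezoid(curve: PKCurve) -> float:
    """Log-trapezoidal AUC (linear rule wherever a segment touches zero or
    rises); provided for comparison, not the default."""
    t, c = curve.times, curve.concentrations
    total = 0.0
    for k in range(len(t) - 1):
        c0, c1, dt = c[k], c[k + 1], t[k + 1] - t[k]
        if c0 > 0 and c1 > 0 and c1 < c0:
            total += dt * (c0 - c1) / np.log(c0 / c1)
        else:
            total += dt * 0.5 * (c0 + c1)
    return float(total)


def abc_percent(auc_tissue: float, auc_plasma: float) -> float:
    """Antibody biodistribution coefficient, % of plasma exposure."""
    if auc_plasma <= 0:
        raise ValueError("plasma AUC must be positive")
    if auc_tissue < 0:
        raise ValueError("tissue AUC must be non-negative")
    return 100.0 * auc_tissue / auc_plasma


def percent_prediction_error(auc_pred: float, auc_obs: float) -> float:
    """%PE = 100 * (AUC_pred / AUC_obs - 1); sign marks over/underprediction."""
    if auc_obs <= 0:
        raise ValueError("observed AUC must be positive")
    return 100.0 * (auc_pred / auc_obs - 1.0)


def absolute_percent_prediction_error(auc_pred: float, auc_obs: float,
                                      ndigits: int = 1) -> float:
    """|%PE| rounded for tabulation (one decimal, as conventionally printed)."""
    return round(abs(percent_prediction_error(auc_pred, auc_obs)), ndigits)
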