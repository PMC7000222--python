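"""One-site saturation binding analysis.

Fits the monovalent ("one-site specific") isotherm

    Y = Bmax * X / (Kd + X)

to (concentration, bound-signal) data by nonlinear least squares, the
standard route to an apparent equilibrium dissociation constant Kd from a
pulldown or titration series.  Replicates are pooled into one residual
vector by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError
from .synthetic import BindingData

__all__ = ["BindingFit", "one_site", "fit_one_site", "predict_one_site"]


@dataclass
class BindingFit:
    """Fitted isotherm parameters and goodness of fit."""

    bmax: float                    # maximum binding capacity (Y units)
    kd: float                      # dissociation constant (X units, nM)
    r2: float
    residuals: np.ndarray
    covariance: np.ndarray         # 2×2, order (bmax, kd)
    bmax_stderr: float
    kd_stderr: float


def one_site(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """Forward isotherm Bmax·X/(Kd + X)."""
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x)


def fit_one_site(data: BindingData, init: tuple[float, float] | None = None,
                 per_replicate: bool = False):
    """Least-squares fit of the one-site isotherm.

    Initialization defaults to Bmax₀ = max(Y), Kd₀ = median(X).  Replicates
    are pooled into a single residual vector unless ``per_replicate`` is
    set, in which case a list of per-replicate fits is returned.
    """
    if per_replicate:
        if data.replicate is None:
            raise FitError("data carries no replicate labels")
        fits = []
        for rep in np.unique(data.replicate):
            sel = data.replicate == rep
            fits.append(fit_one_site(BindingData(x=data.x[sel], y=data.y[sel]),
                                     init=init))
        return fits

    x, y = data.x, data.y
    if np.unique(x).size < 3:
        raise FitError("need ≥3 distinct concentrations to fit two parameters")
    p0 = init if init is not None else (float(np.max(y)), float(np.median(x)))
    try:
        popt, pcov = curve_fit(one_site, x, y, p0=p0,
                               bounds=([0.0, 0.0], [np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"one-site fit did not converge: {exc}") from exc
    bmax, kd = (float(v) for v in popt)
    if bmax <= 0 or kd <= 0:
        raise FitError(f"inadmissible estimates bmax={bmax}, kd={kd}")
    resid = y - one_site(x, bmax, kd)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    err = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return BindingFit(bmax=bmax, kd=kd, r2=r2, residuals=resid,
                      covariance=pcov, bmax_stderr=float(err[0]),
                      kd_stderr=float(err[1]))


def predict_one_site(fit: BindingFit, x) -> np.ndarray:
    """Evaluate the fitted isotherm at concentrations ``x``."""
    return one_site(np.asarray(x, dtype=float), fit.bmax, fit.kd)
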