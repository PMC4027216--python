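"""Four-parameter logistic (4PL) dose-response fitting and IC50 estimation.

The symmetric 4PL on log-dose is the standard potency model for plate-based
screens::

    response(c) = bottom + (top - bottom) / (1 + (c / ec50) ** hill)

With ``hill > 0`` the response falls from ``top`` (low dose) to ``bottom``
(high dose), which is the orientation of an inhibitor titration expressed as
percent of vehicle control.  The IC50 reported here is the fitted midpoint
concentration, which for the symmetric 4PL equals ``ec50``; an absolute-50%
definition (concentration crossing half of a stated reference response) is
available as an option.  Uncertainty is quantified by a seeded residual
bootstrap rather than asymptotic standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FourPL", "FitResult", "fit_4pl", "ic50", "ic50_interval"]


@dataclass(frozen=True)
class FourPL:
    """Parameters of a four-parameter logistic curve.

    bottom, top : response units (e.g. normalized HDR %)
    hill : dimensionless slope (positive = decreasing with dose)
    ec50 : concentration of the half-maximal response, in the units of the
        concentrations the curve is evaluated at (micromolar throughout this
        package).
    """

    bottom: float
    top: float
    hill: float
    ec50: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")

    def predict(self, conc):
        """Evaluate the curve at concentration(s) ``conc`` (> 0)."""
        c = np.asarray(conc, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (c / self.ec50) ** self.hill
        )


@dataclass(frozen=True)
class FitResult:
    params: FourPL | None
    converged: bool
    residual_sd: float
    n: int
    message: str = ""


def _model(logc, bottom, top, hill, log_ec50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ec50)))


def fit_4pl(concentrations, responses, weights=None) -> FitResult:
    """Least-squares 4PL fit on log10 concentration.

    Parameters
    ----------
    concentrations : array-like of positive micromolar doses (>= 4 distinct).
    responses : array-like of responses, same length.
    weights : optional per-point standard deviations (passed as ``sigma``).

    Returns a :class:`FitResult`; degenerate data (flat responses, failed
    optimisation) yield ``converged=False`` rather than an exception, so a
    caller can report non-convergence explicitly.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive (log-scale fit)")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")

    n = y.size
    span = float(np.ptp(y))
    scale = max(1.0, float(np.max(np.abs(y))))
    if span < 1e-9 * scale:
        return FitResult(None, False, 0.0, n, "responses are constant")

    logc = np.log10(c)
    lo, hi = float(np.min(y)), float(np.max(y))
    # slope sign from the dose-response trend; hill>0 means decreasing
    trend = np.polyfit(logc, y, 1)[0]
    hill0 = 1.0 if trend < 0 else -1.0
    mid = 0.5 * (lo + hi)
    log_ec50_0 = float(logc[np.argmin(np.abs(y - mid))])
    p0 = (lo, hi, hill0, log_ec50_0)

    try:
        popt, _ = curve_fit(
            _model, logc, y, p0=p0, sigma=weights, maxfev=20000,
            bounds=([-np.inf, -np.inf, -20, logc.min() - 6],
                    [np.inf, np.inf, 20, logc.max() + 6]),
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
        return FitResult(None, False, float("nan"), n, f"optimisation failed: {exc}")

    bottom, top, hill, log_ec50 = (float(v) for v in popt)
    resid = y - _model(logc, *popt)
    dof = max(n - 4, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    if abs(top - bottom) < max(1e-6 * scale, 1e-12):
        return FitResult(None, False, residual_sd, n, "degenerate fit (top == bottom)")
    params = FourPL(bottom=bottom, top=top, hill=hill, ec50=10.0**log_ec50)
    return FitResult(params, True, residual_sd, n)


def ic50(fit: FitResult, mode: str = "midpoint", reference: float | None = None) -> float:
    """IC50 from a converged 4PL fit, in concentration units.

    ``mode="midpoint"`` (default) returns the fitted half-maximal
    concentration, i.e. ``ec50`` of the symmetric 4PL.  ``mode="absolute"``
    solves ``response(c) = reference / 2`` for a stated reference response
    (e.g. 100 for percent-of-control data).
    """
    if not fit.converged or fit.params is None:
        raise ValueError(f"fit did not converge: {fit.message}")
    p = fit.params
    if mode == "midpoint":
        return p.ec50
    if mode == "absolute":
        if reference is None:
            raise ValueError("absolute mode needs a reference response")
        half = reference / 2.0
        ratio = (p.top - p.bottom) / (half - p.bottom) - 1.0
        if ratio <= 0:
            raise ValueError("half-reference response outside the fitted range")
        return p.ec50 * ratio ** (1.0 / p.hill)
    raise ValueError(f"unknown mode {mode!r}")


def ic50_interval(
    concentrations,
    responses,
    fit: FitResult,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded residual-bootstrap percentile interval for the midpoint IC50.

    Residuals from the converged fit are resampled with replacement onto the
    fitted curve and the model is refit; non-converged resamples are skipped.
    """
    if not fit.converged or fit.params is None:
        raise ValueError("cannot bootstrap a non-converged fit")
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    fitted = fit.params.predict(c)
    resid = y - fitted
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
        f = fit_4pl(c, y_star)
        if f.converged:
            draws.append(f.params.ec50)
    if not draws:
        raise RuntimeError("no bootstrap resample converged")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
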