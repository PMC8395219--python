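"""Hill-equation pharmacology: dose-response and saturation binding.

The sigmoid dose-response model is

    f(x) = bottom + (top − bottom) / (1 + (EC50 / x)^n)

with Hill coefficient n. Fitting is nonlinear least squares in
log-EC50 space with the span (top − bottom) constrained non-negative, so
``top ≥ bottom`` and ``f(EC50) = (top + bottom)/2`` hold by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class HillFit:
    bottom: float
    top: float
    EC50: float  # same units as the concentrations supplied (nM typical)
    n: float  # Hill coefficient
    covariance: np.ndarray | None
    converged: bool
    degenerate: bool = False  # all responses equal

    def predict(self, x: np.ndarray) -> np.ndarray:
        return hill_curve(np.asarray(x, float), self.bottom, self.top, self.EC50, self.n)


def hill_curve(
    x: np.ndarray, bottom: float, top: float, ec50: float, n: float
) -> np.ndarray:
    """Evaluate the Hill equation at concentrations x (> 0)."""
    x = np.asarray(x, float)
    return bottom + (top - bottom) / (1 + (ec50 / x) ** n)


def hill_fit(
    concentrations: np.ndarray,
    responses: np.ndarray,
    weights: np.ndarray | None = None,
) -> HillFit:
    """Fit the Hill equation by nonlinear least squares.

    Requires ≥4 distinct positive concentrations. Parameterization:
    ``(bottom, span, log10 EC50, n)`` with span ≥ 0 and n ∈ (0, 10];
    initial guesses from the response quartiles and the mid-response
    concentration.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(responses, float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.ptp(y) == 0:
        return HillFit(
            bottom=float(y[0]),
            top=float(y[0]),
            EC50=float(np.median(x)),
            n=1.0,
            covariance=None,
            converged=False,
            degenerate=True,
        )

    b0 = float(np.quantile(y, 0.05))
    t0 = float(np.quantile(y, 0.95))
    mid = (b0 + t0) / 2
    # concentration whose mean response is nearest the midpoint
    xs = np.unique(x)
    ybar = np.array([y[x == xi].mean() for xi in xs])
    ec0 = float(xs[np.argmin(np.abs(ybar - mid))])

    def model(x, bottom, span, logec50, n):
        return hill_curve(x, bottom, bottom + span, 10.0**logec50, n)

    sigma = None
    if weights is not None:
        w = np.asarray(weights, float)
        sigma = 1.0 / np.sqrt(w)
    try:
        popt, pcov = optimize.curve_fit(
            model,
            x,
            y,
            p0=[b0, max(t0 - b0, 1e-9), np.log10(ec0), 1.0],
            sigma=sigma,
            bounds=([-np.inf, 0, -12, 1e-3], [np.inf, np.inf, 12, 10]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Hill fit did not converge (initial guesses bottom={b0:.3g}, "
            f"top={t0:.3g}, EC50={ec0:.3g})"
        ) from exc
    bottom, span, logec50, n = popt
    return HillFit(
        bottom=float(bottom),
        top=float(bottom + span),
        EC50=float(10.0**logec50),
        n=float(n),
        covariance=pcov,
        converged=True,
    )


def hill_fit_table(table: pd.DataFrame) -> HillFit:
    """Fit from a long-format table (columns concentration_nM, response)."""
    return hill_fit(table["concentration_nM"].to_numpy(), table["response"].to_numpy())


def peak_response(
    trace: np.ndarray, baseline_window: slice, stimulation_index: int | None = None
) -> float:
    """Peak response normalized to the pre-stimulation baseline.

    ``max(trace after stimulation) / mean(trace in baseline window)``.
    The stimulation index defaults to the end of the baseline window.
    """
    trace = np.asarray(trace, float)
    base = trace[baseline_window]
    if len(base) == 0:
        raise ValueError("empty baseline window")
    if stimulation_index is None:
        stimulation_index = baseline_window.stop or len(base)
    if stimulation_index < (baseline_window.stop or 0):
        raise ValueError("baseline window must precede stimulation")
    b = float(np.mean(base))
    if b == 0:
        raise ValueError("zero baseline")
    return float(np.max(trace[stimulation_index:]) / b)


def specific_binding(
    concentrations: np.ndarray,
    total: np.ndarray,
    nonspecific: np.ndarray,
) -> tuple[np.ndarray, HillFit]:
    """Specific binding = total − nonspecific, floored at 0, Hill-fitted.

    Concentration grids of the two measurements must match point-for-point.
    """
    x = np.asarray(concentrations, float)
    tot = np.asarray(total, float)
    ns = np.asarray(nonspecific, float)
    if tot.shape != ns.shape or tot.shape != x.shape:
        raise ValueError("concentration grids of total and nonspecific must match")
    spec = tot - ns
    if np.any(spec < 0):
        warnings.warn("negative specific binding floored at 0")
        spec = np.clip(spec, 0, None)
    fit = hill_fit(x, spec)
    return spec, fit
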