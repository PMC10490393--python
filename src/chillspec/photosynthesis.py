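"""Light-response curve fitting and gas-exchange indicators.

The light-response model is the modified rectangular hyperbola

    A(I) = alpha * (1 - beta*I) / (1 + gamma*I) * (I - Ic)

which yields the four summary indicators simultaneously: the light
compensation point LCP = Ic (A(Ic) = 0 by construction), the light
saturation point LSP = argmax A(I) found numerically on [0, 2000]
umol m-2 s-1, the maximum net photosynthetic rate Amax = A(LSP), and the
apparent quantum efficiency AQE = A'(0) = alpha * (1 + (beta + gamma) * Ic).

Water-use efficiency is WUE = A/E and the stomatal signal ci/ca is reported
as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .synthetic_cohort import LightResponseCurve, light_response_model

__all__ = [
    "LightResponseFit",
    "FitError",
    "fit_light_response",
    "water_use_efficiency",
    "ci_ca_ratio",
]

LSP_SEARCH_MAX = 2000.0  # umol m-2 s-1; the analyzer program tops out at 1800


class FitError(RuntimeError):
    """Light-response fit failed to converge or produced a degenerate curve."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class LightResponseFit:
    alpha: float
    beta: float
    gamma: float
    Ic: float
    Amax: float   # umol CO2 m-2 s-1
    LCP: float    # umol m-2 s-1
    LSP: float    # umol m-2 s-1
    AQE: float    # umol CO2 umol-1 photons
    rss: float
    lsp_at_cap: bool = False

    def predict(self, par) -> np.ndarray:
        return light_response_model(par, self.alpha, self.beta, self.gamma,
                                    self.Ic)


def _validate_curve(curve: LightResponseCurve) -> None:
    par = np.asarray(curve.par_levels, dtype=float)
    A = np.asarray(curve.A_values, dtype=float)
    if par.shape != A.shape:
        raise ValueError("par_levels and A_values must be paired")
    if np.unique(par).size < 6:
        raise ValueError("need >= 6 distinct PAR levels")
    if not np.any(par == 0):
        raise ValueError("PAR program must include 0")
    if np.any(par < 0):
        raise ValueError("PAR must be non-negative")
    if np.allclose(A, A[0]):
        raise ValueError("A values are constant; nothing to fit")


def fit_light_response(curve: LightResponseCurve,
                       init: tuple | None = None,
                       tol: float = 1e-10,
                       aqe_linear_region: bool = False) -> LightResponseFit:
    """Bounded nonlinear least-squares fit of the light-response model.

    Parameters
    ----------
    init : optional (alpha, beta, gamma, Ic) starting point; the default
        strategy uses the initial secant slope for alpha and the first PAR
        level with positive assimilation for Ic.
    aqe_linear_region : report AQE as the OLS slope over PAR <= 200 instead
        of the fitted curve's derivative at zero.
    """
    _validate_curve(curve)
    par = np.asarray(curve.par_levels, dtype=float)
    A = np.asarray(curve.A_values, dtype=float)

    if init is None:
        order = np.argsort(par)
        p_s, a_s = par[order], A[order]
        nz = p_s > 0
        alpha0 = (a_s[nz][0] - a_s[0]) / p_s[nz][0] if nz.any() else 0.05
        alpha0 = float(np.clip(alpha0, 1e-4, 0.2))
        pos = p_s[a_s > 0]
        Ic0 = float(pos[0]) if pos.size else 10.0
        Ic0 = min(Ic0, 200.0)
        init = (alpha0, 1e-4, 1e-3, Ic0)

    def residuals(theta):
        return light_response_model(par, *theta) - A

    lb = [1e-6, 0.0, 0.0, 0.0]
    ub = [1.0, 5e-3, 5e-2, 500.0]
    sol = least_squares(residuals, x0=np.asarray(init, dtype=float),
                        bounds=(lb, ub), ftol=tol, xtol=tol, gtol=tol)
    if not sol.success:
        raise FitError(f"light-response fit did not converge: {sol.message}",
                       last_iterate=sol.x)
    alpha, beta, gamma, Ic = sol.x

    res = minimize_scalar(
        lambda i: -light_response_model(i, alpha, beta, gamma, Ic),
        bounds=(0.0, LSP_SEARCH_MAX), method="bounded",
        options={"xatol": 1e-6})
    LSP = float(res.x)
    Amax = float(light_response_model(LSP, alpha, beta, gamma, Ic))
    if Amax < 0:
        raise FitError("degenerate fit: negative fitted Amax", last_iterate=sol.x)
    lsp_at_cap = LSP > LSP_SEARCH_MAX - 1e-3

    if aqe_linear_region:
        low = par <= 200.0
        aqe = float(np.polyfit(par[low], A[low], 1)[0])
    else:
        aqe = float(alpha * (1.0 + (beta + gamma) * Ic))

    return LightResponseFit(alpha=float(alpha), beta=float(beta),
                            gamma=float(gamma), Ic=float(Ic), Amax=Amax,
                            LCP=float(Ic), LSP=LSP, AQE=aqe,
                            rss=float(2.0 * sol.cost), lsp_at_cap=lsp_at_cap)


def water_use_efficiency(A: float, E: float) -> float:
    """WUE = A / E, umol CO2 per mmol H2O."""
    if E <= 0:
        raise ValueError("transpiration E must be > 0")
    return A / E


def ci_ca_ratio(ci: float, ca: float) -> float:
    """Intercellular-to-atmospheric CO2 concentration ratio."""
    if ca <= 0:
        raise ValueError("atmospheric CO2 ca must be > 0")
    return ci / ca
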