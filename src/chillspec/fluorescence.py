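"""PAM chlorophyll-fluorescence quenching parameters.

Standard Genty/Kramer "lake model" definitions derived from the five raw
fluorescence levels recorded by a saturating-pulse fluorometer
(F0, Fm dark-adapted; Fs, F0', Fm' light-adapted):

    Fv/Fm   = (Fm - F0) / Fm
    Fv'/Fm' = (Fm' - F0') / Fm'
    qP      = (Fm' - Fs) / (Fm' - F0')
    qL      = qP * F0' / Fs
    qN      = (Fm - Fm') / (Fm - F0')
    Y(II)   = (Fm' - Fs) / Fm'
    Y(NPQ)  = Fs/Fm' - Fs/Fm
    Y(NO)   = Fs / Fm

These satisfy the energy-partition identity Y(II) + Y(NPQ) + Y(NO) = 1
exactly.  1 - qP is reported alongside qP as the fraction of closed PSII
reaction centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import FluorescenceRaw

__all__ = ["FluorescenceDerived", "DegenerateTraceError",
           "derive_fluorescence_params"]

_CLAMP_TOL = 1e-9


class DegenerateTraceError(ValueError):
    """Raised when raw levels make a quenching parameter undefined."""


@dataclass
class FluorescenceDerived:
    FvFm: float
    FvpFmp: float
    qP: float
    qL: float
    qN: float
    one_minus_qP: float
    YII: float
    YNPQ: float
    YNO: float


def _validate(raw: FluorescenceRaw) -> None:
    if not (0 < raw.F0 < raw.Fm):
        raise DegenerateTraceError("require 0 < F0 < Fm")
    if not (0 < raw.F0p <= raw.Fs <= raw.Fmp <= raw.Fm):
        raise DegenerateTraceError("require 0 < F0' <= Fs <= Fm' <= Fm")
    if raw.Fmp - raw.F0p <= 0:
        raise DegenerateTraceError("Fm' = F0': quenching coefficients undefined")


def _clamp_unit(value: float, name: str) -> float:
    """Clamp tiny rounding excursions outside [0, 1]; larger ones raise."""
    if value < -_CLAMP_TOL or value > 1.0 + _CLAMP_TOL:
        raise DegenerateTraceError(f"{name} = {value} outside [0, 1]")
    return float(min(max(value, 0.0), 1.0))


def derive_fluorescence_params(raw: FluorescenceRaw) -> FluorescenceDerived:
    """Derive the nine quenching/yield parameters from raw PAM levels."""
    _validate(raw)
    F0, Fm, Fs, F0p, Fmp = raw.F0, raw.Fm, raw.Fs, raw.F0p, raw.Fmp

    fvfm = _clamp_unit((Fm - F0) / Fm, "Fv/Fm")
    fvpfmp = _clamp_unit((Fmp - F0p) / Fmp, "Fv'/Fm'")
    qp = _clamp_unit((Fmp - Fs) / (Fmp - F0p), "qP")
    ql = _clamp_unit(qp * F0p / Fs, "qL")
    qn = _clamp_unit((Fm - Fmp) / (Fm - F0p), "qN")
    yii = _clamp_unit((Fmp - Fs) / Fmp, "Y(II)")
    ynpq = _clamp_unit(Fs / Fmp - Fs / Fm, "Y(NPQ)")
    yno = _clamp_unit(Fs / Fm, "Y(NO)")

    return FluorescenceDerived(FvFm=fvfm, FvpFmp=fvpfmp, qP=qp, qL=ql, qN=qn,
                               one_minus_qP=1.0 - qp, YII=yii, YNPQ=ynpq,
                               YNO=yno)
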