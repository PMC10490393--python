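"""Synthetic chilling-stress cohort generator.

Emulates a 2-cultivar x 4-temperature x 3-duration factorial experiment on
strawberry plants: a scalar latent stress per treatment cell drives monotone
shifts in raw gas-exchange, PAM fluorescence, solar-induced fluorescence (SIF)
and leaf reflectance measurements, so that every downstream stage of the
pipeline can be tested against known ground truth.

Design highlights
-----------------
* Latent stress is deterministic per (cultivar, temperature level, duration):
  a per-level severity times a duration ramp, with a fixed negative recovery
  term for the short-day cultivar after 9 days at the mildest chilling level
  (short-day strawberries acclimate to 20/10 degC and rebound to an
  unstressed state).
* Raw measurements are noise-free stress-driven means plus independent
  Gaussian noise; all noise standard deviations scale with a single
  ``noise_scale`` multiplier so a noise-free cohort is one config away.
* Seeding: one master seed; per-record substreams are derived from
  ``numpy.random.SeedSequence`` spawn keys built from the treatment cell and
  replicate indices, so cohorts are reproducible and extensible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CULTIVARS",
    "TEMPERATURE_LEVELS",
    "DURATIONS",
    "TreatmentLabel",
    "CohortConfig",
    "GasExchangeRaw",
    "FluorescenceRaw",
    "LightResponseCurve",
    "SpectrumPair",
    "ReflectanceSpectrum",
    "PlantRecord",
    "latent_stress",
    "make_cohort",
    "simulate_reflectance",
    "simulate_sif_spectra",
    "reflectance_wavelengths",
    "sif_wavelengths",
    "write_cohort",
]

CULTIVARS = ("short_day", "long_day")
TEMPERATURE_LEVELS = ("CK", "T1", "T2", "T3")  # 25/15, 20/10, 15/5, 10/0 degC
DURATIONS = (3, 6, 9)

# 18-step PAR program of the gas-exchange analyzer (duplicates retained).
PAR_PROGRAM = np.array(
    [600, 1200, 1800, 1800, 1800, 1600, 1400, 1200, 1000, 800,
     600, 400, 200, 150, 100, 50, 20, 0],
    dtype=float,
)

REFLECTANCE_N_BANDS = 224
REFLECTANCE_RANGE = (410.49, 990.07)  # nm
SIF_RANGE = (645.0, 800.0)  # nm
SIF_STEP = 0.7  # nm, oversampled relative to the 1.4 nm instrument resolution

# Retrieval windows flattened in the injected emission spectrum so that the
# three-band retrieval is exact on noise-free spectra (see module docstring).
O2B_WINDOW = (683.0, 698.0)
O2B_CENTER = 687.0
O2A_WINDOW = (757.0, 771.0)
O2A_CENTER = 760.5


class CohortValidationError(ValueError):
    """Raised for invalid treatment labels or cohort configuration."""


@dataclass(frozen=True)
class TreatmentLabel:
    """One cell of the factorial design plus a replicate index."""

    cultivar: str
    temperature_level: str
    duration_days: int
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.cultivar not in CULTIVARS:
            raise CohortValidationError(f"unknown cultivar {self.cultivar!r}")
        if self.temperature_level not in TEMPERATURE_LEVELS:
            raise CohortValidationError(
                f"unknown temperature level {self.temperature_level!r}")
        if self.duration_days not in DURATIONS:
            raise CohortValidationError(
                f"duration must be one of {DURATIONS}, got {self.duration_days}")
        if self.replicate < 1:
            raise CohortValidationError("replicate must be >= 1")

    @property
    def record_id(self) -> str:
        code = {"short_day": "SD", "long_day": "LD"}[self.cultivar]
        return f"{code}_{self.temperature_level}D{self.duration_days}_r{self.replicate:02d}"


@dataclass
class StressParams:
    """Coefficients mapping treatments to latent stress in [0, 1].

    severity: per-temperature-level base severity.
    duration_factor: multiplicative ramp over treatment duration.
    cultivar_scale: per-cultivar susceptibility multiplier (short-day
        strawberries are the more cold-tolerant).
    recovery: subtracted for the short-day cultivar at T1 after 9 days,
        emulating the acclimation rebound.
    """

    severity: Dict[str, float] = field(default_factory=lambda: {
        "CK": 0.0, "T1": 0.30, "T2": 0.60, "T3": 0.85})
    duration_factor: Dict[int, float] = field(default_factory=lambda: {
        3: 0.75, 6: 1.00, 9: 1.20})
    cultivar_scale: Dict[str, float] = field(default_factory=lambda: {
        "short_day": 0.90, "long_day": 1.00})
    recovery: float = 0.20


@dataclass
class CohortConfig:
    n_replicates: int = 18
    seed: int = 0
    noise_scale: float = 1.0
    stress_params: StressParams = field(default_factory=StressParams)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise CohortValidationError("n_replicates must be >= 1")
        if self.noise_scale < 0:
            raise CohortValidationError("noise_scale must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "noise_scale": self.noise_scale,
            "stress_params": {
                "severity": self.stress_params.severity,
                "duration_factor": {str(k): v for k, v in
                                    self.stress_params.duration_factor.items()},
                "cultivar_scale": self.stress_params.cultivar_scale,
                "recovery": self.stress_params.recovery,
            },
        }


@dataclass
class GasExchangeRaw:
    """Steady-state gas exchange at saturating light."""

    A: float      # net photosynthetic rate, umol CO2 m-2 s-1
    gs: float     # stomatal conductance, mol m-2 s-1
    E: float      # transpiration, mmol H2O m-2 s-1
    ci: float     # intercellular CO2, umol mol-1
    ca: float     # atmospheric CO2, umol mol-1


@dataclass
class FluorescenceRaw:
    """Raw PAM fluorescence levels (arbitrary units)."""

    F0: float
    Fm: float
    Fs: float
    F0p: float
    Fmp: float


@dataclass
class LightResponseCurve:
    """Paired PAR / net assimilation measurements."""

    par_levels: np.ndarray
    A_values: np.ndarray


@dataclass
class SpectrumPair:
    """Leaf radiance and whiteboard irradiance on a shared wavelength grid."""

    wavelength: np.ndarray   # nm
    radiance: np.ndarray     # mW m-2 sr-1 nm-1
    irradiance: np.ndarray   # mW m-2 nm-1


@dataclass
class ReflectanceSpectrum:
    wavelength: np.ndarray
    reflectance: np.ndarray


@dataclass
class PlantRecord:
    label: TreatmentLabel
    latent_stress: float
    light_response: LightResponseCurve
    gas_exchange: GasExchangeRaw
    pam: FluorescenceRaw
    sif_spectra: SpectrumPair
    reflectance: ReflectanceSpectrum
    # Injected-fluorescence ground truth at the two line centers, for
    # retrieval recovery tests.
    true_F_O2B: float = float("nan")
    true_F_O2A: float = float("nan")


# ---------------------------------------------------------------------------
# Latent stress
# ---------------------------------------------------------------------------

def latent_stress(label: TreatmentLabel, config: CohortConfig) -> float:
    """Deterministic latent stress in [0, 1] for one treatment cell.

    Controls sit at zero stress; stress grows with chilling severity and
    duration, except that the short-day cultivar partially recovers after
    9 days at the mildest chilling level (T1).
    """
    p = config.stress_params
    s = (p.cultivar_scale[label.cultivar]
         * p.severity[label.temperature_level]
         * p.duration_factor[label.duration_days])
    if (label.cultivar == "short_day" and label.temperature_level == "T1"
            and label.duration_days == 9):
        s -= p.recovery
    return float(np.clip(s, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Spectral grids
# ---------------------------------------------------------------------------

def reflectance_wavelengths() -> np.ndarray:
    lo, hi = REFLECTANCE_RANGE
    return np.linspace(lo, hi, REFLECTANCE_N_BANDS)


def sif_wavelengths() -> np.ndarray:
    lo, hi = SIF_RANGE
    n = int(round((hi - lo) / SIF_STEP)) + 1
    return lo + SIF_STEP * np.arange(n)


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


# ---------------------------------------------------------------------------
# Reflectance simulation
# ---------------------------------------------------------------------------

def _reflectance_template(wl: np.ndarray) -> np.ndarray:
    """Smooth healthy-leaf template: green peak, red trough, red edge, NIR
    plateau."""
    return (0.05
            + 0.06 * _gauss(wl, 550.0, 25.0)
            - 0.015 * _gauss(wl, 670.0, 30.0)
            + 0.43 / (1.0 + np.exp(-(wl - 722.0) / 16.0)))


def _reflectance_stress_delta(wl: np.ndarray, stress: float) -> np.ndarray:
    """Stress perturbation: chlorophyll loss raises green/yellow reflectance
    (576-615 nm); dehydration and structural collapse lower the NIR plateau
    (826-909 nm) with an extra narrow feature near 882 nm."""
    return stress * (0.07 * _gauss(wl, 595.0, 18.0)
                     - 0.055 * _gauss(wl, 868.0, 40.0)
                     - 0.018 * _gauss(wl, 881.0, 6.0))


REFLECTANCE_NOISE_SD = 0.004  # per band, at noise_scale = 1


def simulate_reflectance(stress: float, rng: np.random.Generator | None = None,
                         noise_scale: float = 0.0) -> ReflectanceSpectrum:
    """Simulate a 224-band leaf reflectance spectrum for a given stress."""
    if not 0.0 <= stress <= 1.0:
        raise CohortValidationError(f"stress must be in [0, 1], got {stress}")
    wl = reflectance_wavelengths()
    refl = _reflectance_template(wl) + _reflectance_stress_delta(wl, stress)
    if noise_scale > 0:
        if rng is None:
            raise CohortValidationError("rng required when noise_scale > 0")
        refl = refl + rng.normal(0.0, REFLECTANCE_NOISE_SD * noise_scale,
                                 size=wl.size)
    refl = np.clip(refl, 1e-4, 1.0 - 1e-4)
    return ReflectanceSpectrum(wavelength=wl, reflectance=refl)


# ---------------------------------------------------------------------------
# SIF spectra simulation
# ---------------------------------------------------------------------------

SIF_RADIANCE_NOISE_SD = 0.10  # mW m-2 sr-1 nm-1, at noise_scale = 1


def _fluorescence_emission(wl: np.ndarray, stress: float,
                           amplitude: float = 1.0) -> np.ndarray:
    """Two-peak chlorophyll fluorescence emission (red ~685 nm, far-red
    ~740 nm), scaled down with stress.  The spectrum is flattened to its
    line-center value inside each O2 retrieval window so that three-band
    retrieval on noise-free spectra is exact."""
    scale = amplitude * (1.0 - 0.65 * stress)
    f = scale * (1.1 * _gauss(wl, 684.0, 9.0) + 2.6 * _gauss(wl, 740.0, 22.0))
    for (lo, hi), center in ((O2B_WINDOW, O2B_CENTER), (O2A_WINDOW, O2A_CENTER)):
        idx_center = int(np.argmin(np.abs(wl - center)))
        in_window = (wl >= lo) & (wl <= hi)
        f[in_window] = f[idx_center]
    return f


SIF_ILLUMINATION_CV = 0.08  # record-to-record sunlight variability, at scale 1


def simulate_sif_spectra(stress: float, rng: np.random.Generator | None = None,
                         noise_scale: float = 0.0,
                         fluorescence_amplitude: float = 1.0,
                         ) -> Tuple[SpectrumPair, float, float]:
    """Simulate a (radiance, irradiance) pair with injected fluorescence.

    Returns the pair plus the true injected fluorescence at the O2-B and
    O2-A line centers.  Irradiance has two absorption wells (O2-B near
    687 nm, O2-A near 760 nm) and a record-to-record illumination factor
    (sunlight varies between outdoor measurements, which is what makes rSIF
    informative beyond SIF); leaf radiance is a constant reflectance factor
    times irradiance plus the emission spectrum.
    """
    if not 0.0 <= stress <= 1.0:
        raise CohortValidationError(f"stress must be in [0, 1], got {stress}")
    wl = sif_wavelengths()
    continuum = 1300.0 - 0.5 * (wl - wl[0])
    irradiance = continuum * (1.0 - 0.55 * _gauss(wl, O2B_CENTER, 1.0)) \
                           * (1.0 - 0.70 * _gauss(wl, O2A_CENTER, 0.9))
    factor = 1.0
    if noise_scale > 0:
        if rng is None:
            raise CohortValidationError("rng required when noise_scale > 0")
        factor = max(1.0 + SIF_ILLUMINATION_CV * noise_scale * rng.normal(),
                     0.5)
        irradiance = factor * irradiance
    rho = 0.48 - 0.06 * stress  # constant leaf reflectance factor
    # Emission scales with the incident light, so rSIF (= F/I) removes the
    # illumination factor while SIF itself carries it.
    fluor = _fluorescence_emission(wl, stress,
                                   factor * fluorescence_amplitude)
    radiance = rho * irradiance + fluor
    if noise_scale > 0:
        if rng is None:
            raise CohortValidationError("rng required when noise_scale > 0")
        radiance = radiance + rng.normal(
            0.0, SIF_RADIANCE_NOISE_SD * noise_scale, size=wl.size)
    iB = int(np.argmin(np.abs(wl - O2B_CENTER)))
    iA = int(np.argmin(np.abs(wl - O2A_CENTER)))
    pair = SpectrumPair(wavelength=wl, radiance=radiance, irradiance=irradiance)
    return pair, float(fluor[iB]), float(fluor[iA])


# ---------------------------------------------------------------------------
# Physiological raw measurements
# ---------------------------------------------------------------------------

def _light_response_params(stress: float) -> Tuple[float, float, float, float]:
    """Modified-rectangular-hyperbola coefficients as functions of stress.

    alpha (initial slope) and the curve maximum fall with stress; the light
    compensation parameter Ic rises; curvature terms rise so the saturation
    point also falls.
    """
    alpha = 0.055 - 0.024 * stress
    beta = 2.0e-4 + 1.2e-4 * stress
    gamma = 1.5e-3 + 1.8e-3 * stress
    Ic = 10.0 + 16.0 * stress
    return alpha, beta, gamma, Ic


def light_response_model(par: np.ndarray, alpha: float, beta: float,
                         gamma: float, Ic: float) -> np.ndarray:
    """A(I) = alpha (1 - beta I) / (1 + gamma I) * (I - Ic)."""
    par = np.asarray(par, dtype=float)
    return alpha * (1.0 - beta * par) / (1.0 + gamma * par) * (par - Ic)


LIGHT_A_NOISE_SD = 0.25     # umol CO2 m-2 s-1, per PAR step
GAS_NOISE_SD = {"A": 0.30, "gs": 0.006, "E": 0.06, "ci": 6.0, "ca": 2.0}
PAM_NOISE_SD = 5.0          # raw fluorescence units, per level


def _simulate_light_response(stress: float, rng: np.random.Generator,
                             noise_scale: float) -> LightResponseCurve:
    alpha, beta, gamma, Ic = _light_response_params(stress)
    A = light_response_model(PAR_PROGRAM, alpha, beta, gamma, Ic)
    if noise_scale > 0:
        A = A + rng.normal(0.0, LIGHT_A_NOISE_SD * noise_scale, A.size)
    return LightResponseCurve(par_levels=PAR_PROGRAM.copy(), A_values=A)


def _simulate_gas_exchange(stress: float, rng: np.random.Generator,
                           noise_scale: float) -> GasExchangeRaw:
    ca = 400.0
    means = {
        "A": 16.5 * (1.0 - 0.68 * stress),
        "gs": 0.17 * (1.0 - 0.70 * stress),
        "E": 2.9 * (1.0 - 0.45 * stress),
        "ci": ca * (0.56 + 0.10 * stress),
        "ca": ca,
    }
    if noise_scale > 0:
        for k in means:
            means[k] += rng.normal(0.0, GAS_NOISE_SD[k] * noise_scale)
    means["E"] = max(means["E"], 0.1)
    means["ca"] = max(means["ca"], 1.0)
    means["gs"] = max(means["gs"], 1e-4)
    means["ci"] = max(means["ci"], 1.0)
    return GasExchangeRaw(**means)


def _simulate_pam(stress: float, rng: np.random.Generator,
                  noise_scale: float) -> FluorescenceRaw:
    # Construct raw levels from target derived parameters so the downstream
    # quenching parameters shift monotonically with stress.
    Fm = 1000.0
    fvfm = 0.83 - 0.08 * stress          # dark-adapted PSII efficiency falls
    qN = 0.03 + 0.35 * stress            # non-photochemical quenching rises
    yii = 0.72 - 0.10 * stress           # effective quantum yield falls
    F0 = Fm * (1.0 - fvfm)
    F0p = 0.95 * F0
    Fmp = Fm - qN * (Fm - F0p)
    Fs = Fmp * (1.0 - yii)
    levels = np.array([F0, Fm, Fs, F0p, Fmp])
    if noise_scale > 0:
        levels = levels + rng.normal(0.0, PAM_NOISE_SD * noise_scale, 5)
    F0, Fm, Fs, F0p, Fmp = levels
    # Restore the physical ordering 0 < F0p <= Fs <= Fmp <= Fm, 0 < F0 < Fm
    # that small noise excursions may break.
    F0 = max(F0, 1.0)
    F0p = max(F0p, 1.0)
    Fs = max(Fs, F0p)
    Fmp = max(Fmp, Fs)
    Fm = max(Fm, max(Fmp, F0 + 1.0))
    return FluorescenceRaw(F0=F0, Fm=Fm, Fs=Fs, F0p=F0p, Fmp=Fmp)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _cells() -> List[Tuple[str, str, int]]:
    return [(c, t, d) for c in CULTIVARS for t in TEMPERATURE_LEVELS
            for d in DURATIONS]


def _record_rng(config: CohortConfig, cell_index: int,
                replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(cell_index, replicate))
    return np.random.default_rng(ss)


def make_record(label: TreatmentLabel, config: CohortConfig,
                rng: np.random.Generator) -> PlantRecord:
    s = latent_stress(label, config)
    ns = config.noise_scale
    lr = _simulate_light_response(s, rng, ns)
    gas = _simulate_gas_exchange(s, rng, ns)
    pam = _simulate_pam(s, rng, ns)
    pair, fB, fA = simulate_sif_spectra(s, rng, ns)
    refl = simulate_reflectance(s, rng, ns)
    return PlantRecord(label=label, latent_stress=s, light_response=lr,
                       gas_exchange=gas, pam=pam, sif_spectra=pair,
                       reflectance=refl, true_F_O2B=fB, true_F_O2A=fA)


def make_cohort(config: CohortConfig) -> List[PlantRecord]:
    """Generate the full factorial cohort: 24 cells x n_replicates records."""
    records: List[PlantRecord] = []
    for cell_index, (cultivar, level, duration) in enumerate(_cells()):
        for rep in range(1, config.n_replicates + 1):
            label = TreatmentLabel(cultivar=cultivar, temperature_level=level,
                                   duration_days=duration, replicate=rep)
            rng = _record_rng(config, cell_index, rep)
            records.append(make_record(label, config, rng))
    return records


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

def write_cohort(records: List[PlantRecord], out_dir: str | Path,
                 config: CohortConfig | None = None) -> None:
    """Serialize a cohort as a directory of CSV files plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    labels = pd.DataFrame([{
        "record_id": r.label.record_id,
        "cultivar": r.label.cultivar,
        "temperature_level": r.label.temperature_level,
        "duration_days": r.label.duration_days,
        "replicate": r.label.replicate,
    } for r in records])
    labels.to_csv(out / "labels.csv", index=False)

    raw = pd.DataFrame([{
        "record_id": r.label.record_id,
        "A": r.gas_exchange.A, "gs": r.gas_exchange.gs, "E": r.gas_exchange.E,
        "ci": r.gas_exchange.ci, "ca": r.gas_exchange.ca,
        "F0": r.pam.F0, "Fm": r.pam.Fm, "Fs": r.pam.Fs,
        "F0p": r.pam.F0p, "Fmp": r.pam.Fmp,
    } for r in records])
    raw.to_csv(out / "indicators_raw.csv", index=False)

    lr_rows = []
    for r in records:
        for par, a in zip(r.light_response.par_levels, r.light_response.A_values):
            lr_rows.append({"record_id": r.label.record_id, "par": par, "A": a})
    pd.DataFrame(lr_rows).to_csv(out / "light_response.csv", index=False)

    def spectra_frame(wl: np.ndarray, columns: Dict[str, np.ndarray]) -> pd.DataFrame:
        df = pd.DataFrame({"wavelength_nm": wl})
        for rid, vals in columns.items():
            df[rid] = vals
        return df

    refl_wl = records[0].reflectance.wavelength
    spectra_frame(refl_wl, {r.label.record_id: r.reflectance.reflectance
                            for r in records}).to_csv(out / "reflectance.csv",
                                                      index=False)
    sif_wl = records[0].sif_spectra.wavelength
    spectra_frame(sif_wl, {r.label.record_id: r.sif_spectra.radiance
                           for r in records}).to_csv(out / "sif_radiance.csv",
                                                     index=False)
    spectra_frame(sif_wl, {r.label.record_id: r.sif_spectra.irradiance
                           for r in records}).to_csv(out / "sif_irradiance.csv",
                                                     index=False)

    truth = {r.label.record_id: {
        "latent_stress": r.latent_stress,
        "true_F_O2B": r.true_F_O2B,
        "true_F_O2A": r.true_F_O2A,
    } for r in records}
    payload = {"records": truth}
    if config is not None:
        payload["config"] = config.to_dict()
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
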