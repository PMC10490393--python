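"""Hyperspectral feature extraction for stress-score inversion.

Pipeline per cohort:

1. Preprocess each 224-band leaf reflectance spectrum: Savitzky-Golay
   smoothing (window 13, cubic), then optionally continuum (upper convex
   hull) removal or first-order differentiation -- three transform types.
2. Decompose each transformed spectrum with the bior1.3 biorthogonal wavelet
   into six detail levels; each level's detail coefficients are reconstructed
   back onto the full wavelength grid (CD1..CD6), so together with the
   untransformed "origin" series there are 3 x 7 = 21 spectral schemes.
3. For every scheme, compute the per-band Pearson correlation with the
   composite stress score (CSPC), take the maximum-correlation band Ba and
   the minimum-correlation band Bb, and build five candidate indices:
   Ba, Bb, Ba-Bb, Ba/Bb, (Ba-Bb)/(Ba+Bb).
4. Keep schemes whose best index correlation exceeds |r| = 0.5 (falling back
   to the top six schemes if none pass); the chosen (scheme, form) index
   values are the inversion model inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt
from scipy.signal import savgol_filter

__all__ = [
    "TRANSFORMS",
    "LEVELS",
    "WaveletConfig",
    "SpectralScheme",
    "FeatureIndex",
    "mean_filter",
    "continuum_removal",
    "first_derivative",
    "wavelet_details",
    "correlation_spectrum",
    "extract_feature_bands",
    "spectral_indices",
    "select_feature_set",
    "evaluate_schemes",
    "INDEX_FORMS",
]

TRANSFORMS = ("mean_filter", "envelope_removal", "first_derivative")
LEVELS = ("origin", "CD1", "CD2", "CD3", "CD4", "CD5", "CD6")
INDEX_FORMS = ("Ba", "Bb", "diff", "ratio", "norm")

_DENOM_EPS = 1e-12


@dataclass(frozen=True)
class WaveletConfig:
    wavelet_name: str = "bior1.3"
    n_levels: int = 6
    mode: str = "symmetric"

    def validate(self, n_bands: int) -> None:
        if self.n_levels > int(np.floor(np.log2(n_bands))):
            raise ValueError(
                f"{self.n_levels} levels too many for {n_bands} bands")


# ---------------------------------------------------------------------------
# Preprocessing transforms
# ---------------------------------------------------------------------------

def mean_filter(spectrum: np.ndarray, window: int = 13,
                poly: int = 3) -> np.ndarray:
    """Savitzky-Golay local-polynomial smoothing (window 13, cubic).

    Edges are handled by fitting the polynomial on the truncated window.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= poly:
        raise ValueError("window must exceed polynomial degree")
    if window >= spectrum.shape[-1]:
        raise ValueError("window must be smaller than the band count")
    return savgol_filter(spectrum, window_length=window, polyorder=poly,
                         mode="interp", axis=-1)


def _upper_hull(x: np.ndarray, y: np.ndarray) -> List[int]:
    """Indices of the upper convex hull (Andrew monotone chain) of points
    sorted by x."""
    hull: List[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = ((x[i2] - x[i1]) * (y[i] - y[i1])
                     - (y[i2] - y[i1]) * (x[i] - x[i1]))
            if cross >= 0:  # hull[-1] lies on/below the chord: drop it
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def continuum_removal(wavelength: np.ndarray,
                      reflectance: np.ndarray) -> np.ndarray:
    """Divide a reflectance spectrum by its linearly interpolated upper
    convex hull; output in (0, 1], exactly 1 at hull-contact bands."""
    wl = np.asarray(wavelength, dtype=float)
    r = np.asarray(reflectance, dtype=float)
    if r.ndim == 2:
        return np.vstack([continuum_removal(wl, row) for row in r])
    if wl.size < 3:
        raise ValueError("need >= 3 bands")
    if np.any(r <= 0):
        raise ValueError("continuum removal requires positive reflectance")
    hull_idx = _upper_hull(wl, r)
    hull = np.interp(wl, wl[hull_idx], r[hull_idx])
    out = r / hull
    out[hull_idx] = 1.0  # exact at contact points
    return out


def first_derivative(wavelength: np.ndarray, values: np.ndarray) -> np.ndarray:
    """First-order differentiation per nm: central differences on interior
    bands, one-sided at the edges."""
    wl = np.asarray(wavelength, dtype=float)
    v = np.asarray(values, dtype=float)
    return np.gradient(v, wl, axis=-1)


# ---------------------------------------------------------------------------
# Wavelet detail reconstruction
# ---------------------------------------------------------------------------

def wavelet_details(spectrum: np.ndarray,
                    config: WaveletConfig = WaveletConfig(),
                    ) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Multilevel bior1.3 decomposition with per-band detail reconstruction.

    Returns ({"CD1": series, ..., "CDn": series}, approximation) where each
    CDj is the level-j detail reconstructed back onto the input grid (all
    other coefficients zeroed) and the approximation is the reconstruction of
    the final low-frequency block.  Approximation + sum of details equals the
    input (perfect reconstruction).
    """
    x = np.asarray(spectrum, dtype=float)
    n = x.shape[-1]
    config.validate(n)
    with warnings.catch_warnings():
        # pywt warns when the level exceeds dwt_max_level for the boundary
        # mode; the decomposition stays perfectly reconstructable.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, config.wavelet_name, mode=config.mode,
                              level=config.n_levels, axis=-1)

    def reconstruct(keep: int) -> np.ndarray:
        selected = [c if i == keep else np.zeros_like(c)
                    for i, c in enumerate(coeffs)]
        rec = pywt.waverec(selected, config.wavelet_name, mode=config.mode,
                           axis=-1)
        return rec[..., :n]

    details = {f"CD{j}": reconstruct(len(coeffs) - j)
               for j in range(1, config.n_levels + 1)}
    approx = reconstruct(0)
    return details, approx


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------

def correlation_spectrum(series: np.ndarray, cspc: np.ndarray,
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-band Pearson correlation between a samples x bands matrix and the
    per-sample composite score.

    Returns (r, zero_variance_flags); flagged bands get r = 0.
    """
    X = np.asarray(series, dtype=float)
    y = np.asarray(cspc, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("sample counts differ")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("CSPC must be finite")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    flags = sx <= 0
    denom = np.where(flags, 1.0, sx) * sy
    r = (Xc * yc[:, None]).sum(axis=0) / denom
    r = np.where(flags, 0.0, r)
    return np.clip(r, -1.0, 1.0), flags


def extract_feature_bands(r: np.ndarray, flags: np.ndarray | None = None,
                          ) -> Tuple[int, int]:
    """Band indices (Ba, Bb): maximum and minimum correlation.

    Bb is the most negative correlation; when every valid band is positive,
    the global minimum (least positive) is returned.  Ties break toward the
    shorter wavelength (lower index).
    """
    r = np.asarray(r, dtype=float)
    if flags is not None and flags.all():
        raise ValueError("all bands flagged; no feature bands available")
    masked = np.where(flags, -np.inf, r) if flags is not None else r
    ba = int(np.argmax(masked))
    masked_min = np.where(flags, np.inf, r) if flags is not None else r
    bb = int(np.argmin(masked_min))
    return ba, bb


def spectral_indices(Ba_values: np.ndarray, Bb_values: np.ndarray,
                     ) -> Dict[str, np.ndarray]:
    """The five per-sample candidate indices built from the two feature
    bands; ratio/normalized forms are NaN where the denominator vanishes."""
    a = np.asarray(Ba_values, dtype=float)
    b = np.asarray(Bb_values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(b) < _DENOM_EPS, np.nan, a / b)
        norm = np.where(np.abs(a + b) < _DENOM_EPS, np.nan,
                        (a - b) / (a + b))
    return {"Ba": a, "Bb": b, "diff": a - b, "ratio": ratio, "norm": norm}


def _pairwise_corr(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return 0.0
    xv, yv = x[ok], y[ok]
    if np.std(xv) <= 0 or np.std(yv) <= 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1])


# ---------------------------------------------------------------------------
# Scheme evaluation and selection
# ---------------------------------------------------------------------------

@dataclass
class SpectralScheme:
    transform: str
    level: str
    series: np.ndarray            # samples x bands
    r: np.ndarray                 # per-band correlation with CSPC
    flags: np.ndarray
    Ba_index: int
    Bb_index: int
    Ba_wavelength: Tuple[float, float]  # (lo, hi); lo == hi for fine scales
    Bb_wavelength: Tuple[float, float]
    index_values: Dict[str, np.ndarray]
    index_r: Dict[str, float]

    @property
    def scheme_id(self) -> str:
        return f"{self.transform}:{self.level}"

    @property
    def best_form(self) -> str:
        return max(self.index_r, key=lambda f: abs(self.index_r[f]))

    @property
    def best_r(self) -> float:
        return self.index_r[self.best_form]


@dataclass
class FeatureIndex:
    scheme_id: str
    form: str
    Ba_wavelength: Tuple[float, float]
    Bb_wavelength: Tuple[float, float]
    values: np.ndarray
    r_with_cspc: float


def _band_range(wavelength: np.ndarray, idx: int, level: str,
                ) -> Tuple[float, float]:
    """Coarse detail scales smear features over ~2^(level-1) bands; report
    that support window around the extremal band."""
    if level == "origin" or level == "CD1":
        return (float(wavelength[idx]), float(wavelength[idx]))
    width = 2 ** (int(level[2:]) - 1)
    lo = max(0, idx - width // 2)
    hi = min(wavelength.size - 1, lo + width - 1)
    return (float(wavelength[lo]), float(wavelength[hi]))


def evaluate_schemes(wavelength: np.ndarray, reflectance: np.ndarray,
                     cspc: np.ndarray,
                     wavelet: WaveletConfig = WaveletConfig(),
                     window: int = 13, poly: int = 3,
                     ) -> List[SpectralScheme]:
    """Build and screen all 21 transform x level schemes for one cohort."""
    wl = np.asarray(wavelength, dtype=float)
    R = np.asarray(reflectance, dtype=float)
    smoothed = mean_filter(R, window=window, poly=poly)
    base_series = {
        "mean_filter": smoothed,
        "envelope_removal": continuum_removal(wl, smoothed),
        "first_derivative": first_derivative(wl, smoothed),
    }
    schemes: List[SpectralScheme] = []
    for transform in TRANSFORMS:
        base = base_series[transform]
        details, _ = wavelet_details(base, wavelet)
        per_level = {"origin": base, **details}
        for level in LEVELS:
            series = per_level[level]
            r, flags = correlation_spectrum(series, cspc)
            ba, bb = extract_feature_bands(r, flags)
            idx_vals = spectral_indices(series[:, ba], series[:, bb])
            idx_r = {form: _pairwise_corr(v, cspc)
                     for form, v in idx_vals.items()}
            schemes.append(SpectralScheme(
                transform=transform, level=level, series=series, r=r,
                flags=flags, Ba_index=ba, Bb_index=bb,
                Ba_wavelength=_band_range(wl, ba, level),
                Bb_wavelength=_band_range(wl, bb, level),
                index_values=idx_vals, index_r=idx_r))
    return schemes


def select_feature_set(schemes: Sequence[SpectralScheme],
                       threshold: float = 0.5) -> List[FeatureIndex]:
    """Keep each scheme's best-|r| index form; select schemes whose best
    |r| exceeds the threshold, falling back to the top six by |r| when the
    selection would be empty."""
    ranked = sorted(schemes, key=lambda s: abs(s.best_r), reverse=True)
    chosen = [s for s in ranked if abs(s.best_r) > threshold]
    if not chosen:
        warnings.warn("no scheme exceeds the correlation threshold; "
                      "falling back to the top 6 by |r|")
        chosen = ranked[:6]
    return [FeatureIndex(scheme_id=s.scheme_id, form=s.best_form,
                         Ba_wavelength=s.Ba_wavelength,
                         Bb_wavelength=s.Bb_wavelength,
                         values=s.index_values[s.best_form],
                         r_with_cspc=s.best_r)
            for s in chosen]


def feature_table(features: Sequence[FeatureIndex],
                  index=None) -> pd.DataFrame:
    """Selected index values as a samples x features DataFrame."""
    data = {f"{f.scheme_id}:{f.form}": f.values for f in features}
    return pd.DataFrame(data, index=index)
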