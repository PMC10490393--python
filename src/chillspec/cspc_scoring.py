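"""Comprehensive Score for Photosynthetic System Chilling injury (CSPC).

Two-round principal component analysis over 20 photosynthetic-fluorescence
indicators grouped into three families (gas exchange / light response, PAM
quenching, solar-induced fluorescence):

1. A PCA per family (on the correlation matrix, i.e. population-standardized
   columns) identifies the indicator with the largest absolute loading on
   PC1 and on PC2 of each family -- six characteristic indicators in total.
2. A second PCA on the six standardized characteristic indicators retains
   the leading components reaching a cumulative variance contribution of
   85%; per-sample component scores S_k are loading-weighted sums of the
   standardized features, the component weights are W_k = P_k / 100 (P_k the
   percent variance contribution over *total* variance), and

       CSPC = sum_k W_k * S_k.

3. Scores are graded into stress levels 0-5 on half-open intervals of width
   SD/2 (lower bounds inclusive) centered at the cohort mean of zero; level
   0 is the healthiest (CSPC >= center + width), level 5 the most stressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_FAMILIES",
    "INDICATOR_COLUMNS",
    "ORIENT_REFERENCE",
    "PCAResult",
    "FeatureSet",
    "GradingScheme",
    "CSPCModel",
    "ZeroVarianceError",
    "standardize",
    "family_pca",
    "select_features",
    "composite_pca",
    "retained_components",
    "pc_scores",
    "weights_from_contributions",
    "cspc_score",
    "grading_scheme",
    "grade",
    "fit_cspc",
]

INDICATOR_FAMILIES: Dict[str, Tuple[str, ...]] = {
    "photosynthetic": ("Amax", "LCP", "LSP", "AQE", "gs", "E", "ci_ca", "WUE"),
    "fluorescence": ("FvFm", "FvpFmp", "one_minus_qP", "qL", "qN",
                     "YII", "YNPQ", "YNO"),
    "sif": ("SIF_O2B", "SIF_O2A", "rSIF_O2B", "rSIF_O2A"),
}
INDICATOR_COLUMNS: Tuple[str, ...] = tuple(
    c for cols in INDICATOR_FAMILIES.values() for c in cols)

# Sign-orientation reference: each component is flipped, if needed, so its
# loading on the first of these features present (with a non-negligible
# loading) is positive.
ORIENT_REFERENCE: Tuple[str, ...] = ("rSIF_O2B", "WUE", "YII")


class ZeroVarianceError(ValueError):
    """A column has zero variance and cannot be standardized."""


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizeParams:
    means: pd.Series
    sds: pd.Series
    convention: str = "population"  # ddof = 0

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.means.index)
        missing = set(cols) - set(table.columns)
        if missing:
            raise ValueError(f"table missing columns: {sorted(missing)}")
        return (table[cols] - self.means) / self.sds


def standardize(table: pd.DataFrame) -> Tuple[pd.DataFrame, StandardizeParams]:
    """Center and scale every column to mean 0, population sd 1."""
    if table.isna().any().any():
        raise ValueError("indicator table contains missing values")
    means = table.mean()
    sds = table.std(ddof=0)
    zero = sds[sds <= 0]
    if len(zero):
        raise ZeroVarianceError(
            f"zero-variance columns: {list(zero.index)}")
    params = StandardizeParams(means=means, sds=sds)
    return params.apply(table), params


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    variables: List[str]
    loadings: pd.DataFrame        # variables x components, orthonormal columns
    eigenvalues: np.ndarray       # non-increasing
    contribution_pct: np.ndarray  # 100 * E_k / sum(E)
    scores: pd.DataFrame          # samples x components


def _orient(loadings: np.ndarray, variables: Sequence[str],
            reference: Sequence[str]) -> np.ndarray:
    """Flip component signs so the loading on the first available reference
    variable is positive (falls back to the largest-|loading| variable)."""
    loadings = loadings.copy()
    for k in range(loadings.shape[1]):
        pivot = None
        for ref in reference:
            if ref in variables and abs(loadings[list(variables).index(ref), k]) > 1e-8:
                pivot = list(variables).index(ref)
                break
        if pivot is None:
            pivot = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[pivot, k] < 0:
            loadings[:, k] *= -1.0
    return loadings


def _pca(std_table: pd.DataFrame,
         reference: Sequence[str] = ORIENT_REFERENCE) -> PCAResult:
    """Correlation-matrix PCA of a standardized table."""
    variables = list(std_table.columns)
    X = std_table.to_numpy(dtype=float)
    n, p = X.shape
    corr = X.T @ X / n  # population convention: trace == p
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rank = int(np.linalg.matrix_rank(corr))
    if rank < p:
        warnings.warn(f"rank-deficient input (rank {rank} < {p}); "
                      "reporting reduced component count")
        evals = evals[:rank]
        evecs = evecs[:, :rank]
    evecs = _orient(evecs, variables, reference)
    comp_names = [f"PC{k + 1}" for k in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=variables, columns=comp_names)
    contribution = 100.0 * evals / p
    scores = pd.DataFrame(X @ evecs, index=std_table.index, columns=comp_names)
    return PCAResult(variables=variables, loadings=loadings,
                     eigenvalues=evals, contribution_pct=contribution,
                     scores=scores)


def family_pca(std_table: pd.DataFrame, family: str | Sequence[str],
               reference: Sequence[str] = ORIENT_REFERENCE) -> PCAResult:
    """PCA of one indicator family's standardized columns."""
    columns = (INDICATOR_FAMILIES[family] if isinstance(family, str)
               else tuple(family))
    if len(columns) < 2:
        raise ValueError("family needs >= 2 columns")
    sub = std_table[list(columns)]
    if len(sub) <= len(columns):
        raise ValueError("need more samples than variables")
    return _pca(sub, reference)


# ---------------------------------------------------------------------------
# Feature selection (round one)
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    names: List[str]
    origin: List[Tuple[str, str]]  # (family, component) per selected name


def select_features(family_results: Dict[str, PCAResult]) -> FeatureSet:
    """Per family: the max-|loading| variable on PC1 and on PC2.

    If both picks coincide, the PC2 pick falls back to the next-largest
    |loading| variable on PC2.
    """
    names: List[str] = []
    origin: List[Tuple[str, str]] = []
    for family, result in family_results.items():
        if result.loadings.shape[1] < 2:
            raise ValueError(f"family {family!r} has fewer than 2 components")
        pc1 = result.loadings["PC1"].abs()
        pc2 = result.loadings["PC2"].abs()
        pick1 = pc1.idxmax()
        order2 = pc2.sort_values(ascending=False).index
        pick2 = order2[0] if order2[0] != pick1 else order2[1]
        names.extend([pick1, pick2])
        origin.extend([(family, "PC1"), (family, "PC2")])
    return FeatureSet(names=names, origin=origin)


# ---------------------------------------------------------------------------
# Composite scoring (round two)
# ---------------------------------------------------------------------------

def retained_components(contribution_pct: Sequence[float],
                        variance_threshold: float = 0.85) -> int:
    """Minimal k whose cumulative variance contribution reaches the
    threshold (contributions in percent)."""
    cum = np.cumsum(np.asarray(contribution_pct, dtype=float)) / 100.0
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    return min(k, len(cum))


def composite_pca(std_features: pd.DataFrame,
                  variance_threshold: float = 0.85,
                  reference: Sequence[str] = ORIENT_REFERENCE,
                  ) -> Tuple[PCAResult, int]:
    """PCA on the characteristic features; retain the minimal k components
    whose cumulative variance contribution reaches the threshold."""
    result = _pca(std_features, reference)
    return result, retained_components(result.contribution_pct,
                                       variance_threshold)


def pc_scores(std_features: pd.DataFrame, loadings: pd.DataFrame,
              eigenvalues: Sequence[float] | None = None,
              weighting: str = "loadings") -> np.ndarray:
    """S_k = sum_i w_ki * x_i.

    weighting="loadings" (default) uses the loadings directly as weights —
    the convention fixed by the published score formulas.
    weighting="eigen_scaled" uses loading / sqrt(eigenvalue) instead
    (requires ``eigenvalues``).
    """
    if list(std_features.columns) != list(loadings.index):
        raise ValueError("feature columns do not match loading variables")
    W = loadings.to_numpy(dtype=float)
    if weighting == "eigen_scaled":
        if eigenvalues is None:
            raise ValueError("eigen_scaled weighting requires eigenvalues")
        W = W / np.sqrt(np.asarray(eigenvalues, dtype=float)[:W.shape[1]])
    elif weighting != "loadings":
        raise ValueError(f"unknown weighting {weighting!r}")
    return std_features.to_numpy(dtype=float) @ W


def weights_from_contributions(contribution_pct: Sequence[float]) -> np.ndarray:
    """W_k = P_k / 100 (normalization by total variance)."""
    p = np.asarray(contribution_pct, dtype=float)
    if np.any(p < 0):
        raise ValueError("contributions must be non-negative")
    if p.sum() > 100.0 + 1e-6:
        raise ValueError("contributions exceed 100%")
    return p / 100.0


def cspc_score(S: np.ndarray, W: np.ndarray) -> np.ndarray:
    """CSPC = sum_k W_k * S_k."""
    S = np.asarray(S, dtype=float)
    W = np.asarray(W, dtype=float)
    if S.shape[-1] != W.shape[0]:
        raise ValueError("S and W are not aligned on retained components")
    return S @ W


# ---------------------------------------------------------------------------
# Grading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradingScheme:
    """Half-SD interval grading: six levels on intervals of ``width``
    anchored at ``center``; lower bounds inclusive, upper bounds exclusive."""

    center: float = 0.0
    width: float = 0.54
    n_levels: int = 6

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")

    def boundaries(self) -> np.ndarray:
        """Descending level boundaries: level 0 above the first, level 5
        below the last."""
        return self.center + self.width * np.arange(1, 3 - self.n_levels, -1)


_BOUNDARY_TOL = 1e-9


def grade(cspc, scheme: GradingScheme = GradingScheme()):
    """Map composite scores to integer stress levels 0-5."""
    x = np.asarray(cspc, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("CSPC scores must be finite")
    c, w = scheme.center, scheme.width
    # level 0: x >= c + w; level L in 1..4 on [c-(L-1)w, c-(L-2)w); level 5 below.
    ratio = (c - x) / w
    levels = 1 + np.ceil(ratio - _BOUNDARY_TOL).astype(int)
    levels = np.where(x >= c + w - _BOUNDARY_TOL * w, 0, levels)
    levels = np.clip(levels, 0, scheme.n_levels - 1)
    return levels if levels.ndim else int(levels)


def grading_scheme(scores: Sequence[float], center: float = 0.0,
                   fixed_width: float | None = None) -> GradingScheme:
    """Half-SD grading scheme: width = sd(scores) / 2 (population sd), or a
    fixed override such as the canonical 0.54."""
    if fixed_width is not None:
        return GradingScheme(center=center, width=fixed_width)
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need >= 2 scores")
    sd = float(np.std(scores, ddof=0))
    if sd <= 0:
        raise ValueError("zero standard deviation; cannot derive grade width")
    return GradingScheme(center=center, width=sd / 2.0)


# ---------------------------------------------------------------------------
# End-to-end model
# ---------------------------------------------------------------------------

@dataclass
class CSPCModel:
    """Fitted CSPC construction: reusable on new samples without refitting."""

    standardize_params: StandardizeParams
    family_results: Dict[str, PCAResult]
    feature_set: FeatureSet
    composite: PCAResult
    retained: int
    weights: np.ndarray
    scheme: GradingScheme

    @property
    def retained_loadings(self) -> pd.DataFrame:
        return self.composite.loadings.iloc[:, :self.retained]

    def score(self, table: pd.DataFrame) -> pd.DataFrame:
        """Score new samples with the stored transform, loadings, weights
        and grading scheme."""
        std = self.standardize_params.apply(table)
        feats = std[self.feature_set.names]
        S = pc_scores(feats, self.retained_loadings)
        cspc = cspc_score(S, self.weights)
        out = pd.DataFrame(S, index=table.index,
                           columns=[f"S{k + 1}" for k in range(self.retained)])
        out["CSPC"] = cspc
        out["level"] = grade(cspc, self.scheme)
        return out


def fit_cspc(table: pd.DataFrame, variance_threshold: float = 0.85,
             fixed_width: float | None = None,
             families: Dict[str, Tuple[str, ...]] | None = None,
             ) -> Tuple[CSPCModel, pd.DataFrame]:
    """Run the full two-round construction on an indicator table.

    Returns the fitted model and the per-sample result table
    (S1..Sk, CSPC, level).
    """
    families = families or INDICATOR_FAMILIES
    std, params = standardize(table[[c for cols in families.values()
                                     for c in cols]])
    family_results = {fam: family_pca(std, cols)
                      for fam, cols in families.items()}
    feature_set = select_features(family_results)
    comp, k = composite_pca(std[feature_set.names], variance_threshold)
    W = weights_from_contributions(comp.contribution_pct[:k])
    S = pc_scores(std[feature_set.names], comp.loadings.iloc[:, :k])
    cspc = cspc_score(S, W)
    scheme = grading_scheme(cspc, fixed_width=fixed_width)
    model = CSPCModel(standardize_params=params, family_results=family_results,
                      feature_set=feature_set, composite=comp, retained=k,
                      weights=W, scheme=scheme)
    result = pd.DataFrame(S, index=table.index,
                          columns=[f"S{j + 1}" for j in range(k)])
    result["CSPC"] = cspc
    result["level"] = grade(cspc, scheme)
    return model, result
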