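"""Two-round PCA scoring: standardization, family PCA, feature selection,
composite weights, and half-SD grading."""

import numpy as np
import pandas as pd
import pytest

from chillspec import (GradingScheme, composite_pca, cspc_score, family_pca,
                       fit_cspc, grade, grading_scheme, pc_scores,
                       select_features, standardize,
                       weights_from_contributions)
from chillspec.cspc_scoring import (PCAResult, ZeroVarianceError,
                                    retained_components)

# Published loadings of the six characteristic indicators on the first three
# composite components (used as a fixed numeric fixture).
COMPOSITE_LOADINGS = pd.DataFrame(
    {
        "PC1": [0.047, -0.506, 0.359, -0.396, 0.456, 0.498],
        "PC2": [0.926, 0.012, 0.281, 0.047, -0.247, -0.013],
        "PC3": [-0.278, 0.043, 0.800, 0.526, -0.024, -0.067],
    },
    index=["WUE", "LCP", "YII", "qN", "SIF_O2B", "rSIF_O2B"],
)
COMPOSITE_CONTRIBUTIONS = (57.167, 17.874, 10.356)


class TestStandardize:
    def test_unit_moments(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        std, params = standardize(table)
        assert std["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert std["x"].std(ddof=0) == pytest.approx(1.0)
        assert params.convention == "population"

    def test_stored_transform_is_idempotent(self):
        table = pd.DataFrame({"x": [1.0, 5.0, 9.0], "y": [2.0, 2.5, 4.0]})
        std, params = standardize(table)
        pd.testing.assert_frame_equal(params.apply(table), std)

    def test_affine_invariance(self):
        x = pd.DataFrame({"x": [0.3, 1.9, 2.2, 5.0]})
        std_x, _ = standardize(x)
        std_ax, _ = standardize(3.7 * x + 11.0)
        np.testing.assert_allclose(std_ax["x"], std_x["x"], atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            standardize(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


class TestFamilyPca:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "b": 2.0 * x})
        std, _ = standardize(table)
        with pytest.warns(UserWarning):
            result = family_pca(std, ("a", "b"))
        assert result.contribution_pct[0] == pytest.approx(100.0)

    def test_two_variable_closed_form(self, rng):
        """PC1 contribution of a 2-variable PCA is 100 (1 + |r|) / 2."""
        x = rng.normal(size=400)
        y = 0.6 * x + 0.8 * rng.normal(size=400)
        table = pd.DataFrame({"a": x, "b": y})
        std, _ = standardize(table)
        r = float(np.corrcoef(std["a"], std["b"])[0, 1])
        result = family_pca(std, ("a", "b"))
        assert result.contribution_pct[0] == pytest.approx(
            100.0 * (1 + abs(r)) / 2.0, rel=1e-9)

    def test_trace_conservation(self, small_indicators):
        std, _ = standardize(small_indicators)
        result = family_pca(std, "photosynthetic")
        assert result.eigenvalues.sum() == pytest.approx(8.0, abs=1e-8)
        assert np.all(np.diff(result.eigenvalues) <= 1e-12)
        # orthonormal loadings
        L = result.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)


def fake_result(variables, pc1, pc2):
    loadings = pd.DataFrame({"PC1": pc1, "PC2": pc2}, index=variables)
    return PCAResult(variables=list(variables), loadings=loadings,
                     eigenvalues=np.array([2.0, 1.0]),
                     contribution_pct=np.array([50.0, 25.0]),
                     scores=pd.DataFrame())


class TestSelectFeatures:
    def test_published_photosynthetic_picks(self):
        """LCP's |loading| 0.424 on PC1 beats Amax's 0.417; WUE dominates
        PC2 -- so the family contributes {LCP, WUE}."""
        result = fake_result(
            ["Amax", "LCP", "WUE"],
            pc1=[0.417, -0.424, 0.10],
            pc2=[0.20, 0.05, 0.738])
        picks = select_features({"photosynthetic": result})
        assert picks.names == ["LCP", "WUE"]

    def test_dominant_variable_falls_back_on_pc2(self):
        result = fake_result(["a", "b"], pc1=[0.9, 0.1], pc2=[0.8, 0.3])
        picks = select_features({"fam": result})
        assert picks.names == ["a", "b"]

    def test_one_pick_per_component_per_family(self, small_indicators):
        from chillspec.cspc_scoring import INDICATOR_FAMILIES
        std, _ = standardize(small_indicators)
        results = {f: family_pca(std, f) for f in INDICATOR_FAMILIES}
        picks = select_features(results)
        assert len(picks.names) == 6
        assert len(set(picks.names)) == 6
        assert [o[1] for o in picks.origin] == ["PC1", "PC2"] * 3


class TestCompositeRetention:
    def test_published_contributions_retain_three(self):
        assert retained_components(COMPOSITE_CONTRIBUTIONS, 0.85) == 3

    def test_single_dominant_direction(self):
        assert retained_components((90.0, 5.0, 5.0), 0.85) == 1

    def test_full_rank_at_threshold_one(self, rng):
        table = pd.DataFrame(rng.normal(size=(100, 6)),
                             columns=list("abcdef"))
        std, _ = standardize(table)
        _, k = composite_pca(std, variance_threshold=1.0)
        assert k == 6


class TestScoresAndWeights:
    def test_zero_features_zero_scores(self):
        std = pd.DataFrame(0.0, index=range(3),
                           columns=COMPOSITE_LOADINGS.index)
        S = pc_scores(std, COMPOSITE_LOADINGS)
        np.testing.assert_array_equal(S, 0.0)

    def test_unit_vector_reads_off_loading(self):
        x = pd.DataFrame([[0, 0, 0, 0, 0, 1.0]],
                         columns=COMPOSITE_LOADINGS.index)
        S = pc_scores(x, COMPOSITE_LOADINGS)
        assert S[0, 0] == pytest.approx(0.498)

    def test_matches_manual_dot_product(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 6)),
                         columns=COMPOSITE_LOADINGS.index)
        S = pc_scores(x, COMPOSITE_LOADINGS)
        manual = np.array([[sum(x.iloc[i, j] * COMPOSITE_LOADINGS.iloc[j, k]
                                for j in range(6)) for k in range(3)]
                           for i in range(5)])
        np.testing.assert_allclose(S, manual, atol=1e-12)

    def test_eigen_scaled_weighting(self, rng):
        x = pd.DataFrame(rng.normal(size=(4, 6)),
                         columns=COMPOSITE_LOADINGS.index)
        evals = np.array([3.43, 1.072, 0.621])
        S = pc_scores(x, COMPOSITE_LOADINGS, eigenvalues=evals,
                      weighting="eigen_scaled")
        plain = pc_scores(x, COMPOSITE_LOADINGS)
        np.testing.assert_allclose(S, plain / np.sqrt(evals), atol=1e-12)
        with pytest.raises(ValueError):
            pc_scores(x, COMPOSITE_LOADINGS, weighting="eigen_scaled")

    def test_feature_mismatch_rejected(self):
        x = pd.DataFrame([[1.0, 2.0]], columns=["WUE", "LCP"])
        with pytest.raises(ValueError):
            pc_scores(x, COMPOSITE_LOADINGS)

    def test_published_weights(self):
        W = weights_from_contributions(COMPOSITE_CONTRIBUTIONS)
        np.testing.assert_allclose(np.round(W, 3), [0.572, 0.179, 0.104])

    def test_single_component_full_weight(self):
        assert weights_from_contributions([100.0])[0] == pytest.approx(1.0)

    def test_weights_sum_to_cumulative_fraction(self):
        W = weights_from_contributions(COMPOSITE_CONTRIBUTIONS)
        assert W.sum() == pytest.approx(sum(COMPOSITE_CONTRIBUTIONS) / 100.0)

    def test_composite_sum(self):
        S = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
        W = np.array([0.572, 0.179, 0.104])
        np.testing.assert_allclose(cspc_score(S, W), [0.855, 0.0])


class TestGrading:
    def test_half_sd_width(self):
        scheme = grading_scheme([-1.08, 1.08])  # population sd = 1.08
        assert scheme.width == pytest.approx(0.54)

    def test_width_scales_with_scores(self):
        base = grading_scheme([-1.0, 0.2, 0.8, -0.3])
        doubled = grading_scheme([-2.0, 0.4, 1.6, -0.6])
        assert doubled.width == pytest.approx(2.0 * base.width)

    def test_fixed_override_ignores_sd(self):
        scheme = grading_scheme([-5.0, 5.0], fixed_width=0.54)
        assert scheme.width == 0.54

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            grading_scheme([1.0, 1.0])

    @pytest.mark.parametrize("score, level", [
        (0.947, 0),    # healthy control scores
        (1.234, 0),
        (0.403, 1),
        (-0.094, 2),
        (-0.842, 3),
        (-1.231, 4),
        (-1.813, 5),
        (-2.157, 5),
        (0.54, 0),     # boundary: lower bounds inclusive
        (0.0, 1),
        (-1.62, 4),
    ])
    def test_levels(self, score, level):
        assert grade(score, GradingScheme()) == level

    def test_partition_and_monotonicity(self):
        xs = np.linspace(-4.0, 4.0, 4001)
        levels = grade(xs, GradingScheme())
        assert set(levels) == {0, 1, 2, 3, 4, 5}
        assert np.all(np.diff(levels) <= 0)  # non-increasing in CSPC

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            grade(float("nan"), GradingScheme())


class TestFitCspc:
    def test_training_mean_is_zero(self, small_cspc):
        _, result = small_cspc
        assert result["CSPC"].mean() == pytest.approx(0.0, abs=1e-8)

    def test_levels_consistent_with_scheme(self, small_cspc):
        model, result = small_cspc
        np.testing.assert_array_equal(
            result["level"], grade(result["CSPC"].to_numpy(), model.scheme))

    def test_rescoring_training_table_reproduces_result(self, small_cspc,
                                                        small_indicators):
        model, result = small_cspc
        rescored = model.score(small_indicators)
        np.testing.assert_allclose(rescored["CSPC"], result["CSPC"],
                                   atol=1e-10)

    def test_end_to_end_affine_invariance(self, small_indicators):
        """Rescaling any raw indicator column by a positive constant leaves
        CSPC unchanged (standardization absorbs it)."""
        _, base = fit_cspc(small_indicators)
        rescaled = small_indicators.copy()
        rescaled["Amax"] = 10.0 * rescaled["Amax"] + 3.0
        _, out = fit_cspc(rescaled)
        np.testing.assert_allclose(out["CSPC"], base["CSPC"], atol=1e-8)
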