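import numpy as np
import pandas as pd
import pytest

from mirct import (
    ArraySimConfig,
    PreprocessParams,
    detection_filter,
    generate_array_dataset,
    knn_impute,
    lowess_normalize,
    preprocess_pipeline,
    shrink_extremes,
)
from mirct.ct_io import CtMatrix
from mirct.errors import ConfigError, DataError

from conftest import make_matrix


class TestDetectionFilter:
    def test_boundary_20_percent_excluded(self):
        vals = np.full((2, 40), 30.0)
        vals[0, :8] = np.nan  # exactly 8/40 = 20% -> excluded
        vals[1, :7] = np.nan  # 17.5% -> retained
        m = make_matrix(vals)
        filtered, excluded = detection_filter(m)
        assert excluded == ["a0"]
        assert filtered.assay_ids == ["a1"]

    def test_fully_observed_assay_retained(self):
        m = make_matrix(np.full((1, 40), 30.0))
        filtered, excluded = detection_filter(m)
        assert excluded == [] and filtered.n_assays == 1

    def test_late_ct_counts_as_missing_and_is_censored(self):
        vals = np.full((1, 10), 30.0)
        vals[0, 0] = 36.0  # 1/10 bad -> retained, but censored to missing
        m = make_matrix(vals)
        filtered, _ = detection_filter(m)
        assert np.isnan(filtered.data.iloc[0, 0])
        assert (filtered.data.iloc[0, 1:] == 30.0).all()

    def test_planted_violations_match_brute_force_recount(self):
        rng = np.random.default_rng(21)
        matrix, _, _ = generate_array_dataset(
            ArraySimConfig(n_assays=120, baseline_ct_mean=31.0, seed=21)
        )
        params = PreprocessParams()
        _, excluded = detection_filter(matrix, params)
        # independent per-row recount
        expected = []
        for assay, row in matrix.data.iterrows():
            bad = sum(1 for v in row if pd.isna(v) or v > params.max_ct)
            if bad / len(row) >= params.max_missing_frac:
                expected.append(assay)
        assert excluded == expected
        # invariance to row/column permutation
        perm = matrix.data.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2
        )
        _, excluded_perm = detection_filter(CtMatrix(perm, stage="raw"), params)
        assert set(excluded_perm) == set(expected)

    def test_empty_matrix_rejected(self):
        m = CtMatrix(pd.DataFrame(dtype=float), stage="raw")
        with pytest.raises(DataError):
            detection_filter(m)


class TestLowessNormalize:
    def _matrix_from_profile(self, profile, columns):
        """Stack per-sample columns derived from a shared reference profile."""
        df = pd.DataFrame(
            {f"s{j}": col for j, col in enumerate(columns)},
            index=[f"a{i}" for i in range(len(profile))],
        )
        return CtMatrix(df, stage="filtered")

    def test_samples_identical_to_reference_unchanged(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(20, 34, size=40)
        m = self._matrix_from_profile(profile, [profile] * 6)
        out = lowess_normalize(m)
        assert np.abs(out.data.to_numpy() - m.data.to_numpy()).max() < 1e-8

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(1)
        profile = rng.uniform(20, 34, size=60)
        cols = [profile, profile, profile, profile + 1.0]
        m = self._matrix_from_profile(profile, cols)
        out = lowess_normalize(m)
        ref = out.data.median(axis=1)
        dev = out.data["s3"] - ref
        assert abs(dev.mean()) < 0.05

    def test_linear_trend_detrended_matches_least_squares_oracle(self):
        rng = np.random.default_rng(2)
        profile = np.sort(rng.uniform(20, 34, size=80))
        slope = 0.1
        tilted = profile + slope * (profile - profile.mean())
        m = self._matrix_from_profile(profile, [profile] * 5 + [tilted])
        out = lowess_normalize(m)
        # residual deviation of the tilted sample vs the reference profile
        resid = (out.data["s5"] - profile).to_numpy()
        fit = np.polyfit(profile, resid, 1)
        assert abs(fit[0]) < 0.02
        # oracle: direct least-squares detrend of the same pairs
        orig_dev = tilted - profile
        lsq = np.polyfit(profile, orig_dev, 1)
        assert lsq[0] == pytest.approx(slope, rel=1e-6)

    def test_missing_cells_stay_missing(self):
        rng = np.random.default_rng(3)
        profile = rng.uniform(22, 32, size=30)
        cols = [profile + rng.normal(0, 0.1, 30) for _ in range(4)]
        m = self._matrix_from_profile(profile, cols)
        m.data.iloc[0, 0] = np.nan
        out = lowess_normalize(m)
        assert np.isnan(out.data.iloc[0, 0])
        assert out.data.notna().iloc[1:, :].all().all()

    def test_sample_with_too_few_values_rejected(self):
        vals = np.full((5, 3), 28.0)
        m = make_matrix(vals, stage="filtered")
        with pytest.raises(DataError, match="s0"):
            lowess_normalize(m)


def knn_oracle(data: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive O(n^2) nearest-neighbour imputation, written from the rule."""
    m, n = data.shape
    out = data.copy()
    for i in range(m):
        for j in range(n):
            if not np.isnan(data[i, j]):
                continue
            dists = []
            for other in range(m):
                if other == i or np.isnan(data[other, j]):
                    continue
                shared = ~np.isnan(data[i]) & ~np.isnan(data[other])
                ns = int(shared.sum())
                if ns == 0:
                    continue
                d = np.sqrt(((data[i, shared] - data[other, shared]) ** 2).sum() / ns)
                dists.append((d, other))
            dists.sort(key=lambda t: (t[0], t[1]))
            chosen = [o for _, o in dists[:k]]
            out[i, j] = np.mean([data[o, j] for o in chosen])
    return out


class TestKnnImpute:
    def test_complete_matrix_is_identity(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.uniform(20, 34, size=(20, 8)), stage="normalized")
        out = knn_impute(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_exact_neighbour_case(self):
        base = np.linspace(20, 30, 6)
        vals = np.vstack([base, base, base, base, base + 5])
        vals = vals.astype(float)
        vals[0, 2] = np.nan
        m = make_matrix(vals, stage="normalized")
        out = knn_impute(m, PreprocessParams(knn_k=3))
        assert out.data.iloc[0, 2] == pytest.approx(base[2], abs=1e-12)

    def test_matches_exhaustive_oracle_exactly(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(20, 34, size=(50, 20))
        mask = rng.random(size=data.shape) < 0.05
        data[mask] = np.nan
        m = make_matrix(data, stage="normalized")
        out = knn_impute(m, PreprocessParams(knn_k=10))
        expected = knn_oracle(data, 10)
        np.testing.assert_array_equal(out.data.to_numpy(), expected)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(6)
        data = rng.uniform(20, 34, size=(30, 10))
        mask = rng.random(size=data.shape) < 0.1
        data[mask] = np.nan
        m = make_matrix(data, stage="normalized")
        out = knn_impute(m)
        obs = ~np.isnan(data)
        np.testing.assert_array_equal(out.data.to_numpy()[obs], data[obs])
        assert not np.isnan(out.data.to_numpy()).any()


class TestShrinkExtremes:
    def test_values_within_bounds_unchanged(self):
        rng = np.random.default_rng(7)
        data = 28 + rng.normal(0, 0.5, size=(10, 20))
        m = make_matrix(data, stage="imputed")
        out = shrink_extremes(m)
        med = np.median(data, axis=1)
        mad = np.median(np.abs(data - med[:, None]), axis=1)
        inside = np.abs(data - med[:, None]) <= 3 * 1.4826 * mad[:, None]
        np.testing.assert_array_equal(out.data.to_numpy()[inside], data[inside])

    def test_zero_mad_row_left_unchanged(self):
        vals = np.full((1, 40), 28.0)
        vals[0, -1] = 50.0  # MAD = 0: no shrinkage applied
        m = make_matrix(vals, stage="imputed")
        out = shrink_extremes(m)
        assert out.data.iloc[0, -1] == 50.0

    def test_extreme_clamped_to_exact_bound(self):
        vals = np.linspace(26.0, 30.0, 40)[None, :].copy()  # MAD > 0
        vals[0, -1] = 50.0
        m = make_matrix(vals, stage="imputed")
        out = shrink_extremes(m)
        row = vals[0]
        med = np.median(row)
        sigma = 1.4826 * np.median(np.abs(row - med))
        assert out.data.iloc[0, -1] == pytest.approx(med + 3 * sigma, abs=1e-12)

    def test_matches_winsorize_oracle_and_is_idempotent(self):
        rng = np.random.default_rng(8)
        data = rng.standard_t(df=3, size=(25, 30)) * 2 + 28
        m = make_matrix(data, stage="imputed")
        out = shrink_extremes(m)
        # brute-force per-row winsorize
        expected = data.copy()
        for i in range(data.shape[0]):
            med = np.median(data[i])
            sigma = 1.4826 * np.median(np.abs(data[i] - med))
            if sigma > 0:
                expected[i] = np.clip(data[i], med - 3 * sigma, med + 3 * sigma)
        np.testing.assert_allclose(out.data.to_numpy(), expected, atol=0, rtol=0)
        twice = shrink_extremes(CtMatrix(out.data, stage="imputed"))
        pd.testing.assert_frame_equal(twice.data, out.data)


class TestPipeline:
    def test_clean_complete_matrix_passes_through_filter_and_imputation(self):
        rng = np.random.default_rng(9)
        data = rng.uniform(22, 32, size=(40, 16))
        m = make_matrix(data)
        out, report = preprocess_pipeline(m)
        assert report["filtered"]["n_excluded"] == 0
        assert report["imputed"]["n_imputed"] == 0
        assert out.stage == "shrunk"

    def test_report_counts_match_independent_recount(self, default_dataset):
        matrix, _, _ = default_dataset
        params = PreprocessParams()
        out, report = preprocess_pipeline(matrix, params)
        bad = matrix.data.isna() | (matrix.data > params.max_ct)
        expected_excluded = int((bad.mean(axis=1) >= params.max_missing_frac).sum())
        assert report["filtered"]["n_excluded"] == expected_excluded
        assert report["filtered"]["n_assays"] == matrix.n_assays - expected_excluded
        assert report["imputed"]["n_missing"] == 0
        assert out.n_assays == report["filtered"]["n_assays"]

    def test_stage_tags_advance_in_order(self, small_dataset):
        matrix, _, _ = small_dataset
        params = PreprocessParams()
        filtered, _ = detection_filter(matrix, params)
        normalized = lowess_normalize(filtered, params)
        imputed = knn_impute(normalized, params)
        shrunk = shrink_extremes(imputed, params)
        stages = [m.stage for m in (matrix, filtered, normalized, imputed, shrunk)]
        assert stages == ["raw", "filtered", "normalized", "imputed", "shrunk"]

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            PreprocessParams(max_missing_frac=0.0)
        with pytest.raises(ConfigError):
            PreprocessParams(knn_k=0)
        with pytest.raises(ConfigError):
            PreprocessParams(lowess_span=1.5)


def test_normalization_centers_sample_deviations(default_dataset):
    """After lowess, each sample's median deviation from the reference is ~0."""
    matrix, _, _ = default_dataset
    filtered, _ = detection_filter(matrix)
    normalized = lowess_normalize(filtered)
    ref = normalized.data.median(axis=1)
    dev = normalized.data.sub(ref, axis=0)
    assert dev.median(axis=0).abs().max() <= 0.05
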