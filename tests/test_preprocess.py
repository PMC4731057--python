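"""Preprocessing chain: resampling, alignment, baseline, smoothing,
normalization, matrix assembly and threshold filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import maldimix as mm
from maldimix.errors import (
    DegenerateInputError,
    EmptyResultError,
    LinkageError,
    ParameterError,
    ValidationError,
)
from maldimix.io import SampleManifest, Spectrum
from maldimix.preprocess import (
    IntensityMatrix,
    MzGrid,
    align_set,
    build_matrix,
    normalize,
    resample,
    smooth,
    subtract_baseline,
    threshold_filter,
)

GRID = MzGrid(2000.0, 3000.0, 1001)  # 1 Da bins, small for speed


def spectrum_on(grid, intensity, **kw):
    return Spectrum(grid.centers, np.asarray(intensity, float), **kw).with_(
        stage=kw.pop("stage", "resampled")
    )


class TestResample:
    def test_identity_when_already_on_grid(self, rng):
        vals = rng.uniform(0, 1, GRID.n_bins)
        s = Spectrum(GRID.centers, vals, stage="raw")
        out = resample(s, GRID)
        np.testing.assert_allclose(out.intensity, vals, atol=1e-12)
        assert out.stage == "resampled"

    def test_midpoint_peak_splits_between_flanking_bins(self):
        # piecewise-linear triangle through (c-delta, 0), (peak, 10),
        # (c+delta, 0) with delta = bin width and the apex midway between
        # two grid centers: both flanking centers interpolate to 5
        delta = GRID.step
        c = GRID.centers[500]
        peak = c + delta / 2
        s = Spectrum(
            np.array([peak - delta, peak, peak + delta]),
            np.array([0.0, 10.0, 0.0]),
            stage="raw",
        )
        out = resample(s, GRID)
        np.testing.assert_allclose(out.intensity[500], 5.0, atol=1e-9)
        np.testing.assert_allclose(out.intensity[501], 5.0, atol=1e-9)

    def test_default_grid_has_30000_bins(self):
        s = Spectrum(np.array([2000.0, 20000.0]), np.array([1.0, 1.0]), stage="raw")
        out = resample(s, MzGrid())
        assert len(out) == 30000

    def test_outside_support_is_zero(self):
        s = Spectrum(np.array([2400.0, 2500.0]), np.array([1.0, 1.0]), stage="raw")
        out = resample(s, GRID)
        assert out.intensity[0] == 0.0
        assert out.intensity[-1] == 0.0

    def test_no_overlap_is_error(self):
        s = Spectrum(np.array([100.0, 200.0]), np.array([1.0, 1.0]), stage="raw")
        with pytest.raises(DegenerateInputError):
            resample(s, GRID)


class TestAlign:
    def _peaky(self, rng):
        x = np.zeros(GRID.n_bins)
        for c in (150, 420, 700, 900):
            x += np.exp(-0.5 * ((np.arange(GRID.n_bins) - c) / 6.0) ** 2)
        return x + rng.uniform(0, 1e-3, GRID.n_bins)

    def test_identical_spectra_offsets_zero(self, rng):
        x = self._peaky(rng)
        spectra = [spectrum_on(GRID, x) for _ in range(4)]
        _, offsets = align_set(spectra, 20)
        assert (offsets == 0).all()

    def test_shift_recovered_inverse(self, rng):
        x = self._peaky(rng)
        shifted = np.roll(x, 3)
        spectra = [spectrum_on(GRID, x) for _ in range(4)] + [
            spectrum_on(GRID, shifted)
        ]
        aligned, offsets = align_set(spectra, 20)
        assert offsets[-1] == -3
        np.testing.assert_allclose(
            aligned[-1].intensity[10:-10], x[10:-10], atol=1e-9
        )

    def test_idempotent(self, rng):
        x = self._peaky(rng)
        spectra = [spectrum_on(GRID, np.roll(x, s)) for s in (0, 2, -4, 1)]
        aligned, _ = align_set(spectra, 20)
        _, offsets2 = align_set(aligned, 20)
        assert (offsets2 == 0).all()

    def test_max_shift_bound_validated(self, rng):
        spectra = [spectrum_on(GRID, self._peaky(rng))]
        with pytest.raises(ParameterError):
            align_set(spectra, GRID.n_bins)


class TestBaseline:
    def test_flat_spectrum_to_zero(self):
        s = spectrum_on(GRID, np.full(GRID.n_bins, 3.7))
        out = subtract_baseline(s, 50)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_narrow_peak_height_preserved(self):
        x = 8.0 * np.exp(-0.5 * ((np.arange(GRID.n_bins) - 500) / 4.0) ** 2)
        out = subtract_baseline(spectrum_on(GRID, x), 100)
        assert out.intensity.max() == pytest.approx(8.0, rel=0.05)

    def test_ramp_mostly_removed(self):
        # a rolling-minimum baseline lags a ramp by ~slope * half_window,
        # so with a half-window of 5% of the length the residual stays
        # below 10% of the ramp amplitude
        ramp = np.linspace(0, 2.0, GRID.n_bins)
        peak = 5.0 * np.exp(-0.5 * ((np.arange(GRID.n_bins) - 500) / 4.0) ** 2)
        out = subtract_baseline(spectrum_on(GRID, peak + ramp), 50)
        residual_ramp = out.intensity[[200, 800]] - peak[[200, 800]]
        assert np.abs(residual_ramp).max() < 0.1 * 2.0

    def test_output_bounded_by_input(self, rng):
        x = rng.exponential(1.0, GRID.n_bins)
        out = subtract_baseline(spectrum_on(GRID, x), 30)
        assert (out.intensity <= x + 1e-12).all()
        assert (out.intensity >= 0).all()

    def test_window_validated(self):
        with pytest.raises(ParameterError):
            subtract_baseline(spectrum_on(GRID, np.ones(GRID.n_bins)), 0)


class TestSmooth:
    def test_quadratic_reproduced_exactly(self):
        t = np.linspace(0, 1, GRID.n_bins)
        q = 3.0 + 2.0 * t + 5.0 * t**2
        out = smooth(spectrum_on(GRID, q), 21, 2)
        np.testing.assert_allclose(out.intensity, q, atol=1e-9)

    def test_white_noise_variance_reduced(self, rng):
        x = rng.normal(10.0, 1.0, GRID.n_bins)
        out = smooth(spectrum_on(GRID, x), 21, 3)
        assert out.intensity.var() < x.var()

    def test_constant_unchanged(self):
        s = spectrum_on(GRID, np.full(GRID.n_bins, 2.5))
        out = smooth(s, 21, 3)
        np.testing.assert_allclose(out.intensity, 2.5, atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            smooth(spectrum_on(GRID, np.ones(GRID.n_bins)), 20, 3)


class TestNormalize:
    def test_simple_example(self):
        s = Spectrum(np.array([2000.0, 2001.0]), np.array([1.0, 3.0]),
                     stage="raw").with_(stage="smoothed")
        out = normalize(s)
        np.testing.assert_allclose(out.intensity, [0.25, 0.75])
        assert out.stage == "normalized"

    def test_fixed_point(self, rng):
        s = spectrum_on(GRID, rng.uniform(0, 1, GRID.n_bins))
        once = normalize(s)
        twice = normalize(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-15)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sum_is_one_for_random_positive_input(self, seed):
        vals = np.random.default_rng(seed).uniform(1e-6, 1.0, 64)
        s = Spectrum(np.arange(64, dtype=float) + 2000.0, vals)
        assert normalize(s).intensity.sum() == pytest.approx(1.0, abs=1e-12)

    def test_l2_mode(self, rng):
        s = spectrum_on(GRID, rng.uniform(0, 1, GRID.n_bins))
        out = normalize(s, mode="l2")
        assert np.linalg.norm(out.intensity) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        s = spectrum_on(GRID, np.zeros(GRID.n_bins))
        with pytest.raises(DegenerateInputError):
            normalize(s)


def _normalized_set(rng, n=4):
    spectra = []
    for i in range(n):
        s = spectrum_on(GRID, rng.uniform(0, 1, GRID.n_bins),
                        sample_id=f"m{i}", replicate=1)
        spectra.append(normalize(s))
    return spectra


def _manifest_for(spectra):
    import pandas as pd

    rows = [
        {"sample_id": s.sample_id, "file": f"{s.sample_id}.tsv",
         "n_cells_A": 1_000_000 - 1000 * i, "n_cells_B": 1000 * i,
         "replicate": s.replicate}
        for i, s in enumerate(spectra)
    ]
    return SampleManifest(pd.DataFrame(rows))


class TestBuildMatrix:
    def test_manifest_order_governs(self, rng):
        spectra = _normalized_set(rng)
        manifest = _manifest_for(spectra)
        m1 = build_matrix(spectra, manifest)
        m2 = build_matrix(spectra[::-1], manifest)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert m1.row_ids == m2.row_ids

    def test_unmatched_spectrum_is_linkage_error(self, rng):
        spectra = _normalized_set(rng)
        manifest = _manifest_for(spectra)
        with pytest.raises(LinkageError):
            build_matrix(spectra[:-1], manifest)

    def test_mismatched_grids_rejected(self, rng):
        spectra = _normalized_set(rng)
        other = GRID
        bad = normalize(
            Spectrum(np.linspace(2000, 3000, 500), rng.uniform(0, 1, 500),
                     sample_id=spectra[-1].sample_id,
                     replicate=spectra[-1].replicate, stage="raw").with_(
                stage="smoothed")
        )
        with pytest.raises(ValidationError):
            build_matrix(spectra[:-1] + [bad], _manifest_for(spectra))

    def test_non_normalized_rejected(self, rng):
        spectra = _normalized_set(rng)
        spectra[0] = spectra[0].with_(stage="smoothed")
        with pytest.raises(ValidationError):
            build_matrix(spectra, _manifest_for(spectra))


class TestThresholdFilter:
    def test_worked_example(self):
        m = IntensityMatrix(
            values=np.array([[0.0005, 0.002, 0.0], [0.0009, 0.0, 0.9]]),
            row_ids=["a", "b"],
            col_mz=np.array([2000.0, 2001.0, 2002.0]),
        )
        out = threshold_filter(m, 1e-3)
        np.testing.assert_allclose(out.col_mz, [2001.0, 2002.0])
        assert out.stage == "thresholded"

    def test_zero_threshold_keeps_any_positive(self, rng):
        vals = rng.uniform(0, 1, (3, 8))
        vals[:, 2] = 0.0
        m = IntensityMatrix(vals, ["a", "b", "c"], np.arange(8, dtype=float))
        out = threshold_filter(m, 0.0)
        assert out.shape[1] == 7

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        vals = r.uniform(0, 2e-3, (4, 12))
        m = IntensityMatrix(vals, list("abcd"), np.arange(12, dtype=float))
        thr = 1e-3
        expected = [j for j in range(12) if max(vals[i][j] for i in range(4)) > thr]
        try:
            out = threshold_filter(m, thr)
        except EmptyResultError:
            assert expected == []
            return
        np.testing.assert_array_equal(out.col_mz, np.array(expected, float))

    def test_idempotent_and_subset(self, rng):
        vals = rng.uniform(0, 3e-3, (3, 30))
        m = IntensityMatrix(vals, list("abc"), np.arange(30, dtype=float))
        once = threshold_filter(m, 1e-3)
        twice = threshold_filter(once, 1e-3)
        np.testing.assert_array_equal(once.values, twice.values)
        assert set(once.col_mz) <= set(m.col_mz)

    def test_nothing_survives_is_error(self):
        m = IntensityMatrix(np.full((2, 3), 1e-5), ["a", "b"],
                            np.arange(3, dtype=float))
        with pytest.raises(EmptyResultError):
            threshold_filter(m, 1e-3)


class TestFullChain:
    def test_row_count_preserved(self, noisy_dataset):
        _, spectra, manifest, _ = noisy_dataset
        cfg = mm.PipelineConfig(seed=2)
        prep = mm.preprocess_dataset(spectra, manifest, cfg)
        assert prep.matrix.shape[0] == len(spectra)
        assert prep.full_matrix.shape == (len(spectra), 30000)

    def test_noiseless_chain_recovers_planted_fingerprint(self, linear_dataset):
        """Cosine similarity >= 0.999 between each processed row and the
        directly resampled + normalized noiseless rendering."""
        gen, spectra, manifest, _ = linear_dataset
        cfg = mm.PipelineConfig(seed=1)
        prep = mm.preprocess_dataset(spectra, manifest, cfg)
        grid = cfg.grid
        for i, s in enumerate(spectra[:6]):
            truth = resample(s, grid)
            truth_v = truth.intensity / truth.intensity.sum()
            row = prep.full_matrix.values[i]
            cos = row @ truth_v / (np.linalg.norm(row) * np.linalg.norm(truth_v))
            assert cos >= 0.999
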