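"""Savitzky-Golay, normalization, SNV and MSC against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agarispec import (
    GeneratorConfig, MscModel, PreprocessConfig, Spectrum, SpectrumSet,
    apply_preprocess, generate_spectra, msc, normalize, savitzky_golay, snv,
)
from agarispec.synthetic import clean_spectrum


def sg_oracle(values, window, polyorder):
    """Brute force: refit the local polynomial at every interior band."""
    half = window // 2
    out = values.copy().astype(float)
    x = np.arange(window) - half
    for i in range(half, values.size - half):
        coef = np.polyfit(x, values[i - half: i + half + 1], polyorder)
        out[i] = np.polyval(coef, 0.0)
    return out


class TestSavitzkyGolay:
    def test_constant_spectrum_unchanged(self, grid):
        s = Spectrum(grid, np.full(grid.n_bands, 0.7))
        assert np.allclose(savitzky_golay(s).values, 0.7, atol=1e-12)

    def test_exact_on_cubic(self, grid):
        x = np.linspace(-1, 1, grid.n_bands)
        s = Spectrum(grid, 0.5 + 0.2 * x - 0.3 * x ** 2 + 0.1 * x ** 3)
        out = savitzky_golay(s, window=9, polyorder=3)
        assert np.max(np.abs(out.values - s.values)) < 1e-10

    def test_matches_brute_force_refit(self, grid, rng):
        for _ in range(5):
            v = rng.random(grid.n_bands)
            out = savitzky_golay(Spectrum(grid, v), window=7, polyorder=2)
            expect = sg_oracle(v, 7, 2)
            interior = slice(3, -3)
            assert np.max(np.abs(out.values[interior] - expect[interior])) < 1e-10

    def test_commutes_with_low_order_polynomial(self, grid, rng):
        v = rng.random(grid.n_bands)
        x = np.linspace(0, 1, grid.n_bands)
        poly = 0.3 + 0.5 * x - 0.2 * x ** 2
        a = savitzky_golay(Spectrum(grid, v + poly), 7, 2).values
        b = savitzky_golay(Spectrum(grid, v), 7, 2).values
        assert np.max(np.abs(a - b - poly)) < 1e-8

    @pytest.mark.parametrize("window, order", [(6, 2), (5, 5)])
    def test_bad_window_rejected(self, grid, rng, window, order):
        with pytest.raises(ValueError):
            savitzky_golay(Spectrum(grid, rng.random(grid.n_bands)), window, order)


class TestNormalize:
    def test_hand_case(self, rng):
        from agarispec import WavelengthGrid
        g = WavelengthGrid(450, 452, 1)
        out = normalize(Spectrum(g, [0.2, 0.6, 1.0]))
        assert np.allclose(out.values, [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_span(self, grid, rng):
        v = rng.random(grid.n_bands)
        once = normalize(Spectrum(grid, v))
        twice = normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_constant_rejected(self, grid):
        with pytest.raises(ValueError, match="constant"):
            normalize(Spectrum(grid, np.ones(grid.n_bands)))

    def test_unit_vector_mode(self, grid, rng):
        out = normalize(Spectrum(grid, rng.random(grid.n_bands)), mode="unit_vector")
        assert np.linalg.norm(out.values) == pytest.approx(1.0)


class TestSnv:
    def test_output_moments(self, grid, rng):
        out = snv(Spectrum(grid, rng.random(grid.n_bands)))
        assert abs(out.values.mean()) < 1e-12
        assert abs(out.values.std() - 1.0) < 1e-12  # population sd

    def test_hand_case_population_sd(self):
        from agarispec import WavelengthGrid
        out = snv(Spectrum(WavelengthGrid(450, 452, 1), [1.0, 2.0, 3.0]))
        assert np.allclose(out.values, [-np.sqrt(3 / 2), 0.0, np.sqrt(3 / 2)])

    @settings(deadline=None)
    @given(a=st.floats(-5, 5), b=st.floats(0.01, 10))
    def test_affine_invariance(self, grid, a, b):
        rng = np.random.default_rng(17)
        v = rng.random(grid.n_bands)
        base = snv(Spectrum(grid, v)).values
        moved = snv(Spectrum(grid, a + b * v)).values
        assert np.max(np.abs(moved - base)) < 1e-9

    def test_zero_sd_rejected(self, grid):
        with pytest.raises(ValueError):
            snv(Spectrum(grid, np.full(grid.n_bands, 0.3)))


class TestMsc:
    def test_reference_corrects_to_itself(self, grid, rng):
        v = rng.random((3, grid.n_bands))
        sset = SpectrumSet(grid, v)
        corrected, model = msc(sset, reference=v[1])
        assert np.allclose(corrected.values[1], v[1], atol=1e-10)
        assert model.slope[1] == pytest.approx(1.0)
        assert model.offset[1] == pytest.approx(0.0, abs=1e-12)

    def test_inverts_known_scatter(self, grid, rng):
        ref = 0.5 + 0.3 * rng.random(grid.n_bands)
        scattered = 0.3 + 1.7 * ref
        sset = SpectrumSet(grid, np.vstack([ref, scattered]))
        corrected, _ = msc(sset, reference=ref)
        assert np.max(np.abs(corrected.values[1] - ref)) < 1e-10

    def test_generator_scatter_closure(self, grid):
        """With the clean spectrum as reference, MSC recovers (a_i, b_i) exactly."""
        clean = clean_spectrum(87.5, 1, grid)[0]
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.03, 20)
        b = rng.lognormal(0, 0.08, 20)
        observed = a[:, None] + b[:, None] * clean
        sset = SpectrumSet(grid, observed)
        model = MscModel.fit(sset, reference=clean)
        corrected = model.transform(sset)
        assert np.max(np.abs(model.slope - b)) < 1e-8
        assert np.max(np.abs(model.offset - a)) < 1e-8
        assert np.max(np.abs(corrected.values - clean)) < 1e-8

    def test_frozen_reference_reused_on_new_spectra(self, grid, rng):
        train = SpectrumSet(grid, 0.5 + 0.1 * rng.random((10, grid.n_bands)))
        cfg = PreprocessConfig(method="msc")
        _, model = apply_preprocess(train, cfg)
        test = SpectrumSet(grid, 0.5 + 0.1 * rng.random((4, grid.n_bands)))
        out, _ = apply_preprocess(test, cfg, msc_model=model)
        assert out.values.shape == test.values.shape
        assert np.array_equal(model.reference, train.values.mean(axis=0))

    def test_grid_and_band_count_preserved(self, clean_set):
        sset, _ = clean_set
        for method in ("sg", "normalization", "snv", "msc"):
            out, _ = apply_preprocess(sset, PreprocessConfig(method=method))
            assert out.grid == sset.grid
            assert out.values.shape == sset.values.shape
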