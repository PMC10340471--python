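"""Data model, CSV round-tripping, moisture formula and shared metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agarispec import (
    MoistureSample, SpectraFormatError, SpectrumSet, WavelengthGrid,
    moisture_content, r2_score, read_spectra, rmse, split_train_test,
    write_spectra,
)


class TestGrid:
    def test_default_band_count_is_311(self, grid):
        assert grid.n_bands == 311
        assert grid.wavelengths[0] == 450 and grid.wavelengths[-1] == 760

    @pytest.mark.parametrize("args", [(760, 450, 1), (450, 760, -1), (450, 760, 7)])
    def test_invalid_grids_rejected(self, args):
        with pytest.raises(ValueError):
            WavelengthGrid(*args)


class TestIO:
    def test_round_trip_preserves_values(self, grid, rng, tmp_path):
        values = rng.random((100, grid.n_bands))
        labels = pd.DataFrame({"moisture_pct": rng.uniform(80, 95, 100)})
        sset = SpectrumSet(grid, values, labels=labels)
        path = tmp_path / "s.csv"
        write_spectra(sset, path)
        back = read_spectra(path)
        assert np.max(np.abs(back.values - values)) < 1e-9
        assert np.allclose(back.label("moisture_pct"), labels["moisture_pct"])
        assert back.sample_ids == sset.sample_ids

    def test_write_is_byte_stable(self, random_set, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_spectra(random_set, p1)
        write_spectra(random_set, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_set_writes_header_only(self, grid, tmp_path):
        sset = SpectrumSet(grid, np.empty((0, grid.n_bands)))
        path = tmp_path / "empty.csv"
        write_spectra(sset, path)
        assert path.read_text().count("\n") == 1

    def test_non_monotone_grid_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,500,499,501\ns0,0.1,0.2,0.3\n")
        with pytest.raises(SpectraFormatError, match="non-monotone"):
            read_spectra(path)

    def test_short_row_names_offending_row(self, tmp_path):
        path = tmp_path / "ragged.csv"
        header = "sample_id," + ",".join(str(w) for w in range(450, 455))
        path.write_text(header + "\ns0,.1,.2,.3,.4,.5\ns1,.1,.2,.3,.4\n")
        with pytest.raises(SpectraFormatError, match="s1"):
            read_spectra(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "alpha.csv"
        header = "sample_id," + ",".join(str(w) for w in range(450, 453))
        path.write_text(header + "\ns0,.1,oops,.3\n")
        with pytest.raises(SpectraFormatError, match="451"):
            read_spectra(path)


class TestMoisture:
    @pytest.mark.parametrize("m1, m2, expected", [
        (5.000, 0.500, 90.0),
        (4.000, 4.000, 0.0),
        (6.123, 0.551, 100 * (6.123 - 0.551) / 6.123),
    ])
    def test_wet_basis_formula(self, m1, m2, expected):
        assert moisture_content(MoistureSample(m1, m2)) == pytest.approx(expected, abs=1e-12)

    def test_out_of_window_mass_warns(self):
        with pytest.warns(UserWarning, match="4-7 g"):
            moisture_content(m1=10.0, m2=1.0)

    def test_negative_moisture_rejected(self):
        with pytest.raises(ValueError, match="negative moisture"):
            MoistureSample(4.0, 4.5)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @settings(deadline=None)
    @given(m1=st.floats(4, 7), frac=st.floats(0, 1), c=st.floats(0.01, 100))
    def test_scale_invariance(self, m1, frac, c):
        m2 = m1 * frac
        base = moisture_content(MoistureSample(m1, m2))
        scaled = moisture_content(MoistureSample(c * m1, c * m2))
        assert scaled == pytest.approx(base, abs=1e-8)


class TestMetrics:
    def test_perfect_and_null_predictions(self, rng):
        y = rng.normal(size=20)
        assert r2_score(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0
        assert r2_score(y, np.full(20, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_hand_case(self):
        assert rmse([1, 2, 3], [1, 2, 4]) == pytest.approx(np.sqrt(1 / 3))

    def test_matches_brute_force_summation(self, rng):
        for _ in range(10):
            y = rng.normal(size=30)
            p = rng.normal(size=30)
            ss_res = sum((a - b) ** 2 for a, b in zip(y, p))
            ss_tot = sum((a - np.mean(y)) ** 2 for a in y)
            assert r2_score(y, p) == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
            assert rmse(y, p) == pytest.approx((ss_res / 30) ** 0.5, abs=1e-12)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            r2_score([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestSplit:
    @pytest.mark.parametrize("n, n_train, n_test", [(200, 160, 40), (160, 128, 32)])
    def test_four_to_one_counts(self, grid, rng, n, n_train, n_test):
        sset = SpectrumSet(grid, rng.random((n, grid.n_bands)))
        train, test = split_train_test(sset, seed=3)
        assert (len(train), len(test)) == (n_train, n_test)

    def test_partition_and_determinism(self, grid, rng):
        sset = SpectrumSet(grid, rng.random((37, grid.n_bands)))
        a = split_train_test(sset, seed=11)
        b = split_train_test(sset, seed=11)
        ids = sorted(a[0].sample_ids + a[1].sample_ids)
        assert ids == sorted(sset.sample_ids)
        assert not set(a[0].sample_ids) & set(a[1].sample_ids)
        assert a[0].sample_ids == b[0].sample_ids and a[1].sample_ids == b[1].sample_ids

    def test_too_few_samples_rejected(self, grid):
        sset = SpectrumSet(grid, np.random.default_rng(0).random((4, grid.n_bands)))
        with pytest.raises(ValueError):
            split_train_test(sset, seed=0)
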