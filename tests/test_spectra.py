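"""Grid/masking/averaging semantics and the CSV round-trip contract."""

import numpy as np
import pytest

from shrubspec import (DEFAULT_WATER_WINDOWS, MaskRegions, SpectralLibrary,
                       Spectrum, WavelengthGrid, average_replicates,
                       library_matrix, mask_water_regions,
                       read_spectral_library, write_spectral_library)
from shrubspec.spectra import SpectralFormatError, mask_library

from conftest import make_spectrum


class TestGrid:
    def test_default_grid_has_2151_points(self, default_grid):
        assert len(default_grid) == 2151
        assert default_grid.wavelengths[0] == 350
        assert default_grid.wavelengths[-1] == 2500

    @pytest.mark.parametrize("start,stop,step", [(500, 400, 1), (400, 500, 0)])
    def test_invalid_grid_rejected(self, start, stop, step):
        with pytest.raises(ValueError):
            WavelengthGrid(start, stop, step)

    def test_nonuniform_wavelengths_rejected(self):
        with pytest.raises(SpectralFormatError, match="uniform"):
            WavelengthGrid.from_wavelengths(np.array([350.0, 351.0, 353.0]))


class TestMasking:
    def test_default_water_windows_mask_483_points(self, default_grid):
        # oracle: direct enumeration of the 1-nm grid over the three windows
        wl = default_grid.wavelengths
        expected = sum(int(np.sum((wl >= lo) & (wl <= hi)))
                       for lo, hi in DEFAULT_WATER_WINDOWS)
        assert expected == 483
        s = make_spectrum(default_grid, 0.3)
        masked = mask_water_regions(s)
        assert int((~masked.valid_mask).sum()) == 483
        assert masked.n_valid() == 1668

    def test_empty_region_list_is_identity(self, spectrum_factory):
        s = spectrum_factory(0.5)
        out = mask_water_regions(s, MaskRegions(()))
        assert np.array_equal(out.valid_mask, s.valid_mask)
        assert np.array_equal(out.reflectance, s.reflectance)

    def test_masking_is_idempotent(self, default_grid):
        s = make_spectrum(default_grid, 0.3)
        once = mask_water_regions(s)
        twice = mask_water_regions(once)
        assert np.array_equal(once.valid_mask, twice.valid_mask)

    def test_region_endpoints_inclusive(self, default_grid):
        s = mask_water_regions(make_spectrum(default_grid, 0.3),
                               MaskRegions(((1350, 1430),)))
        wl = default_grid.wavelengths
        assert not s.valid_mask[wl == 1350][0]
        assert not s.valid_mask[wl == 1430][0]
        assert s.valid_mask[wl == 1349][0]
        assert s.valid_mask[wl == 1431][0]

    def test_fully_masked_spectrum_refused_downstream(self, spectrum_factory, tiny_grid):
        s = mask_water_regions(spectrum_factory(0.5),
                               MaskRegions(((tiny_grid.start_nm, tiny_grid.stop_nm),)))
        assert s.n_valid() == 0
        with pytest.raises(ValueError):
            library_matrix(SpectralLibrary([s]))

    def test_region_outside_grid_rejected(self, spectrum_factory):
        with pytest.raises(ValueError, match="outside grid"):
            mask_water_regions(spectrum_factory(0.5), MaskRegions(((100, 200),)))


class TestReflectanceValidation:
    def test_above_hard_max_rejected(self, tiny_grid):
        with pytest.raises(ValueError, match=r"\[0, 1.5\]"):
            make_spectrum(tiny_grid, 1.6)

    def test_negative_rejected(self, tiny_grid):
        with pytest.raises(ValueError):
            make_spectrum(tiny_grid, -0.1)

    def test_panel_overshoot_warns_but_accepted(self, tiny_grid):
        with pytest.warns(UserWarning, match="above 1"):
            s = make_spectrum(tiny_grid, 1.2)
        assert s.reflectance.max() == 1.2


class TestAveraging:
    def test_single_replicate_is_identity(self, spectrum_factory):
        s = spectrum_factory(0.4)
        out = average_replicates(SpectralLibrary([s]))
        assert len(out) == 1
        avg = next(iter(out))
        assert np.allclose(avg.reflectance, s.reflectance)
        assert avg.replicate == 0

    def test_mean_of_two_constant_spectra(self, spectrum_factory):
        lib = SpectralLibrary([spectrum_factory(0.2, replicate=1),
                               spectrum_factory(0.4, replicate=2)])
        avg = next(iter(average_replicates(lib)))
        assert np.allclose(avg.reflectance, 0.3)

    def test_noise_averaging_shrinks_error(self, tiny_grid):
        # SD of the mean of 5 replicates at noise SD 0.01 is 0.01/sqrt(5);
        # 0.02 is ~4.5 SD away, so exceedances are vanishingly rare.
        rng = np.random.default_rng(12345)
        base = 0.5
        n_bad = 0
        n_trials = 200
        for t in range(n_trials):
            lib = SpectralLibrary(
                make_spectrum(tiny_grid, base + rng.normal(0, 0.01, 10),
                              replicate=r) for r in range(1, 6))
            avg = next(iter(average_replicates(lib)))
            n_bad += int(np.any(np.abs(avg.reflectance - base) > 0.02))
        assert n_bad / n_trials < 0.01

    def test_valid_only_where_all_replicates_valid(self, tiny_grid):
        m1 = np.ones(10, bool); m1[2] = False
        m2 = np.ones(10, bool); m2[7] = False
        lib = SpectralLibrary([
            make_spectrum(tiny_grid, 0.2, replicate=1, mask=m1),
            make_spectrum(tiny_grid, 0.4, replicate=2, mask=m2)])
        avg = next(iter(average_replicates(lib)))
        assert not avg.valid_mask[2] and not avg.valid_mask[7]
        assert avg.valid_mask.sum() == 8

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            average_replicates(SpectralLibrary())

    def test_averaging_commutes_with_masking(self, default_grid):
        rng = np.random.default_rng(5)
        lib = SpectralLibrary(
            make_spectrum(default_grid, np.clip(0.3 + rng.normal(0, 0.02, 2151), 0, 1),
                          replicate=r) for r in (1, 2, 3))
        a = next(iter(mask_library(average_replicates(lib))))
        b = next(iter(average_replicates(mask_library(lib))))
        assert np.array_equal(a.valid_mask, b.valid_mask)
        assert np.allclose(a.reflectance[a.valid_mask], b.reflectance[b.valid_mask])


class TestLibraryIO:
    def test_roundtrip_tiny_library(self, tmp_path, tiny_grid):
        lib = SpectralLibrary([
            make_spectrum(tiny_grid, np.linspace(0.1, 0.2, 10), quadrat="Q1"),
            make_spectrum(tiny_grid, np.linspace(0.3, 0.4, 10), quadrat="Q2")])
        path = write_spectral_library(lib, tmp_path / "lib.csv")
        back = read_spectral_library(path)
        assert len(back) == 2
        for k in lib.keys():
            # 6 significant digits => relative error at most 5e-6
            assert np.allclose(back[k].reflectance, lib[k].reflectance, rtol=5e-6)
            assert back[k].season == lib[k].season

    def test_second_write_is_byte_identical(self, tmp_path, tiny_grid):
        rng = np.random.default_rng(0)
        lib = SpectralLibrary([make_spectrum(tiny_grid, rng.uniform(0, 1, 10))])
        p1 = write_spectral_library(lib, tmp_path / "a.csv")
        p2 = write_spectral_library(read_spectral_library(p1), tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_masked_cells_roundtrip_as_empty(self, tmp_path, tiny_grid):
        mask = np.ones(10, bool)
        mask[3:5] = False
        lib = SpectralLibrary([make_spectrum(tiny_grid, 0.5, mask=mask)])
        path = write_spectral_library(lib, tmp_path / "m.csv")
        text = path.read_text().splitlines()
        assert text[4].endswith(",")  # masked cell serialized empty
        back = next(iter(read_spectral_library(path)))
        assert np.array_equal(back.valid_mask, mask)

    def test_nonuniform_wavelength_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,s1\n350,0.1\n351,0.1\n353,0.1\n")
        with pytest.raises(SpectralFormatError, match="uniform"):
            read_spectral_library(p)

    def test_non_numeric_cell_reported_with_location(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,s1\n350,0.1\n351,oops\n352,0.1\n")
        with pytest.raises(SpectralFormatError, match="row 3.*'s1'"):
            read_spectral_library(p)

    def test_empty_library_write_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_spectral_library(SpectralLibrary(), tmp_path / "x.csv")

    def test_duplicate_keys_rejected(self, spectrum_factory):
        lib = SpectralLibrary([spectrum_factory(0.1)])
        with pytest.raises(KeyError):
            lib.add(spectrum_factory(0.2))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_spectral_library(tmp_path / "nope.csv")
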