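"""Broadband sensor simulation: spectral response functions and resampling.

A band value is the response-weighted mean reflectance over the band's
support, computed only on valid (unmasked) wavelengths.  Bundled band sets
are *parametric* Gaussian stand-ins at the nominal centres and FWHMs of
the Landsat 8 OLI and Sentinel-2 MSI bands; a loader for official SRF
tables (long CSV: sensor, band, wavelength_nm, response) is provided for
users who have them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectralLibrary

__all__ = [
    "BandResponse",
    "BandSet",
    "load_band_responses",
    "synth_band_responses",
    "landsat8_like",
    "sentinel2_like",
    "resample_to_bands",
    "resample_library",
    "effective_bandwidth",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # fwhm * this = sigma


@dataclass(frozen=True)
class BandResponse:
    """One band's relative spectral response, peak-normalised to 1."""

    name: str
    wavelengths: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))
        object.__setattr__(self, "response", np.asarray(self.response, float))
        if self.response.min() < 0:
            raise ValueError(f"band {self.name}: negative response")
        peak = self.response.max()
        if peak <= 0:
            raise ValueError(f"band {self.name}: all-zero response")
        object.__setattr__(self, "response", self.response / peak)

    def response_at(self, wl: np.ndarray) -> np.ndarray:
        return np.interp(wl, self.wavelengths, self.response, left=0.0, right=0.0)


@dataclass(frozen=True)
class BandSet:
    sensor: str
    bands: tuple[BandResponse, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique within a set")

    def __iter__(self):
        return iter(self.bands)

    def names(self) -> list[str]:
        return [b.name for b in self.bands]


def load_band_responses(path: str | Path, grid_bounds=(350.0, 2500.0)) -> dict[str, BandSet]:
    """Read long-format SRF CSV (sensor, band, wavelength_nm, response)."""
    df = pd.read_csv(path)
    need = {"sensor", "band", "wavelength_nm", "response"}
    if not need <= set(df.columns):
        raise ValueError(f"SRF file must have columns {sorted(need)}")
    if (df["response"] < 0).any():
        raise ValueError("negative response values in SRF file")
    lo, hi = grid_bounds
    if df["wavelength_nm"].min() < lo or df["wavelength_nm"].max() > hi:
        raise ValueError(f"SRF wavelengths outside [{lo}, {hi}] nm")
    out = {}
    for sensor, sub in df.groupby("sensor"):
        bands = []
        for band, b in sub.groupby("band", sort=False):
            b = b.sort_values("wavelength_nm")
            bands.append(BandResponse(str(band), b["wavelength_nm"].to_numpy(),
                                      b["response"].to_numpy()))
        out[str(sensor)] = BandSet(str(sensor), tuple(bands))
    return out


def synth_band_responses(spec: list[tuple[str, float, float, str]],
                         sensor: str = "custom",
                         grid_bounds=(350.0, 2500.0),
                         sample_step: float = 0.5) -> BandSet:
    """Parametric bands from (name, center_nm, fwhm_nm, shape) tuples.

    Gaussian bands use ``sigma = fwhm / 2.3548`` sampled over +-5 sigma;
    boxcar bands are 1 on ``center +- fwhm/2`` and 0 just outside.
    """
    lo, hi = grid_bounds
    bands = []
    for name, center, fwhm, shape in spec:
        if fwhm <= 0:
            raise ValueError(f"band {name}: fwhm must be positive")
        if not lo <= center <= hi:
            raise ValueError(f"band {name}: center {center} outside [{lo}, {hi}]")
        if shape == "gaussian":
            sigma = fwhm * _FWHM_TO_SIGMA
            # sample points aligned to multiples of sample_step, so nominal
            # wavelengths (e.g. the FWHM points) are hit exactly
            first = np.ceil(max(center - 5 * sigma, lo) / sample_step) * sample_step
            last = np.floor(min(center + 5 * sigma, hi) / sample_step) * sample_step
            wl = first + sample_step * np.arange(round((last - first) / sample_step) + 1)
            resp = np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        elif shape == "boxcar":
            half = fwhm / 2.0
            eps = 1e-6
            wl = np.array([center - half - eps, center - half,
                           center + half, center + half + eps])
            inner = np.arange(center - half, center + half + sample_step / 2, sample_step)
            wl = np.unique(np.concatenate([wl, inner]))
            resp = np.where((wl >= center - half) & (wl <= center + half), 1.0, 0.0)
        else:
            raise ValueError(f"band {name}: unknown shape {shape!r}")
        bands.append(BandResponse(name, wl, resp))
    return BandSet(sensor, tuple(bands))


def landsat8_like() -> BandSet:
    """Gaussian bands at nominal Landsat 8 OLI centres / FWHMs (nm)."""
    return synth_band_responses([
        ("blue", 482.0, 60.0, "gaussian"),
        ("green", 561.5, 57.3, "gaussian"),
        ("red", 654.5, 37.5, "gaussian"),
        ("nir", 865.0, 28.0, "gaussian"),
        ("swir1", 1608.5, 85.0, "gaussian"),
        ("swir2", 2200.5, 186.6, "gaussian"),
    ], sensor="landsat8_like")


def sentinel2_like() -> BandSet:
    """Gaussian bands at nominal Sentinel-2A MSI centres / FWHMs (nm)."""
    return synth_band_responses([
        ("blue", 492.4, 66.0, "gaussian"),
        ("green", 559.8, 35.0, "gaussian"),
        ("red", 664.6, 31.0, "gaussian"),
        ("red_edge_1", 704.1, 15.0, "gaussian"),
        ("red_edge_2", 740.5, 15.0, "gaussian"),
        ("red_edge_3", 782.8, 20.0, "gaussian"),
        ("nir", 832.8, 106.0, "gaussian"),
        ("water_vapor", 945.1, 20.0, "gaussian"),
        ("swir1", 1613.7, 91.0, "gaussian"),
        ("swir2", 2202.4, 180.0, "gaussian"),
    ], sensor="sentinel2_like")


def resample_to_bands(spectrum: Spectrum, bands: BandSet) -> dict[str, float]:
    """Response-weighted mean reflectance per band over valid wavelengths.

    A band whose support contains no valid wavelength (e.g. one fully
    inside a masked water window) yields NaN.
    """
    wl = spectrum.wavelengths
    out = {}
    for band in bands:
        w = band.response_at(wl) * spectrum.valid_mask
        total = w.sum()
        out[band.name] = float((w @ spectrum.reflectance) / total) if total > 0 else float("nan")
    return out


def resample_library(lib: SpectralLibrary, bands: BandSet) -> pd.DataFrame:
    """Long table (quadrat_id, season, replicate, band, value) for a library."""
    rows = []
    for s in sorted(lib, key=lambda s: s.key):
        vals = resample_to_bands(s, bands)
        for name, v in vals.items():
            rows.append({"quadrat_id": s.quadrat_id, "season": s.season,
                         "replicate": s.replicate, "band": name, "value": v})
    return pd.DataFrame(rows)


def effective_bandwidth(band: BandResponse) -> float:
    """Equivalent width in nm: integral of the response over its peak."""
    return float(np.trapezoid(band.response, band.wavelengths) / band.response.max())
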