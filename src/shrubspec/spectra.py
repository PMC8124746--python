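"""Wavelength-grid data model and I/O for field spectral libraries.

Reflectance spectra live on a uniform nanometre grid (default 350-2500 nm
at 1 nm, the range of field spectroradiometers used for grassland work).
Atmospheric water-vapour windows are unusable in field spectra and are
removed by masking rather than deletion, so every spectrum keeps the full
grid plus a boolean validity mask.

The on-disk format is a wide CSV (first column ``wavelength_nm``, one
column per sample, masked cells empty) with a sidecar metadata CSV keyed
by sample id.  Values are written with 6 significant digits; a
read-write-read cycle is bit-exact at that precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "DEFAULT_WATER_WINDOWS",
    "WavelengthGrid",
    "Spectrum",
    "MaskRegions",
    "SpectralLibrary",
    "mask_water_regions",
    "mask_library",
    "average_replicates",
    "read_spectral_library",
    "write_spectral_library",
    "library_matrix",
]

SEASONS = ("spring", "summer", "fall")

#: Water-vapour absorption windows removed from field spectra (nm, inclusive).
DEFAULT_WATER_WINDOWS = ((1350.0, 1430.0), (1750.0, 1980.0), (2330.0, 2500.0))

#: Reflectances above 1 can occur near panel calibration; beyond 1.5 the
#: value is treated as corrupt.
_REFLECTANCE_HARD_MAX = 1.5


class SpectralFormatError(ValueError):
    """Raised when an on-disk library violates the documented CSV dialect."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid, inclusive of both endpoints."""

    start_nm: float = 350.0
    stop_nm: float = 2500.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError("grid start must be below stop")
        if self.step_nm <= 0:
            raise ValueError("grid step must be positive")

    def __len__(self) -> int:
        return int(np.floor((self.stop_nm - self.start_nm) / self.step_nm + 1e-9)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(len(self))

    def index_of(self, wavelength_nm: float) -> int:
        idx = (wavelength_nm - self.start_nm) / self.step_nm
        i = int(round(idx))
        if abs(idx - i) > 1e-6 or not 0 <= i < len(self):
            raise ValueError(f"{wavelength_nm} nm is not on the grid")
        return i

    @classmethod
    def from_wavelengths(cls, wavelengths: np.ndarray) -> "WavelengthGrid":
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.ndim != 1 or len(wavelengths) < 2:
            raise SpectralFormatError("need at least two wavelengths")
        steps = np.diff(wavelengths)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise SpectralFormatError("wavelength column is not a uniform grid")
        return cls(float(wavelengths[0]), float(wavelengths[-1]), float(steps[0]))


@dataclass
class Spectrum:
    """One reflectance spectrum with a validity mask.

    ``replicate`` numbers field repeats within a quadrat (1-based);
    replicate 0 marks a replicate-averaged spectrum.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray
    valid_mask: np.ndarray | None = None
    sample_id: str = ""
    quadrat_id: str = ""
    season: str = "spring"
    replicate: int = 1
    position_m: float = float("nan")

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != (len(self.grid),):
            raise ValueError("reflectance length must equal grid length")
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.grid), dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (len(self.grid),):
                raise ValueError("valid_mask length must equal grid length")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        vals = self.reflectance[self.valid_mask]
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("reflectance must be finite at valid points")
        if vals.size:
            if vals.min() < 0 or vals.max() > _REFLECTANCE_HARD_MAX:
                raise ValueError(
                    "reflectance outside [0, 1.5]: "
                    f"range [{vals.min():.4g}, {vals.max():.4g}]"
                )
            if vals.max() > 1.0:
                warnings.warn(
                    f"sample {self.sample_id!r}: reflectance above 1 "
                    f"(max {vals.max():.4g}); accepted as panel-calibration overshoot",
                    stacklevel=2,
                )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.quadrat_id, self.season, self.replicate)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass(frozen=True)
class MaskRegions:
    """Closed wavelength intervals to mark invalid (both endpoints included)."""

    regions: tuple[tuple[float, float], ...] = DEFAULT_WATER_WINDOWS

    def __post_init__(self) -> None:
        for low, high in self.regions:
            if low > high:
                raise ValueError(f"mask region ({low}, {high}) has low > high")

    def validate_within(self, grid: WavelengthGrid) -> None:
        for low, high in self.regions:
            if low < grid.start_nm or high > grid.stop_nm:
                raise ValueError(
                    f"mask region ({low}, {high}) outside grid "
                    f"[{grid.start_nm}, {grid.stop_nm}]"
                )

    def mask_array(self, grid: WavelengthGrid) -> np.ndarray:
        """Boolean array: True where the grid point falls inside a region."""
        wl = grid.wavelengths
        hit = np.zeros(len(grid), dtype=bool)
        for low, high in self.regions:
            hit |= (wl >= low) & (wl <= high)
        return hit


class SpectralLibrary:
    """Collection of spectra sharing one grid, keyed by (quadrat, season, replicate)."""

    def __init__(self, spectra: Iterable[Spectrum] = ()) -> None:
        self.grid: WavelengthGrid | None = None
        self._spectra: dict[tuple[str, str, int], Spectrum] = {}
        for s in spectra:
            self.add(s)

    def add(self, spectrum: Spectrum) -> None:
        if self.grid is None:
            self.grid = spectrum.grid
        elif spectrum.grid != self.grid:
            raise ValueError("all library spectra must share one grid")
        if spectrum.key in self._spectra:
            raise KeyError(f"duplicate sample key {spectrum.key}")
        self._spectra[spectrum.key] = spectrum

    def __len__(self) -> int:
        return len(self._spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self._spectra.values())

    def __getitem__(self, key: tuple[str, str, int]) -> Spectrum:
        return self._spectra[key]

    def __contains__(self, key: tuple[str, str, int]) -> bool:
        return key in self._spectra

    def keys(self) -> list[tuple[str, str, int]]:
        return list(self._spectra.keys())

    def subset(self, season: str | None = None,
               quadrat_ids: Sequence[str] | None = None) -> "SpectralLibrary":
        wanted = set(quadrat_ids) if quadrat_ids is not None else None
        return SpectralLibrary(
            s for s in self
            if (season is None or s.season == season)
            and (wanted is None or s.quadrat_id in wanted)
        )


def mask_water_regions(spectrum: Spectrum,
                       regions: MaskRegions = MaskRegions()) -> Spectrum:
    """Return a copy with grid points inside the regions marked invalid.

    Idempotent; endpoints of each region are included.
    """
    regions.validate_within(spectrum.grid)
    new_mask = spectrum.valid_mask & ~regions.mask_array(spectrum.grid)
    return replace(spectrum, valid_mask=new_mask,
                   reflectance=spectrum.reflectance.copy())


def mask_library(lib: SpectralLibrary,
                 regions: MaskRegions = MaskRegions()) -> SpectralLibrary:
    return SpectralLibrary(mask_water_regions(s, regions) for s in lib)


def average_replicates(lib: SpectralLibrary) -> SpectralLibrary:
    """Arithmetic mean over replicates per (quadrat, season).

    A grid point is valid in the mean only where it is valid in every
    replicate.  The averaged spectrum carries replicate number 0.
    """
    if len(lib) == 0:
        raise ValueError("cannot average an empty library")
    groups: dict[tuple[str, str], list[Spectrum]] = {}
    for s in lib:
        groups.setdefault((s.quadrat_id, s.season), []).append(s)
    out = SpectralLibrary()
    for (quadrat_id, season), members in groups.items():
        refl = np.mean([m.reflectance for m in members], axis=0)
        mask = np.logical_and.reduce([m.valid_mask for m in members])
        refl = np.where(mask, refl, np.nan)
        out.add(Spectrum(
            grid=members[0].grid, reflectance=np.nan_to_num(refl),
            valid_mask=mask,
            sample_id=f"{quadrat_id}_{season}_mean",
            quadrat_id=quadrat_id, season=season, replicate=0,
            position_m=members[0].position_m,
        ))
    return out


# ---------------------------------------------------------------------------
# I/O: wide CSV + metadata sidecar

_FLOAT_FMT = "%.6g"


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + "_meta.csv")


def write_spectral_library(lib: SpectralLibrary, path: str | Path) -> Path:
    """Write a wide CSV (masked cells empty) plus a ``*_meta.csv`` sidecar."""
    if len(lib) == 0:
        raise ValueError("refusing to write an empty library")
    path = Path(path)
    spectra = sorted(lib, key=lambda s: s.key)
    wl = lib.grid.wavelengths
    cols = {"wavelength_nm": [_FLOAT_FMT % w for w in wl]}
    meta_rows = []
    for s in spectra:
        cells = [_FLOAT_FMT % v if ok else ""
                 for v, ok in zip(s.reflectance, s.valid_mask)]
        cols[s.sample_id] = cells
        meta_rows.append({
            "sample_id": s.sample_id, "quadrat_id": s.quadrat_id,
            "season": s.season, "replicate": s.replicate,
            "position_m": "" if np.isnan(s.position_m) else _FLOAT_FMT % s.position_m,
        })
    pd.DataFrame(cols).to_csv(path, index=False)
    pd.DataFrame(meta_rows).to_csv(_meta_path(path), index=False)
    return path


def read_spectral_library(path: str | Path) -> SpectralLibrary:
    """Read the wide-CSV dialect written by :func:`write_spectral_library`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectralFormatError(f"cannot parse {path}: {exc}") from exc
    if df.columns[0] != "wavelength_nm":
        raise SpectralFormatError("first column must be wavelength_nm")
    try:
        wavelengths = df["wavelength_nm"].astype(float).to_numpy()
    except ValueError as exc:
        raise SpectralFormatError(f"non-numeric wavelength cell: {exc}") from exc
    grid = WavelengthGrid.from_wavelengths(wavelengths)

    meta = {}
    mpath = _meta_path(path)
    if mpath.exists():
        mdf = pd.read_csv(mpath, dtype=str).fillna("")
        meta = {row["sample_id"]: row for _, row in mdf.iterrows()}

    lib = SpectralLibrary()
    for col in df.columns[1:]:
        raw = df[col]
        mask = ~(raw.isna() | (raw.astype(str).str.strip() == ""))
        refl = np.zeros(len(grid))
        try:
            refl[mask.to_numpy()] = raw[mask].astype(float).to_numpy()
        except ValueError as exc:
            bad = raw[mask][pd.to_numeric(raw[mask], errors="coerce").isna()]
            row = bad.index[0] + 2  # header + 1-based
            raise SpectralFormatError(
                f"non-numeric cell at row {row}, column {col!r}") from exc
        m = meta.get(col, {})
        lib.add(Spectrum(
            grid=grid, reflectance=refl, valid_mask=mask.to_numpy(),
            sample_id=col,
            quadrat_id=str(m.get("quadrat_id", col)),
            season=str(m.get("season", "spring")),
            replicate=int(m.get("replicate", 1) or 1),
            position_m=float(m["position_m"]) if m.get("position_m", "") != "" else float("nan"),
        ))
    if len(lib) == 0:
        raise SpectralFormatError("file contains no sample columns")
    return lib


def library_matrix(lib: SpectralLibrary,
                   keys: Sequence[tuple[str, str, int]] | None = None,
                   ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str, int]]]:
    """Stack spectra into (n_samples, n_valid) matrix over the shared valid points.

    Returns (X, wavelengths_of_columns, row_keys).  Points masked in any
    member are dropped so downstream statistics never touch invalid cells.
    """
    if len(lib) == 0:
        raise ValueError("empty library")
    if keys is None:
        keys = sorted(lib.keys())
    spectra = [lib[k] for k in keys]
    shared = np.logical_and.reduce([s.valid_mask for s in spectra])
    if not shared.any():
        raise ValueError("no wavelength is valid in every spectrum")
    X = np.stack([s.reflectance[shared] for s in spectra])
    return X, lib.grid.wavelengths[shared], list(keys)
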