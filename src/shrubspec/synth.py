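"""Synthetic grassland-transect scenes for exercising the analysis end to end.

The generator emulates the statistical structure the pipeline assumes of a
shrub-encroached fescue prairie transect: a spatially autocorrelated shrub
fraction along the line, a compositional background (green grass, forb,
standing dead, litter, bare soil), per-quadrat spectra built as linear
mixtures of parametric endmember spectra plus instrument noise, replicate
sampling, pure-shrub endmember spectra, seasonal modulation of pigment and
water absorption, line-intercept patches, and the field protocol's visual
cover quantization.

Endmember spectra are parametric, not radiative-transfer output: a visible
baseline with Gaussian pigment wells at 450 and 680 nm, a logistic red edge
onto an NIR plateau, and Gaussian water wells at 1450 and 1940 nm.  This
captures the qualitative contrasts that drive the analysis (pigments in the
visible, leaf structure in the NIR, moisture in the SWIR) without claiming
quantitative realism for any species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import SEASONS, Spectrum, SpectralLibrary, WavelengthGrid

__all__ = [
    "COVER_CLASSES",
    "EndmemberParams",
    "DEFAULT_ENDMEMBERS",
    "TransectConfig",
    "SyntheticScene",
    "LITSummary",
    "generate_endmember",
    "generate_scene",
    "simulate_lit",
    "quantize_cover",
]

#: Top-layer cover classes whose true fractions sum to 1 in every quadrat.
COVER_CLASSES = ("green_grass", "shrub", "forb", "standing_dead", "litter", "bare_soil")


@dataclass(frozen=True)
class EndmemberParams:
    """Parameters of one parametric endmember spectrum.

    ``season_scalars`` maps season -> multipliers for (chlorophyll depth,
    water depth, NIR plateau, visible baseline); the defaults encode spring
    green-up, summer peak moisture and fall senescence brightening.
    """

    kind: str
    vis_base: float = 0.06            # visible baseline reflectance
    npv_slope: float = 0.0            # visible-range slope (per 1000 nm)
    chlorophyll_depth: float = 0.5    # fractional depth of 450/680 nm wells
    red_edge_pos: float = 720.0       # nm, logistic midpoint
    nir_plateau: float = 0.40         # NIR plateau reflectance
    water_depth: float = 0.35         # fractional depth of 1450/1940 nm wells
    swir_decay: float = 0.35          # plateau roll-off into the SWIR
    season_scalars: dict = field(default_factory=lambda: {
        "spring": {"chl": 0.9, "water": 0.9, "nir": 0.95, "vis": 1.0},
        "summer": {"chl": 1.0, "water": 1.0, "nir": 1.0, "vis": 1.0},
        "fall": {"chl": 0.45, "water": 0.6, "nir": 0.9, "vis": 1.5},
    })

    def __post_init__(self) -> None:
        if not 690 <= self.red_edge_pos <= 760:
            raise ValueError("red_edge_pos must lie in [690, 760] nm")


DEFAULT_ENDMEMBERS: dict[str, EndmemberParams] = {
    "green_grass": EndmemberParams("green_grass", vis_base=0.055, chlorophyll_depth=0.55,
                                   red_edge_pos=718, nir_plateau=0.42, water_depth=0.38),
    "shrub": EndmemberParams("shrub", vis_base=0.050, chlorophyll_depth=0.65,
                             red_edge_pos=725, nir_plateau=0.52, water_depth=0.48),
    "forb": EndmemberParams("forb", vis_base=0.058, chlorophyll_depth=0.60,
                            red_edge_pos=716, nir_plateau=0.46, water_depth=0.42),
    "standing_dead": EndmemberParams(
        "standing_dead", vis_base=0.10, npv_slope=0.28, chlorophyll_depth=0.0,
        red_edge_pos=720, nir_plateau=0.38, water_depth=0.12,
        season_scalars={"spring": {"chl": 0.0, "water": 1.0, "nir": 1.0, "vis": 1.0},
                        "summer": {"chl": 0.0, "water": 1.0, "nir": 1.0, "vis": 1.0},
                        "fall": {"chl": 0.0, "water": 0.9, "nir": 1.0, "vis": 1.1}}),
    "litter": EndmemberParams(
        "litter", vis_base=0.13, npv_slope=0.22, chlorophyll_depth=0.0,
        red_edge_pos=720, nir_plateau=0.33, water_depth=0.10,
        season_scalars={s: {"chl": 0.0, "water": 1.0, "nir": 1.0, "vis": 1.0}
                        for s in SEASONS}),
    "bare_soil": EndmemberParams(
        "bare_soil", vis_base=0.11, npv_slope=0.30, chlorophyll_depth=0.0,
        red_edge_pos=720, nir_plateau=0.30, water_depth=0.08,
        season_scalars={s: {"chl": 0.0, "water": 1.0, "nir": 1.0, "vis": 1.0}
                        for s in SEASONS}),
}


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def generate_endmember(params: EndmemberParams, season: str,
                       seed: int | None = None,
                       grid: WavelengthGrid = WavelengthGrid(),
                       jitter: float = 0.0) -> Spectrum:
    """Deterministic parametric endmember spectrum for one season.

    ``jitter`` perturbs the plateau/depth parameters multiplicatively
    (lognormal-ish via 1 + N(0, jitter)) to emulate within-species spectral
    variation; it requires a seed.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    sc = params.season_scalars.get(season, {"chl": 1, "water": 1, "nir": 1, "vis": 1})
    chl = params.chlorophyll_depth * sc["chl"]
    water = params.water_depth * sc["water"]
    nir = params.nir_plateau * sc["nir"]
    vis = params.vis_base * sc["vis"]
    if jitter > 0:
        if seed is None:
            raise ValueError("jitter requires a seed")
        rng = np.random.default_rng(seed)
        f = 1.0 + rng.normal(0.0, jitter, size=4)
        chl, water, nir, vis = chl * f[0], water * f[1], nir * f[2], vis * max(f[3], 0.1)

    wl = grid.wavelengths
    visible = vis * (1.0 + params.npv_slope * (wl - 350.0) / 1000.0)
    edge = 1.0 / (1.0 + np.exp(-(wl - params.red_edge_pos) / 18.0))
    # plateau rolls off gently beyond 1350 nm (dry-matter + water continuum)
    rolloff = 1.0 - params.swir_decay / (1.0 + np.exp(-(wl - 1650.0) / 180.0))
    base = visible + np.maximum(nir * rolloff - visible, 0.0) * edge
    pigment = 1.0 - chl * (_gauss(wl, 450.0, 45.0) + _gauss(wl, 680.0, 40.0))
    moisture = 1.0 - water * (0.9 * _gauss(wl, 1450.0, 55.0)
                              + _gauss(wl, 1940.0, 75.0)
                              + 0.25 * _gauss(wl, 1200.0, 45.0))
    refl = base * pigment * moisture
    if refl.min() < 0 or refl.max() > 1:
        import warnings
        warnings.warn(f"endmember {params.kind}/{season}: reflectance clipped to [0,1]",
                      stacklevel=2)
        refl = np.clip(refl, 0.0, 1.0)
    return Spectrum(grid=grid, reflectance=refl,
                    sample_id=f"em_{params.kind}_{season}",
                    quadrat_id=f"em_{params.kind}", season=season, replicate=1)


@dataclass(frozen=True)
class TransectConfig:
    """Study-condition parameters of one synthetic transect.

    Defaults reproduce the sampling geometry of the emulated field design:
    a 381 m line with quadrats every 3 m (128 quadrats), three seasons,
    five replicate spectra per quadrat, and at least ten pure-shrub
    endmember spectra per season.
    """

    length_m: float = 381.0
    spacing_m: float = 3.0
    seasons: tuple[str, ...] = SEASONS
    shrub_mean: float = 0.20          # target mean shrub fraction
    correlation_length_m: float = 12.0
    noise_sd: float = 0.01            # instrument noise SD (reflectance units)
    n_replicates: int = 5
    n_endmembers: int = 10
    seed: int = 0
    strata: tuple[float, ...] | None = None   # planted shrub fractions
    strata_jitter: float = 0.02
    composition_concentration: float = 1.0    # scales Dirichlet concentration
    grid: WavelengthGrid = WavelengthGrid()

    def __post_init__(self) -> None:
        n = self.length_m / self.spacing_m
        if abs(n - round(n)) > 1e-9:
            raise ValueError("spacing_m must divide length_m")

    @property
    def n_quadrats(self) -> int:
        return int(round(self.length_m / self.spacing_m)) + 1

    @property
    def positions_m(self) -> np.ndarray:
        return self.spacing_m * np.arange(self.n_quadrats)


@dataclass
class LITSummary:
    """Line-intercept transect summary."""

    cover_pct: float
    density_per_m: float
    n_patches: int
    total_length_m: float


@dataclass
class SyntheticScene:
    config: TransectConfig
    quadrats: pd.DataFrame            # one row per quadrat x season
    library: SpectralLibrary          # replicate spectra
    endmember_library: SpectralLibrary  # pure shrub spectra per season
    patches: list[tuple[float, float]]  # shrub canopy intervals along the line


def quantize_cover(true_pct: float) -> float:
    """Visual-estimation rounding: nearest 1% below 5% and above 90%,
    nearest 5% in between."""
    if not 0.0 <= true_pct <= 100.0:
        raise ValueError(f"cover {true_pct} outside [0, 100]")
    if true_pct < 5.0 or true_pct > 90.0:
        q = np.floor(true_pct + 0.5)
    else:
        q = 5.0 * np.floor(true_pct / 5.0 + 0.5)
    return float(min(max(q, 0.0), 100.0))


# Seasonal Dirichlet concentrations for the non-shrub remainder; orderings
# (standing dead largest in fall, green grass peaking in summer) mimic the
# seasonal course of a northern fescue prairie.
_SEASON_ALPHA = {
    "spring": {"green_grass": 3.2, "forb": 1.7, "standing_dead": 3.6,
               "litter": 1.0, "bare_soil": 0.15},
    "summer": {"green_grass": 3.9, "forb": 1.8, "standing_dead": 3.5,
               "litter": 0.7, "bare_soil": 0.10},
    "fall": {"green_grass": 2.7, "forb": 1.5, "standing_dead": 5.0,
             "litter": 0.4, "bare_soil": 0.10},
}

#: Seasonal multiplier on the shrub fraction (slight leaf loss over the year).
_SEASON_SHRUB_SCALE = {"spring": 1.0, "summer": 0.92, "fall": 0.88}

#: Quadrat shrub fractions below this floor are treated as shrub-free.
_SHRUB_FLOOR = 0.03


def _shrub_field(config: TransectConfig, rng: np.random.Generator) -> np.ndarray:
    """Moving-average-smoothed Gaussian field, logistic-squashed to [0, 1]."""
    n = config.n_quadrats
    window = max(1, int(round(config.correlation_length_m / config.spacing_m)))
    z = rng.normal(size=n + window)
    z = np.convolve(z, np.ones(window) / window, mode="valid")[:n]
    z = (z - z.mean()) / max(z.std(), 1e-12)
    mean = min(max(config.shrub_mean, 1e-6), 1 - 1e-6)
    # offset calibrated so E[logistic(offset + s*z)] ~ mean for z ~ N(0,1)
    # (probit-style correction: logit(mean) * sqrt(1 + pi * s^2 / 8))
    s = 2.0
    offset = np.log(mean / (1 - mean)) * np.sqrt(1.0 + np.pi * s * s / 8.0)
    x = 1.0 / (1.0 + np.exp(-(offset + s * z)))
    x[x < _SHRUB_FLOOR] = 0.0
    return x


def generate_scene(config: TransectConfig) -> SyntheticScene:
    """Generate a full transect scene, reproducible from ``config.seed``.

    Randomness is split from a single :class:`numpy.random.SeedSequence`
    into one sub-stream per quadrat (plus streams for the shrub field and
    the endmember library) so scenes are stable across platforms.
    """
    root = np.random.SeedSequence(config.seed)
    ss_field, ss_endmember, *ss_quadrats = root.spawn(2 + config.n_quadrats)
    rng_field = np.random.default_rng(ss_field)

    if config.shrub_mean <= 0 and config.strata is None:
        shrub = np.zeros(config.n_quadrats)
    elif config.strata is not None:
        strata = np.asarray(config.strata, dtype=float)
        idx = np.arange(config.n_quadrats) % len(strata)
        jit = rng_field.normal(0.0, config.strata_jitter, size=config.n_quadrats)
        shrub = np.clip(strata[idx] + np.where(strata[idx] > 0, jit, 0.0), 0.0, 1.0)
    else:
        shrub = _shrub_field(config, rng_field)

    # seasonal pure endmember spectra used for mixing
    mix_endmembers = {
        (kind, season): generate_endmember(DEFAULT_ENDMEMBERS[kind], season, grid=config.grid)
        for kind in COVER_CLASSES for season in config.seasons
    }

    positions = config.positions_m
    lib = SpectralLibrary()
    rows = []
    background = [c for c in COVER_CLASSES if c != "shrub"]
    for q in range(config.n_quadrats):
        rng = np.random.default_rng(ss_quadrats[q])
        qid = f"Q{q:03d}"
        for season in config.seasons:
            s_shrub = min(shrub[q] * _SEASON_SHRUB_SCALE[season], 1.0) if shrub[q] > 0 else 0.0
            alpha = np.array([_SEASON_ALPHA[season][c] for c in background])
            comp = rng.dirichlet(alpha * config.composition_concentration)
            fracs = dict(zip(background, comp * (1.0 - s_shrub)))
            fracs["shrub"] = s_shrub

            mixture = np.zeros(len(config.grid))
            for kind in COVER_CLASSES:
                mixture += fracs[kind] * mix_endmembers[(kind, season)].reflectance
            for rep in range(1, config.n_replicates + 1):
                refl = mixture + rng.normal(0.0, config.noise_sd, size=mixture.shape) \
                    if config.noise_sd > 0 else mixture.copy()
                lib.add(Spectrum(
                    grid=config.grid, reflectance=np.clip(refl, 0.0, 1.0),
                    sample_id=f"{qid}_{season}_r{rep}", quadrat_id=qid,
                    season=season, replicate=rep, position_m=positions[q]))

            green = fracs["green_grass"] + fracs["forb"] + fracs["shrub"]
            pai_scale = {"spring": 0.85, "summer": 1.25, "fall": 1.0}[season]
            pai = max(0.2 + 2.4 * green * pai_scale + rng.normal(0, 0.08), 0.0)
            sm_base = {"spring": 0.148, "summer": 0.183, "fall": 0.189}[season]
            soil_moisture = float(np.clip(
                sm_base + 0.03 * s_shrub + rng.normal(0, 0.015), 0.0, 1.0))
            veg = green + fracs["standing_dead"]
            biomass_green = max(120 * (fracs["green_grass"] + fracs["forb"])
                                * {"spring": 0.7, "summer": 1.0, "fall": 0.8}[season] * 10
                                + rng.normal(0, 15), 0.0)
            biomass_shrub = max(900 * s_shrub + rng.normal(0, 20), 0.0)
            biomass_npv = max(450 * fracs["standing_dead"] / 0.35
                              + rng.normal(0, 30), 0.0)
            row = {
                "quadrat_id": qid, "position_m": positions[q], "season": season,
                "shrub_true_frac": s_shrub, "pai": pai,
                "soil_moisture": soil_moisture,
                "biomass_green_g_m2": biomass_green,
                "biomass_shrub_g_m2": biomass_shrub,
                "biomass_npv_g_m2": biomass_npv,
            }
            for kind in COVER_CLASSES:
                row[f"frac_{kind}"] = fracs[kind]
                row[f"cover_pct_{kind}"] = quantize_cover(100.0 * fracs[kind])
            rows.append(row)

    # pure shrub endmember spectra (>= 10 per season)
    rng_em = np.random.default_rng(ss_endmember)
    em_lib = SpectralLibrary()
    for season in config.seasons:
        for i in range(config.n_endmembers):
            em_seed = int(rng_em.integers(0, 2**31 - 1))
            s = generate_endmember(DEFAULT_ENDMEMBERS["shrub"], season,
                                   seed=em_seed, grid=config.grid, jitter=0.04)
            refl = np.clip(
                s.reflectance + rng_em.normal(0.0, config.noise_sd, size=len(config.grid)),
                0.0, 1.0)
            em_lib.add(Spectrum(
                grid=config.grid, reflectance=refl,
                sample_id=f"EM{i:02d}_{season}", quadrat_id=f"EM{i:02d}",
                season=season, replicate=1))

    patches = _shrub_patches(shrub, positions, config.spacing_m)
    return SyntheticScene(config=config, quadrats=pd.DataFrame(rows),
                          library=lib, endmember_library=em_lib, patches=patches)


def _shrub_patches(shrub: np.ndarray, positions: np.ndarray,
                   spacing: float) -> list[tuple[float, float]]:
    """Canopy intervals along the line: one patch per shrubby quadrat,
    centred on the quadrat, length proportional to its shrub fraction."""
    patches = []
    for frac, pos in zip(shrub, positions):
        if frac > 0:
            half = 0.5 * frac * spacing
            patches.append((pos - half, pos + half))
    return patches


def simulate_lit(scene: SyntheticScene) -> LITSummary:
    """Line-intercept summary: overlapping patches merged before summation."""
    length = scene.config.length_m
    intervals = []
    for lo, hi in sorted(scene.patches):
        lo, hi = max(lo, 0.0), min(hi, length)
        if hi <= lo:
            continue
        if intervals and lo <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], hi)
        else:
            intervals.append([lo, hi])
    covered = sum(hi - lo for lo, hi in intervals)
    n = len(scene.patches)
    return LITSummary(cover_pct=100.0 * covered / length,
                      density_per_m=n / length,
                      n_patches=n, total_length_m=covered)


def write_scene(scene: SyntheticScene, outdir) -> dict[str, str]:
    """Write the quadrat table and both spectral libraries as CSV."""
    from pathlib import Path
    from .spectra import write_spectral_library
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    qpath = outdir / "quadrats.csv"
    scene.quadrats.to_csv(qpath, index=False, float_format="%.6g")
    paths["quadrats"] = str(qpath)
    paths["library"] = str(write_spectral_library(scene.library, outdir / "library.csv"))
    paths["endmembers"] = str(
        write_spectral_library(scene.endmember_library, outdir / "endmembers.csv"))
    return paths
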