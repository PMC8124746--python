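"""End-to-end orchestration: scene -> preprocessing -> grouping -> statistics.

The pipeline mirrors the field-analysis workflow: load or generate the
transect data, average replicates and mask the water windows, screen
biophysical outliers and summarise seasonal change, build shrub-cover
groups from spectral clustering, scan wavelengths with Spearman
correlation, compute separability profiles and ensemble regions between
the shrub-free group and every other group, resample to broadband sensor
bands, and compare groups per band with ANOVA plus Tukey HSD, ending in
the minimum-detectable-cover summary.  Every stage writes its CSV so
stages can be rerun standalone; a JSON manifest records config, seed and
versions.  All randomness flows from the single config seed, so a rerun
reproduces every CSV byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biophys import remove_outliers, seasonal_difference, seasonal_summary, compare_lit_quadrat
from .broadband import landsat8_like, resample_library, sentinel2_like
from .correlation import significant_regions, spearman_profile
from .groups import (CoverGroupScheme, build_cover_scheme, cluster_spectra,
                     optimal_cluster_count, select_balanced_scheme)
from .group_stats import (anova_by_band, min_detectable_cover,
                          pair_separation_counts, tukey_by_band)
from .separability import ensemble_regions, regions_table, separability_profile
from .spectra import (MaskRegions, SEASONS, SpectralLibrary, average_replicates,
                      library_matrix, mask_library, read_spectral_library)
from .synth import TransectConfig, generate_scene, simulate_lit, write_scene

log = logging.getLogger("shrubspec")

BAND_SETS = {"landsat8_like": landsat8_like, "sentinel2_like": sentinel2_like}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Full-run configuration; ``seed`` drives all randomness."""

    out_dir: str = "results"
    seed: int = 0
    # input: either paths to CSVs or synthetic-scene parameters
    library_path: str | None = None
    quadrat_path: str | None = None
    endmember_path: str | None = None
    scene: dict = field(default_factory=dict)   # TransectConfig overrides
    mask_regions: list = field(default_factory=lambda: [list(r) for r in
                                                        ((1350, 1430), (1750, 1980), (2330, 2500))])
    cluster_methods: tuple = ("kmeans", "ward")
    k_range: tuple = (2, 15)
    correlation_alpha: float = 0.05
    min_region_width_nm: float = 10.0
    td_fallback: bool = True
    band_sets: tuple = ("landsat8_like", "sentinel2_like")
    sig_levels: tuple = (0.05, 0.1)
    outlier_k: float = 3.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dict.

    Any stage failure raises :class:`StageError` naming the stage after
    writing a partial manifest to the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {"shrubspec": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "started_unix": time.time(),
        "stages": {},
        "outputs": {},
    }

    def write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "load"
    try:
        if config.library_path:
            lib = read_spectral_library(config.library_path)
            quadrats = pd.read_csv(config.quadrat_path) if config.quadrat_path else None
            em_lib = (read_spectral_library(config.endmember_path)
                      if config.endmember_path else None)
            lit = None
            seasons = sorted({s.season for s in lib}, key=SEASONS.index)
        else:
            scene_cfg = TransectConfig(seed=config.seed, **{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in config.scene.items()})
            scene = generate_scene(scene_cfg)
            paths = write_scene(scene, out / "scene")
            manifest["outputs"].update(paths)
            lib, quadrats, em_lib = scene.library, scene.quadrats, scene.endmember_library
            lit = simulate_lit(scene)
            seasons = list(scene_cfg.seasons)
        manifest["stages"][stage] = "ok"

        stage = "preprocess"
        log.info("[preprocess] masking water windows and averaging replicates")
        regions = MaskRegions(tuple(tuple(r) for r in config.mask_regions))
        lib_mean = mask_library(average_replicates(lib), regions)
        em_mean = mask_library(em_lib, regions) if em_lib is not None else None
        manifest["stages"][stage] = "ok"

        stage = "biophys"
        results: dict[str, pd.DataFrame] = {}
        if quadrats is not None:
            # the 3-SD screen targets the visually estimated covers and PAI,
            # the variables vulnerable to quadrat-shifting noise
            screen_vars = [c for c in quadrats.columns
                           if c.startswith("cover_pct_") or c == "pai"]
            variables = screen_vars + [c for c in ("soil_moisture",)
                                       if c in quadrats.columns]
            clean, removal_log = remove_outliers(quadrats, screen_vars,
                                                 k=config.outlier_k)
            results["outlier_log"] = removal_log
            results["seasonal_summary"] = seasonal_summary(clean, variables)
            if set(SEASONS) <= set(clean["season"].unique()):
                _, results["seasonal_change"] = seasonal_difference(clean, variables)
            if lit is not None and "spring" in seasons:
                results["lit_comparison"] = compare_lit_quadrat(
                    lit.cover_pct, clean, "spring")
            quadrats = clean
        manifest["stages"][stage] = "ok"

        stage = "cover_groups"
        schemes: dict[str, object] = {}
        scheme_rows = []
        cover_col = "cover_pct_shrub"
        for season in seasons:
            qsub = quadrats[quadrats["season"] == season]
            cover_map = dict(zip(qsub["quadrat_id"], qsub[cover_col].astype(float)))
            season_lib = lib_mean.subset(season=season)
            inter_ids = [s.quadrat_id for s in sorted(season_lib, key=lambda s: s.key)
                         if 0 < cover_map.get(s.quadrat_id, 0) < 100]
            zero_ids = [qid for qid, c in cover_map.items() if c == 0]
            n_em = len(em_mean.subset(season=season)) if em_mean is not None else 0
            if not inter_ids:
                # shrub-free transect: zeros plus the endmember set only
                schemes[season] = CoverGroupScheme(
                    breakpoints=(), group_of={qid: 1 for qid in zero_ids},
                    counts=(len(zero_ids), n_em), method="degenerate")
                scheme_rows.append({"season": season, "group": 1, "low_pct": 0.0,
                                    "high_pct": 0.0, "count": len(zero_ids),
                                    "method": "degenerate"})
                scheme_rows.append({"season": season, "group": 2, "low_pct": 0.0,
                                    "high_pct": 100.0, "count": n_em,
                                    "method": "degenerate"})
                continue
            X, _, keys = library_matrix(season_lib.subset(quadrat_ids=inter_ids))
            covers = np.array([cover_map[k[0]] for k in keys])
            candidates = []
            for method in config.cluster_methods:
                k_opt, votes = optimal_cluster_count(
                    X, method=method, k_range=tuple(config.k_range), seed=config.seed)
                res = cluster_spectra(X, k_opt, method=method, seed=config.seed)
                res.index_votes = votes
                candidates.append(build_cover_scheme(
                    res, covers, [k[0] for k in keys], n_em, zero_ids))
            scheme = select_balanced_scheme(candidates)
            schemes[season] = scheme
            for g in range(1, scheme.n_groups + 1):
                lo = 0.0 if g == 1 else (0.0 if g == 2 else scheme.breakpoints[g - 3])
                hi = (0.0 if g == 1 else
                      scheme.breakpoints[g - 2] if g - 2 < len(scheme.breakpoints)
                      else 100.0)
                scheme_rows.append({"season": season, "group": g,
                                    "low_pct": lo, "high_pct": hi,
                                    "count": scheme.counts[g - 1],
                                    "method": scheme.method})
        results["cover_schemes"] = pd.DataFrame(scheme_rows)
        manifest["stages"][stage] = "ok"

        stage = "correlation_scan"
        corr_rows, corr_region_rows = [], []
        for season in seasons:
            season_lib = lib_mean.subset(season=season)
            X, wl, keys = library_matrix(season_lib)
            qsub = quadrats[quadrats["season"] == season]
            cover_map = dict(zip(qsub["quadrat_id"], qsub[cover_col].astype(float)))
            cover = np.array([cover_map.get(k[0], np.nan) for k in keys])
            ok = np.isfinite(cover)
            if np.ptp(cover[ok]) == 0:
                log.warning("[correlation_scan] %s: cover constant, scan skipped", season)
                continue
            prof = spearman_profile(X[ok], cover[ok], wl, alpha=config.correlation_alpha)
            prof.insert(0, "season", season)
            corr_rows.append(prof)
            reg = significant_regions(prof)
            reg.insert(0, "season", season)
            corr_region_rows.append(reg)
        if corr_rows:
            results["correlation_profile"] = pd.concat(corr_rows, ignore_index=True)
            results["correlation_regions"] = pd.concat(
                [r for r in corr_region_rows if len(r)] or corr_region_rows[:1],
                ignore_index=True)
        manifest["stages"][stage] = "ok"

        stage = "separability"
        sep_rows, sep_region_rows = [], []
        for season in seasons:
            scheme = schemes[season]
            season_lib = lib_mean.subset(season=season)
            by_group: dict[int, list] = {}
            for s in season_lib:
                g = scheme.group_of.get(s.quadrat_id)
                if g is not None:
                    by_group.setdefault(g, []).append(s)
            if em_mean is not None:
                by_group.setdefault(scheme.endmember_group, []).extend(
                    em_mean.subset(season=season))
            base = by_group.get(1, [])
            if len(base) < 2:
                continue
            base_lib = SpectralLibrary(base)
            for g in sorted(by_group):
                if g == 1 or len(by_group[g]) < 2:
                    continue
                prof = separability_profile(base_lib, SpectralLibrary(by_group[g]),
                                            pair=(1, g), season=season)
                prof.insert(0, "season", season)
                prof.insert(1, "group_pair", f"1-{g}")
                sep_rows.append(prof)
                regs = regions_table(ensemble_regions(
                    prof, min_width_nm=config.min_region_width_nm,
                    td_fallback=config.td_fallback), season)
                regs.insert(1, "group_pair", f"1-{g}")
                sep_region_rows.append(regs)
        if sep_rows:
            results["separability_profile"] = pd.concat(sep_rows, ignore_index=True)
            nonempty = [r for r in sep_region_rows if len(r)]
            results["separability_regions"] = (
                pd.concat(nonempty, ignore_index=True) if nonempty
                else sep_region_rows[0])
        manifest["stages"][stage] = "ok"

        stage = "broadband"
        band_rows = []
        for name in config.band_sets:
            bset = BAND_SETS[name]()
            for src_lib in (lib_mean, em_mean):
                if src_lib is None:
                    continue
                bv = resample_library(src_lib, bset)
                bv.insert(0, "sensor", name)
                band_rows.append(bv)
        band_values = pd.concat(band_rows, ignore_index=True)
        results["band_values"] = band_values
        manifest["stages"][stage] = "ok"

        stage = "group_stats"
        stat_rows, tukey_rows, summary_rows, count_rows = [], [], [], []
        for name in config.band_sets:
            for season in seasons:
                scheme = schemes[season]
                bv = band_values[(band_values["sensor"] == name)
                                 & (band_values["season"] == season)].copy()
                em_ids = ({s.quadrat_id for s in em_mean.subset(season=season)}
                          if em_mean is not None else set())
                bv["group"] = [
                    scheme.endmember_group if q in em_ids
                    else scheme.group_of.get(q, np.nan)
                    for q in bv["quadrat_id"]]
                bv = bv.dropna(subset=["group"])
                bv["group"] = bv["group"].astype(int)
                an = anova_by_band(bv)
                an.insert(0, "sensor", name)
                stat_rows.append(an)
                tk = tukey_by_band(bv, sig_levels=tuple(config.sig_levels))
                tk.insert(0, "sensor", name)
                tukey_rows.append(tk)
                group_cover = {}
                for g in range(2, scheme.n_groups):
                    group_cover[g] = scheme.breakpoints[g - 2]
                group_cover[scheme.endmember_group] = 100.0
                md = min_detectable_cover(tk, group_cover,
                                          sig_levels=tuple(config.sig_levels))
                md.insert(0, "sensor", name)
                summary_rows.append(md)
                pc = pair_separation_counts(tk)
                pc.insert(0, "sensor", name)
                count_rows.append(pc)
        results["anova"] = pd.concat(stat_rows, ignore_index=True)
        results["tukey"] = pd.concat(tukey_rows, ignore_index=True)
        results["min_detectable"] = pd.concat(summary_rows, ignore_index=True)
        results["band_importance"] = pd.concat(count_rows, ignore_index=True)
        manifest["stages"][stage] = "ok"

        stage = "write"
        for key, df in results.items():
            path = out / f"{key}.csv"
            df.to_csv(path, index=False, float_format="%.8g")
            manifest["outputs"][key] = str(path)
        manifest["finished_unix"] = time.time()
        manifest["stages"][stage] = "ok"
        write_manifest()
        return manifest
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        write_manifest()
        raise StageError(stage, exc) from exc
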