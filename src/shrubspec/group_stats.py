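"""Per-band group comparison: one-way ANOVA, Tukey HSD, detectability summary.

Input is a long band-value table (one row per sample, season and band)
joined with a cover-group id.  For every season and band a classical
one-way ANOVA runs across the groups, followed by a Tukey-Kramer HSD
post-hoc test (harmonic-mean correction for unbalanced groups) with
significance flagged at adjusted p < 0.05 and < 0.1.  The detectability
summary reports, per season and threshold, the lowest-cover group whose
pair with the shrub-free group is significant in at least one band,
together with the supporting bands, and tallies the number of separable
pairs per band.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "anova_by_band",
    "tukey_by_band",
    "min_detectable_cover",
    "pair_separation_counts",
]

SIG_LEVELS = (0.05, 0.1)


def _sig_col(level: float) -> str:
    return f"sig_{int(round(level * 100)):02d}"


def _valid_groups(sub: pd.DataFrame, group_col: str) -> pd.DataFrame:
    sizes = sub.groupby(group_col)["value"].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with <2 members: {small}", stacklevel=3)
        sub = sub[~sub[group_col].isin(small)]
    return sub


def anova_by_band(band_values: pd.DataFrame,
                  group_col: str = "group") -> pd.DataFrame:
    """One-way ANOVA per (season, band).  Returns (season, band, F, p, df1, df2)."""
    rows = []
    for (season, band), sub in band_values.groupby(["season", "band"], sort=False):
        sub = _valid_groups(sub.dropna(subset=["value"]), group_col)
        samples = [g["value"].to_numpy(float)
                   for _, g in sub.groupby(group_col, sort=True)]
        if len(samples) < 2:
            continue
        n = sum(len(s) for s in samples)
        grand = np.concatenate(samples).mean()
        ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
        df1, df2 = len(samples) - 1, n - len(samples)
        if ssw == 0:
            F = 0.0 if ssb == 0 else np.inf
        else:
            F = (ssb / df1) / (ssw / df2)
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        rows.append({"season": season, "band": band, "F": float(F), "p": p,
                     "df1": df1, "df2": df2})
    return pd.DataFrame(rows)


def tukey_by_band(band_values: pd.DataFrame,
                  group_col: str = "group",
                  sig_levels: tuple[float, ...] = SIG_LEVELS) -> pd.DataFrame:
    """Tukey-Kramer adjusted p-values for every group pair, per season and band.

    Returns a long table (season, band, group_a, group_b, meandiff, p_adj,
    sig_05, sig_10); the pair count per (season, band) is k(k-1)/2.
    """
    rows = []
    for (season, band), sub in band_values.groupby(["season", "band"], sort=False):
        sub = _valid_groups(sub.dropna(subset=["value"]), group_col)
        if sub[group_col].nunique() < 2:
            continue
        res = pairwise_tukeyhsd(sub["value"].to_numpy(float),
                                sub[group_col].to_numpy(), alpha=0.05)
        pairs = [(row[0], row[1]) for row in res._results_table.data[1:]]
        for (a, b), diff, p in zip(pairs, res.meandiffs, res.pvalues):
            row = {"season": season, "band": band,
                   "group_a": a, "group_b": b,
                   "meandiff": float(diff), "p_adj": float(p)}
            for lvl in sig_levels:
                row[_sig_col(lvl)] = bool(p < lvl)
            rows.append(row)
    return pd.DataFrame(rows)


def pair_separation_counts(tukey: pd.DataFrame, level: float = 0.05) -> pd.DataFrame:
    """Per season and band: the number of group pairs separable at ``level``."""
    col = _sig_col(level)
    out = (tukey.groupby(["season", "band"])[col].sum()
           .rename("n_separable_pairs").reset_index())
    return out


def min_detectable_cover(tukey: pd.DataFrame, group_cover: dict,
                         baseline_group=1,
                         sig_levels: tuple[float, ...] = SIG_LEVELS) -> pd.DataFrame:
    """Lowest-cover group distinguishable from the shrub-free baseline.

    ``group_cover`` maps group id -> a representative cover percent (upper
    bound of the group's interval; the endmember group is ~100).  For each
    season and significance level the lowest-cover group (other than the
    baseline) whose pair with the baseline is significant in >= 1 band is
    reported with the supporting bands; seasons with no such group report
    'none detectable'.
    """
    rows = []
    for season, sub in tukey.groupby("season", sort=False):
        base = sub[(sub["group_a"] == baseline_group) |
                   (sub["group_b"] == baseline_group)]
        for lvl in sig_levels:
            col = _sig_col(lvl)
            found = None
            for g in sorted((g for g in group_cover if g != baseline_group),
                            key=lambda g: group_cover[g]):
                hits = base[((base["group_a"] == g) | (base["group_b"] == g))
                            & base[col]]
                if len(hits):
                    found = (g, sorted(hits["band"].unique()))
                    break
            rows.append({
                "season": season, "level": lvl,
                "min_detectable_group": found[0] if found else None,
                "min_detectable_cover_pct": group_cover[found[0]] if found else np.nan,
                "supporting_bands": ";".join(found[1]) if found else "none detectable",
            })
    return pd.DataFrame(rows)
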