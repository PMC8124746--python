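"""Tabular operations on per-quadrat biophysical measurements.

Works on the long-format quadrat table produced by the scene generator
(or read from CSV): one row per (quadrat_id, season) with cover
percentages, PAI, soil moisture, and biomass columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "remove_outliers",
    "seasonal_difference",
    "seasonal_summary",
    "compare_lit_quadrat",
]

_KEY = ["quadrat_id", "season"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in _KEY if c not in table.columns]
    if missing:
        raise ValueError(f"quadrat table lacks key columns {missing}")
    if table.duplicated(_KEY).any():
        raise ValueError("(quadrat_id, season) keys must be unique")


def remove_outliers(table: pd.DataFrame, variables: list[str],
                    k: float = 3.0, per_season: bool = True,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass k-standard-deviation screen.

    Per variable (and per season, by default) the mean and sample SD are
    computed once over all records; records with ``|x - mean| > k * SD``
    are dropped.  Non-iterative by design: one screening pass, not
    repeated trimming.  Returns (clean table, removal log).
    """
    _check_table(table)
    drop: set = set()
    log_rows = []
    group_cols = ["season"] if per_season else []
    groups = table.groupby(group_cols) if group_cols else [((), table)]
    for gkey, sub in groups:
        for var in variables:
            x = sub[var].astype(float)
            mean, sd = x.mean(), x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            bad = sub.index[(x - mean).abs() > k * sd]
            for i in bad:
                drop.add(i)
                log_rows.append({
                    "quadrat_id": table.loc[i, "quadrat_id"],
                    "season": table.loc[i, "season"],
                    "variable": var, "value": table.loc[i, var],
                    "mean": mean, "sd": sd, "k": k,
                })
    clean = table.drop(index=sorted(drop)).reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["quadrat_id", "season", "variable",
                                          "value", "mean", "sd", "k"])
    return clean, log


def seasonal_difference(table: pd.DataFrame, variables: list[str],
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-quadrat seasonal deltas: summer-spring and fall-summer.

    Returns (difference table, direction summary).  The summary gives the
    fraction of quadrats with increase / stable / decrease per variable
    and transition.  Quadrats missing a season are skipped (logged via the
    table's ``n_skipped`` attr).
    """
    _check_table(table)
    wide = table.pivot(index="quadrat_id", columns="season", values=variables)
    diffs = []
    transitions = [("summer_minus_spring", "summer", "spring"),
                   ("fall_minus_summer", "fall", "summer")]
    n_skipped = 0
    for qid, row in wide.iterrows():
        rec: dict = {"quadrat_id": qid}
        ok = True
        for name, s2, s1 in transitions:
            for var in variables:
                a, b = row.get((var, s2), np.nan), row.get((var, s1), np.nan)
                if pd.isna(a) or pd.isna(b):
                    ok = False
                rec[f"{var}__{name}"] = a - b
        if ok:
            diffs.append(rec)
        else:
            n_skipped += 1
    diff = pd.DataFrame(diffs)
    summary_rows = []
    for name, _, _ in transitions:
        for var in variables:
            col = diff[f"{var}__{name}"] if len(diff) else pd.Series(dtype=float)
            n = max(len(col), 1)
            summary_rows.append({
                "variable": var, "transition": name,
                "mean_delta": col.mean() if len(col) else np.nan,
                "frac_increase": (col > 0).sum() / n,
                "frac_stable": (col == 0).sum() / n,
                "frac_decrease": (col < 0).sum() / n,
            })
    summary = pd.DataFrame(summary_rows)
    diff.attrs["n_skipped"] = n_skipped
    return diff, summary


def seasonal_summary(table: pd.DataFrame,
                     variables: list[str] | None = None) -> pd.DataFrame:
    """Per-season mean, sample SD (n-1), min and max for each variable."""
    _check_table(table)
    if len(table) == 0:
        raise ValueError("empty table")
    if variables is None:
        variables = [c for c in table.columns
                     if c not in _KEY and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for season, sub in table.groupby("season", sort=False):
        for var in variables:
            x = sub[var].astype(float)
            rows.append({
                "season": season, "variable": var,
                "mean": x.mean(),
                "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                "min": x.min(), "max": x.max(), "n": len(x),
            })
    return pd.DataFrame(rows)


def compare_lit_quadrat(lit_cover_pct: float, table: pd.DataFrame,
                        season: str,
                        cover_column: str = "cover_pct_shrub") -> pd.DataFrame:
    """Side-by-side shrub cover: line-intercept versus quadrat visual mean.

    Positive difference means the line-intercept method reports more
    cover than the averaged visual quadrat estimate.
    """
    _check_table(table)
    sub = table[table["season"] == season]
    if len(sub) == 0:
        raise ValueError(f"season {season!r} absent from table")
    qmean = float(sub[cover_column].astype(float).mean())
    return pd.DataFrame([{
        "season": season,
        "lit_cover_pct": lit_cover_pct,
        "quadrat_mean_cover_pct": qmean,
        "difference_pct": lit_cover_pct - qmean,
    }])
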