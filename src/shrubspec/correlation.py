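"""Wavelength-wise Spearman rank correlation against shrub cover.

Each valid wavelength's reflectance across the transect quadrats is rank
correlated with visually estimated shrub cover.  Visual cover is quantized
and hence heavily tied, so ranks are averaged over ties and the
tie-corrected coefficient (Pearson correlation of the ranks) is used.
Significance at each wavelength is a two-tailed test against the critical
value of Spearman's r at the transect sample size; no correction across
wavelengths is applied by default, matching a per-wavelength screening
read of the correlogram (a Bonferroni option is available).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_critical",
    "spearman_profile",
    "significant_regions",
]


def spearman_critical(n: int, alpha: float = 0.05, method: str = "auto",
                      n_mc: int = 200_000, seed: int = 0) -> float:
    """Two-tailed critical value of Spearman's r at sample size ``n``.

    For n > 30 the Student-t approximation ``r = t / sqrt(n - 2 + t^2)``
    with ``t`` the two-tailed quantile at ``n - 2`` degrees of freedom.
    For n <= 10 the exact permutation null is enumerated exhaustively;
    for 10 < n <= 30 it is sampled by seeded Monte Carlo.  The critical
    value is the smallest attainable r with ``P(|R| >= r) <= alpha``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if method == "auto":
        method = "t" if n > 30 else ("exact" if n <= 10 else "mc")
    if method == "t":
        t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
        return float(t / math.sqrt(n - 2 + t * t))
    denom = n * (n * n - 1)
    if method == "exact":
        import itertools
        base = np.arange(1, n + 1)
        counts: dict[int, int] = {}
        for perm in itertools.permutations(range(1, n + 1)):
            d2 = int(sum((a - b) ** 2 for a, b in zip(base, perm)))
            counts[d2] = counts.get(d2, 0) + 1
        total = math.factorial(n)
        rvals = sorted({abs(1.0 - 6.0 * d2 / denom) for d2 in counts}, reverse=True)
        tail = 0.0
        crit = None
        for r in rvals:
            tail = sum(c for d2, c in counts.items()
                       if abs(1.0 - 6.0 * d2 / denom) >= r - 1e-12) / total
            if tail <= alpha:
                crit = r
            else:
                break
        if crit is None:
            raise ValueError("alpha unattainably small for this n")
        return float(crit)
    if method == "mc":
        rng = np.random.default_rng(seed)
        base = np.arange(1, n + 1, dtype=float)
        perms = np.argsort(rng.random((n_mc, n)), axis=1) + 1.0
        d2 = ((perms - base) ** 2).sum(axis=1)
        rs = np.sort(np.abs(1.0 - 6.0 * d2 / denom))
        # smallest attained value whose estimated tail P(|R| >= v) <= alpha
        left = np.searchsorted(rs, rs, side="left")
        ok = (n_mc - left) <= alpha * n_mc
        if not ok.any():
            raise ValueError("alpha unattainably small for this n")
        return float(rs[ok].min())
    raise ValueError(f"unknown method {method!r}")


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def spearman_profile(X: np.ndarray, cover: np.ndarray,
                     wavelengths: np.ndarray | None = None,
                     alpha: float = 0.05,
                     bonferroni: bool = False) -> pd.DataFrame:
    """Spearman r between each wavelength column of ``X`` and ``cover``.

    ``X`` is (n_quadrats, n_wavelengths).  Returns a DataFrame
    (wavelength_nm, r, significant, sign) with ``n``, ``alpha`` and
    ``r_critical`` (full precision and 2-dp display value) in ``attrs``.
    """
    X = np.asarray(X, dtype=float)
    cover = np.asarray(cover, dtype=float)
    n = len(cover)
    if n < 4:
        raise ValueError("need at least 4 quadrats")
    if X.shape[0] != n:
        raise ValueError("X rows must match cover length")
    if np.ptp(cover) == 0:
        raise ValueError("cover is constant; rank correlation undefined")

    eff_alpha = alpha / X.shape[1] if bonferroni else alpha
    rx = _rank(X, axis=0)
    ry = _rank(cover)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    num = rx.T @ ry
    den = np.sqrt((rx ** 2).sum(axis=0) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)

    r_crit = spearman_critical(n, eff_alpha)
    wl = wavelengths if wavelengths is not None else np.arange(X.shape[1], dtype=float)
    df = pd.DataFrame({
        "wavelength_nm": wl,
        "r": r,
        "significant": np.abs(r) >= r_crit,
        "sign": np.where(r >= 0, "+", "-"),
    })
    df.loc[~np.isfinite(r), "significant"] = False
    df.attrs.update({"n": n, "alpha": alpha, "r_critical": r_crit,
                     "r_critical_2dp": round(r_crit, 2)})
    return df


def significant_regions(profile: pd.DataFrame, step_nm: float = 1.0) -> pd.DataFrame:
    """Maximal contiguous runs of significant wavelengths sharing one sign.

    Runs break at masked gaps in the wavelength column and at sign flips;
    no minimum-width filter is applied.  Each run is reported with its
    bounds, sign, and the peak |r| and its wavelength.
    """
    wl = profile["wavelength_nm"].to_numpy(float)
    r = profile["r"].to_numpy(float)
    sig = profile["significant"].to_numpy(bool)
    sign = np.sign(r)
    rows = []
    start = None
    for i in range(len(wl) + 1):
        end_of_run = (
            i == len(wl)
            or not sig[i]
            or (start is not None and sign[i] != sign[start])
            or (i > 0 and abs(wl[i] - wl[i - 1] - step_nm) > 1e-6)
        )
        if start is not None and end_of_run:
            seg = slice(start, i)
            peak = start + int(np.argmax(np.abs(r[seg])))
            rows.append({
                "low_nm": wl[start], "high_nm": wl[i - 1],
                "sign": "+" if sign[start] > 0 else "-",
                "peak_abs_r": abs(r[peak]), "peak_wavelength_nm": wl[peak],
            })
            start = None
        if i < len(wl) and sig[i] and start is None:
            start = i
    return pd.DataFrame(rows, columns=["low_nm", "high_nm", "sign",
                                       "peak_abs_r", "peak_wavelength_nm"])
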