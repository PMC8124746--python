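"""Univariate spectral separability between two shrub-cover groups.

At each valid wavelength the two groups are summarised by their sample
mean and standard deviation, and five classical class-separability
statistics for univariate normal distributions are evaluated:

* ``M``  — mean difference over summed SDs, ``|mu1-mu2| / (sd1+sd2)``;
  values above 1 indicate separation, with no upper bound.
* ``B``  — Bhattacharyya distance,
  ``(mu1-mu2)^2 / (4 (s1^2+s2^2)) + 0.5 ln[((s1^2+s2^2)/2) / (s1 s2)]``;
  unbounded above.
* ``D``  — divergence (symmetric Kullback-Leibler),
  ``0.5 (s1^2/s2^2 + s2^2/s1^2 - 2) + 0.5 (mu1-mu2)^2 (1/s1^2 + 1/s2^2)``.
* ``TD`` — transformed divergence ``2 (1 - exp(-D/8))``, saturating on [0, 2).
* ``JM`` — Jeffries-Matusita distance ``2 (1 - exp(-B))``, also on [0, 2).

TD and JM admit fixed thresholds: at or above 1.8 separation is *good*,
between 1.5 and 1.8 *moderate*, at or below 1.5 *poor*.  Wavelength
regions where both TD and JM are good (the ensemble rule) are the
reported shrub-sensitive regions; runs narrower than 10 nm are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectralLibrary, library_matrix

__all__ = [
    "METRICS",
    "SpectralRegion",
    "pairwise_metrics",
    "group_moments",
    "separability_profile",
    "classify_value",
    "ensemble_regions",
    "normality_diagnostic",
]

METRICS = ("M", "B", "D", "TD", "JM")

GOOD_THRESHOLD = 1.8
MODERATE_THRESHOLD = 1.5


class ZeroVarianceError(ValueError):
    """A group has zero spectral variance at one or more wavelengths."""


@dataclass(frozen=True)
class SpectralRegion:
    low_nm: float
    high_nm: float
    klass: str              # "good" or "moderate"
    width_nm: float
    metric_basis: str = "TD+JM"   # "TD" when the fall-season fallback fired


def pairwise_metrics(mu1, sd1, mu2, sd2) -> dict[str, np.ndarray]:
    """All five separability statistics, vectorised over wavelengths.

    Raises :class:`ZeroVarianceError` if either SD is zero anywhere; a
    caller that wants to proceed on degenerate synthetic data must apply
    an explicit variance floor first.
    """
    mu1, sd1 = np.atleast_1d(np.asarray(mu1, float)), np.atleast_1d(np.asarray(sd1, float))
    mu2, sd2 = np.atleast_1d(np.asarray(mu2, float)), np.atleast_1d(np.asarray(sd2, float))
    for sd in (sd1, sd2):
        if np.any(sd <= 0):
            idx = np.where(sd <= 0)[0]
            raise ZeroVarianceError(
                f"zero standard deviation at wavelength indices {idx[:10].tolist()}")
    dmu = mu1 - mu2
    v1, v2 = sd1 ** 2, sd2 ** 2
    M = np.abs(dmu) / (sd1 + sd2)
    B = dmu ** 2 / (4.0 * (v1 + v2)) + 0.5 * np.log(((v1 + v2) / 2.0) / (sd1 * sd2))
    D = 0.5 * (v1 / v2 + v2 / v1 - 2.0) + 0.5 * dmu ** 2 * (1.0 / v1 + 1.0 / v2)
    TD = 2.0 * (1.0 - np.exp(-D / 8.0))
    JM = 2.0 * (1.0 - np.exp(-B))
    return {"M": M, "B": B, "D": D, "TD": TD, "JM": JM}


def group_moments(group: SpectralLibrary | np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray, int, np.ndarray | None]:
    """Per-wavelength mean and sample SD (n-1) of a group of spectra.

    Accepts a library (moments over its shared valid wavelengths) or a
    plain (n_samples, n_wavelengths) matrix.  Returns (mu, sd, n,
    wavelengths-or-None).
    """
    if isinstance(group, SpectralLibrary):
        X, wl, _ = library_matrix(group)
    else:
        X, wl = np.asarray(group, dtype=float), None
    if X.shape[0] < 2:
        raise ValueError("need at least 2 spectra per group")
    return X.mean(axis=0), X.std(axis=0, ddof=1), X.shape[0], wl


def separability_profile(group_a: SpectralLibrary | np.ndarray,
                         group_b: SpectralLibrary | np.ndarray,
                         wavelengths: np.ndarray | None = None,
                         variance_floor: float | None = None,
                         pair: tuple = ("a", "b"),
                         season: str = "") -> pd.DataFrame:
    """Five-metric profile between two spectra groups at every valid wavelength.

    Returns a DataFrame (wavelength_nm, M, B, D, TD, JM plus class_TD,
    class_JM, class_M) with the group pair and sizes in ``attrs``.
    ``variance_floor`` (default off) replaces SDs below the floor; without
    it a zero-variance wavelength raises.
    """
    mu1, sd1, n1, wl1 = group_moments(group_a)
    mu2, sd2, n2, wl2 = group_moments(group_b)
    if wl1 is not None and wl2 is not None:
        if len(wl1) != len(wl2) or not np.allclose(wl1, wl2):
            raise ValueError("groups do not share a wavelength grid/mask")
    wl = wl1 if wl1 is not None else wl2
    if wl is None:
        wl = wavelengths
    if wl is None:
        wl = np.arange(len(mu1), dtype=float)
    if len(mu1) != len(mu2):
        raise ValueError("groups do not share a wavelength grid/mask")
    if variance_floor is not None:
        sd1 = np.maximum(sd1, variance_floor)
        sd2 = np.maximum(sd2, variance_floor)
    m = pairwise_metrics(mu1, sd1, mu2, sd2)
    df = pd.DataFrame({"wavelength_nm": wl, **m})
    df["class_TD"] = [classify_value("TD", v) for v in m["TD"]]
    df["class_JM"] = [classify_value("JM", v) for v in m["JM"]]
    df["class_M"] = [classify_value("M", v) for v in m["M"]]
    df.attrs.update({"pair": pair, "season": season, "n_a": n1, "n_b": n2})
    return df


def classify_value(metric: str, value: float) -> str:
    """Threshold classification: good / moderate / poor.

    TD and JM: >= 1.8 good, (1.5, 1.8) moderate, <= 1.5 poor.
    M: > 1 good, else poor (no moderate class exists for M).
    """
    if not np.isfinite(value):
        raise ValueError(f"non-finite {metric} value")
    if metric in ("TD", "JM"):
        if value >= GOOD_THRESHOLD:
            return "good"
        if value > MODERATE_THRESHOLD:
            return "moderate"
        return "poor"
    if metric == "M":
        return "good" if value > 1.0 else "poor"
    raise ValueError(f"no threshold rule for metric {metric!r}")


def _runs(wl: np.ndarray, flag: np.ndarray, step: float) -> list[tuple[int, int]]:
    """Maximal index runs where flag holds, broken at wavelength gaps."""
    runs = []
    start = None
    for i in range(len(wl)):
        contiguous = i > 0 and abs(wl[i] - wl[i - 1] - step) < 1e-6
        if flag[i] and (start is None):
            start = i
        elif start is not None and (not flag[i] or not contiguous):
            runs.append((start, i - 1))
            start = i if flag[i] else None
    if start is not None:
        runs.append((start, len(wl) - 1))
    return runs


def ensemble_regions(profile: pd.DataFrame, min_width_nm: float = 10.0,
                     step_nm: float = 1.0,
                     td_fallback: bool = False) -> list[SpectralRegion]:
    """Contiguous shrub-sensitive wavelength regions under the TD+JM ensemble.

    Good regions: both TD and JM at or above 1.8.  Moderate regions: both
    above 1.5 and not already good.  Runs are broken at masked windows
    and dropped when narrower than ``min_width_nm``.  With
    ``td_fallback``, a season where the ensemble finds nothing is retried
    with TD alone and the output labelled accordingly (mirrors a
    senescent-season situation where JM saturates low).
    """
    wl = profile["wavelength_nm"].to_numpy(float)
    td, jm = profile["TD"].to_numpy(float), profile["JM"].to_numpy(float)

    def extract(good_flag: np.ndarray, mod_flag: np.ndarray, basis: str):
        regions = []
        for klass, flag in (("good", good_flag), ("moderate", mod_flag & ~good_flag)):
            for i0, i1 in _runs(wl, flag, step_nm):
                width = wl[i1] - wl[i0] + step_nm
                if width >= min_width_nm:
                    regions.append(SpectralRegion(wl[i0], wl[i1], klass, width, basis))
        return sorted(regions, key=lambda r: r.low_nm)

    regions = extract((td >= GOOD_THRESHOLD) & (jm >= GOOD_THRESHOLD),
                      (td > MODERATE_THRESHOLD) & (jm > MODERATE_THRESHOLD),
                      "TD+JM")
    if not regions and td_fallback:
        regions = extract(td >= GOOD_THRESHOLD, td > MODERATE_THRESHOLD, "TD")
    return regions


def regions_table(regions: list[SpectralRegion], season: str = "") -> pd.DataFrame:
    rows = [{"season": season, "low_nm": r.low_nm, "high_nm": r.high_nm,
             "width_nm": r.width_nm, "class": r.klass, "basis": r.metric_basis}
            for r in regions]
    return pd.DataFrame(rows, columns=["season", "low_nm", "high_nm",
                                       "width_nm", "class", "basis"])


def normality_diagnostic(group: SpectralLibrary | np.ndarray,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk test per wavelength; advisory only, never blocks.

    Returns a DataFrame (wavelength index or nm, p_value, passed, reason)
    with the pass fraction in ``attrs['pass_fraction']``.
    """
    if isinstance(group, SpectralLibrary):
        X, wl, _ = library_matrix(group)
    else:
        X, wl = np.asarray(group, dtype=float), None
    if X.shape[0] < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 samples")
    if wl is None:
        wl = np.arange(X.shape[1], dtype=float)
    pvals, passed, reasons = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.ptp(col) == 0:
                pvals.append(np.nan)
                passed.append(False)
                reasons.append("zero variance: test undefined")
                continue
            p = stats.shapiro(col).pvalue
            pvals.append(p)
            passed.append(bool(p > alpha))
            reasons.append("")
    df = pd.DataFrame({"wavelength_nm": wl, "p_value": pvals,
                       "passed": passed, "reason": reasons})
    df.attrs["pass_fraction"] = float(np.mean(passed))
    return df
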