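"""County-level ecological analyses of weight inquiries and bullying.

Askers are linked to county attributes (obesity prevalence, median income)
through their registration zip code.  The analyses reproduce four pieces:
the bullying fraction as a function of county obesity prevalence (looking
for a U-shape), the absolute-deviation-from-the-mean exposure transform,
self-classification accuracy in high- versus low-obesity counties, and the
direction of the income-bullying association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CurveBin",
    "link_counties",
    "bullying_fraction_curve",
    "fit_curve_quadratic",
    "abs_deviation_transform",
    "accuracy_by_county",
    "income_bullying_association",
    "odds_ratio_2x2",
]


@dataclass
class CurveBin:
    """One obesity-prevalence bin of the bullying-fraction curve."""

    lo: float
    hi: float
    n_askers: int
    n_bullying: int
    fraction: Optional[float]  # None when the bin is empty


def link_counties(
    records: pd.DataFrame,
    zip_to_county: pd.DataFrame,
    county_table: pd.DataFrame,
) -> pd.DataFrame:
    """Attach county attributes to asker records via zip code.

    ``zip_to_county`` has columns (zip, county_id); duplicated zips keep the
    first mapping (with a warning).  Unlinked records get ``linked=False``
    and NaN attributes; their count is logged, never an error.
    """
    zmap = zip_to_county.copy()
    zmap["zip"] = zmap["zip"].astype(str)
    dup = zmap["zip"].duplicated()
    if dup.any():
        log.warning("zip map contains %d duplicate zips; keeping first", dup.sum())
        zmap = zmap[~dup]
    out = records.copy()
    out["zip"] = out["zip"].astype(str)
    out = out.merge(zmap, on="zip", how="left", suffixes=("", "_map"))
    if "county_id_map" in out.columns:
        out["county_id"] = out.pop("county_id_map")
    out = out.merge(
        county_table[["county_id", "obesity_pct", "median_income"]],
        on="county_id",
        how="left",
    )
    out["linked"] = out["obesity_pct"].notna()
    n_unlinked = int((~out["linked"]).sum())
    if n_unlinked:
        log.warning("%d of %d records could not be linked to a county",
                    n_unlinked, len(out))
    return out


def bullying_fraction_curve(
    records: pd.DataFrame,
    n_bins: int = 10,
    by_term_class: bool = True,
) -> dict:
    """Per-bin bullying fraction over equal-width obesity-prevalence bins.

    ``records`` must be county-linked and carry ``bullying`` (bool) and
    ``obesity_pct``.  Returns ``{"overall": [CurveBin...], "low": ...,
    "high": ...}`` where the partition splits askers by inquired-term class
    (skinny/thin vs fat/obese).  Empty bins get fraction None.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be at least 3")
    linked = records[records.get("linked", True) == True]  # noqa: E712
    x = linked["obesity_pct"].to_numpy(float)
    if len(x) == 0:
        return {"overall": [], "low": [], "high": []}
    lo, hi = x.min(), x.max()
    if lo == hi:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)

    def curve(sub: pd.DataFrame) -> List[CurveBin]:
        xs = sub["obesity_pct"].to_numpy(float)
        # right-inclusive last bin so the max lands in the final bin
        idx = np.clip(np.digitize(xs, edges[1:-1]), 0, n_bins - 1)
        bins = []
        for b in range(n_bins):
            m = idx == b
            n = int(m.sum())
            k = int(sub.loc[m, "bullying"].sum())
            bins.append(
                CurveBin(
                    float(edges[b]), float(edges[b + 1]), n, k,
                    (k / n) if n else None,
                )
            )
        return bins

    out = {"overall": curve(linked)}
    if by_term_class:
        out["low"] = curve(linked[linked["term_class"] == "low"])
        out["high"] = curve(linked[linked["term_class"] == "high"])
    return out


def fit_curve_quadratic(bins: List[CurveBin]) -> dict:
    """Weighted quadratic fit of fraction on bin midpoints.

    Returns the polynomial coefficients and the curvature (second-derivative
    sign); positive curvature is the U-shape criterion.
    """
    pts = [(0.5 * (b.lo + b.hi), b.fraction, b.n_askers) for b in bins if b.fraction is not None]
    if len(pts) < 3:
        return {"curvature": float("nan"), "coefficients": None}
    x, y, w = map(np.asarray, zip(*pts))
    coefs = np.polyfit(x, y, 2, w=np.sqrt(w))
    return {"curvature": float(2.0 * coefs[0]), "coefficients": coefs.tolist()}


def abs_deviation_transform(values) -> np.ndarray:
    """|x - mean(x)| per county; shift-invariant exposure transform."""
    x = np.asarray(list(values), float)
    if x.size == 0:
        raise ValueError("need at least one value")
    return np.abs(x - x.mean())


def accuracy_by_county(
    records: pd.DataFrame,
    split: str = "median",
) -> pd.DataFrame:
    """Self-classification accuracy in high- vs low-obesity counties.

    Counties are split at the median (or mean) obesity prevalence of the
    linked records' counties; within each (gender x actual class) cell the
    congruence rates of the two groups are compared by a chi-squared test.
    Cells with an empty group are skipped with a log message.  Also reports,
    for normal-weight askers, the rate of high-term ("am I fat/obese?")
    inquiries in each county group — the body-image composition comparison.
    """
    linked = records[records.get("linked", True) == True].copy()  # noqa: E712
    if linked.empty:
        return pd.DataFrame()
    county_obs = linked.groupby("county_id")["obesity_pct"].first()
    cut = county_obs.median() if split == "median" else county_obs.mean()
    linked["high_county"] = linked["obesity_pct"] > cut

    rows = []
    for (gender, cls), sub in linked.groupby(["gender", "actual_class3"]):
        for outcome, col in (("congruent", "congruent"), ("asks_high_term", None)):
            if col is None:
                if cls != "normal":
                    continue
                y = (sub["term_class"] == "high").astype(int)
            else:
                y = sub[col].astype(int)
            tab = pd.crosstab(sub["high_county"], y)
            if tab.shape != (2, 2):
                log.info("skipping %s/%s/%s: a county group is empty or constant",
                         gender, cls, outcome)
                continue
            rate_low = y[~sub["high_county"]].mean()
            rate_high = y[sub["high_county"]].mean()
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            rows.append(
                {
                    "gender": gender,
                    "actual_class3": cls,
                    "outcome": outcome,
                    "n_low": int((~sub["high_county"]).sum()),
                    "n_high": int(sub["high_county"].sum()),
                    "rate_low": float(rate_low),
                    "rate_high": float(rate_high),
                    "chi2": float(chi2),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def odds_ratio_2x2(k1: int, n1: int, k2: int, n2: int) -> float:
    """Odds ratio of group 1 vs group 2 from event counts k out of n."""
    if min(n1 - k1, n2 - k2, k2) <= 0:
        return float("nan")
    return (k1 * (n2 - k2)) / ((n1 - k1) * k2)


def income_bullying_association(
    records: pd.DataFrame, n_quantiles: int = 4
) -> dict:
    """Direction and trend test of bullying odds versus county income.

    Fits a logistic model of the bullying flag on median income (per $10k)
    and runs a Cochran-Armitage trend test over income quantile groups.
    Returns the direction ('decreasing' means bullying odds fall as income
    rises), the logistic slope, and the trend statistic.  With a degenerate
    (single-valued) income the association is not evaluable.
    """
    linked = records[records.get("linked", True) == True]  # noqa: E712
    income = linked["median_income"].to_numpy(float)
    y = linked["bullying"].to_numpy(bool)
    if len(linked) == 0 or np.ptp(income) == 0:
        return {"evaluable": False}

    import statsmodels.api as sm

    X = sm.add_constant(income / 1e4)
    try:
        fit = sm.GLM(y.astype(float), X, family=sm.families.Binomial()).fit()
        slope = float(fit.params[1])
        slope_p = float(fit.pvalues[1])
    except Exception:
        slope, slope_p = float("nan"), float("nan")

    # Cochran-Armitage trend over income quantile groups with scores 0..g-1
    q = pd.qcut(income, n_quantiles, labels=False, duplicates="drop")
    groups = pd.DataFrame({"g": q, "y": y}).groupby("g")["y"].agg(["sum", "size"])
    scores = groups.index.to_numpy(float)
    k, n = groups["sum"].to_numpy(float), groups["size"].to_numpy(float)
    N, K = n.sum(), k.sum()
    pbar = K / N
    sbar = (scores * n).sum() / N
    num = (scores * (k - n * pbar)).sum()
    den = pbar * (1 - pbar) * ((scores - sbar) ** 2 * n).sum()
    if den > 0:
        z = num / np.sqrt(den)
        trend_p = float(2 * stats.norm.sf(abs(z)))
    else:
        z, trend_p = float("nan"), float("nan")

    return {
        "evaluable": True,
        "direction": "decreasing" if slope < 0 else "increasing",
        "logistic_slope_per_10k": slope,
        "logistic_p": slope_p,
        "trend_z": float(z),
        "trend_p": trend_p,
        "quantile_rates": (k / n).tolist(),
    }
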