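"""Stratified future-posting ratios with FDR control, and bullying tests.

The central statistic is the posting ratio: the probability that a user in
a stratum (defined by gender, actual weight class, and/or inquired-term
class) later posts to a topical category, divided by the same probability
for the entire pooled asker population.  The unit of analysis is the user
(posted at least once to the category), not the post.  Each ratio carries a
two-sided exact binomial p-value against the pooled rate; q-values are
Benjamini-Hochberg adjusted within a configurable family (per gender by
default).

Note one consequence of pooling: because stratum members are included in
the pooled denominator, a planted rate multiplier m on a stratum holding a
fraction f of the population is estimated as m / (1 + f(m-1)); the bias
vanishes as f -> 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Stratum",
    "PostingRatioResult",
    "posting_ratio",
    "bh_fdr",
    "attach_future_posts",
    "category_overexpression",
    "bullying_association",
]

STRATUM_AXES = ("gender", "actual_class3", "term_class")


@dataclass(frozen=True)
class Stratum:
    """A subset of askers: any combination of the three axes may be fixed."""

    gender: Optional[str] = None
    actual_class3: Optional[str] = None
    term_class: Optional[str] = None

    def label(self) -> str:
        parts = [
            f"{ax}={getattr(self, ax)}"
            for ax in STRATUM_AXES
            if getattr(self, ax) is not None
        ]
        return "&".join(parts) if parts else "all"

    def mask(self, records: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=records.index)
        for ax in STRATUM_AXES:
            v = getattr(self, ax)
            if v is not None:
                m &= records[ax] == v
        return m


@dataclass
class PostingRatioResult:
    """One stratum x category comparison against the pooled population."""

    stratum: str
    category: str
    n_stratum: int
    k_stratum: int
    n_all: int
    k_all: int
    ratio: float  # nan when not evaluable (k_all == 0)
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    evaluable: bool = True


def posting_ratio(
    k_stratum: int, n_stratum: int, k_all: int, n_all: int, category: str,
    stratum_label: str = "stratum",
) -> PostingRatioResult:
    """Posting ratio with a two-sided exact binomial p-value.

    ratio = (k_s/n_s) / (k_all/n_all); the p-value tests k_s out of n_s
    against the pooled rate.  With k_all == 0 the ratio is undefined and the
    result is flagged not evaluable.
    """
    if n_stratum < 1 or n_all < n_stratum:
        raise ValueError(
            f"need 1 <= n_stratum <= n_all, got {n_stratum}, {n_all}"
        )
    if not category:
        raise ValueError("category must be non-empty")
    if k_all == 0:
        return PostingRatioResult(
            stratum_label, category, n_stratum, k_stratum, n_all, k_all,
            float("nan"), 1.0, evaluable=False,
        )
    pooled = k_all / n_all
    ratio = (k_stratum / n_stratum) / pooled
    p = stats.binomtest(k_stratum, n_stratum, pooled, alternative="two-sided").pvalue
    return PostingRatioResult(
        stratum_label, category, n_stratum, k_stratum, n_all, k_all, ratio, float(p)
    )


def bh_fdr(
    p_values: Sequence[float], q_threshold: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q_values, significant) aligned with the input order;
    q_i = min over j>=i in sorted order of m*p_(j)/j, capped at 1.
    """
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    # multipletests' reject uses the adaptive step-up cutoff; re-derive the
    # flag from q <= threshold so the two outputs are always consistent
    return q, q <= q_threshold


def attach_future_posts(
    records: pd.DataFrame, posts: pd.DataFrame
) -> Dict[str, set]:
    """Map each topical category to the set of asker user_ids posting to it.

    Only posts by a known asker, strictly later than that asker's inquiry
    timestamp, and outside the inquiry category count.
    """
    t0 = pd.to_datetime(records.set_index("user_id")["t0"])
    out: Dict[str, set] = {}
    known = posts["user_id"].isin(t0.index)
    later = posts.loc[known].copy()
    later = later[pd.to_datetime(later["timestamp"]) > later["user_id"].map(t0)]
    from .config import INQUIRY_CATEGORY

    later = later[later["category"] != INQUIRY_CATEGORY]
    for cat, sub in later.groupby("category"):
        out[cat] = set(sub["user_id"])
    return out


def category_overexpression(
    records: pd.DataFrame,
    future_posts: pd.DataFrame,
    strata: Optional[Sequence[Stratum]] = None,
    q_threshold: float = 0.05,
    fdr_family: str = "per_gender",
    categories: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Posting ratios for every (stratum, category) pair, FDR-adjusted.

    ``records`` needs user_id, gender, actual_class3, term_class, t0;
    ``future_posts`` needs user_id, timestamp, category.  Default strata are
    the six gender x actual-class cells plus the gender x (normal actual,
    high term) body-image cells.  q-values are adjusted within each gender's
    family of tests (or pooled, per ``fdr_family``).
    """
    if strata is None:
        strata = [
            Stratum(gender=g, actual_class3=c)
            for g in ("male", "female")
            for c in ("underweight", "normal", "overweight")
        ] + [
            Stratum(gender=g, actual_class3="normal", term_class="high")
            for g in ("male", "female")
        ]
    by_cat = attach_future_posts(records, future_posts)
    if categories is None:
        categories = sorted(by_cat)
    n_all = len(records)
    all_users = set(records["user_id"])

    rows: List[PostingRatioResult] = []
    for st in strata:
        mask = st.mask(records)
        n_s = int(mask.sum())
        if n_s == 0:
            continue
        users_s = set(records.loc[mask, "user_id"])
        for cat in categories:
            posters = by_cat.get(cat, set()) & all_users
            k_all = len(posters)
            k_s = len(posters & users_s)
            rows.append(
                posting_ratio(k_s, n_s, k_all, n_all, cat, st.label())
            )

    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        return df
    df["q_value"] = np.nan
    df["significant"] = False
    if fdr_family == "per_gender":
        fam = df["stratum"].str.extract(r"gender=(male|female)")[0].fillna("pooled")
    else:
        fam = pd.Series("pooled", index=df.index)
    for _, idx in df.groupby(fam).groups.items():
        sub = df.loc[idx]
        ev = sub["evaluable"]
        if ev.any():
            q, sig = bh_fdr(sub.loc[ev, "p_value"], q_threshold)
            df.loc[sub.index[ev], "q_value"] = q
            df.loc[sub.index[ev], "significant"] = sig
    df["overexpressed"] = df["significant"] & (df["ratio"] > 1.0)
    return df


def bullying_association(
    records: pd.DataFrame, bullying_flags: pd.Series
) -> dict:
    """Per (gender x term) bullying fractions and the interaction test.

    ``bullying_flags`` is indexed by user_id (True if the asker later posted
    a bullying-related question).  The interaction between inquiry term and
    gender is tested as heterogeneity of term effects across genders: a
    likelihood-ratio G² comparing the log-linear model with additive gender
    and term effects on the bullying odds against the saturated model
    (df = number of terms - 1).  Returns fractions, counts, the interaction
    statistic and p-value; if all flags are false no test is performed.
    """
    df = records.copy()
    df["bullied"] = df["user_id"].map(bullying_flags).fillna(False).astype(bool)

    frac = (
        df.groupby(["gender", "term"])["bullied"]
        .agg(n="size", k="sum")
        .assign(fraction=lambda d: d["k"] / d["n"])
    )
    out = {"fractions": frac.reset_index(), "interaction": None}
    if df["bullied"].sum() == 0:
        return out

    # 2 (gender) x T (term) x 2 (bullied) interaction via logistic LRT
    import statsmodels.api as sm

    cells = frac.reset_index()
    if cells["gender"].nunique() < 2 or cells["term"].nunique() < 2:
        return out
    expected_min = (cells["n"] * df["bullied"].mean()).min()
    if expected_min < 1:
        warnings.warn(
            "expected bullying counts below 1 in some cells; "
            "interaction test may be unreliable", stacklevel=2
        )
    X_add = pd.get_dummies(
        cells[["gender", "term"]], drop_first=True, dtype=float
    )
    X_add = sm.add_constant(X_add, has_constant="add")
    y = np.column_stack([cells["k"], cells["n"] - cells["k"]]).astype(float)
    try:
        # with a full gender x term grid the interaction model is saturated,
        # so the LRT statistic is the additive model's residual deviance
        fit_add = sm.GLM(y, X_add.to_numpy(float), family=sm.families.Binomial()).fit()
        g2 = float(fit_add.deviance)
        dof = int(fit_add.df_resid)
        p = float(stats.chi2.sf(max(g2, 0.0), dof)) if dof > 0 else float("nan")
        out["interaction"] = {"statistic": float(g2), "df": int(dof), "p_value": p}
    except Exception as exc:  # degenerate tables
        warnings.warn(f"interaction test failed: {exc}", stacklevel=2)
    return out
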