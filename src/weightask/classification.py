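"""BMI computation, weight-category assignment, and the asker sample table.

Adults (20+) are classified against the standard NIH/CDC BMI thresholds;
teens (13-19) against BMI-for-age percentiles computed by the LMS (Box-Cox)
method from a bundled reference grid.  The grid in
``data/lms_reference_synthetic.csv`` is a synthetic, smooth CDC-style
reference (both sexes, 6-month knots over 13-20 years) — it plays the role
of the CDC growth curves without bundling the original tables.

Interval convention: every band is half-open ``[lo, hi)``, so BMI 25.0 is
overweight and 30.0 obese, and the 85th percentile falls in the 85-95 band.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .extraction import InquiryTerm

__all__ = [
    "ADULT_BANDS",
    "TEEN_BANDS",
    "HIGH_TERMS",
    "LOW_TERMS",
    "compute_bmi",
    "classify_adult",
    "age_class",
    "load_lms_table",
    "teen_percentile",
    "classify_teen",
    "collapse_class",
    "assess_congruence",
    "AskerRecord",
    "build_asker_table",
    "load_analytic_sample_fixture",
    "load_accounting_fixture",
    "fat_obese_overweight_share",
]

#: Adult BMI categories, half-open [lo, hi).
ADULT_BANDS = (
    (0.0, 18.5, "underweight"),
    (18.5, 25.0, "normal"),
    (25.0, 30.0, "overweight"),
    (30.0, float("inf"), "obese"),
)

#: Teen BMI-for-age percentile bands, half-open [lo, hi) (95+ closed at 100).
TEEN_BANDS = (
    (0.0, 5.0, "<5"),
    (5.0, 85.0, "5-85"),
    (85.0, 95.0, "85-95"),
    (95.0, 100.0, "95+"),
)

HIGH_TERMS = frozenset({"fat", "obese"})
LOW_TERMS = frozenset({"skinny", "thin"})

#: Teen/adult boundary: ages 13-19 are teens, 20+ adults (the convention of
#: the reference sample table this package reproduces).
TEEN_MAX_AGE = 19


def compute_bmi(weight_lb: float, height_in: float) -> float:
    """BMI in kg/m^2 from imperial units: 703 * lb / in^2."""
    if weight_lb <= 0 or height_in <= 0:
        raise ValueError(
            f"weight and height must be positive, got {weight_lb} lb, {height_in} in"
        )
    return 703.0 * weight_lb / height_in**2


def classify_adult(bmi: float) -> str:
    """Adult weight category for a positive finite BMI."""
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi}")
    for lo, hi, name in ADULT_BANDS:
        if lo <= bmi < hi:
            return name
    raise AssertionError("unreachable: bands partition (0, inf)")


def age_class(age_years: int) -> str:
    """'teen' for 13-19, 'adult' for 20+."""
    if age_years < 13:
        raise ValueError(f"ages under 13 are out of scope, got {age_years}")
    return "teen" if age_years <= TEEN_MAX_AGE else "adult"


def load_lms_table() -> pd.DataFrame:
    """Load the bundled LMS reference grid (columns sex, agemos, L, M, S)."""
    path = resources.files("weightask.data").joinpath("lms_reference_synthetic.csv")
    with path.open() as fh:
        tab = pd.read_csv(fh)
    return tab.sort_values(["sex", "agemos"]).reset_index(drop=True)


def _interp_lms(lms_table: pd.DataFrame, sex: str, agemos: float):
    sub = lms_table[lms_table["sex"] == sex]
    if sub.empty:
        raise ValueError(f"sex {sex!r} not present in LMS table")
    lo, hi = sub["agemos"].min(), sub["agemos"].max()
    if not (lo <= agemos <= hi):
        raise ValueError(
            f"age {agemos} months outside LMS table support [{lo}, {hi}]"
        )
    ages = sub["agemos"].to_numpy(float)
    L = float(np.interp(agemos, ages, sub["L"].to_numpy(float)))
    M = float(np.interp(agemos, ages, sub["M"].to_numpy(float)))
    S = float(np.interp(agemos, ages, sub["S"].to_numpy(float)))
    return L, M, S


def teen_percentile(
    bmi: float, agemos: float, sex: str, lms_table: Optional[pd.DataFrame] = None
) -> float:
    """BMI-for-age percentile by the LMS method.

    z = ((bmi/M)^L - 1) / (L*S) for L != 0, z = ln(bmi/M)/S for L = 0, with
    L, M, S linearly interpolated in age (months); the percentile is the
    standard-normal CDF of z, times 100.
    """
    if lms_table is None:
        lms_table = load_lms_table()
    L, M, S = _interp_lms(lms_table, sex, agemos)
    if abs(L) < 1e-12:
        z = np.log(bmi / M) / S
    else:
        z = ((bmi / M) ** L - 1.0) / (L * S)
    return float(norm.cdf(z) * 100.0)


def classify_teen(percentile: float) -> str:
    """Teen percentile band for a percentile in [0, 100]."""
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile must lie in [0, 100], got {percentile}")
    for lo, hi, name in TEEN_BANDS:
        if lo <= percentile < hi or (name == "95+" and percentile == 100.0):
            return name
    raise AssertionError("unreachable")


def collapse_class(category: str) -> str:
    """Collapse an adult category or teen band to underweight/normal/overweight.

    'overweight' here means overweight-or-obese (adult BMI >= 25, teen
    percentile >= 85), the three-way actual-weight axis used by the
    stratified posting analyses.
    """
    mapping = {
        "underweight": "underweight",
        "normal": "normal",
        "overweight": "overweight",
        "obese": "overweight",
        "<5": "underweight",
        "5-85": "normal",
        "85-95": "overweight",
        "95+": "overweight",
    }
    return mapping[category]


#: Default congruence mapping: which collapsed actual classes count as
#: agreeing with a high-term ("am I fat/obese?") inquiry.  Low terms are
#: congruent with the complement.
DEFAULT_CONGRUENT_HIGH = frozenset({"overweight"})


def assess_congruence(
    term: str,
    actual_category: str,
    mapping_high: frozenset = DEFAULT_CONGRUENT_HIGH,
) -> bool:
    """Does the inquired term agree with the computed weight category?

    ``actual_category`` may be an adult category or a teen band; it is
    collapsed to the three-way axis first.  By default {fat, obese} are
    congruent with overweight-or-obese, and {skinny, thin} with anything
    else.  The mapping is configurable because any such rule is a
    convention.
    """
    collapsed = collapse_class(actual_category)
    if term in HIGH_TERMS:
        return collapsed in mapping_high
    if term in LOW_TERMS:
        return collapsed not in mapping_high
    raise ValueError(f"unknown inquiry term {term!r}")


@dataclass
class AskerRecord:
    """A retained asker: complete profile, BMI, category, congruence."""

    user_id: str
    term: str
    age: int
    gender: str
    weight: float
    height: float
    bmi: float
    age_class: str
    actual_category: str  # adult category or teen band
    actual_class3: str  # collapsed underweight/normal/overweight
    congruent: bool
    county_id: Optional[str] = None

    @classmethod
    def from_profile(
        cls,
        user_id: str,
        term: str,
        age: int,
        gender: str,
        weight: float,
        height: float,
        lms_table: Optional[pd.DataFrame] = None,
        county_id: Optional[str] = None,
    ) -> "AskerRecord":
        bmi = compute_bmi(weight, height)
        ac = age_class(age)
        if ac == "teen":
            # integer ages only: mid-year convention, 12*years + 6 months
            pct = teen_percentile(bmi, 12 * age + 6, gender, lms_table)
            cat = classify_teen(pct)
        else:
            cat = classify_adult(bmi)
        return cls(
            user_id=user_id,
            term=term,
            age=age,
            gender=gender,
            weight=weight,
            height=height,
            bmi=bmi,
            age_class=ac,
            actual_category=cat,
            actual_class3=collapse_class(cat),
            congruent=assess_congruence(term, cat),
            county_id=county_id,
        )


_TERMS = ("skinny", "thin", "fat", "obese")
_AGE_ROWS = (("13-15", 13, 15), ("16-18", 16, 18), ("19-25", 19, 25), ("25+", 26, 200))


def build_asker_table(
    records: Iterable[AskerRecord],
    extraction_counts: Optional[dict] = None,
    excluded_counts: Optional[dict] = None,
) -> dict:
    """Build the analytic-sample contingency table with exclusion accounting.

    Returns a dict with:

    ``accounting``
        per-term extracted/excluded/retained counts plus a total row
        (only when both count dicts are given);
    ``age``, ``adult_bmi``, ``teen_pct``
        DataFrames of asker counts, rows = age range / adult BMI band /
        teen percentile band, columns = (gender, term).
    """
    recs = list(records)
    cols = pd.MultiIndex.from_product(
        [("male", "female"), _TERMS], names=["gender", "term"]
    )

    def empty(rows):
        return pd.DataFrame(0, index=list(rows), columns=cols)

    age_tab = empty([r[0] for r in _AGE_ROWS])
    adult_tab = empty([b[2] for b in ADULT_BANDS])
    adult_tab.index = ["<18.5", "18.5-25", "25-30", "30+"]
    teen_tab = empty([b[2] for b in TEEN_BANDS])

    for r in recs:
        key = (r.gender, r.term)
        for label, lo, hi in _AGE_ROWS:
            if lo <= r.age <= hi:
                age_tab.loc[label, key] += 1
                break
        if r.age_class == "adult":
            band = {"underweight": "<18.5", "normal": "18.5-25",
                    "overweight": "25-30", "obese": "30+"}[r.actual_category]
            adult_tab.loc[band, key] += 1
        else:
            teen_tab.loc[r.actual_category, key] += 1

    out = {"age": age_tab, "adult_bmi": adult_tab, "teen_pct": teen_tab}

    if extraction_counts is not None and excluded_counts is not None:
        rows = []
        for t in _TERMS:
            ext = int(extraction_counts[t])
            exc = int(excluded_counts[t])
            ret = ext - exc
            if ret < 0:
                raise ValueError(
                    f"excluded count exceeds extracted for term {t!r}: {exc} > {ext}"
                )
            rows.append({"term": t, "extracted": ext, "excluded": exc, "retained": ret})
        acc = pd.DataFrame(rows)
        total = {
            "term": "total",
            "extracted": acc["extracted"].sum(),
            "excluded": acc["excluded"].sum(),
            "retained": acc["retained"].sum(),
        }
        out["accounting"] = pd.concat(
            [acc, pd.DataFrame([total])], ignore_index=True
        )
    return out


def load_analytic_sample_fixture() -> dict:
    """Keyed-in demo analytic-sample table (age / adult BMI / teen bands).

    Returns the same ``{"age": ..., "adult_bmi": ..., "teen_pct": ...}``
    layout as :func:`build_asker_table`.
    """
    path = resources.files("weightask.data").joinpath("analytic_sample_counts.csv")
    with path.open() as fh:
        raw = pd.read_csv(fh)
    cols = pd.MultiIndex.from_product(
        [("male", "female"), _TERMS], names=["gender", "term"]
    )
    out = {}
    for section, sub in raw.groupby("section", sort=False):
        tab = pd.DataFrame(
            sub[[f"{g}_{t}" for g, t in cols]].to_numpy(),
            index=sub["row"].tolist(),
            columns=cols,
        )
        out[section] = tab
    return out


def load_accounting_fixture() -> tuple:
    """Keyed-in per-term extracted/excluded counts for the demo sample."""
    path = resources.files("weightask.data").joinpath("exclusion_accounting.csv")
    with path.open() as fh:
        acc = pd.read_csv(fh)
    extracted = dict(zip(acc["term"], acc["extracted"]))
    excluded = dict(zip(acc["term"], acc["excluded"]))
    return extracted, excluded


def fat_obese_overweight_share(tables: dict) -> dict:
    """Share of fat/obese inquirers who are actually overweight-or-obese.

    Computed separately for adults (BMI >= 25) and teens (percentile >= 85)
    and by gender, from a table dict shaped like :func:`build_asker_table`
    output.  Values are percentages.
    """
    out = {}
    for section, rows_hi in (("adult_bmi", ["25-30", "30+"]), ("teen_pct", ["85-95", "95+"])):
        tab = tables[section]
        for gender in ("male", "female"):
            cols = [(gender, t) for t in HIGH_TERMS]
            total = tab.loc[:, cols].to_numpy().sum()
            hi = tab.loc[rows_hi, cols].to_numpy().sum()
            key = ("adult" if section == "adult_bmi" else "teen", gender)
            out[key] = 100.0 * hi / total if total else float("nan")
    return out
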