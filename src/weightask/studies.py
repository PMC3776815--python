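"""Preset study configurations: planted-effect recovery and reference correlation.

Two canned experiments exercise the full pipeline on synthetic corpora:

``run_recovery_study``
    20,000 askers with three planted effects — a 4.6x diabetes posting
    multiplier for overweight/obese men, a 3.1x trying-to-conceive
    multiplier for overweight/obese women, and a 1.8% bullying-post
    probability for men asking "am I obese?" — then measures how well the
    posting-ratio estimator and the bullying analysis recover them.
    Omission and ambiguity are disabled (the question is estimator
    recovery, not extraction loss), and anthropometric dispersion is kept
    low so the planted overweight strata stay small: the pooled
    denominator includes the stratum, which attenuates a multiplier m to
    m/(1+f(m-1)) for stratum fraction f, so f is held near 3%.

``run_reference_correlation_study``
    5,000 askers aged 13-20 at default dispersion; the median extracted
    weight per integer age (females) is regressed on the generator's
    reference median curve and the R^2 reported.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnthropometricModel, EffectEntry, SyntheticConfig
from .pipeline import build_asker_records, bullying_flags, extract_corpus
from .posting import category_overexpression
from .synthetic import generate_corpus, posts_to_frame

__all__ = [
    "DIABETES_CATEGORY",
    "CONCEIVE_CATEGORY",
    "PLANTED_DIABETES_MULTIPLIER",
    "PLANTED_CONCEIVE_MULTIPLIER",
    "PLANTED_MALE_OBESE_BULLYING",
    "recovery_config",
    "reference_correlation_config",
    "run_recovery_study",
    "run_reference_correlation_study",
    "ratio_standard_error",
]

DIABETES_CATEGORY = "Health/Diseases/Diabetes"
CONCEIVE_CATEGORY = "Pregnancy & Parenting/Trying to Conceive"

PLANTED_DIABETES_MULTIPLIER = 4.6
PLANTED_CONCEIVE_MULTIPLIER = 3.1
PLANTED_MALE_OBESE_BULLYING = 0.018

_UNIFORMISH_TERMS = {
    "male": {"skinny": 0.10, "thin": 0.10, "fat": 0.35, "obese": 0.45},
    "female": {"skinny": 0.10, "thin": 0.20, "fat": 0.50, "obese": 0.20},
}


def recovery_config(seed: int, n_askers: int = 20_000) -> SyntheticConfig:
    """Adult-only corpus with the three planted effects and small strata.

    Median BMI ~21.5 with ~10% lognormal BMI dispersion puts roughly 6% of
    each gender in the overweight/obese class, keeping the planted strata
    near 3% of the pooled population.
    """
    anthro = AnthropometricModel(
        ages=[20, 59],
        median_height_male=[69.5, 69.5],
        median_height_female=[64.3, 64.3],
        median_weight_male=[147.4, 147.4],
        median_weight_female=[126.2, 126.2],
        weight_sigma=0.09,
        height_sigma=0.02,
    )
    inquiry = {
        f"{g}:{c}": dict(_UNIFORMISH_TERMS[g])
        for g in ("male", "female")
        for c in ("underweight", "normal", "overweight")
    }
    bullying = {
        "male:skinny": 0.012,
        "male:thin": 0.012,
        "male:fat": 0.006,
        "male:obese": PLANTED_MALE_OBESE_BULLYING,
        "female:skinny": 0.024,
        "female:thin": 0.024,
        "female:fat": 0.024,
        "female:obese": 0.024,
    }
    return SyntheticConfig(
        seed=seed,
        n_askers=n_askers,
        age_range=(20, 59),
        female_fraction=0.5,
        anthropometric_model=anthro,
        omission_rates={"age": 0.0, "weight": 0.0, "height": 0.0, "gender": 0.0},
        ambiguity_rate=0.0,
        inquiry_model=inquiry,
        bullying_model=bullying,
        effect_table=[
            EffectEntry(
                gender="male",
                actual_class="overweight",
                category=DIABETES_CATEGORY,
                multiplier=PLANTED_DIABETES_MULTIPLIER,
            ),
            EffectEntry(
                gender="female",
                actual_class="overweight",
                category=CONCEIVE_CATEGORY,
                multiplier=PLANTED_CONCEIVE_MULTIPLIER,
            ),
        ],
    )


def reference_correlation_config(seed: int, n_askers: int = 5_000) -> SyntheticConfig:
    """Teen-heavy corpus, ages 13-20, default anthropometric dispersion."""
    return SyntheticConfig(seed=seed, n_askers=n_askers, age_range=(13, 20))


def ratio_standard_error(result) -> float:
    """Delta-method standard error of a posting ratio.

    Treats the stratum and pooled rates as independent binomials (slightly
    conservative since the stratum is part of the pool).
    """
    if result.k_stratum == 0 or result.k_all == 0:
        return float("nan")
    p_s = result.k_stratum / result.n_stratum
    p_a = result.k_all / result.n_all
    var_log = (1 - p_s) / result.k_stratum + (1 - p_a) / result.k_all
    return float(result.ratio * math.sqrt(var_log))


def _pipeline_records(config: SyntheticConfig):
    posts, truths = generate_corpus(config)
    frame = posts_to_frame(posts)
    extraction = extract_corpus(frame)
    records, _ = build_asker_records(extraction)
    return frame, extraction, records


def run_recovery_study(seed: int, n_askers: int = 20_000) -> dict:
    """Generate the recovery corpus and measure the three planted effects."""
    config = recovery_config(seed, n_askers)
    _, extraction, records = _pipeline_records(config)

    from .config import INQUIRY_CATEGORY

    future = extraction[extraction["category"] != INQUIRY_CATEGORY]
    over = category_overexpression(records, future)

    def row(stratum_label, category):
        sel = over[(over["stratum"] == stratum_label) & (over["category"] == category)]
        if sel.empty:
            raise RuntimeError(f"no result for {stratum_label} / {category}")
        return sel.iloc[0]

    from .posting import PostingRatioResult

    def as_result(r) -> PostingRatioResult:
        return PostingRatioResult(
            r["stratum"], r["category"], int(r["n_stratum"]), int(r["k_stratum"]),
            int(r["n_all"]), int(r["k_all"]), float(r["ratio"]), float(r["p_value"]),
        )

    diab = as_result(row("gender=male&actual_class3=overweight", DIABETES_CATEGORY))
    conc = as_result(row("gender=female&actual_class3=overweight", CONCEIVE_CATEGORY))

    flags = bullying_flags(extraction, records)
    male_obese = records[(records["gender"] == "male") & (records["term"] == "obese")]
    n_mo = len(male_obese)
    k_mo = int(male_obese["user_id"].map(flags).sum())
    frac = k_mo / n_mo if n_mo else float("nan")
    se_frac = math.sqrt(frac * (1 - frac) / n_mo) if n_mo else float("nan")

    return {
        "diabetes_ratio": float(diab.ratio),
        "diabetes_se": ratio_standard_error(diab),
        "diabetes_counts": (diab.k_stratum, diab.n_stratum, diab.k_all, diab.n_all),
        "conceive_ratio": float(conc.ratio),
        "conceive_se": ratio_standard_error(conc),
        "conceive_counts": (conc.k_stratum, conc.n_stratum, conc.k_all, conc.n_all),
        "male_obese_bullying_pct": 100.0 * frac,
        "male_obese_bullying_se_pct": 100.0 * se_frac,
        "male_obese_counts": (k_mo, n_mo),
        "n_askers": len(records),
    }


def run_reference_correlation_study(seed: int, n_askers: int = 5_000) -> dict:
    """R^2 of median extracted female weight per age vs the reference curve."""
    config = reference_correlation_config(seed, n_askers)
    _, extraction, _ = _pipeline_records(config)
    sub = extraction[
        (extraction["gender"] == "female")
        & extraction["age"].notna()
        & extraction["weight"].notna()
    ]
    med = sub.groupby(sub["age"].astype(int))["weight"].median()
    ref = pd.Series(
        {
            age: config.anthropometric_model.median(age, "female")[1]
            for age in med.index
        }
    )
    fit = stats.linregress(ref.to_numpy(), med.to_numpy())
    return {
        "r2": float(fit.rvalue**2),
        "n_ages": int(len(med)),
        "n_askers_used": int(len(sub)),
        "medians": med.to_dict(),
        "reference": ref.to_dict(),
    }
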