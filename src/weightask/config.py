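"""Configuration models for the synthetic corpus generator and the pipeline.

All knobs live in pydantic models so a run is fully described by one YAML
file plus a seed.  Defaults are chosen once to emulate a large weight-themed
Q&A asker population: two thirds female, ages concentrated in the teens
(mean ~17), anthropometrics lognormal around US-shaped median curves, and
per-field omission rates matching the validation profile of a precision-first
extractor (roughly a quarter of ages, a third of weights and an eighth of
heights unparseable).
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "CountyProfile",
    "AnthropometricModel",
    "EffectEntry",
    "CountyBullyingModel",
    "SyntheticConfig",
    "AnalysisOptions",
    "RunConfig",
    "default_county_table",
    "DEFAULT_CATEGORIES",
]

#: Topical categories a retained asker may post to later (slash paths).
DEFAULT_CATEGORIES: Dict[str, float] = {
    "Health/Diseases/Diabetes": 0.01,
    "Health/Diseases/Heart Disease": 0.01,
    "Health/Mental Health": 0.01,
    "Health/Alternative Medicine": 0.01,
    "Pregnancy & Parenting/Trying to Conceive": 0.01,
    "Pregnancy & Parenting/Pregnancy": 0.01,
    "Pregnancy & Parenting/Parenting": 0.01,
    "Pregnancy & Parenting/Toddler & Preschooler": 0.01,
    "Pregnancy & Parenting/Newborn & Baby": 0.01,
    "Family & Relationships/Marriage & Divorce": 0.01,
    "Family & Relationships/Weddings": 0.01,
    "Family & Relationships/Singles & Dating": 0.01,
    "Beauty & Style/Makeup": 0.01,
    "Beauty & Style/Skin & Body": 0.01,
}

INQUIRY_CATEGORY = "Health/Diet & Fitness"


class CountyProfile(BaseModel):
    """One synthetic county: obesity prevalence, income, and its zip codes."""

    county_id: str
    obesity_pct: float = Field(ge=0.0, le=100.0)
    median_income: float = Field(gt=0.0)
    zips: List[str] = Field(default_factory=list)
    weight: float = Field(default=1.0, ge=0.0)  # assignment probability weight


def default_county_table(n: int = 40) -> List[CountyProfile]:
    """Synthetic counties spanning obesity prevalences ~15-45%.

    Income declines with obesity prevalence (plus a deterministic ripple),
    mirroring the real-world negative gradient without any download.
    """
    counties = []
    for i in range(n):
        frac = i / max(n - 1, 1)
        obesity = 15.0 + 30.0 * frac
        income = 65000.0 - 30000.0 * frac + 4000.0 * ((i * 7) % 5 - 2) / 2.0
        counties.append(
            CountyProfile(
                county_id=f"C{i + 1:03d}",
                obesity_pct=round(obesity, 2),
                median_income=round(income, 0),
                zips=[f"{10000 + 13 * i:05d}"],
            )
        )
    return counties


class AnthropometricModel(BaseModel):
    """Lognormal dispersion around piecewise-linear median-by-age curves.

    Heights in inches, weights in pounds; separate curves per gender,
    linearly interpolated between the ``ages`` knots.  ``weight_sigma`` and
    ``height_sigma`` are lognormal standard deviations (dimensionless).
    """

    ages: List[float] = Field(
        default=[13, 14, 15, 16, 17, 18, 19, 20, 25, 35, 50, 60]
    )
    median_height_male: List[float] = Field(
        default=[61.5, 64.5, 66.5, 68.0, 69.0, 69.3, 69.5, 69.5, 69.5, 69.5, 69.3, 69.0]
    )
    median_height_female: List[float] = Field(
        default=[61.8, 63.0, 63.8, 64.0, 64.2, 64.3, 64.3, 64.3, 64.3, 64.3, 64.0, 63.7]
    )
    median_weight_male: List[float] = Field(
        default=[102, 112, 124, 134, 142, 148, 152, 155, 170, 178, 180, 178]
    )
    median_weight_female: List[float] = Field(
        default=[102, 109, 115, 118, 120, 122, 125, 128, 140, 150, 155, 152]
    )
    weight_sigma: float = Field(default=0.15, ge=0.0)
    height_sigma: float = Field(default=0.035, ge=0.0)

    @model_validator(mode="after")
    def _lengths_match(self):
        n = len(self.ages)
        for name in (
            "median_height_male",
            "median_height_female",
            "median_weight_male",
            "median_weight_female",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have {n} entries (one per age knot)")
        if sorted(self.ages) != list(self.ages):
            raise ValueError("age knots must be sorted ascending")
        return self

    def median(self, age: float, gender: str) -> Tuple[float, float]:
        """(height, weight) medians at ``age`` for ``gender``."""
        if not (self.ages[0] <= age <= self.ages[-1]):
            raise ValueError(
                f"age {age} outside anthropometric model support "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        hk = self.median_height_male if gender == "male" else self.median_height_female
        wk = self.median_weight_male if gender == "male" else self.median_weight_female
        h = float(np.interp(age, self.ages, hk))
        w = float(np.interp(age, self.ages, wk))
        return h, w


class EffectEntry(BaseModel):
    """A planted future-posting effect: stratum selector x category x multiplier.

    A selector axis left as ``None`` matches any value; multipliers of
    several matching entries multiply.
    """

    gender: Optional[Literal["male", "female"]] = None
    actual_class: Optional[Literal["underweight", "normal", "overweight"]] = None
    term_class: Optional[Literal["low", "high"]] = None
    category: str
    multiplier: float = Field(ge=0.0)  # 0 silences a stratum entirely


class CountyBullyingModel(BaseModel):
    """How county attributes modulate an asker's bullying-post probability.

    ``shape='ushape'`` multiplies the stratum base rate by
    ``1 + strength * z^2`` where z is the county's obesity prevalence
    standardized over the county table; ``income_coef`` applies a
    log-multiplier per $10,000 of median income above the county mean.
    """

    shape: Literal["flat", "ushape"] = "flat"
    strength: float = 0.0
    income_coef: float = 0.0


def _default_inquiry_model() -> Dict[str, Dict[str, float]]:
    # conditional term distributions by "gender:actual_class3", shaped like a
    # real asker population (females asking "fat" while normal dominate)
    return {
        "male:underweight": {"skinny": 0.27, "thin": 0.29, "fat": 0.44, "obese": 0.00},
        "male:normal": {"skinny": 0.088, "thin": 0.174, "fat": 0.702, "obese": 0.036},
        "male:overweight": {"skinny": 0.016, "thin": 0.097, "fat": 0.729, "obese": 0.158},
        "female:underweight": {"skinny": 0.142, "thin": 0.362, "fat": 0.488, "obese": 0.008},
        "female:normal": {"skinny": 0.071, "thin": 0.232, "fat": 0.658, "obese": 0.039},
        "female:overweight": {"skinny": 0.036, "thin": 0.132, "fat": 0.625, "obese": 0.207},
    }


def _default_bullying_model() -> Dict[str, float]:
    # base probability of a later bullying post by "gender:term"; males who
    # ask "obese" markedly higher, "fat" lower; females uniformly higher
    return {
        "male:skinny": 0.012,
        "male:thin": 0.012,
        "male:fat": 0.006,
        "male:obese": 0.018,
        "female:skinny": 0.024,
        "female:thin": 0.024,
        "female:fat": 0.024,
        "female:obese": 0.024,
    }


class SyntheticConfig(BaseModel):
    """Full parameterization of one synthetic corpus."""

    seed: int = 0
    n_askers: int = Field(ge=0)
    age_range: Tuple[int, int] = (13, 59)
    #: mean of the truncated-geometric age offset above age_range[0]
    age_decay_mean: float = Field(default=4.1, gt=0.0)
    female_fraction: float = Field(default=0.65, ge=0.0, le=1.0)
    anthropometric_model: AnthropometricModel = Field(
        default_factory=AnthropometricModel
    )
    omission_rates: Dict[str, float] = Field(
        default_factory=lambda: {
            "age": 0.23,
            "weight": 0.295,
            "height": 0.135,
            "gender": 0.11,
        }
    )
    ambiguity_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    inquiry_model: Dict[str, Dict[str, float]] = Field(
        default_factory=_default_inquiry_model
    )
    effect_table: List[EffectEntry] = Field(default_factory=list)
    baseline_category_rates: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CATEGORIES)
    )
    bullying_model: Dict[str, float] = Field(default_factory=_default_bullying_model)
    #: latent probability a term-matched bullying post is genuinely about
    #: being bullied (emulates a manual-annotation yield)
    bullying_annotation_rate: float = Field(default=0.68, ge=0.0, le=1.0)
    county_table: List[CountyProfile] = Field(default_factory=default_county_table)
    county_bullying: CountyBullyingModel = Field(default_factory=CountyBullyingModel)
    #: odds multiplier toward the congruent inquiry term in counties above
    #: the median obesity prevalence, keyed "gender:actual_class3"
    congruence_shift: Dict[str, float] = Field(default_factory=dict)
    future_horizon_days: int = Field(default=365, gt=0)

    @field_validator("omission_rates")
    @classmethod
    def _omission_fields(cls, v):
        bad = set(v) - {"age", "weight", "height", "gender"}
        if bad:
            raise ValueError(f"unknown omission fields: {sorted(bad)}")
        for k, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"omission rate for {k} must be in [0,1], got {p}")
        return v

    @model_validator(mode="after")
    def _validate(self):
        problems = []
        if self.age_range[0] < 13:
            problems.append("age_range: minimum asker age is 13")
        if self.age_range[1] < self.age_range[0]:
            problems.append("age_range: upper bound below lower bound")
        for key, dist in self.inquiry_model.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-6:
                problems.append(f"inquiry_model[{key}]: probabilities sum to {tot}")
            if any(p < 0 for p in dist.values()):
                problems.append(f"inquiry_model[{key}]: negative probability")
        for cat, r in self.baseline_category_rates.items():
            if not 0.0 <= r <= 1.0:
                problems.append(f"baseline_category_rates[{cat}]: {r} not in [0,1]")
        for key, p in self.bullying_model.items():
            if not 0.0 <= p <= 1.0:
                problems.append(f"bullying_model[{key}]: {p} not in [0,1]")
        if not self.county_table:
            problems.append("county_table: at least one county required")
        if problems:
            raise ValueError("invalid synthetic config: " + "; ".join(problems))
        return self


class AnalysisOptions(BaseModel):
    """Knobs of the downstream statistical analyses."""

    fdr_threshold: float = Field(default=0.05, gt=0.0, lt=1.0)
    #: FDR family: 'per_gender' adjusts q-values within each gender's tests
    fdr_family: Literal["per_gender", "pooled"] = "per_gender"
    n_bins: int = Field(default=10, ge=3)
    county_split: Literal["median", "mean"] = "median"
    income_quantiles: int = Field(default=4, ge=2)


class RunConfig(BaseModel):
    """One pipeline run: paths, stage options, and the generator block."""

    seed: int = 0
    out_dir: str = "."
    corpus_path: str = "corpus.jsonl"
    truth_path: str = "truth.jsonl"
    county_path: str = "counties.csv"
    zip_map_path: str = "zip_map.csv"
    synthetic: SyntheticConfig = Field(
        default_factory=lambda: SyntheticConfig(n_askers=2000)
    )
    analysis: AnalysisOptions = Field(default_factory=AnalysisOptions)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
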