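"""Ground-truthed synthetic corpus of weight-inquiry Q&A posts.

The generator emulates the statistical structure the downstream analyses
assume: askers with known age/gender/height/weight post an "Am I <term>?"
question rendered in varied dialects (with controllable omission and
ambiguity), then post to topical categories at baseline rates optionally
inflated by planted stratum-specific multipliers, and post bullying-related
questions at planted per-stratum rates modulated by county attributes.
Every post id maps back to a truth record, so extraction, classification and
every estimator can be validated against known ground truth.

All randomness flows from ``config.seed`` through one ``numpy`` generator;
an identical seed and config yields a byte-identical corpus.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classification import (
    AskerRecord,
    collapse_class,
    load_lms_table,
)
from .config import INQUIRY_CATEGORY, CountyProfile, EffectEntry, SyntheticConfig
from .extraction import load_dialect_table

__all__ = [
    "RawPost",
    "TruthRecord",
    "sample_anthropometrics",
    "render_question",
    "assign_future_posts",
    "generate_corpus",
    "write_posts_jsonl",
    "write_truth_jsonl",
    "read_posts_jsonl",
    "read_truth_jsonl",
    "truth_to_frame",
    "posts_to_frame",
]

_EPOCH = datetime(2012, 1, 1)
_BULLY_GENUINE = (
    "I'm being bullied at school and it won't stop.",
    "How can I make new friends after having been bullied?",
)
_BULLY_SPURIOUS = (
    "Is my dog bullying the neighbor's dog?",
    "What's a good movie where the bully loses in the end?",
)


@dataclass
class RawPost:
    """One Q&A post as it appears on the wire (JSONL)."""

    post_id: str
    user_id: str
    timestamp: str  # ISO-8601
    category: str  # slash-separated path
    title: str
    body: str
    zip: str


@dataclass
class TruthRecord:
    """Ground truth for one synthetic asker and all of their posts."""

    user_id: str
    inquiry_post_id: str
    age: int
    gender: str
    height: float  # inches, as rendered (integers)
    weight: float  # pounds, as rendered (integers)
    bmi: float
    age_class: str
    actual_category: str
    actual_class3: str
    term: str
    term_class: str  # low | high
    congruent: bool
    county_id: str
    zip: str
    rendered: Dict[str, str] = field(default_factory=dict)  # field -> dialect id | "omitted"
    future_categories: List[str] = field(default_factory=list)
    future_post_ids: List[str] = field(default_factory=list)
    bullying: bool = False
    genuinely_bullied: bool = False
    bullying_post_id: Optional[str] = None
    t0: str = ""


def sample_anthropometrics(
    age: float,
    gender: str,
    rng: np.random.Generator,
    model=None,
) -> Tuple[float, float]:
    """Draw (height in inches, weight in pounds) for one asker.

    Lognormal dispersion around the model's piecewise-linear median curves:
    with zero dispersion the configured medians are returned exactly.
    """
    from .config import AnthropometricModel

    if model is None:
        model = AnthropometricModel()
    h_med, w_med = model.median(age, gender)  # raises for unsupported age
    h = h_med * float(np.exp(model.height_sigma * rng.standard_normal()))
    w = w_med * float(np.exp(model.weight_sigma * rng.standard_normal()))
    return h, w


def _pick(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(len(seq)))]


def render_question(
    profile: dict,
    term: str,
    dialects: dict,
    rng: np.random.Generator,
    omission_rates: Optional[Dict[str, float]] = None,
    ambiguity_rate: float = 0.0,
) -> Tuple[str, str, Dict[str, str]]:
    """Render an "Am I <term>?" question for a profile.

    ``profile`` must carry age, gender, weight (lb), height (in).  Each of
    the four fields is independently omitted with its configured omission
    rate; a rendered field uses an ambiguous (non-parseable) dialect with
    probability ``ambiguity_rate``, otherwise a random unambiguous dialect.

    Returns ``(title, body, rendered)`` where ``rendered`` maps each field
    to the dialect id used, or ``"omitted"``.
    """
    if term not in {"skinny", "thin", "fat", "obese"}:
        raise ValueError(f"unknown inquiry term {term!r}")
    omission_rates = omission_rates or {}
    feet, inches = int(profile["height"]) // 12, int(profile["height"]) % 12
    values = {
        "age": int(profile["age"]),
        "gender_word": _pick(rng, dialects["gender_words"][profile["gender"]]),
        "weight": int(round(profile["weight"])),
        "feet": feet,
        "inches": inches,
        "total_inches": int(profile["height"]),
    }
    sentences = []
    rendered: Dict[str, str] = {}
    for fld in ("gender", "age", "weight", "height"):
        if rng.random() < omission_rates.get(fld, 0.0):
            rendered[fld] = "omitted"
            continue
        field_spec = dialects["fields"][fld]
        if rng.random() < ambiguity_rate:
            choice = field_spec["ambiguous"]
        else:
            choice = _pick(rng, field_spec["unambiguous"])
        sentences.append(choice["template"].format(**values))
        rendered[fld] = choice["id"]
    sentences.append("Please be honest")
    title = f"Am I {term}?"
    body = ". ".join(sentences) + "."
    return title, body, rendered


def _effect_multiplier(
    effects: Sequence[EffectEntry],
    gender: str,
    actual_class3: str,
    term_class: str,
    category: str,
) -> float:
    m = 1.0
    for e in effects:
        if e.category != category:
            continue
        if e.gender is not None and e.gender != gender:
            continue
        if e.actual_class is not None and e.actual_class != actual_class3:
            continue
        if e.term_class is not None and e.term_class != term_class:
            continue
        m *= e.multiplier
    return m


def assign_future_posts(
    truth: dict,
    effect_table: Sequence[EffectEntry],
    baseline_rates: Dict[str, float],
    rng: np.random.Generator,
) -> List[str]:
    """Draw the categories this asker later posts to.

    For an asker in stratum s the posting probability for category c is
    ``clamp(baseline_c * multiplier(s, c), 0, 1)``; the multiplier defaults
    to 1 for unmatched strata.  Probabilities pushed above 1 are clamped
    with a warning.
    """
    cats = []
    for cat, base in baseline_rates.items():
        m = _effect_multiplier(
            effect_table,
            truth["gender"],
            truth["actual_class3"],
            truth["term_class"],
            cat,
        )
        p = base * m
        if p > 1.0:
            warnings.warn(
                f"posting probability clamped to 1 for category {cat!r} "
                f"(baseline {base} x multiplier {m})",
                stacklevel=2,
            )
            p = 1.0
        if rng.random() < p:
            cats.append(cat)
    return cats


def _county_bully_modifier(cfg: SyntheticConfig, county: CountyProfile) -> float:
    model = cfg.county_bullying
    mod = 1.0
    obs = np.array([c.obesity_pct for c in cfg.county_table], float)
    if model.shape == "ushape" and model.strength != 0.0:
        sd = obs.std() or 1.0
        z = (county.obesity_pct - obs.mean()) / sd
        mod *= 1.0 + model.strength * z * z
    if model.income_coef != 0.0:
        incomes = np.array([c.median_income for c in cfg.county_table], float)
        mod *= float(
            np.exp(model.income_coef * (county.median_income - incomes.mean()) / 1e4)
        )
    return mod


def _term_distribution(
    cfg: SyntheticConfig, gender: str, class3: str, county: CountyProfile
) -> Tuple[List[str], np.ndarray]:
    dist = dict(cfg.inquiry_model[f"{gender}:{class3}"])
    shift = cfg.congruence_shift.get(f"{gender}:{class3}")
    if shift is not None:
        med = float(np.median([c.obesity_pct for c in cfg.county_table]))
        if county.obesity_pct > med:
            high = {"fat", "obese"}
            congruent = high if class3 == "overweight" else {"skinny", "thin"}
            for t in congruent:
                dist[t] = dist.get(t, 0.0) * shift
    terms = list(dist)
    p = np.array([dist[t] for t in terms], float)
    p = p / p.sum()
    return terms, p


def _iso(dt: datetime) -> str:
    return dt.strftime("%Y-%m-%dT%H:%M:%S")


def generate_corpus(
    config: SyntheticConfig,
) -> Tuple[List[RawPost], List[TruthRecord]]:
    """Generate posts and ground truth for ``config.n_askers`` askers.

    Per asker: an inquiry post at t0 (uniform over one year), zero or more
    future-category posts and at most one bullying post, all timestamped
    after t0 within the configured horizon.
    """
    rng = np.random.default_rng(config.seed)
    dialects = load_dialect_table()
    lms = load_lms_table()
    county_w = np.array([c.weight for c in config.county_table], float)
    county_w = county_w / county_w.sum()

    posts: List[RawPost] = []
    truths: List[TruthRecord] = []
    serial = 0

    def next_post_id() -> str:
        nonlocal serial
        serial += 1
        return f"p{serial:08d}"

    lo, hi = config.age_range
    geo_p = 1.0 / (1.0 + config.age_decay_mean)

    for i in range(config.n_askers):
        user_id = f"u{i + 1:06d}"
        age = int(min(lo + rng.geometric(geo_p) - 1, hi))
        gender = "female" if rng.random() < config.female_fraction else "male"
        h, w = sample_anthropometrics(age, gender, rng, config.anthropometric_model)
        height = float(int(round(h)))
        weight = float(int(round(w)))
        county = config.county_table[int(rng.choice(len(county_w), p=county_w))]
        zip_code = county.zips[0] if county.zips else county.county_id

        # classify truth with the same rules the pipeline applies
        rec = AskerRecord.from_profile(
            user_id, "fat", age, gender, weight, height, lms_table=lms
        )
        class3 = rec.actual_class3

        terms, p = _term_distribution(config, gender, class3, county)
        term = terms[int(rng.choice(len(terms), p=p))]
        term_class = "high" if term in {"fat", "obese"} else "low"

        title, body, rendered = render_question(
            {"age": age, "gender": gender, "weight": weight, "height": height},
            term,
            dialects,
            rng,
            config.omission_rates,
            config.ambiguity_rate,
        )
        t0 = _EPOCH + timedelta(seconds=float(rng.uniform(0, 365 * 86400)))
        inquiry_id = next_post_id()
        posts.append(
            RawPost(
                post_id=inquiry_id,
                user_id=user_id,
                timestamp=_iso(t0),
                category=INQUIRY_CATEGORY,
                title=title,
                body=body,
                zip=zip_code,
            )
        )

        truth = TruthRecord(
            user_id=user_id,
            inquiry_post_id=inquiry_id,
            age=age,
            gender=gender,
            height=height,
            weight=weight,
            bmi=rec.bmi,
            age_class=rec.age_class,
            actual_category=rec.actual_category,
            actual_class3=class3,
            term=term,
            term_class=term_class,
            congruent=bool(
                term in {"fat", "obese"}
                and class3 == "overweight"
                or term in {"skinny", "thin"}
                and class3 != "overweight"
            ),
            county_id=county.county_id,
            zip=zip_code,
            rendered=rendered,
            t0=_iso(t0),
        )

        cats = assign_future_posts(
            {"gender": gender, "actual_class3": class3, "term_class": term_class},
            config.effect_table,
            config.baseline_category_rates,
            rng,
        )
        for cat in cats:
            ts = t0 + timedelta(
                seconds=float(
                    rng.uniform(60, config.future_horizon_days * 86400)
                )
            )
            pid = next_post_id()
            leaf = cat.rsplit("/", 1)[-1]
            posts.append(
                RawPost(
                    post_id=pid,
                    user_id=user_id,
                    timestamp=_iso(ts),
                    category=cat,
                    title=f"Question about {leaf}",
                    body=f"I could use some advice about {leaf.lower()}.",
                    zip=zip_code,
                )
            )
            truth.future_categories.append(cat)
            truth.future_post_ids.append(pid)

        p_bully = config.bullying_model.get(f"{gender}:{term}", 0.0)
        p_bully = min(p_bully * _county_bully_modifier(config, county), 1.0)
        if rng.random() < p_bully:
            truth.bullying = True
            truth.genuinely_bullied = rng.random() < config.bullying_annotation_rate
            pool = _BULLY_GENUINE if truth.genuinely_bullied else _BULLY_SPURIOUS
            body_b = str(_pick(rng, pool))
            ts = t0 + timedelta(
                seconds=float(rng.uniform(60, config.future_horizon_days * 86400))
            )
            pid = next_post_id()
            truth.bullying_post_id = pid
            posts.append(
                RawPost(
                    post_id=pid,
                    user_id=user_id,
                    timestamp=_iso(ts),
                    category="Family & Relationships/Friends",
                    title="Need advice",
                    body=body_b,
                    zip=zip_code,
                )
            )
        truths.append(truth)

    return posts, truths


# --- JSONL / DataFrame plumbing ---------------------------------------------

def write_posts_jsonl(posts: Sequence[RawPost], path: str) -> None:
    with open(path, "w") as fh:
        for p in posts:
            fh.write(json.dumps(asdict(p), sort_keys=True) + "\n")


def write_truth_jsonl(truths: Sequence[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(json.dumps(asdict(t), sort_keys=True) + "\n")


def read_posts_jsonl(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"corpus not found: {path}")
    return pd.read_json(path, lines=True, dtype={"zip": str})


def read_truth_jsonl(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"truth not found: {path}")
    return pd.read_json(path, lines=True, dtype={"zip": str})


def posts_to_frame(posts: Sequence[RawPost]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in posts])


def truth_to_frame(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truths])
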