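"""Rule-based extraction of weight inquiries, anthropometrics, and bullying mentions.

The extractor is deliberately precision-first: a field is populated only when
a number appears in an unambiguous unit/keyword context, and an ambiguous
mention (e.g. ``"I weigh 128"`` with no unit suffix) is omitted rather than
guessed.  The failure mode is therefore omission, never a fabricated value.
All patterns are explicit regular expressions driven by the dialect inventory
shipped in ``data/dialects.yaml``; nothing is learned from data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InquiryTerm",
    "MULTI_TERM",
    "ExtractedProfile",
    "ExtractionValidationReport",
    "match_inquiry",
    "extract_profile",
    "match_bullying",
    "validate_extraction",
    "load_dialect_table",
]

KG_TO_LB = 2.20462
CM_TO_IN = 1.0 / 2.54

#: Plausibility bounds enforced after a pattern fires.  Values outside these
#: ranges are treated as non-anthropometric numbers and omitted.
AGE_BOUNDS = (13, 99)
WEIGHT_BOUNDS_LB = (50.0, 700.0)
HEIGHT_BOUNDS_IN = (36.0, 90.0)


class InquiryTerm(str, Enum):
    """Closed vocabulary of weight-inquiry terms."""

    SKINNY = "skinny"
    THIN = "thin"
    FAT = "fat"
    OBESE = "obese"


#: Sentinel returned when a post matches more than one distinct inquiry term.
#: Such posts are excluded downstream rather than assigned a term.
MULTI_TERM = "multiple"

_INQUIRY_RE = re.compile(r"\bam\s+i\s+(skinny|thin|fat|obese)\b", re.IGNORECASE)

_BULLY_RE = re.compile(r"\bbull(?:y|ies|ied|ying)\b", re.IGNORECASE)

# --- anthropometric patterns -------------------------------------------------
# Weight requires an explicit unit suffix.
_WEIGHT_LB_RE = re.compile(
    r"\b(\d{2,3}(?:\.\d+)?)\s*(?:lbs?\b\.?|pounds?\b)", re.IGNORECASE
)
_WEIGHT_KG_RE = re.compile(
    r"\b(\d{2,3}(?:\.\d+)?)\s*(?:kgs?\b|kilos?\b|kilograms?\b)", re.IGNORECASE
)

# Height: feet/inches forms or explicit centimetres; bare numbers never count.
_HEIGHT_FT_IN_RE = re.compile(
    r"\b(\d)\s*(?:'|’|ft\b\.?|foot\b|feet\b)\s*(\d{1,2})"
    r"(?:\s*(?:\"|”|''|in\b\.?|inch(?:es)?\b))?",
    re.IGNORECASE,
)
_HEIGHT_FT_ONLY_RE = re.compile(
    r"\b(\d)\s*(?:ft\b\.?|foot\b|feet\b)(?!\s*\d)", re.IGNORECASE
)
_HEIGHT_CM_RE = re.compile(r"\b(\d{2,3}(?:\.\d+)?)\s*cm\b", re.IGNORECASE)

# Age: "<n> years old" variants, or a guarded "I am <n>" with no measurement
# context following the number.
_AGE_YEARS_RE = re.compile(
    r"\b(\d{1,2})\s*(?:years?[-\s]*old\b|y/?o\b|yrs?[-\s]*old\b)", re.IGNORECASE
)
_AGE_I_AM_RE = re.compile(
    r"\bI\s*(?:am|'m)\s+(\d{1,2})\b"
    r"(?!\s*(?:'|’|\"|ft\b|foot\b|feet\b|in\b|inch|cm\b|kg\b|lbs?\b|pounds?\b|%))",
    re.IGNORECASE,
)

_MALE_RE = re.compile(r"\b(?:male|man|boy|guy)\b", re.IGNORECASE)
_FEMALE_RE = re.compile(r"\b(?:female|woman|girl)\b", re.IGNORECASE)


@dataclass
class ExtractedProfile:
    """Anthropometrics parsed from one post; absence is an explicit state.

    Heights are normalised to inches, weights to pounds, ages to integer
    years.  ``provenance`` maps each populated field to the character span
    of the text that produced it.
    """

    age: Optional[int] = None
    gender: Optional[str] = None  # "male" | "female"
    weight: Optional[float] = None  # pounds
    height: Optional[float] = None  # inches
    provenance: dict = field(default_factory=dict)

    FIELDS = ("age", "gender", "weight", "height")

    def complete(self) -> bool:
        return all(getattr(self, f) is not None for f in self.FIELDS)


def match_inquiry(text: str) -> Optional[str]:
    """Find the literal ``"am I <term>?"`` phrase (case-insensitive).

    Returns the matched :class:`InquiryTerm` value, :data:`MULTI_TERM` if the
    text matches more than one distinct term, or ``None`` if no term matches.
    """
    terms = {m.group(1).lower() for m in _INQUIRY_RE.finditer(text)}
    if not terms:
        return None
    if len(terms) > 1:
        return MULTI_TERM
    return InquiryTerm(terms.pop()).value


def match_bullying(text: str) -> bool:
    """True iff the text explicitly mentions bullying (word-boundary match).

    This is a term matcher only: it intentionally admits false positives
    (e.g. a post about a dog bullying another dog), which a downstream
    annotation step resolves.
    """
    return bool(_BULLY_RE.search(text))


def _in_bounds(value: float, bounds: tuple) -> bool:
    return bounds[0] <= value <= bounds[1]


def extract_profile(text: str) -> ExtractedProfile:
    """Parse age, gender, weight and height from free text.

    Each field is populated only when a pattern with explicit unit/keyword
    context fires and the value is physiologically plausible; conflicting or
    ambiguous mentions leave the field absent.
    """
    prof = ExtractedProfile()

    m = _WEIGHT_LB_RE.search(text)
    if m:
        w = float(m.group(1))
        if _in_bounds(w, WEIGHT_BOUNDS_LB):
            prof.weight = w
            prof.provenance["weight"] = m.span()
    else:
        m = _WEIGHT_KG_RE.search(text)
        if m:
            w = float(m.group(1)) * KG_TO_LB
            if _in_bounds(w, WEIGHT_BOUNDS_LB):
                prof.weight = round(w, 1)
                prof.provenance["weight"] = m.span()

    m = _HEIGHT_FT_IN_RE.search(text)
    if m:
        h = int(m.group(1)) * 12 + int(m.group(2))
        if _in_bounds(h, HEIGHT_BOUNDS_IN):
            prof.height = float(h)
            prof.provenance["height"] = m.span()
    else:
        m = _HEIGHT_CM_RE.search(text)
        if m:
            h = float(m.group(1)) * CM_TO_IN
            if _in_bounds(h, HEIGHT_BOUNDS_IN):
                prof.height = round(h, 1)
                prof.provenance["height"] = m.span()
        else:
            m = _HEIGHT_FT_ONLY_RE.search(text)
            if m:
                h = int(m.group(1)) * 12
                if _in_bounds(h, HEIGHT_BOUNDS_IN):
                    prof.height = float(h)
                    prof.provenance["height"] = m.span()

    m = _AGE_YEARS_RE.search(text) or _AGE_I_AM_RE.search(text)
    if m:
        a = int(m.group(1))
        if _in_bounds(a, AGE_BOUNDS):
            prof.age = a
            prof.provenance["age"] = m.span()

    male = _MALE_RE.search(text)
    female = _FEMALE_RE.search(text)
    if male and not female:
        prof.gender = "male"
        prof.provenance["gender"] = male.span()
    elif female and not male:
        prof.gender = "female"
        prof.provenance["gender"] = female.span()
    # both or neither -> omitted (ambiguous)

    return prof


@dataclass
class ExtractionValidationReport:
    """Per-field accounting of a manual-style validation of the extractor.

    For each field: ``correct + errors + omissions == sample_n``.  An
    omission is a field present in the truth but absent from the extraction;
    an error is a present field whose value disagrees with the truth.
    ``mean_abs_error`` is the mean absolute deviation among numeric errors.
    """

    sample_n: int
    correct: dict
    errors: dict
    omissions: dict
    mean_abs_error: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in ExtractedProfile.FIELDS:
            rows.append(
                {
                    "field": f,
                    "correct": self.correct[f],
                    "errors": self.errors[f],
                    "omissions": self.omissions[f],
                    "mean_abs_error": self.mean_abs_error[f],
                }
            )
        return pd.DataFrame(rows)


def validate_extraction(
    posts: pd.DataFrame,
    truth: pd.DataFrame,
    sample_n: int,
    rng: np.random.Generator,
) -> ExtractionValidationReport:
    """Compare the extractor with ground truth on a random sample of posts.

    ``posts`` must carry ``post_id`` and the rendered text (``title`` and
    ``body``); ``truth`` must carry ``post_id`` and the true ``age``,
    ``gender``, ``weight``, ``height``.  Numeric comparisons use a 0.5-unit
    tolerance to absorb rounding in unit conversion.
    """
    if sample_n > len(posts):
        raise ValueError(
            f"sample_n={sample_n} exceeds corpus size {len(posts)}"
        )
    idx = rng.choice(len(posts), size=sample_n, replace=False)
    sample = posts.iloc[np.sort(idx)]
    truth_by_id = truth.set_index("post_id")

    correct = {f: 0 for f in ExtractedProfile.FIELDS}
    errors = {f: 0 for f in ExtractedProfile.FIELDS}
    omissions = {f: 0 for f in ExtractedProfile.FIELDS}
    abs_errs: dict = {f: [] for f in ExtractedProfile.FIELDS}

    for _, row in sample.iterrows():
        text = f"{row['title']} {row['body']}"
        prof = extract_profile(text)
        t = truth_by_id.loc[row["post_id"]]
        for f in ExtractedProfile.FIELDS:
            true_val = t[f]
            got = getattr(prof, f)
            if got is None:
                omissions[f] += 1
            elif f == "gender":
                if got == true_val:
                    correct[f] += 1
                else:
                    errors[f] += 1
            else:
                if abs(float(got) - float(true_val)) <= 0.5:
                    correct[f] += 1
                else:
                    errors[f] += 1
                    abs_errs[f].append(abs(float(got) - float(true_val)))

    mae = {
        f: (float(np.mean(v)) if v else float("nan")) for f, v in abs_errs.items()
    }
    return ExtractionValidationReport(
        sample_n=sample_n,
        correct=correct,
        errors=errors,
        omissions=omissions,
        mean_abs_error=mae,
    )


def load_dialect_table() -> dict:
    """Load the versioned dialect inventory used by the corpus renderer."""
    with resources.files("weightask.data").joinpath("dialects.yaml").open() as fh:
        return yaml.safe_load(fh)
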