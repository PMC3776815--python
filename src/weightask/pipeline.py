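"""End-to-end pipeline stages: simulate, extract, classify, analyze, report.

Each stage is a plain function over DataFrames, reading and writing the
standard artifacts (JSONL corpus/truth, CSV tables) so the click CLI is a
thin wrapper.  Every written artifact carries a provenance header (config
hash, seed, package version) as a leading comment line where the format
allows it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional, Tuple

import pandas as pd

from . import __version__
from .classification import (
    AskerRecord,
    build_asker_table,
    load_lms_table,
)
from .config import INQUIRY_CATEGORY, RunConfig
from .extraction import (
    MULTI_TERM,
    extract_profile,
    match_bullying,
    match_inquiry,
)
from .posting import bullying_association, category_overexpression
from .county import (
    accuracy_by_county,
    bullying_fraction_curve,
    fit_curve_quadratic,
    income_bullying_association,
    link_counties,
)
from .synthetic import generate_corpus, write_posts_jsonl, write_truth_jsonl

log = logging.getLogger(__name__)

__all__ = [
    "provenance_header",
    "run_simulate",
    "extract_corpus",
    "build_asker_records",
    "run_analyze",
    "summary_report",
]


def provenance_header(config: RunConfig) -> str:
    digest = hashlib.sha256(
        json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    ).hexdigest()[:12]
    return f"# weightask {__version__} seed={config.seed} config={digest}"


def run_simulate(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Generate the corpus and write corpus/truth/county/zip-map artifacts."""
    out = out_dir or config.out_dir
    os.makedirs(out, exist_ok=True)
    syn = config.synthetic.model_copy(update={"seed": config.synthetic.seed or config.seed})
    posts, truths = generate_corpus(syn)
    paths = {
        "corpus": os.path.join(out, config.corpus_path),
        "truth": os.path.join(out, config.truth_path),
        "counties": os.path.join(out, config.county_path),
        "zip_map": os.path.join(out, config.zip_map_path),
    }
    write_posts_jsonl(posts, paths["corpus"])
    write_truth_jsonl(truths, paths["truth"])
    counties = pd.DataFrame(
        [
            {
                "county_id": c.county_id,
                "obesity_pct": c.obesity_pct,
                "median_income": c.median_income,
            }
            for c in syn.county_table
        ]
    )
    counties.to_csv(paths["counties"], index=False)
    zmap = pd.DataFrame(
        [
            {"zip": z, "county_id": c.county_id}
            for c in syn.county_table
            for z in c.zips
        ]
    )
    zmap.to_csv(paths["zip_map"], index=False)
    log.info("simulate: %d posts, %d askers", len(posts), len(truths))
    return {"paths": paths, "n_posts": len(posts), "n_askers": len(truths)}


def extract_corpus(posts: pd.DataFrame, max_malformed_frac: float = 0.01) -> pd.DataFrame:
    """Run the matchers and the profile extractor over every post.

    Returns one row per post with the inquiry term (or the multi-term
    marker), the parsed profile fields, and the bullying-mention flag.
    """
    rows = []
    n_malformed = 0
    for rec in posts.to_dict("records"):
        title, body = rec.get("title"), rec.get("body")
        if not isinstance(title, str) or not isinstance(body, str):
            n_malformed += 1
            continue
        text = f"{title} {body}"
        prof = extract_profile(text)
        rows.append(
            {
                "post_id": rec["post_id"],
                "user_id": rec["user_id"],
                "timestamp": rec["timestamp"],
                "category": rec["category"],
                "zip": rec.get("zip", ""),
                "term": match_inquiry(text),
                "age": prof.age,
                "gender": prof.gender,
                "weight": prof.weight,
                "height": prof.height,
                "bullying_mention": match_bullying(text),
            }
        )
    if n_malformed:
        frac = n_malformed / max(len(posts), 1)
        if frac > max_malformed_frac:
            raise ValueError(
                f"{n_malformed} malformed posts ({frac:.1%}) exceed the "
                f"{max_malformed_frac:.0%} tolerance"
            )
        log.warning("skipped %d malformed posts", n_malformed)
    return pd.DataFrame(rows)


def build_asker_records(
    extraction: pd.DataFrame,
    lms_table: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble retained asker records and the exclusion accounting.

    A user is retained iff they asked in exactly one weight category (no
    multi-term posts, no posts matching several distinct terms) and their
    earliest inquiry post yields a complete profile (age, gender, weight,
    height all parsed).  Returns (records, accounting); accounting counts
    extracted / excluded / retained users per term.
    """
    if lms_table is None:
        lms_table = load_lms_table()
    inq = extraction[extraction["term"].notna()].copy()
    inq = inq.sort_values(["user_id", "timestamp", "post_id"])

    extracted_counts = {t: 0 for t in ("skinny", "thin", "fat", "obese")}
    retained_counts = dict.fromkeys(extracted_counts, 0)
    records = []
    for user_id, sub in inq.groupby("user_id", sort=True):
        terms = set(sub["term"])
        for t in terms & set(extracted_counts):
            extracted_counts[t] += 1
        if MULTI_TERM in terms or len(terms) != 1:
            continue
        term = terms.pop()
        first = sub.iloc[0]
        if any(pd.isna(first[f]) for f in ("age", "gender", "weight", "height")):
            continue
        try:
            rec = AskerRecord.from_profile(
                user_id,
                term,
                int(first["age"]),
                str(first["gender"]),
                float(first["weight"]),
                float(first["height"]),
                lms_table=lms_table,
            )
        except ValueError:
            continue  # implausible combination (e.g. BMI outside support)
        retained_counts[term] += 1
        records.append(
            {
                "user_id": rec.user_id,
                "term": rec.term,
                "term_class": "high" if rec.term in ("fat", "obese") else "low",
                "age": rec.age,
                "gender": rec.gender,
                "weight": rec.weight,
                "height": rec.height,
                "bmi": rec.bmi,
                "age_class": rec.age_class,
                "actual_category": rec.actual_category,
                "actual_class3": rec.actual_class3,
                "congruent": rec.congruent,
                "zip": str(first["zip"]),
                "t0": first["timestamp"],
            }
        )
    acc_rows = [
        {
            "term": t,
            "extracted": extracted_counts[t],
            "excluded": extracted_counts[t] - retained_counts[t],
            "retained": retained_counts[t],
        }
        for t in extracted_counts
    ]
    acc = pd.DataFrame(acc_rows)
    acc.loc[len(acc)] = {
        "term": "total",
        "extracted": acc["extracted"].sum(),
        "excluded": acc["excluded"].sum(),
        "retained": acc["retained"].sum(),
    }
    return pd.DataFrame(records), acc


def bullying_flags(extraction: pd.DataFrame, records: pd.DataFrame) -> pd.Series:
    """Per-user flag: posted a bullying-mentioning question after the inquiry."""
    t0 = pd.to_datetime(records.set_index("user_id")["t0"])
    posts = extraction[extraction["user_id"].isin(t0.index)].copy()
    posts = posts[posts["bullying_mention"]]
    posts = posts[pd.to_datetime(posts["timestamp"]) > posts["user_id"].map(t0)]
    flagged = set(posts["user_id"])
    return pd.Series(
        {u: (u in flagged) for u in records["user_id"]}, dtype=bool
    )


def run_analyze(
    records: pd.DataFrame,
    extraction: pd.DataFrame,
    counties: pd.DataFrame,
    zip_map: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Run over-expression, bullying, and county analyses on asker records."""
    opts = config.analysis
    future = extraction[extraction["category"] != INQUIRY_CATEGORY]
    over = category_overexpression(
        records,
        future,
        q_threshold=opts.fdr_threshold,
        fdr_family=opts.fdr_family,
    )
    flags = bullying_flags(extraction, records)
    bully = bullying_association(records, flags)

    linked = records.copy()
    linked["bullying"] = linked["user_id"].map(flags).astype(bool)
    linked = link_counties(linked, zip_map, counties)
    curves = bullying_fraction_curve(linked, n_bins=opts.n_bins)
    curve_fit = fit_curve_quadratic(curves["overall"])
    accuracy = accuracy_by_county(linked, split=opts.county_split)
    income = income_bullying_association(linked, n_quantiles=opts.income_quantiles)
    return {
        "overexpression": over,
        "bullying": bully,
        "linked": linked,
        "curves": curves,
        "curve_fit": curve_fit,
        "accuracy": accuracy,
        "income": income,
    }


def summary_report(records: pd.DataFrame, acc: pd.DataFrame, analysis: dict) -> str:
    """Human-readable aggregate summary of a full run."""
    lines = ["=== weightask run summary ==="]
    lines.append(f"retained askers: {len(records)}")
    lines.append("exclusion accounting:")
    lines.append(acc.to_string(index=False))
    tables = build_asker_table(
        [AskerRecord(**{  # reconstruct lightweight records for the table
            "user_id": r.user_id, "term": r.term, "age": int(r.age),
            "gender": r.gender, "weight": r.weight, "height": r.height,
            "bmi": r.bmi, "age_class": r.age_class,
            "actual_category": r.actual_category,
            "actual_class3": r.actual_class3, "congruent": bool(r.congruent),
        }) for r in records.itertuples(index=False)]
    )
    for name in ("age", "adult_bmi", "teen_pct"):
        lines.append(f"\n-- {name} x gender x term --")
        lines.append(tables[name].to_string())
    over = analysis.get("overexpression")
    if over is not None and not over.empty:
        sig = over[over["overexpressed"]]
        lines.append(f"\nover-expressed (stratum, category) pairs: {len(sig)}")
        if not sig.empty:
            lines.append(
                sig[["stratum", "category", "ratio", "q_value"]].to_string(index=False)
            )
    inter = analysis.get("bullying", {}).get("interaction")
    if inter:
        lines.append(
            f"\nbullying gender x term interaction: G2={inter['statistic']:.2f} "
            f"df={inter['df']} p={inter['p_value']:.3g}"
        )
    fit = analysis.get("curve_fit", {})
    if fit.get("coefficients") is not None:
        lines.append(f"bullying-curve curvature: {fit['curvature']:.3g}")
    inc = analysis.get("income", {})
    if inc.get("evaluable"):
        lines.append(
            f"income-bullying direction: {inc['direction']} "
            f"(slope/10k={inc['logistic_slope_per_10k']:.3g}, "
            f"trend p={inc['trend_p']:.3g})"
        )
    return "\n".join(lines)
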