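"""Posting-ratio statistic, BH-FDR, over-expression screen, bullying tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from weightask.posting import (
    Stratum,
    bh_fdr,
    bullying_association,
    category_overexpression,
    posting_ratio,
)

CATEGORIES = [f"cat{i:02d}" for i in range(12)]
T0 = "2012-01-01T00:00:00"
LATER = "2012-06-01T00:00:00"


def make_records(n, rng, female_frac=0.5, overweight_frac=0.2, terms=None):
    gender = np.where(rng.random(n) < female_frac, "female", "male")
    r = rng.random(n)
    cls = np.where(r < 0.1, "underweight",
                   np.where(r < 1 - overweight_frac, "normal", "overweight"))
    term = rng.choice(terms or ["skinny", "thin", "fat", "obese"], size=n)
    return pd.DataFrame(
        {
            "user_id": [f"u{i}" for i in range(n)],
            "gender": gender,
            "actual_class3": cls,
            "term": term,
            "term_class": np.where(np.isin(term, ["fat", "obese"]), "high", "low"),
            "t0": T0,
        }
    )


def make_posts(records, rng, baseline=0.01, effects=None):
    """effects: {(gender, class3, category): multiplier}"""
    effects = effects or {}
    rows = []
    for cat in CATEGORIES:
        p = np.full(len(records), baseline)
        for (g, c, ecat), m in effects.items():
            if ecat == cat:
                mask = (records["gender"] == g) & (records["actual_class3"] == c)
                p[mask.to_numpy()] *= m
        hit = rng.random(len(records)) < p
        for uid in records.loc[hit, "user_id"]:
            rows.append({"user_id": uid, "timestamp": LATER, "category": cat})
    return pd.DataFrame(rows, columns=["user_id", "timestamp", "category"])


class TestPostingRatio:
    def test_self_comparison_is_exactly_one(self):
        r = posting_ratio(17, 400, 17, 400, "cat")
        assert r.ratio == 1.0

    def test_hand_arithmetic(self):
        r = posting_ratio(10, 100, 20, 1000, "cat")
        assert r.ratio == pytest.approx(5.0)
        assert 0 <= r.p_value < 1e-4  # 10/100 vs pooled 2% is wildly unlikely

    def test_zero_pooled_not_evaluable(self):
        r = posting_ratio(0, 10, 0, 100, "cat")
        assert not r.evaluable and np.isnan(r.ratio)

    @pytest.mark.parametrize("ks,ns,ka,na", [(1, 0, 1, 10), (1, 20, 1, 10)])
    def test_bad_counts_rejected(self, ks, ns, ka, na):
        with pytest.raises(ValueError):
            posting_ratio(ks, ns, ka, na, "cat")


def bh_oracle(p_values, q_threshold=0.05):
    """Brute-force BH step-up: q_i = min_{j>=i} m*p_(j)/(j+1), capped at 1."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    # tolerance keeps q == threshold decisions stable across op orderings
    return q, q <= q_threshold * (1 + 1e-9)


class TestBHFDR:
    def test_all_ones_nothing_significant(self):
        q, sig = bh_fdr([1.0] * 5)
        assert not sig.any() and (q == 1.0).all()

    def test_single_test_is_unadjusted(self):
        q, sig = bh_fdr([0.04])
        assert q[0] == pytest.approx(0.04) and sig[0]

    def test_three_value_example(self):
        q, _ = bh_fdr([0.01, 0.02, 0.30])
        assert q == pytest.approx([0.03, 0.03, 0.30])

    def test_empty_input(self):
        q, sig = bh_fdr([])
        assert len(q) == 0 and len(sig) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_exhaustive_small_grids_match_oracle(self):
        """BH equals the brute-force step-up on a dense grid of p-vectors."""
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 0.8, 1.0]
        for m in (1, 2, 3):
            for combo in itertools.product(grid, repeat=m):
                q, sig = bh_fdr(list(combo))
                q_exp, sig_exp = bh_oracle(list(combo))
                assert np.allclose(q, q_exp), combo
                assert (sig == sig_exp).all(), combo

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    def test_random_vectors_match_oracle(self, ps):
        q, sig = bh_fdr(ps)
        q_exp, sig_exp = bh_oracle(ps)
        assert np.allclose(q, q_exp)
        assert (sig == sig_exp).all()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=8))
    def test_q_at_least_p_and_monotone_in_sorted_order(self, ps):
        q, _ = bh_fdr(ps)
        p = np.asarray(ps)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestOverexpression:
    def test_pooled_stratum_ratio_is_one(self, rng):
        records = make_records(500, rng)
        posts = make_posts(records, rng, baseline=0.05)
        out = category_overexpression(records, posts, strata=[Stratum()])
        ev = out[out["evaluable"]]
        assert (ev["ratio"] == 1.0).all()

    def test_stratum_without_posts_has_no_overexpression(self, rng):
        records = make_records(300, rng)
        posts = make_posts(records, rng, baseline=0.05)
        posts = posts[
            ~posts["user_id"].isin(
                records.loc[records["actual_class3"] == "overweight", "user_id"]
            )
        ]
        out = category_overexpression(records, posts)
        sub = out[out["stratum"].str.contains("overweight") & out["evaluable"]]
        assert not sub["overexpressed"].any()

    def test_null_screen_controls_fdr(self):
        """Across 100 null replicates the screen flags at most ~5% of tests."""
        rng = np.random.default_rng(17)
        flagged = total = 0
        for _ in range(100):
            records = make_records(2000, rng)
            posts = make_posts(records, rng, baseline=0.02)
            out = category_overexpression(records, posts)
            ev = out[out["evaluable"]]
            flagged += int(ev["significant"].sum())
            total += len(ev)
        assert total > 5000
        assert flagged / total <= 0.05

    def test_planted_effects_detected_with_power(self):
        """Planted multipliers are flagged (and only they are, mostly) in at
        least 90% of replicates at n = 20,000."""
        rng = np.random.default_rng(23)
        effects = {
            ("male", "overweight", "cat03"): 4.6,
            ("female", "overweight", "cat07"): 3.1,
        }
        hits_a = hits_b = 0
        reps = 10
        for _ in range(reps):
            records = make_records(20_000, rng)
            posts = make_posts(records, rng, baseline=0.01, effects=effects)
            out = category_overexpression(records, posts)
            key = out.set_index(["stratum", "category"])["overexpressed"]
            hits_a += bool(key.get(("gender=male&actual_class3=overweight", "cat03"), False))
            hits_b += bool(key.get(("gender=female&actual_class3=overweight", "cat07"), False))
        assert hits_a >= 9
        assert hits_b >= 9


class TestBullyingAssociation:
    def test_all_false_no_test(self, rng):
        records = make_records(200, rng)
        flags = pd.Series(False, index=records["user_id"])
        out = bullying_association(records, flags)
        assert out["interaction"] is None
        assert (out["fractions"]["fraction"] == 0).all()

    def test_two_by_two_chi2_matches_hand_value(self):
        """20/1000 vs 6/1000: chi-squared 7.6378 (closed form), p ~ 0.0057."""
        rng = np.random.default_rng(0)
        n = 1000
        recs = pd.DataFrame(
            {
                "user_id": [f"u{i}" for i in range(2 * n)],
                "gender": ["male"] * n + ["female"] * n,
                "term": ["fat"] * 2 * n,
                "actual_class3": "normal",
                "term_class": "high",
                "t0": T0,
            }
        )
        flags = pd.Series(
            [True] * 20 + [False] * (n - 20) + [True] * 6 + [False] * (n - 6),
            index=recs["user_id"],
        )
        from scipy.stats import chi2_contingency

        tab = np.array([[20, 980], [6, 994]])
        chi2, p, _, _ = chi2_contingency(tab, correction=False)
        # hand arithmetic: N(ad-bc)^2 / (row1*row2*col1*col2)
        hand = 2000 * (20 * 994 - 980 * 6) ** 2 / (1000 * 1000 * 26 * 1974)
        assert chi2 == pytest.approx(hand)
        assert hand == pytest.approx(7.6378, abs=1e-3)
        out = bullying_association(recs, flags)
        frac = out["fractions"].set_index(["gender", "term"])["fraction"]
        assert frac[("male", "fat")] == pytest.approx(0.020)
        assert frac[("female", "fat")] == pytest.approx(0.006)

    def test_planted_interaction_recovered(self):
        """Male 'obese' askers bully-post at 1.8%, male 'fat' at 0.6%,
        females flat: fractions recovered and interaction p < 0.05 in >=90%
        of replicates.  The planted contrast is between the two high terms,
        so only fat/obese askers enter (a 2x2x2 design)."""
        probs = {
            ("male", "fat"): 0.006, ("male", "obese"): 0.018,
            ("female", "fat"): 0.024, ("female", "obese"): 0.024,
        }
        rng = np.random.default_rng(31)
        sig = 0
        reps = 10
        last = None
        for _ in range(reps):
            records = make_records(20_000, rng, terms=["fat", "obese"])
            p = np.array([probs[(g, t)] for g, t in
                          zip(records["gender"], records["term"])])
            flags = pd.Series(rng.random(len(records)) < p,
                              index=records["user_id"].to_numpy())
            out = bullying_association(records, flags)
            sig += out["interaction"]["p_value"] < 0.05
            last = out
        assert sig >= 9
        frac = last["fractions"].set_index(["gender", "term"])
        for (g, t), p_true in probs.items():
            row = frac.loc[(g, t)]
            se = np.sqrt(p_true * (1 - p_true) / row["n"])
            assert abs(row["fraction"] - p_true) < 4 * se
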