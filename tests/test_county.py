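"""County linkage, bullying-fraction curve, accuracy split, income gradient."""

import numpy as np
import pandas as pd
import pytest

from weightask.county import (
    abs_deviation_transform,
    accuracy_by_county,
    bullying_fraction_curve,
    fit_curve_quadratic,
    income_bullying_association,
    link_counties,
    odds_ratio_2x2,
)

N_COUNTIES = 30


def county_frame():
    obesity = np.linspace(15, 45, N_COUNTIES)
    income = 70000 - 1200 * (obesity - 15)
    return pd.DataFrame(
        {
            "county_id": [f"C{i:03d}" for i in range(N_COUNTIES)],
            "obesity_pct": obesity,
            "median_income": income,
        }
    )


def zip_frame():
    return pd.DataFrame(
        {"zip": [f"{20000 + i}" for i in range(N_COUNTIES)],
         "county_id": [f"C{i:03d}" for i in range(N_COUNTIES)]}
    )


def linked_records(n, rng, bully_prob=None, congruent_prob=None):
    """Directly build county-linked asker records with planted outcomes.

    bully_prob / congruent_prob: callables of (county obesity, income,
    gender, class3, term_class) -> probability; defaults are flat.
    """
    counties = county_frame()
    idx = rng.integers(0, N_COUNTIES, n)
    gender = np.where(rng.random(n) < 0.5, "female", "male")
    r = rng.random(n)
    cls = np.where(r < 0.1, "underweight", np.where(r < 0.75, "normal", "overweight"))
    term_class = np.where(rng.random(n) < 0.6, "high", "low")
    obesity = counties["obesity_pct"].to_numpy()[idx]
    income = counties["median_income"].to_numpy()[idx]

    def draw(fn, default):
        if fn is None:
            p = np.full(n, default)
        else:
            p = np.array([
                fn(o, m, g, c, t)
                for o, m, g, c, t in zip(obesity, income, gender, cls, term_class)
            ])
        return rng.random(n) < p

    return pd.DataFrame(
        {
            "user_id": [f"u{i}" for i in range(n)],
            "gender": gender,
            "actual_class3": cls,
            "term_class": term_class,
            "county_id": counties["county_id"].to_numpy()[idx],
            "obesity_pct": obesity,
            "median_income": income,
            "linked": True,
            "bullying": draw(bully_prob, 0.03),
            "congruent": draw(congruent_prob, 0.6),
        }
    )


class TestLinkCounties:
    def test_round_trip_on_generated_corpus(self, clean_records, clean_corpus):
        cfg, _, truth = clean_corpus
        _, records, _ = clean_records
        counties = pd.DataFrame(
            [{"county_id": c.county_id, "obesity_pct": c.obesity_pct,
              "median_income": c.median_income} for c in cfg.county_table]
        )
        zmap = pd.DataFrame(
            [{"zip": z, "county_id": c.county_id}
             for c in cfg.county_table for z in c.zips]
        )
        out = link_counties(records, zmap, counties)
        assert out["linked"].all()
        truth_county = truth.set_index("user_id")["county_id"]
        assert (out.set_index("user_id")["county_id"] ==
                truth_county.loc[out["user_id"]]).all()
        by_county = counties.set_index("county_id")["obesity_pct"]
        assert (out["obesity_pct"].to_numpy() ==
                by_county.loc[out["county_id"]].to_numpy()).all()

    def test_empty_map_all_unlinked(self, rng):
        records = pd.DataFrame({"user_id": ["u1"], "zip": ["99999"]})
        out = link_counties(records, zip_frame().iloc[:0], county_frame())
        assert not out["linked"].any()

    def test_duplicate_zip_first_wins(self):
        records = pd.DataFrame({"user_id": ["u1"], "zip": ["20000"]})
        zmap = pd.DataFrame(
            {"zip": ["20000", "20000"], "county_id": ["C000", "C001"]}
        )
        out = link_counties(records, zmap, county_frame())
        assert out.loc[0, "county_id"] == "C000"


class TestAbsDeviation:
    def test_hand_example(self):
        assert abs_deviation_transform([20, 30, 40]).tolist() == [10.0, 0.0, 10.0]

    def test_all_equal_all_zero(self):
        assert (abs_deviation_transform([7.5] * 4) == 0).all()

    def test_shift_invariance(self, rng):
        x = rng.uniform(10, 50, 25)
        assert np.allclose(
            abs_deviation_transform(x), abs_deviation_transform(x + 13.7)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            abs_deviation_transform([])


class TestBullyingCurve:
    def test_conservation_and_partition(self, rng):
        records = linked_records(4000, rng)
        curves = bullying_fraction_curve(records, n_bins=8)
        total = sum(b.n_askers for b in curves["overall"])
        assert total == len(records)
        for lo_bin, hi_bin, all_bin in zip(
            curves["low"], curves["high"], curves["overall"]
        ):
            assert lo_bin.n_askers + hi_bin.n_askers == all_bin.n_askers
            assert lo_bin.n_bullying + hi_bin.n_bullying == all_bin.n_bullying

    def test_flat_probability_gives_flat_curve(self, rng):
        records = linked_records(8000, rng)
        curves = bullying_fraction_curve(records, n_bins=5)
        for b in curves["overall"]:
            se = np.sqrt(0.03 * 0.97 / b.n_askers)
            assert abs(b.fraction - 0.03) < 4 * se

    def test_single_county_one_occupied_bin(self, rng):
        records = linked_records(200, rng)
        records["obesity_pct"] = 25.0
        curves = bullying_fraction_curve(records, n_bins=4)
        occupied = [b for b in curves["overall"] if b.n_askers > 0]
        assert len(occupied) == 1

    def test_too_few_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            bullying_fraction_curve(linked_records(50, rng), n_bins=2)

    def test_planted_ushape_recovered(self):
        """A quadratic per-county bullying probability yields positive fitted
        curvature in at least 90% of replicates."""
        rng = np.random.default_rng(5)
        mean_obs = 30.0

        def ushape(o, m, g, c, t):
            return 0.02 * (1 + 2.0 * ((o - mean_obs) / 15.0) ** 2)

        hits = 0
        for _ in range(10):
            records = linked_records(6000, rng, bully_prob=ushape)
            curves = bullying_fraction_curve(records, n_bins=8)
            fit = fit_curve_quadratic(curves["overall"])
            hits += fit["curvature"] > 0
        assert hits >= 9


class TestAccuracyByCounty:
    def test_single_county_skips_without_error(self, rng):
        records = linked_records(300, rng)
        records["obesity_pct"] = 25.0
        records["county_id"] = "C000"
        out = accuracy_by_county(records)
        assert out.empty or (out["n_high"] == 0).all()

    def test_null_type_one_error(self):
        """With identical congruence probability everywhere, the share of
        nominally significant comparisons stays near 5%."""
        rng = np.random.default_rng(9)
        sig = total = 0
        for _ in range(40):
            records = linked_records(2000, rng)
            out = accuracy_by_county(records)
            sub = out[out["outcome"] == "congruent"]
            sig += int((sub["p_value"] < 0.05).sum())
            total += len(sub)
        assert total >= 200
        # binomial slack around the nominal rate
        assert sig / total < 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)

    def test_planted_congruence_effect_detected(self):
        """Overweight women congruent more often in high-obesity counties:
        that cell flags significant in >=90% of replicates."""
        rng = np.random.default_rng(13)

        def shift(o, m, g, c, t):
            if g == "female" and c == "overweight" and o > 30:
                return 0.72
            return 0.60

        hits = 0
        for _ in range(10):
            records = linked_records(20_000, rng, congruent_prob=shift)
            out = accuracy_by_county(records)
            row = out[
                (out["gender"] == "female")
                & (out["actual_class3"] == "overweight")
                & (out["outcome"] == "congruent")
            ].iloc[0]
            hits += (row["p_value"] < 0.05) and (row["rate_high"] > row["rate_low"])
        assert hits >= 9

    def test_reports_high_term_composition_for_normal_weight(self, rng):
        records = linked_records(3000, rng)
        out = accuracy_by_county(records)
        comp = out[out["outcome"] == "asks_high_term"]
        assert set(comp["actual_class3"]) == {"normal"}


class TestIncomeBullying:
    def test_hand_odds_ratio(self):
        assert odds_ratio_2x2(100, 1000, 50, 1000) == pytest.approx(2.111, abs=1e-3)

    def test_degenerate_income_not_evaluable(self, rng):
        records = linked_records(100, rng)
        records["median_income"] = 50000.0
        assert income_bullying_association(records) == {"evaluable": False}

    def test_planted_negative_gradient_recovered(self):
        """Bullying odds falling with income: direction 'decreasing' and a
        significant trend in >=90% of replicates."""
        rng = np.random.default_rng(21)

        def grad(o, m, g, c, t):
            return 0.03 * np.exp(-0.4 * (m - 50000) / 1e4)

        hits = 0
        for _ in range(10):
            records = linked_records(8000, rng, bully_prob=grad)
            out = income_bullying_association(records)
            hits += (out["direction"] == "decreasing") and (out["trend_p"] < 0.05)
        assert hits >= 9

    def test_null_gradient_rarely_significant(self):
        rng = np.random.default_rng(27)
        sig = 0
        for _ in range(20):
            records = linked_records(2000, rng)
            out = income_bullying_association(records)
            sig += out["trend_p"] < 0.05
        assert sig <= 4
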