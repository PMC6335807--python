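"""Sperm counting, Fisher presence test, cluster-permutation contrasts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rbchain.fertility import (
    CONTRASTS,
    ClusteredComparison,
    FertilityError,
    average_chambers,
    clustered_group_compare,
    fisher_exact_2x2,
    litter_size_compare,
    scar_excess_summary,
    sperm_count_from_hemocytometer,
    sperm_presence_test,
    weeks_to_first_litter_test,
)


def enumeration_fisher_p(table):
    """Oracle: two-sided Fisher p by full enumeration of tables with the
    observed margins, summing hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestHemocytometer:
    def test_standard_ten_square_count(self):
        # 340 sperm over 10 x 0.04 mm^2 x 0.1 mm, diluted in 2 ml
        assert sperm_count_from_hemocytometer(340) == pytest.approx(1.7e7)

    def test_zero_seen_full_chamber(self):
        assert sperm_count_from_hemocytometer(0, n_squares=1, square_area_mm2=9.0) == 0

    def test_chamber_averaging(self):
        assert average_chambers([16e6, 18e6]) == pytest.approx(17e6)

    def test_linearity_and_volume_scaling(self):
        base = sperm_count_from_hemocytometer(100)
        assert sperm_count_from_hemocytometer(200) == pytest.approx(2 * base)
        assert sperm_count_from_hemocytometer(
            100, n_squares=20
        ) == pytest.approx(base / 2)

    def test_bad_geometry_rejected(self):
        with pytest.raises(FertilityError):
            sperm_count_from_hemocytometer(10, depth_mm=0)


class TestFisher:
    def test_perfect_separation_extreme_p(self, male_records):
        res = sperm_presence_test(male_records)
        # zero-sperm chain carriers vs sperm-positive others at colony scale
        (a, b), (c, d) = res.table
        assert a == 0 and d == 0
        assert res.p_value < 1e-15

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_against_enumeration_oracle_spot(self):
        table = [[1, 9], [9, 1]]
        assert fisher_exact_2x2(table) == pytest.approx(
            enumeration_fisher_p(table), rel=1e-9
        )

    def test_single_group_rejected(self, male_records):
        only_f1 = male_records[male_records["category"] == "F1"]
        with pytest.raises(FertilityError):
            sperm_presence_test(only_f1)


def _null_dataset(rng, n_categories=5, clusters_per_cat=4, per_cluster=3,
                  effect=0.0, effect_cat="F1", slope=0.5):
    cats = list(CONTRASTS and ("CHBU", "CHHN", "F1", "BC.23", "BC.24"))[:n_categories]
    rows = []
    cid = 0
    for cat in cats:
        for _ in range(clusters_per_cat):
            re = rng.normal(0, 0.5)
            for _ in range(per_cluster):
                x = rng.normal(0, 1)
                y = slope * x + re + rng.normal(0, 1)
                if cat == effect_cat:
                    y += effect
                rows.append(
                    {"category": cat, "parent_pair_id": f"c{cid}",
                     "body_mass": x, "response": y}
                )
            cid += 1
    return pd.DataFrame(rows)


class TestClusteredComparison:
    def test_identity_permutation_gives_p_one(self):
        df = _null_dataset(np.random.default_rng(0))
        res = clustered_group_compare(df, "response", n_permutations=0, seed=0)
        assert all(p == 1.0 for p in res.pvalues.values())

    def test_identical_groups_estimate_zero(self):
        rows = []
        for cat in ("F1", "CHHN"):
            for c in range(3):
                for v in (1.0, 2.0, 3.0):
                    rows.append({"category": cat, "parent_pair_id": f"{cat}{c}",
                                 "body_mass": v, "response": v})
        df = pd.DataFrame(rows)
        res = clustered_group_compare(
            df, "response", contrasts=[("F1", "CHHN")], n_permutations=10, seed=0
        )
        assert res.effects[("F1", "CHHN")] == pytest.approx(0.0, abs=1e-10)

    def test_single_cluster_category_rejected(self):
        df = _null_dataset(np.random.default_rng(0), clusters_per_cat=1)
        with pytest.raises(FertilityError, match="single cluster"):
            ClusteredComparison(df, "response")

    def test_cluster_spanning_categories_rejected(self):
        df = _null_dataset(np.random.default_rng(0))
        df.loc[df.index[:2], "parent_pair_id"] = df["parent_pair_id"].iloc[-1]
        with pytest.raises(FertilityError, match="span"):
            ClusteredComparison(df, "response")

    def test_power_at_large_shift(self):
        """A shift the size of the chain-carrier testis-mass deficit
        (~ -57 mg at ~10 mg residual SD) is detected essentially always."""
        rng = np.random.default_rng(42)
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            df = _null_dataset(rng, effect=-5.7, slope=0.5)  # -5.7 units on SD~1.1
            res = clustered_group_compare(
                df, "response", contrasts=[("F1", "CHHN")],
                n_permutations=199, seed=int(rng.integers(2**31)),
            )
            hits += res.pvalues[("F1", "CHHN")] <= 0.05
        assert hits / n_sim > 0.9

    def test_log10_response_requires_positive(self, male_records):
        with pytest.raises(FertilityError, match="positive"):
            clustered_group_compare(
                male_records, "sperm_count", n_permutations=5, log10_response=True
            )

    def test_summary_mentions_contrasts(self):
        df = _null_dataset(np.random.default_rng(1))
        res = clustered_group_compare(df, "response", n_permutations=19, seed=1)
        text = res.summary()
        assert "F1-CHHN" in text and "max-T" in text


class TestLitterAndScars:
    def test_litter_contrasts_detect_hybrid_deficit(self, female_records):
        res = litter_size_compare(female_records, n_permutations=399, seed=5)
        est = res.effects[("F1", "CHHN")]
        assert est < -3.5  # generated deficit is ~ -5.2 pups
        assert res.pvalues[("F1", "CHHN")] <= 0.05

    def test_scar_excess_summary_fraction(self):
        df = pd.DataFrame(
            {
                "female_id": [f"f{i}" for i in range(31)],
                "category": ["F1"] * 31,
                "total_offspring": [1] * 31,
                "scar_count": [5] * 22 + [1] * 9,
            }
        )
        s = scar_excess_summary(df)
        assert s["n_excess"] == 22
        assert s["fraction_excess"] == pytest.approx(22 / 31)

    def test_no_excess_when_scars_equal_offspring(self):
        df = pd.DataFrame(
            {
                "female_id": ["a", "b"],
                "category": ["BC.24", "BC.24"],
                "total_offspring": [7, 8],
                "scar_count": [7, 8],
            }
        )
        s = scar_excess_summary(df)
        assert s["fraction_excess"] == 0.0
        assert s["n_undercount_flagged"] == 0

    def test_undercount_flagged(self):
        df = pd.DataFrame(
            {
                "female_id": ["a"],
                "category": ["F1"],
                "total_offspring": [3],
                "scar_count": [2],
            }
        )
        assert scar_excess_summary(df)["n_undercount_flagged"] == 1

    def test_weeks_rank_sum_exact(self, female_records):
        w, p = weeks_to_first_litter_test(female_records, "BC.24", "F1")
        assert 0 <= p <= 1
        # BC.24 females reproduce sooner: their ranks should be low
        n1 = (female_records["category"] == "BC.24").sum()
        reproduced = female_records.dropna(subset=["weeks_to_first_litter"])
        n2 = (reproduced["category"] == "F1").sum()
        assert w < n1 * n2 / 2
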