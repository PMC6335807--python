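"""Balanced gamete enumeration, backcross prediction and breeding model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings

from rbchain.karyotype import ALL_ARMS, Karyotype, parse_karyotype
from rbchain.meiosis import configurations_from_cross
from rbchain.segregation import (
    NondisjunctionModel,
    SegregationError,
    SegregationModel,
    backcross_karyotype_distribution,
    enumerate_balanced_gametes,
    expected_litter_size,
    expected_scar_excess_per_fertilized,
    haploid_gamete,
    simulate_breeding,
    sterility_rule,
)
from test_karyotype import random_fusion_sets


def brute_force_balanced_sets(members):
    """Oracle: all sub-multisets of configuration members covering each
    of the configuration's arms exactly once."""
    arms = sorted({a for m in members for a in m.arms})
    out = []
    for r in range(len(members) + 1):
        for combo in itertools.combinations(members, r):
            got = sorted(a for m in combo for a in m.arms)
            if got == arms:
                out.append(frozenset(m.content for m in combo))
    return set(out)


class TestGameteEnumeration:
    def test_hybrid_has_exactly_two_classes(self, chbu, chhn):
        cfg = configurations_from_cross(chbu, chhn)
        classes = enumerate_balanced_gametes(cfg)
        assert len(classes) == 2
        contents = {g.chromosomes for g in classes}
        # the two classes are exactly the parental haploid sets
        assert haploid_gamete(chbu).chromosomes in contents
        assert haploid_gamete(chhn).chromosomes in contents
        assert sorted(g.haploid_count for g in classes) == [11, 12]

    def test_within_race_single_class(self, chhn):
        cfg = configurations_from_cross(chhn, chhn)
        classes = enumerate_balanced_gametes(cfg)
        assert len(classes) == 1
        assert classes[0].chromosomes == haploid_gamete(chhn).chromosomes

    def test_trivalent_classes_match_bruteforce(self, ancestral):
        race = parse_karyotype("1.3", name="R")
        cfg = configurations_from_cross(race, ancestral)
        (chain,) = cfg.chains()
        oracle = brute_force_balanced_sets(chain.members)
        got = {
            frozenset(
                c
                for c in g.chromosomes
                if not isinstance(c, str)
                and set(c.arms if hasattr(c, "arms") else [c]) <= {1, 3}
            )
            for g in enumerate_balanced_gametes(cfg)
        }
        assert got == oracle  # {1.3} and {1, 3}

    def test_odd_chain_classes_differ_by_one(self, chbu, chhn):
        classes = enumerate_balanced_gametes(configurations_from_cross(chbu, chhn))
        counts = sorted(g.haploid_count for g in classes)
        assert counts[1] - counts[0] == 1

    @settings(max_examples=30, derandomize=True)
    @given(fa=random_fusion_sets(), fb=random_fusion_sets())
    def test_balance_conservation_property(self, fa, fb):
        a = Karyotype(name="A", fusions=fa)
        b = Karyotype(name="B", fusions=fb)
        cfg = configurations_from_cross(a, b)
        classes = enumerate_balanced_gametes(cfg)
        for g in classes:
            counts = g.arm_counts()
            assert set(counts) == set(ALL_ARMS)
            assert all(v == 1 for v in counts.values())
            assert len(g.sex_chromosomes) == 1
        # 2^multivalents, collapsed for content-identical products
        assert len(classes) <= 2 ** max(len(cfg.multivalents()), 0) * 2
        assert len(classes) >= 1


class TestBackcross:
    def test_hybrid_backcross_distribution(self, chbu, chhn):
        classes = enumerate_balanced_gametes(configurations_from_cross(chbu, chhn))
        assert backcross_karyotype_distribution(classes, chhn) == {23: 0.5, 24: 0.5}

    def test_within_race_distribution(self, chhn):
        classes = enumerate_balanced_gametes(configurations_from_cross(chhn, chhn))
        assert backcross_karyotype_distribution(classes, chhn) == {24: 1.0}

    def test_trivalent_carrier_to_ancestral(self, ancestral):
        race = parse_karyotype("1.3", name="R")
        classes = enumerate_balanced_gametes(configurations_from_cross(race, ancestral))
        assert backcross_karyotype_distribution(classes, ancestral) == {
            39: 0.5,
            40: 0.5,
        }


class TestSterilityRule:
    def test_chain15_male_sterile(self, chbu, chhn):
        cfg = configurations_from_cross(chbu, chhn, "XY")
        assert sterility_rule(cfg, "XY") is False

    def test_bivalent_only_male_fertile(self, chhn):
        cfg = configurations_from_cross(chhn, chhn, "XY")
        assert sterility_rule(cfg, "XY") is True

    def test_female_never_sterile_by_rule(self, chbu, chhn):
        cfg = configurations_from_cross(chbu, chhn)
        assert sterility_rule(cfg, "XX") is True

    def test_short_chain_warns_about_extrapolation(self, ancestral):
        a = parse_karyotype("1.3", name="A")
        b = parse_karyotype("3.6", name="B")
        cfg = configurations_from_cross(a, b, "XY")
        with pytest.warns(UserWarning, match="extrapolates"):
            assert sterility_rule(cfg, "XY") is False


class TestBreedingSimulation:
    def test_no_loss_means_scars_equal_litters(self, chbu, chhn):
        cfg = configurations_from_cross(chbu, chhn)
        model = SegregationModel(nondisjunction_rate=0.0, baseline_loss=0.0)
        rec = simulate_breeding(cfg, chhn, model, n_females=50, seed=3)
        assert (rec["scars"] == rec["litter_size"]).all()

    def test_full_nondisjunction_kills_all_litters(self, chbu, chhn):
        cfg = configurations_from_cross(chbu, chhn)
        model = SegregationModel(nondisjunction_rate=1.0)
        rec = simulate_breeding(cfg, chhn, model, n_females=50, seed=3)
        assert (rec["litter_size"] == 0).all()
        assert rec["scars"].sum() > 0  # trisomic implantations remain

    def test_bivalent_only_carrier_ignores_rate(self, chhn):
        cfg = configurations_from_cross(chhn, chhn)
        model = SegregationModel(nondisjunction_rate=1.0, baseline_loss=0.0)
        rec = simulate_breeding(cfg, chhn, model, n_females=20, seed=3)
        assert (rec["litter_size"] == rec["scars"]).all()
        assert rec["litter_size"].sum() > 0

    def test_seed_reproducibility(self, chbu, chhn):
        cfg = configurations_from_cross(chbu, chhn)
        model = SegregationModel()
        a = simulate_breeding(cfg, chhn, model, n_females=10, seed=9)
        b = simulate_breeding(cfg, chhn, model, n_females=10, seed=9)
        assert a.equals(b)

    def test_simulation_matches_closed_form_expectations(self, chbu, chhn):
        """Law of large numbers against the analytic per-egg expectations."""
        cfg = configurations_from_cross(chbu, chhn)
        model = SegregationModel(nondisjunction_rate=0.6, baseline_loss=0.05)
        rec = simulate_breeding(cfg, chhn, model, n_females=10_000, seed=5)
        n = len(rec)
        excess = (rec["scars"] - rec["litter_size"]).to_numpy(float)
        fert = rec["fertilized"].to_numpy(float)
        e_close = expected_scar_excess_per_fertilized(model)
        resid = excess - e_close * fert
        se = resid.std(ddof=1) / np.sqrt(n) / fert.mean()
        assert abs(excess.sum() / fert.sum() - e_close) < 3 * se
        lit_se = rec["litter_size"].std(ddof=1) / np.sqrt(n)
        assert abs(rec["litter_size"].mean() - expected_litter_size(model)) < 3 * lit_se

    def test_invalid_model_rejected(self):
        with pytest.raises(SegregationError):
            SegregationModel(nondisjunction_rate=1.5)
        with pytest.raises(SegregationError):
            SegregationModel(ovulation_count=0)


class TestNondisjunctionEstimation:
    @pytest.mark.parametrize("rate", [0.1, 0.5, 0.9])
    def test_parameter_recovery(self, rate, chbu, chhn):
        cfg = configurations_from_cross(chbu, chhn)
        model = SegregationModel(nondisjunction_rate=rate, baseline_loss=0.05)
        rec = simulate_breeding(cfg, chhn, model, n_females=200,
                                cycles_per_female=5, seed=21)
        res = NondisjunctionModel(rec, baseline_loss=0.05).fit(seed=22)
        assert res.ci_lower <= rate <= res.ci_upper
        assert abs(res.estimate - rate) < 0.05

    def test_zero_rate_data(self, chbu, chhn):
        cfg = configurations_from_cross(chbu, chhn)
        model = SegregationModel(nondisjunction_rate=0.0, baseline_loss=0.0)
        rec = simulate_breeding(cfg, chhn, model, n_females=100, seed=7)
        res = NondisjunctionModel(rec, baseline_loss=0.0).fit(seed=8)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_records_flagged(self, chbu, chhn):
        cfg = configurations_from_cross(chbu, chhn)
        model = SegregationModel(nondisjunction_rate=1.0, fertilization_prob=0.0)
        rec = simulate_breeding(cfg, chhn, model, n_females=5, seed=1)
        res = NondisjunctionModel(rec).fit(n_boot=50, seed=2)
        assert res.undefined
        assert np.isnan(res.estimate)
        assert "undefined" in res.summary()
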