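"""Species ecological profiles, trophic scoring and groundwater influence."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rivaq import macrophytes as mp
from rivaq.errors import RivaqError


class TestRelativeSD:
    def test_constant_series_is_zero(self):
        assert mp.relative_sd([7.0, 7.0, 7.0]) == 0.0

    def test_two_value_hand_oracle(self):
        # sd = sqrt(50) = 7.0711, mean = 15 -> 47.14 %
        assert mp.relative_sd([10.0, 20.0]) == pytest.approx(47.140452, abs=1e-5)

    def test_scale_invariance(self):
        base = [8.0, 11.0, 14.0, 9.0]
        assert mp.relative_sd(base) == pytest.approx(
            mp.relative_sd([3.7 * v for v in base])
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(RivaqError, match="coefficient of variation"):
            mp.relative_sd([-1.0, 1.0])


class TestEquilibratedClasses:
    def test_ten_distinct_values_five_pairs(self):
        values = [3, 9, 1, 7, 5, 8, 2, 6, 4, 10]
        labels = mp.equilibrated_classes(values, 5)
        counts = np.bincount(labels)
        assert list(counts) == [2, 2, 2, 2, 2]
        # labels ordered by increasing value
        order = np.argsort(values)
        assert list(labels[order]) == sorted(labels)

    def test_four_classes_for_ammonia(self):
        labels = mp.equilibrated_classes(np.arange(36), 4)
        assert list(np.bincount(labels)) == [9, 9, 9, 9]

    def test_ties_fall_into_lower_class(self):
        # the two 5.0 values straddle a boundary; both must take the lower label
        values = [1.0, 2.0, 5.0, 5.0, 9.0, 10.0]
        labels = mp.equilibrated_classes(values, 3)
        assert labels[2] == labels[3] == 1

    def test_heavy_ties_match_invariant_checks(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 5, size=40).astype(float)
        labels = mp.equilibrated_classes(values, 5)
        # equal values share one label; labels monotone in value
        df = pd.DataFrame({"v": values, "l": labels}).sort_values("v")
        assert (df.groupby("v")["l"].nunique() == 1).all()
        assert df["l"].is_monotonic_increasing

    def test_invalid_class_count(self):
        with pytest.raises(RivaqError, match="invalid class count"):
            mp.equilibrated_classes([1, 2, 3], 1)


class TestSpeciesClassResponse:
    def _matrix(self, data):
        return pd.DataFrame(data)

    def test_uniform_species_not_significant(self):
        abund = self._matrix({"sp": [2.0] * 10})
        classes = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]
        profiles, _ = mp.species_class_response(abund, classes)
        prof = profiles["sp"]
        assert prof.weights == pytest.approx(np.full(5, 0.2))
        assert not prof.significant

    def test_concentrated_species_weight_one(self):
        col = [0.0] * 10
        for i in (8, 9):
            col[i] = 3.0
        abund = self._matrix({"sp": col + [0.0, 3.0, 3.0, 3.0]})
        classes = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 4, 4, 4, 4]
        profiles, _ = mp.species_class_response(abund, classes)
        assert profiles["sp"].weights[4] == pytest.approx(1.0)

    def test_occurrence_floor_excludes_rare_species(self):
        abund = self._matrix({"rare": [1.0, 1, 0, 0, 0, 0, 0, 0, 0, 0]})
        classes = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]
        profiles, excluded = mp.species_class_response(abund, classes)
        assert excluded == ["rare"] and profiles == {}

    def test_levene_gate_chooses_a_test(self, community, community_profiles):
        used = {p.test for p in community_profiles["ammonia_profiles"].values()}
        assert used <= {"anova", "kruskal", "degenerate"}
        assert "anova" in used or "kruskal" in used

    def test_planted_optima_recovered(self, community, community_profiles):
        """Argmax of the ammonia profile recovers each planted trophic
        optimum for at least 90% of indicator species."""
        truth = community.truth["species"]
        nprof = community_profiles["ammonia_profiles"]
        trophic_sp = truth[truth["kind"] == "trophic"].index
        hits = [
            int(np.argmax(nprof[sp].weights)) == truth.loc[sp, "optimum"]
            for sp in trophic_sp
            if sp in nprof
        ]
        assert len(hits) >= 20
        assert sum(hits) / len(hits) >= 0.9


class TestPhosphorusScore:
    def test_identical_sites_share_score(self):
        po4 = {"a": [0.1, 0.2], "b": [0.1, 0.2]}
        totp = {"a": [50.0], "b": [50.0]}
        scores = mp.phosphorus_score(po4, totp)
        assert scores["a"] == scores["b"]
        # z-component vanishes: score is the mean log10 PO4 alone
        assert scores["a"] == pytest.approx(np.mean(np.log10([0.1, 0.2])))

    def test_three_site_hand_oracle(self):
        po4 = {"a": [0.01, 0.01], "b": [0.1, 0.1], "c": [1.0, 1.0]}
        totp = {"a": [10.0], "b": [100.0], "c": [1000.0]}
        scores = mp.phosphorus_score(po4, totp)
        logs = np.log10([10.0, 100.0, 1000.0])
        z = (logs - logs.mean()) / logs.std(ddof=1)
        for site, lp, zi in zip("abc", [-2.0, -1.0, 0.0], z):
            assert scores[site] == pytest.approx(lp + zi)

    def test_raising_one_site_raises_its_rank(self):
        po4 = {"a": [0.01], "b": [0.02], "c": [0.04]}
        totp = {s: [50.0] for s in po4}
        before = mp.phosphorus_score(po4, totp).rank()
        po4["a"] = [0.08]
        after = mp.phosphorus_score(po4, totp).rank()
        assert after["a"] > before["a"]
        assert after["b"] < after["c"]

    def test_all_zero_rejected(self):
        with pytest.raises(RivaqError, match="no phosphorus signal"):
            mp.phosphorus_score({"a": [0.0], "b": [0.0]}, {"a": [1.0], "b": [1.0]})

    def test_zero_values_shifted_not_dropped(self):
        scores = mp.phosphorus_score(
            {"a": [0.0, 0.1], "b": [0.1, 0.1]}, {"a": [10.0], "b": [10.0]}
        )
        assert math.isfinite(scores["a"]) and scores["a"] < scores["b"]


FROZEN_5_TO_4 = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [0.25, 0.75, 0.0, 0.0],
        [0.0, 0.5, 0.5, 0.0],
        [0.0, 0.0, 0.75, 0.25],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


class TestCombineTrophicProfile:
    def test_quantile_matrix_matches_frozen_oracle(self):
        assert mp.quantile_correspondence(5, 4) == pytest.approx(FROZEN_5_TO_4)

    def test_uniform_profiles_stay_uniform(self):
        out, both = mp.combine_trophic_profile(np.full(5, 0.2), np.full(4, 0.25))
        assert both
        assert out == pytest.approx(np.full(4, 0.25))

    def test_concentrated_profiles_concentrate(self):
        p = np.array([0, 0, 0, 0, 1.0])
        n = np.array([0, 0, 0, 1.0])
        out, _ = mp.combine_trophic_profile(p, n)
        assert out == pytest.approx([0, 0, 0, 1.0])

    def test_single_profile_passes_through(self):
        out, both = mp.combine_trophic_profile(None, np.array([0.5, 0.5, 0, 0]))
        assert not both
        assert out == pytest.approx([0.5, 0.5, 0, 0])

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.lists(st.floats(0.01, 1), min_size=5, max_size=5),
           st.lists(st.floats(0.01, 1), min_size=4, max_size=4))
    def test_random_profiles_match_matrix_multiplication(self, p5, n4):
        p5 = np.array(p5) / np.sum(p5)
        n4 = np.array(n4) / np.sum(n4)
        out, _ = mp.combine_trophic_profile(p5, n4)
        manual = (p5 @ FROZEN_5_TO_4 + n4) / 2.0
        manual /= manual.sum()
        assert out == pytest.approx(manual, abs=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert (out >= 0).all()


class TestSiteTrophicLevel:
    def test_single_species_dictates_class(self):
        prof = {"sp": np.array([0, 0, 1.0, 0])}
        out = mp.site_trophic_level({"sp": "2"}, prof)
        assert out.assigned_class == "eutrophic"

    def test_scores_are_code_times_profile(self):
        profiles = {
            "a": np.array([0.5, 0.5, 0.0, 0.0]),
            "b": np.array([0.0, 0.0, 0.2, 0.8]),
        }
        out = mp.site_trophic_level({"a": "3", "b": "+"}, profiles)
        manual = 3.0 * profiles["a"] + 0.5 * profiles["b"]
        assert out.class_scores == pytest.approx(manual)

    def test_linear_in_abundance_codes(self):
        profiles = {"a": np.array([0.4, 0.3, 0.2, 0.1])}
        s1 = mp.site_trophic_level({"a": "1"}, profiles)
        s2 = mp.site_trophic_level({"a": "2"}, profiles)
        assert s2.class_scores == pytest.approx(2 * s1.class_scores)
        assert s1.assigned_class == s2.assigned_class

    def test_random_releve_matches_double_loop_oracle(self):
        rng = np.random.default_rng(17)
        codes = list(mp.BB_NUMERIC)
        species = [f"sp{i}" for i in range(12)]
        profiles = {}
        for sp in species:
            w = rng.random(4)
            profiles[sp] = w / w.sum()
        releve = {sp: codes[rng.integers(len(codes))] for sp in species}
        out = mp.site_trophic_level(releve, profiles)
        manual = np.zeros(4)
        for sp, code in releve.items():
            for c in range(4):
                manual[c] += mp.BB_NUMERIC[code] * profiles[sp][c]
        assert out.class_scores == pytest.approx(manual, abs=1e-12)
        assert out.assigned_class == mp.TROPHIC_CLASSES[int(np.argmax(manual))]

    def test_tie_resolves_to_more_eutrophic_and_is_flagged(self):
        profiles = {"a": np.array([0.5, 0.0, 0.0, 0.5])}
        out = mp.site_trophic_level({"a": "1"}, profiles)
        assert out.assigned_class == "hyper-eutrophic" and out.tied

    def test_unscorable_releve_rejected(self):
        with pytest.raises(RivaqError, match="unscorable"):
            mp.site_trophic_level({"unknown": "2"}, {})

    def test_unknown_bb_code_rejected(self):
        with pytest.raises(RivaqError, match="Braun-Blanquet"):
            mp.site_trophic_level({"a": "9"}, {"a": np.full(4, 0.25)})


class TestGroundwaterInfluence:
    def test_no_indicator_species_is_null(self):
        out = mp.groundwater_influence({"x": "1"}, {})
        assert out.index == 0 and out.influence_class == "null"

    def test_strong_groundwater_contingent_is_high(self):
        cats = {f"g{i}": mp.THERMAL_GW for i in range(12)}
        cats["i0"] = mp.THERMAL_INTOLERANT
        releve = {sp: "1" for sp in cats}
        out = mp.groundwater_influence(releve, cats)
        assert out.index == 11 and out.influence_class == "high"

    def test_negative_difference_floors_at_zero(self):
        cats = {"g": mp.THERMAL_GW, "i1": mp.THERMAL_INTOLERANT,
                "i2": mp.THERMAL_INTOLERANT}
        out = mp.groundwater_influence({sp: "+" for sp in cats}, cats)
        assert out.index == 0 and out.influence_class == "null"

    @pytest.mark.parametrize(
        "index,cls",
        [(0, "null"), (1, "low"), (4, "low"), (5, "intermediate"),
         (9, "intermediate"), (10, "high")],
    )
    def test_class_boundaries(self, index, cls):
        assert mp.influence_class(index) == cls

    def test_random_sets_match_counting_oracle(self):
        rng = np.random.default_rng(23)
        pool = [f"s{i}" for i in range(30)]
        cats = {
            sp: rng.choice([mp.THERMAL_GW, mp.THERMAL_INTOLERANT,
                            mp.THERMAL_INDIFFERENT])
            for sp in pool
        }
        for _ in range(20):
            present = rng.choice(pool, size=rng.integers(1, 20), replace=False)
            releve = {sp: "1" for sp in present}
            out = mp.groundwater_influence(releve, cats)
            n_gw = sum(cats[sp] == mp.THERMAL_GW for sp in present)
            n_in = sum(cats[sp] == mp.THERMAL_INTOLERANT for sp in present)
            assert out.index == max(n_gw - n_in, 0)


class TestCommunityPipeline:
    def test_profile_weights_normalized(self, community_profiles):
        for group in ("thermal_profiles", "phosphorus_profiles",
                      "ammonia_profiles"):
            for prof in community_profiles[group].values():
                assert prof.weights.sum() == pytest.approx(1.0, abs=1e-9)
                assert (prof.weights >= 0).all()
        for w in community_profiles["trophic_profiles"].values():
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_site_class_recovery_on_simulated_communities(
        self, community, community_profiles
    ):
        """Assigned site trophic classes match the planted generating class
        for at least 80% of the 36 wetlands."""
        trophic, _ = mp.assess_sites(
            community.releves,
            community_profiles["trophic_profiles"],
            community_profiles["thermal_categories"],
        )
        truth = community.truth["sites"]["trophic_class"]
        hits = sum(
            mp.TROPHIC_CLASSES.index(t.assigned_class) == truth[site]
            for site, t in trophic.items()
        )
        assert hits / len(trophic) >= 0.8

    def test_thermal_categories_follow_planted_optima(
        self, community, community_profiles
    ):
        truth = community.truth["species"]
        cats = community_profiles["thermal_categories"]
        stable = truth[(truth["kind"] == "thermal") & (truth["optimum"] <= 1)].index
        variable = truth[(truth["kind"] == "thermal") & (truth["optimum"] >= 3)].index
        stable_hits = [cats.get(sp) == mp.THERMAL_GW for sp in stable if sp in cats]
        var_hits = [cats.get(sp) == mp.THERMAL_INTOLERANT
                    for sp in variable if sp in cats]
        assert np.mean(stable_hits) >= 0.8
        assert np.mean(var_hits) >= 0.8
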