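import numpy as np
import pytest

from ffascreen import (
    BoundaryUndefinedError,
    Category,
    ConfigurationError,
    ReferenceConfig,
    StrainProfile,
    WeightVector,
    calibrate_weights,
    categorize,
    evaluate_new_strain,
    find_boundary,
    load_weights,
    make_profile_cohort,
    normalize_scores,
    rank_cohort,
    score_cohort,
    score_raw,
    unit_weights,
    write_weights,
)
from ffascreen.synth import SYNTHETIC_REFS, CohortSpec

from oracles import brute_score, oracle_boundary


def _profile(panel, present):
    return StrainProfile.from_presence("S", present, panel)


class TestScoreRaw:
    def test_all_absent_is_zero(self, small_panel):
        assert score_raw(_profile(small_panel, []), unit_weights(small_panel)) == 0

    def test_single_terms(self, small_panel):
        w = unit_weights(small_panel)
        assert score_raw(_profile(small_panel, ["c1"]), w) == 1
        assert score_raw(_profile(small_panel, ["c2"]), w) == -1

    def test_three_positive_two_negative(self, demo_panel):
        present = ["POS001", "POS002", "POS003", "NEG001", "NEG002"]
        got = score_raw(_profile(demo_panel, present), unit_weights(demo_panel))
        assert got == 1

    def test_count_mode_uses_counts(self, small_panel):
        prof = StrainProfile(
            "S", {"c1": 3, "c2": 0, "c3": 0},
            {"c1": True, "c2": False, "c3": False},
            {"og1": True, "og2": False, "og3": False},
        )
        w = unit_weights(small_panel)
        assert score_raw(prof, w, "count") == 3
        assert score_raw(prof, w, "presence") == 1

    def test_missing_weight_is_configuration_error(self, small_panel):
        with pytest.raises(ConfigurationError):
            score_raw(_profile(small_panel, ["c1"]), WeightVector({"c1": 1.0}))

    def test_monotone_in_positive_and_negative_presence(self, demo_panel):
        w = unit_weights(demo_panel)
        base = _profile(demo_panel, ["POS001"])
        s0 = score_raw(base, w)
        assert score_raw(_profile(demo_panel, ["POS001", "POS002"]), w) >= s0
        assert score_raw(_profile(demo_panel, ["POS001", "NEG001"]), w) <= s0


class TestNormalizeScores:
    def test_minmax_formula(self):
        assert normalize_scores({"A": 5, "B": 3, "C": 1}) == {
            "A": 1.0,
            "B": 0.5,
            "C": 0.0,
        }

    def test_top_strain_is_one(self):
        rng = np.random.default_rng(2)
        raws = {f"S{i}": float(v) for i, v in enumerate(rng.normal(size=30))}
        norm = normalize_scores(raws)
        assert max(norm.values()) == 1.0
        assert min(norm.values()) == 0.0

    def test_degenerate_cohort_maps_to_half(self):
        assert normalize_scores({"A": 2, "B": 2}) == {"A": 0.5, "B": 0.5}

    def test_empty_cohort_is_error(self):
        with pytest.raises(ConfigurationError):
            normalize_scores({})


class TestRankCohort:
    def test_descending_order(self):
        assert rank_cohort({"A": 0.9, "B": 0.5, "C": 0.1}) == [
            ("A", 1),
            ("B", 2),
            ("C", 3),
        ]

    def test_tie_broken_lexicographically(self):
        assert rank_cohort({"B": 0.5, "A": 0.5}) == [("A", 1), ("B", 2)]

    def test_ranks_are_bijection(self):
        rng = np.random.default_rng(5)
        norm = {f"S{i}": float(rng.random()) for i in range(40)}
        ranks = [r for _, r in rank_cohort(norm)]
        assert sorted(ranks) == list(range(1, 41))


class TestFindBoundary:
    def test_reference_cluster_lowest_member(self):
        scores = dict(zip("ABCDE", [0.95, 0.93, 0.90, 0.10, 0.05]))
        assert find_boundary(scores, ["A", "B"]) == "C"

    def test_two_strains_singleton_cluster(self):
        assert find_boundary({"ref": 0.9, "other": 0.1}, ["ref"]) == "ref"

    def test_refs_split_is_error(self):
        scores = {"A": 0.99, "B": 0.01, "C": 0.98, "D": 0.02}
        with pytest.raises(BoundaryUndefinedError):
            find_boundary(scores, ["A", "B"])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(3, 16))
            scores = {f"S{i:02d}": float(rng.random()) for i in range(n)}
            refs = sorted(scores, key=lambda s: -scores[s])[:2]
            expected = oracle_boundary(scores, refs)
            if expected is None:
                with pytest.raises(BoundaryUndefinedError):
                    find_boundary(scores, refs)
            else:
                assert find_boundary(scores, refs) == expected

    def test_matches_sklearn_with_many_restarts(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(41)
        for _ in range(30):
            n = int(rng.integers(4, 15))
            scores = {f"S{i:02d}": float(rng.random()) for i in range(n)}
            refs = sorted(scores, key=lambda s: -scores[s])[:2]
            sids = sorted(scores)
            x = np.array([[scores[s]] for s in sids])
            km = KMeans(n_clusters=2, n_init=50, random_state=0).fit(x)
            labels = dict(zip(sids, km.labels_))
            ref_label = labels[refs[0]]
            if labels[refs[1]] != ref_label:
                with pytest.raises(BoundaryUndefinedError):
                    find_boundary(scores, refs)
                continue
            cluster = [s for s in sids if labels[s] == ref_label]
            expected = min(cluster, key=lambda s: (scores[s], s))
            assert find_boundary(scores, refs) == expected


class TestCategorize:
    def test_above_upper_is_top_ranked(self):
        assert categorize(0.99, 0.9433, 0.4) is Category.TOP_RANKED

    def test_equal_upper_is_positive(self):
        assert categorize(0.9433, 0.9433, 0.4) is Category.POSITIVE

    def test_equal_lower_is_negative(self):
        assert categorize(0.4, 0.9433, 0.4) is Category.NEGATIVE

    def test_inverted_boundaries_rejected(self):
        with pytest.raises(ConfigurationError):
            categorize(0.5, 0.3, 0.6)

    def test_partition_sums_to_cohort_size(self, demo_panel):
        pc = make_profile_cohort(demo_panel, CohortSpec(n_strains=40, seed=6))
        records = score_cohort(pc.profiles, unit_weights(demo_panel), pc.refs)
        counts = {c: 0 for c in Category}
        for r in records:
            counts[r.category] += 1
        assert sum(counts.values()) == 40


class TestCalibrateWeights:
    def test_separable_references_end_ordered(self, demo_panel):
        pc = make_profile_cohort(demo_panel, CohortSpec(n_strains=30, seed=13))
        cal = calibrate_weights(pc.profiles, demo_panel, pc.refs)
        assert cal.separable
        raw = {p.strain_id: score_raw(p, cal.weights) for p in pc.profiles}
        for pos in pc.refs.positive_refs:
            for neg in pc.refs.negative_refs:
                assert raw[pos] > raw[neg]

    def test_identical_reference_profiles_flagged_nonseparable(self, small_panel):
        same = ["c1", "c3"]
        profiles = [
            StrainProfile.from_presence("P", same, small_panel),
            StrainProfile.from_presence("N", same, small_panel),
        ]
        refs = ReferenceConfig(
            positive_refs=("P",), negative_refs=("N",),
            upper_boundary="P", lower_boundary="N",
        )
        cal = calibrate_weights(profiles, small_panel, refs)
        assert not cal.separable

    def test_sign_constraints_preserved(self, demo_panel):
        pc = make_profile_cohort(demo_panel, CohortSpec(n_strains=30, seed=13))
        cal = calibrate_weights(pc.profiles, demo_panel, pc.refs)
        for c in demo_panel.criteria:
            w = cal.weights[c.criterion_id]
            assert w < 0 if c.impact.value == "negative" else w > 0

    def test_missing_reference_is_error(self, demo_panel):
        pc = make_profile_cohort(demo_panel, CohortSpec(n_strains=10, seed=13))
        refs = ReferenceConfig(
            positive_refs=("NOT_THERE",), negative_refs=("REF_NEG_1",),
            upper_boundary="NOT_THERE", lower_boundary="REF_NEG_1",
        )
        with pytest.raises(ConfigurationError, match="NOT_THERE"):
            calibrate_weights(pc.profiles, demo_panel, refs)


class TestEvaluateNewStrain:
    @pytest.fixture
    def cohort(self, demo_panel):
        pc = make_profile_cohort(demo_panel, CohortSpec(n_strains=15, seed=19))
        w = unit_weights(demo_panel)
        raws = {p.strain_id: score_raw(p, w) for p in pc.profiles}
        return pc, w, raws

    def test_duplicate_profile_scores_identically(self, demo_panel, cohort):
        pc, w, raws = cohort
        twin_src = pc.profiles[5]
        twin = StrainProfile(
            "zz_twin", dict(twin_src.hit_counts), dict(twin_src.presence),
            dict(twin_src.og_satisfied),
        )
        result = evaluate_new_strain(twin, raws, w, pc.refs, demo_panel)
        assert result.record.raw_score == raws[twin_src.strain_id]
        by_id = {r.strain_id: r for r in result.ranking}
        original = by_id[twin_src.strain_id]
        assert by_id["zz_twin"].normalized_score == original.normalized_score
        # lexicographic tie rule: zz_twin sorts after every cohort strain
        tied = [r for r in result.ranking if r.raw_score == original.raw_score]
        assert by_id["zz_twin"].rank == max(r.rank for r in tied)

    def test_dominant_strain_is_rank_one_top_ranked(self, demo_panel, cohort):
        pc, w, raws = cohort
        best = [
            c.criterion_id
            for c in demo_panel.criteria
            if c.impact.value in ("positive", "required")
        ]
        prof = StrainProfile.from_presence("dominant", best, demo_panel)
        result = evaluate_new_strain(prof, raws, w, pc.refs, demo_panel)
        assert result.rank == 1
        assert result.category is Category.TOP_RANKED
        assert result.score == 1.0

    def test_exposes_score_category_recommendation_rank(self, demo_panel, cohort):
        pc, w, raws = cohort
        prof = StrainProfile.from_presence("new", ["POS001"], demo_panel)
        result = evaluate_new_strain(prof, raws, w, pc.refs, demo_panel)
        assert isinstance(result.score, float)
        assert result.category in set(Category)
        assert isinstance(result.rank, int)
        assert result.recommendations  # mostly-absent strain needs insertions

    def test_id_collision_is_error(self, demo_panel, cohort):
        pc, w, raws = cohort
        prof = StrainProfile.from_presence(pc.profiles[0].strain_id, [], demo_panel)
        with pytest.raises(ConfigurationError):
            evaluate_new_strain(prof, raws, w, pc.refs, demo_panel)

    def test_cohort_raws_not_mutated(self, demo_panel, cohort):
        pc, w, raws = cohort
        snapshot = dict(raws)
        prof = StrainProfile.from_presence("new", ["POS001"], demo_panel)
        evaluate_new_strain(prof, raws, w, pc.refs, demo_panel)
        assert raws == snapshot


def test_score_raw_matches_brute_force_on_random_profiles(demo_panel):
    rng = np.random.default_rng(23)
    w = unit_weights(demo_panel)
    ids = demo_panel.criterion_ids
    for _ in range(200):
        present = [c for c in ids if rng.random() < 0.5]
        prof = StrainProfile.from_presence("S", present, demo_panel)
        assert score_raw(prof, w) == brute_score(prof, w)


def test_weights_roundtrip(tmp_path, demo_panel):
    w = unit_weights(demo_panel)
    path = tmp_path / "w.tsv"
    write_weights(w, path)
    assert load_weights(path).weights == dict(w.weights)


def test_synthetic_reference_config_is_consistent():
    assert set(SYNTHETIC_REFS.positive_refs).isdisjoint(SYNTHETIC_REFS.negative_refs)
    assert SYNTHETIC_REFS.upper_boundary in SYNTHETIC_REFS.positive_refs
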