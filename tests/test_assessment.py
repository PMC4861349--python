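import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from confdiv.assessment import (
    DIFFERENT_BEST,
    METRICS,
    SAME_BEST,
    DecoyRecord,
    Ranking,
    TargetAssessment,
    assess_target,
    cohort_report,
    filter_decoys,
    rank_decoys,
    significance_gate,
    spearman_rho,
)
from confdiv.metrics import SimilarityScores, score_pair
from confdiv.synthetic import SyntheticTargetSpec, generate_backbone, sample_decoys
from tests.conftest import make_structure


def _decoy_from(reference, keep_indices, decoy_id="d"):
    keep = sorted(keep_indices)
    return DecoyRecord(
        decoy_id=decoy_id,
        structure=make_structure(
            reference.coords[keep], nums=reference.res_nums[keep], sid=decoy_id
        ),
    )


def _scored_decoy(decoy_id, rmsd_a, rmsd_b, gdt_a=None, gdt_b=None,
                  significant=True):
    def scores(r, g):
        return SimilarityScores(rmsd=r, gdt_ts=g, tm_score=g, n_aligned=40,
                                coverage=1.0, significant=significant)

    return DecoyRecord(
        decoy_id=decoy_id,
        structure=generate_backbone(20, seed=0),
        scores_a=scores(rmsd_a, gdt_a),
        scores_b=scores(rmsd_b, gdt_b),
        passed_filters=True,
    )


@pytest.fixture(scope="module")
def reference():
    return generate_backbone(100, seed=1)


class TestFilterDecoys:

    def test_coverage_below_080_rejected(self, reference):
        # 79/100 residues, deleted as scattered singletons (no long run)
        drop = set(range(0, 42, 2))  # 21 single-residue deletions
        keep = [i for i in range(100) if i not in drop]
        passed, rejected = filter_decoys([_decoy_from(reference, keep)], reference)
        assert not passed and len(rejected) == 1
        assert rejected[0].filter_coverage == pytest.approx(0.79)
        assert rejected[0].max_consecutive_missing == 1

    def test_run_of_six_rejected_despite_high_coverage(self, reference):
        keep = [i for i in range(100) if i not in range(10, 16)]
        passed, rejected = filter_decoys([_decoy_from(reference, keep)], reference)
        assert not passed
        assert rejected[0].filter_coverage == pytest.approx(0.94)
        assert rejected[0].max_consecutive_missing == 6

    def test_boundary_inclusive(self, reference):
        # exactly 80% coverage and a longest run of exactly 5 must pass
        drop = set(range(10, 15)) | set(range(30, 35)) | set(range(50, 55)) | set(range(70, 75))
        keep = [i for i in range(100) if i not in drop]
        passed, rejected = filter_decoys([_decoy_from(reference, keep)], reference)
        assert len(passed) == 1 and not rejected
        assert passed[0].filter_coverage == pytest.approx(0.80)
        assert passed[0].max_consecutive_missing == 5

    def test_disjoint_numbering_fails_filters(self, reference):
        rec = DecoyRecord(
            decoy_id="x",
            structure=make_structure(np.random.default_rng(0).normal(size=(5, 3)),
                                     nums=np.arange(900, 905)),
        )
        passed, rejected = filter_decoys([rec], reference)
        assert not passed and rejected[0].passed_filters is False


class TestSignificanceGate:
    def test_identical_full_length_significant(self):
        s = generate_backbone(100, seed=1)
        assert significance_gate(score_pair(s, s, metrics=("rmsd",)))

    def test_short_alignment_not_significant(self):
        scores = SimilarityScores(rmsd=1.0, gdt_ts=None, tm_score=None,
                                  n_aligned=10, coverage=0.1)
        assert not significance_gate(scores)

    def test_synthetic_full_coverage_decoy_significant(self):
        spec = SyntheticTargetSpec(n_residues=40, hinge_angle=10, n_decoys_a=1,
                                   n_decoys_b=0, noise_sigma=1.0, seed=5)
        pair, decoys = sample_decoys(spec)
        scores = score_pair(decoys[0].structure, pair.conformer_a, metrics=("rmsd",))
        assert significance_gate(scores)


class TestRankDecoys:
    def test_rmsd_ascending_order(self):
        decoys = [_scored_decoy("d1", 1.0, 1.0), _scored_decoy("d2", 2.0, 2.0),
                  _scored_decoy("d3", 0.5, 0.5)]
        ranking = rank_decoys(decoys, "a", "RMSD")
        assert ranking.ordered_ids == ["d3", "d1", "d2"]
        assert ranking.best_id == "d3"

    def test_gdt_ties_get_average_ranks(self):
        decoys = [_scored_decoy("d1", 1.0, 1.0, gdt_a=0.8, gdt_b=0.8),
                  _scored_decoy("d2", 1.5, 1.5, gdt_a=0.8, gdt_b=0.8)]
        ranking = rank_decoys(decoys, "a", "GDT_TS")
        assert ranking.ranks["d1"] == ranking.ranks["d2"] == 1.5

    def test_rank_vector_matches_independent_sort_oracle(self, rng):
        values = rng.uniform(0.3, 4.0, size=100)
        values[10] = values[20]  # inject a tie
        decoys = [_scored_decoy(f"d{i:03d}", v, v) for i, v in enumerate(values)]
        ranking = rank_decoys(decoys, "a", "RMSD")
        oracle = rankdata(values, method="average")  # independent implementation
        for i, expect in enumerate(oracle):
            assert ranking.ranks[f"d{i:03d}"] == expect

    def test_rmsd_ranking_drops_nonsignificant(self):
        decoys = [_scored_decoy("good", 1.0, 1.0),
                  _scored_decoy("weak", 0.5, 0.5, significant=False)]
        ranking = rank_decoys(decoys, "a", "RMSD")
        assert "weak" not in ranking.ranks
        ranking_all = rank_decoys(decoys, "a", "RMSD", significant_only=False)
        assert ranking_all.best_id == "weak"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rank_decoys([], "a", "RMSD")

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            rank_decoys([_scored_decoy("d", 1, 1)], "a", "WRMSD")


class TestSpearman:
    @staticmethod
    def _ranking(scores: dict, metric="RMSD"):
        ranks = rankdata(list(scores.values()), method="average")
        return Ranking(metric=metric, scores=scores,
                       ranks=dict(zip(scores.keys(), ranks.tolist())))

    def test_identical_rankings(self):
        r = self._ranking({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert spearman_rho(r, r) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        scores = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        rev = {k: -v for k, v in scores.items()}
        assert spearman_rho(self._ranking(scores), self._ranking(rev)) == pytest.approx(-1.0)

    def test_tie_corrected_hand_value(self):
        # ranks (1, 2.5, 2.5, 4) vs (1, 2, 3, 4); Pearson on rank vectors:
        # cov 4.5, var_a 4.5, var_b 5 -> rho = 4.5/sqrt(22.5) = 0.9486832981
        ra = Ranking(metric="RMSD", scores={},
                     ranks={"a": 1.0, "b": 2.5, "c": 2.5, "d": 4.0})
        rb = Ranking(metric="RMSD", scores={},
                     ranks={"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert spearman_rho(ra, rb) == pytest.approx(0.9486832980505138, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self, rng):
        for _ in range(5):
            x = rng.uniform(size=20)
            y = rng.uniform(size=20)
            expected = spearmanr(x, y).statistic
            got = spearman_rho(self._ranking(dict(zip(map(str, range(20)), x))),
                               self._ranking(dict(zip(map(str, range(20)), y))))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_three_shared_is_none(self):
        ra = self._ranking({"a": 1.0, "b": 2.0, "c": 3.0})
        rb = self._ranking({"a": 1.0, "x": 2.0, "y": 3.0})
        assert spearman_rho(ra, rb) is None


class TestAssessTarget:
    def test_zero_hinge_gives_rho_one_for_all_metrics(self):
        spec = SyntheticTargetSpec(n_residues=40, hinge_angle=0.0, n_decoys_a=6,
                                   n_decoys_b=6, noise_sigma=0.5, seed=2)
        pair, decoys = sample_decoys(spec)
        out = assess_target(pair, decoys)
        for metric in METRICS:
            assert out.spearman[metric] == pytest.approx(1.0)
            assert out.classification[metric] == SAME_BEST

    def test_single_cloud_cross_exceeds_own(self):
        # decoys sample only conformer A, so A's best decoy sits near A and
        # far from B; the b-side mirrors the comparison and is uninformative
        hits = 0
        for seed in range(5):
            spec = SyntheticTargetSpec(n_residues=40, hinge_angle=30.0,
                                       n_decoys_a=30, n_decoys_b=0,
                                       noise_sigma=0.5, seed=seed)
            pair, decoys = sample_decoys(spec)
            out = assess_target(pair, decoys, metrics=("RMSD",))
            hits += out.best_rmsd_cross["a"] > out.best_rmsd_own["a"]
        assert hits == 5

    def test_balanced_clouds_different_best(self):
        diff = 0
        for seed in range(5):
            spec = SyntheticTargetSpec(n_residues=40, hinge_angle=30.0,
                                       n_decoys_a=30, n_decoys_b=30,
                                       noise_sigma=0.5, seed=100 + seed)
            pair, decoys = sample_decoys(spec)
            out = assess_target(pair, decoys, metrics=("RMSD",))
            diff += out.classification["RMSD"] == DIFFERENT_BEST
        assert diff == 5

    def test_zero_passed_decoys_flagged(self):
        spec = SyntheticTargetSpec(n_residues=40, hinge_angle=10.0, n_decoys_a=4,
                                   n_decoys_b=0, noise_sigma=0.5, seed=3,
                                   missing_run_prob=1.0)
        pair, decoys = sample_decoys(spec, forced_run_length=8)
        out = assess_target(pair, decoys)
        assert out.n_decoys_passed == 0
        assert "no_decoys_passed_filters" in out.flags
        assert all(v is None for v in out.spearman.values())

    def test_high_quality_counts_significant_comparisons(self):
        spec = SyntheticTargetSpec(n_residues=40, hinge_angle=10.0, n_decoys_a=3,
                                   n_decoys_b=0, noise_sigma=0.5, seed=4)
        pair, decoys = sample_decoys(spec)
        out = assess_target(pair, decoys, metrics=("RMSD",), min_significant=3)
        assert out.n_significant_comparisons == 6  # 3 decoys x 2 conformers
        assert out.high_quality
        strict = assess_target(pair, decoys, metrics=("RMSD",), min_significant=7)
        assert not strict.high_quality

    def test_gdt_and_tm_rank_correlation_high(self):
        spec = SyntheticTargetSpec(n_residues=40, hinge_angle=20.0, n_decoys_a=10,
                                   n_decoys_b=10, noise_sigma=0.5, seed=6)
        pair, decoys = sample_decoys(spec)
        assess_target(pair, decoys)  # scores decoys in place
        passed = [d for d in decoys if d.passed_filters]
        g = rank_decoys(passed, "a", "GDT_TS")
        t = rank_decoys(passed, "a", "TM")
        assert spearman_rho(g, t) >= 0.95


class TestCohortReport:
    @staticmethod
    def _assessment(tid, classification, rho=0.5, own=1.0, cross=2.0,
                    high_quality=True, group="g"):
        return TargetAssessment(
            target_id=tid, n_decoys_total=10, n_decoys_passed=10,
            n_significant_comparisons=20, high_quality=high_quality,
            spearman={m: rho for m in METRICS},
            best_decoy={m: {"a": "x", "b": "y"} for m in METRICS},
            classification={m: classification for m in METRICS},
            best_rmsd_own={"a": own, "b": own},
            best_rmsd_cross={"a": cross, "b": cross},
            group_label=group,
            decoy_score_summary={"rmsd_max_a": 3.0, "rmsd_mean_a": 1.0},
        )

    def test_three_of_ten_same(self):
        assessments = [
            self._assessment(f"t{i}", SAME_BEST if i < 3 else DIFFERENT_BEST)
            for i in range(10)
        ]
        report = cohort_report(assessments)
        entry = report["metrics"]["RMSD"]
        assert entry["fraction_same_best"] == pytest.approx(0.30)
        assert entry["fraction_different_best"] == pytest.approx(0.70)

    def test_fractions_complementary(self):
        assessments = [
            self._assessment(f"t{i}", SAME_BEST if i % 3 else DIFFERENT_BEST)
            for i in range(9)
        ]
        report = cohort_report(assessments)
        for m in METRICS:
            entry = report["metrics"][m]
            assert entry["fraction_same_best"] + entry["fraction_different_best"] == pytest.approx(1.0)

    def test_zero_hinge_cohort_all_same_rho_one(self):
        assessments = []
        for seed in range(3):
            spec = SyntheticTargetSpec(n_residues=40, hinge_angle=0.0, n_decoys_a=5,
                                       n_decoys_b=5, noise_sigma=0.5, seed=seed)
            pair, decoys = sample_decoys(spec)
            assessments.append(assess_target(pair, decoys, metrics=("RMSD",)))
        report = cohort_report(assessments)
        assert report["metrics"]["RMSD"]["fraction_same_best"] == 1.0
        assert report["metrics"]["RMSD"]["mean_spearman"] == pytest.approx(1.0)

    def test_high_quality_subset_filtering(self):
        assessments = [self._assessment("a", SAME_BEST, high_quality=True),
                       self._assessment("b", DIFFERENT_BEST, high_quality=False)]
        report = cohort_report(assessments, high_quality_only=True)
        assert report["n_targets"] == 1
        assert report["metrics"]["RMSD"]["fraction_same_best"] == 1.0

    def test_mean_cross_rmsd_over_different_targets(self):
        assessments = [self._assessment("a", DIFFERENT_BEST, own=1.0, cross=2.0),
                       self._assessment("b", DIFFERENT_BEST, own=2.0, cross=3.0),
                       self._assessment("c", SAME_BEST, own=9.0, cross=9.0)]
        entry = cohort_report(assessments)["metrics"]["RMSD"]
        assert entry["mean_best_rmsd_own_different"] == pytest.approx(1.5)
        assert entry["mean_best_rmsd_cross_different"] == pytest.approx(2.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cohort_report([])
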