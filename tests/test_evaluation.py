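"""Ranking metrics and the similarity-search protocols."""

import numpy as np
import pytest

from npfp import (
    FixtureSpec,
    MoleculeRecord,
    SearchResult,
    auc_from_ranking,
    ecfp4_featurizer,
    enrichment_factor,
    generate_activity_benchmark,
    knn_identification_cv,
    npl_prefilter,
    per_target_screen,
)
from npfp.errors import (
    DegenerateLabelsError,
    NoActivesError,
    TargetTooSmallError,
)


def brute_force_auc(pairs):
    """O(n^2) pairwise concordance count — the independent oracle."""
    pos = [s for s, a in pairs if a]
    neg = [s for s, a in pairs if not a]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        pairs = [(1.0, True), (0.9, True), (0.1, False)]
        assert auc_from_ranking(pairs) == 1.0

    def test_all_ties_is_half(self):
        pairs = [(0.5, True), (0.5, False), (0.5, True), (0.5, False)]
        assert auc_from_ranking(pairs) == 0.5

    def test_hand_computed_example(self):
        # pairs: (0.9>0.8)=1, (0.9>0.1)=1, (0.7<0.8)=0, (0.7>0.1)=1 -> 3/4
        pairs = [(0.9, True), (0.8, False), (0.7, True), (0.1, False)]
        assert auc_from_ranking(pairs) == 0.75

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            pairs = list(zip(scores, labels))
            assert auc_from_ranking(pairs) == pytest.approx(
                brute_force_auc(pairs), abs=1e-12)

    def test_label_inversion_mirrors_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30).astype(bool)
        labels[0], labels[1] = True, False
        a = auc_from_ranking(list(zip(scores, labels)))
        b = auc_from_ranking(list(zip(scores, ~labels)))
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_labels_raise(self):
        with pytest.raises(DegenerateLabelsError):
            auc_from_ranking([(0.5, True), (0.4, True)])


def make_result(n, active_positions, scores=None):
    scores = scores if scores is not None else np.linspace(1, 0, n)
    ranked = [(f"m{i}", float(scores[i]), i in active_positions)
              for i in range(n)]
    return SearchResult(query_id="q", ranked=ranked)


class TestEnrichmentFactor:
    def test_all_actives_in_top_window(self):
        # 10 actives of 1000 all in top 10 -> (10/10)/(10/1000) = 100
        result = make_result(1000, set(range(10)))
        assert enrichment_factor(result, 0.01) == pytest.approx(100.0)

    def test_fraction_one_collapses_to_one(self):
        result = make_result(50, {3, 10, 40})
        assert enrichment_factor(result, 1.0) == pytest.approx(1.0)

    def test_no_actives_in_window_is_zero(self):
        result = make_result(100, {99})
        assert enrichment_factor(result, 0.01) == 0.0

    def test_no_actives_at_all_raises(self):
        with pytest.raises(NoActivesError):
            enrichment_factor(make_result(10, set()), 0.5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = np.sort(rng.random(200))[::-1]
        actives = set(rng.choice(200, 20, replace=False).tolist())
        a = enrichment_factor(make_result(200, actives, scores), 0.05)
        b = enrichment_factor(
            make_result(200, actives, np.exp(3 * scores)), 0.05)
        assert a == b

    def test_bounded_by_inverse_fraction(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(20, 200))
            k = int(rng.integers(1, n // 2))
            actives = set(rng.choice(n, k, replace=False).tolist())
            for fraction in (0.01, 0.1, 0.5):
                ef = enrichment_factor(make_result(n, actives), fraction)
                assert ef <= 1.0 / fraction + 1e-9

    def test_window_never_empty(self):
        result = make_result(10, {0})
        # ceil(0.01 * 10) = 1 molecule in the window
        assert enrichment_factor(result, 0.01) == pytest.approx(10.0)


class TestKnnIdentification:
    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(4)
        a = rng.normal(loc=(10, 0), scale=0.1, size=(50, 2))
        b = rng.normal(loc=(0, 10), scale=0.1, size=(50, 2))
        fps = np.vstack([a, b])
        labels = [True] * 50 + [False] * 50
        assert knn_identification_cv(fps, labels, metric="cosine",
                                     seed=0) == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        fps = np.abs(rng.normal(size=(200, 16))) + 0.1
        labels = rng.integers(0, 2, 200).astype(bool)
        auc = knn_identification_cv(fps, labels, metric="cosine", seed=0)
        assert abs(auc - 0.5) < 0.1

    def test_too_few_per_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            knn_identification_cv(np.ones((12, 4)), [True] * 6 + [False] * 6,
                                  folds=10)


class TestSearchResultInvariants:
    def test_similarities_must_be_sorted(self):
        with pytest.raises(ValueError):
            SearchResult("q", [("a", 0.2, True), ("b", 0.9, False)])

    def test_query_cannot_rank_itself(self):
        with pytest.raises(ValueError):
            SearchResult("q", [("q", 0.9, True)])


@pytest.fixture(scope="module")
def benchmark():
    return generate_activity_benchmark(
        FixtureSpec(n_np=20, n_syn=60, n_targets=3,
                    actives_per_target=6, seed=9))


class TestPerTargetScreen:
    def test_constructed_benchmark_screens_well(self, benchmark):
        report = per_target_screen(benchmark, ecfp4_featurizer(),
                                   metric="tanimoto")
        assert set(report.per_target) == {"T0", "T1", "T2"}
        for target, metrics in report.per_target.items():
            assert metrics.n_queries == 6
            assert metrics.auc_mean >= 0.8, target

    def test_overall_is_mean_of_targets(self, benchmark):
        report = per_target_screen(benchmark, ecfp4_featurizer(),
                                   metric="tanimoto")
        assert report.overall.auc_mean == pytest.approx(
            np.mean([t.auc_mean for t in report.per_target.values()]))
        assert report.overall.ef1_mean == pytest.approx(
            np.mean([t.ef1_mean for t in report.per_target.values()]))

    def test_metric_equivalence_on_equal_popcount_bits(self):
        """For 0/1 vectors of equal popcount, Tanimoto and cosine induce
        the same ranking: check both metrics agree on AUC."""
        rng = np.random.default_rng(7)
        records = []
        feats = []
        for i in range(20):
            bits = np.zeros(32)
            bits[rng.choice(32, 8, replace=False)] = 1
            feats.append(bits)
            records.append(MoleculeRecord(
                id=f"m{i}", smiles="C", target_id="T",
                activity="active" if i < 5 else "inactive",
                source_class="natural"))
        feats = np.array(feats)

        def featurizer(recs):
            return feats[[int(r.id[1:]) for r in recs]]

        rt = per_target_screen(records, featurizer, metric="tanimoto")
        rc = per_target_screen(records, featurizer, metric="cosine")
        assert rt.overall.auc_mean == pytest.approx(rc.overall.auc_mean,
                                                    abs=1e-12)

    def test_single_active_target_rejected(self):
        records = [MoleculeRecord(id=f"m{i}", smiles="CCO", target_id="T",
                                  activity="active" if i == 0 else "inactive")
                   for i in range(5)]
        with pytest.raises(TargetTooSmallError):
            per_target_screen(records, ecfp4_featurizer())


class TestNplPrefilter:
    def _recs(self, scores):
        return [MoleculeRecord(id=f"m{i}", smiles="CCO",
                               source_class="natural", npl=s)
                for i, s in enumerate(scores)]

    def test_no_record_above_threshold_is_identity(self):
        recs = self._recs([0.2, 0.9, -1.0])
        assert npl_prefilter(recs) == recs

    def test_all_above_threshold_leaves_only_synthetics(self):
        recs = self._recs([1.5, 2.0]) + [
            MoleculeRecord(id="s", smiles="CCO", source_class="synthetic",
                           npl=5.0)]
        out = npl_prefilter(recs)
        assert [r.id for r in out] == ["s"]

    def test_threshold_is_strictly_greater(self):
        recs = self._recs([0.5, 1.0, 1.5])
        out = npl_prefilter(recs, threshold=1.0)
        assert [r.npl for r in out] == [0.5, 1.0]

    def test_synthetics_never_touched(self):
        recs = [MoleculeRecord(id="s", smiles="CCO",
                               source_class="synthetic", npl=99.0)]
        assert npl_prefilter(recs) == recs
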