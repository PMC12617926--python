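import numpy as np
import pytest

import pathorm as pm
from pathorm.core_io import ValidationError
from pathorm.evaluation import mann_whitney_auc


def brute_force_auc(scores, labels):
    """Pairwise Mann-Whitney enumeration with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_separation(self):
        r = pm.compute_metrics([0.9, 0.1], [1, 0])
        assert r["auc"] == 1.0 and r["aupr"] == 1.0 and r["acc"] == 1.0

    def test_perfect_inversion(self):
        assert pm.compute_metrics([0.1, 0.9], [1, 0])["auc"] == 0.0

    def test_hand_enumerated_auc(self):
        r = pm.compute_metrics([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert r["auc"] == 0.75

    def test_single_class_markers(self):
        r = pm.compute_metrics([0.9, 0.8], [1, 1])
        assert np.isnan(r["auc"]) and np.isnan(r["aupr"])
        assert r["acc"] == 1.0

    def test_confusion_metrics_at_half(self):
        scores = [0.9, 0.3, 0.6, 0.2]
        labels = [1, 1, 0, 0]
        r = pm.compute_metrics(scores, labels)
        # tp=1 fn=1 fp=1 tn=1
        assert r["acc"] == 0.5
        assert r["precision"] == 0.5
        assert r["recall"] == 0.5
        assert r["specificity"] == 0.5
        assert r["f1"] == 0.5

    def test_auc_matches_brute_force_on_random_vectors(self, rng):
        """Rank-based AUC equals pairwise enumeration exactly, 50 cases."""
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_label_swap_symmetry(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        a = mann_whitney_auc(scores, labels)
        b = mann_whitney_auc(scores, 1 - labels)
        assert a == pytest.approx(1.0 - b)


class TestKfoldSplits:
    def _setup(self):
        rng = np.random.default_rng(3)
        sites = [f"s{i}" for i in range(12)]
        diseases = [f"d{j}" for j in range(6)]
        pairs = [(s, d) for s in sites for d in diseases]
        pos = set(map(tuple, rng.choice(pairs, 10, replace=False)))
        assoc = pm.AssociationTable(pos, set(), sites, diseases)
        C = rng.random((12, 12))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 0.0)
        return assoc, pm.AffinityMatrix(sites, C)

    def test_partition_of_positives(self):
        assoc, C = self._setup()
        folds = pm.kfold_splits(assoc, C, k=10, seed=0)
        test_sets = [f.test_positives for f in folds]
        assert all(len(t) == 1 for t in test_sets)
        union = set().union(*test_sets)
        assert union == assoc.positives
        for i in range(10):
            for j in range(i + 1, 10):
                assert not test_sets[i] & test_sets[j]

    def test_deterministic(self):
        assoc, C = self._setup()
        f1 = pm.kfold_splits(assoc, C, k=5, seed=7)
        f2 = pm.kfold_splits(assoc, C, k=5, seed=7)
        for a, b in zip(f1, f2):
            assert a.test_positives == b.test_positives
            assert a.test_negatives == b.test_negatives
            assert a.train_negatives == b.train_negatives

    def test_imbalanced_ratio(self):
        assoc, C = self._setup()
        folds = pm.kfold_splits(
            assoc, C, k=5, sampler=pm.SamplerConfig(method="random", ratio=10.0), seed=0
        )
        for f in folds:
            assert len(f.test_negatives) == 10 * len(f.test_positives)

    def test_no_test_pair_in_training(self):
        assoc, C = self._setup()
        for f in pm.kfold_splits(assoc, C, k=5, seed=1):
            train = f.train_positives | f.train_negatives
            test = f.test_positives | f.test_negatives
            assert not train & test

    def test_too_few_positives(self):
        assoc, C = self._setup()
        with pytest.raises(ValidationError):
            pm.kfold_splits(assoc, C, k=11, seed=0)


class TestWilcoxon:
    def test_identical_vectors(self):
        assert pm.wilcoxon_compare([0.5] * 10, [0.5] * 10) == 1.0

    def test_uniform_shift_significant(self):
        a = np.arange(10.0)
        assert pm.wilcoxon_compare(a + 1.0, a) < 0.05

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            pm.wilcoxon_compare([1.0], [2.0])

    def test_matches_scipy(self, rng):
        from scipy import stats

        a, b = rng.random(12), rng.random(12)
        assert pm.wilcoxon_compare(a, b) == pytest.approx(
            stats.wilcoxon(a, b, alternative="two-sided").pvalue
        )


class TestRunCvSmall:
    def test_determinism_and_leakage_guard(self, small_bundle):
        b = small_bundle
        C_ss, _ = pm.learn_affinity(b.site_views(), pm.MvSolverConfig(max_iter=150))
        C_dd, _ = pm.learn_affinity(b.disease_views(), pm.MvSolverConfig(max_iter=150))
        kwargs = dict(
            graph_config=pm.GraphConfig(tau=0.1),
            enc=pm.EncoderConfig(hidden_dim=16, seed=0),
            adv=pm.AdvConfig(enabled=True),
            tr=pm.TrainConfig(epochs=40),
            sampler=pm.SamplerConfig(method="gba", ratio=1.0),
            k=5,
            seed=3,
        )
        r1 = pm.run_cv(b.associations, C_ss, C_dd, b.site_semantic, b.disease_semantic, **kwargs)
        r2 = pm.run_cv(b.associations, C_ss, C_dd, b.site_semantic, b.disease_semantic, **kwargs)
        assert r1.per_fold == r2.per_fold
        assert all(np.isfinite(f["auc"]) for f in r1.per_fold)

    def test_lodocv_shapes_and_single_class_handling(self, small_bundle):
        b = small_bundle
        C_ss, _ = pm.learn_affinity(b.site_views(), pm.MvSolverConfig(max_iter=150))
        C_dd, _ = pm.learn_affinity(b.disease_views(), pm.MvSolverConfig(max_iter=150))
        with_pos = sorted({d for _, d in b.associations.positives})[:3]
        out = pm.run_lodocv(
            b.associations, C_ss, C_dd, b.site_semantic, b.disease_semantic,
            pm.GraphConfig(tau=0.1),
            enc=pm.EncoderConfig(hidden_dim=16, seed=0),
            tr=pm.TrainConfig(epochs=40),
            diseases=with_pos,
        )
        assert len(out) == len(with_pos)
        assert all(d in with_pos for d, _ in out)

    def test_lodocv_skips_disease_without_positives(self, small_bundle):
        b = small_bundle
        no_pos = [d for d in b.associations.disease_index
                  if not any(dd == d for _, dd in b.associations.positives)]
        if not no_pos:
            pytest.skip("every disease has a positive in this bundle")
        C_ss, _ = pm.learn_affinity(b.site_views(), pm.MvSolverConfig(max_iter=100))
        C_dd, _ = pm.learn_affinity(b.disease_views(), pm.MvSolverConfig(max_iter=100))
        with pytest.warns(UserWarning, match="no validated sites"):
            out = pm.run_lodocv(
                b.associations, C_ss, C_dd, b.site_semantic, b.disease_semantic,
                pm.GraphConfig(tau=0.1),
                enc=pm.EncoderConfig(hidden_dim=8, seed=0),
                tr=pm.TrainConfig(epochs=5),
                diseases=no_pos[:1],
            )
        assert out == []
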