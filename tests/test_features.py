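import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scmod.features import (
    audit_no_leak,
    build_reference_sets,
    feature_names,
    featurize_samples,
    featurize_training,
    perturb,
    spearman_pairs,
    split_train_test,
)
from scmod.preprocess import ExpressionDataset
from scmod.simulate import SimulationSpec, simulate
from scmod.specificity import SpecificEdgeSet


@pytest.fixture(scope="module")
def small_world():
    """Small simulated study with hand-built specific edge sets."""
    ds, truth = simulate(
        SimulationSpec(T=2, sizes=(16, 24), n_genes=60, module_size=10,
                       n_shared_modules=1, shared_size=10, seed=3)
    )
    edge_sets = {}
    for s in ds.subtypes:
        genes = sorted(truth.specific[s])
        pairs = [(genes[i], genes[j]) for i in range(len(genes))
                 for j in range(i + 1, len(genes))][:20]
        edges = pd.DataFrame(
            {"gene_a": [a for a, _ in pairs], "gene_b": [b for _, b in pairs],
             "delta": 0.5}
        )
        edge_sets[s] = SpecificEdgeSet(
            subtype=s, module=1, module_genes=set(genes), edges=edges
        )
    return ds, edge_sets


class TestSplit:
    def test_stratified_counts(self, small_world):
        ds, _ = small_world
        train, test = split_train_test(ds, 0.1, seed=0)
        labels = ds.labels
        assert sorted(train + test) == sorted(ds.sample_ids)
        for s, n in [("grp01", 16), ("grp02", 24)]:
            n_test = sum(labels[t] == s for t in test)
            assert n_test == max(1, round(0.1 * n))

    def test_zero_fraction_all_train(self, small_world):
        ds, _ = small_world
        train, test = split_train_test(ds, 0.0, seed=0)
        assert test == [] and len(train) == ds.n_samples

    def test_deterministic(self, small_world):
        ds, _ = small_world
        assert split_train_test(ds, 0.2, seed=5) == split_train_test(ds, 0.2, seed=5)


class TestSpearmanPairs:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(5, 9))
        ia = np.array([0, 1, 2])
        ib = np.array([3, 4, 0])
        got = spearman_pairs(M, ia, ib)
        for k in range(3):
            expected = stats.spearmanr(M[ia[k]], M[ib[k]]).statistic
            assert got[k] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_zero(self):
        M = np.vstack([np.ones(6), np.arange(6.0)])
        assert spearman_pairs(M, np.array([0]), np.array([1]))[0] == 0.0


class TestReferenceSets:
    def test_counts_and_range(self, small_world):
        ds, edge_sets = small_world
        train, test = split_train_test(ds, 0.1, seed=0)
        refs = build_reference_sets(ds, train, edge_sets, P=8, n_sets=5, seed=1)
        assert len(refs) == 5
        for ref in refs:
            assert ref.subtypes == ds.subtypes
            for s in ref.subtypes:
                assert len(ref.reference_samples(s)) == 8
                cor = ref.reference_cor(s)
                assert len(cor) == 20
                assert np.all(cor >= -1) and np.all(cor <= 1)

    def test_deterministic(self, small_world):
        ds, edge_sets = small_world
        train, _ = split_train_test(ds, 0.1, seed=0)
        a = build_reference_sets(ds, train, edge_sets, P=8, n_sets=3, seed=9)
        b = build_reference_sets(ds, train, edge_sets, P=8, n_sets=3, seed=9)
        for ra, rb in zip(a, b):
            for s in ra.subtypes:
                assert ra.reference_samples(s) == rb.reference_samples(s)
                assert np.array_equal(ra.reference_cor(s), rb.reference_cor(s))

    def test_oversized_p_errors(self, small_world):
        ds, edge_sets = small_world
        train, _ = split_train_test(ds, 0.1, seed=0)
        with pytest.raises(ValueError, match="P="):
            build_reference_sets(ds, train, edge_sets, P=100, n_sets=2, seed=0)

    def test_no_test_sample_in_references(self, small_world):
        ds, edge_sets = small_world
        train, test = split_train_test(ds, 0.2, seed=2)
        refs = build_reference_sets(ds, train, edge_sets, P=8, n_sets=4, seed=3)
        audit_no_leak(refs, test)  # must not raise
        with pytest.raises(AssertionError):
            audit_no_leak(refs, train[:1] + test)


class TestPerturb:
    def test_length_and_bounds(self, small_world):
        ds, edge_sets = small_world
        train, test = split_train_test(ds, 0.1, seed=0)
        refs = build_reference_sets(ds, train, edge_sets, P=8, n_sets=2, seed=0)
        vec = perturb(ds.values[test[0]], refs[0], sample_id=test[0])
        assert vec.shape == (2 * 20,)  # T * E
        assert np.all(vec >= 0) and np.all(vec <= 2)

    def test_deterministic(self, small_world):
        ds, edge_sets = small_world
        train, test = split_train_test(ds, 0.1, seed=0)
        refs = build_reference_sets(ds, train, edge_sets, P=8, n_sets=1, seed=0)
        v1 = perturb(ds.values[test[0]], refs[0], sample_id=test[0])
        v2 = perturb(ds.values[test[0]], refs[0], sample_id=test[0])
        assert np.array_equal(v1, v2)

    def test_missing_gene_errors(self, small_world):
        ds, edge_sets = small_world
        train, test = split_train_test(ds, 0.1, seed=0)
        refs = build_reference_sets(ds, train, edge_sets, P=8, n_sets=1, seed=0)
        broken = ds.values[test[0]].drop(ds.values.index[0])
        with pytest.raises(ValueError, match="missing"):
            perturb(broken, refs[0], sample_id="nope")

    def test_leave_one_out_when_sample_in_reference(self, small_world):
        """A reference member's perturbation compares the draw with and
        without itself, not a duplicated expansion."""
        ds, edge_sets = small_world
        train, _ = split_train_test(ds, 0.1, seed=0)
        refs = build_reference_sets(ds, train, edge_sets, P=8, n_sets=1, seed=0)
        sub = refs[0].refs[ds.subtypes[0]]
        member = sub.sample_ids[0]
        without = np.delete(sub.values, 0, axis=1)
        expected = np.abs(sub.cor - spearman_pairs(without, sub.ia, sub.ib))
        vec = perturb(ds.values[member], refs[0], sample_id=member)
        assert np.allclose(vec[:20], expected, atol=1e-12)


class TestFeaturizeTraining:
    def test_balance_example(self):
        """9 vs 90 training samples, 10 sets: both classes yield 90."""
        ds, truth = simulate(
            SimulationSpec(T=2, sizes=(9, 90), n_genes=40, module_size=8,
                           n_shared_modules=0, shared_size=0, seed=6)
        )
        edge_sets = {}
        for s in ds.subtypes:
            genes = sorted(truth.specific[s])
            pairs = [(genes[i], genes[j]) for i in range(len(genes))
                     for j in range(i + 1, len(genes))][:10]
            edge_sets[s] = SpecificEdgeSet(
                subtype=s, module=1, module_genes=set(genes),
                edges=pd.DataFrame({"gene_a": [a for a, _ in pairs],
                                    "gene_b": [b for _, b in pairs],
                                    "delta": 0.5}),
            )
        train = ds.sample_ids
        refs = build_reference_sets(ds, train, edge_sets, P=5, n_sets=10, seed=0)
        df = featurize_training(ds, train, refs, edge_sets, seed=0)
        counts = df["label"].value_counts()
        assert counts["grp01"] == 90
        assert counts["grp02"] == 90

    def test_single_set_no_augmentation(self, small_world):
        ds, edge_sets = small_world
        train, _ = split_train_test(ds, 0.1, seed=0)
        refs = build_reference_sets(ds, train, edge_sets, P=8, n_sets=1, seed=0)
        df = featurize_training(ds, train, refs, edge_sets, seed=0)
        assert len(df) == len(train)

    def test_labels_match_source_samples(self, small_world):
        ds, edge_sets = small_world
        train, _ = split_train_test(ds, 0.1, seed=0)
        refs = build_reference_sets(ds, train, edge_sets, P=8, n_sets=3, seed=0)
        df = featurize_training(ds, train, refs, edge_sets, seed=0)
        for (sid, _), label in df["label"].items():
            assert label == ds.labels[sid]
        assert not df.drop(columns="label").isna().any().any()
        assert df.shape[1] - 1 == 2 * 20

    def test_feature_names_order(self, small_world):
        _, edge_sets = small_world
        names = feature_names(edge_sets)
        assert len(names) == 40
        assert all(n.startswith("grp01__") for n in names[:20])
        assert all(n.startswith("grp02__") for n in names[20:])


def test_featurize_samples_all_sets(small_world):
    ds, edge_sets = small_world
    train, test = split_train_test(ds, 0.1, seed=0)
    refs = build_reference_sets(ds, train, edge_sets, P=8, n_sets=4, seed=0)
    df = featurize_samples(ds, test, refs, edge_sets)
    assert len(df) == len(test) * 4
    assert set(df.index.get_level_values("set_id")) == {0, 1, 2, 3}
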