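import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialink.errors import SamplingError, ValidationError
from spatialink.robustness import (
    CorruptionSpec,
    add_fake_edges,
    add_fold_noise,
    apply_dropout,
    compute_auprc,
    compute_auroc,
    compute_auroc_trapezoid,
    compute_fpr_at_threshold,
    remove_edges,
)
from spatialink.spatial_graph import CellGraph


def test_corruption_spec_validation():
    CorruptionSpec("gaussian_fold_noise", 2.0)
    with pytest.raises(ValidationError):
        CorruptionSpec("bogus", 0.5)
    with pytest.raises(ValidationError):
        CorruptionSpec("gene_dropout", 1.0)
    with pytest.raises(ValidationError):
        CorruptionSpec("edge_addition", 11.0)
    with pytest.raises(ValidationError):
        CorruptionSpec("crop", -0.1)


class TestFoldNoise:
    def test_sigma_zero_is_identity_and_pure(self, rng):
        X = rng.random((5, 4))
        X0 = X.copy()
        out = add_fold_noise(X, 0.0, seed=1)
        np.testing.assert_array_equal(out, X)
        np.testing.assert_array_equal(X, X0)
        assert out is not X

    def test_zeros_stay_zero(self):
        X = np.array([[0.0, 2.0], [3.0, 0.0]])
        out = add_fold_noise(X, 5.0, seed=0)
        assert out[0, 0] == 0.0 and out[1, 1] == 0.0

    def test_log2_ratio_follows_stated_distribution(self):
        """Monte-Carlo: log2 of the noise ratio is N(0, sigma)."""
        sigma = 0.8
        n = 100_000
        X = np.ones((n, 1))
        out = add_fold_noise(X, sigma, seed=42)
        r = np.log2(out[:, 0])
        assert abs(r.mean()) < 3 * sigma / np.sqrt(n)
        assert abs(r.std() - sigma) < 0.02 * sigma


class TestApplyDropout:
    def test_fraction_zero_is_identity(self, rng):
        X = rng.random((6, 5))
        np.testing.assert_array_equal(apply_dropout(X, "gene", 0.0, 0), X)
        np.testing.assert_array_equal(apply_dropout(X, "value", 0.0, 0), X)

    def test_gene_kind_zeroes_exact_column_count(self, rng):
        X = rng.random((20, 10)) + 0.1
        out = apply_dropout(X, "gene", 0.5, seed=3)
        zero_cols = (out == 0).all(axis=0)
        assert zero_cols.sum() == 5

    def test_value_kind_exact_count_and_preserves_zeros(self, rng):
        X = rng.random((10, 10))
        X[X < 0.3] = 0.0
        nz = (X > 0).sum()
        out = apply_dropout(X, "value", 0.4, seed=1)
        assert (X == 0).sum() == ((X == 0) & (out == 0)).sum()  # old zeros intact
        assert (out == 0).sum() - (X == 0).sum() == round(0.4 * nz)


class TestEdgeCorruptions:
    def _graph(self):
        edges = {(i, i + 1) for i in range(99)} | {(0, 50)}
        return CellGraph(100, edges)

    def test_remove_counts_and_disjointness(self):
        g = self._graph()
        reduced, removed = remove_edges(g, 0.5, seed=0)
        assert len(removed) == 50
        assert len(reduced.edges) == 50
        assert not (removed & reduced.edges)
        assert removed | reduced.edges == g.edges
        assert g.n_edges == 100  # input untouched

    def test_remove_fraction_zero(self):
        g = self._graph()
        reduced, removed = remove_edges(g, 0.0, seed=0)
        assert removed == set() and reduced.edges == g.edges

    def test_add_fakes_distinct_from_real(self):
        g = self._graph()
        aug, fakes = add_fake_edges(g, 2.0, seed=0)
        assert len(fakes) == 200
        assert not (fakes & g.edges)
        assert aug.edges == g.edges | fakes

    def test_add_fold_zero(self):
        g = self._graph()
        aug, fakes = add_fake_edges(g, 0.0, seed=0)
        assert fakes == set() and aug.edges == g.edges

    def test_add_too_many_reports_feasible_maximum(self):
        g = CellGraph(5, {(0, 1), (1, 2), (2, 3), (3, 4)})
        with pytest.raises(SamplingError, match="feasible"):
            add_fake_edges(g, 10.0, seed=0)


class TestAUROC:
    def test_trivial_values(self):
        assert compute_auroc([1.0, 1.0], [0.0, 0.0]) == 1.0
        assert compute_auroc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_hand_counted_example(self):
        # pairs: (.9,.6) win, (.9,.1) win, (.4,.6) loss, (.4,.1) win -> 3/4
        assert compute_auroc([0.9, 0.4], [0.6, 0.1]) == 0.75

    def test_pair_counting_equals_trapezoid_on_random_instances(self, rng):
        """The two computation routes agree to 1e-12, ties included."""
        for _ in range(100):
            n_pos = rng.integers(1, 30)
            n_neg = rng.integers(1, 30)
            # coarse grid forces ties
            pos = rng.integers(0, 5, n_pos) / 4
            neg = rng.integers(0, 5, n_neg) / 4
            a = compute_auroc(pos, neg)
            b = compute_auroc_trapezoid(pos, neg)
            assert abs(a - b) < 1e-12

    def test_brute_force_pair_count_oracle(self, rng):
        pos = rng.random(15)
        neg = rng.random(20)
        wins = sum(p > q for p in pos for q in neg)
        ties = sum(p == q for p in pos for q in neg)
        expect = (wins + 0.5 * ties) / (15 * 20)
        assert compute_auroc(pos, neg) == pytest.approx(expect, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            compute_auroc([], [1.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        pos, neg = rng.random(10), rng.random(12)
        before = compute_auroc(pos, neg)
        f = lambda x: np.exp(3 * x) - 1  # strictly increasing
        assert compute_auroc(f(pos), f(neg)) == pytest.approx(before, abs=1e-12)


def _brute_force_auprc(pos, neg):
    """Step-interpolated area: sum over descending thresholds of
    (recall gain) x precision."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = (labels[pred] == 1).sum()
        precision = tp / pred.sum()
        recall = tp / len(pos)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestAUPRC:
    def test_perfect_separation(self):
        assert compute_auprc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_reversed_single_pair(self):
        assert compute_auprc([0.0], [1.0]) <= 0.5

    def test_matches_brute_force_threshold_sweep(self, rng):
        for _ in range(30):
            pos = rng.integers(0, 8, rng.integers(1, 10)) / 7
            neg = rng.integers(0, 8, rng.integers(1, 10)) / 7
            assert compute_auprc(pos, neg) == pytest.approx(
                _brute_force_auprc(pos, neg), abs=1e-12
            )


class TestFPR:
    def test_trivial_thresholds(self):
        neg = [0.1, 0.2, 0.3]
        assert compute_fpr_at_threshold(neg, 0.9) == 0.0
        assert compute_fpr_at_threshold(neg, -np.inf) == 1.0

    def test_counting(self):
        neg = [0.1] * 7 + [0.9] * 3
        assert compute_fpr_at_threshold(neg, 0.5) == pytest.approx(0.3)


def test_benchmark_zero_magnitude_matches_plain_run(small_tissue):
    """A magnitude-0 noise corruption with one repeat is exactly a plain
    train/evaluate run on the held-out split."""
    from spatialink import vgae_core
    from spatialink.robustness import _evaluate_run, run_benchmark
    from spatialink.spatial_graph import build_adjacency, split_edges

    ds, _ = small_tissue
    cfg = vgae_core.ModelConfig(hidden1=16, latent=8, disc_h1=8, disc_h2=8,
                                epochs=20, seed=0)
    spec = CorruptionSpec("gaussian_fold_noise", 0.0, seed=5)
    table = run_benchmark(ds, spec, repeats=1, config=cfg)
    graph = build_adjacency(ds.coordinates)
    split = split_edges(graph, 0.1, 100.0, seed=5)
    plain = _evaluate_run(ds, graph, cfg, sorted(split.test_pos),
                          sorted(split.test_neg), split=split, seed=5)
    assert table.loc[0, "auroc"] == plain["auroc"]
    assert list(table.columns[:3]) == ["repeat", "kind", "magnitude"]
    assert len(table) == 1
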