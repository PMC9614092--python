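"""The five reduction front-ends: contracts, oracles, invariants."""

import numpy as np
import pytest

import sketchgs as sg
import sketchgs.reduce as red
from sketchgs.rnla import ImportanceDistribution, LeverageScores


@pytest.fixture(scope="module")
def X20():
    rng = np.random.default_rng(20)
    raw = sg.MarkerMatrix(rng.integers(0, 3, size=(20, 64)).astype(float))
    clean, _ = sg.clean_markers(raw, maf_min=0.05, max_missing=0.0)
    return sg.standardize(clean)


def scores_of(vals):
    v = np.asarray(vals, dtype=float)
    return LeverageScores(scores=v, rank_used=1, kind="exact")


class TestRandomProjection:
    def test_shapes_and_identity_passthrough(self, X20):
        r = sg.reduce_random_projection(X20, 10, seed=1)
        assert r.values.shape == (20, 10)
        assert r.mode == "projected" and not r.selected_marker_ids
        full = sg.reduce_random_projection(X20, X20.n_markers, seed=1, identity=True)
        np.testing.assert_array_equal(full.values, X20.values)
        with pytest.raises(ValueError):
            sg.reduce_random_projection(X20, 5, seed=1, identity=True)
        with pytest.raises(ValueError):
            sg.reduce_random_projection(X20, X20.n_markers + 1, seed=1)

    def test_frobenius_isometry_in_expectation(self, X20):
        base = np.sum(X20.values**2)
        ratios = np.array(
            [
                np.sum(sg.reduce_random_projection(X20, 16, seed=s).values ** 2) / base
                for s in range(500)
            ]
        )
        se = ratios.std(ddof=1) / np.sqrt(ratios.size)
        assert abs(ratios.mean() - 1.0) < 3 * se


class TestRandomSampling:
    def test_concentrated_probs_frequency(self, X20):
        X4 = X20.subset_markers(np.arange(4))
        probs = ImportanceDistribution(np.array([0.97, 0.01, 0.01, 0.01]))
        hits = sum(
            sg.reduce_random_sampling(X4, 1, probs, seed=s).selected_indices[0] == 0
            for s in range(10_000)
        )
        assert abs(hits / 10_000 - 0.97) < 4 * np.sqrt(0.97 * 0.03 / 10_000)

    def test_exhaustive_determinism_and_values(self, X20):
        d = X20.n_markers
        probs = ImportanceDistribution(np.full(d, 1.0 / d))
        r = sg.reduce_random_sampling(X20, d, probs, seed=0)
        assert sorted(r.selected_marker_ids) == sorted(X20.marker_ids)
        a = sg.reduce_random_sampling(X20, 5, probs, seed=7)
        b = sg.reduce_random_sampling(X20, 5, probs, seed=7)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
        # selected values are exactly the parent columns
        np.testing.assert_array_equal(a.values, X20.values[:, a.selected_indices])

    def test_support_limit(self, X20):
        X4 = X20.subset_markers(np.arange(4))
        probs = ImportanceDistribution(np.array([0.5, 0.5, 0.0, 0.0]))
        with pytest.raises(ValueError, match="positive probability"):
            sg.reduce_random_sampling(X4, 3, probs, seed=0)

    def test_inclusion_matches_without_replacement_oracle(self, X20):
        """Empirical inclusion frequencies match sequential-sampling theory."""
        X5 = X20.subset_markers(np.arange(5))
        p = np.array([0.4, 0.25, 0.15, 0.15, 0.05])
        probs = ImportanceDistribution(p)
        # oracle: P(i in draw of 2) = p_i + sum_{j!=i} p_j * p_i / (1 - p_j)
        incl = p + np.array(
            [sum(p[j] * p[i] / (1 - p[j]) for j in range(5) if j != i) for i in range(5)]
        )
        counts = np.zeros(5)
        n = 5000
        for s in range(n):
            counts[sg.reduce_random_sampling(X5, 2, probs, seed=s).selected_indices] += 1
        se = np.sqrt(incl * (1 - incl) / n)
        assert np.all(np.abs(counts / n - incl) < 4 * se)


class TestDeterministic:
    def test_top_k_and_nesting(self, X20):
        s = scores_of([0.9, 0.5, 0.4, 0.1] + [0.0] * (X20.n_markers - 4))
        r = sg.reduce_deterministic(X20, 2, s)
        assert r.selected_indices.tolist() == [0, 1]
        rng = np.random.default_rng(0)
        s2 = scores_of(rng.random(X20.n_markers))
        prev = set()
        for k in range(1, X20.n_markers + 1):
            cur = set(sg.reduce_deterministic(X20, k, s2).selected_indices.tolist())
            assert prev <= cur
            prev = cur
        assert prev == set(range(X20.n_markers))

    def test_tie_break_low_index(self, X20):
        s = scores_of([0.5, 0.9, 0.5] + [0.0] * (X20.n_markers - 3))
        r = sg.reduce_deterministic(X20, 2, s)
        assert r.selected_indices.tolist() == [1, 0]

    def test_threshold_count_hand_example(self):
        s = scores_of([0.9, 0.5, 0.4, 0.1])
        assert red.threshold_count(s, 0.95 * 1.9) == 4
        assert red.threshold_count(s, 1.0) == 2
        with pytest.raises(ValueError):
            red.threshold_count(s, 2.0)


class TestCluster:
    def test_separated_blocks_get_one_representative_each(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal(30)
        v = rng.standard_normal(30)
        cols = np.column_stack(
            [u + 0.01 * rng.standard_normal(30) for _ in range(3)]
            + [v + 0.01 * rng.standard_normal(30) for _ in range(3)]
        )
        X = sg.MarkerMatrix(cols)
        r = sg.reduce_cluster(X, 2, seed=0)
        groups = {tuple(sorted({0, 1, 2} & set(r.selected_indices.tolist()))),
                  tuple(sorted({3, 4, 5} & set(r.selected_indices.tolist())))}
        assert all(len(g) == 1 for g in groups)

    def test_k_equals_d_returns_everything(self, X20):
        r = sg.reduce_cluster(X20, X20.n_markers, seed=0)
        assert sorted(r.selected_marker_ids) == sorted(X20.marker_ids)
        np.testing.assert_array_equal(r.values, X20.values)

    def test_tree_built_once_across_sizes(self, X20, monkeypatch):
        red._TREE_CACHE.clear()
        calls = {"n": 0}
        orig = red.linkage

        def counting_linkage(*a, **kw):
            calls["n"] += 1
            return orig(*a, **kw)

        monkeypatch.setattr(red, "linkage", counting_linkage)
        sg.reduce_cluster(X20, 4, seed=0)
        sg.reduce_cluster(X20, 9, seed=1)
        assert calls["n"] == 1


class TestRidge:
    def test_planted_signal_ranked_first(self):
        rng = np.random.default_rng(2)
        raw = sg.MarkerMatrix(rng.integers(0, 3, size=(40, 50)).astype(float))
        X = sg.standardize(sg.clean_markers(raw, maf_min=0.05)[0])
        y = 3.0 * X.values[:, 7] + 0.01 * rng.standard_normal(40)
        r, ranking = sg.reduce_ridge(X, y, 5, seed=0)
        assert ranking.order[0] == 7
        assert r.selected_indices[0] == 7
        assert ranking.lambda_chosen in ranking.lambda_grid

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((30, 80))
        y = rng.standard_normal(30)
        lambdas = np.logspace(-2, 4, 10)
        betas, _ = red._ridge_path(A, y, lambdas)
        norms = np.linalg.norm(betas, axis=0)
        assert np.all(np.diff(norms) < 0)

    def test_too_few_lines_for_folds(self):
        X = sg.MarkerMatrix(np.random.default_rng(0).standard_normal((3, 10)),
                            standardized=True)
        with pytest.raises(ValueError, match="fold"):
            sg.reduce_ridge(X, np.zeros(3), 2, cv_folds=5)


def test_full_size_selection_reproduces_full_kernel(X20):
    """Every selection method at k = d yields the exact full-data G."""
    d = X20.n_markers
    G_full = X20.values @ X20.values.T / d
    ex = sg.exact_leverage(X20)
    probs = sg.importance_distribution(ex)
    y = np.random.default_rng(4).standard_normal(X20.n_lines)
    outs = [
        sg.reduce_random_sampling(X20, d, probs, seed=1),
        sg.reduce_deterministic(X20, d, ex),
        sg.reduce_cluster(X20, d, seed=1),
        sg.reduce_ridge(X20, y, d, seed=1)[0],
    ]
    for r in outs:
        G = r.values @ r.values.T / d
        np.testing.assert_allclose(G, G_full, atol=1e-10)
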