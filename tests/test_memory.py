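"""Unit and property tests for the sparse attention memory module."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memae.memory import (
    MemoryBank,
    address_weights,
    cosine_similarity,
    hard_shrink,
    init_memory_bank,
    normalize_weights,
    retrieve,
    retrieve_batch_backward,
    retrieve_batch_forward,
    retrieve_map,
)


def bank_of(items, alpha=None, epsilon=1e-12):
    items = np.asarray(items, dtype=float)
    n = items.shape[0]
    return MemoryBank(items=items, alpha=(2.0 / n if alpha is None else alpha),
                      epsilon=epsilon)


class TestCosineSimilarity:
    @pytest.mark.parametrize("z, m, expected", [
        ((1, 2), (1, 2), 1.0),
        ((1, 0), (0, 1), 0.0),
        ((1, 0), (1, 1), 1 / np.sqrt(2)),
        ((2, 0), (-1, 0), -1.0),
    ])
    def test_values(self, z, m, expected):
        assert cosine_similarity(z, m) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        z, m = rng.normal(size=4), rng.normal(size=4)
        assert cosine_similarity(z, m) == pytest.approx(cosine_similarity(m, z))
        assert cosine_similarity(3.7 * z, m) == pytest.approx(cosine_similarity(z, m))

    def test_zero_query_guard(self):
        assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cosine_similarity([1, 2], [1, 2, 3])


class TestAddressWeights:
    def test_identical_items_give_uniform_weights(self):
        z = np.array([1.0, 2.0, 3.0])
        bank = bank_of(np.tile(z, (4, 1)))
        np.testing.assert_allclose(address_weights(z, bank), np.full(4, 0.25),
                                   atol=1e-12)

    def test_matches_explicit_softmax_of_cosines(self):
        rng = np.random.default_rng(1)
        bank = bank_of(rng.normal(size=(5, 3)))
        z = rng.normal(size=3)
        sims = np.array([cosine_similarity(z, m) for m in bank.items])
        expected = np.exp(sims) / np.exp(sims).sum()
        np.testing.assert_allclose(address_weights(z, bank), expected, atol=1e-12)

    def test_softmax_arithmetic(self):
        # similarities (ln 2, 0) must give weights (2/3, 1/3)
        s = np.array([np.log(2.0), 0.0])
        w = np.exp(s) / np.exp(s).sum()
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)


class TestHardShrink:
    def test_at_threshold_is_zero(self):
        assert hard_shrink(np.array([0.25]), alpha=0.25)[0] == 0.0

    def test_below_threshold_is_zero(self):
        assert hard_shrink(np.array([0.001]), alpha=0.0067)[0] == 0.0

    def test_above_threshold_passes_through(self):
        out = hard_shrink(np.array([0.5]), alpha=0.1, epsilon=1e-12)
        assert out[0] == pytest.approx(0.5, abs=1e-9)

    def test_matches_formula(self):
        k = np.array([0.0, 0.05, 0.2, 0.7])
        alpha, eps = 0.1, 1e-6
        expected = np.maximum(k - alpha, 0) * k / (np.abs(k - alpha) + eps)
        np.testing.assert_allclose(hard_shrink(k, alpha, eps), expected)

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError):
            hard_shrink(np.array([-0.1, 0.2]), alpha=0.1)


class TestNormalizeWeights:
    def test_l1_normalization(self):
        w = normalize_weights(np.array([0.5, 0.0, 0.3]), raw=np.array([0.4, 0.3, 0.3]))
        np.testing.assert_allclose(w.sparse, [0.625, 0.0, 0.375], atol=1e-12)
        assert not w.fallback

    def test_symmetric_input(self):
        w = normalize_weights(np.array([0.2, 0.2]), raw=np.array([0.5, 0.5]))
        np.testing.assert_allclose(w.sparse, [0.5, 0.5])

    def test_all_zero_falls_back_to_raw(self):
        w = normalize_weights(np.zeros(2), raw=np.array([0.7, 0.3]))
        np.testing.assert_allclose(w.sparse, [0.7, 0.3])
        assert w.fallback


class TestRetrieve:
    def test_one_hot_weights_return_the_item(self):
        items = np.eye(4)
        # softmax weights are (.175, .175, .175, .475); alpha=0.4 keeps only
        # the matching item, so retrieval is exactly one-hot
        bank = bank_of(items, alpha=0.4)
        out = retrieve(items[3] * 2.0, bank)
        np.testing.assert_allclose(out, items[3], atol=1e-9)

    def test_even_mixture(self):
        shrunk = np.array([0.3, 0.3])
        w = normalize_weights(shrunk, raw=np.array([0.5, 0.5]))
        items = np.array([[0.0, 2.0], [2.0, 0.0]])
        np.testing.assert_allclose(w.sparse @ items, [1.0, 1.0])

    def test_query_equal_to_item_with_orthogonal_rest(self):
        items = np.eye(3)
        # softmax weights are (.212, .576, .212); alpha=0.4 zeroes both
        # mismatched items and retrieval returns m_1 exactly
        bank = bank_of(items, alpha=0.4)
        out = retrieve(items[1], bank)
        # brute-force evaluation of the full chain
        sims = np.array([cosine_similarity(items[1], m) for m in items])
        raw = np.exp(sims) / np.exp(sims).sum()
        shrunk = hard_shrink(raw, bank.alpha, bank.epsilon)
        expected = normalize_weights(shrunk, raw).sparse @ items
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, items[1], atol=1e-9)

    def test_scale_invariance_in_query(self):
        rng = np.random.default_rng(2)
        bank = bank_of(rng.normal(size=(6, 4)))
        z = rng.normal(size=4)
        np.testing.assert_allclose(retrieve(z, bank), retrieve(17.3 * z, bank),
                                   atol=1e-12)

    def test_convex_hull_bound(self):
        rng = np.random.default_rng(3)
        bank = bank_of(rng.normal(size=(8, 5)))
        z = rng.normal(size=5)
        assert np.max(np.abs(retrieve(z, bank))) <= np.max(np.abs(bank.items)) + 1e-12


class TestRetrieveMap:
    def test_single_column_equals_retrieve(self):
        rng = np.random.default_rng(4)
        bank = bank_of(rng.normal(size=(5, 4)))
        z = rng.normal(size=4)
        np.testing.assert_allclose(retrieve_map(z[:, None], bank)[:, 0],
                                   retrieve(z, bank))

    def test_identical_columns_identical_outputs(self):
        rng = np.random.default_rng(5)
        bank = bank_of(rng.normal(size=(5, 4)))
        z = rng.normal(size=4)
        fm = np.stack([z, z], axis=1)
        out = retrieve_map(fm, bank)
        np.testing.assert_allclose(out[:, 0], out[:, 1])

    def test_equals_column_loop_oracle(self):
        rng = np.random.default_rng(6)
        bank = bank_of(rng.normal(size=(5, 4)))
        fm = rng.normal(size=(4, 3))
        out = retrieve_map(fm, bank)
        oracle = np.stack([retrieve(fm[:, t], bank) for t in range(3)], axis=1)
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_dimension_mismatch(self):
        bank = bank_of(np.eye(3))
        with pytest.raises(ValueError):
            retrieve_map(np.zeros((4, 2)), bank)


class TestBankValidation:
    def test_alpha_interval_enforced(self):
        with pytest.raises(ValueError):
            MemoryBank(items=np.eye(4), alpha=0.9)  # > 3/4

    def test_default_init_shape_and_range(self):
        bank = init_memory_bank(300, 64, rng=np.random.default_rng(0))
        assert bank.items.shape == (300, 64)
        assert bank.alpha == pytest.approx(2 / 300)
        assert np.all(np.abs(bank.items) <= 1 / np.sqrt(64))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(2, 10), st.integers(2, 8), st.integers(0, 2 ** 31 - 1))
def test_weight_invariants(n, cf, seed):
    """Raw weights positive and sum to 1; sparse support within {k > alpha}."""
    rng = np.random.default_rng(seed)
    bank = init_memory_bank(n, cf, rng=rng)
    z = rng.normal(size=cf)
    raw = address_weights(z, bank)
    assert np.all(raw > 0)
    assert raw.sum() == pytest.approx(1.0, abs=1e-6)
    shrunk = hard_shrink(raw, bank.alpha, bank.epsilon)
    w = normalize_weights(shrunk, raw)
    assert np.all(w.sparse >= 0)
    assert w.sparse.sum() == pytest.approx(1.0, abs=1e-6)
    if not w.fallback:
        assert np.all(raw[w.sparse > 0] > bank.alpha)


def test_batched_gradients_match_finite_differences():
    """The analytic backward of the retrieval chain is exact to O(eps)."""
    rng = np.random.default_rng(7)
    bank = init_memory_bank(6, 5, alpha=2 / 6, rng=rng)
    queries = rng.normal(size=(4, 5))
    sens = rng.normal(size=(4, 5))

    zhat, cache = retrieve_batch_forward(queries, bank)
    d_q, d_m = retrieve_batch_backward(sens, cache, bank)

    def objective(q, items):
        bank2 = MemoryBank(items=items.copy(), alpha=bank.alpha, epsilon=bank.epsilon)
        out, _ = retrieve_batch_forward(q, bank2)
        return float(np.sum(out * sens))

    eps = 1e-6
    for arr, grad, pick in ((queries, d_q, "q"), (bank.items, d_m, "m")):
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            up, down = arr.copy(), arr.copy()
            up[i] += eps
            down[i] -= eps
            if pick == "q":
                num[i] = (objective(up, bank.items) - objective(down, bank.items)) / (2 * eps)
            else:
                num[i] = (objective(queries, up) - objective(queries, down)) / (2 * eps)
        np.testing.assert_allclose(grad, num, atol=1e-7)
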