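import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import planted_matrix, random_membership
from pasl.inference import (
    boxcox,
    deflate,
    infer_dictionary,
    normalized_variance,
    order_genesets,
    restricted_first_pc,
)


def dynamic_reference(X, G, lam, max_atoms):
    """Brute-force dynamic approach: re-solve over every geneset at each step."""
    R = np.asarray(X, dtype=float).copy()
    sizes = G.sizes
    sequence = []
    for _ in range(max_atoms):
        best = None
        for i in range(G.n_genesets):
            loading, var = restricted_first_pc(R, G.support(i))
            nv = normalized_variance(var, int(sizes[i]), lam)
            key = (-nv, int(sizes[i]), i)
            if best is None or key < best[0]:
                best = (key, i, loading, var, nv)
        _, i, loading, var, nv = best
        if var <= 0 or nv <= 0:
            break
        sequence.append(i)
        R -= np.outer(R @ loading, loading)
    return sequence


def static_reference(X, G, lam, max_atoms):
    """Static approach: rank once, then pop/accept, only refreshing the
    accepted geneset's own entry (linear-scan max, no full reorder)."""
    R = np.asarray(X, dtype=float).copy()
    sizes = G.sizes
    entries = {}
    for i in range(G.n_genesets):
        loading, var = restricted_first_pc(R, G.support(i))
        entries[i] = (normalized_variance(var, int(sizes[i]), lam), var, loading)
    sequence = []
    while len(sequence) < max_atoms and entries:
        i = min(entries, key=lambda k: (-entries[k][0], int(sizes[k]), k))
        # the atom itself is always recomputed on the current residual;
        # only the *ranking* stays static
        loading, var = restricted_first_pc(R, G.support(i))
        nv = normalized_variance(var, int(sizes[i]), lam)
        if var <= 0 or nv <= 0:
            del entries[i]
            continue
        sequence.append(i)
        R -= np.outer(R @ loading, loading)
        loading, var = restricted_first_pc(R, G.support(i))
        entries[i] = (normalized_variance(var, int(sizes[i]), lam), var, loading)
    return sequence


class TestBoxCox:
    @pytest.mark.parametrize(
        "y, lam, expected",
        [(27.0, 1 / 3, 6.0), (math.e, 0.0, 1.0), (5.0, 1.0, 4.0), (1.0, 0.7, 0.0)],
    )
    def test_closed_form_values(self, y, lam, expected):
        assert boxcox(y, lam) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            boxcox(0.0, 0.5)

    @given(st.floats(0.1, 1e4), st.floats(-2, 2))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_continuous_in_lambda_at_zero(self, y, lam):
        eps = 1e-9
        assert boxcox(y, eps) == pytest.approx(boxcox(y, 0.0), rel=1e-5, abs=1e-5)
        if lam != 0:
            assert np.isfinite(boxcox(y, lam))


class TestNormalizedVariance:
    def test_division_by_boxcox_of_size(self):
        assert normalized_variance(12.0, 27, 1 / 3) == pytest.approx(2.0)

    def test_disabled_normalization_returns_raw(self):
        assert normalized_variance(3.7, 100, None) == 3.7

    def test_smaller_geneset_scores_higher_at_equal_raw_variance(self):
        assert normalized_variance(5.0, 30, 1 / 3) > normalized_variance(5.0, 200, 1 / 3)

    def test_singleton_guard_uses_size_two_divisor(self):
        assert normalized_variance(4.0, 1, 1 / 3) == pytest.approx(
            4.0 / boxcox(2, 1 / 3)
        )


class TestRestrictedFirstPc:
    def test_perfectly_correlated_pair(self, rng):
        col = rng.standard_normal(200)
        col = (col - col.mean()) / col.std(ddof=1)
        X = np.column_stack([col, col, rng.standard_normal(200) * 0.0])
        loading, var = restricted_first_pc(X, np.array([0, 1]))
        assert var == pytest.approx(2.0, rel=1e-10)
        assert np.abs(loading[:2]) == pytest.approx(np.full(2, 1 / np.sqrt(2)))
        assert loading[2] == 0.0

    def test_single_column_support(self, rng):
        X = rng.standard_normal((50, 4))
        loading, var = restricted_first_pc(X, np.array([2]))
        assert var == pytest.approx(np.sum(X[:, 2] ** 2) / 49)
        assert loading[2] == 1.0 and np.count_nonzero(loading) == 1

    def test_matches_dense_svd_oracle(self, rng):
        X = rng.standard_normal((6, 10))
        support = np.array([1, 4, 7, 8])
        loading, var = restricted_first_pc(X, support)
        s = np.linalg.svd(X[:, support], compute_uv=False)
        assert var == pytest.approx(s[0] ** 2 / 5, rel=1e-10)
        assert np.linalg.norm(loading) == pytest.approx(1.0)

    def test_zero_block_flags_zero_variance(self):
        X = np.zeros((5, 3))
        loading, var = restricted_first_pc(X, np.array([0, 1]))
        assert var == 0.0 and not loading.any()

    def test_sign_convention_largest_coefficient_positive(self, rng):
        X = rng.standard_normal((20, 6))
        loading, _ = restricted_first_pc(X, np.arange(6))
        assert loading[np.argmax(np.abs(loading))] > 0


class TestDeflate:
    def test_rank_one_annihilation(self, rng):
        d = rng.standard_normal(8)
        d /= np.linalg.norm(d)
        X = np.outer(rng.standard_normal(12), d)
        assert np.allclose(deflate(X, d), 0.0)

    def test_idempotent(self, rng):
        X = rng.standard_normal((10, 7))
        d = rng.standard_normal(7)
        d /= np.linalg.norm(d)
        once = deflate(X, d)
        assert np.allclose(deflate(once, d), once)

    def test_pythagoras_frobenius_bookkeeping(self, rng):
        X = rng.standard_normal((15, 9))
        d = rng.standard_normal(9)
        d /= np.linalg.norm(d)
        Xp = deflate(X, d)
        assert np.sum(Xp**2) == pytest.approx(
            np.sum(X**2) - np.sum((X @ d) ** 2), rel=1e-10
        )

    def test_non_unit_loading_normalized_with_warning(self, rng):
        X = rng.standard_normal((6, 4))
        with pytest.warns(UserWarning, match="unit-norm"):
            Xp = deflate(X, np.array([2.0, 0, 0, 0]))
        assert np.allclose(Xp[:, 0], 0.0)


class TestOrderGenesets:
    def test_scaled_geneset_ranks_first(self, rng):
        G = random_membership(rng, 20, 2)
        # make the two genesets disjoint and equally sized
        m = np.zeros((2, 20), dtype=np.int8)
        m[0, :5] = 1
        m[1, 5:10] = 1
        G.matrix = m
        X = rng.standard_normal((30, 20))
        X[:, :5] *= 10
        entries = order_genesets(X, G, 1 / 3)
        assert entries[0].geneset_index == 0
        assert entries[0].normalized_variance >= entries[1].normalized_variance

    def test_permutation_invariance_of_ranked_names(self, rng):
        G = random_membership(rng, 25, 5)
        X = rng.standard_normal((20, 25))
        names1 = [G.geneset_names[e.geneset_index] for e in order_genesets(X, G, 1 / 3)]
        perm = rng.permutation(5)
        from pasl.genesets import MembershipMatrix

        G2 = MembershipMatrix(
            G.matrix[perm], [G.geneset_names[i] for i in perm], G.feature_ids
        )
        names2 = [G2.geneset_names[e.geneset_index] for e in order_genesets(X, G2, 1 / 3)]
        assert names1 == names2


class TestInferDictionary:
    def test_zero_atoms_records_initial_ordering_only(self, rng):
        G = random_membership(rng, 15, 3)
        X = rng.standard_normal((10, 15))
        atoms, trace = infer_dictionary(X, G, max_atoms=0)
        assert atoms == []
        assert len(trace.initial_ordering) == 3
        assert trace.records == []

    def test_planted_atom_recovered_inside_its_geneset(self, rng):
        G = random_membership(rng, 40, 5, min_size=6, max_size=10)
        X, planted = planted_matrix(rng, G, n=60, n_atoms=1, noise_sd=0.02)
        gi, d_true = planted[0]
        atoms, _ = infer_dictionary(X, G, t=0.9, max_atoms=1, stop_tol=0.0)
        atom = atoms[0]
        assert atom.geneset_index == gi
        assert set(atom.support) <= set(G.support(gi))
        assert abs(atom.loading @ d_true) > 0.99

    @pytest.mark.parametrize("seed", range(8))
    def test_t_one_equals_dynamic_reference(self, seed):
        rng = np.random.default_rng(seed)
        G = random_membership(rng, int(rng.integers(10, 50)), int(rng.integers(2, 10)))
        n = int(rng.integers(5, 30))
        X, _ = planted_matrix(rng, G, n=n, n_atoms=min(2, G.n_genesets), noise_sd=0.5)
        a1 = int(rng.integers(1, 8))
        atoms, _ = infer_dictionary(X, G, t=1.0, max_atoms=a1, stop_tol=0.0)
        assert [a.geneset_index for a in atoms] == dynamic_reference(X, G, 1 / 3, a1)

    @pytest.mark.parametrize("seed", range(8))
    def test_t_zero_equals_static_reference(self, seed):
        rng = np.random.default_rng(100 + seed)
        G = random_membership(rng, int(rng.integers(10, 40)), int(rng.integers(2, 8)))
        X, _ = planted_matrix(rng, G, n=20, n_atoms=min(2, G.n_genesets), noise_sd=0.5)
        a1 = 6
        atoms, trace = infer_dictionary(X, G, t=0.0, max_atoms=a1, stop_tol=0.0)
        assert trace.n_reorders == 1  # only the initial ordering
        assert [a.geneset_index for a in atoms] == static_reference(X, G, 1 / 3, a1)

    def test_atoms_unit_norm_support_in_one_geneset(self, rng):
        G = random_membership(rng, 30, 6)
        X, _ = planted_matrix(rng, G, n=25, n_atoms=3, noise_sd=0.3)
        atoms, _ = infer_dictionary(X, G, t=0.9, max_atoms=10, stop_tol=0.0)
        for atom in atoms:
            assert np.linalg.norm(atom.loading) == pytest.approx(1.0)
            assert set(atom.support) <= set(G.support(atom.geneset_index))

    def test_reconstruction_error_monotone_and_repeat_selection_allowed(self, rng):
        G = random_membership(rng, 30, 4, min_size=8, max_size=12)
        X, _ = planted_matrix(rng, G, n=40, n_atoms=2, noise_sd=0.5)
        atoms, trace = infer_dictionary(X, G, t=0.9, max_atoms=12, stop_tol=0.0)
        errs = [
            r["relative_reconstruction_error"] for r in trace.records if not r["reorder"]
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))
        assert len(atoms) > G.n_genesets  # some geneset contributed twice

    def test_stop_tolerance_halts_early(self, rng):
        G = random_membership(rng, 20, 3)
        X, _ = planted_matrix(rng, G, n=30, n_atoms=1, noise_sd=0.01)
        atoms, trace = infer_dictionary(X, G, t=0.9, max_atoms=15, stop_tol=0.5)
        assert len(atoms) < 15
        assert any("no longer decreasing" in note for note in trace.notes)

    def test_invalid_t_rejected(self, rng):
        G = random_membership(rng, 10, 2)
        with pytest.raises(ValueError, match="t must be"):
            infer_dictionary(np.zeros((4, 10)), G, t=1.5)
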