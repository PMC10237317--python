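"""PCA eigen spaces, subspace similarity, iterative vowel search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurovowel.vowel_search import (
    EigenSpace,
    SearchConfig,
    fit_pca,
    iterative_search,
    search_vowel,
    select_best_frame,
    similarity,
    similarity_batch,
)


def _orthonormal_space(dim, M, rng, vowel=""):
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    lam = np.sort(rng.uniform(0.5, 2.0, M))[::-1]
    return EigenSpace(q[:, :M].T, lam, vowel)


class TestFitPca:
    def test_rank_one_recovers_direction(self):
        e1 = np.zeros(8)
        e1[0] = 1.0
        space = fit_pca(np.tile(e1, (10, 1)), 1)
        np.testing.assert_allclose(np.abs(space.basis[0]), e1, atol=1e-12)
        assert space.eigenvalues[0] == pytest.approx(1.0)

    def test_two_direction_span_exact(self, rng):
        d1, d2 = np.zeros(8), np.zeros(8)
        d1[1], d2[4] = 1.0, 1.0
        coef = rng.standard_normal((20, 2))
        samples = coef @ np.vstack([d1, d2])
        space = fit_pca(samples, 2)
        proj = samples @ space.basis.T @ space.basis
        assert np.max(np.abs(samples - proj)) < 1e-8

    def test_reconstruction_error_is_tail_eigenvalue_sum(self, rng):
        x = rng.standard_normal((50, 32))
        space = fit_pca(x, 8)
        resid = x - x @ space.basis.T @ space.basis
        err = np.sum(resid**2) / len(x)
        w_full = np.linalg.eigvalsh((x.T @ x) / len(x))[::-1]
        assert err == pytest.approx(np.sum(w_full[8:]), abs=1e-6)

    def test_rank_deficiency_names_achieved_rank(self, rng):
        e1 = rng.standard_normal(10)
        with pytest.raises(np.linalg.LinAlgError, match="rank 1"):
            fit_pca(np.tile(e1, (12, 1)), 4)

    def test_basis_is_orthonormal_and_sorted(self, rng):
        space = fit_pca(rng.standard_normal((40, 16)), 8)
        np.testing.assert_allclose(
            space.basis @ space.basis.T, np.eye(8), atol=1e-10
        )
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)


class TestSimilarity:
    def test_own_basis_vector_scores_one(self, rng):
        space = _orthonormal_space(12, 4, rng)
        assert similarity(space.basis[0], space) == pytest.approx(1.0)

    def test_orthogonal_vector_scores_zero(self, rng):
        space = _orthonormal_space(12, 4, rng)
        # build a vector orthogonal to the basis via projection removal
        x = rng.standard_normal(12)
        x -= space.basis.T @ (space.basis @ x)
        assert similarity(x, space) == pytest.approx(0.0, abs=1e-10)

    def test_in_subspace_combination_scores_one(self, rng):
        space = _orthonormal_space(12, 4, rng)
        x = (space.basis[0] + space.basis[1]) / np.sqrt(2)
        assert similarity(x, space) == pytest.approx(1.0)

    def test_non_normalised_basis_still_correct(self, rng):
        # Eq keeps the ||phi||^2 divisor, so scaled bases score the same
        space = _orthonormal_space(12, 4, rng)
        scaled = EigenSpace.__new__(EigenSpace)
        scaled.basis = space.basis * 3.0
        scaled.eigenvalues = space.eigenvalues
        scaled.vowel = ""
        assert similarity_batch(space.basis[0][None], scaled)[0] == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(5)
        space = _orthonormal_space(10, 3, rng)
        x = rng.standard_normal(10)
        assert similarity(scale * x, space) == pytest.approx(similarity(x, space))

    def test_rotation_of_basis_spanning_same_subspace(self, rng):
        space = _orthonormal_space(10, 3, rng)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = EigenSpace(q @ space.basis, space.eigenvalues)
        x = rng.standard_normal(10)
        assert similarity(x, rotated) == pytest.approx(similarity(x, space))

    def test_bounded_on_random_vectors(self, rng):
        space = _orthonormal_space(26, 8, rng)
        x = rng.standard_normal((10_000, 26))
        s = similarity_batch(x, space)
        assert np.all(s >= -1e-12) and np.all(s <= 1 + 1e-12)

    def test_zero_vector_raises(self, rng):
        space = _orthonormal_space(10, 3, rng)
        with pytest.raises(ValueError):
            similarity(np.zeros(10), space)


class TestSelectBestFrame:
    def test_single_candidate_returned(self, rng):
        space = _orthonormal_space(26, 2, rng)
        chunk = np.abs(rng.standard_normal((1, 9, 26)))
        cfg = SearchConfig(search_last_k=1)
        x, (ch, fr) = select_best_frame(chunk, space, cfg)
        assert (ch, fr) == (0, 8)
        np.testing.assert_array_equal(x, chunk[0, 8])

    def test_planted_template_frame_wins(self, rng):
        space = _orthonormal_space(26, 2, rng)
        template = space.basis[0]  # lies exactly in the subspace: S = 1
        wins = 0
        for _ in range(100):
            chunk = rng.standard_normal((21, 9, 26)) * 0.2
            chunk[7, 6] = template  # electrode 7, frame 6 (inside last 6)
            _, (ch, fr) = select_best_frame(chunk, space)
            wins += (ch, fr) == (7, 6)
        assert wins >= 95

    def test_tie_breaks_to_earlier_frame(self, rng):
        space = _orthonormal_space(8, 1, rng)
        chunk = np.zeros((2, 9, 8))
        chunk[0, 4] = space.basis[0]
        chunk[1, 8] = space.basis[0]
        _, (ch, fr) = select_best_frame(chunk, space)
        assert fr == 4 and ch == 0

    def test_all_zero_chunk_raises(self, rng):
        space = _orthonormal_space(8, 1, rng)
        with pytest.raises(ValueError):
            select_best_frame(np.zeros((2, 9, 8)), space)


class TestIterativeSearch:
    def _template_corpus(self, rng, n_chunks=12, noise=0.01):
        """Chunks whose frames are one vowel template + small noise."""
        template = np.abs(rng.standard_normal(26)) + 0.5
        chunks = []
        for _ in range(n_chunks):
            c = np.abs(rng.standard_normal((4, 9, 26))) * noise
            c += template
            chunks.append(c)
        return template, chunks

    def test_converged_start_is_fixed_point(self, rng):
        template, chunks = self._template_corpus(rng)
        cfg = SearchConfig(n_iterations=4)
        space, trace = search_vowel(chunks, cfg, "a")
        # similarity already ~1 from iteration 1 and stays there
        assert trace.mean_similarity[0] > 0.999
        assert trace.mean_similarity[-1] >= trace.mean_similarity[0] - 1e-9

    def test_identical_chunks_rank_one_recovery(self, rng):
        template = np.abs(rng.standard_normal(26)) + 0.5
        chunks = [np.tile(template, (3, 9, 1)) for _ in range(10)]
        cfg = SearchConfig(n_iterations=2, M=1)
        space, _ = search_vowel(chunks, cfg, "i")
        cos = abs(space.basis[0] @ template / np.linalg.norm(template))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_too_few_chunks_names_vowel(self, rng):
        with pytest.raises(ValueError, match="/?e"):
            search_vowel([np.ones((2, 9, 26))] * 3, SearchConfig(), "e")

    def test_all_vowels_searched_deterministically(self, rng):
        corpus = {}
        for v in "ieaou":
            _, chunks = self._template_corpus(rng)
            corpus[v] = chunks
        s1, _ = iterative_search(corpus)
        s2, _ = iterative_search(corpus)
        for v in corpus:
            np.testing.assert_array_equal(s1[v].basis, s2[v].basis)

    def test_unknown_vowel_rejected(self, rng):
        _, chunks = self._template_corpus(rng)
        with pytest.raises(ValueError, match="unknown"):
            iterative_search({"x": chunks})
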