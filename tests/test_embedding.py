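"""SVD factorization, reconstruction metrics and the affine refinement."""

import numpy as np
import pytest

from aagalaxy import (
    MatrixEmbedder,
    center_matrix,
    center_vectors,
    decompose,
    fit_shift_translation,
    frobenius_norm,
    gram,
    load_matrix,
    quality_index,
    random_gram,
    shift_matrix,
    superpose,
    upper_tri_correlation,
)
from aagalaxy.galaxy import Galaxy
from aagalaxy.matrices import BLOSUM_INDICES, SubstitutionMatrix


class TestDecompose:
    def test_gram_round_trip_recovers_rank_and_matrix(self):
        sg = random_gram(n=20, d=5, seed=1)
        E = decompose(sg.gram)
        assert E.dimensionality == 5
        assert not any(r == "negative" for _, _, r in E.dropped_components)
        np.testing.assert_allclose(gram(E).scores, sg.gram, atol=1e-9)
        assert quality_index(sg.gram, gram(E).scores) == pytest.approx(
            100.0, abs=1e-6
        )

    def test_identity_matrix_is_an_orthonormal_frame(self):
        E = decompose(np.eye(20))
        assert E.dimensionality == 20
        np.testing.assert_allclose(E.singular_values, np.ones(20))
        np.testing.assert_allclose(gram(E).scores, np.eye(20), atol=1e-12)

    def test_negative_eigencomponents_are_dropped(self, blosum62):
        E = decompose(blosum62)
        reasons = {r for _, _, r in E.dropped_components}
        assert "negative" in reasons
        # dropped mass is what the raw quality index loses
        q = quality_index(blosum62, gram(E))
        w_all = E.all_singular_values()
        expected = 100.0 * (
            1.0 - sum(w**2 for _, w, r in E.dropped_components) / (w_all @ w_all)
        )
        assert q == pytest.approx(expected, abs=1e-9)

    def test_coordinate_norms_match_singular_values(self, embedder62):
        E = embedder62.embedding_
        np.testing.assert_allclose(
            (E.vectors**2).sum(axis=0), E.singular_values, rtol=1e-9
        )

    def test_frobenius_identity_all_components(self, blosum62):
        E = decompose(blosum62)
        w = E.all_singular_values()
        assert w @ w == pytest.approx(frobenius_norm(blosum62) ** 2, rel=1e-9)

    def test_raw_reconstruction_overestimates_on_average(self, blosum62):
        E = decompose(blosum62)
        assert (gram(E).scores - blosum62.scores).mean() > 0

    def test_asymmetric_input_rejected(self):
        bad = np.eye(20)
        bad[0, 1] = 5.0
        with pytest.raises(ValueError, match="symmetric"):
            decompose(bad)


class TestQualityMetrics:
    def test_exact_reconstruction_scores_100(self, blosum62):
        assert quality_index(blosum62, blosum62) == 100.0

    def test_correlation_is_affine_invariant(self, blosum62):
        shifted = SubstitutionMatrix(scores=2.0 * blosum62.scores + 7.0)
        assert upper_tri_correlation(blosum62, shifted) == pytest.approx(1.0)

    def test_correlation_rejects_constant_input(self, blosum62):
        flat = SubstitutionMatrix(scores=np.zeros((20, 20)))
        with pytest.raises(ValueError, match="variance"):
            upper_tri_correlation(blosum62, flat)

    def test_raw_quality_degrades_along_blosum_series(self):
        qualities = []
        for idx in BLOSUM_INDICES:
            S = load_matrix(f"BLOSUM{idx}")
            qualities.append(quality_index(S, gram(decompose(S))))
        assert all(b < a for a, b in zip(qualities, qualities[1:]))


class TestShiftTranslationFit:
    def test_recovers_known_shift_of_a_gram_matrix(self):
        sg = random_gram(n=20, d=4, shift=2.5, seed=2)
        E = decompose(sg.gram - sg.applied_shift)  # centered-vector route
        fit = fit_shift_translation(sg.gram, E)
        assert fit.shift == pytest.approx(2.5, abs=1e-6)
        np.testing.assert_allclose(fit.translation, 0.0, atol=1e-6)
        assert fit.quality == pytest.approx(100.0, abs=1e-6)

    def test_never_worse_than_raw_reconstruction(self):
        for name in ("BLOSUM62", "PAM10", "PAM250", "BLOSUM100"):
            S = load_matrix(name)
            E = decompose(S)
            raw_q = quality_index(S, gram(E))
            assert fit_shift_translation(S, E).quality >= raw_q - 1e-9

    def test_shift_only_fit_is_close_to_full_fit(self, blosum62):
        E = decompose(center_matrix(blosum62))
        full = fit_shift_translation(blosum62, E)
        # force T = 0: optimum shift is then the mean discrepancy
        resid = blosum62.scores - gram(E).scores
        shift_only = quality_index(
            blosum62, gram(E).scores + resid.mean()
        )
        assert full.quality - shift_only < 3.0
        assert full.quality >= shift_only - 1e-9


class TestGalaxyExtraction:
    def test_centered_vectors_have_zero_mean(self, embedder62):
        G, centroid = center_vectors(embedder62.embedding_)
        np.testing.assert_allclose(G.points.mean(axis=0), 0.0, atol=1e-12)
        assert centroid.shape == (embedder62.embedding_.dimensionality,)

    def test_galaxy_is_shift_invariant(self):
        sg = random_gram(n=20, d=6, seed=3)
        A, _ = center_vectors(decompose(sg.gram))
        B, _ = center_vectors(decompose(sg.gram + 4.0))
        res = superpose(A, B, allow_reflection=True)
        assert res.rmsd < 1e-6

    def test_centered_matrix_and_centered_vectors_agree(self, blosum62):
        A, _ = center_vectors(decompose(blosum62))
        B, _ = center_vectors(decompose(center_matrix(blosum62)))
        # same galaxy up to a rigid motion? Not exactly: the raw embedding
        # drops different negative components.  But for an exact Gram input
        # the two routes must coincide.
        sg = random_gram(n=20, d=5, shift=1.0, seed=4)
        A2, _ = center_vectors(decompose(sg.gram))
        B2, _ = center_vectors(
            decompose(sg.gram - sg.gram.mean())
        )
        assert superpose(A2, B2, allow_reflection=True).rmsd < 1e-6


class TestEstimator:
    def test_sklearn_contract(self, blosum62):
        from sklearn.base import clone

        est = MatrixEmbedder(center=True, refine=True)
        assert clone(est).get_params() == est.get_params()
        est.fit(blosum62)
        assert est.vectors_.shape[0] == 20
        assert est.shift_fit_ is not None
        assert est.transform().shape == est.vectors_.shape

    def test_refine_reports_high_quality(self, blosum62):
        est = MatrixEmbedder(center=True, refine=True).fit(blosum62)
        assert est.shift_fit_.quality > 99.0
        assert est.shift_fit_.correlation > 0.99
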