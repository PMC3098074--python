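"""Distance conversions, triangle audits and distance-based embeddings."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from aagalaxy import (
    DistanceMatrix,
    Galaxy,
    anticorrelation_fit,
    load_matrix,
    shift_matrix,
    similarity_to_distance,
    stress_fit,
    superpose,
    torgerson_embed,
    triangle_violations,
    vector_metric,
)
from aagalaxy.synthetic import random_gram


@pytest.fixture(scope="module")
def gram5():
    return random_gram(n=20, d=5, seed=11)


class TestConversion:
    def test_diagonal_is_zero_for_both_forms(self, blosum62):
        for form in ("LINEAR", "SQRT"):
            D = similarity_to_distance(blosum62, form)
            assert np.all(np.diag(D.values) == 0)

    def test_sqrt_form_recovers_euclidean_distances(self, gram5):
        S = gram5.to_substitution_matrix()
        D = similarity_to_distance(S, "SQRT")
        expected = squareform(pdist(gram5.true_points))
        np.testing.assert_allclose(D.values, expected, atol=1e-9)

    def test_negative_argument_raises_with_pair_names(self):
        from aagalaxy.matrices import SubstitutionMatrix

        s = np.eye(20)
        s[0, 1] = s[1, 0] = 5.0  # similarity exceeding both self-scores
        with pytest.raises(ValueError, match="pairs: AC"):
            similarity_to_distance(SubstitutionMatrix(scores=s), "LINEAR")

    def test_unknown_form_rejected(self, blosum62):
        with pytest.raises(ValueError):
            similarity_to_distance(blosum62, "CUBIC")


class TestTriangleAudit:
    def test_euclidean_distances_have_no_violations(self, gram5):
        D = DistanceMatrix(values=squareform(pdist(gram5.true_points)))
        audit = triangle_violations(D)
        assert audit.count == 0 and audit.inequality_count == 0

    def test_constructed_violation_counted_once(self):
        # residues 0,1,2: d01 = d12 = 1 but d02 = 5
        base = np.ones((20, 20)) * 2.0
        np.fill_diagonal(base, 0.0)
        base[0, 1] = base[1, 0] = 1.0
        base[1, 2] = base[2, 1] = 1.0
        base[0, 2] = base[2, 0] = 5.0
        audit = triangle_violations(DistanceMatrix(values=base))
        # triplet (0,1,2) violates; so does every (0,2,x) with 2-long legs
        assert audit.count == 1 + 17
        count, fraction = audit[:2]  # tuple unpacking stays supported
        assert count == audit.count
        assert fraction == pytest.approx(100.0 * audit.count / 1140)

    def test_vector_metric_is_metric(self, galaxy62):
        audit = triangle_violations(vector_metric(galaxy62))
        assert audit.count == 0

    def test_coincident_points_only_zero_off_diagonal(self):
        pts = np.zeros((20, 2))
        pts[2:] = np.random.default_rng(0).standard_normal((18, 2))
        D = vector_metric(Galaxy(points=pts))
        off = D.values[np.triu_indices(20, 1)]
        assert (off == 0).sum() == 1  # only the coincident pair


class TestTorgerson:
    def test_round_trip_from_known_points(self, gram5):
        S = gram5.to_substitution_matrix()
        D = similarity_to_distance(S, "SQRT")
        X = torgerson_embed(D, dims=5)
        res = superpose(
            Galaxy(points=X), Galaxy(points=gram5.true_points),
            allow_reflection=True,
        )
        assert res.rmsd < 1e-6

    def test_agrees_with_independent_pcoa(self, gram5):
        from skbio.stats.ordination import pcoa

        D = similarity_to_distance(gram5.to_substitution_matrix(), "SQRT")
        ours = torgerson_embed(D, dims=5)
        theirs = pcoa(D.values.copy(), number_of_dimensions=5).samples.to_numpy()
        res = superpose(Galaxy(points=ours), Galaxy(points=theirs),
                        allow_reflection=True)
        assert res.rmsd < 1e-6

    def test_equidistant_points_form_regular_simplex(self):
        vals = np.ones((20, 20)) - np.eye(20)
        X = torgerson_embed(DistanceMatrix(values=vals), dims=19)
        d = pdist(X)
        np.testing.assert_allclose(d, 1.0, atol=1e-9)

    def test_truncation_warning_when_dims_unavailable(self, blosum62):
        D = similarity_to_distance(blosum62, "SQRT")
        with pytest.warns(UserWarning, match="truncat"):
            X = torgerson_embed(D, dims=20)
        assert X.shape[1] < 20


class TestIterativeFits:
    def test_stress_near_zero_at_true_dimension(self, gram5):
        D = similarity_to_distance(gram5.to_substitution_matrix(), "SQRT")
        X = stress_fit(D, dims=5, seed=1, restarts=8)
        assert np.abs(pdist(X) - pdist(gram5.true_points)).max() < 1e-2

    def test_dimensional_obstruction_leaves_residual_stress(self):
        sg = random_gram(n=20, d=2, seed=5)
        D = similarity_to_distance(sg.to_substitution_matrix(), "SQRT")
        X = stress_fit(D, dims=1, seed=1, restarts=4)
        assert np.abs(pdist(X) - pdist(sg.true_points)).max() > 0.1

    def test_stress_fit_deterministic(self, gram5):
        D = similarity_to_distance(gram5.to_substitution_matrix(), "SQRT")
        a = stress_fit(D, dims=3, seed=9, restarts=3)
        b = stress_fit(D, dims=3, seed=9, restarts=3)
        np.testing.assert_array_equal(a, b)

    def test_anticorrelation_reaches_minus_one_for_linear_similarity(self):
        # similarity that decreases linearly with a 1-D inter-point
        # distance: a collinear configuration realizes correlation -1
        t = np.linspace(-2, 2, 20)
        S = -np.abs(t[:, None] - t[None, :])
        from aagalaxy.matrices import SubstitutionMatrix

        X = anticorrelation_fit(SubstitutionMatrix(scores=S), dims=1,
                                seed=0, restarts=5)
        iu = np.triu_indices(20, 1)
        corr = np.corrcoef(S[iu], pdist(X))[0, 1]
        assert corr < -0.999

    def test_anticorrelation_deterministic_and_beats_torgerson(self, blosum62):
        X1 = anticorrelation_fit(blosum62, dims=3, seed=2, restarts=2)
        X2 = anticorrelation_fit(blosum62, dims=3, seed=2, restarts=2)
        np.testing.assert_array_equal(X1, X2)
        iu = np.triu_indices(20, 1)
        corr_anti = np.corrcoef(blosum62.scores[iu], pdist(X1))[0, 1]
        Xt = torgerson_embed(similarity_to_distance(blosum62, "LINEAR"), 3)
        corr_torg = np.corrcoef(blosum62.scores[iu], pdist(Xt))[0, 1]
        assert corr_anti < corr_torg < 0


class TestVectorMetricNeighbors:
    def test_aliphatics_are_mutual_near_neighbors(self, galaxy62):
        D = vector_metric(galaxy62)
        for a in "LIVM":
            for b in "LIVM":
                if a == b:
                    continue
                assert D[a, b] < D[a, "D"]
                assert D[a, b] < D[a, "E"]
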