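import numpy as np
import pytest
import scipy.linalg

from fcgrad.connectome import compute_fc, cosine_affinity, threshold_rows
from fcgrad.gradients import (
    GradientSet,
    ReferenceGradient,
    build_reference,
    diffusion_embed,
    explained_variance_table,
    procrustes_align,
)


def dense_diffusion_oracle(w, n_components, alpha):
    """Literal diffusion-map construction via non-symmetric eigendecomposition.

    Independent of the implementation's symmetric-conjugate path: forms the
    Markov matrix explicitly and calls scipy.linalg.eig on it.
    """
    w = np.asarray(w, dtype=float)
    if w.min() < 0:
        w = w - w.min()
    d = w.sum(axis=1)
    w1 = w / np.outer(d**alpha, d**alpha)
    d1 = w1.sum(axis=1)
    markov = w1 / d1[:, None]
    evals, evecs = scipy.linalg.eig(markov)
    order = np.argsort(-evals.real)[: n_components + 1]
    lam = evals.real[order]
    psi = evecs.real[:, order]
    # normalization convention: unit norm in the sqrt(d1) inner product, then
    # division by the trivial constant eigenvector
    psi = psi / np.linalg.norm(psi * np.sqrt(d1)[:, None], axis=0, keepdims=True)
    psi = psi / psi[:, [0]]
    scores = psi[:, 1:] * (lam[1:] / (1 - lam[1:]))
    for c in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, c]))
        if scores[i, c] < 0:
            scores[:, c] = -scores[:, c]
    return scores, lam[1:]


def _random_affinity(rng, p):
    x = rng.standard_normal((p, p))
    a = cosine_affinity(x)
    return np.abs(a)  # nonnegative, symmetric, unit diagonal


class TestDiffusionEmbed:
    def test_two_block_affinity_separates_blocks_on_gradient_one(self):
        eps = 0.01
        w = np.full((6, 6), eps)
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        g = diffusion_embed(w, n_components=2)
        signs = np.sign(g.scores[:, 0])
        assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1
        assert signs[0] != signs[3]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_nonsymmetric_eig_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(20, 51)
        w = _random_affinity(rng, p)
        g = diffusion_embed(w, n_components=5)
        oracle_scores, oracle_lam = dense_diffusion_oracle(w, 5, 0.5)
        np.testing.assert_allclose(g.eigenvalues, oracle_lam, atol=1e-8)
        np.testing.assert_allclose(g.scores, oracle_scores, atol=1e-6)

    def test_explained_variance_is_eigenvalue_ratio(self):
        rng = np.random.default_rng(10)
        g = diffusion_embed(_random_affinity(rng, 30), n_components=4)
        np.testing.assert_allclose(
            g.explained_variance, g.eigenvalues / g.eigenvalues.sum(), atol=1e-12
        )
        assert abs(g.explained_variance.sum() - 1) < 1e-10
        assert np.all(np.diff(g.eigenvalues) <= 1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        w = _random_affinity(rng, 25)
        a = diffusion_embed(w, 3)
        b = diffusion_embed(w, 3)
        assert np.array_equal(a.scores, b.scores)

    def test_disconnected_graph_rejected(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_embed(w, 2)

    def test_negative_affinity_shift_recorded(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((20, 20))
        a = cosine_affinity(x)  # has negatives
        g = diffusion_embed(a, 3)
        assert g.provenance["affinity_shift"] == pytest.approx(-a.min())

    def test_asymmetric_input_rejected(self):
        w = np.triu(np.ones((5, 5)))
        with pytest.raises(ValueError, match="symmetric"):
            diffusion_embed(w, 2)


class TestProcrustesAlign:
    @pytest.fixture()
    def reference(self):
        rng = np.random.default_rng(13)
        g = diffusion_embed(_random_affinity(rng, 40), n_components=4)
        return ReferenceGradient(gradients=g)

    def _as_subject(self, scores, template):
        return GradientSet(
            scores=scores,
            eigenvalues=template.eigenvalues,
            explained_variance=template.explained_variance,
        )

    def test_swap_and_sign_flip_recovered_exactly(self, reference):
        ref = reference.scores
        perturbed = ref[:, [1, 0, 2, 3]].copy()
        perturbed[:, 0] = -perturbed[:, 0]
        aligned = procrustes_align(
            self._as_subject(perturbed, reference.gradients), reference
        )
        np.testing.assert_allclose(aligned.scores, ref, atol=1e-10)

    def test_identity_when_already_equal(self, reference):
        aligned = procrustes_align(
            self._as_subject(reference.scores.copy(), reference.gradients), reference
        )
        np.testing.assert_allclose(aligned.scores, reference.scores, atol=1e-10)

    def test_plane_rotation_recovered(self, reference):
        theta = np.deg2rad(37)
        rot = np.eye(4)
        rot[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        aligned = procrustes_align(
            self._as_subject(reference.scores @ rot, reference.gradients), reference
        )
        for c in range(2):
            r = np.corrcoef(aligned.scores[:, c], reference.scores[:, c])[0, 1]
            assert abs(r - 1.0) < 1e-10

    def test_frobenius_norm_preserved(self, reference):
        rng = np.random.default_rng(14)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        subject = self._as_subject(reference.scores @ q, reference.gradients)
        aligned = procrustes_align(subject, reference)
        assert np.isclose(
            np.linalg.norm(aligned.scores), np.linalg.norm(subject.scores)
        )

    def test_double_alignment_rejected(self, reference):
        s = self._as_subject(reference.scores.copy(), reference.gradients)
        aligned = procrustes_align(s, reference)
        with pytest.raises(ValueError, match="already aligned"):
            procrustes_align(aligned, reference)

    def test_eigenvalues_untouched(self, reference):
        rng = np.random.default_rng(15)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        s = self._as_subject(reference.scores @ q, reference.gradients)
        aligned = procrustes_align(s, reference)
        np.testing.assert_array_equal(aligned.eigenvalues, s.eigenvalues)


class TestBuildReference:
    def test_single_subject_reference_equals_own_embedding(self):
        rng = np.random.default_rng(16)
        fc = compute_fc(rng.standard_normal((100, 30)))
        ref = build_reference([fc], density=0.2, n_components=3)
        own = diffusion_embed(cosine_affinity(threshold_rows(fc, 0.2)), 3)
        np.testing.assert_allclose(ref.scores, own.scores, atol=1e-12)

    def test_identical_matrices_reduce_to_single(self):
        rng = np.random.default_rng(17)
        fc = compute_fc(rng.standard_normal((100, 30)))
        ref1 = build_reference([fc], density=0.2, n_components=3)
        ref3 = build_reference([fc, fc.copy(), fc.copy()], density=0.2, n_components=3)
        np.testing.assert_allclose(ref1.scores, ref3.scores, atol=1e-12)

    def test_parcel_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_reference([np.zeros((5, 5)), np.zeros((6, 6))])


class TestExplainedVarianceTable:
    def test_table_shape_and_bounds(self):
        rng = np.random.default_rng(18)
        sets = {
            f"s{i}": diffusion_embed(_random_affinity(rng, 25), 5) for i in range(4)
        }
        table = explained_variance_table(sets)
        assert list(table.columns) == ["subject_id", "ev_g1", "ev_g2"]
        assert ((table[["ev_g1", "ev_g2"]] >= 0) & (table[["ev_g1", "ev_g2"]] <= 1)).all().all()

    def test_identical_subjects_have_zero_across_subject_variance(self):
        rng = np.random.default_rng(19)
        w = _random_affinity(rng, 25)
        sets = {f"s{i}": diffusion_embed(w, 5) for i in range(3)}
        table = explained_variance_table(sets)
        assert table["ev_g1"].std() < 1e-12

    def test_mixed_component_counts_rejected(self):
        rng = np.random.default_rng(20)
        sets = {
            "a": diffusion_embed(_random_affinity(rng, 25), 5),
            "b": diffusion_embed(_random_affinity(rng, 25), 4),
        }
        with pytest.raises(ValueError, match="mixed"):
            explained_variance_table(sets)


def test_cohort_recovery_of_planted_axes(null_cohort20):
    """Aligned gradients 1-2 recover the planted latent axes on a null cohort."""
    b = null_cohort20
    fcs = {sid: compute_fc(ts) for sid, ts in b.timeseries.items()}
    hc = b.cohort.loc[b.cohort.group == "HC", "subject_id"].tolist()
    ref = build_reference([fcs[s] for s in hc], 0.10, 10, 0.5)
    r1, r2 = [], []
    for sid in b.cohort.subject_id:
        g = diffusion_embed(cosine_affinity(threshold_rows(fcs[sid], 0.10)), 10, 0.5)
        aligned = procrustes_align(g, ref)
        lat = b.subject_latent[sid]
        r1.append(abs(np.corrcoef(aligned.scores[:, 0], lat[:, 0])[0, 1]))
        r2.append(abs(np.corrcoef(aligned.scores[:, 1], lat[:, 1])[0, 1]))
    assert np.mean(r1) > 0.95
    assert np.mean(r2) > 0.95
    assert min(r1) > 0.90 and min(r2) > 0.90
    # the reference's leading gradient tracks the dominant planted axis
    ref_r = abs(np.corrcoef(ref.scores[:, 0], b.ground_truth.base_latent[:, 0])[0, 1])
    assert ref_r > 0.9
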