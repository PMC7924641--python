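"""Concatenation, DCT/PCA reduction and the sequential forward search."""

import numpy as np
import pytest

from mbhis import (
    ClassifierSpec,
    ConfigurationError,
    CVConfig,
    DataError,
    FeatureMatrix,
    apply_reduction,
    concat_fused,
    dct2_rows,
    fit_pca,
    reduce_dct,
    sequential_forward_search,
)
from mbhis.fusion import choose_smallest_argmax, idct2_rows


def _fm(values, provenance="stf", backbone=None, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return FeatureMatrix(values, ids, provenance, backbone)


class TestConcat:
    def test_contract_width_2774(self, rng):
        sets = [
            _fm(rng.normal(size=(10, 1074)), backbone="resnet50"),
            _fm(rng.normal(size=(10, 1010)), backbone="densenet201"),
            _fm(rng.normal(size=(10, 690)), backbone="mobilenet"),
        ]
        fused = concat_fused(sets)
        assert fused.values.shape == (10, 2774)
        assert fused.provenance == "fused"

    def test_backbone_order_is_canonical(self, rng):
        a = _fm(rng.normal(size=(4, 3)), backbone="resnet50")
        b = _fm(rng.normal(size=(4, 2)), backbone="densenet201")
        c = _fm(rng.normal(size=(4, 5)), backbone="mobilenet")
        fused = concat_fused([c, a, b])
        np.testing.assert_array_equal(
            fused.values, np.concatenate([a.values, b.values, c.values], axis=1)
        )

    def test_single_set_is_identity(self, rng):
        a = _fm(rng.normal(size=(4, 3)))
        out = concat_fused([a])
        np.testing.assert_array_equal(out.values, a.values)

    def test_row_order_mismatch_is_an_error(self, rng):
        a = _fm(rng.normal(size=(4, 3)), ids=list("abcd"))
        b = _fm(rng.normal(size=(4, 3)), ids=list("abdc"))
        with pytest.raises(DataError):
            concat_fused([a, b])


class TestDct:
    def test_against_naive_cosine_sum(self, rng):
        x = rng.normal(size=(3, 16))
        n = 16
        naive = np.zeros_like(x)
        for r in range(3):
            for k in range(n):
                s = sum(x[r, m] * np.cos(np.pi * k * (2 * m + 1) / (2 * n)) for m in range(n))
                scale = np.sqrt(1 / n) if k == 0 else np.sqrt(2 / n)
                naive[r, k] = scale * s
        np.testing.assert_allclose(dct2_rows(x), naive, atol=1e-10)

    def test_constant_row_is_dc_only(self):
        c, n = 3.7, 50
        out = dct2_rows(np.full((1, n), c))
        assert abs(out[0, 0] - c * np.sqrt(n)) < 1e-10
        np.testing.assert_allclose(out[0, 1:], 0, atol=1e-10)

    def test_orthonormal_round_trip_and_parseval(self, rng):
        x = rng.normal(size=(5, 64))
        coeffs = dct2_rows(x)
        np.testing.assert_allclose(idct2_rows(coeffs), x, atol=1e-10)
        np.testing.assert_allclose(
            (coeffs**2).sum(axis=1), (x**2).sum(axis=1), rtol=1e-9
        )

    def test_truncation_and_full_width_round_trip(self, rng):
        fm = _fm(rng.normal(size=(6, 40)), provenance="fused")
        reduced, model = reduce_dct(fm, 7)
        assert reduced.values.shape == (6, 7)
        assert model.retained == 7 and model.fit_sample_ids == []
        full, _ = reduce_dct(fm, 40)
        np.testing.assert_allclose(idct2_rows(full.values), fm.values, atol=1e-10)
        with pytest.raises(ConfigurationError):
            reduce_dct(fm, 41)


class TestPca:
    def test_explained_variance_matches_brute_force_eigenvalues(self):
        x = np.array([[2.0, 0.0, 1.0], [0.0, 1.0, 3.0], [4.0, 2.0, 0.0], [1.0, 5.0, 2.0]])
        fm = _fm(x, provenance="fused")
        model = fit_pca(fm, 3)
        cov = np.cov(x, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(model.explained_variance, eig[:3], atol=1e-8)
        # orthonormal components, non-increasing spectrum
        np.testing.assert_allclose(model.components @ model.components.T, np.eye(3), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_degenerate_line_gives_axis_component(self):
        t = np.linspace(-1, 1, 8)
        x = np.zeros((8, 4))
        x[:, 0] = t
        model = fit_pca(_fm(x, provenance="fused"), 1)
        comp = model.components[0]
        assert abs(abs(comp[0]) - 1) < 1e-8
        np.testing.assert_allclose(comp[1:], 0, atol=1e-8)

    def test_apply_reduction_is_consistent_and_affine(self, rng):
        x = rng.normal(size=(10, 6))
        fm = _fm(x, provenance="fused")
        model = fit_pca(fm, 3)
        scores = apply_reduction(model, fm)
        expected = (x - model.mean) @ model.components.T
        np.testing.assert_allclose(scores.values, expected, atol=1e-10)
        shifted = apply_reduction(model, _fm(x + 1.5, provenance="fused"))
        np.testing.assert_allclose(
            shifted.values - scores.values,
            np.tile(1.5 * model.components.sum(axis=1), (10, 1)),
            atol=1e-10,
        )

    def test_dimension_mismatch_is_an_error(self, rng):
        model = fit_pca(_fm(rng.normal(size=(6, 5)), provenance="fused"), 2)
        with pytest.raises(DataError):
            apply_reduction(model, _fm(rng.normal(size=(3, 4)), provenance="fused"))


class TestSearch:
    def test_smallest_argmax_tie_break(self):
        assert choose_smallest_argmax([100, 200, 300], [0.90, 0.95, 0.95]) == 200
        assert choose_smallest_argmax([50], [0.4]) == 50

    def _separable(self, rng, n_per=12, d=30):
        centers = rng.normal(scale=4.0, size=(3, d))
        x = np.concatenate([c + rng.normal(size=(n_per, d)) for c in centers])
        y = np.repeat(np.arange(3), n_per)
        return _fm(x, provenance="fused"), y

    def test_profile_and_grid_order_invariance(self, rng):
        fm, y = self._separable(rng)
        cfg = CVConfig(k=3, repeats=2, base_seed=0)
        spec = ClassifierSpec("lda")
        a = sequential_forward_search(fm, y, "pca", (2, 5, 8), cfg, spec)
        b = sequential_forward_search(fm, y, "pca", (8, 2, 5), cfg, spec)
        assert a.candidates == sorted(a.candidates) == b.candidates
        assert a.scores == b.scores and a.chosen == b.chosen
        # the chosen dimension scores at least as well as the smallest one
        assert a.scores[a.candidates.index(a.chosen)] >= a.scores[0]

    def test_infeasible_candidates_are_skipped(self, rng):
        fm, y = self._separable(rng, n_per=5)
        cfg = CVConfig(k=3, repeats=1, base_seed=0)
        grid = sequential_forward_search(fm, y, "pca", (2, 500), cfg, ClassifierSpec("lda"))
        assert grid.candidates == [2]
        with pytest.raises(ConfigurationError):
            sequential_forward_search(fm, y, "pca", (500,), cfg, ClassifierSpec("lda"))
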