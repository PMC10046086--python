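"""NNLS decomposition and strict backward-elimination refitting."""

import numpy as np
import pandas as pd
import pytest

from malspectra.signatures import (
    SignatureMatrix,
    SignatureRefitModel,
    cosine_similarity,
    fit_signatures_strict,
    nnls_fit,
)
from malspectra.spectra import CHANNELS_96

from conftest import make_signature_matrix


def orthogonal_matrix(k: int = 3) -> SignatureMatrix:
    """Signatures with disjoint channel support (orthogonal columns)."""
    cols = {}
    block = 96 // k
    for i in range(k):
        v = np.zeros(96)
        v[i * block : (i + 1) * block] = 1.0 / block
        cols[f"S{i + 1}"] = v
    return SignatureMatrix(pd.DataFrame(cols, index=list(CHANNELS_96)))


class TestNNLS:
    def test_exact_single_signature_profile(self):
        mat = orthogonal_matrix(2)
        profile = 100 * mat.data["S1"].values
        fit = nnls_fit(profile, mat)
        assert fit.contributions["S1"] == pytest.approx(100.0, abs=1e-9)
        assert fit.contributions["S2"] == pytest.approx(0.0, abs=1e-9)

    def test_exact_two_signature_mixture(self, signature_matrix):
        truth = 60 * signature_matrix.data["SBS1"].values + 40 * signature_matrix.data[
            "SBS2"
        ].values
        fit = nnls_fit(truth, signature_matrix)
        assert fit.contributions["SBS1"] == pytest.approx(60.0, abs=1e-6)
        assert fit.contributions["SBS2"] == pytest.approx(40.0, abs=1e-6)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_single_signature_matches_clipped_projection(self):
        """1-D NNLS equals the closed-form least squares coefficient clipped
        at zero."""
        rng = np.random.default_rng(1)
        col = rng.dirichlet(np.ones(96))
        mat = SignatureMatrix(pd.DataFrame({"S1": col}, index=list(CHANNELS_96)))
        for sign in (+1, -1):
            profile = np.clip(sign * col + 0.05 * rng.random(96), 0, None)
            fit = nnls_fit(profile, mat)
            expected = max(0.0, float(profile @ col) / float(col @ col))
            assert fit.contributions["S1"] == pytest.approx(expected, rel=1e-9)
            resid = np.linalg.norm(profile - expected * col)
            assert fit.residual_norm == pytest.approx(resid, rel=1e-9)

    def test_zero_profile_rejected(self, signature_matrix):
        with pytest.raises(ValueError):
            nnls_fit(np.zeros(96), signature_matrix)

    def test_kkt_optimality_of_solution(self, signature_matrix):
        """Active-set optimality: gradient >= 0 everywhere, 0 on the support."""
        rng = np.random.default_rng(6)
        profile = rng.poisson(5, 96).astype(float)
        fit = nnls_fit(profile, signature_matrix)
        M = signature_matrix.values
        c = fit.contributions.values
        grad = M.T @ (M @ c - profile)
        assert np.all(grad >= -1e-8)
        assert np.allclose(grad[c > 1e-12], 0, atol=1e-8)


def exhaustive_strict_terminals(profile, matrix, max_delta):
    """Oracle: explore every elimination order under the acceptance rule
    (similarity drop < max_delta vs the previous accepted fit); return the
    set of terminal retained-signature sets."""
    terminals = set()

    def sim_of(names):
        return nnls_fit(profile, matrix.subset(sorted(names))).similarity

    def dfs(state, accepted_sim):
        moved = False
        if len(state) > 1:
            for name in sorted(state):
                new = frozenset(state - {name})
                s = sim_of(new)
                if accepted_sim - s < max_delta + 1e-12:
                    moved = True
                    dfs(new, s)
        if not moved:
            terminals.add(frozenset(state))

    full = frozenset(matrix.names)
    dfs(full, sim_of(full))
    return terminals


class TestStrictRefit:
    def test_pure_profile_retains_single_signature(self, signature_matrix):
        profile = 120 * signature_matrix.data["SBS3"].values
        refit = fit_signatures_strict(profile, signature_matrix, 0.004)
        assert refit.retained == ["SBS3"]
        assert len(refit.dropped) == 3
        assert refit.reconstruction_similarity == pytest.approx(1.0)

    def test_zero_delta_only_removes_free_signatures(self):
        mat = orthogonal_matrix(3)
        profile = 50 * mat.data["S1"].values + 30 * mat.data["S2"].values
        refit = fit_signatures_strict(profile, mat, max_delta=0.0)
        # S3 is unused (removal leaves similarity unchanged); S1/S2 carry
        # signal and their removal must be rejected
        assert set(refit.retained) == {"S1", "S2"}
        assert refit.dropped == ["S3"]

    def test_small_contaminant_dropped_large_kept(self):
        # S3's weight is tiny (similarity cost of removal ~1e-5 < 0.004);
        # S2 carries enough mass that dropping it would cost ~0.012 > 0.004
        mat = orthogonal_matrix(3)
        truth = (
            95 * mat.data["S1"].values
            + 15 * mat.data["S2"].values
            + 0.5 * mat.data["S3"].values
        )
        refit = fit_signatures_strict(truth, mat, 0.004)
        assert refit.dropped == ["S3"]
        assert set(refit.retained) == {"S1", "S2"}
        assert refit.contributions["S1"] == pytest.approx(95, rel=0.05)
        assert refit.contributions["S2"] == pytest.approx(15, rel=0.05)

    @pytest.mark.parametrize("k,seed", [(4, 0), (5, 3), (6, 8)])
    def test_matches_exhaustive_elimination_search(self, k, seed):
        """For small catalogues the greedy loop lands on a terminal set of
        the exhaustive search over all elimination orders, of minimal size."""
        rng = np.random.default_rng(seed)
        mat = make_signature_matrix(k=k, seed=seed, concentration=0.15)
        weights = np.zeros(k)
        weights[: k // 2] = rng.uniform(20, 100, k // 2)
        profile = mat.values @ weights + rng.poisson(0.3, 96)
        refit = fit_signatures_strict(profile, mat, 0.004)
        terminals = exhaustive_strict_terminals(profile, mat, 0.004)
        retained = frozenset(refit.retained)
        assert retained in terminals
        assert len(retained) == min(len(t) for t in terminals)

    def test_similarity_accounting_identity(self, signature_matrix):
        """Final similarity >= all-signature similarity minus
        (#removals x max_delta)."""
        rng = np.random.default_rng(11)
        profile = rng.poisson(4, 96).astype(float)
        max_delta = 0.01
        full = nnls_fit(profile, signature_matrix)
        refit = fit_signatures_strict(profile, signature_matrix, max_delta)
        floor = full.similarity - len(refit.dropped) * max_delta
        assert refit.reconstruction_similarity >= floor - 1e-9

    def test_deterministic_tie_break_by_name(self):
        mat = orthogonal_matrix(3)
        profile = 40 * mat.data["S1"].values  # S2 and S3 tie at zero
        refit = fit_signatures_strict(profile, mat, 0.004)
        assert refit.dropped == ["S2", "S3"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            SignatureMatrix(pd.DataFrame(index=list(CHANNELS_96)))


class TestMatrixIO:
    def test_cosmic_layout_roundtrip(self, tmp_path, signature_matrix):
        path = tmp_path / "sbs.tsv"
        signature_matrix.to_tsv(path)
        loaded = SignatureMatrix.from_tsv(path)
        assert loaded.names == signature_matrix.names
        np.testing.assert_allclose(loaded.values, signature_matrix.values)

    def test_rows_reindexed_to_canonical_order(self, tmp_path, signature_matrix):
        path = tmp_path / "shuffled.tsv"
        shuffled = signature_matrix.data.sample(frac=1, random_state=0)
        shuffled.rename_axis("Type").to_csv(path, sep="\t")
        loaded = SignatureMatrix.from_tsv(path)
        np.testing.assert_allclose(loaded.values, signature_matrix.values)

    def test_column_not_summing_to_one_rejected(self):
        bad = pd.DataFrame({"S1": np.full(96, 0.02)}, index=list(CHANNELS_96))
        with pytest.raises(ValueError, match="sum to 1"):
            SignatureMatrix(bad)


def test_cosine_similarity_zero_vector_guard():
    assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0
    assert cosine_similarity([1, 0], [1, 0]) == pytest.approx(1.0)
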