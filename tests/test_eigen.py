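import numpy as np
import pytest

import eigenphase as ep
from eigenphase import eigen

from conftest import small_matrix


def random_mat(seed, m, n):
    rng = np.random.default_rng(seed)
    return ep.OmicsMatrix(
        rng.normal(5.0, 1.0, (m, n)),
        [f"g{i}" for i in range(m)],
        [f"s{j}" for j in range(n)],
        np.arange(n, dtype=float),
        "rand",
    )


class TestStratify:
    def test_constant_columns_single_level_baseline(self):
        mu = np.array([2.0, 5.0, 1.0, 4.0])
        mat = ep.OmicsMatrix(
            np.tile(mu[:, None], (1, 5)), list("abcd"), [f"s{j}" for j in range(5)],
            np.arange(5.0), "t",
        )
        dec = ep.stratify(mat)
        assert dec.s == 1
        np.testing.assert_allclose(dec.V[:, 0], np.full(5, 1 / np.sqrt(5)), atol=1e-10)
        np.testing.assert_allclose(dec.lambdas[0] * dec.U[:, 0], np.sqrt(5) * mu, atol=1e-10)

    def test_matches_gram_matrix_eigen_oracle(self):
        mat = random_mat(21, 6, 4)
        dec = ep.stratify(mat)
        # independent route: eigen-decomposition of A^T A
        G = mat.values.T @ mat.values
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        np.testing.assert_allclose(dec.lambdas, np.sqrt(evals[order]), rtol=1e-8)
        for k in range(dec.s):
            v_oracle = evecs[:, order[k]]
            np.testing.assert_allclose(
                np.abs(dec.V[:, k]), np.abs(v_oracle), atol=1e-8
            )
            u_oracle = mat.values @ v_oracle / dec.lambdas[k]
            np.testing.assert_allclose(np.abs(dec.U[:, k]), np.abs(u_oracle), atol=1e-8)

    def test_planted_rank_two_recovery(self):
        rng = np.random.default_rng(3)
        u = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        v = np.linalg.qr(rng.standard_normal((5, 2)))[0]
        A = 7.0 * np.outer(u[:, 0], v[:, 0]) + 3.0 * np.outer(u[:, 1], v[:, 1])
        mat = ep.OmicsMatrix(A, [f"g{i}" for i in range(8)], [f"s{j}" for j in range(5)],
                             np.arange(5.0), "t")
        dec = ep.stratify(mat)
        assert dec.s == 2
        np.testing.assert_allclose(dec.lambdas, [7.0, 3.0], rtol=1e-8)
        for k in range(2):
            np.testing.assert_allclose(np.abs(dec.U[:, k]), np.abs(u[:, k]), atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_identities_on_random_matrices(self, seed):
        mat = random_mat(seed, 50, 20)
        dec = ep.stratify(mat)
        A = mat.values
        recon, resid = ep.reconstruct(dec, dec.level_indices)
        assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(A)
        Abar = ep.remove_baseline(dec)
        assert abs(np.sum(dec.lambdas[1:] ** 2) - np.linalg.norm(Abar) ** 2) <= (
            1e-8 * np.linalg.norm(Abar) ** 2
        )
        for k in range(dec.s):
            np.testing.assert_allclose(
                dec.lambdas[k] * dec.U[:, k], A @ dec.V[:, k], atol=1e-8 * dec.lambdas[0]
            )
        np.testing.assert_allclose(dec.U.T @ dec.U, np.eye(dec.s), atol=1e-10)
        np.testing.assert_allclose(dec.V.T @ dec.V, np.eye(dec.s), atol=1e-10)

    def test_orientation_deterministic(self):
        mat = random_mat(5, 12, 6)
        d1, d2 = ep.stratify(mat), ep.stratify(mat)
        np.testing.assert_array_equal(d1.U, d2.U)
        np.testing.assert_array_equal(d1.V, d2.V)

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError):
            ep.OmicsMatrix(
                np.array([[1.0, np.nan, 2.0], [1, 2, 3]]), ["a", "b"],
                ["x", "y", "z"], [0.0, 1.0, 2.0], "t",
            )


class TestBaseline:
    def test_constant_columns_perfect_baseline(self):
        mu = np.array([2.0, 5.0, 1.0])
        mat = ep.OmicsMatrix(np.tile(mu[:, None], (1, 4)), list("abc"),
                             list("wxyz"), np.arange(4.0), "t")
        diag = ep.baseline_diagnostics(ep.stratify(mat))
        assert diag["cv_abs_v0"] == 0.0
        assert diag["mu_max_rel_dev"] <= 1e-10
        assert diag["passed"]

    def test_mean_centered_matrix_fails_with_warning(self):
        mat = random_mat(4, 20, 6)
        centered = ep.OmicsMatrix(
            mat.values - mat.values.mean(axis=1, keepdims=True),
            mat.molecule_ids, mat.sample_ids, mat.sample_times, "t",
        )
        with pytest.warns(UserWarning, match="not a clean baseline"):
            diag = ep.baseline_diagnostics(ep.stratify(centered))
        assert not diag["passed"]

    def test_generator_output_passes(self, transcriptome_dec):
        assert ep.baseline_diagnostics(transcriptome_dec)["passed"]

    def test_remove_baseline_constant_matrix_zero(self):
        mat = ep.OmicsMatrix(np.full((3, 4), 2.5), list("abc"), list("wxyz"),
                             np.arange(4.0), "t")
        np.testing.assert_allclose(ep.remove_baseline(ep.stratify(mat)), 0.0, atol=1e-10)

    def test_abar_orthogonal_to_v0(self):
        dec = ep.stratify(random_mat(6, 10, 5))
        Abar = ep.remove_baseline(dec)
        np.testing.assert_allclose(Abar @ dec.V[:, 0], 0.0, atol=1e-8 * dec.lambdas[0])


class TestContributions:
    def test_single_level_zero_entropy(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(6)
        v = rng.standard_normal(4)
        base = np.full((6, 4), 9.0)
        v = v - v.mean()  # contrast-like second level
        A = base + np.outer(u, v)
        mat = ep.OmicsMatrix(A, [f"g{i}" for i in range(6)], list("wxyz"),
                             np.arange(4.0), "t")
        c = ep.relative_contributions(ep.stratify(mat))
        # a rank-2 matrix has one level beyond baseline
        assert c.ratios.size <= 2
        np.testing.assert_allclose(c.ratios[0], 1.0, atol=1e-12)
        assert c.eigen_entropy <= 1e-10

    def test_equal_levels_max_entropy(self):
        # three equal non-baseline singular values via planted orthogonal design
        rng = np.random.default_rng(1)
        U = np.linalg.qr(rng.standard_normal((10, 4)))[0]
        V = np.linalg.qr(rng.standard_normal((6, 4)))[0]
        lams = [50.0, 2.0, 2.0, 2.0]
        A = sum(l * np.outer(U[:, k], V[:, k]) for k, l in enumerate(lams))
        mat = ep.OmicsMatrix(A, [f"g{i}" for i in range(10)],
                             [f"s{j}" for j in range(6)], np.arange(6.0), "t")
        c = ep.relative_contributions(ep.stratify(mat))
        np.testing.assert_allclose(c.ratios, 1 / 3, atol=1e-10)
        np.testing.assert_allclose(c.eigen_entropy, np.log(3), atol=1e-10)
        np.testing.assert_allclose(c.normalized_entropy, 1.0, atol=1e-10)

    def test_entropy_direct_formula(self):
        # H(0.5, 0.3, 0.2) = 1.0297 nats, recomputed by the direct formula
        p = np.array([0.5, 0.3, 0.2])
        expected = -(p * np.log(p)).sum()
        lams = np.sqrt(p)  # singular values realizing these ratios
        rng = np.random.default_rng(2)
        U = np.linalg.qr(rng.standard_normal((8, 4)))[0]
        V = np.linalg.qr(rng.standard_normal((5, 4)))[0]
        A = 40 * np.outer(U[:, 0], V[:, 0]) + sum(
            l * np.outer(U[:, k + 1], V[:, k + 1]) for k, l in enumerate(lams)
        )
        mat = ep.OmicsMatrix(A, [f"g{i}" for i in range(8)],
                             [f"s{j}" for j in range(5)], np.arange(5.0), "t")
        c = ep.relative_contributions(ep.stratify(mat))
        np.testing.assert_allclose(c.eigen_entropy, expected, atol=1e-8)
        assert round(expected, 4) == 1.0297

    def test_pure_baseline_errors(self):
        mat = ep.OmicsMatrix(np.full((3, 4), 2.0), list("abc"), list("wxyz"),
                             np.arange(4.0), "t")
        with pytest.raises(ValueError, match="no variance beyond baseline"):
            ep.relative_contributions(ep.stratify(mat))


class TestPolarize:
    def test_sorted_with_pole_tags(self):
        lev = eigen.EigenLevel(1, 1.0, np.array([0.3, -0.1, 0.2]),
                               np.array([0.5, -0.5, 0.1]))
        out = ep.polarize(lev, molecule_ids=["a", "b", "c"])
        assert out["molecules"]["loading"].tolist() == [-0.1, 0.2, 0.3]
        assert out["molecules"]["pole"].tolist() == ["negative", "positive", "positive"]

    def test_all_positive_empty_negative_pole(self):
        lev = eigen.EigenLevel(1, 1.0, np.array([0.3, 0.1]), np.array([0.5, 0.2]))
        out = ep.polarize(lev)
        assert (out["molecules"]["pole"] == "positive").all()

    def test_permutation_of_input(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(9)
        lev = eigen.EigenLevel(1, 1.0, u, rng.standard_normal(4))
        out = ep.polarize(lev)
        assert sorted(out["molecules"]["loading"]) == sorted(u.tolist())


class TestCallPhases:
    def test_planted_quadrature_order(self, noiseless_truth):
        t = ep.default_sample_times(noiseless_truth)
        dec = ep.stratify(ep.simulate_omics(noiseless_truth, "transcriptome"))
        ep.orient_to_reference(dec, 1, noiseless_truth.v1(t))
        ep.orient_to_reference(dec, 2, noiseless_truth.v2(t))
        calls = ep.call_phases(dec)
        assert calls.cyclic_order == ["1B", "2A", "1A", "2B"]
        np.testing.assert_array_equal(
            calls.table["sign1"], np.sign(noiseless_truth.v1(t)).astype(int)
        )
        np.testing.assert_array_equal(
            calls.table["sign2"], np.sign(noiseless_truth.v2(t)).astype(int)
        )

    def test_flip_level_one_swaps_labels_and_reverses_order(self, noiseless_truth):
        t = ep.default_sample_times(noiseless_truth)
        dec = ep.stratify(ep.simulate_omics(noiseless_truth, "transcriptome"))
        ep.orient_to_reference(dec, 1, noiseless_truth.v1(t))
        ep.orient_to_reference(dec, 2, noiseless_truth.v2(t))
        before = ep.call_phases(dec)
        dec.flip_level(1)
        after = ep.call_phases(dec)
        swap = {"1A": "1B", "1B": "1A"}
        assert after.table["label1"].tolist() == [
            swap[x] for x in before.table["label1"]
        ]
        # relabeling the swapped sequence at the same circular positions and
        # rotating to the 1B start must reproduce the new order
        expected = [swap.get(x, x) for x in before.cyclic_order]
        start = expected.index("1B")
        assert after.cyclic_order == expected[start:] + expected[:start]

    def test_degenerate_identical_sign_partitions(self):
        # v2 with the same sign pattern as v1 (possible only for boundary or
        # non-orthogonal inputs): duplicated midpoints flagged, and a valid
        # circular sequence over all four labels is still returned
        n = 8
        t = np.arange(n, dtype=float)
        v1 = np.array([1.0, 1, 1, 1, -1, -1, -1, -1]) * 0.35
        v2 = np.array([2.0, 1, 1, 2, -2, -1, -1, -2]) * 0.2
        rng = np.random.default_rng(0)
        U = np.linalg.qr(rng.standard_normal((6, 3)))[0]
        dec = eigen.EigenDecomposition(
            lambdas=np.array([50.0, 5.0, 2.0]),
            U=U,
            V=np.column_stack([np.full(n, 1 / np.sqrt(n)), v1, v2]),
            molecule_ids=[f"g{i}" for i in range(6)],
            sample_ids=[f"s{j}" for j in range(n)],
            sample_times=t,
            source_values=np.zeros((6, n)),
            source_labels=["t"],
        )
        with pytest.warns(UserWarning, match="duplicated phase midpoints"):
            calls = ep.call_phases(dec)
        assert calls.duplicate_midpoints
        assert sorted(calls.cyclic_order) == ["1A", "1B", "2A", "2B"]


class TestReconstruct:
    def test_keep_all_and_keep_none(self, transcriptome_dec):
        dec = transcriptome_dec
        _, resid = ep.reconstruct(dec, dec.level_indices)
        assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(dec.source_values)
        approx, resid = ep.reconstruct(dec, [])
        np.testing.assert_array_equal(approx, 0.0)
        np.testing.assert_array_equal(resid, dec.source_values)

    def test_invalid_level_errors(self, transcriptome_dec):
        with pytest.raises(IndexError):
            ep.reconstruct(transcriptome_dec, [999])

    def test_noise_budget(self, truth):
        # residual beyond levels {0,1,2} carries the noise not absorbed by
        # the three fitted levels: E||resid||^2 ~ mn sigma^2 (1 - 3(m+n)/(mn))
        sigma = truth.omics["transcriptome"].sigma
        ratios = []
        for seed in range(5):
            t = ep.generate_truth(seed=200 + seed)
            mat = ep.simulate_omics(t, "transcriptome")
            dec = ep.stratify(mat)
            _, resid = ep.reconstruct(dec, [0, 1, 2])
            m, n = mat.values.shape
            ratios.append(np.linalg.norm(resid) ** 2 / (m * n * sigma**2))
        assert 0.85 <= np.mean(ratios) <= 1.0


class TestConcat:
    def test_prepared_norm(self):
        mat = random_mat(8, 20, 6)
        prep = ep.concat_prepare(mat)
        np.testing.assert_allclose(np.linalg.norm(prep.values), 1 / np.sqrt(6), atol=1e-10)

    def test_constant_matrix_errors(self):
        mat = ep.OmicsMatrix(np.full((3, 4), 2.0), list("abc"), list("wxyz"),
                             np.arange(4.0), "t")
        with pytest.raises(ValueError, match="pure baseline"):
            ep.concat_prepare(mat)

    def test_duplication_symmetry(self):
        mat = random_mat(10, 15, 5)
        prep = ep.concat_prepare(mat)
        prep2 = ep.OmicsMatrix(prep.values.copy(), prep.molecule_ids,
                               [s + "_b" for s in prep.sample_ids],
                               prep.sample_times, "copy")
        cdec = ep.concat_and_stratify(prep, prep2)
        alone = np.linalg.svd(prep.values, full_matrices=False)
        np.testing.assert_allclose(
            np.abs(cdec.level(1).molecule_loadings), np.abs(alone[0][:, 0]), atol=1e-8
        )
        a, b = cdec.segments[prep.omics_label], cdec.segments["copy"]
        v = cdec.level(1).sample_loadings
        np.testing.assert_allclose(v[a[0]:a[1]], v[b[0]:b[1]], atol=1e-8)

    def test_molecule_mismatch_errors(self):
        m1 = ep.concat_prepare(random_mat(1, 10, 5))
        m2 = ep.concat_prepare(random_mat(2, 10, 5))
        m2.molecule_ids[0] = "other"
        with pytest.raises(ValueError, match="molecule mismatch"):
            ep.concat_and_stratify(m1, m2)

    def test_shared_signal_recovery(self, truth):
        m1 = ep.simulate_omics(truth, "transcriptome")
        t2 = (np.arange(24) + 0.5) * truth.period / 12
        m2 = ep.simulate_omics(truth, "transcriptome", t2)
        cdec = ep.concat_and_stratify(ep.concat_prepare(m1), ep.concat_prepare(m2))
        assert cdec.index_offset == 1
        assert abs(np.dot(cdec.level(1).molecule_loadings, truth.u1)) > 0.95

    def test_noise_dilutes_first_level(self, truth):
        m1 = ep.simulate_omics(truth, "transcriptome")
        rng = np.random.default_rng(0)
        noise = ep.OmicsMatrix(
            rng.standard_normal(m1.values.shape) + 8.0, m1.molecule_ids,
            [s + "_n" for s in m1.sample_ids], m1.sample_times, "noise",
        )
        cdec = ep.concat_and_stratify(ep.concat_prepare(m1), ep.concat_prepare(noise))
        alone = ep.relative_contributions(ep.stratify(m1)).ratios[0]
        diluted = ep.relative_contributions(cdec).ratios[0]
        assert diluted < alone


def test_serialization_round_trip(tmp_path, transcriptome_dec):
    transcriptome_dec.to_dir(tmp_path / "dec")
    back = ep.EigenDecomposition.from_dir(tmp_path / "dec")
    np.testing.assert_allclose(back.lambdas, transcriptome_dec.lambdas, rtol=1e-12)
    np.testing.assert_allclose(back.U, transcriptome_dec.U, atol=1e-12)
    assert back.molecule_ids == transcriptome_dec.molecule_ids
    assert back.index_offset == transcriptome_dec.index_offset
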