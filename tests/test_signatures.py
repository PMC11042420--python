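import numpy as np
import pytest
from scipy.special import gammaln

from organfield import signatures as sg
from organfield import synthetic_data as sd
from organfield.errors import ValidationError
from organfield.organ_io import MOTIF_INDEX, MutationRecord


def snv(mid, ref, alt, context=None):
    return MutationRecord(mid, "G", "1", 100, ref, alt, context=context)


class TestSpectrum:
    def test_purine_complemented(self):
        cat = sg.substitution_spectrum([snv("m1", "G", "A")])
        assert cat.counts6[sg.SUBSTITUTION_CLASSES.index("C>T")] == 1

    def test_a_to_c_counts_as_t_to_g(self):
        cat = sg.substitution_spectrum([snv("m1", "A", "C")])
        assert cat.counts6[sg.SUBSTITUTION_CLASSES.index("T>G")] == 1

    def test_conservation(self):
        records = [snv(f"m{i}", "C", "T") for i in range(10)]
        assert sg.substitution_spectrum(records).counts6.sum() == 10

    def test_selection_subset(self):
        records = [snv("m1", "C", "T"), snv("m2", "C", "A")]
        cat = sg.substitution_spectrum(records, selection={"m1"})
        assert cat.n == 1


class TestCatalog96:
    def test_pyrimidine_context_binned_directly(self):
        cat = sg.context_catalog96([snv("m1", "C", "T", "TCA")])
        assert cat.counts96[MOTIF_INDEX["T[C>T]A"]] == 1

    def test_purine_context_reverse_complemented(self):
        # TGA with G>A reverse-complements to TCA with C>T
        cat = sg.context_catalog96([snv("m1", "G", "A", "TGA")])
        assert cat.counts96[MOTIF_INDEX["T[C>T]A"]] == 1

    def test_invalid_context_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            snv("m1", "A", "G", "ACA")  # center must equal ref

    def test_missing_context_error_lists_ids(self):
        with pytest.raises(ValidationError, match="m1"):
            sg.context_catalog96([snv("m1", "C", "T")])

    def test_missing_context_skip(self):
        cat = sg.context_catalog96(
            [snv("m1", "C", "T"), snv("m2", "C", "T", "TCA")], on_missing="skip"
        )
        assert cat.n == 1

    def test_partition_conservation(self, sig_matrix):
        catalog = sd.simulate_catalog(sd.default_signature_mixture(30), sig_matrix, 500, seed=1)
        # split the counts over two halves; group catalogs sum to pooled
        half = catalog.counts96 // 2
        rest = catalog.counts96 - half
        a, b = sg.catalog_from_counts96(half), sg.catalog_from_counts96(rest)
        assert np.array_equal(a.counts96 + b.counts96, catalog.counts96)
        assert np.array_equal(a.counts6 + b.counts6, catalog.counts6)


class TestFitWeights:
    def test_exact_column_recovery(self, sig_matrix):
        res = sg.fit_signature_weights(sig_matrix.W[:, 3], sig_matrix)
        expected = np.zeros(30)
        expected[3] = 1.0
        assert res.objective < 1e-20
        assert np.abs(res.H - expected).max() < 1e-8

    def test_disjoint_support_mixture(self):
        W = np.zeros((96, 2))
        W[:48, 0] = 1.0 / 48
        W[48:, 1] = 1.0 / 48
        sig = sg.SignatureMatrix(W=W, labels=["a", "b"])
        V = 0.7 * W[:, 0] + 0.3 * W[:, 1]
        res = sg.fit_signature_weights(V, sig)
        assert np.allclose(res.H, [0.7, 0.3], atol=1e-10)

    def test_matches_projected_gradient_oracle(self, sig_matrix):
        rng = np.random.default_rng(5)
        Hstar = rng.dirichlet(np.ones(30))
        V = sig_matrix.W @ Hstar
        res = sg.fit_signature_weights(V, sig_matrix)
        oracle = sg.projected_gradient_weights(V, sig_matrix.W)
        assert np.abs(res.H - oracle).max() < 1e-4
        assert res.objective < 1e-10

    def test_simplex_feasibility(self, sig_matrix, rng):
        V = rng.dirichlet(np.ones(96))
        res = sg.fit_signature_weights(V, sig_matrix, strict=False)
        assert (res.H >= 0).all()
        assert abs(res.H.sum() - 1.0) < 1e-8

    def test_objective_non_increasing_with_added_signature(self, sig_matrix, rng):
        V = rng.dirichlet(np.ones(96))
        for k in range(2, 10):
            sub_small = sg.SignatureMatrix(sig_matrix.W[:, : k - 1], sig_matrix.labels[: k - 1])
            sub_big = sg.SignatureMatrix(sig_matrix.W[:, :k], sig_matrix.labels[:k])
            obj_small = sg.fit_signature_weights(V, sub_small, strict=False).objective
            obj_big = sg.fit_signature_weights(V, sub_big, strict=False).objective
            assert obj_big <= obj_small + 1e-12

    def test_off_simplex_strict_error(self, sig_matrix):
        with pytest.raises(ValidationError):
            sg.fit_signature_weights(np.full(96, 0.5 / 96), sig_matrix, strict=True)

    def test_empty_matrix_error(self):
        with pytest.raises(ValidationError):
            sg.SignatureMatrix(np.zeros((96, 0)), [])


class TestBootstrap:
    def test_pure_signature_significant(self, sig_matrix):
        cat = sd.simulate_catalog(np.eye(30)[0], sig_matrix, 1000, seed=3)
        res = sg.bootstrap_signature_pvalues(cat, sig_matrix, B=200, seed=5)
        assert res.boot_p[0] < 0.005
        assert res.H[0] > 0.95  # concentration on the generating signature

    def test_b_equals_one_granularity(self, sig_matrix):
        cat = sd.simulate_catalog(np.eye(30)[0], sig_matrix, 100, seed=3)
        res = sg.bootstrap_signature_pvalues(cat, sig_matrix, B=1, seed=5)
        assert set(np.unique(res.boot_p)) <= {0.0, 1.0}

    def test_same_seed_identical(self, sig_matrix):
        cat = sd.simulate_catalog(sd.default_signature_mixture(30), sig_matrix, 300, seed=3)
        r1 = sg.bootstrap_signature_pvalues(cat, sig_matrix, B=20, seed=11)
        r2 = sg.bootstrap_signature_pvalues(cat, sig_matrix, B=20, seed=11)
        assert np.array_equal(r1.boot_p, r2.boot_p)

    def test_literal_mode_is_descriptive(self, sig_matrix):
        cat = sd.simulate_catalog(np.eye(30)[0], sig_matrix, 500, seed=3)
        res = sg.bootstrap_signature_pvalues(cat, sig_matrix, B=50, seed=5, mode="literal")
        # the dominant signature's literal p is ~0.5, not small
        assert res.boot_p[0] > 0.2

    def test_empty_catalog_error(self, sig_matrix):
        cat = sg.SpectrumCatalog(np.zeros(6), 0, np.zeros(96))
        with pytest.raises(ValidationError):
            sg.bootstrap_signature_pvalues(cat, sig_matrix, B=10, seed=0)


class TestCompareGroups:
    def test_identical_spectra_p_one(self):
        data = {"a": [5, 5, 5, 5, 5, 5], "b": [5, 5, 5, 5, 5, 5]}
        out = sg.compare_groups(data, mode="spectrum")
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_2x2_equals_hypergeometric_enumeration(self, rng):
        for _ in range(20):
            table = rng.integers(0, 8, size=(2, 2))
            if table.sum() == 0:
                continue
            p_pkg = sg.exact_rxc_test(table)
            # enumeration oracle over the free cell
            r0, r1 = table.sum(axis=1)
            c0 = table[:, 0].sum()
            n = table.sum()
            obs_lp = (
                gammaln(r0 + 1) + gammaln(r1 + 1) + gammaln(c0 + 1) + gammaln(n - c0 + 1)
                - gammaln(n + 1) - gammaln(table + 1).sum()
            )
            p_ref = 0.0
            for x in range(max(0, c0 - r1), min(r0, c0) + 1):
                t = np.array([[x, r0 - x], [c0 - x, r1 - (c0 - x)]])
                lp = (
                    gammaln(r0 + 1) + gammaln(r1 + 1) + gammaln(c0 + 1)
                    + gammaln(n - c0 + 1) - gammaln(n + 1) - gammaln(t + 1).sum()
                )
                if lp <= obs_lp + 1e-9:
                    p_ref += np.exp(lp)
            assert p_pkg == pytest.approx(min(p_ref, 1.0), rel=1e-6)

    def test_enumeration_matches_monte_carlo(self):
        table = np.array([[3, 2, 1], [1, 4, 2], [2, 1, 4]])
        p_enum = sg.exact_rxc_test(table)
        p_mc = sg.exact_rxc_test(table, enumerate_below=0, n_mc=100_000, seed=2024)
        assert p_mc == pytest.approx(p_enum, abs=0.01)

    def test_bh_adjustment(self):
        adj = sg.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_motif_mode(self, rng):
        A = rng.dirichlet(np.ones(96), size=5)
        B = rng.dirichlet(np.ones(96), size=6)
        out = sg.compare_groups({"x": A, "y": B}, mode="motif")
        assert len(out) == 96
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()
        assert (out["fdr"] >= out["p"] - 1e-12).all()

    def test_weights_mode_kruskal(self, rng):
        data = {g: rng.dirichlet(np.ones(5), size=4) for g in ("a", "b", "c")}
        out = sg.compare_groups(data, mode="weights")
        assert len(out) == 5

    def test_empty_group_error(self):
        with pytest.raises(ValidationError):
            sg.compare_groups({"a": [1, 2], "b": []}, mode="spectrum")
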