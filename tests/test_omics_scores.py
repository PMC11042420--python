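import numpy as np
import pytest
import scipy.stats

from organfield import omics_scores as om
from organfield import synthetic_data as sd
from organfield.errors import ValidationError


def make_matrix(values, groups=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return om.AbundanceMatrix(
        values,
        [f"f{i}" for i in range(n)],
        [f"s{j}" for j in range(m)],
        groups or ["g"] * m,
    )


class TestImpute:
    def test_half_minimum(self):
        mat = make_matrix([[4.0, np.nan], [8.0, 6.0]])
        out = om.impute_half_min(mat)
        assert out.values[0, 1] == 2.0
        assert out.values[0, 0] == 4.0  # observed values untouched

    def test_identity_without_missing(self):
        mat = make_matrix([[4.0, 5.0]])
        out = om.impute_half_min(mat)
        assert np.array_equal(out.values, mat.values)

    def test_no_missing_after(self):
        mat = make_matrix([[4.0, np.nan], [np.nan, 6.0]])
        assert not om.impute_half_min(mat).missing_mask.any()

    def test_idempotent(self):
        mat = make_matrix([[4.0, np.nan], [8.0, 6.0]])
        once = om.impute_half_min(mat)
        twice = om.impute_half_min(once)
        assert np.array_equal(once.values, twice.values)

    def test_all_missing_error(self):
        with pytest.raises(ValidationError):
            om.impute_half_min(make_matrix([[np.nan, np.nan]]))


class TestDifferential:
    def groups(self):
        return ["a"] * 4 + ["b"] * 4

    def test_two_fold_up_flagged(self, rng):
        base = rng.uniform(9.5, 10.5, size=(1, 4))
        mat = make_matrix(np.hstack([base * 2.0, base]), self.groups())
        out = om.differential_features(mat, "a", "b")
        assert bool(out["flag"].iloc[0])
        assert out["log2fc"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_small_fold_not_flagged(self, rng):
        base = np.full((1, 4), 10.0) + rng.normal(0, 0.01, (1, 4))
        mat = make_matrix(np.hstack([base * 1.2, base]), self.groups())
        out = om.differential_features(mat, "a", "b")
        assert not out["flag"].iloc[0]  # p tiny but fold criterion fails

    def test_identical_groups_unflagged(self):
        vals = np.tile(np.array([[1.0, 2.0, 3.0, 4.0]]), (3, 2))
        mat = make_matrix(vals, self.groups())
        out = om.differential_features(mat, "a", "b")
        assert not out["flag"].any()

    def test_zero_variance_equal_means(self):
        mat = make_matrix(np.full((1, 8), 5.0), self.groups())
        out = om.differential_features(mat, "a", "b")
        assert out["p"].iloc[0] == 1.0
        assert not out["flag"].iloc[0]

    def test_flag_set_shrinks_with_fold_threshold(self, rng):
        mat, _ = sd.simulate_omics(
            n_features=300, n_monotone_up=30, n_monotone_down=30,
            effect=0.8, noise_sd=0.4, seed=3,
        )
        flags = []
        for fc in (1.0, 1.5, 2.0, 3.0):
            out = om.differential_features(mat, "UC", "NU_LGIN", fold_cutoff=fc)
            flags.append(set(out.loc[out["flag"], "feature_id"]))
        for small, big in zip(flags[1:], flags[:-1]):
            assert small <= big

    def test_needs_two_samples(self):
        mat = make_matrix([[1.0, 2.0]], ["a", "b"])
        with pytest.raises(ValidationError):
            om.differential_features(mat, "a", "b")


class TestMonotonic:
    def test_strict_increase_over_control(self):
        groups = ["control"] * 2 + ["NU_LGIN"] * 2 + ["HGIN"] * 2 + ["UC"] * 2
        vals = np.array([[0.5, 0.5, 1, 1, 2, 2, 3, 3], [1, 1, 1, 1, 3, 3, 2, 2]])
        sets = om.monotonic_features(make_matrix(vals, groups))
        assert sets["up"] == ["f0"]
        assert sets["down"] == []

    def test_non_monotone_excluded(self):
        groups = ["control"] * 2 + ["NU_LGIN"] * 2 + ["HGIN"] * 2 + ["UC"] * 2
        vals = np.array([[0.5, 0.5, 1, 1, 3, 3, 2, 2]])
        sets = om.monotonic_features(make_matrix(vals, groups))
        assert sets["up"] == [] and sets["down"] == []

    def test_planted_recovery_exact(self):
        mat, truth = sd.simulate_omics(noise_sd=0.0, missing_rate=0.0, seed=1)
        sets = om.monotonic_features(mat)
        assert sets["up"] == truth["up"]
        assert sets["down"] == truth["down"]


def naive_es(abund, member_positions, tau):
    """Independent ECDF-difference implementation (oracle)."""
    n = len(abund)
    ranks = scipy.stats.rankdata(abund)
    order = np.argsort(-np.asarray(abund), kind="stable")
    inset = np.zeros(n, dtype=bool)
    inset[list(member_positions)] = True
    wsum = sum(ranks[i] ** tau for i in range(n) if inset[i])
    nout = n - inset.sum()
    es, p_in, p_out = 0.0, 0.0, 0.0
    for pos in order:
        if inset[pos]:
            p_in += ranks[pos] ** tau / wsum
        else:
            p_out += 1.0 / nout
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_matches_naive_oracle(self, rng):
        n = 50
        mat = make_matrix(rng.uniform(1, 10, (n, 5)))
        pathways = [
            om.PathwaySet(f"p{k}", tuple(f"f{i}" for i in rng.choice(n, 7, replace=False)))
            for k in range(5)
        ]
        scores = om.ssgsea(mat, pathways, weight_exponent=0.75)
        for k, p in enumerate(pathways):
            members = [int(mname[1:]) for mname in p.members]
            for j in range(5):
                ref = naive_es(mat.values[:, j], members, 0.75)
                assert scores.values[k, j] == pytest.approx(ref, abs=1e-10)

    def test_top_ranked_set_is_maximal(self, rng):
        n = 30
        vals = np.arange(n, 0, -1, dtype=float)[:, None]
        mat = make_matrix(vals)
        top = om.PathwaySet("top", tuple(f"f{i}" for i in range(5)))
        es_top = om.ssgsea(mat, [top]).values[0, 0]
        for _ in range(50):
            members = tuple(f"f{i}" for i in rng.choice(n, 5, replace=False))
            es = om.ssgsea(mat, [om.PathwaySet("x", members)]).values[0, 0]
            assert es <= es_top + 1e-12

    def test_monotone_transform_invariance(self, rng):
        n = 40
        mat = make_matrix(rng.uniform(1, 10, (n, 3)))
        pathways = [om.PathwaySet("p", tuple(f"f{i}" for i in range(6)))]
        s1 = om.ssgsea(mat, pathways)
        transformed = make_matrix(np.exp(mat.values / 2.0))
        s2 = om.ssgsea(transformed, pathways)
        assert np.array_equal(s1.values, s2.values)

    def test_permutation_null_mean_near_zero(self, rng):
        n = 40
        members = tuple(f"f{i}" for i in range(8))
        es = []
        for _ in range(1000):
            vals = rng.permutation(np.arange(1.0, n + 1))[:, None]
            mat = make_matrix(vals)
            es.append(om.ssgsea(mat, [om.PathwaySet("p", members)], weight_exponent=0.0).values[0, 0])
        es = np.asarray(es)
        se = es.std(ddof=1) / np.sqrt(len(es))
        assert abs(es.mean()) <= 3 * se

    def test_full_set_pathway_error(self):
        mat = make_matrix(np.arange(8.0).reshape(4, 2) + 1)
        with pytest.raises(ValidationError):
            om.ssgsea(mat, [om.PathwaySet("all", ("f0", "f1", "f2", "f3"))])

    def test_absent_members_warn_and_small_sets_dropped(self, rng):
        mat = make_matrix(rng.uniform(1, 5, (10, 2)))
        with pytest.warns(UserWarning):
            scores = om.ssgsea(
                mat,
                [om.PathwaySet("tiny", ("f0", "nope1", "nope2")),
                 om.PathwaySet("ok", ("f0", "f1", "f2"))],
            )
        assert scores.pathway_names == ["ok"]

    def test_normalization_affine(self, rng):
        mat = make_matrix(rng.uniform(1, 5, (20, 4)))
        pws = [om.PathwaySet(f"p{k}", tuple(f"f{i}" for i in range(k + 2, k + 8))) for k in range(3)]
        raw = om.ssgsea(mat, pws, normalize=False)
        norm = om.ssgsea(mat, pws, normalize=True)
        span = raw.values.max() - raw.values.min()
        assert np.allclose(norm.values, raw.values / span)


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        pws = [om.PathwaySet("p1", ("a", "b", "c")), om.PathwaySet("p2", ("d", "e"))]
        path = tmp_path / "sets.gmt"
        om.write_gmt(pws, path)
        again = om.read_gmt(path)
        assert again == pws

    def test_malformed_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\n")
        with pytest.raises(ValidationError):
            om.read_gmt(path)


def test_abundance_matrix_io(tmp_path, rng):
    mat, _ = sd.simulate_omics(
        n_features=20, n_monotone_up=5, n_monotone_down=5, seed=5, missing_rate=0.1
    )
    path = tmp_path / "ab.tsv"
    mat.to_frame().to_csv(path, sep="\t")
    groups = dict(zip(mat.sample_ids, mat.groups))
    again = om.read_abundance_matrix(path, groups)
    assert again.feature_ids == mat.feature_ids
    assert again.groups == mat.groups
    assert np.allclose(again.values, mat.values, equal_nan=True)
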