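"""Structural QC: distances, clustering purity, PCA, parental comparability."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import twinmeth as tm


def _beta(rows, samples):
    return pd.DataFrame(rows, columns=samples, index=[f"cg{i}" for i in range(len(rows))])


class TestDistanceMatrix:
    def test_identical_profiles_zero(self):
        beta = _beta([[0.2, 0.2], [0.8, 0.8]], ["a", "b"])
        d = tm.distance_matrix(beta, ["a", "b"])
        assert d.loc["a", "b"] == 0.0

    def test_unit_cube_diagonal(self):
        beta = _beta([[0, 1], [0, 1], [0, 1]], ["a", "b"])
        d = tm.distance_matrix(beta, ["a", "b"])
        assert d.loc["a", "b"] == pytest.approx(np.sqrt(3))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_with_missingness(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, size=(200, 4))
        x[rng.uniform(size=x.shape) < 0.1] = np.nan
        beta = _beta(x, list("abcd"))
        d = tm.distance_matrix(beta, list("abcd"))
        n = x.shape[0]
        for i, si in enumerate("abcd"):
            for j, sj in enumerate("abcd"):
                shared = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
                brute = np.sqrt(np.nansum((x[shared, i] - x[shared, j]) ** 2))
                brute *= np.sqrt(n / shared.sum())
                assert d.iloc[i, j] == pytest.approx(brute, abs=1e-10)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_no_shared_probes_is_error(self):
        beta = _beta([[0.1, np.nan], [np.nan, 0.5]], ["a", "b"])
        with pytest.raises(tm.InputError, match="share no probes"):
            tm.distance_matrix(beta, ["a", "b"])


class TestClusterPurity:
    def test_separated_groups_pure(self):
        rng = np.random.default_rng(0)
        left = rng.normal(0.2, 0.01, size=(100, 3)).clip(0, 1)
        right = rng.normal(0.6, 0.01, size=(100, 3)).clip(0, 1)
        beta = _beta(np.hstack([left, right]), list("abcdef"))
        d = tm.distance_matrix(beta, list("abcdef"))
        labels = {s: ("L" if s in "abc" else "R") for s in "abcdef"}
        out = tm.cluster_and_purity(d, labels)
        assert out.purity == 1.0
        assert not out.degenerate

    def test_identical_samples_degenerate(self):
        beta = _beta([[0.5] * 4] * 10, list("abcd"))
        d = tm.distance_matrix(beta, list("abcd"))
        out = tm.cluster_and_purity(d, {s: "x" for s in "abcd"})
        assert out.degenerate

    def test_label_permutation_leaves_purity_unchanged(self):
        rng = np.random.default_rng(1)
        beta = _beta(rng.uniform(0, 1, size=(50, 5)), list("abcde"))
        d = tm.distance_matrix(beta, list("abcde"))
        labels = {"a": "L", "b": "L", "c": "R", "d": "R", "e": "R"}
        swapped = {k: ("R" if v == "L" else "L") for k, v in labels.items()}
        assert (
            tm.cluster_and_purity(d, labels).purity
            == tm.cluster_and_purity(d, swapped).purity
        )

    def test_missing_label_is_error(self):
        beta = _beta([[0.1, 0.9]], ["a", "b"])
        d = tm.distance_matrix(beta, ["a", "b"])
        with pytest.raises(tm.InputError, match="missing labels"):
            tm.cluster_and_purity(d, {"a": "L"})


class TestPCA:
    def test_identical_samples_degenerate(self):
        beta = _beta([[0.4] * 4] * 10, list("abcd"))
        out = tm.pca_top_sites(beta, list(beta.index), list("abcd"))
        assert out.degenerate
        assert np.allclose(out.scores, 0.0)

    def test_rank_one_structure(self):
        # two groups differing by a constant shift on half the probes
        probes = 20
        a = np.full(probes, 0.2)
        b = a.copy()
        b[:10] += 0.4
        beta = _beta(np.column_stack([a, a, b, b]), list("wxyz"))
        out = tm.pca_top_sites(beta, list(beta.index), list("wxyz"))
        assert out.explained_variance_fraction[0] == pytest.approx(1.0)
        pc1 = out.scores["PC1"]
        assert np.sign(pc1["w"]) == np.sign(pc1["x"]) != np.sign(pc1["y"])

    def test_reconstruction(self):
        rng = np.random.default_rng(3)
        beta = _beta(rng.uniform(0, 1, size=(30, 6)), list("abcdef"))
        out = tm.pca_top_sites(beta, list(beta.index), list("abcdef"))
        x = beta.to_numpy()
        centered = (x - x.mean(axis=1, keepdims=True)).T
        recon = out.scores.to_numpy() @ out.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        beta = _beta(rng.uniform(0, 1, size=(30, 5)), list("abcde"))
        s1 = tm.pca_top_sites(beta, list(beta.index), list("abcde")).scores
        s2 = tm.pca_top_sites(beta, list(beta.index), list("abcde")).scores
        pd.testing.assert_frame_equal(s1, s2)
        for comp in tm.pca_top_sites(beta, list(beta.index), list("abcde")).loadings.columns:
            load = tm.pca_top_sites(beta, list(beta.index), list("abcde")).loadings[comp]
            assert load.iloc[np.argmax(np.abs(load.to_numpy()))] > 0

    def test_incomplete_probes_dropped(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, size=(20, 4))
        x[0, 1] = np.nan
        beta = _beta(x, list("abcd"))
        out = tm.pca_top_sites(beta, list(beta.index), list("abcd"))
        assert out.n_dropped_probes == 1
        assert "cg0" not in out.loadings.index

    def test_too_few_samples_rejected(self):
        beta = _beta([[0.5]], ["a"])
        with pytest.raises(tm.InputError):
            tm.pca_top_sites(beta, ["cg0"], ["a"])


class TestParentalCheck:
    def test_parent_equal_to_reference_mean(self):
        beta = _beta([[0.3, 0.2, 0.4], [0.7, 0.6, 0.8]], ["P", "H1", "H2"])
        out = tm.parental_check(["cg0", "cg1"], beta, ["P"], ["H1", "H2"])
        assert out.fraction_comparable == 1.0

    def test_deviating_parent_flags_probe(self):
        beta = _beta([[0.9, 0.35, 0.45], [0.4, 0.35, 0.45]], ["P", "H1", "H2"])
        out = tm.parental_check(["cg0", "cg1"], beta, ["P"], ["H1", "H2"])
        assert not out.flags["cg0"]
        assert out.flags["cg1"]
        assert out.fraction_comparable == 0.5

    def test_vacuous_tolerance(self):
        rng = np.random.default_rng(6)
        beta = _beta(rng.uniform(0, 1, size=(50, 3)), ["P", "H1", "H2"])
        out = tm.parental_check(list(beta.index), beta, ["P"], ["H1", "H2"], tolerance=1.0)
        assert out.fraction_comparable == 1.0

    def test_empty_reference_set_is_error(self):
        beta = _beta([[0.5, 0.5]], ["P", "H"])
        with pytest.raises(tm.InputError, match="empty"):
            tm.parental_check(["cg0"], beta, ["P"], [])


def test_first_split_on_synthetic_data(default_run):
    """Planted disease effects dominate: the two-cluster cut separates
    leukemic from non-leukemic samples even with composition confounding."""
    ds = default_run.dataset
    cond = dict(zip(ds.samples["sample_id"], ds.samples["condition"]))
    ids = [
        s for s in ds.beta.columns
        if cond[s] in ("diagnosis", "remission", "healthy", "ref_cd34")
    ]
    d = tm.distance_matrix(ds.beta, ids)
    labels = {s: ("leukemic" if cond[s] == "diagnosis" else "non-leukemic") for s in ids}
    assert tm.cluster_and_purity(d, labels).purity == 1.0


def test_parents_match_healthy_references(default_run):
    """At the signature CpGs the parents look like healthy subjects: no
    inherited disease-like pattern is planted."""
    ds = default_run.dataset
    cpgs = default_run.selection.signature_cpgs
    refs = ["S2", "S3", "A1_r", "A2_r", "A3_r"]
    out = tm.parental_check(cpgs, ds.beta, ["S4", "S5"], refs)
    assert out.fraction_comparable >= 0.9
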