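"""CpG-gene correlation and signature selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import twinmeth as tm


def _inputs(beta_rows, expr_rows, samples):
    beta = pd.DataFrame(beta_rows, columns=samples,
                        index=[f"cg{i}" for i in range(len(beta_rows))])
    expr = pd.DataFrame(expr_rows, columns=samples,
                        index=[f"G{i}" for i in range(len(expr_rows))])
    cand = pd.DataFrame(
        {"probe_id": beta.index, "gene": expr.index[: len(beta.index)], "region": "TSS200"}
    )
    return beta, expr, cand


SAMPLES = [f"s{i}" for i in range(6)]


def test_pearson_on_printed_vectors():
    # direct Pearson formula on these vectors gives -0.99773518
    beta, expr, cand = _inputs(
        [[0.8, 0.75, 0.7, 0.3, 0.25, 0.2]], [[1, 2, 3, 8, 9, 10]], SAMPLES
    )
    rec = tm.correlate_cpg_gene(beta, expr, cand, SAMPLES)
    assert rec.iloc[0]["rho"] == pytest.approx(-0.9977, abs=1e-4)


def test_exact_linear_anticorrelation():
    b = [0.9, 0.7, 0.5, 0.4, 0.3, 0.1]
    beta, expr, cand = _inputs([b], [[10 - 8 * x for x in b]], SAMPLES)
    rec = tm.correlate_cpg_gene(beta, expr, cand, SAMPLES)
    assert rec.iloc[0]["rho"] == pytest.approx(-1.0)
    assert rec.iloc[0]["p_value"] == 0.0


def test_constant_beta_is_degenerate():
    beta, expr, cand = _inputs([[0.5] * 6], [[1, 2, 3, 4, 5, 6]], SAMPLES)
    rec = tm.correlate_cpg_gene(beta, expr, cand, SAMPLES)
    assert bool(rec.iloc[0]["degenerate"])
    assert np.isnan(rec.iloc[0]["p_value"])
    assert np.isnan(rec.iloc[0]["p_corr"])


@pytest.mark.parametrize("seed", range(5))
def test_rho_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = 50
    beta, expr, cand = _inputs(
        rng.uniform(0, 1, size=(n, 6)), rng.normal(5, 2, size=(n, 6)), SAMPLES
    )
    rec = tm.correlate_cpg_gene(beta, expr, cand, SAMPLES)
    for i in range(n):
        x = beta.iloc[i].to_numpy()
        y = expr.iloc[i].to_numpy()
        brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert rec.iloc[i]["rho"] == pytest.approx(brute, abs=1e-12)


def test_p_value_via_t_transform():
    from scipy import stats

    rng = np.random.default_rng(9)
    beta, expr, cand = _inputs(
        rng.uniform(0, 1, size=(10, 6)), rng.normal(size=(10, 6)), SAMPLES
    )
    rec = tm.correlate_cpg_gene(beta, expr, cand, SAMPLES)
    for _, row in rec.iterrows():
        ref = stats.pearsonr(
            beta.loc[row["probe_id"]].to_numpy(),
            expr.loc[row["gene"]].to_numpy(),
        )
        assert row["p_value"] == pytest.approx(ref.pvalue, abs=1e-9)


def test_sample_validation_errors():
    beta, expr, cand = _inputs([[0.1] * 6], [[1] * 6], SAMPLES)
    with pytest.raises(tm.InputError, match="three"):
        tm.correlate_cpg_gene(beta, expr, cand, SAMPLES[:2])
    with pytest.raises(tm.InputError, match="s9"):
        tm.correlate_cpg_gene(beta, expr, cand, SAMPLES[:5] + ["s9"])


def _records(gene, rhos, p_corr=0.01):
    return pd.DataFrame(
        {
            "probe_id": [f"{gene}_cg{i}" for i in range(len(rhos))],
            "gene": gene,
            "rho": rhos,
            "p_value": p_corr,
            "p_corr": p_corr,
            "degenerate": False,
        }
    )


def _de(genes, significant=True, p_fdr=0.001, log2fc=-4.0):
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p_fdr,
            "p_fdr": p_fdr,
            "significant": significant,
        },
        index=pd.Index(genes, name="gene"),
    )


class TestSelection:
    def test_three_negative_cpgs_selected(self):
        rec = _records("RAB32L", [-0.97, -0.9, -0.84])
        out = tm.select_signature_genes(rec, _de(["RAB32L"]))
        assert list(out.genes["gene"]) == ["RAB32L"]
        assert out.genes.iloc[0]["correlation_sign"] == "-"
        assert out.genes.iloc[0]["n_cpgs"] == 3

    def test_two_cpgs_excluded(self):
        rec = _records("G", [-0.97, -0.9])
        assert tm.select_signature_genes(rec, _de(["G"])).genes.empty

    def test_nine_positive_cpgs_selected_with_plus_sign(self):
        rec = _records("MACROD2L", [0.86, 0.9, 0.92, 0.95, 0.97, 0.99, 0.88, 0.91, 0.93])
        out = tm.select_signature_genes(rec, _de(["MACROD2L"], log2fc=5.8))
        assert out.genes.iloc[0]["correlation_sign"] == "+"
        assert out.genes.iloc[0]["n_cpgs"] == 9

    def test_mixed_signs_labelled_mixed(self):
        rec = _records("G", [-0.9, -0.85, 0.95])
        out = tm.select_signature_genes(rec, _de(["G"]))
        assert out.genes.iloc[0]["correlation_sign"] == "mixed"

    def test_de_insignificant_gene_excluded(self):
        rec = _records("G", [-0.97, -0.9, -0.84])
        assert tm.select_signature_genes(rec, _de(["G"], significant=False)).genes.empty

    def test_rho_below_threshold_fails(self):
        rec = _records("G", [-0.69, -0.6, -0.5])
        assert tm.select_signature_genes(rec, _de(["G"])).genes.empty

    def test_pcorr_criterion_toggleable(self):
        rec = _records("G", [-0.97, -0.9, -0.84], p_corr=0.2)
        assert tm.select_signature_genes(rec, _de(["G"])).genes.empty
        out = tm.select_signature_genes(rec, _de(["G"]), require_pcorr=False)
        assert list(out.genes["gene"]) == ["G"]

    def test_sorted_by_de_p_fdr(self):
        rec = pd.concat([_records("G1", [-0.9, -0.9, -0.9]),
                         _records("G2", [-0.9, -0.9, -0.9])])
        de = _de(["G1", "G2"])
        de.loc["G1", "p_fdr"] = 0.01
        de.loc["G2", "p_fdr"] = 0.001
        out = tm.select_signature_genes(rec, de)
        assert list(out.genes["gene"]) == ["G2", "G1"]


def test_signature_self_audit(default_run):
    """Every selected gene re-checks against its own records: >=3 CpGs, each
    with passes=True, |rho| >= 0.7 and adjusted p <= 0.05."""
    sel = default_run.selection
    assert not sel.genes.empty
    recs = sel.records.set_index(["gene", "probe_id"])
    for _, row in sel.genes.iterrows():
        assert row["n_cpgs"] >= 3
        for cpg in row["cpgs"]:
            rec = recs.loc[(row["gene"], cpg)]
            assert bool(rec["passes"])
            assert abs(rec["rho"]) >= 0.7
            assert rec["p_corr"] <= 0.05


def test_multi_gene_probe_contributes_record_per_gene(small_run):
    dup = small_run.candidates["probe_id"].duplicated(keep=False)
    # candidates are unique per (probe, gene)
    assert not small_run.candidates.duplicated(["probe_id", "gene"]).any()
    assert len(small_run.records) == len(small_run.candidates)
    _ = dup
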