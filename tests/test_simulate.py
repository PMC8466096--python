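"""Generator contracts: determinism, planted-truth recovery, round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import twinmeth as tm
from twinmeth.simulate import build_sample_sheet, generate_manifest

from conftest import small_config


@pytest.mark.parametrize(
    "field,overrides",
    [
        ("n_probes", {"n_probes": 0}),
        ("planted_delta_beta", {"planted_delta_beta": 0.2}),
        ("planted_delta_beta", {"planted_delta_beta": 0.9}),
        ("target_abs_rho", {"target_abs_rho": 0.5}),
        ("cpgs_per_signature_gene", {"cpgs_per_signature_gene": 2}),
        ("hyper_fraction", {"hyper_fraction": 1.5}),
        ("beta_precision", {"beta_precision": 0.0}),
        ("n_probes", {"n_probes": 50, "n_signature_genes": 30}),
    ],
)
def test_invalid_config_names_field(field, overrides):
    cfg = small_config(**overrides)
    with pytest.raises(tm.SimulationConfigError, match=field):
        cfg.validate()


def test_signature_probes_forced_by_construction():
    cfg = small_config(n_signature_genes=5, cpgs_per_signature_gene=3)
    manifest, truth = generate_manifest(cfg)
    gene_linked = truth.probes[(truth.probes["is_signature"]) & (truth.probes["gene"] != "")]
    assert len(gene_linked) == 15
    assert gene_linked["gene"].value_counts().eq(3).all()
    # every signature probe's gene appears in its manifest annotation
    by_probe = manifest.set_index("IlmnID")
    for pid, row in gene_linked.iterrows():
        assert row["gene"] in str(by_probe.loc[pid, "UCSC_RefGene_Name"]).split(";")


def test_manifest_deterministic_and_positions_increasing(tmp_path):
    cfg = small_config()
    m1, _ = generate_manifest(cfg)
    m2, _ = generate_manifest(cfg)
    pd.testing.assert_frame_equal(m1, m2)
    p1, p2 = tmp_path / "m1.csv", tmp_path / "m2.csv"
    m1.to_csv(p1, index=False)
    m2.to_csv(p2, index=False)
    assert p1.read_bytes() == p2.read_bytes()
    for _, grp in m1.groupby("CHR"):
        pos = grp["MAPINFO"].to_numpy()
        assert (np.diff(pos) > 0).all()
        assert pos.min() >= 1


def test_composition_probes_never_signature():
    _, truth = generate_manifest(small_config())
    both = truth.probes["is_signature"] & truth.probes["is_composition_confounded"]
    assert not both.any()


def test_noise_free_limit_recovers_planted_delta():
    cfg = small_config(beta_precision=1e6, planted_delta_beta=0.4)
    ds = tm.simulate_dataset(cfg)
    cond = dict(zip(ds.samples["sample_id"], ds.samples["condition"]))
    diag = [s for s in ds.beta.columns if cond[s] == "diagnosis"]
    rem = [s for s in ds.beta.columns if cond[s] == "remission"]
    sig = ds.truth.signature_probes()
    gap = (ds.beta.loc[sig, diag].mean(axis=1) - ds.beta.loc[sig, rem].mean(axis=1)).abs()
    assert (gap - 0.4).abs().max() <= 0.02


def test_hyper_fraction_one_forces_hyper():
    ds = tm.simulate_dataset(small_config(hyper_fraction=1.0))
    sig = ds.truth.probes[ds.truth.probes["is_signature"]]
    assert (sig["direction"] == "hyper").all()


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_planted_probes_pass_twin_contrast(seed):
    """Planted CpGs show a twin-contrast |delta-beta| >= 0.3 nearly always."""
    ds = tm.simulate_dataset(small_config(seed=seed, planted_delta_beta=0.45))
    sig = ds.truth.signature_probes()
    delta = (ds.beta.loc[sig, "S1"] - ds.beta.loc[sig, "S2"]).abs()
    assert (delta >= 0.3).mean() >= 0.9


def test_noise_free_counts_recover_log2fc():
    """With vanishing count noise the mean signature log2FC approaches 6."""
    cfg = small_config(
        nb_dispersion=1e-9,
        target_abs_rho=1.0,
        beta_precision=1e5,
        hyper_fraction=1.0,
        positive_correlation_gene_fraction=0.0,
        expr_residual_sd=0.01,
        expr_subject_sd=0.01,
    )
    ds = tm.simulate_dataset(cfg)
    pairs = tm.expr_pairs(ds.samples)
    factors = tm.size_factors(ds.counts)
    norm = tm.normalize_log2(ds.counts, factors, pseudocount=0.5)
    sig = ds.truth.signature_genes()
    fc = np.mean(
        [
            np.mean([norm.loc[g, d] - norm.loc[g, r] for d, r in pairs])
            for g in sig
        ]
    )
    # hyper + negative correlation sign => downregulated at diagnosis
    assert abs(fc - (-6.0)) <= 0.2


def test_negative_link_sign_in_noise_free_limit():
    cfg = small_config(
        nb_dispersion=1e-9,
        target_abs_rho=1.0,
        beta_precision=1e5,
        hyper_fraction=1.0,
        positive_correlation_gene_fraction=0.0,
        expr_residual_sd=0.01,
        expr_subject_sd=0.01,
    )
    ds = tm.simulate_dataset(cfg)
    run = __import__("conftest").run_stages(ds)
    sig_genes = set(ds.truth.signature_genes())
    sub = run.records[run.records["gene"].isin(sig_genes)]
    assert len(sub) > 0
    assert (sub["rho"] < 0).all()


def test_rho_calibration_on_full_study():
    """At the default target |rho| = 0.9, >=80% of signature-gene CpGs reach
    |rho| >= 0.7 over the six DNA+RNA samples."""
    ds = tm.simulate_dataset(tm.SimulationConfig(seed=7))
    run = __import__("conftest").run_stages(ds)
    sig_genes = set(ds.truth.signature_genes())
    sub = run.records[run.records["gene"].isin(sig_genes)]
    assert len(sub) >= 0.8 * 30 * 4  # most planted CpG-gene pairs survive to here
    assert (sub["rho"].abs() >= 0.7).mean() >= 0.8


def test_dataset_roundtrip_and_determinism(tmp_path, small_dataset):
    d1 = tmp_path / "one"
    d2 = tmp_path / "two"
    tm.write_dataset(small_dataset, str(d1))
    tm.write_dataset(small_dataset, str(d2))
    for name in ("beta.tsv", "counts.tsv", "manifest.csv", "samples.csv", "truth.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    back = tm.read_dataset(str(d1))
    pd.testing.assert_frame_equal(back.beta, small_dataset.beta)
    pd.testing.assert_frame_equal(back.counts, small_dataset.counts)
    pd.testing.assert_frame_equal(back.manifest, small_dataset.manifest)
    pd.testing.assert_frame_equal(
        back.samples.reset_index(drop=True), small_dataset.samples.reset_index(drop=True)
    )
    pd.testing.assert_frame_equal(
        back.truth.probes, small_dataset.truth.probes, check_dtype=False
    )
    pd.testing.assert_frame_equal(
        back.truth.genes, small_dataset.truth.genes, check_dtype=False
    )
    assert back.config == small_dataset.config


def test_write_empty_dataset_refused(tmp_path, small_dataset):
    import dataclasses

    empty = dataclasses.replace(small_dataset, beta=small_dataset.beta.iloc[:0])
    target = tmp_path / "empty"
    with pytest.raises(tm.InputError):
        tm.write_dataset(empty, str(target))
    assert not target.exists() or not any(target.iterdir())


def test_sample_sheet_structure():
    sheet = build_sample_sheet(small_config())
    assert list(sheet["sample_id"][:5]) == ["S1", "S2", "S3", "S4", "S5"]
    assert (sheet.loc[sheet["condition"] == "ref_cd34"].shape[0]) >= 3
    assert (sheet.loc[sheet["condition"] == "ref_cd19"].shape[0]) >= 3
    # expression-only pair carries RNA but no methylation
    a4 = sheet[sheet["pair_id"] == "A4"]
    assert (~a4["has_methylation"]).all() and a4["has_expression"].all()
    assert tm.meth_pairs(sheet) == [("A1_d", "A1_r"), ("A2_d", "A2_r"), ("A3_d", "A3_r")]
    assert len(tm.expr_pairs(sheet)) == 4


def test_missing_expression_samples_is_error(small_dataset):
    truncated = small_dataset.samples[small_dataset.samples["pair_id"] != "A4"]
    with pytest.raises(tm.InputError, match="expression"):
        tm.simulate_counts(
            small_dataset.config, small_dataset.truth, small_dataset.beta, truncated
        )
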