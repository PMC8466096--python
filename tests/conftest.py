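from __future__ import annotations

from types import SimpleNamespace

import pytest

import twinmeth as tm


def small_config(**overrides) -> tm.SimulationConfig:
    """A reduced study: same structure, fewer probes/genes, fast to simulate."""
    kwargs = dict(
        n_probes=2_000,
        n_genes=400,
        n_signature_genes=10,
        cpgs_per_signature_gene=4,
        n_extra_dm_probes=60,
        n_composition_probes=60,
        n_background_de_genes=30,
        n_composition_host_genes=20,
        seed=11,
    )
    kwargs.update(overrides)
    return tm.SimulationConfig(**kwargs)


def run_stages(ds: tm.Dataset) -> SimpleNamespace:
    """Run the analysis chain in memory on a simulated dataset."""
    twin = tm.twin_delta_filter(ds.beta, "S1", "S2", "S3")
    rep = tm.paired_t_test(ds.beta, tm.meth_pairs(ds.samples))
    replicated = tm.replicate_intersect(twin, rep)
    de, norm, factors = tm.run_de(ds.counts, tm.expr_pairs(ds.samples))
    manifest_long = tm.manifest_annotations(ds.manifest)
    candidates = tm.build_candidates(replicated.probes, manifest_long, de)
    dna_rna = [
        s for d, r in tm.expr_pairs(ds.samples) for s in (d, r) if s in ds.beta.columns
    ]
    if candidates.empty:
        records = candidates.assign(rho=[], p_value=[], p_corr=[], degenerate=[])
        selection = None
    else:
        records = tm.correlate_cpg_gene(ds.beta, norm, candidates, dna_rna)
        selection = tm.select_signature_genes(records, de)
    return SimpleNamespace(
        dataset=ds,
        twin=twin,
        paired_t=rep,
        replicated=replicated,
        de=de,
        norm=norm,
        factors=factors,
        manifest_long=manifest_long,
        candidates=candidates,
        records=records,
        selection=selection,
        dna_rna_samples=dna_rna,
    )


@pytest.fixture(scope="session")
def small_dataset() -> tm.Dataset:
    return tm.simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_run(small_dataset) -> SimpleNamespace:
    return run_stages(small_dataset)


@pytest.fixture(scope="session")
def default_dataset() -> tm.Dataset:
    """Full-size study conditions (20k probes, 30 signature genes), seed 1."""
    return tm.simulate_dataset(tm.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_dataset) -> SimpleNamespace:
    return run_stages(default_dataset)
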