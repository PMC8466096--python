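"""End-to-end orchestration: simulate/load -> filter -> replicate -> annotate
-> DE -> correlate -> signature -> QC, with a machine-readable run report.

Configuration is a single YAML/JSON mapping with a strict schema (unknown
keys are errors, protecting against silent threshold typos).  Top-level
sections:

``simulate``
    :class:`~twinmeth.simulate.SimulationConfig` fields; mutually exclusive
    with ``inputs``.
``inputs``
    paths ``beta``, ``counts``, ``manifest``, ``samples`` (and optionally
    ``truth``) of an existing dataset.
``thresholds``
    analysis parameters; see :data:`DEFAULT_THRESHOLDS`.
``roles``
    sample-role overrides (``proband``, ``twin``, ``remission``,
    ``parents``, ``healthy_refs``); by default derived from the sample sheet.
``external_de``
    path to a precomputed DE table (gene, log2fc, p_fdr) used verbatim.
``seed``
    overrides ``simulate.seed``.

Every stage writes its table under the output directory, so any downstream
stage can be resumed from disk; the run report mirrors the stage-by-stage
counts of the analysis chain.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import qc
from .annotation import gene_region_counts, manifest_annotations, region_fraction
from .correlation import build_candidates, correlate_cpg_gene, select_signature_genes
from .expression import load_external_de, run_de
from .filtering import twin_delta_filter
from .io import (
    InputError,
    ensure_dir,
    read_beta,
    read_counts,
    read_manifest,
    read_samples,
)
from .replication import paired_t_test, replicate_intersect
from .simulate import (
    Dataset,
    SimulationConfig,
    Truth,
    expr_pairs,
    meth_pairs,
    read_dataset,
    simulate_dataset,
    write_dataset,
)

logger = logging.getLogger("twinmeth")


class ConfigError(ValueError):
    """Raised when the run configuration violates its schema."""


DEFAULT_THRESHOLDS: dict[str, Any] = {
    "delta_min": 0.30,
    "delta_max_healthy": 0.10,
    "effect_min": 0.30,
    "rep_alpha": None,
    "de_alpha": 0.05,
    "pseudocount": 1.0,
    "min_cpgs": 3,
    "rho_min": 0.7,
    "corr_alpha": 0.05,
    "require_rho": True,
    "require_pcorr": True,
    "parental_tolerance": 0.10,
    "linkage": "complete",
}

_TOP_KEYS = {"simulate", "inputs", "thresholds", "roles", "external_de", "seed"}
_INPUT_KEYS = {"beta", "counts", "manifest", "samples", "truth"}
_ROLE_KEYS = {"proband", "twin", "remission", "parents", "healthy_refs"}


def configure_logging(level: str = "INFO", logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile, mode="w"))
    root = logging.getLogger("twinmeth")
    root.setLevel(getattr(logging, level.upper()))
    root.handlers = handlers
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for h in handlers:
        h.setFormatter(fmt)


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ConfigError("exactly one of 'simulate' and 'inputs' is required")
    if "simulate" in cfg:
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(cfg["simulate"] or {}) - sim_fields
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    if "inputs" in cfg:
        inputs = cfg["inputs"] or {}
        unknown = set(inputs) - _INPUT_KEYS
        if unknown:
            raise ConfigError(f"unknown inputs keys: {sorted(unknown)}")
        missing = {"beta", "counts", "manifest", "samples"} - set(inputs)
        if missing:
            raise ConfigError(f"missing inputs: {sorted(missing)}")
    unknown = set(cfg.get("thresholds") or {}) - set(DEFAULT_THRESHOLDS)
    if unknown:
        raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
    unknown = set(cfg.get("roles") or {}) - _ROLE_KEYS
    if unknown:
        raise ConfigError(f"unknown role keys: {sorted(unknown)}")
    return cfg


@dataclass
class RunReport:
    """Stage-by-stage counts of one pipeline run."""

    n_probes_input: int = 0
    n_twin_filtered: int = 0
    n_twin_hyper: int = 0
    n_twin_hypo: int = 0
    n_twin_excluded_missing: int = 0
    n_replicated: int = 0
    n_replicated_hyper: int = 0
    n_replicated_hypo: int = 0
    n_genes_annotated: int = 0
    n_gene_region_pairs: int = 0
    n_de_genes: int = 0
    n_de_up: int = 0
    n_de_down: int = 0
    n_overlap_genes: int = 0
    n_signature_genes: int = 0
    n_signature_cpgs: int = 0
    promoter_fraction: float | None = None
    cluster_purity: float | None = None
    pc1_explained: float | None = None
    parental_fraction_comparable: float | None = None
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def validate(self) -> "RunReport":
        checks = [
            self.n_replicated <= self.n_twin_filtered,
            self.n_signature_genes <= self.n_overlap_genes <= self.n_de_genes,
            self.n_twin_hyper <= self.n_twin_filtered,
            self.n_replicated_hyper <= self.n_replicated,
        ]
        if not all(checks):
            raise AssertionError(f"run report violates monotonicity invariants: {self}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _derive_roles(samples: pd.DataFrame, roles_cfg: dict | None) -> dict:
    roles_cfg = roles_cfg or {}
    trio = samples[samples["pair_id"] == ""]

    def single(condition: str) -> str:
        found = trio.loc[trio["condition"] == condition, "sample_id"]
        if len(found) != 1:
            raise InputError(
                f"cannot derive the {condition!r} trio sample: found {list(found)}"
            )
        return found.iloc[0]

    roles = {
        "proband": roles_cfg.get("proband") or single("diagnosis"),
        "twin": roles_cfg.get("twin") or single("healthy"),
        "remission": roles_cfg.get("remission") or single("remission"),
        "parents": roles_cfg.get("parents")
        or list(samples.loc[samples["condition"] == "parent", "sample_id"]),
    }
    default_refs = list(
        samples.loc[
            samples["condition"].isin(["healthy", "remission"])
            & (samples["sample_id"] != roles["remission"])
            & samples["has_methylation"],
            "sample_id",
        ]
    ) + [roles["remission"], ]
    roles["healthy_refs"] = roles_cfg.get("healthy_refs") or sorted(set(default_refs))
    return roles


def _load_dataset(cfg: dict, outdir: str) -> Dataset:
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        if cfg.get("seed") is not None:
            sim_kwargs["seed"] = int(cfg["seed"])
        dataset = simulate_dataset(SimulationConfig(**sim_kwargs))
        write_dataset(dataset, os.path.join(outdir, "dataset"))
        return dataset
    inputs = cfg["inputs"]
    truth = None
    if inputs.get("truth"):
        with open(inputs["truth"]) as fh:
            payload = json.load(fh)
        payload.pop("config", None)
        truth = Truth.from_dict(payload)
    return Dataset(
        config=None,
        manifest=read_manifest(inputs["manifest"]),
        beta=read_beta(inputs["beta"]),
        counts=read_counts(inputs["counts"]),
        samples=read_samples(inputs["samples"]),
        truth=truth,
    )


def run_all(cfg: dict, outdir: str) -> tuple[RunReport, "PipelineState"]:
    """Execute every stage; write intermediate tables and the run report."""
    cfg = validate_config(cfg)
    ensure_dir(outdir)
    thresholds = dict(DEFAULT_THRESHOLDS, **(cfg.get("thresholds") or {}))
    state = PipelineState(outdir=outdir, thresholds=thresholds)

    stage = "load"
    try:
        dataset = _load_dataset(cfg, outdir)
        state.dataset = dataset
        roles = _derive_roles(dataset.samples, cfg.get("roles"))
        state.roles = roles
        logger.info(
            "loaded dataset: %d probes, %d genes, %d samples",
            len(dataset.beta),
            len(dataset.counts),
            len(dataset.samples),
        )

        stage = "filter-twin"
        twin = twin_delta_filter(
            dataset.beta,
            roles["proband"],
            roles["twin"],
            roles["remission"],
            delta_min=thresholds["delta_min"],
            delta_max_healthy=thresholds["delta_max_healthy"],
        )
        state.twin = twin
        twin.table.to_csv(os.path.join(outdir, "twin_filter.tsv"), sep="\t")
        dirs = twin.direction_counts()
        logger.info(
            "twin filter: %d/%d CpGs retained (%d hyper, %d hypo)",
            len(twin.retained_probes),
            len(twin.table),
            dirs["hyper"],
            dirs["hypo"],
        )

        stage = "replicate"
        mpairs = meth_pairs(dataset.samples)
        rep = paired_t_test(dataset.beta, mpairs)
        replicated = replicate_intersect(
            twin,
            rep,
            effect_min=thresholds["effect_min"],
            alpha=thresholds["rep_alpha"],
        )
        state.paired_t = rep
        state.replicated = replicated
        rep.table.to_csv(os.path.join(outdir, "paired_t.tsv"), sep="\t")
        replicated.table.to_csv(os.path.join(outdir, "replicated.tsv"), sep="\t")
        logger.info(
            "replication: %d CpGs (%d hyper, %d hypo) over %d pairs",
            len(replicated.probes),
            replicated.n_hyper,
            replicated.n_hypo,
            len(mpairs),
        )

        stage = "annotate"
        manifest_long = manifest_annotations(dataset.manifest)
        counts_ann = gene_region_counts(replicated.probes, dataset.manifest) if (
            replicated.probes
        ) else {"n_genes": 0, "n_gene_region_pairs": 0, "n_unannotated_probes": 0}
        state.manifest_long = manifest_long
        logger.info(
            "annotation: %d distinct genes, %d (gene, region) pairs",
            counts_ann["n_genes"],
            counts_ann["n_gene_region_pairs"],
        )

        stage = "de"
        epairs = expr_pairs(dataset.samples)
        if cfg.get("external_de"):
            de = load_external_de(cfg["external_de"], alpha=thresholds["de_alpha"])
            # Normalized expression is still needed for the correlation stage.
            _, norm, _ = run_de(
                dataset.counts, epairs, alpha=thresholds["de_alpha"],
                pseudocount=thresholds["pseudocount"],
            )
        else:
            de, norm, _ = run_de(
                dataset.counts,
                epairs,
                alpha=thresholds["de_alpha"],
                pseudocount=thresholds["pseudocount"],
            )
        state.de = de
        state.norm_expr = norm
        de.to_csv(os.path.join(outdir, "de.tsv"), sep="\t")
        ranked = de.sort_values("log2fc", ascending=False)["log2fc"]
        ranked.to_csv(os.path.join(outdir, "ranked_genes.rnk"), sep="\t", header=False)
        n_sig_de = int(de["significant"].sum())
        n_up = int((de["significant"] & (de["log2fc"] > 0)).sum())
        logger.info("differential expression: %d genes (up %d, down %d)",
                    n_sig_de, n_up, n_sig_de - n_up)

        stage = "correlate"
        candidates = build_candidates(replicated.probes, manifest_long, de)
        dna_rna_samples = [
            s
            for d, r in epairs
            for s in (d, r)
            if s in dataset.beta.columns
        ]
        if candidates.empty:
            records = pd.DataFrame(
                columns=[
                    "probe_id", "gene", "region", "rho", "p_value", "p_corr",
                    "n_samples", "degenerate",
                ]
            )
        else:
            records = correlate_cpg_gene(dataset.beta, norm, candidates, dna_rna_samples)
        state.correlation_samples = dna_rna_samples
        records.to_csv(os.path.join(outdir, "correlation.tsv"), sep="\t", index=False)

        stage = "signature"
        if records.empty:
            selection = select_signature_genes(
                pd.DataFrame(
                    {
                        "probe_id": pd.Series(dtype=str),
                        "gene": pd.Series(dtype=str),
                        "rho": pd.Series(dtype=float),
                        "p_value": pd.Series(dtype=float),
                        "p_corr": pd.Series(dtype=float),
                        "degenerate": pd.Series(dtype=bool),
                    }
                ),
                de,
                min_cpgs=thresholds["min_cpgs"],
                rho_min=thresholds["rho_min"],
                alpha=thresholds["corr_alpha"],
            )
        else:
            selection = select_signature_genes(
                records,
                de,
                min_cpgs=thresholds["min_cpgs"],
                rho_min=thresholds["rho_min"],
                alpha=thresholds["corr_alpha"],
                require_rho=thresholds["require_rho"],
                require_pcorr=thresholds["require_pcorr"],
            )
        state.selection = selection
        sig_out = selection.genes.copy()
        sig_out["cpgs"] = sig_out["cpgs"].map(";".join)
        sig_out.to_csv(os.path.join(outdir, "signature_genes.tsv"), sep="\t", index=False)
        logger.info(
            "signature: %d genes, %d CpGs",
            len(selection.genes),
            len(selection.signature_cpgs),
        )

        stage = "qc"
        qc_summary = _run_qc(state, dataset, roles, replicated.probes, thresholds)
        state.qc = qc_summary

        stage = "report"
        overlap = _overlap_genes(replicated.probes, manifest_long, de)
        sig_cpgs = selection.signature_cpgs
        promoter = (
            region_fraction(sig_cpgs, dataset.manifest).fraction if sig_cpgs else None
        )
        report = RunReport(
            n_probes_input=len(dataset.beta),
            n_twin_filtered=len(twin.retained_probes),
            n_twin_hyper=dirs["hyper"],
            n_twin_hypo=dirs["hypo"],
            n_twin_excluded_missing=twin.n_excluded_missing,
            n_replicated=len(replicated.probes),
            n_replicated_hyper=replicated.n_hyper,
            n_replicated_hypo=replicated.n_hypo,
            n_genes_annotated=counts_ann["n_genes"],
            n_gene_region_pairs=counts_ann["n_gene_region_pairs"],
            n_de_genes=n_sig_de,
            n_de_up=n_up,
            n_de_down=n_sig_de - n_up,
            n_overlap_genes=len(overlap),
            n_signature_genes=len(selection.genes),
            n_signature_cpgs=len(sig_cpgs),
            promoter_fraction=promoter,
            cluster_purity=qc_summary.get("cluster_purity"),
            pc1_explained=qc_summary.get("pc1_explained"),
            parental_fraction_comparable=qc_summary.get("parental_fraction_comparable"),
            parameters={"thresholds": thresholds, "roles": roles,
                        "config": _jsonable(cfg)},
            seed=cfg.get("seed", (cfg.get("simulate") or {}).get("seed")),
        ).validate()
        with open(os.path.join(outdir, "run_report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        return report, state
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        marker = os.path.join(outdir, "FAILED")
        with open(marker, "w") as fh:
            fh.write(f"{stage}: {exc}\n")
        if isinstance(exc, StageFailure):
            raise
        raise StageFailure(stage, exc) from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _overlap_genes(
    replicated_probes: list[str], manifest_long: pd.DataFrame, de: pd.DataFrame
) -> set[str]:
    meth_genes = set(
        manifest_long.loc[
            manifest_long["probe_id"].isin(set(replicated_probes)), "gene"
        ]
    )
    return meth_genes & set(de.index[de["significant"]])


def _run_qc(state, dataset, roles, replicated_probes, thresholds) -> dict:
    samples = dataset.samples
    meth_ids = samples.loc[samples["has_methylation"], "sample_id"]
    cond = dict(zip(samples["sample_id"], samples["condition"]))

    # Distance clustering: family + paired samples + CD34 references.
    cluster_ids = [
        s
        for s in meth_ids
        if cond[s] in ("diagnosis", "remission", "healthy", "ref_cd34")
    ]
    labels = {
        s: ("leukemic" if cond[s] == "diagnosis" else "non-leukemic")
        for s in cluster_ids
    }
    out: dict[str, Any] = {}
    if len(cluster_ids) >= 2:
        dist = qc.distance_matrix(dataset.beta, cluster_ids)
        dist.to_csv(os.path.join(state.outdir, "distance_matrix.tsv"), sep="\t")
        cl = qc.cluster_and_purity(dist, labels, method=thresholds["linkage"])
        out["cluster_purity"] = cl.purity
        out["cluster_assignments"] = cl.assignments
        logger.info("qc: two-cluster purity %.3f", cl.purity)

    # Targeted PCA on the replicated CpGs with both reference cell types.
    pca_ids = [
        s
        for s in meth_ids
        if cond[s] in ("diagnosis", "remission", "healthy", "ref_cd34", "ref_cd19")
    ]
    if len(replicated_probes) >= 2 and len(pca_ids) >= 2:
        pca = qc.pca_top_sites(dataset.beta, replicated_probes, pca_ids)
        pca.scores.to_csv(os.path.join(state.outdir, "pca_scores.tsv"), sep="\t")
        out["pca_scores"] = pca.scores
        out["pc1_explained"] = (
            float(pca.explained_variance_fraction[0]) if not pca.degenerate else None
        )

    # Parents vs healthy references at the signature CpGs.
    sig_cpgs = state.selection.signature_cpgs
    if sig_cpgs and roles["parents"]:
        pc = qc.parental_check(
            sig_cpgs,
            dataset.beta,
            roles["parents"],
            roles["healthy_refs"],
            tolerance=thresholds["parental_tolerance"],
        )
        out["parental_fraction_comparable"] = pc.fraction_comparable
        logger.info("qc: parental comparability %.3f", pc.fraction_comparable)
    return out


@dataclass
class PipelineState:
    """In-memory results of a run, for tests and the summary stage."""

    outdir: str
    thresholds: dict
    dataset: Dataset | None = None
    roles: dict | None = None
    twin: Any = None
    paired_t: Any = None
    replicated: Any = None
    manifest_long: pd.DataFrame | None = None
    de: pd.DataFrame | None = None
    norm_expr: pd.DataFrame | None = None
    correlation_samples: list[str] | None = None
    selection: Any = None
    qc: dict | None = None


def summarize(state: PipelineState, outdir: str | None = None) -> dict[str, pd.DataFrame]:
    """Per-signature-gene panels: CpG beta values and expression across pairs.

    Each panel holds one row per CpG and a final ``expression`` row, with one
    column per DNA+RNA sample plus ``rho`` and ``p_corr``; the data behind a
    per-gene diagnosis-vs-remission methylation/expression figure.
    """
    selection = state.selection
    outdir = outdir or os.path.join(state.outdir, "panels")
    panels: dict[str, pd.DataFrame] = {}
    if selection is None or selection.genes.empty:
        logger.info("summary: zero signature genes")
        return panels
    ensure_dir(outdir)
    samples = state.correlation_samples
    records = selection.records.set_index(["gene", "probe_id"])
    for _, row in selection.genes.iterrows():
        gene = row["gene"]
        if gene not in state.norm_expr.index:
            raise InputError(f"gene {gene!r} absent from the expression matrix")
        panel = state.dataset.beta.loc[row["cpgs"], samples].copy()
        panel["rho"] = [records.loc[(gene, c), "rho"] for c in row["cpgs"]]
        panel["p_corr"] = [records.loc[(gene, c), "p_corr"] for c in row["cpgs"]]
        expr_row = state.norm_expr.loc[gene, samples]
        panel.loc["expression", samples] = expr_row
        panels[gene] = panel
        panel.to_csv(os.path.join(outdir, f"{gene}.tsv"), sep="\t")
    return panels


def summarize_from_dir(run_dir: str, outdir: str | None = None) -> dict[str, pd.DataFrame]:
    """Rebuild the summary panels from the files a finished run wrote.

    Reads the run report for the resolved configuration, reloads the dataset
    and stage tables from disk, and regenerates the panels; the result equals
    the in-memory summary of the original run.
    """
    with open(os.path.join(run_dir, "run_report.json")) as fh:
        report = json.load(fh)
    cfg = report["parameters"]["config"]
    thresholds = report["parameters"]["thresholds"]
    if "simulate" in cfg:
        dataset = read_dataset(os.path.join(run_dir, "dataset"))
    else:
        dataset = _load_dataset(cfg, run_dir)

    de = pd.read_csv(os.path.join(run_dir, "de.tsv"), sep="\t", index_col=0)
    records = pd.read_csv(os.path.join(run_dir, "correlation.tsv"), sep="\t")
    epairs = expr_pairs(dataset.samples)
    _, norm, _ = run_de(
        dataset.counts, epairs, alpha=thresholds["de_alpha"],
        pseudocount=thresholds["pseudocount"],
    )
    selection = select_signature_genes(
        records,
        de,
        min_cpgs=thresholds["min_cpgs"],
        rho_min=thresholds["rho_min"],
        alpha=thresholds["corr_alpha"],
        require_rho=thresholds["require_rho"],
        require_pcorr=thresholds["require_pcorr"],
    )
    state = PipelineState(outdir=run_dir, thresholds=thresholds)
    state.dataset = dataset
    state.de = de
    state.norm_expr = norm
    state.selection = selection
    state.correlation_samples = [
        s for d, r in epairs for s in (d, r) if s in dataset.beta.columns
    ]
    return summarize(state, outdir)
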