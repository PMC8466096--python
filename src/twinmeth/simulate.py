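"""Synthetic twin-trio methylome + diagnosis-remission transcriptome generator.

Emulates the study design the downstream analysis assumes: a discordant
monozygotic twin trio (proband at diagnosis S1, healthy twin S2, proband at
remission S3) with parents (S4, S5), independent diagnosis-remission patient
pairs with 450K-style methylation and RNA counts, one extra pair with
expression only, and non-leukemic reference cell profiles (CD34+, CD19+).

Planted structure, all recorded in a :class:`Truth` table:

* signature genes, each carrying a fixed number of CpGs whose beta values are
  shifted by ``planted_delta_beta`` in diagnosis samples (hypermethylated with
  probability ``hyper_fraction``), with expression tied to promoter
  methylation so that per-CpG |Pearson rho| meets ``target_abs_rho``;
* additional disease-linked differentially methylated CpGs not tied to
  expression (real replicated sets are far larger than the signature);
* cell-composition-confounded CpGs, shifted in every blast-rich sample
  (diagnosis samples and reference cells alike) but annotated to genes whose
  expression is methylation-independent, so the expression-correlation stage
  must remove them;
* background differentially expressed genes that are methylation-independent.

Beta noise is beta-distributed (mean/precision parameterization), counts are
negative binomial.  Expression noise for signature genes is split into a
subject-level component (shared by both samples of a pair, so it dilutes the
cross-sample correlation without touching paired log2 fold changes) plus a
residual, calibrated so realized per-CpG |rho| over the DNA+RNA samples meets
the target in expectation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    InputError,
    ensure_dir,
    read_beta,
    read_counts,
    read_manifest,
    read_samples,
    write_beta,
    write_counts,
    write_manifest,
    write_samples,
)

logger = logging.getLogger("twinmeth.simulate")

PROMOTER_REGIONS = ("TSS1500", "TSS200")
NON_PROMOTER_REGIONS = ("5'UTR", "1stExon", "Body", "3'UTR")
LOG2E_SQ = math.log2(math.e) ** 2


class SimulationConfigError(ValueError):
    """A simulation configuration field violates its invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions exercised by the test suite:
    20,000 probes, 30 signature genes x 4 CpGs with planted |delta-beta| 0.45
    (85.5% hypermethylated), |log2FC| 6 and target |rho| 0.9, three
    diagnosis-remission pairs with both assays plus one expression-only pair.
    """

    n_probes: int = 20_000
    n_genes: int = 2_000
    n_signature_genes: int = 30
    cpgs_per_signature_gene: int = 4
    n_pairs: int = 3
    n_expr_only_pairs: int = 1
    planted_delta_beta: float = 0.45
    hyper_fraction: float = 0.855
    n_composition_probes: int = 300
    beta_precision: float = 200.0
    nb_dispersion: float = 0.05
    planted_abs_log2fc: float = 6.0
    target_abs_rho: float = 0.9
    positive_correlation_gene_fraction: float = 0.10
    seed: int = 0
    # Secondary structure (disease CpGs beyond the signature, methylation-
    # independent DE genes, composition-offset size, annotation texture).
    n_extra_dm_probes: int = 500
    n_background_de_genes: int = 150
    n_composition_host_genes: int = 50
    composition_delta_low: float = 0.20
    composition_delta_high: float = 0.30
    multi_gene_fraction: float = 0.10
    promoter_signature_fraction: float = 0.65
    annotated_fraction: float = 0.75
    n_ref_per_type: int = 3
    expr_residual_sd: float = 0.25
    expr_subject_sd: float = 0.30

    def validate(self) -> "SimulationConfig":
        c = self
        for name in ("n_probes", "n_genes", "cpgs_per_signature_gene", "n_pairs"):
            if getattr(c, name) <= 0:
                raise SimulationConfigError(f"{name} must be positive")
        for name in (
            "n_signature_genes",
            "n_expr_only_pairs",
            "n_composition_probes",
            "n_extra_dm_probes",
            "n_background_de_genes",
        ):
            if getattr(c, name) < 0:
                raise SimulationConfigError(f"{name} must be non-negative")
        if c.n_pairs < 2:
            raise SimulationConfigError("n_pairs: at least 2 pairs are required")
        if c.cpgs_per_signature_gene < 3:
            raise SimulationConfigError("cpgs_per_signature_gene must be >= 3")
        if not 0.3 <= c.planted_delta_beta <= 0.85:
            raise SimulationConfigError(
                "planted_delta_beta must lie in [0.3, 0.85]; smaller shifts "
                "cannot pass the twin filter"
            )
        for name in (
            "hyper_fraction",
            "positive_correlation_gene_fraction",
            "multi_gene_fraction",
            "promoter_signature_fraction",
            "annotated_fraction",
        ):
            v = getattr(c, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} must lie in [0, 1]")
        for name in ("beta_precision", "nb_dispersion", "planted_abs_log2fc"):
            if getattr(c, name) <= 0:
                raise SimulationConfigError(f"{name} must be positive")
        if not 0.7 < c.target_abs_rho <= 1.0:
            raise SimulationConfigError("target_abs_rho must lie in (0.7, 1]")
        n_planted = (
            c.n_signature_genes * c.cpgs_per_signature_gene
            + c.n_extra_dm_probes
            + c.n_composition_probes
        )
        if n_planted > c.n_probes:
            raise SimulationConfigError(
                "n_probes: planted probes "
                f"({n_planted}) exceed n_probes ({c.n_probes})"
            )
        n_special_genes = (
            c.n_signature_genes + c.n_background_de_genes + c.n_composition_host_genes
        )
        if n_special_genes > c.n_genes:
            raise SimulationConfigError(
                f"n_genes: special genes ({n_special_genes}) exceed n_genes"
            )
        if not 0 <= c.composition_delta_low <= c.composition_delta_high <= 1:
            raise SimulationConfigError("composition_delta_low/high must be ordered in [0, 1]")
        if c.n_ref_per_type < 3:
            raise SimulationConfigError("n_ref_per_type must be >= 3")
        return c


@dataclass
class Truth:
    """Planted ground truth: per-probe and per-gene labels.

    ``probes`` is indexed by probe id with columns ``is_signature``,
    ``direction`` (hyper|hypo, empty until assigned), ``gene`` (empty for
    disease CpGs not tied to a signature gene) and
    ``is_composition_confounded``.  ``genes`` is indexed by gene symbol with
    ``is_signature``, ``correlation_sign`` (+|-), ``true_log2fc`` and
    ``is_background_de``.
    """

    probes: pd.DataFrame
    genes: pd.DataFrame

    def signature_probes(self) -> list[str]:
        return list(self.probes.index[self.probes["is_signature"]])

    def signature_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_signature"]])

    def composition_probes(self) -> list[str]:
        return list(self.probes.index[self.probes["is_composition_confounded"]])

    def to_dict(self) -> dict:
        return {
            "probes": {
                pid: {
                    "is_signature": bool(row.is_signature),
                    "direction": row.direction or None,
                    "gene": row.gene or None,
                    "is_composition_confounded": bool(row.is_composition_confounded),
                }
                for pid, row in self.probes.iterrows()
            },
            "genes": {
                g: {
                    "is_signature": bool(row.is_signature),
                    "correlation_sign": row.correlation_sign or None,
                    "true_log2fc": float(row.true_log2fc),
                    "is_background_de": bool(row.is_background_de),
                }
                for g, row in self.genes.iterrows()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Truth":
        probes = pd.DataFrame.from_dict(d["probes"], orient="index")
        probes["direction"] = probes["direction"].fillna("")
        probes["gene"] = probes["gene"].fillna("")
        probes = probes[["is_signature", "direction", "gene", "is_composition_confounded"]]
        genes = pd.DataFrame.from_dict(d["genes"], orient="index")
        genes["correlation_sign"] = genes["correlation_sign"].fillna("")
        genes = genes[["is_signature", "correlation_sign", "true_log2fc", "is_background_de"]]
        probes.index.name = "probe_id"
        genes.index.name = "gene"
        return cls(probes=probes, genes=genes)


@dataclass
class Dataset:
    """A complete simulated dataset."""

    config: SimulationConfig
    manifest: pd.DataFrame
    beta: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: Truth


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


def generate_manifest(config: SimulationConfig) -> tuple[pd.DataFrame, Truth]:
    """Build a 450K-style manifest plus the truth-table skeleton.

    Positions are 1-based and strictly increasing per chromosome.  Signature
    CpGs are placed in promoter regions (TSS1500/TSS200) for
    ``promoter_signature_fraction`` of probes; composition-confounded probes
    are annotated to dedicated host genes that are never differentially
    expressed; a ``multi_gene_fraction`` of annotated probes carry a second
    gene.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_probes
    probe_ids = _probe_ids(n)
    gene_ids = _gene_ids(config.n_genes)

    # Gene roles: disjoint signature / background-DE / composition-host sets.
    perm_genes = rng.permutation(config.n_genes)
    k1 = config.n_signature_genes
    k2 = k1 + config.n_background_de_genes
    k3 = k2 + config.n_composition_host_genes
    sig_genes = [gene_ids[i] for i in perm_genes[:k1]]
    bg_genes = [gene_ids[i] for i in perm_genes[k1:k2]]
    comp_genes = [gene_ids[i] for i in perm_genes[k2:k3]]
    plain_genes = [gene_ids[i] for i in perm_genes[k3:]]

    # Probe roles.
    n_sig = config.n_signature_genes * config.cpgs_per_signature_gene
    perm = rng.permutation(n)
    sig_idx = perm[:n_sig]
    extra_idx = perm[n_sig : n_sig + config.n_extra_dm_probes]
    comp_idx = perm[
        n_sig
        + config.n_extra_dm_probes : n_sig
        + config.n_extra_dm_probes
        + config.n_composition_probes
    ]
    special = set(sig_idx) | set(extra_idx) | set(comp_idx)

    # Genomic coordinates: chromosome then strictly increasing positions.
    chrom = rng.integers(1, 23, size=n)
    position = np.empty(n, dtype=int)
    for c in range(1, 23):
        mask = chrom == c
        gaps = rng.integers(100, 10_000, size=int(mask.sum()))
        position[mask] = np.cumsum(gaps)

    genes_col = [""] * n
    groups_col = [""] * n

    # Signature probes: fixed CpG count per gene, mostly promoter.
    for j, idx in enumerate(sig_idx):
        gene = sig_genes[j // config.cpgs_per_signature_gene]
        if rng.random() < config.promoter_signature_fraction:
            region = "TSS1500" if rng.random() < 2 / 3 else "TSS200"
        else:
            region = str(rng.choice(NON_PROMOTER_REGIONS))
        genes_col[idx], groups_col[idx] = gene, region

    # Extra disease probes: annotated to plain (never-DE) genes.
    for idx in extra_idx:
        genes_col[idx] = str(rng.choice(plain_genes))
        groups_col[idx] = str(rng.choice(NON_PROMOTER_REGIONS + PROMOTER_REGIONS))

    # Composition probes: annotated to methylation-independent host genes.
    for idx in comp_idx:
        genes_col[idx] = str(rng.choice(comp_genes))
        groups_col[idx] = str(rng.choice(NON_PROMOTER_REGIONS + PROMOTER_REGIONS))

    # Remaining probes: background annotation texture.
    all_regions = PROMOTER_REGIONS + NON_PROMOTER_REGIONS
    annotatable_genes = bg_genes + plain_genes
    for idx in range(n):
        if idx in special:
            continue
        if rng.random() < config.annotated_fraction:
            g1 = str(rng.choice(annotatable_genes))
            r1 = str(rng.choice(all_regions))
            if rng.random() < config.multi_gene_fraction:
                g2 = g1
                while g2 == g1:
                    g2 = str(rng.choice(annotatable_genes))
                genes_col[idx] = f"{g1};{g2}"
                groups_col[idx] = f"{r1};{rng.choice(all_regions)}"
            else:
                genes_col[idx], groups_col[idx] = g1, r1

    manifest = pd.DataFrame(
        {
            "IlmnID": probe_ids,
            "CHR": [str(c) for c in chrom],
            "MAPINFO": position,
            "UCSC_RefGene_Name": genes_col,
            "UCSC_RefGene_Group": groups_col,
        }
    )

    probes = pd.DataFrame(
        {
            "is_signature": False,
            "direction": "",
            "gene": "",
            "is_composition_confounded": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    probes.iloc[sig_idx, probes.columns.get_loc("is_signature")] = True
    probes.iloc[extra_idx, probes.columns.get_loc("is_signature")] = True
    probes.iloc[comp_idx, probes.columns.get_loc("is_composition_confounded")] = True
    for j, idx in enumerate(sig_idx):
        probes.iloc[idx, probes.columns.get_loc("gene")] = sig_genes[
            j // config.cpgs_per_signature_gene
        ]

    genes = pd.DataFrame(
        {
            "is_signature": False,
            "correlation_sign": "",
            "true_log2fc": 0.0,
            "is_background_de": False,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    genes.loc[sig_genes, "is_signature"] = True
    genes.loc[bg_genes, "is_background_de"] = True

    return manifest, Truth(probes=probes, genes=genes)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def build_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        ("S1", "TWIN1", "diagnosis", "", True, False),
        ("S2", "TWIN2", "healthy", "", True, False),
        ("S3", "TWIN1", "remission", "", True, False),
        ("S4", "MOTHER", "parent", "", True, False),
        ("S5", "FATHER", "parent", "", True, False),
    ]
    n_all_pairs = config.n_pairs + config.n_expr_only_pairs
    for i in range(1, n_all_pairs + 1):
        has_meth = i <= config.n_pairs
        rows.append((f"A{i}_d", f"A{i}", "diagnosis", f"A{i}", has_meth, True))
        rows.append((f"A{i}_r", f"A{i}", "remission", f"A{i}", has_meth, True))
    for i in range(1, config.n_ref_per_type + 1):
        rows.append((f"CD34_{i}", f"CB{i}", "ref_cd34", "", True, False))
        rows.append((f"CD19_{i}", f"AD{i}", "ref_cd19", "", True, False))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "subject_id",
            "condition",
            "pair_id",
            "has_methylation",
            "has_expression",
        ],
    )


def meth_pairs(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """Diagnosis-remission sample-id pairs that carry methylation."""
    return _pairs(samples, "has_methylation")


def expr_pairs(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """Diagnosis-remission sample-id pairs that carry expression."""
    return _pairs(samples, "has_expression")


def _pairs(samples: pd.DataFrame, flag: str) -> list[tuple[str, str]]:
    out = []
    paired = samples[(samples["pair_id"] != "") & samples[flag]]
    for pid, grp in paired.groupby("pair_id", sort=True):
        d = grp.loc[grp["condition"] == "diagnosis", "sample_id"]
        r = grp.loc[grp["condition"] == "remission", "sample_id"]
        if len(d) == 1 and len(r) == 1:
            out.append((d.iloc[0], r.iloc[0]))
    return out


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    config: SimulationConfig, manifest: pd.DataFrame, truth: Truth
) -> tuple[pd.DataFrame, pd.DataFrame, Truth]:
    """Draw the beta matrix and complete the truth table.

    Per-probe healthy baselines come from a bimodal (low/high) mixture as on
    real arrays; each observed beta is Beta-distributed around its mean with
    precision ``beta_precision``.  Signature probes are shifted by
    +-``planted_delta_beta`` in diagnosis samples only; composition probes are
    shifted in every blast-rich sample (diagnosis and reference cells).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 22])
    samples = build_sample_sheet(config)
    meth_samples = samples[samples["has_methylation"]]
    sample_ids = list(meth_samples["sample_id"])
    probe_ids = list(manifest["IlmnID"])
    n = len(probe_ids)

    truth = Truth(probes=truth.probes.copy(), genes=truth.genes.copy())
    probes_t, genes_t = truth.probes, truth.genes

    # Planted directions: one direction per signature gene (its CpGs move
    # together, as a promoter does); gene-free disease CpGs draw independently.
    sig_genes = truth.signature_genes()
    gene_dir = {
        g: ("hyper" if rng.random() < config.hyper_fraction else "hypo")
        for g in sorted(sig_genes)
    }
    gene_sign = {
        g: ("+" if rng.random() < config.positive_correlation_gene_fraction else "-")
        for g in sorted(sig_genes)
    }
    for g in sorted(sig_genes):
        d = 1.0 if gene_dir[g] == "hyper" else -1.0
        c = 1.0 if gene_sign[g] == "+" else -1.0
        genes_t.loc[g, "correlation_sign"] = gene_sign[g]
        genes_t.loc[g, "true_log2fc"] = c * d * config.planted_abs_log2fc
    bg = genes_t.index[genes_t["is_background_de"]]
    genes_t.loc[bg, "true_log2fc"] = rng.choice([-1.0, 1.0], size=len(bg)) * rng.uniform(
        1.5, 8.0, size=len(bg)
    )

    is_sig = probes_t["is_signature"].to_numpy()
    has_gene = (probes_t["gene"] != "").to_numpy()
    directions = np.array([""] * n, dtype=object)
    gene_linked = is_sig & has_gene
    directions[gene_linked] = [gene_dir[g] for g in probes_t.loc[gene_linked, "gene"]]
    free = is_sig & ~has_gene
    directions[free] = np.where(
        rng.random(int(free.sum())) < config.hyper_fraction, "hyper", "hypo"
    )
    probes_t["direction"] = directions

    # Healthy baselines: bimodal for unplanted probes; planted probes start
    # from the side that leaves room for the shift.
    baseline = np.where(
        rng.random(n) < 0.55,
        rng.uniform(0.03, 0.25, size=n),
        rng.uniform(0.70, 0.97, size=n),
    )
    hyper = directions == "hyper"
    hypo = directions == "hypo"
    baseline[hyper] = rng.uniform(0.10, 0.35, size=int(hyper.sum()))
    baseline[hypo] = rng.uniform(0.65, 0.90, size=int(hypo.sum()))

    is_comp = probes_t["is_composition_confounded"].to_numpy()
    n_comp = int(is_comp.sum())
    comp_off = rng.uniform(
        config.composition_delta_low, config.composition_delta_high, size=n_comp
    ) * rng.choice([-1.0, 1.0], size=n_comp)
    baseline[is_comp] = np.where(
        comp_off > 0,
        rng.uniform(0.15, 0.50, size=n_comp),
        rng.uniform(0.50, 0.85, size=n_comp),
    )

    disease_shift = np.zeros(n)
    disease_shift[hyper] = config.planted_delta_beta
    disease_shift[hypo] = -config.planted_delta_beta

    cond = dict(zip(meth_samples["sample_id"], meth_samples["condition"]))
    pair_of = dict(zip(meth_samples["sample_id"], meth_samples["pair_id"]))
    mean = np.tile(baseline[:, None], (1, len(sample_ids)))
    u34 = rng.uniform(0.5, 1.0, size=n_comp)
    u19 = rng.uniform(0.5, 1.0, size=n_comp)
    for j, sid in enumerate(sample_ids):
        c = cond[sid]
        blastlike = c == "diagnosis"
        if blastlike:
            mean[:, j] += disease_shift
            mean[is_comp, j] += comp_off
        elif c == "ref_cd34":
            mean[is_comp, j] += comp_off * u34
        elif c == "ref_cd19":
            mean[is_comp, j] += comp_off * u19

    clipped = (mean <= 0.0) | (mean >= 1.0)
    if clipped.any():
        logger.warning(
            "%d planted probe means fell outside (0, 1) and were clipped",
            int(clipped.sum()),
        )
    mean = np.clip(mean, 0.005, 0.995)
    phi = config.beta_precision
    beta = rng.beta(mean * phi, (1.0 - mean) * phi)
    beta = np.clip(beta, 0.001, 0.999)
    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    _ = pair_of  # pairing used by downstream helpers via the sample sheet
    return beta_df, samples, truth


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def _calibrated_subject_sd(config: SimulationConfig, base_log2_mean: np.ndarray) -> np.ndarray:
    """Per-gene extra subject-level log2 noise SD hitting the rho target.

    For a balanced diagnosis/remission design the expected correlation between
    a CpG's beta and log2 expression is
    ``rho = 1 / sqrt((1 + qx)(1 + qy))`` with ``qx`` the beta noise-to-signal
    variance ratio and ``qy`` its expression counterpart.  The beta side is
    fixed by ``beta_precision``; the expression side is met by adding
    subject-level noise on top of the residual and count (negative binomial)
    noise already present.
    """
    s_x = config.planted_delta_beta / 2.0
    sd_b = math.sqrt(0.2 * 0.8 / (1.0 + config.beta_precision))
    qx = (sd_b / s_x) ** 2
    qy = 1.0 / (config.target_abs_rho**2 * (1.0 + qx)) - 1.0
    target_var = max(qy, 0.0) * (config.planted_abs_log2fc / 2.0) ** 2
    mu_low = np.maximum(2.0 ** (base_log2_mean - config.planted_abs_log2fc / 2.0), 1.0)
    nb_var = LOG2E_SQ * (config.nb_dispersion + 1.0 / mu_low)
    extra = target_var - config.expr_residual_sd**2 - config.expr_subject_sd**2 - nb_var
    return np.sqrt(np.maximum(extra, 0.0))


def simulate_counts(
    config: SimulationConfig,
    truth: Truth,
    beta: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Draw negative-binomial gene counts for the expression-bearing pairs.

    Signature-gene log2 means follow the realized mean beta of the gene's
    CpGs (slope ``+-planted_abs_log2fc / planted_delta_beta``, sign from the
    gene's correlation sign), so methylation and expression are mechanistically
    linked in the DNA+RNA pairs; expression-only pairs receive the
    condition-level effect directly.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 33])
    expr = samples[samples["has_expression"]]
    pairs = expr_pairs(samples)
    if len(pairs) != config.n_pairs + config.n_expr_only_pairs:
        raise InputError(
            "sample sheet is missing expression samples: expected "
            f"{config.n_pairs + config.n_expr_only_pairs} pairs, found {len(pairs)}"
        )
    sample_ids = [s for d, r in pairs for s in (d, r)]
    missing = set(sample_ids) - set(expr["sample_id"])
    if missing:
        raise InputError(f"missing expression samples: {sorted(missing)}")
    cond = dict(zip(samples["sample_id"], samples["condition"]))
    subj = dict(zip(samples["sample_id"], samples["subject_id"]))

    genes = list(truth.genes.index)
    n_g, n_s = len(genes), len(sample_ids)
    gidx = {g: i for i, g in enumerate(genes)}

    # Base log2 means: ~3 orders of magnitude overall; planted DE genes start
    # high enough that the down condition keeps nonzero counts.
    base = rng.uniform(3.0, 13.0, size=n_g)
    sig_mask = truth.genes["is_signature"].to_numpy()
    bg_mask = truth.genes["is_background_de"].to_numpy()
    base[sig_mask] = rng.uniform(6.0, 12.0, size=int(sig_mask.sum()))
    base[bg_mask] = rng.uniform(5.0, 12.0, size=int(bg_mask.sum()))

    y = np.tile(base[:, None], (1, n_s))

    # Subject-level noise (shared within a pair) + per-sample residual.
    subjects = sorted({subj[s] for s in sample_ids})
    extra_sd = _calibrated_subject_sd(config, base)
    subj_noise = rng.normal(0.0, config.expr_subject_sd, size=(n_g, len(subjects)))
    extra_noise = rng.normal(0.0, 1.0, size=(n_g, len(subjects))) * extra_sd[:, None]
    sj = {s: i for i, s in enumerate(subjects)}
    for j, sid in enumerate(sample_ids):
        y[:, j] += subj_noise[:, sj[subj[sid]]]
        y[sig_mask, j] += extra_noise[sig_mask, sj[subj[sid]]]
    y += rng.normal(0.0, config.expr_residual_sd, size=(n_g, n_s))

    # Background DE genes: condition effect, methylation-independent.
    half_fc = truth.genes["true_log2fc"].to_numpy() / 2.0
    for j, sid in enumerate(sample_ids):
        s = 1.0 if cond[sid] == "diagnosis" else -1.0
        y[bg_mask, j] += s * half_fc[bg_mask]

    # Signature genes: expression follows promoter methylation in the DNA+RNA
    # pairs, and the condition effect directly in expression-only pairs.
    probe_gene = truth.probes.loc[truth.probes["is_signature"], "gene"]
    meth_sample_set = set(beta.columns)
    for g in truth.signature_genes():
        cpgs = list(probe_gene.index[probe_gene == g])
        c = 1.0 if truth.genes.loc[g, "correlation_sign"] == "+" else -1.0
        d = 1.0 if truth.probes.loc[cpgs[0], "direction"] == "hyper" else -1.0
        slope = c * config.planted_abs_log2fc / config.planted_delta_beta
        linked = [s for s in sample_ids if s in meth_sample_set]
        if linked:
            bbar = beta.loc[cpgs, linked].mean(axis=0)
            center = float(bbar.mean())
            for sid in linked:
                y[gidx[g], sample_ids.index(sid)] += slope * (bbar[sid] - center)
        for sid in sample_ids:
            if sid not in meth_sample_set:
                s = 1.0 if cond[sid] == "diagnosis" else -1.0
                y[gidx[g], sample_ids.index(sid)] += (
                    s * c * d * config.planted_abs_log2fc / 2.0
                )

    depth = rng.uniform(0.6, 1.6, size=n_s)
    mu = np.maximum(2.0**y * depth[None, :], 1e-8)
    alpha = config.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / alpha
        counts = rng.negative_binomial(size, size / (size + mu))
    return pd.DataFrame(
        counts.astype(np.int64), index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )


# ---------------------------------------------------------------------------
# Dataset assembly + I/O
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> Dataset:
    """Generate a full dataset (manifest, beta, counts, samples, truth)."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    config.validate()
    manifest, truth = generate_manifest(config)
    beta, samples, truth = simulate_methylation(config, manifest, truth)
    counts = simulate_counts(config, truth, beta, samples)
    return Dataset(
        config=config, manifest=manifest, beta=beta, counts=counts, samples=samples, truth=truth
    )


def write_dataset(dataset: Dataset, directory: str) -> dict[str, str]:
    """Write beta.tsv, counts.tsv, manifest.csv, samples.csv, truth.json."""
    if dataset.beta.empty or dataset.manifest.empty:
        raise InputError("refusing to write an empty dataset")
    ensure_dir(directory)
    paths = {
        "beta": os.path.join(directory, "beta.tsv"),
        "counts": os.path.join(directory, "counts.tsv"),
        "manifest": os.path.join(directory, "manifest.csv"),
        "samples": os.path.join(directory, "samples.csv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    write_beta(dataset.beta, paths["beta"])
    write_counts(dataset.counts, paths["counts"])
    write_manifest(dataset.manifest, paths["manifest"])
    write_samples(dataset.samples, paths["samples"])
    payload = dataset.truth.to_dict()
    payload["config"] = dataclasses.asdict(dataset.config)
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return paths


def read_dataset(directory: str) -> Dataset:
    """Round-trip counterpart of :func:`write_dataset`."""
    with open(os.path.join(directory, "truth.json")) as fh:
        payload = json.load(fh)
    config = SimulationConfig(**payload.pop("config"))
    truth = Truth.from_dict(payload)
    beta = read_beta(os.path.join(directory, "beta.tsv"))
    counts = read_counts(os.path.join(directory, "counts.tsv"))
    manifest = read_manifest(os.path.join(directory, "manifest.csv"))
    samples = read_samples(os.path.join(directory, "samples.csv"))
    # Restore the generator's index/column ordering contracts.
    truth.probes = truth.probes.loc[manifest["IlmnID"]]
    truth.genes = truth.genes.sort_index()
    genes = _gene_ids(config.n_genes)
    if set(genes) == set(truth.genes.index):
        truth.genes = truth.genes.loc[genes]
    return Dataset(
        config=config, manifest=manifest, beta=beta, counts=counts, samples=samples, truth=truth
    )
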