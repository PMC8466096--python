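"""Probe-to-gene annotation and promoter-region accounting.

The manifest follows the Illumina 450K dialect: ``UCSC_RefGene_Name`` and
``UCSC_RefGene_Group`` are parallel semicolon-joined lists, so a probe can be
annotated to several genes and region categories.  "Promoter" means TSS1500
or TSS200 (within 1500 bp / 200 bp upstream of the transcription start site).
Manifest coordinates are 1-based; any internal interval arithmetic would use
0-based half-open and convert at I/O, but annotation itself is a pure lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io import InputError

PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200"})


def manifest_annotations(manifest: pd.DataFrame) -> pd.DataFrame:
    """Explode the manifest into a long (probe_id, gene, region) table.

    Duplicate (gene, region) entries for a probe are dropped; probes with no
    annotation do not appear.
    """
    rows: list[tuple[str, str, str]] = []
    for pid, names, groups in zip(
        manifest["IlmnID"], manifest["UCSC_RefGene_Name"], manifest["UCSC_RefGene_Group"]
    ):
        if not names:
            continue
        genes = str(names).split(";")
        regions = str(groups).split(";")
        if len(genes) != len(regions):
            raise InputError(
                f"probe {pid}: UCSC_RefGene_Name and UCSC_RefGene_Group lengths differ"
            )
        seen = set()
        for g, r in zip(genes, regions):
            if g and (g, r) not in seen:
                seen.add((g, r))
                rows.append((pid, g, r))
    long = pd.DataFrame(rows, columns=["probe_id", "gene", "region"])
    return long


@dataclass
class AnnotationResult:
    """Probe -> [(gene, region), ...] mapping with unannotated bookkeeping."""

    mapping: dict[str, list[tuple[str, str]]]
    n_unannotated: int

    def distinct_genes(self) -> set[str]:
        return {g for pairs in self.mapping.values() for g, _ in pairs}

    def distinct_gene_regions(self) -> set[tuple[str, str]]:
        return {gr for pairs in self.mapping.values() for gr in pairs}


def annotate_probes(probes: Iterable[str], manifest: pd.DataFrame) -> AnnotationResult:
    """Look up every probe's (gene, region) annotations in the manifest.

    Every input probe is present as a key; probes absent from the manifest or
    without gene annotation map to an empty list and are counted.
    """
    probes = list(probes)
    long = manifest_annotations(manifest)
    grouped: dict[str, list[tuple[str, str]]] = {}
    for pid, g, r in long.itertuples(index=False):
        grouped.setdefault(pid, []).append((g, r))
    mapping = {p: grouped.get(p, []) for p in probes}
    n_unannotated = sum(1 for p in probes if not mapping[p])
    return AnnotationResult(mapping=mapping, n_unannotated=n_unannotated)


@dataclass
class RegionFraction:
    fraction: float
    numerator: int
    denominator: int


def region_fraction(
    probes: Iterable[str],
    manifest: pd.DataFrame,
    regions: Iterable[str] = PROMOTER_REGIONS,
) -> RegionFraction:
    """Fraction of probes with at least one annotation in ``regions``.

    With the default region set this is the promoter fraction
    (TSS1500 or TSS200).
    """
    probes = list(probes)
    if not probes:
        raise InputError("empty probe set")
    regions = set(regions)
    ann = annotate_probes(probes, manifest)
    num = sum(
        1 for p in probes if any(r in regions for _, r in ann.mapping[p])
    )
    return RegionFraction(fraction=num / len(probes), numerator=num, denominator=len(probes))


def gene_region_counts(probes: Iterable[str], manifest: pd.DataFrame) -> dict[str, int]:
    """Distinct gene symbols and distinct (gene, region) pairs hit by probes.

    Both counts are reported because "gene regions" can mean either; neither
    is asserted over the other.
    """
    ann = annotate_probes(probes, manifest)
    return {
        "n_genes": len(ann.distinct_genes()),
        "n_gene_region_pairs": len(ann.distinct_gene_regions()),
        "n_unannotated_probes": ann.n_unannotated,
    }
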