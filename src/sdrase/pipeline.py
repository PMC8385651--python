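"""End-to-end orchestration: observations -> genotypes -> ASE -> association.

Thin joins over the stage modules so the CLI, tests and scripts share one
code path.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import alleles, ase
from .alleles import GenotypeCall, SiteObservation
from .regions import GeneAnnotation, assign_gene


@dataclass
class ASEThresholds:
    """Every knob of the ASE chain in one place (echoed to logs/reports)."""

    min_phred: float = 15.0
    min_dna_depth: int = 20
    het_band: tuple[float, float] = (0.2, 0.8)
    hom_error_rate: float = 0.01
    mono_threshold: float = 0.9
    min_cdna_depth: int = 20
    min_sites: int = 2
    site_agreement: float = 0.8
    alpha: float = 0.05
    bonferroni: bool = False


def call_dna_genotypes(
    observations: Sequence[SiteObservation],
    thresholds: ASEThresholds = ASEThresholds(),
) -> list[GenotypeCall]:
    """Quality-filter DNA observations and genotype each site x individual."""
    dna = [o for o in observations if o.material == "DNA"]
    dna = alleles.filter_by_quality(dna, thresholds.min_phred)
    return [
        alleles.call_genotype_dna(
            o,
            min_depth=thresholds.min_dna_depth,
            het_band=thresholds.het_band,
            error_rate=thresholds.hom_error_rate,
        )
        for o in dna
    ]


def classify_cohort_sites(
    observations: Sequence[SiteObservation],
    dna_calls: Sequence[GenotypeCall],
    thresholds: ASEThresholds = ASEThresholds(),
) -> list[ase.SiteASE]:
    """Join cDNA observations to heterozygous DNA calls and classify."""
    het = {
        (c.site, c.sample_id): c for c in dna_calls if c.call == "het"
    }
    cdna = alleles.filter_by_quality(
        [o for o in observations if o.material == "cDNA"], thresholds.min_phred
    )
    out = []
    for o in cdna:
        call = het.get((o.site, o.sample_id))
        if call is None:
            continue  # site not heterozygous in this individual's DNA
        out.append(
            ase.classify_site_rna(
                o, call, thresholds.mono_threshold, thresholds.min_cdna_depth
            )
        )
    return out


def aggregate_cohort(
    site_calls: Sequence[ase.SiteASE],
    genes: Sequence[GeneAnnotation],
    sex_of: Mapping[str, str],
    thresholds: ASEThresholds = ASEThresholds(),
) -> list[ase.ASECall]:
    """Gene x individual verdicts for every individual with informative sites."""
    grouped: dict[tuple[str, str], list[ase.SiteASE]] = defaultdict(list)
    for c in site_calls:
        gene = assign_gene(c.site.pos - 1, c.site.chrom, genes)
        if gene is None:
            continue
        grouped[(gene, c.sample_id)].append(c)
    return [
        ase.aggregate_gene(
            calls,
            gene_id=gene,
            individual_id=ind,
            sex=sex_of.get(ind),  # type: ignore[arg-type]
            min_sites=thresholds.min_sites,
            site_agreement=thresholds.site_agreement,
        )
        for (gene, ind), calls in sorted(grouped.items())
    ]


def associate_by_gene(
    gene_calls: Sequence[ase.ASECall],
    thresholds: ASEThresholds = ASEThresholds(),
) -> list[ase.SexAssociationResult]:
    """Per-gene Fisher sex association, optional Bonferroni over the panel."""
    by_gene: dict[str, list[ase.ASECall]] = defaultdict(list)
    for c in gene_calls:
        by_gene[c.gene_id].append(c)
    alpha = thresholds.alpha
    if thresholds.bonferroni and by_gene:
        alpha = alpha / len(by_gene)
    return [
        ase.sex_association(calls, alpha=alpha)
        for _gene, calls in sorted(by_gene.items())
    ]


def run_ase_analysis(
    observations: Sequence[SiteObservation],
    genes: Sequence[GeneAnnotation],
    sex_of: Mapping[str, str],
    thresholds: ASEThresholds = ASEThresholds(),
) -> tuple[list[ase.SexAssociationResult], list[ase.ASECall], list[ase.SiteASE]]:
    """The full cohort ASE chain; returns (associations, gene calls, site calls)."""
    dna_calls = call_dna_genotypes(observations, thresholds)
    site_calls = classify_cohort_sites(observations, dna_calls, thresholds)
    gene_calls = aggregate_cohort(site_calls, genes, sex_of, thresholds)
    return associate_by_gene(gene_calls, thresholds), gene_calls, site_calls


def gene_call_table(calls: Sequence[ase.ASECall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": c.gene_id,
            "individual_id": c.individual_id,
            "sex": c.sex,
            "class": c.gene_class,
            "n_informative_sites": c.n_informative_sites,
            "n_tissues_consistent": c.n_tissues_consistent,
        }
        for c in calls
    )


def site_call_table(calls: Sequence[ase.SiteASE]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": c.site.chrom,
            "pos": c.site.pos,
            "ref": c.site.ref,
            "alt": c.site.alt,
            "individual_id": c.sample_id,
            "tissue": c.tissue,
            "class": c.site_class,
            "cdna_fraction": c.cdna_fraction,
        }
        for c in calls
    )
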