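"""Allele-specific expression calls and the cohort-level sex association.

At every site called heterozygous from DNA, the cDNA alternative-allele
fraction classifies the site as biallelic (both alleles transcribed) or
monoallelic (one allele dominates, fraction >= 0.9 or <= 0.1 by default).
Site calls are aggregated to a gene x individual verdict requiring
cross-tissue consistency, and a one-sided Fisher exact test on the
sex x {monoallelic, biallelic} 2x2 table formalizes sex association —
the pattern in which males of a dioecious XY species silence the Y copy
of an SDR gene (the CLC pattern in poplar) while females express both
alleles.

Phase is not required: a gene counts as monoallelic when each informative
site is individually monoallelic, without asking the dominant alleles to
lie on one haplotype.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .alleles import GenotypeCall, SiteObservation, Site
from .regions import GeneAnnotation, assign_gene

SiteClass = Literal["biallelic", "monoallelic_ref", "monoallelic_alt", "undetermined"]
GeneClass = Literal["biallelic", "monoallelic", "undetermined"]
Sex = Literal["male", "female"]
AssociationLabel = Literal["male_associated_ASE", "female_associated_ASE", "none"]


@dataclass(frozen=True)
class SiteASE:
    site: Site
    sample_id: str
    tissue: str | None
    site_class: SiteClass
    cdna_fraction: float | None


@dataclass(frozen=True)
class ASECall:
    gene_id: str
    individual_id: str
    sex: Sex | None
    gene_class: GeneClass
    n_informative_sites: int
    n_tissues_consistent: int


@dataclass(frozen=True)
class SexAssociationResult:
    gene_id: str
    n_male_mono: int
    n_male_bi: int
    n_female_mono: int
    n_female_bi: int
    p_value: float  # NaN when no determined individuals exist
    label: AssociationLabel


class JoinError(ValueError):
    """DNA call and cDNA observation do not refer to the same site/individual."""


def classify_site_rna(
    obs: SiteObservation,
    dna_call: GenotypeCall,
    mono_threshold: float = 0.9,
    min_depth: int = 20,
) -> SiteASE:
    """Classify allelic expression at one DNA-heterozygous site.

    monoallelic_alt when the cDNA alternative fraction >= ``mono_threshold``,
    monoallelic_ref when <= 1 - ``mono_threshold``, biallelic in between;
    undetermined below ``min_depth``.  Only sites heterozygous in DNA are
    informative.
    """
    if obs.site != dna_call.site or obs.sample_id != dna_call.sample_id:
        raise JoinError(
            f"cDNA observation ({obs.site}, {obs.sample_id}) does not match "
            f"DNA call ({dna_call.site}, {dna_call.sample_id})"
        )
    if obs.material != "cDNA":
        raise ValueError(f"expected cDNA observation, got {obs.material}")
    if dna_call.call != "het":
        raise ValueError("site classification requires a heterozygous DNA call")
    total = obs.total_depth
    if total < min_depth:
        return SiteASE(obs.site, obs.sample_id, obs.tissue, "undetermined", None)
    frac = obs.alt_depth / total
    if frac >= mono_threshold:
        cls: SiteClass = "monoallelic_alt"
    elif frac <= 1.0 - mono_threshold:
        cls = "monoallelic_ref"
    else:
        cls = "biallelic"
    return SiteASE(obs.site, obs.sample_id, obs.tissue, cls, frac)


def aggregate_gene(
    site_calls: Sequence[SiteASE],
    gene_id: str,
    individual_id: str,
    sex: Sex | None = None,
    min_sites: int = 2,
    site_agreement: float = 0.8,
) -> ASECall:
    """Aggregate site calls for one gene x individual across tissues.

    A tissue is monoallelic-consistent when >= ``site_agreement`` of its
    informative sites are monoallelic (either direction), and similarly for
    biallelic.  The gene verdict is monoallelic (biallelic) only when every
    tissue holding informative sites agrees; disagreeing tissues, or fewer
    than ``min_sites`` informative site calls overall, give undetermined.
    """
    informative = [c for c in site_calls if c.site_class != "undetermined"]
    n_informative = len(informative)
    if n_informative < min_sites:
        return ASECall(gene_id, individual_id, sex, "undetermined", n_informative, 0)

    by_tissue: dict[str | None, list[SiteASE]] = defaultdict(list)
    for c in informative:
        by_tissue[c.tissue].append(c)

    tissue_verdicts: list[GeneClass] = []
    for calls in by_tissue.values():
        n_mono = sum(c.site_class.startswith("monoallelic") for c in calls)
        n_bi = sum(c.site_class == "biallelic" for c in calls)
        n = len(calls)
        if n_mono / n >= site_agreement:
            tissue_verdicts.append("monoallelic")
        elif n_bi / n >= site_agreement:
            tissue_verdicts.append("biallelic")
        else:
            tissue_verdicts.append("undetermined")

    if all(v == "monoallelic" for v in tissue_verdicts):
        gene_class: GeneClass = "monoallelic"
    elif all(v == "biallelic" for v in tissue_verdicts):
        gene_class = "biallelic"
    else:
        gene_class = "undetermined"
    n_consistent = sum(v == gene_class for v in tissue_verdicts)
    return ASECall(gene_id, individual_id, sex, gene_class, n_informative, n_consistent)


def sex_association(
    ase_calls: Sequence[ASECall], alpha: float = 0.05
) -> SexAssociationResult:
    """One-sided Fisher exact test of monoallelic expression against sex.

    Undetermined individuals are excluded from the 2x2 table.  The test is
    directed toward the sex with the larger monoallelic proportion (males on
    a tie) since direction is part of the claim; the label is assigned only
    when p < ``alpha``.  With no determined individuals at all the p-value
    is NaN and the label ``none``.
    """
    if not ase_calls:
        raise ValueError("no ASE calls supplied")
    gene_ids = {c.gene_id for c in ase_calls}
    if len(gene_ids) != 1:
        raise ValueError(f"calls span multiple genes: {sorted(gene_ids)}")
    (gene_id,) = gene_ids
    seen: set[str] = set()
    counts = {("male", "monoallelic"): 0, ("male", "biallelic"): 0,
              ("female", "monoallelic"): 0, ("female", "biallelic"): 0}
    for c in ase_calls:
        if c.individual_id in seen:
            raise ValueError(f"individual {c.individual_id} appears twice")
        seen.add(c.individual_id)
        if c.gene_class == "undetermined" or c.sex is None:
            continue
        counts[(c.sex, c.gene_class)] += 1

    m_mono, m_bi = counts[("male", "monoallelic")], counts[("male", "biallelic")]
    f_mono, f_bi = counts[("female", "monoallelic")], counts[("female", "biallelic")]
    n_det = m_mono + m_bi + f_mono + f_bi
    if n_det == 0:
        return SexAssociationResult(gene_id, 0, 0, 0, 0, math.nan, "none")

    m_prop = m_mono / (m_mono + m_bi) if (m_mono + m_bi) else 0.0
    f_prop = f_mono / (f_mono + f_bi) if (f_mono + f_bi) else 0.0
    toward_male = m_prop >= f_prop
    table = [[m_mono, m_bi], [f_mono, f_bi]]
    alternative = "greater" if toward_male else "less"
    p = float(fisher_exact(table, alternative=alternative)[1])
    label: AssociationLabel = "none"
    if p < alpha:
        label = "male_associated_ASE" if toward_male else "female_associated_ASE"
    return SexAssociationResult(gene_id, m_mono, m_bi, f_mono, f_bi, p, label)


def compare_wgs_rna_het_sites(
    dna_calls: Sequence[GenotypeCall],
    rna_observations: Sequence[SiteObservation],
    genes: Sequence[GeneAnnotation],
    mono_threshold: float = 0.9,
    min_depth: int = 20,
) -> pd.DataFrame:
    """Per-gene, per-tissue concordance of DNA-het sites with cDNA classes.

    The single-individual analysis: for every site heterozygous in the
    individual's genomic data, count how its cDNA depths classify per
    tissue.  Returns columns gene_id, tissue, n_het_sites, n_biallelic,
    n_monoallelic, n_undetermined.
    """
    individuals = {c.sample_id for c in dna_calls} | {
        o.sample_id for o in rna_observations
    }
    if len(individuals) > 1:
        raise ValueError(
            f"single-individual comparison got several individuals: "
            f"{sorted(individuals)}"
        )
    het = {
        (c.site, c.sample_id): c for c in dna_calls if c.call == "het"
    }
    rows: dict[tuple[str, str | None], dict[str, int]] = {}
    counted_sites: dict[tuple[str, str | None], set[Site]] = defaultdict(set)
    for obs in rna_observations:
        key = (obs.site, obs.sample_id)
        if key not in het:
            continue
        gene = assign_gene(obs.site.pos - 1, obs.site.chrom, genes)
        if gene is None:
            continue
        site_ase = classify_site_rna(obs, het[key], mono_threshold, min_depth)
        row = rows.setdefault(
            (gene, obs.tissue),
            {"n_het_sites": 0, "n_biallelic": 0, "n_monoallelic": 0,
             "n_undetermined": 0},
        )
        counted_sites[(gene, obs.tissue)].add(obs.site)
        row["n_het_sites"] = len(counted_sites[(gene, obs.tissue)])
        if site_ase.site_class == "biallelic":
            row["n_biallelic"] += 1
        elif site_ase.site_class == "undetermined":
            row["n_undetermined"] += 1
        else:
            row["n_monoallelic"] += 1
    out = pd.DataFrame(
        [
            {"gene_id": gene, "tissue": tissue, **row}
            for (gene, tissue), row in sorted(
                rows.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
            )
        ],
        columns=[
            "gene_id", "tissue", "n_het_sites", "n_biallelic",
            "n_monoallelic", "n_undetermined",
        ],
    )
    return out


def association_table(results: Iterable[SexAssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": r.gene_id,
            "n_male_mono": r.n_male_mono,
            "n_male_bi": r.n_male_bi,
            "n_female_mono": r.n_female_mono,
            "n_female_bi": r.n_female_bi,
            "p_value": r.p_value,
            "label": r.label,
        }
        for r in results
    )
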