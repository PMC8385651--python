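"""Per-site allele depths, quality filtering, and DNA genotype calls.

The pipeline starts from allele-depth (AD) tables rather than reads: variant
*discovery* is out of scope and every site present in the input VCF is
genotyped from its ref/alt depths.  The site-level Phred QUAL filter mirrors
the upstream variant-candidate filter (candidates with quality < 15 are
discarded).

A DNA genotype is called heterozygous when the alternative-allele fraction
sits in a band around 0.5 ([0.2, 0.8] by default), and homozygous when the
fraction is outside the band *and* an exact binomial test cannot distinguish
the minor-allele count from sequencing error.  Sites failing both rules, or
below the depth floor, are left undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from cyvcf2 import VCF
from scipy.stats import binomtest

Material = Literal["DNA", "cDNA"]
Call = Literal["het", "hom_ref", "hom_alt", "undetermined"]

#: Default minimum Phred site quality (candidates with QUAL < 15 are dropped).
DEFAULT_MIN_PHRED = 15.0


@dataclass(frozen=True, order=True)
class Site:
    chrom: str
    pos: int  # 1-based, as printed in VCF
    ref: str
    alt: str


@dataclass(frozen=True)
class SiteObservation:
    """Ref/alt allele depths for one site in one sample."""

    site: Site
    sample_id: str
    material: Material
    tissue: str | None
    ref_depth: int
    alt_depth: int
    quality: float

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("negative allele depth")
        if self.quality < 0:
            raise ValueError("negative Phred quality")

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth


@dataclass(frozen=True)
class GenotypeCall:
    site: Site
    sample_id: str
    call: Call
    allelic_fraction: float | None
    total_depth: int


class VCFFormatError(ValueError):
    pass


def parse_sample_name(name: str) -> tuple[str, Material, str | None]:
    """Split a ``individual.material.tissue`` sample name.

    The simulator names VCF sample columns this way (e.g.
    ``M03.cDNA.catkin_axes``).  Names not following the convention are
    treated as DNA samples of unknown tissue.
    """
    parts = name.split(".", 2)
    if len(parts) == 3 and parts[1] in ("DNA", "cDNA"):
        return parts[0], parts[1], parts[2]  # type: ignore[return-value]
    return name, "DNA", None


def read_allele_depths(vcf_path: str | Path) -> list[SiteObservation]:
    """Read per-sample allele depths from a VCF with AD FORMAT fields.

    One observation is produced per site x sample x alternative allele;
    multi-allelic records are decomposed into ref-vs-alt pairs, so a third
    allele never contributes to any fraction.  Samples with missing AD at a
    site are skipped.
    """
    vcf = VCF(str(vcf_path))
    samples = [parse_sample_name(s) for s in vcf.samples]
    out: list[SiteObservation] = []
    for variant in vcf:
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise VCFFormatError(
                f"{vcf_path}: record {variant.CHROM}:{variant.POS} lacks AD"
            )
        qual = float(variant.QUAL) if variant.QUAL is not None else 0.0
        for si, (individual, material, tissue) in enumerate(samples):
            depths = ad[si]
            if depths[0] < 0:  # missing AD for this sample
                continue
            for ai, alt in enumerate(variant.ALT, start=1):
                out.append(
                    SiteObservation(
                        site=Site(variant.CHROM, variant.POS, variant.REF, alt),
                        sample_id=individual,
                        material=material,
                        tissue=tissue,
                        ref_depth=int(depths[0]),
                        alt_depth=int(depths[ai]),
                        quality=qual,
                    )
                )
    return out


def filter_by_quality(
    observations: Iterable[SiteObservation], min_phred: float = DEFAULT_MIN_PHRED
) -> list[SiteObservation]:
    """Drop observations whose site quality is strictly below ``min_phred``."""
    return [o for o in observations if o.quality >= min_phred]


def allelic_fraction(obs: SiteObservation) -> float:
    """Alternative-allele depth fraction, alt / (ref + alt)."""
    total = obs.total_depth
    if total == 0:
        raise ValueError(
            f"allelic fraction undefined at zero depth "
            f"({obs.site.chrom}:{obs.site.pos}, sample {obs.sample_id})"
        )
    return obs.alt_depth / total


def call_genotype_dna(
    obs: SiteObservation,
    min_depth: int = 20,
    het_band: Sequence[float] = (0.2, 0.8),
    error_rate: float = 0.01,
    alpha: float = 0.05,
) -> GenotypeCall:
    """Call het/hom/undetermined from DNA allele depths at one site.

    het: fraction within ``het_band`` (operationalizing the expected ~0.5
    genomic fraction at a heterozygous site).  hom: fraction outside the
    band and the minor-allele count consistent with ``error_rate`` under a
    two-sided exact binomial test at level ``alpha``.  Anything else, or
    total depth < ``min_depth``, is undetermined.
    """
    if obs.material != "DNA":
        raise ValueError(f"genotype calling requires DNA depths, got {obs.material}")
    lo, hi = het_band
    total = obs.total_depth
    if total < min_depth:
        return GenotypeCall(obs.site, obs.sample_id, "undetermined", None, total)
    frac = obs.alt_depth / total
    if lo <= frac <= hi:
        return GenotypeCall(obs.site, obs.sample_id, "het", frac, total)
    minor = min(obs.ref_depth, obs.alt_depth)
    p = binomtest(minor, total, error_rate, alternative="two-sided").pvalue
    if p >= alpha:
        call: Call = "hom_alt" if frac > hi else "hom_ref"
    else:
        call = "undetermined"
    return GenotypeCall(obs.site, obs.sample_id, call, frac, total)


def genotype_table(calls: Iterable[GenotypeCall]):
    """Genotype calls as a DataFrame (chrom, pos, ref, alt, sample, call, ...)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": c.site.chrom,
            "pos": c.site.pos,
            "ref": c.site.ref,
            "alt": c.site.alt,
            "sample": c.sample_id,
            "call": c.call,
            "fraction": c.allelic_fraction,
            "depth": c.total_depth,
        }
        for c in calls
    )
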