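"""Synthetic cohort generator with full ground truth.

Emulates the study design of a dioecious XY poplar cohort without any
sequence-level simulation: read sampling is abstracted to allele-depth
draws, which are the sufficient statistic for every downstream stage.

Two designs are generated together:

* a *bulk pair* — one male and one female with WGS (18x male, 26x female
  per-base depth), binned SDR coverage tracks, and bulk
  RNA-seq of three tissues (leaves, catkin axes, flowers; six libraries in
  total) summarized as a gene x library count matrix;
* an *amplicon cohort* — 10 males and 10 females, each with deep targeted
  amplicon sequencing of DNA (from leaves) and cDNA from the three tissues
  (80 samples in total) over the expressed SDR gene panel.

Every individual is heterozygous at every simulated SDR site (the
intersectional-hybrid premise).  Allele depths are drawn as
Poisson(depth) totals with beta-binomial allele counts
(p* = f(1-e) + (1-f)e; intraclass correlation rho, rho = 0 degenerating to
binomial).  A gene's male allelic ratio is controlled by the fraction of
male transcripts originating from the Y-haplotype allele: 0 models complete
Y-allele silencing (the CLC pattern), 0.5 balanced biallelic expression.
Male hemizygosity is modeled as presence/absence of one haplotype per
interval: female WGS depth is zero there and male depth halves.

Randomness uses one global seed with per-draw substreams derived by stable
hashing of (individual, material, tissue, site), so enlarging the cohort
does not perturb existing individuals' data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alleles import Site, SiteObservation
from .expression import CountMatrix
from .hemizygosity import CoverageTrack
from .regions import (
    GeneAnnotation,
    GenomicInterval,
    SDR_BIN_WIDTH,
    SDR_REGION,
    bin_interval,
    build_sdr_genes,
)

TISSUES_DEFAULT = ("leaves", "catkin_axes", "flowers")

#: Default Y-specific (male-hemizygous) interval: 4 kb of intergenic SDR.
DEFAULT_HEMIZYGOUS_REGIONS = (GenomicInterval("Chr18", 16_290_000, 16_294_000),)


@dataclass(frozen=True)
class GeneTruth:
    """Generative truth for one gene.

    ``expr_rate_per_tissue`` is the mean bulk RNA-seq count per library in
    each tissue (0 = silent).  ``y_allele_expression_fraction_male`` is the
    fraction of a male's transcripts carrying the Y-haplotype allele;
    ``allele_fraction_female`` the fraction from the female's first
    haplotype (0.5 = balanced).
    """

    gene_id: str
    expr_rate_per_tissue: Mapping[str, float]
    y_allele_expression_fraction_male: float = 0.5
    allele_fraction_female: float = 0.5

    def __post_init__(self) -> None:
        for frac in (self.y_allele_expression_fraction_male, self.allele_fraction_female):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"allele fraction outside [0,1]: {frac}")
        if any(r < 0 for r in self.expr_rate_per_tissue.values()):
            raise ValueError("negative expression rate")

    def expressed_in(self, tissue: str) -> bool:
        return self.expr_rate_per_tissue.get(tissue, 0.0) > 0

    @property
    def expressed(self) -> bool:
        return any(r > 0 for r in self.expr_rate_per_tissue.values())


def default_gene_truths(
    tissues: Sequence[str] = TISSUES_DEFAULT,
    expressed_rate: float = 200.0,
) -> list[GeneTruth]:
    """The study pattern: TCP/CLC/MET1 transcribed, NB-ARC/unknown silent;
    the CLC-like gene fully Y-silenced in males, the rest balanced."""
    genes = build_sdr_genes()
    by_symbol = {g.symbol: g.gene_id for g in genes}
    expressed = {t: expressed_rate for t in tissues}
    silent = {t: 0.0 for t in tissues}
    return [
        GeneTruth(by_symbol["TCP"], expressed, 0.5),
        GeneTruth(by_symbol["CLC"], expressed, 0.0),
        GeneTruth(by_symbol["MET1"], expressed, 0.5),
        GeneTruth(by_symbol["NB-ARC"], silent),
        GeneTruth(by_symbol["unknown"], silent),
    ]


@dataclass
class TruthConfig:
    """Full generative specification of a synthetic cohort."""

    n_males: int = 10
    n_females: int = 10
    tissues: tuple[str, ...] = TISSUES_DEFAULT
    genes: list[GeneTruth] = field(default_factory=default_gene_truths)
    hemizygous_regions: tuple[GenomicInterval, ...] = DEFAULT_HEMIZYGOUS_REGIONS
    n_het_sites_per_gene: int = 4
    wgs_depth_male: float = 18.0
    wgs_depth_female: float = 26.0
    rna_depth: float = 100.0
    amplicon_depth: float = 2000.0
    seq_error: float = 0.005
    overdispersion_rho: float = 0.02
    site_qual: float = 60.0
    n_background_genes: int = 1000
    background_log_rate_mean: float = 4.5  # ln scale, ~90 counts
    background_log_rate_sd: float = 1.2
    sex_biased_fraction_per_tissue: Mapping[str, float] = field(
        default_factory=lambda: {"leaves": 0.04, "catkin_axes": 0.15, "flowers": 0.22}
    )
    sex_bias_fold: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("negative cohort size")
        for name in ("wgs_depth_male", "wgs_depth_female", "rna_depth", "amplicon_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.seq_error < 0.5:
            raise ValueError(f"seq_error must be in [0, 0.5), got {self.seq_error}")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if self.n_het_sites_per_gene < 1:
            raise ValueError("need at least one het site per gene")
        self.tissues = tuple(self.tissues)
        self.hemizygous_regions = tuple(self.hemizygous_regions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "genes" in raw:
            raw["genes"] = [GeneTruth(**g) for g in raw["genes"]]
        if "hemizygous_regions" in raw:
            raw["hemizygous_regions"] = tuple(
                GenomicInterval(r["chrom"], r["start"], r["end"])
                for r in raw["hemizygous_regions"]
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k not in ("genes", "hemizygous_regions", "tissues",
                         "sex_biased_fraction_per_tissue")
        }
        raw["tissues"] = list(self.tissues)
        raw["sex_biased_fraction_per_tissue"] = dict(self.sex_biased_fraction_per_tissue)
        raw["genes"] = [
            {
                "gene_id": g.gene_id,
                "expr_rate_per_tissue": dict(g.expr_rate_per_tissue),
                "y_allele_expression_fraction_male": g.y_allele_expression_fraction_male,
                "allele_fraction_female": g.allele_fraction_female,
            }
            for g in self.genes
        ]
        raw["hemizygous_regions"] = [
            {"chrom": r.chrom, "start": r.start, "end": r.end}
            for r in self.hemizygous_regions
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TruthTables:
    """Ground truth behind a synthetic dataset."""

    individuals: pd.DataFrame  # individual_id, sex, design
    sites: pd.DataFrame  # chrom, pos (1-based), ref, alt, gene_id
    phase: pd.DataFrame  # individual_id, chrom, pos, hap1_allele, hap2_allele
    gene_class: pd.DataFrame  # gene_id, individual_id, true_class
    hemizygous_regions: tuple[GenomicInterval, ...]


@dataclass
class SyntheticDataset:
    samples: pd.DataFrame  # sample_id, individual_id, sex, material, tissue, design
    observations: list[SiteObservation]
    wgs_tracks: dict[str, CoverageTrack]  # raw, keyed by individual_id
    rna_tracks: dict[str, CoverageTrack]  # raw, keyed by "individual/tissue"
    bulk_counts: CountMatrix
    truth: TruthTables
    config: TruthConfig

    @property
    def amplicon_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["design"] == "amplicon"].reset_index(drop=True)

    @property
    def bulk_rna_libraries(self) -> pd.DataFrame:
        mask = (self.samples["design"] == "bulk") & (self.samples["material"] == "cDNA")
        return self.samples[mask].reset_index(drop=True)


def _stream(seed: int, *labels) -> np.random.Generator:
    """Deterministic substream keyed by a stable hash of the labels."""
    key = zlib.crc32("|".join(str(x) for x in labels).encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, key])


def sample_allele_depths(
    true_fraction: float,
    depth: float,
    seq_error: float = 0.0,
    rho: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Draw (ref_depth, alt_depth) at one site.

    Total depth is Poisson(``depth``); the alt count is beta-binomial with
    success probability p* = f(1-e) + (1-f)e and intraclass correlation
    ``rho`` (rho = 0 gives a plain binomial).
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError(f"true_fraction outside [0,1]: {true_fraction}")
    if rng is None:
        rng = np.random.default_rng()
    total = int(rng.poisson(depth)) if depth > 0 else 0
    if total == 0:
        return 0, 0
    p = true_fraction * (1.0 - seq_error) + (1.0 - true_fraction) * seq_error
    if rho > 0.0 and 0.0 < p < 1.0:
        shape = (1.0 - rho) / rho
        p = rng.beta(p * shape, (1.0 - p) * shape)
    alt = int(rng.binomial(total, p))
    return total - alt, alt


_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


def _draw_sites(
    config: TruthConfig, annotations: Sequence[GeneAnnotation]
) -> pd.DataFrame:
    rows = []
    ann = {g.gene_id: g for g in annotations}
    for gene in config.genes:
        if gene.gene_id not in ann:
            raise ValueError(f"no annotation for gene {gene.gene_id}")
        iv = ann[gene.gene_id].interval
        rng = _stream(config.seed, "sites", gene.gene_id)
        positions = sorted(
            rng.choice(
                np.arange(iv.start, iv.end),
                size=config.n_het_sites_per_gene,
                replace=False,
            )
        )
        for pos0 in positions:
            ref, alt = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            rows.append(
                {
                    "chrom": iv.chrom,
                    "pos": int(pos0) + 1,
                    "ref": ref,
                    "alt": alt,
                    "gene_id": gene.gene_id,
                }
            )
    return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)


def _in_hemizygous(config: TruthConfig, chrom: str, pos1: int) -> bool:
    return any(
        r.chrom == chrom and r.contains_point(pos1 - 1)
        for r in config.hemizygous_regions
    )


def simulate_cohort(
    config: TruthConfig,
    annotations: Sequence[GeneAnnotation] | None = None,
) -> SyntheticDataset:
    """Generate the full synthetic dataset plus its truth tables.

    Deterministic given ``config.seed``.  See the module docstring for the
    generative model.
    """
    if config.n_males + config.n_females == 0:
        raise ValueError("cohort must contain at least one individual")
    if annotations is None:
        annotations = build_sdr_genes()

    sites = _draw_sites(config, annotations)
    gene_truth = {g.gene_id: g for g in config.genes}

    # Individuals: a bulk WGS/RNA pair plus the amplicon cohort.
    individuals = [("M_bulk", "male", "bulk"), ("F_bulk", "female", "bulk")]
    individuals += [
        (f"M{i:02d}", "male", "amplicon") for i in range(1, config.n_males + 1)
    ]
    individuals += [
        (f"F{i:02d}", "female", "amplicon") for i in range(1, config.n_females + 1)
    ]
    ind_df = pd.DataFrame(individuals, columns=["individual_id", "sex", "design"])

    # Phase: which allele sits on haplotype 1 (the Y in males).
    phase_rows = []
    phase_map: dict[tuple[str, int], tuple[str, str]] = {}
    for ind, sex, _design in individuals:
        for _, s in sites.iterrows():
            rng = _stream(config.seed, "phase", ind, s.chrom, s.pos)
            if rng.random() < 0.5:
                hap1, hap2 = s.ref, s.alt
            else:
                hap1, hap2 = s.alt, s.ref
            phase_rows.append(
                {"individual_id": ind, "chrom": s.chrom, "pos": s.pos,
                 "hap1_allele": hap1, "hap2_allele": hap2}
            )
            phase_map[(ind, s.pos)] = (hap1, hap2)
    phase_df = pd.DataFrame(phase_rows)

    amplicon_panel = [g.gene_id for g in config.genes if g.expressed]

    samples_rows = []
    observations: list[SiteObservation] = []

    def emit_obs(ind: str, sex: str, material: str, tissue: str, depth: float,
                 site_rows: pd.DataFrame) -> None:
        for _, s in site_rows.iterrows():
            gt = gene_truth[s.gene_id]
            hap1, _hap2 = phase_map[(ind, s.pos)]
            hemi = _in_hemizygous(config, s.chrom, s.pos)
            if material == "DNA":
                if hemi:
                    if sex == "female":
                        continue  # Y-specific site absent from females
                    frac_hap1, eff_depth = 1.0, depth / 2.0
                else:
                    frac_hap1, eff_depth = 0.5, depth
            else:  # cDNA
                if not gt.expressed_in(tissue):
                    continue
                frac_hap1 = (
                    gt.y_allele_expression_fraction_male
                    if sex == "male"
                    else gt.allele_fraction_female
                )
                eff_depth = depth
            alt_fraction = frac_hap1 if hap1 == s.alt else 1.0 - frac_hap1
            rng = _stream(config.seed, "depth", ind, material, tissue, s.chrom, s.pos)
            ref_d, alt_d = sample_allele_depths(
                alt_fraction, eff_depth, config.seq_error,
                config.overdispersion_rho, rng,
            )
            observations.append(
                SiteObservation(
                    site=Site(s.chrom, int(s.pos), s.ref, s.alt),
                    sample_id=ind,
                    material=material,  # type: ignore[arg-type]
                    tissue=tissue,
                    ref_depth=ref_d,
                    alt_depth=alt_d,
                    quality=config.site_qual,
                )
            )

    for ind, sex, design in individuals:
        if design == "bulk":
            wgs_depth = config.wgs_depth_male if sex == "male" else config.wgs_depth_female
            samples_rows.append((f"{ind}.DNA.leaves", ind, sex, "DNA", "leaves", design))
            emit_obs(ind, sex, "DNA", "leaves", wgs_depth, sites)
            for tissue in config.tissues:
                samples_rows.append(
                    (f"{ind}.cDNA.{tissue}", ind, sex, "cDNA", tissue, design)
                )
                emit_obs(ind, sex, "cDNA", tissue, config.rna_depth, sites)
        else:
            panel_sites = sites[sites["gene_id"].isin(amplicon_panel)]
            samples_rows.append((f"{ind}.DNA.leaves", ind, sex, "DNA", "leaves", design))
            emit_obs(ind, sex, "DNA", "leaves", config.amplicon_depth, panel_sites)
            for tissue in config.tissues:
                samples_rows.append(
                    (f"{ind}.cDNA.{tissue}", ind, sex, "cDNA", tissue, design)
                )
                emit_obs(ind, sex, "cDNA", tissue, config.amplicon_depth, panel_sites)

    samples = pd.DataFrame(
        samples_rows,
        columns=["sample_id", "individual_id", "sex", "material", "tissue", "design"],
    )

    wgs_tracks = _simulate_wgs_tracks(config)
    rna_tracks = _simulate_rna_tracks(config, annotations)
    bulk_counts = _simulate_bulk_counts(config, annotations)

    gene_class_rows = []
    for ind, sex, _design in individuals:
        for g in config.genes:
            if not g.expressed:
                cls = "silent"
            elif sex == "male":
                y = g.y_allele_expression_fraction_male
                cls = "monoallelic" if (y <= 0.05 or y >= 0.95) else "biallelic"
            else:
                f = g.allele_fraction_female
                cls = "monoallelic" if (f <= 0.05 or f >= 0.95) else "biallelic"
            gene_class_rows.append(
                {"gene_id": g.gene_id, "individual_id": ind, "true_class": cls}
            )

    truth = TruthTables(
        individuals=ind_df,
        sites=sites,
        phase=phase_df,
        gene_class=pd.DataFrame(gene_class_rows),
        hemizygous_regions=config.hemizygous_regions,
    )
    return SyntheticDataset(
        samples=samples,
        observations=observations,
        wgs_tracks=wgs_tracks,
        rna_tracks=rna_tracks,
        bulk_counts=bulk_counts,
        truth=truth,
        config=config,
    )


def _hemizygous_fraction(config: TruthConfig, b: GenomicInterval) -> float:
    covered = sum(b.intersection_length(r) for r in config.hemizygous_regions)
    return covered / b.length()


def _simulate_wgs_tracks(config: TruthConfig) -> dict[str, CoverageTrack]:
    bins = bin_interval(SDR_REGION, SDR_BIN_WIDTH)
    tracks = {}
    for ind, sex, depth in (
        ("M_bulk", "male", config.wgs_depth_male),
        ("F_bulk", "female", config.wgs_depth_female),
    ):
        rng = _stream(config.seed, "wgs_track", ind)
        means = np.empty(len(bins))
        for i, b in enumerate(bins):
            h = _hemizygous_fraction(config, b)
            # males keep one haplotype over hemizygous sequence; females none
            copy = (1.0 - h) + (0.5 * h if sex == "male" else 0.0)
            means[i] = depth * copy * b.length()
        depths = rng.poisson(means) / np.array([b.length() for b in bins])
        tracks[ind] = CoverageTrack(ind, tuple(bins), depths)
    return tracks


def _simulate_rna_tracks(
    config: TruthConfig, annotations: Sequence[GeneAnnotation]
) -> dict[str, CoverageTrack]:
    """Raw binned RNA depth for the bulk pair, keyed ``individual/tissue``.

    Per-base RNA depth over an expressed gene body equals ``rna_depth``;
    hemizygous intervals are untranscribed (no track signal)."""
    bins = bin_interval(SDR_REGION, SDR_BIN_WIDTH)
    ann = {g.gene_id: g for g in annotations}
    tracks = {}
    for ind, sex in (("M_bulk", "male"), ("F_bulk", "female")):
        for tissue in config.tissues:
            rng = _stream(config.seed, "rna_track", ind, tissue)
            means = np.zeros(len(bins))
            for g in config.genes:
                if not g.expressed_in(tissue):
                    continue
                iv = ann[g.gene_id].interval
                for i, b in enumerate(bins):
                    ov = b.intersection_length(iv)
                    if ov:
                        means[i] += config.rna_depth * ov
            depths = rng.poisson(means) / np.array([b.length() for b in bins])
            tracks[f"{ind}/{tissue}"] = CoverageTrack(f"{ind}/{tissue}", tuple(bins), depths)
    return tracks


def _simulate_bulk_counts(
    config: TruthConfig, annotations: Sequence[GeneAnnotation]
) -> CountMatrix:
    """Gene x library counts for the 2-sex x 3-tissue bulk design.

    Rows are the annotated SDR genes followed by background genes with
    log-normal base rates; a tissue-specific fraction of background genes
    is sex-biased (fold ``sex_bias_fold``, random direction), emulating the
    stronger sex differences of generative tissues over leaves.
    """
    rng_bg = _stream(config.seed, "background_genes")
    n_bg = config.n_background_genes
    base = np.exp(
        rng_bg.normal(config.background_log_rate_mean, config.background_log_rate_sd, n_bg)
    )
    # per-tissue expression modulation of background genes
    tissue_mult = {
        t: np.exp(rng_bg.normal(0.0, 0.4, n_bg)) for t in config.tissues
    }
    biased: dict[str, np.ndarray] = {}
    for t in config.tissues:
        frac = config.sex_biased_fraction_per_tissue.get(t, 0.0)
        is_biased = rng_bg.random(n_bg) < frac
        direction = np.where(rng_bg.random(n_bg) < 0.5, 1.0, -1.0)
        biased[t] = np.where(is_biased, config.sex_bias_fold ** direction, 1.0)

    sdr_ids = [g.gene_id for g in config.genes]
    gene_ids = sdr_ids + [f"BG{i:05d}" for i in range(n_bg)]
    lib_rows = []
    columns = {}
    for ind, sex in (("M_bulk", "male"), ("F_bulk", "female")):
        for tissue in config.tissues:
            lib = f"{ind}.cDNA.{tissue}"
            rates_sdr = np.array(
                [gene_truth.expr_rate_per_tissue.get(tissue, 0.0)
                 for gene_truth in config.genes]
            )
            rates_bg = base * tissue_mult[tissue]
            if sex == "male":
                rates_bg = rates_bg * biased[tissue]
            rng = _stream(config.seed, "bulk_counts", ind, tissue)
            counts = rng.poisson(np.concatenate([rates_sdr, rates_bg]))
            columns[lib] = counts
            lib_rows.append({"library_id": lib, "sex": sex, "tissue": tissue})
    counts_df = pd.DataFrame(columns, index=gene_ids)
    counts_df.index.name = "gene_id"
    meta = pd.DataFrame(lib_rows).set_index("library_id")
    return CountMatrix(counts_df, meta)


# --------------------------------------------------------------------------
# Emission of on-disk artifacts
# --------------------------------------------------------------------------

def emit_vcf(dataset: SyntheticDataset, path: str | Path) -> None:
    """Write all allele-depth observations as a VCF 4.2 with GT:AD:DP.

    One sample column per sequencing sample, named
    ``individual.material.tissue``; samples without data at a site carry
    missing genotypes.  Site QUAL comes from the generating config.
    """
    sites = dataset.truth.sites
    sample_ids = list(dataset.samples["sample_id"])
    obs_map = {
        (f"{o.sample_id}.{o.material}.{o.tissue}", o.site.pos): o
        for o in dataset.observations
    }
    max_pos = int(sites["pos"].max()) + 10_000 if len(sites) else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sdrase-simulate\n")
        for chrom in sorted(sites["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom},length={max_pos}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for _, s in sites.iterrows():
            cells = []
            for sid in sample_ids:
                o = obs_map.get((sid, s.pos))
                if o is None:
                    cells.append("./.:.:.")
                else:
                    dp = o.ref_depth + o.alt_depth
                    cells.append(f"0/1:{o.ref_depth},{o.alt_depth}:{dp}")
            qual = dataset.config.site_qual
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t{qual:g}\t.\t.\t"
                "GT:AD:DP\t" + "\t".join(cells) + "\n"
            )


def emit_counts(dataset: SyntheticDataset, path: str | Path) -> None:
    dataset.bulk_counts.to_tsv(path)


def emit_truth(truth: TruthTables, outdir: str | Path) -> None:
    """Write truth tables as TSVs plus a BED of hemizygous regions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.individuals.to_csv(outdir / "individuals.tsv", sep="\t", index=False)
    truth.sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    truth.phase.to_csv(outdir / "phase.tsv", sep="\t", index=False)
    truth.gene_class.to_csv(outdir / "gene_class.tsv", sep="\t", index=False)
    with open(outdir / "hemizygous_regions.bed", "w") as fh:
        for r in truth.hemizygous_regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\themizygous\n")
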