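"""Site/gene ASE classification and the Fisher sex-association test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdrase.alleles import GenotypeCall, Site, SiteObservation
from sdrase.ase import (
    ASECall,
    JoinError,
    SiteASE,
    aggregate_gene,
    classify_site_rna,
    compare_wgs_rna_het_sites,
    sex_association,
)
from sdrase.pipeline import call_dna_genotypes, run_ase_analysis
from sdrase.simulate import TruthConfig, simulate_cohort

SITE = Site("Chr18", 16_268_200, "A", "G")


def cdna_obs(ref, alt, tissue="leaves", site=SITE, ind="M01"):
    return SiteObservation(site, ind, "cDNA", tissue, ref, alt, 60.0)


def het_call(site=SITE, ind="M01"):
    return GenotypeCall(site, ind, "het", 0.5, 100)


def site_ase(cls, tissue="leaves", pos=16_268_200):
    return SiteASE(Site("Chr18", pos, "A", "G"), "M01", tissue, cls, None)


class TestClassifySiteRNA:
    def test_dominant_alt_is_monoallelic(self):
        call = classify_site_rna(cdna_obs(2, 98), het_call())
        assert call.site_class == "monoallelic_alt"
        assert call.cdna_fraction == pytest.approx(0.98)

    def test_balanced_is_biallelic(self):
        assert classify_site_rna(cdna_obs(48, 52), het_call()).site_class == "biallelic"

    def test_shallow_cdna_undetermined(self):
        assert classify_site_rna(cdna_obs(2, 3), het_call()).site_class == "undetermined"

    def test_symmetric_under_ref_alt_relabeling(self):
        fwd = classify_site_rna(cdna_obs(7, 93), het_call())
        rev = classify_site_rna(cdna_obs(93, 7), het_call())
        assert (fwd.site_class, rev.site_class) == ("monoallelic_alt", "monoallelic_ref")
        assert fwd.cdna_fraction == pytest.approx(1 - rev.cdna_fraction)

    def test_mismatched_keys_raise_join_error(self):
        with pytest.raises(JoinError):
            classify_site_rna(cdna_obs(1, 99, ind="M02"), het_call(ind="M01"))

    def test_requires_het_dna(self):
        hom = GenotypeCall(SITE, "M01", "hom_ref", 0.01, 100)
        with pytest.raises(ValueError):
            classify_site_rna(cdna_obs(1, 99), hom)


class TestAggregateGene:
    TISSUES = ("leaves", "catkin_axes", "flowers")

    def _calls(self, cls):
        return [
            site_ase(cls, tissue=t, pos=16_268_200 + i)
            for t in self.TISSUES
            for i in range(3)
        ]

    def test_all_monoallelic_across_tissues(self):
        call = aggregate_gene(self._calls("monoallelic_alt"), "CLC", "M01", "male")
        assert call.gene_class == "monoallelic"
        assert call.n_tissues_consistent == 3
        assert call.n_informative_sites == 9

    def test_all_biallelic(self):
        call = aggregate_gene(self._calls("biallelic"), "TCP", "M01", "male")
        assert call.gene_class == "biallelic"

    def test_disagreeing_tissues_undetermined(self):
        calls = [site_ase("monoallelic_alt", "leaves", 16_268_200 + i) for i in range(3)]
        calls += [site_ase("biallelic", "flowers", 16_268_200 + i) for i in range(3)]
        assert aggregate_gene(calls, "g", "M01").gene_class == "undetermined"

    def test_too_few_informative_sites(self):
        calls = [site_ase("monoallelic_alt")]
        out = aggregate_gene(calls, "g", "M01", min_sites=2)
        assert out.gene_class == "undetermined" and out.n_informative_sites == 1

    def test_empty_input(self):
        out = aggregate_gene([], "g", "M01")
        assert out.gene_class == "undetermined" and out.n_informative_sites == 0


def fisher_oracle(m_mono, m_bi, f_mono, f_bi, toward_male):
    """One-sided Fisher p by hypergeometric enumeration (independent route)."""
    n_total = m_mono + m_bi + f_mono + f_bi
    k_mono = m_mono + f_mono
    n_male = m_mono + m_bi
    denom = math.comb(n_total, n_male)
    lo = max(0, n_male + k_mono - n_total)
    hi = min(k_mono, n_male)
    if toward_male:
        support = range(m_mono, hi + 1)
    else:
        support = range(lo, m_mono + 1)
    return sum(
        math.comb(k_mono, x) * math.comb(n_total - k_mono, n_male - x)
        for x in support
    ) / denom


def make_calls(m_mono, m_bi, f_mono, f_bi):
    calls = []
    i = 0
    for sex, cls, n in (
        ("male", "monoallelic", m_mono), ("male", "biallelic", m_bi),
        ("female", "monoallelic", f_mono), ("female", "biallelic", f_bi),
    ):
        for _ in range(n):
            i += 1
            calls.append(ASECall("g", f"I{i:03d}", sex, cls, 4, 3))
    return calls


class TestSexAssociation:
    def test_complete_separation_in_the_cohort_design(self):
        res = sex_association(make_calls(10, 0, 0, 10))
        assert res.p_value == pytest.approx(1 / math.comb(20, 10))
        assert res.p_value == pytest.approx(5.4128e-6, rel=1e-3)
        assert res.label == "male_associated_ASE"

    def test_all_biallelic_is_unlabeled(self):
        res = sex_association(make_calls(0, 10, 0, 10))
        assert res.label == "none" and res.p_value == 1.0

    def test_single_monoallelic_male_is_chance(self):
        res = sex_association(make_calls(1, 9, 0, 10))
        assert res.p_value == pytest.approx(0.5)
        assert res.label == "none"

    def test_female_direction(self):
        res = sex_association(make_calls(0, 10, 10, 0))
        assert res.label == "female_associated_ASE"

    def test_all_undetermined_gives_nan(self):
        calls = [ASECall("g", f"I{i}", "male", "undetermined", 0, 0) for i in range(4)]
        res = sex_association(calls)
        assert math.isnan(res.p_value) and res.label == "none"

    def test_duplicate_individual_rejected(self):
        calls = make_calls(1, 0, 0, 1)
        with pytest.raises(ValueError, match="twice"):
            sex_association(calls + [calls[0]])

    def test_matches_enumeration_oracle_exhaustively_small(self):
        """p equals the hypergeometric enumeration for all tables with
        up to 6 individuals per sex cell-wise."""
        for m_mono in range(0, 7):
            for m_bi in range(0, 7 - m_mono):
                for f_mono in range(0, 7):
                    for f_bi in range(0, 7 - f_mono):
                        if m_mono + m_bi + f_mono + f_bi == 0:
                            continue
                        res = sex_association(make_calls(m_mono, m_bi, f_mono, f_bi))
                        m_n, f_n = m_mono + m_bi, f_mono + f_bi
                        toward_male = (m_mono / m_n if m_n else 0.0) >= (
                            f_mono / f_n if f_n else 0.0
                        )
                        expected = fisher_oracle(m_mono, m_bi, f_mono, f_bi, toward_male)
                        assert res.p_value == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=150, deadline=None)
    @given(st.tuples(*[st.integers(0, 10)] * 4))
    def test_matches_enumeration_oracle_random_margins_20(self, cells):
        m_mono, m_bi, f_mono, f_bi = cells
        if sum(cells) == 0:
            return
        res = sex_association(make_calls(m_mono, m_bi, f_mono, f_bi))
        m_n, f_n = m_mono + m_bi, f_mono + f_bi
        toward_male = (m_mono / m_n if m_n else 0.0) >= (f_mono / f_n if f_n else 0.0)
        expected = fisher_oracle(m_mono, m_bi, f_mono, f_bi, toward_male)
        assert res.p_value == pytest.approx(expected, abs=1e-12)


class TestSingleIndividualConcordance:
    def _observations(self, dataset, individual):
        return [o for o in dataset.observations if o.sample_id == individual]

    def test_female_expressed_genes_majority_biallelic(self, default_dataset, sdr_genes):
        obs = self._observations(default_dataset, "F_bulk")
        dna_calls = call_dna_genotypes(obs)
        rna = [o for o in obs if o.material == "cDNA"]
        table = compare_wgs_rna_het_sites(dna_calls, rna, sdr_genes)
        assert set(table["gene_id"]) == {
            "PtStettler14.18G127700", "PtStettler14.18G127800", "PtStettler14.18G127900",
        }
        per_gene = table.groupby("gene_id")[["n_biallelic", "n_monoallelic"]].sum()
        assert (per_gene["n_biallelic"] > per_gene["n_monoallelic"]).all()

    def test_male_clc_monoallelic_tcp_met1_biallelic(self, default_dataset, sdr_genes):
        obs = self._observations(default_dataset, "M_bulk")
        dna_calls = call_dna_genotypes(obs)
        rna = [o for o in obs if o.material == "cDNA"]
        table = compare_wgs_rna_het_sites(dna_calls, rna, sdr_genes)
        per_gene = table.groupby("gene_id")[["n_biallelic", "n_monoallelic"]].sum()
        clc = "PtStettler14.18G127800"
        assert per_gene.loc[clc, "n_monoallelic"] > per_gene.loc[clc, "n_biallelic"]
        for other in ("PtStettler14.18G127700", "PtStettler14.18G127900"):
            assert per_gene.loc[other, "n_biallelic"] > per_gene.loc[other, "n_monoallelic"]

    def test_no_overlapping_sites_gives_empty_table(self, sdr_genes):
        table = compare_wgs_rna_het_sites([], [cdna_obs(10, 90)], sdr_genes)
        assert table.empty

    def test_multiple_individuals_rejected(self, sdr_genes):
        with pytest.raises(ValueError, match="several individuals"):
            compare_wgs_rna_het_sites(
                [het_call(ind="M01")], [cdna_obs(10, 90, ind="M02")], sdr_genes
            )


class TestPlantedTruthRecovery:
    def test_clc_pattern_recovered_across_seeds(self, sdr_genes):
        """The Y-silenced gene is labeled male-associated and the balanced
        genes unlabeled in >= 95% of 100 simulated cohorts."""
        clc = "PtStettler14.18G127800"
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            ds = simulate_cohort(TruthConfig(seed=seed))
            sex_of = dict(ds.truth.individuals[["individual_id", "sex"]].values)
            results, _, _ = run_ase_analysis(ds.observations, sdr_genes, sex_of)
            labels = {r.gene_id: r.label for r in results}
            ok = labels.get(clc) == "male_associated_ASE" and all(
                v == "none" for g, v in labels.items() if g != clc
            )
            hits += ok
        assert hits >= 0.95 * n_seeds
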