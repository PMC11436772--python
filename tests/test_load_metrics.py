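"""Unit and property tests for VCF reading, filters and load statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loadfit import load_metrics as lm
from loadfit.load_metrics import (
    ImpactCategory, apply_site_filters, compute_load_profile,
    compute_load_profiles, compute_sfs, gene_pool_lof_summary,
    heterozygosity_per_kb, percent_excess, read_annotated_vcf,
)

from conftest import make_table


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=100000>\n"
    '##INFO=<ID=ANN,Number=.,Type=String,Description="ann">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path, body_lines, samples=("s0", "s1", "s2")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + "".join(l + "\n" for l in body_lines))
    return path


class TestReadAnnotatedVcf:
    def test_impact_categories_from_ann(self, tmp_path):
        vcf = write_vcf(tmp_path / "a.vcf", [
            "chr1\t100\t.\tG\tA\t.\tPASS\tANN=A|stop_gained|HIGH|gX|gX\tGT\t0/1\t0/0\t1/1",
            "chr1\t200\t.\tC\tT\t.\tPASS\tANN=T|synonymous_variant|LOW|gY|gY\tGT\t0/0\t0/1\t0/0",
            "chr1\t300\t.\tC\tG\t.\tPASS\tANN=G|missense_variant|MODERATE|gZ|gZ\tGT\t0/1\t./.\t0/0",
        ])
        table = read_annotated_vcf(vcf)
        assert list(table.sites["impact"]) == ["LOF", "SYNONYMOUS", "MISSENSE"]
        assert list(table.sites["gene"]) == ["gX", "gY", "gZ"]
        np.testing.assert_array_equal(table.genotypes[0], [1, 0, 2])
        np.testing.assert_array_equal(table.genotypes[2], [1, -1, 0])

    def test_missing_or_malformed_ann_becomes_other_with_warning(self, tmp_path):
        vcf = write_vcf(tmp_path / "b.vcf", [
            "chr1\t100\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0",
        ])
        with pytest.warns(UserWarning, match="OTHER"):
            table = read_annotated_vcf(vcf)
        assert list(table.sites["impact"]) == ["OTHER"]

    def test_multiallelic_split_per_alt_annotation(self, tmp_path):
        vcf = write_vcf(tmp_path / "c.vcf", [
            "chr1\t100\t.\tG\tA,T\t.\tPASS\t"
            "ANN=A|stop_gained|HIGH|gX|gX,T|synonymous_variant|LOW|gX|gX"
            "\tGT\t0/1\t1/2\t2/2",
        ])
        table = read_annotated_vcf(vcf)
        assert table.n_sites == 2
        assert list(table.sites["impact"]) == ["LOF", "SYNONYMOUS"]
        np.testing.assert_array_equal(table.genotypes[0], [1, 1, 0])  # allele A
        np.testing.assert_array_equal(table.genotypes[1], [0, 1, 2])  # allele T

    def test_empty_body_gives_zero_sites(self, tmp_path):
        table = read_annotated_vcf(write_vcf(tmp_path / "d.vcf", []))
        assert table.n_sites == 0
        assert table.samples == ["s0", "s1", "s2"]

    def test_missing_required_samples_is_an_error(self, tmp_path):
        vcf = write_vcf(tmp_path / "e.vcf", [])
        with pytest.raises(ValueError, match="sX"):
            read_annotated_vcf(vcf, required_samples=["s0", "sX"])


class TestSiteFilters:
    def test_hand_counted_removals(self):
        # 10 sites: 1 with a missing call, 1 fixed hom_alt, 8 segregating
        g = [[1, 0, 2]] * 8 + [[1, -1, 0]] + [[2, 2, 2]]
        table = make_table(g, ["SYNONYMOUS"] * 10)
        filtered, removed = apply_site_filters(table)
        assert filtered.n_sites == 8
        assert removed == {"missing": 1, "fixed": 1, "monomorphic_ref": 0}

    def test_identity_when_all_complete_and_segregating(self, toy_table):
        filtered, removed = apply_site_filters(toy_table)
        assert filtered.n_sites == toy_table.n_sites
        assert sum(removed.values()) == 0
        np.testing.assert_array_equal(filtered.genotypes, toy_table.genotypes)

    def test_all_het_site_is_not_fixed(self):
        table = make_table([[1, 1, 1]], ["LOF"])
        filtered, removed = apply_site_filters(table)
        assert filtered.n_sites == 1

    def test_monomorphic_reference_dropped(self):
        table = make_table([[0, 0, 0], [0, 1, 0]], ["LOF", "LOF"])
        filtered, removed = apply_site_filters(table)
        assert filtered.n_sites == 1
        assert removed["monomorphic_ref"] == 1


class TestLoadProfile:
    def test_allele_load_hand_count(self):
        # one individual carrying 2 LoF, 3 missense, 5 synonymous derived alleles
        g = np.array([
            [2],           # LOF: 2 alleles
            [1, ], [1], [1],  # MIS het x3
            [2], [2], [1],    # SYN: 2+2+1 = 5
        ], dtype=object)
        geno = [[2], [1], [1], [1], [2], [2], [1]]
        impacts = ["LOF", "MISSENSE", "MISSENSE", "MISSENSE",
                   "SYNONYMOUS", "SYNONYMOUS", "SYNONYMOUS"]
        table = make_table(geno, impacts, samples=["ind"])
        p = compute_load_profile(table, "ind", callable_length_bp=1000)
        assert p.p_lof == pytest.approx(0.2)
        assert p.p_mis == pytest.approx(0.3)
        assert p.p_syn == pytest.approx(0.5)

    def test_all_het_individual_has_zero_expressed_load(self):
        # 50 sites, 5 of them LoF, individual het everywhere
        impacts = ["LOF"] * 5 + ["SYNONYMOUS"] * 45
        geno = [[1, 0]] * 50
        table = make_table(geno, impacts, samples=["a", "b"])
        p = compute_load_profile(table, "a", callable_length_bp=1000)
        assert p.e_lof == 0.0
        assert p.m_lof == pytest.approx(5 / 50)
        assert p.n_sites_scored == 50

    def test_zero_derived_alleles_yields_nan_with_warning(self):
        table = make_table([[0, 1]], ["LOF"], samples=["empty", "carrier"])
        with pytest.warns(UserWarning, match="no derived allele"):
            p = compute_load_profile(table, "empty", callable_length_bp=1000)
        assert np.isnan(p.p_lof)
        assert p.e_lof == 0.0

    def test_other_category_excluded_from_denominators(self):
        geno = [[2, 0], [2, 0], [1, 1]]
        table = make_table(geno, ["LOF", "SYNONYMOUS", "OTHER"], samples=["a", "b"])
        p = compute_load_profile(table, "a", callable_length_bp=1000)
        assert p.n_sites_scored == 2
        assert p.p_lof == pytest.approx(0.5)
        assert p.e_lof == pytest.approx(0.5)
        # but heterozygosity counts the OTHER site
        assert p.het_per_kb == pytest.approx(1 * 1000 / 1000)

    def test_carrier_sites_denominator(self):
        geno = [[2], [0], [1], [0]]
        impacts = ["LOF", "LOF", "SYNONYMOUS", "SYNONYMOUS"]
        table = make_table(geno, impacts, samples=["a"])
        p_all = compute_load_profiles(table, 1000, denominator="all_sites")
        p_car = compute_load_profiles(table, 1000, denominator="carrier_sites")
        assert p_all.loc[0, "e_lof"] == pytest.approx(1 / 4)
        assert p_car.loc[0, "e_lof"] == pytest.approx(1 / 2)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(7)
        cats = np.array(["LOF", "MISSENSE", "SYNONYMOUS", "OTHER"])
        impacts = cats[rng.integers(0, 4, 200)]
        geno = rng.integers(0, 3, size=(200, 10))
        table = make_table(geno, list(impacts))
        table, _ = apply_site_filters(table)
        profiles = compute_load_profiles(table, callable_length_bp=5000)
        g = table.genotypes
        imp = table.sites["impact"].to_numpy()
        scored_idx = [i for i in range(table.n_sites)
                      if imp[i] in ("LOF", "MISSENSE", "SYNONYMOUS")]
        for j, sample in enumerate(table.samples):
            tally = {c: {"alleles": 0, "hom": 0, "het": 0}
                     for c in ("LOF", "MISSENSE", "SYNONYMOUS")}
            het_all = 0
            for i in range(table.n_sites):
                if g[i, j] == 1:
                    het_all += 1
                if i in scored_idx:
                    c = imp[i]
                    tally[c]["alleles"] += int(g[i, j])
                    tally[c]["hom"] += int(g[i, j] == 2)
                    tally[c]["het"] += int(g[i, j] == 1)
            total_alleles = sum(t["alleles"] for t in tally.values())
            n_scored = len(scored_idx)
            row = profiles.loc[profiles["id"] == sample].iloc[0]
            assert row["n_sites_scored"] == n_scored
            for cat, suffix in (("LOF", "lof"), ("MISSENSE", "mis"),
                                ("SYNONYMOUS", "syn")):
                assert row[f"p_{suffix}"] == pytest.approx(
                    tally[cat]["alleles"] / total_alleles)
                assert row[f"e_{suffix}"] == tally[cat]["hom"] / n_scored
                assert row[f"m_{suffix}"] == tally[cat]["het"] / n_scored
            assert row["het_per_kb"] == pytest.approx(het_all * 1000 / 5000)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_proportion_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n_sites, n_ind = rng.integers(2, 40), rng.integers(2, 8)
        cats = np.array(["LOF", "MISSENSE", "SYNONYMOUS"])
        geno = rng.integers(0, 3, size=(n_sites, n_ind))
        table = make_table(geno, list(cats[rng.integers(0, 3, n_sites)]))
        table, _ = apply_site_filters(table)
        if table.n_sites == 0:
            return
        prof = compute_load_profiles(table, 1000)
        p_sum = prof[["p_lof", "p_mis", "p_syn"]].sum(axis=1)
        defined = prof["p_lof"].notna()
        assert np.allclose(p_sum[defined], 1.0)
        # n_sites_scored is constant across individuals post-filter
        assert prof["n_sites_scored"].nunique() == 1
        for c in ("lof", "mis", "syn"):
            assert ((prof[f"e_{c}"] >= 0) & (prof[f"e_{c}"] <= 1)).all()
            assert ((prof[f"e_{c}"] + prof[f"m_{c}"]) <= 1 + 1e-12).all()
        # sum of expressed+masked equals carrier fraction
        carrier = (np.isin(table.sites["impact"], cats)[:, None]
                   & (table.genotypes > 0)).sum(axis=0) / prof["n_sites_scored"][0]
        total = sum(prof[f"e_{c}"] + prof[f"m_{c}"] for c in ("lof", "mis", "syn"))
        assert np.allclose(total, carrier)


class TestSfs:
    def test_hand_tally(self):
        geno = [[1, 0, 0, 0, 0], [0, 0, 0, 0, 1], [2, 1, 1, 0, 0]]
        table = make_table(geno, ["LOF"] * 3)
        sfs = compute_sfs(table, ImpactCategory.LOF)
        expected = np.zeros(9, dtype=int)
        expected[0] = 2   # derived count 1 twice
        expected[3] = 1   # derived count 4 once
        np.testing.assert_array_equal(sfs.counts, expected)
        assert sfs.n_segregating == 3

    def test_conservation_and_zero_category(self, toy_table):
        table, _ = apply_site_filters(toy_table)
        for cat in ImpactCategory:
            sfs = compute_sfs(table, cat)
            n_sites = int((table.sites["impact"] == cat.value).sum())
            assert sfs.n_segregating == n_sites
        empty = make_table([[0, 1]], ["LOF"])
        sfs = compute_sfs(empty, ImpactCategory.MISSENSE)
        assert sfs.counts.sum() == 0

    def test_mean_derived_frequency(self):
        geno = [[1, 0], [2, 2]]
        table = make_table(geno, ["SYNONYMOUS", "SYNONYMOUS"])
        # counts 1 and 4 are out of 4 chromosomes; site 2 is fixed -> excluded
        sfs = compute_sfs(table, ImpactCategory.SYNONYMOUS)
        assert sfs.mean_derived_frequency == pytest.approx(1 / 4)


class TestHeterozygosity:
    def test_arithmetic(self):
        geno = [[1, 0]] * 50
        table = make_table(geno, ["OTHER"] * 50, samples=["a", "b"])
        assert heterozygosity_per_kb(table, "a", 10_000) == pytest.approx(5.0)
        assert heterozygosity_per_kb(table, "b", 10_000) == 0.0

    def test_invalid_callable_length(self, toy_table):
        with pytest.raises(ValueError):
            heterozygosity_per_kb(toy_table, "s0", 0)


class TestGenePool:
    def test_toy_private_counts_and_excess(self):
        # natives carry sites {a, b}; hybrids carry {a, b, c, d}
        geno = [
            [1, 0, 1, 0],  # a: both groups
            [2, 0, 0, 1],  # b: both groups
            [0, 0, 1, 0],  # c: hybrid only
            [0, 0, 0, 2],  # d: hybrid only
        ]
        table = make_table(geno, ["LOF"] * 4, samples=["n1", "n2", "h1", "h2"])
        s = gene_pool_lof_summary(table, {"native": ["n1", "n2"],
                                          "hybrid": ["h1", "h2"]})
        assert (s.n_lof_a, s.n_lof_b) == (2, 4)
        assert (s.private_a, s.private_b) == (0, 2)
        assert s.percent_excess == 100.0

    def test_identical_groups_zero_excess(self):
        geno = [[1, 1], [0, 0], [2, 2]]
        table = make_table(geno, ["LOF"] * 3, samples=["a", "b"])
        s = gene_pool_lof_summary(table, {"g1": ["a"], "g2": ["b"]})
        assert s.percent_excess == 0.0
        assert s.private_a == s.private_b == 0

    def test_study_counts_give_published_excess(self):
        assert percent_excess(1168, 1220) == 4.5

    def test_empty_group_is_an_error(self, toy_table):
        with pytest.raises(ValueError):
            gene_pool_lof_summary(toy_table, {"a": [], "b": ["s0"]})
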