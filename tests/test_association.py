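"""Tests for dosage loading, maf filtering, kinship, pruning, LMM and LD."""

import numpy as np
import pandas as pd
import pytest

from onsen_fate import association as assoc
from onsen_fate.association import GenotypePanel
from onsen_fate.synthetic_data import synth_genotype_aridity, write_vcf


def _panel(dosages, ecotypes=None, **kw):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypePanel(
        ecotypes=ecotypes or [f"e{i}" for i in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
        positions=list(range(100, 100 + m)),
        dosages=dosages,
        **kw,
    )


class TestReadGenotypes:
    def test_vcf_round_trip_with_missing(self, tmp_path):
        panel, _ = synth_genotype_aridity(
            11, n_ecotypes=30, n_snps=6, missing_rate=0.1
        )
        path = tmp_path / "panel.vcf"
        write_vcf(panel, path)
        loaded = assoc.read_genotypes(path)
        assert loaded.ecotypes == panel.ecotypes
        assert loaded.snp_ids == panel.snp_ids
        np.testing.assert_allclose(loaded.dosages, panel.dosages, equal_nan=True)

    def test_multiallelic_sites_skipped_with_warning(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=2>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "2\t100\tsnp1\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n"
            "2\t200\tsnp2\tA\tT,C\t.\tPASS\t.\tGT\t0/1\t0/2\n"
        )
        with pytest.warns(UserWarning, match="multiallelic"):
            panel = assoc.read_genotypes(vcf)
        assert panel.snp_ids == ["snp1"]
        np.testing.assert_allclose(panel.dosages[:, 0], [1.0, 2.0])


class TestMafFilter:
    def test_monomorphic_dropped_and_balanced_kept(self):
        panel = _panel(
            np.column_stack([np.zeros(10), np.repeat([0.0, 2.0], 5)])
        )
        assert assoc.maf_filter(panel) == ["s1"]

    def test_agrees_with_brute_force_counting(self):
        rng = np.random.default_rng(5)
        dosages = rng.binomial(2, rng.uniform(0.05, 0.5, 20), size=(40, 20)).astype(float)
        dosages[rng.random(dosages.shape) < 0.1] = np.nan
        panel = _panel(dosages)
        kept = assoc.maf_filter(panel, threshold=0.3)
        for j, snp in enumerate(panel.snp_ids):
            col = dosages[:, j]
            alleles = []
            for d in col[~np.isnan(col)]:
                alleles += [1] * int(d) + [0] * (2 - int(d))
            p = np.mean(alleles)
            assert (snp in kept) == (min(p, 1 - p) > 0.3)

    def test_all_missing_snp_dropped_with_warning(self):
        panel = _panel(np.column_stack([np.full(6, np.nan), np.repeat([0.0, 2.0], 3)]))
        with pytest.warns(UserWarning, match="missing"):
            kept = assoc.maf_filter(panel)
        assert kept == ["s1"]


class TestKinship:
    def test_duplicate_vectors_give_half(self):
        row = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        panel = _panel(np.vstack([row, row]))
        k = assoc.king_kinship(panel)
        assert k.iloc[0, 1] == pytest.approx(0.5)

    def test_opposite_homozygotes_undefined(self):
        panel = _panel(np.vstack([np.zeros(8), np.full(8, 2.0)]))
        k = assoc.king_kinship(panel)
        assert np.isnan(k.iloc[0, 1])

    def test_symmetry(self):
        panel, _ = synth_genotype_aridity(13, n_ecotypes=25, n_snps=30)
        k = assoc.king_kinship(panel).to_numpy()
        np.testing.assert_allclose(k, k.T, equal_nan=True)

    def test_parent_offspring_around_quarter(self):
        # offspring inherit one parental allele plus one population allele
        rng = np.random.default_rng(7)
        n_sites = 10_000
        freqs = rng.uniform(0.2, 0.8, n_sites)
        ks = []
        for _ in range(20):
            pa = rng.binomial(1, freqs)
            pb = rng.binomial(1, freqs)
            transmitted = np.where(rng.random(n_sites) < 0.5, pa, pb)
            other = rng.binomial(1, freqs)
            parent = (pa + pb).astype(float)
            child = (transmitted + other).astype(float)
            panel = _panel(np.vstack([parent, child]))
            ks.append(assoc.king_kinship(panel).iloc[0, 1])
        assert np.mean(ks) == pytest.approx(0.25, abs=0.02)


class TestPruning:
    def test_duplicate_removed(self):
        panel, truth = synth_genotype_aridity(
            17, n_ecotypes=20, n_duplicate_clusters=1, duplicates_per_cluster=2
        )
        kin = assoc.king_kinship(panel)
        kept = assoc.prune_related(panel, kin)
        # one of the duplicate pair is gone
        pair = {truth["duplicate_sources"][0], truth["duplicate_ids"][0]}
        assert len(pair & set(kept)) == 1

    def test_unrelated_panel_untouched(self):
        panel, _ = synth_genotype_aridity(19, n_ecotypes=30, n_snps=40)
        kin = assoc.king_kinship(panel)
        kept = assoc.prune_related(panel, kin)
        assert kept == panel.ecotypes

    def test_triplet_clusters_keep_one_survivor(self):
        panel, truth = synth_genotype_aridity(
            23, n_ecotypes=30, n_duplicate_clusters=3, duplicates_per_cluster=3
        )
        kin = assoc.king_kinship(panel)
        kept = assoc.prune_related(panel, kin)
        for i, src in enumerate(truth["duplicate_sources"]):
            cluster = {src} | {
                d for d in truth["duplicate_ids"] if d.startswith(src + "_")
            }
            assert len(cluster & set(kept)) == 1


class TestLmm:
    def test_zero_group_variance_matches_ols(self):
        # with no group effects the ML fit collapses to OLS
        rng = np.random.default_rng(3)
        n = 300
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 1.0 + 0.3 * g + rng.normal(0, 1, n)
        panel = _panel(
            g[:, None],
            groups=np.array(["a", "b"] * (n // 2)),
            aridity=y,
        )
        fit = assoc.fit_lmm_snp(panel, "s0")
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(g)).fit()
        if fit.sigma2_group < 1e-8:
            assert fit.beta == pytest.approx(ols.params[1], abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        panel, truth = synth_genotype_aridity(29, causal_ve=4.3)
        fit = assoc.fit_lmm_snp(panel, truth["causal_snp"])
        import statsmodels.formula.api as smf

        df = pd.DataFrame(
            {
                "y": panel.aridity,
                "g": panel.dosage(truth["causal_snp"]),
                "grp": panel.groups,
            }
        )
        md = smf.mixedlm("y ~ g", df, groups=df["grp"]).fit(reml=False)
        assert fit.beta == pytest.approx(md.params["g"], abs=1e-4)
        assert fit.sigma2_resid == pytest.approx(md.scale, rel=1e-3)
        assert fit.sigma2_group == pytest.approx(md.cov_re.iloc[0, 0], rel=1e-2)

    def test_variance_explained_bounds(self):
        panel, truth = synth_genotype_aridity(31, causal_ve=10.0)
        fit = assoc.fit_lmm_snp(panel, truth["causal_snp"])
        assert 0.0 <= fit.variance_explained <= 100.0
        assert fit.sigma2_group >= 0.0 and fit.sigma2_resid >= 0.0

    def test_single_group_rejected(self):
        panel = _panel(
            np.array([[0.0], [1.0], [2.0], [1.0]]),
            groups=np.array(["a"] * 4),
            aridity=np.arange(4.0),
        )
        with pytest.raises(ValueError, match="group"):
            assoc.fit_lmm_snp(panel, "s0")

    def test_constant_dosage_rejected(self):
        panel = _panel(
            np.ones((6, 1)),
            groups=np.array(["a", "b"] * 3),
            aridity=np.arange(6.0),
        )
        with pytest.raises(ValueError, match="constant"):
            assoc.fit_lmm_snp(panel, "s0")


class TestLd:
    def test_self_and_duplicate_column(self):
        rng = np.random.default_rng(41)
        col = rng.binomial(2, 0.4, 50).astype(float)
        panel = _panel(np.column_stack([col, col]))
        r2 = assoc.ld_r2(panel)
        assert r2.iloc[0, 0] == pytest.approx(1.0)
        assert r2.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        panel, _ = synth_genotype_aridity(43, n_ecotypes=1000, n_snps=8)
        r2 = assoc.ld_r2(panel).to_numpy()
        off = r2[~np.eye(8, dtype=bool)]
        assert np.nanmean(off) < 0.01

    def test_allele_relabel_invariance(self):
        panel, _ = synth_genotype_aridity(47, n_ecotypes=100, n_snps=5)
        flipped = _panel(2.0 - panel.dosages)
        a = assoc.ld_r2(panel).to_numpy()
        b = assoc.ld_r2(flipped).to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12, equal_nan=True)

    def test_constant_dosage_flagged(self):
        panel = _panel(
            np.column_stack([np.ones(10), np.tile([0.0, 2.0], 5)])
        )
        r2 = assoc.ld_r2(panel)
        assert np.isnan(r2.iloc[0, 1])
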