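"""Synthetic-data generator: construction rules, calibration of the
sampling model, determinism, and the ground-truth invariants."""

import numpy as np
import pytest
from scipy import stats

from targetmr import synth
from targetmr.errors import ParameterError, ValidationError


def _truth(gene="G", snp="rs5", beta=0.35, theta=0.25,
           scenario="causal_shared", seed=0, **kw):
    return synth.SimulationTruth(gene=gene, causal_snp_ids=[snp],
                                 eqtl_betas={snp: beta}, theta=theta,
                                 scenario=scenario, seed=seed, **kw)


class TestTruthInvariants:
    def test_null_requires_zero_theta(self):
        with pytest.raises(ValidationError):
            _truth(theta=0.1, scenario="null")

    def test_distinct_requires_disjoint_sets(self):
        with pytest.raises(ValidationError):
            _truth(scenario="causal_distinct",
                   outcome_causal_snp_ids=["rs5"],
                   outcome_betas={"rs5": 0.1})

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ParameterError):
            _truth(scenario="wibble")


class TestRegion:
    def test_ar1_within_block_zero_across(self):
        region = synth.simulate_region(4, block_size=2, rho=0.9, seed=0)
        assert region.ld.r[0, 1] == pytest.approx(0.9)
        assert region.ld.r[0, 2] == 0.0
        assert region.ld.r[2, 3] == pytest.approx(0.9)

    def test_zero_rho_gives_identity(self):
        region = synth.simulate_region(6, rho=0.0, seed=0)
        assert np.allclose(region.ld.r, np.eye(6))

    def test_rho_one_rejected(self):
        with pytest.raises(ParameterError):
            synth.simulate_region(4, rho=1.0)

    def test_ld_positive_semidefinite(self):
        region = synth.simulate_region(50, block_size=10, rho=0.8, seed=1)
        assert np.linalg.eigvalsh(region.ld.r).min() >= -1e-8

    def test_positions_strictly_increasing_within_window(self):
        region = synth.simulate_region(80, seed=2)
        assert np.all(np.diff(region.positions) > 0)
        assert np.all(np.abs(region.positions - region.tss) <= 100_000)


class TestEqtlDraws:
    def test_null_pvalues_approximately_uniform(self):
        region = synth.simulate_region(2000, block_size=1, rho=0.0, seed=3)
        truth = _truth(theta=0.0, scenario="null", beta=0.0)
        records = synth.simulate_eqtl_summary(region, truth, seed=3)
        frac = np.mean([r.pval < 0.05 for r in records])
        assert abs(frac - 0.05) < 0.02

    def test_null_pvalues_pass_ks_at_5000_snps(self):
        region = synth.simulate_region(5000, block_size=1, rho=0.0, seed=11)
        truth = _truth(theta=0.0, scenario="null", beta=0.0)
        records = synth.simulate_gwas_summary(region, truth, seed=11)
        ks = stats.kstest([r.pval for r in records], "uniform")
        assert ks.pvalue > 0.01

    def test_uncorrelated_causal_snp_recovers_its_beta(self):
        region = synth.simulate_region(20, rho=0.0, seed=4)
        draws = []
        for rep in range(400):
            recs = synth.simulate_eqtl_summary(region, _truth(snp="rs7"),
                                               seed=rep)
            draws.append(recs[6].beta)
        mcse = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 0.35) < 3 * mcse

    def test_marginal_betas_follow_ld_propagation(self):
        region = synth.simulate_region(10, block_size=10, rho=0.8, seed=5)
        b_true = np.zeros(10)
        b_true[4] = 0.35
        expected = region.ld.r @ b_true
        means = np.zeros(10)
        n_rep = 500
        for rep in range(n_rep):
            recs = synth.simulate_eqtl_summary(region, _truth(snp="rs5"),
                                               seed=rep)
            means += np.array([r.beta for r in recs]) / n_rep
        se = np.array([r.se for r in recs]) / np.sqrt(n_rep)
        assert np.all(np.abs(means - expected) < 3 * se + 1e-12)

    def test_same_seed_identical_records(self):
        region = synth.simulate_region(30, seed=6)
        a = synth.simulate_eqtl_summary(region, _truth(), seed=9)
        b = synth.simulate_eqtl_summary(region, _truth(), seed=9)
        assert a == b

    def test_se_formula(self):
        region = synth.simulate_region(5, seed=7)
        [rec, *_] = synth.simulate_eqtl_summary(region, _truth(snp="rs1"),
                                                n_eqtl=10_000, seed=0)
        expected = 1 / np.sqrt(2 * region.maf[0] * (1 - region.maf[0]) * 10_000)
        assert rec.se == pytest.approx(expected)

    def test_tiny_sample_rejected(self):
        region = synth.simulate_region(5, seed=7)
        with pytest.raises(ParameterError):
            synth.simulate_eqtl_summary(region, _truth(), n_eqtl=1)


class TestGwasDraws:
    def test_full_swap_fraction_flips_every_row(self):
        region = synth.simulate_region(30, seed=8)
        truth = _truth()
        plain = synth.simulate_gwas_summary(region, truth, swap_fraction=0.0,
                                            seed=42)
        flipped = synth.simulate_gwas_summary(region, truth, swap_fraction=1.0,
                                              seed=42)
        for a, b in zip(plain, flipped):
            assert (b.effect_allele, b.other_allele) == (a.other_allele,
                                                         a.effect_allele)
            assert b.beta == pytest.approx(-a.beta)
            assert b.eaf == pytest.approx(1 - a.eaf)

    def test_null_wald_ratios_center_on_zero(self):
        from targetmr.harmonize import harmonize
        from targetmr.mr import wald_ratio
        ratios = []
        for rep in range(300):
            region = synth.simulate_region(10, seed=900 + rep)
            truth = _truth(theta=0.0, scenario="null")
            eqtl = synth.simulate_eqtl_summary(region, truth, seed=rep)
            gwas = synth.simulate_gwas_summary(region, truth, seed=50_000 + rep)
            ratios.append(wald_ratio(harmonize(eqtl[4], gwas[4])).beta)
        mcse = np.std(ratios) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios)) < 3 * mcse

    def test_effective_sample_size(self):
        assert synth.effective_sample_size(100, 100) == pytest.approx(200)
        n_eff = synth.effective_sample_size(29_612, 122_656)
        assert n_eff == pytest.approx(4 / (1 / 29_612 + 1 / 122_656))


class TestDrugTable:
    def test_replica_fostamatinib_row(self):
        rows = {c.drug_name: c for c in synth.table1_replica()}
        fo = rows["fostamatinib"]
        assert fo.gene == "TBK1"
        assert fo.action_type == "inhibitor"
        assert fo.max_phase == "approved"

    def test_replica_glutathione_row(self):
        rows = {c.drug_name: c for c in synth.table1_replica()}
        gl = rows["glutathione"]
        assert gl.max_phase == "3"
        assert gl.broad_spectrum is True
        assert gl.action_type == "cofactor"

    def test_empty_gene_list_gives_replica_only(self):
        assert len(synth.simulate_drug_table([], seed=0)) == 5
        assert synth.simulate_drug_table([], seed=0,
                                         include_table1=False) == []


class TestBundle:
    def test_bundle_reproducible_for_fixed_seed(self):
        a = synth.simulate_bundle(n_genes=5, n_causal=2, n_snps=10, seed=13)
        b = synth.simulate_bundle(n_genes=5, n_causal=2, n_snps=10, seed=13)
        assert a.eqtl == b.eqtl
        assert a.gwas == b.gwas
        assert a.blocklist == b.blocklist

    def test_scenario_counts_match_request(self):
        bundle = synth.simulate_bundle(n_genes=12, n_causal=4, n_snps=10,
                                       seed=14)
        scenarios = [t.scenario for t in bundle.truths.values()]
        assert scenarios.count("causal_shared") == 4
        assert scenarios.count("null") == 8

    def test_winners_curse_switch_conditions_on_significance(self):
        """With a weak causal effect, significance-conditioned resampling
        guarantees every emitted gene region has a discovery-significant top
        SNP (the source of winner's-curse bias)."""
        bundle = synth.simulate_bundle(n_genes=20, n_causal=0, n_snps=10,
                                       eqtl_beta=0.0, seed=21,
                                       winners_curse_p=0.01)
        by_gene = {}
        for rec in bundle.eqtl:
            by_gene.setdefault(rec.gene, []).append(rec.pval)
        assert all(min(ps) < 0.01 for ps in by_gene.values())

    def test_write_bundle_round_trips(self, tmp_path):
        from targetmr import io as tio
        bundle = synth.simulate_bundle(n_genes=3, n_causal=1, n_snps=8,
                                       seed=15)
        paths = synth.write_bundle(bundle, tmp_path / "b", seed=15)
        eqtl = tio.read_summary_stats(paths["eqtl"], kind="eqtl")
        assert len(eqtl) == len(bundle.eqtl)
        genes = tio.read_gene_annotations(paths["genes"])
        assert [g.symbol for g in genes] == [g.symbol for g in bundle.genes]
        ld = tio.read_ld_matrix(paths["ld_dir"] / "G0001.tsv")
        assert ld.snp_ids == bundle.regions["G0001"].ld.snp_ids
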