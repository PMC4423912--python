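"""Generator correctness: determinism, planted-label frequencies, count
marginals, SNP placement, and truth round-trips."""

import numpy as np
import pandas as pd
import pytest

from paraclines import SimConfig
from paraclines.config import ConfigError
from paraclines.containers import PoolSiteTable
from paraclines.diffexpr import classify_sex_bias, classify_tau
from paraclines.fst import add_fst, call_snps
from paraclines.simulate import (
    SimTruth,
    make_ortholog_map,
    simulate_counts,
    simulate_expression_truth,
    simulate_genome,
    simulate_pooled_snps,
    simulate_sex_tissue_profiles,
)


def _truth_for(cfg):
    cats = {"spA": simulate_genome(cfg, "spA"), "spB": simulate_genome(cfg, "spB")}
    orth = make_ortholog_map(cfg, cats["spA"], cats["spB"])
    return cats, orth, simulate_expression_truth(cfg, cats, orth)


class TestGenome:
    def test_intervals_disjoint_within_arm(self):
        cfg = SimConfig(n_genes_per_species=100, n_orthologs=50,
                        arms={"a1": 30, "a2": 30, "a3": 30, "a4": 30, "a5": 30}, seed=1)
        cat = simulate_genome(cfg)
        assert len(cat.genes) == 100
        for _, sub in cat.genes.groupby("arm"):
            sub = sub.sort_values("start")
            assert (sub["start"].values[1:] >= sub["end"].values[:-1]).all()
        # UTR/CDS sub-intervals tile the gene body without overlap
        for _, g in cat.genes.iterrows():
            spans = sorted(
                [(g["utr5_start"], g["utr5_end"]), (g["cds_start"], g["cds_end"]),
                 (g["utr3_start"], g["utr3_end"])]
            )
            assert spans[0][0] == g["start"] and spans[-1][1] == g["end"]
            assert spans[0][1] == spans[1][0] and spans[1][1] == spans[2][0]

    def test_determinism(self):
        cfg = SimConfig(n_genes_per_species=100, n_orthologs=50,
                        arms={"2L": 60, "3R": 60}, seed=7)
        c1, c2 = simulate_genome(cfg), simulate_genome(cfg)
        pd.testing.assert_frame_equal(c1.genes, c2.genes)
        pd.testing.assert_frame_equal(c1.inversions, c2.inversions)

    def test_inversion_fraction(self):
        cfg = SimConfig(n_genes_per_species=1000, n_orthologs=500,
                        arms={"2L": 600, "3R": 600}, inversion_fraction=0.3, seed=3)
        cat = simulate_genome(cfg)
        on_3r = cat.genes[cat.genes["arm"] == "3R"]
        inside = cat.genes_in_inversions()
        frac = sum(g in inside for g in on_3r["gene_id"]) / len(on_3r)
        assert abs(frac - 0.3) < 0.02

    def test_capacity_error_names_size(self):
        with pytest.raises(ConfigError, match="capacit"):
            SimConfig(n_genes_per_species=100, n_orthologs=10, arms={"2L": 40}, seed=0)


class TestExpressionTruth:
    def test_zero_fractions_give_flat_means(self):
        cfg = SimConfig(n_genes_per_species=200, n_orthologs=100,
                        arms={"2L": 120, "3R": 120}, de_fraction_per_temp=0.0,
                        shared_de_fraction=0.0, plasticity_fraction=0.0,
                        gei_fraction=0.0, seed=5)
        _, _, truth = _truth_for(cfg)
        cm = truth.cell_means["spA"]
        assert np.allclose(cm.values, cm.values[:, [0]])
        lab = truth.labels["spA"]
        assert not lab[["de_at_21", "de_at_29", "plastic_low", "plastic_high", "gei"]].any().any()

    def test_same_direction_prob_one(self):
        cfg = SimConfig(n_genes_per_species=2000, n_orthologs=1500,
                        arms={"2L": 1100, "3R": 1100}, shared_de_fraction=0.06,
                        de_fraction_per_temp=0.06, same_direction_prob=1.0,
                        plasticity_fraction=0.0, gei_fraction=0.0, seed=6)
        _, orth, truth = _truth_for(cfg)
        for t in (21, 29):
            pairs = truth.shared_pairs[t]
            assert len(pairs) == 90  # 0.06 * 1500 planted shared pairs
            assert (pairs["sign_a"] == pairs["sign_b"]).all()
            # the planted signs are what landed in the per-gene truth labels
            la = truth.labels["spA"].loc[pairs["gene_a"], f"de_sign_{t}"].to_numpy()
            lb = truth.labels["spB"].loc[pairs["gene_b"], f"de_sign_{t}"].to_numpy()
            assert (la == pairs["sign_a"].to_numpy()).all()
            assert (lb == pairs["sign_b"].to_numpy()).all()

    def test_de_label_fraction_binomial(self):
        cfg = SimConfig(n_genes_per_species=10000, n_orthologs=7000,
                        arms={"2L": 5200, "3R": 5200}, de_fraction_per_temp=0.06,
                        shared_de_fraction=0.01, seed=8)
        _, _, truth = _truth_for(cfg)
        n_de = int(truth.labels["spA"]["de_at_29"].sum())
        sd = np.sqrt(10000 * 0.06 * 0.94)
        assert abs(n_de - 600) <= 3 * sd

    def test_gei_genes_have_opposite_temperature_responses(self, small_experiment):
        truth = small_experiment.truth
        lab = truth.labels["spA"]
        cm = truth.cell_means["spA"]
        gei = lab.index[lab["gei"]]
        resp_low = (cm.loc[gei, "low@29"] - cm.loc[gei, "low@21"]).to_numpy()
        resp_high = (cm.loc[gei, "high@29"] - cm.loc[gei, "high@21"]).to_numpy()
        assert (np.sign(resp_low) == -np.sign(resp_high)).all()
        assert (resp_low != 0).all()

    def test_crossover_truth_is_rank_reversal(self, small_experiment):
        truth = small_experiment.truth
        lab = truth.labels["spA"]
        cm = truth.cell_means[["spA"][0]] if False else truth.cell_means["spA"]
        cross = lab.index[lab["crossover"]]
        d21 = cm.loc[cross, "high@21"] - cm.loc[cross, "low@21"]
        d29 = cm.loc[cross, "high@29"] - cm.loc[cross, "low@29"]
        assert ((np.sign(d21) * np.sign(d29)) < 0).all()
        assert ((d21.abs() + d29.abs()) > 0.5).all()


class TestCounts:
    def test_determinism(self, small_config, small_experiment):
        again = simulate_counts(small_experiment.truth, small_config, species="spA")
        pd.testing.assert_frame_equal(again.counts, small_experiment.counts["spA"].counts)

    def test_poisson_limit_variance(self):
        cfg = SimConfig(n_genes_per_species=4000, n_orthologs=2000,
                        arms={"2L": 2100, "3R": 2100}, dispersion_shape=1e6,
                        n_replicates=3, de_fraction_per_temp=0.0, shared_de_fraction=0.0,
                        plasticity_fraction=0.0, gei_fraction=0.0,
                        baseline_sd_log2=0.0, seed=9)
        cfg2 = cfg
        cats = {"spA": simulate_genome(cfg2, "spA"), "spB": simulate_genome(cfg2, "spB")}
        orth = make_ortholog_map(cfg2, cats["spA"], cats["spB"])
        truth = simulate_expression_truth(cfg2, cats, orth)
        # very large shape -> Poisson: across genes, var of replicate counts ~ mean
        truth.dispersion_shape["spA"][:] = 1e9
        cm = simulate_counts(truth, cfg2, species="spA")
        cols = cm.samples_where(population="low", temperature=21)
        sub = cm.counts[cols] / cm.design.loc[cols, "lib_factor"].values
        ratio = sub.var(axis=1, ddof=1).mean() / sub.mean(axis=1).mean()
        assert 0.9 < ratio < 1.15

    def test_nb_marginal_mean(self, small_experiment, small_config):
        cm = small_experiment.counts["spA"]
        truth = small_experiment.truth
        cols = cm.samples_where(population="low", temperature=21)
        lib = cm.design.loc[cols, "lib_factor"].values
        expected = 2.0 ** truth.cell_means["spA"]["low@21"]
        observed = (cm.counts[cols] / lib).mean(axis=1)
        # pooled across genes the relative error shrinks as 1/sqrt(n)
        rel = (observed.mean() - expected.mean()) / expected.mean()
        assert abs(rel) < 0.05

    def test_planted_effect_recovered_in_cell_means(self):
        cfg = SimConfig(n_genes_per_species=10000, n_orthologs=7000,
                        arms={"2L": 5200, "3R": 5200}, effect_size_log2=1.0,
                        plasticity_fraction=0.0, gei_fraction=0.0, n_replicates=3,
                        dispersion_shape=50.0, seed=10)
        cats = {"spA": simulate_genome(cfg, "spA"), "spB": simulate_genome(cfg, "spB")}
        orth = make_ortholog_map(cfg, cats["spA"], cats["spB"])
        truth = simulate_expression_truth(cfg, cats, orth)
        cm = simulate_counts(truth, cfg, species="spA")
        lab = truth.labels["spA"]
        up = lab.index[lab["de_sign_29"] == 1]
        lo_cols = cm.samples_where(population="low", temperature=29)
        hi_cols = cm.samples_where(population="high", temperature=29)
        lo_lib = cm.design.loc[lo_cols, "lib_factor"].values
        hi_lib = cm.design.loc[hi_cols, "lib_factor"].values
        m_lo = (cm.counts.loc[up, lo_cols] / lo_lib).mean(axis=1)
        m_hi = (cm.counts.loc[up, hi_cols] / hi_lib).mean(axis=1)
        ratio = (m_hi.sum() / m_lo.sum())
        assert abs(ratio - 2.0) < 0.1


class TestPooledSnps:
    def test_sync_determinism(self, small_config, small_experiment):
        pool, _ = simulate_pooled_snps(
            small_experiment.truth, small_experiment.catalogues["spA"], small_config, "spA"
        )
        pd.testing.assert_frame_equal(pool.sites, small_experiment.pools["spA"].sites)

    def test_zero_F_gives_near_zero_fst(self):
        cfg = SimConfig(n_genes_per_species=1500, n_orthologs=1000,
                        arms={"2L": 800, "3R": 800}, fst_background_F=0.0,
                        outlier_fraction=0.0, snps_per_gene_mean=4.0,
                        pool_coverage_mean=200.0, seed=12)
        cats = {"spA": simulate_genome(cfg, "spA"), "spB": simulate_genome(cfg, "spB")}
        orth = make_ortholog_map(cfg, cats["spA"], cats["spB"])
        truth = simulate_expression_truth(cfg, cats, orth)
        pool, _ = simulate_pooled_snps(truth, cats["spA"], cfg, "spA")
        rec = add_fst(call_snps(pool)[0])
        # read-sampling noise alone leaves a small positive residual
        assert rec["fst"].mean() < 0.02

    def test_outlier_flags_and_annotation_recorded(self, small_experiment):
        truth = small_experiment.truth
        snp = truth.snps["spA"]
        assert {"arm", "pos", "gene_id", "class", "outlier", "true_p1", "true_p2"} <= set(
            snp.columns
        )
        assert set(snp["class"]) <= {"5'UTR", "3'UTR", "CDS"}

    def test_coverage_error(self):
        with pytest.raises(ConfigError):
            SimConfig(pool_coverage_mean=0.0)


class TestSexTissue:
    def test_noise_free_label_recovery(self):
        cfg = SimConfig(seed=13)
        sex, tissue, labels = simulate_sex_tissue_profiles(cfg, n_genes=1500,
                                                          male_biased_fraction=0.28)
        called = classify_sex_bias(sex["male_fpkm"], sex["female_fpkm"])
        assert (called == labels["male_biased"]).all()

    def test_tau_extremes_downstream(self):
        cfg = SimConfig(seed=14)
        _, tissue, labels = simulate_sex_tissue_profiles(cfg, n_genes=500)
        taus = classify_tau(tissue)
        single = labels["tissue_specific"]
        assert (taus.loc[single, "tau"] == 1.0).all()
        assert (taus.loc[~single, "tau"] < 0.9).all()

    def test_needs_two_tissues(self):
        with pytest.raises(ConfigError):
            simulate_sex_tissue_profiles(SimConfig(), tissues=("testis",))


def test_truth_roundtrip(tmp_path, small_experiment, small_config):
    truth = small_experiment.truth
    truth.to_dir(tmp_path / "truth")
    back = SimTruth.from_dir(tmp_path / "truth", temperatures=small_config.temperatures)
    for sp in truth.cell_means:
        pd.testing.assert_frame_equal(
            truth.cell_means[sp], back.cell_means[sp], check_dtype=False
        )
        pd.testing.assert_frame_equal(truth.labels[sp], back.labels[sp], check_dtype=False)
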