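"""Pooled SNP calling, F_ST estimation, tail flags, annotation and the
matched bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paraclines.containers import GeneCatalogue, OrthologMap, PoolSiteTable, SYNC_BASES
from paraclines.fst import (
    add_fst,
    annotate_snps,
    call_snps,
    de_outlier_enrichment,
    estimate_fst,
    fst_tail_outliers,
    shared_outlier_gene_overlap,
    snp_count_matched_bootstrap,
    tail_column,
)


def make_sites(rows):
    """rows: list of (arm, pos, ref, pool1 6-counts, pool2 6-counts)."""
    data = {"arm": [], "pos": [], "ref": []}
    for p in (1, 2):
        for b in SYNC_BASES:
            data[f"p{p}_{b}"] = []
    for arm, pos, ref, c1, c2 in rows:
        data["arm"].append(arm)
        data["pos"].append(pos)
        data["ref"].append(ref)
        for p, counts in ((1, c1), (2, c2)):
            for b, c in zip(SYNC_BASES, counts):
                data[f"p{p}_{b}"].append(c)
    return PoolSiteTable(pd.DataFrame(data))


class TestCallSnps:
    def test_low_coverage_one_pool_removed(self):
        sites = make_sites([
            ("2L", 10, "A", (5, 4, 0, 0, 0, 0), (50, 50, 0, 0, 0, 0)),   # cov 9 in pool 1
            ("2L", 20, "A", (6, 4, 0, 0, 0, 0), (50, 50, 0, 0, 0, 0)),   # cov 10 boundary
        ])
        rec, log = call_snps(sites)
        assert log["removed_low_coverage"] == 1
        assert list(rec["pos"]) == [20]

    def test_single_read_minor_allele(self):
        sites = make_sites([
            ("2L", 10, "A", (99, 1, 0, 0, 0, 0), (100, 0, 0, 0, 0, 0)),  # 1 read total
            ("2L", 20, "A", (99, 1, 0, 0, 0, 0), (99, 1, 0, 0, 0, 0)),   # 2 reads total
        ])
        rec, log = call_snps(sites)
        assert log["removed_single_read_allele"] == 1
        assert list(rec["pos"]) == [20]

    def test_maf_filter(self):
        sites = make_sites([
            ("2L", 10, "A", (995, 2, 0, 0, 0, 0), (1000, 1, 0, 0, 0, 0)),  # maf ~0.0015
            ("2L", 20, "A", (90, 10, 0, 0, 0, 0), (95, 5, 0, 0, 0, 0)),
        ])
        rec, log = call_snps(sites)
        assert log["removed_low_maf"] == 1
        assert list(rec["pos"]) == [20]

    def test_multiallelic_dropped(self):
        sites = make_sites([
            ("2L", 10, "A", (50, 30, 20, 0, 0, 0), (50, 30, 20, 0, 0, 0)),
        ])
        rec, log = call_snps(sites)
        assert log["removed_multiallelic"] == 1 and len(rec) == 0

    def test_filter_expectation_on_simulated_sites(self):
        rng = np.random.default_rng(0)
        n = 10000
        maf = rng.uniform(0, 0.5, n)
        rows = []
        for i in range(n):
            c1 = rng.binomial(100, maf[i])
            c2 = rng.binomial(100, maf[i])
            rows.append(("2L", i + 1, "A", (100 - c1, c1, 0, 0, 0, 0),
                         (100 - c2, c2, 0, 0, 0, 0)))
        rec, _ = call_snps(make_sites(rows))
        # analytic expectation: retained iff pooled minor count >= 2 and maf >= 0.01
        from scipy.stats import binom
        p_keep = np.mean(1 - binom.cdf(1, 200, np.minimum(maf, 1 - maf)))
        se = np.sqrt(p_keep * (1 - p_keep) / n)
        assert abs(len(rec) / n - p_keep) < 3 * se + 0.01


class TestEstimateFst:
    @pytest.mark.parametrize("p1,p2,want", [(0.5, 0.5, 0.0), (1.0, 0.0, 1.0),
                                            (0.2, 0.8, 0.36), (0.0, 0.0, 0.0)])
    def test_hand_values(self, p1, p2, want):
        assert estimate_fst(p1, p2) == pytest.approx(want)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_bounds_and_symmetry(self, p1, p2):
        f = estimate_fst(p1, p2)
        assert 0.0 <= f <= 1.0
        assert f == pytest.approx(estimate_fst(p2, p1))

    def test_grid_against_hand_formula(self):
        grid = np.linspace(0.0, 1.0, 21)
        for p1 in grid:
            for p2 in grid:
                hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
                pbar = (p1 + p2) / 2
                ht = 2 * pbar * (1 - pbar)
                want = 0.0 if ht == 0 else max(0.0, (ht - hs) / ht)
                assert estimate_fst(p1, p2) == pytest.approx(want, abs=1e-12)

    def test_estimator_tracks_true_differentiation_at_high_coverage(self):
        # read-based estimate vs the true-frequency statistic, coverage 500
        rng = np.random.default_rng(1)
        n = 2000
        F = rng.uniform(0.01, 0.5, n)
        p_anc = rng.uniform(0.2, 0.8, n)
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
        true_fst = estimate_fst(p1, p2)
        r1 = rng.binomial(500, p1) / 500
        r2 = rng.binomial(500, p2) / 500
        est = estimate_fst(r1, r2)
        from scipy.stats import spearmanr
        rho = spearmanr(true_fst, est).statistic
        assert rho > 0.9


class TestTailOutliers:
    def test_exact_counts_distinct_values(self):
        rng = np.random.default_rng(2)
        rec = pd.DataFrame({"arm": "2L", "pos": np.arange(1000) + 1,
                            "fst": rng.permutation(np.linspace(0, 1, 1000))})
        out, log = fst_tail_outliers(rec)
        assert out["tail_0.01"].sum() == 10
        assert out["tail_0.005"].sum() == 5
        assert out["tail_0.0025"].sum() == 2
        assert log["ties_excluded"] == 0

    def test_all_equal_no_outliers(self):
        rec = pd.DataFrame({"arm": "2L", "pos": np.arange(1000) + 1, "fst": 0.3})
        out, log = fst_tail_outliers(rec)
        assert out["tail_0.01"].sum() == 0
        assert log["ties_excluded"] > 0

    def test_per_arm_independence(self):
        rng = np.random.default_rng(3)
        rec = pd.DataFrame({
            "arm": ["2L"] * 1000 + ["3R"] * 1000,
            "pos": list(range(1, 1001)) * 2,
            "fst": np.concatenate([rng.uniform(0, 0.1, 1000), rng.uniform(0.5, 1.0, 1000)]),
        })
        out, _ = fst_tail_outliers(rec, quantiles=(0.01,))
        per_arm = out.groupby("arm")["tail_0.01"].sum()
        assert per_arm["2L"] == 10 and per_arm["3R"] == 10

    def test_nesting_invariant_and_sort_oracle(self):
        rng = np.random.default_rng(4)
        fst = np.round(rng.uniform(0, 1, 1500), 3)  # ties likely
        rec = pd.DataFrame({"arm": "2L", "pos": np.arange(1500) + 1, "fst": fst})
        out, _ = fst_tail_outliers(rec)
        t1, t2, t3 = (out[tail_column(q)] for q in (0.01, 0.005, 0.0025))
        assert (t3 <= t2).all() and (t2 <= t1).all()
        # sort-based oracle: top floor(qn) minus ties at the cut value
        srt = np.sort(fst)
        for q, flags in ((0.01, t1), (0.005, t2), (0.0025, t3)):
            m = int(np.floor(q * len(fst)))
            thr = srt[len(fst) - m - 1]
            assert (flags.to_numpy() == (fst > thr)).all()

    def test_small_arm_skipped(self):
        rec = pd.DataFrame({"arm": "tiny", "pos": [1, 2, 3], "fst": [0.1, 0.2, 0.3]})
        with pytest.warns(UserWarning, match="too few"):
            out, log = fst_tail_outliers(rec, quantiles=(0.01,))
        assert out["tail_0.01"].sum() == 0 and log["skipped_arms"]


def _toy_catalogue():
    genes = pd.DataFrame(
        [
            ("gA", "2L", 100, 400, "+", 300, 100, 150, 150, 350, 350, 400),
            ("gB", "2L", 300, 600, "+", 300, 300, 340, 340, 520, 520, 600),  # overlaps gA
            ("gC", "3R", 100, 400, "+", 300, 100, 150, 150, 350, 350, 400),
        ],
        columns=["gene_id", "arm", "start", "end", "strand", "exon_length",
                 "utr5_start", "utr5_end", "cds_start", "cds_end",
                 "utr3_start", "utr3_end"],
    )
    return GeneCatalogue(genes)


class TestAnnotate:
    def test_simple_class_assignment(self):
        cat = _toy_catalogue()
        rec = pd.DataFrame({"arm": ["2L", "2L", "2L"], "pos": [120, 200, 700]})
        out = annotate_snps(rec, cat)
        assert list(out["class"]) == ["5'UTR", "CDS", "other"]
        assert out["gene_id"][1] == "gA"

    def test_precedence_cds_over_utr3(self):
        cat = _toy_catalogue()
        # position 360 (1-based) = 359 0-based: 3'UTR of gA and CDS of gB
        out = annotate_snps(pd.DataFrame({"arm": ["2L"], "pos": [360]}), cat)
        assert out["class"][0] == "CDS"
        assert set(out["host_genes"][0].split(",")) == {"gA", "gB"}

    def test_class_proportions_match_interval_lengths(self, small_experiment):
        cat = small_experiment.catalogues["spA"]
        rng = np.random.default_rng(5)
        arm = "2L"
        sub = cat.genes[cat.genes["arm"] == arm]
        lo, hi = int(sub["start"].min()), int(sub["end"].max())
        pos = rng.integers(lo, hi, 20000) + 1
        out = annotate_snps(pd.DataFrame({"arm": arm, "pos": pos}), cat)
        feats = cat.feature_table()
        feats = feats[feats["arm"] == arm]
        span = hi - lo
        for cls in ("5'UTR", "CDS", "3'UTR"):
            frac_len = (feats.loc[feats["class"] == cls, "end"]
                        - feats.loc[feats["class"] == cls, "start"]).sum() / span
            frac_obs = (out["class"] == cls).mean()
            se = np.sqrt(frac_len * (1 - frac_len) / 20000)
            assert abs(frac_obs - frac_len) < 3 * se + 0.01


class TestEnrichment:
    def test_no_tail_snps_p_one(self):
        cat = _toy_catalogue()
        rec = pd.DataFrame({
            "arm": ["2L"], "pos": [200], "fst": [0.1], "tail_0.005": [False],
        })
        rec = annotate_snps(rec, cat)
        res = de_outlier_enrichment({"gA"}, rec, cat, "CDS", 0.005, {"gA", "gB", "gC"})
        assert res.k == 0 and res.pvalue == 1.0

    def test_empty_universe_errors(self):
        cat = _toy_catalogue()
        rec = annotate_snps(pd.DataFrame({"arm": ["2L"], "pos": [200]}), cat)
        rec["tail_0.005"] = False
        with pytest.raises(ValueError, match="universe"):
            de_outlier_enrichment({"gA"}, rec, cat, "CDS", 0.005, set())

    def test_shared_outlier_overlap_disjoint_sets(self):
        genes_a = [f"a{i}" for i in range(50)]
        genes_b = [f"b{i}" for i in range(50)]
        orth = OrthologMap(pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b}))

        def rec_for(genes, outliers):
            return pd.DataFrame({
                "arm": "2L", "pos": range(1, len(genes) + 1),
                "class": "CDS", "gene_id": genes,
                "tail_0.005": [g in outliers for g in genes],
            })

        ra = rec_for(genes_a, set(genes_a[:10]))
        rb = rec_for(genes_b, set(genes_b[40:]))
        res, shared = shared_outlier_gene_overlap(ra, rb, orth, "CDS", 0.005)
        assert res.k == 0 and len(shared) == 0 and res.pvalue >= 0.5


class TestBootstrap:
    def _setup(self, n=200, seed=6):
        rng = np.random.default_rng(seed)
        genes_a = [f"a{i}" for i in range(n)]
        genes_b = [f"b{i}" for i in range(n)]
        orth = OrthologMap(pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b}))
        sc_a = pd.Series(rng.poisson(5, n) + 1, index=genes_a)
        sc_b = pd.Series(rng.poisson(5, n) + 1, index=genes_b)
        return genes_a, genes_b, orth, sc_a, sc_b, rng

    def test_single_replicate_deterministic(self):
        genes_a, genes_b, orth, sc_a, sc_b, rng = self._setup()
        oa = genes_a[:20]
        ob = genes_b[:20]
        b1 = snp_count_matched_bootstrap(oa, ob, sc_a, sc_b, orth, n_boot=1, seed=3)
        b2 = snp_count_matched_bootstrap(oa, ob, sc_a, sc_b, orth, n_boot=1, seed=3)
        assert (b1["distribution"] == b2["distribution"]).all()

    def test_planted_correlation_detected(self):
        genes_a, genes_b, orth, sc_a, sc_b, rng = self._setup()
        # the same ortholog pairs are outliers in both species
        idx = rng.choice(len(genes_a), 25, replace=False)
        oa = [genes_a[i] for i in idx]
        ob = [genes_b[i] for i in idx]
        res = snp_count_matched_bootstrap(oa, ob, sc_a, sc_b, orth, n_boot=200, seed=4)
        assert res["observed"] == 25
        assert res["pvalue"] <= 0.025
        assert res["observed"] > np.percentile(res["distribution"], 97.5)

    def test_matching_respects_snp_counts(self):
        # a unique very-high-count outlier gene can only be replaced by itself,
        # so every replicate reproduces the observed sharing exactly
        genes_a, genes_b, orth, sc_a, sc_b, rng = self._setup()
        sc_a[genes_a[0]] = 1000
        sc_b[genes_b[0]] = 1000
        res = snp_count_matched_bootstrap(
            [genes_a[0]], [genes_b[0]], sc_a, sc_b, orth, n_boot=50, seed=0
        )
        assert res["observed"] == 1
        assert (res["distribution"] == 1).all()
        assert res["pvalue"] == 1.0
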