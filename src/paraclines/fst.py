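"""Pooled allele-frequency F_ST, per-arm tail outliers, and enrichments.

Works from PoPoolation2-style sync content: per-site A:T:C:G:N:del read
counts for one pool per population.  F_ST is the classical
heterozygosity-based estimator on pooled read frequencies,
(h_T - mean(h_S)) / h_T with h = 2p(1-p).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import GeneCatalogue, OrthologMap, PoolSiteTable
from .parallelism import OverlapResult, hypergeom_overlap

_BASE_COLS = ("A", "T", "C", "G")

# annotation precedence when a position falls in several feature classes
CLASS_PRECEDENCE = ("CDS", "3'UTR", "5'UTR")


# ---------------------------------------------------------------------------
# SNP calling


def call_snps(
    table: PoolSiteTable,
    min_coverage: int = 10,
    min_allele_reads: int = 2,
    min_maf: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Filter sites to well-supported biallelic SNPs.

    Filters, in order: per-pool base coverage below ``min_coverage``
    (either pool) removes the site; a pooled minor-allele count below
    ``min_allele_reads`` removes it; a pooled minor-allele frequency below
    ``min_maf`` removes it.  Sites with a third allele at or above
    ``min_allele_reads`` after filtering are dropped and counted.

    Returns (records, removal log).  Records carry per-pool major/minor
    counts and minor-allele frequencies.
    """
    c1 = np.stack([table.sites[f"p1_{b}"].to_numpy(np.int64) for b in _BASE_COLS], axis=1)
    c2 = np.stack([table.sites[f"p2_{b}"].to_numpy(np.int64) for b in _BASE_COLS], axis=1)
    pooled = c1 + c2
    cov1, cov2 = c1.sum(axis=1), c2.sum(axis=1)

    log = {}
    alive = np.ones(len(pooled), dtype=bool)

    low_cov = (cov1 < min_coverage) | (cov2 < min_coverage)
    log["removed_low_coverage"] = int((alive & low_cov).sum())
    alive &= ~low_cov

    order = np.argsort(pooled, axis=1)
    major_idx = order[:, -1]
    minor_idx = order[:, -2]
    third_idx = order[:, -3]
    rows = np.arange(len(pooled))
    minor_count = pooled[rows, minor_idx]
    major_count = pooled[rows, major_idx]

    single_read = minor_count < min_allele_reads
    log["removed_single_read_allele"] = int((alive & single_read).sum())
    alive &= ~single_read

    with np.errstate(invalid="ignore", divide="ignore"):
        maf = minor_count / (major_count + minor_count)
    low_maf = maf < min_maf
    log["removed_low_maf"] = int((alive & low_maf).sum())
    alive &= ~low_maf

    multi = pooled[rows, third_idx] >= min_allele_reads
    log["removed_multiallelic"] = int((alive & multi).sum())
    alive &= ~multi
    log["retained"] = int(alive.sum())

    idx = np.where(alive)[0]
    base_arr = np.array(_BASE_COLS)
    rec = pd.DataFrame(
        {
            "arm": table.sites["arm"].to_numpy()[idx],
            "pos": table.sites["pos"].to_numpy()[idx],
            "ref": table.sites["ref"].to_numpy()[idx],
            "major": base_arr[major_idx[idx]],
            "minor": base_arr[minor_idx[idx]],
            "p1_major": c1[idx, major_idx[idx]],
            "p1_minor": c1[idx, minor_idx[idx]],
            "p2_major": c2[idx, major_idx[idx]],
            "p2_minor": c2[idx, minor_idx[idx]],
        }
    )
    for p in (1, 2):
        tot = rec[f"p{p}_major"] + rec[f"p{p}_minor"]
        rec[f"p{p}_freq"] = np.where(tot > 0, rec[f"p{p}_minor"] / tot, np.nan)
    return rec.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# F_ST


def estimate_fst(p1, p2):
    """Classical F_ST from two population allele frequencies.

    F_ST = (h_T - (h_1 + h_2)/2) / h_T with h = 2p(1-p) and h_T computed
    at the mean frequency; 0 where h_T = 0.  Accepts scalars or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, 0.0)
    fst = np.clip(fst, 0.0, 1.0)
    return float(fst) if fst.ndim == 0 else fst


def add_fst(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    records["fst"] = estimate_fst(records["p1_freq"].values, records["p2_freq"].values)
    return records


# ---------------------------------------------------------------------------
# tail outliers


def tail_column(q: float) -> str:
    return f"tail_{q:g}"


def fst_tail_outliers(
    records: pd.DataFrame,
    quantiles=(0.01, 0.005, 0.0025),
) -> tuple[pd.DataFrame, dict]:
    """Flag per-arm upper-tail F_ST outliers at each quantile.

    Within each arm, the top floor(q * n) sites are flagged using a
    strictly-greater rule against the largest unflagged value, so ties at
    the threshold are excluded (and counted in the log).  Arms with fewer
    than 1/q sites are skipped for that quantile.
    """
    records = records.copy()
    log = {"skipped_arms": [], "ties_excluded": 0}
    for q in quantiles:
        records[tail_column(q)] = False
    for arm, sub in records.groupby("arm"):
        fst = sub["fst"].to_numpy(float)
        n = len(fst)
        srt = np.sort(fst)
        for q in quantiles:
            m = int(np.floor(q * n))
            if n < 1.0 / q or m < 1:
                log["skipped_arms"].append((arm, q))
                warnings.warn(f"arm {arm}: too few sites for the {q:g} tail", stacklevel=2)
                continue
            thr = srt[n - m - 1]
            flag = fst > thr
            log["ties_excluded"] += int(m - flag.sum())
            records.loc[sub.index[flag], tail_column(q)] = True
    return records, log


# ---------------------------------------------------------------------------
# annotation


def annotate_snps(records: pd.DataFrame, catalogue: GeneCatalogue) -> pd.DataFrame:
    """Assign each SNP an annotation class and host gene(s).

    Sync positions are 1-based; catalogue intervals are 0-based half-open.
    When a position falls in several classes (overlapping genes), the
    class follows the precedence CDS > 3'UTR > 5'UTR; all host genes are
    recorded.  Positions outside every feature are "other".
    """
    feats = catalogue.feature_table()
    trees: dict[str, IntervalTree] = {}
    for arm, sub in feats.groupby("arm"):
        tree = IntervalTree()
        for _, f in sub.iterrows():
            tree.addi(int(f["start"]), int(f["end"]), (f["class"], f["gene_id"]))
        trees[arm] = tree

    classes, primary, hosts = [], [], []
    arms = records["arm"].to_numpy()
    pos0 = records["pos"].to_numpy(np.int64) - 1
    for arm, p in zip(arms, pos0):
        tree = trees.get(arm)
        hits = sorted(tree[int(p)]) if tree is not None else []
        if not hits:
            classes.append("other")
            primary.append("")
            hosts.append("")
            continue
        by_class = {}
        all_hosts = []
        for iv in hits:
            cls, gene = iv.data
            by_class.setdefault(cls, []).append(gene)
            all_hosts.append(gene)
        chosen = next(c for c in CLASS_PRECEDENCE if c in by_class)
        classes.append(chosen)
        primary.append(sorted(by_class[chosen])[0])
        hosts.append(",".join(sorted(set(all_hosts))))
    out = records.copy()
    out["class"] = classes
    out["gene_id"] = primary
    out["host_genes"] = hosts
    return out


# ---------------------------------------------------------------------------
# enrichments


def _genes_with_snp(records: pd.DataFrame, cls: str, tail: str | None = None) -> set:
    sub = records[(records["class"] == cls) & (records["gene_id"] != "")]
    if tail is not None:
        sub = sub[sub[tail]]
    return set(sub["gene_id"])


def de_outlier_enrichment(
    de_genes,
    records: pd.DataFrame,
    catalogue: GeneCatalogue,
    cls: str,
    tail_level: float,
    expressed_genes,
) -> OverlapResult:
    """Enrichment of tail SNPs of one annotation class in DE genes.

    Universe: expressed genes possessing at least one annotated feature of
    the class.  K = DE genes in the universe, n = universe genes with a
    tail SNP of the class, k = their intersection.
    """
    feats = catalogue.feature_table()
    with_class = set(feats.loc[feats["class"] == cls, "gene_id"])
    universe = with_class & set(expressed_genes)
    if not universe:
        raise ValueError(f"empty universe for class {cls}")
    K_set = set(de_genes) & universe
    n_set = _genes_with_snp(records, cls, tail_column(tail_level)) & universe
    return hypergeom_overlap(len(universe), len(K_set), len(n_set), len(K_set & n_set))


def shared_outlier_gene_overlap(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    orthologs: OrthologMap,
    cls: str,
    tail_level: float,
) -> tuple[OverlapResult, pd.DataFrame]:
    """Cross-species sharing of genes bearing tail SNPs of one class.

    Universe: one-to-one ortholog pairs with at least one SNP of the class
    in BOTH species.  Returns the overlap result and the shared pairs.
    """
    any_a = _genes_with_snp(records_a, cls)
    any_b = _genes_with_snp(records_b, cls)
    pairs = orthologs.pairs
    uni = pairs[pairs["gene_a"].isin(any_a) & pairs["gene_b"].isin(any_b)]
    if uni.empty:
        raise ValueError(f"no ortholog pairs with {cls} SNPs in both species")
    tail = tail_column(tail_level)
    out_a = _genes_with_snp(records_a, cls, tail)
    out_b = _genes_with_snp(records_b, cls, tail)
    in_a = uni["gene_a"].isin(out_a).to_numpy()
    in_b = uni["gene_b"].isin(out_b).to_numpy()
    res = hypergeom_overlap(len(uni), int(in_a.sum()), int(in_b.sum()), int((in_a & in_b).sum()))
    return res, uni[in_a & in_b].reset_index(drop=True)


# ---------------------------------------------------------------------------
# SNP-count-matched bootstrap


def _matched_sample(rng, required_counts, cand_ids, cand_counts):
    """Sample |required| genes without replacement, each with SNP count >=
    the required count it replaces (required processed in descending order)."""
    order = np.argsort(cand_counts)[::-1]
    ids_desc = cand_ids[order]
    counts_desc = cand_counts[order]
    pool: list = []
    j = 0
    picked = []
    for c in sorted(required_counts, reverse=True):
        while j < len(ids_desc) and counts_desc[j] >= c:
            pool.append(ids_desc[j])
            j += 1
        if not pool:
            raise ValueError(f"no candidate genes left with SNP count >= {c}")
        i = int(rng.integers(len(pool)))
        picked.append(pool[i])
        pool[i] = pool[-1]
        pool.pop()
    return picked


def snp_count_matched_bootstrap(
    outlier_genes_a,
    outlier_genes_b,
    snp_counts_a: pd.Series,
    snp_counts_b: pd.Series,
    orthologs: OrthologMap,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Null distribution of shared outlier-gene counts, matched on SNP count.

    Each replicate draws, per species, a random gene set of the observed
    size in which every drawn gene has at least as many SNPs as the
    observed gene it replaces (sampling without replacement), then counts
    shared ortholog pairs.  Empirical p uses the plus-one rule.
    """
    rng = np.random.default_rng(seed)
    a2b = orthologs.a_to_b
    set_b = set(outlier_genes_b)
    observed = sum(1 for g in outlier_genes_a if a2b.get(g) in set_b)

    req_a = snp_counts_a.loc[list(outlier_genes_a)].to_numpy()
    req_b = snp_counts_b.loc[list(outlier_genes_b)].to_numpy()
    cand_a_ids = snp_counts_a.index.to_numpy()
    cand_a_counts = snp_counts_a.to_numpy()
    cand_b_ids = snp_counts_b.index.to_numpy()
    cand_b_counts = snp_counts_b.to_numpy()

    dist = np.empty(n_boot, dtype=np.int64)
    for r in range(n_boot):
        sa = _matched_sample(rng, req_a, cand_a_ids, cand_a_counts)
        sb = set(_matched_sample(rng, req_b, cand_b_ids, cand_b_counts))
        dist[r] = sum(1 for g in sa if a2b.get(g) in sb)
    p = (1 + int((dist >= observed).sum())) / (n_boot + 1)
    return {
        "observed": int(observed),
        "distribution": dist,
        "median": float(np.median(dist)),
        "pvalue": float(p),
        "n_boot": n_boot,
    }
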