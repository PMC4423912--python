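"""Spatial and chromosomal tests on gene sets.

Physical-clustering randomization, per-arm and X-vs-autosome chi-square
distribution tests, inversion-span enrichment, and a generic flat-term
enrichment carrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneCatalogue
from .diffexpr import bh_adjust
from .parallelism import OverlapResult, hypergeom_overlap


@dataclass
class ClusteringResult:
    observed_median_distance: float
    observed_adjacent_pairs: int
    perm_median_distances: np.ndarray
    perm_adjacent_pairs: np.ndarray
    p_median_lower: float
    p_adjacent_upper: float
    per_arm_median: dict = field(default_factory=dict)
    excluded_arms: list = field(default_factory=list)
    seed: int = 0


def _distance_stats(positions_by_arm: dict, de_index_by_arm: dict):
    """Median gap between consecutive selected genes (pooled over arms) and
    the number of catalogue-adjacent selected pairs."""
    gaps = []
    adjacent = 0
    per_arm = {}
    for arm, idx in de_index_by_arm.items():
        idx = np.sort(idx)
        if len(idx) >= 2:
            starts = positions_by_arm[arm][idx]
            g = np.diff(starts)
            gaps.append(g)
            per_arm[arm] = float(np.median(g))
            adjacent += int((np.diff(idx) == 1).sum())
    med = float(np.median(np.concatenate(gaps))) if gaps else float("nan")
    return med, adjacent, per_arm


def clustering_randomization(
    de_genes,
    catalogue: GeneCatalogue,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusteringResult:
    """Are the selected genes physically clustered on their arms?

    Per permutation, the observed per-arm gene counts are redrawn without
    replacement from that arm's catalogue; the statistics are the pooled
    median start-to-start gap between consecutive selected genes
    (clustering pulls it down; lower-tail p) and the count of pairs
    adjacent in catalogue order (upper-tail p).  Empirical p-values use
    the plus-one rule and are never zero.
    """
    rng = np.random.default_rng(seed)
    de_set = set(de_genes)
    missing = de_set - set(catalogue.genes["gene_id"])
    if missing:
        raise ValueError(f"{len(missing)} selected genes absent from catalogue")

    positions_by_arm, de_idx_by_arm, n_by_arm, excluded = {}, {}, {}, []
    for arm, sub in catalogue.genes.groupby("arm"):
        sub = sub.sort_values("start").reset_index(drop=True)
        positions_by_arm[arm] = sub["start"].to_numpy(np.int64)
        idx = np.where(sub["gene_id"].isin(de_set))[0]
        if len(idx) < 2:
            if len(idx) > 0:
                excluded.append(arm)
            continue
        de_idx_by_arm[arm] = idx
        n_by_arm[arm] = len(sub)

    obs_med, obs_adj, per_arm = _distance_stats(positions_by_arm, de_idx_by_arm)

    perm_med = np.empty(n_perm)
    perm_adj = np.empty(n_perm, dtype=np.int64)
    for r in range(n_perm):
        drawn = {
            arm: rng.choice(n_by_arm[arm], size=len(idx), replace=False)
            for arm, idx in de_idx_by_arm.items()
        }
        perm_med[r], perm_adj[r], _ = _distance_stats(positions_by_arm, drawn)

    p_med = (1 + int((perm_med <= obs_med).sum())) / (n_perm + 1)
    p_adj = (1 + int((perm_adj >= obs_adj).sum())) / (n_perm + 1)
    return ClusteringResult(
        obs_med, obs_adj, perm_med, perm_adj, p_med, p_adj, per_arm, excluded, seed
    )


def arm_distribution_test(de_genes, catalogue: GeneCatalogue) -> pd.DataFrame:
    """Per-arm 2x2 chi-square of DE status vs arm membership, plus a pooled
    X-vs-autosome row.

    When any expected cell drops below 5 the test switches to the exact
    hypergeometric (Fisher) form, noted in the ``method`` column.
    """
    arm_of = catalogue.arm_of()
    de_set = set(de_genes)
    total = len(arm_of)
    total_de = sum(1 for g in arm_of.index if g in de_set)

    def one_test(on_mask: np.ndarray, label: str):
        n_on = int(on_mask.sum())
        de_on = int(sum(1 for g, m in zip(arm_of.index, on_mask) if m and g in de_set))
        table = np.array(
            [[de_on, total_de - de_on], [n_on - de_on, (total - total_de) - (n_on - de_on)]]
        )
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected < 5).any():
            _, p = stats.fisher_exact(table)
            method, chi2 = "hypergeometric_exact", float("nan")
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            method = "chi2"
        return {
            "set": label,
            "genes_on": n_on,
            "de_on": de_on,
            "prop_de_on": de_on / n_on if n_on else float("nan"),
            "prop_de_off": (total_de - de_on) / (total - n_on) if total > n_on else float("nan"),
            "chi2": float(chi2) if method == "chi2" else float("nan"),
            "pvalue": float(p),
            "method": method,
        }

    rows = []
    arms_arr = arm_of.to_numpy()
    for arm in catalogue.arms:
        rows.append(one_test(arms_arr == arm, arm))
    is_x = np.isin(arms_arr, ["X"])
    if is_x.any():
        rows.append(one_test(is_x, "X_vs_autosome"))
    return pd.DataFrame(rows).set_index("set")


def inversion_enrichment(
    de_genes,
    catalogue: GeneCatalogue,
    inversion_spans: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Enrichment of DE genes inside inversion spans (midpoint membership).

    Universe: autosomal genes.  For each span two tests are reported:
    inside-vs-all-autosomal and inside-vs-outside-span universes.  Empty
    spans are skipped with a warning.
    """
    spans = inversion_spans if inversion_spans is not None else catalogue.inversions
    arm_of = catalogue.arm_of()
    mid = catalogue.midpoints()
    auto = arm_of.index[arm_of != "X"]
    de_auto = set(de_genes) & set(auto)

    known_arms = set(catalogue.arms)
    # genes inside any span, for the inside-vs-unspanned universe
    in_any_span: set = set()
    for _, sp in spans.iterrows():
        in_any_span.update(
            g for g in auto
            if arm_of[g] == sp["arm"] and sp["start"] <= mid[g] < sp["end"]
        )
    unspanned = [g for g in auto if g not in in_any_span]

    rows = []
    for _, sp in spans.iterrows():
        if sp["arm"] not in known_arms:
            raise ValueError(f"inversion span on unknown arm {sp['arm']!r}")
        inside = [
            g for g in auto
            if arm_of[g] == sp["arm"] and sp["start"] <= mid[g] < sp["end"]
        ]
        if not inside:
            warnings.warn(f"span {sp['name']} contains no genes; skipped", stacklevel=2)
            continue
        k = len(set(inside) & de_auto)
        res_all = hypergeom_overlap(len(auto), len(inside), len(de_auto), k)
        # inside this span vs autosomal genes not spanned by any inversion
        uni2 = list(inside) + unspanned
        de_uni2 = set(uni2) & de_auto
        n_out = len(unspanned)
        de_out = len(set(unspanned) & de_auto)
        res_out = hypergeom_overlap(len(uni2), len(inside), len(de_uni2), k)
        rows.append(
            {
                "name": sp["name"],
                "arm": sp["arm"],
                "genes_inside": len(inside),
                "de_inside": k,
                "prop_de_inside": k / len(inside),
                "prop_de_outside": de_out / n_out if n_out else float("nan"),
                "expected": res_all.expected,
                "fold": res_all.fold,
                "pvalue_vs_all": res_all.pvalue,
                "pvalue_vs_outside": res_out.pvalue,
            }
        )
    return pd.DataFrame(rows)


def term_enrichment(
    gene_sets: dict,
    query,
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of the query in each term set,
    BH-corrected across terms; terms with no universe overlap are skipped."""
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query set is not contained in the universe")
    rows = []
    for term, genes in gene_sets.items():
        K_set = set(genes) & universe
        if not K_set:
            continue
        res = hypergeom_overlap(len(universe), len(K_set), len(query), len(K_set & query))
        rows.append({"term": term, **res.as_dict()})
    if not rows:
        return pd.DataFrame(columns=["term", "N", "K", "n", "k", "expected", "fold",
                                     "pvalue", "qvalue"])
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out.sort_values("pvalue").reset_index(drop=True)
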