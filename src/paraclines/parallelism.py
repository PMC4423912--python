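"""Cross-species parallel-differentiation statistics.

Overlap enrichment between ortholog-mapped gene sets (upper-tail
hypergeometric), direction concordance of fold changes, genome-wide sign
concordance, and the cross-species fold-change correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OrthologMap


@dataclass
class OverlapResult:
    """(N, K, n, k) contingency of two gene sets drawn from one universe."""

    N: int
    K: int
    n: int
    k: int
    expected: float
    fold: float
    pvalue: float

    def as_dict(self) -> dict:
        return {
            "N": self.N, "K": self.K, "n": self.n, "k": self.k,
            "expected": self.expected, "fold": self.fold, "pvalue": self.pvalue,
        }


@dataclass
class ConcordanceResult:
    n_same: int
    n_opposite: int
    proportion_same: float
    chi2: float
    pvalue: float
    n_excluded: int = 0


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> OverlapResult:
    """Upper-tail hypergeometric enrichment P(X >= k).

    X counts the members of a size-``n`` draw (without replacement) from a
    universe of ``N`` that land in a marked subset of size ``K``.  The tail
    is evaluated by scipy's survival function, which is stable far into the
    tail (log-space internally).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent sizes: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K, n)={min(K, n)}]")
    expected = K * n / N if N > 0 else float("nan")
    pvalue = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = k / expected if expected > 0 else float("nan")
    return OverlapResult(N, K, n, k, expected, fold, min(1.0, pvalue))


def shared_de_genes(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    orthologs: OrthologMap,
) -> tuple[OverlapResult, pd.DataFrame]:
    """Cross-species overlap of significant DE genes on the ortholog universe.

    Both DE frames must cover the expressed ortholog universe; pairs with a
    member absent from either frame are dropped with a warning.  Returns
    the overlap statistics and the shared-pair table carrying both species'
    log2 fold changes.
    """
    pairs = orthologs.pairs
    in_a = pairs["gene_a"].isin(de_a.index)
    in_b = pairs["gene_b"].isin(de_b.index)
    usable = pairs[in_a & in_b]
    n_drop = len(pairs) - len(usable)
    if n_drop:
        warnings.warn(f"{n_drop} ortholog pairs not covered by both DE results", stacklevel=2)

    sig_a = de_a.loc[usable["gene_a"], "significant"].to_numpy(dtype=bool)
    sig_b = de_b.loc[usable["gene_b"], "significant"].to_numpy(dtype=bool)
    N = len(usable)
    K = int(sig_a.sum())
    n = int(sig_b.sum())
    both = sig_a & sig_b
    k = int(both.sum())
    shared = usable[both].copy()
    shared["log2fc_a"] = de_a.loc[shared["gene_a"], "log2fc"].values
    shared["log2fc_b"] = de_b.loc[shared["gene_b"], "log2fc"].values
    return hypergeom_overlap(N, K, n, k), shared.reset_index(drop=True)


def _sign_concordance(fc_a: np.ndarray, fc_b: np.ndarray) -> ConcordanceResult:
    nonzero = (fc_a != 0) & (fc_b != 0)
    excluded = int((~nonzero).sum())
    same = int(((fc_a > 0) == (fc_b > 0))[nonzero].sum())
    opp = int(nonzero.sum()) - same
    total = same + opp
    if total == 0:
        return ConcordanceResult(0, 0, float("nan"), float("nan"), 1.0, excluded)
    if total < 2:
        warnings.warn("sign test degenerate with a single pair", stacklevel=3)
        return ConcordanceResult(same, opp, same / total, float("nan"), 1.0, excluded)
    exp = total / 2.0
    chi2 = (same - exp) ** 2 / exp + (opp - exp) ** 2 / exp
    p = float(stats.chi2.sf(chi2, df=1))
    return ConcordanceResult(same, opp, same / total, float(chi2), p, excluded)


def direction_concordance(shared: pd.DataFrame) -> ConcordanceResult:
    """Sign agreement of shared DE pairs' fold changes vs a 50:50 null.

    Chi-square goodness of fit, df = 1, no continuity correction; pairs
    with a zero fold change in either species are excluded and counted.
    """
    return _sign_concordance(
        shared["log2fc_a"].to_numpy(float), shared["log2fc_b"].to_numpy(float)
    )


def genomewide_sign_concordance(
    de_a: pd.DataFrame, de_b: pd.DataFrame, orthologs: OrthologMap
) -> ConcordanceResult:
    """Same sign test over ALL expressed ortholog pairs, significant or not."""
    pairs = orthologs.pairs
    usable = pairs[pairs["gene_a"].isin(de_a.index) & pairs["gene_b"].isin(de_b.index)]
    return _sign_concordance(
        de_a.loc[usable["gene_a"], "log2fc"].to_numpy(float),
        de_b.loc[usable["gene_b"], "log2fc"].to_numpy(float),
    )


def foldchange_correlation(shared: pd.DataFrame) -> dict:
    """Pearson correlation of the two species' log2 fold changes."""
    if len(shared) < 3:
        raise ValueError("need at least 3 shared pairs for a correlation")
    a = shared["log2fc_a"].to_numpy(float)
    b = shared["log2fc_b"].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        return {"r": float("nan"), "r2": float("nan"), "n": len(shared), "flagged": True}
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "r2": float(r * r), "n": len(shared), "pvalue": float(p),
            "flagged": False}


def within_species_direction_bias(de: pd.DataFrame) -> ConcordanceResult:
    """Among significant genes, up-in-high-latitude vs up-in-low-latitude
    counts against a 50:50 chi-square null.

    Convention: the DE frame's log2fc is high- over low-latitude, so
    positive log2fc means higher expression at high latitude.
    """
    sig = de[de["significant"].astype(bool)]
    up_high = int((sig["log2fc"] > 0).sum())
    up_low = int((sig["log2fc"] < 0).sum())
    total = up_high + up_low
    if total == 0:
        return ConcordanceResult(0, 0, float("nan"), 0.0, 1.0)
    exp = total / 2.0
    chi2 = (up_high - exp) ** 2 / exp + (up_low - exp) ** 2 / exp
    return ConcordanceResult(
        up_high, up_low, up_high / total, float(chi2), float(stats.chi2.sf(chi2, 1))
    )
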