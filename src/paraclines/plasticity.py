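"""Plasticity, population x temperature interaction, and reaction norms.

Plasticity is differential expression between rearing temperatures within
a population.  The interaction (GEI) test fits a cell-means linear model
to log2(CPM + 0.5) per gene and tests the difference-of-differences
contrast (high@Tlow - high@Thigh) - (low@Tlow - low@Thigh) with a
moderated t: residual variances are shrunk toward an inverse-gamma prior
fitted to all genes (empirical Bayes), adding prior degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .containers import CountMatrix, OrthologMap
from .diffexpr import bh_adjust, size_factors_median_ratio, test_de
from .parallelism import OverlapResult, hypergeom_overlap, _sign_concordance


# ---------------------------------------------------------------------------
# plasticity


def test_plasticity(
    cm: CountMatrix,
    population: str,
    dispersion=None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """DE between the two temperatures within one population.

    log2fc is high temperature over low temperature.
    """
    temps = sorted(cm.design["temperature"].unique())
    if len(temps) != 2:
        raise ValueError(f"expected exactly 2 temperatures, found {temps}")
    g_lo = cm.samples_where(population=population, temperature=temps[0])
    g_hi = cm.samples_where(population=population, temperature=temps[1])
    if not g_lo or not g_hi:
        raise ValueError(f"population {population!r} lacks samples at both temperatures")
    return test_de(cm, g_lo, g_hi, dispersion=dispersion, fdr=fdr)


def plasticity_parallelism(
    plast_a_pop1: pd.DataFrame,
    plast_a_pop2: pd.DataFrame,
    plast_b_pop1: pd.DataFrame,
    plast_b_pop2: pd.DataFrame,
    orthologs: OrthologMap,
) -> dict:
    """Cross-population and cross-species plasticity sharing.

    Computes (a) within-species overlap of the two populations' plasticity
    sets with direction concordance, (b) cross-species shared plasticity
    per population, and (c) the cross-species overlap of
    population-SPECIFIC plasticity sets (significant in exactly one
    population of a species), all as upper-tail hypergeometric
    enrichments on the ortholog universe.
    """
    for x, y in ((plast_a_pop1, plast_a_pop2), (plast_b_pop1, plast_b_pop2)):
        if not x.index.equals(y.index):
            raise ValueError("plasticity results within a species must share a universe")

    out = {}
    # (a) within species
    for sp, p1, p2 in (("a", plast_a_pop1, plast_a_pop2), ("b", plast_b_pop1, plast_b_pop2)):
        sig1 = p1["significant"].astype(bool)
        sig2 = p2["significant"].astype(bool)
        both = sig1 & sig2
        out[f"within_{sp}_overlap"] = hypergeom_overlap(
            len(p1), int(sig1.sum()), int(sig2.sum()), int(both.sum())
        )
        out[f"within_{sp}_direction"] = _sign_concordance(
            p1.loc[both, "log2fc"].to_numpy(float), p2.loc[both, "log2fc"].to_numpy(float)
        )

    pairs = orthologs.pairs
    usable = pairs[
        pairs["gene_a"].isin(plast_a_pop1.index) & pairs["gene_b"].isin(plast_b_pop1.index)
    ]
    N = len(usable)

    # (b) cross-species per population
    for pop, pa, pb in (("pop1", plast_a_pop1, plast_b_pop1), ("pop2", plast_a_pop2, plast_b_pop2)):
        sa = pa.loc[usable["gene_a"], "significant"].to_numpy(bool)
        sb = pb.loc[usable["gene_b"], "significant"].to_numpy(bool)
        out[f"cross_species_{pop}"] = hypergeom_overlap(
            N, int(sa.sum()), int(sb.sum()), int((sa & sb).sum())
        )

    # (c) population-specific plasticity, shared across species
    spec_a = (
        plast_a_pop1.loc[usable["gene_a"], "significant"].to_numpy(bool)
        ^ plast_a_pop2.loc[usable["gene_a"], "significant"].to_numpy(bool)
    )
    spec_b = (
        plast_b_pop1.loc[usable["gene_b"], "significant"].to_numpy(bool)
        ^ plast_b_pop2.loc[usable["gene_b"], "significant"].to_numpy(bool)
    )
    out["population_specific_overlap"] = hypergeom_overlap(
        N, int(spec_a.sum()), int(spec_b.sum()), int((spec_a & spec_b).sum())
    )
    return out


# ---------------------------------------------------------------------------
# moderated-t GEI


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (limma-style)
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square prior (d0, s0^2) to gene variances."""
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s0 = np.inf, np.exp(emean)
    return d0, float(s0)


def log2_cpm(cm: CountMatrix, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes."""
    sf = size_factors_median_ratio(cm.counts)
    totals = cm.counts.sum(axis=0).astype(float)
    gm_total = float(np.exp(np.log(totals).mean()))
    lib = sf * gm_total
    return np.log2(cm.counts.div(lib, axis=1) * 1e6 + prior)


def gei_test(cm: CountMatrix, fdr: float = 0.05, prior_df: float | None = None) -> pd.DataFrame:
    """Population x temperature interaction with a moderated t.

    Fits the cell-means model per gene on log2(CPM + 0.5) and tests the
    contrast (high@Tlow - high@Thigh) - (low@Tlow - low@Thigh).  Residual
    variances are empirical-Bayes shrunk; ``prior_df`` overrides the
    fitted prior degrees of freedom.  Returns columns ``contrast, tstat,
    pvalue, qvalue, significant``.
    """
    temps = sorted(cm.design["temperature"].unique())
    pops = sorted(cm.design["population"].unique())
    if len(temps) != 2 or len(pops) != 2:
        raise ValueError("gei_test needs a full 2x2 population x temperature design")
    tlo, thi = temps
    lo_pop, hi_pop = ("low", "high") if set(pops) == {"low", "high"} else (pops[0], pops[1])

    cells = [(hi_pop, tlo), (hi_pop, thi), (lo_pop, tlo), (lo_pop, thi)]
    groups = []
    for pop, t in cells:
        g = cm.samples_where(population=pop, temperature=t)
        if not g:
            raise ValueError(f"missing design cell: population={pop}, temperature={t}")
        groups.append(g)

    y = log2_cpm(cm)
    n_tot = sum(len(g) for g in groups)
    df_res = n_tot - 4
    if df_res < 1:
        raise ValueError("no residual degrees of freedom in 2x2 design")

    means = np.column_stack([y[g].mean(axis=1).values for g in groups])
    # residual variance around cell means
    rss = np.zeros(len(y))
    for j, g in enumerate(groups):
        rss += ((y[g].values - means[:, [j]]) ** 2).sum(axis=1)
    s2 = rss / df_res

    cvec = np.array([1.0, -1.0, -1.0, 1.0])  # (hi,lo)-(hi,hi)-(lo,lo)+(lo,hi)
    contrast = means @ cvec
    var_factor = sum(c * c / len(g) for c, g in zip(cvec, groups))

    if prior_df is None:
        d0, s0 = _fit_variance_prior(s2, df_res)
    else:
        d0 = float(prior_df)
        _, s0 = _fit_variance_prior(s2, df_res)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = 1e6
    else:
        s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res

    tstat = contrast / np.sqrt(s2_post * var_factor)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    qvals = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "contrast": contrast,
            "tstat": tstat,
            "pvalue": pvals,
            "qvalue": qvals,
            "significant": qvals < fdr,
        },
        index=y.index,
    )


def cell_mean_matrix(cm: CountMatrix) -> pd.DataFrame:
    """Normalized linear-scale mean count per factorial cell (genes x 4)."""
    sf = size_factors_median_ratio(cm.counts)
    norm = cm.counts / sf
    temps = sorted(cm.design["temperature"].unique())
    cols = {}
    for pop in sorted(cm.design["population"].unique()):
        for t in temps:
            g = cm.samples_where(population=pop, temperature=t)
            cols[f"{pop}@{t}"] = norm[g].mean(axis=1)
    return pd.DataFrame(cols)


def classify_crossover(
    cell_means: pd.DataFrame,
    threshold: float = 0.5,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Reaction-norm crossover calls from four cell means per gene.

    Columns must be ``low@Tlo, low@Thi, high@Tlo, high@Thi`` (any order;
    parsed from names).  A gene crosses over when the sign of the
    high-minus-low population difference (log2) differs between
    temperatures AND |delta_Tlow| + |delta_Thigh| exceeds ``threshold``
    log2 units.  ``slope_discordant`` marks genes whose two populations'
    temperature slopes have opposite sign.  Zero cell means are
    pseudocounted and flagged.
    """
    parsed = {}
    for c in cell_means.columns:
        pop, t = c.split("@")
        parsed[(pop, t)] = cell_means[c]
    pops = sorted({p for p, _ in parsed})
    temps = sorted({t for _, t in parsed}, key=float)
    if len(pops) != 2 or len(temps) != 2:
        raise ValueError("need 2 populations x 2 temperatures of cell means")
    lo_pop = "low" if "low" in pops else pops[0]
    hi_pop = "high" if "high" in pops else pops[1]
    tlo, thi = temps

    vals = {k: v.to_numpy(dtype=float) for k, v in parsed.items()}
    flagged = np.zeros(len(cell_means), dtype=bool)
    for k in vals:
        zero = vals[k] <= 0
        flagged |= zero
        vals[k] = vals[k] + pseudocount * zero

    d_lo = np.log2(vals[(hi_pop, tlo)] / vals[(lo_pop, tlo)])
    d_hi = np.log2(vals[(hi_pop, thi)] / vals[(lo_pop, thi)])
    magnitude = np.abs(d_lo) + np.abs(d_hi)
    crossover = (np.sign(d_lo) != np.sign(d_hi)) & (magnitude > threshold)

    slope_hi = vals[(hi_pop, thi)] - vals[(hi_pop, tlo)]
    slope_lo = vals[(lo_pop, thi)] - vals[(lo_pop, tlo)]
    slope_discordant = np.sign(slope_hi) != np.sign(slope_lo)

    return pd.DataFrame(
        {
            "delta_Tlow": d_lo,
            "delta_Thigh": d_hi,
            "magnitude": magnitude,
            "crossover": crossover,
            "slope_discordant": slope_discordant,
            "flagged": flagged,
        },
        index=cell_means.index,
    )
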