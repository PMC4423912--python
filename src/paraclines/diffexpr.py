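"""Expression filtering, normalization and NB differential-expression testing.

The test is a conditional exact test on a negative-binomial model: counts
are scaled to a common library size, and the split of a gene's total
between the two groups is compared with its conditional null distribution
(sum of per-group NB totals), two-sided by summing outcome probabilities
not exceeding the observed one.  Dispersions are method-of-moments
estimates shrunk toward a smooth mean-dispersion trend.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix


# ---------------------------------------------------------------------------
# filtering and normalization


def filter_expressed(cm: CountMatrix, min_mean: float = 10.0) -> CountMatrix:
    """Keep genes whose mean raw count across all samples is >= ``min_mean``.

    The boundary is inclusive: a gene averaging exactly ``min_mean`` counts
    is retained.
    """
    keep = cm.counts.mean(axis=1) >= min_mean
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return CountMatrix(cm.counts[keep], cm.design)


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    logc = np.log(counts.replace(0, np.nan))
    ref = logc.mean(axis=1)
    usable = ref.notna()
    if usable.sum() == 0:
        return pd.Series(1.0, index=counts.columns)
    lr = logc[usable].sub(ref[usable], axis=0)
    sf = np.exp(lr.median(axis=0)).fillna(1.0)
    # normalize so factors multiply to 1
    sf = sf / np.exp(np.log(sf).mean())
    return sf


def upper_quartile_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample 75th percentile of nonzero counts, geometric mean 1."""
    uq = counts.apply(lambda col: np.percentile(col[col > 0], 75) if (col > 0).any() else 1.0)
    return uq / np.exp(np.log(uq).mean())


def normalize(
    cm: CountMatrix,
    gene_lengths: dict | pd.Series,
    method: str = "upper_quartile",
):
    """Upper-quartile normalized FPKM.

    FPKM_gs = count_gs * 1e9 / (length_g * f_s * L) with f_s the
    geometric-mean-1 upper-quartile factor and L the geometric mean of the
    per-sample totals; this makes FPKM exactly invariant to rescaling any
    single library.  Returns (fpkm DataFrame, size-factor Series).
    """
    if method != "upper_quartile":
        raise ValueError(f"unknown normalization method: {method}")
    lengths = pd.Series(gene_lengths)
    missing = [g for g in cm.genes if g not in lengths.index or lengths[g] <= 0]
    if missing:
        raise ValueError(f"genes missing positive lengths: {missing[:10]}"
                         f"{'...' if len(missing) > 10 else ''}")
    lengths = lengths.loc[cm.genes]
    factors = upper_quartile_factors(cm.counts)
    totals = cm.counts.sum(axis=0).astype(float)
    gm_total = float(np.exp(np.log(totals).mean()))
    denom = factors * gm_total
    fpkm = cm.counts.div(lengths, axis=0).div(denom, axis=1) * 1e9
    return fpkm, factors


# ---------------------------------------------------------------------------
# dispersion estimation


def estimate_dispersions(
    cm: CountMatrix,
    groups: pd.Series | dict,
    shrink: float | None = None,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-gene NB dispersion (phi; variance = mu + phi mu^2).

    Gene-wise method-of-moments estimates on size-factor-normalized counts,
    pooled across groups, then shrunk toward a lowess mean-dispersion
    trend.  The default trend weight is prior_df / (prior_df + residual df)
    — the moderated-dispersion convention — so few-replicate designs lean
    harder on the trend; pass ``shrink`` to set the weight directly.
    Returns a frame with columns ``raw, trend, dispersion, flagged``.
    """
    groups = pd.Series(groups)
    samples = list(groups.index)
    if shrink is None:
        df_res = sum((groups == g).sum() - 1 for g in groups.unique())
        shrink = prior_df / (prior_df + max(1, df_res))
    counts = cm.counts[samples]
    sf = size_factors_median_ratio(counts)
    norm = counts / sf

    means = norm.mean(axis=1)
    num = pd.Series(0.0, index=norm.index)
    den = pd.Series(0.0, index=norm.index)
    for g in groups.unique():
        cols = list(groups.index[groups == g])
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        sub = norm[cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(cols) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (v - m) / (m ** 2)
        num += w * phi_g.fillna(0.0)
        den += w
    raw = (num / den).clip(lower=0.0)
    flagged = means <= 0
    raw[flagged] = np.nan

    ok = raw.notna()
    if ok.sum() >= 10:
        x = np.log(means[ok].values + 1e-8)
        y = raw[ok].values
        fit = lowess(y, x, frac=0.4, return_sorted=False)
        trend = pd.Series(np.nan, index=raw.index)
        trend[ok] = np.clip(fit, 0.0, None)
        trend = trend.fillna(float(np.nanmedian(trend)))
    else:
        trend = pd.Series(float(np.nanmedian(raw)) if ok.any() else 0.0, index=raw.index)

    disp = shrink * trend + (1.0 - shrink) * raw
    disp[flagged] = trend[flagged]
    return pd.DataFrame(
        {"raw": raw, "trend": trend, "dispersion": disp, "flagged": flagged}
    )


# ---------------------------------------------------------------------------
# exact test


def _nb_logpmf(x, mean, phi):
    """NB log-pmf parameterized by mean and dispersion phi (var = m + phi m^2)."""
    if phi <= 0:
        return stats.poisson.logpmf(x, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return stats.nbinom.logpmf(x, r, p)


def nb_exact_test(s1: float, s2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact NB test on group totals.

    Given library-size-adjusted integer group totals ``s1, s2`` from ``n1``
    and ``n2`` replicates sharing mean mu and dispersion ``phi``, computes
    the probability of any split of ``s1+s2`` at most as likely as the one
    observed.  The sum of n iid NB(mu, phi) is NB(n mu, phi/n).
    """
    s1, s2 = int(round(s1)), int(round(s2))
    t = s1 + s2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    # concentrate computation on the region holding essentially all mass
    center = t * n1 / (n1 + n2)
    spread = np.sqrt(max(n1 * mu * (1.0 + phi * mu), 1.0))
    lo = int(max(0, np.floor(center - 25 * spread - 10)))
    hi = int(min(t, np.ceil(center + 25 * spread + 10)))
    lo, hi = min(lo, s1), max(hi, s1)
    x = np.arange(lo, hi + 1)
    logp = _nb_logpmf(x, n1 * mu, phi / n1) + _nb_logpmf(t - x, n2 * mu, phi / n2)
    logp = logp - logsumexp(logp)
    obs = logp[s1 - lo]
    keep = logp <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def test_de(
    cm: CountMatrix,
    group1: list,
    group2: list,
    dispersion: pd.Series | float | None = None,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial exact test of group2 vs group1.

    Returns a frame indexed by gene with columns ``baseMean1, baseMean2,
    log2fc, pvalue, qvalue, significant, direction`` (log2fc is group2 over
    group1 on pseudocounted normalized means).
    """
    group1, group2 = list(group1), list(group2)
    if set(group1) & set(group2):
        raise ValueError("groups overlap")
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 samples")
    sub = cm.subset_samples(group1 + group2)
    sf = size_factors_median_ratio(sub.counts)
    norm = sub.counts / sf

    if dispersion is None:
        labels = pd.Series(
            ["g1"] * len(group1) + ["g2"] * len(group2), index=group1 + group2
        )
        disp = estimate_dispersions(sub, labels)["dispersion"]
    elif np.isscalar(dispersion):
        disp = pd.Series(float(dispersion), index=sub.genes)
    else:
        disp = pd.Series(dispersion).loc[sub.genes]

    m1 = norm[group1].mean(axis=1)
    m2 = norm[group2].mean(axis=1)
    s1 = norm[group1].sum(axis=1).round().astype(np.int64)
    s2 = norm[group2].sum(axis=1).round().astype(np.int64)
    n1, n2 = len(group1), len(group2)

    pvals = np.empty(len(sub.genes))
    s1v, s2v, dv = s1.values, s2.values, disp.values
    for i in range(len(pvals)):
        pvals[i] = nb_exact_test(s1v[i], s2v[i], n1, n2, max(0.0, dv[i]))

    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    qvals = bh_adjust(pvals)
    significant = qvals < fdr
    direction = np.where(
        ~significant, "none", np.where(log2fc > 0, "up_in_group2", "up_in_group1")
    )
    return pd.DataFrame(
        {
            "baseMean1": m1,
            "baseMean2": m2,
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "significant": significant,
            "direction": direction,
        },
        index=sub.genes,
    )


# ---------------------------------------------------------------------------
# gene-class annotation


def classify_sex_bias(
    male_fpkm, female_fpkm, min_fpkm: float = 2.0, fold: float = 2.0
) -> pd.Series:
    """Male-biased call: male FPKM above ``min_fpkm`` and at least
    ``fold``-times the female value (boundary inclusive)."""
    male = pd.Series(male_fpkm)
    female = pd.Series(female_fpkm)
    return (male > min_fpkm) & (male >= fold * female)


def classify_tau(
    tissue_matrix: pd.DataFrame,
    testis_label: str = "testis",
    tau_threshold: float = 0.9,
) -> pd.DataFrame:
    """Tissue-specificity index tau and testis-biased flags.

    tau = sum_i (1 - x_i / x_max) / (N - 1); 0 for uniform expression, 1
    for single-tissue expression.  All-zero genes get tau = NaN and are
    flagged.  testis_biased requires tau above the threshold and maximal
    expression in the testis column.
    """
    x = tissue_matrix.to_numpy(dtype=float)
    xmax = x.max(axis=1)
    zero = xmax <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = (1.0 - x / xmax[:, None]).sum(axis=1) / (x.shape[1] - 1)
    tau[zero] = np.nan
    max_tissue = tissue_matrix.columns[np.argmax(x, axis=1)].to_numpy(dtype=object)
    max_tissue[zero] = ""
    out = pd.DataFrame(
        {"tau": tau, "max_tissue": max_tissue, "flagged": zero},
        index=tissue_matrix.index,
    )
    out["testis_biased"] = (out["tau"] > tau_threshold) & (out["max_tissue"] == testis_label)
    out.loc[zero, "testis_biased"] = False
    return out


def summarize_fold_changes(results: pd.DataFrame) -> dict:
    """Mean absolute fold change, in percent, for all and significant genes.

    A gene's fold is 2**log2fc with the reference group at 1; the summary
    averages |fold - 1| * 100.
    """
    if results.empty:
        raise ValueError("empty DE results")
    fold = 2.0 ** results["log2fc"]
    dev = (fold - 1.0).abs() * 100.0
    sig = results["significant"].astype(bool)
    return {
        "mean_abs_fold_change_all_pct": float(dev.mean()),
        "mean_abs_fold_change_sig_pct": float(dev[sig].mean()) if sig.any() else float("nan"),
        "n_all": int(len(results)),
        "n_significant": int(sig.sum()),
    }
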