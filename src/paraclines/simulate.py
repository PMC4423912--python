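"""Synthetic two-species factorial experiment with known planted truth.

The generator emulates the structure of a latitudinal RNA-seq study on two
sister species: a 2 (population: low- vs high-latitude) x 2 (rearing
temperature) factorial with replicated negative-binomial gene counts,
planted differential expression with controllable cross-species sharing and
direction concordance, planted plasticity and population x temperature
interaction, and pooled per-site SNP read counts under a Balding-Nichols
differentiation model with outlier SNPs preferentially placed in
differentially expressed genes' 3'UTR/CDS.

Every output is fully determined by ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig, ConfigError
from .containers import CountMatrix, GeneCatalogue, OrthologMap, PoolSiteTable, SYNC_BASES

SPECIES = ("spA", "spB")
POPULATIONS = ("low", "high")  # low- and high-latitude

# fixed per-stage offsets so each generator draws from an independent stream
_STAGE = {"genome": 1, "truth": 2, "counts": 3, "snps": 4, "sex": 5}


def _rng(config: SimConfig, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STAGE[stage], extra])
    )


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig, species: str = "spA") -> GeneCatalogue:
    """Lay out non-overlapping gene models with UTR/CDS structure per arm.

    Genes are placed along each arm with random intergenic gaps; every gene
    carries disjoint 5'UTR, CDS and 3'UTR intervals (order reflecting
    strand).  One arm ("3R" when present) receives inversion spans covering
    ``config.inversion_fraction`` of its genes.
    """
    rng = _rng(config, "genome", extra=SPECIES.index(species) if species in SPECIES else 9)
    n_total = config.n_genes_per_species
    arm_names = list(config.arms)
    caps = np.array([config.arms[a] for a in arm_names], dtype=float)
    # allocate proportionally to capacity, then fix rounding drift
    alloc = np.floor(caps / caps.sum() * n_total).astype(int)
    while alloc.sum() < n_total:
        alloc[int(np.argmax(caps - alloc))] += 1
    for a, cap, k in zip(arm_names, caps, alloc):
        if k > cap:
            raise ConfigError(f"arm {a} capacity {int(cap)} exceeded (needs {k})")

    rows = []
    gid = 0
    prefix = species
    for arm, k in zip(arm_names, alloc):
        pos = int(rng.integers(1000, 5000))
        for _ in range(k):
            u5 = int(rng.integers(100, 300))
            cds = int(rng.integers(500, 2000))
            u3 = int(rng.integers(200, 600))
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos
            if strand == "+":
                u5s, u5e = start, start + u5
                cs, ce = u5e, u5e + cds
                u3s, u3e = ce, ce + u3
            else:  # 3'UTR comes first along the chromosome
                u3s, u3e = start, start + u3
                cs, ce = u3e, u3e + cds
                u5s, u5e = ce, ce + u5
            end = start + u5 + cds + u3
            rows.append(
                (f"{prefix}G{gid:05d}", arm, start, end, strand, u5 + cds + u3,
                 u5s, u5e, cs, ce, u3s, u3e)
            )
            gid += 1
            pos = end + int(rng.integers(500, 5000))

    genes = pd.DataFrame(
        rows,
        columns=["gene_id", "arm", "start", "end", "strand", "exon_length",
                 "utr5_start", "utr5_end", "cds_start", "cds_end",
                 "utr3_start", "utr3_end"],
    )

    inv_arm = "3R" if "3R" in arm_names else arm_names[-1]
    on_arm = genes[genes["arm"] == inv_arm].reset_index(drop=True)
    n_inv = int(round(config.inversion_fraction * len(on_arm)))
    inv_rows = []
    if n_inv >= 2:
        # two contiguous gene blocks emulating cosmopolitan inversions
        sizes = [n_inv // 2, n_inv - n_inv // 2]
        starts_avail = len(on_arm) - n_inv
        anchor = int(rng.integers(0, max(1, starts_avail // 2)))
        second = anchor + sizes[0] + int(rng.integers(1, max(2, starts_avail // 2)))
        second = min(second, len(on_arm) - sizes[1])
        for name, a0, size in (("InvA", anchor, sizes[0]), ("InvB", second, sizes[1])):
            block = on_arm.iloc[a0:a0 + size]
            inv_rows.append((inv_arm, int(block["start"].min()), int(block["end"].max()), name))
    elif n_inv == 1:
        block = on_arm.iloc[:1]
        inv_rows.append((inv_arm, int(block["start"].min()), int(block["end"].max()), "InvA"))
    inversions = pd.DataFrame(inv_rows, columns=["arm", "start", "end", "name"])
    return GeneCatalogue(genes, inversions)


def make_ortholog_map(config: SimConfig, cat_a: GeneCatalogue, cat_b: GeneCatalogue) -> OrthologMap:
    """Pair the first ``n_orthologs`` genes of each species, shuffled."""
    rng = _rng(config, "genome", extra=7)
    ga = list(cat_a.genes["gene_id"].iloc[: config.n_orthologs])
    gb = list(cat_b.genes["gene_id"].iloc[: config.n_orthologs])
    perm = rng.permutation(len(gb))
    return OrthologMap(pd.DataFrame({"gene_a": ga, "gene_b": [gb[i] for i in perm]}))


# ---------------------------------------------------------------------------
# expression truth

CELL_ORDER = None  # filled per config temperatures


def _cells(config: SimConfig) -> list[str]:
    return [f"{pop}@{t}" for pop in POPULATIONS for t in config.temperatures]


@dataclass
class SimTruth:
    """Planted ground truth for every gene, species and SNP."""

    cell_means: dict            # species -> DataFrame genes x cells (log2)
    labels: dict                # species -> DataFrame of boolean labels
    dispersion_shape: dict      # species -> Series of NB shapes
    snps: dict = field(default_factory=dict)   # species -> SNP truth frame
    shared_pairs: dict = field(default_factory=dict)  # temp -> planted shared DE pairs
    temperatures: tuple = (21, 29)

    def crossover_truth(self, species: str, threshold: float = 0.5) -> pd.Series:
        cm = self.cell_means[species]
        tlo, thi = self.temperatures
        d_lo = cm[f"high@{tlo}"] - cm[f"low@{tlo}"]
        d_hi = cm[f"high@{thi}"] - cm[f"low@{thi}"]
        return (np.sign(d_lo) * np.sign(d_hi) < 0) & ((d_lo.abs() + d_hi.abs()) > threshold)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for sp in self.cell_means:
            self.cell_means[sp].to_csv(path / f"truth_means_{sp}.tsv", sep="\t")
            self.labels[sp].to_csv(path / f"truth_labels_{sp}.tsv", sep="\t")
            self.dispersion_shape[sp].rename("shape").to_csv(
                path / f"truth_shape_{sp}.tsv", sep="\t"
            )
            if sp in self.snps:
                self.snps[sp].to_csv(path / f"truth_snps_{sp}.tsv", sep="\t", index=False)
        for t, frame in self.shared_pairs.items():
            frame.to_csv(path / f"truth_shared_{t}.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path, temperatures=(21, 29)) -> "SimTruth":
        path = Path(path)
        cell_means, labels, shapes, snps = {}, {}, {}, {}
        shared = {}
        for f in sorted(path.glob("truth_shared_*.tsv")):
            shared[int(f.stem.split("_")[-1])] = pd.read_csv(f, sep="\t")
        for f in sorted(path.glob("truth_means_*.tsv")):
            sp = f.stem.split("_")[-1]
            cell_means[sp] = pd.read_csv(f, sep="\t", index_col=0)
            labels[sp] = pd.read_csv(path / f"truth_labels_{sp}.tsv", sep="\t", index_col=0)
            shapes[sp] = pd.read_csv(path / f"truth_shape_{sp}.tsv", sep="\t", index_col=0)["shape"]
            snp_f = path / f"truth_snps_{sp}.tsv"
            if snp_f.exists():
                snps[sp] = pd.read_csv(snp_f, sep="\t")
        return cls(cell_means, labels, shapes, snps, shared, tuple(temperatures))


def simulate_expression_truth(
    config: SimConfig,
    catalogues: dict,
    orthologs: OrthologMap,
) -> SimTruth:
    """Plant DE, plasticity and GEI effects on true log2 cell means.

    DE at a temperature shifts the high-latitude population's mean by
    ``±effect_size_log2``; cross-species sharing and sign concordance among
    ortholog pairs follow ``shared_de_fraction`` and ``same_direction_prob``.
    GEI genes get a symmetric rank-reversing interaction of total magnitude
    ``effect_size_log2`` (opposite-sign temperature responses in the two
    populations).
    """
    fwd = orthologs.a_to_b
    rng = _rng(config, "truth")
    tlo, thi = config.temperatures
    cells = _cells(config)
    e = config.effect_size_log2

    cell_means, labels, shapes = {}, {}, {}
    truth_pairs: dict = {}
    # species A drives the shared-pair bookkeeping
    shared_signs: dict[int, dict] = {t: {} for t in config.temperatures}
    pair_idx = np.arange(len(orthologs))

    for si, sp in enumerate(SPECIES):
        cat = catalogues[sp]
        genes = list(cat.genes["gene_id"])
        n = len(genes)
        base = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n)
        cm = pd.DataFrame({c: base.copy() for c in cells}, index=genes)
        lab = pd.DataFrame(False, index=genes,
                           columns=[f"de_at_{tlo}", f"de_at_{thi}",
                                    "plastic_low", "plastic_high", "gei"])
        sign_cols = {f"de_sign_{t}": pd.Series(0, index=genes) for t in config.temperatures}

        own_genes = orthologs.pairs["gene_a"] if sp == SPECIES[0] else orthologs.pairs["gene_b"]
        own_genes = list(own_genes)

        # GEI genes are drawn first and kept disjoint from the DE/plasticity
        # selections (from non-ortholog genes when enough exist) so their
        # planted interaction structure is not overwritten by other effects
        n_gei = int(round(config.gei_fraction * n))
        non_orth = sorted(set(genes) - set(own_genes))
        gei_pool = non_orth if len(non_orth) >= n_gei else genes
        gei_genes = rng.choice(gei_pool, size=n_gei, replace=False)
        gei_set = set(gei_genes)

        for t in config.temperatures:
            n_shared = int(round(config.shared_de_fraction * len(orthologs)))
            if si == 0:
                chosen = rng.choice(pair_idx, size=n_shared, replace=False)
                sa = rng.choice([-1, 1], size=n_shared)
                sb = np.where(rng.random(n_shared) < config.same_direction_prob, sa, -sa)
                shared_signs[t] = {"pairs": chosen, "sa": sa, "sb": sb}
                truth_pairs[t] = pd.DataFrame(
                    {
                        "pair_index": chosen,
                        "gene_a": orthologs.pairs["gene_a"].iloc[chosen].values,
                        "gene_b": orthologs.pairs["gene_b"].iloc[chosen].values,
                        "sign_a": sa,
                        "sign_b": sb,
                    }
                )
            info = shared_signs[t]
            chosen, signs = info["pairs"], (info["sa"] if si == 0 else info["sb"])
            de_genes = [own_genes[i] for i in chosen]
            n_de = int(round(config.de_fraction_per_temp * n))
            extra_pool = np.array(sorted(set(genes) - set(de_genes) - gei_set))
            n_extra = max(0, n_de - len(de_genes))
            extra = rng.choice(extra_pool, size=n_extra, replace=False)
            extra_signs = rng.choice([-1, 1], size=n_extra)
            all_de = list(de_genes) + list(extra)
            all_signs = np.concatenate([signs, extra_signs]) if len(all_de) else np.array([])
            cm.loc[all_de, f"high@{t}"] += all_signs * e
            lab.loc[all_de, f"de_at_{t}"] = True
            sign_cols[f"de_sign_{t}"].loc[all_de] = all_signs.astype(int)

        pl_pool = sorted(set(genes) - gei_set)
        for pop in POPULATIONS:
            n_pl = int(round(config.plasticity_fraction * n))
            pl_genes = rng.choice(pl_pool, size=n_pl, replace=False)
            pl_signs = rng.choice([-1, 1], size=n_pl)
            cm.loc[pl_genes, f"{pop}@{thi}"] += pl_signs * e
            lab.loc[pl_genes, f"plastic_{pop}"] = True

        gei_signs = rng.choice([-1, 1], size=n_gei)
        q = e / 4.0
        cm.loc[gei_genes, f"high@{tlo}"] += gei_signs * q
        cm.loc[gei_genes, f"high@{thi}"] -= gei_signs * q
        cm.loc[gei_genes, f"low@{tlo}"] -= gei_signs * q
        cm.loc[gei_genes, f"low@{thi}"] += gei_signs * q
        lab.loc[gei_genes, "gei"] = True

        for c, s in sign_cols.items():
            lab[c] = s
        shape = np.exp(rng.normal(np.log(config.dispersion_shape), 0.3, size=n))
        cell_means[sp] = cm
        labels[sp] = lab
        shapes[sp] = pd.Series(shape, index=genes)

    truth = SimTruth(cell_means, labels, shapes, shared_pairs=truth_pairs,
                     temperatures=config.temperatures)
    for sp in SPECIES:
        labels[sp]["crossover"] = truth.crossover_truth(sp)
    return truth


# ---------------------------------------------------------------------------
# counts


def simulate_counts(truth: SimTruth, config: SimConfig, species: str = None) -> dict:
    """Draw NB replicate counts for every factorial cell.

    variance = mu + mu^2/shape; per-sample library factors are log-normal
    and recorded in the design as ``lib_factor``.
    """
    out = {}
    targets = [species] if species else list(truth.cell_means)
    for si, sp in enumerate(targets):
        rng = _rng(config, "counts", extra=si)
        cm = truth.cell_means[sp]
        shape = truth.dispersion_shape[sp].values[:, None]
        cols, design_rows = [], []
        data = {}
        for pop in POPULATIONS:
            for t in config.temperatures:
                mu_base = 2.0 ** cm[f"{pop}@{t}"].values
                for r in range(1, config.n_replicates + 1):
                    lib = float(np.exp(rng.normal(0.0, 0.15)))
                    mu = np.maximum(mu_base * lib, 1e-8)
                    p = shape[:, 0] / (shape[:, 0] + mu)
                    counts = rng.negative_binomial(shape[:, 0], p)
                    name = f"{sp}_{pop}_{t}_r{r}"
                    data[name] = counts
                    cols.append(name)
                    design_rows.append((name, sp, pop, t, r, lib))
        counts_df = pd.DataFrame(data, index=cm.index)
        design = pd.DataFrame(
            design_rows,
            columns=["sample", "species", "population", "temperature", "replicate", "lib_factor"],
        ).set_index("sample")
        out[sp] = CountMatrix(counts_df, design)
    return out if species is None else out[species]


# ---------------------------------------------------------------------------
# pooled SNPs

_BASES = ("A", "T", "C", "G")


def simulate_pooled_snps(
    truth: SimTruth,
    catalogue: GeneCatalogue,
    config: SimConfig,
    species: str = "spA",
):
    """Pooled per-site read counts under a Balding-Nichols model.

    Each SNP's two population frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F)
    draws around an ancestral frequency p; outlier SNPs use
    ``fst_outlier_F``.  Outliers land in DE genes' 3'UTR/CDS at
    ``outlier_in_de_enrichment``-fold the background rate.  Read counts are
    binomial at Poisson coverage, one pool per population.

    Returns (PoolSiteTable, snp truth DataFrame).
    """
    if config.pool_coverage_mean <= 0:
        raise ConfigError("pool coverage must be positive")
    rng = _rng(config, "snps", extra=SPECIES.index(species) if species in SPECIES else 9)
    lab = truth.labels[species]
    tlo, thi = config.temperatures
    de_genes = set(lab.index[lab[f"de_at_{tlo}"] | lab[f"de_at_{thi}"]])

    feats = catalogue.feature_table()
    feats = feats.set_index("gene_id", drop=False)

    rows = []
    classes = list(config.annotation_mix)
    class_p = np.array([config.annotation_mix[c] for c in classes])
    for _, g in catalogue.genes.iterrows():
        n_snp = rng.poisson(config.snps_per_gene_mean)
        if n_snp == 0:
            continue
        spans = {
            "5'UTR": (g["utr5_start"], g["utr5_end"]),
            "CDS": (g["cds_start"], g["cds_end"]),
            "3'UTR": (g["utr3_start"], g["utr3_end"]),
        }
        snp_classes = rng.choice(classes, size=n_snp, p=class_p)
        for cls in snp_classes:
            a, b = spans[cls]
            pos0 = int(rng.integers(a, b))
            rows.append((g["arm"], pos0 + 1, g["gene_id"], cls))
    snp = pd.DataFrame(rows, columns=["arm", "pos", "gene_id", "class"])
    snp = snp.drop_duplicates(subset=["arm", "pos"]).reset_index(drop=True)
    n = len(snp)

    in_de_func = snp["gene_id"].isin(de_genes) & snp["class"].isin(("3'UTR", "CDS"))
    q0 = config.outlier_fraction
    q1 = min(1.0, q0 * config.outlier_in_de_enrichment)
    draw = rng.random(n)
    outlier = np.where(in_de_func, draw < q1, draw < q0)
    F = np.where(outlier, config.fst_outlier_F, config.fst_background_F)

    p_anc = rng.uniform(0.1, 0.9, size=n)
    freqs = np.empty((n, 2))
    for j in range(2):
        with np.errstate(divide="ignore", invalid="ignore"):
            a = p_anc * (1.0 - F) / np.where(F > 0, F, 1.0)
            b = (1.0 - p_anc) * (1.0 - F) / np.where(F > 0, F, 1.0)
        drawn = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
        freqs[:, j] = np.where(F > 0, drawn, p_anc)

    ref_idx = rng.integers(0, 4, size=n)
    alt_off = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_off) % 4

    data = {
        "arm": snp["arm"],
        "pos": snp["pos"],
        "ref": [_BASES[i] for i in ref_idx],
    }
    for p_i in (1, 2):
        cov = rng.poisson(config.pool_coverage_mean, size=n)
        alt_reads = rng.binomial(cov, freqs[:, p_i - 1])
        counts = np.zeros((n, len(SYNC_BASES)), dtype=np.int64)
        counts[np.arange(n), ref_idx] = cov - alt_reads
        counts[np.arange(n), alt_idx] = alt_reads
        for bi, bname in enumerate(SYNC_BASES):
            data[f"p{p_i}_{bname}"] = counts[:, bi]
    table = PoolSiteTable(pd.DataFrame(data))

    snp_truth = snp.copy()
    snp_truth["outlier"] = outlier
    snp_truth["F"] = F
    snp_truth["true_p1"] = freqs[:, 0]
    snp_truth["true_p2"] = freqs[:, 1]
    truth.snps[species] = snp_truth
    return table, snp_truth


# ---------------------------------------------------------------------------
# sex-bias / tissue profiles


def simulate_sex_tissue_profiles(
    config: SimConfig,
    n_genes: int = 2000,
    male_biased_fraction: float = 0.28,
    tissues: tuple = ("head", "gut", "testis", "carcass"),
    noise_sd: float = 0.0,
):
    """Male/female FPKM pairs and a tissue expression matrix with truth.

    A planted male-biased gene has male FPKM > 2 and at least 2-fold the
    female value; planted tissue-specific genes express in a single tissue.
    Returns (sex DataFrame, tissue DataFrame, truth label DataFrame).
    """
    if len(tissues) < 2:
        raise ConfigError("at least two tissues required")
    rng = _rng(config, "sex")
    ids = [f"SX{i:05d}" for i in range(n_genes)]
    biased = rng.random(n_genes) < male_biased_fraction
    female = rng.uniform(1.0, 50.0, size=n_genes)
    male = np.where(
        biased,
        np.maximum(female * rng.uniform(2.0, 10.0, size=n_genes), 2.0 + 1e-6),
        female * rng.uniform(0.6, 1.8, size=n_genes),
    )
    # unbiased genes must genuinely fail the rule
    male = np.where(~biased & (male >= 2 * female), female * 1.5, male)
    if noise_sd > 0:
        male = male * np.exp(rng.normal(0, noise_sd, n_genes))
        female = female * np.exp(rng.normal(0, noise_sd, n_genes))
    sex = pd.DataFrame({"male_fpkm": male, "female_fpkm": female}, index=ids)

    spec_frac = 0.2
    specific = rng.random(n_genes) < spec_frac
    spec_tissue = rng.choice(tissues, size=n_genes)
    tissue = pd.DataFrame(
        rng.uniform(5.0, 15.0, size=(n_genes, len(tissues))), index=ids, columns=tissues
    )
    for i, gene in enumerate(ids):
        if specific[i]:
            row = np.zeros(len(tissues))
            row[list(tissues).index(spec_tissue[i])] = rng.uniform(20.0, 100.0)
            tissue.iloc[i] = row
    labels = pd.DataFrame(
        {"male_biased": biased, "tissue_specific": specific, "specific_tissue": spec_tissue},
        index=ids,
    )
    labels.loc[~labels["tissue_specific"], "specific_tissue"] = ""
    return sex, tissue, labels


# ---------------------------------------------------------------------------
# convenience bundle


@dataclass
class Experiment:
    config: SimConfig
    catalogues: dict
    orthologs: OrthologMap
    truth: SimTruth
    counts: dict
    pools: dict          # species -> PoolSiteTable


def simulate_experiment(config: SimConfig, with_snps: bool = True) -> Experiment:
    """Generate the full two-species experiment in one call."""
    catalogues = {sp: simulate_genome(config, sp) for sp in SPECIES}
    orthologs = make_ortholog_map(config, catalogues["spA"], catalogues["spB"])
    truth = simulate_expression_truth(config, catalogues, orthologs)
    counts = simulate_counts(truth, config)
    pools = {}
    if with_snps:
        for sp in SPECIES:
            pools[sp], _ = simulate_pooled_snps(truth, catalogues[sp], config, sp)
    return Experiment(config, catalogues, orthologs, truth, counts, pools)
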