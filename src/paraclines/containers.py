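"""Core in-memory containers shared across the pipeline.

Everything is a thin, validated wrapper around pandas DataFrames so that
intermediate results stay inspectable and writable as plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("species", "population", "temperature", "replicate")

#: nucleotide order used by the PoPoolation2 "sync" format
SYNC_BASES = ("A", "T", "C", "G", "N", "del")


class CountMatrix:
    """Gene x sample integer count table plus its factorial sample design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample, nonnegative
        integers.
    design
        DataFrame indexed by sample id with columns
        ``species, population, temperature, replicate`` (extra columns such
        as recorded library factors are carried along untouched).
    """

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame):
        counts = counts.copy()
        design = design.copy()
        if (counts.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        if counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if design.index.has_duplicates:
            raise ValueError("duplicate sample ids in design")
        missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
        if missing:
            raise ValueError(f"design lacks required columns: {missing}")
        if set(counts.columns) != set(design.index):
            raise ValueError("samples in counts and design do not match")
        # keep design ordered as the count columns
        self.counts = counts
        self.design = design.loc[list(counts.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_where(self, **levels) -> list[str]:
        """Sample ids whose design matches every ``column=value`` given."""
        mask = pd.Series(True, index=self.design.index)
        for col, val in levels.items():
            mask &= self.design[col] == val
        return list(self.design.index[mask])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.design)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.design.loc[list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.counts.shape[0]} genes x {self.counts.shape[1]} samples)"


@dataclass
class GeneCatalogue:
    """Gene models with arm assignment, feature intervals and inversion spans.

    ``genes`` columns: gene_id, arm, start, end, strand, exon_length,
    utr5_start, utr5_end, cds_start, cds_end, utr3_start, utr3_end.
    Intervals are 0-based half-open.  ``inversions`` columns: arm, start,
    end, name.
    """

    genes: pd.DataFrame
    inversions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["arm", "start", "end", "name"])
    )

    def __post_init__(self):
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in catalogue")
        if (g["end"] <= g["start"]).any():
            raise ValueError("gene with non-positive span")
        self.genes = g.reset_index(drop=True)

    @property
    def arms(self) -> list[str]:
        return sorted(self.genes["arm"].unique())

    def midpoints(self) -> pd.Series:
        g = self.genes
        return pd.Series((g["start"].values + g["end"].values) // 2, index=g["gene_id"].values)

    def arm_of(self) -> pd.Series:
        return pd.Series(self.genes["arm"].values, index=self.genes["gene_id"].values)

    def genes_in_inversions(self, names=None) -> set[str]:
        """Gene ids whose midpoint lies inside any (named) inversion span."""
        spans = self.inversions
        if names is not None:
            spans = spans[spans["name"].isin(names)]
        mid = self.midpoints()
        arm = self.arm_of()
        hit: set[str] = set()
        for _, sp in spans.iterrows():
            on_arm = arm.index[(arm == sp["arm"]) & (mid >= sp["start"]) & (mid < sp["end"])]
            hit.update(on_arm)
        return hit

    def feature_table(self) -> pd.DataFrame:
        """Long table of (gene_id, arm, feature class, start, end)."""
        rows = []
        for _, g in self.genes.iterrows():
            for cls, a, b in (
                ("5'UTR", g["utr5_start"], g["utr5_end"]),
                ("CDS", g["cds_start"], g["cds_end"]),
                ("3'UTR", g["utr3_start"], g["utr3_end"]),
            ):
                if b > a:
                    rows.append((g["gene_id"], g["arm"], cls, int(a), int(b)))
        return pd.DataFrame(rows, columns=["gene_id", "arm", "class", "start", "end"])


class OrthologMap:
    """One-to-one ortholog pairs between two species."""

    def __init__(self, pairs: pd.DataFrame):
        pairs = pairs.copy()
        pairs.columns = ["gene_a", "gene_b"]
        if pairs["gene_a"].duplicated().any() or pairs["gene_b"].duplicated().any():
            raise ValueError("ortholog map is not one-to-one")
        self.pairs = pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_to_b(self) -> dict:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    @property
    def b_to_a(self) -> dict:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))

    def restrict(self, genes_a, genes_b) -> "OrthologMap":
        """Keep pairs whose members are present in both supplied universes."""
        sa, sb = set(genes_a), set(genes_b)
        keep = self.pairs["gene_a"].isin(sa) & self.pairs["gene_b"].isin(sb)
        return OrthologMap(self.pairs[keep])


class PoolSiteTable:
    """Per-site read counts for two population pools (sync-format content).

    ``sites`` columns: arm, pos (1-based), ref, then for each pool p in
    (1, 2) the six base-count columns ``p{p}_A .. p{p}_del``.
    """

    def __init__(self, sites: pd.DataFrame):
        needed = ["arm", "pos", "ref"] + [
            f"p{p}_{b}" for p in (1, 2) for b in SYNC_BASES
        ]
        missing = [c for c in needed if c not in sites.columns]
        if missing:
            raise ValueError(f"site table lacks columns: {missing}")
        self.sites = sites.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)

    def pool_counts(self, pool: int) -> np.ndarray:
        """(n_sites, 6) base-count array for one pool (A,T,C,G,N,del)."""
        cols = [f"p{pool}_{b}" for b in SYNC_BASES]
        return self.sites[cols].to_numpy(dtype=np.int64)
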