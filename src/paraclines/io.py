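"""Readers and writers for the pipeline's plain-text formats.

Counts/design/ortholog/DE tables are TSV; gene models travel as GFF3
(parsed with gffutils), inversion spans as BED, and pooled site counts in
the PoPoolation2 sync format (TAB: ref, pos, ref base, then per pool
colon-separated A:T:C:G:N:del counts).
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd

from .containers import CountMatrix, GeneCatalogue, OrthologMap, PoolSiteTable, SYNC_BASES


# ---------------------------------------------------------------------------
# counts / design / generic TSV


def write_counts(cm: CountMatrix, counts_path, design_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.design.rename_axis("sample").to_csv(design_path, sep="\t")


def read_counts(counts_path, design_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return CountMatrix(counts, design)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ---------------------------------------------------------------------------
# orthologs


def write_orthologs(orthologs: OrthologMap, path) -> None:
    orthologs.pairs.to_csv(path, sep="\t", index=False, header=False)


def read_orthologs(path) -> OrthologMap:
    pairs = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b"])
    return OrthologMap(pairs)


# ---------------------------------------------------------------------------
# GFF3 / BED


def write_gff3(catalogue: GeneCatalogue, path) -> None:
    """Emit gene/mRNA/CDS/UTR features; internal 0-based half-open intervals
    become 1-based inclusive GFF3 coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in catalogue.genes.iterrows():
            gid = g["gene_id"]
            base = f"{g['arm']}\tparaclines\t"
            tail = f"\t.\t{g['strand']}\t."
            fh.write(f"{base}gene\t{g['start'] + 1}\t{g['end']}{tail}\tID={gid}\n")
            fh.write(
                f"{base}mRNA\t{g['start'] + 1}\t{g['end']}{tail}\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for feat, a, b in (
                ("five_prime_UTR", g["utr5_start"], g["utr5_end"]),
                ("CDS", g["cds_start"], g["cds_end"]),
                ("three_prime_UTR", g["utr3_start"], g["utr3_end"]),
            ):
                if b > a:
                    fh.write(f"{base}{feat}\t{a + 1}\t{b}{tail}\tParent={gid}.t1\n")


def read_gff3(path) -> GeneCatalogue:
    """Rebuild a GeneCatalogue from GFF3 (gene + UTR/CDS children)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        spans = {"five_prime_UTR": None, "CDS": None, "three_prime_UTR": None}
        for child in db.children(gene, level=2):
            if child.featuretype in spans:
                # GFF3 1-based inclusive -> 0-based half-open
                spans[child.featuretype] = (child.start - 1, child.end)
        u5 = spans["five_prime_UTR"] or (gene.start - 1, gene.start - 1)
        cds = spans["CDS"] or (gene.start - 1, gene.start - 1)
        u3 = spans["three_prime_UTR"] or (gene.start - 1, gene.start - 1)
        exon_length = (u5[1] - u5[0]) + (cds[1] - cds[0]) + (u3[1] - u3[0])
        rows.append(
            (gid, gene.seqid, gene.start - 1, gene.end, gene.strand, exon_length,
             u5[0], u5[1], cds[0], cds[1], u3[0], u3[1])
        )
    genes = pd.DataFrame(
        rows,
        columns=["gene_id", "arm", "start", "end", "strand", "exon_length",
                 "utr5_start", "utr5_end", "cds_start", "cds_end",
                 "utr3_start", "utr3_end"],
    ).sort_values(["arm", "start"], kind="stable").reset_index(drop=True)
    return GeneCatalogue(genes)


def write_bed(spans: pd.DataFrame, path) -> None:
    spans[["arm", "start", "end", "name"]].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["arm", "start", "end", "name"])


# ---------------------------------------------------------------------------
# sync


def write_sync(table: PoolSiteTable, path) -> None:
    with open(path, "w") as fh:
        for _, row in table.sites.iterrows():
            pools = [
                ":".join(str(int(row[f"p{p}_{b}"])) for b in SYNC_BASES) for p in (1, 2)
            ]
            fh.write(f"{row['arm']}\t{int(row['pos'])}\t{row['ref']}\t" + "\t".join(pools) + "\n")


def read_sync(path) -> PoolSiteTable:
    raw = pd.read_csv(path, sep="\t", header=None)
    if raw.shape[1] < 5:
        raise ValueError("sync file needs ref, pos, refbase and two pool columns")
    data = {"arm": raw[0], "pos": raw[1].astype(int), "ref": raw[2]}
    for p, col in ((1, 3), (2, 4)):
        split = raw[col].str.split(":", expand=True).astype(int)
        for bi, b in enumerate(SYNC_BASES):
            data[f"p{p}_{b}"] = split[bi]
    return PoolSiteTable(pd.DataFrame(data))


# ---------------------------------------------------------------------------
# bundles


def write_experiment(exp, out_dir) -> None:
    """Write every artifact of a simulated experiment to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, cm in exp.counts.items():
        write_counts(cm, out / f"counts_{sp}.tsv", out / f"design_{sp}.tsv")
    for sp, cat in exp.catalogues.items():
        write_gff3(cat, out / f"genes_{sp}.gff3")
        if len(cat.inversions):
            write_bed(cat.inversions, out / f"inversions_{sp}.bed")
    write_orthologs(exp.orthologs, out / "orthologs.tsv")
    for sp, pool in exp.pools.items():
        write_sync(pool, out / f"pools_{sp}.sync")
    exp.truth.to_dir(out / "truth")
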