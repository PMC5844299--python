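"""Assignment of called CpG sites to gene features and methylation ratios.

A site falling in any exon interval of a gene counts as exonic for that
gene; inside the gene span but outside every exon it is intronic; and
within the strand-aware 2 kb window upstream of the TSS it belongs to
the upstream class.  A site may be assigned to several overlapping
genes and is counted in each.  Per gene and feature class the
methylation ratio is methylated-called CpGs over detected CpGs
(mCpG/CpG); genes are classified methylated when their exon ratio
exceeds the threshold (default 0.10, strict inequality).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel

__all__ = [
    "FEATURE_CLASSES",
    "assign_sites",
    "compute_ratios",
    "classify_genes",
    "feature_summary",
]

FEATURE_CLASSES = ("exon", "intron", "upstream2kb")


def _build_trees(
    genes: Iterable[GeneModel],
    contig_lengths: Mapping[str, int] | None,
    upstream: int,
) -> dict[str, IntervalTree]:
    """One interval tree per chromosome; payload (gene_id, kind).

    kind 'exon' and 'span' resolve exon-vs-intron within a gene; kind
    'upstream' is independent of the genic classes.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        # intervaltree is half-open; +1 converts 1-based inclusive ends
        tree.addi(g.start, g.end + 1, (g.gene_id, "span"))
        for s, e in g.exons:
            tree.addi(s, e + 1, (g.gene_id, "exon"))
        clen = contig_lengths.get(g.chrom) if contig_lengths else None
        up = g.upstream_interval(window=upstream, contig_length=clen)
        if up is not None:
            tree.addi(up[0], up[1] + 1, (g.gene_id, "upstream"))
    return trees


def assign_sites(
    calls: pd.DataFrame,
    genes: Iterable[GeneModel],
    contig_lengths: Mapping[str, int] | None = None,
    upstream: int = 2000,
) -> pd.DataFrame:
    """Map each called site to (gene_id, feature_class) pairs.

    Returns one row per (site, gene, feature) assignment with columns
    chrom, pos, strand, gene_id, feature_class.  Exon takes precedence
    over intron within one gene; upstream assignments are additional.
    """
    genes = list(genes)
    trees = _build_trees(genes, contig_lengths, upstream)
    rows_chrom, rows_pos, rows_strand, rows_gene, rows_feat = [], [], [], [], []
    for chrom, chrom_calls in calls.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for pos, strand in zip(chrom_calls["pos"], chrom_calls["strand"]):
            hits = tree[int(pos)]
            if not hits:
                continue
            genic: dict[str, str] = {}
            upstream_hits: list[str] = []
            for iv in hits:
                gid, kind = iv.data
                if kind == "exon":
                    genic[gid] = "exon"
                elif kind == "span":
                    genic.setdefault(gid, "intron")
                else:
                    upstream_hits.append(gid)
            for gid, feat in genic.items():
                rows_chrom.append(chrom)
                rows_pos.append(int(pos))
                rows_strand.append(strand)
                rows_gene.append(gid)
                rows_feat.append(feat)
            for gid in upstream_hits:
                rows_chrom.append(chrom)
                rows_pos.append(int(pos))
                rows_strand.append(strand)
                rows_gene.append(gid)
                rows_feat.append("upstream2kb")
    return pd.DataFrame(
        {
            "chrom": rows_chrom,
            "pos": rows_pos,
            "strand": rows_strand,
            "gene_id": rows_gene,
            "feature_class": rows_feat,
        }
    )


def compute_ratios(
    assignment: pd.DataFrame,
    calls: pd.DataFrame,
    genes: Iterable[GeneModel] | None = None,
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-gene methylation ratios and classification.

    Joins the site assignments with the call table and aggregates per
    gene and feature class: detected CpGs, methylated-called CpGs and
    their ratio.  Genes with zero detected CpGs in a feature class get a
    NaN (undefined) ratio, never a silent 0.  When ``genes`` is given,
    genes without any detected site appear with all-NaN ratios.

    Returns one row per gene with columns ``{feat}_n_detected``,
    ``{feat}_n_methylated``, ``{feat}_ratio`` for each feature class,
    plus ``has_any_mcpg`` and ``gene_class``.
    """
    merged = assignment.merge(
        calls[["chrom", "pos", "strand", "is_methylated"]],
        on=["chrom", "pos", "strand"],
        how="left",
        validate="many_to_one",
    )
    agg = (
        merged.groupby(["gene_id", "feature_class"])["is_methylated"]
        .agg(n_detected="size", n_methylated="sum")
        .reset_index()
    )
    wide = agg.pivot(index="gene_id", columns="feature_class", values=["n_detected", "n_methylated"])
    out = pd.DataFrame(index=wide.index)
    for feat in FEATURE_CLASSES:
        nd = (
            wide[("n_detected", feat)]
            if ("n_detected", feat) in wide.columns
            else pd.Series(np.nan, index=wide.index)
        )
        nm = (
            wide[("n_methylated", feat)]
            if ("n_methylated", feat) in wide.columns
            else pd.Series(np.nan, index=wide.index)
        )
        nd = nd.fillna(0).astype(int)
        nm = nm.where(nd > 0, 0).fillna(0).astype(int)
        out[f"{feat}_n_detected"] = nd
        out[f"{feat}_n_methylated"] = nm
        out[f"{feat}_ratio"] = np.where(nd > 0, nm / nd.replace(0, 1), np.nan)
    if genes is not None:
        all_ids = pd.Index([g.gene_id for g in genes], name="gene_id")
        out = out.reindex(all_ids.union(out.index, sort=False))
        for feat in FEATURE_CLASSES:
            out[f"{feat}_n_detected"] = out[f"{feat}_n_detected"].fillna(0).astype(int)
            out[f"{feat}_n_methylated"] = out[f"{feat}_n_methylated"].fillna(0).astype(int)
    ncols = [f"{f}_n_methylated" for f in FEATURE_CLASSES]
    out["has_any_mcpg"] = out[ncols].sum(axis=1) > 0
    out = classify_genes(out, threshold=threshold)
    return out.reset_index().rename(columns={"index": "gene_id"})


def classify_genes(gene_table: pd.DataFrame, threshold: float = 0.10) -> pd.DataFrame:
    """Partition genes into methylated / nonmethylated by exon ratio.

    Strictly greater than the threshold means methylated; genes with an
    undefined exon ratio (no detected exonic CpG) are left unclassified
    (``gene_class`` is NA).
    """
    out = gene_table.copy()
    ratio = out["exon_ratio"]
    cls = pd.Series(pd.NA, index=out.index, dtype="object")
    cls[ratio > threshold] = "methylated"
    cls[(ratio <= threshold)] = "nonmethylated"
    cls[ratio.isna()] = pd.NA
    out["gene_class"] = cls
    return out


def feature_summary(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide percent of CpGs methylated per feature class.

    The aggregate is the count-weighted mean: total methylated-called
    CpGs over total detected CpGs in that class, as a percentage, plus
    the unweighted mean of per-gene ratios.
    """
    rows = []
    for feat in FEATURE_CLASSES:
        nd = int(gene_table[f"{feat}_n_detected"].sum())
        nm = int(gene_table[f"{feat}_n_methylated"].sum())
        ratios = gene_table[f"{feat}_ratio"].dropna()
        rows.append(
            {
                "feature_class": feat,
                "n_detected": nd,
                "n_methylated": nm,
                "percent_mC": 100.0 * nm / nd if nd else np.nan,
                "mean_gene_ratio": float(ratios.mean()) if len(ratios) else np.nan,
            }
        )
    return pd.DataFrame(rows)
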