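"""Joining gene-level methylation with expression.

Expression arrives as TMM-normalised FPKM per gene; methylation as the
per-gene exon ratio and class from :mod:`feature_methylation`.  The
statistics mirror the standard insect gene-body-methylation analyses:
a Spearman rank correlation of exon ratio with FPKM, a rank-based
comparison of expression between methylated and nonmethylated genes,
the overlap between silent (FPKM = 0) genes and genes with zero
methylated exonic CpGs, and binned expression profiles over 10%-wide
exon-ratio bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "join_expression",
    "correlate",
    "compare_class_expression",
    "zero_expression_overlap",
    "binned_expression_profile",
]

BIN_EDGES = np.linspace(0.0, 1.0, 11)


def join_expression(
    gene_table: pd.DataFrame, expression: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Inner join of methylation and expression tables on gene_id.

    Returns the joined frame plus an accounting dict so that genes
    present in only one input are reported, never silently dropped.
    """
    if "fpkm" not in expression.columns:
        raise ValueError("expression table needs columns gene_id, fpkm")
    if (expression["fpkm"] < 0).any():
        raise ValueError("FPKM values must be >= 0")
    joined = gene_table.merge(expression[["gene_id", "fpkm"]], on="gene_id", how="inner")
    meth_only = set(gene_table["gene_id"]) - set(expression["gene_id"])
    expr_only = set(expression["gene_id"]) - set(gene_table["gene_id"])
    report = {
        "n_joined": int(len(joined)),
        "n_methylation_only": len(meth_only),
        "n_expression_only": len(expr_only),
    }
    return joined, report


def correlate(join: pd.DataFrame) -> tuple[float, float]:
    """Spearman rho and p of exon methylation ratio vs FPKM."""
    sub = join.dropna(subset=["exon_ratio", "fpkm"])
    if len(sub) < 10:
        raise ValueError("need at least 10 genes with both measurements")
    x = sub["exon_ratio"].to_numpy()
    y = sub["fpkm"].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant column; Spearman correlation undefined")
    res = _sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_class_expression(join: pd.DataFrame, paired: bool = False) -> dict:
    """Expression of methylated vs nonmethylated genes.

    Default is the independent-samples rank test (Mann-Whitney U);
    ``paired=True`` switches to the Wilcoxon signed-rank test, which is
    only applicable when the two classes form matched pairs of equal
    size.  Medians are reported on the FPKM scale.
    """
    meth = join.loc[join["gene_class"] == "methylated", "fpkm"].dropna().to_numpy()
    non = join.loc[join["gene_class"] == "nonmethylated", "fpkm"].dropna().to_numpy()
    if len(meth) < 2 or len(non) < 2:
        raise ValueError("each class needs at least 2 genes with expression")
    if paired:
        if len(meth) != len(non):
            raise ValueError("signed-rank test needs equal-size paired samples")
        stat, p = _sps.wilcoxon(meth, non)
        test = "wilcoxon-signed-rank"
    else:
        stat, p = _sps.mannwhitneyu(meth, non, alternative="two-sided")
        test = "mann-whitney-u"
    return {
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "median_methylated": float(np.median(meth)),
        "median_nonmethylated": float(np.median(non)),
        "n_methylated": int(len(meth)),
        "n_nonmethylated": int(len(non)),
    }


def zero_expression_overlap(join: pd.DataFrame) -> dict:
    """Silent genes vs genes lacking any methylated exonic CpG.

    Reports (a) among FPKM = 0 genes, the fraction with zero
    methylated-called exonic CpGs, and (b) the same fraction over all
    joined genes.  (a) is NaN-flagged when there are no silent genes.
    """
    zero_meth = join["exon_n_methylated"].fillna(0) == 0
    silent = join["fpkm"] == 0
    n_silent = int(silent.sum())
    frac_all = float(zero_meth.mean()) if len(join) else float("nan")
    if n_silent == 0:
        frac_silent = float("nan")
    else:
        frac_silent = float(zero_meth[silent].mean())
    return {
        "n_silent": n_silent,
        "frac_silent_zero_methylation": frac_silent,
        "frac_all_zero_methylation": frac_all,
        "defined": n_silent > 0,
    }


def binned_expression_profile(join: pd.DataFrame) -> pd.DataFrame:
    """Expression summary per 10%-wide exon-ratio bin.

    Bins are [0,0.1), ..., [0.9,1.0] with the top edge closed.  Summaries
    (median and quartiles of log10 FPKM) use expressed genes only; bin
    counts include silent genes.  Empty bins are retained with n = 0.
    """
    sub = join.dropna(subset=["exon_ratio"])
    idx = np.clip(
        np.digitize(sub["exon_ratio"].to_numpy(), BIN_EDGES[1:-1], right=False), 0, 9
    )
    rows = []
    for b in range(10):
        in_bin = sub.loc[idx == b]
        expressed = in_bin.loc[in_bin["fpkm"] > 0, "fpkm"]
        logv = np.log10(expressed.to_numpy()) if len(expressed) else np.array([])
        rows.append(
            {
                "bin_left": BIN_EDGES[b],
                "bin_right": BIN_EDGES[b + 1],
                "n": int(len(in_bin)),
                "n_expressed": int(len(expressed)),
                "median_log10_fpkm": float(np.median(logv)) if logv.size else np.nan,
                "q25_log10_fpkm": float(np.percentile(logv, 25)) if logv.size else np.nan,
                "q75_log10_fpkm": float(np.percentile(logv, 75)) if logv.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
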