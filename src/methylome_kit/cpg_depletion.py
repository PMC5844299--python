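"""CpG observed/expected depletion statistic per gene.

Historically methylated cytosines deaminate to thymine, so genes with a
long history of methylation are depleted of CpG dinucleotides relative
to the expectation from their mononucleotide composition.  The
normalised statistic is

    CpG O/E = (count(CG) * L) / (count(C) * count(G))

over the gene's sequence (gene body by default, concatenated exons on
request), with N bases excluded from all counts and from L.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io_formats import GeneModel, load_genome

__all__ = ["compute_cpg_oe", "gene_cpg_oe", "compare_classes"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def compute_cpg_oe(sequence: str) -> float:
    """CpG O/E of a nucleotide string; NaN when C or G is absent.

    Counts are taken on the given strand only.  N bases do not count
    toward C, G, CG or the length (an N interrupts any CG it touches).
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    s = sequence.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    if n_c == 0 or n_g == 0:
        return float("nan")
    n_cg = s.count("CG")
    length = len(s) - s.count("N")
    return (n_cg * length) / (n_c * n_g)


def gene_cpg_oe(
    fasta: str | Mapping[str, str],
    genes: Iterable[GeneModel],
    region: str = "gene",
) -> pd.DataFrame:
    """Per-gene CpG O/E over the gene body or concatenated exons.

    The sequence is taken on the annotated strand (reverse complement
    for − strand genes); region 'gene' spans exons+introns, 'exons'
    concatenates exons in genomic order.
    """
    if region not in ("gene", "exons"):
        raise ValueError("region must be 'gene' or 'exons'")
    genome = load_genome(fasta)
    rows = []
    for g in genes:
        contig = genome[g.chrom]
        if region == "gene":
            seq = contig[g.start - 1 : g.end]
        else:
            seq = "".join(contig[s - 1 : e] for s, e in g.exons)
        if g.strand == "-":
            seq = seq.translate(_COMP)[::-1]
        s = seq.upper()
        rows.append(
            {
                "gene_id": g.gene_id,
                "cpg_oe": compute_cpg_oe(s) if len(s) >= 2 else float("nan"),
                "length": len(s) - s.count("N"),
                "n_cpg": s.count("CG"),
                "n_c": s.count("C"),
                "n_g": s.count("G"),
            }
        )
    return pd.DataFrame(rows)


def compare_classes(
    oe: pd.DataFrame, gene_table: pd.DataFrame
) -> dict:
    """Compare CpG O/E between methylated and nonmethylated genes.

    Joins on gene_id and reports per-class means, an F variance-ratio
    statistic with (n1-1, n2-1) degrees of freedom, a Welch two-sample
    mean comparison, and the Spearman correlation of exon methylation
    ratio with CpG O/E (expected negative when depletion tracks
    methylation).
    """
    merged = oe.merge(
        gene_table[["gene_id", "exon_ratio", "gene_class"]], on="gene_id"
    ).dropna(subset=["cpg_oe", "gene_class"])
    meth = merged.loc[merged["gene_class"] == "methylated", "cpg_oe"].to_numpy()
    non = merged.loc[merged["gene_class"] == "nonmethylated", "cpg_oe"].to_numpy()
    if len(meth) < 2 or len(non) < 2:
        raise ValueError("each methylation class needs at least 2 genes with CpG O/E")
    var_m, var_n = np.var(meth, ddof=1), np.var(non, ddof=1)
    f_stat = var_m / var_n
    df1, df2 = len(meth) - 1, len(non) - 1
    # two-sided variance-ratio p
    cdf = _sps.f.cdf(f_stat, df1, df2)
    f_p = 2.0 * min(cdf, 1.0 - cdf)
    t_stat, t_p = _sps.ttest_ind(meth, non, equal_var=False)
    both = merged.dropna(subset=["exon_ratio"])
    rho, rho_p = _sps.spearmanr(both["exon_ratio"], both["cpg_oe"])
    return {
        "n_methylated": int(len(meth)),
        "n_nonmethylated": int(len(non)),
        "mean_methylated": float(np.mean(meth)),
        "mean_nonmethylated": float(np.mean(non)),
        "f_statistic": float(f_stat),
        "f_df": (df1, df2),
        "f_p": float(min(f_p, 1.0)),
        "t_statistic": float(t_stat),
        "t_p": float(t_p),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }
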