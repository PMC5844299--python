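"""Binomial methylation calling at single CpG sites.

Each site with at least ``min_reads`` aligned reads is tested against
the null that all apparent methylation is bisulfite non-conversion
error: with count ``k`` methylated of ``n`` total, the one-sided
p-value is P[X >= k] for X ~ Binomial(n, error_rate).  Benjamini-
Hochberg adjustment is computed over the tested sites only, and a site
is called methylated at adjusted P < alpha.  The error rate defaults to
0.01 (conversion > 99%) and can be estimated from non-CpG cytosines,
which are assumed unmethylated in insects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .distribution_stats import bh_adjust
from .io_formats import CYTOSINE_REPORT_COLUMNS, CytosineRecord

__all__ = [
    "SiteCall",
    "estimate_error_rate",
    "call_sites",
    "summarize_calls",
    "methylation_percentages",
]

CALL_COLUMNS = (
    "chrom", "pos", "strand", "n_meth", "n_total", "level",
    "p_raw", "p_adj", "is_methylated",
)


@dataclass(frozen=True)
class SiteCall:
    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_total: int
    level: float
    p_raw: float
    p_adj: float
    is_methylated: bool


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    recs = list(records)
    if recs and isinstance(recs[0], CytosineRecord):
        return pd.DataFrame(recs, columns=CYTOSINE_REPORT_COLUMNS)
    return pd.DataFrame(recs)


def estimate_error_rate(
    records, mode: str = "non_cpg", value: float | None = None
) -> float:
    """Bisulfite non-conversion error rate in [0, 1].

    ``non_cpg`` mode pools methylated over total read counts across all
    CHG/CHH records (assumed truly unmethylated); ``fixed`` mode returns
    the user-supplied value unchanged.
    """
    if mode == "fixed":
        if value is None or not (0.0 <= value <= 1.0):
            raise ValueError("fixed mode needs an error-rate value in [0, 1]")
        return float(value)
    if mode != "non_cpg":
        raise ValueError(f"unknown mode {mode!r}; use 'non_cpg' or 'fixed'")
    df = _as_frame(records)
    non_cpg = df[df["context"].isin(("CHG", "CHH"))]
    total = int(non_cpg["n_meth"].sum() + non_cpg["n_unmeth"].sum())
    if total == 0:
        raise ValueError(
            "no non-CpG observations in the input; supply mode='fixed' with an "
            "explicit error rate instead"
        )
    return float(non_cpg["n_meth"].sum() / total)


def call_sites(
    records,
    error_rate: float = 0.01,
    min_reads: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-site binomial methylation calls with BH adjustment.

    Sites with fewer than ``min_reads`` total reads are excluded before
    testing, so the BH family is exactly the tested set.  Returns a
    DataFrame with columns chrom, pos, strand, n_meth, n_total, level,
    p_raw, p_adj, is_methylated.
    """
    if not (0.0 < error_rate < 1.0):
        raise ValueError(f"error_rate must be in (0, 1), got {error_rate}")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    df = _as_frame(records)
    if df.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    n_meth = df["n_meth"].to_numpy(dtype=np.int64)
    n_total = n_meth + df["n_unmeth"].to_numpy(dtype=np.int64)
    keep = n_total >= min_reads
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy()[keep],
            "pos": df["pos"].to_numpy(dtype=np.int64)[keep],
            "strand": df["strand"].to_numpy()[keep],
            "n_meth": n_meth[keep],
            "n_total": n_total[keep],
        }
    )
    out["level"] = out["n_meth"] / out["n_total"]
    # upper tail P[X >= k] = sf(k - 1)
    out["p_raw"] = _sps.binom.sf(out["n_meth"] - 1, out["n_total"], error_rate)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["is_methylated"] = out["p_adj"] < alpha
    return out


def methylation_percentages(
    n_methylated: int, genome_cpg_total: int, n_detected: int
) -> tuple[float, float]:
    """(percent of genomic CpGs methylated, percent of detected CpGs).

    Both on the 0-100 scale: 100*n_methylated/genome_cpg_total and
    100*n_methylated/n_detected.
    """
    if genome_cpg_total <= 0 or n_detected <= 0:
        raise ValueError("totals must be positive")
    return (
        100.0 * n_methylated / genome_cpg_total,
        100.0 * n_methylated / n_detected,
    )


def summarize_calls(calls: pd.DataFrame, genome_cpg_total: int) -> dict:
    """Genome-scale summary of a call table.

    Reports detected and methylated site counts, the methylated sites as
    a percentage of all genomic CpGs and of the detected CpGs, and mean
    coverage of detected sites.
    """
    n_detected = int(len(calls))
    n_methylated = int(calls["is_methylated"].sum()) if n_detected else 0
    if n_detected == 0:
        pct_genomic = 100.0 * n_methylated / genome_cpg_total
        pct_detected = 0.0
        mean_cov = float("nan")
    else:
        pct_genomic, pct_detected = methylation_percentages(
            n_methylated, genome_cpg_total, n_detected
        )
        mean_cov = float(calls["n_total"].mean())
    return {
        "n_detected": n_detected,
        "n_methylated": n_methylated,
        "percent_of_genomic": pct_genomic,
        "percent_of_detected": pct_detected,
        "mean_coverage": mean_cov,
    }
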