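"""Targeted bisulfite amplicon analysis between two phenotype groups.

Per sample and CpG site the fractional methylation is methylated reads
over total reads.  Sites are retained when at least one sample reaches
``min_reads`` (default 10) coverage; retained sites with thinner
coverage in some sample contribute missing values there, and each
site's group comparison is complete-case.  Group means are averages of
per-sample fractions; the difference is reported as first group minus
second (long-distance minus short-distance fliers in the motivating
design) and compared with a Student's t-test (Welch by flag).  Raw
p-values are the primary output; a BH-adjusted column is emitted
alongside for transparency.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .distribution_stats import bh_adjust

__all__ = ["site_fractions", "compare_groups", "concordance_wgbs"]

SITE_KEYS = ["gene_id", "scaffold", "pos"]


def site_fractions(
    sample_tables: Mapping[str, pd.DataFrame], min_reads: int = 10
) -> tuple[pd.DataFrame, int]:
    """Per-site-per-sample fraction matrix after coverage filtering.

    Every sample table needs columns gene_id, scaffold, pos, n_meth,
    n_total over the same site set (same coordinate space).  Returns
    (fractions indexed by site keys with one column per sample, number
    of sites dropped by the >= min_reads-in->=1-sample rule).
    """
    if not sample_tables:
        raise ValueError("no sample tables given")
    frames = {}
    ref_index = None
    for sid, tab in sample_tables.items():
        missing = set(SITE_KEYS + ["n_meth", "n_total"]) - set(tab.columns)
        if missing:
            raise ValueError(f"sample {sid}: missing columns {sorted(missing)}")
        t = tab.set_index(SITE_KEYS)
        if ref_index is None:
            ref_index = t.index
        elif not t.index.equals(ref_index):
            raise ValueError(
                f"sample {sid}: site coordinates differ from the first sample"
            )
        frames[sid] = t
    frac = pd.DataFrame(index=ref_index)
    cov = pd.DataFrame(index=ref_index)
    for sid, t in frames.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            frac[sid] = np.where(t["n_total"] > 0, t["n_meth"] / t["n_total"], np.nan)
        cov[sid] = t["n_total"]
    keep = (cov >= min_reads).any(axis=1)
    n_dropped = int((~keep).sum())
    frac = frac.loc[keep]
    # below-threshold observations at retained sites become missing
    frac = frac.mask(cov.loc[keep] < min_reads)
    return frac, n_dropped


def compare_groups(
    fractions: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    groups: Sequence[str] = ("long", "short"),
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-site two-group comparison of fractional methylation.

    ``labels`` maps sample id -> group; ``groups`` fixes the sign
    convention (first minus second).  Sites with fewer than 2
    non-missing samples in either group are flagged ``skipped`` with
    NaN statistics.  Output is sorted by |meth_diff| descending.
    Degenerate sites where both groups are constant get p = 1 when the
    means agree and p = 0 when they differ.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    g1, g2 = groups
    cols1 = [c for c in fractions.columns if labels.get(c) == g1]
    cols2 = [c for c in fractions.columns if labels.get(c) == g2]
    if not cols1 or not cols2:
        raise ValueError(f"need samples in both groups {groups}")
    rows = []
    for key, row in fractions.iterrows():
        a = row[cols1].dropna().to_numpy(dtype=float)
        b = row[cols2].dropna().to_numpy(dtype=float)
        rec = dict(zip(SITE_KEYS, key if isinstance(key, tuple) else (key,)))
        rec["n_" + g1] = len(a)
        rec["n_" + g2] = len(b)
        if len(a) < 2 or len(b) < 2:
            rec.update(
                {f"mean_{g1}": np.nan, f"mean_{g2}": np.nan, "meth_diff": np.nan,
                 "t_statistic": np.nan, "p_value": np.nan, "skipped": True}
            )
            rows.append(rec)
            continue
        ma, mb = float(a.mean()), float(b.mean())
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            t, p = (0.0, 1.0) if ma == mb else (np.inf * np.sign(ma - mb), 0.0)
        else:
            t, p = _sps.ttest_ind(a, b, equal_var=equal_var)
        rec.update(
            {f"mean_{g1}": ma, f"mean_{g2}": mb, "meth_diff": ma - mb,
             "t_statistic": float(t), "p_value": float(p), "skipped": False}
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    out["p_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_bh"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    return (
        out.reindex(out["meth_diff"].abs().sort_values(ascending=False, kind="mergesort").index)
        .reset_index(drop=True)
    )


def concordance_wgbs(
    amplicon_means: pd.Series | np.ndarray, wgbs_levels: pd.Series | np.ndarray
) -> dict:
    """Agreement between amplicon-average and WGBS methylation levels.

    Least-squares fit of the amplicon mean on the WGBS level over shared
    sites; reports R^2, slope, intercept and the regression p-value, and
    flags a negative slope (anti-correlated inputs).
    """
    x = np.asarray(wgbs_levels, dtype=float)
    y = np.asarray(amplicon_means, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 shared sites")
    res = _sps.linregress(x, y)
    return {
        "n_sites": int(x.size),
        "r_squared": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "p_value": float(res.pvalue),
        "negative_slope": bool(res.slope < 0),
    }
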