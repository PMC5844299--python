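"""Statistical machinery shared by the methylome pipeline.

The centrepiece is Hartigan & Hartigan's dip statistic — the largest
vertical distance between the empirical CDF and the closest unimodal
CDF — implemented here from first principles via the iterative greatest
convex minorant (GCM) / least concave majorant (LCM) algorithm, with a
Monte-Carlo uniform null for p-values.  Alongside it live the
Benjamini–Hochberg step-up adjustment and Fisher-exact term enrichment
used throughout the pipeline; plain rank statistics (Spearman,
Mann-Whitney/Wilcoxon) are delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "DipResult",
    "EnrichmentRow",
    "dip_statistic",
    "dip_test",
    "bh_adjust",
    "fisher_enrichment",
    "spearman",
    "rank_two_group",
]


# ---------------------------------------------------------------------------
# Hartigan's dip statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DipResult:
    """Outcome of a Monte-Carlo dip test.

    ``p_value`` is the plus-one-corrected fraction of uniform(0,1) samples
    of the same size whose dip is at least the observed dip.
    """

    dip: float
    p_value: float
    n: int
    n_boot: int
    seed: int | None = None


def dip_statistic(values: Sequence[float]) -> float:
    """Dip statistic of a univariate sample.

    The dip is ``min over unimodal CDFs U of sup_x |F_n(x) - U(x)|``.
    It is bounded below by ``1/(2n)`` (attained by any sample compatible
    with a unimodal law, e.g. an equispaced grid) and above by ``0.25``
    (approached by a balanced two-point mixture).

    Parameters
    ----------
    values : array-like
        Sample of size >= 4; need not be sorted.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.ndim != 1:
        raise ValueError("dip_statistic expects a 1-D sample")
    if x.size < 4:
        raise ValueError(f"dip statistic needs n >= 4 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic requires finite values")
    return _dip_sorted(x)


def _dip_sorted(xs: np.ndarray) -> float:
    """GCM/LCM iteration on a sorted sample (1-based index arithmetic).

    Works in "count" units internally; the final division by 2n converts
    to the probability scale.  Degenerate (all-equal) samples return the
    conventional minimum 1/(2n).
    """
    n = xs.size
    # 1-based arrays: index 0 unused.
    x = np.empty(n + 1)
    x[1:] = xs
    if n < 2 or x[1] == x[n]:
        return 1.0 / (2.0 * n)

    low, high = 1, n
    dip = 1.0  # count units; enforces the 1/(2n) floor

    # mn[j]: previous point through which the GCM can skip from j.
    mn = np.zeros(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    # mj[k]: next point through which the LCM can skip from k.
    mj = np.zeros(n + 1, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    gcm = np.zeros(n + 2, dtype=np.int64)  # change points, high -> low
    lcm = np.zeros(n + 2, dtype=np.int64)  # change points, low -> high

    while True:
        # Collect GCM change points on [low, high], from high down to low.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i            # gcm[l_gcm] == low
        ix = l_gcm - 1

        # Collect LCM change points on [low, high], from low up to high.
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i            # lcm[l_lcm] == high
        iv = 2

        ig, ih = l_gcm, l_lcm
        # Largest distance between the GCM and the LCM fits on [low, high].
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next knot comes from the LCM: distance at lcm[iv]
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next knot comes from the GCM: distance at gcm[ix]
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # Max deviation of the ECDF below the GCM over the part being discarded.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Max deviation of the ECDF above the LCM over the part being discarded.
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l >= dip_u else dip_u
        if dip < dipnew:
            dip = dipnew

        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def dip_test(
    values: Sequence[float],
    n_boot: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DipResult:
    """Monte-Carlo dip test for unimodality.

    The null distribution of the dip is sampled from uniform(0,1) — the
    asymptotically least favourable unimodal law — at the observed sample
    size.  ``p = (1 + #{dip_boot >= dip_obs}) / (n_boot + 1)``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a meaningful Monte-Carlo p-value")
    x = np.asarray(values, dtype=float)
    observed = dip_statistic(x)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = x.size
    exceed = 0
    for _ in range(n_boot):
        boot = np.sort(rng.random(n))
        if _dip_sorted(boot) >= observed:
            exceed += 1
    p = (1.0 + exceed) / (n_boot + 1.0)
    return DipResult(dip=observed, p_value=p, n=n, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, in the input order.

    Step-up rule: sort ascending, multiply p_(i) by m/i, take the running
    minimum from the largest rank down, clip at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adj, 0.0, 1.0, out=adj)
    out = np.empty_like(adj)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Fisher-exact term enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    a: int  # term & target
    b: int  # term & (background \ target)
    c: int  # target without term
    d: int  # (background \ target) without term
    odds_ratio: float
    p_fisher: float
    fdr: float
    enriched: bool


def fisher_enrichment(
    target_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_to_terms: Mapping[str, Iterable[str]] | pd.DataFrame,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher-exact enrichment of terms in a target gene set.

    ``gene_to_terms`` maps gene id -> iterable of term ids, or is a
    two-column DataFrame (gene, term).  The target must be a subset of
    the background; BH-FDR is applied across all tested terms and rows
    with ``fdr < fdr_alpha`` are flagged enriched.
    """
    target = set(target_genes)
    background = set(background_genes)
    if not target:
        raise ValueError("target gene set is empty")
    if not target <= background:
        raise ValueError("target genes must be a subset of the background")

    if isinstance(gene_to_terms, pd.DataFrame):
        if gene_to_terms.shape[1] < 2:
            raise ValueError("gene->term DataFrame needs two columns (gene, term)")
        gcol, tcol = gene_to_terms.columns[:2]
        mapping: dict[str, set[str]] = {}
        for g, t in zip(gene_to_terms[gcol], gene_to_terms[tcol]):
            mapping.setdefault(str(g), set()).add(str(t))
    else:
        mapping = {g: set(ts) for g, ts in gene_to_terms.items()}

    term_genes: dict[str, set[str]] = {}
    for gene in background:
        for term in mapping.get(gene, ()):  # genes without terms simply count as background
            term_genes.setdefault(term, set()).add(gene)

    n_target = len(target)
    n_rest = len(background) - n_target
    rows = []
    for term, genes in sorted(term_genes.items()):
        a = len(genes & target)
        b = len(genes) - a
        c = n_target - a
        d = n_rest - b
        odds, p = _sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term, a, b, c, d, odds, p))
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "a", "b", "c", "d", "odds_ratio", "p_fisher", "fdr", "enriched"]
        )
    df = pd.DataFrame(rows, columns=["term_id", "a", "b", "c", "d", "odds_ratio", "p_fisher"])
    df["fdr"] = bh_adjust(df["p_fisher"].to_numpy())
    df["enriched"] = df["fdr"] < fdr_alpha
    return df.sort_values("p_fisher", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Rank statistics (thin scipy delegates)
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties); returns (rho, p)."""
    res = _sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def rank_two_group(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Rank-based two-group comparison; returns (statistic, p).

    Unpaired (default): Mann–Whitney U / Wilcoxon rank-sum.  Paired:
    Wilcoxon signed-rank, which requires equal-length paired samples.
    """
    if paired:
        res = _sps.wilcoxon(x, y)
    else:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
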