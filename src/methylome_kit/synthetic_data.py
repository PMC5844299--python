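"""Synthetic WGBS study generator.

Produces a small genome with annotated genes, a bimodal gene-level
methylation landscape, binomially sampled bisulfite read counts with a
~1% non-conversion error, expression coupled to methylation class, CpG
depletion proportional to historical methylation, and two-group
targeted-amplicon panels with planted per-site differences — the
statistical structure the downstream analysis assumes, so that every
stage is testable without external data.

Model summary
-------------
* Genes carry a latent class: "methylated" (probability
  ``frac_methylated_genes``) or "nonmethylated".  Each gene draws a
  methylation propensity pi — the fraction of its CpGs that are truly
  methylated — from the class Beta (``beta_params_high`` or
  ``beta_params_low``); the Beta mixture is what makes the gene-level
  exon methylation ratio bimodal.  Individual CpG dinucleotides are
  then binary, the sparse-methylome regime of insects: truly
  methylated with probability pi (attenuated by
  ``intron_attenuation`` in introns), carrying a high per-site
  fraction drawn from ``site_level_params``, or truly unmethylated
  (fraction exactly 0).  Intergenic CpGs are methylated with the small
  ``background_methylation`` probability.
* Historical deamination is applied at the sequence level: inside
  methylated genes each CG is rewritten to TG or CA with probability
  ``deamination_strength``, so CpG O/E depletion emerges from the
  sequence rather than being painted on.
* The observation model is read sampling: coverage is negative
  binomial around ``mean_coverage`` and methylated-read counts are
  Binomial(coverage, m*(1 - over_conversion_rate) + (1 - m)*error_rate).
* Expression is log-normal around a class-shifted mean and a fraction
  of genes (mostly nonmethylated) is silenced to FPKM = 0.

Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    write_cytosine_report,
    write_fasta,
    write_gff,
)

__all__ = [
    "SimulationConfig",
    "TrueState",
    "SimulatedStudy",
    "simulate_genome",
    "simulate_counts",
    "simulate_expression",
    "simulate_amplicon_panel",
    "simulate_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the study design
    (28x mean coverage, >99% conversion, a minority class of highly
    methylated genes, exon-biased methylation).
    """

    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 500_000
    gc_fraction: float = 0.37
    n_genes: int = 400
    frac_methylated_genes: float = 0.2
    beta_params_low: tuple[float, float] = (0.5, 40.0)
    beta_params_high: tuple[float, float] = (8.0, 2.0)
    site_level_params: tuple[float, float] = (20.0, 3.0)
    intron_attenuation: float = 0.2
    mean_coverage: float = 28.0
    coverage_dispersion: float = 8.0
    error_rate: float = 0.01
    over_conversion_rate: float = 0.0
    background_methylation: float = 0.002
    deamination_strength: float = 0.4
    expression_baseline: float = 0.8
    expression_coupling: float = 0.8
    expression_sd: float = 0.55
    silent_fraction_nonmethylated: float = 0.12
    silent_fraction_methylated: float = 0.01
    non_cpg_fraction: float = 0.1
    exon_count_range: tuple[int, int] = (2, 6)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (200, 800)
    min_intergenic: int = 300

    def __post_init__(self):
        for name in (
            "gc_fraction", "frac_methylated_genes", "error_rate",
            "over_conversion_rate", "background_methylation",
            "deamination_strength", "silent_fraction_nonmethylated",
            "silent_fraction_methylated", "non_cpg_fraction",
            "intron_attenuation",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")


@dataclass
class TrueState:
    """Ground truth recorded alongside the synthetic outputs.

    ``genes``: per-gene class label and (after simulate_expression) true
    expression.  ``sites``: per-CpG-cytosine true methylation fraction
    with the gene/feature it falls in ('intergenic' otherwise).
    """

    genes: pd.DataFrame
    sites: pd.DataFrame


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    truth: TrueState
    counts: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sequences.items()}


# ---------------------------------------------------------------------------
# genome + annotation + true methylation states
# ---------------------------------------------------------------------------

def _draw_gene_structures(cfg: SimulationConfig, rng: np.random.Generator):
    """(exon_lengths, intron_lengths) per gene; total span derived."""
    structures = []
    for _ in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        ex = rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1, n_ex)
        intr = rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, n_ex - 1)
        structures.append((ex, intr))
    return structures


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedStudy:
    """Random genome, gene placement, deamination, and true site states.

    Genes (2-6 exons) are placed without overlap, round-robin across
    contigs with randomly sized intergenic gaps.  Raises when the genes
    cannot fit, advising a larger ``contig_length``.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    contigs = {
        f"contig{i + 1}": rng.choice(_BASES, size=cfg.contig_length, p=probs).copy()
        for i in range(cfg.n_contigs)
    }

    structures = _draw_gene_structures(cfg, rng)
    spans = [int(ex.sum() + intr.sum()) for ex, intr in structures]
    per_contig: dict[str, list[int]] = {c: [] for c in contigs}
    names = list(contigs)
    for gi in range(cfg.n_genes):
        per_contig[names[gi % len(names)]].append(gi)

    genes: list[GeneModel] = []
    is_meth_class = rng.random(cfg.n_genes) < cfg.frac_methylated_genes
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    for chrom in names:
        idxs = per_contig[chrom]
        total = sum(spans[i] for i in idxs)
        n_gaps = len(idxs) + 1
        slack = cfg.contig_length - total - n_gaps * cfg.min_intergenic
        if slack < 0:
            raise ValueError(
                f"genes do not fit on {chrom} "
                f"(need {total + n_gaps * cfg.min_intergenic} bp, have "
                f"{cfg.contig_length}); increase contig_length"
            )
        extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
        cursor = 1
        for k, gi in enumerate(idxs):
            cursor += cfg.min_intergenic + int(extra[k])
            ex, intr = structures[gi]
            start = cursor
            exons = []
            p = start
            for j, el in enumerate(ex):
                exons.append((p, p + int(el) - 1))
                p += int(el)
                if j < len(intr):
                    p += int(intr[j])
            end = p - 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:05d}", chrom=chrom,
                    strand=str(strands[gi]), start=start, end=end,
                    exons=tuple(exons),
                )
            )
            cursor = end + 1
    genes.sort(key=lambda g: (g.chrom, g.start))

    # sequence-level deamination: CG -> TG or CA inside methylated genes
    gene_class = {f"gene{gi + 1:05d}": bool(is_meth_class[gi]) for gi in range(cfg.n_genes)}
    if cfg.deamination_strength > 0:
        for g in genes:
            if not gene_class[g.gene_id]:
                continue
            arr = contigs[g.chrom]
            lo, hi = g.start - 1, g.end  # 0-based [lo, hi)
            seg = arr[lo:hi]
            cg = np.flatnonzero((seg[:-1] == ord("C")) & (seg[1:] == ord("G")))
            if cg.size == 0:
                continue
            hit = cg[rng.random(cg.size) < cfg.deamination_strength]
            to_tg = rng.random(hit.size) < 0.5
            seg[hit[to_tg]] = ord("T")          # CG -> TG
            seg[hit[~to_tg] + 1] = ord("A")     # CG -> CA

    sequences = {c: arr.tobytes().decode("ascii") for c, arr in contigs.items()}

    # per-gene methylation propensity pi: fraction of CpGs truly methylated
    a_low, b_low = cfg.beta_params_low
    a_high, b_high = cfg.beta_params_high
    gene_pi = {
        gid: float(rng.beta(a_high, b_high) if meth else rng.beta(a_low, b_low))
        for gid, meth in gene_class.items()
    }
    sites = _true_site_states(cfg, rng, sequences, genes, gene_pi)
    gene_df = pd.DataFrame(
        {
            "gene_id": [f"gene{gi + 1:05d}" for gi in range(cfg.n_genes)],
            "true_class": np.where(is_meth_class, "methylated", "nonmethylated"),
            "true_pi": [gene_pi[f"gene{gi + 1:05d}"] for gi in range(cfg.n_genes)],
        }
    )
    return SimulatedStudy(
        config=cfg, sequences=sequences, genes=genes,
        truth=TrueState(genes=gene_df, sites=sites),
    )


def _true_site_states(cfg, rng, sequences, genes, gene_pi) -> pd.DataFrame:
    """Per-CpG-cytosine true methylation fraction (strand cytosines kept
    separate but the two cytosines of one CG share the same fraction,
    mirroring symmetric maintenance methylation)."""
    from .io_formats import enumerate_genome_cpgs

    cpgs = enumerate_genome_cpgs(sequences)
    if cpgs.empty:
        cpgs["true_m"] = []
        cpgs["gene_id"] = []
        cpgs["feature"] = []
        return cpgs

    # feature lookup per position (exon precedence), first gene wins
    gene_id = np.full(len(cpgs), "", dtype=object)
    feature = np.full(len(cpgs), "intergenic", dtype=object)
    pos = cpgs["pos"].to_numpy()
    chrom = cpgs["chrom"].to_numpy()
    for g in genes:
        mask = (chrom == g.chrom) & (pos >= g.start) & (pos <= g.end)
        if not mask.any():
            continue
        in_exon = np.zeros(mask.sum(), dtype=bool)
        sub = pos[mask]
        for s, e in g.exons:
            in_exon |= (sub >= s) & (sub <= e)
        idx = np.flatnonzero(mask)
        take = feature[idx] == "intergenic"  # do not overwrite an earlier gene
        gene_id[idx[take]] = g.gene_id
        feature[idx[take]] = np.where(in_exon[take], "exon", "intron")

    # binary site states drawn once per CG dinucleotide (+ strand row),
    # shared with the - strand partner (symmetric maintenance methylation)
    plus = cpgs["strand"].to_numpy() == "+"
    n_plus = int(plus.sum())
    feat_plus = feature[plus]
    gid_plus = gene_id[plus]
    p_meth = np.full(n_plus, cfg.background_methylation)
    genic = feat_plus != "intergenic"
    pi_site = np.array([gene_pi.get(g, 0.0) for g in gid_plus])
    p_meth[genic & (feat_plus == "exon")] = pi_site[genic & (feat_plus == "exon")]
    intr = genic & (feat_plus == "intron")
    p_meth[intr] = pi_site[intr] * cfg.intron_attenuation
    is_meth_site = rng.random(n_plus) < p_meth
    levels = rng.beta(*cfg.site_level_params, n_plus)
    m_plus = np.where(is_meth_site, levels, 0.0)

    true_m = np.zeros(len(cpgs))
    true_m[plus] = m_plus
    # the - strand cytosine of each CG inherits the + strand fraction;
    # enumerate emits the two cytosines of a CG adjacently (+ then -)
    minus_idx = np.flatnonzero(~plus)
    true_m[minus_idx] = true_m[minus_idx - 1]

    out = cpgs.copy()
    out["true_m"] = true_m
    out["gene_id"] = gene_id
    out["feature"] = feature
    return out


# ---------------------------------------------------------------------------
# bisulfite count table
# ---------------------------------------------------------------------------

def _nb_coverage(cfg, rng, n) -> np.ndarray:
    """Negative-binomial read depth around mean_coverage."""
    r = cfg.coverage_dispersion
    p = r / (r + cfg.mean_coverage)
    return rng.negative_binomial(r, p, n)


def _trinucleotide(seq: str, pos: int, strand: str) -> str:
    """Trinucleotide context of the cytosine at 1-based pos."""
    i = pos - 1
    if strand == "+":
        return seq[i : i + 3].ljust(3, "N")
    rev = seq[max(0, i - 2) : i + 1].translate(_COMP)[::-1]
    return rev.ljust(3, "N")


def _non_cpg_cytosines(seq: str, chrom: str) -> pd.DataFrame:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    cpg_c = np.zeros_like(is_c)
    cpg_c[:-1] = is_c[:-1] & is_g[1:]
    cpg_g = np.zeros_like(is_g)
    cpg_g[1:] = is_g[1:] & is_c[:-1]
    plus = np.flatnonzero(is_c & ~cpg_c)
    minus = np.flatnonzero(is_g & ~cpg_g)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.concatenate([plus + 1, minus + 1]),
            "strand": np.concatenate([np.full(plus.size, "+"), np.full(minus.size, "-")]),
        }
    )


def simulate_counts(
    study: SimulatedStudy, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Cytosine-report table sampled from the true site states.

    CpG rows follow the observation model
    ``n_meth ~ Binomial(cov, m*(1-over) + (1-m)*error)``; a subsample of
    non-CpG cytosines (truly unmethylated, so apparent methylation is
    pure non-conversion error) is included for error-rate estimation.
    Zero-coverage rows are kept, mirroring real cytosine reports.
    """
    cfg = study.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    sites = study.truth.sites
    n = len(sites)
    cov = _nb_coverage(cfg, rng, n)
    m = sites["true_m"].to_numpy()
    p_obs = np.clip(m * (1.0 - cfg.over_conversion_rate) + (1.0 - m) * cfg.error_rate, 0.0, 1.0)
    n_meth = rng.binomial(cov, p_obs)
    cpg = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "strand": sites["strand"].to_numpy(),
            "n_meth": n_meth,
            "n_unmeth": cov - n_meth,
            "context": "CpG",
        }
    )
    frames = [cpg]
    if cfg.non_cpg_fraction > 0:
        for chrom, seq in study.sequences.items():
            nc = _non_cpg_cytosines(seq, chrom)
            keep = rng.random(len(nc)) < cfg.non_cpg_fraction
            nc = nc.loc[keep].reset_index(drop=True)
            cov_nc = _nb_coverage(cfg, rng, len(nc))
            nm = rng.binomial(cov_nc, cfg.error_rate)
            nc["n_meth"] = nm
            nc["n_unmeth"] = cov_nc - nm
            # CHG when the base two to the 3' side is G on the read strand
            ctx = []
            for pos, strand in zip(nc["pos"], nc["strand"]):
                tri = _trinucleotide(seq, int(pos), strand)
                ctx.append("CHG" if len(tri) == 3 and tri[2] == "G" else "CHH")
            nc["context"] = ctx
            frames.append(nc)
    out = pd.concat(frames, ignore_index=True)
    tris = []
    for chrom, pos, strand in zip(out["chrom"], out["pos"], out["strand"]):
        tris.append(_trinucleotide(study.sequences[chrom], int(pos), strand))
    out["trinucleotide"] = tris
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    study.counts = out
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    study: SimulatedStudy, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """TMM-FPKM-style expression coupled to methylation class.

    log10 FPKM = baseline + coupling * 1[methylated] + Normal(0, sd);
    a class-dependent fraction of genes is silenced to FPKM = 0
    (enriched among nonmethylated genes).
    """
    cfg = study.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    gt = study.truth.genes
    is_meth = (gt["true_class"] == "methylated").to_numpy()
    log_expr = (
        cfg.expression_baseline
        + cfg.expression_coupling * is_meth
        + rng.normal(0.0, cfg.expression_sd, len(gt))
    )
    fpkm = 10.0 ** log_expr
    silent_p = np.where(
        is_meth, cfg.silent_fraction_methylated, cfg.silent_fraction_nonmethylated
    )
    fpkm[rng.random(len(gt)) < silent_p] = 0.0
    out = pd.DataFrame({"gene_id": gt["gene_id"], "fpkm": fpkm})
    study.truth.genes = gt.assign(true_fpkm=fpkm)
    study.expression = out
    return out


# ---------------------------------------------------------------------------
# targeted amplicon panels
# ---------------------------------------------------------------------------

def simulate_amplicon_panel(
    site_table: pd.DataFrame,
    n_per_group: int = 8,
    coverage: float = 500.0,
    coverage_dispersion: float = 8.0,
    error_rate: float = 0.01,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    group_names: Sequence[str] = ("long", "short"),
) -> tuple[dict[str, pd.DataFrame], pd.Series, pd.DataFrame]:
    """Two-phenotype amplicon panel with planted per-site differences.

    ``site_table`` needs columns gene_id, scaffold, pos, mean_short and
    diff; group means are mean_short and mean_short + diff and must lie
    in [0, 1].  Per sample and site, coverage is negative binomial and
    methylated counts Binomial(coverage, m + (1-m)*error_rate).

    Returns (sample tables keyed by sample id, phenotype labels, truth).
    """
    req = {"gene_id", "scaffold", "pos", "mean_short", "diff"}
    if not req <= set(site_table.columns):
        raise ValueError(f"site_table needs columns {sorted(req)}")
    mean_short = site_table["mean_short"].to_numpy(dtype=float)
    mean_long = mean_short + site_table["diff"].to_numpy(dtype=float)
    for name, m in (("short", mean_short), ("long", mean_long)):
        if np.any(m < 0.0) or np.any(m > 1.0):
            raise ValueError(f"planted {name}-group means fall outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    r = coverage_dispersion
    p_nb = r / (r + coverage)
    samples: dict[str, pd.DataFrame] = {}
    labels = {}
    n_sites = len(site_table)
    for group, means in ((group_names[0], mean_long), (group_names[1], mean_short)):
        p_obs = np.clip(means + (1.0 - means) * error_rate, 0.0, 1.0)
        for k in range(n_per_group):
            sid = f"{group}_{k + 1}"
            cov = rng.negative_binomial(r, p_nb, n_sites)
            nm = rng.binomial(cov, p_obs)
            samples[sid] = pd.DataFrame(
                {
                    "gene_id": site_table["gene_id"],
                    "scaffold": site_table["scaffold"],
                    "pos": site_table["pos"],
                    "n_meth": nm,
                    "n_total": cov,
                }
            )
            labels[sid] = group
    truth = site_table.assign(mean_long=mean_long)
    return samples, pd.Series(labels, name="phenotype"), truth


# ---------------------------------------------------------------------------
# orchestration / writers
# ---------------------------------------------------------------------------

def simulate_study(
    config: SimulationConfig | None = None, outdir: str | Path | None = None
) -> SimulatedStudy:
    """Full synthetic study: genome, counts, expression (and files).

    Child RNG streams are derived from ``config.seed`` so each stage is
    independently reproducible.  When ``outdir`` is given, writes
    genome.fa, annotation.gff3, cytosine_report.tsv, expression.tsv and
    truth tables.
    """
    cfg = config or SimulationConfig()
    study = simulate_genome(cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 0])))
    simulate_counts(study)
    simulate_expression(study)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(study.sequences, outdir / "genome.fa")
        write_gff(study.genes, outdir / "annotation.gff3", study.contig_lengths)
        write_cytosine_report(study.counts, outdir / "cytosine_report.tsv")
        study.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        study.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        study.truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    return study
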