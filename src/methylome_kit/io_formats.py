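"""Readers and writers for the external file formats.

All genomic coordinates are held 1-based inclusive internally — the
convention shared by the Bismark-style cytosine report and GFF3 — and
converted to 0-based half-open only at the BED boundary.  FASTA access
goes through ``pyfaidx`` and GFF3 parsing through ``gffutils``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

CYTOSINE_REPORT_COLUMNS = (
    "chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide",
)
CONTEXTS = ("CpG", "CHG", "CHH")

__all__ = [
    "CytosineRecord",
    "GeneModel",
    "read_cytosine_report",
    "load_cytosine_report",
    "write_cytosine_report",
    "read_gff",
    "write_gff",
    "load_genome",
    "write_fasta",
    "enumerate_genome_cpgs",
    "write_site_bed",
    "read_site_bed",
]


@dataclass(frozen=True)
class CytosineRecord:
    """Strand-aware read counts at one cytosine.

    ``pos`` is the 1-based genomic position of the cytosine itself (for a
    CpG this is the C on the + strand and the G position on the − strand).
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str
    trinucleotide: str = ""

    @property
    def n_total(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        """Fractional methylation: methylated reads over total reads."""
        return self.n_meth / self.n_total if self.n_total else float("nan")


@dataclass(frozen=True)
class GeneModel:
    """A gene with exons, on 1-based inclusive coordinates.

    Exons are stored sorted and non-overlapping (overlaps are merged at
    construction time); introns are the within-gene gaps between them.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: bad span {self.start}-{self.end}")
        merged = _merge_intervals(self.exons, self.gene_id)
        for s, e in merged:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside span "
                    f"{self.start}-{self.end}"
                )
        object.__setattr__(self, "exons", merged)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Within-gene gaps between sorted exons (may be empty)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def upstream_interval(
        self, window: int = 2000, contig_length: int | None = None
    ) -> tuple[int, int] | None:
        """Strand-aware window 5' of the gene start (TSS proxy), clipped.

        For + strand genes the window ends at ``start - 1`` and is clipped
        at position 1; for − strand genes it begins at ``end + 1`` and is
        clipped at ``contig_length`` when known.  Returns None when the
        clipped window is empty.
        """
        if self.strand == "+":
            lo = max(1, self.start - window)
            hi = self.start - 1
        else:
            lo = self.end + 1
            hi = self.end + window
            if contig_length is not None:
                hi = min(hi, contig_length)
        if hi < lo:
            return None
        return (lo, hi)


def _merge_intervals(intervals, gene_id: str) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    warned = False
    for s, e in ivs:
        if e < s:
            raise ValueError(f"gene {gene_id}: exon end {e} < start {s}")
        if merged and s <= merged[-1][1] + 0:
            if not warned:
                warnings.warn(f"gene {gene_id}: overlapping exons merged")
                warned = True
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


# ---------------------------------------------------------------------------
# Cytosine report (Bismark dialect): 7 TSV columns, 1-based positions
# ---------------------------------------------------------------------------

def read_cytosine_report(
    path: str | Path, context: str | None = None
) -> Iterator[CytosineRecord]:
    """Stream a cytosine report, optionally keeping a single context.

    The file is TSV with columns chrom, pos (1-based), strand,
    count-methylated, count-unmethylated, context, trinucleotide.
    Malformed lines raise with the offending line number.
    """
    if context is not None and context not in CONTEXTS:
        raise ValueError(f"unknown context filter {context!r}; expected one of {CONTEXTS}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected 7 tab-separated fields, "
                    f"got {len(parts)}"
                )
            chrom, pos_s, strand, nm_s, nu_s, ctx, tri = parts
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(nm_s), int(nu_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if pos < 1:
                raise ValueError(f"{path}: line {lineno}: position {pos} < 1")
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            if strand not in "+-":
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            if context is not None and ctx != context:
                continue
            yield CytosineRecord(chrom, pos, strand, n_meth, n_unmeth, ctx, tri)


def load_cytosine_report(path: str | Path, context: str | None = None) -> pd.DataFrame:
    """Cytosine report as a DataFrame (columns as in the file)."""
    recs = read_cytosine_report(path, context=context)
    df = pd.DataFrame(recs, columns=CYTOSINE_REPORT_COLUMNS)
    return df


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(CYTOSINE_REPORT_COLUMNS)].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse gene/exon features from a GFF3 file into GeneModels.

    Exons are attached to genes via Parent (directly, or through an
    intermediate transcript feature).  Exons without a resolvable gene
    parent are skipped with a warning; overlapping exons are merged.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, dict] = {}
    for g in db.features_of_type("gene"):
        genes[g.id] = {
            "chrom": g.seqid, "strand": g.strand if g.strand in "+-" else "+",
            "start": g.start, "end": g.end, "exons": [],
        }
    # map transcript-level features onto their gene parent
    parent_of: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype in ("gene", "exon"):
            continue
        for par in feat.attributes.get("Parent", []):
            if par in genes:
                parent_of[feat.id] = par
    for ex in db.features_of_type("exon"):
        parents = ex.attributes.get("Parent", [])
        resolved = None
        for par in parents:
            if par in genes:
                resolved = par
                break
            if par in parent_of:
                resolved = parent_of[par]
                break
        if resolved is None:
            warnings.warn(f"exon at {ex.seqid}:{ex.start}-{ex.end} has no gene parent; skipped")
            continue
        genes[resolved]["exons"].append((ex.start, ex.end))
    out = []
    for gid, info in genes.items():
        out.append(
            GeneModel(
                gene_id=gid, chrom=info["chrom"], strand=info["strand"],
                start=info["start"], end=info["end"], exons=tuple(info["exons"]),
            )
        )
    return out


def write_gff(
    genes: Iterable[GeneModel],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write GeneModels as GFF3 gene+exon features (with sequence-region pragmas)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmethylome_kit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tmethylome_kit\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA and genome-wide CpG enumeration
# ---------------------------------------------------------------------------

def load_genome(fasta: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Genome as a plain dict chrom -> uppercase sequence string."""
    if isinstance(fasta, Mapping):
        return {str(k): str(v).upper() for k, v in fasta.items()}
    fa = Fasta(str(fasta))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def enumerate_genome_cpgs(fasta: str | Path | Mapping[str, str]) -> pd.DataFrame:
    """All CpG cytosines in a genome, one row per strand cytosine.

    Each CG dinucleotide contributes the + strand cytosine at the C
    position and the − strand cytosine at the G position (1-based).
    Positions involving N never match CG and are therefore excluded.
    """
    genome = load_genome(fasta)
    frames = []
    for chrom in genome:
        arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        if arr.size < 2:
            continue
        hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if hits.size == 0:
            continue
        pos = np.empty(2 * hits.size, dtype=np.int64)
        pos[0::2] = hits + 1       # C on + strand
        pos[1::2] = hits + 2       # G position = C on - strand
        strand = np.empty(2 * hits.size, dtype="U1")
        strand[0::2] = "+"
        strand[1::2] = "-"
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# BED6 output for site calls
# ---------------------------------------------------------------------------

def write_site_bed(calls: pd.DataFrame, path: str | Path) -> None:
    """Site calls as BED6: chrom, start(0-based), end, name, score, strand.

    The name is chrom:pos of the 1-based cytosine; the score is the
    methylation level scaled to 0-1000 (UCSC convention).
    """
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            score = int(round(1000 * float(row.level)))
            fh.write(
                f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{row.chrom}:{row.pos}\t"
                f"{score}\t{row.strand}\n"
            )


def read_site_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 written by :func:`write_site_bed` back to 1-based sites."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED columns")
            chrom, start, end, _name, score, strand = parts
            rows.append((chrom, int(start) + 1, strand, int(score) / 1000.0))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "level"])
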