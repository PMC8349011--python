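"""Readers/writers for the genomic formats the pipeline consumes.

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive conventions of GTF and MUMmer show-coords tables happens
only at the I/O boundary.  Reads are carried either as lists of
:class:`AlignedRead` (the typed currency for small inputs) or as pandas
DataFrames with BED6 columns (the fast currency for simulations); every
operation accepts both.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("xrcompare")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open interval, the universal coordinate unit."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp overlap, strand-blind (bedtools intersect default)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignedRead:
    """One aligned sequencing read (XR-seq, RNA-seq or simulated)."""

    interval: GenomicInterval
    name: str = "."
    score: str = "0"
    sample_id: str = ""

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene body with strand-aware TSS/TES.

    TSS/TES are single coordinates on the half-open scale: for a ``+`` gene
    TSS = start and TES = end; for a ``-`` gene TSS = end and TES = start,
    so TSS > TES on the minus strand.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class AlignmentSegment:
    """One whole-genome-alignment segment (ref <-> query) with % identity."""

    ref: GenomicInterval
    query: GenomicInterval
    identity: float
    query_strand: str = "+"

    def __post_init__(self):
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.query_strand not in ("+", "-"):
            raise ValueError(f"invalid query strand {self.query_strand!r}")


# ---------------------------------------------------------------------------
# Read containers: list <-> DataFrame coercion
# ---------------------------------------------------------------------------

def reads_to_frame(reads: Iterable[AlignedRead]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.start, r.end, r.name, r.score, r.strand) for r in reads
    ]
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def frame_to_reads(frame: pd.DataFrame, sample_id: str = "") -> list[AlignedRead]:
    names = frame["name"] if "name" in frame else ["."] * len(frame)
    scores = frame["score"] if "score" in frame else ["0"] * len(frame)
    return [
        AlignedRead(
            GenomicInterval(c, int(s), int(e), st),
            name=str(n),
            score=str(sc),
            sample_id=sample_id,
        )
        for c, s, e, st, n, sc in zip(
            frame["chrom"], frame["start"], frame["end"], frame["strand"],
            names, scores,
        )
    ]


def as_read_frame(reads) -> pd.DataFrame:
    """Coerce a list of AlignedRead or a BED6-like DataFrame to a DataFrame."""
    if isinstance(reads, pd.DataFrame):
        missing = [c for c in ("chrom", "start", "end", "strand") if c not in reads]
        if missing:
            raise ValueError(f"read frame missing columns {missing}")
        return reads
    return reads_to_frame(reads)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[AlignedRead]:
    """Read a BED6 file into AlignedRead records, preserving order and
    duplicates (deduplication is a separate, explicit step)."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            reads.append(AlignedRead(iv, name=name, score=score))
    return reads


def read_bed_frame(path) -> pd.DataFrame:
    return reads_to_frame(read_bed(path))


def write_bed(reads, path) -> None:
    frame = as_read_frame(reads)
    cols = [frame[c] if c in frame else pd.Series(["."] * len(frame))
            for c in BED_COLUMNS]
    out = pd.DataFrame(dict(zip(BED_COLUMNS, cols)))
    out.to_csv(path, sep="\t", header=False, index=False)


def dedup_sort_reads(reads, strand_aware: bool = False):
    """Sort reads by (chrom, start, end) and collapse exact coordinate
    duplicates, mirroring ``sort -u -k1,1 -k2,2n -k3,3n`` on a BED file.

    The command-line keys ignore strand, so by default two reads at the same
    coordinates on opposite strands collapse to one; ``strand_aware=True``
    adds strand to the key.  Returns the same container type it was given.
    """
    frame = as_read_frame(reads)
    key = ["chrom", "start", "end"] + (["strand"] if strand_aware else [])
    out = (
        frame.sort_values(["chrom", "start", "end", "strand"], kind="stable")
        .drop_duplicates(subset=key, keep="first")
        .reset_index(drop=True)
    )
    if isinstance(reads, pd.DataFrame):
        return out
    return frame_to_reads(out)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_genes(path, protein_coding_only: bool = True) -> list[GeneModel]:
    """Parse gene records from a GTF file into 0-based half-open GeneModels.

    GTF coordinates are 1-based inclusive; ``start`` is shifted down by one.
    Only ``gene`` feature lines are consumed; when a gene_biotype/gene_type
    attribute is present and ``protein_coding_only`` is set, non-coding
    genes are skipped.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "gene":
                continue
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: unknown strand {strand!r}"
                )
            attr = dict(_ATTR_RE.findall(attrs))
            biotype = attr.get("gene_biotype", attr.get("gene_type"))
            if protein_coding_only and biotype is not None and biotype != "protein_coding":
                continue
            gene_id = attr.get("gene_id", f"gene_line{lineno}")
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, int(start) - 1, int(end), strand))
            )
    return genes


def write_gtf_genes(genes: Sequence[GeneModel], path, source: str = "xrcompare") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "protein_coding";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# show-coords alignment tables
# ---------------------------------------------------------------------------

def read_coords_table(path) -> list[AlignmentSegment]:
    """Read a MUMmer show-coords-style table of alignment segments.

    Two layouts are accepted, auto-detected by token count per line:

    * 7 tokens: ``ref_chrom ref_start ref_end query_chrom query_start
      query_end identity`` (the canonical table this package writes);
    * 9 tokens: ``S1 E1 S2 E2 LEN1 LEN2 %IDY ref_chrom query_chrom``
      (show-coords ``-H -T`` style with name columns last).

    Coordinates are 1-based inclusive; a query start greater than its end
    encodes a reverse-strand alignment.
    """
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = [t for t in line.replace("|", " ").split() if t]
            if not tokens or tokens[0].startswith("#"):
                continue
            try:
                if len(tokens) == 7:
                    rc, rs, re_, qc, qs, qe, idy = tokens
                elif len(tokens) == 9:
                    rs, re_, qs, qe, _l1, _l2, idy, rc, qc = tokens
                else:
                    raise ValueError(f"unrecognized layout ({len(tokens)} fields)")
                rs, re_, qs, qe = int(rs), int(re_), int(qs), int(qe)
                idy = float(idy)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            strand = "+" if qs <= qe else "-"
            q_lo, q_hi = min(qs, qe), max(qs, qe)
            try:
                segments.append(
                    AlignmentSegment(
                        ref=GenomicInterval(rc, rs - 1, re_),
                        query=GenomicInterval(qc, q_lo - 1, q_hi),
                        identity=idy,
                        query_strand=strand,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return segments


def write_coords_table(segments: Sequence[AlignmentSegment], path) -> None:
    """Write segments in the canonical 7-column 1-based layout (reverse
    orientation encoded by swapping query start/end)."""
    with open(path, "w") as fh:
        for s in segments:
            qs, qe = s.query.start + 1, s.query.end
            if s.query_strand == "-":
                qs, qe = qe, s.query.start + 1
            fh.write(
                f"{s.ref.chrom}\t{s.ref.start + 1}\t{s.ref.end}\t"
                f"{s.query.chrom}\t{qs}\t{qe}\t{s.identity:.2f}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ / sequence fetch
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict, path, width: int = 60) -> None:
    """Write chrom -> sequence mapping as FASTA (sequences may be str or
    uint8 ASCII arrays)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            if isinstance(seq, np.ndarray):
                seq = seq.tobytes().decode("ascii")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def load_genome(path):
    """Open an on-disk FASTA through pyfaidx."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def genome_sizes(genome) -> dict[str, int]:
    if isinstance(genome, dict):
        return {k: len(v) for k, v in genome.items()}
    return {name: len(genome[name]) for name in genome.keys()}


def fetch_sequences(genome, intervals: Sequence[GenomicInterval]) -> list[str]:
    """Fetch interval sequences, reverse-complemented on the minus strand
    (bedtools getfasta -s semantics).  ``genome`` may be a pyfaidx.Fasta,
    a dict of strings, or a dict of uint8 ASCII arrays."""
    out = []
    for iv in intervals:
        chunk = genome[iv.chrom][iv.start:iv.end]
        if isinstance(chunk, np.ndarray):
            chunk = chunk.tobytes().decode("ascii")
        chunk = str(chunk).upper()
        out.append(reverse_complement(chunk) if iv.strand == "-" else chunk)
    return out


def read_fastq(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTQ file, via Biopython."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def trim_adapter(
    sequences: Sequence[str],
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> list[str]:
    """Remove a 3' adapter from each read.

    Only the adapter prefix before the first run of ``N`` (the sample-index
    placeholder in the printed adapter) is matched.  The leftmost position
    whose overlap with the adapter prefix (full internal match, or a suffix
    overlap at the read end of >= ``min_overlap`` bases) has at most
    ``max_error_rate`` mismatches is trimmed; reads with no match pass
    through unchanged.
    """
    prefix = adapter.split("N")[0].upper()
    if not prefix:
        raise ValueError("adapter has no non-N prefix")
    out = []
    for seq in sequences:
        s = seq.upper()
        cut = len(s)
        for i in range(len(s)):
            ov = min(len(prefix), len(s) - i)
            if ov < min_overlap:
                break
            mism = sum(1 for a, b in zip(s[i:i + ov], prefix[:ov]) if a != b)
            if mism <= int(max_error_rate * ov):
                cut = i
                break
        out.append(seq[:cut])
    return out


# ---------------------------------------------------------------------------
# Config / logging
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Read a key-value config file (YAML dialect)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
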