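"""Domain types and file I/O for the lncRNA analysis pipeline.

Coordinate convention: all intervals are stored 0-based half-open
internally; GTF input/output converts to and from the 1-based inclusive
convention at the file boundary, and nowhere else.

Sequences are stored on the sense strand as provided by the (stranded)
assembly; reverse complementing is always an explicit operation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

__all__ = [
    "TranscriptRecord",
    "CountMatrix",
    "ExpressionMatrix",
    "GeneLocus",
    "GeneSet",
    "QpcrMeasure",
    "GtfParseError",
    "ValidationError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_qpcr",
    "write_results",
    "reverse_complement",
]

PIGMENTED = "pigmented"
UNPIGMENTED = "unpigmented"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed; message names the line."""


class ValidationError(ValueError):
    """Raised when a record violates a structural invariant."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_seq(seq: str) -> str:
    """Uppercase and map U->T; validate the alphabet."""
    s = seq.upper().replace("U", "T")
    if s.strip("ACGTN"):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValidationError(f"sequence contains non-ACGTN symbols: {bad}")
    return s


@dataclass
class TranscriptRecord:
    """One assembled transcript model.

    ``exons`` are 0-based half-open intervals on ``chrom``, sorted and
    non-overlapping.  ``class_code`` uses the cuffcompare vocabulary
    ('=' exact reference match, 'u' intergenic, 'i' intronic, 'x'
    antisense-exonic, ...).  ``source`` distinguishes annotated coding
    transcripts, known lncRNAs and unannotated candidates.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    class_code: str = "u"
    sequence: str | None = None
    source: str = "candidate"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"{self.transcript_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons unsorted or overlapping at [{s},{e})"
                )
            prev_end = e
        if self.sequence is not None:
            self.sequence = _normalize_seq(self.sequence)
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"{self.transcript_id}: sequence length {len(self.sequence)} "
                    f"!= exon span total {self.length}"
                )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class CountMatrix:
    """Features x samples integer read counts with a two-group design."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: object = None  # array-like; coerced to int ndarray in __post_init__
    group: dict[str, str] = field(default_factory=dict)
    library_sizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import numpy as np

        if self.counts is None:
            raise ValidationError("counts matrix required")
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValidationError("counts must be integers")
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = arr
        for s in self.sample_ids:
            if s not in self.group:
                raise ValidationError(f"sample {s} missing from design")
        if not self.library_sizes:
            totals = arr.sum(axis=0)
            self.library_sizes = {
                s: float(t) for s, t in zip(self.sample_ids, totals)
            }
        for s in self.sample_ids:
            if self.library_sizes.get(s, 0) <= 0:
                raise ValidationError(f"library size for sample {s} must be > 0")

    @property
    def array(self):
        return self.counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def subset(self, feature_ids: list[str]) -> "CountMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return CountMatrix(
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts[rows, :],
            group=dict(self.group),
            library_sizes=dict(self.library_sizes),
        )


@dataclass
class ExpressionMatrix:
    """Features x samples FPKM values (reads per kb per million mapped)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: object = None

    def __post_init__(self) -> None:
        import numpy as np

        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError("expression shape does not match id lists")
        if (arr < 0).any():
            raise ValidationError("FPKM values must be >= 0")
        self.values = arr

    def row(self, feature_id: str):
        return self.values[self.feature_ids.index(feature_id), :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class GeneLocus:
    """Genomic span of one gene; spans cover all member transcripts."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    biotype: str = "coding"  # coding | lncRNA

    def __post_init__(self) -> None:
        s, e = self.span
        if e <= s:
            raise ValidationError(f"{self.gene_id}: empty span")


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: set

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id} has no members")


@dataclass
class QpcrMeasure:
    """One qPCR well: target and housekeeping Ct for one sample/gene."""

    sample_id: str
    group: str
    gene_id: str
    ct_target: float
    ct_housekeeping: float

    def __post_init__(self) -> None:
        import math

        for v in (self.ct_target, self.ct_housekeeping):
            if not math.isfinite(v) or v <= 0:
                raise ValidationError("Ct values must be finite and > 0")


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str) -> list[TranscriptRecord]:
    """Read transcript models from a GTF file.

    Exon rows are grouped per transcript_id; 1-based inclusive coordinates
    become 0-based half-open.  A missing ``class_code`` attribute defaults
    to 'u' (intergenic/unknown).
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"line {lineno}: cannot parse GTF line ({exc})")
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(f"line {lineno}: missing attribute {exc}")
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                cc = feat.attributes.get("class_code", ["u"])[0]
                src = feat.attributes.get("source_label", ["candidate"])[0]
                meta[tid] = {
                    "gene_id": gid,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "class_code": cc,
                    "source": src,
                }
            elif meta[tid]["chrom"] != feat.seqid:
                raise ValidationError(
                    f"line {lineno}: transcript {tid} has exons on multiple "
                    f"chromosomes ({meta[tid]['chrom']}, {feat.seqid})"
                )
            # GTF is 1-based inclusive
            exons[tid].append((feat.start - 1, feat.end))
    records = []
    for tid in order:
        m = meta[tid]
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"] if m["strand"] in "+-" else "+",
                exons=sorted(exons[tid]),
                class_code=m["class_code"],
                source=m["source"],
            )
        )
    return records


def write_gtf(records: list[TranscriptRecord], path: str) -> None:
    """Write exon rows (one block per transcript), converting back to
    1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for rec in records:
            for s, e in rec.exons:
                attrs = (
                    f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}"; '
                    f'class_code "{rec.class_code}"; source_label "{rec.source}";'
                )
                fh.write(
                    f"{rec.chrom}\tlncpig\texon\t{s + 1}\t{e}\t.\t{rec.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map.

    Sequences are uppercased with U mapped to T.  Duplicate ids are an
    error (they would silently shadow each other downstream).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA id: {rec.id}")
        seqs[rec.id] = _normalize_seq(str(rec.seq))
    return seqs


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Counts / design


def read_counts(path: str, design: dict[str, str]) -> CountMatrix:
    """Read a TSV count table (first column feature id) with a design map
    sample -> group.  Non-integer or negative entries are errors."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")
    return CountMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        counts=df.to_numpy(),
        group={s: design[s] for s in df.columns},
    )


def write_counts(cm: CountMatrix, path: str) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"line {lineno}: GMT line needs set id, description and >=1 member"
                )
            sets.append(GeneSet(set_id=parts[0], name=parts[1], members=set(parts[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.set_id}\t{gs.name}\t{members}\n")


# ---------------------------------------------------------------------------
# qPCR table


def read_qpcr(path: str) -> list[QpcrMeasure]:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "group", "gene_id", "ct_target", "ct_housekeeping"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"qPCR table must have columns {sorted(needed)}")
    return [
        QpcrMeasure(
            sample_id=str(r.sample_id),
            group=str(r.group),
            gene_id=str(r.gene_id),
            ct_target=float(r.ct_target),
            ct_housekeeping=float(r.ct_housekeeping),
        )
        for r in df.itertuples()
    ]


def write_results(table: pd.DataFrame, path: str) -> None:
    """Write a result table as TSV with stable float formatting so that
    repeated runs are byte-identical."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def transcript_sequences_from_genome(
    records: list[TranscriptRecord], genome: dict[str, str]
) -> None:
    """Fill ``sequence`` on each record by splicing exon sequences from a
    chromosome map, reverse complementing minus-strand transcripts."""
    for rec in records:
        parts = [genome[rec.chrom][s:e] for s, e in rec.exons]
        seq = "".join(parts)
        if rec.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        rec.sequence = _normalize_seq(seq)
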