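"""Core genomic data types and format I/O.

All coordinates are 0-based half-open (BED convention) throughout the
package.  CAGE tag clusters are mandatorily stranded; enhancer regions and
TADs are unstranded.  Readers preserve input order and raise
:class:`ParseError` with the offending line number on malformed input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed record in a genomic text format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def intersection_length(self, other: "GenomicInterval") -> int:
        """Length of the overlap in bp (0 if disjoint or on other chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # chrA:start-end, BED-style
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff the intervals share at least ``min_bp`` bases (strand ignored)."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return a.intersection_length(b) >= min_bp


def contained_within(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` lies entirely inside ``b`` (same chromosome)."""
    return a.chrom == b.chrom and b.start <= a.start and a.end <= b.end


def interval_point_distance(iv: GenomicInterval, pos: int, chrom: str) -> int:
    """Genomic distance between an interval and a single base.

    0 when the base falls inside the interval; otherwise the number of bases
    separating them, counting adjacency as 1 (bedtools ``closest -d``
    convention).  Infinite when on different chromosomes.
    """
    if iv.chrom != chrom:
        return np.iinfo(np.int64).max
    if iv.start <= pos < iv.end:
        return 0
    if pos < iv.start:
        return iv.start - pos
    return pos - (iv.end - 1)


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Genomic distance between two intervals (0 overlap, 1 adjacency)."""
    if a.chrom != b.chrom:
        return np.iinfo(np.int64).max
    if a.intersection_length(b) > 0:
        return 0
    if a.end <= b.start:
        return b.start - a.end + 1
    return a.start - b.end + 1


@dataclass(frozen=True)
class CagePeak:
    """A stranded CAGE tag cluster with per-sample raw tag counts."""

    id: str
    interval: GenomicInterval
    summit: int
    counts: np.ndarray  # one non-negative integer per sample

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"CAGE peak {self.id} must be stranded")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside {self.interval} for peak {self.id}"
            )
        object.__setattr__(self, "counts", np.asarray(self.counts))
        if (self.counts < 0).any():
            raise ValueError(f"negative counts for peak {self.id}")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def five_prime(self) -> int:
        """5' end of the cluster: start on +, last base on -."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    tss: int
    strand: str


@dataclass
class GeneModel:
    """A protein-coding gene: transcript TSSs plus the union of exons."""

    gene_id: str
    chrom: str
    biotype: str
    transcripts: list[Transcript]
    exons: list[GenomicInterval]

    def tss_positions(self) -> list[tuple[int, str]]:
        return [(t.tss, t.strand) for t in self.transcripts]


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    group: str  # macrophage | non_macrophage
    condition: str = "none"  # untreated | ifng | il4il13 | none
    time_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("macrophage", "non_macrophage"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.condition not in ("untreated", "ifng", "il4il13", "none"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.group == "non_macrophage" and self.condition != "none":
            raise ValueError("non-macrophage samples cannot carry a condition")


@dataclass(frozen=True)
class TAD:
    """A topologically associating domain (unstranded interval)."""

    id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike, expected_columns: int = 3) -> list[BedRecord]:
    """Read BED3/BED4/BED6 into :class:`BedRecord` objects, order preserved."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < max(3, expected_columns):
                raise ParseError(f"{path}:{lineno}: expected >= {expected_columns} columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(BedRecord(iv, name, score))
    return records


def write_bed(records: Iterable[BedRecord], path: str | os.PathLike, columns: int = 6) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fields = [rec.interval.chrom, str(rec.interval.start), str(rec.interval.end)]
            if columns >= 4:
                fields.append(rec.name)
            if columns >= 5:
                fields.append(format(rec.score, "g"))
            if columns >= 6:
                fields.append(rec.interval.strand)
            fh.write("\t".join(fields) + "\n")


def read_tads(path: str | os.PathLike) -> list[TAD]:
    """Read TAD intervals from BED3+ (name from column 4 if present)."""
    tads = []
    for i, rec in enumerate(read_bed(path, expected_columns=3)):
        name = rec.name if rec.name != "." else f"tad_{i:04d}"
        iv = GenomicInterval(rec.interval.chrom, rec.interval.start, rec.interval.end)
        tads.append(TAD(name, iv))
    return tads


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NarrowPeak:
    interval: GenomicInterval
    name: str
    summit: int
    q_value: float  # decoded from the -log10 column


def read_narrowpeak(path: str | os.PathLike) -> list[NarrowPeak]:
    """Read 10-column ENCODE narrowPeak.

    The summit is ``start + offset`` (column 10); an offset of -1 (unknown)
    falls back to the interval midpoint.  The q-value is decoded from the
    -log10(q) column.
    """
    out: list[NarrowPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                neg_log10_q = float(fields[8])
                offset = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            try:
                iv = GenomicInterval(fields[0], start, end, ".")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if offset == -1:
                summit = start + iv.width // 2
            elif 0 <= offset < iv.width:
                summit = start + offset
            else:
                raise ParseError(f"{path}:{lineno}: summit offset {offset} beyond interval")
            out.append(NarrowPeak(iv, fields[3], summit, 10.0 ** (-neg_log10_q)))
    return out


def write_narrowpeak(peaks: Iterable[NarrowPeak], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            neg_log10_q = -np.log10(pk.q_value) if pk.q_value > 0 else 999.0
            fh.write(
                "\t".join(
                    [
                        pk.interval.chrom,
                        str(pk.interval.start),
                        str(pk.interval.end),
                        pk.name,
                        "0",
                        ".",
                        "0",
                        "-1",
                        format(neg_log10_q, ".6g"),
                        str(pk.summit - pk.interval.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GTF via gffutils, or BED12)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GTF (``.gtf``) or BED12 (anything else).

    Per gene the 5'-most coordinate of each transcript (strand-aware) becomes
    its TSS and the exon set is the union over transcripts.  A transcript
    without exons or with an unknown strand is a parse error.
    """
    path = os.fspath(path)
    if path.endswith((".gtf", ".gff", ".gff3")):
        return _read_gtf(path)
    return _read_bed12(path)


def _read_gtf(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=False,
        disable_infer_transcripts=False,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        biotype = (
            gene.attributes.get("gene_biotype", gene.attributes.get("gene_type", ["unknown"]))
        )[0]
        transcripts: list[Transcript] = []
        exons: list[GenomicInterval] = []
        for tx in db.children(gene, featuretype="transcript"):
            tx_exons = list(db.children(tx, featuretype="exon"))
            if not tx_exons:
                raise ParseError(f"transcript {tx.id} has no exons")
            if tx.strand not in ("+", "-"):
                raise ParseError(f"transcript {tx.id} has unknown strand")
            lo = min(e.start for e in tx_exons) - 1  # GFF is 1-based closed
            hi = max(e.end for e in tx_exons)
            tss = lo if tx.strand == "+" else hi - 1
            transcripts.append(Transcript(tx.id, tss, tx.strand))
            for e in tx_exons:
                exons.append(GenomicInterval(e.seqid, e.start - 1, e.end, tx.strand))
        if not transcripts:
            raise ParseError(f"gene {gene.id} has no transcripts")
        genes.append(GeneModel(gene.id, gene.seqid, biotype, transcripts, _union(exons)))
    return genes


def _read_bed12(path: str) -> list[GeneModel]:
    """BED12: one line per transcript; name is ``gene|transcript`` or a bare
    transcript id (then gene id == transcript id)."""
    by_gene: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            n_blocks = int(fields[9])
            if n_blocks < 1:
                raise ParseError(f"{path}:{lineno}: transcript without exons")
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = [
                GenomicInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            gene_id, _, tx_id = name.partition("|")
            tx_id = tx_id or name
            tss = start if strand == "+" else end - 1
            gm = by_gene.setdefault(
                gene_id, GeneModel(gene_id, chrom, "protein_coding", [], [])
            )
            gm.transcripts.append(Transcript(tx_id, tss, strand))
            gm.exons.extend(exons)
    for gm in by_gene.values():
        gm.exons = _union(gm.exons)
    return list(by_gene.values())


def _union(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals (strand collapsed to '.')."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


# ---------------------------------------------------------------------------
# TSS count tables and sample metadata
# ---------------------------------------------------------------------------

TSS_KEY_COLUMNS = ["chrom", "pos", "strand"]


def read_tss_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Per-position stranded CAGE counts: chrom, pos, strand + one column
    per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64, "strand": str})
    missing = [c for c in TSS_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_tss_counts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | os.PathLike) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        time_h = getattr(row, "time_h", None)
        if time_h is not None and pd.isna(time_h):
            time_h = None
        out.append(SampleMetadata(str(row.sample_id), row.group, row.condition, time_h))
    return out


def write_sample_metadata(samples: Sequence[SampleMetadata], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "condition": [s.condition for s in samples],
            "time_h": [s.time_h for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def parse_region_string(region: str) -> GenomicInterval:
    """Parse ``chr10:25119065...25119466``-style region strings (0-based
    start, half-open end)."""
    chrom, _, rest = region.partition(":")
    for sep in ("…", "...", "-"):
        if sep in rest:
            a, b = rest.split(sep)
            return GenomicInterval(chrom, int(a), int(b))
    raise ParseError(f"cannot parse region string {region!r}")
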