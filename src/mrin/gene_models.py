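"""Gene models: annotation parsing, representative transcripts, overlap filtering.

The gene universe used by all downstream statistics is built in three steps:
parse a transcript annotation (refFlat, GTF or BED12), keep one representative
transcript per gene (the longest by spliced length), and drop genes whose
genomic span overlaps a neighbouring gene, so that read assignment is
unambiguous.  All coordinates are handled internally as 0-based half-open
genomic intervals; GTF input (1-based inclusive) is converted on read.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "AnnotationError",
    "Transcript",
    "GeneModel",
    "load_annotation",
    "select_representatives",
    "filter_nonoverlapping",
    "write_gene_universe",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class Transcript:
    """One transcript: exon structure plus optional CDS on genomic coordinates.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted by genomic start regardless of strand.  ``cds_start``/``cds_end``
    are genomic (half-open) or both ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id!r}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id!r}: no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: empty exon ({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: exons overlap or are unsorted"
                )
            prev_end = end
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"transcript {self.transcript_id!r}: partial CDS annotation"
            )
        if self.cds_start is not None and self.cds_end is not None:
            if not (self.exons[0][0] <= self.cds_start < self.cds_end <= self.exons[-1][1]):
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: CDS outside transcript span"
                )

    @property
    def spliced_length(self) -> int:
        """Sum of exon widths (the transcript length L)."""
        return sum(end - start for start, end in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end)."""
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic base to its 0-based position along the spliced
        transcript in 5'->3' orientation.

        Raises ``ValueError`` if the base is not exonic.
        """
        offset = 0
        idx = None
        for start, end in self.exons:
            if start <= gpos < end:
                idx = offset + (gpos - start)
                break
            offset += end - start
        if idx is None:
            raise ValueError(
                f"position {gpos} is not exonic in transcript {self.transcript_id}"
            )
        if self.strand == "+":
            return idx
        return self.spliced_length - 1 - idx

    def transcript_regions(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        """5'UTR, CDS and 3'UTR as half-open intervals in transcript
        coordinates (5'->3').  Requires a coding transcript whose CDS
        boundaries are exonic.
        """
        if not self.is_coding:
            raise ValueError(f"transcript {self.transcript_id} is non-coding")
        assert self.cds_start is not None and self.cds_end is not None
        if self.strand == "+":
            lo = self.genomic_to_transcript(self.cds_start)
            hi = self.genomic_to_transcript(self.cds_end - 1) + 1
        else:
            lo = self.genomic_to_transcript(self.cds_end - 1)
            hi = self.genomic_to_transcript(self.cds_start) + 1
        L = self.spliced_length
        return (0, lo), (lo, hi), (hi, L)


@dataclass(frozen=True)
class GeneModel:
    """A gene represented by its single longest transcript."""

    gene_id: str
    representative: Transcript

    @property
    def chrom(self) -> str:
        return self.representative.chrom

    @property
    def strand(self) -> str:
        return self.representative.strand

    @property
    def n_exons(self) -> int:
        return self.representative.n_exons

    @property
    def spliced_length(self) -> int:
        return self.representative.spliced_length

    @property
    def genomic_span(self) -> tuple[int, int]:
        return self.representative.span


# --------------------------------------------------------------------------
# Parsers


def _open_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, str):
        yield from io.StringIO(source)
    else:
        yield from source


def _parse_refflat(lines: Iterable[str]) -> Iterator[Transcript]:
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise AnnotationError(f"refFlat line {lineno}: expected 11 columns, got {len(fields)}")
        try:
            gene, tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            cds_start, cds_end = int(fields[6]), int(fields[7])
            n_exons = int(fields[8])
            starts = [int(x) for x in fields[9].rstrip(",").split(",")]
            ends = [int(x) for x in fields[10].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationError(f"refFlat line {lineno}: {exc}") from exc
        if len(starts) != n_exons or len(ends) != n_exons:
            raise AnnotationError(f"refFlat line {lineno}: exon count mismatch")
        coding = cds_start < cds_end
        yield Transcript(
            transcript_id=tx,
            gene_id=gene,
            chrom=chrom,
            strand=strand,
            exons=tuple(zip(starts, ends)),
            cds_start=cds_start if coding else None,
            cds_end=cds_end if coding else None,
        )


def _parse_bed12(lines: Iterable[str]) -> Iterator[Transcript]:
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise AnnotationError(f"BED12 line {lineno}: expected 12 columns, got {len(fields)}")
        try:
            chrom = fields[0]
            start = int(fields[1])
            name = fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationError(f"BED12 line {lineno}: {exc}") from exc
        if len(sizes) != block_count or len(offsets) != block_count:
            raise AnnotationError(f"BED12 line {lineno}: block count mismatch")
        exons = tuple((start + off, start + off + size) for off, size in zip(offsets, sizes))
        coding = thick_start < thick_end
        yield Transcript(
            transcript_id=name,
            gene_id=name,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=thick_start if coding else None,
            cds_end=thick_end if coding else None,
        )


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GTF_ATTR_BARE = re.compile(r"(\w+)[ =]([^;]+)")


def _gtf_attributes(raw: str) -> Mapping[str, str]:
    attrs = dict(_GTF_ATTR.findall(raw))
    if not attrs:
        attrs = {k: v.strip().strip('"') for k, v in _GTF_ATTR_BARE.findall(raw)}
    return attrs


def _parse_gtf(lines: Iterable[str]) -> Iterator[Transcript]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise AnnotationError(f"GTF line {lineno}: expected 9 columns, got {len(fields)}")
        feature = fields[2]
        if feature not in ("exon", "CDS"):
            continue
        try:
            start = int(fields[3]) - 1  # GTF is 1-based inclusive
            end = int(fields[4])
        except ValueError as exc:
            raise AnnotationError(f"GTF line {lineno}: {exc}") from exc
        attrs = _gtf_attributes(fields[8])
        tx = attrs.get("transcript_id")
        gene = attrs.get("gene_id", tx)
        if tx is None:
            raise AnnotationError(f"GTF line {lineno}: missing transcript_id attribute")
        key = (gene, fields[0], fields[6])
        if tx in meta and meta[tx] != key:
            raise AnnotationError(
                f"GTF line {lineno}: transcript {tx!r} has conflicting gene/chrom/strand"
            )
        meta[tx] = key
        if feature == "exon":
            exons.setdefault(tx, []).append((start, end))
        else:
            cds.setdefault(tx, []).append((start, end))
    for tx, (gene, chrom, strand) in meta.items():
        ex = sorted(exons.get(tx, []))
        if not ex:
            raise AnnotationError(f"GTF transcript {tx!r}: no exon features")
        cds_iv = cds.get(tx)
        yield Transcript(
            transcript_id=tx,
            gene_id=gene,
            chrom=chrom,
            strand=strand,
            exons=tuple(ex),
            cds_start=min(s for s, _ in cds_iv) if cds_iv else None,
            cds_end=max(e for _, e in cds_iv) if cds_iv else None,
        )


_PARSERS = {"refflat": _parse_refflat, "gtf": _parse_gtf, "bed12": _parse_bed12}


def load_annotation(source, dialect: str = "refflat") -> list[Transcript]:
    """Parse a transcript annotation into :class:`Transcript` records.

    Parameters
    ----------
    source
        Path, multi-line string, or iterable of lines.
    dialect
        One of ``refflat`` (UCSC 11-column), ``gtf``, ``bed12``.

    Duplicate transcript identifiers are rejected.
    """
    key = dialect.lower()
    if key not in _PARSERS:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    out: list[Transcript] = []
    seen: set[str] = set()
    for tx in _PARSERS[key](_open_lines(source)):
        if tx.transcript_id in seen:
            raise AnnotationError(f"duplicate transcript_id {tx.transcript_id!r}")
        seen.add(tx.transcript_id)
        out.append(tx)
    return out


# --------------------------------------------------------------------------
# Gene universe construction


def select_representatives(transcripts: Sequence[Transcript]) -> list[GeneModel]:
    """One :class:`GeneModel` per gene: the longest transcript by spliced
    length, ties broken by lexicographically smallest transcript_id."""
    by_gene: dict[str, Transcript] = {}
    for tx in transcripts:
        cur = by_gene.get(tx.gene_id)
        if cur is None:
            by_gene[tx.gene_id] = tx
            continue
        key_new = (-tx.spliced_length, tx.transcript_id)
        key_cur = (-cur.spliced_length, cur.transcript_id)
        if key_new < key_cur:
            by_gene[tx.gene_id] = tx
    return [GeneModel(gene_id=g, representative=tx) for g, tx in sorted(by_gene.items())]


def filter_nonoverlapping(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Retain only genes whose genomic span overlaps no other gene's span.

    The test is strand-agnostic and uses the representative transcript's
    span; both members of an overlapping pair are removed.
    """
    overlapped: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        ordered = sorted(chrom_genes, key=lambda g: g.genomic_span)
        active: list[GeneModel] = []
        for g in ordered:
            start, _ = g.genomic_span
            active = [a for a in active if a.genomic_span[1] > start]
            for a in active:
                overlapped.add(a.gene_id)
                overlapped.add(g.gene_id)
            active.append(g)
    return [g for g in genes if g.gene_id not in overlapped]


def write_gene_universe(genes: Sequence[GeneModel], path) -> None:
    """Write the retained gene universe as TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tchrom\tstrand\tlength\tn_exons\n")
        for g in genes:
            tx = g.representative
            fh.write(
                f"{g.gene_id}\t{tx.transcript_id}\t{g.chrom}\t{g.strand}\t"
                f"{g.spliced_length}\t{g.n_exons}\n"
            )
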