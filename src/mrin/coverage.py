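"""Per-gene read coverage profiles along the spliced transcript.

A coverage profile stores the per-base depth ``n[x]`` at each exonic position
``x = 1..L``, where ``x = 1`` is the 3'-most exonic nucleotide.  Profiles can
be built from indexed BAM files (per-base depth, CIGAR-aware), from bedGraph
tracks, or from exon-level RPKM tables in which the depth is piecewise
constant within each exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gene_models import GeneModel

__all__ = [
    "CoverageError",
    "CoverageProfile",
    "per_base_profile",
    "exon_level_profile",
    "gene_rpkm",
    "BedGraphCoverage",
    "profile_from_bedgraph",
    "attach_rpkm",
    "write_profile_tsv",
]


class CoverageError(ValueError):
    """Raised for coverage extraction problems."""


@dataclass
class CoverageProfile:
    """Per-base depth along one gene's representative transcript.

    ``n[0]`` corresponds to transcript position x = 1, the 3'-most exonic
    nucleotide.  Values are floats because exon-level (RPKM) mode produces
    non-integer depth.
    """

    gene_id: str
    sample_id: str
    n: np.ndarray
    rpkm: float | None = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.ndim != 1:
            raise CoverageError("coverage vector must be one-dimensional")
        if np.any(self.n < 0):
            raise CoverageError("coverage must be non-negative")

    @property
    def L(self) -> int:
        """Transcript (spliced) length."""
        return int(self.n.size)

    @property
    def h(self) -> float:
        """Total nucleotide coverage, sum over n[x]."""
        return float(self.n.sum())

    @property
    def mean_coverage(self) -> float:
        return self.h / self.L


def _genomic_concat_to_3prime(depth_genomic: np.ndarray, strand: str) -> np.ndarray:
    # depth_genomic is the exon-chain depth in ascending genomic order.  On
    # the "+" strand the 3' end is the genomically largest base, so the
    # vector is reversed; on "-" the genomically smallest base is already
    # x = 1.
    if strand == "+":
        return depth_genomic[::-1]
    return depth_genomic


def per_base_profile(alignments, gene: GeneModel, sample_id: str = "",
                     min_mapq: int = 0) -> CoverageProfile:
    """Per-base depth over the representative transcript from an indexed BAM.

    Each aligned base of each read contributes 1 to the exonic position it
    covers; intronic and flanking bases contribute nothing (deletions/skips
    in the CIGAR are respected).  Secondary, supplementary, duplicate and
    QC-fail alignments are excluded; ``min_mapq`` optionally filters by
    mapping quality (off by default).

    ``alignments`` is a :class:`pysam.AlignmentFile` or a path to an indexed
    BAM.
    """
    import pysam

    own = False
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments), "rb")
        own = True
    try:
        tx = gene.representative
        if tx.chrom not in alignments.references:
            raise CoverageError(
                f"chromosome {tx.chrom!r} absent from alignment file for gene {gene.gene_id}"
            )
        if tx.spliced_length == 0:
            raise CoverageError(f"gene {gene.gene_id}: zero-length exon chain")

        def keep(read) -> bool:
            return not (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.is_qcfail
            ) and read.mapping_quality >= min_mapq

        pieces = []
        for start, end in tx.exons:
            acgt = alignments.count_coverage(
                tx.chrom, start, end, quality_threshold=0, read_callback=keep
            )
            pieces.append(np.sum(np.asarray(acgt, dtype=float), axis=0))
        depth = np.concatenate(pieces)
    finally:
        if own:
            alignments.close()
    return CoverageProfile(
        gene_id=gene.gene_id,
        sample_id=sample_id,
        n=_genomic_concat_to_3prime(depth, tx.strand),
    )


def exon_level_profile(exon_rpkm: Sequence[float], gene: GeneModel,
                       sample_id: str = "") -> CoverageProfile:
    """Piecewise-constant profile from per-exon RPKM values.

    ``exon_rpkm`` is ordered along the transcript 5'->3' (exon 1 is the
    5'-most exon).  The profile value within each exon equals that exon's
    RPKM, so ``h`` equals the sum of RPKM x exon width over exons.
    """
    tx = gene.representative
    vals = np.asarray(exon_rpkm, dtype=float)
    if vals.size != tx.n_exons:
        raise CoverageError(
            f"gene {gene.gene_id}: {vals.size} exon RPKM values for {tx.n_exons} exons"
        )
    # exons in transcript (5'->3') order
    exons = tx.exons if tx.strand == "+" else tx.exons[::-1]
    five_to_three = np.concatenate(
        [np.full(end - start, v, dtype=float) for (start, end), v in zip(exons, vals)]
    )
    return CoverageProfile(gene_id=gene.gene_id, sample_id=sample_id, n=five_to_three[::-1])


def gene_rpkm(profile: CoverageProfile, mapped_read_count: float,
              read_length: float = 100.0) -> float:
    """RPKM from total base coverage: (h / read_length) reads, per kb of
    transcript, per million mapped reads.  Stored on the profile."""
    if read_length <= 0:
        raise CoverageError("read_length must be positive")
    if mapped_read_count <= 0:
        raise CoverageError("mapped_read_count must be positive")
    reads = profile.h / read_length
    rpkm = reads / (profile.L / 1000.0) / (mapped_read_count / 1e6)
    profile.rpkm = rpkm
    return rpkm


def attach_rpkm(cohort: Mapping[str, Mapping[str, CoverageProfile]],
                read_length: float = 100.0) -> None:
    """Fill in RPKM for every profile of a cohort, deriving each sample's
    mapped read count from its total base coverage / read_length."""
    for profiles in cohort.values():
        total_bases = sum(p.h for p in profiles.values())
        mapped = max(total_bases / read_length, 1.0)
        for p in profiles.values():
            gene_rpkm(p, mapped, read_length)


# --------------------------------------------------------------------------
# bedGraph support


class BedGraphCoverage:
    """Run-length per-base coverage loaded from a bedGraph file."""

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._iv = intervals

    @classmethod
    def from_file(cls, path) -> "BedGraphCoverage":
        raw: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise CoverageError(
                        f"bedGraph line {lineno}: expected 4 columns, got {len(fields)}"
                    )
                try:
                    raw.setdefault(fields[0], []).append(
                        (int(fields[1]), int(fields[2]), float(fields[3]))
                    )
                except ValueError as exc:
                    raise CoverageError(f"bedGraph line {lineno}: {exc}") from exc
        iv = {}
        for chrom, rows in raw.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = np.array([r[2] for r in rows], dtype=float)
            iv[chrom] = (starts, ends, vals)
        return cls(iv)

    @property
    def chroms(self) -> list[str]:
        return list(self._iv)

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end); bases not covered by any
        interval are zero."""
        if chrom not in self._iv:
            raise CoverageError(f"chromosome {chrom!r} absent from bedGraph")
        starts, ends, vals = self._iv[chrom]
        out = np.zeros(end - start, dtype=float)
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if e > s:
                out[s - start : e - start] = vals[i]
        return out


def profile_from_bedgraph(cov: BedGraphCoverage, gene: GeneModel,
                          sample_id: str = "") -> CoverageProfile:
    """Extract a gene's 3'-indexed profile from a bedGraph coverage track."""
    tx = gene.representative
    depth = np.concatenate([cov.depth(tx.chrom, s, e) for s, e in tx.exons])
    return CoverageProfile(
        gene_id=gene.gene_id,
        sample_id=sample_id,
        n=_genomic_concat_to_3prime(depth, tx.strand),
    )


def write_profile_tsv(profile: CoverageProfile, path) -> None:
    """Dump a profile as (x, n[x]) TSV for inspection."""
    with open(path, "w") as fh:
        fh.write("x\tn\n")
        for x, v in enumerate(profile.n, 1):
            fh.write(f"{x}\t{v:.6g}\n")
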