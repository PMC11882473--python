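"""Gene-model and alignment containers shared by every pipeline stage.

Coordinates are 0-based half-open everywhere in memory.  GTF files are read
and written with the conventional 1-based closed coordinates; BED12 is
0-based half-open.  A BED12 record encodes one aligned read (one fragment);
its blocks are the aligned segments, so gaps between consecutive blocks are
splice junctions.  Mapping uniqueness travels in the BED score column
(1 = uniquely mapped, 0 = multi-mapped).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

Interval = tuple[int, int]


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; carries the 1-based line number."""


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[Interval, ...]  # sorted by start, non-overlapping

    def __post_init__(self) -> None:
        ex = self.exons
        if not ex:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(
                    f"transcript {self.transcript_id}: exons not ordered/disjoint"
                )

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    def junctions(self) -> list[Interval]:
        """Introns as (donor-side end, acceptor-side start) reference intervals."""
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: tuple[Transcript, ...]

    @property
    def span(self) -> Interval:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s

    def exon_union(self) -> list[Interval]:
        """Merged exon intervals across all transcripts."""
        return merge_intervals(iv for t in self.transcripts for iv in t.exons)

    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exon_union())

    def all_exons(self) -> list[Interval]:
        seen = sorted({iv for t in self.transcripts for iv in t.exons})
        return seen

    def annotated_junctions(self) -> set[Interval]:
        return {j for t in self.transcripts for j in t.junctions()}


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class GenomeAnnotation:
    """Genes with transcript/exon structure plus per-chromosome interval indexes."""

    def __init__(self, genes: Sequence[Gene]):
        self.genes: list[Gene] = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene_id in annotation")
        # interval trees over exon-union intervals, keyed by (chrom, strand)
        self._exon_index: dict[tuple[str, str], IntervalTree] = {}
        self._span_index: dict[tuple[str, str], IntervalTree] = {}
        for g in self.genes:
            key = (g.chrom, g.strand)
            etree = self._exon_index.setdefault(key, IntervalTree())
            for s, e in g.exon_union():
                etree.addi(s, e, g.gene_id)
            stree = self._span_index.setdefault(key, IntervalTree())
            s, e = g.span
            stree.addi(s, e, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def chroms(self) -> set[str]:
        return {g.chrom for g in self.genes}

    def genes_with_exon_overlap(
        self, chrom: str, strand: str | None, start: int, end: int
    ) -> set[str]:
        """Gene ids whose exon union intersects [start, end) on the given strand
        (both strands when strand is None)."""
        strands = ["+", "-"] if strand is None else [strand]
        hits: set[str] = set()
        for st in strands:
            tree = self._exon_index.get((chrom, st))
            if tree is not None:
                hits.update(iv.data for iv in tree.overlap(start, end))
        return hits

    def genes_with_span_overlap(
        self, chrom: str, strand: str | None, start: int, end: int
    ) -> set[str]:
        strands = ["+", "-"] if strand is None else [strand]
        hits: set[str] = set()
        for st in strands:
            tree = self._span_index.get((chrom, st))
            if tree is not None:
                hits.update(iv.data for iv in tree.overlap(start, end))
        return hits


# ---------------------------------------------------------------------------
# GTF reading/writing (1-based closed on disk)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(s: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(s))


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Parse a GTF into a GenomeAnnotation.

    Only ``exon`` features are required; gene and transcript structure is
    inferred from gene_id/transcript_id attributes.  Raises GtfParseError
    naming the offending 1-based line number.
    """
    exons: dict[tuple[str, str], list[Interval]] = {}  # (gene_id, tx_id) -> exons
    meta: dict[str, tuple[str, str, str]] = {}  # gene_id -> (symbol, chrom, strand)
    gene_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in "+-":
                raise GtfParseError(f"line {lineno}: strand must be + or -")
            attrs = _parse_attrs(attrs_s)
            try:
                gid = attrs["gene_id"]
                tid = attrs["transcript_id"]
            except KeyError as exc:
                raise GtfParseError(f"line {lineno}: missing {exc} attribute") from exc
            if gid not in meta:
                meta[gid] = (attrs.get("gene_name", gid), chrom, strand)
                gene_order.append(gid)
            exons.setdefault((gid, tid), []).append((start, end))
    tx_by_gene: dict[str, list[Transcript]] = {}
    for (gid, tid), ivs in exons.items():
        tx_by_gene.setdefault(gid, []).append(Transcript(tid, tuple(sorted(ivs))))
    genes = []
    for gid in gene_order:
        symbol, chrom, strand = meta[gid]
        txs = tuple(sorted(tx_by_gene[gid], key=lambda t: t.transcript_id))
        genes.append(Gene(gid, symbol, chrom, strand, txs))
    return GenomeAnnotation(genes)


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in annotation:
            gs, ge = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tripintegrate\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                ts, te = t.span
                tattrs = attrs + f' transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\tripintegrate\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\tripintegrate\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# Aligned reads (BED12 dialect)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedRead:
    """A strand-aware block-structured alignment; one record per fragment."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[Interval, ...]
    unique: bool = True
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment needs at least one block")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"read {self.read_id}: blocks not ordered/disjoint")

    @property
    def span(self) -> Interval:
        return self.blocks[0][0], self.blocks[-1][1]

    def junctions(self) -> list[Interval]:
        return [(self.blocks[i][1], self.blocks[i + 1][0]) for i in range(len(self.blocks) - 1)]

    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


class Bed12ParseError(ValueError):
    pass


def read_bed12(path: str | Path, sample_id: str = "") -> list[AlignedRead]:
    """Read alignments from BED12; score column carries uniqueness (1/0)."""
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise Bed12ParseError(f"line {lineno}: expected 12 BED fields")
            try:
                chrom_start = int(f[1])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise Bed12ParseError(f"line {lineno}: bad numeric field") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise Bed12ParseError(f"line {lineno}: block count mismatch")
            blocks = tuple(
                (chrom_start + off, chrom_start + off + sz)
                for off, sz in zip(offsets, sizes)
            )
            reads.append(
                AlignedRead(
                    read_id=f[3],
                    chrom=f[0],
                    strand=f[5],
                    blocks=blocks,
                    unique=f[4] not in ("0", "0.0"),
                    sample_id=sample_id,
                )
            )
    return reads


def write_bed12(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            start, end = r.span
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            offsets = ",".join(str(s - start) for s, e in r.blocks)
            score = "1" if r.unique else "0"
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{r.read_id}\t{score}\t{r.strand}"
                f"\t{start}\t{end}\t0\t{len(r.blocks)}\t{sizes}\t{offsets}\n"
            )
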