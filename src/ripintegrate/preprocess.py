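"""Raw-read QC and annotation-aware gene counting / FPKM.

QC keeps a read only if it has at most ``max_n`` ambiguous (N) bases and is
at least ``min_len`` nucleotides long; the N rule is applied first so each
discarded read is attributed to exactly one rule.  Counting assigns a
uniquely mapped fragment to a gene when every aligned block intersects that
gene's exon union on a compatible strand; fragments compatible with more
than one gene are ambiguous and counted for none.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .annotation import AlignedRead, GenomeAnnotation


@dataclass
class QcReport:
    total: int = 0
    kept: int = 0
    discarded_n: int = 0  # > max_n ambiguous bases
    discarded_short: int = 0  # < min_len after the N rule

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "kept": self.kept,
            "discarded_n": self.discarded_n,
            "discarded_short": self.discarded_short,
        }


class FastqParseError(ValueError):
    pass


def filter_raw_reads(
    reads: str | Path | Iterable[SeqRecord],
    max_n: int = 2,
    min_len: int = 16,
) -> tuple[list[SeqRecord], QcReport]:
    """Apply the two raw-read filters; returns (kept records, report).

    ``reads`` may be a FASTQ path or an iterable of SeqRecords.
    """
    if isinstance(reads, (str, Path)):
        iterator = SeqIO.parse(str(reads), "fastq")
    else:
        iterator = iter(reads)
    report = QcReport()
    kept: list[SeqRecord] = []
    idx = -1
    try:
        for idx, rec in enumerate(iterator):
            report.total += 1
            seq = str(rec.seq).upper()
            if seq.count("N") > max_n:
                report.discarded_n += 1
            elif len(seq) < min_len:
                report.discarded_short += 1
            else:
                kept.append(rec)
    except ValueError as exc:
        raise FastqParseError(f"malformed FASTQ near record {idx + 2}: {exc}") from exc
    report.kept = len(kept)
    return kept, report


@dataclass
class CountMatrix:
    """Integer gene-by-sample counts plus library totals and exonic lengths."""

    counts: pd.DataFrame  # genes x samples, int
    totals: pd.Series  # per-sample total mapped fragments
    lengths: pd.Series  # per-gene exon-union length (bp)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not self.counts.columns.equals(self.totals.index):
            self.totals = self.totals.reindex(self.counts.columns)
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        col_sums = self.counts.sum(axis=0)
        if (self.totals < col_sums).any():
            raise ValueError("per-sample totals smaller than column sums")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
        # totals on a commented header line so the table stays a plain matrix
        with open(path) as fh:
            body = fh.read()
        totals = "\t".join(f"{s}={int(v)}" for s, v in self.totals.items())
        with open(path, "w") as fh:
            fh.write(f"# totals\t{totals}\n{body}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        with open(path) as fh:
            first = fh.readline()
        totals = None
        skip = 0
        if first.startswith("# totals"):
            skip = 1
            totals = pd.Series(
                {
                    kv.split("=")[0]: int(kv.split("=")[1])
                    for kv in first.rstrip("\n").split("\t")[1:]
                }
            )
        df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
        lengths = df.pop("length")
        if totals is None:
            totals = df.sum(axis=0)
        return cls(df.astype(int), totals.astype(int), lengths.astype(int))


@dataclass
class CountingReport:
    assigned: int = 0
    ambiguous: int = 0
    unassigned: int = 0
    multi_mapped: int = 0
    strand_skipped: int = 0
    missing_chrom: int = 0


def count_genes(
    alignments: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    samples: Sequence[str] | None = None,
    stranded: bool = True,
) -> tuple[CountMatrix, CountingReport]:
    """Count uniquely mapped fragments per gene and sample.

    A fragment is assigned to a gene iff every one of its blocks intersects
    the gene's exon union (strand-compatible when ``stranded``).  Fragments
    compatible with more than one gene are dropped as ambiguous.
    """
    report = CountingReport()
    gene_ids = [g.gene_id for g in annotation]
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    known_chroms = annotation.chroms
    seen_samples: list[str] = []
    for read in alignments:
        sid = read.sample_id or "sample"
        if sid not in totals:
            totals[sid] = 0
            seen_samples.append(sid)
        if not read.unique:
            report.multi_mapped += 1
            continue
        totals[sid] += 1
        if read.chrom not in known_chroms:
            report.missing_chrom += 1
            continue
        strand = read.strand if stranded else None
        candidates: set[str] | None = None
        for bs, be in read.blocks:
            hits = annotation.genes_with_exon_overlap(read.chrom, strand, bs, be)
            candidates = hits if candidates is None else (candidates & hits)
            if not candidates:
                break
        if not candidates:
            report.unassigned += 1
            continue
        if len(candidates) > 1:
            report.ambiguous += 1
            continue
        gid = next(iter(candidates))
        counts.setdefault(gid, {})[sid] = counts.setdefault(gid, {}).get(sid, 0) + 1
        report.assigned += 1

    cols = list(samples) if samples is not None else seen_samples
    if not cols:
        cols = ["sample"]
    mat = pd.DataFrame(0, index=gene_ids, columns=cols, dtype=int)
    for gid, per_sample in counts.items():
        for sid, c in per_sample.items():
            if sid in mat.columns:
                mat.loc[gid, sid] = c
    totals_s = pd.Series({c: totals.get(c, 0) for c in cols}, dtype=int)
    lengths = pd.Series(
        {g.gene_id: g.exon_union_length() for g in annotation}, dtype=int
    ).reindex(gene_ids)
    return CountMatrix(mat, totals_s, lengths), report


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """FPKM[g, s] = count[g, s] * 1e9 / (length_bp[g] * total_fragments[s])."""
    lengths = cm.lengths.to_numpy(dtype=float)
    totals = cm.totals.to_numpy(dtype=float)
    if (lengths <= 0).any():
        bad = cm.lengths.index[lengths <= 0][0]
        raise ValueError(f"gene {bad} has non-positive exonic length")
    if (totals <= 0).any():
        bad = cm.totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad} has no mapped fragments")
    vals = cm.counts.to_numpy(dtype=float) * 1e9 / np.outer(lengths, totals)
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)
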