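"""RIP-seq peak calling: window scan, depth-rule assembly, within-gene
read-shuffle permutation null, and IP-vs-input enrichment filtering.

The caller works per gene.  Coverage is scanned in 5-bp windows with a 5-bp
step (window depth = mean per-base depth; a trailing partial window keeps
its actual width).  A candidate peak opens at the first window of a run of
``run_len`` consecutive windows that are each at least ``start_factor``
times the gene's mean per-base depth, or whose median depth exceeds
``median_floor``; once open it extends until ``run_len`` consecutive
windows each fall below ``end_fraction`` of the running maximum window
depth, closing just before that run.  Significance comes from an empirical
null: the gene's reads are uniformly re-placed within the gene span
(lengths preserved) ``n_shuffles`` times and the gene-wide maximum window
depth is recorded; the permutation p uses the add-one convention so it is
never zero.  Finally a candidate survives if it is significant
(perm p < 0.05) or tall (max per-base depth >= 10), and its library-
normalised IP abundance exceeds ``fold`` times the input abundance in the
same interval (one pseudo-read added to the input).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import AlignedRead, Gene, GenomeAnnotation

WINDOW_BP = 5
STEP_BP = 5
START_FACTOR = 2.5
RUN_LEN = 8
MEDIAN_FLOOR = 50.0
END_FRACTION = 0.04
N_SHUFFLES = 500
P_THRESHOLD = 0.05
MIN_MAX_DEPTH = 10.0
FOLD = 4.0
INPUT_PSEUDO = 1.0


@dataclass
class CoverageTrack:
    """Per-base read depth over one gene's span."""

    gene: str
    chrom: str
    strand: str
    start: int
    end: int
    depth: np.ndarray  # length end - start
    read_lengths: np.ndarray  # aligned length of each assigned read

    @property
    def n_reads(self) -> int:
        return len(self.read_lengths)

    @property
    def span_length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_reads(cls, gene: Gene, reads: Sequence[AlignedRead]) -> "CoverageTrack":
        gs, ge = gene.span
        depth = np.zeros(ge - gs, dtype=np.int64)
        lengths = []
        for r in reads:
            for bs, be in r.blocks:
                s = max(bs, gs) - gs
                e = min(be, ge) - gs
                if e > s:
                    depth[s:e] += 1
            lengths.append(r.aligned_length())
        return cls(
            gene=gene.gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            start=gs,
            end=ge,
            depth=depth,
            read_lengths=np.asarray(lengths, dtype=np.int64),
        )

    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.span_length else 0.0


def window_depths(
    depth: np.ndarray, window: int = WINDOW_BP, step: int = STEP_BP
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean per-base depth of tiled windows.

    Returns (window_starts, window_ends, window_means) relative to the
    track; the trailing partial window keeps its actual width.
    """
    n = len(depth)
    if n == 0:
        empty = np.array([], dtype=np.int64)
        return empty, empty, np.array([])
    starts = np.arange(0, n, step, dtype=np.int64)
    ends = np.minimum(starts + window, n)
    cs = np.concatenate([[0], np.cumsum(depth, dtype=np.float64)])
    means = (cs[ends] - cs[starts]) / (ends - starts)
    return starts, ends, means


@dataclass
class Peak:
    gene: str
    chrom: str
    strand: str
    start: int  # genomic, 0-based half-open
    end: int
    max_depth: float  # max per-base depth inside the peak
    max_window_depth: float
    median_window_depth: float
    perm_p: float = float("nan")
    ip_abundance: float = float("nan")  # reads in peak per million mapped
    input_abundance: float = float("nan")
    fold_enrichment: float = float("nan")
    passed_filters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("peak start must precede end")


def _window_runs(
    means: np.ndarray,
    start_factor: float,
    run_len: int,
    median_floor: float,
    background_depth: float,
    end_fraction: float,
) -> list[tuple[int, int]]:
    """Scan the window-depth sequence; returns (first, last) window-index
    pairs (inclusive) of assembled peaks."""
    m = len(means)
    spans: list[tuple[int, int]] = []
    thr = start_factor * background_depth
    i = 0
    while i + run_len <= m:
        run = means[i : i + run_len]
        if (run >= thr).all() or float(np.median(run)) > median_floor:
            s = i
            peak_max = 0.0
            low = 0
            j = i
            closed = False
            while j < m:
                d = means[j]
                if peak_max > 0.0 and d < end_fraction * peak_max:
                    low += 1
                else:
                    low = 0
                peak_max = max(peak_max, float(d))
                if low == run_len:
                    spans.append((s, j - run_len))
                    i = j + 1
                    closed = True
                    break
                j += 1
            if not closed:
                spans.append((s, max(s, m - 1 - low)))
                i = m
        else:
            i += 1
    # merge peaks separated by less than one window
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] <= 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def assemble_peaks(
    track: CoverageTrack,
    background_depth: float | None = None,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    start_factor: float = START_FACTOR,
    run_len: int = RUN_LEN,
    median_floor: float = MEDIAN_FLOOR,
    end_fraction: float = END_FRACTION,
) -> list[Peak]:
    """Assemble candidate peaks on one gene's coverage track."""
    if background_depth is None:
        background_depth = track.mean_depth()
    if background_depth <= 0:
        return []
    w_start, w_end, means = window_depths(track.depth, window, step)
    spans = _window_runs(
        means, start_factor, run_len, median_floor, background_depth, end_fraction
    )
    peaks = []
    for s, e in spans:
        lo = int(w_start[s])
        hi = int(w_end[e])
        peaks.append(
            Peak(
                gene=track.gene,
                chrom=track.chrom,
                strand=track.strand,
                start=track.start + lo,
                end=track.start + hi,
                max_depth=float(track.depth[lo:hi].max()),
                max_window_depth=float(means[s : e + 1].max()),
                median_window_depth=float(np.median(means[s : e + 1])),
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def shuffled_max_window_depths(
    track: CoverageTrack,
    n_shuffles: int = N_SHUFFLES,
    rng: np.random.Generator | None = None,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
) -> np.ndarray:
    """Gene-wide maximum window depth under uniform re-placement of reads.

    Each shuffle re-draws every read's start uniformly within the gene span
    (length preserved); returns one maximum per shuffle.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    L = track.span_length
    lengths = track.read_lengths
    if len(lengths) == 0:
        return np.zeros(n_shuffles)
    if (lengths > L).any():
        raise ValueError(f"gene {track.gene} shorter than a read length")
    n = len(lengths)
    highs = (L - lengths + 1).astype(np.int64)
    starts = rng.integers(0, highs[None, :], size=(n_shuffles, n))
    diff = np.zeros((n_shuffles, L + 1), dtype=np.float64)
    rows = np.repeat(np.arange(n_shuffles), n)
    np.add.at(diff, (rows, starts.ravel()), 1.0)
    np.add.at(diff, (rows, (starts + lengths[None, :]).ravel()), -1.0)
    depth = np.cumsum(diff[:, :L], axis=1)
    w_start = np.arange(0, L, step, dtype=np.int64)
    w_end = np.minimum(w_start + window, L)
    cs = np.concatenate(
        [np.zeros((n_shuffles, 1)), np.cumsum(depth, axis=1)], axis=1
    )
    means = (cs[:, w_end] - cs[:, w_start]) / (w_end - w_start)[None, :]
    return means.max(axis=1)


def permutation_p(observed_max_window: float, null_maxima: np.ndarray) -> float:
    """Add-one empirical p: (1 + #{null >= observed}) / (1 + n_shuffles)."""
    return float(
        (1 + int((null_maxima >= observed_max_window).sum())) / (1 + len(null_maxima))
    )


def permutation_test(
    peak: Peak,
    track: CoverageTrack,
    n_shuffles: int = N_SHUFFLES,
    seed: int = 0,
    null_maxima: np.ndarray | None = None,
) -> float:
    """Permutation p-value for one peak against its gene's shuffle null."""
    if null_maxima is None:
        rng = np.random.default_rng([seed, zlib.crc32(track.gene.encode())])
        null_maxima = shuffled_max_window_depths(track, n_shuffles, rng)
    return permutation_p(peak.max_window_depth, null_maxima)


# ---------------------------------------------------------------------------
# Enrichment filter
# ---------------------------------------------------------------------------


class _ReadIndex:
    """Per-(chrom, strand) sorted read midpoints for in-peak counting.

    A read is in a peak when its alignment midpoint falls inside the
    interval; unlike overlap counting this keeps the expected count
    proportional to the interval width, so narrow peaks are not biased
    toward the (wider) effective overlap window.
    """

    def __init__(self, reads: Iterable[AlignedRead]):
        mids: dict[tuple[str, str], list[float]] = {}
        self.total = 0
        for r in reads:
            self.total += 1
            s, e = r.span
            mids.setdefault((r.chrom, r.strand), []).append((s + e) / 2.0)
        self.mids: dict[tuple[str, str], np.ndarray] = {
            key: np.sort(np.asarray(v)) for key, v in mids.items()
        }

    def count_in(self, chrom: str, strand: str, start: int, end: int) -> int:
        key = (chrom, strand)
        if key not in self.mids:
            return 0
        arr = self.mids[key]
        return int(
            np.searchsorted(arr, end, side="left")
            - np.searchsorted(arr, start, side="left")
        )


def filter_peaks(
    candidates: Sequence[Peak],
    ip_reads: Iterable[AlignedRead],
    input_reads: Iterable[AlignedRead] | None,
    p_threshold: float = P_THRESHOLD,
    min_max_depth: float = MIN_MAX_DEPTH,
    fold: float = FOLD,
    pseudo: float = INPUT_PSEUDO,
) -> list[Peak]:
    """Keep candidates that are significant or tall, then input-enriched.

    Stage 1: perm_p < ``p_threshold`` OR max per-base depth >= ``min_max_depth``.
    Stage 2: IP reads-per-million in the peak interval must exceed ``fold``
    times the input reads-per-million (with ``pseudo`` reads added to the
    input count before normalising).
    """
    if input_reads is None:
        raise ValueError("input alignments are required for the enrichment filter")
    ip_index = _ReadIndex(ip_reads)
    input_index = _ReadIndex(input_reads)
    if ip_index.total == 0 or input_index.total == 0:
        raise ValueError("empty IP or input library")
    final: list[Peak] = []
    for pk in candidates:
        stage1 = (pk.perm_p < p_threshold) or (pk.max_depth >= min_max_depth)
        ip_n = ip_index.count_in(pk.chrom, pk.strand, pk.start, pk.end)
        in_n = input_index.count_in(pk.chrom, pk.strand, pk.start, pk.end)
        pk.ip_abundance = ip_n / ip_index.total * 1e6
        pk.input_abundance = (in_n + pseudo) / input_index.total * 1e6
        pk.fold_enrichment = pk.ip_abundance / pk.input_abundance
        stage2 = pk.fold_enrichment > fold
        pk.passed_filters = {"significant_or_tall": stage1, "input_fold": stage2}
        if stage1 and stage2:
            final.append(pk)
    return final


# ---------------------------------------------------------------------------
# Gene-level driver
# ---------------------------------------------------------------------------


def assign_reads_to_genes(
    reads: Iterable[AlignedRead], annotation: GenomeAnnotation, stranded: bool = True
) -> dict[str, list[AlignedRead]]:
    """Assign each read to every gene whose span it overlaps (strand-aware)."""
    by_gene: dict[str, list[AlignedRead]] = {g.gene_id: [] for g in annotation}
    for r in reads:
        s, e = r.span
        strand = r.strand if stranded else None
        for gid in annotation.genes_with_span_overlap(r.chrom, strand, s, e):
            by_gene[gid].append(r)
    return by_gene


def call_peaks(
    ip_reads: Sequence[AlignedRead],
    input_reads: Sequence[AlignedRead],
    annotation: GenomeAnnotation,
    n_shuffles: int = N_SHUFFLES,
    seed: int = 0,
    p_threshold: float = P_THRESHOLD,
    min_max_depth: float = MIN_MAX_DEPTH,
    fold: float = FOLD,
    pseudo: float = INPUT_PSEUDO,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    start_factor: float = START_FACTOR,
    run_len: int = RUN_LEN,
    median_floor: float = MEDIAN_FLOOR,
    end_fraction: float = END_FRACTION,
) -> tuple[list[Peak], list[Peak]]:
    """Full per-gene peak calling; returns (final peaks, all candidates).

    One shuffle null is computed per gene (seeded stably by gene id, so
    results do not depend on gene order) and shared by all of the gene's
    candidates.
    """
    by_gene = assign_reads_to_genes(ip_reads, annotation)
    candidates: list[Peak] = []
    for gene in annotation:
        reads = by_gene[gene.gene_id]
        if not reads:
            continue
        track = CoverageTrack.from_reads(gene, reads)
        cands = assemble_peaks(
            track,
            window=window,
            step=step,
            start_factor=start_factor,
            run_len=run_len,
            median_floor=median_floor,
            end_fraction=end_fraction,
        )
        if not cands:
            continue
        rng = np.random.default_rng([seed, zlib.crc32(gene.gene_id.encode())])
        null = shuffled_max_window_depths(track, n_shuffles, rng, window, step)
        for pk in cands:
            pk.perm_p = permutation_p(pk.max_window_depth, null)
        candidates.extend(cands)
    final = filter_peaks(
        candidates,
        ip_reads,
        input_reads,
        p_threshold=p_threshold,
        min_max_depth=min_max_depth,
        fold=fold,
        pseudo=pseudo,
    )
    return final, candidates


def peaks_to_genes(peaks: Sequence[Peak]) -> tuple[set[str], pd.Series]:
    """De-duplicated target gene set and per-gene peak counts."""
    genes = [p.gene for p in peaks]
    counts = pd.Series(genes, dtype=object).value_counts().sort_index()
    return set(genes), counts


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    rows = [
        {
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "gene": p.gene,
            "strand": p.strand,
            "max_depth": p.max_depth,
            "max_window_depth": p.max_window_depth,
            "median_window_depth": p.median_window_depth,
            "perm_p": p.perm_p,
            "ip_abundance": p.ip_abundance,
            "input_abundance": p.input_abundance,
            "fold_enrichment": p.fold_enrichment,
        }
        for p in peaks
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "gene", "strand", "max_depth",
            "max_window_depth", "median_window_depth", "perm_p",
            "ip_abundance", "input_abundance", "fold_enrichment",
        ],
    )


def write_peaks_bed(peaks: Sequence[Peak], path: str) -> None:
    """BED6+ output: name = gene, score = int(-10 log10 perm_p), three extra
    columns (max_depth, fold_enrichment, perm_p)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = int(round(-10 * np.log10(p.perm_p))) if p.perm_p > 0 else 999
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.gene}\t{score}\t{p.strand}"
                f"\t{p.max_depth:.6g}\t{p.fold_enrichment:.6g}\t{p.perm_p:.6g}\n"
            )
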