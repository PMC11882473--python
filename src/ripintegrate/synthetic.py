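"""Synthetic genome, read and count generator with known planted truths.

Every downstream stage is tested against outputs of this module: it plants
log2 fold-changes into NB gene counts (3-vs-3 replicate design by default),
inclusion-ratio shifts into junction counts, and enriched intervals into
IP read placements, and records each truth so recovery can be scored from
(outputs, truth) alone.

Design notes
------------
* One synthetic chromosome ("chrS"); genes are placed left to right with
  >= ``spacer_bp`` between spans, so counting is unambiguous while the
  counter still supports overlapping genes.
* A configurable fraction of genes carries an alternative transcript
  structure drawn from ten templates, one per alternative-splicing event
  class, cycled in order with deterministic strands — with
  ``alt_structure_frac=1`` and at least ten genes every class is realised
  at least once; remaining genes get random strands.
* RIP-seq IP reads are a uniform background of ``reads_per_gene_ip`` reads
  per gene plus, in peak genes, additional reads confined to the planted
  interval, sized so the expected library-normalised IP/input abundance
  contrast of the interval equals ``peak_enrichment`` (the within-gene
  rate ratio is close to the same value for peaks much shorter than the
  gene).  Input reads are uniform over every gene body.  Placement is over
  the gene span (not exon-restricted), matching the permutation null's
  support.
* All randomness flows from ``SimConfig.seed`` through numpy's PCG64;
  a fixed seed reproduces outputs byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AlignedRead, Gene, GenomeAnnotation, Transcript
from .preprocess import CountMatrix

CHROM = "chrS"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (2000, 3000)
    exons_per_gene_range: tuple[int, int] = (4, 8)
    n_replicates_per_group: int = 3
    lib_size_mean: int = 1_000_000
    nb_dispersion: float = 0.1
    frac_de: float = 0.1
    de_log2fc: float = 1.0
    frac_as_shifted: float = 0.1
    as_delta_ratio: float = 0.3
    peak_fraction: float = 0.25
    peak_enrichment: float = 4.0
    peak_enrichment_range: tuple[float, float] | None = None
    peak_width_bp: int = 100
    reads_per_gene_ip: int = 50
    reads_per_gene_input: int = 500
    alt_structure_frac: float = 0.5
    junction_depth: int = 200
    read_length_bp: int = 30
    spacer_bp: int = 500

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_as_shifted", "peak_fraction", "alt_structure_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("gene_length_range", "exons_per_gene_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"{name} must be an ordered positive range")
        if not 0.0 < self.as_delta_ratio < 1.0:
            raise ValueError("as_delta_ratio must lie in (0, 1)")
        if self.peak_enrichment <= 0 or self.nb_dispersion <= 0:
            raise ValueError("rates must be positive")
        if self.peak_width_bp >= self.gene_length_range[0]:
            raise ValueError("peak_width_bp must be smaller than the shortest gene")

    @property
    def sample_names(self) -> tuple[list[str], list[str]]:
        n = self.n_replicates_per_group
        return (
            [f"control_{i + 1}" for i in range(n)],
            [f"knockdown_{i + 1}" for i in range(n)],
        )


@dataclass
class SyntheticTruth:
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2FC
    as_events: dict[str, tuple[float, float]] = field(default_factory=dict)
    peaks: dict[str, tuple[int, int, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Annotation templates
# ---------------------------------------------------------------------------
# Fractional exon layouts on a plus-strand backbone of unit length.  Each
# entry: (event type on '+', list of transcripts as lists of (lo, hi)
# fractions).  The classifier mirrors A5SS/A3SS and 5p/3pMXE on '-'.

_TEMPLATES: list[tuple[str, list[list[tuple[float, float]]]]] = [
    ("ES", [[(0.0, 0.2), (0.3, 0.4), (0.5, 0.7)], [(0.0, 0.2), (0.5, 0.7)]]),
    (
        "cassetteExon",
        [
            [(0.0, 0.2), (0.3, 0.4), (0.5, 0.6), (0.7, 0.9)],
            [(0.0, 0.2), (0.7, 0.9)],
        ],
    ),
    ("A5SS", [[(0.0, 0.2), (0.4, 0.6)], [(0.0, 0.26), (0.4, 0.6)]]),
    ("A3SS", [[(0.0, 0.2), (0.4, 0.6)], [(0.0, 0.2), (0.34, 0.6)]]),
    (
        "MXE",
        [
            [(0.0, 0.2), (0.3, 0.4), (0.7, 0.9)],
            [(0.0, 0.2), (0.5, 0.6), (0.7, 0.9)],
        ],
    ),
    (
        "5pMXE",
        [[(0.0, 0.15), (0.5, 0.7)], [(0.25, 0.4), (0.5, 0.7)]],
    ),
    (
        "3pMXE",
        [[(0.0, 0.2), (0.3, 0.45)], [(0.0, 0.2), (0.55, 0.7)]],
    ),
    (
        "A5SS&ES",
        [
            [(0.0, 0.2), (0.3, 0.4), (0.5, 0.7)],
            [(0.0, 0.24), (0.5, 0.7)],
        ],
    ),
    (
        "A3SS&ES",
        [
            [(0.0, 0.2), (0.3, 0.4), (0.5, 0.7)],
            [(0.0, 0.2), (0.44, 0.7)],
        ],
    ),
    ("IntronR", [[(0.0, 0.2), (0.3, 0.5)], [(0.0, 0.5)]]),
]

_MIRROR = {"A5SS": "A3SS", "A3SS": "A5SS", "5pMXE": "3pMXE", "3pMXE": "5pMXE",
           "A5SS&ES": "A3SS&ES", "A3SS&ES": "A5SS&ES"}


def template_event_type(template_index: int, strand: str) -> str:
    etype = _TEMPLATES[template_index % len(_TEMPLATES)][0]
    if strand == "-":
        etype = _MIRROR.get(etype, etype)
    return etype


def _scale(frac: float, length: int) -> int:
    return int(round(frac * length))


def _template_gene(
    gene_id: str, symbol: str, start: int, length: int, strand: str, t_idx: int
) -> Gene:
    _etype, layouts = _TEMPLATES[t_idx % len(_TEMPLATES)]
    txs = []
    for k, layout in enumerate(layouts):
        exons = tuple(
            (start + _scale(lo, length), start + _scale(hi, length)) for lo, hi in layout
        )
        txs.append(Transcript(f"{gene_id}.t{k + 1}", exons))
    return Gene(gene_id, symbol, CHROM, strand, tuple(txs))


def _plain_gene(
    gene_id: str,
    symbol: str,
    start: int,
    length: int,
    strand: str,
    n_exons: int,
    rng: np.random.Generator,
) -> Gene:
    """Single-transcript gene: n_exons exons separated by introns, cut from
    the span with minimum exon 30 bp / intron 60 bp."""
    n_seg = 2 * n_exons - 1
    mins = np.array([30 if i % 2 == 0 else 60 for i in range(n_seg)])
    slack = length - mins.sum()
    if slack < 0:
        n_exons = max(1, (length // 90))
        return _plain_gene(gene_id, symbol, start, length, strand, n_exons, rng)
    w = rng.random(n_seg)
    extra = np.floor(w / w.sum() * slack).astype(int)
    seg = mins + extra
    seg[-1] += length - seg.sum()
    bounds = start + np.concatenate([[0], np.cumsum(seg)])
    exons = tuple(
        (int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)
    )
    return Gene(gene_id, symbol, CHROM, strand, (Transcript(f"{gene_id}.t1", exons),))


def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Non-overlapping genes on one synthetic chromosome; a configurable
    fraction carries an alternative transcript structure from the ten
    event templates (cycled)."""
    rng = np.random.default_rng([config.seed, 1])
    genes: list[Gene] = []
    cursor = 1000
    n_alt = int(round(config.alt_structure_frac * config.n_genes))
    t_idx = 0
    for i in range(config.n_genes):
        length = int(
            rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{i:05d}"
        symbol = f"GENE{i:05d}"
        if i < n_alt:
            # deterministic strands: each full pass over the ten templates is
            # on one strand, so 100% alternative structure realises every
            # class on the plus strand alone (mirrors appear on later passes)
            strand = "+" if (t_idx // len(_TEMPLATES)) % 2 == 0 else "-"
            g = _template_gene(gid, symbol, cursor, length, strand, t_idx)
            t_idx += 1
        else:
            n_exons = int(
                rng.integers(
                    config.exons_per_gene_range[0], config.exons_per_gene_range[1] + 1
                )
            )
            g = _plain_gene(gid, symbol, cursor, length, strand, n_exons, rng)
        genes.append(g)
        cursor = g.span[1] + config.spacer_bp + int(rng.integers(0, 200))
    return GenomeAnnotation(genes)


# ---------------------------------------------------------------------------
# NB counts
# ---------------------------------------------------------------------------


def simulate_counts(
    annotation: GenomeAnnotation, config: SimConfig
) -> tuple[CountMatrix, SyntheticTruth]:
    """Two-group NB counts with a planted fraction of DE genes.

    Per-gene base means are log-normal and rescaled so each library's
    expectation is ``lib_size_mean``; variance follows mu + alpha mu^2.
    A ``frac_de`` subset gets its treatment mean shifted by ``de_log2fc``
    with a random sign, recorded in the truth.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    rng = np.random.default_rng([config.seed, 2])
    genes = [g.gene_id for g in annotation]
    G = len(genes)
    base = np.exp(rng.normal(math.log(100.0), 1.0, size=G))
    base *= config.lib_size_mean / base.sum()
    n_de = int(round(config.frac_de * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(G)
    lfc[de_idx] = signs * config.de_log2fc
    ctrl_names, kd_names = config.sample_names
    alpha = config.nb_dispersion
    cols = {}
    for name in ctrl_names:
        cols[name] = _nb_draw(rng, base, alpha)
    trt_mean = base * np.power(2.0, lfc)
    for name in kd_names:
        cols[name] = _nb_draw(rng, trt_mean, alpha)
    counts = pd.DataFrame(cols, index=genes)
    totals = counts.sum(axis=0)
    lengths = pd.Series({g.gene_id: g.exon_union_length() for g in annotation})
    truth = SyntheticTruth(
        de_genes={genes[i]: float(lfc[i]) for i in de_idx}
    )
    return CountMatrix(counts, totals, lengths.reindex(genes)), truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# Junction counts
# ---------------------------------------------------------------------------


def simulate_junctions(
    annotation: GenomeAnnotation, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Per-sample junction and intron-boundary counts with planted
    inclusion-ratio shifts.

    Events realisable from the annotation are enumerated with the splicing
    classifier; each event draws a per-sample total depth of
    ``junction_depth`` and splits it binomially between inclusion and
    exclusion evidence at the group's inclusion ratio.  Junctions not tied
    to an event get constant background counts.  Returns (junction table,
    boundary-count table, truth).
    """
    from .splicing import annotation_junction_table, detect_events

    rng = np.random.default_rng([config.seed, 3])
    ctrl, kd = config.sample_names
    samples = ctrl + kd
    ann_juncs = annotation_junction_table(annotation, samples=[])
    events = detect_events(annotation, ann_juncs)

    jcounts: dict[tuple[str, str, int, int], np.ndarray] = {}
    bcounts: dict[tuple[str, str, int, int], np.ndarray] = {}
    for r in ann_juncs.itertuples():
        jcounts[(r.chrom, r.strand, int(r.start), int(r.end))] = np.full(
            len(samples), float(config.junction_depth)
        )

    n_shift = int(round(config.frac_as_shifted * len(events)))
    shifted = set(rng.choice(len(events), size=n_shift, replace=False).tolist())
    truth = SyntheticTruth()
    depth = config.junction_depth
    for i, ev in enumerate(events):
        p1 = float(rng.uniform(0.2, 0.8))
        if i in shifted:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            p2 = p1 + sign * config.as_delta_ratio
            if not 0.02 <= p2 <= 0.98:
                p2 = p1 - sign * config.as_delta_ratio
        else:
            p2 = p1
        truth.as_events[ev.event_id] = (p1, p2)
        inc_tot = np.array(
            [rng.binomial(depth, p1) for _ in ctrl]
            + [rng.binomial(depth, p2) for _ in kd],
            dtype=float,
        )
        exc_tot = depth - inc_tot
        if ev.type == "IntronR":
            # retained (inclusion) evidence is boundary-spanning reads,
            # spliced (exclusion) evidence is the junction count
            jk = ev.exclusion_junctions[0]
            bcounts[jk] = inc_tot
            jcounts[jk] = exc_tot
        else:
            inc_split = _multinomial_rows(rng, inc_tot, len(ev.inclusion_junctions))
            exc_split = _multinomial_rows(rng, exc_tot, len(ev.exclusion_junctions))
            for k, jk in enumerate(ev.inclusion_junctions):
                jcounts[jk] = inc_split[k]
            for k, jk in enumerate(ev.exclusion_junctions):
                jcounts[jk] = exc_split[k]

    rows = []
    for (chrom, strand, start, end), vec in sorted(jcounts.items()):
        rows.append(
            {"chrom": chrom, "strand": strand, "start": start, "end": end,
             **{s: vec[j] for j, s in enumerate(samples)}}
        )
    junctions = pd.DataFrame(rows, columns=["chrom", "strand", "start", "end", *samples])
    brows = []
    for (chrom, strand, start, end), vec in sorted(bcounts.items()):
        brows.append(
            {"chrom": chrom, "strand": strand, "start": start, "end": end,
             **{s: vec[j] for j, s in enumerate(samples)}}
        )
    boundaries = pd.DataFrame(brows, columns=["chrom", "strand", "start", "end", *samples])
    return junctions, boundaries, truth


def _multinomial_rows(
    rng: np.random.Generator, totals: np.ndarray, k: int
) -> np.ndarray:
    """Split each total uniformly over k cells; returns (k, n_samples)."""
    if k == 1:
        return totals[None, :]
    out = np.zeros((k, len(totals)))
    for j, t in enumerate(totals):
        out[:, j] = rng.multinomial(int(t), np.full(k, 1.0 / k))
    return out


# ---------------------------------------------------------------------------
# RIP read placement
# ---------------------------------------------------------------------------


def simulate_rip_reads(
    annotation: GenomeAnnotation, config: SimConfig
) -> tuple[list[AlignedRead], list[AlignedRead], SyntheticTruth]:
    """IP and input read placements with planted enriched intervals.

    Input reads are uniform over each gene body.  IP reads are a uniform
    background of ``reads_per_gene_ip`` per gene; each peak gene
    additionally receives reads confined to its planted interval.  The
    planted enrichment is calibrated as the expected library-normalised
    IP/input abundance contrast of the interval: with gene length L, peak
    width w, background budget n and IP library total T over G genes, the
    extra read count is E = (w/L) * (f * T/G - n), where T solves the
    self-consistency over all planted genes in closed form.  The implied
    within-gene rate ratio inside/outside is close to f whenever w << L.
    Per-gene enrichments are drawn uniformly from
    ``peak_enrichment_range`` when set, else fixed at ``peak_enrichment``.
    """
    rng = np.random.default_rng([config.seed, 4])
    rl = config.read_length_bp
    truth = SyntheticTruth()
    ip: list[AlignedRead] = []
    inp: list[AlignedRead] = []
    G = len(annotation)
    n_peak = int(round(config.peak_fraction * G))
    peak_gene_idx = set(rng.choice(G, size=n_peak, replace=False).tolist())
    # pass 1: draw planted intervals and enrichments
    w = config.peak_width_bp
    n = config.reads_per_gene_ip
    planted: dict[int, tuple[int, int, float, int]] = {}
    for gi, gene in enumerate(annotation):
        gs, ge = gene.span
        L = ge - gs
        if w > L:
            raise ValueError(f"peak wider than gene {gene.gene_id}")
        if rl > L:
            raise ValueError(f"gene {gene.gene_id} shorter than the read length")
        if gi in peak_gene_idx:
            pstart = int(gs + rng.integers(0, L - w + 1))
            if config.peak_enrichment_range is not None:
                f = float(rng.uniform(*config.peak_enrichment_range))
            else:
                f = config.peak_enrichment
            planted[gi] = (pstart, pstart + w, f, L)
    # closed-form IP library total under the planted extras
    sum_wl = sum(w / L for (_, _, _, L) in planted.values())
    sum_wlf = sum(w / L * f for (_, _, f, L) in planted.values())
    T = n * (G - sum_wl) / (1.0 - sum_wlf / G)
    for gi, gene in enumerate(annotation):
        gs, ge = gene.span
        starts = rng.integers(gs, ge - rl + 1, size=n)
        if gi in planted:
            pstart, pend, f, L = planted[gi]
            truth.peaks[gene.gene_id] = (pstart, pend, f)
            n_extra = max(0, int(round((w / L) * (f * T / G - n))))
            hi = max(pstart + 1, pend - rl + 1)
            extra = rng.integers(pstart, hi, size=n_extra)
            starts = np.concatenate([starts, extra])
        for k, s in enumerate(starts):
            e = min(int(s) + rl, ge)
            ip.append(
                AlignedRead(
                    read_id=f"{gene.gene_id}_ip_{k}",
                    chrom=gene.chrom,
                    strand=gene.strand,
                    blocks=((int(s), e),),
                    unique=True,
                    sample_id="IP",
                )
            )
        in_starts = rng.integers(gs, ge - rl + 1, size=config.reads_per_gene_input)
        for k, s in enumerate(in_starts):
            inp.append(
                AlignedRead(
                    read_id=f"{gene.gene_id}_in_{k}",
                    chrom=gene.chrom,
                    strand=gene.strand,
                    blocks=((int(s), int(s) + rl),),
                    unique=True,
                    sample_id="Input",
                )
            )
    return ip, inp, truth


# ---------------------------------------------------------------------------
# RNA-seq alignments consistent with a count matrix
# ---------------------------------------------------------------------------


def simulate_rna_alignments(
    annotation: GenomeAnnotation, cm: CountMatrix, config: SimConfig
) -> list[AlignedRead]:
    """Place ``counts[g, s]`` single-fragment reads on each gene's exon
    union (spliced across junctions), so re-counting recovers the matrix."""
    rng = np.random.default_rng([config.seed, 5])
    rl = config.read_length_bp
    reads: list[AlignedRead] = []
    for gene in annotation:
        union = gene.exon_union()
        ulen = sum(e - s for s, e in union)
        eff_rl = min(rl, ulen)
        offsets = np.concatenate([[0], np.cumsum([e - s for s, e in union])])
        for sample in cm.samples:
            n = int(cm.counts.loc[gene.gene_id, sample])
            if n == 0:
                continue
            pos = rng.integers(0, ulen - eff_rl + 1, size=n)
            for k, p in enumerate(pos):
                blocks = _union_blocks(union, offsets, int(p), eff_rl)
                reads.append(
                    AlignedRead(
                        read_id=f"{gene.gene_id}_{sample}_{k}",
                        chrom=gene.chrom,
                        strand=gene.strand,
                        blocks=blocks,
                        unique=True,
                        sample_id=sample,
                    )
                )
    return reads


def _union_blocks(
    union: list[tuple[int, int]], offsets: np.ndarray, pos: int, length: int
) -> tuple[tuple[int, int], ...]:
    """Map [pos, pos+length) in exon-union coordinates to genomic blocks."""
    blocks = []
    remaining = length
    for (s, e), off in zip(union, offsets[:-1]):
        if remaining <= 0:
            break
        exon_len = e - s
        if pos >= off + exon_len:
            continue
        local = max(0, pos - off)
        take = min(exon_len - local, remaining)
        blocks.append((s + local, s + local + take))
        remaining -= take
        pos += take
    return tuple(blocks)


# ---------------------------------------------------------------------------
# Raw reads (FASTQ fixtures for the QC filter)
# ---------------------------------------------------------------------------

QC_FIXTURE_SPECS: tuple[tuple[int, int], ...] = (
    (150, 0), (150, 3), (15, 0), (150, 2), (150, 0),
)


def simulate_raw_reads(
    specs: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
    max_n: int = 2,
    min_len: int = 16,
) -> tuple[list[SeqRecord], list[bool]]:
    """FASTQ records from (length, n_count) specs plus truth keep-labels.

    With ``specs=None`` the canonical five-read fixture is produced (three
    of which survive the default QC rules).  Qualities are constant Q40;
    base composition is random ACGT with the requested number of N bases
    at random positions.
    """
    if specs is None:
        specs = QC_FIXTURE_SPECS
    rng = np.random.default_rng([seed, 6])
    records: list[SeqRecord] = []
    labels: list[bool] = []
    for i, (length, n_count) in enumerate(specs):
        if n_count > length:
            raise ValueError("more N bases than read length")
        bases = rng.choice(list("ACGT"), size=length)
        if n_count:
            pos = rng.choice(length, size=n_count, replace=False)
            bases[pos] = "N"
        rec = SeqRecord(
            Seq("".join(bases)),
            id=f"read{i}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [40] * length
        records.append(rec)
        labels.append(n_count <= max_n and length >= min_len)
    return records, labels
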