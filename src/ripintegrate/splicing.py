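"""Junction-based alternative-splicing event detection, quantification and
cross-condition testing.

Events are classified purely from splice-junction geometry against the
annotated exon model of each gene.  A junction is the reference interval
(left, right) spanned by the intron implied by a gapped alignment: ``left``
is the end of the upstream-in-reference exon, ``right`` the start of the
downstream one.  On the plus strand ``left`` is the donor (5') side; on the
minus strand the roles are mirrored, which is what makes A5SS/A3SS and
5pMXE/3pMXE naming strand-aware.

The ten event classes:

* ES — one exclusion junction skips exactly one annotated exon whose
  flanking inclusion junctions are observed or annotated.
* cassetteExon — the multi-exon variant of ES (>= 2 skipped exonic loci).
* A5SS / A3SS — two junctions share one boundary and their alternative
  boundaries are ends of overlapping annotated exon variants.
* MXE — two disjoint internal exons joined to common flanks by four
  junctions and never co-spliced.
* 5pMXE / 3pMXE — mutually exclusive first / last exons: two junctions
  share the boundary of a common exon while their alternative boundaries
  belong to disjoint transcript-terminal exons.
* A5SS&ES / A3SS&ES — composite: the exclusion junction both skips an
  annotated exon and uses an alternative splice site on the flanking exon.
* IntronR — an annotated junction whose intron is fully contained in an
  annotated exon (a retention isoform); retention evidence comes from reads
  spanning the two exon–intron boundaries.

Composite and multi-junction classes take precedence over their component
classes so the ten strata stay disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AlignedRead, Gene, GenomeAnnotation, Interval
from .expression import DesignSpec

EVENT_TYPES = (
    "ES",
    "A5SS",
    "A3SS",
    "MXE",
    "5pMXE",
    "3pMXE",
    "cassetteExon",
    "IntronR",
    "A3SS&ES",
    "A5SS&ES",
)

JunctionKey = tuple[str, str, int, int]  # chrom, strand, left, right


# ---------------------------------------------------------------------------
# Junction extraction
# ---------------------------------------------------------------------------


def extract_junctions(
    alignments: Iterable[AlignedRead], samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tally splice junctions from gapped unique alignments.

    Returns a DataFrame with columns chrom, strand, start, end plus one count
    column per sample; every gap between consecutive blocks of a uniquely
    mapped read contributes one count.
    """
    counts: dict[JunctionKey, dict[str, int]] = {}
    seen_samples: list[str] = []
    for read in alignments:
        sid = read.sample_id or "sample"
        if sid not in seen_samples:
            seen_samples.append(sid)
        if not read.unique:
            continue
        for left, right in read.junctions():
            key = (read.chrom, read.strand, left, right)
            per = counts.setdefault(key, {})
            per[sid] = per.get(sid, 0) + 1
    cols = list(samples) if samples is not None else seen_samples
    rows = []
    for (chrom, strand, left, right), per in sorted(counts.items()):
        row = {"chrom": chrom, "strand": strand, "start": left, "end": right}
        for c in cols:
            row[c] = per.get(c, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "strand", "start", "end", *cols])


def extract_boundary_counts(
    alignments: Iterable[AlignedRead],
    junctions: pd.DataFrame,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reads continuously spanning the two exon–intron boundaries of each junction.

    For junction (left, right) a read block spanning position ``left`` (its
    block satisfies start < left < end) supports retention of the left
    boundary, and likewise for ``right``; the per-sample evidence is the mean
    of the two boundary counts.
    """
    keys = [
        (r.chrom, r.strand, int(r.start), int(r.end)) for r in junctions.itertuples()
    ]
    left_counts: dict[JunctionKey, dict[str, int]] = {k: {} for k in keys}
    right_counts: dict[JunctionKey, dict[str, int]] = {k: {} for k in keys}
    by_pos: dict[tuple[str, str], list[tuple[int, JunctionKey, str]]] = {}
    for k in keys:
        chrom, strand, left, right = k
        by_pos.setdefault((chrom, strand), []).append((left, k, "L"))
        by_pos.setdefault((chrom, strand), []).append((right, k, "R"))
    seen_samples: list[str] = []
    for read in alignments:
        sid = read.sample_id or "sample"
        if sid not in seen_samples:
            seen_samples.append(sid)
        if not read.unique:
            continue
        positions = by_pos.get((read.chrom, read.strand), [])
        for bs, be in read.blocks:
            for pos, key, side in positions:
                if bs < pos < be:
                    target = left_counts if side == "L" else right_counts
                    per = target[key]
                    per[sid] = per.get(sid, 0) + 1
    cols = list(samples) if samples is not None else seen_samples
    rows = []
    for k in keys:
        chrom, strand, left, right = k
        row = {"chrom": chrom, "strand": strand, "start": left, "end": right}
        for c in cols:
            row[c] = (left_counts[k].get(c, 0) + right_counts[k].get(c, 0)) / 2.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "strand", "start", "end", *cols])


def junction_sample_columns(junctions: pd.DataFrame) -> list[str]:
    return [c for c in junctions.columns if c not in ("chrom", "strand", "start", "end")]


def annotation_junction_table(
    annotation: GenomeAnnotation, samples: Sequence[str] = ("annotated",)
) -> pd.DataFrame:
    """All annotated junctions with unit counts — useful to exercise the
    classifier on an annotation alone."""
    rows = []
    for g in annotation:
        for left, right in sorted(g.annotated_junctions()):
            row = {"chrom": g.chrom, "strand": g.strand, "start": left, "end": right}
            for c in samples:
                row[c] = 1
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["chrom", "strand", "start", "end", *samples]
    ).drop_duplicates(subset=["chrom", "strand", "start", "end"])


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene: str
    type: str
    inclusion_junctions: tuple[JunctionKey, ...]
    exclusion_junctions: tuple[JunctionKey, ...]
    alt_region: Interval
    novelty: str  # 'known' | 'novel'

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type}")
        if set(self.inclusion_junctions) & set(self.exclusion_junctions):
            raise ValueError("inclusion and exclusion junction sets overlap")


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


class _GeneModel:
    """Per-gene lookups used by the classifier."""

    def __init__(self, gene: Gene):
        self.gene = gene
        self.exons = gene.all_exons()
        self.ann_juncs = gene.annotated_junctions()
        plus = gene.strand == "+"
        self.first_exons = {
            (t.exons[0] if plus else t.exons[-1]) for t in gene.transcripts
        }
        self.last_exons = {
            (t.exons[-1] if plus else t.exons[0]) for t in gene.transcripts
        }
        self.by_end: dict[int, list[Interval]] = {}
        self.by_start: dict[int, list[Interval]] = {}
        for ex in self.exons:
            self.by_start.setdefault(ex[0], []).append(ex)
            self.by_end.setdefault(ex[1], []).append(ex)

    def loci_inside(self, left: int, right: int) -> list[Interval]:
        """Merged exonic loci strictly inside the open interval (left, right)."""
        inside = [e for e in self.exons if e[0] > left and e[1] < right]
        loci: list[list[int]] = []
        for s, e in sorted(inside):
            if loci and s < loci[-1][1]:
                loci[-1][1] = max(loci[-1][1], e)
            else:
                loci.append([s, e])
        return [(s, e) for s, e in loci]


def _assign_junctions(
    annotation: GenomeAnnotation, junctions: pd.DataFrame
) -> tuple[dict[str, set[Interval]], int]:
    """Map observed junctions to genes by span containment and strand.

    Returns (gene -> set of (left, right)), count of unassignable junctions.
    """
    per_gene: dict[str, set[Interval]] = {g.gene_id: set() for g in annotation}
    dropped = 0
    for r in junctions.itertuples():
        left, right = int(r.start), int(r.end)
        hits = annotation.genes_with_span_overlap(r.chrom, r.strand, left, right)
        hits = {
            gid
            for gid in hits
            if annotation.gene(gid).span[0] <= left and right <= annotation.gene(gid).span[1]
        }
        if not hits:
            dropped += 1
            continue
        for gid in hits:
            per_gene[gid].add((left, right))
    return per_gene, dropped


def detect_events(
    annotation: GenomeAnnotation, junctions: pd.DataFrame
) -> list[SpliceEvent]:
    """Classify alternative-splicing events per gene from junction geometry."""
    per_gene, _dropped = _assign_junctions(annotation, junctions)
    events: list[SpliceEvent] = []
    for g in annotation:
        events.extend(_detect_gene_events(g, per_gene.get(g.gene_id, set())))
    return events


def _detect_gene_events(gene: Gene, observed: set[Interval]) -> list[SpliceEvent]:
    model = _GeneModel(gene)
    all_juncs = set(observed) | model.ann_juncs
    if not all_juncs:
        return []
    plus = gene.strand == "+"
    consumed: set[Interval] = set()
    events: list[SpliceEvent] = []

    def key(j: Interval) -> JunctionKey:
        return (gene.chrom, gene.strand, j[0], j[1])

    def emit(
        etype: str,
        inc: Sequence[Interval],
        exc: Sequence[Interval],
        alt: Interval,
    ) -> None:
        used = list(inc) + list(exc)
        novelty = "novel" if any(j not in model.ann_juncs for j in used) else "known"
        eid = f"{gene.gene_id}|{etype}|{alt[0]}-{alt[1]}"
        events.append(
            SpliceEvent(
                event_id=eid,
                gene=gene.gene_id,
                type=etype,
                inclusion_junctions=tuple(key(j) for j in inc),
                exclusion_junctions=tuple(key(j) for j in exc),
                alt_region=alt,
                novelty=novelty,
            )
        )

    # --- 1. skip-family: ES / cassetteExon / composite alt-site + skip -----
    for junc in sorted(all_juncs):
        left, right = junc
        loci = model.loci_inside(left, right)
        if not loci:
            continue
        first, last = loci[0], loci[-1]
        left_inc = (left, first[0])
        right_inc = (last[1], right)
        left_match = left_inc in all_juncs
        right_match = right_inc in all_juncs
        internal = [
            (loci[i][1], loci[i + 1][0])
            for i in range(len(loci) - 1)
            if (loci[i][1], loci[i + 1][0]) in all_juncs
        ]
        if left_match and right_match:
            etype = "ES" if len(loci) == 1 else "cassetteExon"
            emit(etype, [left_inc, *internal, right_inc], [junc], (first[0], last[1]))
            consumed.add(junc)
            continue
        if right_match:
            # alternative splice site on the left flank whose long form skips
            alt_left = [
                j
                for j in all_juncs
                if j[1] == first[0]
                and j[0] != left
                and any(
                    _overlap(ea, eb)
                    for ea in model.by_end.get(left, [])
                    for eb in model.by_end.get(j[0], [])
                )
            ]
            if alt_left:
                j2 = min(alt_left)
                etype = "A5SS&ES" if plus else "A3SS&ES"
                emit(etype, [j2, *internal, right_inc], [junc],
                     (min(left, j2[0]), max(left, j2[0])))
                consumed.add(junc)
                continue
        if left_match:
            alt_right = [
                j
                for j in all_juncs
                if j[0] == last[1]
                and j[1] != right
                and any(
                    _overlap(ea, eb)
                    for ea in model.by_start.get(right, [])
                    for eb in model.by_start.get(j[1], [])
                )
            ]
            if alt_right:
                j2 = min(alt_right)
                etype = "A3SS&ES" if plus else "A5SS&ES"
                emit(etype, [left_inc, *internal, j2], [junc],
                     (min(right, j2[1]), max(right, j2[1])))
                consumed.add(junc)

    # --- 2. MXE: two disjoint internal exons, four junctions, never joined -
    cotranscribed = {
        frozenset((e1, e2))
        for t in gene.transcripts
        for e1 in t.exons
        for e2 in t.exons
        if e1 != e2
    }
    internal_exons = [
        e for e in model.exons
        if e not in model.first_exons and e not in model.last_exons
    ]
    for i, e1 in enumerate(internal_exons):
        for e2 in internal_exons[i + 1:]:
            if e1[1] > e2[0]:  # overlapping: not mutually exclusive partners
                continue
            if frozenset((e1, e2)) in cotranscribed:
                continue
            if (e1[1], e2[0]) in all_juncs:
                continue  # observed co-splicing
            ups = [
                u for u in all_juncs
                if u[1] == e1[0] and (u[0], e2[0]) in all_juncs and u[0] < e1[0]
            ]
            downs = [
                d for d in all_juncs
                if d[0] == e1[1] and (e2[1], d[1]) in all_juncs and d[1] > e2[1]
            ]
            quads = [
                (u, (u[0], e2[0]), d, (e2[1], d[1]))
                for u in ups
                for d in downs
                if d[1] > e2[1] and u[0] < e1[0]
            ]
            for u1, u2, d1, d2 in quads:
                if {u1, u2, d1, d2} & consumed:
                    continue
                emit("MXE", [u1, d1], [u2, d2], (e1[0], e2[1]))
                consumed.update((u1, u2, d1, d2))
                break

    # --- 3. shared-boundary pairs: A5SS/A3SS and terminal-exon MXE variants
    def classify_pair(shared_right: bool, j1: Interval, j2: Interval) -> None:
        # j1 has the more distal alternative boundary (longer intron)
        if shared_right:
            b1, b2 = j1[0], j2[0]
            exons1 = model.by_end.get(b1, [])
            exons2 = model.by_end.get(b2, [])
        else:
            b1, b2 = j2[1], j1[1]  # note: j1 = (l, r2) with r2 > r1
            exons1 = model.by_start.get(j1[1], [])
            exons2 = model.by_start.get(j2[1], [])
        alt = (min(j1[0], j2[0]), max(j1[0], j2[0])) if shared_right else (
            min(j1[1], j2[1]), max(j1[1], j2[1])
        )
        overlapping = any(_overlap(a, b) for a in exons1 for b in exons2)
        known_both = bool(exons1) and bool(exons2)
        if overlapping or (bool(exons1) ^ bool(exons2)):
            if shared_right:
                etype = "A5SS" if plus else "A3SS"
                inc, exc = (j1, j2) if j1[0] > j2[0] else (j2, j1)
            else:
                etype = "A3SS" if plus else "A5SS"
                inc, exc = (j1, j2) if j1[1] < j2[1] else (j2, j1)
            emit(etype, [inc], [exc], alt)
            consumed.update((j1, j2))
            return
        if known_both:
            terminal_first = all(
                any(e in model.first_exons for e in exs) for exs in (exons1, exons2)
            )
            terminal_last = all(
                any(e in model.last_exons for e in exs) for exs in (exons1, exons2)
            )
            if terminal_first or terminal_last:
                etype = "5pMXE" if terminal_first else "3pMXE"
                if shared_right:
                    inc, exc = (j1, j2) if j1[0] > j2[0] else (j2, j1)
                else:
                    inc, exc = (j1, j2) if j1[1] < j2[1] else (j2, j1)
                emit(etype, [inc], [exc], alt)
                consumed.update((j1, j2))

    remaining = sorted(all_juncs - consumed)
    by_right: dict[int, list[Interval]] = {}
    by_left: dict[int, list[Interval]] = {}
    for j in remaining:
        by_left.setdefault(j[0], []).append(j)
        by_right.setdefault(j[1], []).append(j)
    for r, group in sorted(by_right.items()):
        group = sorted(group)
        for a, b in zip(group, group[1:]):
            if a in consumed or b in consumed:
                continue
            # no skipped exon strictly between the alternative boundaries
            if model.loci_inside(a[0], b[0]):
                continue
            classify_pair(True, a, b)
    for l, group in sorted(by_left.items()):
        group = sorted(group, key=lambda j: j[1])
        for a, b in zip(group, group[1:]):
            if a in consumed or b in consumed:
                continue
            if model.loci_inside(a[1], b[1]):
                continue
            classify_pair(False, b, a)

    # --- 4. IntronR: annotated junction whose intron sits inside an exon ---
    for junc in sorted(model.ann_juncs - consumed):
        left, right = junc
        retained = any(e[0] <= left and right <= e[1] for e in model.exons)
        if retained:
            emit("IntronR", [], [junc], (left, right))
            consumed.add(junc)

    return events


def events_to_frame(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": ev.event_id,
            "gene": ev.gene,
            "type": ev.type,
            "alt_start": ev.alt_region[0],
            "alt_end": ev.alt_region[1],
            "novelty": ev.novelty,
            "inclusion_junctions": ";".join(
                f"{j[2]}-{j[3]}" for j in ev.inclusion_junctions
            ),
            "exclusion_junctions": ";".join(
                f"{j[2]}-{j[3]}" for j in ev.exclusion_junctions
            ),
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "gene", "type", "alt_start", "alt_end", "novelty",
            "inclusion_junctions", "exclusion_junctions",
        ],
    )


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


def quantify_events(
    events: Sequence[SpliceEvent],
    junctions: pd.DataFrame,
    boundary_counts: pd.DataFrame | None = None,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Per-event, per-sample inclusion ratio inc / (inc + exc).

    For junction-defined events ``inc``/``exc`` sum the counts of the
    inclusion/exclusion junction sets.  For IntronR the retained (inclusion)
    evidence is the boundary-spanning read count and the spliced (exclusion)
    evidence the junction count, so the ratio is the retention fraction.
    Samples with inc + exc < ``min_cov`` are flagged undefined (NaN ratio).
    """
    samples = junction_sample_columns(junctions)
    jmap: dict[JunctionKey, np.ndarray] = {}
    for r in junctions.itertuples():
        k = (r.chrom, r.strand, int(r.start), int(r.end))
        jmap[k] = np.array([getattr(r, c) for c in samples], dtype=float)
    bmap: dict[JunctionKey, np.ndarray] = {}
    if boundary_counts is not None:
        bcols = junction_sample_columns(boundary_counts)
        for r in boundary_counts.itertuples():
            k = (r.chrom, r.strand, int(r.start), int(r.end))
            bmap[k] = np.array([getattr(r, c) for c in bcols], dtype=float)

    zero = np.zeros(len(samples))
    rows = []
    for ev in events:
        if ev.type == "IntronR":
            jk = ev.exclusion_junctions[0]
            inc = bmap.get(jk, zero).copy()
            exc = jmap.get(jk, zero).copy()
        else:
            inc = sum((jmap.get(k, zero) for k in ev.inclusion_junctions), zero.copy())
            exc = sum((jmap.get(k, zero) for k in ev.exclusion_junctions), zero.copy())
        tot = inc + exc
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(tot > 0, inc / np.where(tot > 0, tot, 1.0), np.nan)
        ratio = np.where(tot >= min_cov, ratio, np.nan)
        for i, s in enumerate(samples):
            rows.append(
                {
                    "event_id": ev.event_id,
                    "gene": ev.gene,
                    "type": ev.type,
                    "sample": s,
                    "inclusion": inc[i],
                    "exclusion": exc[i],
                    "ratio": ratio[i],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene", "type", "sample", "inclusion", "exclusion", "ratio"],
    )


# ---------------------------------------------------------------------------
# Cross-condition testing
# ---------------------------------------------------------------------------


def test_rase(
    quants: pd.DataFrame,
    design: DesignSpec,
    fdr_threshold: float = 0.05,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Student's t-test (equal variance, two-sided) on per-sample inclusion
    ratios, with BH-FDR across tested events.

    Events with fewer than ``min_samples`` defined ratios in either group are
    reported untested (tested = False, NaN p).  Zero within-group variance in
    both groups gives p = 1 for equal means and p = 0 (degenerate) otherwise.
    """
    from .integration import bh_fdr

    ref_samples = set(design.samples_of(design.reference))
    trt_samples = set(design.samples_of(design.treatment))
    rows = []
    for eid, sub in quants.groupby("event_id", sort=True):
        by_sample = dict(zip(sub["sample"], sub["ratio"]))
        a = np.array([v for s, v in by_sample.items() if s in ref_samples])
        b = np.array([v for s, v in by_sample.items() if s in trt_samples])
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        row = {
            "event_id": eid,
            "gene": sub["gene"].iloc[0],
            "type": sub["type"].iloc[0],
            "mean_ratio_ref": a.mean() if a.size else np.nan,
            "mean_ratio_trt": b.mean() if b.size else np.nan,
            "degenerate": False,
        }
        row["delta_ratio"] = row["mean_ratio_trt"] - row["mean_ratio_ref"]
        if a.size < min_samples or b.size < min_samples:
            row.update(tested=False, p=np.nan)
        else:
            va, vb = a.var(ddof=1), b.var(ddof=1)
            scale = max(np.abs(a).max(), np.abs(b).max(), 1.0)
            tiny = (1e-12 * scale) ** 2
            if va <= tiny and vb <= tiny:
                if abs(a.mean() - b.mean()) <= 1e-12 * scale:
                    p = 1.0
                else:
                    p = 0.0
                    row["degenerate"] = True
            else:
                with warnings.catch_warnings():
                    # near-identical ratio vectors trip scipy's precision-loss
                    # warning; the degenerate cases are handled above
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            row.update(tested=True, p=p)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    tested = out["tested"].to_numpy(dtype=bool)
    if tested.any():
        out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["significant"] = tested & (out["fdr"].to_numpy() <= fdr_threshold)
    return out
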