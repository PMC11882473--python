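import numpy as np
import pandas as pd
import pytest

from ripintegrate.annotation import GenomeAnnotation
from ripintegrate.expression import DesignSpec
from ripintegrate.splicing import (
    EVENT_TYPES,
    annotation_junction_table,
    detect_events,
    extract_boundary_counts,
    extract_junctions,
    quantify_events,
)
from ripintegrate.splicing import test_rase as rase_test
from ripintegrate.synthetic import SimConfig, simulate_annotation, template_event_type

from conftest import make_gene, make_read

DESIGN = DesignSpec(
    {"c1": "ctrl", "c2": "ctrl", "c3": "ctrl", "k1": "kd", "k2": "kd", "k3": "kd"},
    "ctrl",
)


def _jt(gene, juncs, count=50, samples=("s1",)):
    rows = []
    for left, right in juncs:
        row = {"chrom": gene.chrom, "strand": gene.strand, "start": left, "end": right}
        for s in samples:
            row[s] = count
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Junction extraction
# ---------------------------------------------------------------------------


def test_gap_between_blocks_is_one_junction():
    jt = extract_junctions([make_read("r", [(100, 150), (200, 250)])])
    assert len(jt) == 1
    assert (jt.iloc[0]["start"], jt.iloc[0]["end"]) == (150, 200)
    assert jt.iloc[0]["s1"] == 1


def test_three_block_read_yields_two_junctions():
    jt = extract_junctions([make_read("r", [(0, 10), (20, 30), (50, 60)])])
    assert list(zip(jt["start"], jt["end"])) == [(10, 20), (30, 50)]


def test_single_block_and_multimapped_contribute_nothing():
    jt = extract_junctions(
        [make_read("r1", [(0, 30)]),
         make_read("r2", [(0, 10), (20, 30)], unique=False)]
    )
    assert jt.empty or jt[[c for c in jt.columns if c == "s1"]].to_numpy().sum() == 0


def test_extraction_matches_per_read_enumeration(rng):
    reads = []
    for i in range(300):
        s = int(rng.integers(0, 5000))
        n_blocks = int(rng.integers(1, 4))
        blocks, p = [], s
        for _ in range(n_blocks):
            w = int(rng.integers(10, 40))
            blocks.append((p, p + w))
            p += w + int(rng.integers(20, 100))
        reads.append(make_read(f"r{i}", blocks, sample=f"s{int(rng.integers(1, 3))}"))
    jt = extract_junctions(reads)
    brute = {}
    for r in reads:
        for j in r.junctions():
            key = (r.chrom, r.strand, *j)
            brute.setdefault(key, {}).setdefault(r.sample_id, 0)
            brute[key][r.sample_id] += 1
    assert len(jt) == len(brute)
    for row in jt.itertuples():
        key = (row.chrom, row.strand, row.start, row.end)
        for s in ("s1", "s2"):
            assert getattr(row, s) == brute[key].get(s, 0)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------


def test_exon_skip_detected_from_junction_trio():
    gene = make_gene("g", [[(0, 200), (300, 400), (500, 700)]])
    ann = GenomeAnnotation([gene])
    events = detect_events(ann, _jt(gene, [(200, 300), (400, 500), (200, 500)]))
    assert [e.type for e in events] == ["ES"]
    ev = events[0]
    assert ev.alt_region == (300, 400)
    assert set(ev.exclusion_junctions) == {("chr1", "+", 200, 500)}
    assert ev.novelty == "novel"  # the skip junction is not annotated


def test_a5ss_from_shared_acceptor():
    gene = make_gene("g", [[(0, 130), (300, 500)], [(0, 150), (300, 500)]])
    ann = GenomeAnnotation([gene])
    events = detect_events(ann, _jt(gene, [(150, 300), (130, 300)]))
    assert [e.type for e in events] == ["A5SS"]
    assert events[0].alt_region == (130, 150)


def test_a5ss_on_minus_strand_is_a3ss():
    gene = make_gene("g", [[(0, 130), (300, 500)], [(0, 150), (300, 500)]], strand="-")
    ann = GenomeAnnotation([gene])
    events = detect_events(ann, _jt(gene, [(150, 300), (130, 300)]))
    assert [e.type for e in events] == ["A3SS"]


def test_no_events_without_alternatives():
    gene = make_gene("g", [[(0, 200), (300, 500)]])
    ann = GenomeAnnotation([gene])
    assert detect_events(ann, _jt(gene, [(200, 300)])) == []


def test_all_ten_types_realised_and_classified():
    cfg = SimConfig(seed=1, n_genes=10, alt_structure_frac=1.0)
    ann = simulate_annotation(cfg)
    events = detect_events(ann, annotation_junction_table(ann))
    assert {e.type for e in events} == set(EVENT_TYPES)
    # the classifier recovers exactly the planted template class per gene
    for i, gene in enumerate(ann):
        planted = template_event_type(i, gene.strand)
        got = [e.type for e in events if e.gene == gene.gene_id]
        assert got == [planted]


def test_detection_order_independent(rng):
    cfg = SimConfig(seed=4, n_genes=20, alt_structure_frac=1.0)
    ann = simulate_annotation(cfg)
    jt = annotation_junction_table(ann)
    shuffled = jt.sample(frac=1.0, random_state=9).reset_index(drop=True)
    ids = lambda evs: sorted((e.event_id, e.type) for e in evs)
    assert ids(detect_events(ann, jt)) == ids(detect_events(ann, shuffled))


def test_event_strata_are_disjoint():
    cfg = SimConfig(seed=2, n_genes=30, alt_structure_frac=1.0)
    ann = simulate_annotation(cfg)
    events = detect_events(ann, annotation_junction_table(ann))
    assert len({e.event_id for e in events}) == len(events)
    per_gene = {}
    for e in events:
        per_gene.setdefault(e.gene, []).append(e)
    assert all(len(v) == 1 for v in per_gene.values())


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


def _one_event(inc_count, exc_count, min_cov=10):
    gene = make_gene("g", [[(0, 200), (300, 400), (500, 700)]])
    ann = GenomeAnnotation([gene])
    jt = pd.DataFrame(
        [
            {"chrom": "chr1", "strand": "+", "start": 200, "end": 300, "s1": inc_count},
            {"chrom": "chr1", "strand": "+", "start": 400, "end": 500, "s1": inc_count},
            {"chrom": "chr1", "strand": "+", "start": 200, "end": 500, "s1": exc_count},
        ]
    )
    events = detect_events(ann, jt)
    return quantify_events(events, jt, min_cov=min_cov)


def test_ratio_half_and_one():
    q = _one_event(5, 10)  # inc = 5+5 = 10, exc = 10
    assert q.iloc[0]["ratio"] == pytest.approx(0.5)
    q2 = _one_event(10, 0)
    assert q2.iloc[0]["ratio"] == pytest.approx(1.0)


def test_low_coverage_flagged_undefined():
    q = _one_event(2, 3)  # inc + exc = 7 < 10
    assert np.isnan(q.iloc[0]["ratio"])


def test_intron_retention_uses_boundary_evidence():
    gene = make_gene("g", [[(0, 200), (300, 500)], [(0, 500)]])
    ann = GenomeAnnotation([gene])
    jt = _jt(gene, [(200, 300)], count=30)
    # reads spanning both intron boundaries
    reads = [make_read(f"b{i}", [(180, 320)]) for i in range(10)]
    bt = extract_boundary_counts(reads, jt)
    events = detect_events(ann, jt)
    assert [e.type for e in events] == ["IntronR"]
    q = quantify_events(events, jt, bt)
    # retention ratio = boundary / (boundary + junction) = 10 / 40
    assert q.iloc[0]["ratio"] == pytest.approx(10 / 40)


# ---------------------------------------------------------------------------
# Ratio testing
# ---------------------------------------------------------------------------


def _quants(ratios_a, ratios_b):
    rows = []
    for s, r in zip(["c1", "c2", "c3"], ratios_a):
        rows.append({"event_id": "e1", "gene": "g", "type": "ES", "sample": s,
                     "inclusion": 50, "exclusion": 50, "ratio": r})
    for s, r in zip(["k1", "k2", "k3"], ratios_b):
        rows.append({"event_id": "e1", "gene": "g", "type": "ES", "sample": s,
                     "inclusion": 50, "exclusion": 50, "ratio": r})
    return pd.DataFrame(rows)


def test_identical_ratios_give_p_one():
    r = rase_test(_quants([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]), DESIGN)
    assert r.iloc[0]["p"] == 1.0
    assert not r.iloc[0]["significant"]


def test_strong_separation_matches_textbook_t():
    a, b = [0.80, 0.82, 0.78], [0.50, 0.52, 0.48]
    r = rase_test(_quants(a, b), DESIGN)
    # closed-form equal-variance t
    from scipy import stats

    na, nb = 3, 3
    sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
    t = (np.mean(b) - np.mean(a)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p_ref = 2 * stats.t.sf(abs(t), 4)
    assert r.iloc[0]["p"] == pytest.approx(p_ref)
    assert r.iloc[0]["p"] < 0.001
    assert r.iloc[0]["delta_ratio"] == pytest.approx(-0.3)


def test_group_swap_flips_delta_and_preserves_p():
    q = _quants([0.7, 0.75, 0.72], [0.5, 0.55, 0.52])
    r1 = rase_test(q, DESIGN)
    flipped = DesignSpec(dict(DESIGN.groups), "kd")
    r2 = rase_test(q, flipped)
    assert r1.iloc[0]["p"] == pytest.approx(r2.iloc[0]["p"])
    assert r1.iloc[0]["delta_ratio"] == pytest.approx(-r2.iloc[0]["delta_ratio"])


def test_degenerate_constant_but_different_groups():
    r = rase_test(_quants([0.5, 0.5, 0.5], [0.8, 0.8, 0.8]), DESIGN)
    assert r.iloc[0]["p"] == 0.0
    assert r.iloc[0]["degenerate"]


def test_insufficient_coverage_reported_untested():
    q = _quants([0.5, np.nan, np.nan], [0.6, 0.61, 0.59])
    r = rase_test(q, DESIGN)
    assert not r.iloc[0]["tested"]
    assert np.isnan(r.iloc[0]["p"])
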