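import io

import numpy as np
import pytest
from scipy import stats

from ripintegrate.annotation import write_bed12, write_gtf
from ripintegrate.peakcalling import CoverageTrack, assign_reads_to_genes
from ripintegrate.synthetic import (
    SimConfig,
    simulate_annotation,
    simulate_counts,
    simulate_junctions,
    simulate_raw_reads,
    simulate_rip_reads,
    simulate_rna_alignments,
)


def _gtf_text(ann, tmp_path, name):
    path = tmp_path / name
    write_gtf(ann, path)
    return path.read_text()


# ---------------------------------------------------------------------------
# Config validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kw",
    [
        {"frac_de": 1.5},
        {"gene_length_range": (500, 100)},
        {"as_delta_ratio": 0.0},
        {"nb_dispersion": -1.0},
        {"peak_width_bp": 5000},
    ],
)
def test_invalid_config_rejected(kw):
    with pytest.raises(ValueError):
        SimConfig(**kw)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def test_fixed_seed_reproduces_gtf_byte_identically(tmp_path):
    cfg = SimConfig(seed=1, n_genes=10)
    t1 = _gtf_text(simulate_annotation(cfg), tmp_path, "a.gtf")
    t2 = _gtf_text(simulate_annotation(cfg), tmp_path, "b.gtf")
    assert t1 == t2
    t3 = _gtf_text(simulate_annotation(SimConfig(seed=2, n_genes=10)), tmp_path, "c.gtf")
    assert t1 != t3


def test_genes_do_not_overlap_and_are_spaced():
    cfg = SimConfig(seed=5, n_genes=40)
    ann = simulate_annotation(cfg)
    spans = sorted(g.span for g in ann)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 - e1 >= cfg.spacer_bp


def test_single_exon_genes_have_no_junctions():
    cfg = SimConfig(seed=1, n_genes=8, alt_structure_frac=0.0,
                    exons_per_gene_range=(1, 1))
    ann = simulate_annotation(cfg)
    assert all(not g.annotated_junctions() for g in ann)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def test_counts_reproducible_and_truth_consistent():
    cfg = SimConfig(seed=3, n_genes=50, frac_de=0.2)
    ann = simulate_annotation(cfg)
    cm1, t1 = simulate_counts(ann, cfg)
    cm2, t2 = simulate_counts(ann, cfg)
    assert cm1.counts.equals(cm2.counts)
    assert t1.de_genes == t2.de_genes
    assert len(t1.de_genes) == 10
    assert set(t1.de_genes) <= {g.gene_id for g in ann}


def test_null_nb_means_recovered_within_three_se():
    """Without planted effects the sample means match the NB expectation."""
    cfg = SimConfig(seed=7, n_genes=2000, frac_de=0.0, alt_structure_frac=0.0)
    ann = simulate_annotation(cfg)
    cm, _ = simulate_counts(ann, cfg)
    grand = cm.counts.mean(axis=1)
    g1 = cm.counts.iloc[:, :3].mean(axis=1)
    g2 = cm.counts.iloc[:, 3:].mean(axis=1)
    se = np.sqrt((grand + cfg.nb_dispersion * grand**2) / 3)
    ok = (np.abs(g1 - g2) <= 3 * np.sqrt(2) * se) | (grand < 1)
    assert ok.mean() >= 0.95


def test_tiny_dispersion_approaches_poisson():
    cfg = SimConfig(seed=9, n_genes=300, frac_de=0.0, nb_dispersion=1e-6,
                    alt_structure_frac=0.0, n_replicates_per_group=20)
    ann = simulate_annotation(cfg)
    cm, _ = simulate_counts(ann, cfg)
    mu = cm.counts.mean(axis=1)
    var = cm.counts.var(axis=1, ddof=1)
    deep = mu >= 100
    ratio = (var[deep] / mu[deep])
    assert 0.8 <= ratio.median() <= 1.2


# ---------------------------------------------------------------------------
# Junctions
# ---------------------------------------------------------------------------


def test_null_junctions_have_small_ratio_differences():
    cfg = SimConfig(seed=2, n_genes=100, alt_structure_frac=1.0,
                    frac_as_shifted=0.0, junction_depth=2000)
    ann = simulate_annotation(cfg)
    _, _, truth = simulate_junctions(ann, cfg)
    assert all(a == b for a, b in truth.as_events.values())


def test_planted_shift_recovered_from_counts():
    """Planted 0.3 inclusion-ratio shifts are estimable within +-0.05."""
    from ripintegrate.splicing import detect_events, quantify_events

    cfg = SimConfig(seed=1, n_genes=300, alt_structure_frac=1.0,
                    frac_as_shifted=0.5, as_delta_ratio=0.3, junction_depth=200)
    ann = simulate_annotation(cfg)
    junctions, boundaries, truth = simulate_junctions(ann, cfg)
    events = detect_events(ann, junctions)
    q = quantify_events(events, junctions, boundaries)
    ok = 0
    shifted = {k: v for k, v in truth.as_events.items() if v[0] != v[1]}
    for eid, (p1, p2) in shifted.items():
        sub = q[q["event_id"] == eid]
        est = (
            sub[sub["sample"].str.startswith("knockdown")]["ratio"].mean()
            - sub[sub["sample"].str.startswith("control")]["ratio"].mean()
        )
        if abs(est - (p2 - p1)) <= 0.05:
            ok += 1
    assert ok / len(shifted) >= 0.9


def test_junction_tables_reproducible():
    cfg = SimConfig(seed=4, n_genes=30, alt_structure_frac=1.0)
    ann = simulate_annotation(cfg)
    j1, b1, _ = simulate_junctions(ann, cfg)
    j2, b2, _ = simulate_junctions(ann, cfg)
    assert j1.equals(j2) and b1.equals(b2)


# ---------------------------------------------------------------------------
# RIP reads
# ---------------------------------------------------------------------------


def test_no_peaks_means_ip_indistinguishable_from_input():
    cfg = SimConfig(seed=1, n_genes=20, peak_fraction=0.0,
                    reads_per_gene_ip=500, reads_per_gene_input=500)
    ann = simulate_annotation(cfg)
    ip, inp, truth = simulate_rip_reads(ann, cfg)
    assert truth.peaks == {}
    ip_pos = np.array([r.span[0] for r in ip])[:10000]
    in_pos = np.array([r.span[0] for r in inp])[:10000]
    assert stats.ks_2samp(ip_pos, in_pos).pvalue > 0.01


def test_planted_interval_depth_ratio_matches_enrichment():
    """Planted 8x peaks show a mean inside/outside depth ratio in (6, 10)."""
    cfg = SimConfig(seed=2, n_genes=20, peak_fraction=0.25, peak_enrichment=8.0,
                    gene_length_range=(2400, 2600), reads_per_gene_ip=2000)
    ann = simulate_annotation(cfg)
    ip, _, truth = simulate_rip_reads(ann, cfg)
    by_gene = assign_reads_to_genes(ip, ann)
    ratios = []
    for gid, (ps, pe, _f) in truth.peaks.items():
        gene = ann.gene(gid)
        track = CoverageTrack.from_reads(gene, by_gene[gid])
        gs = gene.span[0]
        inside = track.depth[ps - gs : pe - gs].mean()
        mask = np.ones(track.span_length, bool)
        mask[ps - gs : pe - gs] = False
        ratios.append(inside / track.depth[mask].mean())
    assert 6 < np.mean(ratios) < 10


def test_rip_reads_reproducible_as_bed12(tmp_path):
    cfg = SimConfig(seed=6, n_genes=10)
    ann = simulate_annotation(cfg)
    for name in ("x.bed", "y.bed"):
        ip, _, _ = simulate_rip_reads(ann, cfg)
        write_bed12(ip, tmp_path / name)
    assert (tmp_path / "x.bed").read_bytes() == (tmp_path / "y.bed").read_bytes()


def test_peak_wider_than_gene_is_config_error():
    cfg = SimConfig(seed=1, n_genes=5, gene_length_range=(150, 200),
                    peak_width_bp=100)
    ann = simulate_annotation(cfg)
    # shrink genes below the peak width via a direct invalid config
    with pytest.raises(ValueError):
        SimConfig(seed=1, gene_length_range=(80, 90), peak_width_bp=100)


# ---------------------------------------------------------------------------
# RNA alignments consistent with counts
# ---------------------------------------------------------------------------


def test_rna_alignments_recount_to_planted_matrix():
    from ripintegrate.preprocess import count_genes

    cfg = SimConfig(seed=8, n_genes=15, lib_size_mean=3000, alt_structure_frac=0.4)
    ann = simulate_annotation(cfg)
    cm, _ = simulate_counts(ann, cfg)
    reads = simulate_rna_alignments(ann, cm, cfg)
    recount, report = count_genes(reads, ann, samples=cm.samples)
    assert report.ambiguous == 0
    assert recount.counts.equals(cm.counts)


# ---------------------------------------------------------------------------
# Raw reads
# ---------------------------------------------------------------------------


def test_raw_read_fixture_and_labels():
    records, labels = simulate_raw_reads()
    assert [len(r.seq) for r in records] == [150, 150, 15, 150, 150]
    assert [str(r.seq).count("N") for r in records] == [0, 3, 0, 2, 0]
    assert labels == [True, False, False, True, True]


def test_empty_spec_gives_valid_empty_fastq(tmp_path):
    from Bio import SeqIO

    records, labels = simulate_raw_reads([])
    assert records == [] and labels == []
    path = tmp_path / "empty.fastq"
    SeqIO.write(records, path, "fastq")
    assert list(SeqIO.parse(path, "fastq")) == []
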