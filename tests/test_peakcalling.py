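import numpy as np
import pytest

from ripintegrate.benchmarks import random_track, reference_assemble_spans
from ripintegrate.peakcalling import (
    CoverageTrack,
    Peak,
    assemble_peaks,
    filter_peaks,
    peaks_to_genes,
    permutation_p,
    permutation_test,
    shuffled_max_window_depths,
    window_depths,
)

from conftest import make_read


def _track(depth, gene="g1", reads=None):
    depth = np.asarray(depth, dtype=float)
    return CoverageTrack(
        gene=gene, chrom="chr1", strand="+", start=0, end=len(depth),
        depth=depth,
        read_lengths=np.asarray(reads if reads is not None else [30]),
    )


# ---------------------------------------------------------------------------
# Window depths
# ---------------------------------------------------------------------------


def test_constant_depth_gives_constant_windows():
    _, _, means = window_depths(np.full(50, 3.0))
    assert np.allclose(means, 3.0)
    assert len(means) == 10


def test_window_means_hand_case():
    depth = np.array([1, 1, 1, 1, 1, 9, 9, 9, 9, 9], dtype=float)
    _, _, means = window_depths(depth)
    assert list(means) == [1.0, 9.0]


def test_trailing_partial_window_keeps_width():
    depth = np.concatenate([np.zeros(10), np.full(3, 6.0)])
    starts, ends, means = window_depths(depth)
    assert len(means) == int(np.ceil(13 / 5))
    assert ends[-1] - starts[-1] == 3
    assert means[-1] == pytest.approx(6.0)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def test_flat_track_yields_no_candidates():
    assert assemble_peaks(_track(np.full(1000, 2.0))) == []


def test_plateau_recovered_with_bounded_extension():
    depth = np.full(1000, 2.0)
    depth[400:600] = 60.0
    peaks = assemble_peaks(_track(depth), background_depth=2.0)
    assert len(peaks) == 1
    pk = peaks[0]
    assert pk.start <= 400 and pk.end >= 600
    assert pk.start >= 400 - 8 * 5 and pk.end <= 600 + 8 * 5
    assert pk.max_depth == 60.0


def test_seven_window_run_is_not_enough():
    depth = np.full(500, 2.0)
    depth[100:135] = 30.0  # 7 full windows of elevation
    assert assemble_peaks(_track(depth), background_depth=2.0) == []
    depth[100:140] = 30.0  # 8 windows
    assert len(assemble_peaks(_track(depth), background_depth=2.0)) == 1


def test_median_floor_route_opens_peak():
    # depth below 2.5x background but median above the floor
    depth = np.full(500, 30.0)
    depth[100:140] = 60.0
    peaks = assemble_peaks(_track(depth), background_depth=30.0)
    assert peaks  # opened by the median > 50 route


def test_assembly_matches_run_enumeration_reference(rng):
    """Exact interval equality against the exhaustive reference on random
    tracks (the no-shortcut oracle)."""
    n_checked = 0
    for t in range(80):
        depth = random_track(rng)
        bg = float(depth.mean())
        if bg <= 0:
            continue
        track = _track(depth, gene=f"t{t}")
        got = [(p.start, p.end) for p in assemble_peaks(track, background_depth=bg)]
        w_start, w_end, means = window_depths(depth)
        ref = [
            (int(w_start[s]), int(w_end[e]))
            for s, e in reference_assemble_spans(means, bg)
        ]
        assert got == ref
        n_checked += 1
    assert n_checked >= 70


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def test_permutation_p_conventions():
    null = np.arange(500, dtype=float)
    assert permutation_p(1000.0, null) == pytest.approx(1 / 501)
    assert permutation_p(-1.0, null) == pytest.approx(1.0)


def test_permutation_deterministic_for_seed():
    depth = np.zeros(800)
    depth[100:400] += 3
    track = _track(depth, reads=[30] * 40)
    pk = Peak(gene="g1", chrom="chr1", strand="+", start=100, end=400,
              max_depth=3, max_window_depth=3.0, median_window_depth=3.0)
    p1 = permutation_test(pk, track, seed=9)
    p2 = permutation_test(pk, track, seed=9)
    assert p1 == p2
    assert 0 < p1 <= 1


def test_shuffle_errors_when_gene_shorter_than_read():
    track = _track(np.zeros(20), reads=[30])
    with pytest.raises(ValueError, match="shorter"):
        shuffled_max_window_depths(track, 10)


def test_shuffle_preserves_read_mass():
    track = _track(np.zeros(500), reads=[30] * 20)
    null = shuffled_max_window_depths(track, 50, np.random.default_rng(0))
    # max window depth is at least the mean depth, at most the read count
    assert (null >= 20 * 30 / 500).all()
    assert (null <= 20).all()


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def _candidate(**kw):
    base = dict(gene="g1", chrom="chr1", strand="+", start=100, end=200,
                max_depth=5.0, max_window_depth=4.0, median_window_depth=3.0,
                perm_p=0.5)
    base.update(kw)
    return Peak(**base)


def _reads(n, lo, hi, rng, strand="+"):
    return [
        make_read(f"r{i}", [(int(s), int(s) + 30)], strand=strand)
        for i, s in enumerate(rng.integers(lo, hi, size=n))
    ]


def test_or_rule_depth_saves_insignificant_peak(rng):
    ip = _reads(200, 100, 170, rng)
    inp = _reads(200, 0, 2000, rng)
    kept = filter_peaks([_candidate(perm_p=0.2, max_depth=12.0)], ip, inp)
    assert len(kept) == 1
    kept2 = filter_peaks([_candidate(perm_p=0.2, max_depth=5.0)], ip, inp)
    assert kept2 == []


def test_fold_filter_removes_weak_enrichment(rng):
    # IP and input identically distributed: fold ~ 1 < 4
    ip = _reads(300, 0, 2000, rng)
    inp = _reads(300, 0, 2000, rng)
    kept = filter_peaks([_candidate(perm_p=0.001)], ip, inp)
    assert kept == []


def test_zero_input_reads_is_finite_fold(rng):
    ip = _reads(100, 100, 170, rng)
    inp = _reads(100, 1000, 1900, rng)  # none in the peak
    cand = _candidate(perm_p=0.001)
    kept = filter_peaks([cand], ip, inp)
    assert np.isfinite(cand.fold_enrichment)
    assert kept == [cand]


def test_missing_input_is_an_error(rng):
    with pytest.raises(ValueError, match="input"):
        filter_peaks([_candidate()], _reads(10, 0, 100, rng), None)


def test_raising_thresholds_never_adds_peaks(rng):
    cands = [
        _candidate(start=100 * i, end=100 * i + 80, perm_p=float(p), max_depth=d)
        for i, (p, d) in enumerate([(0.001, 20), (0.2, 12), (0.01, 4), (0.5, 3)])
    ]
    ip = _reads(400, 0, 500, rng)
    inp = _reads(400, 0, 2000, rng)
    kept4 = {id(p) for p in filter_peaks(list(cands), ip, inp, fold=4.0)}
    kept8 = {id(p) for p in filter_peaks(list(cands), ip, inp, fold=8.0)}
    assert kept8 <= kept4
    deep = {id(p) for p in filter_peaks(list(cands), ip, inp, min_max_depth=50.0)}
    assert deep <= kept4


# ---------------------------------------------------------------------------
# End-to-end planted recovery
# ---------------------------------------------------------------------------


def test_planted_8x_peaks_recovered():
    """Strong (8x) planted peaks are detected essentially always; the
    input-fold filter then keeps a high-precision majority.  Chained
    background reads widen a minority of calls enough to dilute their
    measured enrichment below the 4x cut, which bounds final recall."""
    from ripintegrate.benchmarks import planted_peak_recovery

    res = planted_peak_recovery(1, n_genes=200, enrichment=8.0)
    assert res["stage1_recall"] >= 0.95
    assert res["recall"] >= 0.6
    assert res["precision"] >= 0.9


# ---------------------------------------------------------------------------
# Target genes
# ---------------------------------------------------------------------------


def test_peaks_to_genes_dedupes_and_counts():
    peaks = [_candidate(start=s, end=s + 50) for s in (0, 100, 200)]
    genes, counts = peaks_to_genes(peaks)
    assert genes == {"g1"}
    assert counts["g1"] == 3


def test_empty_peak_list_gives_empty_set():
    genes, counts = peaks_to_genes([])
    assert genes == set()
    assert counts.empty
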