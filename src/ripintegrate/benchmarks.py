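"""Self-contained evaluation runs: calibration, planted-truth recovery and
oracle-equivalence checks for every pipeline stage.

Each function simulates its own inputs from a seed, runs the pipeline code
under test, and returns plain numbers; nothing is cached or looked up.  The
reference implementations here (run-enumeration peak assembly, tail-summed
hypergeometric) are deliberately naive re-derivations used only to check
the production code paths.
"""

from __future__ import annotations

import dataclasses
import filecmp
import math
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic

from .expression import (
    DesignSpec,
    delta_delta_ct,
    nb_test,
    proliferation_rate,
)
from .integration import hypergeom_overlap
from .peakcalling import (
    END_FRACTION,
    MEDIAN_FLOOR,
    RUN_LEN,
    START_FACTOR,
    CoverageTrack,
    assemble_peaks,
    assign_reads_to_genes,
    call_peaks,
    permutation_p,
    shuffled_max_window_depths,
    window_depths,
)
from .preprocess import CountMatrix, compute_fpkm, filter_raw_reads
from .splicing import detect_events, quantify_events, test_rase
from .synthetic import SimConfig, simulate_annotation


def _design(n: int = 3) -> DesignSpec:
    groups = {f"control_{i + 1}": "control" for i in range(n)}
    groups.update({f"knockdown_{i + 1}": "knockdown" for i in range(n)})
    return DesignSpec(groups, "control")


# ---------------------------------------------------------------------------
# Peak assembly: exhaustive run-enumeration reference
# ---------------------------------------------------------------------------


def reference_assemble_spans(
    means: np.ndarray,
    background: float,
    start_factor: float = START_FACTOR,
    run_len: int = RUN_LEN,
    median_floor: float = MEDIAN_FLOOR,
    end_fraction: float = END_FRACTION,
) -> list[tuple[int, int]]:
    """Window-index peak spans by brute force.

    Every window index is tested for run qualification by explicit slicing;
    the running maximum during extension is recomputed from scratch with a
    slice max at every step (no streaming state).
    """
    m = len(means)

    def qualifies(i: int) -> bool:
        run = means[i : i + run_len]
        if len(run) < run_len:
            return False
        return bool(
            (run >= start_factor * background).all()
            or float(np.median(run)) > median_floor
        )

    def is_low(s: int, k: int) -> bool:
        prev_max = float(means[s:k].max()) if k > s else 0.0
        return prev_max > 0.0 and means[k] < end_fraction * prev_max

    spans: list[tuple[int, int]] = []
    next_free = 0
    for s in range(m):
        if s < next_free or not qualifies(s):
            continue
        closed = False
        for j in range(s, m):
            if j - run_len + 1 > s and all(
                is_low(s, k) for k in range(j - run_len + 1, j + 1)
            ):
                spans.append((s, j - run_len))
                next_free = j + 1
                closed = True
                break
        if not closed:
            c = 0
            while c < m - s and is_low(s, m - 1 - c):
                c += 1
            spans.append((s, max(s, m - 1 - c)))
            next_free = m
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] <= 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def random_track(rng: np.random.Generator, max_len: int = 2000) -> np.ndarray:
    """Random coverage: sparse 30-bp reads plus occasional plateaus."""
    L = int(rng.integers(200, max_len + 1))
    depth = np.zeros(L)
    n_reads = int(rng.integers(5, max(6, L // 20)))
    starts = rng.integers(0, max(1, L - 30), size=n_reads)
    for s in starts:
        depth[s : s + 30] += 1
    for _ in range(int(rng.integers(0, 3))):
        w = int(rng.integers(20, 300))
        s = int(rng.integers(0, max(1, L - w)))
        depth[s : s + w] += float(rng.integers(1, 60))
    return depth


def assembly_oracle_check(seed: int, n_tracks: int = 200, max_len: int = 2000) -> dict:
    """Exact interval-set agreement between the streaming assembler and the
    run-enumeration reference on random tracks."""
    rng = np.random.default_rng([seed, 11])
    n_mismatch = 0
    n_peaks = 0
    for t in range(n_tracks):
        depth = random_track(rng, max_len)
        bg = float(depth.mean())
        if bg <= 0:
            continue
        track = CoverageTrack(
            gene=f"T{t}", chrom="chrS", strand="+", start=0, end=len(depth),
            depth=depth, read_lengths=np.array([30]),
        )
        got = [(p.start, p.end) for p in assemble_peaks(track, background_depth=bg)]
        w_start, w_end, means = window_depths(depth)
        ref_spans = reference_assemble_spans(means, bg)
        ref = [(int(w_start[s]), int(w_end[e])) for s, e in ref_spans]
        n_peaks += len(ref)
        if got != ref:
            n_mismatch += 1
    return {"n_tracks": n_tracks, "n_peaks": n_peaks, "n_mismatch": n_mismatch}


# ---------------------------------------------------------------------------
# Permutation-null calibration
# ---------------------------------------------------------------------------


def permutation_null_calibration(
    seed: int, n_genes: int = 1000, n_shuffles: int = 500
) -> float:
    """Fraction of peak-free genes carrying any candidate with perm p < 0.05."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, peak_fraction=0.0,
                    reads_per_gene_input=50)
    ann = simulate_annotation(cfg)
    ip, _, _ = synthetic.simulate_rip_reads(ann, cfg)
    by_gene = assign_reads_to_genes(ip, ann)
    n_hit = 0
    for gene in ann:
        reads = by_gene[gene.gene_id]
        if not reads:
            continue
        track = CoverageTrack.from_reads(gene, reads)
        cands = assemble_peaks(track)
        if not cands:
            continue
        rng = np.random.default_rng([seed, zlib.crc32(gene.gene_id.encode())])
        null = shuffled_max_window_depths(track, n_shuffles, rng)
        if any(permutation_p(pk.max_window_depth, null) < 0.05 for pk in cands):
            n_hit += 1
    return n_hit / n_genes


# ---------------------------------------------------------------------------
# Planted-peak recovery
# ---------------------------------------------------------------------------


def planted_peak_recovery(
    seed: int,
    n_genes: int = 200,
    enrichment: tuple[float, float] | float = (4.0, 8.0),
    n_shuffles: int = 500,
) -> dict:
    """Recall/precision of final peaks against planted intervals."""
    if isinstance(enrichment, tuple):
        cfg = SimConfig(seed=seed, n_genes=n_genes, peak_fraction=0.25,
                        peak_enrichment_range=enrichment)
    else:
        cfg = SimConfig(seed=seed, n_genes=n_genes, peak_fraction=0.25,
                        peak_enrichment=enrichment)
    ann = simulate_annotation(cfg)
    ip, inp, truth = synthetic.simulate_rip_reads(ann, cfg)
    final, candidates = call_peaks(ip, inp, ann, n_shuffles=n_shuffles, seed=seed)

    def hits(p, iv):
        return p.start < iv[1] and iv[0] < p.end

    recovered = {
        g for g, iv in truth.peaks.items()
        if any(p.gene == g and hits(p, iv) for p in final)
    }
    tp = sum(1 for p in final if p.gene in truth.peaks and hits(p, truth.peaks[p.gene]))
    stage1 = [p for p in candidates if p.perm_p < 0.05 or p.max_depth >= 10]
    detected = {
        g for g, iv in truth.peaks.items()
        if any(p.gene == g and hits(p, iv) for p in stage1)
    }
    return {
        "recall": len(recovered) / max(len(truth.peaks), 1),
        "stage1_recall": len(detected) / max(len(truth.peaks), 1),
        "precision": tp / max(len(final), 1),
        "n_final": len(final),
        "n_planted": len(truth.peaks),
    }


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def deg_calibration(seed: int, n_genes: int = 2000) -> float:
    """Raw p < 0.05 fraction under a 3-vs-3 null NB simulation."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, frac_de=0.0, alt_structure_frac=0.0)
    ann = simulate_annotation(cfg)
    cm, _ = synthetic.simulate_counts(ann, cfg)
    res = nb_test(cm, _design())
    return float((res["p"] < 0.05).mean())


def deg_recovery(seed: int, n_genes: int = 2000, log2fc: float = 1.0) -> float:
    """Median |estimated log2FC| over planted DE genes with base mean >= 100."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, frac_de=0.2, de_log2fc=log2fc,
                    alt_structure_frac=0.0)
    ann = simulate_annotation(cfg)
    cm, truth = synthetic.simulate_counts(ann, cfg)
    res = nb_test(cm, _design())
    de = pd.Series(truth.de_genes)
    deep = de[cm.counts.loc[de.index].mean(axis=1) >= 100]
    est = res.loc[deep.index, "log2FC"].to_numpy() * np.sign(deep.to_numpy())
    return float(np.median(est))


# ---------------------------------------------------------------------------
# Splicing
# ---------------------------------------------------------------------------


def _rase_run(seed: int, n_genes: int, frac_shifted: float, delta: float) -> tuple:
    cfg = SimConfig(seed=seed, n_genes=n_genes, alt_structure_frac=1.0,
                    frac_as_shifted=frac_shifted, as_delta_ratio=delta,
                    junction_depth=200)
    ann = simulate_annotation(cfg)
    junctions, boundaries, truth = synthetic.simulate_junctions(ann, cfg)
    events = detect_events(ann, junctions)
    quants = quantify_events(events, junctions, boundaries)
    rase = test_rase(quants, _design()).set_index("event_id")
    return rase, truth


def splicing_calibration(seed: int, n_events: int = 1000) -> float:
    """Raw p < 0.05 fraction across null (unshifted) events."""
    rase, _ = _rase_run(seed, n_events, 0.0, 0.3)
    return float((rase["p"] < 0.05).mean())


def splicing_recovery(seed: int, n_events: int = 1000, delta: float = 0.3) -> dict:
    """Recall of planted ratio shifts and FPR among nulls at FDR 5%."""
    rase, truth = _rase_run(seed, n_events, 0.1, delta)
    shifted = [k for k, (a, b) in truth.as_events.items() if a != b]
    nulls = [k for k, (a, b) in truth.as_events.items() if a == b]
    return {
        "recall": float(rase.loc[shifted, "significant"].mean()),
        "fpr": float(rase.loc[nulls, "significant"].mean()),
        "n_shifted": len(shifted),
    }


# ---------------------------------------------------------------------------
# Hypergeometric oracle
# ---------------------------------------------------------------------------


def hypergeom_tail_bruteforce(N: int, K: int, n: int, x: int) -> float:
    """Upper tail by explicit summation of the hypergeometric pmf."""
    total = 0.0
    for k in range(x, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k)
    return total / math.comb(N, n)


def hypergeom_oracle_check(seed: int, n_cases: int = 100, max_n: int = 40) -> dict:
    """Max |p - brute force| over random instances plus the fixed cases."""
    rng = np.random.default_rng([seed, 12])
    max_err = 0.0
    for _ in range(n_cases):
        N = int(rng.integers(2, max_n + 1))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        universe = [f"g{i}" for i in range(N)]
        a = list(rng.choice(universe, size=K, replace=False))
        b = list(rng.choice(universe, size=n, replace=False))
        res = hypergeom_overlap(a, b, universe)
        ref = hypergeom_tail_bruteforce(N, K, n, res.overlap)
        max_err = max(max_err, abs(res.p_value - ref))
    uni = [f"g{i}" for i in range(10)]
    extreme = hypergeom_overlap(uni[:5], uni[:5], uni)
    zero = hypergeom_overlap(uni[:5], uni[5:], uni)
    return {
        "max_abs_err": max_err,
        "p_extreme_10_5_5_5": extreme.p_value,  # 1/252
        "p_zero_overlap": zero.p_value,  # exactly 1
    }


# ---------------------------------------------------------------------------
# Formula spot checks
# ---------------------------------------------------------------------------


def formula_checks() -> dict:
    cm = CountMatrix(
        counts=pd.DataFrame({"s1": [10]}, index=["g1"]),
        totals=pd.Series({"s1": 1_000_000}),
        lengths=pd.Series({"g1": 1000}),
    )
    fpkm = float(compute_fpkm(cm).iloc[0, 0])
    records, _ = synthetic.simulate_raw_reads()  # canonical 5-read fixture
    kept, _report = filter_raw_reads(records)
    return {
        "fpkm_plugin": fpkm,
        "ddct_2": delta_delta_ct(20.0, 15.0, 18.0, 15.0),
        "proliferation_pct": proliferation_rate(0.45, 0.80, 0.10),
        "qc_fixture_kept": len(kept),
    }


# ---------------------------------------------------------------------------
# End-to-end determinism
# ---------------------------------------------------------------------------


def determinism_check(seed: int, workdir: str | Path) -> dict:
    """Run the full pipeline twice with one seed; compare output bytes."""
    from .pipeline import run_all, write_fixture

    workdir = Path(workdir)
    cfg = write_fixture(workdir / "fixture", synthetic.SimConfig(
        seed=seed, n_genes=30, gene_length_range=(1500, 2500),
        reads_per_gene_ip=50, reads_per_gene_input=500,
        peak_enrichment=8.0, lib_size_mean=50_000,
    ))
    out_a = dataclasses.replace(cfg, outdir=str(workdir / "run_a"))
    out_b = dataclasses.replace(cfg, outdir=str(workdir / "run_b"))
    manifest = run_all(out_a)
    run_all(out_b)
    files = sorted(p.name for p in (workdir / "run_a").iterdir())
    identical = all(
        filecmp.cmp(workdir / "run_a" / f, workdir / "run_b" / f, shallow=False)
        for f in files
        if f != "manifest.json"  # manifests differ in the outdir path only
    )
    return {
        "identical": identical,
        "n_files": len(files),
        "n_stages": len(manifest["stages"]),
    }
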