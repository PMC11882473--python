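"""End-to-end orchestration: preprocess -> expression -> splicing ->
peak calling -> integration, with a manifest sufficient to replay a run.

Each stage reads files named in :class:`RunConfig` and writes TSV/BED
outputs under ``outdir``; a fixed seed makes every output byte-identical
across reruns.  The global seed fans out to per-stage child seeds derived
by stable hashing of stage names, so adding a stage never perturbs the
randomness of earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import read_bed12, read_gtf, write_bed12, write_gtf
from .expression import DesignSpec, classify_degs, nb_test
from .integration import enrichment_frame, integrate, ora, read_gmt
from .peakcalling import call_peaks, peaks_to_frame, peaks_to_genes, write_peaks_bed
from .preprocess import compute_fpkm, count_genes
from .splicing import detect_events, events_to_frame, quantify_events, test_rase

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    gtf: str
    outdir: str
    design: dict[str, str]  # sample -> group
    reference_group: str
    rna_beds: dict[str, str] = field(default_factory=dict)  # sample -> BED12
    junctions_tsv: str | None = None
    boundaries_tsv: str | None = None
    ip_bed: str | None = None
    input_bed: str | None = None
    gmt: str | None = None
    seed: int = 0
    stranded: bool = True
    deg_fc_up: float = 1.5
    deg_fc_down: float = 0.67
    deg_p: float = 0.05
    deg_use_fdr: bool = False
    rase_fdr: float = 0.05
    rase_min_cov: int = 10
    peak_p: float = 0.05
    peak_min_depth: float = 10.0
    peak_fold: float = 4.0
    shuffles: int = 500

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("deg_p", 0.0, 1.0),
            ("rase_fdr", 0.0, 1.0),
            ("peak_p", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")
        if self.deg_fc_up <= 1 or self.deg_fc_down >= 1:
            raise ValueError("deg_fc_up must exceed 1 and deg_fc_down be below 1")
        if self.shuffles < 1 or self.peak_fold <= 0:
            raise ValueError("shuffles and peak_fold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dict.

    Missing inputs are reported before any computation starts; outputs are
    idempotent for a fixed seed.
    """
    required = [("gtf", config.gtf)]
    required += [(f"rna_bed[{s}]", p) for s, p in config.rna_beds.items()]
    for name in ("junctions_tsv", "boundaries_tsv", "ip_bed", "input_bed", "gmt"):
        p = getattr(config, name)
        if p is not None:
            required.append((name, p))
    for name, p in required:
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input {name}: {p}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
    }

    def record(stage: str, outputs: list[str], **info) -> None:
        manifest["stages"].append({"stage": stage, "outputs": outputs, **info})

    # ---- preprocess ------------------------------------------------------
    stage = "preprocess"
    try:
        annotation = read_gtf(config.gtf)
        reads = []
        for sample, path in sorted(config.rna_beds.items()):
            reads.extend(
                dataclasses.replace(r, sample_id=sample) for r in read_bed12(path)
            )
        cm, count_report = count_genes(
            reads,
            annotation,
            samples=sorted(config.rna_beds) or None,
            stranded=config.stranded,
        )
        cm.to_tsv(out / "counts.tsv")
        fpkm = compute_fpkm(cm)
        fpkm.index.name = "gene"
        fpkm.to_csv(out / "fpkm.tsv", sep="\t", float_format=FLOAT_FMT)
        record(
            stage,
            ["counts.tsv", "fpkm.tsv"],
            assigned=count_report.assigned,
            ambiguous=count_report.ambiguous,
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- expression ------------------------------------------------------
    stage = "expression"
    try:
        design = DesignSpec(config.design, config.reference_group)
        deg = nb_test(cm, design)
        up, down = classify_degs(
            deg,
            fc_up=config.deg_fc_up,
            fc_down=config.deg_fc_down,
            p_threshold=config.deg_p,
            use_fdr=config.deg_use_fdr,
        )
        deg.to_csv(out / "deg.tsv", sep="\t", float_format=FLOAT_FMT)
        record(stage, ["deg.tsv"], n_up=len(up), n_down=len(down))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- splicing --------------------------------------------------------
    stage = "splicing"
    try:
        if config.junctions_tsv:
            junctions = pd.read_csv(config.junctions_tsv, sep="\t")
            boundaries = (
                pd.read_csv(config.boundaries_tsv, sep="\t")
                if config.boundaries_tsv
                else None
            )
            events = detect_events(annotation, junctions)
            quants = quantify_events(
                events, junctions, boundaries, min_cov=config.rase_min_cov
            )
            rase = test_rase(quants, design, fdr_threshold=config.rase_fdr)
        else:
            events, quants = [], pd.DataFrame()
            rase = pd.DataFrame(
                columns=["event_id", "gene", "type", "significant"]
            )
        events_to_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)
        rase.to_csv(out / "rase.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        n_sig = int(rase["significant"].sum()) if len(rase) else 0
        record(stage, ["events.tsv", "rase.tsv"], n_events=len(events), n_significant=n_sig)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- peak calling ----------------------------------------------------
    stage = "peakcalling"
    try:
        if config.ip_bed and config.input_bed:
            ip_reads = read_bed12(config.ip_bed, sample_id="IP")
            input_reads = read_bed12(config.input_bed, sample_id="Input")
            final, candidates = call_peaks(
                ip_reads,
                input_reads,
                annotation,
                n_shuffles=config.shuffles,
                seed=config.stage_seed("peakcalling"),
                p_threshold=config.peak_p,
                min_max_depth=config.peak_min_depth,
                fold=config.peak_fold,
            )
            targets, per_gene = peaks_to_genes(final)
        else:
            final, candidates, targets = [], [], set()
        write_peaks_bed(final, str(out / "peaks.bed"))
        peaks_to_frame(candidates).to_csv(
            out / "peak_candidates.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        with open(out / "peak_targets.txt", "w") as fh:
            for g in sorted(targets):
                fh.write(g + "\n")
        record(
            stage,
            ["peaks.bed", "peak_candidates.tsv", "peak_targets.txt"],
            n_candidates=len(candidates),
            n_final=len(final),
            n_target_genes=len(targets),
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- integration -----------------------------------------------------
    stage = "integration"
    try:
        detected = cm.counts.index[(cm.counts > 0).any(axis=1)]
        symbol_of = {g.gene_id: g.symbol for g in annotation}
        universe = [symbol_of.get(g, g) for g in detected]
        deg_sym = deg.copy()
        deg_sym.index = [symbol_of.get(g, g) for g in deg.index]
        rase_sym = rase.copy()
        if len(rase_sym):
            rase_sym["gene"] = [symbol_of.get(g, g) for g in rase_sym["gene"]]
        target_syms = [symbol_of.get(g, g) for g in targets]
        report = integrate(deg_sym, rase_sym, target_syms, universe)
        summary = {
            "deg_vs_peaks": dataclasses.asdict(report.deg_vs_peaks),
            "rasg_vs_peaks": dataclasses.asdict(report.rasg_vs_peaks),
            "deg_direction_split": report.deg_direction_split,
        }
        with open(out / "integration.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        outputs = ["integration.json"]
        if config.gmt:
            terms = ora(report.deg_genes, read_gmt(config.gmt), universe)
            enrichment_frame(terms).to_csv(
                out / "enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FMT
            )
            outputs.append("enrichment.tsv")
        record(
            stage,
            outputs,
            deg_overlap=report.deg_vs_peaks.overlap,
            rasg_overlap=report.rasg_vs_peaks.overlap,
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Fixture generation (simulate subcommand)
# ---------------------------------------------------------------------------


def write_fixture(outdir: str | Path, config=None) -> RunConfig:
    """Simulate a complete input bundle plus a ready-to-run RunConfig YAML."""
    from .synthetic import SimConfig, simulate_annotation, simulate_counts, \
        simulate_junctions, simulate_rip_reads, simulate_rna_alignments

    if config is None:
        config = SimConfig(n_genes=40, gene_length_range=(1500, 2500),
                           reads_per_gene_ip=150, reads_per_gene_input=600,
                           peak_enrichment=8.0, alt_structure_frac=0.5,
                           lib_size_mean=60_000)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    write_gtf(annotation, out / "annotation.gtf")
    cm, de_truth = simulate_counts(annotation, config)
    rna = simulate_rna_alignments(annotation, cm, config)
    ctrl, kd = config.sample_names
    rna_beds = {}
    for sample in ctrl + kd:
        path = out / f"rna_{sample}.bed12"
        write_bed12([r for r in rna if r.sample_id == sample], path)
        rna_beds[sample] = str(path)
    junctions, boundaries, as_truth = simulate_junctions(annotation, config)
    junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
    boundaries.to_csv(out / "boundaries.tsv", sep="\t", index=False)
    ip, inp, peak_truth = simulate_rip_reads(annotation, config)
    write_bed12(ip, out / "ip.bed12")
    write_bed12(inp, out / "input.bed12")
    truth = {
        "de_genes": de_truth.de_genes,
        "as_events": {k: list(v) for k, v in as_truth.as_events.items()},
        "peaks": {k: list(v) for k, v in peak_truth.peaks.items()},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    run_cfg = RunConfig(
        gtf=str(out / "annotation.gtf"),
        outdir=str(out / "results"),
        design={s: ("control" if s in ctrl else "knockdown") for s in ctrl + kd},
        reference_group="control",
        rna_beds=rna_beds,
        junctions_tsv=str(out / "junctions.tsv"),
        boundaries_tsv=str(out / "boundaries.tsv"),
        ip_bed=str(out / "ip.bed12"),
        input_bed=str(out / "input.bed12"),
        seed=config.seed,
    )
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(run_cfg), fh, sort_keys=True)
    return run_cfg
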