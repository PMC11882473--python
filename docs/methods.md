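# Methods

`ripintegrate` implements an integrative bulk-transcriptomics workflow:
raw-read QC and gene counting, a negative-binomial differential-expression
screen, junction-based alternative-splicing quantification, RIP-seq peak
calling with an empirical within-gene permutation null, and hypergeometric
set-overlap integration of the three result layers. This note records the
models, the parameters that matter, and the choices made where the design
was genuinely open.

## Coordinates and input formats

All in-memory coordinates are 0-based half-open. GTF is read/written
1-based closed; BED12 is 0-based half-open. A BED12 record is one aligned
fragment; its blocks are the aligned segments, so the gap between
consecutive blocks is a splice junction. Mapping uniqueness travels in the
BED score column (1 = unique, 0 = multi-mapped) — a documented dialect,
since BED itself has no such field.

## Read QC and counting

A raw read is kept iff it has at most `max_n = 2` ambiguous bases and is at
least `min_len = 16` nt long; the N rule is applied first so every
discarded read is attributed to exactly one rule. Base-quality trimming is
out of scope (performed upstream by external tools).

A uniquely mapped fragment is assigned to a gene iff every block intersects
the gene's exon union on a compatible strand (the library is treated as
strand-specific by default; `stranded=False` relaxes this). Fragments
compatible with more than one gene are ambiguous and counted for none —
deterministic, and consistent with unique-count practice. Gene length for
FPKM is the exon-union length (merged across transcripts);
FPKM = count × 10⁹ / (length_bp × total fragments).

## Differential expression

The screen is a minimal NB Wald test:

* size factors by median-of-ratios over genes expressed in all samples,
  rescaled to geometric mean 1 (cross-checked against pyDESeq2 in the test
  suite; they agree up to DESeq2's reference scaling);
* per-gene method-of-moments dispersion on normalised counts
  (`var = μ + αμ²`, α floored at 1e-8, pooled within-group variance);
* Wald statistic on log2FC with SE² = (1/μ₁ + α)/n₁ + (1/μ₂ + α)/n₂
  (natural-log scale, converted to log2), group means pseudo-counted with
  0.5 for reporting.

**Reference distribution.** With three replicates per group the MoM
dispersion is very noisy; a normal reference makes the test strongly
anticonservative (empirically ~12% at nominal 5%). The statistic is
therefore referred to a t distribution with n₁+n₂−2 degrees of freedom.
This restores near-nominal type-I error (0.045 measured at 2000 null
genes) without shrinkage or moderation, which are deliberately not
implemented — the screen's contract here is statistical calibration and
fold-change recovery, not bit-compatibility with DESeq2.

Default DEG cut-offs: raw p < 0.05 and fold change > 1.5 or < 0.67. An
FDR-based preset (`use_fdr=True`) is exposed because both conventions
appear in practice.

Two assay utilities ship with this module: relative qPCR expression
2^−ΔΔCT and the CCK-8 proliferation rate
(OD_exp − OD_blank)/(OD_ctrl − OD_blank) × 100%.

## Alternative splicing

Events are classified from splice-junction geometry against each gene's
annotated exon model; ten classes are emitted (ES, cassetteExon, A5SS,
A3SS, MXE, 5pMXE, 3pMXE, A5SS&ES, A3SS&ES, IntronR), with composite and
multi-junction classes taking precedence so strata are disjoint. The rules
(precise geometry in the `splicing` module docstring) are stated choices:
the published ABLas definitions of the terminal-exon and composite classes
live in prior work and are not reconstructable from first principles.
Strand-awareness: the reference-left end of a junction is the donor on
'+' and the acceptor on '−', which is what mirrors A5SS/A3SS and
5pMXE/3pMXE between strands.

Per sample, the inclusion ratio is inc/(inc+exc) over the event's
inclusion/exclusion junction counts (junction-PSI). For intron retention
the retained evidence is the mean of reads continuously spanning the two
exon–intron boundaries and the spliced evidence is the junction count, so
the ratio is the retention fraction. Samples with inc+exc < 10 are flagged
undefined — the floor is ours; junction-count ratios below ~10 reads are
dominated by sampling noise. Cross-condition testing is a two-sided
equal-variance (Student's) t-test on per-sample ratios with BH-FDR across
tested events (default 5%); zero-variance degenerate cases are reported
explicitly rather than producing NaNs.

## RIP-seq peak calling

Per gene: coverage is scanned in 5-bp windows with a 5-bp step (window
depth = mean per-base depth; trailing partial window keeps its width). A
candidate opens at the first window of a run of 8 consecutive windows each
≥ 2.5× the gene's mean per-base depth, or of a run whose median depth
exceeds 50; it extends until 8 consecutive windows each fall below 4% of
the running maximum window depth and closes just before that run.
Background is per-gene (not chromosome-wide) because the significance null
is explicitly per-gene. Significance: the gene's reads are uniformly
re-placed within the gene span 500 times (lengths preserved) and the
gene-wide maximum window depth recorded; the permutation p uses the
add-one convention (never zero). One null is computed per gene and shared
by its candidates, seeded stably from (seed, crc32(gene id)) so results do
not depend on gene order. A candidate survives if perm p < 0.05 OR max
per-base depth ≥ 10, and then only if its IP abundance exceeds 4× the
input abundance in the same interval. Abundance is reads-in-peak per
million mapped; a read is in-peak when its alignment **midpoint** lies in
the interval (any-overlap counting would inflate a 100-bp peak's input
count by roughly (w+readlen−1)/w ≈ 30% and bias the fold filter); one
pseudo-read is added to the input count.

**Operating regime.** The closing rule can only terminate a peak at a
40-bp coverage gap whenever the peak maximum is below ~25× background, so
the caller is designed for sparse, CLIP-like IP coverage in which true
peaks are read stacks separated by near-empty background. In dense uniform
coverage candidates run on to the gene end and the enrichment filter
removes them. The synthetic defaults reflect the sparse regime
(50 IP reads per 2–3 kb gene, ~0.6× mean depth). A consequence worth
knowing: a minority of calls still chain into flanking background reads,
which widens the interval and dilutes the measured IP/input fold; peaks
planted near the 4× filter boundary are therefore systematically harder to
keep than their nominal enrichment suggests (detection itself — the
p/depth stage — is near-perfect down to 4×; the loss is in the strict >4×
abundance filter).

## Integration and enrichment

Overlaps between DEGs, splicing-regulated genes (RASGs) and peak target
genes are tested with the exact hypergeometric upper tail over a stated
universe. The universe is the dominant unstated parameter behind any such
p-value; the pipeline's default is the genes detected in the RNA-seq stage
(non-zero count in ≥ 1 sample), and it is an explicit argument everywhere.
Identifiers are harmonised as upper-cased symbols, optionally through a
user-supplied two-column ortholog map — a deliberate reduction of the
cross-species problem to what symbol matching can support.
Over-representation runs the same test per GMT term with BH-FDR across
terms. GO/KEGG content is not bundled; enrichment is generic over
user-supplied GMT files.

## Synthetic data and what the tests show

The generator plants known truths so every stage has a parameter-recovery
surface: signed log2 fold-changes in NB counts (3-vs-3 by default, NB in
mean–dispersion form, per-gene log-normal base means), inclusion-ratio
shifts in binomial junction counts (depth 200 per event and sample),
and enriched intervals in IP read placements. Ten alternative-structure
templates (one per event class, cycled with deterministic strands)
guarantee every class is realised when alternative structures are enabled.
Placement of RIP reads is uniform over the gene body — matching the
support of the permutation null by design — and the planted enrichment is
calibrated as the expected library-normalised IP/input contrast of the
interval (the implied within-gene rate ratio is nearly the same number
whenever the peak is much shorter than the gene).

Deliberately absent realism: no sequence composition, no error or quality
model, no adapter content, no PCR duplicates, no overdispersion in
junction counts, no mRNA-abundance structure in the input library, and no
cross-species ID noise. Passing recovery tests therefore demonstrate the
statistical machinery under its stated model, not robustness to these
real-data phenomena.

Problem sizes in the evaluation runs (`ripintegrate.benchmarks`, also
driven by `scripts/acceptance.py`): 200 random tracks for the assembly
oracle, 1000 peak-free genes × 500 shuffles for null calibration, 200
genes (25% planted) for peak recovery, 2000 genes for the expression
checks, 1000 events for the splicing checks, and a 30-gene double pipeline
run for byte-level determinism. The whole set completes in about two
minutes on one CPU.

## Numerical and degenerate-input choices

* Permutation p uses (1 + #{null ≥ obs})/(1 + N) — never zero.
* All-zero genes get p = 1 / status "ns"; zero-length genes and empty
  libraries are errors naming the offender.
* Equal-variance t with both groups constant: p = 1 if means equal, else
  p = 0 flagged degenerate (tolerance 1e-12 relative).
* BH-FDR preserves ties and input order; p outside [0, 1] is an error.
* TSV outputs use a fixed float format (%.6g); with a fixed seed every
  pipeline output is byte-identical across reruns, and per-stage child
  seeds are derived by stable hashing of stage names so adding a stage
  never perturbs earlier stages' randomness.

## Known limitations

* Event classification emits one event per local junction configuration;
  genes with many interleaved alternative structures may hide secondary
  events behind the precedence rules that keep strata disjoint.
* The NB screen has no dispersion shrinkage; power at very low counts is
  below DESeq2's, by design.
* The peak caller inherits the closing rule's chaining behaviour described
  above; peak boundaries should be treated as approximate to ± one run
  length (40 bp).
* Intron-retention evidence needs block-level alignments; junction tables
  alone cannot support IntronR quantification.
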