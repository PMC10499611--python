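# Methods

`mosaicscreen` implements the computational readout of a pooled
loss-of-function CRISPR screen with single-cell transcriptomic readout in
mosaic organoids. A lentiviral library delivers one dual-sgRNA cassette per
cell (two guides against the same gene, plus non-targeting controls) together
with a degenerate unique clone barcode (UCB) marking the integration event.
After tissue growth, targeted amplicon sequencing of the single-cell cDNA
recovers which perturbation and which founder clone each cell carries, and
the transcriptome readout quantifies what the perturbation did. This note
describes each stage's model, the tunable parameters, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Guide and clone-barcode assignment

Input is a table of unique (cell barcode, UMI, sequence) read combinations
with read counts — from a FASTQ carrying `CB:Z:`/`UB:Z:` tags or a TSV. Cell
barcodes are assumed corrected upstream by the droplet pipeline; we do no
further correction.

The cascade, per insert type:

1. **Extraction.** The insert is the subsequence between a 5' and a 3'
   flanking anchor. Matching is substitution-only (no indels), with
   mismatches limited to `floor(max_error_rate x matched length)`
   (default rate 0.10), and partial flank overlap at read ends down to
   `min_overlap` nucleotides (3 for guides, 6 for UCBs). Among admissible
   placements we take the longest overlap, then the fewest mismatches, then
   the leftmost position.
2. **Length gate.** Guide candidates must be 15–21 nt; UCB candidates must
   be exactly the pattern length (12 nt default) and match the degenerate
   IUPAC synthesis pattern position by position (default `NVDNHBNVDNHB`).
3. **Whitelist matching** (guides only). Candidate versus every spacer,
   sliding the shorter over the longer with an aligned window of at least
   `len(shorter) - 2`; Hamming distance over the window, hits accepted at
   distance ≤ 2. A tie between two genes' spacers at the best distance is
   ambiguous and discarded (counted).
4. **Read-support filters.** A global cutoff removes entries with reads ≤
   1% of the median (across cells) of each cell's highest-UMI read count;
   then, within each cell–UMI group, labels with ≤ 20% of the group's
   maximal read count are removed (these are predominantly PCR/sequencing
   error variants of the dominant molecule).
5. **One-to-one resolution.** UMIs are counted per cell and label; only
   labels tied at the cell's maximum UMI count survive. A cell is
   *assigned* when exactly one label survives **and** that label has at
   least one UMI supported by more than one read; several tied labels give
   *ambiguous* (the fate of true multiple infections and barcode
   collisions); anything else is *unassigned*. A label supported only by
   single-read molecules is treated as ambient noise — this is the reading
   of the "more than one read" rule under which a screen sequenced at one
   read per molecule yields no assignments at all, which we adopt as a
   design guarantee.

Guide and UCB cascades run independently; a cell's clone identity is the
(guide, UCB) pair, but cells with a guide and no resolved UCB stay assigned
because abundance testing needs only the guide. Threshold conventions
("cutoff applied" = drop at ≤ cutoff; "more than 20%" = strict >) are
documented constants, configurable at the call sites.

One known ambiguity of the assay's description is left as configuration: the
barcoded primer encodes 15 degenerate positions (`NVDNHBNVDNHBNVD`,
36^5 ≈ 6.0x10^7 combinations) while selection retains 12-nt barcodes
(36^4 ≈ 1.7x10^6), and neither count matches the nominal 1.4x10^7 diversity.
We default to the 12-nt pattern and expose both pattern and length.

## Stratified differential abundance

For each guide g and category T (a cell type, or the dorsal/ventral
trajectory split), we form one 2x2 table per library/pool —
rows {g cells, control cells}, columns {in T, not in T} — and test with the
Cochran–Mantel–Haenszel statistic

    X^2 = (Σ_k a_k − Σ_k E_k)^2 / Σ_k V_k,
    E_k = (a_k+b_k)(a_k+c_k)/n_k,
    V_k = (a_k+b_k)(c_k+d_k)(a_k+c_k)(b_k+d_k) / (n_k^2 (n_k−1)),

p-values from chi-square with 1 df (no continuity correction by default;
exposed as a flag), effect size the Mantel–Haenszel common odds ratio
Σ(a_k d_k/n_k) / Σ(b_k c_k/n_k). Stratifying by library absorbs
pool-to-pool differences in guide sampling. On a single stratum this score
statistic equals the Pearson chi-square times exactly (n−1)/n — the
hypergeometric-variance factor — which is the identity our oracle tests
assert. Strata missing either group are dropped; all-degenerate input is an
error.

BH correction is applied across the whole scan (all guide x category pairs
in one family; the granularity is configurable), significance at FDR < 0.05,
and results are summarized as the signed score sign(log OR) x (−log10 FDR).

Controls are cells carrying the non-targeting guide; pooling uninduced cells
as an alternative control is a flag, mirroring designs in which one batch
lacks the spike-in.

Two complementary analyses share this module:

* **Representation.** Per pool, each guide's detected-cell fraction;
  fold change = mean(induced)/mean(uninduced); Welch t-test between the two
  fraction samples (the arms have unequal size and no variance homogeneity
  argument), BH across guides. Constant, identical samples give p = 1 by
  convention; a guide absent from all uninduced pools is flagged with
  infinite fold change.
* **Cross-pool consistency.** Per (pool, guide, type), fold enrichment
  FE = guide fraction / control fraction within the pool; a background
  distribution is built by permuting guide labels within pools (default 100
  seeded rounds), and each (guide, type)'s per-pool log2 FE sample is
  Welch-tested against the background for that type. log2 is the default
  scale (the ratio scale is available); pairs seen in < 2 pools are skipped.

## Neighborhood enrichment

A per-cell, finer-grained version of the same question: on a caller-supplied
embedding (PCA space, or fate-probability space), an exact Euclidean kNN
graph (k = 200 default) defines each cell's neighborhood N(i) = {i} ∪ its k
neighbors (including the cell itself avoids empty-target neighborhoods for
isolated cells; configurable). Per cell, a CMH test stratified by library
compares target versus control counts inside versus outside N(i); the score
is sign(log MH OR) x (−ln p) (natural log; recorded in output metadata).
Cells whose neighborhood lacks both groups score 0.

Scores are smoothed by a random walk with restart on the row-normalized
symmetrized adjacency P:

    s ← r·s0 + (1−r)·P·s,   fixed point  r·(I−(1−r)P)^{-1}·s0,

default restart r = 0.5, tolerance 1e−6, hard iteration cap with an error on
non-convergence. Smoothed values are convex combinations of the input and
stay within [min s0, max s0]. Overlapping neighborhoods make the scores
dependent; no multiplicity correction is attempted — the field is
descriptive, as used for visualization.

kNN construction is deterministic: chunked exact distances, stable argsort,
distance ties broken by the lower cell index, self excluded; n ≤ k reduces
k to n−1 with a warning.

## Differential expression

Per perturbation, condition (target = 1 vs control = 0) is modelled by
logistic regression on nuisance covariates — standardized log total UMI
count, one-hot library, one-hot cell type — and the gene's log-normalized
expression; the gene coefficient is tested by a 1-df likelihood-ratio test
against the covariate-only null, which is fitted once per contrast. The
regression direction (condition as response) follows the convention of the
logistic-regression DE test in the single-cell ecosystem even though the
model is often written with expression on the left. Trajectory-restricted
contrasts subset to one trajectory and drop the cell-type covariate.

Numerics: Newton–Raphson with clipped logits and a floor on the IRLS
weights; fits flagged non-converged (or with |beta| > 30, a quasi-separation
signal) are refitted with a ridge of 1e−6 on the gene coefficient only, and
the reported log-likelihood is always the unpenalized one at the solution so
the LRT stays interpretable. Genes detected in fewer than 5% of tested
cells are excluded; both groups must have ≥ 20 cells. The reported effect
size is the difference in mean log-normalized expression (target −
control); FDR by BH; "TOP-DEGs" are the 30 largest |effect| genes among
FDR < 0.05, with boundary ties all retained.

## Module and risk-gene enrichment

Gene-set overlaps use the two-sided Fisher exact test: the p-value sums
hypergeometric probabilities ≤ the observed table's (relative tie tolerance
1e−7, the R convention); the reported odds ratio is the sample OR with a
Haldane 0.5 correction only when a zero in the off-diagonal would make it
undefined — it feeds the "more than twofold" rule, while the p-value is
always exact. Every test is confined to an explicit background universe
(e.g. genes expressed in strictly more than 5% of cells, or the gene set of
an inferred regulatory network); genes outside the universe never influence
a result. Gene symbols are uppercased and version suffixes stripped before
intersection. BH runs across the modules of one scan; a module is enriched
iff FDR < 0.01 **and** OR > 2. Risk-gene lists are user-supplied files —
nothing is fetched.

## Fate projection

A row-stochastic matrix F (cells x terminal states, rows sum to 1 within
1e−6) is consumed from upstream trajectory analysis. Terminal states are
placed at evenly spaced angles α_t = 2πt/n_t (order caller-specified,
default alphabetical), and each cell is projected to

    x_i = Σ_t f_it cos α_t,   y_i = Σ_t f_it sin α_t,

the convex combination of the state anchors: one-hot rows sit on the unit
circle, uniform rows at the centroid (the origin, for symmetric layouts),
every valid row inside the anchors' convex hull. Coordinates are the raw
sums, not per-cell normalized. Enrichment of perturbed cells in fate space
reuses the neighborhood machinery with F itself as the embedding and
k = 100. Group comparisons of single transition probabilities use the
Wilcoxon rank-sum test (exact enumeration for ≤ 12 values, tie-corrected
normal approximation with continuity correction otherwise), reported with
medians and IQRs.

## Synthetic screens

The generator plants known truth behind every stage; all randomness flows
from one integer seed.

* **Cells.** Guides assigned uniformly with a 4% non-targeting spike-in
  (a 96:4 mix; 36 targets by default). Cell types are drawn from a 16-type
  telencephalon composition; a planted effect (g, T, δ) shifts the logit of
  type T by δ for cells carrying g, so the realized guide-versus-control
  log odds ratio of T equals δ exactly in expectation. Libraries are split
  across batches; clones are log-normal-sized partitions of each guide's
  cells (σ = 0.8, emulating highly variable clone sizes without claiming
  any empirical distribution), each clone carrying a pattern-conforming UCB.
* **Reads.** Per cell, Poisson-distributed guide and UCB UMI counts (mean
  4); per UMI, 1 + Poisson(19) reads; inserts are embedded between the real
  extraction anchors with random pads. Substitution errors (1%/base) are
  per sequenced read: each UMI emits an error-free record and one collapsed
  mutated-variant record, so molecules survive errors the way they do at
  realistic depth. A configured fraction of cells (2%) receives a second
  guide at exactly equal UMI count — planted ambiguity the one-to-one rule
  must remove.
* **Expression.** Gamma–Poisson (negative binomial, dispersion 0.5) counts
  under log-normal size factors (mean depth 5,000), log-normalized to 10^4
  per cell; planted log2 fold changes apply to the perturbed cells.
* **Fates.** Dirichlet rows; a planted bias raises the concentration of one
  terminal state for one guide. The embedding is fate space plus Gaussian
  noise.
* **Representation.** Pool-level detection fractions around the uniform
  library composition with log-normal noise; induced pools scale planted
  guides by their fold change before renormalization.

What it does **not** emulate: real transcriptome manifold structure (no
velocity, no marker-gene programs, no batch effects beyond the pool split),
ambient RNA, barcode swapping, or CBC errors. Passing tests therefore
demonstrate correctness of the statistics and the cascade's logic under the
stated noise model — not robustness to every artefact of real droplet data.

## Verification sizes

The repository's checks run at desk scale, chosen as the smallest sizes at
which the asymptotic tests are calibrated: null calibration pools ten
12,000-cell screens (~3,200 CMH tests) and one 5,000-gene permuted DE
contrast; recovery uses twenty replicate screens with three planted
log-OR = 1.5 effects among 60 scanned pairs; the cascade check uses one
10,000-cell screen at 1% error. `scripts/acceptance.py` recomputes all of
these from scratch under a caller-supplied seed.

## Known limitations

* The CMH scan's BH family is the whole scan; finer families (per category)
  change borderline calls.
* The neighborhood scores are descriptive; their spatial dependence is not
  modelled.
* Logistic DE assumes log-normalized input; raw-count models (NB GLMs,
  pseudobulk) are out of scope.
* The UCB diversity ambiguity above means clone collision rates in real
  libraries may differ from the simulated ones.
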