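# Methods

## The splitting model

A sequencing library split across `k` lanes is modelled at the read level:
the ground-truth (GT) sample is the multiset of reads the library would have
produced on one lane, and each simulated lane is an **independent**
without-replacement draw of `s_j = floor(p_j * N)` records from the full GT
record list (the floor remainder goes to the last lane, so depth is
conserved exactly). The split (S) sample is the concatenation of the lanes.
Independence across lanes is the essential assumption: a GT read can be
drawn into several lanes while another is drawn into none, which is what
erodes uniqueness. Disjoint draws would reassemble GT exactly and produce no
effect at all. Read identity is exact sequence equality; ids and qualities
never enter any statistic.

Three consistent levels are implemented. `split_reads` operates on records;
`split_counts` replaces each lane by one multivariate-hypergeometric draw
over the distinct-sequence multiplicities, which is distributionally
identical on the multiplicity view (verified by a two-sample KS test against
the record-level simulator) and orders of magnitude faster, so the sweeps
use it; `expected_unique` evaluates the exact expectation
`E[U] = sum_i (1 - prod_j C(N-m_i, s_j)/C(N, s_j))` via log-gamma, and
serves as the analytic oracle every Monte-Carlo run is checked against.
Seeding: a master seed plus (iteration, lane) indices feed a
`SeedSequence`, so outputs are bit-reproducible and iterations are
independent.

## Synthetic data

The generators produce the smallest inputs that carry the statistical
structure the analyses depend on; none of them model sequencing error,
strand, pairing or UMIs.

**Read multisets (bulk).** Per transcript, the number of distinct fragments
is Poisson with mean `expected_count / duplication` and each fragment is
replicated `1 + Poisson(duplication - 1)` times, guaranteeing multiplicity
>= 1 and a singleton-dominated, heavy-tailed multiplicity profile. Fragment
start positions are uniform along the transcript — coverage irregularities
are left to arise from splitting, not generation. The default bulk profile
(`heavy_tailed_profile`) gives 60 transcripts log-normal expected counts
(sigma 1.5, total 100k reads) with duplication rising from 1 to 4 with
abundance, mimicking PCR/optical duplicates accumulating on abundant
transcripts. Quality strings are constant `I`; FASTQ requires them and no
analysis reads them.

**ChIP-like reads.** A random genome with rectangular enriched regions:
`enrichment` and `background_rate` are expected read starts per base inside
and outside peaks respectively (so `background_rate=0` confines all reads
to peaks, and doubling enrichment doubles expected peak reads). Defaults:
200 kb genome, 60 non-overlapping peaks of width 300–800 bp with per-base
rates log-spaced over [0.06, 1.0], background 0.02, read length 50,
duplication 1.5. The amplitude range deliberately straddles the caller's
detection limit — real peak amplitude distributions are heavy-tailed with
many weak peaks — because peaks far above threshold are insensitive to
splitting and would show no effect.

**Single-cell counts.** Negative-binomial counts (variance
`mu + alpha*mu^2`, default alpha 0.1, typical of droplet data) over
log-normal base means; cells fall into weighted clusters, each with 25
disjoint planted marker genes whose fold changes are log-spaced from 8 down
to 1.3 — strong and borderline markers alike, as in real data, so marker
rankings have a noise-sensitive tail. The last `island_size` cells form a
small separate subpopulation built on cluster 0's profile plus one dominant
driver gene (50-fold, the analogue of a single highly specific transcript
defining a rare cell type) and five 4-fold companions.

**Bulk DE replicates.** `gen_de_dataset` draws two groups of NB replicates
with dispersion 0.02 — replicates of genetically identical model systems
show biological CVs around 0.1–0.2, i.e. dispersions of 0.01–0.04; the
single-cell level of 0.1 would be wrong for this design. Planted effects
are 4-fold up-shifts in 100 genes with base mean >= 20: a 4-fold change on
a gene observed at a handful of counts is undetectable by any method at
this depth, so planting there would measure depth, not the test.

## Downstream statistics

**Diversity.** Unique/total counts and fragments exclusive to one sample;
per-position A/C/G/T chi-square (4x2 table per position, BH across
positions); per-sequence `log2(m_b/m_a)` on sequences non-zero in both
samples, binned in unit-width log2-abundance bins against the depth
guideline `log2(N_b/N_a)`; per-window scaled coverage differences
`d_w = (a_w - b_w)/(a_w + b_w)` (0 when both are 0, positive = higher in the
whole-sample slot). Windows are non-overlapping 100-nt tiles by default —
per-window counts are then well defined — with the step exposed as a knob;
the normalisation by the summed window means is likewise one of several
defensible scalings and is the configurable default.

**Quantification and DE.** `assign_reads` is explicit toy plumbing: exact
substring assignment with ambiguous reads discarded and tallied
(`assigned + ambiguous + unassigned = N`). Quantile normalisation maps each
column onto the mean-of-order-statistics reference with average ties; it is
exactly idempotent on tie-free data, approximately on ties. `simple_de` is
the stand-in DE test: an exact conditional binomial test on
replicate-summed counts (given the total, the group-A sum is binomial),
with two corrections that make it behave on realistic data. First, counts
are deflated by `1 + alpha_hat * mu` where `alpha_hat` is a global NB
dispersion estimated by a trimmed-mean moment estimator from within-group
replicate variance only (immune to genuinely DE genes); a pure Poisson test
is badly anticonservative under NB noise. Second, the null hypothesis is
the interval `|log2FC| <= 0.5` rather than a point at zero (the spirit of
edgeR's glmTreat): a point-null test combined with a post-hoc fold cutoff
admits null genes whose observed fold change drifts past the cutoff with
honestly small p-values, which in simulation put the false-discovery rate
near 20–30%. `fold_null=0` and `dispersion="poisson"` recover the plain
test; the concordance functions accept any externally produced DE table.
A gene is flagged DE iff `|log2FC| > 0.5` and BH-adjusted p < 0.05;
log2FC uses pseudocount 1 (as do all log transforms in the package).

**Peaks.** The toy caller takes maximal runs of coverage >= threshold,
bridges sub-threshold gaps up to `merge_gap` (30 bp default) and drops runs
under `min_length` (150 bp). Coverage for peak calling is computed on
**deduplicated** reads — one count per distinct sequence — mirroring the
duplicate-removal step of real peak callers; this is precisely where the
loss of unique reads under splitting reaches the peaks (total-coverage
profiles are nearly invariant under splitting, deduplicated ones are
thinned by one minus the recovery ratio). Matching is reciprocal-midpoint:
`(p, q)` match iff each midpoint lies in the other's half-open interval;
many-to-many candidates are resolved greedily by smallest midpoint distance
(lower start breaks ties), which makes the matching symmetric — that tie
rule is this package's design choice, not an external convention.
Coordinates are 0-based half-open throughout; length is `stop - start`.

**Single cell.** QC in two modes (droplet: > 1000 detected genes, < 10%
mitochondrial, > 20% ribosomal, strict inequalities, MT/RP genes dropped
afterwards; plate: features in > 3 cells, cells with > 50 features). PCA on
the 3000 most abundant genes with an explicit sign convention
(largest-magnitude loading positive), 20-NN graphs on 30 components with
index-order tie-breaks — all deterministic. Marker similarity is the
overlap coefficient `|A∩B| / min(|A|,|B|)` — the natural reading of
"restricted to the smaller set" — with classical Jaccard as an option and
empty sets scoring 0. Per-cell clustering similarity is the Jaccard index
between the cell's cluster-mate sets under the two clusterings (computed on
common cells, self included): per-element, in [0,1], 1 exactly on
identical partitions, symmetric. It is a fully specified stand-in for
element-centric similarity, whose affinity-propagation machinery is out of
scope here. Clustering itself is not reimplemented: labels come from the
synthetic truth, the built-in k-means baseline, or imported files.

## Problem sizes

The default study conditions — 100k bulk reads over 60 transcripts, a
200 kb ChIP genome with ~20k reads, 500 cells x 1000 genes, 2000-gene DE
matrices — are the scale at which every effect of interest is resolvable
with comfortable Monte-Carlo margins while a full pipeline run stays in the
tens of seconds; recovery sweeps use 50 iterations per grid point (200 for
the proportion sweep, whose adjacent expected gaps near 50-50 are a few
10⁻⁴ and need the extra precision), peak and single-cell scenarios use the
10 and 3 iterations of the designs they emulate.

## What the synthetic results do and do not show

Passing tests establish that the implementation is faithful to the model
(Monte-Carlo agrees with the exact expectation; count- and read-level
simulators agree in distribution) and that the qualitative effects —
recovery falling with k and depth, minimum at even proportions, peak loss
and shortening growing with k, island collapse without its driver gene,
marker-set erosion, FP-prone DE borderline calls — emerge at realistic
desk-scale conditions. They do not certify effect sizes on real data: the
generators omit sequencing error, mappability structure, amplification
bias and lane-specific fragments (a split lane can contain fragments the
GT lane never sequenced; subsampling cannot create those, it can only lose
or duplicate), so published figures from real datasets are reproduced in
direction, not magnitude.

## Numerical notes and degenerate inputs

`expected_unique` works in log-gamma space and returns exact zeros for
impossible draws (`s_j > N - m`); subsample sizes of zero raise rather than
silently degenerate; empty read sets, all-zero gene rows, constant coverage
vectors (undefined correlation -> recorded missing) and rank-deficient PCA
inputs (fewer components, with a warning) are all handled explicitly.
Manifest checksums exclude wall-clock fields so reruns compare equal on
content.
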