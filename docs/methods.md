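# Methods

## The problem

Allopolyploid wheat carries two or three closely related subgenomes.  An
array probe designed against a SNP in one gene copy usually also
hybridises to the homoeologous and paralogous copies, which contribute
constitutive fluorescence.  The observed signal for a sample is therefore
a *dosage* ratio: with channel doses `x` (first allele) and `y` (second
allele) summed over all hybridising copies, the genotyping plot shows each
sample at

    theta = (2 / pi) * arctan(y / x),        R = total intensity,

with `theta = 0` for pure first-allele signal and `theta = 1` for pure
second-allele signal.  Three consequences shape the data:

* **cluster compression** — nontarget copies add constant dosage, so the
  homozygous clusters of the target SNP move closer together in theta
  (with `k` copies and fixed first-allele background the AA-BB separation
  is `(2/pi)·arctan(1/(k-1))`, ~0.105 at seven copies);
* **extra clusters** — a secondary polymorphism in a probe annealing site
  silences one copy in carriers, shifting both theta and R and producing
  more than the three clusters expected of a biallelic SNP;
* **null clusters** — samples in which every hybridising copy is deleted
  or diverged emit only background: a low-R cluster whose theta is
  meaningless (noise spread across [0, 1]).

Model-based diploid callers assume three Gaussian-ish clusters and fail on
all three phenomena.  The package instead uses model-free density-based
clustering (DBSCAN and OPTICS), which finds any number of clusters of
arbitrary shape from two parameters: the neighbourhood radius ("cluster
distance") and the minimum number of points per cluster.

## Clustering primitives

`cluster_core` implements DBSCAN and OPTICS from scratch on 2-D points —
they are the method, not an accessory, and the deterministic tie rules
below are part of the contract (scikit-learn serves as an independent
cross-check in the tests):

* **DBSCAN** — a core point has at least `min_points` neighbours (itself
  included) within `cluster_distance`; clusters are connected components
  of core points; a border point joins the cluster of its *first core
  neighbour in scan order* (the algorithm leaves this open; fixing it
  makes results reproducible).  Neighbourhoods use a dense all-pairs
  distance matrix — panels are at most a few thousand samples per marker,
  so no spatial index is warranted.
* **OPTICS** — classic priority-queue ordering with core and reachability
  distances capped at `cluster_distance`; priority ties break by point
  index.  Cutting the profile at threshold `t` labels core-at-`t` points
  by walk segments and attaches non-core points by the same border rule,
  which makes the cut at `t = cluster_distance` reproduce the DBSCAN
  partition exactly.
* **Forced-k extraction** — the published description of the re-clustering
  step only states that a user-defined number of clusters is requested.
  Here the requested count is obtained by scanning the distinct
  reachability/core-distance values from `cluster_distance` downward and
  returning the cut at the largest threshold yielding exactly `k` clusters
  of at least `min_points` members; thresholding is the simplest mechanism
  with the DBSCAN-equivalence property.  If no threshold reaches `k`, the
  best achievable labeling below `k` is returned with a shortfall flag.

### Clustering coordinates

Clustering operates on `(theta, w · R / P95)` where `P95` is the marker's
95th intensity percentile and `w = 0.25` (configurable).  Rationale:
genotype clusters separate almost entirely in theta while intensity
scatter at a realistic 10% CV is larger than the 0.07 radius; a quarter
weight keeps intensity noise well inside the radius (effective vertical
spread ≈ 0.025) while the full-versus-null contrast (scaled R ≈ 0.9
vs ≈ 0.07, effective ≈ 0.21) still exceeds the radius comfortably, so
null clusters separate vertically.  Whether and how intensity enters the
clustering metric is not specified by the published protocol; this is a
design choice of the package.

## The three-step protocol

Per assay (`calling.run_protocol`):

1. **DBSCAN, cluster distance 0.07, minimum 10 points**, then filters.
2. Assays that produced a **single cluster** are re-clustered with
   **OPTICS (0.07, 10) forced to two clusters** — the compressed-cluster
   rescue.  Assays failing step 1 for any other reason skip directly to
   step 3, as do step-2 failures.
3. **DBSCAN at 0.09** recovers clusters too broad for the tight radius.

After the accepted step, clusters are summarised (median centers, floored
MAD spreads, all quantised to 6 decimals so the in-memory model equals its
serialised form bit for bit), null-flagged, ordered by ascending theta
(ties by ascending intensity) and named `C1..Cn`; exactly three non-null
clusters are additionally interpreted as `AA`/`AB`/`BB`.  Null clusters
are excluded from the biallelic interpretation — a missing hybridisation
signal is a hemizygous/absent state, not a third allele — and their
members are called `NULL`.  An assay with three genotype clusters plus a
null cluster therefore keeps its biallelic labels (such co-dominant SNPs
with a segregating null do occur) and is exported to VCF with a
`NULL_ALLELE` filter annotation.

**Filters.**  Cluster count within a per-step window (2–6 at steps 1 and
3, exactly 2 at step 2), call rate ≥ 0.90, and MAF ≥ 0.35 in mapping mode
or ≥ 0.05 in diversity mode (the two published floors).  The published
protocol does not state the cluster-count windows or the call-rate floor;
both are configurable defaults here and are logged per assay in the step
report.  MAF is allele-based for biallelic assays (heterozygotes
contribute one copy of each allele; `NULL` excluded) and the minimum
cluster frequency otherwise (with `NULL` as its own class, so a
presence-absence assay with one genotype and one null cluster is
retained).

**Confidence score.**  The published protocol names a confidence-score
limit of 0.8 without defining the score.  The package uses a Gaussian
responsibility: for cluster `k` at spread-standardised distance `d_k`,
`w_k = exp(-d_k²/2)` and the confidence is `max_k w_k / Σ w_k`.  It is 1
at an isolated cluster center, exactly 0.5 midway between two equal
clusters, and bounded in (0, 1]; whether its scale matches the commercial
score is unknown, so the comparison is flagged, not assumed.  Samples
whose nearest cluster is beyond 6 standardised units are reported `NC`
with confidence 0 — this keeps samples from clusters absent in a trained
model (the cluster-file apply workflow) from being force-assigned.
Spreads are floored at 0.01 to keep degenerate (near-coincident) clusters
from producing infinite standardised distances.

## Null-allele detection

A cluster is flagged null when its median scaled intensity is below
`r_ratio = 0.25` times the assay's strongest cluster median (at least two
clusters required; a lone cluster has no reference level).  The ratio is
scale-free because intensities are already normalised per marker.

## Multi-locus resolution

Within one bi-parental population usually a single locus segregates, so
the population's samples split between exactly two clusters of a
multi-cluster assay.  `detect_segregation` declares a pair when the two
largest clusters hold ≥ 90% of the population's called samples and each
has ≥ 10 members (both thresholds configurable; they are not published
values).  A chi-square test against the 1:1 DH expectation is recorded as
annotation only — never a filter, because introgressed segments with
restricted recombination distort ratios.  `build_allelic_map` treats
clusters as nodes and segregating pairs as edges; a node with edges from
two or more populations is a hub (a shared allele state), edge-less
observed clusters are reported unresolved, and contradictory records from
one population mark the marker as conflicted.  A population segregating at
two loci simultaneously produces no qualifying pair and the marker stays
unresolved.  No chromosome assignment is attempted (that requires linkage
mapping).

## Population statistics

Expected heterozygosity `2p(1-p)` averaged over polymorphic markers is the
primary "mean heterozygosity" (the observed heterozygote fraction is also
available — published tables rarely say which definition they use).
Pairwise differentiation uses the Weir & Cockerham (1984) unbiased θ̂ with
the a/b/c variance components and ratio-of-sums combination across
markers; it may legitimately dip below zero for undifferentiated samples.
LD r² uses direct haplotype counts (`D²/(p_A p_a p_B p_b)`) when both
markers are fully homozygous — phase is trivial in inbred material — and
the squared Pearson correlation of allele dosages otherwise; the method
used is recorded.  Markers with null-flagged clusters should be excluded
from these statistics (hemizygosity violates the biallelic frequency
model); the CLI `stats` command keeps only AA/AB/BB/NC markers.

## The simulator

`signal_sim` draws genotypes, converts them to channel doses (two doses
per hybridising site; a heterozygote contributes one of each allele at the
target site; failed sites contribute nothing; per-site signal weight is
equal by default, a weight vector is accepted for robustness tests), and
applies noise:

* theta: additive Gaussian (default sd 0.02), truncated to [0, 1];
* R: multiplicative lognormal with unit mean (default CV 0.1), on a scale
  where a fully hybridising single-copy assay has mean R 1.0;
* null points: theta uniform on [0, 1] and R from a background level
  (default 0.08) with the same multiplicative noise — the theta of a
  no-signal point is pure noise, which reproduces the horizontal spread of
  real low-intensity clusters.

The noise magnitudes of real cluster clouds are not published; these
defaults were chosen once as visually realistic cloud widths and are free
parameters of the simulator, not published values.

Populations: *diversity* panels draw each locus with an inbreeding
coefficient (default 0.9; haplotype pairs are identical by descent with
that probability), reflecting selfing wheat with residual outcrossing;
*DH* populations inherit each unlinked locus 1:1 from two founders with
residual heterozygosity 0.02; *F4*-type populations stay heterozygous at
rate 0.125 where the founders differ — the F4 expectation.  Secondary
(probe-site) polymorphisms are modelled per haplotype, so partially
inbred material produces hemizygous intermediate-intensity classes, as
real data do.  The truth table records each point's genotype, dosage
pair, null status and a deterministic configuration index (0 for null,
1..k by ascending theta then total dosage) — the oracle for every
downstream accuracy measurement, which maps each fitted cluster to the
majority configuration of its members.

### What the simulator does not emulate

No probe thermodynamics, batch or plate-position effects, two-probe
(Infinium I) chemistry, linkage between loci within a population, or
ascertainment bias.  Passing tests therefore demonstrate that the
*algorithmic* pipeline recovers the generating cluster structure under
realistic dosage geometry and noise — not that it would match any
particular laboratory dataset.

## Canonical study conditions (`scenarios`)

* **Default benchmark**: 1000 samples × 200 assays at theta sd 0.02 and
  10% intensity CV.  Samples mirror a cluster-file training panel: 600
  fully inbred diverse accessions, 250 DH lines and 150 F4-type lines
  that populate the heterozygote clusters (real training panels add
  partially heterozygous material for exactly this reason).  Assay mix:
  35% clean three-cluster SNPs, 20% assays monomorphic in the diverse
  accessions but segregating in the cross (two clusters), 25% compressed
  assays with one constitutive duplicate copy, and 20% deletion assays
  segregating a null haplotype at frequency 0.3.  Expected results: ≥99%
  truth concordance of non-NC calls, ≤5% NC, ≥95% null-cluster
  sensitivity with ≤5% false flags.  A handful of deletion assays is
  typically lost to the call-rate filter when hemizygous intermediate
  classes blur the intensity columns — an honest failure mode reported in
  the step accounting.
* **Compressed pairs**: 100-line DH assays with seven hybridising copies
  (theta separation ≈ 0.105, no residual heterozygosity, so the truth is
  an exact two-way split); DBSCAN at 0.07 merges them and the forced
  two-cluster extraction recovers the split at ≥98% pooled accuracy.
  Residual errors are points in the overlap of the two clouds
  (≈ 2.6 sd apart), which no clustering rule can place reliably.
* **Secondary-SNP assays**: two 100-line DH populations segregating
  (C2, C3) and (C1, C3); the allelic map must identify C3 as the hub.
  This panel mixes populations, so it is clustered with the diversity-mode
  MAF floor (a per-cross 0.35 floor would reject clusters holding a
  quarter of the combined panel).
* **Differentiated counts**: two-population genotype tables from
  Balding-Nichols frequency draws at a target F_ST — a closed-form oracle
  for the Weir-Cockerham estimator.

Problem sizes (200 random clustering instances up to n = 300, 100
replicates for the forced split and the allelic map, one 1000 × 200
benchmark) keep a full validation run around half a minute on one CPU
while holding the Monte-Carlo error of every rate well below its margin.

## Numerical choices

* Fixed 6-decimal formatting in every writer and 6-decimal quantisation of
  model parameters and confidences at creation time: serialisation is the
  identity on the model, so a written-and-reloaded cluster file reproduces
  the original calls exactly.
* Deterministic ordering everywhere: markers then samples, lexicographic;
  clustering tie-breaks by point index; identical seeds give bit-identical
  panels.
* Degenerate inputs: zero-signal dosage raises a dedicated error rather
  than returning an arbitrary angle; all-NC assays have undefined MAF
  (error); a monomorphic marker has undefined r²; F_ST with zero total
  variance is undefined (NaN), and slightly negative estimates are
  returned as-is.

## Known limitations

* Hemizygous (half-dosage) classes between the full-signal and null
  intensity levels can bridge intensity columns at the default radius;
  affected assays fail the call-rate filter rather than producing wrong
  calls.
* The forced-k extraction assumes the requested clusters separate at some
  reachability level; heavily overlapping clouds return a shortfall.
* The confidence score is a package definition; its numerical scale is
  not calibrated against the commercial software's score.
* Cluster-file application re-normalises intensity with the new panel's
  own 95th percentile; a panel where an assay is almost entirely null
  would mis-scale (not an issue for the mixed panels simulated here).
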