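# Methods

## Scope and data model

`recurbin` bins assembled contigs using two per-contig features: the
canonical tetranucleotide frequency (TNF) vector and the vector of mean
per-base read depths across M samples. Read mapping and depth
summarization happen upstream (any tool emitting the common
`jgi_summarize_bam_contig_depths` table or a plain contig-by-sample TSV);
gene prediction and HMM search for marker genes likewise happen upstream
(HMMER3 tabular output or a two-column TSV), or through a user-configured
external command. The package never re-implements those tools.

## Composition feature

All 256 overlapping 4-mers are folded by reverse complement into 136
canonical classes (120 complement pairs + 16 palindromes), making the
signature independent of contig strand. Windows containing an N are
skipped entirely; a contig with no valid window receives the uniform row
and a flag (in practice the 1500 bp length filter removes such contigs
first). Rows are normalized to sum to one.

## The probability model

The score of contig S against cluster center G is the product of a
composition posterior and a coverage likelihood.

**Composition posterior.** Empirical densities of the TNF Euclidean
distance D are collected from fragment pairs drawn within one genome
(same) and between genomes (different), and combined by Bayes' rule under
fixed prior odds P(different)/P(same) = 10. Because the distance
distribution depends on fragment length, the posterior is approximated by
a logistic curve `1/(1+exp(-(b + c·D)))` fitted separately for each pair
of contig-length bins. Length bins use geometric lower edges
1500, 3000, 6000, 12000, 24000, 48000, 96000 bp (seven bins, the last
unbounded; lengths below 1500 clamp to the first bin). Fragment lengths
for training are drawn uniformly within each bin, capped at half the
shortest training genome.

Two numerical details matter:

* Training pairs are drawn with a same:different class ratio of
  1:prior_ratio, so the fitted logistic targets the posterior under the
  stated prior rather than a balanced-class posterior. With this choice
  the logistic tracks the histogram posterior to within 0.05 mean
  absolute error on held-out pairs (asserted in the test suite).
* Cells with fewer than 50 pairs of either class borrow parameters from
  the nearest fitted cell (flagged in the model file). Near-separable
  cells are rescaled so |b + c·D| ≤ 50 over the observed distance range,
  which preserves the decision boundary while keeping the log-likelihood
  finite. A fitted slope must be negative (probability decreases with
  distance); this is validated on load.

**Coverage likelihood.** Under Lander–Waterman sequencing the read count
of a contig is Poisson, so its mean depth x given a center depth λ is
scored with the continuous Poisson density
`exp(x·ln λ − λ − lnΓ(x+1))`, which matches the pmf at integers and
handles fractional mean depths smoothly. λ is floored at 0.01 so
zero-coverage centers remain scoreable. Samples are treated as
independent libraries and their factors multiplied. The coverage factor
always consumes raw mean depths; the optional per-sample rescaling
(`normalize_coverage(..., "per_sample_scale")`) exists only for distance
or centroid geometry, since Poisson rates are meaningful only on the
depth scale.

All probability arithmetic is in log space with a global floor of 1e-300.

## The packaged default model

`src/recurbin/data/default_model.json` is trained by
`scripts/train_default_model.py` on 12 synthetic order-0 Markov genomes
of 150 kb at signature divergence 0.9 (seed 20260922), 1200 pairs per
length-bin cell. It is a stand-in corpus: a production user binning real
assemblies should train on real reference genomes with `recurbin train`,
which uses the identical procedure. Length-bin cells above 48–96 kb are
infeasible for 150 kb training genomes and borrow from the nearest fitted
cell.

## Strain-count estimation and seeding

For every catalog marker, the number of distinct contigs carrying it
estimates the strain count. The default `median` strategy takes the lower
median of these counts, which is robust to markers that are spuriously
rare (missed by the scan) or promiscuous (on chimeric contigs); the
`min_literal` strategy takes the minimum count ≥ 1 and is kept as an
option. Among markers achieving the chosen count, the one with the
largest summed hit length (alignment-coordinate span when available,
otherwise lexicographic order) is selected, and its carrier contigs
become the initial centers.

## Bin quality

Given collocated marker sets M = {s}, with N_g the copy number of marker
g inside a bin:

* recall = mean over sets of |{g ∈ s : N_g ≥ 1}| / |s| (completeness),
* contamination index = mean over sets of Σ_{g∈s} max(N_g − 1, 0) / |s|,
* precision = 1 / (1 + contamination index).

The contamination index is 0 for a perfect bin and grows without bound
with duplicated markers; the reciprocal mapping makes "precision ≥ 0.90"
a coherent acceptance threshold (0.90 corresponds to a contamination
index ≤ 1/9). An alternative mapping (1 − index, clamped) was considered
and rejected because it saturates at index ≥ 1, losing ordering between
badly contaminated bins.

Marker catalogs are user-pluggable JSON ({"name", "sets"}); the packaged
catalog is a 20-marker synthetic set used by the generator and tests.

## Clustering

**Stage-1 K-means.** Assignment sends each contig to the center with the
highest combined probability (ties to the lowest center index); the
update replaces each center by its centroid: renormalized mean TNF, mean
depth vector, and median member length as the length proxy for the
logistic lookup (a centroid has no physical length). An emptied cluster
is reseeded with the worst-assigned contig. Iteration stops when
assignments stabilize or after 100 iterations.

**Minimum-probability filter.** The raw combined probability of even a
perfectly placed contig is far below 1 — the Poisson density at its mode
is ≈ (2πλ)^(-1/2) per sample, e.g. ~7·10⁻⁴ for λ = 20 over three samples —
so a fixed absolute threshold of 0.80 on the raw product would discard
everything. The filter therefore thresholds the *normalized assignment
probability*: the contig's probability for its assigned center divided by
the sum over all current centers (softmax of the log scores). This is 1
when k = 1, and 0.80 is a meaningful confidence level; ambiguous contigs
such as cross-genome chimeras split their mass between centers and are
filtered. The literal raw-scale filter is retained as
`prob_filter_kind="raw"` for comparison.

**Acceptance schedule.** A cluster is accepted iff precision ≥ 0.90 and
recall ≥ the current rung of the descending ladder (0.90, 0.60, 0.30).
The rung advances only when a full evaluation accepts nothing at the
current rung, and never resets; when nothing qualifies at the lowest rung
the algorithm terminates. This guarantees progress: every round either
banks at least one bin, shrinks the pool, or terminates, so the recursion
is bounded (additionally capped at 20 rounds).

**Stage-2 K-medoids.** The residual pool S1 ∪ S2 is re-seeded by the
strain-count method applied to its own marker hits (falling back to
random seeds with a small configured k when the pool carries no markers)
and clustered with medoids, i.e. centers that are member contigs.
Dissimilarity is −log P(S ∈ G), the natural metric induced by the scoring
model; the update step exhaustively tries each member as the new medoid
and keeps the minimizer of the mean within-cluster dissimilarity. Both
assignment and swap steps are non-increasing in the summed dissimilarity,
so the iteration converges; on pools of ≤ 12 contigs the fixed point
attains the exhaustive-enumeration optimum (asserted in the tests).

Tie-breaks everywhere are lowest-index / lexicographic, and all
randomness flows from one seeded generator, so runs are bit-reproducible.

## Synthetic communities

The generator emulates exactly the structure the model assumes: each
genome is an i.i.d. nucleotide sequence from its own base composition
drawn from a Dirichlet whose concentration is inversely related to the
`signature_divergence` knob (at 0 all genomes share the uniform
composition; at 0.9 mean inter-genome TNF distance exceeds 3× the
intra-genome fragment distance); genomes are cut into contigs with
truncated-exponential lengths (minimum 2.5 kb, mean ≈ 7.5 kb, optional
31-base overlap, default 0 since overlap is irrelevant to the scoring
model); observed depth of a contig of length L with planted per-sample
mean λ is Poisson(λL)/L; per-genome per-sample means are log-normal
(median 20×, σ = 0.7) or an explicit matrix (e.g. the abundant/rare
two-scale mixture helper: log-normal medians 40× vs 4×). Markers are
bookkeeping hit records — one copy of every catalog marker per genome on
a uniformly chosen contig — and do not alter contig sequences. Optional
chimeras splice the second half of a contig from another genome and mix
the parents' abundances.

What this does *not* emulate: real phylogenetic signal (TNF structure
beyond order-0 composition), sequencing error, strain-level similarity
(closely related genomes sharing composition *and* markers), uneven
marker detection, or assembly artifacts other than simple two-parent
chimeras. Passing tests on these fixtures therefore demonstrate
correctness of the algorithmic machinery under the model's own
assumptions, not field performance on real assemblies.

## Problem sizes and defaults

Test and acceptance runs use communities of 10 genomes × 100 kb × 3
samples (~150 contigs) and two-scale mixtures of 8 genomes; the packaged
model trains on 12 × 150 kb genomes. These sizes were chosen so the full
pipeline exercises every stage (including multi-round recursion on the
hard mixtures) while an entire run remains a few seconds of one-CPU
compute; the algorithms are O(n·k) per iteration in contigs and scale to
real assemblies.

Operational defaults: minimum contig length 1500 bp, minimum assignment
probability 0.80, precision threshold 0.90, recall ladder
0.90/0.60/0.30, prior odds 10, K-means/K-medoids iteration caps 100/50,
round cap 20.

## Known limitations

* The logistic length-bin parameters depend on the training corpus; the
  packaged synthetic model transfers to communities whose
  composition separation resembles its training divergence, and should be
  retrained on reference genomes for real data.
* Centroid coverage (mean of member depths) is a heuristic for the
  Poisson mean of a mixed cluster; a badly mixed cluster has an
  overdispersed depth profile the model cannot represent.
* The quality estimators are only as good as the marker catalog; with few
  or no markers on the residual pool the recursion falls back to random
  seeding and termination relies on the acceptance ladder.
* Contigs are assigned hard labels; no soft/fractional assignment.
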