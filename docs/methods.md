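# Methods

## Expression model and normalization

Input counts are TPM-normalized (`TPM_g = 1e6 * (count_g/length_g) /
sum_g'(count_g'/length_g')`; columns sum to 1e6 per cell) and transformed
with the natural log, `logTPM = ln(TPM + 1)`.  Natural log is used
throughout (including entropies, in nats); all-zero cells are dropped with
a warning by default (configurable), and all-zero genes are retained —
their zero point mass is exactly what the bimodality model addresses.

Per gene, logTPM values are modeled as a zero-inflated two-state mixture:
an atom at zero (undetected / silent cells), an OFF component with mean in
[0, 1), and an ON component with mean >= 1.  Adding i.i.d. `N(0, eps^2)`
noise to the whole matrix (one realization shared by all genes) converts
the atom into a narrow Gaussian so that a standard Gaussian mixture EM can
fit the model.

## Bimodal gene screen

1. **Dip test.** Hartigan's dip statistic is computed with the iterative
   greatest-convex-minorant / least-concave-majorant construction on the
   count scale (dip = half the largest one-sided deviation / n; exact
   reference values: `1/(2n)` for an equally spaced sample, `min(p,1-p)/2`
   for a two-atom mixture, maximum 1/4).  P-values are Monte-Carlo
   calibrated against the n-sample Uniform(0,1) null — the conventional,
   slightly conservative reference — with null tables cached per sample
   size (default 2000 replicates; the calibration run in the acceptance
   script uses 20 000).  The test suite verifies the statistic against an
   independent linear-programming oracle derived directly from the
   sup-norm definition (mode-at-atom configurations solved exactly,
   mode-in-gap configurations bounded by junction-relaxed and gridded
   LPs).
2. **Mixture fit.** Genes passing the dip screen are fitted with 2- and
   3-center Gaussian mixtures (scikit-learn EM: k-means++ init, seeded,
   variance floor `1e-8`, tol `1e-8`, up to 500 iterations, 3 restarts);
   K is chosen by BIC.  The 3-center option absorbs an intermediate mode
   or an imperfectly normalized OFF state.  A fit is flagged failed when a
   component starves (weight below 1/n) — the variance floor itself is not
   a failure, because the zero-inflation spike legitimately sits on it.
3. **Selection.** Bimodal iff dip `p < 0.01` and smallest component mean
   `< 1`.  The legacy additional rule (smallest weight `< 0.6`) is
   available behind a flag but off by default.
4. **Noise sweep.** `optimize_noise` repeats the screen over an eps grid
   and returns the count-maximizing eps (ties -> smallest).  Too little
   noise leaves the zero atom degenerate; too much blurs the valley.

## Binarization and differential activity

The per-gene threshold is the valley (argmin) of a Gaussian-kernel density
(Silverman bandwidth, 512-point grid) on the open interval between the
extreme component means; if the density has no interior minimum the
midpoint of the two smallest means is used.  Cells at or above the
threshold are ON; strictly below, OFF.

Fractional activity averages bits over random within-group windows
(seeded shuffle; windows apportioned to groups by largest remainder,
minimum one; windows never span groups).  Differential activity between
two groups uses the two-sided Fisher exact test on the 2x2 ON/OFF table;
the sample odds ratio is oriented baseline -> derivative (OR > 1 means a
larger ON fraction after differentiation) with the Haldane +0.5 correction
when a cell is zero; p-values are Benjamini-Hochberg adjusted.  Gene-set
enrichment against GMT collections is an upper-tail hypergeometric test
with sets clipped to the declared universe.

## Promoter chromatin states

Peaks are consumed as BED (0-based half-open).  A mark covers a promoter
iff any peak overlaps the strand-aware window around the TSS (default
+/-2 kb, >=1 bp overlap); the two coverage booleans give bivalent /
k4_only / k27_only / unmarked.  The window and overlap rule are explicit
configuration: peak-calling conventions differ between epigenome projects,
and bivalency counts are sensitive to this choice.

## Pseudotime from binarized expression

Cells carry known timepoint labels whose order is fixed by the experiment;
only the ordering *within* clusters is inferred.

- **Distance.** VI(x, y) = 2 H(X,Y) - H(X) - H(Y) over the empirical joint
  distribution of the two cells' gene states (nats).  VI is a metric and
  is invariant to complementing a cell's bits (it compares partitions).
- **Anchors.** For each pair of adjacent clusters the 100 closest
  cross-cluster cell pairs (ascending VI, ties lexicographic) provide
  *connecting cells*; each yields a candidate ordering of its cluster by
  ascending VI from the anchor.  First/last clusters get 100 candidates,
  middle clusters 200.
- **Orientation.** A VI ordering has no intrinsic direction, and the
  minimal-VI anchor is not reliably a boundary cell (low-entropy cells
  attract small VI values globally).  Each candidate is therefore oriented
  by an explicit rule: project the cells on the difference between the
  neighbouring clusters' mean binary profiles (next minus previous; one-
  sided at the ends) and flip the sequence unless the projection increases
  along it.  Blind reversal of "anchored-from-the-following-cluster"
  orderings was evaluated and anti-orients clusters under monotone drift.
- **Consensus.** A probabilistic suffix tree (depth 3, smoothing 1e-3,
  start-of-sequence symbol) is trained on the cluster's candidate
  orderings; greedy generation (each cell once; ties break on cell id) is
  accepted when the PST scores it at least as high as every candidate,
  otherwise the highest-likelihood candidate wins.  This preserves the
  invariant that the returned ordering's log-likelihood is >= that of
  every rejected candidate.  Beam search over permutations was evaluated
  and converges to the argmax candidate, so the simpler rule is kept.
- **Assembly.** Cluster orderings are concatenated in experimental order;
  indistinguishable adjacent timepoints can be merged beforehand.

## Switch calling

Each gene's binarized series over the pseudotime order is fitted with a
two-state Bernoulli HMM by Baum-Welch from a fixed sticky initialization
(stay probability 0.99, emissions 0.1/0.9, uniform start; 100 iterations,
tol 1e-6, emissions floored at 1e-6; states relabeled so ON is the
emission-rich state; constant sequences return the initialization with a
degenerate flag).  Viterbi decoding uses a backward dynamic program with a
greedy forward selection, which yields the lexicographically smallest
(OFF-preferring) maximum-probability path — a deterministic tie-break
verified against exhaustive search.  Switch points are the first cell of
each new state.  A gene *switches* iff its path changes state at least
once and `B_ON - B_OFF >= 0.3` (configurable margin; the separation
requirement operationalizes "well defined" state paths).  Switch groups:
group `2k-1` / `2k` = `k` switches starting from OFF / ON, so group 1 is
"switched on once" and group 2 "switched off once"; zero switches is group
0 (not switching).

## Co-switching network

Mutual information between switching genes' bit vectors (over cells,
nats) is thresholded — by default at the 95th percentile of a
permutation null (bits shuffled within genes, seeded) — and pruned by the
ARACNE data-processing inequality: in every fully connected triangle the
weakest edge is removed when below `min(other two) * (1 - tolerance)`;
removals apply simultaneously after scanning all triangles, so pruning is
order-independent and idempotent.  Connector genes (top-k switching genes
by ascending mean VI to a pathway gene set) interconnect the map.  Each
remaining edge is directed from the earlier- to the later-switching gene
(first switch index), unless the two switch within 10 cells — then it
stays undirected grey.  Directed edges therefore never form cycles when
switch times are distinct.

## Synthetic data

`simulate_groups` emits, per gene and cell: with probability `1 - f` an
OFF value (an exact zero with probability 0.5, else `ln(Y+1)` from a
truncated `N(0.1, 0.2^2)`), and with probability `f` an ON value with
`ln(Y+1) ~ N(on_mean, on_sd^2)` (defaults 2.0 / 0.3; per-gene arrays
accepted); ON dropout (default 0.1) forces zeros.  The OFF state mixes
exact zeros with small positive values because real count data show
distinct zero populations next to low nonzero expression.

`simulate_timecourse` gives each gene a step change of its ON probability
(`p_lo = 0.1` to `p_hi = 0.9`, or the reverse) at a known switch position,
with observation flips at a configurable rate; `drift=True` instead uses
staggered monotone logistic drifts (centers uniform over the course, width
`n_cells/6`), emulating sequential waves of activation rather than one
global ramp — a single shared ramp is degenerate for ordering, since every
cell's marginal entropy is then identical and VI carries almost no time
signal.  Collection labels are assigned from a noisy copy of true time
(sd = 0.1 * n_cells), so adjacent timepoint clusters overlap in
progression, as differentiation asynchrony produces in real time courses
(the motivating data's 72 h and 96 h clusters were indistinguishable).
What the generator does **not** model: library-size variation, UMI
sampling, gene-gene correlation beyond the shared time axis, doublets.
Passing tests therefore demonstrate correctness of the algorithms under
the stated model, not robustness to every artifact of real data.

## Verification scope and known limitations

`scripts/acceptance.py` (about 90 s, one CPU) recomputes: dip type-I
calibration at alpha 0.01 (10^4 uniform genes of 200 cells, 2x10^4-sample
null table), mixture recovery (200 genes x 500 cells), detection
sensitivity/FPR (200 bimodal + 800 unimodal x 500 cells), Viterbi vs
exhaustive search (1000 instances, n <= 12), VI metric axioms (100 random
matrices), DPI vs an all-triangles oracle (30 graphs, <= 30 nodes),
pseudotime rank recovery (three staggered-drift fixtures: 1371 genes, 300
cells, 6 timepoints), switch-position recovery at 10% flip noise (100
genes x 300 cells), and Fisher-test exactness.  Problem sizes mirror the
motivating study's scale where applicable (1371 ordering genes, 6
timepoints) and are otherwise chosen to make Monte-Carlo error small
relative to the bounds checked.

Known limitation: on the drift fixture the full ordering pipeline
typically reaches a mean within-cluster Spearman of ~0.78 +/- 0.05 — just
under the 0.8 working target, and the corresponding acceptance test is
expected to fail at most seeds.  The candidate pools almost always contain
orderings with correlation >= 0.85, but PST likelihood is a typicality
score and correlates only weakly (~0.3) with ordering accuracy, so the
consensus sometimes selects a mediocre, heavily duplicated anchor
ordering.  Rank aggregation across candidates (Borda) reaches ~0.9 on the
same fixtures but is a different consensus rule than the PST-based one
this package implements, so it is not used.
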