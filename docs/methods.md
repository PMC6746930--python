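# Methods

## Model

A paleopolyploidy leaves S homoeologous copies of every ancestral region in
a genome. Measured against an outgroup reference genome that escaped the
event, each copy appears as a track of retained/lost calls over reference
gene ranks. The package quantifies fractionation bias between tracks as a
windowed sign statistic:

* Gene **rank**, not base-pair position, is the coordinate throughout: the
  formulas are defined over genes, and ranks remove assembly-scale effects.
  Ranks are 0-based per chromosome in start order (ties broken by end
  coordinate, then gene id, for reproducibility); all intervals are
  half-open.
* Each reference chromosome c is tiled with consecutive, non-overlapping
  windows of M genes. Non-overlapping tiling makes the window count N_c
  well defined; a sliding variant exists for exploration but is not part of
  the canonical statistic. The trailing window is kept iff it holds at
  least M/2 genes (its denominator is its actual gene count); chromosomes
  shorter than M/2 are excluded. This avoids high-variance tiny windows
  without discarding half a chromosome arm.
* Window i gets retention rates A_ki per track k. The relative difference
  d_i = |A_i − B_i| / (½(A_i + B_i)) flags a window informative (δ_i = 1)
  iff d_i ≥ τ. Windows where both copies are entirely absent give the
  indeterminate form 0/0; they are defined as uninformative (d_i := 0)
  because they carry no directional signal.
* Per chromosome, T_c = |Σ_i sign(A_i − B_i)·δ_i| / n_c with
  n_c = N_c − δ(N_c) informative windows, and the global index is
  P = Σ_c W_c·T_c with W_c = n_c / Σ n_c′ (default) or W_c = N_c / Σ N_c′
  (`weight_scheme="raw"`). Because the weights sum to 1, P ∈ [0, 1]; a
  leading 1/K factor would cap the statistic at 1/K and contradict its
  documented [0, 1] range, so the weighted mean is used as is.
* Chromosomes with no informative window are excluded; if none remains the
  result carries `status="undefined"` and is displayed as 0 with the flag,
  never silently as 0.

### S > 2 subgenomes

The numerator sums signed informative windows over a set of subgenome
pairs (default: all k < j). Two deliberate normalization choices:

* d_i aggregates the **absolute** pairwise relative differences; a signed
  sum would let opposite-signed pairs cancel and misclassify windows as
  uninformative. The divisor is the number of compared pairs
  (`pair_norm="pairs"`), the only choice that reduces exactly to the
  two-track definition at S = 2; dividing by S is available as
  `pair_norm="S"` for fidelity with the alternative published form.
* The term denominator is n_c × |pairs| (`denominator_scheme=
  "informative_pairs"`), keeping T_c ∈ [0, 1] and making the S = 2 case
  coincide with the pairwise statistic to machine precision. The literal
  alternative N_c·C(S,2) − δ(N_c) is kept as `"printed"`; it
  over-normalizes for S > 2 and never exceeds the default.

### Self-reference mode

For a genome whose own structure exposes the homoeology (e.g. a conserved
paleohexaploid used without an outgroup), each region triple designates
one copy as internal reference. Windows are built over that copy's
*retained* genes only; slots the reference itself lost are skipped
entirely, which amounts to a random subsample of the loss record — gene
loss being largely random, this is a sampling experiment rather than a
bias. The two remaining copies form a two-track profile. With
`rotate=True` all three reference choices are evaluated and the mean
reported; under homogeneous loss the rotation spread is small (< 0.1 on
the packaged synthetic hexaploid test).

### Recursive events

For two stacked polyploidies the four tracks are partitioned by the caller
into sibling pairs ((q11, q12), (q21, q22)) produced by the younger event.
The younger (alpha) index computes a two-track term per sibling pair and
pools the two within each chromosome by informative-window-weighted mean
before chromosome weighting; the older (beta) index is the multi-subgenome
statistic restricted to the four cross-pair comparisons. Event assignment
of tracks is input, not inferred.

### Distance matrices

For S ≥ 3 tracks, all pairwise indices form a symmetric zero-diagonal
matrix. Grouping uses average-linkage agglomeration with the cut (2..S−1
groups) maximizing mean between-group minus mean within-group distance —
the published analyses report grouped subgenomes but no explicit cut rule,
so this criterion is this package's own definition, as are the
"integrated" indices (group means of pairwise entries).

### Classification

An event with several (checked genome, reference genome) index values is
classified by their arithmetic mean, allopolyploid iff mean > 0.3
(strict; exactly 0.3 classifies as auto). Per-row values remain the
primary output; the mean is used only for the verdict. On the packaged
transcription of the 24 catalogued angiosperm events this yields 21 allo /
3 auto (87.5% allo), with the three auto calls being the soybean-, apple-
and poplar-specific tetraploidies.

## Subgenome partitioning

Collinear blocks (read from MCScanX-style `.collinearity` or anchor TSV
files; the collinearity inference itself is upstream and out of scope) are
tiled greedily onto S tracks per reference chromosome. The placement unit
is the set of blocks sharing a query chromosome: segments of one query
chromosome descend from one subgenome copy, and the reference scaffold is
what pitches the broken segments back together. Units are sorted by total
anchor count (desc; ties by reference span, query chromosome name,
reference start) and placed on the lowest-index track where they collide
with fewer than `overlap_frac` (default 10%, absorbing block-caller
boundary jitter) of their genes; the residual colliding ranks are trimmed
from the newcomer. Pure block-level placement (`group_by_query=False`) is
available but can interleave complementary segments of different
subgenomes on one track; query-grouped placement recovers planted
subgenomes exactly on well-separated synthetic fixtures and ≥95% of
anchors on shattered ones. Gaps between abutting blocks simply remain LOST
ranks. Tracks are labelled by dominance — descending total retained genes,
exact ties keeping input order so the arbitrary assignment of equally
fractionated tracks is deterministic.

## Fractionation simulator

`simulate_losses` deletes genes in runs: a uniformly random still-retained
gene starts a run, L ~ Geometric(p) (support 1, 2, …; mean 1/p, default
p = 0.5) further still-retained genes are removed in rank order (truncated
at the chromosome end), until the retained fraction reaches the target.
Choosing run starts among retained genes and consuming only retained genes
keeps the marginal run-length distribution geometric on the retained
sequence; the final run may overshoot, bounding the retention error by one
run. `calibrate_from_observed` reverses this: per-track retention is read
off the assignment, and p is fitted by method of moments on observed
lost-run lengths (p = 1/mean). Note that at heavy loss adjacent deletion
runs merge, inflating observed runs and biasing p̂ low; the moment fit is
accurate in the light-loss regime (≥ ~90% retention), which the parameter
recovery test uses.

The default simulated geometry is 10 chromosomes × 2000 genes, M = 100,
τ = 0.05, 100 replicates — a mid-sized plant genome at the documented
window size, large enough that the balanced-loss null mean (≈ 0.10) sits
well below the 0.3 threshold while running in seconds. Replicate r uses
seed `seed + r`, so a published run with seed 1 consumes seeds 1..100;
the generator is numpy's default PCG64, recorded in the config echo.

## Synthetic fixtures

`make_polyploid_fixture` realizes the simulator as on-disk bundles: an
intact ancestor (BED/GFF3/TSV), S fractionated subgenome copies as a query
gene table, anchors in both supported collinearity dialects, and a truth
table. Scenarios: `balanced` (r = 0.6, 0.6), `biased` (0.75, 0.40),
`two_round` (0.75, 0.75, 0.45, 0.45 with sibling pairing), and
`decaploid_grouped` (five tracks, planted 2+3 retention-regime structure).
Blocks can be shattered into segments and, optionally, redistributed onto
fresh query chromosomes — always within a subgenome; inter-subgenome
chromosome fusions are not modelled. What the fixtures deliberately omit:
tandem duplications and dispersed paralogs (every query gene has exactly
one true ancestral slot), translocations between reference chromosomes,
gene family turnover, and annotation noise. Passing tests therefore
demonstrate correctness of the statistic and the reconstruction logic
under clean homoeology, not robustness to the messiness of real
assemblies — on real data the credibility of the index depends on the
quality of the upstream collinearity calls and on using a close,
well-assembled reference.

## Numerical notes

* sign(0) = 0; such windows are already uninformative by construction.
* τ must lie in (0, 1); d_i ≤ 2 always (it is 2|A−B|/(A+B)), so τ ≥ 2
  would flag nothing.
* All computations are deterministic given inputs and seeds: stable sorts
  everywhere, no hidden RNG.
* The production implementation is vectorized; an independent pure-Python
  loop transcription of the formula is kept in the test suite and agrees
  to 1e-12 on randomized profile suites.

## Known limitations

* The greedy tiler is near-optimal for the long sparse blocks that
  fractionation produces but is not an exact interval scheduler; heavily
  rearranged genomes should use externally curated per-track anchor files,
  which bypass partitioning entirely.
* Published index values for real genomes depend on genome assemblies and
  external collinearity runs and are not reproduced here; they enter only
  as classification inputs via the packaged event table.
* The geometric run-length model is a single-parameter idealization of
  "near-geometric" empirical loss patterns.
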