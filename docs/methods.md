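# Methods

This note records the models, conventions and numerical choices behind
`modtrt`, and what the synthetic experiments do and do not demonstrate.

## Synthetic cohort model

A cohort is `n_subjects × 2 sessions (test, retest) × 2 runs (LR, RL)` of
region time series. Each run's rows are i.i.d. draws from a zero-mean
multivariate normal whose correlation matrix is block-constant: `rho_in`
inside a planted module, `rho_out` elsewhere. Subject- and session-level
variability enter as additive offsets on the correlations:

* `b_s ~ N(0, sigma_subject²)`, drawn once per subject and shared by both
  sessions — the between-subject variance component;
* `e_{s,t} ~ N(0, sigma_session²)`, drawn per subject-session — the
  within-subject (occasion) component.

Both runs of a session share one target matrix, so run-to-run differences
are pure sampling noise, mirroring a two-run session acquired with opposite
phase encodings. Effective correlations are clipped to `[0, 0.99]` (keeping
Fisher-z finite) and the target is repaired to the nearest positive
semidefinite correlation matrix by eigenvalue clipping (tolerance 1e-10)
followed by unit-diagonal rescaling. Seeds are hierarchical: the master seed
plus a fixed `(subject, stream)` integer key feeds a `SeedSequence`, so
adding subjects never perturbs earlier subjects' draws and identical specs
reproduce cohorts bit for bit.

Defaults (`n_subjects=45`, `n_timepoints=1200`, 4 modules of 10 on 40
nodes, `rho_in=0.5`, `rho_out=0.1`, `sigma_subject=0.10`,
`sigma_session=0.05`) mirror a 45-subject, 1200-frame test–retest cohort;
the variance magnitudes are chosen for testability — empirical
between-/within-subject FC variances of real cohorts are not publicly
pinned down, and nothing here emulates BOLD spectra, hemodynamics, motion
or physiological noise. Only the correlation structure feeds the pipeline,
which is exactly the quantity the pipeline consumes.

## Construction conventions

Pearson → Fisher-z → LR/RL average → zero negatives → proportional
threshold, in that order (runs are averaged in z-space). The diagonal is
excluded everywhere and stored as 0 (atanh(1) diverges). Constant time
series raise an error naming the node rather than propagating NaN.
Thresholding keeps the `ceil(density · n(n−1)/2)` largest strictly positive
upper-triangle weights — weights preserved, ties broken by (weight
descending, row index, column index) so results are run-to-run identical;
if fewer positives exist, all are kept with a warning.

## Module detection

All three optimizers maximize the same quality function Q (resolution fixed
at 1) and return canonical partitions (modules numbered 1..A by first
appearance in node order), which makes partition equality well defined.

* **Louvain**: phase-1 sweeps visit nodes in a seed-shuffled order, moving a
  node to the neighbouring community with the largest gain (tolerance
  1e-10, ties to the lowest community id); phase 2 collapses communities to
  super-nodes whose self-loops carry twice the internal weight, so plain row
  sums remain strengths and Q is preserved across levels.
* **Tabu search**: starts from singletons; each iteration applies the best
  non-tabu single-node move (to an adjacent community or a fresh
  singleton), accepting downhill moves; reversals are tabu for
  `tenure = max(5, n/10)` iterations unless they beat the best Q seen
  (aspiration); stops at `100·n` iterations or 200 non-improving ones and
  returns the best partition seen. Exact ties among best moves are resolved
  by the seeded generator.
* **Spectral**: recursive leading-eigenvector bisection of the generalized
  subgraph modularity matrix `B(g) = B − diag(row sums of B over g)`, each
  split fine-tuned by greedy single-node sign flips; a group is indivisible
  when the leading eigenvalue or the split's Q contribution is ≤ 1e-12. The
  eigenvector sign is fixed by forcing the lowest-index entry nonnegative,
  making the detector fully deterministic.

**Consensus clustering** runs a detector R = 50 times (seeds `seed+1 ..
seed+R`), thresholds the co-assignment association matrix at tau = 0.5
(diagonal dropped when it is reinterpreted as a network), re-runs the
detector on it, and iterates to unanimity with a 20-iteration cap; a
non-converged ensemble returns its best-Q member on the association matrix.
A deterministic detector converges in one iteration, and R = 1 degenerates
to a single run. Infomap is deliberately not reimplemented; an adapter
contract (edge-list file in, `node module` lines out) lets any external
executable participate as a detector, consensus wrapper included.

## Group-level frameworks

*Ave* averages the subjects' nonnegative z-matrices, thresholds the mean
network to the working density, and consensus-detects on it. *SimMax*
returns the member partition with the highest mean pairwise NMI to the
others (the framework only requires "most similar"; NMI is the
partition-similarity workhorse and is the choice made here — lowest subject
index on ties). *Consensus* thresholds the cross-subject association matrix
at tau and reclusters it. Test and retest cohorts each get their own group
partition; reliability compares the two.

## Metrics and reliability conventions

All five metrics use the full positive-connection FC matrix — a different
object from the 10%-density detection network, deliberately. Zeros left by
negative clipping are treated as absent edges, so intra-/inter-modular
means run over strictly positive pairs. WD uses the population standard
deviation (keeps two-node modules finite); a module with zero spread, or a
singleton, gets WD = 0; an isolated node gets PC = 0.

NMI uses the natural log with `0·log 0 = 0`; two single-module partitions
score 1, exactly one single-module partition scores 0, and identical
partitions (characterized exactly by `n10 = n01 = 0`) return 1.0 without
floating-point division. RI is the unadjusted Rand index. ICC is the
two-way consistency, single-measures form computed from explicit ANOVA sums
of squares (no fitted mixed model, no estimator ambiguity); negative
estimates clamp to 0; a zero-variance table returns 0; bands are
left-closed: [0, .2) poor, [.2, .4) fair, [.4, .6) moderate, [.6, .8) good,
[.8, 1] excellent. Nodal metrics get one ICC per node plus mean and
quartile summaries.

## Pipeline

The individual pipeline detects each subject-session's own partition on its
thresholded network and evaluates metrics with it; the group pipeline warps
each session's group partition onto every subject. Subject-sessions get
disjoint seed blocks, so the experiment is deterministic end to end under a
fixed master seed. `run_full_experiment` writes per-level reports, long
metric tables and a manifest with sha256 checksums; with `--resume`,
reports that match their manifest checksums are not recomputed.

## Experiment scales and what the synthetic results mean

Tests and the acceptance suite run at desk scale, chosen so the whole suite
completes in a few minutes on one CPU: planted-recovery fixtures use 40
nodes and 10 seeds; the qualitative analogs use 20 seeds × 3 session-noise
levels (`sigma_session ∈ {0, 0.15, 0.4}`, T = 300) for the monotonicity
check, 8-subject cohorts with deliberately ambiguous contrast
(`rho_in = 0.3`, `rho_out = 0.2`, T = 80) for the framework ordering, and
T = 80 fixtures for consensus dispersion. The ambiguity is the point: with
strong signal every framework saturates at NMI ≈ 1 and orderings are
degenerate; the SimMax instability (a medoid subject that jumps between
sessions) only expresses itself once individual partitions genuinely
disagree.

One property of the generator deserves emphasis. Because all within-module
entries of a block share latent factors, their sampled correlations err
*together*: the block-mean Fisher-z fluctuation is comparable to the
entry-level noise, and the ratio is invariant to run length or averaging.
A global top-10% edge cut therefore tends to rank whole blocks, and when a
planted module holds more than roughly `0.1·(n−1)+1` nodes, part of the
weakest block's nodes can lose all retained edges and fall out as
singletons even at arbitrarily long run lengths. With modules of size
≤ n/10 (e.g. 8 modules of 5 on 40 nodes) every within-module edge survives
the cut and recovery is exact. Real FC data shares this correlated-error
character, so this is a feature of the simulation worth knowing about, not
an implementation artifact — but it also means synthetic recovery scores
under the 10% threshold are sensitive to planted geometry in a way
independent-noise intuition does not predict.

Passing tests on these cohorts demonstrate the statistical machinery —
variance components propagate to ICC as theory predicts, detectors reach
exhaustively verified optima, consensus reduces dispersion, group
frameworks order as expected under noise. They do not demonstrate anything
about preprocessing choices, atlas construction, hemodynamics or other
properties of real fMRI that the generator does not model.

## Known limitations

Signed-network modularity, overlapping/hierarchical modules, map-equation
internals, ICC absolute-agreement variants, bootstrap confidence intervals
and adjusted agreement indices are out of scope. Tabu search is quadratic
per iteration and intended for networks up to a few hundred nodes.
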