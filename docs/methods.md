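# Methods

This note documents the models, algorithms and design choices behind
`converge`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, with
which defaults, and what the synthetic studies do and do not demonstrate.

## The question the pipeline answers

A transcript assembled from an organism's transcriptome sometimes matches a
distant clade (here: a mosquito transcript matching plant proteins) better
than its own relatives. Two fixed phylogenetic hypotheses then compete for
the aligned protein sequences:

* **H0** — the accepted species phylogeny: the focal taxon stays with its
  relatives (mosquito among insects);
* **H1** — the alternative phylogeny grouping the focal taxon with the
  putative donor clade (mosquito inside the plants).

Only branch lengths are fitted; the topologies are inputs. H1 may come from
any source — in this package typically from the distance-based gene-tree
builder (`treebuild`).

## Substitution models

Likelihoods use empirical amino-acid models assembled from a symmetric
exchangeability matrix S and equilibrium frequencies π:

    Q_ij = S_ij π_j (i ≠ j),  Q_ii = −Σ_{j≠i} Q_ij,

rescaled so −Σ_i π_i Q_ii = 1. With this normalization a branch length is
the expected number of substitutions per site under every model, so lengths
are comparable across models. The bundled matrices are the published
Dayhoff and WAG data, shipped as plain-text files (lower triangle in
ARNDCQEGHILKMFPSTWYV-canonical order plus 20 frequencies) and validated at
load time (Σπ = 1, symmetry, positivity). The `+F` option replaces π with
empirical alignment frequencies (a 0.5 pseudocount keeps absent residues
positive, since π_j > 0 is required for reversibility).

P(t) = exp(Qt) is computed by symmetric eigendecomposition of
diag(√π) Q diag(1/√π); one decomposition per model serves every branch and
rate category. Entries are clamped at 0 against round-off.

Among-site rate variation uses the discrete-gamma approximation: k
equal-weight categories whose rates are the *category means* of
Gamma(α, α) (means, not medians, keep the mixture mean exactly 1), plus an
optional invariant class of weight p_inv; the variable-class rates are
scaled by 1/(1 − p_inv) so the overall mean rate stays 1. A site
contributes invariant-class mass only when its non-missing residues are all
identical (all-missing sites count as likelihood 1). The CAT approximation
used by some fast ML programs is deliberately not reproduced: discrete
gamma is deterministic, testable, and is the heterogeneity family the
hypothesis test itself uses. α, k and p_inv are user inputs; the package
does not estimate them.

Missing data: `-` and `X` are equivalent, and both enter the pruning
recursion as all-ones partial vectors (the standard missing-data
convention; the data source does not distinguish the two cases in any way
that matters downstream).

## Likelihoods and branch fitting

Sitewise log-likelihoods come from Felsenstein pruning, implemented as
message passing on the unrooted tree: the message along the directed edge
u→v is the likelihood of the data on u's side conditional on the state at
v. Messages are rescaled per category and site, with log-normalizers
accumulated separately, so large trees cannot underflow. Because the model
is reversible and mean-rate normalized, the likelihood is invariant to root
placement (pulley principle); the tests assert this to 1e-10.

Branch lengths are fitted coordinate-wise: the likelihood restricted to one
branch needs only the two messages flowing into it, and is maximized by
bounded scalar search (golden section with parabolic acceleration) on
[1e-8, 20]. The upper bound prevents the optimizer escaping onto the
stationary plateau; the lower bound keeps P(t) well-conditioned. Rounds
over all branches repeat until the total log-likelihood improves by less
than `tol` (default 1e-4; the bootstrap studies use 1e-2 — the LRT noise
this adds, ~0.04 units, is negligible against its sampling spread).
Messages are invalidated lazily, so one round costs O(branches) message
updates rather than O(branches²). Hitting the round limit sets a warning
flag on the result instead of raising.

## The convergence statistic and test

Per site, ΔSSLS_i = lnL_i(H0) − lnL_i(H1): negative values support the
convergent hypothesis, positive the species phylogeny. Globally,
LRT = 2(lnL(H1) − lnL(H0)) = −2 Σ_i ΔSSLS_i, an identity the tests check
to 1e-10 on every paired run.

Because the hypotheses are not nested, the LRT is calibrated by parametric
bootstrap rather than a χ² reference: branch lengths of both topologies
are fitted to the observed alignment; replicate alignments of the same
length are simulated under the *fitted H0*; both topologies are re-fitted
on every replicate (fixing them would bias the null); and the p-value is
the fraction of simulated ratios ≤ the observed one, ties counting. At the
5% level, p > 0.95 decides "H1 better", p < 0.05 "H1 worse", anything else
is inconclusive. Model parameters (α, p_inv, frequencies) are held fixed
throughout the bootstrap. Identical seeds reproduce every result
bit-for-bit; replicate seeds are drawn from a single generator seeded by
the user.

### Calibration is regime-dependent

The LRT between two *fixed* topologies is not pivotal: its null
distribution — in particular its mean — depends strongly on the branch
lengths, which the bootstrap must estimate. When the data resolve the
quartet decisively (internal branch ≈ terminal branches), the simulated
null and the observed statistic co-track the fitted lengths, the p-value
concentrates mid-range (measured: p ∈ [0.31, 0.66] across 40 null trials
on a quartet with all branches at 0.2), and the test essentially never
rejects in either direction: conservative, never anti-conservative.
The tails regain mass as the internal branch shrinks (measured upper-tail
rejection over 50–60 null trials: 0% at internal 0.2, ~2% at 0.05–0.02,
~2% at 0). Following the standard practice of evaluating a test's size at
the least-favorable null configuration, the calibration study uses a
quartet with terminal branches 0.2 and the internal branch at zero — the
boundary where the two topologies' distributions touch. Even there the
measured type-I error at the 5% level stays somewhat below nominal
(≈1–4%): the test errs on the side of caution everywhere, and users
should read "inconclusive" on strongly resolved data as exactly that.

## Distance trees

p-distances (differing residues / comparable residues) use pairwise
deletion by default — complete deletion can annihilate gappy transcriptome
alignments; both modes are available and a pair with zero comparable sites
is an error. Neighbor-Joining is the classic Saitou–Nei agglomeration on
the Q-criterion with two determinism rules: ties break toward the lowest
index pair, and a negative branch length is clamped to zero with the
deficit moved to its sister edge. On additive inputs NJ provably recovers
the generating topology and path lengths; the tests verify this on random
8-taxon trees. Bootstrap support resamples alignment columns with
replacement, rebuilds the NJ tree, and annotates each internal edge of the
full-data tree with the percentage of replicates containing the same
bipartition (no consensus tree is built). A replicate that produces an
incomparable pair is redrawn, at most ten times.

## Candidate screening

Similarity-search output is consumed as the standard 12-column tabular
format; rows with E-value above the cutoff (default 1e-3) are dropped at
parse time. Subjects map to groups (plant / insect / other) by
longest-prefix match against a user table; unmatched subjects become
"other" and are counted. Each query is classified from its best plant and
best insect identities:

* **i** — plant > 95 and insect ≥ 85 (highly conserved protein);
* **ii** — plant > 90 and insect < 85 (the informative intermediate);
* **iii** — plant hit present, no insect hit at all;
* otherwise **not_plt**, including ties (insect ≥ plant is read
  conservatively as no plant signal).

These boundaries describe observed transcripts rather than crisp rules, so
all four are configuration keys with the printed values as defaults.
Fisher's exact 2×2 test is computed in log space by summing hypergeometric
probabilities ≤ the observed table's (1e-12 absolute slack absorbs
floating-point ties); no multiple-testing correction is applied by default
(a Benjamini–Hochberg helper exists). Relative expression uses
2^−ΔΔCt with a reference gene and calibrator sample.

## The synthetic-data generator

Alignments are simulated site-independently: per site a rate category is
drawn from the (+G/+I) weights, a root state from π, and states propagate
along each edge by sampling transition-matrix rows. A convergent mixture
assigns each site to the alternative topology by an independent
Bernoulli(f) flag — sites are exchangeable; no autocorrelation of
convergent sites is modelled. Rate categories are drawn per site, not per
sequence (standard among-site rate variation semantics). All generators
are pure functions of their integer seed; the f = 0 mixture is bit-exact
with the pure simulator.

The demo fixture mirrors the shape of the motivating analysis: one focal
"mosquito" taxon, four plant and four insect taxa; H0 keeps the mosquito
with the insects, H1 places it inside the plants (sister to tomato).
Defaults: WAG + Γ4 (α = 0.8, a typical fitted shape for protein data),
200 sites (a typical protein length at this scale), terminal branches
0.1–0.2 and internal branches 0.05–0.3 expected substitutions/site.

What the simulations do **not** emulate: indels (gaps appear only if
present in real inputs), alignment error, compositional heterogeneity
across lineages, site-specific profiles, and autocorrelated convergent
regions. Passing the synthetic studies therefore demonstrates the
correctness and calibration of the *method under its own model*, not
robustness to these real-data complications.

## Problem sizes of the bundled studies

The statistical studies in the test suite and the acceptance script run at
desk scale, chosen as the package's own study design: likelihood oracle
equivalence on 20 random trees of ≤5 leaves (exhaustive state enumeration
is exact there); calibration with 100 trials × 99 bootstrap replicates
(weak-signal quartet, 200 sites); power and monotonicity at convergent
fractions {0, 0.25, 0.5, 1.0} with 20 trials per level (9–19 replicates,
enough to resolve the 5% decision rule); NJ recovery on 50 random 8-taxon
trees; branch-length recovery from 10,000 simulated sites; Fisher's test
against exhaustive enumeration on 200 random tables. Full-scale analyses
(e.g. 1000 bootstrap replicates) are a command-line flag away and scale
linearly.

## Known limitations

* α and p_inv are not estimated; model choice among +G/+GI/+I is the
  user's.
* Fixed-topology LRT calibration degrades to conservatism under strong
  signal (see above).
* The screen's identity thresholds are descriptive defaults, not learned
  decision boundaries.
* No joint test across genes; each alignment is tested on its own, with no
  cross-gene multiplicity correction by default.
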