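# Methods

This note documents the statistical procedures implemented in `allocomm`,
their assumptions, the tunable parameters with their defaults, the design
choices that were genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## Conformational ensembles

An ensemble is F ≥ 2 snapshots of A atom coordinates (Å) for one protein
chain, with residue metadata.  Frames are equally weighted: the ensemble is
treated as the full population of observed conformations, so all variances
divide by F, not F − 1.  Residues without a Cα atom are excluded with a
logged warning and every matrix is sized to the retained residues; internal
indexing is contiguous and 0-based, while all reports use the author
residue numbers.

Superposition fits each frame (rotation + translation by Kabsch SVD,
computed on a selection — Cα by default, backbone available — applied to
all atoms) to the mean structure, refreshing the mean and repeating until
the mean stops moving (tolerance 1e-10 Å on any coordinate, at most 500
rounds).  Iterating to a fixed point rather than a fixed small number of
rounds makes the operation idempotent, which downstream code relies on; on
realistic frame counts it converges in a handful of rounds, and the many
hundreds of rounds possible on 3–5-frame toys are still cheap.  Inter-residue
distances, and therefore commute times, are superposition-invariant;
superposition matters only for RMSF and PCA.

Per-residue RMSF is the per-atom root-mean-square displacement about the
mean structure, averaged over the residue's selected atoms.  For isotropic
Gaussian displacements of per-axis standard deviation σ the expected value
is σ√3, which the tests verify by Monte Carlo.

## Commute times and threshold calibration

CT(i,j) is the population variance over frames of the Cα(i)–Cα(j)
distance, computed with a chunked two-pass algorithm (mean pass, then
squared-deviation pass) so it agrees with a textbook two-pass oracle to
1e-10 relative error; the one-pass E[x²] − E[x]² form was rejected as
numerically unsafe when distances are large compared to their fluctuation.

The fast/slow threshold ε is the smallest value at which the
best-connected residue reaches the target fraction (default 0.20) of other
residues with CT ≤ ε.  Implementation: per residue the candidate is the
k-th smallest off-diagonal CT of its row with k = ceil(target·(N−1)); ε is
the minimum candidate over residues.  This equals an exhaustive scan over
the sorted unique CT values with ties broken toward the smaller value.  At
target 1.0 the limit is the smallest row maximum — one residue covering
everything — not the global matrix maximum.  Rigid ensembles (all-zero CT)
raise a calibration error instructing a manual ε.

## Contacts and hydrogen bonds

The reference non-bonded interaction record is reimplemented as geometric
proximity: a residue pair interacts in a frame when any inter-residue
heavy-atom pair is within 4.0 Å, or any N/O–N/O pair is within the
hydrogen-bond cutoff of 3.5 Å (no angle criterion, hydrogens not
required).  Persistence requires interaction in ≥ 50% of the frames;
sequence-adjacent pairs (|Δseq| ≤ 1) never enter the persistent graph.
Cα-only ensembles fall back to a 7.0 Å Cα distance criterion with a logged
warning — roughly the Cα separation below which side chains of
non-adjacent residues can interact.  The hydrogen-bond table reports
per-atom-pair occupancies; when one atom is nitrogen and the other oxygen
the nitrogen takes the donor role, otherwise the lower residue index does
(a reporting convention only — without hydrogens the distance criterion is
symmetric).

## Pathway growth

A neighbor of residue i must (a) be ≥ 2 apart in sequence (the exclusion
window is configurable, e.g. ±4 to ignore intra-helix contacts), (b) be a
persistent contact and (c) satisfy CT ≤ ε.  Pathways from a start residue
are enumerated depth-first: one initial path per neighbor; a path extends
by any neighbor of its terminal residue that is not yet a member and has
CT ≤ ε to every current member (growth attaches to the terminal only —
paths, not cliques — while the all-members test enforces the clique-like
communication condition).  Extension candidates are ordered by ascending
CT to the terminal, ties by residue index, making the enumeration
deterministic.  Maximal paths are emitted and deduplicated as ordered
tuples; whether the original procedure was exhaustive or greedy is not
documented, so exhaustive-with-dedup is used and flagged here.  A per-start
cap (default 10⁵ paths) bounds combinatorial blowup; truncation sets an
explicit flag and is never silent.  "Number of paths" counts maximal paths
only; an isolated start residue scores path length 1 and 0 paths.

## PCA and local feature analysis

PCA diagonalises the 3N×3N covariance of superposed Cα fluctuations; the
smallest mode count m whose cumulative eigenvalue fraction reaches the
retention target (default 0.80) is kept.  A warning is logged when F ≤ 3N
(rank-deficient covariance).

The LFA conventions, partly under-determined in the literature this
follows, are fixed as:

* outputs O(t) = Σ_{k≤m} ψ_k a_k(t) with a_k the mode projections —
  unwhitened, so the full basis reproduces the fluctuations exactly;
* residual correlation P(i,j) = Σ_α Σ_{k≤m} ψ_k(3i+α) ψ_k(3j+α), α over
  x,y,z, normalized to unit diagonal before thresholding (thresholding raw
  sums would be scale-dependent).  With all 3N modes P is the identity:
  the outputs are completely decorrelated by space;
* sparsification scores reconstruction on the λ-weighted output covariance
  C(i,j) = Σ_α Σ_k λ_k ψ_k(3i+α) ψ_k(3j+α).  The empty-set reconstruction
  is the zero function, so the first seed is the maximal-output-variance
  residue; thereafter the error after conditioning on seed set M is the
  Schur complement diag(C − C[:,M] C[M,M]⁻¹ C[M,:]) (pseudo-inverse with a
  logged warning when the seed submatrix is rank-deficient), and the next
  seed is the unchosen index of maximal error, ties toward the lower
  index.  The error trace is non-increasing and reaches ~0 at |M| = N.

The number of seeds defaults to the number of retained modes, capped at N
(noise-dominated ensembles can retain more modes than residues).

## Independent dynamic segments

Spatial proximity uses the frame-averaged minimum inter-atomic distance
between residue pairs; two residues are neighbors below d_threshold
(default 6.0 Å, a typical residue-contact shell — the source value is not
printed, so this default is a reconstruction).  A segment grows
breadth-first from its seed, candidates examined in ascending mean
distance to the seed (ties by index); a candidate is admitted only if the
aggregated residual correlation over the tentative member set stays at or
above ρ_threshold, and rejected candidates are not revisited.

The aggregation over the cluster's P submatrix is typographically lost in
the source; the **minimum off-diagonal entry** is the default here, with
the mean available as an option.  The mean was tried first and proved
indiscriminate: once a cluster is large, admitting one residue
uncorrelated with every member barely moves the mean, and on planted-block
benchmarks mean-aggregated segments systematically bled ~30% past the
block boundary, violating the recovery contract the method is meant to
satisfy.  The min rule parallels the pathway growth rule (a new member
must be coupled to *all* current members) and recovers planted blocks
exactly.  A singleton segment reports an internal correlation of 1.0
(self-correlation).

ρ_threshold defaults to the 98.75th percentile of off-diagonal |P| (ranked
exactly, so 1.0–1.5% of cross-correlations lie above it); a manual
override is accepted.  The percentile rule presumes a graded correlation
spectrum.  On two-level planted designs (correlations piled at ρ_in and
ρ_out) the percentile lands inside the upper pile and the planted-recovery
benchmarks instead set ρ explicitly to 0.5, the midpoint discriminating
the planted levels — a property of those degenerate fixtures, not of the
method.

## Convergence diagnostics

C(t) is the mean over residue pairs of the normalized time
autocorrelation of the Cα distance series: each series is mean-centred and
variance-normalized (so C(0) = 1 and the pre-factor is one over the number
of contributing pairs), the autocovariance is the biased FFT estimator,
and constant series are excluded with a warning.  The exponential model
A·exp(−t/τ) is fitted by nonlinear least squares over lags from 0 to the
first zero crossing (or the end of the curve), seeded analytically (τ from
the early log-slope, A from C(1) pulled back one decay step); the Pearson
correlation between curve and fit is reported alongside.  An additive
offset variant is available behind a flag; the default has none.  A curve
that fails to decay (C end ≥ C start, or non-positive C(1)) sets a failure
flag instead of coefficients.  On AR(1) fixtures the fitted τ is stable
under temporal subsampling by 2 (τ in subsampled units doubles back to the
original within 10%).

## Synthetic ensembles

The generator emulates the *statistical* structure the analysis detects,
not physics: no force field, no Boltzmann weighting, no solvent.  Each
residue is displaced rigidly by a zero-mean Gaussian vector, isotropic in
x,y,z and correlated across residues per the design: ρ_in inside planted
blocks, ρ_out between blocks, independent background of per-axis variance
σ² (default 1 Å², a typical loop-region Cα fluctuation scale).  A slightly
indefinite design correlation is eigenvalue-clipped to PSD with a warning;
a grossly indefinite one raises a design error naming the offending
blocks.  Chain residues share one common displacement plus independent
jitter of per-axis variance v/2, so their pairwise distance variance is ≈ v
(default 0.01 Å², two orders below background commute times).  Reference
geometries place Cα atoms 3.8 Å apart on a line or an idealized helix
(2.3 Å radius, 100° twist, i→i+3/i+4 spatial proximity); each residue
optionally carries a donor-N and acceptor-O pseudo-atom for contact and
hydrogen-bond tests, and `plant_contacts` positions acceptor atoms to hit
an exact per-pair occupancy.  One seeded generator per ensemble makes every
fixture bit-reproducible.

What passing synthetic tests shows: the estimators implement their
definitions (oracle equivalence), the calibrations hit their bands, and
planted signal well separated from background is recovered.  What it does
not show: behavior on real MD ensembles with anharmonic, multi-basin
dynamics, anisotropic correlations, or graded correlation spectra — the
thresholds' *discriminative* performance there is inherited from the
method's design, not demonstrated by these fixtures.

## Benchmark problem sizes

The standard calibration benchmark is a 100-residue, 1000-frame background
ensemble; planted-recovery benchmarks use 40 residues × 5000 frames (4
blocks of 8) and 30 residues × 2000 frames (4-member chain), 20 seeded
replicates each.  These sizes put sampling error well below the tested
tolerance bands while keeping the whole suite interactive.

## Known limitations

* Single chain, no periodic-boundary imaging, no solvent handling; mmCIF
  and trajectory writing are out of scope.
* Contact typing is geometric only — no aromatic/π or salt-bridge classes,
  and no donor/acceptor chemistry beyond the N/O element rule.
* Commute times come from the ensemble only; elastic-network (Kirchhoff)
  commute times are not implemented.
* Exhaustive pathway enumeration can explode on dense fast-contact graphs;
  the cap truncates deterministically but then under-reports path counts.
* The ρ percentile calibration is inappropriate for two-level correlation
  spectra (see above); inspect the |P| histogram before trusting the
  automatic threshold on unusual data.
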