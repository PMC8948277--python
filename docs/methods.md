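# Methods

`connfp` implements the analysis chain used to ask whether the functional
connections that make a person's connectome *identifiable* are the same
connections that *predict* that person's behaviour. This note documents the
models and procedures, the synthetic study conditions, and the numerical
and design choices that were genuinely open.

## Connectome construction

A functional connectome for one subject and session is the Pearson
correlation matrix of nodal time courses (or a precomputed matrix supplied
as a dense delimited file). Runs within a session are averaged on the r
scale, then the session matrix is Fisher r-to-z transformed (arctanh, with
r clipped to ±(1 − 1e−7) so z stays finite), and the upper triangle is
vectorized. The edge indexing is fixed package-wide: 0-based, row-major
over pairs (i, j) with i < j — the order of `numpy.triu_indices(n, 1)` —
so edge k means the same node pair in every vector.

Two conventions here were open and are pinned as follows:

* "z-scoring" a connectivity matrix means the Fisher transform, the
  convention of the fingerprinting literature; per-vector standardization
  is available as an alternative reading but does not change
  identification (Pearson correlation is invariant to affine per-vector
  maps), only the variability statistics.
* Runs are averaged before the z transform (average on r, then z).

## Identification and differential power

Identification correlates each subject's session-1 edge vector with every
subject's session-2 vector and picks the argmax (and the same in the
reverse direction); a hit is a correct self-match. Argmax ties break to
the lowest subject index and are logged. The permutation null randomises
the identity labels of the database vectors; p is the proportion of
permutations whose accuracy strictly exceeds the observed accuracy, so the
chance level is 1/S.

Differential power (DP) decomposes the identification statistic edge by
edge. With per-vector centered, unit-norm session vectors x̃ and ỹ, the
edgewise product φ_i(j,k) = x̃_{j,i}·ỹ_{k,i} sums over edges i to the
Pearson r used in identification. For edge i and subject j the empirical
exceedance probability is

    P_i(j) = [#{k≠j: φ_i(j,k) > φ_i(j,j)} + #{k≠j: φ_i(k,j) > φ_i(j,j)}]
             / (2(S−1)),

clamped below at 1/(2(S−1)) (a standard pseudo-count that keeps the log
finite while preserving ranking), and DP_i = Σ_j −ln P_i(j). Comparisons
are strict; ties do not count as exceedance, which means an edge that is
numerically identical for everyone clamps to the maximal DP — a documented
degenerate case to look for when reviewing masks. Vectors are centered
before normalization (`dp_center` in spirit); this keeps the φ
decomposition exactly consistent with the identification correlation.

Percentile masks keep the top ⌈((100−pct)/100)·E⌉ values (e.g. 358 of
35,778 edges at the 99th percentile of a 268-node parcellation). Selection
is by value, so ties at the cutoff can enlarge a mask; an all-constant
vector is rejected.

## Connectome-based predictive modelling

CPM per training fold: Pearson-correlate every edge with the score,
threshold the two-sided p (default 0.01; 0.001/0.005/0.05 supported),
split the surviving edges by correlation sign, sum each set into summary
scores S⁺ and S⁻ per subject, and fit y = a + b·S by least squares per
side (or a bivariate fit for `model_side="both"`). Test subjects are
scored with the training fold's edge sets and coefficients. The protocol
is 10-fold cross-validation repeated 100 times with fresh shuffled
size-balanced partitions; per-subject predictions are averaged over
repeats, and an edge's selection frequency is its selected-fold count over
all k·n_repeats folds. Evaluation is the Spearman correlation between
averaged predictions and measured scores (Pearson reported alongside),
with a right-tailed permutation p = #{perm ρ > observed ρ}/(n_perm + 1)
obtained by shuffling the measured scores against the fixed averaged
predictions. Prediction uses the mean of the two session matrices per
subject (a config switch exposes single sessions). Subjects with missing
scores are dropped case by case. A fold whose selected set is empty
predicts the training mean for that side (logged), keeping the CV intact.

Two variants share the repeated-CV machinery:

* **Fixed-edge control** — feature selection is replaced by a fixed mask
  (here: the discriminatory mask), split into positive/negative sets by
  each edge's training-fold correlation sign. This asks whether
  discriminatory edges can predict behaviour directly.
* **Linear SVR** — an L1-regularised linear model with epsilon-insensitive
  loss (strength 0.0035) fitted on all edges per fold; the fold's
  "selected" edges are those at or above the 99th percentile of |weight|.
  The printed hyperparameter combination this emulates mixes two
  regularisation idioms; the L1 reading is pinned here and the per-fold
  weight threshold (top 1%) is a documented choice.

The predictive mask of a behaviour keeps edges selected in at least 80% of
folds (inclusive). Prediction p values across behaviours are
Benjamini–Hochberg corrected as one family; overlap p values are reported
uncorrected.

## Overlap statistics

* **Single edges.** Observed statistic |A ∩ B|. The null rewires the
  predictive (or SD) mask with degree-preserving double edge swaps —
  10·|mask| attempted swaps; no self-loops or duplicate edges; the degree
  sequence is exactly preserved — while the discriminatory mask stays
  fixed. p = (#{null ≥ observed} + 1)/(n_perm + 1): ties count as
  exceedance and the add-one form never returns 0. Rigid graphs (e.g. a
  star) cannot mix and are returned unchanged; this is logged, not fatal.
* **Network cells.** cells[a,b] = 100 · (selected edges with endpoints in
  networks {a,b}) / (possible edges in {a,b}); cells with no possible
  edges are undefined. Two matrices are compared by Pearson correlation
  over the K(K+1)/2 defined cells (df = cells − 2; the parametric reading
  of the df notation), with Spearman available alongside.
* **Topography.** Node degree = number of incident selected edges
  (handshake identity Σdeg = 2|mask| is asserted in tests). Two degree
  maps are compared by Spearman correlation against a spin permutation
  null: each permutation draws a uniform random 3D rotation (QR of a
  Gaussian matrix with sign fix), rotates all unit-sphere centroids, and
  reassigns the second map by nearest original centroid to each rotated
  position, duplicates permitted (the standard parcel-level variant).
  Two-sided on |ρ|, add-one convention. Real atlas centroids are projected
  to the unit sphere first; single-sphere nulls only (no hemisphere
  mirroring).

## Variability statistics

Per-edge SD across participants uses the session-mean matrix by default
(ddof = 1); single-session and pooled bases are config options. The DP/SD
overlap thresholds both vectors at the same percentile (99/98/95) and runs
the edge-overlap test rewiring the SD mask. Group comparisons (all edges,
discriminatory edges, predictive edges per behaviour) use Welch's
heteroscedastic one-way ANOVA (via pingouin) with
ω² ≈ df1(F−1)/(df1(F−1)+N) — an estimate, as the ω² for the Welch setting
is not unique — and Games–Howell post hocs (studentized-range p with
q = t√2, Welch–Satterthwaite df), Benjamini–Hochberg corrected across
pairs. The FDR step is applied even though Games–Howell already controls
familywise error, for fidelity to the analysis being reproduced.

## Synthetic study conditions

There is no public generative model for this analysis, so the cohort
generator uses the minimal additive structure that reproduces the three
empirical ingredients every downstream claim rests on — identifiability,
linear edge–behaviour coupling, and the edge-SD ordering:

    x[j,s,i] = base(i) + u_j(i) + ε[j,s](i)

with block baseline base (0.4 within networks, 0.1 between — chosen to
resemble resting-state block structure; identification and CPM are both
location-invariant per edge, so these do not affect results), subject
components u_j drawn once per subject (session-stable), and independent
session noise ε. Defaults (the reference study conditions): 40 subjects,
60 nodes in 6 spatially contiguous spherical networks (nodes on a
golden-angle lattice, networks as Voronoi caps of rotated seed
directions), 2 sessions; 1% identity edges with subject SD 0.5, 1%
behaviour edges with subject SD 0.1, background SD 0.05, session noise SD
0.075.

Two generator choices deserve explanation:

* **Behaviour-edge coupling.** The behavioural score is
  y_j = Σ_i w_i·u_j(i) + noise over the behaviour edges (w_i = ±1, noise
  SD set by `beta_snr`, default 3). If the u_j(i) were independent across
  the K ≈ 18 behaviour edges, each edge's correlation with y would be
  ≈ 1/√K ≈ 0.24 — undetectable at the p < 0.01 selection threshold with
  ~36 training subjects, so no generator of this family could show CPM
  recovering its own planted edges. The components on behaviour edges
  therefore share a latent trait (`behaviour_coupling` = 0.5 of their
  variance), which raises each edge's correlation with y to ≈ 0.6–0.7 and
  is also the biologically natural reading (edges coupled to one
  behavioural phenotype covary).
* **Session-stability separation.** Differential power saturates with an
  edge's stability ratio σ_u/σ_session rather than growing with σ_u
  itself: at ratio 4 an edge is already nearly as discriminatory as at
  ratio 10. The defaults therefore place behaviour edges at ratio ≈ 1.3
  (0.1/0.075) and identity edges at ≈ 6.7, which keeps behaviour edges
  out of the 99th-percentile DP mask while leaving them individually
  detectable by CPM. With behaviour edges at ratio 4 the planted sets
  bleed into each other's masks and the dissociation the analysis is
  designed to detect cannot be observed even in principle.

Optional nodal time series are stationary Gaussian draws whose population
correlation is the nearest positive-definite projection of the session's
target connectome (eigenvalue clipping at 1e−6, rescaling to unit
diagonal, off-diagonals clipped below |1| with a warning) — the simplest
projection with a testable convergence contract.

What the generator does **not** emulate: haemodynamics, motion and scanner
noise, voxel-level structure, family structure, non-Gaussian edge
distributions, and spatial autocorrelation of edge values beyond the
network-block baseline. Passing tests therefore demonstrate that the
statistics and nulls behave as specified and that planted structure of the
stated kind is recovered — not that any particular empirical effect size
from real cohorts will reproduce.

## Seeding, problem sizes, determinism

A single top-level seed is fanned out to stages through fixed per-stage
keys (`numpy.random.SeedSequence([seed, stage_key, index])`), so adding a
stage never shifts another stage's stream; identical seeds give
bit-identical cohorts and reports. The test suite scales simulations to
the reference cohort (40 × 60) and below: the dissociation checks use 20
seeds with 25 CV repeats and 500 permutations per test; the overlap-null
calibration uses 200 replicates of a 40-node, 120-edge configuration with
200 permutations; spin-geometry checks use 100 nodes and 5000
permutations. These sizes are the package's documented study conditions
for its own validation.

## Known limitations

* The DP formula is a pinned reconstruction of the published scripts'
  behaviour (centered, unit-norm vectors; strict exceedance; clamped
  empirical probability); other implementations may differ in centering
  and tie handling.
* The SVR variant's hyperparameters emulate an ambiguous printed
  configuration; its absolute performance should not be compared across
  packages.
* The degree-preserving null is a finite swap chain (10·|mask| attempts);
  on nearly-rigid graphs mixing is limited and the test is conservative.
* p values from m permutations resolve no finer than ~1/m; empirical
  zeros are reported as "< 1/m".
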