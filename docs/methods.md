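# Methods

`emonet` implements a directed brain-network analysis for task-fMRI ROI
time series: a multi-subject score-based structure search over Markov
equivalence classes, non-Gaussianity-based edge orientation, per-subject
SEM edge weights, network-level descriptors, and the group-level
inferential tests applied to them.  Because the original patient data is
not publicly distributable, the package ships a block-design simulator
with known ground truth; every stage is exercised and calibrated against
it.

## Generative model of the simulator

Each condition's signal is a linear structural equation model with
acyclic contemporaneous coupling over the eight ROIs (LSFG, RSFG, LACC,
LMFG, RInsula, LParah, RParah, LAmygdala):

    x_t = B x_t + e_t,    equivalently    x_t = (I − B)⁻¹ e_t,

with `B[v, u]` the weight of edge u → v.  Innovations `e` are i.i.d.
across time within each stream, from one of three families, all
parameterized so `noise_scale` is the innovation SD:

- **laplace** (default): heavy-tailed (excess kurtosis 3), the
  non-Gaussianity the orientation stage requires;
- **gaussian**: retained deliberately so tests can show orientation
  accuracy collapsing to chance — the identifiability boundary of the
  method, not a defect;
- **squared_gaussian**: centered, scaled χ²₁, a skewed alternative.

An optional AR(1) filter (`ar_coefficient`, default 0.3) smooths each
innovation stream to mimic BOLD temporal autocorrelation.  It leaves the
contemporaneous coupling — and therefore the target of structure
learning — unchanged, but mildly Gaussianizes the marginals (an AR(0.3)
filter scales excess kurtosis by (1−a²)/(1+a²) ≈ 0.84), so it is a mild
stress test for orientation rather than a free parameter.

Defaults mirror the conditions the pipeline targets: 2 groups
(14 + 16 subjects) × 3
conditions, 12 blocks × (20 s fixation + 5 × 4 s images) at TR 2 s = 240
volumes, random ground-truth DAGs at edge density 0.25 with |weights|
uniform in [0.4, 0.8] and random sign (the exclusion of a neighbourhood
of zero keeps true edges detectable in principle).  Fixation volumes are
simulated from the edge-free null model rather than omitted so epoch
extraction is exercised realistically.

What the simulator does **not** emulate: hemodynamic convolution (a
rigid lag shift stands in for it — see below), voxel-level noise, motion
artifacts, physiological confounds, between-subject variability in the
coupling weights (all subjects of a group share one generating model per
condition).  Passing recovery tests therefore show the
search-and-orientation machinery is correct under its own model
assumptions; they do not certify performance on real BOLD data.

## Condition epochs

Per-condition series are built by taking each block's stimulus-period
volumes shifted forward by a rigid hemodynamic lag (default 2 volumes =
4 s, configurable 0–4) and concatenating blocks of the same condition.
A standard acquisition ends exactly at the last stimulus volume, leaving
no room to shift the final block; its window is clipped at the run end
(the final block contributes `lag` fewer rows).  Strict bounds checking
(`clip_final=False`) is available.  Block boundaries are recorded, but
downstream regressions treat rows as exchangeable — the model being
fitted is contemporaneous, not autoregressive.

Epochs are z-scored per subject × condition with the ML (ddof = 0)
variance, so a standardized column has residual variance exactly 1 in
the BIC closed form and regressions need no intercept.  (The
Anderson–Darling statistic studentizes its own input with ddof = 1,
matching the classical formulation; the two conventions are internal to
each statistic and never mix.)

## Structure search

The local score of node y with parent set P on one subject's
standardized epochs is the Gaussian BIC with penalty discount c ≥ 1,

    s(y | P) = −n ln σ̂² − c (|P| + 1) ln n,

σ̂² the ML residual variance of the no-intercept OLS fit, constants
common to all parent sets dropped.  The multi-subject score is the
arithmetic mean over subjects (equivalent to the sum up to a factor;
the mean keeps c interpretable against the per-subject sample size).
Scores are computed from per-subject Gram matrices and cached by
(node, parent-set).

Search runs over equivalence classes with the standard Insert/Delete
operator pair: forward from the empty graph, repeatedly applying the
valid insertion with the largest positive pooled improvement (clique and
semi-directed-path validity checks; improvement threshold 1e−9 to absorb
floating-point noise; ties broken lexicographically on child, parent,
then subset), rebuilding the completed pattern after each move by
consistent DAG extension followed by v-structure detection and Meek
closure; then backward deletions to a local optimum.  Meek rules R1–R3
are applied; R4 cannot fire when all initial orientations come from the
v-structures of a consistent DAG, which is the only way partially
directed graphs arise here.

**Penalty escalation.**  Indirectly measured neural signals readily
produce spuriously triangulated patterns, so the pipeline runs the
search at increasing penalty discounts and keeps the first triangle-free
pattern.  The default grid is (1, 2, 3, 4, 6, 8, 12, 16): a chord
between two children of a common cause is a genuine marginal dependence
and can survive c = 4 at realistic sample sizes, so the grid extends
until the complexity penalty dominates such induced dependences.  A grid
exhausted with triangles remaining is an error carrying the last
pattern.  This selection rule presumes the true network is triangle-free;
the synthetic benchmark samples triangle-free truths for exactly that
reason (with a triangulated truth the rule removes true edges by
construction).

## Orientation

With independent non-Gaussian innovations, the regression residuals of
the correctly oriented model are less Gaussian than those of any
mis-oriented one.  The orientation stage holds the learned adjacency
structure fixed and maximizes the total non-Gaussianity of per-node
residuals, summed over subjects, scored by the Anderson–Darling A²
statistic (studentized sample against the normal family; CDF values
clamped at 1e−15 from each boundary; 5% critical value 0.752 for the
estimated-parameters case, and the suite verifies the empirical size).

By default **all** edges of the skeleton are re-oriented, not just the
pattern's undirected ones.  The search stage is trusted for adjacencies
but not for arrows: near-tied equivalence classes — for instance, which
opposite pair of a chordless four-cycle holds the colliders — are
routinely mis-resolved at fMRI sample sizes on BIC margins of order one,
while the residual-non-Gaussianity objective separates the same classes
by large margins.  Pinning the pattern's compelled arrows is available
(`fix_v_structures=True`).

Acyclic direction assignments are enumerated exhaustively up to 12 free
edges (ties resolve to the first assignment in lexicographic order);
larger skeletons use node-wise greedy flipping to a fixpoint with 5
seeded random restarts, initialized from randomized topological orders.
Exhaustive and greedy modes agree on all test skeletons.

## Edge weights and summaries

Connection strengths are per-subject, no-intercept OLS coefficients of
each node on its parents under the group-common graph — per-subject
rather than pooled estimation is what gives the paired tests and
repeated-measures ANOVAs their subject-level degrees of freedom (16
subjects × 3 conditions → F df (2, 30)).  Group-level strength is the
mean across subjects.

Graph descriptors follow the two-layer framing: {LSFG, RSFG, LMFG, LACC}
prefrontal (the ACC is grouped with the control layer), {RInsula,
LParah, RParah, LAmygdala} limbic.  A directed edge is top-down
(prefrontal → limbic), bottom-up (limbic → prefrontal) or lateral;
density is reported as the raw edge count (how such networks are
compared in practice) with the normalized value alongside.  A connection
"shared" by two graphs is a shared unordered adjacency; orientation
agreement is reported as a separate flag, since shared connections are
conventionally listed by ROI pair without committing to direction.

## Group statistics

Student's pooled-variance two-sample t (Welch behind a flag), paired t
with Cohen's d = mean(diff)/sd(diff), one-way within-subject ANOVA
(F = MS_cond/MS_error, df (k−1, (k−1)(n−1)), partial η² =
SS_cond/(SS_cond+SS_error), no sphericity correction — reported df are
the uncorrected integers), Pearson r with the t-transform p, Pearson
chi-square on 2×2 counts without continuity correction, and Bonferroni
adjustment min(1, m·p).  t tests, correlation and chi-square delegate to
scipy; the RM-ANOVA is computed from its sums of squares and is
cross-checked against pingouin in the suite.  All tests keep their
nominal 5% size under simulated nulls (verified at 2000 replicates
each).

## Benchmark problem sizes

The standing recovery battery runs 20 seeded replicates of 8-node
triangle-free random DAGs (density 0.25, |weights| in [0.4, 0.8],
Laplace innovations, AR 0.3), 10 subjects × 200 standardized time points
each, through penalty selection + pooled search + orientation, and
reports mean adjacency precision/recall and mean direction accuracy
among correctly recovered adjacencies.  The single-edge orientation
benchmark uses one subject of 2000 points over 50 seeds (100 seeds for
the Gaussian-collapse check).  These sizes were chosen as the smallest
at which the asymptotic guarantees of the methods visibly bind; the
small-instance search oracle (exhaustive enumeration over all DAGs)
uses 3–4 nodes, where enumeration is exact.

## Known limitations

- Greedy equivalence search is only asymptotically optimal; on dense
  small-sample instances it can land in a local optimum one BIC point
  from the global one.  The orientation default compensates for arrow
  errors but adjacency errors stand.
- The triangle-free selection rule is an assumption about the true
  network, inherited from the analysis design, not a property of brains.
- The AD-based objective needs clearly non-Gaussian innovations; at AR
  coefficients near 1, or with strongly Gaussianized signals, direction
  accuracy degrades toward chance by construction.
- Condition epochs of a real 240-volume run are short (≈ 40 volumes per
  condition per subject); recovery at study scale leans on pooling
  10–16 subjects.
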