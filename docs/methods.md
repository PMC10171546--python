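# Methods

This note documents the models, conventions and design choices behind
`connectodev`, and what the synthetic validation does and does not
establish about real data.

## Connectome construction

A scan contributes one weighted, symmetric, zero-diagonal N×N matrix per
modality. Functional weights are Pearson correlations between regional
time series; a zero-variance region makes the correlation undefined and is
reported as an error naming the region rather than silently imputed.
Structural weights scale streamline counts by the inverse of the two
endpoint volumes. The literature states the inverse-node-volume principle
without a formula; we use the standard "invnodevol" convention
`w_ij = c_ij * 2/(v_i + v_j)`, i.e. each streamline contributes the
reciprocal of the mean endpoint volume. This makes weights homogeneous of
degree +1 in counts and −1 in volumes, which the tests verify.

Motion QC excludes scans with mean framewise displacement strictly greater
than 0.5 mm; a scan at exactly 0.5 mm is retained. The filter is
idempotent and logs each exclusion.

The parcellation size is a parameter. Real analyses of this kind use a
360-region cortical atlas; the synthetic default is 60 regions in 6
modules so that the full pipeline runs in minutes on one CPU.

## Thresholding

**Functional.** Only positive correlations can form edges: the threshold
grid is 0–0.5 in steps of 0.05, which only makes sense for positive r, so
negative correlations are discarded by construction rather than
absolute-valued (config exposes nothing else; this is a deliberate single
convention). Per candidate τ, each scan's graph is profiled against two
references: a ring lattice matched to the exact edge count (built at the
nearest even per-node degree, then trimmed from the outermost ring) and
degree-preserving double-edge-swap rewirings (10 realizations × 10·|E|
swap attempts by default, seeded). A network is called small-world when
global efficiency exceeds the lattice's and mean local efficiency exceeds
the rewired graphs', both with ratio margin 1.0 (configurable; the
literature says "comparatively high" without a margin). τ* is the smallest
grid value whose scan-averaged profile is small-world with mean cost
inside [0.05, 0.5] — the densest admissible network, since a single chosen
value without an explicit objective is best mirrored by the most inclusive
qualifying threshold. Profiles are computed per scan and averaged (rather
than on a group-mean matrix); both the grid step and this choice are
config options. On the generator's defaults the selection lands on
τ* = 0.15 with cost monotonically decreasing in τ.

**Structural.** For each edge present in at least one subject, the
coefficient of variation of its weight across *all* subjects (sd/mean,
sample sd) is computed; edges with CV at or below the 75th percentile of
the candidate CV distribution are retained. Low CV = consistently
reconstructed: the cited consistency-thresholding literature keeps low-CV
edges, and the generator's labelled false positives confirm the direction
(spurious edges are retained at roughly half the backbone rate at the
default settings). The complementary "keep high CV" reading is selectable
for comparison. Edges whose across-subject mean is zero are never
candidates. Ties at the percentile cut are retained, with a small epsilon
absorbing floating-point noise (an all-identical stack must keep every
edge even though the sd of identical floats evaluates to ~1e−16). Nodes
with zero connections after masking are removed; the kept-node map
preserves regional identity downstream.

## Graph metrics

All metrics operate on binary undirected graphs. Distances are BFS hop
counts; disconnected pairs contribute zero efficiency (no path-length
imputation). Local efficiency follows the neighbour-subgraph definition:
the efficiency of the subgraph induced by a node's neighbours with the
node removed, zero for nodes with fewer than two neighbours. A "nodal"
variant — mean inverse distance from the node to all others — exists
behind a flag because a printed formula of that form also circulates;
the neighbour-subgraph reading is standard and is the default, and no
assumption is made about which variant produced any particular published
table. Betweenness is reported unnormalized with endpoints excluded and
each unordered pair counted once, matching the definitional sum
Σ σ_ab(i)/σ_ab; a normalized variant (÷(N−1)(N−2)/2) is available, and
the downstream models are invariant to that scale. Implementation notes:
all-pairs distances use synchronous matrix-step BFS (fast for small dense
graphs), betweenness uses igraph's Brandes accumulation, and both are
checked against an exhaustive geodesic-enumeration oracle on all graphs
with ≤8 nodes to 1e−9.

## Longitudinal models

Per region and metric the observation is one value per scan, joined with
the scan's covariates. Four nested models are fitted by exact maximum
likelihood, all containing framewise displacement, scanner epoch
(pre/post upgrade, a fixed binary covariate), medication status and sex,
plus a per-subject random intercept (no random slopes: at most three
observations per subject cannot support them):

1. **null** — covariates only ("without predictors" is read as without age
   or group, since the covariates are stated to be in every model);
2. **age** — adds a B-spline smooth of age;
3. **group** — adds a group main effect;
4. **interaction** — adds a group-specific age smooth (separate spline per
   group, shared basis dimension), so trajectories may differ in shape.

The smooth uses an unpenalized B-spline basis with `basis_dim − 1 = 3`
columns at the default basis dimension 4 — the effective dimension a
penalized smooth of that basis size has after its identifiability
constraint. With so small a basis an explicit wiggliness penalty has
little to act on, and the unpenalized fit keeps the likelihood exact and
the AIC degrees of freedom unambiguous. Constant covariate columns (e.g.
nobody medicated in a control-only subset) are dropped from the design;
genuinely collinear predictors raise an error naming the columns.

The random-intercept Gaussian model is fitted by profiling the marginal
likelihood over the variance ratio λ = σ²_subject/σ²_resid: given λ the
GLS coefficients and residual variance are closed-form per subject block,
leaving a one-dimensional bounded optimization (log scale, with the λ = 0
boundary checked explicitly). This is exact ML for this model class; the
unit tests verify agreement with a general-purpose mixed-model optimizer
to ~1e−6 in log-likelihood. AIC counts fixed effects plus the two
variance parameters.

Added-term p-values: Wald (normal) test for the group coefficient;
likelihood-ratio χ² with df = number of spline columns for the age and
interaction smooths. Model selection walks from the most complex model
down: the winner must have p < α (0.05) *and* AIC more than 2 units below
**all** simpler nested models (a config switch restricts the comparison to
the immediate parent; "nested models" is ambiguous between the two
readings and the stricter one is the default). Equal AICs keep the simpler
model; with no qualifying model the null is retained.

FDR families are regions within one metric × modality × contrast
(group-contrast p-values across regions; interaction-contrast p-values
across regions), each corrected by Benjamini–Hochberg at q = 0.05. Pooling
across metrics is not done — the correction is stated "across regions" and
is applied that way. The scan-level global-efficiency model is a
single-region family, so BH passes it through unchanged. Age-model
p-values are reported uncorrected (they are a descriptive trend, not a
group inference). Trajectory predictions hold framewise displacement at
the sample mean, scanner at pre-upgrade, medication at false and sex at
the female reference; grid ages outside the observed range are flagged as
extrapolated and clamped in the basis.

### Calibration on synthetic nulls

Likelihood-ratio tests of variance-free nested fixed effects in ML mixed
models are known to run slightly liberal in finite samples; on the
generator's null cohorts the raw per-region rejection rates at α = 0.05
are ≈0.05 (group, Wald) and ≈0.08–0.10 (smooth terms, LRT). The quantity
the analysis actually reports — the proportion of regions significant
after BH at q = 0.05 — stays well below the nominal level on null cohorts
(≈0.004 and ≈0.002 for the group and interaction contrasts at the default
design), which the acceptance suite verifies within Monte-Carlo error.

## Synthetic cohorts

The generator emulates the design of a two-group, three-wave developmental
cohort; all of its outputs are pure functions of (spec, seed).

**Phenotypes.** 85 subjects per group by default; wave age means
10.40/11.63/13.24 years (SD 0.5), ages forced strictly increasing within
subject; monotone dropout at 0.15 per wave (once out, stays out),
approximating the attrition pattern of multi-wave pediatric cohorts; head
motion log-normal with group- and wave-specific means (clinical group
higher, both declining with age: 0.19/0.16/0.11 vs 0.18/0.13/0.10 mm),
which occasionally produces scans above the 0.5 mm QC ceiling, so the QC
stage has real work; scanner upgrade at wave 3; medication (clinical group
only) at rate 0.17; sex ratios 71% / 56% male. These defaults mirror the
demographic summary tables of the cohort the pipeline is designed for.

**Functional data.** Each scan draws T = 150 exchangeable samples from a
zero-mean multivariate normal whose correlation matrix is a modular
template (within-module r = 0.45, between-module r = 0.12, 6 modules of
10 regions) plus a per-subject within-module perturbation (SD 0.03,
constant across that subject's waves — this is what makes the random
intercept non-trivial) plus any planted effects, projected to the nearest
positive-definite correlation matrix by eigenvalue clipping (floor 1e−4,
renormalized to unit diagonal, logged when triggered). Time samples are
exchangeable (no autocorrelation) by design: the analysis consumes only
correlations, where autocorrelation mainly rescales the effective sample
size, and an autocorrelated option would change no pipeline logic.

Planted effects shift the target regions' **between-module** correlations:
those sit near the operating threshold (r ≈ 0.12 vs τ = 0.15), which is
exactly where a correlation shift converts into changed edge
probabilities and hence into degree/efficiency/betweenness differences.
Shifting within-module correlations (already far above threshold) would
leave the binary topology almost unchanged. A `group_offset` adds the
shift for the clinical group at every age; a `trajectory_divergence` makes
the clinical group's shift grow linearly at `magnitude` per year from age
9, so group trajectories diverge. The calibrated defaults are offset
0.06 (inducing a degree difference of ≈1.5 within-region residual SDs at
80 subjects/group) and divergence 0.025/year (reaching a comparable shift
by the cohort's middle wave). Effects targeted at a region necessarily
spill a small constant amount onto each partner region (every edge has two
endpoints, and partners share one affected edge out of their ~50), so
non-target regions carry genuine small group effects in planted cohorts;
sensitivity is therefore scored on target regions only, and type-I
calibration uses cohorts with no effects at all.

**Structural data.** Streamline counts are negative-binomial around
`backbone × subject_gain × exp(effect)` (backbone 80 within-module / 10 on
sparse between-module bridges; dispersion 20; per-subject log-normal gain
SD 0.15). A fixed 25% of zero-backbone node pairs are "spurious": present
in only about half the subjects with low mean (2) and high dispersion
(0.5), mimicking tractography false positives; their labels are returned
so consistency thresholding can be scored against ground truth. Node
volumes are log-normal around 3000 mm³.

**What passing tests show — and don't.** The synthetic data establish
internal correctness: the formulas compute what they claim, the selection
rule behaves as specified, type-I error is controlled, and effects of the
planted form at the calibrated sizes are recoverable at the stated design.
They do not establish field validity on real data: BOLD autocorrelation
and non-Gaussianity, registration and parcellation error, spatially
structured motion artefact, non-modular covariance and site effects are
all outside the generator. Sensitivity numbers transfer only to effects
that express near the operating threshold, as the planted ones do by
construction.

## Problem sizes and determinism

Default validation sizes (chosen as desk-scale design points): 60 regions,
T = 150; type-I calibration 40 subjects/group × 3 waves × 20 replicates;
recovery 80 subjects/group × 10 replicates; small-world detection 50
seeds of a 100-node, degree-6 ring lattice with 10% rewiring; metric
oracle 200 random graphs with ≤8 nodes. Every random draw flows from an
explicit seed (numpy `SeedSequence`, with per-scan streams keyed by a
stable CRC of the scan id — not Python's randomized string hash); two runs
with the same config and seed produce byte-identical tables, which both a
test and the acceptance script check. All tabular output is TSV with a
provenance header (config hash + seed); matrices are plain delimited text
with a one-label-per-line sidecar, phenotypes CSV.

## Known limitations

- The smooth is a fixed-dimension regression spline, not a
  penalized-likelihood smooth with data-driven effective df; at basis
  dimension 4 the practical difference is small, but smooth-term p-values
  are approximate (LRT) either way.
- The random-effects structure is a subject intercept only; slope
  heterogeneity, if present in real data, would inflate the interaction
  test.
- Consistency thresholding uses one shared mask across the cohort, so
  structural graphs are not independent across subjects; the models treat
  them as such (as is standard).
- No weighted-graph, modularity or rich-club analysis; the analysis scope
  is the four binary-graph measures.
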