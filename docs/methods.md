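# Methods

This note documents the models, numerical conventions and design choices
behind `paramicro`. It is the companion to the API docstrings: the
docstrings say *what* each function computes, this note says *why* it is
computed that way and what the synthetic benchmarks do and do not show.

## Filtering and normalization

The study-wide prevalence filter keeps ASVs with at least 25 reads in at
least 5 samples (both thresholds inclusive); the per-community network
node filter keeps ASVs with at least 10 reads in at least 50% of that
community's samples, with "50% of n" read as `ceil(0.5 n)` (6 of 12) —
the inclusive reading, documented so node counts on real data can be
reconciled. Composition analyses use relative abundance; rarefaction
(default depth 1000, multivariate-hypergeometric draws, i.e. without
replacement) is provided as a robustness check, and samples below the
depth are dropped rather than padded. The clr transform uses a unit
pseudocount on raw counts; the pseudocount only affects display-level
quantities (node sizes, MB inputs), not the SparCC estimator, which has
its own Dirichlet smoothing.

## Diversity

Inverse Simpson D⁻¹ = 1/Σpᵢ² is bounded by [1, R] and equals R exactly at
even proportions; evenness D⁻¹/R therefore lies in (0, 1]. Faith's PD
anchors the spanning subtree at the root by default (a single observed
tip contributes its whole root-to-tip path), matching the convention of
the community-phylogenetics tooling this mirrors; `include_root=False`
trims the path above the crown of the observed tips.

## Weighted UniFrac and PCoA

For samples X, Y with per-branch descendant read proportions p(b),
raw distance = Σ_b l_b·|p_X(b) − p_Y(b)| and the normalized variant
divides by Σ_b l_b·(p_X(b) + p_Y(b)), bounding values in [0, 1] and
making them invariant to a global rescaling of branch lengths.
Proportions come from relative abundances, so library size cancels.
Normalized is the default (the common default of 16S toolchains); raw is
a flag. PCoA is classical scaling: double-center −D²/2, eigendecompose,
scores = eigenvectors scaled by √eigenvalue. Axes with eigenvalues below
1e-10 of the leading one (including all negative axes) are excluded from
scores; no Lingoes/Cailliez correction is applied, and
proportion-explained is relative to the positive part of the spectrum.
Axis signs are arbitrary — downstream Procrustes absorbs reflections.

## Procrustes congruence and leave-one-out attribution

The symmetric Procrustes fit centers both score matrices, scales each to
unit total sum of squares, and finds the optimal rotation/reflection via
the SVD of X'Y; t₀ = Σσᵢ and m₁₂² = 1 − t₀². This matches vegan's
`protest` statistic to machine precision (checked in the test suite by
calling vegan through Rscript). The permutation p-value uses the
(k+1)/(n+1) convention and permutes the row pairing of one side;
999 permutations by default.

Samples are paired by (site, replicate); organs excavated as one unit
additionally share a specimen id. Leave-one-out removes all parasite
ASVs of one clade, recomputes UniFrac and PCoA *for the parasite samples
only* (host scores are frozen — the exclusion is defined on the parasite
dataset, and recomputing the host side would conflate the two roles),
and reports Δt = t_excluded − t₀. A clade with zero total abundance has
Δt = 0 exactly. Clades whose exclusion empties a sample (or leaves fewer
positive axes than requested) are flagged and skipped. Drill-down reruns
the procedure at order rank within the top-3 phyla by |Δt| (the cutoff
for "influential" is a package choice; it is configurable). Phyla whose
wholesale exclusion was infeasible are included in the drill-down
candidates ahead of the ranked ones — a clade too large to remove is
exactly the one worth dissecting. Features with unassigned taxonomy are
never excluded and form no clade record.

## SparCC

SparCC estimates correlations between unobserved absolute abundances
from compositional counts. Per inner iteration (20 by default),
fractions are drawn from a per-sample Dirichlet posterior (counts + 1),
the log-ratio variation matrix T_ij = var(log fᵢ/fⱼ) is formed, and
component variances ω solve the sparsity-approximation linear system
Σ_{j∈Sᵢ} T_ij = |Sᵢ|ωᵢ + Σ_{j∈Sᵢ} ωⱼ, where Sᵢ excludes iteratively
removed pairs: up to 10 rounds, the strongest pair with |ρ| above 0.1 is
dropped from the system (the exclusion heuristic needs D ≥ 4; at D = 3
the base system is solved directly and has a closed form). Correlations
ρ_ij = (ωᵢ + ωⱼ − T_ij)/(2√(ωᵢωⱼ)) are clipped to [−1, 1]; the reported
matrix is the element-wise median over iterations (median, not mean,
for robustness to occasional ill-conditioned draws). Non-positive basis
variances flag a feature and blank its row.

Edge significance is a two-sided sign-crossing bootstrap: samples are
resampled with replacement (100 datasets by default), and
p = 2·min(#{ρ_b ≤ 0}, #{ρ_b ≥ 0})/B, floored at 1/B and capped at 1.
The exact pseudo-p formula of the helper used in the original toolchain
is undocumented, so this explicit, seed-stable definition is adopted;
edge sets on real data may differ at the p ≈ 0.05 margin. Edges require
|ρ| > 0.6 **and** p < 0.05, both strict; isolated nodes stay in the node
set.

## Neighborhood selection with StARS

Each clr-transformed feature is lasso-regressed on all others over a
geometric path of 100 penalties from λ_max (the largest absolute
off-diagonal empirical correlation) down to λ_max·0.002. StARS draws 30
subsamples of size ⌊0.8n⌋ (the large-n 10√n rule exceeds the n = 12 of a
single community type, hence the fixed fraction), records the OR-rule
graph along the path, averages per-pair instability 2θ(1−θ), monotonizes
it with a running supremum toward denser graphs, and selects the densest
penalty whose monotonized instability is ≤ 0.05. Edge weights are the
mean of the two directed coefficients at the selected penalty on the
full data. Two properties of this selector are worth knowing: (i) with
few nodes the per-pair normalization makes the 0.05 threshold
conservative — a handful of true edges flickering at their entry penalty
can dominate the supremum; (ii) the planted-chain benchmark therefore
uses partial correlations ≈ 0.45 (precision coupling 0.5), at which
recovery is reliable at n = 200. Constant features are dropped with a
warning before inference.

## Network statistics and comparison

Degree and betweenness are computed on the unweighted, sign-ignored
graph (the thresholded edge set defines topology; weights are retained
as edge attributes only). Betweenness counts each unordered pair once
and excludes endpoints; Freeman centralization
C_B = Σᵢ(b_max − bᵢ) / ((V−1)²(V−2)/2) is 1 for a star, 0 for any
vertex-transitive graph, and defined 0 for V < 3. Networks are compared
by resampling means of k = 50 centrality values with replacement
(k stays 50 even when a network has fewer nodes), 10 000 times per
network, and applying a two-sample Kolmogorov–Smirnov test with the
asymptotic p-value — at 10⁴ replicates the resolution is far below any
conventional significance call. Both betweenness and degree are
supported as the compared statistic.

## The synthetic-data generator

`simulate_paired_communities` emulates the paired field design: 4 sites
x 3 replicates per community type, 7 plant types + soil, sparse
overdispersed counts with log-normal library sizes (median 10⁴ reads,
log-sd 0.5), and a taxonomy whose pseudo-phyla and pseudo-orders are
monophyletic clades of a simulated tree.

Compositional turnover across specimens is modelled as `n_shared_modes`
(default 2) fixed directions in log-abundance space whose per-specimen
scalar coordinates vary — an infection-associated clade bloom waxing and
waning across excavated units. The directly parasitized host root (IIR)
carries the coordinates fully; the parasite organs (PR, PL) of the same
specimen receive them scaled by κ plus an independent √(1−κ²) remainder,
so per-type variance is independent of κ and κ = 0 yields an
exchangeable permutation null. All other types draw independent
coordinates. The modes are concentrated on a designated driver clade
(default 80% of signal variance; the driver order's taxa), and the
driver clade's baseline abundance is drawn once and shared across
community types, boosted to keep the clade common — a clade whose
typical abundance differed wildly between host and parasite could not
visibly couple their turnover, and a rare clade cannot carry an
abundance-weighted (UniFrac) signal. Latent per-sample log-abundance is
baseline + site effect + specimen signal + noise; counts are multinomial
given a log-normal library size. An association graph can be planted in
the residual covariance (precision I + s·A, shrunk to stay positive
definite).

Default scales (latent log units): baseline sd 2.0, shared signal sd
1.8, residual noise sd 0.6 plus overdispersion 0.3, site sd 0.25. Site
effects are deliberately weak relative to specimen effects: site-level
blocking correlates the rows *within* each side, which breaks the
exchangeability the protest permutation test assumes and would inflate
its type-I error even with no true host–parasite coupling. Real data do
not grant this courtesy — the study design shares sites across
communities — so on real data the permutation p-values should be read
as approximate. This is the main feature of real data the generator
deliberately omits; consequently, the calibration tests certify the
test statistic and its permutation machinery, not robustness to field
pseudo-replication.

Benchmark scenarios (used by the test suite and the acceptance script)
are fixed once: the calibration scenario is κ = 0 at generator defaults
(40 taxa, PR/IIR only); the power scenario is κ = 1 with the signal
fully concentrated on the driver and residual noise off (noise sd 0.1,
no overdispersion or site effects), where t₀ > 0.8 in ≥ 90% of datasets;
the attribution scenario is κ = 0.95, full concentration, noise sd 0.4 —
a strong planted driver, as the question "is the most negative Δt the
driver?" presupposes a driver worth finding. Problem sizes (40 taxa for
congruence scenarios, 30 x 50 for the SparCC null, 10-node chain at
n = 200) keep the full suite in the low minutes on one CPU while leaving
all test margins wide.

## Pipeline

`run_study` runs filter → alpha → global UniFrac/PCoA → per-community
PCoAs → Procrustes grid → leave-one-out (PR:IIR and PL:IIR) → per-
community SparCC networks → stats → pairwise bootstrap-KS, writing TSVs
as it goes plus a JSON manifest with every threshold and the named
sub-seeds (spawned from one master seed) used by each stochastic stage;
a rerun with the same config is byte-identical. Ordinations and
Procrustes comparisons are computed per community type — this matches
the leave-one-out procedure, which recomputes the parasite ordination
alone. The grid reports raw permutation p-values (matching how such
grids are conventionally presented) with a Benjamini–Hochberg column
added and labelled as an extension. Community types with fewer than 3
samples, degenerate ordinations, or fewer than 4 network nodes are
skipped with a logged reason.

## Known limitations

- The generator's softmax link makes large latent swings express
  nonlinearly in proportion space; with partially concentrated signal
  this caps attainable Procrustes t₀ below 1 even at κ = 1.
- StARS with few nodes is conservative (see above); SparCC's sparsity
  approximation biases correlations toward zero when many pairs are
  truly correlated.
- Permutation p-values on site-blocked real data are approximate
  (pseudo-replication, see the generator section).
- The loader drops features absent from the tree rather than grafting
  them; trees are expected to cover all retained ASVs.
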