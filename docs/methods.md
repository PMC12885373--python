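# Methods

## The problem

PCR amplification does not treat all 16S rRNA templates equally.  If taxon
*d* has per-cycle amplification efficiency *b_d* ∈ [1, 2] (1 = no
amplification, 2 = perfect doubling), then after *x* cycles the observed
ratio of two templates is

    w1/w2 = (a1/a2) · (b1/b2)^x,

where *a* is the pre-amplification composition.  In log-ratio coordinates
this exponential law is linear: writing φ(π) = Ψ log π for a (D−1)×D
contrast matrix Ψ whose rows sum to zero,

    φ(w) = φ(a) + x · β,      β = Ψ log b.

PCR bias is therefore a *perturbation* in the sense of compositional data
analysis: a constant additive shift of every sample's log-ratio coordinates.
`ampbias` quantifies what that shift does to downstream α- and β-diversity
analyses, which estimands are immune to it, and how badly it can distort
group comparisons in the worst case.

## Log-ratio geometry (`compositions`)

Compositions are strictly positive vectors summing to one.  All logarithms
are natural, which makes the linear model above exact for e-based
efficiencies.  Two bases are provided: the additive log-ratio block
Ψ = [I, −1] (the default; coordinates are log ratios against the last
taxon) and an orthonormal isometric (Helmert-type) basis in which Euclidean
norms of coordinates equal clr norms.  φ⁻¹ is computed as
closure(exp(pinv(Ψ)η)); because the kernel of Ψ is spanned by the all-ones
vector, the result is the unique composition with φ(c) = η.  Zero parts are
rejected throughout the algebra; the only zero handling is an explicit
pseudo-count option when extracting compositions from observed count tables
(0.5 by convention), so the geometry stays exact.  "Sums to one" and
round-trip tolerances are fixed at 1e-12 absolute.

## Synthetic calibration studies (`synthetic`)

The generator draws data from exactly the hierarchy the inference assumes:

    Y_n ~ Multinomial(depth_n, φ⁻¹(η_n)),    η_n ~ N(Λ X_n, Σ),

with design columns X_n = (community one-hots, cycle count x_n) and
coefficients Λ = [α⁽¹⁾ … α⁽ᶜ⁾ β].  Defaults emulate a mock-community
calibration experiment:

* **10 taxa, 10 communities, 3 replicates each** at PCR cycle numbers
  **{20, 28, 35}**.  Three distinct cycle counts identify the linear-in-x
  model; 35 cycles is the conventional endpoint for evaluating accumulated
  bias.
* **Depth 10,000 reads/sample** — typical amplicon scale, fast at desk scale.
* **Efficiencies uniform on [1.7, 2]** (spread 0.3): per-cycle log-ratio
  biases are small (|β| ≲ 0.16 per contrast) but accumulate into visible
  distortion over 35 cycles.
* **Baseline log-ratios α ~ N(0, 1.5²)** per coordinate, giving the uneven,
  few-dominant-taxa profiles typical of constructed mock communities.
* **Σ = 0.1·I** on contrast coordinates for replicate noise.
* Random rooted bifurcating trees with exponential branch lengths
  (mean 0.1) stand in for a reference phylogeny in UniFrac analyses.

All randomness flows from one integer seed; each sample gets its own child
generator (numpy `SeedSequence.spawn`), so re-simulating any prefix of the
samples is stable.

What the generator does *not* emulate: PCR plateau/saturation kinetics,
chimeras, primer-mismatch effects in the first cycles, sequencing error
beyond multinomial resampling, and real phylogenetic signal in the
efficiencies.  Tests passing on these simulations therefore demonstrate
internal consistency of the model, estimands and inference — not robustness
to model misspecification in real libraries.

## Inference (`inference`)

The multinomial logistic-normal model is fitted by collapse → Laplace →
uncollapse:

1. **Collapse.** With conjugate priors Λ | Σ ~ MN(Θ₀, Σ, Γ₀) and
   Σ ~ IW(Ξ₀, υ₀), both integrate out analytically, leaving η with a
   matrix-t density ∝ |Ξ₀ + (η−Θ₀X) K⁻¹ (η−Θ₀X)ᵀ|^−(υ₀+N)/2 where
   K = I_N + XᵀΓ₀X.  The implementation carries full normalizing constants
   (verified against brute-force Monte-Carlo marginalization in the tests).
2. **Laplace.** The collapsed posterior (multinomial log-likelihood plus
   matrix-t) is maximized over η by L-BFGS with an analytic gradient,
   then polished by Newton steps using the exact dense Hessian (closed-form
   Kronecker expression; block-diagonal multinomial part).  Convergence
   requires gradient max-norm < 1e-6; failure raises with diagnostics, never
   silently.  Near the mode the objective changes by less than double
   precision can resolve, so polish steps are accepted whenever they shrink
   the gradient norm.  The Gaussian approximation uses the inverse negative
   Hessian; dense factorization is comfortable at desk scale (D ≤ 30,
   N ≤ 100).
3. **Uncollapse.** For each Gaussian draw of η, Σ is drawn from its
   conjugate inverse-Wishart conditional and Λ from its conjugate
   matrix-normal conditional.  Draws of (Λ, Σ, η) are index-aligned, so
   downstream estimands evaluated per draw keep the joint posterior
   correlation between a community's baseline α and the shared bias β.

η is initialized deterministically from pseudo-count (+0.5) log-ratios of
the observed counts, so the mode is independent of the number of requested
draws.

**Prior defaults** (all configurable, recorded in output metadata):
Θ₀ = 0, υ₀ = D + 3, Ξ₀ = (υ₀ − D)·I so E[Σ] = I, and **Γ₀ = 100·I**.
The column scale matters more than it looks: in the conjugate prior the
coefficient variance is Σ ⊗ Γ₀, tied to the residual scale.  With Γ₀ = I,
tight replicate agreement (small Σ) silently implies a tight prior around
zero for the baselines and shrinks cycle-0 compositions by order-1 amounts
in log-ratio units.  Γ₀ = 100·I makes each coefficient's prior sd ten
residual sds — weakly informative on the scale of log-ratio compositions —
while leaving β recovery and interval calibration unchanged.  Note that
cycle-0 baselines are an extrapolation when no cycle-0 replicates are
sequenced; designs that include a 0-cycle library pin α directly.

## Diversity metrics (`diversity`)

α metrics: Shannon entropy −Σ p ln p (natural log); the Gini–Simpson index
1 − Σ p² (the bounded "Simpson" variant common in ecology); the Gini
inequality coefficient ΣᵢΣⱼ|pᵢ−pⱼ|/(2D) in its population form (uniform → 0
exactly, degenerate → (D−1)/D); and the Aitchison norm ‖clr(p)‖₂.

β metrics: Bray–Curtis ½Σ|pᵢ−qᵢ| on relative abundances; weighted UniFrac
Σₑ ℓₑ |Pₑ − Qₑ| over tree edges, where Pₑ is the relative abundance mass
descending from edge *e*, computed by one post-order accumulation per
composition (O(#edges) per pair); and the Aitchison distance
‖clr(p) − clr(q)‖₂.  Weighted UniFrac defaults to the normalized variant
(divided by Σ_tips depth_tip (p_tip + q_tip), bounding it in [0, 1]) with a
flag for the raw edge sum; both match scikit-bio to machine precision in
the test suite.  The Aitchison distance is deliberately computed in clr
coordinates: clr is an isometric embedding, so this is the basis-free value
(ALR coordinates would give a different, basis-dependent number).

Only the Aitchison distance (among the β metrics) and the differential
log-ratio τ (among group contrasts) are perturbation invariant.  Bray–Curtis
satisfies 0 ≤ d ≤ 1 and symmetry but not the triangle inequality; that is
documented rather than asserted.

## Bias estimands and invariance (`bias`)

For an α metric *f*, the PCR-induced bias of a community with baseline α is
f(φ⁻¹(α + xβ)) − f(φ⁻¹(α)), evaluated at x = 35 cycles by default; the
relative form divides by the unamplified value and is an explicit error
(not NaN) when that value is zero, e.g. the Aitchison norm at the
barycenter.  β-metric bias shifts *both* communities by the same xβ.
Posterior bias propagates joint (α, β) draws through these formulas; the
summary is the median with a central 95% interval.

`check_invariance` classifies any estimand of a sample collection by Monte
Carlo: draw γ ~ N(0, I) in log-ratio coordinates, apply the same γ to every
sample, and record the largest absolute change over (default) 1,000 trials;
the verdict is "invariant" below 1e-9 on the estimand scale.  This is the
operational form of the theory: an estimand unchanged by every common
perturbation is unchanged by PCR bias in particular, because the bias model
is exactly such a perturbation at fixed cycle number.

## Worst-case group distortion (`grouping`)

Group-difference strength is R² — between-group over total sum of squares
for scalar diversity values (ANOVA), and 1 − SS_within/SS_total on squared
distances (PERMANOVA, with pseudo-F on (1, N−2) degrees of freedom and a
label-permutation p-value that counts the observed statistic).  The
distortion statistic is ΔR² = |R²₃₅ − R²₀| between amplified and
unamplified data, and the worst case is its maximum over binary groupings
with at least 2 samples per group.

Brute force enumerates all 2^(N−1) − 1 bipartitions (exact; the intended
regime is N ≤ ~20 community-level units).  The genetic algorithm
(population 50, 100 generations, tournament 3, uniform crossover 0.8,
per-bit mutation 1/N, elitism 1) and particle swarm (positions in [0,1]^N
thresholded at 0.5; 40 particles; inertia 0.72, c1 = c2 = 1.49; velocity
clamp 0.25; 4 independent swarms sharing a 200-iteration budget) are seeded
heuristics.  The ΔR² landscape has strong local optima that trap a single
gbest-driven swarm, hence the independent restarts; both heuristics finish
with a greedy flip/exchange polish.  Neither can exceed the brute-force
optimum, and on desk-scale instances (N ≤ 12) they attain it in ≳90% of
seeded runs.

## Composition-dependent bias surfaces (`sweep`)

Surfaces evaluate α-metric bias (or β-metric bias against a fixed
reference) on a regular lattice (i, j, m−i−j)/m over the 3-part simplex,
default step 0.01 with boundary floor 1e-6 (metrics need strict
positivity), exported as long-format CSV (p1, p2, p3, ternary x/y, bias)
plus an optional matplotlib ternary rendering.

Two geometric regularities matter for interpretation, and both are
regime-dependent:

* **Even communities suffer most — at realistic bias magnitudes.**  For an
  efficiency scenario such as b = (2, 1.8, 1.8) (35·β ≈ (3.7, 0) in ALR
  coordinates), amplification pushes every starting composition far toward
  the favored vertex, so the bias is ≈ −H(start) for Shannon: small near
  edges and vertices, largest in the even interior.  For very weak bias
  (35·β ≲ 1) the pattern can invert — the edge where the two favored taxa
  meet shows the largest |bias| because the perturbation directly moves
  their balance.  The package's preset scenarios use the efficiency-derived
  magnitudes, where the even-interior rule holds.
* **Alignment matters for β diversity.**  A bias aligned (in isometric/clr
  coordinates) with the axis separating two communities changes their
  distance more than an equal-magnitude orthogonal bias.  The comparison
  must be made in an isometric basis: raw ALR coordinates distort angles
  and can invert the ordering.

## Pipeline and formats (`io`, `pipeline`, `cli`)

Count tables are taxa-by-samples TSV (first column taxon id); metadata is
TSV with sample_id, community, cycles (and optional group); trees are
Newick; ground truth round-trips as JSON; posterior draws as a compressed
numpy archive.  Tabular outputs use 10-significant-digit floats and fixed
column order, so pipeline reruns with the same configuration are
byte-identical — the manifest records a configuration hash and a sha256 per
artifact to make that checkable.  Stage failures are re-raised tagged with
the stage name.  The `ampbias` CLI exposes each stage standalone
(simulate, fit, alpha-bias, beta-bias, sweep, optimize-grouping,
invariance-check, run).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data at
desk scale, chosen to exercise every code path while staying quick: the
calibration preset (10 taxa × 30 samples × depth 10⁴) fits in well under a
second, so posterior-calibration checks use 20 independent replicates;
invariance checks use 1,000 random perturbations; surfaces use the default
0.01 step (4,851 interior points); heuristic-vs-exact grouping comparisons
use N = 12, where brute force enumerates 2,047 bipartitions.

## Known limitations

* The Laplace approximation is a single Gaussian at the mode; heavily
  zero-laden counts at low depth make the collapsed posterior skewed, and
  interval calibration degrades before point recovery does.
* Efficiencies are assumed constant across cycles and samples (the
  exponential model); plateau-phase PCR violates this.
* Presence/absence metrics (Jaccard, unweighted UniFrac) are out of scope:
  under multiplicative bias a taxon never truly reaches zero, so their
  behaviour is governed by detection thresholds the model does not include.
* The worst-case ΔR² search is adversarial by construction; it bounds, not
  estimates, what realistic groupings would experience.
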