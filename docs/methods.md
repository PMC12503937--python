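# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical and design decisions a maintainer would want
spelled out.

## Phylogenetic substrate

All stages condition on the shared-ancestry matrix C of a rooted,
ultrametric, dated tree: C[i,j] is the root-to-MRCA path length (Myr),
which under Brownian motion is proportional to the covariance of tip
values. Trees are parsed with dendropy; pruning is reimplemented on flat
index arrays because the induced subtree must preserve root-to-tip depths
exactly, including a stem (root edge) when every retained tip falls in one
root subtree — C of a pruned tree then equals the corresponding submatrix
of the full C to machine precision, a property the test suite asserts.

*Whitening.* W = Λ^{-1/2}Uᵀ from the eigendecomposition C = UΛUᵀ, so
W C Wᵀ = I. Any square root works: correlations of whitened data are
invariant to the choice. Near-zero eigenvalues (duplicated lineages after
pruning) are ridged by 10⁻¹⁰·T with a warning.

*Effective sample size.* n_eff = T·(1ᵀC⁻¹1), the number of independent
observations that estimate a Brownian mean with the precision the n
correlated tips actually provide. It is exactly n on a star tree and tends
to 1 as lineages collapse. Among the ESS variants in the literature this is
the mean-estimation form; the choice matters, as discussed under
*Limitations*.

## Allometric residuals

Six univariate GLS fits, one per bone: log₁₀ length on [1, log₁₀ mass]
with error covariance ∝ C. Base-10 logs throughout (rates are reported in
log₁₀(mm)²/Myr). A single global fit precedes any subsetting; residuals
are reused downstream rather than refit per developmental class. The GLS
normal equations force the C⁻¹-weighted mean of every residual column to
zero. Residuals are exactly invariant to rescaling masses or lengths by a
constant (intercept shifts only).

Optional curation filters live in input validation, not in the fit:
caller-listed exclusions (e.g. flightless species), dropping one member —
the alphabetically later one, for determinism — of any pair diverging more
recently than a threshold (default 2 Myr when enabled), and collapsing
genera (label prefix before `_`) to their alphabetically first species.

## Modularity contrast

Each developmental subset (altricial = grades 1–2, precocial = grades 1–3;
semi-grades excluded) is whitened on its own pruned tree, so subset rows
are independent draws of the trait covariance. Pearson correlations for
all 15 bone pairs are compared with the standard two-sample Fisher-Z
statistic, one-tailed for weaker altricial correlations, substituting each
subset's n_eff for its species count, uncorrected across pairs.

The substitution makes the test deliberately conservative: whitened-row
correlations have sampling standard error 1/√(n−3) with n the subset
*size*, while the denominator uses n_eff ≪ n. On pure-birth trees n_eff
converges to a small constant (≈ 7 at the default design, measured),
shrinking |z| roughly sevenfold; the one-tailed test then essentially never
rejects, and on null simulations its size is ≈ 0 rather than 0.05. The
direction of the contrast survives: under the default unequal-rate
generator the wing–leg pairs give systematically lower z than within-block
pairs (asserted over replicates in the suite). Users wanting a calibrated
test should pass the subset sizes instead of n_eff; the conservative
substitution is retained as the method's documented behaviour.

## Divergence axis and scores

The evolutionary covariance Σ = (R−1âᵀ)ᵀC⁻¹(R−1âᵀ)/(n−1) (â the
column-wise phylogenetic mean) scales residual covariance by inverse shared
history, giving a Brownian rate matrix. The SVD of its wing×leg cross
block yields the leading salience (u₁, v₁); signs are flipped jointly so
the loading sum is positive. The concordance axis g = (u₁ ⊕ v₁) and the
divergence axis d = (u₁ ⊕ −v₁) are the π/2 rotation of one another in the
plane spanned by the pure-wing and pure-leg directions; gᵀd = 0 exactly.
Scores use the unit-normalized axis, Δ̂ᵢ = rᵢᵀd/√2, so they are in log₁₀ mm
and the downstream rate estimates are on a fixed scale; the same
convention is used end to end in the recovery experiments. The reference
value Δ̄ is the arithmetic mean over included species (a phylogenetic-mean
option exists). Wing-block-positive orientation means positive scores =
disproportionately long wings.

The share s₁²/Σs² of the first salience is the diagnostic that one
concordant axis dominates wing–leg covariance; on default synthetic data it
exceeds 99.9%.

## Regime-dependent Brownian rates

*Mk fit.* Two-state equal-rates likelihood by Felsenstein pruning with
P(t) = (1 ± e^{−2qt})/2, root fixed precocial (the assumed ancestral
state), maximized over q with a coarse log-spaced scan followed by bounded
refinement — the likelihood can have a narrow interior basin against a
high-rate plateau, which a plain bounded search misses.

*Stochastic maps.* Node states by backward pruning / forward sampling;
within-branch histories conditioned on endpoints by uniformization. For the
symmetric two-state chain the uniformized jump chain is the pure state
flip, so the virtual-jump count is a parity-restricted Poisson and every
jump is real — sampling is exact, with no rejection step. Sampled node
marginals are tested against brute-force enumeration on a fixed tree.

*Rate models.* Single rate: μ̂ by GLS, σ̂² = (y−μ̂1)ᵀC⁻¹(y−μ̂1)/n (ML, not
REML, matching the LRT use). Two-rate: Var(y) = σ²ₐBₐ + σ²ₚBₚ with
Bₐ + Bₚ = C the per-regime shared path times; the overall scale and μ are
profiled analytically, leaving a 1-D bounded search over log(σ²ₚ/σ²ₐ)
(multi-start). With Bₐ = 0 the fit reduces exactly to the single-rate fit.
Λ = 2ΔlogL is referred to χ²₁; the equal-rate point is interior so
standard asymptotics apply, and null simulations reject at ≈ 3–5%.

The default fits across 100 sampled maps and reports median rates and
median p (single-map mode available). Conditioning on *inferred* maps is
conservative relative to the true regime history: map-sampling blurs regime
boundaries toward the Mk prior, and estimated scores carry two further
attenuations (below), so full-chain LRT power at 600 tips is well below the
direct-design power. The recovery experiments therefore distinguish the two
designs explicitly.

*Ancestral scores.* BLUP conditional means under single-rate Brownian
motion: root = phylogenetic mean, interior nodes μ̂ + c_kᵀC⁻¹(y−μ̂1) with
c_k the node–tip shared depths; the rate cancels. Output includes node
depths for phenogram plotting.

## Flight ecology

Species scored present for fewer than two styles are dropped (likely
under-documentation); constant-zero columns are dropped with a warning.
Gower range-standardization is the identity on binary columns, so
distances are √(mismatch count). Classical scaling (double-centering,
eigendecomposition) retains axes explaining > 5% of positive-eigenvalue
variance; the implementation is cross-checked against scikit-bio's PCoA in
the suite. Distinctiveness uses the ML (1/n) covariance of pooled retained
scores about the pooled centroid — hence mean D² = number of retained axes
exactly — and is rooted (M = √D²) to tame the right tail. Both ecological
models are ordinary, non-phylogenetic OLS by design: the question is about
realized species positions, not evolutionary increments. They are fit per
developmental subset; mild inflation of "significant" precocial slopes is
expected from phylogenetic pseudo-replication and visible in single
realizations.

## Wing composition

Proportions are closed over the three wing bones; analysis is in centred
log-ratio coordinates (natural log; PCA is base-invariant), whose
covariance has rank 2 by closure — the third eigenvalue vanishes and two
PCs summarize everything. PC2 is oriented so positive scores track a higher
Brachial Index. The Brachial Index is humerus/radius, the radius standing
in for the ulna whose length it matches. Ternary coordinates place the
humerus vertex at the origin, radius at (1,0), carpometacarpus at the
apex. The ancestral composition is the phylogenetic mean per clr
coordinate, exponentiated and re-closed (on a star tree: the closed
geometric mean).

## Synthetic generator

The generator is the package's stand-in for the curated specimen data and
defines the study conditions:

- **Tree**: pure-birth, n = 600 tips, rescaled to height 80 Myr (order of
  crown-bird depth).
- **Regimes**: equal-rates Markov, q = 0.01/Myr, precocial root — about
  40% altricial tips at the present, echoing repeated independent origins
  of altriciality.
- **Traits**: 6-D Brownian motion whose per-regime rate matrix is
  σ²_c g gᵀ + σ²_{d,k} d dᵀ + σ²_w w wᵀ + σ²_n I with σ²_c = 5·10⁻³
  (dominant shared-size axis), σ²_{d,alt} = 3.7·10⁻⁴ and
  σ²_{d,prec} = 2.0·10⁻⁴ (the regime-dependent divergence rates the
  pipeline must recover), σ²_w = 10⁻⁴ and σ²_n = 10⁻⁵, all in
  log₁₀(mm)²/Myr.
- **Planted axes**: g is the uniform size axis. d is wing-positive /
  leg-negative with mild internal structure — the radius loads harder than
  the humerus, so strong divergence shifts the Brachial Index, and the
  proximal leg bones load harder than the tarsometatarsus; block sums of
  ±3 keep d exactly orthogonal to g. w is a regime-independent
  carpometacarpus-share axis (zero leg block, zero wing sum) supplying the
  dominant divergence-*independent* mode of wing-proportion variation.
  This geometry makes compositional PC1 the autopod axis and ties
  compositional PC2 to |Δ̂−Δ̄|, the qualitative pattern the composition
  stage is designed to display; a strictly uniform d would leave wing
  composition blind to divergence (a uniform shift of log wing lengths is
  compositionally invariant).
- **Mass**: log₁₀ mass = 2.5 + Brownian baseline (rate 3·10⁻³) +
  γ·Δ̂_true in altricial tips only + N(0, 0.1²); bone lengths are
  10^(intercept + mass/3 + residual), i.e. planted isometry.
- **Flight styles**: 12 binaries; 4 common styles at base probability 0.6,
  8 rare styles with base logit −3 plus κ·|Δ̂_true−Δ̄| in altricial tips
  only; a redraw rule guarantees ≥ 25% of species carry ≥ 2 styles.

γ = 3.0 and κ = 7.5 are not derived from any generative theory; they were
fixed once by the committed sweep in `scripts/calibrate_generator.py` so
that, through the *full pipeline* at the default design, the altricial
mass model explains about a third of mass variance (median adjusted
R² ≈ 0.33) and the altricial quadratic flight model about a fifth of
M_flight variance (median ≈ 22 points) — the two empirical anchor points
the generator is asked to reproduce.

**What the generator does not emulate**: real taxonomic tree shape (crown
birds are early-burst-like, not pure-birth — this depresses n_eff and
phylogenetic power here relative to the empirical setting), measurement
error beyond isotropic noise, missing data, graded developmental classes
(tips are altricial-2/precocial-2 only), biogeography, and any
flight-style ontology. Passing tests demonstrate internal consistency of
the inference chain under its own assumptions, not field validity.

## Known attenuations (why full-chain power is below direct-design power)

1. The global allometric slope partially absorbs the altricial
   mass–divergence coupling (mass is endogenous there), shrinking
   estimated altricial scores; measured ≈ −17% on the altricial rate at
   default conditions. Direct-design recovery (scores simulated on the
   true map) is unbiased within ≈ 2%.
2. Isotropic trait noise adds ≈ +10⁻⁵ to both regime rates (+3–5%).
3. Inferred stochastic maps blur regime boundaries toward the Mk prior.

The replication suite tests direct-design recovery at 15% and full-chain
recovery at 25%, reflecting 1–3.

## Numerical choices

- Ultrametricity tolerance: relative 10⁻⁶ of tree height.
- Near-singular C: ridge 10⁻¹⁰·T with a warning; in the two-rate fit the
  ridge is applied only if the clean Cholesky fails, so the degenerate
  one-regime case reduces *exactly* to the single-rate fit.
- Optimizers: bounded scalar searches (xatol 10⁻⁹–10⁻¹⁰) after coarse
  log-grid scans; two-rate multi-start at log-ratio −4, 0, +4.
- Ties/degenerate inputs: constant traits report σ̂² = 0; zero-variance
  residual columns yield flagged NaN correlations, not silent zeros;
  all-identical compositions are an error for PCA and a fixed point for
  the ancestral estimate.
- Determinism: every simulation consumes a single integer seed;
  `make_dataset` derives its four stage seeds from one configuration seed,
  and pipeline outputs embed tree/config hashes so reruns compare byte for
  byte.

## Limitations

- The ESS definition is the mean-estimation form; on pure-birth trees it
  saturates near 7 regardless of n, making the Fisher-Z contrast
  conservative to the point of zero rejections at this design (see
  *Modularity contrast*). On strongly early-burst trees (closer to the
  empirical avian shape) n_eff is substantially larger and the contrast
  regains power.
- The two-rate model treats the divergence score as observed; score
  estimation error is not propagated.
- The printed divergence loadings of the empirical study are not blockwise
  proportional to its concordance loadings, so the exact published axis
  construction cannot be the pure block rotation implemented here; the
  rotation is used as described, and the discrepancy is left unresolved
  rather than guessed at.
- Only two regimes and Brownian motion; no OU/early-burst models, no
  multivariate rate fit beyond the univariate score.
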