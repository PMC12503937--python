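# wingleg

Phylogenetic comparative analysis of **modular wing–leg skeletal evolution
in altricial and precocial birds**.

Birds differ enormously in developmental strategy: altricial hatchlings are
helpless and parent-fed, precocial hatchlings locomote and feed themselves
almost immediately. `wingleg` implements a pipeline for asking whether that
strategy shapes how the limb skeleton evolves — whether wing and leg
proportions evolve as independent modules, how fast the two limbs diverge
from one another, and what that divergence buys ecologically.

## The analysis

Inputs are a dated ultrametric phylogeny (Newick), a species trait table
(six limb bone lengths in mm — humerus, radius, carpometacarpus, femur,
tibiotarsus, tarsometatarsus — body mass in g, and a graded developmental
class), and an optional binary species × flight-style table.

1. **Allometric residuals.** Each log₁₀ bone length is regressed on log₁₀
   body mass by generalized least squares with Brownian-motion error
   structure, Var ∝ C, where C is the shared-ancestry matrix
   (C[i,j] = depth of the most recent common ancestor). All later stages
   consume the residuals R.
2. **Modularity by developmental subset.** Residuals of each subset are
   whitened on the subset's own pruned tree (W C Wᵀ = I), Pearson
   correlations ρ are computed for all 15 bone pairs, and altricial vs
   precocial correlations are compared one-tailed with the two-sample
   Fisher statistic
   z = (tanh⁻¹ρₐ − tanh⁻¹ρₚ) / √(1/(nₐ−3) + 1/(nₚ−3)),
   substituting phylogenetic effective sample sizes
   n_eff = T·(1ᵀC⁻¹1) for the raw counts.
3. **Divergence axis.** The evolutionary covariance
   Σ = (R−1âᵀ)ᵀC⁻¹(R−1âᵀ)/(n−1) is estimated; the SVD of its 3×3
   wing-by-leg block gives the leading salience (u₁, v₁). The concordance
   axis g = (u₁ ⊕ v₁) describes joint wing+leg size evolution; rotating by
   π/2 in the block-score plane gives the divergence axis d = (u₁ ⊕ −v₁).
   Species scores Δ̂ᵢ = rᵢᵀd/‖d‖ measure wing-vs-leg trade-off (positive =
   disproportionately long wings).
4. **Regime-dependent rates.** A two-state equal-rates Markov model is fit
   to the binary developmental states (ancestrally precocial), stochastic
   character maps are sampled (backward pruning / forward sampling, exact
   branch histories by uniformization), and single-rate vs two-rate
   Brownian models of Δ̂ — Var(y) = σ²ₐBₐ + σ²ₚBₚ, where Bₖ is shared path
   time in regime k — are compared by a 1-df likelihood-ratio test.
   Ancestral Δ̂ estimates supply phenogram coordinates.
5. **Flight ecology.** Flight-style distinctiveness
   M_flight = √((x−μ)ᵀΣ⁻¹(x−μ)) is the rooted Mahalanobis distance of a
   species' retained principal-coordinate scores (Gower/Euclidean distances
   of the style table, axes > 5% variance) from the pooled centroid; OLS
   models M_flight ≈ c + β₁Δ̂ + β₂Δ̂² and log₁₀(mass) ≈ c + βΔ̂ are fit per
   developmental subset.
6. **Wing composition.** Wing proportions p = (hum, rad, cmc)/Σ are
   analysed by centred log-ratio PCA, projected into a ternary diagram,
   related to the divergence deviation √|Δ̂−Δ̄| and to the Brachial Index
   (humerus/radius), and the ancestral composition is the inverse-clr of
   â = (1ᵀC⁻¹Y)/(1ᵀC⁻¹1).

A synthetic-data generator (`wingleg.simulate`) produces trees, regime
histories, traits, masses and flight styles with exactly the structure the
analysis assumes — one dominant concordant axis, regime-dependent variance
along an orthogonal divergence axis, and mass/flight couplings in altricial
tips only — so every stage is testable end to end without the original
specimen data.

## Worked example

Simulate a 600-species study and run the full pipeline:

```bash
wingleg simulate --n-tips 600 --seed 11 --out demo
cat > demo.yaml <<EOF
tree_path: demo/tree.nwk
traits_path: demo/traits.csv
flight_path: demo/flight_styles.csv
out_dir: demo_out
n_maps: 25
simmap_seed: 1
EOF
wingleg run --config demo.yaml
```

which prints

```
wrote synthetic dataset (600 tips, seed 11) to demo
pipeline finished; tables in demo_out
two-rate model: sigma2_a=0.000262 sigma2_p=0.000216 LRT p=0.11
```

`demo_out/` then contains the per-stage tables. The concordance row of
`axes.csv` is nearly uniform — all six bones load equally on the shared
size axis:

```
concordance,0.581,0.567,0.584,0.576,0.574,0.582
```

`rates.csv` shows the two-regime Brownian fit of the divergence score:
altricial lineages diverge faster (σ²ₐ = 2.6·10⁻⁴ vs σ²ₚ = 2.2·10⁻⁴
log₁₀(mm)²/Myr). Conditioning on *inferred* regime maps is conservative —
see `docs/methods.md` — so the map-averaged LRT p here (0.11) is much
weaker than recovery under the true regime history. `ecology_models.csv`
shows the ecological asymmetry the generator plants and the pipeline
detects: in altricial species the quadratic flight-distinctiveness term is
decisively positive (β₂ = 22.8, p ≈ 4·10⁻²⁵, adjR² = 0.33) and mass rises
with divergence (β = 2.26, p ≈ 3·10⁻²¹), while the precocial quadratic
term is null (p = 0.82).

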