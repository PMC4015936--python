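# Methods

## Model

`crowdrank` models J people's complete rankings of N items on a single
latent continuum. Item *i* has a location μᵢ shared by everyone (the
assumption that one underlying truth exists and everyone has imperfect
access to it). Person *j* forms one mental sample per item,

    x_ij ~ Normal(mu_i, sigma_j),

and reports the items sorted by their samples, smallest first. The
person-specific standard deviation σⱼ is the model's expertise parameter:
the smaller σⱼ, the more likely person *j*'s ranking matches the order of
the true locations. Observed data are therefore permutations; the x are
latent. Rankings are modelled as complete and without ties.

Two analyses fall out of the posterior. The ascending order of the
posterior-mean locations is the crowd (aggregate) ranking; because
participants with small inferred σ constrain the locations more strongly,
the aggregate implicitly up-weights inferred experts — the key difference
from the Borda count, which weights everyone equally. The posterior of σⱼ
measures each person's expertise without using any ground truth.

## Priors and identification

The likelihood is invariant under jointly translating or rescaling
(μ, σ, x), so fully flat priors would leave the posterior improper. The
defaults pin the scale weakly:

| parameter | prior | default rationale |
|---|---|---|
| μᵢ | Normal(0, 1) | fixes origin and scale of the continuum |
| λⱼ = σⱼ⁻² | Gamma(shape 2, rate 2) | proper, prior-mean precision 1, matching the unit location scale |

Both hyperparameters are configurable (`SamplerConfig.prior_location_sd`,
`prior_precision_shape/rate`). Inference about orderings and about relative
expertise is insensitive to the overall scale these priors pin down; the
absolute magnitudes of μ and σ are only identified up to it.

## Gibbs sampler

Full conditionals are all standard given truncated-normal data
augmentation, so the sampler is a bespoke four-step Gibbs sweep:

1. **Mental samples.** For each participant, scan items in their observed
   placement order; x for the item at position p is redrawn from
   Normal(μᵢ, σⱼ) truncated between the current samples of the items placed
   immediately before and after (±∞ at the ends). This leaves the
   order-constrained region invariant; in debug mode the constraint is
   asserted after every sweep.
2. **Locations.** Each μᵢ from its conjugate normal conditional (prior
   precision plus Σⱼλⱼ; precision-weighted mean).
3. **Precisions.** Each λⱼ from its conjugate gamma conditional
   (shape a₀ + N/2, rate b₀ + ½Σᵢ(xᵢⱼ−μᵢ)²).
4. **Translation group move.** The common-shift direction — adding the same
   constant to every μᵢ and every xᵢⱼ — leaves the likelihood and the order
   constraints unchanged and feels only the location prior, so steps 1–3
   alone random-walk along it (observed R̂ up to ≈1.4 at moderate burn-in).
   Sampling the shift from its exact conditional, δ ~ Normal(−mean(μ),
   s₀²/N), and applying it jointly is a standard parameter-expansion update
   that removes this slow mode; with it, R̂ ≈ 1.01 across all parameters at
   a few thousand sweeps.

Truncated normals are drawn by inverse-CDF; intervals in the upper tail are
reflected onto the lower tail, where Φ and Φ⁻¹ keep full relative precision,
and intervals whose probability mass underflows fall back to their
midpoint. Draws are clamped to the open interval so the order constraint
stays strict.

Chains are independent, chain *c* seeded `base_seed + c` on numpy's
`default_rng`; identical data and config give bit-identical posteriors. The
default schedule is 4 chains × (10,000 burn-in sweeps, then 1,000 retained
draws recording every 10th sweep); burn-in counts raw sweeps. The sampler
initializes μ at standardized negative positional tallies (so the
crowd-favoured items start low), λ = 1, and x at observed positions mapped
onto the μ range with sub-gap jitter.

## Aggregates and evaluation

* **Crowd ranking**: ascending posterior-mean μ; exact ties broken by item
  index (logged). Means rather than medians summarize the marginals.
* **Pairwise order probabilities**: fraction of retained draws with
  μᵢ < μₖ (ties counted half).
* **Borda count**: item score N−1−position summed over participants, sorted
  descending, index tie-break. Any affine decreasing positional scoring
  yields the same ordering.
* **Kendall tau distance** counts discordant item pairs (0 = identical,
  N(N−1)/2 = full reversal). The chance distribution of tau for a random
  ordering is computed exactly as the Mahonian inversion-count distribution
  (iterated convolution of discrete uniforms, in probability arithmetic).
* **Posterior tau distribution**: each retained μ draw implies a ranking;
  mass at distance t is the fraction of draws at t.
* **Expertise–performance correlation**: Pearson correlation (default;
  Spearman available) between posterior-mean σⱼ (default; precision scale
  available) and each participant's tau to the truth. Requires J ≥ 3 and
  non-degenerate variance.
* **Better/worse proportions**: fractions of participants a method strictly
  beats / strictly loses to; ties count in neither.
* **R̂**: classic potential-scale-reduction factor on retained (post-thin)
  draws, per parameter; a split-chain variant is available via a flag.
* **Classical MDS**: Torgerson double-centering and eigendecomposition of
  pairwise tau distances; negative eigenvalues among the retained ones are
  clipped to zero with a warning (tau matrices need not be Euclidean).

## Synthetic data

The generator draws datasets from the model's own process: true locations
default to 0..N−1 (equally spaced, unit gap — difficulty is then controlled
entirely by σ), true σⱼ default to log-uniform over (0.5, 3), giving a crowd
that spans near-experts (tau ≈ 0–2) to near-chance participants. The true
ordering and the generating σ are returned alongside the dataset.

Because the generator and the model share the same process, passing
recovery tests demonstrates correctness of the inference machinery, not
realism: real crowds contain shared misconceptions (correlated errors),
memory and anchoring effects, and possibly multiple latent orders, none of
which the generator emulates. Results on synthetic data are therefore a
ceiling, not a forecast, for real tasks.

## Study designs used by the tests and acceptance script

Problem sizes were chosen to exercise the standard regimes at modest cost:
oracle comparisons at N=3, J=2 (40,000 prior draws, 400 forward simulations
each, importance-weighted); expertise recovery at N=10, J=40 over 5
replicates with 4 chains × (1,500 burn-in, 500 kept, thin 3) — verified to
give results identical to the full default schedule; the wisdom-of-crowd
study at N=10, J=30 over 50 replicates with 2 chains × (500 burn-in, 400
kept). Under these conditions the measured median correlation between true
and inferred σ is ≈ 0.80: with only one ranking per participant, very noisy
participants (σ ≳ 2) all produce near-random orderings and are barely
distinguishable from one another, which flattens the top of the σ scale and
bounds this correlation well below 1 regardless of chain length. The
correlation between inferred σ and actual performance is much higher
(≈ 0.97) because both quantities are driven by the same observed ranking.

## Known limitations

* Complete rankings only: no ties, no partial or top-k lists.
* A single latent truth: subgroups with genuinely different orders are
  averaged, not detected.
* Expertise is a single scalar per person per task.
* Absolute scales of μ and σ are prior-pinned, not data-identified; only
  orderings, ratios and relative comparisons are meaningful.
* The Gibbs scan is sequential per sweep; very large J×N fits are
  CPU-bound (a 44-item, 26-person fit at the full default schedule takes on
  the order of a minute).
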