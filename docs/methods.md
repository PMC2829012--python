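# Methods

## Tag-formation model

An anchoring enzyme (AE) cleaves each of a transcript's AE sites
independently with probability `p` (0 < p ≤ 1), assumed common to all sites
and genes within a library and known in advance (it is estimated upstream
from the tag-position distribution; propagation of uncertainty in `p` is not
attempted). Only the 3'-most cleaved site yields an observable tag, so site
`j` (1-based from the 3' end) produces the tag with probability
`(1-p)^(j-1) p`. Sites whose tag sequence cannot be uniquely assigned to one
gene ("ambiguous" sites) are discarded upstream, and a gene's tag-formation
probability is the geometric mass summed over its unambiguous sites:

    phi_i = sum_{j unambiguous} (1-p)^(j-1) p,

which is `1-(1-p)^k` for a gene whose `k` sites are all unambiguous. Genes
with no unambiguous site have `phi = 0`, are unobservable in principle, and
are rejected at library construction. `phi` is computed in linear space:
for the `k` and `p` ranges of interest the values are far from underflow.
Note that `phi` is *not* monotone in `p` when the 3'-most site is ambiguous
(a lone site one position upstream has `phi = p(1-p)`, maximal at `p = 1/2`)
— this matters for the differential-expression bias below.

## Bias map, corrected MLE, corrected posterior

With mRNA-population proportions `m` (positive, summing to 1), the tag pool
is multinomial over the biased proportions

    theta_i = m_i phi_i / sum_j m_j phi_j.

The corrected MLE solves the estimating equation "biased image of m̂ equals
the observed proportions", whose closed-form solution is
`m̂_i ∝ t_i / phi_i`, normalized. (The likelihood's maximum is invariant to
the reparameterization m ↔ theta, so the naive MLE of theta pulls back
through the bias map; no iteration is needed.) Zero-count genes are retained
throughout and receive exactly 0 in the MLE. Under a Dirichlet(alpha) prior
the unnormalized log posterior is

    sum_i [ t_i log(m_i phi_i) + (alpha_i - 1) log m_i ]
      - t_tot log( sum_j m_j phi_j ),

with natural logs. At simplex boundaries the density vanishes (reported as
-inf) where the exponent `t_i + alpha_i - 1` is positive and diverges
(reported as +inf) where it is negative; neither raises. Simplex membership
is checked to |Σm − 1| ≤ 1e-9.

## The three Gibbs samplers

All three place Dirichlet(alpha) on `m`, with the presets `flat`
(alpha_i = 1, uniform over the simplex) and `tub` (alpha_i = 1/l, mass
concentrated at the boundary, minimal shrinkage). Chains default to the
simulation-study settings — 20,500 sweeps, burn-in 500, keep every 20th
(1,000 kept draws) — and are bit-reproducible for a given seed (one
generator per run, vectorized draws in fixed gene order). `m` is initialized
at the corrected MLE with zero-count genes given alpha-proportional mass.

**DPB.** `N ~ ceiling(Gamma(gamma1, gamma2))` (shape/scale; defaults 100 and
200, prior mean 20,000), `g_i ~ Poisson(N m_i)`, `t_i ~ Binomial(g_i,
phi_i)`. Full conditionals: `g_i = t_i + Poisson(N m_i (1-phi_i))` (binomial
thinning), `m ~ Dirichlet(alpha + g)`, `N ~ Gamma(gamma1 + Σg, rate 1/gamma2
+ 1)` sampled continuously and ceiled — the discrete conditional is not
available in closed form and at N ~ 10^4 the discretization error is
negligible (documented approximation).

**DMB.** `N ~ Poisson(lambda)`, `g ~ Multinomial(N, m)`, binomial thinning.
Marginally `u_i = g_i - t_i ~ Poisson(lambda m_i (1-phi_i))` independently;
the data carry no information about `N` itself, so only `m` (and optionally
`u`) is retained. `lambda` carries a Gamma(gamma1, gamma2) hyperprior by
default (update: Gamma(gamma1 + Σg, rate 1/gamma2 + 1)); a fixed-lambda mode
is provided because the reference formulation is ambiguous about whether
lambda is updated. Note that with the hyperprior the DMB m-marginal is
analytically identical to DPB's (both integrate to
`Π(m phi)^t · m^(alpha-1) · (1/gamma2 + Σ m phi)^-(gamma1+t_tot)`), so the
two samplers differ only through N's discretization.

**MD.** The observed vector is augmented by `r`, the unconverted-transcript
count, with prior `r ~ Poisson(mu)`. Conditionals: augmented vector
`(m, m0) ~ Dirichlet(t + alpha, r + 1)`; `r ~ Poisson(mu · m0)` — the unique
conditional consistent with the Poisson-prior × augmented-Dirichlet joint
(solving for the joint supported by both conditionals gives
`π(m, m0, r) ∝ m^(t+alpha-1) (mu·m0)^r / r!`). Kept `m` draws are the first
`l` coordinates renormalized; `r` and `m0` are retained. The default
`mu = t_tot · Σ m̂_i(1-phi_i) / Σ m̂_i phi_i` (plug-in unconverted mass at
the corrected MLE) reduces algebraically to `Σ t_i/phi_i - t_tot` and is
computed once before sampling.

Two closed forms accompany MD: the conditional mode
`(t_i + alpha_i - 1)/(Σ(alpha_j + t_j) + r - l)` (undefined when
`t_i + alpha_i < 1`, e.g. tub prior with a zero count — the formal mode
leaves the simplex), and the prior-marginalized mean obtained by averaging
`E[m_i | r] = (t_i + alpha_i)/(Σ(t_j + alpha_j) + r + 1)` over
`r ~ Poisson(mu)`, evaluated by exhausting the Poisson mass to a 1e-12 tail.

*A flagged discrepancy.* The prior-marginalized mean and the MD sampler
agree only on the renormalized scale, where both reduce exactly to
`(t_i + alpha_i)/Σ(t_j + alpha_j)` (by the Dirichlet aggregation property
the renormalized block is Dirichlet(t+alpha), independent of `m0` and `r`).
On the augmented scale they differ systematically: the sampler's stationary
law tilts the augmented coordinate by `exp(mu · m0)` (posterior
marginalization of `r`), whereas the closed form averages over the *prior*
of `r`. The test suite pins the sampler's augmented-scale behaviour to an
exact one-dimensional tilted-Beta quadrature instead of forcing agreement.
A practical consequence of the aggregation property: MD corrects the
proportion vector only through the single global unconverted category, not
per gene, so on libraries with strongly heterogeneous phi its point
estimates track the uncorrected Dirichlet-multinomial.

### Numerical safeguards

Tub-prior Dirichlet updates draw gammas with shapes as small as 1/l; such
draws frequently fall below the float64 range. Boosted/log-space sampling
cannot help — the values are unrepresentable in the linear space the
normalization requires — so draws below a floor of 1e-290 are clamped to it
and counted (the count is logged and stored per run). The floor sits some
290 orders of magnitude below any posterior mass of interest, yet keeps the
normalized coordinates inside the normal float64 range: letting them go
subnormal both risks underflow to exact zero and degrades sweep throughput
badly (subnormal arithmetic is an order of magnitude slower on common
hardware). The check is skipped when all shapes are ≥ 0.5, where underflow
probability is below ~1e-150. The DPB N-update aborts with a diagnostic if
N overflows 1e15.

### Diagnostics

`autocorrelation` (statsmodels' FFT ACF behind the module surface) reports
sample autocorrelations at requested lags; constant chains are rejected. The
prior-dependent mixing pattern of DPB's N chain deserves a note. The
per-gene feedback gain of the (g → m → g) loop is approximately
`(1-phi_i) · Σg/(Σg + Σalpha)`. Consequences: (i) with protocol-style phi
(all ≥ p = 0.55) the N chain mixes rapidly under *both* priors; (ii) genes
with very low phi and positive counts mix slowly under *either* prior — and
slower under tub, whose pseudo-count damping (Σalpha = 1) vanishes; (iii)
only libraries whose low-phi genes are all zero-count can reproduce the
reference pattern "flat slow / tub fast", and then only partially. The
diagnostic fixture in the test suite uses phi independent of abundance,
log-uniform over the empirically documented range [0.003, 1]; it reproduces
the flat-prior slow mixing (lag-10 autocorrelation ≈ 0.67) but not the
near-zero tub value, for the mechanistic reason above, and the corresponding
assertion is expected to fail until a stand-in with the real library's
phi/count joint structure is available.

## Simulation study

The coverage protocol: per-gene AE-site counts `1 + Poisson(2)` (every
simulated site unambiguous), cleavage probability `p = 0.55`, libraries of
15,000 multinomial tags drawn from the biased proportions, nominal 95%
equal-tail intervals from each sampler, coverage pooled over (genes in
abundance bin) × (replicate libraries). The five abundance bins
(0–1.67e-5, …, 6.74e-3–1.35e-1) carry 25/209/578/165/23 genes for l = 1,000
and 1181/3678/1173/133/13 for l = 6,178.

The true `m` is synthetic: each bin's genes are placed log-uniformly inside
the bin and the vector is renormalized, with bin membership recorded *after*
renormalization (half-open [low, high) intervals). The bottom bin's zero
lower edge is replaced by `upper/7.37`, matching the log-width of the
neighbouring bins. Renormalization divides by ≈ 1.7, so some genes migrate
one bin down; the recorded (post-renormalization) bins are the ones
reported. What this stand-in does *not* emulate: the empirical abundance
distribution inside bins (the original design inherited real-data
estimates), correlation between phi and abundance, and overdispersion
between biological replicates — coverage numbers are therefore
tolerance-level reproductions, not exact ones.

Replicate libraries use per-library seeds (`seed + index`, order
independent); chains are advanced in vectorized batches of 200 libraries
(seeded via `SeedSequence(seed, combo, chunk)`; the batch partition is part
of the protocol definition). A batch on which a sampler fails is excluded
from the tally with a logged count. Default problem sizes were chosen to
make the full study a desk-scale computation: 200 replicate libraries for
the headline run (the acceptance script) with 20,500-sweep chains; the
module default `n_libraries = 1000` matches the original design.

## Differential expression

For a tag formed `k` AE positions upstream of the 3' end, comparing naive
tag proportions across libraries A and B multiplies the true odds ratio by
`(p_a(1-p_a)^k / norm_a) / (p_b(1-p_b)^k / norm_b)`. The default
normalizers are 1 (pure formation-probability ratio), which reproduces the
reference value ~1.9 for `p_a = .92, p_b = .96, k = 1`; normalizing by the
per-library aggregate (≈ p under a 3'-only analysis) instead gives 2.0 for
the same scenario and exactly 1.0 at `k = 0`. The discrepancy between the
two conventions is documented rather than resolved; both are exposed.

`diff_test` pairs kept draws from two independently sampled libraries by
index (equivalent to any pairing under independence, and reproducible),
truncating to the shorter chain, and reports per-gene posterior summaries of
the difference `m_A - m_B` and of the odds ratio
`[m_A(1-m_B)]/[m_B(1-m_A)]` (draws clamped away from 0 as in the samplers),
two-sided tail probabilities `2·min(P(diff>0), P(diff<0))`, and a flag when
the central 95% interval of the difference excludes 0. No multiplicity
adjustment is applied by default; a Bonferroni correction over the tested
set is available behind a flag. `joint_test` restricts the joint draws to a
gene set and reports the fraction of draws in which every difference shares
a strict sign (identical draw sets give 0 — reported as non-informative —
since ties count as neither sign) plus the worst componentwise tail
probability.

## Design choices that were genuinely open

* **Population-size prior vs the corrected posterior.** Integrating N (or
  lambda) out of DPB/DMB leaves an extra factor
  `(1/gamma2 + Σ m phi)^-(gamma1+t_tot)` where the corrected posterior has
  `(Σ m phi)^-t_tot`. The two coincide in the vague limit gamma1 → 0,
  1/gamma2 → 0; with the defaults (gamma1 = 100) the distortion is
  negligible at protocol scale (t_tot = 15,000 ≫ gamma1) but dominant on
  toy libraries. Oracle-equivalence tests therefore use a vague
  population-size prior on toys; applications at realistic scale use the
  defaults.
* **DMB's lambda**: hyperprior by default, fixed mode available (see above).
* **MD's r-conditional**: Poisson(mu·m0), derived as the unique consistent
  form; mu fixed at its plug-in value, not updated within the chain.
* **Tolerances**: simplex membership 1e-9; corrected-MLE estimating-equation
  residual < 1e-12; Poisson-mass truncation 1e-12.

## Known limitations

* `p` is treated as exactly known; uncertainty in `p` (and hence phi) is not
  propagated.
* The synthetic ground truth for the coverage study is a structural stand-in
  (see above); headline coverages reproduce reference values to ±0.05–0.10,
  not to print precision.
* MD's per-gene estimates are uncorrected (aggregation property); it is
  retained for comparison, and DPB is the recommended sampler.
* Tag-to-gene mapping, estimation of `p`, isoform-aware extensions and
  transcriptome-size estimation are out of scope; inputs are tag-count
  tables with known phi (or site counts plus `p`).
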