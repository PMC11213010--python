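# Methods

## Model

`sortscreen` models the counts of guide *h* across the *J* FACS bins of
replicate *n* as Dirichlet-multinomial,
`B_nh ~ DirMult(c_nh, phi_n * q(t_n, beta_h))`, conditioned on the
guide's total `c_nh`. Conditioning on totals deliberately discards
information about guide abundance: sort-seq measures where a guide's
cells sit in the marker distribution, not how many there are, and
abundance is confounded with library representation.

The bin-mass function treats the marker of a perturbed cell as Gaussian
with unit variance and mean shifted by the guide effect (effects are
therefore in marker-SD units; a non-unit marker variance is not
identifiable from binned data and is fixed at 1):

    q(t, beta)_j = Phi(Phi^-1(t_j) + beta) - Phi(Phi^-1(t_{j-1}) + beta)

with `t_0 = 0`, `t_J = 1` mapped symbolically to -inf/+inf. Written this
way a **positive effect moves mass toward bin 1, the lowest-marker
gate**. Which direction is "positive" is a labelling choice; the
simulator sorts cells on `z - sum(beta)` with the same cutpoints, so
simulated truth and inferred effects carry the same sign end to end and
the convention cancels out of every comparison.

Gene-level structure is spike-and-slab: an inclusion indicator
`psi_g ~ Bernoulli(pi)`, a gene effect `mu_g` that is exactly zero when
excluded and `N(0, sigma^2)` when included, and guide effects
`beta_h ~ N(mu_g, tau^2)`. Guides of excluded genes still jitter around
zero with sd `tau` — the model's account of guide-level noise and mild
off-target activity — while control guides are clamped at exactly zero
and anchor the null. There is no explicit off-target term: a guide
inconsistent with its siblings drags the shared `mu_g` toward zero and
lowers the PIP, which is the desired behaviour.

The gate positions `t_n` are parameterized by the per-replicate bin-mass
simplex `w_n` with a `Dirichlet(alpha_t * w0)` prior; cutpoints are
derived by cumulative summation, so monotonicity holds by construction.
Because `t_n` is learned per replicate it absorbs both drifting FACS
gates and unequal per-bin collection or sequencing depth; no per-bin
size factors are used.

### Hyperpriors (defaults, all overridable)

| parameter | prior | default rationale |
|---|---|---|
| sigma (slab sd) | half-Cauchy(1) | weakly informative on the SD scale |
| tau (guide sd) | half-Cauchy(0.5) | guides cluster near their gene effect |
| pi | Beta(1, 9) | screens typically have ~10% true hits |
| phi_n | Gamma(shape 2, rate 0.02) | broad, mean 100; data dominate quickly |
| w_n | Dirichlet(J * w0), w0 equal | one pseudo-count per bin |

## Sampler

Metropolis-within-Gibbs. Three blocks are exact Gibbs draws:

* `psi_g`: Bernoulli full conditional with `mu_g` integrated out in
  closed form (slab, guide prior and spike are all Gaussian, so the
  marginal likelihood of a gene's guide-effect vector under inclusion is
  a one-dimensional Gaussian integral with an analytic answer). Mixing
  of the inclusion indicators is the crux of the model and the collapsed
  update avoids the poor mixing of joint (psi, mu) proposals.
* `mu_g`: conjugate Gaussian given (psi_g, beta, sigma, tau).
* `pi`: conjugate Beta given the indicators.

Everything else — per-guide `beta_h`, the simplex `w_n` in additive
log-ratio coordinates (with the ALR Jacobian in the target), `log phi_n`,
`log sigma`, `log tau` — uses random-walk Metropolis with Robbins-Monro
step-size adaptation toward 0.44 acceptance (0.28 for the multivariate
simplex block), frozen after burn-in so detailed balance holds in the
sampling phase. Defaults are 4 chains x 5,000 draws after 5,000 burn-in;
design sweeps default to 2 chains x 1,000 + 1,000, which testing shows
is enough for stable PIP ranking at sweep scale.

Summaries: PIP is the pooled mean of `psi_g`; the effect estimate and
central credible interval are computed from `mu_g` draws **conditional
on inclusion** (spike draws are identically zero and would pin every
interval to zero; genes with no slab draws are flagged not-callable).
Split-R-hat is reported for the global parameters and the worst guide
effect, with a warning above 1.1. Identical seed, configuration and data
give bit-identical output.

The calling rule at level q: PIP strictly greater than 1 - q **and** the
(1 - q) credible interval excluding zero. The estimated FDR of a call
set made this way is q itself; the Bayesian FDR `mean(1 - PIP)` over
called genes is available from the outputs as a diagnostic. Ranking is
by PIP descending, ties by |effect| descending, then gene id.

### Two-bin (outer-gates-only) screens

Many screens sequence only the two outer gates. The likelihood then
conditions on a cell landing in an observed bin: Dirichlet-multinomial
over observed bins with concentration `phi * q_obs / sum(q_obs)`, which
reduces exactly to the full likelihood when every bin is observed. The
null masses of the full scheme must be supplied (they are known from the
sort configuration, e.g. 15%/5%/1% outer gates). Latent middle-bin
counts are imputed each iteration — unobserved cell count per guide
drawn negative-binomial from the observed total and landing probability,
split across middle bins by their masses — and used only when updating
`w_n` and `phi_n`. The completion is the minimal coherent mechanism for
letting outer-bin data inform the gates; middle masses remain mostly
prior-driven, which is a real limitation of outer-bin-only designs and
one reason they lose power.

## Simulator

The generative process per replicate: a guide-representation simplex
`rho ~ Dirichlet(tau_rep / p * 1_p)` over the `p` library members (one
draw per replicate, representing independent infections); per cell
`k ~ Poisson(MOI)` integrations, uninfected cells discarded (mirroring
GFP+ selection); guide identities drawn with replacement from `rho`;
marker `z - sum(beta)` over the cell's **distinct** effect guides
(additive, no interactions; a double integration of one construct does
not double its effect); gating at the configured cutpoints, cells in
uncollected gates dropped; cell-level counts credit **every**
integration a cell carries (sequencing gDNA amplifies each construct, so
multi-guide cells are represented, not filtered); finally per-bin
sequencing counts are Dirichlet-multinomial across guides centred on the
bin's cell counts.

Choices where reasonable people could differ, made once:

* **Effect family default**: `normal(0, 0.25)` truncated away from
  (-0.02, 0.02), so every "effect" gene has a nonzero effect and the
  median effect is modest (~0.2 SD). Sweep conclusions are conditional
  on the family; it is a required, reportable config field.
* **tau_rep = 1000**: gives mild library-representation skew
  (guide-share CV ~ sqrt(p / tau_rep)); real libraries vary and the
  value is configurable.
* **tau_guide = 0.05**: guides cluster tightly around their gene effect,
  i.e. the library is assumed high-quality; guide-efficiency modelling
  is out of scope.
* **phi_seq = 200**, interpreted as the Dirichlet concentration of an
  average-representation guide (total concentration `phi_seq * p`), so
  sequencing noise (~7% CV) does not blow up with library size.
* **Sequencing depth**: by default each bin is sequenced at its
  collected-cell total; a fixed per-bin depth is configurable.
* **Coverage** in sweeps is the effective (MOI-adjusted) measurements
  per guide, `n_cells * MOI / p`; coverage-targeted configs invert this
  to a cell count.

What the simulator does **not** emulate: guide efficiency and editing
outcomes, fitness effects coupling abundance to the marker, epistatic
interactions, donor-to-donor biology beyond independent replicate draws,
PCR jackpotting beyond the Dirichlet-multinomial, and non-Gaussian
marker shapes. Passing tests therefore show the inference is correct and
well calibrated *under this generative model*, not that any real screen
satisfies its assumptions.

## Numerical notes

* `Phi^-1(0)` / `Phi^-1(1)` are handled symbolically (the CDF evaluates
  to exact 0/1); bin masses are clipped at tiny negative round-off from
  CDF differencing.
* Zero concentrations in the Dirichlet-multinomial are structural
  zeros: probability one if the count is zero, -inf otherwise. An
  all-zero count row has likelihood 0 everywhere and is retained with a
  warning.
* Malformed states (a nonzero control beta, mu != 0 under exclusion)
  raise; -inf is reserved for valid states of zero density (e.g. an
  included gene under pi = 0).
* Child seeds for sweep cells are sha256-derived from the master seed
  and the cell's coordinates, below 2^31, so any row reproduces in
  isolation.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline at
reduced scale — 200-gene calibration screens (vs thousands in a
production screen), 60-gene trend comparisons, 2 chains x 1,000 draws —
sizes chosen so the whole suite completes in minutes while leaving the
qualitative and calibration conclusions stable across seeds. The
acceptance script reports the realized false discovery rate of q = 0.10
calls averaged over 50X/200X/500X coverage and three repetitions per
level.

## Known limitations

* The spike-and-slab CI is slab-conditional; for genes with PIP near
  zero it describes a counterfactual ("if this gene had an effect") and
  should be read together with the PIP.
* Credible-interval coverage is not expected to be nominal under
  shrinkage; empirically ~80-90% at moderate coverage.
* `tau` mixes slowly on very small screens (few true effects); the
  shipped defaults flag this via split-R-hat rather than hiding it.
* The two-bin mode identifies middle-bin masses only weakly (see above).
* Inference uses the gene-level view only; no cell-level inference
  variant is provided.
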