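# Methods

## The biological model

`memokin` models the population dynamics of circulating memory-phenotype
CD4 T cells — central memory (T_CM, CD62L⁺) and effector memory (T_EM,
CD62L⁻) — in mice, as read out by three experimental systems:

1. **BrdU/Ki67 labelling in busulfan chimeras.** BrdU is incorporated
   during DNA synthesis with per-division efficiency ε; Ki67 is
   expressed during and for T ≈ 3 days after mitosis. Following the
   fractions BrdU⁺, BrdU⁺ within Ki67-high, BrdU⁺ within Ki67-low, and
   Ki67-high over a 21-day pulse and 14-day chase constrains division,
   loss and influx rates. Stratifying by host/donor lineage in busulfan
   chimeras separates cell cohorts of different average age; comparing
   young and old mice separates cell-age from host-age effects.
2. **Chimerism (donor-fraction) timecourses.** After bone-marrow
   transplant, donor cells gradually replace host cells in each subset;
   the donor-fraction curve identifies the per-capita replacement rate
   f and the donor content of the influx, and matches each subset to
   its precursor.
3. **Fate-mapping reporters.** Tamoxifen-induced heritable labels
   (mTom in CD4⁺ cells, YFP in Ki67⁺ cells) whose dilution or Ki67
   trajectories test the fitted models out of sample.

### Compartment structure

Each stratified population (cohort × subset × lineage) is described by
eight compartments, {fast, slow} × {Ki67-high, Ki67-low} × {BrdU⁺,
BrdU⁻}, under one of four topologies:

- **branched** — fast and slow are independent lineages, each fed by a
  share (`phi_fast_fraction`) of the constitutive influx;
- **linear** — influx enters the fast pool, which matures into slow at
  rate γ;
- **burst** — influx enters a quiescent pool; cells activate into a
  dynamic, dividing state and revert at a low rate. The quiescent pool
  does not divide (its division rate is fixed at 0 by default; a
  nonzero value is accepted by the data model);
- **temporal** — a single population whose loss rate depends on Ki67
  status. This is the model class the labelling data reject.

Bookkeeping rules: division removes the mother and creates two
Ki67-high daughters; during the pulse an unlabelled division becomes
BrdU⁺ with probability ε (both daughters share the outcome), and
labelled mothers always produce labelled daughters; label dilution
below detection is ignored over the 14-day chase. Influx enters
Ki67-high (new memory cells have recently divided) and is BrdU⁺ with
probability ε during the pulse — the labelling rule for incoming cells
is not dictated by the data, and this choice keeps the per-division
semantics uniform; it is exposed through the same code path should an
alternative be needed. Ki67-high decays to Ki67-low at rate β = 1/T,
either as a single exponential stage (default) or as an Erlang chain
of n sub-stages with total mean T, which sharpens the observed delay
before the first BrdU⁺ Ki67-low cells appear.

### Quasi-equilibrium closure

Total numbers and Ki67 fractions are approximately constant over the
35-day window, so pool sizes are held stationary: loss rates left
unset are solved from the balance equations per pool
(`close_parameters`). For the temporal topology the Ki67-high/low
split is itself rate-determined, so both loss rates are always closed
jointly (single-stage Ki67 only). A consequence worth noting: under
closure the net loss rate λ = δ − α of each pool equals its per-capita
influx exactly, which is the structural form of the influx/net-loss
degeneracy discussed below.

### Numerics

Within each phase (pulse, chase) the system is linear time-invariant,
dx/dt = Ax + b. It is propagated *exactly* by eigendecomposition of A
(x(t) = V e^{Λt} V⁻¹(x₀ − x_p) + x_p), with a matrix-exponential
fallback on the augmented system when V is ill-conditioned
(cond > 1e10) or A is singular. Phase switching at `pulse_end` is
therefore exact, there is no step-size control to tune, and one
likelihood evaluation costs ~0.5 ms. States more negative than
−1e-8 × N are treated as solver failures; smaller negatives (roundoff)
are clipped to zero. Steady states are obtained from the BrdU⁻ block
with one balance row per pool replaced by its occupancy constraint,
which also handles rate-free corner cases exactly. Only the
reporter-dilution predictions, whose forcing is time-varying, use an
adaptive integrator (LSODA, rtol 1e-9, atol 1e-12; the closed-form
check holds to 1e-8).

## Noise model and likelihood

Observed fractions are modelled with independent beta likelihoods,
Beta(μκ_c, (1−μ)κ_c), with the model mean μ from the forward solution
and one fitted precision κ_c per channel. The channels fitted by
default are the three *independent* gate measurements — BrdU⁺ within
Ki67-high, BrdU⁺ within Ki67-low, and the Ki67-high fraction. The
marginal BrdU⁺ fraction is their deterministic combination
(k·b_hi + (1−k)·b_lo, the same identity the data model enforces on
input rows), so fitting it as a fourth independent observation double
counts information; simulation-based calibration showed the resulting
posteriors are over-tight (coverage ~74% at nominal 95%). It can still
be included via `channels=("brdu", ...)`. A logit-normal likelihood
would be a straightforward alternative parameterisation; the beta form
is the default because it respects the [0,1] support at the very small
Ki67-low fractions seen early in the pulse.

## Inference

Posteriors are sampled with an affine-invariant ensemble sampler
(differential-evolution and snooker moves, 80/20), on log/logit-
transformed parameters with weakly-informative normal priors
(documented in `memokin.inference._DEFAULT_PRIORS`, all overridable).
The two-pool models are exchange-symmetric in the fast/slow labels;
the joint prior is truncated to α_fast > α_slow to remove the mirrored
mode. Walkers are initialised from a Laplace approximation at a
Nelder-Mead posterior mode (eigenvalues of the covariance clipped to
[1e-10, 1]), which shortens burn-in substantially; defaults are 32
walkers, 300 burn-in plus 500 kept steps, thinned by 4. Convergence is
flagged with split-Rhat computed over four walker groups (ensemble
walkers are coupled, so per-walker Rhat overstates disagreement) and
pooled effective sample sizes; there is no divergence diagnostic in an
ensemble sampler, and `FitResult.diagnostics` reports 0 by convention.
Pointwise log-likelihoods are collected during sampling (emcee blobs)
and PSIS-LOO/ELPD computed with ArviZ; pairs of models within 4 ELPD
units are flagged indistinguishable, and observations with Pareto-k
above 0.7 are visible through `pareto_k_max`.

### Influx priors

The per-capita replacement rate estimated from donor-fraction
timecourses is the same quantity as the labelling model's influx rate
f. Replacement posteriors are summarised as a lognormal prior on f
(moment-matched on the log scale; quantile agreement with the draws is
checked to 5%) and a beta distribution for the source chimerism. Under
a vague influx prior the posterior correlation between f and the net
loss rate of the influx's main descendant pool exceeds 0.9 — under
quasi-equilibrium these are not separately identifiable — and the
replacement-derived prior pulls it below the 0.9 flag (to ~0.8 under
the default synthetic conditions; part of the correlation is
structural, see the closure note above, so it does not vanish).

## Synthetic data

The generators are the package's study conditions, not fixtures:

- **Labelling**: the 21 d pulse + 14 d chase design with samples on
  days {2,4,7,10,14,17,21,24,28,31,35}, two mice per timepoint, 5000
  flow events per sample. Each mouse × channel mean is first drawn
  from a beta distribution with precision κ = 500 (between-mouse
  biological variability, sd ≈ 0.02 on mid-range fractions — replicate
  mice differ by far more than counting noise at these event depths),
  then gate counts are binomially sampled; the marginal BrdU⁺ fraction
  is reconstituted from the gates so the additive consistency
  invariant holds row by row. Pure binomial noise (κ = None) is
  available and is used by the binomial-variance test.
- **Chimerism**: homogeneous replacement curves with beta noise
  (κ = 200), 14 timepoints × 4 mice over days 45–600 after transplant
  (representing pooled busulfan cohorts), plus constant-chimerism
  reference series for DP1 thymocytes and naive CD4 T cells. The
  replacement-rate truths equal the labelling influx truths by
  construction.
- **Dilution**: exponential-to-plateau source curves with truncated
  Gaussian noise.
- The default parameter preset places rates inside reported ranges:
  fast cells turning over in days, slow interdivision times of 100–200
  d and lifespans of 60–100 d, ε = 0.6, T = 3.1 d, replacement of
  1–2%/day; donor cells in young chimeras carry more fast cells than
  host cells, converging in the old cohort.

What the generators do *not* emulate: gating error and spillover,
longitudinal correlation within a mouse (each mouse is sampled once),
age drift within the 35-day window, and any real-data file layouts.
Passing tests therefore demonstrate correctness of the machinery under
the model's own assumptions, not fidelity to any particular mouse
dataset.

The agent-based oracle is an exact event-driven stochastic simulation
(numba-compiled) of the same rules — per-cell division with BrdU coin
flips, Ki67 reset and decay, loss, influx, pool transitions — run on
multinomially-sampled initial populations. It covers the single-stage
Ki67 model; the Erlang option is exercised through the deterministic
delay property instead. ODE summaries agree with it within Monte-Carlo
error across all four topologies (240 point checks; the test allows
the expected handful of 3–4.2 SE excursions that 240 simultaneous
3-SE checks produce by chance).

## Derived quantities

Net loss λ = δ − α; clonal half-life ln2/λ with an infinite sentinel
for λ ≤ 0 so that posterior summaries remain computable (the mass at
infinity is reported alongside). Size-weighted mean lifespan
1/(Σ N_i δ_i / Σ N_i). Two field-standard approximations are provided
with their validity limits documented: the upslope estimator 2ε/p
(p estimated by weighted least squares through the origin over the
first 4 days by default, a window choice exposed as `t_max`) is
accurate to ~10% when influx is small relative to division; the Ki67
estimator −T/ln(1 − k/2) carries a +2T absolute bias for small k
(est ≈ 1/(f+α) + 2T), so it requires lifespans well above the Ki67
lifetime — comfortably true for memory T cells — and its "within 15%"
recovery property is tested in that regime.

## Validation predictions

Reporter-label dilution disables label creation by division (the label
is heritable) and drives each pool with the source's labelled fraction;
predictions for T_EM can be chained on the predicted T_CM trajectory
(total or fast-pool-only, default total). Bands are pointwise 2.5/97.5
percentiles over posterior draws; non-stationary draws are rejected
and counted. Ki67-reporter transfers are modelled by marking every
Ki67-high cell 3 days before transfer, evolving marked (closed) and
unmarked (influx-receiving) cohorts to the transfer time, then
dropping the influx term for isolated transfers. Both host-side
predictions reproduce the qualitative experimental pattern: marked
cells start Ki67-enriched, decline and converge; isolated effector
memory loses Ki67 while bulk transfers preserve it.

## Known limitations

- Fixed-truth frequentist coverage of the 95% credible intervals is
  below nominal (~85% aggregated) for the ridge-coupled trio
  (α_fast, β, ε) at the default study conditions, although
  self-consistent simulation-based calibration (parameters drawn from
  the prior, data from the fitted likelihood) is statistically
  compatible with nominal coverage. This is the usual behaviour of
  Bayesian intervals at a fixed truth in a weakly-identified direction,
  not a sampler defect (4× longer chains reproduce the intervals).
- Data generated *by* the branched model favour the branched fit: with
  the replacement-derived influx prior, the linear model trails by ~5
  ELPD units and burst by ~10 on default synthetic data, whereas the
  temporal model loses by >50. Real data, which no candidate generates,
  need not show this asymmetry.
- The temporal topology supports single-stage Ki67 closure only.
- Absolute cell counts are carried but not fitted; all likelihoods are
  fraction-level.
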