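# Methods

## The model

`weeddyn` analyses longitudinal surveys in which the abundance of an
arable weed (the motivating system is *Avena fatua*, common wild oat, in
Japanese winter-cereal fields) is recorded once a year per field as an
ordinal coverage class: 0 "absent" (0 % ground cover), 1 "low" (< 20 %),
2 "medium" (20–50 %), 3 "high" (> 50 %). This is a density-structured
population model: the state is the coverage class, and the dynamics are a
Markov chain over the four classes whose transition probabilities depend
on that year's management.

The transition probabilities come from a cumulative-link (proportional-
odds) mixed model. Conditional on the previous year's class *i*, the
covariates *x* of the destination year and a site effect ε_s,

    P(Y_t ≤ j) = logistic(β_{j|j+1} − η),    η = α_i + βᵀx + ε_s,

with strictly ordered thresholds β_{0|1} < β_{1|2} < β_{2|3} and the
class probabilities given by successive differences of the cumulative
probabilities. The previous-year class enters as three free treatment
dummies α_1, α_2, α_3 (α_0 = 0); monotonicity of the α's is *checked*
after fitting and reported as a warning when violated, not imposed during
optimization, because the per-class effects are what the selection table
reports. Covariates are treatment-coded with baseline "wheat, not
irrigated, not delayed"; temperature (mean December–April, °C) enters raw
and uncentered. Covariates attach to the **destination** year of each
transition: they describe the management applied between the two
observations (summer irrigation, for instance, is the summer before the
destination season).

ε_s ~ Normal(0, σ²) is shared by all transitions of a site. The marginal
likelihood integrates it out per site:

    L_s = ∫ ∏_k P(Y_k = y_k | Y_{k−1}, x_k, ε) φ(ε; 0, σ²) dε.

## Numerical choices

* **Quadrature.** Default is adaptive Gauss–Hermite with 15 nodes,
  centred at the per-site posterior mode with curvature-matched scaling;
  the mode is found by a damped, vectorized Newton iteration on the
  strictly concave per-site objective (gradient tolerance 1e−9). A
  Laplace approximation is available by flag. On a three-transition toy
  site the adaptive rule agrees with a 100 001-point trapezoid oracle to
  ~1e−12, and 15 vs 31 nodes differ by less than 1e−6.
* **Parameterization.** Threshold ordering is enforced by optimizing
  (β_{0|1}, log Δ_1, log Δ_2); σ is optimized as log σ. σ = 0 is handled
  exactly (the marginal likelihood degenerates to the conditional one) and
  can be pinned (`FitOptions(fix_sigma=0.0)`) for comparison against
  fixed-effects proportional-odds fits.
* **Optimizer.** L-BFGS-B with 3-point finite-difference gradients, box
  bounds ±30 on coefficients, and up to three deterministic starts: a null
  start, a seeded jittered start, and a warm start from a σ≈0 fit. Fits
  are deterministic given the options. Non-convergence is reported in the
  result (`converged`, `grad_norm`), never raised.
* **Separation.** Categories whose outcome is deterministic in the data
  (paddy rice typically is: every observed transition out of a paddy year
  ends at class 0) drive their coefficient to the box bound. Coefficients
  with |value| > 10 are flagged quasi-separated and reported as-is; no
  penalization is applied because projections only need the saturated
  probabilities, which are insensitive to the exact magnitude.
* **Model count.** AIC = −2·loglik + 2·k with k = 3 thresholds + included
  fixed-effect coefficients (the three α's count when previous coverage is
  included) + 1 for σ. Backward elimination drops, at each stage, the term
  whose removal lowers AIC most, stopping when no removal lowers it; ties
  within 1e−6 resolve toward the smaller model; every evaluated candidate
  is kept so the selection table can be reconstructed.
* **Equilibria.** Transition matrices are built column-by-column from the
  fitted probabilities (each column sums to 1 by construction, to 1e−12).
  Stationary distributions use a dense eigen-decomposition of the 4×4
  matrix, selecting the eigenvalue nearest 1, clipping entries below
  1e−12 in magnitude and renormalizing; numerically complex, negative or
  non-unique eigenvectors trigger a 500-step power-iteration fallback
  with a warning. For a two-use rotation the phase states are the
  stationary vectors of P₁P₂ and P₂P₁; the printed phase row of use 1 is
  the state distribution in the years when use 1 is grown. Convergence
  years are reported at L∞ < 0.01, matching 2-decimal reporting.
* **Projections** fix ε = 0 (the average field); a profile-level
  `epsilon` supports sensitivity analyses. Transition pairs are formed
  only between consecutive years by default (`max_gap=1`); bridging gap
  years is possible but always explicit.

## The projection model

The default model for management projections includes previous coverage,
summer irrigation and farmland use, excluding delayed sowing and
temperature. Both excluded terms move AIC by well under 2 units in the
original analysis and in the emulation here, and a projection model that
required a temperature scenario would be harder to use; this choice is
exposed (`projection_spec()`) and overridable.

## The synthetic-data generator

`simulate_dataset` draws exactly from the model's generative process: per
site a Gaussian intercept, a first-year class from a configurable initial
distribution, then yearly covariates from an i.i.d. management process
(category probabilities for farmland use, Bernoulli rates for irrigation
and delayed sowing, Gaussian temperature) followed by a multinomial class
draw; site-years are masked at a fixed missingness rate while the latent
chain keeps running. Sites consume independent sub-streams, so enlarging
a simulation never perturbs existing sites.

`emulated_survey_config` emulates the motivating survey's design: 41 sites,
candidate years 1997–2009, missingness 0.20 (expected ≈ 426 records,
matching the original 425), temperature ≈ 6.8 ± 0.6 °C, and a
cereal-dominated management mix (55 % wheat, 10 % barley, 10 % other
crop, 10 % paddy rice, 5 % managed fallow, 10 % unmanaged fallow;
irrigation rate 0.10, delayed sowing 0.15). The generating parameters
were chosen to reproduce the *reported transition behaviour* of the
original analysis rather than its printed coefficient table, because the
two are mutually inconsistent under the stated equations (the printed
previous-class effects make class 3 absorbing under wheat, which
contradicts the published wheat equilibrium; the acceptance suite
demonstrates this by computation). Concretely: thresholds (−0.2, 2.2,
3.9), α = (1.5, 3.0, 4.7), irrigation −1.4, barley +0.3, other crop
−6.7, paddy rice −18.8, managed fallow −5.4, unmanaged fallow −1.5,
σ = 1.0. Under these values roughly half of class-0 wheat years rise to
class 1, class-skipping probabilities stay below 0.1, irrigated wheat
retains class 0 with probability ≈ 0.77, other crops return classes 1–2
to 0 with probabilities ≈ 0.99/0.97, and paddy rice eliminates coverage
outright — the reported behaviour. Because the published σ is not
reported, the default is 1.0 (a moderate site effect on the logit scale).
For small fixtures the paddy coefficient is capped at −8
(`default_true_model(cap_paddy=True)`) so tiny datasets keep a
non-degenerate likelihood; the campaign-scale emulation keeps −18.8 because
quasi-complete separation under paddy is a property of the real survey
that the refit must reproduce.

What passing tests on these data do **not** show: that the
proportional-odds form, the i.i.d. management process or the missingness
mechanism are correct for any real field system; real rotations are
structured, fields are spatially correlated, and the ordinal
classification has observer error, none of which is generated.

## Parameter recovery

`recovery_config` defines the validation experiment: 300 sites × 12 years
(3 300 transitions), a two-term truth (previous coverage + irrigation,
irrigation rate 0.5 on an all-wheat landscape), thresholds (−1.0, 0.5,
2.0), α = (1.0, 2.0, 3.0), irrigation −1.0, σ = 1.0. Twenty replicates
give |bias of the mean estimate| < 0.1 for all thresholds and the
irrigation coefficient, and 95 % Wald CI coverage (from the numerically
differenced observed information) for irrigation within [0.85, 1.0].
These sizes keep a full recovery run at roughly two minutes on one core
while leaving Monte-Carlo error well below the tolerance being asserted.

## Known limitations

* The exact AIC values and coefficient estimates of the original survey
  cannot be reproduced without its deposited records, which are not
  redistributable with this package; the corresponding check in the
  acceptance suite runs on the emulation and fails with an explanatory
  message by design.
* AIC comparability with other fitters is limited by the quadrature: a
  Laplace-based fit can differ from adaptive GH by O(0.1–1) AIC units.
* Single-realization AIC differences for truly weak terms fluctuate by
  several units (a likelihood-ratio statistic's worth); claims about weak
  terms are therefore made on averages over emulated surveys.
* The engine accepts any fitted model; it does not test proportional-odds
  adequacy or time-homogeneity of the transition process.
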