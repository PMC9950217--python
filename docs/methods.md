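# Methods

## Model

`radassoc` simulates breast-cancer development at the level of individual
cell clones with the two-stage clonal expansion (TSCE) model.  A pool of
healthy stem cells produces *initiated* (pre-cancerous) cells as a Poisson
process with rate `N*nu` per year; each initiated cell founds a clone.
Within a clone, every cell independently divides symmetrically (rate
`alpha`/year), differentiates or is inactivated (rate `beta`/year), or
transforms malignantly (rate `mu`/year).  Initiated cells have a net growth
advantage `gamma = alpha - beta > 0`, so surviving clones expand
exponentially in expectation while most small clones go extinct.  A person's
cancer is observed a fixed lag `t_lag` after their first malignant
transformation.

Three parameter sets are shipped, all calibrated to LSS breast-cancer
incidence with age-independent baseline parameters, differing only in the
radiation mechanism:

| model | mechanism | radiation effect | N·nu0 | alpha0 | beta0 | mu0 |
|---|---|---|---|---|---|---|
| `M_I` | initiation, instantaneous | `nu = nu0 (1 + 52.4 d)` | 0.054 | 12 | 11.837 | 3.83e-6 |
| `M_P` | promotion, instantaneous | `beta = beta0 - 2.3 d` | 0.177 | 12 | 11.913 | 4.64e-6 |
| `M_P-ll` | promotion, lifelong | `beta = beta0 - 0.112/yr * D_tot` | 0.076 | 12 | 11.867 | 4.30e-6 |

`d` is the dose rate in Gy/year (effects active only during exposure);
`D_tot` is the accumulated dose in Gy (effect persists for life).  Only
three of the four baseline parameters are identifiable from incidence data;
the division rate is pinned to a monthly cycle (`alpha = 12`/year), and the
association measures are insensitive to that choice.  During the exposure
year of `M_P-ll` the accumulated dose — and hence the `beta` reduction —
ramps linearly, the only accumulation consistent with a constant dose rate;
because the scoring window lies decades later this choice is numerically
minor.

The reference exposure scenario is 1 Gy delivered uniformly over one year
at age 30, `t_lag` = 5 years, follow-up to age 80.0, and scoring of all
cancers with onset in the half-open age window [60, 61).

## Two-world simulation and case classification

Each person is simulated from birth in two coupled worlds: the exposed
world and the counterfactual world without the exposure.  Spontaneous
initiations and, while the two worlds' rates are identical, all cell fates
are shared.  Radiation enters in two ways:

* **Excess initiation** (`M_I`): additional clones arise during the
  exposure at rate `N*nu0*52.4*d`; they exist only in the exposed world and
  are marked radiation-associated.
* **Promotion** (`M_P`, `M_P-ll`): while the radiation action is active,
  every step of every clone is computed separately with and without the
  radiation action.  If the two computations leave the clone at the same
  size, radiation is assumed to have had no influence.  On the first
  difference the clone *forks*: the radiation-modified copy (marked
  radiation-associated) and the counterfactual copy evolve independently
  from then on, reflecting the assumption that a radiation-induced size
  change alters the clone's microenvironment and decorrelates subsequent
  intercellular signalling.

Per person the first transformation of each label is recorded: the earliest
shared (both-worlds) event, the earliest counterfactual-only event and the
earliest radiation-associated event.  This is equivalent to the
label-stratified growth-stopping rule (a spontaneous-lineage cancer stops
only spontaneous-lineage clones, and vice versa) because later events of a
label can never displace an earlier recorded first cancer.  Ties between a
shared and a radiation-associated transformation in the same step are
broken toward the spontaneous label (probability O(mu^2 dt^2)).

A person's exposed-world window cancer is then classified against their own
counterfactual: **unaffected** (not radiation-associated — the same cancer
occurs at the same age in both worlds), **new** (no counterfactual cancer
within follow-up), **accelerated** (counterfactual cancer after the
window), or **retarded** (counterfactual cancer before the window;
possible despite a growth-promoting exposure purely through the
stochasticity of post-fork clone evolution).  When both cancers fall inside
the window the sign of the age shift decides, an edge case the scoring
rules leave open; it is rare and does not move the tallies beyond their
run-to-run SDs.  From the tallies: `AS = (tot-spo)/tot`,
`PA = (new+acc+ret)/tot`, `PH = (new+acc)/tot`, `PEH = (new+acc-ret)/tot`,
`PR = ret/tot`, `HRR = (new+acc)/ret` (reported as infinite when `ret = 0`,
as for `M_I`).  `new + acc` is exactly invariant under follow-up
truncation, which `followup_invariance_check` recounts directly.

## Coupling scheme

The statement "computed separately with and without the radiation action"
leaves the joint law of the two worlds open; only the "size unchanged ⇒ no
influence" rule is fixed.  Two schemes are implemented:

* **independent** (default): each step's outcome is drawn independently
  under the two parameter sets; any disagreement forks the clone.  Forks
  then happen within days of the radiation action starting, with the two
  copies differing by one cell in either direction.
* **thinning**: a maximal coupling — divisions and transformations are
  shared, deaths are drawn at the spontaneous rate `beta0` and accepted for
  the radiation copy with probability `beta_rad/beta0`.  Sizes differ
  exactly when a death is thinned away, so forks are rare
  (rate `(beta0-beta_rad)*m` per year) and the radiation copy always starts
  larger.

The choice matters only for the mechanistic split, not the marginal
incidence of either world.  Thinning suppresses retardation (for `M_P`,
desk-scale runs give ret ~60 per 1e6 with HRR ~18 versus the reference
95 and 11.6) because the counterfactual copy is never ahead at the fork;
the independent scheme reproduces the reference mechanistic tallies within
their statistical tolerances and is therefore the default.  The
`coupling=` switch on `simulate_cohort` selects the variant.

## Monte Carlo engine

The simulator advances each clone on a fixed grid `dt = 1/365` year
(default), chosen so that the largest rate times `dt` stays below 1/25 —
validated at run time against the largest effective rate, including the
elevated initiation rate of `M_I`.  Per clone and step the cell-fate counts
are one multinomial draw over (divide, die, transform, stay).  Three exact
rearrangements keep the compiled engine's cost proportional to the number
of cell events rather than steps; each is distributionally identical to
naive stepping:

1. initiation times are sampled from the homogeneous Poisson process per
   constant-rate segment;
2. transformations (per-cell probability `mu*dt` ~ 1e-8) are drawn as a
   geometric number of cell-trials until the first success, with `m` trials
   consumed per step, and the division/death probabilities conditioned on
   no transformation;
3. for clones of at most 16 cells, division/death events are likewise drawn
   from the per-cell Bernoulli stream with geometric gaps (chopping an
   i.i.d. Bernoulli stream into m-trial blocks yields exactly
   Binomial(m, p) events per step); larger clones use per-step binomial
   draws.

Event ages are assigned to the end of the step in which they occur, and the
step grid restarts at rate-change boundaries (exposure start/end), so phase
boundaries are honoured to within one step.  Clones are processed in birth
order and each clone's simulation is capped at the person's currently
earliest shared transformation, which provably cannot change either
recorded first cancer.  Transformations after `follow_up_end - t_lag` can
never be observed and are not simulated.

Randomness: every person has an own 32-bit seed derived from
(base_seed, model, run index) through NumPy's `SeedSequence`, so cohorts
are bit-reproducible, chunk-size-independent and order-independent; the
kernels use numba's legacy NumPy generator re-seeded per person.

## Analytic references

Two deterministic routes validate the stochastic engine and supply the
phenomenological comparison:

* **TSCE hazard**: the probability `u(s, t)` that a clone founded at age
  `s` produces no malignant cell by age `t` solves the backward Riccati
  equation `du/ds = -(alpha u^2 - (alpha + beta(s) + mu) u + beta(s))` with
  `u(t, t) = 1`; the person-level survival is
  `S(t) = exp(-int_0^t N nu(s) (1 - u(s, t)) ds)`.  The equation is
  integrated numerically (RK45, rtol 1e-9) piecewise over the
  parameter-change segments, which uniformly handles the `M_P-ll` dose
  ramp; the constant-coefficient closed form is kept as a unit-test
  cross-check.  Simulated incidence is compared per age bin via z-scores
  (`validate` command; |z| > 4 flags a discrepancy).
* **ERR model**: `h(D, a) = h0(a) (1 + ERR(D, a))` with
  `ERR(D, a) = 1.06 D exp(-1.92 ln(a/70))` active from age 35 (exposure age
  plus lag) and a log-quadratic baseline `h0` with knots at 70 and 51.
  Expected window cases are plain hazard integrals
  `n * int_w h(a) da` (adaptive quadrature, relative tolerance 1e-10):
  matching the reference values requires neglecting the depletion of the
  at-risk population by earlier cancers, the usual rate-times-person-years
  convention of phenomenological risk models; first-cancer counting with
  survival depletion (a ~1-3% correction) is available via
  `depletion=True`.

## Problem sizes and what the tests show

The shipped acceptance computations use 200,000 persons × 3 runs per model,
the package's desk-scale profile; it resolves the ratio measures (AS, PA,
PH, PEH, PR) to about ±0.01-0.05 and is compared against the reference
values at three combined standard deviations.  Full-scale runs (1e6 × 10)
are supported unchanged through `n_persons`/`n_runs`.  All cohorts are
synthetic and identically parameterized: no individual susceptibility, no
competing mortality, a fixed follow-up at 80.0 years and a fixed lag — so
passing tests demonstrate internal consistency with the stated model and
its calibration, not fidelity to any real population's survival or
screening patterns.

## Known limitations

* Only pure-initiation or pure-promotion radiation action; no combined
  mechanisms, no effect on malignant transformation, no age-dependent
  baseline parameters.
* Linear dose response only; single contiguous exposure window.
* The mechanistic split (unaff/acc/ret/new) depends on the coupling scheme,
  i.e. on an assumption about unobservable joint randomness; both extremes
  are implemented and the difference is documented above.  Under either
  scheme a lifelong promotion effect forks every surviving clone
  eventually, so `M_P-ll` has no unaffected cases and PA is exactly 1.
* The discrete time grid biases event ages by O(dt) and per-step
  probabilities by O(rate*dt); at the default grid this is far below the
  Monte Carlo resolution of the shipped cohort sizes.
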