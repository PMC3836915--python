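# Methods

## Model family and notation

All kernels in this package describe the probability that one health state
is judged better than another. Writing v for latent state values:

- **Thurstone, complete form**: P(s ≻ t) = Φ((vₛ − vₜ)/σ_c) with
  comparative dispersion σ_c = √(σₛ² + σₜ² − 2ρσₛσₜ). Case V normalizes
  σ_c = 1, so P = Φ(vₛ − vₜ); because the scale unit is arbitrary this is a
  convention, and the alternative unit-per-stimulus convention
  (σ_c = √2) is available via `unit_stimulus_dispersions=True`.
- **Conditional logit**: P(choose s from a set) = softmax of the values.
  For K = 2 the implementation computes the first component directly as
  logistic(v₀ − v₁) and the second as its complement, so the pairwise
  logistic-difference identity and complementarity hold to the last bit;
  K > 2 uses log-sum-exp.
- **Rasch / MAPR**: P(presented state judged better than own) =
  logistic(vₛ − θᵣ). Response 1 therefore means the *presented* state wins.
  This orientation is a declared convention of the package; the opposite
  orientation is its mirror image (swap v and θ). MAPR adds the linear
  restriction vₛ = zₛ'γ, with zₛ the dummy coding of state s against the
  best level of each attribute.

Only value differences are identified (adding a constant to every v and θ
changes nothing), so the best state — whose design vector is zero — is the
fixed origin of the MAPR scale. Pure Rasch and paired-comparison fits offer
a reference-state constraint (default, first state) or a sum-to-zero
constraint.

## Estimation

**Conditional ML (Rasch).** The likelihood of a response string
conditional on its raw score r is free of θ:
P(x | r) = exp(Σⱼ xⱼvⱼ) / γ_r(ε), where γ_r is the r-th elementary
symmetric function of ε = exp(v). The γ_r are computed with the standard
one-item-at-a-time sum recursion, run in the log domain (logaddexp) so
values spanning many units of severity cannot overflow. Gradients need the
leave-one-out functions γ_r⁽ʲ⁾, recomputed per item (J ≤ a few dozen makes
the O(J²) cost per evaluation irrelevant). Persons with all-0/all-1
strings carry no conditional information and are dropped — verifiably
without effect on the estimates; states answered identically by every
informative person are reported as non-estimable. Missing responses are
handled by grouping persons with identical answered-item sets and
conditioning within each group.

**Joint ML (Rasch JML, MAPR free mode).** The joint likelihood over
(v or γ, θ) is that of a logistic regression with ±1 design entries,
hence concave; JML carries the familiar incidental-parameter bias for
short response strings, which is acknowledged, not corrected. The free-θ
MAPR fit is of exactly this type, which is why a saturated design matrix
reproduces the joint Rasch fit to machine precision.

**Pairwise conditional logit.** Bradley-Terry form over directed win
counts. The comparison graph must be connected (components are listed
otherwise). States that never lose or never win sit at the likelihood
boundary: they are reported as ±∞ with NaN standard errors and the rest
refit, rather than patched with pseudo-counts.

**Structured MAPR.** With θᵣ = z_own'γ from the first-stage
self-classification, the model is a logistic regression on design-vector
differences zₛ − z_own; a presented "dead" pseudo-state contributes one
extra free value parameter. The γ-relevant design matrix must have full
column rank; offending columns are named via QR with pivoting.

**Optimization.** All fits use analytic gradients inside a damped Newton
iteration whose convergence test is the gradient max-norm (tolerance
1e-8, default iteration cap 500, reported as non-converged beyond it).
A function-value line search is useless here: near the optimum the
log-likelihood changes by less than float resolution while the gradient is
still ~1e-6, so damping acts on the gradient norm instead. The
high-dimensional joint fits exploit the diagonal θ-block of the Hessian
through a Schur-complement solve, making each Newton step O(p²·R) for p
structural parameters and R respondents. Standard errors come from the
observed information on the constrained parameterization (Schur
complement over θ for the joint fits; finite differences of the analytic
CML gradient for the conditional fit).

## Synthetic data

The model was proposed without an accompanying dataset, so simulation is
the package's data source, emulating the intended two-stage collection:

- Respondent locations θ are drawn from a configurable distribution
  (normal or uniform). Defaults in the bundled studies use
  θ ~ N(−2, 1.5) against an EQ-5D-like value surface spanning [−4.05, 0],
  so respondents cover the whole continuum — clustered samples are
  exactly the condition under which Rasch-type estimation degrades.
- The generating decrements (γ from −0.15 to −1.0 per level move, severe
  levels 3-4× the moderate ones) are of the magnitude familiar from
  published EQ-5D-type value functions, chosen once as the package's
  standard study condition.
- First-stage classification assigns each respondent the enumerated state
  whose value is nearest its θ (ties to the milder state).
- Responses are Bernoulli draws from the MAPR kernel; in structured mode
  θᵣ is the own state's value, in free mode the latent θᵣ itself. Streams
  are seeded per respondent, so one respondent's records do not depend on
  how many others are simulated.
- The random-utility simulator draws U = v + ε with Gumbel(0,1) or
  standard normal errors and records the argmax; its frequencies converge
  to the conditional logit and the pairwise probit respectively, which the
  tests check at 10⁶ draws against 3 binomial standard errors.

What the generator does **not** emulate: adaptation and coping effects,
cognitive shortcuts, attribute interpretation problems, panel structure,
or taste heterogeneity. Passing recovery tests therefore show that the
estimation machinery is correct under the model's own assumptions — not
that real patients behave this way.

## Study sizes and numerical choices

The bundled recovery studies use J = 20 states × N = 1000 respondents for
conditional-ML recovery, two samples of N = 1500 with θ-means ∓1 for the
invariance comparison, N = 400 × 8 states for the saturated
MAPR-vs-Rasch reduction, and N ∈ {200, 2000} radius-1 pivot designs
(≈10-12 binary tasks per respondent) for γ recovery — sizes at which the
studied effects are comfortably resolved while a full run stays in the
seconds-to-minutes range. The γ-recovery study runs in structured mode:
with ~10 responses per person, free-θ joint ML adds incidental-parameter
bias that is a property of JML, not of the design being evaluated.

Other deliberate choices:

- **Pivot neighborhoods** default to single-attribute, radius-1 moves —
  the closest operationalization of presenting "almost equivalent" states;
  multi-attribute Chebyshev balls and larger radii are config-gated.
  A radius of 0 yields an empty design with a warning, not an error.
- **Adaptive item selection** maximizes the binary Fisher information
  p(1−p), equivalently minimizes |vₛ − θ̂|; ties go to the lowest candidate
  index.
- **Guttman misfits** are counted Goodman-style: after sorting rows and
  columns by their totals (ties broken lexicographically by label, so
  sorting is deterministic and idempotent), a row with total k is compared
  with the step vector 1…1 0…0 of k ones; every differing cell is a
  misfit. Under this definition a perfect scalogram has zero misfits, and
  a single interior flip produces two (the flip plus the step cell it
  displaces) while a flip at a row's step boundary produces another
  perfect pattern and counts zero.
- **Dead anchoring** is the affine map v′ = (v − v_dead)/(v_best −
  v_dead). It requires distinct anchors, warns (but proceeds) when the
  dead estimate exceeds the best state's, and sends states worse than
  dead below zero. The dead parameter itself is only well identified when
  designs confront respondents in poor states with it; the package
  implements the mechanism and makes no claim about its empirical
  validity.
- **Partial profiles** select k of the candidate attributes reproducibly
  under a seed; unselected attributes keep their dummies at zero, i.e.
  contribute no value — an assumption known to be violated in some
  applications, recorded here as a modeling premise.

## Limitations

- Models with person covariates (multinomial logit and mixed forms) are
  out of scope: they break the sample-invariance property this model
  family is built on. So are discrimination-parameter IRT extensions,
  marginal ML with an assumed θ distribution, and Bayesian estimation.
- JML estimates are biased for short response strings; use CML (or the
  structured mode) when invariant state values are the goal.
- Standard errors are asymptotic observed-information quantities; no
  small-sample or clustered corrections are offered.
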