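# Methods

## Dose-toxicity models and their admissible sets

Eight parametric surfaces `F(u, v, theta)` are implemented (see
`combocrm.models`). Each carries the inequality constraints that make the
surface conform the known partial order — toxicity strictly increasing in
each agent's level with the other fixed:

| family | parameters | constraints | notes |
|---|---|---|---|
| `logistic4` | t1..t4 | t2>0, t3>0, t2+t4·v_k>0 ∀k, t3+t4·u_j>0 ∀j | raw or standardized doses |
| `generalized_crm` | a_1..a_K, b | b>0, a_1<…<a_K | agent 2 categorical; the intercept ordering is required for the partial order in k |
| `scaled_logistic` | rho, t1..t3 | 0<rho<1, t2>0, t3>0 | plateaus at rho |
| `change_point` | a, b, g, w | b>0, g>0 | logit F = min(a+bu+gv, w); flat at the cap expit(w) |
| `clayton` | a, b, g | all > 0 | copula of skeleton marginals p_j^a, q_k^b |
| `gumbel` | a, b, g | all > 0 | FGM form 1−(1−p^a)(1−q^b){1+p^a q^b tanh(g/2)} |
| `log_linear` | a, b, g | a>0, b>0, g<0 | needs doses < 1 (log(1−dose)) |
| `six_param` | a1..a3, b1..b3 | all > 0 | doses standardized to [0,1] |

Strict inequalities are enforced with a numerical margin of 1e-10; boundary
parameter vectors are inadmissible. All admissible sets are convex, so
posterior means stay in their closure. One published form required a
reading decision: the printed Gumbel-type formula is typographically
truncated, and we implement the Farlie–Gumbel–Morgenstern completion above,
whose association factor `tanh(g/2)` reproduces the independence product
form exactly at `g = 0`. The change-point surface is only *nondecreasing*
on its plateau; the partial-order matrix check therefore accepts ties for
this family exactly at the cap and is strict everywhere else.

Gradients are central differences with step `h_t = 1e-5 · max(1, |theta_t|)`.
For the change-point family, probes that straddle the threshold surface are
flagged and one-sided derivatives reported; the sign-condition checker
skips (and counts) flagged updates, since the case analysis at the kink is
not a derivative statement.

## Designs

Candidate sets around the current dose `(j, k)`: the ND design uses
`E = {(j+1,k), (j,k+1)}`, `D = {(j-1,k), (j,k-1)}` clipped to the grid; the
D design adds the in-grid anti-diagonal neighbours `(j+1,k-1)`, `(j-1,k+1)`,
each classified into E or D by an ordering surface — the interim estimates
`F(theta_hat_n)` during a trial (and for *weak* audits), the true
probabilities for *strong* audits. An exact ordering tie excludes the
neighbour from both sets: a move to a dose whose order is indeterminate can
then never be classified, which is the conservative reading. Same-sign
diagonal steps `(j±1, k±1)` are never candidates (they skip a dose).

The assignment rule is the admissible dose minimizing `|F_hat - p_T|`. Exact
ties prefer the current dose, then the tied doses minimal in the partial
order, then lexicographic `(j, k)` — a safety-first deterministic rule.
One-stage trials start at the prior estimate of the MTD (the grid argmin of
`|F(prior mean) - p_T|`) unless configured to start at `(1,1)`. Two-stage
trials titrate along a pre-selected monotone path from `(1,1)` (default: a
staircase alternating the two agents), escalating one step per non-DLT; the
switch rule fires at the first DLT, and by default also on path exhaustion
(otherwise the trial would stall at the top of the path). After the switch,
assignments follow the model rule restricted to the usual candidate sets.
Cohort size is one patient: the coherence definitions are per-patient.
Outcomes are Bernoulli draws from the scenario using one seeded stream per
trial, with patient n consuming the n-th draw, so design variants are
comparable under common random numbers.

## Posterior machinery

The posterior is represented on a **fixed node set** built once per
(family, grid, prior): tensor-product Gauss rules matched to the prior
components (Hermite for normal, Laguerre for exponential, Legendre for
uniform) for p ≤ 5 — 24 nodes/axis at p = 4, 32 at p = 3, 12 at p = 5 —
and a seeded self-normalised importance sample from the prior (65 536
draws) for the six-parameter family. Nodes violating the admissibility
constraints get zero weight. Interim updates multiply node weights by
Bernoulli likelihood factors in log space, so every update is an *exact*
Bayes update of a discrete prior: runs are bit-reproducible given the seed,
and update-direction properties that hold for exact posterior means hold
here to floating point. Distance to the *continuous* posterior is a
separate question, quantified by two-resolution self-consistency
(`posterior_mean` flags estimates whose resolutions disagree beyond `tol`),
by an effective-sample-size standard error for importance sampling, and in
the tests by an independent brute-force integrator.

That test oracle (`posterior_mean_oracle`, p ≤ 4 only) is tensor-product
composite Simpson over the truncated prior box (normal: ±6 sd; exponential:
19 mean lifetimes, leaving < 1e-8 prior mass outside), with 33 lattice
points per normal/uniform axis and 61 per exponential axis at resolution 1.

**Default priors** (the published designs do not pin them down): independent
N(0, 2²) on unconstrained components, Exponential(1) on positive ones
(mirrored for the negative log-linear interaction), Uniform(0,1) on the
scaled-logistic plateau, all times the joint admissibility indicator.

**Numerical limitations, measured.** Three regimes defeat *both* integrators
at feasible sizes, and the integrator-agreement tests therefore run on
smooth in-constraint box priors there, with package defaults elsewhere:
(i) the four-parameter logistic's joint admissibility indicator cuts through
the Gauss-Hermite domain, making the integrand discontinuous; (ii) the
copula surfaces have a boundary layer as the exponent parameters approach 0;
(iii) the change-point kink surface in parameter space removes spectral
convergence (posterior means at default resolution are ~3e-3 from a
4-million-draw Monte Carlo reference in kink-active regimes). In the smooth
regimes the Gauss engine and the Simpson oracle agree to 1e-5–1e-7, and the
engine is resolution-stable (identical at 32/48/64 nodes) and matches Monte
Carlo elsewhere; none of this affects the *coherence* audits, whose sign
identities are exact for the discrete measure.

## Audits and checkers

`audit_trace` classifies every transition of a trace against the coherence
definition — a violation is an escalation after a DLT or a de-escalation
after a non-DLT, with the candidate sets rebuilt under weak (model-estimate)
or strong (true-probability) diagonal semantics. Transitions with flagged
(unconverged) posteriors are excluded from the verdict and counted. With a
single agent (K = 1) the classification reduces exactly to the single-agent
coherence rule, which the tests enumerate.

`check_condition_A` evaluates, at every update n and component t, the
product `(Y_n - p_T)(theta_hat_{n,t} - theta_hat_{n-1,t}) dF/dtheta_t` with
the gradient taken at the treated dose and at `theta_hat_{n-1}` (the
estimate in force when the patient was dosed). For all eight families the
gradient's *sign* at a fixed dose does not depend on theta, so this
evaluation point is not a restriction. The verdict requires every product
≥ −1e-6. `check_condition_B` probes, over a seeded sample of admissible
thetas, strict dose-monotonicity (B1) and the agreement of model and true
anti-diagonal orderings (B2), returning witnesses on failure.
`check_theorem6_condition` probes the two-stage switch inequality
`(Y_M - p_T){F(X_{M+1}, theta) - F(X_M, theta)} ≤ 0` over sampled admissible
thetas. All three are **falsifiers with documented coverage** — they certify
only over the sampled sets and can never prove the quantified statements.
The same holds for `check_uniform_monotonicity`, which searches for
direction reversals by paired perturbation; "uniformly monotone" is read as
one direction shared by all parameters, so a witness is either a sign
reversal within a parameter across doses or a direction conflict between
parameters.

## The empirical finding

The sufficient conditions above are discussed in the dose-finding
literature as guaranteeing coherence of these designs. Our audits confirm
the one-step version: from the independent prior, a single observation
moves every posterior-mean component in the direction compatible with the
outcome and the treated dose's gradient (a one-dimensional conditional-
covariance argument, valid because the prior factorises; tested for all
eight families). The *iterated* version fails: once the interim posterior
is correlated across parameters, the same argument has an uncontrolled
cross term. A concrete Clayton-family counterexample (25-record history,
DLT at a dose mostly informative about one agent) moves the posterior mean
of the other agent's exponent in the gradient-incompatible direction by
+0.037 — confirmed to ~3 decimals by the Gauss engine, the dense Simpson
lattice and 20 million plain Monte Carlo draws. Definition-level violations
follow, through two further channels the sign condition does not control:
multi-step descents forced by the no-skipping rule after a hot start (an
intermediate non-DLT does not halt the descent toward a dose that never
competed in earlier argmins), and parameters with zero gradient at the
treated dose (e.g. the agent-1 slope when `u_j = 0` on a standardized grid)
that reshape the surface elsewhere.

Measured magnitudes under the package defaults (4 x 4 grids, vague priors,
`p_T = 0.3`, N = 30): violation rates of roughly 0.5–1.5% of transitions for
most families in both designs (the change-point batches happen to be clean
at these sizes), minimum sign products around −1e-2 — far beyond numerical
tolerance. The acceptance suite asserts the zero-violation claims at their
stated batch conditions and is left failing where these counterexamples
occur; the assertion messages carry the measured counts. Single-agent
(one-parameter) designs are unaffected, consistent with the classical
coherence results for the CRM.

## Synthetic scenarios and fixtures

`gen_scenario` builds true-toxicity matrices additively on the logit scale
from seeded positive row/column increments (Exponential, scale proportional
to `spread`), shifted so the anchored cell lands within `spread/10` of
`p_T`; strict row/column monotonicity holds by construction, anti-diagonal
cells are unconstrained. It emulates smooth, additively interacting
dose-toxicity surfaces; it does not emulate antagonistic interactions,
plateaus, or outlier cells, so clean audits on generated scenarios say
nothing about such surfaces. `gen_misspecified_pair` ships the canonical
weak-but-not-strong construction: a 3 x 3 logistic configuration with a
tight prior whose estimated ordering ranks cell (3,1) above the current
dose (2,2) — and closest to `p_T` — while the truth ranks it below; a
D-design trial started at (1,1) walks into the cell after three non-DLTs,
and the weak/strong audit pair detects exactly that transition. Both
inequalities of the construction are asserted at build time. The fixture
bank also carries the grids, titration paths, a binary-exact assignment-tie
case (dyadic estimates 0.25/0.375 against `p_T = 0.3125`), a change-point
kink case, and a strong-coherence demonstration config whose uniform box
prior forces a theta-invariant diagonal ordering (the agent-1 effect
`t2 - t3 ≥ 0.75` dominates the interaction term `|t4| ≤ 0.15` on the
half-step grid), so the diagonal-agreement condition certifies over the
entire support.

## Batch sizes and runtime

The pytest acceptance suite runs 200 trials per family and design (50 for
the six-parameter family) of N = 30 patients; `scripts/acceptance.py`
recomputes the same quantities at 50 (25) trials per family, finishing in a
few minutes on one CPU. Engines are built once per family and shared across
a batch's trials.

## Known limitations

- Every checker is a falsifier over finite samples; "for any theta" and
  "almost surely" statements are probed, never proven.
- Posterior accuracy (not coherence) degrades in the three regimes listed
  above; `posterior_mean`'s two-resolution flag is the guard.
- No early stopping, MTD selection, cohort expansion, or late-onset
  toxicity handling: the scope is the transition rule and its auditing.
- The titration stage only escalates or switches; de-escalation within
  stage 1 is not modelled.
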