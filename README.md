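# combocrm

Model-based dose finding for two-agent drug-combination phase I trials, with
an auditing engine that empirically checks the *coherence* of every simulated
dose transition.

## The problem

A combination phase I trial escalates and de-escalates through a J x K grid
of dose pairs `(u_j, v_k)` looking for the maximum tolerated dose (MTD): the
combination whose dose-limiting-toxicity (DLT) probability is closest to a
target `p_T`. Toxicity is known to increase when either agent's dose
increases with the other held fixed, but anti-diagonal neighbours such as
`(j+1, k-1)` and `(j, k)` are *a priori* unordered — the partial ordering
that makes combination trials harder than single-agent ones.

Model-based (continual-reassessment-type) designs assume a parametric
dose-toxicity surface `F_jk(theta) = F(u_j, v_k, theta)`, update the
posterior mean `theta_hat_n = E(theta | H_n)` after every patient, and treat
the next patient at

```
X_{n+1} = argmin_{(j,k) in A_n} | F_jk(theta_hat_n) - p_T |
```

where the admissible set `A_n` contains the current dose and its candidate
escalations `E_n` / de-escalations `D_n` — one-step coordinate moves (the
**ND design**) optionally plus the anti-diagonal neighbours classified by
estimated or true toxicity order (the **D design**). A design is **coherent**
if it never escalates after an observed DLT (`Pr(X_{n+1} in E_n | Y_n=1) = 0`)
and never de-escalates after a non-DLT; for D designs this splits into *weak*
coherence (moves judged by the model's own ordering) and *strong* coherence
(judged by the true ordering, which differs under model misspecification).

`combocrm` implements eight published dose-toxicity families behind one
interface — a four-parameter logistic (raw or standardized doses), the
generalized CRM (categorical-by-continuous coding), a scaled logistic that
plateaus at `rho < 1`, a change-point model that flattens past a threshold,
Clayton- and Gumbel-copula combinations of single-agent skeleton curves, a
log-linear model, and a six-parameter interaction model — plus deterministic
posterior-mean machinery, ND / D / two-stage (titration) trial simulation,
and auditors for the coherence definitions and the sufficient sign
conditions discussed for them in the dose-finding literature.

**What the audits find.** The one-step posterior-shift property behind those
sufficient conditions is provable for the *first* update under an
independent prior, and this package's tests confirm it. Iterated along a
trial, however, it fails for every multiparameter family: interim posteriors
develop cross-parameter correlation, a DLT can be "explained" by one
component while the correlation drags another the wrong way, and the
`argmin` rule then occasionally escalates after a DLT or de-escalates after
a non-DLT (roughly 0.5–1.5% of transitions under vague priors on a 4 x 4
grid). The acceptance suite asserts the zero-violation guarantees at their
stated batch conditions and is deliberately left failing where the audits
find these counterexamples; `docs/methods.md` documents the mechanism and
the three-way numerical cross-validation behind it.

## Worked example

```python
from combocrm import audit_trace, check_condition_A, fixture_bank, gen_scenario, run_trial

bank = fixture_bank()
grid = bank["grid_4x4_std"]          # standardized doses logit(skeleton)
prior = bank["prior_logistic4"]      # package default prior
scenario = gen_scenario(4, 4, 0.30, seed=7, grid=grid)
trace = run_trial("one_stage_d", "logistic4", prior, grid, scenario,
                  p_T=0.30, N=12, seed=7)

print("start (prior MTD):", trace.start_level)
print("doses:", " ".join(f"({j},{k})" for j, k in trace.doses()))
print("DLTs: ", [r.y for r in trace.records])
weak, strong = audit_trace(trace, "weak"), audit_trace(trace, "strong")
ca = check_condition_A(trace)
print(f"weak audit: verdict={weak.verdict}, "
      f"{len(weak.violations)} violation(s) / {weak.n_transitions} transitions")
print(f"strong audit: verdict={strong.verdict}")
print(f"sign condition: verdict={ca.verdict}, min product={ca.min_product:.3e}")
```

prints

```
start (prior MTD): (1, 4)
doses: (1,4) (1,3) (2,3) (2,3) (3,2) (2,2) (1,3) (2,2) (2,2) (1,3) (1,3) (1,3)
DLTs:  [1, 0, 0, 1, 1, 0, 1, 0, 0, 0, 0, 0]
weak audit: verdict=True, 0 violation(s) / 11 transitions
strong audit: verdict=False
sign condition: verdict=False, min product=-1.930e-04
```

Patient 4 has a DLT at (2,3) and the D design moves to the anti-diagonal
neighbour (3,2), which the interim model ranks as a *de-escalation* — so the
weak audit is clean — while the true scenario ranks (3,2) above (2,3), so
the strong audit flags an escalation-after-toxicity. The sign-condition
checker also reports a (small) negative product at one update: the posterior
mean of one parameter moved against the direction its gradient at the
treated dose prescribes.

## Command line

```sh
combocrm simulate --config run.yaml --out logs/      # one CSV log per trial
combocrm audit logs/ --semantics strong --scenario logs/scenario.csv
combocrm check --check uniform_monotonicity --family logistic4 --grid grid_4x4_raw
combocrm batch --config bank.yaml --out summary/
```

Exit codes: 0 clean, 2 coherence violation found, 3 posterior-convergence
failures present.

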