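import numpy as np
import pytest

from combocrm.design import PatientRecord, TrialTrace
from combocrm.scenarios import fixture_bank


@pytest.fixture(scope="session")
def bank():
    return fixture_bank()


def make_trace(
    grid,
    steps,
    *,
    family="logistic4",
    design="one_stage_nd",
    p_T=0.30,
    f_hats=None,
    theta_hats=None,
    scenario_p=None,
    switch_index=None,
    stages=None,
):
    """Construct a TrialTrace from a list of (level, y) steps.

    ``steps[i] = (level, y)``; patient i+1's next_level is steps[i+1][0].
    ``f_hats`` optionally gives the per-patient J x K estimate surface
    (default: a partial-order-consistent ramp), ``theta_hats`` the posterior
    mean path including the prior mean at index 0.
    """
    J, K = grid.shape
    default_f = (
        np.add.outer(np.arange(1, J + 1), np.arange(1, K + 1)) / (J + K + 1.0)
    )
    p = 4 if theta_hats is None else len(theta_hats[0])
    theta_prior = np.zeros(p) if theta_hats is None else np.asarray(theta_hats[0], float)
    records = []
    n_steps = len(steps)
    for i, (level, y) in enumerate(steps):
        nxt = steps[i + 1][0] if i + 1 < n_steps else None
        records.append(
            PatientRecord(
                n=i + 1,
                level=tuple(level),
                y=int(y),
                stage=(stages[i] if stages else "model"),
                theta_hat=(
                    np.asarray(theta_hats[i + 1], float)
                    if theta_hats is not None
                    else np.zeros(p)
                ),
                f_hat=np.asarray(
                    f_hats[i] if f_hats is not None else default_f, float
                ),
                mc_error=np.zeros(p),
                converged=True,
                decision_rule="model" if nxt is not None else None,
                sets=None,
                next_level=nxt,
            )
        )
    return TrialTrace(
        design=design,
        family=family,
        grid=grid,
        p_T=p_T,
        N=n_steps,
        seed=None,
        prior_label="constructed",
        engine_method="grid_quadrature",
        scenario_p=None if scenario_p is None else np.asarray(scenario_p, float),
        start_level=tuple(steps[0][0]),
        titration_path=None,
        theta_hat_prior=theta_prior,
        f_hat_prior=np.asarray(f_hats[0] if f_hats is not None else default_f, float),
        switch_index=switch_index,
        records=tuple(records),
    )
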