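"""Trial-log serialization.

One trial is logged as a CSV (one row per patient) plus a JSON manifest
holding the trial-level configuration echo.  Floats are written with 17
significant digits so that audits recomputed from logs reproduce the
in-memory classifications exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import CandidateSets, PatientRecord, TrialTrace
from .grid import DoseGrid

__all__ = ["trace_to_frame", "save_trace", "load_trace"]

_FLOAT_FMT = "%.17g"


def _sets_to_json(sets: Optional[CandidateSets], which: str) -> str:
    if sets is None:
        return ""
    group = sets.escalation if which == "E" else sets.deescalation
    return json.dumps(sorted(list(map(list, group))))


def trace_to_frame(trace: TrialTrace) -> pd.DataFrame:
    p = len(trace.theta_hat_prior)
    J, K = trace.grid.shape
    rows = []
    for rec in trace.records:
        row: dict = {
            "n": rec.n,
            "j": rec.level[0],
            "k": rec.level[1],
            "y": rec.y,
            "stage": rec.stage,
            "decision_rule": rec.decision_rule or "",
            "next_j": rec.next_level[0] if rec.next_level else "",
            "next_k": rec.next_level[1] if rec.next_level else "",
            "converged": int(rec.converged),
        }
        for t in range(p):
            row[f"theta_hat_{t}"] = rec.theta_hat[t]
        for t in range(p):
            row[f"mc_error_{t}"] = rec.mc_error[t]
        row["F_hat_at_dose"] = rec.f_hat[rec.level[0] - 1, rec.level[1] - 1]
        for j in range(J):
            for k in range(K):
                row[f"F_hat_{j + 1}_{k + 1}"] = rec.f_hat[j, k]
        row["E_set"] = _sets_to_json(rec.sets, "E")
        row["D_set"] = _sets_to_json(rec.sets, "D")
        rows.append(row)
    return pd.DataFrame(rows)


def save_trace(trace: TrialTrace, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    trace_to_frame(trace).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    manifest = {
        "design": trace.design,
        "family": trace.family,
        "grid": trace.grid.to_dict(),
        "p_T": trace.p_T,
        "N": trace.N,
        "seed": trace.seed,
        "prior_label": trace.prior_label,
        "engine_method": trace.engine_method,
        "start_level": list(trace.start_level),
        "titration_path": [list(x) for x in trace.titration_path]
        if trace.titration_path
        else None,
        "switch_index": trace.switch_index,
        "theta_hat_prior": [float(x) for x in trace.theta_hat_prior],
        "f_hat_prior": trace.f_hat_prior.tolist(),
        "scenario_p": trace.scenario_p.tolist()
        if trace.scenario_p is not None
        else None,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return csv_path


def load_trace(csv_path: str | Path) -> TrialTrace:
    """Rebuild a trace from its CSV log + JSON manifest.

    Decision candidate sets are not restored (the audit layer reconstructs
    classification sets from the logged F_hat surfaces)."""
    csv_path = Path(csv_path)
    mf = json.loads(csv_path.with_suffix(".json").read_text())
    grid = DoseGrid.from_dict(mf["grid"])
    df = pd.read_csv(csv_path, float_precision="round_trip")
    p = len(mf["theta_hat_prior"])
    J, K = grid.shape
    records = []
    for _, row in df.iterrows():
        f_hat = np.array(
            [[row[f"F_hat_{j + 1}_{k + 1}"] for k in range(K)] for j in range(J)]
        )
        has_next = not (pd.isna(row["next_j"]) or row["next_j"] == "")
        records.append(
            PatientRecord(
                n=int(row["n"]),
                level=(int(row["j"]), int(row["k"])),
                y=int(row["y"]),
                stage=str(row["stage"]),
                theta_hat=np.array([row[f"theta_hat_{t}"] for t in range(p)]),
                f_hat=f_hat,
                mc_error=np.array([row[f"mc_error_{t}"] for t in range(p)]),
                converged=bool(int(row["converged"])),
                decision_rule=str(row["decision_rule"])
                if not pd.isna(row["decision_rule"]) and row["decision_rule"] != ""
                else None,
                sets=None,
                next_level=(int(row["next_j"]), int(row["next_k"]))
                if has_next
                else None,
            )
        )
    return TrialTrace(
        design=mf["design"],
        family=mf["family"],
        grid=grid,
        p_T=float(mf["p_T"]),
        N=int(mf["N"]),
        seed=mf["seed"],
        prior_label=mf["prior_label"],
        engine_method=mf["engine_method"],
        scenario_p=np.array(mf["scenario_p"]) if mf["scenario_p"] else None,
        start_level=tuple(mf["start_level"]),
        titration_path=tuple(map(tuple, mf["titration_path"]))
        if mf["titration_path"]
        else None,
        theta_hat_prior=np.array(mf["theta_hat_prior"]),
        f_hat_prior=np.array(mf["f_hat_prior"]),
        switch_index=mf["switch_index"],
        records=tuple(records),
    )
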