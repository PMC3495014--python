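"""Long-format dataset interchange, fit reports and run manifests.

The analysis dataset is a delimited text table with one row per tumor
assessment plus one row per dose change (SLD empty on dose-change-only
rows), the convention used by nonlinear mixed-effects tools.  Units are
fixed — time in days, SLD in cm, dose in mg/day — and stated in a header
comment line.  The reader validates invariants row by row and drops
patients without a time-0 baseline SLD row with a logged count, mirroring
how such patients are excluded from the analysis population.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimate import FitResult
from .generate import SimulatedCohort
from .model import DOSE_LEVELS, DosingHistory, Observation, PatientRecord

__all__ = [
    "ReadDiagnostics",
    "write_dataset",
    "read_dataset",
    "write_truth",
    "fit_frame",
    "fit_table",
    "fit_to_dict",
    "run_manifest",
]

log = logging.getLogger(__name__)

_HEADER_COMMENT = "# units: time=days, sld=cm, dose=mg/day"
_REQUIRED = ("id", "time", "sld", "dose", "arm")


@dataclass
class ReadDiagnostics:
    n_rows: int = 0
    n_patients: int = 0
    n_dropped_no_baseline: int = 0
    dropped_ids: list = field(default_factory=list)
    messages: list = field(default_factory=list)


def write_dataset(
    source: SimulatedCohort | Sequence[PatientRecord], path
) -> pd.DataFrame:
    """Write patients to the long-format CSV; returns the written frame.

    For a :class:`SimulatedCohort`, patients flagged as missing their
    baseline assessment are written without the time-0 SLD value (the row
    keeps the dose), so a round-trip reproduces the analysis population.
    """

    if isinstance(source, SimulatedCohort):
        patients = source.patients
        missing = set(source.truth.loc[source.truth.baseline_missing, "id"])
    else:
        patients = list(source)
        missing = set()

    rows = []
    for p in patients:
        cov = dict(sorted(p.covariates.items()))
        assess_times = {o.time for o in p.observations}
        for o in p.observations:
            sld = o.sld
            if o.time == 0.0 and p.id in missing:
                sld = math.nan
            rows.append(
                {
                    "id": p.id,
                    "time": o.time,
                    "sld": sld,
                    "dose": p.dosing.dose_at(min(o.time, p.dosing.end - 1e-9)),
                    "arm": p.arm,
                    **cov,
                }
            )
        for t, d in p.dosing.change_points:
            if t not in assess_times:
                rows.append(
                    {
                        "id": p.id,
                        "time": t,
                        "sld": math.nan,
                        "dose": d,
                        "arm": p.arm,
                        **cov,
                    }
                )
    df = pd.DataFrame(rows).sort_values(["id", "time"], kind="stable")
    df = df.reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT + "\n")
        df.to_csv(fh, index=False)
    return df


def read_dataset(path) -> tuple[list[PatientRecord], ReadDiagnostics]:
    """Read and validate the long-format CSV into patient records.

    Rows violating invariants raise with row-numbered diagnostics; patients
    lacking a baseline SLD are dropped and counted.
    """

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    diag = ReadDiagnostics(n_rows=len(df))
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing mandatory columns: {missing_cols}")
    bad_dose = df[~df.dose.isin(DOSE_LEVELS)]
    if len(bad_dose):
        raise ValueError(
            f"dose outside {DOSE_LEVELS} at rows {list(bad_dose.index[:5])}"
        )
    if (df.time < 0).any():
        raise ValueError("negative times present")

    cov_cols = [c for c in df.columns if c not in _REQUIRED]
    patients: list[PatientRecord] = []
    for pid, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("time", kind="stable")
        assess = sub[sub.sld.notna()]
        dup = assess.time.duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate assessment rows for patient {pid!r} at "
                f"times {sorted(assess.time[dup])}"
            )
        base = assess[assess.time == 0.0]
        if not len(base):
            diag.n_dropped_no_baseline += 1
            diag.dropped_ids.append(pid)
            continue
        y0 = float(base.sld.iloc[0])
        obs = [Observation(float(t), float(s)) for t, s in zip(assess.time, assess.sld)]
        last = max(o.time for o in obs)
        changes = []
        prev = None
        for t, d in zip(sub.time, sub.dose):
            if prev is None or d != prev:
                changes.append((float(t), float(d)))
                prev = d
        dosing = DosingHistory.from_changes(changes, end=last + 1.0)
        covariates = {}
        for c in cov_cols:
            vals = sub[c].dropna().unique()
            if len(vals) > 1:
                raise ValueError(f"covariate {c!r} not constant for patient {pid!r}")
            if len(vals):
                covariates[c] = float(vals[0])
        patients.append(
            PatientRecord(
                id=str(pid),
                baseline_sld=y0,
                dosing=dosing,
                observations=obs,
                covariates=covariates,
                arm=str(sub.arm.iloc[0]),
            )
        )
    diag.n_patients = len(patients)
    if diag.n_dropped_no_baseline:
        msg = (
            f"dropped {diag.n_dropped_no_baseline} patients without a "
            f"baseline SLD row"
        )
        diag.messages.append(msg)
        log.info(msg)
    return patients, diag


def write_truth(cohort: SimulatedCohort, path) -> None:
    """Sidecar file: per-patient true parameters, eta draws and event log."""
    cohort.truth.to_csv(path, index=False)


# --------------------------------------------------------------------------
# fit reports
# --------------------------------------------------------------------------

_ROWS = (
    ("Placebo growth rate, r", "r", 1e-3, "10^-3 cm/day", "omega_r"),
    ("Drug effect of 10 mg, E10", "e10", 1e-3, "10^-3/day", "omega_e10"),
    ("Drug effect of 5 mg, E5", "e5", 1e-3, "10^-3/day", "omega_e5"),
    ("Baseline-SLD exponent on growth rate, theta1", "theta1", 1.0, "", None),
    ("Baseline-SLD exponent on drug effect, theta2", "theta2", 1.0, "", None),
    ("Residual error, sigma", "sigma", 1.0, "cm", None),
)


def fit_frame(result: FitResult) -> pd.DataFrame:
    """Machine-readable parameter table: estimate and SE per parameter, with
    the intersubject variability (omega) and its SE alongside."""
    rows = []
    p = result.params
    for label, name, scale, units, omega in _ROWS:
        if name == "e5" and result.variant.value == "model1":
            continue
        rows.append(
            {
                "parameter": label,
                "units": units,
                "estimate": getattr(p, name) / scale,
                "se": result.se(name) / scale,
                "omega": getattr(p, omega) / scale if omega else math.nan,
                "omega_se": result.se(omega) / scale if omega else math.nan,
            }
        )
    for t in p.extra:
        rows.append(
            {
                "parameter": f"Covariate {t.name} on {t.group}",
                "units": "",
                "estimate": t.theta,
                "se": result.se(f"theta_{t.group}_{t.name}"),
                "omega": math.nan,
                "omega_se": math.nan,
            }
        )
    return pd.DataFrame(rows)


def fit_table(result: FitResult) -> str:
    """Human-readable fit summary (estimate +/- SE layout)."""
    df = fit_frame(result)
    lines = [
        f"Model: {result.variant.value}   OFV: {result.ofv:.3f}   "
        f"patients: {result.n_patients}   observations: {result.n_obs}",
        f"converged: {result.converged}   estimated parameters: {result.n_params}",
        "-" * 78,
        f"{'Parameter':<46}{'Units':<14}{'Estimate +/- SE':<20}{'IIV +/- SE'}",
    ]
    for _, row in df.iterrows():
        est = f"{row.estimate:.4g} +/- {row.se:.2g}" if np.isfinite(row.se) else f"{row.estimate:.4g}"
        om = (
            f"{row.omega:.3g} +/- {row.omega_se:.2g}"
            if np.isfinite(row.omega) and np.isfinite(row.omega_se)
            else (f"{row.omega:.3g}" if np.isfinite(row.omega) else "")
        )
        lines.append(f"{row.parameter:<46}{row.units:<14}{est:<20}{om}")
    shr = ", ".join(f"{k}={v:.2f}" for k, v in result.shrinkage.items())
    lines.append("-" * 78)
    lines.append(f"eta-shrinkage: {shr}")
    return "\n".join(lines)


def fit_to_dict(result: FitResult) -> dict:
    """JSON-serializable summary of a fit (for manifests and the CLI)."""
    p = result.params
    return {
        "variant": result.variant.value,
        "ofv": result.ofv,
        "n_params": result.n_params,
        "n_patients": result.n_patients,
        "n_obs": result.n_obs,
        "converged": result.converged,
        "estimates": {
            "r": p.r,
            "e10": p.e10,
            "e5": p.e5,
            "theta1": p.theta1,
            "theta2": p.theta2,
            "omega_r": p.omega_r,
            "omega_e10": p.omega_e10,
            "omega_e5": p.omega_e5,
            "sigma": p.sigma,
            "y0_ref": p.y0_ref,
            "extra": [
                {
                    "name": t.name,
                    "group": t.group,
                    "kind": t.kind,
                    "reference": t.reference,
                    "theta": t.theta,
                }
                for t in p.extra
            ],
        },
        "standard_errors": dict(result.standard_errors),
        "shrinkage": dict(result.shrinkage),
    }


def run_manifest(config: dict, seed: int) -> dict:
    """Deterministic run manifest: canonical config hash, seed, versions.

    No timestamp, so identical configs produce byte-identical manifests."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    from . import __version__

    return {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "tgikit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
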