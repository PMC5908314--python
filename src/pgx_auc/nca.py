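"""Non-compartmental PK analysis of sparse concentration-time profiles.

Profiles are one 12-hr dosing interval sampled at steady state (default grid
0, 1, 2, 3, 4, 8, 12 hr).  AUC is the linear trapezoid over the observed
span; total clearance is dose-per-interval / AUC with ng -> mg and ml -> L
unit conversion.  Profiles with fewer than three samples or no t = 0 sample
are marked non-evaluable rather than raising, mirroring how clinical
tabulations carry "not evaluated" rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOSING_INTERVAL_HR = 12.0
_NG_PER_MG = 1e6
_ML_PER_L = 1e3


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One patient's sampled plasma concentrations over a dosing interval."""

    patient_id: str
    times_hr: tuple[float, ...]
    concentrations_ng_ml: tuple[float, ...]
    dose_mg_per_day: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_hr, dtype=float)
        c = np.asarray(self.concentrations_ng_ml, dtype=float)
        if t.size != c.size:
            raise ValueError("times and concentrations differ in length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.patient_id}: times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError(
                f"{self.patient_id}: negative concentrations are not permitted"
            )
        if not 2.0 <= self.dose_mg_per_day <= 20.0:
            raise ValueError(
                f"{self.patient_id}: dose {self.dose_mg_per_day} mg/day outside [2, 20]"
            )

    @property
    def is_evaluable(self) -> bool:
        """At least 3 samples and a pre-dose (t = 0) sample."""
        return len(self.times_hr) >= 3 and self.times_hr[0] == 0.0


@dataclass(frozen=True)
class PKParameters:
    """Derived NCA quantities for one patient.

    ``total_clearance_l_hr`` is None when AUC is zero (clearance undefined;
    the record is flagged, not rejected).
    """

    patient_id: str
    auc_0_12: float  # ng*hr/ml
    total_clearance_l_hr: float | None
    c_max: float
    c_0hr: float
    trough: float
    evaluable: bool = True


def compute_auc_trapezoid(profile: ConcentrationTimeProfile) -> float:
    """Linear-trapezoid AUC over the observed span, ng*hr/ml."""
    if len(profile.times_hr) < 2:
        raise ValueError(
            f"{profile.patient_id}: need at least 2 samples for a trapezoid AUC"
        )
    return float(
        np.trapezoid(
            np.asarray(profile.concentrations_ng_ml, dtype=float),
            np.asarray(profile.times_hr, dtype=float),
        )
    )


def compute_pk_params(
    profile: ConcentrationTimeProfile, dose_basis: str = "interval"
) -> PKParameters:
    """AUC, clearance, C-max, C-0hr and trough for one profile.

    dose_basis : "interval" (default; daily dose / 2, since the AUC spans one
        12-hr twice-daily interval) or "daily".
    """
    if dose_basis not in ("interval", "daily"):
        raise ValueError(f"dose_basis must be 'interval' or 'daily', got {dose_basis!r}")
    c = np.asarray(profile.concentrations_ng_ml, dtype=float)
    auc = compute_auc_trapezoid(profile)
    dose_mg = profile.dose_mg_per_day / (2.0 if dose_basis == "interval" else 1.0)
    if auc > 0:
        # (mg -> ng) / (ng*hr/ml) = ml/hr; -> L/hr
        clearance = dose_mg * _NG_PER_MG / auc / _ML_PER_L
    else:
        clearance = None
    return PKParameters(
        patient_id=profile.patient_id,
        auc_0_12=auc,
        total_clearance_l_hr=clearance,
        c_max=float(c.max()),
        c_0hr=float(c[0]) if profile.times_hr[0] == 0.0 else float("nan"),
        trough=float(c[-1]),
        evaluable=profile.is_evaluable and auc > 0,
    )


def summarize_pk(params: list[PKParameters]) -> pd.DataFrame:
    """Median and (min, max) per PK parameter over evaluable patients.

    Returns a frame with rows auc_0_12 / total_clearance_l_hr / c_max /
    c_0hr / trough and columns median, min, max, n.
    """
    evaluable = [p for p in params if p.evaluable]
    if not evaluable:
        raise ValueError("no evaluable PK records to summarize")
    fields = ["auc_0_12", "total_clearance_l_hr", "c_max", "c_0hr", "trough"]
    rows = {}
    for f in fields:
        vals = np.array(
            [getattr(p, f) for p in evaluable if getattr(p, f) is not None], dtype=float
        )
        vals = vals[~np.isnan(vals)]
        rows[f] = {
            "median": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": int(vals.size),
        }
    return pd.DataFrame(rows).T


def profiles_from_tables(
    concentrations: pd.DataFrame, doses: pd.DataFrame
) -> list[ConcentrationTimeProfile]:
    """Assemble profiles from the package CSV layout.

    concentrations: patient_id, time_hr, conc_ng_ml (long format).
    doses: patient_id, dose_mg_per_day.
    """
    dose_map = doses.set_index("patient_id")["dose_mg_per_day"].to_dict()
    out = []
    for pid, grp in concentrations.groupby("patient_id", sort=False):
        if pid not in dose_map:
            raise ValueError(f"no dose for patient {pid}")
        grp = grp.sort_values("time_hr")
        out.append(
            ConcentrationTimeProfile(
                patient_id=str(pid),
                times_hr=tuple(grp["time_hr"].astype(float)),
                concentrations_ng_ml=tuple(grp["conc_ng_ml"].astype(float)),
                dose_mg_per_day=float(dose_map[pid]),
            )
        )
    return out


def pk_params_table(params: list[PKParameters]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "auc_0_12": p.auc_0_12,
                "total_clearance_l_hr": p.total_clearance_l_hr,
                "c_max": p.c_max,
                "c_0hr": p.c_0hr,
                "trough": p.trough,
                "evaluable": p.evaluable,
            }
            for p in params
        ]
    )
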