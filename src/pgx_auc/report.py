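"""Clinical tabulations and end-to-end pipeline orchestration.

Best-response and adverse-event tables reproduce the standard efficacy/AE
tabulation arithmetic (counts with one-decimal percentages against the full
cohort n, half-up rounding).  ``run_pipeline`` chains
simulate -> nca -> fit -> predict -> evaluate -> scan -> report and writes a
machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype import build_design_matrix
from .model import ExponentialAUCRegressor, evaluate_calibration, recommend_dose_action
from .nca import compute_pk_params, pk_params_table, profiles_from_tables
from .simulate import RESPONSE_CATEGORIES, CohortConfig, generate_cohort
from .stats import trend_scan

logger = logging.getLogger("pgx_auc")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up decimal rounding (11/44 -> 25.0); bankers' rounding would
    differ on exact .x5 inputs."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResponseSummary:
    n: int
    counts: dict  # category -> count
    percentages: dict  # category -> one-decimal percent of n
    orr_count: int
    orr_percent: float


@dataclass(frozen=True)
class AESummary:
    n: int
    counts: dict  # ae -> {grade: count}
    percentages: dict  # ae -> {grade: one-decimal percent of n}


def best_response_table(outcomes: pd.DataFrame, n: int) -> ResponseSummary:
    """Counts and one-decimal percentages per best-response category.

    ``outcomes`` is the long outcomes table (or any frame with one
    best_response per patient_id); percentages use the full cohort n,
    including non-evaluable patients.  ORR = CR + PR.
    """
    per_patient = outcomes.drop_duplicates("patient_id").set_index("patient_id")[
        "best_response"
    ]
    if len(per_patient) != n:
        raise ValueError(f"{len(per_patient)} patients with responses but n = {n}")
    bad = set(per_patient) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown response categories: {sorted(bad)}")
    counts = {c: int((per_patient == c).sum()) for c in RESPONSE_CATEGORIES}
    pct = {c: round_half_up(100.0 * counts[c] / n) for c in RESPONSE_CATEGORIES}
    orr = counts["CR"] + counts["PR"]
    return ResponseSummary(n, counts, pct, orr, round_half_up(100.0 * orr / n))


def ae_table(outcomes: pd.DataFrame, n: int) -> AESummary:
    """Per-AE grade-2 and grade-3 counts with one-decimal percentages of n."""
    if not {"ae", "grade"}.issubset(outcomes.columns):
        raise ValueError("outcomes must have 'ae' and 'grade' columns")
    grades = outcomes["grade"].to_numpy()
    if not np.isin(grades, [0, 1, 2, 3]).all():
        raise ValueError("AE grades must lie in 0-3")
    counts: dict = {}
    pct: dict = {}
    for ae, grp in outcomes.groupby("ae", sort=True):
        by_patient = grp.drop_duplicates("patient_id")
        counts[ae] = {g: int((by_patient["grade"] == g).sum()) for g in (2, 3)}
        pct[ae] = {g: round_half_up(100.0 * counts[ae][g] / n) for g in (2, 3)}
    return AESummary(n, counts, pct)


# -- pipeline --------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: CohortConfig | None = None,
    outdir: str | Path = "pgx_auc_run",
    k: int = 8,
    selection: str = "forward",
    scan_split: float = 0.5,
) -> dict:
    """Simulate a cohort and run every downstream stage, writing all
    artifacts plus a manifest to ``outdir``.

    Stages: simulate, nca, fit (training split), predict (validation split),
    evaluate (calibration of calculated vs actual AUC), scan (trend scan of
    the panel loci), report (response/AE tables).  Any stage error aborts
    with the failing stage named; partial outputs stay on disk next to a
    FAILED marker.
    """
    config = config or CohortConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    stage = "simulate"
    try:
        logger.info("simulate: n_train=%d n_validation=%d seed=%d",
                    config.n_train, config.n_validation, config.seed)
        cohort = generate_cohort(config)
        paths = cohort.write(outdir)
        manifest["stages"].append({"stage": stage, "status": "PASSED"})

        stage = "nca"
        profiles = profiles_from_tables(cohort.concentrations, cohort.doses_table())
        params = [compute_pk_params(p) for p in profiles]
        pk = pk_params_table(params)
        pk.to_csv(outdir / "pk_params.csv", index=False)
        logger.info("nca: %d profiles, %d evaluable", len(params),
                    int(pk["evaluable"].sum()))
        manifest["stages"].append({"stage": stage, "status": "PASSED"})

        stage = "fit"
        design, evaluable = build_design_matrix(
            cohort.genotypes, cohort.doses_table(), panel=config.loci
        )
        pk = pk.set_index("patient_id")
        train_ids = [p for p in cohort.training_ids if evaluable[p] and pk.loc[p, "evaluable"]]
        std_auc = pk.loc[train_ids, "auc_0_12"].to_numpy() / design.loc[
            train_ids, "dose_mg_per_day"
        ].to_numpy()
        model = ExponentialAUCRegressor(k=k, selection=selection).fit(
            design.loc[train_ids], std_auc
        )
        model.save(outdir / "model.json")
        logger.info("fit: n=%d selected=%s R2(log)=%.3f", len(train_ids),
                    model.selected_labels_, model.r_squared_log_)
        manifest["stages"].append({"stage": stage, "status": "PASSED"})

        stage = "predict"
        valid_ids = [p for p in cohort.validation_ids if evaluable[p]]
        dose_v = design.loc[valid_ids, "dose_mg_per_day"].to_numpy()
        calc = model.predict_calculated_auc(design.loc[valid_ids], dose_v)
        cats = model.categorize(calc)
        pred = pd.DataFrame(
            {
                "patient_id": valid_ids,
                "calculated_auc": calc,
                "category": cats,
                "action": [recommend_dose_action(c)["code"] for c in cats],
            }
        )
        pred.to_csv(outdir / "predictions.csv", index=False, float_format="%.10g")
        manifest["stages"].append({"stage": stage, "status": "PASSED"})

        stage = "evaluate"
        actual_v = pk.loc[valid_ids, "auc_0_12"].to_numpy()
        calibration = evaluate_calibration(calc, actual_v, quartiles=model.training_quartiles_)
        (outdir / "calibration.json").write_text(
            json.dumps(calibration, indent=2, sort_keys=True)
        )
        logger.info("evaluate: validation R2=%.3f p=%.4g", calibration["r_squared"],
                    calibration["regression_p"])
        manifest["stages"].append({"stage": stage, "status": "PASSED"})

        stage = "scan"
        wide = cohort.genotypes.pivot(index="patient_id", columns="rsid", values="category")
        wide = wide.loc[cohort.patient_ids]
        scan = trend_scan(wide, pk["auc_0_12"], split=scan_split)
        scan.to_csv(outdir / "scan.tsv", sep="\t", index=False, float_format="%.10g")
        manifest["stages"].append({"stage": stage, "status": "PASSED"})

        stage = "report"
        oc = cohort.outcomes_table()
        train_oc = oc[oc["patient_id"].isin(cohort.training_ids)]
        resp = best_response_table(train_oc, config.n_train)
        aes = ae_table(train_oc, config.n_train)
        report = {
            "n": config.n_train,
            "best_response": {"counts": resp.counts, "percent": resp.percentages,
                              "orr_count": resp.orr_count, "orr_percent": resp.orr_percent},
            "adverse_events": {"counts": aes.counts, "percent": aes.percentages},
            "pk_summary": json.loads(
                pk.loc[pk["evaluable"], ["auc_0_12", "total_clearance_l_hr", "c_max",
                                          "c_0hr", "trough"]]
                .median()
                .to_json()
            ),
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest["stages"].append({"stage": stage, "status": "PASSED"})
    except Exception as exc:
        manifest["stages"].append({"stage": stage, "status": "FAILED", "error": str(exc)})
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
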