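"""Synthetic cohort generator.

Emulates the statistical structure the analysis pipeline assumes: Hardy-
Weinberg genotypes at six loci, genotype-driven log-scale variation of the
standard AUC, sparse steady-state concentration sampling over a 12-hr
twice-daily dosing interval, and exposure-linked response / adverse-event
outcomes.  The planted regression is the single source of truth: each
patient's noiseless concentration curve is scaled so its exact interval
integral equals the genotype-model AUC, so the full simulate -> NCA -> fit
pipeline can be checked against known coefficients.

Randomness: one master seed; independent sub-streams are spawned
deterministically per operation, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json
import numpy as np
import pandas as pd

from .genotype import encode_genotype
from .nca import DOSING_INTERVAL_HR
from .panel import (
    CATEGORIES,
    HETERO,
    VARIANT,
    WILD,
    LocusDefinition,
    candidate_labels,
    default_panel,
    validate_panel,
)

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
DEFAULT_TIMES = (0.0, 1.0, 2.0, 3.0, 4.0, 8.0, 12.0)
_KA_KE_TOL = 1e-3


@dataclass(frozen=True)
class OutcomeLink:
    """Logistic link P(event) = expit(intercept + slope * ln(actual AUC))."""

    slope: float
    intercept: float


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the clinical setting the pipeline targets: a 44-patient
    training cohort plus 16 prospective validation patients, 10 mg/day
    dosing, sampling at 0-12 hr on day 8, and exposure spread of roughly two
    orders of magnitude driven by six loci plus lognormal residual.
    """

    n_train: int = 44
    n_validation: int = 16
    loci: list[LocusDefinition] = field(default_factory=default_panel)
    intercept_b0: float = float(np.log(15.0))  # ln standard AUC at all-wild
    residual_sd: float = 0.5
    dose_effect: float = 0.0  # log-scale effect per mg/day on standard AUC
    dose_policy: dict = field(default_factory=lambda: {10.0: 1.0})
    sampling_times: tuple = DEFAULT_TIMES
    measurement_cv: float = 0.1
    ka_range: tuple = (0.3, 2.0)  # 1/hr
    ke_range: tuple = (0.05, 0.5)  # 1/hr
    # outcome links on ln(actual AUC); intercepts calibrated to plausible
    # event rates at a median exposure of ~150 ng*hr/ml (ln ~ 5.0)
    responder_link: OutcomeLink = field(default_factory=lambda: OutcomeLink(1.5, -8.5))
    hfs_link: OutcomeLink = field(default_factory=lambda: OutcomeLink(1.5, -8.9))
    hypothyroid_link: OutcomeLink = field(default_factory=lambda: OutcomeLink(1.0, -3.9))
    # hypertension is exposure-independent by construction
    hypertension_probs: tuple = (13.0 / 44.0, 10.0 / 44.0, 21.0 / 44.0)  # G0/1, G2, G3
    # conditional splits: CR among responders; (SD, PD, NE) among the rest
    p_cr_given_responder: float = 1.0 / 12.0
    p_sd_pd_ne: tuple = (25.0 / 32.0, 3.0 / 32.0, 4.0 / 32.0)
    p_hfs_grade3_given_event: float = 3.0 / 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_validation < 0:
            raise ValueError("cohort sizes must be positive")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be >= 0")
        t = np.asarray(self.sampling_times, dtype=float)
        if np.any(t < 0) or not np.all(np.diff(t) > 0):
            raise ValueError("sampling_times must be non-negative, strictly increasing")
        validate_panel(self.loci)
        doses = np.array(list(self.dose_policy))
        probs = np.array(list(self.dose_policy.values()))
        if np.any((doses < 2.0) | (doses > 20.0)):
            raise ValueError("dose_policy doses must lie in [2, 20] mg/day")
        if not np.isclose(probs.sum(), 1.0) or np.any(probs < 0):
            raise ValueError("dose_policy probabilities must be a distribution")

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_validation

    def to_json(self) -> str:
        d = asdict(self)
        d["sampling_times"] = list(self.sampling_times)
        d["dose_policy"] = {str(k): v for k, v in self.dose_policy.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        d["loci"] = [LocusDefinition(**l) for l in d.get("loci", [])] or default_panel()
        d["dose_policy"] = {float(k): v for k, v in d["dose_policy"].items()}
        d["sampling_times"] = tuple(d["sampling_times"])
        for key in ("responder_link", "hfs_link", "hypothyroid_link"):
            d[key] = OutcomeLink(**d[key])
        for key in ("ka_range", "ke_range", "hypertension_probs", "p_sd_pd_ne"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    genotypes: dict  # rsid -> category
    dose_mg_per_day: float
    true_standard_auc: float  # ng*hr/ml per mg/day
    true_auc: float  # ng*hr/ml
    true_clearance_l_hr: float
    ka: float
    ke: float


@dataclass(frozen=True)
class OutcomeRecord:
    patient_id: str
    best_response: str
    ae_grades: dict  # AE name -> grade in {0..3}

    def __post_init__(self) -> None:
        if self.best_response not in RESPONSE_CATEGORIES:
            raise ValueError(f"unknown best_response {self.best_response!r}")
        bad = {k: g for k, g in self.ae_grades.items() if g not in (0, 1, 2, 3)}
        if bad:
            raise ValueError(f"AE grades outside 0-3: {bad}")


@dataclass
class SyntheticCohort:
    config: CohortConfig
    genotypes: pd.DataFrame  # long: patient_id, rsid, category
    truths: list[PatientTruth]
    concentrations: pd.DataFrame  # long: patient_id, time_hr, conc_ng_ml
    outcomes: list[OutcomeRecord]

    @property
    def patient_ids(self) -> list[str]:
        return [t.patient_id for t in self.truths]

    @property
    def training_ids(self) -> list[str]:
        return self.patient_ids[: self.config.n_train]

    @property
    def validation_ids(self) -> list[str]:
        return self.patient_ids[self.config.n_train :]

    def doses_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "dose_mg_per_day": [t.dose_mg_per_day for t in self.truths],
            }
        )

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": t.patient_id,
                    "dose_mg_per_day": t.dose_mg_per_day,
                    "true_standard_auc": t.true_standard_auc,
                    "true_auc": t.true_auc,
                    "true_clearance_l_hr": t.true_clearance_l_hr,
                    "ka": t.ka,
                    "ke": t.ke,
                }
                for t in self.truths
            ]
        )

    def outcomes_table(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            for ae, grade in sorted(o.ae_grades.items()):
                rows.append(
                    {
                        "patient_id": o.patient_id,
                        "best_response": o.best_response,
                        "ae": ae,
                        "grade": grade,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict:
        """Write the CSV layout; truth.csv is withheld from pipeline inputs
        (tests only).  Returns {name: path}."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "concentrations.csv": self.concentrations,
            "genotypes.csv": self.genotypes,
            "doses.csv": self.doses_table(),
            "outcomes.csv": self.outcomes_table(),
            "truth.csv": self.truth_table(),
        }
        for name, df in tables.items():
            p = outdir / name
            df.to_csv(p, index=False)
            paths[name] = str(p)
        (outdir / "cohort_config.json").write_text(self.config.to_json())
        paths["cohort_config.json"] = str(outdir / "cohort_config.json")
        return paths


# -- sub-streams -----------------------------------------------------------

_STREAMS = ("genotypes", "pk", "profiles", "outcomes")


def _rng(config: CohortConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


def _patient_ids(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


# -- operations ------------------------------------------------------------


def generate_genotypes(config: CohortConfig) -> pd.DataFrame:
    """Hardy-Weinberg genotype draw: (wild, hetero, variant) with
    probabilities ((1-q)^2, 2q(1-q), q^2) per locus."""
    rng = _rng(config, "genotypes")
    ids = _patient_ids(config.n_total)
    rows = []
    for locus in config.loci:
        q = locus.variant_allele_frequency
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        draws = rng.choice(3, size=config.n_total, p=probs)
        for pid, d in zip(ids, draws):
            rows.append({"patient_id": pid, "rsid": locus.rsid, "category": CATEGORIES[d]})
    df = pd.DataFrame(rows)
    # stable patient-major ordering
    df["__order"] = df["patient_id"].map({p: i for i, p in enumerate(ids)})
    df = df.sort_values(["__order", "rsid"], kind="stable").drop(columns="__order")
    return df.reset_index(drop=True)


def _locus_effect(locus: LocusDefinition, category: str) -> float:
    if category == WILD:
        return 0.0
    if category == HETERO:
        return locus.effect_hetero
    return locus.effect_variant


def generate_pk_truth(genotypes: pd.DataFrame, config: CohortConfig) -> list[PatientTruth]:
    """Invert the exposure model: ln(standard AUC) = b0 + sum(effects)
    + dose_effect * dose + N(0, residual_sd); AUC = standard AUC x dose."""
    rng = _rng(config, "pk")
    ids = _patient_ids(config.n_total)
    wide = genotypes.pivot(index="patient_id", columns="rsid", values="category")
    wide = wide.reindex(ids)

    doses_support = np.array(sorted(config.dose_policy), dtype=float)
    dose_probs = np.array([config.dose_policy[d] for d in doses_support])
    doses = doses_support[rng.choice(doses_support.size, size=config.n_total, p=dose_probs)]

    eps = rng.normal(0.0, config.residual_sd, size=config.n_total)

    ka_lo, ka_hi = config.ka_range
    ke_lo, ke_hi = config.ke_range
    truths = []
    for i, pid in enumerate(ids):
        calls = {l.rsid: wide.loc[pid, l.rsid] for l in config.loci}
        lin = config.intercept_b0 + config.dose_effect * doses[i]
        lin += sum(_locus_effect(l, calls[l.rsid]) for l in config.loci)
        std_auc = float(np.exp(lin + eps[i]))
        auc = std_auc * doses[i]
        # per-interval dose (BID) in ng over AUC in ng*hr/ml -> ml/hr -> L/hr
        clearance = (doses[i] / 2.0) * 1e6 / auc / 1e3
        ka = ke = None
        while ka is None or abs(ka - ke) < _KA_KE_TOL:
            ka = rng.uniform(ka_lo, ka_hi)
            ke = rng.uniform(ke_lo, ke_hi)
        truths.append(
            PatientTruth(
                patient_id=pid,
                genotypes=calls,
                dose_mg_per_day=float(doses[i]),
                true_standard_auc=std_auc,
                true_auc=float(auc),
                true_clearance_l_hr=float(clearance),
                ka=float(ka),
                ke=float(ke),
            )
        )
    return truths


def steady_state_curve(truth: PatientTruth, times) -> np.ndarray:
    """Noiseless steady-state one-compartment oral-absorption curve over the
    12-hr interval, scaled so the exact integral over [0, tau] equals
    true_auc.

    Shape: e^(-ke t)/(1 - e^(-ke tau)) - e^(-ka t)/(1 - e^(-ka tau));
    its exact interval integral is 1/ke - 1/ka, so the amplitude is
    true_auc / (1/ke - 1/ka).  Works on either side of the flip-flop
    (ka < ke) since amplitude and shape change sign together.
    """
    t = np.asarray(times, dtype=float)
    ka, ke, tau = truth.ka, truth.ke, DOSING_INTERVAL_HR
    if abs(ka - ke) < _KA_KE_TOL:
        raise ValueError(f"{truth.patient_id}: degenerate kinetics ka == ke")
    shape = np.exp(-ke * t) / (1.0 - np.exp(-ke * tau)) - np.exp(-ka * t) / (
        1.0 - np.exp(-ka * tau)
    )
    amplitude = truth.true_auc / (1.0 / ke - 1.0 / ka)
    return amplitude * shape


def simulate_concentration_profile(
    truth: PatientTruth,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed concentrations: noiseless curve x mean-one lognormal noise
    with the configured CV, independent per timepoint."""
    times = np.asarray(config.sampling_times, dtype=float)
    conc = steady_state_curve(truth, times)
    cv = config.measurement_cv
    if cv > 0:
        if rng is None:
            rng = _rng(config, "profiles")
        sigma = float(np.sqrt(np.log1p(cv**2)))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=times.size)
        conc = conc * noise
    return pd.DataFrame(
        {"patient_id": truth.patient_id, "time_hr": times, "conc_ng_ml": conc}
    )


def generate_outcomes(truths: list[PatientTruth], config: CohortConfig) -> list[OutcomeRecord]:
    """Exposure-linked outcomes: responder (CR/PR), grade>=2 hand-foot
    syndrome and grade-2 hypothyroidism follow logistic links in
    ln(actual AUC); hypertension grade is drawn independently of exposure."""
    from scipy.special import expit

    rng = _rng(config, "outcomes")
    log_auc = np.array([np.log(t.true_auc) for t in truths])
    n = len(truths)

    def bern(link: OutcomeLink) -> np.ndarray:
        p = expit(link.intercept + link.slope * log_auc)
        return rng.random(n) < p

    responder = bern(config.responder_link)
    hfs = bern(config.hfs_link)
    hypo = bern(config.hypothyroid_link)
    hyp_grade = rng.choice([0, 2, 3], size=n, p=config.hypertension_probs)

    records = []
    for i, t in enumerate(truths):
        if responder[i]:
            best = "CR" if rng.random() < config.p_cr_given_responder else "PR"
        else:
            best = ["SD", "PD", "NE"][rng.choice(3, p=config.p_sd_pd_ne)]
        grades = {
            "hand_foot_syndrome": (
                3 if (hfs[i] and rng.random() < config.p_hfs_grade3_given_event) else 2
            )
            if hfs[i]
            else 0,
            "hypothyroidism": 2 if hypo[i] else 0,
            "hypertension": int(hyp_grade[i]),
        }
        records.append(OutcomeRecord(t.patient_id, best, grades))
    return records


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Full cohort: genotypes, PK truths, sampled profiles, outcomes.

    The first n_train patients are the training split; the remainder are the
    prospective validation split.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    genotypes = generate_genotypes(config)
    truths = generate_pk_truth(genotypes, config)
    prof_rng = _rng(config, "profiles")
    profiles = [
        simulate_concentration_profile(t, config, rng=prof_rng) for t in truths
    ]
    concentrations = pd.concat(profiles, ignore_index=True)
    outcomes = generate_outcomes(truths, config)
    return SyntheticCohort(config, genotypes, truths, concentrations, outcomes)


def design_from_truths(truths: list[PatientTruth], config: CohortConfig) -> pd.DataFrame:
    """Candidate design matrix straight from generator truth (tests and
    pipeline use; equivalent to genotype.build_design_matrix)."""
    labels = candidate_labels(config.loci)
    rows = []
    for t in truths:
        x = []
        for locus in config.loci:
            x.extend(encode_genotype(t.genotypes[locus.rsid]))
        x.append(t.dose_mg_per_day)
        rows.append(x)
    return pd.DataFrame(
        rows, index=pd.Index([t.patient_id for t in truths], name="patient_id"),
        columns=labels,
    )


def planted_coefficients(config: CohortConfig) -> pd.Series:
    """True log-scale coefficients of the 13 candidates under the generator."""
    labels = candidate_labels(config.loci)
    vals = []
    for locus in config.loci:
        vals.extend([locus.effect_hetero, locus.effect_variant])
    vals.append(config.dose_effect)
    return pd.Series(vals, index=labels, name="planted")
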