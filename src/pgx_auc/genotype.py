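"""Genotype representation, indicator coding, and design-matrix assembly.

Genotypes are three-way categories (wild / hetero / variant).  Each locus is
dummy-coded into an indicator pair: wild -> (0, 0), hetero -> (1, 0),
variant -> (0, 1).  With six loci plus the daily dose this yields the
13-candidate covariate design consumed by the exposure regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import (
    CATEGORIES,
    DOSE_LABEL,
    HETERO,
    VARIANT,
    WILD,
    LocusDefinition,
    candidate_labels,
    default_panel,
)

_ENCODING = {WILD: (0, 0), HETERO: (1, 0), VARIANT: (0, 1)}
_DECODING = {v: k for k, v in _ENCODING.items()}


@dataclass(frozen=True)
class GenotypeCall:
    patient_id: str
    rsid: str
    category: str
    alleles: str | None = None  # optional raw allele pair, provenance only

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown genotype category {self.category!r} "
                f"(expected one of {CATEGORIES})"
            )


def encode_genotype(category: str) -> tuple[int, int]:
    """Map a category to its indicator pair: wild (0,0), hetero (1,0), variant (0,1)."""
    try:
        return _ENCODING[category]
    except KeyError:
        raise ValueError(
            f"unknown genotype category {category!r} (expected one of {CATEGORIES})"
        ) from None


def decode_genotype(pair: tuple[int, int]) -> str:
    """Inverse of :func:`encode_genotype`; rejects inadmissible pairs like (1,1)."""
    try:
        return _DECODING[tuple(pair)]
    except KeyError:
        raise ValueError(f"inadmissible indicator pair {pair!r}") from None


class GenotypeEncoder(BaseEstimator, TransformerMixin):
    """Transform long-format genotype calls plus doses into the candidate design.

    A scikit-learn transformer over a tidy frame with columns
    ``patient_id, rsid, category``.  ``transform`` returns an
    ``(n_patients, 13)`` float array whose columns follow the panel order
    (two indicators per locus, dose last); patients missing any locus call
    are flagged rather than silently dropped.

    Parameters
    ----------
    panel : list of LocusDefinition, optional
        Locus panel defining column order; defaults to the six-locus panel.
    """

    def __init__(self, panel: list[LocusDefinition] | None = None):
        self.panel = panel

    def fit(self, X: pd.DataFrame, y=None) -> "GenotypeEncoder":
        panel = default_panel() if self.panel is None else self.panel
        self.panel_ = panel
        self.feature_names_ = candidate_labels(panel)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_, dtype=object)

    def transform(
        self, X: pd.DataFrame, doses: pd.Series | dict | None = None
    ) -> pd.DataFrame:
        if not hasattr(self, "panel_"):
            self.fit(X)
        design, _ = build_design_matrix(X, doses, panel=self.panel_)
        return design


def build_design_matrix(
    calls: pd.DataFrame,
    doses: pd.Series | dict | pd.DataFrame | None,
    panel: list[LocusDefinition] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the 13-column candidate design from long-format calls.

    Parameters
    ----------
    calls : DataFrame with columns patient_id, rsid, category.
    doses : mapping / Series of patient_id -> dose in mg/day, or a DataFrame
        with columns patient_id, dose_mg_per_day.  Required (missing dose is
        an error); missing locus calls only flag the patient.
    panel : locus panel fixing column order.

    Returns
    -------
    (design, evaluable) : design is an (n, 13) DataFrame indexed by
        patient_id with candidate-label columns; ``evaluable`` is a boolean
        Series marking patients with complete six-locus calls.  Rows of
        non-evaluable patients hold NaN in the missing indicator pairs.
    """
    panel = default_panel() if panel is None else panel
    labels = candidate_labels(panel)
    required = {"patient_id", "rsid", "category"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls must have columns {sorted(required)}")

    if doses is None:
        raise ValueError("doses are required to build the design matrix")
    if isinstance(doses, pd.DataFrame):
        doses = doses.set_index("patient_id")[DOSE_LABEL]
    dose_map = dict(doses.items() if hasattr(doses, "items") else doses)

    patients = list(dict.fromkeys(calls["patient_id"]))
    missing_dose = [p for p in patients if p not in dose_map]
    if missing_dose:
        raise ValueError(f"missing dose for patients: {missing_dose}")

    wide = calls.pivot_table(
        index="patient_id", columns="rsid", values="category", aggfunc="first"
    ).reindex(patients)

    n = len(patients)
    X = np.full((n, len(labels)), np.nan)
    evaluable = np.ones(n, dtype=bool)
    for j, locus in enumerate(panel):
        col = (
            wide[locus.rsid]
            if locus.rsid in wide.columns
            else pd.Series(index=wide.index, dtype=object)
        )
        for i, cat in enumerate(col.to_numpy()):
            if isinstance(cat, str):
                X[i, 2 * j], X[i, 2 * j + 1] = encode_genotype(cat)
            else:
                evaluable[i] = False
    X[:, -1] = [dose_map[p] for p in patients]

    design = pd.DataFrame(X, index=pd.Index(patients, name="patient_id"), columns=labels)
    return design, pd.Series(evaluable, index=design.index, name="evaluable")


def concordance_rate(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> float:
    """Fraction of (patient, locus) keys with identical category in two call sets.

    Mirrors the concordance reported between orthogonal genotyping platforms
    (e.g. Sanger sequencing vs DNA microarray).
    """
    a = calls_a.set_index(["patient_id", "rsid"])["category"]
    b = calls_b.set_index(["patient_id", "rsid"])["category"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("call sets share no (patient_id, rsid) keys")
    return float((a.loc[common].to_numpy() == b.loc[common].to_numpy()).mean())


def _category_from_gt(alleles: tuple) -> str | None:
    """Diploid genotype -> category; any non-reference allele counts as variant
    carriage, so (1,2) at a triallelic site is homozygous-variant."""
    alts = [a for a in alleles if a is not None and a >= 0]
    if len(alts) < 2:
        return None  # missing / half-call
    n_nonref = sum(1 for a in alts if a > 0)
    return (WILD, HETERO, VARIANT)[min(n_nonref, 2)]


def read_genotypes_vcf(
    vcf_path: str, panel: list[LocusDefinition] | None = None
) -> pd.DataFrame:
    """Extract panel genotype calls from a VCF (matching on the ID column).

    Returns a long-format frame (patient_id, rsid, category); sites absent
    from the VCF or with missing GT simply yield no row, leaving the patient
    flagged downstream.  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    panel = default_panel() if panel is None else panel
    wanted = {l.rsid for l in panel}
    rows: list[dict] = []
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    for record in vcf:
        if record.ID not in wanted:
            continue
        for sample, gt in zip(samples, record.genotypes):
            cat = _category_from_gt(tuple(gt[:2]))
            if cat is not None:
                rows.append({"patient_id": sample, "rsid": record.ID, "category": cat})
    return pd.DataFrame(rows, columns=["patient_id", "rsid", "category"])


def read_genotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown genotype categories in {path}: {sorted(bad)}")
    return df[["patient_id", "rsid", "category"]]


def write_genotypes_csv(calls: pd.DataFrame, path) -> None:
    calls[["patient_id", "rsid", "category"]].to_csv(path, index=False)
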