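"""Six-locus pharmacogenetic panel for axitinib exposure prediction.

The panel covers polymorphisms in drug-metabolism (UGT1A) and efflux
(ABCB1, ABCG2) genes plus one olfactory-receptor locus (OR2B11) found by
exome-wide association with axitinib exposure.  Each locus contributes two
indicator covariates to the regression design (hetero and homozygous-variant
carriage); daily dosage is the thirteenth candidate covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Three-way genotype categories used throughout the package.
WILD = "wild"
HETERO = "hetero"
VARIANT = "variant"
CATEGORIES = (WILD, HETERO, VARIANT)

DOSE_LABEL = "dose_mg_per_day"


@dataclass(frozen=True)
class LocusDefinition:
    """One panel locus with its simulated log-scale effects on standard AUC.

    ``effect_hetero`` / ``effect_variant`` are additive effects on
    ln(standard AUC) (dimensionless) used by the cohort simulator; they are
    generator parameters, not literature estimates.
    """

    rsid: str
    gene_label: str
    variant_allele_frequency: float = 0.3
    effect_hetero: float = 0.0
    effect_variant: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.variant_allele_frequency <= 1.0:
            raise ValueError(
                f"{self.rsid}: variant_allele_frequency must be in [0, 1], "
                f"got {self.variant_allele_frequency}"
            )

    @property
    def label_hetero(self) -> str:
        return f"{self.gene_label}_{self.rsid}_het"

    @property
    def label_variant(self) -> str:
        return f"{self.gene_label}_{self.rsid}_var"


def default_panel() -> list[LocusDefinition]:
    """The six-locus panel in its canonical order.

    Allele frequencies (0.2-0.4) and effect sizes are simulator defaults
    chosen to produce a roughly 100-fold spread of exposure across a cohort;
    variant carriage at metabolism/efflux loci raises exposure.
    """
    return [
        LocusDefinition("rs17868323", "UGT1A7", 0.40, 0.20, 0.45),
        LocusDefinition("rs3832043", "UGT1A9-1b", 0.35, 0.25, 0.50),
        LocusDefinition("rs2231142", "ABCG2", 0.30, 0.30, 0.60),
        LocusDefinition("rs2032582", "ABCB1", 0.40, 0.20, 0.40),
        LocusDefinition("rs1045642", "ABCB1", 0.40, 0.15, 0.35),
        LocusDefinition("rs35305980", "OR2B11", 0.20, 0.35, 0.70),
    ]


def candidate_labels(panel: list[LocusDefinition] | None = None) -> list[str]:
    """Ordered labels of the 13 candidate covariates (12 indicators + dose)."""
    panel = default_panel() if panel is None else panel
    labels: list[str] = []
    for locus in panel:
        labels.append(locus.label_hetero)
        labels.append(locus.label_variant)
    labels.append(DOSE_LABEL)
    return labels


def validate_panel(panel: list[LocusDefinition]) -> None:
    rsids = [l.rsid for l in panel]
    if len(set(rsids)) != len(rsids):
        raise ValueError(f"duplicate rsIDs in panel: {rsids}")
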