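"""Shared fixtures: a planted-effect cohort configuration for parameter-
recovery checks, and permutation/enumeration oracles written from rank- and
score-statistic first principles (independent of the package's own test
implementations)."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from pgx_auc import CohortConfig, LocusDefinition
from pgx_auc.simulate import planted_coefficients


def recovery_loci() -> list[LocusDefinition]:
    """Six loci with effects planted on exactly 7 of the 12 indicator
    columns (one locus null, two with a single active category); allele
    frequencies 0.4 keep every genotype category represented at n = 44."""
    return [
        LocusDefinition("rs17868323", "UGT1A7", 0.40, 0.30, 0.60),
        LocusDefinition("rs3832043", "UGT1A9-1b", 0.40, 0.00, 0.50),
        LocusDefinition("rs2231142", "ABCG2", 0.40, 0.40, 0.80),
        LocusDefinition("rs2032582", "ABCB1", 0.40, 0.00, 0.00),
        LocusDefinition("rs1045642", "ABCB1", 0.40, 0.25, 0.00),
        LocusDefinition("rs35305980", "OR2B11", 0.40, 0.00, 0.70),
    ]


def recovery_config(seed: int = 0, residual_sd: float = 0.0,
                    measurement_cv: float = 0.0) -> CohortConfig:
    """Cohort whose ln(standard AUC) has 8 planted candidate effects
    (7 genotype indicators + dose) out of 13."""
    return CohortConfig(
        loci=recovery_loci(),
        residual_sd=residual_sd,
        measurement_cv=measurement_cv,
        dose_effect=0.05,
        dose_policy={4.0: 0.25, 6.0: 0.25, 10.0: 0.4, 14.0: 0.1},
        seed=seed,
    )


def planted_support(config: CohortConfig) -> list[str]:
    p = planted_coefficients(config)
    return list(p[p != 0.0].index)


@pytest.fixture
def small_cohort_config() -> CohortConfig:
    return CohortConfig(n_train=30, n_validation=6, seed=5)


# -- permutation / enumeration oracles -------------------------------------


def kw_statistic_from_ranks(ranks: np.ndarray, sizes: list[int],
                            tie_term: float, n: int) -> np.ndarray:
    """H from group rank sums (vectorized over leading axes of ``ranks``)."""
    out = np.zeros(ranks.shape[:-1])
    offset = 0
    for s in sizes:
        rsum = ranks[..., offset:offset + s].sum(axis=-1)
        out += rsum**2 / s
        offset += s
    h = 12.0 / (n * (n + 1)) * out - 3.0 * (n + 1)
    return h / tie_term


def perm_pvalue_kruskal(groups, n_perm: int = 10_000, seed: int = 0) -> float:
    """Permutation p for the Kruskal-Wallis H, built directly from the
    rank-sum formula with tie correction."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = [len(g) for g in groups]
    n = pooled.size
    ranks = rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))
    obs = kw_statistic_from_ranks(ranks[None, :], sizes, tie_term, n)[0]
    perm = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)
    h = kw_statistic_from_ranks(perm, sizes, tie_term, n)
    return float(np.mean(h >= obs - 1e-12))


def mwu_u_less(a: np.ndarray, b: np.ndarray) -> float:
    """U = #{(a, b) pairs with a < b} + half-ties, by direct counting."""
    diff = a[:, None] - b[None, :]
    return float((diff < 0).sum() + 0.5 * (diff == 0).sum())


def perm_pvalue_mwu(a, b, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p for Mann-Whitney U (distance from n1*n2/2)."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    center = n1 * n2 / 2.0
    obs = abs(mwu_u_less(a, b) - center)
    pooled = np.concatenate([a, b])
    cnt = 0
    perm = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    for row in perm:
        if abs(mwu_u_less(row[:n1], row[n1:]) - center) >= obs - 1e-12:
            cnt += 1
    return cnt / n_perm


def enumerate_pvalue_mwu(a, b) -> float:
    """Exact two-sided p by full enumeration of group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    center = a.size * b.size / 2.0
    obs = abs(mwu_u_less(a, b) - center)
    idx = np.arange(pooled.size)
    hits = total = 0
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        u = mwu_u_less(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - center) >= obs - 1e-12:
            hits += 1
    return hits / total


def perm_pvalue_trend(cases, controls, weights=(0.0, 1.0, 2.0),
                      n_perm: int = 10_000, seed: int = 0,
                      mid_p: bool = False) -> float:
    """Two-sided permutation p for the score-based trend statistic, from
    subject-level scores (cases and controls are genotype-category counts).

    ``mid_p=True`` counts the atom at the observed statistic with weight
    1/2 — the discrete analogue a continuous approximation targets, since
    the trend statistic lives on a lattice.
    """
    rng = np.random.default_rng(seed)
    cases = np.asarray(cases, dtype=int)
    controls = np.asarray(controls, dtype=int)
    w = np.asarray(weights, dtype=float)
    scores = np.repeat(w, cases + controls)
    n1 = int(cases.sum())
    expected = n1 * scores.mean()
    obs = abs(float(np.repeat(w, cases).sum()) - expected)
    perm = rng.permuted(np.tile(scores, (n_perm, 1)), axis=1)
    t = np.abs(perm[:, :n1].sum(axis=1) - expected)
    if mid_p:
        return float(np.mean(t > obs + 1e-9) + 0.5 * np.mean(np.abs(t - obs) <= 1e-9))
    return float(np.mean(t >= obs - 1e-9))
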