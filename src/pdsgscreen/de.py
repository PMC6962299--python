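"""Dosage-expression screen: differential expression concordant with copy
number (screen steps 1-2).

A gene is a candidate on the amplified side when its expression is higher in
copy-number amplified samples than in non-altered ones (Wilcoxon rank-sum
p < 0.01, BH FDR < 0.1, fold change > 1.2), and symmetrically on the deleted
side (fold change < 1/1.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import OmicsCohort
from .partition import AMPLIFIED, DELETED, MIN_ALTERED, partition_samples

logger = logging.getLogger(__name__)

#: largest group size for which the exact Mann-Whitney null is enumerated
_EXACT_MAX_N = 8


@dataclass
class DEResult:
    """Per-gene, per-side differential-expression record."""

    gene: str
    side: str
    n_alt: int
    n_non: int
    statistic: float
    p: float
    fdr: float
    fc: float
    concordant: bool


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups have <= 8 untied
    observations, otherwise the normal approximation with midranks, tie
    correction and continuity correction.  Returns (U statistic of group_a,
    two-sided p).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= _EXACT_MAX_N and b.size <= _EXACT_MAX_N
                         and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(expr_alt, expr_non, pseudocount: float = 1e-9) -> float:
    """Ratio of group means of expression (FPKM scale), pseudocount-guarded."""
    alt = np.asarray(expr_alt, float)
    non = np.asarray(expr_non, float)
    if alt.size == 0 or non.size == 0:
        raise ValueError("both groups must be non-empty")
    return float((alt.mean() + pseudocount) / (non.mean() + pseudocount))


def screen_dosage_de(
    cohort: OmicsCohort,
    x: float = 0.3,
    min_alt: int = MIN_ALTERED,
    p_max: float = 0.01,
    fdr_max: float = 0.1,
    fc_min: float = 1.2,
) -> list[DEResult]:
    """Steps 1-2: test every evaluable gene for expression change concordant
    with its copy-number class at threshold ``x``.

    For each gene with >= ``min_alt`` amplified samples, expression in CNAS is
    tested against CNNS; a gene is candidate-amplified when p < ``p_max``,
    BH FDR < ``fdr_max`` and fold change > ``fc_min``.  The deleted side is
    symmetric with fold change < 1/``fc_min``.  BH is applied separately
    within each side's family of tests.  Results for both sides are returned,
    sorted by (gene, side); genes with no evaluable side are excluded and
    counted in the log.
    """
    sample_pos = {s: i for i, s in enumerate(cohort.expr.columns)}
    expr_mat = cohort.expr.to_numpy(float)
    expr_row = {g: i for i, g in enumerate(cohort.expr.index)}

    per_side: dict[str, list[DEResult]] = {AMPLIFIED: [], DELETED: []}
    n_skipped = 0
    for gene in cohort.genes:
        part = partition_samples(cohort, gene, x)
        non_idx = [sample_pos[s] for s in sorted(part.cnns)]
        evaluable_any = False
        for side in (AMPLIFIED, DELETED):
            alt = part.altered(side)
            if len(alt) < min_alt or not non_idx:
                continue
            evaluable_any = True
            alt_idx = [sample_pos[s] for s in sorted(alt)]
            e_alt = expr_mat[expr_row[gene], alt_idx]
            e_non = expr_mat[expr_row[gene], non_idx]
            stat, p = wilcoxon_rank_sum(e_alt, e_non)
            fc = fold_change(e_alt, e_non)
            per_side[side].append(DEResult(
                gene=gene, side=side, n_alt=len(alt), n_non=len(non_idx),
                statistic=stat, p=p, fdr=np.nan, fc=fc, concordant=False,
            ))
        if not evaluable_any:
            n_skipped += 1
    if n_skipped:
        logger.info("screen_dosage_de: %d genes had no evaluable altered class "
                    "at x=%g", n_skipped, x)

    for side, results in per_side.items():
        if not results:
            continue
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.fdr = float(q)
            fc_ok = r.fc > fc_min if side == AMPLIFIED else r.fc < 1.0 / fc_min
            r.concordant = bool(r.p < p_max and r.fdr < fdr_max and fc_ok)

    out = per_side[AMPLIFIED] + per_side[DELETED]
    out.sort(key=lambda r: (r.gene, r.side))
    return out
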