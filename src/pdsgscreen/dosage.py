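"""Dosage-effect scoring and PDSG selection (screen step 5), plus the
cross-dataset concordance check.

The dosage-effect score of a gene is the Pearson correlation between its
SCNA value and its expression (FPKM) across samples; for a simple linear
regression this R equals the regression R-value, and its p-value is the
t-test on the slope.  A stable prognosis-sensitive gene is a prognostic
dosage-sensitive gene (PDSG) when the score satisfies r >= 0.3 with
p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OmicsCohort
from .partition import AMPLIFIED, partition_samples


@dataclass
class DosageScore:
    gene: str
    r: float
    p: float
    n: int
    is_stable_psg: bool = False
    is_pdsg: bool = False
    evaluable: bool = True


def dosage_score(scna, expr) -> DosageScore:
    """Pearson r between SCNA and expression, with the t-distribution p-value
    (n-2 df) of the linear association.

    Constant input vectors make r undefined; the score is returned flagged
    as non-evaluable.
    """
    x = np.asarray(scna, float)
    y = np.asarray(expr, float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return DosageScore("", np.nan, np.nan, int(x.size), evaluable=False)
    r, p = stats.pearsonr(x, y)
    return DosageScore("", float(r), float(p), int(x.size))


def score_genes(
    cohort: OmicsCohort,
    genes: Sequence[str],
    samples: str = "all",
    x: float = 0.3,
    side: str = AMPLIFIED,
    log_expr: bool = False,
) -> list[DosageScore]:
    """Dosage scores for a gene list.

    By default the score uses every sample; ``samples='altered'`` restricts
    to the gene's altered class at threshold ``x``.  ``log_expr`` scores
    log1p-transformed expression instead of raw FPKM.
    """
    out = []
    for gene in genes:
        if samples == "all":
            cols = list(cohort.scna.columns)
        elif samples == "altered":
            cols = sorted(partition_samples(cohort, gene, x).altered(side))
        else:
            raise ValueError("samples must be 'all' or 'altered'")
        sc = cohort.scna.loc[gene, cols].to_numpy(float)
        ex = cohort.expr.loc[gene, cols].to_numpy(float)
        if log_expr:
            ex = np.log1p(ex)
        s = dosage_score(sc, ex)
        s.gene = gene
        out.append(s)
    return out


def select_pdsg(
    stable_genes: Sequence[str],
    scores: Sequence[DosageScore],
    r_min: float = 0.3,
    p_max: float = 0.05,
) -> list[str]:
    """Intersect stable prognosis-sensitive genes with score-passing genes.

    The boundary r == ``r_min`` passes (>=); p must be strictly below
    ``p_max``.  Scores are also annotated in place with the stability and
    PDSG flags.
    """
    stable = set(stable_genes)
    selected = []
    for s in scores:
        s.is_stable_psg = s.gene in stable
        s.is_pdsg = bool(s.is_stable_psg and s.evaluable
                         and s.p < p_max and s.r >= r_min)
        if s.is_pdsg:
            selected.append(s.gene)
    return sorted(selected)


def cross_dataset_concordance(
    scores_a: Sequence[DosageScore],
    scores_b: Sequence[DosageScore],
) -> tuple[pd.DataFrame, dict]:
    """Compare dosage-effect scores of shared genes across two cohorts.

    Returns the per-gene paired table (gene, r_a, r_b) and a summary with
    the Pearson correlation of the two score vectors plus each vector's
    mean, variance and standard deviation (the magnitude of a reported
    spread statistic can be ambiguous, so both are given).
    """
    a = {s.gene: s.r for s in scores_a if s.evaluable}
    b = {s.gene: s.r for s in scores_b if s.evaluable}
    shared = sorted(set(a) & set(b))
    if len(shared) < 2:
        raise ValueError("need at least 2 genes shared between score sets")
    table = pd.DataFrame({
        "gene": shared,
        "r_dataset_a": [a[g] for g in shared],
        "r_dataset_b": [b[g] for g in shared],
    })
    ra = table["r_dataset_a"].to_numpy(float)
    rb = table["r_dataset_b"].to_numpy(float)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        conc = np.nan
    else:
        conc = float(stats.pearsonr(ra, rb)[0])
    summary = {
        "n_genes": len(shared),
        "mean_a": float(ra.mean()), "var_a": float(ra.var(ddof=1)),
        "sd_a": float(ra.std(ddof=1)),
        "mean_b": float(rb.mean()), "var_b": float(rb.var(ddof=1)),
        "sd_b": float(rb.std(ddof=1)),
        "concordance_r": conc,
    }
    return table, summary
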