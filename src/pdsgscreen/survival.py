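"""Survival screen: univariate Cox filter, Kaplan-Meier estimation,
log-rank testing, and the threshold-sweep stability rule (screen steps 3-4).

Step 3 fits a Cox proportional-hazards model with the continuous SCNA value
of each candidate gene as the single covariate and keeps genes with Wald
p < 0.05.  Step 4 then sweeps the SCNA threshold over a grid (default 0.1 to
0.5 in steps of 0.02, 21 values), re-partitions the samples at each
threshold, and runs a log-rank test of the altered class against the
non-altered class; a gene is a *stable* prognosis-sensitive gene when the
test is significant at strictly more than half of the grid thresholds
(more than 10 of the default 21).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort import OmicsCohort
from .partition import (AMPLIFIED, DELETED, MIN_ALTERED, SamplePartition,
                        ThresholdGrid, has_min_altered, make_grid,
                        partition_samples)

logger = logging.getLogger(__name__)


@dataclass
class CoxResult:
    gene: str
    beta: float
    se: float
    p: float
    n: int
    evaluable: bool = True
    converged: bool = True


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class StabilityProfile:
    """Log-rank p-values of one gene/side across the threshold grid.

    ``pvals`` is aligned to the grid with NaN where the gene is not
    evaluable (altered class below the minimum size, or no events).
    ``stable`` requires the significant count to strictly exceed
    ``stability_fraction`` times the *full* grid size.
    """

    gene: str
    side: str
    grid: ThresholdGrid
    pvals: np.ndarray
    n_significant: int
    n_evaluable: int
    stable: bool


def fit_cox_univariate(covariate, time, event) -> CoxResult:
    """Fit the Cox partial likelihood (Efron ties) for one continuous
    covariate; returns beta (log hazard ratio per unit), its SE and Wald p.

    Degenerate inputs (constant covariate, fewer than two events) yield a
    non-evaluable result rather than an exception; a failed Newton solve is
    returned flagged as non-converged.
    """
    z = np.asarray(covariate, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if not (z.size == t.size == e.size):
        raise ValueError("covariate, time and event must have equal length")
    if e.sum() < 2 or np.ptp(z) == 0:
        return CoxResult("", np.nan, np.nan, np.nan, int(z.size), evaluable=False)
    df = pd.DataFrame({"z": z, "time": t, "event": e})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return CoxResult("", np.nan, np.nan, np.nan, int(z.size),
                         evaluable=True, converged=False)
    s = cph.summary.loc["z"]
    return CoxResult("", float(s["coef"]), float(s["se(coef)"]), float(s["p"]),
                     int(z.size))


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator, reported at the event times."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if t.size == 0:
        raise ValueError("empty sample")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(float)
    if times.size == 0:
        return KMCurve(times=times, survival=np.array([]),
                       at_risk=np.array([], int), events=np.array([], int))
    surv = kmf.survival_function_at_times(times).to_numpy(float)
    return KMCurve(times=times, survival=surv,
                   at_risk=ev["at_risk"].to_numpy(int),
                   events=ev["observed"].to_numpy(int))


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value.

    With no events in either group the test is undefined and (nan, nan) is
    returned.
    """
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return (np.nan, np.nan)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _group_survival(cohort: OmicsCohort, samples: Iterable[str]):
    clin = cohort.clinical.loc[sorted(samples)]
    return clin["time"].to_numpy(float), clin["event"].to_numpy(int)


def is_stable(n_significant: int, n_grid: int,
              stability_fraction: float = 0.5) -> bool:
    """Stability rule: the significant-threshold count must *strictly*
    exceed ``stability_fraction`` of the full grid size (with the default
    21-point grid and fraction 0.5, at least 11 significant thresholds)."""
    return n_significant > stability_fraction * n_grid


def stability_sweep(
    cohort: OmicsCohort,
    gene: str,
    side: str = AMPLIFIED,
    grid: Optional[ThresholdGrid] = None,
    alpha: float = 0.05,
    min_alt: int = MIN_ALTERED,
    stability_fraction: float = 0.5,
) -> StabilityProfile:
    """Step 4: log-rank altered-vs-CNNS at every grid threshold.

    Thresholds where the altered class has fewer than ``min_alt`` samples,
    the non-altered class is empty, or no events occur are not evaluable
    and count as non-significant (the stability denominator is the full
    grid size).
    """
    if grid is None:
        grid = make_grid()
    pvals = np.full(len(grid), np.nan)
    for i, x in enumerate(grid):
        part = partition_samples(cohort, gene, x)
        if not has_min_altered(part, min_alt, side) or not part.cnns:
            continue
        ta, ea = _group_survival(cohort, part.altered(side))
        tb, eb = _group_survival(cohort, part.cnns)
        _, p = logrank_test(ta, ea, tb, eb)
        pvals[i] = p
    n_sig = int(np.nansum(pvals < alpha))
    n_eval = int(np.sum(~np.isnan(pvals)))
    stable = is_stable(n_sig, len(grid), stability_fraction)
    return StabilityProfile(gene=gene, side=side, grid=grid, pvals=pvals,
                            n_significant=n_sig, n_evaluable=n_eval,
                            stable=stable)


def km_table(cohort: OmicsCohort, gene: str, x: float = 0.3,
             side: str = AMPLIFIED) -> pd.DataFrame:
    """Kaplan-Meier curves of the altered vs non-altered class for one gene
    and threshold, as a long table (group, time, survival, at_risk, events)
    ready for plotting or export."""
    part = partition_samples(cohort, gene, x)
    rows = []
    for group, samples in ((side, part.altered(side)), ("cnns", part.cnns)):
        if not samples:
            continue
        t, e = _group_survival(cohort, samples)
        curve = km_estimate(t, e)
        for i in range(curve.times.size):
            rows.append({"gene": gene, "threshold": x, "group": group,
                         "time": curve.times[i],
                         "survival": curve.survival[i],
                         "at_risk": int(curve.at_risk[i]),
                         "events": int(curve.events[i])})
    return pd.DataFrame(rows, columns=["gene", "threshold", "group", "time",
                                       "survival", "at_risk", "events"])


def screen_survival(
    cohort: OmicsCohort,
    candidates: Sequence[tuple[str, str]],
    grid: Optional[ThresholdGrid] = None,
    cox_p: float = 0.05,
    alpha: float = 0.05,
    min_alt: int = MIN_ALTERED,
    stability_fraction: float = 0.5,
    covariate_mode: str = "continuous",
    x_binary: float = 0.3,
) -> tuple[list[CoxResult], list[StabilityProfile]]:
    """Steps 3-4 composed over a candidate (gene, side) list.

    The Cox filter (Wald p < ``cox_p``) runs first on the per-gene SCNA
    covariate — continuous by default, or an altered-class indicator at
    ``x_binary`` when ``covariate_mode='binary'`` — and the stability sweep
    runs only for Cox-passing candidates.
    """
    if grid is None:
        grid = make_grid()
    if covariate_mode not in ("continuous", "binary"):
        raise ValueError("covariate_mode must be 'continuous' or 'binary'")
    time, event = cohort.survival_arrays()
    sample_order = list(cohort.scna.columns)

    cox_results: dict[str, CoxResult] = {}
    for gene in dict.fromkeys(g for g, _ in candidates):
        if covariate_mode == "continuous":
            z = cohort.scna.loc[gene].to_numpy(float)
        else:
            part = partition_samples(cohort, gene, x_binary)
            altered = part.cnas | part.cnds
            z = np.array([1.0 if s in altered else 0.0 for s in sample_order])
        res = fit_cox_univariate(z, time, event)
        res.gene = gene
        cox_results[gene] = res

    profiles = []
    for gene, side in candidates:
        res = cox_results[gene]
        if res.evaluable and res.converged and res.p < cox_p:
            profiles.append(stability_sweep(
                cohort, gene, side, grid=grid, alpha=alpha, min_alt=min_alt,
                stability_fraction=stability_fraction))
    return list(cox_results.values()), profiles
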