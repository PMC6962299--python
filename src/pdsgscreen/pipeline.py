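"""End-to-end orchestration of the five-stage PDSG screen.

Stage order is fixed: (1-2) dosage-concordant differential expression,
(3) univariate Cox filter on the continuous SCNA covariate, (4) log-rank
stability sweep over the threshold grid, (5) dosage-effect score and PDSG
selection.  Each stage consumes only the survivors of the previous one,
and a run manifest records the configuration, input digests and survivor
counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import OmicsCohort, format_value, write_table
from .coexpression import (CoAlterationResult, CoexNetwork, DiffCoexEdge,
                           build_network, co_alteration_matrix,
                           diff_coex_edges, write_graphml, write_sif)
from .de import DEResult, screen_dosage_de
from .dosage import DosageScore, score_genes, select_pdsg
from .partition import ThresholdGrid, make_grid
from .survival import CoxResult, StabilityProfile, screen_survival

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All screen thresholds; the defaults are the protocol's stated values."""

    x_primary: float = 0.3
    min_alt: int = 10
    p_max: float = 0.01
    fdr_max: float = 0.1
    fc_min: float = 1.2
    cox_p: float = 0.05
    grid_start: float = 0.1
    grid_stop: float = 0.5
    grid_step: float = 0.02
    alpha: float = 0.05
    stability_fraction: float = 0.5
    r_min: float = 0.3
    dosage_p: float = 0.05
    coex_hi: float = 0.5
    coex_lo: float = 0.1
    coex_min_group: int = 10
    sign_mode: str = "absolute"
    covariate_mode: str = "continuous"

    def __post_init__(self):
        for name in ("x_primary", "p_max", "fdr_max", "fc_min", "cox_p",
                     "alpha", "stability_fraction", "r_min", "dosage_p",
                     "coex_hi", "coex_lo", "grid_start", "grid_stop",
                     "grid_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.grid()  # validates the grid parameters

    def grid(self) -> ThresholdGrid:
        return make_grid(self.grid_start, self.grid_stop, self.grid_step)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class ScreenResult:
    de_results: list[DEResult]
    candidates: list[tuple[str, str]]
    cox_results: list[CoxResult]
    stability_profiles: list[StabilityProfile]
    dosage_scores: list[DosageScore]
    pdsgs: list[str]
    pdsg_sides: dict[str, str]
    records: pd.DataFrame
    manifest: dict


def _screen_records(result: "ScreenResult") -> pd.DataFrame:
    cox_by_gene = {c.gene: c for c in result.cox_results}
    stab = {(p.gene, p.side): p for p in result.stability_profiles}
    scores = {s.gene: s for s in result.dosage_scores}
    rows = []
    for r in result.de_results:
        c = cox_by_gene.get(r.gene)
        sp = stab.get((r.gene, r.side))
        sc = scores.get(r.gene)
        pass_cox = bool(c is not None and c.evaluable and c.converged
                        and c.p < result.manifest["config"]["cox_p"])
        rows.append({
            "gene": r.gene, "side": r.side,
            "n_alt": r.n_alt, "de_p": r.p, "de_fdr": r.fdr, "de_fc": r.fc,
            "pass_de": r.concordant,
            "cox_beta": c.beta if c else np.nan,
            "cox_p": c.p if c else np.nan,
            "pass_cox": r.concordant and pass_cox,
            "n_significant": sp.n_significant if sp else np.nan,
            "pass_stability": bool(sp and sp.stable),
            "dosage_r": sc.r if sc else np.nan,
            "dosage_p": sc.p if sc else np.nan,
            "is_pdsg": bool(sc and sc.is_pdsg and sp and sp.stable),
        })
    return pd.DataFrame(rows)


def run_screen(cohort: OmicsCohort,
               config: PipelineConfig = PipelineConfig()) -> ScreenResult:
    """Execute stages 1-5 on an aligned cohort and return all stage tables.

    A stage with zero survivors short-circuits the remaining stages cleanly;
    the manifest records where attrition occurred.
    """
    grid = config.grid()

    de_results = screen_dosage_de(
        cohort, x=config.x_primary, min_alt=config.min_alt,
        p_max=config.p_max, fdr_max=config.fdr_max, fc_min=config.fc_min)
    candidates = [(r.gene, r.side) for r in de_results if r.concordant]
    logger.info("stage 1-2: %d/%d tests concordant", len(candidates),
                len(de_results))

    cox_results: list[CoxResult] = []
    profiles: list[StabilityProfile] = []
    if candidates:
        cox_results, profiles = screen_survival(
            cohort, candidates, grid=grid, cox_p=config.cox_p,
            alpha=config.alpha, min_alt=config.min_alt,
            stability_fraction=config.stability_fraction,
            covariate_mode=config.covariate_mode, x_binary=config.x_primary)

    stable_pairs = [(p.gene, p.side) for p in profiles if p.stable]
    stable_genes = sorted({g for g, _ in stable_pairs})
    scores = score_genes(cohort, stable_genes) if stable_genes else []
    pdsgs = select_pdsg(stable_genes, scores, r_min=config.r_min,
                        p_max=config.dosage_p)
    pdsg_sides = {g: s for g, s in stable_pairs if g in set(pdsgs)}

    n_cox_pass = sum(1 for c in cox_results
                     if c.evaluable and c.converged and c.p < config.cox_p)
    manifest = {
        "tool": "pdsgscreen",
        "version": __version__,
        "config": config.to_dict(),
        "input_hashes": cohort.content_hashes(),
        "n_samples": len(cohort.samples),
        "stage_survivors": {
            "genes_tested": len({r.gene for r in de_results}),
            "de_concordant": len({g for g, _ in candidates}),
            "cox_pass": n_cox_pass,
            "stable": len(stable_genes),
            "pdsg": len(pdsgs),
        },
    }
    result = ScreenResult(
        de_results=de_results, candidates=candidates,
        cox_results=cox_results, stability_profiles=profiles,
        dosage_scores=scores, pdsgs=pdsgs, pdsg_sides=pdsg_sides,
        records=pd.DataFrame(), manifest=manifest)
    result.records = _screen_records(result)
    return result


@dataclass
class NetworkResult:
    edges: list[DiffCoexEdge]
    network: CoexNetwork
    co_alteration: Optional[CoAlterationResult]


def run_network(cohort: OmicsCohort, pdsgs: Sequence[str],
                config: PipelineConfig = PipelineConfig(),
                sides: Optional[Mapping[str, str]] = None
                ) -> Optional[NetworkResult]:
    """Differential co-expression network and SCNA co-alteration matrix for
    a PDSG list; returns None (with a message) when the list is empty."""
    if not pdsgs:
        logger.info("run_network: empty PDSG list, nothing to do")
        return None
    edges = diff_coex_edges(
        cohort, list(pdsgs), x=config.x_primary, hi=config.coex_hi,
        lo=config.coex_lo, min_group=config.coex_min_group, sides=sides,
        sign_mode=config.sign_mode)
    network = build_network(edges)
    coalt = co_alteration_matrix(cohort, pdsgs) if len(pdsgs) >= 2 else None
    return NetworkResult(edges=edges, network=network, co_alteration=coalt)


# ---------------------------------------------------------------------------
# run-directory output (fixed filenames, byte-deterministic)

def _stability_table(profiles: Sequence[StabilityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"gene": p.gene, "side": p.side}
        for x, pv in zip(p.grid, p.pvals):
            row[f"p_{x:g}"] = pv
        row.update(n_significant=p.n_significant, n_evaluable=p.n_evaluable,
                   stable=p.stable)
        rows.append(row)
    return pd.DataFrame(rows)


def write_screen_outputs(result: ScreenResult, outdir: str | Path) -> None:
    """Write de.tsv, cox.tsv, stability.tsv, dosage.tsv, pdsg.txt,
    screen_records.tsv and manifest.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame([dataclasses.asdict(r) for r in result.de_results],
                             columns=["gene", "side", "n_alt", "n_non",
                                      "statistic", "p", "fdr", "fc",
                                      "concordant"]),
                outdir / "de.tsv")
    write_table(pd.DataFrame(
        [{"gene": c.gene, "beta": c.beta, "se": c.se, "p": c.p, "n": c.n,
          "evaluable": c.evaluable, "converged": c.converged}
         for c in result.cox_results],
        columns=["gene", "beta", "se", "p", "n", "evaluable", "converged"]),
        outdir / "cox.tsv")
    write_table(_stability_table(result.stability_profiles),
                outdir / "stability.tsv")
    write_table(pd.DataFrame(
        [{"gene": s.gene, "r": s.r, "p": s.p, "n": s.n,
          "is_stable_psg": s.is_stable_psg, "is_pdsg": s.is_pdsg}
         for s in result.dosage_scores],
        columns=["gene", "r", "p", "n", "is_stable_psg", "is_pdsg"]),
        outdir / "dosage.tsv")
    write_table(result.records, outdir / "screen_records.tsv")
    (outdir / "pdsg.txt").write_text(
        "\n".join(result.pdsgs) + ("\n" if result.pdsgs else ""))
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")


def write_network_outputs(result: NetworkResult, outdir: str | Path) -> None:
    """Write edges.tsv, network.sif, network.graphml and coalteration.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame([dataclasses.asdict(e) for e in result.edges],
                             columns=["pdsg", "partner", "r_alt", "r_non",
                                      "active_in"]),
                outdir / "edges.tsv")
    write_sif(result.network, outdir / "network.sif")
    write_graphml(result.network, outdir / "network.graphml")
    if result.co_alteration is not None:
        mat = result.co_alteration.matrix
        lines = ["\t".join(["gene", *mat.columns])]
        for gene, row in zip(mat.index, mat.to_numpy()):
            lines.append(gene + "\t" + "\t".join(format_value(v) for v in row))
        (outdir / "coalteration.tsv").write_text("\n".join(lines) + "\n")
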