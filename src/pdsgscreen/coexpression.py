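"""Differential co-expression network around PDSGs, and SCNA co-alteration.

A gene pair is differentially co-expressed when its expression correlation
is strong (|r| > 0.5 by default) in one sample class of the PDSG's
copy-number partition and absent (|r| < 0.1) in the other; such pairs are
interpreted as alteration-dependent regulatory rewiring.  Co-alteration of
a gene set is the pairwise Pearson correlation of SCNA profiles — genes on
one amplified segment correlate near 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import OmicsCohort
from .partition import AMPLIFIED, DELETED, partition_samples

logger = logging.getLogger(__name__)

ACTIVE_IN_ALTERATION = "alteration"
ACTIVE_IN_NON_ALTERATION = "non_alteration"


@dataclass(frozen=True)
class DiffCoexEdge:
    pdsg: str
    partner: str
    r_alt: float
    r_non: float
    active_in: str


def _row_correlations(mat: np.ndarray, row: np.ndarray) -> np.ndarray:
    """Pearson r of one vector against every row of a matrix (same columns).

    Rows (or the reference vector) with zero variance yield NaN.
    """
    row_c = row - row.mean()
    mat_c = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((mat_c ** 2).sum(axis=1) * (row_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mat_c @ row_c) / denom
    return np.where(denom > 0, r, np.nan)


def _classify(r_alt: float, r_non: float, hi: float, lo: float,
              sign_mode: str) -> Optional[str]:
    if sign_mode == "absolute":
        va, vn = abs(r_alt), abs(r_non)
    elif sign_mode == "signed":
        va, vn = r_alt, r_non
    else:
        raise ValueError("sign_mode must be 'absolute' or 'signed'")
    if np.isnan(va) or np.isnan(vn):
        return None
    if va > hi and vn < lo:
        return ACTIVE_IN_ALTERATION
    if vn > hi and va < lo:
        return ACTIVE_IN_NON_ALTERATION
    return None


def diff_coex_edges(
    cohort: OmicsCohort,
    pdsgs: Sequence[str],
    x: float = 0.3,
    hi: float = 0.5,
    lo: float = 0.1,
    min_group: int = 10,
    sides: Optional[Mapping[str, str]] = None,
    sign_mode: str = "absolute",
) -> list[DiffCoexEdge]:
    """Screen every PDSG against all other expressed genes for differential
    co-expression between its altered class and its non-altered class.

    Samples are partitioned per PDSG at threshold ``x``; the altered class is
    CNAS for amplified PDSGs and CNDS for deleted ones (``sides`` maps gene
    to side, default amplified).  An edge fires when the correlation exceeds
    ``hi`` in one class and stays below ``lo`` in the other; by default both
    thresholds apply to |r| (a signed mode is available).  PDSG-PDSG pairs
    are emitted once; PDSGs whose classes are smaller than ``min_group``
    are skipped with a logged count.
    """
    sides = dict(sides or {})
    for g in pdsgs:
        if g not in cohort.expr.index:
            raise KeyError(f"PDSG {g!r} not in expression matrix")
        if g not in cohort.scna.index:
            raise KeyError(f"PDSG {g!r} not in SCNA matrix")
    sample_pos = {s: i for i, s in enumerate(cohort.expr.columns)}
    expr = cohort.expr.to_numpy(float)
    genes = list(cohort.expr.index)
    gene_row = {g: i for i, g in enumerate(genes)}
    pdsg_set = set(pdsgs)

    edges: list[DiffCoexEdge] = []
    seen_pairs: set[frozenset[str]] = set()
    n_skipped = 0
    for pdsg in pdsgs:
        part = partition_samples(cohort, pdsg, x)
        side = sides.get(pdsg, AMPLIFIED)
        alt = sorted(part.altered(side))
        non = sorted(part.cnns)
        if len(alt) < min_group or len(non) < min_group:
            n_skipped += 1
            continue
        alt_idx = [sample_pos[s] for s in alt]
        non_idx = [sample_pos[s] for s in non]
        prow = gene_row[pdsg]
        r_alt = _row_correlations(expr[:, alt_idx], expr[prow, alt_idx])
        r_non = _row_correlations(expr[:, non_idx], expr[prow, non_idx])
        for gi, partner in enumerate(genes):
            if partner == pdsg:
                continue
            if partner in pdsg_set:
                pair = frozenset((pdsg, partner))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
            active = _classify(r_alt[gi], r_non[gi], hi, lo, sign_mode)
            if active is not None:
                edges.append(DiffCoexEdge(pdsg=pdsg, partner=partner,
                                          r_alt=float(r_alt[gi]),
                                          r_non=float(r_non[gi]),
                                          active_in=active))
    if n_skipped:
        logger.info("diff_coex_edges: skipped %d PDSGs with a class below "
                    "%d samples", n_skipped, min_group)
    edges.sort(key=lambda e: (e.pdsg, e.partner))
    return edges


@dataclass
class CoexNetwork:
    """Differential co-expression graph with node roles and degree map."""

    graph: nx.Graph
    edges: list[DiffCoexEdge]

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def edge_counts_by_class(self) -> dict[str, int]:
        counts = {ACTIVE_IN_ALTERATION: 0, ACTIVE_IN_NON_ALTERATION: 0}
        for e in self.edges:
            counts[e.active_in] += 1
        return counts


def build_network(edges: Sequence[DiffCoexEdge],
                  annotations: Optional[Mapping[str, Sequence[str]]] = None
                  ) -> CoexNetwork:
    """Assemble the edge list into a graph with role labels.

    ``annotations`` maps a label (e.g. ``driver``, ``tsg``) to a gene list;
    matching nodes get the label as a boolean attribute.
    """
    g = nx.Graph()
    for e in edges:
        if e.pdsg == e.partner:
            continue
        g.add_node(e.pdsg, role="pdsg")
        if g.nodes.get(e.partner, {}).get("role") != "pdsg":
            g.add_node(e.partner, role="partner")
        g.add_edge(e.pdsg, e.partner, r_alt=e.r_alt, r_non=e.r_non,
                   active_in=e.active_in)
    for label, gene_list in (annotations or {}).items():
        for gene in gene_list:
            if gene in g:
                g.nodes[gene][label] = True
    return CoexNetwork(graph=g, edges=list(edges))


@dataclass
class CoAlterationResult:
    matrix: pd.DataFrame
    mean_offdiag: float
    excluded: list[str]


def co_alteration_matrix(cohort: OmicsCohort,
                         genes: Sequence[str]) -> CoAlterationResult:
    """Pairwise Pearson correlation of SCNA profiles for a gene set.

    Genes with a constant SCNA row (undefined correlation) are flagged and
    excluded from the off-diagonal mean; the matrix keeps NaN entries for
    them.  The diagonal is exactly 1.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = cohort.scna.loc[list(genes)]
    constant = [g for g in genes if np.ptp(sub.loc[g].to_numpy(float)) == 0]
    mat = sub.T.corr(method="pearson")
    np.fill_diagonal(mat.values, 1.0)
    ok = [g for g in genes if g not in set(constant)]
    vals = mat.loc[ok, ok].to_numpy(float)
    off = vals[~np.eye(len(ok), dtype=bool)]
    mean_off = float(off.mean()) if off.size else np.nan
    return CoAlterationResult(matrix=mat, mean_offdiag=mean_off,
                              excluded=constant)


def write_sif(network: CoexNetwork, path: str | Path) -> None:
    """Cytoscape SIF export: one ``nodeA <interaction> nodeB`` line per edge."""
    lines = []
    for a, b, data in sorted(network.graph.edges(data=True)):
        lines.append(f"{a}\tcoexpressed_{data['active_in']}\t{b}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(network: CoexNetwork, path: str | Path) -> None:
    """GraphML export with node role attributes (Cytoscape-loadable)."""
    nx.write_graphml(network.graph, str(path))
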