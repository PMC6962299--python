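"""Shared fixtures: small hand-built cohorts and TSV writers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pdsgscreen import OmicsCohort


def build_cohort(scna: np.ndarray, expr: np.ndarray, time, event,
                 genes=None, samples=None) -> OmicsCohort:
    """Assemble an OmicsCohort from raw arrays with auto-generated ids."""
    scna = np.atleast_2d(np.asarray(scna, float))
    expr = np.atleast_2d(np.asarray(expr, float))
    n_genes, n_samples = scna.shape
    genes = genes or [f"G{i:04d}" for i in range(n_genes)]
    samples = samples or [f"S{i:04d}" for i in range(n_samples)]
    return OmicsCohort(
        scna=pd.DataFrame(scna, index=genes, columns=samples),
        expr=pd.DataFrame(expr, index=genes, columns=samples),
        clinical=pd.DataFrame({"time": np.asarray(time, float),
                               "event": np.asarray(event, int)},
                              index=samples).rename_axis("sample"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_cohort():
    """3 genes x 4 samples, fully aligned."""
    scna = [[0.5, -0.5, 0.0, 0.4], [0.0, 0.1, -0.2, 0.0], [1.0, 1.2, 0.9, 1.1]]
    expr = [[5.0, 1.0, 2.0, 4.0], [3.0, 3.0, 3.0, 3.0], [9.0, 10.0, 8.0, 9.5]]
    return build_cohort(scna, expr, time=[10, 20, 30, 40], event=[1, 0, 1, 1])


def write_matrix_tsv(path, genes, samples, values, gistic=False):
    """Write a genes-x-samples matrix in either the plain or GISTIC dialect."""
    values = np.asarray(values, float)
    lines = []
    if gistic:
        lines.append("\t".join(["Gene Symbol", "Locus ID", "Cytoband",
                                *samples]))
        for i, g in enumerate(genes):
            lines.append("\t".join([g, str(1000 + i), f"3q{13 + i}",
                                    *(f"{v:.10g}" for v in values[i])]))
    else:
        lines.append("\t".join(["gene", *samples]))
        for i, g in enumerate(genes):
            lines.append("\t".join([g, *(f"{v:.10g}" for v in values[i])]))
    path.write_text("\n".join(lines) + "\n")


def write_clinical_tsv(path, samples, times, events):
    lines = ["sample\ttime\tevent"]
    for s, t, e in zip(samples, times, events):
        lines.append(f"{s}\t{t}\t{e}")
    path.write_text("\n".join(lines) + "\n")
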