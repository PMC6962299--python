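"""Cohort I/O: aligned copy-number / expression / clinical containers.

A cohort bundles a gene-level somatic copy-number alteration (SCNA) matrix
(continuous GISTIC2-style values, genes x samples), an expression matrix on
the FPKM scale, and a clinical table with overall-survival time and event
indicator.  All three are aligned on a common sample set at read time.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Leading metadata columns of a GISTIC "all_data_by_genes"-style table.
_GISTIC_META_COLUMNS = ("Gene Symbol", "Locus ID", "Cytoband")


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort inputs."""


@dataclass
class OmicsCohort:
    """Aligned multi-omics cohort.

    Attributes
    ----------
    scna : pd.DataFrame
        Continuous gene-level SCNA values, genes as rows, samples as columns.
    expr : pd.DataFrame
        Non-negative expression values (FPKM scale), genes x samples.
    clinical : pd.DataFrame
        Indexed by sample id with columns ``time`` (survival time, any unit;
        only relative ordering matters) and ``event`` (1 = death, 0 =
        censored).
    loci : pd.DataFrame, optional
        Gene loci with columns chromosome/start/end/cytoband, 1-based
        inclusive coordinates.
    """

    scna: pd.DataFrame
    expr: pd.DataFrame
    clinical: pd.DataFrame
    loci: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        samples = set(self.clinical.index)
        if set(self.scna.columns) != samples or set(self.expr.columns) != samples:
            raise CohortError("scna, expr and clinical must share one sample set")
        for name, mat in (("scna", self.scna), ("expr", self.expr)):
            if mat.index.duplicated().any():
                dups = mat.index[mat.index.duplicated()].unique().tolist()
                raise CohortError(f"duplicate gene ids in {name}: {dups[:5]}")
            if mat.isna().any().any():
                raise CohortError(f"missing values in {name} matrix are not permitted")
        if (np.asarray(self.expr.values) < 0).any():
            raise CohortError("expression values must be non-negative")
        if (self.clinical["time"] < 0).any():
            raise CohortError("survival times must be >= 0")
        if not self.clinical["event"].isin((0, 1)).all():
            raise CohortError("event indicator must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def genes(self) -> list[str]:
        """Genes present in both matrices (screen universe)."""
        return [g for g in self.scna.index if g in set(self.expr.index)]

    def survival_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(time, event) aligned to the matrix column order."""
        clin = self.clinical.loc[list(self.scna.columns)]
        return clin["time"].to_numpy(float), clin["event"].to_numpy(int)

    def content_hashes(self) -> dict[str, str]:
        """Stable sha256 digests of the three core tables."""
        out = {}
        for name, df in (("scna", self.scna), ("expr", self.expr),
                         ("clinical", self.clinical)):
            canon = df.sort_index().sort_index(axis=1)
            out[name] = hashlib.sha256(
                canon.to_csv(sep="\t", float_format="%.10g").encode()
            ).hexdigest()
        return out


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-samples TSV, auto-detecting the GISTIC dialect.

    The GISTIC gene-level dialect carries "Gene Symbol", "Locus ID" and
    "Cytoband" as its first three columns; the two metadata columns are
    dropped and the gene symbol becomes the index.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise CohortError(f"{path}: expected gene column plus sample columns")
    cols = list(df.columns)
    if tuple(cols[:3]) == _GISTIC_META_COLUMNS:
        df = df.drop(columns=list(_GISTIC_META_COLUMNS[1:]))
        df = df.rename(columns={_GISTIC_META_COLUMNS[0]: "gene"})
    else:
        df = df.rename(columns={cols[0]: "gene"})
    df = df.set_index("gene")
    df.index.name = None
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise CohortError(f"{path}: duplicate gene ids {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise CohortError(
            f"{path}: non-numeric value {df.iloc[r, c]!r} at "
            f"gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise CohortError(
            f"{path}: missing value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return numeric.astype(float)


def _read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required.issubset(df.columns):
        raise CohortError(f"{path}: clinical table needs columns {sorted(required)}")
    df = df.set_index("sample")[["time", "event"]]
    return df


def read_loci(path: str | Path) -> pd.DataFrame:
    """Read a BED-like loci table (chrom, start, end, gene[, cytoband]).

    BED coordinates are 0-based half-open on disk and converted to 1-based
    inclusive here.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise CohortError(f"{path}: loci table needs >= 4 columns")
    names = ["chromosome", "start", "end", "gene"]
    if df.shape[1] >= 5:
        names.append("cytoband")
    df = df.iloc[:, : len(names)]
    df.columns = names
    if "cytoband" not in df.columns:
        df["cytoband"] = ""
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise CohortError(f"{path}: locus with start > end")
    return df.set_index("gene")


def read_cohort(
    scna_path: str | Path,
    expr_path: str | Path,
    clinical_path: str | Path,
    loci_path: str | Path | None = None,
) -> OmicsCohort:
    """Read and sample-align the three core tables.

    The cohort is restricted to the intersection of sample ids across the
    SCNA matrix, the expression matrix and the clinical table, in sorted
    sample order.  Counts of dropped samples are logged.
    """
    scna = _read_matrix(scna_path)
    expr = _read_matrix(expr_path)
    clinical = _read_clinical(clinical_path)

    common = sorted(set(scna.columns) & set(expr.columns) & set(clinical.index))
    if not common:
        raise CohortError(
            "no samples shared between "
            f"{scna_path}, {expr_path} and {clinical_path}"
        )
    for name, have in (("scna", scna.columns), ("expr", expr.columns),
                       ("clinical", clinical.index)):
        dropped = len(have) - len(common)
        if dropped:
            logger.info("read_cohort: dropped %d %s samples outside intersection",
                        dropped, name)
    loci = read_loci(loci_path) if loci_path is not None else None
    return OmicsCohort(
        scna=scna[common], expr=expr[common], clinical=clinical.loc[common],
        loci=loci,
    )


def filter_expressed(cohort: OmicsCohort, zero_fraction: float = 0.8) -> OmicsCohort:
    """Drop genes with zero expression in strictly more than ``zero_fraction``
    of samples; the SCNA matrix is restricted to the surviving genes it shares.

    A gene zero in exactly ``zero_fraction`` of samples is retained (the
    boundary is not strict).
    """
    if not 0 <= zero_fraction <= 1:
        raise ValueError("zero_fraction must be in [0, 1]")
    frac_zero = (cohort.expr == 0).mean(axis=1)
    keep = cohort.expr.index[frac_zero <= zero_fraction]
    if len(keep) == 0:
        raise CohortError("zero-expression filter removed every gene")
    n_dropped = cohort.expr.shape[0] - len(keep)
    if n_dropped:
        logger.info("filter_expressed: removed %d genes with > %.0f%% zeros",
                    n_dropped, 100 * zero_fraction)
    scna_keep = [g for g in cohort.scna.index if g in set(keep)]
    return OmicsCohort(
        scna=cohort.scna.loc[scna_keep],
        expr=cohort.expr.loc[keep],
        clinical=cohort.clinical,
        loci=cohort.loci,
    )


# ---------------------------------------------------------------------------
# deterministic table output

#: column priority used for the deterministic sort of result tables
_SORT_PRIORITY = ("gene", "pdsg", "partner", "side", "threshold", "sample")


def format_value(v) -> str:
    """Fixed formatting: 6 significant digits, scientific below 1e-4."""
    if isinstance(v, (bool, np.bool_)):
        return "True" if v else "False"
    if v is None:
        return "NA"
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "NA"
        return f"{float(v):.6g}"
    return str(v)


def write_table(records: pd.DataFrame | Iterable, path: str | Path) -> None:
    """Write a result table as a TSV with a deterministic row order and
    fixed float formatting, so identical inputs give byte-identical files."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ if hasattr(r, "__dict__") else r
                           for r in records])
    path = Path(path)
    if df.empty:
        cols = list(df.columns)
        path.write_text("\t".join(map(str, cols)) + "\n")
        return
    sort_cols = [c for c in _SORT_PRIORITY if c in df.columns]
    sort_cols += [c for c in df.columns
                  if c not in sort_cols and df[c].map(np.isscalar).all()]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    lines = ["\t".join(map(str, df.columns))]
    for row in df.itertuples(index=False):
        lines.append("\t".join(format_value(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def write_cohort(cohort: OmicsCohort, outdir: str | Path) -> dict[str, Path]:
    """Write scna.tsv / expr.tsv / clinical.tsv into ``outdir`` with the
    deterministic formatting used by all writers; round-trips through
    :func:`read_cohort`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("scna", cohort.scna), ("expr", cohort.expr)):
        path = outdir / f"{name}.tsv"
        lines = ["\t".join(["gene", *map(str, df.columns)])]
        for gene, row in zip(df.index, df.to_numpy()):
            lines.append(gene + "\t" + "\t".join(format_value(v) for v in row))
        path.write_text("\n".join(lines) + "\n")
        paths[name] = path
    path = outdir / "clinical.tsv"
    lines = ["sample\ttime\tevent"]
    for sample, row in cohort.clinical.iterrows():
        lines.append(f"{sample}\t{format_value(float(row['time']))}\t"
                     f"{int(row['event'])}")
    path.write_text("\n".join(lines) + "\n")
    paths["clinical"] = path
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
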