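"""Per-gene sample partitioning at an SCNA threshold, and the threshold grid.

For a gene and a positive threshold ``x``, samples split into three disjoint
classes: copy-number amplified (CNAS, SCNA >= x), deleted (CNDS, SCNA <= -x)
and non-altered (CNNS, |SCNA| < x).  Samples landing exactly on the
threshold belong to the altered class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import OmicsCohort

AMPLIFIED = "amplified"
DELETED = "deleted"

#: default minimum altered-class size for a gene to be evaluable
MIN_ALTERED = 10


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing arithmetic grid of positive SCNA thresholds."""

    values: tuple[float, ...]

    def __post_init__(self):
        v = self.values
        if not v or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("grid must be non-empty and strictly increasing")
        if v[0] <= 0:
            raise ValueError("thresholds must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def make_grid(start: float = 0.1, stop: float = 0.5, step: float = 0.02) -> ThresholdGrid:
    """Inclusive arithmetic grid ``start, start+step, ..., stop``.

    Endpoint inclusion is robust to floating-point drift (tolerance step/2);
    the defaults give the 21-point grid 0.10, 0.12, ..., 0.50.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0 < start <= stop:
        raise ValueError("need 0 < start <= stop")
    n = int(np.floor((stop - start) / step + 0.5)) + 1
    values = tuple(round(start + k * step, 10) for k in range(n))
    return ThresholdGrid(values=values)


@dataclass(frozen=True)
class SamplePartition:
    """Disjoint CNAS / CNDS / CNNS sample sets for one gene at threshold x."""

    gene: str
    x: float
    cnas: frozenset[str]
    cnds: frozenset[str]
    cnns: frozenset[str]

    def altered(self, side: str) -> frozenset[str]:
        if side == AMPLIFIED:
            return self.cnas
        if side == DELETED:
            return self.cnds
        raise ValueError(f"side must be {AMPLIFIED!r} or {DELETED!r}, got {side!r}")


def partition_samples(cohort: OmicsCohort, gene: str, x: float) -> SamplePartition:
    """Partition the cohort's samples for one gene at threshold ``x > 0``.

    Boundary convention: SCNA == x goes to CNAS, SCNA == -x to CNDS.
    """
    if x <= 0:
        raise ValueError("threshold x must be positive")
    if gene not in cohort.scna.index:
        raise KeyError(f"gene {gene!r} not in SCNA matrix")
    values = cohort.scna.loc[gene]
    samples = np.asarray(values.index)
    v = values.to_numpy(float)
    cnas = frozenset(samples[v >= x])
    cnds = frozenset(samples[v <= -x])
    cnns = frozenset(samples[np.abs(v) < x])
    return SamplePartition(gene=gene, x=x, cnas=cnas, cnds=cnds, cnns=cnns)


def has_min_altered(partition: SamplePartition, min_n: int = MIN_ALTERED,
                    side: str = AMPLIFIED) -> bool:
    """True iff the requested altered class holds at least ``min_n`` samples."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    return len(partition.altered(side)) >= min_n
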