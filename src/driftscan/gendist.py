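"""Reynolds coancestry distances between populations, with Phylip export.

The distance is the frequency-based Reynolds-Weir-Cockerham coancestry
measure as computed by Phylip's ``gendist``: over loci l with allele
frequency vectors,

    D = sum_l sum_a (p1_la - p2_la)^2 / (2 * sum_l (1 - sum_a p1_la p2_la))

which for a single biallelic locus reduces to
``(p1 - p2)^2 / (1 - p1*p2 - q1*q2)``. No small-sample correction is
applied (the plain frequency form); distances are built from population
allele frequencies only, so groups known only through published frequencies
can be placed alongside genotype-derived groups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import InputError
from .popfreq import FrequencyTable

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "reynolds_pair",
    "distance_matrix",
    "write_phylip_matrix",
    "read_phylip_matrix",
    "write_long_tsv",
]


@dataclass
class DistanceMatrix:
    """Symmetric population x population distance matrix."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.isfinite(self.d).all():
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.diag(self.d).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


def reynolds_pair(p1: np.ndarray, p2: np.ndarray) -> float:
    """Reynolds distance between two populations from per-locus REF frequencies."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1 or p1.size < 1:
        raise InputError("frequency vectors must be 1-D, equal length >= 1")
    if ((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)).any():
        raise InputError("frequencies must lie in [0, 1]")
    q1, q2 = 1.0 - p1, 1.0 - p2
    num = ((p1 - p2) ** 2 + (q1 - q2) ** 2).sum()
    den = 2.0 * (1.0 - p1 * p2 - q1 * q2).sum()
    if den == 0.0:
        # both populations fixed for the same allele at every locus
        log.warning("reynolds_pair: degenerate pair (identically fixed); distance 0")
        return 0.0
    return float(num / den)


def distance_matrix(ft: FrequencyTable, loci: list[str]) -> DistanceMatrix:
    """All-pairs Reynolds distances over the table's groups at ``loci``."""
    labels = ft.groups
    vecs = {g: ft.ref_freq_vector(g, loci) for g in labels}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = reynolds_pair(vecs[labels[i]], vecs[labels[j]])
    return DistanceMatrix(labels=labels, d=d)


_PHYLIP_NAME_WIDTH = 10


def _sanitize(label: str) -> str:
    return re.sub(r"\s", "_", label)


def write_phylip_matrix(
    dm: DistanceMatrix, path: str | Path, relaxed: bool = False
) -> Path:
    """Write a square Phylip distance matrix (names padded to 10 chars).

    Labels longer than 10 characters raise unless ``relaxed`` is set, in
    which case they are truncated with a warning.
    """
    path = Path(path)
    if not np.isfinite(dm.d).all():
        raise InputError("cannot write non-finite distances")
    names = []
    for lab in dm.labels:
        s = _sanitize(lab)
        if len(s) > _PHYLIP_NAME_WIDTH:
            if not relaxed:
                raise InputError(
                    f"label {lab!r} exceeds {_PHYLIP_NAME_WIDTH} characters "
                    "(use relaxed=True to truncate)"
                )
            log.warning("write_phylip_matrix: truncating label %r", lab)
            s = s[:_PHYLIP_NAME_WIDTH]
        names.append(s.ljust(_PHYLIP_NAME_WIDTH))
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for name, row in zip(names, dm.d):
            fh.write(name + " " + " ".join(f"{x:.9f}" for x in row) + "\n")
    return path


def read_phylip_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square Phylip distance matrix written by :func:`write_phylip_matrix`."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        name = line[:_PHYLIP_NAME_WIDTH].strip()
        values = [float(x) for x in line[_PHYLIP_NAME_WIDTH:].split()]
        labels.append(name)
        rows.append(values)
    d = np.asarray(rows)
    d = 0.5 * (d + d.T)  # absorb printing round-off
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=d)


def write_long_tsv(dm: DistanceMatrix, path: str | Path) -> Path:
    """Long-format export: one row per unordered population pair."""
    rows = [
        dict(pop1=dm.labels[i], pop2=dm.labels[j], distance=dm.d[i, j])
        for i in range(len(dm.labels))
        for j in range(i + 1, len(dm.labels))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)
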