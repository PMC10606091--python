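"""Per-variant Hudson FST, branch lengths, and the Population Branch Statistic.

For a population pair with ALT frequencies p1, p2 estimated from n1, n2
alleles, the Hudson estimator (Bhatia et al. ratio form) is

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)
    FST = N / D

which may be slightly negative for undifferentiated pairs. Each pairwise
FST is turned into a branch length T = -ln(1 - FST) after clamping FST to
[0, 1 - 1e-9], and the PBS of focal population A against B and C is

    PBS_A = (T_AB + T_AC - T_BC) / 2,

the frequency change on A's branch since the A/(B,C) split. Outliers are
called against an empirical percentile (linear-interpolation definition)
of the scan's own PBS distribution, mirroring a gene/region-level scan
with a 99.9th-percentile line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, InputError, PopulationPanel
from .genio import maf_filter, subset_by_population
from .popfreq import GenotypeCounts

log = logging.getLogger(__name__)

__all__ = [
    "FstRecord",
    "PBSRecord",
    "ScanResult",
    "hudson_fst",
    "hudson_fst_arrays",
    "mean_fst",
    "branch_length",
    "pbs",
    "scan",
    "plot_scan",
]

_FST_CAP = 1.0 - 1e-9


@dataclass(frozen=True)
class FstRecord:
    vid: str
    pair: tuple[str, str]
    fst: float  # raw estimator value, may be negative
    fst_clamped: float  # clamped to [0, 1 - 1e-9]
    t: float  # -ln(1 - fst_clamped)


@dataclass(frozen=True)
class PBSRecord:
    vid: str
    focal: str
    pbs: float
    percentile_rank: float  # in [0, 100]
    outlier: bool


@dataclass
class ScanResult:
    """Per-variant PBS table with the empirical outlier threshold.

    ``table`` columns: chrom, pos, vid, p_A, p_B, p_C, fst_AB, fst_AC,
    fst_BC, t_AB, t_AC, t_BC, pbs_focal, percentile_rank, outlier.
    """

    table: pd.DataFrame
    threshold_value: float
    focal: str
    pops: tuple[str, str, str]
    percentile: float
    maf_threshold: float
    records: list[PBSRecord] = field(default_factory=list)


def hudson_fst_arrays(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Vectorized Hudson FST; NaN where the denominator vanishes."""
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    if ((n1 < 2) | (n2 < 2)).any():
        raise InputError("Hudson FST requires at least 2 alleles per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def mean_fst(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> float:
    """Multi-locus Hudson FST as a ratio of averages (sum N / sum D).

    Averaging the numerator and denominator separately before dividing is
    the recommended way to combine loci for this estimator family; the
    per-locus mean of ratios is biased downward. Loci with a vanishing
    denominator are excluded.
    """
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    if not ok.any():
        raise InputError("mean FST undefined: all loci have zero denominator")
    return float(num[ok].sum() / den[ok].sum())


def hudson_fst(c1: GenotypeCounts, c2: GenotypeCounts) -> float:
    """Hudson FST between two populations from their genotype counts."""
    n1, n2 = 2 * c1.n, 2 * c2.n
    if n1 < 2 or n2 < 2:
        raise InputError("Hudson FST requires at least 2 alleles per population")
    p1 = c1.n_alt_alleles / n1
    p2 = c2.n_alt_alleles / n2
    out = hudson_fst_arrays(np.array([p1]), np.array([n1]),
                            np.array([p2]), np.array([n2]))[0]
    return float(out)


def branch_length(fst: float | np.ndarray) -> float | np.ndarray:
    """T = -ln(1 - FST) with FST clamped to [0, 1 - 1e-9]; NaN passes through."""
    clamped = np.clip(fst, 0.0, _FST_CAP)
    t = -np.log1p(-clamped)
    return float(t) if np.isscalar(fst) else t


def pbs(t_ab: float, t_ac: float, t_bc: float) -> float:
    """PBS of focal population A: (T_AB + T_AC - T_BC) / 2."""
    return (t_ab + t_ac - t_bc) / 2.0


def _pop_freqs(gm: GenotypeMatrix, idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
    sub = gm.dosage[idx, :]
    called = sub != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return p.astype(float), n_alleles.astype(float)


def scan(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    pop_a: str,
    pop_b: str,
    pop_c: str,
    focal: str | None = None,
    percentile: float = 99.9,
    maf_threshold: float = 0.05,
) -> ScanResult:
    """PBS selection scan over three populations.

    The MAF filter is applied to the pooled three-population matrix; variants
    where any pairwise FST is undefined (both populations identically fixed)
    are kept in the table with NaN PBS but excluded from the empirical
    percentile. The threshold is the ``percentile``-th linear-interpolation
    percentile of the remaining PBS values; the outlier flag is
    ``pbs > threshold``.
    """
    pops = (pop_a, pop_b, pop_c)
    if len(set(pops)) != 3:
        raise InputError("three distinct populations are required")
    focal = focal or pop_a
    if focal not in pops:
        raise InputError(f"focal population {focal!r} not among {pops}")

    pooled = subset_by_population(gm, panel, pops)
    filtered = maf_filter(pooled, maf_threshold)
    if filtered.n_variants < 2:
        raise InputError(
            "fewer than 2 variants survive the MAF filter; "
            "no empirical distribution to scan against"
        )

    idx = {
        p: [i for i, s in enumerate(filtered.samples) if panel.population_of(s) == p]
        for p in pops
    }
    freqs = {p: _pop_freqs(filtered, idx[p]) for p in pops}

    # focal first, the two outgroups in scan order
    others = [p for p in pops if p != focal]
    pa, na = freqs[focal]
    pb, nb = freqs[others[0]]
    pc, nc = freqs[others[1]]

    fst_ab = hudson_fst_arrays(pa, na, pb, nb)
    fst_ac = hudson_fst_arrays(pa, na, pc, nc)
    fst_bc = hudson_fst_arrays(pb, nb, pc, nc)
    t_ab, t_ac, t_bc = (branch_length(f) for f in (fst_ab, fst_ac, fst_bc))
    pbs_focal = (t_ab + t_ac - t_bc) / 2.0

    valid = ~np.isnan(pbs_focal)
    n_undef = int((~valid).sum())
    if n_undef:
        log.warning("scan: %d variants with undefined FST excluded from percentile",
                    n_undef)
    threshold = float(np.percentile(pbs_focal[valid], percentile))

    sorted_valid = np.sort(pbs_focal[valid])
    rank = np.full(pbs_focal.shape, np.nan)
    rank[valid] = (
        np.searchsorted(sorted_valid, pbs_focal[valid], side="right")
        / sorted_valid.size
        * 100.0
    )
    outlier = valid & (pbs_focal > threshold)

    order = np.argsort([v.pos for v in filtered.variants], kind="stable")
    table = pd.DataFrame(
        {
            "chrom": [filtered.variants[j].chrom for j in order],
            "pos": [filtered.variants[j].pos for j in order],
            "vid": [filtered.variants[j].vid for j in order],
            "p_A": pa[order],
            "p_B": pb[order],
            "p_C": pc[order],
            "fst_AB": fst_ab[order],
            "fst_AC": fst_ac[order],
            "fst_BC": fst_bc[order],
            "t_AB": t_ab[order],
            "t_AC": t_ac[order],
            "t_BC": t_bc[order],
            "pbs_focal": pbs_focal[order],
            "percentile_rank": rank[order],
            "outlier": outlier[order],
        }
    )
    records = [
        PBSRecord(
            vid=row.vid,
            focal=focal,
            pbs=float(row.pbs_focal),
            percentile_rank=float(row.percentile_rank),
            outlier=bool(row.outlier),
        )
        for row in table.itertuples()
        if np.isfinite(row.pbs_focal)
    ]
    return ScanResult(
        table=table,
        threshold_value=threshold,
        focal=focal,
        pops=(focal, others[0], others[1]),
        percentile=percentile,
        maf_threshold=maf_threshold,
        records=records,
    )


def plot_scan(result: ScanResult, path, highlight: list[str] | None = None):
    """Position-vs-PBS scatter with the percentile line; highlighted rsIDs filled."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(t["pos"], t["pbs_focal"], s=18, facecolors="none",
               edgecolors="tab:blue", label="variants")
    if highlight:
        sel = t[t["vid"].isin(highlight)]
        ax.scatter(sel["pos"], sel["pbs_focal"], s=30, color="tab:red",
                   label="highlighted")
    ax.axhline(result.threshold_value, color="black",
               label=f"{result.percentile}th percentile")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(f"PBS ({result.focal})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
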