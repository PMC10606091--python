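"""Genotype counting, allele frequencies, and exact Hardy-Weinberg tests.

The HWE test enumerates the Levene conditional distribution of the
heterozygote count h given the allele counts: with n diploids carrying
n_ref reference and n_alt alternate alleles,

    P(h) ∝ n! / (n_rr! h! n_aa!) * 2**h

over all h with the parity of n_alt (n_rr and n_aa are determined by h).
Because the sites are biallelic the support has at most n+1 states, so the
distribution is enumerated in full; factorials are taken in log-space so
1000 Genomes-scale samples (2n ~ 5000) do not overflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma, log
from typing import Literal

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, InputError, PopulationPanel

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCounts",
    "FrequencyTable",
    "genotype_counts",
    "allele_frequency",
    "frequency_table",
    "hwe_exact",
    "levene_distribution",
    "population_summary",
]

Alternative = Literal["probability", "deficit", "excess"]


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three diploid genotype classes at one biallelic site."""

    n_rr: int  # reference homozygotes (dosage 0)
    n_ra: int  # heterozygotes (dosage 1)
    n_aa: int  # alternate homozygotes (dosage 2)

    def __post_init__(self) -> None:
        if min(self.n_rr, self.n_ra, self.n_aa) < 0:
            raise InputError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_rr + self.n_ra + self.n_aa

    @property
    def n_ref_alleles(self) -> int:
        return 2 * self.n_rr + self.n_ra

    @property
    def n_alt_alleles(self) -> int:
        return 2 * self.n_aa + self.n_ra


@dataclass
class FrequencyTable:
    """Per-(group, variant) reference-allele frequencies with sample sizes.

    Backed by a DataFrame with columns
    ``group, vid, n, n_rr, n_ra, n_aa, p_ref, p_alt, n_alleles``.
    """

    df: pd.DataFrame

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.df["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def p_ref(self, group: str, vid: str) -> float:
        return float(self._row(group, vid)["p_ref"])

    def n_alleles(self, group: str, vid: str) -> int:
        return int(self._row(group, vid)["n_alleles"])

    def ref_freq_vector(self, group: str, loci: list[str]) -> np.ndarray:
        sub = self.df[self.df["group"] == group].set_index("vid")
        missing = [v for v in loci if v not in sub.index]
        if missing:
            raise InputError(f"no frequency rows for {group} at {missing}")
        return sub.loc[loci, "p_ref"].to_numpy(dtype=float)

    def _row(self, group: str, vid: str) -> pd.Series:
        sel = self.df[(self.df["group"] == group) & (self.df["vid"] == vid)]
        if sel.empty:
            raise InputError(f"no frequency row for ({group}, {vid})")
        return sel.iloc[0]


def genotype_counts(gm: GenotypeMatrix, vid: str) -> GenotypeCounts:
    """Tally dosage classes 0/1/2 among non-missing samples at ``vid``."""
    j = gm.variant_index(vid)
    col = gm.dosage[:, j]
    return GenotypeCounts(
        n_rr=int((col == 0).sum()),
        n_ra=int((col == 1).sum()),
        n_aa=int((col == 2).sum()),
    )


def allele_frequency(counts: GenotypeCounts, which: Literal["ref", "alt"]) -> float:
    """Sample allele frequency (2*hom + het) / 2n for the requested allele."""
    if counts.n == 0:
        raise InputError("allele frequency undefined: no typed individuals")
    if which == "ref":
        return counts.n_ref_alleles / (2 * counts.n)
    if which == "alt":
        return counts.n_alt_alleles / (2 * counts.n)
    raise InputError(f"which must be 'ref' or 'alt', got {which!r}")


def frequency_table(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    grouping: Literal["population", "superpopulation"] = "population",
) -> FrequencyTable:
    """Per-group reference-allele frequencies for every variant.

    Groups with zero typed samples at every variant are omitted with a
    warning rather than producing undefined frequencies.
    """
    missing = [s for s in gm.samples if s not in panel.entries]
    if missing:
        raise InputError(f"sample(s) missing from panel: {missing[:5]}")
    key = (
        panel.population_of if grouping == "population" else panel.superpopulation_of
    )
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(gm.samples):
        groups.setdefault(key(s), []).append(i)

    rows = []
    for group, idx in groups.items():
        sub = gm.dosage[idx, :]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        if not n_called.any():
            logger.warning("frequency_table: group %s has no typed samples; omitted", group)
            continue
        n_rr = (sub == 0).sum(axis=0)
        n_ra = (sub == 1).sum(axis=0)
        n_aa = (sub == 2).sum(axis=0)
        n_alleles = 2 * n_called
        with np.errstate(invalid="ignore"):
            p_ref = np.where(n_alleles > 0,
                             (2 * n_rr + n_ra) / np.maximum(n_alleles, 1), np.nan)
        for j, v in enumerate(gm.variants):
            rows.append(
                dict(group=group, vid=v.vid, n=int(n_called[j]),
                     n_rr=int(n_rr[j]), n_ra=int(n_ra[j]), n_aa=int(n_aa[j]),
                     p_ref=float(p_ref[j]), p_alt=1.0 - float(p_ref[j]),
                     n_alleles=int(n_alleles[j]))
            )
    return FrequencyTable(df=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def levene_distribution(n_ref: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the heterozygote count given allele counts.

    Returns ``(h_values, probabilities)`` with probabilities normalized over
    the support (all h with the parity of ``n_alt``, such that the implied
    homozygote counts are non-negative integers).
    """
    if n_ref < 0 or n_alt < 0:
        raise InputError("allele counts must be non-negative")
    if (n_ref + n_alt) % 2:
        raise InputError("total allele count must be even (diploid samples)")
    n = (n_ref + n_alt) // 2
    h_max = min(n_ref, n_alt)
    # h must share the parity of n_alt (and of n_ref)
    hs = np.arange(n_alt % 2, h_max + 1, 2, dtype=int)
    logw = np.array(
        [
            lgamma(n + 1)
            - lgamma((n_ref - h) // 2 + 1)
            - lgamma(h + 1)
            - lgamma((n_alt - h) // 2 + 1)
            + h * log(2.0)
            for h in hs
        ]
    )
    logw -= logw.max()
    w = np.exp(logw)
    return hs, w / w.sum()


def hwe_exact(counts: GenotypeCounts, alternative: Alternative = "probability") -> float:
    """Exact HWE p-value under the Levene conditional distribution.

    ``probability`` sums P over heterozygote counts at least as improbable as
    the observed one; ``deficit`` is P(h <= observed) and ``excess`` is
    P(h >= observed). A monomorphic sample returns 1.0 (no test possible).
    """
    if counts.n < 1:
        raise InputError("HWE test requires at least one typed individual")
    if counts.n_ref_alleles == 0 or counts.n_alt_alleles == 0:
        return 1.0
    hs, probs = levene_distribution(counts.n_ref_alleles, counts.n_alt_alleles)
    obs = counts.n_ra
    p_obs = float(probs[hs == obs][0])
    if alternative == "probability":
        return float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    if alternative == "deficit":
        return float(probs[hs <= obs].sum())
    if alternative == "excess":
        return float(probs[hs >= obs].sum())
    raise InputError(f"unknown alternative {alternative!r}")


def population_summary(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    grouping: Literal["population", "superpopulation"] = "population",
) -> pd.DataFrame:
    """Frequency table augmented with the three exact HWE p-values per row."""
    ft = frequency_table(gm, panel, grouping)
    df = ft.df.copy()
    p_prob, p_def, p_exc = [], [], []
    for _, row in df.iterrows():
        c = GenotypeCounts(int(row["n_rr"]), int(row["n_ra"]), int(row["n_aa"]))
        if c.n == 0:
            p_prob.append(np.nan); p_def.append(np.nan); p_exc.append(np.nan)
            continue
        p_prob.append(hwe_exact(c, "probability"))
        p_def.append(hwe_exact(c, "deficit"))
        p_exc.append(hwe_exact(c, "excess"))
    df["hwe_probability"] = p_prob
    df["hwe_deficit"] = p_def
    df["hwe_excess"] = p_exc
    return df
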