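"""VCF / panel I/O and genotype-matrix handling.

The pipeline's substrate is a samples x variants matrix of alternate-allele
dosages (0, 1, 2, or missing) read from biallelic SNP records of a VCF,
together with a 1000 Genomes-style panel mapping each sample to a population
and superpopulation. Everything downstream (frequencies, HWE, FST, PBS,
Tajima's D) consumes these two objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

#: Sentinel dosage for a missing (or half-called) genotype.
MISSING: int = -1

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeMatrix",
    "PopulationPanel",
    "VCFParseError",
    "InputError",
    "read_vcf",
    "write_vcf",
    "read_panel",
    "write_panel",
    "subset_by_population",
    "maf_filter",
]


class VCFParseError(ValueError):
    """A VCF record could not be interpreted."""


class InputError(ValueError):
    """Invalid user-supplied input (panel, population codes, thresholds)."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP: chromosome, 1-based position, id, REF/ALT bases."""

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF and ALT must differ at {self.vid}")


@dataclass
class GenotypeMatrix:
    """Diploid alternate-allele dosage matrix with missing-data support.

    ``dosage[i, j]`` is the number of ALT alleles carried by sample ``i`` at
    variant ``j`` (0, 1 or 2), or :data:`MISSING`.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = (self.dosage == MISSING) | ((self.dosage >= 0) & (self.dosage <= 2))
        if not ok.all():
            raise ValueError("dosage entries must be in {0, 1, 2} or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, vid: str) -> int:
        for j, v in enumerate(self.variants):
            if v.vid == vid:
                return j
        raise KeyError(f"variant {vid!r} not present in matrix")

    def alt_allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (alt allele count, non-missing allele count)."""
        called = self.dosage != MISSING
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        n_alleles = 2 * called.sum(axis=0)
        return alt.astype(np.int64), n_alleles.astype(np.int64)

    def alt_frequency(self) -> np.ndarray:
        """Per-variant ALT frequency over non-missing alleles (NaN if none)."""
        alt, n = self.alt_allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in idx],
            dosage=self.dosage[:, idx].copy(),
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=list(self.variants),
            dosage=self.dosage[idx, :].copy(),
        )


@dataclass
class PopulationPanel:
    """Sample -> (population, superpopulation) mapping."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop, _ in self.entries.values():
            seen.setdefault(pop, None)
        return list(seen)

    def population_of(self, sample: str) -> str:
        return self.entries[sample][0]

    def superpopulation_of(self, sample: str) -> str:
        return self.entries[sample][1]

    def samples_in(self, pops: Iterable[str]) -> list[str]:
        wanted = set(pops)
        return [s for s, (p, _) in self.entries.items() if p in wanted]


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF into a :class:`GenotypeMatrix`.

    Phased and unphased genotypes are treated identically; ``./.`` and
    half-calls become :data:`MISSING`. With ``biallelic_only``, multiallelic
    and non-SNP records are skipped (the count is logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"{path}: VCF contains zero samples")

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    lineno = 0  # record index within the body, for error messages
    try:
        for rec in vcf:
            lineno += 1
            alts = rec.ALT
            is_snp = len(rec.REF) == 1 and all(len(a) == 1 for a in alts)
            if len(alts) != 1 or not is_snp:
                if biallelic_only:
                    n_skipped += 1
                    continue
                raise VCFParseError(
                    f"{path} record {lineno}: non-biallelic-SNP record "
                    f"{rec.CHROM}:{rec.POS} requires biallelic_only=True"
                )
            col = np.empty(len(samples), dtype=np.int16)
            for i, gt in enumerate(rec.genotypes):
                a, b = gt[0], gt[1]
                col[i] = a + b if (a >= 0 and b >= 0) else MISSING
            variants.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    vid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    ref=rec.REF,
                    alt=alts[0],
                )
            )
            columns.append(col)
    except VCFParseError:
        raise
    except Exception as exc:  # htslib-level failure
        raise VCFParseError(f"{path}: malformed VCF near record {lineno + 1}: {exc}") from exc

    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    dosage = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix as a minimal GT-only VCF 4.2 file."""
    path = Path(path)
    contigs: dict[str, None] = {}
    for v in gm.variants:
        contigs.setdefault(v.chrom, None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            gts = "\t".join(_GT_STRING[int(d)] for d in gm.dosage[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")
    return path


# ---------------------------------------------------------------------------
# Panel

REQUIRED_PANEL_COLUMNS = ("sample", "pop", "super_pop")


def read_panel(path: str | Path) -> PopulationPanel:
    """Read a 1000 Genomes-style TSV panel (sample, pop, super_pop)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: panel is missing required column(s) {missing}")
    dup = df["sample"][df["sample"].duplicated()]
    if not dup.empty:
        raise InputError(f"{path}: duplicate sample ID(s): {sorted(set(dup))}")
    entries = {
        row["sample"]: (row["pop"], row["super_pop"]) for _, row in df.iterrows()
    }
    return PopulationPanel(entries=entries)


def write_panel(panel: PopulationPanel, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\tpop\tsuper_pop\n")
        for sample, (pop, sup) in panel.entries.items():
            fh.write(f"{sample}\t{pop}\t{sup}\n")
    return path


# ---------------------------------------------------------------------------
# Subsetting and filtering

def subset_by_population(
    gm: GenotypeMatrix, panel: PopulationPanel, pops: Iterable[str]
) -> GenotypeMatrix:
    """Restrict the matrix to samples whose population is in ``pops``.

    Sample order is preserved; the variant list is unchanged.
    """
    pops = set(pops)
    absent = pops - set(panel.populations)
    if absent:
        raise InputError(f"population code(s) not in panel: {sorted(absent)}")
    keep = [
        i
        for i, s in enumerate(gm.samples)
        if s in panel.entries and panel.population_of(s) in pops
    ]
    return gm.take_samples(keep)


def maf_filter(gm: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Remove variants whose minor-allele frequency is <= ``threshold``.

    The MAF is computed over the non-missing alleles of the matrix as given;
    variants with MAF strictly greater than the threshold are kept.
    Monomorphic and all-missing variants are always removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise InputError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    p = gm.alt_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = np.where(~np.isnan(maf) & (maf > threshold))[0]
    removed = gm.n_variants - keep.size
    if removed:
        log.info("maf_filter: removed %d of %d variants (MAF <= %g)",
                 removed, gm.n_variants, threshold)
    if keep.size == 0:
        log.warning("maf_filter: all variants removed")
    return gm.take_variants(keep)
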