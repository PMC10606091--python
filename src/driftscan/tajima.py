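"""Windowed Tajima's D from unphased diploid dosages.

Pairwise nucleotide diversity is computed exactly from per-site allele
counts: at a biallelic site carrying n_A reference and n_B alternate
alleles among n = n_A + n_B chromosomes, the number of pairwise differences
is n_A * n_B, so pi_site = n_A n_B / C(n, 2). This equals the explicit
all-haplotype-pairs count, so phasing is never needed. Watterson's
theta is S / a1 and

    D = (pi - S/a1) / sqrt(e1 S + e2 S (S - 1))

with the usual constants depending on the chromosome count. Windows with
S = 0 report D as None (undefined) rather than 0, so invariant windows
cannot masquerade as neutral signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, InputError

log = logging.getLogger(__name__)

__all__ = [
    "TajimaConstants",
    "TajimaWindow",
    "tajima_constants",
    "window_pi_s",
    "tajima_d",
    "windowed_scan",
    "windows_to_frame",
]


@dataclass(frozen=True)
class TajimaConstants:
    """The sample-size constants of the D statistic for ``n_chr`` chromosomes."""

    n_chr: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@dataclass
class TajimaWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_sites: int
    s: int
    pi: float
    theta_w: float
    d: float | None  # None when s == 0


def tajima_constants(n_chr: int) -> TajimaConstants:
    if n_chr < 2:
        raise InputError(f"need at least 2 chromosomes, got {n_chr}")
    n = n_chr
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return TajimaConstants(
        n_chr=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2,
        e1=c1 / a1, e2=c2 / (a1**2 + a2),
    )


def _site_allele_counts(
    gm: GenotypeMatrix, cols: np.ndarray, strict: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """(alt count, total non-missing allele count) per selected site."""
    sub = gm.dosage[:, cols]
    called = sub != MISSING
    if strict:
        keep = called.all(axis=0)
        sub, called = sub[:, keep], called[:, keep]
    n = 2 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    return alt.astype(np.int64), n.astype(np.int64)


def window_pi_s(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    strict: bool = False,
) -> tuple[int, float]:
    """Segregating-site count and mean pairwise differences in a window.

    ``strict`` drops sites with any missing genotype; otherwise each site
    uses its own non-missing allele count.
    """
    cols = np.array(
        [j for j, v in enumerate(gm.variants)
         if v.chrom == chrom and start <= v.pos <= end],
        dtype=int,
    )
    if cols.size == 0:
        return 0, 0.0
    alt, n = _site_allele_counts(gm, cols, strict=strict)
    usable = n >= 2
    alt, n = alt[usable], n[usable]
    seg = (alt > 0) & (alt < n)
    s = int(seg.sum())
    ref = n - alt
    pairs = n * (n - 1) // 2
    pi = float((ref[seg] * alt[seg] / pairs[seg]).sum()) if s else 0.0
    return s, pi


def tajima_d(s: int, pi: float, constants: TajimaConstants) -> float | None:
    """Tajima's D, or None when there are no segregating sites."""
    if s < 0:
        raise InputError("segregating-site count must be >= 0")
    if s == 0:
        return None
    var = constants.e1 * s + constants.e2 * s * (s - 1)
    return float((pi - s / constants.a1) / np.sqrt(var))


def _modal_n_chr(gm: GenotypeMatrix, cols: np.ndarray, strict: bool) -> int | None:
    alt, n = _site_allele_counts(gm, cols, strict=strict)
    n = n[n >= 2]
    if n.size == 0:
        return None
    values, counts = np.unique(n, return_counts=True)
    return int(values[np.argmax(counts)])


def windowed_scan(
    gm: GenotypeMatrix,
    window_size: int = 10_000,
    step: int | None = None,
    strict: bool = False,
    rsids: list[str] | None = None,
) -> tuple[list[TajimaWindow], dict[str, TajimaWindow | None]]:
    """Tile (or slide, if ``step`` < ``window_size``) windows per chromosome.

    Windows cover each chromosome's observed position range. The chromosome
    count used for the constants is the modal non-missing allele count over
    the window's sites (exact when there is no missing data). If ``rsids``
    are given, the second return value maps each id to its containing
    window (None, with a warning, when outside all windows).
    """
    if window_size < 1 or (step is not None and step < 1):
        raise InputError("window_size and step must be >= 1")
    step = step or window_size

    by_chrom: dict[str, list[int]] = {}
    for j, v in enumerate(gm.variants):
        by_chrom.setdefault(v.chrom, []).append(j)

    windows: list[TajimaWindow] = []
    for chrom, idx in by_chrom.items():
        pos = np.array([gm.variants[j].pos for j in idx])
        lo = ((int(pos.min()) - 1) // window_size) * window_size + 1
        hi = int(pos.max())
        start = lo
        while start <= hi:
            end = start + window_size - 1
            cols = np.array([j for j in idx
                             if start <= gm.variants[j].pos <= end], dtype=int)
            s, pi = window_pi_s(gm, chrom, start, end, strict=strict)
            n_chr = _modal_n_chr(gm, cols, strict) if cols.size else None
            if s > 0 and n_chr is not None and n_chr >= 4:
                const = tajima_constants(n_chr)
                d = tajima_d(s, pi, const)
                theta_w = s / const.a1
            else:
                d = None
                theta_w = s / tajima_constants(n_chr).a1 if (s and n_chr) else 0.0
            windows.append(
                TajimaWindow(chrom=chrom, start=start, end=end,
                             n_sites=int(cols.size), s=s, pi=pi,
                             theta_w=theta_w, d=d)
            )
            start += step

    per_snp: dict[str, TajimaWindow | None] = {}
    if rsids:
        pos_of = {v.vid: (v.chrom, v.pos) for v in gm.variants}
        for rsid in rsids:
            hit = None
            if rsid in pos_of:
                chrom, p = pos_of[rsid]
                for w in windows:
                    if w.chrom == chrom and w.start <= p <= w.end:
                        hit = w
                        break
            if hit is None:
                log.warning("windowed_scan: rsID %s falls outside all windows", rsid)
            per_snp[rsid] = hit
    return windows, per_snp


def windows_to_frame(windows: list[TajimaWindow]) -> pd.DataFrame:
    """TSV-ready frame; undefined D becomes NaN."""
    return pd.DataFrame(
        dict(chrom=w.chrom, window_start=w.start, window_end=w.end,
             n_sites=w.n_sites, s=w.s, pi=w.pi, theta_w=w.theta_w,
             tajima_d=(np.nan if w.d is None else w.d))
        for w in windows
    )
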