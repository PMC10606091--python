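"""Synthetic study generator: Balding-Nichols divergence and fixed-count samples.

Two kinds of input are emulated. First, a single-population diploid sample
with exactly prescribed genotype counts (the worked-example fixture: 94
Sardinians typed at one SNP). Second, K populations diverged from a common
ancestor under the Balding-Nichols model: per locus an ancestral frequency
p_anc is drawn uniformly, each population's frequency is

    p_i ~ Beta(p_anc (1-F_i)/F_i, (1-p_anc)(1-F_i)/F_i),

and diploid genotypes are Binomial(2, p_i) — Hardy-Weinberg within
populations, expected pairwise FST ~ F. The model has no linkage
disequilibrium and no explicit demography; it reproduces exactly the
features the downstream statistics consume (allele-frequency divergence
and HWE genotype sampling), which is what makes parameter-recovery tests
possible. An optional planted sweep redraws one locus's genotypes in the
focal population at an elevated target frequency, as a positive control
for the percentile outlier rule.

Variant positions are laid out on a synthetic chr20 contig starting at
35.4 Mb, echoing the coordinate neighbourhood of the locus the worked
example uses; the layout is purely cosmetic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genio import (
    MISSING,
    GenotypeMatrix,
    InputError,
    PopulationPanel,
    VariantRecord,
    write_panel,
    write_vcf,
)

log = logging.getLogger(__name__)

__all__ = [
    "DivergenceConfig",
    "SweepSpec",
    "simulate_divergence",
    "simulate_neutral_sites",
    "plant_sweep",
    "choose_sweep_locus",
    "simulate_genotype_sample",
    "generate_fixture_study",
    "PRESETS",
]

_CONTIG = "chr20"
_BASE_POS = 35_400_000
_POS_SPACING = 50

#: rs143384-style worked-example site: REF G (ancestral), ALT A (derived).
SARDINIA_VARIANT = VariantRecord(
    chrom=_CONTIG, pos=35_437_976, vid="rs143384", ref="G", alt="A"
)
SARDINIA_COUNTS = (13, 54, 27)  # (GG, AG, AA) = (hom-ref, het, hom-alt)

# The paper-scale trio sizes (CEU/CHB/YRI diploid sample counts).
TRIO_SIZES = (99, 103, 105)


@dataclass
class DivergenceConfig:
    """Conditions of a K-population Balding-Nichols divergence simulation."""

    n_pops: int = 3
    samples_per_pop: tuple[int, ...] = TRIO_SIZES
    n_loci: int = 5000
    p_anc_range: tuple[float, float] = (0.05, 0.95)
    f_per_pop: tuple[float, ...] = (0.10, 0.10, 0.10)
    seed: int = 0
    pop_labels: tuple[str, ...] | None = None
    superpop_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_loci < 1:
            raise InputError("n_pops and n_loci must be positive")
        if len(self.samples_per_pop) != self.n_pops:
            raise InputError("samples_per_pop length must equal n_pops")
        if any(s < 1 for s in self.samples_per_pop):
            raise InputError("sample counts must be positive")
        if len(self.f_per_pop) != self.n_pops:
            raise InputError("f_per_pop length must equal n_pops")
        if any(not 0.0 < f < 1.0 for f in self.f_per_pop):
            raise InputError("every F must lie in (0, 1)")
        lo, hi = self.p_anc_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise InputError("p_anc_range must satisfy 0 <= lo <= hi <= 1")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.pop_labels or tuple(f"POP{i + 1}" for i in range(self.n_pops))

    @property
    def superlabels(self) -> tuple[str, ...]:
        return self.superpop_labels or tuple("SYN" for _ in range(self.n_pops))


@dataclass(frozen=True)
class SweepSpec:
    """A planted focal-branch sweep: one locus pushed to ``target_freq``."""

    locus_index: int
    focal_pop: str
    target_freq: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_freq <= 1.0:
            raise InputError("target_freq must lie in [0, 1]")


def _variants(n_loci: int) -> list[VariantRecord]:
    bases = ("A", "C", "G", "T")
    return [
        VariantRecord(
            chrom=_CONTIG,
            pos=_BASE_POS + i * _POS_SPACING,
            vid=f"snp{i:05d}",
            ref=bases[i % 4],
            alt=bases[(i + 1) % 4],
        )
        for i in range(n_loci)
    ]


def _bn_frequencies(
    rng: np.random.Generator, p_anc: np.ndarray, f: float
) -> np.ndarray:
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p_anc * scale, 1e-12),
                    np.maximum((1.0 - p_anc) * scale, 1e-12))


def simulate_divergence(
    cfg: DivergenceConfig,
) -> tuple[GenotypeMatrix, PopulationPanel]:
    """Draw a K-population diverged study; fully reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    p_anc = rng.uniform(*cfg.p_anc_range, size=cfg.n_loci)

    samples: list[str] = []
    entries: dict[str, tuple[str, str]] = {}
    blocks: list[np.ndarray] = []
    for k in range(cfg.n_pops):
        label = cfg.labels[k]
        p_k = _bn_frequencies(rng, p_anc, cfg.f_per_pop[k])
        n_k = cfg.samples_per_pop[k]
        blocks.append(rng.binomial(2, p_k, size=(n_k, cfg.n_loci)).astype(np.int16))
        for i in range(n_k):
            sid = f"{label}_{i:04d}"
            samples.append(sid)
            entries[sid] = (label, cfg.superlabels[k])

    gm = GenotypeMatrix(
        samples=samples,
        variants=_variants(cfg.n_loci),
        dosage=np.concatenate(blocks, axis=0),
    )
    return gm, PopulationPanel(entries=entries)


def simulate_neutral_sites(
    n_samples: int, n_loci: int, seed: int
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Single-population sample whose sites follow the neutral frequency spectrum.

    Balding-Nichols draws with a uniform ancestral frequency produce a flat
    site-frequency spectrum — far too many common variants — which pushes
    pi above Watterson's theta and makes Tajima's D strongly positive even
    without selection. For testing D itself, segregating sites are instead
    drawn from the standard neutral spectrum: the alternate-allele count i
    among the 2*n_samples chromosomes has P(i) proportional to 1/i
    (i = 1 .. 2n-1), and the carriers are a uniformly random chromosome
    subset. Under this spectrum E[pi_site] = 1/a1 per site, so pi and S/a1
    estimate the same quantity and D is centred near zero.

    Returns the diploid matrix (chromosomes 2k, 2k+1 paired into sample k)
    together with the underlying haplotype array (2n x loci), so tests can
    compare allele-count pi against an explicit all-haplotype-pairs count.
    """
    if n_samples < 2 or n_loci < 1:
        raise InputError("need at least 2 samples and 1 locus")
    rng = np.random.default_rng(seed)
    n_chr = 2 * n_samples
    i_vals = np.arange(1, n_chr)
    probs = (1.0 / i_vals) / (1.0 / i_vals).sum()
    counts = rng.choice(i_vals, size=n_loci, p=probs)
    hap = np.zeros((n_chr, n_loci), dtype=np.int8)
    for j, c in enumerate(counts):
        hap[rng.choice(n_chr, size=c, replace=False), j] = 1
    dosage = (hap[0::2] + hap[1::2]).astype(np.int16)
    samples = [f"NEU_{i:04d}" for i in range(n_samples)]
    gm = GenotypeMatrix(samples=samples, variants=_variants(n_loci), dosage=dosage)
    return gm, hap


def plant_sweep(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    spec: SweepSpec,
    seed: int,
) -> GenotypeMatrix:
    """Redraw the focal population's dosages at one locus at the target frequency."""
    if not 0 <= spec.locus_index < gm.n_variants:
        raise InputError(f"locus index {spec.locus_index} out of range")
    if spec.focal_pop not in panel.populations:
        raise InputError(f"unknown focal population {spec.focal_pop!r}")
    rng = np.random.default_rng(seed)
    rows = [i for i, s in enumerate(gm.samples)
            if panel.population_of(s) == spec.focal_pop]
    dosage = gm.dosage.copy()
    dosage[rows, spec.locus_index] = rng.binomial(
        2, spec.target_freq, size=len(rows)
    ).astype(np.int16)
    return GenotypeMatrix(samples=list(gm.samples), variants=list(gm.variants),
                          dosage=dosage)


def simulate_genotype_sample(
    n_rr: int,
    n_ra: int,
    n_aa: int,
    variant: VariantRecord = SARDINIA_VARIANT,
    pop_label: str = "EUR_SAR",
    superpop_label: str = "EUR",
) -> tuple[GenotypeMatrix, PopulationPanel]:
    """Deterministic single-variant sample with exactly the given genotype counts."""
    if min(n_rr, n_ra, n_aa) < 0:
        raise InputError("genotype counts must be non-negative")
    n = n_rr + n_ra + n_aa
    if n == 0:
        raise InputError("cannot build a sample with zero individuals")
    dosage = np.concatenate(
        [np.zeros(n_rr), np.ones(n_ra), np.full(n_aa, 2)]
    ).astype(np.int16)[:, None]
    samples = [f"{pop_label}_{i:04d}" for i in range(n)]
    panel = PopulationPanel(
        entries={s: (pop_label, superpop_label) for s in samples}
    )
    return (
        GenotypeMatrix(samples=samples, variants=[variant], dosage=dosage),
        panel,
    )


# ---------------------------------------------------------------------------
# Packaged presets

def _two_cluster_world(seed: int) -> tuple[GenotypeMatrix, PopulationPanel, dict]:
    """27 populations in two drift-separated clusters (7 vs 20)."""
    params = dict(n_pops=27, cluster_sizes=(7, 20), f_between=0.20,
                  f_within=0.02, samples_per_pop=20, n_loci=200)
    rng = np.random.default_rng(seed)
    n_loci = params["n_loci"]
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    cluster_freqs = [
        _bn_frequencies(rng, p_anc, params["f_between"]) for _ in range(2)
    ]
    samples: list[str] = []
    entries: dict[str, tuple[str, str]] = {}
    blocks = []
    pop_idx = 0
    for c, (n_pops_c, sup) in enumerate(
        zip(params["cluster_sizes"], ("AFR", "OOA"))
    ):
        for _ in range(n_pops_c):
            label = f"{sup}{pop_idx:02d}"
            p = _bn_frequencies(rng, cluster_freqs[c], params["f_within"])
            blocks.append(
                rng.binomial(2, p, size=(params["samples_per_pop"], n_loci))
                .astype(np.int16)
            )
            for i in range(params["samples_per_pop"]):
                sid = f"{label}_{i:04d}"
                samples.append(sid)
                entries[sid] = (label, sup)
            pop_idx += 1
    gm = GenotypeMatrix(samples=samples, variants=_variants(n_loci),
                        dosage=np.concatenate(blocks, axis=0))
    return gm, PopulationPanel(entries=entries), params


#: Preset names accepted by :func:`generate_fixture_study`.
PRESETS = ("neutral_trio", "sweep_trio", "sardinia", "two_cluster_world")

SWEEP_TARGET_FREQ = 0.95
SWEEP_NEUTRAL_F = 0.05
SWEEP_N_LOCI = 1000
SWEEP_BACKGROUND_FREQ = 0.3  # plant where the outgroups sit near this frequency


def choose_sweep_locus(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    focal_pop: str,
    background_freq: float = SWEEP_BACKGROUND_FREQ,
) -> int:
    """Locus whose pooled non-focal ALT frequency is closest to ``background_freq``.

    Planting the sweep at a mid-frequency background locus guarantees a
    large focal-branch frequency jump, making the positive control
    deterministic in effect size rather than dependent on a lucky draw.
    """
    rows = [i for i, s in enumerate(gm.samples)
            if panel.population_of(s) != focal_pop]
    sub = gm.dosage[rows, :]
    called = sub != MISSING
    n = 2 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return int(np.nanargmin(np.abs(p - background_freq)))


def generate_fixture_study(
    out_dir: str | Path, preset: str, seed: int = 20230930
) -> dict[str, Path]:
    """Write VCF + panel + JSON manifest for a named study preset.

    ``neutral_trio``: three populations at the worked trio's sample sizes
    (99/103/105) with per-branch F = 0.10 and 5000 loci — the null scan and
    FST parameter-recovery substrate. ``sweep_trio``: the same study with
    one locus swept to ALT frequency 0.95 in the first population.
    ``sardinia``: the fixed-count single-population worked example.
    ``two_cluster_world``: 27 populations in two drift clusters for the
    ordination topology check.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params: dict = {"preset": preset, "seed": seed}

    if preset in ("neutral_trio", "sweep_trio"):
        if preset == "sweep_trio":
            cfg = DivergenceConfig(
                f_per_pop=(SWEEP_NEUTRAL_F,) * 3, n_loci=SWEEP_N_LOCI, seed=seed
            )
        else:
            cfg = DivergenceConfig(seed=seed)
        gm, panel = simulate_divergence(cfg)
        params.update(
            n_pops=cfg.n_pops, samples_per_pop=list(cfg.samples_per_pop),
            n_loci=cfg.n_loci, f_per_pop=list(cfg.f_per_pop),
            p_anc_range=list(cfg.p_anc_range), pops=list(cfg.labels),
        )
        if preset == "sweep_trio":
            spec = SweepSpec(
                locus_index=choose_sweep_locus(gm, panel, cfg.labels[0]),
                focal_pop=cfg.labels[0],
                target_freq=SWEEP_TARGET_FREQ,
            )
            gm = plant_sweep(gm, panel, spec, seed=seed + 1)
            params.update(
                sweep_locus=gm.variants[spec.locus_index].vid,
                sweep_locus_index=spec.locus_index,
                sweep_focal=spec.focal_pop,
                sweep_target_freq=spec.target_freq,
            )
    elif preset == "sardinia":
        n_rr, n_ra, n_aa = SARDINIA_COUNTS
        gm, panel = simulate_genotype_sample(n_rr, n_ra, n_aa)
        params.update(counts=dict(hom_ref=n_rr, het=n_ra, hom_alt=n_aa),
                      variant=SARDINIA_VARIANT.vid, pop="EUR_SAR")
    elif preset == "two_cluster_world":
        gm, panel, world_params = _two_cluster_world(seed)
        params.update(world_params)
    else:
        raise InputError(f"unknown preset {preset!r}; choose from {PRESETS}")

    paths = {
        "vcf": write_vcf(gm, out_dir / f"{preset}.vcf"),
        "panel": write_panel(panel, out_dir / f"{preset}.panel.tsv"),
        "manifest": out_dir / f"{preset}.manifest.json",
    }
    paths["manifest"].write_text(json.dumps(params, indent=2) + "\n")
    log.info("generate_fixture_study: wrote %s study to %s", preset, out_dir)
    return paths
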