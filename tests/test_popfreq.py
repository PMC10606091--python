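"""Genotype counts, allele frequencies, and the exact HWE test.

The HWE oracle here enumerates the Levene conditional distribution with
exact integer arithmetic (math.comb and Fractions), independently of the
package's log-space implementation.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftscan import popfreq
from driftscan.genio import GenotypeMatrix, InputError, VariantRecord
from driftscan.popfreq import (
    GenotypeCounts,
    allele_frequency,
    frequency_table,
    genotype_counts,
    hwe_exact,
    levene_distribution,
)
from driftscan.synthpop import simulate_genotype_sample


# ---------------------------------------------------------------------------
# Independent exact-enumeration HWE oracle


def exact_levene_weights(n_ref: int, n_alt: int) -> dict[int, int]:
    """Integer weights n!/(n_rr! h! n_aa!) * 2**h over the h support."""
    n = (n_ref + n_alt) // 2
    weights = {}
    for h in range(n_alt % 2, min(n_ref, n_alt) + 1, 2):
        n_rr = (n_ref - h) // 2
        n_aa = (n_alt - h) // 2
        w = comb(n, n_rr) * comb(n - n_rr, h) * 2**h
        weights[h] = w
    return weights


def oracle_hwe(n_rr: int, n_ra: int, n_aa: int, alternative: str) -> Fraction:
    n_ref = 2 * n_rr + n_ra
    n_alt = 2 * n_aa + n_ra
    if n_ref == 0 or n_alt == 0:
        return Fraction(1)
    w = exact_levene_weights(n_ref, n_alt)
    total = sum(w.values())
    obs = w[n_ra]
    if alternative == "probability":
        return Fraction(sum(v for v in w.values() if v <= obs), total)
    if alternative == "deficit":
        return Fraction(sum(v for h, v in w.items() if h <= n_ra), total)
    return Fraction(sum(v for h, v in w.items() if h >= n_ra), total)


# ---------------------------------------------------------------------------
# Counting and frequencies


def test_sardinian_counts_and_percentages(sardinia):
    gm, _ = sardinia
    c = genotype_counts(gm, "rs143384")
    assert (c.n_rr, c.n_ra, c.n_aa) == (13, 54, 27)
    assert c.n == 94
    pct = np.array([c.n_rr, c.n_ra, c.n_aa]) / c.n * 100
    np.testing.assert_allclose(pct, [13.83, 57.45, 28.72], atol=0.005)


def test_sardinian_allele_frequencies(sardinia):
    gm, _ = sardinia
    c = genotype_counts(gm, "rs143384")
    assert allele_frequency(c, "alt") == pytest.approx(108 / 188)
    assert round(allele_frequency(c, "alt"), 3) == 0.574
    assert round(allele_frequency(c, "ref"), 3) == 0.426
    assert allele_frequency(c, "ref") + allele_frequency(c, "alt") == 1.0


def test_counts_skip_missing_and_match_tally(trio):
    gm, _, _ = trio
    rng = np.random.default_rng(0)
    col = rng.integers(-1, 3, size=gm.n_samples).astype(np.int16)
    gm2 = GenotypeMatrix(
        samples=gm.samples,
        variants=[VariantRecord("c", 1, "x", "A", "G")],
        dosage=col[:, None],
    )
    c = genotype_counts(gm2, "x")
    assert (c.n_rr, c.n_ra, c.n_aa) == tuple(int((col == k).sum()) for k in (0, 1, 2))
    assert c.n == int((col != -1).sum())


def test_all_missing_column_gives_zero_counts():
    gm = GenotypeMatrix(
        samples=["a", "b"],
        variants=[VariantRecord("c", 1, "x", "A", "G")],
        dosage=np.full((2, 1), -1, dtype=np.int16),
    )
    c = genotype_counts(gm, "x")
    assert (c.n_rr, c.n_ra, c.n_aa, c.n) == (0, 0, 0, 0)
    with pytest.raises(InputError):
        allele_frequency(c, "ref")


@pytest.mark.parametrize(
    "counts, which, expected",
    [
        ((5, 10, 0), "ref", (2 * 5 + 10) / 30),
        ((0, 7, 0), "ref", 0.5),
        ((9, 0, 0), "ref", 1.0),
    ],
)
def test_allele_frequency_closed_forms(counts, which, expected):
    assert allele_frequency(GenotypeCounts(*counts), which) == pytest.approx(expected)


def test_frequency_table_matches_per_group_tally(trio):
    gm, panel, cfg = trio
    sub = gm.take_variants(np.arange(30))
    ft = frequency_table(sub, panel)
    assert len(ft.df) == 3 * 30
    rng = np.random.default_rng(1)
    for _ in range(20):
        pop = cfg.labels[rng.integers(3)]
        j = int(rng.integers(30))
        rows = [i for i, s in enumerate(sub.samples)
                if panel.population_of(s) == pop]
        col = sub.dosage[rows, j]
        called = col[col != -1]
        p_ref = (2 * (called == 0).sum() + (called == 1).sum()) / (2 * len(called))
        assert ft.p_ref(pop, sub.variants[j].vid) == pytest.approx(p_ref)


def test_frequency_table_superpopulation_pooling(small_matrix):
    gm, panel = small_matrix
    by_pop = frequency_table(gm, panel, "population")
    pooled = frequency_table(gm, panel, "superpopulation")
    assert pooled.groups == ["SUP1"]
    # all samples share one superpopulation: pooled equals whole-matrix tally
    c = genotype_counts(gm, "v1")
    assert pooled.p_ref("SUP1", "v1") == pytest.approx(
        allele_frequency(c, "ref")
    )
    assert set(by_pop.groups) == {"POPA", "POPB"}


def test_frequency_table_requires_full_panel(small_matrix):
    gm, panel = small_matrix
    panel.entries.pop("S4")
    with pytest.raises(InputError, match="S4"):
        frequency_table(gm, panel)


# ---------------------------------------------------------------------------
# HWE exact test


def test_hwe_sardinian_deficit_p_value(sardinia):
    gm, _ = sardinia
    c = genotype_counts(gm, "rs143384")
    assert round(hwe_exact(c, "deficit"), 3) == 0.969


def test_hwe_small_case_exact_fractions():
    c = GenotypeCounts(1, 2, 1)
    assert hwe_exact(c, "deficit") == pytest.approx(54 / 70, abs=1e-12)
    assert hwe_exact(c, "probability") == pytest.approx(1.0, abs=1e-12)


def test_hwe_monomorphic_returns_one():
    for c in (GenotypeCounts(7, 0, 0), GenotypeCounts(0, 0, 7)):
        for alt in ("probability", "deficit", "excess"):
            assert hwe_exact(c, alt) == 1.0


def test_hwe_negative_counts_rejected():
    with pytest.raises(InputError):
        GenotypeCounts(-1, 2, 1)


@given(
    n_rr=st.integers(0, 40), n_ra=st.integers(0, 40), n_aa=st.integers(0, 40)
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_hwe_agrees_with_exact_integer_oracle(n_rr, n_ra, n_aa):
    if n_rr + n_ra + n_aa == 0:
        return
    c = GenotypeCounts(n_rr, n_ra, n_aa)
    for alt in ("probability", "deficit", "excess"):
        assert hwe_exact(c, alt) == pytest.approx(
            float(oracle_hwe(n_rr, n_ra, n_aa, alt)), abs=1e-9
        )


@pytest.mark.parametrize("n", [5, 17, 50, 100])
def test_levene_probabilities_sum_to_one(n):
    for n_alt in range(0, 2 * n + 1):
        hs, probs = levene_distribution(2 * n - n_alt, n_alt)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_deficit_plus_excess_identity():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n_rr, n_ra, n_aa = rng.integers(0, 30, size=3)
        if n_rr + n_ra + n_aa == 0 or (n_rr + n_ra == 0) or (n_aa + n_ra == 0):
            continue
        c = GenotypeCounts(int(n_rr), int(n_ra), int(n_aa))
        hs, probs = levene_distribution(c.n_ref_alleles, c.n_alt_alleles)
        p_obs = float(probs[hs == c.n_ra][0])
        total = hwe_exact(c, "deficit") + hwe_exact(c, "excess") - p_obs
        assert total == pytest.approx(1.0, abs=1e-12)


def randomized_hwe_p(counts: GenotypeCounts, u: float) -> float:
    """Randomized probability-ordering p-value: exactly Uniform(0,1) under HWE.

    The exact test's p-value is discrete (and conservative, with an atom at
    1 whenever the modal heterozygote count is observed); the standard
    randomized version P(T < t_obs) + u * P(T = t_obs) removes the
    discreteness so full-distribution uniformity can be asserted.
    """
    hs, probs = levene_distribution(counts.n_ref_alleles, counts.n_alt_alleles)
    p_obs = float(probs[hs == counts.n_ra][0])
    lt = float(probs[probs < p_obs * (1 - 1e-12)].sum())
    eq = float(probs[np.abs(probs - p_obs) <= p_obs * 1e-12].sum())
    return lt + u * eq


def _hwe_null_sample(seed, n_loci=500, n_ind=100):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_loci):
        p = rng.uniform(0.1, 0.9)
        dosage = rng.binomial(2, p, size=n_ind)
        c = GenotypeCounts(
            int((dosage == 0).sum()), int((dosage == 1).sum()),
            int((dosage == 2).sum()),
        )
        if c.n_ref_alleles and c.n_alt_alleles:
            out.append((c, rng.uniform()))
    return out


def test_hwe_p_values_calibrated_under_null():
    """Randomized p-values are uniform; the reported test is never anticonservative."""
    from scipy import stats

    draws = _hwe_null_sample(seed=7)
    p_rand = [randomized_hwe_p(c, u) for c, u in draws]
    assert stats.kstest(p_rand, "uniform").statistic < 0.08

    p_exact = np.array([hwe_exact(c, "probability") for c, _ in draws])
    n = len(p_exact)
    for alpha in (0.01, 0.05, 0.10, 0.25):
        rate = (p_exact <= alpha).mean()
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n)


def test_population_summary_carries_hwe_columns(sardinia):
    gm, panel = sardinia
    df = popfreq.population_summary(gm, panel)
    row = df.iloc[0]
    assert row["group"] == "EUR_SAR"
    assert round(row["hwe_deficit"], 3) == 0.969
    assert {"n_rr", "n_ra", "n_aa", "p_ref", "p_alt"} <= set(df.columns)


def test_simulate_genotype_sample_reproduces_counts_via_vcf(tmp_path):
    from driftscan.genio import read_vcf, write_vcf

    gm, _ = simulate_genotype_sample(3, 5, 2)
    back = read_vcf(write_vcf(gm, tmp_path / "s.vcf"))
    c = genotype_counts(back, gm.variants[0].vid)
    assert (c.n_rr, c.n_ra, c.n_aa) == (3, 5, 2)
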