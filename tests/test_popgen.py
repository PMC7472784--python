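"""Frequencies, diversity, exact HWE, adjustment, differentials, and F_ST."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from admixprec.datatypes import GenotypeMatrix, ReferenceFrequencies
from admixprec.popgen import (
    adjust_pvalues,
    allele_frequencies,
    freq_differential,
    fst_components,
    heterozygosity,
    hwe_exact_test,
    hwe_table,
    pairwise_fst,
)


def _gm(dosages, prefix="s"):
    d = np.atleast_2d(np.asarray(dosages, dtype=float))
    return GenotypeMatrix(
        [f"{prefix}{i}" for i in range(d.shape[0])],
        [f"m{j}" for j in range(d.shape[1])],
        d,
    )


# ---------------------------------------------------------------------------
# Allele frequencies and diversity
# ---------------------------------------------------------------------------

def test_allele_frequency_with_missing_call():
    g = _gm([[0], [1], [2], [np.nan]])
    f = allele_frequencies(g)
    assert f.alt_freq[0, 0] == pytest.approx(0.5)
    assert f.n_chrom[0, 0] == 6


def test_monomorphic_reference_frequency_zero():
    f = allele_frequencies(_gm([[0], [0], [0]]))
    assert f.alt_freq[0, 0] == 0.0


def test_allele_frequencies_match_per_cell_recount(rng):
    d = rng.integers(0, 3, size=(100, 50)).astype(float)
    d[rng.random(d.shape) < 0.1] = np.nan
    g = _gm(d)
    f = allele_frequencies(g)
    for j in range(50):  # independent loop-based recount
        total, called = 0.0, 0
        for i in range(100):
            if not np.isnan(d[i, j]):
                total += d[i, j]
                called += 1
        assert f.alt_freq[0, j] == pytest.approx(total / (2 * called))
        assert f.n_chrom[0, j] == 2 * called


def test_single_heterozygote_diversity():
    h = heterozygosity(_gm([[1]]))
    assert h["H_obs"][0] == 1.0
    assert h["gene_diversity"][0] == pytest.approx(1.0)  # (2/1)*(1-0.25-0.25)


def test_monomorphic_diversity_zero():
    h = heterozygosity(_gm([[0], [0], [0]]))
    assert h["H_obs"][0] == h["H_exp"][0] == h["gene_diversity"][0] == 0.0


def test_hwe_sample_heterozygosity_matches_expectation(rng):
    d = rng.binomial(2, 0.3, size=(10_000, 1)).astype(float)
    h = heterozygosity(_gm(d))
    assert h["H_obs"][0] == pytest.approx(0.42, abs=0.01)
    assert h["H_exp"][0] == pytest.approx(0.42, abs=0.01)


def test_gene_diversity_bounds_and_peak(rng):
    d = rng.integers(0, 3, size=(40, 30)).astype(float)
    h = heterozygosity(_gm(d))
    assert ((h["gene_diversity"] >= 0) & (h["gene_diversity"] <= 1)).all()
    p = np.linspace(0, 1, 101)
    h_exp = 2 * p * (1 - p)
    assert np.argmax(h_exp) == 50  # maximal at p = 0.5


# ---------------------------------------------------------------------------
# Exact HWE test
# ---------------------------------------------------------------------------

def exact_hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent full enumeration with exact rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_alt = 2 * n_aa + n_Aa
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return Fraction(1)
    weights = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        weights[het] = Fraction(
            factorial(n) * 2**het,
            factorial(hom_minor) * factorial(het) * factorial(hom_major),
        )
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs) / total


def test_hwe_exact_known_values():
    assert hwe_exact_test(1, 2, 1) == pytest.approx(1.0)
    assert hwe_exact_test(2, 0, 2) == pytest.approx(6 / 70)
    assert hwe_exact_test(100, 0, 0) == 1.0  # monomorphic convention


def test_hwe_exact_matches_enumeration_oracle():
    for total in range(1, 21):
        for n_aa in range(total + 1):
            for n_het in range(total - n_aa + 1):
                n_AA = total - n_aa - n_het
                expect = float(exact_hwe_oracle(n_AA, n_het, n_aa))
                got = hwe_exact_test(n_AA, n_het, n_aa)
                assert got == pytest.approx(expect, rel=1e-10), (n_AA, n_het, n_aa)


def test_hwe_exact_is_conservative_under_equilibrium(rng):
    """Type-I error of the exact test stays at or below nominal 5%."""
    rejections = 0
    n_loci = 10_000
    p = rng.uniform(0.05, 0.95, n_loci)
    d = rng.binomial(2, p[None, :].repeat(100, axis=0))
    for j in range(n_loci):
        col = d[:, j]
        pval = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
        rejections += pval < 0.05
    assert rejections / n_loci <= 0.055


def test_hwe_table_flags_monomorphic_and_adjusts(rng):
    d = np.column_stack(
        [rng.binomial(2, 0.4, 50), np.zeros(50), rng.binomial(2, 0.5, 50)]
    ).astype(float)
    t = hwe_table(_gm(d))
    assert t["monomorphic"].tolist() == [False, True, False]
    assert np.isnan(t["adjusted_p"][1])
    tested = t.loc[~t["monomorphic"]]
    assert (tested["adjusted_p"] >= tested["p_value"] - 1e-12).all()


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

def test_bonferroni_single_and_multiplicity():
    assert adjust_pvalues([0.01]).tolist() == [0.01]
    # 207 polymorphic loci, smallest p = 0.0002 -> still significant at 5%
    adjusted = 0.0002 * 207
    assert adjusted == pytest.approx(0.0414)
    got = adjust_pvalues([0.0002] + [0.5] * 206)[0]
    assert got == pytest.approx(0.0414)
    assert got < 0.05


def test_bh_matches_step_up_oracle(rng):
    p = rng.uniform(0, 1, 25)
    got = adjust_pvalues(p, method="bh")
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):  # brute-force step-up
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    assert np.allclose(got, adj)


def test_adjust_empty_and_invalid():
    assert adjust_pvalues([]).size == 0
    with pytest.raises(ValueError):
        adjust_pvalues([1.5])


# ---------------------------------------------------------------------------
# Frequency differentials
# ---------------------------------------------------------------------------

def _freqs(p, pops=("A", "B"), n=200.0):
    p = np.asarray(p, dtype=float)
    return ReferenceFrequencies(
        list(pops),
        [f"m{j}" for j in range(p.shape[1])],
        p,
        np.full(p.shape, n),
    )


def test_freq_differential_basic_and_identical():
    f = _freqs([[0.9, 0.2], [0.1, 0.2]])
    d = freq_differential(f, "A", "B")
    assert d["abs_diff"].tolist() == [pytest.approx(0.8), pytest.approx(0.0)]
    same = freq_differential(_freqs([[0.3, 0.7], [0.3, 0.7]]), "A", "B")
    assert (same["abs_diff"] == 0).all()


def test_freq_differential_ordering_matches_sort_oracle(rng):
    p = rng.uniform(0, 1, (2, 100))
    f = _freqs(p)
    d = freq_differential(f, "A", "B")
    expect = np.sort(np.abs(p[0] - p[1]))[::-1]
    assert np.allclose(d["abs_diff"].to_numpy(), expect)
    with pytest.raises(KeyError):
        freq_differential(f, "A", "Z")


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def test_fixed_opposite_alleles_give_theta_one():
    a = _gm(np.zeros((20, 10)), prefix="a")
    b = _gm(np.full((20, 10), 2.0), prefix="b")
    fst = pairwise_fst({"A": a, "B": b})
    assert fst.pair("A", "B") == pytest.approx(1.0)


def _wc_oracle(counts_a, counts_b):
    """Direct transcription of the two-population variance components."""
    num = den = 0.0
    for (nA, pA, hA), (nB, pB, hB) in zip(counts_a, counts_b):
        r = 2
        nbar = (nA + nB) / 2
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den


def _locus_stats(d):
    out = []
    for j in range(d.shape[1]):
        col = d[:, j][~np.isnan(d[:, j])]
        out.append((len(col), col.sum() / (2 * len(col)), float((col == 1).mean())))
    return out


def test_population_against_itself_matches_component_oracle(rng):
    d = rng.integers(0, 3, size=(30, 40)).astype(float)
    a, b = _gm(d, "a"), _gm(d, "b")
    fst = pairwise_fst({"A": a, "B": b})
    oracle = _wc_oracle(_locus_stats(d), _locus_stats(d))
    assert fst.pair("A", "B") == pytest.approx(oracle, abs=1e-12)
    assert abs(fst.pair("A", "B")) < 0.05  # near zero for a duplicated sample


def test_theta_matches_oracle_on_random_pair(rng):
    da = rng.integers(0, 3, size=(25, 30)).astype(float)
    db = rng.integers(0, 3, size=(35, 30)).astype(float)
    fst = pairwise_fst({"A": _gm(da, "a"), "B": _gm(db, "b")})
    oracle = _wc_oracle(_locus_stats(da), _locus_stats(db))
    assert fst.pair("A", "B") == pytest.approx(oracle, abs=1e-12)


def test_theta_invariant_to_sample_order_and_allele_relabel(rng):
    da = rng.integers(0, 3, size=(20, 25)).astype(float)
    db = rng.integers(0, 3, size=(20, 25)).astype(float)
    base = pairwise_fst({"A": _gm(da, "a"), "B": _gm(db, "b")}).pair("A", "B")
    perm = rng.permutation(20)
    shuffled = pairwise_fst({"A": _gm(da[perm], "a"), "B": _gm(db, "b")}).pair("A", "B")
    assert shuffled == pytest.approx(base, abs=1e-12)
    flipped = pairwise_fst(
        {"A": _gm(2 - da, "a"), "B": _gm(2 - db, "b")}
    ).pair("A", "B")
    assert flipped == pytest.approx(base, abs=1e-12)


def test_theta_from_frequency_table_uses_hwe_heterozygosity():
    f = _freqs([[0.9, 0.8], [0.1, 0.3]], n=100.0)
    fst = pairwise_fst(f)
    counts_a = [(50, 0.9, 2 * 0.9 * 0.1), (50, 0.8, 2 * 0.8 * 0.2)]
    counts_b = [(50, 0.1, 2 * 0.1 * 0.9), (50, 0.3, 2 * 0.3 * 0.7)]
    assert fst.pair("A", "B") == pytest.approx(_wc_oracle(counts_a, counts_b))


def test_all_monomorphic_pair_is_undefined():
    a = _gm(np.zeros((10, 4)), "a")
    b = _gm(np.zeros((10, 4)), "b")
    assert np.isnan(pairwise_fst({"A": a, "B": b}).pair("A", "B"))


def test_fst_components_shapes_and_nan_propagation():
    n = np.array([[10.0, np.nan], [10.0, 5.0]])
    p = np.array([[0.5, np.nan], [0.2, 0.3]])
    h = np.array([[0.4, np.nan], [0.3, 0.2]])
    a, b, c = fst_components(n, p, h)
    assert a.shape == (2,)
    assert np.isnan(a[1]) and np.isnan(b[1])
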