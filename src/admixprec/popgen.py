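"""Descriptive and inferential population-genetic statistics.

Allele frequencies, observed/expected heterozygosity and Nei gene diversity,
the exact conditional Hardy-Weinberg test, multiple-testing adjustment,
absolute allele-frequency differentials, and pairwise Weir-Cockerham
F_ST (theta-hat, ratio-of-sums over loci).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr  # noqa: F401  (ndtr used by assign)
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, MarkerPanel, ReferenceFrequencies

__all__ = [
    "allele_frequencies",
    "heterozygosity",
    "hwe_exact_test",
    "hwe_table",
    "adjust_pvalues",
    "freq_differential",
    "genotype_counts",
    "pairwise_fst",
    "fst_components",
    "FstMatrix",
    "LocusHweResult",
]


# ---------------------------------------------------------------------------
# Frequencies and diversity
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix, population: str = "pop") -> ReferenceFrequencies:
    """Sample ALT-allele frequencies of one population.

    ``p_hat = sum(dosages) / (2 * n_called)`` per marker; markers with no
    non-missing call get ``NaN`` frequency (undefined, not an error).
    """
    d = g.dosages
    called = (~np.isnan(d)).sum(axis=0).astype(float)
    total = np.nansum(d, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, total / (2.0 * called), np.nan)
    return ReferenceFrequencies([population], g.marker_ids, p[None, :], (2.0 * called)[None, :])


def genotype_counts(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker genotype counts (n_homref, n_het, n_homalt)."""
    d = g.dosages
    return pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "n_homref": (d == 0).sum(axis=0),
            "n_het": (d == 1).sum(axis=0),
            "n_homalt": (d == 2).sum(axis=0),
        }
    )


def heterozygosity(g: GenotypeMatrix) -> pd.DataFrame:
    """Observed/expected heterozygosity and Nei unbiased gene diversity.

    Returns a DataFrame with ``H_obs``, ``H_exp = 2p(1-p)``, ``gene_diversity
    = (2n/(2n-1)) * (1 - p^2 - (1-p)^2)`` and the heterozygosity deficit
    ``H_exp - H_obs`` (positive = homozygote excess).
    """
    d = g.dosages
    called = (~np.isnan(d)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, np.nansum(d, axis=0) / (2.0 * called), np.nan)
        h_obs = np.where(called > 0, (d == 1).sum(axis=0) / called, np.nan)
        h_exp = 2.0 * p * (1.0 - p)
        two_n = 2.0 * called
        gd = np.where(
            two_n >= 2,
            two_n / (two_n - 1.0) * (1.0 - p**2 - (1.0 - p) ** 2),
            np.nan,
        )
    return pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "n_called": called.astype(int),
            "alt_freq": p,
            "H_obs": h_obs,
            "H_exp": h_exp,
            "gene_diversity": gd,
            "het_deficit": h_exp - h_obs,
        }
    )


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional two-sided Hardy-Weinberg test for a biallelic locus.

    Conditional on the minor-allele count, the p-value is the summed
    probability of all heterozygote configurations whose conditional
    probability does not exceed that of the observed configuration.
    A monomorphic locus returns 1 by convention.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_alt = 2 * n_aa + n_Aa
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = n - hets - homs_minor
    # log P(het = h | n, n_minor) up to the common normalizer
    logw = (
        hets * np.log(2.0)
        - gammaln(homs_minor + 1)
        - gammaln(hets + 1)
        - gammaln(homs_major + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    obs = w[np.searchsorted(hets, n_Aa)]
    # tolerance guards against ties broken by floating-point rounding
    p = float(w[w <= obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


@dataclass
class LocusHweResult:
    marker_id: str
    n_AA: int
    n_Aa: int
    n_aa: int
    p_value: float
    adjusted_p: float
    het_deficit: float
    monomorphic: bool


def hwe_table(g: GenotypeMatrix, method: str = "bonferroni") -> pd.DataFrame:
    """Exact HWE test per marker with multiple-testing adjustment.

    Monomorphic loci are retained and flagged; they do not enter the number
    of tests used for the adjustment.
    """
    counts = genotype_counts(g)
    het = heterozygosity(g)
    pvals, mono = [], []
    for _, row in counts.iterrows():
        total = row["n_homref"] + row["n_het"] + row["n_homalt"]
        if total == 0:
            pvals.append(np.nan)
            mono.append(True)
            continue
        p = hwe_exact_test(int(row["n_homref"]), int(row["n_het"]), int(row["n_homalt"]))
        is_mono = (row["n_het"] + min(row["n_homref"], row["n_homalt"])) == 0
        pvals.append(p)
        mono.append(bool(is_mono))
    pvals = np.asarray(pvals)
    mono = np.asarray(mono)
    adjusted = np.full_like(pvals, np.nan)
    tested = ~mono & ~np.isnan(pvals)
    if tested.any():
        adjusted[tested] = adjust_pvalues(pvals[tested], method=method)
    out = counts.copy()
    out["p_value"] = pvals
    out["adjusted_p"] = adjusted
    out["het_deficit"] = het["het_deficit"].to_numpy()
    out["monomorphic"] = mono
    return out


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` (min(1, m*p)) or ``bh``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}; use 'bonferroni' or 'bh'")
    return multipletests(p, method=key)[1]


# ---------------------------------------------------------------------------
# Frequency differentials
# ---------------------------------------------------------------------------

def freq_differential(
    f: ReferenceFrequencies, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Per-marker absolute ALT-frequency difference, sorted descending.

    Returns a DataFrame (marker_id, abs_diff) ordered by decreasing
    differential — the standard ranking used to shortlist ancestry-informative
    markers between two source populations.
    """
    ia, ib = f.population_index(pop_a), f.population_index(pop_b)
    delta = np.abs(f.alt_freq[ia] - f.alt_freq[ib])
    out = pd.DataFrame({"marker_id": f.marker_ids, "abs_diff": delta})
    return out.sort_values(
        ["abs_diff", "marker_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

class FstMatrix:
    """Symmetric matrix of pairwise multi-locus theta-hat estimates."""

    def __init__(self, populations, values) -> None:
        self.populations = list(populations)
        v = np.asarray(values, dtype=float)
        k = len(self.populations)
        if v.shape != (k, k):
            raise ValueError("values must be square over populations")
        if not np.allclose(np.diag(v), 0.0, equal_nan=True):
            raise ValueError("diagonal must be 0")
        finite = v[~np.isnan(v)]
        if finite.size and finite.min() < -0.1:
            raise ValueError("theta-hat below sanity bound -0.1")
        with np.errstate(invalid="ignore"):
            if not np.array_equal(v, v.T, equal_nan=True):
                raise ValueError("matrix must be symmetric")
        self.values = v

    def pair(self, pop_a: str, pop_b: str) -> float:
        ia = self.populations.index(pop_a)
        ib = self.populations.index(pop_b)
        return float(self.values[ia, ib])

    def pairs(self) -> dict[tuple[str, str], float]:
        out = {}
        for i in range(len(self.populations)):
            for j in range(i + 1, len(self.populations)):
                out[(self.populations[i], self.populations[j])] = float(self.values[i, j])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)


def fst_components(n, p, h) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) variance components a, b, c per locus.

    Parameters are per-population arrays over loci: ``n`` sample sizes
    (individuals, shape (r, L)), ``p`` ALT frequencies, ``h`` observed
    heterozygote proportions.  Entries may be NaN where a population is
    untyped at a locus; such loci get NaN components.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = nbar / n_c * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    return a, b, c


def _pair_tables(
    freqs: ReferenceFrequencies | None,
    genotypes: dict[str, GenotypeMatrix] | None,
    marker_ids: list[str],
):
    """Per-population (n, p, h) arrays over the requested loci.

    From genotypes the observed heterozygosity is used; from a frequency
    table the Hardy-Weinberg expectation ``2p(1-p)`` stands in for it.
    """
    if genotypes is not None:
        pops = list(genotypes)
        n = np.empty((len(pops), len(marker_ids)))
        p = np.empty_like(n)
        h = np.empty_like(n)
        for i, pop in enumerate(pops):
            g = genotypes[pop].subset_markers(marker_ids)
            if g.n_samples == 0:
                raise ValueError(f"population {pop!r} has zero typed individuals")
            d = g.dosages
            called = (~np.isnan(d)).sum(axis=0).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                n[i] = called
                p[i] = np.where(called > 0, np.nansum(d, axis=0) / (2 * called), np.nan)
                h[i] = np.where(called > 0, (d == 1).sum(axis=0) / called, np.nan)
        return pops, n, p, h
    assert freqs is not None
    f = freqs.subset_markers(marker_ids)
    n = f.n_chrom / 2.0
    p = f.alt_freq
    h = 2.0 * p * (1.0 - p)
    return list(f.populations), n, p, h


def pairwise_fst(
    data: ReferenceFrequencies | dict[str, GenotypeMatrix],
    panel: MarkerPanel | list[str] | None = None,
    clamp_negative: bool = False,
) -> FstMatrix:
    """Pairwise multi-locus Weir-Cockerham theta-hat between all populations.

    ``data`` is either a frequency table with chromosome counts or a mapping
    population -> GenotypeMatrix.  ``theta = sum_l a_l / sum_l (a+b+c)_l``
    over loci with a defined, non-zero denominator; a pair with no such locus
    gets NaN (undefined, flagged by the caller).  Negative estimates are
    reported raw unless ``clamp_negative``.
    """
    if isinstance(data, ReferenceFrequencies):
        all_markers = data.marker_ids
        freqs, genos = data, None
    else:
        if not data:
            raise ValueError("no populations supplied")
        first = next(iter(data.values()))
        all_markers = first.marker_ids
        freqs, genos = None, data
    if panel is None:
        marker_ids = list(all_markers)
    else:
        marker_ids = list(panel.marker_ids if isinstance(panel, MarkerPanel) else panel)
    if not marker_ids:
        raise ValueError("empty locus set")
    pops, n, p, h = _pair_tables(freqs, genos, marker_ids)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    k = len(pops)
    theta = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b, c = fst_components(n[[i, j]], p[[i, j]], h[[i, j]])
            denom = a + b + c
            ok = ~np.isnan(denom) & (np.abs(denom) > 0)
            if not ok.any():
                theta[i, j] = theta[j, i] = np.nan
                continue
            t = a[ok].sum() / denom[ok].sum()
            if clamp_negative:
                t = max(t, 0.0)
            theta[i, j] = theta[j, i] = t
    return FstMatrix(pops, theta)
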