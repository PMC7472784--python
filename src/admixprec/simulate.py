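"""Synthetic reference panels, admixed cohorts, and nuclear families.

The generator reproduces the statistical structure the analysis assumes:

* source-population allele frequencies drift apart from a shared ancestral
  frequency under the Balding-Nichols model, with a *per-population* drift
  coefficient so pairwise differentiation can be made unequal (the regime of
  interest: the European/Native-American distance smallest);
* individual admixture vectors are Dirichlet-distributed with a dominant
  European-like component;
* families follow Mendelian transmission at unlinked loci, so the expected
  offspring ancestry is the parental average;
* designated reference populations can carry monomorphic loci, and genotypes
  can be missing at random.

All randomness flows through a single ``numpy`` Generator derived from the
config seed; identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PedigreeTable, ReferenceFrequencies, SimulationConfig

__all__ = [
    "simulate_reference",
    "simulate_individuals",
    "simulate_families",
    "ReferenceSimulation",
    "FamilySimulation",
    "trihybrid_config",
]


def trihybrid_config(**overrides) -> SimulationConfig:
    """The default trihybrid study design (see :class:`SimulationConfig`)."""
    return SimulationConfig(**overrides)


@dataclass
class ReferenceSimulation:
    """True population frequencies plus sampled reference genotypes."""

    true_freqs: ReferenceFrequencies
    sample_freqs: ReferenceFrequencies
    genotypes: dict[str, GenotypeMatrix]
    ancestral_freq: np.ndarray


@dataclass
class FamilySimulation:
    genotypes: GenotypeMatrix
    pedigree: PedigreeTable
    parent_q: dict[str, np.ndarray]
    expected_offspring_q: dict[str, np.ndarray]


def _rng(cfg: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def _balding_nichols(rng, p_anc: np.ndarray, F: float) -> np.ndarray:
    """Population frequencies around ``p_anc`` with drift F (F=0 exact copy)."""
    if F == 0.0:
        return p_anc.copy()
    shape = (1.0 - F) / F
    return rng.beta(p_anc * shape, (1.0 - p_anc) * shape)


def simulate_reference(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> ReferenceSimulation:
    """Draw true population frequencies and reference genotype samples."""
    rng = _rng(cfg, rng)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.L)
    pi = np.empty((cfg.K, cfg.L))
    for k in range(cfg.K):
        pi[k] = _balding_nichols(rng, p_anc, cfg.drift_F[k])
    if cfg.monomorphic_fraction > 0:
        n_mono = int(np.ceil(cfg.monomorphic_fraction * cfg.L))
        loci = rng.choice(cfg.L, size=n_mono, replace=False)
        k = cfg.monomorphic_population
        pi[k, loci] = np.round(pi[k, loci])
    marker_ids = [f"m{j:04d}" for j in range(cfg.L)]
    genotypes = {}
    sample_p = np.empty_like(pi)
    for k, pop in enumerate(cfg.population_names):
        n = cfg.n_ref[k]
        d = rng.binomial(2, pi[k], size=(n, cfg.L)).astype(float)
        d = _apply_missingness(rng, d, cfg.missing_rate)
        ids = [f"{pop}_{i:03d}" for i in range(n)]
        genotypes[pop] = GenotypeMatrix(ids, marker_ids, d)
        called = (~np.isnan(d)).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            sample_p[k] = np.where(called > 0, np.nansum(d, axis=0) / (2 * called), np.nan)
    n_chrom_true = np.tile(
        2.0 * np.asarray(cfg.n_ref, dtype=float)[:, None], (1, cfg.L)
    )
    called_chrom = np.array(
        [
            2.0 * (~np.isnan(genotypes[pop].dosages)).sum(axis=0)
            for pop in cfg.population_names
        ]
    )
    true_freqs = ReferenceFrequencies(
        list(cfg.population_names), marker_ids, pi, n_chrom_true
    )
    sample_freqs = ReferenceFrequencies(
        list(cfg.population_names), marker_ids, sample_p, np.maximum(called_chrom, 2)
    )
    return ReferenceSimulation(true_freqs, sample_freqs, genotypes, p_anc)


def _apply_missingness(rng, d: np.ndarray, rate: float) -> np.ndarray:
    if rate > 0:
        d = d.copy()
        d[rng.random(d.shape) < rate] = np.nan
    return d


def simulate_individuals(
    freqs: ReferenceFrequencies,
    n: int | None = None,
    q: np.ndarray | None = None,
    dirichlet_alpha=None,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    id_prefix: str = "ind",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Admixed unrelated individuals; returns genotypes plus the true q table.

    Each allele copy descends from population k with probability ``q_k`` and
    is then ALT with probability ``pi_kl``; marginally the dosage is
    Binomial(2, sum_k q_k pi_kl).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    pi = freqs.alt_freq
    if q is None:
        if dirichlet_alpha is None or n is None:
            raise ValueError("supply q, or n together with dirichlet_alpha")
        q = rng.dirichlet(np.asarray(dirichlet_alpha, dtype=float), size=n)
    else:
        q = np.atleast_2d(np.asarray(q, dtype=float))
        if (q < 0).any() or not np.allclose(q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("q rows must lie on the simplex")
        n = q.shape[0]
    if q.shape[1] != freqs.n_populations:
        raise ValueError("q width must equal the number of populations")
    p_alt = q @ pi  # (n, L)
    d = rng.binomial(2, p_alt).astype(float)
    d = _apply_missingness(rng, d, missing_rate)
    ids = [f"{id_prefix}_{i:04d}" for i in range(n)]
    return GenotypeMatrix(ids, freqs.marker_ids, d), q


def simulate_families(
    freqs: ReferenceFrequencies,
    n_families: int,
    dirichlet_alpha,
    offspring_per_family: int = 2,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> FamilySimulation:
    """Nuclear families with Mendelian transmission at unlinked loci.

    Parents are unrelated admixed individuals with q ~ Dirichlet(alpha); each
    offspring receives, per locus, one uniformly chosen allele from each
    parent's genotype.  The truth table records parental q and their mean
    (the expected offspring ancestry).
    """
    if offspring_per_family < 1:
        raise ValueError("offspring_per_family must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = freqs.n_markers
    records, all_ids, rows = [], [], []
    parent_q: dict[str, np.ndarray] = {}
    expected_q: dict[str, np.ndarray] = {}
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    for fam_idx in range(n_families):
        fam = f"F{fam_idx + 1:03d}"
        qm, qf = rng.dirichlet(alpha, size=2)
        pa = qm @ freqs.alt_freq
        pb = qf @ freqs.alt_freq
        dm = rng.binomial(2, pa).astype(float)
        df = rng.binomial(2, pb).astype(float)
        mid, fid = f"{fam}-M", f"{fam}-F"
        parent_q[mid], parent_q[fid] = qm, qf
        records.append((fam, mid, None, None, "mother"))
        records.append((fam, fid, None, None, "father"))
        all_ids.extend([mid, fid])
        rows.extend([dm, df])
        for o in range(offspring_per_family):
            oid = f"{fam}-O{o + 1}"
            # transmitted allele is ALT with probability dosage/2
            do = (
                rng.random(L) < dm / 2.0
            ).astype(float) + (rng.random(L) < df / 2.0)
            records.append((fam, oid, mid, fid, "offspring"))
            all_ids.append(oid)
            rows.append(do.astype(float))
            expected_q[oid] = (qm + qf) / 2.0
    d = np.array(rows)
    d = _apply_missingness(rng, d, missing_rate)
    genotypes = GenotypeMatrix(all_ids, freqs.marker_ids, d)
    ped = PedigreeTable(
        pd.DataFrame(records, columns=list(PedigreeTable.COLUMNS))
    )
    return FamilySimulation(genotypes, ped, parent_q, expected_q)
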