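"""Core in-memory containers shared by all submodules.

Conventions
-----------
* Genotypes are biallelic alt-allele dosages in {0, 1, 2}; missing calls are
  stored as ``numpy.nan`` in a float matrix.
* Frequency tables store the ALT-allele frequency together with the number of
  sampled chromosomes, so downstream code can weight by sample size.
* Ancestry vectors ``q`` live on the K-simplex (non-negative, sum to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerInfo",
    "GenotypeMatrix",
    "ReferenceFrequencies",
    "PedigreeTable",
    "MarkerPanel",
    "AncestryVector",
    "EstimatorOptions",
    "PopulationFit",
    "AssignmentOutcome",
    "SimulationConfig",
]

ROLES = ("mother", "father", "offspring")


@dataclass(frozen=True)
class MarkerInfo:
    """Identity of one biallelic marker (SNP or indel)."""

    marker_id: str
    ref_allele: str = "A"
    alt_allele: str = "T"
    marker_class: str = "SNP"

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValueError("marker_id must be non-empty")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError(f"{self.marker_id}: allele strings must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.marker_id}: ref and alt alleles are identical")
        if self.marker_class not in ("SNP", "indel"):
            raise ValueError(f"{self.marker_id}: marker_class must be 'SNP' or 'indel'")


class GenotypeMatrix:
    """Samples x markers matrix of alt-allele dosages with missingness.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row.
    markers
        :class:`MarkerInfo` (or bare marker-id strings), one per column.
    dosages
        Array-like of shape ``(n_samples, n_markers)``; entries must be
        0, 1, 2 or NaN (missing).
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        markers: Sequence[MarkerInfo | str],
        dosages,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.markers = [
            m if isinstance(m, MarkerInfo) else MarkerInfo(m) for m in markers
        ]
        d = np.asarray(dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        if d.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {d.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Series(self.sample_ids)
            raise ValueError(
                "duplicate sample ids: "
                + ", ".join(sorted(dupes[dupes.duplicated()].unique()))
            )
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids in genotype matrix")
        finite = d[~np.isnan(d)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosages must be 0/1/2/NaN; found {bad!r}")
        self.dosages = d

    # -- basic views ------------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(marker_ids)
        index = {m: j for j, m in enumerate(self.marker_ids)}
        missing = [m for m in wanted if m not in index]
        if missing:
            raise KeyError(f"markers not in matrix: {missing[:5]}")
        cols = [index[m] for m in wanted]
        return GenotypeMatrix(
            self.sample_ids, [self.markers[j] for j in cols], self.dosages[:, cols]
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        rows = [index[s] for s in wanted]
        return GenotypeMatrix(wanted, self.markers, self.dosages[rows, :])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.markers == other.markers
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers)"


class ReferenceFrequencies:
    """Per-population, per-marker ALT-allele frequencies with chromosome counts."""

    def __init__(
        self,
        populations: Sequence[str],
        marker_ids: Sequence[str],
        alt_freq,
        n_chrom,
    ) -> None:
        self.populations = list(populations)
        self.marker_ids = list(marker_ids)
        p = np.asarray(alt_freq, dtype=float)
        n = np.asarray(n_chrom, dtype=float)
        shape = (len(self.populations), len(self.marker_ids))
        if p.shape != shape or n.shape != shape:
            raise ValueError(
                f"alt_freq/n_chrom shapes {p.shape}/{n.shape} != {shape}"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
                raise ValueError("alt_freq entries must lie in [0, 1]")
        if (n[~np.isnan(p)] < 2).any():
            raise ValueError("n_chrom must be >= 2 wherever a frequency is defined")
        self.alt_freq = p
        self.n_chrom = n

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def population_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    def subset_markers(self, marker_ids: Iterable[str]) -> "ReferenceFrequencies":
        wanted = list(marker_ids)
        index = {m: j for j, m in enumerate(self.marker_ids)}
        missing = [m for m in wanted if m not in index]
        if missing:
            raise KeyError(f"markers not in frequency table: {missing[:5]}")
        cols = [index[m] for m in wanted]
        return ReferenceFrequencies(
            self.populations, wanted, self.alt_freq[:, cols], self.n_chrom[:, cols]
        )

    def smoothed(self, freq_floor: float | None = None) -> np.ndarray:
        """Frequencies clipped into ``[floor, 1 - floor]``.

        With ``freq_floor=None`` the floor is the add-half pseudo-count bound
        ``1 / (2 * n_chrom + 2)`` per population and locus, so monomorphic
        reference loci never contribute infinite log-likelihood terms.
        """
        if freq_floor is None:
            floor = 1.0 / (2.0 * self.n_chrom + 2.0)
        else:
            if not 0.0 < freq_floor < 0.5:
                raise ValueError("freq_floor must lie in (0, 0.5)")
            floor = np.full_like(self.alt_freq, freq_floor)
        return np.clip(self.alt_freq, floor, 1.0 - floor)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceFrequencies):
            return NotImplemented
        return (
            self.populations == other.populations
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.alt_freq, other.alt_freq, equal_nan=True)
            and np.array_equal(self.n_chrom, other.n_chrom, equal_nan=True)
        )

    def __repr__(self) -> str:
        return (
            f"ReferenceFrequencies({self.n_populations} populations x "
            f"{self.n_markers} markers)"
        )


class PedigreeTable:
    """Nuclear-family pedigree: one mother and one father per family.

    Backed by a DataFrame with columns ``family_id, sample_id, mother_id,
    father_id, role``; absent parents are ``None``.
    """

    COLUMNS = ("family_id", "sample_id", "mother_id", "father_id", "role")

    def __init__(self, records: pd.DataFrame | Sequence[dict]) -> None:
        df = pd.DataFrame(records, columns=list(self.COLUMNS)).copy()
        df = df.where(pd.notna(df), None)
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in pedigree: {dupes[:5]}")
        bad_role = set(df["role"]) - set(ROLES)
        if bad_role:
            raise ValueError(f"unknown roles: {sorted(bad_role)}")
        known = set(df["sample_id"])
        for fam, grp in df.groupby("family_id", sort=False):
            mothers = grp.loc[grp["role"] == "mother", "sample_id"].tolist()
            fathers = grp.loc[grp["role"] == "father", "sample_id"].tolist()
            if len(mothers) != 1 or len(fathers) != 1:
                raise ValueError(
                    f"family {fam!r}: expected exactly one mother and one father, "
                    f"found {len(mothers)} and {len(fathers)}"
                )
            for _, row in grp.iterrows():
                if row["role"] == "offspring":
                    if row["mother_id"] is None or row["father_id"] is None:
                        raise ValueError(
                            f"offspring {row['sample_id']!r} must reference both parents"
                        )
                    for parent in (row["mother_id"], row["father_id"]):
                        if parent not in known:
                            raise ValueError(
                                f"offspring {row['sample_id']!r} references unknown "
                                f"parent {parent!r}"
                            )
                    if row["mother_id"] != mothers[0] or row["father_id"] != fathers[0]:
                        raise ValueError(
                            f"offspring {row['sample_id']!r} references parents "
                            f"outside family {fam!r}"
                        )
                else:
                    if row["mother_id"] is not None or row["father_id"] is not None:
                        raise ValueError(
                            f"founder {row['sample_id']!r} must have absent parents"
                        )
        self.df = df.reset_index(drop=True)

    @property
    def family_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["family_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def offspring(self) -> pd.DataFrame:
        return self.df[self.df["role"] == "offspring"].reset_index(drop=True)

    def parents_of(self, offspring_id: str) -> tuple[str, str]:
        row = self.df[self.df["sample_id"] == offspring_id]
        if row.empty or row.iloc[0]["role"] != "offspring":
            raise KeyError(f"{offspring_id!r} is not an offspring in this pedigree")
        return row.iloc[0]["mother_id"], row.iloc[0]["father_id"]

    def siblings(self) -> list[tuple[str, str, str]]:
        """All unordered sibling pairs as ``(family_id, sib1, sib2)`` in file order."""
        pairs = []
        off = self.offspring()
        for fam, grp in off.groupby("family_id", sort=False):
            sibs = grp["sample_id"].tolist()
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    pairs.append((fam, sibs[i], sibs[j]))
        return pairs

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PedigreeTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass(frozen=True)
class MarkerPanel:
    """A named ordered subset of marker ids."""

    panel_id: str
    marker_ids: tuple[str, ...]

    def __init__(self, panel_id: str, marker_ids: Iterable[str]) -> None:
        ids = tuple(marker_ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"panel {panel_id!r} contains duplicate marker ids")
        object.__setattr__(self, "panel_id", panel_id)
        object.__setattr__(self, "marker_ids", ids)

    def __len__(self) -> int:
        return len(self.marker_ids)

    def validate_against(self, known_markers: Iterable[str]) -> None:
        known = set(known_markers)
        unknown = [m for m in self.marker_ids if m not in known]
        if unknown:
            raise ValueError(
                f"panel {self.panel_id!r} references unknown markers: {unknown[:5]}"
            )


@dataclass
class AncestryVector:
    """Estimated admixture proportions for one individual."""

    sample_id: str
    q: np.ndarray
    loglik: float
    n_informative_loci: int
    converged: bool
    flat_likelihood: bool = False

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if (self.q < -1e-12).any():
            raise ValueError("q components must be non-negative")
        if abs(self.q.sum() - 1.0) > 1e-9:
            raise ValueError(f"q must sum to 1, got {self.q.sum()!r}")


@dataclass
class EstimatorOptions:
    """Convergence controls for the supervised admixture EM."""

    max_iter: int = 2000
    tol: float = 1e-8
    freq_floor: float | None = None  # None -> add-half adaptive floor
    init: str = "uniform"
    custom_init: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.freq_floor is not None and not 0 < self.freq_floor < 0.5:
            raise ValueError("freq_floor must lie in (0, 0.5)")
        if self.init not in ("uniform", "custom"):
            raise ValueError("init must be 'uniform' or 'custom'")
        if self.init == "custom" and self.custom_init is None:
            raise ValueError("init='custom' requires custom_init")


@dataclass
class PopulationFit:
    """Z-score fit of one profile against one candidate population of origin."""

    population: str
    loglik: float
    expected_loglik: float
    var_loglik: float
    z: float
    p_value: float
    accepted: bool


@dataclass
class AssignmentOutcome:
    """Per-sample assignment: fits for every candidate population plus a label."""

    sample_id: str
    fits: list[PopulationFit]
    label: str | None = None  # rejected / concordant / discordant / ambiguous
    true_population: str | None = None

    def accepted_populations(self) -> list[str]:
        return [f.population for f in self.fits if f.accepted]

    def fit_for(self, population: str) -> PopulationFit:
        for f in self.fits:
            if f.population == population:
                return f
        raise KeyError(f"no fit for population {population!r}")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic trihybrid scenario.

    Defaults emulate an admixed South American cohort drawing on three
    continental sources with unequal drift (AFR-like, EUR-like, NAM-like):
    210 unlinked biallelic markers, reference samples of 100/100/47, and
    individual admixture Dirichlet-distributed around a dominant European
    component (mean 0.540/0.385/0.075).
    """

    K: int = 3
    L: int = 210
    drift_F: tuple[float, ...] = (0.70, 0.30, 0.70)
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    dirichlet_alpha: tuple[float, ...] = (3.85, 5.40, 0.75)  # aligned with (AFR, EUR, NAM)
    n_ref: tuple[int, ...] = (100, 100, 47)
    n_individuals: int = 214
    n_families: int = 65
    offspring_per_family: int = 2
    missing_rate: float = 0.0
    monomorphic_fraction: float = 0.0
    monomorphic_population: int = 0
    population_names: tuple[str, ...] = ("AFR", "EUR", "NAM")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        for name, vec in (
            ("drift_F", self.drift_F),
            ("dirichlet_alpha", self.dirichlet_alpha),
            ("n_ref", self.n_ref),
            ("population_names", self.population_names),
        ):
            if len(vec) != self.K:
                raise ValueError(f"{name} must have length K={self.K}")
        if not all(0.0 <= f < 1.0 for f in self.drift_F):
            raise ValueError("drift_F entries must lie in [0, 1)")
        if not all(a > 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must be a sub-interval of (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.monomorphic_fraction < 1.0:
            raise ValueError("monomorphic_fraction must lie in [0, 1)")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)
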