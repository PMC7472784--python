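"""Z-score biogeographical-ancestry assignment with leave-one-out references.

A profile is scored against each candidate population by its genotype
log-likelihood ``l = sum_l ln P(g_l)`` under that population's genotype-class
probabilities.  Because loci are unlinked, the mean and variance of ``l``
under the hypothesis that the profile originates from the population are
sums of per-locus moments, giving the standardized outlier statistic

    z = (E[l] - l) / sqrt(Var[l]),

large positive z meaning the profile fits the population far worse than a
typical member; the population is rejected when z exceeds a one-sided normal
threshold (default 1.64, p < 0.05).

Genotype-class probabilities come in two modes: ``plugin`` uses
Hardy-Weinberg proportions at the sample frequency, while ``posterior``
(default) integrates over a Jeffreys Beta posterior of the allele frequency
and thereby accounts for the sampling variance of the reference frequencies.

Outcomes are classified against a known true population as concordant,
discordant or ambiguous using a log10 likelihood-ratio rule among the
accepted populations, or rejected when no population is accepted.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import AssignmentOutcome, GenotypeMatrix, PopulationFit

__all__ = [
    "locus_genotype_probs",
    "assignment_z",
    "loo_assign",
    "classify_outcome",
    "ZScoreAssigner",
]

DEFAULT_Z_THRESHOLD = 1.64
DEFAULT_LR_LOG10 = 1.0


def locus_genotype_probs(alt_count, n_chrom, mode: str = "posterior") -> np.ndarray:
    """Genotype-class probabilities (P_homref, P_het, P_homalt) per locus.

    ``plugin``: Hardy-Weinberg proportions at ``p_hat = x/n``.
    ``posterior``: moments of a Beta(x + 1/2, n - x + 1/2) posterior —
    ``P_homalt = E[p^2]``, ``P_het = 2(E[p] - E[p^2])``.
    Accepts scalars or aligned arrays; returns shape ``(..., 3)``.
    """
    x = np.asarray(alt_count, dtype=float)
    n = np.asarray(n_chrom, dtype=float)
    if (n <= 0).any():
        raise ValueError("n_chrom must be positive")
    if ((x < 0) | (x > n)).any():
        raise ValueError("alt_count must lie in [0, n_chrom]")
    if mode == "plugin":
        p = x / n
        ep, ep2 = p, p**2
    elif mode == "posterior":
        alpha = x + 0.5
        beta = n - x + 0.5
        ep = alpha / (alpha + beta)
        ep2 = alpha * (alpha + 1.0) / ((alpha + beta) * (alpha + beta + 1.0))
    else:
        raise ValueError("mode must be 'plugin' or 'posterior'")
    p_homalt = ep2
    p_het = 2.0 * (ep - ep2)
    p_homref = 1.0 - p_het - p_homalt
    return np.stack([p_homref, p_het, p_homalt], axis=-1)


def _loglik_moments(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus E and Var of the genotype log-likelihood contribution."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(probs)
        plogp = np.where(probs > 0, probs * logp, 0.0)
        plog2p = np.where(probs > 0, probs * logp**2, 0.0)
    e = plogp.sum(axis=-1)
    v = plog2p.sum(axis=-1) - e**2
    return e, v


def assignment_z(
    dosages,
    alt_count,
    n_chrom,
    population: str = "pop",
    mode: str = "posterior",
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> PopulationFit:
    """Z-score fit of one profile against one candidate population.

    Missing loci are dropped jointly from the observed log-likelihood and
    its moments, so the statistic stays calibrated per included locus.
    """
    d = np.asarray(dosages, dtype=float)
    mask = ~np.isnan(d)
    if not mask.any():
        raise ValueError("no non-missing loci")
    probs = locus_genotype_probs(
        np.asarray(alt_count, dtype=float)[mask],
        np.asarray(n_chrom, dtype=float)[mask],
        mode,
    )
    classes = d[mask].astype(int)
    with np.errstate(divide="ignore"):
        obs = np.log(probs[np.arange(len(classes)), classes])
    e, v = _loglik_moments(probs)
    var = float(v.sum())
    if var <= 0:
        raise ValueError("zero log-likelihood variance: all loci deterministic")
    loglik = float(obs.sum())
    expected = float(e.sum())
    z = (expected - loglik) / np.sqrt(var)
    p_value = float(1.0 - ndtr(z))
    return PopulationFit(
        population=population,
        loglik=loglik,
        expected_loglik=expected,
        var_loglik=var,
        z=float(z),
        p_value=p_value,
        accepted=bool(z <= threshold),
    )


def _pop_counts(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus ALT-allele counts and typed chromosome counts."""
    d = g.dosages
    x = np.nansum(d, axis=0)
    n = 2.0 * (~np.isnan(d)).sum(axis=0)
    return x, n


def loo_assign(
    g: GenotypeMatrix,
    pop_labels: dict[str, str],
    query_ids=None,
    mode: str = "posterior",
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> list[AssignmentOutcome]:
    """Assign each query against every labelled population, leave-one-out.

    ``pop_labels`` maps reference sample ids to population names.  A query
    that is itself a labelled member of a population is excluded from that
    population's allele counts before being scored against it; external
    queries see the full reference counts.
    """
    populations = list(dict.fromkeys(pop_labels.values()))
    members: dict[str, list[int]] = {p: [] for p in populations}
    row_of = {s: i for i, s in enumerate(g.sample_ids)}
    for s, p in pop_labels.items():
        if s not in row_of:
            raise KeyError(f"labelled sample {s!r} not in genotype matrix")
        members[p].append(row_of[s])
    counts = {}
    for p in populations:
        sub = g.dosages[members[p]]
        counts[p] = (
            np.nansum(sub, axis=0),
            2.0 * (~np.isnan(sub)).sum(axis=0),
        )
    if query_ids is None:
        query_ids = list(g.sample_ids)
    outcomes = []
    for qid in query_ids:
        i = row_of[qid]
        d = g.dosages[i]
        typed = ~np.isnan(d)
        fits = []
        for p in populations:
            x, n = counts[p]
            if pop_labels.get(qid) == p:
                x = x - np.where(typed, d, 0.0)
                n = n - np.where(typed, 2.0, 0.0)
                if (n[typed] <= 0).any():
                    raise ValueError(
                        f"excluding {qid!r} empties population {p!r} at some loci"
                    )
            fits.append(
                assignment_z(d, x, n, population=p, mode=mode, threshold=threshold)
            )
        outcomes.append(AssignmentOutcome(sample_id=qid, fits=fits))
    return outcomes


def classify_outcome(
    fits: list[PopulationFit] | AssignmentOutcome,
    true_population: str,
    lr_log10_threshold: float = DEFAULT_LR_LOG10,
) -> AssignmentOutcome:
    """Four-way outcome label given the true population of origin.

    rejected — no population accepted; concordant — the true population is
    accepted and either uniquely so or with a log10 likelihood-ratio of at
    least the threshold over every other accepted population; discordant —
    another population is accepted while the true one is rejected or beaten
    by at least the threshold; ambiguous — multiple acceptances with
    non-significantly different likelihoods.
    """
    if isinstance(fits, AssignmentOutcome):
        sample_id, fit_list = fits.sample_id, fits.fits
    else:
        sample_id, fit_list = "sample", list(fits)
    pops = [f.population for f in fit_list]
    if true_population not in pops:
        raise ValueError(f"true population {true_population!r} not among fits")
    accepted = [f for f in fit_list if f.accepted]
    if not accepted:
        label = "rejected"
    else:
        true_fit = next(f for f in fit_list if f.population == true_population)
        others = [f for f in accepted if f.population != true_population]
        if true_fit.accepted:
            if not others:
                label = "concordant"
            else:
                margins = [
                    (true_fit.loglik - f.loglik) / np.log(10.0) for f in others
                ]
                if all(m >= lr_log10_threshold for m in margins):
                    label = "concordant"
                elif any(m <= -lr_log10_threshold for m in margins):
                    label = "discordant"
                else:
                    label = "ambiguous"
        else:
            label = "discordant"
    return AssignmentOutcome(
        sample_id=sample_id,
        fits=fit_list,
        label=label,
        true_population=true_population,
    )


class ZScoreAssigner(ClassifierMixin, BaseEstimator):
    """Z-score population-of-origin classifier (scikit-learn style).

    ``fit(X, y)`` stores per-population allele counts from reference dosages
    ``X`` labelled by ``y``; ``decision_function(X)`` returns ``-z`` per
    population (higher = better fit); ``predict(X)`` returns the accepted
    population with the smallest z, or ``"rejected"``.
    """

    def __init__(
        self,
        mode: str = "posterior",
        threshold: float = DEFAULT_Z_THRESHOLD,
        lr_log10_threshold: float = DEFAULT_LR_LOG10,
    ):
        self.mode = mode
        self.threshold = threshold
        self.lr_log10_threshold = lr_log10_threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.array(list(dict.fromkeys(y.tolist())))
        self.counts_ = {}
        for pop in self.classes_:
            sub = X[y == pop]
            self.counts_[pop] = (
                np.nansum(sub, axis=0),
                2.0 * (~np.isnan(sub)).sum(axis=0),
            )
        self.n_features_in_ = X.shape[1]
        return self

    def _fits(self, X) -> list[list[PopulationFit]]:
        check_is_fitted(self, "counts_")
        X = np.asarray(X, dtype=float)
        out = []
        for row in X:
            out.append(
                [
                    assignment_z(
                        row,
                        *self.counts_[pop],
                        population=pop,
                        mode=self.mode,
                        threshold=self.threshold,
                    )
                    for pop in self.classes_
                ]
            )
        return out

    def decision_function(self, X) -> np.ndarray:
        return np.array([[-f.z for f in fits] for fits in self._fits(X)])

    def predict(self, X) -> np.ndarray:
        labels = []
        for fits in self._fits(X):
            accepted = [f for f in fits if f.accepted]
            if not accepted:
                labels.append("rejected")
            else:
                labels.append(min(accepted, key=lambda f: f.z).population)
        return np.array(labels)

    def assign(self, X, sample_ids=None) -> list[AssignmentOutcome]:
        fits = self._fits(X)
        ids = sample_ids or [f"sample_{i}" for i in range(len(fits))]
        return [AssignmentOutcome(sample_id=s, fits=f) for s, f in zip(ids, fits)]
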