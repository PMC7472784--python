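"""Supervised maximum-likelihood estimation of individual admixture.

Each individual's genotype at locus l is modelled as two independent allele
draws with ALT probability ``pi_l = sum_k q_k p_kl``, where ``p_kl`` are
fixed (smoothed) reference ALT frequencies of the K source populations and
``q`` is the individual's admixture vector on the K-simplex.  ``q`` is
estimated by EM; for fixed frequencies the log-likelihood is concave in
``q``, so the maximizer is unique up to flat directions and the uniform
start only affects iteration count.

This is the deterministic, supervised counterpart of population-assisted
Bayesian clustering: reference allele frequencies are treated as known and
only the admixture proportions are inferred, which removes all Monte-Carlo
noise from downstream precision metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import (
    AncestryVector,
    EstimatorOptions,
    GenotypeMatrix,
    MarkerPanel,
    ReferenceFrequencies,
)

__all__ = [
    "SupervisedAdmixture",
    "admixture_loglik",
    "estimate_ancestry",
    "estimate_cohort",
    "cohort_summary",
    "ancestry_frame",
    "simplex_grid",
    "grid_search_ancestry",
    "grid_search_cohort",
]

_FLAT_EPS = 1e-12


def admixture_loglik(dosages, q, f: ReferenceFrequencies, freq_floor: float | None = None) -> float:
    """Log-likelihood of one individual's dosages under admixture vector ``q``.

    ``l(q) = sum_l [ a_l ln(pi_l) + (2 - a_l) ln(1 - pi_l) ]`` over
    non-missing loci, with ``pi_l = sum_k q_k p~_kl`` and smoothed
    frequencies ``p~``.
    """
    a = np.asarray(dosages, dtype=float)
    q = np.asarray(q, dtype=float)
    if q.shape != (f.n_populations,):
        raise ValueError(
            f"q has length {q.shape}, expected K={f.n_populations}"
        )
    if a.shape != (f.n_markers,):
        raise ValueError("dosage vector length does not match frequency table")
    p = f.smoothed(freq_floor)
    pi = q @ p
    mask = ~np.isnan(a)
    a = a[mask]
    pi = pi[mask]
    return float(a @ np.log(pi) + (2.0 - a) @ np.log1p(-pi))


def _em_batch(
    D: np.ndarray,
    P: np.ndarray,
    opts: EstimatorOptions,
    record_trace: bool = False,
):
    """Batched EM over individuals (rows of D) with per-individual convergence.

    Returns (Q, loglik, converged, n_iter, traces).  Monotone in the
    log-likelihood by the standard EM argument; the simplex constraint is
    conserved exactly because the per-locus responsibilities sum to the
    allele count.
    """
    n, L = D.shape
    K = P.shape[0]
    A = np.where(np.isnan(D), 0.0, D)
    B = np.where(np.isnan(D), 0.0, 2.0 - D)
    n_loci = (~np.isnan(D)).sum(axis=1).astype(float)
    if (n_loci == 0).any():
        raise ValueError("every individual needs at least one non-missing locus")

    flat = bool(np.all(P.max(axis=0) - P.min(axis=0) < _FLAT_EPS))

    if opts.init == "custom":
        Q = np.tile(np.asarray(opts.custom_init, dtype=float), (n, 1))
    else:
        Q = np.full((n, K), 1.0 / K)

    def ll(Qc, rows):
        Pi = Qc @ P
        return (A[rows] * np.log(Pi) + B[rows] * np.log1p(-Pi)).sum(axis=1)

    prev = ll(Q, slice(None))
    traces = [prev.copy()] if record_trace else None
    converged = np.zeros(n, dtype=bool)
    if flat:
        return Q, prev, np.ones(n, dtype=bool), 0, traces

    it = 0
    active = np.arange(n)
    for it in range(1, opts.max_iter + 1):
        Qa = Q[active]
        Pi = Qa @ P
        with np.errstate(divide="ignore", invalid="ignore"):
            T = (A[active] / Pi) @ P.T + (B[active] / (1.0 - Pi)) @ (1.0 - P).T
        Qnew = Qa * T / (2.0 * n_loci[active])[:, None]
        # exact renormalization against accumulated rounding
        Qnew /= Qnew.sum(axis=1, keepdims=True)
        Q[active] = Qnew
        cur_active = ll(Qnew, active)
        delta = cur_active - prev[active]
        prev[active] = cur_active
        if record_trace:
            traces.append(prev.copy())
        newly = delta < opts.tol
        converged[active[newly]] = True
        active = active[~newly]
        if active.size == 0:
            break
    return Q, prev, converged, it, traces


def estimate_ancestry(
    dosages,
    f: ReferenceFrequencies,
    opts: EstimatorOptions | None = None,
    sample_id: str = "sample",
) -> AncestryVector:
    """Supervised ML admixture estimate for one individual."""
    opts = opts or EstimatorOptions()
    a = np.asarray(dosages, dtype=float)[None, :]
    P = f.smoothed(opts.freq_floor)
    Q, llk, conv, _, _ = _em_batch(a, P, opts)
    flat = bool(np.all(P.max(axis=0) - P.min(axis=0) < _FLAT_EPS))
    informative = int(np.sum(~np.isnan(a[0]) & (P.max(axis=0) - P.min(axis=0) >= _FLAT_EPS)))
    return AncestryVector(
        sample_id=sample_id,
        q=Q[0],
        loglik=float(llk[0]),
        n_informative_loci=informative,
        converged=bool(conv[0]),
        flat_likelihood=flat,
    )


def estimate_cohort(
    g: GenotypeMatrix,
    f: ReferenceFrequencies,
    panel: MarkerPanel | list[str] | None = None,
    opts: EstimatorOptions | None = None,
) -> tuple[list[AncestryVector], pd.DataFrame]:
    """Per-individual estimates restricted to a panel, plus a cohort summary."""
    opts = opts or EstimatorOptions()
    if panel is not None:
        ids = list(panel.marker_ids if isinstance(panel, MarkerPanel) else panel)
        if not ids:
            raise ValueError("empty panel")
        g = g.subset_markers(ids)
        f = f.subset_markers(ids)
    elif g.marker_ids != f.marker_ids:
        f = f.subset_markers(g.marker_ids)
    P = f.smoothed(opts.freq_floor)
    Q, llk, conv, _, _ = _em_batch(g.dosages, P, opts)
    flat = bool(np.all(P.max(axis=0) - P.min(axis=0) < _FLAT_EPS))
    info_cols = P.max(axis=0) - P.min(axis=0) >= _FLAT_EPS
    results = [
        AncestryVector(
            sample_id=s,
            q=Q[i],
            loglik=float(llk[i]),
            n_informative_loci=int(np.sum(~np.isnan(g.dosages[i]) & info_cols)),
            converged=bool(conv[i]),
            flat_likelihood=flat,
        )
        for i, s in enumerate(g.sample_ids)
    ]
    return results, cohort_summary(results, f.populations)


def cohort_summary(results: list[AncestryVector], components) -> pd.DataFrame:
    """Mean, SD, variance, min, max of q per ancestry component."""
    Q = np.array([r.q for r in results])
    return pd.DataFrame(
        {
            "component": list(components),
            "mean": Q.mean(axis=0),
            "sd": Q.std(axis=0, ddof=1) if len(results) > 1 else np.zeros(Q.shape[1]),
            "variance": Q.var(axis=0, ddof=1) if len(results) > 1 else np.zeros(Q.shape[1]),
            "min": Q.min(axis=0),
            "max": Q.max(axis=0),
        }
    )


def ancestry_frame(results: list[AncestryVector], components) -> pd.DataFrame:
    """Estimates as a DataFrame indexed by sample id (one column per component)."""
    return pd.DataFrame(
        [r.q for r in results],
        index=[r.sample_id for r in results],
        columns=list(components),
    )


# ---------------------------------------------------------------------------
# Brute-force cross-check
# ---------------------------------------------------------------------------

def simplex_grid(K: int, step: float) -> np.ndarray:
    """All points of the K-simplex lattice with the given step (K <= 3 exact)."""
    m = int(round(1.0 / step))
    if K == 1:
        return np.array([[1.0]])
    if K == 2:
        i = np.arange(m + 1)
        return np.column_stack([i, m - i]) / m
    if K == 3:
        i, j = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
        keep = (i + j) <= m
        i, j = i[keep], j[keep]
        return np.column_stack([i, j, m - i - j]) / m
    raise NotImplementedError("simplex_grid supports K <= 3")


def grid_search_ancestry(
    dosages,
    f: ReferenceFrequencies,
    step: float = 0.001,
    freq_floor: float | None = None,
    chunk: int = 100_000,
) -> np.ndarray:
    """Exhaustive simplex grid maximizer of the admixture likelihood.

    Independent of the EM path: evaluates the log-likelihood at every lattice
    point and returns the argmax (first in lexicographic grid order on ties).
    Intended as a brute-force cross-check at small problem sizes.
    """
    a = np.asarray(dosages, dtype=float)
    P = f.smoothed(freq_floor)
    grid = simplex_grid(f.n_populations, step)
    mask = ~np.isnan(a)
    av = a[mask]
    Pm = P[:, mask]
    best_val, best_q = -np.inf, None
    for start in range(0, len(grid), chunk):
        G = grid[start : start + chunk]
        Pi = G @ Pm
        vals = np.log(Pi) @ av + np.log1p(-Pi) @ (2.0 - av)
        j = int(np.argmax(vals))
        if vals[j] > best_val:
            best_val, best_q = float(vals[j]), G[j]
    return best_q


def grid_search_cohort(
    g: GenotypeMatrix,
    f: ReferenceFrequencies,
    step: float = 0.001,
    freq_floor: float | None = None,
    chunk: int = 50_000,
) -> np.ndarray:
    """Batched :func:`grid_search_ancestry` over a cohort with no missing calls.

    The grid log-probabilities are computed once per chunk and shared across
    individuals, so the cost is one matrix product per chunk instead of one
    full grid sweep per individual.  Requires a complete (no-NaN) matrix;
    with missingness fall back to the per-individual search.
    """
    D = g.dosages
    if np.isnan(D).any():
        return np.array(
            [grid_search_ancestry(row, f, step, freq_floor, chunk) for row in D]
        )
    P = f.smoothed(freq_floor)
    grid = simplex_grid(f.n_populations, step)
    n = D.shape[0]
    best_val = np.full(n, -np.inf)
    best_q = np.zeros((n, f.n_populations))
    A = D.T  # (L, n)
    B = 2.0 - A
    for start in range(0, len(grid), chunk):
        G = grid[start : start + chunk]
        Pi = G @ P
        vals = np.log(Pi) @ A + np.log1p(-Pi) @ B  # (chunk, n)
        j = np.argmax(vals, axis=0)
        v = vals[j, np.arange(n)]
        better = v > best_val
        best_val[better] = v[better]
        best_q[better] = G[j[better]]
    return best_q


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class SupervisedAdmixture(TransformerMixin, BaseEstimator):
    """Supervised admixture-proportion estimator (scikit-learn style).

    ``fit(X, y)`` learns per-population ALT-allele frequencies from reference
    genotypes ``X`` (n_samples x n_markers dosages, NaN = missing) labelled by
    source population ``y``; ``transform(X)`` returns the (n_samples, K)
    matrix of estimated admixture proportions.  Alternatively construct from
    a pre-computed frequency table with :meth:`from_frequencies`.

    Parameters
    ----------
    max_iter, tol
        EM stopping rule (absolute log-likelihood change).
    freq_floor
        Constant frequency floor, or None for the adaptive add-half floor
        ``1/(2 n_chrom + 2)`` per population and locus.
    """

    def __init__(self, max_iter: int = 2000, tol: float = 1e-8, freq_floor: float | None = None):
        self.max_iter = max_iter
        self.tol = tol
        self.freq_floor = freq_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        pops = list(dict.fromkeys(y.tolist()))
        L = X.shape[1]
        p = np.empty((len(pops), L))
        n = np.empty((len(pops), L))
        for i, pop in enumerate(pops):
            sub = X[y == pop]
            called = (~np.isnan(sub)).sum(axis=0).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                p[i] = np.where(called > 0, np.nansum(sub, axis=0) / (2 * called), np.nan)
            n[i] = 2 * called
        self.populations_ = pops
        self.frequencies_ = ReferenceFrequencies(
            pops, [f"m{j}" for j in range(L)], p, np.maximum(n, 2)
        )
        self.n_features_in_ = L
        return self

    @classmethod
    def from_frequencies(cls, f: ReferenceFrequencies, **params) -> "SupervisedAdmixture":
        est = cls(**params)
        est.populations_ = list(f.populations)
        est.frequencies_ = f
        est.n_features_in_ = f.n_markers
        return est

    def _options(self) -> EstimatorOptions:
        return EstimatorOptions(max_iter=self.max_iter, tol=self.tol, freq_floor=self.freq_floor)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "frequencies_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must have {self.n_features_in_} columns")
        P = self.frequencies_.smoothed(self.freq_floor)
        Q, _, _, _, _ = _em_batch(X, P, self._options())
        return Q

    def score(self, X, y=None) -> float:
        """Mean per-individual maximized log-likelihood."""
        check_is_fitted(self, "frequencies_")
        X = np.asarray(X, dtype=float)
        P = self.frequencies_.smoothed(self.freq_floor)
        _, llk, _, _, _ = _em_batch(X, P, self._options())
        return float(np.mean(llk))
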