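"""Marker-panel construction by balanced differentiation criteria.

Two selection strategies over pairwise Weir-Cockerham theta-hat:

* ``max_balanced`` — maximize the smallest pairwise theta-hat (ties broken
  by smaller spread max-min over pairs, then lexicographically by marker
  ids), i.e. "highest and most balanced" differentiation;
* ``balance_first`` — minimize the spread max-min over pairwise theta-hat
  subject to the smallest pair staying above a configurable floor, i.e.
  equal levels of differentiation between all reference pairs.

Multi-locus theta-hat is a ratio of summed variance components, so a
panel's value is not a sum of per-locus scores; the search therefore
re-evaluates the full ratio for every candidate.  Search is exhaustive when
the subset count is small, otherwise greedy forward selection refined by a
deterministic best-improvement swap pass with the same objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .datatypes import GenotypeMatrix, MarkerPanel, ReferenceFrequencies
from .popgen import FstMatrix, _pair_tables, fst_components, pairwise_fst

__all__ = [
    "SelectionObjective",
    "SelectionResult",
    "panel_fst",
    "select_panel",
    "BalancedPanelSelector",
]


def panel_fst(
    data: ReferenceFrequencies | dict[str, GenotypeMatrix],
    panel: MarkerPanel,
) -> FstMatrix:
    """Pairwise multi-locus theta-hat restricted to a panel's loci."""
    if len(panel) == 0:
        raise ValueError("panel is empty")
    return pairwise_fst(data, panel)


@dataclass
class SelectionObjective:
    """Configuration of one panel-selection run."""

    strategy: str = "max_balanced"
    size: int = 40
    min_fst_floor: float = 0.0  # balance_first feasibility floor
    priority_pair: tuple[str, str] | None = None
    exhaustive_limit: int = 100_000

    def __post_init__(self) -> None:
        if self.strategy not in ("max_balanced", "balance_first"):
            raise ValueError("strategy must be 'max_balanced' or 'balance_first'")
        if self.size < 1:
            raise ValueError("size must be >= 1")


@dataclass
class SelectionResult:
    panel: MarkerPanel
    fst: FstMatrix
    objective_value: float
    search_mode: str
    feasible: bool = True
    pairwise: dict = field(default_factory=dict)


class _PairComponents:
    """Per-locus Weir-Cockerham numerators/denominators for every population pair."""

    def __init__(self, data, marker_ids=None):
        if isinstance(data, ReferenceFrequencies):
            freqs, genos = data, None
            all_markers = data.marker_ids
        else:
            freqs, genos = None, data
            all_markers = next(iter(data.values())).marker_ids
        self.marker_ids = list(marker_ids) if marker_ids is not None else list(all_markers)
        pops, n, p, h = _pair_tables(freqs, genos, self.marker_ids)
        self.populations = pops
        self.pair_names = list(combinations(pops, 2))
        num, den = [], []
        for i, j in combinations(range(len(pops)), 2):
            a, b, c = fst_components(n[[i, j]], p[[i, j]], h[[i, j]])
            d = a + b + c
            bad = np.isnan(d)
            a = np.where(bad, 0.0, a)
            d = np.where(bad, 0.0, d)
            num.append(a)
            den.append(d)
        self.num = np.array(num)  # (n_pairs, L)
        self.den = np.array(den)

    def theta(self, idx) -> np.ndarray:
        """Pairwise multi-locus theta-hat of the subset ``idx`` (locus indices)."""
        idx = np.asarray(idx, dtype=int)
        num = self.num[:, idx].sum(axis=1)
        den = self.den[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den != 0, num / den, np.nan)


def _objective_key(theta: np.ndarray, objective: SelectionObjective, comp: _PairComponents):
    """Larger key = better panel; NaN pairs make a panel infeasible."""
    if np.isnan(theta).any():
        return (-np.inf,)
    lo, hi = float(theta.min()), float(theta.max())
    spread = hi - lo
    prio = 0.0
    if objective.priority_pair is not None:
        pair = tuple(sorted(objective.priority_pair))
        for (a, b), t in zip(comp.pair_names, theta):
            if tuple(sorted((a, b))) == pair:
                prio = float(t)
                break
        else:
            raise KeyError(f"priority pair {objective.priority_pair!r} not found")
    if objective.strategy == "max_balanced":
        return (lo, -spread, prio)
    feasible = lo >= objective.min_fst_floor
    return (1.0 if feasible else 0.0, -spread, lo, prio)


def _tie_break_ids(comp: _PairComponents, idx) -> tuple[str, ...]:
    return tuple(sorted(comp.marker_ids[i] for i in idx))


def select_panel(
    data: ReferenceFrequencies | dict[str, GenotypeMatrix],
    objective: SelectionObjective,
    panel_id: str | None = None,
) -> SelectionResult:
    """Select ``objective.size`` markers optimizing the configured criterion.

    Deterministic: ties are broken by the lexicographically smallest sorted
    marker-id tuple.  With ``balance_first`` an unreachable floor yields
    ``feasible=False`` (the best-spread panel is still reported) rather than
    silently relaxing the constraint.
    """
    comp = _PairComponents(data)
    n = len(comp.marker_ids)
    if objective.size > n:
        raise ValueError(f"size {objective.size} exceeds {n} available markers")
    if comb(n, objective.size) <= objective.exhaustive_limit:
        idx, mode = _search_exhaustive(comp, objective), "exhaustive"
    else:
        idx, mode = _search_greedy(comp, objective), "greedy+swap"
    theta = comp.theta(idx)
    key = _objective_key(theta, objective, comp)
    feasible = key[0] != -np.inf and (
        objective.strategy != "balance_first" or key[0] == 1.0
    )
    ordered = sorted(idx)
    panel = MarkerPanel(
        panel_id or f"{objective.strategy}_{objective.size}",
        [comp.marker_ids[i] for i in ordered],
    )
    k = len(comp.populations)
    values = np.zeros((k, k))
    for (a, b), t in zip(combinations(range(k), 2), theta):
        values[a, b] = values[b, a] = t
    fst = FstMatrix(comp.populations, values)
    obj_value = float(theta.min()) if objective.strategy == "max_balanced" else float(
        theta.max() - theta.min()
    )
    return SelectionResult(
        panel=panel,
        fst=fst,
        objective_value=obj_value,
        search_mode=mode,
        feasible=bool(feasible),
        pairwise={f"{a}-{b}": float(t) for (a, b), t in zip(comp.pair_names, theta)},
    )


def _search_exhaustive(comp: _PairComponents, objective: SelectionObjective):
    best_key, best_ids, best_idx = None, None, None
    for idx in combinations(range(len(comp.marker_ids)), objective.size):
        key = _objective_key(comp.theta(idx), objective, comp)
        ids = _tie_break_ids(comp, idx)
        if best_key is None or key > best_key or (key == best_key and ids < best_ids):
            best_key, best_ids, best_idx = key, ids, list(idx)
    return best_idx


_MAX_STARTS = 32


def _candidate_keys(num_new, den_new, objective, comp, prio_idx):
    """Vectorized objective keys for candidate panels given summed components.

    Returns arrays aligned with candidates; larger is better in lexicographic
    order (feasibility only enters for balance_first; NaN pairs -> -inf).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den_new != 0, num_new / den_new, np.nan)
    bad = np.isnan(theta).any(axis=0)
    lo = np.where(bad, -np.inf, np.where(np.isnan(theta), np.inf, theta).min(axis=0))
    hi = np.where(bad, np.inf, np.where(np.isnan(theta), -np.inf, theta).max(axis=0))
    spread = hi - lo
    prio = theta[prio_idx] if prio_idx is not None else np.zeros(theta.shape[1])
    prio = np.where(bad, -np.inf, prio)
    return lo, spread, prio


def _best_candidate(num_new, den_new, objective, comp, prio_idx, id_ranks):
    """Index of the best candidate column, deterministic id tie-break."""
    lo, spread, prio = _candidate_keys(num_new, den_new, objective, comp, prio_idx)
    if objective.strategy == "max_balanced":
        order = np.lexsort((id_ranks, -prio, spread, -lo))
    else:
        feas = (lo >= objective.min_fst_floor) & np.isfinite(lo)
        order = np.lexsort((id_ranks, -prio, -lo, spread, ~feas))
    return int(order[0])


def _search_greedy(comp: _PairComponents, objective: SelectionObjective):
    """Deterministic multi-start greedy with best-improvement swap refinement.

    Forward selection is run once unseeded and once seeded from each of up to
    ``_MAX_STARTS`` candidate markers (lexicographic id order); every run is
    refined by steepest-ascent single swaps, and the best panel over all
    starts is returned.  The spread objective is far from submodular, so the
    multi-start and swap passes are what make the heuristic reliably reach
    the exhaustive optimum at small instance sizes.
    """
    n = len(comp.marker_ids)
    id_ranks = np.argsort(np.argsort(comp.marker_ids))
    prio_idx = None
    if objective.priority_pair is not None:
        pair = tuple(sorted(objective.priority_pair))
        for pi, (a, b) in enumerate(comp.pair_names):
            if tuple(sorted((a, b))) == pair:
                prio_idx = pi
                break
        else:
            raise KeyError(f"priority pair {objective.priority_pair!r} not found")

    by_id = sorted(range(n), key=lambda i: comp.marker_ids[i])
    seeds: list[list[int]] = [[]]
    seeds += [[i] for i in by_id[:_MAX_STARTS]]
    if objective.size >= 2 and comb(n, 2) <= 4 * _MAX_STARTS:
        seeds += [list(pair) for pair in combinations(by_id, 2)]

    best_key, best_ids, best_panel = None, None, None
    for seed in seeds:
        chosen = _greedy_fill(comp, objective, list(seed), prio_idx, id_ranks)
        chosen = _swap_refine(comp, objective, chosen, prio_idx, id_ranks)
        key = _objective_key(comp.theta(chosen), objective, comp)
        ids = _tie_break_ids(comp, chosen)
        if best_key is None or key > best_key or (key == best_key and ids < best_ids):
            best_key, best_ids, best_panel = key, ids, chosen
    return sorted(best_panel)


def _greedy_fill(comp, objective, chosen, prio_idx, id_ranks):
    n = len(comp.marker_ids)
    in_panel = np.zeros(n, dtype=bool)
    in_panel[chosen] = True
    cur_num = comp.num[:, chosen].sum(axis=1) if chosen else np.zeros(comp.num.shape[0])
    cur_den = comp.den[:, chosen].sum(axis=1) if chosen else np.zeros(comp.den.shape[0])
    while len(chosen) < objective.size:
        cands = np.flatnonzero(~in_panel)
        num_new = cur_num[:, None] + comp.num[:, cands]
        den_new = cur_den[:, None] + comp.den[:, cands]
        j = _best_candidate(num_new, den_new, objective, comp, prio_idx, id_ranks[cands])
        pick = int(cands[j])
        chosen.append(pick)
        in_panel[pick] = True
        cur_num += comp.num[:, pick]
        cur_den += comp.den[:, pick]
    return chosen


def _swap_refine(comp, objective, chosen, prio_idx, id_ranks, max_passes: int = 50):
    n = len(comp.marker_ids)
    chosen = list(chosen)
    cur_key = _objective_key(comp.theta(chosen), objective, comp)
    cur_ids = _tie_break_ids(comp, chosen)
    for _ in range(max_passes):
        in_panel = np.zeros(n, dtype=bool)
        in_panel[chosen] = True
        out_idx = np.flatnonzero(~in_panel)
        if out_idx.size == 0:
            break
        tot_num = comp.num[:, chosen].sum(axis=1)
        tot_den = comp.den[:, chosen].sum(axis=1)
        best = (cur_key, cur_ids, None)
        for out in chosen:
            base_num = tot_num - comp.num[:, out]
            base_den = tot_den - comp.den[:, out]
            num_new = base_num[:, None] + comp.num[:, out_idx]
            den_new = base_den[:, None] + comp.den[:, out_idx]
            j = _best_candidate(
                num_new, den_new, objective, comp, prio_idx, id_ranks[out_idx]
            )
            inc = int(out_idx[j])
            trial = [i for i in chosen if i != out] + [inc]
            key = _objective_key(comp.theta(trial), objective, comp)
            ids = _tie_break_ids(comp, trial)
            if key > best[0] or (key == best[0] and ids < best[1]):
                best = (key, ids, (out, inc))
        if best[2] is None:
            break
        out, inc = best[2]
        chosen.remove(out)
        chosen.append(inc)
        cur_key, cur_ids = best[0], best[1]
    return chosen


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted


class BalancedPanelSelector(SelectorMixin, BaseEstimator):
    """Feature selector picking markers with balanced pairwise differentiation.

    ``fit(X, y)`` takes reference genotype dosages ``X`` (NaN = missing)
    labelled by source population ``y`` and selects ``size`` markers with the
    configured strategy; ``transform(X)`` keeps only the selected columns.
    """

    def __init__(
        self,
        size: int = 40,
        strategy: str = "max_balanced",
        min_fst_floor: float = 0.0,
        exhaustive_limit: int = 100_000,
    ):
        self.size = size
        self.strategy = strategy
        self.min_fst_floor = min_fst_floor
        self.exhaustive_limit = exhaustive_limit

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        pops = list(dict.fromkeys(y.tolist()))
        marker_ids = [f"m{j}" for j in range(X.shape[1])]
        genotypes = {
            pop: GenotypeMatrix(
                [f"{pop}_{i}" for i in range(int((y == pop).sum()))],
                marker_ids,
                X[y == pop],
            )
            for pop in pops
        }
        objective = SelectionObjective(
            strategy=self.strategy,
            size=self.size,
            min_fst_floor=self.min_fst_floor,
            exhaustive_limit=self.exhaustive_limit,
        )
        result = select_panel(genotypes, objective)
        mask = np.zeros(X.shape[1], dtype=bool)
        index = {m: j for j, m in enumerate(marker_ids)}
        for m in result.panel.marker_ids:
            mask[index[m]] = True
        self.support_ = mask
        self.result_ = result
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
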