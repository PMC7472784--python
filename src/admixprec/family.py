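"""Family-design precision metrics for admixture estimates.

With unlinked markers and Mendelian transmission, an offspring's expected
ancestry is the average of the parental ancestries, and full siblings share
the same expectation.  Deviations from these identities, computed on
*estimated* q (never on simulation truth), measure the precision of the full
estimation pipeline: a more informative panel yields smaller parent-offspring
and sibling-sibling discrepancies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import PedigreeTable

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyDeviation",
    "SiblingDeviation",
    "parent_offspring_deviation",
    "sibling_deviation",
    "group_means",
    "component_correlation",
    "deviation_from_reference",
    "deviation_summary",
]


@dataclass
class FamilyDeviation:
    family_id: str
    offspring_id: str
    deviation: np.ndarray  # |q_offspring - mean(q_mother, q_father)| per component
    signed: np.ndarray  # q_offspring - mean(q_mother, q_father)


@dataclass
class SiblingDeviation:
    family_id: str
    sib1: str
    sib2: str
    deviation: np.ndarray  # |q_sib1 - q_sib2| per component


def _check_frame(q: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(q, pd.DataFrame):
        raise TypeError("estimates must be a DataFrame indexed by sample_id")
    return q


def deviation_summary(devs: list[np.ndarray], components) -> pd.DataFrame:
    """Mean, SD, min, max per component over a list of deviation vectors."""
    if not devs:
        return pd.DataFrame(
            columns=["component", "mean", "sd", "min", "max"]
        )
    arr = np.array(devs)
    return pd.DataFrame(
        {
            "component": list(components),
            "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1) if len(devs) > 1 else np.zeros(arr.shape[1]),
            "min": arr.min(axis=0),
            "max": arr.max(axis=0),
        }
    )


def parent_offspring_deviation(
    q: pd.DataFrame, ped: PedigreeTable
) -> tuple[list[FamilyDeviation], pd.DataFrame]:
    """Per-offspring |q_offspring - parental mean| with a cohort summary.

    Offspring whose parents lack estimates are skipped with a warning (and
    excluded from the summary).
    """
    q = _check_frame(q)
    out: list[FamilyDeviation] = []
    skipped = 0
    for _, row in ped.offspring().iterrows():
        oid = row["sample_id"]
        mid, fid = row["mother_id"], row["father_id"]
        if oid not in q.index or mid not in q.index or fid not in q.index:
            skipped += 1
            logger.warning("offspring %s skipped: missing estimate", oid)
            continue
        mid_q = (q.loc[mid].to_numpy() + q.loc[fid].to_numpy()) / 2.0
        signed = q.loc[oid].to_numpy() - mid_q
        out.append(FamilyDeviation(row["family_id"], oid, np.abs(signed), signed))
    if skipped:
        logger.warning("%d offspring skipped in parent_offspring_deviation", skipped)
    summary = deviation_summary([d.deviation for d in out], q.columns)
    return out, summary


def sibling_deviation(
    q: pd.DataFrame, ped: PedigreeTable
) -> tuple[list[SiblingDeviation], pd.DataFrame]:
    """Per-pair |q_sib1 - q_sib2| over all unordered sibling pairs."""
    q = _check_frame(q)
    out: list[SiblingDeviation] = []
    for fam, s1, s2 in ped.siblings():
        if s1 not in q.index or s2 not in q.index:
            logger.warning("sibling pair (%s, %s) skipped: missing estimate", s1, s2)
            continue
        dev = np.abs(q.loc[s1].to_numpy() - q.loc[s2].to_numpy())
        out.append(SiblingDeviation(fam, s1, s2, dev))
    summary = deviation_summary([d.deviation for d in out], q.columns)
    return out, summary


_GROUPS = ("parents", "offspring1", "offspring2", "all_offspring")


def _group_ids(ped: PedigreeTable, grouping: str) -> list[str]:
    if grouping == "parents":
        return ped.df.loc[ped.df["role"].isin(("mother", "father")), "sample_id"].tolist()
    off = ped.offspring()
    if grouping == "all_offspring":
        return off["sample_id"].tolist()
    # offspring 1 / offspring 2 identity comes from file order within family
    rank = off.groupby("family_id", sort=False).cumcount()
    if grouping == "offspring1":
        return off.loc[rank == 0, "sample_id"].tolist()
    if grouping == "offspring2":
        return off.loc[rank == 1, "sample_id"].tolist()
    raise ValueError(f"unknown grouping {grouping!r}; use one of {_GROUPS}")


def group_means(
    q: pd.DataFrame, ped: PedigreeTable, groupings=_GROUPS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-component group means and |mean_A - mean_B| for all group pairs."""
    q = _check_frame(q)
    means = {}
    for grouping in groupings:
        ids = [s for s in _group_ids(ped, grouping) if s in q.index]
        if not ids:
            logger.warning("group %s is empty", grouping)
            means[grouping] = np.full(q.shape[1], np.nan)
        else:
            means[grouping] = q.loc[ids].mean(axis=0).to_numpy()
    means_df = pd.DataFrame(means, index=q.columns).T
    rows = []
    names = list(means)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                [f"{names[i]}|{names[j]}"]
                + list(np.abs(means[names[i]] - means[names[j]]))
            )
    diffs = pd.DataFrame(rows, columns=["groups"] + list(q.columns))
    return means_df, diffs


def component_correlation(
    x: pd.DataFrame, y: pd.DataFrame, component
) -> tuple[float, float]:
    """Pearson r of one ancestry component across two estimate sets.

    Returns ``(r, mean |x - y|)``; r is NaN (flagged undefined) when either
    side has zero variance.  The two frames must cover the same samples.
    """
    x, y = _check_frame(x), _check_frame(y)
    only_x = set(x.index) - set(y.index)
    only_y = set(y.index) - set(x.index)
    if only_x or only_y:
        raise ValueError(
            f"sample mismatch: {sorted(only_x)[:5]} only in x, "
            f"{sorted(only_y)[:5]} only in y"
        )
    if len(x) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    xv = x[component].to_numpy()
    yv = y.loc[x.index, component].to_numpy()
    concordance = float(np.abs(xv - yv).mean())
    if np.std(xv) == 0 or np.std(yv) == 0:
        return float("nan"), concordance
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r, concordance


def deviation_from_reference(estimate, reference) -> tuple[np.ndarray, float]:
    """Per-component |mean estimate - reference| and their sum.

    The reference is an external per-component ancestry profile (e.g. a
    genome-wide estimate) aligned with the estimate's components.
    """
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"component mismatch: {est.shape} vs {ref.shape}")
    per = np.abs(est - ref)
    return per, float(per.sum())
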