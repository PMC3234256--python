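"""CLASP scoring: combine distance and PD deviations, rank, and evaluate.

The score of a candidate match is S = w_d * D + w_p * P with

    D = sum_pairs |d_q - d_ref| / d_ref
    P = sum_pairs |P_q - P_ref| / max(|P_ref|, P_floor)

where pairs in the PD sum are skipped when both the query and reference
PDs sit inside the near-zero ignore band (|.| < eps_zero): charge-neutral
pairs carry no electrostatic signal.  Distance deviations are normalized
by the reference distance (a 1 Å deviation matters more at 4 Å than at
8 Å) and PD deviations by the reference magnitude (deviations at large
PDs are more loosely constrained).  Lower scores mean better matches, and
a motif scored against its own reference structure scores exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from clasp.congruence import MatchGeometry, SearchParams, enumerate_candidates
from clasp.electrostatics import PotentialGrid, pair_pd
from clasp.motif_library import GroupConfig, Motif, pair_order
from clasp.structure_io import ReactiveAtomConfig, Structure


@dataclass(frozen=True)
class Weights:
    """Non-negative weights for the distance (w_d) and PD (w_p) terms."""

    w_d: float = 1.0
    w_p: float = 1.0

    def __post_init__(self) -> None:
        if self.w_d < 0 or self.w_p < 0:
            raise ValueError("weights must be non-negative")
        if self.w_d == 0 and self.w_p == 0:
            raise ValueError("at least one weight must be positive")


@dataclass(frozen=True)
class Thresholds:
    """eps_zero: both-near-zero PD ignore band; p_floor: denominator floor
    (both kT/e)."""

    eps_zero: float = 25.0
    p_floor: float = 50.0

    def __post_init__(self) -> None:
        if self.eps_zero < 0:
            raise ValueError("eps_zero must be non-negative")
        if self.p_floor <= 0:
            raise ValueError("p_floor must be positive")


@dataclass
class ScoredMatch:
    geometry: MatchGeometry
    p_q: Optional[np.ndarray]
    distance_term: float
    pd_term: float
    score: float

    def label(self) -> str:
        return self.geometry.label()


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


# ---------------------------------------------------------------------------
# score terms

def distance_term(abs_delta_d: Sequence[float], d_ref: Sequence[float]) -> float:
    """D = sum_i |delta_d_i| / d_ref_i (reference-normalized, additive)."""
    dd = np.abs(np.asarray(abs_delta_d, dtype=float))
    dr = np.asarray(d_ref, dtype=float)
    if dd.shape != dr.shape:
        raise ValueError("deviation and reference vectors differ in length")
    if np.any(dr <= 0):
        raise ValueError("reference distances must be positive")
    return float(np.sum(dd / dr))


def pd_term(p_q: Sequence[float], p_ref: Sequence[float],
            th: Optional[Thresholds] = None) -> float:
    """P = sum over informative pairs of |P_q - P_ref| / max(|P_ref|, floor)."""
    th = th or Thresholds()
    pq = np.asarray(p_q, dtype=float)
    pr = np.asarray(p_ref, dtype=float)
    if pq.shape != pr.shape:
        raise ValueError("query and reference PD vectors differ in length")
    ignore = (np.abs(pq) < th.eps_zero) & (np.abs(pr) < th.eps_zero)
    denom = np.maximum(np.abs(pr), th.p_floor)
    contrib = np.where(ignore, 0.0, np.abs(pq - pr) / denom)
    return float(np.sum(contrib))


def clasp_score(match: MatchGeometry, motif: Motif,
                p_q: Optional[Sequence[float]] = None,
                weights: Optional[Weights] = None,
                thresholds: Optional[Thresholds] = None) -> ScoredMatch:
    """Score one candidate: S = w_d * D + w_p * P.

    When the motif has no reference PDs or ``p_q`` is not supplied the PD
    term is zero and the score is purely spatial.
    """
    w = weights or Weights()
    th = thresholds or Thresholds()
    D = distance_term(np.abs(match.delta_d), motif.d_ref)
    if p_q is not None and motif.p_ref is not None:
        pq = np.asarray(p_q, dtype=float)
        P = pd_term(pq, motif.p_ref, th)
    else:
        pq = None
        P = 0.0
    return ScoredMatch(match, pq, D, P, w.w_d * D + w.w_p * P)


# ---------------------------------------------------------------------------
# best match / library ranking

PDProvider = Union[PotentialGrid, Callable[[MatchGeometry], np.ndarray], None]


def _query_pds(match: MatchGeometry, pd_source: PDProvider) -> Optional[np.ndarray]:
    if pd_source is None:
        return None
    if isinstance(pd_source, PotentialGrid):
        pairs = pair_order(len(match.atoms))
        return np.array([pair_pd(pd_source, match.atoms[i], match.atoms[j]).value
                         for i, j in pairs])
    return np.asarray(pd_source(match), dtype=float)


class NoMatchError(LookupError):
    """The query structure contains no motif-congruent candidate."""


def best_match(
    s: Structure,
    m: Motif,
    pd_source: PDProvider = None,
    groups: Optional[GroupConfig] = None,
    search: Optional[SearchParams] = None,
    weights: Optional[Weights] = None,
    thresholds: Optional[Thresholds] = None,
    reactive_cfg: Optional[ReactiveAtomConfig] = None,
    n_alternates: int = 3,
) -> tuple[ScoredMatch, list[ScoredMatch]]:
    """Search, score, and pick the minimum-score match plus alternates.

    Ties break by smaller distance term, then lexicographic residue ids,
    so reports are deterministic.  Raises :class:`NoMatchError` when the
    search yields nothing (explicitly distinct from a zero score).
    """
    matches = enumerate_candidates(s, m, groups, search, reactive_cfg)
    if not matches:
        raise NoMatchError(f"no congruent match for motif {m.source_id!r} "
                           f"in {s.source_id!r}")
    scored = [clasp_score(g, m, _query_pds(g, pd_source), weights, thresholds)
              for g in matches]
    scored.sort(key=lambda sm: (sm.score, sm.distance_term,
                                sm.geometry.residue_ids))
    return scored[0], scored[1:1 + n_alternates]


@dataclass
class ScanResult:
    """Ranked motif-vs-structure table plus any no-match motifs."""

    table: pd.DataFrame
    no_match: list[str]


def rank_library(
    s: Structure,
    motifs: Sequence[Motif],
    pd_source: PDProvider = None,
    groups: Optional[GroupConfig] = None,
    search: Optional[SearchParams] = None,
    weights: Optional[Weights] = None,
    thresholds: Optional[Thresholds] = None,
    reactive_cfg: Optional[ReactiveAtomConfig] = None,
) -> ScanResult:
    """Scan a structure against a motif library; sort ascending by score.

    Motifs without any congruent match are reported in ``no_match`` rather
    than with a sentinel score.
    """
    rows = []
    missed = []
    for m in motifs:
        try:
            top, _ = best_match(s, m, pd_source, groups, search, weights,
                                thresholds, reactive_cfg)
        except NoMatchError:
            missed.append(m.source_id)
            continue
        rows.append({
            "motif": m.source_id,
            "score": top.score,
            "distance_term": top.distance_term,
            "pd_term": top.pd_term,
            "site": top.label(),
        })
    table = pd.DataFrame(rows, columns=["motif", "score", "distance_term",
                                        "pd_term", "site"])
    if len(table):
        table = table.sort_values(
            ["score", "distance_term", "motif"], kind="mergesort",
        ).reset_index(drop=True)
    return ScanResult(table, missed)


# ---------------------------------------------------------------------------
# classification metrics

def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), FPR FP/(FP+TN).

    A zero denominator yields NaN for that measure (flagged undefined).
    """
    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.tn + c.fp)
    fpr = ratio(c.fp, c.fp + c.tn)
    return {"sensitivity": sens, "specificity": spec, "fpr": fpr,
            "recall": sens}


def roc_sweep(scores: Sequence[float], labels: Sequence[bool],
              ) -> pd.DataFrame:
    """Sensitivity-vs-FPR curve sweeping thresholds over observed scores.

    Lower score predicts positive; the threshold is inclusive (score <= t).
    Returns a stepwise-monotone curve anchored at (0, 0), one row per
    distinct observed score.  Raises on single-class input.
    """
    sc = np.asarray(scores, dtype=float)
    lb = np.asarray(labels, dtype=bool)
    if sc.shape != lb.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(lb.sum())
    n_neg = int((~lb).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    rows = [{"threshold": -np.inf, "sensitivity": 0.0, "fpr": 0.0}]
    for t in np.unique(sc):
        pred = sc <= t
        rows.append({
            "threshold": float(t),
            "sensitivity": float((pred & lb).sum() / n_pos),
            "fpr": float((pred & ~lb).sum() / n_neg),
        })
    return pd.DataFrame(rows)


def roc_auc(curve: pd.DataFrame) -> float:
    """Area under a :func:`roc_sweep` curve (trapezoidal)."""
    return float(np.trapezoid(curve["sensitivity"], curve["fpr"]))


def sensitivity_at_fpr(curve: pd.DataFrame, fpr: float) -> float:
    """Best achievable sensitivity at or below a target FPR."""
    ok = curve[curve["fpr"] <= fpr]
    return float(ok["sensitivity"].max()) if len(ok) else 0.0
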