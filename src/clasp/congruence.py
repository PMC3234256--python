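"""Spatial congruence search: find residue tuples matching a motif geometry.

The search enumerates ordered tuples of residues, one per motif site, such
that each residue's type belongs to the site's stereochemical group, every
pairwise reactive-atom distance is below the cutoff, and every pairwise
distance deviates from the motif reference by at most the tolerance.  The
pruned depth-first search is exact: a brute-force Cartesian enumeration
with the identical acceptance predicate serves as its oracle on small
inputs.

Matching uses pairwise distances only, so it is invariant under rigid
motions and -- a documented limitation -- blind to mirror images.
Candidates are drawn from a single chain at a time; composite multi-chain
sites are out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from clasp.motif_library import GroupConfig, Motif, load_groups, pair_order
from clasp.structure_io import (
    Atom,
    MissingAtomError,
    ReactiveAtomConfig,
    Structure,
    reactive_atom,
)


class OracleCapError(RuntimeError):
    """Brute-force oracle refused: candidate count above its safety cap."""


@dataclass
class SearchParams:
    """cutoff: max pairwise distance within a match (Å); tolerance: max
    per-pair |deviation| from the reference distances (Å)."""

    cutoff: float = 15.0
    tolerance: float = 1.5
    max_matches: int = 100000

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class MatchGeometry:
    """A candidate residue tuple with its distance vector and deviations."""

    residue_ids: tuple[tuple[str, int, str], ...]  # ordered as motif sites
    residue_types: tuple[str, ...]
    atoms: tuple[Atom, ...]
    d_q: np.ndarray       # Å, canonical pair order
    delta_d: np.ndarray   # d_q - d_ref, signed

    @property
    def max_abs_deviation(self) -> float:
        return float(np.abs(self.delta_d).max())

    def label(self) -> str:
        return "+".join(f"{t}{r[1]}{r[2]}" for t, r in
                        zip(self.residue_types, self.residue_ids))


def _site_candidates(s: Structure, m: Motif, gc: GroupConfig,
                     cfg: ReactiveAtomConfig, chain: str) -> list[list[tuple]]:
    """Per site: (residue_id, residue_type, reactive atom) candidates."""
    residues = s.residues(chain)
    resolved: dict[tuple, tuple] = {}
    for r in residues:
        try:
            atom = reactive_atom(r, cfg)
        except MissingAtomError:
            continue
        resolved[r.residue_id] = (r.residue_id, r.residue_type, atom)
    out = []
    for label in m.group_labels:
        members = gc[label].members
        out.append([v for v in resolved.values() if v[1] in members])
    return out


def _geometry(cand: Sequence[tuple], m: Motif) -> MatchGeometry:
    coords = np.array([c[2].xyz for c in cand])
    pairs = pair_order(len(cand))
    d_q = np.array([float(np.linalg.norm(coords[i] - coords[j]))
                    for i, j in pairs])
    return MatchGeometry(
        residue_ids=tuple(c[0] for c in cand),
        residue_types=tuple(c[1] for c in cand),
        atoms=tuple(c[2] for c in cand),
        d_q=d_q,
        delta_d=d_q - m.d_ref,
    )


def _accept(cand: Sequence[tuple], m: Motif, params: SearchParams) -> bool:
    n = len(cand)
    coords = [np.asarray(c[2].xyz) for c in cand]
    for k, (i, j) in enumerate(pair_order(n)):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > params.cutoff or abs(d - m.d_ref[k]) > params.tolerance:
            return False
    return True


def enumerate_candidates(
    s: Structure,
    m: Motif,
    groups: Optional[GroupConfig] = None,
    params: Optional[SearchParams] = None,
    reactive_cfg: Optional[ReactiveAtomConfig] = None,
) -> list[MatchGeometry]:
    """Pruned exhaustive search for motif-congruent residue tuples.

    Sites are processed in ascending candidate-count order; a partial tuple
    is extended only while every new pairwise distance satisfies both the
    cutoff and the per-pair tolerance against the reference, which makes
    the enumeration exact with respect to :func:`brute_force`.  Assignment
    is injective (one residue cannot fill two sites).  Output is duplicate
    free and sorted by residue ids.
    """
    gc = groups or load_groups()
    params = params or SearchParams()
    cfg = reactive_cfg or ReactiveAtomConfig.default()
    results: list[MatchGeometry] = []
    npairs_index = {pr: k for k, pr in enumerate(pair_order(m.n))}

    for chain in s.chains:
        site_cands = _site_candidates(s, m, gc, cfg, chain)
        if any(not c for c in site_cands):
            continue
        site_order = sorted(range(m.n), key=lambda i: len(site_cands[i]))

        def extend(partial: dict[int, tuple]) -> None:
            if len(results) >= params.max_matches:
                return
            if len(partial) == m.n:
                cand = [partial[i] for i in range(m.n)]
                results.append(_geometry(cand, m))
                return
            site = site_order[len(partial)]
            used = {c[0] for c in partial.values()}
            for c in site_cands[site]:
                if c[0] in used:
                    continue
                ok = True
                for other_site, oc in partial.items():
                    i, j = min(site, other_site), max(site, other_site)
                    k = npairs_index[(i, j)]
                    a = np.asarray(c[2].xyz)
                    b = np.asarray(oc[2].xyz)
                    d = float(np.linalg.norm(a - b))
                    if d > params.cutoff or abs(d - m.d_ref[k]) > params.tolerance:
                        ok = False
                        break
                if ok:
                    partial[site] = c
                    extend(partial)
                    del partial[site]

        extend({})
    results.sort(key=lambda g: g.residue_ids)
    return results[: params.max_matches]


def brute_force(
    s: Structure,
    m: Motif,
    groups: Optional[GroupConfig] = None,
    params: Optional[SearchParams] = None,
    reactive_cfg: Optional[ReactiveAtomConfig] = None,
    cap: int = 2_000_000,
) -> list[MatchGeometry]:
    """Cartesian-product oracle with the identical acceptance predicate.

    Guarded for small inputs only: refuses with :class:`OracleCapError`
    when the product of per-site candidate counts exceeds ``cap``.
    """
    gc = groups or load_groups()
    params = params or SearchParams()
    cfg = reactive_cfg or ReactiveAtomConfig.default()
    results: list[MatchGeometry] = []
    for chain in s.chains:
        site_cands = _site_candidates(s, m, gc, cfg, chain)
        total = 1
        for c in site_cands:
            total *= len(c)
        if total > cap:
            raise OracleCapError(
                f"candidate product {total} exceeds oracle cap {cap}")
        if total == 0:
            continue
        for cand in itertools.product(*site_cands):
            ids = [c[0] for c in cand]
            if len(set(ids)) != len(ids):
                continue
            if _accept(cand, m, params):
                results.append(_geometry(cand, m))
    results.sort(key=lambda g: g.residue_ids)
    return results


def pairwise_deviation(d_q: Sequence[float], m: Motif) -> np.ndarray:
    """Signed per-pair deviations d_q - d_ref in canonical order."""
    d_q = np.asarray(d_q, dtype=float)
    if d_q.shape != m.d_ref.shape:
        raise ValueError(
            f"length mismatch: got {d_q.shape[0]} pairs, motif has "
            f"{m.d_ref.shape[0]}")
    return d_q - m.d_ref
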