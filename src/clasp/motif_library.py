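"""Motif definitions, stereochemical groups, and Catalytic Site Atlas intake.

A motif is an ordered set of 3-5 catalytic sites taken from a reference
structure.  Each site carries a stereochemical group label (the set of
residue types allowed at that site when scanning other proteins), and the
motif stores the reference pairwise reactive-atom distances (Å) and
reference pairwise potential differences (kT/e).  Pair order is canonical:
lexicographic (i, j) with i < j over site index, and the PD for pair (i, j)
is phi(site i) - phi(site j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from clasp.electrostatics import PotentialGrid, pair_pd
from clasp.structure_io import (
    ReactiveAtomConfig,
    Structure,
    reactive_atom,
)

logger = logging.getLogger(__name__)

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Default stereochemical groups used when scanning: nucleophile-like
#: serines may be replaced by Thr/Tyr/Cys (class C beta-lactamases use a
#: Tyr in the Ser130 position), basic sites by Lys/Arg/His, and acidic
#: sites by Asp/Glu.
DEFAULT_GROUPS = """\
Sergrp: SER THR TYR CYS
Lysgrp: LYS ARG HIS
Aspgrp: ASP GLU
Hisgrp: HIS
"""


class GroupConfigError(ValueError):
    """Duplicate label or unknown residue code in a group config."""


@dataclass(frozen=True)
class StereoGroup:
    """A named set of residue types treated as interchangeable at a site."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise GroupConfigError(f"group {self.label!r} is empty")


@dataclass
class GroupConfig:
    groups: dict[str, StereoGroup] = field(default_factory=dict)

    def __getitem__(self, label: str) -> StereoGroup:
        return self.groups[label]

    def __contains__(self, label: str) -> bool:
        return label in self.groups


def load_groups(config_text: str = DEFAULT_GROUPS) -> GroupConfig:
    """Parse ``Label: RES RES ...`` lines into a :class:`GroupConfig`.

    Singleton ``<Xaa>only`` groups are always available for every standard
    amino acid, so restricting a site to exactly one residue type never
    needs configuration.
    """
    groups: dict[str, StereoGroup] = {}
    for raw in config_text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        label, _, members = line.partition(":")
        label = label.strip()
        codes = tuple(m.upper() for m in members.split())
        if label in groups:
            raise GroupConfigError(f"duplicate group label {label!r}")
        unknown = [c for c in codes if c not in _AA3]
        if unknown:
            raise GroupConfigError(
                f"unknown residue code(s) {unknown} in group {label!r}")
        groups[label] = StereoGroup(label, frozenset(codes))
    for aa in sorted(_AA3):
        label = aa.title() + "only"
        groups.setdefault(label, StereoGroup(label, frozenset({aa})))
    return GroupConfig(groups)


# ---------------------------------------------------------------------------
# Motif

def pair_order(n: int) -> list[tuple[int, int]]:
    """Canonical pair order: (0,1), (0,2), ..., lexicographic with i < j."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


@dataclass
class Motif:
    """An ordered active-site template with reference distances and PDs."""

    source_id: str
    sites: list[tuple[str, str, str]]  # (group label, residue id "A:70", atom name)
    d_ref: np.ndarray                  # Å, canonical pair order
    p_ref: Optional[np.ndarray] = None  # kT/e, same order; None if not computed

    def __post_init__(self) -> None:
        n = len(self.sites)
        if n not in (3, 4, 5):
            raise ValueError(f"motif must have 3-5 sites, got {n}")
        self.d_ref = np.asarray(self.d_ref, dtype=float)
        npairs = n * (n - 1) // 2
        if self.d_ref.shape != (npairs,):
            raise ValueError(f"d_ref must have length {npairs}")
        if np.any(self.d_ref <= 0):
            raise ValueError("reference distances must be positive")
        if self.p_ref is not None:
            self.p_ref = np.asarray(self.p_ref, dtype=float)
            if self.p_ref.shape != (npairs,):
                raise ValueError(f"p_ref must have length {npairs}")

    @property
    def n(self) -> int:
        return len(self.sites)

    @property
    def group_labels(self) -> list[str]:
        return [s[0] for s in self.sites]

    def to_text(self) -> str:
        doc = {
            "source": self.source_id,
            "sites": [list(s) for s in self.sites],
            "d_ref": [float(x) for x in self.d_ref],
            "p_ref": None if self.p_ref is None else [float(x) for x in self.p_ref],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_text(cls, text: str) -> "Motif":
        doc = yaml.safe_load(text)
        return cls(
            source_id=doc["source"],
            sites=[tuple(s) for s in doc["sites"]],
            d_ref=np.array(doc["d_ref"], dtype=float),
            p_ref=None if doc.get("p_ref") is None
            else np.array(doc["p_ref"], dtype=float),
        )


def _parse_residue_id(rid: str) -> tuple[str, int, str]:
    chain, _, rest = rid.partition(":")
    num = ""
    icode = ""
    for ch in rest:
        if ch.isdigit() or (ch == "-" and not num):
            num += ch
        else:
            icode += ch
    return chain, int(num), icode


def build_motif(
    s: Structure,
    grid: Optional[PotentialGrid],
    residues: Sequence[str],
    groups: Sequence[str],
    group_config: Optional[GroupConfig] = None,
    reactive_cfg: Optional[ReactiveAtomConfig] = None,
    source_id: str = "",
) -> Motif:
    """Build a motif from a reference structure.

    ``residues`` are ``"chain:number[icode]"`` strings in site order;
    ``groups`` assigns each site its stereochemical group label and each
    reference residue's type must belong to its declared group.  When a
    solved ``grid`` is given, reference PDs are evaluated at the reactive
    atoms over the canonical pairs; otherwise ``p_ref`` is left unset.
    """
    if len(residues) != len(groups):
        raise ValueError("residues and groups must have equal length")
    gc = group_config or load_groups()
    cfg = reactive_cfg or ReactiveAtomConfig.default()

    atoms = []
    sites = []
    for rid, label in zip(residues, groups):
        chain, num, icode = _parse_residue_id(rid)
        res = s.residue(chain, num, icode)
        if label not in gc:
            raise GroupConfigError(f"unknown group label {label!r}")
        if res.residue_type not in gc[label].members:
            raise ValueError(
                f"residue {rid} is {res.residue_type}, outside group {label!r} "
                f"{sorted(gc[label].members)}")
        atom = reactive_atom(res, cfg)
        atoms.append(atom)
        sites.append((label, rid, atom.name))

    pairs = pair_order(len(atoms))
    coords = np.array([a.xyz for a in atoms])
    d_ref = np.array([float(np.linalg.norm(coords[i] - coords[j]))
                      for i, j in pairs])
    p_ref = None
    if grid is not None:
        p_ref = np.array([pair_pd(grid, atoms[i], atoms[j]).value
                          for i, j in pairs])
    return Motif(source_id or s.source_id, sites, d_ref, p_ref)


# ---------------------------------------------------------------------------
# Catalytic Site Atlas intake

@dataclass(frozen=True)
class CSARecord:
    """One annotated catalytic site: residues grouped by (PDB id, site number)."""

    pdb_id: str
    site_number: int
    residues: tuple[tuple[str, str, int], ...]  # (res type, chain, number)
    literature_evidence: bool

    @property
    def chains(self) -> set[str]:
        return {chain for _, chain, _ in self.residues}


def parse_csa(list_text: str) -> list[CSARecord]:
    """Parse a comma-separated CSA 2.2.x listing.

    Expected columns: PDB ID, SITE NUMBER, RESIDUE TYPE, CHAIN ID, RESIDUE
    NUMBER, CHEMICAL FUNCTION, EVIDENCE TYPE [, extra columns tolerated].
    Evidence ``LIT`` marks hand-annotated literature entries; anything else
    (typically ``PSIBLAST``) is homology-inferred.  Malformed lines are
    skipped with one logged warning reporting the count.
    """
    rows: dict[tuple[str, int], list[tuple[str, str, int, bool]]] = {}
    order: list[tuple[str, int]] = []
    bad = 0
    for raw in list_text.splitlines():
        line = raw.strip()
        if not line or line.upper().startswith("PDB ID"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 7:
            bad += 1
            continue
        try:
            pdb_id = parts[0].lower()
            site = int(parts[1])
            res_type = parts[2].upper()
            chain = parts[3]
            num = int(parts[4])
            evidence = parts[6].upper()
        except (ValueError, IndexError):
            bad += 1
            continue
        if len(pdb_id) != 4 or not res_type:
            bad += 1
            continue
        key = (pdb_id, site)
        if key not in rows:
            rows[key] = []
            order.append(key)
        rows[key].append((res_type, chain, num, evidence == "LIT"))
    if bad:
        logger.warning("parse_csa skipped %d malformed line(s)", bad)
    records = []
    for key in order:
        entries = rows[key]
        records.append(CSARecord(
            pdb_id=key[0],
            site_number=key[1],
            residues=tuple((r, c, n) for r, c, n, _ in entries),
            literature_evidence=all(lit for *_, lit in entries),
        ))
    return records


@dataclass(frozen=True)
class MotifSpec:
    """A filtered CSA site ready for motif construction against its PDB entry."""

    pdb_id: str
    chain: str
    residues: tuple[tuple[str, str, int], ...]
    group_labels: tuple[str, ...]


def filter_csa(records: Sequence[CSARecord]) -> list[MotifSpec]:
    """Keep literature-annotated, single-chain sites with 3-5 residues.

    Multi-chain (subunit-shared) active sites are discarded.  Each retained
    site gets singleton group labels (``<Xaa>only``) so CSA-derived motifs
    are maximally specific by default; idempotent by construction.
    """
    out = []
    for rec in records:
        if not rec.literature_evidence:
            continue
        if not 3 <= len(rec.residues) <= 5:
            continue
        if len(rec.chains) != 1:
            continue
        labels = tuple(r.title() + "only" for r, _, _ in rec.residues)
        out.append(MotifSpec(rec.pdb_id, next(iter(rec.chains)),
                             rec.residues, labels))
    return out
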