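"""PDB ingestion, reactive-atom resolution and charge/radius parameterization.

All distance and potential-difference measurements downstream operate on one
designated "reactive atom" per residue (e.g. Ser OG, Lys NZ).  Charges and
radii follow a heavy-atom PARSE-like table: per-residue partial charges sum
to the formal charge at pH 7 (Asp/Glu -1, Lys/Arg +1, His neutral) and the
Ser OG charge is -0.49 e.  Hydrogens are not modelled; the external
Poisson-Boltzmann backend adds them itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import gemmi

logger = logging.getLogger(__name__)

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_METAL_ELEMENTS = {"ZN", "MG", "CA", "MN", "FE", "CU", "NI", "CO", "NA", "K"}


class PDBParseError(ValueError):
    """Raised when PDB text lacks ATOM records or has malformed columns."""


class MissingAtomError(KeyError):
    """Raised when none of a residue's configured reactive atoms is present."""


class ParameterizationError(KeyError):
    """Raised under strict policy for residues/atoms absent from the table."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom with its residue identity.

    ``residue_number`` plus ``icode`` (insertion code, ``""`` if none)
    identify the residue within ``chain_id``; matching is always by the
    triple (chain, number, icode).
    """

    name: str
    element: str
    residue_type: str
    residue_number: int
    chain_id: str
    xyz: tuple[float, float, float]
    icode: str = ""
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    is_metal: bool = False

    def __post_init__(self) -> None:
        if not all(abs(c) < 1e8 for c in self.xyz):
            raise ValueError(f"non-finite coordinate in atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.icode)


@dataclass(frozen=True)
class ParameterizedAtom(Atom):
    """Atom carrying a partial charge (e) and a dielectric-boundary radius (Å)."""

    charge: float = 0.0
    radius: float = 1.5

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not -2.0 <= self.charge <= 2.0:
            raise ValueError(f"charge {self.charge} outside [-2, 2] e")


@dataclass(frozen=True)
class ResidueView:
    """Atoms of one residue, in file order."""

    residue_type: str
    residue_number: int
    icode: str
    chain_id: str
    atoms: tuple[Atom, ...]

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """A single-model protein structure as an ordered atom list."""

    atoms: list[Atom]
    source_id: str = ""
    model_index: int = 0

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def residues(self, chain: Optional[str] = None) -> list[ResidueView]:
        out: list[ResidueView] = []
        current: list[Atom] = []
        for a in self.atoms:
            if chain is not None and a.chain_id != chain:
                continue
            if current and a.residue_id != current[0].residue_id:
                out.append(_view(current))
                current = []
            current.append(a)
        if current:
            out.append(_view(current))
        return out

    def residue(self, chain_id: str, number: int, icode: str = "") -> ResidueView:
        for r in self.residues(chain_id):
            if r.residue_number == number and r.icode == icode:
                return r
        raise KeyError(f"residue {chain_id}:{number}{icode} not found")

    def translated(self, offset: Sequence[float]) -> "Structure":
        dx, dy, dz = offset
        moved = [
            replace(a, xyz=(a.xyz[0] + dx, a.xyz[1] + dy, a.xyz[2] + dz))
            for a in self.atoms
        ]
        return Structure(moved, source_id=self.source_id, model_index=self.model_index)


def _view(atoms: list[Atom]) -> ResidueView:
    a0 = atoms[0]
    return ResidueView(a0.residue_type, a0.residue_number, a0.icode,
                       a0.chain_id, tuple(atoms))


# ---------------------------------------------------------------------------
# Reactive-atom configuration

#: Default reactive atom per residue type, with ordered fallbacks.  Ser/Thr/
#: Tyr/Cys nucleophiles use the side-chain O/S; bases use the distal N.
DEFAULT_REACTIVE_ATOMS = """\
SER: OG
THR: OG1
TYR: OH
CYS: SG
LYS: NZ
ARG: NH1 NH2
HIS: NE2 ND1
ASP: OD1 OD2
GLU: OE1 OE2
ASN: OD1
GLN: OE1
TRP: NE1
MET: SD
"""


@dataclass
class ReactiveAtomConfig:
    """Map residue type -> ordered list of candidate reactive atom names."""

    table: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_text(cls, text: str) -> "ReactiveAtomConfig":
        table: dict[str, tuple[str, ...]] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            res, _, names = line.partition(":")
            atoms = tuple(names.split())
            if not atoms:
                raise ValueError(f"no atom names for residue {res.strip()!r}")
            table[res.strip().upper()] = atoms
        return cls(table)

    @classmethod
    def default(cls) -> "ReactiveAtomConfig":
        return cls.from_text(DEFAULT_REACTIVE_ATOMS)


def reactive_atom(residue: ResidueView, cfg: Optional[ReactiveAtomConfig] = None) -> Atom:
    """Return the residue's reactive atom: first configured name present.

    Deterministic in the residue contents and the config; raises
    :class:`MissingAtomError` when none of the configured atoms exists
    (e.g. a truncated side chain).
    """
    cfg = cfg or ReactiveAtomConfig.default()
    try:
        names = cfg.table[residue.residue_type]
    except KeyError:
        raise MissingAtomError(
            f"no reactive-atom entry for residue type {residue.residue_type}")
    for name in names:
        atom = residue.atom(name)
        if atom is not None:
            return atom
    raise MissingAtomError(
        f"residue {residue.chain_id}:{residue.residue_number}{residue.icode} "
        f"({residue.residue_type}) lacks all of {names}")


# ---------------------------------------------------------------------------
# PDB reading

def read_pdb(text: str, chain: Optional[str] = None, source_id: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Only the first MODEL is retained.  For alternate locations the highest
    occupancy wins, ties broken by altloc letter.  Waters are dropped;
    HETATM metal ions are kept and flagged ``is_metal``; other hetero
    groups are kept and flagged ``is_hetero`` so the parameterization
    policy can decide about them.
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no ATOM records found")
    st.setup_entities()
    model = st[0]

    atoms: list[Atom] = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.name in ("HOH", "WAT", "DOD"):
                continue
            het = res.het_flag == "H"
            for a in _resolve_altlocs(res):
                elem = a.element.name.upper()
                if elem == "H":
                    continue
                atoms.append(Atom(
                    name=a.name,
                    element=elem,
                    residue_type=res.name,
                    residue_number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    chain_id=ch.name,
                    xyz=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=(a.altloc or "").strip(),
                    is_hetero=het,
                    is_metal=het and elem in _METAL_ELEMENTS,
                ))
    if not atoms:
        raise PDBParseError("no ATOM records found"
                            + (f" for chain {chain!r}" if chain else ""))
    return Structure(atoms, source_id=source_id or st.name)


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in res:
        key = a.name
        if key not in by_name:
            by_name[key] = a
            order.append(key)
        else:
            b = by_name[key]
            # highest occupancy wins; tie broken by altloc letter order
            if (a.occ, _alt_rank(b.altloc)) > (b.occ, _alt_rank(a.altloc)):
                by_name[key] = a
    return [by_name[k] for k in order]


def _alt_rank(altloc: str) -> int:
    return -ord(altloc) if altloc else 0


# ---------------------------------------------------------------------------
# Charge / radius table

#: Heavy-atom charge (e) and radius (Å) table.  Backbone is shared across
#: residue types; side-chain charges localize the formal charge on the
#: chemically relevant atoms.  Format: RES ATOM CHARGE RADIUS; `*` matches
#: any residue type for backbone atoms.
DEFAULT_CHARGE_TABLE = """\
*    N    -0.40  1.50
*    CA    0.40  1.70
*    C     0.55  1.70
*    O    -0.55  1.40
*    OXT   0.00  1.40
ALA  CB    0.00  1.70
VAL  CB    0.00  1.70
VAL  CG1   0.00  1.70
VAL  CG2   0.00  1.70
LEU  CB    0.00  1.70
LEU  CG    0.00  1.70
LEU  CD1   0.00  1.70
LEU  CD2   0.00  1.70
ILE  CB    0.00  1.70
ILE  CG1   0.00  1.70
ILE  CG2   0.00  1.70
ILE  CD1   0.00  1.70
PRO  CB    0.00  1.70
PRO  CG    0.00  1.70
PRO  CD    0.00  1.70
MET  CB    0.00  1.70
MET  CG    0.06  1.70
MET  SD   -0.12  1.85
MET  CE    0.06  1.70
PHE  CB    0.00  1.70
PHE  CG    0.00  1.70
PHE  CD1   0.00  1.70
PHE  CD2   0.00  1.70
PHE  CE1   0.00  1.70
PHE  CE2   0.00  1.70
PHE  CZ    0.00  1.70
TRP  CB    0.00  1.70
TRP  CG    0.00  1.70
TRP  CD1   0.00  1.70
TRP  CD2   0.00  1.70
TRP  NE1  -0.35  1.50
TRP  CE2   0.35  1.70
TRP  CE3   0.00  1.70
TRP  CZ2   0.00  1.70
TRP  CZ3   0.00  1.70
TRP  CH2   0.00  1.70
GLY  __    0.00  1.70
SER  CB    0.49  1.70
SER  OG   -0.49  1.40
THR  CB    0.49  1.70
THR  OG1  -0.49  1.40
THR  CG2   0.00  1.70
TYR  CB    0.00  1.70
TYR  CG    0.00  1.70
TYR  CD1   0.00  1.70
TYR  CD2   0.00  1.70
TYR  CE1   0.00  1.70
TYR  CE2   0.00  1.70
TYR  CZ    0.49  1.70
TYR  OH   -0.49  1.40
CYS  CB    0.30  1.70
CYS  SG   -0.30  1.85
ASN  CB    0.00  1.70
ASN  CG    0.55  1.70
ASN  OD1  -0.55  1.40
ASN  ND2   0.00  1.50
GLN  CB    0.00  1.70
GLN  CG    0.00  1.70
GLN  CD    0.55  1.70
GLN  OE1  -0.55  1.40
GLN  NE2   0.00  1.50
ASP  CB    0.00  1.70
ASP  CG    0.10  1.70
ASP  OD1  -0.55  1.40
ASP  OD2  -0.55  1.40
GLU  CB    0.00  1.70
GLU  CG    0.00  1.70
GLU  CD    0.10  1.70
GLU  OE1  -0.55  1.40
GLU  OE2  -0.55  1.40
LYS  CB    0.00  1.70
LYS  CG    0.00  1.70
LYS  CD    0.00  1.70
LYS  CE    0.25  1.70
LYS  NZ    0.75  1.50
ARG  CB    0.00  1.70
ARG  CG    0.00  1.70
ARG  CD    0.00  1.70
ARG  NE    0.00  1.50
ARG  CZ    0.20  1.70
ARG  NH1   0.40  1.50
ARG  NH2   0.40  1.50
HIS  CB    0.00  1.70
HIS  CG    0.00  1.70
HIS  ND1  -0.40  1.50
HIS  CD2   0.00  1.70
HIS  CE1   0.40  1.70
HIS  NE2   0.00  1.50
ZN   ZN    2.00  1.39
MG   MG    2.00  1.18
"""


@dataclass
class ChargeRadiusTable:
    """(residue_type, atom_name) -> (charge e, radius Å); `*` rows are backbone."""

    entries: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_text(cls, text: str) -> "ChargeRadiusTable":
        entries: dict[tuple[str, str], tuple[float, float]] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"bad charge-table line: {raw!r}")
            res, atom, q, r = parts
            entries[(res.upper(), atom.upper())] = (float(q), float(r))
        return cls(entries)

    @classmethod
    def default(cls) -> "ChargeRadiusTable":
        return cls.from_text(DEFAULT_CHARGE_TABLE)

    def lookup(self, residue_type: str, atom_name: str) -> Optional[tuple[float, float]]:
        hit = self.entries.get((residue_type, atom_name))
        if hit is None:
            hit = self.entries.get(("*", atom_name))
        return hit


def assign_parameters(
    s: Structure,
    table: Optional[ChargeRadiusTable] = None,
    strict: bool = True,
    include_metals: bool = True,
) -> list[ParameterizedAtom]:
    """Assign charge and radius to every retained atom.

    Assignment is a pure function of (residue_type, atom_name) -- it never
    inspects coordinates.  Under ``strict`` any uncovered (residue, atom)
    raises :class:`ParameterizationError` naming all offenders; otherwise
    uncovered atoms are skipped with a logged count.  Metal ions carry
    their formal +2 charge unless ``include_metals`` is false, in which
    case they are dropped.
    """
    table = table or ChargeRadiusTable.default()
    out: list[ParameterizedAtom] = []
    missing: list[str] = []
    for a in s.atoms:
        if a.is_metal and not include_metals:
            continue
        hit = table.lookup(a.residue_type, a.name)
        if hit is None:
            missing.append(f"{a.residue_type}:{a.name}@"
                           f"{a.chain_id}{a.residue_number}{a.icode}")
            continue
        q, r = hit
        out.append(ParameterizedAtom(
            name=a.name, element=a.element, residue_type=a.residue_type,
            residue_number=a.residue_number, chain_id=a.chain_id,
            xyz=a.xyz, icode=a.icode, occupancy=a.occupancy,
            altloc=a.altloc, is_hetero=a.is_hetero, is_metal=a.is_metal,
            charge=q, radius=r,
        ))
    if missing:
        if strict:
            raise ParameterizationError(
                f"{len(missing)} atom(s) not covered by the charge table: "
                + ", ".join(missing[:20]))
        logger.warning("skipped %d unparameterized atom(s)", len(missing))
    return out


# ---------------------------------------------------------------------------
# PQR output

def write_pqr(atoms: Iterable[ParameterizedAtom]) -> str:
    """Serialize to whitespace-delimited PQR (10 fields per ATOM record)."""
    lines = ["REMARK   1 PQR written by clasp (whitespace-delimited)"]
    for i, a in enumerate(atoms, start=1):
        lines.append(
            f"ATOM {i:6d} {a.name:<4s} {a.residue_type:<4s} "
            f"{a.residue_number:5d} "
            f"{a.xyz[0]:10.3f} {a.xyz[1]:10.3f} {a.xyz[2]:10.3f} "
            f"{a.charge:8.4f} {a.radius:7.4f}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_pqr(text: str) -> list[ParameterizedAtom]:
    """Parse whitespace-delimited PQR written by :func:`write_pqr`."""
    out: list[ParameterizedAtom] = []
    for raw in text.splitlines():
        if not raw.startswith(("ATOM", "HETATM")):
            continue
        parts = raw.split()
        if len(parts) != 10:
            raise PDBParseError(f"expected 10 PQR fields, got {len(parts)}: {raw!r}")
        _, _, name, res, num, x, y, z, q, r = parts
        out.append(ParameterizedAtom(
            name=name, element=name[0], residue_type=res,
            residue_number=int(num), chain_id="A",
            xyz=(float(x), float(y), float(z)),
            charge=float(q), radius=float(r)))
    return out
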