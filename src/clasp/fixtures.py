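"""Deterministic synthetic structures, charge systems, and labeled score sets.

Everything downstream is testable without downloads: toy single-chain PDB
files with planted active-site geometries (alanine-like scaffolds carrying
full functional side chains whose reactive atoms sit at exact target
coordinates), point-charge systems for the Poisson solver, and labeled
positive/decoy score sets that emulate the empirical observation driving
PD-based pruning -- within an enzyme family the per-pair active-site PDs
fall in a narrow band (standard deviations of order 10-25 kT/e around
means of order 100-250 kT/e), while unrelated but spatially congruent
sites show uninformative PDs.

Planted geometries for the serine-protease triad and the alkaline-
phosphatase site use the published reactive-atom pairwise distances of
trypsin (1A0J) and shrimp alkaline phosphatase (1K7H) as inputs; the class
A beta-lactamase tetrad geometry is synthetic (plausible coordinates, no
crystallographic source) and its family PD profile uses the published
class A reference values.  Every generator is a pure function of its spec
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import gemmi
import numpy as np

from clasp.motif_library import pair_order
from clasp.structure_io import ParameterizedAtom


class GenerationError(RuntimeError):
    """Fixture generation produced invalid output (e.g. clashing atoms)."""


# ---------------------------------------------------------------------------
# distance-matrix embedding

def embed_distances(d_vec: Sequence[float], n: int, tol: float = 1e-8) -> np.ndarray:
    """Coordinates in R^3 realizing the pairwise distance vector exactly.

    Classical multidimensional scaling: the vector is in canonical pair
    order; raises :class:`GenerationError` when the distances are not
    embeddable in three dimensions.
    """
    D = np.zeros((n, n))
    for k, (i, j) in enumerate(pair_order(n)):
        D[i, j] = D[j, i] = d_vec[k]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    dims = min(3, n - 1)
    X = V[:, :dims] * np.sqrt(np.maximum(w[:dims], 0.0))
    out = np.zeros((n, 3))
    out[:, :dims] = X
    # verify reconstruction
    for k, (i, j) in enumerate(pair_order(n)):
        if abs(np.linalg.norm(out[i] - out[j]) - d_vec[k]) > max(tol, 1e-6):
            raise GenerationError("embedding failed to reproduce distances")
    return out


def deviated_coordinates(d_ref: Sequence[float], abs_deltas: Sequence[float],
                         n: int) -> np.ndarray:
    """Coordinates whose pairwise distances deviate from ``d_ref`` by
    exactly the requested absolute amounts.

    Sign patterns over the deviations are tried in a deterministic order
    until one yields an embeddable distance set.
    """
    d_ref = np.asarray(d_ref, dtype=float)
    ad = np.asarray(abs_deltas, dtype=float)
    npairs = len(d_ref)
    for bits in range(1 << npairs):
        signs = np.array([1.0 if (bits >> k) & 1 == 0 else -1.0
                          for k in range(npairs)])
        d_q = d_ref + signs * ad
        if np.any(d_q <= 0):
            continue
        try:
            return embed_distances(d_q, n)
        except GenerationError:
            continue
    raise GenerationError("no sign pattern yields an embeddable deviation set")


# ---------------------------------------------------------------------------
# reference geometries and family PD profiles

#: Serine-protease catalytic triad, site order (Ser, His, Asp); canonical
#: pairs (S,H), (S,D), (H,D).  Distances from the trypsin reference.
TRYPSIN_TRIAD_DISTANCES = (3.3, 7.8, 5.5)
TRYPSIN_TRIAD_TYPES = ("SER", "HIS", "ASP")
TRYPSIN_TRIAD_GROUPS = ("Sergrp", "Hisgrp", "Aspgrp")

#: The same triad in the alkaline-phosphatase (shrimp AP) predicted site.
AP_SITE_DISTANCES = (4.6, 7.7, 3.2)

#: Serine-protease family PD profile (kT/e), canonical pairs (S,H), (S,D),
#: (H,D): means from the trypsin reference, spreads typical of the family.
PROTEASE_PD_MEAN = (104.8, -144.1, -123.4)
PROTEASE_PD_SD = (20.0, 15.0, 10.0)

#: Class A beta-lactamase tetrad, site order (Ser70, Lys73, Ser130,
#: Lys234).  Coordinates are synthetic; the derived d_ref is what matters.
LACTAMASE_SITE_COORDS = np.array([
    [0.0, 0.0, 0.0],    # Ser70 OG
    [2.9, 1.8, 1.1],    # Lys73 NZ
    [4.6, -2.8, 0.7],   # Ser130 OG
    [7.4, 0.9, -1.6],   # Lys234 NZ
])
LACTAMASE_SITE_TYPES = ("SER", "LYS", "SER", "LYS")
LACTAMASE_GROUPS = ("Sergrp", "Lysgrp", "Sergrp", "Lysgrp")

#: Class A beta-lactamase family PD profile (kT/e), canonical pair order
#: (S70/K73, S70/S130, S70/K234, K73/S130, K73/K234, S130/K234): the
#: published class A reference values and the family spreads.
LACTAMASE_PD_MEAN = (-201.7, 22.3, -250.3, 224.0, -48.6, -272.7)
LACTAMASE_PD_SD = (7.8, 15.3, 9.0, 8.9, 15.7, 24.0)


def lactamase_d_ref() -> np.ndarray:
    c = LACTAMASE_SITE_COORDS
    return np.array([float(np.linalg.norm(c[i] - c[j]))
                     for i, j in pair_order(4)])


# ---------------------------------------------------------------------------
# toy structure generation

#: Atom layout per residue type: reactive atom first, then the rest of the
#: side chain, then backbone.  Local offsets (Å) are applied in a frame
#: whose first axis points away from the motif centroid.
_RESIDUE_TEMPLATES: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "SER": [("OG", (0.0, 0.0, 0.0)), ("CB", (1.4, 0.3, 0.0)),
            ("CA", (2.6, -0.4, 0.4)), ("N", (3.6, 0.3, 1.2)),
            ("C", (3.3, -1.0, -0.8)), ("O", (3.1, -2.2, -1.0))],
    "THR": [("OG1", (0.0, 0.0, 0.0)), ("CB", (1.4, 0.3, 0.0)),
            ("CG2", (1.9, 1.6, 0.7)), ("CA", (2.6, -0.4, 0.4)),
            ("N", (3.6, 0.3, 1.2)), ("C", (3.3, -1.0, -0.8)),
            ("O", (3.1, -2.2, -1.0))],
    "CYS": [("SG", (0.0, 0.0, 0.0)), ("CB", (1.7, 0.4, 0.0)),
            ("CA", (2.9, -0.4, 0.4)), ("N", (3.9, 0.3, 1.2)),
            ("C", (3.6, -1.0, -0.8)), ("O", (3.4, -2.2, -1.0))],
    "TYR": [("OH", (0.0, 0.0, 0.0)), ("CZ", (1.3, 0.2, 0.0)),
            ("CE1", (2.1, 1.2, 0.5)), ("CE2", (1.9, -0.9, -0.6)),
            ("CD1", (3.4, 1.3, 0.4)), ("CD2", (3.2, -0.8, -0.7)),
            ("CG", (4.0, 0.2, -0.2)), ("CB", (5.4, 0.3, -0.3)),
            ("CA", (6.2, -0.6, 0.5)), ("N", (7.2, 0.1, 1.2)),
            ("C", (6.9, -1.3, -0.7)), ("O", (6.7, -2.5, -0.9))],
    "LYS": [("NZ", (0.0, 0.0, 0.0)), ("CE", (1.4, 0.3, 0.2)),
            ("CD", (2.6, -0.5, 0.0)), ("CG", (4.0, 0.1, 0.2)),
            ("CB", (5.2, -0.7, 0.0)), ("CA", (6.6, -0.1, 0.2)),
            ("N", (7.4, 0.6, 1.2)), ("C", (7.3, -1.2, -0.7)),
            ("O", (7.1, -2.4, -0.9))],
    "ARG": [("NH1", (0.0, 0.0, 0.0)), ("CZ", (1.3, 0.3, 0.0)),
            ("NH2", (1.9, 1.4, 0.5)), ("NE", (2.1, -0.6, -0.7)),
            ("CD", (3.5, -0.4, -0.7)), ("CG", (4.3, -1.3, 0.2)),
            ("CB", (5.7, -0.9, 0.3)), ("CA", (6.6, -1.7, 1.1)),
            ("N", (7.5, -0.9, 1.9)), ("C", (7.3, -2.7, 0.3)),
            ("O", (7.1, -3.9, 0.5))],
    "HIS": [("NE2", (0.0, 0.0, 0.0)), ("CE1", (1.2, 0.6, 0.0)),
            ("CD2", (0.4, -1.3, 0.2)), ("ND1", (2.2, -0.4, 0.3)),
            ("CG", (1.8, -1.6, 0.4)), ("CB", (2.7, -2.8, 0.6)),
            ("CA", (4.1, -2.5, 1.0)), ("N", (4.9, -1.9, -0.1)),
            ("C", (4.8, -3.8, 1.4)), ("O", (4.6, -4.9, 0.9))],
    "ASP": [("OD1", (0.0, 0.0, 0.0)), ("CG", (1.3, 0.2, 0.0)),
            ("OD2", (1.9, 1.3, 0.3)), ("CB", (2.2, -1.0, -0.2)),
            ("CA", (3.6, -0.6, -0.1)), ("N", (4.4, -1.0, 1.1)),
            ("C", (4.3, -1.3, -1.3)), ("O", (4.1, -2.5, -1.5))],
    "GLU": [("OE1", (0.0, 0.0, 0.0)), ("CD", (1.3, 0.2, 0.0)),
            ("OE2", (1.9, 1.3, 0.3)), ("CG", (2.2, -1.0, -0.2)),
            ("CB", (3.6, -0.6, -0.1)), ("CA", (4.8, -1.4, 0.3)),
            ("N", (5.7, -0.7, 1.2)), ("C", (5.5, -1.8, -0.9)),
            ("O", (5.3, -3.0, -1.1))],
    "ASN": [("OD1", (0.0, 0.0, 0.0)), ("CG", (1.3, 0.2, 0.0)),
            ("ND2", (1.9, 1.3, 0.3)), ("CB", (2.2, -1.0, -0.2)),
            ("CA", (3.6, -0.6, -0.1)), ("N", (4.4, -1.0, 1.1)),
            ("C", (4.3, -1.3, -1.3)), ("O", (4.1, -2.5, -1.5))],
    "ALA": [("CB", (0.0, 0.0, 0.0)), ("CA", (1.5, 0.2, 0.0)),
            ("N", (2.3, 0.9, 1.0)), ("C", (2.2, -1.1, -0.6)),
            ("O", (2.0, -2.3, -0.8))],
}


@dataclass
class FixtureSpec:
    """Recipe for one toy structure.

    ``site_types`` and ``site_coords`` plant reactive atoms at exact
    positions (before optional Gaussian ``noise_sigma``); ``decoy_types``
    are placed on a ring ``decoy_distance`` Å from the motif centroid,
    outside the search cutoff by default.
    """

    site_types: tuple[str, ...]
    site_coords: np.ndarray
    decoy_types: tuple[str, ...] = ()
    decoy_distance: float = 25.0
    noise_sigma: float = 0.0
    seed: int = 0
    source_id: str = "toy"

    def __post_init__(self) -> None:
        self.site_coords = np.asarray(self.site_coords, dtype=float)
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if len(self.site_types) != len(self.site_coords):
            raise ValueError("site types and coordinates differ in length")


def _frame(u: np.ndarray) -> np.ndarray:
    u = u / (np.linalg.norm(u) or 1.0)
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return np.stack([u, v, w])


def make_toy_structure(spec: FixtureSpec) -> str:
    """Render the spec as single-chain PDB text (deterministic under seed)."""
    rng = np.random.default_rng(spec.seed)
    coords = spec.site_coords.copy()
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    # orientations come from the noise-free layout so jitter translates each
    # residue rigidly instead of swinging long side chains into neighbours
    centroid = spec.site_coords.mean(axis=0)

    st = gemmi.Structure()
    st.name = spec.source_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    placed: list[np.ndarray] = []
    resnum = 0

    def add_residue(res_type: str, anchor: np.ndarray, direction: np.ndarray) -> None:
        nonlocal resnum
        resnum += 1
        try:
            template = _RESIDUE_TEMPLATES[res_type]
        except KeyError:
            raise GenerationError(f"no template for residue type {res_type}")
        frame = _frame(direction)
        res = gemmi.Residue()
        res.name = res_type
        res.seqid = gemmi.SeqId(resnum, " ")
        for name, local in template:
            pos = anchor + np.asarray(local) @ frame
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(name[0])
            a.pos = gemmi.Position(*pos)
            a.occ = 1.0
            res.add_atom(a)
            placed.append(pos)
        chain.add_residue(res)

    # out-of-plane tilts keep side chains of tightly spaced (or nearly
    # collinear) sites from clashing while reactive atoms stay exact
    tilts = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0],
                      [0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    for idx, (res_type, c0, c) in enumerate(
            zip(spec.site_types, spec.site_coords, coords)):
        direction = c0 - centroid
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        direction = direction + 1.2 * tilts[idx % len(tilts)]
        add_residue(res_type, c, direction)

    for k, res_type in enumerate(spec.decoy_types):
        angle = 2.0 * np.pi * k / max(len(spec.decoy_types), 1)
        direction = np.array([np.cos(angle), np.sin(angle),
                              0.3 * ((k % 3) - 1)])
        direction /= np.linalg.norm(direction)
        anchor = centroid + spec.decoy_distance * direction
        add_residue(res_type, anchor, direction)

    pts = np.array(placed)
    if len(pts) > 1:
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < 1.0:
            raise GenerationError(
                f"overlapping atoms (min distance {np.sqrt(d2.min()):.2f} Å)")

    model.add_chain(chain)
    st.add_model(model)
    return st.make_pdb_string()


def trypsin_triad_structure(noise_sigma: float = 0.0, seed: int = 0,
                            decoys: int = 0,
                            distances: Sequence[float] = TRYPSIN_TRIAD_DISTANCES,
                            source_id: str = "toy-triad") -> str:
    """Toy single-chain structure with a planted Ser-His-Asp triad."""
    coords = embed_distances(distances, 3)
    spec = FixtureSpec(
        site_types=TRYPSIN_TRIAD_TYPES,
        site_coords=coords,
        decoy_types=tuple(("ALA", "SER", "LYS")[k % 3] for k in range(decoys)),
        noise_sigma=noise_sigma,
        seed=seed,
        source_id=source_id,
    )
    return make_toy_structure(spec)


def lactamase_structure(noise_sigma: float = 0.0, seed: int = 0,
                        decoys: int = 0,
                        coords: Optional[np.ndarray] = None,
                        source_id: str = "toy-lactamase") -> str:
    """Toy structure with the planted Ser-Lys-Ser-Lys tetrad."""
    spec = FixtureSpec(
        site_types=LACTAMASE_SITE_TYPES,
        site_coords=LACTAMASE_SITE_COORDS if coords is None else coords,
        decoy_types=tuple(("ALA", "THR", "ARG")[k % 3] for k in range(decoys)),
        noise_sigma=noise_sigma,
        seed=seed,
        source_id=source_id,
    )
    return make_toy_structure(spec)


# ---------------------------------------------------------------------------
# point-charge systems

def make_charge_fixture(kind: str, seed: int = 0) -> list[ParameterizedAtom]:
    """Point-charge systems for solver oracles.

    ``monopole``: one +1 e charge; ``dipole``: +-1 e, 4 Å apart along x;
    ``random``: 20 charges uniform in [-1, 1] e inside an 8 Å box.
    """
    def atom(i: int, xyz: tuple, q: float, r: float = 1.5) -> ParameterizedAtom:
        return ParameterizedAtom(
            name=f"Q{i}", element="C", residue_type="UNK",
            residue_number=i, chain_id="A", xyz=xyz, charge=q, radius=r)

    if kind == "monopole":
        return [atom(1, (0.0, 0.0, 0.0), 1.0)]
    if kind == "dipole":
        return [atom(1, (-2.0, 0.0, 0.0), 1.0), atom(2, (2.0, 0.0, 0.0), -1.0)]
    if kind == "random":
        rng = np.random.default_rng(seed)
        xyz = rng.uniform(-4.0, 4.0, (20, 3))
        q = rng.uniform(-1.0, 1.0, 20)
        r = rng.uniform(1.2, 2.0, 20)
        return [atom(i + 1, tuple(xyz[i]), float(q[i]), float(r[i]))
                for i in range(20)]
    raise ValueError(f"unknown charge fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# labeled score sets

@dataclass
class LabeledItem:
    """One synthetic query: structure text, its per-pair PDs, and the label."""

    name: str
    is_positive: bool
    structure_text: str
    pd_vector: np.ndarray


@dataclass
class FamilyPDProfile:
    """Per-pair PD mean and spread (kT/e) defining an enzyme family's band."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd differ in length")
        if np.any(self.sd < 0):
            raise ValueError("spreads must be non-negative")

    @classmethod
    def lactamase(cls) -> "FamilyPDProfile":
        return cls(np.array(LACTAMASE_PD_MEAN), np.array(LACTAMASE_PD_SD))

    @classmethod
    def protease(cls) -> "FamilyPDProfile":
        return cls(np.array(PROTEASE_PD_MEAN), np.array(PROTEASE_PD_SD))


def make_labeled_scoreset(
    n_pos: int = 5,
    n_neg: int = 45,
    family_pd_profile: Optional[FamilyPDProfile] = None,
    seed: int = 0,
    noise_sigma: float = 0.25,
    decoy_pd_range: float = 350.0,
) -> list[LabeledItem]:
    """Labeled structures for pruning/ROC experiments.

    Positives carry the planted beta-lactamase tetrad (geometry jittered
    by ``noise_sigma``) and PDs drawn from the narrow family band;
    negatives carry the same jittered geometry -- spatial congruence alone
    cannot reject them -- but PDs drawn uniformly from the broad
    uninformative range [-decoy_pd_range, +decoy_pd_range].
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    profile = family_pd_profile or FamilyPDProfile.lactamase()
    rng = np.random.default_rng(seed)
    npairs = len(profile.mean)
    items: list[LabeledItem] = []
    for i in range(n_pos):
        text = lactamase_structure(noise_sigma=noise_sigma,
                                   seed=int(rng.integers(2 ** 31)),
                                   source_id=f"pos{i:03d}")
        pds = rng.normal(profile.mean, profile.sd)
        items.append(LabeledItem(f"pos{i:03d}", True, text, pds))
    for i in range(n_neg):
        text = lactamase_structure(noise_sigma=noise_sigma,
                                   seed=int(rng.integers(2 ** 31)),
                                   source_id=f"neg{i:03d}")
        pds = rng.uniform(-decoy_pd_range, decoy_pd_range, npairs)
        items.append(LabeledItem(f"neg{i:03d}", False, text, pds))
    return items
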