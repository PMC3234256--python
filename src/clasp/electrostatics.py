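"""Finite-difference Poisson-Boltzmann electrostatics on a cubic lattice.

The solver discretizes div(eps grad phi) = -rho on a node-centred cubic
grid: charges are spread to the eight surrounding nodes with trilinear
weights, the dielectric is the solute value inside the probe-inflated union
of atom spheres and the solvent value outside (harmonically averaged on
cell faces), and the boundary is Dirichlet with a solvent-dielectric
Coulomb (Debye-screened when the ionic strength is nonzero) superposition.
Potentials are in dimensionless kT/e at the configured temperature; at zero
ionic strength the equation reduces to the Poisson equation.

Node potentials are grid-sensitive; potential *differences* between two
points evaluated on the same grid are the robust observable and are the
quantity scored downstream.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import constants

from clasp.structure_io import Atom, ParameterizedAtom


class ConvergenceError(RuntimeError):
    """Solver failed to reach the residual tolerance within the iteration cap."""


class GridBoundsError(ValueError):
    """A point or atom lies outside the potential grid."""


class BackendUnavailableError(RuntimeError):
    """The external PB backend executables are not on PATH."""


class BackendError(RuntimeError):
    """The external PB backend exited with a failure."""


def coulomb_constant(temperature: float = 298.0) -> float:
    """e^2/(4 pi eps0 kT) in Å: prefactor of q/(eps r) for phi in kT/e."""
    e = constants.elementary_charge
    k = constants.Boltzmann
    eps0 = constants.epsilon_0
    metres = e * e / (4.0 * np.pi * eps0 * k * temperature)
    return metres * 1e10


@dataclass
class GridParams:
    """Continuum-electrostatics parameters.

    Defaults follow standard protein PB practice: solute dielectric 2,
    solvent dielectric 78, probe radius 1.4 Å, 298 K, zero ionic strength,
    grid spacing selected in [0.4, 0.6] Å (largest spacing whose node count
    fits ``max_nodes``), 10 Å padding around the molecular extent.
    """

    spacing: Optional[float] = None
    solute_dielectric: float = 2.0
    solvent_dielectric: float = 78.0
    probe_radius: float = 1.4
    temperature: float = 298.0
    ionic_strength: float = 0.0
    padding: float = 10.0
    convergence_tol: float = 1e-6
    max_iterations: int = 20000
    omega: float = 1.9
    max_nodes: int = 3_000_000
    boundary_offset: float = 0.0  # kT/e added to all Dirichlet values

    def __post_init__(self) -> None:
        if self.spacing is not None and not 0.3 <= self.spacing <= 1.0:
            raise ValueError(f"grid spacing {self.spacing} outside [0.3, 1.0] Å")
        if self.solute_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectrics must be positive")
        if self.padding <= self.probe_radius:
            raise ValueError("padding must exceed the probe radius")

    def choose_spacing(self, extent: Sequence[float]) -> float:
        if self.spacing is not None:
            return self.spacing
        for h in (0.6, 0.65, 0.7, 0.8, 0.9, 1.0):
            n = 1
            for e in extent:
                n *= int(np.ceil((e + 2 * self.padding) / h)) + 1
            if n <= self.max_nodes:
                return h
        raise ValueError("molecule too large for the configured node cap")


@dataclass
class PotentialGrid:
    """Solved potential (kT/e) and the dielectric map on a cubic lattice."""

    origin: tuple[float, float, float]
    spacing: float
    values: np.ndarray
    dielectric: np.ndarray = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def contains(self, point: Sequence[float]) -> bool:
        g = (np.asarray(point) - np.asarray(self.origin)) / self.spacing
        return bool(np.all(g > 0) and np.all(g < np.asarray(self.shape) - 1))


@dataclass(frozen=True)
class PotentialDifference:
    """phi(a) - phi(b) in kT/e, with (a, b) in motif order."""

    value: float
    atom_a: str
    atom_b: str
    motif_order: bool = True


# ---------------------------------------------------------------------------
# solver

def _trilinear_spread(coords: np.ndarray, charges: np.ndarray,
                      origin: np.ndarray, h: float,
                      shape: tuple[int, int, int]) -> np.ndarray:
    rho = np.zeros(shape)
    g = (coords - origin) / h
    i0 = np.floor(g).astype(int)
    frac = g - i0
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        idx = i0 + off
        np.add.at(rho, (idx[:, 0], idx[:, 1], idx[:, 2]), charges * w)
    return rho


def _dielectric_map(coords: np.ndarray, radii: np.ndarray,
                    origin: np.ndarray, h: float,
                    shape: tuple[int, int, int], params: GridParams) -> np.ndarray:
    eps = np.full(shape, params.solvent_dielectric)
    axes = [origin[d] + h * np.arange(shape[d]) for d in range(3)]
    for (x, y, z), r in zip(coords, radii):
        rr = r + params.probe_radius
        sl = []
        for d, c in enumerate((x, y, z)):
            lo = max(0, int(np.floor((c - rr - origin[d]) / h)))
            hi = min(shape[d] - 1, int(np.ceil((c + rr - origin[d]) / h)))
            if lo > hi:
                sl = None
                break
            sl.append((lo, hi))
        if sl is None:
            continue
        ax = axes[0][sl[0][0]:sl[0][1] + 1] - x
        ay = axes[1][sl[1][0]:sl[1][1] + 1] - y
        az = axes[2][sl[2][0]:sl[2][1] + 1] - z
        inside = (ax[:, None, None] ** 2 + ay[None, :, None] ** 2
                  + az[None, None, :] ** 2) <= rr * rr
        sub = eps[sl[0][0]:sl[0][1] + 1, sl[1][0]:sl[1][1] + 1,
                  sl[2][0]:sl[2][1] + 1]
        sub[inside] = params.solute_dielectric
    return eps


def _boundary_coulomb(coords: np.ndarray, charges: np.ndarray,
                      origin: np.ndarray, h: float,
                      shape: tuple[int, int, int], params: GridParams) -> np.ndarray:
    """Dirichlet boundary: screened-Coulomb superposition at solvent dielectric."""
    phi = np.zeros(shape)
    C = coulomb_constant(params.temperature) / params.solvent_dielectric
    kappa = _debye_kappa(params)
    axes = [origin[d] + h * np.arange(shape[d]) for d in range(3)]

    def fill(face_idx: tuple) -> None:
        X, Y, Z = np.meshgrid(axes[0][face_idx[0]], axes[1][face_idx[1]],
                              axes[2][face_idx[2]], indexing="ij")
        acc = np.zeros_like(X)
        for (x, y, z), q in zip(coords, charges):
            r = np.sqrt((X - x) ** 2 + (Y - y) ** 2 + (Z - z) ** 2)
            r = np.maximum(r, 0.5 * h)
            screen = np.exp(-kappa * r) if kappa > 0 else 1.0
            acc += C * q * screen / r
        phi[face_idx] = acc

    n0, n1, n2 = shape
    fill((np.array([0, n0 - 1]), slice(None), slice(None)))
    fill((slice(None), np.array([0, n1 - 1]), slice(None)))
    fill((slice(None), slice(None), np.array([0, n2 - 1])))
    if params.boundary_offset:
        for face in ((0,), (n0 - 1,)):
            phi[face, :, :] += params.boundary_offset
        phi[1:-1, (0, n1 - 1), :] += params.boundary_offset
        phi[1:-1, 1:-1, (0, n2 - 1)] += params.boundary_offset
    return phi


def _debye_kappa(params: GridParams) -> float:
    if params.ionic_strength <= 0:
        return 0.0
    e = constants.elementary_charge
    k = constants.Boltzmann
    eps0 = constants.epsilon_0
    n = 2.0 * params.ionic_strength * 1000.0 * constants.Avogadro  # ions/m^3
    kappa_m = np.sqrt(n * e * e
                      / (eps0 * params.solvent_dielectric * k * params.temperature))
    return kappa_m * 1e-10  # 1/Å


def solve_potential(atoms: Sequence[ParameterizedAtom],
                    params: Optional[GridParams] = None) -> PotentialGrid:
    """Solve the linearized PB equation (Poisson at zero ionic strength).

    Red-black successive over-relaxation on the face-harmonic dielectric
    stencil; convergence is declared when the relative max update drops
    below ``convergence_tol``.  Raises :class:`ConvergenceError` with the
    final residual otherwise.
    """
    if not atoms:
        raise ValueError("need at least one atom")
    params = params or GridParams()
    coords = np.array([a.xyz for a in atoms], dtype=float)
    charges = np.array([a.charge for a in atoms], dtype=float)
    radii = np.array([a.radius for a in atoms], dtype=float)

    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    h = params.choose_spacing(hi - lo)
    origin = lo - params.padding
    shape = tuple(int(np.ceil((hi[d] + params.padding - origin[d]) / h)) + 1
                  for d in range(3))

    rho = _trilinear_spread(coords, charges, origin, h, shape)
    eps = _dielectric_map(coords, radii, origin, h, shape, params)
    phi = _boundary_coulomb(coords, charges, origin, h, shape, params)

    if not np.any(charges):
        grid = PotentialGrid(tuple(origin), h, np.zeros(shape), eps)
        return grid

    # face dielectrics (harmonic mean across each cell face)
    def harm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return 2.0 * a * b / (a + b)

    ex = harm(eps[:-1, :, :], eps[1:, :, :])
    ey = harm(eps[:, :-1, :], eps[:, 1:, :])
    ez = harm(eps[:, :, :-1], eps[:, :, 1:])

    K = 4.0 * np.pi * coulomb_constant(params.temperature)
    src = K * rho[1:-1, 1:-1, 1:-1] / h
    exm = ex[:-1, 1:-1, 1:-1]
    exp_ = ex[1:, 1:-1, 1:-1]
    eym = ey[1:-1, :-1, 1:-1]
    eyp = ey[1:-1, 1:, 1:-1]
    ezm = ez[1:-1, 1:-1, :-1]
    ezp = ez[1:-1, 1:-1, 1:]
    diag = exm + exp_ + eym + eyp + ezm + ezp

    # linearized-PB volume term: kappa^2 h^2 eps_s on solvent nodes
    kappa = _debye_kappa(params)
    if kappa > 0:
        solvent = eps[1:-1, 1:-1, 1:-1] >= 0.5 * (params.solute_dielectric
                                                  + params.solvent_dielectric)
        diag = diag + np.where(solvent,
                               (kappa * h) ** 2 * params.solvent_dielectric, 0.0)

    ii, jj, kk = np.indices(tuple(s - 2 for s in shape))
    red = (ii + jj + kk) % 2 == 0
    black = ~red
    omega = params.omega

    residual = np.inf
    for _ in range(params.max_iterations):
        max_upd = 0.0
        for mask in (red, black):
            nb = (exm * phi[:-2, 1:-1, 1:-1] + exp_ * phi[2:, 1:-1, 1:-1]
                  + eym * phi[1:-1, :-2, 1:-1] + eyp * phi[1:-1, 2:, 1:-1]
                  + ezm * phi[1:-1, 1:-1, :-2] + ezp * phi[1:-1, 1:-1, 2:])
            target = (nb + src) / diag
            inner = phi[1:-1, 1:-1, 1:-1]
            upd = omega * (target - inner)
            inner[mask] += upd[mask]
            max_upd = max(max_upd, float(np.abs(upd[mask]).max()))
        scale = float(np.abs(phi).max()) or 1.0
        residual = max_upd / scale
        if residual < params.convergence_tol:
            break
    else:
        raise ConvergenceError(
            f"no convergence in {params.max_iterations} sweeps "
            f"(final relative residual {residual:.3e})")
    return PotentialGrid(tuple(origin), h, phi, eps)


# ---------------------------------------------------------------------------
# evaluation

def potential_at(grid: PotentialGrid, point: Sequence[float]) -> float:
    """Trilinear interpolation of the eight nodes surrounding ``point``."""
    g = (np.asarray(point, dtype=float) - np.asarray(grid.origin)) / grid.spacing
    if np.any(g < 0) or np.any(g > np.asarray(grid.shape) - 1):
        raise GridBoundsError(f"point {tuple(point)} outside the grid")
    i0 = np.minimum(np.floor(g).astype(int), np.asarray(grid.shape) - 2)
    f = g - i0
    v = 0.0
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        w = float(np.prod(np.where(off, f, 1.0 - f)))
        v += w * float(grid.values[tuple(i0 + off)])
    return v


def pair_pd(grid: PotentialGrid, a: Atom, b: Atom) -> PotentialDifference:
    """PD(a, b) = phi(a) - phi(b) at the reactive atoms, in kT/e."""
    va = potential_at(grid, a.xyz)
    vb = potential_at(grid, b.xyz)
    label = lambda at: f"{at.residue_type}{at.residue_number}:{at.name}"  # noqa: E731
    return PotentialDifference(va - vb, label(a), label(b))


def estimate_pka(intrinsic_pka: float, charging_energy: float,
                 site_is_acid: bool) -> float:
    """Shift the intrinsic pKa by a charging free energy in kT.

    The shift is charging_energy / ln(10); destabilizing the deprotonated
    (charged) form of an acid raises its pKa, while destabilizing the
    protonated form of a base lowers it.
    """
    shift = charging_energy / np.log(10.0)
    return intrinsic_pka + shift if site_is_acid else intrinsic_pka - shift


# ---------------------------------------------------------------------------
# OpenDX interoperability

def write_dx(grid: PotentialGrid) -> str:
    n0, n1, n2 = grid.shape
    h = grid.spacing
    lines = [
        "# OpenDX scalar grid written by clasp",
        f"object 1 class gridpositions counts {n0} {n1} {n2}",
        f"origin {grid.origin[0]:.6e} {grid.origin[1]:.6e} {grid.origin[2]:.6e}",
        f"delta {h:.6e} 0.000000e+00 0.000000e+00",
        f"delta 0.000000e+00 {h:.6e} 0.000000e+00",
        f"delta 0.000000e+00 0.000000e+00 {h:.6e}",
        f"object 2 class gridconnections counts {n0} {n1} {n2}",
        f"object 3 class array type double rank 0 items {n0 * n1 * n2} data follows",
    ]
    flat = grid.values.ravel(order="C")
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    return "\n".join(lines) + "\n"


def read_dx(text: str) -> PotentialGrid:
    counts = None
    origin = None
    deltas = []
    data: list[float] = []
    in_data = False
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith("#") or s.startswith("attribute"):
            continue
        if s.startswith("object") and "gridpositions" in s:
            counts = tuple(int(x) for x in s.split()[-3:])
        elif s.startswith("origin"):
            origin = tuple(float(x) for x in s.split()[1:])
        elif s.startswith("delta"):
            deltas.append([float(x) for x in s.split()[1:]])
        elif s.startswith("object") and "data follows" in s:
            in_data = True
        elif in_data:
            data.extend(float(x) for x in s.split())
    if counts is None or origin is None or not deltas:
        raise ValueError("malformed OpenDX text")
    h = deltas[0][0]
    values = np.array(data).reshape(counts, order="C")
    return PotentialGrid(origin, h, values)


# ---------------------------------------------------------------------------
# external backend contract

def generate_backend_input(pqr_name: str, params: GridParams,
                           dime: tuple[int, int, int] = (97, 97, 97),
                           length: tuple[float, float, float] = (60.0, 60.0, 60.0),
                           ) -> str:
    """Render an APBS-style input deck from :class:`GridParams`."""
    p = params
    return "\n".join([
        "read",
        f"    mol pqr {pqr_name}",
        "end",
        "elec",
        "    mg-manual",
        f"    dime {dime[0]} {dime[1]} {dime[2]}",
        f"    glen {length[0]:.3f} {length[1]:.3f} {length[2]:.3f}",
        "    gcent mol 1",
        "    mol 1",
        "    lpbe",
        "    bcfl sdh",
        f"    pdie {p.solute_dielectric:.3f}",
        f"    sdie {p.solvent_dielectric:.3f}",
        f"    srad {p.probe_radius:.3f}",
        f"    temp {p.temperature:.2f}",
        "    chgm spl2",
        "    srfm smol",
        "    calcenergy no",
        "    calcforce no",
        "    write pot dx pot",
        "end",
        "quit",
    ]) + "\n"


def external_backend(pdb_text: str, params: Optional[GridParams] = None,
                     workdir: Optional[str] = None) -> PotentialGrid:
    """Run the out-of-process pdb2pqr + apbs pipeline and read back the grid.

    Raises :class:`BackendUnavailableError` when the executables are not on
    PATH (the internal solver remains usable) and :class:`BackendError`
    with the captured log on a nonzero exit.
    """
    import os
    import tempfile

    params = params or GridParams()
    pdb2pqr = shutil.which("pdb2pqr") or shutil.which("pdb2pqr30")
    apbs = shutil.which("apbs")
    if pdb2pqr is None or apbs is None:
        raise BackendUnavailableError(
            "external backend needs 'pdb2pqr' and 'apbs' on PATH")
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        pdb_path = os.path.join(tmp, "query.pdb")
        pqr_path = os.path.join(tmp, "query.pqr")
        with open(pdb_path, "w") as fh:
            fh.write(pdb_text)
        r = subprocess.run([pdb2pqr, "--ff=PARSE", pdb_path, pqr_path],
                           capture_output=True, text=True)
        if r.returncode != 0:
            raise BackendError(f"pdb2pqr failed:\n{r.stderr}")
        in_path = os.path.join(tmp, "apbs.in")
        with open(in_path, "w") as fh:
            fh.write(generate_backend_input(pqr_path, params))
        r = subprocess.run([apbs, in_path], capture_output=True, text=True,
                           cwd=tmp)
        if r.returncode != 0:
            raise BackendError(f"apbs failed:\n{r.stderr}")
        with open(os.path.join(tmp, "pot.dx")) as fh:
            return read_dx(fh.read())
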