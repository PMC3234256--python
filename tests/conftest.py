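import numpy as np
import pytest

import clasp
from clasp import fixtures as fx
from clasp.motif_library import build_motif
from clasp.structure_io import Atom, Structure

#: Coarse-but-converged solver settings used throughout the suite; toy
#: fixtures are a few residues, so 0.8 Å spacing resolves the pair PDs.
TEST_GRID = dict(spacing=0.8, padding=8.0)


def minimal_structure(entries, source_id="mini"):
    """Structure of single-reactive-atom residues: (res_type, atom, xyz)."""
    atoms = [
        Atom(name=name, element=name[0], residue_type=rt, residue_number=i + 1,
             chain_id="A", xyz=tuple(map(float, xyz)))
        for i, (rt, name, xyz) in enumerate(entries)
    ]
    return Structure(atoms, source_id=source_id)


@pytest.fixture(scope="session")
def triad_structure():
    return clasp.read_pdb(fx.trypsin_triad_structure(decoys=2),
                          source_id="toy-triad")


@pytest.fixture(scope="session")
def triad_grid(triad_structure):
    return clasp.solve_potential(clasp.assign_parameters(triad_structure),
                                 clasp.GridParams(**TEST_GRID))


@pytest.fixture(scope="session")
def triad_motif(triad_structure, triad_grid):
    return build_motif(triad_structure, triad_grid, ["A:1", "A:2", "A:3"],
                       list(fx.TRYPSIN_TRIAD_GROUPS))


@pytest.fixture(scope="session")
def lactamase_structure():
    return clasp.read_pdb(fx.lactamase_structure(), source_id="toy-lactamase")


@pytest.fixture(scope="session")
def lactamase_grid(lactamase_structure):
    return clasp.solve_potential(clasp.assign_parameters(lactamase_structure),
                                 clasp.GridParams(**TEST_GRID))


@pytest.fixture(scope="session")
def lactamase_motif(lactamase_structure, lactamase_grid):
    return build_motif(lactamase_structure, lactamase_grid,
                       ["A:1", "A:2", "A:3", "A:4"],
                       list(fx.LACTAMASE_GROUPS))


def random_minimal_structure(rng, n_residues, box=12.0, min_sep=2.5):
    """Random structure of single-reactive-atom residues for oracle tests."""
    pool = [("SER", "OG"), ("HIS", "NE2"), ("ASP", "OD1"), ("LYS", "NZ"),
            ("THR", "OG1"), ("ARG", "NH1"), ("ALA", "CB"), ("GLU", "OE1")]
    coords = []
    while len(coords) < n_residues:
        p = rng.uniform(0.0, box, 3)
        if all(np.linalg.norm(p - q) >= min_sep for q in coords):
            coords.append(p)
    entries = []
    for p in coords:
        rt, name = pool[rng.integers(len(pool))]
        entries.append((rt, name, p))
    return minimal_structure(entries, source_id="random")
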