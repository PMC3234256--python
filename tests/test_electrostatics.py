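import dataclasses

import numpy as np
import pytest

from clasp import fixtures as fx
from clasp.electrostatics import (
    BackendUnavailableError,
    GridBoundsError,
    GridParams,
    PotentialGrid,
    coulomb_constant,
    estimate_pka,
    external_backend,
    generate_backend_input,
    pair_pd,
    potential_at,
    read_dx,
    solve_potential,
    write_dx,
)
from clasp.structure_io import Atom


def probe(name, xyz):
    return Atom(name=name, element=name[0], residue_type="UNK",
                residue_number=1, chain_id="A", xyz=xyz)


class TestSolver:
    def test_zero_charges_give_zero_potential(self):
        atoms = fx.make_charge_fixture("monopole")
        atoms = [dataclasses.replace(a, charge=0.0) for a in atoms]
        g = solve_potential(atoms, GridParams(spacing=1.0, padding=6.0))
        assert np.all(g.values == 0.0)

    def test_monopole_matches_analytic_coulomb(self):
        # uniform dielectric 78: the discrete solution must track C q/(78 r)
        atoms = fx.make_charge_fixture("monopole")
        params = GridParams(spacing=0.6, padding=12.0,
                            solute_dielectric=78.0, solvent_dielectric=78.0)
        g = solve_potential(atoms, params)
        C = coulomb_constant(298.0)
        for r in np.arange(3.0, 9.5, 0.7):
            for u in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0.577, 0.577, 0.577)]:
                num = potential_at(g, tuple(r * np.array(u)))
                ana = C / (78.0 * r)
                assert num == pytest.approx(ana, rel=0.05)

    def test_dipole_midplane_is_zero(self):
        atoms = fx.make_charge_fixture("dipole")
        g = solve_potential(atoms, GridParams(spacing=0.5, padding=10.0))
        i_mid = round((0.0 - g.origin[0]) / g.spacing)
        assert np.abs(g.values[i_mid]).max() == pytest.approx(0.0, abs=1e-6)

    def test_linearity_in_charges(self):
        atoms = fx.make_charge_fixture("random", seed=7)
        params = GridParams(spacing=0.8, padding=8.0)
        g1 = solve_potential(atoms, params)
        doubled = [dataclasses.replace(a, charge=2 * a.charge) for a in atoms]
        g2 = solve_potential(doubled, params)
        a, b = probe("P1", (1.0, 1.0, 1.0)), probe("P2", (-2.0, 0.5, 0.0))
        pd1 = pair_pd(g1, a, b).value
        pd2 = pair_pd(g2, a, b).value
        assert pd2 == pytest.approx(2 * pd1, rel=1e-3)

    def test_boundary_offset_leaves_pair_pd_unchanged(self):
        atoms = fx.make_charge_fixture("random", seed=7)
        base = GridParams(spacing=0.8, padding=8.0)
        lifted = dataclasses.replace(base, boundary_offset=50.0)
        g1 = solve_potential(atoms, base)
        g2 = solve_potential(atoms, lifted)
        a, b = probe("P1", (1.0, 1.0, 1.0)), probe("P2", (-2.0, 0.5, 0.0))
        # the potential itself shifts, the difference does not
        assert potential_at(g2, a.xyz) != pytest.approx(
            potential_at(g1, a.xyz), abs=1.0)
        assert pair_pd(g2, a, b).value == pytest.approx(
            pair_pd(g1, a, b).value, abs=0.5)

    def test_grid_refinement_keeps_pair_pd_stable(self):
        # on the uniform-dielectric Coulomb fixture; points near dielectric
        # boundaries are the known grid-sensitive case
        atoms = fx.make_charge_fixture("monopole")
        a, b = probe("P1", (4.0, 0.0, 0.0)), probe("P2", (0.0, 7.0, 0.0))
        pds = []
        for h in (0.6, 0.3):
            g = solve_potential(atoms, GridParams(
                spacing=h, padding=8.0,
                solute_dielectric=78.0, solvent_dielectric=78.0))
            pds.append(pair_pd(g, a, b).value)
        assert pds[1] == pytest.approx(pds[0], rel=0.05)

    def test_spacing_outside_band_rejected(self):
        with pytest.raises(ValueError):
            GridParams(spacing=0.2)
        with pytest.raises(ValueError):
            GridParams(padding=1.0)


@pytest.fixture()
def grid():
    values = np.arange(27, dtype=float).reshape(3, 3, 3)
    return PotentialGrid(origin=(0.0, 0.0, 0.0), spacing=1.0, values=values)


class TestEvaluation:
    def test_point_on_node(self, grid):
        assert potential_at(grid, (1.0, 1.0, 1.0)) == grid.values[1, 1, 1]

    def test_axis_midpoint_is_mean_of_neighbours(self, grid):
        v = potential_at(grid, (1.5, 1.0, 1.0))
        assert v == pytest.approx(0.5 * (grid.values[1, 1, 1]
                                         + grid.values[2, 1, 1]))

    def test_outside_grid_raises(self, grid):
        with pytest.raises(GridBoundsError):
            potential_at(grid, (5.0, 0.0, 0.0))

    def test_pd_of_atom_with_itself_is_zero(self, grid):
        a = probe("P1", (1.0, 1.2, 0.7))
        assert pair_pd(grid, a, a).value == 0.0

    def test_pd_antisymmetry_exact(self, grid):
        a, b = probe("P1", (0.5, 0.5, 0.5)), probe("P2", (1.5, 1.7, 0.9))
        assert pair_pd(grid, a, b).value == -pair_pd(grid, b, a).value


class TestPka:
    def test_zero_energy_no_shift(self):
        assert estimate_pka(4.0, 0.0, site_is_acid=True) == 4.0

    def test_acid_shift_of_one_unit(self):
        assert estimate_pka(4.0, np.log(10.0), site_is_acid=True) == \
            pytest.approx(5.0)

    def test_base_shift_is_opposite(self):
        assert estimate_pka(10.4, np.log(10.0), site_is_acid=False) == \
            pytest.approx(9.4)


class TestDx:
    def test_round_trip(self):
        atoms = fx.make_charge_fixture("dipole")
        g = solve_potential(atoms, GridParams(spacing=1.0, padding=6.0))
        back = read_dx(write_dx(g))
        assert back.spacing == pytest.approx(g.spacing)
        assert np.allclose(back.values, g.values, rtol=1e-5)
        assert back.origin == pytest.approx(g.origin)


class TestExternalBackend:
    def test_params_appear_in_generated_input(self):
        text = generate_backend_input("query.pqr", GridParams())
        assert "pdie 2.000" in text
        assert "sdie 78.000" in text
        assert "srad 1.400" in text
        assert "temp 298.00" in text

    def test_unavailable_error_when_executables_missing(self, monkeypatch):
        monkeypatch.setenv("PATH", "/nonexistent")
        with pytest.raises(BackendUnavailableError):
            external_backend("ATOM ...\n")
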