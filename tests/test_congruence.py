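import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import clasp
from clasp import fixtures as fx
from clasp.congruence import (
    OracleCapError,
    SearchParams,
    brute_force,
    enumerate_candidates,
    pairwise_deviation,
)
from clasp.motif_library import build_motif
from clasp.structure_io import Structure

from tests.conftest import minimal_structure, random_minimal_structure


def geometry_motif(structure, residues, groups):
    return build_motif(structure, None, residues, groups)


def transformed(s: Structure, rot: Rotation, shift) -> Structure:
    import dataclasses
    atoms = [dataclasses.replace(
        a, xyz=tuple(rot.apply(np.asarray(a.xyz)) + shift)) for a in s.atoms]
    return Structure(atoms, source_id=s.source_id)


class TestEnumerate:
    def test_planted_copy_found_exactly_once(self, triad_structure, triad_motif):
        matches = enumerate_candidates(triad_structure, triad_motif)
        exact = [m for m in matches if m.max_abs_deviation < 1e-6]
        assert len(exact) == 1
        assert exact[0].residue_types == ("SER", "HIS", "ASP")

    def test_no_basic_residue_empty_result(self, triad_motif):
        s = minimal_structure([("SER", "OG", (0, 0, 0)),
                               ("ASP", "OD1", (5, 0, 0)),
                               ("SER", "OG", (0, 5, 0))])
        # triad needs a His-like site; none present
        assert enumerate_candidates(s, triad_motif) == []

    def test_matches_sorted_and_duplicate_free(self, triad_structure,
                                               triad_motif):
        params = SearchParams(tolerance=3.0)
        matches = enumerate_candidates(triad_structure, triad_motif, params=params)
        ids = [m.residue_ids for m in matches]
        assert ids == sorted(ids)
        assert len(set(ids)) == len(ids)

    def test_injective_assignment(self, lactamase_motif):
        # a single Ser cannot fill both Ser sites of the tetrad
        coords = fx.LACTAMASE_SITE_COORDS
        s = minimal_structure([
            ("SER", "OG", coords[0]),
            ("LYS", "NZ", coords[1]),
            ("LYS", "NZ", coords[3]),
        ])
        assert enumerate_candidates(s, lactamase_motif) == []

    def test_rigid_motion_invariance(self, triad_structure, triad_motif):
        params = SearchParams(tolerance=2.0)
        before = enumerate_candidates(triad_structure, triad_motif, params=params)
        rot = Rotation.from_euler("xyz", [31.0, -57.0, 12.0], degrees=True)
        after = enumerate_candidates(
            transformed(triad_structure, rot, (8.0, -4.0, 2.5)),
            triad_motif, params=params)
        assert [m.residue_ids for m in before] == [m.residue_ids for m in after]
        for a, b in zip(before, after):
            assert np.allclose(a.delta_d, b.delta_d, atol=1e-9)

    def test_mirror_blindness_documented_limitation(self, triad_structure,
                                                    triad_motif):
        import dataclasses
        mirrored = Structure([
            dataclasses.replace(a, xyz=(-a.xyz[0], a.xyz[1], a.xyz[2]))
            for a in triad_structure.atoms], source_id="mirror")
        params = SearchParams(tolerance=2.0)
        before = enumerate_candidates(triad_structure, triad_motif, params=params)
        after = enumerate_candidates(mirrored, triad_motif, params=params)
        assert [m.residue_ids for m in before] == [m.residue_ids for m in after]

    def test_monotone_in_tolerance(self, triad_structure, triad_motif):
        small = enumerate_candidates(triad_structure, triad_motif,
                                     params=SearchParams(tolerance=0.5))
        large = enumerate_candidates(triad_structure, triad_motif,
                                     params=SearchParams(tolerance=2.5))
        small_ids = {m.residue_ids for m in small}
        large_ids = {m.residue_ids for m in large}
        assert small_ids <= large_ids


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(25))
    def test_equivalence_on_random_small_fixtures(self, seed, triad_motif):
        rng = np.random.default_rng(seed)
        s = random_minimal_structure(rng, n_residues=8)
        params = SearchParams(tolerance=3.0)
        fast = enumerate_candidates(s, triad_motif, params=params)
        slow = brute_force(s, triad_motif, params=params)
        assert [m.residue_ids for m in fast] == [m.residue_ids for m in slow]
        for a, b in zip(fast, slow):
            assert np.allclose(a.d_q, b.d_q)

    def test_empty_structure_empty_result(self, triad_motif):
        s = minimal_structure([("ALA", "CB", (0, 0, 0))])
        assert brute_force(s, triad_motif) == []

    def test_cap_exceeded_guard(self, triad_motif):
        entries = []
        for i, (rt, name) in enumerate(
                [("SER", "OG")] * 4 + [("HIS", "NE2")] * 3 + [("ASP", "OD1")] * 3):
            entries.append((rt, name, (4.0 * i, 0.0, 0.0)))
        s = minimal_structure(entries)
        with pytest.raises(OracleCapError):
            brute_force(s, triad_motif, cap=10)


class TestPairwiseDeviation:
    def test_reference_candidate_zero_vector(self, triad_motif):
        dev = pairwise_deviation(triad_motif.d_ref, triad_motif)
        assert np.allclose(dev, 0.0)

    def test_length_mismatch_errors(self, triad_motif):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_deviation([1.0, 2.0], triad_motif)

    def test_printed_lysozyme_deviation_set_recovered(self, lactamase_motif):
        # candidate constructed to deviate from the tetrad reference by the
        # printed false-positive deviation magnitudes, max below 1 Å
        target = np.array([0.2, 0.7, 0.5, 0.3, 0.7, 1.0])
        coords = fx.deviated_coordinates(lactamase_motif.d_ref, target, 4)
        d_q = np.array([np.linalg.norm(coords[i] - coords[j])
                        for i, j in [(0, 1), (0, 2), (0, 3),
                                     (1, 2), (1, 3), (2, 3)]])
        dev = pairwise_deviation(d_q, lactamase_motif)
        assert np.allclose(np.abs(dev), target, atol=1e-5)
        assert np.abs(dev).max() <= 1.0 + 1e-6

    def test_translation_leaves_deviation_unchanged(self, triad_structure,
                                                    triad_motif):
        m0 = enumerate_candidates(triad_structure, triad_motif)[0]
        shifted = triad_structure.translated((3.0, -9.0, 1.0))
        m1 = enumerate_candidates(shifted, triad_motif)[0]
        assert np.allclose(m0.delta_d, m1.delta_d, atol=1e-9)
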