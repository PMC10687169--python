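"""Ring geometry, pi-pi classification, and cation-pi detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ubrbox import (PiCationCriteria, PiPiThresholds, classify_pi_pi,
                    find_pi_cation_contacts, find_pi_pi_contacts, fit_plane,
                    make_ring_pair, pair_geometry, ring_descriptor)
from ubrbox.geometry import DegeneratePlaneError
from ubrbox.model import Residue, StructureModel

from conftest import atom


def hexagon(radius: float = 1.39, z: float = 0.0) -> np.ndarray:
    ang = np.arange(6) * math.pi / 3.0
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.full(6, z)])


class TestFitPlane:
    def test_flat_hexagon(self):
        c, n, rms = fit_plane(hexagon())
        np.testing.assert_allclose(c, 0.0, atol=1e-12)
        np.testing.assert_allclose(np.abs(n), [0, 0, 1], atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_translation_moves_centroid_only(self):
        shift = np.array([1.0, 2.0, 3.0])
        c, n, _ = fit_plane(hexagon() + shift)
        np.testing.assert_allclose(c, shift, atol=1e-12)
        np.testing.assert_allclose(np.abs(n), [0, 0, 1], atol=1e-12)

    def test_rms_matches_brute_force_normal_search(self):
        # perturbed hexagon; oracle = direct minimization of the mean
        # squared out-of-plane distance over spherical normal directions
        rng = np.random.default_rng(7)
        pts = hexagon() + np.column_stack(
            [np.zeros(6), np.zeros(6), rng.uniform(-0.01, 0.01, 6)])
        _, _, rms = fit_plane(pts)
        centered = pts - pts.mean(axis=0)

        def msd(angles):
            th, ph = angles
            n = np.array([math.sin(th) * math.cos(ph),
                          math.sin(th) * math.sin(ph), math.cos(th)])
            return float(np.mean((centered @ n) ** 2))

        best = min(minimize(msd, x0, method="Nelder-Mead").fun
                   for x0 in [(0.1, 0.1), (1.0, 2.0), (2.0, 4.0)])
        assert rms == pytest.approx(math.sqrt(best), abs=1e-9)

    def test_collinear_points_raise(self):
        pts = np.outer(np.arange(5), [1.0, 2.0, 3.0])
        with pytest.raises(DegeneratePlaneError):
            fit_plane(pts)


class TestRingDescriptor:
    def _residue(self, name, atom_names, coords):
        res = Residue("A", 1, name)
        res.atoms = [atom(n, n[0], name, 1, "A", c)
                     for n, c in zip(atom_names, coords)]
        return res

    def test_phe_single_ring(self):
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        res = self._residue("PHE", names, hexagon())
        rings = ring_descriptor(res)
        assert len(rings) == 1
        assert rings[0].ring_label == "six_membered"
        assert abs(np.linalg.norm(rings[0].normal) - 1.0) < 1e-9

    def test_trp_two_rings(self):
        # idealized indole: fused pentagon + hexagon sharing CD2-CE2
        five = ["CG", "CD1", "NE1", "CE2", "CD2"]
        six = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
        ang5 = np.arange(5) * 2 * math.pi / 5
        pent = np.column_stack([1.17 * np.cos(ang5), 1.17 * np.sin(ang5), np.zeros(5)])
        hexc = hexagon() + np.array([2.4, 0.0, 0.0])
        coords = {n: c for n, c in zip(five, pent)}
        for n, c in zip(six, hexc):
            coords.setdefault(n, c)
        res = self._residue("TRP", list(coords), np.array(list(coords.values())))
        assert len(ring_descriptor(res)) == 2

    def test_missing_atom_skips_ring_with_warning(self, caplog):
        names = ["CG", "CD1", "CE1", "CE2", "CD2"]  # CZ deleted
        res = self._residue("PHE", names, hexagon()[:5])
        with caplog.at_level("WARNING"):
            rings = ring_descriptor(res)
        assert rings == []
        assert any("missing" in r.message for r in caplog.records)

    def test_non_aromatic_residue_gives_no_rings(self):
        res = self._residue("ALA", ["CA"], np.zeros((1, 3)))
        assert ring_descriptor(res) == []


def rings_of(model: StructureModel):
    return [r for res in model.residues() for r in ring_descriptor(res)]


class TestPairGeometry:
    def test_coaxial_parallel_rings(self):
        ra, rb = rings_of(make_ring_pair(5.0, 0.0))
        assert pair_geometry(ra, rb) == (pytest.approx(5.0), pytest.approx(0.0))

    def test_perpendicular_rings(self):
        ra, rb = rings_of(make_ring_pair(5.0, 90.0))
        _, gamma = pair_geometry(ra, rb)
        assert gamma == pytest.approx(90.0, abs=1e-9)

    def test_symmetric_under_swap(self):
        ra, rb = rings_of(make_ring_pair(5.3, 37.0))
        assert pair_geometry(ra, rb) == pair_geometry(rb, ra)

    @pytest.mark.parametrize("r_cen", [3.0, 4.7, 5.5, 6.5, 8.0])
    @pytest.mark.parametrize("gamma", [0.0, 15.0, 44.9, 50.8, 77.6, 90.0])
    def test_constructor_round_trip_grid(self, r_cen, gamma):
        ra, rb = rings_of(make_ring_pair(r_cen, gamma))
        r_meas, g_meas = pair_geometry(ra, rb)
        assert abs(r_meas - r_cen) < 1e-6
        assert abs(g_meas - gamma) < 1e-6

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(3.0, 8.0), st.floats(0.0, 90.0), st.integers(0, 2**31 - 1))
    def test_gamma_invariant_under_rigid_motion(self, r_cen, gamma, seed):
        model = make_ring_pair(r_cen, gamma)
        rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        shift = np.random.RandomState(seed).uniform(-50, 50, 3)
        for a in model.atoms:
            a.position = rot @ a.position + shift
        ra, rb = rings_of(model)
        r_meas, g_meas = pair_geometry(ra, rb)
        assert abs(r_meas - r_cen) < 1e-8
        assert abs(g_meas - gamma) < 1e-7


class TestClassification:
    @pytest.mark.parametrize("r_cen,gamma,expected", [
        (5.5, 50.8, "t_shaped"),    # Phe1713-Tyr1 geometry class
        (5.5, 77.6, "t_shaped"),
        (5.5, 44.9, "intermediate"),
        (5.5, 47.6, "intermediate"),
        (5.0, 5.0, "parallel"),
        (8.0, 5.0, "none"),
        (2.0, 5.0, "none"),
    ])
    def test_default_bands(self, r_cen, gamma, expected):
        assert classify_pi_pi(r_cen, gamma) == expected

    def test_boundaries_left_closed(self):
        assert classify_pi_pi(5.0, 30.0) == "intermediate"
        assert classify_pi_pi(5.0, 29.999999) == "parallel"
        assert classify_pi_pi(5.0, 50.0) == "t_shaped"
        assert classify_pi_pi(5.0, 49.999999) == "intermediate"
        assert classify_pi_pi(5.0, 90.0) == "t_shaped"

    def test_thresholds_configurable(self):
        custom = PiPiThresholds(parallel_max=40.0, t_shaped_min=60.0)
        assert classify_pi_pi(5.0, 35.0, custom) == "parallel"
        assert classify_pi_pi(5.0, 55.0, custom) == "intermediate"

    def test_invalid_thresholds_raise(self):
        with pytest.raises(ValueError):
            PiPiThresholds(parallel_max=60.0, t_shaped_min=40.0)
        with pytest.raises(ValueError):
            PiPiThresholds(r_min=7.0, r_max=3.0)


class TestFindPiPi:
    def test_synthetic_pair_one_contact(self):
        contacts = find_pi_pi_contacts(make_ring_pair(5.5, 60.0))
        assert len(contacts) == 1
        assert contacts[0].conformation == "t_shaped"
        assert contacts[0].intermolecular  # chains A and B

    def test_empty_selection(self):
        contacts = find_pi_pi_contacts(make_ring_pair(5.5, 60.0),
                                       selection=lambda res: False)
        assert contacts == []

    def test_out_of_window_pair_not_reported(self):
        assert find_pi_pi_contacts(make_ring_pair(9.0, 60.0)) == []


class TestPiCation:
    def _with_cation(self, model, resname, atom_specs):
        for name, pos in atom_specs:
            model.atoms.append(atom(name, name[0], resname, 5, "C", pos))
        return model

    def test_lys_on_ring_axis(self):
        model = self._with_cation(make_ring_pair(20.0, 0.0), "LYS",
                                  [("NZ", (0.0, 0.0, 4.0))])
        contacts = find_pi_cation_contacts(model)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(4.0)
        assert contacts[0].offset_angle == pytest.approx(0.0, abs=1e-9)

    def test_beyond_cutoff_not_reported(self):
        model = self._with_cation(make_ring_pair(20.0, 0.0), "LYS",
                                  [("NZ", (0.0, 0.0, 8.0))])
        assert find_pi_cation_contacts(model) == []

    def test_guanidinium_offset_angle(self):
        # guanidinium centre at 45 deg off the ring normal, 4.5 A away
        d = 4.5 / math.sqrt(2.0)
        centre = np.array([d, 0.0, d])
        offsets = [np.array([0.3, 0, 0]), np.array([-0.3, 0, 0]),
                   np.array([0, 0.3, 0]), np.array([0, -0.3, 0])]
        specs = [(n, centre + o) for n, o in zip(("NE", "CZ", "NH1", "NH2"), offsets)]
        model = self._with_cation(make_ring_pair(20.0, 0.0), "ARG", specs)
        contacts = find_pi_cation_contacts(
            model, criteria=PiCationCriteria(max_distance=6.0, max_offset_angle=60.0))
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(4.5, abs=1e-9)
        assert contacts[0].offset_angle == pytest.approx(45.0, abs=0.1)
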