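"""Superposition RMSD, its decomposition, contacts, H-bonds and geometry."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pacemix import fixtures
from pacemix.analysis import (
    AnalysisError, count_backbone_hbonds, count_interface_contacts,
    pore_metrics, projection_area, rmsd_decomposition, superpose_rmsd,
    tilt_angle, trajectory_metrics, trimer_geometry,
)
from pacemix.model_core import CG, UA
from pacemix.partitioner import PartitionSpec


class TestSuperpose:
    def test_identical_sets_zero(self):
        x = np.random.default_rng(0).uniform(0, 1, (10, 3))
        _, _, rmsd = superpose_rmsd(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 2, (20, 3))
        R = Rotation.random(random_state=rng).as_matrix()
        y = x @ R.T + np.array([1.0, -2.0, 0.5])
        _, _, rmsd = superpose_rmsd(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_two_point_hand_solution(self):
        ref = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        mob = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        _, _, rmsd = superpose_rmsd(ref, mob)
        assert rmsd == pytest.approx(0.1, rel=1e-9)

    def test_agrees_with_scipy_align_vectors(self):
        """Independent cross-check against scipy's Kabsch implementation."""
        rng = np.random.default_rng(2)
        ref = rng.uniform(0, 2, (15, 3))
        mob = ref + rng.normal(0, 0.1, ref.shape)
        _, _, rmsd = superpose_rmsd(ref, mob)
        rot, rssd = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        assert rmsd == pytest.approx(rssd / math.sqrt(len(ref)), rel=1e-6)

    def test_shape_mismatch_errors(self):
        with pytest.raises(AnalysisError):
            superpose_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def uniform_partition(s, boundary):
    assignment = {}
    for ch in s.chains:
        for r in ch.residues:
            assignment[(ch.id, r.index)] = UA if r.index <= boundary else CG
    return PartitionSpec.from_assignment(s, assignment)


class TestRMSDDecomposition:
    def test_identical_model_all_zero(self, two_domain):
        s, (spec, _) = two_domain
        rep = rmsd_decomposition(s, s, spec)
        assert rep.rmsd_all == pytest.approx(0.0, abs=1e-9)
        assert rep.rmsd_ua == pytest.approx(0.0, abs=1e-9)
        assert rep.rmsd_cg == pytest.approx(0.0, abs=1e-9)
        assert rep.rmsd_itf == pytest.approx(0.0, abs=1e-9)
        assert rep.n == rep.n_ua + rep.n_cg == s.n_residues

    def test_rigid_hinge_goes_entirely_to_interface(self):
        s = fixtures.make_ideal_helix(30)
        spec = uniform_partition(s, 15)
        model = s.copy()
        xyz = model.coords()
        sites = list(model.sites())
        mask = np.array([site.residue_index > 15 for site in sites])
        pivot = xyz[mask].mean(axis=0)
        R = Rotation.from_euler("y", 25, degrees=True).as_matrix()
        xyz[mask] = (xyz[mask] - pivot) @ R.T + pivot
        model.set_coords(xyz)
        rep = rmsd_decomposition(s, model, spec)
        assert rep.rmsd_ua == pytest.approx(0.0, abs=1e-6)
        assert rep.rmsd_cg == pytest.approx(0.0, abs=1e-6)
        assert rep.rmsd_itf == pytest.approx(rep.rmsd_all, rel=1e-6)
        assert rep.rmsd_all > 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_decomposition_inequality_random_perturbations(self, seed):
        s = fixtures.make_ideal_helix(40)
        spec = uniform_partition(s, 20)
        model = fixtures.perturb_coordinates(s, amplitude=2.0, seed=seed)
        rep = rmsd_decomposition(s, model, spec)
        lhs = rep.n * rep.rmsd_all ** 2
        rhs = rep.n_ua * rep.rmsd_ua ** 2 + rep.n_cg * rep.rmsd_cg ** 2
        assert lhs >= rhs - 1e-9
        assert rep.rmsd_itf >= 0.0

    def test_empty_cg_set_reports_undefined_interface(self):
        s = fixtures.make_ideal_helix(10)
        spec = PartitionSpec.uniform(s, UA)
        rep = rmsd_decomposition(s, fixtures.perturb_coordinates(s, 1.0, 1), spec)
        assert rep.rmsd_cg is None and rep.rmsd_itf is None
        assert rep.n_cg == 0


class TestContacts:
    def test_separated_subunits_zero(self):
        s = fixtures.make_ideal_helix(20)
        spec = uniform_partition(s, 10)
        xyz = s.coords()
        sites = list(s.sites())
        mask = np.array([site.residue_index > 10 for site in sites])
        xyz[mask] += np.array([5.0, 0, 0])   # 50 A apart
        s2 = s.copy()
        s2.set_coords(xyz)
        assert count_interface_contacts(s2, spec) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        s = fixtures.make_ideal_helix(30)
        spec = uniform_partition(s, 15)
        s2 = fixtures.perturb_coordinates(s, 3.0, seed)
        n = count_interface_contacts(s2, spec)
        # brute force over backbone sites
        ua, cg = [], []
        for ch in s2.chains:
            for r in ch.residues:
                (ua if spec.resolution_of(ch.id, r.index) == UA else cg).append(
                    r.backbone_site.position)
        brute = sum(1 for a in ua for b in cg
                    if np.linalg.norm(a - b) * 10 < 6.0)
        assert n == brute

    def test_monotone_in_cutoff(self):
        s = fixtures.make_ideal_helix(30)
        spec = uniform_partition(s, 15)
        counts = [count_interface_contacts(s, spec, c) for c in (8.0, 6.0, 4.0, 2.0)]
        assert counts == sorted(counts, reverse=True)


class TestBackboneHbonds:
    def test_extended_chain_zero(self):
        assert count_backbone_hbonds(fixtures.make_extended_strand(15)) == 0

    def test_ideal_helix_equals_brute_force(self):
        s = fixtures.make_ideal_helix(15)
        n = count_backbone_hbonds(s)
        ch = s.chains[0]
        by_index = {r.index: r for r in ch.residues}
        brute = 0
        for r in ch.residues:
            for off in (3, 4):
                p = by_index.get(r.index + off)
                if p is None or r.ss_label != "H" or p.ss_label != "H":
                    continue
                d = np.linalg.norm(r.site("O").position - p.site("N").position) * 10
                if d <= 3.5:
                    brute += 1
        assert n == brute > 0

    def test_infinite_cutoff_counts_all_candidates(self):
        s = fixtures.make_ideal_helix(15)
        n_all = count_backbone_hbonds(s, cutoff=float("inf"))
        helical = [r.index for r in s.residues() if r.ss_label == "H"]
        expected = sum(1 for i in helical for off in (3, 4) if i + off in helical)
        assert n_all == expected


class TestProjectionArea:
    def test_equilateral_closed_form(self):
        p = [np.array([1.0, 0, 0]), np.array([-0.5, math.sqrt(3) / 2, 0]),
             np.array([-0.5, -math.sqrt(3) / 2, 0])]
        rep = projection_area(*(x * (1 / math.sqrt(3)) for x in p))
        assert rep.circumradius == pytest.approx(1 / math.sqrt(3), rel=1e-12)
        assert rep.projection_area == pytest.approx(math.pi / 3, rel=1e-12)

    def test_3_4_5_right_triangle(self):
        rep = projection_area(np.zeros(3), np.array([3.0, 0, 0]), np.array([0.0, 4, 0]))
        assert rep.circumradius == pytest.approx(2.5, rel=1e-12)
        assert rep.projection_area == pytest.approx(math.pi * 6.25, rel=1e-12)
        assert rep.projection_area == pytest.approx(19.635, abs=1e-3)

    def test_collinear_errors(self):
        with pytest.raises(AnalysisError):
            projection_area(np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))


class TestTiltAngle:
    def test_parallel_zero(self):
        assert tilt_angle([[0, 0, 1]], [[0, 0, 0]], [[0, 0, 1]], [[0, 0, 0]]) == pytest.approx(0.0)

    def test_orthogonal_ninety(self):
        assert tilt_angle([[1, 0, 0]], [[0, 0, 0]], [[0, 0, 1]], [[0, 0, 0]]) == pytest.approx(90.0)

    def test_zero_length_errors(self):
        with pytest.raises(AnalysisError):
            tilt_angle([[0, 0, 0]], [[0, 0, 0]], [[0, 0, 1]], [[0, 0, 0]])

    @pytest.mark.parametrize("tilt", [30.0, 63.0, 90.0, 120.0])
    def test_trimer_round_trip(self, tilt):
        s, sel = fixtures.make_trimer_toy(tilt=tilt, radius=1.0)
        rep = trimer_geometry(s, sel)
        assert rep.tilt_angle == pytest.approx(tilt, abs=0.1)


class TestPoreMetrics:
    def test_c3_symmetry_equal_distances(self, trimer):
        s, sel = trimer
        pos = {site.id: site.position for site in s.sites()}
        t37 = [np.array([pos[i] for i in ids]) for ids in sel["tm37"]]
        t38 = [np.array([pos[i] for i in ids]) for ids in sel["tm38"]]
        center = np.vstack(t37 + t38).mean(axis=0)
        per_chain = [np.linalg.norm(x.mean(axis=0) - center) for x in t37]
        assert max(per_chain) - min(per_chain) < 1e-12

    def test_explicit_radius_construction(self):
        s, sel = fixtures.make_trimer_toy(tilt=63.0, radius=1.0, r37=1.0, r38=0.5)
        rep = trimer_geometry(s, sel)
        assert rep.d37 == pytest.approx(10.0, abs=1e-9)
        assert rep.d38 == pytest.approx(5.0, abs=1e-9)
        assert rep.dV == pytest.approx(10.0, abs=1e-9)

    def test_translation_invariance(self, trimer):
        s, sel = trimer
        rep1 = trimer_geometry(s, sel)
        s2 = s.copy()
        s2.set_coords(s.coords() + np.array([3.0, -2.0, 7.0]))
        rep2 = trimer_geometry(s2, sel)
        assert rep2.d37 == pytest.approx(rep1.d37, abs=1e-9)
        assert rep2.d38 == pytest.approx(rep1.d38, abs=1e-9)
        assert rep2.dV == pytest.approx(rep1.dV, abs=1e-9)
        assert rep2.projection_area == pytest.approx(rep1.projection_area, rel=1e-12)

    def test_wrong_selection_count_errors(self):
        with pytest.raises(AnalysisError):
            pore_metrics([np.zeros((2, 3))] * 2, [np.zeros((2, 3))] * 3,
                         [np.zeros(3)] * 3)


def test_trajectory_metrics_frames(two_domain):
    s, (spec, _) = two_domain
    traj = s.copy()
    traj.extra_frames = [fixtures.perturb_coordinates(s, 1.0, k).coords()
                         for k in (1, 2)]
    df = trajectory_metrics(s, traj, spec)
    assert list(df["frame"]) == [0, 1, 2]
    assert df.loc[0, "rmsd_all"] == pytest.approx(0.0, abs=1e-9)
    assert (df.loc[1:, "rmsd_all"] > 0).all()
    assert set(df.columns) >= {"rmsd_all", "rmsd_ua", "rmsd_cg", "rmsd_itf",
                               "contacts", "hbonds"}
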