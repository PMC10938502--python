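"""CG mapping, interface bonded terms, elastic networks, exclusions, HMR."""

import numpy as np
import pytest

from pacemix import fixtures
from pacemix.energy_eval import bonded_elastic_energy
from pacemix.model_core import CG, UA, Chain, Residue, Site, Structure
from pacemix.topology_builder import (
    ELASTIC_HI, ELASTIC_LO, K_ANGLE_INTERFACE, K_BOND_INTERFACE, K_ELASTIC,
    HarmonicBond, MixedTopology, TopologyError, apply_hmr,
    build_elastic_network, build_interface_bonded, build_mixed_topology,
    map_residue_to_beads, map_to_cg, read_topology, write_topology,
)

_LYS_SIDE = {
    # name -> (position nm, mass)
    "CB": ([0.10, 0.00, 0.00], 12.011), "CG": ([0.20, 0.05, 0.00], 12.011),
    "CD": ([0.30, 0.00, 0.05], 12.011), "CE": ([0.40, 0.05, 0.00], 12.011),
    "NZ": ([0.50, 0.00, 0.00], 14.007),
}


def lys_residue():
    r = Residue(index=1, name="LYS")
    r.sites.append(Site(id=0, chain_id="A", residue_index=1, name="CA",
                        position=np.array([1.0, 2.0, 3.0]), mass=12.011, element="C"))
    for i, (name, (pos, mass)) in enumerate(_LYS_SIDE.items(), start=1):
        r.sites.append(Site(id=i, chain_id="A", residue_index=1, name=name,
                            position=np.array(pos), mass=mass, element=name[0]))
    return r


class TestMapToCG:
    def test_bb_sits_on_calpha(self):
        beads = map_residue_to_beads(lys_residue())
        bb = next(b for b in beads if b.name == "BB")
        assert np.allclose(bb.position, [1.0, 2.0, 3.0])

    def test_gly_maps_to_bb_only(self):
        r = Residue(index=1, name="GLY", sites=[
            Site(id=0, chain_id="A", residue_index=1, name="CA",
                 position=np.zeros(3), mass=12.011, element="C")])
        beads = map_residue_to_beads(r)
        assert [b.name for b in beads] == ["BB"]

    def test_lys_side_beads_at_member_com(self):
        beads = {b.name: b for b in map_residue_to_beads(lys_residue())}
        assert set(beads) == {"BB", "SC1", "SC2"}
        # oracle: direct mass-weighted COM over the member atoms
        for bead, members in (("SC1", ("CB", "CG", "CD")), ("SC2", ("CE", "NZ"))):
            pos = np.array([_LYS_SIDE[m][0] for m in members])
            w = np.array([_LYS_SIDE[m][1] for m in members])
            com = (pos * w[:, None]).sum(axis=0) / w.sum()
            assert np.allclose(beads[bead].position, com, atol=1e-12)

    def test_unknown_residue_name_errors(self):
        r = Residue(index=1, name="XXX", sites=[
            Site(id=0, chain_id="A", residue_index=1, name="CA", position=np.zeros(3))])
        with pytest.raises(TopologyError, match="absent"):
            map_residue_to_beads(r)

    def test_mixed_structure_resolutions(self, two_domain):
        s, (spec, _) = two_domain
        mixed = map_to_cg(s, spec.residues_with(CG))
        for ch in mixed.chains:
            for r in ch.residues:
                want = spec.resolution_of(ch.id, r.index)
                assert {site.resolution for site in r.sites} == {want}


class TestInterfaceBonded:
    def test_term_inventory_and_constants(self, two_domain):
        s, (spec, _) = two_domain
        _, top = build_mixed_topology(s, spec)
        iface = [b for b in top.bonds if b.origin == "interface"]
        assert len(iface) == 1
        assert iface[0].k == K_BOND_INTERFACE == 150000.0
        assert len(top.angles) == 2
        assert all(a.k == K_ANGLE_INTERFACE == 40.0 for a in top.angles)
        assert all(b.k == K_ELASTIC == 500.0 for b in top.elastic_bonds)

    def test_zero_energy_at_reference(self, two_domain):
        s, (spec, _) = two_domain
        _, top = build_mixed_topology(s, spec)
        e_bonded, e_elastic = bonded_elastic_energy(top)
        assert e_bonded == 0.0
        assert e_elastic == 0.0

    def test_stretched_interface_bond_energy(self, two_domain):
        s, (spec, _) = two_domain
        _, top = build_mixed_topology(s, spec)
        bond = next(b for b in top.bonds if b.origin == "interface")
        only = MixedTopology(sites=top.sites, bonds=[bond])
        coords = top.coords().copy()
        i_a = next(i for i, x in enumerate(top.sites) if x.id == bond.site_a)
        i_b = next(i for i, x in enumerate(top.sites) if x.id == bond.site_b)
        u = coords[i_b] - coords[i_a]
        coords[i_b] += 0.01 * u / np.linalg.norm(u)
        e, _ = bonded_elastic_energy(only, coords)
        assert e == pytest.approx(0.5 * 150000.0 * 0.01 ** 2, rel=1e-9)  # 7.5 kJ/mol

    @pytest.mark.parametrize("d", [0.45, 0.60, 0.85, 0.95])
    def test_cross_elastic_native_contact_window(self, d):
        """The i-bead-to-C-alpha pair gets a spring iff 0.5 < d < 0.9 nm."""
        positions = {
            ("CA", 1): np.array([-0.38, 0.01, 0.0]),
            ("CA", 2): np.array([0.0, 0.0, 0.0]),
            ("BB", 3): np.array([0.38, 0.0, 0.0]),
            ("BB", 4): np.array([0.0, d, 0.0]),   # controlled pair vs CA(2)
        }
        residues = []
        for sid, ((name, idx), pos) in enumerate(positions.items()):
            residues.append(Residue(index=idx, name="ALA", sites=[
                Site(id=sid, chain_id="A", residue_index=idx, name=name,
                     position=pos, resolution=CG if name == "BB" else UA,
                     mass=72.0 if name == "BB" else 12.011,
                     type_key="P5" if name == "BB" else "",
                     element="X" if name == "BB" else "C")]))
        mixed = Structure(chains=[Chain(id="A", residues=residues)])
        from pacemix.partitioner import PartitionSpec
        spec = PartitionSpec.from_assignment(
            mixed, {("A", 1): UA, ("A", 2): UA, ("A", 3): CG, ("A", 4): CG})
        _, _, elastic = build_interface_bonded(mixed, spec)
        bb4 = mixed.residue("A", 4).site("BB")
        ca2 = mixed.residue("A", 2).site("CA")
        pair = (min(bb4.id, ca2.id), max(bb4.id, ca2.id))
        present = pair in {(b.site_a, b.site_b) for b in elastic}
        assert present == (0.5 < d < 0.9)


class TestElasticNetwork:
    @staticmethod
    def bb(i, x, chain="A"):
        return Site(id=i, chain_id=chain, residue_index=i + 1, name="BB",
                    position=np.array([x, 0.0, 0.0]), resolution=CG, mass=72.0)

    def test_collinear_beads_three_springs(self):
        sites = [self.bb(i, 0.4 * i) for i in range(5)]
        springs = build_elastic_network(sites)
        pairs = {(b.site_a, b.site_b) for b in springs}
        assert pairs == {(0, 2), (1, 3), (2, 4)}
        assert all(b.d0 == pytest.approx(0.8) for b in springs)

    @pytest.mark.parametrize("d", [0.95, 0.49, 0.5, 0.9])
    def test_window_is_open_interval(self, d):
        sites = [self.bb(0, 0.0), self.bb(2, d)]
        assert build_elastic_network(sites) == []

    def test_adjacent_beads_never_spring(self):
        sites = [self.bb(0, 0.0), self.bb(1, 0.7)]
        assert build_elastic_network(sites) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_filter(self, seed):
        rng = np.random.default_rng(seed)
        sites = [self.bb(i, 0.0) for i in range(25)]
        for s in sites:
            s.position = rng.uniform(0, 2.0, 3)
        springs = {(b.site_a, b.site_b) for b in build_elastic_network(sites)}
        brute = set()
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                d = float(np.linalg.norm(sites[i].position - sites[j].position))
                if ELASTIC_LO < d < ELASTIC_HI and abs(
                        sites[i].residue_index - sites[j].residue_index) >= 2:
                    brute.add((sites[i].id, sites[j].id))
        assert springs == brute


class TestExclusions:
    def test_interface_neighbourhood(self, two_domain):
        s, (spec, _) = two_domain
        mixed, top = build_mixed_topology(s, spec)
        cut = spec.cuts[0]
        b = cut.residue_index
        ca_b = mixed.residue("A", b).site("CA")       # k site
        bb1 = mixed.residue("A", b + 1).site("BB")    # j site (1 bond)
        bb2 = mixed.residue("A", b + 2).site("BB")    # 2 bonds
        bb3 = mixed.residue("A", b + 3).site("BB")    # 3 bonds
        def pair(x, y):
            return (min(x.id, y.id), max(x.id, y.id))
        assert pair(ca_b, bb1) in top.exclusions
        assert pair(ca_b, bb2) in top.exclusions
        assert pair(ca_b, bb3) not in top.exclusions

    def test_exclusions_symmetric_storage(self, two_domain):
        s, (spec, _) = two_domain
        _, top = build_mixed_topology(s, spec)
        assert all(a < b for a, b in top.exclusions)


class TestHMR:
    @staticmethod
    def topology_with_hydrogens():
        sites = [
            Site(id=0, chain_id="A", residue_index=1, name="N",
                 position=np.zeros(3), mass=14.007, element="N"),
            Site(id=1, chain_id="A", residue_index=1, name="H",
                 position=np.array([0.10, 0, 0]), mass=1.008, element="H"),
            Site(id=2, chain_id="A", residue_index=1, name="CA",
                 position=np.array([0.0, 0.15, 0]), mass=12.011, element="C"),
        ]
        return MixedTopology(sites=sites)

    def test_mass_borrowed_from_bonded_heavy_atom(self):
        top = apply_hmr(self.topology_with_hydrogens(), 4.0)
        by_name = {s.name: s for s in top.sites}
        assert by_name["H"].mass == pytest.approx(4.032)
        assert by_name["N"].mass == pytest.approx(14.007 - 3.024)
        assert by_name["CA"].mass == 12.011

    def test_total_mass_conserved(self):
        base = self.topology_with_hydrogens()
        top = apply_hmr(base, 4.0)
        assert top.total_mass == pytest.approx(base.total_mass, rel=1e-14)

    def test_factor_one_is_identity(self):
        base = self.topology_with_hydrogens()
        top = apply_hmr(base, 1.0)
        assert [s.mass for s in top.sites] == [s.mass for s in base.sites]

    def test_orphan_hydrogen_errors(self):
        top = MixedTopology(sites=[
            Site(id=0, chain_id="A", residue_index=1, name="H",
                 position=np.zeros(3), mass=1.008, element="H")])
        with pytest.raises(TopologyError):
            apply_hmr(top, 4.0)


class TestSerialization:
    def test_round_trip_identical(self, two_domain, tmp_path):
        s, (spec, _) = two_domain
        _, top = build_mixed_topology(s, spec)
        path = tmp_path / "mixed.top"
        write_topology(top, path)
        back = read_topology(path)
        assert top.equals(back)

    def test_round_trip_after_hmr(self, two_domain, tmp_path):
        s, (spec, _) = two_domain
        _, top = build_mixed_topology(s, spec)
        top = apply_hmr(top, 4.0)
        path = tmp_path / "mixed.top"
        write_topology(top, path)
        assert read_topology(path).hmr_factor == 4.0
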