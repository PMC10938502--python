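"""Mixed-resolution topology construction.

Builds everything the cross-resolution potential needs from a structure and
a partition: coarse-grained mapping (backbone bead on C-alpha, side-chain
beads at member-atom centres of mass), the bonded terms that stitch each
interface together (one stiff bond between the boundary BB bead and
C-alpha, two angles over the four sites flanking the cut, with equilibria
measured on the reference structure), elastic networks (the standard CG
network plus cross-resolution springs near each interface), exclusions
(pairs separated by at most two covalent bonds), the mixed nonbonded pair
table, and hydrogen-mass repartitioning.

Force constants (from the parent CG elastic-network model): interface bond
150000 kJ nm^-2 mol^-1, interface angle 40.0 kJ mol^-1, elastic springs
500 kJ nm^-2 mol^-1 applied to native-contact pairs with reference distance
between 0.5 and 0.9 nm.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .mappings import CG_MAPPING, BeadDef
from .model_core import CG, UA, Chain, Residue, Site, Structure, StructureError
from .param_mixer import (
    LJParams, ParamTable, ScalingFactors, build_cross_table, default_cg_table,
    default_ua_table, scale_pair_table,
)
from .partitioner import PartitionError, PartitionSpec, validate_partition

K_BOND_INTERFACE = 150000.0   # kJ nm^-2 mol^-1
K_ANGLE_INTERFACE = 40.0      # kJ mol^-1 rad^-2
K_ELASTIC = 500.0             # kJ nm^-2 mol^-1
K_BOND_CG_BACKBONE = 150000.0
ELASTIC_LO = 0.5              # nm
ELASTIC_HI = 0.9              # nm
ELASTIC_MIN_SEQ_SEP = 2

ORIGIN_INTERFACE = "interface"
ORIGIN_ELASTIC = "elastic"
ORIGIN_CG_BACKBONE = "cg_backbone"

# covalent bond detection cutoffs, nm
_HEAVY_BOND_CUTOFF = 0.18
_H_BOND_CUTOFF = 0.125


class TopologyError(ValueError):
    pass


@dataclass(frozen=True)
class HarmonicBond:
    site_a: int
    site_b: int
    k: float          # kJ nm^-2 mol^-1
    d0: float         # nm
    origin: str

    def __post_init__(self):
        if self.d0 <= 0 or self.k <= 0:
            raise TopologyError(f"bond {self.site_a}-{self.site_b}: need positive k and d0")


@dataclass(frozen=True)
class HarmonicAngle:
    site_i: int
    site_j: int
    site_k: int
    k: float          # kJ mol^-1 rad^-2
    theta0: float     # degrees

    def __post_init__(self):
        if not 0.0 < self.theta0 < 180.0:
            raise TopologyError(f"angle equilibrium {self.theta0} outside (0, 180)")


@dataclass
class MixedTopology:
    sites: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    elastic_bonds: list = field(default_factory=list)
    exclusions: set = field(default_factory=set)     # frozenset-free sorted pairs
    pair_table: dict = field(default_factory=dict)   # (ua_type, cg_type) -> LJParams
    scaling: ScalingFactors = field(default_factory=ScalingFactors)
    hmr_factor: float = 1.0

    def site_by_id(self, sid: int) -> Site:
        return self._index()[sid]

    def _index(self) -> dict:
        if not hasattr(self, "_site_index") or len(self._site_index) != len(self.sites):
            self._site_index = {s.id: s for s in self.sites}
        return self._site_index

    def coords(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.sites))

    def equals(self, other: "MixedTopology", tol: float = 0.0) -> bool:
        if len(self.sites) != len(other.sites):
            return False
        for a, b in zip(self.sites, other.sites):
            if (a.id, a.chain_id, a.residue_index, a.name, a.resolution,
                    a.type_key, a.element) != (b.id, b.chain_id, b.residue_index,
                                               b.name, b.resolution, b.type_key, b.element):
                return False
            if abs(a.charge - b.charge) > tol or abs(a.mass - b.mass) > tol:
                return False
            if np.max(np.abs(a.position - b.position)) > tol:
                return False
        def close(x, y):
            return abs(x - y) <= tol
        for la, lb in ((self.bonds, other.bonds), (self.elastic_bonds, other.elastic_bonds)):
            if len(la) != len(lb):
                return False
            for x, y in zip(la, lb):
                if (x.site_a, x.site_b, x.origin) != (y.site_a, y.site_b, y.origin):
                    return False
                if not (close(x.k, y.k) and close(x.d0, y.d0)):
                    return False
        if len(self.angles) != len(other.angles):
            return False
        for x, y in zip(self.angles, other.angles):
            if (x.site_i, x.site_j, x.site_k) != (y.site_i, y.site_j, y.site_k):
                return False
            if not (close(x.k, y.k) and close(x.theta0, y.theta0)):
                return False
        if self.exclusions != other.exclusions:
            return False
        if set(self.pair_table) != set(other.pair_table):
            return False
        for key in self.pair_table:
            a, b = self.pair_table[key], other.pair_table[key]
            if not (close(a.epsilon, b.epsilon) and close(a.sigma, b.sigma)):
                return False
        return (close(self.hmr_factor, other.hmr_factor)
                and close(self.scaling.gamma, other.scaling.gamma)
                and close(self.scaling.eta, other.scaling.eta)
                and close(self.scaling.zeta, other.scaling.zeta))


# ---------------------------------------------------------------------------
# CG mapping

def map_residue_to_beads(residue: Residue, table: dict = CG_MAPPING) -> list[Site]:
    """Beads for one residue: BB on the C-alpha, side-chain beads at the
    mass-weighted centre of their member heavy atoms (ids unset)."""
    if residue.name not in table:
        raise TopologyError(f"residue name {residue.name!r} absent from the CG mapping table")
    ca = residue.site("CA") or residue.site("BB")
    if ca is None:
        raise TopologyError(f"residue {residue.index} lacks a CA/BB site for mapping")
    beads: list[Site] = []
    for bead in table[residue.name]:
        if bead.name == "BB":
            pos = ca.position.copy()
        else:
            members = [residue.site(m) for m in bead.members]
            members = [m for m in members if m is not None]
            if not members:
                continue   # side chain not present in this (possibly backbone-only) model
            w = np.array([max(m.mass, 1.0) for m in members])
            pos = np.average([m.position for m in members], axis=0, weights=w)
        beads.append(Site(
            id=-1, chain_id=ca.chain_id, residue_index=residue.index, name=bead.name,
            position=pos, resolution=CG, mass=bead.mass, type_key=bead.type_key,
            element="X",
        ))
    return beads


def map_to_cg(s: Structure, cg_residues: set, table: dict = CG_MAPPING) -> Structure:
    """Mixed structure: residues in ``cg_residues`` (set of ``(chain_id,
    residue_index)``) replaced by beads, the rest kept united-atom.  Site ids
    are renumbered consecutively."""
    out = Structure(box=None if s.box is None else s.box.copy())
    sid = 0
    for ch in s.chains:
        new_ch = Chain(id=ch.id)
        for r in ch.residues:
            new_r = Residue(index=r.index, name=r.name, ss_label=r.ss_label,
                            environment=r.environment)
            if (ch.id, r.index) in cg_residues:
                new_sites = map_residue_to_beads(r, table)
            else:
                import copy as _copy
                new_sites = [_copy.deepcopy(site) for site in r.sites]
            for site in new_sites:
                site.id = sid
                sid += 1
                new_r.sites.append(site)
            new_ch.residues.append(new_r)
        out.chains.append(new_ch)
    return out


_UA_TYPE_FALLBACK = {"C": "CT", "N": "NT", "O": "OT", "H": "H", "S": "S"}


def assign_site_types(s: Structure, ua_table: ParamTable, cg_table: ParamTable) -> None:
    """Fill ``type_key``/``charge`` on every site from the parameter tables.

    UA atoms are typed by atom name when the name is a table key, otherwise
    by an element-based generic type; CG beads were typed by the mapping
    table and only pick up their charge here.
    """
    for site in s.sites():
        if site.resolution == CG:
            if site.type_key not in cg_table:
                raise TopologyError(f"bead type {site.type_key!r} missing from the CG table")
            site.charge = cg_table.charge(site.type_key)
        else:
            key = site.name if site.name in ua_table else _UA_TYPE_FALLBACK.get(site.element)
            if key is None or key not in ua_table:
                raise TopologyError(
                    f"no UA parameters for atom {site.name!r} (element {site.element!r})")
            site.type_key = key
            site.charge = ua_table.charge(key)


# ---------------------------------------------------------------------------
# bonded terms

def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosx = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosx, -1.0, 1.0))))


def _interface_sites(mixed: Structure, cut) -> tuple:
    """(i, j, k, l) sites around one cut: i, j BB beads on the CG side
    (j adjacent to the interface), k, l C-alphas on the UA side (k adjacent).
    i and l may be None at chain termini."""
    ch = next(c for c in mixed.chains if c.id == cut.chain_id)
    pos = {r.index: r for r in ch.residues}

    def bb(idx):
        r = pos.get(idx)
        return r.site("BB") if r is not None else None

    def ca(idx):
        r = pos.get(idx)
        return r.site("CA") if r is not None else None

    b = cut.residue_index
    if cut.cg_side == "N-terminal":
        i, j, k, l = bb(b - 1), bb(b), ca(b + 1), ca(b + 2)
    else:
        i, j, k, l = bb(b + 2), bb(b + 1), ca(b), ca(b - 1)
    if j is None or k is None:
        raise TopologyError(
            f"cut at {cut.chain_id}:{b}: boundary residue lacks its BB/CA site")
    return i, j, k, l


def build_interface_bonded(mixed: Structure, p: PartitionSpec):
    """Bonded terms for every interface cut, with equilibria measured on the
    reference coordinates.

    Per cut: one stiff bond j-k across the interface, angles i-j-k and
    j-k-l, and cross-resolution elastic springs between the near-interface
    sites ({i, j} against every UA C-alpha; every BB bead against {k, l})
    whose reference distance falls in the 0.5-0.9 nm native-contact window.
    """
    bonds: list[HarmonicBond] = []
    angles: list[HarmonicAngle] = []
    elastic: list[HarmonicBond] = []
    all_ca = [s for s in mixed.sites() if s.name == "CA" and s.resolution == UA]
    all_bb = [s for s in mixed.sites() if s.name == "BB"]
    seen_pairs: set = set()
    for cut in p.cuts:
        i, j, k, l = _interface_sites(mixed, cut)
        bonds.append(HarmonicBond(j.id, k.id, K_BOND_INTERFACE,
                                  float(np.linalg.norm(j.position - k.position)),
                                  ORIGIN_INTERFACE))
        seen_pairs.add(tuple(sorted((j.id, k.id))))
        if i is not None:
            angles.append(HarmonicAngle(i.id, j.id, k.id, K_ANGLE_INTERFACE,
                                        _angle_deg(i.position, j.position, k.position)))
        if l is not None:
            angles.append(HarmonicAngle(j.id, k.id, l.id, K_ANGLE_INTERFACE,
                                        _angle_deg(j.position, k.position, l.position)))
        near_cg = [x for x in (i, j) if x is not None]
        near_ua = [x for x in (k, l) if x is not None]
        for a_side, b_side in ((near_cg, all_ca), (all_bb, near_ua)):
            for x in a_side:
                for y in b_side:
                    if x.id == y.id:
                        continue
                    key = tuple(sorted((x.id, y.id)))
                    if key in seen_pairs:
                        continue
                    d = float(np.linalg.norm(x.position - y.position))
                    if ELASTIC_LO < d < ELASTIC_HI:
                        elastic.append(HarmonicBond(key[0], key[1], K_ELASTIC, d,
                                                    ORIGIN_ELASTIC))
                        seen_pairs.add(key)
    return bonds, angles, elastic


def build_elastic_network(bb_sites: list, min_seq_sep: int = ELASTIC_MIN_SEQ_SEP,
                          lo: float = ELASTIC_LO, hi: float = ELASTIC_HI,
                          k: float = K_ELASTIC) -> list:
    """Springs between same-chain BB-bead pairs with reference distance in
    (``lo``, ``hi``) nm and residue separation >= ``min_seq_sep``."""
    out = []
    for a in range(len(bb_sites)):
        for b in range(a + 1, len(bb_sites)):
            x, y = bb_sites[a], bb_sites[b]
            if x.chain_id != y.chain_id:
                continue
            if abs(x.residue_index - y.residue_index) < min_seq_sep:
                continue
            d = float(np.linalg.norm(x.position - y.position))
            if lo < d < hi:
                out.append(HarmonicBond(*sorted((x.id, y.id)), k=k, d0=d,
                                        origin=ORIGIN_ELASTIC))
    return out


def build_cg_backbone_bonds(mixed: Structure) -> list:
    """Stiff harmonic bonds between consecutive CG backbone beads."""
    out = []
    for ch in mixed.chains:
        for a, b in zip(ch.residues, ch.residues[1:]):
            if b.index != a.index + 1:
                continue
            x, y = a.site("BB"), b.site("BB")
            if x is None or y is None:
                continue
            out.append(HarmonicBond(x.id, y.id, K_BOND_CG_BACKBONE,
                                    float(np.linalg.norm(x.position - y.position)),
                                    ORIGIN_CG_BACKBONE))
    return out


# ---------------------------------------------------------------------------
# covalent graph and exclusions

def covalent_graph(mixed: Structure, interface_bonds: Optional[list] = None) -> dict:
    """Adjacency (site id -> set of site ids) of the covalent bond network.

    UA bonds are detected by distance within a residue and across the
    peptide bond (C-N of consecutive residues); CG beads are chained
    BB(i)-BB(i+1) and BB-SC1-SC2-... within a residue; interface bonds
    connect the two resolutions.
    """
    adj: dict[int, set] = {s.id: set() for s in mixed.sites()}

    def link(a: Site, b: Site) -> None:
        adj[a.id].add(b.id)
        adj[b.id].add(a.id)

    for ch in mixed.chains:
        prev = None
        for r in ch.residues:
            ua_sites = [s for s in r.sites if s.resolution == UA]
            for ai in range(len(ua_sites)):
                for bi in range(ai + 1, len(ua_sites)):
                    a, b = ua_sites[ai], ua_sites[bi]
                    cutoff = _H_BOND_CUTOFF if "H" in (a.element, b.element) else _HEAVY_BOND_CUTOFF
                    if a.element == "H" and b.element == "H":
                        continue
                    if np.linalg.norm(a.position - b.position) < cutoff:
                        link(a, b)
            beads = [s for s in r.sites if s.resolution == CG]
            order = {"BB": 0, "SC1": 1, "SC2": 2, "SC3": 3, "SC4": 4}
            beads.sort(key=lambda s: order.get(s.name, 9))
            for a, b in zip(beads, beads[1:]):
                link(a, b)
            if prev is not None and r.index == prev.index + 1:
                if prev.site("BB") is not None and r.site("BB") is not None:
                    link(prev.site("BB"), r.site("BB"))
                elif prev.site("C") is not None and r.site("N") is not None:
                    link(prev.site("C"), r.site("N"))
            prev = r
    for bond in interface_bonds or []:
        adj[bond.site_a].add(bond.site_b)
        adj[bond.site_b].add(bond.site_a)
    return adj


def build_exclusions(adj: dict, max_bonds: int = 2) -> set:
    """All site pairs separated by <= ``max_bonds`` covalent bonds."""
    out: set = set()
    for start in adj:
        dist = {start: 0}
        q = deque([start])
        while q:
            u = q.popleft()
            if dist[u] == max_bonds:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for v, d in dist.items():
            if v != start and d <= max_bonds:
                out.add((min(start, v), max(start, v)))
    return out


# ---------------------------------------------------------------------------
# HMR

def apply_hmr(top: MixedTopology, factor: float = 4.0) -> MixedTopology:
    """Hydrogen-mass repartitioning: multiply every hydrogen mass by
    ``factor`` and subtract the borrowed mass from the bonded heavy atom
    (the nearest heavy atom in the same residue); total mass is conserved.
    Returns a new topology."""
    import copy as _copy
    if factor <= 0:
        raise TopologyError("HMR factor must be positive")
    out = _copy.deepcopy(top)
    by_residue: dict[tuple, list] = {}
    for s in out.sites:
        by_residue.setdefault((s.chain_id, s.residue_index), []).append(s)
    for sites in by_residue.values():
        heavies = [s for s in sites if s.element != "H" and s.resolution == UA]
        for h in sites:
            if h.element != "H" or h.resolution != UA:
                continue
            if not heavies:
                raise TopologyError(
                    f"hydrogen {h.chain_id}:{h.residue_index}:{h.name} has no bonded heavy atom")
            host = min(heavies, key=lambda s: float(np.linalg.norm(s.position - h.position)))
            delta = (factor - 1.0) * h.mass
            h.mass *= factor
            host.mass -= delta
    out.hmr_factor = factor * top.hmr_factor
    return out


# ---------------------------------------------------------------------------
# orchestration

def build_mixed_topology(s: Structure, p: PartitionSpec,
                         ua_table: Optional[ParamTable] = None,
                         cg_table: Optional[ParamTable] = None,
                         lipid_table: Optional[ParamTable] = None,
                         mapping: dict = CG_MAPPING,
                         factors: ScalingFactors = ScalingFactors()) -> tuple:
    """Full pipeline: validate, map, type, build bonded/elastic/exclusion
    sets and the mixed pair table.  Returns ``(mixed_structure, topology)``.

    The pair table covers every UA x CG-protein type pair (well depths
    scaled by gamma) and, when a lipid table is given, every UA x CG-lipid
    pair (scaled by eta; lipid keys are prefixed ``lipid:``).
    """
    violations = validate_partition(s, p)
    if violations:
        ids = ", ".join(f"{v.rule}@{v.chain_id}:{v.residue_index}" for v in violations)
        raise PartitionError(f"partition violates placement rules: {ids}")
    ua_table = ua_table or default_ua_table()
    cg_table = cg_table or default_cg_table()
    mixed = map_to_cg(s, p.residues_with(CG), mapping)
    assign_site_types(mixed, ua_table, cg_table)

    bonds, angles, elastic = build_interface_bonded(mixed, p)
    bonds = build_cg_backbone_bonds(mixed) + bonds
    bb_sites = [x for x in mixed.sites() if x.name == "BB"]
    network = build_elastic_network(bb_sites)
    have = {(b.site_a, b.site_b) for b in elastic}
    elastic += [b for b in network if (b.site_a, b.site_b) not in have]

    interface_bonds = [b for b in bonds if b.origin == ORIGIN_INTERFACE]
    adj = covalent_graph(mixed, interface_bonds)
    exclusions = build_exclusions(adj)

    pair_table = build_cross_table(ua_table, cg_table, factors.gamma)
    if lipid_table is not None:
        lipid_cross = build_cross_table(ua_table, lipid_table, 1.0)
        lipid_cross = scale_pair_table(lipid_cross, factors.eta)
        pair_table.update({(ku, f"lipid:{kc}"): v for (ku, kc), v in lipid_cross.items()})

    top = MixedTopology(sites=list(mixed.sites()), bonds=bonds, angles=angles,
                        elastic_bonds=elastic, exclusions=exclusions,
                        pair_table=pair_table, scaling=factors)
    return mixed, top


# ---------------------------------------------------------------------------
# serialization (GROMACS-dialect, custom sections)

def write_topology(top: MixedTopology, path) -> None:
    """Write a GROMACS-dialect topology file (custom ``pacemix`` dialect:
    standard section names, one extra ``[ pacemix ]`` header and reference
    coordinates carried on the atom lines so the file re-parses losslessly)."""
    lines = ["; pacemix mixed-resolution topology"]
    lines.append("[ pacemix ]")
    lines.append(f"hmr_factor {top.hmr_factor!r}")
    lines.append(f"gamma {top.scaling.gamma!r}")
    lines.append(f"eta {top.scaling.eta!r}")
    lines.append(f"zeta {top.scaling.zeta!r}")
    lines.append("")
    lines.append("[ atoms ]")
    lines.append("; id type chain resi name resolution charge mass element x y z (nm)")
    for s in top.sites:
        x, y, z = (float(v) for v in s.position)
        lines.append(f"{s.id + 1} {s.type_key or '?'} {s.chain_id} {s.residue_index} "
                     f"{s.name} {s.resolution} {float(s.charge)!r} {float(s.mass)!r} "
                     f"{s.element or '?'} {x!r} {y!r} {z!r}")
    lines.append("")
    lines.append("[ bonds ]")
    lines.append("; ai aj funct d0 k origin")
    for b in top.bonds:
        lines.append(f"{b.site_a + 1} {b.site_b + 1} 1 {b.d0!r} {b.k!r} {b.origin}")
    lines.append("")
    lines.append("[ angles ]")
    lines.append("; ai aj ak funct theta0 k")
    for a in top.angles:
        lines.append(f"{a.site_i + 1} {a.site_j + 1} {a.site_k + 1} 1 {a.theta0!r} {a.k!r}")
    lines.append("")
    lines.append("[ elastic ]")
    lines.append("; ai aj funct d0 k origin")
    for b in top.elastic_bonds:
        lines.append(f"{b.site_a + 1} {b.site_b + 1} 1 {b.d0!r} {b.k!r} {b.origin}")
    lines.append("")
    lines.append("[ exclusions ]")
    for a, b in sorted(top.exclusions):
        lines.append(f"{a + 1} {b + 1}")
    lines.append("")
    lines.append("[ nonbond_params ]")
    lines.append("; type_i type_j funct sigma epsilon")
    for (ki, kj), lj in sorted(top.pair_table.items()):
        lines.append(f"{ki} {kj} 1 {lj.sigma!r} {lj.epsilon!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path) -> MixedTopology:
    """Parse a file produced by :func:`write_topology`."""
    top = MixedTopology()
    header: dict[str, float] = {}
    section = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").strip()
            continue
        parts = line.split()
        if section == "pacemix":
            header[parts[0]] = float(parts[1])
        elif section == "atoms":
            sid = int(parts[0]) - 1
            top.sites.append(Site(
                id=sid, chain_id=parts[2], residue_index=int(parts[3]), name=parts[4],
                position=np.array([float(parts[9]), float(parts[10]), float(parts[11])]),
                resolution=parts[5], charge=float(parts[6]), mass=float(parts[7]),
                type_key="" if parts[1] == "?" else parts[1],
                element="" if parts[8] == "?" else parts[8],
            ))
        elif section in ("bonds", "elastic"):
            bond = HarmonicBond(int(parts[0]) - 1, int(parts[1]) - 1,
                                k=float(parts[4]), d0=float(parts[3]), origin=parts[5])
            (top.bonds if section == "bonds" else top.elastic_bonds).append(bond)
        elif section == "angles":
            top.angles.append(HarmonicAngle(int(parts[0]) - 1, int(parts[1]) - 1,
                                            int(parts[2]) - 1, k=float(parts[5]),
                                            theta0=float(parts[4])))
        elif section == "exclusions":
            top.exclusions.add((int(parts[0]) - 1, int(parts[1]) - 1))
        elif section == "nonbond_params":
            top.pair_table[(parts[0], parts[1])] = LJParams(float(parts[4]), float(parts[3]))
    top.hmr_factor = header.get("hmr_factor", 1.0)
    top.scaling = ScalingFactors(header.get("gamma", 0.7), header.get("eta", 0.95),
                                 header.get("zeta", 1.5))
    return top
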