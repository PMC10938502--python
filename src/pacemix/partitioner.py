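"""UA/CG partitioning: specs, validation rules, automatic partitioning.

A partition assigns every residue to the united-atom (UA) or coarse-grained
(CG) representation and records, for every point where a chain switches
resolution, which backbone bond the interface severs.  The convention used
throughout:

* ``InterfaceCut.residue_index`` labels the boundary: the last residue of
  the N-terminal segment.
* When the CG part is on the C-terminal side, the severed bond is the
  Calpha-C bond of ``residue_index`` itself; when the CG part is on the
  N-terminal side, it is the N-Calpha bond of ``residue_index + 1``.  In
  both cases the severed residue is the UA residue flanking the interface
  (the UA side retains the atoms next to the cut).

Validation rules (rule ids returned by :func:`validate_partition`):

* ``r1`` - the severed residue lies inside a helix or a multi-strand
  beta-sheet, or a multi-strand sheet is split across resolutions;
* ``r2`` - fewer than two residues separate the severed residue from the
  nearest helix/sheet residue;
* ``r3`` - the severed bond belongs to a proline;
* ``r4`` - cut bond/side inconsistency, or cuts that do not match the
  residue assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml

from .model_core import CG, UA, Structure

BOND_N_CA = "N-CA"
BOND_CA_C = "CA-C"
SIDE_N = "N-terminal"
SIDE_C = "C-terminal"

#: minimum |severed residue - H/E residue| (two residues strictly in between)
MARGIN = 3

#: Calpha-Calpha pairing distance for beta-strands, nm
STRAND_PAIR_CUTOFF = 0.55
#: number of close Calpha pairs required for two strands to pair
STRAND_PAIR_MIN = 2


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class InterfaceCut:
    chain_id: str
    residue_index: int           # last residue of the N-terminal segment
    bond_crossed: str            # N-CA | CA-C
    cg_side: str                 # N-terminal | C-terminal

    @property
    def severed_residue(self) -> int:
        """Author index of the residue whose internal bond is severed."""
        return self.residue_index + 1 if self.bond_crossed == BOND_N_CA else self.residue_index

    @property
    def consistent(self) -> bool:
        return (self.bond_crossed == BOND_N_CA) == (self.cg_side == SIDE_N)


def _cut_for_boundary(chain_id: str, boundary: int, n_side: str) -> InterfaceCut:
    """Cut at the boundary after residue ``boundary``; ``n_side`` is the
    resolution of the N-terminal segment."""
    if n_side == CG:
        return InterfaceCut(chain_id, boundary, BOND_N_CA, SIDE_N)
    return InterfaceCut(chain_id, boundary, BOND_CA_C, SIDE_C)


@dataclass
class PartitionSpec:
    """Per-residue UA/CG assignment plus the interface cuts it implies."""

    assignment: dict = field(default_factory=dict)   # (chain_id, resi) -> UA|CG
    cuts: list = field(default_factory=list)

    def resolution_of(self, chain_id: str, residue_index: int) -> str:
        return self.assignment[(chain_id, residue_index)]

    def residues_with(self, resolution: str) -> set:
        return {k for k, v in self.assignment.items() if v == resolution}

    @classmethod
    def from_assignment(cls, s: Structure, assignment: dict) -> "PartitionSpec":
        """Derive the cut list from a per-residue assignment."""
        cuts = []
        for ch in s.chains:
            for a, b in zip(ch.residues, ch.residues[1:]):
                ra = assignment[(ch.id, a.index)]
                rb = assignment[(ch.id, b.index)]
                if ra != rb:
                    cuts.append(_cut_for_boundary(ch.id, a.index, ra))
        return cls(assignment=dict(assignment), cuts=cuts)

    @classmethod
    def uniform(cls, s: Structure, resolution: str) -> "PartitionSpec":
        return cls(assignment={(ch.id, r.index): resolution
                               for ch in s.chains for r in ch.residues}, cuts=[])


@dataclass(frozen=True)
class Violation:
    rule: str
    chain_id: str
    residue_index: int
    message: str


def _strands(s: Structure) -> list[list]:
    """Maximal runs of E residues, as lists of Residue (with chain ids)."""
    out = []
    for ch in s.chains:
        run = []
        for r in ch.residues:
            if r.ss_label == "E":
                run.append((ch.id, r))
            else:
                if run:
                    out.append(run)
                run = []
        if run:
            out.append(run)
    return out


def find_sheets(s: Structure) -> list[list]:
    """Group strands into sheets: connected components of the pairing graph.

    Two strands pair when at least ``STRAND_PAIR_MIN`` Calpha-Calpha
    distances between them fall below ``STRAND_PAIR_CUTOFF`` nm.  Only
    components with >= 2 strands are returned (a lone strand is not a sheet).
    """
    strands = _strands(s)
    coords = []
    for st in strands:
        cas = [r.backbone_site for _, r in st]
        coords.append(np.array([c.position for c in cas if c is not None]))
    n = len(strands)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if len(coords[i]) == 0 or len(coords[j]) == 0:
                continue
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :], axis=-1)
            if int((d < STRAND_PAIR_CUTOFF).sum()) >= STRAND_PAIR_MIN:
                adj[i].append(j)
                adj[j].append(i)
    seen = set()
    sheets = []
    for i in range(n):
        if i in seen:
            continue
        comp, stack = [], [i]
        seen.add(i)
        while stack:
            k = stack.pop()
            comp.append(k)
            for m in adj[k]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        if len(comp) >= 2:
            sheets.append([strands[k] for k in sorted(comp)])
    return sheets


def validate_partition(s: Structure, p: PartitionSpec) -> list[Violation]:
    """Check a partition against the interface-placement rules.

    Returns an empty list iff the partition is admissible.  Raises
    :class:`PartitionError` if the spec references unknown residues or does
    not cover the structure.
    """
    known = {(ch.id, r.index) for ch in s.chains for r in ch.residues}
    unknown = set(p.assignment) - known
    if unknown:
        raise PartitionError(f"assignment references unknown residues: {sorted(unknown)[:5]}")
    missing = known - set(p.assignment)
    if missing:
        raise PartitionError(f"assignment does not cover residues: {sorted(missing)[:5]}")

    violations: list[Violation] = []
    by_chain = {ch.id: ch for ch in s.chains}

    # r4: every cut consistent and matching an assignment boundary, and vice versa
    boundaries = {}
    for ch in s.chains:
        for a, b in zip(ch.residues, ch.residues[1:]):
            ra, rb = p.assignment[(ch.id, a.index)], p.assignment[(ch.id, b.index)]
            if ra != rb:
                boundaries[(ch.id, a.index)] = ra
    cut_keys = set()
    for cut in p.cuts:
        key = (cut.chain_id, cut.residue_index)
        cut_keys.add(key)
        if not cut.consistent:
            violations.append(Violation("r4", cut.chain_id, cut.residue_index,
                                        f"bond {cut.bond_crossed} inconsistent with CG on {cut.cg_side} side"))
            continue
        if key not in boundaries:
            violations.append(Violation("r4", cut.chain_id, cut.residue_index,
                                        "cut does not sit on a resolution boundary"))
            continue
        n_side = boundaries[key]
        expected = _cut_for_boundary(cut.chain_id, cut.residue_index, n_side)
        if expected.bond_crossed != cut.bond_crossed:
            violations.append(Violation("r4", cut.chain_id, cut.residue_index,
                                        f"CG side is {n_side}-start boundary but bond is {cut.bond_crossed}"))
    for key, n_side in boundaries.items():
        if key not in cut_keys:
            violations.append(Violation("r4", key[0], key[1],
                                        "resolution changes without a declared cut"))

    # r1/r2/r3 on the severed residue of each consistent cut
    for cut in p.cuts:
        if not cut.consistent:
            continue
        ch = by_chain.get(cut.chain_id)
        if ch is None:
            continue
        sev = cut.severed_residue
        res = next((r for r in ch.residues if r.index == sev), None)
        if res is None:
            violations.append(Violation("r4", cut.chain_id, sev, "severed residue not in chain"))
            continue
        if res.ss_label in ("H", "E"):
            violations.append(Violation("r1", cut.chain_id, sev,
                                        f"cut inside a secondary-structure element ({res.ss_label})"))
        else:
            dmin = min((abs(sev - r.index) for r in ch.residues if r.ss_label in ("H", "E")),
                       default=None)
            if dmin is not None and dmin < MARGIN:
                violations.append(Violation("r2", cut.chain_id, sev,
                                            f"cut only {dmin - 1} residue(s) from a helix/sheet (need >= 2)"))
        if res.name == "PRO":
            violations.append(Violation("r3", cut.chain_id, sev, "cut severs a proline"))

    # r1: multi-strand sheets may not be split across resolutions
    for sheet in find_sheets(s):
        residues = [(cid, r.index) for strand in sheet for cid, r in strand]
        resolutions = {p.assignment[k] for k in residues}
        if len(resolutions) > 1:
            cid, idx = residues[0]
            violations.append(Violation("r1", cid, idx,
                                        "multi-strand beta-sheet split across resolutions"))
    return violations


def _midpoint_candidates(s: Structure, chain_id: str):
    ch = next(c for c in s.chains if c.id == chain_id)
    idx = [r.index for r in ch.residues]
    target = len(idx) / 2.0  # ordinal midpoint
    order = sorted(range(len(idx) - 1), key=lambda i: (abs((i + 1) - target), i))
    return ch, idx, order


def auto_partition_monomer(s: Structure, strategy: str = "midpoint") -> PartitionSpec:
    """Partition a single-chain structure automatically.

    ``midpoint``: place one admissible cut as close as possible to the
    sequence midpoint (N-terminal tie-break); the N-terminal segment is UA.
    ``largest_sheet``: keep the sheet with the most strand residues (and any
    sheet it forces in) at one resolution (UA) and the remainder at CG, with
    admissible cuts at the segment boundaries.
    """
    if len(s.chains) != 1:
        raise PartitionError("auto-partitioning expects a single chain")
    ch = s.chains[0]
    if strategy == "midpoint":
        ch, idx, order = _midpoint_candidates(s, ch.id)
        for i in order:
            boundary = idx[i]
            assignment = {(ch.id, r.index): (UA if r.index <= boundary else CG)
                          for r in ch.residues}
            spec = PartitionSpec.from_assignment(s, assignment)
            if not validate_partition(s, spec):
                return spec
        raise PartitionError("unpartitionable: no admissible cut position exists")

    if strategy == "largest_sheet":
        sheets = find_sheets(s)
        if not sheets:
            raise PartitionError("largest_sheet strategy requires a multi-strand sheet")
        sizes = [sum(len(strand) for strand in sheet) for sheet in sheets]
        main = sheets[int(np.argmax(sizes))]
        lo = min(r.index for strand in main for _, r in strand)
        hi = max(r.index for strand in main for _, r in strand)
        idx = [r.index for r in ch.residues]
        # grow the interval so no other sheet is split
        changed = True
        while changed:
            changed = False
            for sheet in sheets:
                s_lo = min(r.index for strand in sheet for _, r in strand)
                s_hi = max(r.index for strand in sheet for _, r in strand)
                inside = s_lo >= lo and s_hi <= hi
                outside = s_hi < lo or s_lo > hi
                if not inside and not outside:
                    lo, hi = min(lo, s_lo), max(hi, s_hi)
                    changed = True

        def try_interval(a: int, b: int) -> Optional[PartitionSpec]:
            assignment = {(ch.id, r.index): (UA if a <= r.index <= b else CG)
                          for r in ch.residues}
            spec = PartitionSpec.from_assignment(s, assignment)
            return spec if not validate_partition(s, spec) else None

        for a in range(lo, idx[0] - 1, -1):
            for b in range(hi, idx[-1] + 1):
                spec = try_interval(a, b)
                if spec is not None:
                    return spec
        raise PartitionError("unpartitionable: no admissible sheet interval exists")

    raise ValueError(f"unknown strategy {strategy!r}")


def swap_resolutions(p: PartitionSpec) -> PartitionSpec:
    """Exchange UA and CG everywhere; an involution preserving cut positions."""
    assignment = {k: (CG if v == UA else UA) for k, v in p.assignment.items()}
    cuts = []
    for cut in p.cuts:
        if cut.cg_side == SIDE_C:
            cuts.append(replace(cut, bond_crossed=BOND_N_CA, cg_side=SIDE_N))
        else:
            cuts.append(replace(cut, bond_crossed=BOND_CA_C, cg_side=SIDE_C))
    return PartitionSpec(assignment=assignment, cuts=cuts)


# ---------------------------------------------------------------------------
# serialization

def partition_to_yaml(p: PartitionSpec, path=None) -> str:
    """Serialize as a list of {chain, range, resolution} segments."""
    segments = []
    by_chain: dict[str, list] = {}
    for (cid, idx), res in sorted(p.assignment.items()):
        by_chain.setdefault(cid, []).append((idx, res))
    for cid, items in by_chain.items():
        items.sort()
        start, prev, cur = items[0][0], items[0][0], items[0][1]
        for idx, res in items[1:]:
            if res != cur or idx != prev + 1:
                segments.append({"chain": cid, "range": [start, prev], "resolution": cur})
                start, cur = idx, res
            prev = idx
        segments.append({"chain": cid, "range": [start, prev], "resolution": cur})
    text = yaml.safe_dump({"segments": segments}, sort_keys=False)
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text


def partition_from_yaml(source, s: Structure) -> PartitionSpec:
    """Load a segment list (path or YAML string) and derive the cuts."""
    from pathlib import Path
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    data = yaml.safe_load(text)
    assignment = {}
    for seg in data["segments"]:
        lo, hi = seg["range"]
        for i in range(lo, hi + 1):
            assignment[(seg["chain"], i)] = seg["resolution"]
    return PartitionSpec.from_assignment(s, assignment)
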