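"""Nonbonded parameter tables and cross-resolution mixing.

Unlike-pair Lennard-Jones parameters between united-atom and coarse-grained
sites are generated with the Lorentz-Berthelot rule — arithmetic mean for
sigma, geometric mean for epsilon — and the well depth is then rescaled by
one of three universal factors:

* ``gamma`` (default 0.7): UA-protein x CG-protein pairs;
* ``eta`` (default 0.95): UA-protein x CG-lipid pairs;
* ``zeta`` (default 1.5): the helical backbone hydrogen-bond well depth of
  membrane-embedded helices (solution helices keep the unscaled depth).

Sigma is never rescaled by any factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from .model_core import Residue


class ParamError(ValueError):
    pass


@dataclass(frozen=True)
class LJParams:
    epsilon: float      # kJ/mol
    sigma: float        # nm

    def __post_init__(self):
        if self.epsilon < 0:
            raise ParamError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.sigma <= 0:
            raise ParamError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class ScalingFactors:
    """The three universal well-depth factors of the coupling scheme."""

    gamma: float = 0.7    # UA-protein x CG-protein
    eta: float = 0.95     # UA-protein x CG-lipid
    zeta: float = 1.5     # membrane helical hydrogen bond

    def __post_init__(self):
        if min(self.gamma, self.eta, self.zeta) <= 0:
            raise ParamError("scaling factors must be positive")


@dataclass(frozen=True)
class HelicalHBParams:
    """LJ-like backbone O(i)..N(i+3/i+4) attraction stabilising helical turns."""

    epsilon_hel: float = 5.0    # kJ/mol (illustrative default)
    sigma_hel: float = 0.28     # nm; well minimum near a 3.1 A hydrogen bond
    zeta_applied: bool = False

    def __post_init__(self):
        if self.epsilon_hel < 0:
            raise ParamError("epsilon_hel must be >= 0")


@dataclass
class ParamTable:
    """type_key -> LJ parameters (+ charge); kind in {UA, CG, lipid}."""

    entries: dict = field(default_factory=dict)   # type -> LJParams
    charges: dict = field(default_factory=dict)   # type -> e
    kind: str = "UA"

    def __post_init__(self):
        if self.kind not in ("UA", "CG", "lipid"):
            raise ParamError(f"bad table kind {self.kind!r}")

    def add(self, type_key: str, lj: LJParams, charge: float = 0.0) -> None:
        if type_key in self.entries:
            raise ParamError(f"duplicate type {type_key!r}")
        self.entries[type_key] = lj
        self.charges[type_key] = charge

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, type_key: str) -> bool:
        return type_key in self.entries

    def __getitem__(self, type_key: str) -> LJParams:
        return self.entries[type_key]

    def charge(self, type_key: str) -> float:
        return self.charges.get(type_key, 0.0)

    @classmethod
    def from_dict(cls, d: dict, kind: str) -> "ParamTable":
        t = cls(kind=kind)
        for key, (eps, sig, q) in d.items():
            t.add(key, LJParams(eps, sig), q)
        return t


def default_ua_table() -> ParamTable:
    from .params_data import UA_TYPES
    return ParamTable.from_dict(UA_TYPES, "UA")


def default_cg_table() -> ParamTable:
    from .params_data import CG_TYPES
    return ParamTable.from_dict(CG_TYPES, "CG")


def default_lipid_table() -> ParamTable:
    from .params_data import LIPID_TYPES
    return ParamTable.from_dict(LIPID_TYPES, "lipid")


def c6c12_to_lj(c6: float, c12: float) -> LJParams:
    """Convert GROMACS C6/C12 to (epsilon, sigma)."""
    if c6 <= 0 or c12 <= 0:
        # purely repulsive or undefined pair: zero well depth, nominal sigma
        return LJParams(0.0, 0.47)
    sigma = (c12 / c6) ** (1.0 / 6.0)
    epsilon = c6 * c6 / (4.0 * c12)
    return LJParams(epsilon, sigma)


def load_param_table(path, dialect: str = "simple_table", kind: str = "UA") -> ParamTable:
    """Load a parameter table from a text file.

    ``simple_table``: whitespace columns ``type epsilon sigma [charge]``
    (epsilon kJ/mol, sigma nm); ``#`` starts a comment.

    ``martini_itp``: a MARTINI-style topology include file; the
    ``[ atomtypes ]`` block is read as ``name mass charge ptype c6 c12``
    (or ``name mass charge ptype sigma epsilon`` when the fifth column is
    smaller than the sixth and below 1, which is how sigma/epsilon dialect
    files are laid out) and converted to (epsilon, sigma).
    """
    path = Path(path)
    text = path.read_text()
    table = ParamTable(kind=kind)
    if dialect == "simple_table":
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParamError(f"{path}: bad line {line!r}")
            q = float(parts[3]) if len(parts) > 3 else 0.0
            table.add(parts[0], LJParams(float(parts[1]), float(parts[2])), q)
    elif dialect == "martini_itp":
        in_block = False
        for line in text.splitlines():
            line = line.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                in_block = line.replace(" ", "") == "[atomtypes]"
                continue
            if not in_block:
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParamError(f"{path}: bad atomtypes line {line!r}")
            name, _mass, q, _ptype, v5, v6 = parts[0], parts[1], float(parts[2]), parts[3], float(parts[4]), float(parts[5])
            if 0 < v5 < 1.0 and v5 < v6:
                lj = LJParams(v6, v5)          # sigma epsilon dialect
            else:
                lj = c6c12_to_lj(v5, v6)       # C6 C12 dialect
            table.add(name, lj, q)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(table) == 0:
        raise ParamError(f"{path}: empty parameter table")
    return table


def mix_cross_params(a: LJParams, b: LJParams, gamma: float = 1.0) -> LJParams:
    """Lorentz-Berthelot mixing with well-depth rescaling.

    sigma = (sigma_a + sigma_b) / 2;  epsilon = gamma * sqrt(eps_a * eps_b).
    Symmetric in its two arguments.
    """
    return LJParams(gamma * math.sqrt(a.epsilon * b.epsilon),
                    0.5 * (a.sigma + b.sigma))


def build_cross_table(ua: ParamTable, cg: ParamTable, factor: float) -> dict:
    """Full (ua_type, cg_type) -> LJParams product table, epsilon scaled by
    ``factor`` (gamma for CG-protein tables, eta for lipid tables)."""
    return {(ku, kc): mix_cross_params(ua[ku], cg[kc], factor)
            for ku in ua.entries for kc in cg.entries}


def scale_pair_table(table: dict, factor: float) -> dict:
    """Multiply every epsilon in a pair table by ``factor``; sigma untouched."""
    return {k: replace(v, epsilon=factor * v.epsilon) for k, v in table.items()}


def helical_hb_for_residue(hb: HelicalHBParams, residue: Residue,
                           f: ScalingFactors) -> HelicalHBParams:
    """Helical hydrogen-bond parameters for one residue.

    Membrane-embedded helical residues get the well depth multiplied by
    ``zeta``; solution helices keep the base depth.
    """
    if residue.ss_label == "H" and residue.environment == "membrane":
        return HelicalHBParams(f.zeta * hb.epsilon_hel, hb.sigma_hel, True)
    return HelicalHBParams(hb.epsilon_hel, hb.sigma_hel, False)


def apply_env_scalings(cross_lipid_table: Optional[dict], hb: HelicalHBParams,
                       residues: Iterable[Residue], f: ScalingFactors):
    """Environment-dependent rescalings.

    Returns ``(scaled_lipid_table, per_residue_hb)``: every UA-protein x
    CG-lipid epsilon multiplied by ``eta``; per-residue helical HB parameters
    with ``zeta`` applied only for membrane helices.
    """
    scaled = scale_pair_table(cross_lipid_table, f.eta) if cross_lipid_table else None
    per_res = {}
    for r in residues:
        per_res[r.index] = helical_hb_for_residue(hb, r, f)
    return scaled, per_res
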