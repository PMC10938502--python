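import math

import numpy as np
import pytest

from pacemix import fixtures
from pacemix.model_core import CG, UA, Site
from pacemix.param_mixer import LJParams
from pacemix.topology_builder import MixedTopology


@pytest.fixture(scope="session")
def helix15():
    return fixtures.make_ideal_helix(15)


@pytest.fixture(scope="session")
def two_domain():
    """(structure, (partition, swapped partition)) for the standard fixture."""
    return fixtures.make_two_domain_fixture(seed=0)


@pytest.fixture(scope="session")
def trimer():
    return fixtures.make_trimer_toy(tilt=63.0, radius=1.0)


def random_cross_topology(rng: np.random.Generator, n_sites: int,
                          box: float = 2.0, n_types: int = 4) -> MixedTopology:
    """Random mixed topology for nonbonded oracle tests: n_sites sites of
    alternating resolution in a box (nm), random charges, a random pair
    table, and a few random exclusions."""
    ua_types = [f"U{i}" for i in range(n_types)]
    cg_types = [f"G{i}" for i in range(n_types)]
    top = MixedTopology()
    for i in range(n_sites):
        res = UA if i % 2 == 0 else CG
        types = ua_types if res == UA else cg_types
        top.sites.append(Site(
            id=i, chain_id="A", residue_index=i + 1,
            name="CA" if res == UA else "BB",
            position=rng.uniform(0, box, 3), resolution=res,
            charge=float(rng.uniform(-0.5, 0.5)),
            type_key=types[int(rng.integers(n_types))],
        ))
    for ku in ua_types:
        for kc in cg_types:
            top.pair_table[(ku, kc)] = LJParams(float(rng.uniform(0.1, 4.0)),
                                                float(rng.uniform(0.3, 0.5)))
    n_excl = int(rng.integers(0, max(2, n_sites // 4)))
    for _ in range(n_excl):
        a, b = rng.integers(0, n_sites, 2)
        if a != b:
            top.exclusions.add((int(min(a, b)), int(max(a, b))))
    return top


def brute_force_cross_energy(top: MixedTopology, settings) -> tuple:
    """Independent O(N^2) double loop over UA x CG pairs (scalar math only)."""
    lj_sum = 0.0
    coul_sum = 0.0
    for a in top.sites:
        if a.resolution != UA:
            continue
        for b in top.sites:
            if b.resolution != CG:
                continue
            pair = (min(a.id, b.id), max(a.id, b.id))
            if pair in top.exclusions:
                continue
            r = math.dist(tuple(a.position), tuple(b.position))
            if r >= settings.cutoff:
                continue
            p = top.pair_table[(a.type_key, b.type_key)]
            sr6 = (p.sigma / r) ** 6
            u = 4 * p.epsilon * (sr6 * sr6 - sr6)
            if settings.lj_shift:
                sc6 = (p.sigma / settings.cutoff) ** 6
                u -= 4 * p.epsilon * (sc6 * sc6 - sc6)
            lj_sum += u
            pref = 138.935458 * a.charge * b.charge / settings.epsilon_r
            if settings.coulomb_mode == "truncated":
                coul_sum += pref / r
            else:
                rc = settings.cutoff
                coul_sum += pref * (1 / r + r * r / (2 * rc ** 3) - 3 / (2 * rc))
    return lj_sum, coul_sum
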