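"""Dynamic LAD-lamina bond model.

Bonding represents tether proteins (LBR-like) that link lamina-associated
chromatin domains to the lamin meshwork.  A bond is a shifted harmonic
spring,

    E_bond(r) = -k_bond (r_b - sigma)^2 + k_bond (r - sigma)^2,

zero at the formation/breaking radius ``r = r_b`` and minimal (most
negative) at contact ``r = sigma``.  Bonds form deterministically whenever
an unbonded, bond-eligible LAD bead has a lamin bead within ``r_b`` (to the
nearest such bead; exact ties go to the lowest lamin index).  A bond can
break only while stretched beyond ``r_b``, and then does so with
probability ``P_break = exp(-U_bond / k_B T)`` per update, consistent with
detailed balance for a bond of formation energy ``U_bond``.

Occupancy: each LAD bead carries at most one bond in total (a bead stands
for a tether-protein-scale unit); several LAD beads may bond the same
lamin bead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import CorruptedStateError
from .units import SimulationParameters


def bond_energy(r: float, kbond: float, sigma: float, r_bond: float) -> float:
    """Shifted harmonic bond energy; zero at ``r = r_bond``, minimal at ``r = sigma``."""
    return -kbond * (r_bond - sigma) ** 2 + kbond * (r - sigma) ** 2


def break_probability(ubond: float, thermal_energy: float = 1.0) -> float:
    """Per-update breaking probability for a bond stretched beyond r_b."""
    return math.exp(-ubond / thermal_energy)


@dataclass
class BondSet:
    """Current LAD-lamin bonds, stored as a per-bead partner index.

    ``partner[i]`` is the lamin index bonded to chromatin bead ``i``, or -1.
    The one-bond-per-LAD occupancy rule is structural in this encoding.
    """

    partner: np.ndarray

    @classmethod
    def empty(cls, n_beads: int) -> "BondSet":
        return cls(np.full(n_beads, -1, dtype=np.int32))

    def __post_init__(self) -> None:
        self.partner = np.ascontiguousarray(self.partner, dtype=np.int32)

    @property
    def count(self) -> int:
        return int(np.sum(self.partner >= 0))

    def pairs(self) -> list[tuple[int, int]]:
        idx = np.flatnonzero(self.partner >= 0)
        return [(int(i), int(self.partner[i])) for i in idx]

    def copy(self) -> "BondSet":
        return BondSet(self.partner.copy())

    def validate(self, bondable: np.ndarray) -> None:
        bonded = self.partner >= 0
        if np.any(bonded & ~np.asarray(bondable, dtype=bool)):
            raise CorruptedStateError("bond on a non-eligible bead")


def update_bonds(
    chain,
    shell,
    bonds: BondSet,
    params: SimulationParameters,
    rng: np.random.Generator,
) -> BondSet:
    """One bond-kinetics update: a breaking pass, then a formation pass.

    Breaking: every existing bond currently stretched beyond ``r_bond`` is
    deleted with probability ``exp(-U_bond/kT)`` (one uniform draw per
    candidate, in ascending bead order).  Formation: every unbonded,
    bond-eligible LAD bead with at least one lamin bead within ``r_bond``
    bonds to the nearest one.

    Reference implementation; the integrator applies the same update
    in-kernel every step.
    """
    bonds.validate(chain.bondable)
    new = bonds.copy()
    pos = chain.positions
    lam = shell.lamin_positions
    p_break = break_probability(params.ubond, params.thermal_energy)

    for i in np.flatnonzero(new.partner >= 0):
        r = np.linalg.norm(pos[i] - lam[new.partner[i]])
        if r > params.r_bond and rng.random() < p_break:
            new.partner[i] = -1

    candidates = np.flatnonzero(chain.bondable & (new.partner < 0))
    if candidates.size:
        tree = cKDTree(lam)
        dist, nearest = tree.query(pos[candidates], k=1)
        for i, d, j in zip(candidates, dist, nearest):
            if d < params.r_bond:
                new.partner[i] = j
    return new
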