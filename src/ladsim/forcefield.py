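"""Potential-energy terms of the model and their analytic forces.

The total energy decomposes into six terms:

    E_tot = E_stretch + E_bend + E_chrom_LJ + E_wall + E_lamin_LJ + E_bond

* stretching: harmonic springs ``k_s (r - 2a)^2`` between consecutive beads;
* bending: ``k_b (1 - cos theta)`` per internal angle, theta = 0 when straight;
* chromatin-chromatin Lennard-Jones with a pair-type-dependent depth
  (epsilon_matrix) and cutoff 2.5 sigma (attractive chain) or 2^(1/6) sigma
  (purely repulsive, WCA);
* wall: repulsive WCA acting on the gap to the nearest wall point;
* lamin-chromatin LJ: attractive (cutoff 2.5 sigma) for LAD beads,
  repulsive WCA for non-LAD beads;
* LAD-lamina bonds: shifted harmonic springs (see :mod:`ladsim.bonding`).

LJ energies are truncated and shifted to zero at the cutoff so the energy
is continuous; forces come from the unshifted analytic derivative and are
therefore unaffected by the shift.

This module is the plain-NumPy reference implementation, quadratic in the
number of beads; the production integrator uses neighbor-list kernels that
are tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .builder import ChromatinChain
from .bonding import BondSet, bond_energy
from .exceptions import (
    EscapedBeadError,
    InvalidParameterError,
    SingularAngleError,
    SingularOverlapError,
)
from .lamina import LaminaShell
from .units import LAD, SimulationParameters


@dataclass(frozen=True)
class EnergyBreakdown:
    """The six terms of the total energy, plus their sum."""

    stretch: float
    bend: float
    chrom_lj: float
    wall: float
    lamin_lj: float
    bond: float

    @property
    def total(self) -> float:
        return self.stretch + self.bend + self.chrom_lj + self.wall + self.lamin_lj + self.bond

    def as_tuple(self) -> tuple[float, ...]:
        return (self.stretch, self.bend, self.chrom_lj, self.wall, self.lamin_lj, self.bond)


def lj_shift(eps: float, sigma: float, cutoff: float) -> float:
    """Energy offset that brings the truncated LJ potential to zero at the cutoff."""
    sr6 = (sigma / cutoff) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def lj_pair(r, eps: float, sigma: float, cutoff: float, shifted: bool = True):
    """Lennard-Jones energy and force magnitude for separation(s) ``r``.

    Returns ``(energy, force)`` where the force is the magnitude of
    ``-dE/dr`` (positive = repulsive).  Both vanish for ``r >= cutoff``.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise SingularOverlapError("zero separation in LJ pair")
    sr6 = (sigma / r) ** 6
    energy = 4.0 * eps * (sr6 * sr6 - sr6)
    if shifted:
        energy = energy - lj_shift(eps, sigma, cutoff)
    force = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    inside = r < cutoff
    energy = np.where(inside, energy, 0.0)
    force = np.where(inside, force, 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def bonded_terms(
    positions: np.ndarray,
    spring_constant: float,
    rest_length: float,
    bending_stiffness: float,
) -> tuple[float, float]:
    """Stretching and bending energies of the chain.

    Stretch sums ``k_s (r_i - 2a)^2`` over the N-1 springs; bend sums
    ``k_b (1 - cos theta_i)`` over the N-2 internal angles between
    successive bond vectors.
    """
    positions = np.asarray(positions, dtype=np.float64)
    n = positions.shape[0]
    if n < 2:
        raise InvalidParameterError("need at least two beads")
    bonds = positions[1:] - positions[:-1]
    lengths = np.linalg.norm(bonds, axis=1)
    if np.any(lengths < 1e-12):
        raise SingularAngleError("coincident consecutive beads")
    stretch = float(spring_constant * np.sum((lengths - rest_length) ** 2))
    bend = 0.0
    if n >= 3:
        cos_t = np.sum(bonds[:-1] * bonds[1:], axis=1) / (lengths[:-1] * lengths[1:])
        bend = float(bending_stiffness * np.sum(1.0 - cos_t))
    return stretch, bend


def _chain_pairs(chain: ChromatinChain, params: SimulationParameters):
    pos = chain.positions
    n = pos.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = pos[iu] - pos[ju]
    r = np.linalg.norm(d, axis=1)
    eps = params.epsilon_matrix[chain.bead_type[iu], chain.bead_type[ju]]
    return iu, ju, d, r, eps


def total_energy(
    chain: ChromatinChain,
    shell: LaminaShell | None,
    bonds: BondSet | None,
    params: SimulationParameters,
) -> EnergyBreakdown:
    """Six-term energy breakdown of the full system (O(N^2) reference)."""
    pos = chain.positions
    sigma = params.bead_diameter
    stretch, bend = bonded_terms(
        pos, params.spring_constant, params.rest_length, params.bending_stiffness
    )

    rc = params.effective_chrom_cutoff
    iu, ju, _, r, eps = _chain_pairs(chain, params)
    inside = r < rc
    if np.any(r[inside] <= 0):
        raise SingularOverlapError("overlapping beads")
    sr6 = (sigma / r[inside]) ** 6
    chrom = float(np.sum(4.0 * eps[inside] * (sr6 * sr6 - sr6) - eps[inside] * _cshift(sigma, rc)))

    wall = 0.0
    lamin = 0.0
    bond = 0.0
    if shell is not None:
        radii = np.linalg.norm(pos, axis=1)
        if np.any(radii >= shell.confinement_radius):
            raise EscapedBeadError("bead outside confinement sphere")
        gaps = shell.confinement_radius - radii
        rcw = params.cutoff_repulsive
        inw = gaps < rcw
        if np.any(inw):
            sr6w = (sigma / gaps[inw]) ** 6
            wall = float(
                np.sum(
                    4.0 * params.eps_wall * (sr6w * sr6w - sr6w)
                    - params.eps_wall * _cshift(sigma, rcw)
                )
            )
        dist = cdist(pos, shell.lamin_positions)
        is_lad = chain.bead_type == LAD
        for mask, eps_l, rc_l in (
            (is_lad, params.eps_lad_lamin, params.cutoff_attractive),
            (~is_lad, params.eps_nonlad_lamin, params.cutoff_repulsive),
        ):
            sub = dist[mask]
            inl = sub < rc_l
            if np.any(inl):
                sr6l = (sigma / sub[inl]) ** 6
                lamin += float(
                    np.sum(4.0 * eps_l * (sr6l * sr6l - sr6l) - eps_l * _cshift(sigma, rc_l))
                )
        if bonds is not None:
            for lad_i, lam_j in bonds.pairs():
                r_b = float(np.linalg.norm(pos[lad_i] - shell.lamin_positions[lam_j]))
                bond += bond_energy(r_b, params.kbond, sigma, params.r_bond)
    return EnergyBreakdown(stretch, bend, chrom, wall, lamin, bond)


def _cshift(sigma: float, cutoff: float) -> float:
    sr6 = (sigma / cutoff) ** 6
    return 4.0 * (sr6 * sr6 - sr6)


def forces(
    chain: ChromatinChain,
    shell: LaminaShell | None,
    bonds: BondSet | None,
    params: SimulationParameters,
) -> np.ndarray:
    """Analytic forces -grad(E_tot) on every chromatin bead (O(N^2) reference).

    Lamin beads are static and receive no force.
    """
    pos = chain.positions
    n = pos.shape[0]
    sigma = params.bead_diameter
    f = np.zeros((n, 3))

    # stretching
    bvec = pos[1:] - pos[:-1]
    blen = np.linalg.norm(bvec, axis=1)
    if np.any(blen < 1e-12):
        raise SingularAngleError("coincident consecutive beads")
    fs = 2.0 * params.spring_constant * (blen - params.rest_length)[:, None] * (bvec / blen[:, None])
    np.add.at(f, np.arange(n - 1), fs)
    np.add.at(f, np.arange(1, n), -fs)

    # bending
    if n >= 3:
        b1, b2 = bvec[:-1], bvec[1:]
        n1, n2 = blen[:-1], blen[1:]
        c = np.sum(b1 * b2, axis=1) / (n1 * n2)
        g1 = b2 / (n1 * n2)[:, None] - (c / n1**2)[:, None] * b1
        g2 = b1 / (n1 * n2)[:, None] - (c / n2**2)[:, None] * b2
        kb = params.bending_stiffness
        np.add.at(f, np.arange(n - 2), -kb * g1)
        np.add.at(f, np.arange(1, n - 1), kb * (g1 - g2))
        np.add.at(f, np.arange(2, n), kb * g2)

    # chromatin-chromatin LJ
    rc = params.effective_chrom_cutoff
    iu, ju, d, r, eps = _chain_pairs(chain, params)
    inside = r < rc
    if np.any(inside):
        ri = r[inside]
        sr6 = (sigma / ri) ** 6
        fr = 24.0 * eps[inside] * (2.0 * sr6 * sr6 - sr6) / ri**2
        fij = fr[:, None] * d[inside]
        np.add.at(f, iu[inside], fij)
        np.add.at(f, ju[inside], -fij)

    if shell is not None:
        radii = np.linalg.norm(pos, axis=1)
        if np.any(radii >= shell.confinement_radius):
            raise EscapedBeadError("bead outside confinement sphere")
        gaps = shell.confinement_radius - radii
        rcw = params.cutoff_repulsive
        inw = (gaps < rcw) & (radii > 1e-12)
        if np.any(inw):
            sr6w = (sigma / gaps[inw]) ** 6
            fw = 24.0 * params.eps_wall * (2.0 * sr6w * sr6w - sr6w) / gaps[inw]
            f[inw] -= (fw / radii[inw])[:, None] * pos[inw]

        dvec = pos[:, None, :] - shell.lamin_positions[None, :, :]
        dist = np.linalg.norm(dvec, axis=2)
        is_lad = chain.bead_type == LAD
        for mask, eps_l, rc_l in (
            (is_lad, params.eps_lad_lamin, params.cutoff_attractive),
            (~is_lad, params.eps_nonlad_lamin, params.cutoff_repulsive),
        ):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            sub = dist[idx]
            inl = sub < rc_l
            sr6l = np.where(inl, (sigma / np.where(inl, sub, 1.0)) ** 6, 0.0)
            frl = np.where(inl, 24.0 * eps_l * (2.0 * sr6l * sr6l - sr6l) / np.where(inl, sub, 1.0) ** 2, 0.0)
            f[idx] += np.einsum("jm,jmk->jk", frl, dvec[idx])

        if bonds is not None:
            for lad_i, lam_j in bonds.pairs():
                dv = pos[lad_i] - shell.lamin_positions[lam_j]
                rb = float(np.linalg.norm(dv))
                if rb > 1e-12:
                    f[lad_i] -= 2.0 * params.kbond * (rb - sigma) * dv / rb
    return f
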