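"""Energy terms and analytic forces, checked against hand values, an
independent brute-force oracle, and central finite differences."""

import math

import numpy as np
import pytest

from ladsim import (
    BondSet,
    SimulationParameters,
    bonded_terms,
    build_shell,
    forces,
    lj_pair,
    total_energy,
)
from ladsim.builder import ChromatinChain, initial_configuration
from ladsim.exceptions import SingularOverlapError
from ladsim.units import LAD, NONLAD


def brute_force_energy(chain, shell, bonds, params):
    """Plain-Python oracle: every term summed by explicit double loops."""
    pos = chain.positions
    n = len(pos)
    sigma = params.bead_diameter

    def lj(r, eps, cutoff):
        if r >= cutoff:
            return 0.0
        shift = 4 * eps * ((sigma / cutoff) ** 12 - (sigma / cutoff) ** 6)
        return 4 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6) - shift

    stretch = sum(
        params.spring_constant
        * (math.dist(pos[i], pos[i + 1]) - params.rest_length) ** 2
        for i in range(n - 1)
    )
    bend = 0.0
    for i in range(1, n - 1):
        b1 = pos[i] - pos[i - 1]
        b2 = pos[i + 1] - pos[i]
        c = float(np.dot(b1, b2) / (np.linalg.norm(b1) * np.linalg.norm(b2)))
        bend += params.bending_stiffness * (1 - c)
    chrom = 0.0
    rc = params.effective_chrom_cutoff
    for i in range(n):
        for j in range(i + 1, n):
            eps = params.epsilon_matrix[chain.bead_type[i], chain.bead_type[j]]
            chrom += lj(math.dist(pos[i], pos[j]), eps, rc)
    wall = lamin = bond = 0.0
    if shell is not None:
        for i in range(n):
            gap = shell.confinement_radius - float(np.linalg.norm(pos[i]))
            wall += lj(gap, params.eps_wall, params.cutoff_repulsive)
            for q in range(shell.n_lamin):
                r = math.dist(pos[i], shell.lamin_positions[q])
                if chain.bead_type[i] == LAD:
                    lamin += lj(r, params.eps_lad_lamin, params.cutoff_attractive)
                else:
                    lamin += lj(r, params.eps_nonlad_lamin, params.cutoff_repulsive)
        if bonds is not None:
            for i, q in bonds.pairs():
                r = math.dist(pos[i], shell.lamin_positions[q])
                bond += -params.kbond * (params.r_bond - sigma) ** 2 + params.kbond * (
                    r - sigma
                ) ** 2
    return stretch + bend + chrom + wall + lamin + bond


def make_system(n=40, phi=0.15, seed=3, psi=1.0):
    p = SimulationParameters(n_beads=n, psi=psi, rng_seed=seed).with_phi(phi)
    pos = initial_configuration(n, p.confinement_radius, 1.0, seed)
    rng = np.random.default_rng(seed)
    types = (rng.random(n) < 0.5).astype(np.int8)
    chain = ChromatinChain(pos, types, types == LAD)
    shell = build_shell(p.confinement_radius, 1.0)
    bonds = BondSet.empty(n)
    from scipy.spatial import cKDTree

    d, j = cKDTree(shell.lamin_positions).query(pos)
    for i in range(n):
        if chain.bondable[i] and d[i] < p.r_bond:
            bonds.partner[i] = j[i]
    return p, chain, shell, bonds


class TestLjPair:
    def test_zero_crossing_at_sigma(self):
        e, f = lj_pair(1.0, 1.0, 1.0, 2.5, shifted=False)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert f == pytest.approx(24.0)

    def test_minimum(self):
        e, f = lj_pair(2 ** (1 / 6), 1.0, 1.0, 2.5, shifted=False)
        assert e == pytest.approx(-1.0)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_beyond_cutoff(self):
        assert lj_pair(2.6, 1.0, 1.0, 2.5) == (0.0, 0.0)

    def test_shift_makes_energy_continuous(self):
        e_in, _ = lj_pair(2.5 - 1e-9, 1.0, 1.0, 2.5)
        assert abs(e_in) < 1e-7

    def test_singular_overlap(self):
        with pytest.raises(SingularOverlapError):
            lj_pair(0.0, 1.0, 1.0, 2.5)


class TestBondedTerms:
    def test_straight_chain_at_rest(self):
        pos = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        stretch, bend = bonded_terms(pos, 100.0, 1.0, 2.0)
        assert stretch == pytest.approx(0.0, abs=1e-12)
        assert bend == pytest.approx(0.0, abs=1e-12)

    def test_single_stretched_spring(self):
        pos = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        stretch, _ = bonded_terms(pos, 100.0, 1.0, 2.0)
        assert stretch == pytest.approx(1.0)

    def test_right_angle_kink(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]])
        _, bend = bonded_terms(pos, 100.0, 1.0, 2.0)
        assert bend == pytest.approx(2.0)


class TestTotalEnergy:
    def test_two_distant_beads(self):
        p = SimulationParameters(n_beads=2, spring_constant=0.0, bending_stiffness=0.0)
        chain = ChromatinChain(
            np.array([[0.0, 0, 0], [3.0, 0, 0]]),
            np.zeros(2, dtype=np.int8),
        )
        eb = total_energy(chain, None, None, p)
        assert eb.total == pytest.approx(0.0, abs=1e-12)

    def test_breakdown_sums_to_total(self):
        p, chain, shell, bonds = make_system()
        eb = total_energy(chain, shell, bonds, p)
        assert eb.total == pytest.approx(sum(eb.as_tuple()), rel=1e-10)

    def test_matches_brute_force_oracle(self):
        for seed in (1, 2, 3):
            p, chain, shell, bonds = make_system(seed=seed)
            eb = total_energy(chain, shell, bonds, p)
            ref = brute_force_energy(chain, shell, bonds, p)
            assert eb.total == pytest.approx(ref, rel=1e-10)

    def test_kernel_matches_reference(self):
        from ladsim import _kernels as K

        p, chain, shell, bonds = make_system(n=60)
        cc = K.build_all_half_list(60)
        cl = K.build_all_cross_list(60, shell.n_lamin)
        F = np.empty((60, 3))
        E = np.empty(6)
        status = K.compute_forces(
            chain.positions, chain.bead_type, bonds.partner, shell.lamin_positions,
            cc[0], cc[1], cl[0], cl[1], p.confinement_radius, 1.0,
            p.spring_constant, p.rest_length, p.bending_stiffness,
            p.epsilon_matrix, p.effective_chrom_cutoff,
            p.eps_lad_lamin, p.cutoff_attractive, p.eps_nonlad_lamin,
            p.cutoff_repulsive, p.eps_wall, p.cutoff_repulsive,
            p.kbond, p.r_bond, F, E, True,
        )
        assert status == 0
        eb = total_energy(chain, shell, bonds, p)
        np.testing.assert_allclose(E, eb.as_tuple(), rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(F, forces(chain, shell, bonds, p), rtol=1e-9, atol=1e-9)


class TestForces:
    def test_straight_chain_at_rest_force_free(self):
        p = SimulationParameters(n_beads=5, epsilon_matrix=np.zeros((2, 2)))
        pos = np.column_stack([np.arange(5.0) * 1.0, np.zeros(5), np.zeros(5)])
        chain = ChromatinChain(pos, np.zeros(5, dtype=np.int8))
        f = forces(chain, None, None, p)
        # LJ between non-adjacent beads at distance >= 2: only weak core terms
        assert np.abs(f).max() < 1e-9

    def test_newtons_third_law_chain_terms(self):
        p, chain, _, _ = make_system()
        f = forces(chain, None, None, p)
        assert np.linalg.norm(f.sum(axis=0)) < 1e-9 * max(1.0, np.abs(f).max())

    def test_translation_invariance_of_chain_energy(self):
        p, chain, _, _ = make_system()
        e0 = total_energy(chain, None, None, p).total
        shifted = ChromatinChain(chain.positions + 3.7, chain.bead_type, chain.bondable)
        assert total_energy(shifted, None, None, p).total == pytest.approx(e0, rel=1e-12)

    def test_finite_difference_consistency(self):
        """Analytic forces match central differences of the total energy."""
        p, chain, shell, bonds = make_system(n=50, seed=5)
        f = forces(chain, shell, bonds, p)
        scale = max(1.0, float(np.abs(f).max()))
        h = 1e-6
        rng = np.random.default_rng(0)
        for i in rng.choice(50, size=12, replace=False):
            for d in range(3):
                orig = chain.positions[i, d]
                chain.positions[i, d] = orig + h
                ep = total_energy(chain, shell, bonds, p).total
                chain.positions[i, d] = orig - h
                em = total_energy(chain, shell, bonds, p).total
                chain.positions[i, d] = orig
                fd = -(ep - em) / (2 * h)
                assert abs(fd - f[i, d]) <= 1e-5 * scale
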