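"""Observables: profiles, classification, contact maps, polymer statistics."""

import numpy as np
import pytest

from ladsim import (
    ClassificationThresholds,
    RadialProfile,
    angular_segregation,
    classify_organization,
    contact_map,
    persistence_length,
    radial_profile,
    scaling_exponent,
)
from ladsim.analysis import center_of_mass_offset, contact_scaling_slope
from ladsim.exceptions import FitFailureError, InvalidInputError
from ladsim.units import LAD, NONLAD

from conftest import make_semiflexible_chains


def uniform_sphere_points(n, radius, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    return pts * radius * rng.random(n)[:, None] ** (1 / 3)


class TestRadialProfile:
    def test_uniform_points_flat_profile(self):
        frames = np.stack([uniform_sphere_points(20_000, 10.0, s) for s in range(5)])
        prof = radial_profile(frames, 10.0, n_shells=10)
        # skip the innermost shells where counts are low
        outer = prof.phi_local[3:]
        se = outer.std() / np.sqrt(outer.size)
        assert np.all(np.abs(outer - outer.mean()) < 3 * np.sqrt(outer.var() + 9 * se**2) + 3 * se * 3)
        # direct flatness check: relative spread below 10%
        assert outer.std() / outer.mean() < 0.1

    def test_volume_weighted_mean_is_global_phi(self):
        n, rc = 5000, 8.0
        frames = uniform_sphere_points(n, rc, 1)
        prof = radial_profile(frames, rc, 20)
        phi_global = n * (0.5) ** 3 / rc**3
        assert prof.volume_weighted_mean() == pytest.approx(phi_global, rel=1e-9)

    def test_localized_shell(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(3000, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        radii = 0.85 + 0.1 * rng.random(3000)
        pts *= (radii * 10.0)[:, None]
        prof = radial_profile(pts, 10.0, 10)
        occupied = prof.phi_local > 0
        assert occupied.tolist() == [False] * 8 + [True, True]

    def test_empty_trajectory_rejected(self):
        with pytest.raises(InvalidInputError):
            radial_profile(np.empty((0, 0, 3)), 5.0)


def synthetic_profile(shape, n_shells=30):
    r = np.linspace(0.5 / n_shells, 1 - 0.5 / n_shells, n_shells)
    if shape == "flat":
        phi = np.full(n_shells, 0.3)
    elif shape == "peripheral":
        phi = np.exp(-((r - 0.95) ** 2) / 0.004)
        phi[r < 0.5] = 0.0
    elif shape == "central":
        phi = np.exp(-(r**2) / 0.05)
    return RadialProfile(r, phi, 1)


class TestClassification:
    def test_flat_profile_is_conventional(self):
        assert classify_organization(synthetic_profile("flat")).mode == "conventional"

    def test_peripheral_peak(self):
        assert classify_organization(synthetic_profile("peripheral")).mode == "peripheral"

    def test_central_peak(self):
        assert classify_organization(synthetic_profile("central")).mode == "central"

    def test_scale_invariance(self):
        for shape in ("flat", "peripheral", "central"):
            prof = synthetic_profile(shape)
            scaled = RadialProfile(prof.shell_centers, 7.3 * prof.phi_local, 1)
            assert (
                classify_organization(prof).mode == classify_organization(scaled).mode
            )

    def test_wetting_droplet_grouped_central(self):
        call = classify_organization(synthetic_profile("central"), com_offset=0.3)
        assert call.mode == "central"
        assert call.is_wetting


class TestContactMap:
    def test_straight_rod_contacts_banded(self):
        pos = np.column_stack([np.arange(50.0), np.zeros(50), np.zeros(50)])
        mat, s, p_s = contact_map(pos, contact_distance=2.5)
        # contacts only for separation 2 (distance 2 < 2.5); none beyond
        assert p_s[0] == 1.0  # s = 2
        assert np.all(p_s[1:] == 0.0)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(80, 3)) * 2
        mat, _, _ = contact_map(pos, 2.5, bin_beads=4)
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 1.0)

    def test_p_of_s_monotone_for_globule(self):
        """P(s) decays with contour distance for a collapsed conformation."""
        # build a compact space-filling-ish conformation: random walk in a box
        rng = np.random.default_rng(3)
        pos = np.zeros((500, 3))
        for i in range(1, 500):
            while True:
                step = rng.normal(size=3)
                cand = pos[i - 1] + step / np.linalg.norm(step)
                if np.all(np.abs(cand) < 5):
                    pos[i] = cand
                    break
        _, s, p_s = contact_map(pos, 2.5)
        coarse = [p_s[(s >= a) & (s < b)].mean() for a, b in [(2, 10), (10, 50), (50, 250)]]
        assert coarse[0] > coarse[1] > coarse[2]


class TestScalingExponent:
    def test_ideal_chain_exponent(self):
        """Gaussian chains scale with nu = 1/2."""
        rng = np.random.default_rng(7)
        confs = np.cumsum(rng.normal(size=(30, 400, 3)), axis=1)
        nu, ci = scaling_exponent(confs)
        assert nu == pytest.approx(0.50, abs=0.03)
        assert ci[0] < nu < ci[1]

    def test_rod_exponent(self):
        pos = np.column_stack([np.arange(200.0), np.zeros(200), np.zeros(200)])
        confs = np.stack([pos] * 25)
        nu, _ = scaling_exponent(confs)
        # rod R_g^2(s) = ((s+1)^2 - 1)/12: slightly below slope 2 at finite s
        assert nu == pytest.approx(1.0, abs=0.05)

    def test_too_few_conformations(self):
        with pytest.raises(InvalidInputError):
            scaling_exponent(np.zeros((5, 100, 3)))


class TestPersistenceLength:
    def test_freely_rotating_oracle(self):
        """Chains built with exact exponential tangent decay recover l_p."""
        target_lp = 2.0
        cos_alpha = np.exp(-1.0 / target_lp)
        chains = make_semiflexible_chains(25, 300, cos_alpha, seed=11)
        lp = persistence_length(chains)
        assert lp == pytest.approx(target_lp, rel=0.05)

    def test_flexible_limit(self):
        chains = make_semiflexible_chains(25, 300, 0.30, seed=2)
        lp = persistence_length(chains)
        assert lp < 1.5

    def test_rigid_rod_fit_failure(self):
        pos = np.column_stack([np.arange(100.0), np.zeros(100), np.zeros(100)])
        with pytest.raises(FitFailureError):
            persistence_length(np.stack([pos] * 25))


class TestAngularSegregation:
    def peripheral_frame(self, n, seed, hemispheres=False):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pos = pts * 9.5
        if hemispheres:
            types = np.where(pos[:, 2] > 0, LAD, NONLAD).astype(np.int8)
        else:
            types = (rng.random(n) < 0.5).astype(np.int8)
        return pos, types

    def test_shuffled_types_index_near_one(self):
        pos, types = self.peripheral_frame(800, 0)
        idx = angular_segregation(pos, types, 10.0)
        assert idx == pytest.approx(1.0, abs=0.05)

    def test_hemispheric_demixing(self):
        pos, types = self.peripheral_frame(800, 1, hemispheres=True)
        idx = angular_segregation(pos, types, 10.0)
        assert idx > 1.5

    def test_single_type_degenerate(self):
        pos, _ = self.peripheral_frame(500, 2)
        types = np.full(500, LAD, dtype=np.int8)
        assert angular_segregation(pos, types, 10.0) == 1.0

    def test_too_few_peripheral_beads(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(200, 3))  # all near the center of a big sphere
        types = np.zeros(200, dtype=np.int8)
        with pytest.raises(InvalidInputError):
            angular_segregation(pos, types, 50.0)


class TestCenterOfMassOffset:
    def test_centered_cloud(self):
        pts = uniform_sphere_points(5000, 5.0, 4)
        assert center_of_mass_offset(pts, 5.0) < 0.05

    def test_displaced_cloud(self):
        pts = uniform_sphere_points(2000, 2.0, 5) + np.array([3.0, 0, 0])
        assert center_of_mass_offset(pts, 5.0) == pytest.approx(0.6, abs=0.05)
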