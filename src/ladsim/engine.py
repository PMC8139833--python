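"""Overdamped Langevin (Brownian dynamics) integrator and the two-stage
equilibration protocol.

Each step displaces every chromatin bead by

    dr = -(dt / gamma m) grad E_tot + sqrt(2 kT dt / gamma m) * xi,

with xi a unit-variance Gaussian per component (a uniform variate with the
matching second moment is available for strict fidelity to the classic
sqrt(6 kT dt / gamma m) prefactor).  Lamin beads never move.  Bond
formation/breaking is attempted every step after the move.

The equilibration protocol mirrors how the model is meant to be started:
a soft push-off to remove initial overlaps, a purely repulsive
(self-avoiding) stage with lamina interactions and bonding active, then
the attractive stage with the configured chromatin self-attraction.  The
repulsive and attractive stages each run until the windowed mean radius
of gyration changes by less than 1% over two consecutive windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .bonding import BondSet, break_probability
from .builder import ChromatinChain, build_chain
from .exceptions import EscapedBeadError, SingularAngleError, UnstableTimestepError
from .forcefield import EnergyBreakdown
from .lamina import LaminaShell, build_shell
from .units import SimulationParameters

DEFAULT_SKIN = 0.8  # Verlet skin in units of sigma


@dataclass
class SimulationState:
    """Mutable simulation state: chain, shell, bonds, step counter, RNG cursor."""

    chain: ChromatinChain
    shell: LaminaShell | None
    bonds: BondSet
    params: SimulationParameters
    step: int = 0
    seed_counter: int = 0
    stage_log: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def next_seed(self) -> int:
        """Deterministic per-chunk kernel seed derived from the base seed."""
        s = (self.params.rng_seed * 1_000_003 + self.seed_counter * 7_919 + 12_345) % (2**31 - 1)
        self.seed_counter += 1
        return s


@dataclass
class Trajectory:
    """Sampled frames of a run: (step, positions, bond_count, EnergyBreakdown)."""

    frames: list
    sampling_interval: int
    partner_frames: list | None = None

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def steps(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames])

    @property
    def positions(self) -> np.ndarray:
        return np.stack([f[1] for f in self.frames])

    @property
    def bond_counts(self) -> np.ndarray:
        return np.array([f[2] for f in self.frames])

    @property
    def energies(self) -> list:
        return [f[3] for f in self.frames]


def initialize(params: SimulationParameters, bead_type: np.ndarray | None = None) -> SimulationState:
    """Build chain, shell, and an empty bond set from a parameter object."""
    chain = build_chain(params, bead_type=bead_type)
    shell = None
    if params.confinement_radius is not None:
        shell = build_shell(params.confinement_radius, params.lamin_spacing)
    return SimulationState(chain, shell, BondSet.empty(chain.n_beads), params)


def _kernel_call(
    state: SimulationState,
    params: SimulationParameters,
    n_steps: int,
    sample_every: int,
    store_frames: bool = False,
    cap_disp: float = 0.0,
    noise_off: bool = False,
    use_all_pairs: bool = False,
    seed: int | None = None,
    skin: float | None = None,
):
    chain, shell = state.chain, state.shell
    n = chain.n_beads
    lam = shell.lamin_positions if shell is not None else np.empty((0, 3))
    rc_conf = shell.confinement_radius if shell is not None else -1.0
    n_samples = n_steps // sample_every if sample_every > 0 else 0
    frames = np.empty((n_samples if store_frames else 0, n, 3))
    partners = np.empty((n_samples if store_frames else 0, n), dtype=np.int32)
    rg = np.empty(max(n_samples, 1))
    en = np.empty((max(n_samples, 1), 6))
    bc = np.empty(max(n_samples, 1), dtype=np.int64)
    if seed is None:
        seed = state.next_seed()
    fail_bead = np.full(1, -1, dtype=np.int64)
    status, at_step = K.run_chunk(
        chain.positions,
        chain.bead_type,
        chain.bondable.astype(np.int8),
        state.bonds.partner,
        lam,
        rc_conf,
        params.bead_diameter,
        params.spring_constant,
        params.rest_length,
        params.bending_stiffness,
        params.epsilon_matrix,
        params.effective_chrom_cutoff,
        params.eps_lad_lamin,
        params.cutoff_attractive,
        params.eps_nonlad_lamin,
        params.cutoff_repulsive,
        params.eps_wall,
        params.cutoff_repulsive,
        params.kbond,
        params.r_bond,
        break_probability(params.ubond, params.thermal_energy),
        params.psi > 0.0,
        params.timestep * params.mobility,
        _noise_amp(params),
        params.noise == "uniform",
        noise_off,
        cap_disp,
        (DEFAULT_SKIN if skin is None else skin) * params.bead_diameter,
        use_all_pairs,
        n_steps,
        sample_every if sample_every > 0 else 0,
        store_frames,
        seed,
        frames,
        rg,
        en,
        bc,
        partners,
        fail_bead,
    )
    if status == K.STATUS_UNSTABLE:
        err = UnstableTimestepError(state.step + at_step, 0.5)
        err.bead = int(fail_bead[0])
        raise err
    if status == K.STATUS_ESCAPED:
        raise EscapedBeadError(f"bead escaped the sphere at step {state.step + at_step}")
    if status == K.STATUS_SINGULAR:
        raise SingularAngleError(f"degenerate geometry at step {state.step + at_step}")
    state.step += n_steps
    return frames, rg[:n_samples], en[:n_samples], bc[:n_samples], partners


def _noise_amp(params: SimulationParameters) -> float:
    dt_mob = params.timestep * params.mobility
    if params.noise == "uniform":
        # sqrt(6 kT dt/gamma m) prefactor on U[-1,1]: same second moment
        return math.sqrt(6.0 * params.thermal_energy * dt_mob)
    return math.sqrt(2.0 * params.thermal_energy * dt_mob)


def langevin_step(
    state: SimulationState,
    params: SimulationParameters | None = None,
    noise_off: bool = False,
    seed: int | None = None,
) -> SimulationState:
    """Advance the state by a single Langevin step (in place)."""
    params = state.params if params is None else params
    _kernel_call(state, params, 1, 0, noise_off=noise_off, seed=seed)
    return state


def run(
    state: SimulationState,
    n_steps: int,
    sampling_interval: int,
    params: SimulationParameters | None = None,
    noise_off: bool = False,
    use_all_pairs: bool = False,
) -> Trajectory:
    """Advance ``n_steps`` and return a trajectory sampled every
    ``sampling_interval`` steps (the initial frame included)."""
    params = state.params if params is None else params
    from .forcefield import total_energy

    first = (
        state.step,
        state.chain.positions.copy(),
        state.bonds.count,
        total_energy(state.chain, state.shell, state.bonds, params),
    )
    first_partner = state.bonds.partner.copy()
    start = state.step
    frames, rg, en, bc, partners = _kernel_call(
        state,
        params,
        n_steps,
        sampling_interval,
        store_frames=True,
        noise_off=noise_off,
        use_all_pairs=use_all_pairs,
    )
    out = [first]
    partner_frames = [first_partner]
    for k in range(frames.shape[0]):
        eb = EnergyBreakdown(*en[k])
        out.append((start + (k + 1) * sampling_interval, frames[k].copy(), int(bc[k]), eb))
        partner_frames.append(partners[k].copy())
    return Trajectory(out, sampling_interval, partner_frames)


def equilibrate_protocol(
    state: SimulationState,
    params: SimulationParameters | None = None,
    pushoff_steps: int = 3000,
    window: int = 10_000,
    max_windows_repulsive: int = 10,
    max_windows_attractive: int = 30,
    min_windows_attractive: int = 3,
    plateau_rtol: float = 0.01,
    eq_timestep: float | None = None,
    eq_cap: float = 0.15,
    eq_skin: float = 1.6,
) -> SimulationState:
    """Three-stage start-up: soft push-off, repulsive stage, attractive stage.

    Each of the two physical stages runs window by window until the
    windowed mean R_g changes by less than ``plateau_rtol`` over two
    consecutive windows (or the window budget runs out, in which case the
    state is still returned and the stage log notes the non-convergence).

    ``eq_timestep`` lets the two equilibration stages integrate at a
    larger step than production, with per-step displacements capped at
    ``eq_cap`` sigma so core collisions rattle instead of diverging; the
    mild sampling bias near contacts is irrelevant while the protocol is
    only steering the system toward its organization mode.  Production
    sampling should follow at the unbiased (smaller) step.
    """
    params = state.params if params is None else params
    stage_params = params if eq_timestep is None else params.replace(timestep=eq_timestep)
    stage_cap = 0.0 if eq_timestep is None else eq_cap * params.bead_diameter

    # stage 0: noise-free, capped-displacement descent ("soft push-off"),
    # purely repulsive, bonding inert (a bond formed while the cap restrains
    # motion could stretch without bound, since stretched bonds almost never
    # break).  Runs until the largest drift displacement is well under the
    # stability guard, so stage 1 starts from a relaxed configuration.
    pushoff = params.replace(chrom_cutoff=params.cutoff_repulsive, psi=0.0)
    chunk = max(200, pushoff_steps // 5)
    sigma = params.bead_diameter
    # Inflation: the folded random walk is locally over-dense, so descend
    # with a fixed cap until no pair (and no wall gap) is tighter than
    # 0.85 sigma; then polish with a smaller cap (a capped descent
    # oscillates around stiff contacts and cannot fully converge).
    for _ in range(max(10, 100_000 // chunk)):
        _kernel_call(state, pushoff, chunk, 0, cap_disp=0.05 * sigma, noise_off=True,
                     skin=eq_skin)
        if _tightest_contact(state) > 0.85 * sigma:
            break
    for _ in range(3):
        _kernel_call(state, pushoff, chunk, 0, cap_disp=0.01 * sigma, noise_off=True,
                     skin=eq_skin)
        if _tightest_contact(state) > 0.9 * sigma:
            break
    state.stage_log.append("pushoff")

    repulsive = stage_params.replace(chrom_cutoff=params.cutoff_repulsive)
    _run_to_plateau(
        state, repulsive, window, max_windows_repulsive, plateau_rtol, "repulsive",
        stage_cap, skin=eq_skin,
    )
    attractive = stage_params.replace(chrom_cutoff=None)
    _run_to_plateau(
        state, attractive, window, max_windows_attractive, plateau_rtol, "attractive",
        stage_cap, min_windows_attractive, skin=eq_skin,
    )
    if eq_timestep is not None:
        # settle: anneal out contacts left over-tight by the capped larger
        # step, so uncapped production at the smaller step starts stable
        settle = params.replace(chrom_cutoff=None)
        _kernel_call(state, settle, 2000, 0, cap_disp=0.1 * params.bead_diameter)
    return state


def _tightest_contact(state: SimulationState) -> float:
    """Smallest of (min pair distance, min wall gap) in the current state."""
    from scipy.spatial import cKDTree

    pos = state.chain.positions
    tree = cKDTree(pos)
    d, _ = tree.query(pos, k=2)
    tight = float(d[:, 1].min())
    if state.shell is not None:
        gap = state.shell.confinement_radius - float(np.linalg.norm(pos, axis=1).max())
        tight = min(tight, gap)
    return tight


def _run_to_plateau(state, params, window, max_windows, rtol, label, cap_disp=0.0,
                    min_windows=3, skin=None):
    sample_every = max(1, window // 20)
    means = []
    converged = False
    for _ in range(max_windows):
        _, rg, _, _, _ = _kernel_call(
            state, params, window, sample_every, cap_disp=cap_disp, skin=skin
        )
        means.append(float(np.mean(rg)))
        if len(means) >= max(3, min_windows):
            d1 = abs(means[-1] - means[-2]) / means[-2]
            d2 = abs(means[-2] - means[-3]) / means[-3]
            if d1 < rtol and d2 < rtol:
                converged = True
                break
    state.stage_log.append(label)
    if not converged:
        state.warnings.append(f"stage '{label}': no R_g plateau within {max_windows} windows")
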