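"""Small self-contained validation battery used by the ``validate`` CLI
subcommand: force consistency, profile conservation, and bond occupancy
on a tiny system.  The full pytest suite is the authoritative check; this
is a quick field diagnostic."""

from __future__ import annotations

import numpy as np

from .bonding import BondSet
from .builder import ChromatinChain, initial_configuration, select_bondable, synthesize_lad_pattern
from .engine import equilibrate_protocol, initialize, run
from .forcefield import forces, total_energy
from .analysis import radial_profile
from .units import SimulationParameters


def run_battery(n_beads: int = 100, seed: int = 0) -> list[str]:
    failures: list[str] = []
    params = SimulationParameters(n_beads=n_beads, rng_seed=seed, timestep=2e-4).with_phi(0.2)
    state = initialize(params)

    # analytic forces vs central finite differences on a handful of beads
    f = forces(state.chain, state.shell, state.bonds, params)
    h = 1e-6
    rng = np.random.default_rng(seed)
    scale = max(1.0, float(np.abs(f).max()))
    for i in rng.integers(0, n_beads, 5):
        for d in range(3):
            orig = state.chain.positions[i, d]
            state.chain.positions[i, d] = orig + h
            ep = total_energy(state.chain, state.shell, state.bonds, params).total
            state.chain.positions[i, d] = orig - h
            em = total_energy(state.chain, state.shell, state.bonds, params).total
            state.chain.positions[i, d] = orig
            fd = -(ep - em) / (2 * h)
            if abs(fd - f[i, d]) > 1e-4 * scale:
                failures.append(f"force mismatch bead {i} axis {d}: {f[i, d]:.6g} vs {fd:.6g}")

    # short run: profile conservation and bond occupancy
    equilibrate_protocol(state, pushoff_steps=500, window=1000,
                         max_windows_repulsive=3, max_windows_attractive=3)
    traj = run(state, 2000, 500)
    prof = radial_profile(traj.positions[1:], params.confinement_radius, 10)
    phi = prof.volume_weighted_mean()
    if abs(phi - params.phi) > 0.01 * params.phi:
        failures.append(f"profile mean {phi:.4f} != global phi {params.phi:.4f}")
    max_bonds = int(np.floor(params.psi * state.chain.n_lad + 0.5))
    if traj.bond_counts.max() > max_bonds:
        failures.append("bond count exceeded psi * n_LAD")
    return failures
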