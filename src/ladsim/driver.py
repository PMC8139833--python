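"""Single-run pipeline and the (phi, psi, epsilon) state-diagram sweep.

A single run builds the system, applies the two-stage equilibration,
collects a production trajectory, and reduces it to a radial profile and
an organization call.  The sweep driver repeats this over a grid of
(phi, psi, epsilon) triples with replicate seeds, appending one CSV row
per run, skipping completed rows on resume, and reporting a majority-vote
mode per grid point.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as lio
from .analysis import (
    OrganizationCall,
    center_of_mass_offset,
    classify_organization,
    radial_profile,
)
from .engine import Trajectory, _kernel_call, _tightest_contact, equilibrate_protocol, initialize, run
from .exceptions import InvalidParameterError
from .units import NONLAD, SimulationParameters


@dataclass
class RunSettings:
    """Desk-scale run-length defaults for equilibration and production.

    ``timestep`` is the production integration step.  The Table-default
    0.01 tau sits at the overdamped-Euler stability boundary of the bond
    springs, and the Lennard-Jones core is unstable (curvature * dt >= 2)
    for thermally visited separations at steps above ~5e-4 tau.  Confined
    production therefore integrates at 1e-4 tau: the dense wall layer
    makes ~17 kT contacts occasionally reachable, and at 1e-4 the drift
    guard threshold sits at ~40 kT contacts, far outside anything the
    system visits.
    """

    timestep: float = 1e-4
    eq_timestep: float = 2e-3
    pushoff_steps: int = 3000
    window: int = 9_000
    max_windows_repulsive: int = 3
    max_windows_attractive: int = 8
    min_windows_attractive: int = 6
    production_steps: int = 10_000
    sampling_interval: int = 1_000
    n_shells: int = 30


@dataclass
class SweepSpec:
    """Grid of (phi, psi, epsilon) triples with replicate seeds."""

    grid: list  # of (phi, psi, epsilon)
    replicate_seeds: list
    scaled_n_beads: int = 2000
    output_dir: str | Path = "sweep_out"

    def __post_init__(self) -> None:
        if not self.grid:
            raise InvalidParameterError("sweep grid must be non-empty")
        for phi, psi, eps in self.grid:
            if not 0.0 < phi <= 1.0:
                raise InvalidParameterError(f"phi={phi} outside (0, 1]")
            if not 0.0 <= psi <= 1.0:
                raise InvalidParameterError(f"psi={psi} outside [0, 1]")
            if eps < 0.0:
                raise InvalidParameterError(f"epsilon={eps} negative")
        if not self.replicate_seeds:
            raise InvalidParameterError("need at least one replicate seed")


def params_for_point(
    phi: float, psi: float, epsilon: float, n_beads: int = 2000, seed: int = 0
) -> SimulationParameters:
    """Parameter set for one state-diagram point; R_c follows from phi."""
    p = SimulationParameters(
        n_beads=n_beads,
        psi=psi,
        epsilon_matrix=np.full((2, 2), epsilon),
        rng_seed=seed,
    )
    return p.with_phi(phi)


def run_single(
    params: SimulationParameters,
    settings: RunSettings | None = None,
    outdir: str | Path | None = None,
    bead_type: np.ndarray | None = None,
) -> tuple[OrganizationCall, Trajectory]:
    """Build, equilibrate, run production, classify; optionally write artifacts."""
    settings = settings or RunSettings()
    params = params.replace(timestep=settings.timestep)
    state = initialize(params, bead_type=bead_type)
    equilibrate_protocol(
        state,
        pushoff_steps=settings.pushoff_steps,
        window=settings.window,
        max_windows_repulsive=settings.max_windows_repulsive,
        max_windows_attractive=settings.max_windows_attractive,
        min_windows_attractive=settings.min_windows_attractive,
        eq_timestep=settings.eq_timestep,
    )
    traj = run(state, settings.production_steps, settings.sampling_interval)
    # skip the pre-production frame when averaging the profile
    frames = traj.positions[1:]
    profile = radial_profile(
        frames, params.confinement_radius, settings.n_shells, params.bead_diameter
    )
    com = center_of_mass_offset(frames, params.confinement_radius)
    call = classify_organization(profile, com)
    if state.warnings:
        call = OrganizationCall(
            call.mode, call.com_offset, {**call.evidence, "unconverged": True}
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lio.write_xyz(outdir / "trajectory.xyz", traj, state.chain.bead_type, params, state.shell)
        lio.write_thermo_csv(outdir / "thermo.csv", traj, params)
        lio.write_profile_csv(outdir / "profile.csv", profile, params)
        lio.write_labels_csv(outdir / "labels.csv", state.chain.bead_type, params)
        lio.write_classification_json(
            outdir / "classification.json", call, params, {"bond_count": int(traj.bond_counts[-1])}
        )
    return call, traj


RESULT_COLUMNS = ["phi", "psi", "epsilon", "seed", "mode", "com_offset", "bond_count", "rg"]


def run_sweep(spec: SweepSpec, settings: RunSettings | None = None):
    """State-diagram sweep: one row per (grid point x seed), plus consensus.

    Appends to ``results.csv`` under the output directory; rows already
    present are skipped, so an interrupted sweep resumes where it stopped.
    Returns (rows, consensus) as lists of dicts.
    """
    settings = settings or RunSettings()
    outdir = Path(spec.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results_path = outdir / "results.csv"
    done: set[tuple] = set()
    rows: list[dict] = []
    if results_path.exists():
        with results_path.open() as fh:
            for row in csv.DictReader(line for line in fh if not line.startswith("#")):
                rows.append(row)
                done.add((row["phi"], row["psi"], row["epsilon"], row["seed"]))
    new_file = not results_path.exists()
    with results_path.open("a") as fh:
        writer = csv.writer(fh)
        if new_file:
            writer.writerow(RESULT_COLUMNS)
        for phi, psi, eps in spec.grid:
            for seed in spec.replicate_seeds:
                key = (f"{phi:g}", f"{psi:g}", f"{eps:g}", str(seed))
                if key in done:
                    continue
                params = params_for_point(phi, psi, eps, spec.scaled_n_beads, seed)
                try:
                    call, traj = run_single(params, settings)
                    row = {
                        "phi": f"{phi:g}",
                        "psi": f"{psi:g}",
                        "epsilon": f"{eps:g}",
                        "seed": str(seed),
                        "mode": call.mode,
                        "com_offset": f"{call.com_offset:.4f}",
                        "bond_count": str(int(traj.bond_counts[-1])),
                        "rg": f"{float(np.sqrt(np.mean(np.sum((traj.positions[-1] - traj.positions[-1].mean(axis=0)) ** 2, axis=1)))):.4f}",
                    }
                except Exception as exc:  # record the failure, keep sweeping
                    row = {
                        "phi": f"{phi:g}",
                        "psi": f"{psi:g}",
                        "epsilon": f"{eps:g}",
                        "seed": str(seed),
                        "mode": f"error:{type(exc).__name__}",
                        "com_offset": "",
                        "bond_count": "",
                        "rg": "",
                    }
                writer.writerow([row[c] for c in RESULT_COLUMNS])
                fh.flush()
                rows.append(row)
    consensus = consensus_modes(rows)
    return rows, consensus


def consensus_modes(rows: list[dict]) -> list[dict]:
    """Majority-vote mode per (phi, psi, epsilon) grid point."""
    from collections import Counter, defaultdict

    votes: dict[tuple, Counter] = defaultdict(Counter)
    for row in rows:
        if row["mode"].startswith("error:"):
            continue
        votes[(row["phi"], row["psi"], row["epsilon"])][row["mode"]] += 1
    out = []
    for (phi, psi, eps), counter in votes.items():
        mode, count = counter.most_common(1)[0]
        out.append(
            {
                "phi": phi,
                "psi": psi,
                "epsilon": eps,
                "mode": mode,
                "votes": count,
                "n_seeds": sum(counter.values()),
            }
        )
    return out


# ---------------------------------------------------------------------------
# unconfined-chain measurement pipelines (persistence length, Flory exponents)

def _pivot_sweep(pos, n_attempts, cutoff, bending_stiffness, rng):
    """Metropolis pivot moves for an unconfined repulsive chain.

    Rotates the chain tail about a random internal bead by a random
    rotation, accepting with the Boltzmann factor of the change in the
    nonbonded (WCA) energy between the two halves plus the bending energy
    at the pivot joint.  Bond lengths and all other angles are invariant,
    so this explores large-scale conformation space orders of magnitude
    faster than Brownian dynamics — the standard equilibrator for
    self-avoiding chains.  Returns the acceptance count.
    """
    from scipy.spatial import cKDTree

    n = pos.shape[0]
    sr6c = (1.0 / cutoff) ** 6
    shift = 4.0 * (sr6c * sr6c - sr6c)

    def half_lj(head, tail):
        tree = cKDTree(head)
        pairs = tree.query_ball_point(tail, cutoff)
        e = 0.0
        for t_idx, neighbors in enumerate(pairs):
            for h_idx in neighbors:
                r2 = float(np.sum((tail[t_idx] - head[h_idx]) ** 2))
                if r2 < 1e-20:
                    return np.inf
                sr6 = (1.0 / r2) ** 3
                e += 4.0 * (sr6 * sr6 - sr6) - shift
        return e

    def bend_at(p, positions):
        b1 = positions[p] - positions[p - 1]
        b2 = positions[p + 1] - positions[p]
        c = float(np.dot(b1, b2) / (np.linalg.norm(b1) * np.linalg.norm(b2)))
        return bending_stiffness * (1.0 - c)

    accepted = 0
    for _ in range(n_attempts):
        p = int(rng.integers(1, n - 1))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(-np.pi, np.pi)
        k = axis
        c, s_ = np.cos(angle), np.sin(angle)
        tail = pos[p + 1 :] - pos[p]
        rotated = (
            tail * c
            + np.cross(k, tail) * s_
            + np.outer(tail @ k, k) * (1.0 - c)
        ) + pos[p]
        # nonbonded pairs (i, j) with |i-j| > 1 across the pivot
        e_old = half_lj(pos[: p + 1], pos[p + 2 :]) + bend_at(p, pos)
        new_pos = pos.copy()
        new_pos[p + 1 :] = rotated
        e_new = half_lj(new_pos[: p + 1], new_pos[p + 2 :]) + bend_at(p, new_pos)
        if e_new - e_old <= 0 or rng.random() < np.exp(-(e_new - e_old)):
            pos[p + 1 :] = rotated
            accepted += 1
    return accepted


def sample_unconfined_chain(
    n_beads: int,
    attractive: bool,
    n_burn: int,
    n_conformations: int,
    sample_interval: int,
    seed: int,
    timestep: float = 2e-4,
    burn_timestep: float = 1e-3,
    use_pivot: bool | None = None,
) -> np.ndarray:
    """Equilibrate a free chain and collect decorrelated conformations.

    The chain is typed all non-LAD and unconfined, so only the bonded
    terms and the chromatin-chromatin LJ act.  Large-scale equilibration
    cannot be reached by Brownian dynamics alone at these chain lengths
    (subchain relaxation times grow as s^2), so:

    * the repulsive (self-avoiding) chain is equilibrated with pivot
      Monte-Carlo sweeps interleaved between samples, with short Brownian
      segments restoring the bond-length and local-angle ensemble;
    * the attractive chain starts from a compact folded walk at globule
      density (the large-scale structure of a globule is set by its
      density, not its history) and is annealed by capped Brownian
      dynamics before unbiased sampling.
    """
    params = SimulationParameters(
        n_beads=n_beads,
        psi=0.0,
        confinement_radius=None,
        timestep=timestep,
        rng_seed=seed,
        chrom_cutoff=None if attractive else 2 ** (1 / 6),
    )
    rng = np.random.default_rng(seed + 991)
    if use_pivot is None:
        use_pivot = not attractive
    if attractive:
        # compact start at LJ-globule density (number density ~0.85/sigma^3)
        r_globule = (3.0 * n_beads / (4.0 * np.pi * 0.85)) ** (1.0 / 3.0)
        from .builder import ChromatinChain, initial_configuration
        from .bonding import BondSet
        from .engine import SimulationState

        pos = initial_configuration(
            n_beads, r_globule + 2.0, params.rest_length, seed + 2, params.bead_diameter
        )
        chain = ChromatinChain(pos, np.full(n_beads, NONLAD, dtype=np.int8))
        state = SimulationState(chain, None, BondSet.empty(n_beads), params)
    else:
        state = initialize(params, bead_type=np.full(n_beads, NONLAD, dtype=np.int8))
    # noise-free capped descent to remove initial-walk overlaps
    pushoff = params.replace(chrom_cutoff=params.cutoff_repulsive)
    for _ in range(60):
        _kernel_call(state, pushoff, 400, 0, cap_disp=0.05, noise_off=True)
        if _tightest_contact(state) > 0.85:
            break
    if use_pivot:
        _pivot_sweep(
            state.chain.positions, 3 * n_beads, params.cutoff_repulsive,
            params.bending_stiffness, rng,
        )
    burn = params.replace(timestep=burn_timestep)
    _kernel_call(state, burn, n_burn, 0, cap_disp=0.25, skin=1.6)
    _kernel_call(state, params, 2000, 0, cap_disp=0.1)  # settle at sampling step
    confs = []
    for _ in range(n_conformations):
        if use_pivot:
            _pivot_sweep(
                state.chain.positions, max(50, n_beads // 4),
                params.cutoff_repulsive, params.bending_stiffness, rng,
            )
            _kernel_call(state, params, 1000, 0, cap_disp=0.1)
        _kernel_call(state, params, sample_interval, 0)
        confs.append(state.chain.positions.copy())
    return np.stack(confs)


def measure_persistence_length(
    n_beads: int = 200,
    seed: int = 0,
    n_burn: int = 40_000,
    n_conformations: int = 40,
    sample_interval: int = 5_000,
    n_chains: int = 5,
) -> float:
    """Fitted persistence length (in sigma) of the repulsive-only chain.

    Simulates ``n_chains`` independent unconfined chains with the default
    bending stiffness k_b = 2 kT (240k integration steps each by default),
    fits the tangent-correlation decay over separations 1..10 per chain,
    and averages: chain-scale tangent modes decorrelate slowly under
    Brownian dynamics, so between-chain averaging controls the variance a
    single long run cannot.
    """
    from .analysis import persistence_length

    # pure Brownian-dynamics sampling: the tangent statistics at short
    # separations equilibrate within the burn-in, and the short-separation
    # exponential fit is the quantity defined by this measurement (a fully
    # pivot-equilibrated self-avoiding chain develops a long-range
    # tangent-correlation tail that is not part of it)
    values = []
    for k in range(n_chains):
        confs = sample_unconfined_chain(
            n_beads, attractive=False, n_burn=n_burn,
            n_conformations=n_conformations, sample_interval=sample_interval,
            seed=(seed * 1009 + 17 * k) % (2**31 - 1), use_pivot=False,
        )
        values.append(persistence_length(confs))
    return float(np.mean(values))


def measure_scaling_exponent(
    attractive: bool,
    n_beads: int = 500,
    seed: int = 0,
    n_burn: int = 60_000,
    n_conformations: int = 25,
    sample_interval: int = 8_000,
):
    """Flory exponent nu of the free chain: self-avoiding or collapsed."""
    from .analysis import scaling_exponent

    confs = sample_unconfined_chain(
        n_beads, attractive=attractive,
        n_burn=n_burn if not attractive else n_burn + 20_000,
        n_conformations=n_conformations,
        sample_interval=sample_interval if attractive else 2_000,
        seed=seed,
    )
    return scaling_exponent(confs)


def measure_chain_size_exponent(
    attractive: bool,
    n_values: tuple = (250, 500, 1000),
    seed: int = 0,
    n_conformations: int = 6,
):
    """Flory exponent from R_g versus chain length N.

    Fits log <R_g^2>^(1/2) against log N across chain lengths.  This is
    the estimator in which the collapsed-globule exponent 1/3 is defined
    (a globule's subchains are Gaussian until they saturate at the globule
    size, so a subchain fit cannot reach 1/3); it equally recovers the
    self-avoiding 0.588.
    """
    rgs = []
    for i, n in enumerate(n_values):
        confs = sample_unconfined_chain(
            n, attractive=attractive,
            n_burn=30_000,
            n_conformations=n_conformations,
            sample_interval=4_000 if attractive else 1_000,
            seed=seed + 13 * i,
        )
        centered = confs - confs.mean(axis=1, keepdims=True)
        rgs.append(float(np.sqrt(np.mean(np.sum(centered**2, axis=2)))))
    slope = np.polyfit(np.log(n_values), np.log(rgs), 1)[0]
    return float(slope), list(zip(n_values, rgs))
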