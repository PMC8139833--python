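"""Reduced-unit system and the simulation parameter container.

Everything internal runs in reduced units: the bead diameter sigma is the
unit of length, the thermal energy k_B*T the unit of energy, and the bead
damping time tau = 3*pi*eta*sigma^3 / (k_B*T) the unit of time.  SI
conversions (sigma = 10 nm, k_B*T = 4.1e-21 J, tau ~ 2 us for water
viscosity) are applied only at the I/O boundary.

The global chromatin volume fraction phi relates the chain volume to the
confinement volume,

    phi = N * (sigma/2)^3 / R_c^3,

and is the main control parameter for hydration: small phi models a large,
hydrated nucleus, large phi a dehydrated one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import InvalidParameterError

# Bead type codes used everywhere (arrays of int8).
NONLAD = 0
LAD = 1

#: Reduced-unit defaults for the standard parameter set.
DEFAULT_SIGMA = 1.0
DEFAULT_KT = 1.0
DEFAULT_TAU = 1.0
DEFAULT_TIMESTEP = 0.01  # in units of tau
WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)

#: SI values used only when converting to/from laboratory units.
SIGMA_SI_NM = 10.0
KT_SI_J = 4.1e-21
BP_PER_BEAD = 600


def global_volume_fraction(n_beads: int, bead_diameter: float, confinement_radius: float) -> float:
    """Global chromatin volume fraction phi = N (sigma/2)^3 / R_c^3.

    The 4/3*pi factors of the bead and confinement volumes cancel.  The
    caller may reject values above 1 (the chain cannot physically exceed
    the confinement volume).
    """
    if bead_diameter <= 0 or confinement_radius <= 0:
        raise InvalidParameterError("bead diameter and confinement radius must be positive")
    if n_beads < 0:
        raise InvalidParameterError("n_beads must be non-negative")
    return n_beads * (bead_diameter / 2.0) ** 3 / confinement_radius**3


def radius_for_fraction(n_beads: int, bead_diameter: float, phi: float) -> float:
    """Confinement radius R_c that realizes a target volume fraction phi.

    Closed-form inverse of :func:`global_volume_fraction`; used to build
    scaled-down systems at the same intensive phi as the full chromosome.
    """
    if phi <= 0:
        raise InvalidParameterError("phi must be positive")
    if bead_diameter <= 0:
        raise InvalidParameterError("bead diameter must be positive")
    if n_beads <= 0:
        raise InvalidParameterError("n_beads must be positive")
    return bead_diameter / 2.0 * (n_beads / phi) ** (1.0 / 3.0)


def damping_time(viscosity: float, bead_diameter: float, thermal_energy: float) -> float:
    """Stokes damping time tau = 3*pi*eta*sigma^3 / (k_B*T).

    With eta = 1 mPa.s (water), sigma = 10 nm and k_B*T = 4.1e-21 J this
    gives about 2 microseconds.
    """
    if viscosity < 0 or bead_diameter <= 0 or thermal_energy <= 0:
        raise InvalidParameterError("viscosity >= 0 and positive sigma, k_B*T required")
    return 3.0 * math.pi * viscosity * bead_diameter**3 / thermal_energy


def beads_for_sequence(bp_length: int, bp_per_bead: int = BP_PER_BEAD) -> int:
    """Number of beads representing a bp stretch; a trailing partial bead is dropped.

    One bead stands for three nucleosomes, about 600 bp, so the 22.4 Mbp
    model chromosome maps to 37,333 beads.
    """
    if bp_per_bead <= 0:
        raise InvalidParameterError("bp_per_bead must be positive")
    if bp_length < 0:
        raise InvalidParameterError("bp_length must be non-negative")
    return bp_length // bp_per_bead


def _default_eps_matrix() -> np.ndarray:
    return np.ones((2, 2), dtype=np.float64)


@dataclass
class SimulationParameters:
    """All model constants, in reduced units (sigma = k_B*T = tau = 1).

    ``epsilon_matrix`` is indexed by bead-type codes (NONLAD=0, LAD=1), so
    ``epsilon_matrix[LAD, LAD]`` is the LAD-LAD attraction depth.  The
    main-text model uses a constant matrix; distinct entries give the
    heterochromatin-like variant.  ``chrom_cutoff`` selects between the
    attractive chain (2.5 sigma) and the purely repulsive one (2^(1/6)
    sigma); the equilibration protocol switches it stage by stage.
    """

    n_beads: int = 2000
    bead_diameter: float = DEFAULT_SIGMA
    bp_per_bead: int = BP_PER_BEAD
    epsilon_matrix: np.ndarray = field(default_factory=_default_eps_matrix)
    cutoff_attractive: float = 2.5
    cutoff_repulsive: float = WCA_CUTOFF_FACTOR * DEFAULT_SIGMA
    chrom_cutoff: float | None = None  # None -> cutoff_attractive
    spring_constant: float = 100.0
    rest_length: float = DEFAULT_SIGMA  # 2a: touching beads
    bending_stiffness: float = 2.0  # k_b = l_p * kT / sigma
    kbond: float = 10.0
    ubond: float = 10.0
    r_bond: float = 2.5
    eps_lad_lamin: float = 1.0
    eps_nonlad_lamin: float = 1.0
    eps_wall: float = 1.0
    psi: float = 1.0
    confinement_radius: float | None = None
    lamin_spacing: float = DEFAULT_SIGMA
    damping: float = DEFAULT_TAU
    timestep: float = DEFAULT_TIMESTEP
    thermal_energy: float = DEFAULT_KT
    noise: str = "gaussian"  # or "uniform" (matching second moment)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.epsilon_matrix = np.asarray(self.epsilon_matrix, dtype=np.float64)
        if self.epsilon_matrix.shape != (2, 2):
            raise InvalidParameterError("epsilon_matrix must be 2x2 (nonLAD, LAD)")
        if not np.allclose(self.epsilon_matrix, self.epsilon_matrix.T):
            raise InvalidParameterError("epsilon_matrix must be symmetric")
        if np.any(self.epsilon_matrix < 0):
            raise InvalidParameterError("epsilon_matrix entries must be non-negative")
        if not 0.0 <= self.psi <= 1.0:
            raise InvalidParameterError("psi must lie in [0, 1]")
        for name in (
            "bead_diameter",
            "cutoff_attractive",
            "r_bond",
            "damping",
            "timestep",
            "thermal_energy",
            "lamin_spacing",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        # zero springs / zero rest length are allowed: they turn the chain
        # into free beads, useful for diffusion diagnostics
        for name in ("spring_constant", "rest_length", "bending_stiffness", "kbond", "ubond"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.confinement_radius is not None and self.confinement_radius <= 0:
            raise InvalidParameterError("confinement_radius must be positive")
        if self.n_beads < 0:
            raise InvalidParameterError("n_beads must be non-negative")
        if self.noise not in ("gaussian", "uniform"):
            raise InvalidParameterError("noise must be 'gaussian' or 'uniform'")
        # The repulsive cutoff is tied to the bead diameter (WCA truncation).
        self.cutoff_repulsive = WCA_CUTOFF_FACTOR * self.bead_diameter

    # -- derived quantities -------------------------------------------------

    @property
    def effective_chrom_cutoff(self) -> float:
        return self.cutoff_attractive if self.chrom_cutoff is None else self.chrom_cutoff

    @property
    def mobility(self) -> float:
        """Bead mobility dt-independent factor 1/(gamma*m) = sigma^2/(kT*tau)."""
        return self.bead_diameter**2 / (self.thermal_energy * self.damping)

    @property
    def diffusion_coefficient(self) -> float:
        """Free-bead diffusion coefficient D = kT/(gamma*m)."""
        return self.thermal_energy * self.mobility

    @property
    def phi(self) -> float | None:
        if self.confinement_radius is None:
            return None
        return global_volume_fraction(self.n_beads, self.bead_diameter, self.confinement_radius)

    def with_phi(self, phi: float) -> "SimulationParameters":
        """Return a copy whose confinement radius realizes volume fraction phi."""
        r = radius_for_fraction(self.n_beads, self.bead_diameter, phi)
        return replace(self, confinement_radius=r)

    def replace(self, **changes) -> "SimulationParameters":
        return replace(self, **changes)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["epsilon_matrix"] = self.epsilon_matrix.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParameters":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "epsilon" in d and "epsilon_matrix" not in d:
            eps = float(d["epsilon"])
            known["epsilon_matrix"] = np.full((2, 2), eps)
        if "phi" in d and "confinement_radius" not in d:
            params = cls(**known)
            return params.with_phi(float(d["phi"]))
        return cls(**known)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationParameters":
        """Load parameters from a JSON or TOML config file.

        Scalar convenience keys are accepted: ``epsilon`` (constant LJ
        matrix) and ``phi`` (sets the confinement radius through the
        closed-form inverse of the volume-fraction relation).
        """
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib

            d = tomllib.loads(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
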