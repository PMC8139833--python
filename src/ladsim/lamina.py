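"""Static lamin-bead shell on the confinement sphere.

The nuclear lamina is represented two ways at once, following the energy
decomposition of the model: (i) a continuum hard wall acting on every
chromatin bead through a purely repulsive potential of the gap
``g = R_c - |r|``, and (ii) a discrete set of static lamin beads on the
sphere that carry the LAD/non-LAD Lennard-Jones interactions and the
dynamic LAD-lamina bonds.  Lamin beads never move and do not interact
with each other.

The bead lattice is a golden-angle (Fibonacci) covering: near-uniform,
deterministic, with one bead per ``spacing**2`` of surface area so that
every LAD bead close to the wall has a lamin bead within bonding range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import EscapedBeadError, InvalidParameterError


@dataclass(frozen=True)
class LaminaShell:
    """Static lamin bead coordinates on the confinement sphere."""

    lamin_positions: np.ndarray
    confinement_radius: float
    surface_spacing: float

    @property
    def n_lamin(self) -> int:
        return self.lamin_positions.shape[0]


def build_shell(confinement_radius: float, surface_spacing: float = 1.0) -> LaminaShell:
    """Place ~4*pi*R_c^2/spacing^2 lamin beads on a Fibonacci spherical lattice.

    The construction is deterministic.  Every bead sits exactly on the
    sphere of radius ``R_c``.
    """
    if surface_spacing <= 0:
        raise InvalidParameterError("surface_spacing must be positive")
    if confinement_radius <= surface_spacing:
        raise InvalidParameterError("confinement radius must exceed the lamin spacing")
    m = max(4, round(4.0 * math.pi * confinement_radius**2 / surface_spacing**2))
    k = np.arange(m, dtype=np.float64)
    z = 1.0 - (2.0 * k + 1.0) / m
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    theta = golden * k
    pts = np.empty((m, 3))
    pts[:, 0] = rho * np.cos(theta)
    pts[:, 1] = rho * np.sin(theta)
    pts[:, 2] = z
    pts *= confinement_radius
    return LaminaShell(np.ascontiguousarray(pts), float(confinement_radius), float(surface_spacing))


def wall_gap(position: np.ndarray, confinement_radius: float) -> float:
    """Distance from a bead to its nearest point on the spherical wall.

    Raises :class:`EscapedBeadError` if the bead lies on or outside the
    sphere — the signature of an integrator blow-up.
    """
    r = float(np.linalg.norm(np.asarray(position, dtype=np.float64)))
    if r >= confinement_radius:
        raise EscapedBeadError(f"bead at radius {r:.4g} >= R_c = {confinement_radius:.4g}")
    return confinement_radius - r
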