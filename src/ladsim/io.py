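"""Text output formats: XYZ / LAMMPS-dump trajectories, thermo CSV,
label CSV, classification JSON.

Every file carries a header comment with the config hash and seed so
reruns are traceable; rewriting with an identical config is bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

ATOM_LABELS = {0: "NLD", 1: "LAD"}
LAMIN_LABEL = "LAM"

THERMO_COLUMNS = [
    "step",
    "stretch",
    "bend",
    "chrom_lj",
    "wall",
    "lamin_lj",
    "bond",
    "total",
    "rg",
    "bond_count",
]


def _header_line(params, prefix: str = "#") -> str:
    return f"{prefix} ladsim config={params.config_hash()} seed={params.rng_seed}"


def write_xyz(path, trajectory, bead_type, params, shell=None) -> None:
    """XYZ trajectory with bead type as the atom label (LAD/NLD/LAM).

    When a shell is given its static lamin beads are appended to every
    frame so molecular viewers render the envelope.
    """
    path = Path(path)
    lam = shell.lamin_positions if shell is not None else np.empty((0, 3))
    with path.open("w") as fh:
        for step, pos, _, _ in trajectory.frames:
            fh.write(f"{pos.shape[0] + lam.shape[0]}\n")
            fh.write(f"step={step} {_header_line(params, prefix='')}\n")
            for i in range(pos.shape[0]):
                label = ATOM_LABELS[int(bead_type[i])]
                fh.write(f"{label} {pos[i, 0]:.6f} {pos[i, 1]:.6f} {pos[i, 2]:.6f}\n")
            for j in range(lam.shape[0]):
                fh.write(f"{LAMIN_LABEL} {lam[j, 0]:.6f} {lam[j, 1]:.6f} {lam[j, 2]:.6f}\n")


def write_lammps_dump(path, trajectory, bead_type, params, shell=None) -> None:
    """LAMMPS-dump-style text trajectory (id, type, x, y, z per frame).

    Types: 1 = non-LAD, 2 = LAD, 3 = lamin.
    """
    path = Path(path)
    lam = shell.lamin_positions if shell is not None else np.empty((0, 3))
    box = params.confinement_radius or float(np.abs(trajectory.frames[0][1]).max() + 1)
    with path.open("w") as fh:
        for step, pos, _, _ in trajectory.frames:
            n_total = pos.shape[0] + lam.shape[0]
            fh.write("ITEM: TIMESTEP\n%d\n" % step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % n_total)
            fh.write("ITEM: BOX BOUNDS ff ff ff\n")
            for _ in range(3):
                fh.write(f"{-box:.6f} {box:.6f}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            for i in range(pos.shape[0]):
                fh.write(
                    f"{i + 1} {int(bead_type[i]) + 1} "
                    f"{pos[i, 0]:.6f} {pos[i, 1]:.6f} {pos[i, 2]:.6f}\n"
                )
            for j in range(lam.shape[0]):
                fh.write(
                    f"{pos.shape[0] + j + 1} 3 {lam[j, 0]:.6f} {lam[j, 1]:.6f} {lam[j, 2]:.6f}\n"
                )


def write_thermo_csv(path, trajectory, params) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_line(params) + "\n")
        fh.write(",".join(THERMO_COLUMNS) + "\n")
        for step, pos, bond_count, eb in trajectory.frames:
            centered = pos - pos.mean(axis=0)
            rg = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
            vals = [step, *eb.as_tuple(), eb.total, rg, bond_count]
            fh.write(",".join(f"{v:.10g}" if isinstance(v, float) else str(v) for v in vals) + "\n")


def write_labels_csv(path, bead_type, params) -> None:
    """Two-column per-bead type export (bead_index, type)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_line(params) + "\n")
        fh.write("bead_index,type\n")
        for i, t in enumerate(bead_type):
            fh.write(f"{i},{ATOM_LABELS[int(t)]}\n")


def write_profile_csv(path, profile, params) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_line(params) + "\n")
        fh.write("r_over_Rc,phi_local\n")
        for r, p in zip(profile.shell_centers, profile.phi_local):
            fh.write(f"{r:.6f},{p:.8g}\n")


def write_classification_json(path, call, params, extra: dict | None = None) -> None:
    from .analysis import ClassificationThresholds

    record = {
        "mode": call.mode,
        "com_offset": call.com_offset,
        "evidence": call.evidence,
        "thresholds": ClassificationThresholds().__dict__,
        "config": params.config_hash(),
        "seed": params.rng_seed,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=float) + "\n")


def write_contact_map(path, matrix, params, sparse: bool = False) -> None:
    """Contact map as dense text matrix or sparse COO triplets."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_line(params) + "\n")
        if sparse:
            fh.write("i,j,frequency\n")
            nz = np.argwhere(matrix > 0)
            for i, j in nz:
                if i <= j:
                    fh.write(f"{i},{j},{matrix[i, j]:.6g}\n")
        else:
            for row in matrix:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def write_contact_probability_csv(path, s, p_of_s, params) -> None:
    """P(s): mean contact frequency versus contour separation."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_line(params) + "\n")
        fh.write("separation,contact_probability\n")
        for si, pi in zip(s, p_of_s):
            fh.write(f"{si},{pi:.8g}\n")


def write_bond_events_csv(path, trajectory, params) -> None:
    """Bond formation/breaking events between consecutive sampled frames.

    Events are derived by diffing the bond-partner snapshots stored with
    each frame, so their timing is resolved to the sampling interval, not
    the integration step.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_line(params) + "\n")
        fh.write("step,event,lad_index,lamin_index\n")
        prev = None
        snapshots = trajectory.partner_frames or []
        for frame, partner in zip(trajectory.frames, snapshots):
            step = frame[0]
            if prev is not None:
                changed = np.flatnonzero(partner != prev)
                for i in changed:
                    if prev[i] >= 0:
                        fh.write(f"{step},break,{i},{prev[i]}\n")
                    if partner[i] >= 0:
                        fh.write(f"{step},form,{i},{partner[i]}\n")
            prev = partner
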