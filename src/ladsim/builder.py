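"""Chain construction: LAD annotation handling, bead typing, bond
eligibility, and the initial spatial configuration.

The model chromosome is a bead-spring chain whose beads are typed LAD or
non-LAD.  Types come either from a BED-like annotation (0-based half-open
bp intervals, mapped to beads at 600 bp/bead with a majority-overlap rule)
or from a synthetic generator that reproduces the two statistics of the
Drosophila ChrX LAD pattern it emulates: 48% LAD content with a mean
domain size of 90 kbp (150 beads).

A fraction psi of the LAD beads is flagged "bondable": only those may form
dynamic bonds with lamin beads.  This models a limited pool of tethering
proteins (LBR-like) rather than a property of the chromatin itself.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    AnnotationParseError,
    InfeasibleGeometryError,
    InvalidParameterError,
)
from .units import LAD, NONLAD, BP_PER_BEAD


@dataclass(frozen=True)
class LadAnnotation:
    """Sorted, merged, half-open LAD intervals on one chromosome."""

    intervals: tuple[tuple[int, int], ...]
    chromosome_length_bp: int

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.intervals:
            if not 0 <= start < end:
                raise InvalidParameterError(f"bad interval [{start}, {end})")
            if start < prev_end:
                raise InvalidParameterError("intervals must be sorted and disjoint")
            prev_end = end
        if self.intervals and self.intervals[-1][1] > self.chromosome_length_bp:
            raise InvalidParameterError("interval extends past chromosome end")

    @property
    def lad_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)


def read_lad_intervals(annotation_stream, chromosome_length_bp: int | None = None) -> LadAnnotation:
    """Parse a BED-like stream (``chrom<TAB>start<TAB>end``) into a LadAnnotation.

    Coordinates are 0-based half-open.  Overlapping or touching intervals
    are merged; the output is sorted.  Lines starting with ``#``, ``track``
    or ``browser`` and blank lines are skipped.
    """
    if isinstance(annotation_stream, str):
        annotation_stream = _io.StringIO(annotation_stream)
    raw: list[tuple[int, int]] = []
    for lineno, line in enumerate(annotation_stream, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            fields = line.split()
        if len(fields) < 3:
            raise AnnotationParseError("expected at least 3 columns", lineno)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise AnnotationParseError("non-numeric start/end", lineno) from None
        if end <= start or start < 0:
            raise AnnotationParseError(f"bad interval [{start}, {end})", lineno)
        raw.append((start, end))
    raw.sort()
    merged: list[list[int]] = []
    for start, end in raw:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    intervals = tuple((s, e) for s, e in merged)
    if chromosome_length_bp is None:
        chromosome_length_bp = intervals[-1][1] if intervals else 0
    return LadAnnotation(intervals, chromosome_length_bp)


def intervals_to_bead_labels(
    annotation: LadAnnotation, n_beads: int, bp_per_bead: int = BP_PER_BEAD
) -> np.ndarray:
    """Map bp intervals to per-bead LAD/non-LAD labels.

    Bead ``i`` covers ``[i*bp_per_bead, (i+1)*bp_per_bead)`` and is labeled
    LAD iff at least half of its bp lie inside LAD intervals (ties label
    LAD).  Beads past the end of the annotation are non-LAD.
    """
    if bp_per_bead <= 0:
        raise InvalidParameterError("bp_per_bead must be positive")
    labels = np.full(n_beads, NONLAD, dtype=np.int8)
    if not annotation.intervals:
        return labels
    overlap = np.zeros(n_beads, dtype=np.int64)
    for start, end in annotation.intervals:
        first = start // bp_per_bead
        last = min(n_beads - 1, (end - 1) // bp_per_bead)
        for i in range(first, last + 1):
            b0, b1 = i * bp_per_bead, (i + 1) * bp_per_bead
            overlap[i] += max(0, min(end, b1) - max(start, b0))
    labels[overlap * 2 >= bp_per_bead] = LAD
    return labels


def synthesize_lad_pattern(
    n_beads: int, lad_fraction: float, mean_domain_beads: int, seed: int
) -> np.ndarray:
    """Random alternating LAD/non-LAD block pattern.

    LAD block lengths are geometric with mean ``mean_domain_beads``;
    non-LAD blocks are geometric with mean ``mean_domain_beads*(1-f)/f``,
    so the realized LAD fraction converges to ``lad_fraction`` for long
    chains while the mean LAD domain size stays at the configured value.
    """
    if not 0.0 <= lad_fraction <= 1.0:
        raise InvalidParameterError("lad_fraction must lie in [0, 1]")
    if mean_domain_beads < 1:
        raise InvalidParameterError("mean_domain_beads must be >= 1")
    labels = np.empty(n_beads, dtype=np.int8)
    if lad_fraction == 0.0:
        labels[:] = NONLAD
        return labels
    if lad_fraction == 1.0:
        labels[:] = LAD
        return labels
    rng = np.random.default_rng(seed)
    p_lad = 1.0 / mean_domain_beads
    mean_nonlad = mean_domain_beads * (1.0 - lad_fraction) / lad_fraction
    p_non = min(1.0, 1.0 / mean_nonlad)
    pos = 0
    current = LAD if rng.random() < lad_fraction else NONLAD
    while pos < n_beads:
        p = p_lad if current == LAD else p_non
        block = rng.geometric(p)
        end = min(n_beads, pos + block)
        labels[pos:end] = current
        pos = end
        current = NONLAD if current == LAD else LAD
    return labels


def select_bondable(bead_type: np.ndarray, psi: float, seed: int) -> np.ndarray:
    """Flag exactly round(psi * n_LAD) LAD beads as bond-eligible.

    The subset is drawn uniformly at random; non-LAD beads are never
    flagged.  Repeated calls with different seeds flag different subsets
    of identical size.
    """
    if not 0.0 <= psi <= 1.0:
        raise InvalidParameterError("psi must lie in [0, 1]")
    bead_type = np.asarray(bead_type)
    bondable = np.zeros(bead_type.shape[0], dtype=bool)
    lad_idx = np.flatnonzero(bead_type == LAD)
    k = int(np.floor(psi * lad_idx.size + 0.5))
    if k > 0:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(lad_idx, size=k, replace=False)
        bondable[chosen] = True
    return bondable


def initial_configuration(
    n_beads: int,
    confinement_radius: float | None,
    rest_length: float,
    seed: int,
    bead_diameter: float = 1.0,
) -> np.ndarray:
    """Compact random-walk initial configuration centered in the nucleus.

    A self-intersecting random walk with fixed step ``rest_length`` is
    folded into the sphere of radius ``R_c - sigma`` by resampling any step
    that would leave it, then translated so the center of mass sits at the
    origin.  Bead overlaps are tolerated here and removed later by the
    soft push-off stage of the equilibration protocol.
    """
    if n_beads < 1:
        raise InvalidParameterError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    if confinement_radius is None:
        pos = _random_walk(rng, n_beads, rest_length, None)
        return pos - pos.mean(axis=0)
    if n_beads * (bead_diameter / 2.0) ** 3 >= confinement_radius**3:
        raise InfeasibleGeometryError(
            f"{n_beads} beads of diameter {bead_diameter} cannot fit in radius "
            f"{confinement_radius}"
        )
    limit = confinement_radius - bead_diameter
    if limit <= rest_length:
        raise InfeasibleGeometryError("confinement too tight for the rest length")
    # Fold inside 90% of the allowed radius so the post-hoc center-of-mass
    # shift cannot push any bead outside R_c - sigma.
    for attempt in range(20):
        pos = _random_walk(rng, n_beads, rest_length, 0.9 * limit)
        com = pos.mean(axis=0)
        pos = pos - com
        if np.max(np.linalg.norm(pos, axis=1)) <= limit:
            return pos
    raise InfeasibleGeometryError("could not center the initial walk inside the sphere")


def _random_walk(
    rng: np.random.Generator, n: int, step: float, fold_radius: float | None
) -> np.ndarray:
    pos = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(1000):
            v = rng.normal(size=3)
            norm = np.linalg.norm(v)
            if norm < 1e-12:
                continue
            cand = pos[i - 1] + step * v / norm
            if fold_radius is None or np.dot(cand, cand) <= fold_radius**2:
                pos[i] = cand
                break
        else:  # pragma: no cover - essentially impossible geometrically
            raise InfeasibleGeometryError("random walk could not stay inside the sphere")
    return pos


@dataclass
class ChromatinChain:
    """Bead positions, types, and bond eligibility of the model chromosome."""

    positions: np.ndarray
    bead_type: np.ndarray
    bondable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.bead_type = np.ascontiguousarray(self.bead_type, dtype=np.int8)
        if self.bondable is None:
            self.bondable = np.zeros(self.positions.shape[0], dtype=bool)
        self.bondable = np.ascontiguousarray(self.bondable, dtype=bool)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3):
            raise InvalidParameterError("positions must be (N, 3)")
        if self.bead_type.shape[0] != n or self.bondable.shape[0] != n:
            raise InvalidParameterError("per-bead arrays must all have length N")
        if np.any(self.bondable & (self.bead_type != LAD)):
            raise InvalidParameterError("only LAD beads may be bondable")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be finite")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_lad(self) -> int:
        return int(np.sum(self.bead_type == LAD))

    def radius_of_gyration(self) -> float:
        centered = self.positions - self.positions.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def build_chain(params, bead_type: np.ndarray | None = None, seed: int | None = None) -> ChromatinChain:
    """Assemble a ChromatinChain from parameters: types, eligibility, positions.

    When no explicit type vector is given, the synthetic LAD pattern
    generator is used with the ChrX-like defaults (48% LAD, 150-bead mean
    domain).
    """
    seed = params.rng_seed if seed is None else seed
    if bead_type is None:
        bead_type = synthesize_lad_pattern(params.n_beads, 0.48, 150, seed)
    bondable = select_bondable(bead_type, params.psi, seed + 1)
    positions = initial_configuration(
        params.n_beads,
        params.confinement_radius,
        params.rest_length,
        seed + 2,
        params.bead_diameter,
    )
    return ChromatinChain(positions, bead_type, bondable)
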