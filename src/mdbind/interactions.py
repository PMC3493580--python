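"""Geometric hydrogen-bond occurrence and ring-stacking descriptors.

H-bonds follow the common geometric criterion (donor–acceptor distance and
hydrogen–donor–acceptor angle; 0.35 nm / 30° by default, the widely used
default of the GROMACS analysis tools — configurable).

A π-stacking contact between two aromatic rings is characterised per frame
by three descriptors:

* ``r`` — centroid–centroid distance (nm);
* ``φ`` — elevation of the centroid–centroid unit vector over the FIRST
  ring's plane, so two perfectly facing rings give φ = 90° and coplanar
  side-by-side rings φ = 0° (the first ring is the reference — for a
  receptor His-imidazole contact, the imidazole);
* ``Ψ`` — angle between the two ring normals folded into [0°, 90°],
  0° meaning perfect parallelism.

An interaction counts as "formed" inside a configurable (r, φ, Ψ) box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegeneratePlaneError, ValidationError
from .fluctuation import BlockErrorEstimate, block_standard_error
from .trajectory_io import Trajectory

__all__ = [
    "HBondCriterion",
    "RingDefinition",
    "StackingSeries",
    "StackingThresholds",
    "hbond_count",
    "ring_plane",
    "stacking_series",
    "stacking_occupancy",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond cutoffs: D–A distance (nm) and H–D–A angle (deg)."""

    max_da_distance: float = 0.35
    max_hda_angle: float = 30.0

    def __post_init__(self):
        if self.max_da_distance <= 0 or self.max_hda_angle <= 0:
            raise ValidationError("criterion cutoffs must be positive")


@dataclass(frozen=True)
class RingDefinition:
    """Atom indices (≥ 3) spanning one ring, with a label for reporting."""

    atom_indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.atom_indices)
        if len(idx) < 3:
            raise ValidationError("a ring needs at least 3 atoms")
        if len(set(idx)) != len(idx):
            raise ValidationError("ring atom indices must be unique")
        object.__setattr__(self, "atom_indices", idx)


@dataclass
class StackingSeries:
    """Per-frame (r, φ, Ψ) descriptors of one ring pair."""

    r: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        n = self.r.size
        if self.phi.size != n or self.psi.size != n:
            raise ValidationError("r, phi, psi must have equal lengths")
        if np.any(self.r <= 0):
            raise ValidationError("r must be positive")
        for name, arr in (("phi", self.phi), ("psi", self.psi)):
            if np.any((arr < -1e-9) | (arr > 90 + 1e-9)):
                raise ValidationError(f"{name} must lie in [0, 90] degrees")

    @property
    def n_frames(self) -> int:
        return self.r.size


@dataclass(frozen=True)
class StackingThresholds:
    """The (r, φ, Ψ) box inside which a stacking contact counts as formed.

    The defaults (r ≤ 0.55 nm, φ ≥ 60°, Ψ ≤ 30°) delimit a near-face-to-face
    geometry; they are analysis choices, always reported alongside results.
    """

    r_max: float = 0.55
    phi_min: float = 60.0
    psi_max: float = 30.0


def hbond_count(traj: Trajectory, donors, acceptors,
                criterion: HBondCriterion = HBondCriterion()):
    """Count geometric H-bonds per frame over all donor/acceptor triples.

    ``donors`` is a list of ``(donor_index, hydrogen_index)`` pairs,
    ``acceptors`` a list of acceptor indices.  A triple is bonded in a frame
    iff |D−A| ≤ the distance cutoff and the angle between D→H and D→A is ≤
    the angle cutoff.  Returns ``(per-frame counts,
    BlockErrorEstimate of the mean count)``.
    """
    donors = [(int(d), int(h)) for d, h in donors]
    acceptors = [int(a) for a in acceptors]
    n = traj.n_atoms
    for d, h in donors:
        if not (0 <= d < n) or not (0 <= h < n):
            raise ValidationError(f"donor pair ({d}, {h}) out of range")
        if d == h:
            raise ValidationError(f"donor {d} lacks a distinct hydrogen")
    for a in acceptors:
        if not (0 <= a < n):
            raise ValidationError(f"acceptor {a} out of range")
    if not donors or not acceptors:
        raise ValidationError("need at least one donor pair and one acceptor")

    X = traj.coordinates
    cos_cut = np.cos(np.deg2rad(criterion.max_hda_angle))
    counts = np.zeros(traj.n_frames, dtype=int)
    for d, h in donors:
        dh = X[:, h, :] - X[:, d, :]
        dh_norm = np.linalg.norm(dh, axis=1)
        for a in acceptors:
            if a == d or a == h:
                continue
            da = X[:, a, :] - X[:, d, :]
            dist = np.linalg.norm(da, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (dh * da).sum(axis=1) / (dh_norm * dist)
            ok = (dist <= criterion.max_da_distance) & (cosang >= cos_cut)
            counts += ok.astype(int)
    est = block_standard_error(counts.astype(float), n_blocks=3) \
        if traj.n_frames >= 3 else BlockErrorEstimate(float(counts.mean()), 0.0, 2)
    return counts, est


def ring_plane(frame: np.ndarray, ring: RingDefinition):
    """Centroid and least-squares plane normal of a ring in one frame.

    The normal is the smallest principal axis of the ring-atom scatter
    (sign-free: callers take |·| where orientation matters).  Collinear
    atoms raise :class:`DegeneratePlaneError`.
    """
    pts = np.asarray(frame, dtype=float)[list(ring.atom_indices), :]
    center = pts.mean(axis=0)
    centered = pts - center
    _, s, Vt = np.linalg.svd(centered)
    if s[1] < 1e-10:
        raise DegeneratePlaneError(
            f"ring {ring.label or ring.atom_indices} atoms are collinear"
        )
    return center, Vt[2]


def stacking_series(traj: Trajectory, ring_a: RingDefinition,
                    ring_b: RingDefinition) -> StackingSeries:
    """Per-frame (r, φ, Ψ) between two rings; ring A provides the plane.

    r = |c_B − c_A|; φ = 90° − arccos(|u·n_A|) with u the centroid–centroid
    unit vector (so u ∥ n_A ⇒ φ = 90°, u in plane A ⇒ φ = 0°);
    Ψ = arccos(|n_A·n_B|) ∈ [0°, 90°].  Coincident centroids
    (r < 1e-6 nm) make the geometry undefined for that frame and raise.
    """
    n_atoms = traj.n_atoms
    for ring in (ring_a, ring_b):
        if max(ring.atom_indices) >= n_atoms or min(ring.atom_indices) < 0:
            raise ValidationError(
                f"ring {ring.label or ring.atom_indices} index out of range"
            )
    r = np.empty(traj.n_frames)
    phi = np.empty(traj.n_frames)
    psi = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        ca, na = ring_plane(frame, ring_a)
        cb, nb = ring_plane(frame, ring_b)
        v = cb - ca
        dist = np.linalg.norm(v)
        if dist < 1e-6:
            raise ValidationError(
                f"frame {f}: ring centroids coincide (r < 1e-6 nm); "
                "stacking geometry undefined"
            )
        u = v / dist
        r[f] = dist
        phi[f] = 90.0 - np.rad2deg(np.arccos(np.clip(abs(u @ na), 0.0, 1.0)))
        psi[f] = np.rad2deg(np.arccos(np.clip(abs(na @ nb), 0.0, 1.0)))
    return StackingSeries(r=r, phi=phi, psi=psi)


def stacking_occupancy(series: StackingSeries,
                       thresholds: StackingThresholds = StackingThresholds()
                       ) -> float:
    """Fraction of frames with the stacking contact formed (inside the box)."""
    if series.n_frames == 0:
        raise ValidationError("empty stacking series")
    formed = ((series.r <= thresholds.r_max)
              & (series.phi >= thresholds.phi_min)
              & (series.psi <= thresholds.psi_max))
    return float(formed.mean())
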