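"""Synthetic trajectories and λ-coupling samples with planted, known structure.

Every generator here is the oracle half of a module pair: the statistical or
geometric property it plants is exactly what the corresponding analysis
operation is supposed to recover.

* :func:`gen_gaussian_traj` — Gaussian positional fluctuations around a mean
  structure with a planted low-rank covariance (known eigenpairs).
* :func:`gen_two_state_loop` — open/closed two-basin motion of a loop, with
  the per-frame state labels returned for membership checks.
* :func:`gen_ring_pair_series` — two aromatic rings placed so their centroid
  distance r, elevation angle φ and inter-normal angle Ψ follow a prescribed
  per-frame schedule exactly.
* :func:`gen_hbond_series` — a donor/hydrogen/acceptor triple whose geometry
  satisfies the default H-bond criterion in exactly a planted fraction of
  frames.
* :func:`gen_ti_samples` — ∂H/∂λ samples from a harmonic λ-coupled model
  whose free-energy difference has the closed form (RT/2)·ln(k2/k1).

All generators are bit-reproducible functions of their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .trajectory_io import Atom, Trajectory

R_KJ_PER_MOL_K = 8.314462618e-3  # kJ/(mol·K)

__all__ = [
    "PlantedMode",
    "HarmonicTIModel",
    "rigid_body_modes",
    "internal_mode_basis",
    "gen_gaussian_traj",
    "gen_two_state_loop",
    "gen_ring_pair_series",
    "gen_hbond_series",
    "gen_ti_samples",
]


@dataclass(frozen=True)
class PlantedMode:
    """A collective-motion direction (unit 3N-vector) with its variance (nm²)."""

    direction: np.ndarray
    variance: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float).ravel()
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-10:
            raise ValidationError(f"mode direction must be a unit vector (|d|={norm})")
        if self.variance < 0:
            raise ValidationError("mode variance must be ≥ 0")
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class HarmonicTIModel:
    """Harmonic λ-coupling k(λ) = (1−λ)·k1 + λ·k2 with analytic ΔF.

    Force constants in kJ/(mol·nm²), temperature in K.  The exact free-energy
    difference between the λ=0 and λ=1 states is (RT/2)·ln(k2/k1) per degree
    of freedom.
    """

    k1: float
    k2: float
    temperature: float = 300.0

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValidationError("force constants must be positive")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")

    def k(self, lam: float) -> float:
        return (1.0 - lam) * self.k1 + lam * self.k2

    @property
    def exact_delta_f(self) -> float:
        """Closed-form ΔF in kJ/mol."""
        rt = R_KJ_PER_MOL_K * self.temperature
        return 0.5 * rt * np.log(self.k2 / self.k1)


def _chain_atoms(n_atoms: int, name: str = "CA", resname: str = "ALA",
                 chain: str = "A", element: str = "C") -> list[Atom]:
    return [
        Atom(serial=i + 1, name=name, residue_name=resname,
             residue_id=i + 1, chain=chain, element=element)
        for i in range(n_atoms)
    ]


def _chain_mean_structure(n_atoms: int) -> np.ndarray:
    """A deterministic, non-degenerate pseudo-Cα arrangement (nm).

    A gentle helix keeps the atoms non-collinear so rigid-body fits are
    well conditioned.
    """
    i = np.arange(n_atoms, dtype=float)
    return np.column_stack([
        0.23 * np.cos(i * 0.6),
        0.23 * np.sin(i * 0.6),
        0.15 * i,
    ])


def rigid_body_modes(structure: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N × 6) of rigid translations/rotations at a structure.

    Useful for planting *internal* collective modes: a displacement with a
    rigid-body component is (partly) absorbed by trajectory superposition,
    so covariance analysis can only ever recover its internal part.
    """
    structure = np.asarray(structure, dtype=float)
    n = structure.shape[0]
    centered = structure - structure.mean(axis=0)
    cols = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        cols.append(t.ravel())
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        cols.append(np.cross(omega, centered).ravel())
    Q, _ = np.linalg.qr(np.column_stack(cols))
    return Q


def internal_mode_basis(n_atoms: int, n_modes: int, seed: int,
                        mean_structure: np.ndarray | None = None) -> np.ndarray:
    """Random orthonormal 3N directions orthogonal to all rigid-body modes.

    These are valid planted directions for :func:`gen_gaussian_traj` and
    :func:`gen_two_state_loop` whose amplitudes survive superposition intact.
    Returns a (3N, n_modes) matrix with orthonormal columns.
    """
    mean = (_chain_mean_structure(n_atoms) if mean_structure is None
            else np.asarray(mean_structure, dtype=float))
    rigid = rigid_body_modes(mean)
    rng = np.random.default_rng(seed)
    G = rng.normal(size=(3 * n_atoms, n_modes))
    G -= rigid @ (rigid.T @ G)
    Q, _ = np.linalg.qr(G)
    return Q[:, :n_modes]


def gen_gaussian_traj(n_atoms: int, modes: list[PlantedMode], iso_noise: float,
                      n_frames: int, seed: int,
                      mean_structure: np.ndarray | None = None) -> Trajectory:
    """Gaussian fluctuations with a planted low-rank covariance.

    Each frame is ``mean + Σ_k a_k · direction_k + ε`` with
    ``a_k ~ N(0, variance_k)`` and isotropic coordinate noise of variance
    ``iso_noise`` (nm²).  The population covariance therefore has eigenvalue
    ``variance_k + iso_noise`` along each planted direction and ``iso_noise``
    elsewhere.
    """
    if n_frames < 2:
        raise ValidationError("need at least 2 frames")
    if iso_noise < 0:
        raise ValidationError("iso_noise must be ≥ 0")
    dirs = [m.direction for m in modes]
    for d in dirs:
        if d.size != 3 * n_atoms:
            raise ValidationError("mode direction length must be 3·n_atoms")
    for i in range(len(dirs)):
        for j in range(i + 1, len(dirs)):
            if abs(np.dot(dirs[i], dirs[j])) > 1e-8:
                raise ValidationError(f"modes {i} and {j} are not orthogonal")

    mean = (_chain_mean_structure(n_atoms) if mean_structure is None
            else np.asarray(mean_structure, dtype=float))
    rng = np.random.default_rng(seed)
    disp = np.zeros((n_frames, 3 * n_atoms))
    for m in modes:
        a = rng.normal(0.0, np.sqrt(m.variance), size=n_frames)
        disp += a[:, None] * m.direction[None, :]
    if iso_noise > 0:
        disp += rng.normal(0.0, np.sqrt(iso_noise), size=(n_frames, 3 * n_atoms))
    coords = mean[None, :, :] + disp.reshape(n_frames, n_atoms, 3)
    return Trajectory(atoms=_chain_atoms(n_atoms), coordinates=coords)


def gen_two_state_loop(n_atoms: int, displacement: np.ndarray, open_fraction: float,
                       n_frames: int, jitter: float, seed: int):
    """Two-basin (open/closed) motion with returned state labels.

    Frames are drawn from two jittered centres separated by ``displacement``
    (a 3N-vector, nm); a frame is "open" (label 1) with probability
    ``open_fraction``.  Jitter is the isotropic coordinate variance (nm²).

    Returns ``(trajectory, labels)`` where ``labels`` is an int array with 1
    for the displaced (open) basin.
    """
    if not 0.0 < open_fraction < 1.0:
        raise ValidationError("open_fraction must lie strictly between 0 and 1")
    disp = np.asarray(displacement, dtype=float).ravel()
    if disp.size != 3 * n_atoms:
        raise ValidationError("displacement length must be 3·n_atoms")
    if np.linalg.norm(disp) == 0.0:
        raise ValidationError("two basins require a nonzero displacement")
    if jitter < 0:
        raise ValidationError("jitter must be ≥ 0")

    rng = np.random.default_rng(seed)
    labels = (rng.random(n_frames) < open_fraction).astype(int)
    base = _chain_mean_structure(n_atoms).reshape(-1)
    coords = np.tile(base, (n_frames, 1))
    coords[labels == 1] += disp
    if jitter > 0:
        coords += rng.normal(0.0, np.sqrt(jitter), size=coords.shape)
    traj = Trajectory(atoms=_chain_atoms(n_atoms),
                      coordinates=coords.reshape(n_frames, n_atoms, 3))
    return traj, labels


def _regular_polygon(n_sides: int, side: float) -> np.ndarray:
    """Vertices of a regular polygon in the xy-plane, centred at the origin."""
    radius = side / (2.0 * np.sin(np.pi / n_sides))
    ang = 2.0 * np.pi * np.arange(n_sides) / n_sides
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(n_sides)])


#: Ring templates: hexagon side 0.14 nm (pyridine/phenyl-like), pentagon side
#: 0.137 nm (furan/imidazole-like).  Geometric conveniences, not measured bond
#: lengths.
_RING_TEMPLATES = {
    "hexagon": _regular_polygon(6, 0.14),
    "pentagon": _regular_polygon(5, 0.137),
}


def gen_ring_pair_series(schedule, ring_b: str = "hexagon"):
    """Two planar rings following an exact (r, φ, Ψ) schedule.

    ``schedule`` is an iterable of per-frame triples ``(r_nm, phi_deg,
    psi_deg)`` with r > 0, 0 ≤ φ ≤ 90, 0 ≤ ψ ≤ 90.  Ring A (reference plane)
    is a hexagon fixed in the xy-plane; ring B (``"hexagon"`` or
    ``"pentagon"``) is centred at ``r·u`` with ``u = (cos φ, 0, sin φ)`` and
    oriented with normal ``(sin ψ, 0, cos ψ)``, so the measured descriptors
    reproduce the schedule by construction.

    Returns ``(trajectory, ring_a_indices, ring_b_indices)``.
    """
    sched = np.atleast_2d(np.asarray(list(schedule), dtype=float))
    if sched.shape[1] != 3:
        raise ValidationError("schedule entries must be (r, phi, psi) triples")
    r, phi, psi = sched[:, 0], sched[:, 1], sched[:, 2]
    if np.any(r <= 0):
        raise ValidationError("r must be positive")
    if np.any((phi < 0) | (phi > 90)) or np.any((psi < 0) | (psi > 90)):
        raise ValidationError("phi and psi must lie in [0, 90] degrees")

    ring_a_xyz = _RING_TEMPLATES["hexagon"]
    try:
        ring_b_xyz = _RING_TEMPLATES[ring_b]
    except KeyError:
        raise ValidationError(f"unknown ring template {ring_b!r}") from None
    n_a, n_b = len(ring_a_xyz), len(ring_b_xyz)

    phi_r = np.deg2rad(phi)
    psi_r = np.deg2rad(psi)
    frames = np.empty((len(sched), n_a + n_b, 3))
    for f in range(len(sched)):
        center_b = r[f] * np.array([np.cos(phi_r[f]), 0.0, np.sin(phi_r[f])])
        # rotate ring B about y so its normal becomes (sin psi, 0, cos psi)
        c, s = np.cos(psi_r[f]), np.sin(psi_r[f])
        rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        frames[f, :n_a] = ring_a_xyz
        frames[f, n_a:] = ring_b_xyz @ rot.T + center_b

    atoms = []
    for i in range(n_a):
        atoms.append(Atom(serial=i + 1, name=f"A{i+1}", residue_name="RGA",
                          residue_id=1, chain="A", element="C"))
    for i in range(n_b):
        atoms.append(Atom(serial=n_a + i + 1, name=f"B{i+1}", residue_name="RGB",
                          residue_id=2, chain="A", element="C"))
    traj = Trajectory(atoms=atoms, coordinates=frames)
    return traj, tuple(range(n_a)), tuple(range(n_a, n_a + n_b))


def gen_hbond_series(occupancy: float, n_frames: int, seed: int):
    """Donor–hydrogen–acceptor geometry formed in an exact fraction of frames.

    In formed frames the donor–acceptor distance is 0.28 nm with the
    hydrogen on the D→A axis (angle 0°), comfortably inside the default
    criterion (≤ 0.35 nm, ≤ 30°); in broken frames the acceptor sits at
    0.42 nm, violating the distance cutoff by ≥ 0.05 nm.  Exactly
    ``round(occupancy · n_frames)`` frames are formed; which ones is a
    seed-determined shuffle.

    Returns ``(trajectory, formed_labels)``; atoms are ordered D, H, A.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValidationError("occupancy must lie in [0, 1]")
    if n_frames < 1:
        raise ValidationError("need at least one frame")
    n_formed = int(round(occupancy * n_frames))
    labels = np.zeros(n_frames, dtype=int)
    labels[:n_formed] = 1
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    coords = np.zeros((n_frames, 3, 3))
    coords[:, 1, 0] = 0.10                      # hydrogen on the D→A axis
    coords[:, 2, 0] = np.where(labels == 1, 0.28, 0.42)
    atoms = [
        Atom(serial=1, name="N", residue_name="DON", residue_id=1, chain="A", element="N"),
        Atom(serial=2, name="H", residue_name="DON", residue_id=1, chain="A", element="H"),
        Atom(serial=3, name="O", residue_name="ACC", residue_id=2, chain="A", element="O"),
    ]
    return Trajectory(atoms=atoms, coordinates=coords), labels


def gen_ti_samples(model: HarmonicTIModel, lambdas, n_per_lambda: int, seed: int):
    """∂H/∂λ samples from the harmonic λ-coupled model.

    With H(λ) = ½·k(λ)·x², ∂H/∂λ = ½·(k2 − k1)·x² and, at equilibrium,
    x ~ N(0, RT/k(λ)); the λ-integral of ⟨∂H/∂λ⟩ is (RT/2)·ln(k2/k1).

    Returns a :class:`mdbind.thermo.TIProfile` over the given grid (which
    must be strictly increasing and span [0, 1]).
    """
    from .thermo import TIProfile  # local import: avoid a module cycle

    lambdas = np.asarray(list(lambdas), dtype=float)
    if lambdas.size == 0:
        raise ValidationError("empty λ grid")
    if n_per_lambda < 2:
        raise ValidationError("need ≥ 2 samples per λ")
    rt = R_KJ_PER_MOL_K * model.temperature
    rng = np.random.default_rng(seed)
    samples = []
    for lam in lambdas:
        x = rng.normal(0.0, np.sqrt(rt / model.k(lam)), size=n_per_lambda)
        samples.append(0.5 * (model.k2 - model.k1) * x**2)
    return TIProfile(lambdas=lambdas, dhdl_samples=samples,
                     temperature=model.temperature)
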