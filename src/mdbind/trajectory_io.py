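"""Multi-model PDB trajectory I/O, atom selections and rigid-body superposition.

Coordinates are kept in **nanometres** throughout the package; the PDB
boundary converts Å ↔ nm.  A trajectory is the plain container the rest of
the package operates on: an ordered atom list shared by all frames plus a
``(n_frames, n_atoms, 3)`` coordinate array.

Superposition uses the Kabsch algorithm with the determinant correction that
excludes reflections; a batched variant (one SVD per frame, vectorised over
frames) backs the fluctuation and essential-dynamics modules, which align
tens of thousands of frames per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .exceptions import (
    DegenerateFitError,
    FormatError,
    SelectionError,
    StructureError,
    ValidationError,
)

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0

__all__ = [
    "Atom",
    "Trajectory",
    "Selection",
    "SuperpositionResult",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select",
    "superpose",
]


@dataclass(frozen=True)
class Atom:
    """Static metadata of one atom (coordinates live on the trajectory)."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    element: str = ""


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (nm) with shared atom metadata.

    ``times`` (ps) is optional; if present it must be strictly increasing and
    have one entry per frame.
    """

    atoms: list[Atom]
    coordinates: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError(
                f"coordinates must be (n_frames, n_atoms, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValidationError("a trajectory needs at least one frame")
        if self.coordinates.shape[1] != len(self.atoms):
            raise ValidationError(
                f"{len(self.atoms)} atoms but coordinate frames hold "
                f"{self.coordinates.shape[1]} triples"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates contain non-finite values")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise ValidationError("times must have one entry per frame")
            if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
                raise ValidationError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i`` as an (n_atoms, 3) array (nm)."""
        return self.coordinates[i]


@dataclass(frozen=True)
class Selection:
    """Ordered, duplicate-free 0-based atom indices into a trajectory."""

    indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValidationError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rotation + translation mapping mobile onto reference.

    ``rotation @ x + translation`` carries a mobile coordinate into the
    reference frame; ``rmsd`` is the post-fit value over the fit selection.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _atom_key(a: Atom) -> tuple:
    return (a.name, a.residue_name, a.residue_id, a.chain)


def read_multimodel_pdb(path) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    One frame per ``MODEL`` record (a bare ATOM block is one frame);
    coordinates are converted Å → nm.  Atom metadata comes from the first
    model; every later model must list the same atoms in the same order.
    Frame times are recovered from ``REMARK   6 TIME_PS`` lines when present.
    """
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("traj", str(path))
    except PDBConstructionException as exc:
        raise FormatError(f"unparsable PDB record: {exc}") from exc

    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no MODEL or ATOM records found")

    frames: list[np.ndarray] = []
    meta: list[list[Atom]] = []
    for model in models:
        atoms = []
        coords = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    atoms.append(
                        Atom(
                            serial=int(atom.serial_number),
                            name=atom.get_name(),
                            residue_name=residue.get_resname().strip(),
                            residue_id=int(residue.id[1]),
                            chain=chain.id.strip() or "A",
                            element=(atom.element or "").strip(),
                        )
                    )
                    coords.append(atom.get_coord())
        if not atoms:
            raise FormatError(f"{path}: model {model.id} holds no atoms")
        meta.append(atoms)
        frames.append(np.asarray(coords, dtype=float) * NM_PER_ANGSTROM)

    first = meta[0]
    for m, atoms in enumerate(meta[1:], start=2):
        if len(atoms) != len(first):
            raise StructureError(
                f"{path}: model {m} has {len(atoms)} atoms, model 1 has {len(first)}"
            )
        for i, (a, b) in enumerate(zip(first, atoms)):
            if _atom_key(a) != _atom_key(b):
                raise StructureError(
                    f"{path}: model {m} atom {i} is {_atom_key(b)}, "
                    f"model 1 has {_atom_key(a)}"
                )

    times = _scan_times(path, len(frames))
    return Trajectory(atoms=first, coordinates=np.stack(frames), times=times)


def _scan_times(path, n_frames: int) -> np.ndarray | None:
    vals = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK   6 TIME_PS"):
                try:
                    vals.append(float(line.split()[-1]))
                except ValueError:
                    return None
    if len(vals) == n_frames:
        return np.asarray(vals)
    return None


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: names of <4 chars start at column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (nm → Å, 3 decimals)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            if traj.times is not None:
                fh.write(f"REMARK   6 TIME_PS {traj.times[f]:.4f}\n")
            xyz = traj.coordinates[f] * ANGSTROM_PER_NM
            for a, (x, y, z) in zip(traj.atoms, xyz):
                fh.write(
                    "ATOM  {serial:5d} {name:4s} {res:>3s} {chain:1s}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{elem:>2s}\n".format(
                        serial=a.serial % 100000,
                        name=_format_atom_name(a.name),
                        res=a.residue_name[:3],
                        chain=(a.chain or "A")[:1],
                        resid=a.residue_id % 10000,
                        x=x, y=y, z=z, occ=1.0, b=0.0,
                        elem=a.element[:2],
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_SELECTION_KEYS = {"name", "resname", "resid", "chain"}


def _parse_clause(clause: str):
    parts = clause.replace("=", " ").split()
    if len(parts) < 2 or parts[0] not in _SELECTION_KEYS:
        raise SelectionError(
            f"malformed clause {clause!r}; expected '<key> <value>...' with key "
            f"in {sorted(_SELECTION_KEYS)}"
        )
    key, values = parts[0], parts[1:]
    if key == "resid":
        ranges = []
        for v in values:
            token = v.replace(":", "-")
            try:
                if "-" in token[1:]:
                    cut = token.index("-", 1)
                    ranges.append((int(token[:cut]), int(token[cut + 1:])))
                else:
                    ranges.append((int(token), int(token)))
            except ValueError as exc:
                raise SelectionError(f"bad residue range {v!r}") from exc
        return key, ranges
    return key, set(values)


def select(traj: Trajectory, expression: str) -> Selection:
    """Evaluate a selection expression against the trajectory topology.

    Grammar: clauses joined by ``and``; each clause is ``name <N>...``,
    ``resname <R>...``, ``chain <C>...`` or ``resid <i>``/``resid <i>-<j>``
    (``:`` also accepted as a range separator).  Matching atoms keep their
    original order; an expression matching nothing yields an empty selection.
    """
    if not expression or not expression.strip():
        raise SelectionError("empty selection expression")
    clauses = [c.strip() for c in expression.split(" and ")]
    parsed = [_parse_clause(c) for c in clauses if c]
    if not parsed:
        raise SelectionError("empty selection expression")

    idx = []
    for i, atom in enumerate(traj.atoms):
        ok = True
        for key, spec in parsed:
            if key == "name":
                ok = atom.name in spec
            elif key == "resname":
                ok = atom.residue_name in spec
            elif key == "chain":
                ok = atom.chain in spec
            elif key == "resid":
                ok = any(lo <= atom.residue_id <= hi for lo, hi in spec)
            if not ok:
                break
        if ok:
            idx.append(i)
    return Selection(tuple(idx))


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def _check_fit_atoms(ref_fit: np.ndarray) -> None:
    if ref_fit.shape[0] < 3:
        raise DegenerateFitError(
            f"need ≥3 fit atoms, got {ref_fit.shape[0]}"
        )
    centered = ref_fit - ref_fit.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise DegenerateFitError("fit atoms are collinear")


def kabsch_batch(mobile: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray):
    """Optimal proper rotations/translations for a stack of frames.

    Parameters
    ----------
    mobile : (F, N, 3) frames to fit.
    reference : (N, 3) target coordinates.
    fit_idx : integer indices of the atoms the fit minimises over.

    Returns ``(rotations (F,3,3), translations (F,3), rmsd (F,))`` with the
    rmsd evaluated over the fit atoms after the transform.
    """
    mob_fit = mobile[:, fit_idx, :]
    ref_fit = reference[fit_idx, :]
    _check_fit_atoms(ref_fit)

    mob_c = mob_fit.mean(axis=1)                      # (F, 3)
    ref_c = ref_fit.mean(axis=0)                      # (3,)
    P = mob_fit - mob_c[:, None, :]
    Q = ref_fit - ref_c
    H = np.einsum("fni,nj->fij", P, Q)                # (F, 3, 3)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    # R = V D U^T, proper by construction
    R = np.einsum("fji,fjk,flk->fil", Vt, D, U)
    t = ref_c - np.einsum("fij,fj->fi", R, mob_c)
    fitted = np.einsum("fij,fnj->fni", R, mob_fit) + t[:, None, :]
    rmsd = np.sqrt(((fitted - ref_fit) ** 2).sum(axis=2).mean(axis=1))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply per-frame rigid transforms to (F, N, 3) coordinates."""
    return np.einsum("fij,fnj->fni", R, coords) + t[:, None, :]


def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_selection: Selection) -> SuperpositionResult:
    """Least-squares rigid-body fit of one frame onto a reference.

    Mass-unweighted; reflections are excluded via the determinant correction,
    so the returned rotation always has det +1 (a mirror image therefore
    keeps a positive residual rmsd).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValidationError("mobile and reference must have identical shapes")
    if len(fit_selection) == 0:
        raise ValidationError("fit selection is empty")
    fit_idx = fit_selection.as_array()
    if fit_idx.max(initial=-1) >= mobile.shape[0]:
        raise ValidationError("fit selection index out of range")

    if np.array_equal(mobile, reference):
        _check_fit_atoms(reference[fit_idx])
        return SuperpositionResult(np.eye(3), np.zeros(3), 0.0)

    R, t, rmsd = kabsch_batch(mobile[None], reference, fit_idx)
    return SuperpositionResult(R[0], t[0], float(rmsd[0]))


def iterative_mean_fit(coords: np.ndarray, fit_idx: np.ndarray,
                       tol: float = 1e-6, max_iter: int = 10):
    """Superpose all frames onto their iteratively refined mean structure.

    Frames are first fitted to frame 0, a mean is formed, then refitting to
    the running mean repeats until the mean moves by < ``tol`` nm (max
    ``max_iter`` rounds).  Returns ``(aligned (F,N,3), mean (N,3))``.
    """
    ref = coords[0]
    aligned = coords
    for _ in range(max_iter):
        R, t, _ = kabsch_batch(coords, ref, fit_idx)
        aligned = apply_transform(coords, R, t)
        new_mean = aligned.mean(axis=0)
        shift = np.abs(new_mean - ref).max()
        ref = new_mean
        if shift < tol:
            break
    return aligned, ref
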