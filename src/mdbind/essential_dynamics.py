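"""Essential dynamics: covariance eigenanalysis, projections, basins, overlap.

The positional-fluctuation covariance matrix C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩ over the
aligned frames of a selection (3N × 3N, nm²) is diagonalised into
eigenvectors — collective motion directions in the 3N-dimensional
configuration space — and eigenvalues, the mean-square fluctuations along
them.  Projecting a trajectory onto the plane of the two leading
eigenvectors (the "essential plane") exposes the sampled conformational
basins; representative frames extracted from basin maxima seed downstream
free-energy calculations.  Cross-system comparisons share one plane built
from the concatenated trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError
from .trajectory_io import (
    Selection,
    Trajectory,
    apply_transform,
    iterative_mean_fit,
    kabsch_batch,
)

__all__ = [
    "CovarianceModel",
    "EssentialProjection",
    "Basin",
    "BasinSet",
    "build_covariance",
    "project",
    "extract_basins",
    "compare_conformational_spaces",
    "common_plane_projections",
]

#: eigenvalues below this (nm²) are clamped to exactly zero
EIGENVALUE_FLOOR = 1e-12

#: how many eigenvalues the spectrum summary reports by default
N_REPORTED_EIGENVALUES = 20


@dataclass
class CovarianceModel:
    """Mean structure + covariance eigensystem of a selection's fluctuations.

    ``matrix`` is 3N×3N (nm²); ``eigenvalues`` are sorted descending with
    ``eigenvectors[:, k]`` the matching orthonormal 3N-direction; ``trace``
    (nm²) measures the total fluctuation and equals Σ eigenvalues.
    ``selection`` records the atoms the model was built on so projections
    stay consistent.
    """

    mean_structure: np.ndarray
    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    trace: float
    selection: Selection

    def spectrum(self, n: int = N_REPORTED_EIGENVALUES) -> np.ndarray:
        """The first ``n`` eigenvalues (nm²)."""
        return self.eigenvalues[:n]


@dataclass
class EssentialProjection:
    """Per-frame coordinates (nm) on a pair of eigenvectors (1-based indices)."""

    coords_2d: np.ndarray
    eigenvector_indices: tuple[int, int]

    def __post_init__(self):
        self.coords_2d = np.asarray(self.coords_2d, dtype=float)
        if self.coords_2d.ndim != 2 or self.coords_2d.shape[1] != 2:
            raise ValidationError("coords_2d must be (n_frames, 2)")
        if not np.all(np.isfinite(self.coords_2d)):
            raise ValidationError("projection coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords_2d.shape[0]


@dataclass(frozen=True)
class Basin:
    """A local density maximum on the essential plane."""

    center_2d: tuple[float, float]
    population: float
    representative_frame: int


@dataclass
class BasinSet:
    """Extracted basins plus per-frame nearest-basin assignments.

    ``warning`` is set when fewer maxima than requested exist.
    """

    basins: list[Basin]
    assignments: np.ndarray
    warning: str | None = None

    def __iter__(self):
        return iter(self.basins)

    def __len__(self):
        return len(self.basins)


def build_covariance(traj: Trajectory, selection: Selection,
                     align: bool = True) -> CovarianceModel:
    """Covariance of positional fluctuations over a selection.

    Frames are superposed onto their iteratively refined mean over the same
    selection (``align=False`` trusts the caller's pre-superposition), then
    C = ⟨δx δxᵀ⟩ with the population (1/F) normalisation, which makes
    trace(C) identically Σ per-atom RMSF².  Eigenvalues below 1e-12 nm² are
    clamped to zero.
    """
    if traj.n_frames < 2:
        raise ValidationError("covariance needs at least 2 frames")
    if len(selection) < 2:
        raise ValidationError("selection must contain at least 2 atoms")
    idx = selection.as_array()
    if align:
        aligned, mean = iterative_mean_fit(traj.coordinates, idx)
    else:
        aligned = traj.coordinates
        mean = aligned.mean(axis=0)
    X = aligned[:, idx, :].reshape(traj.n_frames, -1)
    mu = X.mean(axis=0)
    dX = X - mu
    C = dX.T @ dX / traj.n_frames
    C = 0.5 * (C + C.T)  # symmetrise fp residue; trace reported from the
    # clamped spectrum so a constant trajectory yields exactly zero

    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals[np.abs(evals) < EIGENVALUE_FLOOR] = 0.0
    return CovarianceModel(
        mean_structure=mu.reshape(-1, 3),
        matrix=C,
        eigenvalues=evals,
        eigenvectors=evecs,
        trace=float(evals.sum()),
        selection=selection,
    )


def project(traj: Trajectory, model: CovarianceModel,
            k: tuple[int, int] = (1, 2)) -> EssentialProjection:
    """Project a trajectory onto a pair of the model's eigenvectors.

    ``k`` uses 1-based eigenvector ranks (``(1, 2)`` = the essential plane).
    Each frame is first superposed onto the model's mean structure over the
    model's selection; the projection is then (x − ⟨x⟩)·v_k.
    """
    k = tuple(int(i) for i in k)
    if len(k) != 2:
        raise ValidationError("k must be a pair of eigenvector ranks")
    n = model.eigenvalues.size
    if not all(1 <= i <= n for i in k):
        raise ValidationError(f"eigenvector indices {k} out of range 1..{n}")
    idx = model.selection.as_array()
    if idx.max(initial=-1) >= traj.n_atoms:
        raise ValidationError("model selection exceeds trajectory atom count")

    R, t, _ = kabsch_batch(traj.coordinates[:, idx, :],
                           model.mean_structure, np.arange(idx.size))
    aligned = apply_transform(traj.coordinates[:, idx, :], R, t)
    dX = aligned.reshape(traj.n_frames, -1) - model.mean_structure.reshape(-1)
    V = model.eigenvectors[:, [k[0] - 1, k[1] - 1]]
    return EssentialProjection(coords_2d=dX @ V, eigenvector_indices=k)


def _grid_edges(points: np.ndarray, bins: int, pad_frac: float = 0.05):
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    span = hi - lo
    pad = np.where(span > 0, pad_frac * span, 0.5)
    return (np.linspace(lo[0] - pad[0], hi[0] + pad[0], bins + 1),
            np.linspace(lo[1] - pad[1], hi[1] + pad[1], bins + 1))


def extract_basins(projection: EssentialProjection, grid_bins: int = 50,
                   n_basins: int = 1) -> BasinSet:
    """Locate the most-populated conformational basins on the plane.

    The plane is histogrammed on a ``grid_bins``² grid over the data
    bounding box padded by 5%.  Basins are the top-``n_basins`` local maxima
    (cells at least as dense as their 8 neighbours) pairwise separated by a
    Chebyshev distance of ≥ 2 cells; equal-density ties break towards lower
    (p1, p2) cell centres.  The maxima search runs on a lightly smoothed
    histogram (Gaussian, σ = 2 cells) and discards maxima below 5% of the
    densest cell, so sampling noise in sparse tails does not masquerade as
    extra basins.  Each basin's representative frame is the frame
    closest (Euclidean, in the plane) to the maximum's cell centre;
    populations are nearest-basin frame fractions.  If fewer maxima exist
    than requested, the result carries a warning instead of failing.
    """
    if n_basins < 1:
        raise ValidationError("n_basins must be ≥ 1")
    if projection.n_frames == 0:
        raise ValidationError("empty projection")
    pts = projection.coords_2d
    ex, ey = _grid_edges(pts, grid_bins)
    H, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[ex, ey])
    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])

    S = gaussian_filter(H, sigma=2.0, mode="constant")
    padded = np.full((grid_bins + 2, grid_bins + 2), -np.inf)
    padded[1:-1, 1:-1] = S
    is_max = np.ones_like(S, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            neigh = padded[1 + di: 1 + di + grid_bins, 1 + dj: 1 + dj + grid_bins]
            is_max &= S >= neigh
    is_max &= S >= 0.05 * S.max()

    cand = [(float(-S[i, j]), float(cx[i]), float(cy[j]), i, j)
            for i, j in zip(*np.nonzero(is_max))]
    cand.sort()

    chosen: list[tuple[int, int]] = []
    centers: list[tuple[float, float]] = []
    for _, x, y, i, j in cand:
        if all(max(abs(i - pi), abs(j - pj)) >= 2 for pi, pj in chosen):
            chosen.append((i, j))
            centers.append((x, y))
        if len(chosen) == n_basins:
            break

    warning = None
    if len(chosen) < n_basins:
        warning = (f"only {len(chosen)} local maxima found; "
                   f"{n_basins} basins requested")

    carr = np.asarray(centers)
    d2 = ((pts[:, None, :] - carr[None, :, :]) ** 2).sum(axis=2)
    assignments = d2.argmin(axis=1)
    basins = []
    for b, (x, y) in enumerate(centers):
        rep = int(np.argmin((pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2))
        pop = float((assignments == b).mean())
        basins.append(Basin(center_2d=(x, y), population=pop,
                            representative_frame=rep))
    return BasinSet(basins=basins, assignments=assignments, warning=warning)


def compare_conformational_spaces(projections, grid_bins: int = 50) -> np.ndarray:
    """Pairwise overlap coefficients of projected conformational spaces.

    All projections must live on a common plane (built from the
    concatenated trajectories; see :func:`common_plane_projections`).  A
    shared 2D histogram is normalised per system and
    overlap(i, j) = Σ_cells min(f_i, f_j) ∈ [0, 1]; the matrix is symmetric
    with unit diagonal.  Identical clouds give 1, disjoint supports 0.
    """
    projections = list(projections)
    if not projections:
        raise ValidationError("no projections given")
    for p in projections:
        if p.n_frames == 0:
            raise ValidationError("empty projection")
    allpts = np.vstack([p.coords_2d for p in projections])
    ex, ey = _grid_edges(allpts, grid_bins)
    freqs = []
    for p in projections:
        H, _, _ = np.histogram2d(p.coords_2d[:, 0], p.coords_2d[:, 1],
                                 bins=[ex, ey])
        freqs.append(H / p.n_frames)
    n = len(freqs)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = float(np.minimum(freqs[i], freqs[j]).sum())
    return M


def common_plane_projections(trajs, selection: Selection,
                             k: tuple[int, int] = (1, 2)):
    """One covariance over concatenated trajectories; project each separately.

    Returns ``(model, [EssentialProjection, ...])`` — the construction used
    to compare the conformational spaces of several systems on an identical
    essential plane.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValidationError("no trajectories given")
    atoms = trajs[0].atoms
    coords = np.concatenate([t.coordinates for t in trajs], axis=0)
    concat = Trajectory(atoms=atoms, coordinates=coords)
    model = build_covariance(concat, selection)
    return model, [project(t, model, k) for t in trajs]
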