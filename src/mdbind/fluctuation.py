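"""RMSD/RMSF profiles, the ΔRMSD comparison metric, and block standard errors.

All quantities are mass-unweighted and reported in nm.  Per-residue profiles
are indexed by residue id of a designated atom (Cα by default), mirroring
the usual practice of characterising backbone perturbation residue by
residue and comparing a ligand-bound profile against the apo enzyme
(ΔRMSD = RMSD_complex − RMSD_apo per residue, zero meaning the ligand leaves
the average structure untouched).

Statistical errors on trajectory averages use block averaging over a small
number of contiguous blocks (three by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ProfileAlignmentError, ValidationError
from .trajectory_io import (
    Selection,
    Trajectory,
    apply_transform,
    iterative_mean_fit,
    kabsch_batch,
)

__all__ = [
    "FluctuationProfile",
    "BlockErrorEstimate",
    "rmsd_series",
    "per_atom_rmsf",
    "per_residue_rmsd",
    "delta_rmsd",
    "block_standard_error",
]

VALID_KINDS = ("rmsf", "residue_rmsd", "delta_rmsd")


@dataclass
class FluctuationProfile:
    """Per-atom or per-residue values (nm) with their labels.

    ``kind`` is one of ``rmsf``, ``residue_rmsd`` or ``delta_rmsd``; the
    first two are non-negative by definition, ΔRMSD may take either sign.
    """

    values: np.ndarray
    labels: list
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in VALID_KINDS:
            raise ValidationError(f"kind must be one of {VALID_KINDS}")
        if len(self.labels) != self.values.size:
            raise ValidationError("one label per value required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("profile values must be finite")
        if self.kind != "delta_rmsd" and np.any(self.values < 0):
            raise ValidationError(f"{self.kind} values must be non-negative")


@dataclass(frozen=True)
class BlockErrorEstimate:
    """Trajectory-average ± standard error from contiguous block means."""

    mean: float
    standard_error: float
    n_blocks: int


def rmsd_series(traj: Trajectory, reference: np.ndarray, fit_selection: Selection,
                measure_selection: Selection) -> np.ndarray:
    """Per-frame RMSD (nm) after fitting each frame onto the reference.

    Each frame is superposed over ``fit_selection``; the deviation is then
    measured over ``measure_selection`` (the two may differ, e.g. Cα fit with
    all-ligand-atom measurement).
    """
    reference = np.asarray(reference, dtype=float)
    if len(fit_selection) == 0 or len(measure_selection) == 0:
        raise ValidationError("selections must be non-empty")
    R, t, _ = kabsch_batch(traj.coordinates, reference, fit_selection.as_array())
    aligned = apply_transform(traj.coordinates, R, t)
    m = measure_selection.as_array()
    diff = aligned[:, m, :] - reference[m, :]
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))


def per_atom_rmsf(traj: Trajectory, fit_selection: Selection,
                  measure_selection: Selection,
                  fit_to_mean: bool = True) -> FluctuationProfile:
    """Root-mean-square fluctuation of each measured atom about its mean.

    With ``fit_to_mean`` (default) frames are superposed onto an iteratively
    refined mean structure (fit repeated until the mean moves < 1e-6 nm, at
    most 10 rounds), the convention under which Σ RMSF² equals the trace of
    the positional-fluctuation covariance built on the same selection.
    ``fit_to_mean=False`` fits to the first frame instead.
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    if len(fit_selection) == 0 or len(measure_selection) == 0:
        raise ValidationError("selections must be non-empty")
    fit_idx = fit_selection.as_array()
    if fit_to_mean:
        aligned, mean = iterative_mean_fit(traj.coordinates, fit_idx)
    else:
        R, t, _ = kabsch_batch(traj.coordinates, traj.coordinates[0], fit_idx)
        aligned = apply_transform(traj.coordinates, R, t)
        mean = aligned.mean(axis=0)
    m = measure_selection.as_array()
    dev = aligned[:, m, :] - mean[m, :]
    rmsf = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    labels = [traj.atoms[i].residue_id for i in m]
    return FluctuationProfile(values=rmsf, labels=labels, kind="rmsf")


def per_residue_rmsd(traj: Trajectory, reference: np.ndarray,
                     fit_selection: Selection,
                     designated_atom: str = "CA") -> FluctuationProfile:
    """Time-averaged per-residue deviation from a reference structure.

    After global superposition of every frame onto the reference (typically
    the simulation starting structure) over ``fit_selection``, residue i's
    value is sqrt(⟨|r_i(t) − r_i(ref)|²⟩_t) for its designated atom.
    Residues lacking the designated atom are excluded with a warning.
    """
    reference = np.asarray(reference, dtype=float)
    if len(fit_selection) == 0:
        raise ValidationError("fit selection must be non-empty")
    R, t, _ = kabsch_batch(traj.coordinates, reference, fit_selection.as_array())
    aligned = apply_transform(traj.coordinates, R, t)

    atom_of_residue: dict[tuple, int] = {}
    order: list[tuple] = []
    seen: set[tuple] = set()
    for i, a in enumerate(traj.atoms):
        key = (a.chain, a.residue_id)
        if key not in seen:
            order.append(key)
            seen.add(key)
        if a.name == designated_atom and key not in atom_of_residue:
            atom_of_residue[key] = i
    absent = [key for key in order if key not in atom_of_residue]
    if absent:
        warnings.warn(
            f"residues without a {designated_atom!r} atom excluded: {absent}",
            stacklevel=2,
        )
    keys = [k for k in order if k in atom_of_residue]
    idx = np.array([atom_of_residue[k] for k in keys], dtype=int)
    diff = aligned[:, idx, :] - reference[idx, :]
    vals = np.sqrt((diff**2).sum(axis=2).mean(axis=0))
    return FluctuationProfile(values=vals, labels=[k[1] for k in keys],
                              kind="residue_rmsd")


def delta_rmsd(complex_profile: FluctuationProfile,
               apo_profile: FluctuationProfile) -> FluctuationProfile:
    """Elementwise complex − apo profile difference (ΔRMSD).

    Profiles must carry identical residue labels in identical order; a
    mismatch raises :class:`ProfileAlignmentError` naming the offenders.
    """
    la, lb = list(complex_profile.labels), list(apo_profile.labels)
    if la != lb:
        sa, sb = set(la), set(lb)
        offending = sorted(sa.symmetric_difference(sb)) or [
            x for x, y in zip(la, lb) if x != y
        ]
        raise ProfileAlignmentError(offending)
    return FluctuationProfile(
        values=complex_profile.values - apo_profile.values,
        labels=la,
        kind="delta_rmsd",
    )


def block_standard_error(series, n_blocks: int = 3) -> BlockErrorEstimate:
    """Standard error of a trajectory average from contiguous block means.

    The series splits into ``n_blocks`` equal contiguous blocks (any
    remainder at the end is dropped); SE = stdev(block means, ddof=1)/√n_blocks.
    """
    series = np.asarray(series, dtype=float).ravel()
    if n_blocks < 2:
        raise ValidationError("need at least 2 blocks")
    if series.size < n_blocks:
        raise ValidationError(
            f"series of length {series.size} cannot form {n_blocks} blocks"
        )
    m = series.size // n_blocks
    used = series[: m * n_blocks].reshape(n_blocks, m)
    means = used.mean(axis=1)
    se = float(means.std(ddof=1) / np.sqrt(n_blocks))
    return BlockErrorEstimate(mean=float(means.mean()), standard_error=se,
                              n_blocks=n_blocks)
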