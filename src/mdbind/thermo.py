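"""Free-energy machinery: TI quadrature, error propagation, entropy/enthalpy
decomposition, Cheng–Prusoff conversion, and the tautomer-linkage cycle.

Thermodynamic integration turns per-λ samples of the coupling derivative
∂H/∂λ into a free-energy difference ΔF = ∫₀¹ ⟨∂H/∂λ⟩ dλ, with the per-λ
statistical error estimated by block averaging and propagated through the
quadrature weights.  Relative binding free energies ΔΔμ° are differences
against a chosen reference ligand; repeating the integration at a second
temperature decomposes ΔΔG into entropic and enthalpic parts via the
finite-difference −∂ΔΔG/∂T.

The tautomer side of the cycle combines per-conformer gas-phase and
hydration free energies into solution chemical potentials by Boltzmann
summation (log-sum-exp, overflow safe), yielding the tautomer equilibrium
constant K = [a]/[b]; the linkage relation
[complex_a]/[complex_b] = K · exp(−(ΔΔμ_a − ΔΔμ_b)/RT) then couples the
free-solution equilibrium to the relative binding strengths.

All free energies are kJ/mol; R = 8.314462618 J/(mol·K).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import FormatError, ValidationError
from .fluctuation import block_standard_error

R_KJ_PER_MOL_K = 8.314462618e-3  # kJ/(mol·K)

__all__ = [
    "SoftCoreMetadata",
    "TIProfile",
    "FreeEnergyResult",
    "ConformerEnergy",
    "TautomerEquilibrium",
    "InhibitionData",
    "EntropyDecomposition",
    "integrate_ti",
    "relative_binding_ddg",
    "entropy_decomposition",
    "ic50_to_ddmu",
    "tautomer_equilibrium",
    "bound_tautomer_ratio",
    "read_lambda_table",
    "ti_profile_from_tables",
    "read_binding_table",
    "read_conformer_table",
]


@dataclass(frozen=True)
class SoftCoreMetadata:
    """Engine-side soft-core settings carried as provenance only.

    The alchemical engine used a soft-core nonbonded form with α = 1.51,
    σ = 0.3 nm and Δλ = 0.001; this module never evaluates that potential —
    the fields merely document where the samples came from.
    """

    alpha: float = 1.51
    sigma_nm: float = 0.3
    delta_lambda: float = 0.001


@dataclass
class TIProfile:
    """A λ grid with per-λ ∂H/∂λ samples (kJ/mol) at one temperature."""

    lambdas: np.ndarray
    dhdl_samples: list
    temperature: float
    softcore: SoftCoreMetadata = field(default_factory=SoftCoreMetadata)

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.size < 1:
            raise ValidationError("empty λ grid")
        if self.lambdas.size > 1 and not np.all(np.diff(self.lambdas) > 0):
            raise ValidationError("λ grid must be strictly increasing")
        if not (math.isclose(self.lambdas[0], 0.0, abs_tol=1e-12)
                and math.isclose(self.lambdas[-1], 1.0, abs_tol=1e-12)):
            raise ValidationError("λ grid must span [0, 1]")
        if len(self.dhdl_samples) != self.lambdas.size:
            raise ValidationError("one sample list per λ required")
        self.dhdl_samples = [np.asarray(s, dtype=float).ravel()
                             for s in self.dhdl_samples]
        for lam, s in zip(self.lambdas, self.dhdl_samples):
            if s.size < 2:
                raise ValidationError(f"λ = {lam}: need ≥ 2 samples")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")


@dataclass(frozen=True)
class FreeEnergyResult:
    """A free energy (kJ/mol) with its standard error at a temperature."""

    value: float
    standard_error: float
    temperature: float

    def __post_init__(self):
        if self.standard_error < 0:
            raise ValidationError("standard error must be ≥ 0")


@dataclass(frozen=True)
class ConformerEnergy:
    """One conformer's gas-phase relative and hydration free energies."""

    label: str
    tautomer: str
    gas_rel_free_energy: float
    hydration_free_energy: float

    def __post_init__(self):
        if self.tautomer not in ("a", "b"):
            raise ValidationError("tautomer must be 'a' or 'b'")
        if not (np.isfinite(self.gas_rel_free_energy)
                and np.isfinite(self.hydration_free_energy)):
            raise ValidationError("conformer energies must be finite")

    @property
    def solution_free_energy(self) -> float:
        """Gas-phase + hydration contribution (kJ/mol)."""
        return self.gas_rel_free_energy + self.hydration_free_energy


@dataclass(frozen=True)
class TautomerEquilibrium:
    """K = [a]/[b] with Δμ = μ_a − μ_b = −RT·ln K (kJ/mol)."""

    K: float
    delta_mu: float
    temperature: float

    def __post_init__(self):
        if self.K <= 0:
            raise ValidationError("K must be positive")
        rt = R_KJ_PER_MOL_K * self.temperature
        if abs(self.delta_mu + rt * math.log(self.K)) > 1e-10:
            raise ValidationError("delta_mu must equal −RT·ln K")


@dataclass(frozen=True)
class InhibitionData:
    """IC50 with assay conditions (all molar) for Cheng–Prusoff conversion."""

    ic50: float
    substrate_conc: float
    km: float

    def __post_init__(self):
        if min(self.ic50, self.substrate_conc, self.km) <= 0:
            raise ValidationError("IC50, S and Km must all be positive")

    @property
    def ki(self) -> float:
        """Cheng–Prusoff inhibition constant Ki = IC50/(1 + S/Km)."""
        return self.ic50 / (1.0 + self.substrate_conc / self.km)


@dataclass(frozen=True)
class EntropyDecomposition:
    """Finite-difference ΔΔS/ΔΔH with propagated errors."""

    delta_delta_s: float            # kJ/(mol·K)
    delta_delta_s_se: float
    delta_delta_h: float            # kJ/mol
    delta_delta_h_se: float
    consistent_with_zero_entropy: bool
    temperatures: tuple[float, float]


# ---------------------------------------------------------------------------
# TI quadrature
# ---------------------------------------------------------------------------

def _trapezoid_weights(lambdas: np.ndarray) -> np.ndarray:
    w = np.zeros_like(lambdas)
    d = np.diff(lambdas)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def _simpson_weights(lambdas: np.ndarray) -> np.ndarray:
    n = lambdas.size
    if n < 3 or n % 2 == 0:
        raise ValidationError("Simpson rule needs an odd number of ≥3 λ points")
    h = np.diff(lambdas)
    if not np.allclose(h, h[0], rtol=1e-8):
        raise ValidationError("Simpson rule requires a uniform λ grid")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h[0] / 3.0


def integrate_ti(profile: TIProfile, n_blocks: int = 3,
                 rule: str = "trapezoid") -> FreeEnergyResult:
    """Quadrature of per-λ sample means with propagated block errors.

    ΔF = Σ_k w_k·⟨∂H/∂λ⟩_k with trapezoid weights on the (possibly
    non-uniform) grid; ``rule="simpson"`` switches to composite Simpson on a
    uniform odd-length grid.  Each λ's standard error comes from
    ``n_blocks``-block averaging of its samples and the result's SE is
    sqrt(Σ w_k² SE_k²).
    """
    if profile.lambdas.size < 2:
        raise ValidationError("TI needs at least 2 λ points")
    if rule == "trapezoid":
        w = _trapezoid_weights(profile.lambdas)
    elif rule == "simpson":
        w = _simpson_weights(profile.lambdas)
    else:
        raise ValidationError(f"unknown quadrature rule {rule!r}")
    means = np.array([s.mean() for s in profile.dhdl_samples])
    ses = np.array([
        block_standard_error(s, n_blocks=n_blocks).standard_error
        if s.size >= n_blocks else 0.0
        for s in profile.dhdl_samples
    ])
    value = float(w @ means)
    se = float(np.sqrt(((w * ses) ** 2).sum()))
    return FreeEnergyResult(value=value, standard_error=se,
                            temperature=profile.temperature)


def relative_binding_ddg(results: dict, reference_system: str) -> dict:
    """Express binding free energies relative to a reference ligand.

    ΔΔ_i = value_i − value_ref with SE_i = sqrt(SE_i² + SE_ref²); the
    reference entry is (0, 0) by convention.  All inputs must share one
    temperature.
    """
    if reference_system not in results:
        raise ValidationError(f"reference {reference_system!r} not among results")
    temps = {r.temperature for r in results.values()}
    if len(temps) > 1:
        raise ValidationError(f"mixed temperatures {sorted(temps)}")
    ref = results[reference_system]
    out = {}
    for name, r in results.items():
        if name == reference_system:
            out[name] = FreeEnergyResult(0.0, 0.0, r.temperature)
        else:
            out[name] = FreeEnergyResult(
                value=r.value - ref.value,
                standard_error=float(np.hypot(r.standard_error,
                                              ref.standard_error)),
                temperature=r.temperature,
            )
    return out


def entropy_decomposition(ddg_t1: FreeEnergyResult,
                          ddg_t2: FreeEnergyResult) -> EntropyDecomposition:
    """Two-temperature finite-difference split of ΔΔG into ΔΔS and ΔΔH.

    ΔΔS = −(ΔΔG(T2) − ΔΔG(T1))/(T2 − T1) and ΔΔH = ΔΔG(T1) + T1·ΔΔS, with
    standard errors propagated linearly.  The flag is true when |ΔΔS| ≤
    SE(ΔΔS), i.e. the entropic contribution is indistinguishable from zero
    at one standard error — the qualitative signature of
    enthalpy-dominated binding.
    """
    t1, t2 = ddg_t1.temperature, ddg_t2.temperature
    if t2 <= t1:
        raise ValidationError("need T2 > T1")
    dt = t2 - t1
    dds = -(ddg_t2.value - ddg_t1.value) / dt
    dds_se = math.hypot(ddg_t1.standard_error, ddg_t2.standard_error) / dt
    # ΔΔH = (1 + T1/ΔT)·ΔΔG(T1) − (T1/ΔT)·ΔΔG(T2)
    c1 = 1.0 + t1 / dt
    c2 = t1 / dt
    ddh = c1 * ddg_t1.value - c2 * ddg_t2.value
    ddh_se = math.hypot(c1 * ddg_t1.standard_error, c2 * ddg_t2.standard_error)
    return EntropyDecomposition(
        delta_delta_s=dds,
        delta_delta_s_se=dds_se,
        delta_delta_h=ddh,
        delta_delta_h_se=ddh_se,
        consistent_with_zero_entropy=abs(dds) <= dds_se,
        temperatures=(t1, t2),
    )


def ic50_to_ddmu(a: InhibitionData, b: InhibitionData,
                 temperature: float) -> float:
    """Relative binding free energy (kJ/mol) from two IC50 measurements.

    ΔΔμ = RT·ln(Ki_b/Ki_a) with Ki from Cheng–Prusoff; when both compounds
    share S and Km this reduces to RT·ln(IC50_b/IC50_a).  Differing assay
    conditions trigger a warning and the full (unreduced) form.
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    rt = R_KJ_PER_MOL_K * temperature
    same = (math.isclose(a.substrate_conc, b.substrate_conc, rel_tol=1e-9)
            and math.isclose(a.km, b.km, rel_tol=1e-9))
    if not same:
        warnings.warn(
            "substrate concentration or Km differ between compounds; "
            "using the full Cheng–Prusoff form rather than the IC50 ratio",
            stacklevel=2,
        )
    return rt * math.log(b.ki / a.ki)


def tautomer_equilibrium(conformers, temperature: float) -> TautomerEquilibrium:
    """Multi-conformer tautomer equilibrium constant K = [a]/[b].

    Each conformer contributes G_i = gas-phase relative + hydration free
    energy; the tautomer chemical potential is the Boltzmann sum
    μ_X = −RT·ln Σ_{i∈X} exp(−G_i/RT) (evaluated with log-sum-exp), and
    K = exp(−(μ_a − μ_b)/RT).
    """
    conformers = list(conformers)
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    rt = R_KJ_PER_MOL_K * temperature
    sides = {"a": [], "b": []}
    for c in conformers:
        sides[c.tautomer].append(c.solution_free_energy)
    for side, gs in sides.items():
        if not gs:
            raise ValidationError(f"no conformers for tautomer {side!r}")
    mu = {side: -rt * logsumexp(-np.asarray(gs) / rt)
          for side, gs in sides.items()}
    delta_mu = float(mu["a"] - mu["b"])
    return TautomerEquilibrium(K=math.exp(-delta_mu / rt),
                               delta_mu=delta_mu, temperature=temperature)


def bound_tautomer_ratio(k_taut, ddmu_a: float, ddmu_b: float,
                         temperature: float) -> float:
    """Population ratio of the two bound tautomer complexes.

    [complex_a]/[complex_b] = exp(−(ΔΔμ_a − ΔΔμ_b)/RT) · K, linking the
    relative binding free energies to the free-solution tautomer
    equilibrium K = [a]/[b] (pass a :class:`TautomerEquilibrium` or a bare
    K value).
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    K = k_taut.K if isinstance(k_taut, TautomerEquilibrium) else float(k_taut)
    if K <= 0:
        raise ValidationError("K must be positive")
    rt = R_KJ_PER_MOL_K * temperature
    return math.exp(-(ddmu_a - ddmu_b) / rt) * K


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def read_lambda_table(path):
    """Read a two-column λ (or time) vs ∂H/∂λ text table.

    Columns may be separated by whitespace or commas; lines starting with
    ``#`` or ``@`` (XVG headers) and blank lines are ignored.  Returns
    ``(x, dhdl)`` arrays.
    """
    xs, ys = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, "
                                  f"got {line!r}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric entry in {line!r}"
                ) from exc
    if not xs:
        raise FormatError(f"{path}: no data lines found")
    return np.asarray(xs), np.asarray(ys)


def ti_profile_from_tables(tables, temperature: float) -> TIProfile:
    """Assemble a :class:`TIProfile` from per-λ sample files.

    ``tables`` maps λ values to file paths; each file's second column is the
    ∂H/∂λ sample series at that λ.
    """
    lams = sorted(float(l) for l in tables)
    samples = []
    for lam in lams:
        _, y = read_lambda_table(tables[lam])
        samples.append(y)
    return TIProfile(lambdas=np.asarray(lams), dhdl_samples=samples,
                     temperature=temperature)


def read_binding_table(path) -> dict:
    """Read a relative-binding-free-energy CSV.

    Expected columns: ``system`` plus ``ddg_<T>K_kJmol``/``se_<T>K_kJmol``
    pairs for one or more temperatures.  Returns
    ``{system: {T: FreeEnergyResult}}``.
    """
    df = pd.read_csv(path)
    if "system" not in df.columns:
        raise FormatError(f"{path}: missing 'system' column")
    temp_cols = {}
    for col in df.columns:
        m = re.fullmatch(r"ddg_(\d+(?:\.\d+)?)K_kJmol", col)
        if m:
            t = float(m.group(1))
            se_col = f"se_{m.group(1)}K_kJmol"
            if se_col not in df.columns:
                raise FormatError(f"{path}: missing column {se_col}")
            temp_cols[t] = (col, se_col)
    if not temp_cols:
        raise FormatError(f"{path}: no ddg_<T>K_kJmol columns found")
    out: dict = {}
    for _, row in df.iterrows():
        system = str(row["system"])
        out[system] = {
            t: FreeEnergyResult(value=float(row[vc]),
                                standard_error=float(row[sc]),
                                temperature=t)
            for t, (vc, sc) in temp_cols.items()
        }
    return out


def read_conformer_table(path) -> list:
    """Read a per-conformer energy CSV into :class:`ConformerEnergy` rows.

    Expected columns: ``species``, ``tautomer`` (a/b),
    ``gas_rel_free_energy_kJmol``, ``hydration_free_energy_kJmol``.
    """
    df = pd.read_csv(path)
    required = {"species", "tautomer", "gas_rel_free_energy_kJmol",
                "hydration_free_energy_kJmol"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        ConformerEnergy(
            label=str(row["species"]),
            tautomer=str(row["tautomer"]).strip(),
            gas_rel_free_energy=float(row["gas_rel_free_energy_kJmol"]),
            hydration_free_energy=float(row["hydration_free_energy_kJmol"]),
        )
        for _, row in df.iterrows()
    ]
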