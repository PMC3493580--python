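"""Bundled reference tables.

Two small CSVs ship with the package, transcribing the published
experimental/computed inputs of the MMP-2 non-zinc-binding inhibitor study:

* ``binding_ddg.csv`` — relative binding free energies ΔΔμ° (kJ/mol, with
  propagated standard errors) of the tautomers 1a, 1b and of compound 2 at
  300 K and 323 K, referenced to 1b at 300 K.
* ``conformer_energies.csv`` — gas-phase relative and hydration free
  energies (kJ/mol, 300 K) of the six low-lying pyrazole-ring conformers
  1a1–1a3 / 1b1–1b3 used for the tautomer-equilibrium cycle.
"""

from importlib import resources

from .thermo import read_binding_table, read_conformer_table


def _data_path(name: str):
    return resources.files(__package__) / "data" / name


def binding_free_energies() -> dict:
    """``{system: {T: FreeEnergyResult}}`` for 1a, 1b, 2 at 300 and 323 K."""
    with resources.as_file(_data_path("binding_ddg.csv")) as p:
        return read_binding_table(p)


def conformer_energies() -> list:
    """The six :class:`~mdbind.thermo.ConformerEnergy` rows (300 K)."""
    with resources.as_file(_data_path("conformer_energies.csv")) as p:
        return read_conformer_table(p)
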