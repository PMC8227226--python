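"""Packaged reference tables.

``table1_energies.csv``
    Quantum-chemistry energy table for the chlorferron template against eight
    candidate functional monomers (complex, template and monomer total
    energies; unit label passed through as printed).

``table2_interference.csv``
    Measured signed current changes and percent changes of the 10 uM
    chlorferron anodic peak in the presence of four interferents at
    10/50/100 uM.

``table3_recovery.csv``
    Spike-recovery summary for plasma and urine (spiked level, mean measured
    concentration, printed recovery % and %RSD, n = 3).

``ratio_scan_synthetic.csv``
    SYNTHETIC template:monomer stoichiometry scan. Real semi-empirical
    complex energies for the ratio optimisation were never published; this
    stand-in is constructed so that the 1:4 ratio is the energy minimum,
    letting the selection logic be exercised. Do not mistake its scores for
    computed chemistry.
"""

from importlib.resources import files
from pathlib import Path


def _data_path(name: str) -> Path:
    return Path(str(files(__package__).joinpath(name)))


def table1_energies_path() -> Path:
    """Path to the packaged monomer binding-energy table."""
    return _data_path("table1_energies.csv")


def table2_interference_path() -> Path:
    """Path to the packaged interference table."""
    return _data_path("table2_interference.csv")


def table3_recovery_path() -> Path:
    """Path to the packaged spike-recovery table."""
    return _data_path("table3_recovery.csv")


def ratio_scan_synthetic_path() -> Path:
    """Path to the synthetic template:monomer ratio scan (see module docs)."""
    return _data_path("ratio_scan_synthetic.csv")
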