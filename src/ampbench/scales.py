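"""Per-residue property scales and class alphabets used by the extractors.

All scales cover the 20 standard amino acids.  Sources are the classic
literature tables used throughout peptide informatics: Eisenberg consensus
hydrophobicity, Hopp-Woods hydrophilicity, Chou's side-chain masses,
Chou-Fasman secondary-structure propensities, Levitt helix propensity,
Vihinen flexibility, Wolfenden/Boman transfer free energies, EMBOSS pKa
values, and the Dubchak-style 7-attribute/3-class alphabets behind the
composition-transition-distribution (CTD) descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .seqdata import AMINO_ACIDS


@dataclass(frozen=True)
class PropertyScale:
    """A named numeric value per residue for all 20 standard amino acids."""

    name: str
    values: Dict[str, float]

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues "
                             f"{sorted(missing)}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def mean_over(self, seq: str) -> float:
        return sum(self.values[a] for a in seq) / len(seq)


EISENBERG = PropertyScale("eisenberg_hydrophobicity", {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08})

HOPP_WOODS = PropertyScale("hopp_woods_hydrophilicity", {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3,
    "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3,
    "V": -1.5})

SIDE_CHAIN_MASS = PropertyScale("side_chain_mass", {
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0, "Q": 72.0,
    "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0, "L": 57.0, "K": 73.0,
    "M": 75.0, "F": 91.0, "P": 42.0, "S": 31.0, "T": 45.0, "W": 130.0,
    "Y": 107.0, "V": 43.0})

CHOU_FASMAN_ALPHA = PropertyScale("chou_fasman_alpha", {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
    "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
    "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
    "Y": 0.69, "V": 1.06})

CHOU_FASMAN_BETA = PropertyScale("chou_fasman_beta", {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
    "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
    "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
    "Y": 1.47, "V": 1.70})

CHOU_FASMAN_TURN = PropertyScale("chou_fasman_turn", {
    "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19, "Q": 0.98,
    "E": 0.74, "G": 1.56, "H": 0.95, "I": 0.47, "L": 0.59, "K": 1.01,
    "M": 0.60, "F": 0.60, "P": 1.52, "S": 1.43, "T": 0.96, "W": 0.96,
    "Y": 1.14, "V": 0.50})

LEVITT_ALPHA = PropertyScale("levitt_alpha", {
    "A": 1.29, "R": 0.96, "N": 0.90, "D": 1.04, "C": 1.11, "Q": 1.27,
    "E": 1.44, "G": 0.56, "H": 1.22, "I": 0.97, "L": 1.30, "K": 1.23,
    "M": 1.47, "F": 1.07, "P": 0.52, "S": 0.82, "T": 0.82, "W": 0.99,
    "Y": 0.72, "V": 0.91})

VIHINEN_FLEXIBILITY = PropertyScale("vihinen_flexibility", {
    "A": 0.984, "R": 1.008, "N": 1.048, "D": 1.068, "C": 0.906, "Q": 1.037,
    "E": 1.094, "G": 1.031, "H": 0.950, "I": 0.927, "L": 0.935, "K": 1.102,
    "M": 0.952, "F": 0.915, "P": 1.049, "S": 1.046, "T": 0.997, "W": 0.904,
    "Y": 0.929, "V": 0.931})

# Transfer free energies behind the Boman (protein-binding) index; the index
# itself is minus the sequence mean.  Proline has no tabulated value (0.0).
BOMAN_TRANSFER = PropertyScale("boman_transfer", {
    "A": 1.81, "R": -14.92, "N": -6.64, "D": -8.72, "C": 1.28, "Q": -5.54,
    "E": -6.81, "G": 0.94, "H": -4.66, "I": 4.92, "L": 4.92, "K": -5.55,
    "M": 2.35, "F": 2.98, "P": 0.0, "S": -3.40, "T": -2.57, "W": 2.33,
    "Y": -0.14, "V": 4.04})

PK1_ALPHA_COOH = PropertyScale("pk1_alpha_cooh", {
    "A": 2.34, "R": 2.17, "N": 2.02, "D": 1.88, "C": 1.96, "Q": 2.17,
    "E": 2.19, "G": 2.34, "H": 1.82, "I": 2.36, "L": 2.36, "K": 2.18,
    "M": 2.28, "F": 1.83, "P": 1.99, "S": 2.21, "T": 2.09, "W": 2.83,
    "Y": 2.20, "V": 2.32})

PK2_ALPHA_NH3 = PropertyScale("pk2_alpha_nh3", {
    "A": 9.69, "R": 9.04, "N": 8.80, "D": 9.60, "C": 10.28, "Q": 9.13,
    "E": 9.67, "G": 9.60, "H": 9.17, "I": 9.60, "L": 9.60, "K": 8.95,
    "M": 9.21, "F": 9.13, "P": 10.60, "S": 9.15, "T": 9.10, "W": 9.39,
    "Y": 9.11, "V": 9.62})

# EMBOSS ionizable-group pKa values for Henderson-Hasselbalch charge.
PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

# ---------------------------------------------------------------------------
# CTD class alphabets: 7 attributes x 3 classes (Dubchak/PROFEAT tables).
# ---------------------------------------------------------------------------
CTD_ATTRIBUTES: Tuple[Tuple[str, Tuple[str, str, str]], ...] = (
    ("hydrophobicity", ("RKEDQN", "GASTPHY", "CLVIMFW")),
    ("normalized_vdw_volume", ("GASCTPD", "NVEQIL", "MHKFRYW")),
    ("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    ("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    ("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    ("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    ("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MSPTHY")),
)

# Three-letter-group alphabets used by the MACREL-style extractor:
# free energy of transition from random coil (aqueous) to helix (lipid),
# and solvent accessibility.
FET_GROUPS: Tuple[str, str, str] = ("ILVWAMGT", "FYSQCN", "PHKEDR")
SA_GROUPS: Tuple[str, str, str] = ("ALFCGIVW", "RKQEND", "MSPTHY")
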