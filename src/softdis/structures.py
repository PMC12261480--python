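"""Chain-level structure records.

A :class:`ChainStructure` holds one polymer chain of a crystallographic
entry: the full construct sequence (from SEQRES), per-residue presence
flags, C-alpha coordinates and B-factors, and the experiment metadata
used to pick cluster representatives (resolution, R-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: one-letter codes for the 20 standard amino acids
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine keeps its parent letter so alignments are unaffected
    "MSE": "M",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}
ONE_TO_THREE["X"] = "UNK"

NUCLEOTIDE_NAMES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U", "DI": "I",
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "T", "I": "I",
}


def three_to_one(resname: str) -> str:
    """Map a residue name to one letter; nonstandard residues become 'X'."""
    name = resname.strip().upper()
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    if name in NUCLEOTIDE_NAMES:
        return NUCLEOTIDE_NAMES[name]
    return "X"


@dataclass
class Atom:
    """One heavy atom: name (e.g. ``CA``), element symbol, coordinates (Å)."""

    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class ResidueRecord:
    """Per-residue record within the full chain sequence.

    ``seq_index`` is the 1-based position in the construct sequence.
    ``present`` is True when the residue is resolved in the ATOM records;
    unresolved residues carry no coordinates and no B-factor.
    ``bfactor`` is the C-alpha isotropic B-factor (Å²) when a C-alpha
    atom exists; residues resolved without a C-alpha stay ``bfactor=None``
    and are never flagged as flexible.
    """

    seq_index: int
    aa: str
    present: bool = False
    ca_coords: Optional[np.ndarray] = None
    bfactor: Optional[float] = None
    author_id: Optional[tuple[int, str]] = None
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ca_coords is not None:
            self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if not self.present and (self.ca_coords is not None or self.bfactor is not None):
            raise ValueError(
                f"residue {self.seq_index}: absent residues cannot carry "
                "coordinates or B-factors"
            )


@dataclass
class ChainStructure:
    """One protein (or nucleic) chain of a crystallographic entry."""

    structure_id: str
    chain_id: str
    residues: list[ResidueRecord]
    resolution: Optional[float] = None
    r_value: Optional[float] = None
    experiment: str = "X-RAY DIFFRACTION"
    molecule_class: str = "protein"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("chain must contain at least one residue")
        for i, res in enumerate(self.residues, start=1):
            if res.seq_index != i:
                raise ValueError(
                    f"chain {self.key}: seq_index must be contiguous from 1 "
                    f"(found {res.seq_index} at rank {i})"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure_id, self.chain_id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def present_mask(self) -> np.ndarray:
        return np.array([r.present for r in self.residues], dtype=bool)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~self.present_mask

    @property
    def bfactors(self) -> np.ndarray:
        """C-alpha B-factors with NaN where no value exists."""
        return np.array(
            [r.bfactor if r.bfactor is not None else np.nan for r in self.residues],
            dtype=float,
        )

    @property
    def ca_coords(self) -> np.ndarray:
        """(L, 3) C-alpha coordinates with NaN rows where no C-alpha exists."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            if r.ca_coords is not None:
                out[i] = r.ca_coords
        return out

    @property
    def has_coordinates(self) -> bool:
        return any(r.ca_coords is not None or r.atoms for r in self.residues)
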