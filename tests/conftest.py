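"""Shared test fixtures: in-memory chain builders and synthetic clusters."""

from __future__ import annotations

import numpy as np
import pytest

from softdis.structures import Atom, ChainStructure, ResidueRecord, STANDARD_AA


def make_ca_chain(
    structure_id: str = "test",
    chain_id: str = "A",
    sequence: str | None = None,
    length: int = 20,
    bfactors=None,
    missing=(),
    coords=None,
    resolution: float | None = 2.0,
    r_value: float | None = 0.20,
    molecule_class: str = "protein",
    spacing: float = 3.8,
    offset=(0.0, 0.0, 0.0),
) -> ChainStructure:
    """Build a straight C-alpha trace chain with optional missing residues."""
    if sequence is None:
        sequence = (STANDARD_AA * (length // 20 + 1))[:length]
    length = len(sequence)
    if bfactors is None:
        bfactors = [20.0] * length
    missing = set(missing)  # 1-based indices
    residues = []
    for i in range(length):
        idx = i + 1
        if idx in missing:
            residues.append(
                ResidueRecord(idx, sequence[i], present=False, author_id=(idx, ""))
            )
            continue
        xyz = (
            np.asarray(coords[i], dtype=float)
            if coords is not None
            else np.array([i * spacing, 0.0, 0.0]) + np.asarray(offset)
        )
        b = round(float(bfactors[i]), 2)
        residues.append(
            ResidueRecord(
                idx,
                sequence[i],
                present=True,
                ca_coords=xyz,
                bfactor=b,
                author_id=(idx, ""),
                atoms=[Atom("CA", "C", xyz, b)],
            )
        )
    return ChainStructure(
        structure_id=structure_id,
        chain_id=chain_id,
        residues=residues,
        resolution=resolution,
        r_value=r_value,
        molecule_class=molecule_class,
    )


def make_nucleic_chain(
    structure_id: str = "test",
    chain_id: str = "D",
    length: int = 6,
    coords=None,
) -> ChainStructure:
    """Single-atom-per-nucleotide DNA chain (C1' pseudo-atoms)."""
    residues = []
    for i in range(length):
        xyz = np.asarray(coords[i], dtype=float) if coords is not None else np.array(
            [i * 3.8, 0.0, 0.0]
        )
        residues.append(
            ResidueRecord(
                i + 1,
                "A",
                present=True,
                author_id=(i + 1, ""),
                atoms=[Atom("C1'", "C", xyz)],
            )
        )
    return ChainStructure(
        structure_id=structure_id,
        chain_id=chain_id,
        residues=residues,
        resolution=2.0,
        r_value=0.2,
        molecule_class="nucleic",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)
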