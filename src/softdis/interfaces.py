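"""Interface residue detection.

Protein-protein interfaces: a residue is at an interface when its
C-alpha lies within a distance cutoff (default 5 Å, inclusive) of a
C-alpha in a different protein chain of the same entry.

Protein-nucleic interfaces: a residue is at an interface when its
solvent-accessible surface area (ASA) decreases upon complexation with
the entry's DNA/RNA chains.  ASA is computed with a Shrake-Rupley
numerical scheme: a deterministic Fibonacci point lattice on each atom's
solvent-expanded sphere, NACCESS-compatible van der Waals radii, and a
1.4 Å probe.  Chains resolved only at the C-alpha level are handled as
one sphere per residue, which the result object declares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from softdis.structures import ChainStructure

Key = Hashable

#: NACCESS-compatible van der Waals radii by element (Å)
VDW_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.80
DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 1024
DEFAULT_CONTACT_CUTOFF = 5.0
DEFAULT_DELTA_ASA_EPSILON = 0.01


@dataclass
class InterfaceTrack:
    """Per-residue interface flags for one chain."""

    chain_key: Key
    protein_iface: np.ndarray
    nucleic_iface: np.ndarray
    partners: list[Key] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.protein_iface = np.asarray(self.protein_iface, dtype=bool)
        self.nucleic_iface = np.asarray(self.nucleic_iface, dtype=bool)

    def __len__(self) -> int:
        return len(self.protein_iface)


@dataclass
class AsaResult:
    """Per-residue accessible surface areas (Å²) for a set of chains."""

    residue_asa: dict[Key, np.ndarray]
    probe_radius: float
    points_per_atom: int
    ca_only: bool


def _empty_track(chain: ChainStructure) -> InterfaceTrack:
    n = len(chain)
    return InterfaceTrack(chain.key, np.zeros(n, bool), np.zeros(n, bool))


def protein_contacts(
    chains: Sequence[ChainStructure],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> dict[Key, InterfaceTrack]:
    """Flag residues with a cross-chain C-alpha contact within ``cutoff``.

    The cutoff is inclusive and contacts are symmetric.  A KD-tree
    accelerates the search but the result is contractually identical to
    the all-pairs distance computation.  Chains without any coordinates
    are skipped with a warning; nucleic chains are ignored here.
    """
    tracks: dict[Key, InterfaceTrack] = {}
    coords = []
    owner = []  # (chain index, residue index)
    usable = []
    for chain in chains:
        if chain.molecule_class != "protein":
            continue
        if not chain.has_coordinates:
            warnings.warn(f"chain {chain.key}: no coordinates, skipped in contacts")
            continue
        tracks[chain.key] = _empty_track(chain)
        ci = len(usable)
        usable.append(chain)
        ca = chain.ca_coords
        for i in range(len(chain)):
            if not np.isnan(ca[i]).any():
                coords.append(ca[i])
                owner.append((ci, i))
    if not coords:
        return tracks
    pts = np.asarray(coords)
    tree = cKDTree(pts)
    for a, b in tree.query_pairs(cutoff):
        ca_chain, ca_res = owner[a]
        cb_chain, cb_res = owner[b]
        if ca_chain == cb_chain:
            continue
        ka, kb = usable[ca_chain].key, usable[cb_chain].key
        tracks[ka].protein_iface[ca_res] = True
        tracks[kb].protein_iface[cb_res] = True
        if kb not in tracks[ka].partners:
            tracks[ka].partners.append(kb)
        if ka not in tracks[kb].partners:
            tracks[kb].partners.append(ka)
    return tracks


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point lattice."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _gather_atoms(
    chains: Sequence[ChainStructure],
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]], bool]:
    """Flatten atoms across chains -> (coords, radii, (chain, residue) owner)."""
    coords, radii, owner = [], [], []
    ca_only = True
    for ci, chain in enumerate(chains):
        for ri, res in enumerate(chain.residues):
            if not res.present:
                continue
            atoms = res.atoms
            if atoms:
                if len(atoms) > 1 or atoms[0].name != "CA":
                    ca_only = False
                for a in atoms:
                    coords.append(a.coords)
                    radii.append(VDW_RADII.get(a.element.upper(), DEFAULT_RADIUS))
                    owner.append((ci, ri))
            elif res.ca_coords is not None:
                coords.append(res.ca_coords)
                radii.append(VDW_RADII.get("C"))
                owner.append((ci, ri))
    if not coords:
        raise ValueError("no atoms with coordinates")
    return np.asarray(coords), np.asarray(radii), owner, ca_only


def compute_asa(
    chains: Sequence[ChainStructure],
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_POINTS,
) -> AsaResult:
    """Shrake-Rupley accessible surface area, summed per residue.

    Every heavy atom contributes a sphere of radius vdW + probe sampled
    at ``points`` lattice points; the accessible fraction times the
    sphere area is the atom's ASA.  C-alpha-only chains reduce to a
    single sphere per residue (flagged via ``AsaResult.ca_only``).
    """
    coords, radii, owner, ca_only = _gather_atoms(chains)
    sphere = _fibonacci_sphere(points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()

    per_residue: dict[Key, np.ndarray] = {
        chain.key: np.full(len(chain), np.nan) for chain in chains
    }
    for chain in chains:
        arr = per_residue[chain.key]
        for ri, res in enumerate(chain.residues):
            if res.present:
                arr[ri] = 0.0

    for i in range(len(coords)):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + max_reach) if j != i]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_r = expanded[neighbors]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r**2)[None, :] - 1e-12).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        ci, rsi = owner[i]
        per_residue[chains[ci].key][rsi] += frac * 4.0 * np.pi * ri * ri
    return AsaResult(
        residue_asa=per_residue,
        probe_radius=probe,
        points_per_atom=points,
        ca_only=ca_only,
    )


def nucleic_interfaces(
    protein_chains: Sequence[ChainStructure],
    nucleic_chains: Sequence[ChainStructure],
    probe: float = DEFAULT_PROBE,
    epsilon: float = DEFAULT_DELTA_ASA_EPSILON,
    points: int = DEFAULT_POINTS,
) -> dict[Key, InterfaceTrack]:
    """Flag protein residues buried by DNA/RNA binding.

    A residue is flagged when its ASA in isolation exceeds its ASA in
    the protein+nucleic complex by more than ``epsilon`` (Å²), the small
    tolerance absorbing numerical sampling noise.
    """
    if not protein_chains or not nucleic_chains:
        raise ValueError("need at least one protein and one nucleic chain")
    tracks: dict[Key, InterfaceTrack] = {}
    nucleic_keys = [c.key for c in nucleic_chains]
    for chain in protein_chains:
        track = _empty_track(chain)
        if not chain.has_coordinates:
            warnings.warn(f"chain {chain.key}: no coordinates, skipped in interfaces")
            tracks[chain.key] = track
            continue
        iso = compute_asa([chain], probe=probe, points=points)
        complexed = compute_asa([chain, *nucleic_chains], probe=probe, points=points)
        delta = iso.residue_asa[chain.key] - complexed.residue_asa[chain.key]
        with np.errstate(invalid="ignore"):
            track.nucleic_iface = np.nan_to_num(delta, nan=0.0) > epsilon
        if track.nucleic_iface.any():
            track.partners = list(nucleic_keys)
        tracks[chain.key] = track
    return tracks


def combine_tracks(
    protein_tracks: Optional[dict[Key, InterfaceTrack]],
    nucleic_tracks: Optional[dict[Key, InterfaceTrack]],
    chains: Sequence[ChainStructure],
) -> dict[Key, InterfaceTrack]:
    """Merge protein-contact and nucleic-burial tracks per chain."""
    out: dict[Key, InterfaceTrack] = {}
    for chain in chains:
        if chain.molecule_class != "protein":
            continue
        track = _empty_track(chain)
        for source in (protein_tracks, nucleic_tracks):
            if source and chain.key in source:
                src = source[chain.key]
                track.protein_iface |= src.protein_iface
                track.nucleic_iface |= src.nucleic_iface
                for p in src.partners:
                    if p not in track.partners:
                        track.partners.append(p)
        out[chain.key] = track
    return out


def write_interface_tsv(
    tracks: dict[Key, InterfaceTrack], path
) -> None:
    """Serialize per-entry interface tracks as TSV."""
    with open(path, "w") as fh:
        fh.write("chain\tposition\tprotein_iface\tnucleic_iface\tpartner_chains\n")
        for key, track in tracks.items():
            partners = ";".join(str(p) for p in track.partners)
            for i in range(len(track)):
                fh.write(
                    f"{key}\t{i + 1}\t{int(track.protein_iface[i])}\t"
                    f"{int(track.nucleic_iface[i])}\t{partners}\n"
                )
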