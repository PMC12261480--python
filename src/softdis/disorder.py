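"""Soft-disorder annotation: per-chain flags and per-cluster profiles.

A residue is *soft disordered* in a chain when it is either missing from
the electron density or flexible, i.e. its normalized C-alpha B-factor
b_i = (B_i - mean(B)) / std(B) exceeds 3 (strict inequality).  Across a
cluster of alternative structures of the same sequence, per-position
counts give a soft-disorder frequency and a categorical label:

* ``ID``  -- missing in every chain that aligns to the position
  (intrinsic-disorder-like; excluded from the frequency track),
* ``SD``  -- soft disordered in at least one chain but not ID,
* ``DtO`` -- missing in some chains and resolved in others
  (disorder-to-order transition; always co-occurs with SD),
* ``none``      -- aligned but never soft disordered,
* ``unaligned`` -- no cluster member maps to the position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Optional

import numpy as np

from softdis.seq_cluster import Cluster
from softdis.structures import ChainStructure

Key = Hashable

#: normalized-B-factor threshold above which a residue counts as flexible
HIGH_B_THRESHOLD = 3.0


@dataclass
class ChainAnnotation:
    """Per-residue boolean disorder tracks for one chain."""

    chain_key: Key
    missing: np.ndarray
    high_b: np.ndarray
    soft: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.missing = np.asarray(self.missing, dtype=bool)
        self.high_b = np.asarray(self.high_b, dtype=bool)
        if self.missing.shape != self.high_b.shape:
            raise ValueError("missing and high_b tracks must have equal length")
        if np.any(self.high_b & self.missing):
            raise ValueError("a missing residue has no B-factor and cannot be high-B")
        self.soft = self.missing | self.high_b

    def __len__(self) -> int:
        return len(self.missing)


@dataclass
class ClusterProfile:
    """Per-position counts and frequencies on the representative sequence."""

    representative_key: Key
    sequence: str
    n_chains: int
    n_aligned: np.ndarray
    n_missing: np.ndarray
    n_soft: np.ndarray
    n_interface_protein: np.ndarray
    n_interface_nucleic: np.ndarray

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_id(self) -> np.ndarray:
        """Positions missing in every chain observing them."""
        return (self.n_aligned > 0) & (self.n_missing == self.n_aligned)

    @property
    def is_dto(self) -> np.ndarray:
        """Positions missing somewhere but resolved elsewhere."""
        return (self.n_missing >= 1) & (self.n_missing < self.n_aligned)

    @property
    def is_sd(self) -> np.ndarray:
        """Soft disordered somewhere, excluding always-missing positions."""
        return (self.n_soft >= 1) & (self.n_missing < self.n_aligned)

    @property
    def freq_soft(self) -> np.ndarray:
        """Fraction of aligned chains calling the position soft disordered.

        NaN where undefined: unaligned positions and ID positions
        (consistently missing sites are excluded from the track).
        """
        out = np.full(len(self), np.nan)
        ok = (self.n_aligned > 0) & ~self.is_id
        out[ok] = self.n_soft[ok] / self.n_aligned[ok]
        return out

    @property
    def freq_interface_protein(self) -> np.ndarray:
        return self._freq(self.n_interface_protein)

    @property
    def freq_interface_nucleic(self) -> np.ndarray:
        return self._freq(self.n_interface_nucleic)

    def _freq(self, counts: np.ndarray) -> np.ndarray:
        out = np.full(len(self), np.nan)
        ok = self.n_aligned > 0
        out[ok] = counts[ok] / self.n_aligned[ok]
        return out

    @property
    def categories(self) -> list[str]:
        """Primary label per position: SD / ID / none / unaligned.

        DtO co-occurs with SD and is reported via :attr:`is_dto`; the
        composite string ``"SD,DtO"`` marks such positions.
        """
        out = []
        sd, idd, dto = self.is_sd, self.is_id, self.is_dto
        for i in range(len(self)):
            if self.n_aligned[i] == 0:
                out.append("unaligned")
            elif idd[i]:
                out.append("ID")
            elif sd[i] and dto[i]:
                out.append("SD,DtO")
            elif sd[i]:
                out.append("SD")
            else:
                out.append("none")
        return out

    def to_tsv(self, path: str | Path) -> None:
        cats = self.categories
        fs = self.freq_soft
        fip = self.freq_interface_protein
        fin = self.freq_interface_nucleic
        with open(path, "w") as fh:
            fh.write(
                "position\taa\tn_aligned\tn_missing\tn_soft\t"
                "freq_soft\tfreq_interface_protein\tfreq_interface_nucleic\tcategory\n"
            )
            for i, aa in enumerate(self.sequence):
                fh.write(
                    f"{i + 1}\t{aa}\t{self.n_aligned[i]}\t{self.n_missing[i]}\t"
                    f"{self.n_soft[i]}\t{_fmt(fs[i])}\t{_fmt(fip[i])}\t"
                    f"{_fmt(fin[i])}\t{cats[i]}\n"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "representative_key": list(self.representative_key)
            if isinstance(self.representative_key, tuple)
            else self.representative_key,
            "sequence": self.sequence,
            "n_chains": self.n_chains,
            "n_aligned": self.n_aligned.tolist(),
            "n_missing": self.n_missing.tolist(),
            "n_soft": self.n_soft.tolist(),
            "n_interface_protein": self.n_interface_protein.tolist(),
            "n_interface_nucleic": self.n_interface_nucleic.tolist(),
            "categories": self.categories,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _fmt(x: float) -> str:
    return "-" if np.isnan(x) else f"{x:.6g}"


def normalize_bfactors(chain: ChainStructure) -> np.ndarray:
    """Z-score the chain's C-alpha B-factors.

    Mean and population standard deviation are computed over present
    residues that carry a C-alpha B-factor; all other positions get NaN.
    A chain with constant B-factors (sigma = 0) returns all zeros, so no
    residue can exceed a positive flexibility threshold.
    """
    b = chain.bfactors
    valid = ~np.isnan(b)
    if not valid.any():
        raise ValueError(f"chain {chain.key}: no C-alpha B-factors available")
    mean = b[valid].mean()
    sigma = b[valid].std()  # population std: the chain is the whole population
    out = np.full(len(b), np.nan)
    if sigma == 0.0:
        out[valid] = 0.0
    else:
        out[valid] = (b[valid] - mean) / sigma
    return out


def annotate_chain(
    chain: ChainStructure, threshold: float = HIGH_B_THRESHOLD
) -> ChainAnnotation:
    """Compute missing / high-B / soft tracks for one chain.

    ``high_b`` is True where the normalized B-factor strictly exceeds
    ``threshold``; ``soft`` is the elementwise union with ``missing``.
    """
    normalized = normalize_bfactors(chain)
    with np.errstate(invalid="ignore"):
        high_b = np.nan_to_num(normalized, nan=-np.inf) > threshold
    return ChainAnnotation(
        chain_key=chain.key,
        missing=chain.missing_mask,
        high_b=high_b,
    )


def aggregate_cluster(
    cluster: Cluster,
    annotations: Mapping[Key, ChainAnnotation],
    interfaces: Optional[Mapping[Key, "InterfaceTrack"]] = None,
    sequences: Optional[Mapping[Key, str]] = None,
) -> ClusterProfile:
    """Accumulate member tracks onto the representative sequence.

    Each member contributes through its position mapping; representative
    positions not covered by a member's alignment receive nothing from
    that member (they do not count as missing).  Member order is
    irrelevant.
    """
    rep_key = cluster.representative_key
    if sequences is not None and rep_key in sequences:
        sequence = sequences[rep_key]
        length = len(sequence)
    else:
        length = max(
            (max(m.values(), default=0) for m in cluster.member_mappings.values()),
            default=0,
        )
        sequence = "X" * length

    n_aligned = np.zeros(length, dtype=int)
    n_missing = np.zeros(length, dtype=int)
    n_soft = np.zeros(length, dtype=int)
    n_ip = np.zeros(length, dtype=int)
    n_in = np.zeros(length, dtype=int)

    for key in cluster.member_keys:
        ann = annotations[key]
        mapping = cluster.member_mappings[key]
        if mapping and max(mapping) > len(ann):
            raise ValueError(
                f"member {key}: annotation length {len(ann)} shorter than "
                f"mapped positions"
            )
        iface = interfaces.get(key) if interfaces else None
        if iface is not None and len(iface.protein_iface) != len(ann):
            raise ValueError(f"member {key}: interface track length mismatch")
        for mpos, rpos in mapping.items():
            i = rpos - 1
            n_aligned[i] += 1
            if ann.missing[mpos - 1]:
                n_missing[i] += 1
            if ann.soft[mpos - 1]:
                n_soft[i] += 1
            if iface is not None:
                if iface.protein_iface[mpos - 1]:
                    n_ip[i] += 1
                if iface.nucleic_iface[mpos - 1]:
                    n_in[i] += 1

    return ClusterProfile(
        representative_key=rep_key,
        sequence=sequence,
        n_chains=len(cluster.member_keys),
        n_aligned=n_aligned,
        n_missing=n_missing,
        n_soft=n_soft,
        n_interface_protein=n_ip,
        n_interface_nucleic=n_in,
    )
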