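"""ML-ready dataset construction from cluster profiles.

Each record carries a representative sequence with a binary
soft-disorder label per position (1 when the cluster frequency is
positive), the frequency track itself, and a mask marking positions
where no label is defined (consistently missing / unaligned sites).
Splits are assigned at random with largest-remainder rounding so that
split sizes match the requested fractions exactly, and validation/test
records can be pruned against the training set at a sequence-identity
threshold to control leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from softdis import seq_cluster
from softdis.disorder import ClusterProfile

DEFAULT_MIN_LEN = 20
DEFAULT_MAX_LEN = 2048
DEFAULT_FRACTIONS = (0.70, 0.10, 0.20)
SPLIT_NAMES = ("train", "val", "test")


@dataclass
class DatasetRecord:
    """One representative sequence with per-position labels."""

    key: str
    sequence: str
    binary_labels: np.ndarray
    freq_labels: np.ndarray
    mask: np.ndarray
    split: Optional[str] = None

    def __post_init__(self) -> None:
        self.binary_labels = np.asarray(self.binary_labels, dtype=np.int8)
        self.freq_labels = np.asarray(self.freq_labels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.sequence)
        if not (len(self.binary_labels) == len(self.freq_labels) == len(self.mask) == n):
            raise ValueError(f"record {self.key}: track lengths differ from sequence")
        unmasked = ~self.mask
        if np.any((self.binary_labels[unmasked] == 1) != (self.freq_labels[unmasked] > 0)):
            raise ValueError(
                f"record {self.key}: binary labels must equal (freq > 0) off-mask"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def record_from_profile(profile: ClusterProfile, key: Optional[str] = None) -> DatasetRecord:
    """Collapse a cluster profile into a labeled dataset record.

    Binary label 1 marks positions soft disordered in at least one
    cluster member; ID and unaligned positions are masked rather than
    labeled 0, leaving their treatment to the training pipeline.
    """
    freq = profile.freq_soft
    mask = np.isnan(freq)
    freq_filled = np.where(mask, 0.0, freq)
    binary = (freq_filled > 0).astype(np.int8)
    if key is None:
        rk = profile.representative_key
        key = "_".join(str(p) for p in rk) if isinstance(rk, tuple) else str(rk)
    return DatasetRecord(
        key=key,
        sequence=profile.sequence,
        binary_labels=binary,
        freq_labels=freq_filled,
        mask=mask,
    )


def filter_lengths(
    records: Sequence[DatasetRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[DatasetRecord]:
    """Keep records with min_len <= length <= max_len (inclusive bounds)."""
    return [r for r in records if min_len <= len(r) <= max_len]


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def make_splits(
    records: Sequence[DatasetRecord],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> list[DatasetRecord]:
    """Assign train/val/test splits uniformly at random.

    Split sizes follow largest-remainder rounding of the fractions, so
    e.g. 100 records at (0.7, 0.1, 0.2) give exactly 70/10/20.  The
    assignment is a deterministic function of the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fractions) != len(SPLIT_NAMES):
        raise ValueError(f"expected {len(SPLIT_NAMES)} fractions")
    if len(records) < len(SPLIT_NAMES):
        raise ValueError("need at least as many records as splits")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    counts = _largest_remainder_counts(len(records), fractions)
    assignment = [""] * len(records)
    pos = 0
    for name, count in zip(SPLIT_NAMES, counts):
        for idx in order[pos : pos + count]:
            assignment[idx] = name
        pos += count
    return [replace(r, split=assignment[i]) for i, r in enumerate(records)]


def prune_splits(
    records: Sequence[DatasetRecord], threshold: float
) -> list[DatasetRecord]:
    """Drop val/test records reaching ``threshold`` identity to any
    training record (delegates to :func:`softdis.seq_cluster.prune_against`)."""
    if any(r.split is None for r in records):
        raise ValueError("splits must be assigned before pruning")
    train = {r.key: r.sequence for r in records if r.split == "train"}
    out: list[DatasetRecord] = []
    for name in SPLIT_NAMES:
        subset = [r for r in records if r.split == name]
        if name == "train":
            out.extend(subset)
            continue
        kept = seq_cluster.prune_against(
            {r.key: r.sequence for r in subset}, train, threshold
        )
        out.extend(r for r in subset if r.key in kept)
    return out


def export_dataset(
    records: Sequence[DatasetRecord],
    out_dir: str | Path,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    """Write the dataset as FASTA + per-record TSV + JSON manifest.

    Masked positions are serialized with the sentinel label ``-``.
    Frequencies are written with full precision so a re-import
    reproduces the records bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels_dir = out_dir / "labels"
    labels_dir.mkdir(exist_ok=True)
    seq_cluster.write_fasta({r.key: r.sequence for r in records}, out_dir / "sequences.fasta")
    for r in records:
        with open(labels_dir / f"{r.key}.tsv", "w") as fh:
            fh.write("position\taa\tbinary\tfreq\tmask\n")
            for i, aa in enumerate(r.sequence):
                if r.mask[i]:
                    fh.write(f"{i + 1}\t{aa}\t-\t-\t1\n")
                else:
                    fh.write(
                        f"{i + 1}\t{aa}\t{int(r.binary_labels[i])}\t"
                        f"{float(r.freq_labels[i])!r}\t0\n"
                    )
    manifest = {
        "n_records": len(records),
        "splits": {
            name: {
                "n_records": sum(1 for r in records if r.split == name),
                "n_positions": int(
                    sum((~r.mask).sum() for r in records if r.split == name)
                ),
                "n_positive": int(
                    sum(int(r.binary_labels[~r.mask].sum()) for r in records if r.split == name)
                ),
            }
            for name in SPLIT_NAMES
        },
        "label_balance": _label_balance(records),
        "seed": seed,
        "config": config or {},
        "records": {r.key: r.split for r in records},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _label_balance(records: Sequence[DatasetRecord]) -> Optional[float]:
    """Fraction of unmasked positions labeled soft disordered."""
    total = sum(int((~r.mask).sum()) for r in records)
    if total == 0:
        return None
    pos = sum(int(r.binary_labels[~r.mask].sum()) for r in records)
    return pos / total


def import_dataset(out_dir: str | Path) -> list[DatasetRecord]:
    """Re-load an exported dataset; inverse of :func:`export_dataset`."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    seqs = seq_cluster.read_fasta(out_dir / "sequences.fasta")
    records = []
    for key, seq in seqs.items():
        n = len(seq)
        binary = np.zeros(n, dtype=np.int8)
        freq = np.zeros(n, dtype=float)
        mask = np.zeros(n, dtype=bool)
        with open(out_dir / "labels" / f"{key}.tsv") as fh:
            next(fh)  # header
            for line in fh:
                pos_s, _aa, b, f, m = line.rstrip("\n").split("\t")
                i = int(pos_s) - 1
                if m == "1":
                    mask[i] = True
                else:
                    binary[i] = int(b)
                    freq[i] = float(f)
        records.append(
            DatasetRecord(
                key=key,
                sequence=seq,
                binary_labels=binary,
                freq_labels=freq,
                mask=mask,
                split=manifest["records"].get(key),
            )
        )
    return records
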