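"""Sequence-identity clustering, member-to-representative mapping, and
leakage pruning of evaluation sets.

The clustering is an incremental greedy scheme in the CD-HIT style:
sequences are processed longest first and join the first existing cluster
whose representative they match at or above both the identity and the
coverage threshold, otherwise they found a new cluster.  Identity uses
the CD-HIT denominator (identical aligned pairs divided by the shorter
sequence length); the same convention is used for database construction
and for pruning so that thresholds mean the same thing everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

Key = Hashable

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class AlignmentResult:
    """Pairwise global alignment summary.

    ``identity`` is the fraction of identical aligned pairs over the
    shorter sequence length.  ``coverage_a``/``coverage_b`` are the
    fractions of each sequence inside the aligned (non-terminal-gap)
    span.  ``mapping`` sends 1-based positions of A onto positions of B
    for residues aligned without gaps; it is strictly increasing in both
    coordinates.
    """

    identity: float
    coverage_a: float
    coverage_b: float
    mapping: dict[int, int] = field(default_factory=dict)


@dataclass
class Cluster:
    """A set of near-identical chains with per-member position mappings
    onto the representative sequence."""

    cluster_id: str
    representative_key: Key
    member_keys: list[Key]
    member_mappings: dict[Key, dict[int, int]]
    member_identities: dict[Key, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.member_keys)


def _make_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    # free end gaps: near-identical chains differ mostly by terminal tags
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def align_pair(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Globally align two sequences with affine gaps (BLOSUM62, 11/1).

    Identity uses the min-length denominator; coverage of each sequence
    is the aligned span excluding terminal gaps.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    bad = (set(seq_a) | set(seq_b)) - _VALID
    if bad:
        raise ValueError(f"unsupported residue letters: {sorted(bad)}")
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    mapping: dict[int, int] = {}
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for off in range(a1 - a0):
            i, j = a0 + off, b0 + off
            mapping[i + 1] = j + 1
            if seq_a[i] == seq_b[j]:
                matches += 1
    if mapping:
        a_idx = sorted(mapping)
        span_a = a_idx[-1] - a_idx[0] + 1
        b_vals = [mapping[i] for i in a_idx]
        span_b = b_vals[-1] - b_vals[0] + 1
    else:
        span_a = span_b = 0
    return AlignmentResult(
        identity=matches / min(len(seq_a), len(seq_b)),
        coverage_a=span_a / len(seq_a),
        coverage_b=span_b / len(seq_b),
        mapping=mapping,
    )


def greedy_cluster(
    seqs: Mapping[Key, str],
    identity_threshold: float = 0.9,
    coverage_threshold: float = 0.9,
) -> list[Cluster]:
    """Greedy incremental clustering at identity/coverage thresholds.

    Sequences are processed by decreasing length (ties broken by key),
    so representatives are the longest members and the outcome does not
    depend on input order.
    """
    if not (0.0 < identity_threshold <= 1.0 and 0.0 < coverage_threshold <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), str(k)))
    clusters: list[Cluster] = []
    for key in order:
        seq = seqs[key]
        placed = False
        for cl in clusters:
            rep_seq = seqs[cl.representative_key]
            res = align_pair(seq, rep_seq)
            if (
                res.identity >= identity_threshold
                and res.coverage_a >= coverage_threshold
                and res.coverage_b >= coverage_threshold
            ):
                cl.member_keys.append(key)
                cl.member_mappings[key] = res.mapping
                cl.member_identities[key] = res.identity
                placed = True
                break
        if not placed:
            ident = {i + 1: i + 1 for i in range(len(seq))}
            clusters.append(
                Cluster(
                    cluster_id=f"cluster_{len(clusters):05d}",
                    representative_key=key,
                    member_keys=[key],
                    member_mappings={key: ident},
                    member_identities={key: 1.0},
                )
            )
    return clusters


def prune_against(
    query_seqs: Mapping[Key, str],
    reference_seqs: Mapping[Key, str],
    identity_threshold: float,
) -> dict[Key, str]:
    """Drop queries reaching ``identity_threshold`` to any reference.

    Returns the subset of ``query_seqs`` whose maximum pairwise identity
    to every reference sequence stays below the threshold.  Used to
    de-leak validation/test splits against a training set.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    kept: dict[Key, str] = {}
    for qk, qseq in query_seqs.items():
        hit = any(
            align_pair(qseq, rseq).identity >= identity_threshold
            for rseq in reference_seqs.values()
        )
        if not hit:
            kept[qk] = qseq
    return kept


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an ordered {id: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[Key, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, seq in seqs.items():
            fh.write(f">{key}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_cluster_tsv(clusters: Sequence[Cluster], path: str | Path) -> None:
    """Emit cluster membership as TSV (cluster_id, member, identity)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_key\tidentity_to_representative\n")
        for cl in clusters:
            for key in cl.member_keys:
                ident = cl.member_identities.get(key, float("nan"))
                fh.write(f"{cl.cluster_id}\t{key}\t{ident:.4f}\n")
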