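"""Synthetic crystallographic fixtures with controlled ground truth.

The generator emulates a cluster of alternative crystal structures of
one protein sequence: each member shares a base sequence (with optional
point mutations), and carries planted missing segments (omitted from
ATOM records, listed under REMARK 465), planted flexible segments
(B-factors elevated so the normalized value strictly exceeds 3 by
construction), and optionally a partner chain positioned to create
C-alpha contacts within 5 Å over a chosen span.

Geometry is a simple extended C-alpha trace at 3.8 Å spacing; it is
sufficient for distance cutoffs and sphere-based surface area but makes
no claim of physical realism.  Everything is a deterministic function
of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from softdis.metrics import ScoreProfile
from softdis.structures import Atom, ChainStructure, ResidueRecord, STANDARD_AA
from softdis.structure_io import write_pdb

CA_SPACING = 3.8  # Å between consecutive C-alpha atoms
PARTNER_DISTANCE = 4.5  # Å, inside the 5 Å contact cutoff
NUCLEIC_DISTANCE = 4.0  # Å, close enough to bury surface


@dataclass
class FixtureSpec:
    """Parameters of one synthetic cluster.

    ``missing_segments`` and ``high_b_segments`` give, per planted
    segment, the (start, end) span (1-based, inclusive) and the member
    indices it is planted in.  ``interface_span`` plants a partner
    protein chain creating contacts on that span in every member.
    """

    n_members: int = 4
    length: int = 60
    mutation_rate: float = 0.02
    missing_segments: list[tuple[int, int, tuple[int, ...]]] = field(default_factory=list)
    high_b_segments: list[tuple[int, int, tuple[int, ...]]] = field(default_factory=list)
    interface_span: Optional[tuple[int, int]] = None
    b_base: float = 20.0
    b_noise: float = 0.3
    b_high: float = 150.0
    seed: int = 0
    tag: str = "c00"

    def validate(self) -> None:
        if self.n_members < 1 or self.length < 5:
            raise ValueError("need n_members >= 1 and length >= 5")
        if not (1 <= len(self.tag) <= 3) or not self.tag.isalnum():
            raise ValueError("tag must be 1-3 alphanumeric characters")
        if self.n_members > 36:
            raise ValueError("at most 36 members (one id character per member)")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")
        for start, end, members in self.missing_segments + self.high_b_segments:
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"segment ({start}, {end}) outside chain of length {self.length}")
            if any(m < 0 or m >= self.n_members for m in members):
                raise ValueError("segment member index out of range")
        if self.interface_span is not None:
            s, e = self.interface_span
            if not (1 <= s <= e <= self.length):
                raise ValueError("interface_span outside chain")


def _member_masks(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """(n_members, length) boolean missing and high-B masks."""
    missing = np.zeros((spec.n_members, spec.length), dtype=bool)
    for start, end, members in spec.missing_segments:
        for m in members:
            missing[m, start - 1 : end] = True
    high_b = np.zeros((spec.n_members, spec.length), dtype=bool)
    for start, end, members in spec.high_b_segments:
        for m in members:
            high_b[m, start - 1 : end] = True
    # a residue missing in a member cannot also carry a B-factor there
    high_b &= ~missing
    return missing, high_b


def _bfactors(
    rng: np.random.Generator, high: np.ndarray, missing: np.ndarray, spec: FixtureSpec
) -> np.ndarray:
    """Two-decimal B-factors whose normalized values separate cleanly.

    With k flagged residues among n present ones and a large base-to-high
    gap, the normalized value of a flagged residue is close to
    sqrt((n-k)/k); the spec is infeasible when that margin cannot
    strictly exceed 3.
    """
    b = spec.b_base + rng.uniform(-spec.b_noise, spec.b_noise, size=spec.length)
    b[high] = spec.b_high + rng.uniform(-spec.b_noise, spec.b_noise, size=int(high.sum()))
    b = np.round(b, 2)
    present = ~missing
    vals = b[present]
    mean, sigma = vals.mean(), vals.std()
    if sigma > 0:
        z = (b - mean) / sigma
        if high.any() and z[high].min() <= 3.05:
            raise ValueError(
                "infeasible spec: planted high-B residues do not exceed the "
                "normalization threshold (too many flexible residues per chain)"
            )
        quiet = present & ~high
        if quiet.any() and z[quiet].max() >= 2.95:
            raise ValueError("infeasible spec: background B-factors reach the threshold")
    elif high.any():
        raise ValueError("infeasible spec: constant B-factors cannot flag residues")
    return b


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point mutations in the chain interior.

    Termini are left untouched so that pairwise alignments of cluster
    members stay ungapped identity mappings, and the mutation count is
    capped so members always clear a 90% identity threshold.
    """
    out = list(seq)
    margin = 3
    cap = max(0, int(0.08 * len(out)))
    mutated = 0
    for i in range(margin, len(out) - margin):
        if mutated >= cap:
            break
        if rng.random() < rate:
            choices = [a for a in STANDARD_AA if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
            mutated += 1
    return "".join(out)


def _build_member(
    spec: FixtureSpec,
    idx: int,
    seq: str,
    missing: np.ndarray,
    bfac: np.ndarray,
    rng: np.random.Generator,
) -> list[ChainStructure]:
    residues = []
    for i in range(spec.length):
        x = i * CA_SPACING
        if missing[i]:
            residues.append(ResidueRecord(seq_index=i + 1, aa=seq[i], present=False,
                                          author_id=(i + 1, "")))
        else:
            coords = np.array([x, 0.0, 0.0])
            residues.append(
                ResidueRecord(
                    seq_index=i + 1,
                    aa=seq[i],
                    present=True,
                    ca_coords=coords,
                    bfactor=float(bfac[i]),
                    author_id=(i + 1, ""),
                    atoms=[Atom("CA", "C", coords, float(bfac[i]))],
                )
            )
    member_char = "0123456789abcdefghijklmnopqrstuvwxyz"[idx]
    main = ChainStructure(
        structure_id=f"{spec.tag}{member_char}",
        chain_id="A",
        residues=residues,
        resolution=round(1.5 + 0.1 * idx, 2),
        r_value=round(0.18 + 0.005 * idx, 3),
    )
    chains = [main]
    if spec.interface_span is not None:
        s, e = spec.interface_span
        span = range(s - 1, e)
        partner_seq = "".join(STANDARD_AA[rng.integers(20)] for _ in span)
        partner_res = []
        for j, i in enumerate(span):
            coords = np.array([i * CA_SPACING, PARTNER_DISTANCE, 0.0])
            partner_res.append(
                ResidueRecord(
                    seq_index=j + 1,
                    aa=partner_seq[j],
                    present=True,
                    ca_coords=coords,
                    bfactor=float(round(spec.b_base, 2)),
                    author_id=(j + 1, ""),
                    atoms=[Atom("CA", "C", coords, float(round(spec.b_base, 2)))],
                )
            )
        chains.append(
            ChainStructure(
                structure_id=main.structure_id,
                chain_id="B",
                residues=partner_res,
                resolution=main.resolution,
                r_value=main.r_value,
            )
        )
    return chains


def generate_cluster(
    spec: FixtureSpec, out_dir: Union[str, Path]
) -> tuple[list[Path], dict]:
    """Write one synthetic cluster as PDB files and return ground truth.

    Returns the file paths (one entry per member) and a dictionary with
    per-member planted masks and the expected per-position cluster
    profile (counts, soft-disorder frequency, categories) computed from
    the construction.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    base_seq = "".join(STANDARD_AA[rng.integers(20)] for _ in range(spec.length))
    missing, high_b = _member_masks(spec)

    paths: list[Path] = []
    members = []
    for m in range(spec.n_members):
        seq = base_seq if m == 0 else _mutate(rng, base_seq, spec.mutation_rate)
        bfac = _bfactors(rng, high_b[m], missing[m], spec)
        chains = _build_member(spec, m, seq, missing[m], bfac, rng)
        path = out_dir / f"{chains[0].structure_id}.pdb"
        write_pdb(chains, path)
        paths.append(path)
        members.append({"sequence": seq, "structure_id": chains[0].structure_id})

    soft = missing | high_b
    n = spec.n_members
    n_missing = missing.sum(axis=0)
    n_soft = soft.sum(axis=0)
    iface = np.zeros(spec.length, dtype=bool)
    if spec.interface_span is not None:
        s, e = spec.interface_span
        iface[s - 1 : e] = True
    # interface flags require the residue to be resolved in that member
    n_iface = (iface[None, :] & ~missing).sum(axis=0)

    is_id = n_missing == n
    freq_soft = np.where(is_id, np.nan, n_soft / n)
    categories = []
    for i in range(spec.length):
        if is_id[i]:
            categories.append("ID")
        elif n_soft[i] >= 1 and 1 <= n_missing[i] < n:
            categories.append("SD,DtO")
        elif n_soft[i] >= 1:
            categories.append("SD")
        else:
            categories.append("none")

    ground_truth = {
        "tag": spec.tag,
        "base_sequence": base_seq,
        "members": members,
        "missing": missing,
        "high_b": high_b,
        "soft": soft,
        "interface_span": spec.interface_span,
        "n_aligned": np.full(spec.length, n, dtype=int),
        "n_missing": n_missing,
        "n_soft": n_soft,
        "n_interface_protein": n_iface,
        "freq_soft": freq_soft,
        "freq_interface_protein": n_iface / n,
        "categories": categories,
    }
    return paths, ground_truth


def random_fixture_spec(
    rng: np.random.Generator,
    tag: str,
    n_members: int = 4,
    length: int = 60,
    mutation_rate: float = 0.02,
    with_interface: bool = True,
) -> FixtureSpec:
    """Draw a feasible random fixture spec: one missing segment planted
    in a strict subset of members, one always-missing segment, and one
    short flexible segment."""
    seg_len = int(rng.integers(2, 5))
    start = int(rng.integers(5, length // 3))
    n_carriers = int(rng.integers(1, n_members)) if n_members > 1 else 1
    carriers = tuple(sorted(rng.choice(n_members, size=n_carriers, replace=False).tolist()))
    id_start = int(rng.integers(length // 2, length - 10))
    hb_len = max(1, min(3, length // 15))
    hb_start = int(rng.integers(length // 3, length // 2))
    spec = FixtureSpec(
        n_members=n_members,
        length=length,
        mutation_rate=mutation_rate,
        missing_segments=[
            (start, start + seg_len - 1, carriers),
            (id_start, id_start + 2, tuple(range(n_members))),
        ],
        high_b_segments=[(hb_start, hb_start + hb_len - 1, (int(rng.integers(n_members)),))],
        interface_span=(length - 8, length - 3) if with_interface else None,
        seed=int(rng.integers(2**31 - 1)),
        tag=tag,
    )
    return spec


def beta_shape_for_auc(auc_target: float) -> float:
    """Shape t such that Beta(t, 1) positives vs Beta(1, t) negatives
    have Mann-Whitney AUC equal to ``auc_target``.

    Closed form: AUC(t) = 1 - Gamma(t+1)^2 / Gamma(2t+1), increasing
    from 0.5 at t=1 toward 1.
    """
    if not (0.5 < auc_target < 1.0):
        raise ValueError("auc_target must lie in (0.5, 1)")

    def auc(t: float) -> float:
        return 1.0 - np.exp(2.0 * gammaln(t + 1.0) - gammaln(2.0 * t + 1.0))

    return float(brentq(lambda t: auc(t) - auc_target, 1.0, 500.0, xtol=1e-12))


def generate_predictions(
    labels: Mapping[str, Union[np.ndarray, Sequence[int]]],
    auc_target: float,
    seed: int = 0,
) -> list[ScoreProfile]:
    """Draw per-residue scores with a controlled expected ROC AUC.

    Positives are drawn from Beta(t, 1) and negatives from Beta(1, t),
    with t chosen so the analytic Mann-Whitney concordance equals
    ``auc_target``.  ``auc_target=1.0`` uses disjoint uniform supports
    instead (scores above/below 0.5).  Masked labels (-1) receive NaN.
    """
    if not (0.5 < auc_target <= 1.0):
        raise ValueError("auc_target must lie in (0.5, 1]")
    rng = np.random.default_rng(seed)
    shape = None if auc_target == 1.0 else beta_shape_for_auc(auc_target)
    profiles = []
    for key, lab in labels.items():
        lab = np.asarray(lab, dtype=np.int8)
        scores = np.full(len(lab), np.nan)
        pos = lab == 1
        neg = lab == 0
        if shape is None:
            scores[pos] = rng.uniform(0.5, 1.0, size=int(pos.sum()))
            scores[neg] = rng.uniform(0.0, 0.5 - 1e-9, size=int(neg.sum()))
        else:
            scores[pos] = rng.beta(shape, 1.0, size=int(pos.sum()))
            scores[neg] = rng.beta(1.0, shape, size=int(neg.sum()))
        profiles.append(ScoreProfile(key=key, scores=scores, labels=lab))
    return profiles
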