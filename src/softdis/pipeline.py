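"""End-to-end pipeline: structure files -> cluster profiles -> dataset.

``build_profiles`` parses a corpus of crystallographic entries, detects
interfaces within each entry, annotates per-chain soft disorder,
clusters the protein sequences (90% identity / 90% coverage by
default), re-anchors every cluster on its best-resolved chain, and
aggregates member tracks into per-cluster profiles.

``build_dataset`` turns profiles into ML-ready records: redundancy
reduction by clustering representatives (50% identity / 80% coverage),
length filtering, random 70/10/20 splits, and identity pruning of
validation/test against training.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

from softdis import seq_cluster
from softdis.dataset import (
    DEFAULT_FRACTIONS,
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    DatasetRecord,
    filter_lengths,
    make_splits,
    prune_splits,
    record_from_profile,
)
from softdis.disorder import (
    HIGH_B_THRESHOLD,
    ChainAnnotation,
    ClusterProfile,
    aggregate_cluster,
    annotate_chain,
)
from softdis.interfaces import (
    DEFAULT_CONTACT_CUTOFF,
    InterfaceTrack,
    combine_tracks,
    nucleic_interfaces,
    protein_contacts,
)
from softdis.seq_cluster import Cluster, align_pair, greedy_cluster
from softdis.structure_io import parse_structure, select_representative
from softdis.structures import ChainStructure


def annotate_entry(
    chains: Sequence[ChainStructure],
    bfactor_threshold: float = HIGH_B_THRESHOLD,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> tuple[dict, dict]:
    """Per-entry disorder and interface tracks for protein chains."""
    protein = [c for c in chains if c.molecule_class == "protein"]
    nucleic = [c for c in chains if c.molecule_class == "nucleic"]
    ptracks = protein_contacts(chains, cutoff=contact_cutoff)
    ntracks: Optional[dict] = None
    if protein and nucleic and any(c.has_coordinates for c in nucleic):
        ntracks = nucleic_interfaces(protein, nucleic)
    interfaces = combine_tracks(ptracks, ntracks, chains)
    annotations = {}
    for chain in protein:
        try:
            annotations[chain.key] = annotate_chain(chain, threshold=bfactor_threshold)
        except ValueError as exc:
            warnings.warn(f"chain {chain.key} skipped: {exc}")
            interfaces.pop(chain.key, None)
    return annotations, interfaces


def _reanchor(
    cluster: Cluster,
    chains_by_key: dict,
    seqs: dict,
) -> Cluster:
    """Re-anchor a cluster on its best-determined chain.

    The greedy clustering anchors on the longest member; the reported
    representative is the chain with the best resolution (ties broken by
    R-value, then key), with member positions re-mapped onto it.
    """
    members = [chains_by_key[k] for k in cluster.member_keys]
    rep = select_representative(members)
    if rep.key == cluster.representative_key:
        return cluster
    rep_seq = seqs[rep.key]
    mappings, identities = {}, {}
    for key in cluster.member_keys:
        if key == rep.key:
            mappings[key] = {i + 1: i + 1 for i in range(len(rep_seq))}
            identities[key] = 1.0
        else:
            res = align_pair(seqs[key], rep_seq)
            mappings[key] = res.mapping
            identities[key] = res.identity
    return Cluster(
        cluster_id=cluster.cluster_id,
        representative_key=rep.key,
        member_keys=list(cluster.member_keys),
        member_mappings=mappings,
        member_identities=identities,
    )


def build_profiles(
    paths: Sequence[Union[str, Path]],
    dialect: str = "pdb",
    identity_threshold: float = 0.9,
    coverage_threshold: float = 0.9,
    bfactor_threshold: float = HIGH_B_THRESHOLD,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    xray_only: bool = True,
) -> dict:
    """Run the full annotation pipeline over a corpus of entries.

    Returns {representative key: ClusterProfile}, one per cluster of
    protein chains.  Non-X-ray entries are excluded unless
    ``xray_only=False``.
    """
    chains_by_key: dict = {}
    seqs: dict = {}
    annotations: dict = {}
    interfaces: dict = {}
    for path in paths:
        chains = parse_structure(path, dialect=dialect)
        if xray_only:
            chains = [c for c in chains if "X-RAY" in c.experiment.upper()]
        if not chains:
            continue
        ann, ifc = annotate_entry(
            chains, bfactor_threshold=bfactor_threshold, contact_cutoff=contact_cutoff
        )
        annotations.update(ann)
        interfaces.update(ifc)
        for chain in chains:
            if chain.molecule_class == "protein" and chain.key in ann:
                chains_by_key[chain.key] = chain
                seqs[chain.key] = chain.sequence

    clusters = greedy_cluster(seqs, identity_threshold, coverage_threshold)
    profiles = {}
    for cluster in clusters:
        cluster = _reanchor(cluster, chains_by_key, seqs)
        profile = aggregate_cluster(cluster, annotations, interfaces, sequences=seqs)
        profiles[cluster.representative_key] = profile
    return profiles


def profiles_to_records(profiles: dict) -> list[DatasetRecord]:
    """Collapse cluster profiles into labeled dataset records."""
    return [record_from_profile(p) for p in profiles.values()]


def build_dataset(
    profiles: dict,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    reduce_identity: float = 0.5,
    reduce_coverage: float = 0.8,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    prune_threshold: Optional[float] = 0.3,
) -> list[DatasetRecord]:
    """Profiles -> leakage-controlled ML dataset.

    Steps: length filter (20..2048 inclusive), redundancy reduction by
    clustering representative sequences at 50% identity / 80% coverage
    and keeping one record per cluster, random 70/10/20 splits, then
    pruning validation/test at ``prune_threshold`` identity against the
    training set (None skips pruning).
    """
    records = profiles_to_records(profiles)
    records = filter_lengths(records, min_len, max_len)
    if reduce_identity is not None and len(records) > 1:
        reps = {
            c.representative_key
            for c in greedy_cluster(
                {r.key: r.sequence for r in records},
                reduce_identity,
                reduce_coverage,
            )
        }
        records = [r for r in records if r.key in reps]
    records = make_splits(records, fractions=fractions, seed=seed)
    if prune_threshold is not None:
        records = prune_splits(records, prune_threshold)
    return records
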