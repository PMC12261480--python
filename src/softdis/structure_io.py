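"""Read and write crystallographic structure files at the chain level.

Parsing is backed by gemmi.  The full construct sequence comes from
SEQRES (or ``_entity_poly`` for mmCIF); residues observed in the ATOM
records are mapped onto it, and the remaining positions are the missing
(unresolved) residues, cross-checked against REMARK 465 when present.
ATOM-only files fall back to the observed residues, with gaps in the
author numbering flagged as missing.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from softdis.structures import (
    Atom,
    ChainStructure,
    ONE_TO_THREE,
    ResidueRecord,
    three_to_one,
)


class StructureParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


_R_VALUE_RE = re.compile(r"REMARK   3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)")
_REMARK465_RE = re.compile(
    r"^REMARK 465\s+(?:\d+\s+)?([A-Z0-9]{1,3})\s+(\S)\s+(-?\d+)([A-Z]?)\s*$"
)


def _parse_remark465(lines: Iterable[str]) -> dict[str, list[tuple[str, int, str]]]:
    """Extract (resname, resnum, icode) per chain from REMARK 465 lines."""
    out: dict[str, list[tuple[str, int, str]]] = {}
    for line in lines:
        m = _REMARK465_RE.match(line.rstrip())
        if m is None:
            continue
        resname, chain, num, icode = m.groups()
        if resname in ("RES", "SSSEQI"):  # header line
            continue
        out.setdefault(chain, []).append((resname, int(num), icode))
    return out


def _molecule_class(ptype: gemmi.PolymerType) -> str:
    if ptype in (gemmi.PolymerType.PeptideL, gemmi.PolymerType.PeptideD):
        return "protein"
    if ptype in (
        gemmi.PolymerType.Dna,
        gemmi.PolymerType.Rna,
        gemmi.PolymerType.DnaRnaHybrid,
    ):
        return "nucleic"
    return "other"


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    """Highest-occupancy alternate location; ties prefer altloc 'A'/first."""
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ + 1e-9:
            best = a
    return best


def _convert_residue_atoms(res: gemmi.Residue) -> list[Atom]:
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        if a.element.name == "H":
            continue
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name, group in by_name.items():
        a = _pick_altloc(group)
        out.append(
            Atom(
                name=name,
                element=a.element.name,
                coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                # PDB fixed columns carry two decimals; rounding removes
                # float32 noise from the underlying reader
                bfactor=round(float(a.b_iso), 2),
                occupancy=round(float(a.occ), 2),
            )
        )
    return out


def _build_chain(
    structure_id: str,
    chain: gemmi.Chain,
    full_sequence: list[str],
    missing_for_chain: list[tuple[str, int, str]],
    resolution: Optional[float],
    r_value: Optional[float],
    experiment: str,
) -> Optional[ChainStructure]:
    polymer = chain.get_polymer()
    if len(polymer) == 0:
        warnings.warn(f"chain {chain.name}: no polymer residues, skipped")
        return None
    mclass = _molecule_class(polymer.check_polymer_type())

    observed: dict[int, gemmi.Residue] = {}
    use_label_seq = bool(full_sequence) and all(
        r.label_seq is not None for r in polymer
    )
    if use_label_seq:
        length = len(full_sequence)
        for r in polymer:
            observed[int(r.label_seq)] = r
        seq = [three_to_one(n) for n in full_sequence]
    else:
        # ATOM-only fallback: order by author numbering, flag numbering gaps
        # (and REMARK 465 entries) as missing residues.
        authors: dict[tuple[int, str], Optional[gemmi.Residue]] = {}
        for r in polymer:
            authors[(r.seqid.num, r.seqid.icode.strip())] = r
        for resname, num, icode in missing_for_chain:
            authors.setdefault((num, icode), None)
        keys = sorted(authors)
        lo, hi = keys[0][0], keys[-1][0]
        for num in range(lo, hi + 1):
            authors.setdefault((num, ""), None)
        keys = sorted(authors)
        length = len(keys)
        missing_names = {(num, icode): rn for rn, num, icode in missing_for_chain}
        seq = []
        for idx, k in enumerate(keys, start=1):
            r = authors[k]
            if r is not None:
                observed[idx] = r
                seq.append(three_to_one(r.name))
            else:
                seq.append(three_to_one(missing_names.get(k, "UNK")))

    residues: list[ResidueRecord] = []
    missing_iter = iter(missing_for_chain)
    for idx in range(1, length + 1):
        r = observed.get(idx)
        if r is not None:
            atoms = _convert_residue_atoms(r)
            ca = next((a for a in atoms if a.name == "CA"), None)
            residues.append(
                ResidueRecord(
                    seq_index=idx,
                    aa=seq[idx - 1] if use_label_seq else seq[idx - 1],
                    present=True,
                    ca_coords=None if ca is None else ca.coords,
                    bfactor=None if ca is None else ca.bfactor,
                    author_id=(r.seqid.num, r.seqid.icode.strip()),
                    atoms=atoms,
                )
            )
        else:
            # pair unresolved SEQRES positions with REMARK 465 entries in order
            author_id = None
            entry = next(missing_iter, None)
            if entry is not None:
                resname, num, icode = entry
                author_id = (num, icode)
                if use_label_seq and three_to_one(resname) != seq[idx - 1]:
                    warnings.warn(
                        f"chain {chain.name}: REMARK 465 residue {resname} {num} "
                        f"does not match SEQRES position {idx} ({seq[idx - 1]})"
                    )
            residues.append(
                ResidueRecord(
                    seq_index=idx,
                    aa=seq[idx - 1],
                    present=False,
                    author_id=author_id,
                )
            )
    return ChainStructure(
        structure_id=structure_id,
        chain_id=chain.name,
        residues=residues,
        resolution=resolution,
        r_value=r_value,
        experiment=experiment,
        molecule_class=mclass,
    )


def parse_structure(path: str | Path, dialect: str = "pdb") -> list[ChainStructure]:
    """Parse a structure file into one :class:`ChainStructure` per chain.

    Parameters
    ----------
    path:
        Structure file in the given dialect.
    dialect:
        ``"pdb"`` or ``"mmcif"``.

    Returns
    -------
    list of ChainStructure
        Protein chains plus nucleic chains (``molecule_class="nucleic"``,
        retained because protein-nucleic interface detection needs them).
        Chains with no polymer residues are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if dialect not in ("pdb", "mmcif"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    try:
        fmt = gemmi.CoorFormat.Pdb if dialect == "pdb" else gemmi.CoorFormat.Mmcif
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no coordinate model found")
    st.setup_entities()
    st.assign_label_seq_id()

    structure_id = (st.name or path.stem).lower()[:4] or path.stem

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    r_value = None
    experiment = ""
    remark465: dict[str, list[tuple[str, int, str]]] = {}
    if dialect == "pdb":
        text_lines = path.read_text().splitlines()
        for line in text_lines:
            if line.startswith("EXPDTA"):
                experiment = line[10:].strip()
            m = _R_VALUE_RE.match(line)
            if m:
                r_value = float(m.group(1))
        remark465 = _parse_remark465(
            ln for ln in text_lines if ln.startswith("REMARK 465")
        )
    else:
        if st.meta.experiments:
            experiment = st.meta.experiments[0].method
        if st.meta.refinement:
            rv = st.meta.refinement[0].r_work
            r_value = rv if rv == rv else None  # NaN check
    if not experiment:
        experiment = "X-RAY DIFFRACTION"

    model = st[0]
    full_seqs: dict[str, list[str]] = {}
    for chain in model:
        sub = chain.get_polymer()
        ent = st.get_entity_of(sub)
        full_seqs[chain.name] = list(ent.full_sequence) if ent is not None else []

    chains: list[ChainStructure] = []
    for chain in model:
        built = _build_chain(
            structure_id,
            chain,
            full_seqs.get(chain.name, []),
            remark465.get(chain.name, []),
            resolution,
            r_value,
            experiment,
        )
        if built is not None:
            chains.append(built)
    return chains


def select_representative(chains: Sequence[ChainStructure]) -> ChainStructure:
    """Pick the best-determined chain of a cluster.

    Highest resolution (smallest Å value) wins; ties fall back to the
    smallest R-value, then to lexicographic (structure_id, chain_id).
    Chains without a stated resolution or R-value sort last.
    """
    if not chains:
        raise ValueError("cannot select a representative from an empty list")
    INF = float("inf")
    return min(
        chains,
        key=lambda c: (
            c.resolution if c.resolution is not None else INF,
            c.r_value if c.r_value is not None else INF,
            c.structure_id,
            c.chain_id,
        ),
    )


def write_pdb(chains: Sequence[ChainStructure], path: str | Path) -> None:
    """Write chains as a PDB-format file parseable by :func:`parse_structure`.

    Emits HEADER, EXPDTA, REMARK 2 (resolution), REMARK 3 (R-value),
    REMARK 465 (missing residues), SEQRES and ATOM records.  B-factors are
    written at the format's two-decimal precision, so generated fixtures
    should carry two-decimal B-factors to round-trip exactly.
    """
    if not chains:
        raise ValueError("no chains to write")
    path = Path(path)
    first = chains[0]
    lines: list[str] = []
    lines.append(
        f"HEADER    SYNTHETIC STRUCTURE                     01-JAN-00   "
        f"{first.structure_id.upper():<4}"
    )
    lines.append(f"EXPDTA    {first.experiment}")
    if first.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {first.resolution:.2f} ANGSTROMS.")
    if first.r_value is not None:
        lines.append(
            f"REMARK   3   R VALUE            (WORKING SET) : {first.r_value:.3f}"
        )
    missing_entries = []
    for ch in chains:
        for res in ch.residues:
            if not res.present:
                num, icode = res.author_id if res.author_id else (res.seq_index, "")
                missing_entries.append((_resname(ch, res), ch.chain_id, num, icode))
    if missing_entries:
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465 THE FOLLOWING RESIDUES WERE NOT LOCATED IN THE")
        lines.append("REMARK 465 EXPERIMENT.")
        lines.append("REMARK 465   M RES C SSSEQI")
        for resname, cid, num, icode in missing_entries:
            lines.append(f"REMARK 465     {resname:>3} {cid}{num:>6}{icode:<1}")
    for ch in chains:
        names = [_resname(ch, r) for r in ch.residues]
        for i in range(0, len(names), 13):
            block = names[i : i + 13]
            lines.append(
                f"SEQRES {i // 13 + 1:>3} {ch.chain_id} {len(names):>4}  "
                + " ".join(f"{n:>3}" for n in block)
            )
    serial = 1
    for ch in chains:
        last = None
        for res in ch.residues:
            if not res.present:
                continue
            num, icode = res.author_id if res.author_id else (res.seq_index, "")
            resname = _resname(ch, res)
            atoms = res.atoms or (
                [Atom("CA", "C", res.ca_coords, res.bfactor or 0.0)]
                if res.ca_coords is not None
                else []
            )
            for a in atoms:
                x, y, z = a.coords
                lines.append(
                    f"ATOM  {serial:>5} {a.name:^4}{resname:>4} {ch.chain_id}"
                    f"{num:>4}{icode:<1}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{a.occupancy:6.2f}{a.bfactor:6.2f}          "
                    f"{a.element:>2}"
                )
                serial += 1
                last = (resname, num, icode)
        if last is not None:
            lines.append(
                f"TER   {serial:>5}      {last[0]:>3} {ch.chain_id}{last[1]:>4}{last[2]:<1}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _resname(chain: ChainStructure, res: ResidueRecord) -> str:
    if chain.molecule_class == "nucleic":
        return f"D{res.aa}" if res.aa in "ACGT" else res.aa
    return ONE_TO_THREE.get(res.aa, "UNK")
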