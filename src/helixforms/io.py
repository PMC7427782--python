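"""PDB / mmCIF reading and writing, and conformer bookkeeping.

Parsing and serialisation are delegated to gemmi; this module converts
between gemmi's hierarchy and the package's own :class:`~helixforms.model`
types, keeping author residue numbering, alternate-location labels and
occupancies intact, and provides the operations that turn a dual-conformation
model (altloc-duplicated residue ranges) into complete single-conformer
structures.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Optional

import gemmi
import numpy as np

from .model import AtomRecord, ChainModel, Residue, Structure

__all__ = [
    "read_structure",
    "write_structure",
    "split_conformers",
    "conformer_occupancies",
    "classify_entity_role",
]

_METAL_RESIDUES = {"ZN", "MG", "CA", "MN", "FE", "NA", "K", "NI", "CU", "CO", "CD"}


def classify_entity_role(residues: list[Residue]) -> str:
    """Heuristic functional role of a chain.

    Long polypeptides (>=150 residues) are called ``receptor``, shorter ones
    (>=30, the size of an antibody variable domain and up) ``antibody``,
    single metal residues ``ion``, non-water heteroatom content ``ligand``,
    and anything else (e.g. pure water chains) ``other``. Override the result
    on the chain when the heuristic is wrong for a particular deposition.
    """
    n_aa = sum(1 for r in residues if r.is_amino_acid)
    if n_aa >= 150:
        return "receptor"
    if n_aa >= 30:
        return "antibody"
    non_water = [r for r in residues if not r.is_water]
    if not non_water:
        return "other"
    if all(r.name in _METAL_RESIDUES for r in non_water):
        return "ion"
    if n_aa == 0:
        return "ligand"
    return "other"


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("pdb", "mmcif"):
            raise ValueError(f"unknown format {fmt!r} (expected 'pdb' or 'mmcif')")
        return fmt
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".cif", ".mmcif")):
        return "mmcif"
    return "pdb"


def read_structure(
    path: str | Path,
    format: Optional[str] = None,
    skip_waters: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file (optionally gzip-compressed).

    All ATOM/HETATM records are represented; author numbering, altloc labels
    and occupancies are preserved. Hydrogens present in the file are kept at
    this stage (geometry operations rebuild amide hydrogens themselves).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _detect_format(path, format)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc

    structure = Structure(id=st.name or path.stem, source_format=fmt)
    if len(st) == 0:
        return structure
    if len(st) > 1:
        warnings.warn(
            f"{path}: {len(st)} models present, using the first", stacklevel=2
        )
    model = st[0]
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if skip_waters and gres.is_water():
                continue
            res = Residue(
                number=gres.seqid.num,
                name=gres.name,
                insertion_code=(gres.seqid.icode or "").strip(),
            )
            for gatom in gres:
                res.add_atom(
                    AtomRecord(
                        name=gatom.name,
                        element=gatom.element.name,
                        position=np.array(
                            [gatom.pos.x, gatom.pos.y, gatom.pos.z]
                        ),
                        altloc=gatom.altloc.strip("\x00") if gatom.altloc else "",
                        occupancy=float(gatom.occ),
                        b_factor=float(gatom.b_iso),
                    )
                )
            residues.append(res)
        if not residues:
            continue
        chain = ChainModel(
            chain_id=gchain.name,
            residues=residues,
            entity_role=classify_entity_role(residues),
        )
        structure.chains.append(chain)
    return structure


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id or "XXXX"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gres.het_flag = "A" if res.is_amino_acid else "H"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                element = gemmi.Element(atom.element)
                if element.name == "X" and atom.element.upper() != "X":
                    raise ValueError(
                        f"chain {chain.chain_id} residue {res.name}{res.number}: "
                        f"unmappable element {atom.element!r} for atom {atom.name!r}"
                    )
                gatom.element = element
                gatom.pos = gemmi.Position(*atom.position)
                gatom.altloc = atom.altloc or "\x00"
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.b_factor
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(
    structure: Structure, path: str | Path, format: Optional[str] = None
) -> None:
    """Write a structure as PDB or mmCIF (format inferred from the suffix)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    st = _to_gemmi(structure)
    if fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def split_conformers(
    structure: Structure,
    mapping: Optional[Mapping[str, str]] = None,
    fill_rule: str = "shared",
) -> dict[str, Structure]:
    """Split a dual/multi-conformation model into single-conformer structures.

    ``mapping`` sends each altloc label to a conformer name (default: each
    label maps to itself). Every output contains, per residue, the
    blank-altloc atoms plus the atoms of exactly one label; residues lacking
    that label fall back to their blank-altloc atoms (``fill_rule='shared'``).
    Labels are cleared in the outputs, so no altloc duplication remains.
    """
    if fill_rule != "shared":
        raise ValueError(f"unknown fill_rule {fill_rule!r}")
    labels = set()
    for chain in structure.chains:
        for res in chain.residues:
            labels |= res.altlocs()
    if mapping is None:
        mapping = {label: label for label in sorted(labels)}
    unknown = labels - set(mapping)
    if unknown:
        raise ValueError(f"altloc labels {sorted(unknown)} missing from mapping")
    if not mapping:
        # no altlocs anywhere: single conformer equals the input
        return {"full": structure.copy()}

    outputs: dict[str, Structure] = {}
    for label, name in mapping.items():
        out = Structure(
            id=f"{structure.id}_{name}" if structure.id else name,
            source_format=structure.source_format,
        )
        for chain in structure.chains:
            new_residues = []
            for res in chain.residues:
                blank = [a for a in res.atoms if a.altloc == ""]
                chosen = [a for a in res.atoms if a.altloc == label]
                if not blank and not chosen and res.atoms:
                    raise ValueError(
                        f"chain {chain.chain_id} residue {res.name}{res.number}: "
                        f"no blank-altloc atoms and no altloc {label!r} atoms"
                    )
                atoms = []
                for a in blank + chosen:
                    a = a.copy()
                    a.altloc = ""
                    atoms.append(a)
                new_residues.append(
                    Residue(res.number, res.name, atoms, res.insertion_code)
                )
            out.chains.append(
                ChainModel(chain.chain_id, new_residues, chain.entity_role)
            )
        outputs[name] = out
    return outputs


def conformer_occupancies(
    structure: Structure,
    residue_range: Optional[tuple[int, int]] = None,
    chain_id: Optional[str] = None,
) -> dict[str, float]:
    """Mean occupancy per altloc label over a residue range, 2 decimals.

    Returns an empty mapping when the range holds no altloc-bearing atoms.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for chain in structure.chains:
        if chain_id is not None and chain.chain_id != chain_id:
            continue
        for res in chain.select(residue_range):
            for atom in res.atoms:
                if atom.altloc:
                    sums[atom.altloc] = sums.get(atom.altloc, 0.0) + atom.occupancy
                    counts[atom.altloc] = counts.get(atom.altloc, 0) + 1
    return {
        label: round(sums[label] / counts[label], 2) for label in sorted(sums)
    }
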