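"""In-memory hierarchy for crystallographic models.

The hierarchy is deliberately small: Structure -> ChainModel -> Residue ->
AtomRecord, with author residue numbering throughout (the numbering used in
publications, e.g. Arg264), alternate-location labels and fractional
occupancies preserved exactly as deposited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainModel",
    "Structure",
    "STANDARD_AMINO_ACIDS",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)


@dataclass
class AtomRecord:
    """One atom of a crystallographic model.

    ``altloc`` is the single-character alternate-location label; the empty
    string means the atom belongs to every conformer. ``occupancy`` is the
    refined fractional occupancy in [0, 1].
    """

    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )
        if len(self.altloc) > 1:
            raise ValueError(f"atom {self.name}: altloc must be one character")

    def copy(self) -> "AtomRecord":
        return AtomRecord(
            self.name,
            self.element,
            self.position.copy(),
            self.altloc,
            self.occupancy,
            self.b_factor,
        )


@dataclass
class Residue:
    """A residue keyed by author number (+ optional insertion code)."""

    number: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for atom in self.atoms:
            key = (atom.name, atom.altloc)
            if key in seen:
                raise ValueError(
                    f"residue {self.name}{self.number}: duplicate atom {key}"
                )
            seen.add(key)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def add_atom(self, atom: AtomRecord) -> None:
        if any(a.name == atom.name and a.altloc == atom.altloc for a in self.atoms):
            raise ValueError(
                f"residue {self.name}{self.number}: duplicate atom "
                f"({atom.name!r}, {atom.altloc!r})"
            )
        self.atoms.append(atom)

    def atom(self, name: str, altloc: Optional[str] = None) -> Optional[AtomRecord]:
        """Return the named atom.

        With ``altloc=None`` a blank-altloc atom is preferred; if only
        labelled copies exist the first is returned (useful on
        single-conformer views where labels were cleared).
        """
        blank = None
        labelled = None
        for atom in self.atoms:
            if atom.name != name:
                continue
            if altloc is not None:
                if atom.altloc == altloc:
                    return atom
                continue
            if atom.altloc == "":
                blank = blank or atom
            else:
                labelled = labelled or atom
        if altloc is not None:
            return None
        return blank or labelled

    def altlocs(self) -> set[str]:
        return {a.altloc for a in self.atoms if a.altloc}

    @property
    def is_amino_acid(self) -> bool:
        return self.name in STANDARD_AMINO_ACIDS

    @property
    def is_water(self) -> bool:
        return self.name in ("HOH", "WAT", "DOD")

    def copy(self) -> "Residue":
        return Residue(
            self.number,
            self.name,
            [a.copy() for a in self.atoms],
            self.insertion_code,
        )


@dataclass
class ChainModel:
    """An ordered chain of residues with a coarse functional role.

    ``entity_role`` is one of receptor / antibody / ligand / ion / other; it
    is assigned heuristically on read and may be overridden.
    """

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    entity_role: str = "other"

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError(
                f"chain {self.chain_id}: residue numbering not strictly increasing"
            )

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int, insertion_code: str = "") -> Optional[Residue]:
        for res in self.residues:
            if res.number == number and res.insertion_code == insertion_code:
                return res
        return None

    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def select(self, residue_range: Optional[tuple[int, int]] = None) -> list[Residue]:
        """Residues with author number in the inclusive range (or all)."""
        if residue_range is None:
            return list(self.residues)
        lo, hi = residue_range
        return [r for r in self.residues if lo <= r.number <= hi]

    def ca_coordinates(
        self, residue_range: Optional[tuple[int, int]] = None
    ) -> tuple[np.ndarray, list[int]]:
        """Cα coordinates and their residue numbers over a range."""
        coords, numbers = [], []
        for res in self.select(residue_range):
            ca = res.atom("CA")
            if ca is not None:
                coords.append(ca.position)
                numbers.append(res.number)
        if coords:
            return np.array(coords), numbers
        return np.empty((0, 3)), numbers

    def has_altlocs(self) -> bool:
        return any(res.altlocs() for res in self.residues)

    def copy(self) -> "ChainModel":
        return ChainModel(
            self.chain_id, [r.copy() for r in self.residues], self.entity_role
        )


@dataclass
class Structure:
    """A full model: uniquely identified chains plus format provenance."""

    id: str = ""
    chains: list[ChainModel] = field(default_factory=list)
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"structure {self.id}: duplicate chain ids")

    def __iter__(self) -> Iterator[ChainModel]:
        return iter(self.chains)

    def chain(self, chain_id: str) -> ChainModel:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(f"structure {self.id}: no chain {chain_id!r}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def has_altlocs(self) -> bool:
        return any(c.has_altlocs() for c in self.chains)

    def copy(self) -> "Structure":
        return Structure(self.id, [c.copy() for c in self.chains], self.source_format)
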