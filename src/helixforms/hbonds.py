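"""Main-chain hydrogen-bond geometry and α vs 3₁₀ classification.

Amide hydrogens are always rebuilt from heavy-atom geometry (X-ray
depositions at ~3 Å resolution carry no experimental hydrogens), then every
CO(i)···HN(j) candidate at helical offsets j−i ∈ {3, 4} is scored with two
criteria: the O···N distance, rounded to one decimal, must be ≤ 3.5 Å, and
the O···H−N angle measured at the hydrogen (180° = linear) must be ≥ 130°.
Proline, lacking the amide hydrogen, can never donate. Bonds with rounded
O···N distance in 3.2–3.5 Å are flagged weak. A residue supported only by
i→i+3 bonds is 3₁₀-helical, only by i→i+4 bonds α-helical; a residue with
both is labelled by the shorter O···N distance (ties → α).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .geom import bond_angle, unit
from .model import AtomRecord, ChainModel, Residue, Structure

__all__ = [
    "GeometryConfig",
    "HBondRecord",
    "HelixClassification",
    "build_amide_hydrogens",
    "scan_helical_hbonds",
    "count_bonds",
    "classify_helix",
    "named_atom_distance",
    "residue_contacts",
    "coordination_sphere",
    "hbond_table",
]

AMIDE_H = "H"


@dataclass(frozen=True)
class GeometryConfig:
    """Every threshold and reporting convention used by the geometry stages.

    hbond_max_ON : maximum O···N distance for a hydrogen bond (Å); applied
        to the 1-decimal-rounded distance unless ``round_distances`` is off.
    hbond_min_angle : minimum O···H−N angle at the hydrogen (degrees).
    nh_length : rebuilt N–H bond length (Å).
    weak_band : rounded-distance band labelled "weak" (Å).
    contact_cutoff : heavy-atom residue-contact cutoff (Å), inclusive.
    coordination_cutoff : metal-coordination cutoff (Å), inclusive.
    """

    hbond_max_ON: float = 3.5
    hbond_min_angle: float = 130.0
    nh_length: float = 1.00
    weak_band: tuple[float, float] = (3.2, 3.5)
    contact_cutoff: float = 4.0
    coordination_cutoff: float = 2.6
    round_distances: bool = True

    def __post_init__(self) -> None:
        for name in ("hbond_max_ON", "hbond_min_angle", "nh_length",
                     "contact_cutoff", "coordination_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.weak_band
        if not 0 < lo <= hi <= self.hbond_max_ON:
            raise ValueError("weak_band must lie within (0, hbond_max_ON]")


DEFAULT_CONFIG = GeometryConfig()


@dataclass
class HBondRecord:
    """One CO(i)···HN(j) candidate with its verdict."""

    acceptor_residue: int
    donor_residue: int
    offset: int
    d_ON: float
    angle_OHN: float  # NaN when the donor has no rebuilt hydrogen
    is_bond: bool
    is_weak: bool
    donor_is_proline: bool
    acceptor_name: str = ""
    donor_name: str = ""


@dataclass
class HelixClassification:
    """Per-residue helical labels with the bonds supporting each label."""

    labels: dict[int, str] = field(default_factory=dict)
    support: dict[int, list[HBondRecord]] = field(default_factory=dict)
    records: list[HBondRecord] = field(default_factory=list)

    def label(self, residue_number: int) -> str:
        return self.labels.get(residue_number, "turn_or_none")


def build_amide_hydrogens(
    chain: ChainModel, config: GeometryConfig = DEFAULT_CONFIG
) -> tuple[ChainModel, list[int]]:
    """Place backbone amide hydrogens; returns (new chain, gap report).

    H sits at ``nh_length`` from N in the C(i−1)–N–CA plane, opposite the
    bisector of the N→C(i−1) and N→CA unit vectors. The first residue and
    prolines get no hydrogen. Residues with missing backbone atoms are
    skipped and listed in the gap report.
    """
    if chain.has_altlocs():
        raise ValueError(
            f"chain {chain.chain_id} still carries altlocs; split conformers first"
        )
    out = chain.copy()
    gaps: list[int] = []
    for prev, res in zip(out.residues, out.residues[1:]):
        if res.name == "PRO":
            continue
        c_prev = prev.atom("C")
        n = res.atom("N")
        ca = res.atom("CA")
        if c_prev is None or n is None or ca is None:
            gaps.append(res.number)
            continue
        # skip across chain breaks: C(i-1)-N(i) must be a real peptide bond
        if np.linalg.norm(c_prev.position - n.position) >= 2.0:
            gaps.append(res.number)
            continue
        direction = -(unit(c_prev.position - n.position) + unit(ca.position - n.position))
        h_pos = n.position + config.nh_length * unit(direction)
        if res.atom(AMIDE_H) is None:
            res.add_atom(AtomRecord(AMIDE_H, "H", h_pos))
        else:
            res.atom(AMIDE_H).position = h_pos
    return out, gaps


def _ensure_hydrogens(
    chain: ChainModel, config: GeometryConfig
) -> ChainModel:
    has_h = any(r.atom(AMIDE_H) is not None for r in chain.residues)
    if has_h:
        return chain
    built, _ = build_amide_hydrogens(chain, config)
    return built


def _verdict(
    d_on: float, angle: float, donor_is_pro: bool, config: GeometryConfig
) -> tuple[bool, bool]:
    d_eff = round(d_on, 1) if config.round_distances else d_on
    lo, hi = config.weak_band
    if donor_is_pro or not np.isfinite(angle):
        return False, False
    bonded = d_eff <= config.hbond_max_ON and angle >= config.hbond_min_angle
    weak = bonded and lo <= d_eff <= hi
    return bonded, weak


def scan_helical_hbonds(
    chain: ChainModel,
    residue_range: tuple[int, int],
    config: GeometryConfig = DEFAULT_CONFIG,
) -> list[HBondRecord]:
    """CO(i)···HN(i+3) and CO(i)···HN(i+4) records for acceptors i in range."""
    chain = _ensure_hydrogens(chain, config)
    numbers = set(chain.residue_numbers())
    lo, hi = residue_range
    if not any(lo <= n <= hi for n in numbers):
        raise ValueError(
            f"range {residue_range} outside chain {chain.chain_id} residues"
        )
    records: list[HBondRecord] = []
    for i in range(lo, hi + 1):
        acceptor = chain.residue(i)
        if acceptor is None or acceptor.atom("O") is None:
            continue
        o_pos = acceptor.atom("O").position
        for offset in (3, 4):
            donor = chain.residue(i + offset)
            if donor is None or donor.atom("N") is None:
                continue
            n_pos = donor.atom("N").position
            d_on = float(np.linalg.norm(o_pos - n_pos))
            h = donor.atom(AMIDE_H)
            is_pro = donor.name == "PRO"
            angle = (
                bond_angle(o_pos, h.position, n_pos) if h is not None else float("nan")
            )
            is_bond, is_weak = _verdict(d_on, angle, is_pro, config)
            records.append(
                HBondRecord(
                    acceptor_residue=i,
                    donor_residue=i + offset,
                    offset=offset,
                    d_ON=d_on,
                    angle_OHN=angle,
                    is_bond=is_bond,
                    is_weak=is_weak,
                    donor_is_proline=is_pro,
                    acceptor_name=acceptor.name,
                    donor_name=donor.name,
                )
            )
    return records


def count_bonds(
    records: Iterable[HBondRecord],
    offset: int,
    acceptor_range: Optional[tuple[int, int]] = None,
) -> int:
    """Number of accepted bonds at one offset with acceptor in a range."""
    total = 0
    for rec in records:
        if rec.offset != offset or not rec.is_bond:
            continue
        if acceptor_range is not None:
            lo, hi = acceptor_range
            if not lo <= rec.acceptor_residue <= hi:
                continue
        total += 1
    return total


def classify_helix(
    chain: ChainModel,
    residue_range: tuple[int, int],
    config: GeometryConfig = DEFAULT_CONFIG,
) -> HelixClassification:
    """Label residues in range as alpha / three10 / turn_or_none.

    A residue participates in a bond as acceptor or donor; offset-4
    participation → alpha, offset-3 → three10, both → the shorter O···N
    distance decides (ties → alpha).
    """
    lo, hi = residue_range
    # widen the scan so residues in range can appear as donors
    numbers = chain.residue_numbers()
    scan_lo = max(min(numbers), lo - 4)
    scan_hi = min(max(numbers), hi)
    records = scan_helical_hbonds(chain, (scan_lo, scan_hi), config)
    result = HelixClassification(records=list(records))
    for res in chain.select(residue_range):
        mine = [
            r
            for r in records
            if r.is_bond and res.number in (r.acceptor_residue, r.donor_residue)
        ]
        by3 = [r for r in mine if r.offset == 3]
        by4 = [r for r in mine if r.offset == 4]
        if by3 and by4:
            d3 = min(r.d_ON for r in by3)
            d4 = min(r.d_ON for r in by4)
            label = "three10" if d3 < d4 else "alpha"
            support = by3 if d3 < d4 else by4
        elif by3:
            label, support = "three10", by3
        elif by4:
            label, support = "alpha", by4
        else:
            label, support = "turn_or_none", []
        result.labels[res.number] = label
        result.support[res.number] = support
    return result


def named_atom_distance(
    chain: ChainModel,
    residue_a: int,
    atom_a: str,
    residue_b: int,
    atom_b: str,
    config: GeometryConfig = DEFAULT_CONFIG,
) -> float:
    """Distance between two named atoms, at reporting precision (1 d.p.)."""
    pair = []
    for number, name in ((residue_a, atom_a), (residue_b, atom_b)):
        res = chain.residue(number)
        atom = res.atom(name) if res is not None else None
        if atom is None:
            raise ValueError(
                f"chain {chain.chain_id}: atom {name!r} of residue {number} not found"
            )
        pair.append(atom.position)
    d = float(np.linalg.norm(pair[0] - pair[1]))
    return round(d, 1) if config.round_distances else d


def _gather(
    structure: Structure | ChainModel,
    selection: Sequence[tuple[str, Optional[tuple[int, int]]]] | tuple,
) -> list[tuple[str, Residue]]:
    """Resolve a selection into (chain_id, residue) pairs.

    A selection is a list of ``(chain_id, residue_range-or-None)`` items;
    a bare ``(chain_id, range)`` tuple is accepted too.
    """
    if isinstance(structure, ChainModel):
        structure = Structure(chains=[structure])
    if selection and isinstance(selection[0], str):
        selection = [selection]  # single (chain_id, range) tuple
    out: list[tuple[str, Residue]] = []
    for chain_id, residue_range in selection:
        chain = structure.chain(chain_id)
        out.extend((chain_id, r) for r in chain.select(residue_range))
    return out


@dataclass
class ContactRecord:
    chain_a: str
    residue_a: int
    name_a: str
    chain_b: str
    residue_b: int
    name_b: str
    min_distance: float
    atom_a: str = ""
    atom_b: str = ""


def residue_contacts(
    structure: Structure | ChainModel,
    selection_a,
    selection_b,
    cutoff: Optional[float] = None,
    config: GeometryConfig = DEFAULT_CONFIG,
) -> list[ContactRecord]:
    """Residue pairs with any heavy-atom distance ≤ cutoff (inclusive).

    Hydrogens are excluded; the list is sorted by minimum distance. The two
    selections may name different chains, ligand residues included.
    """
    cutoff = config.contact_cutoff if cutoff is None else cutoff
    group_a = _gather(structure, selection_a)
    group_b = _gather(structure, selection_b)
    if not group_a or not group_b:
        raise ValueError("empty selection")
    contacts = []
    for ca_id, res_a in group_a:
        pos_a = np.array(
            [a.position for a in res_a.atoms if a.element.upper() != "H"]
        )
        if pos_a.size == 0:
            continue
        for cb_id, res_b in group_b:
            if ca_id == cb_id and res_a.key == res_b.key:
                continue
            heavy_b = [a for a in res_b.atoms if a.element.upper() != "H"]
            if not heavy_b:
                continue
            pos_b = np.array([a.position for a in heavy_b])
            dists = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
            idx = np.unravel_index(np.argmin(dists), dists.shape)
            dmin = float(dists[idx])
            if dmin <= cutoff:
                heavy_a = [a for a in res_a.atoms if a.element.upper() != "H"]
                contacts.append(
                    ContactRecord(
                        ca_id, res_a.number, res_a.name,
                        cb_id, res_b.number, res_b.name,
                        dmin,
                        atom_a=heavy_a[idx[0]].name,
                        atom_b=heavy_b[idx[1]].name,
                    )
                )
    contacts.sort(key=lambda c: c.min_distance)
    return contacts


@dataclass
class CoordinationRecord:
    metal_chain: str
    metal_residue: int
    metal_name: str
    atoms: list[tuple[str, int, str, str, float]]
    # each entry: (chain_id, residue_number, residue_name, atom_name, distance)


def coordination_sphere(
    structure: Structure,
    center_element: str = "Zn",
    cutoff: Optional[float] = None,
    config: GeometryConfig = DEFAULT_CONFIG,
) -> list[CoordinationRecord]:
    """Coordinating atoms around every atom of a metal element.

    Water oxygens, carbons and hydrogens are excluded from the sphere;
    the cutoff is inclusive. An absent element yields an empty list with a
    warning rather than an error.
    """
    import warnings

    cutoff = config.coordination_cutoff if cutoff is None else cutoff
    target = center_element.capitalize()
    spheres: list[CoordinationRecord] = []
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                if atom.element.capitalize() != target:
                    continue
                entries = []
                for other_chain in structure.chains:
                    for other in other_chain.residues:
                        if other.is_water:
                            continue
                        for oat in other.atoms:
                            if oat is atom:
                                continue
                            if oat.element.upper() in ("C", "H") or (
                                oat.element.capitalize() == target
                            ):
                                continue
                            d = float(np.linalg.norm(oat.position - atom.position))
                            if d <= cutoff:
                                entries.append(
                                    (
                                        other_chain.chain_id,
                                        other.number,
                                        other.name,
                                        oat.name,
                                        d,
                                    )
                                )
                entries.sort(key=lambda e: e[4])
                spheres.append(
                    CoordinationRecord(chain.chain_id, res.number, res.name, entries)
                )
    if not spheres:
        warnings.warn(f"no {center_element} atoms in structure", stacklevel=2)
    return spheres


def hbond_table(records: Iterable[HBondRecord], chain_id: str = "") -> str:
    """TSV rendering of hydrogen-bond records (1 d.p. Å, integer degrees)."""
    lines = ["chain\ti\tres_i\tj\tres_j\toffset\td_ON\tangle_OHN\tis_bond\tlabel"]
    for r in records:
        angle = "" if not np.isfinite(r.angle_OHN) else f"{r.angle_OHN:.0f}"
        label = "weak" if r.is_weak else ("bond" if r.is_bond else "none")
        lines.append(
            f"{chain_id}\t{r.acceptor_residue}\t{r.acceptor_name}\t"
            f"{r.donor_residue}\t{r.donor_name}\t{r.offset}\t"
            f"{r.d_ON:.1f}\t{angle}\t{int(r.is_bond)}\t{label}"
        )
    return "\n".join(lines) + "\n"
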