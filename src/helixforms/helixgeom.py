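"""Backbone dihedrals, helix axes, bend angles and the helical advance.

The advance is the straight-line Cα(i)→Cα(i+span) distance — the simplest
metric of how stretched a helical segment is; for the ideal α-helix at span
7 it equals the standard 10.5 Å. Helix axes come from the bisector (Kahn)
construction: for points on any ideal helix the bisector
(Cα(i−1)−Cα(i)) + (Cα(i+1)−Cα(i)) is exactly perpendicular to the helix
axis, so the axis is recovered as the common normal of the bisectors —
exact for ideal helices of any length, robust to noise through a
least-squares normal (smallest principal component of the bisector set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geom import dihedral_angle, unit
from .model import ChainModel

__all__ = [
    "RegionScheme",
    "HelixAxis",
    "backbone_dihedrals",
    "helix_axis",
    "interaxis_angle",
    "helical_advance",
    "dihedral_table",
]

PEPTIDE_BOND_MAX = 2.0  # Å; C(i)–N(i+1) beyond this is a chain break


@dataclass(frozen=True)
class RegionScheme:
    """Named residue ranges of the mobile helix IV–ICL2–helix V cassette.

    Defaults follow the author numbering of AdipoR1: intracellular loop 2
    (ICL2) 255–263 and the helix-V partition NT 264–267 / M1 268–272 /
    M2 273–280 / CT 281–288; the mobile region 250–288 is the part excluded
    from rigid-body fit frames, and 250–279 is the dual-conformation range.
    """

    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "ICL2": (255, 263),
            "NT": (264, 267),
            "M1": (268, 272),
            "M2": (273, 280),
            "CT": (281, 288),
            "mobile_region": (250, 288),
            "dual_region": (250, 279),
        }
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise ValueError(f"region {name}: empty range {lo}-{hi}")

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regions


DEFAULT_REGIONS = RegionScheme()


def backbone_dihedrals(
    chain: ChainModel,
) -> dict[int, tuple[Optional[float], Optional[float], Optional[float]]]:
    """Per-residue (φ, ψ, ω) in degrees, ``None`` where undefined.

    φ of the first residue and ψ/ω of the last are undefined, as are values
    across chain breaks (C(i)–N(i+1) ≥ 2 Å) or missing backbone atoms.
    """
    out: dict[int, tuple] = {}
    residues = chain.residues
    for idx, res in enumerate(residues):
        prev = residues[idx - 1] if idx > 0 else None
        nxt = residues[idx + 1] if idx + 1 < len(residues) else None
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        phi = psi = omega = None
        if None not in (n, ca, c):
            if prev is not None and prev.atom("C") is not None:
                c_prev = prev.atom("C")
                if np.linalg.norm(c_prev.position - n.position) < PEPTIDE_BOND_MAX:
                    phi = dihedral_angle(
                        c_prev.position, n.position, ca.position, c.position
                    )
            if nxt is not None and nxt.atom("N") is not None:
                n_next = nxt.atom("N")
                if np.linalg.norm(c.position - n_next.position) < PEPTIDE_BOND_MAX:
                    psi = dihedral_angle(
                        n.position, ca.position, c.position, n_next.position
                    )
                    if nxt.atom("CA") is not None:
                        omega = dihedral_angle(
                            ca.position,
                            c.position,
                            n_next.position,
                            nxt.atom("CA").position,
                        )
        out[res.number] = (phi, psi, omega)
    return out


@dataclass
class HelixAxis:
    """A fitted local helix axis: unit direction (N→C) plus centroid."""

    direction: np.ndarray
    centroid: np.ndarray
    n_residues: int
    residue_range: tuple[int, int]


def helix_axis(chain: ChainModel, residue_range: tuple[int, int]) -> HelixAxis:
    """Axis of the helical segment spanning a residue range (≥ 4 Cα).

    Bisectors of consecutive Cα triples are radial (perpendicular to the
    axis) on an ideal helix; the axis is their least-squares common normal.
    The direction is oriented from the first to the last residue of the
    range (a reversed range therefore yields the antiparallel axis).
    """
    lo, hi = residue_range
    reverse = lo > hi
    if reverse:
        lo, hi = hi, lo
    ca, numbers = chain.ca_coordinates((lo, hi))
    if len(ca) < 4:
        raise ValueError(
            f"range {residue_range}: need >= 4 Cα atoms, found {len(ca)}"
        )
    bisectors = np.array(
        [
            unit((ca[i - 1] - ca[i]) + (ca[i + 1] - ca[i]))
            for i in range(1, len(ca) - 1)
        ]
    )
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(bisectors - 0.0)
    direction = unit(vt[-1])  # common normal = least principal component
    chain_dir = ca[-1] - ca[0]
    if np.dot(direction, chain_dir) < 0:
        direction = -direction
    if reverse:
        direction = -direction
    return HelixAxis(direction, centroid, len(ca), residue_range)


def interaxis_angle(axis_a: HelixAxis | np.ndarray, axis_b: HelixAxis | np.ndarray) -> float:
    """Angle between two (oriented) axes, degrees in [0, 180]."""
    a = axis_a.direction if isinstance(axis_a, HelixAxis) else unit(np.asarray(axis_a, float))
    b = axis_b.direction if isinstance(axis_b, HelixAxis) else unit(np.asarray(axis_b, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))


def helical_advance(chain: ChainModel, start_residue: int, span: int) -> float:
    """|Cα(start) − Cα(start+span)| in Å, one decimal."""
    a = chain.residue(start_residue)
    b = chain.residue(start_residue + span)
    ca_a = a.atom("CA") if a is not None else None
    ca_b = b.atom("CA") if b is not None else None
    if ca_a is None or ca_b is None:
        missing = start_residue if ca_a is None else start_residue + span
        raise ValueError(f"chain {chain.chain_id}: Cα of residue {missing} missing")
    return round(float(np.linalg.norm(ca_a.position - ca_b.position)), 1)


def dihedral_table(chain: ChainModel) -> str:
    """TSV per-residue dihedral table (degrees, 1 d.p.)."""
    dihedrals = backbone_dihedrals(chain)
    lines = ["residue\tname\tphi\tpsi\tomega"]
    for res in chain.residues:
        phi, psi, omega = dihedrals[res.number]
        fmt = lambda v: "" if v is None else f"{v:.1f}"
        lines.append(f"{res.number}\t{res.name}\t{fmt(phi)}\t{fmt(psi)}\t{fmt(omega)}")
    return "\n".join(lines) + "\n"
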