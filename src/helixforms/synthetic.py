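"""Synthetic backbone models with known ground-truth geometry.

Every analysis stage of the package can be exercised without any downloaded
structure: ideal α-helices (φ≈−57°, ψ≈−47°) and 3₁₀-helices (φ≈−49°,
ψ≈−26°), helices kinked by a chosen angle at a chosen residue,
dual-conformation files with altloc-duplicated residue ranges and fractional
occupancies, and toy metal sites.

Backbones are built by sequential internal-coordinate placement (NeRF) with
standard bond lengths and angles: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å;
angles CA–C–N 116.2°, C–N–CA 121.7°, and a tetrahedral N–CA–C angle of
109.47° at Cα; C=O 1.231 Å in the peptide plane trans to the next amide
nitrogen. With these values the textbook helical parameters (rise ≈ 1.5
Å/residue, Cα(i)→Cα(i+7) ≈ 10.5 Å for the α-helix; rise ≈ 1.95 Å/residue
at 3.0 residues/turn for the 3₁₀-helix) emerge from the construction
rather than being imposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geom import place_atom, rotation_about_axis, unit
from .model import AtomRecord, ChainModel, Residue, Structure

__all__ = [
    "HelixSpec",
    "ALPHA_PHI_PSI",
    "THREE10_PHI_PSI",
    "make_ideal_helix",
    "make_kinked_helix",
    "make_dual_conformer_file",
    "make_metal_site",
]

# canonical helical dihedrals (degrees)
ALPHA_PHI_PSI = (-57.0, -47.0)
THREE10_PHI_PSI = (-49.0, -26.0)

# standard backbone internal coordinates; the tetrahedral Cα angle is the
# classic model-building choice and is what makes the textbook helical
# parameters (α rise 1.50 Å/res, Cα(i)→Cα(i+7) = 10.5 Å; 3₁₀ rise ~1.95
# Å/res at 3.0 res/turn) come out of the construction
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 109.47122
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class HelixSpec:
    """Recipe for a synthetic helix.

    ``kink``, when given, is a ``(kink_residue, kink_angle)`` pair: residues
    after ``kink_residue`` (1-based position in the chain) are rigidly
    rotated by ``kink_angle`` degrees about an axis through that residue's
    Cα, perpendicular to the pre-kink helix axis. ``noise_sigma`` is the
    standard deviation of isotropic Gaussian coordinate noise in Å, applied
    with ``seed``.
    """

    n_residues: int
    phi: float = ALPHA_PHI_PSI[0]
    psi: float = ALPHA_PHI_PSI[1]
    omega: float = 180.0
    sequence: Optional[Sequence[str] | str] = None
    kink: Optional[tuple[int, float]] = None
    noise_sigma: float = 0.0
    seed: int = 0
    start_number: int = 1

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        for name, value in (("phi", self.phi), ("psi", self.psi), ("omega", self.omega)):
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.kink is not None:
            k, _ = self.kink
            if not 1 < k < self.n_residues:
                raise ValueError(
                    f"kink_residue {k} must lie strictly inside the chain"
                )

    def residue_names(self) -> list[str]:
        if self.sequence is None:
            return ["ALA"] * self.n_residues
        if isinstance(self.sequence, str):
            names = [_ONE_TO_THREE[c.upper()] for c in self.sequence]
        else:
            names = [str(s).upper() for s in self.sequence]
        if len(names) != self.n_residues:
            raise ValueError(
                f"sequence length {len(names)} != n_residues {self.n_residues}"
            )
        return names


def _build_backbone(spec: HelixSpec) -> list[dict[str, np.ndarray]]:
    """Noise-free backbone coordinates, one dict of atom positions per residue."""
    n = spec.n_residues
    coords: list[dict[str, np.ndarray]] = [dict() for _ in range(n)]

    # seed the first residue in the xy-plane
    coords[0]["N"] = np.zeros(3)
    coords[0]["CA"] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    coords[0]["C"] = coords[0]["CA"] + _B_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )

    for i in range(n - 1):
        n_i, ca_i, c_i = coords[i]["N"], coords[i]["CA"], coords[i]["C"]
        n_next = place_atom(n_i, ca_i, c_i, _B_C_N, _A_CA_C_N, spec.psi)
        ca_next = place_atom(ca_i, c_i, n_next, _B_N_CA, _A_C_N_CA, spec.omega)
        c_next = place_atom(c_i, n_next, ca_next, _B_CA_C, _A_N_CA_C, spec.phi)
        coords[i]["O"] = place_atom(n_next, ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
        coords[i + 1]["N"] = n_next
        coords[i + 1]["CA"] = ca_next
        coords[i + 1]["C"] = c_next
    last = coords[-1]
    last["O"] = place_atom(
        last["N"], last["CA"], last["C"], _B_C_O, _A_CA_C_O, spec.psi - 180.0
    )
    return coords


def _assemble_chain(
    spec: HelixSpec, coords: list[dict[str, np.ndarray]], chain_id: str = "A"
) -> ChainModel:
    rng = np.random.default_rng(spec.seed)
    names = spec.residue_names()
    residues = []
    for i, per_atom in enumerate(coords):
        res = Residue(number=spec.start_number + i, name=names[i])
        for atom_name in ("N", "CA", "C", "O"):
            pos = per_atom[atom_name].copy()
            if spec.noise_sigma > 0:
                pos = pos + rng.normal(0.0, spec.noise_sigma, 3)
            element = atom_name[0]
            res.add_atom(AtomRecord(atom_name, element, pos))
        residues.append(res)
    return ChainModel(chain_id=chain_id, residues=residues, entity_role="receptor")


def make_ideal_helix(spec: HelixSpec, chain_id: str = "A") -> ChainModel:
    """Build an ideal helix; interior (φ,ψ) reproduce the requested values exactly at zero noise."""
    return _assemble_chain(spec, _build_backbone(spec), chain_id)


def _prekink_axis(coords: list[dict[str, np.ndarray]], k: int) -> np.ndarray:
    """Axis of the helix formed by residues 1..k (N→C oriented), bisector method."""
    ca = np.array([coords[i]["CA"] for i in range(k)])
    bis = np.array(
        [unit((ca[i - 1] - ca[i]) + (ca[i + 1] - ca[i])) for i in range(1, len(ca) - 1)]
    )
    _, _, vt = np.linalg.svd(bis)
    axis = vt[-1]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return unit(axis)


def make_kinked_helix(spec: HelixSpec, chain_id: str = "A") -> ChainModel:
    """Ideal helix bent by a known angle at a known residue.

    The fragment downstream of the hinge Cα — the hinge residue's C/O plus
    every later residue — is rigidly rotated about an axis through the hinge
    Cα perpendicular to the pre-kink helix axis. Rotation about a point on
    the axis preserves every bond length (including Cα–C at the hinge); the
    hinge ψ simply re-derives to a new value instead of the requested one.
    """
    if spec.kink is None:
        raise ValueError("spec.kink must be set for make_kinked_helix")
    k, angle = spec.kink
    if not -90.0 < angle < 90.0:
        raise ValueError(f"kink_angle {angle} outside (-90, 90)")
    coords = _build_backbone(spec)
    if angle != 0.0:
        helix_axis = _prekink_axis(coords, k)
        perp = np.cross(helix_axis, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(helix_axis, np.array([0.0, 1.0, 0.0]))
        rot = rotation_about_axis(unit(perp), angle)
        pivot = coords[k - 1]["CA"]

        def move(p: np.ndarray) -> np.ndarray:
            return pivot + rot @ (p - pivot)

        coords[k - 1]["C"] = move(coords[k - 1]["C"])
        coords[k - 1]["O"] = move(coords[k - 1]["O"])
        for i in range(k, spec.n_residues):
            for name in coords[i]:
                coords[i][name] = move(coords[i][name])
    return _assemble_chain(spec, coords, chain_id)


def make_dual_conformer_file(
    base: HelixSpec,
    alt_range: tuple[int, int],
    displacement: float,
    occupancies: tuple[float, float] = (0.5, 0.5),
    chain_id: str = "A",
    structure_id: str = "synthetic-dual",
) -> Structure:
    """Helix with a residue range duplicated as altlocs A/B.

    Conformer B is conformer A rigidly translated by ``displacement`` Å
    perpendicular to the helix axis; occupancies must sum to 1.
    """
    p, q = occupancies
    if abs(p + q - 1.0) > 1e-6:
        raise ValueError(f"occupancies {occupancies} do not sum to 1")
    chain = (
        make_kinked_helix(base, chain_id)
        if base.kink is not None
        else make_ideal_helix(base, chain_id)
    )
    numbers = chain.residue_numbers()
    lo, hi = alt_range
    if lo not in numbers or hi not in numbers or lo > hi:
        raise ValueError(f"alt_range {alt_range} outside chain residues")

    ca, _ = chain.ca_coordinates()
    axis = _prekink_axis([{"CA": c} for c in ca], len(ca))
    perp = np.cross(axis, np.array([1.0, 0.0, 0.0]))
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, np.array([0.0, 1.0, 0.0]))
    shift = displacement * unit(perp)

    for res in chain.residues:
        if lo <= res.number <= hi:
            originals = list(res.atoms)
            for atom in originals:
                atom.altloc = "A"
                atom.occupancy = p
                dup = atom.copy()
                dup.altloc = "B"
                dup.occupancy = q
                dup.position = atom.position + shift
                res.add_atom(dup)
    return Structure(id=structure_id, chains=[chain], source_format="pdb")


_TETRAHEDRAL = np.array(
    [[1, 1, 1], [-1, -1, 1], [-1, 1, -1], [1, -1, -1]], dtype=float
) / math.sqrt(3.0)


def make_metal_site(
    n_ligands: int, distance: float = 2.1, structure_id: str = "synthetic-metal"
) -> Structure:
    """A Zn ion with ``n_ligands`` side-chain nitrogens at ``distance`` Å.

    Up to four ligands sit on exact tetrahedral directions (ligand–Zn–ligand
    ≈ 109.47°); beyond four, extra ligands are spread on a Fibonacci sphere.
    """
    if n_ligands < 0:
        raise ValueError("n_ligands must be >= 0")
    residues = [
        Residue(number=1, name="ZN", atoms=[AtomRecord("ZN", "Zn", np.zeros(3))])
    ]
    if n_ligands <= 4:
        directions = _TETRAHEDRAL[:n_ligands]
    else:
        idx = np.arange(n_ligands)
        phi = math.pi * (3.0 - math.sqrt(5.0)) * idx
        z = 1.0 - 2.0 * (idx + 0.5) / n_ligands
        r = np.sqrt(1.0 - z * z)
        directions = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    for i, direction in enumerate(directions):
        residues.append(
            Residue(
                number=2 + i,
                name="HIS",
                atoms=[AtomRecord("NE2", "N", distance * direction)],
            )
        )
    chain = ChainModel(chain_id="M", residues=residues, entity_role="ion")
    return Structure(id=structure_id, chains=[chain], source_format="pdb")
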