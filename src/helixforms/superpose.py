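"""Least-squares superposition and closed/open displacement measurements.

All RMSDs come from the Kabsch algorithm restricted to proper rotations
(reflections are never allowed: a mirror-related pair is fitted with the
best proper rotation, not an improper one). Displacement measurements
superpose on a fit selection that excludes the mobile helix IV–ICL2–helix V
cassette, then report how far individual atoms moved — the way the closed
and open conformers are compared residue by residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .helixgeom import DEFAULT_REGIONS, RegionScheme
from .io import split_conformers
from .model import ChainModel, Structure

__all__ = [
    "SuperpositionResult",
    "DisplacementRecord",
    "kabsch_fit",
    "chain_rmsd",
    "atom_displacement",
    "region_superpose_deviation",
    "compare_dual_model",
    "DualComparison",
]


@dataclass
class SuperpositionResult:
    """Proper-rotation least-squares fit of coords_b onto coords_a.

    ``transform(x)`` maps a point from the b frame into the a frame;
    ``deviations`` are the per-atom residuals after the fit, in input order.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    deviations: np.ndarray
    fit_selection: str = ""
    measure_selection: str = ""
    residue_numbers: list[int] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class DisplacementRecord:
    residue_number: int
    atom_name: str
    displacement: float


def kabsch_fit(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation + translation of b onto a (paired points).

    Raises on fewer than 3 points or a degenerate (collinear) point set,
    where the rotation is not uniquely determined.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"paired Nx3 coordinate sets required, got {a.shape}/{b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 atoms for a superposition, got {n}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    aa = a - cen_a
    bb = b - cen_b
    cov = bb.T @ aa
    u, s, vt = np.linalg.svd(cov)
    # collinear sets leave a rotation about the line undetermined
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) coordinates: rotation ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cen_a - rotation @ cen_b
    moved = bb @ rotation.T + cen_a
    deviations = np.linalg.norm(a - moved, axis=1)
    rmsd = float(np.sqrt(np.mean(deviations**2)))
    return SuperpositionResult(rotation, translation, rmsd, n, deviations)


def _paired_coordinates(
    chain_a: ChainModel,
    chain_b: ChainModel,
    atom_selection: Sequence[str],
    residue_range: Optional[tuple[int, int]] = None,
    exclude: Optional[tuple[int, int]] = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Coordinates paired by author residue number over residues modeled in both."""
    common = sorted(
        set(chain_a.residue_numbers()) & set(chain_b.residue_numbers())
    )
    if residue_range is not None:
        lo, hi = residue_range
        common = [n for n in common if lo <= n <= hi]
    if exclude is not None:
        lo, hi = exclude
        common = [n for n in common if not lo <= n <= hi]
    xs, ys, numbers = [], [], []
    for number in common:
        res_a = chain_a.residue(number)
        res_b = chain_b.residue(number)
        for atom_name in atom_selection:
            at_a = res_a.atom(atom_name)
            at_b = res_b.atom(atom_name)
            if at_a is not None and at_b is not None:
                xs.append(at_a.position)
                ys.append(at_b.position)
                numbers.append(number)
    if not xs:
        raise ValueError("no common residues with the selected atoms")
    return np.array(xs), np.array(ys), numbers


def chain_rmsd(
    chain_a: ChainModel,
    chain_b: ChainModel,
    atom_selection: Sequence[str] = ("CA",),
    residue_range: Optional[tuple[int, int]] = None,
) -> SuperpositionResult:
    """Whole-chain (or range-restricted) RMSD over residues modeled in both."""
    xs, ys, numbers = _paired_coordinates(
        chain_a, chain_b, atom_selection, residue_range
    )
    result = kabsch_fit(xs, ys)
    result.fit_selection = f"{'+'.join(atom_selection)} common residues"
    result.measure_selection = result.fit_selection
    result.residue_numbers = numbers
    return result


def atom_displacement(
    chain_a: ChainModel,
    chain_b: ChainModel,
    targets: Sequence[tuple[int, str]],
    fit_exclude: Optional[tuple[int, int]] = None,
    regions: RegionScheme = DEFAULT_REGIONS,
) -> tuple[list[DisplacementRecord], list[tuple[int, str]]]:
    """Per-atom displacements after a main-body fit.

    The fit uses Cα of residues modeled in both chains, excluding
    ``fit_exclude`` (default: the mobile region 250–288, so the fixed body
    of the receptor defines the frame). Returns (records, missing targets).
    """
    if fit_exclude is None:
        fit_exclude = regions["mobile_region"]
    xs, ys, _ = _paired_coordinates(chain_a, chain_b, ("CA",), exclude=fit_exclude)
    fit = kabsch_fit(xs, ys)
    records: list[DisplacementRecord] = []
    missing: list[tuple[int, str]] = []
    for number, atom_name in targets:
        res_a = chain_a.residue(number)
        res_b = chain_b.residue(number)
        at_a = res_a.atom(atom_name) if res_a is not None else None
        at_b = res_b.atom(atom_name) if res_b is not None else None
        if at_a is None or at_b is None:
            missing.append((number, atom_name))
            continue
        moved = fit.transform(at_b.position[None, :])[0]
        records.append(
            DisplacementRecord(
                number, atom_name, float(np.linalg.norm(at_a.position - moved))
            )
        )
    return records, missing


def region_superpose_deviation(
    chain_a: ChainModel,
    chain_b: ChainModel,
    fit_range: tuple[int, int],
    measure_range: tuple[int, int],
) -> tuple[dict[int, float], SuperpositionResult]:
    """Fit on one region's Cα, report per-residue Cα deviations on another."""
    xs, ys, _ = _paired_coordinates(chain_a, chain_b, ("CA",), fit_range)
    if len(xs) < 3:
        raise ValueError(f"fit range {fit_range}: fewer than 3 common Cα")
    fit = kabsch_fit(xs, ys)
    fit.fit_selection = f"CA {fit_range[0]}-{fit_range[1]}"
    fit.measure_selection = f"CA {measure_range[0]}-{measure_range[1]}"
    mx, my, numbers = _paired_coordinates(chain_a, chain_b, ("CA",), measure_range)
    moved = fit.transform(my)
    deviations = np.linalg.norm(mx - moved, axis=1)
    return dict(zip(numbers, deviations.tolist())), fit


@dataclass
class DualComparison:
    """Outcome of matching a dual-conformation model against references."""

    assignment: dict[str, str]  # conformer name -> reference name
    rmsd: dict[str, dict[str, float]]  # conformer -> reference -> Å

    def table(self) -> str:
        refs = sorted(next(iter(self.rmsd.values())).keys())
        lines = ["conformer\t" + "\t".join(refs) + "\tassigned"]
        for conf in sorted(self.rmsd):
            row = "\t".join(f"{self.rmsd[conf][r]:.3f}" for r in refs)
            lines.append(f"{conf}\t{row}\t{self.assignment[conf]}")
        return "\n".join(lines) + "\n"


def compare_dual_model(
    dual: Structure,
    references: Mapping[str, ChainModel],
    dual_region: Optional[tuple[int, int]] = None,
    chain_id: Optional[str] = None,
    mapping: Optional[Mapping[str, str]] = None,
    regions: RegionScheme = DEFAULT_REGIONS,
) -> DualComparison:
    """Split a dual-conformation model and assign each conformer a reference.

    Each altloc-defined conformer is superposed (whole-chain Cα) against
    every reference chain; a conformer is assigned the label of its
    nearest reference. The assignment is a pure function of the RMSD table,
    so it is invariant under reference ordering.
    """
    if dual_region is None:
        dual_region = regions["dual_region"]
    if not dual.has_altlocs():
        raise ValueError("structure has no alternate locations to split")
    conformers = split_conformers(dual, mapping)
    if chain_id is None:
        candidates = [c.chain_id for c in dual.chains if c.has_altlocs()]
        chain_id = candidates[0]
    rmsd_table: dict[str, dict[str, float]] = {}
    assignment: dict[str, str] = {}
    for conf_name, conf_structure in conformers.items():
        conf_chain = conf_structure.chain(chain_id)
        row = {
            ref_name: chain_rmsd(ref_chain, conf_chain).rmsd
            for ref_name, ref_chain in references.items()
        }
        rmsd_table[conf_name] = row
        assignment[conf_name] = min(sorted(row), key=lambda k: row[k])
    return DualComparison(assignment, rmsd_table)
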