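"""End-to-end closed/open analysis: one config in, one JSON report out.

``analyze`` chains every stage — amide-hydrogen rebuild, helical
hydrogen-bond scan, α/3₁₀ classification, dihedrals/axes/advance, pairwise
RMSDs and displacements, contacts and metal coordination — over the
receptor chains of one or more structures. Stage failures are captured per
stage and the report is still emitted with the gaps flagged. Reports are
deterministic for a given config except for the timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from datetime import datetime, timezone
from importlib import resources
from typing import Any, Mapping, Optional

import numpy as np

from . import __version__
from .hbonds import (
    GeometryConfig,
    classify_helix,
    coordination_sphere,
    count_bonds,
    scan_helical_hbonds,
)
from .helixgeom import (
    RegionScheme,
    backbone_dihedrals,
    helical_advance,
    helix_axis,
    interaxis_angle,
)
from .io import read_structure
from .model import Structure
from .superpose import atom_displacement, chain_rmsd, compare_dual_model

__all__ = ["analyze", "validate_report", "load_schema", "config_hash"]

# acceptor window of the 3_10 stretch: the M2 region minus its first residue
# (whose CO terminates the 3_10 conformation) and the last three (whose i+3
# donors fall outside the region)
def _m2_acceptor_window(regions: RegionScheme) -> tuple[int, int]:
    lo, hi = regions["M2"]
    return (lo + 1, hi - 3)


def config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _records_to_json(records) -> list[dict]:
    out = []
    for r in records:
        d = dataclasses.asdict(r)
        for key, value in d.items():
            if isinstance(value, float) and math.isnan(value):
                d[key] = None
        out.append(d)
    return out


def _chain_report(
    chain, regions: RegionScheme, geometry: GeometryConfig
) -> dict[str, Any]:
    numbers = chain.residue_numbers()
    report: dict[str, Any] = {"n_residues": len(numbers)}
    helix_lo, helix_hi = regions["NT"][0], regions["CT"][1]
    have_helix_v = any(helix_lo <= n <= helix_hi for n in numbers)
    scan_range = (helix_lo, helix_hi) if have_helix_v else (min(numbers), max(numbers))

    dihedrals = backbone_dihedrals(chain)
    report["dihedrals"] = {
        str(num): [None if v is None else round(v, 1) for v in vals]
        for num, vals in dihedrals.items()
    }

    records = scan_helical_hbonds(chain, scan_range, geometry)
    report["hbonds"] = _records_to_json(records)

    classification = classify_helix(chain, scan_range, geometry)
    report["classification"] = {
        str(num): label for num, label in classification.labels.items()
    }

    if have_helix_v:
        window = _m2_acceptor_window(regions)
        report["m2_bond_counts"] = {
            "offset3": count_bonds(records, 3, window),
            "offset4": count_bonds(records, 4, window),
            "acceptor_window": list(window),
        }
        m2 = regions["M2"]
        try:
            report["m2_advance"] = helical_advance(chain, m2[0], m2[1] - m2[0])
        except ValueError:
            report["m2_advance"] = None
        axes = {}
        for name in ("M1", "CT"):
            try:
                axes[name] = helix_axis(chain, regions[name]).direction.tolist()
            except ValueError:
                axes[name] = None
        report["axes"] = axes
        if axes.get("M1") and axes.get("CT"):
            report["m1_ct_bend"] = round(
                interaxis_angle(np.array(axes["M1"]), np.array(axes["CT"])), 1
            )
        else:
            report["m1_ct_bend"] = None
        n3 = report["m2_bond_counts"]["offset3"]
        report["form_call"] = (
            "closed-like" if n3 >= 3 else "open-like" if n3 <= 1 else "intermediate"
        )
    return report


def analyze(config: Mapping[str, Any]) -> dict[str, Any]:
    """Run the full pipeline described by ``config``; see the CLI docs.

    Minimal config: ``{"structures": [{"path": "model.pdb"}]}``. Optional
    keys: ``chains`` (receptor chain ids), ``regions`` (range overrides),
    ``thresholds`` (GeometryConfig overrides), ``metal_element``,
    ``displacement_targets`` ([[residue, atom], ...]).
    """
    regions = RegionScheme(
        {**RegionScheme().regions, **{
            k: tuple(v) for k, v in config.get("regions", {}).items()
        }}
    )
    geometry = GeometryConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in config.get("thresholds", {}).items()
    })
    report: dict[str, Any] = {
        "provenance": {
            "inputs": [str(s["path"]) for s in config["structures"]],
            "config_hash": config_hash(config),
            "tool_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        "chains": {},
        "comparisons": {},
        "errors": {},
    }

    structures: list[Structure] = []
    for entry in config["structures"]:
        try:
            st = read_structure(entry["path"], entry.get("format"))
            if "id" in entry:
                st.id = entry["id"]
            structures.append(st)
        except (OSError, ValueError) as exc:
            report["errors"][f"read:{entry['path']}"] = str(exc)
    if not structures:
        return report

    wanted = config.get("chains")
    selected = []  # (label, chain) over single-conformer views
    dual_structures = []
    for st in structures:
        if st.has_altlocs():
            dual_structures.append(st)
        for chain in st.chains:
            if wanted is not None:
                if chain.chain_id not in wanted:
                    continue
            elif chain.entity_role != "receptor":
                continue
            label = f"{st.id}:{chain.chain_id}" if len(structures) > 1 else chain.chain_id
            if chain.has_altlocs():
                continue  # analysed via the dual-model pathway
            selected.append((label, chain))

    for label, chain in selected:
        try:
            report["chains"][label] = _chain_report(chain, regions, geometry)
        except (ValueError, KeyError) as exc:
            report["errors"][f"chain:{label}"] = str(exc)

    # pairwise RMSDs and displacements between analysed chains
    if len(selected) >= 2:
        matrix: dict[str, dict[str, float]] = {}
        for i, (label_a, chain_a) in enumerate(selected):
            for label_b, chain_b in selected[i + 1 :]:
                try:
                    value = round(chain_rmsd(chain_a, chain_b).rmsd, 3)
                except ValueError as exc:
                    report["errors"][f"rmsd:{label_a}/{label_b}"] = str(exc)
                    continue
                matrix.setdefault(label_a, {})[label_b] = value
        report["comparisons"]["rmsd_ca"] = matrix

        targets = [
            (int(num), str(atom))
            for num, atom in config.get(
                "displacement_targets",
                [[254, "CA"], [262, "CA"], [264, "CA"]],
            )
        ]
        displacements: dict[str, dict[str, float]] = {}
        for i, (label_a, chain_a) in enumerate(selected):
            for label_b, chain_b in selected[i + 1 :]:
                try:
                    recs, _missing = atom_displacement(
                        chain_a, chain_b, targets, regions=regions
                    )
                except ValueError as exc:
                    report["errors"][f"displace:{label_a}/{label_b}"] = str(exc)
                    continue
                displacements[f"{label_a}/{label_b}"] = {
                    f"{r.residue_number}:{r.atom_name}": round(r.displacement, 2)
                    for r in recs
                }
        report["comparisons"]["displacements"] = displacements

    # dual-conformation models against the single-conformer chains
    if dual_structures and selected:
        references = {label: chain for label, chain in selected}
        dual_section = {}
        for st in dual_structures:
            try:
                cmp_result = compare_dual_model(st, references, regions=regions)
                dual_section[st.id] = {
                    "assignment": cmp_result.assignment,
                    "rmsd": {
                        c: {r: round(v, 3) for r, v in row.items()}
                        for c, row in cmp_result.rmsd.items()
                    },
                }
            except ValueError as exc:
                report["errors"][f"dual:{st.id}"] = str(exc)
        if dual_section:
            report["dual"] = dual_section

    metal = config.get("metal_element", "Zn")
    coordination = []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for st in structures:
            for sphere in coordination_sphere(st, metal, config=geometry):
                coordination.append(
                    {
                        "structure": st.id,
                        "metal": f"{sphere.metal_chain}:{sphere.metal_name}{sphere.metal_residue}",
                        "atoms": [
                            {
                                "chain": c,
                                "residue": f"{name}{num}",
                                "atom": atom,
                                "distance": round(dist, 2),
                            }
                            for c, num, name, atom, dist in sphere.atoms
                        ],
                    }
                )
    report["coordination"] = coordination
    return report


def load_schema() -> dict:
    with resources.files("helixforms").joinpath("schema/report.schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: Mapping[str, Any], schema: Optional[dict] = None) -> None:
    """Check a report against the shipped minimal schema (raises ValueError).

    The schema uses a small subset of JSON-Schema vocabulary: ``type``,
    ``required`` and ``properties``.
    """
    schema = schema or load_schema()
    _walk(report, schema, path="$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _walk(value: Any, schema: Mapping[str, Any], path: str) -> None:
    expected = schema.get("type")
    if expected is not None:
        if value is None and schema.get("nullable"):
            return
        if not isinstance(value, _TYPES[expected]):
            raise ValueError(f"{path}: expected {expected}, got {type(value).__name__}")
    for key in schema.get("required", []):
        if key not in value:
            raise ValueError(f"{path}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if isinstance(value, dict) and key in value:
            _walk(value[key], sub, f"{path}.{key}")
    items = schema.get("items")
    if items and isinstance(value, list):
        for i, item in enumerate(value):
            _walk(item, items, f"{path}[{i}]")
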