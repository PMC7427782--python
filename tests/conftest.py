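"""Shared fixtures: synthetic ground-truth structures, no downloads needed.

Paper-value tests against the deposited crystal structures run only when
the entries have been placed under tests/data/ by the user (see README);
everything else is generated programmatically.
"""

from pathlib import Path

import pytest

import helixforms as hf

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def alpha_helix() -> hf.ChainModel:
    """Noise-free 14-residue ideal α-helix."""
    return hf.make_ideal_helix(hf.HelixSpec(n_residues=14))


@pytest.fixture(scope="session")
def three10_helix() -> hf.ChainModel:
    """Noise-free 14-residue ideal 3₁₀-helix."""
    phi, psi = hf.THREE10_PHI_PSI
    return hf.make_ideal_helix(hf.HelixSpec(n_residues=14, phi=phi, psi=psi))


@pytest.fixture(scope="session")
def dual_structure() -> hf.Structure:
    """20-residue helix with residues 8-12 duplicated as altlocs A/B (0.44/0.56)."""
    return hf.make_dual_conformer_file(
        hf.HelixSpec(n_residues=20), (8, 12), displacement=11.0, occupancies=(0.44, 0.56)
    )


def deposited(entry: str) -> Path:
    """Path of a locally provided deposited entry, or skip the test."""
    for suffix in (".pdb", ".cif", ".pdb.gz", ".cif.gz"):
        path = DATA_DIR / f"{entry}{suffix}"
        if path.exists():
            return path
    pytest.skip(
        f"deposited entry {entry} not present under tests/data/ "
        f"(download it from the PDB to run this check)"
    )
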