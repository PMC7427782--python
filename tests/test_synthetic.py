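"""Generator ground truth: dihedral exactness, determinism, chirality,
kinks, dual-conformer construction and metal-site toys."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helixforms as hf
from helixforms.geom import bond_angle, dihedral_angle


def backbone(chain):
    return {
        (r.number, a.name): a.position for r in chain.residues for a in r.atoms
    }


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    phi=st.floats(min_value=-90, max_value=-35),
    psi=st.floats(min_value=-70, max_value=-10),
)
def test_dihedral_round_trip_exact_at_zero_noise(phi, psi):
    """Interior (φ,ψ) of a noiseless generated helix equal the spec to 1e-3°,
    over the helical region of Ramachandran space."""
    chain = hf.make_ideal_helix(hf.HelixSpec(n_residues=8, phi=phi, psi=psi))
    dihedrals = hf.backbone_dihedrals(chain)
    for num in range(2, 8):
        got_phi, got_psi, got_omega = dihedrals[num]
        assert got_phi == pytest.approx(phi, abs=1e-3)
        if num < 8:
            assert got_psi == pytest.approx(psi, abs=1e-3)
            assert abs(abs(got_omega) - 180.0) < 1e-3


def test_dihedral_convention_matches_gemmi(alpha_helix):
    """Own torsion code agrees with gemmi's IUPAC convention (independent oracle)."""
    import gemmi

    res = alpha_helix.residues
    p = lambda i, a: res[i].atom(a).position
    g = lambda v: gemmi.Position(*v)
    mine = dihedral_angle(p(4, "C"), p(5, "N"), p(5, "CA"), p(5, "C"))
    oracle = np.degrees(
        gemmi.calculate_dihedral(g(p(4, "C")), g(p(5, "N")), g(p(5, "CA")), g(p(5, "C")))
    )
    assert mine == pytest.approx(oracle, abs=1e-9)
    assert mine == pytest.approx(-57.0, abs=1e-9)


def test_standard_bond_geometry_realized(alpha_helix):
    atoms = backbone(alpha_helix)
    assert np.linalg.norm(atoms[(5, "N")] - atoms[(5, "CA")]) == pytest.approx(1.458, abs=1e-6)
    assert np.linalg.norm(atoms[(5, "CA")] - atoms[(5, "C")]) == pytest.approx(1.525, abs=1e-6)
    assert np.linalg.norm(atoms[(5, "C")] - atoms[(6, "N")]) == pytest.approx(1.329, abs=1e-6)
    assert np.linalg.norm(atoms[(5, "C")] - atoms[(5, "O")]) == pytest.approx(1.231, abs=1e-6)
    assert bond_angle(atoms[(5, "CA")], atoms[(5, "C")], atoms[(6, "N")]) == pytest.approx(116.2, abs=1e-6)


def test_alpha_advance_is_standard(alpha_helix):
    """Cα(i)→Cα(i+7) = 10.5 Å (1 d.p.): the standard α-helix advance."""
    assert hf.helical_advance(alpha_helix, 3, 7) == 10.5


def test_three10_contacts_shorter_at_offset3(three10_helix):
    """Brute force over generated coordinates: every CO(i)···N(i+3) contact
    is shorter than CO(i)···N(i+4) in a 3₁₀-helix, and vice versa for α."""
    atoms = backbone(three10_helix)
    for i in range(1, 10):
        d3 = np.linalg.norm(atoms[(i, "O")] - atoms[(i + 3, "N")])
        d4 = np.linalg.norm(atoms[(i, "O")] - atoms[(i + 4, "N")])
        assert d3 < d4


def test_determinism_and_seed_sensitivity():
    a1 = hf.make_ideal_helix(hf.HelixSpec(n_residues=8, noise_sigma=0.1, seed=7))
    a2 = hf.make_ideal_helix(hf.HelixSpec(n_residues=8, noise_sigma=0.1, seed=7))
    b = hf.make_ideal_helix(hf.HelixSpec(n_residues=8, noise_sigma=0.1, seed=8))
    pos = lambda ch: np.array([a.position for r in ch.residues for a in r.atoms])
    assert np.array_equal(pos(a1), pos(a2))
    assert not np.allclose(pos(a1), pos(b))


def test_alpha_helix_is_right_handed(alpha_helix):
    """Rise per residue along the N→C axis is positive and ≈1.5 Å."""
    axis = hf.helix_axis(alpha_helix, (1, 14))
    ca, _ = alpha_helix.ca_coordinates()
    rise = np.dot(ca[-1] - ca[0], axis.direction) / (len(ca) - 1)
    assert rise == pytest.approx(1.5, abs=0.05)


@pytest.mark.parametrize("angle", [10.0, 18.0, 30.0])
def test_kink_recovered_by_axis_estimator(angle):
    chain = hf.make_kinked_helix(hf.HelixSpec(n_residues=20, kink=(10, angle)))
    pre = hf.helix_axis(chain, (1, 10))
    post = hf.helix_axis(chain, (11, 20))
    assert hf.interaxis_angle(pre, post) == pytest.approx(angle, abs=2.0)


def test_zero_kink_is_identity():
    spec = hf.HelixSpec(n_residues=12, kink=(6, 0.0))
    kinked = backbone(hf.make_kinked_helix(spec))
    straight = backbone(hf.make_ideal_helix(hf.HelixSpec(n_residues=12)))
    for key in straight:
        assert np.allclose(kinked[key], straight[key])


def test_kink_preserves_bond_lengths_at_hinge():
    chain = hf.make_kinked_helix(hf.HelixSpec(n_residues=20, kink=(10, 30.0)))
    atoms = backbone(chain)
    assert np.linalg.norm(atoms[(10, "CA")] - atoms[(10, "C")]) == pytest.approx(1.525, abs=1e-9)
    assert np.linalg.norm(atoms[(10, "C")] - atoms[(11, "N")]) == pytest.approx(1.329, abs=1e-9)


def test_kink_angle_out_of_range_rejected():
    with pytest.raises(ValueError, match="kink_angle"):
        hf.make_kinked_helix(hf.HelixSpec(n_residues=20, kink=(10, 95.0)))
    with pytest.raises(ValueError, match="strictly inside"):
        hf.HelixSpec(n_residues=10, kink=(10, 20.0))


def test_dual_conformer_construction(dual_structure):
    occ = hf.conformer_occupancies(dual_structure, (8, 12))
    assert occ == {"A": 0.44, "B": 0.56}
    outs = hf.split_conformers(dual_structure)
    a, b = outs["A"].chains[0], outs["B"].chains[0]
    recs, missing = hf.atom_displacement(a, b, [(10, "CA")], fit_exclude=(8, 12))
    assert not missing
    assert recs[0].displacement == pytest.approx(11.0, abs=0.01)


def test_dual_conformer_zero_displacement_identical():
    st = hf.make_dual_conformer_file(hf.HelixSpec(n_residues=12), (5, 7), 0.0)
    outs = hf.split_conformers(st)
    pos = lambda s: np.array(
        [a.position for r in s.chains[0].residues for a in r.atoms]
    )
    assert np.allclose(pos(outs["A"]), pos(outs["B"]))


def test_dual_conformer_bad_occupancies_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        hf.make_dual_conformer_file(hf.HelixSpec(n_residues=12), (5, 7), 1.0, (0.5, 0.6))
    with pytest.raises(ValueError, match="alt_range"):
        hf.make_dual_conformer_file(hf.HelixSpec(n_residues=12), (10, 30), 1.0)


@pytest.mark.parametrize("n,expected", [(0, 0), (3, 3), (4, 4)])
def test_metal_site_coordination_counts(n, expected):
    st = hf.make_metal_site(n, distance=2.1)
    spheres = hf.coordination_sphere(st, "Zn", 2.6)
    assert len(spheres[0].atoms) == expected
    for *_rest, d in spheres[0].atoms:
        assert d == pytest.approx(2.1, abs=1e-9)


def test_metal_site_tetrahedral_angles():
    st = hf.make_metal_site(4, distance=2.1)
    chain = st.chains[0]
    zn = chain.residues[0].atoms[0].position
    ligands = [r.atoms[0].position for r in chain.residues[1:]]
    for i in range(4):
        for j in range(i + 1, 4):
            assert bond_angle(ligands[i], zn, ligands[j]) == pytest.approx(109.47, abs=0.1)
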