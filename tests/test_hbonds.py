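"""Amide-hydrogen rebuilding, hydrogen-bond verdicts, helical classification,
contacts and coordination spheres."""

import numpy as np
import pytest

import helixforms as hf
from helixforms.geom import bond_angle
from helixforms.hbonds import AMIDE_H, hbond_table
from helixforms.model import AtomRecord, ChainModel, Residue, Structure


def test_hydrogen_placement_geometry(alpha_helix):
    """|N–H| = 1.00 Å, H coplanar with C(i−1)/N/CA, first residue bare."""
    built, gaps = hf.build_amide_hydrogens(alpha_helix)
    assert gaps == []
    assert built.residues[0].atom(AMIDE_H) is None
    for prev, res in zip(built.residues, built.residues[1:]):
        h = res.atom(AMIDE_H)
        n = res.atom("N").position
        assert np.linalg.norm(h.position - n) == pytest.approx(1.00, abs=1e-9)
        # coplanarity: H in the C(i-1)-N-CA plane
        normal = np.cross(
            prev.atom("C").position - n, res.atom("CA").position - n
        )
        normal /= np.linalg.norm(normal)
        assert abs(np.dot(h.position - n, normal)) < 1e-3
        # opposite the bisector: H-N-C(i-1) and H-N-CA angles equal
        a1 = bond_angle(h.position, n, prev.atom("C").position)
        a2 = bond_angle(h.position, n, res.atom("CA").position)
        assert a1 == pytest.approx(a2, abs=1e-6)


def test_proline_gets_no_hydrogen():
    chain = hf.make_ideal_helix(
        hf.HelixSpec(n_residues=8, sequence="AAAPAAAA")
    )
    built, _ = hf.build_amide_hydrogens(chain)
    assert built.residue(4).name == "PRO"
    assert built.residue(4).atom(AMIDE_H) is None
    assert built.residue(5).atom(AMIDE_H) is not None


def test_single_residue_chain_has_no_hydrogens():
    chain = hf.make_ideal_helix(hf.HelixSpec(n_residues=4))
    lone = ChainModel("A", [chain.residues[0].copy()])
    built, gaps = hf.build_amide_hydrogens(lone)
    assert all(r.atom(AMIDE_H) is None for r in built.residues)
    assert gaps == []


def test_missing_backbone_reported_as_gap(alpha_helix):
    maimed = alpha_helix.copy()
    res = maimed.residue(6)
    res.atoms = [a for a in res.atoms if a.name != "N"]
    built, gaps = hf.build_amide_hydrogens(maimed)
    assert gaps == [6]


def test_scan_records_both_offsets_with_brute_force_distances(alpha_helix):
    """d_ON matches a brute-force recomputation; offset-4 bonds dominate in α."""
    records = hf.scan_helical_hbonds(alpha_helix, (3, 8))
    assert {r.offset for r in records} == {3, 4}
    for rec in records:
        o = alpha_helix.residue(rec.acceptor_residue).atom("O").position
        n = alpha_helix.residue(rec.donor_residue).atom("N").position
        assert rec.d_ON == pytest.approx(float(np.linalg.norm(o - n)), abs=1e-9)
        if rec.offset == 4:
            assert rec.is_bond
        else:
            # α offset-3: short enough but far from linear → rejected by angle
            assert round(rec.d_ON, 1) <= 3.5
            assert rec.angle_OHN < 130
            assert not rec.is_bond


def test_proline_donor_never_bonds():
    chain = hf.make_ideal_helix(hf.HelixSpec(n_residues=12, sequence="AAAAAAAPAAAA"))
    records = hf.scan_helical_hbonds(chain, (2, 8))
    pro = [r for r in records if r.donor_residue == 8]
    assert pro and all(r.donor_is_proline and not r.is_bond for r in pro)
    other = [r for r in records if r.donor_residue != 8]
    assert any(r.is_bond for r in other)


def test_verdict_is_pure_function_of_rounded_distance_and_angle():
    """3.54 Å rounds to 3.5 → bond; 3.56 Å rounds to 3.6 → no bond."""
    cfg = hf.GeometryConfig()

    def toy(d_on):
        # acceptor O at origin; donor N at d_on with a linear O···H−N geometry
        res1 = Residue(1, "ALA", [
            AtomRecord("N", "N", (0, 0, -3)), AtomRecord("CA", "C", (0, 1, -2)),
            AtomRecord("C", "C", (0, 0.5, -1)), AtomRecord("O", "O", (0, 0, 0)),
        ])
        donor_n = np.array([0.0, 0.0, d_on])
        res2 = Residue(4, "ALA", [
            AtomRecord("N", "N", donor_n),
            AtomRecord("CA", "C", donor_n + (1.0, 1.0, 0.2)),
            AtomRecord("C", "C", donor_n + (2.0, 0.0, 0.4)),
            AtomRecord("O", "O", donor_n + (2.5, -1.0, 0.4)),
            AtomRecord(AMIDE_H, "H", donor_n - (0.0, 0.0, 1.0)),
        ])
        return ChainModel("A", [res1, res2])

    rec_in = hf.scan_helical_hbonds(toy(3.54), (1, 1), cfg)[0]
    rec_out = hf.scan_helical_hbonds(toy(3.56), (1, 1), cfg)[0]
    assert rec_in.is_bond and rec_in.is_weak
    assert not rec_out.is_bond
    raw = hf.GeometryConfig(round_distances=False)
    assert not hf.scan_helical_hbonds(toy(3.54), (1, 1), raw)[0].is_bond


def test_count_bonds_filters_offset_and_range(alpha_helix):
    records = hf.scan_helical_hbonds(alpha_helix, (2, 9))
    assert hf.count_bonds(records, 4, (2, 9)) == 8
    assert hf.count_bonds(records, 4, (3, 5)) == 3
    assert hf.count_bonds(records, 3, (2, 9)) == 0
    assert hf.count_bonds([], 3) == 0


def test_classification_on_ideal_helices(alpha_helix, three10_helix):
    assert all(
        label == "alpha"
        for label in hf.classify_helix(alpha_helix, (5, 10)).labels.values()
    )
    assert all(
        label == "three10"
        for label in hf.classify_helix(three10_helix, (5, 10)).labels.values()
    )


def test_classification_labels_are_supported_by_bonds(alpha_helix):
    result = hf.classify_helix(alpha_helix, (5, 10))
    for num, label in result.labels.items():
        if label != "turn_or_none":
            assert result.support[num], f"residue {num} label lacks a bond"
            assert all(r.is_bond for r in result.support[num])


def test_noisy_classification_accuracy_over_realizations():
    """≥99% of interior labels correct over seeded σ=0.1 Å realizations.

    (Scaled to 150 realizations here; the acceptance suite runs 1000.)"""
    correct = total = 0
    for seed in range(150):
        for (phi, psi), want in ((hf.ALPHA_PHI_PSI, "alpha"), (hf.THREE10_PHI_PSI, "three10")):
            chain = hf.make_ideal_helix(
                hf.HelixSpec(n_residues=14, phi=phi, psi=psi, noise_sigma=0.1, seed=seed)
            )
            for label in hf.classify_helix(chain, (5, 10)).labels.values():
                correct += label == want
                total += 1
    assert correct / total >= 0.99


def test_named_atom_distance(alpha_helix):
    d = hf.named_atom_distance(alpha_helix, 3, "O", 7, "N")
    assert d == pytest.approx(2.9, abs=0.05)
    assert hf.named_atom_distance(alpha_helix, 5, "CA", 5, "CA") == 0.0
    with pytest.raises(ValueError, match="CB"):
        hf.named_atom_distance(alpha_helix, 3, "CB", 7, "N")


def two_residue_structure(separation):
    res_a = Residue(1, "ALA", [AtomRecord("CA", "C", (0.0, 0.0, 0.0))])
    res_b = Residue(2, "ALA", [AtomRecord("CA", "C", (separation, 0.0, 0.0))])
    return Structure("toy", [ChainModel("A", [res_a]), ChainModel("B", [res_b])])


def test_contacts_inclusive_cutoff_and_symmetry():
    st = two_residue_structure(4.0)
    hits = hf.residue_contacts(st, ("A", None), ("B", None), cutoff=4.0)
    assert len(hits) == 1 and hits[0].min_distance == pytest.approx(4.0)
    assert hf.residue_contacts(st, ("B", None), ("A", None), cutoff=4.0)[0].chain_a == "B"
    far = two_residue_structure(4.01)
    assert hf.residue_contacts(far, ("A", None), ("B", None), cutoff=4.0) == []
    with pytest.raises(ValueError, match="empty selection"):
        hf.residue_contacts(st, [], ("B", None))


def test_contacts_ignore_hydrogens(alpha_helix):
    built, _ = hf.build_amide_hydrogens(alpha_helix)
    st = Structure("h", [built])
    hits = hf.residue_contacts(st, ("A", (3, 3)), ("A", (7, 7)), cutoff=2.5)
    # O(3)···H(7) is ~1.9 Å but hydrogens are excluded; heavy atoms are farther
    assert hits == []


def test_coordination_sphere_absent_element_warns():
    st = hf.make_metal_site(3)
    with pytest.warns(UserWarning, match="no Fe"):
        assert hf.coordination_sphere(st, "Fe") == []


def test_hbond_tsv_columns(alpha_helix):
    table = hbond_table(hf.scan_helical_hbonds(alpha_helix, (3, 5)), "A")
    header = table.splitlines()[0].split("\t")
    assert header == ["chain", "i", "res_i", "j", "res_j", "offset",
                      "d_ON", "angle_OHN", "is_bond", "label"]
    assert len(table.splitlines()) == 7  # 3 acceptors × 2 offsets + header
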