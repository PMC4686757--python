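"""Tests for SASA, interfaces, superposition, contacts and symmetry."""
import numpy as np
import pytest

import bindspec as bs
from bindspec.structcmp import (Atom, Chain, Crystal, Residue, Structure,
                                polymer_indices, select)


def sphere_structure(positions, element="S", resname="GLY"):
    ch = Chain("A")
    for i, p in enumerate(positions):
        r = Residue(resname, i + 1)
        r.atoms.append(Atom("CA", element, np.asarray(p, float)))
        ch.residues.append(r)
    return Structure([ch])


# --------------------------------------------------------------------- SASA

def test_single_sphere_matches_analytic_area():
    # r = 1.9 A with a 1.4 A probe: area = 4 pi (3.3)^2 = 136.85 A^2
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="single-sphere",
                                                  element="X"))
    areas = bs.sasa(s, probe_radius=1.4, n_points=960, radii={"X": 1.9})
    analytic = 4 * np.pi * 3.3 ** 2
    assert areas.sum() == pytest.approx(analytic, rel=0.005)


def test_unknown_element_warns_and_uses_fallback():
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="single-sphere",
                                                  element="Q"))
    with pytest.warns(UserWarning, match="unknown element"):
        areas = bs.sasa(s, fallback_radius=1.9)
    assert areas.sum() == pytest.approx(4 * np.pi * 3.3 ** 2, rel=0.005)


def test_far_separated_spheres_are_additive():
    s = bs.make_toy_structure(
        bs.ToyStructureSpec(kind="sphere-pair", separation=100.0, element="S"))
    areas = bs.sasa(s)
    single = 4 * np.pi * (1.8 + 1.4) ** 2
    assert areas.sum() == pytest.approx(2 * single, rel=0.005)
    assert areas[0] == pytest.approx(areas[1], rel=1e-9)


def test_fused_spheres_match_spherical_cap_formula():
    """Two equal spheres at d < 2R: exposed area per extended sphere is
    4 pi R^2 - 2 pi R h with cap height h = R - d/2 (R = r + probe)."""
    r, probe, d = 1.7, 1.4, 3.0
    R = r + probe
    s = sphere_structure([[0, 0, 0], [d, 0, 0]], element="C")
    areas = bs.sasa(s, probe_radius=probe, n_points=4000)
    h = R - d / 2.0
    analytic_each = 4 * np.pi * R ** 2 - 2 * np.pi * R * h
    assert areas[0] == pytest.approx(analytic_each, rel=0.01)
    assert areas[1] == pytest.approx(analytic_each, rel=0.01)


def test_sasa_cross_checked_against_biotite(rng):
    """Total SASA of a random atom cloud agrees with biotite's
    independent Shrake-Rupley implementation under matched radii."""
    import biotite.structure as struc

    n = 40
    coords = rng.normal(size=(n, 3)) * 4.0
    elements = rng.choice(["C", "N", "O", "S"], size=n)
    s = Structure([Chain("A")])
    for i, (xyz, el) in enumerate(zip(coords, elements)):
        r = Residue("GLY", i + 1)
        r.atoms.append(Atom("CA", el, xyz))
        s.chains[0].residues.append(r)
    ours = bs.sasa(s, probe_radius=1.4, n_points=1000).sum()

    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.element = elements
    arr.atom_name = np.array(["CA"] * n)
    arr.res_name = np.array(["GLY"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.chain_id = np.array(["A"] * n)
    radii = np.array([bs.structcmp.VDW_RADII[e] for e in elements])
    theirs = struc.sasa(arr, probe_radius=1.4, point_number=1000,
                        vdw_radii=radii).sum()
    assert ours == pytest.approx(theirs, rel=0.02)


def test_sasa_quadrature_convergence():
    spec = bs.ToyStructureSpec(kind="helix-of-atoms", n_atoms=25)
    s = bs.make_toy_structure(spec)
    a1 = bs.sasa(s, n_points=960).sum()
    a2 = bs.sasa(s, n_points=1920).sum()
    assert abs(a2 - a1) / a2 < 0.005


# --------------------------------------------------------------- interfaces

def test_distant_chains_bury_nothing():
    s = bs.make_toy_structure(
        bs.ToyStructureSpec(kind="two-chain-block", separation=100.0))
    rep = bs.interface_area(s, "A", "B")
    assert abs(rep.buried_area) < 1e-6
    assert bs.interface_residue_fraction(rep, "A") == 0.0


def test_interface_symmetry_under_swap():
    s = bs.make_toy_structure(
        bs.ToyStructureSpec(kind="two-chain-block", separation=4.0))
    r1 = bs.interface_area(s, "A", "B")
    r2 = bs.interface_area(s, "B", "A")
    assert r1.buried_area == pytest.approx(r2.buried_area, abs=1e-9)
    assert r1.buried_area > 0


def test_interface_bounded_by_component_areas():
    s = bs.make_toy_structure(
        bs.ToyStructureSpec(kind="two-chain-block", separation=3.5))
    rep = bs.interface_area(s, "A", "B")
    assert 0 < rep.buried_area <= min(rep.sasa_a, rep.sasa_b)


def test_tight_blocks_have_full_interface_fraction():
    s = bs.make_toy_structure(
        bs.ToyStructureSpec(kind="two-chain-block", separation=3.5,
                            block_shape=(1, 2, 2)))
    rep = bs.interface_area(s, "A", "B")
    assert bs.interface_residue_fraction(rep, "A") == 100.0
    assert bs.interface_residue_fraction(rep, "B") == 100.0


def test_overlapping_selections_rejected():
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="two-chain-block"))
    idx = select(s, "A")
    with pytest.raises(ValueError, match="overlap"):
        bs.interface_area(s, idx, idx)


# ------------------------------------------------------------------- Kabsch

def test_identical_sets_have_zero_rmsd(rng):
    X = rng.normal(size=(30, 3))
    sup = bs.kabsch_superpose(X, X.copy())
    assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)


def rotation_matrix(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def test_rigid_copy_recovers_transform(rng):
    X = rng.normal(size=(50, 3)) * 10
    R = rotation_matrix(rng)
    t = rng.normal(size=3) * 5
    Y = X @ R.T + t
    sup = bs.kabsch_superpose(X, Y)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(sup.rotation, R, atol=1e-9)
    np.testing.assert_allclose(sup.translation, t, atol=1e-8)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


def test_rmsd_invariant_under_rigid_motion_and_symmetric(rng):
    X = rng.normal(size=(40, 3)) * 8
    Y = X + rng.normal(size=(40, 3))
    base = bs.kabsch_superpose(X, Y).rmsd
    R = rotation_matrix(rng)
    t = rng.normal(size=3)
    assert bs.kabsch_superpose(X @ R.T + t, Y).rmsd == pytest.approx(base, abs=1e-6)
    assert bs.kabsch_superpose(Y, X).rmsd == pytest.approx(base, abs=1e-6)


def test_gaussian_noise_rmsd_expectation(rng):
    """Isotropic sigma=0.5 A noise per coordinate: rmsd ~ sigma*sqrt(3)
    within 10% at 200 atoms (Monte-Carlo expectation)."""
    sigma = 0.5
    X = rng.normal(size=(200, 3)) * 20
    Y = X + rng.normal(scale=sigma, size=(200, 3))
    sup = bs.kabsch_superpose(X, Y)
    assert sup.rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.10)


def test_kabsch_agrees_with_scipy_oracle(rng):
    from scipy.spatial.transform import Rotation
    X = rng.normal(size=(25, 3)) * 6
    Y = X @ rotation_matrix(rng).T + rng.normal(size=(25, 3)) * 0.4
    sup = bs.kabsch_superpose(X, Y)
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    rot, rssd = Rotation.align_vectors(Yc, Xc)
    np.testing.assert_allclose(sup.rotation, rot.as_matrix(), atol=1e-8)
    assert sup.rmsd == pytest.approx(rssd / np.sqrt(len(X)), abs=1e-8)


def test_degenerate_geometry_rejected():
    line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(ValueError, match="degenerate|collinear"):
        bs.kabsch_superpose(line, line + 1.0)
    with pytest.raises(ValueError, match="at least 3"):
        bs.kabsch_superpose(np.zeros((2, 3)), np.ones((2, 3)))


# -------------------------------------------------------------- alignment

def protein_chain(seq, start=1, coords=None):
    ch = Chain("A")
    one_to_three = {v: k for k, v in
                    {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D",
                     "CYS": "C", "GLN": "Q", "GLU": "E", "GLY": "G",
                     "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
                     "MET": "M", "PHE": "F", "PRO": "P", "SER": "S",
                     "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}.items()}
    for i, aa in enumerate(seq):
        r = Residue(one_to_three[aa], start + i)
        xyz = coords[i] if coords is not None else [3.8 * i, 0.0, 0.0]
        r.atoms.append(Atom("CA", "C", xyz))
        ch.residues.append(r)
    return ch


def test_self_alignment_is_identity():
    ch = protein_chain("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
    corr = bs.align_sequences(ch, ch)
    assert len(corr) == 33
    assert corr.identity == pytest.approx(100.0)


def test_truncated_self_alignment_pairs_shorter_length():
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    full = protein_chain(seq)
    short = protein_chain(seq[:-5])
    corr = bs.align_sequences(full, short)
    assert len(corr) == len(seq) - 5


def needleman_wunsch(a, b, match_matrix, gap_open, gap_extend):
    """Independent affine-gap global aligner (Gotoh) returning
    (score, identity%) over aligned pairs of one optimal alignment."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    ptr = {}
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match_matrix[a[i - 1], b[j - 1]]
            opts = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            M[i, j] = max(opts) + s
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
    # traceback on best end state
    i, j = n, m
    best_score = max(M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    ident = aligned = 0
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            aligned += 1
            if a[i - 1] == b[j - 1]:
                ident += 1
            s = match_matrix[a[i - 1], b[j - 1]]
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            state = 0 if M[i - 1, j] + gap_open >= Ix[i - 1, j] + gap_extend else 1
            i -= 1
        else:
            state = 0 if M[i, j - 1] + gap_open >= Iy[i, j - 1] + gap_extend else 2
            j -= 1
    return best_score, 100.0 * ident / aligned


def test_alignment_matches_dp_oracle(rng):
    """Alignment score equals an independent Gotoh implementation exactly;
    identity agrees up to co-optimal-alignment differences."""
    from Bio.Align import substitution_matrices
    blosum = substitution_matrices.load("BLOSUM62")
    mat = {(x, y): blosum[x, y] for x in blosum.alphabet for y in blosum.alphabet}
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(3):
        a = "".join(rng.choice(list(aas), size=50))
        b = "".join(rng.choice(list(aas), size=50))
        corr = bs.align_sequences(protein_chain(a), protein_chain(b))
        score, ident = needleman_wunsch(a, b, mat, gap_open=-11.0,
                                        gap_extend=-1.0)
        assert corr.score == pytest.approx(score, abs=1e-9)
        assert corr.identity == pytest.approx(ident, abs=4.0)


def test_alignment_requires_protein():
    empty = Chain("A")
    with pytest.raises(ValueError, match="amino-acid"):
        bs.align_sequences(empty, empty)


# ---------------------------------------------------------------- contacts

def test_planted_hydrogen_bond_is_classified():
    s = bs.make_contact_fixture(distance=2.8)
    recs = bs.classify_contacts(s)
    hb = [r for r in recs if r.is_hbond]
    assert len(hb) == 1
    assert hb[0].protein_atom == "OG" and hb[0].dna_atom == "OP1"
    assert hb[0].dna_group == "backbone"
    assert hb[0].distance == pytest.approx(2.8, abs=1e-3)


def test_contact_beyond_cutoff_ignored():
    s = bs.make_contact_fixture(distance=4.2)
    recs = bs.classify_contacts(s)
    assert not any(r.is_hbond for r in recs)
    assert all(r.distance <= 4.0 for r in recs)


def test_contact_classes_partition_dna_atoms():
    from bindspec.structcmp import _dna_atom_group
    for name, expected in [("P", "backbone"), ("OP2", "backbone"),
                           ("O5'", "backbone"), ("C1'", "deoxyribose"),
                           ("O4'", "deoxyribose"), ("N7", "base"),
                           ("O6", "base"), ("N2", "base")]:
        assert _dna_atom_group(name) == expected


def test_contacts_require_dna():
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="two-chain-block"))
    with pytest.raises(ValueError, match="DNA"):
        bs.classify_contacts(s)


# ---------------------------------------------------------------- symmetry

def cubic_crystal(a=30.0):
    # P 21 21 21-like toy operator set: identity + one 2-fold screw
    ops = [
        (np.eye(3), np.zeros(3)),
        (np.diag([-1.0, -1.0, 1.0]), np.array([0.5, 0.0, 0.5])),
    ]
    return Crystal("P 1 21 1", (a, a, a, 90.0, 90.0, 90.0), ops)


def test_symmetry_requires_crystal():
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="single-sphere"))
    with pytest.raises(ValueError, match="crystal"):
        bs.expand_symmetry(s)


def test_symmetry_mates_are_isometric():
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="helix-of-atoms",
                                                  n_atoms=12))
    s.crystal = cubic_crystal(a=18.0)
    mates = bs.expand_symmetry(s, contact_cutoff=25.0)
    assert mates
    _, orig = s.atom_table()
    d_orig = np.linalg.norm(orig[:, None] - orig[None, :], axis=2)
    for mate in mates:
        _, xyz = mate.atom_table()
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
        np.testing.assert_allclose(d, d_orig, atol=1e-6)


def test_pure_lattice_translation_preserves_coordinates_shape():
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="single-sphere"))
    s.crystal = Crystal("P 1", (5.0, 5.0, 5.0, 90, 90, 90),
                        [(np.eye(3), np.zeros(3))])
    mates = bs.expand_symmetry(s, contact_cutoff=6.0)
    # neighbours along each axis at 5 A
    assert len(mates) == 6
    for mate in mates:
        _, xyz = mate.atom_table()
        assert np.linalg.norm(xyz[0]) == pytest.approx(5.0)


def test_operator_determinant_validation():
    with pytest.raises(ValueError, match="determinant"):
        Crystal("bad", (10, 10, 10, 90, 90, 90),
                [(np.eye(3) * 2.0, np.zeros(3))])


# ------------------------------------------------------------------- I/O

def test_pdb_roundtrip_preserves_atoms(tmp_path):
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="two-chain-block",
                                                  separation=6.0))
    path = tmp_path / "toy.pdb"
    bs.write_pdb(s, path)
    again = bs.read_structure(path)
    assert again.n_atoms == s.n_atoms
    _, c1 = s.atom_table()
    _, c2 = again.atom_table()
    np.testing.assert_allclose(c2, c1, atol=1e-3)
    assert [c.name for c in again.chains] == ["A", "B"]


def test_altloc_keeps_highest_occupancy(tmp_path):
    pdb = (
        "ATOM      1  CA AALA A   1      0.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      2  CA BALA A   1      5.000   0.000   0.000  0.60  0.00           C\n"
        "END\n")
    p = tmp_path / "altloc.pdb"
    p.write_text(pdb)
    s = bs.read_structure(p)
    assert s.n_atoms == 1
    atom = next(s.iter_atoms())[2]
    assert atom.pos[0] == pytest.approx(5.0)  # the 0.6-occupancy conformer


def test_malformed_file_raises(tmp_path):
    p = tmp_path / "bad.cif"
    p.write_text("this is not a structure\n")
    with pytest.raises(ValueError, match="parse|failed"):
        bs.read_structure(p, fmt="cif")


def test_crystal_header_roundtrip(tmp_path):
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="single-sphere"))
    s.crystal = Crystal("P 1", (20.0, 20.0, 20.0, 90, 90, 90),
                        [(np.eye(3), np.zeros(3))])
    path = tmp_path / "cryst.pdb"
    bs.write_pdb(s, path)
    again = bs.read_structure(path)
    assert again.crystal is not None
    assert again.crystal.cell[0] == pytest.approx(20.0)


def test_selection_syntax(tmp_path):
    s = bs.make_toy_structure(bs.ToyStructureSpec(kind="two-chain-block",
                                                  block_shape=(2, 2, 2)))
    assert len(select(s, "A")) == 8
    assert len(select(s, "A:1-4")) == 4
    assert len(select(s, "A:1-4,B:1-2")) == 6
    with pytest.raises(ValueError, match="matched no atoms"):
        select(s, "Z")
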