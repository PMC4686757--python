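"""Structure comparison and protein-DNA contact analysis.

Covers the quantitative structural toolbox: PDB/mmCIF reading (via
gemmi), sequence-guided C-alpha superposition (Kabsch), Shrake-Rupley
solvent-accessible surface area, pairwise buried interface areas and
interface-residue fractions (PISA-style half-buried-area convention),
distance-based protein-DNA contact classification, and crystallographic
symmetry-mate expansion.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

# ------------------------------------------------------------------- domain

#: van der Waals radii (A) used for SASA; standard set.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_FALLBACK_RADIUS = 1.70

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
NUCLEOTIDES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U", "DI"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "C", "PYL": "K",
}

DNA_BACKBONE_ATOMS = {"P", "OP1", "OP2", "OP3", "O5'", "O3'"}
DNA_SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"}


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray          # (3,) in A
    occupancy: float = 1.0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.isfinite(self.pos).all():
            raise ValueError("atom coordinates must be 3 finite numbers")


@dataclass
class Residue:
    name: str
    seqid: int
    icode: str = ""
    atoms: List[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_amino_acid(self) -> bool:
        return self.name in AMINO_ACIDS

    @property
    def is_nucleotide(self) -> bool:
        return self.name in NUCLEOTIDES


@dataclass
class Chain:
    name: str
    residues: List[Residue] = field(default_factory=list)

    @property
    def is_protein(self) -> bool:
        aa = sum(r.is_amino_acid for r in self.residues)
        return aa > len(self.residues) / 2 if self.residues else False

    @property
    def is_dna(self) -> bool:
        nt = sum(r.is_nucleotide for r in self.residues)
        return nt > len(self.residues) / 2 if self.residues else False

    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X")
                       for r in self.residues if r.is_amino_acid)


@dataclass
class Crystal:
    spacegroup: str
    cell: Tuple[float, float, float, float, float, float]
    operators: List[Tuple[np.ndarray, np.ndarray]]  # fractional (R, t)

    def __post_init__(self):
        for R, _ in self.operators:
            det = float(np.linalg.det(R))
            if abs(abs(det) - 1.0) > 1e-6:
                raise ValueError(f"symmetry rotation determinant {det} is not +-1")


@dataclass
class Structure:
    """Chains -> residues -> atoms, plus crystal symmetry when present."""

    chains: List[Chain] = field(default_factory=list)
    crystal: Optional[Crystal] = None
    label: str = ""

    def chain(self, name: str) -> Chain:
        for c in self.chains:
            if c.name == name:
                return c
        raise KeyError(f"no chain named {name!r}")

    def iter_atoms(self):
        """Yield (chain, residue, atom) triples in file order."""
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def atom_table(self):
        """Parallel arrays: coords (n,3), element, chain name, residue key."""
        triples = list(self.iter_atoms())
        coords = np.array([a.pos for _, _, a in triples]) if triples else np.empty((0, 3))
        return triples, coords

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def subset(self, indices: Sequence[int], label: str = "") -> "Structure":
        """New Structure containing only the atoms at the given global
        indices (in :meth:`iter_atoms` order)."""
        wanted = set(int(i) for i in indices)
        chains: List[Chain] = []
        idx = 0
        for c in self.chains:
            new_c = Chain(c.name)
            for r in c.residues:
                new_r = Residue(r.name, r.seqid, r.icode)
                for a in r.atoms:
                    if idx in wanted:
                        new_r.atoms.append(a)
                    idx += 1
                if new_r.atoms:
                    new_c.residues.append(new_r)
            if new_c.residues:
                chains.append(new_c)
        return Structure(chains, crystal=self.crystal,
                         label=label or self.label)


# ----------------------------------------------------------------- file I/O

def read_structure(path, fmt: Optional[str] = None,
                   keep_waters: bool = False) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    The format is inferred from the extension unless given ('pdb' or
    'cif'). Alternate conformations are reduced to the highest-occupancy
    conformer; waters are dropped unless ``keep_waters``. Crystal
    symmetry operators are taken from the space-group header when
    present.
    """
    import gemmi

    path = Path(path)
    fmt = (fmt or ("cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")).lower()
    try:
        if fmt in ("cif", "mmcif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc

    st.setup_entities()
    if not keep_waters:
        st.remove_waters()

    model = st[0]
    chains: List[Chain] = []
    for ch in model:
        chain = Chain(ch.name)
        for res in ch:
            residue = Residue(res.name.strip(), res.seqid.num,
                              res.seqid.icode.strip())
            # altloc reduction: keep the highest-occupancy conformer per
            # atom name (ties resolve to the first one encountered)
            chosen: Dict[str, Atom] = {}
            for at in res:
                atom = Atom(
                    name=at.name,
                    element=at.element.name.upper() or "X",
                    pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=float(at.occ),
                )
                prev = chosen.get(at.name)
                if prev is None or atom.occupancy > prev.occupancy:
                    chosen[at.name] = atom
            residue.atoms = list(chosen.values())
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            chains.append(chain)

    crystal = None
    if st.cell and st.cell.a > 1.0 and st.spacegroup_hm:
        sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm)
        if sg is not None:
            ops = []
            for op in sg.operations():
                R = np.array(op.rot, dtype=float) / op.DEN
                t = np.array(op.tran, dtype=float) / op.DEN
                ops.append((R, t))
            crystal = Crystal(
                spacegroup=st.spacegroup_hm,
                cell=(st.cell.a, st.cell.b, st.cell.c,
                      st.cell.alpha, st.cell.beta, st.cell.gamma),
                operators=ops,
            )
    return Structure(chains, crystal=crystal, label=path.stem)


def write_pdb(structure: Structure, path) -> None:
    """Write a minimal PDB file (ATOM/TER records, CRYST1 when present)."""
    with open(path, "w") as fh:
        if structure.crystal is not None:
            a, b, c, al, be, ga = structure.crystal.cell
            fh.write("CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f %-11s\n"
                     % (a, b, c, al, be, ga, structure.crystal.spacegroup))
        serial = 1
        for chain in structure.chains:
            for res in chain.residues:
                for at in res.atoms:
                    name = at.name if len(at.name) >= 4 else f" {at.name:<3s}"
                    record = "ATOM" if (res.is_amino_acid or res.is_nucleotide) else "HETATM"
                    fh.write(
                        "%-6s%5d %-4s %-3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f          %2s\n"
                        % (record, serial, name, res.name[:3], chain.name[:1],
                           res.seqid, res.icode[:1] or " ",
                           at.pos[0], at.pos[1], at.pos[2], at.occupancy, 0.0,
                           at.element[:2]))
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


# --------------------------------------------------------------- selections

def select(structure: Structure, spec: str) -> List[int]:
    """Global atom indices matching a ``chain`` or ``chain:first-last``
    selection (author numbering, 1-based inclusive). Multiple terms may
    be joined with commas."""
    indices: List[int] = []
    terms = [t.strip() for t in spec.split(",") if t.strip()]
    if not terms:
        raise ValueError("empty selection")
    for term in terms:
        if ":" in term:
            chain_name, rng = term.split(":", 1)
            lo_s, _, hi_s = rng.partition("-")
            lo = int(lo_s)
            hi = int(hi_s) if hi_s else lo
        else:
            chain_name, lo, hi = term, None, None
        found = False
        idx = 0
        for c in structure.chains:
            for r in c.residues:
                keep = (c.name == chain_name
                        and (lo is None or lo <= r.seqid <= hi))
                for _ in r.atoms:
                    if keep:
                        indices.append(idx)
                        found = True
                    idx += 1
        if not found:
            raise ValueError(f"selection {term!r} matched no atoms")
    return indices


def split_at_largest_gap(chain: Chain) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Split a protein chain into two residue ranges at its largest
    author-numbering gap.

    Tandem-domain chains whose inter-domain linker is partly unmodelled
    (e.g. the two DNA-binding domains of an atypical E2F) show up as a
    numbering discontinuity; the residues before the largest gap form the
    first group (domain 1 plus any resolved linker helices), those after
    it the second (domain 2). Returns ((first_start, first_end),
    (second_start, second_end)) in author numbering, inclusive.
    """
    seqids = [r.seqid for r in chain.residues if r.is_amino_acid]
    if len(seqids) < 2:
        raise ValueError("chain has fewer than 2 amino-acid residues")
    gaps = np.diff(seqids)
    k = int(np.argmax(gaps))
    if gaps[k] <= 1:
        raise ValueError("chain has no numbering gap to split at")
    return (seqids[0], seqids[k]), (seqids[k + 1], seqids[-1])


def polymer_indices(structure: Structure, exclude_het: bool = True) -> List[int]:
    """Atom indices of polymer residues (amino acids + nucleotides)."""
    out = []
    for i, (c, r, a) in enumerate(structure.iter_atoms()):
        if not exclude_het or r.is_amino_acid or r.is_nucleotide:
            out.append(i)
    return out


# -------------------------------------------------------- sequence alignment

@dataclass
class Correspondence:
    """One-to-one residue pairing with C-alpha coordinates on both sides."""

    pairs: List[Tuple[Residue, Residue]]
    coords_a: np.ndarray
    coords_b: np.ndarray
    identity: float          # percent identical over aligned (ungapped) pairs
    n_gaps: int
    score: float = 0.0       # alignment score (substitution matrix units)

    def __len__(self) -> int:
        return len(self.pairs)


def align_sequences(res_a: Sequence[Residue] | Chain,
                    res_b: Sequence[Residue] | Chain,
                    gap_open: float = -11.0,
                    gap_extend: float = -1.0) -> Correspondence:
    """Global protein-sequence alignment (BLOSUM62, affine gaps) yielding
    the aligned, ungapped residue pairs whose C-alpha atoms exist."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    res_a = list(res_a.residues) if isinstance(res_a, Chain) else list(res_a)
    res_b = list(res_b.residues) if isinstance(res_b, Chain) else list(res_b)
    res_a = [r for r in res_a if r.is_amino_acid]
    res_b = [r for r in res_b if r.is_amino_acid]
    if not res_a or not res_b:
        raise ValueError("both inputs must contain amino-acid residues")

    seq_a = "".join(THREE_TO_ONE.get(r.name, "X") for r in res_a)
    seq_b = "".join(THREE_TO_ONE.get(r.name, "X") for r in res_b)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a, seq_b)[0]

    pairs, ca_a, ca_b = [], [], []
    n_ident = n_aligned = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            n_aligned += 1
            if seq_a[i] == seq_b[j]:
                n_ident += 1
            a_ca = res_a[i].atom("CA")
            b_ca = res_b[j].atom("CA")
            if a_ca is not None and b_ca is not None:
                pairs.append((res_a[i], res_b[j]))
                ca_a.append(a_ca.pos)
                ca_b.append(b_ca.pos)
    if not pairs:
        raise ValueError("alignment produced no residue pairs with C-alpha atoms")
    blocks = aln.aligned[0]
    n_gaps = (len(blocks) - 1)
    return Correspondence(
        pairs=pairs,
        coords_a=np.asarray(ca_a), coords_b=np.asarray(ca_b),
        identity=100.0 * n_ident / n_aligned,
        n_gaps=n_gaps,
        score=float(aln.score),
    )


# ---------------------------------------------------------------- Kabsch fit

@dataclass
class Superposition:
    rotation: np.ndarray     # (3,3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float              # A
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rotation": self.rotation.tolist(),
                       "translation": self.translation.tolist(),
                       "rmsd": self.rmsd, "n_pairs": self.n_pairs},
                      fh, indent=2)


def kabsch_superpose(corr_or_a, b: Optional[np.ndarray] = None) -> Superposition:
    """Least-squares rigid superposition of paired coordinates.

    Accepts a :class:`Correspondence` or two (n, 3) arrays (moving A onto
    fixed B).  The rotation is proper (determinant +1; reflections are
    disallowed).  RMSD is over the paired atoms after the transform.
    """
    if b is None:
        A, B = corr_or_a.coords_a, corr_or_a.coords_b
    else:
        A, B = np.asarray(corr_or_a, float), np.asarray(b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    # collinear/degenerate point sets leave the rotation under-determined
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A @ R.T + t - B
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


# --------------------------------------------------------------------- SASA

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral / Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(structure: Structure, probe_radius: float = 1.4, n_points: int = 960,
         radii: Optional[Dict[str, float]] = None,
         fallback_radius: float = DEFAULT_FALLBACK_RADIUS,
         include_het: bool = False) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), A^2.

    Waters/heteroatoms are excluded by default (they receive area 0).
    Unknown elements fall back to ``fallback_radius`` with a warning.
    """
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    triples, coords = structure.atom_table()
    n = len(triples)
    areas = np.zeros(n)
    if n == 0:
        return areas
    active = np.array([
        (include_het or r.is_amino_acid or r.is_nucleotide) and a.element != "H"
        for _, r, a in triples
    ])
    if not active.any():
        return areas
    idx = np.flatnonzero(active)
    rad = np.empty(idx.size)
    warned = set()
    for k, i in enumerate(idx):
        el = triples[i][2].element
        if el not in table and el not in warned:
            warnings.warn(f"unknown element {el!r}: using fallback radius "
                          f"{fallback_radius} A")
            warned.add(el)
        rad[k] = table.get(el, fallback_radius)

    pts = _sphere_points(n_points)
    xyz = coords[idx]
    ext = rad + probe_radius
    tree = cKDTree(xyz)
    max_reach = 2.0 * ext.max()
    for k in range(idx.size):
        neigh = [j for j in tree.query_ball_point(xyz[k], ext[k] + ext.max())
                 if j != k]
        surface = xyz[k] + ext[k] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = ((surface - xyz[j]) ** 2).sum(axis=1)
            exposed &= d2 > ext[j] ** 2
        areas[idx[k]] = 4.0 * np.pi * ext[k] ** 2 * exposed.sum() / n_points
    return areas


# ------------------------------------------------------------- interfaces

@dataclass
class InterfaceReport:
    """Buried area between two atom selections plus per-residue detail.

    ``buried_area = (SASA_A + SASA_B - SASA_AB) / 2`` (PISA convention);
    a residue is an interface residue when its summed delta-SASA exceeds
    ``residue_threshold``.
    """

    buried_area: float
    sasa_a: float
    sasa_b: float
    sasa_ab: float
    dsasa_a: Dict[Tuple[str, int, str], float]    # (chain, seqid, resname) -> dSASA
    dsasa_b: Dict[Tuple[str, int, str], float]
    n_residues_a: int
    n_residues_b: int
    probe_radius: float
    n_points: int
    residue_threshold: float = 0.1

    def interface_residues(self, side: str) -> List[Tuple[str, int, str]]:
        table = self.dsasa_a if side == "A" else self.dsasa_b
        return [k for k, v in sorted(table.items()) if v > self.residue_threshold]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# buried_area_A2\t{self.buried_area:.3f}\n")
            fh.write(f"# probe_radius_A\t{self.probe_radius}\n")
            fh.write("side\tchain\tresidue\tname\tdelta_sasa_A2\tinterface\n")
            for side, table in (("A", self.dsasa_a), ("B", self.dsasa_b)):
                for (ch, num, name), v in sorted(table.items()):
                    fh.write(f"{side}\t{ch}\t{num}\t{name}\t{v:.3f}\t"
                             f"{int(v > self.residue_threshold)}\n")


def interface_area(structure: Structure, set_a: Sequence[int] | str,
                   set_b: Sequence[int] | str, probe_radius: float = 1.4,
                   n_points: int = 960,
                   residue_threshold: float = 0.1) -> InterfaceReport:
    """Buried interface area between two disjoint atom selections.

    The three SASA computations (A alone, B alone, A+B) use identical
    sampling so quadrature error largely cancels in the difference.
    """
    if isinstance(set_a, str):
        set_a = select(structure, set_a)
    if isinstance(set_b, str):
        set_b = select(structure, set_b)
    sa, sb = set(set_a), set(set_b)
    if sa & sb:
        raise ValueError("selections overlap")

    sub_a = structure.subset(sorted(sa), label="A")
    sub_b = structure.subset(sorted(sb), label="B")
    sub_ab = structure.subset(sorted(sa | sb), label="AB")

    kw = dict(probe_radius=probe_radius, n_points=n_points)
    areas_a = sasa(sub_a, **kw)
    areas_b = sasa(sub_b, **kw)
    areas_ab = sasa(sub_ab, **kw)

    def per_residue(sub: Structure, areas: np.ndarray) -> Dict:
        out: Dict[Tuple[str, int, str], float] = {}
        for i, (c, r, a) in enumerate(sub.iter_atoms()):
            key = (c.name, r.seqid, r.name)
            out[key] = out.get(key, 0.0) + float(areas[i])
        return out

    iso_a = per_residue(sub_a, areas_a)
    iso_b = per_residue(sub_b, areas_b)
    ab = per_residue(sub_ab, areas_ab)
    dsasa_a = {k: v - ab.get(k, 0.0) for k, v in iso_a.items()}
    dsasa_b = {k: v - ab.get(k, 0.0) for k, v in iso_b.items()}

    def n_polymer_res(sub: Structure) -> int:
        return sum(1 for c in sub.chains for r in c.residues
                   if r.is_amino_acid or r.is_nucleotide)

    total_a, total_b, total_ab = areas_a.sum(), areas_b.sum(), areas_ab.sum()
    return InterfaceReport(
        buried_area=float((total_a + total_b - total_ab) / 2.0),
        sasa_a=float(total_a), sasa_b=float(total_b), sasa_ab=float(total_ab),
        dsasa_a=dsasa_a, dsasa_b=dsasa_b,
        n_residues_a=n_polymer_res(sub_a), n_residues_b=n_polymer_res(sub_b),
        probe_radius=probe_radius, n_points=n_points,
        residue_threshold=residue_threshold,
    )


def interface_residue_fraction(report: InterfaceReport, side: str) -> float:
    """Percentage of a side's modelled residues that are at the interface."""
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    n = report.n_residues_a if side == "A" else report.n_residues_b
    if n == 0:
        return 0.0
    return 100.0 * len(report.interface_residues(side)) / n


# ----------------------------------------------------------------- contacts

@dataclass(frozen=True)
class ContactRecord:
    protein_chain: str
    protein_residue: str     # e.g. 'ARG313'
    protein_atom: str
    dna_chain: str
    dna_residue: str         # e.g. 'DG10'
    dna_atom: str
    distance: float
    dna_group: str           # 'backbone' | 'deoxyribose' | 'base'
    is_hbond: bool


def _dna_atom_group(atom_name: str) -> str:
    if atom_name in DNA_BACKBONE_ATOMS:
        return "backbone"
    if atom_name in DNA_SUGAR_ATOMS:
        return "deoxyribose"
    return "base"


def classify_contacts(structure: Structure,
                      protein_sel: Sequence[int] | str | None = None,
                      dna_sel: Sequence[int] | str | None = None,
                      hbond_cutoff: float = 3.5,
                      contact_cutoff: float = 4.0) -> List[ContactRecord]:
    """Distance-based protein-DNA contacts, classified by the DNA atom.

    Any protein/DNA atom pair within ``contact_cutoff`` is a contact;
    pairs of N/O atoms (donor/acceptor-capable) within ``hbond_cutoff``
    are additionally flagged as hydrogen bonds.  The DNA atom's group
    labels the contact backbone (phosphate), deoxyribose (sugar) or base
    (ring); the three classes partition the DNA atom names.  One record
    per atom pair.
    """
    triples, coords = structure.atom_table()

    def resolve(sel, default_pred):
        if sel is None:
            return [i for i, (c, r, a) in enumerate(triples) if default_pred(c, r)]
        if isinstance(sel, str):
            return select(structure, sel)
        return list(sel)

    prot_idx = resolve(protein_sel, lambda c, r: r.is_amino_acid)
    dna_idx = resolve(dna_sel, lambda c, r: r.is_nucleotide)
    if not prot_idx:
        raise ValueError("protein selection is empty")
    dna_idx = [i for i in dna_idx if triples[i][1].is_nucleotide]
    if not dna_idx:
        raise ValueError("no DNA atoms in selection")

    tree = cKDTree(coords[dna_idx])
    records = []
    for pi in prot_idx:
        c_p, r_p, a_p = triples[pi]
        for local_j in tree.query_ball_point(coords[pi], contact_cutoff):
            di = dna_idx[local_j]
            c_d, r_d, a_d = triples[di]
            dist = float(np.linalg.norm(a_p.pos - a_d.pos))
            if dist <= 0:
                continue
            hbond = (a_p.element in ("N", "O") and a_d.element in ("N", "O")
                     and dist <= hbond_cutoff)
            records.append(ContactRecord(
                protein_chain=c_p.name,
                protein_residue=f"{r_p.name}{r_p.seqid}",
                protein_atom=a_p.name,
                dna_chain=c_d.name,
                dna_residue=f"{r_d.name}{r_d.seqid}",
                dna_atom=a_d.name,
                distance=round(dist, 3),
                dna_group=_dna_atom_group(a_d.name),
                is_hbond=hbond,
            ))
    records.sort(key=lambda r: (r.protein_chain, r.protein_residue,
                                r.protein_atom, r.dna_chain, r.dna_residue,
                                r.dna_atom))
    return records


def contacts_to_tsv(records: Iterable[ContactRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_chain\tprotein_residue\tprotein_atom\tdna_chain\t"
                 "dna_residue\tdna_atom\tdistance_A\tdna_group\thbond\n")
        for r in records:
            fh.write(f"{r.protein_chain}\t{r.protein_residue}\t{r.protein_atom}\t"
                     f"{r.dna_chain}\t{r.dna_residue}\t{r.dna_atom}\t"
                     f"{r.distance:.3f}\t{r.dna_group}\t{int(r.is_hbond)}\n")


# ---------------------------------------------------------------- symmetry

def expand_symmetry(structure: Structure, contact_cutoff: float = 5.0) -> List[Structure]:
    """Crystallographic symmetry mates close to the asymmetric unit.

    Every space-group operator combined with lattice translations within
    one unit cell of the original is applied in orthogonal coordinates;
    a mate is kept when any of its atoms lies within ``contact_cutoff``
    of the original. The identity copy itself is not returned.
    """
    import gemmi

    if structure.crystal is None:
        raise ValueError("structure carries no crystal symmetry")
    a, b, c, al, be, ga = structure.crystal.cell
    cell = gemmi.UnitCell(a, b, c, al, be, ga)
    orth = np.array(cell.orth.mat.tolist())
    frac_m = np.array(cell.frac.mat.tolist())

    triples, coords = structure.atom_table()
    frac = coords @ frac_m.T
    tree = cKDTree(coords)

    mates = []
    shifts = [np.array([i, j, k], float)
              for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    for op_i, (R, t) in enumerate(structure.crystal.operators):
        base = frac @ R.T + t
        for shift in shifts:
            if op_i == 0 and not shift.any() and np.allclose(R, np.eye(3)) \
                    and not np.asarray(t).any():
                continue  # the original itself
            new_frac = base + shift
            new_xyz = new_frac @ orth.T
            dmin, _ = tree.query(new_xyz, k=1)
            if dmin.min() > contact_cutoff:
                continue
            if np.abs(new_xyz - coords).max() < 1e-6:
                continue  # identity image reached through another operator
            mate = _with_coords(structure, new_xyz,
                                label=f"{structure.label}_op{op_i}"
                                      f"_{int(shift[0])}{int(shift[1])}{int(shift[2])}")
            mates.append(mate)
    return mates


def _with_coords(structure: Structure, coords: np.ndarray, label: str) -> Structure:
    out = Structure(chains=[], crystal=structure.crystal, label=label)
    i = 0
    for c in structure.chains:
        nc = Chain(c.name)
        for r in c.residues:
            nr = Residue(r.name, r.seqid, r.icode)
            for a in r.atoms:
                nr.atoms.append(Atom(a.name, a.element, coords[i].copy(),
                                     a.occupancy))
                i += 1
            nc.residues.append(nr)
        out.chains.append(nc)
    return out
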