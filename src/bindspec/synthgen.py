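"""Synthetic inputs for every pipeline stage.

The SELEX generator emulates the ligand design of the assay this
package analyses: a 6-bp and a 3-bp barcode flanking a 40-bp randomized
region, selected over up to four cycles against a planted binding model
with Boltzmann-style retention on the best-scoring site per ligand.
The ITC generator produces a 20-injection titration at 20 C with
Gaussian heat noise from the exact one-site forward model, and the toy
structure factory builds small geometric fixtures for the SASA /
superposition / contact machinery.

All randomness flows through one seeded generator per call; seeds live
in the configs so every fixture is reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Union

import numpy as np

from ._alphabet import BASES, encode
from .itc import Isotherm, OneSiteParams, one_site_isotherm
from .motif import DinucModel, PWM, best_window_scores
from .pool import ReadPool
from .structcmp import Atom, Chain, Residue, Structure

# ------------------------------------------------------------------ SELEX

@dataclass
class SelexSimConfig:
    """Configuration of a simulated HT-SELEX experiment.

    Defaults mirror the assayed ligand layout (6+40+3 bp) and selection
    depth (4 cycles). ``selection_strength`` is the Boltzmann sharpness
    applied to the best-window log2-odds score of each ligand; the
    default ln(2)/n_cycles makes the cumulative enrichment over all
    cycles reproduce the planted model's site composition exactly at the
    fixed point (see docs/methods.md).

    ``library_depth`` models the fact that the unselected ligand library
    is far deeper than what is sequenced: selection operates on
    ``library_depth x n_reads_per_cycle`` virtual molecules, and each
    cycle's emitted pool is a sequenced subsample of ``n_reads_per_cycle``
    reads. At depth 1 selection degenerates to resampling the sequenced
    pool itself, which at desk scale contains essentially no perfect
    motif matches (a 40-bp random region yields one exact 12-mer site
    per ~15 million reads). The default depth of 400 gives the library
    ~90 expected exact-consensus founders for a 12-mer site at the
    default pool size, which keeps the shared Poisson noise of the
    seed-anchored counting estimator within a few percent (see
    docs/methods.md for the variance budget).
    """

    random_region_len: int = 40
    barcode5: str = "ACGTGC"
    barcode3: str = "GTC"
    n_reads_per_cycle: int = 50_000
    n_cycles: int = 4
    planted_model: Optional[Union[PWM, DinucModel]] = None
    selection_strength: Optional[float] = None   # None -> ln(2)/n_cycles
    background_base_probs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    library_depth: int = 400
    rng_seed: int = 0

    def __post_init__(self):
        for bc in (self.barcode5, self.barcode3):
            if (encode(bc) < 0).any():
                raise ValueError(f"barcode {bc!r} contains non-ACGT characters")
        if self.random_region_len < 0:
            raise ValueError("random_region_len must be >= 0")
        if not (0 <= self.n_cycles <= 4):
            raise ValueError("n_cycles must be in 0..4")
        if self.n_reads_per_cycle <= 0:
            raise ValueError("n_reads_per_cycle must be positive")
        self.background_base_probs = np.asarray(self.background_base_probs, float)
        if self.background_base_probs.shape != (4,) or \
                abs(self.background_base_probs.sum() - 1.0) > 1e-12:
            raise ValueError("background_base_probs must be a 4-vector summing to 1")
        if self.selection_strength is not None and self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")
        if self.library_depth < 1:
            raise ValueError("library_depth must be >= 1")
        if self.planted_model is not None and \
                len(self.planted_model) > self.random_region_len:
            raise ValueError("planted model longer than the randomized region")

    @property
    def read_length(self) -> int:
        return len(self.barcode5) + self.random_region_len + len(self.barcode3)

    @property
    def effective_strength(self) -> float:
        if self.selection_strength is not None:
            return self.selection_strength
        return math.log(2.0) / max(self.n_cycles, 1)


def make_ligand(cfg: SelexSimConfig, rng: np.random.Generator) -> str:
    """One ligand: barcode5 + i.i.d. random region + barcode3."""
    region = rng.choice(4, size=cfg.random_region_len,
                        p=cfg.background_base_probs)
    return cfg.barcode5 + "".join(BASES[b] for b in region) + cfg.barcode3


def _random_pool_codes(cfg: SelexSimConfig, rng: np.random.Generator,
                       n: int) -> np.ndarray:
    p = cfg.background_base_probs
    shape = (n, cfg.random_region_len)
    if np.allclose(p, 0.25):
        region = rng.integers(0, 4, size=shape, dtype=np.int8)
    else:
        # inverse-CDF sampling; much faster than rng.choice at this scale
        region = np.searchsorted(np.cumsum(p)[:-1], rng.random(shape),
                                 side="right").astype(np.int8)
    left = np.tile(encode(cfg.barcode5), (n, 1))
    right = np.tile(encode(cfg.barcode3), (n, 1))
    return np.concatenate([left, region, right], axis=1)


def _scores_chunked(codes: np.ndarray, model, background,
                    chunk: int = 200_000) -> np.ndarray:
    out = np.empty(codes.shape[0])
    for lo in range(0, codes.shape[0], chunk):
        out[lo:lo + chunk] = best_window_scores(
            codes[lo:lo + chunk], model, both_strands=True,
            background=background)
    return out


def simulate_selex(cfg: SelexSimConfig) -> List[ReadPool]:
    """Simulate cycles 0..n_cycles; cycle 0 is the unselected library.

    Selection operates on a virtual library of
    ``library_depth x n_reads_per_cycle`` background molecules: each
    cycle redraws the molecule abundances by weighted multinomial
    resampling with replacement, with per-molecule weight
    exp(selection_strength x best-window log2-odds over both strands)
    under the planted model. The emitted pool for every cycle is a
    sequenced subsample of ``n_reads_per_cycle`` reads.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_reads_per_cycle
    m = cfg.library_depth * n
    library = _random_pool_codes(cfg, rng, m)

    def sequence_pool(abundance: np.ndarray, cycle: int) -> ReadPool:
        idx = rng.choice(m, size=n, replace=True, p=abundance / abundance.sum())
        return _pool_from_codes(library[idx], cycle)

    abundance = np.ones(m)
    pools = [sequence_pool(abundance, 0)]
    if cfg.n_cycles == 0:
        return pools
    if cfg.planted_model is None:
        raise ValueError("selection cycles require a planted_model")

    lam = cfg.effective_strength
    scores = _scores_chunked(library, cfg.planted_model,
                             cfg.background_base_probs)
    w = np.exp(lam * (scores - scores.max()))
    for cycle in range(1, cfg.n_cycles + 1):
        p = abundance * w
        total = p.sum()
        if not np.isfinite(total) or total <= 0:
            raise RuntimeError(
                f"selection produced an empty pool at cycle {cycle}: "
                f"score range [{scores.min():.2f}, {scores.max():.2f}], "
                f"strength {lam:.3f}")
        abundance = rng.multinomial(m, p / total).astype(float)
        pools.append(sequence_pool(abundance, cycle))
    return pools


def _pool_from_codes(codes: np.ndarray, cycle: int) -> ReadPool:
    reads = ["".join(BASES[b] for b in row) for row in codes]
    pool = ReadPool(reads, cycle=cycle)
    pool._codes = codes.copy()
    return pool


def write_pools(pools: List[ReadPool], prefix, fmt: str = "txt") -> List[Path]:
    """Write one file per cycle with a ``_cN`` suffix; fmt in
    {'txt', 'txt.gz', 'fastq'}."""
    paths = []
    for pool in pools:
        if fmt == "fastq":
            path = Path(f"{prefix}_c{pool.cycle}.fastq")
            pool.to_fastq(path)
        elif fmt == "txt.gz":
            path = Path(f"{prefix}_c{pool.cycle}.txt.gz")
            pool.to_text(path)
        else:
            path = Path(f"{prefix}_c{pool.cycle}.txt")
            pool.to_text(path)
        paths.append(path)
    return paths


# ----------------------------------------------- reference planted models

def e2f8_like_pwm(core_prob: float = 0.95, flank_prob: float = 0.85) -> PWM:
    """A PWM with the E2F8-style consensus TTTGGCGGGAAA.

    The TGGCGGGA core gets ``core_prob`` on the consensus base; the A/T
    flanks get ``flank_prob``; remaining mass is spread evenly.
    """
    consensus = "TTTGGCGGGAAA"
    core = range(2, 10)  # TGGCGGGA
    probs = np.empty((len(consensus), 4))
    for i, b in enumerate(consensus):
        p = core_prob if i in core else flank_prob
        probs[i] = (1.0 - p) / 3.0
        probs[i, BASES.index(b)] = p
    return PWM(probs)


def e2f8_like_dinuc(stay_prob: float = 0.78, core_prob: float = 0.9,
                    flank_at: float = 0.46) -> DinucModel:
    """A first-order model with consensus WWWTGGCGGGAAA and an AA/TT-
    correlated 5' flank.

    Positions 0-2 are A/T-rich with a 'stay on the same base' bias that
    plants positive dinucleotide excess exactly at AA and TT of pairs
    (0,1) and (1,2).  All later transitions are independent of the
    source base, so every other pair is exactly positionally independent
    (zero excess).
    """
    consensus = "WWWTGGCGGGAAA"
    L = len(consensus)
    other = (1.0 - flank_at * 2) / 2.0
    m0 = np.array([flank_at, other, other, flank_at])

    def flank_T():
        T = np.empty((4, 4))
        off = (1.0 - stay_prob) / 3.0
        for b1 in range(4):
            if b1 in (0, 3):  # A or T: biased to stay
                T[b1] = off
                T[b1, b1] = stay_prob
                # most of the off-mass goes to the other W base
                w_other = 3 - b1
                T[b1, w_other] = 1.0 - stay_prob - 2 * 0.02
                T[b1, [1, 2]] = 0.02
            else:
                T[b1] = np.array([flank_at, other, other, flank_at])
        return T

    def toward(base: str, p: float):
        row = np.full(4, (1.0 - p) / 3.0)
        row[BASES.index(base)] = p
        return np.tile(row, (4, 1))  # source-independent => zero excess

    transitions = []
    for i in range(L - 1):
        nxt = consensus[i + 1]
        if i < 2:
            transitions.append(flank_T())
        elif nxt == "W":
            transitions.append(toward("A", 0.5))  # unused branch, safety
        else:
            transitions.append(toward(nxt, core_prob))

    pair_probs = np.empty((L - 1, 16))
    m = m0
    for i, T in enumerate(transitions):
        joint = m[:, None] * T
        pair_probs[i] = joint.ravel()
        m = joint.sum(axis=0)
    return DinucModel(pair_probs)


# -------------------------------------------------------------------- ITC

@dataclass
class ItcSimConfig:
    """A simulated one-site titration.

    Defaults follow the measurement protocol this package models: 20
    injections at 20 C, DNA in the cell at 12 uM titrated with 0.1 mM
    protein. Cell volume (200 uL) and injection volume (2.5 uL) are
    instrument-class defaults chosen so the final molar ratio exceeds
    twice the stoichiometry.
    """

    Kd: float = 260e-9              # M
    dH: float = -10.0               # kcal/mol
    n_sites: float = 1.0
    cell_conc: float = 12e-6        # M (DNA, in the cell)
    syringe_conc: float = 100e-6    # M (protein, titrant)
    cell_volume: float = 200e-6     # L
    n_injections: int = 20
    injection_volume: float = 2.5e-6  # L
    temperature: float = 293.15     # K
    noise_sd: float = 0.15          # kcal / mol injectant
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("Kd", "n_sites", "cell_conc", "syringe_conc",
                     "cell_volume", "injection_volume", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_injections < 2:
            raise ValueError("n_injections must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_isotherm(cfg: ItcSimConfig) -> Isotherm:
    """Exact one-site forward model plus i.i.d. Gaussian heat noise."""
    schedule = Isotherm(
        injection_volumes=np.full(cfg.n_injections, cfg.injection_volume),
        cell_volume=cfg.cell_volume,
        cell_conc=cfg.cell_conc,
        syringe_conc=cfg.syringe_conc,
        temperature=cfg.temperature,
    )
    params = OneSiteParams(Kd=cfg.Kd, dH=cfg.dH, n_sites=cfg.n_sites)
    heats = one_site_isotherm(params, schedule)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.rng_seed)
        heats = heats + rng.normal(0.0, cfg.noise_sd, size=heats.shape)
    return replace(schedule, heats=heats)


# --------------------------------------------------------- toy structures

@dataclass
class ToyStructureSpec:
    """Deterministic geometric fixtures emitted as Structure values.

    kinds: 'single-sphere' (one atom at the origin), 'sphere-pair' (two
    single-atom chains separated along x), 'helix-of-atoms' (one chain
    of atoms on a regular helix), 'two-chain-block' (two rectangular
    atom grids with a tunable inter-chain gap along x).
    """

    kind: str = "single-sphere"
    element: str = "C"
    separation: float = 10.0     # A; sphere-pair / two-chain-block gap
    n_atoms: int = 20            # helix
    helix_radius: float = 2.3    # A
    helix_rise: float = 1.5      # A per atom
    helix_twist_deg: float = 100.0
    block_shape: tuple = (3, 3, 3)
    block_spacing: float = 3.8   # A
    rng_seed: int = 0

    KINDS = ("single-sphere", "sphere-pair", "helix-of-atoms", "two-chain-block")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown toy-structure kind {self.kind!r}")


def make_toy_structure(spec: ToyStructureSpec) -> Structure:
    el = spec.element

    def chain_of(name: str, coords: np.ndarray, res_per_atom: bool = True) -> Chain:
        ch = Chain(name)
        for i, xyz in enumerate(coords):
            res = Residue("GLY", i + 1)
            res.atoms.append(Atom("CA", el, np.asarray(xyz, float)))
            ch.residues.append(res)
        return ch

    if spec.kind == "single-sphere":
        chains = [chain_of("A", np.zeros((1, 3)))]
    elif spec.kind == "sphere-pair":
        chains = [chain_of("A", np.zeros((1, 3))),
                  chain_of("B", np.array([[spec.separation, 0.0, 0.0]]))]
    elif spec.kind == "helix-of-atoms":
        i = np.arange(spec.n_atoms)
        theta = np.deg2rad(spec.helix_twist_deg) * i
        coords = np.column_stack([
            spec.helix_radius * np.cos(theta),
            spec.helix_radius * np.sin(theta),
            spec.helix_rise * i,
        ])
        chains = [chain_of("A", coords)]
    else:  # two-chain-block
        nx, ny, nz = spec.block_shape
        grid = np.array([[x, y, z] for x in range(nx)
                         for y in range(ny) for z in range(nz)],
                        dtype=float) * spec.block_spacing
        width = (nx - 1) * spec.block_spacing
        shift = np.array([width + spec.separation, 0.0, 0.0])
        chains = [chain_of("A", grid), chain_of("B", grid + shift)]

    return Structure(chains=chains, label=f"toy-{spec.kind}")


def make_contact_fixture(distance: float = 2.8) -> Structure:
    """A serine OG placed ``distance`` A from a nucleotide phosphate OP1.

    Minimal protein-DNA fixture for contact-classification tests: chain
    A holds one SER (CB + OG), chain B one DG whose backbone, sugar and
    base atoms sit in distinct distance shells.
    """
    ser = Residue("SER", 1)
    ser.atoms.append(Atom("CB", "C", [distance + 1.4, 0.0, 0.0]))
    ser.atoms.append(Atom("OG", "O", [distance, 0.0, 0.0]))
    protein = Chain("A")
    protein.residues.append(ser)

    dg = Residue("DG", 10)
    dg.atoms.append(Atom("P", "P", [-1.5, 0.0, 0.0]))
    dg.atoms.append(Atom("OP1", "O", [0.0, 0.0, 0.0]))
    dg.atoms.append(Atom("OP2", "O", [-2.2, 1.3, 0.0]))
    dg.atoms.append(Atom("C1'", "C", [-3.0, -2.5, 0.0]))
    dg.atoms.append(Atom("O4'", "O", [-4.2, -3.1, 0.0]))
    dg.atoms.append(Atom("N9", "N", [-6.0, -5.0, 0.0]))
    dg.atoms.append(Atom("O6", "O", [-9.0, -7.5, 0.0]))
    dna = Chain("B")
    dna.residues.append(dg)
    return Structure(chains=[protein, dna], label="toy-contact")
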