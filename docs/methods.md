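# Methods

`bindspec` reimplements, as one tested pipeline, the four quantitative
analyses used to characterize the DNA-binding specificity of E2F-family
transcription factors: HT-SELEX motif inference, riverlake dinucleotide
logos, protein–DNA structure comparison, and one-site ITC
thermodynamics. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely
open.

## Seed-anchored multinomial motif counting

HT-SELEX reads are scanned against a degenerate IUPAC seed (e.g.
`NTTTGGCGGGAAAN`; `N` matches any base, `W` matches A/T). Counting uses
the *multinomial setting 1* rule: the base frequency at seed position
*i* is tallied from every read window (both strands by default) that
matches the seed at **all positions except** *i*; adjacent-dinucleotide
frequencies at pair (*i*, *i*+1) analogously require a match everywhere
except at the two paired positions. This one-mismatch conditioning
makes the estimate at each position independent of the base actually
observed there, which is what lets a strongly selected pool yield an
unbiased per-position frequency estimate.

Counts are normalized with an additive pseudocount (default 1 for
model building; the exact-oracle tests use 0):
`p_i(b) = (c_i(b) + pc) / (Σ_b c_i(b) + 4·pc)`, and identically over 16
entries for dinucleotide rows. The consensus is the per-position argmax
with ties broken A<C<G<T and flagged. Window scoring is the standard
log₂-odds sum against a background base composition; a first-order
(Markov) model scores a window as
`log₂ m_0(b_0)/bg(b_0) + Σ_i log₂ P_i(b_{i+1}|b_i)/bg(b_{i+1})`.

Choices the source protocol leaves open, fixed here and configurable:
both strands are counted by default (SELEX ligands are double-stranded);
all overlapping windows count with no per-read cap; models are built
from a single user-chosen cycle with no cycle-0 background correction;
reads containing non-ACGT characters are skipped and tallied in a
diagnostic counter.

## Synthetic SELEX generator

The generator emulates the assay's ligand design: a 6-bp and a 3-bp
barcode flanking a 40-bp randomized region (49-bp reads), selected for
up to four cycles. Selection is Boltzmann retention on the best site
per ligand: each molecule carries weight
`exp(λ · S_best)` where `S_best` is its best-window log₂-odds over both
strands under the planted model, and each cycle redraws molecule
abundances by weighted multinomial resampling.

Two scale parameters make this work at desk scale:

- **Selection strength λ.** After *k* cycles the cumulative tilt on a
  site of score *S* is `exp(k·λ·S) = (p/bg)^{k·λ/ln 2}` for a PWM site.
  With the default `λ = ln 2 / n_cycles` the exponent is exactly 1 at
  the final cycle, so the enriched site composition's fixed point *is*
  the planted model — the property the recovery tests rely on. λ is a
  free parameter of the emulation; the bench protocol's stringency per
  cycle is not published.
- **Library depth.** A sequenced pool of 50,000 reads of 40 random bp
  contains on average only ~0.35 exact copies of a given 12-mer, so
  selection acting on the sequenced pool alone can never enrich exact
  sites. As in the real assay — where the ligand input is ~10⁷-fold
  deeper than the sequencing — selection here operates on a virtual
  library of `library_depth × n_reads_per_cycle` molecules and each
  cycle's pool is a sequenced subsample. Because every consensus-cell
  estimate of the counting step shares the same pool of perfect-site
  founders, the estimator's error is dominated by Poisson noise in the
  founder count `N₀ ≈ depth × n_reads × 76 × 4⁻¹²`. A 3σ budget for
  the weakest (flank, p = 0.85) cells,
  `3 · p(1−p) · √(1.3/N₀) < 0.05`, requires `N₀ ≳ 95`; the default
  depth 400 provides ~90 and measured recovery errors of 0.02–0.04.

What the generator does **not** model: PCR bias, sequencing error,
cross-contamination, position-dependent background, or ligand secondary
structure. Passing recovery tests therefore demonstrate correctness of
the counting/normalization machinery under the stated selection model,
not robustness to real library artefacts.

The packaged planted models mirror the studied factor: a PWM with
consensus `TTTGGCGGGAAA` (core `TGGCGGGA` at 0.95 per position, A/T
flanks at 0.85), and a first-order model with consensus
`WWWTGGCGGGAAA` whose 5′ flank carries an A/T "stay" bias that plants
positive dinucleotide excess exactly at AA and TT of the two flank
pairs; all other transitions are source-independent, hence exactly
positionally independent.

## Riverlake logos

A riverlake renders an adjacent-dinucleotide model as four rows of
circles (one per base) per position. Mononucleotide frequencies are
derived from the dinucleotide model itself: first-base marginals of
each pair row, and the second-base marginal of the last pair for the
final position. Circle radius is `radius_scale · m_i(b)`; the line
joining two circles has width `width_scale · p_i(b₁,b₂)`, so the
outgoing widths of a circle sum exactly to
`(width_scale/radius_scale) ×` its radius (flow conservation, asserted
on random models).

Departures from positional independence are measured by
`e_i(b₁,b₂) = p_i(b₁,b₂) − m_i(b₁)·m_{i+1}(b₂)` (each row sums to 0).
Edges with `e` above a threshold (default 0.01, to suppress numerical
noise; no published value exists) are drawn dark blue
(`#00338D`). A *deficit* — predicted frequency exceeding the observed
one — is indicated by a yellow (`#FFD700`) dotted overlay drawn at
width `width_scale · |e|`: the observed-frequency line itself cannot
carry this information, since the observed frequency may be zero. This
width convention for the deficit overlay is this package's
interpretation; the original description does not state one.

Rendering is deterministic: fixed element order, fixed float
formatting, no timestamps — the SVG bytes are a pure function of
(model, style). Circles with `m < 0.005` are still drawn at a 0.5-px
minimum radius so edges keep their anchors.

## Structure comparison

Parsing is delegated to gemmi (PDB and mmCIF); alternate conformations
are reduced to the highest-occupancy conformer and waters dropped by
default. Selections use `chain` or `chain:first-last` author
numbering.

- **SASA** is Shrake–Rupley sphere sampling on a deterministic golden-
  spiral lattice (default 960 points/atom, probe 1.4 Å) with the
  standard radius set C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å and a
  warned fallback of 1.70 Å for unknown elements. Accuracy is held to
  the analytic one- and two-sphere solutions within 1% and to <0.5%
  drift on doubling the sampling density.
- **Interfaces** use the PISA-style half-buried-area convention,
  `(SASA_A + SASA_B − SASA_AB)/2`, with identical sampling in all three
  terms so quadrature error cancels in the difference. An interface
  residue is one losing more than 0.1 Å² of SASA; the published
  interface-residue percentages depend on this threshold, so it is an
  explicit parameter. Waters and heteroatoms are excluded by default.
- **Superposition** pairs residues by global sequence alignment
  (BLOSUM62, affine gaps −11/−1, via Biopython) and keeps aligned,
  ungapped pairs with Cα atoms on both sides; the Kabsch SVD solution
  is constrained to proper rotations (no reflections) and degenerate
  (collinear) inputs are rejected. No iterative outlier rejection is
  applied — the published superposition method is unstated, so the
  simplest convention is used and reported as-is.
- **Tandem-domain splitting** for intra-chain interfaces uses the
  largest author-numbering gap in the chain (partly unmodelled linkers
  appear as numbering discontinuities); residues before the gap form
  domain 1 plus its resolved linker helices, residues after it domain 2.
- **Contacts** are distance-only: any protein/DNA atom pair within
  4.0 Å is a contact, N/O–N/O pairs within 3.5 Å are additionally
  flagged hydrogen bonds (no geometric or energetic scoring). Each
  contact is labelled by the DNA atom's group — backbone (P, OP1/OP2/
  OP3, O5′/O3′), deoxyribose (sugar atoms), or base (everything else) —
  which partitions the DNA atom names.
- **Symmetry expansion** applies every space-group operator plus
  lattice translations within one cell, in orthogonal coordinates, and
  keeps mates with any atom within 5 Å of the original.

## One-site ITC

The forward model solves the one-site mass balance in closed form:
with total sites `S = n·[cell]` and titrant `X`, the bound complex is
the stable root of `PL² − (S + X + K_d)·PL + S·X = 0`. Dilution follows
the constant-volume displacement (perfusion) convention — an injection
of volume *v* into cell volume *V₀* scales the cell species by
`(1 − v/V₀)` and mixes in titrant at `[syringe]·v/V₀` — and the heat of
injection *i* is `ΔH·V₀·(PL_i − PL_{i−1}·(1 − v_i/V₀))` per mole of
titrant injected. Because unbound cell material is displaced before it
can bind, the cumulative heat approaches the stoichiometric limit
`n·ΔH·(cell moles)` from below: within 2% in a fast-saturating regime,
and ~9% short at the default 260 nM protocol (final molar ratio 2.4).

Fitting minimizes least squares over (ln K_d, ΔH, n) with
`scipy.optimize.least_squares` (bounded, trust-region reflective),
log-parameterizing K_d to keep it positive, with a three-start spread
of an order of magnitude around the initial K_d guess. Parameter
standard deviations come from the Gauss–Newton curvature at the
optimum (delta method for K_d); non-convergence or non-finite
uncertainties are flagged, never silently accepted — a flat isotherm
from very weak binding yields a flagged result or a K_d uncertainty
exceeding the estimate. Derived quantities satisfy
`ΔG = R·T·ln K_d` and `ΔS = (ΔH − ΔG)/T` exactly
(R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹). Units are kcal-based throughout, the
instrument convention.

Simulation defaults follow the published protocol where stated — 20
injections, 20 °C, DNA in the cell (12 µM, within the published
0.012–0.016 mM range) titrated with 0.1 mM protein — and instrument-
class defaults elsewhere: 200 µL cell, 2.5 µL injections (chosen so the
final molar ratio exceeds twice the stoichiometry), Gaussian heat noise
of 0.15 kcal/mol of injectant. The first injection can be excluded from
fits (`discard_first`), the common bench practice.

## Numerical and testing conventions

All randomness flows through one `numpy` Generator seeded per call;
configs carry their seeds, so every fixture is reproducible and every
CLI run is idempotent. Problem sizes in the test-suite reproductions
are the study-scale ones where the analysis depends on them (50,000
reads/cycle over 4 selection cycles for motif recovery; 20 injections
and 20 fit replicates for ITC) and desk-scale elsewhere. The
deposited-entry analyses (interface areas, interface-residue fractions,
inter-structure RMSD, symmetry-mate interfaces) require the user to
download PDB entries 4YO2 and 1CF7 into `data/structures/`; no
structure files ship with the package, and those tests fail with an
explanatory message until the files are present.

## Known limitations

- The SELEX emulation's selection acts on the best window only (max-
  affinity site, matching one-site occupancy logic); multi-site
  cooperative retention is not modelled.
- Multinomial settings other than 1, automatic seed discovery, gapped/
  dimeric motif models, and match statistics (E-values) are out of
  scope.
- Hydrogen bonds are distance-defined; donor/acceptor chemistry and
  angles are not checked.
- The ITC module fits a single class of independent sites only; no
  baseline extraction from raw power traces.
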