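# Methods

This note records the models, conventions and numerical choices behind
`pmhcgroove`, and what the synthetic test bed does and does not establish
about real data.

## Systems and selections

A `MolecularSystem` is an ordered atom table with per-atom force-field
parameters (mass, partial charge, Lennard-Jones ε and r_min/2, a Born/vdW
radius) attached from a packaged tab-separated table keyed on
(residue, atom). The packaged table is a coarse fixed-charge set in the
spirit of united-atom protein force fields: polar groups carry standard
charges (backbone N/H/C/O, side-chain amides, hydroxyls, guanidinium,
carboxylates), aliphatic carbons are near-neutral, and only polar hydrogens
are explicit. It exists to exercise the energetic machinery on synthetic
systems; it is not a validated force field.

Chain conventions follow the HLA-DR literature: chain `A` is the α chain,
`B` the β chain, waters (HOH/WAT/TIP3) map to class `W`, any other chain is
the peptide `P`. Residue numbering is taken verbatim from the input file
(mature-protein numbering, 1-based per chain); insertion codes are ignored.
The default binding site is α1 5–76 plus β1 5–90, intersected with residues
actually present. The groove compartments default to D1 (α50–51/β85–86),
D2 (α53–55/β78–83), D3 (α60–65/β65–70), D4 (α68–73/β56–61); both are
overridable in configuration.

I/O goes through MDAnalysis: PDB structures, DCD or multi-model-PDB
trajectories. Coordinates are Å; frame spacing is ps. The synthetic
trajectory default is 600 frames at 20 ps (a 12 ns desk-scale stand-in for
production-scale runs), chosen so the default 20 ps SIE stride evaluates
every frame.

## RMSD and distributions

Superposition is a proper-rotation least-squares fit (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) computed on the Cα atoms
of the chosen selection and applied to the whole frame; RMSD is reported
over the fit atoms. The reference is the first trajectory frame by default
(an external reference, e.g. the X-ray structure, may be passed instead).
Cα-only is the default atom set; a full-backbone fit (N, Cα, C, O) is one
keyword away. Whether one superposes on the binding site only or the whole
protein is a genuine choice; the selection is an explicit argument and the
binding site is the default.

Distributions are normalized histograms (default bin widths 0.1 Å for RMSD,
0.25 Å for groove widths). Modes come from a Gaussian KDE with absolute
bandwidth 2× the bin width; local maxima are kept when their prominence
exceeds 5% of the peak density, boundary maxima included. Mode masses are
the sample fractions between adjacent KDE minima. A constant series is
special-cased to a single mode of mass 1. The package reports the mode
list only; verbal labels such as "unimodal" are left to the analyst.

Compartment width is the Euclidean distance between the mass-weighted
centers of the *heavy* atoms of the α-side and β-side selections — an
internal coordinate, invariant to rigid motion of the frame.

## Interaction detectors

All three detectors decide per frame per residue pair, OR-combining atom
pairs within the pair, and report pairs whose persistence (mean presence)
reaches the threshold, 0.2 by default.

* Hydrogen bonds: donor–acceptor heavy-atom distance ≤ 3.1 Å and
  donor–H–acceptor angle ≥ 130° (the ≥ convention keeps near-linear bonds).
  Donors are N/O/S with a covalent hydrogen (bond inferred geometrically,
  ≤ 1.25 Å, on the reference frame); acceptors are any N/O. Both directions
  of each residue pair are searched.
* Stacking: acute angle between least-squares ring planes ≤ 30° and ring
  centroid distance ≤ 5.0 Å. Planar residues are His, Phe, Tyr, Trp and
  Arg; arginine's guanidinium (NE, CZ, NH1, NH2) is included because it
  behaves as a planar stacking partner against aromatic rings in grooves.
  The Trp indole is treated as a single 9-atom plane. Plane normals come
  from the SVD of the centered ring coordinates.
* Hydrophobic contacts: minimum side-chain heavy-atom distance ≤ 4.0 Å with
  no water oxygen within 4.0 Å of any atom participating in a
  within-cutoff pair. The hydrophobic class is {Ala, Val, Leu, Ile, Pro,
  Phe, Met, Trp}, configurable.

Per-frame presence traces are retained on every record, so the persistence
filter is purely a reporting step.

## Quasi-harmonic entropy

Frames are iteratively superposed on their mean structure over the
selection Cα atoms (three alignment/mean refinement passes). The 3n×3n
covariance of the centered Cartesian fluctuations is mass-weighted
(σ = M^{1/2} C M^{1/2}) and diagonalized; eigenvalues below 10⁻¹² amu Å²
are dropped as rank/rigid-body artifacts (superposition removes six degrees
of freedom). Each remaining eigenvalue is an oscillator with
x = ħω/k_BT = ħ/√(k_BT·λ), and

    S/k_B = Σᵢ [ xᵢ/(e^{xᵢ}−1) − ln(1−e^{−xᵢ}) ].

Units are internal (kcal/mol, amu, Å), with ħ = 0.3104783 in those units
and k_B = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹; temperature defaults to 310 K. One
estimate is produced per ensemble (a covariance method has no meaningful
single-frame value).

The test oracle draws frames from a known Gaussian whose covariance is
constructed inside the subspace orthogonal to rigid-body motion
(translations plus infinitesimal rotations about the reference). Because
alignment approximately projects onto that subspace, the closed-form
entropy of the true covariance is the correct target; the estimator agrees
within 5% at 600 frames and 1% at 10⁴ frames.

## SIE and alanine scanning

Per frame, over all receptor–ligand atom pairs:

    ΔG = α · (E_coul + ΔG_RF + E_vdW + γ·ΔMSA) + C

* E_coul: Coulomb sum screened by the interior dielectric D_in
  (332.0636·qᵢqⱼ/(D_in·r)).
* E_vdW: 12-6 Lennard-Jones with geometric-mean ε and summed r_min/2, no
  distance cutoff (synthetic systems are small).
* ΔG_RF: change in reaction-field solvation on binding, estimated with a
  generalized-Born cross term with fixed per-atom Born radii and outer
  dielectric 78.5: −332.0636·(1/D_in − 1/78.5)·Σ qᵢqⱼ/f_GB, with the usual
  f_GB = √(r² + RᵢRⱼ·e^{−r²/4RᵢRⱼ}). With fixed radii the self terms cancel
  exactly, leaving only cross pairs — a deliberate simplification relative
  to boundary-element Poisson solvers.
* ΔMSA: buried interface area, A(complex) − A(receptor) − A(ligand)
  (negative on burial), from Shrake–Rupley solvent-accessible area on heavy
  atoms (biotite, probe 1.4 Å, 300 Fibonacci points by default). Defined as
  an accessible-surface estimate rather than a molecular (solvent-excluded)
  surface; since γ multiplies a small area difference, this changes only
  the absolute scale.

Default coefficients are the published AMBER-trained SIE set (α = 0.1048,
D_in = 2.25, γ = 0.0129 kcal mol⁻¹ Å⁻², C = −2.89 kcal/mol), all
overridable. Pairs closer than 0.5 Å raise a clash warning with the frame
index. Trajectory scoring evaluates frames at a stride (default 20 ps,
never finer than the frame spacing) and reports mean, SD, and the derived
IC50.

Because the continuum term and area definition are simplified and the
parameter table is coarse, absolute ΔG values on synthetic systems are not
comparable to solvated-trajectory results; the package's validated claims
about SIE are structural (linearity in α, component additivity,
receptor/ligand symmetry, closed-form pair energetics) plus the exact
ΔG↔IC50 arithmetic.

Alanine scanning is single-trajectory: for each position the side chain is
truncated past Cβ on the same frames, the residue re-typed to alanine, and
the score recomputed; ΔΔG = ΔG_mut − ΔG_wt. Glycine positions are an error
(no Cβ); alanine positions return 0 with a warning. Locality holds: a
zero-charge non-contacting residue changes ΔG by < 0.01 kcal/mol.

## IC50 conversion

IC50 (mol/L) = exp(ΔG/k_BT), reported in nM, at 310 K by default. The
published protective-allele values validate the convention: −17.5 kcal/mol
gives 4.6×10⁻⁴ nM, −12.2 gives 2.5 nM, and their ratio reproduces the
published ≈5.4×10³ within 0.5%. (The published predisposing-allele IC50
cells are mutually swapped with respect to their printed free energies —
see `pmhcgroove/datasets.py`; the package reproduces the cells verbatim and
targets the self-consistent rows.) Binder classification uses the standard
inclusive 1000 nM threshold.

## Synthetic generator

The toy complex is deliberately non-physical: three parallel backbones
(α at y = +8 Å, β at y = −8 Å, peptide between them), 3.8 Å residue
spacing, minimal side chains (only the atoms each detector needs), side
chains pointing away from the groove so that *no* interaction criterion is
satisfied by accident, and waters parked on a distant grid. Interactions
are then planted frame-by-frame: the moved residue is rigidly placed so the
relevant criterion holds with margin (≥ 0.2 Å / 10°) in exactly
round(f·T) seeded-sampled frames and fails with margin elsewhere, making
persistence assertions exact. Hydrophobic plants can additionally park a
water 3.0 Å from the contact in a chosen fraction of satisfying frames to
exercise the water veto. Planted residues moved into contact are
geometrically valid for the detectors but energetically arbitrary — SIE
scores of planted frames can be extreme, which is why energetic tests use
unplanted trajectories.

Fluctuation modes: isotropic Gaussian noise; full-covariance Gaussian
sampling (eigendecomposition of the supplied PSD matrix); and a two-state
groove in which the β wall of one compartment is rigidly translated along
the wall-to-wall axis to hit two exact target widths with a fixed occupancy
(state frames chosen without replacement, so occupancies are exact).

Consequently, passing tests establish the correctness of the analysis
mathematics — superposition, covariance spectra, geometric criteria,
persistence bookkeeping, energy combination rules — not the realism of any
force field, solvent model, or conformational ensemble. Real trajectories
bring correlated anharmonic motion, protonation states, and solvation
effects the generator does not emulate, and absolute RMSD/entropy/ΔG
magnitudes from the toys should never be compared against experimental or
published simulation values.

## Pipeline

The YAML-driven pipeline applies the stages per system with a packaged
defaults profile (cutoffs, residue ranges, 310 K, 20% persistence, 20 ps
stride), writes CSV/JSON artifacts with fixed float formatting, logs
per-stage timings to stderr, and stamps outputs with a SHA-256 hash of the
effective configuration. Runs are deterministic given config and seed —
repeated runs are byte-identical — and the pipeline is a thin composition
of the public stage functions (no hidden state). Cross-system comparison
reports IC50 ratios against a reference system, ΔΔG, per-compartment mode
shifts, and network set differences.
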