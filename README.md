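# pmhcgroove

Post-simulation analysis of peptide–MHC class II binding-groove dynamics.

MHC class II (HLA-DR) molecules are αβ heterodimers whose α1/β1 domains form
an open-ended groove that presents peptides to T cells. Molecular-dynamics
trajectories of such complexes are commonly dissected into a standard set of
observables: stability of the binding site, local width and flexibility of
the groove, the persistent interaction network anchoring the peptide, the
configurational entropy of the site, and an end-point estimate of the
binding free energy. `pmhcgroove` implements that entire post-processing
pipeline as a reusable, tested library with a CLI, together with a
synthetic-trajectory generator that plants known ground truth so every stage
can be validated without running MD.

## What it computes

* **Binding-site RMSD** — per-frame Cα RMSD of the binding-site residues
  (α1 5–76 and β1 5–90 by default) after least-squares rigid superposition
  (Kabsch) on the first frame, plus normalized RMSD probability
  distributions with KDE-based mode detection.
* **Groove-width dissection** — the groove is split into four compartments
  D1 (α50–51/β85–86), D2 (α53–55/β78–83), D3 (α60–65/β65–70) and
  D4 (α68–73/β56–61); per compartment the package tracks the distance
  between the mass-weighted heavy-atom centers of the α and β walls.
* **Interaction networks** — per-frame detection of hydrogen bonds
  (donor–acceptor ≤ 3.1 Å and D–H···A angle ≥ 130°), planar/aromatic
  stacking (ring-plane angle ≤ 30°, centroid distance ≤ 5.0 Å) and
  water-excluded hydrophobic contacts (side-chain heavy atoms ≤ 4.0 Å, no
  water oxygen within 4.0 Å). Residue pairs persisting ≥ 20% of the frames
  are reported.
* **Quasi-harmonic entropy** — frames are superposed on their mean
  structure, the mass-weighted covariance σ of Cα fluctuations is
  diagonalized, each eigenvalue λᵢ defines an oscillator
  ωᵢ = √(k_BT/λᵢ), and

      S = k_B Σᵢ [ xᵢ/(e^{xᵢ}−1) − ln(1−e^{−xᵢ}) ],   xᵢ = ħωᵢ/k_BT,

  reported as T·S in kcal/mol at 310 K.
* **SIE binding free energy** — solvated interaction energy over frames at a
  20 ps stride: ΔG = α·(E_coul + ΔG_RF + E_vdW + γ·ΔMSA) + C with the
  published AMBER-trained coefficients (α = 0.1048, D_in = 2.25,
  γ = 0.0129 kcal mol⁻¹ Å⁻², C = −2.89 kcal/mol); reaction field via a
  generalized-Born cross term, buried area via Shrake–Rupley. Includes a
  single-trajectory virtual alanine scan (side chains truncated past Cβ).
* **IC50 conversion** — ΔG ≈ k_BT·ln(IC50) with IC50 in mol/L (reported in
  nM), ratios relative to a reference peptide, and binder classification at
  the 1000 nM threshold.

## Worked example

```python
import pmhcgroove as pg

system = pg.make_toy_complex(80, 95, 14, with_waters=4, seed=0,
                             sequences={"B": {82: "ASN"}, "P": {8: "SER"}})
site = pg.binding_site_selection(system)
beta = pg.ResidueSelection("beta_site", tuple(m for m in site.members if m[0] == "B"))
peptide = pg.ResidueSelection("peptide", tuple(("P", r) for r in range(1, 15)))

base = pg.sample_trajectory(system, pg.FluctuationSpec(amplitude=0.3, seed=0), 600)
planted = pg.plant_interaction(
    base, pg.PlantedInteraction("hbond", (("B", 82), ("P", 8)), 0.6, seed=1))

rmsd = pg.rmsd_series(base, site)
print(f"mean binding-site RMSD: {rmsd.values.mean():.3f} A")
print(pg.network_summary(pg.detect_hbonds(planted, beta, peptide)).to_string(index=False))
ts = pg.quasiharmonic_entropy(base, site)
print(f"T*S = {ts.TS:.1f} kcal/mol over {ts.n_frames_used} frames")
dg = pg.sie_trajectory(base, site, peptide, pg.SIEParams(), stride_ps=20.0)
print(f"dG = {dg.dg_mean:.2f} +/- {dg.dg_sd:.2f} kcal/mol, IC50 = {dg.ic50_nM:.3g} nM")
print(f"published protective-allele check: {pg.ic50_from_dg(-17.5):.2g} nM "
      f"and {pg.ic50_from_dg(-12.2):.2g} nM")
```

prints

```
mean binding-site RMSD: 0.753 A
 kind chain  res_mhc resname_mhc  res_pep resname_pep  persistence
hbond     B       82         ASN        8         SER          0.6
T*S = 491.1 kcal/mol over 600 frames
dG = -3.59 +/- 0.04 kcal/mol, IC50 = 2.93e+06 nM
published protective-allele check: 0.00046 nM and 2.5 nM
```

The 0.6 persistence is the planted ground truth recovered exactly; the
entropy and ΔG numbers describe the synthetic toy (its isotropic 0.3 Å
fluctuations and coarse geometry), not a real complex, while the final line
shows the IC50 arithmetic reproducing the published protective-allele
values (4.6×10⁻⁴ nM for the self peptide, 2.5 nM for the viral one).

The same analyses run from the shell:

```bash
pmhcgroove run --config run.yaml          # full pipeline, CSV/JSON outputs
pmhcgroove synth --out-prefix toy         # generate synthetic PDB inputs
pmhcgroove stage --config run.yaml --label sys1 --name entropy
pmhcgroove compare --config run.yaml --reference sys1
```

## Scope

The package analyzes trajectories; it does not produce them. Structure
preparation, homology modelling, docking, and the MD simulations themselves
are out of scope, and the absolute entropy/free-energy scales of any real
system depend on solvated force-field trajectories that the synthetic
generator deliberately does not emulate (see `docs/methods.md`).
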