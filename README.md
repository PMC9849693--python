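# camryr

Integrated biophysical analysis of calmodulin (CaM) recognition of the
ryanodine-receptor CaM-binding peptides (RyR1/RyR2 CaMBD2), for
structural biochemists studying how arrhythmia-associated CaM variants
(N97I, Q135P) perturb target selectivity. The package covers the full
desk-side analysis chain for this kind of study: equilibrium and
thermodynamic binding models for fluorescence titrations and isothermal
titration calorimetry (ITC), 1:1 Langmuir kinetics for surface plasmon
resonance (SPR), essential-dynamics analytics for coordinate ensembles,
and protein-structure-network (PSN) topology with the Communication
Robustness index between EF-hand Ca²⁺-binding motifs. A seeded
synthetic-data module emulates every input stage, so the whole chain
builds and tests without wet-lab or trajectory data.

## Models

**Equilibrium binding** — the fraction of peptide bound is
`fb = (y − y0)/(ymax − y0)` from the Trp emission-peak wavelength;
one-site isotherms are fitted per replica either as the hyperbola
`fb = x/(K_D + x)` on total titrant or as the exact 1:1 mass-balance
root with ligand depletion. Free energies follow
`ΔG = RT ln K_D = ΔH − TΔS` (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹,
T = 298.15 K) and `ΔΔG = ΔG_mut − ΔG_WT`.

**ITC** — a one-set-of-sites forward model with the standard
perfusion-cell displacement correction; least squares over (N, K_D,
ΔH), with ΔG and −TΔS derived through the same conversion layer.

**SPR** — dissociation first, `R(t) = R0·exp(−koff t)`; then
pseudo-first-order association, `R(t) = Req·(1 − exp(−kobs t))` with
`kon = (kobs − koff)/C`; rates aggregate as mean ± s.e.m. over curves
and `K_D = koff/kon`.

**Ensembles** — iterative-mean Kabsch superposition, per-particle RMSF,
PCA of the Cα covariance, projections, the RMSIP subspace overlap
`sqrt((1/S) Σ (v_n·v_m)²)`, and an LDA replica-consistency report.

**PSN** — residues as nodes, edges where an interaction persists in at
least a fraction pT of frames (pT from the dissolution knee of the
largest hydrophobic cluster); hub degrees, ΔDegree between variant and
WT networks, and Communication Robustness `CR = (n_XY·pT)/l` between
the EF-hand glutamates E31/E67/E104/E140, with CR ≥ 0.1 deemed robust.

## Worked example

```
$ python examples/itc_thermodynamics.py
fitted: N = 1.00, K_D = 7.19 nM, ΔH = -11.30 kcal/mol  (planted 8.62 nM, -11.28 kcal/mol)
derived: ΔG = -11.11, −TΔS = 0.19 kcal/mol

variant peptide  dg_calc  dg_ref  minus_tds_calc  minus_tds_ref  ddg_calc  ddg_ref
     WT    RyR1   -10.79  -10.78           -0.85          -0.84       NaN      NaN
   N97I    RyR1   -10.51  -10.50           -0.93          -0.92      0.29     0.28
  Q135P    RyR1    -9.83   -9.83           10.14          10.14      0.96     0.95
     WT    RyR2   -11.00  -11.01            0.28           0.27       NaN      NaN
   N97I    RyR2   -10.79  -10.78           -0.77          -0.76      0.21     0.23
  Q135P    RyR2    -9.66   -9.65            6.54           6.55      1.35     1.36
```

The first two lines fit a noisy synthetic thermogram and recover the
planted parameters. The table recomputes, from the published
calorimetric (K_D, ΔH) inputs alone, the binding free energy ΔG, the
entropic term −TΔS and the mutational penalty ΔΔG for every CaM
variant × RyR peptide pair; each recomputed column matches the
published reference cells within ±0.02 kcal/mol. Positive ΔΔG (both
variants, both peptides) means weakened binding, largest for Q135P
with RyR2 — the cardiac-muscle target.

The other scripts in `examples/` walk through titration fitting, SPR
kinetic discrimination, essential-dynamics consistency, and EF-hand
communication robustness the same way.

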