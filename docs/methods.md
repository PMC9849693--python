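# Methods

This note documents the models, numerical choices and limitations of
`camryr`. It covers what each module computes, why the defaults are
what they are, and what the synthetic generators do and do not emulate.

## Equilibrium binding (`equilibria`)

A fixed concentration L of RyR peptide (1 µM in the emulated protocol)
is titrated with CaM at total concentration x. The observable is the
Trp emission-peak wavelength, converted to fraction bound
`fb = (y − y0)/(ymax − y0)`; noise can push fb slightly outside [0, 1]
and it is deliberately left unclamped so residuals stay unbiased.

Two isotherms are available:

* `hyperbolic` — `fb = x/(K_D + x)` on *total* titrant. This ignores
  ligand depletion and is the classic one-site saturation function.
* `quadratic_depletion` — the exact 1:1 mass-balance root
  `fb = ((x + L + K_D) − sqrt((x + L + K_D)² − 4xL)) / (2L)`.
  With L = 1 µM and K_D of order 100 nM, depletion is material
  (roughly x·fb of the titrant is consumed), so this form is the
  generator's truth model and the recommended fit model; both are
  exposed and can be reported side by side.

Fits are per replica, never pooled: each replica yields its own K_D
and replicas aggregate as mean ± s.d., with Welch's t-test for
pairwise condition comparisons. K_D is optimized as log₁₀K_D (bounds
10⁻¹³–10⁻² M) to condition the nM–µM range; the signal endpoints
y0/ymax are free parameters by default. Pinning them to the first/last
observed signal is available but is only unbiased when the titration
actually saturates — on a 0–4 µM grid with K_D ≈ 256 nM the final
point sits near fb ≈ 0.92, so pinning systematically underestimates
K_D. That is a property of the estimator, not a bug, and is why free
endpoints are the default.

Thermodynamics: `ΔG = RT ln(K_D/1 M)` with R = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹ and T = 298.15 K for 25 °C; `−TΔS = ΔG − ΔH`;
`ΔΔG = ΔG_mut − ΔG_WT` defined only for records sharing peptide and
temperature. `ThermoRecord` enforces both identities at construction
to 10⁻⁹ kcal/mol, so the thermodynamic cycle closes by design. The
depletion-corrected isotherm converges pointwise to the hyperbola as
L → 0; the leading correction scales as (L/K_D)·K_D²/(K_D+x)², which
the tests verify by halving-rate rather than at a fixed L.

## ITC (`calorimetry`)

One-set-of-sites model for a perfusion cell: after cumulative injected
volume ΔV into cell volume V₀,

    [M]ᵢ = M₀ (1 − ΔV/2V₀)/(1 + ΔV/2V₀)
    [X]ᵢ = Xs (ΔV/V₀)/(1 + ΔV/2V₀)

are the displacement-corrected totals of macromolecule and titrant,
the bound complex solves the 1:1 quadratic with site concentration
N·[M]ᵢ, and the measured injection heat is
`qᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2` with `Qᵢ = [MX]ᵢ·ΔH·V₀`,
normalized to kcal per mole of injectant. An independent per-injection
root-finding oracle (Brent's method on the mass balance) reproduces
the closed-form heats to 10⁻⁶ relative in the tests.

Fitting floats N, log₁₀K_D and ΔH. N is free (not pinned to 1) so a
recovered N ≈ 1 serves as the stoichiometry check. The Wiseman
c-parameter (N·M₀/K_D) is evaluated after the fit and a reliability
warning is issued outside 1–1000; with the emulated protocol (10 µM
cell, K_D ≈ 10 nM) c ≈ 10³, at the steep edge of that window, which is
exactly why K_D recovery there is specified loosely (median within
20 %) while ΔH recovers within a few per cent. Blank (heat-of-
dilution) runs subtract element-wise before fitting. First-injection
discard is available but off by default.

Energy bookkeeping: total integrated heat approaches N·M₀·V₀·ΔH only
when the equivalence volume is small relative to the cell; the
displacement model necessarily loses the unbound macromolecule carried
out of the cell (≈ ΔV_eq/2V₀, about 4 % under the default protocol),
so the conservation test runs in the low-equivalence-volume regime.

## SPR kinetics (`kinetics`)

1:1 Langmuir scheme with pseudo-first-order association
(`kobs = kon·C + koff`) and single-exponential dissociation. The
analysis is two-stage in the order the data support best: the
dissociation phase (300 s, concentration-independent) is fitted first,
and the resulting koff is held fixed while each association phase
(60 s) yields kobs, hence kon = (kobs − koff)/C. koff can be fitted
per curve (default) or globally across all dissociation phases.
kobs ≤ koff is rejected as a negative-kon error — it indicates a
mislabeled concentration or a bad koff, not a fittable curve. kobs is
initialized from the observed half-rise time, which keeps the
optimizer out of the saturated-exponential local minimum. Rates
aggregate as mean ± s.e.m. over curves; fold changes between
conditions propagate first-order ratio errors; `K_D = koff/kon` holds
exactly by construction. Bulk refractive-index offsets and
injection-artifact masking exist as options, both off by default.

## Ensemble analytics (`ensemble`)

Superposition is a Kabsch least-squares fit of every frame onto an
iteratively refined average (default 2 refinement rounds; the fixed
point is independent of initial frame orientations, which the tests
verify at 10 rounds). Rotations are proper. The fit selection defaults
to Cα; ions are excluded from fitting but included in RMSF.

RMSF is `sqrt(⟨|r(t) − ⟨r⟩|²⟩)` per particle and requires a superposed
ensemble. For isotropic per-axis jitter σ it converges to σ√3. PCA
diagonalizes the 3P×3P covariance of the flattened Cα coordinates (no
mass weighting); eigenvalues are clipped at zero and the trace equals
the total coordinate variance. RMSIP between two S-dimensional
essential subspaces is `sqrt((1/S) ΣΣ (vₙ·vₘ)²)`: 1 for identical
subspaces, 0 for orthogonal ones, ≈ sqrt(S/3P) for random ones —
0.258 for S = 20 in 300 dimensions, which is the floor against which
observed overlaps should be judged. Subspaces are comparable only in a
common reference frame: superpose the concatenated ensemble once, then
split into replicas. Replica consistency fits an LDA on the 2-D PC
scores; consistent replicas classify near chance and overlap highly.
The overlap scalar is the closed-form Bhattacharyya coefficient of
per-replica Gaussian fits in the score plane — a reproducible stand-in
for the visual density-overlap comparison this analysis usually ends
with.

## Protein structure networks (`psn`)

Inputs are frame-wise interaction records (H-bond / electrostatic /
hydrophobic) between residues; the primary ingestion path is
pre-computed records, keeping the module trajectory-format-agnostic.
Persistence is the fraction of frames a pair interacts (duplicates
within a frame count once). The PSN has an edge where merged
persistence ≥ pT; classes merge by maximum persistence (sum is
available but can double-count a contact detected in two classes).

pT selection scans a grid (default 0.05–0.95, step 0.05), tracking the
largest connected component of the hydrophobic-only network, and picks
the grid point just before the steepest drop; ties resolve to the
smaller pT (more inclusive network), and a flat or empty profile falls
back to pT = 0.2 with a warning.

Topology: hubs are nodes with degree strictly greater than `min_degree`
(default 4); the comparative reporting set collects nodes reaching
degree ≥ 6 in at least one of the compared networks; ΔDegree is
variant-minus-WT degree per node, with missing nodes counted as degree
0 under a notice. Shortest paths are unweighted BFS; the count n_XY is
over distinct node sequences, validated against exhaustive DFS
enumeration on graphs of ≤ 12 nodes.

Communication Robustness between two residues combines the number n of
shortest paths, their length l and pT. Two algebraic readings of this
index circulate; both are implemented: `(n·pT)/l` (default — it yields
values in the 0–0.5 range where the 0.1 robustness threshold is
meaningful) and `n·pT^l` (selectable — it collapses below 0.1 for any
l ≥ 2 at typical pT, which would make the threshold vacuous). The
EF-hand CR matrix evaluates all six pairs of the representative
bidentate glutamates E31/E67/E104/E140 (mature-protein numbering, no
initiator Met) and flags pairs with CR ≥ 0.1 as robust.

## Synthetic generators (`synthetic`)

All generators are pure functions of their arguments with
`numpy.random.default_rng(seed)` randomness and return ground truth
alongside the data. Defaults are the emulated study conditions:
0–4 µM titrant over 12 points with 1 µM ligand; thirty 1-µL
injections of 125 µM titrant into 10 µM cell at 200 µL; sensorgram
series at 0.25/0.5/1/2 µM with 60 s + 300 s phases sampled at 2 Hz;
20-particle helical backbones with planted orthonormal modes; and
Bernoulli per-frame interaction records with planted persistences.
Noise defaults — 2 % of signal span (fluorescence), 2 % of max |heat|
(ITC), 1 RU (SPR), 0.3 Å jitter (ensembles) — were chosen once to
keep recovery nontrivial but reliable at the study's replicate counts.

The EF-network generator wires the four EF-hand glutamates through
intermediate residues: EF3–EF4 always carries two parallel two-hop
routes at persistence 0.8; EF1–EF3 carries the same by default and is
severed in the "mutant-like" setting, leaving only a long detour that
falls below the CR threshold. Low-persistence distractor pairs sit far
below any sensible pT.

What the generators do **not** emulate: forcefield physics, correlated
instrument drift, mass-transport limitation in SPR, baseline
integration of raw ITC power traces, or anharmonic/multi-basin
conformational dynamics. Passing the recovery suites therefore shows
that the estimators are correct and well-conditioned under the stated
noise models — not that real MD ensembles or instrument quirks are
captured. Quantities that require microsecond trajectory ensembles
(experimental RMSIP values, ΔRMSF profiles, specific ΔDegree totals
and CR values of real complexes) are covered by property suites and
planted-structure analogues only.

## Problem sizes and determinism

The test and acceptance workloads are sized for a single CPU: 100
fluorescence seeds, 50 ITC seeds, 12 sensorgrams per kinetic
condition, 200 random-subspace draws, 5000-frame RMSF ensembles, 50
oracle graphs and 100 EF-network instances; the full suite runs in a
few seconds. Every stochastic step derives from an explicit seed, and
`RunConfig` serializes itself (with a hash) into every summary bundle
so any run is reproducible from its own log.
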