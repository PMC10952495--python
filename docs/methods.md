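# Methods

This note records the models implemented, the conventions and defaults the
package commits to, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## REES quantification

Emission spectra (nominally 315–500 nm at 1 nm, excited 292–310 nm at 1 nm)
are modelled as a sum of two skewed Gaussians; the extra component absorbs
non-tryptophan contributions (scatter, additional emission bands) so that
the tryptophan component can be summarised alone. Conventions:

* **Skewed Gaussian.** `f(λ) = f_max exp(−ln2 [ln(1+2b(λ−λ_max)/w)/b]²)`,
  defined as 0 where the log argument is non-positive. `w` is the FWHM in
  the symmetric limit. For |b| < 1e−6 the symmetric Gaussian branch is used;
  the exact branch is evaluated with `log1p`, and at the threshold the two
  branches agree to better than 1e−6·f_max (the threshold was set where that
  agreement holds, which is why it is tighter than the naive 1e−4 one might
  pick for `ln(1+x)/x` stability).
* **Tryptophan assignment.** The component with λ_max in 320–400 nm carrying
  the larger integrated area; ties fall back to area, then smaller λ_max.
* **CSM** is the intensity-weighted mean **emission** wavelength of the
  component evaluated on the measured emission grid. (The index in the sum
  runs over emission wavelengths; CSM₀ then reports like a λ_max but uses
  the whole band shape.)
* **Replicates** (up to 12 per excitation) are averaged point-wise before
  fitting.
* **Fit initialisation.** λ_max from the argmax of a 7-point moving average,
  w from the empirical FWHM clipped to [5, 200] nm, b = 0.1, |b| ≤ 2,
  second component seeded 70 nm to the red at 40 % amplitude.
* **REES exponential.** `CSM = CSM₀ + A e^{RΔλ_Ex}` fitted unweighted
  (optional per-point sigmas accepted); starting values CSM₀ = min CSM,
  A = range, R = 0.1 nm⁻¹ with only R bounded positive. A fitted amplitude
  within 2 SE of zero flags the curve as flat instead of reporting an
  unstable A/R.

## Two-state melts

`θ(T) = [b_f+m_f T + (b_u+m_u T)K_u]/(1+K_u)` with the van't Hoff constant
`K_u = exp[−ΔH(1−T/T_m)/(RT)]` (R = 8.314 J mol⁻¹ K⁻¹; the denominator is
RT, not RT_m). The sign convention is fixed so that unfolding is favoured
above T_m for ΔH > 0; K_u(T_m) = 1 identically, and at T_m the model passes
through the mean of the two baselines. Temperatures are Kelvin throughout
(CSV input in °C is converted when a units column says so). Normalising a
curve to 0/1 at two anchor temperatures is affine and therefore commutes
with the fit. Initialisation: T_m from the extremum of a smoothed dθ/dT,
ΔH = 300 kJ/mol, baselines from linear fits to the outer 15 % of points.
**No-transition rule:** fitted transition amplitude at T_m below 5 % of the
signal range, or T_m pinned at a range bound — this reproduces the
"unfolded before the ramp" phenotype of the non-glycosylated apo enzyme
without inventing a midpoint.

## Kinetics and MMRT

Turnover = slope/(ε·l·[E]·60) with ε₄₅₀(DAP) = 10 600 M⁻¹cm⁻¹.
Michaelis–Menten fits run on per-enzyme rates; k_cat/K_M is reported in
s⁻¹ M⁻¹ (mM → M conversion). The MMRT expression is fitted on ln k (variance
stabilised) with T₀ fixed at 298 K — T₀ is arbitrary, and 298 K makes the
reported ΔH‡/ΔS‡ directly comparable with the published HRP values. ΔH‡ is
in kJ mol⁻¹ and ΔS‡/ΔC_p‡ in kJ mol⁻¹ K⁻¹ (a published table prints ΔH‡
with K⁻¹ in the unit; dimensional analysis of the rate law requires
kJ mol⁻¹ and that is what `reference.py` stores). The apparent optimum is
the closed-form stationary point `T_opt = (ΔC_p‡T₀ − ΔH‡)/(ΔC_p‡ + R)`,
which exists as a maximum only for ΔC_p‡ < −R; it is cross-checked against
a numeric argmax on a 1 mK grid. Rates below detection are excluded, not
clamped.

## Rigidity analysis

**Model.** Every atom is a rigid body with 6 degrees of freedom. Constraints
place bars between bodies: rotatable covalent bonds 5 bars (one dihedral
left), non-rotatable bonds 6 (peptide bonds, carbonyls/carboxylates/amides,
planar aromatic and guanidinium groups, the haem porphyrin as one conjugated
unit, Ca²⁺ coordination), hydrogen bonds 5 (between the hydrogen and the
acceptor), hydrophobic tethers 2, artificial glycosylation constraints 6
(configurable). These are the standard body-bar conventions for protein
rigidity; the source does not fix them, so they are exposed as module
constants.

**Covalent detection** is distance-based (covalent-radius sums + 0.4 Å,
clipped to 0.7–2.6 Å); hydrogens bond to their single nearest heavy atom.
Disulfides and metal coordination fall out of the same rule via the radii.

**Hydrogen-bond energy.** No explicit energy function was published for the
dilution; we adopt the Mayo-style 12-10 potential that the pebble-game
lineage of rigidity software uses:
`E = V₀[5(d₀/d)¹² − 6(d₀/d)¹⁰]·cos²θ·e^{−(π−θ)⁶}·cos²(φ−φ₀)` with
V₀ = 8 kcal/mol, d₀ = 2.8 Å (donor–acceptor), θ the D–H···A angle (gated at
90°), φ the H···A–base angle with φ₀ = 120° (sp²) or 109.5° (sp³). Salt
bridges between Arg/Lys and Asp/Glu groups get a fixed −10 kcal/mol so they
survive every cutoff. Only E < 0 is kept. Sensitivity of absolute RC1 counts
to this choice is the main caveat when comparing against published counts
for a specific crystal structure.

**Pebble game.** The (6,6) pebble game inserts each bar by gathering seven
pebbles on its endpoints; failures mark redundant bars. After insertion,
two bodies are mutually rigid iff a seventh pebble cannot be gathered onto
them; mutual rigidity is transitive and rigid components induce connected
subgraphs, so clusters are built by union-find over bonded pairs that test
rigid. The test suite proves equivalence with an independent numeric oracle
(rank of the generic body-bar rigidity matrix with random bar attachments)
on 100 random frameworks — residual DOF and the full pairwise rigid/flexible
classification.

**Dilution.** Cutoffs −1.0 → −4.0 kcal/mol in 0.5 steps. RC1 is the cluster
with the most Cα members (ties by atom count); ranking by Cα membership
makes the profile provably non-increasing under constraint removal. A
residue belongs to RC1 iff its Cα atom is in that cluster.

**Mimics.** Apo: delete all atoms of the HEM residue(s), nothing else.
Glycosylation: 6-bar Cα(i)–Cα(i±1) constraints at each listed asparagine
(HRP defaults N13, N57, N158, N186, N198, N214, N255, N268); a terminal
site contributes only its existing flank. Six bars fully lock the local
backbone triple — the strongest defensible reading of "reduced backbone
flexibility at the site"; the count is configurable for weaker readings.

**Inputs.** The analysis expects a protonated single-model PDB; a real
structure should be protonated with an external tool first. Waters are
dropped; alternate locations resolved by occupancy. Quantitative RC1 counts
for a specific published structure are sensitive to protonation and to the
H-bond energy function and are treated as benchmarks to track, not as unit
tests; the qualitative orderings (haem removal shrinks RC1, glycan
constraints never shrink it, the four-form ranking holo-glyco > holo >
apo-glyco > apo at intermediate cutoffs) are asserted on constructed
structures.

## Ensemble networks

Frames are superposed by Kabsch least squares over Cα. RMSF is per-residue
Cα fluctuation about the frame-mean position. ΔRMSF significance is
relative: threshold = 10 % of max|Δ| (scale-invariant by construction).
The "smallest distance over the simulation" matrix is ambiguous between
min-of-frames and mean-of-frame-minima; the default is mean-of-frame-minima
(matching how trajectory distance-matrix tools average), with `mode="min"`
available. Heavy-atom minima are the default, Cα-only by flag. The contact
gate for difference networks includes a pair if it is within 5.5 Å in
either condition (flag to require both); the "closer" classification uses
a 0.3 Å threshold — just below the smallest distance change displayed in
the published networks, and configurable. The interaction classifier
(HBOND: D–A ≤ 3.5 Å, D–H···A ≥ 120°; VDW: vdW-radius sum + 0.5 Å;
IONIC: charged-group centroids ≤ 4.0 Å; PIPISTACK: ring centroids ≤ 5.5 Å,
plane angle ≤ 30° or ≥ 150°) is a deliberately simple geometric stand-in
for a full interaction-typing engine, not a reimplementation of one.

## Synthetic data

Generators are deterministic given their seed and emit their ground truth
alongside the data. Defaults are the study conditions: excitation 292–310 nm,
emission 315–500 nm, melts 300–370 K (60 points), substrate 0.1–4.0 mM in
triplicate, kinetics temperatures 293–313 K (9 points), REES truth
(CSM₀, A, R) = (345, 1.5, 0.12), kinetic truths from the published HRP
parameter sets (k_cat 917 s⁻¹, K_M 0.92 mM; ΔH‡ 1.3, ΔS‡ 1.13,
ΔC_p‡ −1.9 at T₀ = 298 K), melt midpoint 350.8 K with a 450 kJ/mol van't
Hoff enthalpy typical of a ~34 kDa glycoprotein (the study did not publish
its fitted ΔH).

* REES spectra are constructed so the tryptophan-component CSM follows the
  exponential law *exactly on the measurement grid* (λ_max is solved
  numerically per excitation; grid truncation makes CSM slightly nonlinear
  in λ_max, so a closed-form shift would not be exact).
* The toy structure is an ideal α-helix (φ = −57°, ψ = −47°) of alanines
  with amide hydrogens built by internal-coordinate placement; its i→i+4
  N–H···O bonds are detected geometrically and then assigned *designed*
  energies through an override table, so dilution tests break at exactly the
  designed cutoffs instead of depending on sub-0.1-kcal geometry tuning.
  The optional "HEM" ligand is a rigid carbon polyline laid alongside a
  chosen residue span in van der Waals contact with the Cβ atoms — a
  minimal cofactor analogue that bridges the chain through hydrophobic
  tethers and disappears under the apo mimic.
* Ensembles displace each residue independently and isotropically per frame;
  with per-axis standard deviation σ the expected Cα RMSF is σ√3 (this is
  the generator's documented convention, asserted in closed form). Frames
  share one reference frame by construction, so RMSF recovery tests need no
  superposition step. Scripted motifs (ionic pair, H-bond, π-stack, van der
  Waals contact) are placed in interaction geometry in an exact, seeded
  subset of frames.

**What passing tests show — and not.** Zero-noise recovery, Monte-Carlo
spread and oracle equivalence demonstrate the estimators and algorithms are
correct on data generated by the models they fit. Real spectra have
instrument baselines and inner-filter effects, real melts deviate from
two-state behaviour near aggregation, real trajectories have correlated,
anisotropic fluctuations, and real structures have protonation ambiguity —
none of which the generators emulate. Conclusions about a real protein
still require the measurements.

## Problem sizes

Default test problem sizes were chosen to keep every check sharp at desk
scale: 19-excitation spectra, 60-point melts, 200-seed Monte-Carlo studies,
100 random frameworks of ≤ 12 bodies for the rank oracle, 15-residue toy
helices (~90–180 atoms) for dilution tests, and ensembles of ≤ 500 frames ×
≤ 10 residues for brute-force comparisons. The rigidity pipeline itself is
pure Python and handles full-size proteins (thousands of atoms) in minutes
per cutoff; nothing in the implementation is limited to the toy sizes.

## Known limitations

* The pebble-game cluster labelling relies on rigid components inducing
  connected subgraphs — true generically and verified exhaustively against
  the rank oracle, but not formally proved here for degenerate geometries.
* The H-bond energy function and protonation dominate absolute RC1 counts;
  comparisons across structures are meaningful, absolute counts less so.
* The interaction classifier approximates "strict" interaction-typing
  thresholds; frequencies for marginal geometries will differ from engines
  with residue-specific rules.
* Body-bar rigidity slightly over-rigidifies rings (a 5-bar cycle of six
  bodies is rigid), a known property of the model rather than a bug.
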