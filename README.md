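# glycoflex

Tools for asking a structural question about enzyme engineering: **does a
post-translational modification far from the active site change a protein's
rigidity — and with it, its stability and turnover?** The package was built
around horseradish peroxidase (HRP), whose plant form carries eight N-linked
glycans while the recombinant form carries none, but every component works on
generic inputs.

It implements five analysis stages plus a synthetic-data generator:

1. **REES fluorescence** (`glycoflex.spectra`) — tryptophan emission spectra
   measured at excitation wavelengths λ_Ex = 292–310 nm are deconvolved into
   sums of two skewed Gaussians,
   `f(λ) = f_max · exp(−ln2 · [ln(1 + 2b(λ−λ_max)/w)/b]²)`,
   and the centre of spectral mass (CSM = Σ fᵢλᵢ / Σ fᵢ) of the tryptophan
   component is fitted to `CSM = CSM₀ + A·exp(R·Δλ_Ex)`. The ratio A/R is an
   empirical flexibility metric: a wider distribution of solvent–fluorophore
   environments (a more flexible protein) gives a larger A/R.
2. **Thermal melts** (`glycoflex.melt`) — CD ellipticity at 222 nm fitted to
   a two-state model with sloping baselines,
   `θ(T) = [b_f + m_f T + (b_u + m_u T)·K_u]/(1 + K_u)` with
   `K_u = exp[−ΔH(1 − T/T_m)/(RT)]`, yielding T_m and the Van't Hoff ΔH.
3. **Kinetics & MMRT** (`glycoflex.kinetics`) — absorbance slopes converted
   to turnover with the DAP extinction coefficient (ε₄₅₀ = 10 600 M⁻¹cm⁻¹),
   Michaelis–Menten fitting, and macromolecular rate theory for the curved
   temperature dependence of k_cat:
   `ln k = ln(k_B T/h) − [ΔH‡ + ΔC_p‡(T−T₀)]/(RT) + [ΔS‡ + ΔC_p‡ ln(T/T₀)]/R`,
   with the apparent optimum `T_opt = (ΔC_p‡·T₀ − ΔH‡)/(ΔC_p‡ + R)`.
4. **Pebble-game rigidity** (`glycoflex.rigidity`) — an all-atom body-bar
   network (atoms = bodies with 6 DOF; covalent bonds 5 or 6 bars, hydrogen
   bonds 5, hydrophobic tethers 2) decomposed into rigid clusters by the
   (6,6) pebble game, validated against a generic rigidity-matrix rank
   oracle. A rigidity dilution lowers the hydrogen-bond energy cutoff from
   −1.0 to −4.0 kcal/mol and tracks RC1, the largest rigid cluster. Mimics:
   apo (strip the haem) and glycosylation (artificial Cα(i±1) constraints at
   the modified asparagines).
5. **Ensemble networks** (`glycoflex.ensembles`) — multi-model PDB ensembles
   reduced to Cα RMSF profiles (with the >10 %-of-max |ΔRMSF| significance
   rule), residue minimum-distance difference networks (5.5 Å contact gate,
   > i+4 long-range flag) and interaction-frequency differences (±10 %
   retention cutoff) with a simple geometric H-bond/VDW/ionic/π-stack
   classifier.

`glycoflex.synthetic` generates every input with known ground truth —
spectra whose CSM follows the REES law exactly, melts, rate tables,
MMRT series, protonated helical peptides with designed hydrogen-bond
energies and an optional bridging ligand, and Gaussian-fluctuation
ensembles with scripted interactions — so the whole pipeline is testable by
parameter recovery.

## Worked example

```python
from glycoflex.synthetic import gen_rees_dataset, gen_kinetics
from glycoflex.spectra import fit_spectrum, build_rees_curve, fit_rees_curve
from glycoflex.kinetics import fit_mmrt, compute_topt

spectra, truth = gen_rees_dataset(seed=1, noise_sd=0.002)   # truth: CSM0=345, A=1.5, R=0.12
fits = [fit_spectrum(s) for s in spectra]
rees = fit_rees_curve(build_rees_curve(spectra, fits))
print(f"CSM0 = {rees.csm0:.2f} nm, A = {rees.a:.3f} nm, "
      f"R = {rees.r:.4f} /nm, A/R = {rees.a/rees.r:.1f} nm^2")

_, series, _ = gen_kinetics(seed=1)        # pHRP-like MMRT truth
fit = fit_mmrt(series, t0=298.0)
print(f"dH = {fit.dh_t0:.1f} kJ/mol, dCp = {fit.dcp:.2f} kJ/mol/K, "
      f"Topt = {compute_topt(fit):.1f} K")
```

prints

```
CSM0 = 345.28 nm, A = 1.467 nm, R = 0.1203 /nm, A/R = 12.2 nm^2
dH = 1.3 kJ/mol, dCp = -1.90 kJ/mol/K, Topt = 300.0 K
```

i.e. the REES parameters are recovered from the noisy spectra to within a
few percent, and the fitted activation parameters place the apparent
temperature optimum of turnover at 300.0 K — a flat enthalpy barrier with a
strongly negative activation heat capacity, the signature that makes an
enzyme's rate peak well below its melting temperature.

A CLI mirrors the library (`glycoflex rees|melt|kinetics|rigidity|traj|synth …`),
e.g. `glycoflex rigidity run --pdb protein.pdb --apo` writes the dilution
profile and per-cutoff cluster assignments as CSV.

## Layout

```
src/glycoflex/
  spectra.py      REES deconvolution and exponential fitting
  melt.py         two-state thermal melts
  kinetics.py     Michaelis–Menten + MMRT + T_opt
  rigidity/       PDB parsing, bond/H-bond/tether detection, pebble game,
                  dilution, apo & glycosylation mimics
  ensembles.py    ensemble superposition, RMSF/distance/interaction networks
  synthetic.py    seeded ground-truth generators
  reference.py    published HRP characterisation used as defaults
  io.py, cli.py   CSV formats and the `glycoflex` command
docs/methods.md   modelling choices, conventions, limitations
```
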