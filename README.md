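# cannula

Quantitative analyses for cannula-forming proteins of hyperthermophilic
archaea — NMR titration, diffusion and polymerization data, plus structure
geometry — packaged as a tested, reusable pipeline.

The cannula proteins (CanA and its N-terminally truncated, non-polymerizing
variant) form heat-stable hollow tubes when divalent ions trigger
polymerization. Characterizing that process from solution NMR involves a
recurring set of small quantitative analyses, which this package implements
for peak lists, decay tables and PDB coordinates:

- **Chemical-shift-perturbation mapping** (`cannula.csp`): combined amide
  shift changes Δδ_comb = √(Δδ_H² + (w·Δδ_N)²) with w = 0.2 by default, an
  outlier-corrected significance threshold σ₀ (iterative RMS about zero with
  3σ exclusion), per-residue significance classes, and the slow-exchange rate
  bound k_ex ≤ πΔν/√2 from split resonances.
- **Per-residue dissociation constants** (`cannula.binding`): least-squares
  fits of the ligand-depletion isotherm
  Δδ(c_T) = Δδ_N/(2NM_T)·(K_D + c_T + NM_T − √((K_D + c_T + NM_T)² − 4NM_T·c_T))
  with N fixed at 1, standard errors from the fit covariance, and grouping of
  residues into the high-affinity (BA1) and low-affinity (BA2) binding areas.
- **PFG diffusion** (`cannula.diffusion`): attenuation fits I = I₀·e^(−aD·G²),
  hydrodynamic radii via the internal DSS reference
  (R_h = R_h(DSS)·D(DSS)/D(analyte), R_h(DSS) = 0.346 nm), and apparent masses
  by cubic scaling against an explicit user reference.
- **Polymerization kinetics** (`cannula.kinetics`): single/double exponential
  decays with an asymptote, reduced-χ² model comparison, and the critical
  monomer concentration (asymptote in concentration units, ≈ the monomer-off
  K_D).
- **Structure geometry** (`cannula.structure_tools`): Lys–carboxylate salt
  bridges (N–O < 0.4 nm, any-model union over an ensemble), charge census and
  sequence mass, Shrake–Rupley solvent accessibility with the >10% surface
  rule, Kabsch-superposed global and sliding-window local backbone RMSD, and
  interface residues by buried surface and interatomic distance.
- **Synthetic data** (`cannula.synthetic_data`): seeded generators for every
  input above, so the whole pipeline is testable without downloads, plus a
  clearly-labelled synthetic stand-in for the full-length protein sequence.

## Worked example

Fit the study-condition polymerization time course and extract the critical
concentration:

```python
from cannula import kinetics
from cannula.synthetic_data import default_kinetics_scenario, make_kinetics

curve, truth = make_kinetics(default_kinetics_scenario())
single = kinetics.fit_decay(curve, "single")
double = kinetics.fit_decay(curve, "double")
sel = kinetics.model_selection(single, double)
print(sel.preferred)                      # double
print([round(k, 3) for k in double.rates])  # [0.19, 0.03]
print(round(kinetics.critical_concentration(double, 1.0), 3))  # 2.48
```

The double-exponential model wins the reduced-χ² comparison, its two rates
separate the fast oligomerization phase (0.19 per time unit) from the slow
tube-assembly phase (0.03), and the fitted asymptote — 2.48 µM — is the free
monomer concentration coexisting with polymer.

The same pattern works for titrations:

```python
from cannula import binding
from cannula.synthetic_data import (default_titration_scenario,
                                    make_titration,
                                    titration_series_from_peaklists)

scen = default_titration_scenario("Ca2+", seed=0)
scen.noise_sigma = 0.0
peaklists, truth = make_titration(scen)
for s in titration_series_from_peaklists(peaklists, scen.M_T):
    fit = binding.fit_kd(s)
    print(s.residue.label, round(fit.K_D, 2))   # e.g. D57 0.74, D114 0.58 ...
```

A `cannula` command-line interface wraps the same stages
(`cannula csp`, `cannula kd-fit`, `cannula diffusion`, `cannula kinetics`,
`cannula structure`, `cannula simulate`); every run writes CSV/JSON reports
with a provenance block.

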