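# Methods

This note documents the models implemented in the package, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Chemical-shift perturbation

The combined amide shift change between two conditions is the weighted norm

    Δδ_comb = sqrt(Δδ_H² + (w · Δδ_N)²)

with the ¹⁵N weight `w` defaulting to 0.2, the conventional value derived
from the gyromagnetic-ratio scale of the two nuclei; it is a parameter
because laboratories use slightly different weights. The significance
threshold σ₀ is the standard deviation **about zero** of the per-residue
Δδ_comb values — perturbations are magnitudes with a null of zero, so an
RMS about the mean would be biased — computed iteratively: values larger
than 3σ (the signal) are removed and σ recomputed until a pass removes
nothing. The iteration refuses to drop below three retained values. Classes
follow the usual two-tier rule: above σ₀ significant (often second-layer
residues), above 2σ₀ strong (likely direct contact).

Residues present in only one peak list are reported as *unassessed*, never
as zero change: a vanished peak usually means exchange broadening or
polymerization loss, not absence of perturbation.

The slow-exchange bound on the interconversion rate of two resolved
conformers uses the coalescence criterion k_ex ≤ πΔν/√2 with
Δν = Δδ(ppm) × ν_Larmor(MHz) in Hz. The convention is stated in the report
output so an alternative (e.g. πΔν/2) can be substituted; published bounds
for this system are internally inconsistent at the 3% level, and the field
strength used for them is not recoverable, so no numeric cross-check is
asserted.

## Ligand-depletion binding isotherm

Per-residue apparent dissociation constants come from the exact single-site
depletion solution (protein not in excess over ligand):

    Δδ(c_T) = Δδ_N/(2NM_T) · (K_D + c_T + NM_T − sqrt((K_D + c_T + NM_T)² − 4NM_T·c_T))

with total protein M_T and N ligands per site fixed at 1 (the data cannot
determine N, so all K_D are *apparent*). Fits use bounded nonlinear least
squares (trust-region reflective) on (K_D, Δδ_N), initialized at the
half-maximal titration point and 1.1× the maximal observed change;
standard errors come from the linearized covariance at the optimum.
Optimizer failure or a bound-pinned solution yields `converged=False`
rather than an exception, so batch fits over dozens of residues continue.
Binding-area membership (BA1: D57, E97, K99, D114, K115, E116, G183;
BA2: D42, D140, E164, D169) is shipped as an editable CSV, not code, since
it derives from perturbation patterns plus surface accessibility rather
than from any formula.

Polymerization-induced intensity loss during full-length-protein titrations
is treated as extra noise only; no decay-correction term is applied.

## Diffusion

Only the composite exponent slope a·D of I = I₀e^(−aDG²) is ever fitted —
the gradient calibration constant a is unknown and cancels in the ratio
D(reference)/D(analyte) used for the hydrodynamic radius. Curves carry a
calibration tag and mixing tags is an error, because the cancellation only
holds within one calibration. A log-linear fit of ln I vs G² (weights ∝ I)
provides start values for the nonlinear refinement; both agree to well
under 0.5% on clean data. Slopes whose total attenuation over the gradient
range is below 10⁻⁹ are reported as exactly zero (the non-diffusing
control). Apparent masses use cubic scaling M_app = M_ref·(R_h/R_h,ref)³
against an explicit user-supplied reference pair; there is deliberately no
default, because the conversion assumes compact similar shapes and should
be a conscious choice.

## Polymerization kinetics

The free-monomer signal is modelled as one or two exponentials plus an
asymptote. The double model is initialized from the single fit with a
log-spaced rate pair (k/5, 5k) and amplitudes from a linear solve at those
fixed rates; rates are returned sorted descending. Model comparison uses
reduced χ² (unit weights unless per-point σ are given), with ratios within
[0.9, 1.1] flagged indistinguishable. The asymptote times a user conversion
factor gives the critical monomer concentration, which to first
approximation equals the K_D for monomer dissociation from polymer ends.

Time units: rates are reported in the reciprocal of whatever unit the time
axis uses; the package never guesses unit conversions. The default
synthetic scenario uses hours, with rate constants 0.19 h⁻¹ and 0.03 h⁻¹
over a 42 h window — the printed unit labels for such fits elsewhere are
inconsistent with an hours-long process, so the numerals are used with a
matching time axis.

Constant input curves degenerate gracefully: amplitude 0, asymptote equal
to the constant, and a `degenerate_rate` flag instead of a meaningless rate.

## Structure geometry

* **Salt bridges**: minimum Lys-NZ to Asp-OD1/OD2 or Glu-OE1/OE2 distance
  below 0.4 nm. Over an NMR ensemble a pair counts if the criterion holds
  in at least one model ("could be formed"); per-model hits are also
  reported. Residues missing side-chain atoms are skipped with a warning.
* **Accessibility**: hand-written Shrake–Rupley sampler with deterministic
  golden-spiral points (960 by default; quantization error shrinks with the
  point count and 2000 points agree with a 10⁵-sample Monte-Carlo oracle to
  ~2%). The probe radius defaults to 0.14 nm — the standard water probe
  radius; a source describing it as a 0.14 nm *diameter* is interpreted as
  the radius, and the interpretation is recorded in report metadata.
  Relative accessibility uses theoretical Gly-X-Gly maxima (Tien-style
  table, shipped as data) and is capped at 1.0, since an isolated residue
  exposes more surface than the reference context; residues above 10%
  relative accessibility are surface residues.
* **RMSD**: Kabsch superposition (SVD with reflection guard) over the
  selected residues and atoms (backbone N, CA, C by default), then
  coordinate RMSD over the same selection. The local profile superposes a
  5-residue window centered on each residue (window configurable, odd) and
  records the central residue's backbone RMSD; windows spanning chain
  breaks are skipped. Significance thresholds reuse the same iterative
  outlier-corrected RMS-about-zero as the shift perturbations.
* **Interfaces**: a residue of the target chain interacts with partner
  chain P when its accessible surface drops by more than 0.01 nm² upon
  adding P, or any heavy atom lies within 0.5 nm of P. The exact constants
  of the originating protocol are not public; these defaults are
  configurable and recorded in output.
* **Sequence arithmetic**: residue-type counts by direct string counting;
  polypeptide mass as the sum of average residue masses plus one water
  (via Biopython), reported in kg/mol.

## Synthetic data

Generators are pure functions of (scenario, seed) — fixed seeds reproduce
outputs bit-for-bit. Defaults encode the study conditions:

* **Titrations**: 0.17 mM protein; calcium doubling ladder 0, 0.1, …,
  25.6 mM (magnesium 0, 0.2, …, 51.2 mM); the per-residue apparent-K_D
  tables of the truncated construct for both ions; Gaussian shift noise of
  0.002 ppm per component (chosen to match the scatter scale of published
  titration plots). Saturation shift changes are not published; defaults
  are 0.15 ppm for high-affinity-area residues (0.25/0.30 ppm for the two
  strongest responders, K115/E116), 0.08–0.12 ppm elsewhere — set once at
  the scale of strong amide perturbations. Combined changes are split into
  ¹H/¹⁵N components with a fixed 60% ¹H fraction so the peak-list →
  perturbation → K_D chain runs end to end.
* **Kinetics**: 0.97 mM initial monomer decaying to a 2.48 µM asymptote,
  decaying amplitude split 60/40 between rates 0.19 h⁻¹ and 0.03 h⁻¹,
  sampled in the two acquisition blocks 100 × 3.5 min + 72 × 29.5 min
  (172 points over ≈41 h); optional Gaussian noise as a fraction (default
  scenarios use 2%) of the initial intensity.
* **Diffusion**: Gaussian-in-G² decays with arbitrary gradient units and a
  shared calibration tag; slope 0 emulates the polyacrylamide control.
* **Toy structures**: extended-chain peptides with idealized backbone
  offsets and explicitly placed side-chain atoms, with ground-truth
  salt-bridge/contact annotations; clashes below 0.08 nm are rejected.

The **reference sequence** is a synthetic stand-in: the real sequence is
published only as a figure image. Every residue whose identity and position
the analyses rely on (the mobile N-terminal segment, secondary-structure
boundary residues, H28, all charged residues of the binding areas and the
salt-bridge census, M1/M166, C-terminal G183) sits at its stated position;
filler positions were chosen once so that the composition census
(21 Asp+Glu, 12 Lys, 1 His, 0 Arg) and the chain mass (19.85 kg/mol) match
the real protein. Sequence-level results computed on it (census, mass) are
exact by construction; any residue-adjacency or hydrophobicity analysis on
the filler positions would be meaningless, and none is performed.

What the generators do **not** emulate: spectral crowding and assignment
ambiguity, exchange broadening, intensity loss from polymerization during
titrations, baseline drift, correlated noise, or realistic 3D folds.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated noise model, not robustness to all real-data pathologies.

## Recovery performance and problem sizes

Noise-free recovery is exact to optimizer precision (≪0.1%) for every fit.
Under the default noise models, measured with 200 seeded replicates each:

* Titration K_D (0.002 ppm noise, doubling ladder): median relative error
  2–5% for K_D well inside the titration range, 12–14% near its upper end.
  A K_D above the largest titration point is flagged by stderr/K_D ≥ 0.2.
* Kinetics rates (2% intensity noise): median relative error ~5% for the
  fast rate, ~13% for the slow rate, ~8% pooled over both. The slow-rate
  error is dominated by the asymptote (2.48 µM) lying far below the noise
  level (~19 µM), which lets the slow rate and asymptote trade off.

Test and acceptance runs use these same sizes (172-point time courses,
10-point titrations, 200 replicates, 5-residue accessibility toys with a
10⁵-point Monte-Carlo oracle); they complete in seconds and were chosen as
the smallest sizes that exercise the estimators at the study conditions.

## Known limitations

* Absolute diffusion coefficients are out of scope (no gradient
  calibration); only ratios and radii are reported.
* Multi-site or cooperative binding models are not fitted; each residue is
  fitted independently, which is why all K_D are apparent.
* Mechanistic polymerization models (nucleation–elongation) are not
  implemented; the two-exponential description is empirical.
* Ramachandran statistics are deliberately not computed: favored/allowed
  region definitions are tool-specific and no reference definition is
  available.
* The deposited-coordinate geometry checks (solution ensemble vs tube
  protomer) require the user to download the PDB entries; the package
  ships no coordinates.
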