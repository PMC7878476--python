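# Methods

`xlintegrate` implements the computational core of an integrative
structural analysis of a multidomain Hsp40 chaperone (DnaJB8): chemical
cross-linking mass spectrometry (XL-MS) contact mapping, distance
restraints on structural models, hydrodynamic size comparison, and the
solution biophysics (NMR titrations and fluorescence-polarization
binding) used to dissect the J-domain/C-terminal-domain interaction.
This note records the models, parameter choices, numerical decisions,
and the limits of what the synthetic-data tests demonstrate.

## Cross-linker mass accounting

All mass parameters are derived from a monoisotopic atomic mass table
(IUPAC values to ≥6 decimals: H 1.00782503, ²H 2.01410178, C 12,
N 14.00307400, O 15.99491462, S 31.97207100 Da), never hard-coded:

| chemistry | reaction | mass shift |
|---|---|---|
| ADH cross-link | C₆H₁₄N₄O₂ bridge − 2 H₂O | +138.09055 Da |
| ADH monolink (hydrolyzed) | bridge − 1 H₂O | +156.10111 Da |
| DMTMM coupling | zero-length, − 1 H₂O | −18.01056 Da |
| DSS cross-link | C₈H₁₀O₂ bridge | +138.06808 Da |
| DSS monolink (hydrolyzed) | bridge + H₂O | +156.07864 Da |
| ADH h8/d8 isotope delta | 8 × (m(²H) − m(¹H)) | +8.05021 Da |

Two documented discrepancies with commonly used search-parameter values:
the DSS-d12 delta computed from atomic masses is 12.07532 Da where
search configurations often carry 12.07573 Da, and the DSS aminolysis
monolink (+NH₃) computes to 155.09463 Da versus a configured 155.09643
Da. We report the computed values and do not assert the configured ones.
Which DSS monolink mass corresponds to hydrolysis versus aminolysis is
not standardized; both compositions are exposed by name.

Distance bounds for satisfaction: acid–acid (ADH) 21 Å, acid–lysine
(DMTMM) 16 Å. DSS has no canonical bound in this workflow; the default
is 30 Å Cα–Cα (the common literature convention), configurable in the
chemistry registry. The protein N-terminus is treated as amine-reactive
only when explicitly configured (default off).

## Cross-link tables and contact maps

Residue coordinates are 1-based inclusive. Deduplication collapses
records to unique unordered residue pairs per (chemistry class,
condition); chemistry *class* groups linkers by reactive pair so two
acid–acid reagents dedup together. Domain classification uses the
DnaJB8 map JD 1–82, G/F 83–139, S/T 140–169, CTD 170–232; the G/F↔S/T
boundary is not sharply defined by the construct annotation, so the
139/140 split is flagged "approximate" in the map metadata and is
configurable. Class labels order domain names lexicographically
("CTD–JD"), making classification symmetric by construction. An H5
helix interval may be configured as a sub-feature; it is reported as an
annotation, never as a class. In homo-oligomeric samples intra- and
intermolecular links are indistinguishable, so records default to
"ambiguous"; monomeric-sample metadata can mark them intramolecular.

Covariation overlap: a cross-link pair overlaps a covarying pair
(probability ≥ 0.7) if both coordinates agree within a ±2-residue
window, in either orientation. The window accounts for the residue-level
granularity difference between covariation and cross-link chemistry;
both threshold and window are parameters.

Published cross-link counts from the original mass-spectrometry searches
are not reproducible from this package (they depend on raw spectra and
search-engine scoring); the table operations are instead validated
against brute-force set-operation oracles on randomized synthetic
tables.

## Ensemble satisfaction scoring

A link is satisfied by a model when the inter-residue distance is ≤ the
chemistry bound (inclusive; boundary behavior tested). The atom
convention is Cα–Cα by default — robust for backbone-only models and
consistent with the magnitudes of the 21/16 Å bounds — with Cβ and
reactive-terminal-atom (NZ/CG/CD) rules available; whether published
thresholds refer to Cα or side-chain distances is not stated anywhere
authoritative, so the choice is exposed. Models missing a linked residue
score that link unsatisfiable (False) and are flagged rather than
dropped, so histogram mass always equals the model count. Scoring is
verified exactly against a brute-force double loop on 50-model ×
50-link synthetic instances and is invariant under rigid motions.

## Restraint-driven collapse

The collapse module reproduces the *logic* of restraint-guided
compaction — apply cross-link upper bounds to an extended conformation,
minimize, compare sizes — at desk scale with a transparent
coarse-grained model, not an all-atom force field:

* one bead per residue; harmonic bonds at 3.8 Å (k = 10);
* flat-bottom harmonic restraints: zero inside the upper bound,
  quadratic outside (weight default 1);
* soft-sphere repulsion, σ = 4 Å (k = 1), between beads ≥2 apart in
  sequence.

Units are arbitrary but consistent; only the geometry matters.
Fully flexible chains are minimized with L-BFGS-B using the analytic
gradient (energies of accepted iterates are non-increasing because each
line search enforces sufficient decrease). Chains with rigid groups use
projected gradient descent with backtracking: the per-bead gradient
within a group is reduced to its net force and torque, groups move only
rigidly, and group coordinates are re-derived from the stored template
by Kabsch superposition each step, keeping internal geometry exact to
1e-6 Å. Five seeded restarts (small Gaussian perturbations of the free
beads) guard against trapped conformations; the best-energy result is
returned, deterministically for a given seed. A satisfied restraint ends
numerically *on* the flat-bottom boundary, so satisfaction of minimizer
output is scored with a small slack (0.05 Å in the tests); ensemble
scoring of structures uses the strict inclusive bound.

Published collapsed/expanded sizes for the full-length chaperone
(Rh 9.27 → 4.02 nm, Rg 6.65 → 2.45 nm) came from an all-atom modeling
and rigorous hydrodynamics pipeline and are not asserted here; the
package reports its own coarse-grained sizes for qualitative comparison.
The number and weighting of restraints in the original full-length
collapse is not recorded, so both are configuration.

## Hydrodynamic size

Rg is the root-mean-square distance from the centroid with uniform bead
weights (backbone-only models carry no reliable masses). The
Marsh–Forman-Kay empirical chain-length laws Rh = A·N^B use A = 2.49 Å,
B = 0.509 for disordered chains and A = 4.75 Å, B = 0.29 for folded
ones; the disordered law at N = 232 gives 3.98 nm, the value used to
size a disordered full-length monomer. The Kirkwood approximation
1/Rh = (1/N²)·Σ_{i≠j} 1/r_ij is a transparent first-order estimate of
the hydrodynamic radius from bead coordinates — no bead radius, no
hydration shell — and is homogeneous of degree 1 in the coordinates;
it underestimates Rh for compact particles relative to bead-shell
methods, which is why the published HYDROPRO radii are reported as
reference numbers, not targets. Internal units are Å with a single
conversion to nm at the API boundary.

## Sequence charge

NCPR is the mean formal charge over a sliding window (default 10):
D/E −1, K/R +1, H 0 by default (fractional protonation configurable),
all else 0. Values are reported at the window start (1-based);
centering is configurable. Charge blocks are maximal constant-sign runs
with |NCPR| ≥ threshold.

## NMR chemical-shift perturbation

Peaks are matched by shared assignment when available; otherwise by
globally optimal nearest-neighbour assignment (Hungarian algorithm) on
the tolerance-normalized ellipse (ΔδH/0.05)² + (ΔδN/0.5)² ≤ 1, each
peak matched at most once. The combined CSP is
Δδ = sqrt(ΔδH² + (0.14·ΔδN)²); the 0.14 nitrogen scaling is the field's
standard glycine-excluded convention and is configurable. Perturbed
residues are called either strictly above the mean CSP over non-proline
assignments (prolines have no amide peak) or above a fixed ppm cutoff;
both rules are implemented because published figures often use "average
CSP ≈ 0.005 ppm" language that is ambiguous between the two. No
published perturbed-peak count is asserted — that requires the
underlying peak data.

## FP binding models

The one-site model solves the exact quadratic mass balance for the
tracer–ligand complex, because at tracer 0.2 µM against sub-µM Kd the
non-depleting hyperbola is visibly biased. The numerically stable
smaller root 2TL/(b + sqrt(b² − 4TL)), b = T + L + Kd, avoids
cancellation. Fitting is weighted least squares over (Kd, FP_min,
FP_max) with multistart over log-spaced Kd guesses; standard errors come
from the fit covariance; a flat curve yields a flagged (non-converged)
fit rather than an exception.

The competitive model couples one tracer J to two mutually exclusive
partners C (Kd₁) and H (Kd₂): Jf·(1 + Cf/Kd₁ + Hf/Kd₂) = Jt with
Cf = Ct/(1 + Jf/Kd₁) and Hf = Ht/(1 + Jf/Kd₂). The residual is monotone
in Jf, so Brent's method on [0, Jt] gives the unique root; mass is
conserved to better than 1e-9 relative. Fitting Kd₂ requires the
free-tracer and competitor-complex plateaus from control curves:
fitting them freely is unidentifiable because the free and
competitor-bound fractions co-vary along the titration. Absent
controls, both are fixed to the zero-titrant baseline (exact at the
start of the titration, approximate insofar as the competitor is
depleted by the tracer). The model-free apparent EC50 (interpolated
half-maximal response) and the Cheng–Prusoff prediction
Kd₂·(1 + [C]/Kd₁) are reported alongside.

At the concentrations of the reported competition experiment (fixed
competitor ≈ 3 µM, Kd₁ ≈ 4.4 µM) the simple competitive model predicts
only a ~1.7-fold apparent-affinity shift, whereas a ≥10-fold shift was
observed experimentally; that gap presumably involves avidity or
oligomeric effects outside this model, so the package surfaces both
numbers and asserts neither. The fixed-competitor concentration
defaults to 3.125 µM (the documented assay value), configurable.

## Synthetic data

Generators derive an independent RNG stream from (seed, stage-name), so
adding a generator never perturbs existing fixtures, and every output is
a pure function of its arguments. Defaults mirror the study designs:
FP titrations use 0.2 µM tracer, two-fold dilutions from 150 µM plus a
zero point, triplicate, additive Gaussian noise σ = 5 mP (no measured σ
is available; 5 mP matches typical triplicate plate-reader scatter);
peak lists draw δH in 6–10 and δN in 100–135 ppm; chains are
self-avoiding (minimum pairwise distance 3.5 Å, fixed 3.8 Å bonds);
ensembles add isotropic Gaussian jitter to a base conformation.

What passing tests do and do not show: planted cross-link tables have
no peptide-level ambiguity, charge-state duplication beyond simple
repeats, or FDR structure, so the table tests validate set logic, not
search-engine behavior; jittered ensembles are not physically relaxed,
so satisfaction tests validate geometry, not conformational realism;
synthetic FP noise is homoscedastic Gaussian, so Kd-recovery results
bound estimator behavior only under that noise model.

## Problem sizes

Test and acceptance runs use desk-scale instances: 40–80-residue
chains, 20–50-model ensembles, ≤50 links, 100-seed FP recovery studies,
1000-trial table-oracle sweeps. These sizes were chosen so the entire
suite completes in well under a minute while still exercising every
code path at the sizes where the brute-force oracles remain exact.

## Known limitations

* Kirkwood Rh ignores bead size and hydration; absolute values are
  systematically low for compact states.
* The collapse model has no secondary-structure or sidechain terms; its
  collapsed coordinates are illustrative, not predictive.
* Competition fitting assumes mutually exclusive 1:1 binding; avidity
  and oligomer effects are out of scope.
* Peak matching assumes fast-exchange (single moving peak per residue);
  slow-exchange doubling is not modeled.
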