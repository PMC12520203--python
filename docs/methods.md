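# Methods

This note documents the models behind `tpscreen`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions used throughout.

## Mass and formula model

All species live in the CHNOClFS element universe — sufficient for both study
drugs and every transformation product (TP) they are known to form. Masses
come from a fixed embedded monoisotopic table (C = 12 exactly,
H 1.00782503, N 14.00307401, O 15.99491462, F 18.99840322, Cl 34.96885268,
S 31.97207117; electron 0.00054858 u) so results cannot drift with library
versions. Positive-mode cation m/z subtracts one electron mass per charge;
the reporting convention rounds m/z half-even to 4 decimals and mass errors
to 1 decimal, matching instrument-software output. Only [M+H]⁺ adducts are
modelled; fine isotope structure within a unit bin (e.g. ¹³C₂ vs ³⁷Cl) is
deliberately not resolved.

## Transformation rules and the TP registry

TiO₂ photocatalysis proceeds mainly by hydroxyl-radical chemistry, so the
elementary rule set is hydroxylation (+O), oxidation (+O−H₂),
dehydrogenation/hydrogenation (∓H₂), and halogen-to-hydroxyl substitution
(−Cl+OH, −F+OH). Ring and side-chain cleavages do not follow a generative
grammar — each is a specific structural event — so they are encoded as
one-shot deltas taken from the curated registry (e.g. loss of the
hydroxyquinolinone moiety −C₉H₉NO₂ for aripiprazole) and may appear at most
once per rule chain. The default chain depth is 4, the minimum needed for
the quadruple hydroxylation product of haloperidol.

The registry ships as editable TSV files. Two masses are listed without a
structural description (haloperidol 378.1696, aripiprazole 319.0960); they
are flagged and excluded from the default registry, which fixes the
canonical counts at 14 formulas / 32 isomers (haloperidol) and 12 / 13
(aripiprazole). One registry entry stores a corrected formula: the
dichlorinated TP at m/z 229.0284 is kept as C₁₀H₁₁Cl₂N₂⁺ (−4.3 ppm), because
the one-nitrogen formula printed for it corresponds to m/z ≈ 215.03 and the
proposed dichlorophenyl-tetrahydropyrazine structure carries two nitrogens;
the original text is preserved in the entry's note field. Similarly, the
reference MSⁿ tables carry a `printed_loss` provenance column for the two
loss brackets whose arithmetic does not close against their precursor
(an H₂ and a C₂ discrepancy); the stored loss formula is the
closure-consistent one implied by the published fragment formulas, and loss
closure (fragment + loss = precursor, exactly) is enforced on load.

## Fragment annotation

Subformula assignment enumerates every element-wise subformula of the
precursor cation (≤ ~3×10⁴ combinations for these precursors), keeps
candidates within the fragment tolerance (default 10 ppm; the screening
tolerance is a separate 50 ppm knob), and ranks by:

1. mass error — optionally relative to a *calibrated reference error*: in
   fragmentation trees the precursor's own observed bias is used, because
   Orbitrap mass errors are dominated by a per-acquisition systematic term
   shared between precursor and fragments;
2. the even-electron rule — candidates whose implied neutral loss contains
   an odd number of odd-valence atoms would require a radical loss and are
   excluded unless radical assignments are explicitly enabled (the one
   documented case is the loss of a chlorine atom from dichlorinated TPs);
3. RDBE plausibility (−0.5 ≤ RDBE ≤ precursor RDBE + 1), then fewer
   heteroatoms removed, then the Hill string as a deterministic tie-break.

MS³ peaks are assigned only against the best assignment of the MS² peak
matching their isolation m/z, which makes formulas nested and losses
telescoping along every root-to-leaf path by construction.

Chlorine count is inferred by comparing the observed M+2/M (and M+4/M)
intensity ratios with the closed-form binomial chlorine pattern
(0.320 per Cl for M+2); the argmin over {0, 1, 2} is returned with its
deviation as a match score. Identification confidence uses the 1–5
nontarget-screening scale: retention time + MS² match to an authentic
standard → 1, diagnostic MS² evidence alone → 3, exact mass with a unique
formula → 4, exact mass only → 5.

A suspect detection requires an EIC apex above
max(absolute threshold, 3 × median EIC level) — the median of a mostly-flat
extracted trace is a robust baseline estimate — plus, whenever the dataset
contains tandem spectra, at least one fragment assignable as a subformula of
the suspect in an MS² scan matching the apex in precursor m/z and retention
time. The MS² gate is what keeps chlorine isotopologues of co-screened
species (³⁷Cl satellites of a TP two mass units below can fall inside a
50 ppm window of another TP) from being counted as detections. Isomers are
lettered A, B, C… in elution order per TP; a shoulder counts only if it is a
distinct local maximum.

## Kinetics

No kinetic law is implied by the data themselves; pseudo-first order is
adopted because it is the standard description of dilute TiO₂ photocatalysis,
and the synthetic generator uses the same law, making parameter recovery a
self-consistency check rather than a model-selection exercise. Presets pin
the rate constants to the reported end points: haloperidol 93.2% removal at
120 min → k = −ln(0.068)/120 ≈ 0.0224 min⁻¹; aripiprazole 10% remaining at
5 min → k ≈ 0.4605 min⁻¹. Fitting is nonlinear least squares on
C₀·exp(−kt) (log-linear start values), which behaves well when late points
approach zero. TP appearance/disappearance uses a two-compartment
(formation/decay) rise-and-fall with a fixed 5:1 rate ratio, parameterized
directly by the time of maximum (10 min for most TPs, 60 min for the two
slow-forming isomers of the m/z 314 product).

## Semi-quantitation

External calibration over 1–750 ng L⁻¹, ordinary least squares. LOD and LOQ
default to 3.3·s_res/slope and 10·s_res/slope; the experimentally determined
limits (haloperidol 0.40/1 ng L⁻¹, aripiprazole 4.5/10 ng L⁻¹) are applied
as fixed overrides when censoring the river batch, since those are the
limits that govern the reported grid. The SPE enrichment factor is computed
from the volumes (500 mL → 500 µL = 1000×) rather than the nominal 2500×
concentration factor, which is inconsistent with those volumes; both are
selectable. Recovery correction (dividing by 0.77 or 0.45) is off by
default because the reported concentrations are not stated to be
recovery-corrected. Parent concentrations below the LOQ are censored to
"n.d."; TP estimates use the parent's curve under the like-parent ionization
assumption, are flagged semi-quantitative, and are *not* censored at the
parent's LOQ — the reported TP levels (0.16–0.47 ng L⁻¹) all sit below it —
but only at a reporting-resolution floor of 0.005 ng L⁻¹ so that true zeros
never surface as rounding noise.

## The synthetic generator

One seeded generator per scenario drives every draw; identical scenario +
seed is byte-identical output. Photocatalysis runs place each species
(parent + every registry isomer) as a Gaussian chromatographic peak
(σ = 0.05 min on a 0.05-min scan grid) at a deterministic retention time —
published anchors are used where they exist (parent retention times, the
18.45-min isomer of the m/z 392 product, whose shoulder isomer is generated
0.2 min later at quarter intensity so the isomer-counting contract is
testable); the rest are spaced programmatically. Per-species mass offsets
are drawn once, uniform within ±5 ppm. Chlorinated species emit M+2/M+4
isotopologues from the exact pattern expansion. MS² (and, for the parents,
MS³) spectra are attached to the 10-minute run — where TP signals are
strongest — using the transcribed reference fragmentation tables for the
parents and a generic small-neutral-loss fragment (water, or HCl for
oxygen-free cations) for TPs, whose full fragment tables are not available.
The river batch maps true concentrations through a linear instrument
response after the enrichment factor; "n.d." cells are generated as true
zeros, which makes censoring tests sharp.

What passing tests therefore show: the *pipeline arithmetic* — formula
logic, tolerance windows, peak picking, isomer counting, tree closure,
calibration algebra, censoring — is correct under controlled conditions.
What they do not show: robustness to real chromatographic tailing,
coelution, matrix suppression, profile-mode peak shapes, or ionization
differences between TPs and parents.

## Numerical conventions and edge cases

Tolerance windows are symmetric and closed (|Δ| ≤ tol). Retention times are
reported to 2 decimals, m/z to 4, mass errors to 1. Peak areas use the
trapezoid between flanking local minima. Constant concentration series fit
k = 0 with a warning; negative back-calculated concentrations are reported
as 0 with a warning and censored. Empty compositions are legal (mass 0) but
cannot form ions. All report serialization is C-locale CSV with '.' decimal
separators.

## Problem sizes

The default fixtures are sized for routine laptop runs: 7 time points ×
~250–300 MS1 scans per run, 33 (haloperidol) or 14 (aripiprazole) species,
500-replicate kinetic recovery simulations, and 1000-draw chlorine-classifier
simulations. The full test suite completes in well under a minute.
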