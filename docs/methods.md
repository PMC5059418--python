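# Methods

## Model

After exhaustive chemical per-acylation, every lysine of a protein carries
either the endogenous acyl group (light) or the reagent-installed
isotope-labeled one (heavy: acetyl-d3, +45.029395 Da; succinyl-d4,
+104.041152 Da). The site occupancy θ is estimated as the intensity fraction
L/(L+H). Quantification is done at the fragment level: for a target site,
the differentiating b/y ions — those whose residue span contains the site —
are enumerated, their light and heavy m/z computed, and extracted ion
chromatograms (XICs) pulled from the MS2 scans of the single SWATH isolation
window in which both precursor forms were sampled. Peak areas are trapezoidal
integrals over the target's retention-time borders. Per fragment the ratio
L/(L+H) is formed; the site value is the median over passing fragments, with
the rank-1 fragment (largest light+heavy area) reported alongside.

Assumptions inherited from the labeling chemistry: the light and heavy forms
co-elute (deuterium RT shifts are not modeled), ionize identically, and every
lysine is either endogenously acylated or chemically labeled. Sites carrying
other modifications (methylation, ubiquitination) are invisible to both
channels and bias θ upward slightly.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `ppm_tol` | 20 ppm | XIC extraction half-width; suits ~15k MS2 resolution. |
| `min_heavy_area` | 1000 intensity·min | minimum-area filter. Heavy is tested first; if it fails, the light area is tested against the same threshold, so near-saturated sites (heavy ≈ 0) are not discarded. A fragment passes if either channel clears it. |
| fragment charges | 1+ | higher charges configurable. |
| missed cleavages | 2 (target building) | Glu-C digestion (cleavage C-terminal to E and D). |
| median rule | lower central value at even counts | determinism. |

Rank-1 is defined by the largest light+heavy summed area among passing
fragments. Spectral-library intensity ranking would be the natural choice
when a library exists, but identification is out of scope here; summed area
is the proxy for "best ion statistics", and a user-supplied ranking can be
substituted by sorting the fragment table externally.

## Multi-lysine peptides

Mixed label permutations (LH/HL) of a multi-lysine peptide share precursor
m/z and are unresolvable at MS1. At the fragment level, the strict
differentiating set of the first lysine is a pure b-ion run (fragments
containing that site and no other) and that of the last lysine a pure y-ion
run; each run measures its site's marginal occupancy directly, regardless of
the other site's state. For three-lysine peptides the middle site has no
strict set; it is estimated in *extended mode*: every fragment containing ≥2
sites produces a label-count ladder (rungs spaced by the label delta), whose
expected rung fractions under independent per-site Bernoulli label states
are a polynomial in the site occupancies. With the flanking occupancies
fixed from their b-/y-runs, the middle occupancy is fit by bounded scalar
least squares (tolerance 1e-10). Results carry an "extended-mode" QC note:
the independence assumption is a modeling choice, exact in the simulator and
plausible but unverifiable in real data.

## Window schemes and co-isolation

Isolation windows overlap by ~1 m/z (vendor convention); the scheme
de-overlaps neighbours by splitting the overlap equally and assigns
precursors to half-open effective intervals, boundary values to the
higher-index window. Quantification requires the light and heavy precursors
(all label permutations, for multi-site peptides) to co-isolate in one
window; pairs that straddle an effective boundary are flagged and left
unquantified rather than merged across windows. The bundled default is a
64-window variable-width scheme over m/z 400–1250 (widths 5–89, dense
mid-range).

## The simulator

`simulate` writes standard mzML (centroid sticks, 64-bit float arrays) on a
3.2 s cycle grid: one MS1 scan plus the MS2 windows per cycle. Per peptide it
enumerates label species from the chemistry: a site is light with probability
θ; otherwise labeled with completeness c (default 1.0; residual unlabeled
lysines are a chemistry-side failure mode exposed for study); a labeled site
is truly heavy with reagent purity p — with probability 1−p it is
mass-identical to light. Species weights therefore give an expected apparent
occupancy of θ + (1−θ)·c·(1−p), i.e. a floor of 1−p at θ=0 (2% for
succinyl-d4 at p=0.98, 1% for acetyl-d6 at p=0.99), which the pipeline
reproduces and which is why reported occupancies are upper limits. An
optional purity correction is deliberately not applied by default.

MS1 envelopes use a 4-isotope averagine-style Poisson approximation (rate
5.3e-4 per Da). This is enough to exercise the known isotope-overlap issue:
at charge 2 the light M+3 peak (3.0101 Da) falls ~10 ppm from the heavy
acetyl monoisotope (3.0188 Da) and bleeds into the heavy MS1 channel at the
default 20 ppm tolerance. No isotope-overlap deconvolution is performed —
MS1 values are comparison values, not the estimator.

Elution is Gaussian in RT (default sd 0.08 min, ~5 s); fragment relative
intensities default to a smooth index-dependent profile and are
user-settable. Noise, when enabled, is Poisson shot noise on every stick;
interferences are injected as Gaussian-eluting sticks at arbitrary m/z in
MS1 or a chosen MS2 window. All randomness comes from the scenario seed; the
ground-truth JSON written beside the mzML contains species weights, windows,
elution parameters and the cycle grid, sufficient to recompute every
expected area in closed form.

What the simulator does **not** emulate: chromatographic drift between runs,
profile-mode peak shapes, deuterium RT shifts, correlated (non-Poisson)
noise, and real interference structure. Passing tests therefore demonstrate
the correctness and calibration of the algorithm under its stated model, not
performance on any particular instrument's data.

## Problem sizes used in the test-suite

Simulated studies use panels of 10–24 peptides per run, a single run per
condition/seed (5 seeds for purity-floor means, one 24-peptide run across six
occupancy levels from 0.005 to 0.923, and an 18-peptide panel per dilution
level for the mixture series) — sizes chosen to give stable means at Poisson
noise levels comparable to the benchmark experiments while keeping each run
to a few thousand spectra.

## Degenerate inputs and tie-breaks

- Fragments where both channels fail the area threshold get no ratio; a site
  with no passing fragments is reported empty with a QC note.
- Empty RT-range XICs are flagged, not errors; peak integration over fewer
  than two points returns area 0 with a low-points flag.
- Boundary m/z assignment is upper-exclusive, deterministic.
- Peptides whose precursor falls outside the window scheme are excluded from
  simulation output and recorded in the ground truth.

## Known limitations

- No cross-run normalization, RT alignment, or protein-level rollup.
- Light/heavy co-elution is assumed; deuterium isotope effects on RT are not
  corrected.
- Extended-mode middle-site estimates rest on the label-independence
  assumption.
- MS1 occupancies are uncorrected for isotope overlap and are reported only
  for single-lysine targets.
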