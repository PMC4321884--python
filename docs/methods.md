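# Methods

## Statistical model

Observed and calculated structure-factor amplitudes are compared on the
normalized (E-value) scale: `E = |F| / sqrt(eps * <I/eps>_bin)`, with
epsilon the symmetry multiplicity factor and `<I/eps>` the mean
epsilon-corrected intensity of the amplitude set in its resolution bin
(equal-count bins on s² = 1/d², default 20 bins of at least 50
reflections). Each amplitude set — observed or calculated — is normalized
against its own bin means, so overall scale and any uniform isotropic B
offset cancel by construction.

Conditional on the model, an acentric observed E follows a Rice density
with mean parameter `sigmaA * E_c` and variance `1 − sigmaA²`; a centric
one follows the corresponding Woolfson (folded-normal) density. The
resolution-dependent correlation is the Luzzati form

    sigmaA(s) = sqrt(f_p) * exp(−2 π² s² vrms² / 3)

with `f_p` the modeled fraction of asymmetric-unit scattering (ratio of
occupancy-weighted sums of squared electron counts) and `vrms` the
effective 3-D rms coordinate error. The LLG subtracts the Wilson
log-density at every reflection, so a model with sigmaA → 0 scores exactly
0. The damping term is identical to a Debye–Waller factor with
ΔB = (8π²/3)·vrms²; the acceptance suite verifies this equivalence through
the structure-factor route to 1e−6 relative.

Measurement sigmas are read but do not enter the likelihood: synthetic
data controls the noise level explicitly, and the amplitude-only model
keeps the null exactly calibrated. Epsilon factors enter only through
normalization.

A model whose bounded vrms optimum still scores below the Wilson null is
treated as information-free: the sigmaA family contains the null as the
vrms → ∞ limit, which the bounded search cannot reach, so the refinement
reports LLG = 0 at the upper vrms bound. Without this closure, a model
annihilated by extreme B inflation (e.g. template B values misread as
errors in Å) would receive a large spurious negative score driven by its
low-resolution reflections.

## Error-to-B weighting

Per-residue error estimates |Δr| (absolute scale, Å) are converted to B
increments ΔB = (8π²/3)|Δr|² added onto a baseline B (default: the Wilson
B of the observed data, fallback 20 Å²; cumulative evaluations pin it to
the constant-scheme value 20 Å² so the rms and constant schemes differ
only through B *differences*). The comparison variant `rms_no3` omits the
factor of 3. Four schemes are supported: `original`, `rms`, `rms_no3`,
`constant`. All applied B values are clamped to ≥ 2 Å². Residue-level
estimates broadcast to all atoms of the residue. No scale-factor search
over submitted estimates is performed (a config hook exists, off by
default).

## Scoring protocol

1. Analyze the target ASU once: reference chain (most atoms), transforms
   onto every additional copy (Kabsch on CA pairs, pairing by residue
   number), residues with inter-copy CA deviation > 3 Å excluded from the
   trim selection, non-matching chains stored as unpredicted extra
   components.
2. Superpose the prediction on the reference chain (≥ 3 CA pairs;
   superposition rmsd > 10 Å flags the score invalid — outside the
   convergence radius of refinement).
3. Trim to the selection, apply the B scheme, reconstitute all copies plus
   extras.
4. Structure factors by direct summation over atoms and space-group
   operators (supported groups: P1, P2₁, P2₁2₁2₁), IT92 4-Gaussian form
   factors for H/C/N/O/S/P with electron-count fallback, Debye–Waller
   exp(−B s²/4).
5. Refine: per-chain rigid body (axis-angle rotation about the chain
   centroid, bound ±5°; translation bound ±3 Å; L-BFGS-B with numeric
   gradients on a resolution-stratified subsample of ≤ 1200 reflections —
   reported LLG always uses the full set), alternating with bounded 1-D
   vrms refinement (bounds [0.01, 3] Å, restarts from 0.4/0.8/1.5 Å) and
   overall-B refinement, until the full-set LLG improves by < 0.01 or 10
   cycles. The LLG never decreases across cycles.

The multi-start vrms policy exists because the LLG-vs-vrms surface is
occasionally multimodal; disagreement > 1% relative between polished
restarts sets `converged = False` rather than silently keeping a minor
maximum.

Overall-B refinement is near-degenerate by design: per-bin normalization
absorbs any uniform B change (the same fact that makes the error-weighting
scheme sensitive only to B differences). It is implemented against bin
means held fixed from the starting model, detects a flat surface (LLG
range < 0.5 across the bounds) and then returns 0 with `converged = False`.

GDT_TS uses a simplified LGA-style search: superpositions seeded from
every contiguous 3/5/7-residue window plus the global Kabsch fit, each
refined by re-superposing on the atoms currently inside the cutoff, the
fraction within {1, 2, 4, 8} Å maximized per cutoff and averaged.
This is an approximation to the full LGA optimization, adequate for the
qualitative LLG–GDT_TS comparisons made here.

## Cumulative evaluation

Per target and B scheme, structure Z scores use the mean and *population*
standard deviation over all valid records of that target; a zero standard
deviation yields Z = 0 for every structure. Per-predictor Z is the mean
over that predictor's structures. The improvement score of a predictor is
the mean over attempted targets of
`(LLG_best − LLG_baseline) / (LLG_baseline − LLG_unpredicted)`; targets
with a zero denominator are excluded with a warning, and skipped targets
simply do not contribute. The best-scheme census breaks exact LLG ties by
the fixed precedence original > rms > constant > rms_no3.

A predictor is flagged as submitting genuine error estimates when its mean
Z under the rms scheme exceeds the better of the original and constant
schemes by ≥ 0.1 and it was scored on ≥ 4 targets (both configurable).
The Z-gap statistic measures *relative standing*, so it is meaningful when
the per-target score distributions are comparable across schemes — i.e.
when the bulk of the corpus is unaffected by the scheme change. The
default synthetic corpus is built that way (see below); with a handful of
predictors whose records collapse or explode under one scheme, the
standardization itself shifts and the gap conflates corpus composition
with estimate quality.

## Synthetic data

`make_target` builds poly-alanine-like backbones (N, CA, C, O per residue)
along self-avoiding smoothed random walks with helix-like straight
segments, biased toward a compact globule (radius ≈ 3.2·n^{1/3} Å);
per-residue B factors U[10, 40] Å²; the unit cell is grown until all
symmetry and lattice images are ≥ 2 Å apart. Amplitudes are complete to
d_min with optional multiplicative Gaussian noise (default 3% in
benchmarks) — simple, scale-free, and sufficient for LLG behavior, unlike
counting statistics it does not couple noise to intensity.

Error profiles specify the per-residue **1-D per-coordinate** sd σ; the
3-D relation is <|Δr|²> = 3σ², so an honest predictor writes σ·√3 into
the B column. Keeping the two conventions explicit matters because
conflating them is exactly the factor-of-3 pitfall the `rms`/`rms_no3`
pair probes. Predictions are derived from the target by per-atom Gaussian
displacement, optional residue deletion (completeness), and one of four
B-column behaviors: honest, scaled-by-k (miscalibrated), zeros, or
template-B carryover.

The default 11-predictor benchmark corpus mirrors the evaluation
situation the detection heuristic targets: two honest submitters and one
mildly miscalibrated one sit *inside* the quality range of a bulk of
eight zeros-submitters, and the single template-B archetype is
structurally poor, so its collapse under the rms scheme stays within the
bulk's range. Benchmarks default to 40–80-residue targets in P1 and
P2₁2₁2₁ at d_min 2.0–2.9 Å — sizes chosen so that full multi-seed studies
run in minutes on one CPU while leaving thousands of reflections per
target.

What passing tests on this generator do *not* show: real diffraction data
carry bulk solvent, anisotropy, measurement-error structure and lattice
imperfections that the forward model here omits; real predictions have
correlated, non-Gaussian errors and alignment ambiguities. Absolute LLG
values are therefore not comparable to production MR software; the package
tests the *mechanisms* (weighting, refinement, cumulative scoring) under
known ground truth.

## Numerical choices

- log I₀ via the exponentially scaled Bessel function (`i0e`), log cosh
  via |x| − log 2 + log1p(exp(−2|x|)): stable for arbitrarily large
  arguments.
- Wilson null computed analytically from the same E-values, making LLG
  exactly 0 at sigmaA = 0.
- Kabsch superposition by SVD with the determinant sign fixed to +1.
- Optimizers: scipy L-BFGS-B (bounded, numeric gradients) for vrms and
  rigid body; bounded Brent for overall B. Convergence: ΔLLG < 0.01, ≤ 10
  outer cycles.
- Reflection reduction maps every index to a canonical reciprocal-ASU
  representative (Friedel mates merged by averaging); systematic absences
  are dropped; epsilon and centric flags come from the space-group
  operators and are cross-checked against a brute-force operator loop in
  the tests.
- Degenerate inputs: empty models, empty selections, negative amplitudes
  or B values, occupancies outside [0, 1] and unsupported space groups are
  rejected with typed errors; zero-occupancy atoms and hydrogens are
  dropped on input; alternate locations keep the first conformer.

## Known limitations

- Direct summation scales as atoms × reflections; fine at desk scale,
  wrong tool beyond ~10⁴ atoms.
- No bulk-solvent or anisotropic scaling; low-resolution terms are
  therefore systematically imperfect for real data.
- The three supported space groups cover the synthetic benchmarks, not
  the full crystallographic zoo.
- Overall-B refinement carries no information under self-consistent
  normalization (by design); the parameter is retained for completeness
  and for fixed-bin workflows.
- GDT_TS is a window-seeded approximation, not full LGA.
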