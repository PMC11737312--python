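# Methods

## Bite-force model

The jaw is modelled as a static third-class lever in two dimensions, viewed
laterally, with the base of the quadratojugal–quadrate complex as the
fulcrum and the fulcrum–rhamphotheca line as the angular reference. Cranial
kinesis and dynamic effects are outside the model. Per muscle, the chain is
volume = mass/density, thickness = volume/area, fascicle length =
thickness/sin 45°, PCSA = m·cos θ/(ρ·l), force = tetanic stress × PCSA,
torque = mean moment arm × force × sin(line-of-action angle). Adductor
torques are summed, divided by the out-lever and doubled for bilateral
symmetry. The depressor mandibulae (the jaw opener) is carried through the
chain for reporting but never contributes to the closing force.

Because the fascicle length is derived from the same mass, mass and density
cancel: PCSA = corrected area × sin 45° × cos θ. The implementation keeps
the full chain (each intermediate is reported per muscle) and the test
suite asserts the reduction to < 10⁻¹² relative error. A consequence worth
knowing: with this estimator, bite force is set entirely by areas, angles
and lever arms; wet masses affect only the reported volumes and fascicle
lengths.

### Constants and switches

| parameter | default | units | rationale |
|---|---|---|---|
| muscle density ρ | 1.06×10⁻³ | g/mm³ | standard wet-muscle density (1.06 g/cm³). One published equation prints "1060 g/mm³", a unit typo; the prose value 1.06 mg/mm³ is adopted. |
| tetanic stress σ | 0.3 | N/mm² | common estimate of maximal isometric muscle stress |
| fascicle angle | π/4 | rad | fascicles observed rising from the bone at ~45° rather than projecting normally |
| bilateral factor | 2 | – | whole-jaw force from one-side dissections; set 1 to report a single side |
| area_scale_power | 2 | – | the lens-compression correction is a *linear* landmark ratio; areas are corrected by its square for dimensional consistency. The published account does not state the power; 1 is available as a switch. |
| pennation angle | 0 | rad | required input column; per-muscle values (from µCT literature) are not tabulated, so the neutral cos θ = 1 is the default and sensitivity to ±15° is a user-side diagnostic, not a hidden constant |

Angles are radians internally; CSV files carry degrees (`*_deg` columns)
and are converted at the I/O boundary. When both head sides were dissected,
per-muscle masses should be averaged into a single `side = mean` specimen
before modelling; the bilateral ×2 then restores the whole jaw. When a
muscle's area is a bony proxy (palatine bone for the m. pterygoideus
dorsalis), the chain proceeds unchanged and the output row is flagged
`area_is_proxy` so reports can annotate the approximation. The geometric
construction of the three moment arms from photographs is upstream of this
package; the three lengths are consumed as given, and the scale factor is
applied to areas only (whether published values also corrected moment arms
is unstated).

## Phylogenetic regression

Traits are log₁₀-transformed; rows with missing optional fields are dropped
per relationship. Residual covariance follows Brownian motion on the tree:
C[i,j] is the shared root-to-MRCA branch length, and Pagel's λ multiplies
the off-diagonals, V(λ) = λ(C − diag C) + diag C. λ is profiled by maximum
likelihood on [0, 1] (bounded scalar search, boundary candidates checked
explicitly). GLS is solved by Cholesky whitening; coefficient SEs use the
df-corrected residual variance and two-sided t tests with df = n − 2 (no
multiple-testing correction, matching the published analyses). Two R² values
are reported: the OLS-style 1 − SSE/SST on raw residuals and a generalized
R² measured in the V-metric against the GLS intercept-only model, because
the convention used for the published R² is not stated.

Note on λ semantics: the published analysis defines λ as a variance-components ratio
from a Bayesian mixed model; here λ is the branch-length transform in a
frequentist GLS — the standard ML analogue with the same endpoints (0 = no
signal in residuals, 1 = fully Brownian) but not numerically identical in
finite samples.

Isometric expectations are held explicitly: a force scales as mass^0.66 and
as length² under geometric similarity. The published body-mass isometry
statistic (t₁₈ = 0.632 against slope 0.978, SE 0.087) is inconsistent with
its own slope/SE pair ((0.978 − 0.66)/0.087 = 3.66) and is therefore not
used as a check.

### Method-comparison ANCOVA

The comparison of calculated vs transducer-measured bite forces is a GLS
ANCOVA with Pagel's λ: full model `log BF ~ log BM × method`; if the
interaction is not significant at α = 0.05 the model is refit additively
and the method main effect is tested. Species present under both methods
contribute two rows whose mutual covariance is the species' full depth
scaled by λ, so the (1 − λ) share is an independent residual per row; λ is
consequently bounded at 1 − 10⁻⁶ because λ = 1 makes duplicated rows
exactly collinear. This maximum-likelihood formulation replaces a Bayesian
MCMC mixed model (reported settings: 500 000 iterations, thinning 500,
burn-in 10 000); it targets the same estimand — a method offset controlling
for mass and phylogeny — while being deterministic and directly testable.
On the packaged tables (19 calculated + 9 measured species, simulated
unit-depth tree), the interaction is non-significant, λ̂ ≈ 0 and the method
effect is +0.10 log₁₀ units with p ≈ 0.11: no significant method effect,
independent of the tree seed because λ̂ ≈ 0 removes the tree from the fit.

## Scar power law

Bite force vs adductor-scar length is fit on log₁₀-log₁₀ axes (OLS when no
tree is supplied; the published relationship has λ < 0.001). The power-law
coefficient is the back-transformed intercept: 10^(−0.026) = 0.94. The
published table labels this row "Loge", but e^(−0.026) = 0.974 ≠ 0.94, so the
natural-log label is treated as a typo and base 10 used throughout. The
species-level scar lengths behind the published fit are not tabulated, so
the fitting path is exercised on synthetic and round-trip data anchored by
the printed (intercept, slope) pair. Prediction intervals from the fit's
residual variance are provided as an extra diagnostic of this
implementation; the published analysis reports none.

## Synthetic data

The generator emulates the study's data structure: a Yule tree rescaled to
unit depth (pure-birth waiting times, uniform lineage choice, a terminal
exponential stretch so no pendant edge is zero); Brownian log₁₀ body mass
(root 2.3 log₁₀ g, rate 0.3 per unit depth, spanning roughly the 29–1254 g
study range); and per-trait allometric rules (intercept, slope, residual
sd) fit once by OLS against the packaged 19-species table — skull mass
(−2.106, 1.137, 0.11), skull length (0.892, 0.364, 0.03), jaw muscle mass
(−2.570, 1.133, 0.16), bite force (−0.403, 0.929, 0.14), scar length
derived by pushing the bite-force rule through the inverse scar law. The
default study size is 19 species, matching the dissection sample.

Dissection tables are built by inverting the lever model: the six-muscle
profile (depressor plus five adductors, ethmomandibularis and adductor
mandibulae externus carrying the largest shares) allocates masses, angles
and moment-arm fractions of skull length, and a single joint area scale is
solved so the forward model reproduces the species' bite force exactly.
Optional measurement noise is log-normal on masses and areas and truncated
normal on angles — multiplicative error as a measurement process would
produce. Defaults are noise-free, so forward/backward consistency holds to
machine precision; the "measured" generator adds a method offset δ and
log-scale noise (δ = 0 is the no-method-effect scenario the published
comparison found). The generator makes no attempt to mimic the real parrot
topology, lens distortion beyond the scalar factor, or intraspecific
variation: passing tests demonstrate internal consistency and statistical
calibration of the estimators, not fidelity to any particular dissection.

## Numerical choices and problem sizes

GLS via Cholesky with an explicit condition-number report on failure; λ
search tolerance 10⁻⁸; ML (not REML) likelihood for λ, so variance
estimates carry the usual small-sample ML bias while slopes are unaffected.
Statistical calibration is checked at study-like scales chosen for tight
Monte-Carlo error: slope unbiasedness over 500 Brownian replicates on
50-tip trees (|mean bias| < 0.02), ANCOVA type-I error over 500 null
replicates at 30 species (observed ≤ 0.08 at nominal 0.05) and power over
200 replicates at δ = 0.2 (≥ 0.8). Degenerate inputs (zero areas, zero
reference distances, out-lever ≤ 0, trees without branch lengths,
single-level factors) raise typed errors rather than propagating NaNs; a
specimen without adductors returns 0 N with an explicit warning record.

## Known limitations

- The published jaw-muscle-mass regression (slope 0.715, intercept 1.538)
  is not recoverable from the published species means, which give
  0.778/1.720 — the published fit evidently used adductor-only mass sums that are not
  tabulated. The package reports what the packaged data yield.
- Two printed bite-force:body-mass ratios are internally inconsistent with
  their own table rows (Psittacula eupatria, and Psittacus erithacus at the
  last decimal); recomputation flags them.
- λ is a point estimate; no profile intervals are reported for it.
- The lever model is 2D and static; gape-angle effects, cranial kinesis and
  muscle-force–length dynamics are out of scope.
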