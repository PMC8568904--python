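# Methods

## Model

Each cortical parcel is reduced to one population state, the average
synaptic gating fraction `S_i ∈ [0, 1]`, obeying

    dS_i/dt = −S_i/τ_s + r (1 − S_i) H(x_i) + σ_i ν_i(t)
    H(x)    = (a x − b) / (1 − exp(−d (a x − b)))
    x_i     = w_i J S_i + G J Σ_j C_ij S_j + I_i

with `ν_i` uncorrelated standard Gaussian white noise. The transfer
function `H` maps total input current (nA) to population firing rate
(Hz); it is strictly positive, strictly increasing, continuous at the
removable singularity `a x = b` (value `1/d`), and asymptotically linear
(`H → a x − b`, with relative gap `exp(−d(ax−b))`, about 1e−4 at
`ax−b = 60`). Fixed circuit constants: `J = 0.2609 nA`, `a = 270 n/C`,
`b = 108 Hz`, `d = 0.154 s`, `r = 0.641`, `τ_s = 0.1 s`.

The *parametric* variant ties the regional parameters to two cortical
gradient maps (a T1w/T2w-like myelin map `Mye` and a principal
FC-gradient-like map `Grad`, both z-scored across regions):

    w_i = a_w Mye_i + b_w Grad_i + c_w      (likewise I_i and σ_i)

leaving 10 free quantities: the nine linear coefficients plus the global
coupling `G`. The unconstrained heterogeneous variant (every `w_i`,
`I_i`, `σ_i` free plus `G`) has `3N + 1` free parameters — 205 at
`N = 68`.

## Hemodynamics

Gating activity drives the nonlinear balloon–windkessel model per
region: vasodilatory signal `ṡ = z − κ s − γ (f − 1)`, inflow `ḟ = s`,
volume `τ v̇ = f − v^{1/α}`, deoxyhemoglobin
`τ q̇ = f E(f, ρ)/ρ − v^{1/α} q / v` with `E(f, ρ) = 1 − (1 − ρ)^{1/f}`,
and BOLD read-out `y = V₀ (k₁ (1 − q) + k₂ (1 − q/v) + k₃ (1 − v))`.
Constants: `κ = 0.65 s⁻¹`, `γ = 0.41 s⁻¹`, `τ = 0.98 s`, `α = 0.32`,
`ρ = 0.34`, `V₀ = 0.02`, and 3 T read-out coefficients `k₁ = 3.72`,
`k₂ = 0.527`, `k₃ = 0.53`. The resting state (`s = 0, f = v = q = 1`)
gives exactly zero BOLD, so simulated signals are baseline-relative.
All constants are exposed on `HemodynamicConstants` and can be swapped.

## Integration protocol

Euler–Maruyama with `dt = 10 ms` and the SDE-consistent `√dt` noise
scaling: `S ← clip(S + dt·drift + σ √dt ξ, 0, 1)`. Clamping is needed
because `S` is a fraction and Euler steps can overshoot; with the
default noise levels clamp events are rare. Initial states are
`Uniform(0, 1)` per region from the run seed. Hemodynamics are
integrated with Euler at the same `dt` from rest. Default run length is
16.4 min; the first 2 min of BOLD are discarded and the remainder is
sampled instantaneously at every TR boundary (`TR = 0.72 s`,
`72 = TR/dt` steps per frame), yielding 1200 frames. Halving `dt`
changes the deterministic terminal state by < 1e−4. Both integrator
loops are JIT-compiled (numba) with noise pre-drawn outside the kernel,
so results are bit-reproducible for a fixed seed regardless of the
compilation path.

## Observables

- **Static FC**: Pearson correlations of the full-run regional BOLD.
- **FCD**: per-window FC over 83-frame sliding windows (59.76 s at
  TR 0.72 s), stride 1; window FCs vectorized over the strictly-upper
  triangle; FCD = correlations between those vectors. A 1200-frame run
  gives 1118 windows.
- **FCD-entry distribution**: 200 uniform bins on [−1, 1], normalized to
  unit mass. Distributions from different runs are averaged bin-wise
  (FCD matrices themselves cannot be averaged across runs — there is no
  temporal correspondence).
- **Cost**: `w_fc (1 − r) + w_fcd KS`, default weights 1, where `r` is
  the Pearson correlation of Fisher z-transformed upper-triangle FC
  entries and `KS` the Kolmogorov–Smirnov sup-distance between FCD-entry
  distributions (ECDFs for raw samples, cumulative sums at bin edges for
  binned ones; the implementation agrees exactly with a brute-force
  ECDF oracle).
- **FCD mean time course**: row means of the FCD matrix, excluding the
  diagonal self-correlation (a constant +1 bias; switchable).
- **SW-STD**: per-region, per-window population (÷n) standard deviation
  of the BOLD signal, on the same windowing as the FCD.
- **State classification**: a two-component Gaussian mixture (EM,
  seeded, 5 restarts) on the FCD-mean histogram; the threshold is the
  crossing point of the weighted component densities between the two
  means (the quadratic in `x` solved in closed form); if no crossing
  lies between the means, their midpoint is used and a warning logged.
  Windows above threshold are *coherent*, below *incoherent*; dwell
  times are maximal constant-label run lengths.
- **FCD-STD coupling map**: per region, the Pearson correlation between
  the forward-differenced FCD mean and forward-differenced SW-STD time
  courses. The permutation null re-pairs FCD-mean and SW-STD series
  across runs, averages per region, and uses the add-one estimator
  `p = (1 + #{null ≥ obs}) / (1 + n_perm)` with Benjamini–Hochberg FDR
  across regions.

## Fitting

The 10 coefficients are estimated by CMA-ES against a target FC and a
target FCD-entry distribution. The optimizer is a self-contained
(μ/μ_w, λ) CMA-ES with cumulative step-size adaptation and rank-one plus
rank-μ covariance updates (standard weights, learning rates and
damping); box constraints are enforced by projecting candidates onto
the feasible box. Defaults: population `4 + ⌊3 ln n⌋`, initial step 0.2
of each bound range, random initial mean per restart. Every evaluated
candidate is logged with its training cost.

Candidate evaluation runs a small number of simulations (default 3)
under a fixed seed schedule shared across candidates (common random
numbers, for ranking stability), averages the FCs entry-wise and the
FCD distributions bin-wise, and returns `(r, KS, cost)`. Coefficients
producing any `w_i ≤ 0` or `σ_i ≤ 0`, and runs that diverge, receive
the sentinel cost 3.0 (the cost's upper bound at default weights).

Selection follows the train/validation protocol: candidates are
re-scored on validation targets and picked greedily by ascending
validation cost, skipping any candidate whose concatenated z-scored
(w, I, σ) regional maps correlate at ≥ 0.98 with an already selected
one. Search bounds default to regional values `w ∈ (0, 10)`,
`I ∈ (0, 1)`, `σ ∈ (0.0005, 0.05)`, `G ∈ (0, 8)` (offsets span the
range, slopes half the range); the scaled-down recovery experiment uses
physiological subranges (`w (0.3, 3)`, `I (0.2, 0.5)`, `G (0, 2)`) —
with the full box, its ~2000-evaluation budget cannot locate the
well-fitting region at all.

## Perturbation experiment

Within a simulated run, maximal windows-below-threshold segments of the
FCD mean are located. At the midpoint of the longest qualifying segment
the gating variables of the target regions are pushed for 72 integrator
steps (one TR): `S ← S + 0.8 (S_max − S)` if the region's gating is at
or below the midpoint of `[S_min, S_max]`, else `S ← S − 0.8 (S −
S_min)`, where the extremes are taken over all regions within the
segment. The run then continues with the *same* pre-drawn noise as the
unperturbed baseline, so a zero-strength perturbation reproduces the
baseline bit-exactly. The effect is measured counterfactually: the mean
FCD mean over every window that samples frames at or after the
perturbation onset, perturbed run minus baseline run. This isolates the
causal effect cleanly; measuring "before vs after" within the perturbed
run alone conflates the effect with the segment's own drift and dilutes
the roughly one-window-scale transient.

## Spatial statistics

Marker contrasts (e.g. a PVALB−SST analogue) are differences of
per-gene z-scored expression profiles. The spin test draws uniform
random 3-D rotations (QR of a Gaussian matrix, sign-fixed, determinant
+1), rotates the parcel centroids on the unit sphere, reassigns each
region the value of the nearest rotated centroid, and recomputes the
correlation; `p` is two-sided with the add-one estimator. Because
rotation is a relabelling, the null preserves the map's value multiset,
and for spatially smooth maps the spin p exceeds a naive shuffle p (the
autocorrelation correction). Synthetic centroids live on a single
sphere; mirrored two-hemisphere rotation for real cortical data is out
of scope. The expression PC1 map is the leading right singular vector
of the gene-standardized expression matrix, sign-fixed intrinsically
(largest-magnitude score positive) so relabelling or globally negating
the data leaves it unchanged.

## Synthetic data

The generators emulate the *structure* of the empirical inputs, not
their content: connectomes are random symmetric graphs (spanning tree
plus uniform fill to the requested density) with heavy-tailed
log-normal weights normalized to maximum 1; gradient maps are smooth
1-D Gaussian-process profiles, z-scored, with a prescribed mutual
correlation (default 0.4); expression tables carry a planted rank-1
smooth spatial factor plus noise with two designated anchor genes of
strong opposite loading; centroids are a Fibonacci lattice on the
sphere. Group-consensus structural connectivity zeroes entries nonzero
in fewer than half the subjects (a tie at exactly half survives) and
averages surviving entries over the nonzero subjects only; the rule is
idempotent. None of this reproduces cortical geometry, hemispheric
structure, or the empirical degree/weight statistics of tractography —
passing tests show the algorithms behave correctly, not that the brain
does.

Two reference operating points are shipped:

- **Switching fixture** (`multistable_coefficients`, 68 regions,
  `w = 1`, `σ ≈ 0.15`, `G = 0.5`, intercept calibrated by
  `calibrate_multistable_intercept`): at `w = 1` the single node sits
  near the cusp of its bistable wedge, so regions whose connectome row
  strength places their total input inside the narrow fold
  neighbourhood hop stochastically between a low and a high branch, and
  coupling ripples the transitions network-wide. Epochs with drivers in
  the high branch have coherent, high-amplitude BOLD (high FCD mean);
  quiescent epochs are incoherent. The intercept scan is needed because
  the fold neighbourhood is narrow compared with connectome-to-
  connectome variation. The fixture's noise amplitude (≈0.15 nA)
  deliberately exceeds the default fitting search range: at σ ≤ 0.05
  the escape time from either branch exceeds the run length everywhere
  except a knife-edge (< 0.001 nA wide) in the input — robust switching
  inside that range does not exist in this model, which is itself an
  informative property of the dynamics. The perturbation census on this
  fixture uses segment length ≥ 100 windows and a mixture-crossover
  incoherence threshold (≈ 0.2) because its coherent epochs are weaker
  and shorter than those of human recordings (where 0.6 / 200 TRs are
  appropriate).

- **Recovery fixture** (`recovery_coefficients`, 10 regions): the
  coupling places the network's intermediate-activity operating point
  just below the edge of linear instability (drift-Jacobian spectral
  abscissa ≈ −2 s⁻¹, found by `tune_coupling_to_edge` via noiseless
  relaxation plus eigenanalysis). The resulting slow collective modes
  give 2-minute BOLD runs strong, reproducible FC structure; away from
  the edge the model's BOLD-band correlations are too weak for
  inversion at that run length (run-to-run FC reliability ≈ 0.05). The
  external-input gradient is deliberately the strongest of the three:
  it anchors regional operating points and suppresses (though does not
  eliminate) a mirror-image degeneracy in which a sign-flipped σ map
  with compensating w adjustments reproduces both observables almost
  exactly.

## Identifiability

At the desk scale used in the recovery experiment (10 regions, 2-minute
runs, 3 simulations per cost evaluation, ≤ 64 generations × 2 restarts)
the `w` and `I` maps are usually recovered well (correlations ≳ 0.9 in
most runs), but the σ map's direction is only weakly identified: sign-flipped σ
solutions with compensating adjustments can match the target FC and
FCD distributions to within the evaluation noise floor, and which
valley the optimizer settles in depends on its seed. Cleaner targets
(30 simulations), per-candidate randomized evaluation seeds, and
high-precision final re-scoring all leave this ambiguity in place, so
it is a property of the cost function at this problem size, not of the
optimizer. Model degeneracy of exactly this kind — distinct regional
parameter maps producing near-identical observables — is a recognized
feature of connectome-coupled mean-field models, and the recovery
experiment reports the signed σ-map correlation rather than hiding it.

## Problem sizes and numerics

Test and acceptance protocols use 10-region systems for fitting (2-min
BOLD, 43-frame windows, ~2000 cost evaluations, 12-simulation final
re-scoring) and the 68-region switching fixture for multi-stability and
perturbation (full 16.4-min runs, 83-frame windows, 40 paired
perturbation trials, 12-run FCD-STD maps) — sizes chosen so each
protocol completes in minutes while keeping every qualitative property
of the full-scale analyses. Numerical conventions: correlations clipped
to [−1, 1] after floating-point round-off; the transfer function's
singular point handled by an explicit 1e−9 guard band; permutation and
rotation p-values never zero (add-one estimator); all generators and
experiments deterministic given their seed.

## Known limitations

- Synthetic connectomes and maps share none of the spatial embedding of
  real cortex; spin tests on them exercise the machinery, not
  anatomical autocorrelation structure.
- The switching fixture's noise amplitude is outside the default
  fitting bounds (see above), so its coefficients are a demonstration
  operating point, not a fittable target.
- The σ-map direction is weakly identified at desk scale (see
  Identifiability).
- Hemodynamic constants follow the standard 3 T parameterization; no
  subject- or field-strength-specific calibration is attempted.
- Single-sphere centroids: no hemisphere mirroring in the spin test.
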