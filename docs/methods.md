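# Methods

This note records the models, conventions and numerical choices behind
`fepnet`, and what the synthetic validation does and does not establish.

## Free-energy estimation (MBAR)

Per-leg free energies are estimated from the reduced-potential matrix
u_kn (state k's dimensionless potential evaluated on sample n, samples
ordered by origin state) by solving the MBAR self-consistent equations

    f_k = −ln Σ_n exp(−u_kn) / Σ_l N_l exp(f_l − u_ln),

gauge-fixed at f_0 = 0. The solver runs a few self-consistent sweeps from
a warm start (a forward exponential-averaging ladder over adjacent
sampled states, with linear interpolation across unsampled "virtual"
states), then attempts Newton–Raphson steps on f_1..f_{K−1} using the
analytic gradient and Hessian of the MBAR objective; a Newton step that
does not reduce the self-consistency residual, fails to solve, or exceeds
50 in any component falls back to a self-consistent sweep. Convergence is
max|Δf| < 1e−10 between iterations (the method reference names no solver
settings; this tolerance makes the estimate bit-reproducible for a given
input). Non-convergence returns a flagged result with a warning, never a
silent success. All exponentials are evaluated through max-shifted
log-sum-exp; raw exponentials of reduced potentials never appear.

Uncertainties use the asymptotic weighted-sample covariance
Θ = V S (I − S Vᵀ N V S)⁺ S Vᵀ, computed from the eigendecomposition of
the K×K Gram matrix WᵀW of the normalized weight matrix (the sample
dimension is never decomposed), with a pseudo-inverse (rcond 1e−10) for
the structurally singular inner matrix. σ(Δf) between two states is the
usual quadratic form on Θ. Samples are treated as i.i.d. — correct for
the Gaussian generator by construction; real trajectory data would need
decorrelation/subsampling first, which this package deliberately does not
do.

BAR (two-state Bennett) is solved by Brent root finding on the monotone
acceptance equation; at K = 2 its fixed point is algebraically identical
to MBAR's, which the tests exploit as an exact cross-check (< 1e−8).
A vanishing slope of the acceptance equation at the root (all Fermi terms
saturated) is diagnosed as lack of phase-space overlap. Zwanzig
exponential averaging in both directions provides the bracketing oracle.

## Network assembly

One repeat of one directed edge gives ΔΔG = ΔG_complex − ΔG_free with
quadrature errors. Repeats aggregate as mean ± std/√n (n ≥ 2); a single
repeat keeps its propagated estimator error. Forward and reverse
measurements of a pair are distinct directed edges throughout.

**Racemates.** A racemic ligand is represented by two enantiomer
sub-ligands whose edges are computed separately and collapsed before
network assembly with the 1:1 mixture rule

    ΔΔG_rac→X = −kT ln[ (exp(−ΔΔG_R→X/kT) + exp(−ΔΔG_S→X/kT)) / 2 ],

evaluated per repeat in the log domain (stable to |ΔΔG| of hundreds of
kT) and with Boltzmann-weight-propagated errors. The rule is stated for
the racemate-as-source direction; edges *into* the racemate are combined
through the negation conjugate −combine(−ΔΔG_R, −ΔΔG_S), so that both
directions imply one and the same effective racemate affinity
(dG_eff = +kT ln[(exp(g_R/kT) + exp(g_S/kT))/2]) and noiseless data stay
exactly cycle-consistent. Applying the as-printed rule to both directions
would build an artificial ~kT-scale hysteresis into every racemate edge.

**Reconstruction.** Absolute per-ligand values solve a weighted least
squares over every directed observation (residual
(ΔG_t − ΔG_s − ΔΔG_st)/σ_st), with the reference ligand eliminated as a
hard constraint at ΔG_ref = RT ln(K_i,ref/C⁰) (K_i = 10 μM for ligand
"3"; T = 300 K everywhere, including the conversion, since no assay
temperature is available). Edge σ's are floored at 1e−6 kcal/mol so
noiseless synthetic data keep finite weights. Per-ligand uncertainties
come from the diagonal of the pseudo-inverse normal matrix, rescaled by
the reduced chi-square of the fit (standard WLS practice): with two
repeats per edge the stated σ's are themselves noisy and systematically
understate the scatter, and the residual-based scale restores
calibration (validated against ground truth in the tests). Ligands with
no path to the reference are reported as unresolvable, never silently
dropped. Edges between ligands of unequal modelled net charge carry a
warning flag; no numerical correction is applied.

A weighted-path-averaging scheme would have been an equally defensible
reconstruction; WLS was chosen as the simplest estimator with a
closed-form covariance, and the brute-force-minimizer test pins down the
objective it optimizes.

## Diagnostics

Hysteresis of a bidirectionally measured pair is
h = ΔΔG(X→Y) + ΔΔG(Y→X) (ideal 0; the sign convention makes it the
closure of the 2-cycle). Cycle closures sum oriented hop values around
simple cycles of length 3–4, enumerated over all pairs with at least one
measured direction and canonicalized under rotation/reflection; an
explicit curated list (e.g. the twelve published cycles) can be supplied
instead. Per hop, the default `as_measured` policy averages the
along-traversal value with the negated against-traversal value when both
directions exist; `forward_only`/`reverse_only` use a single direction
(falling back to the negated opposite where only one was measured).
Averaging halves direction-*dependent* errors and is how the published
closure table is best reproduced; the single-direction policies expose
them — a purely antisymmetric (source-keyed) bias cancels exactly under
averaging, which is why the full screen `diagnose_network` includes the
2-cycles (hysteresis) alongside the longer cycles. Flagging compares
|mean closure| ≥ threshold (default 0.8 kcal/mol, inclusive); the closure
uncertainty does not enter the comparison, matching how the published
table is bolded (−0.7 ± 0.8 is not flagged). Ligands are ranked by the
number of flagged cycles containing them, ties broken by id.

## Benchmark metrics

R² is the squared Pearson correlation (identical to regression R² with
an intercept, which is what is fitted); the slope is from OLS of
predicted on experimental (predicted as ordinate); MUE is the mean
absolute deviation. All ligands with both values enter, including the
anchored reference — this flatters the metrics slightly and is
documented rather than corrected. Uncertainties come from a Gaussian
parametric bootstrap (default 1000 draws): each draw perturbs every
predicted value by its own σ and every experimental value by an assumed
uniform σ_exp = 0.4 kcal/mol (the conventional figure when K_i values
are published without error bars). The achievable-R² upper bound is the
same bootstrap applied to the experimental vector against a
noise-perturbed copy of itself: for a batch-1-like spread
(six ligands over ≈ 4.4 kcal/mol) it evaluates to ≈ 0.96–0.97 at
σ_exp = 0.4, i.e. no predictor should be expected to exceed that.
σ_exp = 0 short-circuits to exactly (1, 0).

## Synthetic data

The generator emulates the study's structure, not its molecules:

* **Map.** 15 ligands in two batches (batch 1: "2"–"7", neutral;
  batch 2: "8"–"45", +1 except "15", modelled neutral), 22 undirected
  pairs measured in both directions with 2 repeats each, whose 3-/4-cycles
  include the twelve published ones; "8"–"15" is the charge-mismatch
  edge, and "7"–"15" bridges the batches. Ligand "38" is racemic with
  enantiomers 38R/38S. A `random_connected` topology (path plus
  triangle-closing chords) is available for small tests.
* **Truth.** Per-ligand ΔG uniform over the span implied by the series'
  K_i range (10 μM down to 0.2 nM at 300 K, i.e. ≈ −6.86 to −13.3
  kcal/mol); the reference "3" pinned at K_i = 10 μM. The racemate's
  enantiomers differ by 0.2–1.0 kcal/mol, solved backwards so the
  parent's effective value is the drawn one.
* **Legs.** Each leg is a chain of 11 one-dimensional Gaussian states
  u_k(x) = (x − μ_k)²/2 + c_k with μ_k spanning [0, 2] (strong adjacent
  overlap) and offsets linear in λ, so the exact end-to-end free energy
  equals the leg's target and MBAR's only error is statistical. The free
  leg of a pair gets a per-pair base value (reverse = negated); the
  complex leg carries the true ΔΔG on top, plus per-repeat Gaussian
  noise (default σ = 0.3 kcal/mol, a calibration choice — the real
  per-edge repeat spread is unknown) and, when the directed source
  ligand is in the misposed/water-defect set, a constant bias
  (pose δ = 2.0, water 1.0 kcal/mol in the protocol analogues). Keying
  the bias to the λ = 0 source of the *complex* leg is the minimal
  mechanism that makes forward and reverse disagree (hysteresis) without
  modelling kinetics; binding-site problems do not touch the solvent
  leg. `samples_per_state = 0` is an analytic mode: legs carry their
  exact noisy targets and the estimator stage is skipped.
* **Experiment.** The emitted K_i table carries multiplicative lognormal
  noise equivalent to 0.4 kcal/mol Gaussian noise on ΔG.
* **Protocol analogues.** A = pose + water bias; B = water bias only;
  C = pose bias only; D = unbiased; E = A with ten-fold samples —
  mapping the five set-up protocols onto bias/sampling knobs.

What passing tests show: the estimator chain is unbiased and its error
bars calibrated under the stated noise model, the diagnostics flag the
planted problem ligands, and the file formats round-trip. What they do
not show: anything about force fields, sampling of real conformational
ensembles, correlated trajectory noise, or which real ligands mispose —
the generator's noise is i.i.d. Gaussian by construction and its biases
are constants, both idealizations.

## Problem sizes and determinism

Validation studies use sizes chosen to keep the full suite fast on one
CPU: 100 seeded replicates for the two-state Gaussian coverage and the
(analytic-mode) detection study, 6 replicates of the full sampled
pipeline at 2000 samples/state for parameter recovery — detection needs
no per-leg sampling because the property under test lives downstream of
the estimator, and running it sampled would multiply cost by ~200 for no
extra discrimination. Every random draw flows from one seed
(`numpy.random.default_rng` / `SeedSequence`); equal seeds give
byte-identical outputs, including file outputs (fixed column order, full
precision).

## Known limitations

* No trajectory decorrelation; real u_kn data must be subsampled first.
* No charge-correction scheme for net-charge perturbations (the
  mismatched edge is only flagged).
* The WLS reconstruction assumes independent edge errors; repeats on the
  same pose share systematic error in reality.
* Cycle enumeration is capped at length 4 (cycles beyond that add little
  diagnostic power and blow up combinatorially).
* The curated-cycle selection of the published table is not derivable
  from the map; both "all cycles" and "explicit list" modes are exposed.
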