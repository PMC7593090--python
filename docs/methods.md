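# Methods

## The measurement being modelled

A ribosome–nascent-chain complex carries a single N-terminal oxazine
fluorophore.  Contact quenching by an internal tryptophan (present in W6
constructs, replaced by phenylalanine in W6F controls) or by
ribosome-surface quenchers switches the dye between a fluorescent and a
dark state.  The fluorescence autocorrelation of such a complex is a
product of (i) a ms-scale diffusion term, (ii) a triplet-state term with
~40 µs relaxation, and (iii) µs-scale relaxations from the quenching
kinetics.  The package models (i)–(ii) empirically and (iii)
mechanistically.

## Empirical ACF model

G(τ) = (1 + c₁e^(−k₁τ) + c₂e^(−k₂τ)) · (1−F+F·e^(−k_f τ))/(1−F) · (1/N)
· (1+k_dτ)⁻¹, in the baseline-0 convention, with an optional additive
offset (default 0) absorbing alternative normalizations of published
tables.  A 2D diffusion term is the default (the measurement geometry's
long axial dimension makes the 2D and 3D forms differ by a few percent
for the fast components); everything is in seconds and s⁻¹ internally,
µs only at presentation layers.  Note the triplet factor equals 1/(1−F)
at τ=0, so G(0) = (1+c₁+c₂)/((1−F)·N).

Fitting: weighted least squares (weights 1/sd when per-lag standard
deviations exist, else uniform); rates, amplitudes and N in log₁₀ space
and F in logit space so positivity and F∈(0,1) need no constraints; a
seeded Latin-hypercube multi-start (16 draws around the initial guess)
with ties broken by lowest residual then lowest k₁; the (c,k) pairs are
canonically ordered k₁ ≥ k₂ after fitting.

**Triplet box.**  The triplet factor is just one more exponential, so on
multiphasic curves it is partially degenerate with tens-of-µs kinetic
relaxations.  Two defenses are built in and used by the workflows:
(1) the triplet parameters can be boxed to the photophysically known
window (default 25–50 µs relaxation, amplitude fraction ≤ 0.4);
(2) `fit_empirical_global` fits a *shared* envelope (N, F, k_f, k_d)
across a panel of curves while each curve keeps its own relaxations —
the kinetics differ between curves (W6 vs W6F) but the photophysics do
not, which is what makes the envelope identifiable.  Residual envelope
error after both defenses shifts fitted conformational rates by well
under the 1 kJ/mol barrier tolerance checked end-to-end.

Stripping divides the fitted diffusion and triplet factors out of the
curve and truncates lags where that envelope has decayed below 10⁻³ of
its τ=0 value (dividing by a vanishing envelope only amplifies noise);
workflow stripping additionally truncates to τ ≤ 2×10⁻⁴ s, the window
the kinetic models describe.

## Kinetic networks

States carry a binary brightness (quenched states are exactly dark:
static quenching).  Presets: `2e` (one fluorescent conformation D with
ribosome- and Trp-quenched states), `3e` (adds the compact conformation
C exchanging with D), `5e-O` (C and D share the quenched states W and R —
cyclic topology), `5e-H` (separate Wc/Wd/Rc/Rd per conformation — tree
topology).  Rate names: `k_CD`/`k_DC` for conformational exchange,
`kon_X`/`koff_X` for quenched-complex formation/dissociation.

The generator K (column sums zero) gives the equilibrium as its null
space.  The predicted dynamic ACF component in correlation mode is

y(t) = qᵀ·e^{Kt}·diag(p)·q / (qᵀp)² − 1,

evaluated by eigen-decomposition with an expm fallback when the
eigenbasis condition number exceeds 10¹².  An amplitude-fit mode
(y(t) = Σ_s a_s·(x_s(t) − x_s(∞)) from the photon-weighted initial
condition, one free coefficient per species shared across a dataset — the
convention of simulation-based kinetics packages) is implemented for both
simulation and global fitting; with a_s = q_s/(qᵀp) it reproduces
correlation mode exactly.  Correlation mode is the default everywhere
because it is parameter-free and exactly matches the normalization of
stripped correlation data; the amplitude-mode global fit adds near-
degenerate amplitude×rate directions that make the 30-odd-parameter
panel fits slow and fragile.

Trp-quenching on-rates may be declared bimolecular (s⁻¹·mM⁻¹);
`apply_trp_concentration` converts them to pseudo-first-order rates at a
free-Trp concentration.  W6F constructs are modelled by zeroing the
Trp-quenching on-rates.

## Global fitting

Each curve maps its scheme rates to shared parameters through a link
configuration: `lock` (fixed values), `groups` (one estimate across a
set of constructs), `share_all`, `tie` (two rate names share one
parameter within each construct), `bimolecular`.  The published protocol
is the preset `paper-5eH`/`paper-5eO`: dye–Trp dissociation locked
(2.2 µs⁻¹ / 2.0 µs⁻¹), ribosome dequenching shared panel-wide, D-state
on-rates linked pairwise between wt and 4xA variants of a length,
C-state on-rates shared across constructs, and any "112 4xA" construct
left free apart from the shared ribosome dequenching.  The same locking
and pairwise-linking logic is applied to the reduced schemes 2e/3e when
they enter model comparison (the physical arguments — the dissociation
is a property of the dye–quencher pair, the on-rates of the chain's
position — do not depend on the scheme).

Rates are optimized in log₁₀ space inside [10², 10⁹] s⁻¹ with
`least_squares` under lmfit; weights are 1/sd when decays carry standard
deviations (uniform otherwise, in which case χ²/DoF values are
comparable in ordering but not absolutely calibrated).  Multi-start:
8 seeded starts by default, drawn log-uniformly inside per-rate-class
physical windows (conformational exchange 0.03–3 µs⁻¹, C-state quenching
0.01–1 µs⁻¹, D-state quenching 1–20 µs⁻¹, dequenching 0.1–3 µs⁻¹ —
the µs regimes the instrument resolves); blind draws over the full six-
decade range almost never converge for ~26-parameter panels, so the
windows are an initialization device only (bounds remain wide).  Ties
break by lowest χ², then lexicographically.  Standard errors come from
the covariance at the optimum, delta-converted from log space.

`compare_models` fits each scheme with its own preset linking, in order
of increasing state count, warm-starting each scheme from the best
simpler fit (rates matched by construct and base name; newly opened
C-state quenching equilibria start nearly closed at 10³ s⁻¹), and ranks
by χ²/DoF.

Confidence intervals: 1-D profile scans re-optimizing all other
parameters, with the interval defined by the constant-contour convention
χ²_min/χ²_profile ≥ 0.833 (a likelihood-ratio-style alternative is the
same machinery with a different contour).  On a quadratic surface this
reproduces the covariance interval with half-width
SE·√((1/0.833 − 1)·DoF).

## Transition-state analysis

ΔG‡ = −RT·ln(k·h/(κ·k_B·T)) with R = 8.3145 J mol⁻¹K⁻¹ and, by default,
the truncated printed constants k_B = 1.38×10⁻²³ J/K, h = 6.6×10⁻³⁴ J·s,
T = 295 K, κ = 1 (CODATA values switchable; ~0.05 kJ/mol difference).
Both exchange directions (C→D and D→C) are computed and labelled
explicitly.  SEs propagate by the delta method, σ_ΔG = RT·σ_k/k.
Kramers-type friction corrections are out of scope: applying them would
require solvent-viscosity information that does not exist for a chain
inside the exit tunnel.

## Force profiles

f_FL = ΣFL/(ΣFL+ΣAR) per construct length and replicate (double bands
summed before the ratio); profiles carry the across-replicate SEM
(sd/√n, 0 for single replicates).  High-tension regions are maximal runs
of sampled lengths with mean f_FL ≥ threshold (default 0.4 over a ~0.2
baseline, minimum run 2 sampled lengths, single-length gaps bridged when
both flanks exceed threshold — the transient force reliefs seen inside
otherwise continuous regions).  No numeric region definition exists in
the source literature, so region boundaries are reproduced descriptively
and never asserted against published coordinates.

## Synthetic data and oracles

`generate_truth_presets` draws seeded ground truths inside the measured
regimes: Trp quenching ~0.01–0.1 µs⁻¹ from C and 3–8 µs⁻¹ from D,
ribosome quenching 0.1–0.4 / 5–11 µs⁻¹, dequenching 0.3 µs⁻¹ (ribosome)
and 2.2 µs⁻¹ (Trp), conformational exchange drawn through Eyring
barriers in the 37–46 kJ/mol window; envelope N = 1, F = 0.15,
k_f = 2.5×10⁴ s⁻¹ (40 µs), k_d = 10³ s⁻¹ (1 ms).  Rates that the
published linking protocol ties together are drawn once and shared, so
linked fits can recover the truth exactly.  The default panel is three
lengths (70/102/112) × wt/4xA, each with a W6 and a W6F curve
(12 curves); the titration preset is one Trp-free construct across
0–45 mM free Trp with a bimolecular on-rate.

Full ACFs are composed as (1+y_kin)·triplet·(1/N)·diffusion on an
8-point-per-octave lag ladder (10⁻⁷–1 s) with multiplicative Gaussian
noise; the default noise is flat in relative terms (1% unless stated), a
√(τ/τ_min) growth law (capped at 10×) being available to mimic the fewer
independent correlator samples at long lags.  Pre-stripped decay panels
use additive noise with sd = noise_sd × y(0) per curve.  Replicate
variance beyond these noise draws is not modelled; photon shot noise is
not simulated (a binary brightness trace suffices to validate the
kinetics); neither limitation affects what the tests check, which is
recovery of kinetic truth from correlator-level data, not detector
realism.

The stochastic oracle is an exact Gillespie simulation of the jump
process, point-sampled every dt (so sampled correlations equal the
continuous-time ones at grid lags), fed to a multi-tau correlator
(16 lags per stage, factor-2 coarsening, symmetric normalization) with
standard errors from 32 contiguous blocks.  Because coarsening averages
the signal, estimator-level comparisons use the exact expectation of the
multi-tau output under the kinetic truth (a closed-form geometric-sum
response per eigenmode), which removes coarsening bias from the
comparison.

## Problem sizes and seeds

The shipped tests and the acceptance script use: 1000-draw algebra
round-trips; 20 random rate sets (5 per scheme) with 0.02 s traces at
dt = 2×10⁻⁸ s for the stochastic oracle; the 12-curve panel with 4-start
comparisons for recovery and ranking; a single-construct (2-curve)
end-to-end barrier check; and a 7-concentration single-construct
titration.  All randomness is seeded; the acceptance script derives
every seed from its `--seed` argument.

## Known limitations

* χ²/DoF on real data depends on the (unpublished) per-point noise
  model; orderings are meaningful, absolute values only when decays
  carry true standard deviations.
* The triplet/slow-relaxation degeneracy is managed, not eliminated; for
  chains whose slowest conformational mode falls inside 25–50 µs the
  stripped decays inherit a residual systematic error.
* On data generated from the tree-topology five-equilibria scheme, the
  shared-quenched-state scheme (5e-O) under the published locking
  carries a structural misfit (its locked dissociation edges return
  half of the quenching events to the compact state), so its χ²/DoF can
  land near — on either side of — the three-equilibria scheme's, while
  the generating scheme fits at χ²/DoF ≈ 1 and the reduced schemes
  misfit by an order of magnitude.
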