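# Methods

This note states precisely what `anpca` computes, the conventions it
commits to, and the reasoning behind the choices that were genuinely open.

## Signal model

Scalp potentials are modelled as an instantaneous noiseless linear mixture
`x(k) = A s(k)` of `N` mutually independent, zero-mean sources observed on
`M ≥ N` channels (default M = 8, N = 4, 256 Hz). The separation model
adopts the standard unit-variance source convention `E{s sᵀ} = I`: any
amplitude of a source can be absorbed into its mixing column, so scale
(and permutation) of the recovered sources is unidentifiable in principle.
All quality statements are made against this convention (see *Scoring*).

Preprocessing is a sixth-order Butterworth band-pass, 1–12 Hz, applied
forward–backward by default (zero phase, so the 300 ms P300 latency is not
shifted); a causal single-pass mode exists for strict real-time semantics.
Stimulus-locked epochs are closed intervals (`[0, 0.7]` s at 256 Hz yields
`round(0.7·fs)+1 = 180` samples; the onset sample is `round(onset·fs)`),
baseline-corrected on `[−0.1, 0]` s.

## The four-step cascade

**Step 1 — pre-separation (batch PCA twice).** The sensor covariance is
eigendecomposed; the retained components are scaled to unit variance by
`B = Λ^(−1/2)Vᵀ`. Rank selection `"auto"` keeps relative eigenvalues above
1e−8: on the reference mixtures the ERP direction sits at λ/λ₁ ≈ 1e−5
while the null space of a noiseless rank-deficient mixture sits at ≈1e−16,
so the floor separates signal from numerical noise by more than three
decades on either side (an earlier floor of 1e−3 silently discarded the
ERP). The whitened signal `x̄` is then rotated by the eigenvectors of the
covariance of the delayed sum `x̃(k) = x̄(k) + x̄(k−τ)`; in source
coordinates that covariance is diagonal with entries `2(1 + ρ_i(τ))`, so
distinct lag-τ autocorrelations identify the residual rotation. Because
1–12 Hz band-limited signals all have lag-1 autocorrelations in
[0.96, 1], a single-lag default would be near-degenerate for *any* source
set; the default therefore averages the symmetrized delayed covariances
over τ ∈ {1..32} (up to 125 ms) before the eigendecomposition, and a
`degenerate` flag reports near-equal eigenvalues. For strictly streaming
use an Oja-type tracker `v ← v + β·x̆·(x* − v·x̆*)`, `x̆ = vᴴx` (β = 0.6)
follows the dominant eigenvector of a sample stream; its cost
`E(v) = ½‖(I − vvᴴ)x‖²` and the exact gradient are unit-tested against
central finite differences.

**Step 2 — adaptive whitening.** Per signal block (256 samples ≈ 1 s),
`P(k+1) = P(k) + η(k)(I − R̂_uu)P(k)` with `u = Px̆` and `R̂_uu` the block
covariance; the fixed point is `P R P ᵀ = I`. This keeps the signals white
under drift that the one-shot batch whitener of step 1 would miss.

**Step 3 — nonlinear PCA separation.** After whitening, the remaining
mixing is orthogonal, and second-order statistics cannot resolve it; the
per-sample rule on `y = Wᵀu` with `f(t) = tanh t` injects higher-order
statistics. Two rules are implemented:

* `printed` (default): `W ← W + μ·f(y)(uᵀ − f(y)ᵀ)W`, with periodic
  symmetric orthonormalization `W ← W(WᵀW)^(−1/2)` (every 100 updates)
  enforcing the orthogonality assumption under which the rule is derived.
  This rule is a *near-convergence fine-tuner*: started at `W = I` on the
  pre-separated signals it polishes and tracks, but it does not by itself
  find a far-from-identity rotation (the test suite demonstrates both
  behaviours).
* `standard_npca`: the classical subspace rule
  `W ← W + μ·(u − W f(y))f(y)ᵀ`, which does recover full rotations and is
  the documented fallback if the printed rule destabilizes.

Gaussian-only source sets are not identifiable by any such contrast; the
suite checks that the rule then (correctly) fails to separate.

**Step 4 — mixing estimation.** `Q` minimizes `E‖x − Qy‖²` by a
stochastic rule `Q ← Q + α(k)(x − Qy)yᵀ` with `Q(0) = 0`; its columns
estimate the mixing columns up to the usual permutation/scale ambiguity.

## The adaptive learning rate

All three adaptive stages share one schedule,

```
1/rate(k) = (1 − forget) · 1/rate(k−1) + ‖z(k)‖² ,
```

driven by the stage's output power, with forgetting *rates*
ξ = 0.01, γ = 0.002, α = 0.3. This is the recursive-least-squares-style
gain: the inverse rate accumulates signal energy with exponential memory
≈ 1/forget, so the gain anneals like 1/k early on and plateaus at
`forget/E‖z‖²`. The alternative reading of the constants — as
*multipliers* of the previous inverse rate — makes the gain essentially
memoryless (`rate ≈ 1/‖z‖²` ≈ 0.25 for four unit-variance outputs), and a
constant-step stochastic rule at that gain has a diffusion floor far above
the performance levels this method is known to reach; that reading was
therefore rejected on convergence grounds before any experiments were
run. In step 4 the same family appears as a normalized gain
`α(k) = α/‖y(k)‖²`: a constant-α LMS rule is only stable while
`α‖y‖² < 2`, which whitened multichannel outputs routinely violate.

## Scoring

With `V` the total pre-separation map, the combined system is
`C = Wᵀ P V A_eff`, where `A_eff = A · diag(σ_j)` and `σ_j` is the
standard deviation of band-passed source `j` — i.e. the mixing of the
equivalent *unit-variance* sources. Scoring against the raw `A` would
penalize nothing but the (unidentifiable) source amplitudes, which differ
by two orders of magnitude between the µV-scale ERP and the backgrounds.

The performance index of a square `C` is

```
PI = 1/(2(M−1)) · Σ_i [(1 − Ca_i) + (1 − Cb_i)],
Ca_i = max_j |c_ij|² / Σ_j |c_ij|²   (rows),  Cb_i likewise for columns.
```

PI = 0 exactly for scaled permutations, 1 for an all-equal square matrix;
it is invariant to row/column permutations and to global scaling, and
PI = 0 is preserved under arbitrary nonzero diagonal row/column scalings.
(Invariance under arbitrary *independent* row and column scalings does not
hold in general and is not claimed: scaling one row of the all-ones 2×2
matrix changes its PI.) The index is computed in exact rational
arithmetic so both boundary values are attained bit-exactly; decibels are
`20·log10 PI`. Convergence of a per-epoch PI trajectory is declared at the
first epoch followed by two relative changes below 1%.

## Synthetic sessions

No public recordings accompany the method, so all quantitative claims are
made on a seeded generator designed to mimic the relevant statistical
structure of an oddball session rather than its cosmetics:

* *Schedule*: 7 stimuli per block, each flashed once in random order,
  350 ms onset-to-onset (50 ms flash + 300 ms blank), one fixed attended
  target per session.
* *ERP source*: Gaussian bump (peak 1.5 µV at onset + 300 ms, sd 60 ms)
  at target onsets, plus a smaller earlier bump (0.45 µV at 150 ms) at
  non-target onsets so target classification is not trivial.
* *Backgrounds*: two AR(2) resonances (10 Hz, pole radius 0.98; 6 Hz,
  0.95) driven by uniform innovations, mixed with low-pass 1/f drift,
  40 µV RMS each. Uniform innovations keep the marginals light-tailed, so
  the sources are identifiable both by second-order structure (distinct
  autocorrelations, for steps 1–2) and by the tanh contrast (step 3).
* *Artifact*: slow piecewise-linear ramps, 100 µV RMS (electrode drift).
* *Mixing*: unit-norm columns, redrawn until the condition number is
  ≤ 10; additive Gaussian sensor noise optional (default off).

All sub-seeds derive deterministically from one session seed. Known
limits: sources are stationary and exactly linearly mixed; there is no
inter-trial P300 variability, no eye-blink transients, and no channel-
specific noise — the generator validates the algorithms, not the
electrophysiology.

## Reference experiment and baselines

The canned study (`anpca.experiments`) replays one 7000-sample block
(≈27 s) for up to 10 epochs with ξ = 0.01, γ = 0.002, α = 0.3, `W(0) = I`,
logging PI every 50 iterations. Observed on seeds 0–5: final PI
0.001–0.027 (median 0.008, worst −31 dB), PI < 0.1 within the first 50
iterations, settled within 8 epochs.

Baselines run on identical sessions: SOBI (exact whitening + Jacobi joint
diagonalization of symmetrized lagged covariances, lags 1–10) reaches a
comparable final PI but only after ~30 batch sweeps (~2×10⁵
sample-visits; PI < 0.1 after ≈4 sweeps ≈ 2.8×10⁴), and plain NPCA (the
separation rule alone on exactly whitened data, without the
delayed-covariance rotation) does not reach PI < 0.1 within one pass.
The comparison isolates where the speed comes from: the pre-separation
rotation hands the adaptive stages a nearly solved problem.

## Numerical conventions

Sample covariances are symmetrized before eigendecomposition; eigenvalues
are sorted descending and each eigenvector's largest-magnitude entry is
made positive, so all batch transforms are deterministic. Divergence of
any adaptive rule (non-finite coefficients, or tracker norm > 10) raises
a diagnostic error naming the parameter to reduce. EDF export uses a
minimal 16-bit encoder (integer rates, one record per second) and is
round-trip-tested against an independent reader (MNE); delimited text
round-trips floats exactly via `repr`.
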