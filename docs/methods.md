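# Methods

## Model and assumptions

Expression dynamics along pseudotime are modelled as a linear ODE
dx/dt = A x on the G-dimensional expression vector, with A factored
through D-dimensional latent dynamics: dz = diag(b) z dt, x = W z, so
that Z[i, c] = e^{b_i t_c}, W is the least-squares fit of X onto Z, and
A = W diag(b) W⁺.  The assumptions this inherits:

* pseudotime is a faithful, error-free time axis (it is an *input*;
  the package never infers it);
* the dynamics are linear and autonomous over the whole trajectory —
  no branching, switching or saturation;
* B is diagonal, so the latent coordinates are uncoupled exponentials;
  only decay/growth rates b_i within [bmin, bmax] are searched;
* by construction rank(A) ≤ D: the method scores regulatory structure
  only up to a D-dimensional dynamical skeleton.

The factored form A = W diag(b) W⁺ is an approximation to a directly
optimized A; no claim is made about the size of that approximation
error, only about the factored estimator itself.

## Optimization

The rates b are found by greedy Monte Carlo search: each proposal copies
the incumbent and resamples exactly one uniformly chosen coordinate,
uniformly on [bmin, bmax]; a proposal is accepted iff it strictly lowers
the total RSS between X and the refit W Z.  Ties keep the incumbent, and
among equal-RSS candidates in one batch the lowest row index wins — both
rules exist purely for determinism.  The best-so-far RSS trace is
therefore non-increasing by construction.  There is no annealing, no
gradient, and no adaptive proposal: the search is pure uniform
resampling, which is why convergence into a narrow optimum slows once
the neighbourhood of the optimum is reached (the probability of a draw
landing within δ of the optimum is ~δ/(bmax−bmin) per proposal).

The batched path expands the incumbent into BS independent
one-coordinate perturbations per round and accepts the best iff it
improves.  This is the natural parallelization of "resample one
coordinate": at BS = 1 it is the sequential loop, and more candidates
per round can only sample a weakly better per-round minimum.

RNG protocol: one seeded PCG64 stream; per round, first all coordinate
index draws (one per perturbed row), then all replacement-value draws,
in row order.  The sequential loop makes one index draw then one value
draw per iteration — identical stream consumption to a BS = 1 round.
This fixed protocol is what makes the batched ≡ sequential equivalence
exactly testable rather than merely statistical.

Multiple restarts use sub-seeds spawned from the main seed; the
minimum-RSS restart wins.  Score matrices are never averaged across
restarts (a single best B is the estimator).

## Parameters

| parameter | default | meaning |
|---|---|---|
| D | 4 | latent dimension; caps rank(A) |
| iterations | 100 | optimization rounds |
| bmin, bmax | −10, 2 | uniform sampling range of the rates b (1/pseudotime units) |
| BS (candidate batch) | 64 | candidate b-vectors scored per round |
| gene batch | balanced over workers | genes handed to one worker |
| chunk | auto | genes per inner array operation |
| restarts | 1 | independent searches; best RSS wins |

Defaults for D, iterations and the sampling range follow the original
reference implementation's conventions; they are deliberately ordinary
choices, exposed on the CLI and echoed into `run_meta.txt`.  With
pseudotime normalized to [0, 1], b = −10 corresponds to e-folding decay
about ten times over the trajectory and b = 2 to e²-fold growth.

## Numerical choices

* **Least squares.**  Wᵀ = (ZZᵀ)⁻¹ZXᵀ is solved by SVD-based
  minimum-norm least squares with a relative singular-value cutoff of
  1e−10, never by explicit inversion: uniform sampling can draw
  near-duplicate rates, which makes rows of Z coincide and ZZᵀ
  singular.  Such draws degrade gracefully to the pseudoinverse
  solution (logged once per process) instead of crashing a run.
* **Pseudotime normalization.**  Times are rescaled to [0, 1] by
  dividing by the maximum at alignment (flag, default on, factor
  logged); otherwise e^{b t} overflows for large raw pseudotimes.  An
  overflow in Z raises an error naming the offending (i, c) pair and
  advising normalization.
* **RSS definition.**  The scalar RSS is defined as the sum of the
  per-gene residual vector, so the per-gene diagnostics and the scalar
  objective are consistent by construction; cross-partition totals are
  summed in ascending partition order with compensated summation.
* **Precision.**  Double precision everywhere in the reference path.
  Registered computation backends must reproduce the reference backend
  on a probe suite (matmul, least squares, exp, reduction) within
  1e−10 relative error at registration time.
* **Chunking.**  "auto" chooses the largest gene chunk whose working
  set (chunk·C + chunk·D + D·C elements) stays under an element budget
  (default 5×10⁷); the decision is recorded in run metadata.
* **Degenerate inputs.**  All-zero expression fits exactly with W = 0
  and RSS = 0 (no move can strictly improve, so the initial b stands).
  Constant pseudotime and single-cell inputs are rejected at parse
  time as unidentifiable.

## Synthetic data generator

The generator draws data from the estimator's own model class:
b_true uniform on the sampling range with a minimum pairwise gap of
0.1×range width (so Z has full row rank and recovery is well-posed),
W_true standard normal, times on a uniform grid over [0, 1] (or sorted
uniform draws), and X = W_true Z + i.i.d. Gaussian noise.  Noise can be
specified as an absolute sd or relative to the noiseless signal's sd.
The ground-truth score matrix is defined as A_true = W_true diag(b_true)
W_true⁺ — the model class the estimator searches — so tests measure the
optimizer, not model mismatch.

What this does **not** emulate: count noise, dropout/zero inflation,
library-size effects, branching trajectories, or pseudotime-inference
error.  Passing tests therefore demonstrate correctness of the
algorithm under its own assumptions, not robustness on real scRNA-seq
data.

Edge recovery is scored as AUROC for classifying the top-fraction
largest |A_true| off-diagonal entries using |A_est| as the ranking
score; absolute values make the metric sign-invariant (activation vs
repression is not scored).

## Problem sizes used in the test suite

Unit tests run on instances of a few dozen genes/cells.  The heaviest
check fits G=100, C=200, D=4 with 500 rounds of 64 candidates, ten
seeds per noise level at noise {0.1, 0.5, 2.0}× signal sd — sizes at
which the stochastic behaviour of the search is stable while a full run
of the suite stays in the minutes range on one CPU.  The dense-grid
optimality check uses a one-dimensional latent space, where the
objective can be enumerated on a 10,001-point grid.

## Known limitations

* The greedy uniform search has no local refinement; terminal
  convergence is slow and high-precision fits need many iterations
  (the noiseless end-to-end example uses 800 rounds).
* Worker parallelism uses a thread pool over gene partitions; with a
  GIL-releasing BLAS this helps, but the default single-process plan is
  the reference semantics and the only performance claim made is value
  equivalence, not speedup.
* Scores are raw: no thresholding, no sign post-processing, no
  significance calibration of |A| entries.
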