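# Methods

## Problem and data model

The package forecasts four weekly surface-water indicators — pH
(dimensionless), dissolved oxygen (DO, mg/L), permanganate index
(COD_Mn, mg/L) and ammonia nitrogen (NH3-N, mg/L) — one step ahead,
jointly across a panel of monitoring stations.  A panel is a cube
(station × week × indicator); timestamps must be strictly increasing
and uniformly weekly.  Stations whose missing fraction exceeds 20% in
any indicator are dropped; remaining interior gaps are linearly
interpolated in time and edge gaps take the nearest observation.  The
20% threshold and the interpolation rule are package conventions for
"relatively complete" station records.

Supervised examples slide a lookback window (default 10 weeks) over
the panel.  Each indicator's model input is that indicator's values at
all stations over the window, flattened time-major into one vector, so
with S stations the per-indicator input has 10·S features and the
output is one value per station.  The prediction horizon is fixed at
one week by default but is a parameter.

Splitting is chronological — first 60% of windows train, next 20%
validate, last 20% test; train and validation take the floor of their
fractions and the remainder goes to test, which keeps the earlier
subsets exactly at their nominal sizes and is deterministic.

Scaling is per-indicator min–max to [0, 1], fit on training windows
only.  Targets must be non-negative because every output head ends in
a ReLU; [0, 1] scaling guarantees that no valid target is clamped.
Out-of-range validation/test values are not clipped, so the transform
stays exactly invertible; all reported metrics are computed after
inverting back to the original measurement scale.

## Sharing structures

All structures are built from dense layers z = Wx + b with ReLU
activations.  Per indicator there is one encoder (a single dense+ReLU
layer, never weight-shared across indicators) and one tower (a stack
of dense+ReLU layers — 3 hidden layers for pH and DO, 2 for COD_Mn
and NH3-N — ending in a station-sized dense+ReLU head).

* **Hard sharing**: towers all consume
  `out_shared = concat(out_pH, out_DO, out_COD, out_NHN)`.
* **Soft sharing**: a two-layer dense+ReLU hidden block over the
  concatenation of all indicators' raw inputs produces
  `hidden_shared`; each tower consumes `concat(out_i, hidden_shared)`.
* **Gated sharing**: per task τ a dense readout of the concatenated
  encoder outputs is softmax-normalized into four weights; one
  weight-tied **linear** map (no ReLU — the corresponding printed
  equation carries none, unlike its gated-hidden counterpart) turns
  each encoder output into a candidate vector, and the tower consumes
  the convex combination Σ_i w_τ[i]·hidden_i.
* **Gated-hidden sharing**: the soft hidden block plus, per task, a
  two-way softmax gate over `concat(out_τ, hidden_shared)`.  The task
  candidate is `hidden_τ = ReLU(M·concat(out_τ, hidden_shared))` with
  M weight-tied across tasks, and the fused tower input is
  `v_τ = w_τ·hidden_τ + w_hidden,τ·P(hidden_shared)` where P is a
  shared linear projection to the fusion width.  As printed, both
  fusion terms multiply `hidden_τ`, which would cancel the gate
  (the two weights sum to 1); the projection form keeps the two gated
  branches distinct.  The literal form remains available behind
  `StructureConfig.gh_literal_fusion` for comparison.

Two reference models complete the comparison grid: `single_task`
(independent encoder + tower per indicator, seeing only its own
indicator's history — the stacked-MLP single-task baseline) and
`linear_baseline` (one affine map per indicator).

Tower variants for ablations reshape the fused vector to a short
sequence (default length 5, zero-padded) and apply one canonical
layer of the named kind — LSTM cell, GRU cell, width-3 1-D
convolution with mean pooling, or single-head scaled-dot-product
self-attention with mean pooling — followed by the same dense ReLU
head.  The originating description names the layer types but not
their internals, so minimal standard forms are used.

## Training

The training loss is the mean over samples of the summed per-indicator
squared errors, with each indicator's error averaged over stations:
equivalently, the sum over tasks of mean squared error.  (The source
formula is labeled RMSE but contains no square root; it is implemented
literally, which is monotonically equivalent for optimization.  RMSE
appears only as an evaluation metric.)  The station average makes the
loss scale invariant to the station count; the per-sample reduction in
the printed formula is scalar and silent on stations.

Optimization is Adam with the reference protocol defaults: learning
rate 0.001, 100 epochs, batch size 5, standard moment constants
(β₁ 0.9, β₂ 0.999, ε 1e-8).  Training windows are reshuffled every
epoch from the run seed.  Both losses are recorded every epoch and the
checkpoint with minimal validation loss is returned by default; the
fixed-final-epoch model is available via `checkpoint_best=False`.
Identical seed, data and configuration reproduce the loss history
bitwise.  Gradients come from reverse-mode automatic differentiation
(autograd) over the numpy forward passes.

Numerical choices that mattered in practice:

* **Initialization** — He-style fan-in uniform weights from the run
  seed; hidden biases zero.  **Output-head biases start at 0.5**, the
  mid-range of the [0, 1]-scaled targets: with a ReLU output head, a
  unit whose pre-activation steps negative early receives zero
  gradient forever, and permanently dead station outputs were
  observed on degenerate panels with zero-initialized head biases.
* **Input centering** — encoders and the hidden block subtract 1/2
  from the [0, 1]-scaled inputs, moving them to [−1/2, 1/2].
  All-positive inputs condition first-layer learning poorly; the
  shift is a fixed documented constant, not a data transform (the
  scaler contract and the affine linear baseline are unchanged).
* **Softmax** — stabilized by max subtraction.
* **ReLU ties** — the gradient checker excludes coordinates where the
  loss is locally non-smooth (forward/backward or step-halving
  disagreement of the numerical derivative) or locally flat while the
  tie convention reports a nonzero subgradient (exactly-zero
  pre-activations downstream of dead layers); excluded coordinates
  are counted and reported.

## Synthetic panels

The generator emulates the premise that indicators of the same water
body co-move.  Per station s, a latent AR(1) factor z_t with
stationary standard deviation `shared_std`; indicator i observes

    value = mu_i + a_i·z_t + u_t^(i) + A_i·sin(2πt/period + phase_i) + e_t

with u an indicator-specific AR(1), e white noise, period 52 weeks,
and a 100-step burn-in discarded.  Values are clipped at physical
floors only (pH > 0, concentrations ≥ 0), preserving the
linear-Gaussian structure almost everywhere.  Randomness comes from a
splittable seed sequence with sub-streams per station and indicator,
so adding stations never changes existing series.  Default means are
plausible surface-water conventions (pH 7.5, DO 8 mg/L, COD_Mn
4 mg/L, NH3-N 0.5 mg/L), not estimates from any dataset.

The strong-shared-factor configuration used by the simulation study
sets 8 stations, 400 weeks, all loadings 1, and both idiosyncratic
terms (AR residual and observation noise) at 0.3× the shared
stationary std.  Its AR coefficients were chosen by an explicit
covariance computation of the population-optimal linear one-step
predictor: with a fast factor (phi 0.8) and persistent residuals
(phi 0.5) the optimal multi-indicator predictor beats the optimal
single-indicator predictor by only ~2.5% RMSE — a single indicator's
own lags already pin down the factor, and the scenario fails to
contain the cross-indicator signal it exists to exhibit.  With a slow
factor (phi 0.95, half-life ≈ 13 weeks, as for seasonal hydrological
drivers) and near-white residuals (phi 0.2) the population gap is
~6.5%, and a ridge-regression oracle on the same finite windows
recovers a ~3% advantage in every seed tested.  These coefficients
are therefore the scenario defaults.

What the generator does not emulate: pollution spikes and other
heavy-tailed events, irregular or sub-weekly sampling, cross-station
coupling (each station has its own factor), measurement drift, and
regime changes.  Passing the simulation study therefore shows that
the structures exploit a shared latent state under clean Gaussian
dynamics — not that they would on any particular real monitoring
network.

## Evaluation and harnesses

RMSE, MAE and MAPE are computed per indicator on inverse-scaled
values, flattened over (sample, station).  MAPE is a fraction
internally, percent at interfaces, and raises on targets within 1e-8
of zero, where it is undefined.  The multi-indicator aggregate is the
SUM of per-indicator values — the convention under which the
reference multi-indicator cells equal the row sums of the
per-indicator table — with `convention="mean"` available.
Improvement rows are 100·(reference − candidate)/reference, rounded
half-away-from-zero to one decimal, with the reference being the best
non-multi-task model in the same column.

The benchmark harness trains every requested structure on identical
splits and seeds and emits a per-indicator grid, an aggregate grid
with the improvement row, a 4-task-versus-3-task-subset grid (excluded
indicators blank), and a tower-type grid.  Each row records its seeds
and a configuration hash; a failed run becomes missing cells without
aborting the harness.

The multi-task-advantage study (`mtl_advantage_trial`) compares Mt-GH
against the matched-width single-task MLP at hidden width 32 with a
reduced protocol — Adam, learning rate 0.01, 150 epochs, batch 16 —
chosen so a full ten-seed battery of both models on strong-factor and
independent-indicator panels completes on one CPU; the reference
protocol (0.001/100/5) remains the package default elsewhere.

## Known limitations

* Training is CPU-bound reverse-mode autodiff over numpy; it is meant
  for panels of tens of stations and hundreds of weeks, not for large
  grids or long horizons.
* The ReLU output head cannot predict below the training minimum of
  an indicator (scaled 0), which matters when the test period drifts
  below the training range.
* Run-to-run training variance at the study's sample size (≈230
  training windows) is a few percent of aggregate RMSE, the same
  order as the multi-task information advantage; single-seed
  comparisons of two structures are therefore noisy, and the
  harnesses support seed batteries for that reason.
* MAPE is undefined at zero targets and the package refuses to
  compute it there; indicators that can reach zero (NH3-N in clean
  water) need means or floors away from zero in synthetic studies.
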