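# Methods

## Problem and data model

The package estimates a freely moving animal's position from simultaneously
recorded hippocampal single units. A session is a set of per-unit spike
times plus a 50 Hz tracked position trace, either 2D coordinates in a
1 m × 1 m open field or 1D arc length along a Z-shaped track (two 190 cm
arms joined by a 220 cm diagonal, 600 cm total). Time is seconds and
position is cm throughout; config fields carry an `_ms` suffix where the
conventional unit is milliseconds.

## Feature extraction

Spike counts are taken in sliding half-open windows `[start, start + T)`
of length `window_len_ms` (scanned 200–4000 ms in the full protocol)
spaced `stride_ms = 200` apart, so consecutive windows overlap by
`1 − stride/T` (0% at 200 ms, 50% at 400 ms, 80% at 1000 ms). The window
grid is anchored at the start of the usable span (the exact intersection of
the spike and tracking time ranges). A spike on a window's start boundary
is counted, one on its end boundary is not, so non-overlapping windows
partition spikes exactly.

A sequence sample is `seq_len = 100` consecutive count vectors; its target
is the tracked position linearly interpolated at the centre of the last
window. With the default stride a sample covers 20 s of activity. Samples
that would need windows before the session start simply do not exist (no
padding), which fixes the sample-count arithmetic used by the fold
construction.

## Ratemaps and occupancy

Spike and dwell maps use 2 cm bins (square in 2D, arc-length segments in
1D). Each tracking sample contributes its inter-sample interval to its
bin, so raw occupancy sums exactly to the tracked duration. Both maps are
smoothed with a truncated Gaussian kernel (σ = 1.5 bins, radius 4σ) and
the rate is their ratio. Smoothing redistributes each source bin's mass
over *visited* bins with per-source renormalised weights: total spike mass
is conserved exactly, no mass leaks into unvisited bins, and away from
edges the operation equals ordinary convolution. Visited means raw
occupancy > 0; unvisited bins are excluded from decoding. Rates on visited
bins are floored at `rate_floor_hz = 0.01` so Poisson log-likelihoods stay
finite — a numerical necessity, configurable.

The occupancy prior p(x) is the normalised occupancy over visited bins. By
default it is computed from the training split only (leakage-safe); a
full-trial mode exists for protocols that estimate it from the entire
session.

A Skaggs-style spatial information score (bits/spike),
Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄) with λ̄ = Σᵢ pᵢλᵢ, is provided as a utility for
ranking comparisons; the formula follows the place-field literature it
originates from, and a silent unit returns NaN rather than a score.

## Bayesian decoders

All likelihood math runs in the log domain (log k! via the log-gamma
function); direct products overflow for 4 s windows with high-rate units.
Per window, the flat-prior decoder normalises

    log P(K|x) = Σᵢ [kᵢ log(T αᵢ(x)) − T αᵢ(x) − log kᵢ!]

over visited bins and reads out the argmax bin centre, ties to the lowest
bin index. The memory decoder multiplies in the occupancy prior and, from
the third window on, a continuity Gaussian in the distance from each bin
centre to the previously decoded position. Its σ is the mean decoded step
displacement over the last up-to-15 steps, times a scale factor (1 open
field, 5 track), floored at `min_sigma_cm = 2` (one bin) so a stationary
decode cannot collapse to a delta. Design points the protocol leaves open,
resolved here: σ uses *decoded* (not true) displacements, since truth is
unavailable at decode time; with fewer than 15 previous steps all
available ones are used; the first window uses prior × likelihood only, and
the second as well because no decoded displacement exists yet; the
continuity density is evaluated on bin centres. Setting the scale to
infinity disables the continuity term; with a uniform prior the memory
decoder then reproduces the flat decoder exactly (a tested identity).

## Recurrent decoder

The many-to-one regressor is an input layer of size N (recorded units),
two LSTM layers (512 units each at full scale), and a linear output layer
with one node per coordinate. The loss is applied only to the
final-timestep output: mean over samples of the summed squared coordinate
error. Training is RMSprop (ρ = 0.9, ε = 1e-7) at a constant learning rate
0.001, batch size 64, 50 epochs at full scale, no early stopping and no
validation-based decisions.

The implementation is plain NumPy: explicit forward recursion, exact
backpropagation through time for both weight and input gradients, Glorot
input weights, orthogonal recurrent weights, forget-gate bias 1, all
seed-pinned. Runs are bit-reproducible on a machine given the seed, and a
float64 mode supports finite-difference verification of the gradients
(checked to ~1e-6 relative in the suite).

Two deliberate scaling choices where the training recipe is silent:

- **Inputs** are raw spike counts; optional standardisation sits behind a
  config flag (off by default).
- **Targets are centred**: the network regresses residuals around the
  training-mean position and predictions add the mean back. With
  RMSprop's magnitude-normalised steps at lr 0.001, an output layer
  initialised near zero moves only ~lr per update and cannot traverse the
  ~50 cm offset to the arena centre within desk-scale update budgets;
  centring removes that nuisance component without touching the loss or
  optimiser. (Verified: a 64-unit model on 500 samples beats the
  predict-mean baseline with centring and does not without.)

A desk-scale profile (2 × 128 hidden units, 20 epochs) is first-class for
CPU runs; the architecture is otherwise fixed and hyperparameters live in
config.

## Cross-validation and error quantification

Folds are contiguous blocks of samples (fold 1 = first tenth of the
recording, remainder samples to the last fold). A validation sample is
discarded iff its seq_len-window span shares any window index with a
training sample's span — the predicate, not the resulting constant, is
authoritative; for 100-window sequences it discards 99 samples at each
border, so interior folds of a 4000-sample session retain 202 and border
folds 301. For the single-window Bayesian decoders the same predicate is
applied at their actual dependency length, `ceil(window_len/stride)`
windows, because overlapping windows share spikes even without shared
count vectors. Bayesian ratemaps and priors are refit per fold on the
training time only.

Both stride conventions are supported for the Bayesian decoders: the fixed
200 ms stride (comparable sample grid to the recurrent decoder) and
half-overlap windows (stride = T/2). The memory decoder's continuity σ —
the mean displacement *per decoding step* — is calibrated to the
half-overlap convention; on a 200 ms grid the per-step displacement is a
single bin and the continuity term over-constrains the path. The
benchmark therefore evaluates the memory decoder on half-overlap windows
and the flat decoder on the 200 ms grid; run configs record the stride
used.

The deterministic Bayesian decoders run once per fold. The stochastic
recurrent decoder supports `n_repeats` realizations with distinct seeds;
each sample's reported error is the average of its errors over
realizations, not the error of the averaged prediction.

Errors: 2D mode uses the Euclidean distance on continuous coordinates
(MED = mean, plus median and per-coordinate |Δx|, |Δy|); `bin2d` snaps the
true position to its bin centre first (decoded positions are already bin
centres); 1D mode is |Δs| along the track after projecting 2D points
orthogonally onto the Z polyline and taking cumulative arc length. Error
histograms use 2 cm bins with one overflow bin above 50 cm. Chance
references are predict-the-arena-centre and predict-the-training-mean
baselines computed per session. Speed at a sample is the displacement over
the 200 ms around the window centre divided by 0.2 s; covariate reports
use tie-corrected Spearman correlations and Welch t-tests between speed
classes split at 0.5 and 10.5 cm/s.

## Sensitivity analyses

Knockout without retraining zeroes one unit's counts in the validation
data only, re-predicts, and reports the mean-error increase and the
resulting ranking. Gradient sensitivity computes per-sample
|∂loss/∂input| by BPTT (per-sample loss, magnitudes only) and averages the
D × T × N tensor along samples, units, or sequence position; the spatial
"sensitivity field" assigns each sample's final-timestep gradient to the
bin of its true location. For the sensitivity-vs-rate curve, each unit's
counts and gradient magnitudes are divided by their own 99th percentile
(the maximum is an outlier for sparse units; a few normalised values
exceed 1), pooled, and averaged per normalised-rate bin (10 bins on
[0, max]).

## Synthetic sessions

The simulator generates what the decoders assume, plus known violations:

- **Trajectory (2D):** Ornstein–Uhlenbeck velocity (relaxation 1 s) with
  wall reflection and stationary pauses (rate 0.05 /s, mean 2 s). The OU
  speed scale is calibrated so the session-mean speed matches
  `mean_speed_cm_s` (default 12 cm/s, within 10% over ≥ 600 s).
- **Trajectory (Z-track):** constant-speed shuttling in arc length with OU
  speed noise and dwell pauses at corners and ends (the reward sites);
  direction reverses at the ends.
- **Tuning:** place-field centres uniform over the arena, σ 5–10 cm
  (fields ~20–40 cm across, typical of dorsal CA1 in a 1 m box), peaks
  5–20 Hz, baselines 0.05–0.5 Hz. Interneuron-like units get ~4× the top
  place-unit peak as a flat, untuned rate.
- **Spiking:** inhomogeneous Poisson by thinning at the instantaneous rate
  λᵢ(t) = b + (p − b)·exp(−‖x(t) − c‖²/2σ²). With finite
  `overdispersion_k` (default 3) the rate is multiplied per 1 s block by a
  Gamma(k, 1/k) variate (mean 1), giving super-Poisson count variability
  (Fano > 1) of the kind real place cells show.

The default benchmark is 40 place units + 3 interneurons over 1200 s —
inside the envelope of typical recorded sessions (tens of units, ~20–45
minute trials). What the simulator deliberately omits: theta phase
precession, replay/non-local activity during immobility, head-direction
tuning, multi-field cells, and behavioural structure beyond pauses.
Passing tests therefore demonstrate correctness of the machinery and
realistic-order error levels, not performance on real recordings, where
non-local activity and field instability will inflate errors.

## Benchmark problem sizes

The test suite and the reproduction script run, per seed: full 10-fold
blocked CV for the Bayesian decoders at 1400 ms windows (~5 990 windows),
and the recurrent decoder at the desk-scale profile on one blocked fold
(first tenth validation) with the training set thinned to every 2nd
sample (~2 600 samples, 20 epochs, single realization). These sizes are
the package's chosen defaults for a single-CPU run; the full protocol
(10 × 10-fold CV, 512-unit layers, 50 epochs) is available through the
same interfaces.

## Numerical and degenerate-input conventions

Posterior rows are normalised in the log domain and sum to 1 within 1e-9.
Argmax ties break to the lowest bin index. Empty spans, empty
trajectories, zero temporal overlap, all-zero occupancy and negative
counts raise; silent units are flagged and retained (NaN information
score, zero knockout delta by construction). Out-of-arena tracking points
are clamped with a logged count (strict mode rejects); points more than
5 cm outside are always rejected. Non-finite training losses abort with a
diagnostic rather than continuing.

## Known limitations

- The NumPy LSTM is single-threaded BLAS-bound; the full 512-unit, 50-epoch
  protocol is feasible but slow on one CPU.
- The memory decoder's continuity term can self-trap when early decodes
  are poor (σ shrinks toward its floor on a stationary decoded path); the
  floor bounds but does not remove this failure mode, which is inherent to
  decoded-displacement σ estimation.
- The knockout and gradient rankings measure different notions of
  importance; on synthetic populations dominated by homogeneous place
  cells plus extreme-rate interneurons their agreement is weaker than on
  heterogeneous real populations (see the discordance of high-rate units:
  top knockout rank, low gradient rank).
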