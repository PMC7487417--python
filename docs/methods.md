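# Methods

## Model and conventions

Time is discrete in integer steps of `dt` (default 1 ms); all timestamps
are 0-based step counts and every gap `(t', t]` is half-open on the left.
Internal state timestamps initialize to −1 ("before step 0"), so events
occurring at step 0 fall inside the first gap.  The state stored at a
timestamp includes the spike that triggered the event there, and when a
pre- and a post-synaptic spike coincide at one step the post-synaptic
spike is applied at the segment boundary *before* the presynaptic
bookkeeping — this ordering is used identically by every strategy, which
is what makes the exactness comparisons meaningful.

Each trace chain `s -> z -> e -> p` (and `z_i z_j -> e_ij -> p_ij`) is a
cascade of first-order low-pass filters `tau dY/dt = X - Y`.  Between
spikes the cascade is linear with a closed-form solution — a mixture of
exponentials with coefficients `a = tau_z/(tau_z - tau_e)`,
`b = tau_z/(tau_z - tau_p*)`, `c = tau_e/(tau_e - tau_p*)` and, for the
joint chain, the harmonic constant `tau_zij = (1/tau_zi + 1/tau_zj)^-1`.
The effective probability constant is `tau_p* = tau_p / kappa` with the
learning-rate modulation `kappa = 1` by default.  A spike adds +1 to the
z trace after the decay.  These closed forms are verified against a
1 µs-substep Euler integration (1e-4 relative) and satisfy the semigroup
property `update(d1+d2) = update(d2) ∘ update(d1)` to 1e-10, which is the
formal license for event-driven evaluation.

Default kinetics: `tau_zi = tau_zj = 10 ms`, `tau_e = 200 ms`,
`tau_p = 1000 ms`, `tau_m = 10 ms`.  These are plausible magnitudes for a
fast-coincidence / eligibility / probability cascade; nothing in the
package depends on them except through the explicit configuration.  The
three constants along a chain must be pairwise distinct (the closed form
divides by their differences); the validator rejects collisions.

The weight is the BCPNN log-odds `w_ij = log(p_ij / (p_i p_j))` with all
probabilities floored at `weight_floor` (1e-8), and the intrinsic bias is
`beta_j = log p_j`.  The weight formula and bias follow standard BCPNN
practice; the floor keeps weights finite for silent synapses.

## Network dynamics and training protocol

Minicolumn support integrates `beta_j + sum_i s_i w_ij` through a leaky
integrator (`tau_m`), competes within its hypercolumn through a
temperature-1 softmax (soft winner-take-all, max-subtracted for
stability), is scaled to a per-step rate `r_j = r_max o_j` (with
`r_max = 0.1` at 1 ms steps, the ~100 Hz ceiling of a minicolumn's
projecting cells), and spikes when `r_j` exceeds a uniform draw.

Training is teacher-forced: the target minicolumn of each active
hypercolumn is clamped to `r_max`, its siblings to the losing rate `r_l`,
and deactivated hypercolumns fire uniformly at `r_s = r_max / M`.  This
reproduces the winner/loser/silent regime structure deterministically,
which both the rate-distribution measurements and the common-random-number
strategy comparisons rely on.  The exact membrane equation and stimulus
protocol of the original GPU experiments are not published; this clamping
protocol is the package's explicit stand-in, and the recall example
(cue + free-run) demonstrates that it produces a functioning associative
memory (recall accuracy 0.33 vs 0.1 chance on the 10 × 10 example) rather
than matching any reported recall figure.

The shipped regime-rate table (`r_l`, `r_w` for M = 10 … 100, with
`r_s = r_max / M` always computed) satisfies
`(r_w + (M−1) r_l)/M = r_max/M` exactly in every column; values for
intermediate M interpolate linearly.

## Update strategies

All four engines share spike generation (one uniform stream per
(seed, hypercolumn, minicolumn)), the time-driven j-vector, and support
integration, so a common seed yields identical spike rasters.

* **time_driven** — forward Euler of every trace every step; the O(dt)
  reference.
* **lazy** — rows advance on presynaptic spikes, columns on post-synaptic
  spikes, each via the exact closed form; six words per cell
  (`e_ij, p_ij, w_ij, z_i2, z_j2, t_ij`).
* **cue** — no column updates.  Per-cell timestamps collapse onto the row
  timestamp `t_i` and `z_i2` onto the i-vector `z_i` (four words per
  cell).  A row update reconstructs each column's post-synaptic spikes
  over the gap — the trailing L steps exactly from the ring buffer, older
  steps from the approximation function — and replays them segment by
  segment (decay with z values at the segment start, then z_j += 1).
  Beyond-horizon predictions draw one Bernoulli per step from a stream
  keyed by (seed, row, trigger step), so reconstruction is reproducible
  and independent of evaluation order.
* **flushing** — buffered lazy evaluation: row updates consume buffered
  spikes; when a spike is about to fall off the buffer tail its column is
  force-updated by replaying all of that column's unconsumed buffered
  spikes (only that column's; the rest of the buffer is untouched).  No
  information is lost, so the method is exact at the price of keeping
  column access.

Because lazy, oracle-CUE and flushing apply the *same* exact segment
kernels at the same boundaries, their trajectories agree to accumulated
rounding (~1e-15 observed over 5000 steps); the tests assert 1e-10.

The adaptive predictor's status recorder classifies each minicolumn every
`record_period = 300` steps into winner (`o_j > 0.5`), silent hypercolumn
(`max_j o_j < 2/M`) or loser, keeping `record_slots = 32` entries
(9600 steps of coverage, 2 bits per entry).  Queries use the record
nearest in time, ties to the older record; before anything is recorded
the predictor falls back to the all-silent prior, which coincides with
the static predictor.

## Error analysis

The analytic factor `P(t − t' > L) = Σ_r P(r) · r · (1−r)^L` uses the
three-point rate distribution `P(r_l) = α(M−1)/M`, `P(r_w) = α/M`,
`P(r_s) = 1−α`; its expectancy equals `r_s` for the shipped table at
every α.

The conditional factor `P(err > eps | H)` is estimated by single-synapse
Monte-Carlo trials (default 1e5): presynaptic and post-synaptic regimes
drawn independently from the rate distribution (spikes are assumed bursty,
so a regime persists through the trial); the presynaptic gap is geometric
at the presynaptic rate conditioned on exceeding L and capped at 10 L
(longer gaps contribute negligibly — the presynaptic z trace has decayed
to nothing); traces start at their stationary means and burn in for 500
steps of joint firing before the gap; ground-truth and candidate runs
share all random numbers except the beyond-horizon prediction, so the
error isolates the predictor.  The error is the relative weight
difference at the evaluating presynaptic spike (`|Δw / w_true|`).  Trials
with `|w_true| < 0.01` log-units are tallied separately and excluded: a
relative error against a near-zero weight measures the denominator, not
the prediction.  The adaptive trials model an accurate recorder
(prediction at the true regime rate); recorder misclassification during
regime transitions is not modelled.

These trials reproduce the qualitative claims (spike-dropping errors are
strictly one-signed, static-approximation errors two-signed; adaptive
dominates static) and the quantitative bounds at M = 100, L = 100:
overall error probability below 1e-4 for every α and ~1.6e-8 at α = 1
with the adaptive predictor.

Note that this is a *per-prediction* bound.  In a full network run a
committed prediction error persists in the e/p state and is re-observed at
every later evaluation of the drifted cell, so raw full-run error
frequencies are not directly comparable to the bound.

## Memory accounting

Storage per hypercolumn: `C·M·vars·4` bytes of synaptic matrix (vars = 6
lazy/flushing, 4 CUE, 3 time-driven) plus i-vector (4 words per
connection), j-vector (3 words per minicolumn) and, for the buffered
strategies, L bits per minicolumn.  The CUE synaptic saving is exactly
2/6 ≈ 33%.

Traffic is counted in *logical* bytes — words the algorithm actually
reads/writes — not cache lines or DRAM transactions (a configurable line
factor `k_line` is provided but defaults to 1, and cancels in
percentages).  The ledger charges: row event = M·vars·4 bytes each way
per hypercolumn (+ i-vector row); column/flush event = C·vars·4 each
way; the per-step time-driven j-vector update; one weight-row load per
presynaptic spike for support integration; buffer pushes at M bits per
step and queries at one word per minicolumn per row update.  Under this
accounting the classic symmetry holds (100 rows of a 10⁴ × 100 matrix =
one column = 240 KB; 10⁴ rows/s vs 100 columns/s per hypercolumn), and
the instrumented CUE-vs-lazy reduction on the 10 × 10 training run is
~47%: the column share (~38% of baseline traffic) disappears, row cells
shrink 6 → 4 words, and buffer overhead plus the unchanged j-vector and
support traffic hold the total under 50%.

## Problem sizes and determinism

The packaged experiments use a 10 × 10 network (C = 100) trained on 10
random patterns × 500 ms (5000 steps) — the smallest configuration that
exhibits the full winner/loser/silent structure and thousands of row
events — and 1e5-trial Monte-Carlo estimates; both complete in seconds to
a couple of minutes on one core.  Every random element (spiking,
patterns, beyond-horizon prediction, trial draws) derives from explicit
integer seeds; identical (config, seed) runs are byte-identical.

## Known limitations

* Full connectivity only (`C = H·M`); sparse patchy connectivity is out
  of scope.
* No synaptic delays, spike-amplitude scaling, or adaptation currents;
  the support integrator is the only neuron model.
* Hardware metrics (cache hit rates, DRAM transaction counts, kernel
  latency) are outside the model; the ledger is a logical-traffic model.
* The synthetic training protocol emulates regime structure, not any
  specific cortical dataset; passing tests certify the algorithms and
  their relative costs, not biological fidelity.
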