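# Methods

## Data model and file dialects

Spiking activity is modelled as a sparse event stream — (time, gid) pairs —
while membrane voltage is a dense frame-major matrix with one value per
neuron per time step. All times are milliseconds, voltages millivolts,
positions micrometers, and ids 0-based. Intervals are half-open
`[t_start, t_end)` except that a report's final instant is included, which
removes double counting at interior bin edges while still letting the last
bin own the window's right edge.

Three plain-text dialects (circuit CSV with a fixed header, NEST-style
whitespace-separated spike lines, voltage CSV with a `t_start,dt` header
row and a gid-order row) keep the artifact dependency-free and diffable.
Writers emit floats in `repr`-shortest form, so write∘read is the identity
for integers and within 1e-9 for reals; equal generator seeds therefore
produce byte-identical files.

## Synthetic circuits and activity

The generator emulates the organization of a cortical-column microcircuit
rather than its biophysics. Columns sit on hexagonal rings (one center plus
rings of 6, 12, … at `column_spacing` = 500 µm); minicolumns form a
jittered square grid at `minicolumn_spacing` = 30 µm inside the column
footprint; each minicolumn stacks its neurons evenly through six
equal-thickness depth bands (`layer_thickness` = 280 µm, layer I at the
top / largest y). The full-size preset (7 columns × 310 minicolumns × 100
neurons = 217,000 cells) mirrors the organization reported for large
cortical-column datasets; the `tiny` preset (2 × 3 × 10) keeps tests fast.
A fraction `inhibitory_fraction` = 0.10 of cells is inhibitory, and by
default the morphological type is coupled to the physiological one
(pyramidal ⇔ excitatory) behind a single spec switch. Morphometrics are
i.i.d. log-normal per attribute with medians at plausible orders of
magnitude (soma volume ≈ 2,000 µm³, dendritic surface ≈ 9,000 µm², ≈ 30
bifurcations); they exist to exercise glyphs and filters, not to match any
measured distribution.

Activity is homogeneous Poisson background (default 2 Hz per neuron over
300 ms) plus stimulus-evoked bursts: for each stimulus, layers fire in the
order VI → I with a 10 ms per-layer latency, each as a Poisson burst of
300 Hz lasting 8 ms. With these defaults the burst windows of successive
layers do not overlap, so the deep-to-superficial wave is unambiguous even
in a 60-neuron circuit, and each bursting neuron spikes ≈ 2.4 times
(≈ 9 % stay silent and are excluded from first-spike statistics). The
voltage trace is a display model only: each spike jumps the cell to
`v_peak` (20 mV) and relaxes exponentially to `v_rest` (−65 mV) with
τ = 5 ms, sampled at `dt` = 0.5 ms — there is no membrane ODE, no synapses,
no refractoriness.

Randomness uses one named stream per concern (placement, types,
morphometrics, spikes), each seeded by `SeedSequence([master_seed,
stream_id])`, so changing the activity parameters never shifts the circuit
layout and fixtures stay stable.

What passing tests on this data do show: the analysis operators (binning,
normalization, decay, compositing, filtering, aggregation, the bus) are
correct under realistic event statistics and spatial organization. What
they do not show: behavior on correlated or oscillatory network dynamics,
inhomogeneous rates, or real morphometric covariance — none of which the
generator produces.

## Temporal engine

Bin `i` of an `n_bins` binning of `[t0, t1]` covers
`[t0 + i·w, t0 + (i+1)·w)` with `w = (t1−t0)/n_bins`; an event exactly at
`t1` is assigned to the last bin. Spike mode counts events; voltage mode
averages the per-frame subset mean over the frames in each bin, and a bin
containing no frame copies its left neighbor (the first bin falls back to
the report's first frame) so over-fine binnings plateau instead of dropping
to spurious zeros.

Local normalization divides by the subset's own maximum (all-zero stays
all-zero); global normalization divides by the whole-dataset row's maximum,
which in spike mode always dominates any subset (counts are additive), so
`global_curve ≤ local_curve` bin-wise with equality on the whole-dataset
row. In voltage mode curves are first shifted to a zero minimum (subset
minimum locally, dataset minimum globally) so they live in [0, 1] for
negative mV; because a subset's mean can leave the range of the
whole-dataset mean, the voltage global curve is clamped to [0, 1] rather
than treated as a contract violation — the strict dominance law is a
spike-mode property.

The logarithmic display scale is `y = ln(1 + c·x)/ln(1 + c)` applied to the
normalized curve (not to raw counts): a monotone bijection of [0, 1] fixing
both endpoints and defined at zero. The default `c = 1000` maps a value of
1/1000 of the maximum to ≈ 0.1 of the axis, which is what makes small
precursor peaks (the layer-VI onset) visible next to the main response.
Default `n_bins` = 250, a display-oriented choice.

The focus view re-bins the raw events inside the clamped ROI at
`ceil(n_bins · scaling_factor · width/(t1−t0))` bins (minimum 1) — never an
interpolation of the context curve — so its total count always equals the
brute-force event count inside the ROI.

## Particle engine

Life is a single linear clock: a spike sets life to 1 at the spike time
(re-spiking resets rather than stacks, keeping life bounded) and life
decreases by `Δt/decay`, clamped at 0. All perceptual shaping is delegated
to the transfer functions over life, so an exponential-looking fade is a
matter of control points, not of the clock; as decay → 0⁺ only neurons
spiking within the current step remain lit (the blinking limit). `seek`
computes the same state from each neuron's last spike at or before the
target time, giving O(events) random access that is bit-identical to
stepping `advance` from the start. Voltage mode maps the instantaneous
value through `(v − v_min)/(v_max − v_min)` with no decay.

The camera is a standard pinhole: world→camera 4×4 view matrix
(right-handed, column vectors, looking down −z), focal length
`(height/2)/tan(fov/2)`, pixel origin top-left with y down; points at or
before the near plane are flagged and skipped. Particles are filled disks
(diameter from the size function) rasterized at pixel-center precision —
a deterministic CPU surface chosen so tests can compare images exactly;
GPU parity and throughput are non-goals. Traditional blending sorts far→
near (stable, depth descending, gid ascending for reproducible ties) and
applies source-over (`C = Cs·αs + Cd·(1−αs)`, `α = αs + αd·(1−αs)`);
accumulative blending adds `rgb·α` and `α` per channel in any order and
clamps, which is permutation-invariant because addition of non-negative
terms commutes. Under an active selection, non-selected neurons draw in a
semi-transparent gray context color at a fixed small context size.

## Structural engine

Glyph scalar encodings normalize `x → (x−min)/(max−min)` against the
currently displayed (post-filter) population, so each view spends its full
visual dynamic range; a degenerate range maps to 0. The pie fraction uses
the population's bifurcation range (an absolute cap would need a
convention the data does not supply). Filters are a conjunction of closed
ranges; `fade` keeps removed neurons in the layout at opacity 0.25 (fixed
for determinism, configurable), `hide` drops them before layout. Sorting
is stable with gid as the tie-break. The grid layout is row-major with
`cols = ceil(√n)`; the 3D layout reuses the particle camera projection so
a shared camera makes glyph and particle positions coincide. Aggregate
selection states are computed for columns, layers-within-columns and
minicolumns: *full* iff every member is selected, *none* iff none is,
*partial* otherwise — monotone in the selection by construction.

## Linked-views bus

Messages serialize as the topic name, a newline, and canonical JSON
(sorted keys, tight separators, shortest-repr floats), so serialization is
bit-exact across processes and round-trips to identity. Validation is
per-topic structural checking with three distinct error kinds (unknown
topic, schema violation, truncated bytes). Transport is plain TCP with
explicit endpoints — a small broker fans length-prefixed frames out to
subscribers in per-publisher order — because the protocol's content
(topics and payloads) is the interesting part, not service discovery. The
broker retains the latest message per topic and replays it on subscribe;
since selection, frame and camera payloads are full state (gid lists, not
deltas), late joiners converge idempotently. The playback state machine
clamps the play-head into its window under every message; ticking past the
end wraps modularly (overshoot carried past the start) when looping, else
parks at the end and stops.

## Problem sizes and numerics

The test-suite and acceptance-script problem sizes are chosen to exercise
every law at statistical power without waste: 50 random reports for the
temporal laws, 20 for seek/advance equivalence, 8 seeded ≤5-particle
32×32 scenes for the compositing oracles (the oracle is an O(n·pixels)
per-pixel painter's loop, deliberately independent of the production
rasterizer), 200-neuron populations for the structural oracles, and the
full 217,000-neuron preset for the generator echo (a ~2 s build).
Floating-point comparisons use 1e-9 for I/O round-trips and compositing,
1e-12 where the computation is algebraically exact; Poisson count checks
use a ±4σ band.

## Known limitations

No biophysical realism in the generator (no synapses, correlations, or
refractoriness); voltage mode has no decay semantics; the rasterizer draws
hard-edged disks (no antialiasing or textured sprites); the bus has no
discovery, authentication or cross-version negotiation; abstraction levels
above the column (brain areas) are not modelled.
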