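# Methods

This note documents the models and procedures implemented in `placefields`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about real recordings.

## Track geometry and preprocessing

All positions are in cm from the left track end. The analysed region
excludes a reward zone (default 15 cm) at each end of the 140 cm track and
is tiled by 40 half-open bins (the last bin closed), giving 2.75 cm bins.
Optogenetic and control zones are 33 cm intervals inside the analysed
region; they may be specified per running direction to compensate a fixed
tracking latency (a staggered zone per lap direction).

Velocity is the absolute central-difference derivative of position, smoothed
with a centred 2 s moving average whose window shrinks one-sidedly at the
recording edges (this avoids a systematic early/late bias that a causal
window would introduce). Running epochs are maximal runs with speed above
7 cm/s whose path length (Σ|Δx|) is at least 10 cm; shorter bursts are
rejected wholesale.

ΔF/F₀ uses a sliding-window baseline: the 1st percentile of raw fluorescence
in a centred 10 s window. Cells whose baseline is non-positive anywhere are
flagged and those samples marked unusable. Cell quality control keeps cells
with event rate ≥ 0.005 Hz and SNR ≥ 10, where SNR is defined (the upstream
convention leaves the formula open) as the peak ΔF/F over a robust noise
scale — 1.4826 × MAD of the trace after subtracting a ~2 s median filter.
This definition is parameter-light and monotone in true SNR.

Behaviour sampled faster than imaging (e.g. 30 fps tracking vs 10 Hz
imaging) is brought onto the imaging grid by nearest-timestamp resampling.

## Rate maps and smoothing

Within one direction, running-gated events outside the reward zones are
counted per bin and divided by the running occupancy time per bin. Smoothing
uses a truncated Gaussian kernel (σ = 1.5 bins, radius 4σ) written as a
bin-to-bin matrix whose columns are renormalised over valid (occupied)
bins. The kernel is applied to the event counts and to the occupancy
*separately*, and the smoothed rate is their ratio. This choice — rather
than smoothing the rate map itself — preserves total events, total
occupancy, and therefore the occupancy-weighted mean rate r̄ exactly, keeps
the map well-behaved where occupancy is uneven, and renormalises cleanly at
region edges and around unoccupied bins (which stay missing, never
interpolated). Occupancy probabilities for the information statistic are
taken from the smoothed occupancy so that r̄ = Σ pᵢ rᵢ holds to machine
precision.

## Spatial information and the shuffle test

SI = Σ pᵢ (rᵢ/r̄) log₂(rᵢ/r̄) in bits per event, computed on the smoothed
map; zero-rate bins contribute zero and a silent map scores zero. Event
amplitudes are ignored — the statistic counts unit events.

The null distribution comes from 1000 circular shifts of the event train.
Two details matter and were settled empirically during development:

1. **The shift acts on the concatenated valid-sample timeline** (running,
   correct direction, inside the analysed region), not on wall-clock time.
   A wall-clock shift moves events into gated-out periods, so shuffled maps
   lose events; the resulting small-sample inflation of null SI can mask
   even strongly tuned cells. The valid-timeline shift preserves the event
   count and inter-event structure exactly.
2. **Offsets are uniform over the whole circle.** Excluding near-identity
   offsets (a common "minimum shift" convention) leaves the shuffles more
   correlated with each other than with the observed train; that asymmetry
   breaks the joint exchangeability a permutation test relies on and
   measurably inflated the false-positive rate to ~0.15 at a nominal 0.05
   on untuned simulations. With full-circle offsets the test is exact.

Classification uses the empirical tail probability
p = (1 + #{null ≥ SI}) / (n_shuffles + 1), one-tailed (only high SI can
indicate spatial coding), at α = 0.05. The standard score
z = (SI − null mean)/null sd is reported as an effect size but not used for
classification: the null SI is approximately a scaled χ² whose effective
degrees of freedom are reduced by smoothing, so its skew does not vanish
with event count and a normal-approximation z-test stays anti-conservative
at any rate. The permutation p-value is calibrated by construction; the
type-I error of the full test measured on 500 untuned Poisson cells falls
within the 99% binomial band around α.

Degenerate cases: a cell with no events, or a shuffle distribution with zero
variance, is reported as a non-place cell and flagged.

## Direction handling and field geometry

Left and right traversals are analysed separately. A cell significant in
both directions keeps only the direction with the higher mean running event
rate (an exact tie — probability zero on real data — keeps the rightward
map deterministically, with a warning). Each retained map is normalised to
its maximum bin, and these normalised directional maps are pooled as the
analysis set for all subsequent population analyses.

Field centre = bin of maximal normalised activity (lowest index on ties);
field bins = the maximal contiguous run through the centre with activity
≥ 75% of the centre bin; field width = number of field bins × bin width.
Split-half reliability separates even- and odd-numbered traversals *within*
a direction (on a linear track the global lap counter alternates direction,
so its parity would confound the split) and correlates the two maps.

## Across-session stability

For each session-1 place cell, the session-2 map is taken in the cell's
retained session-1 direction irrespective of session-2 status. The spatial
correlation is Pearson's r over jointly occupied bins; it is *excluded*
(not scored zero) when session-2 activity is entirely silent or either map
is constant. Group statistics use the Fisher transform with r clipped to
±(1 − 10⁻⁶) so perfect correlations stay finite.

Retention: lost (no longer a place cell), stable (|field shift| ≤ 2 bins,
inclusive), remapped (> 2 bins). These classes partition the session-1
place-cell set exactly; a cell absent from the session-2 recording counts
as lost. A separate stable/unstable categorisation thresholds the spatial
correlation at r ≥ 0.5 (boundary inclusive, configurable).

The population-vector matrix correlates, across cells, the activity vector
at session-1 bin i with the vector at session-2 bin j, using max-normalised
maps (configurable); constant or undefined vectors yield missing entries,
which are excluded from (never zero-filled into) zone means. Zone scores
average the matrix diagonal over the zone's bins.

## Zone statistics, thinning control, interneuron summaries

Zone event rates divide in-zone running events by in-zone running
occupancy, per cell; the opto/control/ends zone counts recompose the total
running event count exactly. Place-cell zone proportions assign each cell
by its field-centre bin using the retained direction's zone interval.

The thinning control removes exactly ⌊0.30 · n⌋ of each cell's in-zone
events by seeded sampling without replacement, leaving out-of-zone events
untouched, and re-runs the full pipeline. Because the generator applies
optogenetic modulation multiplicatively to the Poisson rate, thinning is an
independent code path, and on synthetic control sessions it reproduces the
expected pattern: fewer in-zone place cells detected, with the surviving
cells' across-session spatial correlations statistically unchanged.

Interneuron (OLM) lap activity is the mean running-gated ΔF/F per lap per
cell; environment means average the per-lap means (mean of lap means, not
pooled samples — the two differ whenever lap durations differ) over the
last 10 laps of the familiar session and the first 8–10 (available) laps of
the novel session, with shrunken windows recorded when fewer laps exist.
The velocity profile bins activity in 5 cm/s velocity bins (bin width
configurable; the convention is not pinned down upstream) and reports
per-cell Pearson correlations between activity and velocity over all
samples.

## Longitudinal registration

The moving session's summed footprint image is aligned to the reference by
maximising the enhanced correlation coefficient (zero-mean normalised
correlation) over a rigid transform — rotation about the image centre plus
translation. A coarse stage grids rotation at 1° steps over ±10° with the
translation per candidate from phase cross-correlation; Nelder-Mead then
refines (θ, dy, dx). If nothing improves on the identity, the identity is
returned with a warning. Rigid motion suffices for chronic lens imaging and
keeps the recovery oracle checkable; affine models are out of scope.

Footprint NCC is computed over the union support of the two footprints
after mean removal — restricting to the union stops the shared empty
background from dominating on large fields of view; disjoint footprints
then score ≤ 0. Matching is greedy: the globally best remaining pair is
accepted and both cells removed, while the best NCC exceeds 0.5. Equal-NCC
ties break to the lexicographically lowest id pair, making the result
independent of input ordering and symmetric under swapping sessions.

## Synthetic sessions: what they emulate

The generator is a pure function of its seed and produces the statistical
structure the analysis assumes:

- **Behaviour** — end-to-end traversals of the 140 cm track at a mean
  running speed of 15 cm/s (typical for mice on a familiar track), with a
  ±30% lap-to-lap speed spread, 10% within-lap Gaussian speed noise, and
  1 s reward-zone dwell pauses. The lap-speed spread keeps lap durations
  incommensurate — a property of real behaviour that the circular-shift
  null depends on; perfectly metronomic laps would make time shifts nearly
  equivalent to spatial translations.
- **Pyramidal cells** — inhomogeneous Poisson events with Gaussian spatial
  tuning (default peak 5 Hz, tuning width 8 cm, baseline 0.05 Hz), gated to
  a preferred direction (the non-preferred direction fires at baseline),
  multiplied by a novelty gain and, inside the optogenetic zone, by an
  opto gain. Events sit on the frame grid with Gamma(2, 0.5) amplitudes.
- **Session pairs** — per-cell stability classes drawn from
  (p_stable, p_remap, p_lost); stable fields jitter by N(0, 0.5 bins),
  remapped fields redraw uniformly excluding ±2 bins around the original
  centre, lost cells fall silent.
- **Fluorescence** — events convolved with a unit-peak double-exponential
  kernel (rise 0.1 s, decay 0.6 s) on a baseline with white noise;
  interneuron traces have E[ΔF/F] = gain × velocity × novelty factor with
  log-normal per-cell gains.
- **Footprints** — 2-D Gaussian blobs (σ = 2 px) rejection-sampled with a
  minimum separation of twice the blob radius, transformed rigidly across
  sessions with per-cell centroid jitter and a fixed dropped fraction.

Validation experiments run 20 round-trip laps (40 traversals) per session —
about 20 passes through a direction-selective field, the regime in which
the argmax field-centre estimator is reliable to ±1 bin.

What passing these tests shows: the implementation recovers what the
generative model put in, at the stated sizes, with calibrated error rates.
What it does not show: robustness to features the generator omits — lapwise
novelty dynamics (novelty elevation is uniform in time), theta/phase
structure, non-Poisson burstiness beyond the event amplitudes, imaging
artefacts, source-extraction errors, or behavioural idiosyncrasies such as
mid-track reversals. Raw-video synthesis and source extraction are out of
scope; the pipeline starts from extracted traces and deconvolved events.

## Numerical conventions

- Bins are 0-indexed; intervals half-open [lo, hi) except the final bin.
- Zero-occupancy bins are missing everywhere (maps, SI, correlations).
- All randomness flows through integer seeds; per-cell test seeds are
  derived with CRC32 of the cell key so results are independent of
  iteration order and of Python's hash randomisation.
- Default problem sizes in the validation suite (500 cells for calibration,
  100 for recovery, 150 place cells for the mixture, 40 footprints, 20
  thinning seeds) give tolerance bands of roughly 2–3 binomial/multinomial
  standard deviations while keeping a full run around half a minute.

## Known limitations

- Across-day population-vector matrices are not computed: registration
  omits cells inactive on one day, which would bias the population vectors;
  per-cell spatial correlations and field shifts are the across-day
  statistics.
- The ECC alignment assumes rigid motion; strong non-rigid tissue
  deformation would require an affine or diffeomorphic model.
- The SNR definition is a reasonable stand-in for the (unspecified)
  upstream convention; absolute SNR values are not comparable across
  definitions, only the ordering matters for the QC cut.
- The empirical permutation p-value has resolution 1/(n_shuffles + 1)
  (~0.001 at the default 1000 shuffles); α far below that would need more
  shuffles.
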