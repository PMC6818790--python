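# Methods

## The problem

Mating yeast cells find a partner by decoding a pheromone gradient with a
GPCR (Ste2) coupled to a heterotrimeric G protein. Two features make this
hard: the gradient across a ~5-µm cell is shallow, and the receptors
themselves are distributed unevenly (up to ~3-fold side-to-side), creating a
randomly oriented receptor-density gradient that a naive "count active
receptors" readout would confuse with the pheromone direction. The package
models a *ratiometric* readout — G-protein inactivation catalysed by a
receptor-tethered RGS, so output tracks the ratio of occupied to unoccupied
receptors — and contrasts it with a *nonratiometric* readout in which active
G protein decays with one spatially uniform rate constant.

## Steady-state model (`steady_state`)

Local mass-action kinetics for the active G fraction `g` at receptor
occupancy `f`:

* ratiometric: `dg/dt = k_a f (1-g) − k_i (1−f) g`
* nonratiometric: `dg/dt = k_a f (1-g) − k_nr g`

With `β = k_i / k_a` and the two models matched to have equal inactivation
at `f = 1/2` (`k_nr = β k_a / 2`), the steady states are
`g = f / (f + β(1−f))` and `g = f / (f + β/2)`. These are the minimal forms
with all the documented properties: `g = f` exactly at `β = 1`
(ratiometric); profiles convex for `β > 1`, linear at `β = 1`, concave for
`β < 1` (ratiometric) and concave for every `β` (nonratiometric).

The receptor-occupancy gradient is linear, `f(x) = 1/2 + σ(x/L − 1/2)` over
the cell width `L` (default 5 µm); σ ∈ [0, 1] is the steepness normalised to
the maximal 0→100% gradient. The Signal Ratio is
`SR = ΔG*_ratiometric / ΔG*_nonratiometric` where ΔG* is the difference of
`g` between the cell ends. Analytically `SR → 2` as σ → 0 (the derivative
ratio at `f = 1/2`) and `SR = (2+β)/2` at σ = 1, so SR exceeds 2 whenever
β > 2 at steep gradients. The tests confirm both closed forms against
direct numerical integration of the ODEs (an independent oracle in
`tests/_oracles.py`).

Curvature classification uses second differences of a sampled profile with
relative tolerance 1e−10; mixed signs return "indeterminate" rather than
raising, since measured profiles can be non-ideal.

## Particle simulator (`particles`)

Receptors (default 10,000, immobile) and G proteins (default 2,500,
D = 0.002 µm²/s) are points on a sphere of diameter 5 µm. Each step
(dt = 0.1 s): particles take an isotropic tangent-plane Gaussian step
(per-axis variance 2·D·dt) and are re-projected radially — valid because the
per-step RMS displacement (≤ 28 nm) is far below the radius. Bimolecular
reactions use a λ-ρ rule: a G protein within chordal distance ρ = 4 nm of at
least one eligible receptor reacts with probability `p_lambda` (default 1),
one Bernoulli trial per G per channel per step (at `p_lambda = 1` the
per-pair and per-particle semantics coincide). Activation and inactivation
act on disjoint sets (inactive vs active G), so a G changes state at most
once per step. Neighbour queries use a KD-tree over receptor positions,
rebuilt only when receptors move. A single seeded NumPy generator drives
everything; identical config + seed gives bit-identical traces.

Note the deliberate tension in the defaults: the per-step RMS displacement
(~28 nm) exceeds ρ, so encounters are endpoint-sampled and some crossings
within a step are missed. The simulator warns rather than silently changing
either number; encounter rates are therefore *effective* rates, which is
why the nonratiometric rate constant is calibrated by simulation rather
than derived from ρ and `p_lambda` analytically.

Gradients are laid down by rejection sampling with acceptance probability
linear along the gradient axis: a density gradient spans a stated fold
(default 3) between the poles; an activity gradient activates each receptor
with probability linear between `lo` and `hi` (default 40%→60%).

The directional readout is the G-protein vector — the resultant of the unit
position vectors of all active G proteins — summarised by its angle to the
gradient axis (0° = up-gradient; undefined, NaN, when no active G or a
negligible resultant).

**Calibration.** `calibrate_nonratiometric_rate` matches the nonratiometric
`k_inact` to the ratiometric model's steady-state active-G count at uniform
50% occupancy: a log-space bisection against a simulated reference
(burn-in 300 s, 300-s averaging window, 3 seeds, 2% relative tolerance),
with a mean-field initial bracket. At the reduced scale used in the tests
(1,000 receptors / 250 G) this yields k ≈ 0.003 s⁻¹.

**Problem sizes in the tests.** Simulation-level checks run at 1,000
receptors / 250 G proteins with 600–900-s runs and 12–16 seeds per
condition — large enough that the directional phenotypes (density-gradient
invariance of the ratiometric model, density bias of the nonratiometric
model, lower ratiometric orientation noise) are statistically resolvable,
while a full-suite run stays in minutes. At this scale single-run
orientation angles are noisy (a ~115-active-G resultant carries shot noise
comparable to the gradient signal), so "correct orientation" is asserted
as a pooled mean significantly below the 90° random expectation rather
than a small absolute angle; at the full published scale the same readout
is much sharper. Occupancy-equivalence runs start G proteins at the
predicted steady-state fraction (a stationarity test): with an
equilibration time of a few hundred seconds, a cold start would need much
longer runs to separate the fixed point from the transient. The
reaction-limited variant (`p_lambda` = 1e−4) relaxes ~10⁴× more slowly
still at this receptor count, so probability-independence of the channel
balance is tested at the react-step level instead of via long runs.

**Gradient decay.** `gradient_decay_experiment` removes G proteins, lets
receptors carrying a 40→60% activity gradient diffuse for 2,000 s, and
quantifies the gradient as the regression slope of active-receptor counts
in 250-nm bins along the axis. The l = 1 relaxation rate on a sphere is
2D/R², so at D = 5e−4 µm²/s the slope decays only ~25% over 2,000 s —
receptor diffusion does not erase the gradient on the relevant timescale —
while decay grows monotonically with D.

## Reporter model (`reporter`)

`dP/dt = k_s(t) − (k_m + k_d) P`, `dR/dt = k_m P − k_d R` with square-wave
synthesis (`k_s = F` in G1, 1 otherwise), maturation `k_m = 0.123 min⁻¹`
(sfGFP), dilution `k_d = 0.007 min⁻¹` (100-min doubling), G1 = first third
of a 100-min cycle. Because the system is linear with piecewise-constant
input, the periodic steady state is the fixed point of an affine
matrix-exponential map — computed in closed form and used as the oracle for
the repeated-cycle numerical integrator (agreement required to 1e−6).

The observable *fractional change* is `(max R − min R) / R(bud emergence)`,
the normaliser chosen to match how experimental traces are normalised to
the first-bud-emergence time point (min- and mean-normalisers are
available). The map F ↦ fractional change is strictly increasing, so
`required_fold_change` inverts it by bracketed root-finding; with the
default parameters a 20% fluctuation requires F ≈ 5.40. The maturation lag
(1/k_m ≈ 8 min) delays the trace: R keeps falling in early G1 and peaks
shortly after bud emergence.

## Image metrics (`image_metrics`)

**Clustering parameter.** In-ROI intensities are min-max normalised; the
empirical CDF `D(i)` (strict inequality) is evaluated at 500 levels
`i_n = n/500` and `CP = 2·mean(D − U)`, clipped to [0, 1], with U the
uniform CDF. The printed summation form of this metric omits the Δi factor
(its maximum would be ~500); implementing CP as twice the mean restores the
stated [0, 1] range. Both mean and trapezoid quadrature are provided
(difference < 0.3%). Known properties asserted in tests: exact affine
invariance; CP ≈ 0.998 for one bright pixel in 10,000; CP = 0.5 for 25%
bright pixels; and the quirk that a half-bright/half-dark image scores 0.

**MAPK metric.** `m_t = 2 − CV_t / CV_ref`, reference CV at the frame
before fusion; CV of in-ROI pixels proxies the nuclear:cytoplasmic ratio of
the sensor and is scale-invariant, so m is insensitive to expression level.

**Linescans.** Closed-contour profiles are background-subtracted and
normalised to unit trapezoidal integral (or percent-of-max). For averaging,
each scan is circularly rotated to put the peak of a periodic smoothing
spline at the centre; the smoothing factor (default 0.75, mapped to the
spline residual budget `s = factor·n·var`) is an in-spirit equivalent of
R's `smooth.spline` spar — exact knot placement differs, so it is tested
through peak-location robustness only. The side-to-side asymmetry fold is
the mean over the brightest half-contour divided by the mean over the
opposite half; for a single-peak profile the brightest half is the one
centred on the peak, and the max-mean definition guarantees fold ≥ 1 for
arbitrary profiles.

## Geometry and timing (`geometry_stats`)

Orientation is the unsigned planar angle at the cell centre between the
cluster-centroid direction and the reference direction (partner or previous
division site), binned into six 30° segments (half-open, 180° in the last
bin). The "random orientation" null is uniform on [0°, 180°] in the imaging
plane — 1/6 ≈ 17% per segment; a sin-weighted spherical null is available
as an option but is not the default. KS tests use scipy's two-sample
statistic with asymptotic p-values (exact sup-difference verified against
a brute-force oracle); significance threshold 0.05. `bias_analysis`
stratifies by birth order, tests each stratum against the uniform null,
compares strata, and splits indecisive-phase durations at a 60° orientation
threshold.

## FRAP (`frap`)

Bleach-region signal is divided by the whole-cell signal frame by frame
(cancelling acquisition photobleaching), fitted from the first post-bleach
frame with `f(t) = f_inf − (f_inf − f0)·exp(−kt)` (three parameters, so an
immobile fraction is representable), and converted with the circular-spot
half-time relation `D = 0.224 w²/t_half`, `t_half = ln 2/k`. The
exponential is an approximation to the exact Bessel-type recovery curve
and the cell is finite, so recovered D carries a systematic bias that grows
with the spot-to-cell size ratio: with a 1-µm spot in a 2.5-µm-radius cell
the bias reaches ~2.4× at D = 5e−4 µm²/s, with a 0.5-µm spot it stays
within ~1.6× over D ∈ [2.5e−4, 2e−3]. Recovery tests therefore use
w = 0.5 µm. Ordering is preserved throughout: larger true D always yields
larger estimated D, and receptor-like (5e−4) vs v-SNARE-like (5e−3)
regimes separate without overlap at ~12 replicates.

## Synthetic data (`synthetic`)

All generators are pure functions of parameters + seed (bit-identical
outputs) and record their ground truth.

* `gen_cluster_image` — disk cell, uniform background plus an edge Gaussian
  spot carrying a set fraction of total signal; emulates polarity-factor
  images. CP rises with signal fraction, falls with spot width.
* `gen_sensor_image` — cytoplasm at 1, nucleus disk at `nc_ratio`; CV rises
  with `nc_ratio`, so a falling series yields a rising MAPK metric.
* `gen_linescan` — von-Mises bump on a base chosen so the discrete
  half-vs-half fold equals the requested value exactly at zero noise.
* `gen_frap_trace` — explicit finite-difference diffusion in a disk with
  reflecting walls, offset circular bleach spot, 15-s frames over 10 min,
  optional per-frame acquisition fading and Gaussian noise.
* `gen_mating_field` — pairs of first/second-born cells; cluster angles von
  Mises around the partner with stratum-specific concentration κ (κ = 0 is
  exactly the uniform null); neck directions independent; indecisive-phase
  durations lognormal, median 42 min, or 28 vs 46 min split at 60° when the
  duration link is on; partners share a fusion time. Clustering occurs
  5.1 ± 2.8 min after birth; committed-phase median 20 min.

What the generators deliberately do not emulate: optics (PSF, z-stacks,
photon noise statistics), segmentation errors, cell growth or movement, and
receptor endocytosis/delivery. Passing recovery tests therefore shows the
*metrics and estimators* are correct and well-conditioned at realistic
signal levels, not that the upstream imaging pipeline is robust.

## Numerical choices

* Chordal distance for the ρ test (differs from geodesic by < 1e−12 at
  these scales); KD-tree cells are safely larger than ρ plus one step.
* Curvature tolerance 1e−10 relative; asymmetry tie-breaks to the first
  maximal half-window; smoothed-peak ties flag the output.
* Reporter root-finding brackets F in [1, 100]; calibration bisects
  `k_inact` in log space with an auto-expanding bracket and fails loudly
  when it cannot bracket.
* Degenerate inputs are defined, not fatal, where the field does so:
  constant image → CP 0 (flagged); zero resultant → NaN angle; flat FRAP
  trace → explicit fit error.

## Known limitations

* The steady-state model has no diffusion; the particle model has no
  cytosolic (3D) species, receptor turnover, or downstream polarity
  feedback.
* Endpoint-sampled encounters under-count crossings when step RMS > ρ, so
  microscopic rate constants are effective; cross-implementation rate
  comparisons should calibrate, not transcribe.
* The exponential FRAP fit is biased for large bleach spots (documented
  above); the full Bessel-function fit is out of scope.
* Experimental observations (median phase durations, the 3-fold receptor
  asymmetry value, D ≈ 5e−4 µm²/s for Ste2) enter only as generator
  defaults for synthetic data, not as validated outputs.
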