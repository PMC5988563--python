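# Methods

This note documents the models, estimators and numerical choices behind
`lipidsite`, the assumptions they rest on, and what the synthetic benchmark
does and does not demonstrate.

## Contact definition and smoothing

All geometry is computed in nm on orthorhombic periodic boxes with the
minimum-image convention; triclinic boxes are rejected. Two interaction
rules are implemented on minimum bead–bead distances between a lipid and
the protein:

* **headgroup** — at least one lipid phosphate bead within the cutoff of
  any protein bead;
* **whole lipid** — at least four distinct lipid beads each within the
  cutoff of some protein bead.

The cutoff is configurable and defaults to 0.7 nm, the same length scale
used for the residue-coincidence metric below, so a single bead-contact
length scale governs the whole toolkit. Distances (not boolean masks) are
smoothed by a centred running average before thresholding; the window
defaults to 50 frames, i.e. 60 ns at the default 1.2 ns frame spacing, and
is truncated at the series edges so the output length is unchanged. For
even windows the centre sits half a frame left of the window middle.
Smoothing-then-thresholding removes fast on–off flicker but shifts a
threshold crossing by up to about half a window and bridges gaps shorter
than roughly half a window; analyses that need frame-accurate boundaries
(e.g. the generator-closure test) should use a small window or none.

Interaction intervals are maximal runs of interacting frames, closed
`[start, end]` with 0-based frames; durations count frames inclusively,
`(end − start + 1) × frame_spacing`. Intervals touching either trajectory
end are flagged censored: they enter the survival analysis with the windows
they do cover (dropping them would bias against long-lived interactions,
whose true length the finite trajectory anyway truncates) and the flags are
carried through all reports so downstream users can condition on them.

## Survival correlation and residence times

For lipid ensemble `j = 1..N_j` (only lipids with non-zero interaction time
count) the survival time-correlation function on lag grid `t = k·dt` is

```
sigma(t) = (1/N_j) (1/(T−t)) sum_j sum_nu rho_j(nu, nu+t)
```

with `rho_j(nu, nu+t) = 1` iff lipid j interacts continuously over the whole
window. `nu` runs on the same grid (default step 1 ns, decoupled from the
1.2 ns frame spacing by treating intervals in continuous time); windows
extending past `T` contribute nothing, so on the discrete grid the
normaliser is the exact count of admissible start points,
`floor((T−t)/dt) + 1` — the discrete realisation of `1/(T−t)` (the two
differ by one grid step; the count version makes `sigma ≡ 1` exact for a
lipid bound throughout). The lag `t = T` is dropped and the curve is
normalised by `sigma(0)`. The implementation counts windows per interval in
closed form and is verified against an exhaustive window-enumeration oracle.

**Fit range.** `1/(T−t)` amplifies tail variance, and lags covered by only
a couple of very long intervals carry no trustworthy shape information, so
the fit range keeps lags supported by at least 10 raw windows *and* at
least 10 distinct intervals (both configurable).

**Single-exponential fit.** `sigma(t) ~ exp(−t/theta)` by weighted least
squares (`scipy.optimize.curve_fit`), per-lag uncertainty proportional to
`1/sqrt(window count)` — window counts are Poisson-like and early lags are
supported by orders of magnitude more windows than the tail. The initial
theta is the first lag where sigma drops below 1/e (fallback `T/10`). A
curve indistinguishable from 1 raises a degenerate-fit error: the residence
time exceeds the observable window.

**Two-population fit.** `sigma(t) ~ A exp(−t/theta1) + B exp(−t/theta2)`
with `theta1 < theta2`; `theta2` (the long population) is the reported
residence time. The fit is *staged* (exponential peeling): (1) the slow
component is fitted on the tail past the half-decay point; (2) the fast
component is fitted on the early-lag residual together with a constant +
linear nuisance term that absorbs the local leak of the slow fit; (3) the
tail fit is restarted past `8·theta1` once (which matters when the fast
amplitude is large) and (4) amplitudes are re-solved by exact weighted
linear least squares at the staged timescales. A joint 4-parameter
multi-start fit is retained as a fallback. A joint fit used alone is not
identifiable at realistic event counts: sampling fluctuations of the
length-biased slow tail masquerade as a spurious fast timescale, and in
simulation the joint optimum put theta1 at 5–40× truth in about a third of
1000-event replicates, while the staged estimator recovers exact curves to
<1% and mixtures to well within the sampling noise. Guards: a reported
second timescale must satisfy `dt_lag ≤ theta1`, `2·theta1 ≤ theta2 ≤ T`
and both amplitudes must exceed 1e−6; otherwise the curve carries one
resolvable population and the single fit is reported (with a warning).

**Model selection.** `model='auto'` fits both; the two-population model is
kept only when its residual sum of squares beats the single fit (nested
consistency) *and* an F-test with two extra parameters is significant at
alpha = 0.05. Explicitly requested models are honoured.

**Uncertainty.** The lipid set is resampled with replacement (default 1500
times); sigma is rebuilt from cached per-lipid window counts and refitted;
the corrected (n−1 denominator) standard deviation of the fitted residence
times is the reported error. Failed refits are dropped and counted; more
than 50% failures aborts. Identical interval sets give exactly zero SD.

**Leaflets.** The protein surfaces facing the inner and outer leaflet are
two separate interaction surfaces. Lipids are assigned once, at a reference
frame (default 0): inner iff the mean phosphate z lies below the midplane
(the mean phosphate z over all lipids). Planar patches do not flip on these
timescales; a `check_flips` flag re-evaluates per frame and warns. The
overall residence time of a lipid type is the arithmetic mean of its two
per-leaflet values; a missing leaflet propagates NaN with a warning.
MARTINI-style effective time is raw simulation time × 4 (configurable).

## Binding sites

Per frame and per cardiolipin, the residues with any bead within 0.7 nm of
either phosphate bead are tabulated (unsmoothed distances; an atomistic
variant counts per-residue contact frames at 3 Å). For leaflet l,

```
d_l(res_i, res_j) = 1 − pair_counts(i, j) / N_int,l
```

where `pair_counts` counts (cardiolipin, frame) events touching both
residues simultaneously and `N_int,l` counts all (residue, cardiolipin,
frame) contact events in the leaflet — the only normalisation that keeps
`d` in [0, 1] by construction. The diagonal holds `1 − single-residue
count / N_int,l`. Matrices from repeat simulations are averaged elementwise
with weights defaulting to each repeat's `N_int,l` (repeats with more
interaction evidence count more; equal weights are a flag).

Residues with at least one contact are clustered by single linkage
(`scipy.cluster.hierarchy`) on `d`; the dendrogram is cut at height 0.995
by default and clusters below `min_size = 2` are discarded. The cut is high
because `N_int,l` counts every contact in the leaflet, so even strongly
coincident pairs sit near 1; only genuinely recurrent co-contact survives
the cut. Sites are ordered and labelled by lowest residue index
(`inner-1`, `outer-2`, ...); site-class labels for aggregating sites (e.g.
crystallographic vs matrix-helix) are user-supplied.

A site's occupancy timeline assigns, per frame, the cardiolipin contacting
at least `min_residues = 2` of the site's residues (grazing suppression);
ties go to the most residues contacted, then the lowest lipid id. Per-site
(or per-class) residence times reuse the survival machinery on site-contact
masks built from the same table.

## Synthetic benchmark

The generator emulates the statistical structure the estimators assume —
not membrane physics. A static scaffold of one backbone bead per residue
sits on two rings (one per leaflet headgroup plane, 30 residues each,
radius 1.5 nm). Lipids are rigid point clusters (CDL: 2 phosphates + 4
tails; POPC/POPE: 1 phosphate + 2 tails) diffusing laterally as 2-D
Brownian motion (D = 0.01 nm²/ns) with periodic wrapping and Gaussian
positional flicker (0.05 nm). Planted sites bind one lipid at a time:
an eligible free lipid within the 1 nm capture radius binds with
probability `1 − exp(−k_on·w·dt)` per frame (`w` = type-selectivity
weight), sits with its phosphate within 0.7 nm of the site's residues, and
unbinds after a continuously drawn exponential dwell. A nonspecific
background attachment (150 ns mean dwell) models the annular shell.
Unbound lipids are kept outside an excluded-volume shell
(scaffold radius + 0.9 nm) and released lipids honour a short re-binding
refractory, so *every* contact stems from a logged event and the emitted
ground truth is complete. Everything is reproducible bit-for-bit from one
seed.

Default conditions (the standard benchmark): 20 µs effective time at
1.2 ns frames, 40 lipids per leaflet apportioned 9:7:4
POPC:POPE:CDL by largest remainder (18/14/8; a 125-lipid patch gives
56/44/25), three cardiolipin-selective inner-leaflet sites with
`k_off = 5×10⁻⁴ ns⁻¹` (mean dwell 2 µs), optionally mirrored on the outer
leaflet. These sizes mirror the regimes of interest — microsecond-scale
specific sites over a ~150 ns background — while keeping a full pipeline
run under a minute.

What passing tests on this generator show: the contact rules, interval
extraction, sigma window counting, exponential fitting, clustering and
occupancy logic are correct, and the pipeline recovers planted kinetics
and site memberships under realistic event counts. What they do not show:
robustness to membrane undulations, leaflet flip-flop, protein flexibility,
intra-lipid dynamics, electrostatics or force-field realism — none of which
the generator models.

Ground-truth events are discretised to frames by round-half-up on
`time/frame_spacing`. With raw (unsmoothed) masks the extracted intervals
match ground truth within ±1 frame at every boundary (the rounding
convention itself accounts for the ±1); any centred smoothing window can
shift a boundary by one more frame, so the smoothed closure check allows
±2.

## Numerical and degenerate-input conventions

* Frames are 0-based; intervals closed; box lengths per frame.
* The fixture text format writes floats with shortest round-trip repr, so
  write→read is bitwise.
* Lipids with no intervals are excluded from `N_j`; an ensemble with none
  raises an estimation error rather than returning NaNs.
* An all-identical-z membrane yields a one-leaflet assignment with a
  warning; a trajectory without cardiolipin yields empty contact tables
  with a warning; `N_int,l = 0` yields an all-ones distance matrix with a
  warning.
* Clustering tie-breaks are deterministic (scipy's linkage order; sites
  sorted by lowest residue index), bootstrap resampling uses a single
  `numpy` Generator seeded from the run seed, and pipeline outputs are
  byte-stable for a fixed config + seed (the config hash excludes the
  output directory).

## Known limitations

* Residence times approaching the trajectory length are under-estimated
  (censoring); such fits raise or flag degeneracy rather than extrapolate.
* The two-population fit needs the timescales separated by at least ~2×
  and a resolvable fast amplitude; closer mixtures are reported as one
  population.
* The d-metric cut height and minimum cluster size are conventions, not
  estimates; on sparse data (short trajectories) background co-contact
  strings can form transient clusters, which show up with near-background
  residence times and low occupancy.
* Whole-lipid mode cannot trigger for the generator's 3-bead POPC/POPE
  models (they have fewer than four beads); synthetic benchmarks therefore
  use headgroup mode, and whole-lipid logic is validated on toy fixtures.
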