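# Methods

This note records what `dgmap` computes, the assumptions behind each stage,
the parameters that matter, and what the synthetic fixtures do and do not
establish about real recordings.

## Electrode geometry

The recording model is a stack of parallel tissue layers (default 6, 12 mm
apart, stacked along +z with layer 0 basal), each instrumented with 10
plunge needles carrying 4 terminals at 4 mm spacing along the shaft.  Two
canonical layouts (`config_id` 1 and 2) are provided as stylized two-cavity
cross-sections: six needles radial to the left-ventricular (LV) cavity
(terminal radii 13/17/21/25 mm) and four radial to the right-ventricular
(RV) cavity (9/13/17/21 mm), with LV centre at (0, 0) and RV centre at
(22, 0) mm.  Absolute electrode positions in experiments of this kind are
visual estimates, so no claim of anatomical fidelity is made beyond the
length scales; the azimuths are chosen so that closed electrode rings exist
around the LV cavity, around the RV cavity (closed on the septal side by
the two LV needles facing the septum), and around both cavities jointly,
each ring's hops staying inside the neighbor radius.  Cavity axes are
vertical lines through the two cavity centres plus a combined axis at their
midpoint.

**Neighbor rule.** k-nearest within a hard radius, symmetrized by union:
defaults `max_distance = 15 mm`, `max_neighbors = 14`.  The radius must
span the inter-needle gaps (10–15 mm) without bridging a cavity; the count
must admit the azimuthal hops between adjacent needles (12.4–14.2 mm on the
canonical layouts) after the closer same-needle and same-vertical
electrodes (4–12.6 mm) have taken their slots — with k = 8 those hops never
qualify and the lattice falls apart into needle columns, so 14 is the
smallest comfortable choice.  Both values are configurable.

## Synthetic activation patterns

All generators are kinematic phase maps — pure functions of (grid,
parameters, seed) with exact ground truth — not reaction–diffusion
simulations.  What they deliberately omit: wavefront curvature effects,
restitution, conduction anisotropy, rotor meander, and beat-to-beat
variability.  Consequently, passing the recovery tests shows the *pipeline*
is correct on idealized inputs; it does not show robustness to the full
physiological repertoire (jitter and dropout stressors in `perturb` cover
the first-order degradations only).

- **focal**: `LAT(e) = t0 + dist(e, origin)/cv` per beat; default
  cv 0.8 mm/ms (mid-range ventricular), beats several hundred ms apart.
- **planar**: `LAT(e) = t0 + ⟨pos(e), n̂⟩/cv`; the negative control — no
  cycles, no interior sources.
- **rotor**: `LAT(e, k) = t0 + CL·(θ(e)/2π + k)` with θ the azimuth around
  an arbitrary core axis.  The default fixtures use a *horizontal*
  intramural axis (a scroll-wave filament lying in the wall): with 4 mm
  transmural and ~13 mm azimuthal electrode spacing, rings that encircle a
  vertical intramural core at velocity-consistent hop times do not exist
  on this lattice, whereas the transmural (terminal × layer) lattice
  supports them.  Near the core the phase map implies arbitrarily slow
  apparent conduction; the velocity gate removes those hops, which is the
  physiological behaviour at a rotor core.
- **macro_reentry**: as rotor but around a cavity axis (LV, RV, or the
  combined axis), with events restricted to the grid's per-cavity
  *encircling wall sets*: all LV needles for LV; RV needles plus the septal
  LV needles for RV; everything except the innermost septal terminals for
  "both" (those terminals sit between the axes and would let a loop cut
  through the septum rather than encircle both cavities).
- **electrograms**: each LAT is rendered as a derivative-of-Gaussian
  biphasic wavelet (σ = 5 ms, ~20 ms footprint, unit peak) whose steepest
  negative slope falls exactly at the LAT sample, making the annotation
  rule exactly invertible; focal-origin electrodes get a QS morphology
  (negative lobe only).  Gaussian noise is specified relative to unit peak.

## LAT annotation

Markings are minima of the trace's first difference, each the most negative
within a sliding 200 ms window; a marking survives only if the peak
absolute amplitude within ±10 ms reaches 10% of the electrode's *average
peak amplitude*, interpreted as the mean absolute peak over that
electrode's own detected deflections (the only self-contained reading).
Rejected markings are rescued when a neighboring electrode holds an
accepted LAT within 10 ms — the tolerance quantifies an otherwise
qualitative "close enough" rule and equals the amplitude-check half-window.
Manual curation is an explicit add/remove overlay table rather than a GUI,
which keeps edits reproducible and diffable.

## Activation graphs

Defaults `cv_min = 0.2 mm/ms`, `cv_max = 2.0 mm/ms` bracket human/canine
ventricular conduction; both are open bounds, so `ΔLAT = 0` (undefined
direction, infinite apparent speed) never draws an edge.  At build time `t`
each electrode contributes its LAT nearest to `t` within `lat_window`
(default: one estimated activation cycle length, the median
same-electrode inter-activation interval).  The merge offset `delta_t`
defaults to half that cycle length, which places the LAT discontinuity of
any loop at opposite phases in the two graphs regardless of the loop's
timing.  Frames are computed every `step = 50 ms`.

## Reentry analysis

**Cycle enumeration.** Elementary directed cycles up to `max_len = 12`
electrodes via bounded Johnson enumeration, with a per-frame cap of 2000
cycles.  The longest minimal encircling ring on the canonical layouts is 10
electrodes, so 12 retains every loop class; beyond that, additional cycles
are chord-variants of loops already found, which the clustering condenses
anyway — the cap bounds a combinatorial blow-up on dense, highly consistent
merged graphs at no cost to the detected reentry set.

**Impossible-loop filter.** (a) Self-crossings: non-adjacent segments
passing within 0.5 mm of each other after projection onto the cycle's
best-fit plane (exact 3D crossings are measure-zero).  (b) Sharp
doubling-back: at any vertex, if the cosine of the angle between the two
incident segments (vectors from the vertex to its cycle neighbors) exceeds
0.75, the trajectory is unphysiological.  Under this convention a U-turn
gives cos → +1 (excluded) and a straight pass-through cos → −1 (kept); the
alternative convention (angle between successive direction vectors) would
do the opposite and reject smooth loops.

**Grouping.** DBSCAN over cycle centroids, `d_eps = 10 mm`, `min_pts = 2`,
with the classical self-inclusive core rule `|N_eps(p)| ≥ minPts` by
default; a `strict_core` flag switches to the strict `>` variant, under
which a pair of coincident detections would be demoted to noise.  Noise
points are retained as singleton reentries — a lone clean loop is still a
reentry.  Distance is Euclidean between centroids only; loop shape and
extent do not enter, which is adequate for comparing episodes of the same
recording type but too coarse for absolute loop counting.

**Classification.** Winding numbers of the cycle polygon around the LV and
RV axes (projected perpendicular to each axis; |winding| used, so
orientation does not matter).  Both ≥ 1 → `biventricular`; exactly one →
`holo_LV` / `holo_RV`; neither → `localized`.  A loop that encircles both
cavities necessarily winds around each single-cavity axis as well, so
"encircles both" is the defining test for biventricular loops; the combined
axis is kept in the geometry for reference but is redundant to the
classification.  A DBSCAN cluster can contain cycles of several classes;
the cluster takes the modal class of its members (ties broken toward the
more extensive class), and a track takes the modal class of its frames.

**Tracking.** Greedy nearest-centre matching between consecutive frames
within `linking_radius = d_eps`; unmatched clusters open tracks, unmatched
tracks close.  No rule for this linking is established in the mapping
literature at this resolution; greedy matching is the simplest
order-independent-enough choice and is exposed for replacement.

**Profiles.** Simultaneous-loop counts are integrated over reentry-present
time; fractions per count sum to 100% of that time, the mean is
time-weighted, and the holo fraction is the share of reentry-present time
during which at least one concurrent track is holo- or bi-ventricular.
Episodes with no reentry report a null holo fraction and mean 0.

## Focal analysis

Candidates are merged-graph nodes with outgoing edges only, deduplicated by
(electrode, LAT).  Verification automates what is usually a manual
electrogram reading: confirmed iff the positive excursion in the 15 ms
before the LAT stays within 10% of the trace's mean peak amplitude (the
same fraction as the annotator's amplitude check), and iff that pre-LAT
baseline was actually recorded — a candidate activating at the first
recorded sample cannot be verified and is rejected.  Without electrograms a
pre-LAT silence criterion substitutes: no neighbor activation within 50 ms
before the candidate.  Heatmaps are per-electrode counts aggregated per
subject.  The randomness reference is the binomial occupancy null
`p_x = C(n,x)(1/e)^x (1−1/e)^(n−x)`; rows with observed electrodes where
the expected electrode count falls below 0.05 are flagged as hotspots.  No
formal goodness-of-fit p-value is attached: the observed/expected table is
the deliverable, and the flag operationalizes "essentially impossible under
uniform placement".

## Episode statistics

Episodes lasting ≥ 10 s are labelled non-terminating (NT) — by protocol
such episodes are terminated by defibrillation — otherwise self-terminating
(ST).  Group comparisons use the Mann–Whitney U with `U = min(U1, U2)` and
half-credit ties.  For pooled sizes ≤ 25 the full permutation distribution
(all `C(n1+n2, n1)` group assignments) is enumerated, so the p-value is
exact even with ties; beyond that the tie-corrected normal approximation
with continuity correction is used.  One-sided p is the lower-tail
probability of the observed minimum U; two-sided counts both tails.
Sidedness is always reported explicitly because small-sample U tests are
frequently quoted without it.

## Numerical choices and degenerate inputs

- Ties in LAT (`ΔLAT = 0`) draw no edge anywhere; this also makes
  single-time graphs DAGs by construction.
- Two-node cycles (mutual edges from the two merged graphs) are discarded:
  a reentry needs ≥ 3 distinct electrodes.
- Winding numbers are rounded sums of wrapped angle increments; cycles
  passing exactly through an axis are not meaningful at 4 mm resolution and
  are not special-cased.
- The best-fit plane for the crossing test comes from an SVD of the
  centred cycle points; for degenerate (collinear) cycles the angle filter
  removes the cycle first.
- `simultaneous_profile` breaks time at every track boundary *and* every
  frame time, so within-track class changes are integrated exactly.
- All randomness is through `numpy.random.default_rng(seed)`; pipeline
  outputs embed the resolved configuration and seed.

## Problem sizes used in the shipped tests

Recovery fixtures use the full 240-electrode grid with 3–5 rotations at a
200 ms cycle length (600–1000 ms episodes, frames every 50 ms) and 3–5
focal beats; property suites use 1000 random 20-point clustering instances,
150 random ≤ 10-node digraphs against exhaustive cycle search, and 10⁵
Monte-Carlo occupancy draws.  These sizes exercise every code path while
keeping the suite around a minute or two on one CPU.

## Known limitations

- Localized reentry cannot be split into functional vs anatomical at this
  electrode density, and rotor meander is not tracked; both are out of
  scope by design.
- The loop-grouping is suitable for within-study comparisons, not for
  absolute loop counts.
- The synthetic electrogram is a single-wavelet model: no far-field
  components, fractionation, or baseline wander; the annotator's rescue
  rule is therefore exercised only by constructed cases.
- Classification assumes cavity axes perpendicular to the layer planes; a
  strongly oblique recording would need re-anchored axes.
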