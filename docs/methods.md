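# Methods

This note documents the models, conventions and numerical choices behind
loomkit, what the synthetic generator does and does not emulate, and the
package's known limitations.

## Coordinate and timing conventions

Coordinates are centimetres; x/y span the arena floor and z is height.
Times are seconds, frames are 0-based, and every interval (bouts, windows,
segments) is half-open `[start, end)`. One convention is used everywhere
and asserted at module boundaries.

## Arena model

The assay arena is a circular open field (diameter 50 cm) with a concentric
trigger circle (diameter 25 cm) and an adjoining 50 × 10 cm refuge alley.
Published descriptions of such rigs do not fix the refuge's exact placement
or the entrance geometry, so loomkit adopts a convention: the refuge
rectangle is tangent to the field circle on the +y side and the entrance is
a 10-cm segment of the shared wall centred on the tangency point. Because
circle and rectangle meet only at a point, a thin "doorway" band (entrance
width × 1 cm) is included in the valid domain so trajectories can cross the
wall anywhere within the entrance. Point-in-region tests are strict for the
trigger circle (the boundary counts as outside) and closed for the refuge
rectangle; the trigger circle and refuge are geometrically disjoint, so
centre and refuge occupancy can never overlap.

## Stimulus protocol

The looming stimulus is a dark overhead disc expanding linearly from 2° to
40° of visual angle in 300 ms, held for 50 ms, and repeated 15 times with
30-ms inter-stimulus intervals (total 5 670 ms); the auditory variant is
80 dB SPL broadband noise for 5 s. The profile generator reproduces this
piecewise ramp/hold/gap curve; the behavioural simulator only uses the
onset time, since the animal's response is modelled at the level of
movement scheduling, not visual physics.

## Skeleton and landmark roster

The pipeline operates on 16 body landmarks. Their identity and order are a
package convention (upstream pose estimation is out of scope): nose, both
ears, neck, three spine points, tail base, four limb points and four paws.
The five torso landmarks (neck, spine1-3, tail base) define the centroid
and the heading axis (tail base → neck). The default capture rate is 30 Hz
and is configurable; it is likewise a package convention, not a measured
property.

## Synthetic trial generator

A trial is a schedule of motif legs (walk to a waypoint, sniff, rear,
freeze, ...) executed along a path inside the arena. The default scenario
reproduces the assay's event chain: acclimation wandering in the annulus
between trigger circle and wall, an approach into the trigger circle
(stimulus onset = first entry), a short threat-detection pause, a 45 cm/s
escape run through the entrance, refuge behavior (a freezing bout for
Freezing animals, sniffing otherwise), refuge exit and re-exploration.
Non-escaping animals skip the flight and keep exploring; a Freezing
non-escaper freezes in place in the field, so an animal's Freezing status
is drawn independently of its escape status.

Each motif template deforms a canonical 16-point pose with motif-specific
kinematics; the parameters were chosen once as field-plausible values:

| motif | speed (cm/s) | signature |
|---|---|---|
| walking / trotting / running / flight | 8 / 18 / 35 / 45 | diagonal gait, swing amplitude 1.2-1.8 cm |
| stepping | 4 | small slow steps |
| left/right turning | 3 | ±120°/s heading change, ±2.5 cm lateral spine bend |
| looking up / stretching up / rearing | 1.5 | nose raised 2.5 / 4.5 / 5.5 cm, trunk raised |
| hunching | 1.5 | retracted head, arched trunk |
| sniffing | 2.5 | 7-Hz head bob, amplitude 1.2 cm |
| grooming | 1.5 | head turned to flank, 4-Hz cyclic head motion |
| freezing | 0 | complete immobility |

Only head/limb/paw points carry oscillations, so a leg's torso-centroid
speed equals its path speed exactly — planted locomotion is recoverable to
numerical precision. Measurement noise is isotropic Gaussian per landmark
per frame (default sd 0.2 cm), the simplest model that supports recovery
testing. Cohorts draw each animal's Freezing status from its sex's
probability and escape from `p_escape` (default 0.9, the typical escape
rate of the assay); per-animal seeds spawn from one root seed, so cohorts
are bit-reproducible.

The generator emulates the *structure* of assay recordings: event chains,
motif-specific kinematics, landmark noise, sex-specific freezing odds. It
does not emulate pose-estimation artefacts (occlusion, identity swaps,
non-isotropic error), postural variability within a motif class, individual
behavioural idiosyncrasy, or any visual physics. Tests passing on this
generator therefore demonstrate that the pipeline recovers planted
structure under realistic noise — not that it resolves every ambiguity of
real videos.

## Motion decomposition

Locomotion is the centred finite-difference speed of the torso centroid,
boxcar-smoothed over 5 frames. Egocentric alignment removes translation
(centroid to origin) and heading (tail-base→neck to +x) per frame, keeping
height; features are the 48 aligned coordinates plus their frame-to-frame
deltas. Deltas are computed on coordinates pre-smoothed with a 3-frame
boxcar and scaled ×3: raw single-frame differences of noisy landmarks are
dominated by noise (σ√2 per coordinate), and without the re-weighting,
motifs that share a posture but differ in movement (walking vs freezing)
would be indistinguishable in frame distances. Both knobs are exposed.

Segmentation uses non-overlapping 0.4-s windows (12 frames at 30 Hz; the
last window may be shorter), optionally merging adjacent windows whose mean
features are closer than a threshold. Sub-second windows match the
timescale of single steps, sniffs and head movements. Segment speeds are
z-scored across the cohort (population sd; per-animal mode available) and
negative z-values are clipped to zero — only positive normalised velocity
enters the feature space. Zero-variance speed vectors yield all-zero
locomotion with a warning rather than an error.

## DTAK

The kernel follows the canonical max-formulation dynamic program with
diagonal weight 2 and path-length normalisation n+m (see README for the
recursion); segments of unequal length are compared directly, without
resampling. The local-kernel bandwidth defaults to the median heuristic —
the median pairwise frame-feature distance over a pooled subsample of at
most 500 frames. DTAK matrices are not guaranteed positive semidefinite,
so the embedding consumes the dissimilarity `d = √(2 − 2k̂)` rather than an
eigendecomposition. The dynamic program is checked against an exhaustive
enumeration of monotone alignment paths on segments up to 4 × 4 frames.

## Behavior map

UMAP (n_neighbors 15, min_dist 0.1, fixed seed, exact mode) embeds the
dissimilarity into (UMAP1, UMAP2); the clipped z-scored speed is the third
dimension. Clustering defaults to Ward agglomerative — deterministic and
k-controllable — with k-means and a density-based (DBSCAN) mode as
alternatives; cluster IDs are relabelled 1..k by descending size, so
phenotype 1 is always the most common. The default phenotype→movement
designation table ships the reference 40-phenotype assignment; since
cluster IDs depend on the data, that table is meaningful for the solution
it was designated on — users designate their own phenotypes after inspecting the
per-phenotype summaries (mean skeleton and normalised moving intensity,
i.e. mean per-frame landmark displacement scaled so the most vigorous
phenotype is 1).

Flight and freezing are detected by kinematic rules rather than clusters,
because they are defined by stimulus context: flight is the first run of
≥ 0.2 s with speed ≥ 20 cm/s after stimulus onset whose net displacement is
toward the refuge entrance; freezing is any run of ≥ 0.5 s with centroid
speed ≤ 1 cm/s and mean landmark speed below threshold. The two detectors
use different speed channels: flight onsets need frame accuracy (light
smoothing), freezing needs a stable near-zero baseline (15-frame position
boxcar), and freezing bout edges are refined against the raw speed so
durations are accurate to a frame or two despite the smoothing. All
thresholds are configuration-exposed; how the original assay scored these
bouts operationally is not recoverable, so these rules are package
definitions.

## Trial metrics

Responsive latency is flight onset minus trigger; return time is the first
refuge entry after the trigger; mean return speed divides the *path length*
(not displacement) from trigger to entry by the return time; refuge time is
the dwell from that entry to the next exit. "Initial distance to refuge" is
measured to the entrance-segment midpoint. Acclimation occupancy is
reported both as refuge-to-outside ratio (NaN sentinel if the animal never
left the refuge) and as refuge fraction of total time, since both ratio
conventions appear in common use. An animal "escaped" if flight was
detected and the refuge reached within 30 s of the trigger (configurable);
escape-dependent metrics are absent otherwise.

## Ethogram statistics

Ethograms are per-frame label streams over the 14 categories (12 movements
plus flight and freezing), run-length encoded into bouts. Epoch windows are
pre ([−60 s, 0) relative to stimulus onset), escape ([0, refuge entry)) and
refuge ([entry, exit)); bouts are clipped to windows and clipped durations
sum to the window length. Fractions are time shares (summing to 1, with an
explicit residual category if a window outruns the trial); frequencies are
raw bout counts per window with a per-minute rate as a secondary column — a
bout spanning a window edge counts once. Transition matrices are
row-stochastic over the bout sequence with a structurally zero diagonal.
An animal is in the Freezing group iff at least one freezing bout starts at
or after stimulus onset.

Group comparisons fit a two-way (group × movement) ANOVA on per-animal
fraction tables (untransformed by default; an arcsine-square-root option
exists because fractions are bounded) with per-movement two-sample
contrasts adjusted by Holm–Šídák; multi-level designs (age) use Tukey HSD
within movements. Holm–Šídák controls the family-wise error rate, so the
calibrated null property is that the *family* rejects in ≈ α of runs; the
per-contrast null rate is necessarily far below α. Calibration and power
checks simulate per-animal fraction tables directly (Dirichlet
compositions) rather than full cohorts, which keeps 200-run calibration
suites fast without changing the statistical question.

## Problem sizes

Default verification sizes, chosen to give tight statistical bounds at
interactive runtimes on one CPU: 500 random segment pairs for the DTAK
oracle; 6 motif classes × 30 segments for recovery (ARI); 50 trials with
60-s acclimations for detector fidelity; 1 000 animals per sex (5-s
acclimations, trajectories only) for proportion recovery, where the
binomial 3σ on a proportion of 0.7 is ≈ 0.043; 200 runs of 20 + 20 animals
for null calibration. The trial generator's default acclimation is 60 s — a
scaled-down stand-in for the assay's 5-min habituation, available in full
via configuration.

## Known limitations

- The DTAK variant (max recursion, diagonal weight 2, n+m normalisation,
  Gaussian local kernel) is the canonical definition, stated here rather
  than recovered from any particular prior implementation.
- UMAP determinism holds for a fixed seed and version; embeddings are not
  comparable across library versions.
- The default label-mapping table applies to the clustering solution it
  was designated on; any new dataset requires manual designation.
- Freezing/flight thresholds are calibrated for the generator's kinematics;
  real recordings may need re-tuning (all thresholds are exposed in
  configuration).
- The statistics module implements fixed-effects ANOVA on fractions;
  repeated-measures or mixed-model designs are out of scope.
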