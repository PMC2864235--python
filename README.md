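# skelopod

Automated detection, tracking and statistical characterisation of
**pseudopodial activity** in time-lapse movies of amoeboid cells.

Amoeboid motility — the crawling of *Dictyostelium*, neutrophils and
other cells — proceeds by cycles of membrane protrusion and retraction.
Global shape descriptors (velocity, roundness, chemotactic index) often
cannot separate phenotypes that differ only in *how* individual
pseudopods extend, retract and split. `skelopod` extracts that local
information automatically from single-cell movies acquired by
fluorescence, phase-contrast or DIC microscopy, and can correlate it
with the membrane localisation of fluorescently tagged proteins.

## Method at a glance

For each frame the cell is segmented into a binary mask `I_n`, its
boundary smoothed with a closed uniform quadratic B-spline, and the
**medial-axis skeleton** `S_n` computed — the locus of centres of
maximal inscribed balls, so every membrane protrusion contributes a
skeleton branch. Branches are pruned by two criteria (length threshold
*p*<sub>threshold</sub> = body length/10 with combine/delete ratio
*r* = 1.5; terminal-to-membrane distance threshold
*PrDist*<sub>threshold</sub> = body length/6) until each pseudopod maps
to exactly one outer branch.

Between consecutive frames, the growing region `I_{n+1} \ I_n` and
withdrawing region `I_n \ I_{n+1}` are intersected with the skeletons:
a growing component entered by a branch of `S_{n+1}` is a
**protrusion**, a withdrawing component entered by a branch of `S_n` a
**retraction**, each with a membrane start point `(x, y)`, an angle θ
relative to the chemoattractant gradient, a time `t` and a length (the
branch arc inside the region). Activities are then clustered
**backwards in time** into pseudopod lineages using a distance score

    score = R · √( [β·(D/R)² + (1−β)·Θ²] · Δt/Δt_frame ),

with D and Θ the first/second-order spatial and angular differences of
the candidate link (weights α = β = 0.5, cell radius R = 5 µm), joined
when the score is below *Dist*<sub>threshold</sub> = perimeter/10 within
a lifetime window T = 50 s; a split is recorded when two tracks claim
the same earlier activity as their ancestor. Per-pseudopod statistics
(lifetime, protrusion/retraction ratio and speed, state persistence,
angle dynamics, splitting behaviour), cell-level summaries, hierarchical
activity ranking and Gaussian fits of protrusion-angle histograms
follow, plus the normalised space-time cross-correlation
`C(Δk, Δθ)` — a `(360/Δθ) × (2N−1)` matrix — between activity and
membrane-intensity signals `A(k, θ)`, `I(k, θ)`.

A fully scripted **synthetic-movie generator** renders blob-like cells
with finger pseudopods and closed-form ground truth (masks, per-frame
activities, lineages, coupled fluorescence), so the entire pipeline is
testable without microscopy data.

## Worked example

```python
from skelopod import PipelineConfig, PseudopodEvent, analyze_movie, render_movie
from skelopod.stats import pseudopod_stats_table

events = [
    PseudopodEvent(theta0=0, t_start=30, duration=60, growth_rate=4),
    PseudopodEvent(theta0=120, t_start=50, duration=50, growth_rate=3,
                   retract_rate=3, retract_delay=20),
]
movie, truth = render_movie(events=events, n_frames=20, seed=1)
result = analyze_movie(movie, PipelineConfig())

print(f"{len(result.activities)} activities in {len(result.pseudopods)} pseudopods")
table = pseudopod_stats_table(result.pseudopods, frame_interval=10.0, pixel_size=0.2)
cols = ["pseudopod_id", "lifetime", "n_activities", "protrusion_ratio",
        "state_persistence", "net_speed", "mean_angle", "origin"]
print(table[cols].round(2).to_string(index=False))
```

prints

```
14 activities in 2 pseudopods
 pseudopod_id  lifetime  n_activities  protrusion_ratio  state_persistence  net_speed  mean_angle  origin
            0     100.0             8               0.5                0.4        0.0      122.81 de_novo
            1      60.0             6               1.0                1.0        4.6       -0.67 de_novo
```

Pseudopod 1 is the scripted pure protrusion up the gradient
(mean angle ≈ 0°): six activities over a 60 s lifetime, all
protrusions (ratio 1.0, state persistence 1.0), advancing the membrane
at 4.6 µm/min. Pseudopod 0 is the second event at 120°: it protrudes
and then retracts (ratio 0.5), so its longest consistent state covers
0.4 of its 100 s lifetime and its net membrane displacement is zero.
Both formed de novo — no splits were scripted.

The same pipeline runs from the shell:

```bash
skelopod simulate --out sim --n-frames 20 --seed 1
skelopod analyze sim/movie.tif --out results
skelopod stats results
```

writing masks, boundary curves, a skeleton branch table, activity and
pseudopod CSVs, cell-level statistics JSON and the resolved
configuration. `skelopod correlate` adds the `(Δk, Δθ)` correlation map
and site-intensity pairings for a second fluorescence channel.

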