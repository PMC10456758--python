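# Methods

## The measure

For a configuration of N agents, a neighbor graph is built and one distance is
collected per agent–neighbor incidence (each undirected edge contributes
twice; the factor of 2 cancels in the probabilities, so per-edge counting
gives identical entropies — covered by a test). Distances are binned into
uniform right-open bins `[k·w, (k+1)·w)` anchored at 0; anchoring at the
origin makes results independent of the sample minimum. With `pᵢ = Xᵢ/X`,

- `H_NDist = −Σ pᵢ log₂ pᵢ` (bits),
- `H_NDist,norm = [H_NDist + Σ pᵢ log₂ wᵢ] / log₂(Σ wᵢ)`,

where `Σ wᵢ` runs over **all** bins of the span, empty ones included (an
occupied-only span would let a delta distribution normalize to 1). The
normalized form is the plug-in estimate of a differential entropy divided by
the log-span, so a histogram uniform over its span scores exactly 1 and values
are comparable across bin sizes. Spans of ≤ 1 length unit make the normalizer
non-positive; this raises a domain error advising a smaller length unit.
Distances and bin widths share one length unit (pixels for tracked data,
simulation units otherwise); the default bin size is 1 unit, which should be
kept below the particle radius of the system under study — coarser bins wash
out the small distance shifts that carry the signal, and H_NDist decreases
with increasing bin size (cell merging cannot raise Shannon entropy).

Numerical details: a distance lying within 1e-9 bin widths below a bin edge is
snapped up to that edge's bin, so geometrically equal distances that differ
only by floating-point rounding (a perfect lattice) land in a single bin.

## Neighbor graphs

**Topological.** Two agents are neighbors iff their Voronoi cells share an
edge, computed as Delaunay adjacency (scipy/Qhull). Periodic boundaries tile
the box 3×3 with ghost copies, keep ridges incident to the canonical copy, and
map back with minimum-image distances; on generic points this satisfies
2E = 6N exactly (Euler's formula on the torus), which is asserted in tests.
Co-circular degeneracies (e.g. square lattices) are broken by a deterministic
jitter of 1e-9 × box from a fixed internal seed; distances are always computed
on the unperturbed coordinates, so the tie-break never moves the histogram.
Open-boundary tessellations keep adjacencies of unbounded border cells: only
distances are consumed downstream, and no clipping rule is imposed.

**Metric.** All pairs within radius R (closed comparison, `≤ R`, fixed for
determinism), via a k-d tree; periodic queries use the tree's toroidal mode,
falling back to a dense minimum-image scan when R exceeds half the box.

## Boid model

Point-like agents at constant speed V in a periodic box. Per step and per
agent, three social forces over the neighbor set φ:
separation `Σ (rᵢ−rⱼ)/rᵢⱼ²`, alignment `(Σ vⱼ)/nᵢ − vᵢ`, cohesion
`(Σ rⱼ)/nᵢ − rᵢ`, each normalized to unit length before summing (a term of
norm < 1e-12 is dropped rather than divided by ~0; agents without neighbors
feel no force). The new heading is the quadrant-aware angle (atan2) of
`vᵢ + S·Fᵢ`; uniform noise in (−η, η) degrees is then added per agent per
step, the speed is reset to exactly V, and positions advance by `v·Δt` with
periodic wrapping. Displacements and neighbor centroids use the minimum-image
convention throughout. The neighbor graph is rebuilt every step. Runs are
bitwise reproducible from a single integer seed (one generator drives both
initialization and noise).

### Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| N | 200 | — | large enough for stable Voronoi statistics, small enough for desk runs |
| box | 1000 × 1000 | length | matches the standard simulation domain |
| V | 2 | length/step | a small fraction of the box per step |
| S | 0.1 | — | accepted range 0.001–0.1 (warning outside) |
| η | 0 | degrees | half-width of the per-step angular noise |
| Δt | 1 | step | time is measured in steps |
| w (bin) | 1 | length | below the particle scale of typical tracked data |

**The speed sets the noise crossover.** The steering torque per step scales as
S·|F|/V, so for fixed S the noise level at which alignment collapses scales
like 1/V. With S = 0.001 (the noise-sweep condition) and V = 2, all of
η ∈ 1–7° sit deep in the disordered phase and the sweep shows no transition.
The sweep driver (`sweep_base_params`) therefore uses **V = 0.4**, placing the
alignment transition at η ≈ 3–4°, where it is observed in the reference
system; a coarse scan over V ∈ {0.05, …, 2} confirms the 1/V shift of the
transition. This is the one place the package deliberately departs from the
"only V·Δt relative to box size matters" intuition: it is true for zero-noise
runs but not for the noise sweep.

### Experiment drivers and problem sizes

- **Zero-noise evolution** (alignment first, positional order second):
  N = 100, box 1000², S = 0.1, V = 2, 8000 steps. v_a is recorded every step;
  H_NDist every 250 steps — four samples per steady-state window, coarse
  enough to average over H's per-step sampling fluctuation (~0.05 bits).
  Steady-state statistics use the final 1000 steps (population std, ddof = 0).
- **Noise sweep** (η ∈ {0,…,7}°, S = 0.001): N = 100, box 500² (the model
  never fixes N, so density is a scaling choice; the smaller box reaches
  spatial steady state at desk scale), V = 0.4, 8000 steps, 3 independent
  seeds per η, mean ± std across seeds of last-1000-step window means.
  Metric-mode default radius R = 100 = twice the mean spacing, giving ~12
  metric neighbors versus ~6 topological ones; R is otherwise a required
  user parameter, since no canonical value exists.

## Synthetic stand-ins

The generators emulate the *states* whose tracked coordinates the measure is
meant to analyze, not their dynamics or imaging artifacts:

- `hexagonal_lattice` — the H_NDist = 0 calibration point (all neighbor
  distances equal). Periodic rows must be even to stay commensurate.
- `jittered_lattice` — uniform displacement per site; any positive amplitude
  makes H_NDist strictly positive while the mean Voronoi degree stays 6.
- `uniform_gas` / `gaussian_clusters` — dispersed versus aggregated steady
  states at equal N and box. Cluster centers are resampled until ≥ 6σ apart.
- `gas_series` / `aggregated_series` — frame sequences standing in for
  steady-state videos. A gas decorrelates between frames, so gas frames are
  independent draws; an aggregate persists, so its frames rattle around a
  fixed cluster structure with amplitude σ/10 (caged motion). Under this
  emulation the entropy time series of the gas fluctuates ~2× more than the
  aggregate's. Note that applying the *same* small jitter to both fixtures
  would invert the ordering — a uniform gas's entropy is self-averaging —
  which is why the series generators model configurational renewal rather
  than positional jitter.
- `letter_configuration` — hexagonal close packing masked by fixed 5×7
  glyph bitmaps (defined in `glyphs.py`); open boundary, fully deterministic.
  Letter entropies differ because edge sites contribute different distance
  profiles; the exact values depend on the repo's glyph geometry and serve as
  regression constants, not physical predictions.

What passing tests on these stand-ins do **not** show: robustness to tracking
noise, missed detections, or perspective distortion in real video data; the
CSV reader accepts such data, but the validation here is on clean synthetic
geometry.

## Design choices in open territory

- Histogram span is per-configuration (per frame); no cross-frame fixed range
  is imposed.
- The normalized entropy's algebraic form (above) was chosen so that values
  are comparable across bin sizes and uniform histograms score exactly 1;
  the defining expression is otherwise ambiguous in its source formulation.
- Letter analyses default to w = spacing/10 (well below the particle scale)
  and open boundaries.
- `steady_state_stats` uses the population standard deviation (ddof = 0), the
  convention for error bars over a fixed window.

## Known limitations

- Periodic Voronoi via 3×3 tiling is exact when the box is much larger than
  the typical spacing but costs 9× the tessellation size; very small N in a
  periodic box (N ≤ 2) yields an empty graph since only self-images remain.
- The desk-scale flock (N = 100) compresses the separation between velocity
  ordering and positional ordering that large systems show; the ordering of
  the two transitions is preserved but their gap is only a few hundred steps.
- Open-boundary Voronoi graphs include long border adjacencies (no clipping),
  which inflate the distance tails of small finite shapes; this is part of
  the letter signal, not removed from it.
- 2-D only; no Laguerre/weighted tessellations; no cell-area statistics.
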