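# ndentropy

**Entropy by neighbor distance (H_NDist) for 2-D collective systems**, with a
constant-speed boid simulator, the average-velocity order parameter, and
synthetic pattern generators.

## The problem

Collective systems — bird flocks, active colloids, robot swarms — self-organize
into spatiotemporal patterns whose *positional* order is hard to quantify with
the classic alignment order parameter. `ndentropy` implements an
information-theoretic measure of positional order: pool the distances between
every agent and its neighbors, bin them into a histogram of width *w*, and take
the Shannon entropy of the bin probabilities *pᵢ = Xᵢ / X*:

```
H_NDist = − Σᵢ pᵢ log₂ pᵢ        (bits)
```

A perfect hexagonal lattice, where every neighbor distance equals the lattice
spacing, has H_NDist = 0; a dispersed gas has a broad distance distribution and
a large H_NDist. For comparisons across bin sizes, the normalized variant
corrects for the bin width and the spanned range,

```
H_NDist,norm = [H_NDist + Σᵢ pᵢ log₂ wᵢ] / log₂(Σᵢ wᵢ),
```

which equals 1 for a histogram uniform over its span.

Neighbors can be **topological** (Voronoi cells sharing an edge, i.e. Delaunay
adjacency — degree ≈ 6 regardless of density) or **metric** (all agents within
a radius R). Both work under open or periodic boundaries; periodic geometry
uses a 3×3 ghost tiling and minimum-image distances.

The package also ships the boid model used to study these measures: point-like
agents at constant speed V combining unit-normalized separation, alignment and
cohesion forces weighted by a steering factor S, with uniform angular noise of
half-width η degrees per step, and the Vicsek order parameter
`v_a = |Σᵢ vᵢ| / (N V)`.

## Worked example

```python
import ndentropy as nd

# calibration: a hexagonal lattice is perfectly ordered
lattice = nd.hexagonal_lattice(12, 12, spacing=10.0)
print(nd.entropy_by_neighbor_distance(lattice, bin_size=1.0).h_ndist)
# 0.0

# a dispersed gas versus an aggregated (clustered) state, same N and box
gas = nd.uniform_gas(500, (1000.0, 1000.0), seed=7)
clusters = nd.gaussian_clusters(5, 100, sigma=10.0, box=(1000.0, 1000.0), seed=7)
print(round(nd.entropy_by_neighbor_distance(gas, 1.0).h_ndist, 3),
      round(nd.entropy_by_neighbor_distance(clusters, 1.0).h_ndist, 3))
# 6.546 3.813   — the gas carries ~2.7 bits more neighbor-distance entropy

# a zero-noise flock: velocity order emerges, then positional order follows
params = nd.BoidParams(n_boids=100, steering=0.1, seed=1)
traj = nd.run(params, n_steps=8000, record_every=250)
print(round(float(traj.va_per_step[-1000:].mean()), 3),
      round(traj.series["h_ndist"].iloc[0] - traj.series["h_ndist"].iloc[-1], 2))
# 0.999 0.91   — v_a reaches ~1 while H_NDist drops ~0.9 bits from the random start
```

The same analyses run from the shell on trajectory CSVs
(`frame,id,x,y[,vx,vy]`):

```bash
ndentropy sim --n-boids 100 --steering 0.1 --steps 8000 --out-prefix runs/flock
ndentropy entropy --input runs/flock.trajectory.csv --boundary periodic \
    --box 1000 1000 --bin-size 1 --out runs/flock.entropy.csv
ndentropy sweep-noise --mode voronoi --out runs/noise_voronoi.csv
ndentropy letters --out runs/letters.csv
```

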