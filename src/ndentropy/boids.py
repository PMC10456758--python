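"""Boid simulator: cohesion, separation and alignment with constant speed.

Point-like agents move in a periodic rectangular box at constant speed ``V``.
Each step, every boid sums three unit-normalized social forces over its
neighbor set φ (topological or metric):

    F_sep,i = sum_{j in φ} (r_i - r_j) / r_ij^2
    F_alg,i = (sum_{j in φ} v_j) / n_i - v_i
    F_coh,i = (sum_{j in φ} r_j) / n_i - r_i
    F_i     = F_sep/|F_sep| + F_alg/|F_alg| + F_coh/|F_coh|

(a term whose norm is below 1e-12 is dropped; a boid with no neighbors has
F_i = 0).  The new heading is the quadrant-aware angle of ``v_i + S F_i``
where ``S`` is the steering factor; an angular noise term drawn uniformly
from ``(-eta, eta)`` degrees is then added per boid per step, the speed is
reset to exactly ``V``, and positions advance by ``v dt`` with periodic
wrapping.  All displacements, centroids and distances use the minimum-image
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .neighbors import (
    NeighborGraph,
    PointSet,
    build_metric_graph,
    build_voronoi_graph,
    minimum_image,
    neighbor_distances,
)
from .entropy import entropy_of_sample

_ZERO_NORM = 1e-12


@dataclass(frozen=True)
class BoidParams:
    """Simulation parameters.

    ``steering`` weighs the social force against the boid's own velocity; the
    accepted range is [0.001, 0.1] (values outside trigger a warning, not an
    error).  ``noise_deg`` is the half-width eta of the uniform angular
    perturbation in degrees.  ``metric_radius`` is required in metric mode.
    """

    n_boids: int = 200
    box: tuple[float, float] = (1000.0, 1000.0)
    speed: float = 2.0
    steering: float = 0.1
    noise_deg: float = 0.0
    neighbor_mode: str = "voronoi"
    metric_radius: float | None = None
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boids < 1:
            raise ConfigurationError("n_boids must be >= 1")
        if self.speed <= 0:
            raise ConfigurationError("speed must be positive")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.noise_deg < 0:
            raise ConfigurationError("noise_deg must be >= 0")
        if self.box[0] <= 0 or self.box[1] <= 0:
            raise ConfigurationError("box extents must be positive")
        if self.neighbor_mode not in ("voronoi", "metric"):
            raise ConfigurationError(f"unknown neighbor mode {self.neighbor_mode!r}")
        if self.neighbor_mode == "metric" and self.metric_radius is None:
            raise ConfigurationError("metric neighbor mode requires metric_radius")
        if not (0.001 <= self.steering <= 0.1) and self.steering != 0.0:
            warnings.warn(
                f"steering factor {self.steering} outside the tuned range [0.001, 0.1]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BoidState:
    """Positions (canonical in box) and headings (radians) at one step."""

    positions: np.ndarray
    headings: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "headings", np.asarray(self.headings, dtype=float))

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def velocities(self, speed: float) -> np.ndarray:
        return speed * np.column_stack([np.cos(self.headings), np.sin(self.headings)])

    def point_set(self, box: tuple[float, float]) -> PointSet:
        return PointSet(coords=self.positions, boundary="periodic", box=box)


@dataclass(frozen=True)
class ForceSet:
    """Per-boid separation/alignment/cohesion forces and their combination."""

    f_sep: np.ndarray
    f_alg: np.ndarray
    f_coh: np.ndarray
    total: np.ndarray


def init_state(params: BoidParams, rng: np.random.Generator | None = None) -> BoidState:
    """Uniform-random positions over the box and headings over [0, 2*pi)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box)
    positions = rng.uniform(0.0, 1.0, size=(params.n_boids, 2)) * box
    headings = rng.uniform(0.0, 2.0 * np.pi, size=params.n_boids)
    return BoidState(positions=positions, headings=headings, step_index=0)


def _unit_or_zero(vecs: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vecs, axis=1)
    out = np.zeros_like(vecs)
    ok = norms > _ZERO_NORM
    out[ok] = vecs[ok] / norms[ok, None]
    return out


def compute_forces(state: BoidState, graph: NeighborGraph, params: BoidParams) -> ForceSet:
    """Evaluate the three social-force rules on the current neighbor graph."""
    n = state.n
    pos = state.positions
    vel = state.velocities(params.speed)
    f_sep = np.zeros((n, 2))
    f_alg = np.zeros((n, 2))
    f_coh = np.zeros((n, 2))

    if graph.n_edges > 0:
        src, dst, _ = graph.directed()
        disp = minimum_image(pos[dst] - pos[src], params.box)  # r_j - r_i
        r2 = np.einsum("ij,ij->i", disp, disp)
        np.add.at(f_sep, src, -disp / r2[:, None])
        np.add.at(f_alg, src, vel[dst])
        np.add.at(f_coh, src, disp)
        deg = graph.degrees
        has = deg > 0
        f_alg[has] = f_alg[has] / deg[has, None] - vel[has]
        f_alg[~has] = 0.0
        f_coh[has] = f_coh[has] / deg[has, None]

    total = _unit_or_zero(f_sep) + _unit_or_zero(f_alg) + _unit_or_zero(f_coh)
    return ForceSet(f_sep=f_sep, f_alg=f_alg, f_coh=f_coh, total=total)


def build_graph(state: BoidState, params: BoidParams) -> NeighborGraph:
    points = state.point_set(params.box)
    if params.neighbor_mode == "voronoi":
        return build_voronoi_graph(points)
    return build_metric_graph(points, params.metric_radius)


def step(
    state: BoidState,
    params: BoidParams,
    rng: np.random.Generator,
    graph: NeighborGraph | None = None,
) -> BoidState:
    """Advance one time step.

    The steering update rotates each boid toward ``v_i + S F_i``; the angular
    noise is applied after the steering update, independently per boid; the
    speed is exactly ``V`` at every step.
    """
    if graph is None:
        graph = build_graph(state, params)
    forces = compute_forces(state, graph, params)
    combined = state.velocities(params.speed) + params.steering * forces.total
    headings = np.arctan2(combined[:, 1], combined[:, 0])
    dtheta = np.deg2rad(rng.uniform(-params.noise_deg, params.noise_deg, size=state.n))
    headings = headings + dtheta
    velocities = params.speed * np.column_stack([np.cos(headings), np.sin(headings)])
    positions = np.mod(
        state.positions + velocities * params.dt, np.asarray(params.box)
    )
    return BoidState(positions=positions, headings=headings, step_index=state.step_index + 1)


@dataclass
class Trajectory:
    """Recorded output of one simulation run."""

    params: BoidParams
    frames: list[BoidState] = field(default_factory=list)
    series: pd.DataFrame | None = None   # step, v_a, h_ndist, h_norm at cadence
    va_per_step: np.ndarray | None = None  # v_a at every step, length n_steps+1
    n_steps_run: int = 0

    def to_table(self) -> pd.DataFrame:
        """Recorded frames in the trajectory CSV dialect (frame, id, x, y, vx, vy)."""
        rows = []
        for st in self.frames:
            vel = st.velocities(self.params.speed)
            rows.append(
                pd.DataFrame(
                    {
                        "frame": st.step_index,
                        "id": np.arange(st.n),
                        "x": st.positions[:, 0],
                        "y": st.positions[:, 1],
                        "vx": vel[:, 0],
                        "vy": vel[:, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _va(state: BoidState) -> float:
    u = np.column_stack([np.cos(state.headings), np.sin(state.headings)])
    return float(np.linalg.norm(u.mean(axis=0)))


def run(
    params: BoidParams,
    n_steps: int,
    record_every: int | None = None,
    bin_size: float = 1.0,
    compute_entropy: bool = True,
    stop_tol: float | None = None,
    stop_window: int = 1000,
) -> Trajectory:
    """Advance the simulation, recording states and observables.

    States and the H_NDist series are recorded every ``record_every`` steps
    (default: only the initial and final states); the order parameter v_a is
    recorded at every step.  If ``stop_tol`` is given, the run ends early once
    the mean v_a over the trailing ``stop_window`` steps changes by less than
    ``stop_tol`` relative to the preceding window.  Bitwise reproducible for
    a given seed.
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    if record_every is None:
        record_every = n_steps
    if record_every < 1:
        raise ConfigurationError("record_every must be >= 1")

    rng = np.random.default_rng(params.seed)
    state = init_state(params, rng)
    va = [_va(state)]
    frames: list[BoidState] = []
    records: list[dict] = []

    def record(st: BoidState, graph: NeighborGraph) -> None:
        frames.append(st)
        row = {"step": st.step_index, "v_a": va[st.step_index]}
        if compute_entropy:
            sample = neighbor_distances(st.point_set(params.box), graph)
            if sample.n > 0:
                res = entropy_of_sample(sample, bin_size)
                row.update(h_ndist=res.h_ndist, h_norm=res.h_norm)
            else:
                row.update(h_ndist=np.nan, h_norm=np.nan)
        records.append(row)

    for t in range(n_steps):
        graph = build_graph(state, params)
        if t % record_every == 0:
            record(state, graph)
        state = step(state, params, rng, graph)
        va.append(_va(state))
        if (
            stop_tol is not None
            and len(va) >= 2 * stop_window
            and abs(
                np.mean(va[-stop_window:]) - np.mean(va[-2 * stop_window : -stop_window])
            )
            < stop_tol
        ):
            break

    graph = build_graph(state, params)
    record(state, graph)

    series = pd.DataFrame(records)
    return Trajectory(
        params=params,
        frames=frames,
        series=series,
        va_per_step=np.asarray(va),
        n_steps_run=state.step_index,
    )
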