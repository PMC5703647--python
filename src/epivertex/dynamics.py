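"""Mechanics and stochastic dynamics of the fluctuating vertex model.

Vertices move by overdamped gradient descent on a tissue energy with
interface-tension and area-elasticity terms; line tensions follow an
Ornstein-Uhlenbeck process around per-edge reference tensions derived
from per-cell draws.  Interfaces shorter than a threshold undergo T1
neighbor exchanges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .tissue import Box, Tissue, TopologyError, build_honeycomb, build_voronoi

__all__ = [
    "ModelParams",
    "TensionState",
    "SimState",
    "T1Event",
    "SimResult",
    "tissue_energy",
    "vertex_forces",
    "draw_cell_tensions",
    "draw_preferred_areas",
    "reference_tensions",
    "ou_update",
    "step",
    "handle_short_edges",
    "relax",
    "run_simulation",
]


@dataclass
class ModelParams:
    """All model constants, in units of the characteristic cell length
    ``l_char``, the reference tension and minutes.

    The wild-type calibration: packing time ``tau_p = alpha*l/gamma`` of
    4.4 min, tension/area-elasticity ratio ``gamma/(K l^3)`` of 0.025,
    preferred-area spread 0.19 l^2, extrinsic tension spread 1.07 gamma,
    intrinsic/extrinsic ratio 0.08/0.13 and tension persistence time
    2.2 min.
    """

    alpha: float = 4.4
    gamma_mean: float = 1.0
    sigma_e: float = 1.07
    sigma_i: float = 1.07 * 0.08 / 0.13
    tau_m: float = 2.2
    K: float = 40.0
    A0_mean: float = 1.0
    sigma_A: float = 0.19
    l_char: float = 1.0
    l_t1: float = 0.07
    l_new_factor: float = 1.5
    dt: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "alpha",
            "gamma_mean",
            "tau_m",
            "K",
            "A0_mean",
            "l_char",
            "l_t1",
            "dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_e < 0 or self.sigma_i < 0 or self.sigma_A < 0:
            raise ValueError("spread parameters must be nonnegative")
        if self.l_new_factor <= 1.0:
            raise ValueError("l_new_factor must exceed 1 (l_new > l_t1)")
        if self.dt >= min(self.tau_m, self.tau_p) / 10:
            raise ValueError(
                f"dt={self.dt} too large: must be < min(tau_m, tau_p)/10 "
                f"= {min(self.tau_m, self.tau_p) / 10:.4g}"
            )

    @property
    def tau_p(self) -> float:
        """Characteristic packing time alpha*l/gamma."""
        return self.alpha * self.l_char / self.gamma_mean

    @property
    def l_new(self) -> float:
        return self.l_new_factor * self.l_t1

    def with_tension_ratio(self, ratio: float) -> "ModelParams":
        """Scale the mean line tension (for gamma/gamma0 sweeps), other
        parameters held fixed."""
        return replace(self, gamma_mean=ratio * 1.0)


@dataclass
class TensionState:
    """Instantaneous and reference tensions, plus the per-cell draws."""

    gamma: np.ndarray  # (E,) instantaneous
    gamma0: np.ndarray  # (E,) reference
    cell_gamma: np.ndarray  # (F,)

    def copy(self) -> "TensionState":
        return TensionState(
            self.gamma.copy(), self.gamma0.copy(), self.cell_gamma.copy()
        )


@dataclass
class T1Event:
    event_id: int
    time: float
    edge_id: int
    quartet: tuple[int, int, int, int]
    losing: tuple[int, int]
    gaining: tuple[int, int]
    reversal_of: int | None = None
    # the four outer edges of the quartet at flip time (first neighbors)
    neighbor_edges: tuple[int, int, int, int] = (-1, -1, -1, -1)


@dataclass
class SimState:
    tissue: Tissue
    tension: TensionState
    params: ModelParams
    rng: np.random.Generator
    time: float = 0.0
    events: list[T1Event] = field(default_factory=list)
    deferred_flips: int = 0
    refused_flips: int = 0
    frustrated_checks: int = 0
    clip_count: int = 0
    step_index: int = 0
    recheck_interval: int = 10  # steps between opening re-tests per edge
    _quartet_last: dict = field(default_factory=dict)
    _next_check: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# energy and forces

def tissue_energy(tissue: Tissue, tension: TensionState, params: ModelParams) -> float:
    """E = sum_e gamma_e * l_e + sum_c (K/2) (A_c - A0_c)^2."""
    lengths = tissue.edge_lengths()
    areas = tissue.cell_areas()
    a0 = tissue.preferred_areas
    return float(
        np.dot(tension.gamma, lengths) + 0.5 * params.K * np.sum((areas - a0) ** 2)
    )


def vertex_forces(
    tissue: Tissue, tension: TensionState, params: ModelParams
) -> np.ndarray:
    """Force -dE/dx on every vertex, shape (V, 2)."""
    p = tissue.positions
    nv = tissue.n_vertices

    # tension term: each edge pulls both endpoints together
    vec = tissue.edge_vectors()
    lengths = np.linalg.norm(vec, axis=1)
    unit = vec / np.maximum(lengths, 1e-12)[:, None]
    pull = tension.gamma[:, None] * unit
    e0, e1 = tissue.edges[:, 0], tissue.edges[:, 1]
    fx = np.bincount(e0, weights=pull[:, 0], minlength=nv) - np.bincount(
        e1, weights=pull[:, 0], minlength=nv
    )
    fy = np.bincount(e0, weights=pull[:, 1], minlength=nv) - np.bincount(
        e1, weights=pull[:, 1], minlength=nv
    )

    # area term: shoelace gradient, minimum-image differences
    flat = tissue._flat()
    vid = flat["vid"]
    pv = p[vid]
    d_next = tissue.box.delta(pv, p[vid[flat["next"]]])
    d_prev = tissue.box.delta(pv, p[vid[flat["prev"]]])
    rel = d_next - d_prev  # p_next - p_prev in the local frame
    areas = tissue.cell_areas()
    coef = -params.K * (areas - tissue.preferred_areas)[flat["cell"]]
    fx += np.bincount(vid, weights=coef * 0.5 * rel[:, 1], minlength=nv)
    fy += np.bincount(vid, weights=coef * (-0.5) * rel[:, 0], minlength=nv)
    return np.column_stack([fx, fy])


# ----------------------------------------------------------------------
# stochastic tensions

def draw_cell_tensions(
    params: ModelParams, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell tensions from a normal truncated to [0, inf)."""
    mu, sd = params.gamma_mean, params.sigma_e
    if sd == 0:
        return np.full(n_cells, mu)
    a = (0.0 - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n_cells, random_state=rng)


def draw_preferred_areas(
    params: ModelParams, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Preferred areas ~ N(A0_mean, sigma_A), floored at a small positive
    value (negative targets are meaningless; draws there are vanishingly
    rare at the default spread)."""
    a0 = rng.normal(params.A0_mean, params.sigma_A, size=n_cells)
    return np.maximum(a0, 0.05 * params.A0_mean)


def reference_tensions(tissue: Tissue, cell_tensions: np.ndarray) -> np.ndarray:
    """Per-edge reference: mean of the two adjacent cells' draws."""
    return cell_tensions[tissue.edge_cells].mean(axis=1)


def ou_update(
    gamma: np.ndarray,
    gamma0: np.ndarray,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One Euler-Maruyama step of the tension OU process, clipped at 0.

    Returns the updated tensions and the number of clipped entries.
    """
    noise = np.sqrt(2.0 * params.sigma_i**2 * dt / params.tau_m)
    z = rng.standard_normal(np.shape(gamma))
    out = gamma - (dt / params.tau_m) * (gamma - gamma0) + noise * z
    clipped = int(np.count_nonzero(out < 0))
    return np.maximum(out, 0.0), clipped


def init_tension_state(
    tissue: Tissue, params: ModelParams, rng: np.random.Generator
) -> TensionState:
    cell_gamma = draw_cell_tensions(params, tissue.n_cells, rng)
    gamma0 = reference_tensions(tissue, cell_gamma)
    return TensionState(gamma=gamma0.copy(), gamma0=gamma0, cell_gamma=cell_gamma)


# ----------------------------------------------------------------------
# integration

class NumericalBlowup(RuntimeError):
    pass


def step(state: SimState, with_noise: bool = True) -> None:
    """Advance the state by one time step dt (in place)."""
    params = state.params
    f = vertex_forces(state.tissue, state.tension, params)
    dx = (params.dt / params.alpha) * f
    max_dx = float(np.abs(dx).max()) if dx.size else 0.0
    if max_dx > 0.5 * params.l_char:
        raise NumericalBlowup(
            f"vertex displacement {max_dx:.3g} l in one step at t="
            f"{state.time:.3g} min; reduce dt (currently {params.dt})"
        )
    state.tissue.positions = state.tissue.box.wrap(state.tissue.positions + dx)
    if with_noise and params.sigma_i > 0:
        state.tension.gamma, clipped = ou_update(
            state.tension.gamma, state.tension.gamma0, params, params.dt, state.rng
        )
        state.clip_count += clipped
    state.time += params.dt
    state.step_index += 1
    handle_short_edges(state)


def _flip_quartet(tissue: Tissue, e: int) -> tuple:
    """Identify the quartet and outer edges of a prospective T1 on ``e``.

    Returns (va, vb, cl, cr, cp, cq, stay_a, move_a, stay_b, move_b)
    where ``move_*`` are the outer edges that would swap endpoints.
    """
    va, vb = map(int, tissue.edges[e])
    cl, cr = map(int, tissue.edge_cells[e])
    v_edges = tissue.vertex_edges()
    v_cells = tissue.vertex_cells()
    cp = next(c for c in v_cells[va] if c not in (cl, cr))
    cq = next(c for c in v_cells[vb] if c not in (cl, cr))
    stay_a = move_a = stay_b = move_b = -1
    for k in v_edges[va]:
        if k == e:
            continue
        if cr in tissue.edge_cells[k]:
            move_a = k
        else:
            stay_a = k
    for k in v_edges[vb]:
        if k == e:
            continue
        if cl in tissue.edge_cells[k]:
            move_b = k
        else:
            stay_b = k
    return va, vb, cl, cr, cp, cq, stay_a, move_a, stay_b, move_b


def t1_opening_rate(
    tissue: Tissue, tension: TensionState, params: ModelParams, e: int
) -> float:
    """Predicted d(length)/dt of the post-flip edge, without mutating.

    A flip is only productive when the reconnected edge is pulled open
    by the surrounding forces; otherwise the short edge persists as an
    effective four-way vertex until fluctuations resolve it.
    """
    box = tissue.box
    va, vb, cl, cr, cp, cq, stay_a, move_a, stay_b, move_b = _flip_quartet(tissue, e)
    p = tissue.positions
    pa, pb = p[va], p[vb]
    d = box.delta(pa, pb)
    norm = float(np.linalg.norm(d))
    if norm > 1e-9:
        u_old = d / norm
        n = np.array([-u_old[1], u_old[0]])  # toward cell_left
    else:  # four-way vertex: open along the losing cells' centroid axis
        axis = box.delta(tissue.cell_centroid(cr), tissue.cell_centroid(cl))
        n = axis / max(np.linalg.norm(axis), 1e-12)
    mid = box.wrap(pa + 0.5 * box.delta(pa, pb))
    new_pos = {
        va: box.wrap(mid + 0.5 * params.l_new * n),
        vb: box.wrap(mid - 0.5 * params.l_new * n),
    }

    def pos(v: int) -> np.ndarray:
        return new_pos.get(v, p[v])

    gamma_new = float(tension.cell_gamma[[cp, cq]].mean())
    f = {va: np.zeros(2), vb: np.zeros(2)}

    def pull(v: int, other: int, g: float) -> None:
        vec = box.delta(pos(v), pos(other))
        ln = max(float(np.linalg.norm(vec)), 1e-12)
        f[v] += g * vec / ln

    pull(va, vb, gamma_new)
    pull(vb, va, gamma_new)
    other_a = int(tissue.edges[stay_a][tissue.edges[stay_a] != va][0])
    pull(va, other_a, float(tension.gamma[stay_a]))
    other_b = int(tissue.edges[stay_b][tissue.edges[stay_b] != vb][0])
    pull(vb, other_b, float(tension.gamma[stay_b]))
    # moved outer edges: (vb, s) -> (va, s) and (va, w) -> (vb, w)
    s = int(tissue.edges[move_b][tissue.edges[move_b] != vb][0])
    pull(va, s, float(tension.gamma[move_b]))
    w = int(tissue.edges[move_a][tissue.edges[move_a] != va][0])
    pull(vb, w, float(tension.gamma[move_a]))

    # area terms over the four post-flip cell polygons
    cyc_cl = [v for v in tissue.cells[cl] if v != vb]
    cyc_cr = [v for v in tissue.cells[cr] if v != va]
    cyc_cp = list(tissue.cells[cp])
    cyc_cp.insert(cyc_cp.index(va), vb)
    cyc_cq = list(tissue.cells[cq])
    cyc_cq.insert(cyc_cq.index(vb), va)
    for cid, cyc in ((cl, cyc_cl), (cr, cyc_cr), (cp, cyc_cp), (cq, cyc_cq)):
        pts = np.array([pos(v) for v in cyc])
        steps = box.delta(pts[:-1], pts[1:])
        xy = np.vstack([pts[0], pts[0] + np.cumsum(steps, axis=0)])
        x, y = xy[:, 0], xy[:, 1]
        area = 0.5 * float(
            np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
        )
        coef = -params.K * (area - tissue.preferred_areas[cid])
        for v in (va, vb):
            if v in cyc:
                i = cyc.index(v)
                nxt, prv = cyc[(i + 1) % len(cyc)], cyc[i - 1]
                dn = box.delta(pos(v), pos(nxt))
                dp = box.delta(pos(v), pos(prv))
                rel = dn - dp
                f[v] += coef * 0.5 * np.array([rel[1], -rel[0]])

    u_new = box.delta(new_pos[va], new_pos[vb])
    u_new /= max(float(np.linalg.norm(u_new)), 1e-12)
    return float(np.dot(f[vb] - f[va], u_new)) / params.alpha


def handle_short_edges(state: SimState) -> list[T1Event]:
    """Flip edges below the T1 threshold whose reconnected edge would
    open (vertex-disjoint set per step, shortest first).  Flips whose
    new edge would immediately re-contract are held back (the short
    edge persists as an effective four-way vertex); deferred and
    refused flips are counted."""
    tissue = state.tissue
    params = state.params
    lengths = tissue.edge_lengths()
    short = np.flatnonzero(lengths < params.l_t1)
    if short.size == 0:
        return []
    applied: list[T1Event] = []
    touched: set[int] = set()
    for e in short[np.argsort(lengths[short], kind="stable")]:
        e = int(e)
        v1, v2 = map(int, tissue.edges[e])
        if v1 in touched or v2 in touched:
            state.deferred_flips += 1
            continue
        cl, cr = tissue.edge_cells[e]
        if len(tissue.cells[cl]) <= 3 or len(tissue.cells[cr]) <= 3:
            state.refused_flips += 1
            continue
        # a frustrated edge is only re-tested every few steps; tensions
        # decorrelate over tau_m >> recheck_interval * dt
        if state.step_index < state._next_check.get(e, 0):
            continue
        if t1_opening_rate(tissue, state.tension, params, e) <= 0.0:
            state.frustrated_checks += 1
            state._next_check[e] = state.step_index + state.recheck_interval
            continue
        state._next_check.pop(e, None)
        quartet_edges = _flip_quartet(tissue, e)
        outer = (quartet_edges[6], quartet_edges[7], quartet_edges[8], quartet_edges[9])
        try:
            rec = tissue.t1_flip(e, params.l_new)
        except TopologyError:
            state.refused_flips += 1
            continue
        touched.update((v1, v2, int(tissue.edges[e][0]), int(tissue.edges[e][1])))
        # new interface inherits its cells' mean tension, no noise history
        g0 = float(state.tension.cell_gamma[list(tissue.edge_cells[e])].mean())
        state.tension.gamma0[e] = g0
        state.tension.gamma[e] = g0
        key = frozenset(rec.quartet)
        prior = state._quartet_last.get(key)
        reversal_of = None
        if prior is not None and set(prior.gaining) == set(rec.losing):
            reversal_of = prior.event_id
        ev = T1Event(
            event_id=len(state.events),
            time=state.time,
            edge_id=e,
            quartet=rec.quartet,
            losing=rec.losing,
            gaining=rec.gaining,
            reversal_of=reversal_of,
            neighbor_edges=outer,
        )
        state.events.append(ev)
        state._quartet_last[key] = ev
        applied.append(ev)
    return applied


def relax(
    tissue: Tissue,
    tension: TensionState,
    params: ModelParams,
    tol: float = 1e-3,
    max_iter: int = 200_000,
) -> Tissue:
    """Noise-free gradient descent until the residual force drops below
    ``tol`` (force units) or the configuration stops moving.  Tensions
    are pinned at their references.

    A frustrated four-fold vertex (short edge held shut by the force
    gate) carries a finite residual force forever, so stalling motion
    (max displacement < 1e-7 l per step) also counts as converged.
    """
    state = SimState(
        tissue=tissue.copy(),
        tension=TensionState(
            tension.gamma0.copy(), tension.gamma0.copy(), tension.cell_gamma.copy()
        ),
        params=params,
        rng=np.random.default_rng(0),
    )
    prev = state.tissue.positions.copy()
    for it in range(max_iter):
        f = vertex_forces(state.tissue, state.tension, params)
        resid = float(np.abs(f).max())
        if resid < tol:
            return state.tissue
        step(state, with_noise=False)
        if it % 50 == 49:
            moved = np.abs(
                state.tissue.box.delta(prev, state.tissue.positions)
            ).max()
            if moved < 1e-7 * params.l_char * 50:
                return state.tissue
            prev = state.tissue.positions.copy()
    raise RuntimeError(
        f"relaxation did not converge in {max_iter} iterations; residual {resid:.3g}"
    )


# ----------------------------------------------------------------------
# driver

@dataclass
class SimResult:
    """Recorded trajectory of one simulation run."""

    times: np.ndarray  # (T,) frame times, min
    lengths: np.ndarray  # (T, E) edge lengths
    tensions: np.ndarray  # (T, E) instantaneous tensions
    sides: np.ndarray  # (T, F) per-cell side counts
    events: list[T1Event]
    tissue: Tissue  # final state
    tension: TensionState
    params: ModelParams
    n_junctions_t0: int
    burn_in: float
    duration: float
    frame_tissues: list[Tissue] | None = None
    clip_count: int = 0
    deferred_flips: int = 0
    refused_flips: int = 0

    @property
    def post_burn_in_events(self) -> list[T1Event]:
        return [e for e in self.events if e.time >= self.burn_in]


def run_simulation(
    params: ModelParams,
    n_cells: int = 156,
    duration: float = 80.0,
    burn_in: float = 20.0,
    frame_interval: float = 0.5,
    init: str = "honeycomb",
    keep_tissues: bool = False,
    relax_tol: float = 5e-2,
    progress: bool = False,
) -> SimResult:
    """Initialize, relax without noise, then run the fluctuating model.

    ``duration`` is the simulated time after burn-in over which frames
    and statistics are recorded; frames are written every
    ``frame_interval`` minutes (default 30 s, the imaging cadence).
    """
    rng = np.random.default_rng(params.seed)
    tissue = _initial_tissue(init, n_cells, params, rng)
    tissue.preferred_areas = draw_preferred_areas(params, tissue.n_cells, rng)
    tension = init_tension_state(tissue, params, rng)
    tissue = relax(tissue, tension, params, tol=relax_tol)

    state = SimState(tissue=tissue, tension=tension, params=params, rng=rng)
    n_junctions_t0 = tissue.n_edges

    total = burn_in + duration
    n_steps = int(round(total / params.dt))
    record_every = max(1, int(round(frame_interval / params.dt)))
    n_frames = n_steps // record_every + 1

    times = np.zeros(n_frames)
    lengths = np.zeros((n_frames, tissue.n_edges))
    tensions = np.zeros((n_frames, tissue.n_edges))
    sides = np.zeros((n_frames, tissue.n_cells), dtype=np.int64)
    frame_tissues: list[Tissue] = []

    def _record(k: int) -> None:
        times[k] = state.time
        lengths[k] = state.tissue.edge_lengths()
        tensions[k] = state.tension.gamma
        sides[k] = state.tissue.cell_sides()
        if keep_tissues:
            frame_tissues.append(state.tissue.copy())

    _record(0)
    k = 1
    for i in range(1, n_steps + 1):
        step(state)
        if i % record_every == 0:
            _record(k)
            k += 1
        if progress and i % 1000 == 0:
            print(f"  step {i}/{n_steps}, t={state.time:.1f} min, "
                  f"events={len(state.events)}", flush=True)

    return SimResult(
        times=times[:k],
        lengths=lengths[:k],
        tensions=tensions[:k],
        sides=sides[:k],
        events=state.events,
        tissue=state.tissue,
        tension=state.tension,
        params=params,
        n_junctions_t0=n_junctions_t0,
        burn_in=burn_in,
        duration=duration,
        frame_tissues=frame_tissues if keep_tissues else None,
        clip_count=state.clip_count,
        deferred_flips=state.deferred_flips,
        refused_flips=state.refused_flips,
    )


def _initial_tissue(
    init: str, n_cells: int, params: ModelParams, rng: np.random.Generator
) -> Tissue:
    # box sized so that the mean cell area is ~A0_mean
    if init == "honeycomb":
        side = np.sqrt(params.A0_mean * 2.0 / (3.0 * np.sqrt(3.0)))
        nx = max(2, int(round(np.sqrt(n_cells))))
        ny = max(2, int(round(n_cells / nx)))
        if ny % 2:
            ny += 1
        return build_honeycomb(nx, ny, side)
    if init == "voronoi":
        w = np.sqrt(n_cells * params.A0_mean)
        return build_voronoi(n_cells, int(rng.integers(2**31)), Box(w, w))
    raise ValueError(f"unknown init '{init}' (use 'honeycomb' or 'voronoi')")
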