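"""Brownian-dynamics engine for glutamate in the synaptic cleft.

One run releases ``N_g`` glutamate molecules at the center of the active
zone and follows each molecule with Gaussian displacement steps
(per-axis sd ``sqrt(2 D dt)``) through the extracellular space, with
specular reflection off every membrane.  When a step crosses a
receptor- or transporter-bearing surface the crossing is a potential
binding event: the surface molecule owning that patch of membrane (the
nearest one — a Voronoi partition of the surface) is tested with a
per-crossing probability calibrated so that, in a well-mixed volume, the
simulated association flux reproduces the mass-action rate constant (see
:func:`calibrate_binding_probability`).  Bound glutamate is re-emitted on
unbinding and deleted on transport.  Receptor and transporter Markov
states advance by competing risks once per time step.

All kernel arithmetic is in nm and microseconds.  Glutamate is conserved
exactly (integer bookkeeping: free + bound + removed = N_g at every
step); a violation aborts the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import curves
from .geometry import SynapseGeometry, build_geometry
from .kinetics import CompiledScheme, KineticScheme, builtin_scheme, compile_scheme
from .population import SynapseConfig

__all__ = [
    "SimParams",
    "RunResult",
    "BatchResult",
    "displacement_sigma",
    "calibrate_binding_probability",
    "binding_probability_for_area",
    "run",
    "run_batch",
    "default_schemes",
]

AVOGADRO = 6.02214076e23

#: default glutamate diffusion coefficient, um^2/ms.
D_GLUTAMATE = 0.33


@dataclass(frozen=True)
class SimParams:
    """Physical and numerical parameters of one simulation run.

    ``transporter_placement`` selects which membranes carry glutamate
    transporters: ``"peri_only"`` (the perisynaptic box alone — transporters
    belong to the *neuronal and glial* processes surrounding the synapse,
    which is what the perisynaptic box represents) or ``"both"`` (adding the
    extrasynaptic pre/post apposed faces, which are purely neuronal
    membrane).  The default follows the perisynaptic reading; see the
    methods note for the quantitative difference (~20% on mean maxOPEN).
    """

    D_g: float = D_GLUTAMATE  # um^2/ms
    dt_us: float = 1.0
    T_total_ms: float = 10.0
    N_g: int = 3000
    temperature_C: float = 35.0
    transporter_placement: str = "peri_only"  # or "both"

    def __post_init__(self) -> None:
        if self.transporter_placement not in ("both", "peri_only"):
            raise ValueError("transporter_placement must be 'both' or 'peri_only'")

    @property
    def n_steps(self) -> int:
        return int(round(self.T_total_ms * 1000.0 / self.dt_us))

    @property
    def sigma_nm(self) -> float:
        return displacement_sigma(self.D_g, self.dt_us)


def displacement_sigma(D: float, dt_us: float) -> float:
    """Per-axis Gaussian step sd sqrt(2 D dt), nm (D in um^2/ms, dt in us)."""
    if D < 0:
        raise ValueError("D must be non-negative")
    if dt_us <= 0:
        raise ValueError("dt must be positive")
    return math.sqrt(2.0 * D * 1000.0 * dt_us)


def binding_probability_for_area(
    kon: float, D: float, dt_us: float, area_nm2: float
) -> float:
    """Per-crossing binding probability for a site owning ``area_nm2``.

    Matches the simulated association flux to mass action: a molecule
    uniformly distributed in a closed volume V hits a wall patch of area a
    at rate E|dz| * a / (2 V dt) per step, so
    ``p = kon * sqrt(pi dt / D) / (N_A a)`` yields a per-site association
    rate of ``kon / (N_A V)`` — the bimolecular mass-action rate for one
    pair.  Note p * (crossing rate) is independent of dt, so halving the
    time step leaves the matched flux unchanged.
    """
    if kon < 0:
        raise ValueError("kon must be non-negative")
    if kon == 0:
        return 0.0
    if area_nm2 <= 0:
        raise ValueError("area must be positive")
    d_nm2_us = D * 1000.0  # um^2/ms -> nm^2/us
    konv = kon * 1e18 / AVOGADRO  # 1/(M s) -> nm^3/us per molecule pair
    p = konv * math.sqrt(math.pi * dt_us / d_nm2_us) / area_nm2
    if p > 1.0:
        raise ValueError(
            f"per-crossing binding probability {p:.3f} exceeds 1; "
            "use a smaller time step dt"
        )
    return p


def calibrate_binding_probability(
    kon: float, D: float, dt_us: float, tile_density_per_um2: float
) -> float:
    """Per-crossing probability for sites packed at ``tile_density_per_um2``."""
    if tile_density_per_um2 <= 0:
        raise ValueError("tile density must be positive")
    return binding_probability_for_area(kon, D, dt_us, 1e6 / tile_density_per_um2)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    """Open-receptor time series and summary of one run."""

    open_counts: np.ndarray  # int32[n_steps]
    free_counts: np.ndarray  # int32[n_steps], free glutamate per step
    dt_us: float
    maxOPEN: int
    peak_time_us: float
    auc: float  # sum(open_counts) * dt, receptor-us
    removed: int  # glutamate molecules transported out
    seed: int
    discarded_steps: int = 0
    snapshot_steps: np.ndarray | None = None
    open_snapshots: np.ndarray | None = None  # uint8[n_snaps, n_receptors]
    receptor_xy: np.ndarray | None = None  # float64[n_receptors, 2]


@dataclass
class BatchResult:
    """Independent seeded runs of one configuration plus their mean curve."""

    results: list[RunResult]
    mean_curve: np.ndarray  # float64[n_steps]
    dt_us: float

    @property
    def max_open_values(self) -> np.ndarray:
        return np.array([r.maxOPEN for r in self.results])

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([r.peak_time_us for r in self.results])


def default_schemes() -> dict[str, KineticScheme]:
    return {"ampa": builtin_scheme("ampa"), "glut": builtin_scheme("glut")}


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

_EPS = 1e-4  # nm, post-reflection offset off a face
_EMIT_OFF = 0.5  # nm, re-emission offset off a membrane
_MAX_BOUNCES = 64


@njit(cache=True, inline="always")
def _box_entry(x, y, z, dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2):
    """First intersection of segment p -> p+d with an AABB, from outside.

    Returns (t_enter, axis, side); side is -1 when entering through the
    low face of that axis, +1 through the high face.  axis == -1: miss.
    """
    t_enter = -1.0
    t_exit = 2.0
    axis = -1
    side = 0
    for a in range(3):
        if a == 0:
            c, d, lo, hi = x, dx, lo0, hi0
        elif a == 1:
            c, d, lo, hi = y, dy, lo1, hi1
        else:
            c, d, lo, hi = z, dz, lo2, hi2
        if d == 0.0:
            if c < lo or c > hi:
                return -1.0, -1, 0
        else:
            ta = (lo - c) / d
            tb = (hi - c) / d
            s = -1
            if ta > tb:
                ta, tb = tb, ta
                s = 1
            if ta > t_enter:
                t_enter = ta
                axis = a
                side = s
            if tb < t_exit:
                t_exit = tb
    if t_enter >= 0.0 and t_enter <= 1.0 and t_enter <= t_exit:
        return t_enter, axis, side
    return -1.0, -1, 0


@njit(cache=True, inline="always")
def _nearest_receptor(
    px, py, half_ls, grid_nx, grid_cs, r_cap2, grid_start, grid_items, r_x, r_y,
):
    """Nearest receptor within the capture radius, regardless of state.

    Each receptor owns the Voronoi cell around its position: a crossing is
    assigned to its owner and succeeds only if the owner's current state
    can bind.  Assigning crossings to the nearest *bindable* receptor
    instead would silently re-partition the capture area of saturated
    receptors onto their neighbours and overshoot mass action as the PSD
    saturates.
    """
    if grid_nx == 0:
        return -1
    ix = int((px + half_ls) / grid_cs)
    iy = int((py + half_ls) / grid_cs)
    if ix < 0:
        ix = 0
    elif ix >= grid_nx:
        ix = grid_nx - 1
    if iy < 0:
        iy = 0
    elif iy >= grid_nx:
        iy = grid_nx - 1
    best = -1
    best_d2 = r_cap2
    for gx in range(max(0, ix - 1), min(grid_nx, ix + 2)):
        for gy in range(max(0, iy - 1), min(grid_nx, iy + 2)):
            c = gx * grid_nx + gy
            for k in range(grid_start[c], grid_start[c + 1]):
                i = grid_items[k]
                ddx = r_x[i] - px
                ddy = r_y[i] - py
                d2 = ddx * ddx + ddy * ddy
                if d2 < best_d2:
                    best_d2 = d2
                    best = i
    return best


@njit(cache=True)
def _trace(
    x, y, z, dx, dy, dz,
    # world extents
    px_lo, px_hi, py_lo, py_hi, pz_lo, pz_hi,
    ex_half, post_zlo, pre_zhi, hc, half_ls,
    # receptors
    r_x, r_y, r_state, p_bind_r, grid_start, grid_items, grid_nx, grid_cs, r_cap2,
    # transporter faces (always 8: extras_post, extras_pre, 6 peri walls)
    t_state, p_bind_t,
    f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map,
):
    """Advance one molecule by one Brownian step with reflections.

    Returns (code, x, y, z, idx): code 0 = moved, 1 = bound receptor idx,
    2 = bound transporter idx, 3 = step discarded (bounce limit).
    """
    ox, oy, oz = x, y, z
    for _ in range(_MAX_BOUNCES):
        # earliest hit among peri walls and the two element boxes
        t_best = 2.0
        kind = -1  # 0 peri, 1 post box, 2 pre box
        axis = -1
        ndir = 0.0  # face normal direction into the ECS along `axis`

        if dx > 0.0 and x + dx > px_hi:
            t = (px_hi - x) / dx
            if t < t_best:
                t_best, kind, axis, ndir = t, 0, 0, -1.0
        elif dx < 0.0 and x + dx < px_lo:
            t = (px_lo - x) / dx
            if t < t_best:
                t_best, kind, axis, ndir = t, 0, 0, 1.0
        if dy > 0.0 and y + dy > py_hi:
            t = (py_hi - y) / dy
            if t < t_best:
                t_best, kind, axis, ndir = t, 0, 1, -1.0
        elif dy < 0.0 and y + dy < py_lo:
            t = (py_lo - y) / dy
            if t < t_best:
                t_best, kind, axis, ndir = t, 0, 1, 1.0
        if dz > 0.0 and z + dz > pz_hi:
            t = (pz_hi - z) / dz
            if t < t_best:
                t_best, kind, axis, ndir = t, 0, 2, -1.0
        elif dz < 0.0 and z + dz < pz_lo:
            t = (pz_lo - z) / dz
            if t < t_best:
                t_best, kind, axis, ndir = t, 0, 2, 1.0

        t, a, s = _box_entry(
            x, y, z, dx, dy, dz, -ex_half, -ex_half, post_zlo, ex_half, ex_half, 0.0
        )
        if a >= 0 and t < t_best:
            # entering through the low face => ECS lies on the low side
            t_best, kind, axis, ndir = t, 1, a, (-1.0 if s == -1 else 1.0)
        t, a, s = _box_entry(
            x, y, z, dx, dy, dz, -ex_half, -ex_half, hc, ex_half, ex_half, pre_zhi
        )
        if a >= 0 and t < t_best:
            t_best, kind, axis, ndir = t, 2, a, (-1.0 if s == -1 else 1.0)

        if kind < 0:
            return 0, x + dx, y + dy, z + dz, -1

        hx = x + t_best * dx
        hy = y + t_best * dy
        hz = z + t_best * dz

        # --- binding attempt, depending on which face was struck ---------
        face = -1
        if kind == 0:
            face = 2 + axis * 2 + (1 if ndir < 0.0 else 0)  # lo wall first
        elif kind == 1 and axis == 2 and ndir > 0.0:
            # top face of the postsynaptic element (z = 0)
            if abs(hx) <= half_ls and abs(hy) <= half_ls:
                ridx = _nearest_receptor(
                    hx, hy, half_ls, grid_nx, grid_cs, r_cap2,
                    grid_start, grid_items, r_x, r_y,
                )
                if ridx >= 0 and np.random.random() < p_bind_r[r_state[ridx]]:
                    return 1, hx, hy, hz, ridx
            else:
                face = 0  # extrasynaptic_post annulus
        elif kind == 2 and axis == 2 and ndir < 0.0:
            # bottom face of the presynaptic element (z = Hc)
            if not (abs(hx) <= half_ls and abs(hy) <= half_ls):
                face = 1  # extrasynaptic_pre annulus

        if face >= 0:
            if face == 0 or face == 1 or axis == 2:
                u, v = hx, hy
            else:
                u = hy if f_uax[face] == 1 else hx
                v = hz if f_vax[face] == 2 else hy
            iu = int((u - f_u0[face]) / f_du[face])
            iv = int((v - f_v0[face]) / f_dv[face])
            if iu < 0:
                iu = 0
            elif iu >= f_nu[face]:
                iu = f_nu[face] - 1
            if iv < 0:
                iv = 0
            elif iv >= f_nv[face]:
                iv = f_nv[face] - 1
            slot = f_map[f_off[face] + iu * f_nv[face] + iv]
            if slot >= 0:
                pb = p_bind_t[face, t_state[slot]]
                if pb > 0.0 and np.random.random() < pb:
                    return 2, hx, hy, hz, slot

        # --- specular reflection -----------------------------------------
        rem = 1.0 - t_best
        dx *= rem
        dy *= rem
        dz *= rem
        if axis == 0:
            dx = ndir * abs(dx)
            x, y, z = hx + ndir * _EPS, hy, hz
        elif axis == 1:
            dy = ndir * abs(dy)
            x, y, z = hx, hy + ndir * _EPS, hz
        else:
            dz = ndir * abs(dz)
            x, y, z = hx, hy, hz + ndir * _EPS
    return 3, ox, oy, oz, -1


@njit(cache=True)
def _run_kernel(
    seed, n_steps, n_g, sigma,
    rel_x, rel_y, rel_z,
    px_lo, px_hi, py_lo, py_hi, pz_lo, pz_hi,
    ex_half, post_zlo, pre_zhi, hc, half_ls,
    # receptors (AMPA)
    r_x, r_y, r_state, p_bind_r, bind_target_r,
    grid_start, grid_items, grid_nx, grid_cs, r_cap2,
    r_pany, r_ustart, r_etarget, r_ecum, r_eemit, r_eremove, r_lig, r_open_idx,
    # transporters (GluT)
    t_state, t_emit, p_bind_t, bind_target_t,
    t_pany, t_ustart, t_etarget, t_ecum, t_eemit, t_eremove, t_init_idx,
    f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map,
    # outputs
    open_counts, free_counts, snap_steps, snap_open,
):
    """One full run.  Returns (removed, discarded, steps_done, err)."""
    np.random.seed(seed)
    n_r = r_x.shape[0]

    fx = np.empty(n_g)
    fy = np.empty(n_g)
    fz = np.empty(n_g)
    for i in range(n_g):
        fx[i] = rel_x
        fy[i] = rel_y
        fz[i] = rel_z - 1e-3  # just inside the cleft, on the AZ center
    n_free = n_g

    # per-state index lists of non-resting transporters: Bernoulli thinning
    # of a state population is drawn as one binomial count plus uniform
    # picks, which is exact and avoids one RNG draw per molecule per step
    n_ts = t_pany.shape[0]
    t_list = np.empty((n_ts, n_g + 16), dtype=np.int64)
    t_cnt = np.zeros(n_ts, dtype=np.int64)
    bound_t = 0
    removed = 0
    discarded = 0
    snap_ptr = 0
    steps_done = 0

    for step in range(n_steps):
        # ---- diffusion + collision-mediated binding ----------------------
        # The ray-tracing logic is written inline (not via _trace): the
        # per-call cost of passing this many arrays dominated the kernel.
        i = 0
        while i < n_free:
            x = fx[i]
            y = fy[i]
            z = fz[i]
            dx = sigma * np.random.standard_normal()
            dy = sigma * np.random.standard_normal()
            dz = sigma * np.random.standard_normal()
            code = 3  # discarded unless the bounce loop resolves
            idx = -1
            for _bounce in range(_MAX_BOUNCES):
                t_best = 2.0
                kind = -1
                axis = -1
                ndir = 0.0
                if dx > 0.0 and x + dx > px_hi:
                    t = (px_hi - x) / dx
                    if t < t_best:
                        t_best, kind, axis, ndir = t, 0, 0, -1.0
                elif dx < 0.0 and x + dx < px_lo:
                    t = (px_lo - x) / dx
                    if t < t_best:
                        t_best, kind, axis, ndir = t, 0, 0, 1.0
                if dy > 0.0 and y + dy > py_hi:
                    t = (py_hi - y) / dy
                    if t < t_best:
                        t_best, kind, axis, ndir = t, 0, 1, -1.0
                elif dy < 0.0 and y + dy < py_lo:
                    t = (py_lo - y) / dy
                    if t < t_best:
                        t_best, kind, axis, ndir = t, 0, 1, 1.0
                if dz > 0.0 and z + dz > pz_hi:
                    t = (pz_hi - z) / dz
                    if t < t_best:
                        t_best, kind, axis, ndir = t, 0, 2, -1.0
                elif dz < 0.0 and z + dz < pz_lo:
                    t = (pz_lo - z) / dz
                    if t < t_best:
                        t_best, kind, axis, ndir = t, 0, 2, 1.0
                t, a, s = _box_entry(
                    x, y, z, dx, dy, dz,
                    -ex_half, -ex_half, post_zlo, ex_half, ex_half, 0.0,
                )
                if a >= 0 and t < t_best:
                    t_best, kind, axis = t, 1, a
                    ndir = -1.0 if s == -1 else 1.0
                t, a, s = _box_entry(
                    x, y, z, dx, dy, dz,
                    -ex_half, -ex_half, hc, ex_half, ex_half, pre_zhi,
                )
                if a >= 0 and t < t_best:
                    t_best, kind, axis = t, 2, a
                    ndir = -1.0 if s == -1 else 1.0
                if kind < 0:
                    x += dx
                    y += dy
                    z += dz
                    code = 0
                    break
                hx = x + t_best * dx
                hy = y + t_best * dy
                hz = z + t_best * dz
                face = -1
                if kind == 0:
                    face = 2 + axis * 2 + (1 if ndir < 0.0 else 0)
                elif kind == 1 and axis == 2 and ndir > 0.0:
                    if abs(hx) <= half_ls and abs(hy) <= half_ls:
                        ridx = _nearest_receptor(
                            hx, hy, half_ls, grid_nx, grid_cs, r_cap2,
                            grid_start, grid_items, r_x, r_y,
                        )
                        if (
                            ridx >= 0
                            and np.random.random() < p_bind_r[r_state[ridx]]
                        ):
                            code = 1
                            idx = ridx
                            break
                    else:
                        face = 0
                elif kind == 2 and axis == 2 and ndir < 0.0:
                    if not (abs(hx) <= half_ls and abs(hy) <= half_ls):
                        face = 1
                if face >= 0:
                    if face == 0 or face == 1 or axis == 2:
                        u, v = hx, hy
                    else:
                        u = hy if f_uax[face] == 1 else hx
                        v = hz if f_vax[face] == 2 else hy
                    iu = int((u - f_u0[face]) / f_du[face])
                    iv = int((v - f_v0[face]) / f_dv[face])
                    if iu < 0:
                        iu = 0
                    elif iu >= f_nu[face]:
                        iu = f_nu[face] - 1
                    if iv < 0:
                        iv = 0
                    elif iv >= f_nv[face]:
                        iv = f_nv[face] - 1
                    slot = f_map[f_off[face] + iu * f_nv[face] + iv]
                    if slot >= 0:
                        pb = p_bind_t[face, t_state[slot]]
                        if pb > 0.0 and np.random.random() < pb:
                            code = 2
                            idx = slot
                            break
                rem = 1.0 - t_best
                dx *= rem
                dy *= rem
                dz *= rem
                if axis == 0:
                    dx = ndir * abs(dx)
                    x, y, z = hx + ndir * _EPS, hy, hz
                elif axis == 1:
                    dy = ndir * abs(dy)
                    x, y, z = hx, hy + ndir * _EPS, hz
                else:
                    dz = ndir * abs(dz)
                    x, y, z = hx, hy, hz + ndir * _EPS

            if code == 1:
                r_state[idx] = bind_target_r[r_state[idx]]
                n_free -= 1
                fx[i] = fx[n_free]
                fy[i] = fy[n_free]
                fz[i] = fz[n_free]
            elif code == 2:
                tgt = bind_target_t[t_state[idx]]
                t_state[idx] = tgt
                bound_t += 1
                if t_cnt[tgt] >= t_list.shape[1]:
                    return removed, discarded, steps_done, 2
                t_list[tgt, t_cnt[tgt]] = idx
                t_cnt[tgt] += 1
                n_free -= 1
                fx[i] = fx[n_free]
                fy[i] = fy[n_free]
                fz[i] = fz[n_free]
            else:
                if code == 3:
                    discarded += 1
                else:
                    fx[i] = x
                    fy[i] = y
                    fz[i] = z
                i += 1

        # ---- unimolecular receptor transitions ---------------------------
        lig_r = 0
        n_open = 0
        for i in range(n_r):
            s = r_state[i]
            if r_pany[s] > 0.0 and np.random.random() < r_pany[s]:
                u = np.random.random()
                e = r_ustart[s]
                end = r_ustart[s + 1]
                while e < end - 1 and u > r_ecum[e]:
                    e += 1
                r_state[i] = r_etarget[e]
                if r_eemit[e] == 1:
                    fx[n_free] = r_x[i]
                    fy[n_free] = r_y[i]
                    fz[n_free] = _EMIT_OFF
                    n_free += 1
                elif r_eremove[e] == 1:
                    removed += 1
                s = r_state[i]
            lig_r += r_lig[s]
            if s == r_open_idx:
                n_open += 1

        # ---- unimolecular transporter transitions ------------------------
        # states processed in reverse index order; for the packaged cycle
        # (T <- TG -> TR -> T) a molecule therefore never moves twice in
        # one step, and for a general scheme the double-move probability
        # is O(p_any^2) per step
        for s in range(n_ts - 1, -1, -1):
            if s == t_init_idx or t_cnt[s] == 0 or t_pany[s] <= 0.0:
                continue
            n_move = np.random.binomial(t_cnt[s], t_pany[s])
            for _m in range(n_move):
                j = np.random.randint(0, t_cnt[s])
                idx = t_list[s, j]
                u = np.random.random()
                e = t_ustart[s]
                end = t_ustart[s + 1]
                while e < end - 1 and u > t_ecum[e]:
                    e += 1
                tgt = t_etarget[e]
                t_state[idx] = tgt
                t_cnt[s] -= 1
                t_list[s, j] = t_list[s, t_cnt[s]]
                if tgt != t_init_idx:
                    if t_cnt[tgt] >= t_list.shape[1]:
                        return removed, discarded, steps_done, 2
                    t_list[tgt, t_cnt[tgt]] = idx
                    t_cnt[tgt] += 1
                if t_eemit[e] == 1:
                    fx[n_free] = t_emit[idx, 0]
                    fy[n_free] = t_emit[idx, 1]
                    fz[n_free] = t_emit[idx, 2]
                    n_free += 1
                    bound_t -= 1
                elif t_eremove[e] == 1:
                    removed += 1
                    bound_t -= 1

        # ---- bookkeeping and recording -----------------------------------
        if n_free + lig_r + bound_t + removed != n_g:
            return removed, discarded, steps_done, 1
        open_counts[step] = n_open
        free_counts[step] = n_free
        steps_done = step + 1
        if snap_ptr < snap_steps.shape[0] and step == snap_steps[snap_ptr]:
            for i in range(n_r):
                snap_open[snap_ptr, i] = 1 if r_state[i] == r_open_idx else 0
            snap_ptr += 1
        if n_free == 0 and lig_r == 0 and bound_t == 0:
            break  # remaining steps stay identically zero

    return removed, discarded, steps_done, 0


@njit(cache=True)
def _tracer_kernel(
    seed, pos, n_steps, sigma, sample_every,
    px_lo, px_hi, py_lo, py_hi, pz_lo, pz_hi,
    ex_half, post_zlo, pre_zhi, hc, half_ls,
    r_x, r_y, r_state, p_bind_r, grid_start, grid_items, grid_nx, grid_cs, r_cap2,
    t_state, p_bind_t,
    f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map,
    out,
):
    """Non-reacting tracer diffusion; samples positions every k-th step."""
    np.random.seed(seed)
    n = pos.shape[0]
    ptr = 0
    for step in range(n_steps):
        for i in range(n):
            ddx = sigma * np.random.standard_normal()
            ddy = sigma * np.random.standard_normal()
            ddz = sigma * np.random.standard_normal()
            code, nx_, ny_, nz_, _ = _trace(
                pos[i, 0], pos[i, 1], pos[i, 2], ddx, ddy, ddz,
                px_lo, px_hi, py_lo, py_hi, pz_lo, pz_hi,
                ex_half, post_zlo, pre_zhi, hc, half_ls,
                r_x, r_y, r_state, p_bind_r, grid_start, grid_items,
                grid_nx, grid_cs, r_cap2,
                t_state, p_bind_t,
                f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map,
            )
            if code == 0:
                pos[i, 0] = nx_
                pos[i, 1] = ny_
                pos[i, 2] = nz_
        if (step + 1) % sample_every == 0:
            for i in range(n):
                out[ptr, 0] = pos[i, 0]
                out[ptr, 1] = pos[i, 1]
                out[ptr, 2] = pos[i, 2]
                ptr += 1
    return ptr


# ---------------------------------------------------------------------------
# world assembly (python side)
# ---------------------------------------------------------------------------


@dataclass
class _World:
    """Flat-array view of one configuration, ready for the kernel."""

    geom: SynapseGeometry
    comp_a: CompiledScheme
    comp_t: CompiledScheme
    params: SimParams
    p_bind_r_template: np.ndarray
    n_receptors: int
    args_static: dict = field(default_factory=dict)


def _face_local_axes(face) -> tuple[int, int]:
    return face.u_axis, face.v_axis


def _build_transporter_faces(
    geom: SynapseGeometry,
    density_per_um2: float,
    comp_t: CompiledScheme,
    params: SimParams,
    rng: np.random.Generator,
):
    """Jittered-grid transporter placement on the 8 transporter faces.

    Every face gets one molecule per grid cell of area ~1/density; the
    per-crossing binding probability uses the exact cell area, so the
    aggregate association flux matches mass action exactly.  Cells whose
    center falls inside the AZ/PSD cutout of the annulus faces hold no
    transporter (map slot -1).
    """
    faces = geom.transporter_faces
    assert len(faces) == 8
    n_states = comp_t.n_states
    f_uax = np.zeros(8, dtype=np.int64)
    f_vax = np.zeros(8, dtype=np.int64)
    f_u0 = np.zeros(8)
    f_v0 = np.zeros(8)
    f_du = np.ones(8)
    f_dv = np.ones(8)
    f_nu = np.ones(8, dtype=np.int64)
    f_nv = np.ones(8, dtype=np.int64)
    f_off = np.zeros(8, dtype=np.int64)
    maps = []
    emit_chunks = []
    p_bind_t = np.zeros((8, n_states))
    total = 0
    target_area = 1e6 / density_per_um2 if density_per_um2 > 0 else math.inf
    side = math.sqrt(target_area) if density_per_um2 > 0 else math.inf

    peri_only = params.transporter_placement == "peri_only"
    for f_idx, face in enumerate(faces):
        u0, u1 = face.u_range
        v0, v1 = face.v_range
        f_uax[f_idx], f_vax[f_idx] = _face_local_axes(face)
        f_u0[f_idx], f_v0[f_idx] = u0, v0
        bare = peri_only and face.tag.startswith("extrasynaptic")
        if bare or density_per_um2 <= 0 or (u1 - u0) <= 0 or (v1 - v0) <= 0:
            maps.append(np.full(1, -1, dtype=np.int64))
            f_off[f_idx] = sum(m.size for m in maps[:-1])
            continue
        nu = max(1, int(round((u1 - u0) / side)))
        nv = max(1, int(round((v1 - v0) / side)))
        du = (u1 - u0) / nu
        dv = (v1 - v0) / nv
        f_nu[f_idx], f_nv[f_idx] = nu, nv
        f_du[f_idx], f_dv[f_idx] = du, dv
        p_bind_t[f_idx] = np.array(
            [
                binding_probability_for_area(k, params.D_g, params.dt_us, du * dv)
                if k > 0
                else 0.0
                for k in comp_t.bind_rate
            ]
        )
        cell_map = np.full(nu * nv, -1, dtype=np.int64)
        iu, iv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
        iu = iu.ravel()
        iv = iv.ravel()
        uc = u0 + (iu + 0.5) * du
        vc = v0 + (iv + 0.5) * dv
        keep = np.ones(iu.size, dtype=bool)
        if face.exclude is not None:
            keep = ~((np.abs(uc) < face.exclude[0]) & (np.abs(vc) < face.exclude[1]))
        n_here = int(keep.sum())
        cell_map[np.nonzero(keep)[0]] = total + np.arange(n_here)
        # positions (jittered within cell) -> emission points off the face
        up = u0 + (iu[keep] + rng.random(n_here)) * du
        vp = v0 + (iv[keep] + rng.random(n_here)) * dv
        emit = np.empty((n_here, 3))
        emit[:, face.u_axis] = up
        emit[:, face.v_axis] = vp
        emit[:, face.axis] = face.coord + face.normal_sign * _EMIT_OFF
        emit_chunks.append(emit)
        maps.append(cell_map)
        f_off[f_idx] = sum(m.size for m in maps[:-1])
        total += n_here

    f_map = np.concatenate(maps) if maps else np.full(1, -1, dtype=np.int64)
    t_emit = (
        np.concatenate(emit_chunks, axis=0) if emit_chunks else np.empty((0, 3))
    )
    t_state = np.full(total, comp_t.initial_idx, dtype=np.int64)
    return (
        t_state, t_emit, p_bind_t,
        f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map,
    )


def _build_receptor_grid(xy: np.ndarray, half_ls: float, r_cap: float):
    """CSR bucket grid over the PSD for nearest-receptor queries."""
    n = xy.shape[0]
    if n == 0:
        return (
            np.zeros(2, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
            0,
            1.0,
        )
    nx = max(1, int(math.ceil(2.0 * half_ls / r_cap)))
    cs = 2.0 * half_ls / nx
    ix = np.clip(((xy[:, 0] + half_ls) / cs).astype(np.int64), 0, nx - 1)
    iy = np.clip(((xy[:, 1] + half_ls) / cs).astype(np.int64), 0, nx - 1)
    cell = ix * nx + iy
    order = np.argsort(cell, kind="stable")
    start = np.zeros(nx * nx + 1, dtype=np.int64)
    np.add.at(start[1:], cell, 1)
    start = np.cumsum(start)
    return start, order.astype(np.int64), nx, cs


def _prepare_world(
    cfg: SynapseConfig,
    geom: SynapseGeometry | None,
    schemes: dict[str, KineticScheme] | None,
    params: SimParams,
    nampa_override: int | None,
) -> _World:
    if geom is None:
        geom = build_geometry(cfg)
    if schemes is None:
        schemes = default_schemes()
    comp_a = compile_scheme(schemes["ampa"], params.dt_us, T=params.temperature_C)
    comp_t = compile_scheme(schemes["glut"], params.dt_us, T=params.temperature_C)
    if comp_a.open_idx < 0:
        raise ValueError("the receptor scheme must have a conducting (open) state")
    n_r = cfg.nAMPA if nampa_override is None else int(nampa_override)
    if n_r > 0:
        area_per_receptor = geom.As / n_r
        p_bind_r = np.array(
            [
                binding_probability_for_area(
                    k, params.D_g, params.dt_us, area_per_receptor
                )
                if k > 0
                else 0.0
                for k in comp_a.bind_rate
            ]
        )
    else:
        p_bind_r = np.zeros(comp_a.n_states)
    return _World(
        geom=geom,
        comp_a=comp_a,
        comp_t=comp_t,
        params=params,
        p_bind_r_template=p_bind_r,
        n_receptors=n_r,
    )


def _geometry_scalars(geom: SynapseGeometry):
    return dict(
        px_lo=float(geom.peri_lo[0]), px_hi=float(geom.peri_hi[0]),
        py_lo=float(geom.peri_lo[1]), py_hi=float(geom.peri_hi[1]),
        pz_lo=float(geom.peri_lo[2]), pz_hi=float(geom.peri_hi[2]),
        ex_half=float(geom.half_La),
        post_zlo=float(geom.post_lo[2]),
        pre_zhi=float(geom.pre_hi[2]),
        hc=float(geom.Hc),
        half_ls=float(geom.half_Ls),
    )


def _run_seed(seed: int | np.random.SeedSequence) -> tuple[np.random.Generator, int]:
    """Split one run seed into a placement stream and a kernel seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        [int(seed)]
    )
    place_ss, kernel_ss = ss.spawn(2)
    kernel_seed = int(kernel_ss.generate_state(1)[0] & 0x7FFFFFFF)
    return np.random.default_rng(place_ss), kernel_seed


def _run_prepared(
    world: _World,
    cfg: SynapseConfig,
    seed: int | np.random.SeedSequence,
    record_steps=None,
) -> RunResult:
    geom, params = world.geom, world.params
    comp_a, comp_t = world.comp_a, world.comp_t
    rng, kernel_seed = _run_seed(seed)

    n_r = world.n_receptors
    half_ls = geom.half_Ls
    r_xy = rng.uniform(-half_ls, half_ls, size=(n_r, 2))
    if n_r > 0:
        r_cap = 3.0 * math.sqrt(geom.As / (math.pi * n_r))
    else:
        r_cap = 1.0
    grid_start, grid_items, grid_nx, grid_cs = _build_receptor_grid(
        r_xy, half_ls, r_cap
    )
    r_state = np.full(n_r, comp_a.initial_idx, dtype=np.int64)

    trans = _build_transporter_faces(geom, cfg.glut_density, comp_t, params, rng)
    (t_state, t_emit, p_bind_t,
     f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map) = trans

    n_steps = params.n_steps
    open_counts = np.zeros(n_steps, dtype=np.int32)
    free_counts = np.zeros(n_steps, dtype=np.int32)
    if record_steps is None:
        snap_steps = np.empty(0, dtype=np.int64)
    else:
        snap_steps = np.asarray(sorted(int(s) for s in record_steps), dtype=np.int64)
    snap_open = np.zeros((snap_steps.size, n_r), dtype=np.uint8)

    g = _geometry_scalars(geom)
    rel = geom.release_point
    removed, discarded, steps_done, err = _run_kernel(
        kernel_seed, n_steps, params.N_g, params.sigma_nm,
        float(rel[0]), float(rel[1]), float(rel[2]),
        g["px_lo"], g["px_hi"], g["py_lo"], g["py_hi"], g["pz_lo"], g["pz_hi"],
        g["ex_half"], g["post_zlo"], g["pre_zhi"], g["hc"], g["half_ls"],
        r_xy[:, 0].copy(), r_xy[:, 1].copy(), r_state,
        world.p_bind_r_template, comp_a.bind_target,
        grid_start, grid_items, grid_nx, grid_cs, r_cap * r_cap,
        comp_a.p_any, comp_a.uni_start, comp_a.edge_target, comp_a.edge_cum,
        comp_a.edge_emit, comp_a.edge_remove, comp_a.ligand_count, comp_a.open_idx,
        t_state, t_emit, p_bind_t, comp_t.bind_target,
        comp_t.p_any, comp_t.uni_start, comp_t.edge_target, comp_t.edge_cum,
        comp_t.edge_emit, comp_t.edge_remove, comp_t.initial_idx,
        f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map,
        open_counts, free_counts, snap_steps, snap_open,
    )
    if err == 1:
        raise RuntimeError(
            f"glutamate conservation violated at step {steps_done} "
            f"(config {cfg.id}); this indicates an internal bookkeeping bug"
        )
    if err == 2:
        raise RuntimeError("transporter active-list overflow")

    max_open, peak_t, auc = curves.summarize_run(open_counts, params.dt_us)
    seed_int = kernel_seed
    return RunResult(
        open_counts=open_counts,
        free_counts=free_counts,
        dt_us=params.dt_us,
        maxOPEN=int(max_open),
        peak_time_us=float(peak_t),
        auc=float(auc),
        removed=int(removed),
        seed=seed_int,
        discarded_steps=int(discarded),
        snapshot_steps=snap_steps if snap_steps.size else None,
        open_snapshots=snap_open if snap_steps.size else None,
        receptor_xy=r_xy if snap_steps.size else None,
    )


def reflect(geom: SynapseGeometry, start, displacement) -> np.ndarray:
    """Resolve one Brownian segment against the membranes of ``geom``.

    Returns the final position after specular reflection off every face;
    the start point must lie in the ECS and the final position does too.
    This is the same ray-tracing the simulation kernel applies, exposed
    without any reactive surfaces (binding tests live in the kernel,
    where crossings are resolved in traversal order).
    """
    start = np.asarray(start, dtype=float).reshape(3)
    d = np.asarray(displacement, dtype=float).reshape(3)
    return _reflect_one(geom, start, d)


def _reflect_one(geom: SynapseGeometry, p: np.ndarray, d: np.ndarray) -> np.ndarray:
    comp_t = compile_scheme(builtin_scheme("glut"), 1.0)
    trans = _build_transporter_faces(geom, 0.0, comp_t, SimParams(),
                                     np.random.default_rng(0))
    (t_state, _e, p_bind_t,
     f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map) = trans
    g = _geometry_scalars(geom)
    code, x, y, z, _ = _trace(
        float(p[0]), float(p[1]), float(p[2]),
        float(d[0]), float(d[1]), float(d[2]),
        g["px_lo"], g["px_hi"], g["py_lo"], g["py_hi"], g["pz_lo"], g["pz_hi"],
        g["ex_half"], g["post_zlo"], g["pre_zhi"], g["hc"], g["half_ls"],
        np.empty(0), np.empty(0), np.empty(0, dtype=np.int64), np.zeros(1),
        np.zeros(2, dtype=np.int64), np.zeros(0, dtype=np.int64), 0, 1.0, 1.0,
        t_state, p_bind_t,
        f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map,
    )
    if code == 3:
        return np.asarray(p, dtype=float)  # unresolvable step: discarded
    return np.array([x, y, z])


def diffuse_tracers(
    geom: SynapseGeometry,
    start_positions: np.ndarray,
    n_steps: int,
    params: SimParams | None = None,
    seed: int = 0,
    sample_every: int = 1,
) -> np.ndarray:
    """Diffuse non-reacting tracers through the ECS of ``geom``.

    Returns sampled positions (every ``sample_every`` steps, concatenated
    over sampling times).  Used to validate the Einstein relation and the
    uniform stationary distribution of the reflected walk.
    """
    params = params or SimParams()
    comp_t = compile_scheme(builtin_scheme("glut"), params.dt_us)
    rng = np.random.default_rng(seed)
    trans = _build_transporter_faces(geom, 0.0, comp_t, params, rng)
    (t_state, _t_emit, p_bind_t,
     f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map) = trans
    g = _geometry_scalars(geom)
    pos = np.ascontiguousarray(start_positions, dtype=np.float64)
    n_samples = (n_steps // sample_every) * pos.shape[0]
    out = np.empty((n_samples, 3))
    n = _tracer_kernel(
        int(seed) & 0x7FFFFFFF, pos, n_steps, params.sigma_nm, sample_every,
        g["px_lo"], g["px_hi"], g["py_lo"], g["py_hi"], g["pz_lo"], g["pz_hi"],
        g["ex_half"], g["post_zlo"], g["pre_zhi"], g["hc"], g["half_ls"],
        np.empty(0), np.empty(0), np.empty(0, dtype=np.int64), np.zeros(1),
        np.zeros(2, dtype=np.int64), np.zeros(0, dtype=np.int64), 0, 1.0, 1.0,
        t_state, p_bind_t,
        f_uax, f_vax, f_u0, f_v0, f_du, f_dv, f_nu, f_nv, f_off, f_map,
        out,
    )
    return out[:n]


def run(
    cfg: SynapseConfig,
    geom: SynapseGeometry | None = None,
    schemes: dict[str, KineticScheme] | None = None,
    params: SimParams | None = None,
    seed: int = 0,
    record_steps=None,
    nampa_override: int | None = None,
) -> RunResult:
    """Simulate one vesicle release in one synapse configuration.

    ``nampa_override`` is a test hook forcing the receptor count (0 gives
    an all-zero open curve).  ``record_steps`` requests per-receptor open
    flags at those step indices (for spatial opening maps).
    """
    params = params or SimParams()
    world = _prepare_world(cfg, geom, schemes, params, nampa_override)
    return _run_prepared(world, cfg, np.random.SeedSequence([int(cfg.seed), int(seed)]),
                         record_steps)


def run_batch(
    cfg: SynapseConfig,
    n_runs: int,
    root_seed: int | None = None,
    geom: SynapseGeometry | None = None,
    schemes: dict[str, KineticScheme] | None = None,
    params: SimParams | None = None,
    record_steps=None,
) -> BatchResult:
    """Independent seeded runs of one configuration plus their mean curve.

    Run ``j`` is seeded by (config seed, j), so any run is reproducible in
    isolation and results are independent of worker scheduling.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    params = params or SimParams()
    base = cfg.seed if root_seed is None else root_seed
    world = _prepare_world(cfg, geom, schemes, params, None)
    results = []
    for j in range(n_runs):
        results.append(
            _run_prepared(
                world, cfg, np.random.SeedSequence([int(base), int(j)]), record_steps
            )
        )
    mean_curve = np.mean([r.open_counts for r in results], axis=0)
    return BatchResult(results=results, mean_curve=mean_curve, dt_us=params.dt_us)
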