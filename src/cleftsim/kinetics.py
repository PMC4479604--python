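"""Continuous-time Markov schemes for surface molecules.

AMPA receptors and glutamate transporters are modelled as independent
continuous-time Markov chains over a small set of conformational states.
Unimolecular transitions (conformational changes, unbinding, transport)
carry first-order rate constants in 1/s; bimolecular transitions (ligand
binding) carry second-order rate constants in 1/(M*s) and are *not*
executed here — they are collision events owned by the diffusion engine,
which reads the bimolecular rate constants off the scheme.

Rate constants are loaded from versioned YAML files that transcribe the
published schemes (see ``cleftsim/schemes/``) and are adjusted to the
simulation temperature with the usual Q10 law before use.

Discretization: at each time step dt a molecule performs at most one
unimolecular transition, drawn by competing risks — no transition with
probability exp(-k_total*dt), otherwise an edge chosen proportionally to
its rate.  This is exact for single-exit states and converges to the CTMC
marginals as dt -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Transition",
    "KineticScheme",
    "CompiledScheme",
    "MoleculeStateArray",
    "AdvanceEvents",
    "q10_adjust",
    "step_probability",
    "load_scheme",
    "builtin_scheme",
    "compile_scheme",
    "advance_states",
]

UNIMOLECULAR = 1
BIMOLECULAR = 2


def q10_adjust(k_ref: float, T_ref: float, T: float, Q10: float) -> float:
    """Temperature-correct a rate constant: k_ref * Q10**((T - T_ref)/10)."""
    if Q10 <= 0:
        raise ValueError("Q10 must be positive")
    return k_ref * Q10 ** ((T - T_ref) / 10.0)


def step_probability(k: float, dt: float) -> float:
    """Probability 1 - exp(-k*dt) of a first-order event within one step."""
    if k < 0:
        raise ValueError("rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -math.expm1(-k * dt)


@dataclass(frozen=True)
class Transition:
    """One directed edge of a kinetic scheme.

    ``order`` is 1 (rate in 1/s) or 2 (ligand binding, rate in 1/(M*s)).
    ``releases_ligand`` marks unbinding (a free glutamate is re-emitted);
    ``removes_ligand`` marks transport (the glutamate is deleted).
    """

    source: str
    target: str
    rate: float
    order: int = UNIMOLECULAR
    releases_ligand: bool = False
    removes_ligand: bool = False

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"negative rate on {self.source}->{self.target}")
        if self.order not in (UNIMOLECULAR, BIMOLECULAR):
            raise ValueError("order must be 1 or 2")
        if self.order == BIMOLECULAR and (self.releases_ligand or self.removes_ligand):
            raise ValueError("binding transitions cannot release/remove ligand")
        if self.releases_ligand and self.removes_ligand:
            raise ValueError("a transition releases or removes, not both")

    @property
    def ligand_delta(self) -> int:
        if self.order == BIMOLECULAR:
            return +1
        if self.releases_ligand or self.removes_ligand:
            return -1
        return 0


@dataclass(frozen=True)
class KineticScheme:
    """States and transitions of one surface-molecule species."""

    name: str
    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    initial_state: str
    open_state: str | None
    T_ref: float  # degrees C of the source rate constants
    Q10: float
    citation: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        if self.initial_state not in self.states:
            raise ValueError("initial_state not among states")
        if self.open_state is not None and self.open_state not in self.states:
            raise ValueError("open_state not among states")
        for t in self.transitions:
            if t.source not in self.states or t.target not in self.states:
                raise ValueError(f"transition {t.source}->{t.target} uses unknown state")
        self.ligand_counts  # validates consistency

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def ligand_counts(self) -> dict[str, int]:
        """Bound-glutamate count per state, propagated from the initial state.

        Raises if two paths from the initial state disagree, or if any
        state ends up with a negative count.
        """
        counts: dict[str, int] = {self.initial_state: 0}
        frontier = [self.initial_state]
        while frontier:
            s = frontier.pop()
            for t in self.transitions:
                pairs = []
                if t.source == s:
                    pairs.append((t.target, counts[s] + t.ligand_delta))
                if t.target == s:
                    pairs.append((t.source, counts[s] - t.ligand_delta))
                for other, c in pairs:
                    if other in counts:
                        if counts[other] != c:
                            raise ValueError(
                                f"inconsistent ligand bookkeeping at state {other}"
                            )
                    else:
                        counts[other] = c
                        frontier.append(other)
        missing = set(self.states) - set(counts)
        if missing:
            raise ValueError(f"states unreachable from initial state: {missing}")
        if any(c < 0 for c in counts.values()):
            raise ValueError("negative bound-ligand count")
        return counts

    def at_temperature(self, T: float) -> "KineticScheme":
        """Q10-correct every rate constant from T_ref to T (degrees C)."""
        new = tuple(
            replace(t, rate=q10_adjust(t.rate, self.T_ref, T, self.Q10))
            for t in self.transitions
        )
        return replace(self, transitions=new, T_ref=T)

    def with_clamped_ligand(self, conc_M: float) -> "KineticScheme":
        """Convert binding edges to pseudo-first-order at a fixed [glutamate].

        Used for well-mixed oracle comparisons; ligand bookkeeping is
        disabled (the bath is infinite).
        """
        new = []
        for t in self.transitions:
            if t.order == BIMOLECULAR:
                new.append(
                    Transition(t.source, t.target, t.rate * conc_M, UNIMOLECULAR)
                )
            else:
                new.append(replace(t, releases_ligand=False, removes_ligand=False))
        return replace(self, transitions=tuple(new), name=self.name + "_clamped")


# ---------------------------------------------------------------------------
# YAML loading
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = {"name", "states", "transitions", "initial_state", "T_ref_C", "Q10", "units"}


def load_scheme(path: str | Path) -> KineticScheme:
    """Load and validate a scheme file (strict schema, explicit units)."""
    doc = yaml.safe_load(Path(path).read_text())
    missing = _REQUIRED_KEYS - set(doc)
    if missing:
        raise ValueError(f"scheme file {path} missing keys: {sorted(missing)}")
    units = doc["units"]
    if units.get("unimolecular") != "1/s" or units.get("bimolecular") != "1/(M*s)":
        raise ValueError(
            "scheme files must declare units unimolecular '1/s' and bimolecular '1/(M*s)'"
        )
    transitions = tuple(
        Transition(
            source=str(e["from"]),
            target=str(e["to"]),
            rate=float(e["rate"]),
            order=int(e.get("order", 1)),
            releases_ligand=bool(e.get("releases_ligand", False)),
            removes_ligand=bool(e.get("removes_ligand", False)),
        )
        for e in doc["transitions"]
    )
    return KineticScheme(
        name=str(doc["name"]),
        states=tuple(str(s) for s in doc["states"]),
        transitions=transitions,
        initial_state=str(doc["initial_state"]),
        open_state=str(doc["open_state"]) if doc.get("open_state") else None,
        T_ref=float(doc["T_ref_C"]),
        Q10=float(doc["Q10"]),
        citation=str(doc.get("citation", "")),
        note=str(doc.get("note", "")),
    )


def builtin_scheme(name: str) -> KineticScheme:
    """Load one of the packaged default schemes by short name.

    ``"ampa"`` -> 9-state AMPA receptor scheme; ``"glut"`` -> glutamate
    transporter cycle.
    """
    from importlib.resources import files

    fname = {"ampa": "ampa_hausser_roth_1997.yaml", "glut": "glut_franks_2002.yaml"}[name]
    return load_scheme(files("cleftsim") / "schemes" / fname)


# ---------------------------------------------------------------------------
# Compilation to flat arrays (shared by advance_states and the engine)
# ---------------------------------------------------------------------------


@dataclass
class CompiledScheme:
    """Array form of a scheme at a fixed temperature and time step.

    Unimolecular edges are stored CSR-style per source state.  For each
    state at most one bimolecular (binding) edge is allowed — true of all
    packaged schemes — recorded as a per-state rate and target.
    """

    scheme: KineticScheme
    dt_us: float
    n_states: int
    initial_idx: int
    open_idx: int  # -1 when the scheme has no conducting state
    ligand_count: np.ndarray  # int64[n_states]
    k_total: np.ndarray  # float64[n_states], 1/s
    p_any: np.ndarray  # float64[n_states], per-step transition prob
    uni_start: np.ndarray  # int64[n_states + 1], CSR into edge arrays
    edge_target: np.ndarray  # int64[n_edges]
    edge_cum: np.ndarray  # float64[n_edges], cumulative branch prob in-state
    edge_emit: np.ndarray  # uint8[n_edges]
    edge_remove: np.ndarray  # uint8[n_edges]
    bind_rate: np.ndarray  # float64[n_states], 1/(M*s); 0 = non-binding state
    bind_target: np.ndarray  # int64[n_states]


def compile_scheme(scheme: KineticScheme, dt_us: float, T: float | None = None) -> CompiledScheme:
    """Flatten a scheme into arrays, optionally Q10-adjusted to T first."""
    if T is not None:
        scheme = scheme.at_temperature(T)
    idx = {s: i for i, s in enumerate(scheme.states)}
    n = scheme.n_states
    lig = np.array([scheme.ligand_counts[s] for s in scheme.states], dtype=np.int64)

    per_state: list[list[Transition]] = [[] for _ in range(n)]
    bind_rate = np.zeros(n)
    bind_target = np.full(n, -1, dtype=np.int64)
    for t in scheme.transitions:
        if t.order == BIMOLECULAR:
            s = idx[t.source]
            if bind_rate[s] > 0:
                raise ValueError(
                    f"state {t.source} has more than one binding edge (unsupported)"
                )
            bind_rate[s] = t.rate
            bind_target[s] = idx[t.target]
        else:
            per_state[idx[t.source]].append(t)

    k_total = np.zeros(n)
    uni_start = np.zeros(n + 1, dtype=np.int64)
    targets, cums, emits, removes = [], [], [], []
    for s in range(n):
        edges = per_state[s]
        k_total[s] = sum(t.rate for t in edges)
        acc = 0.0
        for t in edges:
            acc += t.rate / k_total[s] if k_total[s] > 0 else 0.0
            targets.append(idx[t.target])
            cums.append(acc)
            emits.append(1 if t.releases_ligand else 0)
            removes.append(1 if t.removes_ligand else 0)
        if edges:
            cums[-1] = 1.0 + 1e-12  # guard against rounding in the branch draw
        uni_start[s + 1] = len(targets)
        # a ligand-holding state must be able to leave, otherwise glutamate
        # would be silently trapped forever
        if lig[s] > 0 and k_total[s] == 0.0:
            raise ValueError(f"ligand-holding state {scheme.states[s]} has no exit")

    dt_s = dt_us * 1e-6
    return CompiledScheme(
        scheme=scheme,
        dt_us=dt_us,
        n_states=n,
        initial_idx=idx[scheme.initial_state],
        open_idx=idx[scheme.open_state] if scheme.open_state else -1,
        ligand_count=lig,
        k_total=k_total,
        p_any=-np.expm1(-k_total * dt_s),
        uni_start=uni_start,
        edge_target=np.array(targets, dtype=np.int64),
        edge_cum=np.array(cums, dtype=np.float64),
        edge_emit=np.array(emits, dtype=np.uint8),
        edge_remove=np.array(removes, dtype=np.uint8),
        bind_rate=bind_rate,
        bind_target=bind_target,
    )


# ---------------------------------------------------------------------------
# Vectorized state advancement
# ---------------------------------------------------------------------------


@dataclass
class MoleculeStateArray:
    """Per-molecule Markov state and surface position for one species."""

    compiled: CompiledScheme
    states: np.ndarray  # int64[n_molecules]
    positions: np.ndarray | None = None  # float64[n_molecules, 3]

    @classmethod
    def initial(cls, compiled: CompiledScheme, n: int, positions=None) -> "MoleculeStateArray":
        return cls(compiled, np.full(n, compiled.initial_idx, dtype=np.int64), positions)

    @property
    def n(self) -> int:
        return self.states.size

    def state_counts(self) -> np.ndarray:
        return np.bincount(self.states, minlength=self.compiled.n_states)

    def bound_ligand(self) -> int:
        return int(self.compiled.ligand_count[self.states].sum())

    def n_open(self) -> int:
        if self.compiled.open_idx < 0:
            return 0
        return int(np.count_nonzero(self.states == self.compiled.open_idx))


@dataclass
class AdvanceEvents:
    """Ligand events emitted by one unimolecular update."""

    emitted_positions: np.ndarray  # (n_emitted, 3); empty when no positions
    n_emitted: int
    n_removed: int


def advance_states(
    mols: MoleculeStateArray, dt_us: float, rng: np.random.Generator
) -> AdvanceEvents:
    """One competing-risks step for every molecule (unimolecular edges only).

    Each molecule transitions with probability 1 - exp(-k_total*dt) and the
    destination edge is drawn proportionally to its rate.  Unbinding edges
    report the emission positions; transport edges report removals.
    """
    comp = mols.compiled
    if not math.isclose(dt_us, comp.dt_us, rel_tol=1e-12):
        comp = compile_scheme(comp.scheme, dt_us)
        mols.compiled = comp
    s = mols.states
    moving = np.nonzero(rng.random(s.size) < comp.p_any[s])[0]
    n_emit = 0
    n_rem = 0
    emit_pos = []
    if moving.size:
        u = rng.random(moving.size)
        for j, i in enumerate(moving):
            st = s[i]
            e = comp.uni_start[st]
            end = comp.uni_start[st + 1]
            while e < end - 1 and u[j] > comp.edge_cum[e]:
                e += 1
            s[i] = comp.edge_target[e]
            if comp.edge_emit[e]:
                n_emit += 1
                if mols.positions is not None:
                    emit_pos.append(mols.positions[i])
            elif comp.edge_remove[e]:
                n_rem += 1
    out = (
        np.array(emit_pos, dtype=float).reshape(-1, 3)
        if emit_pos
        else np.empty((0, 3))
    )
    return AdvanceEvents(out, n_emit, n_rem)
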