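"""Finite-state-machine model of the sequential two-step TRAP1 ATPase cycle.

The closed TRAP1 dimer is asymmetric: one protomer arm is buckled, the other
straight, and only the buckled protomer is hydrolysis-competent.  The cycle
modeled here is

    Open(ATP,ATP) --k_close--> Closed(ATP,ATP; one protomer buckled)
        --k_hyd_buckled--> Closed(ADP buckled, ATP straight)
        --k_flip--> Closed(ADP straight, ATP buckled)     (asymmetry flip)
        --k_hyd_buckled--> Closed(ADP,ADP)
        --k_open_dd--> Open                               (cycle reset)

Buckling on closure is a fair, independent coin per dimer, and while both
sites still hold ATP the closed dimer exchanges its buckling direction
(rate ``k_swap_tt``): the asymmetry only locks in once the first ATP is
hydrolyzed.  This reproduces the 50:50 conformer partition seen for the
ATP/ATP state and lets the hydrolysis-competent protomer of a heterodimer
eventually reach the buckled, catalytic conformation, so exactly half of
the bound ATP is consumed by a +/hydrolysis-dead dimer under
single-turnover conditions.

Protomer variants: ``hydrolysis_competent=False`` models the active-site
E115A mutation (binds but never hydrolyzes); ``gamma_sensor_intact=False``
models the γ-phosphate-sensor mutation (R402A/R417A), which pins that
protomer in the straight, ADP-like conformation (its partner is buckled
whenever the dimer is closed, and neither closure coin nor swap nor flip
can move the pinned arm).

Two engines run the same state graph: an exact stochastic simulation
(Gillespie SSA) over independent dimers, and the linear chemical master
equation propagated with matrix exponentials.  A crystal mode freezes the
conformation (no closure, swap, flip or reopening) and lets both arms
hydrolyze at separate rates, mimicking in-lattice hydrolysis time courses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import expm


class State(NamedTuple):
    """Instantaneous dimer state: conformation, per-protomer nucleotide, buckled arm."""

    conf: str  # "open" | "closed"
    nuc: tuple  # ("T"|"D", "T"|"D") per protomer
    buckled: Optional[int]  # protomer index, None when open

    def label(self) -> str:
        if self.conf == "open":
            return f"Open({self.nuc[0]},{self.nuc[1]})"
        marks = ["b" if self.buckled == i else "s" for i in range(2)]
        return f"Closed({self.nuc[0]}{marks[0]},{self.nuc[1]}{marks[1]})"

    @property
    def n_adp(self) -> int:
        return sum(1 for n in self.nuc if n == "D")


@dataclass(frozen=True)
class ProtomerSpec:
    hydrolysis_competent: bool = True
    gamma_sensor_intact: bool = True
    labeled: bool = False


@dataclass(frozen=True)
class Variant:
    """A pair of protomer specifications defining the dimer variant."""

    protomers: tuple

    def __post_init__(self):
        if len(self.protomers) != 2:
            raise ValueError("a dimer has exactly two protomers")
        if sum(p.labeled for p in self.protomers) > 1:
            raise ValueError("at most one protomer may carry the conformer label")
        if all(not p.gamma_sensor_intact for p in self.protomers):
            raise ValueError(
                "both protomers are sensor-broken: contradictory pinning, "
                "both arms cannot be straight in a closed dimer"
            )

    def __getitem__(self, i: int) -> ProtomerSpec:
        return self.protomers[i]

    @property
    def labeled_index(self) -> Optional[int]:
        for i, p in enumerate(self.protomers):
            if p.labeled:
                return i
        return None

    @property
    def pinned_straight(self) -> Optional[int]:
        for i, p in enumerate(self.protomers):
            if not p.gamma_sensor_intact:
                return i
        return None

    @classmethod
    def wild_type(cls, labeled: Optional[int] = 0) -> "Variant":
        return cls(tuple(ProtomerSpec(labeled=(i == labeled)) for i in range(2)))

    @classmethod
    def het_hydrolysis_dead(cls, labeled: Optional[int] = 0) -> "Variant":
        """+/E115A: protomer 1 binds ATP but never hydrolyzes."""
        return cls(
            (
                ProtomerSpec(labeled=(labeled == 0)),
                ProtomerSpec(hydrolysis_competent=False, labeled=(labeled == 1)),
            )
        )

    @classmethod
    def dead_dead(cls) -> "Variant":
        return cls(tuple(ProtomerSpec(hydrolysis_competent=False) for _ in range(2)))

    @classmethod
    def het_sensor_broken(cls, labeled: Optional[int] = 0) -> "Variant":
        """+/R402A: protomer 1 is pinned in the straight, ADP-like conformation."""
        return cls(
            (
                ProtomerSpec(labeled=(labeled == 0)),
                ProtomerSpec(gamma_sensor_intact=False, labeled=(labeled == 1)),
            )
        )


@dataclass
class CycleRates:
    """Rate parameterization of the cycle, all in events per ``time_unit``."""

    k_close: float
    k_hyd_buckled: float
    k_open_dd: float
    k_flip: float = math.inf  # inf = flip instantaneous on Pi release
    k_hyd_straight: float = 0.0
    k_open_leak: float = 0.0
    k_swap_tt: float = 10.0
    time_unit: str = "min"
    regime: str = "mg"

    def __post_init__(self):
        for name in ("k_close", "k_hyd_buckled", "k_open_dd", "k_hyd_straight",
                     "k_open_leak", "k_swap_tt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_flip < 0:
            raise ValueError("k_flip must be >= 0 (or inf)")

    @classmethod
    def mg(cls, **overrides) -> "CycleRates":
        """Turnover conditions with Mg2+: closure (0.16/min) is rate-limiting."""
        defaults = dict(
            k_close=0.16, k_hyd_buckled=2.0, k_open_dd=5.0, k_flip=10.0,
            k_hyd_straight=0.0, k_open_leak=0.0, k_swap_tt=10.0,
            time_unit="min", regime="mg",
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def mg_free(cls, **overrides) -> "CycleRates":
        """Mg2+-free conditions: closure 6.95/hr, buckled hydrolysis 0.5808/hr."""
        defaults = dict(
            k_close=6.95, k_hyd_buckled=0.5808, k_open_dd=10.0, k_flip=20.0,
            k_hyd_straight=0.0, k_open_leak=0.0, k_swap_tt=60.0,
            time_unit="hr", regime="mg_free",
        )
        defaults.update(overrides)
        return cls(**defaults)


def _closed(nuc, buckled) -> State:
    return State("closed", tuple(nuc), buckled)


def _flip_allowed(state: State, variant: Variant) -> bool:
    """Flip fires from the hemi-hydrolyzed state: ADP on the buckled arm,
    ATP on a straight arm that is free to buckle."""
    b = state.buckled
    s = 1 - b
    return (
        state.nuc[b] == "D"
        and state.nuc[s] == "T"
        and variant[s].gamma_sensor_intact
    )


def transitions(
    state: State,
    rates: CycleRates,
    variant: Variant,
    mode: str = "multiple",
    crystal: bool = False,
):
    """All outgoing transitions of a state: list of (rate, target, tag).

    Branching transitions (the buckling coin and, in single-turnover mode,
    the random re-assignment of the dimer's own nucleotides on closure)
    appear as parallel edges with the branch probability folded into the
    rate, so the list is directly usable by both engines.
    """
    if mode not in ("multiple", "single"):
        raise ValueError("mode must be 'multiple' or 'single'")
    out = []
    if state.conf == "open":
        if crystal or rates.k_close == 0 or "T" not in state.nuc:
            return out
        assignments = [state.nuc]
        if state.nuc[0] != state.nuc[1]:
            # nucleotides are exchangeable in the open dimer
            assignments.append((state.nuc[1], state.nuc[0]))
        pin = variant.pinned_straight
        bucklings = [1 - pin] if pin is not None else [0, 1]
        w = rates.k_close / (len(assignments) * len(bucklings))
        for nuc in assignments:
            for b in bucklings:
                out.append((w, _closed(nuc, b), "close"))
        return out

    b = state.buckled
    s = 1 - b
    # buckling exchange while both sites still hold ATP
    if (
        not crystal
        and state.nuc == ("T", "T")
        and variant.pinned_straight is None
        and rates.k_swap_tt > 0
    ):
        out.append((rates.k_swap_tt, _closed(state.nuc, s), "swap"))
    # hydrolysis on the buckled arm
    if state.nuc[b] == "T" and variant[b].hydrolysis_competent and rates.k_hyd_buckled > 0:
        new_nuc = list(state.nuc)
        new_nuc[b] = "D"
        target = _closed(new_nuc, b)
        if not crystal and math.isinf(rates.k_flip) and _flip_allowed(target, variant):
            target = _closed(new_nuc, s)  # instantaneous flip on Pi release
        out.append((rates.k_hyd_buckled, target, "hyd"))
    # residual hydrolysis on the straight arm (crystal lattice, or a leak)
    if state.nuc[s] == "T" and variant[s].hydrolysis_competent and rates.k_hyd_straight > 0:
        new_nuc = list(state.nuc)
        new_nuc[s] = "D"
        out.append((rates.k_hyd_straight, _closed(new_nuc, b), "hyd"))
    if crystal:
        return out
    # asymmetry flip after the first hydrolysis
    if not math.isinf(rates.k_flip) and rates.k_flip > 0 and _flip_allowed(state, variant):
        out.append((rates.k_flip, _closed(state.nuc, s), "flip"))
    # reopening
    if state.nuc == ("D", "D") and rates.k_open_dd > 0:
        nuc = ("T", "T") if mode == "multiple" else ("D", "D")
        out.append((rates.k_open_dd, State("open", nuc, None), "open"))
    elif state.nuc != ("D", "D") and rates.k_open_leak > 0:
        nuc = ("T", "T") if mode == "multiple" else state.nuc
        out.append((rates.k_open_leak, State("open", nuc, None), "open_leak"))
    return out


@dataclass
class StateGraph:
    """Reachable labeled state space with its transition list."""

    states: list
    index: dict
    edges: list  # (i, j, rate, tag)
    initial: np.ndarray  # initial probability distribution over states
    variant: Variant
    mode: str
    crystal: bool

    @property
    def n(self) -> int:
        return len(self.states)

    def rate_matrix(self) -> np.ndarray:
        """Generator A with A[i, j] the i->j rate; dP/dt = P A for row vector P."""
        A = np.zeros((self.n, self.n))
        for i, j, rate, _ in self.edges:
            A[i, j] += rate
        A[np.diag_indices(self.n)] -= A.sum(axis=1)
        return A

    def hydrolysis_rates(self) -> np.ndarray:
        """Total hydrolysis flux out of each state (for cumulative Pi)."""
        h = np.zeros(self.n)
        for i, _, rate, tag in self.edges:
            if tag == "hyd":
                h[i] += rate
        return h

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": [s.label() for s in self.states],
                "edges": [
                    {"from": self.states[i].label(), "to": self.states[j].label(),
                     "rate": rate, "event": tag}
                    for i, j, rate, tag in self.edges
                ],
                "initial": {
                    self.states[i].label(): p
                    for i, p in enumerate(self.initial) if p > 0
                },
                "mode": self.mode,
                "crystal": self.crystal,
            },
            indent=2,
        )


def _initial_distribution(variant: Variant, initial: str) -> list:
    """(state, probability) pairs for the named initial condition."""
    if initial == "open_tt":
        return [(State("open", ("T", "T"), None), 1.0)]
    if initial == "closed_tt":
        pin = variant.pinned_straight
        if pin is not None:
            return [(_closed(("T", "T"), 1 - pin), 1.0)]
        return [(_closed(("T", "T"), 0), 0.5), (_closed(("T", "T"), 1), 0.5)]
    raise ValueError("initial must be 'open_tt' or 'closed_tt'")


def enumerate_states(
    rates: CycleRates,
    variant: Variant,
    mode: str = "multiple",
    crystal: bool = False,
    initial: str = "open_tt",
) -> StateGraph:
    """Breadth-first enumeration of the reachable state graph."""
    if crystal and initial == "open_tt":
        initial = "closed_tt"  # the lattice fixes the closed state
    init_pairs = _initial_distribution(variant, initial)
    states: list = []
    index: dict = {}
    edges: list = []
    frontier = []
    for s, _ in init_pairs:
        if s not in index:
            index[s] = len(states)
            states.append(s)
            frontier.append(s)
    while frontier:
        s = frontier.pop()
        for rate, target, tag in transitions(s, rates, variant, mode=mode, crystal=crystal):
            if rate <= 0:
                continue
            if target not in index:
                index[target] = len(states)
                states.append(target)
                frontier.append(target)
            edges.append((index[s], index[target], rate, tag))
    init = np.zeros(len(states))
    for s, p in init_pairs:
        init[index[s]] += p
    return StateGraph(states, index, edges, init, variant, mode, crystal)


@dataclass
class SimResult:
    """Occupancies and observables from either engine on a common time grid."""

    engine: str  # "ssa" | "master"
    times: np.ndarray
    graph: StateGraph
    occupancy: np.ndarray  # (n_times, n_states) fractions/probabilities
    fraction_closed: np.ndarray
    cum_pi: np.ndarray  # cumulative Pi released per dimer
    hydrolyzed_fraction: np.ndarray  # of initially bound ATP (2 per dimer)
    n_dimers: Optional[int] = None
    seed: Optional[int] = None
    first_tt_buckled: Optional[np.ndarray] = None  # per-dimer labeled-arm coin
    events: Optional[list] = None  # per-dimer (time, tag) logs when recorded

    @property
    def variant(self) -> Variant:
        return self.graph.variant


def _observables(graph: StateGraph, times: np.ndarray, occ: np.ndarray):
    closed_mask = np.array([s.conf == "closed" for s in graph.states], dtype=float)
    n_adp = np.array([s.n_adp for s in graph.states], dtype=float)
    fraction_closed = occ @ closed_mask
    hydrolyzed = occ @ n_adp / 2.0
    flux = occ @ graph.hydrolysis_rates()
    cum_pi = np.concatenate([[0.0], cumulative_trapezoid(flux, times)])
    return fraction_closed, cum_pi, hydrolyzed


def simulate_master(
    rates: CycleRates,
    variant: Variant,
    t_grid,
    mode: str = "multiple",
    crystal: bool = False,
    initial: str = "open_tt",
) -> SimResult:
    """Propagate the chemical master equation on the enumerated state graph.

    Probabilities are advanced with matrix exponentials of the generator, so
    arbitrary (strictly increasing) time grids are supported; cumulative Pi
    per dimer is the time integral of the hydrolysis flux.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    graph = enumerate_states(rates, variant, mode=mode, crystal=crystal, initial=initial)
    A = graph.rate_matrix()
    occ = np.empty((len(t), graph.n))
    p = graph.initial.copy()
    if t[0] > 0:
        p = p @ expm(A * t[0])
    occ[0] = p
    prop_cache: dict = {}
    for k in range(1, len(t)):
        dt = t[k] - t[k - 1]
        key = round(dt, 12)
        if key not in prop_cache:
            prop_cache[key] = expm(A * dt)
        p = p @ prop_cache[key]
        occ[k] = p
    if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-9):
        raise RuntimeError("master-equation probabilities drifted; use a finer grid")
    fraction_closed, cum_pi, hydrolyzed = _observables(graph, t, occ)
    return SimResult("master", t, graph, occ, fraction_closed, cum_pi, hydrolyzed)


def simulate_ssa(
    rates: CycleRates,
    variant: Variant,
    n_dimers: int,
    t_max: float,
    seed: int,
    n_times: int = 101,
    mode: str = "multiple",
    crystal: bool = False,
    initial: str = "open_tt",
    record_events: bool = False,
) -> SimResult:
    """Exact Gillespie simulation of ``n_dimers`` independent dimers.

    Per-dimer random substreams are derived deterministically from the single
    integer seed.  A state with zero total propensity is absorbing; the
    trajectory is padded as constant to ``t_max``.
    """
    if n_dimers < 1:
        raise ValueError("n_dimers must be >= 1")
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    graph = enumerate_states(rates, variant, mode=mode, crystal=crystal, initial=initial)
    # per-state outgoing edge arrays for fast sampling
    out_rates = [[] for _ in range(graph.n)]
    out_targets = [[] for _ in range(graph.n)]
    out_tags = [[] for _ in range(graph.n)]
    for i, j, rate, tag in graph.edges:
        out_rates[i].append(rate)
        out_targets[i].append(j)
        out_tags[i].append(tag)
    cum_rates = [np.cumsum(r) if r else np.empty(0) for r in out_rates]
    totals = [c[-1] if len(c) else 0.0 for c in cum_rates]

    t_grid = np.linspace(0.0, t_max, n_times)
    occ_counts = np.zeros((n_times, graph.n), dtype=np.int64)
    pi_counts = np.zeros(n_times)
    lab = variant.labeled_index
    first_tt = np.full(n_dimers, np.nan)
    all_events: Optional[list] = [] if record_events else None

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_dimers)
    init_cum = np.cumsum(graph.initial)
    is_closed_tt = [s.conf == "closed" and s.nuc == ("T", "T") for s in graph.states]

    for d in range(n_dimers):
        rng = np.random.default_rng(children[d])
        si = int(np.searchsorted(init_cum, rng.random(), side="right"))
        t = 0.0
        gi = 0  # next grid index to fill
        events = [] if record_events else None
        if is_closed_tt[si] and lab is not None:
            first_tt[d] = 1.0 if graph.states[si].buckled == lab else 0.0
        while True:
            total = totals[si]
            if total <= 0.0:
                occ_counts[gi:, si] += 1
                break
            t_next = t + rng.exponential(1.0 / total)
            g_next = int(np.searchsorted(t_grid, min(t_next, t_max), side="right"))
            occ_counts[gi:g_next, si] += 1
            gi = g_next
            if t_next > t_max:
                break
            pick = int(np.searchsorted(cum_rates[si], rng.random() * total, side="right"))
            tag = out_tags[si][pick]
            si = out_targets[si][pick]
            t = t_next
            if tag == "hyd":
                pi_counts[gi:] += 1.0
            if tag == "close" and np.isnan(first_tt[d]) and is_closed_tt[si] and lab is not None:
                first_tt[d] = 1.0 if graph.states[si].buckled == lab else 0.0
            if events is not None:
                events.append((t, tag, graph.states[si].label()))
        if all_events is not None:
            all_events.append(events)

    occ = occ_counts / float(n_dimers)
    closed_mask = np.array([s.conf == "closed" for s in graph.states], dtype=float)
    n_adp = np.array([s.n_adp for s in graph.states], dtype=float)
    return SimResult(
        engine="ssa",
        times=t_grid,
        graph=graph,
        occupancy=occ,
        fraction_closed=occ @ closed_mask,
        cum_pi=pi_counts / float(n_dimers),
        hydrolyzed_fraction=occ @ n_adp / 2.0,
        n_dimers=n_dimers,
        seed=seed,
        first_tt_buckled=first_tt if lab is not None else None,
        events=all_events,
    )


def single_turnover_fraction(
    rates: CycleRates,
    variant: Variant,
    t_max: float,
    n_times: int = 200,
    engine: str = "master",
    n_dimers: int = 10000,
    seed: int = 0,
) -> SimResult:
    """Fraction of initially bound ATP hydrolyzed over time (no rebinding).

    Under single-turnover conditions each dimer carries its two initially
    bound ATPs and the pool is never replenished: released nucleotides can
    only re-assort over the dimer's own two sites on re-closure.  The
    asymptote is 1.0 for +/+, 0.5 for +/hydrolysis-dead with no reopening
    leak, and 0.0 for a doubly dead dimer.
    """
    if engine == "master":
        t = np.linspace(0.0, t_max, n_times)
        return simulate_master(rates, variant, t, mode="single")
    return simulate_ssa(
        rates, variant, n_dimers, t_max, seed, n_times=n_times, mode="single"
    )


def crystal_mode_timecourse(
    rates: CycleRates,
    t_checkpoints,
    variant: Optional[Variant] = None,
):
    """Nucleotide-state occupancies of a lattice-trapped closed dimer.

    With flip and closure disabled (the crystal fixes the conformation), both
    arms hydrolyze independently at ``k_hyd_buckled`` and ``k_hyd_straight``.
    Returns one row per checkpoint with P(TT), P(TD), P(DD) and, within the
    TD intermediate, the probability that the remaining ATP sits on the
    straight arm.
    """
    import pandas as pd

    if variant is None:
        variant = Variant.wild_type()
    t = np.asarray(t_checkpoints, dtype=float)
    grid = np.unique(np.concatenate([[0.0], t]))
    res = simulate_master(rates, variant, grid, crystal=True, initial="closed_tt")
    rows = []
    for tc in t:
        k = int(np.argmin(np.abs(res.times - tc)))
        p = res.occupancy[k]
        p_tt = p_td = p_dd = p_td_t_straight = 0.0
        for i, s in enumerate(res.graph.states):
            if s.n_adp == 0:
                p_tt += p[i]
            elif s.n_adp == 2:
                p_dd += p[i]
            else:
                p_td += p[i]
                if s.nuc[1 - s.buckled] == "T":
                    p_td_t_straight += p[i]
        rows.append(
            {
                "time": tc,
                "P_TT": p_tt,
                "P_TD": p_td,
                "P_DD": p_dd,
                "P_T_on_straight_given_TD": p_td_t_straight / p_td if p_td > 0 else np.nan,
                "dominant": max(
                    [("TT", p_tt), ("TD", p_td), ("DD", p_dd)], key=lambda x: x[1]
                )[0],
            }
        )
    return pd.DataFrame(rows)


_CONDITIONS = {
    "closed_tt": lambda s: s.conf == "closed" and s.nuc == ("T", "T"),
    "hemi": lambda s: s.conf == "closed" and s.n_adp == 1,
    "dd": lambda s: s.conf == "closed" and s.n_adp == 2,
    "closed": lambda s: s.conf == "closed",
}


def buckled_fraction(result: SimResult, condition: str = "closed_tt") -> Optional[float]:
    """Fraction of labeled protomers buckled, conditioned on a state class.

    Aggregates occupancy over the whole recorded time grid (dimer-time within
    the class).  Requires exactly one labeled protomer; returns None when the
    conditioning class is never occupied.
    """
    lab = result.variant.labeled_index
    if lab is None:
        raise ValueError("variant has no labeled protomer for conformer readout")
    try:
        pred = _CONDITIONS[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}; choose from {sorted(_CONDITIONS)}")
    weights = result.occupancy.sum(axis=0)
    total = buckled = 0.0
    for i, s in enumerate(result.graph.states):
        if pred(s):
            total += weights[i]
            if s.buckled == lab:
                buckled += weights[i]
    if total <= 0:
        return None
    return buckled / total
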