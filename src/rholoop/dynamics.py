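"""Synchronous and random-asynchronous simulation, attractors, output classes.

Synchronous semantics: every reaction takes one time increment, so all
regulated nodes recompute simultaneously from the state at time ``t``.  Nodes
without a rule (the clamped input, constitutive inhibitors, knocked-out
nodes) hold their value.  Because the synchronous map is a function on a
finite state space, every trajectory enters a cycle; :func:`find_attractor`
locates it by hashing visited states.

Random-asynchronous semantics: in each increment at most one executable
reaction fires — a node whose rule value disagrees with its current state is
drawn uniformly with a seeded generator and updated.  If no node is unstable
the state carries over.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .expr import evaluate
from .model import BooleanNetwork, NetworkError

StateVector = dict[str, int]


def _check_state(net: BooleanNetwork, s: StateVector) -> None:
    missing = set(net.node_names) - set(s)
    if missing:
        raise NetworkError(f"state missing node(s): {sorted(missing)}")


def step_synchronous(net: BooleanNetwork, s: StateVector) -> StateVector:
    """One synchronous update; clamped/rule-less nodes keep their value."""
    _check_state(net, s)
    nxt: StateVector = {}
    for node in net.nodes:
        rule = net.rule(node.name)
        if rule is None or node.is_clamped:
            nxt[node.name] = s[node.name] if node.clamp is None else node.clamp
        else:
            nxt[node.name] = int(evaluate(rule.expression, s))
    return nxt


@dataclass
class Trace:
    """Binary time-course: ``states[t, i]`` is node ``nodes[i]`` at time t."""

    nodes: list[str]
    states: np.ndarray  # shape (T+1, N), uint8
    update_scheme: str = "synchronous"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2 or self.states.shape[1] != len(self.nodes):
            raise ValueError("trace shape does not match node list")

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def T(self) -> int:
        return self.states.shape[0] - 1

    def series(self, name: str) -> np.ndarray:
        return self.states[:, self.nodes.index(name)]

    def state_at(self, t: int) -> StateVector:
        return dict(zip(self.nodes, (int(v) for v in self.states[t])))

    def first_on(self, name: str) -> int | None:
        """First increment at which the node is ON, or None."""
        hits = np.flatnonzero(self.series(name) == 1)
        return int(hits[0]) if hits.size else None

    def first_off(self, name: str) -> int | None:
        hits = np.flatnonzero(self.series(name) == 0)
        return int(hits[0]) if hits.size else None

    def to_tsv(self) -> str:
        """Heatmap layout: rows = nodes in declaration order, columns = t."""
        header = "node\t" + "\t".join(str(t) for t in range(len(self)))
        lines = [header]
        for i, name in enumerate(self.nodes):
            lines.append(name + "\t" + "\t".join(str(int(v)) for v in self.states[:, i]))
        return "\n".join(lines) + "\n"


def simulate_synchronous(net: BooleanNetwork, T: int) -> Trace:
    """Deterministic trace of length ``T + 1`` from the initial condition."""
    if T < 1:
        raise ValueError("T must be >= 1")
    names = net.node_names
    s = net.initial_state
    rows = [[s[n] for n in names]]
    for _ in range(T):
        s = step_synchronous(net, s)
        rows.append([s[n] for n in names])
    return Trace(names, np.array(rows, dtype=np.uint8), "synchronous")


def simulate_asynchronous(net: BooleanNetwork, T: int, seed: int) -> Trace:
    """Random-asynchronous trace: one uniformly drawn unstable node updates
    per increment.  Identical (network, seed) pairs give identical traces."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    names = net.node_names
    ruled = [(n.name, net.rule(n.name)) for n in net.nodes
             if net.rule(n.name) is not None and not n.is_clamped]
    s = net.initial_state
    rows = [[s[n] for n in names]]
    for _ in range(T):
        unstable = [name for name, rule in ruled
                    if int(evaluate(rule.expression, s)) != s[name]]
        if unstable:
            pick = unstable[int(rng.integers(len(unstable)))]
            s = dict(s)
            s[pick] = 1 - s[pick]
        rows.append([s[n] for n in names])
    return Trace(names, np.array(rows, dtype=np.uint8), "asynchronous", seed)


class NodeClass(str, Enum):
    STABLE_ACTIVE = "stable_active"
    STABLE_INACTIVE = "stable_inactive"
    CYCLIC = "cyclic"


@dataclass
class AttractorReport:
    """Transient length, attractor cycle and per-node dynamic class."""

    transient_length: int
    cycle: list[StateVector]
    node_class: dict[str, NodeClass] = field(default_factory=dict)
    on_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def cycle_length(self) -> int:
        return len(self.cycle)

    def to_json(self) -> str:
        return json.dumps(
            {
                "transient_length": self.transient_length,
                "cycle_length": self.cycle_length,
                "node_class": {k: v.value for k, v in self.node_class.items()},
                "on_fraction": self.on_fraction,
            },
            indent=2,
            sort_keys=True,
        )


def find_attractor(net: BooleanNetwork, max_steps: int | None = None) -> AttractorReport:
    """Follow the deterministic orbit until a state repeats.

    The pigeonhole bound guarantees a repeat within ``2**N`` steps; the
    repeat closes the attractor cycle because synchronous dynamics are a
    function of state.
    """
    names = net.node_names
    if max_steps is None:
        max_steps = 2 ** min(len(names), 24) + 1
    s = net.initial_state
    seen: dict[tuple[int, ...], int] = {}
    orbit: list[StateVector] = []
    for t in range(max_steps + 1):
        key = tuple(s[n] for n in names)
        if key in seen:
            start = seen[key]
            cycle = orbit[start:]
            return _report(names, start, cycle)
        seen[key] = t
        orbit.append(s)
        s = step_synchronous(net, s)
    raise RuntimeError("no repeat found within max_steps")  # pragma: no cover


def _report(names: list[str], transient: int, cycle: list[StateVector]) -> AttractorReport:
    node_class: dict[str, NodeClass] = {}
    on_fraction: dict[str, float] = {}
    for n in names:
        frac = sum(s[n] for s in cycle) / len(cycle)
        on_fraction[n] = frac
        if frac == 1.0:
            node_class[n] = NodeClass.STABLE_ACTIVE
        elif frac == 0.0:
            node_class[n] = NodeClass.STABLE_INACTIVE
        else:
            node_class[n] = NodeClass.CYCLIC
    return AttractorReport(transient, cycle, node_class, on_fraction)


class OutputCategory(str, Enum):
    """RhoA/Rac1 binary output dynamics of a simulation."""

    RAC_PERSISTENT = "rac_persistent"   # Rac1 stable ON, RhoA stable OFF
    CYCLIC = "cyclic"                   # both outputs cycle
    SWITCH = "switch"                   # Rac1 stable OFF, RhoA stable ON
    OTHER = "other"                     # any remaining combination


@dataclass(frozen=True)
class ClassifiedOutput:
    category: OutputCategory
    rhoa_dominant: bool
    rac1_class: NodeClass
    rhoa_class: NodeClass


def classify_hierarchy_output(
    report: AttractorReport, rac1: str = "Rac1", rhoa: str = "RhoA"
) -> ClassifiedOutput:
    """Classify the GTPase output dynamics of an attractor report.

    The three outcomes the model exhibits are persistent Rac1 activity,
    cyclic bursts of both GTPases, and the Rac1-to-RhoA switch; anything
    else (e.g. both outputs stably OFF after a knockout) is ``OTHER``.
    ``rhoa_dominant`` flags RhoA being ON for more of the cycle than Rac1.
    """
    for name in (rac1, rhoa):
        if name not in report.node_class:
            raise NetworkError(f"report lacks output node {name!r}")
    rc, hc = report.node_class[rac1], report.node_class[rhoa]
    if rc is NodeClass.STABLE_ACTIVE and hc is NodeClass.STABLE_INACTIVE:
        category = OutputCategory.RAC_PERSISTENT
    elif rc is NodeClass.STABLE_INACTIVE and hc is NodeClass.STABLE_ACTIVE:
        category = OutputCategory.SWITCH
    elif rc is NodeClass.CYCLIC and hc is NodeClass.CYCLIC:
        category = OutputCategory.CYCLIC
    else:
        category = OutputCategory.OTHER
    dominant = report.on_fraction[rhoa] > report.on_fraction[rac1]
    return ClassifiedOutput(category, dominant, rc, hc)


@dataclass(frozen=True)
class SwitchOnTime:
    """ON-increments of each output after the first Rac1-OFF/RhoA-ON switch."""

    switched: bool
    switch_time: int | None
    rac_on: int
    rhoa_on: int


def on_time_after_switch(
    trace: Trace, rac1: str = "Rac1", rhoa: str = "RhoA"
) -> SwitchOnTime:
    """Locate the first increment with Rac1 OFF and RhoA ON and count each
    output's ON increments strictly after it.  A trace in which the switch
    never occurs yields a flagged result rather than an exception."""
    for name in (rac1, rhoa):
        if name not in trace.nodes:
            raise NetworkError(f"trace lacks output node {name!r}")
    rac = trace.series(rac1)
    rho = trace.series(rhoa)
    hits = np.flatnonzero((rac == 0) & (rho == 1))
    if hits.size == 0:
        return SwitchOnTime(False, None, 0, 0)
    k = int(hits[0])
    return SwitchOnTime(True, k, int(rac[k + 1:].sum()), int(rho[k + 1:].sum()))
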