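"""Independent brute-force oracles used only by the test suite.

The attractor oracle enumerates the full 2**N synchronous transition graph
by vectorised rule evaluation over every state at once, then walks the
successor array from the initial state.  It shares no code path with
``rholoop.dynamics.find_attractor`` beyond expression evaluation.
"""

from __future__ import annotations

import numpy as np

from rholoop.expr import evaluate
from rholoop.model import BooleanNetwork


def transition_table(net: BooleanNetwork) -> np.ndarray:
    """successor[i] = index of the synchronous successor of state i, where
    state index i encodes node k (declaration order) in bit k."""
    names = net.node_names
    n = len(names)
    if n > 20:
        raise ValueError("exhaustive enumeration limited to 20 nodes")
    idx = np.arange(2 ** n, dtype=np.int64)
    bits = {name: (idx >> k) & 1 for k, name in enumerate(names)}
    successor = np.zeros_like(idx)
    for k, name in enumerate(names):
        node = net.node(name)
        rule = net.rule(name)
        if node.clamp is not None:
            value = np.full_like(idx, node.clamp)
        elif rule is None:
            value = bits[name]
        else:
            value = evaluate(rule.expression, bits) & 1
        successor |= value.astype(np.int64) << k
    return successor


def brute_force_attractor(net: BooleanNetwork):
    """(transient_length, cycle as list of state dicts) from the initial
    condition, via the exhaustive transition table."""
    names = net.node_names
    successor = transition_table(net)
    init = net.initial_state
    state = 0
    for k, name in enumerate(names):
        state |= init[name] << k
    seen: dict[int, int] = {}
    orbit: list[int] = []
    while state not in seen:
        seen[state] = len(orbit)
        orbit.append(state)
        state = int(successor[state])
    start = seen[state]
    cycle = [
        {name: (s >> k) & 1 for k, name in enumerate(names)}
        for s in orbit[start:]
    ]
    return start, cycle
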