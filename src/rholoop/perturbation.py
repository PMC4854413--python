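"""In-silico single-node knockout screening.

A knockout removes every inward edge of one node so it remains OFF for all
time (``clamp_off``); the constitutive input-less inhibitors PTEN, SHIP2 and
PP2a are instead set ON (``clamp_on``), since they are already OFF in the
unperturbed model.  The screen re-simulates the network to its attractor for
every non-output node under each hierarchy of interest and classifies the
RhoA/Rac1 output dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import pandas as pd

from .dynamics import ClassifiedOutput, classify_hierarchy_output, find_attractor
from .model import BooleanNetwork, HierarchySpec, NetworkError

OUTPUTS = ("Rac1", "RhoA")


@dataclass(frozen=True)
class KnockoutSpec:
    """A single-node perturbation."""

    node: str
    mode: str = "clamp_off"  # or "clamp_on" for constitutive inhibitors

    def __post_init__(self) -> None:
        if self.mode not in ("clamp_off", "clamp_on"):
            raise NetworkError(f"unknown knockout mode {self.mode!r}")


def knockout_for(net: BooleanNetwork, node: str) -> KnockoutSpec:
    """The appropriate spec for ``node``: constitutive inhibitors are set ON,
    everything else is clamped OFF."""
    return KnockoutSpec(node, "clamp_on" if net.node(node).constitutive else "clamp_off")


def apply_knockout(net: BooleanNetwork, ko: KnockoutSpec) -> BooleanNetwork:
    """Return a new network with the node clamped; ``net`` is untouched.

    ``clamp_off`` removes the node's update rule and sets both its initial
    and clamped state to 0, so even basally active nodes remain OFF for all
    time.  Applying the same knockout twice is a no-op.
    """
    spec = net.node(ko.node)
    if spec.kind == "output":
        raise NetworkError(f"cannot knock out output node {ko.node!r}")
    if ko.mode == "clamp_on" and not spec.constitutive:
        raise NetworkError(
            f"clamp_on is only defined for constitutive inhibitors, not {ko.node!r}"
        )
    out = net.copy()
    target = out.node(ko.node)
    value = 1 if ko.mode == "clamp_on" else 0
    target.clamp = value
    target.initial_state = value
    out.rules = [r for r in out.rules if r.target != ko.node]
    out._reindex()
    out.validate()
    return out


@dataclass
class ScreenResult:
    """Per-(node, hierarchy) knockout outcomes plus unperturbed baselines."""

    table: pd.DataFrame  # columns: node, hierarchy, rac1_class, rhoa_class,
    #                                category, rhoa_dominant
    baselines: dict[str, ClassifiedOutput]

    def category(self, node: str, hierarchy: str) -> str:
        sel = self.table[(self.table.node == node) & (self.table.hierarchy == hierarchy)]
        if sel.empty:
            raise KeyError((node, hierarchy))
        return str(sel.category.iloc[0])

    def to_csv(self) -> str:
        return self.table.to_csv(index=False)


def run_screen(
    net_factory: Callable[[HierarchySpec], BooleanNetwork],
    hierarchies: Iterable[HierarchySpec],
) -> ScreenResult:
    """Knock out every non-output node under every hierarchy and classify
    the resulting attractor's GTPase output dynamics."""
    rows = []
    baselines: dict[str, ClassifiedOutput] = {}
    for hierarchy in hierarchies:
        label = hierarchy.label()
        base_net = net_factory(hierarchy)
        baselines[label] = classify_hierarchy_output(find_attractor(base_net))
        for node in base_net.nodes:
            if node.kind == "output":
                continue
            ko_net = apply_knockout(base_net, knockout_for(base_net, node.name))
            cls = classify_hierarchy_output(find_attractor(ko_net))
            rows.append(
                {
                    "node": node.name,
                    "hierarchy": label,
                    "rac1_class": cls.rac1_class.value,
                    "rhoa_class": cls.rhoa_class.value,
                    "category": cls.category.value,
                    "rhoa_dominant": cls.rhoa_dominant,
                }
            )
    return ScreenResult(pd.DataFrame(rows), baselines)


def compare_hierarchy_screens(a: ScreenResult, b: ScreenResult) -> pd.DataFrame:
    """Nodes whose knockout prediction differs between two screens.

    Each knockout's *effect signature* under a hierarchy is None when the
    outcome category equals that hierarchy's unperturbed baseline, and the
    outcome category otherwise.  A node is listed when its signatures under
    the two screens differ.  Raw categories cannot be compared directly:
    the two baselines already differ, so a knockout with no effect anywhere
    would otherwise be listed, while an Eps8 knockout — which turns the
    cyclic output into the switch, the very category the switch hierarchy
    already produces unperturbed — would be missed.
    """
    ha = _single_label(a)
    hb = _single_label(b)
    nodes_a = set(a.table.node)
    if nodes_a != set(b.table.node):
        raise NetworkError("screens cover different node sets")
    rows = []
    for node in sorted(nodes_a):
        cat_a = a.category(node, ha)
        cat_b = b.category(node, hb)
        eff_a = cat_a != a.baselines[ha].category.value
        eff_b = cat_b != b.baselines[hb].category.value
        sig_a = cat_a if eff_a else None
        sig_b = cat_b if eff_b else None
        if sig_a != sig_b:
            rows.append(
                {
                    "node": node,
                    "category_a": cat_a,
                    "category_b": cat_b,
                    "affects_a": eff_a,
                    "affects_b": eff_b,
                }
            )
    df = pd.DataFrame(rows, columns=["node", "category_a", "category_b",
                                     "affects_a", "affects_b"])
    df.attrs["hierarchy_a"] = ha
    df.attrs["hierarchy_b"] = hb
    return df


def _single_label(res: ScreenResult) -> str:
    labels = sorted(set(res.table.hierarchy))
    if len(labels) != 1:
        raise NetworkError(
            "compare_hierarchy_screens expects single-hierarchy screens; "
            f"got {labels}"
        )
    return labels[0]


def split_by_hierarchy(res: ScreenResult) -> dict[str, ScreenResult]:
    """Split a multi-hierarchy screen into per-hierarchy results."""
    out = {}
    for label in sorted(set(res.table.hierarchy)):
        sub = res.table[res.table.hierarchy == label].reset_index(drop=True)
        out[label] = ScreenResult(sub, {label: res.baselines[label]})
    return out
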