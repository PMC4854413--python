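"""Data model for logical signalling networks.

A :class:`BooleanNetwork` is a set of named binary nodes, one update rule per
regulated node, and (optionally) a :class:`HierarchySpec` describing the
precedence with which Rac1's GEFs and its GAP compete for the GTPase.  A GEF
and a GAP cannot engage a Rho GTPase in the same spatiotemporal state, so
whichever regulator binds preferentially wins; the hierarchy is compiled into
Rac1's update rule by :func:`compile_rac1_rule`.

Networks round-trip through a line-oriented text format (see
:func:`parse_network` / :func:`write_network`) chosen for diffability and
hand-transcription of curated interaction tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .expr import Expr, Lit, Not, and_, literals, lits, or_, parse_expr

NODE_KINDS = ("input", "output", "intermediate")

#: Rac1's activators (GEFs) in canonical order, and its sole inhibitor (GAP).
RAC1_ACTIVATORS = ("Vav2", "RalBP1", "Sos1E")
RAC1_INHIBITOR = "pRacGAP1"
RAC1 = "Rac1"


class NetworkError(ValueError):
    """Raised for structurally invalid networks or definition documents."""


@dataclass
class NodeSpec:
    """One species in the network.

    ``constitutive`` marks input-less inhibitory nodes (PTEN, SHIP2, PP2a)
    that carry no update rule and simply hold their state.  ``clamp`` pins a
    node to a fixed value for all time (used for the EGF input and for
    in-silico knockouts).
    """

    name: str
    kind: str = "intermediate"
    initial_state: int = 0
    constitutive: bool = False
    clamp: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise NetworkError(f"node {self.name!r}: unknown kind {self.kind!r}")
        if self.initial_state not in (0, 1):
            raise NetworkError(f"node {self.name!r}: initial state must be 0 or 1")

    @property
    def is_clamped(self) -> bool:
        return self.clamp is not None


@dataclass
class UpdateRule:
    """Update rule ``target(t+1) = expression(state at t)``."""

    target: str
    expression: Expr
    provenance: str = ""

    def __str__(self) -> str:
        return f"{self.target}, {self.expression}"


@dataclass(frozen=True)
class HierarchySpec:
    """Precedence ordering over Rac1's regulators.

    ``tiers`` is an ordered sequence of disjoint regulator sets; an earlier
    tier binds Rac1 preferentially over a later one (the '>' relation).  Only
    the partition of activators above vs below the single inhibitor is
    dynamically meaningful, so :meth:`canonical` collapses same-side tiers.
    """

    tiers: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        members = [m for tier in self.tiers for m in tier]
        if len(members) != len(set(members)):
            raise NetworkError("hierarchy tiers are not disjoint")
        expected = set(RAC1_ACTIVATORS) | {RAC1_INHIBITOR}
        if set(members) != expected:
            missing = expected - set(members)
            extra = set(members) - expected
            raise NetworkError(
                f"hierarchy must cover {sorted(expected)}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for tier in self.tiers:
            if RAC1_INHIBITOR in tier and len(tier) > 1:
                raise NetworkError(
                    "a tier may not mix the inhibitor pRacGAP1 with an activator"
                )

    @property
    def above_inhibitor(self) -> frozenset[str]:
        """Activators ranked strictly above the inhibitor."""
        above: set[str] = set()
        for tier in self.tiers:
            if RAC1_INHIBITOR in tier:
                return frozenset(above)
            above |= tier
        return frozenset(above)

    @property
    def below_inhibitor(self) -> frozenset[str]:
        return frozenset(RAC1_ACTIVATORS) - self.above_inhibitor

    def canonical(self) -> "HierarchySpec":
        """Collapse to at most three tiers: above > inhibitor > below."""
        tiers: list[frozenset[str]] = []
        if self.above_inhibitor:
            tiers.append(self.above_inhibitor)
        tiers.append(frozenset({RAC1_INHIBITOR}))
        if self.below_inhibitor:
            tiers.append(self.below_inhibitor)
        return HierarchySpec(tuple(tiers))

    def label(self) -> str:
        def fmt(tier: frozenset[str]) -> str:
            ordered = [n for n in RAC1_ACTIVATORS if n in tier]
            if RAC1_INHIBITOR in tier:
                ordered.append(RAC1_INHIBITOR)
            return ", ".join(ordered)

        return " > ".join(fmt(t) for t in self.canonical().tiers)

    @staticmethod
    def from_text(text: str) -> "HierarchySpec":
        tiers = []
        for part in text.split(">"):
            members = frozenset(m.strip() for m in part.split(",") if m.strip())
            if not members:
                raise NetworkError(f"empty tier in hierarchy {text!r}")
            tiers.append(members)
        return HierarchySpec(tuple(tiers))


def compile_rac1_rule(
    activators: tuple[str, ...] | frozenset[str],
    inhibitor: str,
    hierarchy: HierarchySpec,
    *,
    target: str = RAC1,
    antagonists: tuple[str, ...] = (),
    provenance: str = "compiled from regulator hierarchy",
) -> UpdateRule:
    """Compile Rac1's update rule under precedence semantics.

    An activator ranked above the inhibitor switches Rac1 on unconditionally;
    an activator ranked below acts only while the inhibitor is OFF.  A
    self-maintenance literal keeps basally active Rac1 on until the inhibitor
    fires, and is always guarded.  ``antagonists`` (e.g. a direct RhoA
    antagonism edge) are grouped with the inhibitor guard, i.e. ranked below
    every top-tier activator.
    """
    activators = tuple(a for a in RAC1_ACTIVATORS if a in set(activators))
    if inhibitor != RAC1_INHIBITOR:
        raise NetworkError(f"unknown Rac1 inhibitor {inhibitor!r}")
    above = [a for a in activators if a in hierarchy.above_inhibitor]
    below = [a for a in activators if a not in hierarchy.above_inhibitor]
    guard = [Not(Lit(inhibitor))] + [Not(Lit(a)) for a in antagonists]
    guarded = and_(or_(*lits(*below), Lit(target)), *guard)
    expression = or_(*lits(*above), guarded)
    return UpdateRule(target, expression, provenance)


def enumerate_hierarchies() -> list[HierarchySpec]:
    """All 8 canonical hierarchies: one per subset of activators placed above
    the single inhibitor (activator order on one side is irrelevant)."""
    out = []
    for r in range(len(RAC1_ACTIVATORS) + 1):
        for combo in itertools.combinations(RAC1_ACTIVATORS, r):
            tiers: list[frozenset[str]] = []
            if combo:
                tiers.append(frozenset(combo))
            tiers.append(frozenset({RAC1_INHIBITOR}))
            rest = frozenset(RAC1_ACTIVATORS) - set(combo)
            if rest:
                tiers.append(rest)
            out.append(HierarchySpec(tuple(tiers)))
    return out


@dataclass
class BooleanNetwork:
    """A validated logical network."""

    nodes: list[NodeSpec]
    rules: list[UpdateRule]
    hierarchy: HierarchySpec | None = None
    metadata: str = ""
    _rule_index: dict[str, UpdateRule] = field(init=False, repr=False)
    _node_index: dict[str, NodeSpec] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._reindex()
        self.validate()

    def _reindex(self) -> None:
        self._node_index = {n.name: n for n in self.nodes}
        self._rule_index = {r.target: r for r in self.rules}

    # -- access -----------------------------------------------------------
    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node(self, name: str) -> NodeSpec:
        try:
            return self._node_index[name]
        except KeyError:
            raise NetworkError(f"no such node: {name!r}") from None

    def rule(self, name: str) -> UpdateRule | None:
        return self._rule_index.get(name)

    def nodes_of_kind(self, kind: str) -> list[NodeSpec]:
        return [n for n in self.nodes if n.kind == kind]

    @property
    def initial_state(self) -> dict[str, int]:
        return {
            n.name: (n.clamp if n.clamp is not None else n.initial_state)
            for n in self.nodes
        }

    def copy(self) -> "BooleanNetwork":
        return BooleanNetwork(
            nodes=[replace(n) for n in self.nodes],
            rules=[UpdateRule(r.target, r.expression, r.provenance) for r in self.rules],
            hierarchy=self.hierarchy,
            metadata=self.metadata,
        )

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        names = [n.name for n in self.nodes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise NetworkError(f"duplicate node names: {sorted(dupes)}")
        targets = [r.target for r in self.rules]
        dupes = {t for t in targets if targets.count(t) > 1}
        if dupes:
            raise NetworkError(f"duplicate rule for target(s): {sorted(dupes)}")
        declared = set(names)
        for r in self.rules:
            if r.target not in declared:
                raise NetworkError(f"rule targets undeclared node {r.target!r}")
            unknown = literals(r.expression) - declared
            if unknown:
                raise NetworkError(
                    f"rule for {r.target!r} references undeclared node(s) "
                    f"{sorted(unknown)}"
                )
        for n in self.nodes:
            needs_rule = n.kind != "input" and not n.constitutive and not n.is_clamped
            if needs_rule and n.name not in self._rule_index:
                raise NetworkError(f"node {n.name!r} has no update rule")
            if (n.kind == "input" or n.constitutive) and n.name in self._rule_index:
                raise NetworkError(
                    f"{n.kind if n.kind == 'input' else 'constitutive'} node "
                    f"{n.name!r} may not carry an update rule"
                )

    # -- graph view -------------------------------------------------------
    def edges(self) -> list[tuple[str, str, int]]:
        """Signed interaction list (source, target, sign) where sign is +1
        for activation and -1 for inhibition (literal under odd negation)."""
        out = []
        for r in self.rules:
            for src, sign in sorted(_signed_literals(r.expression).items()):
                out.append((src, r.target, sign))
        return out

    def to_graph(self):
        """The interaction graph as a :class:`networkx.DiGraph`."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for src, dst, sign in self.edges():
            g.add_edge(src, dst, sign=sign)
        return g


def _signed_literals(expr: Expr, negated: bool = False) -> dict[str, int]:
    from .expr import And, Or

    out: dict[str, int] = {}
    if isinstance(expr, Lit):
        out[expr.name] = -1 if negated else 1
    elif isinstance(expr, Not):
        out.update(_signed_literals(expr.operand, not negated))
    elif isinstance(expr, (And, Or)):
        for op in expr.operands:
            for name, sign in _signed_literals(op, negated).items():
                # a literal appearing both ways is reported as inhibitory
                out[name] = min(out.get(name, sign), sign)
    return out


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

def parse_network(text: str) -> BooleanNetwork:
    """Parse a network-definition document.

    Format (UTF-8, ``#`` comments)::

        [nodes]
        EGF, input, 1
        PTEN, intermediate, 0, constitutive
        ...
        [rules]
        EGFR1, EGF
        Akt, PIP3 AND PDK1 AND NOT PP2a   # provenance after '|'
        [hierarchy]
        Sos1E > pRacGAP1 > Vav2, RalBP1

    If a ``[hierarchy]`` section is present, Rac1's rule is compiled from it
    and must not also appear under ``[rules]``.
    """
    nodes: list[NodeSpec] = []
    rules: list[UpdateRule] = []
    hierarchy: HierarchySpec | None = None
    metadata_lines: list[str] = []
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("nodes", "rules", "hierarchy", "metadata"):
                raise NetworkError(f"line {lineno}: unknown section {section!r}")
            continue
        if section == "nodes":
            parts = [p.strip() for p in line.split(",")]
            if not 3 <= len(parts) <= 5:
                raise NetworkError(
                    f"line {lineno}: expected 'name, kind, initial[, flags...]'"
                )
            name, kind, init = parts[:3]
            constitutive = False
            clamp: int | None = None
            for flag in parts[3:]:
                if flag == "constitutive":
                    constitutive = True
                elif flag in ("clamp:0", "clamp:1"):
                    clamp = int(flag[-1])
                else:
                    raise NetworkError(f"line {lineno}: unknown flag {flag!r}")
            try:
                node = NodeSpec(name, kind, int(init), constitutive, clamp)
            except (ValueError, NetworkError) as exc:
                raise NetworkError(f"line {lineno}: {exc}") from None
            if node.kind == "input":
                node.clamp = node.initial_state
            nodes.append(node)
        elif section == "rules":
            if "," not in line:
                raise NetworkError(f"line {lineno}: expected 'target, expression'")
            target, rhs = line.split(",", 1)
            provenance = ""
            if "|" in rhs:
                rhs, provenance = rhs.split("|", 1)
            try:
                expression = parse_expr(rhs.strip())
            except ValueError as exc:
                raise NetworkError(f"line {lineno}: {exc}") from None
            rules.append(UpdateRule(target.strip(), expression, provenance.strip()))
        elif section == "hierarchy":
            hierarchy = HierarchySpec.from_text(line)
        elif section == "metadata":
            metadata_lines.append(line)
        else:
            raise NetworkError(f"line {lineno}: content outside any section")
    if hierarchy is not None:
        if any(r.target == RAC1 for r in rules):
            raise NetworkError(
                "Rac1 rule may not be given explicitly when a [hierarchy] "
                "section is present"
            )
        rules.append(
            compile_rac1_rule(
                RAC1_ACTIVATORS, RAC1_INHIBITOR, hierarchy,
                antagonists=("RhoA",) if any(n.name == "RhoA" for n in nodes) else (),
            )
        )
    try:
        return BooleanNetwork(nodes, rules, hierarchy, "\n".join(metadata_lines))
    except NetworkError:
        raise


def write_network(net: BooleanNetwork) -> str:
    """Serialise; ``parse_network(write_network(net))`` is structurally
    identical to ``net``."""
    lines: list[str] = []
    if net.metadata:
        lines.append("[metadata]")
        lines.extend(net.metadata.splitlines())
    lines.append("[nodes]")
    for n in net.nodes:
        entry = f"{n.name}, {n.kind}, {n.initial_state}"
        if n.constitutive:
            entry += ", constitutive"
        if n.clamp is not None and n.kind != "input":
            entry += f", clamp:{n.clamp}"
        lines.append(entry)
    lines.append("[rules]")
    for r in net.rules:
        if net.hierarchy is not None and r.target == RAC1:
            continue  # regenerated from the [hierarchy] section on parse
        entry = f"{r.target}, {r.expression}"
        if r.provenance:
            entry += f" | {r.provenance}"
        lines.append(entry)
    if net.hierarchy is not None:
        lines.append("[hierarchy]")
        lines.append(net.hierarchy.label())
    return "\n".join(lines) + "\n"


def edge_csv(net: BooleanNetwork) -> str:
    """CSV export of the signed edge list for external graph tools."""
    rows = ["source,target,sign"]
    rows += [f"{s},{t},{sign}" for s, t, sign in net.edges()]
    return "\n".join(rows) + "\n"
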