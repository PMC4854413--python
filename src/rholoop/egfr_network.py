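"""The curated EGFR1 -> Rac1/RhoA logical network (41 nodes).

The network describes EGF/EGFR1 signalling at the leading edge of a cell in
which RCP-driven co-trafficking of alpha5beta1 integrin and EGFR1 potentiates
receptor signalling: one input node (EGF, clamped ON to model sustained
stimulation), two output nodes (the GTPases Rac1 and RhoA) and 38
intermediates.  Under basal conditions, prior to EGF stimulation, PDK1, mTor,
c-Src, Pip2 and Rac1 are ON; every other node starts OFF.

Key circuit features:

* PI3K/PIP3/Akt axis: Akt phosphorylates RacGAP1, which is recruited to the
  leading edge by the scaffold IQGAP1; phosphorylated RacGAP1 (pRacGAP1) is
  the model's sole Rac1 inhibitor.
* Three Rac1 GEFs: Vav2 (PIP3/Src dependent, also the RhoA activator),
  RalBP1 (downstream of Ras -> RalGDS -> RalA) and Sos1E, the Rac-specific
  GEF activity of the Sos1-Eps8-Abi1 complex.
* A Sos1 negative feedback loop: Sos1 -> Ras -> Raf1 -> MEK1/2 -> ERK1/2 ->
  p90RSK, with active ERK1/2 or p90RSK switching Sos1 OFF by serine/threonine
  phosphorylation, after which the loop re-initiates.  The loop drives
  pseudo-oscillations in everything downstream of Sos1, including Sos1E and
  RalBP1.
* Mutual Rac1/RhoA antagonism: RhoA activates only while Rac1 is OFF, and a
  direct RhoA antagonism literal is grouped with the pRacGAP1 guard inside
  Rac1's compiled rule.

Rules whose wiring is not fixed by the reported behaviours of the original
curation are transcribed from canonical EGFR pathway maps and carry a
provenance tag ending in ``(inferred)``.  Every behaviour the package asserts
(node census, switch timings, the hierarchy taxonomy, knockout outcomes, the
asynchronous RhoA-dominance ordering) is a reported one.
"""

from __future__ import annotations

from .model import (
    RAC1,
    RAC1_ACTIVATORS,
    RAC1_INHIBITOR,
    BooleanNetwork,
    HierarchySpec,
    NodeSpec,
    UpdateRule,
    compile_rac1_rule,
)
from .expr import parse_expr

#: nodes whose basal activity precedes EGF stimulation
BASAL_ON = ("PDK1", "mTor", "c-Src", "Pip2", "Rac1")

#: input-less inhibitory nodes, constitutively OFF; their perturbation sets
#: them ON instead of OFF
CONSTITUTIVE_INHIBITORS = ("PTEN", "SHIP2", "PP2a")

#: members of the Sos1 negative feedback loop (plus the complex it gates)
FEEDBACK_LOOP_NODES = (
    "Sos1", "Ras", "Raf1", "MEK1/2", "ERK1/2", "p90RSK", "Eps8", "Abi1",
)

# name -> (kind, initially_on)
_NODES: list[tuple[str, str]] = [
    ("EGF", "input"),
    ("Rac1", "output"),
    ("RhoA", "output"),
    # receptor-proximal
    ("EGFR1", "intermediate"),
    ("Shc", "intermediate"),
    ("Grb2", "intermediate"),
    ("Gab1", "intermediate"),
    ("c-Src", "intermediate"),
    # lipid signalling
    ("PI3K", "intermediate"),
    ("Pip2", "intermediate"),
    ("PIP3", "intermediate"),
    ("PTEN", "intermediate"),
    ("SHIP2", "intermediate"),
    ("PLCg", "intermediate"),
    ("DAG", "intermediate"),
    ("PKC", "intermediate"),
    # Akt axis and the Rac GAP arm
    ("PDK1", "intermediate"),
    ("mTor", "intermediate"),
    ("Akt", "intermediate"),
    ("PP2a", "intermediate"),
    ("IQGAP1", "intermediate"),
    ("RacGAP1", "intermediate"),
    ("pRacGAP1", "intermediate"),
    # Rac GEFs
    ("Vav2", "intermediate"),
    ("Sos1", "intermediate"),
    ("Eps8", "intermediate"),
    ("Abi1", "intermediate"),
    ("Sos1E", "intermediate"),
    # MAPK feedback loop
    ("Ras", "intermediate"),
    ("Raf1", "intermediate"),
    ("MEK1/2", "intermediate"),
    ("ERK1/2", "intermediate"),
    ("p90RSK", "intermediate"),
    # Ral arm
    ("RalGDS", "intermediate"),
    ("RalA", "intermediate"),
    ("RalBP1", "intermediate"),
    # effectors
    ("Cdc42", "intermediate"),
    ("ROCK", "intermediate"),
    ("FHOD3", "intermediate"),
    ("WAVE", "intermediate"),
    ("Arp2/3", "intermediate"),
]

# target -> (expression, provenance)
_RULES: dict[str, tuple[str, str]] = {
    "EGFR1": ("EGF", "EGF ligation activates EGFR1"),
    "Shc": ("EGFR1", "Shc recruited to autophosphorylated EGFR1"),
    "Grb2": ("Shc", "Grb2 binds phospho-Shc"),
    "Gab1": ("Grb2", "Gab1 recruited via Grb2 (inferred)"),
    "c-Src": ("c-Src OR EGFR1", "basal Src activity, reinforced by EGFR1"),
    "PI3K": ("EGFR1 OR Gab1", "p85 recruitment to receptor/Gab1"),
    "Pip2": ("Pip2", "basal membrane lipid pool (inferred)"),
    "PIP3": (
        "PI3K AND Pip2 AND NOT PTEN AND NOT SHIP2",
        "PI3K phosphorylates Pip2; PTEN/SHIP2 dephosphorylate PIP3",
    ),
    "PLCg": ("EGFR1", "PLCgamma recruited to EGFR1 (inferred)"),
    "DAG": ("PLCg AND Pip2", "PLCgamma hydrolyses Pip2 to DAG"),
    "PKC": ("DAG", "DAG activates conventional PKC (inferred)"),
    "PDK1": ("PDK1 OR PIP3", "basal PDK1, membrane-recruited by PIP3"),
    "mTor": ("mTor", "basal mTor activity"),
    "Akt": (
        "PIP3 AND PDK1 AND mTor AND NOT PP2a",
        "PIP3-recruited Akt activated by PDK1/mTor; PP2a dephosphorylates",
    ),
    "IQGAP1": ("EGFR1", "scaffold engaged downstream of receptor (inferred)"),
    "RacGAP1": ("c-Src", "RacGAP1 availability downstream of Src (inferred)"),
    "pRacGAP1": (
        "Akt AND RacGAP1 AND IQGAP1",
        "Akt phosphorylates RacGAP1; IQGAP1 recruits it to the leading edge",
    ),
    "Vav2": ("PIP3 AND c-Src", "PIP3-bound Vav2 activated by Src"),
    "Sos1": (
        "Grb2 AND NOT ERK1/2 AND NOT p90RSK",
        "Grb2-bound Sos1; ERK1/2 or p90RSK phosphorylation dissociates and "
        "down-regulates Sos1 (negative feedback)",
    ),
    "Eps8": ("Ras AND PI3K", "Ras acts via PI3K on the complex (inferred)"),
    "Abi1": ("Eps8", "Abi1 joins the Eps8 module (inferred)"),
    "Sos1E": (
        "Sos1 AND Eps8 AND Abi1",
        "trimeric Sos1-Eps8-Abi1 complex with Rac-specific GEF activity",
    ),
    "Ras": ("Sos1", "Sos1 is the Ras GEF"),
    "Raf1": ("Ras", "Ras-GTP recruits and activates Raf1"),
    "MEK1/2": ("Raf1", "Raf1 phosphorylates MEK1/2"),
    "ERK1/2": ("MEK1/2", "MEK1/2 phosphorylates ERK1/2"),
    "p90RSK": ("ERK1/2 AND PDK1", "p90RSK needs ERK1/2 and active PDK1"),
    "RalGDS": ("Ras", "RalGDS is a Ras effector"),
    "RalA": ("RalGDS", "RalGDS is the Ral GEF"),
    "RalBP1": ("RalA OR RalGDS", "Ral effector RalBP1 engaged during GEF "
               "recruitment and while RalA-GTP persists (inferred)"),
    "Cdc42": ("Vav2", "Vav2 GEF activity towards Cdc42 (inferred)"),
    "RhoA": ("Vav2 AND NOT Rac1",
             "Vav2 activates RhoA; mutual Rac1/RhoA antagonism"),
    "ROCK": ("RhoA", "RhoA effector kinase"),
    "FHOD3": ("ROCK", "ROCK-activated formin driving actin spikes"),
    "WAVE": ("Rac1 AND Abi1", "WAVE regulatory complex needs Rac1-GTP and Abi1"),
    "Arp2/3": ("WAVE", "WAVE activates Arp2/3 branching"),
}


def cyclic_hierarchy() -> HierarchySpec:
    """Sos1E > pRacGAP1 > Vav2, RalBP1 — the accepted pseudo-oscillatory
    hierarchy with clear RhoA dominance."""
    return HierarchySpec(
        (
            frozenset({"Sos1E"}),
            frozenset({RAC1_INHIBITOR}),
            frozenset({"Vav2", "RalBP1"}),
        )
    )


def switch_hierarchy() -> HierarchySpec:
    """pRacGAP1 > Sos1E, RalBP1, Vav2 — the simple Rac1-to-RhoA switch."""
    return HierarchySpec(
        (frozenset({RAC1_INHIBITOR}), frozenset(RAC1_ACTIVATORS))
    )


def curated_network(hierarchy: HierarchySpec | None = None) -> BooleanNetwork:
    """Build the 41-node network with Rac1's rule compiled from ``hierarchy``
    (default: the accepted cyclic hierarchy)."""
    if hierarchy is None:
        hierarchy = cyclic_hierarchy()
    nodes = []
    basal = set(BASAL_ON)
    for name, kind in _NODES:
        spec = NodeSpec(
            name,
            kind,
            initial_state=1 if (name in basal or kind == "input") else 0,
            constitutive=name in CONSTITUTIVE_INHIBITORS,
        )
        if kind == "input":
            spec.clamp = spec.initial_state  # sustained EGF stimulation
        nodes.append(spec)
    rules = [
        UpdateRule(target, parse_expr(text), provenance)
        for target, (text, provenance) in _RULES.items()
    ]
    rules.append(
        compile_rac1_rule(
            RAC1_ACTIVATORS,
            RAC1_INHIBITOR,
            hierarchy,
            antagonists=("RhoA",),
            provenance="compiled from regulator hierarchy; direct RhoA "
            "antagonism grouped with the pRacGAP1 guard",
        )
    )
    net = BooleanNetwork(
        nodes,
        rules,
        hierarchy,
        metadata=f"EGFR1->Rac1/RhoA leading-edge network; hierarchy {hierarchy.label()}",
    )
    _check_census(net)
    return net


def _check_census(net: BooleanNetwork) -> None:
    n_in = len(net.nodes_of_kind("input"))
    n_out = len(net.nodes_of_kind("output"))
    n_mid = len(net.nodes_of_kind("intermediate"))
    if (n_in, n_out, n_mid) != (1, 2, 38):
        raise AssertionError(
            f"fixture census mismatch: {n_in} input / {n_out} output / "
            f"{n_mid} intermediate"
        )
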