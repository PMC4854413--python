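"""Run configuration, pipeline orchestration and figure-grade exports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import egfr_network
from .dynamics import (
    Trace,
    classify_hierarchy_output,
    find_attractor,
    on_time_after_switch,
    simulate_asynchronous,
    simulate_synchronous,
)
from .model import BooleanNetwork, HierarchySpec, parse_network
from .perturbation import apply_knockout, knockout_for, run_screen

HIERARCHY_ALIASES = {
    "cyclic": egfr_network.cyclic_hierarchy,
    "switch": egfr_network.switch_hierarchy,
}


class ConfigError(ValueError):
    """Invalid run configuration; message enumerates every problem."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run bundle."""

    network: str | None = None            # path to a network document, or None
    hierarchy: str = "cyclic"             # alias or explicit tier expression
    scheme: str = "synchronous"
    T: int = 50
    seeds: list[int] | None = None        # asynchronous scheme only
    knockouts: list[str] = field(default_factory=list)
    outdir: str = "rholoop_out"

    def validate(self) -> None:
        problems = []
        if self.scheme not in ("synchronous", "asynchronous"):
            problems.append(f"unknown scheme {self.scheme!r}")
        if self.T < 1:
            problems.append("T must be >= 1")
        if self.scheme == "synchronous" and self.seeds:
            problems.append("seeds are only meaningful with the asynchronous scheme")
        if self.scheme == "asynchronous" and not self.seeds:
            problems.append("asynchronous scheme requires at least one seed")
        if self.network is not None and not Path(self.network).is_file():
            problems.append(f"network file not found: {self.network}")
        try:
            self.resolve_hierarchy()
        except Exception as exc:
            problems.append(f"bad hierarchy: {exc}")
        if problems:
            raise ConfigError("; ".join(problems))

    def resolve_hierarchy(self) -> HierarchySpec:
        if self.hierarchy in HIERARCHY_ALIASES:
            return HIERARCHY_ALIASES[self.hierarchy]()
        return HierarchySpec.from_text(self.hierarchy)

    def build_network(self) -> BooleanNetwork:
        if self.network is None:
            return egfr_network.curated_network(self.resolve_hierarchy())
        return parse_network(Path(self.network).read_text())


def export_heatmap(trace: Trace) -> str:
    """Deterministic TSV heatmap: rows = nodes in declaration order,
    columns = time increments, 0/1 cells."""
    return trace.to_tsv()


def export_heatmap_png(trace: Trace, path: str | Path,
                       highlight: tuple[str, ...] = ("Rac1", "RhoA")) -> None:
    """Optional PNG rendering of the binary heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, trace.T / 8), max(3, len(trace.nodes) / 5))
    )
    ax.imshow(trace.states.T, aspect="auto", interpolation="nearest",
              cmap="Greys", vmin=0, vmax=1)
    ax.set_yticks(range(len(trace.nodes)))
    ax.set_yticklabels(
        trace.nodes,
        fontsize=6,
    )
    for name in highlight:
        if name in trace.nodes:
            ax.get_yticklabels()[trace.nodes.index(name)].set_color("tab:red")
    ax.set_xlabel("time increment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """simulate -> classify -> (optional screen) -> export.

    Writes per-run trace TSVs, an attractor/classification JSON, a knockout
    CSV when knockouts are requested, and a log of all parameters and
    seeds.  Returns a mapping artefact name -> file path.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = cfg.build_network()
    outputs: dict[str, str] = {}

    traces: list[Trace] = []
    if cfg.scheme == "synchronous":
        traces.append(simulate_synchronous(net, cfg.T))
    else:
        for seed in cfg.seeds or []:
            traces.append(simulate_asynchronous(net, cfg.T, seed))
    for trace in traces:
        suffix = "" if trace.seed is None else f"_seed{trace.seed}"
        path = outdir / f"trace{suffix}.tsv"
        path.write_text(export_heatmap(trace))
        outputs[f"trace{suffix}"] = str(path)

    report = find_attractor(net)
    cls = classify_hierarchy_output(report)
    attractor_path = outdir / "attractor.json"
    payload = json.loads(report.to_json())
    payload["category"] = cls.category.value
    payload["rhoa_dominant"] = cls.rhoa_dominant
    if cfg.scheme == "asynchronous":
        payload["on_time_after_switch"] = [
            vars(on_time_after_switch(t)) for t in traces
        ]
    attractor_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    outputs["attractor"] = str(attractor_path)

    if cfg.knockouts:
        rows = []
        for node in cfg.knockouts:
            ko_net = apply_knockout(net, knockout_for(net, node))
            ko_cls = classify_hierarchy_output(find_attractor(ko_net))
            rows.append(
                f"{node},{ko_cls.rac1_class.value},{ko_cls.rhoa_class.value},"
                f"{ko_cls.category.value},{ko_cls.rhoa_dominant}"
            )
        screen_path = outdir / "screen.csv"
        screen_path.write_text(
            "node,rac1_class,rhoa_class,category,rhoa_dominant\n"
            + "\n".join(rows) + "\n"
        )
        outputs["screen"] = str(screen_path)

    log_path = outdir / "run.json"
    log_path.write_text(json.dumps(vars(cfg), indent=2, sort_keys=True, default=str))
    outputs["log"] = str(log_path)
    return outputs
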