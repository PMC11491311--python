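"""End-to-end orchestration: read -> impute -> dichotomize -> fit -> report.

``run_pipeline`` drives the full analysis from a flat config and writes all
artifacts (binary matrix, network JSON/edge TSV/GraphML, centrality TSV,
bootstrap outputs, prevalence TSV, run report JSON) into an output
directory.  A single master seed governs every stochastic stage.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import (
    DEFAULT_PROPORTIONS,
    case_dropping,
    cs_coefficient,
    difference_test,
    edge_ci_bootstrap,
)
from .centrality import strength
from .data_model import (
    BinaryMatrix,
    build_binary_matrix,
    impute_median,
    prevalence_report,
    read_response_table,
)
from .elasso import DEFAULT_GAMMA, DEFAULT_RULE, fit_ising
from .instruments import DEFAULT_INSTRUMENTS, Instrument

logger = logging.getLogger("symptomnet")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults reproduce the study settings
    (gamma = 0.25, AND rule, B = 1000 bootstrap replicates)."""

    input_path: str = ""
    output_dir: str = "results/run"
    gamma: float = DEFAULT_GAMMA
    rule: str = DEFAULT_RULE
    bootstrap_B: int = 1000
    seed: int = 0
    drop_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    alpha: float = 0.05
    instruments: tuple[str, ...] = tuple(i.value for i in Instrument)
    run_bootstrap: bool = True
    top_k: int = 5

    def selected_instruments(self):
        wanted = {s.upper() for s in self.instruments}
        unknown = wanted - {i.value for i in Instrument}
        if unknown:
            raise ValueError(f"unknown instruments: {sorted(unknown)}")
        return tuple(s for s in DEFAULT_INSTRUMENTS if s.instrument_id.value in wanted)


@dataclass
class RunReport:
    """Machine-readable summary; sufficient to re-run identically."""

    settings: dict
    n: int
    p: int
    node_labels: list[str]
    dropped_columns: list[str]
    n_edges: int
    top_strength: list[dict]
    cs_coefficient: float | None
    n_significant_edge_pairs: int | None
    n_significant_strength_pairs: int | None
    prevalence: list[dict] | None = None
    version: str = __version__
    platform: str = field(default_factory=platform.platform)
    wall_clock_s: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=float))


def load_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` config file (later CLI flags override)."""
    cfg = RunConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(cfg, key):
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, bool):
            setattr(cfg, key, value.lower() in {"1", "true", "yes"})
        elif isinstance(current, int):
            setattr(cfg, key, int(value))
        elif isinstance(current, float):
            setattr(cfg, key, float(value))
        elif isinstance(current, tuple):
            parts = [v for v in value.replace(",", " ").split() if v]
            if key == "drop_proportions":
                setattr(cfg, key, tuple(float(v) for v in parts))
            else:
                setattr(cfg, key, tuple(parts))
        else:
            setattr(cfg, key, value)
    return cfg


def _stage(name: str, t0: float, **info) -> None:
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
                " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis; returns the report (also written to disk)."""
    t0 = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = read_response_table(config.input_path)
    _stage("read", t0, rows=len(table))

    table = impute_median(table)
    _stage("impute", t0)

    matrix = build_binary_matrix(table, instruments=config.selected_instruments())
    matrix.to_tsv(out / "binary_matrix.tsv")
    _stage("dichotomize", t0, n=matrix.n, p=matrix.p)

    prev = prevalence_report(matrix)
    prev.to_csv(out / "prevalence.tsv", sep="\t", index=False)

    # constant columns cannot enter the nodewise regressions; drop with reason
    means = matrix.values.mean(axis=0)
    dropped = [
        f"{lab}: constant (prevalence {means[j]:.0%})"
        for j, lab in enumerate(matrix.node_labels)
        if means[j] in (0.0, 1.0)
    ]
    if dropped:
        keep = tuple(
            lab for j, lab in enumerate(matrix.node_labels) if means[j] not in (0.0, 1.0)
        )
        logger.warning("dropping constant columns: %s", dropped)
        matrix = matrix.select(keep)

    fit = fit_ising(matrix, gamma=config.gamma, rule=config.rule)
    net = fit.network
    net.to_json(out / "network.json")
    net.to_edgelist_tsv(out / "edges.tsv")
    net.to_graphml(out / "network.graphml")
    _stage("fit", t0, edges=net.n_edges)

    cent = strength(net)
    cent.to_csv(out / "centrality.tsv", sep="\t", index=False)

    cs = None
    n_sig_edges = n_sig_strengths = None
    if config.run_bootstrap and config.bootstrap_B >= 2:
        ci_table, ensemble = edge_ci_bootstrap(
            matrix, B=config.bootstrap_B, seed=config.seed,
            gamma=config.gamma, rule=config.rule,
        )
        ci_table.to_csv(out / "edge_ci.tsv", sep="\t", index=False)
        sig_e, names_e = difference_test(ensemble, "edge", alpha=config.alpha)
        pd.DataFrame(sig_e.astype(int), index=names_e, columns=names_e).to_csv(
            out / "edge_difference.tsv", sep="\t"
        )
        sig_s, names_s = difference_test(ensemble, "strength", alpha=config.alpha)
        pd.DataFrame(sig_s.astype(int), index=names_s, columns=names_s).to_csv(
            out / "strength_difference.tsv", sep="\t"
        )
        n_sig_edges = int(sig_e.sum() // 2)
        n_sig_strengths = int(sig_s.sum() // 2)
        _stage("bootstrap_ci", t0, B=ensemble.B, redrawn=ensemble.n_redrawn)

        stab = case_dropping(
            matrix, proportions=config.drop_proportions, B=config.bootstrap_B,
            seed=config.seed, gamma=config.gamma, rule=config.rule,
        )
        stab.to_frame().to_csv(out / "stability.tsv", sep="\t", index=False)
        cs = cs_coefficient(stab)
        (out / "stability.json").write_text(json.dumps(
            {"cs_coefficient": cs,
             "correlation_threshold": stab.correlation_threshold,
             "probability_threshold": stab.probability_threshold,
             "drop_proportions": list(stab.drop_proportions)}, indent=1))
        _stage("case_dropping", t0, cs=cs)

    top = cent.sort_values("rank").head(config.top_k)
    report = RunReport(
        settings={
            "input_path": str(config.input_path),
            "gamma": config.gamma,
            "rule": config.rule,
            "bootstrap_B": config.bootstrap_B,
            "seed": config.seed,
            "alpha": config.alpha,
            "drop_proportions": list(config.drop_proportions),
            "instruments": list(config.instruments),
            "run_bootstrap": config.run_bootstrap,
        },
        n=matrix.n,
        p=matrix.p,
        node_labels=list(matrix.node_labels),
        dropped_columns=dropped,
        n_edges=net.n_edges,
        top_strength=top.to_dict("records"),
        cs_coefficient=cs,
        n_significant_edge_pairs=n_sig_edges,
        n_significant_strength_pairs=n_sig_strengths,
        prevalence=prev.to_dict("records"),
        wall_clock_s=time.perf_counter() - t0,
    )
    report.to_json(out / "report.json")
    _stage("report", t0)
    return report
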