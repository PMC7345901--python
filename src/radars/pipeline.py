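"""End-to-end pipeline: simulate -> summarize -> build network -> metrics.

Writes ``clones.csv``, ``antigens.csv``, ``net.graphml`` and ``report.json``
into the output directory; the report echoes the configuration (and its
hash) so any run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np

from . import __version__
from .config import RunConfig, save_config
from .distributions import InsufficientTailError, fit_tail_exponent
from .network import (
    NetworkError,
    box_covering_dimension,
    build_hierarchical_network,
    eq10_box_dimension,
    fit_degree_exponent,
    ideal_exponent,
    save_network,
)
from .repertoire import (
    Stage,
    antigens_dataframe,
    clones_dataframe,
    run_simulation,
    summarize_repertoire,
)

__all__ = ["run_pipeline"]

log = logging.getLogger("radars")


def run_pipeline(config: RunConfig, out_dir: "str | Path | None" = None) -> Dict[str, Any]:
    """Execute the full model pipeline and return the run report.

    Stages: agent-based simulation, repertoire summary, hierarchical network
    construction, degree-exponent and box-dimension metrics with the
    (γ−1)/(γ−2) consistency prediction.  Metric entries appear in the report
    only if their stage ran; failures carry the stage name.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: Dict[str, Any] = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stages": [],
    }

    log.info("simulate: %d steps, %d antigens", config.simulation.n_steps,
             config.simulation.n_antigens)
    try:
        state = run_simulation(config.simulation_config())
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    report["stages"].append("simulate")

    summary = summarize_repertoire(state)
    report["summary"] = {
        "n_clones": int(len(summary.clones)),
        "n_cells": int(sum(summary.cell_counts.values())),
        "stage_counts": summary.stage_counts,
        "mean_dg": summary.mean_dg,
    }
    report["stages"].append("summarize")

    clones = clones_dataframe(state)
    clones.to_csv(out / "clones.csv", index=False)
    antigens_dataframe(state).to_csv(out / "antigens.csv", index=False)
    summary.clones[["id", "k_sys"]].rename(columns={"k_sys": "ksys"}).to_csv(
        out / "ksys.csv", index=False
    )

    if len(summary.clones) == 0:
        report["network"] = None
        report["notice"] = "empty repertoire; network stage skipped"
        _finish(report, config, out)
        return report

    table = summary.clones.copy()
    table["id"] = table["id"].astype(str)
    table["role"] = [
        "LLPC" if s == "LLPC" else ("MBC" if s == "MBC" else ("B1" if s == "B1" else "naive"))
        for s in table["stage"]
    ]
    # subnetwork = the structural direction a clone belongs to: its driving
    # antigen if it matured, otherwise the nearest antigen whose shape falls
    # inside the clone's angular resolution cap; clones recognising no
    # sampled antigen form singleton subnetworks
    sim_cfg = config.simulation_config()
    sub_labels = []
    for i, a in zip(table["id"], table["subnetwork"]):
        if a >= 0:
            sub_labels.append(f"ag{a}")
            continue
        d = state.directions[int(i)]
        ang = np.arccos(np.clip(state.ag_directions @ d, -1.0, 1.0))
        within = np.flatnonzero(ang <= sim_cfg.theta(state.dg[int(i)]))
        if within.size:
            sub_labels.append(f"ag{within[np.argmin(ang[within])]}")
        else:
            sub_labels.append(f"solo{i}")
    table["subnetwork"] = sub_labels
    table["direction"] = [state.directions[int(i)] for i in table["id"]]
    net = build_hierarchical_network(table)
    save_network(net, str(out / "net.graphml"))
    report["stages"].append("build-network")

    metrics: Dict[str, Any] = {
        "n_nodes": net.n_nodes,
        "n_links": net.n_links,
        "ideal_gamma": ideal_exponent(),
    }
    try:
        tail = fit_tail_exponent(
            summary.clones["k_sys"].to_numpy(), k_min=1.0
        )
        metrics["ksys_tail_exponent"] = tail.alpha_hat
        metrics["ksys_tail_stderr"] = tail.stderr
        metrics["eq_d_b_from_ksys"] = eq10_box_dimension(tail.alpha_hat)
        metrics["phi2_residual"] = tail.alpha_hat - ideal_exponent()
    except (InsufficientTailError, ValueError) as exc:
        metrics["ksys_tail_exponent"] = None
        log.info("K_sys tail fit skipped: %s", exc)
    try:
        gamma = fit_degree_exponent(net, k_min=config.network.k_min)
        metrics["gamma_hat"] = gamma.alpha_hat
        metrics["gamma_stderr"] = gamma.stderr
        metrics["eq_d_b_from_gamma"] = eq10_box_dimension(gamma.alpha_hat)
    except (InsufficientTailError, NetworkError) as exc:
        metrics["gamma_hat"] = None
        log.info("degree-exponent fit skipped: %s", exc)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            box = box_covering_dimension(
                net,
                range(config.network.lb_min, config.network.lb_max + 1),
                n_restarts=config.network.box_restarts,
                seed=config.seed,
            )
        metrics["d_b_hat"] = box.d_b_hat
        metrics["d_b_stderr"] = box.stderr
        metrics["n_boxes_by_lb"] = {str(k): v for k, v in box.n_boxes_by_lb.items()}
    except NetworkError as exc:
        metrics["d_b_hat"] = None
        log.info("box covering skipped: %s", exc)
    report["network"] = metrics
    report["stages"].append("metrics")

    _finish(report, config, out)
    return report


def _finish(report: Dict[str, Any], config: RunConfig, out: Path) -> None:
    save_config(config, out / "config.yaml")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
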