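"""End-to-end orchestration: config → artifacts → run report.

Stage order mirrors the analysis it packages: reverse coding →
correlation → redundant-item reduction → regularized network estimation →
(bridge) expected influence → bootstrap accuracy/stability. Every
analysis-relevant choice (correlation method, γ or fixed λ, thresholds,
replicate counts, seed) is recorded in the resolved config written beside
the outputs, and all report numbers are recomputable from the serialized
intermediate artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_table, rank_nodes
from .network import NetworkModel, estimate_network
from .questionnaire import (
    ItemResponseMatrix,
    correlation_matrix,
    load_responses,
    load_scales,
    reverse_code,
)
from .redundancy import find_bad_pairs, reduce_nodes
from .resampling import (
    BootstrapResult,
    EstimatorConfig,
    StabilityResult,
    case_dropping_bootstrap_multi,
    centrality_difference_tests,
    cs_coefficient,
    nonparametric_bootstrap,
)
from .synthetic import SyntheticSpec, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; YAML round-trip is lossless."""

    responses_csv: str | None = None
    scales_yaml: str | None = None
    synthetic: dict | None = None       # SyntheticSpec fields; used when no CSV
    corr_method: str = "spearman"
    p_threshold: float = 0.05
    share_threshold: float = 0.75
    gamma: float = 0.25
    fixed_lambda: float | None = None
    n_points: int = 100
    min_ratio: float = 0.01
    B: int = 1000
    drop_levels: list[float] = field(
        default_factory=lambda: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
    )
    alpha: float = 0.05
    seed: int = 0
    top_k: int = 3
    output_dir: str = "bridgenet_run"

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def estimator(self) -> EstimatorConfig:
        return EstimatorConfig(
            corr_method=self.corr_method,
            gamma=self.gamma,
            n_points=self.n_points,
            min_ratio=self.min_ratio,
            fixed_lambda=self.fixed_lambda,
        )


def study_like_config(seed: int = 0, output_dir: str = "bridgenet_run") -> RunConfig:
    """The study-like synthetic preset: 22+65 items, n=101, B=200.

    Uses a 15-point penalty path down to a fifth of λ_max and five drop
    levels — the documented runtime-conscious defaults for the bundled
    preset (see the methods note); the full-size library defaults remain
    available by constructing RunConfig directly.
    """
    return RunConfig(
        synthetic={"seed": seed},
        B=200,
        n_points=15,
        min_ratio=0.2,
        drop_levels=[0.1, 0.3, 0.5, 0.7, 0.9],
        seed=seed,
        output_dir=output_dir,
    )


def validate_config(config: RunConfig) -> list[tuple[str, str]]:
    """Return (level, message) findings; never raises."""
    findings: list[tuple[str, str]] = []
    if config.responses_csv is None and config.synthetic is None:
        findings.append(("error", "no input: set responses_csv/scales_yaml or synthetic"))
    if config.responses_csv is not None and config.scales_yaml is None:
        findings.append(("error", "responses_csv given without scales_yaml"))
    if not 0 < config.p_threshold < 1:
        findings.append(("error", f"p_threshold {config.p_threshold} outside (0, 1)"))
    if not 0 < config.share_threshold < 1:
        findings.append(("error", f"share_threshold {config.share_threshold} outside (0, 1)"))
    if config.gamma is not None and not 0 <= config.gamma <= 0.5:
        findings.append(
            ("warning", f"gamma {config.gamma} outside the conventional [0, 0.5] range")
        )
    if config.fixed_lambda is not None and config.fixed_lambda < 0:
        findings.append(("error", "fixed_lambda must be nonnegative"))
    if config.B < 0:
        findings.append(("error", f"negative bootstrap replicate count B={config.B}"))
    if not 0 < config.alpha <= 1:
        findings.append(("error", f"alpha {config.alpha} outside (0, 1]"))
    for lv in config.drop_levels:
        if not 0 < lv < 1:
            findings.append(("error", f"drop level {lv} outside (0, 1)"))
    if config.n_points < 2:
        findings.append(("error", "n_points must be >= 2"))
    if not 0 < config.min_ratio < 1:
        findings.append(("error", "min_ratio must be in (0, 1)"))
    if config.synthetic is not None:
        try:
            SyntheticSpec(**config.synthetic)
        except (TypeError, ValueError) as exc:
            findings.append(("error", f"invalid synthetic spec: {exc}"))
    return findings


@dataclass
class RunReport:
    seed: int
    version: str
    n: int
    items_entered: int
    items_retained: int
    removed_items: list[str]
    selected_lambda: float
    gamma: float | None
    ebic: float
    edge_count: int
    top_nodes: dict[str, list[str]]
    cs_ei: float | None
    cs_bridge_ei: float | None
    n_significant_ei_pairs: int | None
    bootstrap_failures: int | None
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stability_frame(results: dict[str, StabilityResult]) -> pd.DataFrame:
    rows = []
    for stat, res in results.items():
        for level in res.drop_levels:
            for b, c in enumerate(res.correlations[level]):
                rows.append((stat, level, b, c))
    return pd.DataFrame(rows, columns=["statistic", "drop_level", "replicate", "correlation"])


def _bootstrap_frame(result: BootstrapResult) -> pd.DataFrame:
    pairs = result.edge_pairs
    B, n_edges = result.edge_samples.shape
    return pd.DataFrame(
        {
            "replicate": np.repeat(np.arange(B), n_edges),
            "node_a": [a for _ in range(B) for a, _b in pairs],
            "node_b": [b for _ in range(B) for _a, b in pairs],
            "weight": result.edge_samples.ravel(),
        }
    )


def run_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Execute the full analysis; write artifacts unless ``write=False``."""
    findings = validate_config(config)
    errors = [msg for lvl, msg in findings if lvl == "error"]
    if errors:
        raise PipelineError("config", ValueError("; ".join(errors)))
    for lvl, msg in findings:
        logger.warning("config: %s", msg)

    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
    report_warnings: list[str] = []

    # --- input ------------------------------------------------------------
    try:
        if config.responses_csv is not None:
            scales = load_scales(config.scales_yaml)
            m = load_responses(config.responses_csv, scales)
        else:
            syn = dict(config.synthetic or {})
            syn.setdefault("seed", config.seed)
            spec = SyntheticSpec(**syn)
            m, gt = generate_dataset(spec)
            if write:
                write_dataset(m, outdir)
                gt.to_json(outdir / "ground_truth.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", exc) from exc
    logger.info("input: n=%d, p=%d, missing %.4f%%", m.n, m.p, 100 * m.missing_fraction)

    # --- reverse coding + correlation ------------------------------------
    try:
        m = reverse_code(m)
        S = correlation_matrix(m, method=config.corr_method)
    except Exception as exc:
        raise PipelineError("correlation", exc) from exc

    # --- redundant-item reduction -----------------------------------------
    try:
        report0 = find_bad_pairs(
            S, n=m.n,
            p_threshold=config.p_threshold,
            share_threshold=config.share_threshold,
        )
        m_red, red_report = reduce_nodes(m, report0)
        S_red = correlation_matrix(m_red, method=config.corr_method)
    except Exception as exc:
        raise PipelineError("redundancy", exc) from exc
    if write:
        red_report.to_json(outdir / "redundancy.json")
        S_red.to_csv(outdir / "correlation.csv")
    logger.info(
        "item selection: %d entered, %d removed, %d retained",
        m.p, len(red_report.removed_items), m_red.p,
    )

    # --- network estimation ------------------------------------------------
    try:
        model = estimate_network(
            S_red,
            n=m_red.n,
            gamma=config.gamma,
            n_points=config.n_points,
            min_ratio=config.min_ratio,
            fixed_lambda=config.fixed_lambda,
            communities=m_red.communities,
        )
    except Exception as exc:
        raise PipelineError("estimation", exc) from exc
    if write:
        model.edge_list().to_csv(outdir / "edge_list.csv", index=False)
        model.adjacency_frame().to_csv(outdir / "adjacency.csv", index_label="item_id")
        model.write_graphml(outdir / "network.graphml")
    logger.info(
        "network: λ=%.4f (γ=%s), %d edges", model.selected_lambda,
        model.gamma, model.edge_count,
    )

    # --- centrality ---------------------------------------------------------
    try:
        table = centrality_table(model)
    except Exception as exc:
        raise PipelineError("centrality", exc) from exc
    if write:
        table.to_csv(outdir / "centrality.csv", index=False)
    top_nodes = {
        metric: rank_nodes(table, metric, config.top_k)
        for metric in ("ei1", "ei2", "bridge_ei1", "bridge_ei2")
    }

    # --- bootstrap accuracy & stability -------------------------------------
    cs_ei = cs_bei = n_sig = boot_failures = None
    if config.B > 0:
        estimator = config.estimator()
        try:
            boot = nonparametric_bootstrap(
                m_red, estimator, B=config.B, seed=config.seed
            )
            diffs = centrality_difference_tests(boot, metric="ei", alpha=config.alpha)
            n_sig = sum(d.significant for d in diffs)
            boot_failures = boot.n_failed
            stab = case_dropping_bootstrap_multi(
                m_red, estimator,
                statistics=("ei", "bridge_ei"),
                drop_levels=tuple(config.drop_levels),
                B=config.B, seed=config.seed,
            )
            cs_ei = cs_coefficient(stab["ei"])
            cs_bei = cs_coefficient(stab["bridge_ei"])
        except Exception as exc:
            raise PipelineError("bootstrap", exc) from exc
        if write:
            _bootstrap_frame(boot).to_csv(outdir / "bootstrap_edges.csv", index=False)
            pd.DataFrame(
                {
                    "node_a": [a for a, _ in boot.edge_pairs],
                    "node_b": [b for _, b in boot.edge_pairs],
                    "weight": boot.point_edges,
                    "ci_lower": boot.ci_lower,
                    "ci_upper": boot.ci_upper,
                }
            ).to_csv(outdir / "edge_ci.csv", index=False)
            _stability_frame(stab).to_csv(outdir / "stability.csv", index=False)
    else:
        msg = "B=0: bootstrap accuracy and stability stages skipped"
        warnings.warn(msg)
        report_warnings.append(msg)
        logger.warning(msg)

    report = RunReport(
        seed=config.seed,
        version=__version__,
        n=m.n,
        items_entered=m.p,
        items_retained=m_red.p,
        removed_items=list(red_report.removed_items),
        selected_lambda=float(model.selected_lambda),
        gamma=model.gamma,
        ebic=float(model.ebic_values.min()),
        edge_count=model.edge_count,
        top_nodes=top_nodes,
        cs_ei=cs_ei,
        cs_bridge_ei=cs_bei,
        n_significant_ei_pairs=n_sig,
        bootstrap_failures=boot_failures,
        warnings=report_warnings,
    )
    if write:
        report.to_json(outdir / "report.json")
    return report
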