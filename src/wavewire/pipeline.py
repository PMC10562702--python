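"""End-to-end orchestration: simulate/load -> dynamics -> waves -> flow ->
signatures -> hubs -> recovery report, from a single validated config.

Every stage writes its tables under the output directory and the run closes
with a manifest (thresholds, seeds, stage list, SHA-256 of every output), so
re-running an identical config reproduces identical deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dynamics, flownet, hubnet, signatures, simulate, waves
from .io import (ExpressionStudy, GeneSetCollection, read_expression, read_gmt,
                 write_expression, write_gmt, write_network)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run.

    Defaults are the study conventions this package mirrors: chi-squared gate
    p < 0.01 with fold change >= 2, fuzzifier 1.25, membership threshold 0.5,
    flow sensitivity 10% of the source wave, hub decile 10%, correlation
    significance 0.05 and BH FDR 0.05.
    """

    out_dir: str = "results/run"
    seed: int = 17
    # inputs: either planted simulation (matrix_path None) or files on disk
    matrix_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    tf_list_path: str | None = None
    genotypes: tuple[str, str] = ("WT", "Onc")
    # thresholds
    p_threshold: float = 0.01
    fc_threshold: float = 2.0
    chi2_scale: str = "linear"
    fuzzifier: float = 1.25
    membership_threshold: float = 0.5
    overlap_threshold: float = 0.85
    c_range: tuple[int, int] = (2, 8)
    n_waves: int | None = None       # fixed cluster count; None -> select
    sensitivity: float = 0.10
    ssgsea_alpha: float = 0.25
    corr_alpha: float = 0.05
    frac_threshold: float = 0.2
    hub_fraction: float = 0.10
    fdr: float = 0.05
    powers: tuple[int, ...] = tuple(range(1, 21))
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)

    def __post_init__(self) -> None:
        checks = [
            (0 < self.p_threshold <= 1, "p_threshold must be in (0, 1]"),
            (self.fc_threshold >= 1, "fc_threshold must be >= 1"),
            (self.fuzzifier > 1, "fuzzifier must be > 1"),
            (0 < self.membership_threshold <= 1,
             "membership_threshold must be in (0, 1]"),
            (0 < self.sensitivity <= 1, "sensitivity must be in (0, 1]"),
            (0 < self.hub_fraction <= 1, "hub_fraction must be in (0, 1]"),
            (0 < self.corr_alpha <= 1, "corr_alpha must be in (0, 1]"),
            (0 < self.fdr <= 1, "fdr must be in (0, 1]"),
            (self.c_range[0] >= 2 and self.c_range[1] >= self.c_range[0],
             "c_range must be an increasing pair with minimum >= 2"),
            (self.chi2_scale in ("linear", "log2"),
             "chi2_scale must be 'linear' or 'log2'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = raw["simulation"]
            if "baseline_range" in sim:
                sim["baseline_range"] = tuple(sim["baseline_range"])
            raw["simulation"] = simulate.SimulationConfig(**sim)
        for key in ("genotypes", "c_range", "powers"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns in-memory results keyed by stage name.

    Raises with the failing stage's name on any stage error.  Writes CSV/TSV
    tables, GraphML exports and ``manifest.json`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g_src, g_tgt = config.genotypes
    results: dict = {}
    stages: list[str] = []

    def stage(name):
        stages.append(name)
        logger.info("stage: %s", name)

    try:
        stage("data")
        truth = None
        if config.matrix_path is None:
            study, truth = simulate.generate(config.simulation, seed=config.seed)
            write_expression(study, out / "matrix.tsv", out / "design.tsv")
            truth.to_json(out / "truth.json")
            sets = simulate.truth_gene_sets(truth)
            write_gmt(sets, out / "sets.gmt")
        else:
            study = read_expression(config.matrix_path, config.design_path)
            sets = read_gmt(config.gmt_path) if config.gmt_path else None
        results["study"], results["truth"], results["sets"] = study, truth, sets
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc

    try:
        stage("dynamics")
        calls = {}
        for g in config.genotypes:
            calls[g] = dynamics.chi2_dynamic(
                study, g, p_threshold=config.p_threshold,
                fc_threshold=config.fc_threshold, scale=config.chi2_scale)
            calls[g].to_csv(out / f"calls_{g}.csv")
        results["calls"] = calls
    except Exception as exc:
        raise RuntimeError(f"stage 'dynamics' failed: {exc}") from exc

    try:
        stage("waves")
        wavesets = {}
        for g in config.genotypes:
            dyn = list(calls[g].index[calls[g]["dynamic"]])
            means = study.time_point_means(g).loc[dyn]
            z = dynamics.standardize_rows(means)
            wavesets[g] = waves.build_waveset(
                z, g, member_log2_means=means, c=config.n_waves,
                c_range=range(config.c_range[0], config.c_range[1] + 1),
                m=config.fuzzifier,
                membership_threshold=config.membership_threshold,
                overlap_threshold=config.overlap_threshold, seed=config.seed)
            wavesets[g].to_frame().to_csv(out / f"waves_{g}.csv")
        results["wavesets"] = wavesets
    except Exception as exc:
        raise RuntimeError(f"stage 'waves' failed: {exc}") from exc

    try:
        stage("flow")
        flow = flownet.build_flow(wavesets[g_src], calls[g_src],
                                  wavesets[g_tgt], calls[g_tgt],
                                  sensitivity=config.sensitivity)
        write_network(flow.graph, out / "flow.graphml")
        flownet.flow_summary(flow).to_csv(out / "flow_summary.csv")
        results["flow"] = flow
    except Exception as exc:
        raise RuntimeError(f"stage 'flow' failed: {exc}") from exc

    try:
        stage("signatures")
        typing, profiles, clusters = {}, {}, {}
        if sets is not None and len(sets):
            per_sample = signatures.ssgsea_matrix(study, sets,
                                                  alpha=config.ssgsea_alpha)
            for g in config.genotypes:
                typing[g] = signatures.type_all_signatures(
                    study, sets, g, r_crit_alpha=config.corr_alpha,
                    frac_threshold=config.frac_threshold)
                typing[g].to_csv(out / f"typing_{g}.csv")
                profiles[g] = signatures.enrichment_profiles(
                    study, sets, g, per_sample=per_sample)
                profiles[g].to_csv(out / f"enrichment_{g}.csv")
                if len(profiles[g]) >= 2:
                    clusters[g] = signatures.signature_clusters(
                        profiles[g], alpha=config.corr_alpha)
        results["typing"], results["profiles"] = typing, profiles
        results["clusters"] = clusters
    except Exception as exc:
        raise RuntimeError(f"stage 'signatures' failed: {exc}") from exc

    try:
        stage("hubs")
        networks = {}
        for g in config.genotypes:
            dyn = list(calls[g].index[calls[g]["dynamic"]])
            means = study.time_point_means(g).loc[dyn]
            networks[g] = hubnet.build_wave_networks(
                wavesets[g], means, powers=config.powers,
                hub_fraction=config.hub_fraction)
            pd.concat(
                [nw.table.assign(wave=nw.wave, name=nw.name, beta=nw.beta)
                 for nw in networks[g]]
            ).to_csv(out / f"hubs_{g}.csv")
        overlap = hubnet.hub_overlap(networks[g_src], networks[g_tgt])
        overlap.to_csv(out / "hub_overlap.csv")
        results["networks"], results["hub_overlap"] = networks, overlap
    except Exception as exc:
        raise RuntimeError(f"stage 'hubs' failed: {exc}") from exc

    try:
        stage("report")
        if truth is not None:
            report = simulate.benchmark_recovery(
                truth, calls=calls, wavesets=wavesets, flow=flow,
                networks=networks, typing=typing or None)
            report.to_csv(out / "recovery.csv", index=False)
            results["recovery"] = report
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc

    manifest = {
        "stages": stages,
        "seed": config.seed,
        "thresholds": {
            "p_threshold": config.p_threshold,
            "fc_threshold": config.fc_threshold,
            "chi2_scale": config.chi2_scale,
            "fuzzifier": config.fuzzifier,
            "membership_threshold": config.membership_threshold,
            "sensitivity": config.sensitivity,
            "ssgsea_alpha": config.ssgsea_alpha,
            "corr_alpha": config.corr_alpha,
            "hub_fraction": config.hub_fraction,
            "fdr": config.fdr,
        },
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
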