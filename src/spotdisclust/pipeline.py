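"""End-to-end orchestration: data or simulation -> SPOTDis -> clustering ->
embedding -> evaluation, with deterministic seeds and a run manifest.

Scenario presets encode the parameter sets of the published simulation
protocols under short names (``fig1`` ... ``s11``); any field can be
overridden, which is how the scaled-down variants used in the test-suite are
expressed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cluster_embed import ClusterConfig, cluster_hdbscan, embed_tsne
from .evaluate import (EvaluationReport, ari_noise_rule,
                       silhouette_from_dissimilarity)
from .spike_data import EpochSet, read_epochs_csv
from .spotdis import spotdis_matrix
from .synthetic import (SimulationConfig, expected_spike_count, simulate)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SCENARIOS", "scenario_config", "run"]

# Parameter sets of the published simulation protocols (rates in spks/sample,
# durations in samples).  Values are SimulationConfig field overrides.
SCENARIOS: dict[str, dict] = {
    "fig1": dict(p=5, n_neurons=50, t_epoch=300, t_pulse=30,
                 lam_in=0.2, lam_out=0.02, reps=30, n_noise=150),
    "fig2": dict(p=500, n_neurons=50, t_epoch=300, t_pulse=30,
                 lam_in=0.35, lam_out=0.05, reps=30, n_noise=15000),
    "fig3a": dict(kind="bimodal", p=5, n_neurons=50, t_epoch=300, t_pulse=20,
                  lam_in=0.35, lam_out=0.05, reps=30, n_noise=150),
    "fig3b": dict(kind="deactivation", p=5, n_neurons=50, t_epoch=300,
                  t_deactivation=150, t_pulse=150, lam_in=0.3, lam_out=0.02,
                  reps=30, n_noise=150),
    "fig4a": dict(kind="coarse_fine", p=4, n_neurons=50, t_epoch=300,
                  t_pulse=90, t_pulse_fine=30, lam_in=0.2, lam_in_fine=0.8,
                  lam_out=0.05, reps=30, n_noise=150),
    "fig4b": dict(kind="synchronous", p=4, n_neurons=50, t_epoch=300,
                  t_pulse=50, lam_in=0.4, lam_out=0.05, reps=30, n_noise=150),
    "fig5": dict(p=5, n_neurons=100, t_epoch=300, t_pulse=30,
                 lam_in=0.3, lam_out=0.1, reps=40, n_noise=200),
    "fig6-sparse": dict(p=5, n_neurons=50, t_epoch=300, t_pulse=30,
                        lam_in=0.015, lam_out=0.0001, reps=30, n_noise=150),
    "fig7a": dict(p=2, n_neurons=50, t_epoch=300, t_pulse=30,
                  lam_in=0.2, lam_out=0.02, reps=30, n_noise=30),
    "s7": dict(p=5, n_neurons=330, t_epoch=300, t_pulse=30,
               lam_in=0.15, lam_out=0.01, reps=30, n_noise=150),
    "s8": dict(p=5, n_neurons=50, t_epoch=300, t_pulse=30,
               lam_in=0.2, lam_out=0.02, reps=30, n_noise=150),
    "s9": dict(p=5, n_neurons=50, t_epoch=300, t_pulse=1,
               lam_in=1.0, lam_out=0.0, reps=30, n_noise=0),
    "s11": dict(p=5, n_neurons=50, t_epoch=300, t_pulse=30,
                lam_in=0.2, lam_out=0.02, reps=30, n_noise=150),
}
SCENARIOS["fig6"] = SCENARIOS["fig6-sparse"]


def scenario_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A SimulationConfig for a named scenario, with optional field overrides."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    params = {**SCENARIOS[name], **overrides, "seed": seed}
    return SimulationConfig(**params)


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source, clustering setup, outputs."""

    csv_path: str | None = None
    t_epoch: int | None = None
    scenario: str | None = None
    scenario_overrides: dict = field(default_factory=dict)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    exclude_same_electrode: bool = False
    compute_embedding: bool = True
    seed: int = 0
    n_workers: int = 1

    def __post_init__(self):
        if (self.csv_path is None) == (self.scenario is None):
            raise ValueError("exactly one of csv_path or scenario is required")
        if self.csv_path is not None and self.t_epoch is None:
            raise ValueError("t_epoch is required for CSV input")


def _load_input(cfg: RunConfig) -> tuple[EpochSet, dict]:
    meta: dict = {}
    if cfg.csv_path is not None:
        es = read_epochs_csv(cfg.csv_path, cfg.t_epoch)
        meta["source"] = {"csv": str(cfg.csv_path), "t_epoch": cfg.t_epoch}
    else:
        sim = scenario_config(cfg.scenario, seed=cfg.seed, **cfg.scenario_overrides)
        es, patterns = simulate(sim)
        meta["source"] = {"scenario": cfg.scenario,
                          "config": dataclasses.asdict(sim)}
        if patterns:
            meta["expected_spikes_per_epoch"] = round(
                expected_spike_count(patterns[0]), 2)
    return es, meta


def run(cfg: RunConfig, outdir) -> Path:
    """Execute the full pipeline and persist all artifacts plus a manifest.

    Identical config and seed reproduce every numeric output bitwise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__,
                "python": platform.python_version(),
                "seed": cfg.seed}
    stage = "load"
    try:
        t0 = time.perf_counter()
        es, meta = _load_input(cfg)
        manifest.update(meta)
        logger.info("loaded %d epochs x %d neurons (%.2fs)",
                    es.n_epochs, es.n_neurons, time.perf_counter() - t0)

        stage = "spotdis"
        t0 = time.perf_counter()
        D = spotdis_matrix(es, exclude_same_electrode=cfg.exclude_same_electrode,
                           n_workers=cfg.n_workers)
        D.save(outdir / "dissimilarity.csv")
        logger.info("SPOTDis %dx%d (%.2fs)", D.n_epochs, D.n_epochs,
                    time.perf_counter() - t0)

        stage = "cluster"
        labels = cluster_hdbscan(D, cfg.cluster)
        np.savetxt(outdir / "labels.csv",
                   np.column_stack([es.epoch_ids, labels]).astype(int),
                   delimiter=",", header="epoch_id,label", comments="", fmt="%d")

        stage = "embed"
        if cfg.compute_embedding and cfg.cluster.perplexity < es.n_epochs:
            coords = embed_tsne(D, cfg.cluster)
            rows = np.column_stack([np.asarray(es.epoch_ids, float), coords])
            np.savetxt(outdir / "embedding.csv", rows, delimiter=",",
                       header="epoch_id,x,y", comments="")

        stage = "evaluate"
        report = EvaluationReport()
        if len(set(labels)) > 1:
            report.silhouette = silhouette_from_dissimilarity(D, labels)
        truth = [lab for lab in es.labels if lab is not None]
        if len(truth) == es.n_epochs:
            report.ari = ari_noise_rule(list(es.labels), labels)
        report.save(outdir / "report.txt")
        manifest["n_clusters"] = int(len(set(labels) - {-1}))
        manifest["ari"] = report.ari
        manifest["silhouette"] = report.silhouette
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.exception("pipeline failed in stage %r", stage)
        raise
    manifest["cluster"] = dataclasses.asdict(cfg.cluster)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
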