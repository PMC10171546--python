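"""End-to-end orchestration: simulate -> connectome -> threshold -> metrics ->
model -> report, as one reproducible run.

A run is fully determined by its :class:`RunConfig` (including the seed);
every output table is written as TSV with a provenance header line carrying
the config hash and seed, and re-running an identical config reproduces
byte-identical tables. The functional branch repeats the analysis at each
threshold of the sensitivity grid so significant-region lists can be
compared across thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as cio
from . import metrics as cmetrics
from . import models as cmodels
from . import simulate as csim
from . import thresholding as cthr

logger = logging.getLogger("connectodev")

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    out_dir: str = "run_output"
    modality: str = "both"  # functional | structural | both
    seed: int = 0
    n_regions: int = 60
    n_modules: int = 6
    T: int = 150
    cohort: csim.CohortSpec = field(default_factory=csim.CohortSpec)
    effects: list[csim.EffectSpec] = field(default_factory=list)
    sensitivity_grid: tuple[float, ...] = cthr.SENSITIVITY_TAUS
    primary_tau: float = cthr.PRIMARY_TAU
    select_threshold: bool = False
    n_random: int = 10
    consistency_percentile: float = cthr.DEFAULT_CV_PERCENTILE
    fd_max: float = cio.FD_MAX_MM
    model: cmodels.ModelConfig = field(default_factory=cmodels.ModelConfig)

    def __post_init__(self) -> None:
        if self.modality not in ("functional", "structural", "both"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw:
            raw["cohort"] = csim.CohortSpec(**raw["cohort"])
        if "effects" in raw:
            raw["effects"] = [
                csim.EffectSpec(**{**e, "target_regions": tuple(e["target_regions"])})
                for e in raw["effects"]
            ]
        if "model" in raw:
            raw["model"] = cmodels.ModelConfig(**raw["model"])
        if "sensitivity_grid" in raw:
            raw["sensitivity_grid"] = tuple(raw["sensitivity_grid"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    header = f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline TSV, skipping the provenance header line."""
    return pd.read_csv(path, sep="\t", comment="#")


def _observation_table(
    tables: Sequence[cmetrics.NodeMetricTable], records: Sequence[cio.ScanRecord]
) -> pd.DataFrame:
    """Long-format join of node metrics with phenotypes, plus scan-level eglob."""
    by_scan = {r.scan_id: r for r in records}
    rows = []
    for t in tables:
        rec = by_scan[t.scan_id]
        cov = {
            "subject_id": rec.subject_id, "wave": rec.wave, "age": rec.age,
            "group": rec.group, "sex": rec.sex, "fd": rec.fd,
            "scanner": rec.scanner, "medicated": rec.medicated,
        }
        for _, nrow in t.nodes.iterrows():
            for metric in ("degree", "eloc", "bc"):
                rows.append(
                    {
                        "scan_id": t.scan_id,
                        "region_label": nrow.region_label,
                        "metric_name": metric,
                        "value": float(nrow[metric]),
                        **cov,
                    }
                )
        rows.append(
            {
                "scan_id": t.scan_id, "region_label": "whole_brain",
                "metric_name": "eglob", "value": t.eglob, **cov,
            }
        )
    return pd.DataFrame(rows)


def metrics_for_graphs(
    graphs: Sequence[cthr.BinaryGraph], scan_ids: Sequence[str]
) -> list[cmetrics.NodeMetricTable]:
    return [
        cmetrics.node_metric_table(g, scan_id=sid) for g, sid in zip(graphs, scan_ids)
    ]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("functional")
def run_functional(
    cfg: RunConfig,
    records: list[cio.ScanRecord],
    template: csim.NetworkTemplate,
    out: Path,
) -> dict[str, pd.DataFrame]:
    ts = csim.generate_functional_timeseries(
        records, template, cfg.effects, T=cfg.T, seed=cfg.seed + 1
    )
    matrices = [cio.compute_functional_matrix(t) for t in ts]
    results: dict[str, pd.DataFrame] = {}
    if cfg.select_threshold:
        tau_star, profile = cthr.select_functional_threshold(
            matrices, n_real=cfg.n_random, seed=cfg.seed + 2
        )
        logger.info("selected functional threshold tau=%.2f", tau_star)
        _write_tsv(profile, out / "functional_threshold_profile.tsv", cfg)
        results["threshold_profile"] = profile
    taus = sorted(set(cfg.sensitivity_grid) | {cfg.primary_tau})
    for tau in taus:
        graphs = [cthr.binarize(m, tau) for m in matrices]
        tables = metrics_for_graphs(graphs, [m.scan_id for m in matrices])
        obs = _observation_table(tables, records)
        res = cmodels.regionwise_analysis(obs, cfg.model)
        tag = f"tau{tau:.2f}".replace(".", "p")
        _write_tsv(res, out / f"results_functional_{tag}.tsv", cfg)
        results[f"functional_{tag}"] = res
        if tau == cfg.primary_tau:
            results["functional"] = res
    return results


@_stage("structural")
def run_structural(
    cfg: RunConfig,
    records: list[cio.ScanRecord],
    template: csim.NetworkTemplate,
    out: Path,
) -> dict[str, pd.DataFrame]:
    counts, vols, _ = csim.generate_structural_counts(
        records, template, cfg.effects, seed=cfg.seed + 3
    )
    matrices = [
        cio.scale_structural_matrix(
            counts[r.scan_id], vols, scan_id=r.scan_id,
            region_labels=template.region_labels,
        )
        for r in records
    ]
    mask = cthr.consistency_threshold(matrices, percentile=cfg.consistency_percentile)
    graphs = [cthr.apply_mask_and_prune(m, mask) for m in matrices]
    tables = metrics_for_graphs(graphs, [m.scan_id for m in matrices])
    obs = _observation_table(tables, records)
    res = cmodels.regionwise_analysis(obs, cfg.model)
    _write_tsv(res, out / "results_structural.tsv", cfg)
    return {"structural": res}


def report(results: dict[str, pd.DataFrame], fdr_q: float = 0.05) -> str:
    """Human-readable per-metric summary of the model-selection outcome."""
    lines = ["connectodev run report", "======================"]
    for key in sorted(results):
        res = results[key]
        if not {"metric_name", "winner"}.issubset(res.columns):
            continue
        lines.append(f"\n[{key}]")
        if res.empty:
            lines.append("  (no results)")
            continue
        for metric in sorted(res.metric_name.unique()):
            sub = res[res.metric_name == metric]
            sig = sub[sub.get("significant", False) == True]  # noqa: E712
            by_winner = sub.winner.value_counts().to_dict()
            lines.append(
                f"  {metric}: {len(sub)} regions; winners {by_winner}; "
                f"significant after FDR (q<{fdr_q:g}): {len(sig)}"
            )
            for _, row in sig.iterrows():
                lines.append(
                    f"    {row.region_label}: {row.winner} model, "
                    f"p={row.p_term:.2e}, q={row.q_value:.2e}"
                )
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages; writes result tables, report and provenance."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = dataclasses.replace(cfg.cohort, seed=cfg.seed)
    all_records = csim.generate_phenotypes(cohort)
    records, exclusions = cio.qc_filter_scans(all_records, fd_max=cfg.fd_max)
    cio.write_phenotypes(records, out / "phenotypes.csv")
    if exclusions:
        _write_tsv(pd.DataFrame(exclusions), out / "qc_exclusions.tsv", cfg)
    template = csim.default_template(
        n_regions=cfg.n_regions, n_modules=cfg.n_modules, seed=cfg.seed + 17
    )
    results: dict[str, pd.DataFrame] = {}
    if cfg.modality in ("functional", "both"):
        results.update(run_functional(cfg, records, template, out))
    if cfg.modality in ("structural", "both"):
        results.update(run_structural(cfg, records, template, out))
    if cfg.effects:
        _write_tsv(csim.ground_truth_table(cfg.effects), out / "ground_truth.tsv", cfg)
    (out / "report.txt").write_text(report(results, cfg.model.fdr_q))
    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_scans_retained": len(records),
        "n_scans_excluded": len(exclusions),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    logger.info("run complete: %s", out)
    return results
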