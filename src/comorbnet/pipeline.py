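"""End-to-end workflow: ingest → clean → cohorts → baselines → final
network → metrics → exports, with a run manifest.

The manifest records the seed, the configuration, the parsing/cleaning
counters, and the patient-count funnel at every filtering step, so a run
is auditable and exactly repeatable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .attribution import (
    attribution_adjust,
    top_edges,
    top_nodes,
    write_final_gexf,
    write_final_graphml,
)
from .cohorts import (
    build_histories,
    clean_records,
    membership_table,
    read_episode_table,
    sample_equal,
    select_cohorts,
)
from .icd import load_mapping
from .metrics import summarize, summary_table
from .network import (
    aggregate,
    build_individual,
    edge_table,
    node_table,
    write_gexf,
    write_graphml,
)
from .synthetic import SyntheticConfig, generate, write_truth

logger = logging.getLogger(__name__)

STAGES = ("cohorts", "networks", "final", "metrics")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


@dataclass
class RunConfig:
    input: Union[str, Path]
    outdir: Union[str, Path]
    mapping: Optional[Union[str, Path]] = None
    exclusions: Optional[Union[str, Path]] = None
    index_a: str = "T2DM"
    index_b: str = "CVD"
    seed: int = 0
    sample_size: Union[str, int] = "min"   # "min" or an explicit count
    prune_zero: bool = False
    fdr: bool = False
    metric_convention: str = "directed"
    top_k: int = 10

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.input).exists():
            raise FileNotFoundError(f"input not found: {self.input}")
        for p in (self.mapping, self.exclusions):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"mapping file not found: {p}")
        if self.metric_convention not in ("directed", "undirected"):
            raise ValueError("metric_convention must be 'directed' or 'undirected'")
        if self.sample_size != "min" and int(self.sample_size) <= 0:
            raise ValueError("sample_size must be 'min' or a positive integer")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(
    config: RunConfig, stop_after: Optional[str] = None
) -> dict:
    """Run the workflow and write artifacts; returns the manifest.

    ``stop_after`` truncates the run after one of ``cohorts``,
    ``networks`` or ``final`` (metrics is the last stage anyway).
    """
    config.validate()
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "seed": int(config.seed),
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages_completed": [],
    }

    tables = _stage("mapping")(load_mapping)(config.mapping, config.exclusions)
    disease_a = tables.index_diseases[config.index_a]
    disease_b = tables.index_diseases[config.index_b]

    episodes, parse_stats = _stage("ingest")(read_episode_table)(config.input)
    cleaned, clean_stats = _stage("clean")(clean_records)(
        episodes, tables.exclusions
    )
    manifest["parsing"] = parse_stats
    manifest["cleaning"] = clean_stats
    manifest["episodes_raw"] = len(episodes)
    manifest["episodes_clean"] = len(cleaned)

    histories = build_histories(cleaned)
    ab, a_only, funnel = _stage("cohorts")(select_cohorts)(
        histories, disease_a, disease_b, tables.comorbidities
    )
    manifest["cohort_funnel"] = funnel
    manifest["cohort_sizes"] = {ab.label: len(ab), a_only.label: len(a_only)}

    if config.sample_size == "min":
        n = min(len(ab), len(a_only))
    else:
        n = int(config.sample_size)
    rng = np.random.default_rng(config.seed)
    seed_ab, seed_a = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    ab_sample = _stage("cohorts")(sample_equal)(ab, n, seed_ab)
    a_sample = _stage("cohorts")(sample_equal)(a_only, n, seed_a)
    manifest["sampled_per_cohort"] = n

    membership_table(ab_sample, a_sample).to_csv(
        outdir / "cohort_members.csv", index=False
    )
    manifest["stages_completed"].append("cohorts")
    if stop_after == "cohorts":
        return _finish(manifest, outdir)

    @_stage("networks")
    def _baselines():
        nets_ab = [
            build_individual(ab_sample.members[pid], tables.comorbidities)
            for pid in sorted(ab_sample.members)
        ]
        nets_a = [
            build_individual(a_sample.members[pid], tables.comorbidities)
            for pid in sorted(a_sample.members)
        ]
        return (
            aggregate(nets_ab, label=f"N_{ab.label}"),
            aggregate(nets_a, label=f"N_{a_only.label}"),
        )

    baseline_ab, baseline_a = _baselines()
    for net, stem in ((baseline_ab, "baseline_dual"), (baseline_a, "baseline_single")):
        write_graphml(net, outdir / f"{stem}.graphml")
        write_gexf(net, outdir / f"{stem}.gexf")
        node_table(net).to_csv(outdir / f"{stem}_nodes.csv", index=False)
        edge_table(net).to_csv(outdir / f"{stem}_edges.csv", index=False)
    manifest["baselines"] = {
        net.meta["label"]: {
            "n_nodes": len(net.nodes),
            "n_edges": len(net.edges),
            "total_frequency": net.total_frequency,
            "total_weight": net.total_weight,
            "n_patients": net.meta["n_patients"],
            "n_episodes": net.meta["n_episodes"],
        }
        for net in (baseline_ab, baseline_a)
    }
    manifest["stages_completed"].append("networks")
    if stop_after == "networks":
        return _finish(manifest, outdir)

    final = _stage("final")(attribution_adjust)(
        baseline_ab, baseline_a, fdr=config.fdr
    )
    write_final_graphml(final, outdir / "final.graphml", config.prune_zero)
    write_final_gexf(final, outdir / "final.gexf", config.prune_zero)
    top_nodes(final, config.top_k).to_csv(outdir / "final_top_nodes.csv", index=False)
    top_edges(final, config.top_k).to_csv(outdir / "final_top_edges.csv", index=False)
    manifest["final"] = {
        "adjustment": final.meta["adjustment"],
        "n_positive_nodes": sum(1 for s in final.node_scores.values() if s > 0),
        "n_positive_edges": sum(1 for s in final.edge_scores.values() if s > 0),
    }
    manifest["stages_completed"].append("final")
    if stop_after == "final":
        return _finish(manifest, outdir)

    summaries = _stage("metrics")(
        lambda: [
            summarize(baseline_a, baseline_a.meta["label"], config.metric_convention),
            summarize(baseline_ab, baseline_ab.meta["label"], config.metric_convention),
            summarize(final, "N_final", config.metric_convention),
        ]
    )()
    summary_table(summaries).to_csv(outdir / "network_metrics.csv", index=False)
    manifest["metrics"] = {s.label: s.to_dict() for s in summaries}
    manifest["stages_completed"].append("metrics")
    return _finish(manifest, outdir)


def _finish(manifest: dict, outdir: Path) -> dict:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

PROFILES = {
    "tiny": dict(n_patients_ab=8, n_patients_a=8, n_episodes_range=(3, 5)),
    "paper-scale": dict(),
}


def make_fixture(
    seed: int, profile: str, outdir: Union[str, Path]
) -> dict[str, Path]:
    """Write a synthetic episode table plus its planted-truth file."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(seed=seed, **PROFILES[profile])
    table, truth = generate(config)
    episodes_path = outdir / "episodes.csv"
    truth_path = outdir / "truth.json"
    table.to_csv(episodes_path, index=False)
    write_truth(truth, truth_path)
    logger.info(
        "fixture %r: %d rows, %d patients", profile, len(table),
        table["patient_id"].nunique(),
    )
    return {"episodes": episodes_path, "truth": truth_path}
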