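"""End-to-end orchestration: simulate -> connect -> metrics -> compare -> classify.

A :class:`RunConfig` captures every stage parameter plus the stage toggles;
it round-trips losslessly through JSON and any unknown key is a hard error,
so a written config always reproduces its run. One global seed is fanned
out to per-stage child seeds, so disabling one stage does not shift the
random stream of another. Every table written carries a provenance header
(config hash, seed, package version) as ``#`` comment lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierConfig, c_sweep, cohort_feature_matrix
from .compare import compare_all_metrics, group_average_matrix, summarize_z
from .io import read_cohort, write_cohort, write_matrix
from .metrics import cohort_auc_table
from .network import pearson_fisher, rectify_negative, threshold_sweep
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "docnet-run"
    manifest: str | None = None  # None => simulate a synthetic cohort
    seed: int = 42

    simulate: bool = True
    connect: bool = True
    metrics: bool = True
    compare: bool = True
    classify: bool = True

    # synthetic stage
    n_regions: int = 90
    n_timepoints: int = 200
    group_sizes: dict = field(default_factory=lambda: {"NC": 30, "MCS": 19, "VS": 40})

    # network stage
    s_min: float = 0.05
    s_max: float = 0.40
    s_step: float = 0.01

    # comparison stage
    n_perm: int = 10_000
    alpha: float = 0.05
    correction: str | None = None

    # classification stage
    c_min: float = 0.1
    c_max: float = 1.0
    c_step: float = 0.01
    smote_k: int = 5
    svm_kernel: str = "linear"
    svm_cost: float = 1.0
    paper_mode: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# docnet {__version__} config={config.config_hash()} "
                 f"seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _stage_seed(config: RunConfig, stage: int) -> int:
    # Independent per-stage streams from the single global seed.
    ss = np.random.SeedSequence([config.seed, stage])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns a summary of artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    summary: dict = {"out_dir": str(out)}

    cohort = None
    if config.simulate:
        spec = CohortSpec(
            n_regions=config.n_regions,
            n_timepoints=config.n_timepoints,
            group_sizes=dict(config.group_sizes),
            seed=_stage_seed(config, 0),
        )
        cohort = generate_cohort(spec)
        manifest = write_cohort(cohort, out / "timeseries")
        summary["manifest"] = str(manifest)
        logger.info("simulated %d subjects", len(cohort))
    elif config.manifest:
        cohort = read_cohort(config.manifest)
        summary["manifest"] = config.manifest

    if not any([config.connect, config.metrics, config.compare, config.classify]):
        return summary
    if cohort is None:
        raise ValueError("connect stage needs a manifest or the simulate stage")

    groups = {ts.subject_id: ts.group for ts in cohort}
    labels = cohort[0].region_labels

    conn = {}
    if config.connect or config.metrics or config.compare:
        for ts in cohort:
            conn[ts.subject_id] = pearson_fisher(ts)
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        for sid, C in conn.items():
            write_matrix(C.z, C.region_labels, conn_dir / f"{sid}.tsv")
        summary["connectivity_dir"] = str(conn_dir)

    z_rows = []
    present_groups = sorted(set(groups.values()),
                            key=["NC", "MCS", "VS"].index)
    for g in present_groups:
        avg = group_average_matrix(
            list(conn.values()), [groups[s] for s in conn], g
        )
        zs = summarize_z(avg, group=g)
        z_rows.append((g, zs.mean_z, zs.sd_z))
    zsum = pd.DataFrame(z_rows, columns=["group", "mean_z", "sd_z"])
    _write_table(zsum, out / "z_summary.tsv", config)
    summary["z_summary"] = str(out / "z_summary.tsv")

    if not (config.metrics or config.compare or config.classify):
        return summary

    nets = {
        sid: threshold_sweep(rectify_negative(C), config.s_min, config.s_max,
                             config.s_step)
        for sid, C in conn.items()
    }
    auc = cohort_auc_table(nets, groups)
    _write_table(auc, out / "auc_table.tsv", config)
    summary["auc_table"] = str(out / "auc_table.tsv")

    if config.compare and len(present_groups) >= 2:
        pairs = [
            (a, b)
            for i, a in enumerate(present_groups)
            for b in present_groups[i + 1 :]
        ]
        frames = []
        for pair in pairs:
            res = compare_all_metrics(
                auc, pair, n_perm=config.n_perm, alpha=config.alpha,
                rng=_stage_seed(config, 3), correction=config.correction,
            )
            frames.append(res)
        comparison = pd.concat(frames, ignore_index=True)
        _write_table(comparison, out / "comparisons.tsv", config)
        summary["comparisons"] = str(out / "comparisons.tsv")

    if config.classify:
        feats = cohort_feature_matrix(auc, labels)
        if feats:
            cc = ClassifierConfig(
                smote_k=config.smote_k, svm_kernel=config.svm_kernel,
                svm_cost=config.svm_cost, paper_mode=config.paper_mode,
                seed=_stage_seed(config, 4),
            )
            report = c_sweep(feats, config.c_min, config.c_max, config.c_step, cc)
            _write_table(report, out / "c_sweep.tsv", config)
            summary["c_sweep"] = str(out / "c_sweep.tsv")
            best = report[report["best"]].iloc[0]
            summary["best_C"] = float(best["C"])
            summary["best_accuracy"] = float(best["accuracy"])

    return summary
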