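"""End-to-end pipeline orchestration: config, stages, persisted tables.

Every stage is deterministic given the run configuration and its master
seed: stage seeds are derived as a stable hash of (master seed, stage name,
replicate), so reruns are byte-identical and any stage can be recomputed in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import architectures, grid, sampling, seqdata, stats, synthetic
from .util import derive_seed, stable_hash

logger = logging.getLogger(__name__)

CORE_ARCHITECTURES = tuple(s.name for s in architectures.registry())
ALL_METHODS = tuple(s.name for s in sampling.builtin_specs())


@dataclass
class RunConfig:
    """Full study configuration (serializable; hashed into every manifest)."""

    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig)
    methods: Tuple[str, ...] = ALL_METHODS
    architectures: Tuple[str, ...] = CORE_ARCHITECTURES
    n_replicates: int = 2
    split_fraction: float = 0.8
    positive_identity_threshold: float = 0.9
    pairing_rule: str = "paired_replicate"
    master_seed: int = 97

    def __post_init__(self):
        if isinstance(self.synthetic, dict):
            self.synthetic = synthetic.SyntheticConfig(**self.synthetic)
        self.methods = tuple(self.methods)
        self.architectures = tuple(self.architectures)
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown sampling methods {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["architectures"] = list(self.architectures)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return stable_hash(yaml.safe_dump(self.as_dict(), sort_keys=True))


def small_config(seed: int = 97) -> RunConfig:
    """A minutes-scale configuration used for smoke runs and fixtures."""
    return RunConfig(
        synthetic=synthetic.SyntheticConfig(n_positive=200,
                                            n_background=12000, seed=seed),
        methods=("AmpGram", "dbAMP", "Gabere&Noble"),
        architectures=("AMAP", "MACREL", "iAMP-2L"),
        n_replicates=2,
        master_seed=seed)


def fixture_config(seed: int = 97) -> RunConfig:
    """Mid-size configuration for sampler-invariant checks (all methods)."""
    return RunConfig(
        synthetic=synthetic.SyntheticConfig(n_positive=300,
                                            n_background=16000, seed=seed),
        n_replicates=5,
        master_seed=seed)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def build_inputs(config: RunConfig):
    """Generate (or regenerate) the positive split and background database."""
    scfg = dataclasses.replace(config.synthetic)
    positives = synthetic.generate_positives(scfg)
    background = synthetic.generate_background(scfg)
    positives = seqdata.reduce_redundancy_positive(
        positives, config.positive_identity_threshold)
    split = seqdata.split_positive(
        positives, config.split_fraction,
        seed=derive_seed(config.master_seed, "positive_split"))
    logger.info("inputs: %d positives (%d train / %d bench), %d background",
                len(split.train) + len(split.bench), len(split.train),
                len(split.bench), len(background))
    return split, background


def sample_all(config: RunConfig, split, background
               ) -> Dict[str, List[sampling.ReplicatedDataset]]:
    """Run every configured sampling method for every replicate."""
    datasets = {}
    for name in config.methods:
        spec = sampling.spec_by_name(name)
        datasets[name] = sampling.assemble_negative_sample(
            spec, background, split, n_replicates=config.n_replicates,
            seed=derive_seed(config.master_seed, "sampling", name))
        logger.info("sampled %s: train=%d bench=%d", name,
                    len(datasets[name][0].neg_train),
                    len(datasets[name][0].neg_bench))
    return datasets


def run_benchmark(config: RunConfig,
                  datasets: Dict[str, List[sampling.ReplicatedDataset]],
                  completed: Optional[List[grid.GridResult]] = None,
                  progress=None) -> List[grid.GridResult]:
    plan = grid.plan_grid(config.architectures, config.methods,
                          config.n_replicates, config.pairing_rule)
    return grid.run_grid(plan, datasets,
                         seed=derive_seed(config.master_seed, "grid"),
                         completed=completed, progress=progress)


def run_all(config: RunConfig, outdir=None, resume: bool = False):
    """Execute the full pipeline; optionally persist tables under `outdir`.

    Returns (grid results, distance records).
    """
    split, background = build_inputs(config)
    datasets = sample_all(config, split, background)
    distances = stats.compute_distance_records(datasets)
    completed = None
    grid_path = None
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "grid").mkdir(parents=True, exist_ok=True)
        grid_path = outdir / "grid" / "grid.csv"
        if resume and grid_path.exists():
            completed = grid.frame_to_results(pd.read_csv(grid_path))
    results = run_benchmark(config, datasets, completed=completed)
    if outdir is not None:
        write_table(grid.results_to_frame(results), grid_path)
        write_table(stats.distances_to_frame(distances),
                    outdir / "grid" / "distances.csv")
        write_manifest(config, outdir / "grid" / "manifest.json")
    return results, distances


def compute_stats(results, distances, seed: int = 0) -> dict:
    """All diagnostic tables from a finished grid."""
    summary = stats.bias_summary(results)
    df = grid.results_to_frame(results)
    tables = {
        "bias_per_architecture": summary.per_architecture.reset_index(),
        "correlations": stats.correlation_analyses(results, distances,
                                                   seed=seed),
        "replicate_sd": summary.replicate_sd,
        "mad_ratios": pd.DataFrame([
            {"grouping": grouping,
             "mad_ratio": (stats.mad_ratio(df.auc, df[column])
                           if df[column].nunique() > 1 else float("nan"))}
            for grouping, column in (("architecture", "architecture"),
                                     ("train_method", "train_method"),
                                     ("bench_method", "bench_method"))
        ]),
    }
    tests = stats.group_tests(results)
    tables["kruskal_wallis"] = tests["kruskal_wallis"]
    for family, t in tests["pairwise_wilcoxon"].items():
        tables[f"wilcoxon_{family}"] = t
    tables["fraction_significant"] = pd.DataFrame(
        [{"family": k, "fraction": v}
         for k, v in tests["fraction_significant"].items()])
    tables["summary_scalars"] = pd.DataFrame([{
        "mean_diagonal_auc": summary.mean_diagonal_auc,
        "mean_offdiagonal_auc": summary.mean_offdiagonal_auc,
        "n_cells": len(df),
    }])
    return tables


# ---------------------------------------------------------------------------
# persistence helpers (stable text formats for byte-identical reruns)
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_manifest(config: RunConfig, path) -> None:
    import numpy
    import sklearn

    from . import __version__

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash,
                "master_seed": config.master_seed,
                "methods": list(config.methods),
                "architectures": list(config.architectures),
                "n_replicates": config.n_replicates,
                "versions": {"ampbench": __version__,
                             "numpy": numpy.__version__,
                             "sklearn": sklearn.__version__}}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_datasets(datasets: Dict[str, List[sampling.ReplicatedDataset]],
                   split, outdir) -> None:
    """Persist per-replicate FASTA pairs plus provenance/stage-count TSVs."""
    outdir = Path(outdir)
    posdir = outdir / "positives"
    posdir.mkdir(parents=True, exist_ok=True)
    seqdata.write_fasta(split.train, posdir / "pos_train.fasta")
    seqdata.write_fasta(split.bench, posdir / "pos_bench.fasta")
    with open(outdir / "sampling_specs.yaml", "w") as fh:
        yaml.safe_dump([sampling.spec_by_name(n).to_dict()
                        for n in sorted(datasets)], fh, sort_keys=True)
    for name, reps in datasets.items():
        for ds in reps:
            d = outdir / _slug(name) / f"replicate_{ds.replicate_index}"
            d.mkdir(parents=True, exist_ok=True)
            seqdata.write_fasta(ds.neg_train, d / "neg_train.fasta")
            seqdata.write_fasta(ds.neg_bench, d / "neg_bench.fasta")
            with open(d / "provenance.tsv", "w") as fh:
                fh.write("id\tparent_id\tstart\tend\n")
                for rec in ds.neg_train + ds.neg_bench:
                    parent, s, e = ds.provenance[rec.id]
                    fh.write(f"{rec.id}\t{parent}\t{s}\t{e}\n")
            with open(d / "stage_counts.tsv", "w") as fh:
                fh.write("stage\tcount\n")
                for stage, count in ds.stage_counts.items():
                    fh.write(f"{stage}\t{count}\n")


def _slug(name: str) -> str:
    import re

    return re.sub(r"[^A-Za-z0-9]+", "", name)
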