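"""The cross-benchmark experiment grid.

Every architecture is trained on the shared positive training sample plus
each sampling method's negative training sample (per replicate), and every
trained model is evaluated — by ROC AUC — against the shared positive
benchmark sample paired with *every* sampling method's negative benchmark
sample.  The diagonal of the resulting (training method x benchmark method)
grid corresponds to the conventional, potentially self-serving benchmark
design; the off-diagonal cells measure transfer to differently-sampled
negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import architectures as arch
from .sampling import ReplicatedDataset
from .util import derive_seed as _derive_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridPlan:
    """The experiment design: which models to train and how to pair them."""

    architectures: tuple
    sampling_methods: tuple
    n_replicates: int
    pairing_rule: str = "paired_replicate"  # or "full_cross"

    def __post_init__(self):
        if not self.architectures or not self.sampling_methods:
            raise ValueError("empty architecture or sampling-method list")
        if self.pairing_rule not in ("paired_replicate", "full_cross"):
            raise ValueError(f"unknown pairing rule {self.pairing_rule!r}")

    @property
    def n_models(self) -> int:
        return (len(self.architectures) * len(self.sampling_methods)
                * self.n_replicates)

    @property
    def n_evaluations(self) -> int:
        per_model = len(self.sampling_methods)
        if self.pairing_rule == "full_cross":
            per_model *= self.n_replicates
        return self.n_models * per_model


def plan_grid(architectures: Sequence[str], sampling_methods: Sequence[str],
              n_replicates: int,
              pairing_rule: str = "paired_replicate") -> GridPlan:
    """Build a grid plan and log its model/evaluation counts."""
    plan = GridPlan(tuple(architectures), tuple(sampling_methods),
                    n_replicates, pairing_rule)
    logger.info("grid plan: %d models, %d evaluations",
                plan.n_models, plan.n_evaluations)
    return plan


@dataclass(frozen=True)
class GridResult:
    """One AUC for (architecture, training method, benchmark method,
    replicate) — the atom of the analysis."""

    architecture: str
    train_method: str
    bench_method: str
    replicate: int
    auc: float
    n_pos_bench: int
    n_neg_bench: int


def roc_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Area under the ROC curve with half-credit for ties.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    sp = np.asarray(scores_pos, dtype=float)
    sn = np.asarray(scores_neg, dtype=float)
    if sp.size == 0 or sn.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([sp, sn]))
    u = ranks[:sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sn.size))


def results_to_frame(results: Sequence[GridResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def frame_to_results(df: pd.DataFrame) -> List[GridResult]:
    return [GridResult(row.architecture, row.train_method, row.bench_method,
                       int(row.replicate), float(row.auc),
                       int(row.n_pos_bench), int(row.n_neg_bench))
            for row in df.itertuples()]


def run_grid(plan: GridPlan,
             datasets: Dict[str, List[ReplicatedDataset]],
             specs: Optional[Sequence[arch.ArchitectureSpec]] = None,
             seed: int = 0,
             completed: Optional[Sequence[GridResult]] = None,
             progress=None) -> List[GridResult]:
    """Execute the grid: train each (architecture, TSM, replicate) model and
    evaluate it on every benchmark sampling method.

    Cells already present in `completed` are skipped (resumability); cells
    are independent, so any execution order yields identical results.
    Benchmark feature matrices are cached per (extractor, benchmark set) for
    training-independent extractors.
    """
    for method in plan.sampling_methods:
        if method not in datasets:
            raise KeyError(f"missing datasets for sampling method {method!r}")
        reps = {d.replicate_index for d in datasets[method]}
        if not set(range(1, plan.n_replicates + 1)) <= reps:
            raise KeyError(f"missing replicates for {method!r}: have {reps}")
    if specs is None:
        specs = [arch.spec_by_name(a) for a in plan.architectures]
    spec_map = {s.name: s for s in specs}
    by_method_rep = {(d.spec_name, d.replicate_index): d
                     for method in plan.sampling_methods
                     for d in datasets[method]}
    done = {(r.architecture, r.train_method, r.bench_method, r.replicate)
            for r in (completed or [])}
    results: List[GridResult] = list(completed or [])
    feature_cache: dict = {}

    for a_name in plan.architectures:
        spec = spec_map[a_name]
        for tsm in plan.sampling_methods:
            for rep in range(1, plan.n_replicates + 1):
                bench_reps = ([rep] if plan.pairing_rule == "paired_replicate"
                              else list(range(1, plan.n_replicates + 1)))
                todo = [(bsm, brep) for bsm in plan.sampling_methods
                        for brep in bench_reps
                        if (a_name, tsm, bsm, rep) not in done]
                if not todo:
                    continue
                train_ds = by_method_rep[(tsm, rep)]
                model_seed = _derive_seed(seed, a_name, tsm, rep)
                model = arch.train(spec.with_seed(model_seed),
                                   train_ds.pos_train, train_ds.neg_train)
                pos_scores_cache: dict = {}
                for bsm, brep in todo:
                    bench_ds = by_method_rep[(bsm, brep)]
                    key_pos = ("pos", brep)
                    if key_pos not in pos_scores_cache:
                        pos_scores_cache[key_pos] = _scores(
                            model, bench_ds.pos_bench, feature_cache,
                            ("posbench", brep))
                    sp = pos_scores_cache[key_pos]
                    sn = _scores(model, bench_ds.neg_bench, feature_cache,
                                 ("negbench", bsm, brep))
                    res = GridResult(a_name, tsm, bsm, rep,
                                     roc_auc(sp, sn),
                                     len(sp), len(sn))
                    results.append(res)
                    done.add((a_name, tsm, bsm, rep))
                    logger.info("cell %s TSM=%s BSM=%s rep=%d auc=%.4f",
                                a_name, tsm, bsm, rep, res.auc)
                if progress is not None:
                    progress(a_name, tsm, rep)
    return results


def _scores(model: arch.TrainedModel, records, feature_cache, set_key):
    """Model scores with caching of raw feature matrices per benchmark set
    (only for extractors whose features do not depend on training data)."""
    spec = model.spec
    training_dependent = spec.extractor in ("ngram", "lz_profile")
    if training_dependent:
        return arch.predict_scores(model, records)
    cache_key = (spec.extractor, repr(sorted(spec.extractor_params.items())),
                 set_key)
    if cache_key not in feature_cache:
        feature_cache[cache_key] = arch.extract_matrix(
            spec.extractor, [r.residues for r in records],
            spec.extractor_params)
    X = feature_cache[cache_key]
    if model.selector_state is not None:
        kind = model.selector_state["kind"]
        if kind == "PCA":
            X = model.selector_state["pca"].transform(X)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    return np.clip(model.classifier.predict_scores(X), 0.0, 1.0)
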