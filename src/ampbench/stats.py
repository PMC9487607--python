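"""Bias diagnostics over the cross-benchmark grid.

The central question: do models score higher when the benchmark negatives
come from the same sampling method as their training negatives (the
diagonal of the grid) than when they come from a different one?  The module
quantifies that effect and attributes AUC dispersion to its three design
components (architecture, training sampling method, benchmark sampling
method) via MAD ratios, set-distance correlations and non-parametric tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqdata import AA_INDEX, SequenceRecord
from .grid import GridResult, results_to_frame
from .sampling import ReplicatedDataset


# ---------------------------------------------------------------------------
# set-level distances
# ---------------------------------------------------------------------------

def _pooled_frequencies(records: Sequence[SequenceRecord]) -> np.ndarray:
    counts = np.zeros(20)
    for r in records:
        for a in r.residues:
            counts[AA_INDEX[a]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("empty sequence set")
    return counts / total


def composition_distance(set_a: Sequence[SequenceRecord],
                         set_b: Sequence[SequenceRecord]) -> float:
    """Euclidean distance between pooled 20-dim residue-frequency vectors."""
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    return float(np.linalg.norm(_pooled_frequencies(set_a)
                                - _pooled_frequencies(set_b)))


@dataclass(frozen=True)
class DistanceRecord:
    """Pairwise train/bench set properties for one grid cell."""

    tsm: str
    bsm: str
    replicate: int
    composition_distance: float
    median_length_abs_diff: float
    bench_neg_vs_pos_median_length_diff: float


def compute_distance_records(datasets: Dict[str, List[ReplicatedDataset]]
                             ) -> List[DistanceRecord]:
    """Distances between each training and benchmark negative sample.

    The positive sample is shared by every grid cell, so the train/bench
    set differences live entirely in the negatives; the distances are
    therefore computed between the TSM negative training sample and the BSM
    negative benchmark sample (per replicate), plus the benchmark
    negative-vs-positive median-length gap.
    """
    out = []
    methods = sorted(datasets)
    by_key = {(d.spec_name, d.replicate_index): d
              for m in methods for d in datasets[m]}
    reps = sorted({d.replicate_index for m in methods for d in datasets[m]})
    for tsm, bsm, rep in itertools.product(methods, methods, reps):
        dt = by_key[(tsm, rep)]
        db = by_key[(bsm, rep)]
        med_train = float(np.median([len(r) for r in dt.neg_train]))
        med_bench = float(np.median([len(r) for r in db.neg_bench]))
        med_bench_neg = med_bench
        med_bench_pos = float(np.median([len(r) for r in db.pos_bench]))
        out.append(DistanceRecord(
            tsm=tsm, bsm=bsm, replicate=rep,
            composition_distance=composition_distance(dt.neg_train,
                                                      db.neg_bench),
            median_length_abs_diff=abs(med_train - med_bench),
            bench_neg_vs_pos_median_length_diff=(med_bench_neg
                                                 - med_bench_pos)))
    return out


def distances_to_frame(records: Sequence[DistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# MAD ratio
# ---------------------------------------------------------------------------

def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation (no consistency factor)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def mad_ratio(values: Sequence[float], groups: Sequence) -> float:
    """Between-group MAD (of group medians) over within-group MAD (median of
    per-group MADs).

    Degenerate dispersions are flagged as special values: inf when the
    within-group MAD vanishes but the between-group MAD does not, and nan
    when both vanish.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    medians, mads = [], []
    for g in uniq:
        sel = values[groups == g]
        if sel.size == 0:
            raise ValueError(f"empty group {g!r}")
        medians.append(np.median(sel))
        mads.append(_mad(sel))
    between = _mad(np.array(medians))
    within = float(np.median(mads))
    if within == 0.0:
        return math.nan if between == 0.0 else math.inf
    return between / within


# ---------------------------------------------------------------------------
# bias summary
# ---------------------------------------------------------------------------

@dataclass
class BiasSummary:
    """Per-architecture same- vs different-method AUC comparison plus the
    grouped AUC distributions and replicate dispersion."""

    per_architecture: pd.DataFrame       # mean_same, mean_diff, improvement_%
    auc_by_architecture: Dict[str, np.ndarray]
    auc_by_tsm: Dict[str, np.ndarray]
    auc_by_bsm: Dict[str, np.ndarray]
    replicate_sd: pd.DataFrame           # per (architecture, tsm, bsm)
    mean_diagonal_auc: float
    mean_offdiagonal_auc: float


def bias_summary(grid: Sequence[GridResult]) -> BiasSummary:
    """Diagonal-vs-off-diagonal comparison and grouped AUC distributions."""
    df = results_to_frame(list(grid))
    if df.empty:
        raise ValueError("empty grid")
    diag = df[df.train_method == df.bench_method]
    off = df[df.train_method != df.bench_method]
    rows = []
    for a, sub in df.groupby("architecture"):
        same = sub[sub.train_method == sub.bench_method].auc
        diff = sub[sub.train_method != sub.bench_method].auc
        if same.empty or diff.empty:
            raise ValueError(f"architecture {a!r} lacks diagonal or "
                             f"off-diagonal cells")
        mean_same, mean_diff = float(same.mean()), float(diff.mean())
        improvement = (100.0 * (mean_same - mean_diff) / mean_diff
                       if mean_diff > 0 else math.nan)
        rows.append({"architecture": a, "mean_auc_same": mean_same,
                     "mean_auc_diff": mean_diff,
                     "improvement_pct": improvement})
    per_arch = pd.DataFrame(rows).set_index("architecture")
    rep_sd = (df.groupby(["architecture", "train_method", "bench_method"])
              ["auc"].std(ddof=1).rename("auc_sd").reset_index())
    return BiasSummary(
        per_architecture=per_arch,
        auc_by_architecture={a: s.auc.to_numpy()
                             for a, s in df.groupby("architecture")},
        auc_by_tsm={t: s.auc.to_numpy()
                    for t, s in df.groupby("train_method")},
        auc_by_bsm={b: s.auc.to_numpy()
                    for b, s in df.groupby("bench_method")},
        replicate_sd=rep_sd,
        mean_diagonal_auc=float(diag.auc.mean()),
        mean_offdiagonal_auc=float(off.auc.mean()),
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _spearman(x: np.ndarray, y: np.ndarray, seed: int = 0):
    """Spearman rho with a t-approximation p for n > 30 and a permutation
    p-value for smaller samples (exact enumeration up to n = 8)."""
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        rho, p_t = sps.spearmanr(x, y)
    if math.isnan(rho):
        return math.nan, math.nan
    if n > 30:
        return float(rho), float(p_t)
    res = sps.permutation_test(
        (x,), lambda xs: sps.spearmanr(xs, y).statistic,
        permutation_type="pairings",
        n_resamples=40320 if n <= 8 else 9999,
        alternative="two-sided", rng=seed)
    return float(rho), float(res.pvalue)


def correlation_analyses(grid: Sequence[GridResult],
                         distances: Sequence[DistanceRecord],
                         seed: int = 0) -> pd.DataFrame:
    """Spearman correlations of mean AUC with train/bench set distances.

    AUC is averaged over architectures at (TSM, BSM, replicate) granularity
    and joined with the distance records on those keys.  Reports rho and p
    for (i) composition distance, (ii) absolute median-length difference and
    (iii) benchmark negative-minus-positive median-length difference.
    """
    gdf = results_to_frame(list(grid))
    mean_auc = (gdf.groupby(["train_method", "bench_method", "replicate"])
                ["auc"].mean().reset_index())
    ddf = distances_to_frame(list(distances)).rename(
        columns={"tsm": "train_method", "bsm": "bench_method"})
    joined = mean_auc.merge(ddf, on=["train_method", "bench_method",
                                     "replicate"], how="inner")
    if len(joined) < 3:
        raise ValueError("fewer than 3 joined (grid, distance) points")
    rows = []
    for label, col in (
            ("auc_vs_composition_distance", "composition_distance"),
            ("auc_vs_median_length_abs_diff", "median_length_abs_diff"),
            ("auc_vs_bench_neg_pos_length_diff",
             "bench_neg_vs_pos_median_length_diff")):
        rho, p = _spearman(joined[col].to_numpy(),
                           joined["auc"].to_numpy(), seed=seed)
        rows.append({"analysis": label, "rho": rho, "p_value": p,
                     "n": len(joined)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def bonferroni(pvals: Sequence[float]) -> np.ndarray:
    """adjusted p = min(1, p * m)."""
    p = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, p * p.size)


def group_tests(grid: Sequence[GridResult], alpha: float = 0.05) -> dict:
    """The grid's hypothesis tests.

    * per-architecture Kruskal-Wallis comparing same-method vs
      different-method AUC sets, Bonferroni-adjusted across architectures;
    * pairwise paired Wilcoxon tests within each grouping family
      (architectures, TSMs, BSMs), pairing cells by the complementary keys,
      Bonferroni-adjusted within the family; the fraction of significant
      comparisons per family is reported.
    """
    df = results_to_frame(list(grid))
    kw_rows = []
    for a, sub in df.groupby("architecture"):
        same = sub[sub.train_method == sub.bench_method].auc.to_numpy()
        diff = sub[sub.train_method != sub.bench_method].auc.to_numpy()
        if np.all(np.concatenate([same, diff])
                  == np.concatenate([same, diff])[0]):
            p = 1.0
        else:
            p = float(sps.kruskal(same, diff).pvalue)
        kw_rows.append({"architecture": a, "p_raw": p})
    kw = pd.DataFrame(kw_rows)
    kw["p_adj"] = bonferroni(kw.p_raw)
    kw["significant"] = kw.p_adj < alpha

    families = {}
    for family, key, others in (
            ("architecture", "architecture",
             ["train_method", "bench_method", "replicate"]),
            ("train_method", "train_method",
             ["architecture", "bench_method", "replicate"]),
            ("bench_method", "bench_method",
             ["architecture", "train_method", "replicate"])):
        wide = df.pivot_table(index=others, columns=key, values="auc")
        levels = list(wide.columns)
        rows = []
        for g1, g2 in itertools.combinations(levels, 2):
            sub = wide[[g1, g2]].dropna()
            if sub.empty:
                raise ValueError(f"no paired cells for {g1!r} vs {g2!r}")
            d = sub[g1] - sub[g2]
            if np.allclose(d, 0.0):
                p = 1.0
            else:
                p = float(sps.wilcoxon(sub[g1], sub[g2]).pvalue)
            rows.append({"group_1": g1, "group_2": g2, "p_raw": p})
        fam = pd.DataFrame(rows)
        fam["p_adj"] = bonferroni(fam.p_raw)
        fam["significant"] = fam.p_adj < alpha
        families[family] = fam
    frac = {family: float(t.significant.mean())
            for family, t in families.items()}
    return {"kruskal_wallis": kw, "pairwise_wilcoxon": families,
            "fraction_significant": frac}
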