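"""Named architecture specs binding feature extractors to classifiers.

An *architecture* is one published approach to AMP prediction — a feature
extraction scheme, an optional feature-selection step, and a classifier —
and a *model* is one trained instance of an architecture (one training
sampling method, one replicate).  Classifier hyperparameters default to
conventional choices (random forest with 200 trees — AUC is insensitive to
more trees at these sample sizes; RBF-kernel SVM with C=1,
gamma=1/n_features, linear kernel for the pure-AAC SVM; fuzzy k-NN with
k=5, m=2); all are configurable per spec.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy.sparse import issparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from . import features as F
from .seqdata import SequenceRecord

#: architectures excluded from desk-scale training (deep learning stand-ins
#: would need a neural-network stack and the headline analysis does not
#: require them); they are still registered for grid planning.
DEEP_ARCHITECTURES = ("AMPScannerV2", "Deep-AmPEP30")


@dataclass(frozen=True)
class ArchitectureSpec:
    """A named feature-extractor + selector + classifier configuration."""

    name: str
    extractor: str                       # feature scheme identifier
    selector: Optional[str] = None       # None | "QuiPT" | "PCA"
    classifier: str = "random_forest"    # random_forest | svm | fknn
    classifier_params: dict = field(default_factory=dict)
    extractor_params: dict = field(default_factory=dict)
    seed: int = 0

    def with_seed(self, seed: int) -> "ArchitectureSpec":
        return replace(self, seed=seed)


def registry(include_deep: bool = False,
             lz_reference_size: int = 100) -> List[ArchitectureSpec]:
    """The classical architecture roster (10 core entries).

    `lz_reference_size` sets the LZ-complexity reference-panel size for the
    similarity-profile SVM (the original used 1000; the default here is a
    desk-scale panel, configurable).
    """
    specs = [
        ArchitectureSpec("AMAP", "aac", None, "svm",
                         {"kernel": "linear"}),
        ArchitectureSpec("AmPEP", "ampep_subset", None, "random_forest"),
        ArchitectureSpec("AmPEPpy", "ctd_distribution", None,
                         "random_forest"),
        ArchitectureSpec("AmpGram", "ngram", "QuiPT", "random_forest"),
        ArchitectureSpec("ampir", "ampir", None, "svm"),
        ArchitectureSpec("CS-AMPPred", "cs_amppred", "PCA", "svm"),
        ArchitectureSpec("iAMP-2L", "pseaac", None, "fknn",
                         extractor_params={"lam": 20, "clip_lam": True}),
        ArchitectureSpec("MACREL", "macrel", None, "random_forest"),
        ArchitectureSpec("MLAMP", "mlamp", None, "random_forest"),
        ArchitectureSpec("SVM-LZ", "lz_profile", None, "svm",
                         extractor_params={"size": lz_reference_size}),
    ]
    if include_deep:
        specs += [ArchitectureSpec("AMPScannerV2", "embedding", None, "dnn"),
                  ArchitectureSpec("Deep-AmPEP30", "psekraac", None, "cnn")]
    return specs


def spec_by_name(name: str, **kwargs) -> ArchitectureSpec:
    for spec in registry(include_deep=True, **kwargs):
        if spec.name == name:
            return spec
    raise KeyError(f"unknown architecture {name!r}")


# ---------------------------------------------------------------------------
# feature extraction plumbing
# ---------------------------------------------------------------------------

_DENSE_EXTRACTORS: Dict[str, Callable] = {
    "aac": lambda s, p: F.aac(s).values,
    "ampep_subset": lambda s, p: F.ampep_subset(s).values,
    "ctd_distribution": lambda s, p: F.ctd_distribution(s).values,
    "ampir": lambda s, p: F.ampir_features(s).values,
    "cs_amppred": lambda s, p: F.cs_amppred_features(s).values,
    "pseaac": lambda s, p: F.pseaac(s, **p).values,
    "macrel": lambda s, p: F.macrel_features(s).values,
    "mlamp": lambda s, p: F.mlamp_features(s).values,
}


def extract_matrix(extractor: str, seqs: Sequence[str], params: dict,
                   state: Optional[dict] = None):
    """Feature matrix for a list of peptides.

    For training-dependent extractors (n-gram vocabulary, LZ reference
    panel) the fitted state must be supplied.
    """
    if extractor in _DENSE_EXTRACTORS:
        fn = _DENSE_EXTRACTORS[extractor]
        return np.vstack([fn(s, params) for s in seqs])
    if extractor == "ngram":
        return F.ngram_matrix(seqs, state["vocabulary"])
    if extractor == "lz_profile":
        ref: F.LZReferenceSet = state["reference"]
        return np.vstack([ref.profile(s).values for s in seqs])
    raise ValueError(f"unknown or untrainable extractor {extractor!r}")


# ---------------------------------------------------------------------------
# fuzzy k-nearest neighbours
# ---------------------------------------------------------------------------

def fknn_classify(query_features: np.ndarray, train_features: np.ndarray,
                  train_labels: np.ndarray, k: int = 5,
                  m: float = 2.0) -> np.ndarray:
    """Fuzzy k-NN membership in the positive class.

    u(q) = sum_j y_j d_j^(-2/(m-1)) / sum_j d_j^(-2/(m-1)) over the k nearest
    training points (Euclidean), with an exact-match short-circuit.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(train_features):
        raise ValueError("k exceeds training-set size")
    if m <= 1:
        raise ValueError("m must exceed 1")
    Q = np.atleast_2d(np.asarray(query_features, dtype=float))
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=float)
    out = np.empty(len(Q))
    d2 = ((Q[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    for i in range(len(Q)):
        idx = np.argpartition(d2[i], k - 1)[:k]
        d = np.sqrt(d2[i][idx])
        if np.any(d == 0.0):
            out[i] = y[idx][d == 0.0][0]
            continue
        w = d ** (-2.0 / (m - 1.0))
        out[i] = float((w * y[idx]).sum() / w.sum())
    return out if len(out) > 1 else out


class _FknnModel:
    """Fuzzy k-NN with an indexed neighbour search (same definition as
    :func:`fknn_classify`, vectorized for large query sets)."""

    def __init__(self, k: int, m: float):
        self.k, self.m = k, m

    def fit(self, X, y):
        from sklearn.neighbors import NearestNeighbors

        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=float)
        self.nn_ = NearestNeighbors(n_neighbors=self.k).fit(self.X_)
        return self

    def predict_scores(self, X):
        X = np.asarray(X, dtype=float)
        d, idx = self.nn_.kneighbors(X)
        y = self.y_[idx]
        exact = d[:, 0] == 0.0
        with np.errstate(divide="ignore"):
            w = d ** (-2.0 / (self.m - 1.0))
        w[~np.isfinite(w)] = 0.0
        out = np.where(w.sum(axis=1) > 0,
                       (w * y).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300),
                       0.0)
        out[exact] = y[exact, 0]
        return out


class _PlattSvm:
    """SVM with a sigmoid score calibration fitted on training data."""

    def __init__(self, kernel: str, C: float, seed: int):
        if kernel == "linear":
            self.svm = LinearSVC(C=C, random_state=seed, dual="auto",
                                 max_iter=20000)
        else:
            self.svm = SVC(kernel=kernel, C=C, gamma="auto",
                           random_state=seed)
        self.platt = LogisticRegression(random_state=seed)

    def fit(self, X, y):
        self.svm.fit(X, y)
        d = self.svm.decision_function(X).reshape(-1, 1)
        if len(np.unique(y)) < 2:
            raise ValueError("one-class training input")
        self.platt.fit(d, y)
        return self

    def predict_scores(self, X):
        d = self.svm.decision_function(X).reshape(-1, 1)
        return self.platt.predict_proba(d)[:, 1]


class _RfModel:
    def __init__(self, n_estimators: int, seed: int):
        self.rf = RandomForestClassifier(n_estimators=n_estimators,
                                         random_state=seed, n_jobs=1)

    def fit(self, X, y):
        self.rf.fit(X, y)
        return self

    def predict_scores(self, X):
        return self.rf.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# trained model
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted architecture instance with its training fingerprint."""

    spec: ArchitectureSpec
    classifier: object
    extractor_state: Optional[dict]
    scaler: Optional[StandardScaler]
    selector_state: Optional[dict]
    fingerprint: str

    def transform(self, seqs: Sequence[str]):
        X = extract_matrix(self.spec.extractor, seqs,
                           self.spec.extractor_params, self.extractor_state)
        if self.selector_state is not None:
            kind = self.selector_state["kind"]
            if kind == "QuiPT":
                X = X[:, self.selector_state["columns"]]
                if issparse(X):
                    X = np.asarray(X.todense())
            elif kind == "PCA":
                X = self.selector_state["pca"].transform(X)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X


def _data_fingerprint(pos: Sequence[str], neg: Sequence[str],
                      spec: ArchitectureSpec) -> str:
    h = hashlib.sha256()
    h.update(repr((spec.name, spec.seed, spec.classifier_params,
                   spec.extractor_params)).encode())
    for s in pos:
        h.update(b"+" + s.encode())
    for s in neg:
        h.update(b"-" + s.encode())
    return h.hexdigest()[:16]


def train(spec: ArchitectureSpec, pos_train: Sequence[SequenceRecord],
          neg_train: Sequence[SequenceRecord],
          quipt_alpha: float = 0.05, quipt_max_features: int = 5000,
          pca_variance: float = 0.95) -> TrainedModel:
    """Train one model: extract features, fit selector (training data only),
    fit the classifier with the spec seed.

    QuiPT keeps n-gram columns significant after Benjamini-Hochberg at
    `quipt_alpha`, capped at `quipt_max_features` by ascending p-value.
    """
    if spec.name in DEEP_ARCHITECTURES:
        raise NotImplementedError(
            f"{spec.name} is a deep-learning architecture outside the "
            f"trainable desk-scale roster")
    if not pos_train or not neg_train:
        raise ValueError("both classes must be non-empty")
    pos_seqs = [r.residues for r in pos_train]
    neg_seqs = [r.residues for r in neg_train]
    y = np.concatenate([np.ones(len(pos_seqs)), np.zeros(len(neg_seqs))])

    state: Optional[dict] = None
    if spec.extractor == "ngram":
        state = {"vocabulary": F.build_ngram_vocabulary(pos_seqs + neg_seqs)}
    elif spec.extractor == "lz_profile":
        size = spec.extractor_params.get("size", 1000)
        state = {"reference": F.build_lz_reference(pos_seqs, neg_seqs,
                                                   size=size,
                                                   seed=spec.seed)}
    X = extract_matrix(spec.extractor, pos_seqs + neg_seqs,
                       spec.extractor_params
                       if spec.extractor != "lz_profile" else {}, state)

    selector_state = None
    if spec.selector == "QuiPT":
        pvals = F.quipt_pvalues(X, y.astype(int))
        keep = _benjamini_hochberg(pvals, quipt_alpha)
        cols = np.flatnonzero(keep)
        if len(cols) == 0:
            cols = np.argsort(pvals)[:50]  # degenerate fallback
        if len(cols) > quipt_max_features:
            cols = cols[np.argsort(pvals[cols], kind="stable")
                        [:quipt_max_features]]
            cols = np.sort(cols)
        selector_state = {"kind": "QuiPT", "columns": cols}
        X = X[:, cols]
        if issparse(X):
            X = np.asarray(X.todense())
    elif spec.selector == "PCA":
        n_comp = _pca_components(np.asarray(X, dtype=float), pca_variance)
        pca, X = F.pca_transform(X, n_comp)
        selector_state = {"kind": "PCA", "pca": pca}

    scaler = None
    if spec.classifier in ("svm", "fknn"):
        scaler = StandardScaler(with_mean=not issparse(X))
        X = scaler.fit_transform(X)

    if spec.classifier == "random_forest":
        clf = _RfModel(spec.classifier_params.get("n_estimators", 200),
                       spec.seed)
    elif spec.classifier == "svm":
        clf = _PlattSvm(spec.classifier_params.get("kernel", "rbf"),
                        spec.classifier_params.get("C", 1.0), spec.seed)
    elif spec.classifier == "fknn":
        clf = _FknnModel(spec.classifier_params.get("k", 5),
                         spec.classifier_params.get("m", 2.0))
    else:
        raise ValueError(f"unknown classifier {spec.classifier!r}")
    clf.fit(X, y)

    return TrainedModel(spec=spec, classifier=clf, extractor_state=state,
                        scaler=scaler, selector_state=selector_state,
                        fingerprint=_data_fingerprint(pos_seqs, neg_seqs,
                                                      spec))


def _benjamini_hochberg(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean mask of discoveries under BH at level alpha."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    thresholds = alpha * (np.arange(1, m + 1)) / m
    passed = pvals[order] <= thresholds
    keep = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        keep[order[:k + 1]] = True
    return keep


def _pca_components(X: np.ndarray, variance: float) -> int:
    """Smallest component count explaining `variance` of training variance."""
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    ratios = np.cumsum(s ** 2) / np.sum(s ** 2)
    return int(np.searchsorted(ratios, variance - 1e-12) + 1)


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (opaque binary blob) with a text manifest
    (spec, seed, training fingerprint) alongside it."""
    import json
    import pickle
    from pathlib import Path

    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    manifest = {"architecture": model.spec.name, "seed": model.spec.seed,
                "extractor": model.spec.extractor,
                "selector": model.spec.selector,
                "classifier": model.spec.classifier,
                "training_fingerprint": model.fingerprint}
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> TrainedModel:
    import pickle

    with open(path, "rb") as fh:
        return pickle.load(fh)


def predict_scores(model: TrainedModel,
                   peptides: Sequence) -> np.ndarray:
    """AMP-likeness scores in [0, 1]; higher = more AMP-like."""
    seqs = [p.residues if isinstance(p, SequenceRecord) else p
            for p in peptides]
    if not seqs:
        return np.empty(0)
    X = model.transform(seqs)
    scores = model.classifier.predict_scores(X)
    return np.clip(scores, 0.0, 1.0)
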