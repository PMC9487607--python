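"""Feature extraction for the classical AMP-prediction architectures.

Every extractor is a pure deterministic function from a peptide (residues
over the 20-letter alphabet) to a fixed-length numeric vector.  The module
also houses the two feature-selection tools the architectures use: QuiPT
(an exact permutation test on binary features, computed by hypergeometric
enumeration of 2x2 contingency tables) and train-fitted PCA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from numba import njit
from scipy.sparse import csr_matrix
from scipy.special import xlogy
from scipy.stats import hypergeom
from sklearn.decomposition import PCA

from . import scales
from .seqdata import AMINO_ACIDS, AA_INDEX


@dataclass
class FeatureVector:
    """An ordered numeric vector with feature labels."""

    values: np.ndarray
    names: List[str]
    scheme: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values/names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.scheme}: non-finite feature values")

    def __len__(self) -> int:
        return len(self.values)


def _check_peptide(residues: str) -> str:
    if not residues:
        raise ValueError("empty peptide")
    residues = residues.upper()
    bad = set(residues) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}")
    return residues


# ---------------------------------------------------------------------------
# composition-style descriptors
# ---------------------------------------------------------------------------

def aac(residues: str) -> FeatureVector:
    """Amino-acid composition: the 20 residue frequencies (sums to 1)."""
    residues = _check_peptide(residues)
    counts = np.zeros(20)
    for a in residues:
        counts[AA_INDEX[a]] += 1
    return FeatureVector(counts / len(residues),
                         [f"aac_{a}" for a in AMINO_ACIDS], "aac")


_DEFAULT_PSE_SCALES = (scales.EISENBERG, scales.HOPP_WOODS,
                       scales.SIDE_CHAIN_MASS)


def _standardized(scale: scales.PropertyScale) -> np.ndarray:
    v = np.array([scale[a] for a in AMINO_ACIDS])
    return (v - v.mean()) / v.std()


def pseaac(residues: str, lam: int = 20, weight: float = 0.05,
           property_scales: Sequence[scales.PropertyScale]
           = _DEFAULT_PSE_SCALES, clip_lam: bool = False) -> FeatureVector:
    """Chou's pseudo-amino-acid composition (type 1), length 20 + lam.

    The first 20 entries are the residue frequencies and the last `lam` are
    weighted sequence-order correlation factors over the configured
    standardized property scales; all entries share the 1/(1 + w * sum(theta))
    normalization.

    Peptides must be longer than `lam`; with ``clip_lam=True`` shorter
    peptides are allowed and correlation factors beyond the available
    sequence span are zero (keeps the dimension contract for rosters whose
    data contain very short peptides).
    """
    residues = _check_peptide(residues)
    L = len(residues)
    if L <= lam and not clip_lam:
        raise ValueError(f"peptide length {L} must exceed lam={lam}")
    if L < 2:
        raise ValueError("peptide too short for sequence-order factors")
    mats = np.stack([_standardized(s) for s in property_scales])
    idx = np.array([AA_INDEX[a] for a in residues])
    props = mats[:, idx]  # (n_scales, L)
    thetas = np.zeros(lam)
    for j in range(1, min(lam, L - 1) + 1):
        diff = props[:, j:] - props[:, :-j]
        thetas[j - 1] = np.mean(diff ** 2)
    freqs = aac(residues).values
    denom = 1.0 + weight * thetas.sum()
    values = np.concatenate([freqs, weight * thetas]) / denom
    names = ([f"pse_{a}" for a in AMINO_ACIDS] +
             [f"theta_{j}" for j in range(1, lam + 1)])
    return FeatureVector(values, names, f"pseaac{lam}")


def _class_positions(residues: str, group: str) -> List[int]:
    gset = set(group)
    return [i + 1 for i, a in enumerate(residues) if a in gset]  # 1-based


def _distribution_descriptors(positions: List[int], L: int) -> List[float]:
    """first / 25% / 50% / 75% / 100% relative positions (0s if absent)."""
    if not positions:
        return [0.0] * 5
    m = len(positions)
    out = [positions[0] / L]
    for q in (0.25, 0.5, 0.75, 1.0):
        k = max(1, math.ceil(q * m))
        out.append(positions[k - 1] / L)
    return out


def ctd_distribution(residues: str) -> FeatureVector:
    """CTD distribution descriptors: 7 attributes x 3 classes x 5 = 105."""
    residues = _check_peptide(residues)
    L = len(residues)
    values: List[float] = []
    names: List[str] = []
    for attr, groups in scales.CTD_ATTRIBUTES:
        for ci, group in enumerate(groups, start=1):
            desc = _distribution_descriptors(
                _class_positions(residues, group), L)
            values.extend(desc)
            names.extend(f"{attr}_c{ci}_{tag}"
                         for tag in ("first", "q25", "q50", "q75", "q100"))
    return FeatureVector(np.array(values), names, "ctd_distribution")


#: Fixed 23-descriptor subset of the 105 CTD-distribution space used by the
#: reduced AmPEP-style architecture: all 15 hydrophobicity descriptors, the
#: 5 positive-charge-class descriptors, and the first/median/last positions
#: of the helix class.  A documented package constant (see docs/methods.md).
AMPEP_SUBSET_INDICES: Tuple[int, ...] = tuple(
    list(range(0, 15))                      # hydrophobicity classes 1-3
    + list(range(60, 65))                   # charge class 1 (K, R)
    + [75, 77, 79]                          # secondary-structure helix class
)


def ampep_subset(residues: str) -> FeatureVector:
    """The reduced 23-descriptor projection of :func:`ctd_distribution`."""
    full = ctd_distribution(residues)
    idx = list(AMPEP_SUBSET_INDICES)
    return FeatureVector(full.values[idx], [full.names[i] for i in idx],
                         "ampep_subset")


# ---------------------------------------------------------------------------
# global physicochemical panel
# ---------------------------------------------------------------------------

def net_charge(residues: str, pH: float = 7.0) -> float:
    """Peptide net charge by Henderson-Hasselbalch over ionizable groups."""
    residues = _check_peptide(residues)
    q = 1.0 / (1.0 + 10 ** (pH - scales.PKA_POSITIVE["nterm"]))
    q -= 1.0 / (1.0 + 10 ** (scales.PKA_NEGATIVE["cterm"] - pH))
    for a in residues:
        if a in scales.PKA_POSITIVE:
            q += 1.0 / (1.0 + 10 ** (pH - scales.PKA_POSITIVE[a]))
        elif a in scales.PKA_NEGATIVE:
            q -= 1.0 / (1.0 + 10 ** (scales.PKA_NEGATIVE[a] - pH))
    return q


def isoelectric_point(residues: str, tol: float = 1e-8) -> float:
    """pH at which the net charge vanishes (bisection on [0, 14])."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(residues, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobic_moment(residues: str, angle_deg: float = 100.0) -> float:
    """Eisenberg hydrophobic moment per residue (alpha-helical periodicity)."""
    residues = _check_peptide(residues)
    angles = np.deg2rad(angle_deg) * np.arange(len(residues))
    h = np.array([scales.EISENBERG[a] for a in residues])
    mx = float(np.sum(h * np.cos(angles)))
    my = float(np.sum(h * np.sin(angles)))
    return math.hypot(mx, my) / len(residues)


def physchem_panel(residues: str, pH: float = 7.0) -> Dict[str, float]:
    """Named global descriptors used by several architectures.

    Charge and pI follow Henderson-Hasselbalch with EMBOSS pKa values;
    hydrophobic moment is the Eisenberg vector sum at 100 degrees per
    residue; instability and molecular weight come from the standard
    ProtParam tables; propensities and flexibility are mean per-residue
    scale values.
    """
    residues = _check_peptide(residues)
    L = len(residues)
    q = net_charge(residues, pH)
    h_mean = scales.EISENBERG.mean_over(residues)
    mu_h = hydrophobic_moment(residues)
    abs_h = sum(abs(scales.EISENBERG[a]) for a in residues) / L
    pa = ProteinAnalysis(residues)
    counts = {a: residues.count(a) for a in "AVIL"}
    aliphatic = 100.0 * (counts["A"] + 2.9 * counts["V"]
                         + 3.9 * (counts["I"] + counts["L"])) / L
    return {
        "net_charge": q,
        "isoelectric_point": isoelectric_point(residues),
        "hydrophobicity_mean": h_mean,
        "hydrophobic_moment": mu_h,
        "instability_index": pa.instability_index() if L >= 2 else 0.0,
        "aliphatic_index": aliphatic,
        "boman_index": -scales.BOMAN_TRANSFER.mean_over(residues),
        "amphipathicity": mu_h / abs_h if abs_h > 0 else 0.0,
        "flexibility": scales.VIHINEN_FLEXIBILITY.mean_over(residues),
        "alpha_propensity": scales.CHOU_FASMAN_ALPHA.mean_over(residues),
        "beta_propensity": scales.CHOU_FASMAN_BETA.mean_over(residues),
        "loop_propensity": scales.CHOU_FASMAN_TURN.mean_over(residues),
        "molecular_weight": pa.molecular_weight(),
        "solubility_flag": 1.0 if (abs(q) >= 1.0 or h_mean < 0.0) else 0.0,
    }


_CS_AMPPRED_KEYS = ("alpha_propensity", "beta_propensity", "loop_propensity",
                    "net_charge", "hydrophobicity_mean", "flexibility",
                    "amphipathicity", "hydrophobic_moment")


def cs_amppred_features(residues: str) -> FeatureVector:
    """Nine structural/physicochemical scalars (helix scale + panel)."""
    residues = _check_peptide(residues)
    panel = physchem_panel(residues)
    values = [scales.LEVITT_ALPHA.mean_over(residues)]
    names = ["alpha_helix_levitt"]
    for key in _CS_AMPPRED_KEYS:
        values.append(panel[key])
        names.append(key)
    return FeatureVector(np.array(values), names, "cs_amppred")


def _first_occurrence(residues: str, group: str) -> float:
    gset = set(group)
    for i, a in enumerate(residues):
        if a in gset:
            return (i + 1) / len(residues)
    return 0.0


_MACREL_GLOBAL_KEYS = ("net_charge", "isoelectric_point", "solubility_flag",
                       "instability_index", "aliphatic_index", "boman_index",
                       "hydrophobic_moment", "hydrophobicity_mean",
                       "amphipathicity", "molecular_weight")


def macrel_features(residues: str) -> FeatureVector:
    """22 descriptors: first-occurrence and fraction for the free-energy-of-
    transition and solvent-accessibility 3-group alphabets, plus the global
    panel descriptors (charge, solubility, instability, aliphaticity,
    membrane-binding propensity, hydrophobicity, ...)."""
    residues = _check_peptide(residues)
    values: List[float] = []
    names: List[str] = []
    for tag, groups in (("fet", scales.FET_GROUPS), ("sa", scales.SA_GROUPS)):
        for gi, group in enumerate(groups, start=1):
            values.append(_first_occurrence(residues, group))
            names.append(f"{tag}_g{gi}_first")
    for tag, groups in (("fet", scales.FET_GROUPS), ("sa", scales.SA_GROUPS)):
        gsets = [set(g) for g in groups]
        for gi, gset in enumerate(gsets, start=1):
            frac = sum(1 for a in residues if a in gset) / len(residues)
            values.append(frac)
            names.append(f"{tag}_g{gi}_fraction")
    panel = physchem_panel(residues)
    for key in _MACREL_GLOBAL_KEYS:
        values.append(panel[key])
        names.append(key)
    return FeatureVector(np.array(values), names, "macrel")


_AMPIR_GLOBAL_KEYS = ("amphipathicity", "hydrophobicity_mean",
                      "isoelectric_point", "molecular_weight", "net_charge")


def ampir_features(residues: str) -> FeatureVector:
    """PseAAC (lam=2) plus five global descriptors -> 27 features."""
    pse = pseaac(residues, lam=2)
    panel = physchem_panel(residues)
    values = np.concatenate([pse.values,
                             [panel[k] for k in _AMPIR_GLOBAL_KEYS]])
    return FeatureVector(values, pse.names + list(_AMPIR_GLOBAL_KEYS),
                         "ampir")


# ---------------------------------------------------------------------------
# grey-model PseAAC (MLAMP style)
# ---------------------------------------------------------------------------

_MLAMP_SCALES = (scales.EISENBERG, scales.HOPP_WOODS, scales.SIDE_CHAIN_MASS,
                 scales.PK1_ALPHA_COOH, scales.PK2_ALPHA_NH3)


def _minmax_12(scale: scales.PropertyScale) -> Dict[str, float]:
    v = np.array([scale[a] for a in AMINO_ACIDS])
    lo, hi = v.min(), v.max()
    return {a: 1.0 + (scale[a] - lo) / (hi - lo) for a in AMINO_ACIDS}


def gm11_coefficients(series: Sequence[float]) -> Tuple[float, float]:
    """Least-squares GM(1,1) grey-model coefficients (a, b).

    Fits x0[k] = -a * z[k] + b where z is the mean-adjacent accumulated
    series; a constant series gives a = 0, b = the constant, exactly.
    """
    x0 = np.asarray(series, dtype=float)
    if x0.size < 4:
        raise ValueError("GM(1,1) needs at least 4 points")
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z, np.ones_like(z)])
    coef, *_ = np.linalg.lstsq(B, x0[1:], rcond=None)
    return float(coef[0]), float(coef[1])


def mlamp_features(residues: str) -> FeatureVector:
    """AAC plus GM(1,1) coefficients of 5 property series -> 30 features."""
    residues = _check_peptide(residues)
    if len(residues) < 4:
        raise ValueError("mlamp_features needs length >= 4")
    base = aac(residues)
    values = list(base.values)
    names = list(base.names)
    for scale in _MLAMP_SCALES:
        mapped = _minmax_12(scale)
        a, b = gm11_coefficients([mapped[r] for r in residues])
        values.extend([a, b])
        names.extend([f"gm_a_{scale.name}", f"gm_b_{scale.name}"])
    return FeatureVector(np.array(values), names, "mlamp")


# ---------------------------------------------------------------------------
# n-grams + QuiPT
# ---------------------------------------------------------------------------

def _seq_ngrams(seq: str) -> Iterable[str]:
    """Contiguous 1-/2-/3-grams and single-gap 2-/3-grams of a peptide."""
    L = len(seq)
    for i in range(L):
        yield seq[i]
    for i in range(L - 1):
        yield seq[i:i + 2]
    for i in range(L - 2):
        yield seq[i:i + 3]
        yield seq[i] + "_" + seq[i + 2]            # gapped 2-gram
    for i in range(L - 3):
        yield seq[i] + "_" + seq[i + 2:i + 4]      # a_bc
        yield seq[i:i + 2] + "_" + seq[i + 3]      # ab_c
    return


def build_ngram_vocabulary(seqs: Iterable[str]) -> Dict[str, int]:
    """All n-grams observed in the training sequences, sorted for
    determinism, mapped to column indices."""
    vocab = set()
    for s in seqs:
        vocab.update(_seq_ngrams(s))
    return {g: i for i, g in enumerate(sorted(vocab))}


def ngram_features(residues: str, vocabulary: Dict[str, int]) -> csr_matrix:
    """Binary presence/absence row vector over the vocabulary (sparse)."""
    cols = sorted({vocabulary[g] for g in set(_seq_ngrams(residues))
                   if g in vocabulary})
    data = np.ones(len(cols))
    return csr_matrix((data, (np.zeros(len(cols), dtype=int), cols)),
                      shape=(1, len(vocabulary)))


def ngram_matrix(seqs: Sequence[str], vocabulary: Dict[str, int]
                 ) -> csr_matrix:
    indptr = [0]
    indices: List[int] = []
    for s in seqs:
        cols = sorted({vocabulary[g] for g in set(_seq_ngrams(s))
                       if g in vocabulary})
        indices.extend(cols)
        indptr.append(len(indices))
    data = np.ones(len(indices))
    return csr_matrix((data, indices, indptr),
                      shape=(len(seqs), len(vocabulary)))


def _information_gain(a: np.ndarray, n: int, n1: int, k: int) -> np.ndarray:
    """IG (natural log) of the 2x2 tables with cell a = #(x=1, y=1)."""
    a = np.asarray(a, dtype=float)
    b = k - a            # x=1, y=0
    c = n1 - a           # x=0, y=1
    d = n - n1 - k + a   # x=0, y=0

    def entropy(p1, p0):
        tot = p1 + p0
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -(xlogy(p1, p1 / tot) + xlogy(p0, p0 / tot)) / tot
        return np.where(tot > 0, h, 0.0)

    h_y = entropy(np.array(float(n1)), np.array(float(n - n1)))
    cond = (k / n) * entropy(a, b) + ((n - k) / n) * entropy(c, d)
    return h_y - cond


def quipt(feature_column: Sequence[int], target: Sequence[int]) -> float:
    """Quick Permutation Test: exact permutation p-value of the
    information-gain statistic for a binary feature against a binary label.

    Because IG depends only on the 2x2 contingency table, the permutation
    null collapses to the hypergeometric distribution over tables with the
    observed margins; the p-value sums the probabilities of tables with
    IG >= observed (ties included).
    """
    x = np.asarray(feature_column, dtype=int)
    y = np.asarray(target, dtype=int)
    if x.shape != y.shape:
        raise ValueError("feature and target must have equal length")
    if set(np.unique(x)) - {0, 1} or set(np.unique(y)) - {0, 1}:
        raise ValueError("both columns must be binary")
    n = x.size
    n1 = int(y.sum())
    k = int(x.sum())
    if k in (0, n) or n1 in (0, n):
        return 1.0  # degenerate column: nothing to permute
    a_obs = int(np.sum((x == 1) & (y == 1)))
    a_lo = max(0, k - (n - n1))
    a_hi = min(k, n1)
    a_range = np.arange(a_lo, a_hi + 1)
    pmf = hypergeom.pmf(a_range, n, n1, k)
    ig = _information_gain(a_range, n, n1, k)
    ig_obs = float(_information_gain(np.array([a_obs]), n, n1, k)[0])
    return float(min(1.0, pmf[ig >= ig_obs - 1e-12].sum()))


def quipt_pvalues(X: csr_matrix, target: Sequence[int]) -> np.ndarray:
    """Vectorized QuiPT over the columns of a sparse binary matrix."""
    y = np.asarray(target, dtype=int)
    n = y.size
    n1 = int(y.sum())
    Xc = X.tocsc()
    ks = np.asarray(Xc.sum(axis=0)).ravel().astype(int)
    a_obs = np.asarray(Xc[y == 1].sum(axis=0)).ravel().astype(int)
    pvals = np.ones(X.shape[1])
    if n1 in (0, n):
        return pvals
    cache: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for j in range(X.shape[1]):
        k = ks[j]
        if k in (0, n):
            continue
        if k not in cache:
            a_lo = max(0, k - (n - n1))
            a_hi = min(k, n1)
            a_range = np.arange(a_lo, a_hi + 1)
            pmf = hypergeom.pmf(a_range, n, n1, k)
            ig = _information_gain(a_range, n, n1, k)
            order = np.argsort(-ig)
            cache[k] = (ig[order], np.cumsum(pmf[order]), a_range[order])
        ig_sorted, cum, a_sorted = cache[k]
        ig_obs = float(_information_gain(np.array([a_obs[j]]), n, n1, k)[0])
        m = ig_sorted >= ig_obs - 1e-12
        pvals[j] = cum[m.sum() - 1] if m.any() else 0.0
    return np.minimum(pvals, 1.0)


# ---------------------------------------------------------------------------
# LZ76 complexity profile
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lz76_count(s: np.ndarray) -> int:
    """Number of phrases in the exhaustive Lempel-Ziv (1976) history."""
    n = s.size
    if n == 0:
        return 0
    c = 1
    l = 1
    i = 0
    k = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lz76_complexity(seq: str) -> int:
    """LZ76 phrase-count complexity of a sequence."""
    return int(_lz76_count(np.frombuffer(seq.encode(), dtype=np.uint8)))


def lz_similarity(a: str, b: str) -> float:
    """Normalized LZ76 similarity s = 1 - (C(ab) - min(Ca, Cb)) / max(...)."""
    ca, cb = lz76_complexity(a), lz76_complexity(b)
    cab = lz76_complexity(a + b)
    return 1.0 - (cab - min(ca, cb)) / max(ca, cb)


class LZReferenceSet:
    """A fixed reference panel for LZ-complexity similarity profiles.

    At training time the panel is drawn from the training data (half
    positives, half negatives); the profile of a query is its similarity to
    every reference sequence.
    """

    def __init__(self, sequences: Sequence[str]):
        if not sequences:
            raise ValueError("empty reference set")
        self.sequences = list(sequences)
        self._complexities = [lz76_complexity(s) for s in self.sequences]

    @property
    def size(self) -> int:
        return len(self.sequences)

    def profile(self, residues: str) -> FeatureVector:
        residues = _check_peptide(residues)
        cx = lz76_complexity(residues)
        values = np.empty(self.size)
        for i, (r, cr) in enumerate(zip(self.sequences, self._complexities)):
            cab = lz76_complexity(residues + r)
            values[i] = 1.0 - (cab - min(cx, cr)) / max(cx, cr)
        return FeatureVector(values,
                             [f"lz_ref_{i}" for i in range(self.size)],
                             "lz_profile")


def build_lz_reference(pos_seqs: Sequence[str], neg_seqs: Sequence[str],
                       size: int = 1000, seed: int = 0) -> LZReferenceSet:
    """Draw a balanced reference panel (size/2 positives, size/2 negatives)."""
    rng = np.random.default_rng(seed)
    half = size // 2
    if len(pos_seqs) < half or len(neg_seqs) < size - half:
        raise ValueError(f"need >= {half} sequences per class for a "
                         f"reference panel of {size}")
    pi = rng.choice(len(pos_seqs), size=half, replace=False)
    ni = rng.choice(len(neg_seqs), size=size - half, replace=False)
    return LZReferenceSet([pos_seqs[i] for i in pi] +
                          [neg_seqs[i] for i in ni])


def lz_similarity_profile(residues: str,
                          reference_set: LZReferenceSet,
                          expected_size: int = 1000) -> FeatureVector:
    """Similarity profile against a fixed reference panel.

    Raises if the panel size differs from the configured `expected_size`.
    """
    if reference_set.size != expected_size:
        raise ValueError(f"reference set has {reference_set.size} sequences, "
                         f"expected {expected_size}")
    return reference_set.profile(residues)


def write_sparse_triplets(matrix: csr_matrix, path, names=None) -> None:
    """Persist a sparse binary feature matrix as text coordinate triplets
    (row, column, value) with an optional feature-name header block."""
    coo = matrix.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# shape\t{matrix.shape[0]}\t{matrix.shape[1]}\n")
        if names is not None:
            fh.write("# columns\t" + "\t".join(names) + "\n")
        fh.write("row\tcol\tvalue\n")
        for r, c, v in sorted(zip(coo.row, coo.col, coo.data)):
            fh.write(f"{r}\t{c}\t{v:g}\n")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_transform(train_matrix: np.ndarray, n_components: int
                  ) -> Tuple[PCA, np.ndarray]:
    """Centred PCA fitted on training features only.

    Returns the fitted projection (use ``projection.transform`` for
    benchmark data, so no benchmark information leaks into the fit) and the
    projected training matrix.
    """
    X = np.asarray(train_matrix, dtype=float)
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds feature count")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("constant feature matrix")
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca, pca.fit_transform(X)
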