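"""Seeded synthetic positive sets and an annotated negative-source database.

The generator emulates the two inputs a negative-sampling study needs:

* a positive set of short, cationic/hydrophobic AMP-like peptides
  (length median ~18, maximum 190), and
* a broad UniProt-like background of annotated records with function
  keywords (antimicrobial, secreted, transmembrane, toxin, ...),
  subcellular-localization terms and a wide log-normal length spread.

Composition is the synthetic ground truth: background records carry the
database-average residue frequencies, modulated by their annotations
(transmembrane records are aliphatic-rich, secreted/toxin records
cysteine-rich), and a configurable fraction of records annotated
``antimicrobial`` are planted with positive-style composition.  These
annotation-linked composition shifts are what make the different
negative-sampling rules produce statistically different samples, which is
the structure the downstream bias analysis probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import yaml

from .seqdata import AMINO_ACIDS, AA_INDEX, SequenceRecord

# UniProtKB-average amino-acid frequencies (percent, alphabetical order),
# long-run database statistics.
_UNIPROT_AVG = {
    "A": 8.25, "C": 1.38, "D": 5.45, "E": 6.75, "F": 3.86, "G": 7.07,
    "H": 2.27, "I": 5.96, "K": 5.84, "L": 9.66, "M": 2.42, "N": 4.06,
    "P": 4.70, "Q": 3.93, "R": 5.53, "S": 6.56, "T": 5.34, "V": 6.87,
    "W": 1.08, "Y": 2.92,
}

# AMP-like composition: enriched in K/R (cationic) and L/I/F/W (hydrophobic).
_AMP_COMP = {
    "A": 6.5, "C": 3.0, "D": 1.5, "E": 1.5, "F": 6.0, "G": 9.0,
    "H": 2.0, "I": 7.0, "K": 13.5, "L": 13.0, "M": 1.5, "N": 2.5,
    "P": 4.0, "Q": 2.0, "R": 7.5, "S": 4.5, "T": 3.5, "V": 5.5,
    "W": 3.0, "Y": 2.5,
}

# Multiplicative composition modifiers keyed by annotation term; applied to
# the background vector then renormalized.
_COMP_MODIFIERS: Dict[str, Dict[str, float]] = {
    "transmembrane": {"L": 2.0, "I": 1.9, "V": 1.7, "F": 1.8, "A": 1.3,
                      "K": 0.5, "R": 0.5, "D": 0.45, "E": 0.45},
    "secreted": {"C": 4.0, "G": 1.25, "S": 1.2, "E": 0.8},
    "toxin": {"C": 3.5, "K": 1.5},
}


def _vector(freqs: Dict[str, float]) -> np.ndarray:
    v = np.array([freqs[aa] for aa in AMINO_ACIDS], dtype=float)
    return v / v.sum()


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic positive set and background database.

    Length laws are dictionaries: the positive law is a shifted negative
    binomial (``shift + NB(r, p)``, truncated to ``[min, max]``) whose
    defaults put the median near 18 residues; the background law is a
    discretized log-normal spanning short peptides to ~2000-residue proteins.
    """

    n_positive: int = 1200
    n_background: int = 60000
    positive_length_law: dict = field(default_factory=lambda: {
        "kind": "shifted_negbinom", "r": 3.0, "p": 1.0 / 6.0,
        "shift": 5, "min": 5, "max": 190})
    background_length_law: dict = field(default_factory=lambda: {
        "kind": "lognormal", "mu": 5.63, "sigma": 1.1, "min": 5, "max": 2000})
    positive_composition: list = field(
        default_factory=lambda: _vector(_AMP_COMP).tolist())
    background_composition: list = field(
        default_factory=lambda: _vector(_UNIPROT_AVG).tolist())
    keyword_prevalence: dict = field(default_factory=lambda: {
        "antimicrobial": 0.012, "antibiotic": 0.008, "antibacterial": 0.008,
        "antiviral": 0.006, "fungicide": 0.004, "defensin": 0.003,
        "bacteriocin": 0.002, "defence": 0.005, "toxin": 0.015,
        "secreted": 0.15, "transmembrane": 0.25, "transit peptide": 0.08})
    localization_prevalence: dict = field(default_factory=lambda: {
        "cytoplasm": 0.40, "secreted": 0.15, "mitochondria": 0.12,
        "endoplasmic reticulum": 0.06, "golgi": 0.04})
    #: fraction of antimicrobial-keyword records planted with AMP-like
    #: composition (mislabel-like true AMPs hiding in the background).
    amp_like_fraction: float = 0.5
    #: odds ratio linking the "secreted" keyword to "antimicrobial".
    secreted_antimicrobial_or: float = 4.0
    seed: int = 20_06

    def __post_init__(self) -> None:
        for name in ("positive_composition", "background_composition"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (20,) or (v < 0).any():
                raise ValueError(f"{name} must be a non-negative 20-vector")
            if v.sum() <= 0:
                raise ValueError(f"{name} is degenerate (zero vector)")
            if abs(v.sum() - 1.0) > 1e-9:
                v = v / v.sum()
            setattr(self, name, v.tolist())
        for m in (self.keyword_prevalence, self.localization_prevalence):
            for term, p in m.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence of {term!r} outside [0,1]")

    # -- serialization ------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _draw_lengths(law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law["kind"]
    lo, hi = int(law.get("min", 1)), int(law.get("max", 10**9))
    out = np.empty(n, dtype=int)
    filled = 0
    # rejection-sample the truncation so the law stays a clean parametric form
    while filled < n:
        m = max(2 * (n - filled), 16)
        if kind == "shifted_negbinom":
            x = law["shift"] + rng.negative_binomial(law["r"], law["p"], m)
        elif kind == "lognormal":
            x = np.rint(rng.lognormal(law["mu"], law["sigma"], m)).astype(int)
        else:
            raise ValueError(f"unknown length law {kind!r}")
        x = x[(x >= lo) & (x <= hi)]
        take = min(len(x), n - filled)
        out[filled:filled + take] = x[:take]
        filled += take
    return out


def _draw_sequences(lengths: np.ndarray, comp: np.ndarray,
                    rng: np.random.Generator) -> List[str]:
    """Draw i.i.d. residues for every length in one vectorized pass."""
    if comp.sum() <= 0:
        raise ValueError("degenerate composition (zero vector)")
    total = int(lengths.sum())
    letters = rng.choice(20, size=total, p=comp / comp.sum())
    arr = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)[letters]
    seqs, pos = [], 0
    for L in lengths:
        seqs.append(arr[pos:pos + L].tobytes().decode())
        pos += L
    return seqs


def generate_positives(config: SyntheticConfig) -> List[SequenceRecord]:
    """Generate the synthetic AMP-like positive set (deterministic per seed)."""
    if config.n_positive < 1:
        raise ValueError("n_positive must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lengths = _draw_lengths(config.positive_length_law, config.n_positive, rng)
    comp = np.asarray(config.positive_composition)
    seqs = _draw_sequences(lengths, comp, rng)
    return [SequenceRecord(id=f"pos{i:06d}", residues=s, source="positive")
            for i, s in enumerate(seqs)]


def generate_background(config: SyntheticConfig) -> List[SequenceRecord]:
    """Generate the annotated background (negative-source) database.

    Keywords and localizations are drawn per their prevalences, with two
    deliberate dependencies: the ``secreted`` keyword is positively
    associated with ``antimicrobial`` (configurable odds ratio) and with the
    ``secreted`` localization, so keyword screens change set composition the
    way they do on real data.  Records planted with AMP-like composition are
    flagged via :attr:`SequenceRecord.amp_like` as the held-out synthetic
    oracle.
    """
    if config.n_background < 1:
        raise ValueError("n_background must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_background
    lengths = _draw_lengths(config.background_length_law, n, rng)

    kw_prev = dict(config.keyword_prevalence)
    p_amp = kw_prev.pop("antimicrobial", 0.0)
    p_sec = kw_prev.pop("secreted", 0.0)
    has_amp = rng.random(n) < p_amp
    # secreted | antimicrobial follows the configured odds ratio
    odds = p_sec / (1.0 - p_sec) if p_sec < 1 else np.inf
    p_sec_amp = (config.secreted_antimicrobial_or * odds /
                 (1.0 + config.secreted_antimicrobial_or * odds))
    u = rng.random(n)
    has_sec = np.where(has_amp, u < p_sec_amp, u < p_sec)

    keyword_draws = {term: rng.random(n) < p for term, p in kw_prev.items()}
    keyword_draws["antimicrobial"] = has_amp
    keyword_draws["secreted"] = has_sec

    loc_prev = dict(config.localization_prevalence)
    p_loc_sec = loc_prev.pop("secreted", 0.0)
    loc_draws = {term: rng.random(n) < p for term, p in loc_prev.items()}
    u2 = rng.random(n)
    loc_draws["secreted"] = np.where(has_sec, u2 < 0.8, u2 < p_loc_sec)

    planted = has_amp & (rng.random(n) < config.amp_like_fraction)

    # group records by composition class so residues can be drawn in bulk
    base = np.asarray(config.background_composition)
    mod_terms = sorted(_COMP_MODIFIERS)
    active = {t: keyword_draws.get(t, np.zeros(n, bool)) for t in mod_terms}
    active["secreted"] = active["secreted"] | loc_draws["secreted"]
    class_key = planted.astype(int) * 8
    for bit, t in enumerate(mod_terms):
        class_key = class_key + active[t].astype(int) * (1 << bit)

    seqs: List[str] = [""] * n
    for key in np.unique(class_key):
        idx = np.flatnonzero(class_key == key)
        if key >= 8:
            comp = np.asarray(config.positive_composition)
        else:
            comp = base.copy()
            for bit, t in enumerate(mod_terms):
                if key & (1 << bit):
                    for aa, mult in _COMP_MODIFIERS[t].items():
                        comp[AA_INDEX[aa]] *= mult
            comp = comp / comp.sum()
        for i, s in zip(idx, _draw_sequences(lengths[idx], comp, rng)):
            seqs[i] = s

    records = []
    for i in range(n):
        kws = {t for t, flags in keyword_draws.items() if flags[i]}
        locs = {t for t, flags in loc_draws.items() if flags[i]}
        records.append(SequenceRecord(
            id=f"bg{i:06d}", residues=seqs[i], keywords=kws,
            localization=locs, source="negative_pool",
            amp_like=bool(planted[i])))
    return records
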