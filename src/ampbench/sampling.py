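"""The 11 negative-sampling methods as one configurable engine.

Each published AMP predictor built its non-AMP class from an annotated
protein database with its own rule set: keyword exclusions, length policies
(whole records in a range, or fragments matching the positive length
distribution), redundancy reduction, localization restrictions and ad-hoc
screens.  This module expresses each rule set as a declarative
:class:`SamplingSpec` and assembles replicated negative train/benchmark
samples with leakage prevention (coordinate-level train/bench disjointness,
no negative identical to any positive, deterministic seeding).

Sequence-identity clustering is a CD-HIT-style stand-in: greedy
longest-first clustering where identity is measured for the shorter
sequence against the best-matching region of the longer one (edlib infix
alignment), relative to the shorter sequence's length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .seqdata import PositiveSplit, SequenceRecord

#: Table-footnote screen: records carrying any of these are "potential AMPs".
POTENTIAL_AMP_KEYWORDS = frozenset(
    {"antimicrobial", "antibiotic", "defence", "defensin", "bacteriocin",
     "fungicide"})

# ---------------------------------------------------------------------------
# identity + clustering
# ---------------------------------------------------------------------------

def alignment_identity(a: str, b: str) -> float:
    """CD-HIT-style pairwise identity relative to the shorter sequence.

    The shorter sequence is aligned against the best-matching region of the
    longer one (banded/infix alignment, like CD-HIT's limited-gap band);
    identity = (shorter_length - edit_distance) / shorter_length.  A
    sequence contained in another therefore scores 1.0, and two sequences
    differing at one of ten positions score 0.9.
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    d = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    return max(0.0, (len(short) - d) / len(short))


def _identity_at_least(a: str, b: str, threshold: float) -> bool:
    """identity >= threshold, via edlib's banded search with cutoff k."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    m = len(short)
    if m == 0:
        return False
    k = int(np.floor((1.0 - threshold) * m + 1e-9))
    d = edlib.align(short, long_, mode="HW", task="distance",
                    k=k)["editDistance"]
    return d != -1


def _greedy_cluster(seqs: Sequence[str], threshold: float
                    ) -> Tuple[List[int], Dict[int, int]]:
    """Greedy longest-first clustering on raw sequences.

    Returns representative indices (in founding order) and the
    member -> representative assignment.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    reps: List[int] = []
    assign: Dict[int, int] = {}
    for i in order:
        for r in reps:
            if _identity_at_least(seqs[i], seqs[r], threshold):
                assign[i] = r
                break
        else:
            reps.append(i)
            assign[i] = i
    return reps, assign


def greedy_identity_cluster(records: Sequence[SequenceRecord],
                            threshold: float) -> List[SequenceRecord]:
    """CD-HIT-style redundancy reduction; returns cluster representatives."""
    reps, _ = _greedy_cluster([r.residues for r in records], threshold)
    return [records[i] for i in reps]


# ---------------------------------------------------------------------------
# declarative sampling specs (one per published method)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingSpec:
    """Declarative description of one negative-sampling method."""

    name: str
    excluded_keywords: frozenset
    length_policy: str  # "equal_to_positive" | "similar_to_positive" | "range"
    length_range: Optional[Tuple[int, int]] = None
    clustering_threshold: Optional[float] = None
    localization_whitelist: Optional[frozenset] = None
    cysteine_free_substrings: bool = False
    remove_potential_amps: bool = False
    amp_similarity_screen: bool = False
    balanced: bool = True
    imbalance_ratio: float = 1.0

    def __post_init__(self):
        if self.length_policy not in ("equal_to_positive",
                                      "similar_to_positive", "range"):
            raise ValueError(f"unknown length policy {self.length_policy!r}")
        if self.length_policy == "range":
            lo, hi = self.length_range
            if not 1 <= lo <= hi:
                raise ValueError(f"invalid length range {self.length_range}")

    @property
    def ratio(self) -> float:
        return 1.0 if self.balanced else self.imbalance_ratio

    def to_dict(self) -> dict:
        """Structured-text form mirroring the published summary table."""
        return {
            "name": self.name,
            "excluded_keywords": sorted(self.excluded_keywords),
            "length_policy": self.length_policy,
            "length_range": (list(self.length_range)
                             if self.length_range else None),
            "clustering_threshold": self.clustering_threshold,
            "localization_whitelist": (sorted(self.localization_whitelist)
                                       if self.localization_whitelist
                                       else None),
            "cysteine_free_substrings": self.cysteine_free_substrings,
            "remove_potential_amps": self.remove_potential_amps,
            "amp_similarity_screen": self.amp_similarity_screen,
            "balanced": self.balanced,
            "imbalance_ratio": self.imbalance_ratio,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SamplingSpec":
        data = dict(data)
        data["excluded_keywords"] = frozenset(data["excluded_keywords"])
        if data.get("length_range"):
            data["length_range"] = tuple(data["length_range"])
        if data.get("localization_whitelist"):
            data["localization_whitelist"] = frozenset(
                data["localization_whitelist"])
        return cls(**data)


def builtin_specs() -> List[SamplingSpec]:
    """The 11 published negative-sampling methods.

    Imbalance ratios for the unbalanced methods are package defaults chosen
    to match the qualitative descriptions (slightly / highly imbalanced,
    minority of non-AMPs); all are configurable via ``dataclasses.replace``.
    """
    kw = frozenset
    return [
        SamplingSpec("Wang", kw({"secreted", "antimicrobial"}),
                     "similar_to_positive", clustering_threshold=0.7,
                     balanced=False, imbalance_ratio=2.0),
        SamplingSpec("CS-AMPPred", kw({"antimicrobial"}), "range",
                     length_range=(16, 90), clustering_threshold=0.4,
                     balanced=True),
        SamplingSpec("iAMP-2L",
                     kw({"antimicrobial", "antibiotic", "fungicide",
                         "defensin"}),
                     "range", length_range=(5, 100), clustering_threshold=0.4,
                     balanced=False, imbalance_ratio=2.0),
        SamplingSpec("Gabere&Noble", kw({"antimicrobial"}),
                     "equal_to_positive",
                     localization_whitelist=kw({"golgi", "cytoplasm",
                                                "endoplasmic reticulum",
                                                "mitochondria"}),
                     balanced=False, imbalance_ratio=5.0),
        SamplingSpec("AMAP", kw({"antimicrobial"}), "similar_to_positive",
                     clustering_threshold=0.4, balanced=False,
                     imbalance_ratio=1.2),
        SamplingSpec("AMPScannerV2",
                     kw({"antimicrobial", "antibiotic", "antiviral",
                         "fungicide", "secreted"}),
                     "equal_to_positive",
                     localization_whitelist=kw({"cytoplasm"}),
                     amp_similarity_screen=True, balanced=True),
        SamplingSpec("dbAMP",
                     kw({"transmembrane", "toxin", "secreted", "defensin",
                         "antimicrobial", "antibiotic", "antiviral",
                         "fungicide"}),
                     "range", length_range=(10, 100),
                     clustering_threshold=0.4, balanced=False,
                     imbalance_ratio=1.2),
        SamplingSpec("Witten&Witten",
                     kw({"antimicrobial", "antibiotic", "antiviral",
                         "fungicide", "secreted"}),
                     "equal_to_positive", clustering_threshold=0.4,
                     localization_whitelist=kw({"cytoplasm"}),
                     cysteine_free_substrings=True, balanced=True),
        SamplingSpec("AmpGram",
                     kw({"antimicrobial", "antibacterial", "antiviral",
                         "fungicide", "secreted", "transit peptide"}),
                     "equal_to_positive", balanced=True),
        SamplingSpec("ampir-mature", kw({"antimicrobial"}), "range",
                     length_range=(10, 40), clustering_threshold=0.9,
                     balanced=False, imbalance_ratio=0.8),
        SamplingSpec("AMPlify",
                     kw({"antimicrobial", "antibiotic", "defence",
                         "defensin", "bacteriocin", "fungicide"}),
                     "equal_to_positive", remove_potential_amps=True,
                     balanced=True),
    ]


def spec_by_name(name: str) -> SamplingSpec:
    for spec in builtin_specs():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown sampling method {name!r}")


# ---------------------------------------------------------------------------
# filter operators
# ---------------------------------------------------------------------------

def filter_by_keywords(db: Iterable[SequenceRecord],
                       excluded: Iterable[str]) -> List[SequenceRecord]:
    """Retain records whose keyword set is disjoint from `excluded`."""
    excluded = {t.lower() for t in excluded}
    return [r for r in db if not (r.keywords & excluded)]


def filter_by_localization(db: Iterable[SequenceRecord],
                           whitelist: Iterable[str]) -> List[SequenceRecord]:
    """Retain records localized to at least one whitelisted compartment."""
    whitelist = {t.lower() for t in whitelist}
    if not whitelist:
        raise ValueError("localization whitelist must be non-empty")
    return [r for r in db if r.localization & whitelist]


def filter_by_length_range(db: Iterable[SequenceRecord], lo: int,
                           hi: int) -> List[SequenceRecord]:
    """Retain records with lo <= length <= hi (both inclusive)."""
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid range ({lo}, {hi})")
    return [r for r in db if lo <= len(r) <= hi]


def remove_potential_amps(db: Iterable[SequenceRecord]) -> List[SequenceRecord]:
    """Drop records annotated with any potential-AMP function keyword."""
    return [r for r in db if not (r.keywords & POTENTIAL_AMP_KEYWORDS)]


def cysteine_free_substrings(record: SequenceRecord, target_length: int,
                             rng) -> Optional[Tuple[int, int]]:
    """Uniformly pick a cysteine-free window of `target_length`, or None.

    Returns 0-based half-open (start, end) coordinates.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    starts = _cysteine_free_starts(record.residues, target_length)
    if not starts:
        return None
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    s = int(starts[int(rng.integers(len(starts)))])
    return s, s + target_length


def _cysteine_free_starts(seq: str, L: int) -> List[int]:
    n = len(seq)
    if L > n:
        return []
    bad = np.array([c == "C" for c in seq], dtype=int)
    window = np.convolve(bad, np.ones(L, dtype=int), mode="valid")
    return np.flatnonzero(window == 0).tolist()


def _kmer_set(seqs: Iterable[str], k: int) -> set:
    out = set()
    for s in seqs:
        for i in range(len(s) - k + 1):
            out.add(s[i:i + k])
    return out


def amp_similarity_screen(candidates: Sequence[SequenceRecord],
                          positives: Sequence[SequenceRecord],
                          k: int = 10) -> List[SequenceRecord]:
    """Remove candidates sharing an exact k-mer (or full match) with AMPs.

    Deterministic stand-in for a local-alignment (BLAT-style) screen.
    """
    kmers = _kmer_set((p.residues for p in positives), k)
    full = {p.residues for p in positives}
    out = []
    for c in candidates:
        s = c.residues
        if s in full:
            continue
        if any(s[i:i + k] in kmers for i in range(len(s) - k + 1)):
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------

class _FragmentSampler:
    """Samples length-exact fragments from a record pool with rejection."""

    def __init__(self, pool: Sequence[SequenceRecord],
                 cysteine_free: bool = False,
                 forbidden_kmers: Optional[set] = None,
                 kmer_k: int = 10,
                 forbidden_sequences: Optional[set] = None):
        if not pool:
            raise ValueError("empty record pool for fragment sampling")
        self.pool = sorted(pool, key=lambda r: (len(r), r.id))
        self.lengths = np.array([len(r) for r in self.pool])
        self.cysteine_free = cysteine_free
        self.forbidden_kmers = forbidden_kmers
        self.kmer_k = kmer_k
        self.forbidden_sequences = forbidden_sequences or set()
        self.used_coords: set = set()

    def _ok(self, frag: str) -> bool:
        if frag in self.forbidden_sequences:
            return False
        if self.forbidden_kmers:
            k = self.kmer_k
            if any(frag[i:i + k] in self.forbidden_kmers
                   for i in range(len(frag) - k + 1)):
                return False
        return True

    def sample_one(self, L: int, rng, extra_ok=None, max_tries: int = 500):
        """One fragment of exact length L honouring all rejection rules."""
        first = int(np.searchsorted(self.lengths, L))
        if first >= len(self.pool):
            raise ValueError(f"no database record of length >= {L}")
        for _ in range(max_tries):
            idx = first + int(rng.integers(len(self.pool) - first))
            rec = self.pool[idx]
            if self.cysteine_free:
                coords = cysteine_free_substrings(rec, L, rng)
                if coords is None:
                    continue
                start, end = coords
            else:
                start = int(rng.integers(len(rec) - L + 1))
                end = start + L
            key = (rec.id, start, end)
            if key in self.used_coords:
                continue
            frag = rec.residues[start:end]
            if not self._ok(frag):
                continue
            if extra_ok is not None and not extra_ok(frag):
                continue
            self.used_coords.add(key)
            return frag, key
        raise ValueError(f"could not sample an admissible fragment of "
                         f"length {L} after {max_tries} tries")

    def sample_many(self, lengths: Sequence[int], rng):
        frags, provs = [], []
        for L in lengths:
            f, p = self.sample_one(int(L), rng)
            frags.append(f)
            provs.append(p)
        return frags, provs


def sample_lengths_equal(db: Sequence[SequenceRecord],
                         positive_lengths: Sequence[int], seed) -> list:
    """Fragments whose length multiset equals `positive_lengths` exactly.

    Returned record ids encode the provenance (parent id, 0-based half-open
    start/end coordinates).
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    sampler = _FragmentSampler(db)
    frags, provs = sampler.sample_many(positive_lengths, rng)
    return [_fragment_record(f, p, i) for i, (f, p) in
            enumerate(zip(frags, provs))]


def sample_lengths_similar(db: Sequence[SequenceRecord],
                           positive_lengths: Sequence[int], seed,
                           clustering_threshold: Optional[float] = None
                           ) -> list:
    """Equal-length sampling followed by redundancy reduction.

    With no threshold this degenerates to :func:`sample_lengths_equal`;
    with one, clustering may remove members so only an approximate
    distribution match is guaranteed.
    """
    records = sample_lengths_equal(db, positive_lengths, seed)
    if clustering_threshold is None:
        return records
    return greedy_identity_cluster(records, clustering_threshold)


def _fragment_record(frag: str, prov: Tuple[str, int, int], i: int,
                     prefix: str = "frag") -> SequenceRecord:
    parent, start, end = prov
    return SequenceRecord(id=f"{prefix}_{parent}_{start}_{end}",
                          residues=frag, source="negative_pool")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class ReplicatedDataset:
    """One replicate of a sampling method's negative train/bench sample."""

    spec_name: str
    replicate_index: int
    neg_train: List[SequenceRecord]
    neg_bench: List[SequenceRecord]
    pos_train: List[SequenceRecord]
    pos_bench: List[SequenceRecord]
    provenance: Dict[str, Tuple[str, int, int]] = field(default_factory=dict)
    stage_counts: Dict[str, int] = field(default_factory=dict)


def _repeat_lengths(lengths: Sequence[int], ratio: float, rng) -> List[int]:
    """Target length list = `ratio` copies of the positive length multiset."""
    whole = int(np.floor(ratio + 1e-9))
    out = list(lengths) * whole
    frac = ratio - whole
    if frac > 1e-9:
        extra = int(round(frac * len(lengths)))
        idx = rng.choice(len(lengths), size=extra, replace=False)
        out += [lengths[i] for i in idx]
    return out


def assemble_negative_sample(spec: SamplingSpec,
                             db: Sequence[SequenceRecord],
                             split: PositiveSplit,
                             n_replicates: int = 5,
                             seed: int = 0,
                             kmer_k: int = 10) -> List[ReplicatedDataset]:
    """Run one sampling method, producing `n_replicates` leakage-free
    negative train/bench samples.

    Stage order: keyword filter -> localization filter -> potential-AMP
    screen -> length policy -> (fragment rules) -> clustering -> AMP
    similarity screen -> positive-overlap removal -> sizing -> train/bench
    partition.  Each replicate uses an independently derived seed.
    """
    counts: Dict[str, int] = {"input": len(db)}
    pool = filter_by_keywords(db, spec.excluded_keywords)
    counts["keyword_filter"] = len(pool)
    if spec.localization_whitelist:
        pool = filter_by_localization(pool, spec.localization_whitelist)
        counts["localization_filter"] = len(pool)
    if spec.remove_potential_amps:
        pool = remove_potential_amps(pool)
        counts["potential_amp_screen"] = len(pool)
    if not pool:
        raise ValueError(f"{spec.name}: empty pool after filtering "
                         f"(stages: {counts})")

    positives_all = list(split.train) + list(split.bench)
    pos_sequences = {p.residues for p in positives_all}

    if spec.length_policy == "range":
        return _assemble_whole_records(spec, pool, split, positives_all,
                                       pos_sequences, counts, n_replicates,
                                       seed)
    return _assemble_fragments(spec, pool, split, pos_sequences, counts,
                               n_replicates, seed, kmer_k)


def _assemble_whole_records(spec, pool, split, positives_all, pos_sequences,
                            counts, n_replicates, seed):
    lo, hi = spec.length_range
    pool = filter_by_length_range(pool, lo, hi)
    counts["length_range"] = len(pool)
    pool = [r for r in pool if r.residues not in pos_sequences]
    counts["positive_overlap"] = len(pool)
    n_tr = int(round(spec.ratio * len(split.train)))
    n_be = int(round(spec.ratio * len(split.bench)))
    if spec.clustering_threshold is not None:
        # desk-scale: cluster a seeded subsample just large enough to meet
        # the sampling target, growing it until the survivors suffice
        rng0 = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        order = rng0.permutation(len(pool))
        cap = min(len(pool), max(3 * (n_tr + n_be), 1500))
        while True:
            sub = [pool[i] for i in order[:cap]]
            clustered = greedy_identity_cluster(sub,
                                                spec.clustering_threshold)
            if len(clustered) >= n_tr + n_be or cap == len(pool):
                break
            cap = min(len(pool), cap * 2)
        pool = clustered
        counts["clustering"] = len(pool)
    if n_tr + n_be > len(pool):
        raise ValueError(
            f"{spec.name}: target size {n_tr + n_be} unreachable; at most "
            f"{len(pool)} negatives available after filtering")
    out = []
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        idx = rng.choice(len(pool), size=n_tr + n_be, replace=False)
        chosen = [pool[i] for i in idx]
        neg_train = [_relabel(r, spec.name, rep, i)
                     for i, r in enumerate(chosen[:n_tr])]
        neg_bench = [_relabel(r, spec.name, rep, n_tr + i)
                     for i, r in enumerate(chosen[n_tr:])]
        prov = {nr.id: (r.id, 0, len(r)) for nr, r in
                zip(neg_train + neg_bench, chosen)}
        out.append(ReplicatedDataset(
            spec.name, rep, neg_train, neg_bench, list(split.train),
            list(split.bench), provenance=prov,
            stage_counts=dict(counts, neg_train=n_tr, neg_bench=n_be)))
    return out


def _assemble_fragments(spec, pool, split, pos_sequences, counts,
                        n_replicates, seed, kmer_k):
    forbidden_kmers = None
    if spec.amp_similarity_screen:
        forbidden_kmers = _kmer_set(pos_sequences, kmer_k)
    out = []
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        sampler = _FragmentSampler(
            pool, cysteine_free=spec.cysteine_free_substrings,
            forbidden_kmers=forbidden_kmers, kmer_k=kmer_k,
            forbidden_sequences=pos_sequences)
        lengths_tr = _repeat_lengths(split.train_lengths, spec.ratio, rng)
        lengths_be = _repeat_lengths(split.bench_lengths, spec.ratio, rng)
        frags_tr, provs_tr = sampler.sample_many(lengths_tr, rng)
        frags_be, provs_be = sampler.sample_many(lengths_be, rng)
        n_tr = len(frags_tr)
        frags = frags_tr + frags_be
        provs = provs_tr + provs_be

        if spec.clustering_threshold is not None:
            if spec.length_policy == "equal_to_positive":
                frags, provs = _cluster_refill(
                    frags, provs, sampler, rng, spec.clustering_threshold)
            else:  # similar: clustering may shrink the sample
                reps, _ = _greedy_cluster(frags, spec.clustering_threshold)
                keep = sorted(reps)
                frags = [frags[i] for i in keep]
                provs = [provs[i] for i in keep]
                n_tr = sum(1 for i in keep if i < n_tr)

        neg_train = [_relabel_frag(f, spec.name, rep, i)
                     for i, f in enumerate(frags[:n_tr])]
        neg_bench = [_relabel_frag(f, spec.name, rep, n_tr + i)
                     for i, f in enumerate(frags[n_tr:])]
        prov = {nr.id: p for nr, p in zip(neg_train + neg_bench, provs)}
        out.append(ReplicatedDataset(
            spec.name, rep, neg_train, neg_bench, list(split.train),
            list(split.bench), provenance=prov,
            stage_counts=dict(counts, neg_train=len(neg_train),
                              neg_bench=len(neg_bench))))
    return out


def _cluster_refill(frags, provs, sampler, rng, threshold):
    """Cluster fragments, resampling replacements until the length multiset
    is restored (keeps the exact-length property of equal-length methods
    while still applying the redundancy threshold)."""
    reps, _ = _greedy_cluster(frags, threshold)
    keep = set(reps)
    rep_seqs = [frags[i] for i in sorted(keep)]
    out_frags, out_provs = list(frags), list(provs)

    def fresh(f):
        return not any(_identity_at_least(f, r, threshold) for r in rep_seqs)

    for i in (j for j in range(len(frags)) if j not in keep):
        try:
            frag, prov = sampler.sample_one(len(frags[i]), rng,
                                            extra_ok=fresh, max_tries=30)
        except ValueError:
            # very short lengths can make non-redundancy unsatisfiable
            # (identity is quantized at 1/length); keep the multiset exact
            # and accept a redundant fragment for this slot
            frag, prov = sampler.sample_one(len(frags[i]), rng)
        out_frags[i], out_provs[i] = frag, prov
        rep_seqs.append(frag)
    return out_frags, out_provs


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "", name)


def _relabel(rec: SequenceRecord, spec_name: str, rep: int,
             i: int) -> SequenceRecord:
    return SequenceRecord(id=f"neg_{_slug(spec_name)}_r{rep}_{i:05d}",
                          residues=rec.residues, keywords=set(rec.keywords),
                          localization=set(rec.localization),
                          source="negative_pool", amp_like=rec.amp_like)


def _relabel_frag(frag: str, spec_name: str, rep: int,
                  i: int) -> SequenceRecord:
    return SequenceRecord(id=f"neg_{_slug(spec_name)}_r{rep}_{i:05d}",
                          residues=frag, source="negative_pool")
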