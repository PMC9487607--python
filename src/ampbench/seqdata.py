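"""Sequence records, FASTA/annotation I/O and the positive-set split.

The data model mirrors what a minimal UniProt-like database needs for
negative-set sampling: a sequence over the 20 standard amino acids plus
free-form function keywords and subcellular-localization terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class SequenceRecord:
    """One annotated protein/peptide entry.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header up to the first whitespace).
    residues : str
        Upper-case sequence over the 20 standard amino acids.
    keywords : set of str
        Lower-case function keywords (may be empty).
    localization : set of str
        Lower-case subcellular compartment terms (may be empty).
    source : str
        ``"positive"`` or ``"negative_pool"``.
    amp_like : bool
        Synthetic-oracle flag: True for background records planted with
        AMP-like composition (unused for real data).
    """

    id: str
    residues: str
    keywords: set = field(default_factory=set)
    localization: set = field(default_factory=set)
    source: str = "negative_pool"
    amp_like: bool = False

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        self.keywords = {k.lower() for k in self.keywords}
        self.localization = {l.lower() for l in self.localization}

    def __len__(self) -> int:
        return len(self.residues)

    def is_standard(self) -> bool:
        return len(self.residues) > 0 and set(self.residues) <= AA_SET


@dataclass
class PositiveSplit:
    """Positive data split into a training and a benchmark sample."""

    train: list
    bench: list
    split_fraction: float
    seed: int

    @property
    def train_lengths(self) -> list:
        return [len(r) for r in self.train]

    @property
    def bench_lengths(self) -> list:
        return [len(r) for r in self.bench]


class FastaFormatError(ValueError):
    """Malformed FASTA input (carries the offending line number)."""


def read_fasta(path, source: str = "negative_pool"):
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Records containing non-standard residues (anything outside the 20-letter
    alphabet) or empty sequences are dropped with a counted warning, mirroring
    the usual curation step for peptide databases.

    Returns
    -------
    records : list of SequenceRecord
    n_dropped : int
        Number of entries rejected for non-standard residues.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    n_dropped = 0
    seen_ids: set[str] = set()

    def flush() -> None:
        nonlocal n_dropped
        if header is None:
            return
        rec = SequenceRecord(id=header, residues="".join(chunks).upper(),
                             source=source)
        if not rec.is_standard():
            n_dropped += 1
            logger.warning("dropping record %r (line %d): non-standard or "
                           "empty sequence", header, header_line)
            return
        records.append(rec)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FastaFormatError(
                        f"{path}:{lineno}: empty FASTA header")
                if name in seen_ids:
                    raise FastaFormatError(
                        f"{path}:{lineno}: duplicate id {name!r}")
                seen_ids.add(name)
                header, header_line, chunks = name, lineno, []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before first header")
                chunks.append(line)
        flush()
    return records, n_dropped


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def read_annotations(path, records: Sequence[SequenceRecord]):
    """Attach keyword/localization annotations from a TSV table.

    The table has columns ``id``, ``keywords``, ``localization`` with
    semicolon-joined multi-values.  Records absent from the table keep empty
    sets; table ids absent from `records` produce a warning.  Duplicate ids in
    the table are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["id", "keywords", "localization"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"annotation table must have columns {expected}, "
                         f"got {list(df.columns)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in annotation table: {dups[:5]}")

    def parse_terms(cell: str) -> set:
        return {t.strip().lower() for t in cell.split(";") if t.strip()}

    table = {row.id: (parse_terms(row.keywords), parse_terms(row.localization))
             for row in df.itertuples()}
    known = {r.id for r in records}
    for unknown in set(table) - known:
        logger.warning("annotation row for unknown record id %r", unknown)

    out = []
    for rec in records:
        kw, loc = table.get(rec.id, (set(), set()))
        out.append(replace(rec, keywords=set(kw), localization=set(loc)))
    return out


def write_annotations(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tkeywords\tlocalization\n")
        for rec in records:
            fh.write(f"{rec.id}\t{';'.join(sorted(rec.keywords))}\t"
                     f"{';'.join(sorted(rec.localization))}\n")


def split_positive(records: Sequence[SequenceRecord], fraction: float = 0.8,
                   seed: int = 0) -> PositiveSplit:
    """Uniform random 80/20-style partition of the positive set.

    The training size is ``floor(fraction * n + 0.5)``; the split is performed
    before any negative sampling so that no benchmark information leaks into
    training-set construction.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(math.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = set(order[:n_train].tolist())
    train = [records[i] for i in range(n) if i in train_idx]
    bench = [records[i] for i in range(n) if i not in train_idx]
    return PositiveSplit(train=train, bench=bench, split_fraction=fraction,
                         seed=seed)


def reduce_redundancy_positive(records: Sequence[SequenceRecord],
                               threshold: float = 0.9):
    """Remove redundant positives above a pairwise identity threshold.

    Delegates to the shared CD-HIT-style greedy clustering used for negative
    sets; returns the cluster representatives.
    """
    from .sampling import greedy_identity_cluster

    return greedy_identity_cluster(records, threshold)
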