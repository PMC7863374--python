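"""Sequence screening, rarefaction and OTU-level filtering.

Pipeline order is fixed: screen reads -> (external clustering/classification)
-> rarefy -> filter rare OTUs -> subset samples and prune empty OTU columns.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .io_formats import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "CurationConfig",
    "screen_sequences",
    "rarefy",
    "filter_rare_otus",
    "subset_and_prune",
]

_HOMOPOLYMER_RE = re.compile(r"(.)\1*")
_UNAMBIGUOUS = set("ACGT-")


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds for read screening and table-level filtering.

    The length window stands in for reference-alignment screening (no
    reference alignment is part of this toolkit); defaults suit single-end
    300-nt V1V2 reads.
    """

    max_ambiguous: int = 0
    max_homopolymer: int = 8
    min_length: int = 200
    max_length: int = 320
    rarefaction_depth: int = 5000
    min_otu_total: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_homopolymer <= 0:
            raise ValueError("max_homopolymer must be positive")
        if self.max_ambiguous < 0:
            raise ValueError("max_ambiguous must be >= 0")
        if self.min_length <= 0 or self.max_length <= 0:
            raise ValueError("length bounds must be positive")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if self.min_otu_total <= 0:
            raise ValueError("min_otu_total must be positive")


def _longest_homopolymer(seq: str) -> int:
    return max((m.end() - m.start() for m in _HOMOPOLYMER_RE.finditer(seq)), default=0)


def screen_sequences(reads, cfg: CurationConfig):
    """Drop reads with too many ambiguous calls, long homopolymers, or
    out-of-window lengths.

    Rules are applied in that order and each removal is attributed to the
    first failing rule.  ``reads`` is an iterable of (name, sequence) pairs.

    Returns ``(kept, report)`` where report counts removals per rule.
    """
    kept: list[tuple[str, str]] = []
    report = {"input": 0, "ambiguous": 0, "homopolymer": 0, "length": 0, "kept": 0}
    for name, seq in reads:
        report["input"] += 1
        seq_u = seq.upper()
        bases = seq_u.replace("-", "")
        n_ambig = sum(1 for b in bases if b not in _UNAMBIGUOUS)
        if n_ambig > cfg.max_ambiguous:
            report["ambiguous"] += 1
            continue
        if _longest_homopolymer(bases) > cfg.max_homopolymer:
            report["homopolymer"] += 1
            continue
        if not (cfg.min_length <= len(bases) <= cfg.max_length):
            report["length"] += 1
            continue
        kept.append((name, seq))
    report["kept"] = len(kept)
    return kept, report


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.
    Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept_rows: list[int] = []
    rows: list[np.ndarray] = []
    for i, total in enumerate(totals):
        if total < depth:
            logger.warning(
                "dropping sample %r: total %d below rarefaction depth %d",
                table.sample_ids[i], int(total), depth,
            )
            continue
        row = table.counts[i]
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_rows.append(i)
    sample_ids = tuple(table.sample_ids[i] for i in kept_rows)
    counts = np.vstack(rows) if rows else np.zeros((0, table.n_otus), dtype=np.int64)
    return OtuTable(sample_ids, table.otu_ids, counts)


def filter_rare_otus(table: OtuTable, min_total: int) -> OtuTable:
    """Remove OTUs whose total count across all retained samples is below
    ``min_total``; survivor order is preserved."""
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    keep = table.otu_totals() >= min_total
    return table.select_otus(keep)


def subset_and_prune(table: OtuTable, sample_subset) -> OtuTable:
    """Restrict rows to ``sample_subset`` and drop OTU columns whose total
    becomes zero."""
    sub = table.select_samples(list(sample_subset))
    keep = sub.otu_totals() > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("subset_and_prune: removed %d OTUs with no sequences in subset", dropped)
    return sub.select_otus(keep)
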