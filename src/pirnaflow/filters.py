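"""piRNA candidate screening.

Four pure, commuting filters: ncRNA blacklist removal (any alignment
overlapping a tRNA/rRNA/snRNA/snoRNA locus by >= 1 nt on either strand
discards the read), a 23-29 nt length gate, an optional exact-sequence
whitelist (a stand-in for piRNA-database membership), and the minimum
pooled count rule (total count across ALL samples >= 10 by default).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AlignmentRecord, CollapsedRead, FeatureInterval


@dataclass
class FilterReport:
    """Per-stage removal tallies; ``input_n = kept_n + sum(removed_*)``."""

    input_n: int = 0
    removed_blacklist: int = 0
    removed_length: int = 0
    removed_whitelist: int = 0
    removed_mincount: int = 0
    kept_n: int = 0

    def validate(self) -> None:
        removed = (self.removed_blacklist + self.removed_length
                   + self.removed_whitelist + self.removed_mincount)
        if self.input_n != self.kept_n + removed:
            raise ValueError(f"filter tallies not conserved: {self}")
        if min(self.input_n, self.kept_n, self.removed_blacklist,
               self.removed_length, self.removed_whitelist,
               self.removed_mincount) < 0:
            raise ValueError(f"negative tally in {self}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


class _IntervalLookup:
    """Per-contig sorted interval arrays for >=1 nt overlap queries."""

    def __init__(self, intervals: Sequence[FeatureInterval]):
        per: dict[str, list[FeatureInterval]] = defaultdict(list)
        for iv in intervals:
            per[iv.contig].append(iv)
        self._arr: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, ivs in per.items():
            starts = np.array([iv.start for iv in ivs])
            ends = np.array([iv.end for iv in ivs])
            self._arr[contig] = (starts, ends)

    def overlaps_any(self, contig: str, start: int, end: int) -> bool:
        if contig not in self._arr:
            return False
        starts, ends = self._arr[contig]
        return bool(np.any((starts < end) & (ends > start)))


def blacklist_filter(
    reads: Sequence[CollapsedRead],
    alignments: dict[str, list[AlignmentRecord]],
    blacklist: Sequence[FeatureInterval],
) -> tuple[list[CollapsedRead], int]:
    """Remove reads with ANY alignment overlapping ANY blacklist interval.

    Overlap of a single nucleotide on either strand suffices: contamination
    removal is deliberately the strictest rule.  Idempotent.
    """
    lookup = _IntervalLookup(blacklist)
    kept, removed = [], 0
    for read in reads:
        hit = any(
            lookup.overlaps_any(a.contig, a.start, a.end)
            for a in alignments.get(read.id, [])
        )
        if hit:
            removed += 1
        else:
            kept.append(read)
    return kept, removed


def length_whitelist_filter(
    reads: Sequence[CollapsedRead],
    min_len: int = 23,
    max_len: int = 29,
    whitelist: set[str] | None = None,
) -> tuple[list[CollapsedRead], int, int]:
    """Keep reads with ``min_len <= length <= max_len`` (both inclusive).

    If a whitelist of sequences is supplied, reads must additionally be
    exact members.  Returns ``(kept, n_removed_length, n_removed_whitelist)``.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept, n_len, n_wl = [], 0, 0
    for read in reads:
        if not (min_len <= read.length <= max_len):
            n_len += 1
        elif whitelist is not None and read.sequence not in whitelist:
            n_wl += 1
        else:
            kept.append(read)
    return kept, n_len, n_wl


def mincount_filter(
    reads: Sequence[CollapsedRead],
    min_total: int = 10,
    scope: str = "pooled",
    groups: Sequence[str] | None = None,
) -> tuple[list[CollapsedRead], int]:
    """Keep reads whose counts reach ``min_total``.

    ``scope="pooled"`` (default) sums over ALL samples of both conditions,
    the reading of "a minimum count across the samples" this package
    adopts.  ``scope="per_group"`` instead requires some single group's sum
    to reach the threshold (needs ``groups``, one label per sample column).
    """
    if scope not in ("pooled", "per_group"):
        raise ValueError(f"unknown mincount scope {scope!r}")
    if scope == "per_group" and groups is None:
        raise ValueError("per_group scope requires group labels")
    kept, removed = [], 0
    if scope == "per_group":
        glab = np.asarray(groups)
        uniq = np.unique(glab)
    for read in reads:
        if scope == "pooled":
            ok = read.total >= min_total
        else:
            ok = any(int(read.counts[glab == g].sum()) >= min_total for g in uniq)
        if ok:
            kept.append(read)
        else:
            removed += 1
    return kept, removed


def run_filters(
    reads: Sequence[CollapsedRead],
    alignments: dict[str, list[AlignmentRecord]],
    blacklist: Sequence[FeatureInterval],
    min_len: int = 23,
    max_len: int = 29,
    whitelist: set[str] | None = None,
    min_total: int = 10,
    mincount_scope: str = "pooled",
    groups: Sequence[str] | None = None,
) -> tuple[list[CollapsedRead], FilterReport]:
    """Apply blacklist -> length/whitelist -> min-count and tally removals.

    The filters are pure per-read predicates, so the outcome set is
    order-independent; the fixed order only attributes each removal to the
    first rule that would have fired.
    """
    report = FilterReport(input_n=len(reads))
    kept, report.removed_blacklist = blacklist_filter(reads, alignments, blacklist)
    kept, report.removed_length, report.removed_whitelist = length_whitelist_filter(
        kept, min_len=min_len, max_len=max_len, whitelist=whitelist)
    kept, report.removed_mincount = mincount_filter(
        kept, min_total=min_total, scope=mincount_scope, groups=groups)
    report.kept_n = len(kept)
    report.validate()
    return kept, report
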