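"""Ping-pong signature: 5'-5' overlap histogram and z-score at 10 nt.

The germline ping-pong cycle cleaves a transposon transcript opposite
nucleotides 10-11 of the guide piRNA, so reciprocal sense/antisense piRNA
pairs share exactly 10 complementary 5' nucleotides.  The signature
statistic standardizes the weighted count of 10-nt 5' overlaps against the
background of the other overlap lengths in ``[1, kmax]``.

Overlap convention (1-based inclusive): for a plus-strand read with 5' end
``f+`` and a minus-strand read with 5' end ``f-`` on the same contig, the
overlap is ``k = f- - f+ + 1`` — the number of genomic positions shared by
the two 5'-anchored k-prefixes.  ``k = 10`` is the ping-pong signature::

    + read 5'->   100 101 ... 109
    - read          109 <- ... <-100   (5' at 109)
    k = 109 - 100 + 1 = 10
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import AlignmentRecord


class DegenerateHistogramError(ValueError):
    """Raised when the background has zero spread so z is undefined."""


@dataclass
class OverlapHistogram:
    """Weighted pair counts ``O(k)`` for overlaps ``k in [1, kmax]``."""

    o: dict[int, float]
    kmax: int = 20

    def counts(self) -> np.ndarray:
        return np.array([self.o.get(k, 0.0) for k in range(1, self.kmax + 1)])


@dataclass(frozen=True)
class PingPongResult:
    z: float
    signal: float          # O(10)
    bg_mean: float
    bg_sd: float


def overlap_histogram(
    alignments: Iterable[AlignmentRecord],
    weights: dict[str, float],
    kmax: int = 20,
    weight_mode: str = "product",
) -> OverlapHistogram:
    """Tally weighted opposite-strand 5'-5' overlaps.

    Every (plus, minus) read pair on the same contig with overlap
    ``1 <= k <= kmax`` contributes ``w+ * w-`` (default) or ``min(w+, w-)``
    to ``O(k)``; each unordered pair is counted exactly once because pairs
    are enumerated as plus x minus.
    """
    if weight_mode not in ("product", "min"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    plus: dict[str, dict[int, list[float]]] = defaultdict(lambda: defaultdict(list))
    minus: dict[str, dict[int, list[float]]] = defaultdict(lambda: defaultdict(list))
    for a in alignments:
        w = float(weights.get(a.read_id, 1.0))
        side = plus if a.strand == "+" else minus
        side[a.contig][a.five_prime].append(w)
    o: dict[int, float] = {k: 0.0 for k in range(1, kmax + 1)}
    for contig, pdict in plus.items():
        mdict = minus.get(contig)
        if not mdict:
            continue
        if weight_mode == "product":
            psum = {fp: sum(ws) for fp, ws in pdict.items()}
            msum = {fp: sum(ws) for fp, ws in mdict.items()}
            for fp, wp in psum.items():
                for k in range(1, kmax + 1):
                    wm = msum.get(fp + k - 1)
                    if wm:
                        o[k] += wp * wm
        else:
            for fp, wps in pdict.items():
                for k in range(1, kmax + 1):
                    wms = mdict.get(fp + k - 1)
                    if wms:
                        o[k] += sum(min(a_, b_) for a_ in wps for b_ in wms)
    return OverlapHistogram(o=o, kmax=kmax)


def pingpong_zscore(hist: OverlapHistogram, signal_k: int = 10) -> PingPongResult:
    """z-score of ``O(10)`` against the other overlap lengths.

    ``z = (O(10) - mean(bg)) / sd(bg)`` with the sample standard deviation
    (n-1 denominator) over ``bg = {O(k): k != 10}``.  A flat histogram
    (``sd = 0``) has no defined z and raises
    :class:`DegenerateHistogramError`.
    """
    if hist.kmax < signal_k + 1:
        raise ValueError(f"kmax must be >= {signal_k + 1}")
    counts = hist.counts()
    signal = counts[signal_k - 1]
    bg = np.delete(counts, signal_k - 1)
    bg_mean = float(bg.mean())
    bg_sd = float(bg.std(ddof=1))
    if bg_sd == 0.0:
        raise DegenerateHistogramError(
            f"flat background (all O(k) = {bg_mean}); z undefined")
    return PingPongResult(z=float((signal - bg_mean) / bg_sd),
                         signal=float(signal), bg_mean=bg_mean, bg_sd=bg_sd)


def histogram_to_frame(hist: OverlapHistogram) -> pd.DataFrame:
    return pd.DataFrame(
        {"overlap": list(range(1, hist.kmax + 1)), "weight": hist.counts()})
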