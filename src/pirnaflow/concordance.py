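"""Antisense piRNA / gene fold-change concordance (quadrant analysis).

Pairs significant piRNAs with the significant DE genes they map antisense
to, then counts the four (gene direction x piRNA direction) quadrants.  The
headline fraction — among piRNA-down pairs, the share sitting on up-
regulated genes — quantifies the expected signature of antisense-piRNA
gene regulation: losing a silencing piRNA de-represses its target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .annotate import CategoryAssignment

log = logging.getLogger(__name__)


@dataclass
class QuadrantTable:
    """Counts by (gene, piRNA) direction; ``u`` = up, ``d`` = down."""

    n_uu: int
    n_ud: int
    n_du: int
    n_dd: int
    n_zero_excluded: int
    headline_fraction: float      # P(gene up | piRNA down)
    ci_low: float
    ci_high: float

    @property
    def n_pairs(self) -> int:
        return self.n_uu + self.n_ud + self.n_du + self.n_dd


def antisense_pairs(
    pirna_de: pd.DataFrame,
    assignments: Sequence[CategoryAssignment],
    gene_de: pd.DataFrame,
    gene_alpha: float = 0.05,
    sense_filter: str = "antisense",
    collapse_targets: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Emit (significant piRNA, significant gene) pairs.

    ``pirna_de`` is the piRNA DE table (indexed by read id, with
    ``log2fc`` and ``direction``); ``gene_de`` must carry ``gene_id,
    log2fc, q``.  A pair is emitted when a piRNA's genic assignment targets
    the gene and both members pass their significance rules; the sense
    filter defaults to antisense-only.  Gene ids missing from ``gene_de``
    are skipped with a logged tally, returned as the second element.
    Multi-target piRNAs contribute one pair per target gene unless
    ``collapse_targets`` keeps only the first (sorted) gene.
    """
    if sense_filter not in ("antisense", "sense", "both"):
        raise ValueError(f"unknown sense_filter {sense_filter!r}")
    sig_pirna = pirna_de[pirna_de["direction"] != "ns"]
    genes = gene_de.set_index("gene_id")
    sig_genes = genes[genes["q"] <= gene_alpha]
    rows, skipped = [], 0
    by_read: dict[str, list[CategoryAssignment]] = {}
    for a in assignments:
        if a.category != "genic":
            continue
        if sense_filter != "both" and a.sense != sense_filter:
            continue
        by_read.setdefault(a.read_id, []).append(a)
    for read_id in sig_pirna.index:
        targets = sorted({a.target_id for a in by_read.get(read_id, [])})
        if collapse_targets:
            targets = targets[:1]
        for gene_id in targets:
            if gene_id not in genes.index:
                skipped += 1
                continue
            if gene_id not in sig_genes.index:
                continue
            rows.append(dict(
                pirna_id=read_id, gene_id=gene_id,
                pirna_log2fc=float(sig_pirna.loc[read_id, "log2fc"]),
                gene_log2fc=float(sig_genes.loc[gene_id, "log2fc"]),
                pirna_sense=sense_filter if sense_filter != "both"
                else by_read[read_id][0].sense,
            ))
    if skipped:
        log.info("antisense_pairs: %d target gene ids absent from gene DE", skipped)
    pairs = pd.DataFrame(
        rows, columns=["pirna_id", "gene_id", "pirna_log2fc",
                       "gene_log2fc", "pirna_sense"])
    pairs = pairs.sort_values(["pirna_id", "gene_id"], kind="mergesort",
                              ignore_index=True)
    return pairs, skipped


def quadrant_counts(pairs: pd.DataFrame) -> QuadrantTable:
    """Quadrant structure of the fold-change scatter.

    Signs come from the log2 fold changes; pairs with a zero fold change on
    either axis are excluded and tallied.  The headline fraction (among
    piRNA-down pairs, the gene-up share) carries an exact Clopper-Pearson
    95% interval.  Raises on empty input.
    """
    if len(pairs) == 0:
        raise ValueError("quadrant_counts requires at least one pair")
    nonzero = pairs[(pairs["gene_log2fc"] != 0) & (pairs["pirna_log2fc"] != 0)]
    n_zero = len(pairs) - len(nonzero)
    gene_up = nonzero["gene_log2fc"] > 0
    pirna_up = nonzero["pirna_log2fc"] > 0
    n_uu = int((gene_up & pirna_up).sum())
    n_ud = int((gene_up & ~pirna_up).sum())
    n_du = int((~gene_up & pirna_up).sum())
    n_dd = int((~gene_up & ~pirna_up).sum())
    n_down = n_ud + n_dd
    if n_down > 0:
        frac = n_ud / n_down
        ci = stats.binomtest(n_ud, n_down).proportion_ci(confidence_level=0.95)
        lo, hi = float(ci.low), float(ci.high)
    else:
        frac, lo, hi = float("nan"), float("nan"), float("nan")
    return QuadrantTable(n_uu=n_uu, n_ud=n_ud, n_du=n_du, n_dd=n_dd,
                         n_zero_excluded=n_zero, headline_fraction=frac,
                         ci_low=lo, ci_high=hi)


def quadrants_to_frame(q: QuadrantTable) -> pd.DataFrame:
    return pd.DataFrame([vars(q)])
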