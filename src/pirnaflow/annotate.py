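"""Hierarchical categorization of piRNAs and composition summaries.

Each read is assigned one category over ALL of its alignments with the
precedence transposon > satellite > genic > unannotated (standard
small-RNA practice: a read touching a transposable element anywhere is a
transposon piRNA even if it also has genic placements).  An alignment
"overlaps" a feature only when at least half of the read lies inside it,
which blocks 1-nt grazing assignments.  The deciding alignment is the one
with maximal overlap to a feature of the winning category (ties resolved
to the leftmost ``(contig, start)``); the sense call compares the deciding
alignment's strand with the feature's strand.  Genic reads additionally get
the gene-part class (CDS-exon / intron / 5'UTR / 3'UTR) with maximal
overlap, ties broken utr3 > utr5 > exon > intron.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    GENIC_TYPES,
    SATELLITE_TYPE,
    TRANSPOSON_TYPE,
    AlignmentRecord,
    CollapsedRead,
    FeatureInterval,
)

_FEATURE_PRECEDENCE = {"utr3": 0, "utr5": 1, "exon": 2, "intron": 3}


@dataclass
class CategoryAssignment:
    """The category + strand-sense call for one collapsed read."""

    read_id: str
    category: str               # transposon | satellite | genic | unannotated
    te_class: str = "none"      # LTR | LINE | none
    feature: str = "none"       # exon | intron | utr5 | utr3 | none
    sense: str = "none"         # sense | antisense | none
    target_id: str = ""
    weight: float = 1.0
    length: int = 0

    def __post_init__(self):
        if (self.feature != "none") != (self.category == "genic"):
            raise ValueError("feature set iff category genic")
        if (self.te_class != "none") != (self.category == "transposon"):
            raise ValueError("te_class set iff category transposon")
        if (self.sense == "none") != (self.category == "unannotated"):
            raise ValueError("sense none iff category unannotated")


class FeatureIndex:
    """Category-bucketed per-contig interval arrays for overlap queries."""

    def __init__(self, features: Sequence[FeatureInterval]):
        self.by_gene: dict[str, list[FeatureInterval]] = defaultdict(list)
        buckets: dict[str, dict[str, list[FeatureInterval]]] = {
            "transposon": defaultdict(list),
            "satellite": defaultdict(list),
            "genic": defaultdict(list),
        }
        for f in features:
            if f.ftype == TRANSPOSON_TYPE:
                buckets["transposon"][f.contig].append(f)
            elif f.ftype == SATELLITE_TYPE:
                buckets["satellite"][f.contig].append(f)
            elif f.ftype in GENIC_TYPES:
                buckets["genic"][f.contig].append(f)
                self.by_gene[f.attrs.get("gene_id", f.feature_id)].append(f)
        self._arr: dict[str, dict[str, tuple]] = {}
        for cat, per in buckets.items():
            self._arr[cat] = {}
            for contig, ivs in per.items():
                starts = np.array([iv.start for iv in ivs])
                ends = np.array([iv.end for iv in ivs])
                self._arr[cat][contig] = (starts, ends, ivs)

    def overlapping(self, category: str, contig: str, start: int, end: int,
                    min_ov: int) -> list[tuple[FeatureInterval, int]]:
        """Features of ``category`` overlapping [start, end) by >= min_ov."""
        per = self._arr[category]
        if contig not in per:
            return []
        starts, ends, ivs = per[contig]
        ov = np.minimum(ends, end) - np.maximum(starts, start)
        idx = np.nonzero(ov >= min_ov)[0]
        return [(ivs[i], int(ov[i])) for i in idx]


def genic_feature(alignment: AlignmentRecord,
                  gene_parts: Sequence[FeatureInterval]) -> str:
    """Gene-part class with maximal overlap with the read span.

    Ties break by fixed precedence utr3 > utr5 > exon > intron ("exon"
    means CDS-exon, disjoint from the UTRs).
    """
    best, best_key = "none", None
    for part in gene_parts:
        ov = part.overlap(alignment.start, alignment.end)
        if ov <= 0:
            continue
        cls = GENIC_TYPES[part.ftype]
        key = (-ov, _FEATURE_PRECEDENCE[cls])
        if best_key is None or key < best_key:
            best, best_key = cls, key
    return best


def assign_category(
    read: CollapsedRead,
    alignments: Sequence[AlignmentRecord],
    index: FeatureIndex,
    min_overlap_frac: float = 0.5,
    weight: float | None = None,
) -> CategoryAssignment:
    """Assign one hierarchical category to a read from all its placements."""
    min_ov = max(1, int(np.ceil(min_overlap_frac * read.length)))
    w = read.total if weight is None else weight
    for category in ("transposon", "satellite", "genic"):
        candidates: list[tuple[tuple, AlignmentRecord, FeatureInterval]] = []
        for aln in alignments:
            for feat, ov in index.overlapping(category, aln.contig,
                                              aln.start, aln.end, min_ov):
                # maximal overlap wins; ties -> leftmost (contig, start)
                candidates.append(((-ov, aln.contig, aln.start), aln, feat))
        if not candidates:
            continue
        _, aln, feat = min(candidates, key=lambda c: c[0])
        sense = "sense" if aln.strand == feat.strand else "antisense"
        if category == "transposon":
            return CategoryAssignment(
                read_id=read.id, category=category,
                te_class=feat.attrs.get("class", "LTR"), sense=sense,
                target_id=feat.attrs.get("family", feat.feature_id),
                weight=w, length=read.length)
        if category == "satellite":
            return CategoryAssignment(
                read_id=read.id, category=category, sense=sense,
                target_id=feat.feature_id, weight=w, length=read.length)
        gene_id = feat.attrs.get("gene_id", feat.feature_id)
        fclass = genic_feature(aln, index.by_gene.get(gene_id, [feat]))
        return CategoryAssignment(
            read_id=read.id, category="genic", feature=fclass, sense=sense,
            target_id=gene_id, weight=w, length=read.length)
    return CategoryAssignment(read_id=read.id, category="unannotated",
                              weight=w, length=read.length)


def assign_all(
    reads: Sequence[CollapsedRead],
    alignments: dict[str, list[AlignmentRecord]],
    features: Sequence[FeatureInterval] | FeatureIndex,
    min_overlap_frac: float = 0.5,
    weighting: str = "count",
) -> list[CategoryAssignment]:
    """Assign every read; ``weighting`` is ``"count"`` (pooled counts) or
    ``"unique"`` (each sequence counts once)."""
    if weighting not in ("count", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    out = []
    for read in reads:
        w = read.total if weighting == "count" else 1
        out.append(assign_category(read, alignments.get(read.id, []), index,
                                   min_overlap_frac=min_overlap_frac, weight=w))
    return out


@dataclass
class CompositionTable:
    """Read-weighted percentage composition (categories sum to 100)."""

    category_pct: dict[str, float]
    genic_feature_pct: dict[str, float]
    te_class_pct: dict[str, float]
    total_weight: float
    genic_weight: float
    transposon_weight: float

    def validate(self) -> None:
        for name, d in (("category", self.category_pct),
                        ("genic feature", self.genic_feature_pct),
                        ("te class", self.te_class_pct)):
            if d and abs(sum(d.values()) - 100.0) > 0.01:
                raise ValueError(f"{name} percentages do not sum to 100: {d}")

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(level="category", key=k, pct=v)
                for k, v in self.category_pct.items()]
        rows += [dict(level="genic_feature", key=k, pct=v)
                 for k, v in self.genic_feature_pct.items()]
        rows += [dict(level="te_class", key=k, pct=v)
                 for k, v in self.te_class_pct.items()]
        return pd.DataFrame(rows)


def composition_summary(assignments: Sequence[CategoryAssignment]) -> CompositionTable:
    """Weighted composition percentages; genic-feature and TE-class splits
    are conditioned on their category."""
    if not assignments:
        raise ValueError("no assignments to summarize")
    cat_w: dict[str, float] = defaultdict(float)
    feat_w: dict[str, float] = defaultdict(float)
    te_w: dict[str, float] = defaultdict(float)
    for a in assignments:
        cat_w[a.category] += a.weight
        if a.category == "genic":
            feat_w[a.feature] += a.weight
        elif a.category == "transposon":
            te_w[a.te_class] += a.weight
    total = sum(cat_w.values())
    genic = sum(feat_w.values())
    te = sum(te_w.values())
    table = CompositionTable(
        category_pct={k: 100.0 * v / total for k, v in sorted(cat_w.items())},
        genic_feature_pct={k: 100.0 * v / genic for k, v in sorted(feat_w.items())}
        if genic else {},
        te_class_pct={k: 100.0 * v / te for k, v in sorted(te_w.items())}
        if te else {},
        total_weight=total, genic_weight=genic, transposon_weight=te,
    )
    table.validate()
    return table


def assignments_to_frame(assignments: Sequence[CategoryAssignment]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in assignments])
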