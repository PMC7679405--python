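"""Shared value types for the piRNA analysis pipeline.

All genomic coordinates inside the package are 0-based, half-open
``[start, end)``.  GFF3 (1-based, inclusive) is converted at the I/O
boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: GFF3 feature types making up a protein-coding gene model.  "exon" in the
#: composition tables means CDS-exon, disjoint from the UTRs.
GENIC_TYPES = {
    "five_prime_UTR": "utr5",
    "CDS": "exon",
    "intron": "intron",
    "three_prime_UTR": "utr3",
}

#: ncRNA classes treated as contamination and removed before any piRNA call.
BLACKLIST_TYPES = ("tRNA", "rRNA", "snRNA", "snoRNA")

TRANSPOSON_TYPE = "transposable_element"
SATELLITE_TYPE = "satellite_DNA"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureInterval:
    """A typed, stranded genomic interval.

    Parameters
    ----------
    contig : str
        Contig/chromosome name.
    start, end : int
        0-based half-open span; ``0 <= start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    ftype : str
        GFF3 feature type (``CDS``, ``intron``, ``transposable_element`` ...).
    attrs : dict
        Free-form attributes (``gene_id``, ``family``, ``class`` ...).
    """

    contig: str
    start: int
    end: int
    strand: str
    ftype: str
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def feature_id(self) -> str:
        return self.attrs.get("ID", f"{self.ftype}:{self.contig}:{self.start}")

    def overlap(self, start: int, end: int) -> int:
        """Length of the overlap with ``[start, end)`` (0 if disjoint)."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class AnnotatedGenome:
    """Reference sequences plus typed, stranded feature intervals."""

    contigs: dict[str, str]
    features: list[FeatureInterval]

    def features_of_type(self, *ftypes: str) -> list[FeatureInterval]:
        want = set(ftypes)
        return [f for f in self.features if f.ftype in want]

    def validate(self) -> None:
        """Check every feature fits inside its contig."""
        for f in self.features:
            if f.contig not in self.contigs:
                raise ValueError(f"feature on unknown contig {f.contig}")
            if f.end > len(self.contigs[f.contig]):
                raise ValueError(f"feature {f} exceeds contig bounds")


@dataclass
class CollapsedRead:
    """A unique small-RNA sequence with per-sample occurrence counts."""

    id: str
    sequence: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.sequence) < 1:
            raise ValueError("empty read sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AlignmentRecord:
    """One exact placement of a read on the genome.

    ``five_prime`` is the genomic coordinate of the read's 5' nucleotide:
    ``start`` on the plus strand and ``end - 1`` on the minus strand.
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start
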