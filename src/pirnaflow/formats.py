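"""Reading and writing of the standard formats the pipeline touches.

FASTA/FASTQ parsing goes through :mod:`pysam` (``FastxFile``); GFF3 and all
tables are plain text handled with :mod:`pandas`.  GFF3 coordinates are
converted from 1-based inclusive to the package-internal 0-based half-open
convention on read, and back on write.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import AlignmentRecord, CollapsedRead, FeatureInterval

log = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into a ``{name: sequence}`` map.

    An empty file yields an empty map.  Malformed records raise
    :class:`ParseError`.
    """
    path = os.fspath(path)
    if os.path.getsize(path) == 0:
        return {}
    contigs: dict[str, str] = {}
    try:
        with pysam.FastxFile(path) as fh:
            for rec in fh:
                if rec.name in contigs:
                    raise ParseError(f"duplicate FASTA record {rec.name!r} in {path}")
                contigs[rec.name] = (rec.sequence or "").upper()
    except OSError as exc:  # pysam signals malformed input via OSError
        raise ParseError(f"malformed FASTA {path}: {exc}") from exc
    return contigs


def write_fasta(contigs: dict[str, str], path: str | os.PathLike, width: int = 80) -> str:
    path = os.fspath(path)
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_fastq(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> str:
    """Write ``(name, sequence)`` records as FASTQ with uniform quality 'I'."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def write_collapsed_fasta(reads: Sequence[CollapsedRead], path: str | os.PathLike) -> str:
    """Write collapsed reads with ``>seq<i>_x<count>`` headers."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f">seq{i}_x{r.total}\n{r.sequence}\n")
    return path


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = [
    "contig", "source", "ftype", "start", "end",
    "score", "strand", "phase", "attributes",
]


def _parse_attrs(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ParseError(f"malformed GFF3 attribute field: {text!r}")
        key, val = part.split("=", 1)
        attrs[key.strip()] = val.strip()
    return attrs


def read_gff3(path: str | os.PathLike) -> list[FeatureInterval]:
    """Read GFF3 into :class:`FeatureInterval` objects (0-based half-open).

    Output is ordered by ``(contig, start)``.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"contig": str}, na_filter=False,
    )
    feats = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise ParseError(f"GFF3 end < start ({start}, {end}) on {row.contig}")
        if row.strand not in ("+", "-"):
            raise ParseError(f"unknown strand symbol {row.strand!r} in GFF3")
        feats.append(
            FeatureInterval(
                contig=str(row.contig),
                start=start - 1,          # 1-based inclusive -> 0-based half-open
                end=end,
                strand=row.strand,
                ftype=str(row.ftype),
                attrs=_parse_attrs(str(row.attributes)),
            )
        )
    feats.sort(key=lambda f: (f.contig, f.start, f.end, f.ftype))
    return feats


def write_gff3(features: Sequence[FeatureInterval], path: str | os.PathLike,
               source: str = "pirnaflow") -> str:
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in sorted(f.attrs.items()))
            fh.write(
                f"{f.contig}\t{source}\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs or '.'}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Read collapsing
# ---------------------------------------------------------------------------

def collapse_reads(fastq_paths: Sequence[str | os.PathLike]) -> tuple[list[CollapsedRead], int]:
    """Collapse FASTQ files (one per sample) into unique sequences.

    Returns ``(reads, n_dropped)`` where ``counts[j]`` of each read is its
    occurrence count in sample ``j`` and ``n_dropped`` tallies reads that
    contained ``N`` (dropped, the exact-match mapper cannot place them).
    Characters outside ``{A,C,G,T,N}`` raise :class:`ParseError`.

    Output order is deterministic: descending pooled count, then sequence.
    """
    n_samples = len(fastq_paths)
    table: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(n_samples, dtype=np.int64))
    n_dropped = 0
    for j, path in enumerate(fastq_paths):
        path = os.fspath(path)
        if os.path.getsize(path) == 0:
            continue
        with pysam.FastxFile(path) as fh:
            for rec in fh:
                seq = rec.sequence.upper()
                if not VALID_ALPHABET.issuperset(seq):
                    bad = sorted(set(seq) - VALID_ALPHABET)
                    raise ParseError(f"invalid characters {bad} in {path}")
                if "N" in seq:
                    n_dropped += 1
                    continue
                table[seq][j] += 1
    if n_dropped:
        log.info("collapse_reads: dropped %d N-containing reads", n_dropped)
    order = sorted(table, key=lambda s: (-int(table[s].sum()), s))
    reads = [
        CollapsedRead(id=f"seq{i}", sequence=s, counts=table[s])
        for i, s in enumerate(order, start=1)
    ]
    return reads, n_dropped


# ---------------------------------------------------------------------------
# Tables and BED
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed6(alignments: Iterable[AlignmentRecord], scores: dict[str, int],
               path: str | os.PathLike) -> str:
    """Write alignments as BED6 (name=read id, score=pooled count)."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f"{a.contig}\t{a.start}\t{a.end}\t{a.read_id}\t"
                f"{scores.get(a.read_id, 0)}\t{a.strand}\n"
            )
    return path


def read_bed6(path: str | os.PathLike) -> list[AlignmentRecord]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "name": str},
    )
    return [
        AlignmentRecord(read_id=r.name, contig=r.contig, start=int(r.start),
                        end=int(r.end), strand=r.strand)
        for r in df.itertuples(index=False)
    ]
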