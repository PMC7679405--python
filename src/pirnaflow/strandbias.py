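"""Transposon length-by-strand spectra and the sense-bias test.

The spectrum tallies read-weighted counts per length and strand-sense for
transposon-assigned piRNAs (the wild-type brain shows a sense bias that a
functional piRNA scaffold maintains; ovaries show the reverse, antisense
bias).  The bias statistic is the weighted sense fraction with a two-sided
exact binomial test against parity (0.5) — exact rather than normal
approximation because desk-scale totals can be small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .annotate import CategoryAssignment


@dataclass(frozen=True)
class SpectrumRow:
    length: int
    sense_count: float
    antisense_count: float


@dataclass(frozen=True)
class BiasResult:
    sense_fraction: float
    p_parity: float
    n_total: float


def length_strand_spectrum(
    assignments: Sequence[CategoryAssignment],
    min_len: int = 18,
    max_len: int = 35,
) -> list[SpectrumRow]:
    """Weighted sense/antisense counts per read length.

    Only transposon-assigned reads are tallied; one row per length observed
    within ``[min_len, max_len]``, ordered by length.  Column sums equal
    the total transposon-assigned weight within the window.
    """
    sense: dict[int, float] = {}
    anti: dict[int, float] = {}
    for a in assignments:
        if a.category != "transposon":
            continue
        if not (min_len <= a.length <= max_len):
            continue
        if a.sense == "sense":
            sense[a.length] = sense.get(a.length, 0.0) + a.weight
        else:
            anti[a.length] = anti.get(a.length, 0.0) + a.weight
    lengths = sorted(set(sense) | set(anti))
    return [SpectrumRow(L, sense.get(L, 0.0), anti.get(L, 0.0)) for L in lengths]


def bias_test(spectrum: Sequence[SpectrumRow]) -> BiasResult:
    """Sense fraction and exact two-sided binomial p-value against 0.5.

    Weighted counts are rounded to integers for the exact test.  Raises
    ``ValueError`` on an empty spectrum (no transposon weight).
    """
    s = sum(row.sense_count for row in spectrum)
    a = sum(row.antisense_count for row in spectrum)
    n = s + a
    if n <= 0:
        raise ValueError("bias_test requires positive total weight")
    k, m = int(round(s)), int(round(s)) + int(round(a))
    p = stats.binomtest(k, m, 0.5, alternative="two-sided").pvalue if m > 0 else 1.0
    return BiasResult(sense_fraction=s / n, p_parity=float(p), n_total=n)


def spectrum_to_frame(spectrum: Sequence[SpectrumRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.length, r.sense_count, r.antisense_count) for r in spectrum],
        columns=["length", "sense", "antisense"],
    )


def plot_spectrum(spectrum: Sequence[SpectrumRow], path: str, title: str = "") -> str:
    """Render the paired-bar length spectrum to ``path`` (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = spectrum_to_frame(spectrum)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(df["length"] - 0.2, df["sense"], width=0.4, label="sense (+)")
    ax.bar(df["length"] + 0.2, df["antisense"], width=0.4, label="antisense (-)")
    ax.set_xlabel("piRNA length (nt)")
    ax.set_ylabel("weighted reads")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
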