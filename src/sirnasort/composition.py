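"""Per-bin nucleotide composition at guide positions g1/g2.

g1 is the 5'-terminal nucleotide of the guide (equal, for an anchored
siRNA, to the precursor's +1 nucleotide); g2 is the second position, whose
identity proxies the thermodynamic stability of the duplex's 5'-terminal
base pair: A/U ("weak") pairs are less stable than C/G ("strong") pairs.

Frequencies are tallied over distinct precursor species, unweighted by read
counts (the species-level view); pass ``weighted=True`` to weight each
species by its precursor read count for sensitivity analysis.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .ce import CERecord
from .seqio import to_rna

NUCLEOTIDES = ("A", "U", "C", "G")
WEAK = frozenset("AT")  # internal DNA alphabet; A/U pairs
STRONG = frozenset("CG")


@dataclass(frozen=True)
class BinComposition:
    n: int
    freqs: Mapping[str, float]  # keys are RNA letters A/U/C/G, or weak/strong


@dataclass(frozen=True)
class CompositionTable:
    """Per-bin nucleotide frequencies at one guide position."""

    position: int
    bins: Mapping[int, BinComposition] = field(default_factory=dict)
    symbols: tuple[str, ...] = NUCLEOTIDES

    def frequency(self, bin_id: int, symbol: str) -> float:
        return self.bins[bin_id].freqs[symbol]


@dataclass(frozen=True)
class StabilityClassTable:
    """Per-bin weak (A/U) vs strong (C/G) g2 frequencies, given a fixed g1."""

    g1_filter: str
    bins: Mapping[int, BinComposition] = field(default_factory=dict)
    symbols: tuple[str, ...] = ("weak", "strong")

    def frequency(self, bin_id: int, symbol: str) -> float:
        return self.bins[bin_id].freqs[symbol]


def _require_binned(records: Sequence[CERecord]) -> dict[int, list[CERecord]]:
    by_bin: dict[int, list[CERecord]] = {}
    for r in records:
        if r.bin is None:
            raise ValueError(f"record {r.p4rna_id} has no bin assigned")
        by_bin.setdefault(r.bin, []).append(r)
    return dict(sorted(by_bin.items()))


def positional_frequency(
    records: Sequence[CERecord], position: int, weighted: bool = False
) -> CompositionTable:
    """Frequency of each nucleotide at ``position`` (1-based), per bin."""
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    by_bin = _require_binned(records)
    bins: dict[int, BinComposition] = {}
    for b, recs in by_bin.items():
        if not recs:
            raise ValueError(f"bin {b} is empty")
        tally = {nt: 0.0 for nt in NUCLEOTIDES}
        for r in recs:
            if len(r.sequence) < position:
                raise ValueError(f"{r.p4rna_id}: sequence shorter than position {position}")
            w = r.p4rna_reads if weighted else 1
            tally[to_rna(r.sequence[position - 1])] += w
        total = sum(tally.values())
        bins[b] = BinComposition(
            n=len(recs), freqs={nt: tally[nt] / total for nt in NUCLEOTIDES}
        )
    return CompositionTable(position=position, bins=bins)


def stability_bias(
    records: Sequence[CERecord], g1_filter: str, weighted: bool = False
) -> StabilityClassTable:
    """Weak vs strong g2 class per bin, restricted to a given g1 nucleotide.

    Bins in which no species carries the requested g1 are reported with
    n = 0 and NaN frequencies (flagged, not an error).
    """
    g1 = g1_filter.upper().replace("U", "T")
    if g1 not in "ACGT" or len(g1) != 1:
        raise ValueError(f"g1_filter must be one nucleotide, got {g1_filter!r}")
    by_bin = _require_binned(records)
    bins: dict[int, BinComposition] = {}
    for b, recs in by_bin.items():
        weak = strong = 0.0
        n = 0
        for r in recs:
            if len(r.sequence) < 2:
                raise ValueError(f"{r.p4rna_id}: sequence too short for g2")
            if r.sequence[0] != g1:
                continue
            n += 1
            w = r.p4rna_reads if weighted else 1
            if r.sequence[1] in WEAK:
                weak += w
            else:
                strong += w
        if n == 0:
            bins[b] = BinComposition(n=0, freqs={"weak": math.nan, "strong": math.nan})
        else:
            total = weak + strong
            bins[b] = BinComposition(n=n, freqs={"weak": weak / total, "strong": strong / total})
    return StabilityClassTable(g1_filter=to_rna(g1), bins=bins)


def trend_summary(table: CompositionTable | StabilityClassTable, symbol: str) -> float:
    """freq(highest-CE bin) - freq(lowest-CE bin) for one symbol.

    Bins with n = 0 (possible after a g1 filter) are excluded; at least two
    populated bins are required.
    """
    if symbol not in table.symbols:
        raise ValueError(f"symbol {symbol!r} not in table ({table.symbols})")
    populated = [b for b, c in sorted(table.bins.items()) if c.n > 0]
    if len(populated) < 2:
        raise ValueError("trend requires at least two populated bins")
    return table.frequency(populated[-1], symbol) - table.frequency(populated[0], symbol)


# ---------------------------------------------------------------------------
# Serialization and plotting


def write_composition_tsv(table: CompositionTable | StabilityClassTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["bin", "n", *table.symbols])
        for b, comp in sorted(table.bins.items()):
            w.writerow([b, comp.n, *(repr(comp.freqs[s]) for s in table.symbols)])


def plot_composition(
    table: CompositionTable | StabilityClassTable, path: str | Path, title: str = ""
) -> None:
    """Stacked per-bin bar chart of the composition table (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = [b for b, c in sorted(table.bins.items()) if c.n > 0]
    bottom = [0.0] * len(bins)
    fig, ax = plt.subplots(figsize=(4, 3))
    for sym in table.symbols:
        vals = [table.frequency(b, sym) for b in bins]
        ax.bar([str(b) for b in bins], vals, bottom=bottom, label=sym)
        bottom = [bo + v for bo, v in zip(bottom, vals)]
    ax.set_xlabel("CE bin (1 = lowest)")
    ax.set_ylabel("frequency")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
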