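"""Conversion efficiency (CE) and quartile binning.

CE for a precursor species is the number of AGO-bound small-RNA reads whose
5' ends coincide exactly with the precursor's 5' end, divided by the number
of precursor reads.  It measures how readily a given precursor sequence is
diced and loaded into an Argonaute.  Species are then split into ``n_bins``
equal-size bins in ascending CE order (bin 1 = lowest CE, bin n = highest).

A siRNA counts toward a precursor iff it is an exact sense-strand prefix of
the precursor sequence (offset-0, zero-mismatch).  A siRNA that is a prefix
of k precursors contributes its full count to each of the k by default;
``fractional=True`` gives each 1/k instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .catalog import P4RNA
from .seqio import SmallRNARead, to_rna


@dataclass(frozen=True)
class CERecord:
    """Per-species conversion efficiency, with bin once assigned."""

    p4rna_id: str
    p4rna_reads: int
    sirna_reads: float
    ce: float
    sequence: str
    bin: int | None = None

    def __post_init__(self) -> None:
        if self.p4rna_reads < 1:
            raise ValueError(f"{self.p4rna_id}: p4rna_reads must be positive")
        if self.sirna_reads < 0:
            raise ValueError(f"{self.p4rna_id}: sirna_reads must be non-negative")


def count_anchored_sirnas(
    catalog: Sequence[P4RNA],
    sirna_reads: Iterable[SmallRNARead],
    fractional: bool = False,
    length_range: tuple[int, int] | None = None,
) -> dict[str, float]:
    """Summed counts of siRNA reads that are exact prefixes of each species.

    ``length_range`` (inclusive) optionally restricts which siRNA lengths
    are counted; by default any prefix-matching read counts.  Species with
    no matching read get 0.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    reads = [
        r
        for r in sirna_reads
        if length_range is None or length_range[0] <= len(r) <= length_range[1]
    ]
    lengths = sorted({len(r) for r in reads})
    # prefix index: species sequence prefix (at each observed read length) -> ids
    index: dict[str, list[str]] = {}
    for p in catalog:
        for L in lengths:
            if L <= len(p.sequence):
                index.setdefault(p.sequence[:L], []).append(p.id)
    counts: dict[str, float] = {p.id: 0.0 for p in catalog}
    for r in reads:
        matches = index.get(r.sequence, ())
        if not matches:
            continue
        w = r.count / len(matches) if fractional else float(r.count)
        for pid in matches:
            counts[pid] += w
    return counts


def compute_ce(counts: Mapping[str, float], catalog: Sequence[P4RNA]) -> list[CERecord]:
    """CE = sirna_reads / p4rna_reads, one record per catalog species.

    Species absent from ``counts`` get sirna_reads = 0 (ce = 0).
    """
    records = []
    for p in catalog:
        if p.read_count <= 0:
            raise ValueError(f"{p.id}: p4rna_reads must be positive for CE")
        s = float(counts.get(p.id, 0.0))
        records.append(
            CERecord(
                p4rna_id=p.id,
                p4rna_reads=p.read_count,
                sirna_reads=s,
                ce=s / p.read_count,
                sequence=p.sequence,
            )
        )
    return records


def assign_bins(records: Sequence[CERecord], n_bins: int = 4) -> list[CERecord]:
    """Split records into ``n_bins`` contiguous ascending-CE groups.

    Records are sorted by (ce, p4rna_id) — the id tie-break makes the split
    deterministic — and partitioned into bins whose sizes differ by at most
    one; when the count does not divide evenly, the lower-numbered bins take
    the extra record.  Bin 1 holds the lowest CEs.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = len(records)
    if n < n_bins:
        raise ValueError(f"cannot split {n} records into {n_bins} bins")
    ordered = sorted(records, key=lambda r: (r.ce, r.p4rna_id))
    base, extra = divmod(n, n_bins)
    out: list[CERecord] = []
    start = 0
    for b in range(1, n_bins + 1):
        size = base + (1 if b <= extra else 0)
        out.extend(replace(r, bin=b) for r in ordered[start : start + size])
        start += size
    return out


# ---------------------------------------------------------------------------
# Serialization

_TSV_COLS = ["p4rna_id", "p4rna_reads", "sirna_reads", "ce", "bin", "sequence"]


def write_ce_tsv(records: Sequence[CERecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLS)
        for r in records:
            w.writerow(
                [
                    r.p4rna_id,
                    r.p4rna_reads,
                    repr(r.sirna_reads),
                    repr(r.ce),
                    "" if r.bin is None else r.bin,
                    to_rna(r.sequence),
                ]
            )


def read_ce_tsv(path: str | Path) -> list[CERecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                CERecord(
                    p4rna_id=row["p4rna_id"],
                    p4rna_reads=int(row["p4rna_reads"]),
                    sirna_reads=float(row["sirna_reads"]),
                    ce=float(row["ce"]),
                    sequence=row["sequence"].upper().replace("U", "T"),
                    bin=int(row["bin"]) if row["bin"] else None,
                )
            )
    return out
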