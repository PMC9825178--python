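"""P4RNA catalog construction.

P4RNAs are 30-40 nt Pol IV transcripts; the catalog holds one species per
distinct 5' end.  Mapped precursor reads sharing a 5' anchor (cluster,
position, strand) are combined into a single species whose representative
sequence is the longest member (ties broken lexicographically, keeping
maximal 3' context for downstream positional analysis) and whose read count
is the sum over members.  Species are then kept only if strictly longer than
``min_length_exclusive`` nt and supported by strictly more than
``min_reads_exclusive`` reads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import AnchoredHit, SmallRNARead, to_rna


@dataclass(frozen=True)
class P4RNA:
    """One distinct precursor species surviving collapse (and filters)."""

    id: str
    sequence: str
    cluster: str
    position: int  # 0-based 5' position on the cluster
    strand: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError(f"P4RNA {self.id}: read_count must be >= 1")
        if not self.sequence:
            raise ValueError(f"P4RNA {self.id}: empty sequence")
        if self.position < 0:
            raise ValueError(f"P4RNA {self.id}: negative anchor position")

    @property
    def anchor(self) -> tuple[str, int, str]:
        return (self.cluster, self.position, self.strand)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CatalogParams:
    """Strict-inequality species filters (length > 30 nt, reads > 50)."""

    min_length_exclusive: int = 30
    min_reads_exclusive: int = 50

    def __post_init__(self) -> None:
        if self.min_length_exclusive < 0 or self.min_reads_exclusive < 0:
            raise ValueError("filter thresholds must be >= 0")


def collapse_by_five_prime(
    mapped_reads: Iterable[tuple[SmallRNARead, AnchoredHit]],
    strand: str = "+",
) -> list[P4RNA]:
    """Combine reads sharing a 5' end into one P4RNA species each.

    Groups by (cluster, offset, strand); per group the representative
    sequence is the longest member (ties -> lexicographically smallest) and
    read counts are summed.  Empty input yields an empty catalog.
    """
    groups: dict[tuple[str, int, str], tuple[str, int]] = {}
    for read, hit in mapped_reads:
        key = (hit.reference_id, hit.offset, strand)
        seq, total = groups.get(key, ("", 0))
        cand = read.sequence
        # longest wins; at equal length the lexicographically smaller wins
        if not seq or len(cand) > len(seq) or (len(cand) == len(seq) and cand < seq):
            seq = cand
        groups[key] = (seq, total + read.count)
    out = []
    for key in sorted(groups):
        cluster, pos, st = key
        seq, total = groups[key]
        out.append(
            P4RNA(
                id=f"{cluster}:{pos}:{st}",
                sequence=seq,
                cluster=cluster,
                position=pos,
                strand=st,
                read_count=total,
            )
        )
    return out


def filter_catalog(candidates: Iterable[P4RNA], params: CatalogParams | None = None) -> list[P4RNA]:
    """Keep species with length > min_length and read_count > min_reads.

    Both comparisons are strict; output is ordered by anchor.  Idempotent.
    """
    params = params or CatalogParams()
    kept = [
        p
        for p in candidates
        if len(p) > params.min_length_exclusive and p.read_count > params.min_reads_exclusive
    ]
    return sorted(kept, key=lambda p: p.anchor)


# ---------------------------------------------------------------------------
# Catalog serialization

_TSV_COLS = ["id", "cluster", "position", "strand", "length", "read_count", "sequence"]


def write_catalog_tsv(catalog: Sequence[P4RNA], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLS)
        for p in catalog:
            w.writerow(
                [p.id, p.cluster, p.position, p.strand, len(p), p.read_count, to_rna(p.sequence)]
            )


def read_catalog_tsv(path: str | Path) -> list[P4RNA]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                P4RNA(
                    id=row["id"],
                    sequence=row["sequence"].upper().replace("U", "T"),
                    cluster=row["cluster"],
                    position=int(row["position"]),
                    strand=row["strand"],
                    read_count=int(row["read_count"]),
                )
            )
    return out


def write_catalog_fasta(catalog: Sequence[P4RNA], path: str | Path) -> None:
    """FASTA of species sequences (ids carry the summed counts, ``_xN``)."""
    with open(path, "w") as fh:
        for p in catalog:
            fh.write(f">{p.id}_x{p.read_count}\n{to_rna(p.sequence)}\n")
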