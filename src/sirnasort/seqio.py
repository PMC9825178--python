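"""Sequence I/O, adapter trimming, and exact anchored matching.

Small-RNA reads and reference sequences are normalised to a single internal
DNA alphabet (``A C G T``; ``U`` is accepted on input and mapped to ``T``).
Mapping is exact-match only: ungapped, zero mismatches, sense strand.  This
is deliberately more conservative than a short-read aligner run with default
mismatch tolerance, and is the reproducible choice for desk-scale work;
replication against real libraries mapped with a mismatch-tolerant aligner
may retain slightly more reads.

Coordinates are 0-based, half-open throughout.  BED input is interpreted as
standard 0-based half-open intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

#: TruSeq small RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_VALID = frozenset("ACGT")
_COUNT_RE = re.compile(r"_x(\d+)$")


class ParseError(ValueError):
    """Raised when a sequence record violates the alphabet or count rules."""


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and map RNA ``U`` to internal ``T``.

    Raises :class:`ParseError` on symbols outside ``{A, C, G, U, T}``.
    """
    s = seq.upper().replace("U", "T")
    if not s:
        raise ParseError("empty sequence")
    bad = set(s) - _VALID
    if bad:
        raise ParseError(f"invalid symbols {sorted(bad)} in sequence {seq!r}")
    return s


def to_rna(seq: str) -> str:
    """Render an internal DNA-alphabet sequence as RNA (T -> U)."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class SmallRNARead:
    """A collapsed small-RNA read: sequence, multiplicity and a label."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.count < 1:
            raise ParseError(f"read {self.id!r}: count must be >= 1, got {self.count}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceSet:
    """Named reference sequences: either Pol IV clusters or P4RNA species."""

    entries: Mapping[str, str]
    kind: str = "cluster"  # "cluster" | "p4rna"

    def __post_init__(self) -> None:
        norm = {rid: normalize_sequence(s) for rid, s in self.entries.items()}
        object.__setattr__(self, "entries", norm)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AnchoredHit:
    """One exact sense-strand occurrence of a read on a reference.

    ``anchored`` is true iff the read's 5' end coincides with the
    reference's 5' end (offset 0).
    """

    read_id: str
    reference_id: str
    offset: int

    @property
    def anchored(self) -> bool:
        return self.offset == 0


@dataclass(frozen=True)
class TrimResult:
    read: SmallRNARead | None  # None when the trimmed read fell below min_length
    trimmed: bool


def trim_adapter(
    read: SmallRNARead,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 8,
    min_length: int = 15,
) -> TrimResult:
    """Remove a 3' adapter by exact prefix-suffix match.

    A match is the leftmost position at which the remainder of the read
    equals a prefix of the adapter (at least ``min_overlap`` nt; the whole
    adapter if the read extends past it, in which case everything 3' of the
    match is also removed).  Trimming repeats until no match remains, so the
    operation is idempotent.  A trimmed sequence shorter than ``min_length``
    is discarded (``read=None``).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ad = normalize_sequence(adapter)
    seq = read.sequence
    trimmed = False
    while True:
        cut = _find_adapter(seq, ad, min_overlap)
        if cut is None:
            break
        seq = seq[:cut]
        trimmed = True
        if not seq:
            break
    if not trimmed:
        return TrimResult(read, False)
    if len(seq) < min_length:
        return TrimResult(None, True)
    return TrimResult(replace(read, sequence=seq), True)


def _find_adapter(seq: str, adapter: str, min_overlap: int) -> int | None:
    for i in range(len(seq) - min_overlap + 1):
        m = min(len(adapter), len(seq) - i)
        if seq[i : i + m] == adapter[:m]:
            return i
    return None


def map_to_references(read: SmallRNARead, refs: ReferenceSet) -> list[AnchoredHit]:
    """Every exact, ungapped, sense-strand occurrence of ``read`` in ``refs``.

    Hits are ordered by reference id, then offset.  No hits -> empty list.
    """
    hits: list[AnchoredHit] = []
    for rid in sorted(refs.entries):
        ref = refs.entries[rid]
        start = ref.find(read.sequence)
        while start != -1:
            hits.append(AnchoredHit(read.id, rid, start))
            start = ref.find(read.sequence, start + 1)
    return hits


def map_reads_bulk(
    reads: Iterable[SmallRNARead], refs: ReferenceSet
) -> list[tuple[SmallRNARead, AnchoredHit]]:
    """Map many reads at once via a window index over the references.

    Agrees with :func:`map_to_references` read-by-read but runs in
    O(|refs| x distinct read lengths) index-build time instead of scanning
    every reference per read.  Output order: reads in input order, each
    read's hits by (reference id, offset).
    """
    reads = list(reads)
    lengths = sorted({len(r) for r in reads})
    index: dict[str, list[tuple[str, int]]] = {}
    for rid in sorted(refs.entries):
        ref = refs.entries[rid]
        for L in lengths:
            for off in range(len(ref) - L + 1):
                index.setdefault(ref[off : off + L], []).append((rid, off))
    out: list[tuple[SmallRNARead, AnchoredHit]] = []
    for r in reads:
        for rid, off in index.get(r.sequence, ()):
            out.append((r, AnchoredHit(r.id, rid, off)))
    return out


def anchored_filter(hits: Iterable[AnchoredHit]) -> list[AnchoredHit]:
    """Keep only hits whose 5' end coincides with the reference 5' end."""
    return [h for h in hits if h.offset == 0]


# ---------------------------------------------------------------------------
# File readers/writers


def _read_count_from_id(rid: str) -> int:
    m = _COUNT_RE.search(rid)
    return int(m.group(1)) if m else 1


def read_small_rnas(path: str | Path, fmt: str | None = None) -> list[SmallRNARead]:
    """Read collapsed small RNAs from FASTA or FASTQ.

    FASTA ids of the form ``name_xN`` carry a collapsed count of N; any
    other id gets count 1.  Format is inferred from the suffix unless given
    (``fasta`` or ``fastq``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        reads.append(
            SmallRNARead(id=rec.id, sequence=str(rec.seq), count=_read_count_from_id(rec.id))
        )
    return reads


def write_small_rnas_fasta(reads: Iterable[SmallRNARead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with ``id_xN`` count-carrying headers."""
    with open(path, "w") as fh:
        for r in reads:
            rid = r.id if _COUNT_RE.search(r.id) else f"{r.id}_x{r.count}"
            fh.write(f">{rid}\n{to_rna(r.sequence)}\n")


def read_fasta_references(path: str | Path, kind: str = "cluster") -> ReferenceSet:
    entries = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return ReferenceSet(entries=entries, kind=kind)


def _iter_bed(path: str | Path) -> Iterator[tuple[str, int, int, str]]:
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{i + 1}: BED line needs >= 3 fields")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
            if not 0 <= start < end:
                raise ParseError(f"{path}:{i + 1}: bad interval [{start}, {end})")
            yield chrom, start, end, name


def read_cluster_references(bed_path: str | Path, genome_fasta: str | Path) -> ReferenceSet:
    """Extract cluster sequences for BED intervals from a genome FASTA.

    Intervals are 0-based half-open; ids come from the BED name column.
    """
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    entries: dict[str, str] = {}
    for chrom, start, end, name in _iter_bed(bed_path):
        if chrom not in genome:
            raise ParseError(f"BED chromosome {chrom!r} absent from genome FASTA")
        if end > len(genome[chrom]):
            raise ParseError(f"interval {name} exceeds {chrom} length {len(genome[chrom])}")
        if name in entries:
            raise ParseError(f"duplicate cluster id {name!r}")
        entries[name] = genome[chrom][start:end]
    return ReferenceSet(entries=entries, kind="cluster")
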