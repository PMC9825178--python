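"""Generative model of heterochromatic siRNA biogenesis and AGO loading.

The simulator mimics the canonical RdDM biogenesis chain at species level:

* Pol IV transcribes one 31-40 nt single-stranded precursor per locus, with
  a +1 (first-nucleotide) bias toward purines, A in particular;
* per-locus expression is heavy-tailed: locus means are log-normal and read
  counts are negative-binomial around them, rescaled to a fixed precursor
  sequencing depth by a multinomial draw;
* dicing yields 5'-anchored guides of 19-25 nt, so guide g1 equals the
  precursor +1 nucleotide;
* AGO loading draws a fixed depth of bound reads multinomially over guides,
  with per-guide weight = precursor abundance x 5'-nucleotide weight x a
  g2 weak-pair multiplier x a guide-length weight.

The duplex passenger strand is not represented; g2 identity on the guide is
the terminal-pair stability proxy.  Dicing end preference is absorbed into
the loading weights by default; ``dicing_bias`` keyed on the precursor +1
nucleotide can be enabled to study biogenesis-vs-loading confounding.

Every stage draws from an independent substream derived from one top-level
seed, so identical parameters give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import SmallRNARead, to_rna, write_small_rnas_fasta

_NTS = "ACGT"  # internal DNA alphabet; parameters use RNA keys A/U/C/G
_SAMPLE_NTS = "ATCG"  # DNA letters aligned with the A/U/C/G weight-vector order


def _weights_vector(w: Mapping[str, float]) -> np.ndarray:
    v = np.array([w.get(nt, w.get("T" if nt == "U" else nt, 0.0)) for nt in "AUCG"], float)
    if (v < 0).any():
        raise ValueError("nucleotide weights must be >= 0")
    if v.sum() == 0:
        raise ValueError("nucleotide weights must not all be zero")
    return v


# AGO4-like preset: relative loading efficiencies of 5' U/C/G vs A
# (~50%, ~20%, ~30%) measured in vitro.
AGO4_LIKE_5P_WEIGHTS = {"A": 1.0, "U": 0.5, "C": 0.2, "G": 0.3}
# AGO6-like preset: a strict-5'A caricature (no measured AGO6 weights exist).
AGO6_LIKE_5P_WEIGHTS = {"A": 1.0, "U": 0.05, "C": 0.05, "G": 0.05}
NEUTRAL_5P_WEIGHTS = {"A": 1.0, "U": 1.0, "C": 1.0, "G": 1.0}

#: Default guide-length weights: both AGOs prefer 23-25 nt with a 24-nt peak.
DEFAULT_LENGTH_WEIGHTS = {19: 0.05, 20: 0.05, 21: 0.1, 22: 0.15, 23: 0.6, 24: 1.0, 25: 0.5}


@dataclass(frozen=True)
class BiogenesisParams:
    """Pol IV transcription and precursor-abundance model."""

    n_loci: int = 2000
    length_range: tuple[int, int] = (31, 40)
    # +1 bias toward A and G, A strongest (~60% of 24-nt siRNAs carry 5' A)
    plus_one_weights: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.5, "G": 0.3, "C": 0.1, "U": 0.1}
    )
    body_composition: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "U": 0.25, "C": 0.25, "G": 0.25}
    )
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 1.2
    abundance_dispersion: float = 0.3
    precursor_depth: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("length_range must satisfy 0 < lo <= hi")
        if self.n_loci < 1 or self.precursor_depth < 1:
            raise ValueError("n_loci and precursor_depth must be positive")
        _weights_vector(self.plus_one_weights)
        _weights_vector(self.body_composition)


@dataclass(frozen=True)
class LoadingParams:
    """AGO loading preference model: 5' identity x g2 stability x length."""

    five_prime_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(AGO4_LIKE_5P_WEIGHTS)
    )
    g2_stability_weight: float = 1.0  # multiplier when g2 is A or U (weak pair)
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    sirna_depth: int = 100_000
    seed: int = 0
    # optional dicing end-preference keyed on the precursor +1 nucleotide
    # (equal to guide g1 for anchored guides); None leaves dicing neutral
    dicing_bias: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        _weights_vector(self.five_prime_weights)
        if self.dicing_bias is not None:
            _weights_vector(self.dicing_bias)
        if self.g2_stability_weight < 0:
            raise ValueError("g2_stability_weight must be >= 0")
        if self.sirna_depth < 1:
            raise ValueError("sirna_depth must be >= 1")
        if not self.length_weights or any(w < 0 for w in self.length_weights.values()):
            raise ValueError("length_weights must be non-empty and >= 0")


@dataclass(frozen=True)
class Locus:
    id: str
    sequence: str  # precursor, internal DNA alphabet
    count: int  # precursor reads


@dataclass(frozen=True)
class Guide:
    sequence: str
    locus_id: str
    abundance: float  # source precursor abundance


@dataclass(frozen=True)
class SyntheticDataset:
    precursors: list[SmallRNARead]
    sirnas: list[SmallRNARead]
    loci: list[Locus]
    bio: BiogenesisParams
    load: LoadingParams
    anchors: dict[str, int]  # locus id -> precursor start within its cluster
    clusters: dict[str, str]  # cluster id -> sequence (precursor + flanks)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def simulate_p4rna_pool(params: BiogenesisParams) -> list[Locus]:
    """Draw precursor species and heavy-tailed per-locus read counts.

    Counts are rescaled to ``precursor_depth`` exactly via a multinomial
    draw over the negative-binomial locus counts; loci drawn to zero remain
    in the output with count 0 (they produce no reads downstream).
    """
    rng_seq = _rng(params.seed, 0)
    rng_abund = _rng(params.seed, 1)
    lo, hi = params.length_range
    p1 = _weights_vector(params.plus_one_weights)
    body = _weights_vector(params.body_composition)
    lengths = rng_seq.integers(lo, hi + 1, size=params.n_loci)
    loci: list[Locus] = []
    seqs = []
    for i in range(params.n_loci):
        first = _SAMPLE_NTS[rng_seq.choice(4, p=p1 / p1.sum())]
        rest = "".join(
            _SAMPLE_NTS[j]
            for j in rng_seq.choice(4, size=int(lengths[i]) - 1, p=body / body.sum())
        )
        seqs.append(first + rest)
    mu = rng_abund.lognormal(params.abundance_log_mean, params.abundance_log_sd, params.n_loci)
    mu *= params.precursor_depth / mu.sum()
    k = params.abundance_dispersion
    raw = rng_abund.negative_binomial(k, k / (k + mu)).astype(float)
    if raw.sum() == 0:
        raw = mu  # degenerate draw: fall back to expected abundances
    counts = rng_abund.multinomial(params.precursor_depth, raw / raw.sum())
    width = len(str(params.n_loci))
    for i in range(params.n_loci):
        loci.append(Locus(id=f"locus{i:0{width}d}", sequence=seqs[i], count=int(counts[i])))
    return loci


def dice_to_guides(precursor: str, lengths: Sequence[int]) -> list[str]:
    """5'-anchored prefixes of the precursor at each requested length."""
    seq = precursor.upper().replace("U", "T")
    out = []
    for L in lengths:
        if L > len(seq):
            raise ValueError(f"guide length {L} exceeds precursor length {len(seq)}")
        out.append(seq[:L])
    return out


def simulate_loading(guides: Sequence[Guide], params: LoadingParams) -> list[SmallRNARead]:
    """Multinomial draw of AGO-bound reads over guides.

    Weight per guide: abundance x 5'-nucleotide weight x g2 weak-pair
    multiplier x length weight.  Returns collapsed species (identical guide
    sequences aggregated), ordered by sequence.
    """
    w5 = {nt: params.five_prime_weights.get(to_rna(nt), 0.0) for nt in _NTS}
    dicing = (
        {nt: params.dicing_bias.get(to_rna(nt), 0.0) for nt in _NTS}
        if params.dicing_bias is not None
        else None
    )
    weights = np.empty(len(guides))
    for i, g in enumerate(guides):
        w = g.abundance * w5[g.sequence[0]] * params.length_weights.get(len(g.sequence), 0.0)
        if g.sequence[1] in "AT":
            w *= params.g2_stability_weight
        if dicing is not None:
            w *= dicing[g.sequence[0]]
        weights[i] = w
    if weights.sum() <= 0:
        raise ValueError("all guide weights are zero; nothing to load")
    rng = _rng(params.seed, 2)
    draws = rng.multinomial(params.sirna_depth, weights / weights.sum())
    by_seq: dict[str, int] = {}
    for g, c in zip(guides, draws):
        if c:
            by_seq[g.sequence] = by_seq.get(g.sequence, 0) + int(c)
    return [
        SmallRNARead(id=f"sirna{i:06d}", sequence=s, count=c)
        for i, (s, c) in enumerate(sorted(by_seq.items()))
    ]


def guides_from_loci(loci: Sequence[Locus], lengths: Sequence[int]) -> list[Guide]:
    """All 5'-anchored guides from expressed loci, carrying locus abundance."""
    out = []
    for loc in loci:
        if loc.count <= 0:
            continue
        for g in dice_to_guides(loc.sequence, lengths):
            out.append(Guide(sequence=g, locus_id=loc.id, abundance=float(loc.count)))
    return out


def make_dataset(
    bio: BiogenesisParams,
    load: LoadingParams,
    outdir: str | Path | None = None,
    flank: int = 10,
) -> SyntheticDataset:
    """Simulate a full dataset and (optionally) write it to ``outdir``.

    Files written: ``precursors.fasta`` and ``sirnas.fasta`` (collapsed,
    ``id_xN`` counts), ``clusters.bed`` + ``genome.fasta`` (one cluster per
    locus, the precursor embedded between random flanks), and
    ``ground_truth.json``.  Identical parameters -> byte-identical files.
    """
    loci = simulate_p4rna_pool(bio)
    lengths = sorted(params_lengths(load))
    guides = guides_from_loci(loci, lengths)
    sirnas = simulate_loading(guides, load)
    rng_flank = _rng(bio.seed, 3)
    anchors = {}
    genome: dict[str, str] = {}
    for loc in loci:
        f5 = "".join(_NTS[j] for j in rng_flank.integers(0, 4, flank))
        f3 = "".join(_NTS[j] for j in rng_flank.integers(0, 4, flank))
        genome[loc.id] = f5 + loc.sequence + f3
        anchors[loc.id] = flank
    precursors = [
        SmallRNARead(id=f"{loc.id}", sequence=loc.sequence, count=loc.count)
        for loc in loci
        if loc.count > 0
    ]
    ds = SyntheticDataset(
        precursors=precursors,
        sirnas=sirnas,
        loci=list(loci),
        bio=bio,
        load=load,
        anchors=anchors,
        clusters=genome,
    )
    if outdir is not None:
        _write_dataset(ds, genome, Path(outdir))
    return ds


def params_lengths(load: LoadingParams) -> list[int]:
    return [L for L, w in load.length_weights.items() if w > 0]


def _write_dataset(ds: SyntheticDataset, genome: Mapping[str, str], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_small_rnas_fasta(ds.precursors, outdir / "precursors.fasta")
    write_small_rnas_fasta(ds.sirnas, outdir / "sirnas.fasta")
    with open(outdir / "genome.fasta", "w") as fh:
        for cid in sorted(genome):
            fh.write(f">{cid}\n{genome[cid]}\n")
    with open(outdir / "clusters.bed", "w") as fh:
        for cid in sorted(genome):
            fh.write(f"{cid}\t0\t{len(genome[cid])}\t{cid}\n")
    truth = {
        "biogenesis": _params_dict(ds.bio),
        "loading": _params_dict(ds.load),
        "anchors": ds.anchors,
        "locus_counts": {loc.id: loc.count for loc in ds.loci},
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _params_dict(p) -> dict:
    d = dataclasses.asdict(p)
    for key in ("plus_one_weights", "body_composition", "five_prime_weights"):
        if key in d:
            d[key] = dict(d[key])
    if "length_weights" in d:
        d["length_weights"] = {str(k): v for k, v in d["length_weights"].items()}
    if "length_range" in d:
        d["length_range"] = list(d["length_range"])
    return d
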