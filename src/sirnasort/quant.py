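"""Quantification of in vitro RISC-assembly gel readouts.

Band intensities (arbitrary units, one value per condition x replicate)
enter as a long-format table.  Two normalisations are provided: relative to
a reference condition (e.g. the 5' A duplex) within each replicate, and
relative to the replicate total (length-distribution view).  Paired
two-sided t-tests with Benjamini-Hochberg FDR correction compare declared
condition pairs across replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_COLS = ["condition", "replicate", "intensity"]


def read_measurements_tsv(path: str | Path) -> pd.DataFrame:
    """Read a condition/replicate/intensity TSV into a long DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"condition": str})
    missing = set(_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement TSV missing columns {sorted(missing)}")
    return validate_measurements(df)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    df = df[_COLS].copy()
    df["intensity"] = df["intensity"].astype(float)
    if (df["intensity"] < 0).any():
        raise ValueError("intensities must be non-negative")
    if df.duplicated(["condition", "replicate"]).any():
        raise ValueError("duplicate condition/replicate measurements")
    return df


def _pivot(df: pd.DataFrame) -> pd.DataFrame:
    """replicate x condition intensity matrix; NaN marks missing cells."""
    return validate_measurements(df).pivot(
        index="replicate", columns="condition", values="intensity"
    )


@dataclass(frozen=True)
class RelativeEfficiency:
    """Per-replicate reference-normalised values with mean and sample SD."""

    reference: str
    per_replicate: pd.DataFrame  # replicate x condition
    mean: pd.Series
    sd: pd.Series  # ddof=1


def normalize_to_reference(df: pd.DataFrame, reference: str) -> RelativeEfficiency:
    """Divide each condition by the reference condition, per replicate.

    The reference must be present with positive intensity in every
    replicate (its normalised value is exactly 1 everywhere).  Invariant to
    uniform rescaling of any replicate's intensities.
    """
    mat = _pivot(df)
    if reference not in mat.columns:
        raise ValueError(f"reference condition {reference!r} absent")
    ref = mat[reference]
    if ref.isna().any() or (ref <= 0).any():
        bad = ref.index[ref.isna() | (ref <= 0)].tolist()
        raise ValueError(f"reference {reference!r} missing or non-positive in replicates {bad}")
    norm = mat.div(ref, axis=0)
    return RelativeEfficiency(
        reference=reference, per_replicate=norm, mean=norm.mean(), sd=norm.std(ddof=1)
    )


@dataclass(frozen=True)
class TotalNormalizedDistribution:
    """Per-replicate total-normalised fractions (sum to 1 per replicate)."""

    per_replicate: pd.DataFrame
    mean: pd.Series
    sd: pd.Series


def total_normalized_distribution(df: pd.DataFrame) -> TotalNormalizedDistribution:
    """Divide each condition by the replicate's total intensity."""
    mat = _pivot(df)
    totals = mat.sum(axis=1, skipna=True)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"replicates with zero total intensity: {bad}")
    frac = mat.div(totals, axis=0)
    return TotalNormalizedDistribution(per_replicate=frac, mean=frac.mean(), sd=frac.std(ddof=1))


@dataclass(frozen=True)
class TestResult:
    comparison: str
    t: float
    p_raw: float
    p_adj: float
    degenerate: bool = False  # zero-variance paired differences; no p reported


def paired_t_bh(
    df: pd.DataFrame, comparisons: Sequence[tuple[str, str]]
) -> list[TestResult]:
    """Two-sided paired t-tests with Benjamini-Hochberg FDR adjustment.

    Adjustment is computed across all non-degenerate comparisons requested.
    A comparison whose paired differences have zero variance is flagged
    degenerate (t and p reported as NaN) and excluded from the adjustment
    with a warning.
    """
    mat = _pivot(df)
    if len(mat) < 2:
        raise ValueError("paired t-tests need at least 2 replicates")
    results: list[TestResult] = []
    raw: list[float] = []
    live_idx: list[int] = []
    for i, (a, b) in enumerate(comparisons):
        for c in (a, b):
            if c not in mat.columns:
                raise ValueError(f"condition {c!r} absent from measurements")
        xa, xb = mat[a], mat[b]
        if xa.isna().any() or xb.isna().any():
            raise ValueError(f"incomplete pairing for comparison {a} vs {b}")
        diffs = xa - xb
        label = f"{a} vs {b}"
        if float(diffs.std(ddof=1)) == 0.0:
            warnings.warn(f"zero-variance paired differences for {label}; p undefined")
            results.append(TestResult(label, math.nan, math.nan, math.nan, degenerate=True))
            continue
        t, p = stats.ttest_rel(xa, xb)
        results.append(TestResult(label, float(t), float(p), math.nan))
        raw.append(float(p))
        live_idx.append(len(results) - 1)
    if raw:
        _, p_adj, _, _ = multipletests(raw, method="fdr_bh")
        for i, pa in zip(live_idx, p_adj):
            r = results[i]
            results[i] = TestResult(r.comparison, r.t, r.p_raw, float(pa))
    return results


def write_test_results_tsv(results: Sequence[TestResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "comparison": r.comparison,
                "t": r.t,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
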