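"""Relative abundance, detection, prevalence and size-fraction enrichment.

The abundance model follows the single-copy-gene normalization idea: the
pooled sequencing depth of a universal single-copy marker (rpoB) in a
metagenome is a proxy for the genome-equivalent depth of the whole community,
so

    relative abundance of a MAG  =  TAD(MAG) / depth(rpoB pool)

A population counts as *detected* when its abundance strictly exceeds a
threshold (default 0.01% == 1e-4, roughly 2x coverage in the source setting).
Prevalence is the percentage of samples (optionally a subset) in which a
genome is detected. Size-fraction enrichment replaces a DESeq2 fit with a
plain normalized log2 ratio between mean proportions of two filter fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import TabularAlignment

__all__ = [
    "MarkerDepth",
    "EnrichmentResult",
    "marker_depth",
    "simple_marker_filter",
    "relative_abundance",
    "detect",
    "prevalence",
    "fraction_enrichment",
]


@dataclass(frozen=True)
class MarkerDepth:
    """Pooled marker-gene (rpoB) sequencing depth in one sample."""

    sample_id: str
    total_bases: float
    reference_length: float  # effective (mean) marker gene length, bp

    def __post_init__(self) -> None:
        if self.reference_length <= 0:
            raise ValueError("effective marker reference length must be > 0")
        if self.total_bases < 0:
            raise ValueError("total aligned bases must be >= 0")

    @property
    def depth(self) -> float:
        return self.total_bases / self.reference_length


def marker_depth(
    filtered_hits: Iterable[TabularAlignment],
    reference_lengths: Sequence[float],
    sample_id: str = "",
) -> MarkerDepth:
    """Marker depth = total aligned bases / mean reference gene length.

    ``filtered_hits`` must already be restricted to bona fide marker reads
    (the upstream ROCker-style filtering step); :func:`simple_marker_filter`
    provides a plain score/identity filter for that purpose.
    """
    if len(reference_lengths) == 0:
        raise ValueError("reference_lengths must be non-empty")
    total = float(sum(a.length for a in filtered_hits))
    if total == 0.0:
        warnings.warn(f"no marker hits for sample {sample_id!r}; marker depth is 0", stacklevel=2)
    mean_len = float(sum(reference_lengths)) / len(reference_lengths)
    return MarkerDepth(sample_id, total, mean_len)


def simple_marker_filter(
    hits: Iterable[TabularAlignment], min_bitscore: float = 0.0, min_pident: float = 0.0
) -> list[TabularAlignment]:
    """Threshold filter standing in for model-based marker-read classification."""
    if min_bitscore < 0 or min_pident < 0:
        raise ValueError("thresholds must be >= 0")
    return [a for a in hits if a.bitscore >= min_bitscore and a.pident >= min_pident]


def relative_abundance(tad_value: float, marker: MarkerDepth) -> float:
    """Fraction of the community a genome represents: TAD / marker depth."""
    if tad_value < 0:
        raise ValueError("TAD must be >= 0")
    if marker.depth == 0:
        raise ValueError(
            f"marker depth is zero in sample {marker.sample_id!r}; abundance is undefined"
        )
    return tad_value / marker.depth


def detect(abundance: float, threshold: float = 1e-4) -> bool:
    """Detection is *strictly* greater than the threshold (default 0.01%)."""
    if abundance < 0:
        raise ValueError("abundance must be >= 0")
    return abundance > threshold


def _truncate1(x: float) -> float:
    """Truncate toward zero to one decimal (65.789 -> 65.7), as printed."""
    return math.floor(x * 10.0 + 1e-9) / 10.0


def prevalence(
    detections: pd.DataFrame, subset: Sequence[str] | None = None
) -> pd.Series:
    """Percent of samples in which each genome is detected, one decimal.

    ``detections`` is a boolean genome x sample frame; ``subset`` restricts
    the denominator to those sample columns.
    """
    if subset is None:
        cols = list(detections.columns)
    else:
        cols = list(subset)
        missing = set(cols) - set(detections.columns)
        if missing:
            raise ValueError(f"subset samples not in detection table: {sorted(missing)}")
    if len(cols) == 0:
        raise ValueError("prevalence over an empty sample subset is undefined")
    frac = detections[cols].astype(bool).sum(axis=1) / len(cols)
    return (100.0 * frac).map(_truncate1)


@dataclass(frozen=True)
class EnrichmentResult:
    """log2 fold change of one feature between small and large size fractions."""

    feature_id: str
    mean_small: float
    mean_large: float
    log2_fold_change: float
    classification: str  # small_enriched | large_enriched | neutral


def _to_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    sums = counts.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    return counts / sums


def fraction_enrichment(
    counts_small: pd.DataFrame,
    counts_large: pd.DataFrame,
    pseudocount: float | None = None,
    log2_small_threshold: float = 2.0,
    log2_large_threshold: float = -1.0,
) -> list[EnrichmentResult]:
    """Classify features as enriched in the small or large size fraction.

    Count tables (features x samples) are column-normalized to proportions and
    averaged within each fraction; the log2 fold change is
    ``log2((m_small + p) / (m_large + p))`` with pseudocount ``p`` defaulting
    to half the smallest nonzero proportion observed in either table.
    Features above ``log2_small_threshold`` are ``small_enriched``, below
    ``log2_large_threshold`` ``large_enriched``, otherwise ``neutral``.
    """
    if set(counts_small.index) != set(counts_large.index):
        raise ValueError("feature sets of the two fraction tables differ")
    counts_large = counts_large.loc[counts_small.index]
    prop_s = _to_proportions(counts_small.astype(float))
    prop_l = _to_proportions(counts_large.astype(float))
    if pseudocount is None:
        nonzero = pd.concat([prop_s.stack(), prop_l.stack()])
        nonzero = nonzero[nonzero > 0]
        if nonzero.empty:
            raise ValueError("all proportions are zero; cannot derive a pseudocount")
        pseudocount = float(nonzero.min()) / 2.0
    m_s = prop_s.mean(axis=1)
    m_l = prop_l.mean(axis=1)
    out: list[EnrichmentResult] = []
    for feat in counts_small.index:
        l2 = math.log2((m_s[feat] + pseudocount) / (m_l[feat] + pseudocount))
        if l2 > log2_small_threshold:
            cls = "small_enriched"
        elif l2 < log2_large_threshold:
            cls = "large_enriched"
        else:
            cls = "neutral"
        out.append(EnrichmentResult(str(feat), float(m_s[feat]), float(m_l[feat]), l2, cls))
    return out
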