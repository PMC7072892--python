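"""Sequence-level characterization of false-positive miRNAs.

Microarray probes with high GC-content hybridize more stably (three hydrogen
bonds per G:C pair versus two for A:T), so they tolerate mismatched targets —
a proposed mechanism for miRNAs that light up on arrays yet show no reads in
matched sequencing. This module computes probe GC-content, counts approximate
(Hamming-distance, substitutions-only) occurrences of a probe sequence in a
genome on both strands, identifies false-positive miRNAs (high array signal,
no sequencing signal), and compares sequence features between the
false-positive group and the remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .validation import _mannwhitney

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")

# byte codes used by the vectorized scanner
_N_CODE = ord("N")


def _normalize(seq: str, label: str = "sequence") -> str:
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise ValueError(f"{label} is empty")
    if not set(seq) <= _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"{label} contains invalid characters: {bad}")
    return seq


def gc_content(seq: str) -> float:
    """Fraction of G and C bases, N bases excluded from the denominator."""
    seq = _normalize(seq)
    informative = len(seq) - seq.count("N")
    if informative == 0:
        raise ValueError("sequence has no informative (non-N) bases")
    return (seq.count("G") + seq.count("C")) / informative


def reverse_complement(seq: str) -> str:
    return str(Seq(_normalize(seq)).reverse_complement())


def _mismatch_positions(pattern: np.ndarray, text: np.ndarray) -> np.ndarray:
    """Number of window start positions at each Hamming distance <= len(pattern).

    Returns the per-position mismatch counts for sliding ``pattern`` along
    ``text`` (both uint8 byte arrays). N in either string counts as a mismatch.
    """
    n_windows = text.size - pattern.size + 1
    mismatches = np.zeros(n_windows, dtype=np.int32)
    for offset, base in enumerate(pattern):
        window = text[offset : offset + n_windows]
        # N never matches: base==N makes `window != base` true for all non-N
        # windows and the second clause catches N-vs-N
        mismatches += (window != base) | (window == _N_CODE)
    return mismatches


def count_genomic_occurrences(
    pattern: str,
    genome: str | Iterable[str],
    max_mismatches: int = 2,
    both_strands: bool = True,
) -> int:
    """Count approximate occurrences of a probe sequence in a genome.

    Every alignment start position whose Hamming distance (substitutions
    only, no gaps) to the pattern is at most ``max_mismatches`` counts once,
    on the forward strand and — unless ``both_strands`` is disabled — for the
    reverse complement of the pattern against the forward text. Overlapping
    sites all count; counts are summed over genome records. A pattern longer
    than every record yields 0 with a warning.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    pattern = _normalize(pattern, "pattern")
    records = [genome] if isinstance(genome, str) else list(genome)
    if not records:
        raise ValueError("no genome records supplied")
    queries = [pattern]
    if both_strands:
        queries.append(reverse_complement(pattern))
    total = 0
    scanned_any = False
    for record in records:
        record = _normalize(record, "genome record")
        if len(record) < len(pattern):
            continue
        scanned_any = True
        text = np.frombuffer(record.encode("ascii"), dtype=np.uint8)
        for query in queries:
            q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
            mism = _mismatch_positions(q, text)
            total += int(np.count_nonzero(mism <= max_mismatches))
    if not scanned_any:
        logger.warning(
            "pattern of length %d exceeds every genome record; count is 0",
            len(pattern),
        )
    return total


@dataclass(frozen=True)
class FalsePositiveCall:
    """Classification of one miRNA as false positive or not.

    A false positive is highly expressed on the array (median at or above the
    top-quantile cutoff) yet not expressed in the sequencing reference
    (median RPM at or below the expressed cutoff).
    """

    name: str
    array_median: float
    seq_rpm: float
    is_false_positive: bool


def identify_false_positives(
    array_medians: Mapping[str, float] | pd.Series,
    reference: pd.Series,
    top_quantile: float = 0.90,
    expressed_cutoff: float = 0.0,
) -> list[FalsePositiveCall]:
    """Call false-positive miRNAs from paired array and sequencing medians.

    The array-expression cutoff is the empirical ``top_quantile`` quantile
    (linear interpolation, boundary inclusive) of all array medians. miRNAs
    absent from the reference count as RPM 0. Returns a call for every miRNA
    in ``array_medians``.
    """
    medians = pd.Series(array_medians, dtype=float)
    if medians.empty:
        raise ValueError("array_medians is empty")
    if not 0.0 < top_quantile < 1.0:
        raise ValueError("top_quantile must lie in (0, 1)")
    cutoff = float(np.quantile(medians.to_numpy(), top_quantile))
    rpm = reference.reindex(medians.index).fillna(0.0)
    calls = [
        FalsePositiveCall(
            name=str(name),
            array_median=float(medians[name]),
            seq_rpm=float(rpm[name]),
            is_false_positive=bool(
                medians[name] >= cutoff and rpm[name] <= expressed_cutoff
            ),
        )
        for name in medians.index
    ]
    n_fp = sum(c.is_false_positive for c in calls)
    logger.info(
        "array-median cutoff %.4g (quantile %.2f): %d/%d miRNAs called false positive",
        cutoff,
        top_quantile,
        n_fp,
        len(calls),
    )
    return calls


@dataclass(frozen=True)
class FeatureComparison:
    """One-sided Mann-Whitney comparison of a feature between FP and non-FP groups."""

    u_statistic: float
    p_value: float
    direction: str
    n_false_positive: int
    n_other: int


def compare_feature(
    calls: list[FalsePositiveCall],
    feature_values: Mapping[str, float] | pd.Series,
) -> FeatureComparison:
    """Test whether false positives have stochastically greater feature values.

    One-sided Mann-Whitney U (alternative: false-positive group greater),
    with tie correction. ``direction`` reports which group has the larger
    mean rank regardless of significance.
    """
    values = pd.Series(feature_values, dtype=float)
    fp = [c.name for c in calls if c.is_false_positive and c.name in values.index]
    other = [c.name for c in calls if not c.is_false_positive and c.name in values.index]
    if not fp or not other:
        raise ValueError(
            "both the false-positive group and the remainder must be "
            "non-empty after joining on names"
        )
    x = values[fp].to_numpy()
    y = values[other].to_numpy()
    u, p = _mannwhitney(x, y, "greater")
    expected = x.size * y.size / 2.0
    if u > expected:
        direction = "false-positives greater"
    elif u < expected:
        direction = "false-positives smaller"
    else:
        direction = "no difference"
    return FeatureComparison(
        u_statistic=u,
        p_value=p,
        direction=direction,
        n_false_positive=len(fp),
        n_other=len(other),
    )
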