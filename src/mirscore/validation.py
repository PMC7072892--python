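"""Benchmarking a score table against a sequencing reference profile.

The reference is a per-miRNA median RPM (reads per million) profile from
miRNA-seq; RPM > 10 is the conventional "expressed" cutoff. Validation asks
whether miRNAs selected by score are concordant with the sequencing evidence,
how much better score-based selection is than raw-intensity selection (the
specificity ratio), and which weights maximize that ratio.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationSet
from .scoring import ScoreTable, ScoreWeights, apply_weights, component_table

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.75
DEFAULT_RPM_THRESHOLD = 10.0


def cumulative_coverage(reference: pd.Series) -> np.ndarray:
    """Percentage of total expression mass covered by the top-n miRNAs.

    Entries are sorted by RPM descending; element k (0-based) is the percent
    of the summed RPM contributed by the k+1 most expressed miRNAs. In real
    tissue the curve saturates fast: a few dozen miRNAs carry >90% of reads.
    """
    values = np.sort(np.asarray(reference, dtype=float))[::-1]
    total = values.sum()
    if total <= 0:
        raise ValueError("reference profile has no positive RPM values")
    return np.cumsum(values) / total * 100.0


@dataclass(frozen=True)
class ConcordanceReport:
    """Concordance of score-selected miRNAs with a sequencing reference.

    ``ratio`` is the specificity gain: how many discordant (low-RPM) miRNAs
    raw-intensity selection of the same size yields per discordant miRNA of
    the score-based selection. ``None`` when the score selection has no
    discordant members.
    """

    n_selected: int
    n_concordant: int
    n_discordant: int
    baseline_discordant: int
    ratio: float | None

    def summary(self) -> str:
        ratio = "undefined" if self.ratio is None else f"{self.ratio:.2f}x"
        return (
            f"{self.n_selected} miRNAs selected by score; "
            f"{self.n_concordant} concordant with the sequencing reference, "
            f"{self.n_discordant} discordant; same-size selection by raw "
            f"median expression: {self.baseline_discordant} discordant "
            f"(specificity ratio {ratio})"
        )


def _reference_rpm(score_table: ScoreTable, reference: pd.Series) -> pd.Series:
    names = score_table.frame.index
    if not names.isin(reference.index).any():
        raise ValueError("score table and reference profile share no miRNA names")
    missing = [n for n in names if n not in reference.index]
    if missing:
        logger.info(
            "%d scored miRNAs absent from the reference counted as RPM 0",
            len(missing),
        )
    return reference.reindex(names).fillna(0.0)


def concordance(
    score_table: ScoreTable,
    reference: pd.Series,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    rpm_threshold: float = DEFAULT_RPM_THRESHOLD,
) -> ConcordanceReport:
    """Compare score-based selection with the sequencing reference.

    Selection is strict (score > threshold); a selected miRNA is concordant
    when its reference RPM is strictly above ``rpm_threshold``. miRNAs absent
    from the reference count as RPM 0: sequencing quantifiers report every
    detected miRNA, so absence is evidence of non-expression. The baseline
    takes the same number of miRNAs ranked by raw median expression (ties by
    ascending MIMAT number) and counts its discordant members.
    """
    frame = score_table.frame
    rpm = _reference_rpm(score_table, reference)
    selected = frame.index[frame["score"] > score_threshold]
    n_selected = len(selected)
    n_concordant = int((rpm.loc[selected] > rpm_threshold).sum())
    n_discordant = n_selected - n_concordant

    by_median = frame.sort_values(
        ["median", "mimat"], ascending=[False, True], kind="mergesort"
    )
    baseline = by_median.index[:n_selected]
    baseline_discordant = int((rpm.loc[baseline] <= rpm_threshold).sum())

    ratio: float | None
    ratio = None if n_discordant == 0 else baseline_discordant / n_discordant
    return ConcordanceReport(
        n_selected=n_selected,
        n_concordant=n_concordant,
        n_discordant=n_discordant,
        baseline_discordant=baseline_discordant,
        ratio=ratio,
    )


@dataclass(frozen=True)
class RankSeparation:
    """Mann-Whitney comparison of two score groups."""

    u_statistic: float
    p_value: float
    mean1: float
    sd1: float
    mean2: float
    sd2: float


def _mannwhitney(x, y, alternative: str) -> tuple[float, float]:
    """Mann-Whitney U with the exact/asymptotic switch used throughout.

    Exact null distribution when both groups have <= 8 observations and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    correction (scipy's exact method silently ignores ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and tie_free) else "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(result.statistic), float(result.pvalue)


def rank_separation(scores_group1, scores_group2) -> RankSeparation:
    """Two-sided Mann-Whitney U between two groups of scores.

    Returns the U statistic of group 1 (number of pairwise wins, ties counting
    half), the two-sided p-value, and each group's mean and sample (n-1)
    standard deviation.
    """
    x = np.asarray(scores_group1, dtype=float)
    y = np.asarray(scores_group2, dtype=float)
    u, p = _mannwhitney(x, y, "two-sided")
    return RankSeparation(
        u_statistic=u,
        p_value=p,
        mean1=float(x.mean()),
        sd1=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        mean2=float(y.mean()),
        sd2=float(y.std(ddof=1)) if y.size > 1 else 0.0,
    )


def weight_grid(grid_step: float) -> list[ScoreWeights]:
    """All weight triples on the unit-simplex lattice with spacing grid_step."""
    if grid_step <= 0 or grid_step > 1:
        raise ValueError("grid_step must lie in (0, 1]")
    steps = round(1.0 / grid_step)
    if abs(steps * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1 evenly")
    triples = []
    for i, j in itertools.product(range(steps + 1), repeat=2):
        k = steps - i - j
        if k >= 0:
            triples.append(
                ScoreWeights(i * grid_step, j * grid_step, k * grid_step)
            )
    return triples


def optimize_weights(
    mirna_matrix: pd.DataFrame,
    annotation: AnnotationSet,
    reference: pd.Series,
    precursor_matrix: pd.DataFrame | None = None,
    grid_step: float = 0.05,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    rpm_threshold: float = DEFAULT_RPM_THRESHOLD,
    **score_kwargs,
) -> tuple[ScoreWeights, float]:
    """Exhaustive simplex-lattice search for the specificity-maximizing weights.

    The objective is the concordance ratio (baseline discordant count divided
    by score-selection discordant count); a selection with zero discordant
    members counts as +inf, an empty selection as -inf. Ties break toward
    larger concordant counts, then lexicographically by (w_A, w_B, w_C)
    descending. Components are computed once; only the weighting is re-run
    per candidate.
    """
    components, m_max, n_max, unannotated = component_table(
        mirna_matrix, annotation, precursor_matrix, **score_kwargs
    )
    candidates = weight_grid(grid_step)
    logger.info("evaluating %d weight triples (grid step %g)", len(candidates), grid_step)
    best_key: tuple | None = None
    best: tuple[ScoreWeights, float] | None = None
    for weights in candidates:
        table = apply_weights(components, weights, m_max, n_max, unannotated)
        report = concordance(table, reference, score_threshold, rpm_threshold)
        if report.n_selected == 0:
            objective = -math.inf
        elif report.n_discordant == 0:
            objective = math.inf
        else:
            objective = report.baseline_discordant / report.n_discordant
        key = (objective, report.n_concordant, weights.w_a, weights.w_b, weights.w_c)
        if best_key is None or key > best_key:
            best_key, best = key, (weights, objective)
    assert best is not None
    return best
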