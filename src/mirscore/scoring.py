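"""Per-miRNA reliability scoring.

Each mature miRNA receives a score in [0, 1] combining three signals:

* ``A = m / m_max`` — its median expression across samples, scaled by the
  largest median in the analyzed set;
* ``B = 1 - N / N_max`` — its miRBase MIMAT accession number, scaled so that
  early (low-N, historically better-validated) miRNAs score high;
* ``C = (c + 1) / 2`` — the Spearman correlation between the miRNA and its
  precursor expression, mapped from [-1, 1] to [0, 1].

The score is the weighted combination ``w_A*A + w_B*B + w_C*C`` with default
weights (0.5, 0.3, 0.2), chosen to maximize specificity against sequencing
references. Because each component lies in [0, 1] and the weights sum to 1,
the score itself lies in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationSet, validate_expression_matrix

logger = logging.getLogger(__name__)

#: neutral C value used when the precursor correlation is unavailable
NEUTRAL_C = 0.5

#: below this many paired samples, Spearman correlation is considered
#: unreliable and treated as absent
DEFAULT_MIN_SAMPLES = 5


@dataclass(frozen=True)
class ScoreWeights:
    """Weights (w_A, w_B, w_C) of the three score components.

    Each must lie in [0, 1]; the constructor renormalizes the triple to sum
    to 1 (so e.g. ``ScoreWeights(0.5, 0.3, 0)`` becomes (0.625, 0.375, 0)).
    """

    w_a: float
    w_b: float
    w_c: float

    def __post_init__(self) -> None:
        for w in (self.w_a, self.w_b, self.w_c):
            if not (0.0 <= w <= 1.0 + 1e-9):
                raise ValueError(f"weight {w} outside [0, 1]")
        total = self.w_a + self.w_b + self.w_c
        if total <= 0:
            raise ValueError("weights must not all be zero")
        if abs(total - 1.0) > 1e-9:
            object.__setattr__(self, "w_a", self.w_a / total)
            object.__setattr__(self, "w_b", self.w_b / total)
            object.__setattr__(self, "w_c", self.w_c / total)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_a, self.w_b, self.w_c)


DEFAULT_WEIGHTS = ScoreWeights(0.5, 0.3, 0.2)


def median_expression(matrix: pd.DataFrame, feature: str) -> float:
    """Median of a feature's expression across all samples.

    Even sample counts use the arithmetic mean of the two central order
    statistics.
    """
    if feature not in matrix.index:
        raise KeyError(f"feature {feature!r} not in expression matrix")
    row = matrix.loc[feature].to_numpy(dtype=float)
    if row.size == 0:
        raise ValueError("expression matrix has no samples")
    return float(np.median(row))


def precursor_correlation(
    mirna_row: np.ndarray | pd.Series,
    precursor_rows: list[np.ndarray] | np.ndarray | pd.DataFrame,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> float | None:
    """Spearman correlation between a miRNA and its precursor(s).

    With several precursors (a mature excised from multiple genomic loci)
    the maximum correlation is returned: agreement with any one locus is
    evidence of genuine biogenesis. Returns ``None`` when no precursor row is
    given or fewer than ``min_samples`` paired samples are available.
    """
    x = np.asarray(mirna_row, dtype=float)
    if isinstance(precursor_rows, pd.DataFrame):
        rows = [precursor_rows.iloc[i].to_numpy(dtype=float) for i in range(len(precursor_rows))]
    else:
        rows = [np.asarray(r, dtype=float) for r in np.atleast_2d(precursor_rows)]
    if not rows:
        return None
    if x.size < min_samples:
        return None
    best: float | None = None
    for row in rows:
        if row.size != x.size:
            raise ValueError(
                f"sample count mismatch: miRNA has {x.size}, precursor has {row.size}"
            )
        rho = stats.spearmanr(x, row).statistic
        if math.isnan(rho):
            continue  # constant vector: correlation undefined
        if best is None or rho > best:
            best = float(rho)
    return best


def scale_components(
    m: float,
    m_max: float,
    N: int,
    n_max: int,
    c: float | None,
    clip: bool = True,
) -> tuple[float, float, float]:
    """Scale raw (m, N, c) into the unit-interval components (A, B, C).

    ``A = m/m_max``; ``B = 1 - N/n_max`` clipped at 0 if N exceeds n_max;
    ``C = (c+1)/2``, with an absent correlation mapped to the neutral 0.5.
    """
    if m_max <= 0:
        raise ValueError("m_max must be positive")
    if n_max <= 0:
        raise ValueError("n_max must be positive")
    if N < 1:
        raise ValueError("MIMAT number must be >= 1")
    if m < 0:
        raise ValueError("median expression must be non-negative")
    a = m / m_max
    if a > 1.0:
        if not clip:
            raise ValueError(f"median {m} exceeds m_max {m_max}")
        a = 1.0
    b = 1.0 - N / n_max
    if b < 0.0:
        b = 0.0  # N above the configured n_max clips rather than going negative
    if c is None:
        c_scaled = NEUTRAL_C
    else:
        if not -1.0 - 1e-12 <= c <= 1.0 + 1e-12:
            raise ValueError(f"correlation {c} outside [-1, 1]")
        c_scaled = (min(max(c, -1.0), 1.0) + 1.0) / 2.0
    return a, b, c_scaled


def compute_score(components, weights: ScoreWeights = DEFAULT_WEIGHTS):
    """Weighted combination of unit-interval components (A, B, C).

    Accepts scalars or equally shaped numpy arrays for vectorized
    evaluation; the result lies in [0, 1] whenever the inputs do.
    """
    a, b, c = components
    a, b, c = np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    for label, arr in (("A", a), ("B", b), ("C", c)):
        if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
            raise ValueError(f"component {label} outside [0, 1]")
    score = weights.w_a * a + weights.w_b * b + weights.w_c * c
    return float(score) if score.ndim == 0 else score


@dataclass
class ScoreTable:
    """Result of scoring: one row per miRNA plus the scaling constants.

    ``frame`` is indexed by mature name with columns median, mimat,
    correlation (NaN when absent), A, B, C, score — sorted score-descending,
    ties broken by ascending MIMAT number. ``unannotated`` lists expression
    features that had no annotation record and were therefore not scored.
    """

    frame: pd.DataFrame
    weights: ScoreWeights
    m_max: float
    n_max: int
    unannotated: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def scores(self) -> pd.Series:
        return self.frame["score"]


def component_table(
    mirna_matrix: pd.DataFrame,
    annotation: AnnotationSet,
    precursor_matrix: pd.DataFrame | None = None,
    *,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    m_max: float | None = None,
    n_max: int | None = None,
    negative: str = "error",
) -> tuple[pd.DataFrame, float, int, tuple[str, ...]]:
    """Compute per-miRNA (m, N, c, A, B, C) without applying weights.

    Split out from :func:`score_all` so weight optimization can re-weight a
    fixed component table instead of recomputing medians and correlations
    for every candidate triple.
    """
    validate_expression_matrix(mirna_matrix)
    if negative not in ("error", "shift"):
        raise ValueError(f"unknown negative-value policy: {negative!r}")
    lowest = float(mirna_matrix.to_numpy().min())
    if lowest < 0:
        if negative == "error":
            raise ValueError(
                "expression table contains negative values; medians must be "
                "non-negative for A = m/m_max (pass negative='shift' to "
                "min-shift the table)"
            )
        mirna_matrix = mirna_matrix - lowest
        logger.info("min-shifted expression table by %+g", -lowest)

    scored_names = [f for f in mirna_matrix.index if f in annotation]
    unannotated = tuple(f for f in mirna_matrix.index if f not in annotation)
    if not scored_names:
        raise ValueError(
            "no overlap between expression features and annotation records"
        )
    if unannotated:
        logger.warning(
            "%d expression features missing from the annotation were not "
            "scored: %s%s",
            len(unannotated),
            ", ".join(unannotated[:5]),
            "..." if len(unannotated) > 5 else "",
        )

    if precursor_matrix is not None:
        validate_expression_matrix(precursor_matrix)
        if set(precursor_matrix.columns) != set(mirna_matrix.columns):
            raise ValueError(
                "miRNA and precursor matrices must cover the same samples"
            )
        precursor_matrix = precursor_matrix[list(mirna_matrix.columns)]

    medians = mirna_matrix.loc[scored_names].median(axis=1)
    effective_m_max = float(medians.max()) if m_max is None else float(m_max)
    if effective_m_max <= 0:
        raise ValueError("m_max must be positive")
    effective_n_max = annotation.n_max if n_max is None else int(n_max)
    observed_n_max = max(annotation[f].mimat_number for f in scored_names)
    if effective_n_max < observed_n_max:
        raise ValueError(
            f"n_max {effective_n_max} smaller than largest scored MIMAT "
            f"number {observed_n_max}"
        )
    logger.info("scaling constants: m_max=%g n_max=%d", effective_m_max, effective_n_max)

    rows = []
    for name in scored_names:
        record = annotation[name]
        corr: float | None = None
        if precursor_matrix is not None and record.precursor_names:
            available = [
                precursor_matrix.loc[p].to_numpy(dtype=float)
                for p in record.precursor_names
                if p in precursor_matrix.index
            ]
            if available:
                corr = precursor_correlation(
                    mirna_matrix.loc[name].to_numpy(dtype=float),
                    available,
                    min_samples=min_samples,
                )
        a, b, c_scaled = scale_components(
            float(medians[name]),
            effective_m_max,
            record.mimat_number,
            effective_n_max,
            corr,
        )
        rows.append(
            {
                "name": name,
                "median": float(medians[name]),
                "mimat": record.mimat_number,
                "correlation": np.nan if corr is None else corr,
                "A": a,
                "B": b,
                "C": c_scaled,
            }
        )
    frame = pd.DataFrame(rows).set_index("name")
    return frame, effective_m_max, effective_n_max, unannotated


def apply_weights(
    components: pd.DataFrame,
    weights: ScoreWeights,
    m_max: float,
    n_max: int,
    unannotated: tuple[str, ...] = (),
    missing_corr: str = "neutral",
) -> ScoreTable:
    """Turn a component table into a sorted ScoreTable under given weights.

    ``missing_corr="neutral"`` keeps C at 0.5 where the correlation is absent;
    ``missing_corr="drop-weight"`` instead zeroes w_C and renormalizes the
    remaining weights — the recommended fallback when the sample count is too
    low for meaningful Spearman correlations.
    """
    if missing_corr not in ("neutral", "drop-weight"):
        raise ValueError(f"unknown missing_corr policy: {missing_corr!r}")
    effective = weights
    if missing_corr == "drop-weight":
        effective = ScoreWeights(weights.w_a, weights.w_b, 0.0)
    frame = components.copy()
    frame["score"] = compute_score(
        (frame["A"].to_numpy(), frame["B"].to_numpy(), frame["C"].to_numpy()),
        effective,
    )
    frame = frame.sort_values(
        ["score", "mimat"], ascending=[False, True], kind="mergesort"
    )
    return ScoreTable(
        frame=frame,
        weights=effective,
        m_max=m_max,
        n_max=n_max,
        unannotated=unannotated,
    )


def score_all(
    mirna_matrix: pd.DataFrame,
    annotation: AnnotationSet,
    precursor_matrix: pd.DataFrame | None = None,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
    *,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    missing_corr: str = "neutral",
    m_max: float | None = None,
    n_max: int | None = None,
    negative: str = "error",
) -> ScoreTable:
    """Score every miRNA present in both the expression table and annotation.

    The scaling constants m_max and N_max are taken over the analyzed set
    (overridable). Rows come back sorted by score descending with ascending
    MIMAT number breaking ties; unscored (unannotated) features are reported
    on the result, never silently dropped.
    """
    components, eff_m_max, eff_n_max, unannotated = component_table(
        mirna_matrix,
        annotation,
        precursor_matrix,
        min_samples=min_samples,
        m_max=m_max,
        n_max=n_max,
        negative=negative,
    )
    return apply_weights(
        components, weights, eff_m_max, eff_n_max, unannotated, missing_corr
    )
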