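"""Reader-panel difficulty scoring and quartile labelling of normal cases.

Each case's difficulty score is the fraction of readers who called a truly
normal case equivocal or malignant (rating 3-5 on the 1-5 RANZCR scale,
i.e. a false-positive call). Cases at or above the 75th percentile of
scores are labelled hardest-to-interpret, at or below the 25th percentile
easiest-to-interpret; the middle half is excluded from modelling. A
Kruskal-Wallis test compares difficulty between low-density (BI-RADS A/B)
and high-density (C/D) cases.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

HARDEST, EASIEST, EXCLUDED = "hardest", "easiest", "excluded"

MISCLASSIFY_MIN_SCORE = 3  # RANZCR rating at or above this = false-positive call


@dataclass
class DifficultyRecord:
    case_id: str
    score: float
    n_readers: int
    label: str = EXCLUDED
    density_group: str = "unknown"


def difficulty_score(ratings) -> float:
    """Fraction of non-missing ratings that are >= 3 (a misclassification)."""
    r = np.asarray(ratings, dtype=np.float64)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("difficulty_score needs at least one non-missing rating")
    return float((r >= MISCLASSIFY_MIN_SCORE).sum() / r.size)


def score_rating_matrix(ratings: pd.DataFrame) -> pd.Series:
    """Per-case difficulty scores from a readers x cases rating matrix.

    Missing entries (NaN) are excluded from both numerator and denominator:
    a reader who skipped a case did not read it.
    """
    return ratings.apply(lambda col: difficulty_score(col.to_numpy()), axis=0)


def quartile_labels(
    scores,
    lower_q: float = 25.0,
    upper_q: float = 75.0,
    interpolation: str = "linear",
) -> list[str]:
    """Label each score hardest (>= Q75), easiest (<= Q25), or excluded.

    Percentiles use linear interpolation between order statistics by
    default (configurable). Boundary ties are included on the qualifying
    side. If every score is identical the two rules would label every case
    both ways; that degenerate distribution yields all-excluded with a
    warning.
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.size < 8:
        raise ValueError(f"quartile labelling needs >= 8 scores, got {s.size}")
    q25, q75 = np.percentile(s, [lower_q, upper_q], method=interpolation)
    if q25 == q75:
        logger.warning(
            "degenerate difficulty distribution (Q25 == Q75 == %g): all cases excluded", q25
        )
        return [EXCLUDED] * s.size
    return [
        HARDEST if v >= q75 else EASIEST if v <= q25 else EXCLUDED
        for v in s
    ]


def density_group(birads: str) -> str:
    """Map a BI-RADS density category to low (A/B) or high (C/D) density."""
    b = str(birads).strip().upper()
    if b in ("A", "B"):
        return "low"
    if b in ("C", "D"):
        return "high"
    logger.warning("unknown BI-RADS density category %r -> group 'unknown'", birads)
    return "unknown"


def density_difficulty_test(records: list[DifficultyRecord]) -> tuple[float, float]:
    """Kruskal-Wallis test of difficulty scores between density groups.

    Returns (H, p) using midranks for ties and the tie-corrected chi-square
    approximation. Identical groups (zero rank variance) give H = 0, p = 1.
    """
    low = [r.score for r in records if r.density_group == "low"]
    high = [r.score for r in records if r.density_group == "high"]
    if not low or not high:
        raise ValueError("both density groups must be nonempty")
    if len(set(low + high)) == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(low, high)
    return float(h), float(p)


def build_difficulty_records(
    ratings: pd.DataFrame,
    density: pd.Series | None = None,
) -> list[DifficultyRecord]:
    """Score, label, and density-group every case of a rating matrix."""
    scores = score_rating_matrix(ratings)
    labels = quartile_labels(scores.to_numpy())
    n_read = ratings.notna().sum(axis=0)
    recs = []
    for case_id, label in zip(scores.index, labels):
        grp = density_group(density[case_id]) if density is not None else "unknown"
        recs.append(
            DifficultyRecord(
                case_id=str(case_id),
                score=float(scores[case_id]),
                n_readers=int(n_read[case_id]),
                label=label,
                density_group=grp,
            )
        )
    return recs
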