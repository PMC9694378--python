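"""Score normalization, ranking, and rank-by-rank consensus.

Heterogeneous scoring-function columns are min-max normalized to [0, 1]
(lower-is-better columns are sign-flipped first, so 1 always means best),
each column is converted to ranks (1 = best, fractional ties), and the
consensus rank of a compound is the arithmetic mean of its per-column
ranks.  Implemented for any K >= 1 columns; K = 6 reproduces the published
Surflex + five-GOLD-functions scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

HIGHER = "higher_better"
LOWER = "lower_better"

ID_COLUMNS = ("compound_id", "pose_id", "label")


@dataclass
class ScoreTable:
    """Per-pose scores from K scoring functions.

    ``frame`` must carry compound_id and pose_id columns (label optional);
    ``orientations`` maps every score column to higher_better/lower_better.
    """

    frame: pd.DataFrame
    orientations: dict[str, str]

    def __post_init__(self) -> None:
        if not self.orientations:
            raise ValueError("at least one score column required")
        for col, orient in self.orientations.items():
            if col not in self.frame.columns:
                raise ValueError(f"score column {col!r} missing from table")
            if orient not in (HIGHER, LOWER):
                raise ValueError(f"orientation for {col!r} must be {HIGHER} or {LOWER}")

    @property
    def score_columns(self) -> list[str]:
        return list(self.orientations)


@dataclass
class ConsensusResult:
    normalized: pd.DataFrame  # per-column normalized scores
    ranks: pd.DataFrame  # per-column ranks (1 = best)
    consensus_rank: pd.Series  # mean rank per row
    ordering: pd.DataFrame  # rows sorted best-to-worst by consensus rank


def normalize_scores(column, orientation: str = HIGHER) -> np.ndarray:
    """Min-max normalize to [0, 1] with 1 = best (Eq.-1-style scaling)."""
    values = np.asarray(column, dtype=float)
    if np.sum(np.isfinite(values)) < 2:
        raise ValueError("need at least two finite scores to normalize")
    if orientation == LOWER:
        values = -values
    elif orientation != HIGHER:
        raise ValueError(f"unknown orientation {orientation!r}")
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi == lo:
        warnings.warn("constant score column; normalizing to 0.5", stacklevel=2)
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def rank_scores(normalized) -> np.ndarray:
    """Ranks with 1 = best (highest normalized score); ties -> average rank."""
    values = np.asarray(normalized, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("ranks require finite values")
    return rankdata(-values, method="average")


def consensus_rank(rank_lists: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Arithmetic mean of K aligned rank lists (rank-by-rank consensus)."""
    ranks = np.atleast_2d(np.asarray(rank_lists, dtype=float))
    if ranks.shape[0] == 0:
        raise ValueError("consensus requires K >= 1 rank lists")
    lengths = {r.shape[0] for r in ranks.reshape(ranks.shape[0], -1)}
    if len(lengths) != 1:
        raise ValueError("rank lists must have equal length")
    return ranks.mean(axis=0)


def consensus_table(table: ScoreTable) -> ConsensusResult:
    """Normalize, rank and average every score column of a table."""
    frame = table.frame.reset_index(drop=True)
    normalized = pd.DataFrame(index=frame.index)
    ranks = pd.DataFrame(index=frame.index)
    for col in table.score_columns:
        normalized[col] = normalize_scores(frame[col], table.orientations[col])
        ranks[col] = rank_scores(normalized[col])
    consensus = consensus_rank([ranks[c].to_numpy() for c in table.score_columns])
    consensus = pd.Series(consensus, index=frame.index, name="consensus_rank")
    ordered = frame.copy()
    ordered["consensus_rank"] = consensus
    first_col = table.score_columns[0]
    ordered["_tie1"] = ranks[first_col]
    sort_keys = ["consensus_rank", "_tie1"]
    if "compound_id" in ordered.columns:
        sort_keys.append("compound_id")
    ordered = ordered.sort_values(sort_keys, kind="mergesort").drop(columns="_tie1")
    return ConsensusResult(
        normalized=normalized, ranks=ranks, consensus_rank=consensus, ordering=ordered
    )


def best_pose_per_compound(table: ScoreTable, by_column: str) -> ScoreTable:
    """Keep, per compound, the pose with the best oriented score in
    ``by_column`` (ties broken by pose_id for determinism)."""
    if by_column not in table.orientations:
        raise ValueError(f"unknown score column {by_column!r}")
    frame = table.frame.copy()
    sign = 1.0 if table.orientations[by_column] == HIGHER else -1.0
    frame["_key"] = sign * frame[by_column].astype(float)
    frame = frame.sort_values(["_key", "pose_id"], ascending=[False, True], kind="mergesort")
    best = frame.drop_duplicates("compound_id", keep="first").drop(columns="_key")
    best = best.sort_index().reset_index(drop=True)
    return ScoreTable(frame=best, orientations=dict(table.orientations))
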