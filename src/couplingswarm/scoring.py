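"""The grouped log-MAE competition metric and leaderboard ranking.

The score of a submission is

    score = (1/T) * sum_t log( (1/n_t) * sum_i |y_i - yhat_i| )

where ``t`` runs over the T coupling types present in the scored selection
(T = 8 for a full competition dataset), ``n_t`` is the number of records of
type ``t``, and the logarithm is natural.  Lower is better.  Because each
type contributes through the log of its own MAE, a 10% relative improvement
in any one type moves the score by the same amount (ln 0.9 / T) regardless
of that type's abundance or value scale — no coupling class dominates.

``exp(score)`` is the geometric mean over types of the per-type MAE: a
single Hz-scale accuracy summary.  Score differences therefore translate
into multiplicative accuracy factors (a drop of 2.5 is an ~12x error
reduction).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteSubmissionError, InvalidSubmissionError, ScoringError
from .types import CouplingDataset, LeaderboardEntry, ScoreReport, SubmissionSet

#: Per-type MAE is floored at this value (Hz) before the log so that a
#: perfect submission scores log(MAE_FLOOR) per type rather than -inf.
MAE_FLOOR = 1e-9


def _aligned_predictions(
    predictions: pd.Series, ids: np.ndarray, team: str | None = None
) -> np.ndarray:
    """Return predictions aligned to ``ids``, validating coverage and finiteness."""
    missing = np.setdiff1d(ids, predictions.index.to_numpy(), assume_unique=False)
    if missing.size:
        who = f" (team {team})" if team else ""
        raise IncompleteSubmissionError(
            f"submission{who} missing prediction for record id {missing[0]}"
            + (f" and {missing.size - 1} more" if missing.size > 1 else "")
        )
    values = predictions.reindex(ids).to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = ids[~np.isfinite(values)]
        who = f" (team {team})" if team else ""
        raise InvalidSubmissionError(
            f"submission{who} has non-finite prediction at record id {bad[0]}"
        )
    return values


def score_errors(abs_errors: np.ndarray, type_labels: np.ndarray,
                 split_scored: str = "custom") -> ScoreReport:
    """Score from per-record absolute errors and their coupling-type labels."""
    if abs_errors.shape != type_labels.shape:
        raise ScoringError("errors and type labels must align")
    if abs_errors.size == 0:
        raise ScoringError("cannot score an empty selection")
    frame = pd.DataFrame({"err": abs_errors, "type": type_labels})
    mae = frame.groupby("type", sort=True)["err"].mean()
    counts = frame.groupby("type", sort=True)["err"].size()
    floored = np.maximum(mae.to_numpy(), MAE_FLOOR)
    log_mae = np.log(floored)
    value = float(np.mean(log_mae))
    return ScoreReport(
        per_type_mae=dict(zip(mae.index, floored)),
        per_type_log_mae=dict(zip(mae.index, log_mae)),
        score=value,
        geometric_mean_error=math.exp(value),
        n_types_used=len(mae),
        split_scored=split_scored,
        per_type_n={k: int(v) for k, v in counts.items()},
    )


def score(
    predictions: SubmissionSet | pd.Series,
    truth: CouplingDataset,
    split: str | Sequence[int] = "public",
) -> ScoreReport:
    """Score a submission against the truth table on a record selection.

    Parameters
    ----------
    predictions:
        A :class:`SubmissionSet` or a bare series of predicted coupling
        constants indexed by record id.  Must cover every selected record.
    truth:
        The competition dataset.
    split:
        ``"public"``, ``"private"``, ``"all"``/``"test"``, or an explicit
        sequence of record ids (scored as ``split_scored="custom"``).
    """
    team = predictions.team_id if isinstance(predictions, SubmissionSet) else None
    series = predictions.predictions if isinstance(predictions, SubmissionSet) else predictions

    if isinstance(split, str):
        ids = truth.record_ids(split)
        label = "all" if split == "test" else split
    else:
        ids = np.asarray(list(split))
        label = "custom"
    if ids.size == 0:
        raise ScoringError(f"no records selected by split {label!r}")

    true_vals = truth.truth("test").reindex(ids).to_numpy(dtype=float)
    if np.isnan(true_vals).any():
        raise ScoringError("selection contains ids outside the test records")
    types = truth.types("test").reindex(ids).to_numpy()
    preds = _aligned_predictions(series, ids, team)
    return score_errors(np.abs(preds - true_vals), types, split_scored=label)


def geometric_mean_error(score_value: float) -> float:
    """exp(score): the geometric-mean absolute error in Hz."""
    if not np.isfinite(score_value):
        raise ScoringError(f"score must be finite, got {score_value}")
    return math.exp(score_value)


def rank_submissions(
    submissions: Iterable[SubmissionSet],
    truth: CouplingDataset,
    split: str = "public",
) -> list[LeaderboardEntry]:
    """Rank teams by their best (lowest) submission score on a split.

    Each team appears once, at its best score; ties are broken by the
    earlier timestamp of the best submission, then by team id.  Ranks are
    1-based.  An empty collection yields an empty leaderboard.
    """
    best: dict[str, tuple[float, float]] = {}
    for sub in submissions:
        s = score(sub, truth, split).score
        entry = (s, sub.timestamp_days)
        if sub.team_id not in best or entry < best[sub.team_id]:
            best[sub.team_id] = entry
    ordered = sorted(best.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0]))
    return [
        LeaderboardEntry(rank=i + 1, team_id=team, score=s, timestamp_days=t)
        for i, (team, (s, t)) in enumerate(ordered)
    ]
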