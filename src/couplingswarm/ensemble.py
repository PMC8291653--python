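"""Meta-ensemble (ME) construction over ranked competition submissions.

An ME prediction is a linear combination of the ranked submissions'
predictions,

    y_{i,ME} = sum_{j=k..N} w_j * y_{i,j},    w_j >= 0,  sum_j w_j = 1,

where k is the lowest (best) rank still included: k = 1 uses the whole
pool, k = 6 excludes the top five models, and the k-sweep probes how much
of the leaders' accuracy is recoverable from the rest of the field.

The weights are chosen to minimize the grouped log-MAE score of the ME
predictions on a fitting half of the test records (a seeded 50/50 split
stratified by coupling type); the untouched half provides an honest
evaluation score.  The objective is piecewise-smooth and non-convex in w,
so the optimizer evaluates every simplex vertex and the uniform point as
candidates, runs constrained local searches from the most promising of
them, and keeps the best candidate found — which also guarantees that the
fitted ME never scores worse than any single constituent on the fitting
half (vertex dominance).

``grid_search_simplex`` enumerates the full simplex lattice at a fixed
step; it is exact brute force, intended as an independent check of the
optimizer at small pool sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConfigurationError, IncompleteSubmissionError, ScoringError
from .scoring import MAE_FLOOR, score_errors
from .synthetic import largest_remainder_counts
from .types import CouplingDataset, SubmissionSet

__all__ = [
    "EnsembleFit", "KSweepResult", "combine", "contributor_count",
    "fit_weights", "grid_search_simplex", "k_sweep", "split_fit_eval",
]


@dataclass
class EnsembleFit:
    """A fitted meta-ensemble.

    ``weights`` maps constituent rank (1-based, within the supplied pool
    ordering) to its simplex weight; in per-type mode it maps
    ``(type, rank)``.  ``fit_score``/``eval_score`` are grouped log-MAE
    values on the two disjoint halves of the scored records.
    """

    constituent_ranks: list[int]
    team_ids: dict[int, str]
    weights: dict
    k: int
    mode: str
    combiner: str
    fit_record_ids: np.ndarray
    eval_record_ids: np.ndarray
    fit_score: float
    eval_score: float

    def weight_of_rank(self, rank: int) -> float:
        """Total effective weight of one constituent (max over types in per-type mode)."""
        if self.mode == "per_type":
            vals = [w for (t, r), w in self.weights.items() if r == rank]
            return max(vals) if vals else 0.0
        return self.weights.get(rank, 0.0)

    def contributor_count_at(self, threshold: float = 0.01) -> int:
        return contributor_count(self, threshold)

    def weights_frame(self) -> pd.DataFrame:
        """Weights as a tidy frame (rank, team_id, [type], weight)."""
        if self.mode == "per_type":
            rows = [
                {"type": t, "rank": r, "team_id": self.team_ids[r], "weight": w}
                for (t, r), w in sorted(self.weights.items())
            ]
        else:
            rows = [
                {"rank": r, "team_id": self.team_ids[r], "weight": w}
                for r, w in sorted(self.weights.items())
            ]
        return pd.DataFrame(rows)


@dataclass
class KSweepResult:
    """Per-k summary of the exclusion sweep."""

    table: pd.DataFrame  # columns: k, me_score, best_score, gap, contributors
    fits: dict[int, EnsembleFit]
    failures: dict[int, str] = field(default_factory=dict)


def _prediction_matrix(
    submissions: Sequence[SubmissionSet], ids: np.ndarray
) -> np.ndarray:
    """n_records x n_submissions matrix of predictions aligned on ``ids``."""
    cols = []
    for sub in submissions:
        vals = sub.predictions.reindex(ids).to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise IncompleteSubmissionError(
                f"submission {sub.team_id} does not cover all requested records")
        cols.append(vals)
    return np.column_stack(cols)


def split_fit_eval(
    truth: CouplingDataset, seed: int, split: str = "test"
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 50/50 split of the scored records, stratified by coupling type.

    Stratification guarantees every type present in the selection appears
    in both halves, so both halves are scoreable over the same type set.
    """
    rng = np.random.default_rng(seed)
    ids = truth.record_ids(split)
    types = truth.types(split).to_numpy()
    fit_parts, eval_parts = [], []
    for label in np.unique(types):
        t_ids = ids[types == label]
        t_ids = rng.permutation(t_ids)
        n_fit, _ = largest_remainder_counts(len(t_ids), [0.5, 0.5])
        fit_parts.append(t_ids[:n_fit])
        eval_parts.append(t_ids[n_fit:])
    return np.concatenate(fit_parts), np.concatenate(eval_parts)


def _type_sorted(
    P: np.ndarray, y: np.ndarray, types: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[slice]]:
    """Sort rows by type label and return contiguous per-type slices."""
    order = np.argsort(types, kind="stable")
    types_sorted = types[order]
    bounds = np.flatnonzero(np.r_[True, types_sorted[1:] != types_sorted[:-1], True])
    slices = [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    return P[order], y[order], slices


#: Full local searches are launched from the uniform point and this many of
#: the best-scoring vertices; every vertex is still *evaluated* as a
#: candidate, which is what guarantees vertex dominance.
_N_VERTEX_STARTS = 4


def _optimize_simplex(
    P: np.ndarray, y: np.ndarray, slices: list[slice],
    extra_starts: Sequence[np.ndarray] = (),
) -> tuple[np.ndarray, float]:
    """Minimize the grouped log-MAE of P @ w over the probability simplex.

    Multi-start: every simplex vertex and the uniform point enter the
    candidate pool; constrained local searches run from the uniform point
    and the best vertices; the best candidate overall is returned, so the
    solution never scores worse than any single constituent.
    """
    m = P.shape[1]
    T = len(slices)
    starts_idx = np.array([sl.start for sl in slices])
    counts = np.array([sl.stop - sl.start for sl in slices], dtype=float)

    def objective(w: np.ndarray) -> float:
        err = np.abs(P @ w - y)
        mae = np.add.reduceat(err, starts_idx) / counts
        return float(np.log(np.maximum(mae, MAE_FLOOR)).mean())

    def gradient(w: np.ndarray) -> np.ndarray:
        # d/dw mean_t log MAE_t = mean_t grad(MAE_t)/MAE_t, with
        # grad(MAE_t) = mean_i sign(r_i) P_i (a subgradient at kinks)
        r = P @ w - y
        mae = np.add.reduceat(np.abs(r), starts_idx) / counts
        coef = 1.0 / (np.maximum(mae, MAE_FLOOR) * counts * T)
        return (np.sign(r) * np.repeat(coef, counts.astype(int))) @ P

    vertex_vals = np.array([objective(e) for e in np.eye(m)])
    order = np.argsort(vertex_vals, kind="stable")
    starts = [np.full(m, 1.0 / m)]
    starts.extend(np.eye(m)[order[:_N_VERTEX_STARTS]])
    starts.extend(extra_starts)

    best_idx = int(order[0])
    best_w, best_val = np.eye(m)[best_idx], float(vertex_vals[best_idx])
    for w0 in starts:
        val0 = objective(w0)
        if val0 < best_val:
            best_w, best_val = w0, val0
        if m == 1:
            continue
        res = minimize(
            objective, w0, method="SLSQP", jac=gradient,
            bounds=[(0.0, 1.0)] * m,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                          "jac": lambda w: np.ones(m)}],
            options={"maxiter": 10_000, "ftol": 1e-10},
        )
        w = np.clip(res.x, 0.0, None)
        total = w.sum()
        if total <= 0:
            continue
        w /= total
        val = objective(w)
        if val < best_val:
            best_w, best_val = w, val
    return best_w, best_val


def _optimize_mae_simplex(P: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimize plain MAE of P @ w over the simplex (per-type subproblem).

    The per-type objective is convex, but the same multi-start, best-of
    scheme is reused for uniformity and vertex dominance.
    """
    m = P.shape[1]

    def objective(w: np.ndarray) -> float:
        return float(np.abs(P @ w - y).mean())

    def gradient(w: np.ndarray) -> np.ndarray:
        return (np.sign(P @ w - y) @ P) / len(y)

    vertex_vals = np.array([objective(e) for e in np.eye(m)])
    order = np.argsort(vertex_vals, kind="stable")
    starts = [np.full(m, 1.0 / m)]
    starts.extend(np.eye(m)[order[:_N_VERTEX_STARTS]])
    best_idx = int(order[0])
    best_w, best_val = np.eye(m)[best_idx], float(vertex_vals[best_idx])
    for w0 in starts:
        val0 = objective(w0)
        if val0 < best_val:
            best_w, best_val = w0, val0
        if m == 1:
            continue
        res = minimize(
            objective, w0, method="SLSQP", jac=gradient,
            bounds=[(0.0, 1.0)] * m,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                          "jac": lambda w: np.ones(m)}],
            options={"maxiter": 10_000, "ftol": 1e-12},
        )
        w = np.clip(res.x, 0.0, None)
        if w.sum() <= 0:
            continue
        w /= w.sum()
        val = objective(w)
        if val < best_val:
            best_w, best_val = w, val
    return best_w


def combine(
    submissions: Sequence[SubmissionSet],
    weights: Sequence[float] | Mapping | None = None,
    combiner: str = "mean",
    types: pd.Series | None = None,
    team_id: str = "ensemble",
) -> SubmissionSet:
    """Combine submissions into one prediction vector.

    ``combiner="mean"`` takes the weighted mean with simplex ``weights``
    (a sequence aligned to ``submissions``, or in per-type form a mapping
    type -> weight sequence, which requires ``types``: record id -> type).
    ``combiner="median"`` takes the unweighted per-record median; at even
    counts the lower of the two middle values is used (deterministic).
    """
    if not submissions:
        raise ConfigurationError("no submissions to combine")
    ids = submissions[0].predictions.index.to_numpy()
    for sub in submissions[1:]:
        if not np.array_equal(np.sort(sub.predictions.index.to_numpy()), np.sort(ids)):
            raise IncompleteSubmissionError(
                f"submission {sub.team_id} covers different record ids")
    P = _prediction_matrix(submissions, ids)

    if combiner == "median":
        m = len(submissions)
        lower_mid = (m - 1) // 2  # lower of the two middle values when even
        combined = np.sort(P, axis=1)[:, lower_mid]
    elif combiner == "mean":
        if weights is None:
            weights = np.full(len(submissions), 1.0 / len(submissions))
        if isinstance(weights, Mapping):
            if types is None:
                raise ConfigurationError("per-type weights require a types series")
            combined = np.empty(len(ids))
            type_arr = types.reindex(ids).to_numpy()
            for label, w_t in weights.items():
                mask = type_arr == label
                combined[mask] = P[mask] @ np.asarray(w_t, dtype=float)
        else:
            combined = P @ np.asarray(weights, dtype=float)
    else:
        raise ConfigurationError(f"unknown combiner {combiner!r}")
    return SubmissionSet(team_id=team_id, predictions=pd.Series(combined, index=ids))


def fit_weights(
    submissions: Sequence[SubmissionSet],
    truth: CouplingDataset,
    k: int = 1,
    mode: str = "global",
    combiner: str = "mean",
    seed: int = 0,
    fit_ids: np.ndarray | None = None,
    eval_ids: np.ndarray | None = None,
    rank_order: Sequence[int] | None = None,
    warm_start: np.ndarray | None = None,
) -> EnsembleFit:
    """Fit simplex ME weights over the constituents ranked k..N.

    Constituents are ranked by individual score on the fitting half unless
    ``rank_order`` supplies an external ordering (indices into
    ``submissions``, best first) — e.g. a replayed leaderboard.  ``fit_ids``
    and ``eval_ids`` default to a seeded type-stratified 50/50 split of the
    test records; if given explicitly they must be disjoint.
    """
    if mode not in ("global", "per_type"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if combiner not in ("mean", "median"):
        raise ConfigurationError(f"unknown combiner {combiner!r}")
    if fit_ids is None or eval_ids is None:
        fit_ids, eval_ids = split_fit_eval(truth, seed)
    else:
        fit_ids = np.asarray(fit_ids)
        eval_ids = np.asarray(eval_ids)
        if np.intersect1d(fit_ids, eval_ids).size:
            raise ConfigurationError("fit and eval halves overlap")

    truth_all = truth.truth("test")
    types_all = truth.types("test")
    y_fit = truth_all.reindex(fit_ids).to_numpy()
    t_fit = types_all.reindex(fit_ids).to_numpy()
    y_eval = truth_all.reindex(eval_ids).to_numpy()
    t_eval = types_all.reindex(eval_ids).to_numpy()

    # Rank the pool on the fitting half (or replay an external order).
    if rank_order is None:
        fit_scores = []
        for sub in submissions:
            P1 = _prediction_matrix([sub], fit_ids)[:, 0]
            fit_scores.append(
                score_errors(np.abs(P1 - y_fit), t_fit).score)
        rank_order = list(np.argsort(fit_scores, kind="stable"))
    ranked = [submissions[i] for i in rank_order]

    n = len(ranked)
    if not (1 <= k <= n):
        raise ConfigurationError(
            f"k={k} leaves an empty ensemble (pool size {n})")
    pool = ranked[k - 1:]
    ranks = list(range(k, n + 1))
    team_ids = {r: s.team_id for r, s in zip(ranks, pool)}

    P_fit = _prediction_matrix(pool, fit_ids)
    P_eval = _prediction_matrix(pool, eval_ids)

    if combiner == "median":
        lower_mid = (len(pool) - 1) // 2
        pred_fit = np.sort(P_fit, axis=1)[:, lower_mid]
        pred_eval = np.sort(P_eval, axis=1)[:, lower_mid]
        weights = {r: 1.0 / len(pool) for r in ranks}
    elif mode == "global":
        Ps, ys, slices = _type_sorted(P_fit, y_fit, t_fit)
        extra = [np.asarray(warm_start, dtype=float)] if warm_start is not None else []
        w, _ = _optimize_simplex(Ps, ys, slices, extra_starts=extra)
        pred_fit = P_fit @ w
        pred_eval = P_eval @ w
        weights = {r: float(wi) for r, wi in zip(ranks, w)}
    else:  # per_type: independent convex MAE minimization per type
        weights = {}
        pred_fit = np.empty(len(fit_ids))
        pred_eval = np.empty(len(eval_ids))
        for label in np.unique(t_fit):
            mask_f = t_fit == label
            w_t = _optimize_mae_simplex(P_fit[mask_f], y_fit[mask_f])
            pred_fit[mask_f] = P_fit[mask_f] @ w_t
            mask_e = t_eval == label
            pred_eval[mask_e] = P_eval[mask_e] @ w_t
            for r, wi in zip(ranks, w_t):
                weights[(label, r)] = float(wi)
        uncovered = ~np.isin(t_eval, np.unique(t_fit))
        if uncovered.any():
            raise ScoringError("eval half contains a type absent from the fit half")

    fit_score = score_errors(np.abs(pred_fit - y_fit), t_fit).score
    eval_score = score_errors(np.abs(pred_eval - y_eval), t_eval).score
    return EnsembleFit(
        constituent_ranks=ranks, team_ids=team_ids, weights=weights,
        k=k, mode=mode, combiner=combiner,
        fit_record_ids=fit_ids, eval_record_ids=eval_ids,
        fit_score=float(fit_score), eval_score=float(eval_score),
    )


def contributor_count(fit: EnsembleFit, threshold: float = 0.01) -> int:
    """Number of constituents with optimized weight strictly above ``threshold``.

    In per-type mode a constituent counts if its weight exceeds the
    threshold for at least one type.
    """
    return sum(
        1 for r in fit.constituent_ranks if fit.weight_of_rank(r) > threshold
    )


def k_sweep(
    submissions: Sequence[SubmissionSet],
    truth: CouplingDataset,
    k_range: Iterable[int],
    mode: str = "global",
    combiner: str = "mean",
    seed: int = 0,
    threshold: float = 0.01,
) -> KSweepResult:
    """Exclusion sweep: refit the ME using only ranks >= k, for each k.

    For each k the summary records the ME eval score, the best individual
    eval score among the remaining constituents, their gap (best - ME;
    positive when the ensemble wins), and the contributor count at the
    weight threshold.  Per-k failures are recorded without aborting the
    sweep.
    """
    fit_ids, eval_ids = split_fit_eval(truth, seed)
    truth_all = truth.truth("test")
    types_all = truth.types("test")
    y_fit = truth_all.reindex(fit_ids).to_numpy()
    t_fit = types_all.reindex(fit_ids).to_numpy()
    y_eval = truth_all.reindex(eval_ids).to_numpy()
    t_eval = types_all.reindex(eval_ids).to_numpy()

    fit_scores = []
    eval_scores = []
    for sub in submissions:
        pf = _prediction_matrix([sub], fit_ids)[:, 0]
        pe = _prediction_matrix([sub], eval_ids)[:, 0]
        fit_scores.append(score_errors(np.abs(pf - y_fit), t_fit).score)
        eval_scores.append(score_errors(np.abs(pe - y_eval), t_eval).score)
    rank_order = list(np.argsort(fit_scores, kind="stable"))
    eval_by_rank = [eval_scores[i] for i in rank_order]

    rows, fits, failures = [], {}, {}
    n = len(submissions)
    prev_weights: dict[int, float] = {}
    for k in k_range:
        warm = None
        if prev_weights and 1 <= k <= n:
            vec = np.array([prev_weights.get(r, 0.0) for r in range(k, n + 1)])
            if vec.size:
                warm = (vec / vec.sum() if vec.sum() > 1e-6
                        else np.full(vec.size, 1.0 / vec.size))
        try:
            fit = fit_weights(
                submissions, truth, k=k, mode=mode, combiner=combiner,
                fit_ids=fit_ids, eval_ids=eval_ids, rank_order=rank_order,
                warm_start=warm,
            )
        except Exception as exc:  # record, keep sweeping
            failures[k] = str(exc)
            continue
        best_eval = float(min(eval_by_rank[k - 1:]))
        rows.append({
            "k": k,
            "me_score": fit.eval_score,
            "best_score": best_eval,
            "gap": best_eval - fit.eval_score,
            "contributors": contributor_count(fit, threshold),
        })
        fits[k] = fit
        if mode == "global" and combiner == "mean":
            # seed the next k's optimizer with this solution, re-normalized
            # over whatever ranks remain then
            prev_weights = dict(fit.weights)
    return KSweepResult(table=pd.DataFrame(rows), fits=fits, failures=failures)


def _compositions_3(total: int) -> np.ndarray:
    """All integer compositions of ``total`` into 3 parts, vectorized."""
    lens = total + 1 - np.arange(total + 1)
    i0 = np.repeat(np.arange(total + 1), lens)
    offsets = np.cumsum(lens) - lens
    i1 = np.arange(lens.sum()) - np.repeat(offsets, lens)
    return np.column_stack([i0, i1, total - i0 - i1])


def _compositions(total: int, parts: int):
    """Yield blocks of integer compositions of ``total`` into ``parts`` parts.

    Exhaustive — the lattice of a step-1/total simplex grid.  The leading
    coordinates are peeled off one at a time; the final three are built
    vectorized.
    """
    if parts == 1:
        yield np.array([[total]])
    elif parts == 2:
        i0 = np.arange(total + 1)
        yield np.column_stack([i0, total - i0])
    elif parts == 3:
        yield _compositions_3(total)
    else:
        for head in range(total + 1):
            for tail in _compositions(total - head, parts - 1):
                block = np.empty((len(tail), parts), dtype=np.int64)
                block[:, 0] = head
                block[:, 1:] = tail
                yield block


def grid_search_simplex(
    P: np.ndarray,
    y: np.ndarray,
    types: np.ndarray,
    step: float = 0.001,
) -> tuple[np.ndarray, float]:
    """Exhaustive simplex grid search for the grouped log-MAE objective.

    Enumerates every weight vector on the lattice {0, step, 2*step, ..., 1}
    with coordinates summing to 1 and returns the best (weights, score).
    Exact brute force — O(steps^(m-1)) points — usable as an independent
    oracle for small constituent counts.
    """
    n_steps = round(1.0 / step)
    if not math.isclose(n_steps * step, 1.0, rel_tol=1e-9):
        raise ConfigurationError("step must divide 1 exactly")
    Ps, ys, slices = _type_sorted(np.asarray(P, dtype=float),
                                  np.asarray(y, dtype=float),
                                  np.asarray(types))
    starts = np.array([sl.start for sl in slices])
    stops = np.array([sl.stop for sl in slices])

    best_w, best_val = None, np.inf
    for block in _compositions(n_steps, P.shape[1]):
        W = block.astype(float) * step
        pred = Ps @ W.T                        # n_records x n_points
        err = np.abs(pred - ys[:, None])
        csum = np.cumsum(err, axis=0)
        csum = np.vstack([np.zeros((1, err.shape[1])), csum])
        mae = (csum[stops] - csum[starts]) / (stops - starts)[:, None]
        vals = np.log(np.maximum(mae, MAE_FLOOR)).mean(axis=0)
        idx = int(np.argmin(vals))
        if vals[idx] < best_val:
            best_val = float(vals[idx])
            best_w = W[idx]
    return best_w, best_val
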