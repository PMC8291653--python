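"""Leaderboard progress curves: running-best extraction and bi-exponential fits.

Community competitions typically improve in two phases: a fast initial
phase in which teams adopt known-good baselines, and a slow phase of
incremental refinement.  The leader (running-best) score trace is modelled
as

    s(t) = A * exp(-t / tau1) + B * exp(-t / tau2) + C

with tau1 >= tau2 > 0 (slow and fast time constants, in days), amplitudes
A, B and asymptote C in score units.  Because the score is a log-scale
quantity, a score change ``d`` corresponds to an ``exp(d)``-fold change in
geometric-mean error; ``accuracy_ratio`` exposes that transform.

Fitting a sum of exponentials is notoriously initialization-sensitive, so
the fitter is separable: for each (tau1, tau2) pair on a logarithmic grid
the linear parameters (A, B, C) are solved in closed form by least squares,
and the best grid point seeds a joint Levenberg-Marquardt refinement of all
five parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InsufficientDataError, ScoringError
from .types import LeaderboardTrace


def biexponential(t: np.ndarray | float, A: float, B: float,
                  tau1: float, tau2: float, C: float) -> np.ndarray | float:
    """Evaluate A*exp(-t/tau1) + B*exp(-t/tau2) + C."""
    t = np.asarray(t, dtype=float)
    out = A * np.exp(-t / tau1) + B * np.exp(-t / tau2) + C
    return out if out.ndim else float(out)


@dataclass
class BiexpFit:
    """Fitted progress-curve parameters with diagnostics.

    ``tau1 >= tau2`` is enforced by swapping the (amplitude, tau) pairs
    after fitting.  For a constant trace the exponential terms are
    unidentifiable: both amplitudes are 0, the taus are NaN and
    ``identifiable`` is False.
    """

    A: float
    B: float
    tau1: float
    tau2: float
    C: float
    rss: float
    converged: bool
    identifiable: bool = True

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        if not self.identifiable:
            t = np.asarray(t, dtype=float)
            out = np.full_like(t, self.C, dtype=float)
            return out if out.ndim else float(out)
        return biexponential(t, self.A, self.B, self.tau1, self.tau2, self.C)

    def as_dict(self) -> dict:
        return {
            "A": self.A, "B": self.B, "tau1": self.tau1, "tau2": self.tau2,
            "C": self.C, "rss": self.rss, "converged": self.converged,
            "identifiable": self.identifiable,
        }


def running_best(points: pd.DataFrame | Iterable[tuple]) -> LeaderboardTrace:
    """Cumulative minimum of score over time.

    ``points`` is a DataFrame with columns ``timestamp_days``, ``score``,
    ``team_id`` (or an iterable of such tuples).  Simultaneous submissions
    are resolved stably by team id then original order.  Idempotent: the
    running best of a running-best trace is itself.
    """
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame(
            list(points), columns=["timestamp_days", "score", "team_id"]
        )
    if points.empty:
        empty = points.iloc[0:0]
        return LeaderboardTrace(points=empty, running_best=empty[["timestamp_days", "score"]])
    ordered = points.sort_values(
        ["timestamp_days", "team_id"], kind="stable"
    ).reset_index(drop=True)
    best = ordered[["timestamp_days"]].copy()
    best["score"] = ordered["score"].cummin()
    return LeaderboardTrace(points=ordered, running_best=best)


def resample_daily(trace: pd.DataFrame, step_days: float = 1.0) -> pd.DataFrame:
    """Resample a running-best trace to a uniform time grid.

    Last value carried forward (the leader score is a step function), so
    dense submission bursts do not dominate a subsequent fit.
    """
    t = trace["timestamp_days"].to_numpy(dtype=float)
    s = trace["score"].to_numpy(dtype=float)
    if t.size == 0:
        return trace.copy()
    grid = np.arange(t[0], t[-1] + 0.5 * step_days, step_days)
    idx = np.searchsorted(t, grid, side="right") - 1
    return pd.DataFrame({"timestamp_days": grid, "score": s[idx]})


def _solve_linear(t: np.ndarray, s: np.ndarray,
                  tau1: float, tau2: float) -> tuple[np.ndarray, float]:
    """Closed-form (A, B, C) for fixed time constants; returns (params, rss)."""
    design = np.column_stack(
        [np.exp(-t / tau1), np.exp(-t / tau2), np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(design, s, rcond=None)
    resid = s - design @ coef
    return coef, float(resid @ resid)


def fit_biexponential(
    trace: pd.DataFrame | LeaderboardTrace,
    tau_grid: Sequence[float] | None = None,
    resample_step_days: float | None = 1.0,
    seed: int | None = None,
) -> BiexpFit:
    """Fit the five-parameter bi-exponential to a running-best trace.

    Parameters
    ----------
    trace:
        Running-best trace: DataFrame with ``timestamp_days`` and ``score``,
        or a :class:`LeaderboardTrace` (its ``running_best`` is used).
    tau_grid:
        Candidate time constants for the separable multi-start, default a
        logarithmic grid over [0.1, 200] days.  All ordered pairs
        (tau1 > tau2) are tried.
    resample_step_days:
        Resample the trace to this uniform step before fitting (None to fit
        the raw event times).
    seed:
        Unused by the deterministic grid search; accepted for interface
        stability.
    """
    if isinstance(trace, LeaderboardTrace):
        trace = trace.running_best
    if resample_step_days is not None and len(trace) > 1:
        trace = resample_daily(trace, resample_step_days)
    t = trace["timestamp_days"].to_numpy(dtype=float)
    s = trace["score"].to_numpy(dtype=float)
    if t.size < 6:
        raise InsufficientDataError(
            f"bi-exponential fit needs >= 6 points, got {t.size}"
        )
    if np.any(t < 0):
        raise InsufficientDataError("timestamps must be nonnegative")

    if np.ptp(s) == 0.0:
        # Flat trace: exponential amplitudes and taus unidentifiable.
        return BiexpFit(A=0.0, B=0.0, tau1=math.nan, tau2=math.nan,
                        C=float(s[0]), rss=0.0, converged=True,
                        identifiable=False)

    if tau_grid is None:
        tau_grid = np.geomspace(0.1, 200.0, 25)
    tau_grid = np.asarray(tau_grid, dtype=float)

    best = None
    for i, tau1 in enumerate(tau_grid):
        for tau2 in tau_grid[:i]:  # tau1 > tau2 at initialization
            coef, rss = _solve_linear(t, s, tau1, tau2)
            if best is None or rss < best[0]:
                best = (rss, coef, tau1, tau2)
    rss0, (A0, B0, C0), tau1_0, tau2_0 = best

    def residual(p: np.ndarray) -> np.ndarray:
        return biexponential(t, p[0], p[1], p[2], p[3], p[4]) - s

    x0 = np.array([A0, B0, tau1_0, tau2_0, C0])
    lower = [-np.inf, -np.inf, 1e-6, 1e-6, -np.inf]
    upper = [np.inf] * 5
    result = least_squares(residual, x0, bounds=(lower, upper),
                           xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=10_000)
    rss = float(result.fun @ result.fun)
    # Monotone acceptance: keep the grid solution if refinement regressed.
    if rss <= rss0:
        A, B, tau1, tau2, C = result.x
        converged = bool(result.success)
    else:
        A, B, tau1, tau2, C = A0, B0, tau1_0, tau2_0, C0
        rss, converged = rss0, False
    if tau1 < tau2:
        A, B, tau1, tau2 = B, A, tau2, tau1
    # Equal time constants are a single exponential in disguise; canonicalize
    # the unidentifiable amplitude split so the slow term carries it all.
    if np.isfinite(tau1) and np.isfinite(tau2) and abs(tau1 - tau2) <= 1e-3 * tau1:
        A, B = A + B, 0.0
    return BiexpFit(A=float(A), B=float(B), tau1=float(tau1),
                    tau2=float(tau2), C=float(C), rss=rss,
                    converged=converged)


def accuracy_ratio(delta_score: float) -> float:
    """Fold-change in geometric-mean error implied by a score improvement.

    A score drop of 2.5 corresponds to an ``exp(2.5) ~ 12.18``-fold error
    reduction.
    """
    if not np.isfinite(delta_score):
        raise ScoringError(f"delta_score must be finite, got {delta_score}")
    return math.exp(delta_score)


def phase_summary(fit: BiexpFit, boundary_days: float,
                  t_start: float = 0.0, t_end: float | None = None) -> dict:
    """Split the fitted curve into two phases at ``boundary_days``.

    Returns per-phase duration, score change along the fitted curve, the
    implied accuracy factor exp(-delta), and the dominant time constant
    (the tau whose exponential term loses the most amplitude within the
    phase).  ``t_end`` defaults to three slow time constants past the
    boundary when identifiable.
    """
    if t_end is None:
        t_end = boundary_days + (3.0 * fit.tau1 if fit.identifiable else 1.0)
    if not (t_start <= boundary_days <= t_end):
        raise ScoringError(
            f"phase boundary {boundary_days} outside [{t_start}, {t_end}]"
        )

    def term_drop(amplitude: float, tau: float, a: float, b: float) -> float:
        if not fit.identifiable or not np.isfinite(tau):
            return 0.0
        return abs(amplitude) * (math.exp(-a / tau) - math.exp(-b / tau))

    phases = {}
    for name, (a, b) in {
        "phase1": (t_start, boundary_days),
        "phase2": (boundary_days, t_end),
    }.items():
        delta = float(fit(b) - fit(a))
        drops = {
            "tau1": term_drop(fit.A, fit.tau1, a, b),
            "tau2": term_drop(fit.B, fit.tau2, a, b),
        }
        dominant = max(drops, key=drops.get)
        phases[name] = {
            "duration_days": b - a,
            "score_change": delta,
            "accuracy_factor": accuracy_ratio(-delta),
            "dominant_time_constant_days": getattr(fit, dominant),
        }
    return phases
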