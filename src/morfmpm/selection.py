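"""Feature-subset selection by simulated annealing over a scatter criterion.

The separability score of a column subset is J_d = tr(S_w + S_b), with
S_b = sum_i P_i (m_i - m)(m_i - m)^T the between-class scatter and
S_w = sum_i P_i (1/N_i) sum_{x in class i} (x - m_i)(x - m_i)^T the
prior-weighted within-class scatter (P_i = N_i / N). Note that
tr(S_w) + tr(S_b) collapses algebraically to the trace of the pooled total
scatter (1/N) sum_j ||x_j - m||^2 — i.e. the criterion as stated is
label-independent and rewards high-variance columns. It is implemented
verbatim, with that identity documented and tested; a trace-ratio
alternative tr(S_w^{-1} S_b) is available behind ``criterion="trace_ratio"``.

The annealer performs one single-feature swap per temperature level,
accepts any improvement, accepts a worsening move with probability
exp(-|dJ|/T), cools geometrically (T <- r*T), and returns the best state
visited.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ValidationError

DEFAULT_T_MAX = 1.0
DEFAULT_T_MIN = 1e-4
DEFAULT_RATE = 0.9995


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for the annealer."""

    t_max: float = DEFAULT_T_MAX
    t_min: float = DEFAULT_T_MIN
    rate: float = DEFAULT_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_max > self.t_min > 0):
            raise ValidationError("need t_max > t_min > 0")
        if not (0 < self.rate < 1):
            raise ValidationError("cooling rate must be in (0, 1)")


@dataclass(frozen=True)
class ScatterResult:
    """Traces of the scatter matrices on a column subset."""

    j_d: float
    s_b_trace: float
    s_w_trace: float


@dataclass
class SelectionResult:
    """Outcome of one annealing run: the best-visited subset, its score,
    and the per-iteration trajectory (iteration, T, current J_d, accepted)."""

    selected: tuple
    j_d: float
    trajectory: list


def _check_two_classes(y: np.ndarray) -> tuple:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(
            f"need exactly two classes in y, got {classes.size}"
        )
    return classes


def scatter_criterion(X: np.ndarray, y: np.ndarray, subset: Sequence[int]) -> ScatterResult:
    """J_d = tr(S_w + S_b) on the given column subset, by the literal
    matrix formulas with empirical priors P_i = N_i / N."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subset = list(subset)
    if not subset:
        raise ValidationError("subset must be nonempty")
    if min(subset) < 0 or max(subset) >= X.shape[1]:
        raise ValidationError("subset column out of range")
    classes = _check_two_classes(y)
    Xs = X[:, subset]
    n_total = Xs.shape[0]
    m = Xs.mean(axis=0)
    s_b = np.zeros((len(subset), len(subset)))
    s_w = np.zeros((len(subset), len(subset)))
    for cls in classes:
        Xi = Xs[y == cls]
        n_i = Xi.shape[0]
        p_i = n_i / n_total
        m_i = Xi.mean(axis=0)
        d = (m_i - m)[:, None]
        s_b += p_i * (d @ d.T)
        centered = Xi - m_i
        s_w += p_i * (centered.T @ centered) / n_i
    return ScatterResult(
        j_d=float(np.trace(s_w) + np.trace(s_b)),
        s_b_trace=float(np.trace(s_b)),
        s_w_trace=float(np.trace(s_w)),
    )


def trace_ratio_criterion(X: np.ndarray, y: np.ndarray, subset: Sequence[int],
                          ridge: float = 1e-9) -> float:
    """Non-default alternative: tr(S_w^{-1} S_b), which unlike J_d is
    genuinely label-dependent."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subset = list(subset)
    classes = _check_two_classes(y)
    Xs = X[:, subset]
    m = Xs.mean(axis=0)
    d_dim = len(subset)
    s_b = np.zeros((d_dim, d_dim))
    s_w = np.zeros((d_dim, d_dim))
    for cls in classes:
        Xi = Xs[y == cls]
        p_i = Xi.shape[0] / Xs.shape[0]
        m_i = Xi.mean(axis=0)
        dd = (m_i - m)[:, None]
        s_b += p_i * (dd @ dd.T)
        centered = Xi - m_i
        s_w += p_i * (centered.T @ centered) / Xi.shape[0]
    s_w = s_w + ridge * np.trace(s_w) / d_dim * np.eye(d_dim)
    return float(np.trace(np.linalg.solve(s_w, s_b)))


def acceptance_probability(j_current: float, j_proposed: float, temperature: float) -> float:
    """Probability of moving to the proposed state: 1 for an improvement,
    exp(-|dJ|/T) otherwise (so an equal-score move is always taken)."""
    if j_proposed > j_current:
        return 1.0
    if temperature <= 0:
        return 0.0
    return math.exp(-abs(j_current - j_proposed) / temperature)


def _column_scores(X: np.ndarray, y: np.ndarray, pool: Sequence[int],
                   criterion: str) -> dict | None:
    """Per-column J_d contributions; valid because the trace is additive
    over subset columns. Returns None for non-additive criteria."""
    if criterion != "jd":
        return None
    return {c: scatter_criterion(X, y, [c]).j_d for c in pool}


def anneal_select(
    X: np.ndarray,
    y: np.ndarray,
    n_fea: int,
    pool: Sequence[int] | None = None,
    schedule: AnnealSchedule = AnnealSchedule(),
    criterion: str = "jd",
) -> SelectionResult:
    """Simulated-annealing search for a size-``n_fea`` column subset
    maximizing the scatter criterion; returns the best state visited."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    pool = list(range(X.shape[1])) if pool is None else list(pool)
    if n_fea < 1:
        raise ValidationError("n_fea must be >= 1")
    if n_fea > len(pool):
        raise ValidationError(f"n_fea={n_fea} exceeds pool size {len(pool)}")

    def evaluate(subset: Sequence[int]) -> float:
        if criterion == "jd":
            return scatter_criterion(X, y, subset).j_d
        if criterion == "trace_ratio":
            return trace_ratio_criterion(X, y, subset)
        raise ValidationError(f"unknown criterion {criterion!r}")

    if n_fea == len(pool):
        sel = tuple(sorted(pool))
        return SelectionResult(selected=sel, j_d=evaluate(sel), trajectory=[])

    col_scores = _column_scores(X, y, pool, criterion)
    rng = np.random.default_rng(schedule.seed)
    state = list(rng.choice(pool, size=n_fea, replace=False))
    in_state = set(state)
    outside = [c for c in pool if c not in in_state]

    if col_scores is not None:
        j_current = sum(col_scores[c] for c in state)
    else:
        j_current = evaluate(state)

    best_state = tuple(sorted(state))
    best_j = j_current
    trajectory = []

    t = schedule.t_max
    iteration = 0
    while t > schedule.t_min:
        # one single-feature swap per temperature level
        out_idx = rng.integers(len(state))
        in_idx = rng.integers(len(outside))
        leaving, entering = state[out_idx], outside[in_idx]
        if col_scores is not None:
            j_proposed = j_current - col_scores[leaving] + col_scores[entering]
        else:
            trial = list(state)
            trial[out_idx] = entering
            j_proposed = evaluate(trial)
        accepted = rng.random() < acceptance_probability(j_current, j_proposed, t)
        if accepted:
            state[out_idx], outside[in_idx] = entering, leaving
            j_current = j_proposed
            if j_current > best_j:
                best_j = j_current
                best_state = tuple(sorted(state))
        trajectory.append((iteration, t, j_current, accepted))
        t *= schedule.rate
        iteration += 1

    return SelectionResult(selected=best_state, j_d=float(best_j), trajectory=trajectory)


def candidate_sweep(
    X: np.ndarray,
    y: np.ndarray,
    n_fea_range: Sequence[int],
    pool: Sequence[int] | None = None,
    schedule: AnnealSchedule = AnnealSchedule(),
    criterion: str = "jd",
) -> dict:
    """One annealing run per subset size, with per-run seeds derived from
    the schedule's master seed; deterministic given that seed."""
    n_fea_range = list(n_fea_range)
    if not n_fea_range:
        raise ValidationError("n_fea_range must be nonempty")
    children = np.random.SeedSequence(schedule.seed).spawn(len(n_fea_range))
    out = {}
    for n_fea, child in zip(n_fea_range, children):
        child_seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
        run_schedule = AnnealSchedule(
            t_max=schedule.t_max, t_min=schedule.t_min,
            rate=schedule.rate, seed=child_seed,
        )
        out[n_fea] = anneal_select(X, y, n_fea, pool, run_schedule, criterion)
    return out


def write_trajectory(path, result: SelectionResult) -> None:
    """Trajectory log as TSV: iteration, temperature, J_d, accepted."""
    with open(path, "w") as fh:
        fh.write("iteration\ttemperature\tj_d\taccepted\n")
        for it, t, j, acc in result.trajectory:
            fh.write(f"{it}\t{t:.8g}\t{j:.10g}\t{int(acc)}\n")
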