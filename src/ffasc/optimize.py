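"""Criterion-weight estimation by constrained generalized pattern search.

The weights of the 49 criteria are fitted against one positive and one
negative reference strain (experimentally established good and poor FFA
producers).  The optimizer maximises

    f(w) = w^T |x_pos - x_neg|  +  p * rank_gap(w)

subject to the box bounds 0.001 <= w_j <= 1, the budget sum_j w_j = 12 and
the strict separation constraint w^T |x_pos - x_neg| > 0.001, where
``rank_gap`` is rank(neg) - rank(pos) in the weighted ranking of all
species (positive when the good producer ranks better, since rank 1 is
best) and ``p`` is the ranking-effect coefficient (default 0.010241).

Generalized pattern search (GPS) polls the 2m signed coordinate directions
scaled by the current mesh size; each poll point is projected onto the
feasible set (Euclidean projection onto box ∩ hyperplane), candidates that
violate the separation floor are rejected, the first improving candidate is
accepted (mesh expands ×2), and a full unsuccessful poll contracts the mesh
×0.5 until it falls below the mesh tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleConfigError
from .scoring import rank_species, score_matrix

SUM_TOLERANCE = 1e-9


@dataclass
class OptimizationConfig:
    """Tunable parameters of the weight optimization.

    ``p`` trades score separation against rank separation; the bounds and
    the weight budget ``sum_target`` define the feasible set; the mesh
    parameters control the pattern-search schedule.
    """

    p: float = 0.010241
    lower_bound: float = 0.001
    upper_bound: float = 1.0
    sum_target: float = 12.0
    separation_floor: float = 0.001
    initial_mesh: float = 0.25
    expansion: float = 2.0
    contraction: float = 0.5
    mesh_tolerance: float = 1e-6
    mesh_cap: float = 2.0  # polls beyond the box diameter only get clipped
    #: forcing constant of the sufficient-increase rule: a poll point is
    #: accepted only when it gains more than c·mesh² (plus a floating-point
    #: floor), which prevents the search from chasing rounding-level noise
    #: at large mesh sizes
    forcing_constant: float = 1e-3
    improvement_floor: float = 1e-12
    max_iterations: int = 2000
    seed: int = 0

    def validate(self, m: int) -> None:
        if self.p < 0:
            raise InfeasibleConfigError("ranking-effect coefficient p must be ≥ 0")
        if not (m * self.lower_bound <= self.sum_target <= m * self.upper_bound):
            raise InfeasibleConfigError(
                f"sum target {self.sum_target} outside "
                f"[{m * self.lower_bound}, {m * self.upper_bound}] for m={m}"
            )


@dataclass
class TraceRecord:
    iteration: int
    objective: float
    mesh: float
    accepted: bool


@dataclass
class OptimizationResult:
    weights: np.ndarray
    objective: float
    iterations: int
    trace: list[TraceRecord] = field(default_factory=list)
    feasible: bool = True
    og_ids: list[str] | None = None

    def weight_series(self) -> pd.Series:
        index = self.og_ids if self.og_ids is not None else range(len(self.weights))
        return pd.Series(self.weights, index=index, name="weight")


def project_to_feasible(
    w: Sequence[float], config: OptimizationConfig
) -> np.ndarray:
    """Euclidean projection onto {lb <= w <= ub, sum w = S}.

    Computed as ``clip(w + lam, lb, ub)`` with the shift ``lam`` found by
    bisection on the monotone sum; this is the exact minimum-distance
    projection.  Returns the input unchanged when already feasible; the
    returned sum matches the target within 1e-9.
    """
    wa = np.asarray(w, dtype=float)
    m = wa.shape[0]
    config.validate(m)
    lb, ub, target = config.lower_bound, config.upper_bound, config.sum_target
    if (
        np.all(wa >= lb)
        and np.all(wa <= ub)
        and abs(wa.sum() - target) <= SUM_TOLERANCE
    ):
        return wa.copy()

    lo = lb - wa.max()          # all entries clipped to lb: sum = m*lb <= S
    hi = ub - wa.min()          # all entries clipped to ub: sum = m*ub >= S
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        s = np.clip(wa + mid, lb, ub).sum()
        if s < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 * max(1.0, abs(hi)):
            break
    projected = np.clip(wa + 0.5 * (lo + hi), lb, ub)
    # distribute any residual over strictly interior coordinates
    residual = target - projected.sum()
    interior = (projected > lb) & (projected < ub)
    if abs(residual) > 0 and interior.any():
        projected[interior] += residual / interior.sum()
        projected = np.clip(projected, lb, ub)
    return projected


def rank_gap(
    weights: Sequence[float],
    criteria: pd.DataFrame,
    pos_id: str,
    neg_id: str,
) -> int:
    """rank(negative) − rank(positive) under the weighted ranking.

    Positive when the positive reference strain ranks better (closer to 1).
    """
    for sid in (pos_id, neg_id):
        if sid not in criteria.index:
            raise KeyError(f"species {sid!r} not in criteria matrix")
    scores = score_matrix(criteria, weights)
    table = rank_species(scores).set_index("species_id")["rank"]
    return int(table[neg_id] - table[pos_id])


def objective_value(
    w: Sequence[float],
    x_pos: Sequence[float],
    x_neg: Sequence[float],
    p: float,
    gap: int,
) -> float:
    """Score-separation term plus the rank-effect term: w^T|Δx| + p·gap."""
    wa = np.asarray(w, dtype=float)
    delta = np.abs(np.asarray(x_pos, dtype=float) - np.asarray(x_neg, dtype=float))
    return float(wa @ delta) + p * gap


def pattern_search_optimize(
    criteria: pd.DataFrame,
    pos_id: str,
    neg_id: str,
    config: OptimizationConfig | None = None,
    initial_weights: Sequence[float] | None = None,
) -> OptimizationResult:
    """Fit criterion weights by GPS on the reference-pair objective.

    Accepted-iterate objectives are non-decreasing by construction; every
    evaluated point (and the returned solution) satisfies the box and sum
    constraints.  Deterministic for fixed inputs and configuration.
    """
    if pos_id == neg_id:
        raise ValueError("positive and negative reference must differ")
    cfg = config or OptimizationConfig()
    m = criteria.shape[1]
    cfg.validate(m)

    x_pos = criteria.loc[pos_id].to_numpy(dtype=float)
    x_neg = criteria.loc[neg_id].to_numpy(dtype=float)
    delta = np.abs(x_pos - x_neg)

    if initial_weights is None:
        initial_weights = np.full(m, cfg.sum_target / m)
    w = project_to_feasible(np.asarray(initial_weights, dtype=float), cfg)

    # vectorised rank gap (same descending-score, id-tie-break convention
    # as scoring.rank_species, which unit tests cross-check)
    C = criteria.to_numpy(dtype=float)
    ids = [str(s) for s in criteria.index]
    i_pos, i_neg = ids.index(str(pos_id)), ids.index(str(neg_id))
    id_lt_pos = np.array([s < ids[i_pos] for s in ids])
    id_lt_neg = np.array([s < ids[i_neg] for s in ids])

    def fast_gap(wv: np.ndarray) -> int:
        scores = C @ wv
        r_pos = 1 + int((scores > scores[i_pos]).sum()) + int(
            ((scores == scores[i_pos]) & id_lt_pos).sum()
        )
        r_neg = 1 + int((scores > scores[i_neg]).sum()) + int(
            ((scores == scores[i_neg]) & id_lt_neg).sum()
        )
        return r_neg - r_pos

    def separation(wv: np.ndarray) -> float:
        return float(wv @ delta)

    def f(wv: np.ndarray) -> float:
        return separation(wv) + cfg.p * fast_gap(wv)

    current = f(w)
    mesh = cfg.initial_mesh
    trace: list[TraceRecord] = [TraceRecord(0, current, mesh, True)]
    iterations = 0

    for iteration in range(1, cfg.max_iterations + 1):
        if mesh < cfg.mesh_tolerance:
            break
        iterations = iteration
        improved = False
        threshold = max(cfg.improvement_floor, cfg.forcing_constant * mesh * mesh)
        for j in range(m):
            for sign in (1.0, -1.0):
                candidate = w.copy()
                candidate[j] += sign * mesh
                candidate = project_to_feasible(candidate, cfg)
                if separation(candidate) <= cfg.separation_floor:
                    continue  # strict separation constraint
                value = f(candidate)
                if value > current + threshold:
                    w, current = candidate, value
                    improved = True
                    break
            if improved:
                break
        if improved:
            mesh = min(mesh * cfg.expansion, cfg.mesh_cap)
        else:
            mesh *= cfg.contraction
        trace.append(TraceRecord(iteration, current, mesh, improved))

    feasible = (
        bool(np.all(w >= cfg.lower_bound - 1e-12))
        and bool(np.all(w <= cfg.upper_bound + 1e-12))
        and abs(float(w.sum()) - cfg.sum_target) <= SUM_TOLERANCE
        and separation(w) > cfg.separation_floor
    )
    return OptimizationResult(
        weights=w,
        objective=current,
        iterations=iterations,
        trace=trace,
        feasible=feasible,
        og_ids=list(criteria.columns),
    )
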