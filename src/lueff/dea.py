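"""CCR data envelopment analysis in multiplier form.

Each decision-making unit (DMU; here a landscape unit) is scored by the
linear program

    max   sum_r u_r y_rk                      (weighted outputs of unit k)
    s.t.  sum_i v_i x_ij - sum_r u_r y_rj >= 0   for every unit j
          sum_i v_i x_ik = 1                     (input normalization)
          u_r, v_i >= eps_w > 0

under constant returns to scale.  The optimum theta_k lies in (0, 1]; units
with theta = 1 span the efficient frontier.  Under constant returns the
multiplier score coincides with both the input- and output-oriented radial
technical efficiency, so the single score serves an output-oriented reading
(how far outputs could be expanded at given cost).

Strict weight positivity is enforced through the classic non-Archimedean
epsilon surrogate: a small lower bound ``eps_w`` (default 1e-9) on every
multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

CATEGORIES = ("efficient", "less_inefficient", "more_inefficient")


@dataclass
class DEAProblem:
    """Input/output data for a CCR efficiency analysis.

    ``x`` is the n x m input matrix, ``y`` the n x s output matrix; both must
    be strictly positive (zeros are replaced upstream).
    """

    x: np.ndarray
    y: np.ndarray
    dmu_names: list[str] = field(default_factory=list)
    input_names: list[str] = field(default_factory=list)
    output_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y must have one row per DMU")
        if self.x.shape[0] < 1:
            raise ValueError("need at least one DMU")
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            raise ValueError("DEA data must be strictly positive")
        if not self.dmu_names:
            self.dmu_names = [str(j) for j in range(self.n)]

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def m(self) -> int:
        return self.x.shape[1]

    @property
    def s(self) -> int:
        return self.y.shape[1]


@dataclass
class DEAResult:
    """Scores, multiplier weights, peers and categories for all DMUs."""

    scores: np.ndarray  # theta_k in (0, 1]
    input_weights: np.ndarray  # n x m optimal v
    output_weights: np.ndarray  # n x s optimal u
    peers: list[list[int]]  # binding reference units per DMU
    categories: np.ndarray  # strings from CATEGORIES
    dmu_names: list[str]

    @property
    def n_efficient(self) -> int:
        return int(np.sum(self.categories == "efficient"))

    def summary(self) -> dict[str, float]:
        return {
            "n": len(self.scores),
            "mean": float(np.mean(self.scores)),
            "sd": float(np.std(self.scores, ddof=1)) if len(self.scores) > 1 else 0.0,
            "n_efficient": self.n_efficient,
        }


def _scaled_data(problem: DEAProblem) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-rescaled copies of (x, y) with unit column maxima.

    CCR scores are invariant to units, so solving on rescaled data changes
    nothing mathematically while making the LP numerics invariant to the
    units of the raw columns (scores move by ~1e-12, not solver tolerance).
    """
    xmax = problem.x.max(axis=0)
    ymax = problem.y.max(axis=0)
    return problem.x / xmax, problem.y / ymax, xmax, ymax


def _constraint_matrix(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    # rows j:  -v.x_j + u.y_j <= 0, variables ordered [v (m), u (s)]
    return np.hstack([-xs, ys])


def solve_ccr(
    problem: DEAProblem,
    k: int,
    eps_w: float = 1e-9,
    _A_ub: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray, list[int]]:
    """Solve the CCR multiplier LP for DMU ``k``.

    Returns ``(theta, v, u, peers)`` where peers are the DMUs whose
    output/input constraint binds at the optimum (the reference set).
    """
    if not 0 <= k < problem.n:
        raise IndexError(f"DMU index {k} out of range")
    if eps_w < 0:
        raise ValueError("eps_w must be non-negative")
    m, s = problem.m, problem.s
    xs, ys, xmax, ymax = _scaled_data(problem)
    A_ub = _A_ub if _A_ub is not None else _constraint_matrix(xs, ys)
    c = np.concatenate([np.zeros(m), -ys[k]])
    A_eq = np.concatenate([xs[k], np.zeros(s)])[None, :]
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(problem.n),
        A_eq=A_eq,
        b_eq=[1.0],
        # non-Archimedean lower bound applied to the unit-scaled multipliers;
        # original-scale weights stay strictly positive (>= eps_w / col_max)
        # and the scaled LP is identical under any column rescaling
        bounds=[(eps_w, None)] * (m + s),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(
            f"CCR LP failed for DMU {k} ({problem.dmu_names[k]}): {res.message}; "
            f"eps_w={eps_w} may be too large for feasibility"
        )
    w = res.x
    theta = float(w[m:] @ ys[k])
    if theta > 1.0 + 1e-6:
        raise RuntimeError(f"CCR score {theta} exceeds 1 beyond tolerance for DMU {k}")
    theta = min(theta, 1.0)
    slack = A_ub @ w  # <= 0, zero where binding
    peers = [int(j) for j in np.flatnonzero(slack > -1e-7)]
    # express multipliers on the original data scale
    v, u = w[:m] / xmax, w[m:] / ymax
    return theta, v, u, peers


def efficiency_all(
    problem: DEAProblem, eps_w: float = 1e-9, tol: float = 1e-6
) -> DEAResult:
    """Score every DMU and attach efficiency categories."""
    xs, ys, _, _ = _scaled_data(problem)
    A_ub = _constraint_matrix(xs, ys)
    thetas = np.empty(problem.n)
    vs = np.empty((problem.n, problem.m))
    us = np.empty((problem.n, problem.s))
    peers: list[list[int]] = []
    for k in range(problem.n):
        try:
            theta, v, u, pk = solve_ccr(problem, k, eps_w, _A_ub=A_ub)
        except RuntimeError as exc:
            raise RuntimeError(f"DEA failed at DMU {problem.dmu_names[k]}: {exc}") from exc
        thetas[k] = theta
        vs[k] = v
        us[k] = u
        peers.append(pk)
    categories = categorize_efficiency(thetas, tol=tol)
    return DEAResult(
        scores=thetas,
        input_weights=vs,
        output_weights=us,
        peers=peers,
        categories=categories,
        dmu_names=list(problem.dmu_names),
    )


def categorize_efficiency(
    scores: np.ndarray, tol: float = 1e-6, mean_of_inefficient: bool = False
) -> np.ndarray:
    """Three-way efficiency classification.

    Units with theta >= 1 - tol are ``efficient``.  The remaining
    (inefficient) units are ``less_inefficient`` when at or above the average
    efficiency and ``more_inefficient`` below it.  The average is taken over
    all scores by default; ``mean_of_inefficient`` restricts it to the
    inefficient subset.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to categorize")
    if np.any(scores <= 0) or np.any(scores > 1 + 1e-9):
        raise ValueError("scores must lie in (0, 1]")
    efficient = scores >= 1.0 - tol
    ref = scores[~efficient].mean() if mean_of_inefficient and (~efficient).any() else scores.mean()
    out = np.where(
        efficient,
        "efficient",
        np.where(scores >= ref, "less_inefficient", "more_inefficient"),
    )
    return out.astype(object)


def brute_force_oracle(
    problem: DEAProblem, k: int, grid_density: int = 10_000, refine_rounds: int = 4
) -> float:
    """Independent simplex-grid oracle for the single-input CCR score.

    With one input the normalization fixes v = 1/x_k, and for any direction
    ``w`` on the output-weight simplex the best feasible scaling is

        t(w) = min_j x_j / (x_k * (w . y_j)),   score(w) = t(w) * (w . y_k).

    The oracle maximizes ``score`` over a dense grid of simplex directions,
    then re-grids locally around the best candidates.  Every evaluated point
    is feasible, so the oracle approaches the LP optimum from below.
    """
    if problem.m != 1:
        raise ValueError("oracle supports a single input only")
    if problem.s > 3:
        raise ValueError("oracle supports at most 3 outputs")
    x = problem.x[:, 0]
    y = problem.y
    s = problem.s

    def best_on(points: np.ndarray) -> tuple[float, np.ndarray]:
        denom = points @ y.T  # (p, n)
        t = (x / x[k] / denom).min(axis=1)
        scores = t * (points @ y[k])
        i = int(np.argmax(scores))
        return float(scores[i]), points[i]

    if s == 1:
        return best_on(np.array([[1.0]]))[0]

    # initial grid with about `grid_density` points on the (s-1)-simplex
    if s == 2:
        D = max(2, grid_density)
        a = np.linspace(0.0, 1.0, D + 1)
        pts = np.column_stack([a, 1.0 - a])
    else:
        D = max(2, int(np.sqrt(2.0 * grid_density)))
        ij = [(i, j) for i in range(D + 1) for j in range(D + 1 - i)]
        arr = np.array(ij, dtype=float) / D
        pts = np.column_stack([arr[:, 0], arr[:, 1], 1.0 - arr.sum(axis=1)])
    pts = np.maximum(pts, 0.0)
    mask = pts.sum(axis=1) > 0
    best, w = best_on(pts[mask])

    # nested local grids around the incumbent (still pure feasible evaluation)
    half = 1.5 / D
    for _ in range(refine_rounds):
        grids = [np.linspace(max(0.0, w[d] - half), w[d] + half, 21) for d in range(s)]
        mesh = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, s)
        mesh = mesh[mesh.sum(axis=1) > 0]
        mesh = mesh / mesh.sum(axis=1, keepdims=True)
        cand, wc = best_on(mesh)
        if cand > best:
            best, w = cand, wc
        half /= 8.0
    return best
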