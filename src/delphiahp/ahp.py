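"""Analytic-hierarchy-process weighting driven by mean-score differences.

One positive reciprocal judgment matrix is built per parent node (plus one
over the top-level indicators) by mapping the absolute difference of sibling
mean scores onto the 1–9 comparison scale through a binned lookup. Weights
come from the principal right eigenvector (power iteration); consistency is
checked with CR = CI/RI against the 0.1 gate.

Two λmax estimators are provided. The eigenvalue from power iteration is the
mathematically exact one; ``column_mean`` normalises each column, averages
rows into weights, and takes λmax as the mean of (Aw)_i/w_i. The column-mean
estimator is the default for *consistency reporting* because it is the
convention of the reference implementation this package reproduces (its CRs
match the published four-decimal values; the exact eigenvalue differs in the
fourth decimal for near-consistent matrices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SaatyMapping",
    "JudgmentMatrix",
    "ConsistencyResult",
    "WeightVector",
    "AhpReport",
    "AhpError",
    "ConsistencyGateError",
    "DEFAULT_SAATY_BINS",
    "DEFAULT_RANDOM_INDEX",
    "build_matrix",
    "principal_weights",
    "geometric_mean_weights",
    "column_mean_weights",
    "consistency",
    "combine_weights",
    "full_ahp",
    "calibrate_mapping",
]

# |mean difference| bins: (inclusive upper bound, scale value)
DEFAULT_SAATY_BINS: tuple[tuple[float, int], ...] = (
    (0.0, 1),
    (0.15, 2),
    (0.35, 3),
    (0.50, 4),
    (0.75, 5),
    (0.85, 6),
    (math.inf, 7),
)

# Random index by matrix order; CR := 0 for n <= 2.
DEFAULT_RANDOM_INDEX: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.52,
    4: 0.89,
    5: 1.12,
    6: 1.26,
    7: 1.36,
    8: 1.41,
    9: 1.46,
}

CR_THRESHOLD = 0.1
_RECIPROCAL_TOL = 1e-9


class AhpError(ValueError):
    pass


class ConsistencyGateError(AhpError):
    """Raised when a judgment matrix fails the CR < 0.1 gate."""

    def __init__(self, failures: dict[str, float]):
        self.failures = dict(failures)
        names = ", ".join(f"{k} (CR={v:.4f})" for k, v in self.failures.items())
        super().__init__(f"consistency gate failed for: {names}")


@dataclass(frozen=True)
class SaatyMapping:
    """Binned lookup from |mean difference| to the 1–9 comparison scale.

    Bins are (inclusive upper bound, scale) pairs with strictly increasing
    bounds and non-decreasing scales; the first bin maps a zero difference
    to scale 1.
    """

    bins: tuple[tuple[float, int], ...] = DEFAULT_SAATY_BINS

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.bins]
        scales = [s for _, s in self.bins]
        if not bounds or bounds[0] != 0.0 or scales[0] != 1:
            raise AhpError("first bin must map difference 0 to scale 1")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise AhpError("bin bounds must be strictly increasing")
        if any(s2 < s1 for s1, s2 in zip(scales, scales[1:])):
            raise AhpError("scale values must be non-decreasing")
        if any(not 1 <= s <= 9 for s in scales):
            raise AhpError("scale values must lie in 1..9")

    def scale(self, diff: float) -> float:
        """Scale value for an absolute mean difference."""
        d = abs(diff)
        for bound, s in self.bins:
            if d <= bound + 1e-12:
                return float(s)
        return float(self.bins[-1][1])

    @classmethod
    def from_config(cls, entries: Sequence[Mapping | Sequence]) -> "SaatyMapping":
        bins = []
        for e in entries:
            if isinstance(e, Mapping):
                bound = float(e["upper"]) if e["upper"] is not None else math.inf
                bins.append((bound, int(e["scale"])))
            else:
                bound, scale = e
                bins.append(
                    (math.inf if bound is None else float(bound), int(scale))
                )
        return cls(tuple(bins))


@dataclass(frozen=True)
class JudgmentMatrix:
    """Positive reciprocal pairwise-comparison matrix over sibling items."""

    item_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.item_ids)
        if v.shape != (n, n):
            raise AhpError(f"matrix shape {v.shape} does not match {n} items")
        if np.any(v <= 0):
            raise AhpError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(v), 1.0, atol=_RECIPROCAL_TOL):
            raise AhpError("judgment matrix diagonal must be 1")
        if not np.allclose(v * v.T, 1.0, atol=1e-6):
            raise AhpError("judgment matrix is not reciprocal")

    @property
    def n(self) -> int:
        return len(self.item_ids)


@dataclass(frozen=True)
class ConsistencyResult:
    lambda_max: float
    ci: float
    ri: float
    cr: float

    @property
    def passed(self) -> bool:
        return self.cr < CR_THRESHOLD


@dataclass(frozen=True)
class WeightVector:
    """Local (sibling-normalised) and combination (global) weights per id."""

    local: dict[str, float]
    combination: dict[str, float]
    leaf_rank: dict[str, int]


@dataclass(frozen=True)
class AhpReport:
    matrices: dict[str | None, JudgmentMatrix]
    consistency: dict[str | None, ConsistencyResult]
    weights: WeightVector


# -- matrix construction ---------------------------------------------------


def build_matrix(
    means: Mapping[str, float], mapping: SaatyMapping | None = None
) -> JudgmentMatrix:
    """Judgment matrix from sibling mean scores.

    ``a_ij = scale(|mean_i − mean_j|)`` when item i scores at least as high as
    item j, and the reciprocal otherwise; the diagonal is 1. Deterministic for
    a given mapping. Iteration order of ``means`` fixes the item order.
    """
    if not means:
        raise AhpError("cannot build a judgment matrix from an empty item set")
    mapping = mapping or SaatyMapping()
    ids = tuple(means.keys())
    mu = np.array([float(means[i]) for i in ids])
    if not np.all(np.isfinite(mu)):
        raise AhpError("mean scores must be finite")
    n = len(ids)
    a = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            d = mu[i] - mu[j]
            if abs(d) < 1e-12:
                a[i, j] = 1.0
            elif d > 0:
                a[i, j] = mapping.scale(d)
            else:
                a[i, j] = 1.0 / mapping.scale(d)
    return JudgmentMatrix(ids, a)


# -- weight extraction -----------------------------------------------------


def principal_weights(
    matrix: JudgmentMatrix | np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Normalised principal right eigenvector and λmax by power iteration.

    Starts from the uniform vector; converged when successive normalised
    iterates differ by less than ``tol`` in max-norm. λmax is the Rayleigh
    quotient at the converged vector. Non-convergence signals a malformed
    matrix and raises :class:`AhpError`.
    """
    a = matrix.values if isinstance(matrix, JudgmentMatrix) else np.asarray(matrix)
    n = a.shape[0]
    if n == 1:
        return np.array([1.0]), 1.0
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = a @ w
        nxt = nxt / nxt.sum()
        if np.max(np.abs(nxt - w)) < tol:
            w = nxt
            break
        w = nxt
    else:
        raise AhpError("power iteration failed to converge")
    lam = float((w @ (a @ w)) / (w @ w))
    return w, lam


def geometric_mean_weights(matrix: JudgmentMatrix | np.ndarray) -> np.ndarray:
    """Row-geometric-mean weights (exact for consistent matrices; used as the
    small-n oracle for the eigenvector route)."""
    a = matrix.values if isinstance(matrix, JudgmentMatrix) else np.asarray(matrix)
    g = np.exp(np.log(a).mean(axis=1))
    return g / g.sum()


def column_mean_weights(
    matrix: JudgmentMatrix | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Normalised-column-average weights and the λmax estimate
    ``mean_i (Aw)_i / w_i`` — the reference consistency convention."""
    a = matrix.values if isinstance(matrix, JudgmentMatrix) else np.asarray(matrix)
    w = (a / a.sum(axis=0)).mean(axis=1)
    lam = float(np.mean((a @ w) / w))
    return w, lam


def consistency(
    matrix: JudgmentMatrix | np.ndarray,
    lambda_max: float | None = None,
    random_index: Mapping[int, float] | None = None,
    lambda_method: str = "column_mean",
) -> ConsistencyResult:
    """CI = (λmax − n)/(n − 1), CR = CI/RI(n); CR is 0 by definition for n ≤ 2.

    When ``lambda_max`` is not supplied it is estimated with ``lambda_method``
    ("column_mean" or "eigen"); see the module docstring for why column_mean
    is the reporting default.
    """
    a = matrix.values if isinstance(matrix, JudgmentMatrix) else np.asarray(matrix)
    n = a.shape[0]
    ri_table = random_index or DEFAULT_RANDOM_INDEX
    if n <= 2:
        lam = float(n) if lambda_max is None else float(lambda_max)
        return ConsistencyResult(lambda_max=lam, ci=0.0, ri=0.0, cr=0.0)
    if lambda_max is None:
        if lambda_method == "column_mean":
            _, lambda_max = column_mean_weights(a)
        elif lambda_method == "eigen":
            _, lambda_max = principal_weights(a)
        else:
            raise AhpError(f"unknown lambda_method {lambda_method!r}")
    ci = (lambda_max - n) / (n - 1)
    try:
        ri = ri_table[n]
    except KeyError:
        raise AhpError(f"no random index for matrix order {n}") from None
    return ConsistencyResult(
        lambda_max=float(lambda_max), ci=float(ci), ri=float(ri), cr=float(ci / ri)
    )


# -- hierarchical combination ----------------------------------------------


def combine_weights(
    hierarchy, local_weights: Mapping[str | None, Mapping[str, float]]
) -> WeightVector:
    """Combination weight = product of local weights along the root path.

    ``local_weights`` maps each parent id (``None`` for the top level) to the
    sibling-normalised weights of its children. Output includes a descending
    competition rank over the leaves.
    """
    combination: dict[str, float] = {}
    local: dict[str, float] = {}

    def descend(parent: str | None, parent_weight: float) -> None:
        children = (
            hierarchy.active_at_level(1)
            if parent is None
            else hierarchy.children_of(parent)
        )
        if not children:
            return
        key = parent
        if key not in local_weights:
            raise AhpError(f"missing local weight vector for parent {key!r}")
        locals_here = local_weights[key]
        for child in children:
            if child.id not in locals_here:
                raise AhpError(
                    f"no local weight for {child.id} under parent {key!r}"
                )
            lw = float(locals_here[child.id])
            local[child.id] = lw
            combination[child.id] = parent_weight * lw
            descend(child.id, combination[child.id])

    descend(None, 1.0)
    leaf_ids = [leaf.id for leaf in hierarchy.leaves()]
    order = sorted(leaf_ids, key=lambda i: (-combination[i], i))
    leaf_rank = {}
    for pos, iid in enumerate(order):
        if pos > 0 and combination[iid] == combination[order[pos - 1]]:
            leaf_rank[iid] = leaf_rank[order[pos - 1]]
        else:
            leaf_rank[iid] = pos + 1
    return WeightVector(local=local, combination=combination, leaf_rank=leaf_rank)


def full_ahp(
    hierarchy,
    means: Mapping[str, float],
    mapping: SaatyMapping | None = None,
    random_index: Mapping[int, float] | None = None,
    cr_threshold: float = CR_THRESHOLD,
    force: bool = False,
    lambda_method: str = "column_mean",
) -> AhpReport:
    """Weights, consistency and combination weights for a whole hierarchy.

    Builds one judgment matrix per active non-leaf parent (and one over the
    top-level indicators), always regenerated from means + mapping. Refuses to
    emit weights while any matrix has CR ≥ ``cr_threshold`` unless ``force``.
    """
    mapping = mapping or SaatyMapping()
    active_ids = [i.id for i in hierarchy.active()]
    missing = [i for i in active_ids if i not in means]
    if missing:
        raise AhpError(f"no mean score for indicator(s): {', '.join(missing)}")

    parents: list[str | None] = [None] + [
        i.id for i in hierarchy.active() if hierarchy.children_of(i.id)
    ]
    matrices: dict[str | None, JudgmentMatrix] = {}
    cons: dict[str | None, ConsistencyResult] = {}
    local_weights: dict[str | None, dict[str, float]] = {}
    failures: dict[str, float] = {}
    for parent in parents:
        children = (
            hierarchy.active_at_level(1)
            if parent is None
            else hierarchy.children_of(parent)
        )
        child_means = {c.id: float(means[c.id]) for c in children}
        m = build_matrix(child_means, mapping)
        w, _ = principal_weights(m)
        c = consistency(
            m, random_index=random_index, lambda_method=lambda_method
        )
        matrices[parent] = m
        cons[parent] = c
        local_weights[parent] = dict(zip(m.item_ids, map(float, w)))
        if c.cr >= cr_threshold:
            failures[parent if parent is not None else "<top level>"] = c.cr
    if failures and not force:
        raise ConsistencyGateError(failures)
    weights = combine_weights(hierarchy, local_weights)
    return AhpReport(matrices=matrices, consistency=cons, weights=weights)


# -- mapping calibration ---------------------------------------------------


def calibrate_mapping(
    observations: Sequence[tuple[Sequence[float], Sequence[float]]],
    max_scale: int = 9,
    ndigits: int = 2,
) -> SaatyMapping:
    """Fit a difference→scale mapping to (sibling means, target local weights)
    pairs by exhaustive search over monotone scale assignments.

    Distinct absolute mean differences (rounded to ``ndigits``) each get one
    scale value; assignments must be non-decreasing in the difference, with a
    zero difference pinned to scale 1. The assignment minimising the summed
    squared error between eigenvector weights and targets wins; bin bounds are
    placed midway between adjacent differences that received different scales.
    """
    diffs: set[float] = set()
    for means, _ in observations:
        mu = list(means)
        for i in range(len(mu)):
            for j in range(i + 1, len(mu)):
                d = round(abs(mu[i] - mu[j]), ndigits)
                if d > 0:
                    diffs.add(d)
    ordered = sorted(diffs)
    k = len(ordered)
    if k == 0:
        return SaatyMapping(((0.0, 1), (math.inf, 1)))

    best_err, best_assign = math.inf, None

    def evaluate(assign: dict[float, int]) -> float:
        err = 0.0
        for means, target in observations:
            mu = list(means)
            n = len(mu)
            a = np.ones((n, n))
            for i in range(n):
                for j in range(n):
                    d = mu[i] - mu[j]
                    key = round(abs(d), ndigits)
                    if key == 0:
                        continue
                    s = assign[key]
                    a[i, j] = s if d > 0 else 1.0 / s
            w, _ = principal_weights(a)
            err += float(((w - np.asarray(target, dtype=float)) ** 2).sum())
        return err

    def rec(idx: int, floor: int, assign: dict[float, int]) -> None:
        nonlocal best_err, best_assign
        if idx == k:
            err = evaluate(assign)
            if err < best_err:
                best_err, best_assign = err, dict(assign)
            return
        for s in range(max(floor, 2), max_scale + 1):
            assign[ordered[idx]] = s
            rec(idx + 1, s, assign)
        del assign[ordered[idx]]

    rec(0, 2, {})
    assert best_assign is not None
    bins: list[tuple[float, int]] = [(0.0, 1)]
    for i, d in enumerate(ordered):
        s = best_assign[d]
        upper = (
            math.inf
            if i == k - 1
            else round((d + ordered[i + 1]) / 2.0, ndigits + 2)
        )
        if i < k - 1 and best_assign[ordered[i + 1]] == s:
            continue  # extend the bin instead of closing it
        bins.append((upper, s))
    if bins[-1][0] != math.inf:
        bins[-1] = (math.inf, bins[-1][1])
    return SaatyMapping(tuple(bins))
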