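"""Analytic Hierarchy Process core.

Validates positive reciprocal pairwise-comparison (judgment) matrices,
derives priority weights as the principal right eigenvector (power
iteration), computes Saaty's consistency diagnostics (lambda_max, CI, CR),
aggregates multiple experts by the entry-wise geometric mean, and composes
local weights down a hierarchy of indicators.

Consistency ratio: CI = (lambda_max - n)/(n - 1), CR = CI / RI(n) with
Saaty's random-index table; CR < 0.1 is the conventional acceptability bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConvergenceError, InputValidationError

#: Saaty's random consistency index, RI(n) for n = 1..10
RANDOM_INDEX = (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49)

#: admissible raw expert entries: 1..9 and their reciprocals
SAATY_SCALE = tuple(1.0 / k for k in range(9, 1, -1)) + tuple(float(k) for k in range(1, 10))

RECIPROCITY_RTOL = 1e-9


def validate_matrix(m, *, require_saaty: bool = False) -> np.ndarray:
    """Validate a pairwise-comparison matrix and return it as float ndarray.

    Checks: square, order 2-10, strictly positive, unit diagonal, and
    reciprocity a_ji = 1/a_ij to relative tolerance 1e-9.  With
    ``require_saaty`` the entries must additionally come from the discrete
    Saaty scale {1/9..1/2, 1..9} (raw single-expert matrices; geometric-mean
    aggregates are exempt).
    """
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputValidationError(f"matrix must be square; got shape {a.shape}")
    n = a.shape[0]
    if not 2 <= n <= 10:
        raise InputValidationError(f"matrix order {n} outside supported range 2..10")
    if not np.all(a > 0):
        i, j = np.argwhere(~(a > 0))[0]
        raise InputValidationError(f"entry ({i}, {j}) = {a[i, j]} is not positive")
    if not np.allclose(np.diag(a), 1.0, rtol=0, atol=1e-12):
        i = int(np.flatnonzero(~np.isclose(np.diag(a), 1.0, rtol=0, atol=1e-12))[0])
        raise InputValidationError(f"diagonal entry ({i}, {i}) = {a[i, i]} != 1")
    recip_err = np.abs(a * a.T - 1.0)
    if np.any(recip_err > RECIPROCITY_RTOL):
        i, j = np.argwhere(recip_err > RECIPROCITY_RTOL)[0]
        raise InputValidationError(
            f"reciprocity violated at ({i}, {j}): a_ij={a[i, j]}, a_ji={a[j, i]}"
        )
    if require_saaty:
        scale = np.asarray(SAATY_SCALE)
        for i in range(n):
            for j in range(n):
                if i != j and not np.any(np.isclose(a[i, j], scale, rtol=1e-6)):
                    raise InputValidationError(
                        f"entry ({i}, {j}) = {a[i, j]} is not on the Saaty scale"
                    )
    return a


@dataclass(frozen=True)
class PriorityResult:
    """Priority weights and consistency diagnostics of a judgment matrix."""

    weights: np.ndarray
    lambda_max: float
    consistency_index: float
    consistency_ratio: float
    iterations: int


def priority_vector(m, tol: float = 1e-12, max_iter: int = 10_000) -> PriorityResult:
    """Principal right eigenvector of a validated judgment matrix.

    Power iteration from the uniform vector, normalised to sum 1, with
    lambda_max estimated as the mean Rayleigh ratio (A w)_i / w_i.
    """
    a = validate_matrix(m)
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    lam = float(n)
    for it in range(1, max_iter + 1):
        aw = a @ w
        w_new = aw / aw.sum()
        lam = float(np.mean(aw / w))
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    else:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} iterations",
            residual=float(np.max(np.abs(a @ w - lam * w))),
        )
    ci = 0.0 if n <= 2 else (lam - n) / (n - 1)
    ri = RANDOM_INDEX[n - 1]
    cr = 0.0 if ri == 0.0 else ci / ri
    return PriorityResult(
        weights=w, lambda_max=lam, consistency_index=ci, consistency_ratio=cr, iterations=it
    )


def aggregate_experts(matrices: Sequence) -> np.ndarray:
    """Entry-wise geometric mean of several expert judgment matrices.

    The aggregate is reciprocal by construction and need not stay on the
    discrete Saaty scale.
    """
    if len(matrices) == 0:
        raise InputValidationError("need at least one matrix")
    arrs = [validate_matrix(m) for m in matrices]
    n = arrs[0].shape[0]
    for k, a in enumerate(arrs):
        if a.shape[0] != n:
            raise InputValidationError(f"matrix {k} has order {a.shape[0]}, expected {n}")
    return np.exp(np.mean(np.log(np.stack(arrs)), axis=0))


def row_geometric_mean(m) -> np.ndarray:
    """Row-geometric-mean priority approximation (cross-check method)."""
    a = validate_matrix(m)
    g = np.exp(np.log(a).mean(axis=1))
    return g / g.sum()


@dataclass
class Node:
    """Hierarchy node: local weights of the children are either given
    explicitly or derived from a judgment matrix over the children."""

    name: str
    children: list["Node"] = field(default_factory=list)
    local_weight: float | None = None
    matrix: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Hierarchy:
    """Indicator hierarchy: dimension nodes at the top level, arbitrary
    nesting below; 14 leaves in the default sarcopenia configuration."""

    dimensions: list[Node]

    @classmethod
    def from_dict(cls, d: Mapping) -> "Hierarchy":
        def build(nd: Mapping) -> Node:
            node = Node(
                name=nd["name"],
                children=[build(c) for c in nd.get("children", [])],
                local_weight=nd.get("local_weight"),
                matrix=np.asarray(nd["matrix"], dtype=float) if "matrix" in nd else None,
            )
            return node

        return cls(dimensions=[build(nd) for nd in d["dimensions"]])

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node.name)
            for c in node.children:
                walk(c)

        for d in self.dimensions:
            walk(d)
        return out


def _resolve_locals(node: Node) -> None:
    """Fill children's local weights, from the node's judgment matrix when
    given, and check they sum to 1."""
    if not node.children:
        return
    if node.matrix is not None:
        res = priority_vector(node.matrix)
        if len(res.weights) != len(node.children):
            raise InputValidationError(
                f"node {node.name}: matrix order {len(res.weights)} != {len(node.children)} children"
            )
        for c, w in zip(node.children, res.weights):
            c.local_weight = float(w)
    weights = [c.local_weight for c in node.children]
    if any(w is None for w in weights):
        raise InputValidationError(f"node {node.name}: children lack local weights")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise InputValidationError(
            f"node {node.name}: children weights sum to {sum(weights)}, expected 1"
        )
    for c in node.children:
        _resolve_locals(c)


def compose_hierarchy(h: Hierarchy) -> dict[str, dict[str, float]]:
    """Within-dimension leaf weights: the product of local weights along each
    leaf's path below its dimension node.

    Returns ``{dimension name: {leaf name: weight}}``; each dimension's leaf
    weights sum to 1.
    """
    out: dict[str, dict[str, float]] = {}
    for dim in h.dimensions:
        _resolve_locals(dim)
        leaf_w: dict[str, float] = {}

        def walk(node: Node, acc: float) -> None:
            if node.is_leaf:
                leaf_w[node.name] = acc
                return
            for c in node.children:
                walk(c, acc * c.local_weight)

        if dim.is_leaf:
            leaf_w[dim.name] = 1.0
        else:
            for c in dim.children:
                walk(c, c.local_weight)
        out[dim.name] = leaf_w
    return out
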