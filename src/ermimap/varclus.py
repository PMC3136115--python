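"""Disjoint oblique principal-component variable clustering.

Reduces the 36 standardized species columns to a small set of disjoint
clusters, each summarized by its first principal component (FPC), in the
style of the classic oblique-component variable-clustering procedure:

1.  All variables start in a single cluster.
2.  While any cluster's correlation-matrix second eigenvalue exceeds the
    splitting criterion (default 1.0), the cluster with the largest second
    eigenvalue is split in two: each member joins whichever of the first
    two principal components it correlates with more strongly, followed by
    one local refinement pass against the two subgroup FPCs (an
    approximation of the orthoblique rotation split).
3.  A best-first full-search reassignment phase then moves variables to
    better-fitting clusters, judging own-cluster fit leave-one-out and
    absorbing singletons only when the merged cluster decisively satisfies
    the splitting criterion (see :func:`_reassign`).  Steps 2-3 alternate
    until no split is required and no move helps.

The search targets the criterion's fixed point: every cluster satisfies
the splitting criterion and no two clusters could be merged while keeping
it satisfied.

Each cluster's FPC is the standardized first-eigenvector combination of its
member columns, so high-loading (high information) members get the largest
absolute scoring weights.  Diagnostics per species are ``r2_own`` (squared
correlation with its own cluster's FPC; exactly 1 for a singleton) and
``r2_next`` (best squared correlation with any other cluster's FPC).

Everything is deterministic: eigendecompositions, the fixed variable order
of the sweeps, ties resolved toward the lower cluster index, and
eigenvector signs fixed so the largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, InputError, IterationLimitError

__all__ = ["VariableCluster", "VarclusResult", "varclus", "fpc_scores", "r2_diagnostics"]

_TOL = 1e-12


@dataclass(frozen=True)
class VariableCluster:
    """A disjoint variable cluster and its leading principal component."""

    cluster_id: int
    members: tuple[str, ...]
    eig1: float
    eig2: float  # defined as 0 for singletons
    scoring_coefficients: np.ndarray  # per member, defines the FPC

    def __post_init__(self):
        if not self.members:
            raise InputError("cluster must have at least one member")
        if not self.eig1 >= self.eig2 >= 0:
            raise InputError("need eig1 >= eig2 >= 0")


@dataclass(frozen=True)
class VarclusResult:
    """Clustering output: clusters, per-species diagnostics, FPC scores."""

    clusters: tuple[VariableCluster, ...]
    table: pd.DataFrame        # species, cluster, r2_own, r2_next
    fpc_scores: pd.DataFrame   # homes x clusters, columns "FPC1".."FPCk"
    total_variance: float      # sum of first eigenvalues

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def assignments(self) -> dict[str, int]:
        return {m: c.cluster_id for c in self.clusters for m in c.members}


# ---------------------------------------------------------------------------
# internals: everything indexes into a fixed correlation matrix R


def _standardized(z: pd.DataFrame) -> np.ndarray:
    vals = z.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(z.columns, sd) if s == 0]
        raise InputError(f"constant columns cannot be clustered: {bad}")
    return (vals - vals.mean(axis=0)) / sd


def _eig(R: np.ndarray, members: list[int]):
    sub = R[np.ix_(members, members)]
    w, v = np.linalg.eigh(sub)
    order = np.argsort(w)[::-1]
    w = np.maximum(w[order], 0.0)
    v = v[:, order]
    # sign convention: largest-magnitude loading positive
    lead = np.abs(v[:, 0]).argmax()
    if v[lead, 0] < 0:
        v = -v
    return w, v


def _eig1(R: np.ndarray, members: list[int]) -> float:
    if len(members) == 1:
        return float(R[members[0], members[0]])
    w, _ = _eig(R, members)
    return float(w[0])


def _fpc(R: np.ndarray, members: list[int]):
    """(v1, eig1) of the members' correlation submatrix."""
    if len(members) == 1:
        return np.array([1.0]), float(R[members[0], members[0]])
    w, v = _eig(R, members)
    return v[:, 0], float(w[0])


def _r2_with_fpc(R: np.ndarray, j: int, members: list[int], v1, l1: float) -> float:
    if l1 <= _TOL:
        return 0.0
    cov = float(R[j, members] @ v1)
    return cov * cov / l1


def _split(R: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """Split a cluster across its first two principal components."""
    w, v = _eig(R, members)
    l1, l2 = w[0], w[1]
    # correlation of member j with PC_k is sqrt(l_k) * v[j, k]
    pref2 = l2 * v[:, 1] ** 2 > l1 * v[:, 0] ** 2
    if pref2.all() or not pref2.any():
        # force a non-trivial split on the strongest PC2 alignment
        pref2 = np.zeros(len(members), dtype=bool)
        pref2[np.abs(v[:, 1]).argmax()] = True
    g1 = [m for m, p2 in zip(members, pref2) if not p2]
    g2 = [m for m, p2 in zip(members, pref2) if p2]
    # one local refinement pass against the subgroup FPCs
    v1a, l1a = _fpc(R, g1)
    v1b, l1b = _fpc(R, g2)
    new1, new2 = [], []
    for m in members:
        ra = _r2_with_fpc(R, m, g1, v1a, l1a)
        rb = _r2_with_fpc(R, m, g2, v1b, l1b)
        (new2 if rb > ra else new1).append(m)
    if new1 and new2:
        g1, g2 = new1, new2
    return g1, g2


def _loo_r2(R: np.ndarray, j: int, members: list[int]) -> float:
    """Leave-one-out fit: r2 of member j with the FPC of the other members."""
    rest = [m for m in members if m != j]
    if not rest:
        return 1.0  # a singleton's component is the variable itself
    v, l1 = _fpc(R, rest)
    return _r2_with_fpc(R, j, rest, v, l1)


def _reassign(R: np.ndarray, clusters: list[list[int]], max_moves: int, n: int,
              max_eig2: float):
    """Best-first full search; returns (clusters, n_moves, converged).

    Two kinds of moves, applied best-first one at a time:

    *Regular moves* — a variable in a cluster of size >= 2 moves to the
    cluster whose FPC fits it best when the gain over its own leave-one-out
    fit (squared correlation with the component of the *other* members) is
    positive.  The leave-one-out baseline stops a small stranded fragment
    from holding a variable by self-inflation.

    *Singleton absorption* — a singleton is perfectly explained by its own
    component, so fit alone can never justify dissolving it.  It is
    absorbed into the best-fitting cluster only when the merged cluster
    decisively satisfies the splitting criterion: merged second eigenvalue
    <= max_eig2 - sqrt(m/n), the guard being the null sampling width of
    correlation-matrix eigenvalues for m variables on n observations.  A
    genuinely independent variable sits exactly at the criterion
    (population second eigenvalue 1.0) and is therefore kept apart, while
    a stray member of an existing cluster merges decisively below it.
    """
    for move in range(max_moves):
        if len(clusters) < 2:
            return clusters, move, True
        comps = [_fpc(R, c) for c in clusters]
        best_gain, best_move = _TOL, None
        for ci, c in enumerate(clusters):
            if len(c) == 1:
                continue
            for j in c:
                baseline = _loo_r2(R, j, c)
                for di, (d, (v1, l1)) in enumerate(zip(clusters, comps)):
                    if di == ci:
                        continue
                    gain = _r2_with_fpc(R, j, d, v1, l1) - baseline
                    if gain > best_gain:
                        best_gain, best_move = gain, (ci, j, di)
        if best_move is None:
            # regular moves exhausted: consider absorbing one singleton
            best_r2 = _TOL
            for ci, c in enumerate(clusters):
                if len(c) > 1:
                    continue
                j = c[0]
                for di, (d, (v1, l1)) in enumerate(zip(clusters, comps)):
                    if di == ci:
                        continue
                    r2 = _r2_with_fpc(R, j, d, v1, l1)
                    if r2 <= best_r2:
                        continue
                    merged = d + [j]
                    w, _ = _eig(R, merged)
                    guard = np.sqrt(len(merged) / n)
                    if w[1] <= max_eig2 - guard:
                        best_r2, best_move = r2, (ci, j, di)
            if best_move is None:
                return clusters, move, True
        ci, j, di = best_move
        clusters[di] = clusters[di] + [j]
        src = [m for m in clusters[ci] if m != j]
        if src:
            clusters[ci] = src
        else:
            del clusters[ci]
    return clusters, max_moves, False


def _build_result(z: pd.DataFrame, zs: np.ndarray, R: np.ndarray,
                  groups: list[list[int]]) -> VarclusResult:
    names = list(z.columns)
    # report order: decreasing member count, then lexicographic first member
    keyed = sorted(
        groups, key=lambda g: (-len(g), min(names[j] for j in g))
    )
    comps = [_fpc(R, g) for g in keyed]
    clusters = []
    scores = {}
    n = len(z)
    for cid, (g, (v1, l1)) in enumerate(zip(keyed, comps), start=1):
        if len(g) == 1:
            eig2 = 0.0
        else:
            w, _ = _eig(R, g)
            eig2 = float(w[1])
        clusters.append(
            VariableCluster(
                cluster_id=cid,
                members=tuple(names[j] for j in g),
                eig1=l1,
                eig2=eig2,
                scoring_coefficients=v1 / np.sqrt(max(l1, _TOL)),
            )
        )
        scores[f"FPC{cid}"] = zs[:, g] @ v1 / np.sqrt(max(l1, _TOL))
    rows = []
    for cid, (g, (v1, l1)) in enumerate(zip(keyed, comps), start=1):
        for j in g:
            r2_own = _r2_with_fpc(R, j, g, v1, l1)
            r2_next = 0.0
            for other, (vo, lo) in zip(keyed, comps):
                if other is g:
                    continue
                r2_next = max(r2_next, _r2_with_fpc(R, j, other, vo, lo))
            rows.append(
                {"species": names[j], "cluster": cid,
                 "r2_own": r2_own, "r2_next": r2_next}
            )
    table = pd.DataFrame(rows)
    return VarclusResult(
        clusters=tuple(clusters),
        table=table,
        fpc_scores=pd.DataFrame(scores, index=z.index),
        total_variance=float(sum(l1 for _, l1 in comps)),
    )


# ---------------------------------------------------------------------------
# public API


def varclus(z, max_eig2: float = 1.0, max_sweeps: int = 50) -> VarclusResult:
    """Cluster the columns of a standardized homes-by-variables matrix.

    Parameters
    ----------
    z : DataFrame or array
        Homes x variables; columns are standardized internally (population
        z-scores) so correlation matrices drive everything.  Constant
        columns are rejected.
    max_eig2 : float
        Splitting criterion: clusters are split while their second
        eigenvalue exceeds this (1.0 = "less structure than one average
        variable left over").
    max_sweeps : int
        Cap on reassignment sweeps; exceeding it raises
        :class:`~ermimap.errors.IterationLimitError` carrying the partial
        result.
    """
    z = pd.DataFrame(z)
    if z.shape[1] < 1:
        raise InputError("need at least one variable")
    zs = _standardized(z)
    n = len(z)
    R = (zs.T @ zs) / n
    np.fill_diagonal(R, 1.0)

    groups: list[list[int]] = [list(range(z.shape[1]))]
    p = z.shape[1]
    max_moves = max_sweeps * p  # budget: "sweeps" of best-first single moves
    for _outer in range(max_sweeps):
        # split phase to completion: worst second eigenvalue first
        while True:
            worst, worst_eig2 = None, max_eig2
            for i, g in enumerate(groups):
                if len(g) < 2:
                    continue
                w, _ = _eig(R, g)
                if w[1] > worst_eig2 + _TOL:
                    worst, worst_eig2 = i, w[1]
            if worst is None:
                break
            g1, g2 = _split(R, groups[worst])
            groups[worst] = g1
            groups.append(g2)
        # full-search reassignment phase
        groups, _used, converged = _reassign(R, groups, max_moves, n, max_eig2)
        if not converged:
            raise IterationLimitError(
                f"reassignment did not converge within {max_moves} moves",
                partial=_build_result(z, zs, R, groups),
            )
        # reassignment can re-inflate a cluster's second eigenvalue
        needs_split = any(
            len(g) > 1 and _eig(R, g)[0][1] > max_eig2 + _TOL for g in groups
        )
        if not needs_split:
            return _build_result(z, zs, R, groups)
    raise IterationLimitError(
        f"split/reassign alternation did not settle within {max_sweeps} rounds",
        partial=_build_result(z, zs, R, groups),
    )


def fpc_scores(z, clusters) -> pd.DataFrame:
    """Standardized first-principal-component scores for given clusters.

    Columns ``FPC<cluster_id>``; each column has (population) mean 0 and
    sd 1.  For a singleton cluster the score equals the member's z-score.
    """
    z = pd.DataFrame(z)
    names = list(z.columns)
    index = {nm: i for i, nm in enumerate(names)}
    zs = _standardized(z)
    R = (zs.T @ zs) / len(z)
    np.fill_diagonal(R, 1.0)
    out = {}
    for c in clusters:
        try:
            g = [index[m] for m in c.members]
        except KeyError as exc:
            raise AlignmentError(f"cluster member {exc} not a column of z") from None
        v1, l1 = _fpc(R, g)
        out[f"FPC{c.cluster_id}"] = zs[:, g] @ v1 / np.sqrt(max(l1, _TOL))
    return pd.DataFrame(out, index=z.index)


def r2_diagnostics(z, clusters) -> pd.DataFrame:
    """Per-variable squared correlation with own vs next-closest FPC.

    ``r2_next`` is 0 when only one cluster exists.
    """
    z = pd.DataFrame(z)
    names = list(z.columns)
    index = {nm: i for i, nm in enumerate(names)}
    zs = _standardized(z)
    R = (zs.T @ zs) / len(z)
    np.fill_diagonal(R, 1.0)
    comps = {}
    for c in clusters:
        g = [index[m] for m in c.members]
        comps[c.cluster_id] = (g, *_fpc(R, g))
    rows = []
    for c in clusters:
        for m in c.members:
            j = index[m]
            g, v1, l1 = comps[c.cluster_id]
            r2_own = _r2_with_fpc(R, j, g, v1, l1)
            r2_next = 0.0
            for cid, (go, vo, lo) in comps.items():
                if cid == c.cluster_id:
                    continue
                r2_next = max(r2_next, _r2_with_fpc(R, j, go, vo, lo))
            rows.append(
                {"species": m, "cluster": c.cluster_id,
                 "r2_own": r2_own, "r2_next": r2_next}
            )
    return pd.DataFrame(rows)
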