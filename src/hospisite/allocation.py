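"""P-Median and maximal-covering (MCLP) location-allocation solvers.

Both problems choose ``p`` facility sites from a candidate set and
allocate demand points to them over a travel-time OD matrix:

* **P-Median** minimises the demand-weighted sum of travel times
  ``sum_i w_i * min_{j in S} d_ij`` over site sets ``|S| = p``.  Demands
  with no chosen site within the impedance cut-off are UNALLOCATED and
  excluded from the sum (they survive to the combined optimiser's second
  stage instead of being infinitely penalised).
* **MCLP** maximises the total demand weight within the cut-off of at
  least one chosen site.

The combined **MC-P-Median** optimiser runs the P-Median, removes
demands that no candidate can reach within the cut-off ("inaccessible or
redundant"), and re-solves maximal coverage on the remainder, keeping an
audit log of every removal and reassignment.

Exact solving is exhaustive enumeration under a subset-count guard —
enumeration is the objective's definition and doubles as the test
oracle.  Above the guard the P-Median refuses exact mode (use the
Teitz–Bart vertex-substitution heuristic); the MCLP, whose objective is
cleanly linear, switches to an ILP (HiGHS via scipy).

Tie-breaks are deterministic everywhere: lexicographically smallest
facility-id set among equal objectives, nearest-then-lowest-id for
assignments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp
from sklearn.base import BaseEstimator

from .network import ODMatrix

__all__ = [
    "UNALLOCATED",
    "Allocation",
    "OptimizedAllocation",
    "InstanceTooLargeError",
    "PMedian",
    "MaxCoveringLocation",
    "MCPMedian",
    "p_median_exact",
    "p_median_heuristic",
    "mclp_solve",
    "flag_inaccessible",
    "mc_p_median_optimize",
]

UNALLOCATED = None
_ENUM_GUARD = 10**6
_TOL = 1e-12


class InstanceTooLargeError(ValueError):
    """Exact mode refused: C(n_candidates, p) exceeds the enumeration guard."""


@dataclass
class Allocation:
    """Solver output: chosen sites, demand assignments, objective value."""

    chosen_sites: tuple[int, ...]  # facility ids, sorted
    assignment: dict[int, int | None]  # demand_id -> facility_id or UNALLOCATED
    objective: float  # weighted cost (P-Median) or covered weight (MCLP)
    cutoff_h: float | None
    kind: str  # "p-median" | "mclp"

    @property
    def allocated_count(self) -> int:
        return sum(1 for f in self.assignment.values() if f is not None)

    def covered_weight(self, weights: dict[int, float]) -> float:
        return sum(weights[d] for d, f in self.assignment.items() if f is not None)

    def recompute_objective(self, od: ODMatrix, weights: dict[int, float]) -> float:
        """Re-derive the stored objective from the assignment (consistency check)."""
        di = {d: i for i, d in enumerate(od.demand_ids)}
        fi = {f: j for j, f in enumerate(od.facility_ids)}
        if self.kind == "p-median":
            return sum(
                weights[d] * od.times[di[d], fi[f]]
                for d, f in self.assignment.items()
                if f is not None
            )
        return self.covered_weight(weights)


@dataclass
class OptimizedAllocation:
    """MC-P-Median result: the P-Median stage, removals, and the final stage."""

    p_median: Allocation
    inaccessible: frozenset[int]
    final: Allocation
    audit_log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# internals on plain arrays


def _prep(od: ODMatrix, weights, facility_ids=None):
    """Columns sorted by facility id (lex tie-breaks), weights as an array."""
    if facility_ids is None:
        facility_ids = list(od.facility_ids)
    fid_sorted = sorted(facility_ids)
    cols = [od.facility_ids.index(f) for f in fid_sorted]
    D = od.times[:, cols]
    if isinstance(weights, dict):
        w = np.array([float(weights[d]) for d in od.demand_ids])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(od.demand_ids),):
            raise ValueError("weights length mismatch")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    return D, w, fid_sorted


def _pmedian_objective(D, w, subset, cutoff):
    sub = D[:, subset]
    jmin = np.argmin(sub, axis=1)  # first (lowest-id) column on ties
    dmin = sub[np.arange(len(sub)), jmin]
    served = np.isfinite(dmin)
    if cutoff is not None:
        served &= dmin <= cutoff
    return float(np.sum(w[served] * dmin[served])), jmin, served


def _covered_weight(D, w, subset, cutoff):
    dmin = D[:, subset].min(axis=1)
    return float(np.sum(w[dmin <= cutoff]))


def _assignment_from(D, w, subset, cutoff, demand_ids, fid_sorted):
    _, jmin, served = _pmedian_objective(D, w, subset, cutoff)
    return {
        d: (fid_sorted[subset[jmin[i]]] if served[i] else UNALLOCATED)
        for i, d in enumerate(demand_ids)
    }


def _check_p(p, n):
    if not 1 <= p <= n:
        raise ValueError(f"p={p} out of range [1, {n}]")


# ---------------------------------------------------------------------------
# estimators


class PMedian(BaseEstimator):
    """P-Median solver over a travel-time matrix.

    Parameters
    ----------
    p : int
        Number of sites to open.
    cutoff_h : float or None
        Impedance cut-off in hours; demands farther than this from every
        chosen site stay unallocated and do not enter the objective.
    method : {"exact", "heuristic", "auto"}
        Exact = exhaustive enumeration (guarded); heuristic = Teitz–Bart
        vertex substitution with restarts; auto picks exact when the
        subset count is within the guard.
    seed, restarts : heuristic controls.

    Attributes (after ``fit(X, sample_weight=...)`` with X the
    (n_demands, n_candidates) travel-time matrix)
    ----------
    chosen_idx_ : tuple of column indices of the opened sites
    labels_ : array of opened-column index per demand, -1 if unallocated
    objective_ : the weighted cost
    """

    def __init__(self, p=1, cutoff_h=None, method="auto", seed=0, restarts=10,
                 max_enumeration=_ENUM_GUARD):
        self.p = p
        self.cutoff_h = cutoff_h
        self.method = method
        self.seed = seed
        self.restarts = restarts
        self.max_enumeration = max_enumeration

    def fit(self, X, sample_weight=None):
        D = np.asarray(X, dtype=float)
        n_d, n_f = D.shape
        _check_p(self.p, n_f)
        w = (np.ones(n_d) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        method = self.method
        n_subsets = math.comb(n_f, self.p)
        if method == "auto":
            method = "exact" if n_subsets <= self.max_enumeration else "heuristic"
        if method == "exact":
            if n_subsets > self.max_enumeration:
                raise InstanceTooLargeError(
                    f"C({n_f},{self.p}) = {n_subsets} exceeds the enumeration "
                    f"guard {self.max_enumeration}; use method='heuristic'"
                )
            best_obj, best_set = math.inf, None
            for subset in itertools.combinations(range(n_f), self.p):
                obj, _, _ = _pmedian_objective(D, w, list(subset), self.cutoff_h)
                if obj < best_obj - _TOL:
                    best_obj, best_set = obj, subset
        elif method == "heuristic":
            best_obj, best_set = self._teitz_bart(D, w)
        else:
            raise ValueError(f"unknown method {method!r}")
        self.chosen_idx_ = tuple(best_set)
        self.objective_ = best_obj
        _, jmin, served = _pmedian_objective(D, w, list(best_set), self.cutoff_h)
        self.labels_ = np.where(served, np.array(best_set)[jmin], -1)
        return self

    def _teitz_bart(self, D, w):
        n_f = D.shape[1]
        rng = np.random.default_rng(self.seed)
        best_obj, best_set = math.inf, None
        for _ in range(max(1, self.restarts)):
            current = sorted(rng.choice(n_f, size=self.p, replace=False).tolist())
            obj, _, _ = _pmedian_objective(D, w, current, self.cutoff_h)
            improved = True
            while improved:
                improved = False
                cand_obj, cand_set = obj, None
                inside = set(current)
                for out in range(n_f):
                    if out in inside:
                        continue
                    for k in range(self.p):
                        trial = sorted(current[:k] + current[k + 1:] + [out])
                        t_obj, _, _ = _pmedian_objective(D, w, trial, self.cutoff_h)
                        if t_obj < cand_obj - _TOL or (
                            abs(t_obj - cand_obj) <= _TOL
                            and cand_set is not None and tuple(trial) < tuple(cand_set)
                        ):
                            cand_obj, cand_set = t_obj, trial
                if cand_set is not None:
                    current, obj, improved = cand_set, cand_obj, True
            if obj < best_obj - _TOL or (
                abs(obj - best_obj) <= _TOL
                and (best_set is None or tuple(current) < tuple(best_set))
            ):
                best_obj, best_set = obj, tuple(current)
        return best_obj, best_set


class MaxCoveringLocation(BaseEstimator):
    """Maximal covering location solver (MCLP) over a travel-time matrix.

    Maximises the demand weight within ``cutoff_h`` of at least one of the
    ``p`` chosen sites.  ``method="exact"`` enumerates below the guard and
    otherwise solves the standard ILP with HiGHS; ``method="greedy"`` adds
    sites by maximal marginal covered weight (the classic (1 - 1/e)
    approximation).
    """

    def __init__(self, p=1, cutoff_h=None, method="exact",
                 max_enumeration=_ENUM_GUARD):
        self.p = p
        self.cutoff_h = cutoff_h
        self.method = method
        self.max_enumeration = max_enumeration

    def fit(self, X, sample_weight=None):
        if self.cutoff_h is None:
            raise ValueError("MCLP requires a cutoff_h (coverage is cut-off defined)")
        D = np.asarray(X, dtype=float)
        n_d, n_f = D.shape
        _check_p(self.p, n_f)
        w = (np.ones(n_d) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        if self.method == "exact":
            if math.comb(n_f, self.p) <= self.max_enumeration:
                best_w, best_set = -math.inf, None
                for subset in itertools.combinations(range(n_f), self.p):
                    cw = _covered_weight(D, w, list(subset), self.cutoff_h)
                    if cw > best_w + _TOL:
                        best_w, best_set = cw, subset
            else:
                best_w, best_set = self._ilp(D, w)
        elif self.method == "greedy":
            best_w, best_set = self._greedy(D, w)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.chosen_idx_ = tuple(sorted(best_set))
        self.objective_ = best_w
        sub = D[:, self.chosen_idx_]
        jmin = np.argmin(sub, axis=1)
        dmin = sub[np.arange(n_d), jmin]
        covered = dmin <= self.cutoff_h
        self.labels_ = np.where(covered, np.array(self.chosen_idx_)[jmin], -1)
        return self

    def _greedy(self, D, w):
        n_d, n_f = D.shape
        cover = D <= self.cutoff_h  # (n_d, n_f) boolean
        chosen: list[int] = []
        covered = np.zeros(n_d, dtype=bool)
        for _ in range(self.p):
            gains = np.array([
                w[~covered & cover[:, j]].sum() if j not in chosen else -1.0
                for j in range(n_f)
            ])
            j_best = int(np.argmax(gains))  # argmax takes the lowest index on ties
            chosen.append(j_best)
            covered |= cover[:, j_best]
        return float(w[covered].sum()), tuple(chosen)

    def _ilp(self, D, w):
        n_d, n_f = D.shape
        cover = sparse.csr_matrix(D <= self.cutoff_h, dtype=float)
        # variables: y_0..y_{nf-1}, z_0..z_{nd-1}
        c = np.concatenate([np.zeros(n_f), -w])  # maximize w.z
        a_p = sparse.hstack([sparse.csr_matrix(np.ones((1, n_f))),
                             sparse.csr_matrix((1, n_d))])
        a_cov = sparse.hstack([-cover, sparse.eye(n_d, format="csr")])
        constraints = [
            LinearConstraint(a_p, self.p, self.p),
            LinearConstraint(a_cov, -np.inf, 0.0),
        ]
        res = milp(c, constraints=constraints,
                   integrality=np.ones(n_f + n_d),
                   bounds=(0, 1))
        if not res.success:
            raise RuntimeError(f"MCLP ILP failed: {res.message}")
        y = np.round(res.x[:n_f]).astype(bool)
        subset = tuple(np.flatnonzero(y).tolist())
        return _covered_weight(D, w, list(subset), self.cutoff_h), subset


class MCPMedian(BaseEstimator):
    """The combined MC-P-Median optimiser (see module docstring).

    ``fit(X, sample_weight)`` runs: (1) P-Median at the cut-off;
    (2) removal of demands no candidate reaches within the cut-off;
    (3) MCLP on the remainder; final nearest-chosen-site assignment.
    """

    def __init__(self, p=1, cutoff_h=None, pmedian_method="auto",
                 mclp_method="exact", seed=0, restarts=10):
        self.p = p
        self.cutoff_h = cutoff_h
        self.pmedian_method = pmedian_method
        self.mclp_method = mclp_method
        self.seed = seed
        self.restarts = restarts

    def fit(self, X, sample_weight=None):
        if self.cutoff_h is None:
            raise ValueError("MC-P-Median requires a cutoff_h")
        D = np.asarray(X, dtype=float)
        n_d = D.shape[0]
        w = (np.ones(n_d) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))

        pm = PMedian(p=self.p, cutoff_h=self.cutoff_h, method=self.pmedian_method,
                     seed=self.seed, restarts=self.restarts).fit(D, w)
        self.pmedian_ = pm

        dmin_all = D.min(axis=1)
        self.inaccessible_idx_ = np.flatnonzero(dmin_all > self.cutoff_h)
        keep = np.flatnonzero(dmin_all <= self.cutoff_h)

        mc = MaxCoveringLocation(p=self.p, cutoff_h=self.cutoff_h,
                                 method=self.mclp_method).fit(D[keep], w[keep])
        self.mclp_ = mc
        self.chosen_idx_ = mc.chosen_idx_
        labels = np.full(n_d, -1)
        labels[keep] = mc.labels_
        self.labels_ = labels
        self.objective_ = mc.objective_
        return self


# ---------------------------------------------------------------------------
# functional wrappers on ODMatrix


def _alloc_from_estimator(est, od, weights, fid_sorted, kind) -> Allocation:
    chosen_ids = tuple(fid_sorted[j] for j in est.chosen_idx_)
    assignment = {
        d: (fid_sorted[lab] if lab >= 0 else UNALLOCATED)
        for d, lab in zip(od.demand_ids, est.labels_)
    }
    return Allocation(chosen_sites=chosen_ids, assignment=assignment,
                      objective=est.objective_, cutoff_h=est.cutoff_h, kind=kind)


def p_median_exact(od: ODMatrix, weights, p: int,
                   cutoff_h: float | None = None) -> Allocation:
    """Globally optimal P-Median by exhaustive enumeration (guarded)."""
    D, w, fid_sorted = _prep(od, weights)
    est = PMedian(p=p, cutoff_h=cutoff_h, method="exact").fit(D, w)
    return _alloc_from_estimator(est, od, weights, fid_sorted, "p-median")


def p_median_heuristic(od: ODMatrix, weights, p: int,
                       cutoff_h: float | None = None, seed: int = 0,
                       restarts: int = 10) -> Allocation:
    """Teitz–Bart vertex-substitution P-Median; deterministic given seed."""
    D, w, fid_sorted = _prep(od, weights)
    est = PMedian(p=p, cutoff_h=cutoff_h, method="heuristic", seed=seed,
                  restarts=restarts).fit(D, w)
    return _alloc_from_estimator(est, od, weights, fid_sorted, "p-median")


def mclp_solve(od: ODMatrix, weights, p: int, cutoff_h: float,
               method: str = "exact") -> Allocation:
    """Maximal covering location problem; method 'exact' or 'greedy'."""
    if cutoff_h is None:
        raise ValueError("MCLP requires a cutoff")
    D, w, fid_sorted = _prep(od, weights)
    est = MaxCoveringLocation(p=p, cutoff_h=cutoff_h, method=method).fit(D, w)
    return _alloc_from_estimator(est, od, weights, fid_sorted, "mclp")


def flag_inaccessible(od: ODMatrix, cutoff_h: float) -> set[int]:
    """Demands that no facility in the OD matrix reaches within the cut-off."""
    dmin = np.where(np.isfinite(od.times), od.times, np.inf).min(axis=1)
    return {d for d, t in zip(od.demand_ids, dmin) if t > cutoff_h}


def mc_p_median_optimize(
    od: ODMatrix,
    weights,
    p: int,
    cutoff_h: float,
    pmedian_method: str = "auto",
    mclp_method: str = "exact",
    seed: int = 0,
    restarts: int = 10,
) -> OptimizedAllocation:
    """Run the staged MC-P-Median optimisation with a full audit log.

    Stage 1: P-Median allocation at the cut-off.  Stage 2: demands that no
    candidate site reaches within the cut-off are flagged inaccessible and
    removed.  Stage 3: MCLP re-solve over the remaining demands; every
    remaining demand is assigned to its nearest chosen site (demands the
    chosen set still cannot reach within the cut-off stay UNALLOCATED and
    are audit-logged — with p equal to the full candidate count there are
    none).
    """
    D, w, fid_sorted = _prep(od, weights)
    est = MCPMedian(p=p, cutoff_h=cutoff_h, pmedian_method=pmedian_method,
                    mclp_method=mclp_method, seed=seed, restarts=restarts).fit(D, w)

    stage1 = _alloc_from_estimator(est.pmedian_, od, weights, fid_sorted, "p-median")
    inaccessible = frozenset(od.demand_ids[i] for i in est.inaccessible_idx_)
    final = _alloc_from_estimator(est, od, weights, fid_sorted, "mclp")
    for d in inaccessible:  # removed demands never carry an assignment
        final.assignment[d] = UNALLOCATED

    log: list[dict] = []
    for d in sorted(inaccessible):
        log.append({"event": "removed", "demand_id": d,
                    "reason": "inaccessible or redundant at cutoff"})
    for d in od.demand_ids:
        if d in inaccessible:
            continue
        before, after = stage1.assignment[d], final.assignment[d]
        if before != after:
            log.append({"event": "reassigned", "demand_id": d,
                        "from": before, "to": after})
        if after is UNALLOCATED:
            log.append({"event": "uncovered", "demand_id": d,
                        "reason": "no chosen site within cutoff"})
    return OptimizedAllocation(p_median=stage1, inaccessible=inaccessible,
                               final=final, audit_log=log)
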