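"""Penalized l1 sparse coding.

Solves

    min_x  0.5 * ||y - A x||_2^2 + tau * ||x||_1

by gradient projection on the nonnegative split ``x = u - v`` with
Barzilai-Borwein step lengths and monotone backtracking.  This is the
penalized (Lagrangian) form of basis-pursuit; every sparse-representation
classifier in this package codes its query vectors through :func:`solve_l1`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SparseProblem",
    "SparseCode",
    "default_tau",
    "solve_l1",
    "split_by_class",
]

#: coefficients with magnitude below this are reported as exactly zero
ZERO_TOL = 1e-12

#: dictionaries with more atoms than this skip the exact active-set polish
POLISH_MAX_ATOMS = 100


@dataclass(frozen=True)
class SparseProblem:
    """An l1-penalized least-squares instance.

    Parameters
    ----------
    A : ndarray of shape (n_features, n_atoms)
        Dictionary matrix; columns are atoms.
    y : ndarray of shape (n_features,)
        Query vector.
    tau : float
        Nonnegative l1 penalty weight.
    tol : float
        Relative objective-decrease threshold for convergence.
    max_iter : int
        Iteration cap; exceeding it flags ``converged=False``.
    """

    A: np.ndarray
    y: np.ndarray
    tau: float
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        y = np.asarray(self.y, dtype=float).ravel()
        if A.ndim != 2:
            raise ValueError("dictionary A must be a 2-D matrix")
        if A.shape[1] < 1:
            raise ValueError("dictionary A must have at least one column")
        if A.shape[0] != y.shape[0]:
            raise ValueError(
                f"feature dimension mismatch: A has {A.shape[0]} rows, "
                f"y has length {y.shape[0]}"
            )
        if not np.all(np.isfinite(A)):
            raise ValueError("dictionary A contains non-finite entries")
        if not np.all(np.isfinite(y)):
            raise ValueError("query y contains non-finite entries")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "y", y)


@dataclass
class SparseCode:
    """Solver output: coefficients plus diagnostics."""

    x_hat: np.ndarray
    objective_trace: np.ndarray = field(repr=False)
    n_iter: int = 0
    converged: bool = True

    @property
    def n_nonzero(self) -> int:
        """Number of coefficients above the reporting zero-threshold."""
        return int(np.sum(np.abs(self.x_hat) > ZERO_TOL))


def default_tau(A: np.ndarray, y: np.ndarray, scale: float = 0.01) -> float:
    """Data-scaled default penalty ``scale * ||A^T y||_inf``.

    The max-correlation norm is the smallest penalty at which the zero
    vector is already optimal, so a small fraction of it keeps the
    solution nontrivially sparse on any input scale.
    """
    g = np.abs(np.asarray(A, dtype=float).T @ np.asarray(y, dtype=float))
    return float(scale * g.max()) if g.size else 0.0


def _objective(A: np.ndarray, y: np.ndarray, x: np.ndarray, tau: float) -> float:
    r = y - A @ x
    return 0.5 * float(r @ r) + tau * float(np.abs(x).sum())


def solve_l1(problem: SparseProblem) -> SparseCode:
    """Solve the penalized l1 problem by projected-gradient descent.

    The variable is split as ``x = u - v`` with ``u, v >= 0``; the smooth
    part is minimized over the nonnegative orthant with Barzilai-Borwein
    step proposals, backtracked until the full objective does not
    increase.  The returned ``objective_trace`` is therefore
    non-increasing after its first entry.

    Deterministic: identical inputs give identical outputs.
    """
    A, y, tau = problem.A, problem.y, problem.tau
    M = A.shape[1]

    if not np.any(y):
        # zero query: x = 0 is the exact global minimizer for tau > 0
        return SparseCode(
            x_hat=np.zeros(M),
            objective_trace=np.array([0.0]),
            n_iter=0,
            converged=True,
        )

    Aty = A.T @ y
    u = np.maximum(Aty, 0.0)
    v = np.maximum(-Aty, 0.0)
    # crude scaling of the least-squares start onto the right magnitude
    denom = float(np.sum((A @ (u - v)) ** 2))
    if denom > 0:
        s = float((u - v) @ Aty) / denom
        u *= max(s, 0.0)
        v *= max(s, 0.0)

    # complementary start: u'v = 0, so split and true objectives agree
    x = u - v
    obj = _objective(A, y, x, tau)  # equals split objective while u'v = 0
    trace = [obj]

    grad_f = A.T @ (A @ x - y)
    gu = grad_f + tau
    gv = -grad_f + tau

    step = 1.0
    converged = False
    lipschitz = None
    n_iter = 0
    for n_iter in range(1, problem.max_iter + 1):
        # monotone line search on the SPLIT objective
        # 0.5||y - A(u - v)||^2 + tau (1'u + 1'v) along the projection arc
        for _ in range(60):
            u_new = np.maximum(u - step * gu, 0.0)
            v_new = np.maximum(v - step * gv, 0.0)
            x_new = u_new - v_new
            r = y - A @ x_new
            obj_split = 0.5 * float(r @ r) + tau * float(u_new.sum() + v_new.sum())
            if obj_split <= obj + 1e-15:
                break
            step *= 0.5
        else:  # pragma: no cover - pathological scaling
            break

        # shrink the common part: x unchanged, split objective drops to
        # the true objective, keeping the reported trace monotone
        common = np.minimum(u_new, v_new)
        u_new -= common
        v_new -= common
        obj_new = 0.5 * float(r @ r) + tau * float(np.abs(x_new).sum())

        du = u_new - u
        dv = v_new - v
        grad_f_new = A.T @ (A @ x_new - y)
        gu_new = grad_f_new + tau
        gv_new = -grad_f_new + tau

        # Barzilai-Borwein step for the next iterate
        sTs = float(du @ du + dv @ dv)
        sTg = float(du @ (gu_new - gu) + dv @ (gv_new - gv))
        step = sTs / sTg if sTg > 1e-30 else 1.0
        step = min(max(step, 1e-10), 1e10)

        rel_drop = (obj - obj_new) / max(obj, 1e-30)
        u, v, x = u_new, v_new, x_new
        gu, gv = gu_new, gv_new
        obj = obj_new
        trace.append(obj)

        if 0 <= rel_drop < problem.tol:
            # confirm first-order optimality before declaring convergence;
            # BB steps can stall with a tiny objective drop far from optimum
            viol = np.maximum(
                np.where(x != 0, np.abs(grad_f_new + tau * np.sign(x)), 0.0),
                np.where(x == 0, np.maximum(np.abs(grad_f_new) - tau, 0.0), 0.0),
            ).max() if x.size else 0.0
            scale = max(float(np.abs(Aty).max()), 1.0)
            if viol <= problem.tol ** 0.75 * scale:
                converged = True
                break
            # stalled short of optimality: one proximal step with the
            # Lipschitz step length can move atoms across zero that the
            # projection-arc search keeps pinned
            if lipschitz is None:
                lipschitz = float(np.linalg.norm(A, 2)) ** 2
            z = x - grad_f_new / lipschitz
            x = np.sign(z) * np.maximum(np.abs(z) - tau / lipschitz, 0.0)
            u = np.maximum(x, 0.0)
            v = np.maximum(-x, 0.0)
            obj = _objective(A, y, x, tau)
            trace.append(obj)
            grad_f = A.T @ (A @ x - y)
            gu = grad_f + tau
            gv = -grad_f + tau
            step = 1.0

    # active-set polish: starting from the (near-final) support, refit
    # the face system exactly, pruning sign-flipped atoms and admitting
    # the worst KKT violator, until first-order optimality; accepted
    # only if the true objective does not increase, keeping the
    # reported trace monotone.  Skipped on large dictionaries, where
    # classification needs speed rather than machine-precision optima.
    x_new = _active_set_polish(A, y, Aty, tau, x) if M <= POLISH_MAX_ATOMS else None
    if x_new is not None:
        obj_new = _objective(A, y, x_new, tau)
        if obj_new <= obj + 1e-15:
            x, obj = x_new, obj_new
            trace.append(obj)
            converged = True

    x = np.where(np.abs(x) > ZERO_TOL, x, 0.0)
    return SparseCode(
        x_hat=x,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
    )


def _active_set_polish(A, y, Aty, tau, x0):
    """Finish the solve with a primal active-set refinement.

    With support S and signs s fixed, the penalized objective is smooth
    and its face optimum solves ``A_S' A_S z = A_S' y - tau * s``.  The
    iterate moves toward the face optimum but stops at the first atom
    crossing zero (which then leaves S); on reaching a face optimum, the
    atom with the largest off-support gradient excess (|g_i| > tau)
    enters with the opposing sign.  Objective-monotone by construction;
    returns the best iterate found.
    """
    M = A.shape[1]
    x = np.where(np.abs(x0) > ZERO_TOL, x0, 0.0)
    support = set(np.flatnonzero(x))
    signs = {int(i): float(np.sign(x[i])) for i in support}
    if not support:
        i = int(np.argmax(np.abs(Aty)))
        if np.abs(Aty[i]) <= tau:
            return np.zeros(M)  # zero vector is optimal
        support = {i}
        signs = {i: float(np.sign(Aty[i]))}

    kkt_tol = 1e-12 * max(1.0, float(np.abs(Aty).max()))
    best = x.copy()
    best_obj = _objective(A, y, x, tau)
    entering = None
    for _ in range(16 * M + 32):
        if not support:
            break
        idx = np.fromiter(sorted(support), dtype=int)
        As = A[:, idx]
        s = np.array([signs[i] for i in idx])
        G = As.T @ As
        rhs = Aty[idx] - tau * s
        z = np.linalg.lstsq(G, rhs, rcond=None)[0]

        scale = max(float(np.abs(rhs).max()), 1.0)
        if float(np.abs(G @ z - rhs).max()) > 1e-9 * scale:
            # singular face with no stationary point: descend along the
            # Gram null space (linear slope, zero curvature) until an
            # atom crosses zero and leaves the face
            q = G @ x[idx] - rhs  # gradient of the face objective
            w, V = np.linalg.eigh(G)
            null = V[:, w < 1e-10 * max(w.max(), 1e-30)]
            if null.size == 0:
                break  # pragma: no cover - inconsistency was numerical
            slopes = null.T @ q
            j = int(np.argmax(np.abs(slopes)))
            v = -np.sign(slopes[j]) * null[:, j]
            with np.errstate(divide="ignore", invalid="ignore"):
                cross = np.where(
                    np.sign(v) * np.sign(x[idx]) < 0, -x[idx] / v, np.inf
                )
            cross[x[idx] == 0.0] = np.inf
            k = int(np.argmin(cross))
            if not np.isfinite(cross[k]):
                break  # pragma: no cover - safeguard
            x[idx] = x[idx] + cross[k] * v
            leaver = int(idx[k])
            x[leaver] = 0.0
            support.discard(leaver)
            signs.pop(leaver, None)
            obj = _objective(A, y, x, tau)
            if obj < best_obj:
                best, best_obj = x.copy(), obj
            continue

        d = z - x[idx]

        # largest step in (0, 1] before any atom crosses zero
        t = 1.0
        leaver = None
        for k in range(len(idx)):
            xk, zk = x[idx[k]], z[k]
            if xk != 0.0 and np.sign(zk) * np.sign(xk) < 0:
                tk = xk / (xk - zk)
                if tk < t:
                    t, leaver = tk, int(idx[k])
            elif xk == 0.0 and np.sign(zk) * s[k] < 0:
                t, leaver = 0.0, int(idx[k])
                break

        if t <= 0.0:
            # the just-entered atom refuses its sign: degenerate face
            support.discard(leaver)
            signs.pop(leaver, None)
            if leaver == entering:
                break  # no progress possible; stop with the best so far
            continue

        x[idx] = x[idx] + t * d
        if leaver is not None:
            x[leaver] = 0.0
            support.discard(leaver)
            signs.pop(leaver, None)
            continue

        obj = _objective(A, y, x, tau)
        if obj > best_obj + 1e-15:
            break  # inconsistent/singular face produced no descent
        if obj < best_obj:
            best, best_obj = x.copy(), obj

        g = A.T @ (A @ x - y)
        mask = np.ones(M, dtype=bool)
        mask[idx] = False
        off = np.flatnonzero(mask)
        if off.size == 0:
            break
        viol = np.abs(g[off]) - tau
        k = int(np.argmax(viol))
        if viol[k] <= kkt_tol:
            break
        entering = int(off[k])
        support.add(entering)
        signs[entering] = -float(np.sign(g[entering]))
    return best


def split_by_class(code: SparseCode | np.ndarray, labels, class_id) -> np.ndarray:
    """Zero out every coefficient not belonging to ``class_id``.

    Returns a vector of the same length as the coefficient vector, equal
    to it on positions whose label is ``class_id`` and zero elsewhere.
    Summing the result over all distinct labels reconstructs the input.
    """
    x = code.x_hat if isinstance(code, SparseCode) else np.asarray(code, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError(
            f"labels length {labels.shape[0]} != coefficient length {x.shape[0]}"
        )
    mask = labels == class_id
    if not mask.any():
        raise ValueError(f"class {class_id!r} not present in labels")
    return np.where(mask, x, 0.0)
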