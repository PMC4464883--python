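"""Component-wise functional gradient descent boosting.

Every iteration computes the negative-gradient residuals, fits each
base-learner to them by (penalized) least squares, and updates only the
learner with the smallest residual sum of squares by a shrunken step
``nu``.  Fitting all learners is vectorized by grouping learners with the
same basis dimension into stacked tensors, so one iteration costs a single
mat-vec plus small batched solves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .learners import BaseLearner, ResolvedLearner, resolve, resolve_all
from .losses import LossSpec, get_loss

__all__ = [
    "BoostFit",
    "NotEnoughSelectionsError",
    "boost",
    "boost_until_q",
    "fit_component",
    "cv_mstop",
]


class NotEnoughSelectionsError(RuntimeError):
    """Raised when boosting cannot select ``q`` distinct learners in time.

    Carries the partial fit and the number of distinct learners reached.
    """

    def __init__(self, message: str, fit: "BoostFit", reached: int):
        super().__init__(message)
        self.fit = fit
        self.reached = reached


@dataclass
class BoostFit:
    """State of one component-wise boosting run."""

    offset: float | np.ndarray
    nu: float
    loss_name: str
    learner_ids: list[str]
    coefficients: list[np.ndarray]
    selection_path: list[str]
    risk_path: np.ndarray
    distinct_path: np.ndarray
    steps: list[tuple[int, np.ndarray]] = field(repr=False, default_factory=list)
    _resolved: list[ResolvedLearner] | None = field(repr=False, default=None)

    @property
    def m_stop(self) -> int:
        return len(self.selection_path)

    @property
    def selected(self) -> list[str]:
        """Distinct selected learner ids, in order of first selection."""
        return list(dict.fromkeys(self.selection_path))

    def predict(self, X: np.ndarray, scale: str = "link") -> np.ndarray:
        """Predictor on new data; ``scale='response'`` applies the response
        function of the loss."""
        if self._resolved is None:
            raise RuntimeError("fit does not carry resolved learners")
        X = np.asarray(X, dtype=float)
        eta = np.full(X.shape[0], float(np.mean(self.offset)))
        if np.ndim(self.offset) == 1 and len(self.offset) == X.shape[0]:
            eta = np.asarray(self.offset, dtype=float).copy()
        for rl, coef in zip(self._resolved, self.coefficients):
            if np.any(coef):
                eta += rl.basis(X) @ coef
        if scale == "link":
            return eta
        if scale == "response":
            return get_loss(self.loss_name).response(eta)
        raise ValueError("scale must be 'link' or 'response'")

    def to_dict(self) -> dict:
        return {
            "loss": self.loss_name,
            "nu": self.nu,
            "offset": (
                float(self.offset)
                if np.ndim(self.offset) == 0
                else np.asarray(self.offset).tolist()
            ),
            "coefficients": {
                lid: coef.tolist()
                for lid, coef in zip(self.learner_ids, self.coefficients)
            },
            "selection_path": list(self.selection_path),
            "risk_path": np.asarray(self.risk_path).tolist(),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# engine


class _Prepared:
    """Bases/grams for a set of resolved learners, grouped by basis width."""

    def __init__(self, resolved: Sequence[ResolvedLearner], rows: np.ndarray | None):
        self.resolved = list(resolved)
        self.n = (
            self.resolved[0].B.shape[0] if rows is None else len(rows)
        )
        groups: dict[int, list[int]] = {}
        for j, rl in enumerate(self.resolved):
            groups.setdefault(rl.K, []).append(j)
        self.groups = []
        order: list[int] = []
        for K, idx in groups.items():
            Bs = []
            Ainv = np.empty((len(idx), K, K))
            G = np.empty((len(idx), K, K))
            for g, j in enumerate(idx):
                rl = self.resolved[j]
                B = rl.B if rows is None else rl.B[rows]
                Bs.append(B)
                gram = B.T @ B
                G[g] = gram
                pen = gram if rl.penalty is None else gram + rl.lam * rl.penalty
                try:
                    Ainv[g] = np.linalg.inv(pen)
                except np.linalg.LinAlgError:
                    # degenerate within this row subset (e.g. a constant
                    # column after subsampling): minimum-norm fit instead
                    Ainv[g] = np.linalg.pinv(pen)
            BT = np.ascontiguousarray(
                np.stack([b.T for b in Bs]).reshape(len(idx) * K, self.n)
            )
            self.groups.append(
                {"K": K, "idx": np.array(idx), "B": Bs, "BT": BT, "Ainv": Ainv, "G": G}
            )
            order.extend(idx)
        # position of learner j in the concatenated RSS vector
        self._pos = np.empty(len(self.resolved), dtype=int)
        self._pos[np.array(order)] = np.arange(len(order))
        self._order = np.array(order)

    def fit_all(self, u: np.ndarray):
        """Fit every learner to the residuals; return (rss per learner,
        list of per-group coefficient blocks)."""
        uu = float(u @ u)
        rss = np.empty(len(self.resolved))
        coefs = []
        for grp in self.groups:
            K = grp["K"]
            V = (grp["BT"] @ u).reshape(-1, K)
            C = np.einsum("gij,gj->gi", grp["Ainv"], V)
            q1 = np.einsum("gi,gi->g", C, V)
            q2 = np.einsum("gi,gij,gj->g", C, grp["G"], C)
            rss[grp["idx"]] = uu - 2.0 * q1 + q2
            coefs.append(C)
        return rss, coefs

    def coef_of(self, j: int, coefs) -> np.ndarray:
        for grp, C in zip(self.groups, coefs):
            where = np.nonzero(grp["idx"] == j)[0]
            if where.size:
                return C[where[0]]
        raise IndexError(j)

    def basis_of(self, j: int) -> np.ndarray:
        for grp in self.groups:
            where = np.nonzero(grp["idx"] == j)[0]
            if where.size:
                return grp["B"][where[0]]
        raise IndexError(j)


def _make_offset(
    loss: LossSpec,
    y: np.ndarray,
    offset_mode: str,
    offset_value: float | np.ndarray | None,
) -> float | np.ndarray:
    if offset_value is not None:
        off = np.asarray(offset_value, dtype=float)
        return float(off) if off.ndim == 0 else off
    if offset_mode == "zero":
        return 0.0
    if offset_mode == "loss_minimizer":
        return loss.offset(y)
    raise ValueError("offset_mode must be 'zero' or 'loss_minimizer'")


def _run(
    prepared: _Prepared,
    y: np.ndarray,
    loss: LossSpec,
    nu: float,
    offset: float | np.ndarray,
    m_stop: int | None = None,
    q: int | None = None,
    max_iter: int | None = None,
    record_steps: bool = False,
) -> BoostFit:
    p = len(prepared.resolved)
    eta = np.full(prepared.n, 0.0) + offset
    coefficients = [np.zeros(rl.K) for rl in prepared.resolved]
    selection_path: list[str] = []
    risk_path: list[float] = []
    distinct_path: list[int] = []
    steps: list[tuple[int, np.ndarray]] = []
    distinct: set[int] = set()
    limit = m_stop if q is None else max_iter
    m = 0
    while m < limit:
        m += 1
        u = loss.negative_gradient(y, eta)
        rss, coefs = prepared.fit_all(u)
        j = int(np.argmin(rss))  # ties -> lowest learner index
        c = prepared.coef_of(j, coefs)
        coefficients[j] = coefficients[j] + nu * c
        eta = eta + nu * (prepared.basis_of(j) @ c)
        selection_path.append(prepared.resolved[j].id)
        risk_path.append(loss.risk(y, eta))
        distinct.add(j)
        distinct_path.append(len(distinct))
        if record_steps:
            steps.append((j, nu * c))
        if q is not None and len(distinct) >= q:
            break
    fit = BoostFit(
        offset=offset,
        nu=nu,
        loss_name=loss.name,
        learner_ids=[rl.id for rl in prepared.resolved],
        coefficients=coefficients,
        selection_path=selection_path,
        risk_path=np.asarray(risk_path),
        distinct_path=np.asarray(distinct_path, dtype=int),
        steps=steps,
        _resolved=prepared.resolved,
    )
    if q is not None and len(distinct) < q:
        raise NotEnoughSelectionsError(
            f"only {len(distinct)} of q={q} distinct base-learners selected "
            f"within max_iter={max_iter}",
            fit,
            len(distinct),
        )
    return fit


def _validate(X: np.ndarray, y: np.ndarray, loss: LossSpec, nu: float):
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN values in X or y")
    if not (0.0 < nu <= 1.0):
        raise ValueError("nu must lie in (0, 1]")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    loss.check_response(y)


# ---------------------------------------------------------------------------
# public operations


def fit_component(learner: BaseLearner | ResolvedLearner, X, u):
    """Fit a single base-learner to a residual vector by (penalized) least
    squares.

    Returns
    -------
    (coefficients, rss):
        The minimizer of ``||u - B c||^2 (+ lam * c' P c)`` and the residual
        sum of squares (penalty excluded) at that minimizer.
    """
    X = np.asarray(X, dtype=float)
    u = np.asarray(u, dtype=float)
    rl = learner if isinstance(learner, ResolvedLearner) else resolve(learner, X)
    B = rl.B
    gram = B.T @ B
    if rl.penalty is not None:
        gram = gram + rl.lam * rl.penalty
    coef = np.linalg.solve(gram, B.T @ u)
    resid = u - B @ coef
    return coef, float(resid @ resid)


def boost(
    X,
    y,
    loss,
    learners: Sequence[BaseLearner],
    nu: float = 0.1,
    m_stop: int = 100,
    offset_mode: str = "loss_minimizer",
    offset_value: float | np.ndarray | None = None,
    record_steps: bool = False,
) -> BoostFit:
    """Run component-wise boosting for a fixed number of iterations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    loss = get_loss(loss)
    _validate(X, y, loss, nu)
    if m_stop < 0:
        raise ValueError("m_stop must be >= 0")
    resolved = resolve_all(learners, X)
    offset = _make_offset(loss, y, offset_mode, offset_value)
    return _run(
        _Prepared(resolved, None), y, loss, nu, offset,
        m_stop=m_stop, record_steps=record_steps,
    )


def boost_until_q(
    X,
    y,
    loss,
    learners: Sequence[BaseLearner],
    nu: float = 0.1,
    q: int = 1,
    max_iter: int = 2500,
    offset_mode: str = "loss_minimizer",
    offset_value: float | np.ndarray | None = None,
) -> BoostFit:
    """Boost until ``q`` distinct base-learners have been selected.

    The iteration that first selects the q-th distinct learner is included.
    Raises :class:`NotEnoughSelectionsError` (carrying the partial fit) if
    ``q`` distinct learners are not reached within ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    loss = get_loss(loss)
    _validate(X, y, loss, nu)
    if not (1 <= q <= len(learners)):
        raise ValueError(f"q={q} must lie in [1, number of learners={len(learners)}]")
    if max_iter < q:
        raise ValueError("max_iter must be >= q")
    resolved = resolve_all(learners, X)
    offset = _make_offset(loss, y, offset_mode, offset_value)
    return _run(
        _Prepared(resolved, None), y, loss, nu, offset, q=q, max_iter=max_iter
    )


def boost_resolved(
    resolved: Sequence[ResolvedLearner],
    y: np.ndarray,
    loss: LossSpec,
    rows: np.ndarray | None = None,
    nu: float = 0.1,
    m_stop: int | None = None,
    q: int | None = None,
    max_iter: int | None = None,
    offset_mode: str = "loss_minimizer",
    offset_value: float | np.ndarray | None = None,
) -> BoostFit:
    """Boost on pre-resolved learners, optionally restricted to a row subset.

    This is the fast path used by subsampling: bases are sliced from the
    full-data resolution (ridge multipliers kept fixed), grams recomputed.
    """
    loss = get_loss(loss)
    y = np.asarray(y, dtype=float)
    ysub = y if rows is None else y[rows]
    loss.check_response(ysub)
    off_val = offset_value
    if off_val is not None and np.ndim(off_val) == 1 and rows is not None:
        off_val = np.asarray(off_val, dtype=float)[rows]
    offset = _make_offset(loss, ysub, offset_mode, off_val)
    return _run(
        _Prepared(resolved, rows), ysub, loss, nu, offset,
        m_stop=m_stop, q=q, max_iter=max_iter,
    )


def cv_mstop(
    X,
    y,
    loss,
    learners: Sequence[BaseLearner],
    nu: float = 0.1,
    m_grid: Sequence[int] = (10, 25, 50, 100, 250, 500),
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick the stopping iteration by k-fold cross-validation.

    Returns the grid value minimizing the mean out-of-fold empirical risk
    (ties resolved towards the smaller m).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    loss = get_loss(loss)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(m_grid) == 0:
        raise ValueError("m_grid must be non-empty")
    m_grid = sorted(int(m) for m in m_grid)
    if m_grid[0] < 0:
        raise ValueError("m_grid entries must be >= 0")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)
    risks = np.zeros((folds, len(m_grid)))
    for f, val_idx in enumerate(fold_ids):
        train_idx = np.setdiff1d(perm, val_idx, assume_unique=True)
        fit = boost(
            X[train_idx], y[train_idx], loss, learners, nu=nu,
            m_stop=m_grid[-1], record_steps=True,
        )
        Xval, yval = X[val_idx], y[val_idx]
        eta_val = np.full(len(val_idx), float(np.mean(fit.offset)))
        bases = {}
        grid_pos = {m: i for i, m in enumerate(m_grid)}
        if 0 in grid_pos:
            risks[f, grid_pos[0]] = loss.risk(yval, eta_val)
        for m, (j, c_inc) in enumerate(fit.steps, start=1):
            if j not in bases:
                bases[j] = fit._resolved[j].basis(Xval)
            eta_val = eta_val + bases[j] @ c_inc
            if m in grid_pos:
                risks[f, grid_pos[m]] = loss.risk(yval, eta_val)
    mean_risk = risks.mean(axis=0)
    return m_grid[int(np.argmin(mean_risk))]
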