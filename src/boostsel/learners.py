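"""Base-learner definitions and their resolution into concrete designs.

A :class:`BaseLearner` is a declarative description (kind, columns, target
degrees of freedom).  :func:`resolve` turns it into a
:class:`ResolvedLearner` holding the basis expansion, penalty matrix and a
ridge multiplier fixed once, before boosting, so that the trace of the
smoother matrix equals the requested degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import solve
from scipy.optimize import brentq

__all__ = [
    "BaseLearner",
    "ResolvedLearner",
    "linear",
    "pspline",
    "ridge_categorical",
    "resolve",
    "resolve_all",
]

_KINDS = ("linear", "pspline", "ridge_categorical")

#: P-spline defaults: cubic splines, 20 interior knots, 2nd-order penalty.
PSPLINE_DEGREE = 3
PSPLINE_INTERIOR_KNOTS = 20
DEFAULT_DF = 4.0
_DF_TOL = 1e-6


@dataclass(frozen=True)
class BaseLearner:
    """Declarative base-learner description.

    ``scale_column`` (ridge_categorical only) names a column whose value
    multiplies every basis row, which is how group-specific random effects
    with sum-to-zero group coding are expressed.
    """

    id: str
    kind: str
    columns: tuple[int, ...]
    df: float | None = None
    scale_column: int | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if self.kind == "linear":
            if self.df is not None:
                raise ValueError("linear learners carry no penalty / df")
        else:
            if self.df is None or self.df <= 0:
                raise ValueError(f"penalized learner {self.id!r} needs df > 0")
        if self.scale_column is not None and self.kind != "ridge_categorical":
            raise ValueError("scale_column is only valid for ridge_categorical")


def linear(column: int, id: str | None = None) -> BaseLearner:
    """Linear learner on one column (per-learner intercept included)."""
    return BaseLearner(id=id or f"x{column}", kind="linear", columns=(column,))


def pspline(column: int, df: float = DEFAULT_DF, id: str | None = None) -> BaseLearner:
    """Cubic P-spline learner with a 2nd-order difference penalty."""
    return BaseLearner(
        id=id or f"x{column}", kind="pspline", columns=(column,), df=df
    )


def ridge_categorical(
    column: int,
    df: float = DEFAULT_DF,
    id: str | None = None,
    scale_column: int | None = None,
) -> BaseLearner:
    """Ridge-penalized indicator block (random-effect surrogate)."""
    return BaseLearner(
        id=id or f"cat{column}",
        kind="ridge_categorical",
        columns=(column,),
        df=df,
        scale_column=scale_column,
    )


def _second_diff_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


class ResolvedLearner:
    """A base-learner bound to a training design.

    Stores whatever is needed to rebuild the basis on new data (knots for
    P-splines, level codes for categorical blocks) together with the
    resolved ridge multiplier ``lam`` and the cached training basis.
    """

    def __init__(self, learner: BaseLearner, X: np.ndarray, lam: float | None = None):
        self.learner = learner
        self.id = learner.id
        x = np.asarray(X, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if max(learner.columns) >= x.shape[1]:
            raise ValueError(
                f"learner {learner.id!r} refers to column {max(learner.columns)}"
                f" but X has {x.shape[1]} columns"
            )
        self.n_columns = x.shape[1]
        self._setup(x)
        self.B = self._basis_raw(x)
        self.K = self.B.shape[1]
        self.penalty = self._penalty_matrix()
        if learner.kind == "linear":
            self.lam = 0.0
            gram = self.B.T @ self.B
            if np.linalg.matrix_rank(gram) < self.K:
                raise np.linalg.LinAlgError(
                    f"singular unpenalized design for learner {learner.id!r}"
                )
        else:
            if learner.df >= self.K:
                raise ValueError(
                    f"learner {learner.id!r}: df={learner.df} must be below the "
                    f"basis dimension {self.K}"
                )
            self.lam = self._resolve_lambda(learner.df) if lam is None else float(lam)

    # -- basis construction -------------------------------------------------

    def _setup(self, X: np.ndarray) -> None:
        kind = self.learner.kind
        col = X[:, self.learner.columns[0]]
        if kind == "pspline":
            lo, hi = float(np.min(col)), float(np.max(col))
            if hi <= lo:
                raise ValueError(
                    f"learner {self.learner.id!r}: degenerate column range"
                )
            # equally spaced knots extended past the range (not clamped), so
            # the 2nd-order penalty null space maps to exactly linear fits
            deg = PSPLINE_DEGREE
            h = (hi - lo) / (PSPLINE_INTERIOR_KNOTS + 1)
            self.knots = lo + h * np.arange(
                -deg, PSPLINE_INTERIOR_KNOTS + 2 + deg
            )
            # clip to the realized knot domain (guards fp rounding of hi)
            self._range = (float(self.knots[deg]), float(self.knots[-deg - 1]))
        elif kind == "ridge_categorical":
            self.levels = np.unique(col)

    def _basis_raw(self, X: np.ndarray) -> np.ndarray:
        kind = self.learner.kind
        col = np.asarray(X, dtype=float)[:, self.learner.columns[0]]
        if kind == "linear":
            return np.column_stack([np.ones_like(col), col])
        if kind == "pspline":
            lo, hi = self._range
            clipped = np.clip(col, lo, hi)
            dm = BSpline.design_matrix(clipped, self.knots, PSPLINE_DEGREE)
            return np.asarray(dm.todense(), dtype=float)
        # ridge_categorical
        B = (col[:, None] == self.levels[None, :]).astype(float)
        if self.learner.scale_column is not None:
            B = B * np.asarray(X, dtype=float)[:, [self.learner.scale_column]]
        return B

    def _penalty_matrix(self) -> np.ndarray | None:
        kind = self.learner.kind
        if kind == "linear":
            return None
        if kind == "pspline":
            return _second_diff_penalty(self.K)
        return np.eye(self.K)

    def basis(self, X: np.ndarray) -> np.ndarray:
        """Basis expansion of new data (P-spline inputs clipped to the
        training range; unseen categorical levels map to all-zero rows)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_columns:
            raise ValueError(
                f"expected {self.n_columns} columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-matrix input'}"
            )
        return self._basis_raw(X)

    # -- degrees of freedom -------------------------------------------------

    def effective_df(self, lam: float | None = None) -> float:
        """trace of the smoother B (B'B + lam*P)^{-1} B'."""
        lam = self.lam if lam is None else lam
        G = self.B.T @ self.B
        if self.penalty is None:
            return float(np.trace(solve(G, G)))
        return float(np.trace(solve(G + lam * self.penalty, G, assume_a="pos")))

    def _resolve_lambda(self, df: float) -> float:
        G = self.B.T @ self.B
        P = self.penalty

        def trace_df(loglam: float) -> float:
            return float(np.trace(solve(G + np.exp(loglam) * P, G, assume_a="pos")))

        lo, hi = -25.0, 25.0
        # expand the bracket if the target df lies outside
        while trace_df(lo) < df and lo > -60:
            lo -= 10
        while trace_df(hi) > df and hi < 60:
            hi += 10
        if trace_df(lo) < df:
            raise ValueError(
                f"learner {self.learner.id!r}: cannot reach df={df}"
                f" (max attainable {trace_df(lo):.3f})"
            )
        loglam = brentq(lambda ll: trace_df(ll) - df, lo, hi, xtol=1e-12)
        lam = float(np.exp(loglam))
        if abs(trace_df(loglam) - df) > _DF_TOL:
            raise RuntimeError(
                f"learner {self.learner.id!r}: df resolution did not converge"
            )
        return lam

    def with_lambda(self, lam: float) -> "ResolvedLearner":
        """Copy of this resolved learner with an explicit ridge multiplier."""
        out = ResolvedLearner.__new__(ResolvedLearner)
        out.__dict__.update(self.__dict__)
        out.lam = float(lam)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ResolvedLearner({self.id!r}, kind={self.learner.kind}, "
            f"K={self.K}, lam={self.lam:.4g})"
        )


def resolve(learner: BaseLearner, X: np.ndarray, lam: float | None = None) -> ResolvedLearner:
    """Bind a learner to a design matrix, fixing its ridge multiplier."""
    return ResolvedLearner(learner, X, lam=lam)


def resolve_all(learners: Sequence[BaseLearner], X: np.ndarray) -> list[ResolvedLearner]:
    if not learners:
        raise ValueError("at least one base-learner is required")
    ids = [lr.id for lr in learners]
    if len(set(ids)) != len(ids):
        raise ValueError("base-learner ids must be unique")
    return [resolve(lr, X) for lr in learners]
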