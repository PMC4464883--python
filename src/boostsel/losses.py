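"""Loss functions for component-wise gradient boosting.

Each loss is described by a :class:`LossSpec` bundling the pointwise loss
``rho(y, eta)``, its negative gradient with respect to the predictor
``eta``, the response function mapping ``eta`` to the mean scale, and the
scalar offset minimizing the empirical risk of a constant model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "LossSpec",
    "GAUSSIAN",
    "BINOMIAL",
    "get_loss",
    "negative_gradient",
]


@dataclass(frozen=True)
class LossSpec:
    """A boosting loss: pointwise risk, negative gradient, link machinery."""

    name: str
    loss: Callable[[np.ndarray, np.ndarray], np.ndarray]
    negative_gradient: Callable[[np.ndarray, np.ndarray], np.ndarray]
    response: Callable[[np.ndarray], np.ndarray]
    offset: Callable[[np.ndarray], float]
    check_response: Callable[[np.ndarray], None] = field(
        default=lambda y: None, repr=False
    )

    def risk(self, y: np.ndarray, eta: np.ndarray) -> float:
        """Empirical risk: mean pointwise loss."""
        return float(np.mean(self.loss(y, eta)))


def _gaussian_loss(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # half squared error so the negative gradient is the plain residual
    return 0.5 * (y - eta) ** 2


def _gaussian_ngrad(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y - eta


def _check_binary(y: np.ndarray) -> None:
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("binomial loss requires a 0/1 response")


def _binomial_loss(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # negative Bernoulli log-likelihood with logit link, in the stable
    # log-sum-exp form log(1 + exp(eta)) - y*eta
    return np.logaddexp(0.0, eta) - y * eta


def _binomial_ngrad(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y - expit(eta)


def _binomial_offset(y: np.ndarray) -> float:
    n = y.shape[0]
    # clip away from the boundary so degenerate (single-class) responses
    # still yield a finite offset
    mean = float(np.clip(np.mean(y), 0.5 / n, 1.0 - 0.5 / n))
    return float(logit(mean))


GAUSSIAN = LossSpec(
    name="gaussian",
    loss=_gaussian_loss,
    negative_gradient=_gaussian_ngrad,
    response=lambda eta: np.asarray(eta, dtype=float),
    offset=lambda y: float(np.mean(y)),
)

BINOMIAL = LossSpec(
    name="binomial",
    loss=_binomial_loss,
    negative_gradient=_binomial_ngrad,
    response=expit,
    offset=_binomial_offset,
    check_response=_check_binary,
)

_REGISTRY = {"gaussian": GAUSSIAN, "binomial": BINOMIAL}


def get_loss(name: str | LossSpec) -> LossSpec:
    """Return a registered :class:`LossSpec` by name (pass-through for specs)."""
    if isinstance(name, LossSpec):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown loss {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def negative_gradient(loss: str | LossSpec, y, eta) -> np.ndarray:
    """Negative gradient of the loss with respect to the predictor.

    Parameters
    ----------
    loss:
        Loss name or :class:`LossSpec`.
    y, eta:
        Response and current predictor, same length.

    Returns
    -------
    numpy.ndarray
        ``u_i = -d rho(y_i, eta)/d eta`` evaluated at ``eta_i``.
    """
    spec = get_loss(loss)
    y = np.asarray(y, dtype=float)
    eta = np.broadcast_to(np.asarray(eta, dtype=float), y.shape)
    if y.shape != eta.shape:
        raise ValueError("y and eta must have the same length")
    spec.check_response(y)
    return spec.negative_gradient(y, eta)
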