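"""Link functions for the single-index model ``eta(x) = g(b0 + b.x)``.

A link maps the real-valued index to a class-1 probability.  The two
built-in links are the logistic CDF and the rescaled arctangent; both are
strictly increasing, so the sign pattern of the population quadratic-loss
minimizer matches the sign pattern of the true coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class Link:
    """A link function with optional first/second derivatives.

    Parameters
    ----------
    name : str
        Tag of the link ("logistic", "arctan" or "custom").
    g : callable
        Vectorized map from index values to probabilities in [0, 1].
    dg, d2g : callable, optional
        First and second derivative of ``g``; used by the oracle
        classifier's Newton iteration when available.
    """

    name: str
    g: Callable[[np.ndarray], np.ndarray]
    dg: Optional[Callable[[np.ndarray], np.ndarray]] = field(default=None)
    d2g: Optional[Callable[[np.ndarray], np.ndarray]] = field(default=None)

    def __call__(self, u):
        return self.g(u)


def _logistic(u):
    # expit is overflow-safe: exp(u)/(1+exp(u)) for u<0, 1/(1+exp(-u)) else
    return expit(np.asarray(u, dtype=float))


def _logistic_d1(u):
    p = _logistic(u)
    return p * (1.0 - p)


def _logistic_d2(u):
    p = _logistic(u)
    return p * (1.0 - p) * (1.0 - 2.0 * p)


def _arctan(u):
    return np.arctan(np.asarray(u, dtype=float)) / np.pi + 0.5


def _arctan_d1(u):
    u = np.asarray(u, dtype=float)
    return 1.0 / (np.pi * (1.0 + u * u))


def _arctan_d2(u):
    u = np.asarray(u, dtype=float)
    return -2.0 * u / (np.pi * (1.0 + u * u) ** 2)


LOGISTIC = Link("logistic", _logistic, _logistic_d1, _logistic_d2)
ARCTAN = Link("arctan", _arctan, _arctan_d1, _arctan_d2)

_REGISTRY = {"logistic": LOGISTIC, "arctan": ARCTAN}


def get_link(link) -> Link:
    """Resolve a link tag, callable or Link instance to a :class:`Link`.

    Raises
    ------
    ValueError
        If a string tag is not one of the registered links.
    """
    if isinstance(link, Link):
        return link
    if callable(link):
        return Link("custom", link)
    try:
        return _REGISTRY[link]
    except KeyError:
        raise ValueError(
            f"unknown link {link!r}; registered links: {sorted(_REGISTRY)}"
        ) from None
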