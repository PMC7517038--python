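"""Synthetic data from the semiparametric single-index classification model.

Labels Y in {-1, +1} are generated with class-1 probability
``eta(x) = g(beta_0 + beta.x)`` where ``g`` is a known monotone link and the
design rows are equicorrelated Gaussians: X ~ N(0, H) with H_jj = 1 and
H_jk = rho for j != k.  This is the generative model of the simulation
study; every ground-truth quantity (the index, the Bayes risk, population
minimizers) is derived from a :class:`ModelSpec`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .links import Link, get_link

__all__ = [
    "ModelSpec",
    "Dataset",
    "make_true_beta",
    "sample_design",
    "response_probability",
    "sample_labels",
    "make_dataset",
    "bayes_risk",
    "design_covariance",
    "read_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class ModelSpec:
    """Ground-truth generative model.

    Parameters
    ----------
    p : int
        Number of predictors.
    beta : ndarray, shape (p+1,)
        True coefficient vector; index 0 is the intercept beta_0, indices
        1..p are the slopes acting on the predictors.
    link : str, callable or Link
        Monotone map from index to class-1 probability.
    rho : float
        Common off-diagonal correlation of the design, in [0, 1).
    """

    p: int
    beta: np.ndarray
    link: Union[str, Link] = "logistic"
    rho: float = 0.5

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != (self.p + 1,):
            raise ValueError(f"beta must have length p+1={self.p + 1}, got {beta.shape}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "link", get_link(self.link))

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def slopes(self) -> np.ndarray:
        """The slope vector (without the intercept)."""
        return self.beta[1:]

    @property
    def support(self) -> np.ndarray:
        """1-based indices of the active predictors, T = {j >= 1 : beta_j != 0}."""
        return np.flatnonzero(self.slopes) + 1

    def to_dict(self) -> dict:
        if self.link.name == "custom":
            raise ValueError("custom links are not serializable")
        return {
            "p": self.p,
            "beta": self.beta.tolist(),
            "link": self.link.name,
            "rho": self.rho,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(p=int(d["p"]), beta=np.asarray(d["beta"], float),
                   link=d["link"], rho=float(d["rho"]))

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class Dataset:
    """An n x p design with labels in {-1, +1}."""

    X: np.ndarray
    y: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if y.shape != (X.shape[0],):
            raise ValueError("y must have one entry per row of X")
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("labels must lie in {-1, +1}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def make_true_beta(p: int, k: int, seed: int) -> np.ndarray:
    """Draw the true coefficient vector (1, ±1 x k, 0 x (p-k)).

    The intercept is 1, the first ``k`` slopes are ±1 with signs drawn
    uniformly at random, and the remaining slopes are zero.
    """
    if not (0 <= k <= p):
        raise ValueError(f"need 0 <= k <= p, got k={k}, p={p}")
    rng = np.random.default_rng(seed)
    beta = np.zeros(p + 1)
    beta[0] = 1.0
    beta[1 : k + 1] = rng.choice((-1.0, 1.0), size=k)
    return beta


def design_covariance(p: int, rho: float) -> np.ndarray:
    """The equicorrelated covariance H with unit diagonal.

    Eigenvalues are 1 - rho (multiplicity p-1) and 1 + (p-1) rho, so H is
    positive definite for every rho in [0, 1).
    """
    H = np.full((p, p), rho)
    np.fill_diagonal(H, 1.0)
    return H


def sample_design(n: int, spec: ModelSpec, seed: int,
                  columns: Optional[np.ndarray] = None) -> np.ndarray:
    """Sample n i.i.d. rows from N(0, H(rho)).

    Uses the one-factor decomposition X_ij = sqrt(rho) Z_i + sqrt(1-rho) W_ij
    with Z, W standard normal, which realizes the equicorrelated covariance
    exactly.  ``columns`` restricts generation to a subset of predictor
    columns (0-based); the marginal law of any column subset is the
    equicorrelated Gaussian of that dimension, so this is a genuine
    marginalization, not an approximation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ncols = spec.p if columns is None else len(columns)
    z = rng.standard_normal((n, 1))
    w = rng.standard_normal((n, ncols))
    return np.sqrt(spec.rho) * z + np.sqrt(1.0 - spec.rho) * w


def response_probability(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Class-1 probability eta(x) = g(beta_0 + beta.x) for rows of ``x``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    u = spec.intercept + x @ spec.slopes
    eta = np.asarray(spec.link(u), dtype=float)
    return eta if eta.shape else eta.reshape(())


def sample_labels(X: np.ndarray, spec: ModelSpec, seed: int) -> np.ndarray:
    """Draw Y_i = +1 with probability eta(X_i), else -1, independently."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != spec.p:
        raise ValueError(f"X has {X.shape[1]} columns, spec expects {spec.p}")
    eta = response_probability(X, spec)
    rng = np.random.default_rng(seed)
    return np.where(rng.random(X.shape[0]) < eta, 1.0, -1.0)


def make_dataset(n: int, spec: ModelSpec, seed: int) -> Dataset:
    """Sample a full dataset: design from ``sample_design``, labels from
    ``sample_labels`` (with a derived, distinct label seed)."""
    X = sample_design(n, spec, seed)
    y = sample_labels(X, spec, seed=np.random.default_rng([seed, 1]).integers(2**31))
    return Dataset(X=X, y=y, seed=seed)


def bayes_risk(spec: ModelSpec, m: int = 10**6, seed: int = 0):
    """Monte-Carlo estimate of the Bayes risk R_B = E[min(eta, 1 - eta)].

    The Bayes classifier sign(2 eta(x) - 1) errs at x with probability
    min(eta(x), 1 - eta(x)); averaging over m design draws estimates the
    irreducible misclassification risk.

    Returns
    -------
    (estimate, standard_error)
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    # The index beta_0 + beta.x is Gaussian under the model, so we draw it
    # directly: variance beta.H.beta in closed form.
    var = index_variance(spec)
    rng = np.random.default_rng(seed)
    u = spec.intercept + np.sqrt(var) * rng.standard_normal(m)
    eta = np.asarray(spec.link(u), dtype=float)
    loss = np.minimum(eta, 1.0 - eta)
    return float(loss.mean()), float(loss.std(ddof=1) / np.sqrt(m))


def index_variance(spec: ModelSpec) -> float:
    """Var(beta.X) = (1-rho)|beta|_2^2 + rho (sum beta_j)^2, in closed form."""
    b = spec.slopes
    return float((1.0 - spec.rho) * b @ b + spec.rho * b.sum() ** 2)


def write_dataset(data: Dataset, path) -> None:
    """Write a dataset as delimited text with a 'y' label column."""
    df = pd.DataFrame(data.X, columns=[f"x{j}" for j in range(1, data.p + 1)])
    df.insert(0, "y", data.y.astype(int))
    df.to_csv(path, index=False)


def read_dataset(path) -> Dataset:
    """Read a delimited dataset; the label column is named 'y'.

    Labels coded {0, 1} are mapped to {-1, +1} with a warning.
    """
    df = pd.read_csv(path)
    if "y" not in df.columns:
        raise ValueError("dataset file must contain a 'y' column")
    y = df.pop("y").to_numpy(dtype=float)
    uniq = set(np.unique(y))
    if uniq <= {0.0, 1.0}:
        warnings.warn("labels coded {0,1}; recoding to {-1,+1}")
        y = 2.0 * y - 1.0
    return Dataset(X=df.to_numpy(dtype=float), y=y)
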