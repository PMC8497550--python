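"""Preliminary score matrix and its latent-factor densification.

The preliminary lncRNA-disease score matrix is the product of the two
aligned adjacencies: entry (i, j) counts the miRNAs shared by lncRNA i and
disease j.  Because that matrix is sparse, it is approximated by a rank-K
factorization psi = X @ Y fitted with full-batch gradient descent on a
squared-error loss with L2 regularization on both factors; the dense psi
scores every zero cell through the shared latent structure.

Training notes
--------------
* The loss sums the squared residual over ALL m x e entries, not only the
  non-zeros: scoring the zero cells is the point of the densification.
* X and Y are updated simultaneously each iteration from their current
  values (full-batch, not alternating and not per-entry stochastic).
* Defaults: learning rate 2e-4, regularization weight 4e-3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import AlignedTriple
from .exceptions import DataError, NumericalError

DEFAULT_ALPHA = 0.0002
DEFAULT_LAMBDA = 0.004
DEFAULT_K = 50
DEFAULT_MAX_ITERS = 5000
DEFAULT_TOL = 1e-6

STAGES = ("preliminary", "reconstructed", "lncrna_projection",
          "disease_projection", "final")


@dataclass
class ScoreMatrix:
    """Real-valued lncRNA x disease score matrix with named axes."""

    lncrna_names: list[str]
    disease_names: list[str]
    values: np.ndarray
    stage: str = "preliminary"

    def __post_init__(self) -> None:
        self.lncrna_names = list(self.lncrna_names)
        self.disease_names = list(self.disease_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lncrna_names), len(self.disease_names)):
            raise DataError(
                f"score shape {self.values.shape} does not match name lists "
                f"({len(self.lncrna_names)} x {len(self.disease_names)})"
            )
        if self.stage not in STAGES:
            raise DataError(f"unknown stage {self.stage!r}")
        if self.stage == "preliminary":
            v = self.values
            if (v < 0).any() or not np.array_equal(v, np.round(v)):
                raise DataError("preliminary scores must be non-negative integers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LatentFactorModel:
    """Fitted rank-K factorization of a score matrix."""

    X: np.ndarray  # m x K
    Y: np.ndarray  # K x e
    k_dim: int
    alpha: float
    lam: float
    max_iters: int
    tol: float
    seed: int
    loss_trace: list[float] = field(default_factory=list)
    lncrna_names: list[str] = field(default_factory=list)
    disease_names: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Serialize the model (factors + hyperparameters) as JSON."""
        payload = {
            "X": self.X.tolist(),
            "Y": self.Y.tolist(),
            "k_dim": self.k_dim,
            "alpha": self.alpha,
            "lam": self.lam,
            "max_iters": self.max_iters,
            "tol": self.tol,
            "seed": self.seed,
            "loss_trace": self.loss_trace,
            "lncrna_names": self.lncrna_names,
            "disease_names": self.disease_names,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "LatentFactorModel":
        d = json.loads(Path(path).read_text())
        d["X"] = np.asarray(d["X"], dtype=float)
        d["Y"] = np.asarray(d["Y"], dtype=float)
        return cls(**d)


def preliminary_scores(triple: AlignedTriple) -> ScoreMatrix:
    """Common-neighbour counts: A_LD = A_LM @ A_MD on the shared axis."""
    values = triple.a_lm.adjacency @ triple.a_md.adjacency
    return ScoreMatrix(triple.lncrna_names, triple.disease_names,
                       np.round(values), stage="preliminary")


def loss(X: np.ndarray, Y: np.ndarray, target: np.ndarray, lam: float) -> float:
    """Squared reconstruction error over all entries plus L2 penalties."""
    resid = target - X @ Y
    return float((resid * resid).sum() + lam * (X * X).sum() + lam * (Y * Y).sum())


def gradients(
    X: np.ndarray, Y: np.ndarray, target: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic full-batch gradients of :func:`loss` w.r.t. X and Y."""
    resid = X @ Y - target  # m x e
    g_x = 2.0 * resid @ Y.T + 2.0 * lam * X
    g_y = 2.0 * X.T @ resid + 2.0 * lam * Y
    return g_x, g_y


def fit(
    target: ScoreMatrix,
    k_dim: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
    lam: float = DEFAULT_LAMBDA,
    max_iters: int = DEFAULT_MAX_ITERS,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> LatentFactorModel:
    """Fit the rank-K factorization of ``target`` by gradient descent.

    Factors are initialized uniformly on [0, 1/sqrt(K)) from a seeded
    generator, so initial reconstructions of a non-negative count matrix
    start small and non-negative.  Training stops at ``max_iters`` or when
    the relative loss change drops below ``tol``.  A non-finite loss
    raises :class:`NumericalError` (reduce ``alpha``).
    """
    if k_dim < 1:
        raise DataError("k_dim must be >= 1")
    if alpha <= 0:
        raise DataError("alpha must be > 0")
    if lam < 0:
        raise DataError("lam must be >= 0")
    A = target.values
    m, e = A.shape
    if k_dim >= min(m, e):
        warnings.warn(
            f"k_dim={k_dim} >= min(m, e)={min(m, e)}: factorization is not "
            "low-rank",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(k_dim)
    X = rng.uniform(0.0, scale, size=(m, k_dim))
    Y = rng.uniform(0.0, scale, size=(k_dim, e))

    trace = [loss(X, Y, A, lam)]
    for it in range(max_iters):
        g_x, g_y = gradients(X, Y, A, lam)
        X = X - alpha * g_x
        Y = Y - alpha * g_y
        current = loss(X, Y, A, lam)
        if not np.isfinite(current):
            raise NumericalError(
                f"loss diverged at iteration {it + 1}; try a smaller alpha "
                f"(current alpha={alpha})"
            )
        previous = trace[-1]
        trace.append(current)
        if abs(current - previous) / max(previous, 1e-12) < tol:
            break

    return LatentFactorModel(
        X=X, Y=Y, k_dim=k_dim, alpha=alpha, lam=lam, max_iters=max_iters,
        tol=tol, seed=seed, loss_trace=trace,
        lncrna_names=list(target.lncrna_names),
        disease_names=list(target.disease_names),
    )


def reconstruct(model: LatentFactorModel) -> ScoreMatrix:
    """Dense score matrix psi = X @ Y; larger score, stronger association."""
    if model.X.shape[1] != model.Y.shape[0]:
        raise DataError("factor inner dimensions do not match")
    return ScoreMatrix(model.lncrna_names, model.disease_names,
                       model.X @ model.Y, stage="reconstructed")
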