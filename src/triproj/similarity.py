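"""Cosine and Jaccard similarity over binary association profiles.

lncRNA similarity is computed over the rows of the lncRNA--miRNA adjacency,
disease similarity over the columns of the miRNA--disease adjacency.  The
two kernels are fused into an "integrated" similarity: their average where
cosine is non-zero, Jaccard alone otherwise.  Entities with all-zero
profiles get an all-zero similarity row, diagonal included, so that they
contribute nothing to the downstream projections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DataError

KINDS = ("cosine", "jaccard", "integrated")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity axis."""

    names: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise DataError(f"similarity shape {self.values.shape} != ({n}, {n})")
        if self.kind not in KINDS:
            raise DataError(f"unknown similarity kind {self.kind!r}")


def _as_profiles(profiles: np.ndarray | Sequence[Sequence[float]]) -> np.ndarray:
    try:
        p = np.asarray(profiles, dtype=float)
    except (ValueError, TypeError) as exc:
        raise DataError("profiles must form a rectangular 2-D array (equal lengths)") from exc
    if p.ndim != 2 or p.shape[1] < 1:
        raise DataError("profiles must form a 2-D array with length >= 1 rows")
    return p


def _default_names(n: int) -> list[str]:
    return [f"e{i}" for i in range(n)]


def cosine_similarity(
    profiles: np.ndarray | Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise cosine similarity of profile vectors.

    Pairs where either vector has zero norm score 0, including the
    diagonal of all-zero profiles.
    """
    p = _as_profiles(profiles)
    norms = np.linalg.norm(p, axis=1)
    dots = p @ p.T
    denom = np.outer(norms, norms)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
    # exact 1 on the diagonal for nonzero profiles despite fp rounding
    np.fill_diagonal(values, np.where(norms > 0, 1.0, 0.0))
    values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(
        _default_names(p.shape[0]) if names is None else list(names), values, "cosine"
    )


def jaccard_similarity(
    profiles: np.ndarray | Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise Jaccard similarity of binary profile supports.

    |support_i intersect support_j| / |support_i union support_j|, with the
    0/0 case (two empty supports) defined as 0.
    """
    p = (_as_profiles(profiles) != 0).astype(float)
    inter = p @ p.T
    sizes = p.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    values = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix(
        _default_names(p.shape[0]) if names is None else list(names), values, "jaccard"
    )


def integrate_similarity(cos: SimilarityMatrix, jac: SimilarityMatrix) -> SimilarityMatrix:
    """Fuse cosine and Jaccard: (cos+jac)/2 where cos != 0, else jac.

    On binary profiles cosine and Jaccard vanish together (both are zero
    exactly for disjoint supports), so the fallback branch only ever
    returns 0 there; it is kept literal for non-binary inputs.
    """
    if cos.names != jac.names:
        raise DataError("cosine and jaccard similarity have different entity lists")
    values = np.where(cos.values != 0, (cos.values + jac.values) / 2.0, jac.values)
    return SimilarityMatrix(list(cos.names), values, "integrated")


def integrated_similarity(
    profiles: np.ndarray | Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Convenience: cosine + Jaccard + integration in one call."""
    return integrate_similarity(
        cosine_similarity(profiles, names), jaccard_similarity(profiles, names)
    )
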