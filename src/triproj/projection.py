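"""Similarity-space projection of the dense score matrix and fusion.

Each score-matrix row is projected through the lncRNA similarity space and
each column through the disease similarity space; the two projections are
then combined with weight ``omega`` and divided by the sum of the two
similarity-vector norms.

Two styles are exposed.  ``"paper"`` (the default) divides each
projection by its similarity-vector norm AND divides again in the fusion
step, exactly as the source model prints it.  ``"ncp"`` is the classic
network-consistency-projection variant that normalizes only once, in the
fusion step.  Zero-norm similarity vectors (isolated entities) always
yield score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .latent_factor import ScoreMatrix
from .similarity import SimilarityMatrix

DEFAULT_OMEGA = 0.3

PROJECTION_STYLES = ("paper", "ncp")


@dataclass
class FusionConfig:
    """Weight of the lncRNA-projection share in the fused score."""

    omega: float = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise DataError(f"omega must lie in [0, 1], got {self.omega}")


def _safe_divide(num: np.ndarray, denom: np.ndarray) -> np.ndarray:
    return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)


def lncrna_projection(
    ils: SimilarityMatrix, psi: ScoreMatrix, normalize: bool = True
) -> ScoreMatrix:
    """Project score rows through the lncRNA similarity space.

    Row i of the output is the similarity-weighted sum of all score rows
    (self term included), divided by the Euclidean norm of similarity
    row i when ``normalize`` is on.  All-zero similarity rows give
    all-zero output rows.
    """
    if ils.names != psi.lncrna_names:
        raise DataError("lncRNA similarity and score matrix name lists differ")
    weighted = ils.values @ psi.values
    if normalize:
        norms = np.linalg.norm(ils.values, axis=1)
        weighted = _safe_divide(weighted, norms[:, None])
    return ScoreMatrix(psi.lncrna_names, psi.disease_names, weighted,
                       stage="lncrna_projection")


def disease_projection(
    ids: SimilarityMatrix, psi: ScoreMatrix, normalize: bool = True
) -> ScoreMatrix:
    """Project score columns through the disease similarity space.

    Column j of the output is the similarity-weighted sum of all score
    columns, divided by the Euclidean norm of similarity column j when
    ``normalize`` is on.  Structurally this is the transpose of
    :func:`lncrna_projection` applied to the transposed scores.
    """
    if ids.names != psi.disease_names:
        raise DataError("disease similarity and score matrix name lists differ")
    weighted = psi.values @ ids.values
    if normalize:
        norms = np.linalg.norm(ids.values, axis=0)
        weighted = _safe_divide(weighted, norms[None, :])
    return ScoreMatrix(psi.lncrna_names, psi.disease_names, weighted,
                       stage="disease_projection")


def fuse(
    lp: ScoreMatrix,
    dp: ScoreMatrix,
    ils: SimilarityMatrix,
    ids: SimilarityMatrix,
    cfg: FusionConfig | None = None,
) -> ScoreMatrix:
    """Combine the two projections with weight omega.

    Entry (i, j) is (omega*LP + (1-omega)*DP) divided by the sum of the
    lncRNA similarity row-i norm and the disease similarity column-j
    norm; entries where both norms vanish are 0.
    """
    cfg = cfg or FusionConfig()
    if lp.lncrna_names != dp.lncrna_names or lp.disease_names != dp.disease_names:
        raise DataError("projection axes differ")
    if ils.names != lp.lncrna_names or ids.names != lp.disease_names:
        raise DataError("similarity axes do not match projection axes")
    row_norms = np.linalg.norm(ils.values, axis=1)
    col_norms = np.linalg.norm(ids.values, axis=0)
    denom = row_norms[:, None] + col_norms[None, :]
    num = cfg.omega * lp.values + (1.0 - cfg.omega) * dp.values
    return ScoreMatrix(lp.lncrna_names, lp.disease_names,
                       _safe_divide(num, denom), stage="final")


def project_and_fuse(
    ils: SimilarityMatrix,
    ids: SimilarityMatrix,
    psi: ScoreMatrix,
    cfg: FusionConfig | None = None,
    style: str = "paper",
) -> ScoreMatrix:
    """Run both projections and the fusion in the requested style."""
    if style not in PROJECTION_STYLES:
        raise DataError(f"unknown projection style {style!r}")
    normalize = style == "paper"
    lp = lncrna_projection(ils, psi, normalize=normalize)
    dp = disease_projection(ids, psi, normalize=normalize)
    return fuse(lp, dp, ils, ids, cfg)
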