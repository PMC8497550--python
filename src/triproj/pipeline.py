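"""End-to-end orchestration: files in, fused score matrix and report out.

The heavy lifting lives in the stage modules; this module wires them
together, resolves configuration (CLI flags > config file > defaults),
and writes reproducible run artifacts (all intermediate matrices, a
ranked pair list, and a manifest with every resolved parameter and input
checksum).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import data_io, latent_factor, projection, similarity
from .data_io import AlignedTriple, BipartiteNetwork
from .evaluation import EvaluationResult, kfold_auc, loocv_auc
from .exceptions import DataError
from .latent_factor import ScoreMatrix

logger = logging.getLogger("triproj")

DEFAULT_OMEGA_GRID = [round(0.1 * i, 1) for i in range(11)]


@dataclass
class PipelineConfig:
    """Resolved parameters of one prediction run."""

    lm_path: str
    md_path: str
    labels_path: str | None = None
    k_dim: int = latent_factor.DEFAULT_K
    alpha: float = latent_factor.DEFAULT_ALPHA
    lam: float = latent_factor.DEFAULT_LAMBDA
    max_iters: int = latent_factor.DEFAULT_MAX_ITERS
    tol: float = latent_factor.DEFAULT_TOL
    seed: int = 0
    omega: float = projection.DEFAULT_OMEGA
    projection_style: str = "paper"
    align_mode: str = "intersection"
    normalize_ids: bool = False
    out_dir: str = "triproj_out"

    @classmethod
    def resolve(cls, config_file: str | Path | None = None, **overrides) -> "PipelineConfig":
        """Merge defaults, a YAML/JSON config file, and explicit overrides."""
        values: dict = {}
        if config_file is not None:
            import yaml

            loaded = yaml.safe_load(Path(config_file).read_text()) or {}
            if not isinstance(loaded, dict):
                raise DataError(f"config file {config_file} must hold a mapping")
            unknown = set(loaded) - set(cls.__dataclass_fields__)
            if unknown:
                raise DataError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


@dataclass
class PipelineResult:
    """All intermediate and final matrices of one run."""

    triple: AlignedTriple
    ils: similarity.SimilarityMatrix
    ids: similarity.SimilarityMatrix
    a_ld: ScoreMatrix
    model: latent_factor.LatentFactorModel
    psi: ScoreMatrix
    lp: ScoreMatrix
    dp: ScoreMatrix
    final: ScoreMatrix


def load_triple(cfg: PipelineConfig) -> AlignedTriple:
    lm_pairs = data_io.read_edge_list(cfg.lm_path, normalize=cfg.normalize_ids,
                                      kinds=("rna", "rna"))
    md_pairs = data_io.read_edge_list(cfg.md_path, normalize=cfg.normalize_ids,
                                      kinds=("rna", "disease"))
    lm = data_io.build_network(lm_pairs)
    md = data_io.build_network(md_pairs)
    return data_io.align_on_mirna(lm, md, mode=cfg.align_mode)


def predict_from_triple(triple: AlignedTriple, cfg: PipelineConfig) -> PipelineResult:
    """Run similarity -> latent factor -> projection on aligned networks."""
    t0 = time.perf_counter()
    ils = similarity.integrated_similarity(triple.a_lm.adjacency, triple.lncrna_names)
    ids = similarity.integrated_similarity(triple.a_md.adjacency.T, triple.disease_names)
    logger.info("similarities: ILS %s, IDS %s (%.2fs)", ils.values.shape,
                ids.values.shape, time.perf_counter() - t0)

    a_ld = latent_factor.preliminary_scores(triple)
    t0 = time.perf_counter()
    model = latent_factor.fit(
        a_ld, k_dim=cfg.k_dim, alpha=cfg.alpha, lam=cfg.lam,
        max_iters=cfg.max_iters, tol=cfg.tol, seed=cfg.seed,
    )
    logger.info("latent factor fit: %d iterations, final loss %.6g (%.2fs)",
                len(model.loss_trace) - 1, model.loss_trace[-1],
                time.perf_counter() - t0)
    logger.debug("loss trace: %s", model.loss_trace)
    psi = latent_factor.reconstruct(model)

    normalize = cfg.projection_style == "paper"
    if cfg.projection_style not in projection.PROJECTION_STYLES:
        raise DataError(f"unknown projection style {cfg.projection_style!r}")
    lp = projection.lncrna_projection(ils, psi, normalize=normalize)
    dp = projection.disease_projection(ids, psi, normalize=normalize)
    final = projection.fuse(lp, dp, ils, ids, projection.FusionConfig(cfg.omega))
    return PipelineResult(triple, ils, ids, a_ld, model, psi, lp, dp, final)


def load_labels(path: str | Path, normalize: bool = False) -> BipartiteNetwork:
    pairs = data_io.read_edge_list(path, normalize=normalize, kinds=("rna", "disease"))
    return data_io.build_network(pairs)


def evaluate_scores(
    scores: ScoreMatrix,
    labels: BipartiteNetwork,
    mode: str = "loocv",
    k: int = 5,
    seed: int = 0,
) -> EvaluationResult:
    if mode == "loocv":
        return loocv_auc(scores, labels)
    if mode == "kfold":
        return kfold_auc(scores, labels, k=k, seed=seed)
    raise DataError(f"unknown evaluation mode {mode!r}")


def sweep_omega(
    result: PipelineResult,
    labels: BipartiteNetwork,
    grid: Sequence[float] | None = None,
) -> list[tuple[float, float]]:
    """AUC at each omega on a shared psi/LP/DP computation."""
    if grid is None:
        grid = DEFAULT_OMEGA_GRID
    grid = list(grid)
    if not grid:
        raise DataError("empty omega grid")
    table = []
    for omega in grid:
        fused = projection.fuse(result.lp, result.dp, result.ils, result.ids,
                                projection.FusionConfig(omega))
        table.append((float(omega), loocv_auc(fused, labels).auc))
    return table


def _ranked_pairs(scores: ScoreMatrix) -> list[tuple[str, str, float]]:
    m, e = scores.shape
    order = np.argsort(-scores.values, axis=None, kind="stable")
    out = []
    for flat in order:
        i, j = divmod(int(flat), e)
        out.append((scores.lncrna_names[i], scores.disease_names[j],
                    float(scores.values[i, j])))
    return out


def write_outputs(result: PipelineResult, cfg: PipelineConfig) -> dict[str, Path]:
    """Write all matrices, the ranked pair list, and the run manifest.

    On any failure every file created by this run is removed so no
    partial output survives.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _matrix(name: str, sm: ScoreMatrix) -> None:
        path = out_dir / f"{name}.tsv"
        data_io.write_matrix(sm.lncrna_names, sm.disease_names, sm.values, path)
        written.append(path)

    try:
        _matrix("a_ld", result.a_ld)
        _matrix("psi", result.psi)
        _matrix("lp", result.lp)
        _matrix("dp", result.dp)
        _matrix("lfmp", result.final)

        ranked_path = out_dir / "ranked_pairs.tsv"
        lines = ["lncRNA\tdisease\tscore"]
        lines += [f"{l}\t{d}\t{s:.10g}" for l, d, s in _ranked_pairs(result.final)]
        ranked_path.write_text("\n".join(lines) + "\n")
        written.append(ranked_path)

        model_path = out_dir / "model.json"
        result.model.save(model_path)
        written.append(model_path)

        manifest = {
            "config": asdict(cfg),
            "inputs": {
                "lm": {"path": cfg.lm_path, "sha256": data_io.file_sha256(cfg.lm_path)},
                "md": {"path": cfg.md_path, "sha256": data_io.file_sha256(cfg.md_path)},
            },
            "shapes": {
                "a_lm": list(result.triple.a_lm.shape),
                "a_md": list(result.triple.a_md.shape),
                "scores": list(result.final.shape),
            },
            "n_iterations": len(result.model.loss_trace) - 1,
            "final_loss": result.model.loss_trace[-1],
        }
        if cfg.labels_path:
            manifest["inputs"]["labels"] = {
                "path": cfg.labels_path,
                "sha256": data_io.file_sha256(cfg.labels_path),
            }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    return {p.stem: p for p in written}


def run_predict(cfg: PipelineConfig) -> tuple[PipelineResult, dict[str, Path]]:
    """File-to-file prediction run."""
    triple = load_triple(cfg)
    result = predict_from_triple(triple, cfg)
    paths = write_outputs(result, cfg)
    return result, paths
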