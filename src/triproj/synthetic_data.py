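"""Planted-module tripartite network generator.

Produces lncRNA-miRNA and miRNA-disease layers with block structure:
entities are assigned to modules uniformly at random and edges are drawn
with probability ``p_in`` inside a module and ``p_out`` across modules.
Ground-truth lncRNA-disease positives are planted among same-module pairs
with probability ``q`` — the same shared-miRNA-neighbourhood mechanism the
predictor exploits, so recovery measures the method rather than the
generator.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data_io import AlignedTriple, BipartiteNetwork, write_edge_list
from .exceptions import DataError


@dataclass
class SyntheticConfig:
    m: int = 60  # lncRNAs
    n: int = 30  # miRNAs
    e: int = 40  # diseases
    g: int = 3  # planted modules
    p_in: float = 0.6
    p_out: float = 0.05
    q: float = 0.5  # planted-positive probability for same-module pairs
    seed: int = 0

    def __post_init__(self) -> None:
        for prob in (self.p_in, self.p_out, self.q):
            if not 0.0 <= prob <= 1.0:
                raise DataError("probabilities must lie in [0, 1]")
        # p_out == p_in is allowed as the explicit null (no-signal) model
        if self.p_out > self.p_in:
            raise DataError("p_out must be <= p_in")
        if self.g < 1:
            raise DataError("g must be >= 1")
        if min(self.m, self.n, self.e) < self.g:
            raise DataError("entity counts must be >= g")


def _edge_probs(mod_a: np.ndarray, mod_b: np.ndarray, p_in: float, p_out: float) -> np.ndarray:
    same = mod_a[:, None] == mod_b[None, :]
    return np.where(same, p_in, p_out)


def generate(cfg: SyntheticConfig) -> tuple[AlignedTriple, BipartiteNetwork]:
    """Draw one tripartite network plus its planted truth set.

    Returns the aligned lncRNA-miRNA / miRNA-disease layers and a
    lncRNA x disease network of planted positives over the full axes.
    """
    rng = np.random.default_rng(cfg.seed)
    lnc = [f"L{i:04d}" for i in range(cfg.m)]
    mir = [f"M{i:04d}" for i in range(cfg.n)]
    dis = [f"D{i:04d}" for i in range(cfg.e)]

    mod_l = rng.integers(cfg.g, size=cfg.m)
    mod_m = rng.integers(cfg.g, size=cfg.n)
    mod_d = rng.integers(cfg.g, size=cfg.e)

    a_lm = (rng.random((cfg.m, cfg.n))
            < _edge_probs(mod_l, mod_m, cfg.p_in, cfg.p_out)).astype(float)
    a_md = (rng.random((cfg.n, cfg.e))
            < _edge_probs(mod_m, mod_d, cfg.p_in, cfg.p_out)).astype(float)

    same_module = mod_l[:, None] == mod_d[None, :]
    truth = (same_module & (rng.random((cfg.m, cfg.e)) < cfg.q)).astype(float)

    triple = AlignedTriple(
        BipartiteNetwork(lnc, mir, a_lm),
        BipartiteNetwork(mir, dis, a_md),
    )
    return triple, BipartiteNetwork(lnc, dis, truth)


def write_fixture(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the generated network as edge-list files plus the config.

    Emits the same 2-column tab-separated format the parser reads:
    ``lncrna_mirna.tsv``, ``mirna_disease.tsv``, ``lncrna_disease_truth.tsv``
    and ``synthetic_config.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    triple, truth = generate(cfg)
    paths = {
        "lncrna_mirna": out_dir / "lncrna_mirna.tsv",
        "mirna_disease": out_dir / "mirna_disease.tsv",
        "truth": out_dir / "lncrna_disease_truth.tsv",
        "config": out_dir / "synthetic_config.json",
    }
    write_edge_list(triple.a_lm, paths["lncrna_mirna"])
    write_edge_list(triple.a_md, paths["mirna_disease"])
    write_edge_list(truth, paths["truth"])
    paths["config"].write_text(json.dumps(asdict(cfg), indent=2))
    return paths
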