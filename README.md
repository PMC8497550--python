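# triproj

Link prediction on tripartite lncRNA–miRNA–disease networks, with no
lncRNA–disease training pairs.  Given a lncRNA–miRNA association edge list
and a miRNA–disease association edge list, triproj:

1. builds binary adjacency matrices and aligns them on a shared miRNA axis;
2. computes cosine + Jaccard similarity over association profiles and fuses
   them into integrated lncRNA and disease similarity matrices;
3. forms a preliminary score matrix by common-neighbour counting
   (`A_LM @ A_MD`) and densifies it with a rank-K latent-factor model
   trained by full-batch gradient descent (defaults: learning rate 2e-4,
   L2 weight 4e-3);
4. projects the dense scores through both similarity spaces and fuses the
   two projections with weight `omega` (default 0.3);
5. evaluates rankings against held-out labels (LOOCV / k-fold AUC, AUPR,
   per-disease candidate tables).  Labels are used *only* for evaluation,
   never as model input.

A planted-module synthetic generator makes the whole pipeline testable
offline: entities are grouped into modules, edges are dense within modules
and sparse across them, and ground-truth lncRNA–disease positives are
planted among same-module pairs.

## CLI

```sh
# generate a synthetic fixture (three edge lists + config)
triproj simulate --out-dir fixture/ --m 60 --n 30 --e 40 --g 3 --seed 1

# run the full pipeline; writes a_ld/psi/lp/dp/lfmp matrices,
# ranked_pairs.tsv, model.json and a manifest with checksums
triproj predict --lm fixture/lncrna_mirna.tsv --md fixture/mirna_disease.tsv \
    --out-dir run/ --k-dim 50 --omega 0.3

# evaluate a score matrix against held-out labels
triproj evaluate --scores run/lfmp.tsv --labels fixture/lncrna_disease_truth.tsv \
    --mode loocv --out report.json --plot curves.png

# AUC as a function of the fusion weight (default grid 0.0..1.0 step 0.1)
triproj sweep-omega --lm fixture/lncrna_mirna.tsv --md fixture/mirna_disease.tsv \
    --labels fixture/lncrna_disease_truth.tsv --out sweep.tsv
```

Options may also come from a YAML config file (`--config`); explicit flags
win over the file, which wins over defaults.  Exit codes: 2 usage error,
3 data/parse error, 4 numerical error.

Two projection styles are available: `--projection-style paper` (default)
divides each projection by its similarity-vector norm and divides again by
the norm sum during fusion; `ncp` is the classic single-normalization
network-consistency-projection variant.

## Library use

```python
from triproj import (PipelineConfig, SyntheticConfig, generate,
                     predict_from_triple, loocv_auc, preliminary_scores)

triple, truth = generate(SyntheticConfig(seed=0))
cfg = PipelineConfig(lm_path="-", md_path="-", k_dim=20, max_iters=2000)
result = predict_from_triple(triple, cfg)
print(loocv_auc(result.final, truth).auc)
```
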