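# commassembly

Tools for asking — and quantitatively answering — a central question of
microbial community ecology: **do metabolically similar environments select
for similar microbial communities?**

When enrichment communities are serially passaged in minimal media on a
single carbon source, the final composition is shaped by selection on
metabolic traits: growth rate on the supplied substrate and the secretion
and cross-feeding of metabolic by-products. This package implements a
complete analysis pipeline around a flux-based measure of environment
similarity:

1. **Metabolic similarity.** Each carbon source is imposed on a
   constraint-based metabolic model as an uptake bound of −1 cmol/gDW/h
   (equal carbon supply across substrates). Growth is optimized by
   parsimonious flux balance analysis (pFBA), and the similarity of two
   substrates is the Pearson correlation of their intracellular flux
   vectors (transporters, exchanges, biomass and maintenance excluded):
   `s(α, β) = corr(v_int(α), v_int(β))`.
2. **Growth traits.** Average growth rates are estimated from OD620 curves
   as `r = ln(N2/N1)/(t2 − t1)`, where `t2` is the time of maximum
   derivative of the smoothed log-OD curve (minimum 5 h) and `(t1, N1)` is
   the third reading (the first two are discarded as bubble artifacts).
   Four alternative metrics (fixed 16 h endpoint, maximum rate, logistic
   fit, area under the curve) are provided, plus strain × substrate trait
   matrices, clade contrasts (fermenter E+ vs respirator P+ families) and
   per-strain similarity trends.
3. **By-product profiles.** Untargeted metabolomics peak tables are
   filtered against no-carbon controls (any control signal above 5% of a
   metabolite's maximum removes it), gated on growth (OD > 0.04 in every
   replicate), replicate-averaged, z-scored across carbon sources, and
   compared between substrates by Pearson correlation.
4. **Community similarity.** Amplicon count tables are rarefied, aggregated
   to the ESV / Genus / Family / Clade level, and compared by Renkonen
   similarity `S(X, Y) = Σ_i min(X_i, Y_i)` (equivalently 1 − Bray-Curtis).
   Matrix relationships are tested with a seeded Mantel permutation test
   (9999 permutations, add-one p-values), and compositional variance is
   partitioned between inoculum and carbon source by redundancy-analysis
   adjusted R².
5. **Nearest-template prediction.** Community composition on a new target
   substrate is predicted to be the composition observed on the most
   metabolically similar *non-identical* template substrate, evaluated by
   leave-one-carbon-source-out cross-validation against an exhaustive
   random-template null, with a one-tailed Mann-Whitney comparison. The
   same machinery extends to 2–3-substrate mixtures (components excluded
   as templates).

A synthetic-data module generates all four input classes (toy metabolic
models, growth curves, peak tables, community tables) with the planted
statistical structure the analysis assumes, so the full pipeline is
testable end to end without any experimental data.

## Worked example

```python
import numpy as np
from commassembly import (
    GeneratorConfig, make_toy_model, metabolic_similarity,
    simulate_communities, rarefy, library_from_table,
    loco_predict, null_performance, compare_to_null,
    similarity_vs_metabolic,
)
from commassembly.community import per_inoculum_renkonen

model, envs = make_toy_model("branched", k=20, seed=11)
sim = metabolic_similarity(model, envs)          # 20 x 20 Pearson matrix

ct, tax, _ = simulate_communities(GeneratorConfig(seed=1), model, envs)
rare = rarefy(ct, seed=1)                        # 2733 reads per sample
comm = per_inoculum_renkonen(rare, "inoc1")      # Renkonen matrix
print(similarity_vs_metabolic(comm, sim.labels, sim.values, seed=1))
# {'pearson_r': 0.8338164254185743, 'mantel_p': 0.0001, 'n_substrates': 20}

lib = library_from_table(rare, "inoc1")
results = loco_predict(lib, lib, sim)
print(compare_to_null(results, null_performance(lib, lib)))
# {'median_pred': 0.9403585803146726, 'median_null': 0.7061836809366996,
#  'U': 7090.0, 'p': 3.343516443277041e-11, 'n_pred': 20, 'n_null': 380}
```

Communities assembled on metabolically similar substrates are measurably
more similar (Mantel r = 0.83, p = 1e-4 — the add-one floor at 9999
permutations), and nearest-template predictions (median Renkonen 0.94)
clearly beat the exhaustive random-template null (median 0.71).

A command-line layer mirrors the library:

```bash
commassembly simulate --what model --seed 3 --outdir sim/
commassembly similarity --model sim/model.json --envs sim/envs.yaml --out sim.csv
commassembly community --counts counts.tsv --tax taxonomy.tsv \
    --meta counts_meta.tsv --level Family --seed 1 --out renkonen.csv
```

## Layout

- `src/commassembly/model.py` — metabolic models, reaction classes, environments
- `src/commassembly/flux.py` — FBA/pFBA and the metabolic-similarity matrix
- `src/commassembly/growth.py` — growth-rate estimation and trait analyses
- `src/commassembly/secretions.py` — metabolomics filtering and by-product profiles
- `src/commassembly/community.py` — rarefaction, taxonomy, Renkonen, variance partition
- `src/commassembly/stats.py` — Mantel, Mann-Whitney, correlations
- `src/commassembly/predict.py` — nearest-template prediction and nulls
- `src/commassembly/synth.py` — synthetic-data generators
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
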