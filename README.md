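# lakemicro

Statistical analysis of microbial communities in multi-lake amplicon
surveys: diversity, environmental drivers, community-assembly processes
and co-occurrence networks, with a synthetic-data generator that
provides ground truth for every stage.

## The scientific problem

High-altitude lake surveys produce OTU tables (samples × taxa counts), a
phylogeny of the OTUs and per-sample water chemistry. The questions a
microbial ecologist asks of such data are:

1. **Diversity** — how rich and even are the communities
   (Shannon H′ = −Σ pᵢ ln pᵢ, Gini–Simpson 1 − Σ pᵢ², Chao1
   S_obs + F₁²/2F₂, Faith's PD, Pielou J′), and how do they turn over
   between lakes (Bray–Curtis, PCoA, ANOSIM)?
2. **Drivers** — which environmental factors shape composition?
   (VIF < 10 screening, redundancy analysis on Hellinger-transformed
   counts with permutation-tested factors, PCNM spatial eigenfunctions,
   and variation partitioning into pure water / pure spatial / shared /
   residual adjusted-R² fractions.)
3. **Assembly processes** — how much of the turnover is deterministic
   versus stochastic? The Sloan neutral model predicts a taxon's
   occurrence frequency from its mean relative abundance p as the upper
   tail above the detection limit d = 1/N_T of Beta(N_T·m·p,
   N_T·m·(1−p)), where m is the immigration rate. The phylogenetic null
   model standardizes the between-community mean nearest taxon distance
   (βMNTD) against taxon-label shuffles: βNTI < −2 flags homogeneous
   selection, βNTI > 2 heterogeneous selection. Within |βNTI| ≤ 2, the
   abundance-based Raup–Crick index classifies RC_bray > 0.95 as
   dispersal limitation, RC_bray < −0.95 as homogeneous dispersal, and
   the rest as undominated.
4. **Networks** — which taxa co-occur? Edges are Spearman |ρ| > 0.8
   with Benjamini–Hochberg adjusted p < 0.01; topology (degree, density,
   clustering, path lengths, modularity) is compared against 1000
   Erdős–Rényi G(n, M) graphs of equal size.

Because every stage rests on null models and estimators, the package
ships a first-class generator (`lakemicro.simulate`) that produces OTU
tables, trees and metadata under controlled regimes — neutral drift,
homogeneous/heterogeneous selection, dispersal limitation — so each
estimator can be validated against known truth.

## Worked example

```python
import numpy as np
from lakemicro import (SimulationConfig, simulate_metacommunity,
                       beta_nti, raup_crick_bray, classify_processes)
from lakemicro.simulate import REGIME_STUDY_OVERRIDES

cfg = SimulationConfig(n_groups=4, samples_per_group=3,
                       regime="homogeneous_selection", seed=1,
                       **REGIME_STUDY_OVERRIDES["homogeneous_selection"])
cm, tree, env, truth = simulate_metacommunity(cfg)

bnti = beta_nti(cm, tree, n_null=199, seed=0)
rc = raup_crick_bray(cm, n_null=199, seed=0)
print(classify_processes(bnti, rc).fractions.round(1))
```

prints

```
heterogeneous_selection     0.0
homogeneous_selection      75.8
dispersal_limitation        0.0
homogeneous_dispersal       0.0
undominated                24.2
```

i.e. 75.8% of the sample pairs are classified as homogeneous selection —
the modal process matches the regime the survey was generated under.
The `examples/` directory holds one short script per capability
(simulation, diversity, drivers, neutral fit, assembly partition,
networks); each prints the numbers it computes and a line on what they
mean. A thin CLI mirrors the stages:

```bash
lakemicro --seed 1 --out-dir survey simulate --regime neutral
lakemicro --seed 1 --out-dir out all --community survey/otu_table.tsv \
    --env survey/metadata.tsv --tree survey/tree.nwk
```

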