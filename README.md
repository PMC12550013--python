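# jipclust

Baseline phenotyping of early rheumatoid arthritis (RA) cohorts from
mixed-type clinical data. The package stratifies patients at first
presentation — before treatment interferes — into **joint involvement
pattern (JIP)** phenotypes, and validates those phenotypes against
treatment response, remission and synovial histology.

It is written for biostatisticians and rheumatology researchers who want a
tested, end-to-end reference implementation of this analysis style:

1. **Cohort model** — a 44-joint atlas (DAS44 scheme, feet included),
   patient tables with serology (RF/ACPA), blood labs, ESR and per-joint
   tender/swollen flags; CSV I/O, complete-case filtering, and the
   3-component disease activity scores
   `DAS28(3) = 1.08(0.56√TJC28 + 0.28√SJC28 + 0.70 ln ESR) + 0.16` and
   `DAS44(3) = 0.54√RAI + 0.065·SJC44 + 0.33 ln ESR + 0.22`
   (remission: DAS44 < 1.6).
2. **Synthetic cohorts** — a generator planting four phenotypes
   (JIP-foot, JIP-oligo, JIP-hand, JIP-poly) with published-table
   marginals, region-structured joint involvement with left-right
   symmetry coupling, exponential outcome clocks, and proportional-odds
   Krenn synovitis grades. Since real registries of this kind cannot be
   shared, the generator provides ground truth for every downstream claim.
3. **Embedding** — Yeo-Johnson / log / one-hot feature encoding with
   frozen parameters, then a multimodal autoencoder (128→64→8, Bernoulli
   loss for binary features, Gaussian loss for numeric ones, Adam, early
   stopping) implemented in numpy.
4. **Clustering** — PhenoGraph-style kNN-Jaccard graph + Louvain
   (implemented here, cross-checked against exhaustive modularity search),
   bootstrap co-clustering stability, frozen-model projection of external
   cohorts, and LISI diagnostics for physician mixing.
5. **Interpretation & outcome statistics** — gradient-boosted surrogate
   with Monte-Carlo permutation Shapley attributions, Table-1-style
   cluster profiles, joint-prevalence matrices; Kaplan-Meier/log-rank/Cox
   (Efron ties, Schoenfeld checks, nested-model LRTs), LOCF remission,
   chi-square, Kruskal-Wallis + Dunn, and proportional-odds ordinal
   regression with Wald contrasts.

## Worked example

```python
import numpy as np
from jipclust import default_calibration, generate_cohort, generate_outcomes
from jipclust.cluster import JIPClusterPipeline
from jipclust.graph import adjusted_rand_index
from jipclust.interpret import cluster_profile

cfg = default_calibration()                       # published-table marginals
lab = generate_cohort(cfg, seed=1, n_patients=1387)

pipe = JIPClusterPipeline(random_state=1).fit(lab.cohort)
print("communities:", pipe.partition_.n_communities)
print("sizes:", np.bincount(pipe.labels_))
print("ARI vs planted phenotypes:",
      round(adjusted_rand_index(pipe.labels_,
                                lab.cohort.df["true_label"]), 3))

rep = pipe.stability(iterations=200, subsample_fraction=0.8, seed=11)
print("mean per-patient stability:", round(rep.mean_stability, 3))

new = generate_cohort(cfg, seed=77, n_patients=1000)   # replication cohort
labels = pipe.predict(new.cohort)                      # frozen projection
print("replication ARI:",
      round(adjusted_rand_index(labels,
                                new.cohort.df["true_label"]), 3))
```

Output:

```
communities: 4
sizes: [260 264 504 359]
ARI vs planted phenotypes: 0.918
mean per-patient stability: 0.99
replication ARI: 0.861
```

Four communities emerge whose sizes track the planted mixing
(596:761:450:402 scaled to n=1387); the adjusted Rand index of 0.92 means
the graph communities essentially coincide with the planted phenotypes;
stability of 0.99 says patients nearly always stay with their cluster
across resampled re-clustering runs; and a fresh cohort projected through
the frozen transforms and encoder recovers its own planted labels with
ARI 0.86 — the replication path uses no statistic of the new data.

`cluster_profile(lab.cohort, pipe.labels_)` then prints the per-cluster
baseline table (n, % female, age, RF/ACPA %, ESR/SJC/TJC/DAS medians) in
the conventional format, and `joint_prevalence` exports the per-joint
involvement fractions behind mannequin-style heatmaps.

## Layout

```
src/jipclust/
  atlas.py        44-joint atlas and regions
  cohort.py       patient tables, CSV I/O, joint counts, DAS scores
  simulate.py     synthetic phenotype generator (+ outcomes, synovium)
  preprocess.py   Yeo-Johnson / log / one-hot encoding, frozen params
  autoencoder.py  multimodal autoencoder (numpy, Adam, early stopping)
  graph.py        kNN-Jaccard graph, modularity, Louvain, ARI
  cluster.py      pipeline estimator, stability, projection, LISI
  interpret.py    surrogate, Shapley attributions, profiles, prevalence
  outcomes.py     KM/log-rank/Cox/Schoenfeld, LOCF, chi2, Kruskal-Dunn,
                  proportional-odds ordinal fits
docs/methods.md   model assumptions, calibration, numerical choices
```
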