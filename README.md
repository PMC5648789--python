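# scpls

Removing hidden confounding effects from single-cell (and bulk)
expression data by jointly modeling **control genes** and **target
genes**.

## The problem

scRNA-seq measurements are shaped by hidden technical factors
(amplification efficiency, capture rate, batch) and by nuisance
biological processes such as the cell cycle. Left in the data, these
confounders distort clustering, differential expression and most other
downstream analyses. Many studies carry a natural *control set* —
ERCC spike-ins, which contain technical variation only, or annotated
cell-cycle genes — that is known *a priori* to be free of the
biological signal of interest. Methods that infer confounders from the
control set alone ignore the fact that the same confounders also act
on the thousands of target genes; methods that pool all genes risk
removing the biology along with the noise.

`scpls` implements a partial-least-squares-style latent factor model
that does both at once. For cell *i* with control expression
**x**<sub>i</sub> (length *q*) and target expression **y**<sub>i</sub>
(length *p*), both log-transformed and per-gene centered:

```
x_i = Λ_x z_i + ε_xi,          ε_xi ~ MVN(0, Ψ_x)
y_i = Λ_y z_i + Λ_u u_i + ε_yi, ε_yi ~ MVN(0, Ψ_y)
```

* **z**<sub>i</sub> (dimension *k<sub>z</sub>*): confounding factors
  shared by both gene sets;
* **u**<sub>i</sub> (dimension *k<sub>u</sub>*): structured biological
  factors acting on the targets only — they shield real signal
  (cell subpopulations, pathways, treatment effects) from being
  mistaken for confounding;
* Ψ<sub>x</sub>, Ψ<sub>y</sub>: diagonal residual variances; the
  factors have standard-normal priors.

The model is fitted by EM (an exact algorithm, plus a chunked E-step
variant that partitions the target genes and averages posterior
moments across chunks for speed), *k<sub>z</sub>* and *k<sub>u</sub>*
can be chosen by BIC, and the cleaned expression is the residual
**y**<sub>i</sub> − Λ̂<sub>y</sub> ẑ<sub>i</sub> — confounding removed,
biology retained.

## Worked example

Simulate two cell groups whose signature is carried by differentially
expressed target genes, obscured by two shared confounding factors,
then recover the groups after correction:

```python
import numpy as np
from scpls import SimConfig, ScPLS, simulate_dataset, cluster_and_score

config = SimConfig(n_cells=200, q_controls=50, p_targets=1000,
                   pde=0.3, loading_mode="target_pve", seed=4)
truth, pair = simulate_dataset(config)

model = ScPLS(pair)
result = model.fit(kz=2, ku=5, method="chunks", chunk_size=500, seed=4)
print(result.summary())

before = cluster_and_score(pair.Y, truth.labels, seed=4)
after = cluster_and_score(result.corrected_Y, truth.labels, seed=4)
print(f"mean ARI before correction: {before.ari_mean:.3f}")
print(f"mean ARI after correction:  {after.ari_mean:.3f}")
```

prints

```
scPLS fit results
==============================================
cells                 200
control genes (q)     50
target genes (p)      759
confounding factors   kz = 2
biological factors    ku = 5
log-likelihood        -226537.4099
BIC                   486040.9504
EM iterations         178
median PVE confounding  0.121
median PVE biological   0.260
==============================================
mean ARI before correction: 0.007
mean ARI after correction:  1.000
```

Before correction, k-means cannot find the two groups (adjusted Rand
index ≈ 0 against the true labels); after removing the estimated
confounding component it recovers them perfectly. The PVE lines are
the median per-gene share of expression variance attributed to the
confounding and biological components.

The same pipeline is available from the shell:

```sh
scpls simulate --pde 0.3 --seed 4 --out sim/
scpls fit sim/counts.tsv --controls sim/controls.txt --kz 2 --ku 5 --out fit/
scpls evaluate fit/corrected.tsv --labels sim/cells.tsv
```

`scpls fit --select` chooses *k<sub>z</sub>* ∈ {1..3} and
*k<sub>u</sub>* ∈ {1..10} by BIC; `scpls filter` applies the
low-expression filter (a target gene needs ≥ 5 counts, a control ≥ 1
count, in more than a third of cells).

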