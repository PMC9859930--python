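# entropysort

Unsupervised cleanup and feature selection for single-cell RNA-seq (and
other binarizable high-dimensional data) built on **entropy sorting**: a
correlation metric and hypothesis test defined over pairs of binary
features, plus the two algorithms that consume it —

* **FFAVES** flags data points in a discrete cells × genes matrix that
  are statistically likely to display the wrong state (false-negative
  dropouts and threshold artifacts, false-positive leaky expression),
  by accumulating divergence evidence across all gene pairs over
  repeated correction cycles.
* **ESFW** assigns every gene an importance weight measuring how
  strongly it is embedded in a set of mutually dependent features, and
  turns the weights into a ranked gene list for unsupervised feature
  selection — an alternative to variance-based highly-variable-gene
  pickers that needs no clustering, no normalization and no
  significance threshold.

The package also ships a synthetic scRNA-seq benchmark generator with
exhaustive per-coordinate ground truth (cell-type blocks, multimodal
genes, doublets, dropout, sub-optimal discretization thresholds, leaky
expression, batch effects), which is how the algorithms are validated.

## The mathematics in brief

Binarize expression and re-encode each gene by its *minority state*
(whichever of active/inactive is rarer). For an ordered pair — a
reference feature RF partitioning the N cells into its minority group
G1 and majority group G2, and a query feature QF with QFm minority
states — the conditional entropy of QF given RF is a smooth function of
a single variable, the overlap count x = |RF-minority ∩ QF-minority|:

    CE(x) = (G1/N) · H2(x/G1) + (G2/N) · H2((QFm − x)/G2)

with H2 the binary entropy (base 2). CE is concave with its maximum at
the independence point x_max = G1·QFm/N and minima at the feasible
boundaries x_lo = max(0, QFm − G2), x_hi = min(G1, QFm). On this curve:

* **SD** = sign(x − x_max): sort direction (enrichment vs depletion);
* **SW** = (MaxEnt − MinEnt)/MaxEnt: entropy removable at the
  SD-relevant minimum, as a fraction of the maximum;
* **SG** = (MaxEnt − ObsEnt)/(MaxEnt − MinEnt): fraction of that
  removable entropy actually removed by the observed arrangement;
* **ESS** = SD·SW·SG ∈ [−1, 1]: the entropy sort score, a
  correlation-like measure;
* **divergence** = ObsEnt − MinEnt: how far the observation sits above
  the optimal-dependence minimum; each *divergent cell* (RF-minority
  cell showing the "wrong" QF state) carries divergence/n_divergent =
  **DPC_dependent**, compared against **DPC_independent** =
  MaxEnt/(x_boundary − x_max), the per-cell divergence expected if the
  overlap were chance;
* **EP** = DPC_dependent − DPC_independent: the error potential.
  EP > 0 favours "dependent features plus error", EP < 0 favours
  independence — with no user-set significance threshold.

## Worked example

`examples/02_ffaves_error_detection.py` plants five dropouts in a
3-gene perfectly co-expressed block over 200 cells and runs FFAVES:

```
planted 5 dropouts; FFAVES flagged 5 FN and 0 FP in 2 cycle(s)
  FN at cell c0, gene a
  FN at cell c1, gene a
  FN at cell c2, gene b
  FN at cell c3, gene b
  FN at cell c4, gene c
corrected matrix equals the clean block: True
```

Every planted coordinate — and nothing else — is recovered: each
dropout makes its gene's pairs divergent, the EP test certifies those
pairs as dependent-with-error, and the divergent cells collect votes
from a majority of their gene's partners.

`examples/03_benchmark_pipeline.py` runs a reduced benchmark end to end
(300 cells × 186 genes) and scores the output against the generator's
annotations:

```
FFAVES converged in 7 cycles
  FN            precision=0.931 recall=0.738 (tp=2266, fp=167, fn=803)
  FP            precision=0.487 recall=0.488 (tp=233, fp=245, fn=244)
  threshold_FN  precision=1.000 recall=0.764 (tp=162, fp=0, fn=50)
ESFW ranking keeps precision >= 0.95 up to recall 0.976
top-126 selected genes that are truly structured: 97.6%
```

The FN channel is precise and sensitive; the FP channel is deliberately
conservative (flipping an observed active state destroys evidence); and
the post-correction ESFW ranking separates structured from randomly
expressed genes almost perfectly.

## Command line

A thin CLI mirrors the library: `entropysort synth | discretize |
es-scores | ffaves | esfw | pipeline | evaluate`. For instance:

```
entropysort synth --seed 1 --out-dir bench/
entropysort ffaves --discrete-matrix bench/corrupted_discrete.csv --out-mask mask.csv
entropysort esfw --discrete-matrix bench/corrupted_discrete.csv --mask mask.csv --out-weights w.csv
```

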