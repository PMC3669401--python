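# pandanet

Message-passing refinement of gene regulatory networks, integrating three
sources of evidence into one coherent model:

- a **regulatory prior** `W⁰` (TF × gene), e.g. from promoter motif scans;
- a **protein-cooperativity network** `P⁰` (TF × TF), e.g. from physical
  protein–protein interactions;
- a **co-regulation network** `C⁰` (gene × gene), built from Pearson
  correlation of expression profiles.

The package is for computational biologists who already have these tables
(as plain delimited text) and want a condition-specific regulatory network
that is *consistent* across all three kinds of evidence, plus the simulation
and evaluation machinery to quantify how much signal the refinement recovers.

## The model

All seed networks are first z-score normalized along both axes,
`Z = (Z_row + Z_col)/√2`, so edge weights share a common scale.  Agreement
between two weight vectors *x*, *y* is scored with a continuous
Tanimoto-style similarity

```
T(x, y) = ⟨x, y⟩ / sqrt(‖x‖² + ‖y‖² − |⟨x, y⟩|)
```

which is positive when the vectors agree (including shared confident
*absence* of edges) and negative when they disagree.  Each iteration *t*
computes, for every TF *i* and gene *j*:

- responsibility `R_ij = T(P_i·, W_·j)` — agreement between the TFs that
  cooperate with *i* and the TFs that target *j*;
- availability `A_ij = T(W_i·, C_·j)` — agreement between *i*'s targets and
  the genes co-regulated with *j*;

then steps the three networks with update rate α (default 0.05):

```
W ← (1−α) W + α (R + A)/2
P ← (1−α) P + α T(W rows)         (TF–TF similarity of target profiles)
C ← (1−α) C + α T(W columns)      (gene–gene similarity of regulator profiles)
```

The diagonals of the `P`/`C` candidates grow as `n·sd·exp(2αt)`, so
self-similarity progressively dominates and the iteration provably settles;
the loop stops when the mean absolute change of `W` drops below `1e-5`.
Final edge weights are z-score-like: higher means more confidently supported
by the joint evidence.

## Worked example

```python
from pandanet import Panda
from pandanet.fixtures import make_toy_bundle

make_toy_bundle(seed=0, out_dir="toy")        # 4 TFs x 10 genes, 2 modules
model = Panda.from_files("toy/prior.tsv", "toy/ppi.tsv", "toy/expression.tsv")
res = model.fit(alpha=0.05)
print(res.summary())
```

```
Message-passing network refinement
==================================
TFs:                4
genes:              10
alpha:              0.05
tolerance:          1e-05
iterations:         106 (max 500)
converged:          True
final distance:     9.692e-06
W weight range:     [-3.289, 3.327]
degenerate entries: 0
```

The toy bundle plants two regulatory modules (TF1/TF2 → genes g01–g05,
TF3/TF4 → g06–g10) and deliberately corrupts the prior.  The refined network
ranks the planted edges on top — `res.top_edges(3).edges` gives

```
TF2->g02: 3.33   TF2->g04: 3.24   TF2->g03: 3.22
```

and `res.evaluate(gold)` scores AUC 1.0 against the planted gold standard,
including the edge that was removed from the prior.  The same pipeline is
available from the shell:

```bash
panda run --prior toy/prior.tsv --ppi toy/ppi.tsv --expression toy/expression.tsv \
          --out-dir results --trace trace.txt
panda evaluate --pred results/regulatory.txt --gold toy/gold.tsv
```

plus `panda simulate`, `panda study`, `panda compare` and `panda fixtures`
(see `--help` on each).

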